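"""Reading and writing of structures, annotations, molecules and tables.

Annotation files use a small versioned JSON dialect (schema_version 1)
modelled on catalytic-site-atlas-style API output: one reference site
whose residues define the slot order, plus homologous sites aligned
positionally to it (``null`` for a non-aligned residue).  Residues may
optionally embed their atom coordinates, which lets a whole conformer
ensemble live in one plain-text file.

Structure files (mmCIF or PDB) are read with gemmi.  Policy on load:
first model only, hydrogens dropped, and for alternate locations only
the highest-occupancy conformer is kept (ties broken alphabetically by
altloc id) — the superposition maths requires single-conformer sites.
"""

from __future__ import annotations

import json
from pathlib import Path

import gemmi

from .core import (
    ActiveSite,
    AtomRecord,
    CatalyticResidue,
    Experiment,
    FamilyAnnotation,
    SmallMolecule,
)

SCHEMA_VERSION = 1

__all__ = [
    "load_family_annotation",
    "save_family_annotation",
    "load_structure",
    "structure_to_dict",
    "load_small_molecule",
    "save_small_molecule",
    "load_code_table",
    "AnnotationSchemaError",
]


class AnnotationSchemaError(ValueError):
    """Annotation file violates the documented JSON dialect."""


# ---------------------------------------------------------------------------
# family annotation JSON

def _atom_to_json(a: AtomRecord) -> dict:
    return {
        "name": a.name,
        "element": a.element,
        "position": list(a.position),
        "occupancy": a.occupancy,
        "altloc": a.altloc,
    }


def _atom_from_json(d: dict) -> AtomRecord:
    return AtomRecord(
        name=d["name"],
        element=d["element"],
        position=tuple(d["position"]),
        occupancy=d.get("occupancy", 1.0),
        altloc=d.get("altloc", ""),
    )


def _residue_to_json(r: CatalyticResidue | None) -> dict | None:
    if r is None:
        return None
    out = {
        "chain_id": r.chain_id,
        "residue_name": r.residue_name,
        "residue_number": r.residue_number,
        "function_location": r.function_location.value,
        "role": r.role,
        "role_category": r.role_category.value,
        "equiv_group": r.equiv_group,
    }
    if r.atoms:
        out["atoms"] = [_atom_to_json(a) for a in r.atoms]
    return out


def _residue_from_json(d: dict | None) -> CatalyticResidue | None:
    if d is None:
        return None
    try:
        return CatalyticResidue(
            chain_id=d["chain_id"],
            residue_name=d["residue_name"],
            residue_number=int(d["residue_number"]),
            function_location=d.get("function_location", "side_chain"),
            role=d.get("role", ""),
            role_category=d.get("role_category", "reactant"),
            equiv_group=int(d.get("equiv_group", 0)),
            atoms=[_atom_from_json(a) for a in d.get("atoms", [])],
        )
    except KeyError as exc:
        raise AnnotationSchemaError(f"residue record missing key {exc}") from exc


def _site_to_json(s: ActiveSite) -> dict:
    return {
        "site_id": s.site_id,
        "structure_id": s.structure_id,
        "is_reference": s.is_reference,
        "resolution": s.resolution,
        "experiment": s.experiment.value,
        "sequence_accession": s.sequence_accession,
        "residues": [_residue_to_json(r) for r in s.residues],
    }


def _site_from_json(d: dict) -> ActiveSite:
    try:
        return ActiveSite(
            site_id=d["site_id"],
            structure_id=d["structure_id"],
            residues=[_residue_from_json(r) for r in d["residues"]],
            is_reference=d.get("is_reference", False),
            resolution=d.get("resolution"),
            experiment=d.get("experiment", "xray"),
            sequence_accession=d.get("sequence_accession"),
        )
    except KeyError as exc:
        raise AnnotationSchemaError(f"site record missing key {exc}") from exc


def save_family_annotation(family: FamilyAnnotation, path: str | Path) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "family_id": family.family_id,
        "ec_number": family.ec_number,
        "reference": _site_to_json(family.reference_site),
        "homologs": [_site_to_json(s) for s in family.homolog_sites],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_family_annotation(path: str | Path) -> FamilyAnnotation:
    """Load a family annotation file (documented JSON dialect, v1)."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise AnnotationSchemaError(f"malformed JSON in {path}: {exc}") from exc
    if "reference" not in doc:
        raise AnnotationSchemaError(f"{path}: missing required key 'reference'")
    if doc.get("schema_version", SCHEMA_VERSION) != SCHEMA_VERSION:
        raise AnnotationSchemaError(
            f"{path}: unsupported schema_version {doc.get('schema_version')}"
        )
    ref = _site_from_json(doc["reference"])
    if not ref.is_reference:
        raise AnnotationSchemaError(f"{path}: reference site lacks is_reference")
    homologs = [_site_from_json(s) for s in doc.get("homologs", [])]
    n = len(ref.residues)
    for s in homologs:
        if len(s.residues) != n:
            raise AnnotationSchemaError(
                f"{path}: homolog {s.site_id} is not aligned to the reference "
                f"({len(s.residues)} slots vs {n})"
            )
    try:
        return FamilyAnnotation(
            family_id=doc.get("family_id", Path(path).stem),
            reference_site=ref,
            homolog_sites=homologs,
            ec_number=doc.get("ec_number"),
        )
    except ValueError as exc:
        raise AnnotationSchemaError(str(exc)) from exc


# ---------------------------------------------------------------------------
# structures

def _pick_altloc(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Highest-occupancy conformer per atom name; ties alphabetical."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in residue:
        cur = by_name.get(atom.name)
        if cur is None:
            by_name[atom.name] = atom
            continue
        key_new = (atom.occ, -ord(atom.altloc or "~"))
        key_cur = (cur.occ, -ord(cur.altloc or "~"))
        if key_new > key_cur:
            by_name[atom.name] = atom
    return list(by_name.values())


def load_structure(path: str | Path, assembly: int = 1) -> gemmi.Structure:
    """Read an mmCIF or PDB file into a gemmi Structure.

    Keeps only the requested model (NMR multi-model files: model
    ``assembly`` by 1-based index), removes hydrogens, and reduces
    alternate locations to the single highest-occupancy conformer.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: structure contains no models")
    if assembly < 1 or assembly > len(st):
        raise LookupError(f"{path}: model/assembly index {assembly} out of range")
    keep = st[assembly - 1].num
    for i in reversed(range(len(st))):
        if st[i].num != keep:
            del st[i]
    st.remove_hydrogens()
    # collapse altlocs
    for model in st:
        for chain in model:
            for residue in chain:
                chosen = _pick_altloc(residue)
                names = {(a.name, a.altloc) for a in chosen}
                for i in reversed(range(len(residue))):
                    a = residue[i]
                    if (a.name, a.altloc) not in names:
                        del residue[i]
    return st


def structure_to_dict(st: gemmi.Structure) -> dict[str, dict[int, dict]]:
    """Flatten a structure to {chain: {resnum: {"name", "atoms"}}}.

    Only the first model is used; atoms become :class:`AtomRecord`.
    """
    out: dict[str, dict[int, dict]] = {}
    model = st[0]
    for chain in model:
        cdict = out.setdefault(chain.name, {})
        for residue in chain:
            atoms = [
                AtomRecord(
                    name=a.name,
                    element=a.element.name,
                    position=(a.pos.x, a.pos.y, a.pos.z),
                    occupancy=a.occ,
                    altloc=a.altloc or "",
                )
                for a in residue
            ]
            cdict[residue.seqid.num] = {
                "name": residue.name,
                "het": residue.het_flag == "H",
                "atoms": atoms,
            }
    return out


# ---------------------------------------------------------------------------
# small molecules (SDF-like minimal JSON block)

def load_small_molecule(path: str | Path) -> SmallMolecule:
    d = json.loads(Path(path).read_text())
    return small_molecule_from_dict(d)


def small_molecule_from_dict(d: dict) -> SmallMolecule:
    return SmallMolecule(
        comp_id=d["comp_id"],
        atoms=tuple((el, int(i)) for el, i in d["atoms"]),
        bonds=tuple((int(i), int(j), int(o)) for i, j, o in d.get("bonds", [])),
    )


def save_small_molecule(mol: SmallMolecule, path: str | Path) -> None:
    doc = {
        "comp_id": mol.comp_id,
        "atoms": [[el, i] for el, i in mol.atoms],
        "bonds": [[i, j, o] for i, j, o in mol.bonds],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


# ---------------------------------------------------------------------------
# code tables (cofactors, crystallisation artefacts)

def load_code_table(path: str | Path) -> dict[str, str]:
    """TSV of (three-letter comp_id, label); '#' comments allowed."""
    table: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        table[parts[0].strip().upper()] = parts[1].strip() if len(parts) > 1 else ""
    return table
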