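"""Synthetic structures, annotations and conformer ensembles.

Everything downstream of this module is testable without touching a
database: idealized residue geometries (enough to place the backbone
and the functional triad atoms; rotamer realism is out of scope) are
arranged into active sites, perturbed under one of four conformational
presets with the ground truth recorded, and optionally written out as
the same mmCIF/PDB/JSON files the readers consume.

Presets emulate the four family-level behaviours the analysis module
classifies:

* ``rigid``      — per-residue isotropic displacements, sigma 0.1 Å;
* ``flexible``   — per-residue sigma drawn once per family from
                   [0.5, 1.5] Å;
* ``two_state``  — displaced residues toggle between two conformers
                   2.5 Å apart (plus 0.1 Å background noise);
* ``extensive``  — half the residues drift on a per-site random walk
                   (step 0.5 Å), giving a broad, irregular spread.

All randomness flows through one ``numpy`` generator seeded from the
spec, so fixtures are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .core import (
    ActiveSite,
    AtomRecord,
    CatalyticResidue,
    Experiment,
    FamilyAnnotation,
    FunctionLocation,
    RoleCategory,
    SmallMolecule,
)

__all__ = [
    "EnsembleSpec",
    "SiteEnsemble",
    "generate_site_ensemble",
    "AssemblySpec",
    "generate_assembly",
    "make_reference_site",
    "make_residue",
    "write_structure_files",
    "structure_dict_from_sites",
    "example_molecules",
    "RESIDUE_TEMPLATES",
]

# Idealized local geometries: atom name, element, offset (Å) from the
# residue frame origin (CA).  Bond lengths/angles are approximate but
# chemically sensible; triad atoms are always non-collinear.
RESIDUE_TEMPLATES: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    "GLY": [("N", "N", (-1.20, 0.85, 0.0)), ("CA", "C", (0.0, 0.0, 0.0)),
            ("C", "C", (1.25, 0.88, 0.0))],
    "ALA": [("N", "N", (-1.20, 0.85, 0.0)), ("CA", "C", (0.0, 0.0, 0.0)),
            ("C", "C", (1.25, 0.88, 0.0)), ("CB", "C", (0.0, -1.53, 0.0))],
    "SER": [("N", "N", (-1.20, 0.85, 0.0)), ("CA", "C", (0.0, 0.0, 0.0)),
            ("C", "C", (1.25, 0.88, 0.0)), ("CB", "C", (0.0, -1.53, 0.0)),
            ("OG", "O", (0.45, -2.85, 0.45))],
    "CYS": [("N", "N", (-1.20, 0.85, 0.0)), ("CA", "C", (0.0, 0.0, 0.0)),
            ("C", "C", (1.25, 0.88, 0.0)), ("CB", "C", (0.0, -1.53, 0.0)),
            ("SG", "S", (0.55, -3.05, 0.55))],
    "THR": [("N", "N", (-1.20, 0.85, 0.0)), ("CA", "C", (0.0, 0.0, 0.0)),
            ("C", "C", (1.25, 0.88, 0.0)), ("CB", "C", (0.0, -1.53, 0.0)),
            ("OG1", "O", (0.50, -2.82, 0.50)), ("CG2", "C", (-1.30, -2.20, -0.40))],
    "ASP": [("N", "N", (-1.20, 0.85, 0.0)), ("CA", "C", (0.0, 0.0, 0.0)),
            ("C", "C", (1.25, 0.88, 0.0)), ("CB", "C", (0.0, -1.53, 0.0)),
            ("CG", "C", (0.05, -2.95, 0.20)),
            ("OD1", "O", (1.10, -3.62, 0.30)), ("OD2", "O", (-1.08, -3.58, 0.25))],
    "ASN": [("N", "N", (-1.20, 0.85, 0.0)), ("CA", "C", (0.0, 0.0, 0.0)),
            ("C", "C", (1.25, 0.88, 0.0)), ("CB", "C", (0.0, -1.53, 0.0)),
            ("CG", "C", (0.05, -2.95, 0.20)),
            ("OD1", "O", (1.10, -3.62, 0.30)), ("ND2", "N", (-1.08, -3.58, 0.25))],
    "GLU": [("N", "N", (-1.20, 0.85, 0.0)), ("CA", "C", (0.0, 0.0, 0.0)),
            ("C", "C", (1.25, 0.88, 0.0)), ("CB", "C", (0.0, -1.53, 0.0)),
            ("CG", "C", (0.05, -2.95, 0.20)), ("CD", "C", (0.10, -4.40, 0.40)),
            ("OE1", "O", (1.15, -5.08, 0.50)), ("OE2", "O", (-1.02, -5.05, 0.45))],
    "GLN": [("N", "N", (-1.20, 0.85, 0.0)), ("CA", "C", (0.0, 0.0, 0.0)),
            ("C", "C", (1.25, 0.88, 0.0)), ("CB", "C", (0.0, -1.53, 0.0)),
            ("CG", "C", (0.05, -2.95, 0.20)), ("CD", "C", (0.10, -4.40, 0.40)),
            ("OE1", "O", (1.15, -5.08, 0.50)), ("NE2", "N", (-1.02, -5.05, 0.45))],
    "HIS": [("N", "N", (-1.20, 0.85, 0.0)), ("CA", "C", (0.0, 0.0, 0.0)),
            ("C", "C", (1.25, 0.88, 0.0)), ("CB", "C", (0.0, -1.53, 0.0)),
            ("CG", "C", (0.05, -2.95, 0.20)),
            ("ND1", "N", (1.12, -3.75, 0.30)), ("CD2", "C", (-1.02, -3.80, 0.28)),
            ("CE1", "C", (0.72, -5.02, 0.45)), ("NE2", "N", (-0.58, -5.06, 0.42))],
    "ARG": [("N", "N", (-1.20, 0.85, 0.0)), ("CA", "C", (0.0, 0.0, 0.0)),
            ("C", "C", (1.25, 0.88, 0.0)), ("CB", "C", (0.0, -1.53, 0.0)),
            ("CG", "C", (0.05, -2.95, 0.20)), ("CD", "C", (0.55, -4.30, 0.35)),
            ("NE", "N", (-0.15, -5.45, 0.55)), ("CZ", "C", (0.10, -6.72, 0.75)),
            ("NH1", "N", (1.28, -7.32, 0.85)), ("NH2", "N", (-0.92, -7.45, 0.82))],
    "LYS": [("N", "N", (-1.20, 0.85, 0.0)), ("CA", "C", (0.0, 0.0, 0.0)),
            ("C", "C", (1.25, 0.88, 0.0)), ("CB", "C", (0.0, -1.53, 0.0)),
            ("CG", "C", (0.05, -2.95, 0.20)), ("CD", "C", (0.62, -4.28, 0.30)),
            ("CE", "C", (-0.28, -5.55, 0.58)), ("NZ", "N", (0.48, -6.85, 0.38))],
    "TYR": [("N", "N", (-1.20, 0.85, 0.0)), ("CA", "C", (0.0, 0.0, 0.0)),
            ("C", "C", (1.25, 0.88, 0.0)), ("CB", "C", (0.0, -1.53, 0.0)),
            ("CG", "C", (0.05, -2.95, 0.20)),
            ("CD1", "C", (1.15, -3.68, 0.28)), ("CD2", "C", (-1.05, -3.72, 0.25)),
            ("CE1", "C", (1.12, -5.05, 0.42)), ("CE2", "C", (-1.08, -5.10, 0.40)),
            ("CZ", "C", (0.02, -5.80, 0.50)), ("OH", "O", (0.0, -7.15, 0.62))],
    "PHE": [("N", "N", (-1.20, 0.85, 0.0)), ("CA", "C", (0.0, 0.0, 0.0)),
            ("C", "C", (1.25, 0.88, 0.0)), ("CB", "C", (0.0, -1.53, 0.0)),
            ("CG", "C", (0.05, -2.95, 0.20)),
            ("CD1", "C", (1.15, -3.68, 0.28)), ("CD2", "C", (-1.05, -3.72, 0.25)),
            ("CE1", "C", (1.12, -5.05, 0.42)), ("CE2", "C", (-1.08, -5.10, 0.40)),
            ("CZ", "C", (0.02, -5.80, 0.50))],
    "VAL": [("N", "N", (-1.20, 0.85, 0.0)), ("CA", "C", (0.0, 0.0, 0.0)),
            ("C", "C", (1.25, 0.88, 0.0)), ("CB", "C", (0.0, -1.53, 0.0)),
            ("CG1", "C", (1.22, -2.32, 0.45)), ("CG2", "C", (-1.18, -2.35, 0.42))],
    "LEU": [("N", "N", (-1.20, 0.85, 0.0)), ("CA", "C", (0.0, 0.0, 0.0)),
            ("C", "C", (1.25, 0.88, 0.0)), ("CB", "C", (0.0, -1.53, 0.0)),
            ("CG", "C", (0.05, -2.95, 0.20)),
            ("CD1", "C", (1.20, -3.65, 0.38)), ("CD2", "C", (-1.12, -3.68, 0.35))],
    "ILE": [("N", "N", (-1.20, 0.85, 0.0)), ("CA", "C", (0.0, 0.0, 0.0)),
            ("C", "C", (1.25, 0.88, 0.0)), ("CB", "C", (0.0, -1.53, 0.0)),
            ("CG1", "C", (1.22, -2.30, 0.42)), ("CG2", "C", (-1.15, -2.32, 0.45)),
            ("CD1", "C", (1.35, -3.75, 0.55))],
    "MET": [("N", "N", (-1.20, 0.85, 0.0)), ("CA", "C", (0.0, 0.0, 0.0)),
            ("C", "C", (1.25, 0.88, 0.0)), ("CB", "C", (0.0, -1.53, 0.0)),
            ("CG", "C", (0.05, -2.95, 0.20)), ("SD", "S", (0.68, -4.42, 0.40)),
            ("CE", "C", (-0.35, -5.72, 0.65))],
    "TRP": [("N", "N", (-1.20, 0.85, 0.0)), ("CA", "C", (0.0, 0.0, 0.0)),
            ("C", "C", (1.25, 0.88, 0.0)), ("CB", "C", (0.0, -1.53, 0.0)),
            ("CG", "C", (0.05, -2.95, 0.20)),
            ("CD1", "C", (1.15, -3.70, 0.30)), ("CD2", "C", (-1.05, -3.75, 0.28)),
            ("NE1", "N", (0.82, -5.00, 0.45)), ("CE2", "C", (-0.55, -5.05, 0.42))],
}

# default residue make-up of generated sites, cycled to n_residues
DEFAULT_RESIDUE_CYCLE = ("SER", "HIS", "ASP", "GLU", "ARG", "LYS",
                         "THR", "TYR", "ASN", "GLN")
DEFAULT_ROLES = {
    "SER": ("nucleophile", RoleCategory.REACTANT),
    "HIS": ("proton shuttle", RoleCategory.REACTANT),
    "ASP": ("electrostatic stabiliser", RoleCategory.INTERACTION),
    "GLU": ("proton acceptor", RoleCategory.REACTANT),
    "ARG": ("electrostatic stabiliser", RoleCategory.SPECTATOR),
    "LYS": ("electrostatic stabiliser", RoleCategory.SPECTATOR),
    "THR": ("hydrogen bond donor", RoleCategory.INTERACTION),
    "TYR": ("proton donor", RoleCategory.REACTANT),
    "ASN": ("oxyanion hole", RoleCategory.INTERACTION),
    "GLN": ("steric role", RoleCategory.SPECTATOR),
}


def _rot_z(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via QR of a Gaussian matrix."""
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def _remove_rigid_component(shifts: np.ndarray, coms: np.ndarray) -> np.ndarray:
    """Subtract the best-fit rigid motion (translation + infinitesimal
    rotation about the site centroid) from a per-residue shift field.

    A net rigid drift is not a perturbation of site geometry — the
    superposition removes it exactly — so recorded ground-truth
    displacements must exclude it or they would overstate the true
    deformation.
    """
    c = coms - coms.mean(axis=0)
    n = len(shifts)
    A = np.zeros((3 * n, 6))
    for s in range(n):
        A[3 * s:3 * s + 3, :3] = np.eye(3)
        x, y, z = c[s]
        A[3 * s:3 * s + 3, 3:] = np.array([[0, z, -y], [-z, 0, x], [y, -x, 0]])
    x, *_ = np.linalg.lstsq(A, shifts.ravel(), rcond=None)
    return shifts - (A @ x).reshape(n, 3)


def make_residue(
    residue_name: str,
    residue_number: int,
    chain_id: str = "A",
    origin: np.ndarray | tuple = (0.0, 0.0, 0.0),
    rotation: np.ndarray | None = None,
    function_location: FunctionLocation = FunctionLocation.SIDE_CHAIN,
    role: str | None = None,
    role_category: RoleCategory | None = None,
    equiv_group: int = 0,
) -> CatalyticResidue:
    """Instantiate one template residue at a position/orientation."""
    name = residue_name.upper()
    tpl = RESIDUE_TEMPLATES[name]
    R = np.eye(3) if rotation is None else rotation
    o = np.asarray(origin, dtype=float)
    dflt_role, dflt_cat = DEFAULT_ROLES.get(name, ("catalytic", RoleCategory.REACTANT))
    atoms = [
        AtomRecord(name=an, element=el, position=tuple(R @ np.asarray(p) + o))
        for an, el, p in tpl
    ]
    return CatalyticResidue(
        chain_id=chain_id,
        residue_name=name,
        residue_number=residue_number,
        function_location=function_location,
        role=role if role is not None else dflt_role,
        role_category=role_category if role_category is not None else dflt_cat,
        equiv_group=equiv_group,
        atoms=atoms,
    )


def make_reference_site(
    n_residues: int = 6,
    residue_names: tuple[str, ...] | None = None,
    ring_radius: float = 7.0,
    site_id: str = "ref",
    structure_id: str = "SYNTH_REF",
    chain_id: str = "A",
    sequence_accession: str | None = "ACC_REF",
) -> ActiveSite:
    """An idealized site: residues on a ring, side chains pointing in."""
    if residue_names is None:
        residue_names = tuple(
            DEFAULT_RESIDUE_CYCLE[i % len(DEFAULT_RESIDUE_CYCLE)]
            for i in range(n_residues)
        )
    residues: list[CatalyticResidue | None] = []
    for i, name in enumerate(residue_names):
        theta = 2.0 * np.pi * i / max(len(residue_names), 1)
        origin = ring_radius * np.array([np.cos(theta), np.sin(theta), 0.0])
        # rotate so the local -y (side-chain direction) faces the ring center
        rot = _rot_z(theta + np.pi / 2.0)
        residues.append(make_residue(
            name, residue_number=10 + 2 * i, chain_id=chain_id,
            origin=origin, rotation=rot,
        ))
    return ActiveSite(
        site_id=site_id,
        structure_id=structure_id,
        residues=residues,
        is_reference=True,
        resolution=1.5,
        experiment=Experiment.SYNTHETIC,
        sequence_accession=sequence_accession,
    )


@dataclass
class EnsembleSpec:
    """Conditions for one synthetic conformer ensemble."""

    preset: str = "rigid"            # rigid | flexible | two_state | extensive
    n_sites: int = 50
    n_residues: int = 6
    sigma: float | None = None       # background / preset noise (Å)
    two_state_gap: float = 2.5       # conformer separation (Å)
    walk_step: float = 0.5           # extensive random-walk step (Å)
    displaced_slots: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.preset not in ("rigid", "flexible", "two_state", "extensive"):
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.n_sites < 2:
            raise ValueError("n_sites must be >= 2")
        if self.sigma is not None and self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass
class SiteEnsemble:
    """A generated family plus its ground truth."""

    spec: EnsembleSpec
    family: FamilyAnnotation
    displacements: np.ndarray      # (n_sites, n_slots) true |shift| per residue
    states: np.ndarray | None = None  # two_state: 0/1 conformer per site


def generate_site_ensemble(spec: EnsembleSpec) -> SiteEnsemble:
    """Generate a family of homologous sites under one preset.

    Each homologue is the reference under a random rigid motion plus
    per-residue displacement vectors drawn per the preset; true
    per-slot displacement magnitudes (before the rigid motion, which
    superposition removes) are recorded as ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    ref = make_reference_site(n_residues=spec.n_residues)
    n_slots = len(ref.residues)
    ref_coms = np.stack([r.center_of_mass() for r in ref.residues])
    slots = list(range(n_slots))
    displaced = (
        list(spec.displaced_slots) if spec.displaced_slots is not None
        else slots[: max(1, n_slots // 3)] if spec.preset == "two_state"
        else slots[: n_slots // 2] if spec.preset == "extensive"
        else []
    )

    base_sigma = {"rigid": 0.1, "two_state": 0.1}.get(spec.preset, 0.0)
    if spec.sigma is not None:
        base_sigma = spec.sigma
    flexible_sigmas = rng.uniform(0.5, 1.5, size=n_slots)
    if spec.preset == "flexible" and spec.sigma is not None:
        flexible_sigmas = np.full(n_slots, spec.sigma)
    # one fixed offset direction per displaced slot (two_state)
    gap_dirs = rng.normal(size=(n_slots, 3))
    gap_dirs /= np.linalg.norm(gap_dirs, axis=1, keepdims=True)
    walk = np.zeros((n_slots, 3))  # running displacement for `extensive`

    homologs: list[ActiveSite] = []
    disp = np.zeros((spec.n_sites, n_slots))
    states = rng.integers(0, 2, size=spec.n_sites) if spec.preset == "two_state" else None
    for k in range(spec.n_sites):
        shifts = np.zeros((n_slots, 3))
        if spec.preset == "rigid":
            shifts = rng.normal(0.0, base_sigma, size=(n_slots, 3))
        elif spec.preset == "flexible":
            shifts = rng.normal(size=(n_slots, 3)) * flexible_sigmas[:, None]
        elif spec.preset == "two_state":
            shifts = rng.normal(0.0, base_sigma, size=(n_slots, 3))
            if states[k] == 1:
                for s in displaced:
                    shifts[s] += spec.two_state_gap * gap_dirs[s]
        elif spec.preset == "extensive":
            for s in displaced:
                walk[s] += rng.normal(0.0, spec.walk_step, size=3)
            shifts = rng.normal(0.0, 0.1, size=(n_slots, 3))
            shifts[displaced] += walk[displaced]
        shifts = _remove_rigid_component(shifts, ref_coms)
        disp[k] = np.linalg.norm(shifts, axis=1)

        R = _random_rotation(rng)
        t = rng.uniform(-20.0, 20.0, size=3)
        residues: list[CatalyticResidue | None] = []
        for s, r in enumerate(ref.residues):
            atoms = [
                AtomRecord(
                    name=a.name, element=a.element,
                    position=tuple(R @ (a.xyz + shifts[s]) + t),
                )
                for a in r.atoms
            ]
            residues.append(CatalyticResidue(
                chain_id=r.chain_id, residue_name=r.residue_name,
                residue_number=r.residue_number,
                function_location=r.function_location,
                role=r.role, role_category=r.role_category,
                equiv_group=r.equiv_group, atoms=atoms,
            ))
        homologs.append(ActiveSite(
            site_id=f"{spec.preset}_{k:03d}",
            structure_id=f"SYNTH_{k:03d}",
            residues=residues,
            resolution=1.5,
            experiment=Experiment.SYNTHETIC,
            sequence_accession=ref.sequence_accession,
        ))

    family = FamilyAnnotation(
        family_id=f"FAM_{spec.preset.upper()}_{spec.seed}",
        reference_site=ref,
        homolog_sites=homologs,
        ec_number="1.1.1.1",
    )
    return SiteEnsemble(spec=spec, family=family, displacements=disp, states=states)


# ---------------------------------------------------------------------------
# assemblies

@dataclass
class LigandPlacement:
    """A hetero component placed relative to a site centroid."""

    comp_id: str
    offset: tuple[float, float, float]
    atoms: tuple[tuple[str, str, tuple[float, float, float]], ...] | None = None
    # None -> single atom named after comp_id (element guessed from code)


@dataclass
class AssemblySpec:
    n_chains: int = 2
    n_residues: int = 3
    interface: bool = False
    chain_separation: float = 40.0
    ligands: tuple[LigandPlacement, ...] = ()
    decoy_offset: float | None = None   # plant a far-away catalytic residue copy
    seed: int = 0


# minimal 3D geometries for a few hetero components used in fixtures
_HET_GEOMETRIES: dict[str, tuple[tuple[str, str, tuple[float, float, float]], ...]] = {
    "HOH": (("O", "O", (0.0, 0.0, 0.0)),),
    "ZN": (("ZN", "ZN", (0.0, 0.0, 0.0)),),
    "GOL": (("C1", "C", (0.0, 0.0, 0.0)), ("O1", "O", (1.25, 0.6, 0.0)),
            ("C2", "C", (-0.8, 1.2, 0.2)), ("O2", "O", (-2.1, 0.9, 0.4)),
            ("C3", "C", (-0.5, 2.6, 0.1)), ("O3", "O", (0.8, 2.9, -0.2))),
    "HEM": (("FE", "FE", (0.0, 0.0, 0.0)),
            ("NA", "N", (2.0, 0.0, 0.0)), ("NB", "N", (0.0, 2.0, 0.0)),
            ("NC", "N", (-2.0, 0.0, 0.0)), ("ND", "N", (0.0, -2.0, 0.0)),
            ("C1A", "C", (3.0, 1.0, 0.1)), ("C1B", "C", (-1.0, 3.0, 0.1)),
            ("C1C", "C", (-3.0, -1.0, 0.1)), ("C1D", "C", (1.0, -3.0, 0.1))),
}


def _hetero_atoms(p: LigandPlacement) -> list[AtomRecord]:
    geom = p.atoms if p.atoms is not None else _HET_GEOMETRIES.get(
        p.comp_id, (("X1", p.comp_id[:2].capitalize(), (0.0, 0.0, 0.0)),)
    )
    off = np.asarray(p.offset, dtype=float)
    return [
        AtomRecord(name=an, element=el, position=tuple(np.asarray(xyz) + off))
        for an, el, xyz in geom
    ]


def generate_assembly(
    spec: AssemblySpec,
    out_dir: str | Path | None = None,
) -> dict:
    """Build a multi-chain assembly exercising site reconstruction and
    ligand detection.

    Default mode: each chain carries one complete copy of the site,
    chains separated by ``chain_separation`` Å (a homodimer yields two
    single-chain sites).  ``interface=True`` builds one symmetric site
    straddling two chains, with paired equivalence groups as in a
    retroviral-protease dimer.  ``decoy_offset`` plants an extra copy
    of the first catalytic residue far from any site in the last
    chain, to exercise the sanity rules.

    Returns a dict with the reference site, the per-chain structure
    dictionary, the expected number of sites, and (if ``out_dir``)
    paths of the written PDB/mmCIF/annotation files.
    """
    rng = np.random.default_rng(spec.seed)
    chain_ids = [chr(ord("A") + i) for i in range(spec.n_chains)]
    names = tuple(DEFAULT_RESIDUE_CYCLE[i % len(DEFAULT_RESIDUE_CYCLE)]
                  for i in range(spec.n_residues))

    structure: dict[str, dict[int, dict]] = {c: {} for c in chain_ids}
    ref_residues: list[CatalyticResidue | None] = []
    expected_sites = spec.n_chains

    if spec.interface:
        if spec.n_chains != 2:
            raise ValueError("interface mode needs exactly 2 chains")
        expected_sites = 1
        # two equivalence-group copies of each residue around one center
        for g, chain in enumerate(chain_ids):
            for i, name in enumerate(names):
                theta = np.pi * (2 * i + g * len(names)) / (2 * len(names)) * 2
                origin = 6.0 * np.array([np.cos(theta), np.sin(theta), 0.3 * g])
                res = make_residue(
                    name, residue_number=10 + i, chain_id=chain,
                    origin=origin, rotation=_rot_z(theta + np.pi / 2),
                    equiv_group=g,
                )
                if g == 0:
                    ref_residues.append(res)
                structure[chain][res.residue_number] = {
                    "name": name, "het": False, "atoms": list(res.atoms),
                }
        # reference lists both equivalence-group copies, aligned slots
        second = []
        for i, name in enumerate(names):
            theta = np.pi * (2 * i + len(names)) / (2 * len(names)) * 2
            origin = 6.0 * np.array([np.cos(theta), np.sin(theta), 0.3])
            second.append(make_residue(
                name, residue_number=10 + i, chain_id="B",
                origin=origin, rotation=_rot_z(theta + np.pi / 2),
                equiv_group=1,
            ))
        ref_residues = ref_residues + second
        site_centroids = [np.zeros(3)]
    else:
        site_centroids = []
        for ci, chain in enumerate(chain_ids):
            offset = np.array([spec.chain_separation * ci, 0.0, 0.0])
            site_centroids.append(offset)
            for i, name in enumerate(names):
                theta = 2.0 * np.pi * i / len(names)
                origin = offset + 7.0 * np.array([np.cos(theta), np.sin(theta), 0.0])
                res = make_residue(
                    name, residue_number=10 + 2 * i, chain_id=chain,
                    origin=origin, rotation=_rot_z(theta + np.pi / 2),
                )
                if ci == 0:
                    ref_residues.append(res)
                structure[chain][res.residue_number] = {
                    "name": name, "het": False, "atoms": list(res.atoms),
                }

    if spec.decoy_offset is not None:
        # Emulate broken residue numbering: the last chain loses its
        # copy of the first catalytic residue, and an equivalent decoy
        # sits in a spurious chain far away.  The clusterer can only
        # fill that slot with the decoy, so the 3x sanity rule fires.
        name = names[0]
        num = 10  # names[0] residue number in either layout
        structure[chain_ids[-1]].pop(num, None)
        far = np.array([0.0, spec.decoy_offset, 0.0])
        res = make_residue(name, residue_number=num, chain_id="Z", origin=far)
        structure.setdefault("Z", {})[num] = {
            "name": name, "het": False, "atoms": list(res.atoms),
        }

    # hetero components, placed relative to each site centroid
    het_num = 900
    for centroid in site_centroids:
        for p in spec.ligands:
            atoms = _hetero_atoms(LigandPlacement(
                comp_id=p.comp_id,
                offset=tuple(np.asarray(p.offset) + centroid),
                atoms=p.atoms,
            ))
            structure.setdefault("L", {})[het_num] = {
                "name": p.comp_id, "het": True, "atoms": atoms,
            }
            het_num += 1

    reference = ActiveSite(
        site_id="ref",
        structure_id="SYNTH_ASM",
        residues=ref_residues,
        is_reference=True,
        resolution=1.5,
        experiment=Experiment.SYNTHETIC,
        sequence_accession="ACC_ASM",
    )
    out = {
        "reference": reference,
        "structure": structure,
        "expected_sites": expected_sites,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pdb, cif = write_structure_files(structure, out_dir / "assembly")
        from .io import save_family_annotation  # local import avoids cycle

        ann = out_dir / "annotation.json"
        save_family_annotation(
            FamilyAnnotation(family_id="FAM_ASM", reference_site=reference,
                             ec_number="3.4.23.16"),
            ann,
        )
        out.update({"pdb": pdb, "cif": cif, "annotation": ann})
    return out


def structure_dict_from_sites(sites: list[ActiveSite]) -> dict[str, dict[int, dict]]:
    """Assemble a structure dictionary from explicit sites (testing aid)."""
    structure: dict[str, dict[int, dict]] = {}
    for site in sites:
        for _, r in site.filled():
            structure.setdefault(r.chain_id, {})[r.residue_number] = {
                "name": r.residue_name, "het": False, "atoms": list(r.atoms),
            }
    return structure


def write_structure_files(
    structure: dict[str, dict[int, dict]],
    stem: str | Path,
) -> tuple[Path, Path]:
    """Write the structure dictionary as sibling .pdb and .cif files."""
    st = gemmi.Structure()
    st.name = "SYNTH"
    model = gemmi.Model("1")
    for chain_id in sorted(structure):
        chain = gemmi.Chain(chain_id)
        for resnum in sorted(structure[chain_id]):
            rec = structure[chain_id][resnum]
            res = gemmi.Residue()
            res.name = rec["name"]
            res.seqid = gemmi.SeqId(resnum, " ")
            res.het_flag = "H" if rec.get("het") else "A"
            for a in rec["atoms"]:
                atom = gemmi.Atom()
                atom.name = a.name
                atom.element = gemmi.Element(a.element)
                atom.pos = gemmi.Position(*a.position)
                atom.occ = a.occupancy
                atom.altloc = a.altloc or "\0"
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    stem = Path(stem)
    pdb_path = stem.with_suffix(".pdb")
    cif_path = stem.with_suffix(".cif")
    st.write_pdb(str(pdb_path))
    doc = st.make_mmcif_document()
    doc.write_file(str(cif_path))
    return pdb_path, cif_path


# ---------------------------------------------------------------------------
# small-molecule fixtures

def example_molecules() -> dict[str, SmallMolecule]:
    """Chemical graphs for fixtures: hydrocarbon/alcohol pairs with
    known overlap scores, plus common additives and cognates."""
    return {
        "ETH": SmallMolecule("ETH", atoms=(("C", 0), ("C", 1)),
                             bonds=((0, 1, 1),)),
        "EOH": SmallMolecule("EOH", atoms=(("C", 0), ("C", 1), ("O", 2)),
                             bonds=((0, 1, 1), (1, 2, 1))),
        "MOH": SmallMolecule("MOH", atoms=(("C", 0), ("O", 1)),
                             bonds=((0, 1, 1),)),
        "GOL": SmallMolecule(
            "GOL",
            atoms=(("C", 0), ("C", 1), ("C", 2), ("O", 3), ("O", 4), ("O", 5)),
            bonds=((0, 1, 1), (1, 2, 1), (0, 3, 1), (1, 4, 1), (2, 5, 1)),
        ),
        "PYR": SmallMolecule(  # pyruvate: CH3-CO-COO
            "PYR",
            atoms=(("C", 0), ("C", 1), ("C", 2), ("O", 3), ("O", 4), ("O", 5)),
            bonds=((0, 1, 1), (1, 2, 1), (1, 3, 2), (2, 4, 2), (2, 5, 1)),
        ),
        "LAC": SmallMolecule(  # lactate: CH3-CHOH-COO
            "LAC",
            atoms=(("C", 0), ("C", 1), ("C", 2), ("O", 3), ("O", 4), ("O", 5)),
            bonds=((0, 1, 1), (1, 2, 1), (1, 3, 1), (2, 4, 2), (2, 5, 1)),
        ),
        "ZN": SmallMolecule("ZN", atoms=(("ZN", 0),), bonds=()),
        "SF4": SmallMolecule(  # cubane-like FeS cluster fragment
            "SF4",
            atoms=(("FE", 0), ("FE", 1), ("S", 2), ("S", 3)),
            bonds=((0, 2, 1), (0, 3, 1), (1, 2, 1), (1, 3, 1)),
        ),
    }
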