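"""Ligand detection, chemical classification and centrality scoring.

Components near a site are found with a k-d tree radius search around
every catalytic atom, with pseudo-centers interpolated between distant
residues so that a ligand sitting in the gap of a spread-out site is
not missed.  Each component is then classified:

* **substrate-like** — scores at least 60% chemical similarity to a
  cognate reactant or product of the enzyme's native reaction;
* **cofactor** — its three-letter code appears in the cofactor table
  (ionic, non-ionic and single-atom components);
* **artefact** — a known crystallisation additive that fails a 30%
  similarity bar against every cognate component;
* **uncertain** — anything else.

The similarity measure is an atom-overlap score on the maximum common
connected substructure of the two chemical graphs (elements must
match, bond orders are ignored):

    score = |MCS| / (|A| + |B| - |MCS|)

It is undefined (``None``) for polymers and single-atom components.
The MCS search engine is pluggable; the default is an exact
branch-and-bound over connected, induced, element-matched common
subgraphs, exhaustive for the small molecules enzymes bind.
"""

from __future__ import annotations

from dataclasses import replace
from importlib import resources
from typing import Callable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .core import ActiveSite, AtomRecord, LigandClass, LigandRecord, Proximity, SmallMolecule
from .io import load_code_table

__all__ = [
    "parity_similarity",
    "mcs_size",
    "exact_mcs_engine",
    "find_adjacent_ligands",
    "find_distal_components",
    "classify_ligand",
    "ligand_centrality",
    "default_cofactor_table",
    "default_artefact_table",
    "molecule_graph",
]

SUBSTRATE_SIMILARITY = 0.6   # native-like ligand bar
ARTEFACT_SIMILARITY = 0.3    # additive must fail this vs every cognate
ADJACENT_RADIUS = 3.0        # Å around each catalytic atom
DISTAL_RADIUS = 30.0         # Å around the site centroid
PSEUDO_CENTER_GAP = 6.0      # Å; residue pairs further apart get a midpoint center

MCSEngine = Callable[[nx.Graph, nx.Graph], int]


def default_cofactor_table() -> dict[str, str]:
    with resources.as_file(resources.files("sitevar.data") / "cofactors.tsv") as p:
        return load_code_table(p)


def default_artefact_table() -> dict[str, str]:
    with resources.as_file(resources.files("sitevar.data") / "artefacts.tsv") as p:
        return load_code_table(p)


# ---------------------------------------------------------------------------
# chemical similarity

def molecule_graph(mol: SmallMolecule) -> nx.Graph:
    g = nx.Graph()
    for el, i in mol.atoms:
        g.add_node(i, element=el.upper())
    for i, j, _ in mol.bonds:
        g.add_edge(i, j)
    return g


def exact_mcs_engine(ga: nx.Graph, gb: nx.Graph) -> int:
    """Exact maximum common connected induced subgraph size.

    McGregor-style branch-and-bound: a partial atom mapping is grown
    one pair at a time, requiring equal elements, induced edge
    consistency with every mapped pair, and (beyond the first pair)
    adjacency to the mapped set.
    """
    if ga.number_of_nodes() > gb.number_of_nodes():
        ga, gb = gb, ga
    na = ga.number_of_nodes()
    best = 0

    a_nodes = list(ga.nodes)
    b_nodes = list(gb.nodes)

    def extend(mapping: dict, used_b: set, excluded: frozenset) -> None:
        nonlocal best
        best = max(best, len(mapping))
        # candidates: unmapped, unexcluded A-atoms adjacent to the mapped set
        frontier = {
            n for a in mapping for n in ga.neighbors(a)
            if n not in mapping and n not in excluded
        }
        if not frontier:
            return
        # bound: mapping every still-available A atom cannot beat best
        if na - len(excluded) <= best:
            return
        a = min(frontier)  # deterministic branch order
        # option 1: map a to each consistent b
        for b in b_nodes:
            if b in used_b:
                continue
            if gb.nodes[b]["element"] != ga.nodes[a]["element"]:
                continue
            ok = True
            for a2, b2 in mapping.items():
                if ga.has_edge(a, a2) != gb.has_edge(b, b2):
                    ok = False
                    break
            if ok:
                mapping[a] = b
                extend(mapping, used_b | {b}, excluded)
                del mapping[a]
        # option 2: leave a out of the common subgraph
        extend(mapping, used_b, excluded | {a})

    for a0 in a_nodes:
        for b0 in b_nodes:
            if ga.nodes[a0]["element"] == gb.nodes[b0]["element"]:
                extend({a0: b0}, {b0}, frozenset())
    return best


def mcs_size(a: SmallMolecule, b: SmallMolecule, engine: MCSEngine | None = None) -> int:
    engine = engine or exact_mcs_engine
    return engine(molecule_graph(a), molecule_graph(b))


def parity_similarity(
    a: SmallMolecule,
    b: SmallMolecule,
    engine: MCSEngine | None = None,
) -> float | None:
    """Atom-overlap similarity of two small molecules in [0, 1].

    ``None`` for single-atom components (no topology to compare);
    polymers never reach this function (they carry no chemical graph).
    """
    if a.n_atoms < 2 or b.n_atoms < 2:
        return None
    m = mcs_size(a, b, engine)
    return m / (a.n_atoms + b.n_atoms - m)


# ---------------------------------------------------------------------------
# spatial searches

def _component_instances(
    structure_dict: Mapping[str, Mapping[int, dict]],
    site_chains: set[str],
    catalytic_keys: set[tuple[str, int]],
) -> tuple[list[tuple[str, int, str, list[AtomRecord]]], list[tuple[str, int, list[AtomRecord]]]]:
    """Split the structure into hetero component instances and foreign
    polymer residues (chains not contributing to the site)."""
    hetero = []
    polymer = []
    for chain_id, residues in structure_dict.items():
        for resnum, rec in residues.items():
            if (chain_id, resnum) in catalytic_keys:
                continue
            if rec.get("het"):
                hetero.append((chain_id, resnum, rec["name"].upper(), rec["atoms"]))
            elif chain_id not in site_chains:
                polymer.append((chain_id, resnum, rec["atoms"]))
    return hetero, polymer


def _search_centers(site: ActiveSite, gap: float = PSEUDO_CENTER_GAP) -> np.ndarray:
    centers = [a.xyz for _, r in site.filled() for a in r.atoms]
    coms = site.residue_coms()
    slots = sorted(coms)
    for ki, i in enumerate(slots):
        for j in slots[ki + 1:]:
            if np.linalg.norm(coms[i] - coms[j]) > gap:
                centers.append((coms[i] + coms[j]) / 2.0)
    return np.asarray(centers)


def find_adjacent_ligands(
    site: ActiveSite,
    structure_dict: Mapping[str, Mapping[int, dict]],
    radius: float = ADJACENT_RADIUS,
    pseudo_center_gap: float = PSEUDO_CENTER_GAP,
) -> list[LigandRecord]:
    """Components with any atom within ``radius`` of any search center.

    Search centers are every catalytic atom plus one pseudo-center at
    the mean center of mass of each residue pair separated by more
    than ``pseudo_center_gap`` (so ligands in the gap between distant
    residues are still captured).  Polymer residues from foreign
    chains are merged into a single POLYMER record per chain.
    """
    centers = _search_centers(site, pseudo_center_gap)
    tree = cKDTree(centers)
    site_chains = {r.chain_id for _, r in site.filled()}
    catalytic_keys = {(r.chain_id, r.residue_number) for _, r in site.filled()}
    hetero, polymer = _component_instances(structure_dict, site_chains, catalytic_keys)

    def captured(atoms: Sequence[AtomRecord]) -> bool:
        pts = np.asarray([a.xyz for a in atoms])
        return any(len(h) > 0 for h in tree.query_ball_point(pts, r=radius))

    records: list[LigandRecord] = []
    for chain_id, resnum, comp_id, atoms in hetero:
        if captured(atoms):
            records.append(LigandRecord(
                comp_id=comp_id, proximity=Proximity.ADJACENT,
                chain_id=chain_id, residue_number=resnum, atoms=list(atoms),
            ))
    by_chain: dict[str, list[AtomRecord]] = {}
    for chain_id, resnum, atoms in polymer:
        if captured(atoms):
            by_chain.setdefault(chain_id, []).extend(atoms)
    for chain_id, atoms in sorted(by_chain.items()):
        records.append(LigandRecord(
            comp_id="POLYMER", proximity=Proximity.ADJACENT,
            chain_id=chain_id, atoms=atoms,
        ))
    return records


def find_distal_components(
    site: ActiveSite,
    structure_dict: Mapping[str, Mapping[int, dict]],
    radius: float = DISTAL_RADIUS,
    exclude: Sequence[LigandRecord] = (),
    cofactor_table: Mapping[str, str] | None = None,
    cognate_components: Sequence[SmallMolecule] = (),
    component_library: Mapping[str, SmallMolecule] | None = None,
    engine: MCSEngine | None = None,
) -> list[LigandRecord]:
    """Cofactor-like and substrate-like hetero components within
    ``radius`` of the site centroid, excluding already-adjacent ones."""
    cofactor_table = default_cofactor_table() if cofactor_table is None else cofactor_table
    component_library = component_library or {}
    centroid = site.centroid()
    site_chains = {r.chain_id for _, r in site.filled()}
    catalytic_keys = {(r.chain_id, r.residue_number) for _, r in site.filled()}
    hetero, _ = _component_instances(structure_dict, site_chains, catalytic_keys)
    seen = {(r.chain_id, r.residue_number, r.comp_id) for r in exclude}

    records: list[LigandRecord] = []
    for chain_id, resnum, comp_id, atoms in hetero:
        if (chain_id, resnum, comp_id) in seen:
            continue
        pts = np.asarray([a.xyz for a in atoms])
        if np.min(np.linalg.norm(pts - centroid, axis=1)) > radius:
            continue
        rec = LigandRecord(
            comp_id=comp_id, proximity=Proximity.DISTAL,
            chain_id=chain_id, residue_number=resnum, atoms=list(atoms),
        )
        rec = classify_ligand(
            rec, cognate_components, cofactor_table, {},
            component_library=component_library, engine=engine,
        )
        if rec.ligand_class in (LigandClass.SUBSTRATE_LIKE, LigandClass.COFACTOR):
            records.append(rec)
    return records


# ---------------------------------------------------------------------------
# classification & centrality

def classify_ligand(
    ligand: LigandRecord,
    cognate_components: Sequence[SmallMolecule],
    cofactor_table: Mapping[str, str] | None = None,
    artefact_table: Mapping[str, str] | None = None,
    component_library: Mapping[str, SmallMolecule] | None = None,
    engine: MCSEngine | None = None,
    substrate_threshold: float = SUBSTRATE_SIMILARITY,
    artefact_threshold: float = ARTEFACT_SIMILARITY,
) -> LigandRecord:
    """Assign a chemical class to one ligand record.

    Pipeline order: similarity against every cognate reactant/product
    (best match kept, ties to the lexicographically smallest comp id);
    substrate-like at >= 60%; else cofactor by table lookup; else
    artefact if in the additive table and below the 30% bar against
    every cognate (and every cofactor with a known chemical graph);
    else uncertain.
    """
    cofactor_table = default_cofactor_table() if cofactor_table is None else cofactor_table
    artefact_table = default_artefact_table() if artefact_table is None else artefact_table
    component_library = component_library or {}

    mol = component_library.get(ligand.comp_id)
    best_match: str | None = None
    best_sim: float | None = None
    if mol is not None and ligand.comp_id != "POLYMER":
        scored = []
        for cog in cognate_components:
            s = parity_similarity(mol, cog, engine)
            if s is not None:
                scored.append((s, cog.comp_id))
        if scored:
            best_sim = max(s for s, _ in scored)
            best_match = min(cid for s, cid in scored if s == best_sim)

    if best_sim is not None and best_sim >= substrate_threshold:
        cls = LigandClass.SUBSTRATE_LIKE
    elif ligand.comp_id in cofactor_table:
        cls = LigandClass.COFACTOR
    elif ligand.comp_id in artefact_table:
        # the 30% screen also counts cofactors with known chemistry
        screen = [best_sim] if best_sim is not None else []
        if mol is not None:
            for code in cofactor_table:
                cof = component_library.get(code)
                if cof is not None:
                    s = parity_similarity(mol, cof, engine)
                    if s is not None:
                        screen.append(s)
        if not screen or max(screen) <= artefact_threshold:
            cls = LigandClass.ARTEFACT
        else:
            cls = LigandClass.UNCERTAIN
    else:
        cls = LigandClass.UNCERTAIN
    return replace(ligand, ligand_class=cls, best_match=best_match, similarity=best_sim)


def ligand_centrality(ligand: LigandRecord, site: ActiveSite) -> float | None:
    """Mean ligand-to-residue COM distance over the mean inter-residue
    COM distance; ``None`` for sites with fewer than two residues."""
    coms = list(site.residue_coms().values())
    if len(coms) < 2:
        return None
    lig = ligand.center_of_mass()
    num = float(np.mean([np.linalg.norm(lig - c) for c in coms]))
    den = site.mean_intra_residue_distance()
    if den == 0:
        return None
    return num / den
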