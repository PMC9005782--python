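"""Reconstruction of active sites inside a biological assembly.

An assembly may hold several copies of an enzyme's active site, and a
single site may straddle two chains (e.g. the symmetric interface
sites of retroviral proteases).  Given the per-chain catalytic-residue
hits and the family reference definition, this module

1. clusters the hits into candidate sites by greedy center-of-mass
   growth seeded on equivalent residues across chains,
2. validates each candidate's geometry against the reference and its
   sibling sites (distance-ratio sanity rules), and
3. removes redundant copies that arise from crystallographic symmetry
   (greedy retention under a 0.5 Å wRMSD threshold).
"""

from __future__ import annotations

import logging
from collections import defaultdict

import numpy as np

from .core import ActiveSite, CatalyticResidue, SanityVerdict, pairwise_com_distances
from .superpose import gaussian_weighted_superpose

logger = logging.getLogger(__name__)

__all__ = [
    "cluster_catalytic_residues",
    "check_site_sanity",
    "deduplicate_sites",
    "collect_catalytic_hits",
]

# Sanity thresholds (distances between residue centers of mass, Å):
# only pairs further apart than PAIR_DISTANCE_GATE are tested; a pair
# fails if it exceeds REF_RATIO x the reference distance, or
# SIBLING_RATIO x the equivalent pair in a sibling site of the same
# structure.  Empirical values; see the methods note.
PAIR_DISTANCE_GATE = 8.0
REF_RATIO = 3.0
SIBLING_RATIO = 1.3
DEDUP_WRMSD = 0.5


def collect_catalytic_hits(
    structure_dict: dict[str, dict[int, dict]],
    reference: ActiveSite,
) -> list[CatalyticResidue]:
    """Find every residue in the structure matching a reference slot's
    (residue_name, residue_number), carrying over the slot annotations.

    Atom coordinates come from the structure; role/location metadata
    from the reference slot (first slot with that key, which is exact
    unless slots differ only by equivalence group — those share
    metadata by construction).
    """
    by_key: dict[tuple[str, int], CatalyticResidue] = {}
    for r in reference.residues:
        if r is not None:
            by_key.setdefault((r.residue_name.upper(), r.residue_number), r)
    hits: list[CatalyticResidue] = []
    for chain_id in sorted(structure_dict):
        for resnum in sorted(structure_dict[chain_id]):
            rec = structure_dict[chain_id][resnum]
            key = (rec["name"].upper(), resnum)
            if key not in by_key:
                continue
            ref = by_key[key]
            hits.append(
                CatalyticResidue(
                    chain_id=chain_id,
                    residue_name=rec["name"].upper(),
                    residue_number=resnum,
                    function_location=ref.function_location,
                    role=ref.role,
                    role_category=ref.role_category,
                    equiv_group=0,
                    atoms=list(rec["atoms"]),
                )
            )
    return hits


def cluster_catalytic_residues(
    structure_dict: dict[str, dict[int, dict]],
    reference: ActiveSite,
    structure_id: str = "",
) -> list[ActiveSite]:
    """Cluster catalytic-residue hits into candidate active sites.

    The seed residue is the first hit in (chain_id, residue_number)
    lexicographic order; every residue equivalent to it (same name and
    number in another chain) seeds one cluster, except that when the
    reference itself contains k > 1 equivalence-group copies of that
    (name, number) — a symmetric interface site — the n equivalent hits
    seed only n // k clusters.  Growth is globally greedy: at each step
    the (cluster, slot, candidate) addition with the smallest distance
    to the cluster's current center of mass is made, ties broken by
    lower (chain_id, residue_number).  Unfillable slots stay null.
    """
    hits = collect_catalytic_hits(structure_dict, reference)
    if not hits:
        return []

    ref_slots = [(i, r) for i, r in enumerate(reference.residues) if r is not None]
    slots_by_key: dict[tuple[str, int], list[int]] = defaultdict(list)
    for i, r in ref_slots:
        slots_by_key[(r.residue_name.upper(), r.residue_number)].append(i)

    hits = sorted(hits, key=lambda h: (h.chain_id, h.residue_number))
    seed_hit = hits[0]
    seed_key = (seed_hit.residue_name, seed_hit.residue_number)
    equivalents = [h for h in hits if (h.residue_name, h.residue_number) == seed_key]
    k = len(slots_by_key[seed_key])  # slots sharing the seed key (interface copies)
    n_sites = max(1, len(equivalents) // k)

    n_slots = len(reference.residues)
    clusters: list[dict[int, CatalyticResidue]] = []
    assigned: set[int] = set()
    hit_index = {id(h): i for i, h in enumerate(hits)}
    for s in range(n_sites):
        seed = equivalents[s]
        slot = slots_by_key[seed_key][0]
        clusters.append({slot: seed})
        assigned.add(hit_index[id(seed)])

    def com(cluster: dict[int, CatalyticResidue]) -> np.ndarray:
        return np.mean([r.center_of_mass() for r in cluster.values()], axis=0)

    while True:
        best = None  # (dist, chain, resnum, cluster_idx, slot, hit_idx)
        for ci, cluster in enumerate(clusters):
            c = com(cluster)
            for i, h in enumerate(hits):
                if i in assigned:
                    continue
                key = (h.residue_name, h.residue_number)
                open_slots = [s for s in slots_by_key.get(key, []) if s not in cluster]
                if not open_slots:
                    continue
                d = float(np.linalg.norm(h.center_of_mass() - c))
                cand = (d, h.chain_id, h.residue_number, ci, open_slots[0], i)
                if best is None or cand < best:
                    best = cand
        if best is None:
            break
        _, _, _, ci, slot, i = best
        clusters[ci][slot] = hits[i]
        assigned.add(i)

    sites: list[ActiveSite] = []
    for ci, cluster in enumerate(clusters):
        residues: list[CatalyticResidue | None] = [None] * n_slots
        for slot, h in cluster.items():
            # tag the residue with the slot's equivalence group
            ref = reference.residues[slot]
            h.equiv_group = ref.equiv_group if ref is not None else 0
            residues[slot] = h
        sites.append(
            ActiveSite(
                site_id=f"{structure_id or 'site'}_{ci}",
                structure_id=structure_id,
                residues=residues,
                resolution=None,
            )
        )
    return sites


def check_site_sanity(
    site: ActiveSite,
    reference: ActiveSite,
    siblings: list[ActiveSite] | None = None,
    gate: float = PAIR_DISTANCE_GATE,
    ref_ratio: float = REF_RATIO,
    sibling_ratio: float = SIBLING_RATIO,
) -> SanityVerdict:
    """Validate the geometry of a reconstructed site.

    Every inter-residue center-of-mass distance above ``gate`` (8 Å)
    must be at most ``ref_ratio`` (3x) its reference counterpart, and
    at most ``sibling_ratio`` (1.3x) the equivalent distance in every
    sibling site from the same structure.  Pairs whose counterpart is
    missing (null slot) are skipped and logged.
    """
    siblings = siblings or []
    obs = pairwise_com_distances(site)
    ref = pairwise_com_distances(reference)
    sib_dists = [pairwise_com_distances(s) for s in siblings]
    failed: list[tuple[int, int, float, float, str]] = []
    for (i, j), d in obs.items():
        if d <= gate:
            continue
        if (i, j) not in ref:
            logger.info("sanity: pair (%d,%d) missing in reference, skipped", i, j)
        else:
            limit = ref_ratio * ref[(i, j)]
            if d > limit:
                failed.append((i, j, d, limit, "vs_reference_3x"))
        for sd in sib_dists:
            if (i, j) in sd:
                limit = sibling_ratio * sd[(i, j)]
                if d > limit:
                    failed.append((i, j, d, limit, "vs_sibling_1p3x"))
    return SanityVerdict(passed=not failed, failed_pairs=failed)


def deduplicate_sites(
    sites: list[ActiveSite],
    threshold: float = DEDUP_WRMSD,
) -> list[ActiveSite]:
    """Greedy redundancy reduction within one structure.

    Walks the sites in input order and keeps a site only if its
    functional-atom wRMSD to every already-retained site is at least
    ``threshold`` (default 0.5 Å, an estimate of coordinate error at
    typical resolution).  Removes symmetry-mate copies of one site.
    """
    retained: list[ActiveSite] = []
    for site in sites:
        duplicate = False
        for kept in retained:
            try:
                res = gaussian_weighted_superpose(site, kept)
            except ValueError:
                continue
            if res.wrmsd < threshold:
                duplicate = True
                logger.info(
                    "dedup: %s dropped (wRMSD %.3f to %s)",
                    site.site_id, res.wrmsd, kept.site_id,
                )
                break
        if not duplicate:
            retained.append(site)
    return retained
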