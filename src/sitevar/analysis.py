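"""Family-level analyses of active-site conformational variability.

Builds all-vs-all superposition matrices, applies the dataset
clean-up filters, groups comparison pairs by ligand state, clusters
conformers on the RMSD dissimilarity matrix, classifies each family's
conformational behaviour into one of four paradigms, assigns each pair
to a main-chain/side-chain flexibility quadrant, and computes
flexible-over-rigid enrichment odds ratios per residue type and role.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import skew
from sklearn.mixture import GaussianMixture

from .core import ActiveSite, PairComparison, Paradigm, ParadigmCall
from .superpose import batched_pairwise_wrmsd, ca_rmsd, gaussian_weighted_superpose

logger = logging.getLogger(__name__)

__all__ = [
    "all_vs_all_matrix",
    "compare_pair",
    "apply_pair_filters",
    "group_pairs_by_ligand_state",
    "cluster_sites",
    "classify_paradigm",
    "flexibility_quadrant",
    "quadrant_fractions",
    "enrichment_odds_ratios",
    "FLEXIBILITY_THRESHOLD",
]

FLEXIBILITY_THRESHOLD = 0.5      # Å; >= flexible, < rigid (experimental error)
RESOLUTION_CUTOFF = 2.0          # Å, dataset filter
MAX_PAIR_RMSD = 10.0             # Å, artefact filter
MAX_SINGLE_RESIDUE_RMSD = 20.0   # Å, ligand-effect filter
OUTLIER_WRMSD = 1.5              # Å, with max residue RMSD > 3x wRMSD -> excluded
INTRA_DISTANCE_DISCREPANCY = 5.0 # Å, mean intra-residue distance mismatch
FAMILY_PAIR_CAP = 30             # per-family sample cap (seq/struct profile)
PRUNE_FACTOR = 0.4               # dendrogram cut at 0.4 x max merge height
MIN_SITES_FOR_PARADIGM = 50
ENRICHMENT_SAMPLE = 50           # per-family superposition sample
ENRICHMENT_FLOOR = 0.02          # groups below 2% of the sample are suppressed


# ---------------------------------------------------------------------------
# matrices

def all_vs_all_matrix(
    sites: list[ActiveSite],
    mode: str = "functional",
    c: float = 2.0,
) -> np.ndarray:
    """Symmetric matrix of pairwise RMSD values (Å).

    ``mode='functional'`` uses the Gaussian-weighted fit over
    functional atom triads; ``mode='ca'`` a plain Kabsch over CA
    atoms.  Pairs that cannot be superposed become NaN (logged).
    """
    if len(sites) < 2:
        raise ValueError("need at least 2 sites")
    if mode not in ("functional", "ca"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "functional":
        try:  # homogeneous gap-free families take the batched route
            return batched_pairwise_wrmsd(sites, c=c)
        except ValueError:
            pass
    n = len(sites)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                if mode == "functional":
                    v = gaussian_weighted_superpose(sites[i], sites[j], c=c).wrmsd
                else:
                    v = ca_rmsd(sites[i], sites[j])
            except ValueError as exc:
                logger.warning("pair (%s, %s) failed: %s",
                               sites[i].site_id, sites[j].site_id, exc)
                v = np.nan
            M[i, j] = M[j, i] = v
    M = (M + M.T) / 2.0  # symmetrization (exact here; guards fp drift)
    np.fill_diagonal(M, 0.0)
    return M


def compare_pair(
    site_a: ActiveSite,
    site_b: ActiveSite,
    family_id: str = "",
    c: float = 2.0,
    bound_a: bool | None = None,
    bound_b: bool | None = None,
    ec_number: str | None = None,
) -> PairComparison:
    """Superpose two sites and package the result with the metadata
    the filters and groupings consume."""
    res = gaussian_weighted_superpose(site_a, site_b, c=c)
    try:
        ca = ca_rmsd(site_a, site_b)
    except ValueError:
        ca = None
    conserved = all(
        (ra is None) == (rb is None)
        and (ra is None or ra.residue_name == rb.residue_name)
        for ra, rb in zip(site_a.residues, site_b.residues)
    )
    same_protein = (
        site_a.sequence_accession is not None
        and site_a.sequence_accession == site_b.sequence_accession
    )
    state = None
    if bound_a is not None and bound_b is not None:
        state = {
            (False, False): "free_free",
            (True, True): "bound_bound",
        }.get((bound_a, bound_b), "bound_free")
    resolutions = [r for r in (site_a.resolution, site_b.resolution) if r is not None]
    return PairComparison(
        site_a=site_a.site_id,
        site_b=site_b.site_id,
        family_id=family_id,
        wrmsd=res.wrmsd,
        max_residue_rmsd=res.max_residue_rmsd,
        ca_rmsd=ca,
        per_residue=res.per_residue_rmsd,
        same_protein=same_protein,
        conserved=conserved,
        ligand_state=state,
        resolution=max(resolutions) if resolutions else None,
        is_nmr=(site_a.experiment.value == "nmr" or site_b.experiment.value == "nmr"),
        ec_number=ec_number,
        has_gap=site_a.has_gaps or site_b.has_gaps,
        intra_distance_discrepancy=abs(
            site_a.mean_intra_residue_distance() - site_b.mean_intra_residue_distance()
        ),
    )


# ---------------------------------------------------------------------------
# dataset clean-up

def apply_pair_filters(
    pairs: list[PairComparison],
    profile: str,
    seed: int = 0,
    cap: int = FAMILY_PAIR_CAP,
) -> list[PairComparison]:
    """Apply one of the two dataset clean-up profiles.

    ``seq_struct``: resolution <= 2.0 Å, no NMR, RMSD <= 10 Å (both
    weighted functional and CA where available), then a seeded random
    sample capped at ``cap`` pairs per family.

    ``ligand_effect``: resolution/NMR as above, EC number required, no
    gapped sites, mean intra-residue distance discrepancy <= 5 Å,
    wRMSD <= 10 Å, max single-residue RMSD <= 20 Å, and exclusion of
    pairs with wRMSD > 1.5 Å whose max residue RMSD exceeds 3x the
    wRMSD.  Every exclusion is logged with its rule tag.
    """
    if profile not in ("seq_struct", "ligand_effect"):
        raise ValueError(f"unknown filter profile {profile!r}")

    def drop(p: PairComparison, tag: str) -> None:
        logger.info("filter %s: dropped (%s, %s) [%s]",
                    profile, p.site_a, p.site_b, tag)

    kept: list[PairComparison] = []
    for p in pairs:
        if p.resolution is not None and p.resolution > RESOLUTION_CUTOFF:
            drop(p, "resolution_gt_2.0"); continue
        if p.is_nmr:
            drop(p, "nmr"); continue
        if profile == "seq_struct":
            if p.wrmsd > MAX_PAIR_RMSD:
                drop(p, "rmsd_gt_10"); continue
            if p.ca_rmsd is not None and p.ca_rmsd > MAX_PAIR_RMSD:
                drop(p, "ca_rmsd_gt_10"); continue
        else:
            if p.ec_number is None:
                drop(p, "no_ec"); continue
            if p.has_gap:
                drop(p, "gapped_site"); continue
            if (p.intra_distance_discrepancy is not None
                    and p.intra_distance_discrepancy > INTRA_DISTANCE_DISCREPANCY):
                drop(p, "intra_distance_discrepancy_gt_5"); continue
            if p.wrmsd > MAX_PAIR_RMSD:
                drop(p, "wrmsd_gt_10"); continue
            if p.max_residue_rmsd > MAX_SINGLE_RESIDUE_RMSD:
                drop(p, "max_residue_rmsd_gt_20"); continue
            if p.wrmsd > OUTLIER_WRMSD and p.max_residue_rmsd > 3.0 * p.wrmsd:
                drop(p, "max_residue_gt_3x_wrmsd"); continue
        kept.append(p)

    if profile == "seq_struct":
        rng = np.random.default_rng(seed)
        by_family: dict[str, list[PairComparison]] = defaultdict(list)
        for p in kept:
            by_family[p.family_id].append(p)
        sampled: list[PairComparison] = []
        for fam in sorted(by_family):
            fam_pairs = by_family[fam]
            if len(fam_pairs) > cap:
                idx = rng.choice(len(fam_pairs), size=cap, replace=False)
                fam_pairs = [fam_pairs[i] for i in sorted(idx)]
                logger.info("filter seq_struct: family %s capped at %d", fam, cap)
            sampled.extend(fam_pairs)
        kept = sampled
    return kept


# ---------------------------------------------------------------------------
# ligand-state grouping

def group_pairs_by_ligand_state(
    pairs: list[PairComparison],
) -> dict[tuple[bool, bool, str], dict[str, float]]:
    """Per-family mean wRMSD in the 12 (same-protein x conserved x
    ligand-state) buckets; empty buckets are omitted."""
    acc: dict[tuple[bool, bool, str], dict[str, list[float]]] = defaultdict(
        lambda: defaultdict(list)
    )
    for p in pairs:
        if p.ligand_state is None:
            continue
        acc[(p.same_protein, p.conserved, p.ligand_state)][p.family_id].append(p.wrmsd)
    return {
        bucket: {fam: float(np.mean(vals)) for fam, vals in fams.items()}
        for bucket, fams in acc.items()
    }


# ---------------------------------------------------------------------------
# conformer clustering

@dataclass
class ClusterResult:
    labels: np.ndarray
    linkage_matrix: np.ndarray
    cut_height: float


def cluster_sites(
    matrix: np.ndarray,
    method: str = "average",
    prune_factor: float = PRUNE_FACTOR,
) -> ClusterResult:
    """Hierarchical (linkage) clustering of the RMSD dissimilarity
    matrix, cut at ``prune_factor`` times the maximum merge height.

    NaN cells are imputed with the matrix maximum (logged).
    """
    M = np.array(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("matrix must be square")
    if np.isnan(M).any():
        mx = np.nanmax(M)
        logger.warning("cluster_sites: imputing %d NaN cells with max %.3f",
                       int(np.isnan(M).sum()), mx)
        M = np.where(np.isnan(M), mx, M)
    np.fill_diagonal(M, 0.0)
    Z = linkage(squareform(M, checks=False), method=method)
    cut = prune_factor * Z[:, 2].max() if len(Z) else 0.0
    cut = max(cut, 1e-8)  # all-identical sites are one conformer
    labels = fcluster(Z, t=cut, criterion="distance")
    return ClusterResult(labels=labels, linkage_matrix=Z, cut_height=float(cut))


# ---------------------------------------------------------------------------
# paradigm classification

def _two_state_contrast(M: np.ndarray) -> tuple[float, float]:
    """Evidence for exactly two conformer populations in a pairwise
    RMSD matrix: force a 2-way average-linkage partition of the sites
    and return (between/within mean RMSD ratio, minority fraction).

    Two genuinely distinct conformations without intermediates give a
    high contrast with both groups populated; a drifting continuum of
    states gives a contrast near 1.
    """
    n = M.shape[0]
    Z = linkage(squareform(M, checks=False), method="average")
    lab = fcluster(Z, 2, criterion="maxclust")
    iu = np.triu_indices(n, k=1)
    same = (lab[:, None] == lab[None, :])[iu]
    v = M[iu]
    within, between = v[same], v[~same]
    if len(between) == 0 or len(within) == 0 or within.mean() == 0:
        return 1.0, 0.0
    minority = min((lab == 1).sum(), (lab == 2).sum()) / n
    return float(between.mean() / within.mean()), float(minority)


def classify_paradigm(
    values: np.ndarray,
    n_sites: int,
    family_id: str = "",
    min_sites: int = MIN_SITES_FOR_PARADIGM,
    rigid_mean: float = FLEXIBILITY_THRESHOLD,
    delta_bic: float = 10.0,
    separation_factor: float = 2.0,
    contrast_cut: float = 1.8,
    minority_cut: float = 0.15,
    hetero_cut: float = 0.22,
    min_spread: float = 0.1,
    seed: int = 0,
) -> ParadigmCall:
    """Label a family's conformational behaviour from its all-vs-all
    functional-atom wRMSD distribution.

    ``values`` may be the full square matrix (preferred: the site
    partition and site-exchangeability statistics need it) or a flat
    vector of pairwise values.

    Decision cascade (all thresholds configurable):

    1. fewer than ``min_sites`` sites, or < 2 values -> unclassified;
    2. open/closed: a 2-component Gaussian mixture beats 1 component
       by more than ``delta_bic`` BIC, the component means are
       separated by > ``separation_factor`` pooled sigma, *and* the
       2-way site partition shows a between/within contrast of at
       least ``contrast_cut`` with both groups holding at least
       ``minority_cut`` of the sites — two distinct conformations
       without intermediates;
    3. extensively variable: sites are not exchangeable — the spread
       of per-site mean RMSD exceeds ``hetero_cut`` of the overall
       spread (some conformers drift far while others stay put) and
       the absolute spread exceeds ``min_spread`` (so pure
       experimental noise is never read as structure);
    4. inherently rigid: mean wRMSD below ``rigid_mean`` (0.5 Å, the
       experimental error bar — rigidity means flexibility within
       experimental error);
    5. else inherently flexible (unimodal spread beyond error, all
       sites exchangeable).
    """
    V = np.asarray(values, dtype=float)
    matrix = V.ndim == 2
    flat = V[np.triu_indices(V.shape[0], k=1)] if matrix else V
    flat = flat[np.isfinite(flat)]
    if n_sites < min_sites or len(flat) < 2:
        return ParadigmCall(family_id=family_id, label=Paradigm.UNCLASSIFIED,
                            n_pairs=len(flat), n_sites=n_sites)
    mu = float(np.mean(flat))
    sd = float(np.std(flat))
    g = float(skew(flat))

    X = flat.reshape(-1, 1)
    gm1 = GaussianMixture(1, random_state=seed).fit(X)
    gm2 = GaussianMixture(2, random_state=seed, n_init=3).fit(X)
    dbic = float(gm1.bic(X) - gm2.bic(X))  # >0 favours two components
    m2 = gm2.means_.ravel()
    s2 = gm2.covariances_.ravel()
    w2 = gm2.weights_.ravel()
    pooled = math.sqrt(float(w2 @ s2))
    sep = float(abs(m2[0] - m2[1]) / pooled) if pooled > 0 else float("inf")

    contrast, minority, hetero = None, None, None
    if matrix:
        M = np.where(np.isnan(V), np.nanmax(V), V)
        contrast, minority = _two_state_contrast(M)
        row_means = M.sum(axis=1) / (M.shape[0] - 1)
        hetero = float(row_means.std() / sd) if sd > 0 else 0.0

    stats = dict(mean=mu, sd=sd, skewness=g, delta_bic=dbic,
                 component_separation=sep, cluster_contrast=contrast,
                 minority_fraction=minority,
                 n_pairs=len(flat), n_sites=n_sites)
    two_state = (
        dbic > delta_bic and sep > separation_factor and min(w2) > 0.10
        and (contrast is None or (contrast >= contrast_cut and minority >= minority_cut))
    )
    irregular = (
        hetero >= hetero_cut and sd >= min_spread if hetero is not None
        else dbic > 2 * delta_bic  # vector input: multimodality only
    )
    if two_state:
        label = Paradigm.OPEN_CLOSED
    elif irregular:
        label = Paradigm.EXTENSIVE
    elif mu < rigid_mean:
        label = Paradigm.RIGID
    else:
        label = Paradigm.FLEXIBLE
    return ParadigmCall(family_id=family_id, label=label, **stats)


# ---------------------------------------------------------------------------
# flexibility quadrants

def flexibility_quadrant(
    ca: float,
    functional: float,
    threshold: float = FLEXIBILITY_THRESHOLD,
) -> str:
    """Quadrant of one pair in the (CA RMSD, functional-atom RMSD)
    plane; "flexible" is >= threshold (boundary inclusive)."""
    if ca < 0 or functional < 0:
        raise ValueError("RMSD values must be nonnegative")
    ca_flex = ca >= threshold
    fn_flex = functional >= threshold
    if ca_flex and fn_flex:
        return "flexible_both"
    if not ca_flex and not fn_flex:
        return "rigid_both"
    if fn_flex:
        return "side_chain_only"
    return "main_chain_only"


def quadrant_fractions(
    pairs: list[PairComparison],
    threshold: float = FLEXIBILITY_THRESHOLD,
) -> dict[str, float]:
    counts = {"rigid_both": 0, "flexible_both": 0,
              "side_chain_only": 0, "main_chain_only": 0}
    usable = [p for p in pairs if p.ca_rmsd is not None]
    for p in usable:
        counts[flexibility_quadrant(p.ca_rmsd, p.wrmsd, threshold)] += 1
    n = len(usable)
    return {k: v / n for k, v in counts.items()} if n else counts


# ---------------------------------------------------------------------------
# residue-role enrichment

def enrichment_odds_ratios(
    records: pd.DataFrame,
    sample_per_family: int = ENRICHMENT_SAMPLE,
    seed: int = 0,
    threshold: float = FLEXIBILITY_THRESHOLD,
    floor: float = ENRICHMENT_FLOOR,
    group_by: str = "residue_type",
) -> pd.DataFrame:
    """Flexible-over-rigid enrichment odds ratios.

    ``records`` needs columns family_id, residue_type, role,
    role_category, rmsd (one row per residue observation in a
    superposition).  Per family a seeded random sample of at most
    ``sample_per_family`` rows is drawn; rows are partitioned into
    rigid (< threshold) and flexible (>= threshold); for each group
    label the within-partition frequencies and their ratio
    freq_flexible / freq_rigid are reported.  Groups holding less
    than ``floor`` of the sample are suppressed; a zero rigid
    frequency yields an infinite ratio (logged).
    """
    if group_by not in ("residue_type", "role", "role_category"):
        raise ValueError(f"unknown grouping {group_by!r}")
    rng = np.random.default_rng(seed)
    sampled = []
    for fam, sub in records.groupby("family_id", sort=True):
        if len(sub) > sample_per_family:
            idx = rng.choice(len(sub), size=sample_per_family, replace=False)
            sub = sub.iloc[np.sort(idx)]
        sampled.append(sub)
    df = pd.concat(sampled, ignore_index=True)
    flexible = df[df["rmsd"] >= threshold]
    rigid = df[df["rmsd"] < threshold]
    rows = []
    for label, total in df[group_by].value_counts().items():
        if total / len(df) < floor:
            continue
        ff = (flexible[group_by] == label).sum() / max(len(flexible), 1)
        fr = (rigid[group_by] == label).sum() / max(len(rigid), 1)
        if fr == 0:
            ratio = float("inf")
            logger.info("enrichment: group %r absent from rigid partition", label)
        else:
            ratio = ff / fr
        rows.append({"group": label, "freq_flexible": float(ff),
                     "freq_rigid": float(fr), "odds_ratio": float(ratio)})
    return pd.DataFrame(rows).sort_values("group").reset_index(drop=True)
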