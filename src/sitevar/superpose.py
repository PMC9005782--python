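"""Symmetry-aware superposition of homologous active sites.

Sites are aligned over *functional atom triads*: three atoms per
catalytic residue drawn from the moiety that performs the catalysis
(e.g. the guanidino endpoint atoms CZ, NH1, NH2 for an arginine acting
through its side chain), so the fit anchors on the functionally
relevant part of each residue and leaves the rest free to vary.

Three complications are handled explicitly:

* **Mutations.** Conservative substitutions within the equivalence
  sets Asp/Glu, Asn/Gln, Ser/Thr/Tyr and Val/Leu/Ile are paired over
  chemically analogous triad positions; non-equivalent substitutions
  are paired with all three atoms wildcarded (mutually exchangeable);
  a residue facing a gap is excluded entirely.
* **Crystallographic symmetry.** Chemically indistinguishable atoms
  (the two carboxylate oxygens of Asp/Glu, the His ring atoms, the
  terminal methyls of Val/Leu, the Phe ring CE pair, the Arg NH pair)
  may be swapped between depositions.  Within each exchangeability
  class the optimal one-to-one atom correspondence is found with the
  Kuhn-Munkres (Hungarian) assignment on pairwise distances after a
  crude unweighted Kabsch fit on the unambiguous atoms.
* **Partial flexibility.** The final fit is a Gaussian-weighted
  iterative Kabsch: atom weights are recomputed as
  ``w_i = exp(-d_i^2 / c)`` each round, which biases the fit towards
  the invariant core of the site and away from mobile residues.  The
  reported wRMSD is ``sqrt(sum(w d^2) / sum(w))`` under the final
  weights; per-residue RMSDs are unweighted under the final transform.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import ActiveSite, CatalyticResidue, FunctionLocation

logger = logging.getLogger(__name__)

__all__ = [
    "FunctionalTriad",
    "ResiduePair",
    "PairKind",
    "SuperpositionResult",
    "AtomCorrespondence",
    "TriadUnavailableError",
    "functional_triad",
    "pair_residues",
    "resolve_correspondence",
    "kabsch",
    "gaussian_weighted_superpose",
    "ca_rmsd",
    "SIDE_CHAIN_TRIADS",
    "MAIN_CHAIN_TRIAD",
    "CONSERVATIVE_SETS",
]

# Side-chain triads: (atom names, per-position exchangeability tag).
# Positions sharing a non-None tag are chemically indistinguishable and
# may be permuted by the assignment step.  Overridable per call.
SIDE_CHAIN_TRIADS: dict[str, tuple[tuple[str, str, str], tuple[int | None, ...]]] = {
    "ARG": (("CZ", "NH1", "NH2"), (None, 1, 1)),
    "LYS": (("CD", "CE", "NZ"), (None, None, None)),
    "HIS": (("ND1", "CE1", "NE2"), (1, 1, 1)),
    "ASP": (("CG", "OD1", "OD2"), (None, 1, 1)),
    "GLU": (("CD", "OE1", "OE2"), (None, 1, 1)),
    "SER": (("CA", "CB", "OG"), (None, None, None)),
    "THR": (("CA", "CB", "OG1"), (None, None, None)),
    "CYS": (("CA", "CB", "SG"), (None, None, None)),
    "TYR": (("CE1", "CZ", "OH"), (None, None, None)),
    "ASN": (("CG", "OD1", "ND2"), (None, None, None)),
    "GLN": (("CD", "OE1", "NE2"), (None, None, None)),
    "TRP": (("CD1", "NE1", "CE2"), (None, None, None)),
    "MET": (("CG", "SD", "CE"), (None, None, None)),
    "PHE": (("CE1", "CZ", "CE2"), (1, None, 1)),
    "VAL": (("CB", "CG1", "CG2"), (None, 1, 1)),
    "LEU": (("CG", "CD1", "CD2"), (None, 1, 1)),
    "ILE": (("CB", "CG1", "CD1"), (None, None, None)),
}

MAIN_CHAIN_TRIAD: tuple[str, str, str] = ("N", "CA", "C")

# Conservative substitution sets: mismatches inside one set are paired
# position-wise over chemically analogous triad atoms.
CONSERVATIVE_SETS: tuple[frozenset[str], ...] = (
    frozenset({"ASP", "GLU"}),
    frozenset({"ASN", "GLN"}),
    frozenset({"SER", "THR", "TYR"}),
    frozenset({"VAL", "LEU", "ILE"}),
)


class TriadUnavailableError(KeyError):
    """Raised when a residue lacks an atom its triad requires."""


class TriadSource(str, Enum):
    SIDE_CHAIN = "side_chain"
    MAIN_CHAIN = "main_chain"
    MISMATCH_PSEUDO = "mismatch_pseudo"


@dataclass(frozen=True)
class FunctionalTriad:
    slot: int
    atom_names: tuple[str, str, str]
    symmetry_classes: tuple[int | None, int | None, int | None]
    source: TriadSource


class PairKind(str, Enum):
    MATCH = "match"
    CONSERVATIVE = "conservative_mismatch"
    NONEQUIVALENT = "nonequivalent_mismatch"
    GAP = "gap"


@dataclass(frozen=True)
class ResiduePair:
    """Pairing of one reference slot between two sites.

    ``exchange_classes`` groups triad positions (0..2) that are
    mutually exchangeable between the two sides; positions not listed
    are unambiguous name-mapped pairs.
    """

    slot: int
    kind: PairKind
    names_a: tuple[str, ...] = ()
    names_b: tuple[str, ...] = ()
    exchange_classes: tuple[tuple[int, ...], ...] = ()


@dataclass
class AtomCorrespondence:
    """Resolved one-to-one atom mapping between two sites."""

    slots: np.ndarray          # residue slot per mapped atom pair
    names_a: list[str]
    names_b: list[str]
    coords_a: np.ndarray       # (n, 3)
    coords_b: np.ndarray       # (n, 3)

    @property
    def n_atoms(self) -> int:
        return len(self.names_a)


@dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    wrmsd: float
    per_residue_rmsd: dict[int, float]
    max_residue_rmsd: float
    n_atoms: int
    correspondence: AtomCorrespondence
    iterations: int
    converged: bool
    # (objective before, after) each weighted solve at that round's
    # fixed weights; after <= before is the descent guarantee
    objective_trace: list[tuple[float, float]] = field(default_factory=list)


def functional_triad(
    residue: CatalyticResidue,
    table: dict | None = None,
) -> FunctionalTriad:
    """Select the three superposition atoms for one catalytic residue.

    Residues acting through the main chain, post-translationally
    modified residues, and residue types without a side-chain entry
    (Ala, Gly, Pro, unknown codes) use the backbone triad (N, CA, C).

    Raises
    ------
    TriadUnavailableError
        If any required atom is absent from the coordinates; callers
        demote the slot to a gap.
    """
    table = SIDE_CHAIN_TRIADS if table is None else table
    name = residue.residue_name.upper()
    use_main = (
        residue.function_location
        in (FunctionLocation.MAIN_CHAIN, FunctionLocation.POST_TRANSLATIONAL)
        or name not in table
    )
    if use_main:
        names, classes = MAIN_CHAIN_TRIAD, (None, None, None)
        source = TriadSource.MAIN_CHAIN
    else:
        names, classes = table[name]
        source = TriadSource.SIDE_CHAIN
    for n in names:
        if residue.atom(n) is None:
            raise TriadUnavailableError(
                f"atom {n!r} missing from {name}{residue.residue_number} "
                f"(chain {residue.chain_id})"
            )
    return FunctionalTriad(slot=-1, atom_names=names, symmetry_classes=classes,
                           source=source)


def _classes_to_groups(classes: tuple[int | None, ...]) -> tuple[tuple[int, ...], ...]:
    groups: dict[int, list[int]] = {}
    for pos, tag in enumerate(classes):
        if tag is not None:
            groups.setdefault(tag, []).append(pos)
    return tuple(tuple(g) for g in groups.values() if len(g) > 1)


def _same_conservative_set(a: str, b: str) -> bool:
    return any(a in s and b in s for s in CONSERVATIVE_SETS)


def pair_residues(
    site_a: ActiveSite,
    site_b: ActiveSite,
    table: dict | None = None,
) -> list[ResiduePair]:
    """Pair the two sites slot-by-slot, classifying each slot as a
    match, conservative mismatch, non-equivalent mismatch or gap."""
    if len(site_a.residues) != len(site_b.residues):
        raise ValueError("sites are not positionally aligned (length mismatch)")
    pairs: list[ResiduePair] = []
    for slot, (ra, rb) in enumerate(zip(site_a.residues, site_b.residues)):
        if ra is None or rb is None:
            pairs.append(ResiduePair(slot=slot, kind=PairKind.GAP))
            continue
        try:
            ta = functional_triad(ra, table)
            tb = functional_triad(rb, table)
        except TriadUnavailableError as exc:
            logger.warning("slot %d demoted to gap: %s", slot, exc)
            pairs.append(ResiduePair(slot=slot, kind=PairKind.GAP))
            continue
        na, nb = ra.residue_name.upper(), rb.residue_name.upper()
        if na == nb or (ta.source == TriadSource.MAIN_CHAIN
                        and tb.source == TriadSource.MAIN_CHAIN):
            # position-wise AND keeps a class only where both sides are symmetric
            classes = tuple(
                ca if (ca is not None and cb is not None) else None
                for ca, cb in zip(ta.symmetry_classes, tb.symmetry_classes)
            )
            pairs.append(ResiduePair(
                slot=slot, kind=PairKind.MATCH,
                names_a=ta.atom_names, names_b=tb.atom_names,
                exchange_classes=_classes_to_groups(classes),
            ))
        elif _same_conservative_set(na, nb):
            classes = tuple(
                ca if (ca is not None and cb is not None) else None
                for ca, cb in zip(ta.symmetry_classes, tb.symmetry_classes)
            )
            pairs.append(ResiduePair(
                slot=slot, kind=PairKind.CONSERVATIVE,
                names_a=ta.atom_names, names_b=tb.atom_names,
                exchange_classes=_classes_to_groups(classes),
            ))
        else:
            # pseudo-mutation: all three functional atoms treated as equal
            pairs.append(ResiduePair(
                slot=slot, kind=PairKind.NONEQUIVALENT,
                names_a=ta.atom_names, names_b=tb.atom_names,
                exchange_classes=((0, 1, 2),),
            ))
    return pairs


def kabsch(
    P: np.ndarray,
    Q: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted least-squares rigid fit of P onto Q.

    Finds the proper rotation R and translation t minimising
    ``sum_i w_i ||R p_i + t - q_i||^2``.  A reflection in the optimal
    orthogonal transform is corrected by flipping the sign of the
    smallest singular component, so det(R) = +1 always.

    Returns (R, t, rmsd) with ``rmsd = sqrt(sum(w d^2)/sum(w))``.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must both be (n, 3)")
    n = P.shape[0]
    if n < 3:
        raise ValueError("at least 3 atom pairs are required")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0):
            raise ValueError("weights must be n nonnegative reals")
        if not np.any(w > 0):
            raise ValueError("weights must not all be zero")
    wsum = w.sum()
    cp = (w[:, None] * P).sum(axis=0) / wsum
    cq = (w[:, None] * Q).sum(axis=0) / wsum
    Pc, Qc = P - cp, Q - cq
    H = (w[:, None] * Pc).T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d == 0:  # rank-deficient covariance: pick the proper branch
        d = 1.0
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    dev = np.linalg.norm((R @ P.T).T + t - Q, axis=1)
    rmsd = float(np.sqrt((w * dev**2).sum() / wsum))
    return R, t, rmsd


def resolve_correspondence(
    pairs: list[ResiduePair],
    site_a: ActiveSite,
    site_b: ActiveSite,
) -> AtomCorrespondence:
    """Resolve the one-to-one atom mapping between two paired sites.

    Unambiguous atoms are mapped by triad position.  Within each
    exchangeability class the minimum-total-squared-distance perfect
    assignment (Hungarian algorithm) is taken after a crude unweighted
    Kabsch fit on the unambiguous atoms; if fewer than three such
    atoms exist, wildcard atoms in file (triad) order seed the crude
    fit, used for initialisation only.
    """
    entries = []  # (slot, pos, name_a, name_b, xyz_a, xyz_b, ambiguous)
    class_blocks = []  # (start index into entries of class, positions, pair)
    for pair in pairs:
        if pair.kind == PairKind.GAP:
            continue
        ra = site_a.residues[pair.slot]
        rb = site_b.residues[pair.slot]
        ca = ra.coords(pair.names_a)
        cb = rb.coords(pair.names_b)
        ambiguous = {p for grp in pair.exchange_classes for p in grp}
        base = len(entries)
        for pos in range(len(pair.names_a)):
            entries.append([pair.slot, pos, pair.names_a[pos], pair.names_b[pos],
                            ca[pos], cb[pos], pos in ambiguous])
        for grp in pair.exchange_classes:
            class_blocks.append((base, grp))
    if len(entries) < 3:
        raise ValueError("fewer than 3 atom pairs overall; cannot superpose")

    A = np.asarray([e[4] for e in entries])
    B = np.asarray([e[5] for e in entries])
    unamb = np.asarray([not e[6] for e in entries])

    # crude initial fit
    if unamb.sum() >= 3:
        Pc, Qc = A[unamb], B[unamb]
    else:
        Pc, Qc = A, B
    degenerate = _is_collinear(Pc) or _is_collinear(Qc)
    if degenerate:
        warnings.warn(
            "degenerate (collinear) geometry in crude fit; "
            "falling back to name-order atom mapping",
            RuntimeWarning,
        )
        R, t = np.eye(3), np.zeros(3)
    else:
        R, t, _ = kabsch(Pc, Qc)
    A_fit = (R @ A.T).T + t

    # Hungarian assignment inside each exchangeability class
    if not degenerate:
        for base, grp in class_blocks:
            idx = [base + p for p in grp]
            pa = A_fit[idx]
            pb = B[idx]
            cost = ((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2)
            rows, cols = linear_sum_assignment(cost)
            new_names_b = [entries[idx[c]][3] for c in cols]
            new_xyz_b = [entries[idx[c]][5] for c in cols]
            for k, i in enumerate(idx):
                entries[i][3] = new_names_b[k]
                entries[i][5] = new_xyz_b[k]

    return AtomCorrespondence(
        slots=np.asarray([e[0] for e in entries], dtype=int),
        names_a=[e[2] for e in entries],
        names_b=[e[3] for e in entries],
        coords_a=np.asarray([e[4] for e in entries]),
        coords_b=np.asarray([e[5] for e in entries]),
    )


def _is_collinear(X: np.ndarray, tol: float = 1e-8) -> bool:
    if len(X) < 3:
        return True
    Xc = X - X.mean(axis=0)
    s = np.linalg.svd(Xc, compute_uv=False)
    return bool(s[1] <= tol * max(s[0], 1.0))


def gaussian_weighted_superpose(
    site_a: ActiveSite,
    site_b: ActiveSite,
    c: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 50,
    table: dict | None = None,
) -> SuperpositionResult:
    """Iterative Gaussian-weighted rigid superposition of two sites.

    Parameters
    ----------
    c : float
        Gaussian variance parameter in Å²; atom weights are
        ``exp(-d^2/c)``.  ``c = inf`` reproduces the classical
        uniform-weight Kabsch fit.
    tol : float
        Convergence threshold on the change in wRMSD between rounds (Å).
    max_iter : int
        Maximum number of reweighting rounds; on non-convergence the
        best iterate is returned with ``converged=False``.
    """
    pairs = pair_residues(site_a, site_b, table)
    corr = resolve_correspondence(pairs, site_a, site_b)
    P, Q = corr.coords_a, corr.coords_b
    n = corr.n_atoms
    w = np.ones(n)
    prev_wrmsd = None
    trace: list[tuple[float, float]] = []
    converged = False
    R, t = np.eye(3), np.zeros(3)
    wrmsd = float("inf")
    iterations = 0
    for iterations in range(1, max_iter + 1):
        pre_dev = np.linalg.norm((R @ P.T).T + t - Q, axis=1)
        pre_obj = float((w * pre_dev**2).sum())
        R, t, wrmsd = kabsch(P, Q, w)
        dev = np.linalg.norm((R @ P.T).T + t - Q, axis=1)
        trace.append((pre_obj, float((w * dev**2).sum())))
        if prev_wrmsd is not None and abs(prev_wrmsd - wrmsd) < tol:
            converged = True
            break
        prev_wrmsd = wrmsd
        if np.isfinite(c):
            w = np.exp(-(dev**2) / c)
            if not np.any(w > 0):  # all deviations astronomically large
                w = np.ones(n)
        # c = inf: weights stay uniform (classical Kabsch limit)

    dev = np.linalg.norm((R @ P.T).T + t - Q, axis=1)
    per_res: dict[int, float] = {}
    for slot in np.unique(corr.slots):
        m = corr.slots == slot
        per_res[int(slot)] = float(np.sqrt(np.mean(dev[m] ** 2)))
    return SuperpositionResult(
        rotation=R,
        translation=t,
        wrmsd=wrmsd,
        per_residue_rmsd=per_res,
        max_residue_rmsd=max(per_res.values()),
        n_atoms=n,
        correspondence=corr,
        iterations=iterations,
        converged=converged,
        objective_trace=trace,
    )


def _batched_kabsch(
    P: np.ndarray, Q: np.ndarray, w: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Weighted Kabsch for a stack of point-set pairs.

    P, Q: (N, m, 3); w: (N, m).  Returns (R, t, wrmsd, dev) with the
    SVD batched over all N pairs at once.
    """
    wsum = w.sum(axis=1)
    cp = np.einsum("nm,nmi->ni", w, P) / wsum[:, None]
    cq = np.einsum("nm,nmi->ni", w, Q) / wsum[:, None]
    Pc = P - cp[:, None]
    Qc = Q - cq[:, None]
    H = np.einsum("nm,nmi,nmj->nij", w, Pc, Qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    d[d == 0] = 1.0
    D = np.ones((len(P), 3))
    D[:, 2] = d
    V = Vt.transpose(0, 2, 1)
    R = (V * D[:, None, :]) @ U.transpose(0, 2, 1)
    t = cq - np.einsum("nij,nj->ni", R, cp)
    dev = np.linalg.norm(
        np.einsum("nij,nmj->nmi", R, P) + t[:, None] - Q, axis=2)
    wrmsd = np.sqrt((w * dev**2).sum(axis=1) / wsum)
    return R, t, wrmsd, dev


def _permutations(k: int) -> np.ndarray:
    import itertools
    return np.asarray(list(itertools.permutations(range(k))))


def batched_pairwise_wrmsd(
    sites: list[ActiveSite],
    c: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 50,
) -> np.ndarray:
    """All-vs-all Gaussian-weighted wRMSD matrix for a homogeneous
    family (same residue type in every slot, no gaps).

    Numerically equivalent to calling
    :func:`gaussian_weighted_superpose` on every pair, but the crude
    fit, the exchange-class assignment (exhaustive over the <= 3!
    permutations of each class) and the reweighting iterations are
    batched over all pairs, with one stacked 3x3 SVD per round.

    Raises ``ValueError`` for heterogeneous families; callers fall
    back to the per-pair route.
    """
    n = len(sites)
    if n < 2:
        raise ValueError("need at least 2 sites")
    ref = sites[0]
    pairs = pair_residues(ref, ref)
    if any(p.kind != PairKind.MATCH for p in pairs):
        raise ValueError("family is not gap-free/homogeneous")
    sig = [None if r is None else r.residue_name for r in ref.residues]
    for s in sites[1:]:
        if [None if r is None else r.residue_name for r in s.residues] != sig:
            raise ValueError("family is not homogeneous")

    # fixed atom layout shared by every site
    blocks, unamb, class_groups = [], [], []
    offset = 0
    for p in pairs:
        blocks.append((p.slot, p.names_a))
        amb = {k for grp in p.exchange_classes for k in grp}
        unamb.extend(k not in amb for k in range(len(p.names_a)))
        for grp in p.exchange_classes:
            class_groups.append([offset + k for k in grp])
        offset += len(p.names_a)
    unamb = np.asarray(unamb)
    X = np.stack([
        np.concatenate([site.residues[slot].coords(names)
                        for slot, names in blocks])
        for site in sites
    ])
    I, J = np.triu_indices(n, k=1)
    P, Q = X[I].copy(), X[J].copy()
    N, m = P.shape[0], P.shape[1]

    # crude fit on unambiguous atoms, then resolve each exchange class
    # by exhaustive minimum over its permutations (= Hungarian, k <= 3)
    sub = unamb if unamb.sum() >= 3 else np.ones(m, bool)
    R0, t0, _, _ = _batched_kabsch(P[:, sub], Q[:, sub], np.ones((N, int(sub.sum()))))
    Pf = np.einsum("nij,nmj->nmi", R0, P) + t0[:, None]
    for idx in class_groups:
        perms = _permutations(len(idx))
        # cost[n, p] = sum_k |Pf[n, idx[k]] - Q[n, idx[perm[k]]]|^2
        diffs = Pf[:, idx][:, :, None, :] - Q[:, idx][:, None, :, :]
        d2 = (diffs**2).sum(axis=3)               # (N, k, k)
        rows = np.arange(len(idx))[None, :]       # (1, k) vs perms (P, k)
        cost = d2[:, rows, perms].sum(axis=-1)    # (N, P)
        best = perms[np.argmin(cost, axis=1)]     # (N, k)
        Qi = Q[:, idx]                            # (N, k, 3) copy
        Q[:, idx] = Qi[np.arange(N)[:, None], best]

    w = np.ones((N, m))
    prev = np.full(N, np.nan)
    done = np.zeros(N, bool)
    wrmsd = np.zeros(N)
    for _ in range(max_iter):
        _, _, wrmsd, dev = _batched_kabsch(P, Q, w)
        done |= np.abs(prev - wrmsd) < tol
        if done.all():
            break
        prev = wrmsd
        if np.isfinite(c):
            upd = ~done
            w[upd] = np.exp(-(dev[upd] ** 2) / c)
        else:
            break  # uniform weights never change

    M = np.zeros((n, n))
    M[I, J] = wrmsd
    M[J, I] = wrmsd
    return M


def ca_rmsd(site_a: ActiveSite, site_b: ActiveSite) -> float:
    """Plain unweighted Kabsch RMSD over the CA atoms of shared slots."""
    P, Q = [], []
    for ra, rb in zip(site_a.residues, site_b.residues):
        if ra is None or rb is None:
            continue
        aa, ab = ra.atom("CA"), rb.atom("CA")
        if aa is None or ab is None:
            continue
        P.append(aa.xyz)
        Q.append(ab.xyz)
    if len(P) < 3:
        raise ValueError("fewer than 3 shared CA atoms")
    _, _, rmsd = kabsch(np.asarray(P), np.asarray(Q))
    return rmsd
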