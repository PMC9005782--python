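"""Superposition kernel: triads, pairing, assignment, weighted fit."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sitevar.core import FunctionLocation
from sitevar.superpose import (
    PairKind,
    TriadUnavailableError,
    batched_pairwise_wrmsd,
    functional_triad,
    gaussian_weighted_superpose,
    kabsch,
    pair_residues,
    resolve_correspondence,
)
from sitevar.synthetic import make_reference_site, make_residue

from conftest import displace_site, rotation_about, swap_atoms


# ---------------------------------------------------------------------------
# triads

@pytest.mark.parametrize("resname,location,names,sym_sets", [
    ("ARG", "side_chain", ("CZ", "NH1", "NH2"), [{"NH1", "NH2"}]),
    ("HIS", "side_chain", ("ND1", "CE1", "NE2"), [{"ND1", "CE1", "NE2"}]),
    ("ASP", "side_chain", ("CG", "OD1", "OD2"), [{"OD1", "OD2"}]),
    ("GLY", "main_chain", ("N", "CA", "C"), []),
    ("SER", "main_chain", ("N", "CA", "C"), []),  # main-chain function wins
    ("SER", "side_chain", ("CA", "CB", "OG"), []),
])
def test_functional_triad_selection(resname, location, names, sym_sets):
    res = make_residue(resname, 5, function_location=FunctionLocation(location))
    triad = functional_triad(res)
    assert triad.atom_names == names
    groups = {}
    for n, c in zip(triad.atom_names, triad.symmetry_classes):
        if c is not None:
            groups.setdefault(c, set()).add(n)
    assert sorted(map(sorted, groups.values())) == sorted(map(sorted, sym_sets))


def test_missing_atom_raises():
    res = make_residue("ARG", 5)
    res.atoms = [a for a in res.atoms if a.name != "NH2"]
    with pytest.raises(TriadUnavailableError):
        functional_triad(res)


# ---------------------------------------------------------------------------
# pairing

def _site_of(residues, site_id="s", ref=False):
    from sitevar.core import ActiveSite

    return ActiveSite(site_id=site_id, structure_id="X", residues=residues,
                      is_reference=ref)


def test_pair_residues_mutation_taxonomy():
    a = _site_of([make_residue("ASP", 1), make_residue("LYS", 2),
                  make_residue("SER", 3)])
    b = _site_of([make_residue("GLU", 1), make_residue("ARG", 2), None])
    pairs = pair_residues(a, b)
    assert pairs[0].kind == PairKind.CONSERVATIVE
    # carboxylate triads paired position-wise, oxygens exchangeable
    assert pairs[0].names_a == ("CG", "OD1", "OD2")
    assert pairs[0].names_b == ("CD", "OE1", "OE2")
    assert pairs[0].exchange_classes == ((1, 2),)
    assert pairs[1].kind == PairKind.NONEQUIVALENT
    assert pairs[1].exchange_classes == ((0, 1, 2),)
    assert pairs[2].kind == PairKind.GAP
    assert pairs[2].names_a == ()


def test_missing_triad_atom_demotes_slot_to_gap():
    a = _site_of([make_residue("SER", 1), make_residue("HIS", 2),
                  make_residue("ASP", 3)])
    broken = make_residue("HIS", 2)
    broken.atoms = [x for x in broken.atoms if x.name != "CE1"]
    b = _site_of([make_residue("SER", 1), broken, make_residue("ASP", 3)])
    pairs = pair_residues(a, b)
    assert pairs[1].kind == PairKind.GAP


# ---------------------------------------------------------------------------
# Kabsch kernel

def test_kabsch_identity():
    P = np.random.default_rng(0).normal(size=(5, 3))
    R, t, rmsd = kabsch(P, P)
    assert np.allclose(R, np.eye(3), atol=1e-12)
    assert np.allclose(t, 0, atol=1e-12)
    assert rmsd < 1e-12


@settings(derandomize=True, max_examples=60)
@given(st.floats(-3, 3), st.floats(-3, 3), st.floats(-3, 3),
       st.floats(0.01, 3.1), st.floats(-20, 20), st.floats(-20, 20),
       st.floats(-20, 20))
def test_kabsch_recovers_planted_transform(ax, ay, az, angle, tx, ty, tz):
    if abs(ax) + abs(ay) + abs(az) < 1e-3:
        ax = 1.0
    rng = np.random.default_rng(1)
    P = rng.normal(size=(6, 3))
    R_true = rotation_about([ax, ay, az], angle)
    t_true = np.array([tx, ty, tz])
    Q = (R_true @ P.T).T + t_true
    R, t, rmsd = kabsch(P, Q)
    assert np.allclose(R, R_true, atol=1e-9)
    assert np.allclose(t, t_true, atol=1e-8)
    assert rmsd < 1e-9


def test_kabsch_contract_errors():
    P = np.zeros((2, 3))
    with pytest.raises(ValueError):
        kabsch(P, P)
    P = np.random.default_rng(0).normal(size=(4, 3))
    with pytest.raises(ValueError):
        kabsch(P, P, weights=np.zeros(4))
    with pytest.raises(ValueError):
        kabsch(P, P, weights=np.array([1, 1, -1, 1.0]))


def _rotation_grid_min_rmsd(P, Q, n=20000):
    """Brute-force oracle: best RMSD over a dense sample of proper
    rotations (optimal translation applied via centering)."""
    from scipy.spatial.transform import Rotation

    Pc = P - P.mean(0)
    Qc = Q - Q.mean(0)
    Rs = Rotation.random(n, random_state=0).as_matrix()
    rot = np.einsum("rij,mj->rmi", Rs, Pc)
    d2 = ((rot - Qc) ** 2).sum(axis=2).mean(axis=1)
    return float(np.sqrt(d2.min()))


def test_kabsch_mirror_stays_proper_and_matches_grid_oracle():
    """A mirrored chiral point set cannot be superposed exactly; the
    returned rotation must stay proper and its residual must match the
    brute-force minimum over a dense rotation sample."""
    P = np.array([[0, 0, 0], [1.5, 0, 0], [0, 1.2, 0], [0.3, 0.4, 1.7]])
    Q = P.copy()
    Q[:, 2] = -Q[:, 2]  # mirror image
    R, t, rmsd = kabsch(P, Q)
    assert np.isclose(np.linalg.det(R), 1.0, atol=1e-9)
    assert rmsd > 0.1
    best = _rotation_grid_min_rmsd(P, Q)
    # the analytic optimum can only improve on the sampled minimum
    assert rmsd <= best + 1e-9
    assert rmsd == pytest.approx(best, abs=0.05)


def test_weighted_kabsch_downweights_outlier():
    rng = np.random.default_rng(2)
    P = rng.normal(size=(6, 3))
    Q = P.copy()
    Q[5] += np.array([4.0, 0, 0])
    w = np.array([1, 1, 1, 1, 1, 1e-9])
    R, t, rmsd = kabsch(P, Q, w)
    core = np.linalg.norm((R @ P[:5].T).T + t - Q[:5], axis=1)
    assert core.max() < 1e-6


# ---------------------------------------------------------------------------
# symmetry resolution

def _brute_force_min_wrmsd(site_a, site_b, pairs):
    """Oracle: try every permutation inside every exchange class."""
    from sitevar.core import ActiveSite

    best = np.inf
    perm_spaces = []
    for p in pairs:
        for grp in p.exchange_classes:
            perm_spaces.append((p, grp, list(itertools.permutations(grp))))
    for combo in itertools.product(*[s[2] for s in perm_spaces]) or [()]:
        coords_a, coords_b = [], []
        for p in pairs:
            if p.kind == PairKind.GAP:
                continue
            ra = site_a.residues[p.slot]
            rb = site_b.residues[p.slot]
            names_b = list(p.names_b)
            for (pp, grp, _), perm in zip(perm_spaces, combo):
                if pp is p:
                    orig = [p.names_b[k] for k in grp]
                    for k, dst in zip(grp, perm):
                        names_b[k] = p.names_b[dst]
            coords_a.append(ra.coords(p.names_a))
            coords_b.append(rb.coords(tuple(names_b)))
        A = np.concatenate(coords_a)
        B = np.concatenate(coords_b)
        _, _, rmsd = kabsch(A, B)
        best = min(best, rmsd)
    return best


def test_his_flip_resolved_by_assignment(reference_site):
    """A 180-degree imidazole flip is a pure atom-naming ambiguity; the
    assignment must undo it exactly, while naive name-order mapping
    leaves a large residual."""
    flipped_res = swap_atoms(reference_site.residues[1], "ND1", "NE2")
    site_b = displace_site(reference_site)
    site_b.residues[1] = flipped_res
    res = gaussian_weighted_superpose(reference_site, site_b)
    assert res.wrmsd < 1e-6
    # name-order mapping (no exchange classes) cannot recover it
    naive = pair_residues(reference_site, site_b)
    coords_a = np.concatenate([reference_site.residues[p.slot].coords(p.names_a)
                               for p in naive])
    coords_b = np.concatenate([site_b.residues[p.slot].coords(p.names_b)
                               for p in naive])
    _, _, naive_rmsd = kabsch(coords_a, coords_b)
    assert naive_rmsd > 0.3


def test_asp_oxygen_swap_resolved(reference_site):
    site_b = displace_site(reference_site)
    site_b.residues[2] = swap_atoms(site_b.residues[2], "OD1", "OD2")
    res = gaussian_weighted_superpose(reference_site, site_b)
    assert res.wrmsd < 1e-6


def test_assignment_equals_exhaustive_minimum(reference_site):
    """Hungarian resolution must equal the brute-force permutation
    minimum on every exchange class, including the all-wildcard class
    of a non-equivalent mutation."""
    site_b = displace_site(reference_site, shifts={
        0: np.array([0.3, 0.1, -0.2]), 3: np.array([-0.2, 0.25, 0.1]),
    }, rotation=rotation_about([1, 1, 0], 0.4), translation=[3, -2, 1])
    # plant a non-equivalent mutation: LYS slot 5 -> ARG
    site_b.residues[5] = make_residue(
        "ARG", site_b.residues[5].residue_number,
        origin=site_b.residues[5].atom("CA").xyz)
    pairs = pair_residues(reference_site, site_b)
    res = gaussian_weighted_superpose(reference_site, site_b, c=np.inf)
    oracle = _brute_force_min_wrmsd(reference_site, site_b, pairs)
    assert res.wrmsd == pytest.approx(oracle, abs=1e-6)


def test_degenerate_collinear_falls_back_with_warning():
    from sitevar.core import ActiveSite, AtomRecord, CatalyticResidue

    def line_res(num, x):
        return CatalyticResidue(
            chain_id="A", residue_name="GLY", residue_number=num,
            function_location=FunctionLocation.MAIN_CHAIN,
            atoms=[AtomRecord("N", "N", (x, 0, 0)),
                   AtomRecord("CA", "C", (x + 0.5, 0, 0)),
                   AtomRecord("C", "C", (x + 1.0, 0, 0))])

    a = ActiveSite("a", "X", [line_res(1, 0.0), line_res(2, 5.0)])
    b = ActiveSite("b", "X", [line_res(1, 0.0), line_res(2, 5.0)])
    pairs = pair_residues(a, b)
    with pytest.warns(RuntimeWarning):
        corr = resolve_correspondence(pairs, a, b)
    assert corr.n_atoms == 6


# ---------------------------------------------------------------------------
# Gaussian-weighted fit

def test_identical_sites_zero_wrmsd(reference_site):
    res = gaussian_weighted_superpose(reference_site, reference_site)
    assert res.wrmsd < 1e-12
    assert all(v < 1e-12 for v in res.per_residue_rmsd.values())


def test_weighted_fit_locks_rigid_core(reference_site):
    """Five rigid residues plus one displaced by 5 Å: the reweighted
    fit must park the error on the mobile residue, while the uniform
    fit smears it over the core."""
    site_b = displace_site(reference_site, shifts={5: np.array([5.0, 0, 0])},
                           rotation=rotation_about([0, 1, 1], 0.7),
                           translation=[4, 4, -2])
    res = gaussian_weighted_superpose(reference_site, site_b)
    core = [res.per_residue_rmsd[i] for i in range(5)]
    assert max(core) < 0.05
    assert res.per_residue_rmsd[5] == pytest.approx(5.0, abs=0.3)
    uniform = gaussian_weighted_superpose(reference_site, site_b, c=np.inf)
    assert max(uniform.per_residue_rmsd[i] for i in range(5)) > 0.3


def test_uniform_limit_reproduces_classical_kabsch(reference_site):
    rng = np.random.default_rng(3)
    site_b = displace_site(
        reference_site,
        shifts={i: rng.normal(0, 0.4, 3) for i in range(6)},
        rotation=rotation_about([1, 0, 2], 1.1), translation=[1, 2, 3])
    res = gaussian_weighted_superpose(reference_site, site_b, c=np.inf)
    corr = res.correspondence
    _, _, classical = kabsch(corr.coords_a, corr.coords_b)
    assert res.wrmsd == pytest.approx(classical, abs=1e-6)


def test_wrmsd_symmetry_and_rigid_invariance(reference_site):
    rng = np.random.default_rng(4)
    site_b = displace_site(
        reference_site,
        shifts={i: rng.normal(0, 0.5, 3) for i in range(6)})
    ab = gaussian_weighted_superpose(reference_site, site_b).wrmsd
    ba = gaussian_weighted_superpose(site_b, reference_site).wrmsd
    assert ab == pytest.approx(ba, abs=1e-6)
    moved = displace_site(site_b, rotation=rotation_about([2, 1, 1], 2.2),
                          translation=[-7, 3, 9])
    ab2 = gaussian_weighted_superpose(reference_site, moved).wrmsd
    assert ab2 == pytest.approx(ab, abs=1e-6)


def test_objective_descends_within_each_round(reference_site):
    rng = np.random.default_rng(5)
    site_b = displace_site(
        reference_site,
        shifts={i: rng.normal(0, 0.8, 3) for i in range(6)})
    res = gaussian_weighted_superpose(reference_site, site_b)
    for pre, post in res.objective_trace:
        assert post <= pre + 1e-9


def test_batched_matrix_matches_per_pair_route(reference_site):
    rng = np.random.default_rng(6)
    sites = [reference_site] + [
        displace_site(reference_site,
                      shifts={i: rng.normal(0, 0.5, 3) for i in range(6)},
                      site_id=f"h{k}")
        for k in range(4)
    ]
    M = batched_pairwise_wrmsd(sites)
    for i in range(len(sites)):
        for j in range(i + 1, len(sites)):
            ref = gaussian_weighted_superpose(sites[i], sites[j]).wrmsd
            assert M[i, j] == pytest.approx(ref, abs=1e-9)
    assert np.allclose(M, M.T)
    assert np.allclose(np.diag(M), 0)
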