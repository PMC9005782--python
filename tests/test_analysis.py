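"""Family-level analyses: matrices, filters, grouping, clustering,
paradigms, quadrants, enrichment."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sitevar.core import PairComparison, Paradigm
from sitevar.analysis import (
    all_vs_all_matrix,
    apply_pair_filters,
    classify_paradigm,
    cluster_sites,
    compare_pair,
    enrichment_odds_ratios,
    flexibility_quadrant,
    group_pairs_by_ligand_state,
    quadrant_fractions,
)
from sitevar.synthetic import EnsembleSpec, generate_site_ensemble, make_reference_site

from conftest import displace_site, displacement_field as _displacement_field


# ---------------------------------------------------------------------------
# matrices

def test_identical_sites_give_zero_matrix(reference_site):
    M = all_vs_all_matrix([reference_site,
                           displace_site(reference_site, site_id="b")])
    assert np.allclose(M, 0, atol=1e-9)


def test_matrix_recovers_planted_pair_distances(reference_site):
    """Three sites with planted pairwise wRMSDs ~ (0.1, 2.0, 2.0):
    the displacement fields live on the fitted (triad) atoms only, are
    equal-magnitude, rigid-motion-free and mutually orthogonal, so
    each is an exact fixed point of the reweighted fit and the planted
    values survive.  Residue types without exchangeable atoms are
    used, otherwise symmetry reassignment would (correctly) absorb
    part of the plant."""
    from sitevar.superpose import functional_triad

    reference_site = make_reference_site(
        residue_names=("SER", "THR", "CYS", "ASN", "GLN", "TYR"))
    rng = np.random.default_rng(11)
    triad_names = [functional_triad(r).atom_names
                   for r in reference_site.residues]
    P = np.concatenate([r.coords(names) for r, names
                        in zip(reference_site.residues, triad_names)])
    f1 = _displacement_field(P, 0.1, rng)
    f2 = _displacement_field(P, 2.0, rng, orthogonal_to=f1)

    def apply_field(f, site_id):
        from dataclasses import replace
        from sitevar.core import AtomRecord
        out, k = [], 0
        for r, names in zip(reference_site.residues, triad_names):
            shifts = {}
            for name in names:
                shifts[name] = f[k]
                k += 1
            atoms = [AtomRecord(a.name, a.element,
                                tuple(a.xyz + shifts.get(a.name, 0.0)))
                     for a in r.atoms]
            out.append(replace(r, atoms=atoms))
        return replace(reference_site, residues=out, site_id=site_id,
                       is_reference=False)

    b = apply_field(f1, "b")
    c = apply_field(f2, "c")
    M = all_vs_all_matrix([reference_site, b, c])
    assert M[0, 1] == pytest.approx(0.1, abs=0.05)
    assert M[0, 2] == pytest.approx(2.0, abs=0.05)
    # |f2 - f1| = sqrt(2^2 + 0.1^2) atomwise by orthogonality
    assert M[1, 2] == pytest.approx(np.sqrt(4.01), abs=0.05)
    assert np.array_equal(M, M.T)
    assert np.allclose(np.diag(M), 0)


# ---------------------------------------------------------------------------
# clean-up filters

def _pair(wrmsd, max_res, **kw):
    defaults = dict(site_a="a", site_b="b", family_id="F", ca_rmsd=0.4,
                    resolution=1.5, is_nmr=False, ec_number="1.1.1.1",
                    has_gap=False, intra_distance_discrepancy=0.5)
    defaults.update(kw)
    return PairComparison(wrmsd=wrmsd, max_residue_rmsd=max_res, **defaults)


def test_ligand_effect_outlier_rule_boundary():
    """wRMSD 1.6 with max residue 5.0 is excluded (5.0 > 3 x 1.6);
    with max residue 4.0 it is retained (4.0 < 4.8)."""
    excluded = _pair(1.6, 5.0)
    retained = _pair(1.6, 4.0)
    out = apply_pair_filters([excluded, retained], "ligand_effect")
    assert out == [retained]


@pytest.mark.parametrize("pair,profile", [
    (_pair(0.4, 0.5, resolution=2.5), "seq_struct"),
    (_pair(0.4, 0.5, is_nmr=True), "seq_struct"),
    (_pair(11.0, 12.0), "seq_struct"),
    (_pair(0.4, 0.5, ca_rmsd=11.0), "seq_struct"),
    (_pair(0.4, 0.5, ec_number=None), "ligand_effect"),
    (_pair(0.4, 0.5, has_gap=True), "ligand_effect"),
    (_pair(0.4, 0.5, intra_distance_discrepancy=5.5), "ligand_effect"),
    (_pair(11.0, 12.0), "ligand_effect"),
    (_pair(5.0, 21.0), "ligand_effect"),
])
def test_each_cleanup_rule_fires(pair, profile):
    assert apply_pair_filters([pair], profile) == []


def test_family_cap_sampling_is_seeded_and_idempotent():
    pairs = [_pair(0.4, 0.5, site_a=f"s{i}", site_b=f"t{i}") for i in range(100)]
    out1 = apply_pair_filters(pairs, "seq_struct", seed=42)
    out2 = apply_pair_filters(pairs, "seq_struct", seed=42)
    assert len(out1) == 30
    assert out1 == out2
    assert apply_pair_filters(out1, "seq_struct", seed=42) == out1  # idempotent
    assert apply_pair_filters(pairs, "seq_struct", seed=7) != out1


# ---------------------------------------------------------------------------
# ligand-state grouping

def test_bucket_combinatorics_hand_counted():
    """3 free and 2 bound sites in one family: C(3,2)=3 free_free,
    C(2,2)=1 bound_bound, 3x2=6 bound_free pairs."""
    bound = [False, False, False, True, True]
    pairs = []
    for i, j in itertools.combinations(range(5), 2):
        state = {(False, False): "free_free", (True, True): "bound_bound"}.get(
            (bound[i], bound[j]), "bound_free")
        pairs.append(_pair(0.5, 0.6, site_a=f"s{i}", site_b=f"s{j}",
                           same_protein=True, conserved=True,
                           ligand_state=state))
    groups = group_pairs_by_ligand_state(pairs)
    counts = {k[2]: sum(1 for p in pairs if p.ligand_state == k[2])
              for k in groups}
    assert counts == {"free_free": 3, "bound_bound": 1, "bound_free": 6}
    assert set(groups) == {(True, True, "free_free"), (True, True, "bound_bound"),
                           (True, True, "bound_free")}


def test_all_mutated_leaves_conserved_buckets_empty():
    pairs = [_pair(0.5, 0.6, conserved=False, ligand_state="free_free")]
    groups = group_pairs_by_ligand_state(pairs)
    assert all(not conserved for _, conserved, _ in groups)


def test_planted_bound_state_ordering():
    """Bound-bound pairs planted at low RMSD, free-free at high: the
    per-family means must recover bound_bound < free_free."""
    rng = np.random.default_rng(13)
    pairs = []
    for fam in ("F1", "F2"):
        for k in range(10):
            pairs.append(_pair(abs(rng.normal(0.3, 0.05)), 1.0, family_id=fam,
                               ligand_state="bound_bound"))
            pairs.append(_pair(abs(rng.normal(1.0, 0.1)), 2.0, family_id=fam,
                               ligand_state="free_free"))
            pairs.append(_pair(abs(rng.normal(1.2, 0.1)), 2.0, family_id=fam,
                               ligand_state="bound_free"))
    g = group_pairs_by_ligand_state(pairs)
    for fam in ("F1", "F2"):
        bb = g[(False, True, "bound_bound")][fam]
        ff = g[(False, True, "free_free")][fam]
        bf = g[(False, True, "bound_free")][fam]
        assert bb < ff < bf


# ---------------------------------------------------------------------------
# clustering

def _upgma_oracle(M, cut):
    """Brute-force average-linkage agglomeration for tiny matrices."""
    clusters = [[i] for i in range(M.shape[0])]
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = np.mean([M[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        if d > cut:
            break
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return sorted(tuple(sorted(c)) for c in clusters)


def test_two_conformer_groups_yield_two_clusters(reference_site):
    """Two tight conformer groups ~0.2 Å wide and far apart must give
    exactly two clusters with correct membership."""
    rng = np.random.default_rng(17)
    dirs = rng.normal(size=(6, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    sites = []
    for k in range(8):
        state = k % 2
        shifts = {i: state * 2.5 * dirs[i] + rng.normal(0, 0.05, 3)
                  for i in range(6)}
        sites.append(displace_site(reference_site, shifts=shifts, site_id=f"s{k}"))
    M = all_vs_all_matrix(sites)
    res = cluster_sites(M)
    assert res.labels.max() == 2
    states = np.array([k % 2 for k in range(8)])
    # cluster labels must partition exactly by state
    assert len({(s, l) for s, l in zip(states, res.labels)}) == 2


def test_identical_sites_form_single_cluster(reference_site):
    sites = [displace_site(reference_site, site_id=f"c{i}") for i in range(4)]
    M = all_vs_all_matrix(sites)
    assert cluster_sites(M).labels.max() == 1


def test_agreement_with_brute_force_agglomeration():
    rng = np.random.default_rng(19)
    for trial in range(5):
        pts = rng.normal(size=(6, 2)) * 2
        M = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = cluster_sites(M)
        oracle = _upgma_oracle(M, res.cut_height)
        got = sorted(
            tuple(sorted(np.flatnonzero(res.labels == lab)))
            for lab in np.unique(res.labels))
        assert got == oracle, trial


def test_nan_cells_imputed_with_matrix_max():
    M = np.array([[0.0, 1.0, np.nan], [1.0, 0.0, 1.2], [np.nan, 1.2, 0.0]])
    res = cluster_sites(M)
    assert len(res.labels) == 3


# ---------------------------------------------------------------------------
# paradigms (single-ensemble sanity; the recovery-rate study lives in
# the acceptance suite)

@pytest.mark.parametrize("preset,expected", [
    ("rigid", Paradigm.RIGID),
    ("flexible", Paradigm.FLEXIBLE),
    ("two_state", Paradigm.OPEN_CLOSED),
    ("extensive", Paradigm.EXTENSIVE),
])
def test_paradigm_presets_recovered(preset, expected):
    ens = generate_site_ensemble(EnsembleSpec(preset=preset, n_sites=50, seed=1))
    M = all_vs_all_matrix(ens.family.all_sites)
    call = classify_paradigm(M, n_sites=len(ens.family.all_sites), seed=0)
    assert call.label == expected


def test_small_families_are_unclassified():
    ens = generate_site_ensemble(EnsembleSpec(preset="rigid", n_sites=10, seed=2))
    M = all_vs_all_matrix(ens.family.all_sites)
    call = classify_paradigm(M, n_sites=11)
    assert call.label == Paradigm.UNCLASSIFIED
    assert classify_paradigm(np.array([0.1]), n_sites=60).label == Paradigm.UNCLASSIFIED


# ---------------------------------------------------------------------------
# quadrants

@pytest.mark.parametrize("ca,fn,expected", [
    (0.2, 0.3, "rigid_both"),
    (0.2, 0.9, "side_chain_only"),
    (0.9, 0.3, "main_chain_only"),
    (0.9, 0.9, "flexible_both"),
    (0.5, 0.5, "flexible_both"),   # boundary inclusive on flexible
    (0.5, 0.2, "main_chain_only"),
])
def test_flexibility_quadrants(ca, fn, expected):
    assert flexibility_quadrant(ca, fn) == expected


@settings(derandomize=True, max_examples=100)
@given(st.floats(0, 30, allow_nan=False), st.floats(0, 30, allow_nan=False))
def test_quadrant_is_a_total_function(ca, fn):
    """Every nonnegative (CA, functional) RMSD pair lands in exactly
    one of the four quadrants, consistent with the 0.5 Å threshold."""
    q = flexibility_quadrant(ca, fn)
    assert q in {"rigid_both", "flexible_both", "side_chain_only",
                 "main_chain_only"}
    assert (ca >= 0.5) == (q in {"flexible_both", "main_chain_only"})
    assert (fn >= 0.5) == (q in {"flexible_both", "side_chain_only"})


def test_quadrant_fractions_sum_to_one():
    rng = np.random.default_rng(23)
    pairs = [_pair(w, w, ca_rmsd=c)
             for w, c in zip(rng.uniform(0, 1.2, 40), rng.uniform(0, 1.2, 40))]
    fr = quadrant_fractions(pairs)
    assert sum(fr.values()) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# enrichment

def _records(rows):
    return pd.DataFrame(rows, columns=["family_id", "residue_type", "role",
                                       "role_category", "rmsd"])


def test_odds_ratio_matches_hand_arithmetic():
    """His is 10/100 of the flexible partition and 30/100 of the rigid
    one -> odds ratio 1/3 exactly."""
    rows = []
    for i in range(100):  # flexible partition (rmsd >= 0.5)
        rows.append(("F", "HIS" if i < 10 else "SER", "r", "reactant", 1.0))
    for i in range(100):  # rigid partition
        rows.append(("F", "HIS" if i < 30 else "SER", "r", "reactant", 0.1))
    table = enrichment_odds_ratios(_records(rows), sample_per_family=200)
    his = table[table["group"] == "HIS"].iloc[0]
    assert his["freq_flexible"] == pytest.approx(0.10)
    assert his["freq_rigid"] == pytest.approx(0.30)
    assert his["odds_ratio"] == pytest.approx(1 / 3)


def test_type_absent_from_rigid_partition_gets_infinite_marker():
    rows = [("F", "LYS", "r", "spectator", 0.9)] * 10 \
         + [("F", "SER", "r", "reactant", 0.1)] * 10
    table = enrichment_odds_ratios(_records(rows), sample_per_family=50)
    lys = table[table["group"] == "LYS"].iloc[0]
    assert np.isinf(lys["odds_ratio"])


def test_rare_groups_below_two_percent_suppressed():
    rows = [("F", "SER", "r", "reactant", 0.1)] * 99 \
         + [("F", "TRP", "r", "reactant", 0.9)]
    table = enrichment_odds_ratios(_records(rows), sample_per_family=200)
    assert "TRP" not in set(table["group"])


def test_planted_role_category_effect_straddles_one():
    """Reactant residues perturbed at sigma 0.1 Å and spectators at
    1.0 Å: the spectator odds ratio must exceed 1, the reactant ratio
    must fall below it."""
    rng = np.random.default_rng(29)
    rows = []
    for fam in ("F1", "F2", "F3"):
        for _ in range(60):
            rows.append((fam, "SER", "nucleophile", "reactant",
                         abs(rng.normal(0, 0.1)) * np.sqrt(6)))
            rows.append((fam, "LYS", "stabiliser", "spectator",
                         abs(rng.normal(0, 1.0)) * np.sqrt(6)))
    table = enrichment_odds_ratios(_records(rows), sample_per_family=50,
                                   group_by="role_category", seed=1)
    by = {r["group"]: r["odds_ratio"] for _, r in table.iterrows()}
    assert by["spectator"] > 1.0 > by["reactant"]


def test_enrichment_sampling_is_seeded():
    rng = np.random.default_rng(31)
    rows = [("F", rng.choice(["SER", "HIS"]), "r", "reactant",
             float(rng.uniform(0, 1.2))) for _ in range(300)]
    t1 = enrichment_odds_ratios(_records(rows), seed=5)
    t2 = enrichment_odds_ratios(_records(rows), seed=5)
    pd.testing.assert_frame_equal(t1, t2)
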