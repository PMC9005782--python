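# Methods

This note documents the models and procedures implemented in
`sitevar`, the assumptions behind them, the parameters that matter,
and what the synthetic-data tests do and do not demonstrate.

## Coordinate and numbering conventions

All coordinates are Å.  Residues keep author numbering from the
source file; within a site, residues occupy 0-based ordinal *slots*
aligned to the family reference, with explicit `None` for a
non-aligned residue (gap).  On structure load only the first model is
kept, hydrogens are dropped, and alternate locations are reduced to
the highest-occupancy conformer (ties broken alphabetically by altloc
id) — the superposition mathematics requires single-conformer sites.
NMR entries can be loaded but are excluded by the dataset filters.

## Site reconstruction

An assembly may contain several copies of a site, and a site may
straddle two chains.  Reconstruction is seeded on the first
catalytic-residue hit in (chain, residue-number) order; every residue
equivalent to it (same name and number in another chain) seeds one
cluster.  When the reference itself lists k > 1 equivalence-group
copies of that (name, number) — a symmetric interface site such as the
aspartate pair of a retroviral protease dimer — the n equivalent hits
seed n // k clusters instead, so one interface site is built rather
than two half-sites.  Growth is globally greedy: at each step the
(cluster, slot, candidate) addition with the smallest distance to the
cluster's center of mass (all heavy atoms, unit masses) is made; ties
break on lower (chain, residue number).  The original procedure
seeded on a random residue; a deterministic first-in-order seed is
used here so results are reproducible and chain-order invariant.

**Sanity rules.**  Non-standard residue or chain numbering can
assemble geometric nonsense.  Every inter-residue center-of-mass
distance above 8 Å must be at most 3× its counterpart in the
manually-annotated reference, and at most 1.3× the equivalent
distance in every sibling site of the same structure.  The 8 Å gate
is applied to both rules (the sibling rule is a tightened version of
the reference rule, not an independent criterion); thresholds are
empirical and exposed as parameters.

**Redundancy.**  Biological assemblies replicate sites through
crystallographic symmetry.  Sites are walked in build order and one is
dropped when its functional-atom wRMSD to an already-retained site is
below 0.5 Å — an estimate of coordinate error at typical resolution.
This means a perfect homodimer yields two *built* sites but one
*retained* site, which is the intended behaviour.

## Superposition

Each catalytic residue contributes a three-atom functional triad.
Side-chain triads follow a shipped, overridable table chosen on
chemical function (Arg: CZ/NH1/NH2; Lys: CD/CE/NZ; His: the ring
atoms ND1/CE1/NE2; Asp: CG/OD1/OD2; …); residues acting through the
main chain, post-translationally modified residues, and Ala/Gly/Pro
use N/CA/C.  A residue missing a required atom demotes its slot to a
gap with a logged warning.

Mutation handling: conservative substitutions within {Asp, Glu},
{Asn, Gln}, {Ser, Thr, Tyr}, {Val, Leu, Ile} are paired position-wise
over chemically analogous triad atoms; any other substitution pairs
all three atoms as mutually exchangeable wildcards; gaps are excluded
entirely.

Atom-identity ambiguity (His ring flips, Asp/Glu carboxylate oxygen
swaps, Phe ring and Val/Leu methyl pairs, Arg NH pair) is resolved
per exchangeability class by the Hungarian algorithm on squared
distances after a crude unweighted Kabsch fit over the unambiguous
atoms; with fewer than three unambiguous atoms the crude fit falls
back to file-order inclusion of wildcards, and degenerate (collinear)
geometry falls back to name-order mapping with a warning.  Classes
here never exceed three atoms, so the assignment provably equals the
exhaustive permutation minimum (asserted in tests).

The final fit is iteratively re-weighted least squares: starting from
uniform weights, each round solves the weighted Kabsch problem (SVD
with reflection correction, so det R = +1 always), recomputes per-atom
deviations d_i, and sets w_i = exp(−d_i²/c).  Defaults: c = 2.0 Å²,
convergence when the wRMSD changes by less than 1e−5 Å, at most 50
rounds (non-convergence returns the last iterate flagged).  c → ∞
recovers the classical Kabsch fit exactly.  The wRMSD is
√(Σ w d²/Σ w) under the final weights; per-residue RMSDs are
*unweighted* under the final transform, so a mobile residue's true
displacement is reported rather than its down-weighted shadow.  The
exact weight kernel and schedule are this package's own construction,
consistent with the published Gaussian-weighted RMSD literature.

Two implementations exist: a per-pair route that handles gaps and
mutations, and a batched route for homogeneous gap-free families that
stacks all pairs into one array pipeline (one batched 3×3 SVD per
round; exchange classes resolved by vectorised exhaustive
permutation).  They agree to < 1e−9 Å and the batched route is ~20×
faster; `all_vs_all_matrix` picks automatically.

A note on planted-deformation fixtures: at deformations ≳ 2 Å the
reweighting deliberately manufactures a core out of whatever subset
fits best, so naive "displace everything by δ and expect wRMSD = δ"
fixtures collapse.  Test fixtures therefore plant equal-magnitude
displacement fields orthogonal to the six rigid-body modes on the
triad atoms of symmetry-free residues, which are exact fixed points of
the iteration.

## Ligand annotation

Adjacent components are found with a k-d tree search of 3 Å radius
around every catalytic atom plus one pseudo-center at the mean center
of mass of each residue pair more than 6 Å apart (so a ligand in the
gap of a spread-out site is not missed).  Polymer residues from
chains not contributing to the site are merged into one POLYMER
record per chain; distal cofactor/substrate-like components are
reported within 30 Å of the site centroid and never duplicate
adjacent records.  Distal records are reported but feed no downstream
statistic.

Chemical similarity is an atom-overlap score on the maximum common
connected induced subgraph of the two element-labelled bond graphs
(bond orders ignored): |MCS| / (|A| + |B| − |MCS|).  The search is an
exact McGregor-style branch-and-bound; a pluggable engine hook allows
swapping in an external cheminformatics backend.  The score is
undefined for single-atom components and polymers.  Classification
order: ≥ 0.6 against any cognate reaction component → substrate-like;
else cofactor by three-letter-code table; else artefact if in the
additive table and ≤ 0.3 against every cognate (and every cofactor
with a known graph); else uncertain.  The shipped cofactor/artefact
tables are editable data files, not exhaustive references.

Centrality of a ligand is its mean center-of-mass distance to the
catalytic residues divided by the mean inter-residue center-of-mass
distance; values near 1/√3 ≈ 0.58 indicate a ligand amid an
equilateral three-residue site, values ≫ 1 a peripheral one.  It is
undefined for single-residue sites.

## Dataset filters and groupings

Two clean-up profiles mirror the two analysis tracks:

* `seq_struct`: resolution ≤ 2.0 Å, no NMR, both RMSD measures
  ≤ 10 Å, then a seeded random cap of 30 pairs per family against
  over-represented superfamilies.
* `ligand_effect`: resolution/NMR as above, an EC number required, no
  gapped sites, mean intra-residue distance discrepancy ≤ 5 Å,
  wRMSD ≤ 10 Å, max single-residue RMSD ≤ 20 Å, and exclusion of
  pairs with wRMSD > 1.5 Å whose max residue RMSD exceeds 3× the
  wRMSD (a signature of erroneous site building rather than biology).

Every exclusion is logged with a rule tag; filters are idempotent.
Pairs are grouped by same/different protein (sequence-accession
equality stands in for a UniProt mapping), conserved/mutated
residues, and ligand state — a site counts as *bound* when it has at
least one adjacent non-artefact ligand (substrate-like or cofactor) —
with per-family mean wRMSD reported in each of the 12 buckets.

## Paradigm classification

Families with at least 50 sites are labelled from their all-vs-all
wRMSD matrix.  The four paradigms were originally assigned by visual
inspection of RMSD histograms; the decision rule here formalizes that
judgement with explicit, configurable statistics:

1. **open/closed** — a 2-component Gaussian mixture beats 1 component
   by ΔBIC > 10, component separation > 2 pooled σ, *and* a forced
   2-way average-linkage partition of the sites shows between/within
   mean-RMSD contrast ≥ 1.8 with both groups ≥ 15 % of sites: two
   distinct conformations without intermediates.
2. **extensively variable** — sites are not exchangeable: the spread
   of per-site mean RMSD exceeds 0.22 of the overall spread while the
   absolute spread exceeds 0.1 Å (the guard keeps pure experimental
   noise, whose relative heterogeneity is meaningless, from being
   read as structure).
3. **inherently rigid** — mean wRMSD < 0.5 Å, i.e. flexibility within
   the experimental error bar.  (The histogram means of rigid
   families in the source analyses run below 1 Å; under the weighted
   fit and these generator conditions 0.5 Å — the same experimental
   error threshold used for the rigid/flexible quadrants — is the
   defensible boundary, and it is a parameter.)
4. **inherently flexible** — everything else: unimodal spread beyond
   error with exchangeable sites.

Fewer than 50 sites (or fewer than 2 values) → unclassified.  When
only a flat vector of pairwise values is supplied the partition and
exchangeability evidence are unavailable and the rule degrades to the
mixture statistics alone.

Per-pair flexibility quadrants compare CA RMSD and functional-atom
wRMSD against 0.5 Å (flexible at or above the threshold): rigid-both,
flexible-both, side-chain-only, main-chain-only.

Enrichment odds ratios partition per-residue RMSD observations at
0.5 Å into rigid and flexible sets after a seeded per-family sample
of at most 50 observations, compute within-partition frequencies per
residue type / role / role category, and report
freq_flexible/freq_rigid.  Groups under 2 % of the sample are
suppressed; a zero rigid frequency reports an infinite marker.

## Synthetic data: what it emulates, and what it does not

`generate_site_ensemble` builds a reference site from idealized
residue templates (backbone + triad atoms at chemically sensible
offsets; no rotamer realism) arranged on a 7 Å ring, and homologues as
the reference under a random rigid motion plus per-residue
perturbations:

* `rigid` — isotropic per-residue shifts, σ = 0.1 Å;
* `flexible` — per-residue σ drawn once per family from [0.5, 1.5] Å;
* `two_state` — a third of the residues (configurable) toggle between
  two conformers 2.5 Å apart with 0.1 Å background noise;
* `extensive` — half the residues drift on a per-site random walk
  with 0.5 Å steps.

Perturbation fields have their best-fit rigid component removed
before application: a net rigid drift is not a deformation of site
geometry (superposition removes it exactly), so leaving it in would
make the recorded ground truth overstate the true displacement.  All
randomness flows through one seeded generator; output is
bit-reproducible.  `generate_assembly` writes matching mmCIF, PDB and
annotation files and supports homodimers, two-chain interface sites
with equivalence groups, planted ligands, and decoy residues that
violate the 3× sanity rule.

What passing tests on this data show: the pipeline's algebra, the
estimator's bias structure, and the classifier's behaviour under
known distributions.  What they do not show: robustness to real
crystallographic pathologies (correlated anisotropic error, missing
atoms and density, alternate conformer mixtures, non-isotropic loop
motion), realistic rotamer geometry, or the empirical base rates of
the four paradigms in real structure collections.  Problem sizes in
tests and the acceptance script (50 ensembles per preset, 50 sites
per ensemble) are the package's chosen study conditions for the
recovery-rate checks.

## Numerical choices and degenerate inputs

* Reflection in the Kabsch SVD is corrected by flipping the smallest
  singular component; rank-deficient covariance takes the proper
  branch (d = +1).
* Collinear point sets cannot fix a rotation; the correspondence step
  detects them via the second singular value and falls back to
  name-order mapping with a `RuntimeWarning`.
* Ties: equidistant clustering candidates break on lower
  (chain, residue number); equal-similarity cognate matches break on
  the lexicographically smallest component id; altloc occupancy ties
  break alphabetically.
* An all-zero RMSD matrix clusters as a single conformer (the cut
  height is floored at 1e−8 Å above float noise).
* NaN matrix cells (failed superpositions) are imputed with the
  matrix maximum before clustering, and logged.

## Known limitations

* The weighted fit's wRMSD is not a metric; symmetry holds to 1e−6 Å
  for converged fits but the triangle inequality is not guaranteed.
* The MCS search is exponential in the worst case; it is exact and
  fast for enzyme-scale small molecules, but very large ligands
  should use the pluggable external engine.
* Interface-site reconstruction assumes the annotation's
  equivalence-group count divides the number of equivalent hits;
  partially occupied interface assemblies fill what they can and
  leave null slots.
* Paradigm thresholds are calibrated on the generator's study
  conditions; applying them to matrices from other sources may
  require retuning the configurable cuts.
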