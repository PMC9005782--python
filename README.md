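# sitevar

Enzyme active sites are small constellations of catalytic residues, and
across the many crystal structures of one enzyme family those
constellations are not static: side chains flip, loops carry residues
between open and closed positions, and ligand binding locks conformers
in place.  `sitevar` is a library and command-line tool for studying
this conformational variability.  Given protein structures (mmCIF/PDB)
and catalytic-residue annotations, it

1. **reconstructs** every copy of an active site in a biological
   assembly — including sites straddling two chains — validates the
   geometry against the family reference, and removes redundant
   symmetry-mate copies;
2. **superposes** homologous sites over *functional atom triads* with
   a symmetry-aware, Gaussian-weighted Kabsch fit;
3. **annotates ligands** near each site and classifies them as
   substrate-like, cofactor or crystallisation artefact by a maximum
   common-substructure similarity score; and
4. **classifies family-level behaviour** into four conformational
   paradigms: inherently rigid, inherently flexible, open/closed
   (two-state), and extensively variable.

It is aimed at structural bioinformaticians working with
catalytic-site annotations who want reproducible, per-residue-resolved
comparisons of active-site conformers without aligning whole chains.

## The core statistic

Two homologous sites are compared over three functional atoms per
catalytic residue (e.g. Arg contributes its guanidino tips CZ, NH1,
NH2; main-chain-acting residues contribute N, CA, C).  After resolving
atom correspondence — conservative mutations (Asp↔Glu, Asn↔Gln,
Ser↔Thr↔Tyr, Val↔Leu↔Ile) are paired over analogous atoms,
non-equivalent mutations over wildcards, and chemically
indistinguishable atoms (His ring, Asp/Glu carboxylate oxygens, …) by
the Kuhn–Munkres assignment after a crude Kabsch fit — the sites are
aligned by iteratively re-weighted least squares:

    w_i ← exp(−d_i² / c),        R, t ← argmin Σ w_i ‖R p_i + t − q_i‖²

with `c = 2 Å²` by default, iterated to a 10⁻⁵ Å fixed point.  The
reported **wRMSD** `= √(Σ w_i d_i² / Σ w_i)` locks onto the invariant
core of the site and parks the error on genuinely mobile residues;
per-residue RMSDs under the final transform expose which residues
those are.  Family-level all-vs-all wRMSD matrices then feed conformer
clustering (average linkage, dendrogram pruned at 0.4 × the maximum
merge height) and the paradigm classifier.

## Worked example

Everything is testable offline: the `sitevar.synthetic` module
generates structures, annotations and conformer ensembles with known
ground truth.  Simulate a two-state family of 50 sites and analyze it:

```sh
$ sitevar simulate --preset two_state --n-sites 50 --seed 2 --out demo/sim
wrote demo/sim/family.json (50 homologous sites)

$ sitevar analyze --family demo/sim/family.json --min-sites 50 --out demo/an
paradigm open_closed, 9 clusters -> demo/an/analysis.json
```

`analysis.json` then contains (abridged):

```
paradigm: open_closed
mean 0.348   sd 0.161   delta_bic 1062.9   component_separation 5.16
```

Reading: the all-vs-all wRMSD distribution over the 1 275 site pairs
has mean 0.35 Å, but a two-component mixture is preferred over one by
ΔBIC ≈ 1063 with the component means more than 5 pooled standard
deviations apart, and the sites split into two populated groups with a
sharp between/within contrast — the signature of a site toggling
between two distinct conformations (here planted by the generator, so
the call is checkable).  A `rigid` preset instead yields mean wRMSD
≈ 0.2 Å and a single component; a `flexible` preset a unimodal spread
beyond the 0.5 Å experimental-error bar.

The same pipeline runs on real files: `sitevar build-sites` takes an
mmCIF/PDB assembly plus a JSON annotation file (schema documented in
`sitevar/io.py`), and `sitevar annotate-ligands`, `sitevar superpose`
and `sitevar analyze` consume the intermediate outputs.

## Layout

```
src/sitevar/
  core.py       domain types (sites, residues, molecules, results)
  io.py         mmCIF/PDB reading, annotation JSON schema, tables
  superpose.py  triads, mutation pairing, Hungarian assignment,
                weighted Kabsch (per-pair and batched)
  sites.py      site clustering, sanity rules, redundancy reduction
  ligands.py    k-d tree searches, MCS similarity, classification
  analysis.py   matrices, filters, grouping, clustering, paradigms,
                quadrants, enrichment
  synthetic.py  generators with recorded ground truth
  cli.py        subcommand pipeline
  data/         editable cofactor and artefact code tables
docs/methods.md the methods note: model, assumptions, parameters
```
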