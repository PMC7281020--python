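# Methods

This note records the modelling choices, parameter conventions and
numerical details behind the package, and what the synthetic benchmark
does and does not establish.

## Model and assumptions

The method assumes a monogenic metabolic disorder perturbs metabolite
concentrations in the network neighborhood of the affected protein's
primary reaction, and that this perturbation is detectable as extreme
control-referenced Z-scores in untargeted metabolomics. Gene ranking is a
pure enrichment problem: no flux model, kinetics or direction of change is
assumed — only that aberrant metabolites cluster inside the right gene's
metabolite set. Consequences of the assumptions:

- **Undirected traversal.** Set extension ignores reaction direction.
  Substrate accumulation upstream of a block is as diagnostic as product
  depletion downstream, so a directed traversal would systematically
  discard upstream biomarkers (classically, tyrosine several steps
  upstream of the fumarylacetoacetase defect).
- **Global participation counts.** The extension-stringency gate compares
  a metabolite's participation count computed once on the full
  blacklist-filtered network, not on any subgraph, because the count
  proxies the metabolite's global promiscuity (currency behavior), which
  does not depend on which gene's set is being built.
- **Uniform gate.** The stringency gate applies to distance-0 members as
  well. A gene whose primary reaction involves only promiscuous
  metabolites therefore keeps its primary set but never extends it. The
  alternative (always expanding from the primary set) is available as
  `ExtensionParams(exempt_primary=True)`; the default is the uniform rule
  because the gate is defined per metabolite, not per distance.
- **Enrichment background.** The Fisher 2×2 universe is the set of
  measured (annotated, finite-Z) entities of the patient's profile.
  Enrichment must be judged relative to what the assay can see; a
  background of all network metabolites would penalize genes whose
  neighborhoods are poorly ionizable for reasons unrelated to the patient.
- **One-sided test.** The method asks whether aberrant metabolites are
  over-represented in a set; a two-sided option exists
  (`enrich_gene(..., two_sided=True)`) but is not the default.
- **Worst-rank ties.** Tied p-values all receive the worst rank of the
  tie block. This is conservative for the top-10 criterion: diagnostic
  value can never be inflated by arbitrary within-tie ordering, and all
  missed genes (p = 1.0) share the list's final block. `min` and
  `average` tie rules are available on `prioritize`.

## Parameters

| parameter | meaning | default | grid |
|---|---|---|---|
| D, max distance | extension steps from the primary reaction | 4 | 0–5 |
| T, extension stringency | max reactions a metabolite may join to be expanded through | 15 | 8, 10, 12, 15, 17, 19 |
| (L, U), biochemical stringency | paired Z thresholds; aberrant iff Z < L or Z > U (strict) | (−3, +3) | (−1, 1.5), (−1.5, 2), (−3, 3), (−5, 5) |
| ppm window | peak-to-mass annotation tolerance | 2 ppm | — |
| scan range | m/z interval retained | 70–600 | — |

The single-combination defaults (D = 4, T ≤ 15, ±3.0) reflect the regime
that performs best on real dried-blood-spot cohorts — moderate extension
with a strict Z threshold; on any new assay the full 144-cell sweep
(`parameter_sweep` / `crossomics sweep`) should be rerun rather than
trusting these defaults.

Z-scores use the sample (n−1) standard deviation — control cohorts are
small (~30) — and technical replicates are averaged per sample *before*
control statistics; a per-replicate alternative was considered and
rejected because the replicate level is pure technical noise. A control's
own value stays in the reference statistics by default
(`compute_zscores(..., leave_one_out=True)` for sensitivity analysis).
Entities with zero control variance have no defined Z: they are flagged
and excluded from both the enrichment universe and the sets' measured
intersections, never silently dropped.

The shipped currency-metabolite blacklist (water, proton, ATP/ADP/AMP,
phosphate, NAD(P)(H), FAD(H₂), CoA, CO₂, O₂, H₂O₂, ammonia, Na⁺, K⁺) is a
placeholder keyed to lower-case common names; users of a real reaction
database must substitute their own curated identifier list
(`--blacklist`).

## Evaluation conventions

- Simulated exomes draw `n_background` (default 200) distinct genes from
  the universe *excluding* the disease gene, then append it — exactly 201
  distinct candidates, so list length is never eroded by collisions.
- Diagnostic value = fraction of analyses with disease-gene rank ≤ 10
  (boundary inclusive). Missed disease genes sit in the final tie block
  and can never count as accurate in any non-degenerate list.
- Gene sets depend only on (D, T): the sweep builds 36 set collections
  and reuses them across the 4 thresholds. A gene's p-value against a
  patient depends only on (gene, patient, combination), not on the
  simulated exome, so p-values are precomputed once per combination and
  repetitions only sample candidate lists and read ranks. The equivalence
  of this vectorized path with the per-gene `prioritize` path is asserted
  in the test suite.
- Randomness: one master seed spawns per-(patient, repetition) child
  streams (`numpy.random.SeedSequence`), making sweeps bit-reproducible
  and candidate lists independent across repetitions.
- The random-chance baseline follows the Monte-Carlo recipe (uniform
  disease position vs. uniform top-10 subset, 1000 × 97 draws) whose
  analytic expectation is 10/201 ≈ 0.0498; both are exposed.

## Synthetic studies

`SyntheticSpec` defaults define the benchmark conditions: 300 metabolites,
220 reactions (1–2 metabolites per side), 2% hub metabolites injected to
participation > 19 so the stringency gate is exercised, 200 genes (10%
unmapped, 10% with two primary reactions), 30 controls, 40 patients,
effect size β = 5 decaying by δ = 0.6 per step out to one reaction from
the primary set, alternating sign with distance parity, 20% lognormal
control noise, 2% replicate jitter, and 60% assay coverage (40% of
metabolites have no mass-table entry, emulating compounds — e.g. reactive
CoA esters — that direct-infusion metabolomics never sees). Partial
coverage is what gives distance extension its value: when a primary set is
invisible to the assay, only D ≥ 1 sets can catch the surrounding signal,
which is the method's central claim. Signal is implanted as multiplicative
intensity shifts, so the package's own annotation, isomer collapsing and
Z computation lie between the generator and any recovered effect; the
perturbation footprint never propagates through hub metabolites, since a
metabolic block does not perturb the neighborhoods of currency metabolites
it happens to share.

What passing synthetic benchmarks does **not** show: robustness to real
network topology (degree correlations, pathway modularity), adducts and
in-source fragments, batch effects, partially treated patients (the
generator's `treated_fraction` nulls signal entirely), or database
incompleteness beyond random masking. Absolute diagnostic values on real
cohorts cannot be inferred from the synthetic recovery rate.

## Problem sizes

The shipped test-suite and benchmark sizes are chosen so a full run
completes in well under a minute of compute for the unit layer and a few
tens of seconds for the grid sweep: the synthetic recovery benchmark uses
the default 40-patient cohort with 100 repetitions and 151-gene candidate
lists (the 200-gene synthetic universe cannot support 201-gene lists, so
the random-chance reference is computed for list length 151 accordingly);
extension is verified exhaustively on 100 random networks of 6–16
metabolites; Fisher p-values are verified against an exact-rational
hypergeometric tail sum on every 2×2 table with total ≤ 12.

## Known limitations

- Gene names are the only genetic input; variant-level evidence
  (zygosity, pathogenicity scores) is out of scope by design.
- Metabolite identifiers are opaque strings; compartmentalized databases
  (the same species in several compartments) are used as given.
- Adduct/charge handling is the caller's responsibility: the mass table
  must already live in the measured m/z space.
- Genes without a reconstructable metabolite set can never be prioritized,
  however causal; this is intrinsic to the method, not an implementation
  limit.
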