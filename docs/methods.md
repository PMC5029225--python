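# Methods

## Module model and quantification

A module database is an ordered list of modules; a module an ordered list of
steps; a step a disjunction of alternatives; an alternative a conjunction
(complex) of ortholog identifiers. Modules are *linear* step lists — there
are no parenthesised sub-paths. Branched real-world definitions must be
pre-flattened into alternatives within steps; this keeps "fraction of steps
detected" well defined, since coverage presumes a flat step count.

Quantification of module *M* in sample *s*:

- complex abundance = min over members (a complex is limited by its scarcest
  subunit; a missing member zeroes the complex);
- step abundance = max over alternatives (the best available route carries
  the step; summing alternatives would double-count promiscuous enzymes and
  change the abundance unit);
- coverage = detected steps / total steps, an exact rational k/n stored as a
  float;
- presence = coverage **strictly greater than** the threshold (default 2/3,
  a user flag). The gate is strict by definition, so a 2-step module with
  one detected step (coverage 0.5) is absent at threshold 0.5.
- abundance = mean of step abundances over the **covered steps only**
  (median available via `estimator="median"` for robustness to one inflated
  step); 0 when no step is covered. Abundance and coverage are always
  reported even when the presence gate fails, so the gate only flips calls,
  never hides measurements.

Consequences used as test invariants: abundance is degree-1 homogeneous in
the input matrix while coverage and presence are scale-invariant; adding
abundance anywhere never decreases any coverage; a module of singleton steps
reduces to "fraction of its orthologs detected".

Orthologs referenced by the database but missing from the matrix count as 0.
Matrix orthologs matching no module are warned about and counted in the run
log — they are signal the database cannot interpret, relevant when judging
database completeness.

## Two-group comparison

Module abundance vectors (absence contributing 0 — absence is biologically
informative, not missing data) are compared between two groups with the
two-sided Wilcoxon rank-sum test. The U statistic is computed from midranks.
The p-value is exact when the pooled n is at most 25 and the pooled values
are tie-free: the full null distribution of U is built from the count
recurrence c(n, m, u) = c(n−1, m, u−m) + c(n, m−1, u) (counts stay below
2^53 up to n+m = 25, so float64 arithmetic is exact), and
p = min(1, 2·min(P(U ≤ u), P(U ≥ u))). Otherwise a normal approximation is
used with tie-corrected variance and a continuity correction that shrinks
|U − nm/2| by 0.5 with a floor at zero — the floor makes elementwise-equal
groups return p = 1 exactly rather than a value slightly below it. The
small-sample regime matters here: typical designs in this field have 4–10
samples per group, where asymptotic p-values are unreliable.

Multiple testing uses the Benjamini–Hochberg step-up,
q_(i) = min_{j ≥ i} (m·p_(j)/j) capped at 1, computed over the **tested**
modules only. A module is tested when it is present in at least
`min_prevalence` (default 0.2) of all samples; all-zero or nearly-absent
modules would otherwise enlarge m and dilute power — the same argument that
favours a biome-specific database over a universal one. Significance is
q ≤ alpha (default 0.05). Direction is the sign of median_a − median_b
("none" iff equal). Output rows sort by (q, p, module id), a stable,
deterministic order. The tested grid can be switched from abundance to
coverage with a flag; abundance is the default because it is the quantity
the module definitions are designed to estimate.

## Parsimony filter

Per sample, the observed orthologs (positive abundance, occurring in at
least one module) must be explained by a minimum-cardinality set of modules
(unweighted set cover over module ortholog content; abundances are
deliberately ignored — the question is existence, not dosage). Orthologs in
no module are reported as unexplained and excluded from the requirement,
otherwise no cover exists. The exact solver is branch-and-bound: greedy
upper bound, branching on the ortholog with the fewest covering modules,
pruning with the bound |chosen| + ceil(|uncovered| / max content size);
tie-breaks are deterministic (larger new coverage first, then lexicographic
module id), and `mode="auto"` uses exact up to 20 candidate modules. Greedy
mode is the classical ln(d)+1-approximation. Parsimony runs on raw observed
orthologs (pre-gate) and is intersected with the coverage gate: presence
after filtering requires both. Coverage and abundance grids are never
modified — the filter only forces presence calls to false, with a per-pair
reason recorded (`kept`, `redundant_by_parsimony`, `no_observed_orthologs`).

The filter is exposed but off by default: it is a comparator/diagnostic, not
part of the core workflow, and it can also remove genuinely co-present
modules whose content is subsumed by a larger module.

## Synthetic data

The generators exist so that every stage is testable with known ground
truth; they are pure functions of (parameters, seed).

`generate_module_db` draws step counts uniformly from `steps_range`
(default 2–4), alternatives from `alts_range` (default 1–2), makes an
alternative a 2-member complex with probability `p_complex` (default 0.15),
and with probability `p_shared` reuses an ortholog from an earlier module —
the cross-module enzyme sharing that creates decoy artifacts.

`generate_abundance` gives every ortholog occurrence a contribution
`base_scale × effect × noise` per sample, where the module's effect
multiplier applies in group A only, and orthologs shared between modules
**sum** their modules' contributions — so a decoy sharing enzymes with a
truly shifted module inherits its signal by construction. Noise is
ortholog-level (coverage then varies realistically across samples):
lognormal with σ = 0.5 for intensity-like data, or negative binomial with
dispersion 0.3 (variance μ + 0.3μ²) for count-like data; `base_scale`
defaults to 100.

What the generators do **not** emulate: compositionality/normalisation
artefacts of real sequencing depth, correlated noise between orthologs of
one organism, taxonomic structure, or the heavy zero-inflation of real
spectral counts beyond what the negative-binomial produces. Passing tests
therefore demonstrate correctness of the algorithms under a clean planted
model, not performance guarantees on real meta-omics data.

The worked example (`make_worked_example`) is hand-written, not sampled: 6
modules, 12 orthologs, 8 samples (4 vs 4 — the small-n regime typical of
metaproteome studies). Three modules carry a ~4× shift in the healthy group;
`XD9001` is a decoy whose two steps are both orthologs of the shifted
butyrate module, so it is present everywhere and perfectly separated between
groups despite having no biology of its own. Values were chosen tie-free
within each module's 8-sample abundance vector so the exact rank-sum path
applies, and such that four modules attain the minimal exact p = 2/70,
making the BH-adjusted q = 6·(2/70)/4 ≈ 0.0429 cross the 0.05 line — the
fixture thus exhibits the decoy artifact at q-level significance and its
complete removal by exact parsimony (the decoy's content is a strict subset
of the butyrate module's, so no minimal cover contains it).

## Numerical and format choices

- All output TSVs use 6-significant-digit floats, 1/0 booleans, "NA" for
  untested p/q, Unix newlines; runs on identical inputs are byte-identical
  (the run log carries counts, never timestamps).
- Map-coloring effects are log2(median_a/median_b); a zero median is
  replaced by ε = (smallest positive abundance in the profile)/10, recorded
  in the run log. At small n zero medians are common, and the guard keeps
  the sign and a finite magnitude.
- The module flat-file grammar reserves `,` `+` `/` `#` and whitespace;
  identifiers may not contain them. Parsing accepts Windows newlines,
  writing always emits Unix newlines, and parse(write(db)) is exact.
- Degenerate inputs: empty module files parse to an empty database; an
  empty observed set yields an empty cover; fewer than two tested modules
  warns but still runs; empty groups, unassigned profiled samples, negative
  or non-finite abundances, and ragged TSV rows are hard errors (exit
  status 2 at the CLI, with file and line in the message).

## Problem sizes in the checks

The acceptance script and test suite use: 200 enumeration instances
(pooled n ≤ 10), 1000 BH vectors (m ≤ 100), 500 quantification modules,
100 set-cover instances (≤ 12 modules, exhaustive subset oracle), 1000 null
modules at 10 vs 10 for type-I calibration, and 20 planted-recovery runs at
8 vs 8 with a 4× effect. These sizes give stable verdicts (e.g. the null
rejection rate has a sampling SD of ~0.007 around the exact test's achievable
level of ~0.045) while the whole script completes in seconds.

## Known limitations

- Two-group designs only; no paired tests, no >2-group analysis, no
  covariate adjustment.
- Linear modules only (see above); no KEGG flat-file import.
- Parsimony is unweighted; abundance-weighted covers are out of scope.
- The exact test's discreteness makes achievable significance levels jump
  at very small n (4 vs 4 cannot go below p = 2/70); this is a property of
  the statistic, not of the implementation.
- The ILP route for set cover is unnecessary at the supported scales; the
  branch-and-bound is exact and fast for the ≤ 20-candidate auto regime,
  and greedy handles anything larger.
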