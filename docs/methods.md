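# Methods

## The inference problem

The package integrates four independent public evidence streams into a
single hypothesis object — a bipartite network of plausible repressive
miRNA:mRNA interactions in papillary (PTC) and anaplastic (ATC) thyroid
carcinoma — and then asks whether alteration of the network's target
genes carries clinical signal in a tumor cohort. None of the streams is
trusted on its own: literature reports conflict, individual prediction
algorithms have high false-positive rates, and expression datasets come
from heterogeneous platforms. Every stage is therefore a *vote-counting
consensus* rather than a quantitative meta-analysis.

## Stage models and parameters

### Literature vote counting

Input: one call per (study, tumor type, miRNA) with a direction. After
alias normalization (a packaged many-to-one table; strict mode rejects
unknown names, lenient mode passes them through with a warning; no
heuristic arm guessing), calls are tallied per (miRNA, tumor type) over
distinct studies. With `m` the minimum study count (default 3):

* `selected` — n_reports ≥ m and unanimous direction;
* `inconsistent` — n_reports ≥ m with both directions reported
  (unanimity is required: a single opposite report vetoes selection,
  regardless of how many agree);
* `insufficient` — n_reports < m.

A study contributing to both tumor types counts once per type; evidence
never crosses types. Output ordering is a stable sort by tumor type,
descending report count, then name. Raising `m` can only shrink the
selected set.

The packaged fixture digitizes a published multi-study deregulation
table (53 miRNAs, 174 calls over 11 PTC and 4 ATC study columns). Under
m = 3 it yields a 10-miRNA PTC panel (12 miRNAs reach three reports; 2
are inconsistent) and a 7-miRNA ATC panel — the arithmetic the
acceptance script recomputes.

### Target-prediction consensus

Votes are (miRNA, gene, algorithm) triples from a declared roster
(default: the 8 comparative predictors a miRWalk-style query
aggregates). Undeclared algorithms and duplicate votes are hard errors
— both indicate a misjoined join key, which silent dropping would hide.
A pair is a consensus target at `vote_count ≥ a` (default 5 of 8,
boundary inclusive). Gene identifiers are opaque symbols; no
symbol/Entrez mapping is attempted, so inputs must be pre-harmonized.

### Cross-dataset DE concordance

Per dataset and gene: log2 fold-change and adjusted p (GEO2R-style
columns are accepted on input). A dataset supports a direction iff
`adj_p < alpha` (strict, default 0.05) and the sign matches; `log_fc ==
0` with small p is logged and supports nothing. A gene is `consensus`
when the larger directional support is at least fraction `f` (default
0.5) of the datasets *in which the gene is measured* and the opposite
direction has zero significant support; `--denominator all` restores
the stricter all-datasets denominator. Significant support in both
directions is `conflicting` — mirroring the unanimity veto at the
miRNA level. Genes measured once can reach consensus (1/1) unless
`min_datasets` says otherwise.

### Network construction

Edge (m, g) exists iff m is selected for the tumor type, (m, g) is a
consensus target, g is a consensus DE gene, and the two directions are
opposite. The rule is per-pair: a gene may anti-correlate with one
targeting miRNA and be discarded against another. Concordant candidate
pairs are kept in a discard log with a reason, because exclusions are
part of the result. Edges carry `vote_count` so consumers can
re-threshold without re-joining. Direction symmetry (swapping up↔down
everywhere) leaves the edge set unchanged, and this is tested.

### Enrichment

For a query list of size n drawn against a background of size N, a set
with K members in the background and k in the query scores

* `p = P(X ≥ k)`, hypergeometric upper tail, evaluated in log space and
  clamped into (0, 1];
* EASE variant `P(X ≥ k−1)` (default, matching DAVID's conservative
  convention; equals 1 for k ≤ 1);
* `fold = (k/n)/(K/N)`, `percent = 100·k/n`.

The background defaults to the union of genes measured in the DE stage;
published DAVID-style tables used an unknowable 2015-era annotation and
background, so their p-values are structural references only, not
reproduction targets. Raw p-values are reported by default with BH
correction opt-in, since the reference tables show uncorrected values.
The percent column is defined as 100·k/n; published tables are
internally inconsistent on this column for some rows, and that
discrepancy is documented rather than imitated. Rank-based running-sum
enrichment ("GSEA" proper) is deliberately out of scope — the
statistics here are overlap counts on a fixed list.

### Clinical association

*Alteration calls.* z = (x − mean)/sd per gene, reference population =
all samples by default; `reference_samples` switches to a
diploid-style reference subset (the convention of cBioPortal z-scores
is not uniquely fixed, so both are exposed; concordance with the real
cBioPortal pipeline is explicitly not a test target). Threshold
inclusive at |z| ≥ 2.0. Zero-variance and missing genes are skipped
with a log message. A sample is altered when ≥ 1 listed gene triggers.

*Group comparison.* Kolmogorov–Smirnov against a normal with the
group's own mean and sd gates the branch (Lilliefors correction behind
a flag); both groups Gaussian at `alpha_normal = 0.05` → Student's
t-test, else Mann–Whitney. For combined n ≤ 12 the Mann–Whitney p is
exact: the U statistic is enumerated over all C(n, n_a) assignments of
the pooled midranks, which handles ties without approximation; larger
samples use scipy's tie-corrected normal approximation. Star codes:
\* p<0.05, ** p<0.01, *** p<0.001.

*Survival.* Kaplan–Meier product-limit curves and the two-group
log-rank test are delegated to lifelines; tests pin them to
hand-computed product-limit and observed-minus-expected tables, and to
a Monte-Carlo null calibration (rejection rate at nominal 0.05 within
[0.03, 0.07] over 2000 null cohorts). Time units are metadata
(months assumed for TCGA-style exports) and never converted.

## Synthetic data: what it emulates, what it does not

Generators are pure functions of `(config, seed)`; each stage draws
from its own `SeedSequence` substream in a fixed order, so resizing one
input never perturbs another. Defaults mirror the *shape* of the real
study: ~10 literature studies with a core of strongly replicated
miRNAs plus sparse noise calls (noise on planted miRNAs is concordant,
so recovery failures isolate the selection logic); an 8-algorithm
panel where planted pairs get ≥ 5 votes and background pairs draw
Binomial(8, 0.2) votes (spurious consensus rate = the Binomial tail
P(X ≥ 5) ≈ 1%, verified against the closed form); 5 DE datasets where
planted genes are significant with the anti-correlated sign in
⌈5·f⌉ = 3 datasets and null elsewhere; a 20-set GMT collection with
one set overlapping the true targets far beyond chance; and a
388-sample cohort, one third altered, with 3-sd shifts in two
co-altered genes, exponential survival at hazard ratio 3 against a
60-month baseline median, and independent exponential censoring tuned
to the requested censoring fraction.

Effect sizes (3-sd shifts, HR 3, |log2FC| ≈ 2) are chosen for clear
desk-scale recovery, not to mimic real-data magnitudes. The generators
do not simulate probe-level microarray structure, sequence-based
prediction, nomenclature drift, correlated noise between studies, or
covariate-dependent censoring — so passing recovery tests demonstrates
the pipeline's logic, not robustness to those real-data pathologies.
Adjusted p-values are generated directly (uniform nulls, sub-threshold
planted) because the pipeline consumes adjusted values; simulating raw
intensities plus a correction step would add nothing the consumers can
see. An expected ~5% of planted DE genes are vetoed by a significant
opposite null draw; end-to-end edge recall reflects that and the
recovery tests bound it accordingly.

## Numerical and degenerate-input choices

* Hypergeometric tails via `scipy.stats.hypergeom.logsf`, exponentiated
  and clamped to [5e-324, 1]; exhaustively checked against
  integer-arithmetic enumeration for all configurations with N ≤ 60 at
  1e-10.
* BH adjustment via statsmodels; it dominates raw p, caps at 1, and is
  monotone after sorting. Re-applying BH to its own output is *not* a
  fixed point (the step-up minimum inflates already-adjusted values);
  only determinism and the dominance/monotonicity invariants are
  guaranteed.
* Identical constant groups degenerate the t-test to NaN; the
  comparison reports p = 1 (not different) instead.
* Empty networks, empty queries, all-censored survival and empty call
  matrices are valid inputs with defined outputs (warning, k = 0 rows
  at p = 1, flat curve at 1, empty tally).
* Tallies, consensus tables, edges and enrichment rows all have
  documented deterministic sort orders so outputs are byte-stable.

## Problem sizes used in the test suite

The suite exercises the oracle sweeps and calibrations at sizes chosen
to keep a full run around two minutes on one core: the exhaustive
hypergeometric sweep covers N ≤ 60 (~1.1 M tail values), Mann–Whitney
exactness is checked on 100 random small-sample inputs, log-rank null
calibration uses 2000 cohorts of n = 100, null DE calibration uses
10,000 genes × 5 datasets, and planted-structure recovery averages 50
seeds for the selection stage and 20 full end-to-end seeds. These are
the package's reference conditions; nothing in the code depends on
them.

## Known limitations

* Vote counting discards effect sizes and study quality; a
  well-powered study counts the same as a small one. This is the
  intended design, not an approximation to a random-effects model.
* The unanimity veto is harsh at large m: one contrarian study can
  block an otherwise overwhelming consensus.
* Per-dataset DE computation (limma/GEO2R) is upstream of this
  package; duplicated gene rows are rejected rather than collapsed.
* The enrichment background is a modeling choice that changes p-values
  materially; the default (genes measured in the DE stage) is sensible
  but not canonical.
* Risk-group dichotomization is taken as a given label in the cohort
  file; the package does not derive it from clinical attributes.
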