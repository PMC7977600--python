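# Methods

## The analysis model

The workflow models a single-channel spotted miRNA array experiment with a
pooled design: per experimental group (AL control, CR, EX, HF) the RNA of
several animals is pooled onto **one** array, so between-animal variance is
invisible and no replicate-based test is possible. Differential expression
is therefore a deterministic screen on normalized fold changes, and all
inferential statistics in the package live where replication exists: the
over-representation analysis (many genes) and the qPCR validation (five
animals per group).

Processing steps, with their conventions:

1. **Net intensity** = foreground − background per spot, kept on the raw
   linear scanner scale. Negative nets are retained (they can never enter
   the reference or accepted sets, but clamping would bias medians near
   zero).
2. **Replicate collapsing**: median over a probe's replicate spots on one
   array; even counts use the midpoint of the two central order statistics.
3. **Median normalization**: the reference set is the probes with net
   **strictly above 50** in *all* samples; each sample is divided by its own
   median over that shared set. One divisor per sample makes arrays
   comparable while a shared reference set keeps the divisors estimating
   the same quantity. (A single global median could not correct
   between-array scale; per-sample medians over a common set is the
   standard reading of median normalization, and the two coincide when
   arrays share a scale — a fact the tests exploit.)
4. **Acceptance filter**: per comparison, a probe is kept iff its raw net
   is **≥ 50 in at least one** of the two compared samples. The floor is
   applied to raw nets, not normalized values, because 50 is a raw-unit
   scanner threshold. Note the deliberate asymmetry with step 3: the
   reference set uses "> 50 in all samples", the acceptance filter "not
   (< 50 in both)".
5. **Fold-change calls**: up iff FC ≥ 1.5 (inclusive), down iff FC ≤ 2/3.
   The down threshold is the reciprocal of the up threshold — symmetric
   screening on the log scale. Accepted probes with non-positive control
   signal cannot yield a meaningful ratio; they are excluded with a warning
   and reported as filtered.
6. **Abundance strata** per group: very-low iff raw net < 50 in that
   group's sample; the remaining accepted probes are ranked by normalized
   intensity and split top 25% high / middle 50% medium / bottom 25% low.
   Tail sizes are round-half-up of n/4 at both tails (so |high| = |low| and
   the partition is exact); value ties break by probe id for determinism.
   Ranking uses normalized values (an option exposes raw ranking).
7. **Cross-condition algebra**: a probe filtered or unchanged in a
   comparison is *absent* from that comparison's DE set; the union,
   per-condition shares (|DE_t|/|union|), pairwise concordant/discordant
   overlaps and direction-pattern labels (fixed CR, EX, HF order) are pure
   set operations, tested against exhaustive enumeration.
8. **Consensus targets**: a miRNA–gene pair is kept iff predicted by at
   least 3 of the 4 supplied predictor exports; gene symbols are
   case-normalized first. Predictor internals are out of scope — the tables
   are inputs. A tissue-specificity table then restricts targets to genes
   annotated to the requested tissue; unannotated genes are dropped and
   counted separately.
9. **Over-representation**: per term, the 2×2 table (k, n−k; K−k,
   N−K−n+k) is tested one-sided for enrichment with the exact
   hypergeometric upper tail P(X ≥ k); Pearson's χ² (no continuity
   correction by default; Yates flag available) is reported alongside.
   The tail sum accumulates scipy `hypergeom.pmf` terms from the extreme
   tail upward, which keeps tiny p-values at full double precision.
   Benjamini–Hochberg FDR is applied within each category (BP, CC, MF,
   pathway) to mirror per-category reporting; a term is significant iff
   both p < α and FDR < α (α = 0.05). The EASE deflation (testing k−1) is
   available but off by default. The default universe is the gene pool
   behind the supplied term map; it is an explicit argument.
10. **qPCR**: technical replicates are averaged (mean by default, median
    optional), ΔCt = Ct_target − Ct_reference per sample, ΔΔCt anchors on
    the arithmetic mean ΔCt of the control group (so the control group's
    geometric-mean RQ is exactly 1), RQ = 2^−ΔΔCt. Group comparisons use
    Student's t (Welch optional) or one-way ANOVA with Tukey's HSD;
    zero-variance degenerate inputs are flagged rather than producing NaN
    (equal means → t = 0, p = 1; unequal → p reported at machine epsilon
    with a warning). Summaries are mean ± SE of RQ.

## Synthetic data: what it emulates and what it does not

The generator is the package's instrument: every pipeline input is produced
with known ground truth.

* **Arrays**: 601 probes, quadruplicate spots, one pooled sample per group.
  A fraction (default 0.55) of probes is expressed with baseline signal
  2^N(8, 2²), truncated below at 60 raw units so that, noise-free, a probe
  is detectable iff it is expressed. Backgrounds are N(30, 5²) clipped at
  zero; spots carry multiplicative 2^N(0, 0.1²) noise and additive N(0, 3²)
  scanner noise. DE is planted per treatment with rates calibrated to the
  motivating study's printed counts — fractions 0.087/0.120/0.135 of
  expressed probes DE in CR/EX/HF with up-shares 0.808/0.974/0.513 — and is
  biased toward low-abundance probes via exponential rank weights
  (`abundance_bias`, default 2). Planted fold changes are 1.5·2^(m+|N(0,s)|)
  for up (reciprocal for down), so every planted effect clears the screen
  threshold by construction; `m` lets tests plant exact 3-fold effects.
* **Predictor tables**: true miRNA–gene pairs receive a support count drawn
  from a configurable distribution over 0–4 predictors; decoys are always
  supported by ≤ 2, so 3-of-4 consensus can recover truth exactly when the
  rates allow.
* **Annotation tables**: null terms sample genes uniformly; planted
  enriched terms sample with a configurable odds weight on a designated
  selection.
* **Ct plates**: per-animal loading effects (which cancel in ΔCt), planted
  fold changes encoded as −log2 FC shifts of the target Ct, Gaussian cycle
  noise, n = 5 animals per group, triplicate wells, U6-style reference.

Not emulated: scanner spatial artifacts, dye bias, probe-specific affinity,
cross-hybridization, carry-over between predictors' error modes, GO-graph
structure (terms are flat gene sets), or amplification-efficiency
differences in qPCR. Passing tests therefore demonstrate the *procedures*
are correct and calibrated under clean distributional assumptions, not that
the thresholds are optimal for any real chip. Two real-data features are
deliberately muted at the defaults: per-group detected counts are nearly
equal (real arrays lose more probes near the floor), and planted fold
changes concentrate just above 1.5, so fold-change calls recover only part
of the planted truth at the defaults — as a threshold screen on one array
pair genuinely would.

## Numerical and design choices

* Percentages destined for reports use decimal half-up rounding to one
  decimal, matching the printed-value convention; this is exposed as
  `de_screen.percent`.
* Medians everywhere are midpoint-of-central-pair for even counts (numpy's
  convention, asserted against a sort-and-pick oracle).
* The abundance quartile rule round-half-up(n/4) at both tails was chosen
  over ceil-at-both-tails; the two differ by at most one probe and agree on
  the documented examples.
* Fisher p-values are computed by tail summation rather than
  `1 − cdf` to avoid cancellation; agreement with an exact
  integer-arithmetic oracle is ≤ 1e-12 relative error on all tables with
  N ≤ 60.
* Type-I calibration checks use large, dense hypergeometric tables
  (universe 3000, terms 400–700, selections of 300): with small tables an
  exact test is conservative enough that its rejection rate under the null
  falls visibly below α, which is a property of exact tests, not a defect.
* Simulation sizes in tests (100–1000 replicates, 120–200-probe arrays)
  were chosen so the whole suite completes in a few minutes while keeping
  Monte-Carlo error well inside the asserted tolerances; the acceptance
  script uses 40 recovery replicates and 200 plates for the same reason.
* Determinism: every generator takes an explicit integer seed
  (numpy `default_rng`; no global state); the pipeline derives stage seeds
  from the run seed via `SeedSequence.spawn`, and identical configs produce
  byte-identical output files.
* The orchestrator writes every stage's output as TSV and quotes those
  tables in its summary rather than recomputing, so the summary cannot
  drift from the artifacts.

## Known limitations

* With one pooled array per group, fold-change calls have no error model;
  the recovery guarantees hold for planted |log2 FC| ≥ log2 3 under the
  stated noise, not near the 1.5 threshold.
* The enrichment universe defaults to the supplied term map's gene pool;
  with a biased universe (e.g. only predicted targets) the test answers a
  different question — the argument is explicit for that reason.
* Printed counts in the motivating literature for this design are not
  always internally consistent; the package reproduces arithmetic from
  stated inputs and does not attempt reconciliation.
* χ² on sparse 2×2 tables (expected counts < 5) is reported but should not
  be preferred over the exact test; no automatic switching is done.
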