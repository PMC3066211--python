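# Methods

## The assay and its statistical model

kinscreen analyses arrayed dual-channel RNAi screens of the kind used to
dissect the AhR/CYP1A1 pathway in MCF-7 cells: a library of r = 3 siRNAs per
gene, one siRNA per well, distributed over 96-well plates, read out in two
channels per well after TCDD induction —

* **EROD** (ethoxyresorufin-*O*-deethylase): CYP1A1 enzyme activity, taken
  as the OLS slope of resorufin fluorescence over a 15-minute kinetic read
  (fluorescence units / min).
* **MB** (methylene blue): cell-density absorbance, read after the EROD
  assay.

Every plate carries four negative-control wells (non-targeting siRNA or
transfection reagent only; A12, B12, G12, H12) and two positive-control
wells (AhR siRNA, which abolishes the EROD readout without changing cell
density; G1, H1). The screened design is 3 replicate experiments × 30
plates × 96 wells for 712 genes.

Readouts are treated as scale-type: every systematic effect (plate batch,
edge position, knock-down phenotype, measurement noise) acts
multiplicatively. This is the assumption behind both the per-plate
normalization and the lognormal noise in the simulator.

## Scoring path

1. **Plate normalization.** Per plate and channel, each well is divided by
   the median of the plate's sample wells (`plate_median`). The alternative
   `percent_of_neg_controls` (each well as a percentage of the
   negative-control mean, controls at 100%) is kept for control QC exports,
   where it is the natural scale for control scatter plots.
2. **Ratio.** The per-well EROD/MB ratio cancels cell-number effects: a
   siRNA that reduces both channels proportionally (a pure viability
   phenotype) leaves the ratio at baseline. Wells whose normalized MB falls
   below `mb_floor` (default 0.1, i.e. <10 % of plate-typical density) carry
   no interpretable activity reading and are excluded with reason
   `low_viability_signal` rather than producing explosive ratios.
3. **Per-plate ratio re-centering.** Channel-wise medians leave a residual
   per-plate factor (median_MB / median_EROD) in the ratio. The ratio is
   therefore divided by the plate median of included sample-well ratios
   before scores are pooled across plates. This step is what makes the
   score *exactly* invariant to rescaling a whole plate (both channels ×γ)
   and to rescaling both channels of any single well — without it those
   invariances hold only until a rescaled well crosses a plate median.
4. **Score.** log2 of the re-centered ratio by default
   (`score_on_log_ratio`), so reductions and increases are symmetric; raw
   ratio scoring is available.
5. **Robust z.** Per replicate, over all non-excluded sample wells pooled
   across the replicate's plates: z = (median − x) / (1.4826 · MAD).
   Reduction-positive sign: siRNAs that *reduce* pathway activity score
   positive, matching the convention in which reported hits carry positive
   mean z. Per-replicate pooling (rather than per-plate) keeps plate
   normalization and scoring unconfounded; by construction each replicate's
   sample-well z has median 0 and scaled MAD 1.
6. **Summarization.** Per siRNA, the arithmetic mean of its per-replicate
   z-scores, with the number of contributing replicates recorded. Missing
   wells are excluded, never imputed.

The MB channel alone is scored through the same machinery (log2 normalized
MB → per-replicate robust z → replicate mean), yielding density z-scores
used by the viability filter and the single-channel density hit analysis.

### Degenerate inputs

The `robust_z` primitive raises `DegenerateDispersionError` when MAD = 0,
as its contract requires. At pipeline level a zero MAD (possible whenever
fewer than half the wells carry any effect and noise is absent) falls back
to the standard deviation; only a perfectly constant score vector — no
effects and no noise at all — still raises. A perfectly flat MB channel
leaves density z undefined (NaN) instead of aborting the EROD analysis;
NaN density z is never viability-flagged (no evidence of a confound).
Ties in ranking, including at the k-th rank, break lexicographically by
siRNA identifier, keeping runs bit-reproducible instead of inflating k.

## Hit calling

siRNAs are ranked by summarized EROD z (descending for
`direction="reduction"`); a gene is a **hit** when at least m = 2 of its
r = 3 siRNAs fall in the top k = 150, the standard guard against
single-siRNA off-target phenotypes. Consequently the number of hit genes
can never exceed floor(k/m) = 75, and the m = 3 hit set is always a subset
of the m = 2 set.

The viability filter removes siRNAs with |z_MB| ≥ c (default c = 2.0
robust-z units) from candidacy *before* the top-k selection, making
"without affecting cell density" explicit; c = ∞ reproduces pure
ratio-only behaviour, and the alternative order (rank first, then discard)
is configurable. The threshold is a design choice of this package: the
original workflow relied on the ratio plus visual exclusion and never
stated a numeric cutoff. `direction="increase"` supports scanning for
negative regulators (siRNAs that raise the pathway readout).

The hit rate is reported as round(100 · hits / genes) percent. For the
published screen arithmetic, 22 hits among 712 kinases gives 3 %.

## Enrichment

Term overrepresentation of the hit list uses the hypergeometric upper tail
P(X ≥ k) — identical to a right-tailed Fisher exact test on the one-sided
2×2 table — computed in log space (logsumexp over log-pmf terms) for deep
tails, with Benjamini–Hochberg adjustment across all tested terms and the
**coverage** statistic floor(100·k/K) (flooring, not rounding: 2/7 → 28 %,
4/140 → 2 %). The background universe defaults to the union of annotated
genes and should be supplied explicitly when known; published p-values from
such screens are generally not recomputable without the original universe,
which is why the packaged worked example checks counts and coverage, not
p-values. The packaged annotation (`go_terms_synthetic.gmt`) reproduces the
curated hit-per-term counts and term sizes with synthetic `PADnnn` filler
genes — the original annotation source is not publicly retrievable — and is
for exercising the machinery, not for biology. `min_term_size` defaults to
1 because singleton terms are legitimately reported (coverage 100 %).

## The simulator

`simulate_screen` generates complete screens with known truth:

    EROD = base_E · plate_factor · edge · gene_effect_E · noise
    MB   = base_M · plate_factor · edge · gene_effect_M · noise′

* Gene classes are assigned by exact counts (round(fraction · n_genes));
  identities are drawn from the seeded generator. Defaults:
  `fraction_erod_hits = 0.03` (21 pathway genes, the ~3 % hit-rate regime),
  `fraction_viability_genes = 0.05`, effects 0.3 (70 % reduction of the
  affected channel(s) — a strong phenotype).
* Each siRNA draws its knockdown efficacy **once** (default q = 0.8); an
  inefficient siRNA has no effect in any replicate. This models the
  dominant false-negative source of such screens (insufficient siRNA
  activity), and makes the ≥2-of-3 rule's sensitivity analytically
  predictable: P(≥2 of 3 efficient) = 3q²(1−q) + q³ (= 20/27 ≈ 0.741 at
  q = 2/3; at q = 1 with zero noise, recovery is exact).
* Plate factors and per-well noise are lognormal. `noise_sd = 0.065` was
  chosen analytically from the planted signal variance so that pairwise
  replicate correlations of per-siRNA scores on default screens fall near
  0.8, the regime reported for well-behaved triplicate kinome screens, and
  verified by simulation (~0.80–0.82). `plate_effect_sd = 0.15` represents
  typical between-plate batch variation; it is removed entirely by plate
  normalization.
* The 712 × 3 = 2136 siRNAs are spread evenly over the 30 plates (71–72
  per plate, sequential by default, optionally shuffled); trailing sample
  positions stay empty and are ignored by all statistics. Positive
  controls multiply EROD by `pos_control_effect = 0.05` only.
* An optional `edge_effect` multiplies border wells in both channels; it
  cancels in the ratio, so it perturbs single-channel (density) analysis
  only — useful for demonstrating why the two-channel design is robust to
  spatial artefacts that this package deliberately does not correct
  (no B-score / median polish).
* Kinetic mode emits 16-point fluorescence traces F(t) = F₀ + activity·t
  over 15 min instead of precomputed activities; `erod_slope` recovers the
  generating activity exactly.

Under the null (no planted effects) the selection rule still calls genes
by chance: E[hits] = n_genes · P(Hypergeom(N = 2136, K = 3, n = 150) ≥ 2)
≈ 10.0 of 712, which simulated null screens reproduce. The simulator does
not model siRNA seed-sequence off-targets, transfection gradients, or
compound pharmacology, so passing recovery tests demonstrate correctness
of the statistics under the stated noise model, not performance on any
particular real screen.

## Reproducibility and output conventions

All randomness lives in the simulator and is seed-controlled; identical
seeds give bit-identical screens, and identical inputs give byte-identical
result tables. Raw-data writers (`write_readouts` etc.) format floats at
`%.17g` and reads use round-trip float parsing, so data round trips are
bit-exact; derived result tables from `run_pipeline` are formatted at 6
significant digits for readability. Test and acceptance simulations use
the full screen geometry (712 genes, 3 × 30 plates), with 50 seeds for
stochastic recovery estimates and 20 for null/property sweeps — sizes at
which the Monte-Carlo standard error of the reported means is well below
the tolerances asserted.

## Known limitations

* The viability threshold c and `mb_floor` are pragmatic defaults, not
  fitted to data.
* Published per-gene mean z-scores from the original EROD screen cannot be
  recomputed here because the underlying per-siRNA activity z-scores were
  never deposited; only the rule's arithmetic and behaviour on simulated
  ground truth are verifiable.
* No spatial correction is applied to real data; the simulator can
  generate edge effects precisely to show their consequence.
* Enrichment assumes a flat annotation (GMT); there is no GO-graph
  propagation or OBO parsing.
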