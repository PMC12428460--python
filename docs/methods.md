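# Methods

## The model

A ceRNA feed-forward loop (FFL) is a triple (circRNA *c*, miRNA *m*,
gene *g*) in which (i) *m* is validated to repress *g*, (ii) *c* carries
AGO-CLIP-supported binding sites for *m*, and (iii) *g* is the host gene
of *c*.  Because back-spliced circRNAs escape the miRNA-mediated decay
of their linear host transcript, high circRNA expression titrates *m*
away and de-represses *g* — a self-reinforcing loop.  The pipeline finds
all such triples in which *g* belongs to a user-supplied gene signature
and both supporting interaction layers pass the candidate funnel.

The funnel mirrors the screening logic of signature-driven ceRNA
studies: miRNAs must hit at least `min_targets` (default 4) distinct
signature genes; circRNAs must be hosted by signature genes and sponge a
candidate miRNA; and a circRNA's total miRNA-binding-site count (MBS —
sites for the same *or* different candidate miRNAs all count) must reach
the cohort median.  The median is computed **once** over all candidate
circRNAs and frozen before filtering; ties at the median are retained.
This one-pass semantics makes the filter idempotent with respect to the
stored threshold.

## Statistics

All group and correlation analyses are nonparametric, reflecting the
skewed, small-n expression data this pipeline targets (the cohort
workflow it implements screens normality first and then commits to
rank-based tests throughout).  The kernel lives in `cernaloop.stats`;
every stage calls through it.

* **Mann–Whitney** — U from average ranks.  Exact p by enumerating all
  C(n₁+n₂, n₁) rank subsets when n₁+n₂ ≤ 12 without ties; otherwise
  normal approximation with tie correction and a 0.5 continuity
  correction (off by a flag for cross-checks against library
  implementations).  The two-sided exact p is 2·min(P(U ≤ u), P(U ≥ u)),
  capped at 1 — equal to tail-counting since the tie-free null
  distribution of U is symmetric.  Enumeration shows the approximation
  stays within 0.05 of the exact value once both groups have ≥ 3
  observations; for min group sizes 1–2 the normal approximation itself
  deviates by up to ≈ 0.13, which is why the exact path exists.
* **Kruskal–Wallis** — tie-corrected H, χ² reference with k−1 df; an
  all-equal input returns H = 0, p = 1 rather than 0/0.
* **Dunn post hoc** — pairwise z on pooled mean ranks with the
  tie-corrected variance; two-sided p adjusted across all pairs,
  Bonferroni by default (the family-wise convention common in
  prism-style workflows); Benjamini–Hochberg by flag.  The source
  analyses do not name their adjustment, so it is configurable and
  logged.
* **Fisher exact** — two-sided by the minimum-likelihood rule (sum of
  hypergeometric probabilities ≤ that of the observed table, margins
  fixed), with a 1+1e−9 relative tolerance on the pmf comparison to
  absorb floating-point ties; odds ratio reported, ∞/0 allowed; a zero
  margin is a degenerate-table error.
* **Spearman** — Pearson on average ranks (tie-aware).  Exact p for
  n ≤ 8 without ties as the fraction of all n! pairings with
  |ρ| ≥ observed; otherwise the t approximation with n−2 df.
* **Fold-change between medians** — FC = 2^(median(x) − median(y)) on
  log2-scale input, i.e. the linear-scale ratio of group medians.  The
  linear (back-transformed) reading is used because the expression
  matrices consumed here are log2 of variance-stabilized data.
* **Multiplicity** — step-up Benjamini–Hochberg with enforced
  monotonicity; adjusted ≥ raw by construction.

Reported p-values are floored at 1e−300 and a floored value prints as
"< 1e-300" in reports.

## Synthetic data: what it emulates, and what it does not

`cernaloop.synthetic` generates every pipeline input with planted ground
truth.  Key defaults (all overridable in `SimConfig`):

| parameter | default | meaning |
|---|---|---|
| `n_signature_genes` | 34 | signature size |
| `n_mirnas` | 32 | miRNA pool (planted + decoys) |
| `min_targets` | 4 | funnel threshold |
| `min_sites` + Poisson(`sites_lambda`) | 3 + Pois(3) | sites per planted sponge edge |
| `n_samples` | 79/10 (grade 1 NR/R), 12/7 (grade 2 NR/R) | cohort cells |
| `expr_noise_sd` | 0.25 | within-group sd, log2 scale |
| planted shifts | log2 2.3 (grade 2), +log2 2.95 (recurrent grade 2) | on the focal gene |
| subtype prevalences (grade 2) | (0.333, 0.417, 0.25) NR; (0, 0.143, 0.857) R | A/B/C |
| planted correlations | −0.47 (NF2), +0.42 (proliferation index) in grade 2 | Spearman targets |
| `n_tissues` / ΔCt correlations | 19; 0.87, 0.58, 0.68 | qPCR panel |
| `ct_noise_sd` | 0.25 cycles | technical noise |

Decoy design: every decoy fails **exactly one** funnel rule — decoy
miRNAs carry `min_targets − 1` signature targets; off-signature decoy
circRNAs sponge a candidate miRNA but are hosted outside the signature;
and each planted circRNA is paired with a same-host decoy carrying a
single binding site.  Pairing low-MBS decoys one-to-one with planted
circRNAs makes the cohort median (1 + min planted MBS)/2, which always
separates the two groups, so planted-motif precision and recall are 1
by construction — the recovery test verifies the implementation, not
luck.

Correlations are planted through a Gaussian copula: a Spearman target
ρ_s maps to a latent Pearson r = 2 sin(πρ_s/6).  For the qPCR panel the
planted value refers to the **observed** ΔCt profiles, so the latent
correlation is pre-compensated for the attenuation factor
1 + (ct_noise_sd/dct_sd)² that independent technical noise would
otherwise introduce.  ΔCt values are generated directly (mean 10, sd 2
across tissues) and the separately drawn reference Ct (~N(18, 1)) is
added back, so tables hold raw cycles in (0, 45].

`expr_noise_sd = 0.25` is the within-group spread of a strongly
expressed gene after variance stabilization; at this spread the sampling
sd of a median difference at n = 7 vs 12 is ≈ 0.15 log2 units, which is
what makes a planted fold-change of 2.95 recoverable within [2.5, 3.5]
in the large majority of cohorts.

What the generator does **not** emulate: count-level sequencing noise
and the variance-stabilizing transform itself (expression is drawn
directly on the log2 scale); mean–variance coupling across genes;
realistic genome coordinates or sequence content; correlated clinical
covariates beyond the planted ones; batch structure.  Passing recovery
tests therefore demonstrate correctness of the estimators and filters
under the stated model, not robustness to the full messiness of real
cohorts.

## Numerical and design choices

* Gene symbols are upper-cased before comparison; miRNA ids are
  compared verbatim (arm suffixes are case-meaningful).
* Coordinates are 0-based half-open internally; 1-based inclusive input
  converts on read.  circRNA "size" prefers spliced length and falls
  back to genomic span — external sponge databases are ambiguous about
  which they report, so the choice is an explicit, logged flag
  (`size_mode`).
* The RBP screen is one-sided (candidate > background) because the
  hypothesis screened for is directional; the "similar size" background
  is the caller's responsibility, with a seed-controlled helper sampling
  within ±20% of the candidate mean size.
* Stratified comparisons always filter first, then test; missing
  annotation values are never imputed — samples drop per comparison with
  logged counts.
* A proliferation-index correlation with p ≥ 0.05 is reported with its
  raw values and no significance label.
* The Kruskal–Wallis example value frozen in the tests (H = 32/7 for
  [1,2],[3,4],[5,6]) was computed independently from the rank formula
  and cross-checked against scipy.

## Problem sizes used in the shipped checks

The acceptance script and test suite run the worked-example network
(15 edges), 100 generator seeds for motif recovery, 10,000 null
replicates for Mann–Whitney calibration, 200 cohorts at n = 7 vs 12 for
fold-change recovery, and 500 nineteen-tissue panels for correlation
recovery — sizes at which every Monte-Carlo margin above is stable from
run to run.

## Known limitations

* Exact Mann–Whitney enumeration is limited to n₁+n₂ ≤ 12 and tie-free
  data; tied small samples use the corrected normal approximation.
* The Dunn variance uses the large-sample normal reference; very small
  groups (< 5) give conservative pairwise p-values.
* Funnel results on real database extracts depend on the database
  version; headline counts from any particular release are treated as
  documentation examples, not regression targets.
* The CLI's `express` stage analyses one focal gene per run
  (`focus_gene`); genome-wide screens should call the library directly.
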