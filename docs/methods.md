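# Methods

## The discovery model

`varfunnel` implements a case-only rare-variant discovery design. No
matched controls are sequenced; instead each cohort variant is compared
against public reference panels of similar ancestry. The design therefore
rests on two ideas:

* a **prioritization funnel** that removes low-confidence calls,
  non-recurrent variants, population polymorphisms, and variants without
  predicted functional impact, in that order; and
* a **per-variant burden comparison** that treats each panel as a sample
  of 2N chromosomes from the background population and asks whether the
  cohort's alternate-allele count is compatible with the panel frequency.

Variants absent from every panel but recurrent in the cohort cannot be
tested this way; they are reported as *novel* by a deterministic rule
(≥ `min_carriers` carriers, zero frequency everywhere). Panel-present
variants are *differential* when their Fisher q-value is below α in every
panel where they appear.

## Funnel stages and their parameters

| stage | parameter | default | meaning |
|---|---|---|---|
| QC | `min_depth` | 30 reads | calls below this depth fail regardless of AF |
| QC | `het_low`, `het_high` | 0.4, 0.6 | open interval of read-level AF for a heterozygous call |
| QC | `hom_threshold` | 0.9 | AF strictly above this is homozygous |
| recurrence | `min_carriers` | 2 | minimum patients carrying the variant |
| population | `panel_af_cutoff` | 0.05 | frequency above which a panel calls the variant common |
| population | `panel_af_mode` | `both` | remove only if common in every panel (`any`: in at least one) |
| consensus | `min_deleterious_votes` | 2 | predictors (of 5) that must call the variant deleterious |

Boundary behaviour is strict as stated: AF exactly 0.4, 0.6 or 0.9 fails
QC, and AF in (0.6, 0.9] is neither window, hence a QC failure. A variant
common in only one panel is *kept* under `both` mode (the literal
conjunction) and counted in a report warning, because many pipelines
would drop it; the `any` switch reproduces that stricter behaviour.
Descriptions of this design sometimes state recurrence as "two or more"
carriers and sometimes as "more than two"; the default here is ≥ 2,
configurable via `min_carriers`.

The funnel stages after QC are order-independent (each is a per-variant
predicate on a distinct attribute); the implemented order is the one the
report's stage counts describe.

## Burden testing

Case alternate alleles are `n_het + 2·n_hom` out of `2·n_cases`
chromosomes. Panels publish frequencies, not counts, so panel alternate
alleles are `round(af · 2 · n_samples)` with half-up rounding; counts
must be integral for the exact test. Fisher's two-sided p uses the
probability-mass definition (sum over margin-fixed tables no more
probable than the observed one) — stated explicitly because the doubling
convention differs. The 1-df Pearson χ² without continuity correction is
computed alongside and reported, with a warning flag when any expected
cell is below 5; classification uses Fisher only, since the exact test is
valid at the small allele counts this design produces.

BH-FDR is applied per panel over all panel-present funnel survivors —
the most literal family for a per-database comparison; classification
then combines panels with a conservative AND (`panel_sig_mode="all"`,
switchable to `any`). α defaults to 0.05.

Degenerate tables (a zero margin) return p = 1 by convention rather than
erroring, so an all-reference panel row never produces a spurious signal.

## Enrichment

Gene-family over-representation is the hypergeometric upper tail
P(X ≥ k) with K the family size *within the universe*, n the candidate
gene count and N the universe size, computed via the survival function in
log space. The universe is the set of genes carrying ≥ 1 variant that
survived QC, recurrence and the population filter (the "exome-tested"
genes), intersected with the genes that have family annotation; the
deleteriousness stage is deliberately excluded from the universe so that
the background reflects what could have been a candidate. Families are
ranked by −log₁₀(q) (q clipped at 1e-300 before the log), ties broken by
overlap size then family id. Genes may belong to several families; each
membership counts once.

## Clinical subgroup analysis

Continuous features (Cobb angle, tilted-vertebrae count) are compared
between carriers and non-carriers with the Wilcoxon rank-sum test: exact
enumeration when the combined sample is ≤ 12 and tie-free, otherwise the
normal approximation with tie-corrected variance and continuity
correction. Binary features (direction, apex class, shape, sex) use
Fisher's exact test on the 2×2 carrier-by-level table — a rank-sum on 0/1
coding is an equivalent proportion test, and a `binary_feature_test`
switch provides it. BH runs within each feature; the Venn intersection
defaults to the four radiographic features (apex location, Cobb angle,
curve direction, tilted count), with sex and shape screened but excluded
from the Venn. Lenke type is recorded and summarized but never analyzed
downstream. Mean-splits send values exactly at the mean to the "below"
group; this tie rule is configurable by supplying custom levels.

Feature–feature correlation picks its test by type: Fisher (2×2) or χ²
for categorical pairs, Wilcoxon/Kruskal–Wallis for categorical vs
continuous, Spearman for continuous pairs. The statistic behind the
published correlation heatmaps is not specified anywhere; this per-type
scheme is this package's documented choice.

## The synthetic cohort generator

The generator emulates the study conditions: 195 cases; reference panels
CHS (105 diploid samples) and EAS (4,327); clinical margins fixed at the
cohort's published descriptives (156 F / 39 M, 131 C / 64 S, 52 L /
143 R, apex 106 / 89; age ~ N(14.93, 3.04), Cobb ~ N(41.88, 18.35)
truncated above 10°, tilted count ~ round N(13.00, 3.84) clipped ≥ 2,
Lenke uniform on 1–6). Category counts are made exact by
largest-remainder apportionment, then shuffled across patients.

Null variants draw a latent population frequency from a point mass at
zero (probability 0.25) plus a Beta(0.5, 8) component scaled to
(0, 0.5] — a rough rare-skewed exome spectrum; no distributional
description of the real cohort's spectrum exists, so these are the
package's own documented choices, not calibrated values. Case carrier
counts are Binomial(n, 1 − (1 − af)²) and panel frequencies are binomial
resamples of the latent frequency, so case and panel distributions agree
under the null. Carriers are heterozygous with alt fraction uniform in
(0.42, 0.58) — inside the QC window even after read-count rounding — and
depth Poisson(100) clipped to ≥ 1; a `corruption_rate` (default 0.05)
emits low-depth or off-window calls among *null* variants only, so QC has
failing inputs while planted truth survives deterministically.

Planted novel variants get 5–10 carriers, zero panel frequency and ≥ 2
deleterious votes; planted differential variants get the same carrier
excess and a latent frequency of 0.001. A panel emits a variant only when
`af · 2n` rounds to at least one allele, mirroring real frequency tables
whose resolution is 1/(2n): a 0.001 variant therefore appears in EAS
(9/8654 alleles) but is genuinely absent from CHS, whose resolution is
1/210. All planted genes belong to one designated family; null genes
scatter uniformly over 40 background families.

What the generator does **not** model: linkage disequilibrium between
variants, population structure or relatedness within the cohort,
alignment or capture artifacts, gene length variation, and any
genotype–phenotype coupling (clinical features are independent of
genotypes unless a test plants one). Passing recovery tests therefore
demonstrates that the pipeline's logic and statistics behave as specified
under the stated design — not that the thresholds are optimal for real
exome data.

## Operating characteristics measured

`varfunnel.evaluation` replicates the design at configurable scale; the
validation suite and `scripts/acceptance.py` use 150–200 replicates of
300–400-variant cohorts (sizes chosen to estimate pooled rates from
≥ 1,000 planted events while keeping a replicate under a second). Under
these conditions planted novel recovery is exact by construction,
differential sensitivity exceeds 0.9, the planted family ranks first in
over 95% of replicates, the empirical FDR among differential calls stays
below α, and the Fisher p-value is super-uniform under the allele-level
null (it is conservative, as expected for an exact test at small counts).

## Known limitations

* The panel comparison ignores panel genotype uncertainty and treats the
  published frequency as exact up to allele-count rounding.
* The novel-variant rule is purely presence/absence; a variant at
  frequency just below one panel allele is indistinguishable from a truly
  absent one.
* Per-variant tests ignore gene-level aggregation (no SKAT/collapsing
  burden tests) and any covariate adjustment or kinship correction.
* The headline candidate counts of a real 195-patient exome cohort cannot
  be reproduced from synthetic data; the funnel's *structure* (stage
  monotonicity, hand-traceable counts) is what the tests pin down.
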