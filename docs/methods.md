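# Methods

## Problem setting

Bulk whole-exome sequencing of an atherosclerotic plaque cut into
longitudinal segments gives, per segment, a mixture signal over all cells
in that piece of tissue. A somatic mutation confined to one expanded
clone appears at a VAF proportional to the clone's share of the sample;
reading VAFs across neighbouring segments therefore traces each clone's
physical footprint along the plaque axis. The package implements that
inference chain and, because the motivating patient-level data cannot be
redistributed, a calibrated simulator that plants a known architecture
and lets every stage be scored against truth.

## Somatic validation model

A candidate variant is validated for a patient when it passes, in the
same tissue sample, the full per-round filter in each of two sequencing
rounds prepared independently from raw DNA:

| threshold | default | rationale |
|---|---|---|
| min alt reads | 5 | below ~5 reads at 700× a call is indistinguishable from noise |
| min VAF | 1% | detection floor; error-driven VAF expectation is ~0.1% |
| min mean base quality | 25 (Phred) | removes low-quality miscall pileups |
| max buffy VAF | 0.01% | "no or very low" blood signal; at 700× this effectively demands zero alt reads in the matched buffy coat |
| rounds required | 2 | independent library/sequencing replication |
| germline window | [0.40, 0.60] | operationalises "approximately 50% in all samples" |

Two readings of the two-round rule exist (both rounds pass all
thresholds, versus merely showing the variant in round 2); the stricter
one is implemented and is what the sensitivity figures below refer to.
The base-quality threshold is applied to the per-variant *mean* base
quality supplied in the input (the package never recomputes it from
reads); a record lacking it fails the check rather than passing silently.
Germline removal pools rounds per sample and requires the pooled VAF to
sit in the window in *every* covered sample, blood included. Variants
validated in more than one patient are excluded outright, as
platform-specific artifacts are the parsimonious explanation for exact
cross-patient recurrence at exome scale.

After validation, a mutation is quantified in every sample of its
patient; per-sample *presence* reuses the discovery thresholds (pooled
alt ≥ 5 and pooled VAF ≥ 1%), below which the clonal cell frequency is
recorded as 0 for mapping purposes. This reuse is a convention — the
choice was open — and keeps discovery and re-quantification consistent.

## Clonal cell frequency

CCF = 2·VAF under diploidy and heterozygosity; male chrX (and chrY)
variants are haploid, so CCF = VAF there, and a sex-chromosome variant
with unknown patient sex is an error rather than a guessed multiplier.
Values are capped at 1.0 after doubling (the uncapped value is kept in a
diagnostic column; the data model is silent on VAF > 50% and no
copy-number correction is attempted). Pooling across rounds is the
read-weighted mean (Σalt/Σdepth), which is permutation-invariant and
bounded by the per-round VAFs. Uncertainty on a pooled VAF uses the
exact Clopper–Pearson binomial interval, scaled by the same multiplier
onto the CCF axis; these intervals are deliberately conservative
(coverage ≥ 95%). Sample cell counts are DNA yield / 6.6 pg, the average
DNA mass of a diploid cell; burden-versus-cell-count association uses
Spearman rank correlation with tie-averaged ranks.

## Spatial mapping and clone grouping

Segments are disjoint half-open intervals [start, end) in mm along the
plaque axis (frozen sections alternate with unfrozen gaps, hence the
4–10 mm spacing between sequenced pieces). For a mutation positive in an
outermost segment pair, the clone must at least bridge the nearest edges
(lower bound) and can at most span the farthest edges (upper bound);
both bounds are always reported, the nearest-edge bound being the
headline "extent of at least X mm" number. Positions are 1-based (VCF
convention) throughout; only the mm geometry is half-open.

Grouping: two mutations are linkable iff (i) they are detected in
exactly the same samples and (ii) in every shared sample their
frequencies differ by at most `rel_tol` relative to the larger (default
0.5). Groups are connected components under this relation —
deterministic, order-invariant, no cluster count to choose; the
representative profile is the member-wise median. The tolerance
operationalises "similar magnitude and intersample differences"; 0.5 is
permissive enough to absorb binomial sampling scatter at 700× for
frequencies ≥ 4% while separating clones whose fractions differ by more
than twofold. A `gap_tolerant` mode allows one interior dropout column
(clone present but below detection mid-plaque); it is off by default
because it trades specificity for recall. Grouping output is a
hypothesis about co-travel, not ground truth, and is labelled as such.

A sample whose summed CCFs exceed 100% proves that clones there carry
more than one mutation each; the flag is computed per matrix column.

## CHIP screening and infiltration

Blood (buffy-coat) calls are screened tumor-only: gene on the CHIP
panel, ≥ 20 pooled reads, VAF ≥ 1%, gnomAD MAF < 1% — a variant absent
from gnomAD passes, since absence from ~140k genomes implies rarity —
and damaging evidence by ClinVar, a loss-of-function consequence,
CADD > 23, or ≥ 4 of 5 dbNSFP predictors (OR-combined: these are
alternative lines of evidence). The bundled 78-symbol panel in
`src/plaqueclone/data/chip_genes.txt` is a synthetic stand-in assembled
from canonical CHIP/myeloid-driver genes and is meant to be replaced by
the user's own list. Screened sites are force-called in every sample of
every patient (zero alt reads is a 0; a site missing from a sample's
data is no-coverage, kept as NaN and never conflated with 0), and
variants qualifying in more than one patient are excluded. Infiltration
into plaque tissue is quantified with the somatic presence thresholds
(alt ≥ 5, VAF ≥ 1%); the 1% floor matches the somatic limit of
detection, the natural choice where no separate CHIP floor is defined.

## The simulator: what it emulates and what it does not

Planted architecture per patient: 2–5 mm segments with 4–10 mm gaps,
somatic clones as contiguous segment intervals with one cell fraction
shared by all member mutations and all occupied segments (fractions
drawn from [0.01, 0.31] by default), autosomal germline heterozygotes at
expected VAF 50% everywhere, CHIP clones with a blood fraction and
independent per-segment infiltration fractions, and error-only sites.
Clone sets whose fractions sum above 1 in any segment are infeasible and
rejected. Read counts: per-site depth ~ Poisson(700) clipped at ≥ 1
(constant-depth mode available; only the target coverage is knowable, so
Poisson is the minimal overdispersion-free choice), alt reads ~
Binomial(depth, VAF + (1−VAF)·ε) with ε = 10⁻³ per base, miscalls adding
to the alt count. Rounds are drawn independently. Buffy-coat candidate
tables carry germline and CHIP support only — the matched caller screens
stochastic miscalls out of the normal, so raw error reads are not
injected there; modelling them as raw counts would make the <0.01% rule
reject ~75% of true somatic mutations at 700×, which is a property of
that naive noise model, not of the pipeline.

Not emulated: read-level artifacts (mapping, strand bias, UMI
structure), indels, copy-number variation, within-segment frequency
gradients, contamination, and any coupling between DNA yield and
mutation burden. Passing tests therefore demonstrate correctness of the
statistical pipeline under binomial sampling noise — not robustness to
alignment artifacts, which the upstream caller and manual curation
handle in practice.

## Numerical and design choices

- Multiallelic VCF records are split one row per alt allele (the input
  convention is unstated upstream; splitting is the lossless choice).
- Chromosome names are normalised to "chrX" style; "23"/"24" map to
  X/Y.
- Missing annotation values stay missing (NaN) and are never coerced to
  0; a missing gnomAD MAF passes the rarity filter by design.
- Mean base quality is carried as a single per-record float (MBQ FORMAT
  field) in simulator VCFs.
- Determinism: one integer seed drives geometry, architecture, sites,
  read draws and annotations through separate child generators; the
  on-disk dataset is byte-stable for a fixed config.
- Tie-breaks: grouping has none (connected components); concordance
  discovery-sample selection takes the lexicographically first passing
  sample.

## Problem sizes used in the validation suites

Specificity runs 10⁵ error-only sites at 700×; sensitivity and
frequency recovery use 100 simulated plaques of 4 segments (clones
4–30%, ≤ 2 mutations each); grouping accuracy uses 100 plaques with 2–3
clones of 3–4 mutations at 5–30% and is scored by the Rand index against
planted labels (≥ 0.9 required; measured ≈ 0.95–0.97); extent bounds are
checked exhaustively over all subsets of up to 6 segments; CHIP
detection uses 200 replicate carriers at the 4% blood-fraction floor and
50 carriers for interval-coverage checks. These sizes give stable
estimates (binomial standard errors well inside the asserted margins)
while keeping the default test run light.

## Known limitations

- The germline window [0.40, 0.60] can in principle swallow a true
  somatic clone at ~90% cell fraction present in every sample; such
  clones do not occur under the planted fraction ranges and would be
  biologically extraordinary in this tissue.
- Sensitivity degrades sharply below ~3% cell fraction (VAF 1.5%), as
  the 1%-VAF and 5-read floors bind; this is the intended limit of
  detection, not a defect.
- Clone grouping cannot separate two clones that genuinely share a
  presence pattern and similar fractions; the Rand-index figures above
  include that irreducible confusion.
- The pipeline consumes candidate calls; it does not re-call variants,
  recompute annotations, or correct for purity/ploidy.
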