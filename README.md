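# plaqueclone

Somatic mutations accumulate in the cells of atherosclerotic plaques, and
locally expanded clones can occupy a substantial fraction of the lesion.
`plaqueclone` implements the bulk whole-exome analysis that turns
multi-segment plaque sequencing into a clonal-architecture readout:
matched tissue-versus-blood somatic filtering, conversion of variant
allele frequencies into clonal cell frequencies, spatial mapping of
clones along the plaque axis, grouping of co-travelling mutations into
putative clones, and screening for clonal hematopoiesis (CHIP) with
quantification of hematopoietic-clone infiltration into the plaque.

It is written for vascular-genomics researchers analysing endarterectomy
material sequenced in longitudinal segments (2–5 mm frozen sections
spaced 4–10 mm apart, ~700× coverage, two independent sequencing rounds
per sample, patient-matched buffy-coat reference). Because such patient
data are access-restricted, the package ships a first-class synthetic
cohort simulator with planted ground truth, so every stage is testable
end to end and the pipeline's operating characteristics (sensitivity,
specificity, frequency-recovery error) are measured, not assumed.

## Model

For a heterozygous somatic variant in diploid cells, a clone occupying a
fraction *f* of a sample's cells is expected at variant allele frequency
VAF = *f*/2, so the clonal cell frequency is

    CCF = 2 · VAF        (autosomes; chrX in females)
    CCF = VAF            (chrX/chrY in males — single copy)

VAFs are pooled over sequencing rounds by total reads,
VAF = (Σ alt)/(Σ depth). A somatic mutation is *validated* when, in at
least one sample, it passes the per-round filter — ≥ 5 alt reads,
VAF ≥ 1%, mean base quality ≥ 25, matched buffy-coat VAF < 0.01% — in
each of two independent rounds; variants at ~50% VAF in every sample are
removed as germline and variants recurring across patients are excluded.
A clone detected in segments [a₁,a₂) and [b₁,b₂) must physically span at
least b₁−a₂ mm (nearest edges) and at most b₂−a₁ mm (farthest edges).
Mutations with identical presence patterns and per-sample frequencies
within a relative tolerance (default 0.5) are grouped as one putative
clone. CHIP carriers are found tumor-only in blood over a 78-gene panel
(≥ 20 reads, VAF ≥ 1%, gnomAD MAF < 1%, damaging by ClinVar /
loss-of-function / CADD > 23 / ≥ 4 of 5 dbNSFP predictors), then
force-called across all samples of all patients.

## Worked example

The numbered drivers under `analysis/` run the whole pipeline on the
built-in synthetic cohort (8 plaques × 4 segments, ~700×, two rounds,
clones at 1–31% cell fraction, CHIP clones in three patients) and write
tables to `results/`. Running them in order prints, among other things:

```
$ python analysis/02_filter_somatic.py
                  stage  n_candidates
       per_round_filter            52
      round_concordance            51
       germline_removal            51
cross_patient_exclusion            51
validated: 51 mutations (51/52 planted somatic recovered; 0 non-somatic leaked)

$ python analysis/03_clonal_frequencies.py
clonal cell frequencies across 51 mutations: median 0.145, range 0.035-0.336
mean absolute error vs planted fractions: 1.03 percentage points

$ python analysis/04_map_clones.py
24 putative clone groups (15 with >1 mutation, largest 5)
19 groups span multiple segments: minimum physical extents 4.0-27.2 mm
8 samples have summed clonal frequencies > 100% (multi-mutation clones required)

$ python analysis/05_chip_screening.py
CHIP carriers: 3/8 patients (3 mutations; 0 cross-patient exclusions)
  p4 NOTCH2: buffy VAF 0.102 -> clonal cell frequency 0.204
  p4 chr6:14567452: detected in 3/4 plaque samples, tissue frequencies 0.138-0.174
```

Reading the output: the filter cascade recovered 51 of 52 planted
somatic mutations (the miss is a clone at 3% cell fraction, below the
sensitivity floor) with zero false positives from 800 error-only sites
and 160 germline variants; estimated clonal cell frequencies land within
about one percentage point of the planted fractions; spatially extended
clone groups must bridge at least 4 mm of tissue; and the planted
NOTCH2-like hematopoietic clone is picked up in blood and found
infiltrating 3 of 4 plaque segments at 13.8–17.4% of cells, matching its
planted 13.4–18.4% range.

The same pipeline is available as a CLI for on-disk datasets
(per-sample-per-round VCFs with AD/DP, an annotation TSV and a
`samples.yaml` manifest):

```bash
plaqueclone simulate --out cohort/ --seed 7
plaqueclone run --dataset cohort/ --out results/
plaqueclone report --results results/
```

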