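"""Pool rounds, convert VAFs to clonal cell frequencies, summarise per
patient, and correlate mutation burden with estimated sample cell counts."""

import numpy as np

import plaqueclone as pc
from common import RESULTS, cohort

KEY = ["chrom", "pos", "ref", "alt"]

cfg, truth, obs, _ann = cohort()
res = pc.run_cascade(obs)
muts = pc.quantify_mutations(res.validated, obs, truth.samples)
muts.to_csv(RESULTS / "mutation_frequencies.tsv", sep="\t", index=False)

summary = pc.summarize_frequencies(muts, truth.samples)
summary["per_patient"].to_csv(RESULTS / "ccf_per_patient.tsv", sep="\t", index=False)

pc.write_report(
    dict(patients=sorted(truth.samples.patient.unique()), mutations=muts),
    RESULTS / "report",
)

det = muts[muts.present]
print(f"clonal cell frequencies across {det[KEY].drop_duplicates().shape[0]} "
      f"mutations: median {det.clonal_cell_frequency.median():.3f}, "
      f"range {det.clonal_cell_frequency.min():.3f}-{det.clonal_cell_frequency.max():.3f}")

ev = truth.expected_vaf.merge(
    truth.variants.loc[truth.variants.kind == "somatic", ["variant_id"] + KEY],
    on="variant_id",
).rename(columns={"sample": "truth_sample"})
j = muts.merge(ev, on=KEY)
occ = j[(j["sample"] == j.truth_sample) & (j.expected_vaf > 0)]
mae = np.abs(occ.clonal_cell_frequency - 2 * occ.expected_vaf).mean()
print(f"mean absolute error vs planted fractions: {mae * 100:.2f} percentage points")
print(f"burden vs estimated cells: Spearman rho = "
      f"{summary['burden_vs_cells_spearman']:.3f} "
      f"(p = {summary['burden_vs_cells_pvalue']:.3g})")
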