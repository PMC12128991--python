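"""Screen buffy coats for CHIP mutations, force-call the hits in every
sample of every patient, and quantify infiltration into plaque tissue."""

import plaqueclone as pc
from common import RESULTS, cohort

cfg, truth, obs, ann = cohort()
buffy = obs[obs["sample"] == "buffy"]
cand = pc.screen_buffy(buffy, ann, truth.samples, all_obs=obs)
mat, excluded = pc.force_call(cand, obs)
infil = pc.quantify_infiltration(mat, truth.samples)

cand.to_csv(RESULTS / "chip_carriers.tsv", sep="\t", index=False)
infil["per_sample"].to_csv(RESULTS / "chip_infiltration.tsv", sep="\t", index=False)

n_carriers = cand.patient.nunique()
print(f"CHIP carriers: {n_carriers}/{cfg.n_patients} patients "
      f"({len(cand)} mutations; {len(excluded)} cross-patient exclusions)")
for _, r in cand.iterrows():
    print(f"  {r.patient} {r.gene}: buffy VAF {r.vaf:.3f} -> "
          f"clonal cell frequency {r.clonal_cell_frequency:.3f}")
per = infil["per_sample"]
for (p, g), grp in per.groupby(["patient", per.chrom + ":" + per.pos.astype(str)]):
    pos_frac = grp.detected.mean()
    det = grp[grp.detected]
    rng = (f", tissue frequencies {det.clonal_cell_frequency.min():.3f}-"
           f"{det.clonal_cell_frequency.max():.3f}" if len(det) else "")
    print(f"  {p} {g}: detected in {int(grp.detected.sum())}/{len(grp)} "
          f"plaque samples{rng}")
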