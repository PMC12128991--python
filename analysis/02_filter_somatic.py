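"""Run the matched somatic filter cascade on the cohort and check the
validated set against planted truth."""

import plaqueclone as pc
from common import RESULTS, cohort

KEY = ["chrom", "pos", "ref", "alt"]

cfg, truth, obs, _ann = cohort()
res = pc.run_cascade(obs)

res.funnel.to_csv(RESULTS / "filter_funnel.tsv", sep="\t", index=False)
res.validated.to_csv(RESULTS / "validated_mutations.tsv", sep="\t", index=False)

ids = obs[KEY + ["variant_id"]].drop_duplicates()
got = res.validated.merge(ids, on=KEY).merge(
    truth.variants[["variant_id", "kind"]], on="variant_id"
)
n_somatic = (truth.variants.kind == "somatic").sum()

print(res.funnel.to_string(index=False))
print(f"validated: {len(res.validated)} mutations "
      f"({(got.kind == 'somatic').sum()}/{n_somatic} planted somatic recovered; "
      f"{(got.kind != 'somatic').sum()} non-somatic leaked)")
per_patient = res.validated.groupby("patient").size()
print("per patient:", dict(per_patient))
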