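"""Shared cohort definition for the numbered analysis drivers.

One deterministic synthetic cohort stands in for the GDPR-restricted
patient data: 8 plaques of 4 frozen segments each at ~700x over two
sequencing rounds, with 2-4 planted somatic clones per plaque (cell
fractions 1-31%, up to 3 mutations per clone), 20 germline variants and
100 error-only sites per patient, and CHIP clones in three patients —
one blood-only, one moderately infiltrating, and one patterned after a
large NOTCH2-style clone (21.6% of blood cells, infiltrating 3 of 4
segments).
"""

from pathlib import Path

import plaqueclone as pc

SEED = 20260929 % (2**31)

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


def cohort_config() -> pc.SimConfig:
    chip = {
        1: [pc.ChipSpec(0.08, gene="DNMT3A")],  # blood-only
        3: [pc.ChipSpec(0.216, (0.134, 0.184, 0.0, 0.15), gene="NOTCH2")],
        5: [pc.ChipSpec(0.12, (0.0, 0.06, 0.0, 0.0), gene="TET2")],
    }
    return pc.SimConfig(
        n_patients=8,
        segments_per_plaque=4,
        n_clones=(2, 4),
        clone_fraction=(0.01, 0.31),
        mutations_per_clone=(1, 3),
        n_germline=20,
        n_error_sites=100,
        chip=chip,
        seed=SEED,
    )


def cohort():
    cfg = cohort_config()
    truth = pc.simulate_truth(cfg)
    obs = pc.simulate_reads(truth, cfg)
    ann = pc.synthesize_annotations(truth)
    return cfg, truth, obs, ann
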