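import numpy as np
import pandas as pd
import pytest

import plaqueclone as pc


@pytest.fixture
def two_clone_truth():
    """One patient, two planted clones (20% spanning all four segments,
    8% in the middle two), ten germline variants, error-free reads."""
    cfg = pc.SimConfig(
        n_patients=1,
        seed=7,
        error_rate=0.0,
        n_error_sites=0,
        n_germline=10,
        clones=[[pc.CloneSpec(0.20, 0, 3, 2), pc.CloneSpec(0.08, 1, 2, 3)]],
    )
    truth = pc.simulate_truth(cfg)
    obs = pc.simulate_reads(truth, cfg)
    return cfg, truth, obs


@pytest.fixture
def meta_one_patient():
    return pd.DataFrame(
        dict(
            patient=["p1"] * 5,
            sample=["s1", "s2", "s3", "s4", "buffy"],
            sex=["male"] * 5,
            tissue_class=["plaque"] * 4 + ["buffy"],
            start_mm=[0.0, 6.0, 12.0, 20.0, np.nan],
            end_mm=[2.0, 8.0, 14.0, 24.0, np.nan],
            dna_yield_pg=[6.6e5] * 5,
        )
    )


def obs_row(
    patient="p1",
    sample="s1",
    rnd=1,
    chrom="chr1",
    pos=1000,
    ref="A",
    alt="T",
    alt_reads=8,
    total_reads=700,
    mbq=33.0,
):
    return dict(
        patient=patient,
        sample=sample,
        round=rnd,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        alt_reads=alt_reads,
        total_reads=total_reads,
        mean_base_quality=mbq,
    )


@pytest.fixture
def make_obs():
    """Factory turning obs_row kwargs dicts into an observation frame."""

    def _make(rows):
        return pd.DataFrame([obs_row(**r) for r in rows])

    return _make
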