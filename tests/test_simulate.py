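"""Simulator: planted truth geometry, read sampling, on-disk round-trip."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import plaqueclone as pc
from plaqueclone.simulate import synthesize_annotations


def test_no_clones_yields_only_germline_and_error_sites():
    cfg = pc.SimConfig(n_clones=0, n_germline=5, n_error_sites=3, seed=1)
    truth = pc.simulate_truth(cfg)
    assert truth.clones.empty
    assert truth.variants.kind.value_counts().to_dict() == {"germline": 5, "error": 3}


def test_single_clone_expected_vaf_is_half_fraction_everywhere():
    cfg = pc.SimConfig(
        clones=[[pc.CloneSpec(0.20, 0, 3)]],
        sexes=("female",),
        n_germline=0,
        n_error_sites=0,
        seed=2,
    )
    truth = pc.simulate_truth(cfg)
    ev = truth.expected_vaf
    tissue = ev[ev["sample"] != "buffy"]
    assert np.allclose(tissue.expected_vaf, 0.10)
    assert np.allclose(ev[ev["sample"] == "buffy"].expected_vaf, 0.0)


def test_overlapping_fractions_summing_over_one_rejected():
    cfg = pc.SimConfig(
        clones=[[pc.CloneSpec(0.6, 0, 1), pc.CloneSpec(0.5, 1, 2)]], seed=3
    )
    with pytest.raises(pc.InfeasibleArchitectureError):
        pc.simulate_truth(cfg)


def test_multimutation_clone_members_share_per_sample_fractions():
    cfg = pc.SimConfig(seed=11, n_clones=(2, 3), mutations_per_clone=(2, 3))
    truth = pc.simulate_truth(cfg)
    joined = truth.expected_vaf.merge(
        truth.variants[["variant_id", "clone_id", "kind"]], on="variant_id"
    )
    for (clone, _sample), grp in joined[joined.kind == "somatic"].groupby(
        ["clone_id", "sample"]
    ):
        assert grp.expected_vaf.nunique() == 1, clone


def test_clone_occupancy_is_contiguous_and_matches_expected_vaf():
    cfg = pc.SimConfig(seed=13)
    truth = pc.simulate_truth(cfg)
    ev = truth.expected_vaf.merge(
        truth.variants[["variant_id", "clone_id", "kind"]], on="variant_id"
    )
    for _, clone in truth.clones.iterrows():
        occupied = [f"s{i + 1}" for i in range(clone.first_segment, clone.last_segment + 1)]
        sub = ev[(ev.clone_id == clone.clone_id) & (ev["sample"] != "buffy")]
        nonzero = sorted(sub[sub.expected_vaf > 0]["sample"].unique())
        assert nonzero == sorted(occupied)


def test_segment_layout_widths_and_gaps_within_config_ranges():
    cfg = pc.SimConfig(seed=5, n_patients=3, segments_per_plaque=5)
    truth = pc.simulate_truth(cfg)
    for _, g in truth.samples[truth.samples.tissue_class == "plaque"].groupby("patient"):
        g = g.sort_values("start_mm")
        widths = g.end_mm - g.start_mm
        assert ((widths >= 2.0) & (widths <= 5.0)).all()
        gaps = g.start_mm.to_numpy()[1:] - g.end_mm.to_numpy()[:-1]
        assert ((gaps >= 4.0) & (gaps <= 10.0)).all()


def test_determinism_identical_config_identical_tables():
    cfg = pc.SimConfig(seed=42, n_patients=2)
    a = pc.simulate_reads(pc.simulate_truth(cfg), cfg)
    b = pc.simulate_reads(pc.simulate_truth(cfg), cfg)
    pd.testing.assert_frame_equal(a, b)


def test_zero_error_zero_vaf_gives_zero_alt_reads():
    cfg = pc.SimConfig(
        n_clones=0, n_germline=0, n_error_sites=200, error_rate=0.0, seed=6
    )
    truth = pc.simulate_truth(cfg)
    obs = pc.simulate_reads(truth, cfg)
    assert (obs.alt_reads == 0).all()


def test_binomial_mean_within_three_standard_errors():
    # 2000 independent draws at expected VAF 0.10, constant depth 700
    cfg = pc.SimConfig(
        segments_per_plaque=1,
        clones=[[pc.CloneSpec(0.20, 0, 0, 2000)]],
        sexes=("female",),
        n_germline=0,
        n_error_sites=0,
        error_rate=0.0,
        constant_depth=True,
        n_rounds=1,
        seed=8,
    )
    obs = pc.simulate_reads(pc.simulate_truth(cfg), cfg)
    tissue = obs[obs["sample"] == "s1"]
    assert len(tissue) == 2000
    vafs = tissue.alt_reads / tissue.total_reads
    se = np.sqrt(0.1 * 0.9 / 700) / np.sqrt(2000)
    assert abs(vafs.mean() - 0.10) < 3 * se


def test_germline_vaf_rarely_leaves_forty_to_sixty_window():
    # binomial tail: P(0.4 < X/700 < 0.6) at p=0.5 is ~1 - 1e-7
    cfg = pc.SimConfig(
        segments_per_plaque=1,
        n_clones=0,
        n_germline=500,
        n_error_sites=0,
        error_rate=0.0,
        constant_depth=True,
        seed=9,
    )
    obs = pc.simulate_reads(pc.simulate_truth(cfg), cfg)
    vafs = obs.alt_reads / obs.total_reads
    assert (vafs.between(0.4, 0.6)).mean() >= 0.99


def test_alt_read_distribution_calibrated_against_binomial():
    # chi-square goodness of fit of 2000 draws vs Binomial(700, 0.10), alpha=0.01
    cfg = pc.SimConfig(
        segments_per_plaque=1,
        clones=[[pc.CloneSpec(0.20, 0, 0, 2000)]],
        sexes=("female",),
        n_germline=0,
        n_error_sites=0,
        error_rate=0.0,
        constant_depth=True,
        n_rounds=1,
        seed=10,
    )
    obs = pc.simulate_reads(pc.simulate_truth(cfg), cfg)
    alt = obs[obs["sample"] == "s1"].alt_reads.to_numpy()
    edges = np.concatenate([[-0.5], np.arange(50.5, 91, 5), [700.5]])
    observed, _ = np.histogram(alt, bins=edges)
    cdf = stats.binom.cdf(edges, 700, 0.10)
    expected = np.diff(cdf) * len(alt)
    _, p = stats.chisquare(observed, expected * observed.sum() / expected.sum())
    assert p > 0.01


def test_dataset_roundtrip_and_byte_stability(tmp_path):
    cfg = pc.SimConfig(seed=21, n_germline=3, n_error_sites=5, n_clones=(1, 2))
    truth = pc.simulate_truth(cfg)
    obs = pc.simulate_reads(truth, cfg)
    d1 = tmp_path / "a"
    d2 = tmp_path / "b"
    pc.write_dataset(obs, truth, d1)
    pc.write_dataset(obs, truth, d2)

    # same seed twice -> identical bytes
    for f in sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file()):
        assert (d1 / f).read_bytes() == (d2 / f).read_bytes(), f

    read_obs, meta = pc.read_dataset(d1)
    want = (
        obs[pc.io.OBS_COLUMNS]
        .sort_values(pc.io.OBS_COLUMNS)
        .reset_index(drop=True)
    )
    got = read_obs.sort_values(pc.io.OBS_COLUMNS).reset_index(drop=True)
    pd.testing.assert_frame_equal(got, want, check_dtype=False)

    with pytest.raises(FileExistsError):
        pc.write_dataset(obs, truth, d1)
    pc.write_dataset(obs, truth, d1, overwrite=True)


def test_truth_file_bookkeeping(tmp_path):
    cfg = pc.SimConfig(
        seed=22,
        n_germline=4,
        n_error_sites=6,
        clones=[[pc.CloneSpec(0.1, 0, 1, 2), pc.CloneSpec(0.2, 2, 3, 3)]],
        chip={0: [pc.ChipSpec(0.1)]},
    )
    truth = pc.simulate_truth(cfg)
    obs = pc.simulate_reads(truth, cfg)
    pc.write_dataset(obs, truth, tmp_path / "d")
    rows = pd.read_csv(tmp_path / "d" / "truth_variants.tsv", sep="\t")
    assert len(rows) == (2 + 3) + 4 + 1 + 6


def test_annotations_cover_every_variant_and_chip_is_damaging():
    cfg = pc.SimConfig(seed=23, chip={0: [pc.ChipSpec(0.2, gene="TET2")]})
    truth = pc.simulate_truth(cfg)
    ann = synthesize_annotations(truth)
    merged = truth.variants.merge(ann, on=["chrom", "pos", "ref", "alt"])
    assert len(merged) == len(truth.variants)
    chip = merged[merged.kind == "chip"]
    assert ((chip.cadd_phred > 23) | (chip.consequence == "loss_of_function")).all()
    germ = merged[merged.kind == "germline"]
    assert (germ.gnomad_maf > 0.01).all()


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(depth=0.0),
        dict(error_rate=0.02),
        dict(clone_fraction=(0.5, 0.2)),
        dict(sexes=("male",), n_patients=2),
    ],
)
def test_invalid_configs_rejected(kwargs):
    with pytest.raises(ValueError):
        pc.SimConfig(**kwargs)
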