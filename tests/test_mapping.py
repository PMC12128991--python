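"""Spatial clone mapping: matrices, extent bounds, putative-clone grouping
and the multi-mutation flag."""

import itertools

import numpy as np
import pandas as pd
import pytest

import plaqueclone as pc
from plaqueclone.mapping import (
    build_matrix,
    clone_extent,
    flag_multimutation_samples,
    group_into_clones,
)

GEO = pd.DataFrame(
    dict(start_mm=[0.0, 6.0, 12.0, 20.0], end_mm=[2.0, 8.0, 14.0, 24.0]),
    index=["s1", "s2", "s3", "s4"],
)


def test_build_matrix_zero_fills_and_orders_columns(meta_one_patient):
    muts = pd.DataFrame(
        dict(
            patient=["p1"] * 4,
            sample=["s1", "s2", "s4", "s2"],
            chrom=["chr1"] * 4,
            pos=[1, 1, 1, 2],
            ref=["A"] * 4,
            alt=["T"] * 4,
            clonal_cell_frequency=[0.1, 0.2, 0.3, 0.4],
        )
    )
    mat = build_matrix(muts, meta_one_patient, "p1")
    assert list(mat.columns) == ["s1", "s2", "s3", "s4"]
    assert mat.loc["chr1:1:A>T"].tolist() == [0.1, 0.2, 0.0, 0.3]
    assert mat.loc["chr1:2:A>T"].tolist() == [0.0, 0.4, 0.0, 0.0]


def test_build_matrix_requires_geometry(meta_one_patient):
    meta = meta_one_patient.copy()
    meta.loc[meta["sample"] == "s2", "start_mm"] = np.nan
    muts = pd.DataFrame(
        dict(patient=["p1"], sample=["s1"], chrom=["chr1"], pos=[1], ref=["A"],
             alt=["T"], clonal_cell_frequency=[0.1])
    )
    with pytest.raises(ValueError, match="s2"):
        build_matrix(muts, meta, "p1")


@pytest.mark.parametrize(
    "presence,lower,upper",
    [
        ([1, 0, 0, 0], 0.0, 2.0),     # single segment [0,2)
        ([1, 1, 0, 0], 4.0, 8.0),     # [0,2) and [6,8): bridge >= 4 mm
        ([1, 1, 1, 0], 10.0, 14.0),
        ([0, 1, 0, 1], 12.0, 18.0),
    ],
)
def test_clone_extent_edge_arithmetic(presence, lower, upper):
    lo, hi = clone_extent(np.array(presence), GEO)
    assert (lo, hi) == (lower, upper)


def test_clone_extent_matches_exhaustive_pairwise_oracle():
    # all non-empty presence patterns over up to 6 segments
    rng = np.random.default_rng(0)
    for n in range(1, 7):
        starts, pos = [], 0.0
        widths = rng.uniform(2, 5, n)
        for i in range(n):
            if i > 0:
                pos += rng.uniform(4, 10)
            starts.append(pos)
            pos += widths[i]
        geo = pd.DataFrame(
            dict(start_mm=starts, end_mm=np.array(starts) + widths),
            index=[f"s{i}" for i in range(n)],
        )
        for bits in itertools.product([0, 1], repeat=n):
            if not any(bits):
                continue
            pos = [i for i, b in enumerate(bits) if b]
            lower_oracle = max(
                max((geo.start_mm.iloc[j] - geo.end_mm.iloc[i] for i in pos for j in pos)), 0.0
            )
            upper_oracle = max(
                geo.end_mm.iloc[j] - geo.start_mm.iloc[i] for i in pos for j in pos
            )
            lo, hi = clone_extent(np.array(bits), geo)
            assert lo == pytest.approx(lower_oracle)
            assert hi == pytest.approx(upper_oracle)


def test_grouping_joins_similar_profiles_and_splits_pattern_mismatch():
    mat = pd.DataFrame(
        [
            [0.05, 0.31, 0.10],   # the large media-intima spanning profile
            [0.05, 0.30, 0.10],   # co-travelling mutation, near-identical
            [0.05, 0.00, 0.10],   # same magnitudes but a missing sample
        ],
        index=["m1", "m2", "m3"],
        columns=["s3", "s4", "s5"],
    )
    groups = group_into_clones(mat)
    parts = sorted(sorted(g.members) for g in groups)
    assert parts == [["m1", "m2"], ["m3"]]
    g12 = [g for g in groups if "m1" in g.members][0]
    assert g12.profile == pytest.approx([0.05, 0.305, 0.10])


def test_grouping_relative_tolerance_boundary():
    mat = pd.DataFrame(
        [[0.10, 0.10], [0.05, 0.05], [0.04, 0.04]],
        index=["a", "b", "c"],
        columns=["s1", "s2"],
    )
    # |0.10-0.05|/0.10 = 0.5 links a-b; 0.04 links to b (rel 0.2) -> one
    # component by single linkage even though a-c alone would not link
    groups = group_into_clones(mat, rel_tol=0.5)
    assert len(groups) == 1
    groups = group_into_clones(mat, rel_tol=0.4)
    parts = sorted(sorted(g.members) for g in groups)
    assert parts == [["a"], ["b", "c"]]


def _brute_force_groups(mat, rel_tol=0.5):
    """Independent oracle: explicit pairwise rule + BFS components."""
    vals = mat.to_numpy()
    n = len(vals)

    def linkable(a, b):
        if not np.array_equal(a > 0, b > 0):
            return False
        if not (a > 0).any():
            return False
        sel = a > 0
        return all(
            abs(x - y) / max(x, y) <= rel_tol for x, y in zip(a[sel], b[sel])
        )

    seen, parts = set(), []
    for i in range(n):
        if i in seen:
            continue
        comp, queue = {i}, [i]
        while queue:
            u = queue.pop()
            for v in range(n):
                if v not in comp and linkable(vals[u], vals[v]):
                    comp.add(v)
                    queue.append(v)
        seen |= comp
        parts.append(sorted(mat.index[k] for k in comp))
    return sorted(parts)


@pytest.mark.parametrize("seed", range(8))
def test_grouping_equals_brute_force_on_random_matrices(seed):
    rng = np.random.default_rng(seed)
    vals = rng.uniform(0.01, 0.4, size=(20, 5)) * (rng.random((20, 5)) < 0.6)
    mat = pd.DataFrame(vals, index=[f"m{i}" for i in range(20)],
                       columns=[f"s{j}" for j in range(5)])
    mat = mat[(mat > 0).any(axis=1)]
    got = sorted(sorted(g.members) for g in group_into_clones(mat))
    assert got == _brute_force_groups(mat)


def test_grouping_invariant_to_row_order():
    rng = np.random.default_rng(5)
    vals = rng.uniform(0.01, 0.4, size=(12, 4)) * (rng.random((12, 4)) < 0.7)
    mat = pd.DataFrame(vals, index=[f"m{i}" for i in range(12)])
    mat = mat[(mat > 0).any(axis=1)]
    base = sorted(sorted(g.members) for g in group_into_clones(mat))
    shuffled = mat.sample(frac=1.0, random_state=1)
    assert sorted(sorted(g.members) for g in group_into_clones(shuffled)) == base


def test_gap_tolerant_mode_allows_one_interior_dropout():
    mat = pd.DataFrame(
        [[0.10, 0.00, 0.10], [0.10, 0.09, 0.10], [0.00, 0.09, 0.10]],
        index=["dropout", "full", "edge"],
        columns=["s1", "s2", "s3"],
    )
    strict = sorted(sorted(g.members) for g in group_into_clones(mat))
    assert strict == [["dropout"], ["edge"], ["full"]]
    tolerant = sorted(
        sorted(g.members) for g in group_into_clones(mat, gap_tolerant=True)
    )
    # interior zero may be bridged; a leading-edge mismatch may not
    assert ["dropout", "full"] in tolerant
    assert ["edge"] in tolerant


def test_multimutation_flag_on_column_sums():
    mat = pd.DataFrame([[0.6, 0.3], [0.6, 0.3]], columns=["s1", "s2"])
    flags = flag_multimutation_samples(mat)
    assert flags.tolist() == [True, False]


def test_planted_two_mutation_clone_flags_sample_and_groups_resolve(meta_one_patient):
    cfg = pc.SimConfig(
        n_patients=1,
        seed=17,
        error_rate=0.0,
        n_error_sites=0,
        n_germline=5,
        clones=[[pc.CloneSpec(0.60, 1, 2, 2)]],
    )
    truth = pc.simulate_truth(cfg)
    obs = pc.simulate_reads(truth, cfg)
    res = pc.run_cascade(obs)
    muts = pc.quantify_mutations(res.validated, obs, truth.samples)
    mat = build_matrix(muts, truth.samples, "p1")
    flags = flag_multimutation_samples(mat)
    assert flags[["s2", "s3"]].all()  # 2 x 0.6 = 1.2 > 1
    groups = group_into_clones(mat)
    assert len(groups) == 1 and len(groups[0].members) == 2
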