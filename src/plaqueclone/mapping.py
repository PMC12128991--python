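"""Spatial clone mapping across plaque segments.

Works on a mutation-by-sample matrix of clonal cell frequencies for one
patient, with columns ordered along the 1-D plaque axis.  Provides
physical clone-extent bounds from segment edge arithmetic, grouping of
mutations into putative clones by co-occurrence plus frequency-profile
similarity (connected components of a pairwise linkage rule), and a flag
for samples whose summed frequencies exceed 100% — direct evidence that
some clone carries more than one mutation.

Clone groups are hypotheses: bulk data cannot prove two mutations share
a clone, only that their spatial and frequency profiles are compatible
with it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "build_matrix",
    "clone_extent",
    "group_into_clones",
    "attach_extents",
    "flag_multimutation_samples",
    "CloneGroup",
]

KEY = ["chrom", "pos", "ref", "alt"]


@dataclass
class CloneGroup:
    """Mutations inferred to travel together in one clone."""

    members: tuple[str, ...]          # mutation keys "chrom:pos:ref>alt"
    profile: np.ndarray               # column-wise median frequency of members
    samples: tuple[str, ...]          # column labels of the matrix
    extent_lower_mm: float
    extent_upper_mm: float


def build_matrix(
    mutations: pd.DataFrame, sample_meta: pd.DataFrame, patient: str
) -> pd.DataFrame:
    """Mutation x sample matrix of clonal cell frequencies for one patient.

    Columns are the patient's plaque samples sorted by segment start;
    a plaque sample without geometry is an error.  Cells absent from the
    quantification are 0.
    """
    meta = sample_meta[
        (sample_meta.patient == patient) & (sample_meta.tissue_class == "plaque")
    ]
    if meta.start_mm.isna().any() or meta.end_mm.isna().any():
        bad = meta[meta.start_mm.isna() | meta.end_mm.isna()]["sample"].tolist()
        raise ValueError(f"plaque sample(s) without segment geometry: {bad}")
    order = meta.sort_values("start_mm")["sample"].tolist()

    sub = mutations[
        (mutations.patient == patient) & (mutations["sample"].isin(order))
    ].copy()
    if sub.empty:
        return pd.DataFrame(columns=order)
    sub["key"] = (
        sub.chrom + ":" + sub.pos.astype(str) + ":" + sub.ref + ">" + sub.alt
    )
    mat = sub.pivot_table(
        index="key", columns="sample", values="clonal_cell_frequency", fill_value=0.0
    )
    return mat.reindex(columns=order, fill_value=0.0)


def _geometry(sample_meta: pd.DataFrame, patient: str) -> pd.DataFrame:
    g = sample_meta[
        (sample_meta.patient == patient) & (sample_meta.tissue_class == "plaque")
    ].sort_values("start_mm")
    return g.set_index("sample")[["start_mm", "end_mm"]]


def clone_extent(
    presence: np.ndarray | pd.Series, geometry: pd.DataFrame
) -> tuple[float, float]:
    """Physical extent bounds of a clone from its positive segments.

    The lower bound is the gap a clone must at least bridge: the distance
    between the nearest edges of the outermost positive segments (0 for a
    single segment).  The upper bound is the distance between their
    farthest edges.  ``geometry`` rows must align with ``presence`` and be
    ordered along the axis.
    """
    pos = np.flatnonzero(np.asarray(presence) > 0)
    if pos.size == 0:
        raise ValueError("clone_extent requires at least one positive sample")
    starts = geometry.start_mm.to_numpy()
    ends = geometry.end_mm.to_numpy()
    first, last = pos[0], pos[-1]
    if first == last:
        lower = 0.0
    else:
        # disjoint ordered intervals make this positive; clamp regardless
        lower = max(float(starts[last] - ends[first]), 0.0)
    upper = float(ends[last] - starts[first])
    return lower, upper


def _linkable(
    a: np.ndarray, b: np.ndarray, rel_tol: float, gap_tolerant: bool
) -> bool:
    """Pairwise rule: identical nonzero pattern and, in every shared
    positive sample, relative frequency difference within ``rel_tol``."""
    pa, pb = a > 0, b > 0
    if not np.array_equal(pa, pb):
        if not gap_tolerant:
            return False
        # allow exactly one interior mismatch where one profile drops out
        diff = np.flatnonzero(pa != pb)
        if diff.size != 1:
            return False
        i = diff[0]
        union = np.flatnonzero(pa | pb)
        if i == union[0] or i == union[-1]:
            return False
    shared = pa & pb
    if not shared.any():
        return False
    fa, fb = a[shared], b[shared]
    rel = np.abs(fa - fb) / np.maximum(fa, fb)
    return bool(np.all(rel <= rel_tol))


def group_into_clones(
    matrix: pd.DataFrame, rel_tol: float = 0.5, gap_tolerant: bool = False
) -> list[CloneGroup]:
    """Group mutations into putative clones.

    Two mutations are linkable iff they occupy exactly the same samples
    and their clonal cell frequencies agree within a relative tolerance
    in every shared sample; groups are the connected components of this
    relation (single linkage), so the output is deterministic and
    invariant to row order.  The representative profile is the
    column-wise median over members.

    Extent bounds are attached when the matrix columns can be mapped to
    geometry later via :func:`clone_extent`; here they are computed in
    column-index units only if geometry is unknown, so callers wanting mm
    bounds should call :func:`clone_extent` with real geometry.
    """
    if not 0.0 < rel_tol <= 1.0:
        raise ValueError("rel_tol must lie in (0, 1]")
    keys = list(matrix.index)
    n = len(keys)
    vals = matrix.to_numpy(dtype=float)

    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _linkable(vals[i], vals[j], rel_tol, gap_tolerant):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)

    groups = []
    for root in sorted(comps):
        idx = comps[root]
        profile = np.median(vals[idx], axis=0)
        groups.append(
            CloneGroup(
                members=tuple(keys[i] for i in idx),
                profile=profile,
                samples=tuple(matrix.columns),
                extent_lower_mm=float("nan"),
                extent_upper_mm=float("nan"),
            )
        )
    return groups


def attach_extents(
    groups: list[CloneGroup], sample_meta: pd.DataFrame, patient: str
) -> list[CloneGroup]:
    """Fill in mm extent bounds for each group from the patient geometry."""
    geo = _geometry(sample_meta, patient)
    out = []
    for g in groups:
        lo, hi = clone_extent(g.profile, geo.loc[list(g.samples)])
        out.append(
            CloneGroup(g.members, g.profile, g.samples, lo, hi)
        )
    return out


def flag_multimutation_samples(matrix: pd.DataFrame) -> pd.Series:
    """Samples where summed clonal cell frequencies exceed 1 — at least
    one clone there must carry more than one of the mutations."""
    return matrix.sum(axis=0) > 1.0
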