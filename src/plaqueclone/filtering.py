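"""Matched tissue-vs-buffy somatic filtering cascade.

A mutation counts as validated for a patient when, in at least one tissue
sample, it independently passes the per-round filter (>= 5 alt reads,
VAF >= 1%, mean base quality >= 25, buffy-coat VAF < 0.01%) in each of
two sequencing rounds started from raw DNA.  Variants at ~50% VAF in
every covered sample of a patient are removed as germline, and any
substitution validated in more than one patient is excluded as a likely
artifact.  Every stage only ever shrinks the candidate set and is
idempotent on its own output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "FilterParams",
    "MatchedDesignError",
    "CascadeResult",
    "filter_matched_round",
    "require_round_concordance",
    "remove_germline",
    "exclude_cross_patient",
    "run_cascade",
]

KEY = ["chrom", "pos", "ref", "alt"]


class MatchedDesignError(ValueError):
    """Raised when the mandatory matched buffy-coat data are missing."""


@dataclass(frozen=True)
class FilterParams:
    min_alt_reads: int = 5
    min_vaf: float = 0.01
    max_buffy_vaf: float = 1e-4
    min_base_quality: float = 25.0
    require_rounds: int = 2
    germline_vaf_low: float = 0.40
    germline_vaf_high: float = 0.60

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_vaf <= 1.0:
            raise ValueError("min_vaf outside [0, 1]")
        if self.min_alt_reads < 1:
            raise ValueError("min_alt_reads must be >= 1")
        if not self.germline_vaf_low <= 0.5 <= self.germline_vaf_high:
            raise ValueError("germline window must contain 0.5")
        if self.require_rounds < 1:
            raise ValueError("require_rounds must be >= 1")


@dataclass
class CascadeResult:
    """Validated mutations plus a per-stage funnel of surviving counts."""

    validated: pd.DataFrame  # patient + variant key (+ discovery sample)
    funnel: pd.DataFrame     # stage, n_candidates
    rejected_cross_patient: pd.DataFrame = field(default_factory=pd.DataFrame)


def _vaf(df: pd.DataFrame) -> pd.Series:
    with np.errstate(invalid="ignore", divide="ignore"):
        return df.alt_reads / df.total_reads.where(df.total_reads > 0)


def filter_matched_round(
    tissue_obs: pd.DataFrame, buffy_obs: pd.DataFrame, params: FilterParams
) -> pd.DataFrame:
    """Per-round candidate filter against the patient-matched buffy coat.

    A variant absent from the buffy calls counts as buffy VAF 0; a patient
    with no buffy observations at all is a design error, not a pass.
    """
    missing = set(tissue_obs.patient.unique()) - set(buffy_obs.patient.unique())
    if missing:
        raise MatchedDesignError(
            f"no buffy-coat observations for patient(s): {sorted(missing)}"
        )
    if tissue_obs.empty:
        return tissue_obs.copy()

    b = buffy_obs.copy()
    b["buffy_vaf"] = _vaf(b)
    b = b.groupby(["patient", "round"] + KEY, as_index=False).buffy_vaf.max()

    t = tissue_obs.merge(b, on=["patient", "round"] + KEY, how="left")
    t["buffy_vaf"] = t.buffy_vaf.fillna(0.0)
    vaf = _vaf(t)
    keep = (
        (t.alt_reads >= params.min_alt_reads)
        & (vaf >= params.min_vaf)
        & (t.mean_base_quality >= params.min_base_quality)
        & (t.buffy_vaf < params.max_buffy_vaf)
    )
    return t[keep.fillna(False)].drop(columns="buffy_vaf").reset_index(drop=True)


def require_round_concordance(
    candidates: pd.DataFrame,
    params: FilterParams,
    available_rounds: Iterable[int],
) -> pd.DataFrame:
    """Keep mutations passing the per-round filter in >= ``require_rounds``
    rounds within the same sample; returns one row per (patient, key) with
    the discovery sample.

    ``available_rounds`` are the rounds actually sequenced; fewer than
    ``require_rounds`` is an explicit error rather than a silent pass.
    """
    rounds = sorted(set(int(r) for r in available_rounds))
    if len(rounds) < params.require_rounds:
        raise ValueError(
            f"dataset has {len(rounds)} sequencing round(s); "
            f"{params.require_rounds} required for concordance"
        )
    if candidates.empty:
        return pd.DataFrame(columns=["patient"] + KEY + ["discovery_sample"])
    per_sample = (
        candidates.groupby(["patient", "sample"] + KEY)["round"]
        .nunique()
        .reset_index(name="n_rounds")
    )
    ok = per_sample[per_sample.n_rounds >= params.require_rounds]
    out = (
        ok.sort_values(["patient", "sample"])
        .groupby(["patient"] + KEY, as_index=False)
        .first()
        .rename(columns={"sample": "discovery_sample"})
        .drop(columns="n_rounds")
    )
    return out.reset_index(drop=True)


def remove_germline(
    validated: pd.DataFrame, all_obs: pd.DataFrame, params: FilterParams
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop variants whose pooled VAF lies in the germline window in every
    covered sample (buffy included) of the patient.

    Returns (kept, removed).  Rounds are pooled per sample before the
    window test; samples without coverage of the site are ignored.
    """
    if validated.empty:
        return validated.copy(), validated.iloc[0:0].copy()
    pooled = (
        all_obs.groupby(["patient", "sample"] + KEY, as_index=False)[
            ["alt_reads", "total_reads"]
        ].sum()
    )
    pooled = pooled[pooled.total_reads > 0]
    pooled["vaf"] = pooled.alt_reads / pooled.total_reads
    pooled["in_window"] = pooled.vaf.between(
        params.germline_vaf_low, params.germline_vaf_high
    )
    status = pooled.groupby(["patient"] + KEY).in_window.all().rename("germline")
    v = validated.merge(status, on=["patient"] + KEY, how="left")
    v["germline"] = v.germline.fillna(False)
    kept = v[~v.germline].drop(columns="germline").reset_index(drop=True)
    removed = v[v.germline].drop(columns="germline").reset_index(drop=True)
    return kept, removed


def exclude_cross_patient(
    validated: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove substitutions validated in more than one patient.

    Returns (kept, removed); the removed frame lists each offending key
    with every patient it appeared in.
    """
    if validated.empty:
        return validated.copy(), validated.iloc[0:0].copy()
    n_pat = validated.groupby(KEY).patient.nunique().rename("n_patients")
    v = validated.merge(n_pat, on=KEY)
    kept = v[v.n_patients == 1].drop(columns="n_patients").reset_index(drop=True)
    removed = v[v.n_patients > 1].drop(columns="n_patients").reset_index(drop=True)
    return kept, removed


def run_cascade(
    obs: pd.DataFrame, params: FilterParams | None = None
) -> CascadeResult:
    """Full cascade: per-round matched filter -> two-round concordance ->
    germline removal -> cross-patient exclusion, with a stage funnel."""
    params = params or FilterParams()
    tissue = obs[obs["sample"] != "buffy"]
    buffy = obs[obs["sample"] == "buffy"]

    candidates = filter_matched_round(tissue, buffy, params)
    n0 = candidates[["patient"] + KEY].drop_duplicates().shape[0]

    validated = require_round_concordance(
        candidates, params, obs["round"].unique()
    )
    n1 = len(validated)

    validated, _germ = remove_germline(validated, obs, params)
    n2 = len(validated)

    validated, crossed = exclude_cross_patient(validated)
    n3 = len(validated)

    funnel = pd.DataFrame(
        dict(
            stage=[
                "per_round_filter", "round_concordance",
                "germline_removal", "cross_patient_exclusion",
            ],
            n_candidates=[n0, n1, n2, n3],
        )
    )
    return CascadeResult(validated=validated, funnel=funnel, rejected_cross_patient=crossed)
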