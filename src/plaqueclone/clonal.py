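"""Clonal cell-frequency estimation from pooled variant allele frequencies.

The model assumes diploid cells and heterozygous mutations, so a somatic
variant carried by a clone occupying a fraction f of a sample's cells is
expected at VAF f/2 on autosomes.  Hence the clonal cell frequency (CCF)
is 2 x VAF, except on the X chromosome in males (single copy: CCF = VAF,
and likewise chrY).  VAFs are pooled over the independent sequencing
rounds by summing reads, i.e. a depth-weighted mean:

    pooled VAF = (sum_r alt_r) / (sum_r depth_r)

CCF estimates are capped at 1; the uncapped value is kept as a
diagnostic.  Exact (Clopper-Pearson) binomial intervals on the pooled
VAF propagate to the CCF scale by the same multiplier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "pool_rounds",
    "vaf_to_ccf",
    "estimate_cell_count",
    "quantify_mutations",
    "summarize_frequencies",
    "binomial_interval",
    "PG_PER_CELL",
]

KEY = ["chrom", "pos", "ref", "alt"]

#: average DNA mass of one diploid cell, in picograms
PG_PER_CELL = 6.6


def pool_rounds(alt_reads, total_reads) -> float:
    """Read-weighted pooled VAF across sequencing rounds.

    Rounds with zero depth contribute nothing; if no round has coverage
    the pooled VAF is undefined and NaN is returned.
    """
    alt = np.asarray(alt_reads, dtype=float)
    tot = np.asarray(total_reads, dtype=float)
    if np.any(alt > tot):
        raise ValueError("alt_reads exceeds total_reads")
    denom = tot.sum()
    if denom <= 0:
        return float("nan")
    return float(alt.sum() / denom)


def vaf_to_ccf(
    vaf: float, chrom: str = "chr1", sex: str | None = "female", cap: bool = True
) -> float:
    """Convert a VAF to a clonal cell frequency.

    Autosomes and female chrX double the VAF (two copies, heterozygous
    mutation); male chrX and chrY are haploid, multiplier 1.  A sex
    chromosome with unknown sex is an error — there is no safe default.
    """
    if not 0.0 <= vaf <= 1.0:
        raise ValueError(f"vaf {vaf} outside [0, 1]")
    c = str(chrom)
    sexchrom = c in ("chrX", "chrY", "X", "Y")
    if sexchrom:
        if sex not in ("male", "female"):
            raise ValueError(f"sex must be known for {chrom} variants")
        if c in ("chrY", "Y") and sex == "female":
            raise ValueError("chrY variant in a female sample")
        mult = 1.0 if (sex == "male") else 2.0
    else:
        mult = 2.0
    ccf = mult * vaf
    return min(ccf, 1.0) if cap else ccf


def estimate_cell_count(dna_yield_pg: float, pg_per_cell: float = PG_PER_CELL):
    """Estimate the number of cells in a sample from its DNA yield,
    assuming an average diploid DNA content per cell.

    Returns (cells, rounded_count); a missing or non-positive yield is an
    error — the metric is then unavailable, never zero.
    """
    if dna_yield_pg is None or not np.isfinite(dna_yield_pg):
        raise ValueError("DNA yield unavailable")
    if dna_yield_pg <= 0:
        raise ValueError("DNA yield must be positive")
    cells = dna_yield_pg / pg_per_cell
    return cells, int(round(cells))


def binomial_interval(alt, total, conf: float = 0.95):
    """Exact Clopper-Pearson interval for a binomial proportion
    (vectorised); returns (low, high) arrays."""
    alt = np.atleast_1d(np.asarray(alt, dtype=float))
    total = np.atleast_1d(np.asarray(total, dtype=float))
    a = (1.0 - conf) / 2.0
    low = np.where(alt > 0, stats.beta.ppf(a, alt, total - alt + 1), 0.0)
    high = np.where(
        alt < total, stats.beta.ppf(1 - a, alt + 1, total - alt), 1.0
    )
    return low, high


@dataclass(frozen=True)
class PresenceParams:
    """Per-sample presence thresholds applied after patient-level
    validation (the discovery thresholds re-used for quantification)."""

    min_alt_reads: int = 5
    min_vaf: float = 0.01


def quantify_mutations(
    validated: pd.DataFrame,
    obs: pd.DataFrame,
    sample_meta: pd.DataFrame,
    presence: PresenceParams | None = None,
) -> pd.DataFrame:
    """Quantify every validated mutation in every sample of its patient.

    Rounds are pooled per (mutation, sample); the CCF is set to 0 where
    the pooled support falls below the presence thresholds, so downstream
    spatial mapping sees presence/absence plus magnitude in one table.
    Output columns include pooled counts, pooled VAF, capped CCF, the
    uncapped CCF diagnostic, and Clopper-Pearson bounds on the CCF.
    """
    presence = presence or PresenceParams()
    if validated.empty:
        return pd.DataFrame(
            columns=["patient", "sample"] + KEY + [
                "alt_reads", "total_reads", "vaf", "present",
                "clonal_cell_frequency", "ccf_uncapped", "ccf_low", "ccf_high",
            ]
        )
    sex = sample_meta.drop_duplicates("patient").set_index("patient").sex

    pooled = obs.merge(validated[["patient"] + KEY], on=["patient"] + KEY)
    pooled = pooled.groupby(["patient", "sample"] + KEY, as_index=False)[
        ["alt_reads", "total_reads"]
    ].sum()
    # complete the (mutation x sample) grid with zero-coverage rows absent
    pooled["vaf"] = pooled.alt_reads / pooled.total_reads.where(pooled.total_reads > 0)
    pooled["present"] = (pooled.alt_reads >= presence.min_alt_reads) & (
        pooled.vaf >= presence.min_vaf
    )

    mult = np.where(
        pooled.chrom.isin(["chrX", "chrY"])
        & (pooled.patient.map(sex) == "male"),
        1.0,
        2.0,
    )
    bad = pooled.chrom.eq("chrY") & (pooled.patient.map(sex) == "female")
    if bad.any():
        r = pooled[bad].iloc[0]
        raise ValueError(f"chrY variant {r.chrom}:{r.pos} in female patient {r.patient}")
    unknown = pooled.chrom.isin(["chrX", "chrY"]) & ~pooled.patient.map(sex).isin(
        ["male", "female"]
    )
    if unknown.any():
        raise ValueError("sex unknown for a patient with sex-chromosome variants")

    uncapped = mult * pooled.vaf.fillna(0.0)
    pooled["ccf_uncapped"] = uncapped.where(pooled.present, 0.0)
    pooled["clonal_cell_frequency"] = pooled.ccf_uncapped.clip(upper=1.0)
    low, high = binomial_interval(pooled.alt_reads, pooled.total_reads)
    pooled["ccf_low"] = np.clip(mult * low, 0.0, 1.0)
    pooled["ccf_high"] = np.clip(mult * high, 0.0, 1.0)
    return pooled


def summarize_frequencies(
    mutations: pd.DataFrame, sample_meta: pd.DataFrame
) -> dict:
    """Per-patient and per-sample clonal-frequency summaries plus the
    rank correlation between mutation burden and estimated cell count.

    Spearman's rho (tie-aware, via scipy) is computed across samples with
    a DNA yield, pairing each sample's number of detected mutations with
    its estimated cell count.
    """
    det = mutations[mutations.present] if len(mutations) else mutations

    def _stats(g: pd.Series) -> dict:
        return dict(
            n=len(g),
            median=float(g.median()) if len(g) else np.nan,
            iqr_low=float(g.quantile(0.25)) if len(g) else np.nan,
            iqr_high=float(g.quantile(0.75)) if len(g) else np.nan,
            min=float(g.min()) if len(g) else np.nan,
            max=float(g.max()) if len(g) else np.nan,
        )

    per_patient = pd.DataFrame(
        [
            dict(patient=p, **_stats(g.clonal_cell_frequency))
            for p, g in det.groupby("patient")
        ]
    )
    per_sample = pd.DataFrame(
        [
            dict(patient=p, sample=s, **_stats(g.clonal_cell_frequency))
            for (p, s), g in det.groupby(["patient", "sample"])
        ]
    )

    counts = (
        det.groupby(["patient", "sample"]).size().rename("n_mutations").reset_index()
        if len(det)
        else pd.DataFrame(columns=["patient", "sample", "n_mutations"])
    )
    sm = sample_meta.merge(counts, on=["patient", "sample"], how="left")
    sm = sm[sm.tissue_class == "plaque"].copy()
    sm["n_mutations"] = sm.n_mutations.fillna(0)
    sm = sm.dropna(subset=["dna_yield_pg"])
    sm["cells"] = sm.dna_yield_pg / PG_PER_CELL
    if len(sm) >= 3 and sm.n_mutations.nunique() > 1:
        rho, pval = stats.spearmanr(sm.n_mutations, sm.cells)
    else:
        rho, pval = np.nan, np.nan
    return dict(
        per_patient=per_patient,
        per_sample=per_sample,
        burden_vs_cells_spearman=float(rho) if rho == rho else np.nan,
        burden_vs_cells_pvalue=float(pval) if pval == pval else np.nan,
        sample_cells=sm,
    )
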