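"""CHIP screening from buffy-coat calls and plaque-infiltration analysis.

Clonal hematopoiesis of indeterminate potential (CHIP) carriers are
identified without a matched normal, through a tumor-only cascade over a
user-editable panel of CHIP driver genes: panel membership, >= 20 reads
of coverage, VAF >= 1%, gnomAD minor allele frequency < 1% (absence from
gnomAD passes — absence implies rarity), and damaging evidence from any
of ClinVar, a loss-of-function consequence, CADD > 23, or >= 4 of 5
dbNSFP predictors.  Identified sites are then force-called in every
sample of every patient; variants qualifying in more than one patient
are discarded as platform noise.  Infiltration of a blood clone into
plaque tissue is quantified per (mutation, tissue sample) with the same
presence thresholds as the somatic pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .clonal import binomial_interval, vaf_to_ccf
from .filtering import FilterParams, remove_germline

__all__ = [
    "ChipParams",
    "default_gene_list",
    "load_gene_list",
    "screen_buffy",
    "force_call",
    "quantify_infiltration",
]

KEY = ["chrom", "pos", "ref", "alt"]


def load_gene_list(path: str | Path) -> frozenset[str]:
    """One gene symbol per line; '#' comments and blank lines ignored."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"CHIP gene list not found: {p}")
    genes = []
    for line in p.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            genes.append(line)
    if not genes:
        raise ValueError(f"CHIP gene list {p} is empty")
    return frozenset(genes)


def default_gene_list() -> frozenset[str]:
    """The bundled 78-gene CHIP panel (synthetic stand-in assembled from
    canonical CHIP/myeloid driver genes; replace with your own file via
    :func:`load_gene_list` for real analyses)."""
    with resources.as_file(
        resources.files("plaqueclone.data").joinpath("chip_genes.txt")
    ) as p:
        return load_gene_list(p)


@dataclass(frozen=True)
class ChipParams:
    gene_list: frozenset[str] = field(default_factory=default_gene_list)
    min_depth: int = 20
    max_gnomad_maf: float = 0.01
    min_cadd: float = 23.0
    min_votes: int = 4
    min_vaf: float = 0.01

    def __post_init__(self) -> None:
        if not self.gene_list:
            raise ValueError("CHIP gene list must be non-empty")
        if not 0.0 <= self.max_gnomad_maf <= 1.0:
            raise ValueError("max_gnomad_maf outside [0, 1]")
        if self.min_depth < 1 or not 0 <= self.min_votes <= 5:
            raise ValueError("invalid depth or vote threshold")


def _pool_buffy(buffy_obs: pd.DataFrame) -> pd.DataFrame:
    pooled = buffy_obs.groupby(["patient"] + KEY, as_index=False)[
        ["alt_reads", "total_reads"]
    ].sum()
    pooled["vaf"] = pooled.alt_reads / pooled.total_reads.where(pooled.total_reads > 0)
    return pooled


def screen_buffy(
    buffy_obs: pd.DataFrame,
    annotations: pd.DataFrame,
    sample_meta: pd.DataFrame,
    params: ChipParams | None = None,
    all_obs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Tumor-only CHIP screen on pooled buffy-coat observations.

    Returns one row per candidate (patient, variant) with pooled counts,
    buffy VAF and clonal cell frequency.  When ``all_obs`` is given, the
    ~50%-VAF-in-all-samples germline rule is applied on top of the gnomAD
    frequency filter.
    """
    params = params or ChipParams()
    pooled = _pool_buffy(buffy_obs)
    ann = annotations.drop_duplicates(subset=KEY)
    cand = pooled.merge(ann, on=KEY, how="inner")

    damaging = (
        cand.clinvar_damaging.astype(bool)
        | (cand.consequence == "loss_of_function")
        | (cand.cadd_phred > params.min_cadd)
        | (cand.dbnsfp_damaging_votes >= params.min_votes)
    )
    rare = cand.gnomad_maf.isna() | (cand.gnomad_maf < params.max_gnomad_maf)
    keep = (
        cand.gene.isin(params.gene_list)
        & (cand.total_reads >= params.min_depth)
        & (cand.vaf >= params.min_vaf)
        & rare
        & damaging
    )
    cand = cand[keep.fillna(False)].reset_index(drop=True)

    if all_obs is not None and not cand.empty:
        fp = FilterParams()
        cand, _removed = remove_germline(cand, all_obs, fp)

    if cand.empty:
        return cand.assign(clonal_cell_frequency=pd.Series(dtype=float))

    sex = sample_meta.drop_duplicates("patient").set_index("patient").sex
    cand["clonal_cell_frequency"] = [
        vaf_to_ccf(v, c, sex.get(p)) for v, c, p in zip(cand.vaf, cand.chrom, cand.patient)
    ]
    return cand


def force_call(
    chip_mutations: pd.DataFrame, obs: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Force-call every screened CHIP site in every sample of every
    patient, then exclude variants that qualified in more than one
    patient.

    Returns (matrix, excluded).  The matrix holds one row per (site,
    patient, sample) with pooled counts; sites a sample has no data for
    appear with NaN counts — no-coverage, never conflated with zero.
    """
    if chip_mutations.empty:
        return (
            pd.DataFrame(columns=["carrier"] + KEY + ["patient", "sample", "alt_reads", "total_reads", "vaf"]),
            chip_mutations.copy(),
        )
    n_pat = chip_mutations.groupby(KEY).patient.nunique().rename("n_patients")
    merged = chip_mutations.merge(n_pat, on=KEY)
    kept = merged[merged.n_patients == 1].drop(columns="n_patients")
    excluded = merged[merged.n_patients > 1].drop(columns="n_patients")

    pooled = obs.groupby(["patient", "sample"] + KEY, as_index=False)[
        ["alt_reads", "total_reads"]
    ].sum()

    sites = kept[KEY + ["patient"]].rename(columns={"patient": "carrier"})
    grid = sites.merge(
        obs[["patient", "sample"]].drop_duplicates(), how="cross"
    )
    mat = grid.merge(pooled, on=["patient", "sample"] + KEY, how="left")
    mat["vaf"] = mat.alt_reads / mat.total_reads.where(mat.total_reads > 0)
    return mat.reset_index(drop=True), excluded.reset_index(drop=True)


def quantify_infiltration(
    forcecall: pd.DataFrame,
    sample_meta: pd.DataFrame,
    min_alt_reads: int = 5,
    min_vaf: float = 0.01,
) -> dict:
    """Quantify hematopoietic-clone infiltration into plaque tissue.

    Per (mutation, tissue sample of the carrier patient): pooled VAF,
    clonal cell frequency with exact binomial bounds, and a detected
    flag (>= ``min_alt_reads`` alt reads and VAF >= ``min_vaf``).  Per
    carrier patient: the fraction of plaque samples positive for each
    mutation.
    """
    sex = sample_meta.drop_duplicates("patient").set_index("patient").sex
    tissue_ids = set(
        zip(
            sample_meta[sample_meta.tissue_class == "plaque"].patient,
            sample_meta[sample_meta.tissue_class == "plaque"]["sample"],
        )
    )
    in_tissue = np.array(
        [(p, s) in tissue_ids for p, s in zip(forcecall.patient, forcecall["sample"])]
    )
    t = forcecall[(forcecall.patient == forcecall.carrier) & in_tissue].copy()
    covered = t.total_reads.notna() & (t.total_reads > 0)
    t["detected"] = covered & (t.alt_reads >= min_alt_reads) & (t.vaf >= min_vaf)
    ccf = [
        vaf_to_ccf(v, c, sex.get(p)) if covered_i and d else (0.0 if covered_i else np.nan)
        for v, c, p, d, covered_i in zip(
            t.vaf.fillna(0.0), t.chrom, t.patient, t.detected, covered
        )
    ]
    t["clonal_cell_frequency"] = ccf
    low = np.full(len(t), np.nan)
    high = np.full(len(t), np.nan)
    if covered.any():
        lo, hi = binomial_interval(
            t.alt_reads[covered].to_numpy(), t.total_reads[covered].to_numpy()
        )
        mult = np.where(
            t.chrom[covered].isin(["chrX", "chrY"])
            & (t.patient[covered].map(sex) == "male"),
            1.0, 2.0,
        )
        low[np.flatnonzero(covered)] = np.clip(mult * lo, 0, 1)
        high[np.flatnonzero(covered)] = np.clip(mult * hi, 0, 1)
    t["ccf_low"] = low
    t["ccf_high"] = high

    per_patient = (
        t.groupby(["patient"] + KEY)
        .agg(
            n_samples=("detected", "size"),
            n_positive=("detected", "sum"),
        )
        .reset_index()
    )
    per_patient["fraction_positive"] = per_patient.n_positive / per_patient.n_samples
    return dict(per_sample=t.reset_index(drop=True), per_patient=per_patient)
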