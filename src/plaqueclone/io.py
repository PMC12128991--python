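"""Readers and writers for variant observations, annotations and metadata.

VCF input goes through :mod:`pysam`; positions stay 1-based end-to-end and
multiallelic records are split into one observation row per alternate
allele.  Chromosome names are normalised to the ``chr``-prefixed
convention ("X"/"23" -> "chrX").  Parsing never silently drops a record:
structurally broken input raises with the offending record named.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam
import yaml

__all__ = [
    "normalize_chrom",
    "read_variants",
    "read_dataset",
    "read_annotations",
    "write_report",
    "OBS_COLUMNS",
]

OBS_COLUMNS = [
    "patient", "sample", "round", "chrom", "pos", "ref", "alt",
    "alt_reads", "total_reads", "mean_base_quality",
]

_ANN_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "consequence", "gnomad_maf",
    "cadd_phred", "dbnsfp_damaging_votes", "clinvar_damaging",
]

_CONSEQUENCES = {"missense", "loss_of_function", "synonymous", "other"}


def normalize_chrom(chrom: str) -> str:
    """Map "X", "23", "chrX", "chr23" ... onto the canonical "chrX" style."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c == "23":
        c = "X"
    elif c == "24":
        c = "Y"
    elif c == "25":
        c = "MT"
    return "chr" + c


def read_variants(
    files: Iterable[Mapping], sample_meta: pd.DataFrame
) -> pd.DataFrame:
    """Read per-sample-per-round VCFs into one observation table.

    ``files`` holds mappings with keys ``path``, ``patient``, ``sample``
    and ``round``; every (patient, sample) must exist in ``sample_meta``.
    AD/DP FORMAT fields map to alt_reads/total_reads; a record without
    both is a hard error.  MBQ, when present, supplies the mean base
    quality (missing -> NaN, which downstream filters treat as failing).
    """
    known = set(zip(sample_meta.patient, sample_meta["sample"]))
    rows = []
    for spec in files:
        patient, sample, rnd = spec["patient"], spec["sample"], int(spec["round"])
        if (patient, sample) not in known:
            raise KeyError(
                f"sample {patient}/{sample} from {spec['path']} not in metadata"
            )
        with pysam.VariantFile(str(spec["path"])) as vf:
            for rec in vf:
                if not rec.samples:
                    raise ValueError(f"{spec['path']}: record {rec.chrom}:{rec.pos} has no sample column")
                fmt = rec.samples[0]
                ad = fmt.get("AD")
                dp = fmt.get("DP")
                if ad is None or dp is None or any(a is None for a in ad):
                    raise ValueError(
                        f"{spec['path']}: record {rec.chrom}:{rec.pos} lacks AD/DP"
                    )
                mbq = fmt.get("MBQ")
                if mbq is None:
                    mbq = np.nan
                elif isinstance(mbq, tuple):
                    mbq = float(mbq[0])
                alts = rec.alts or ()
                for i, alt in enumerate(alts):
                    rows.append(
                        (
                            patient, sample, rnd, normalize_chrom(rec.chrom),
                            int(rec.pos), rec.ref, alt, int(ad[i + 1]), int(dp),
                            float(mbq),
                        )
                    )
    return pd.DataFrame(rows, columns=OBS_COLUMNS)


def read_dataset(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load a dataset directory written by the simulator (or hand-built to
    the same layout): returns (observations, sample_meta)."""
    path = Path(path)
    with open(path / "samples.yaml") as fh:
        manifest = yaml.safe_load(fh)
    sexes = {p: d["sex"] for p, d in manifest["patients"].items()}
    meta = pd.DataFrame(manifest["samples"])
    meta["sex"] = meta.patient.map(sexes)
    for col in ("start_mm", "end_mm"):
        meta[col] = pd.to_numeric(meta[col], errors="coerce")
    _check_meta(meta)
    files = [dict(f, path=path / f["path"]) for f in manifest["files"]]
    obs = read_variants(files, meta)
    return obs, meta


def _check_meta(meta: pd.DataFrame) -> None:
    geo = meta.dropna(subset=["start_mm", "end_mm"])
    bad = geo[geo.end_mm <= geo.start_mm]
    if not bad.empty:
        r = bad.iloc[0]
        raise ValueError(f"sample {r.patient}/{r['sample']}: end_mm <= start_mm")
    for patient, grp in geo.groupby("patient"):
        iv = sorted(zip(grp.start_mm, grp.end_mm))
        for (s1, e1), (s2, _) in zip(iv, iv[1:]):
            if s2 < e1:
                raise ValueError(f"patient {patient}: overlapping segment intervals")


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read the per-variant annotation TSV.

    Missing gnomAD MAF / CADD stay missing (NaN), never coerced to 0;
    a malformed row raises with its (1-based, post-header) row number.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing = set(_ANN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation file lacks columns: {sorted(missing)}")
    df["chrom"] = df.chrom.map(normalize_chrom)
    for i, r in df.iterrows():
        row = i + 1
        if not (pd.isna(r.gnomad_maf) or 0.0 <= r.gnomad_maf <= 1.0):
            raise ValueError(f"annotation row {row}: gnomad_maf outside [0, 1]")
        if not (0 <= int(r.dbnsfp_damaging_votes) <= 5):
            raise ValueError(f"annotation row {row}: dbnsfp votes outside 0-5")
        if r.consequence not in _CONSEQUENCES:
            raise ValueError(
                f"annotation row {row}: unknown consequence {r.consequence!r}"
            )
        if int(r.pos) < 1:
            raise ValueError(f"annotation row {row}: position < 1")
    df["dbnsfp_damaging_votes"] = df.dbnsfp_damaging_votes.astype(int)
    df["clinvar_damaging"] = df.clinvar_damaging.astype(bool)
    return df


def write_report(results: Mapping, outdir: str | Path) -> Path:
    """Write the analysis summary: per-patient counts and clonal-frequency
    statistics (TSV + JSON), plus any mutation/clone-group/CHIP tables.

    ``results`` keys handled: ``patients`` (iterable of all patient ids,
    so zero-mutation patients are reported as 0), ``mutations`` (per
    mutation x sample quantification), ``clone_groups``, ``chip`` —
    all optional except ``patients``/``mutations``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    muts: pd.DataFrame = results["mutations"]
    patients = list(results["patients"])

    present = muts[muts.clonal_cell_frequency > 0] if len(muts) else muts
    summary_rows = []
    for p in patients:
        sub = present[present.patient == p] if len(present) else present
        freqs = (
            sub.drop_duplicates(["chrom", "pos", "ref", "alt"])  # per mutation
            .clonal_cell_frequency
            if len(sub)
            else pd.Series(dtype=float)
        )
        n_mut = (
            sub[["chrom", "pos", "ref", "alt"]].drop_duplicates().shape[0]
            if len(sub)
            else 0
        )
        summary_rows.append(
            dict(
                patient=p,
                n_mutations=n_mut,
                ccf_median=float(freqs.median()) if len(freqs) else np.nan,
                ccf_iqr_low=float(freqs.quantile(0.25)) if len(freqs) else np.nan,
                ccf_iqr_high=float(freqs.quantile(0.75)) if len(freqs) else np.nan,
                ccf_min=float(freqs.min()) if len(freqs) else np.nan,
                ccf_max=float(freqs.max()) if len(freqs) else np.nan,
            )
        )
    summary = pd.DataFrame(summary_rows)
    summary.to_csv(outdir / "per_patient_summary.tsv", sep="\t", index=False)
    if len(muts):
        muts.to_csv(outdir / "mutations.tsv", sep="\t", index=False)
    for key, name in (("clone_groups", "clone_groups.tsv"), ("chip", "chip.tsv")):
        if key in results and results[key] is not None and len(results[key]):
            results[key].to_csv(outdir / name, sep="\t", index=False)

    with open(outdir / "report.json", "w") as fh:
        json.dump(
            {
                "patients": {
                    r["patient"]: {k: (None if pd.isna(v) else v) for k, v in r.items() if k != "patient"}
                    for r in summary_rows
                }
            },
            fh,
            indent=2,
        )
    return outdir
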