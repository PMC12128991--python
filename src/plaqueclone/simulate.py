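"""Synthetic plaque/blood cohort simulator with planted clonal truth.

The generator emulates a multi-segment endarterectomy study design: each
patient contributes a plaque that was cut longitudinally into 2-5 mm
segments, with the frozen (sequenced) segments separated by 4-10 mm gaps,
plus a matched buffy-coat (blood leukocyte) reference.  Somatic clones are
planted as contiguous 1-D intervals of segments with a uniform cell
fraction inside every occupied segment; multi-mutation clones share one
per-sample fraction across all member mutations.  Germline heterozygous
variants sit at 50% expected VAF in every sample including blood, and CHIP
(clonal hematopoiesis) clones live in the buffy coat with optional,
independently parameterised infiltration fractions per tissue segment.

Read counts are drawn per site, sample and sequencing round as

    depth_site ~ Poisson(depth) clipped to >= 1   (or constant depth)
    alt_reads  ~ Binomial(depth_site, vaf + (1 - vaf) * error_rate)

so sequencing miscalls add to the alternate-read count.  Two independent
rounds per sample reproduce the duplicate-library validation design.
All randomness flows from ``SimConfig.seed``; identical configs give
identical tables and identical on-disk files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CloneSpec",
    "ChipSpec",
    "SimConfig",
    "TruthSet",
    "InfeasibleArchitectureError",
    "simulate_truth",
    "simulate_reads",
    "synthesize_annotations",
    "write_dataset",
]

AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))
BASES = ("A", "C", "G", "T")

#: diploid genome mass used to convert DNA yield to cell counts elsewhere
PG_PER_CELL = 6.6


class InfeasibleArchitectureError(ValueError):
    """Planted clone fractions sum to more than 1 in at least one sample."""


@dataclass(frozen=True)
class CloneSpec:
    """Explicitly planted somatic clone.

    fraction: cell fraction inside every occupied segment, in [0, 1].
    first_segment/last_segment: inclusive 0-based segment indices of the
    contiguous occupancy interval.
    """

    fraction: float
    first_segment: int
    last_segment: int
    n_mutations: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"clone fraction {self.fraction} outside [0, 1]")
        if self.last_segment < self.first_segment:
            raise ValueError("last_segment before first_segment")
        if self.n_mutations < 1:
            raise ValueError("clone needs at least one mutation")


@dataclass(frozen=True)
class ChipSpec:
    """Planted hematopoietic (CHIP) clone.

    blood_fraction: clonal cell fraction in the buffy coat.
    tissue_fractions: per-segment infiltration cell fractions (0 = absent);
    independent of the blood fraction by design.
    site: optional fixed (chrom, pos, ref, alt) — used to plant the same
    variant in several patients, e.g. to exercise recurrence exclusion.
    """

    blood_fraction: float
    tissue_fractions: tuple[float, ...] = ()
    gene: str = "DNMT3A"
    site: tuple[str, int, str, str] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.blood_fraction <= 1.0:
            raise ValueError("blood_fraction outside [0, 1]")
        for f in self.tissue_fractions:
            if not 0.0 <= f <= 1.0:
                raise ValueError("tissue fraction outside [0, 1]")


@dataclass
class SimConfig:
    """Study-design parameters for one synthetic cohort.

    Defaults reproduce the emulated study conditions: ~700x mean depth,
    two independent sequencing rounds, 2-5 mm frozen segments spaced
    4-10 mm apart, clone cell fractions on [0.01, 0.31] and a 1e-3
    per-base miscall rate.
    """

    n_patients: int = 1
    segments_per_plaque: int = 4
    segment_width_mm: tuple[float, float] = (2.0, 5.0)
    inter_segment_gap_mm: tuple[float, float] = (4.0, 10.0)
    depth: float = 700.0
    constant_depth: bool = False
    n_rounds: int = 2
    error_rate: float = 1e-3
    n_clones: int | tuple[int, int] = (2, 4)
    clone_fraction: tuple[float, float] = (0.01, 0.31)
    mutations_per_clone: int | tuple[int, int] = (1, 3)
    n_germline: int = 20
    n_error_sites: int = 100
    x_mutation_prob: float = 0.0
    sexes: Sequence[str] | None = None
    clones: Sequence[Sequence[CloneSpec]] | None = None
    chip: Mapping[int, Sequence[ChipSpec]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0.0 <= self.error_rate < 0.01:
            raise ValueError("error_rate must lie in [0, 0.01)")
        if self.n_rounds < 1 or self.n_patients < 1 or self.segments_per_plaque < 1:
            raise ValueError("counts must be >= 1")
        lo, hi = self.clone_fraction
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("clone_fraction bounds outside [0, 1]")
        if not 0.0 <= self.x_mutation_prob <= 1.0:
            raise ValueError("x_mutation_prob outside [0, 1]")
        if self.sexes is not None:
            if len(self.sexes) != self.n_patients:
                raise ValueError("sexes must have one entry per patient")
            bad = set(self.sexes) - {"male", "female"}
            if bad:
                raise ValueError(f"unknown sex values: {sorted(bad)}")
        if self.clones is not None and len(self.clones) != self.n_patients:
            raise ValueError("explicit clones must have one list per patient")


@dataclass
class TruthSet:
    """Ground truth for one simulated cohort.

    samples: patient, sample, sex, tissue_class, start_mm, end_mm,
        dna_yield_pg (geometry columns are NaN for buffy coats).
    variants: variant_id, patient, chrom, pos, ref, alt, kind
        (somatic | germline | chip | error), clone_id, gene.
    clones: clone_id, patient, kind, fraction, first/last segment,
        occ_start_mm, occ_end_mm, n_mutations, blood_fraction.
    expected_vaf: variant_id x sample expected VAF (one row per pair).
    """

    samples: pd.DataFrame
    variants: pd.DataFrame
    clones: pd.DataFrame
    expected_vaf: pd.DataFrame
    config: SimConfig


def _draw_count(rng: np.random.Generator, spec: int | tuple[int, int]) -> int:
    if isinstance(spec, tuple):
        lo, hi = spec
        return int(rng.integers(lo, hi + 1))
    return int(spec)


def _draw_site(
    rng: np.random.Generator, used: set[tuple[str, int]], on_x: bool = False
) -> tuple[str, int, str, str]:
    while True:
        chrom = "chrX" if on_x else AUTOSOMES[int(rng.integers(len(AUTOSOMES)))]
        pos = int(rng.integers(1, 100_000_000))
        if (chrom, pos) not in used:
            used.add((chrom, pos))
            ref = BASES[int(rng.integers(4))]
            alt = BASES[int(rng.integers(4))]
            while alt == ref:
                alt = BASES[int(rng.integers(4))]
            return chrom, pos, ref, alt


def _segment_geometry(rng: np.random.Generator, cfg: SimConfig) -> list[tuple[float, float]]:
    """Alternating frozen-segment / gap layout along the plaque axis."""
    pos = 0.0
    out = []
    for i in range(cfg.segments_per_plaque):
        if i > 0:
            pos += rng.uniform(*cfg.inter_segment_gap_mm)
        width = rng.uniform(*cfg.segment_width_mm)
        out.append((round(pos, 3), round(pos + width, 3)))
        pos += width
    return out


def _draw_clone_set(rng: np.random.Generator, cfg: SimConfig) -> list[CloneSpec]:
    """Random clone architecture; resampled until per-segment feasible."""
    for _ in range(500):
        n = _draw_count(rng, cfg.n_clones)
        specs = []
        for _ in range(n):
            a = int(rng.integers(cfg.segments_per_plaque))
            b = int(rng.integers(cfg.segments_per_plaque))
            first, last = min(a, b), max(a, b)
            frac = float(rng.uniform(*cfg.clone_fraction))
            k = _draw_count(rng, cfg.mutations_per_clone)
            specs.append(CloneSpec(frac, first, last, k))
        if _feasible(specs, cfg.segments_per_plaque):
            return specs
    raise InfeasibleArchitectureError(
        "could not draw a clone set with per-sample fractions summing to <= 1"
    )


def _feasible(specs: Sequence[CloneSpec], n_segments: int) -> bool:
    sums = np.zeros(n_segments)
    for c in specs:
        sums[c.first_segment : c.last_segment + 1] += c.fraction
    return bool(np.all(sums <= 1.0 + 1e-12))


def simulate_truth(config: SimConfig) -> TruthSet:
    """Plant the clonal architecture and tabulate per-sample expected VAFs.

    Raises :class:`InfeasibleArchitectureError` when explicitly supplied
    clones exceed a summed cell fraction of 1 in any segment.
    """
    rng = np.random.default_rng(config.seed)
    used_sites: set[tuple[str, int]] = set()

    sample_rows, variant_rows, clone_rows, evaf_rows = [], [], [], []
    vid = 0
    for p in range(config.n_patients):
        patient = f"p{p + 1}"
        sex = (
            config.sexes[p]
            if config.sexes is not None
            else ("male" if rng.random() < 0.5 else "female")
        )
        geometry = _segment_geometry(rng, config)
        tissue_samples = [f"s{i + 1}" for i in range(config.segments_per_plaque)]
        for s, (start, end) in zip(tissue_samples, geometry):
            sample_rows.append(
                dict(
                    patient=patient, sample=s, sex=sex, tissue_class="plaque",
                    start_mm=start, end_mm=end,
                    dna_yield_pg=float(np.round(rng.uniform(3e5, 5e6), 1)),
                )
            )
        sample_rows.append(
            dict(
                patient=patient, sample="buffy", sex=sex, tissue_class="buffy",
                start_mm=np.nan, end_mm=np.nan,
                dna_yield_pg=float(np.round(rng.uniform(1e6, 8e6), 1)),
            )
        )
        all_samples = tissue_samples + ["buffy"]

        def plant(chrom, pos, ref, alt, kind, clone_id, gene, per_sample_vaf):
            nonlocal vid
            vid += 1
            variant_id = f"v{vid:05d}"
            variant_rows.append(
                dict(
                    variant_id=variant_id, patient=patient, chrom=chrom, pos=pos,
                    ref=ref, alt=alt, kind=kind, clone_id=clone_id, gene=gene,
                )
            )
            for s in all_samples:
                evaf_rows.append(
                    dict(
                        variant_id=variant_id, patient=patient, sample=s,
                        expected_vaf=float(per_sample_vaf.get(s, 0.0)),
                    )
                )
            return variant_id

        # somatic clones
        if config.clones is not None:
            specs = list(config.clones[p])
            for c in specs:
                if c.last_segment >= config.segments_per_plaque:
                    raise ValueError("clone segment index out of range")
            if not _feasible(specs, config.segments_per_plaque):
                raise InfeasibleArchitectureError(
                    f"patient {patient}: summed clone fractions exceed 1 in a segment"
                )
        else:
            specs = _draw_clone_set(rng, config)

        for ci, spec in enumerate(specs):
            clone_id = f"{patient}_c{ci + 1}"
            occupied = tissue_samples[spec.first_segment : spec.last_segment + 1]
            clone_rows.append(
                dict(
                    clone_id=clone_id, patient=patient, kind="somatic",
                    fraction=spec.fraction, first_segment=spec.first_segment,
                    last_segment=spec.last_segment,
                    occ_start_mm=geometry[spec.first_segment][0],
                    occ_end_mm=geometry[spec.last_segment][1],
                    n_mutations=spec.n_mutations, blood_fraction=0.0,
                )
            )
            for _ in range(spec.n_mutations):
                on_x = rng.random() < config.x_mutation_prob
                chrom, pos, ref, alt = _draw_site(rng, used_sites, on_x)
                mult = 1.0 if (chrom == "chrX" and sex == "male") else 0.5
                plant(
                    chrom, pos, ref, alt, "somatic", clone_id, f"PLQ{vid + 1:04d}",
                    {s: spec.fraction * mult for s in occupied},
                )

        # germline heterozygous variants (autosomal): 50% VAF everywhere
        for _ in range(config.n_germline):
            chrom, pos, ref, alt = _draw_site(rng, used_sites)
            plant(
                chrom, pos, ref, alt, "germline", None, f"GML{vid + 1:04d}",
                {s: 0.5 for s in all_samples},
            )

        # CHIP clones in blood, optionally infiltrating tissue segments
        for ci, spec in enumerate((config.chip or {}).get(p, [])):
            clone_id = f"{patient}_chip{ci + 1}"
            if spec.site is not None:
                chrom, pos, ref, alt = spec.site
                used_sites.add((chrom, pos))
            else:
                chrom, pos, ref, alt = _draw_site(rng, used_sites)
            tf = list(spec.tissue_fractions) + [0.0] * (
                config.segments_per_plaque - len(spec.tissue_fractions)
            )
            pos_segs = [i for i, f in enumerate(tf) if f > 0]
            clone_rows.append(
                dict(
                    clone_id=clone_id, patient=patient, kind="chip",
                    fraction=np.nan,
                    first_segment=pos_segs[0] if pos_segs else -1,
                    last_segment=pos_segs[-1] if pos_segs else -1,
                    occ_start_mm=geometry[pos_segs[0]][0] if pos_segs else np.nan,
                    occ_end_mm=geometry[pos_segs[-1]][1] if pos_segs else np.nan,
                    n_mutations=1, blood_fraction=spec.blood_fraction,
                )
            )
            vafs = {"buffy": spec.blood_fraction / 2.0}
            for s, f in zip(tissue_samples, tf):
                vafs[s] = f / 2.0
            plant(chrom, pos, ref, alt, "chip", clone_id, spec.gene, vafs)

        # error-only sites: expected VAF 0; miscalls come from the read model
        for _ in range(config.n_error_sites):
            chrom, pos, ref, alt = _draw_site(rng, used_sites)
            plant(chrom, pos, ref, alt, "error", None, f"ERR{vid + 1:04d}", {})

    samples = pd.DataFrame(sample_rows)
    variants = pd.DataFrame(variant_rows)
    clones = pd.DataFrame(
        clone_rows,
        columns=[
            "clone_id", "patient", "kind", "fraction", "first_segment",
            "last_segment", "occ_start_mm", "occ_end_mm", "n_mutations",
            "blood_fraction",
        ],
    )
    expected = pd.DataFrame(evaf_rows)
    return TruthSet(samples, variants, clones, expected, config)


def simulate_reads(truth: TruthSet, config: SimConfig) -> pd.DataFrame:
    """Draw per-round read counts for every (variant, sample) of a cohort.

    Returns one observation table with columns patient, sample, round,
    chrom, pos, ref, alt, alt_reads, total_reads, mean_base_quality and a
    variant_id column linking back to the truth.  CHIP sites are emitted
    for every patient's samples (a shared force-calling panel); all other
    sites only for the carrier patient.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    ev = truth.expected_vaf.merge(
        truth.variants[["variant_id", "chrom", "pos", "ref", "alt", "kind"]],
        on="variant_id",
    )
    # cross-patient CHIP panel: expected VAF 0 in every non-carrier sample
    chip = truth.variants.query("kind == 'chip'")
    if not chip.empty:
        extra = []
        for _, v in chip.iterrows():
            others = truth.samples[truth.samples.patient != v.patient]
            for _, s in others.iterrows():
                extra.append(
                    dict(
                        variant_id=v.variant_id, patient=s.patient, sample=s["sample"],
                        expected_vaf=0.0, chrom=v.chrom, pos=v.pos, ref=v.ref,
                        alt=v.alt, kind=v.kind,
                    )
                )
        if extra:
            ev = pd.concat([ev, pd.DataFrame(extra)], ignore_index=True)

    n = len(ev)
    frames = []
    for rnd in range(1, config.n_rounds + 1):
        if config.constant_depth:
            depth = np.full(n, int(round(config.depth)))
        else:
            depth = np.maximum(rng.poisson(config.depth, size=n), 1)
        # miscalls on non-variant templates add to the alt count in tissue;
        # buffy candidate tables carry germline/CHIP support only (the
        # matched caller screens raw noise out of the normal)
        v = ev.expected_vaf.to_numpy()
        err = np.where(ev["sample"].to_numpy() == "buffy", 0.0, config.error_rate)
        p = np.clip(v + (1.0 - v) * err, 0.0, 1.0)
        alt = rng.binomial(depth, p)
        mbq = np.round(np.clip(rng.normal(36.0, 2.0, size=n), 2.0, 60.0), 1)
        frames.append(
            pd.DataFrame(
                dict(
                    patient=ev.patient.to_numpy(),
                    sample=ev["sample"].to_numpy(),
                    round=rnd,
                    chrom=ev.chrom.to_numpy(),
                    pos=ev.pos.to_numpy(),
                    ref=ev.ref.to_numpy(),
                    alt=ev.alt.to_numpy(),
                    alt_reads=alt,
                    total_reads=depth,
                    mean_base_quality=mbq,
                    variant_id=ev.variant_id.to_numpy(),
                )
            )
        )
    obs = pd.concat(frames, ignore_index=True)
    return obs.sort_values(
        ["patient", "sample", "round", "chrom", "pos", "alt"]
    ).reset_index(drop=True)


def synthesize_annotations(truth: TruthSet, seed: int | None = None) -> pd.DataFrame:
    """Truth-informed annotation table for every planted variant.

    CHIP variants receive damaging evidence (loss-of-function or high CADD
    with 5/5 predictor votes) and no gnomAD entry; germline variants get a
    common gnomAD MAF; somatic/error sites get neutral-ish annotations.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([truth.config.seed if seed is None else seed, 2])
    )
    rows = []
    for _, v in truth.variants.iterrows():
        if v.kind == "chip":
            lof = rng.random() < 0.5
            rows.append(
                dict(
                    chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt, gene=v.gene,
                    consequence="loss_of_function" if lof else "missense",
                    gnomad_maf=np.nan,
                    cadd_phred=float(np.round(rng.uniform(25, 45), 1)),
                    dbnsfp_damaging_votes=5, clinvar_damaging=False,
                )
            )
        elif v.kind == "germline":
            rows.append(
                dict(
                    chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt, gene=v.gene,
                    consequence="synonymous" if rng.random() < 0.5 else "missense",
                    gnomad_maf=float(np.round(rng.uniform(0.05, 0.45), 4)),
                    cadd_phred=float(np.round(rng.uniform(0, 15), 1)),
                    dbnsfp_damaging_votes=int(rng.integers(0, 3)),
                    clinvar_damaging=False,
                )
            )
        else:
            rows.append(
                dict(
                    chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt, gene=v.gene,
                    consequence="missense" if rng.random() < 0.8 else "other",
                    gnomad_maf=np.nan,
                    cadd_phred=float(np.round(rng.uniform(0, 40), 1)),
                    dbnsfp_damaging_votes=int(rng.integers(0, 6)),
                    clinvar_damaging=False,
                )
            )
    return pd.DataFrame(rows).drop_duplicates(
        subset=["chrom", "pos", "ref", "alt"]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# on-disk dataset

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=plaqueclone-simulator
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##FORMAT=<ID=MBQ,Number=1,Type=Float,Description="Mean base quality of alt reads">
"""


def _write_vcf(path: Path, rows: pd.DataFrame, sample_name: str) -> None:
    contigs = sorted(rows.chrom.unique(), key=lambda c: (len(c), c))
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + sample_name + "\n"
        )
        for r in rows.itertuples():
            gt = "0/1" if r.alt_reads > 0 else "0/0"
            ad = f"{r.total_reads - r.alt_reads},{r.alt_reads}"
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\t"
                f"GT:AD:DP:MBQ\t{gt}:{ad}:{r.total_reads}:{r.mean_base_quality}\n"
            )


def write_dataset(
    obs: pd.DataFrame,
    truth: TruthSet,
    outdir: str | Path,
    annotations: pd.DataFrame | None = None,
    overwrite: bool = False,
) -> Path:
    """Write a complete dataset: per-sample-per-round VCFs, annotation TSV,
    sample-metadata YAML and truth TSVs.  Byte-stable for a fixed config.

    Refuses to write into a directory that already holds a dataset unless
    ``overwrite`` is set.
    """
    import yaml

    outdir = Path(outdir)
    manifest_path = outdir / "samples.yaml"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(
            f"{manifest_path} exists; pass overwrite=True to replace the dataset"
        )
    (outdir / "vcf").mkdir(parents=True, exist_ok=True)

    if annotations is None:
        annotations = synthesize_annotations(truth)

    files = []
    for (patient, sample, rnd), rows in obs.groupby(
        ["patient", "sample", "round"], sort=True
    ):
        rel = f"vcf/{patient}_{sample}_r{rnd}.vcf"
        rows = rows.sort_values(["chrom", "pos", "alt"], kind="mergesort")
        _write_vcf(outdir / rel, rows, f"{patient}_{sample}")
        files.append(dict(patient=patient, sample=sample, round=int(rnd), path=rel))

    meta = {
        "patients": {
            p: {"sex": sex}
            for p, sex in truth.samples.drop_duplicates("patient")[
                ["patient", "sex"]
            ].itertuples(index=False)
        },
        "samples": [
            {
                "patient": r.patient,
                "sample": r["sample"],
                "tissue_class": r.tissue_class,
                "start_mm": None if pd.isna(r.start_mm) else float(r.start_mm),
                "end_mm": None if pd.isna(r.end_mm) else float(r.end_mm),
                "dna_yield_pg": float(r.dna_yield_pg),
            }
            for _, r in truth.samples.iterrows()
        ],
        "files": files,
    }
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)

    annotations.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    truth.variants.to_csv(outdir / "truth_variants.tsv", sep="\t", index=False)
    truth.clones.to_csv(outdir / "truth_clones.tsv", sep="\t", index=False)
    truth.expected_vaf.to_csv(outdir / "truth_expected_vaf.tsv", sep="\t", index=False)
    return outdir
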