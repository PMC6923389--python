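"""Readers, writers and containers for targeted deep-sequencing pileup data.

Targeted deep sequencing (TDS) of ~250 bp amplicons produces, for every
genomic position of a target region, per-allele and per-strand read counts
for a lesion sample and its matched control.  This module holds the three
containers the rest of the package consumes — :class:`TargetRegion`,
:class:`AlleleCounts` and :class:`VafProfile` — together with the format
plumbing: BED target lists, TSV allele-count tables, optional counting
straight from coordinate-sorted alignment files, and minimal VCF output for
somatic calls.

Coordinates are 0-based half-open internally (BED native); the VCF writer
converts to 1-based on output.  The allele alphabet is ``{A, C, G, T}``; N
bases, deletions and reference skips are excluded from depth.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

ALLELES: tuple[str, ...] = ("A", "C", "G", "T")
ALLELE_INDEX: Mapping[str, int] = {a: i for i, a in enumerate(ALLELES)}
STRANDS: tuple[str, ...] = ("fwd", "rev")

#: Amplicons are a few hundred bp; anything larger is almost certainly a
#: mis-specified target rather than a real amplicon.
MAX_REGION_LENGTH = 10_000

COUNT_COLUMNS = [f"{a}_{s}" for a in ALLELES for s in STRANDS]
TABLE_COLUMNS = ["sample_id", "region_id", "pos", "ref"] + COUNT_COLUMNS


class PileupFormatError(ValueError):
    """Raised for malformed or invariant-violating input tables."""


@dataclasses.dataclass(frozen=True)
class TargetRegion:
    """One amplicon target: 0-based half-open interval on a chromosome."""

    region_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise PileupFormatError(
                f"region {self.region_id!r}: end ({self.end}) must be > start ({self.start})"
            )
        if self.start < 0:
            raise PileupFormatError(f"region {self.region_id!r}: negative start")
        if len(self) > MAX_REGION_LENGTH:
            raise PileupFormatError(
                f"region {self.region_id!r}: length {len(self)} exceeds "
                f"amplicon-scale maximum {MAX_REGION_LENGTH}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclasses.dataclass
class AlleleCounts:
    """Per-position, per-allele, per-strand read counts for one sample/region.

    ``counts`` has shape ``(n_positions, 4, 2)``: alleles in ``ALLELES``
    order along axis 1, (forward, reverse) strand along axis 2.  Positions
    are 0-based genomic coordinates and must be contiguous.
    """

    sample_id: str
    region_id: str
    positions: np.ndarray
    ref: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype="<U1")
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = self.positions.shape[0]
        if self.counts.shape != (n, 4, 2):
            raise PileupFormatError(
                f"counts shape {self.counts.shape} does not match {n} positions"
            )
        if self.ref.shape[0] != n:
            raise PileupFormatError("ref length does not match positions")
        if n and np.any(np.diff(self.positions) != 1):
            if np.any(np.diff(self.positions) <= 0):
                raise PileupFormatError(
                    f"duplicated or unsorted position in {self.sample_id}/{self.region_id}"
                )
            raise PileupFormatError(
                f"positions not contiguous in {self.sample_id}/{self.region_id}"
            )
        if np.any(self.counts < 0):
            raise PileupFormatError("negative read count")
        bad = ~np.isin(self.ref, ALLELES)
        if np.any(bad):
            raise PileupFormatError(f"reference allele not in {ALLELES}")

    @property
    def n_positions(self) -> int:
        return int(self.positions.shape[0])

    def depth(self) -> np.ndarray:
        """Total depth per position, pooled over alleles and strands."""
        return self.counts.sum(axis=(1, 2))

    def pooled(self) -> np.ndarray:
        """Strand-pooled counts, shape ``(n_positions, 4)``."""
        return self.counts.sum(axis=2)

    def to_frame(self) -> pd.DataFrame:
        data = {
            "sample_id": self.sample_id,
            "region_id": self.region_id,
            "pos": self.positions,
            "ref": self.ref,
        }
        for ai, a in enumerate(ALLELES):
            for si, s in enumerate(STRANDS):
                data[f"{a}_{s}"] = self.counts[:, ai, si]
        return pd.DataFrame(data, columns=TABLE_COLUMNS)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AlleleCounts":
        missing = [c for c in TABLE_COLUMNS if c not in frame.columns]
        if missing:
            raise PileupFormatError(f"allele-count table missing columns: {missing}")
        samples = frame["sample_id"].unique()
        regions = frame["region_id"].unique()
        if len(samples) != 1 or len(regions) != 1:
            raise PileupFormatError(
                "from_frame expects a single (sample, region); got "
                f"samples={list(samples)} regions={list(regions)}"
            )
        frame = frame.sort_values("pos")
        if frame["pos"].duplicated().any():
            dup = int(frame.loc[frame["pos"].duplicated(), "pos"].iloc[0])
            raise PileupFormatError(
                f"duplicated position {dup} in {samples[0]}/{regions[0]}"
            )
        counts = np.stack(
            [
                np.stack([frame[f"{a}_{s}"].to_numpy() for s in STRANDS], axis=1)
                for a in ALLELES
            ],
            axis=1,
        )
        return cls(
            sample_id=str(samples[0]),
            region_id=str(regions[0]),
            positions=frame["pos"].to_numpy(),
            ref=frame["ref"].to_numpy(),
            counts=counts,
        )


@dataclasses.dataclass
class VafProfile:
    """Per-position, per-allele variant allele fractions for one sample.

    ``vaf`` has shape ``(n_positions, 4)``; rows at zero-depth positions are
    NaN and flagged ``defined == False`` — they are excluded from all
    downstream statistics rather than treated as zero.
    """

    sample_id: str
    region_id: str
    positions: np.ndarray
    ref: np.ndarray
    vaf: np.ndarray
    depth: np.ndarray
    defined: np.ndarray


def compute_vaf(counts: AlleleCounts) -> VafProfile:
    """Strand-pooled VAF per position and allele: count / depth.

    Zero-depth positions are flagged undefined (NaN), not errors.
    """
    pooled = counts.pooled().astype(float)
    depth = counts.depth()
    defined = depth > 0
    vaf = np.full_like(pooled, np.nan)
    vaf[defined] = pooled[defined] / depth[defined, None]
    return VafProfile(
        sample_id=counts.sample_id,
        region_id=counts.region_id,
        positions=counts.positions.copy(),
        ref=counts.ref.copy(),
        vaf=vaf,
        depth=depth,
        defined=defined,
    )


# ---------------------------------------------------------------------------
# BED targets


def read_targets(path: str | Path) -> list[TargetRegion]:
    """Read a 3+ column BED file of amplicon targets (0-based half-open).

    The optional 4th column provides the region id; otherwise
    ``chrom:start-end`` is used.  Malformed rows raise
    :class:`PileupFormatError` naming the line number.
    """
    regions: list[TargetRegion] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise PileupFormatError(
                    f"{path}:{lineno}: expected >=3 tab-separated BED columns"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise PileupFormatError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from exc
            region_id = fields[3] if len(fields) > 3 and fields[3] else f"{chrom}:{start}-{end}"
            try:
                regions.append(TargetRegion(region_id, chrom, start, end))
            except PileupFormatError as exc:
                raise PileupFormatError(f"{path}:{lineno}: {exc}") from exc
    return regions


def write_targets(regions: Sequence[TargetRegion], path: str | Path) -> None:
    with open(path, "w") as handle:
        for r in regions:
            handle.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\n")


# ---------------------------------------------------------------------------
# Allele-count TSV tables


def write_allele_counts(
    counts: AlleleCounts | Iterable[AlleleCounts], path: str | Path
) -> None:
    """Write one or more allele-count tables to a single TSV."""
    if isinstance(counts, AlleleCounts):
        counts = [counts]
    frames = [c.to_frame() for c in counts]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_allele_counts_table(path: str | Path) -> list[AlleleCounts]:
    """Read a TSV that may hold several (sample, region) blocks."""
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "region_id": str})
    missing = [c for c in TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise PileupFormatError(f"{path}: missing columns {missing}")
    if (frame[COUNT_COLUMNS] < 0).to_numpy().any():
        raise PileupFormatError(f"{path}: negative read count")
    out = []
    for (_, _), grp in frame.groupby(["sample_id", "region_id"], sort=False):
        out.append(AlleleCounts.from_frame(grp))
    return out


def read_allele_counts(
    path: str | Path,
    sample_id: str | None = None,
    region_id: str | None = None,
) -> AlleleCounts:
    """Read a single validated :class:`AlleleCounts` from a TSV.

    If the file holds several (sample, region) blocks the selectors must
    disambiguate.
    """
    tables = read_allele_counts_table(path)
    if sample_id is not None:
        tables = [t for t in tables if t.sample_id == sample_id]
    if region_id is not None:
        tables = [t for t in tables if t.region_id == region_id]
    if not tables:
        raise PileupFormatError(f"{path}: no matching (sample, region) block")
    if len(tables) > 1:
        keys = [(t.sample_id, t.region_id) for t in tables]
        raise PileupFormatError(
            f"{path}: ambiguous, holds {keys}; pass sample_id/region_id"
        )
    return tables[0]


# ---------------------------------------------------------------------------
# Counting from alignments


def counts_from_alignments(
    path: str | Path,
    targets: Sequence[TargetRegion],
    *,
    fasta: str | Path | None = None,
    min_base_quality: int = 20,
    min_mapping_quality: int = 20,
    sample_id: str | None = None,
) -> list[AlleleCounts]:
    """Count per-position, per-strand base calls from a coordinate-sorted,
    indexed alignment file (BAM/CRAM).

    Non-``ACGT`` base calls, deletions and reference skips are excluded.
    The reference allele per position is taken from ``fasta`` when given,
    otherwise the majority base call is used (flagged choice for synthetic
    or reference-free workflows).  Returns one table per target, in target
    order.
    """
    import pysam

    path = str(path)
    if sample_id is None:
        sample_id = Path(path).stem
    ref_fa = pysam.FastaFile(str(fasta)) if fasta is not None else None
    results: list[AlleleCounts] = []
    try:
        with pysam.AlignmentFile(path) as af:
            if not af.has_index():
                raise PileupFormatError(f"{path}: alignment index is required")
            for target in targets:
                if target.chrom not in af.references:
                    raise PileupFormatError(
                        f"target chrom {target.chrom!r} absent from alignment header"
                    )
                n = len(target)
                counts = np.zeros((n, 4, 2), dtype=np.int64)
                for col in af.pileup(
                    target.chrom,
                    target.start,
                    target.end,
                    truncate=True,
                    # the samtools stepper honours the quality thresholds;
                    # "all" applies only the flag filter
                    stepper="samtools",
                    ignore_overlaps=False,
                    min_base_quality=min_base_quality,
                    min_mapping_quality=min_mapping_quality,
                    max_depth=1_000_000,
                ):
                    offset = col.reference_pos - target.start
                    for pr in col.pileups:
                        if pr.is_del or pr.is_refskip or pr.query_position is None:
                            continue
                        base = pr.alignment.query_sequence[pr.query_position].upper()
                        ai = ALLELE_INDEX.get(base)
                        if ai is None:  # N or ambiguity code
                            continue
                        si = 1 if pr.alignment.is_reverse else 0
                        counts[offset, ai, si] += 1
                if ref_fa is not None:
                    seq = ref_fa.fetch(target.chrom, target.start, target.end).upper()
                    ref = np.array(list(seq), dtype="<U1")
                    if np.any(~np.isin(ref, ALLELES)):
                        # fall back to majority at non-ACGT reference bases
                        maj = np.array(ALLELES)[counts.sum(axis=2).argmax(axis=1)]
                        ref = np.where(np.isin(ref, ALLELES), ref, maj)
                else:
                    ref = np.array(ALLELES)[counts.sum(axis=2).argmax(axis=1)]
                results.append(
                    AlleleCounts(
                        sample_id=sample_id,
                        region_id=target.region_id,
                        positions=np.arange(target.start, target.end),
                        ref=ref,
                        counts=counts,
                    )
                )
    finally:
        if ref_fa is not None:
            ref_fa.close()
    return results


# ---------------------------------------------------------------------------
# VCF output

_VCF_META = """\
##fileformat=VCFv4.2
##source=adenoclone
##INFO=<ID=DJ,Number=1,Type=Float,Description="Max absolute VAF difference lesion vs control at this position">
##INFO=<ID=MU,Number=1,Type=Float,Description="Windowed background mean of the VAF-difference track">
##INFO=<ID=SIGMA,Number=1,Type=Float,Description="Windowed background SD of the VAF-difference track">
##INFO=<ID=PVAL,Number=1,Type=Float,Description="Upper-tail normal p-value of DJ under the background model">
##INFO=<ID=VAF_LESION,Number=1,Type=Float,Description="Lesion VAF of the called allele">
##INFO=<ID=VAF_CONTROL,Number=1,Type=Float,Description="Control VAF of the called allele">
##FILTER=<ID=p_value,Description="Background-model p-value not below alpha">
##FILTER=<ID=d_min,Description="VAF difference not above the minimum difference threshold">
##FILTER=<ID=control_vaf,Description="A non-reference allele exceeds the control VAF ceiling">
"""

_VCF_COLUMNS = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"


def _fmt(x: float) -> str:
    if x != x:  # NaN
        return "."
    return format(float(x), ".6g")


def write_calls(calls: Sequence, path: str | Path) -> None:
    """Write somatic calls as a minimal VCF 4.2 file.

    Positions convert from the package's 0-based convention to VCF's
    1-based.  FILTER is ``PASS`` for verdict-true calls, otherwise the
    semicolon-joined names of the failed rules.
    """
    chroms = sorted({call.chrom for call in calls})
    with open(path, "w") as handle:
        handle.write(_VCF_META)
        for chrom in chroms:
            handle.write(f"##contig=<ID={chrom}>\n")
        handle.write(_VCF_COLUMNS)
        for call in calls:
            failed = []
            if not call.p_pass:
                failed.append("p_value")
            if not call.d_pass:
                failed.append("d_min")
            if not call.control_pass:
                failed.append("control_vaf")
            filt = "PASS" if not failed else ";".join(failed)
            info = (
                f"DJ={_fmt(call.d)};MU={_fmt(call.mu)};SIGMA={_fmt(call.sigma)};"
                f"PVAL={_fmt(call.p_value)};VAF_LESION={_fmt(call.lesion_vaf)};"
                f"VAF_CONTROL={_fmt(call.control_vaf)}"
            )
            handle.write(
                f"{call.chrom}\t{call.pos + 1}\t.\t{call.ref}\t{call.alt}\t.\t{filt}\t{info}\n"
            )
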