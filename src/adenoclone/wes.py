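"""Hard-filter battery for candidate SNVs from exome calling.

Exome-wide candidate single-nucleotide variants arrive from upstream
callers as a table of read support and allele fractions; a candidate is
discarded if *any* of the following hold (defaults in parentheses):

* total read number below the minimum (100),
* mutant read number below the minimum (7),
* disease-sample VAF below the minimum (0.024),
* germline-control VAF above the maximum (0.01),
* mutant reads on only one strand,
* presence in a population database (1000 Genomes / in-house), supplied
  as a precomputed boolean.

Every discarded candidate is labelled with all violated rules, so the
retained and discarded lists always partition the input.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

RULE_TOTAL_READS = "total_reads"
RULE_MUTANT_READS = "mutant_reads"
RULE_VAF_DISEASE = "vaf_disease"
RULE_VAF_GERMLINE = "vaf_germline"
RULE_STRAND = "strand"
RULE_POPULATION_DB = "population_db"

ALL_RULES = (
    RULE_TOTAL_READS,
    RULE_MUTANT_READS,
    RULE_VAF_DISEASE,
    RULE_VAF_GERMLINE,
    RULE_STRAND,
    RULE_POPULATION_DB,
)


@dataclasses.dataclass(frozen=True)
class CandidateSNV:
    """One candidate single-nucleotide variant from exome calling."""

    chrom: str
    pos: int
    ref: str
    alt: str
    total_reads: int
    mutant_reads_fwd: int
    mutant_reads_rev: int
    vaf_disease: float
    vaf_germline: float
    in_population_db: bool
    annotation: str | None = None

    def __post_init__(self) -> None:
        if min(self.total_reads, self.mutant_reads_fwd, self.mutant_reads_rev) < 0:
            raise ValueError("read counts must be >= 0")
        if self.mutant_reads > self.total_reads:
            raise ValueError(
                f"{self.chrom}:{self.pos}: mutant reads ({self.mutant_reads}) "
                f"exceed total reads ({self.total_reads})"
            )
        for name in ("vaf_disease", "vaf_germline"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @property
    def mutant_reads(self) -> int:
        return self.mutant_reads_fwd + self.mutant_reads_rev


@dataclasses.dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the discard battery (see module docstring)."""

    min_total_reads: int = 100
    min_mutant_reads: int = 7
    min_vaf_disease: float = 0.024
    max_vaf_germline: float = 0.01
    require_both_strands: bool = True
    exclude_population_db: bool = True

    def __post_init__(self) -> None:
        for name in (
            "min_total_reads",
            "min_mutant_reads",
            "min_vaf_disease",
            "max_vaf_germline",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def violated_rules(snv: CandidateSNV, config: FilterConfig | None = None) -> list[str]:
    """All discard rules the candidate violates (empty list = retained)."""
    config = config or FilterConfig()
    rules = []
    if snv.total_reads < config.min_total_reads:
        rules.append(RULE_TOTAL_READS)
    if snv.mutant_reads < config.min_mutant_reads:
        rules.append(RULE_MUTANT_READS)
    if snv.vaf_disease < config.min_vaf_disease:
        rules.append(RULE_VAF_DISEASE)
    if snv.vaf_germline > config.max_vaf_germline:
        rules.append(RULE_VAF_GERMLINE)
    if config.require_both_strands and (
        snv.mutant_reads_fwd == 0 or snv.mutant_reads_rev == 0
    ):
        rules.append(RULE_STRAND)
    if config.exclude_population_db and snv.in_population_db:
        rules.append(RULE_POPULATION_DB)
    return rules


@dataclasses.dataclass
class FilterResult:
    retained: list[CandidateSNV]
    discarded: list[tuple[CandidateSNV, list[str]]]


def filter_candidates(
    candidates: Sequence[CandidateSNV], config: FilterConfig | None = None
) -> FilterResult:
    """Partition candidates into retained and discarded-with-reasons."""
    config = config or FilterConfig()
    retained: list[CandidateSNV] = []
    discarded: list[tuple[CandidateSNV, list[str]]] = []
    for snv in candidates:
        rules = violated_rules(snv, config)
        if rules:
            discarded.append((snv, rules))
        else:
            retained.append(snv)
    return FilterResult(retained=retained, discarded=discarded)


@dataclasses.dataclass
class CohortSummary:
    """Per-cohort mutation burden and VAF summary over retained SNVs."""

    n_patients: int
    n_patients_mutated: int
    mean_snvs_per_patient: float
    vaf_mean: float
    vaf_min: float
    vaf_max: float

    @property
    def fraction_mutated(self) -> float:
        if self.n_patients == 0:
            return float("nan")
        return self.n_patients_mutated / self.n_patients


def summarize_cohort(
    per_patient: Mapping[str, Sequence[CandidateSNV]],
) -> CohortSummary:
    """Counts and VAF summaries over per-patient retained SNV lists.

    An empty cohort (or one with no retained SNVs) yields NaN-flagged VAF
    summaries rather than errors.
    """
    n_patients = len(per_patient)
    counts = [len(snvs) for snvs in per_patient.values()]
    vafs = np.array(
        [snv.vaf_disease for snvs in per_patient.values() for snv in snvs]
    )
    return CohortSummary(
        n_patients=n_patients,
        n_patients_mutated=sum(1 for c in counts if c > 0),
        mean_snvs_per_patient=float(np.mean(counts)) if counts else float("nan"),
        vaf_mean=float(vafs.mean()) if vafs.size else float("nan"),
        vaf_min=float(vafs.min()) if vafs.size else float("nan"),
        vaf_max=float(vafs.max()) if vafs.size else float("nan"),
    )


# ---------------------------------------------------------------------------
# TSV plumbing

_TSV_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "total_reads",
    "mutant_reads_fwd",
    "mutant_reads_rev",
    "vaf_disease",
    "vaf_germline",
    "in_population_db",
    "annotation",
]


def read_candidates(path: str | Path) -> list[CandidateSNV]:
    frame = pd.read_csv(path, sep="\t")
    out = []
    for row in frame.itertuples(index=False):
        annotation = getattr(row, "annotation", None)
        if annotation is not None and (pd.isna(annotation) or annotation == ""):
            annotation = None
        out.append(
            CandidateSNV(
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=str(row.ref),
                alt=str(row.alt),
                total_reads=int(row.total_reads),
                mutant_reads_fwd=int(row.mutant_reads_fwd),
                mutant_reads_rev=int(row.mutant_reads_rev),
                vaf_disease=float(row.vaf_disease),
                vaf_germline=float(row.vaf_germline),
                in_population_db=bool(row.in_population_db),
                annotation=annotation,
            )
        )
    return out


def write_candidates(
    candidates: Iterable[CandidateSNV | tuple[CandidateSNV, list[str]]],
    path: str | Path,
) -> None:
    """Write candidates, with a ``filter_reasons`` column when present."""
    rows = []
    for item in candidates:
        snv, reasons = item if isinstance(item, tuple) else (item, [])
        row = {c: getattr(snv, c) for c in _TSV_COLUMNS}
        row["filter_reasons"] = ";".join(reasons)
        rows.append(row)
    pd.DataFrame(rows, columns=_TSV_COLUMNS + ["filter_reasons"]).to_csv(
        path, sep="\t", index=False
    )
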