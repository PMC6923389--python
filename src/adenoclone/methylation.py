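"""Bisulfite methylation quantification over promoter amplicons.

Bisulfite conversion turns unmethylated cytosines into uracil (read as T)
while methylated CpG cytosines stay C.  Given per-CpG methylated /
unmethylated read counts over an amplicon (e.g. the two progesterone
receptor promoter regions, PR-A and PR-B), the per-CpG methylation
frequency is ``methylated / (methylated + unmethylated)``; reads with any
other base at the CpG are excluded from the callable denominator so
sequencing error does not inflate either state.  Per-sample amplicon
summaries are unweighted means over CpG sites; group comparisons use
Welch's t-test on the per-sample means.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .stats import welch_t


@dataclasses.dataclass
class BisulfiteCounts:
    """Per-CpG read counts for one sample and amplicon.

    ``noncpg_converted`` / ``noncpg_unconverted`` hold pooled counts at
    non-CpG cytosines for conversion-efficiency QC (0 when unavailable).
    """

    sample_id: str
    amplicon_id: str
    cpg_index: np.ndarray
    methylated: np.ndarray
    unmethylated: np.ndarray
    other: np.ndarray
    noncpg_converted: int = 0
    noncpg_unconverted: int = 0

    def __post_init__(self) -> None:
        self.cpg_index = np.asarray(self.cpg_index, dtype=np.int64)
        self.methylated = np.asarray(self.methylated, dtype=np.int64)
        self.unmethylated = np.asarray(self.unmethylated, dtype=np.int64)
        self.other = np.asarray(self.other, dtype=np.int64)
        n = self.cpg_index.shape[0]
        for name in ("methylated", "unmethylated", "other"):
            arr = getattr(self, name)
            if arr.shape[0] != n:
                raise ValueError(f"{name} length does not match cpg_index")
            if np.any(arr < 0):
                raise ValueError(f"negative {name} count")
        if min(self.noncpg_converted, self.noncpg_unconverted) < 0:
            raise ValueError("negative non-CpG count")

    def callable(self) -> np.ndarray:
        return self.methylated + self.unmethylated


@dataclasses.dataclass
class MethylationProfile:
    """Per-CpG methylation frequencies plus the amplicon-mean summary.

    ``freq`` is NaN at CpGs with zero callable reads; ``amplicon_mean`` is
    the unweighted mean over defined CpGs (``depth_weighted_mean`` is the
    callable-read-weighted alternative).  ``group`` carries an optional
    cohort label (e.g. KRAS-WT / KRAS-Mut).
    """

    sample_id: str
    amplicon_id: str
    cpg_index: np.ndarray
    freq: np.ndarray
    callable_reads: np.ndarray
    amplicon_mean: float
    depth_weighted_mean: float
    group: str | None = None


def methylation_frequency(
    counts: BisulfiteCounts, group: str | None = None
) -> MethylationProfile:
    """Per-CpG frequency ``methylated / callable`` and amplicon summary."""
    callable_reads = counts.callable()
    freq = np.full(callable_reads.shape[0], np.nan)
    ok = callable_reads > 0
    freq[ok] = counts.methylated[ok] / callable_reads[ok]
    amplicon_mean = float(freq[ok].mean()) if ok.any() else float("nan")
    total = int(callable_reads[ok].sum())
    weighted = (
        float(counts.methylated[ok].sum() / total) if total else float("nan")
    )
    return MethylationProfile(
        sample_id=counts.sample_id,
        amplicon_id=counts.amplicon_id,
        cpg_index=counts.cpg_index.copy(),
        freq=freq,
        callable_reads=callable_reads,
        amplicon_mean=amplicon_mean,
        depth_weighted_mean=weighted,
        group=group,
    )


def conversion_qc(
    converted: int, unconverted: int, *, min_rate: float = 0.98
) -> float:
    """Bisulfite conversion rate at non-CpG cytosines.

    Warns when the rate falls below ``min_rate`` (incomplete conversion
    inflates apparent methylation).  NaN when no non-CpG reads are
    available.
    """
    total = converted + unconverted
    if total == 0:
        return float("nan")
    rate = converted / total
    if rate < min_rate:
        warnings.warn(
            f"bisulfite conversion rate {rate:.4f} below {min_rate}; apparent "
            "methylation will be inflated",
            stacklevel=2,
        )
    return rate


@dataclasses.dataclass(frozen=True)
class GroupComparison:
    """Welch comparison of per-sample mean methylation between two groups."""

    amplicon_id: str
    t: float
    df: float
    p_value: float
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int


def compare_groups(
    profiles_a: Sequence[MethylationProfile],
    profiles_b: Sequence[MethylationProfile],
) -> GroupComparison:
    """Welch's t-test on per-sample amplicon means between two groups.

    Both groups need at least two samples and must cover the same
    amplicon.
    """
    if len(profiles_a) < 2 or len(profiles_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    amplicons = {p.amplicon_id for p in profiles_a} | {
        p.amplicon_id for p in profiles_b
    }
    if len(amplicons) != 1:
        raise ValueError(f"profiles span multiple amplicons: {sorted(amplicons)}")
    x = np.array([p.amplicon_mean for p in profiles_a])
    y = np.array([p.amplicon_mean for p in profiles_b])
    t, df, p = welch_t(x, y)
    return GroupComparison(
        amplicon_id=next(iter(amplicons)),
        t=t,
        df=df,
        p_value=p,
        mean_a=float(x.mean()),
        sd_a=float(x.std(ddof=1)),
        n_a=len(x),
        mean_b=float(y.mean()),
        sd_b=float(y.std(ddof=1)),
        n_b=len(y),
    )


# ---------------------------------------------------------------------------
# TSV plumbing

_COLUMNS = ["sample_id", "amplicon_id", "cpg_index", "meth", "unmeth", "other"]


def read_bisulfite_counts(path) -> list[BisulfiteCounts]:
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = []
    for (sid, amp), grp in frame.groupby(["sample_id", "amplicon_id"], sort=False):
        grp = grp.sort_values("cpg_index")
        out.append(
            BisulfiteCounts(
                sample_id=str(sid),
                amplicon_id=str(amp),
                cpg_index=grp["cpg_index"].to_numpy(),
                methylated=grp["meth"].to_numpy(),
                unmethylated=grp["unmeth"].to_numpy(),
                other=grp["other"].to_numpy(),
            )
        )
    return out


def write_bisulfite_counts(counts: Sequence[BisulfiteCounts], path) -> None:
    rows = []
    for c in counts:
        for i in range(c.cpg_index.shape[0]):
            rows.append(
                {
                    "sample_id": c.sample_id,
                    "amplicon_id": c.amplicon_id,
                    "cpg_index": int(c.cpg_index[i]),
                    "meth": int(c.methylated[i]),
                    "unmeth": int(c.unmethylated[i]),
                    "other": int(c.other[i]),
                }
            )
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)
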