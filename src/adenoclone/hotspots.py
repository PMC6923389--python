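"""Panel-derived VAF cutoffs and hotspot calling for macro-dissected tissue.

When no germline sample is available (e.g. macro-dissected endometrium and
myometrium), an alteration at a recurrent hotspot class (KRAS p.G12/G13,
KRAS p.Q61, PIK3CA p.E542/E545, PIK3CA p.H1047, PPP2R1A p.R179-R183) is
accepted as a true mutation when its VAF exceeds the mean + 3 SD of the
VAFs observed at the same hotspot across a negative-control panel of
normal-endometrium samples.

Percent is the canonical VAF unit in this module — the panel statistics
and cutoffs are reported in percent — and conversion to fractions happens
only at module boundaries.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Sequence
from pathlib import Path

import numpy as np
import pandas as pd


def percent_to_fraction(v: float) -> float:
    return v / 100.0


def fraction_to_percent(v: float) -> float:
    return v * 100.0


@dataclasses.dataclass(frozen=True)
class HotspotDef:
    """A hotspot class: a non-empty set of (chrom, pos, alt) sites.

    A class may pool several codons (e.g. G12/G13); the sample-level
    hotspot VAF is then the maximum single alt-allele VAF within the class.
    """

    hotspot_id: str
    gene: str
    sites: tuple[tuple[str, int, str], ...]

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError(f"hotspot {self.hotspot_id!r}: empty position set")


@dataclasses.dataclass(frozen=True)
class HotspotCutoff:
    """Panel statistics and detection cutoff for one hotspot, in percent."""

    hotspot_id: str
    panel_mean: float
    panel_sd: float
    cutoff: float
    panel_n: int


def estimate_cutoff(
    panel_vafs: Sequence[float],
    hotspot: HotspotDef | str,
    *,
    ddof: int = 0,
    n_sd: float = 3.0,
) -> HotspotCutoff:
    """Mean + ``n_sd`` x SD cutoff from a negative-panel VAF vector (%).

    ``ddof=0`` (population SD) by default; requires at least two panel
    samples.
    """
    vafs = np.asarray(panel_vafs, dtype=float)
    if vafs.size < 2:
        raise ValueError(f"panel has {vafs.size} sample(s); need >= 2")
    if np.any(vafs < 0):
        raise ValueError("negative VAF in panel")
    hotspot_id = hotspot.hotspot_id if isinstance(hotspot, HotspotDef) else str(hotspot)
    mean = float(vafs.mean())
    sd = float(vafs.std(ddof=ddof))
    return HotspotCutoff(
        hotspot_id=hotspot_id,
        panel_mean=mean,
        panel_sd=sd,
        cutoff=mean + n_sd * sd,
        panel_n=int(vafs.size),
    )


def leave_one_out_cutoffs(
    panel_vafs: Sequence[float],
    hotspot: HotspotDef | str,
    *,
    ddof: int = 0,
    n_sd: float = 3.0,
) -> list[HotspotCutoff]:
    """Cutoffs recomputed with each panel sample excluded in turn."""
    vafs = list(map(float, panel_vafs))
    out = []
    for i in range(len(vafs)):
        out.append(
            estimate_cutoff(vafs[:i] + vafs[i + 1 :], hotspot, ddof=ddof, n_sd=n_sd)
        )
    return out


def call_hotspot(sample_vaf: float, cutoff: HotspotCutoff) -> bool:
    """True iff the sample VAF (%) strictly exceeds the cutoff."""
    if sample_vaf < 0:
        raise ValueError(f"negative sample VAF: {sample_vaf}")
    return sample_vaf > cutoff.cutoff


def hotspot_vaf(per_site_vafs: Sequence[float]) -> float:
    """Aggregate per-site alt VAFs into the class-level VAF (maximum)."""
    vafs = np.asarray(per_site_vafs, dtype=float)
    if vafs.size == 0:
        return float("nan")
    return float(vafs.max())


def group_mutation_table(
    samples: pd.DataFrame,
    cutoffs: dict[str, HotspotCutoff] | Sequence[HotspotCutoff],
) -> pd.DataFrame:
    """Per-group mutation frequencies and VAF vectors per hotspot.

    ``samples`` needs columns ``sample_id``, ``group`` (e.g. A / E /
    Non-A/E), ``hotspot_id`` and ``vaf_percent``; every sample must carry
    exactly one group label.  Returns one row per (group, hotspot) with the
    number and fraction of panel-positive samples and the VAF vector, ready
    for downstream group comparisons.  Groups with zero samples for a
    hotspot are NaN-flagged.
    """
    required = {"sample_id", "group", "hotspot_id", "vaf_percent"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"sample table missing columns: {sorted(missing)}")
    if samples["group"].isna().any():
        bad = samples.loc[samples["group"].isna(), "sample_id"].tolist()
        raise ValueError(f"unlabeled sample(s): {bad}")
    labels = samples.groupby("sample_id")["group"].nunique()
    if (labels > 1).any():
        bad = labels[labels > 1].index.tolist()
        raise ValueError(f"sample(s) with multiple group labels: {bad}")
    if not isinstance(cutoffs, dict):
        cutoffs = {c.hotspot_id: c for c in cutoffs}
    rows = []
    for (group, hotspot_id), grp in samples.groupby(["group", "hotspot_id"]):
        cutoff = cutoffs.get(hotspot_id)
        if cutoff is None:
            raise ValueError(f"no cutoff for hotspot {hotspot_id!r}")
        vafs = grp["vaf_percent"].to_numpy(dtype=float)
        calls = np.array([call_hotspot(v, cutoff) for v in vafs])
        n = len(grp)
        rows.append(
            {
                "group": group,
                "hotspot_id": hotspot_id,
                "n_samples": n,
                "n_positive": int(calls.sum()),
                "fraction_positive": calls.sum() / n if n else float("nan"),
                "vafs_percent": list(vafs),
                "positive_vafs_percent": list(vafs[calls]),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# JSON hotspot definitions


def read_hotspot_defs(path: str | Path) -> list[HotspotDef]:
    """Read hotspot definitions from JSON.

    Format: a list of objects with keys ``id``, ``gene`` and ``sites``
    (list of ``[chrom, pos, alt]``).
    """
    with open(path) as handle:
        raw = json.load(handle)
    out = []
    for entry in raw:
        out.append(
            HotspotDef(
                hotspot_id=entry["id"],
                gene=entry["gene"],
                sites=tuple((s[0], int(s[1]), s[2]) for s in entry["sites"]),
            )
        )
    return out


def write_hotspot_defs(defs: Sequence[HotspotDef], path: str | Path) -> None:
    payload = [
        {"id": d.hotspot_id, "gene": d.gene, "sites": [list(s) for s in d.sites]}
        for d in defs
    ]
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=2)
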