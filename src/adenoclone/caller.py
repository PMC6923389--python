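"""Position-local background-noise test for ultra-low-VAF somatic mutations.

Deep amplicon sequencing detects variants at allele fractions far below the
error floor of a single fixed threshold.  The approach implemented here
validates a candidate position against the noise of its own amplicon: for
every position *i* of a target region a VAF-difference statistic

    d_i = max over y in {A,C,G,T} of | a_{y,i} - n_{y,i} |

is formed between the lesion profile *a* and the matched control profile
*n*.  For a tested position *j*, the mean ``mu_j`` and standard deviation
``sigma_j`` of the difference track over the window
``{d_k : k = j-K, ..., j-1, j+1, ..., j+K}`` (position *j* excluded,
truncated at region boundaries) define a normal null ``X ~ N(mu_j,
sigma_j^2)``.  The position is called somatic when all three of the
following hold:

* ``P(X > d_j) < alpha``          (default ``alpha = 0.05``),
* ``d_j > d_min``                 (default ``0.001``), and
* every non-reference allele in the control has VAF below
  ``control_vaf_max`` (default ``0.01``).

``K`` defaults to the full region length, so by default the window is the
whole amplicon minus the tested position.  The test is one-sided
(upper tail) and applied per position with no multiple-testing correction
by default; a Bonferroni option over the number of tested positions is
available for scan-style use.

A statsmodels-style surface is provided: build a :class:`TdsNoiseModel`
from lesion and control counts and call :meth:`~TdsNoiseModel.fit`, which
returns a :class:`TdsCallResults` carrying per-position calls, the
background estimates and a summary table.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .pileup import ALLELES, AlleleCounts, TargetRegion, VafProfile, compute_vaf


class RegionMismatchError(ValueError):
    """Lesion and control profiles do not cover the same region/positions."""


class DegenerateBackgroundError(ValueError):
    """Fewer than two usable window positions for the background model."""

    def __init__(self, position: int, n_window: int):
        self.position = position
        self.n_window = n_window
        super().__init__(
            f"position {position}: only {n_window} defined window position(s); "
            "need >= 2 for a background model"
        )


@dataclasses.dataclass(frozen=True)
class CallerConfig:
    """Thresholds and window settings for the background-noise test.

    alpha : significance level for the upper-tail normal test.
    d_min : minimum VAF difference; guards against statistically significant
        but biologically negligible differences at very quiet positions.
    control_vaf_max : ceiling on every non-reference allele VAF in the
        control sample at the tested position (germline/noise guard).
    K : window half-width in positions; ``None`` uses the full region
        length, i.e. the window is the whole amplicon minus the tested
        position.
    sd_ddof : delta degrees of freedom for ``sigma_j`` (0 = population SD).
    bonferroni : when true, the per-position significance level becomes
        ``alpha / n_tested_positions``.
    """

    alpha: float = 0.05
    d_min: float = 0.001
    control_vaf_max: float = 0.01
    K: int | None = None
    sd_ddof: int = 0
    bonferroni: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.d_min < 0:
            raise ValueError("d_min must be >= 0")
        if not 0 < self.control_vaf_max < 1:
            raise ValueError("control_vaf_max must be in (0, 1)")
        if self.K is not None and self.K < 1:
            raise ValueError("K must be >= 1")
        if self.sd_ddof not in (0, 1):
            raise ValueError("sd_ddof must be 0 or 1")


@dataclasses.dataclass
class DifferenceTrack:
    """Per-position max absolute VAF difference between lesion and control.

    ``d`` maximises over all four alleles (the reference included — at a
    true variant the reference difference mirrors the variant's).
    ``alt_index`` is the candidate *variant* allele: the argmax over
    non-reference alleles, since a somatic call must name a non-reference
    allele.
    """

    region_id: str
    positions: np.ndarray
    d: np.ndarray
    alt_index: np.ndarray
    defined: np.ndarray


@dataclasses.dataclass(frozen=True)
class BackgroundModel:
    """Windowed null for one position: ``X ~ N(mu, sigma^2)``."""

    position: int
    K: int
    mu: float
    sigma: float
    n_window: int


@dataclasses.dataclass(frozen=True)
class SomaticCall:
    """Verdict and supporting statistics for one candidate position/allele."""

    chrom: str
    pos: int
    ref: str
    alt: str
    d: float
    mu: float
    sigma: float
    p_value: float
    lesion_vaf: float
    control_vaf: float
    p_pass: bool
    d_pass: bool
    control_pass: bool
    verdict: bool


def difference_track(lesion: VafProfile, control: VafProfile) -> DifferenceTrack:
    """Compute ``d_i = max_y |a_{y,i} - n_{y,i}|`` and the argmax allele.

    Defined only where both samples have nonzero depth.  Ties between
    alleles break alphabetically (A < C < G < T).
    """
    if lesion.region_id != control.region_id:
        raise RegionMismatchError(
            f"region mismatch: {lesion.region_id!r} vs {control.region_id!r}"
        )
    if lesion.positions.shape != control.positions.shape or np.any(
        lesion.positions != control.positions
    ):
        raise RegionMismatchError("lesion and control cover different positions")
    defined = lesion.defined & control.defined
    diff = np.abs(lesion.vaf - control.vaf)
    diff[~defined] = np.nan
    d = np.full(lesion.positions.shape[0], np.nan)
    alt_index = np.zeros(lesion.positions.shape[0], dtype=np.int64)
    if defined.any():
        d[defined] = np.max(diff[defined], axis=1)
        # Candidate allele: best non-reference difference; np.argmax takes
        # the first maximum -> alphabetical tie-break.
        ref_col = np.array([ALLELES.index(r) for r in lesion.ref])
        nonref = diff.copy()
        nonref[np.arange(nonref.shape[0]), ref_col] = -np.inf
        alt_index[defined] = np.argmax(nonref[defined], axis=1)
    return DifferenceTrack(
        region_id=lesion.region_id,
        positions=lesion.positions.copy(),
        d=d,
        alt_index=alt_index,
        defined=defined,
    )


def _resolve_K(track: DifferenceTrack, config: CallerConfig) -> int:
    return config.K if config.K is not None else int(track.positions.shape[0])


def fit_background(
    track: DifferenceTrack, j: int, config: CallerConfig | None = None
) -> BackgroundModel:
    """Windowed mean/SD of the difference track around genomic position ``j``.

    The window covers the 2K neighbourhood excluding ``j`` itself,
    truncated at region boundaries and restricted to defined positions.
    """
    config = config or CallerConfig()
    K = _resolve_K(track, config)
    idx = int(j - track.positions[0])
    n = track.positions.shape[0]
    if not 0 <= idx < n:
        raise DegenerateBackgroundError(j, 0)
    lo, hi = max(0, idx - K), min(n, idx + K + 1)
    window = np.r_[track.d[lo:idx], track.d[idx + 1 : hi]]
    window = window[~np.isnan(window)]
    if window.size < 2:
        raise DegenerateBackgroundError(j, int(window.size))
    return BackgroundModel(
        position=j,
        K=K,
        mu=float(window.mean()),
        sigma=float(window.std(ddof=config.sd_ddof)),
        n_window=int(window.size),
    )


def _upper_tail_p(d: float, mu: float, sigma: float) -> float:
    """``P(X > d)`` for ``X ~ N(mu, sigma^2)``; a point mass when sigma=0."""
    if sigma > 0:
        return float(norm.sf((d - mu) / sigma))
    return 0.0 if d > mu else 1.0


def test_position(
    track: DifferenceTrack,
    background: BackgroundModel,
    lesion: VafProfile,
    control: VafProfile,
    j: int,
    config: CallerConfig | None = None,
    *,
    chrom: str = ".",
    n_tests: int = 1,
) -> SomaticCall:
    """Evaluate the three-part somatic call at genomic position ``j``.

    The tested allele is the argmax allele of the difference track at
    ``j``; the control gate checks every non-reference allele.
    """
    config = config or CallerConfig()
    idx = int(j - track.positions[0])
    if not track.defined[idx] or np.isnan(track.d[idx]):
        raise DegenerateBackgroundError(j, 0)
    d = float(track.d[idx])
    p = _upper_tail_p(d, background.mu, background.sigma)
    alpha = config.alpha / n_tests if config.bonferroni else config.alpha
    ai = int(track.alt_index[idx])
    ref = str(lesion.ref[idx])
    alt = ALLELES[ai]
    nonref = [k for k, a in enumerate(ALLELES) if a != ref]
    control_nonref = control.vaf[idx, nonref]
    p_pass = p < alpha
    d_pass = d > config.d_min
    control_pass = bool(np.all(control_nonref < config.control_vaf_max))
    return SomaticCall(
        chrom=chrom,
        pos=int(j),
        ref=ref,
        alt=alt,
        d=d,
        mu=background.mu,
        sigma=background.sigma,
        p_value=p,
        lesion_vaf=float(lesion.vaf[idx, ai]),
        control_vaf=float(control.vaf[idx, ai]),
        p_pass=p_pass,
        d_pass=d_pass,
        control_pass=control_pass,
        verdict=p_pass and d_pass and control_pass,
    )


def _window_stats(
    d: np.ndarray, defined: np.ndarray, K: int, ddof: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised leave-one-out window mean/SD with boundary truncation.

    Returns (mu, sigma, n_window) arrays over all positions; NaN where the
    window holds fewer than two defined values.
    """
    n = d.shape[0]
    x = np.where(defined, d, 0.0)
    c = defined.astype(np.int64)
    S = np.concatenate([[0.0], np.cumsum(x)])
    Q = np.concatenate([[0.0], np.cumsum(x * x)])
    C = np.concatenate([[0], np.cumsum(c)])
    idx = np.arange(n)
    lo = np.maximum(0, idx - K)
    hi = np.minimum(n, idx + K + 1)
    wsum = S[hi] - S[lo] - x
    wsq = Q[hi] - Q[lo] - x * x
    wcnt = C[hi] - C[lo] - c
    mu = np.full(n, np.nan)
    sigma = np.full(n, np.nan)
    ok = wcnt >= 2
    mu[ok] = wsum[ok] / wcnt[ok]
    var = np.maximum(wsq[ok] / wcnt[ok] - mu[ok] ** 2, 0.0)
    if ddof:
        var = var * wcnt[ok] / (wcnt[ok] - ddof)
    sigma[ok] = np.sqrt(var)
    return mu, sigma, wcnt


def call_region(
    lesion: AlleleCounts,
    control: AlleleCounts,
    target: TargetRegion,
    config: CallerConfig | None = None,
    positions: Sequence[int] | None = None,
) -> list[SomaticCall]:
    """Run the background-noise test over a target region.

    ``positions`` optionally restricts testing to a candidate list
    (genomic coordinates); by default every defined position is tested.
    Deterministic for fixed input.
    """
    return TdsNoiseModel(lesion, control, target, config).fit(positions).calls


class TdsNoiseModel:
    """Position-local noise model for one lesion/control amplicon pair.

    Parameters
    ----------
    lesion, control : AlleleCounts
        Read counts for the lesion sample and its matched control over the
        same contiguous positions.
    target : TargetRegion
        The amplicon; supplies the chromosome and bounds the tested
        positions.
    config : CallerConfig, optional
    """

    def __init__(
        self,
        lesion: AlleleCounts,
        control: AlleleCounts,
        target: TargetRegion,
        config: CallerConfig | None = None,
    ):
        self.config = config or CallerConfig()
        self.target = target
        self.lesion_vaf = compute_vaf(lesion)
        self.control_vaf = compute_vaf(control)
        self.track = difference_track(self.lesion_vaf, self.control_vaf)
        inside = (self.track.positions >= target.start) & (
            self.track.positions < target.end
        )
        if not np.any(inside & self.track.defined):
            raise RegionMismatchError(
                f"no defined overlap between samples and target {target.region_id!r}"
            )
        self._inside = inside

    def fit(self, positions: Sequence[int] | None = None) -> "TdsCallResults":
        """Fit the windowed background and test positions.

        Returns a :class:`TdsCallResults`; positions whose background is
        degenerate (fewer than two defined window values) are skipped.
        """
        cfg = self.config
        track = self.track
        K = _resolve_K(track, cfg)
        mu, sigma, n_window = _window_stats(track.d, track.defined, K, cfg.sd_ddof)
        if positions is None:
            test_idx = np.flatnonzero(self._inside & track.defined)
        else:
            wanted = np.asarray(sorted(set(int(p) for p in positions)))
            offs = wanted - track.positions[0]
            ok = (offs >= 0) & (offs < track.positions.shape[0])
            offs = offs[ok]
            test_idx = offs[track.defined[offs]]
        n_tests = int(test_idx.size) if cfg.bonferroni else 1
        calls: list[SomaticCall] = []
        for idx in test_idx:
            if n_window[idx] < 2:
                continue
            bg = BackgroundModel(
                position=int(track.positions[idx]),
                K=K,
                mu=float(mu[idx]),
                sigma=float(sigma[idx]),
                n_window=int(n_window[idx]),
            )
            calls.append(
                test_position(
                    track,
                    bg,
                    self.lesion_vaf,
                    self.control_vaf,
                    int(track.positions[idx]),
                    cfg,
                    chrom=self.target.chrom,
                    n_tests=max(n_tests, 1),
                )
            )
        return TdsCallResults(self, calls)


class TdsCallResults:
    """Fit results: the per-position calls plus diagnostics.

    Attributes
    ----------
    calls : list of SomaticCall
    model : TdsNoiseModel
    """

    def __init__(self, model: TdsNoiseModel, calls: list[SomaticCall]):
        self.model = model
        self.calls = calls

    @property
    def somatic(self) -> list[SomaticCall]:
        """Calls with verdict true."""
        return [c for c in self.calls if c.verdict]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(c) for c in self.calls])

    def to_vcf(self, path) -> None:
        from .pileup import write_calls

        write_calls(self.calls, path)

    def summary(self) -> str:
        """Human-readable account of the fit and the passing calls."""
        cfg = self.model.config
        lines = [
            "TDS position-local noise model",
            "==============================",
            f"region:           {self.model.target.region_id} "
            f"({self.model.target.chrom}:{self.model.target.start}-{self.model.target.end})",
            f"lesion sample:    {self.model.lesion_vaf.sample_id}",
            f"control sample:   {self.model.control_vaf.sample_id}",
            f"positions tested: {len(self.calls)}",
            f"alpha={cfg.alpha}  d_min={cfg.d_min}  control_vaf_max={cfg.control_vaf_max}"
            f"  K={_resolve_K(self.model.track, cfg)}  sd_ddof={cfg.sd_ddof}",
            "",
            f"somatic calls (verdict true): {len(self.somatic)}",
        ]
        if self.somatic:
            frame = pd.DataFrame(
                [
                    {
                        "pos": c.pos,
                        "ref": c.ref,
                        "alt": c.alt,
                        "lesion_vaf": round(c.lesion_vaf, 6),
                        "control_vaf": round(c.control_vaf, 6),
                        "d_j": round(c.d, 6),
                        "mu_j": round(c.mu, 6),
                        "sigma_j": round(c.sigma, 6),
                        "p": format(c.p_value, ".3g"),
                    }
                    for c in self.somatic
                ]
            )
            lines.append(frame.to_string(index=False))
        return "\n".join(lines)
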