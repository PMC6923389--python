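"""Seeded generators for every input the pipeline consumes.

The generators emulate ultra-deep amplicon sequencing of benign uterine
lesions: ~250 bp target regions at depth 10^3-10^5 with position-specific
substitution error, somatic clones spiked at VAF 0.1-20%, multi-region
clone-sharing structure across adenomyosis / endometriosis / normal
tissues, negative-control panels of normal endometrium, bisulfite reads
with per-CpG methylation probabilities, and Table-1-style cohort
metadata.  Every generator is a pure function of its parameters and seed,
and each emits ground truth sufficient to score the downstream inference.

Error model
-----------
Per-sample, per-position, per-substitution error rates are drawn from a
beta distribution matched to the negative-panel scale observed in normal
endometrium (mean 0.065%, SD 0.09%, capped at 1%), so null VAF-difference
tracks have magnitudes of roughly 0.03-0.3%.  Rates are drawn
independently for each sample, which makes the null difference track
exchangeable across positions — the structure the windowed background
model assumes — and makes the amplicon and negative-panel generators one
consistent model.

Clone convention
----------------
Somatic variants are heterozygous in diploid cells, so a clone at cell
fraction ``f`` contributes VAF ``purity * f / 2``; the purity factor
emulates the bulk-versus-microdissected contrast (epithelial content of a
bulk lesion is low, so bulk VAFs are small even for sizeable clones).
"""

from __future__ import annotations

import dataclasses
import zlib
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .clonality import LESION_CLASSES, SampleMeta
from .hotspots import HotspotDef
from .methylation import BisulfiteCounts, MethylationProfile, methylation_frequency
from .pileup import ALLELE_INDEX, ALLELES, AlleleCounts, TargetRegion


@dataclasses.dataclass(frozen=True)
class ErrorProfile:
    """Beta law for per-sample, per-position substitution error rates.

    ``beta_mean`` / ``beta_sd`` parameterise the beta distribution by
    moments; ``rate_cap`` truncates pathological draws (all rates stay in
    ``[0, rate_cap]``).  Defaults match the negative-panel noise scale in
    normal endometrium.
    """

    beta_mean: float = 6.5e-4
    beta_sd: float = 9.0e-4
    rate_cap: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.beta_mean < 1:
            raise ValueError("beta_mean must be in (0, 1)")
        if self.beta_sd <= 0:
            raise ValueError("beta_sd must be > 0")
        if self.beta_sd**2 >= self.beta_mean * (1 - self.beta_mean):
            raise ValueError("beta_sd too large for a valid beta distribution")
        if not 0 < self.rate_cap <= 1:
            raise ValueError("rate_cap must be in (0, 1]")

    @property
    def beta_params(self) -> tuple[float, float]:
        m, s = self.beta_mean, self.beta_sd
        nu = m * (1 - m) / s**2 - 1
        return m * nu, (1 - m) * nu

    def draw_rates(self, rng: np.random.Generator, shape) -> np.ndarray:
        a, b = self.beta_params
        return np.clip(rng.beta(a, b, size=shape), 0.0, self.rate_cap)


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def reference_for_region(region: TargetRegion) -> np.ndarray:
    """Deterministic synthetic reference sequence for a target region.

    Derived from a CRC32 of the region id so every sample of a patient
    (and every run) sees the same reference.
    """
    seed = zlib.crc32(region.region_id.encode())
    rng = np.random.default_rng(seed)
    return rng.choice(np.array(ALLELES), size=len(region))


def simulate_amplicon(
    region: TargetRegion,
    depth: int,
    error_profile: ErrorProfile | None = None,
    spikes: Sequence[tuple[int, str, float]] = (),
    seed: int | np.random.Generator | None = 0,
    *,
    sample_id: str = "sim",
    ref: np.ndarray | None = None,
    rates: np.ndarray | None = None,
) -> AlleleCounts:
    """Simulate one sample's amplicon pileup.

    ``spikes`` is a list of ``(genomic_pos, alt_allele, vaf)`` somatic
    signals added on top of the error process.  Per position the four
    allele counts are one multinomial draw of size ``depth``
    (reference probability ``1 - sum(errors) - sum(spikes)``), then each
    allele count splits into strands with a fair binomial.  ``rates``
    optionally overrides the drawn ``(n_positions, 3)`` error-rate matrix
    (e.g. to share rates between samples in sensitivity studies).
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    profile = error_profile or ErrorProfile()
    rng = _as_rng(seed)
    n = len(region)
    if ref is None:
        ref = reference_for_region(region)
    ref = np.asarray(ref, dtype="<U1")
    ref_idx = np.array([ALLELE_INDEX[r] for r in ref])
    if rates is None:
        rates = profile.draw_rates(rng, (n, 3))
    probs = np.zeros((n, 4))
    for i in range(n):
        alts = [k for k in range(4) if k != ref_idx[i]]
        probs[i, alts] = rates[i]
    for pos, alt, vaf in spikes:
        if not region.contains(pos):
            raise ValueError(
                f"spike at {pos} outside region {region.region_id!r} "
                f"[{region.start}, {region.end})"
            )
        if not 0 <= vaf <= 1:
            raise ValueError(f"spike VAF {vaf} outside [0, 1]")
        i = pos - region.start
        ai = ALLELE_INDEX[alt]
        if ai == ref_idx[i]:
            raise ValueError(f"spike allele {alt} equals reference at {pos}")
        probs[i, ai] += vaf
    ref_prob = 1.0 - probs.sum(axis=1)
    if np.any(ref_prob < 0):
        raise ValueError("error rates plus spikes exceed 1 at some position")
    probs[np.arange(n), ref_idx] = ref_prob
    pooled = rng.multinomial(depth, probs)
    fwd = rng.binomial(pooled, 0.5)
    counts = np.stack([fwd, pooled - fwd], axis=2)
    return AlleleCounts(
        sample_id=sample_id,
        region_id=region.region_id,
        positions=np.arange(region.start, region.end),
        ref=ref,
        counts=counts,
    )


# ---------------------------------------------------------------------------
# Multi-region patients


@dataclasses.dataclass(frozen=True)
class CloneSpec:
    """One mutant clone: its mutations and per-sample cell fractions.

    ``mutations`` is a tuple of ``(region_id, genomic_pos, alt_allele)``;
    ``fractions`` maps sample ids to the clone's cell fraction there
    (samples not listed carry fraction 0).
    """

    clone_id: str
    mutations: tuple[tuple[str, int, str], ...]
    fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        for sid, f in self.fractions.items():
            if not 0 <= f <= 1:
                raise ValueError(
                    f"clone {self.clone_id!r}: fraction {f} for {sid!r} outside [0, 1]"
                )


@dataclasses.dataclass
class PatientSimulation:
    """Paired data and ground truth for one simulated patient."""

    patient_id: str
    meta: list[SampleMeta]
    targets: list[TargetRegion]
    clones: list[CloneSpec]
    counts: dict[str, dict[str, AlleleCounts]]  # sample -> region -> counts
    truth: pd.DataFrame
    control_sample_id: str
    purity: float


def _truth_sharing(
    true_vaf: pd.DataFrame, meta: Sequence[SampleMeta]
) -> pd.DataFrame:
    """Sharing classes from the generator's own bookkeeping.

    Restates the count-based definitions directly on true clone placement
    (every sample assayed, presence = true VAF > 0) so downstream
    classification can be scored against an independent truth.
    """
    by_class: dict[str, list[str]] = {}
    for m in meta:
        by_class.setdefault(m.tissue_class, []).append(m.sample_id)
    counts = {cls: len(by_class.get(cls, [])) for cls in LESION_CLASSES}
    dominant = max(LESION_CLASSES, key=lambda cls: counts[cls])
    dom_ids = by_class.get(dominant, [])
    lesion_ids = [
        sid for cls in LESION_CLASSES for sid in by_class.get(cls, [])
    ]
    non_blood = [
        m.sample_id for m in meta if m.tissue_class != "blood"
    ]
    rows = []
    for label in true_vaf.index:
        pres = true_vaf.loc[label] > 0
        n_lesion = int(pres[lesion_ids].sum())
        basis = n_lesion if n_lesion > 0 else int(pres[non_blood].sum())
        if len(dom_ids) >= 2 and all(pres[sid] for sid in dom_ids):
            cls = "ubiquitous"
        elif basis > 1:
            cls = "restricted"
        else:
            cls = "private"
        rows.append(
            {
                "sharing_class": cls,
                "cross_lesion_shared": bool(
                    pres[by_class.get("adenomyosis", [])].any()
                    and pres[by_class.get("endometriosis", [])].any()
                ),
                "normal_shared": bool(
                    pres[by_class.get("normal_endometrium", [])].any()
                ),
            }
        )
    return pd.DataFrame(rows, index=true_vaf.index)


def simulate_patient(
    clones: Sequence[CloneSpec],
    meta: Sequence[SampleMeta],
    targets: Sequence[TargetRegion],
    *,
    depth: int = 10_000,
    error_profile: ErrorProfile | None = None,
    purity: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> PatientSimulation:
    """Simulate a multi-region patient plus its ground-truth matrix.

    Every sample (including normal tissues and the blood germline
    control, which is always drawn null) is simulated over every target;
    a clone at cell fraction ``f`` adds VAF ``purity * f / 2`` at each of
    its mutation sites.  The returned truth table carries the expected
    VAF per (mutation, sample) and the generator's sharing classes.
    """
    rng = _as_rng(seed)
    metas = list(meta)
    targets = list(targets)
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    patients = {m.patient_id for m in metas}
    if len(patients) != 1:
        raise ValueError("meta spans multiple patients")
    blood = [m.sample_id for m in metas if m.tissue_class == "blood"]
    if len(blood) != 1:
        raise ValueError("exactly one blood (germline control) sample required")
    region_by_id = {t.region_id: t for t in targets}
    refs = {t.region_id: reference_for_region(t) for t in targets}

    # Aggregate spike VAFs per (sample, region): clones may share mutations.
    mutation_keys: list[tuple[str, int, str]] = []
    for clone in clones:
        for site in clone.mutations:
            if site[0] not in region_by_id:
                raise ValueError(f"clone {clone.clone_id!r}: unknown region {site[0]!r}")
            if site not in mutation_keys:
                mutation_keys.append(site)
    spikes: dict[str, dict[str, dict[tuple[int, str], float]]] = {
        m.sample_id: {t.region_id: {} for t in targets} for m in metas
    }
    for clone in clones:
        for sid, f in clone.fractions.items():
            if sid not in spikes:
                raise ValueError(
                    f"clone {clone.clone_id!r}: unknown sample {sid!r}"
                )
            for region_id, pos, alt in clone.mutations:
                cell = spikes[sid][region_id]
                cell[(pos, alt)] = cell.get((pos, alt), 0.0) + purity * f / 2.0

    counts: dict[str, dict[str, AlleleCounts]] = {}
    for m in metas:  # deterministic iteration order drives the rng stream
        counts[m.sample_id] = {}
        for t in targets:
            spike_list = [
                (pos, alt, vaf)
                for (pos, alt), vaf in sorted(spikes[m.sample_id][t.region_id].items())
            ]
            counts[m.sample_id][t.region_id] = simulate_amplicon(
                t,
                depth,
                error_profile,
                spike_list,
                rng,
                sample_id=m.sample_id,
                ref=refs[t.region_id],
            )

    labels = []
    truth_rows = []
    sample_ids = [m.sample_id for m in metas]
    for region_id, pos, alt in mutation_keys:
        ref = refs[region_id][pos - region_by_id[region_id].start]
        label = f"{region_by_id[region_id].chrom}:{pos}:{ref}>{alt}"
        labels.append(label)
        row = {
            "region_id": region_id,
            "chrom": region_by_id[region_id].chrom,
            "pos": pos,
            "ref": ref,
            "alt": alt,
        }
        for sid in sample_ids:
            row[sid] = spikes[sid][region_id].get((pos, alt), 0.0)
        truth_rows.append(row)
    truth = pd.DataFrame(truth_rows, index=labels)
    sharing = _truth_sharing(truth[sample_ids], metas)
    truth = truth.join(sharing)
    return PatientSimulation(
        patient_id=next(iter(patients)),
        meta=metas,
        targets=targets,
        clones=list(clones),
        counts=counts,
        truth=truth,
        control_sample_id=blood[0],
        purity=purity,
    )


def _alt_for(ref: str) -> str:
    """Deterministic non-reference allele (next base cyclically)."""
    return ALLELES[(ALLELE_INDEX[ref] + 1) % 4]


def default_multiregion_design(
    *,
    patient_id: str = "P1",
    depth: int = 10_000,
    error_profile: ErrorProfile | None = None,
    purity: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> PatientSimulation:
    """The package's reference multi-region study design.

    Six adenomyosis regions plus one endometriosis lesion, normal
    endometrium, normal myometrium and a blood germline control, assayed
    over two 250 bp amplicons.  Five clones cover the sharing spectrum —
    a trunk clone in all six regions (VAF 8%), a restricted subclone in
    regions 1-3 (5%), a private subclone in region 2 (2.5%, the lowest
    lesion VAF observed in the study's cohort), a cross-lesion clone
    shared between regions 4-5 and the endometriosis sample (4%), and a
    clone shared with normal endometrium (3%).
    """
    targets = [
        TargetRegion("AMP1", "chr12", 1000, 1250),
        TargetRegion("AMP2", "chr3", 2000, 2250),
    ]
    meta = [
        SampleMeta(f"A{i}", patient_id, "adenomyosis", str(i)) for i in range(1, 7)
    ] + [
        SampleMeta("EN1", patient_id, "endometriosis", "EN"),
        SampleMeta("NE1", patient_id, "normal_endometrium", "NE"),
        SampleMeta("NM1", patient_id, "normal_myometrium", "NM"),
        SampleMeta("B", patient_id, "blood", "B"),
    ]
    refs = {t.region_id: reference_for_region(t) for t in targets}

    def site(region_id: str, pos: int) -> tuple[str, int, str]:
        t = next(t for t in targets if t.region_id == region_id)
        return (region_id, pos, _alt_for(refs[region_id][pos - t.start]))

    adeno = [f"A{i}" for i in range(1, 7)]
    clones = [
        CloneSpec("trunk", (site("AMP1", 1100),), {s: 0.16 for s in adeno}),
        CloneSpec(
            "restricted", (site("AMP1", 1180),), {s: 0.10 for s in adeno[:3]}
        ),
        CloneSpec("private", (site("AMP2", 2050),), {"A2": 0.05}),
        CloneSpec(
            "cross_lesion",
            (site("AMP2", 2120),),
            {"A4": 0.08, "A5": 0.08, "EN1": 0.08},
        ),
        CloneSpec(
            "normal_shared",
            (site("AMP1", 1210),),
            {"A1": 0.06, "A2": 0.06, "NE1": 0.06},
        ),
    ]
    return simulate_patient(
        clones,
        meta,
        targets,
        depth=depth,
        error_profile=error_profile,
        purity=purity,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Negative panels


def simulate_negative_panel(
    n_samples: int,
    hotspots: Sequence[HotspotDef],
    error_profile: ErrorProfile | None = None,
    seed: int | np.random.Generator = 0,
    *,
    depth: int = 10_000,
) -> pd.DataFrame:
    """Null per-hotspot VAF table for a negative-control sample panel.

    Each (sample, hotspot site) draws its own error rate from the beta
    law and an observed VAF from a binomial at ``depth``; the class-level
    VAF is the maximum over the hotspot's sites.  Output is in percent,
    ready for cutoff estimation.
    """
    if n_samples < 2:
        raise ValueError("panel needs >= 2 samples")
    profile = error_profile or ErrorProfile()
    rng = _as_rng(seed)
    rows = []
    for i in range(n_samples):
        sid = f"NE{i + 1:02d}"
        for hs in hotspots:
            rates = profile.draw_rates(rng, len(hs.sites))
            obs = rng.binomial(depth, rates) / depth
            rows.append(
                {
                    "sample_id": sid,
                    "hotspot_id": hs.hotspot_id,
                    "vaf_percent": float(obs.max()) * 100.0,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bisulfite reads


def simulate_bisulfite(
    meth_probs: Sequence[float],
    depth: int,
    conversion_rate: float = 1.0,
    seed: int | np.random.Generator = 0,
    *,
    sample_id: str = "sim",
    amplicon_id: str = "PR-A",
    other_rate: float = 0.002,
    n_noncpg_reads: int = 10_000,
) -> BisulfiteCounts:
    """Binomial bisulfite counts for one sample over an amplicon.

    A truly methylated cytosine always reads C; an unmethylated one reads
    T with probability ``conversion_rate`` and C otherwise, so incomplete
    conversion inflates apparent methylation by
    ``(1 - p) * (1 - conversion_rate)``.  ``other_rate`` sends a small
    fraction of reads to non-C/T states (excluded from callable).
    Non-CpG cytosine counts for conversion QC are drawn at the same
    conversion rate.
    """
    probs = np.asarray(meth_probs, dtype=float)
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("methylation probabilities must be in [0, 1]")
    if not 0 <= conversion_rate <= 1:
        raise ValueError("conversion_rate must be in [0, 1]")
    rng = _as_rng(seed)
    n = probs.shape[0]
    other = rng.binomial(depth, other_rate, size=n)
    call = depth - other
    apparent = probs + (1 - probs) * (1 - conversion_rate)
    meth = rng.binomial(call, apparent)
    unmeth = call - meth
    converted = int(rng.binomial(n_noncpg_reads, conversion_rate))
    return BisulfiteCounts(
        sample_id=sample_id,
        amplicon_id=amplicon_id,
        cpg_index=np.arange(n),
        methylated=meth,
        unmethylated=unmeth,
        other=other,
        noncpg_converted=converted,
        noncpg_unconverted=n_noncpg_reads - converted,
    )


def simulate_methylation_cohort(
    *,
    n_wt: int = 20,
    n_mut: int = 11,
    mean_wt: float = 0.05,
    mean_mut: float = 0.5,
    concentration: float = 30.0,
    n_cpgs: int = 20,
    depth: int = 1_000,
    conversion_rate: float = 0.995,
    amplicon_id: str = "PR-B",
    seed: int | np.random.Generator = 0,
) -> tuple[list[MethylationProfile], list[MethylationProfile]]:
    """Two-group promoter-methylation design (wild-type vs mutant).

    Defaults mirror the study's bisulfite contrast: 20 mutation-wild-type
    versus 11 mutation-carrying samples, low promoter methylation in the
    wild-type group and high methylation in the mutant group.  Per-sample
    per-CpG probabilities draw from a beta around the group mean
    (``concentration`` controls biological spread).  Returns
    ``(wt_profiles, mut_profiles)``.
    """
    rng = _as_rng(seed)

    def group(n: int, mean: float, label: str) -> list[MethylationProfile]:
        a, b = mean * concentration, (1 - mean) * concentration
        out = []
        for i in range(n):
            probs = rng.beta(a, b, size=n_cpgs)
            counts = simulate_bisulfite(
                probs,
                depth,
                conversion_rate,
                rng,
                sample_id=f"{label}{i + 1:02d}",
                amplicon_id=amplicon_id,
            )
            out.append(methylation_frequency(counts, group=label))
        return out

    return group(n_wt, mean_wt, "WT"), group(n_mut, mean_mut, "MUT")


# ---------------------------------------------------------------------------
# Cohort metadata

#: Characteristic prevalences (P(char | wild-type), P(char | mutated))
#: mirroring the study cohort's Table-1-style rates.
DEFAULT_CHAR_PROBS: Mapping[str, tuple[float, float]] = {
    "dng_pretreated": (2 / 44, 11 / 26),
    "en_ov": (12 / 44, 18 / 26),
    "en_di": (9 / 44, 12 / 26),
}


def simulate_cohort_metadata(
    n_patients: int = 70,
    char_probs: Mapping[str, tuple[float, float]] | None = None,
    seed: int | np.random.Generator = 0,
    *,
    p_mutated: float = 26 / 70,
    status_column: str = "kras_mutated",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Patient metadata table with known characteristic-status associations.

    Each patient's mutation status is Bernoulli(``p_mutated``); each
    boolean characteristic is Bernoulli with a status-conditional
    probability.  Returns the table (consumable by
    :func:`adenoclone.stats.table1_battery`) and the generating odds
    ratios.
    """
    rng = _as_rng(seed)
    probs = dict(char_probs if char_probs is not None else DEFAULT_CHAR_PROBS)
    status = rng.random(n_patients) < p_mutated
    data = {
        "patient_id": [f"PT{i + 1:03d}" for i in range(n_patients)],
        status_column: status,
    }
    true_or = {}
    for name, (p_wt, p_mut) in probs.items():
        p = np.where(status, p_mut, p_wt)
        data[name] = rng.random(n_patients) < p
        if 0 < p_wt < 1 and 0 < p_mut < 1:
            true_or[name] = (p_mut / (1 - p_mut)) / (p_wt / (1 - p_wt))
        else:
            true_or[name] = float("nan")
    return pd.DataFrame(data), true_or
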