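"""Multi-region mutation sharing and clonality analysis.

Multi-regional sampling of a lesion (e.g. six adenomyosis regions plus
adjacent normal myometrium/endometrium, co-existing endometriosis or
leiomyoma, and a blood germline reference) yields a mutations x samples
VAF matrix.  Classifying how each mutation is shared across regions
reveals the clonal structure: mutations present in (almost) all regions
were acquired early (trunk), mutations present in a subset mark
subclones, and mutations shared across distinct lesion types or with
histologically normal endometrium point to a common cellular origin.

Sharing classes (count-based, mutually exclusive):

* ``ubiquitous`` — present in every assayed sample of the dominant lesion
  tissue class (requires at least two such samples);
* ``restricted`` — present in more than one lesion sample but not all;
* ``private``    — present in exactly one sample.

Two orthogonal flags sit on top of the count-based class:
``cross_lesion_shared`` (present in at least one adenomyosis AND one
endometriosis sample) and ``normal_shared`` (present in normal
endometrium).  Blood columns are carried for display but excluded from
all sharing computations.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

TISSUE_CLASSES = (
    "adenomyosis",
    "endometriosis",
    "leiomyoma",
    "normal_endometrium",
    "normal_myometrium",
    "blood",
)
LESION_CLASSES = ("adenomyosis", "endometriosis", "leiomyoma")

SHARING_UBIQUITOUS = "ubiquitous"
SHARING_RESTRICTED = "restricted"
SHARING_PRIVATE = "private"

#: Default absolute VAF floor for calling a matrix cell "present".
PRESENCE_VAF_MIN = 0.01


@dataclasses.dataclass(frozen=True)
class SampleMeta:
    """Identity and tissue class of one multi-region sample."""

    sample_id: str
    patient_id: str
    tissue_class: str
    region_label: str | None = None

    def __post_init__(self) -> None:
        if self.tissue_class not in TISSUE_CLASSES:
            raise ValueError(
                f"sample {self.sample_id!r}: unknown tissue class "
                f"{self.tissue_class!r}; expected one of {TISSUE_CLASSES}"
            )


MutationKey = tuple[str, int, str, str]  # chrom, pos, ref, alt


@dataclasses.dataclass
class MultiRegionMatrix:
    """Mutations x samples VAF matrix with presence booleans.

    ``vaf`` and ``present`` are DataFrames indexed by mutation key rows
    (``chrom:pos:ref>alt`` strings) with sample-id columns; cells that a
    sample did not assay are NaN in ``vaf`` and False in ``present`` with
    ``assayed`` False.  ``sharing`` is populated by
    :func:`classify_sharing`.
    """

    patient_id: str
    samples: list[SampleMeta]
    mutations: pd.DataFrame  # chrom, pos, ref, alt (+ optional gene)
    vaf: pd.DataFrame
    present: pd.DataFrame
    assayed: pd.DataFrame
    sharing: pd.DataFrame | None = None

    def meta_by_id(self) -> dict[str, SampleMeta]:
        return {m.sample_id: m for m in self.samples}

    def non_blood_samples(self) -> list[str]:
        return [m.sample_id for m in self.samples if m.tissue_class != "blood"]

    def samples_of_class(self, tissue_class: str) -> list[str]:
        return [
            m.sample_id for m in self.samples if m.tissue_class == tissue_class
        ]


def _mutation_label(key: MutationKey) -> str:
    chrom, pos, ref, alt = key
    return f"{chrom}:{pos}:{ref}>{alt}"


def build_matrix(
    calls_by_sample: Mapping[str, Sequence],
    meta: Sequence[SampleMeta],
    *,
    presence_vaf_min: float = PRESENCE_VAF_MIN,
    require_verdict: bool = True,
) -> MultiRegionMatrix:
    """Assemble the mutations x samples matrix from per-sample calls.

    ``calls_by_sample`` maps sample ids to call lists (objects with
    ``chrom``/``pos``/``ref``/``alt``/``lesion_vaf``/``verdict``
    attributes, e.g. :class:`~adenoclone.caller.SomaticCall`).  The row
    set is the union of verdict-true, presence-eligible mutations across
    non-blood samples; VAF is looked up per sample (0 when the sample
    assayed the site without a qualifying call, NaN when not assayed).

    A cell is *present* when the sample's call at the site has a true
    verdict (if ``require_verdict``) and lesion VAF at or above
    ``presence_vaf_min``.  The default rule mirrors how the package's
    display matrices are built: statistical support plus a VAF floor.
    """
    metas = list(meta)
    patients = {m.patient_id for m in metas}
    if len(patients) != 1:
        raise ValueError(f"samples from multiple patients: {sorted(patients)}")
    patient_id = next(iter(patients))
    known = {m.sample_id for m in metas}
    unknown = set(calls_by_sample) - known
    if unknown:
        raise ValueError(f"calls for samples without metadata: {sorted(unknown)}")
    non_blood = [m for m in metas if m.tissue_class != "blood"]
    if len(non_blood) < 2:
        raise ValueError("need >= 2 non-blood samples for a multi-region matrix")

    def is_present(call) -> bool:
        ok = call.verdict if require_verdict else True
        return bool(ok and call.lesion_vaf >= presence_vaf_min)

    # Row set: union of present mutations over non-blood samples.
    keys: list[MutationKey] = []
    seen = set()
    non_blood_ids = {m.sample_id for m in non_blood}
    for sid, calls in calls_by_sample.items():
        if sid not in non_blood_ids:
            continue
        for call in calls:
            key = (call.chrom, call.pos, call.ref, call.alt)
            if is_present(call) and key not in seen:
                seen.add(key)
                keys.append(key)
    if not keys:
        raise ValueError("no present mutations across non-blood samples")
    keys.sort(key=lambda k: (k[0], k[1], k[3]))
    labels = [_mutation_label(k) for k in keys]
    sample_ids = [m.sample_id for m in metas]

    vaf = pd.DataFrame(np.nan, index=labels, columns=sample_ids)
    present = pd.DataFrame(False, index=labels, columns=sample_ids)
    assayed = pd.DataFrame(False, index=labels, columns=sample_ids)
    for sid in sample_ids:
        calls = calls_by_sample.get(sid, [])
        by_site = {}
        for call in calls:
            by_site[(call.chrom, call.pos, call.ref, call.alt)] = call
        # A sample assayed a site if it tested the position at all.
        positions_tested = {(c.chrom, c.pos) for c in calls}
        for label, key in zip(labels, keys):
            call = by_site.get(key)
            if call is not None:
                assayed.loc[label, sid] = True
                vaf.loc[label, sid] = call.lesion_vaf
                present.loc[label, sid] = is_present(call)
            elif (key[0], key[1]) in positions_tested:
                # Position covered but a different allele maximised there:
                # covered, absent.
                assayed.loc[label, sid] = True
                vaf.loc[label, sid] = 0.0
    mutations = pd.DataFrame(
        [{"chrom": c, "pos": p, "ref": r, "alt": a} for c, p, r, a in keys],
        index=labels,
    )
    return MultiRegionMatrix(
        patient_id=patient_id,
        samples=metas,
        mutations=mutations,
        vaf=vaf,
        present=present,
        assayed=assayed,
    )


def dominant_lesion_class(matrix: MultiRegionMatrix) -> str:
    """Lesion tissue class with the most samples (ties favour the order
    adenomyosis > endometriosis > leiomyoma)."""
    counts = {
        cls: len(matrix.samples_of_class(cls)) for cls in LESION_CLASSES
    }
    best = max(counts.values())
    if best == 0:
        raise ValueError("matrix holds no lesion-class samples")
    for cls in LESION_CLASSES:
        if counts[cls] == best:
            return cls


def classify_sharing(matrix: MultiRegionMatrix) -> pd.DataFrame:
    """Assign each mutation a sharing class plus cross-lesion/normal flags.

    Blood samples never count.  ``ubiquitous`` means present in every
    assayed sample of the dominant lesion class (at least two); the
    restricted/private levels count presence across all lesion samples
    (falling back to all non-blood samples for mutations seen only in
    normal tissue).  The result is stored on ``matrix.sharing`` and
    returned.
    """
    if matrix.present.shape[0] == 0:
        raise ValueError("empty matrix")
    meta = matrix.meta_by_id()
    dom = dominant_lesion_class(matrix)
    dom_ids = matrix.samples_of_class(dom)
    lesion_ids = [
        sid
        for sid in matrix.non_blood_samples()
        if meta[sid].tissue_class in LESION_CLASSES
    ]
    adeno_ids = matrix.samples_of_class("adenomyosis")
    endo_ids = matrix.samples_of_class("endometriosis")
    ne_ids = matrix.samples_of_class("normal_endometrium")

    rows = []
    for label in matrix.present.index:
        pres = matrix.present.loc[label]
        assay = matrix.assayed.loc[label]
        n_lesion = int(pres[lesion_ids].sum())
        basis = n_lesion if n_lesion > 0 else int(
            pres[matrix.non_blood_samples()].sum()
        )
        dom_assayed = [sid for sid in dom_ids if assay[sid]]
        ubiquitous = (
            len(dom_assayed) >= 2 and all(pres[sid] for sid in dom_assayed)
        )
        if ubiquitous:
            cls = SHARING_UBIQUITOUS
        elif basis > 1:
            cls = SHARING_RESTRICTED
        else:
            cls = SHARING_PRIVATE
        rows.append(
            {
                "sharing_class": cls,
                "n_present": int(pres[matrix.non_blood_samples()].sum()),
                "cross_lesion_shared": bool(
                    pres[adeno_ids].any() and pres[endo_ids].any()
                ),
                "normal_shared": bool(pres[ne_ids].any()),
            }
        )
    sharing = pd.DataFrame(rows, index=matrix.present.index)
    matrix.sharing = sharing
    return sharing


def mutual_exclusivity(
    matrix: MultiRegionMatrix, tissue_class_a: str, tissue_class_b: str
) -> tuple[float, list[str]]:
    """Fraction of mutations present in both tissue classes.

    Returns ``|shared| / |union|`` together with the shared mutation
    labels; 0.0 for disjoint mutation sets, 1.0 for identical ones.
    """
    ids_a = matrix.samples_of_class(tissue_class_a)
    ids_b = matrix.samples_of_class(tissue_class_b)
    if not ids_a:
        raise ValueError(f"no samples of class {tissue_class_a!r}")
    if not ids_b:
        raise ValueError(f"no samples of class {tissue_class_b!r}")
    in_a = matrix.present[ids_a].any(axis=1)
    in_b = matrix.present[ids_b].any(axis=1)
    union = in_a | in_b
    shared = in_a & in_b
    if int(union.sum()) == 0:
        return 0.0, []
    return float(shared.sum() / union.sum()), list(matrix.present.index[shared])


def to_long_frame(matrix: MultiRegionMatrix) -> pd.DataFrame:
    """Long-form export: one row per (mutation, sample) cell."""
    meta = matrix.meta_by_id()
    records = []
    for label in matrix.vaf.index:
        for sid in matrix.vaf.columns:
            records.append(
                {
                    "patient_id": matrix.patient_id,
                    "mutation": label,
                    "sample_id": sid,
                    "tissue_class": meta[sid].tissue_class,
                    "vaf": matrix.vaf.loc[label, sid],
                    "present": bool(matrix.present.loc[label, sid]),
                    "assayed": bool(matrix.assayed.loc[label, sid]),
                }
            )
    return pd.DataFrame(records)


def matrix_from_counts(
    counts_by_sample: Mapping[str, Mapping[str, "AlleleCounts"]],
    control_by_region: Mapping[str, "AlleleCounts"],
    targets: Sequence["TargetRegion"],
    meta: Sequence[SampleMeta],
    *,
    positions: Sequence[int] | None = None,
    config=None,
    presence_vaf_min: float = PRESENCE_VAF_MIN,
) -> MultiRegionMatrix:
    """Run the noise caller per sample/region and assemble the matrix.

    ``counts_by_sample`` maps sample id to per-region allele counts;
    ``control_by_region`` supplies the matched (germline) control per
    region.  Samples of tissue class ``blood`` are skipped (they are the
    control).  ``positions`` optionally restricts calling to a candidate
    site list, mirroring validation panels designed around known
    candidates.
    """
    from .caller import call_region

    meta_by_id = {m.sample_id: m for m in meta}
    target_by_id = {t.region_id: t for t in targets}
    calls_by_sample: dict[str, list] = {}
    for sid, per_region in counts_by_sample.items():
        m = meta_by_id.get(sid)
        if m is None:
            raise ValueError(f"no metadata for sample {sid!r}")
        if m.tissue_class == "blood":
            continue
        calls: list = []
        for region_id, counts in per_region.items():
            control = control_by_region.get(region_id)
            if control is None:
                raise ValueError(f"no control counts for region {region_id!r}")
            calls.extend(
                call_region(
                    counts, control, target_by_id[region_id], config, positions
                )
            )
        calls_by_sample[sid] = calls
    return build_matrix(
        calls_by_sample,
        [m for m in meta],
        presence_vaf_min=presence_vaf_min,
    )


def render_heatmap(matrix: MultiRegionMatrix, path: str | Path) -> None:
    """Render the VAF matrix as a heatmap with tissue-class annotations.

    Deterministic layout: rows/columns in matrix order, VAF colour scale,
    blood columns displayed but visually separated.  Raises on an empty
    matrix rather than producing a blank file.
    """
    if matrix.vaf.shape[0] == 0 or matrix.vaf.shape[1] == 0:
        raise ValueError("refusing to render an empty matrix")
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    meta = matrix.meta_by_id()
    n_mut, n_smp = matrix.vaf.shape
    fig, ax = plt.subplots(
        figsize=(max(3.0, 0.6 * n_smp + 2.0), max(2.5, 0.35 * n_mut + 1.5))
    )
    data = matrix.vaf.to_numpy(dtype=float)
    masked = np.ma.masked_invalid(data)
    cmap = plt.get_cmap("Reds").copy()
    cmap.set_bad("0.85")
    vmax = np.nanmax(data) if np.isfinite(data).any() else 1.0
    im = ax.imshow(masked, aspect="auto", cmap=cmap, vmin=0.0, vmax=max(vmax, 1e-9))
    ax.set_xticks(range(n_smp))
    ax.set_xticklabels(
        [
            f"{sid}\n({meta[sid].tissue_class})"
            for sid in matrix.vaf.columns
        ],
        rotation=90,
        fontsize=7,
    )
    ax.set_yticks(range(n_mut))
    ax.set_yticklabels(matrix.vaf.index, fontsize=7)
    ax.set_title(f"Patient {matrix.patient_id}: VAF by region")
    fig.colorbar(im, ax=ax, label="VAF")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
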