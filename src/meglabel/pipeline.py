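"""End-to-end dipole labeling: discover, filter, transform, label, account.

The flow mirrors a clinical MEG reporting session: a subject folder holds the
native T1, one ``.dip`` file per task (IED, SEF, LEF, ...) and the MEG-MRI
coregistration; dipoles that survive the single-ECD (sECD) acceptance
criteria are carried HEAD -> WORLD -> VOXEL and labeled against every
configured native-space atlas. Every input dipole is accounted for in exactly
one disposition — accepted, rejected(reason) or excluded(reason) — so no
dipole can silently vanish between the scanner and the report.

The sECD acceptance criteria follow the clinical defaults: reduced
chi-square < 2 (strict), goodness of fit >= 80 % (inclusive), confidence
volume < 1000 mm^3 (strict) and dipole strength in the inclusive 100-500 nAm
range. A dipole missing an optional statistic is evaluated only on the
criteria it carries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .atlas import Atlas, LabelResult, lookup as atlas_lookup, nearest_labeled
from .formats import Dipole, DipoleGroup
from .geometry import FrameTransform, Volume, map_point, world_to_voxel

__all__ = [
    "FilterCriteria",
    "DipoleLabelRecord",
    "SubjectManifest",
    "SubjectLayoutError",
    "discover_subject",
    "filter_dipoles",
    "dipole_to_voxel",
    "label_dipoles",
    "summarize",
    "records_to_table",
]


class SubjectLayoutError(FileNotFoundError):
    pass


@dataclass(frozen=True)
class FilterCriteria:
    """sECD acceptance thresholds.

    Boundary semantics: chi-square and confidence volume are strict ``<``;
    goodness of fit is inclusive ``>=``; the strength window is inclusive on
    both ends.
    """

    chi2_max: float = 2.0
    gof_min_pct: float = 80.0
    cv_max_mm3: float = 1000.0
    q_min_nam: float = 100.0
    q_max_nam: float = 500.0

    def __post_init__(self) -> None:
        if self.q_min_nam > self.q_max_nam:
            raise ValueError("q_min_nam must be <= q_max_nam")
        for name in ("chi2_max", "gof_min_pct", "cv_max_mm3", "q_min_nam", "q_max_nam"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def first_failure(self, d: Dipole) -> Optional[str]:
        """First failing criterion in the fixed order chi2, gof, cv, strength.

        Returns ``None`` when the dipole passes every criterion it carries;
        optional statistics that are absent are skipped.
        """
        if d.chi2_reduced is not None and not (d.chi2_reduced < self.chi2_max):
            return "chi2"
        if not (d.gof_pct >= self.gof_min_pct):
            return "gof"
        if d.conf_volume_mm3 is not None and not (d.conf_volume_mm3 < self.cv_max_mm3):
            return "cv"
        if not (self.q_min_nam <= d.q_nam <= self.q_max_nam):
            return "strength"
        return None


@dataclass
class SubjectManifest:
    folder: Path
    t1_path: Optional[Path]
    coreg_path: Optional[Path]
    dip_paths: dict[str, Path]  # task -> file
    norm_path: Optional[Path] = None  # canonical affine normalization
    warp_path: Optional[Path] = None  # displacement-field NIfTI
    missing: list[str] = field(default_factory=list)


_T1_PATTERNS = ("t1.nii", "t1.nii.gz", "T1.nii", "T1.nii.gz")
_COREG_NAMES = ("coreg.txt",)
_NORM_NAMES = ("norm.txt",)
_WARP_PATTERNS = ("warp.nii", "warp.nii.gz")


def discover_subject(folder, require_complete: bool = True) -> SubjectManifest:
    """Identify the pipeline inputs inside a subject folder.

    Discovery is deterministic and by naming convention: every ``*.dip`` file
    is one task group (task = file stem), the T1 is ``t1.nii[.gz]`` (case
    tolerated), the coregistration is ``coreg.txt`` and optional saved
    normalizations are ``norm.txt`` / ``warp.nii[.gz]``. Unrelated files are
    ignored. With ``require_complete`` a missing T1 or coreg raises a
    :class:`SubjectLayoutError` naming exactly what was not found.
    """
    folder = Path(folder)
    if not folder.is_dir():
        raise SubjectLayoutError(f"subject folder {folder} does not exist")

    dip_paths = {p.stem: p for p in sorted(folder.glob("*.dip"))}
    if not dip_paths:
        raise SubjectLayoutError(f"{folder}: no .dip dipole files found")

    def first_match(names: Sequence[str]) -> Optional[Path]:
        for name in names:
            p = folder / name
            if p.exists():
                return p
        return None

    t1 = first_match(_T1_PATTERNS)
    coreg = first_match(_COREG_NAMES)
    norm = first_match(_NORM_NAMES)
    warp = first_match(_WARP_PATTERNS)

    missing = []
    if t1 is None:
        missing.append(f"T1 volume (expected one of {', '.join(_T1_PATTERNS)})")
    if coreg is None:
        missing.append(f"coregistration (expected {_COREG_NAMES[0]})")
    if require_complete and missing:
        raise SubjectLayoutError(f"{folder}: missing " + "; ".join(missing))
    return SubjectManifest(
        folder=folder,
        t1_path=t1,
        coreg_path=coreg,
        dip_paths=dip_paths,
        norm_path=norm,
        warp_path=warp,
        missing=missing,
    )


@dataclass
class RejectedDipole:
    dipole: Dipole
    reason: str


def filter_dipoles(
    group: DipoleGroup, criteria: FilterCriteria | None = None
) -> tuple[DipoleGroup, list[RejectedDipole]]:
    """Split a group into sECD-accepted dipoles and rejections with reasons.

    The union of the two outputs is exactly the input; each rejection carries
    the *first* failing criterion (chi2 -> gof -> cv -> strength).
    """
    criteria = criteria or FilterCriteria()
    accepted: list[Dipole] = []
    rejected: list[RejectedDipole] = []
    for d in group:
        reason = criteria.first_failure(d)
        if reason is None:
            accepted.append(d)
        else:
            rejected.append(RejectedDipole(dipole=d, reason=reason))
    acc_group = DipoleGroup(task=group.task, dipoles=accepted, source_path=group.source_path)
    return acc_group, rejected


def dipole_to_voxel(
    d: Dipole, coreg: FrameTransform, t1: Volume
) -> tuple[np.ndarray, bool]:
    """Map one dipole HEAD-frame position to the T1 voxel grid.

    Applies the coregistration (HEAD->WORLD mm) and the inverse of the T1
    voxel->world affine, then rounds to the nearest voxel centre. Returns the
    integer voxel index and whether it lies inside the T1 field of view.
    """
    world = map_point(coreg, d.position)
    cont_idx, in_fov = world_to_voxel(t1, world)
    return np.rint(cont_idx).astype(int), bool(in_fov)


@dataclass
class DipoleLabelRecord:
    """One fully-accounted dipole: where it landed and what every atlas says."""

    group: str
    dipole: Dipole
    disposition: str  # "accepted" | "rejected" | "excluded"
    reason: str = ""
    voxel: Optional[np.ndarray] = None
    world_mm: Optional[np.ndarray] = None
    in_fov: bool = False
    results: list[LabelResult] = field(default_factory=list)
    fallback_results: list[LabelResult] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.disposition not in ("accepted", "rejected", "excluded"):
            raise ValueError(f"bad disposition {self.disposition!r}")
        if self.disposition != "accepted" and not self.reason:
            raise ValueError("rejected/excluded records must carry a reason")


def label_dipoles(
    groups: Sequence[DipoleGroup],
    atlases_native: Sequence[Atlas],
    coreg: FrameTransform,
    t1: Volume,
    criteria: FilterCriteria | None = None,
    nearest_fallback: bool = False,
    fallback_radius_mm: float = 10.0,
    excluded_ids: Sequence[str] = (),
) -> list[DipoleLabelRecord]:
    """Label every dipole of every group against every native-space atlas.

    ``excluded_ids`` marks dipoles set aside by expert judgment (the manual
    disposition for, e.g., dipoles deep in white matter/CSF); they are
    accounted as ``excluded`` and never labeled. The nearest-labeled fallback
    is opt-in and its results are recorded *separately* — a fallback label
    never silently replaces the direct lookup.
    """
    criteria = criteria or FilterCriteria()
    excluded = set(excluded_ids)
    for a in atlases_native:
        if a.space != "native":
            raise ValueError(f"atlas {a.name!r} must be reverse-normalized first")
    records: list[DipoleLabelRecord] = []
    for group in groups:
        for d in group:
            if d.id in excluded:
                records.append(
                    DipoleLabelRecord(
                        group=group.task,
                        dipole=d,
                        disposition="excluded",
                        reason="manual exclusion",
                    )
                )
                continue
            reason = criteria.first_failure(d)
            if reason is not None:
                records.append(
                    DipoleLabelRecord(
                        group=group.task, dipole=d, disposition="rejected", reason=reason
                    )
                )
                continue
            try:
                voxel, in_fov = dipole_to_voxel(d, coreg, t1)
            except Exception as exc:
                raise RuntimeError(f"dipole {d.id}: {exc}") from exc
            world = map_point(coreg, d.position)
            results = [atlas_lookup(a, voxel) for a in atlases_native]
            fallback: list[LabelResult] = []
            if nearest_fallback:
                fallback = [
                    nearest_labeled(a, voxel, max_radius_mm=fallback_radius_mm)
                    for a in atlases_native
                ]
            records.append(
                DipoleLabelRecord(
                    group=group.task,
                    dipole=d,
                    disposition="accepted",
                    voxel=voxel,
                    world_mm=world,
                    in_fov=in_fov,
                    results=results,
                    fallback_results=fallback,
                )
            )
    return records


def summarize(records: Sequence[DipoleLabelRecord]) -> dict:
    """Accounting summary: dispositions plus per-atlas labeling outcomes.

    Conservation holds by construction: ``n_total == n_accepted + n_rejected
    + n_excluded`` and, per atlas, ``labeled + unlabeled + out_of_fov ==
    n_accepted``.
    """
    n_total = len(records)
    n_accepted = sum(r.disposition == "accepted" for r in records)
    n_rejected = sum(r.disposition == "rejected" for r in records)
    n_excluded = sum(r.disposition == "excluded" for r in records)
    per_atlas: dict[str, dict[str, int]] = {}
    for r in records:
        if r.disposition != "accepted":
            continue
        for res in r.results:
            c = per_atlas.setdefault(
                res.atlas_name, {"labeled": 0, "unlabeled": 0, "out_of_fov": 0}
            )
            c[res.status] += 1
    reject_reasons: dict[str, int] = {}
    for r in records:
        if r.disposition == "rejected":
            reject_reasons[r.reason] = reject_reasons.get(r.reason, 0) + 1
    return {
        "n_total": n_total,
        "n_accepted": n_accepted,
        "n_rejected": n_rejected,
        "n_excluded": n_excluded,
        "reject_reasons": reject_reasons,
        "per_atlas": per_atlas,
    }


def records_to_table(records: Sequence[DipoleLabelRecord]) -> pd.DataFrame:
    """Flatten records into the per-dipole report table.

    One row per dipole with its group, voxel index, world mm position,
    disposition and, per atlas, status/code/label plus any fallback label and
    distance.
    """
    rows = []
    for r in records:
        row: dict = {
            "group": r.group,
            "dipole_id": r.dipole.id,
            "disposition": r.disposition,
            "reason": r.reason,
            "in_fov": r.in_fov if r.disposition == "accepted" else "",
        }
        for axis, name in enumerate("ijk"):
            row[f"voxel_{name}"] = int(r.voxel[axis]) if r.voxel is not None else ""
        for axis, name in enumerate("xyz"):
            row[f"world_{name}_mm"] = (
                float(r.world_mm[axis]) if r.world_mm is not None else ""
            )
        for res in r.results:
            row[f"{res.atlas_name}:status"] = res.status
            row[f"{res.atlas_name}:code"] = res.code
            row[f"{res.atlas_name}:label"] = res.label
        for res in r.fallback_results:
            row[f"{res.atlas_name}:fallback_label"] = res.label
            row[f"{res.atlas_name}:fallback_distance_mm"] = (
                res.distance_mm if res.status == "labeled" else ""
            )
        rows.append(row)
    return pd.DataFrame(rows)
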