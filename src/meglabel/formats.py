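"""Readers and writers for every file the labeling pipeline touches.

* ``.dip`` — the Neuromag/MEGIN-style plain-text dipole dialect: one fitted
  equivalent current dipole (ECD) per row,
  ``begin_ms end_ms x y z Qx Qy Qz Q gof [chi2r cv_mm3]``, positions in
  HEAD-frame mm, moments in nAm, ``#`` comments. Missing optional trailing
  values may be written as ``-``.
* atlas lookup tables — ``<integer code> "<label name>"`` lines mapping the
  integer codes of a label NIfTI to anatomical region names.
* canonical transform / coregistration files — a small structured text format
  carrying a 4x4 matrix plus explicit frame and unit declarations, so that a
  wrong-frame or wrong-unit file fails at parse time rather than silently
  mislabeling dipoles.
* FSL FLIRT-style ``.mat`` — 4x4 whitespace ASCII in FSL's scaled-voxel
  convention, converted here to a plain world->world mm transform.
* displacement-field NIfTI — a 4-D ``(nx, ny, nz, 3)`` vector volume.
* NIfTI-1 volumes via nibabel; the voxel->world affine is preserved exactly
  and never reoriented.

All readers reject rather than coerce: non-finite numbers, duplicate codes,
missing declarations and malformed rows are errors.
"""

from __future__ import annotations

import shlex
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import nibabel as nib
import numpy as np

from .geometry import (
    DeformationField,
    Frame,
    FrameTransform,
    Volume,
)

__all__ = [
    "Dipole",
    "DipoleGroup",
    "LookupTable",
    "FormatError",
    "read_dip",
    "write_dip",
    "read_lookup_table",
    "write_lookup_table",
    "read_transform",
    "write_transform",
    "read_coreg",
    "write_coreg",
    "load_volume",
    "save_volume",
    "load_displacement_field",
    "save_displacement_field",
]


class FormatError(ValueError):
    """Raised for any malformed input file."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Dipole:
    """One fitted equivalent current dipole.

    Position is in the MEG HEAD frame (mm); the moment vector and strength
    ``q_nam`` are in nanoampere-metres; ``gof_pct`` is the goodness of fit in
    percent; ``chi2_reduced`` and ``conf_volume_mm3`` are the optional fit
    statistics used by the clinical acceptance criteria.
    """

    id: str
    begin_ms: float
    end_ms: float
    position: np.ndarray
    moment: np.ndarray
    q_nam: float
    gof_pct: float
    chi2_reduced: Optional[float] = None
    conf_volume_mm3: Optional[float] = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        mom = np.asarray(self.moment, dtype=float)
        if pos.shape != (3,) or mom.shape != (3,):
            raise ValueError("dipole position and moment must be 3-vectors")
        if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(mom))):
            raise ValueError(f"dipole {self.id}: non-finite position or moment")
        if not 0.0 <= self.gof_pct <= 100.0:
            raise ValueError(f"dipole {self.id}: gof_pct must be in [0, 100]")
        if self.q_nam < 0:
            raise ValueError(f"dipole {self.id}: strength must be >= 0")
        if self.conf_volume_mm3 is not None and self.conf_volume_mm3 <= 0:
            raise ValueError(f"dipole {self.id}: confidence volume must be > 0")
        if self.begin_ms > self.end_ms:
            raise ValueError(f"dipole {self.id}: begin_ms > end_ms")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "moment", mom)


@dataclass
class DipoleGroup:
    """A task-named collection of dipoles (IED, SEF, LEF, ...)."""

    task: str
    dipoles: list[Dipole]
    source_path: str = ""

    def __post_init__(self) -> None:
        if not self.task:
            raise ValueError("dipole group task name must be non-empty")
        ids = [d.id for d in self.dipoles]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate dipole ids in group {self.task!r}")

    def __len__(self) -> int:
        return len(self.dipoles)

    def __iter__(self):
        return iter(self.dipoles)


@dataclass
class LookupTable:
    """Mapping from the integer codes of a label volume to region names.

    Code 0 is reserved for "no label" and may never appear as an entry.
    """

    atlas_name: str
    entries: dict[int, str]

    def __post_init__(self) -> None:
        for code, label in self.entries.items():
            if code <= 0:
                raise ValueError(f"lookup code must be >= 1, got {code}")
            if not label:
                raise ValueError(f"lookup code {code} has an empty label")

    def __contains__(self, code: int) -> bool:
        return code in self.entries

    def __getitem__(self, code: int) -> str:
        return self.entries[code]

    def codes(self) -> set[int]:
        return set(self.entries)


# ---------------------------------------------------------------------------
# .dip dialect
# ---------------------------------------------------------------------------

_DIP_COLUMNS = (
    "begin_ms end_ms x_mm y_mm z_mm Qx_nAm Qy_nAm Qz_nAm Q_nAm gof_pct chi2r cv_mm3"
)
_MISSING = "-"


def _parse_float(token: str, path, lineno: int, what: str) -> float:
    try:
        value = float(token)
    except ValueError:
        raise FormatError(
            f"{path}:{lineno}: could not parse {what} from {token!r}"
        ) from None
    if not np.isfinite(value):
        raise FormatError(f"{path}:{lineno}: non-finite {what}")
    return value


def _parse_optional(token: str, path, lineno: int, what: str) -> Optional[float]:
    if token in (_MISSING, "."):
        return None
    return _parse_float(token, path, lineno, what)


def read_dip(path, task: str | None = None) -> DipoleGroup:
    """Read a Neuromag-style ``.dip`` text file into a :class:`DipoleGroup`.

    Lines starting with ``#`` are comments. Each data row carries 10 required
    whitespace-separated columns plus up to two optional fit statistics; the
    task name defaults to the file stem (``SEF.dip`` -> task ``SEF``).
    Dipole ids are ``<task>_<ordinal>``, 1-based in file order.
    """
    path = Path(path)
    if task is None:
        task = path.stem
    dipoles: list[Dipole] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 10 or len(tokens) > 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 10-12 columns "
                    f"({_DIP_COLUMNS}), got {len(tokens)}"
                )
            vals = [
                _parse_float(t, path, lineno, f"column {i + 1}")
                for i, t in enumerate(tokens[:10])
            ]
            chi2 = cv = None
            if len(tokens) >= 11:
                chi2 = _parse_optional(tokens[10], path, lineno, "chi2r")
            if len(tokens) == 12:
                cv = _parse_optional(tokens[11], path, lineno, "cv_mm3")
            try:
                dipoles.append(
                    Dipole(
                        id=f"{task}_{len(dipoles) + 1:03d}",
                        begin_ms=vals[0],
                        end_ms=vals[1],
                        position=vals[2:5],
                        moment=vals[5:8],
                        q_nam=vals[8],
                        gof_pct=vals[9],
                        chi2_reduced=chi2,
                        conf_volume_mm3=cv,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    if not dipoles:
        raise FormatError(f"{path}: no dipoles (file has no data rows)")
    return DipoleGroup(task=task, dipoles=dipoles, source_path=str(path))


def _fmt(value: Optional[float]) -> str:
    return _MISSING if value is None else f"{value:.6f}"


def write_dip(group: DipoleGroup, path) -> Path:
    """Write a dipole group as a ``.dip`` text file (re-readable, byte-stable)."""
    if len(group) == 0:
        raise ValueError("refusing to write a dipole-less .dip file")
    path = Path(path)
    lines = [f"# task: {group.task}", f"# columns: {_DIP_COLUMNS}"]
    for d in group:
        fields = [
            _fmt(d.begin_ms),
            _fmt(d.end_ms),
            *(_fmt(x) for x in d.position),
            *(_fmt(x) for x in d.moment),
            _fmt(d.q_nam),
            _fmt(d.gof_pct),
            _fmt(d.chi2_reduced),
            _fmt(d.conf_volume_mm3),
        ]
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# lookup tables
# ---------------------------------------------------------------------------


def read_lookup_table(path, atlas_name: str) -> LookupTable:
    """Parse a ``<code> "<label>"`` lookup table text file.

    Blank lines and ``#`` comments are skipped; labels may be quoted or bare;
    duplicate, zero or negative codes are errors.
    """
    path = Path(path)
    entries: dict[int, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                parts = shlex.split(line, comments=False)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if len(parts) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected '<code> \"<label>\"', got {line!r}"
                )
            try:
                code = int(parts[0])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: code {parts[0]!r} is not an integer"
                ) from None
            if code == 0:
                raise FormatError(f"{path}:{lineno}: code 0 is reserved for 'no label'")
            if code < 0:
                raise FormatError(f"{path}:{lineno}: negative code {code}")
            if code in entries:
                raise FormatError(f"{path}:{lineno}: duplicate code {code}")
            if not parts[1]:
                raise FormatError(f"{path}:{lineno}: empty label for code {code}")
            entries[code] = parts[1]
    return LookupTable(atlas_name=atlas_name, entries=entries)


def write_lookup_table(table: LookupTable, path) -> Path:
    path = Path(path)
    lines = [f"# atlas: {table.atlas_name}"]
    for code in sorted(table.entries):
        lines.append(f'{code} "{table.entries[code]}"')
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# canonical transform / coreg files
# ---------------------------------------------------------------------------

_TRANSFORM_MAGIC = "meglabel transform v1"
_COREG_MAGIC = "meglabel coreg v1"


def _read_structured(path, magic: str) -> dict:
    path = Path(path)
    text = path.read_text(encoding="utf-8").splitlines()
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    in_matrix = False
    first_content = True
    for lineno, raw in enumerate(text, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if first_content and magic not in line:
                raise FormatError(
                    f"{path}: not a '{magic}' file (header is {line!r})"
                )
            first_content = False
            continue
        first_content = False
        if in_matrix:
            tokens = line.split()
            if len(tokens) != 4:
                raise FormatError(f"{path}:{lineno}: matrix rows must have 4 entries")
            rows.append([_parse_float(t, path, lineno, "matrix entry") for t in tokens])
            continue
        if ":" not in line:
            raise FormatError(f"{path}:{lineno}: expected 'key: value', got {line!r}")
        key, _, value = line.partition(":")
        key, value = key.strip(), value.strip()
        if key == "matrix":
            in_matrix = True
        else:
            meta[key] = value
    if len(rows) != 4:
        raise FormatError(f"{path}: expected a 4x4 matrix, got {len(rows)} rows")
    meta["_matrix"] = np.array(rows)  # type: ignore[assignment]
    return meta


def _write_structured(path, magic: str, meta: Mapping[str, str], matrix: np.ndarray) -> Path:
    path = Path(path)
    lines = [f"# {magic}"]
    lines += [f"{k}: {v}" for k, v in meta.items()]
    lines.append("matrix:")
    for row in np.asarray(matrix, dtype=float):
        lines.append(" ".join(f"{x:.12g}" for x in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def write_transform(t: FrameTransform, path) -> Path:
    """Write a transform in the canonical structured-text dialect."""
    meta = {
        "source_frame": t.source.value,
        "target_frame": t.target.value,
        "units": "mm",
    }
    return _write_structured(path, _TRANSFORM_MAGIC, meta, t.matrix)


def _fsl_scaled_voxel(vol_meta) -> np.ndarray:
    """VOXEL -> FSL scaled-voxel matrix for one volume.

    FSL FLIRT matrices act on voxel indices multiplied by the voxel
    dimensions; on volumes whose voxel->world affine has a *positive*
    determinant the x index is additionally flipped (``(nx-1) - i``).
    ``vol_meta`` needs ``shape``, ``affine`` (a Volume works).
    """
    affine = np.asarray(vol_meta.affine, dtype=float)
    shape = vol_meta.shape
    zooms = np.linalg.norm(affine[:3, :3], axis=0)
    m = np.diag([zooms[0], zooms[1], zooms[2], 1.0])
    if np.linalg.det(affine[:3, :3]) > 0:
        m[0, 0] = -zooms[0]
        m[0, 3] = (shape[0] - 1) * zooms[0]
    return m


def flirt_to_world(flirt_matrix: np.ndarray, moving, fixed) -> FrameTransform:
    """Convert an FSL FLIRT matrix into a WORLD(native)->TEMPLATE mm transform.

    ``moving`` / ``fixed`` supply shape and voxel->world affine of the
    registered (native) and reference (template) volumes — FLIRT matrices are
    meaningless without them.
    """
    m = np.asarray(flirt_matrix, dtype=float)
    if m.shape != (4, 4):
        raise FormatError(f"FLIRT matrix must be 4x4, got {m.shape}")
    if not np.all(np.isfinite(m)):
        raise FormatError("FLIRT matrix contains non-finite entries")
    s_mov = _fsl_scaled_voxel(moving)
    s_fix = _fsl_scaled_voxel(fixed)
    a_mov = np.asarray(moving.affine, dtype=float)
    a_fix = np.asarray(fixed.affine, dtype=float)
    world = a_fix @ np.linalg.inv(s_fix) @ m @ s_mov @ np.linalg.inv(a_mov)
    return FrameTransform(world, Frame.WORLD, Frame.TEMPLATE)


def read_transform(
    path,
    dialect: str = "canonical",
    moving=None,
    fixed=None,
):
    """Read a spatial-normalization transform.

    ``dialect`` is one of:

    * ``canonical`` — the structured-text format written by
      :func:`write_transform`; frames are taken from the file.
    * ``flirt_mat`` — FSL-style 4x4 ASCII in the scaled-voxel convention;
      ``moving`` and ``fixed`` volume geometries are required.
    * ``displacement_field`` — a 4-D NIfTI of per-voxel mm displacement
      vectors; returns a :class:`~meglabel.geometry.DeformationField`.
    """
    if dialect == "canonical":
        meta = _read_structured(path, _TRANSFORM_MAGIC)
        for key in ("source_frame", "target_frame"):
            if key not in meta:
                raise FormatError(f"{path}: missing {key} declaration")
        try:
            src = Frame(meta["source_frame"])
            tgt = Frame(meta["target_frame"])
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from None
        return FrameTransform(meta["_matrix"], src, tgt)
    if dialect == "flirt_mat":
        if moving is None or fixed is None:
            raise FormatError(
                "flirt_mat dialect requires the moving and fixed volume geometries"
            )
        rows = []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if line.strip():
                rows.append(
                    [_parse_float(t, path, lineno, "matrix entry") for t in line.split()]
                )
        m = np.array(rows)
        if m.shape != (4, 4):
            raise FormatError(f"{path}: FLIRT matrix must be 4x4, got {m.shape}")
        return flirt_to_world(m, moving, fixed)
    if dialect == "displacement_field":
        return load_displacement_field(path)
    raise ValueError(f"unknown transform dialect {dialect!r}")


def write_coreg(t: FrameTransform, path, head_unit: str = "mm") -> Path:
    """Write a HEAD->WORLD coregistration in the canonical dialect.

    The matrix is written as-is; ``head_unit`` declares the unit of the HEAD
    coordinates the matrix expects (``mm`` or ``m``).
    """
    if t.source != Frame.HEAD or t.target != Frame.WORLD:
        raise ValueError("coreg transform must map HEAD->WORLD")
    if head_unit not in ("mm", "m"):
        raise ValueError("head_unit must be 'mm' or 'm'")
    meta = {"source_frame": "HEAD", "target_frame": "WORLD", "head_unit": head_unit}
    return _write_structured(path, _COREG_MAGIC, meta, t.matrix)


def read_coreg(path) -> FrameTransform:
    """Read a canonical coregistration file as a HEAD->WORLD mm transform.

    The unit of the HEAD frame must be declared; if it is metres, the returned
    transform folds in the m->mm conversion so its input is metre coordinates
    and its output is always millimetres. A missing declaration is an error —
    silently assuming a unit is exactly the failure mode this format exists
    to prevent.
    """
    meta = _read_structured(path, _COREG_MAGIC)
    if "head_unit" not in meta:
        raise FormatError(f"{path}: missing head_unit declaration (mm or m)")
    unit = meta["head_unit"]
    if unit not in ("mm", "m"):
        raise FormatError(f"{path}: head_unit must be 'mm' or 'm', got {unit!r}")
    matrix = meta["_matrix"]
    if unit == "m":
        scale = np.diag([1000.0, 1000.0, 1000.0, 1.0])
        matrix = matrix @ scale
    return FrameTransform(matrix, Frame.HEAD, Frame.WORLD)


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------


def load_volume(path, role: str = "intensity", world_frame: Frame = Frame.WORLD) -> Volume:
    """Load a NIfTI-1 volume; the voxel->world affine is preserved exactly."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    if role in ("label", "mask"):
        data = np.rint(np.asarray(data, dtype=float)).astype(np.int32)
    else:
        data = np.asarray(data, dtype=float)
    v2w = FrameTransform(img.affine, Frame.VOXEL, world_frame)
    return Volume(data, v2w, role=role)


def save_volume(volume: Volume, path) -> Path:
    path = Path(path)
    data = volume.values
    if volume.role in ("label", "mask"):
        data = data.astype(np.int16 if data.max() < 2**15 else np.int32)
    else:
        data = data.astype(np.float32)
    img = nib.Nifti1Image(data, volume.affine)
    img.header.set_qform(volume.affine, code=1)
    img.header.set_sform(volume.affine, code=1)
    nib.save(img, str(path))
    return path


def load_displacement_field(path, world_frame: Frame = Frame.WORLD) -> DeformationField:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 5 and data.shape[3] == 1:  # FSL-style (x, y, z, 1, 3)
        data = data[:, :, :, 0, :]
    if data.ndim != 4 or data.shape[3] != 3:
        raise FormatError(
            f"{path}: displacement field must be (nx, ny, nz, 3), got {data.shape}"
        )
    v2w = FrameTransform(img.affine, Frame.VOXEL, world_frame)
    return DeformationField(data, v2w)


def save_displacement_field(field: DeformationField, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(field.displacements.astype(np.float32), field.voxel_to_world.matrix)
    img.header.set_qform(field.voxel_to_world.matrix, code=1)
    img.header.set_sform(field.voxel_to_world.matrix, code=1)
    nib.save(img, str(path))
    return path
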