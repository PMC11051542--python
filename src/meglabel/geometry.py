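"""Coordinate frames, homogeneous affines and voxel/world conversion.

Every spatial object in the pipeline lives in one of four named frames:

* ``HEAD`` — the MEG device/head coordinate frame in which dipoles are fitted,
* ``WORLD`` — the native scanner/anatomical frame of the subject's MRI
  (RAS+ millimetres),
* ``VOXEL`` — 0-based voxel indices of a particular grid,
* ``TEMPLATE`` — the standard-space (MNI-like) world frame, millimetres.

A :class:`FrameTransform` is a 4x4 homogeneous affine *tagged* with its source
and target frame, so that an illegal chain (e.g. applying a head->world
coregistration to voxel indices) fails loudly at composition time instead of
silently producing nonsense coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "Frame",
    "FrameTransform",
    "Volume",
    "DeformationField",
    "FrameError",
    "compose",
    "invert",
    "map_point",
    "world_to_voxel",
    "identity_transform",
    "translation",
    "rotation_z",
]


class FrameError(ValueError):
    """Raised when transforms are chained across mismatched frames."""


class Frame(str, Enum):
    HEAD = "HEAD"
    WORLD = "WORLD"
    VOXEL = "VOXEL"
    TEMPLATE = "TEMPLATE"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_BOTTOM_ROW = np.array([0.0, 0.0, 0.0, 1.0])


@dataclass(frozen=True)
class FrameTransform:
    """A 4x4 homogeneous affine between two named coordinate frames.

    Units are millimetres for world-like frames (HEAD, WORLD, TEMPLATE) and
    voxel indices for VOXEL. The bottom row must be exactly ``(0, 0, 0, 1)``
    and the 3x3 linear block must be invertible.
    """

    matrix: np.ndarray
    source: Frame
    target: Frame

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"transform matrix must be 4x4, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValueError("transform matrix contains non-finite entries")
        if not np.array_equal(m[3], _BOTTOM_ROW):
            raise ValueError("transform bottom row must be exactly (0, 0, 0, 1)")
        if abs(np.linalg.det(m[:3, :3])) <= 1e-12:
            raise ValueError("transform linear block is singular")
        src = Frame(self.source)
        tgt = Frame(self.target)
        if src == tgt and not np.allclose(m, np.eye(4), atol=1e-9):
            raise FrameError(
                f"non-identity transform may not map frame {src} onto itself"
            )
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "source", src)
        object.__setattr__(self, "target", tgt)

    # -- application ------------------------------------------------------

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply the affine to one point ``(3,)`` or a stack ``(n, 3)``."""
        p = np.asarray(points, dtype=float)
        if not np.all(np.isfinite(p)):
            raise ValueError("points contain non-finite coordinates")
        single = p.ndim == 1
        p = np.atleast_2d(p)
        if p.shape[1] != 3:
            raise ValueError(f"points must have 3 coordinates, got shape {p.shape}")
        out = p @ self.matrix[:3, :3].T + self.matrix[:3, 3]
        return out[0] if single else out

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return self.apply(points)

    # -- algebra ----------------------------------------------------------

    def then(self, other: "FrameTransform") -> "FrameTransform":
        """``self`` followed by ``other`` (see :func:`compose`)."""
        return compose(self, other)

    def inverse(self) -> "FrameTransform":
        return invert(self)

    def is_identity(self, atol: float = 1e-9) -> bool:
        return bool(np.allclose(self.matrix, np.eye(4), atol=atol))


def identity_transform(frame: Frame, target: Frame | None = None) -> FrameTransform:
    return FrameTransform(np.eye(4), frame, frame if target is None else target)


def translation(t, source: Frame = Frame.WORLD, target: Frame = Frame.WORLD) -> FrameTransform:
    m = np.eye(4)
    m[:3, 3] = np.asarray(t, dtype=float)
    return FrameTransform(m, source, target)


def rotation_z(degrees: float, source: Frame = Frame.WORLD, target: Frame = Frame.WORLD) -> FrameTransform:
    a = np.deg2rad(degrees)
    m = np.eye(4)
    m[0, 0] = m[1, 1] = np.cos(a)
    m[0, 1] = -np.sin(a)
    m[1, 0] = np.sin(a)
    return FrameTransform(m, source, target)


def compose(a: FrameTransform, b: FrameTransform) -> FrameTransform:
    """Chain two transforms: the result applies ``a`` first, then ``b``.

    Frames must agree: ``a.target == b.source``. For any point ``p``,
    ``compose(a, b)(p) == b(a(p))``.
    """
    if a.target != b.source:
        raise FrameError(
            "cannot chain transforms: first maps "
            f"{a.source}->{a.target} but second expects {b.source} input"
        )
    return FrameTransform(b.matrix @ a.matrix, a.source, b.target)


def invert(t: FrameTransform) -> FrameTransform:
    """Invert an affine; source and target frames swap."""
    return FrameTransform(np.linalg.inv(t.matrix), t.target, t.source)


def map_point(t: FrameTransform, p) -> np.ndarray:
    """Map one 3-point (or a stack of points) through a transform."""
    return t.apply(p)


_ROLES = ("intensity", "label", "mask")


@dataclass
class Volume:
    """A 3-D scalar grid with a VOXEL->WORLD affine and a role tag.

    ``role`` is one of ``intensity`` (arbitrary real values), ``label``
    (non-negative integer region codes, 0 = no label) or ``mask`` (0/1).
    World coordinates are RAS+ millimetres; voxel indices are 0-based and a
    continuous index ``i`` sits at the *centre* of voxel ``i`` (NIfTI affine
    semantics).
    """

    values: np.ndarray
    voxel_to_world: FrameTransform
    role: str = "intensity"

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 3 or min(v.shape) < 1:
            raise ValueError(f"volume values must be a 3-D grid, got shape {v.shape}")
        if self.role not in _ROLES:
            raise ValueError(f"role must be one of {_ROLES}, got {self.role!r}")
        if self.voxel_to_world.source != Frame.VOXEL:
            raise FrameError("voxel_to_world must map from VOXEL")
        if self.voxel_to_world.target not in (Frame.WORLD, Frame.TEMPLATE):
            raise FrameError("voxel_to_world must map to a world-like frame")
        if self.role == "label":
            if not np.issubdtype(v.dtype, np.integer):
                if not np.all(v == np.round(v)):
                    raise ValueError("label volume must hold integer codes")
                v = v.astype(np.int32)
            if v.min() < 0:
                raise ValueError("label codes must be non-negative")
        if self.role == "mask":
            uniq = np.unique(v)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask volume must be 0/1")
            v = v.astype(np.uint8)
        if self.role == "intensity" and not np.all(np.isfinite(v)):
            raise ValueError("intensity volume contains non-finite values")
        self.values = v

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.values.shape)  # type: ignore[return-value]

    @property
    def affine(self) -> np.ndarray:
        return self.voxel_to_world.matrix

    @property
    def voxel_size(self) -> np.ndarray:
        """Physical voxel dimensions in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def same_grid(self, other: "Volume", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def voxel_centers_world(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape ``(*shape, 3)``."""
        idx = np.indices(self.shape, dtype=float)
        pts = np.moveaxis(idx, 0, -1).reshape(-1, 3)
        return self.voxel_to_world.apply(pts).reshape(*self.shape, 3)

    def with_values(self, values: np.ndarray, role: str | None = None) -> "Volume":
        return Volume(values, self.voxel_to_world, self.role if role is None else role)


def world_to_voxel(volume: Volume, p_world) -> tuple[np.ndarray, bool | np.ndarray]:
    """Map world mm coordinates to the continuous voxel index of ``volume``.

    Returns ``(continuous_index, in_fov)`` where ``in_fov`` tests whether the
    nearest-integer index (ties-to-even, via ``np.rint``) lies inside the grid
    on every axis.
    """
    idx = invert(volume.voxel_to_world).apply(p_world)
    rounded = np.rint(idx)
    shape = np.asarray(volume.shape)
    in_fov = np.all((rounded >= 0) & (rounded <= shape - 1), axis=-1)
    if idx.ndim == 1:
        return idx, bool(in_fov)
    return idx, in_fov


@dataclass
class DeformationField:
    """A dense nonlinear mapping from a target grid into a source world frame.

    ``displacements`` has shape ``(nx, ny, nz, 3)``: for each voxel of the
    target grid, the vector (mm) to add to its world coordinate to obtain the
    corresponding source-space world coordinate. A zero field is the identity.
    This is how FNIRT/CAT12-style nonlinear normalizations enter the pipeline.
    """

    displacements: np.ndarray
    voxel_to_world: FrameTransform
    source_frame: Frame = Frame.TEMPLATE

    def __post_init__(self) -> None:
        d = np.asarray(self.displacements, dtype=float)
        if d.ndim != 4 or d.shape[3] != 3:
            raise ValueError(
                f"displacement field must have shape (nx, ny, nz, 3), got {d.shape}"
            )
        if self.voxel_to_world.source != Frame.VOXEL:
            raise FrameError("field voxel_to_world must map from VOXEL")
        self.displacements = d

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.displacements.shape[:3])  # type: ignore[return-value]

    def source_coordinates_world(self) -> np.ndarray:
        """Per-voxel source-space world coordinate, shape ``(*shape, 3)``."""
        idx = np.indices(self.shape, dtype=float)
        pts = np.moveaxis(idx, 0, -1).reshape(-1, 3)
        world = self.voxel_to_world.apply(pts).reshape(*self.shape, 3)
        return world + self.displacements
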