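"""Affine spatial normalization and resampling.

The built-in normalization estimates a 12-parameter affine (3 translations,
3 rotations, 3 scales, 3 shears) mapping the native WORLD frame onto the
TEMPLATE frame by derivative-free minimization of the negative normalized
cross-correlation between the fixed template and the resampled moving image.
The search proceeds in three deterministic stages: (1) a closed-form
initialization from intensity centroids and second moments, which pins
translation and anisotropic scale; (2) a fixed rotation-vector grid search
that captures the residual rotation (the similarity surface has false rotation
minima within a few degrees of the true pose, so a purely local refinement is
not enough); (3) Powell direction-set refinement, coarse to fine over
fixed-grid sampling strides. Coarse levels sample the fixed grid by plain
decimation rather than a blurred pyramid: low-pass filtering erases the
thin-shell structure that identifies the pose. The estimator plays the role an
external linear registration tool (FSL FLIRT) plays in a clinical deployment;
nonlinear normalizations (FNIRT/CAT12) are not estimated here — their outputs
are ingested as transform files or displacement fields and applied by
:func:`resample` / :func:`apply_displacement_field`.

Both modality channels are T1-weighted, so normalized cross-correlation is an
adequate similarity metric; mutual information is a documented extension
point, not implemented. Every stage is deterministic: identical inputs and
configuration always produce bit-identical transforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize

from .geometry import (
    DeformationField,
    Frame,
    FrameError,
    FrameTransform,
    Volume,
)

__all__ = [
    "RegistrationConfig",
    "RegistrationResult",
    "QCMetrics",
    "RegistrationError",
    "register_affine",
    "resample",
    "apply_displacement_field",
    "normalization_qc",
]


class RegistrationError(RuntimeError):
    pass


@dataclass
class RegistrationConfig:
    """Tuning knobs for the built-in affine normalization.

    ``strides`` are fixed-grid sampling factors, coarse to fine (a stride of 2
    evaluates the similarity on every second fixed voxel); ``max_iter`` caps
    Powell iterations per stride. ``rotation_search_deg`` / ``rotation_step_deg``
    define the global rotation-capture grid applied after the moments-based
    initialization. Scales and shears are optimized in percent so every
    parameter moves on a comparable scale (mm, degrees, percent).
    """

    strides: tuple[int, ...] = (2, 1)
    max_iter: tuple[int, ...] = (6, 3)
    rotation_search_deg: float = 15.0
    rotation_step_deg: float = 3.0
    xtol: float = 1e-3
    ftol: float = 1e-6
    estimate_shear: bool = True


@dataclass
class RegistrationResult:
    transform: FrameTransform  # WORLD (native) -> TEMPLATE, mm
    cost_initial: float
    cost_final: float
    levels: list[dict] = field(default_factory=list)
    converged: bool = True


def _params_to_matrix(p: np.ndarray, center_moving: np.ndarray, center_fixed: np.ndarray) -> np.ndarray:
    """Build the world affine from the 12-vector.

    Layout: t (mm, 3), rotations about x/y/z (degrees, 3), scale deviation
    (percent, 3), shear (percent, 3). The linear part acts about the moving
    centroid and the result maps the moving centroid to the fixed centroid
    when all parameters are zero (centre-of-mass initialization is built into
    the parametrization).
    """
    t = p[0:3]
    rx, ry, rz = np.deg2rad(p[3:6])
    s = 1.0 + p[6:9] / 100.0
    h = p[9:12] / 100.0

    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    rot_x = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    rot_y = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rot_z = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    shear = np.array([[1, h[0], h[1]], [0, 1, h[2]], [0, 0, 1]])
    linear = rot_z @ rot_y @ rot_x @ np.diag(s) @ shear

    m = np.eye(4)
    m[:3, :3] = linear
    m[:3, 3] = center_fixed + t - linear @ center_moving
    return m


def _foreground_weights(values: np.ndarray) -> np.ndarray:
    """Background-suppressed intensity weights.

    Shifts to a zero floor and soft-thresholds at 10 % of the dynamic range so
    that (possibly noisy) background voxels get zero weight instead of
    dominating the spatial moments by sheer count.
    """
    w = values - values.min()
    return np.maximum(w - 0.1 * w.max(), 0.0)


def _center_of_mass_world(vol: Volume) -> np.ndarray:
    v = _foreground_weights(vol.values)
    total = v.sum()
    if total <= 0:
        raise RegistrationError("degenerate intensity: volume has no contrast")
    com_idx = np.array(ndimage.center_of_mass(v))
    return vol.voxel_to_world.apply(com_idx)


def _intensity_moments(vol: Volume) -> tuple[np.ndarray, np.ndarray]:
    """Foreground-intensity-weighted mean and covariance in world mm."""
    w = _foreground_weights(vol.values).ravel()
    total = w.sum()
    if total <= 0:
        raise RegistrationError("degenerate intensity: volume has no contrast")
    idx = np.indices(vol.shape, dtype=float)
    pts = vol.voxel_to_world.apply(np.moveaxis(idx, 0, -1).reshape(-1, 3))
    mu = (w[:, None] * pts).sum(axis=0) / total
    d = pts - mu
    cov = np.einsum("n,ni,nj->ij", w, d, d) / total
    return mu, cov


def _spd_sqrt(cov: np.ndarray, inverse: bool = False) -> np.ndarray:
    e, u = np.linalg.eigh(cov)
    if np.any(e <= 0):
        raise RegistrationError("degenerate intensity: singular moment matrix")
    d = 1.0 / np.sqrt(e) if inverse else np.sqrt(e)
    return u @ np.diag(d) @ u.T


class _MomentsFamily:
    """The family of affines that match first and second intensity moments.

    Every affine matching centroids and covariances has the form
    ``L(W) = cov_f^1/2 W cov_m^-1/2`` with ``W`` orthogonal and translation
    ``mu_f - L(W) mu_m``: the moments pin translation and stretch exactly but
    leave a rotation in the whitened space undetermined. Searching rotations
    *inside* this family (rather than composing rotations onto one member)
    keeps every candidate moment-matched — composing an outside rotation onto
    the ``W = I`` member drags a spurious stretch along and the true pose is
    never on that path.
    """

    def __init__(self, moving: Volume, fixed: Volume):
        self.mu_m, cov_m = _intensity_moments(moving)
        self.mu_f, cov_f = _intensity_moments(fixed)
        self.sqrt_f = _spd_sqrt(cov_f)
        self.invsqrt_m = _spd_sqrt(cov_m, inverse=True)

    def matrix(self, rotvec_deg=(0.0, 0.0, 0.0)) -> np.ndarray:
        linear = self.sqrt_f @ _rotvec_matrix(rotvec_deg) @ self.invsqrt_m
        m = np.eye(4)
        m[:3, :3] = linear
        m[:3, 3] = self.mu_f - linear @ self.mu_m
        return m


def _rotvec_matrix(rotvec_deg) -> np.ndarray:
    """3x3 rotation from a rotation vector in degrees (axis * angle)."""
    rotvec_deg = np.asarray(rotvec_deg, dtype=float)
    theta = np.linalg.norm(rotvec_deg)
    if theta == 0.0:
        return np.eye(3)
    axis = rotvec_deg / theta
    a = np.deg2rad(theta)
    k = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k)


def _rotation_grid(max_deg: float, step_deg: float) -> np.ndarray:
    """Rotation vectors on a cubic grid, clipped to a ball of ``max_deg``."""
    axis_vals = np.arange(-max_deg, max_deg + 0.5 * step_deg, step_deg)
    grid = np.array(np.meshgrid(axis_vals, axis_vals, axis_vals)).reshape(3, -1).T
    keep = np.linalg.norm(grid, axis=1) <= max_deg + 1e-9
    return grid[keep]


def _stride_fixed(fixed: Volume, stride: int) -> tuple[np.ndarray, np.ndarray]:
    """Fixed volume sampled every ``stride`` voxels, with the matching affine.

    Plain grid decimation, deliberately without smoothing: low-pass filtering
    erases the thin-shell structure that makes the pose identifiable, which
    biases coarse pyramid levels toward wrong optima.
    """
    sub = fixed.values[::stride, ::stride, ::stride].astype(float)
    affine = fixed.affine @ np.diag([stride, stride, stride, 1.0])
    return sub, affine


def _sampled_moving(
    moving: Volume, fixed_affine: np.ndarray, fixed_shape, world: np.ndarray
) -> np.ndarray:
    """Moving image resampled on a fixed grid through ``world`` (mov->fix)."""
    idx_map = np.linalg.inv(moving.affine) @ np.linalg.inv(world) @ fixed_affine
    return ndimage.affine_transform(
        moving.values.astype(float),
        idx_map[:3, :3],
        offset=idx_map[:3, 3],
        output_shape=tuple(fixed_shape),
        order=1,
        mode="constant",
        cval=0.0,
        prefilter=False,
    )


def _neg_ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel()
    b = b.ravel()
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom <= 0:
        return 0.0
    return float(-(a @ b) / denom)


def register_affine(
    moving: Volume, fixed: Volume, config: RegistrationConfig | None = None
) -> RegistrationResult:
    """Estimate the affine normalization of ``moving`` (native) onto ``fixed``.

    Returns a :class:`RegistrationResult` whose transform maps native WORLD mm
    coordinates into the TEMPLATE frame of ``fixed``. Raises
    :class:`RegistrationError` on constant input or when the centre-of-mass
    initialization leaves the volumes with no overlap.
    """
    config = config or RegistrationConfig()
    for name, vol in (("moving", moving), ("fixed", fixed)):
        if vol.role != "intensity":
            raise ValueError(f"{name} volume must be intensity-role")
        if float(np.std(vol.values)) == 0.0:
            raise RegistrationError(f"degenerate intensity: {name} volume is constant")

    family = _MomentsFamily(moving, fixed)
    base = family.matrix()
    c_fix = _center_of_mass_world(fixed)

    n_params = 12 if config.estimate_shear else 9
    p = np.zeros(n_params)

    def full(pvec: np.ndarray) -> np.ndarray:
        out = np.zeros(12)
        out[: len(pvec)] = pvec
        return out

    def make_cost(stride: int):
        fix_vals, fix_affine = _stride_fixed(fixed, stride)

        def cost_matrix(world: np.ndarray) -> float:
            return _neg_ncc(
                _sampled_moving(moving, fix_affine, fix_vals.shape, world), fix_vals
            )

        return cost_matrix

    search_cost = make_cost(config.strides[0])

    # no-overlap guard after the moments initialization
    fix_vals0, fix_affine0 = _stride_fixed(fixed, config.strides[0])
    if float(np.abs(_sampled_moving(moving, fix_affine0, fix_vals0.shape, base)).max()) == 0.0:
        raise RegistrationError(
            "volumes do not overlap after moments-based initialization"
        )

    # global capture of the whitened-space rotation the moments leave free
    n_grid = 0
    if config.rotation_search_deg > 0:
        best_c = search_cost(base)
        for rv in _rotation_grid(config.rotation_search_deg, config.rotation_step_deg):
            c = search_cost(family.matrix(rv))
            n_grid += 1
            if c < best_c - 1e-12:
                best_c, base = c, family.matrix(rv)

    def world_matrix(pvec: np.ndarray) -> np.ndarray:
        # residual affine about the fixed centroid on top of the
        # initialization; p == 0 is exactly the initialization
        return _params_to_matrix(full(pvec), c_fix, c_fix) @ base

    level_reports: list[dict] = []
    for stride, maxiter in zip(config.strides, config.max_iter):
        cost_matrix = make_cost(stride)

        def cost(pvec: np.ndarray) -> float:
            return cost_matrix(world_matrix(pvec))

        c0 = cost(p)
        res = minimize(
            cost,
            p,
            method="Powell",
            options={
                "maxiter": maxiter,
                "xtol": config.xtol,
                "ftol": config.ftol,
                "disp": False,
            },
        )
        p = np.asarray(res.x, dtype=float)
        level_reports.append(
            {
                "stride": stride,
                "cost_initial": c0,
                "cost_final": float(res.fun),
                "n_evaluations": int(res.nfev),
            }
        )
    if n_grid:
        level_reports.insert(
            0, {"stride": config.strides[0], "rotation_grid_evaluations": n_grid}
        )

    cost_finest = make_cost(config.strides[-1])
    cost_initial = cost_finest(base)
    cost_final = cost_finest(world_matrix(p))
    converged = True
    if cost_final > cost_initial:
        # keep the initialization rather than a worse optimum
        p = np.zeros(n_params)
        cost_final = cost_initial
        converged = False

    return RegistrationResult(
        transform=FrameTransform(world_matrix(p), Frame.WORLD, Frame.TEMPLATE),
        cost_initial=cost_initial,
        cost_final=cost_final,
        levels=level_reports,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------


def _target_geometry(target_grid) -> tuple[tuple[int, int, int], np.ndarray, FrameTransform]:
    if isinstance(target_grid, Volume):
        return target_grid.shape, target_grid.affine, target_grid.voxel_to_world
    shape, v2w = target_grid
    if isinstance(v2w, FrameTransform):
        return tuple(shape), v2w.matrix, v2w
    t = FrameTransform(np.asarray(v2w, float), Frame.VOXEL, Frame.WORLD)
    return tuple(shape), t.matrix, t


def _sample(
    source: Volume, source_idx: np.ndarray, out_shape, interp: str
) -> np.ndarray:
    """Sample ``source`` at continuous source voxel coordinates.

    ``source_idx`` has shape ``(n, 3)``. Nearest-neighbour uses ties-to-even
    rounding with out-of-grid voxels set to 0 (the reserved no-label code);
    trilinear delegates to scipy with zero fill.
    """
    if interp == "nearest":
        rounded = np.rint(source_idx).astype(np.int64)
        shape = np.asarray(source.values.shape)
        inside = np.all((rounded >= 0) & (rounded <= shape - 1), axis=1)
        out = np.zeros(len(source_idx), dtype=source.values.dtype)
        r = rounded[inside]
        out[inside] = source.values[r[:, 0], r[:, 1], r[:, 2]]
        return out.reshape(out_shape)
    if interp == "trilinear":
        coords = source_idx.T  # (3, n)
        out = ndimage.map_coordinates(
            source.values.astype(float),
            coords,
            order=1,
            mode="constant",
            cval=0.0,
            prefilter=False,
        )
        return out.reshape(out_shape)
    raise ValueError(f"unknown interpolation {interp!r}")


def resample(
    source: Volume,
    transform: FrameTransform,
    target_grid,
    interp: str = "trilinear",
) -> Volume:
    """Resample ``source`` onto ``target_grid`` through a world transform.

    ``transform`` maps *target-space world* coordinates to *source-space
    world* coordinates (for reverse-normalizing a template-space atlas onto a
    native grid this is exactly the native->template normalization). Each
    target voxel centre is mapped into the source and sampled; voxels falling
    outside the source field of view become 0. Label and mask volumes must use
    nearest-neighbour interpolation — categorical codes cannot be averaged.
    """
    if source.role in ("label", "mask") and interp != "nearest":
        raise ValueError(f"{source.role} volumes require nearest-neighbour resampling")
    shape, tgt_affine, tgt_v2w = _target_geometry(target_grid)
    if transform.source != tgt_v2w.target or transform.target != source.voxel_to_world.target:
        raise FrameError(
            f"resample needs a {tgt_v2w.target}->{source.voxel_to_world.target} "
            f"world transform, got {transform.source}->{transform.target}"
        )
    # target voxel -> target world -> source world -> source voxel
    m = np.linalg.inv(source.affine) @ transform.matrix @ tgt_affine
    idx = np.indices(shape, dtype=float)
    pts = np.moveaxis(idx, 0, -1).reshape(-1, 3)
    src_idx = pts @ m[:3, :3].T + m[:3, 3]
    values = _sample(source, src_idx, shape, interp)
    out_v2w = FrameTransform(tgt_affine, Frame.VOXEL, tgt_v2w.target)
    return Volume(values, out_v2w, role=source.role)


def apply_displacement_field(
    source: Volume, df: DeformationField, interp: str = "trilinear"
) -> Volume:
    """Resample ``source`` through a dense displacement field.

    Same contract as :func:`resample` with per-voxel source-space world
    coordinates ``target_world + displacement``. The field geometry defines
    the target grid.
    """
    if source.role in ("label", "mask") and interp != "nearest":
        raise ValueError(f"{source.role} volumes require nearest-neighbour resampling")
    if not np.all(np.isfinite(df.displacements)):
        raise ValueError("displacement field contains non-finite vectors")
    src_world = df.source_coordinates_world().reshape(-1, 3)
    inv_src = np.linalg.inv(source.affine)
    src_idx = src_world @ inv_src[:3, :3].T + inv_src[:3, 3]
    values = _sample(source, src_idx, df.shape, interp)
    out_v2w = FrameTransform(
        df.voxel_to_world.matrix, Frame.VOXEL, df.voxel_to_world.target
    )
    return Volume(values, out_v2w, role=source.role)


# ---------------------------------------------------------------------------
# normalization QC
# ---------------------------------------------------------------------------


@dataclass
class QCMetrics:
    """Skull-overlay style agreement between two head masks on one grid."""

    dice: float
    mean_boundary_distance_mm: float
    max_boundary_distance_mm: float
    threshold: float
    passed: bool


def _boundary(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1)
    )
    return mask & ~eroded


def normalization_qc(
    native_head_mask: Volume,
    template_head_mask_in_native: Volume,
    dice_threshold: float = 0.85,
) -> QCMetrics:
    """Quantify normalization quality by head-mask overlap.

    This is the automated counterpart of the visual skull-overlay check: a
    low Dice between the subject's head mask and the reverse-normalized
    template head mask signals a failed normalization.
    """
    a = native_head_mask
    b = template_head_mask_in_native
    if not a.same_grid(b):
        raise ValueError("QC masks must share one grid")
    am = a.values.astype(bool)
    bm = b.values.astype(bool)
    if not am.any() or not bm.any():
        raise ValueError("empty mask: cannot compute normalization QC")
    inter = float(np.logical_and(am, bm).sum())
    dice = 2.0 * inter / float(am.sum() + bm.sum())

    sampling = a.voxel_size
    dist_to_b = ndimage.distance_transform_edt(~_boundary(bm), sampling=sampling)
    surf_a = _boundary(am)
    dists = dist_to_b[surf_a]
    return QCMetrics(
        dice=dice,
        mean_boundary_distance_mm=float(dists.mean()),
        max_boundary_distance_mm=float(dists.max()),
        threshold=dice_threshold,
        passed=dice >= dice_threshold,
    )
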