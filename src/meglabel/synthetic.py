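"""Synthetic phantoms, toy atlases, transforms and dipole sets.

Everything the pipeline consumes — a native T1, a template, template-space
atlases with lookup tables, a MEG-MRI coregistration, dipole files and a
ground-truth label table — can be generated here from a seed, so the whole
package is testable end to end with no downloaded data and with *known*
correct answers at every stage.

The phantom is a concentric-ellipsoid head ("brain", CSF gap, "skull" shell,
"scalp" shell) with two asymmetric internal features that break rotational
symmetry, which makes the affine normalization identifiable. The toy atlas
partitions the brain into contiguous nearest-centroid regions and can leave an
interior core unlabeled to emulate white matter under a grey-matter
parcellation. Dipoles are planted at region-interior voxel centres (at least
one voxel from any boundary) and back-transformed into the HEAD frame, so
with the true transforms the pipeline must recover the planted label for
every accepted dipole — any miss is a pipeline bug, and under an *estimated*
normalization the registration error is the only possible error source.

Every generator is a pure function of its seed: re-generation is
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .formats import (
    Dipole,
    DipoleGroup,
    LookupTable,
    save_volume,
    write_coreg,
    write_dip,
    write_lookup_table,
    write_transform,
)
from .atlas import Atlas, reverse_normalize_atlas
from .geometry import Frame, FrameTransform, Volume, invert

__all__ = [
    "PhantomSpec",
    "SyntheticSubject",
    "make_phantom",
    "make_template",
    "make_toy_atlas",
    "make_ground_truth_transforms",
    "make_dipole_set",
    "make_subject_folder",
    "affine_from_params",
]

TEMPLATE_SEED = 1234  # the fixed "standard template" phantom


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity recipe for one phantom head.

    Radii are semi-axes in mm of the brain ellipsoid; shells are offsets from
    it. Defaults give a 64^3 grid at 2 mm isotropic (128 mm field of view)
    that comfortably contains the head.
    """

    seed: int
    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 2.0
    brain_radii_mm: tuple[float, float, float] = (40.0, 34.0, 30.0)
    csf_gap_mm: float = 3.0
    skull_thickness_mm: float = 6.0
    scalp_thickness_mm: float = 5.0
    level_brain: float = 100.0
    level_csf: float = 30.0
    level_skull: float = 20.0
    level_scalp: float = 70.0
    level_feature_bright: float = 150.0
    level_feature_dark: float = 45.0
    noise_sd: float = 0.0
    features: bool = True

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        fov_half = np.array(self.shape) * self.voxel_size_mm / 2.0
        outer = (
            np.array(self.brain_radii_mm)
            + self.csf_gap_mm
            + self.skull_thickness_mm
            + self.scalp_thickness_mm
        )
        if np.any(outer >= fov_half):
            raise ValueError(
                f"head (semi-axes {tuple(outer)}) does not fit in the "
                f"field of view (half-extent {tuple(fov_half)})"
            )


def _centered_affine(shape, voxel_size: float) -> np.ndarray:
    """RAS+ mm affine placing the grid centre at world (0, 0, 0)."""
    a = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    a[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * voxel_size
    return a


def _ellipsoid(coords_mm: np.ndarray, center: np.ndarray, radii: np.ndarray) -> np.ndarray:
    d = (coords_mm - center) / radii
    return np.einsum("...i,...i->...", d, d) <= 1.0


def make_phantom(spec: PhantomSpec, world_frame: Frame = Frame.WORLD):
    """Build the phantom T1 plus head and brain masks.

    Returns ``(t1, head_mask, brain_mask)`` as :class:`Volume` objects sharing
    one grid. With ``noise_sd=0`` voxel values take exactly the configured
    tissue levels.
    """
    rng = np.random.default_rng(spec.seed)
    affine = _centered_affine(spec.shape, spec.voxel_size_mm)
    v2w = FrameTransform(affine, Frame.VOXEL, world_frame)

    idx = np.indices(spec.shape, dtype=float)
    pts = np.moveaxis(idx, 0, -1)
    coords = pts @ affine[:3, :3].T + affine[:3, 3]

    brain_r = np.asarray(spec.brain_radii_mm)
    csf_r = brain_r + spec.csf_gap_mm
    skull_r = csf_r + spec.skull_thickness_mm
    scalp_r = skull_r + spec.scalp_thickness_mm
    center = np.zeros(3)

    brain = _ellipsoid(coords, center, brain_r)
    csf = _ellipsoid(coords, center, csf_r)
    skull = _ellipsoid(coords, center, skull_r)
    scalp = _ellipsoid(coords, center, scalp_r)

    t1 = np.zeros(spec.shape, dtype=float)
    t1[scalp] = spec.level_scalp
    t1[skull] = spec.level_skull
    t1[csf] = spec.level_csf
    t1[brain] = spec.level_brain

    if spec.features:
        # two off-centre blobs break mirror and rotational symmetry
        bright = _ellipsoid(coords, np.array([12.0, 9.0, -6.0]), np.array([9.0, 7.0, 7.0]))
        dark = _ellipsoid(coords, np.array([-10.0, -7.0, 8.0]), np.array([6.0, 6.0, 8.0]))
        t1[brain & bright] = spec.level_feature_bright
        t1[brain & dark] = spec.level_feature_dark

    if spec.noise_sd > 0:
        t1 = t1 + rng.normal(0.0, spec.noise_sd, size=spec.shape)

    t1_vol = Volume(t1, v2w, role="intensity")
    head_vol = Volume(scalp.astype(np.uint8), v2w, role="mask")
    brain_vol = Volume(brain.astype(np.uint8), v2w, role="mask")
    return t1_vol, head_vol, brain_vol


def make_template(noise_sd: float = 0.0):
    """The package's standard-space phantom (plays the MNI template's role)."""
    spec = PhantomSpec(seed=TEMPLATE_SEED, noise_sd=noise_sd)
    return make_phantom(spec, world_frame=Frame.TEMPLATE)


# ---------------------------------------------------------------------------
# toy atlas
# ---------------------------------------------------------------------------


def make_toy_atlas(
    brain_mask: Volume,
    k_regions: int,
    seed: int,
    unlabeled_core_fraction: float = 0.0,
    centroids_world: Optional[np.ndarray] = None,
    name: str = "toy",
) -> Atlas:
    """Partition a brain mask into k contiguous nearest-centroid regions.

    Region codes are 1..k with lookup names ``region_1..region_k``. With a
    positive ``unlabeled_core_fraction`` the deepest interior voxels (by
    distance to the mask boundary) are set to code 0, emulating the unlabeled
    white-matter core of a grey-matter atlas. Explicit seed centroids (world
    mm) may be supplied, e.g. mirrored pairs for symmetry checks.
    """
    if k_regions < 2:
        raise ValueError("k_regions must be >= 2")
    mask = brain_mask.values.astype(bool)
    vox = np.argwhere(mask)
    if k_regions > len(vox):
        raise ValueError(f"k_regions={k_regions} exceeds {len(vox)} brain voxels")
    world = brain_mask.voxel_to_world.apply(vox.astype(float))

    if centroids_world is None:
        rng = np.random.default_rng(seed)
        picks = rng.choice(len(vox), size=k_regions, replace=False)
        centroids_world = world[picks]
    else:
        centroids_world = np.asarray(centroids_world, dtype=float)
        if centroids_world.shape != (k_regions, 3):
            raise ValueError("centroids_world must have shape (k_regions, 3)")

    d2 = ((world[:, None, :] - centroids_world[None, :, :]) ** 2).sum(axis=2)
    assign = np.argmin(d2, axis=1) + 1  # codes 1..k

    labels = np.zeros(brain_mask.shape, dtype=np.int32)
    labels[tuple(vox.T)] = assign

    if unlabeled_core_fraction > 0:
        depth = ndimage.distance_transform_edt(mask, sampling=brain_mask.voxel_size)
        inside = depth[mask]
        thr = np.quantile(inside, 1.0 - unlabeled_core_fraction)
        core = mask & (depth > thr)
        labels[core] = 0

    lut = LookupTable(
        atlas_name=name,
        entries={c: f"region_{c}" for c in range(1, k_regions + 1)},
    )
    space = "template" if brain_mask.voxel_to_world.target == Frame.TEMPLATE else "native"
    return Atlas(
        name=name,
        labels=Volume(labels, brain_mask.voxel_to_world, role="label"),
        lookup=lut,
        space=space,
    )


# ---------------------------------------------------------------------------
# ground-truth transforms
# ---------------------------------------------------------------------------


def affine_from_params(
    translation_mm,
    rotation_deg,
    scale=(1.0, 1.0, 1.0),
    center=(0.0, 0.0, 0.0),
) -> np.ndarray:
    """4x4 affine: rotate (x, then y, then z) and scale about ``center``,
    then translate."""
    rx, ry, rz = np.deg2rad(rotation_deg)
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    rot = (
        np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        @ np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        @ np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    )
    linear = rot @ np.diag(np.asarray(scale, dtype=float))
    c = np.asarray(center, dtype=float)
    m = np.eye(4)
    m[:3, :3] = linear
    m[:3, 3] = np.asarray(translation_mm, dtype=float) + c - linear @ c
    return m


def make_ground_truth_transforms(
    seed: int,
    magnitude: float = 1.0,
    out_dir=None,
) -> tuple[FrameTransform, FrameTransform]:
    """Random-but-seeded normalization and coregistration ground truth.

    ``magnitude`` in [0, 1] scales the draw bounds (translations up to 10 mm,
    rotations up to 10 degrees, scales in 0.9-1.1; the coregistration is
    rigid). ``magnitude=0`` yields identities. When ``out_dir`` is given the
    canonical ``norm.txt`` and ``coreg.txt`` files are written there.
    """
    if not 0.0 <= magnitude <= 1.0:
        raise ValueError("magnitude must be in [0, 1]")
    rng = np.random.default_rng(seed)
    t_n = rng.uniform(-10, 10, 3) * magnitude
    r_n = rng.uniform(-10, 10, 3) * magnitude
    s_n = 1.0 + rng.uniform(-0.1, 0.1, 3) * magnitude
    norm = FrameTransform(
        affine_from_params(t_n, r_n, s_n), Frame.WORLD, Frame.TEMPLATE
    )
    t_c = rng.uniform(-10, 10, 3) * magnitude
    r_c = rng.uniform(-10, 10, 3) * magnitude
    coreg = FrameTransform(
        affine_from_params(t_c, r_c), Frame.HEAD, Frame.WORLD
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_transform(norm, out_dir / "norm.txt")
        write_coreg(coreg, out_dir / "coreg.txt", head_unit="mm")
    return norm, coreg


# ---------------------------------------------------------------------------
# dipole sets with known true labels
# ---------------------------------------------------------------------------


def make_dipole_set(
    atlas_native: Atlas,
    coreg: FrameTransform,
    n_per_region: int = 1,
    seed: int = 0,
    fit_stats_mode: str = "all_pass",
    task: str = "IED",
) -> tuple[DipoleGroup, dict[str, str]]:
    """Plant dipoles at region-interior voxel centres with known labels.

    Positions are snapped to voxel centres strictly interior to their region
    (>= 1 voxel from any boundary) and back-transformed through the inverse
    coregistration into the HEAD frame. In ``all_pass`` mode every dipole's
    fit statistics satisfy the sECD criteria; in ``mixed`` mode the first four
    dipoles each violate exactly one criterion (chi2, gof, cv, strength, in
    that order). Returns the group plus the truth table (dipole id -> planted
    region label).
    """
    if atlas_native.space != "native":
        raise ValueError("atlas must be in native space")
    if fit_stats_mode not in ("all_pass", "mixed"):
        raise ValueError("fit_stats_mode must be 'all_pass' or 'mixed'")
    rng = np.random.default_rng(seed)
    labels = atlas_native.labels.values
    v2w = atlas_native.labels.voxel_to_world
    inv_coreg = invert(coreg)

    placements: list[tuple[np.ndarray, str]] = []
    structure = ndimage.generate_binary_structure(3, 1)
    for code in sorted(atlas_native.lookup.codes()):
        region = labels == code
        if not region.any():
            raise ValueError(f"region code {code} is empty in atlas {atlas_native.name!r}")
        interior = ndimage.binary_erosion(region, structure=structure)
        pool = np.argwhere(interior if interior.any() else region)
        centroid = pool.mean(axis=0)
        order = np.argsort(((pool - centroid) ** 2).sum(axis=1), kind="stable")
        chosen = [pool[order[0]]]
        if n_per_region > 1:
            extra = rng.choice(len(pool), size=min(n_per_region - 1, len(pool)), replace=False)
            chosen.extend(pool[i] for i in extra)
        for voxel in chosen[:n_per_region]:
            placements.append((voxel, atlas_native.lookup[code]))

    dipoles: list[Dipole] = []
    truth: dict[str, str] = {}
    violations = ("chi2", "gof", "cv", "strength")
    for i, (voxel, label) in enumerate(placements):
        world = v2w.apply(voxel.astype(float))
        head = inv_coreg.apply(world)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        chi2 = float(rng.uniform(0.5, 1.5))
        gof = float(rng.uniform(85.0, 95.0))
        cv = float(rng.uniform(100.0, 800.0))
        q = float(rng.uniform(150.0, 450.0))
        if fit_stats_mode == "mixed" and i < len(violations):
            bad = violations[i]
            if bad == "chi2":
                chi2 = 2.5
            elif bad == "gof":
                gof = 70.0
            elif bad == "cv":
                cv = 1500.0
            else:
                q = 600.0
        did = f"{task}_{i + 1:03d}"
        dipoles.append(
            Dipole(
                id=did,
                begin_ms=10.0 * i,
                end_ms=10.0 * i + 5.0,
                position=head,
                moment=direction * q,
                q_nam=q,
                gof_pct=gof,
                chi2_reduced=chi2,
                conf_volume_mm3=cv,
            )
        )
        truth[did] = label
    return DipoleGroup(task=task, dipoles=dipoles), truth


# ---------------------------------------------------------------------------
# complete synthetic subject folder
# ---------------------------------------------------------------------------


@dataclass
class SyntheticSubject:
    """Paths and in-memory ground truth of one generated subject folder."""

    folder: Path
    t1: Volume
    head_mask: Volume
    template_t1: Volume
    template_head_mask: Volume
    atlas_template: Atlas
    atlas_native: Atlas
    norm: FrameTransform
    coreg: FrameTransform
    groups: list[DipoleGroup]
    truth: dict[str, str]
    truth_path: Path
    manifest_path: Path
    template_dir: Path


def make_subject_folder(
    out_dir,
    seed: int,
    k_regions: int = 5,
    n_per_region: int = 2,
    tasks: Sequence[str] = ("IED", "SEF"),
    fit_stats_mode: str = "all_pass",
    magnitude: float = 1.0,
    noise_sd: float = 2.0,
    unlabeled_core_fraction: float = 0.15,
) -> SyntheticSubject:
    """Generate a complete fake subject folder the pipeline can consume.

    Layout written under ``out_dir``: ``t1.nii``, ``coreg.txt``, ``norm.txt``
    (the true normalization), one ``<task>.dip`` per task, ``truth.tsv``
    (dipole id -> planted label), an ``atlases/`` bundle (label NIfTI +
    lookup table + manifest) in template space, and ``template/`` with the
    standard-space phantom T1 and head mask for built-in registration and
    skull-outline QC.

    The native T1 is the template phantom carried through the *inverse* of
    the ground-truth normalization (i.e. ``native(x) = template(norm(x))``)
    plus seeded Gaussian noise, so registering it back to the template should
    recover ``norm``.
    """
    from .registration import resample  # local import to avoid cycle at import time

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    template_t1, template_head, template_brain = make_template()
    norm, coreg = make_ground_truth_transforms(seed, magnitude=magnitude, out_dir=out_dir)

    native_grid = Volume(
        np.zeros(template_t1.shape, dtype=np.uint8),
        FrameTransform(template_t1.affine, Frame.VOXEL, Frame.WORLD),
        role="mask",
    )
    t1 = resample(template_t1, norm, native_grid, interp="trilinear")
    if noise_sd > 0:
        t1 = t1.with_values(t1.values + rng.normal(0.0, noise_sd, size=t1.shape))
    head_mask = resample(template_head, norm, native_grid, interp="nearest")

    atlas_template = make_toy_atlas(
        template_brain,
        k_regions=k_regions,
        seed=seed + 1,
        unlabeled_core_fraction=unlabeled_core_fraction,
    )
    atlas_native = reverse_normalize_atlas(atlas_template, t1, norm)

    groups: list[DipoleGroup] = []
    truth: dict[str, str] = {}
    for j, task in enumerate(tasks):
        group, ttable = make_dipole_set(
            atlas_native,
            coreg,
            n_per_region=n_per_region,
            seed=seed + 100 + j,
            fit_stats_mode=fit_stats_mode,
            task=task,
        )
        groups.append(group)
        truth.update(ttable)
        write_dip(group, out_dir / f"{task}.dip")

    save_volume(t1, out_dir / "t1.nii")
    save_volume(head_mask, out_dir / "head_mask.nii")

    atlas_dir = out_dir / "atlases"
    atlas_dir.mkdir(exist_ok=True)
    save_volume(atlas_template.labels, atlas_dir / "toy.nii")
    write_lookup_table(atlas_template.lookup, atlas_dir / "toy_lut.txt")
    manifest_path = atlas_dir / "manifest.txt"
    manifest_path.write_text(
        "# atlas bundle: name<TAB>volume<TAB>lookup\ntoy\ttoy.nii\ttoy_lut.txt\n",
        encoding="utf-8",
    )

    template_dir = out_dir / "template"
    template_dir.mkdir(exist_ok=True)
    save_volume(template_t1, template_dir / "t1.nii")
    save_volume(template_head, template_dir / "head_mask.nii")

    truth_path = out_dir / "truth.tsv"
    truth_path.write_text(
        "# dipole_id\ttrue_label\n"
        + "".join(f"{k}\t{v}\n" for k, v in sorted(truth.items())),
        encoding="utf-8",
    )

    return SyntheticSubject(
        folder=out_dir,
        t1=t1,
        head_mask=head_mask,
        template_t1=template_t1,
        template_head_mask=template_head,
        atlas_template=atlas_template,
        atlas_native=atlas_native,
        norm=norm,
        coreg=coreg,
        groups=groups,
        truth=truth,
        truth_path=truth_path,
        manifest_path=manifest_path,
        template_dir=template_dir,
    )
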