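"""Atlas handling: reverse-normalization, label lookup and skull outlines.

An :class:`Atlas` binds an integer-coded label volume to its lookup table.
Atlases ship in template (MNI-like) space; :func:`reverse_normalize_atlas`
carries them onto the subject's native grid through the saved normalization,
after which :func:`lookup` answers "what anatomical region is at this voxel?"
— the operation at the heart of dipole labeling.

A code of 0, or a code with no lookup entry, means *unlabeled*: under a grey
matter parcellation this is the normal outcome for dipoles sitting in white
matter or CSF, not an error. :func:`nearest_labeled` automates the manual
"drag the cursor to the nearest grey matter" verification step by searching
for the closest labeled voxel in world millimetres within a bounded radius.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
from scipy import ndimage

from .formats import LookupTable, load_volume, read_lookup_table
from .geometry import DeformationField, Frame, FrameTransform, Volume
from .registration import apply_displacement_field, resample

__all__ = [
    "Atlas",
    "LabelResult",
    "reverse_normalize_atlas",
    "lookup",
    "nearest_labeled",
    "skull_outline",
    "query_all",
    "read_atlas_manifest",
]

Normalization = Union[FrameTransform, DeformationField]


@dataclass
class Atlas:
    """A named, integer-coded label volume plus its code->name lookup table."""

    name: str
    labels: Volume
    lookup: LookupTable
    space: str = "template"  # "template" | "native"

    def __post_init__(self) -> None:
        if self.labels.role != "label":
            raise ValueError("atlas volume must have role='label'")
        if self.space not in ("template", "native"):
            raise ValueError(f"atlas space must be template|native, got {self.space!r}")
        present = set(np.unique(self.labels.values)) - {0}
        missing = present - self.lookup.codes()
        if missing:
            # codes without names are reported, not fatal
            warnings.warn(
                f"atlas {self.name!r}: {len(missing)} code(s) have no lookup entry: "
                f"{sorted(missing)[:10]}",
                stacklevel=2,
            )


@dataclass(frozen=True)
class LabelResult:
    """Outcome of one label query against one atlas.

    ``status`` is ``labeled`` (code >= 1 with a lookup entry), ``unlabeled``
    (code 0 or no entry — typically white matter/CSF under a grey-matter
    atlas), ``out_of_fov`` (query voxel outside the atlas grid) or
    ``not_found`` (nearest-labeled search exhausted its radius).
    ``distance_mm`` is 0 unless the nearest-labeled fallback was used.
    """

    atlas_name: str
    status: str
    code: int = 0
    label: str = ""
    distance_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.status not in ("labeled", "unlabeled", "out_of_fov", "not_found"):
            raise ValueError(f"bad status {self.status!r}")
        if (self.status == "labeled") != (self.code >= 1 and bool(self.label)):
            raise ValueError("status 'labeled' requires code >= 1 and a label name")
        if self.distance_mm < 0:
            raise ValueError("distance_mm must be >= 0")


def reverse_normalize_atlas(
    atlas: Atlas, native: Volume, norm: Normalization
) -> Atlas:
    """Carry a template-space atlas onto the native grid.

    ``norm`` is the saved normalization: either the WORLD(native)->TEMPLATE
    affine, or a displacement field defined on the native grid pointing into
    template space. Labels are resampled nearest-neighbour (categorical codes)
    and the lookup table is carried unchanged.
    """
    if atlas.space != "template":
        raise ValueError(f"atlas {atlas.name!r} is already in native space")
    if isinstance(norm, FrameTransform):
        if norm.source != Frame.WORLD or norm.target != Frame.TEMPLATE:
            raise ValueError(
                f"normalization must map WORLD->TEMPLATE, got {norm.source}->{norm.target}"
            )
        labels = resample(atlas.labels, norm, native, interp="nearest")
    elif isinstance(norm, DeformationField):
        labels = apply_displacement_field(atlas.labels, norm, interp="nearest")
    else:
        raise TypeError(f"unsupported normalization type {type(norm).__name__}")
    return Atlas(name=atlas.name, labels=labels, lookup=atlas.lookup, space="native")


def lookup(atlas: Atlas, voxel) -> LabelResult:
    """Anatomical label at one integer voxel index of a native-space atlas."""
    if atlas.space != "native":
        raise ValueError(f"atlas {atlas.name!r} must be in native space for lookup")
    idx = np.asarray(voxel, dtype=int)
    shape = atlas.labels.shape
    if np.any(idx < 0) or np.any(idx >= np.asarray(shape)):
        return LabelResult(atlas_name=atlas.name, status="out_of_fov")
    code = int(atlas.labels.values[tuple(idx)])
    if code == 0 or code not in atlas.lookup:
        return LabelResult(atlas_name=atlas.name, status="unlabeled")
    return LabelResult(
        atlas_name=atlas.name, status="labeled", code=code, label=atlas.lookup[code]
    )


def nearest_labeled(atlas: Atlas, voxel, max_radius_mm: float = 10.0) -> LabelResult:
    """Closest labeled voxel (Euclidean world distance) within a radius.

    Ties are broken deterministically: smaller distance, then smaller code,
    then lexicographically smaller voxel index. Returns status ``not_found``
    when no labeled voxel lies within ``max_radius_mm``.
    """
    if max_radius_mm < 0:
        raise ValueError("max_radius_mm must be >= 0")
    direct = lookup(atlas, voxel)
    if direct.status == "labeled":
        return direct

    idx = np.asarray(voxel, dtype=int)
    shape = np.asarray(atlas.labels.shape)
    vox_size = atlas.labels.voxel_size
    half = np.ceil(max_radius_mm / vox_size).astype(int) + 1
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, shape)
    if np.any(lo >= hi):
        return LabelResult(atlas_name=atlas.name, status="not_found")

    block = atlas.labels.values[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    valid = sorted(atlas.lookup.codes())
    labeled = np.isin(block, valid)
    if not labeled.any():
        return LabelResult(atlas_name=atlas.name, status="not_found")

    cand_idx = np.argwhere(labeled) + lo
    codes = atlas.labels.values[cand_idx[:, 0], cand_idx[:, 1], cand_idx[:, 2]]
    p_query = atlas.labels.voxel_to_world.apply(idx.astype(float))
    p_cand = atlas.labels.voxel_to_world.apply(cand_idx.astype(float))
    dists = np.linalg.norm(p_cand - p_query, axis=1)
    within = dists <= max_radius_mm
    if not within.any():
        return LabelResult(atlas_name=atlas.name, status="not_found")
    cand_idx, codes, dists = cand_idx[within], codes[within], dists[within]
    order = np.lexsort(
        (cand_idx[:, 2], cand_idx[:, 1], cand_idx[:, 0], codes, dists)
    )
    best = order[0]
    code = int(codes[best])
    return LabelResult(
        atlas_name=atlas.name,
        status="labeled",
        code=code,
        label=atlas.lookup[code],
        distance_mm=float(dists[best]),
    )


def skull_outline(
    template_head_mask: Volume, native: Volume, norm: Normalization
) -> Volume:
    """One-voxel-thick head/skull boundary on the native grid.

    The template head mask is reverse-normalized onto the native grid
    (nearest-neighbour) and the outline is the mask minus its one-voxel
    erosion. An empty reverse-normalized mask signals a failed normalization
    and raises.
    """
    if template_head_mask.role != "mask":
        raise ValueError("template head mask must have role='mask'")
    if isinstance(norm, FrameTransform):
        mask = resample(template_head_mask, norm, native, interp="nearest")
    elif isinstance(norm, DeformationField):
        mask = apply_displacement_field(template_head_mask, norm, interp="nearest")
    else:
        raise TypeError(f"unsupported normalization type {type(norm).__name__}")
    m = mask.values.astype(bool)
    if not m.any():
        raise ValueError(
            "reverse-normalized head mask is empty: normalization likely failed"
        )
    eroded = ndimage.binary_erosion(
        m, structure=ndimage.generate_binary_structure(3, 1)
    )
    outline = (m & ~eroded).astype(np.uint8)
    return Volume(outline, mask.voxel_to_world, role="mask")


def query_all(atlases: Sequence[Atlas], voxel) -> list[LabelResult]:
    """Label one voxel against every configured atlas, order preserved."""
    return [lookup(a, voxel) for a in atlases]


def read_atlas_manifest(path, space: str = "template") -> list[Atlas]:
    """Load an atlas bundle from a manifest file.

    The manifest lives in a directory of paired NIfTI + lookup-table files;
    each non-comment line is ``<name>\\t<volume_file>\\t<lookup_file>`` and the
    line order fixes the display/query order.
    """
    path = Path(path)
    base = path.parent
    atlases: list[Atlas] = []
    world = Frame.TEMPLATE if space == "template" else Frame.WORLD
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split("\t")]
        if len(parts) != 3:
            raise ValueError(
                f"{path}:{lineno}: expected 'name<TAB>volume<TAB>lookup', got {line!r}"
            )
        name, vol_file, lut_file = parts
        labels = load_volume(base / vol_file, role="label", world_frame=world)
        lut = read_lookup_table(base / lut_file, atlas_name=name)
        atlases.append(Atlas(name=name, labels=labels, lookup=lut, space=space))
    if not atlases:
        raise ValueError(f"{path}: manifest lists no atlases")
    return atlases
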