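"""Static tri-planar QC snapshots.

Renders the classic clinical layout — coronal top-left, sagittal top-right,
axial bottom-left — through a crosshair voxel, with the skull outline and
dipole markers overlaid. In radiological orientation the left-right axis of
the axial and coronal panels is mirrored (patient right appears on the
viewer's left); the sagittal panel is unaffected. These images are a QC
artifact, not a measurement surface: the only testable geometry is marker
placement, which :func:`triplanar_panels` exposes without touching pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .geometry import Volume

__all__ = ["PanelSpec", "triplanar_panels", "render_triplanar"]

_ORIENTATIONS = ("neurological", "radiological")

# (panel name, slicing axis, horizontal data axis, vertical data axis, mirrored?)
_PANELS = (
    ("coronal", 1, 0, 2),   # slice y; display x horizontally, z vertically
    ("sagittal", 0, 1, 2),  # slice x; display y horizontally, z vertically
    ("axial", 2, 0, 1),     # slice z; display x horizontally, y vertically
)
_MIRRORABLE = {"coronal", "axial"}  # panels whose horizontal axis is left-right


@dataclass
class PanelSpec:
    """One rendered panel: its 2-D image plus marker pixel coordinates.

    ``crosshair`` and ``markers`` are (horizontal, vertical) pixel coordinates
    in the panel's display frame, after any radiological mirroring.
    """

    name: str
    image: np.ndarray
    outline: Optional[np.ndarray]
    crosshair: tuple[float, float]
    markers: list[tuple[float, float]]
    extent_h: int


def _panel_coords(voxel, h_axis: int, v_axis: int, mirror: bool, n_h: int):
    h = float(voxel[h_axis])
    if mirror:
        h = (n_h - 1) - h
    return h, float(voxel[v_axis])


def triplanar_panels(
    t1: Volume,
    crosshair_voxel,
    outline: Optional[Volume] = None,
    dipole_voxels: Optional[Sequence] = None,
    orientation: str = "neurological",
) -> dict[str, PanelSpec]:
    """Extract the three orthogonal slices and marker geometry."""
    if orientation not in _ORIENTATIONS:
        raise ValueError(f"orientation must be one of {_ORIENTATIONS}")
    ch = np.asarray(crosshair_voxel, dtype=int)
    shape = np.asarray(t1.shape)
    if np.any(ch < 0) or np.any(ch >= shape):
        raise ValueError(f"crosshair voxel {tuple(ch)} outside volume {tuple(shape)}")
    dipoles = [np.asarray(v, dtype=float) for v in (dipole_voxels or [])]

    panels: dict[str, PanelSpec] = {}
    for name, s_axis, h_axis, v_axis in _PANELS:
        sl = [slice(None)] * 3
        sl[s_axis] = int(ch[s_axis])
        img = np.asarray(t1.values[tuple(sl)], dtype=float)
        out = None
        if outline is not None:
            out = np.asarray(outline.values[tuple(sl)], dtype=float)
        if h_axis > v_axis:  # keep (h, v) index order consistent
            img = img.T
            out = out.T if out is not None else None
        mirror = orientation == "radiological" and name in _MIRRORABLE
        n_h = t1.shape[h_axis]
        if mirror:
            img = img[::-1, :]
            out = out[::-1, :] if out is not None else None
        cross = _panel_coords(ch, h_axis, v_axis, mirror, n_h)
        markers = [
            _panel_coords(v, h_axis, v_axis, mirror, n_h)
            for v in dipoles
            if int(round(v[s_axis])) == int(ch[s_axis])
        ]
        panels[name] = PanelSpec(
            name=name,
            image=img,
            outline=out,
            crosshair=cross,
            markers=markers,
            extent_h=n_h,
        )
    return panels


def render_triplanar(
    t1: Volume,
    crosshair_voxel,
    out_path,
    outline: Optional[Volume] = None,
    dipole_voxels: Optional[Sequence] = None,
    orientation: str = "neurological",
    title: str = "",
) -> dict[str, PanelSpec]:
    """Write the tri-planar QC snapshot PNG; returns the panel geometry."""
    panels = triplanar_panels(t1, crosshair_voxel, outline, dipole_voxels, orientation)
    fig, axes = plt.subplots(2, 2, figsize=(8, 8))
    layout = {"coronal": axes[0, 0], "sagittal": axes[0, 1], "axial": axes[1, 0]}
    axes[1, 1].axis("off")
    if title:
        fig.suptitle(title)
    for name, ax in layout.items():
        p = panels[name]
        # imshow with origin='lower': rows = vertical axis -> transpose (h, v)
        ax.imshow(p.image.T, origin="lower", cmap="gray", interpolation="nearest")
        if p.outline is not None:
            masked = np.ma.masked_where(p.outline.T == 0, p.outline.T)
            ax.imshow(masked, origin="lower", cmap="autumn", interpolation="nearest")
        ax.axvline(p.crosshair[0], color="cyan", lw=0.6)
        ax.axhline(p.crosshair[1], color="cyan", lw=0.6)
        for mx, my in p.markers:
            ax.plot(mx, my, "o", color="yellow", ms=4)
        ax.set_title(f"{name} ({orientation})", fontsize=9)
        ax.set_xticks([])
        ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(Path(out_path), dpi=100)
    plt.close(fig)
    return panels
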