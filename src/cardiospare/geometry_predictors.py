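"""Anatomical predictors of cardiac sparing: PTV size, CC distance, 3D
distance, and the in-field overlap volume histogram (iOVH).

All distances are Euclidean between voxel centers, in physical mm, honoring
anisotropic spacing.  The iOVH expands the PTV's axial (in-plane) projection
and measures the overlapped fraction of a cardiac substructure, counting only
substructure voxels whose CC coordinate lies within a slab extending a
penumbra margin (default 6.4 mm) beyond the PTV's CC extent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumetric_core import PatientBundle, StructureMask, _check_same_lattice, volume_cc


@dataclass(frozen=True)
class IOVHParams:
    """iOVH construction parameters (mm)."""

    slab_margin_mm: float = 6.4
    step_mm: float = 1.0
    max_radius_mm: float | None = None   # default: in-plane lattice diagonal
    per_slice: bool = False              # sensitivity alternative, see iovh()

    def __post_init__(self) -> None:
        if self.slab_margin_mm < 0:
            raise ValueError("slab margin must be >= 0 mm")
        if self.step_mm <= 0:
            raise ValueError("expansion step must be > 0 mm")


@dataclass(frozen=True)
class IOVHCurve:
    """Distance-expansion → overlapped-CS-volume-fraction curve."""

    ptv_label: str
    cs_label: str
    radii_mm: np.ndarray
    overlap_fraction: np.ndarray   # of *total* CS volume
    in_field_fraction: float       # in-slab CS volume / total CS volume

    @property
    def plateau(self) -> float:
        return float(self.overlap_fraction[-1])


def _require_nonempty(*masks: StructureMask) -> None:
    for m in masks:
        if m.voxel_count == 0:
            raise ValueError(f"structure {m.label!r} is empty")


def _z_extent_mm(mask: StructureMask) -> tuple[float, float]:
    zs = mask.lattice.axis_centers(2)
    present = mask.voxels.any(axis=(0, 1))
    z = zs[present]
    return float(z.min()), float(z.max())


def cc_distance(ptv: StructureMask, cs: StructureMask) -> float:
    """Cranio-caudal gap (mm) between the CC-extent intervals of two masks.

    Zero when the closed intervals overlap or touch.
    """
    _check_same_lattice(ptv, cs)
    _require_nonempty(ptv, cs)
    a_lo, a_hi = _z_extent_mm(ptv)
    b_lo, b_hi = _z_extent_mm(cs)
    return max(0.0, max(a_lo, b_lo) - min(a_hi, b_hi))


def distance_to_mask_mm(mask: StructureMask) -> np.ndarray:
    """Exact Euclidean distance (mm) from every voxel center to the nearest
    mask voxel center (0 inside the mask)."""
    return ndimage.distance_transform_edt(~mask.voxels, sampling=mask.lattice.spacing)


def distance_3d(ptv: StructureMask, cs: StructureMask) -> float:
    """Shortest 3D center-to-center distance (mm) between two masks; 0 if they
    intersect."""
    _check_same_lattice(ptv, cs)
    _require_nonempty(ptv, cs)
    dist = distance_to_mask_mm(ptv)
    return float(dist[cs.voxels].min())


def _inplane_distance_to_projection(ptv: StructureMask) -> np.ndarray:
    """2D distance map (mm) to the PTV's axial projection, per (x, y)."""
    proj = ptv.voxels.any(axis=2)
    if proj.all():
        return np.zeros(proj.shape)
    return ndimage.distance_transform_edt(~proj, sampling=ptv.lattice.spacing[:2])


def iovh(ptv: StructureMask, cs: StructureMask, params: IOVHParams | None = None) -> IOVHCurve:
    """In-field overlap volume histogram of a cardiac substructure.

    The in-field slab spans ``[z_min(PTV) − margin, z_max(PTV) + margin]``
    (voxel-center z, boundary inclusive).  For every CS voxel inside the slab
    the in-plane distance to the PTV's axial projection is computed (Δz
    ignored); the curve value at radius r is the volume fraction of the *whole*
    CS whose in-slab voxels lie within r.  A CS entirely outside the slab
    yields a valid all-zero curve.

    With ``params.per_slice`` the expansion is restricted to PTV voxels on the
    same slice (no overlap possible on slices beyond the PTV) — kept as a
    sensitivity alternative to the projection reading.
    """
    params = params or IOVHParams()
    _check_same_lattice(ptv, cs)
    _require_nonempty(ptv, cs)
    lat = ptv.lattice

    z_lo, z_hi = _z_extent_mm(ptv)
    zs = lat.axis_centers(2)
    in_slab_z = (zs >= z_lo - params.slab_margin_mm) & (zs <= z_hi + params.slab_margin_mm)
    cs_in_slab = cs.voxels & in_slab_z[None, None, :]

    rmax = params.max_radius_mm
    if rmax is None:
        nx, ny = lat.shape[:2]
        rmax = float(np.hypot(nx * lat.spacing[0], ny * lat.spacing[1]))
    radii = np.arange(0.0, rmax + params.step_mm / 2, params.step_mm)

    n_cs = cs.voxel_count
    in_field = cs_in_slab.sum() / n_cs
    if not cs_in_slab.any():
        return IOVHCurve(ptv.label, cs.label, radii, np.zeros_like(radii), 0.0)

    if params.per_slice:
        dist_map = np.full(lat.shape, np.inf)
        for k in range(lat.shape[2]):
            sl = ptv.voxels[:, :, k]
            if sl.any():
                dist_map[:, :, k] = ndimage.distance_transform_edt(
                    ~sl, sampling=lat.spacing[:2]
                )
        d = dist_map[cs_in_slab]
    else:
        d2 = _inplane_distance_to_projection(ptv)
        ix, iy, _ = np.nonzero(cs_in_slab)
        d = d2[ix, iy]

    counts = np.searchsorted(np.sort(d), radii, side="right")
    fraction = counts / n_cs
    return IOVHCurve(ptv.label, cs.label, radii, fraction, float(in_field))


def predictor_table(
    cohort: list[PatientBundle],
    cs_labels: tuple[str, ...],
    params: IOVHParams | None = None,
) -> pd.DataFrame:
    """Per-patient geometric predictors, one row per patient.

    Columns: ``ptv_cc`` plus, per CS, ``cc_mm_<cs>``, ``d3d_mm_<cs>`` and
    ``infield_<cs>`` (in-field volume fraction).  A missing CS leaves NaN.
    """
    from .volumetric_core import base_of_heart  # local to avoid cycle at import

    rows = []
    for bundle in cohort:
        ptv = bundle.masks["PTV"]
        row: dict[str, object] = {
            "patient_id": bundle.patient_id,
            "ptv_cc": volume_cc(ptv),
        }
        dist = distance_to_mask_mm(ptv)
        for cs_label in cs_labels:
            mask = bundle.masks.get(cs_label)
            if mask is None and cs_label == "base_of_heart":
                try:
                    mask = base_of_heart(bundle.masks)
                except ValueError:
                    mask = None
            if mask is None or mask.voxel_count == 0:
                row[f"cc_mm_{cs_label}"] = np.nan
                row[f"d3d_mm_{cs_label}"] = np.nan
                row[f"infield_{cs_label}"] = np.nan
                continue
            row[f"cc_mm_{cs_label}"] = cc_distance(ptv, mask)
            row[f"d3d_mm_{cs_label}"] = float(dist[mask.voxels].min())
            row[f"infield_{cs_label}"] = iovh(ptv, mask, params).in_field_fraction
        rows.append(row)
    return pd.DataFrame(rows).set_index("patient_id")


def iovh_long_table(
    cohort: list[PatientBundle],
    cs_labels: tuple[str, ...],
    params: IOVHParams | None = None,
) -> pd.DataFrame:
    """Long-format iOVH curves: (patient_id, cs, radius_mm, overlap_fraction)."""
    frames = []
    for bundle in cohort:
        ptv = bundle.masks["PTV"]
        for cs_label in cs_labels:
            mask = bundle.masks.get(cs_label)
            if mask is None or mask.voxel_count == 0:
                continue
            curve = iovh(ptv, mask, params)
            frames.append(
                pd.DataFrame(
                    {
                        "patient_id": bundle.patient_id,
                        "cs": cs_label,
                        "radius_mm": curve.radii_mm,
                        "overlap_fraction": curve.overlap_fraction,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


__all__ = [
    "IOVHCurve",
    "IOVHParams",
    "cc_distance",
    "distance_3d",
    "distance_to_mask_mm",
    "iovh",
    "iovh_long_table",
    "predictor_table",
]
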