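"""Lattice-aware binary structure masks and dose grids.

Conventions
-----------
Arrays are indexed ``[x, y, z]`` with ``z`` the cranio-caudal (CC) axis and
``x``/``y`` in-plane (axial).  All physical coordinates refer to *voxel
centers*: the center of voxel ``(i, j, k)`` sits at
``origin + spacing * (i, j, k)`` in mm.  Masks and dose grids participating
in one analysis must share one :class:`Lattice`.

On disk a patient is a directory of NIfTI volumes (one per structure, one
per plan dose) plus a ``patient.json`` sidecar::

    {"patient_id": "...",
     "plans": [{"label": "noncs", "dose_file": "dose_noncs.nii.gz",
                "n_fractions": 8, "dose_per_fraction": 7.5}],
     "structures": {"PTV": "PTV.nii.gz", ...},
     "waivers": []}
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger("cardiospare")

#: Controlled structure vocabulary.  Unknown labels warn but are accepted.
KNOWN_STRUCTURES = frozenset(
    {
        "PTV",
        "GTV",
        "heart",
        "left_atrium",
        "left_ventricle",
        "right_ventricle",
        "right_atrium",
        "ascending_aorta",
        "base_of_heart",
        "aortic_valve",
        "coronary_sinus",
        "inferior_vena_cava",
        "superior_vena_cava",
        "pulmonary_artery",
        "pulmonary_veins",
        "spinal_cord",
        "esophagus",
        "lungs",
        "trachea",
    }
)

#: The five constrained cardiac substructures (left atrium, left ventricle,
#: right ventricle, whole heart, base of heart = right atrium ∪ ascending
#: aorta).  Superior vena cava and pulmonary artery constraints are excluded.
CONSTRAINED_CS = (
    "left_atrium",
    "left_ventricle",
    "right_ventricle",
    "heart",
    "base_of_heart",
)

PLAN_NONCS = "noncs"
PLAN_CSP = "csp"


class LatticeMismatchError(ValueError):
    """Two fields do not live on the same voxel lattice."""


class MissingStructureError(ValueError):
    """A required structure is absent from a patient directory."""


@dataclass(frozen=True)
class Lattice:
    """Regular voxel grid: shape (nx, ny, nz), spacing/origin in mm."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 3.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError(f"lattice shape must be three ints >= 1, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"lattice spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def axis_centers(self, axis: int) -> np.ndarray:
        """Physical voxel-center coordinates (mm) along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def center_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable (nx,1,1)/(1,ny,1)/(1,1,nz) center-coordinate grids."""
        xs = self.axis_centers(0)[:, None, None]
        ys = self.axis_centers(1)[None, :, None]
        zs = self.axis_centers(2)[None, None, :]
        return xs, ys, zs

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag((*self.spacing, 1.0))
        aff[:3, 3] = self.origin
        return aff

    def __eq__(self, other: object) -> bool:  # tolerant float compare
        if not isinstance(other, Lattice):
            return NotImplemented
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=1e-6)
            and np.allclose(self.origin, other.origin, atol=1e-4)
        )

    def __hash__(self) -> int:
        return hash(self.shape)


def _check_same_lattice(a: "StructureMask | DoseGrid", b: "StructureMask | DoseGrid") -> None:
    if a.lattice != b.lattice:
        raise LatticeMismatchError(
            f"incompatible lattices: {a.lattice.shape}/{a.lattice.spacing} vs "
            f"{b.lattice.shape}/{b.lattice.spacing}"
        )


@dataclass(frozen=True)
class StructureMask:
    """Binary voxel mask of one delineated structure."""

    lattice: Lattice
    voxels: np.ndarray
    label: str

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("structure label must be nonempty")
        vox = np.asarray(self.voxels, dtype=bool)
        if vox.shape != self.lattice.shape:
            raise ValueError(
                f"mask shape {vox.shape} does not match lattice {self.lattice.shape}"
            )
        object.__setattr__(self, "voxels", vox)
        if self.label not in KNOWN_STRUCTURES:
            warnings.warn(
                f"structure label {self.label!r} is not in the controlled vocabulary",
                stacklevel=3,
            )

    @property
    def voxel_count(self) -> int:
        return int(self.voxels.sum())

    def indices(self) -> np.ndarray:
        """(N, 3) integer voxel indices of the mask."""
        return np.argwhere(self.voxels)

    def coordinates_mm(self) -> np.ndarray:
        """(N, 3) physical voxel-center coordinates (mm)."""
        idx = self.indices().astype(float)
        return np.asarray(self.lattice.origin) + idx * np.asarray(self.lattice.spacing)


@dataclass(frozen=True)
class DoseGrid:
    """Scalar dose field in Gy accumulated over the full course."""

    lattice: Lattice
    dose: np.ndarray
    plan_label: str = PLAN_NONCS

    def __post_init__(self) -> None:
        d = np.asarray(self.dose, dtype=np.float64)
        if d.shape != self.lattice.shape:
            raise ValueError(f"dose shape {d.shape} does not match lattice {self.lattice.shape}")
        if not np.all(np.isfinite(d)):
            raise ValueError("dose grid contains non-finite values")
        if d.min() < 0:
            raise ValueError(f"dose grid contains negative dose (min {d.min():g} Gy)")
        object.__setattr__(self, "dose", d)


@dataclass(frozen=True)
class FractionationScheme:
    """Uniform fractionation: total course dose = n_fractions × dose_per_fraction."""

    n_fractions: int
    dose_per_fraction: float

    def __post_init__(self) -> None:
        if int(self.n_fractions) < 1:
            raise ValueError("n_fractions must be a positive integer")
        if self.dose_per_fraction <= 0:
            raise ValueError("dose_per_fraction must be > 0 Gy")
        object.__setattr__(self, "n_fractions", int(self.n_fractions))
        object.__setattr__(self, "dose_per_fraction", float(self.dose_per_fraction))

    @property
    def total_dose(self) -> float:
        return self.n_fractions * self.dose_per_fraction


@dataclass
class PatientBundle:
    """Everything loaded for one patient: masks, plan doses, schemes, waivers."""

    patient_id: str
    masks: dict[str, StructureMask]
    doses: dict[str, DoseGrid] = field(default_factory=dict)
    schemes: dict[str, FractionationScheme] = field(default_factory=dict)
    waivers: tuple[str, ...] = ()

    @property
    def lattice(self) -> Lattice:
        return next(iter(self.masks.values())).lattice

    def plan_labels(self) -> tuple[str, ...]:
        return tuple(self.doses)


# ---------------------------------------------------------------------------
# set algebra and volume accounting
# ---------------------------------------------------------------------------

def volume_cc(mask: StructureMask) -> float:
    """Structure volume in cm³ (voxel count × voxel volume)."""
    return mask.voxel_count * mask.lattice.voxel_volume_cc


def union(a: StructureMask, b: StructureMask, label: str | None = None) -> StructureMask:
    """Voxelwise OR of two masks on the same lattice."""
    _check_same_lattice(a, b)
    return StructureMask(a.lattice, a.voxels | b.voxels, label or a.label)


def intersection(a: StructureMask, b: StructureMask, label: str | None = None) -> StructureMask:
    """Voxelwise AND of two masks on the same lattice."""
    _check_same_lattice(a, b)
    return StructureMask(a.lattice, a.voxels & b.voxels, label or a.label)


def base_of_heart(masks: dict[str, StructureMask]) -> StructureMask:
    """Base of the heart: union of the right atrium and the ascending aorta."""
    missing = [s for s in ("right_atrium", "ascending_aorta") if s not in masks]
    if missing:
        raise MissingStructureError(
            f"cannot derive base_of_heart, missing: {', '.join(missing)}"
        )
    return union(masks["right_atrium"], masks["ascending_aorta"], label="base_of_heart")


# ---------------------------------------------------------------------------
# NIfTI + sidecar I/O
# ---------------------------------------------------------------------------

SIDECAR_NAME = "patient.json"


def _lattice_from_nifti(img: nib.Nifti1Image) -> Lattice:
    aff = img.affine
    spacing = tuple(float(s) for s in np.abs(np.diag(aff)[:3]))
    origin = tuple(float(o) for o in aff[:3, 3])
    return Lattice(tuple(int(n) for n in img.shape[:3]), spacing, origin)


def _write_nifti(path: Path, lattice: Lattice, data: np.ndarray) -> None:
    img = nib.Nifti1Image(np.asarray(data), lattice.affine)
    img.header.set_zooms(lattice.spacing)
    nib.save(img, str(path))


def write_patient(bundle: PatientBundle, dir_path: str | Path) -> Path:
    """Write a patient bundle as NIfTI volumes + JSON sidecar; returns the dir."""
    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    structures: dict[str, str] = {}
    for name, mask in bundle.masks.items():
        fname = f"{name}.nii.gz"
        _write_nifti(out / fname, mask.lattice, mask.voxels.astype(np.uint8))
        structures[name] = fname
    plans = []
    for label, grid in bundle.doses.items():
        fname = f"dose_{label}.nii.gz"
        _write_nifti(out / fname, grid.lattice, grid.dose.astype(np.float32))
        scheme = bundle.schemes[label]
        plans.append(
            {
                "label": label,
                "dose_file": fname,
                "n_fractions": scheme.n_fractions,
                "dose_per_fraction": scheme.dose_per_fraction,
            }
        )
    sidecar = {
        "patient_id": bundle.patient_id,
        "plans": plans,
        "structures": structures,
        "waivers": list(bundle.waivers),
    }
    (out / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return out


def _resample_mask_nn(mask: StructureMask, target: Lattice) -> StructureMask:
    """Nearest-neighbour resampling of a mask onto the target lattice.

    The dose lattice is authoritative; dose itself is never interpolated.
    """
    src = mask.lattice
    idx = []
    for ax in range(3):
        centers = target.axis_centers(ax)
        j = np.round((centers - src.origin[ax]) / src.spacing[ax]).astype(int)
        if j.max() < 0 or j.min() >= src.shape[ax]:
            raise LatticeMismatchError(
                f"mask {mask.label!r} does not overlap the dose lattice on axis {ax}"
            )
        idx.append(np.clip(j, 0, src.shape[ax] - 1))
    vox = mask.voxels[np.ix_(idx[0], idx[1], idx[2])]
    return StructureMask(target, vox, mask.label)


def read_patient(
    dir_path: str | Path,
    required_structures: tuple[str, ...] = ("PTV",),
) -> PatientBundle:
    """Load one patient directory written by :func:`write_patient`.

    All volumes are verified to share one lattice; masks on a finer lattice are
    resampled nearest-neighbour onto the dose lattice.  Missing required
    structures raise :class:`MissingStructureError` naming every gap
    (``base_of_heart`` may be derived, so its absence is tolerated when the
    right atrium and ascending aorta are present).
    """
    root = Path(dir_path)
    sidecar_path = root / SIDECAR_NAME
    if not sidecar_path.exists():
        raise FileNotFoundError(f"no {SIDECAR_NAME} sidecar in {root}")
    meta = json.loads(sidecar_path.read_text())

    doses: dict[str, DoseGrid] = {}
    schemes: dict[str, FractionationScheme] = {}
    dose_lattice: Lattice | None = None
    for plan in meta.get("plans", []):
        img = nib.load(str(root / plan["dose_file"]))
        lat = _lattice_from_nifti(img)
        grid = DoseGrid(lat, np.asarray(img.dataobj, dtype=np.float64), plan["label"])
        if dose_lattice is None:
            dose_lattice = lat
        elif lat != dose_lattice:
            raise LatticeMismatchError("plan dose grids disagree on lattice")
        doses[plan["label"]] = grid
        schemes[plan["label"]] = FractionationScheme(
            plan["n_fractions"], plan["dose_per_fraction"]
        )

    masks: dict[str, StructureMask] = {}
    for name, fname in meta.get("structures", {}).items():
        img = nib.load(str(root / fname))
        lat = _lattice_from_nifti(img)
        mask = StructureMask(lat, np.asarray(img.dataobj) > 0, name)
        if dose_lattice is not None and lat != dose_lattice:
            mask = _resample_mask_nn(mask, dose_lattice)
        masks[name] = mask

    missing = [
        s
        for s in required_structures
        if s not in masks
        and not (
            s == "base_of_heart"
            and {"right_atrium", "ascending_aorta"} <= masks.keys()
        )
    ]
    if missing:
        raise MissingStructureError(
            f"patient {meta.get('patient_id', root.name)!r} is missing required "
            f"structure(s): {', '.join(sorted(missing))}"
        )

    return PatientBundle(
        patient_id=meta.get("patient_id", root.name),
        masks=masks,
        doses=doses,
        schemes=schemes,
        waivers=tuple(meta.get("waivers", [])),
    )


def read_cohort(
    cohort_dir: str | Path,
    required_structures: tuple[str, ...] = ("PTV",),
) -> list[PatientBundle]:
    """Load every patient subdirectory (those containing a sidecar), sorted by name."""
    root = Path(cohort_dir)
    dirs = sorted(p for p in root.iterdir() if (p / SIDECAR_NAME).exists())
    if not dirs:
        raise FileNotFoundError(f"no patient directories with {SIDECAR_NAME} under {root}")
    return [read_patient(p, required_structures) for p in dirs]


__all__ = [
    "CONSTRAINED_CS",
    "DoseGrid",
    "FractionationScheme",
    "KNOWN_STRUCTURES",
    "Lattice",
    "LatticeMismatchError",
    "MissingStructureError",
    "PatientBundle",
    "PLAN_CSP",
    "PLAN_NONCS",
    "StructureMask",
    "base_of_heart",
    "intersection",
    "read_cohort",
    "read_patient",
    "union",
    "volume_cc",
    "write_patient",
]
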