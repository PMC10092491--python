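"""Phantom-patient generator: geometry + analytic dose with planted truth.

Every phantom lives on the clinical 1×1×3 mm lattice and contains a heart
built from ellipsoids (five constrained cardiac substructures, mutually
disjoint by construction), two conventional OAR cylinders, and a spherical
PTV whose position encodes one of three scenarios:

``far``
    PTV well cranial of the heart — no CS constraint can be violated.
``near_spareable``
    PTV abuts the left atrium in the same axial planes (CC distance 0) with a
    small in-plane surface gap: the non-sparing plan violates the left-atrium
    near-maximum constraint, while the steered cardiac-sparing plan clears
    every CS and departmental constraint.
``near_unspareable``
    PTV overlaps the left atrium: more than 0.1 cm³ of the atrium receives
    the full prescription in *any* plan, so sparing can only be partial.

Dose model
----------
The package analyses plans, it does not optimise them, so dose is a smooth
monotone surrogate rather than a beam model:

    D(v) = Rx · erfc(d_eff(v) / (√2 σ))

with d_eff the anisotropically weighted Euclidean distance from the PTV
surface (0 inside, so PTV coverage is exactly the prescription).  σ is fixed
by requiring the 80%→20% falloff to span 6.4 mm — the lung penumbra scale
that also motivates the iOVH slab.  The cardiac-sparing plan multiplies
d_eff by ``1 + a·max(0, cosθ)`` where θ is the angle to the steering
direction (PTV centroid → heart center): dose shrinks monotonically on the
cardiac side and is untouched on the PTV, emulating a replan without
re-optimisation.

Planted truth (per-CS dose metrics, violation labels, sparing classes) is
computed here with a self-contained numpy implementation of the D-at-volume /
EQD2 definitions so that downstream recovery by ``dose_metrics`` +
``constraints`` is a genuine dual-route check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import erfc, erfcinv

from .constraints import cs_constraint_table, departmental_constraint_table
from .dose_metrics import MetricKind
from .volumetric_core import (
    DoseGrid,
    FractionationScheme,
    Lattice,
    PatientBundle,
    PLAN_CSP,
    PLAN_NONCS,
    StructureMask,
    base_of_heart,
    write_patient,
)

#: 80% → 20% dose falloff distance (mm) of erfc(d/(√2σ)), the lung penumbra
#: scale; solving erfc gives σ ≈ 6.22 mm.
PENUMBRA_80_20_MM = 6.4
SIGMA_PENUMBRA_MM = PENUMBRA_80_20_MM / (np.sqrt(2.0) * (erfcinv(0.2) - erfcinv(0.8)))

SCENARIO_FAR = "far"
SCENARIO_SPAREABLE = "near_spareable"
SCENARIO_UNSPAREABLE = "near_unspareable"
SCENARIOS = (SCENARIO_FAR, SCENARIO_SPAREABLE, SCENARIO_UNSPAREABLE)

#: Chamber ellipsoids: label -> (center offset from heart center, semi-axes),
#: mm.  Listed in carving priority; later entries cede overlap to earlier
#: ones, which keeps the chambers mutually disjoint.
CS_ELLIPSOIDS: dict[str, tuple[tuple[float, float, float], tuple[float, float, float]]] = {
    "left_atrium": ((15.0, 8.0, 15.0), (12.0, 12.0, 15.0)),
    "left_ventricle": ((15.0, -6.0, -18.0), (14.0, 13.0, 18.0)),
    "right_ventricle": ((-15.0, -8.0, -15.0), (13.0, 12.0, 16.0)),
    "right_atrium": ((-16.0, 10.0, 12.0), (11.0, 11.0, 13.0)),
    "ascending_aorta": ((0.0, 16.0, 30.0), (8.0, 8.0, 20.0)),
}

#: Conventional OAR cylinders (full CC extent): label -> ((cx, cy) mm, radius mm).
OAR_CYLINDERS: dict[str, tuple[tuple[float, float], float]] = {
    "spinal_cord": ((70.0, 15.0), 5.0),
    "esophagus": ((70.0, 40.0), 6.0),
}

#: Fraction of central (8×7.5 Gy) vs ultra-central (12×5 Gy) presentations.
CENTRAL_FRACTION = 16.0 / 34.0

SCHEME_CENTRAL = FractionationScheme(8, 7.5)
SCHEME_ULTRACENTRAL = FractionationScheme(12, 5.0)


@dataclass(frozen=True)
class DoseModel:
    """Analytic erfc dose falloff around the PTV."""

    prescription_gy: float = 60.0
    sigma_xy_mm: float = SIGMA_PENUMBRA_MM
    sigma_z_mm: float = SIGMA_PENUMBRA_MM
    csp_attenuation: float = 5.0   # distance amplification on the cardiac side


@dataclass(frozen=True)
class PhantomSpec:
    """Complete recipe for one phantom patient (deterministic)."""

    patient_id: str
    scenario: str
    ptv_center_mm: tuple[float, float, float]
    ptv_volume_cc: float
    scheme: FractionationScheme = SCHEME_CENTRAL
    lattice: Lattice = Lattice((150, 140, 72), (1.0, 1.0, 3.0))
    heart_center_mm: tuple[float, float, float] = (70.0, 72.0, 84.0)
    heart_semi_axes_mm: tuple[float, float, float] = (40.0, 35.0, 45.0)
    gtv_margin_mm: float = 4.0
    dose_model: DoseModel = field(default_factory=DoseModel)
    make_csp: bool = False

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not 1.8 <= self.ptv_volume_cc <= 221.5:
            raise ValueError(
                f"PTV volume {self.ptv_volume_cc:.1f} cm³ outside plausible 1.8–221.5"
            )


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

def ellipsoid_mask(
    lattice: Lattice,
    center_mm: tuple[float, float, float],
    semi_axes_mm: tuple[float, float, float],
    label: str,
) -> StructureMask:
    """Voxels whose centers lie inside the axis-aligned ellipsoid."""
    xs, ys, zs = lattice.center_grids()
    cx, cy, cz = center_mm
    ax, ay, az = semi_axes_mm
    inside = ((xs - cx) / ax) ** 2 + ((ys - cy) / ay) ** 2 + ((zs - cz) / az) ** 2 <= 1.0
    return StructureMask(lattice, inside, label)


def ball_mask(
    lattice: Lattice,
    center_mm: tuple[float, float, float],
    volume_cc: float,
    label: str,
) -> StructureMask:
    """Quasi-spherical mask of the k voxel centers nearest to ``center_mm``,
    k = round(volume / voxel volume): the realised volume is within half a
    voxel of the target, which a thresholded analytic radius cannot promise
    on a 1×1×3 mm grid.  Ties break on flat index (deterministic)."""
    for ax in range(3):
        lo = lattice.origin[ax]
        hi = lo + lattice.spacing[ax] * (lattice.shape[ax] - 1)
        if not lo <= center_mm[ax] <= hi:
            raise ValueError(
                f"PTV center {center_mm} outside lattice extent on axis {ax}"
            )
    k = int(round(volume_cc / lattice.voxel_volume_cc))
    if k < 1:
        raise ValueError(f"target volume {volume_cc} cm³ is below one voxel")
    xs, ys, zs = lattice.center_grids()
    d2 = (xs - center_mm[0]) ** 2 + (ys - center_mm[1]) ** 2 + (zs - center_mm[2]) ** 2
    flat = np.argsort(d2, axis=None, kind="stable")[:k]
    vox = np.zeros(lattice.shape, dtype=bool)
    vox[np.unravel_index(flat, lattice.shape)] = True
    return StructureMask(lattice, vox, label)


def _cylinder_mask(
    lattice: Lattice, cxy: tuple[float, float], radius_mm: float, label: str
) -> StructureMask:
    xs, ys, _ = lattice.center_grids()
    inplane = (xs - cxy[0]) ** 2 + (ys - cxy[1]) ** 2 <= radius_mm**2
    vox = np.broadcast_to(inplane, lattice.shape).copy()
    return StructureMask(lattice, vox, label)


def _anatomy_masks(spec: PhantomSpec) -> dict[str, StructureMask]:
    lat = spec.lattice
    hc = np.asarray(spec.heart_center_mm)
    masks: dict[str, StructureMask] = {}
    claimed = np.zeros(lat.shape, dtype=bool)
    for label, (offset, semi) in CS_ELLIPSOIDS.items():
        ell = ellipsoid_mask(lat, tuple(hc + np.asarray(offset)), semi, label)
        vox = ell.voxels & ~claimed
        claimed |= vox
        masks[label] = StructureMask(lat, vox, label)
    heart_shell = ellipsoid_mask(lat, spec.heart_center_mm, spec.heart_semi_axes_mm, "heart")
    masks["heart"] = StructureMask(lat, heart_shell.voxels | claimed, "heart")
    masks["base_of_heart"] = base_of_heart(masks)
    for label, (cxy, r) in OAR_CYLINDERS.items():
        masks[label] = _cylinder_mask(lat, cxy, r, label)
    return masks


def _gtv_from_ptv(ptv: StructureMask, margin_mm: float) -> StructureMask:
    inner = ndimage.distance_transform_edt(ptv.voxels, sampling=ptv.lattice.spacing)
    vox = inner > margin_mm
    if not vox.any():  # degenerate small PTV: keep the deepest voxel
        vox = inner == inner.max()
    return StructureMask(ptv.lattice, vox, "GTV")


# ---------------------------------------------------------------------------
# dose synthesis
# ---------------------------------------------------------------------------

def _dose_fields(
    spec: PhantomSpec, ptv: StructureMask
) -> tuple[np.ndarray, np.ndarray | None]:
    """Return (noncs, csp-or-None) dose arrays in Gy."""
    lat, dm = spec.lattice, spec.dose_model
    sampling = (
        lat.spacing[0],
        lat.spacing[1],
        lat.spacing[2] * dm.sigma_xy_mm / dm.sigma_z_mm,
    )
    d = ndimage.distance_transform_edt(~ptv.voxels, sampling=sampling)
    scale = np.sqrt(2.0) * dm.sigma_xy_mm
    noncs = dm.prescription_gy * erfc(d / scale)
    if not spec.make_csp:
        return noncs, None

    centroid = ptv.coordinates_mm().mean(axis=0)
    steer = np.asarray(spec.heart_center_mm) - centroid
    steer /= np.linalg.norm(steer)
    xs, ys, zs = lat.center_grids()
    vx, vy, vz = xs - centroid[0], ys - centroid[1], zs - centroid[2]
    norm = np.sqrt(vx**2 + vy**2 + vz**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = (vx * steer[0] + vy * steer[1] + vz * steer[2]) / norm
    cos = np.nan_to_num(np.clip(cos, 0.0, 1.0))
    csp = dm.prescription_gy * erfc(d * (1.0 + dm.csp_attenuation * cos) / scale)
    return noncs, csp


# ---------------------------------------------------------------------------
# planted truth (independent numpy route)
# ---------------------------------------------------------------------------

def _truth_d_at_volume(doses: np.ndarray, v_cc: float, vox_cc: float) -> float:
    desc = np.sort(doses)[::-1]
    if v_cc >= desc.size * vox_cc:
        return float(desc[-1])
    cum = vox_cc * np.arange(1, desc.size + 1)
    return float(np.interp(v_cc, cum, desc))


def _truth_eqd2(dose_gy: np.ndarray, scheme: FractionationScheme, ab: float) -> np.ndarray:
    return dose_gy * (dose_gy / scheme.n_fractions + ab) / (2.0 + ab)


def _planted_cs_labels(
    masks: dict[str, StructureMask],
    dose: np.ndarray,
    scheme: FractionationScheme,
    table,
) -> dict[str, tuple[float, bool]]:
    """{structure: (achieved EQD2, violated)} per CS constraint, own math."""
    vox_cc = next(iter(masks.values())).lattice.voxel_volume_cc
    out: dict[str, tuple[float, bool]] = {}
    for c in table:
        vals = _truth_eqd2(dose[masks[c.structure].voxels], scheme, c.alpha_beta)
        if c.metric.kind is MetricKind.D_AT_ABSOLUTE_VOLUME:
            v_cc = c.metric.param
        else:  # the five CS constraints are all quantile-type
            v_cc = c.metric.param / 100.0 * vals.size * vox_cc
        achieved = _truth_d_at_volume(vals, v_cc, vox_cc)
        out[c.structure] = (achieved, not achieved < c.optimal)
    return out


# ---------------------------------------------------------------------------
# patient and cohort generation
# ---------------------------------------------------------------------------

def generate_patient(spec: PhantomSpec) -> tuple[PatientBundle, dict]:
    """Build one phantom bundle plus its planted ground-truth record."""
    masks = _anatomy_masks(spec)
    ptv = ball_mask(spec.lattice, spec.ptv_center_mm, spec.ptv_volume_cc, "PTV")
    masks = {"PTV": ptv, "GTV": _gtv_from_ptv(ptv, spec.gtv_margin_mm), **masks}

    noncs, csp = _dose_fields(spec, ptv)
    doses = {PLAN_NONCS: DoseGrid(spec.lattice, noncs, PLAN_NONCS)}
    schemes = {PLAN_NONCS: spec.scheme}
    if csp is not None:
        doses[PLAN_CSP] = DoseGrid(spec.lattice, csp, PLAN_CSP)
        schemes[PLAN_CSP] = spec.scheme
    bundle = PatientBundle(spec.patient_id, masks, doses, schemes)

    cs_table = cs_constraint_table()
    dept_table = departmental_constraint_table()
    truth: dict = {
        "patient_id": spec.patient_id,
        "scenario": spec.scenario,
        "n_fractions": spec.scheme.n_fractions,
        "dose_per_fraction": spec.scheme.dose_per_fraction,
        "ptv_cc": ptv.voxel_count * spec.lattice.voxel_volume_cc,
    }
    labels_noncs = _planted_cs_labels(masks, noncs, spec.scheme, cs_table)
    violated_noncs = sorted(s for s, (_, bad) in labels_noncs.items() if bad)
    truth["needs_sparing"] = bool(violated_noncs)
    truth["n_cs_violated_noncs"] = len(violated_noncs)
    truth["violated_cs_noncs"] = ";".join(violated_noncs)
    for s, (v, _) in labels_noncs.items():
        truth[f"eqd2_noncs_{s}"] = v

    if csp is None:
        truth["csp_class"] = "not_required" if not violated_noncs else "pending"
        truth["n_cs_violated_csp"] = 0
        truth["violated_cs_csp"] = ""
    else:
        labels_csp = _planted_cs_labels(masks, csp, spec.scheme, cs_table)
        violated_csp = sorted(s for s, (_, bad) in labels_csp.items() if bad)
        dept = _planted_cs_labels(masks, csp, spec.scheme, dept_table)
        dept_violated = [s for s, (_, bad) in dept.items() if bad]
        for s, (v, _) in labels_csp.items():
            truth[f"eqd2_csp_{s}"] = v
        if not violated_noncs:
            truth["csp_class"] = "not_required"
        elif not violated_csp and not dept_violated:
            truth["csp_class"] = "successful"
        elif len(violated_csp) < len(cs_table) and not dept_violated:
            truth["csp_class"] = "partially_successful"
        else:
            truth["csp_class"] = "not_feasible"
        truth["n_cs_violated_csp"] = len(violated_csp)
        truth["violated_cs_csp"] = ";".join(violated_csp)
    return bundle, truth


def _resolve_mix(n: int, mix: dict[str, float] | None) -> dict[str, int]:
    mix = dict(mix or {SCENARIO_FAR: 18, SCENARIO_SPAREABLE: 10, SCENARIO_UNSPAREABLE: 6})
    unknown = set(mix) - set(SCENARIOS)
    if unknown:
        raise ValueError(f"unknown scenario(s) in mix: {sorted(unknown)}")
    total = sum(mix.values())
    if abs(total - 1.0) < 1e-9:  # fractions: largest-remainder apportionment
        raw = {s: n * f for s, f in mix.items()}
        counts = {s: int(np.floor(v)) for s, v in raw.items()}
        short = n - sum(counts.values())
        for s in sorted(raw, key=lambda s: raw[s] - counts[s], reverse=True)[:short]:
            counts[s] += 1
    else:
        counts = {s: int(round(v)) for s, v in mix.items()}
        if sum(counts.values()) != n:
            raise ValueError(f"mix counts {counts} do not sum to n={n}")
    if sum(c > 0 for c in counts.values()) == 1:
        warnings.warn(
            "degenerate scenario mix (single class): downstream ROC stages "
            "will have an empty class",
            stacklevel=3,
        )
    return counts


def _la_anchor(spec_lattice: Lattice) -> tuple[np.ndarray, np.ndarray, float]:
    """Left-atrium centroid, in-plane outward unit direction, surface radius."""
    hc = np.asarray(PhantomSpec.__dataclass_fields__["heart_center_mm"].default)
    off, semi = CS_ELLIPSOIDS["left_atrium"]
    la_c = hc + np.asarray(off)
    u = np.array([off[0], off[1], 0.0])
    u /= np.linalg.norm(u)
    # ellipsoid surface radius along u (a == b for the atrium in-plane)
    r_surf = 1.0 / np.sqrt((u[0] / semi[0]) ** 2 + (u[1] / semi[1]) ** 2)
    return la_c, u, float(r_surf)


def _draw_spec(
    rng: np.random.Generator, scenario: str, patient_id: str, lattice: Lattice
) -> PhantomSpec:
    scheme = SCHEME_CENTRAL if rng.random() < CENTRAL_FRACTION else SCHEME_ULTRACENTRAL
    hc = np.asarray(PhantomSpec.__dataclass_fields__["heart_center_mm"].default)
    semi = np.asarray(PhantomSpec.__dataclass_fields__["heart_semi_axes_mm"].default)
    z_max_mm = lattice.origin[2] + lattice.spacing[2] * (lattice.shape[2] - 1)

    if scenario == SCENARIO_FAR:
        vol = float(np.clip(rng.lognormal(np.log(28.1), 0.8), 1.8, 110.0))
        r = (3.0 * vol * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
        cx = hc[0] + rng.uniform(-15, 15)
        cy = hc[1] + rng.uniform(-15, 15)
        cz = min(hc[2] + semi[2] + 30.0 + r, z_max_mm - lattice.spacing[2] - r)
        return PhantomSpec(patient_id, scenario, (cx, cy, cz), vol, scheme, lattice)

    la_c, u, r_surf = _la_anchor(lattice)
    if scenario == SCENARIO_SPAREABLE:
        gap = rng.uniform(3.5, 6.5)
        r = rng.uniform(10.0, 20.0)
        theta = np.deg2rad(rng.uniform(-10.0, 10.0))
    else:
        # deep overlap with the left atrium, swung toward the ascending
        # aorta: the non-sparing plan then typically violates several CS
        # while the steered plan can clear all but the atrium
        gap = rng.uniform(-10.0, -4.0)
        r = rng.uniform(22.0, 30.0)
        theta = np.deg2rad(rng.uniform(12.0, 20.0))
    rot = np.array(
        [
            [np.cos(theta), -np.sin(theta), 0.0],
            [np.sin(theta), np.cos(theta), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    direction = rot @ u
    center = la_c + direction * (r_surf + gap + r)
    center[2] += rng.uniform(-6.0, 6.0)
    vol = 4.0 / 3.0 * np.pi * r**3 / 1000.0
    return PhantomSpec(
        patient_id, scenario, tuple(center), vol, scheme, lattice, make_csp=True
    )


def generate_cohort(
    n: int,
    mix: dict[str, float] | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    lattice: Lattice | None = None,
) -> tuple[list[PatientBundle], pd.DataFrame]:
    """Generate a phantom cohort; optionally write it to disk.

    ``mix`` maps scenario → fraction (summing to 1) or count (summing to
    ``n``); default 18/10/6 far/spareable/unspareable at n=34.  Returns the
    bundles and the planted ground-truth table; with ``out_dir`` each patient
    directory plus ``truth.csv`` is written in the standard on-disk format.
    """
    if n < 2:
        raise ValueError("a cohort needs n >= 2 patients")
    counts = _resolve_mix(n, mix)
    lattice = lattice or PhantomSpec.__dataclass_fields__["lattice"].default
    rng = np.random.default_rng(seed)
    scenarios = [s for s in SCENARIOS for _ in range(counts.get(s, 0))]

    bundles: list[PatientBundle] = []
    truth_rows: list[dict] = []
    for i, scenario in enumerate(scenarios):
        spec = _draw_spec(rng, scenario, f"p{i + 1:03d}", lattice)
        bundle, truth = generate_patient(spec)
        bundles.append(bundle)
        truth_rows.append(truth)
        if out_dir is not None:
            write_patient(bundle, Path(out_dir) / bundle.patient_id)
    truth = pd.DataFrame(truth_rows)
    if out_dir is not None:
        truth.to_csv(Path(out_dir) / "truth.csv", index=False)
    return bundles, truth


__all__ = [
    "CS_ELLIPSOIDS",
    "DoseModel",
    "OAR_CYLINDERS",
    "PENUMBRA_80_20_MM",
    "PhantomSpec",
    "SCENARIOS",
    "SCENARIO_FAR",
    "SCENARIO_SPAREABLE",
    "SCENARIO_UNSPAREABLE",
    "SIGMA_PENUMBRA_MM",
    "ball_mask",
    "ellipsoid_mask",
    "generate_cohort",
    "generate_patient",
]
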