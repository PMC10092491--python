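"""Constraint tables, per-plan evaluation, and patient stratification.

A plan *needs cardiac sparing* when at least one of the five selected
cardiac-substructure (CS) constraints is violated in the non-CS-constrained
plan.  A cardiac-sparing plan (CSP) is *successful* when it meets every CS
constraint and every departmental OAR constraint, and *partially successful*
when the departmental table is met but 1–4 of the 5 CS constraints remain
violated.  Violation is judged on the optimal limit with a strict ``<``
comparator (equality violates); for two-level constraints the mandatory
status is reported alongside.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .dose_metrics import DoseMetricSpec, eqd2_metric
from .volumetric_core import (
    CONSTRAINED_CS,
    PLAN_CSP,
    PLAN_NONCS,
    PatientBundle,
    base_of_heart,
)


class ConstraintStatus(enum.Enum):
    MET = "met"
    OPTIMAL_VIOLATED = "optimal_violated"
    MANDATORY_VIOLATED = "mandatory_violated"
    UNEVALUABLE = "unevaluable"

    @property
    def violated(self) -> bool:
        """Violation keyed on the optimal limit (the stricter of the two)."""
        return self in (
            ConstraintStatus.OPTIMAL_VIOLATED,
            ConstraintStatus.MANDATORY_VIOLATED,
        )


@dataclass(frozen=True)
class ConstraintSpec:
    """One constraint-table row: structure, metric, EQD2 limit(s), α/β."""

    structure: str
    metric: DoseMetricSpec
    optimal: float
    mandatory: float | None = None
    alpha_beta: float = 2.0
    source: str = ""

    def __post_init__(self) -> None:
        if self.optimal <= 0:
            raise ValueError("optimal limit must be > 0 Gy EQD2")
        if self.mandatory is not None and self.mandatory < self.optimal:
            raise ValueError("mandatory limit must be >= optimal limit")

    @property
    def name(self) -> str:
        return f"{self.structure} {self.metric}"


@dataclass(frozen=True)
class ConstraintResult:
    spec: ConstraintSpec
    achieved_eqd2: float | None
    status: ConstraintStatus
    waived: bool = False

    @property
    def ratio(self) -> float | None:
        """Achieved EQD2 relative to the optimal constraint level."""
        if self.achieved_eqd2 is None:
            return None
        return self.achieved_eqd2 / self.spec.optimal


class CSPClass(enum.Enum):
    NOT_REQUIRED = "not_required"
    SUCCESSFUL = "successful"
    PARTIALLY_SUCCESSFUL = "partially_successful"
    NOT_FEASIBLE = "not_feasible"
    PENDING = "pending"


@dataclass(frozen=True)
class StratificationResult:
    patient_id: str
    needs_sparing: bool
    csp_class: CSPClass
    violated_cs_noncs: tuple[str, ...]
    violated_cs_csp: tuple[str, ...]
    n_cs_constraints: int
    departmental_violations_csp: tuple[str, ...] = ()

    @property
    def n_violated_noncs(self) -> int:
        return len(self.violated_cs_noncs)

    @property
    def n_violated_csp(self) -> int:
        return len(self.violated_cs_csp)


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

def _spec_from_row(row: dict) -> ConstraintSpec:
    return ConstraintSpec(
        structure=row["structure"],
        metric=DoseMetricSpec.parse(row["metric"]),
        optimal=float(row["optimal"]),
        mandatory=None if row.get("mandatory") is None else float(row["mandatory"]),
        alpha_beta=float(row.get("alpha_beta", 2.0)),
        source=row.get("source", ""),
    )


def load_constraint_table(path: str | Path) -> list[ConstraintSpec]:
    """Load a YAML constraint table: {constraints: [{structure, metric, ...}]}."""
    data = yaml.safe_load(Path(path).read_text())
    return [_spec_from_row(r) for r in data["constraints"]]


def _bundled(name: str) -> list[ConstraintSpec]:
    text = resources.files("cardiospare.data").joinpath(name).read_text()
    return [_spec_from_row(r) for r in yaml.safe_load(text)["constraints"]]


def cs_constraint_table() -> list[ConstraintSpec]:
    """The five selected literature CS constraints (EQD2 Gy)."""
    return _bundled("cs_constraints_table2.yaml")


def departmental_constraint_table() -> list[ConstraintSpec]:
    """Placeholder departmental OAR table — synthetic; review before use."""
    return _bundled("departmental_oar_placeholder.yaml")


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_plan(
    bundle: PatientBundle,
    plan_label: str,
    table: list[ConstraintSpec],
) -> list[ConstraintResult]:
    """Evaluate every constraint of ``table`` against one plan of a patient.

    ``base_of_heart`` is derived on the fly (right atrium ∪ ascending aorta)
    when not delineated.  A missing structure yields an UNEVALUABLE result
    rather than a crash.  Structures listed in the patient's waivers are
    evaluated but marked waived and excluded from violation accounting.
    """
    if plan_label not in bundle.doses:
        raise KeyError(f"patient {bundle.patient_id!r} has no plan {plan_label!r}")
    dose = bundle.doses[plan_label]
    scheme = bundle.schemes[plan_label]
    results: list[ConstraintResult] = []
    for spec in table:
        mask = bundle.masks.get(spec.structure)
        if mask is None and spec.structure == "base_of_heart":
            try:
                mask = base_of_heart(bundle.masks)
            except ValueError:
                mask = None
        if mask is None or mask.voxel_count == 0:
            results.append(ConstraintResult(spec, None, ConstraintStatus.UNEVALUABLE))
            continue
        val = eqd2_metric(mask, dose, scheme, spec.metric, spec.alpha_beta).eqd2_gy
        if val < spec.optimal:
            status = ConstraintStatus.MET
        elif spec.mandatory is not None and val >= spec.mandatory:
            status = ConstraintStatus.MANDATORY_VIOLATED
        else:
            status = ConstraintStatus.OPTIMAL_VIOLATED
        results.append(
            ConstraintResult(spec, val, status, waived=spec.structure in bundle.waivers)
        )
    return results


def _violated_structures(results: list[ConstraintResult]) -> tuple[str, ...]:
    return tuple(
        r.spec.structure for r in results if r.status.violated and not r.waived
    )


def stratify(
    patient_id: str,
    noncs_results: list[ConstraintResult],
    csp_results: list[ConstraintResult] | None = None,
    departmental_csp_results: list[ConstraintResult] | None = None,
) -> StratificationResult:
    """Classify one patient by need for and success of cardiac sparing."""
    violated_noncs = _violated_structures(noncs_results)
    needs = len(violated_noncs) > 0
    n_cs = len(noncs_results)

    if not needs:
        return StratificationResult(
            patient_id, False, CSPClass.NOT_REQUIRED, violated_noncs, (), n_cs
        )
    if csp_results is None:
        return StratificationResult(
            patient_id, True, CSPClass.PENDING, violated_noncs, (), n_cs
        )
    violated_csp = _violated_structures(csp_results)
    dept_violated = (
        _violated_structures(departmental_csp_results)
        if departmental_csp_results is not None
        else ()
    )
    if not violated_csp and not dept_violated:
        cls = CSPClass.SUCCESSFUL
    elif len(violated_csp) < n_cs and not dept_violated:
        cls = CSPClass.PARTIALLY_SUCCESSFUL
    else:
        cls = CSPClass.NOT_FEASIBLE
    return StratificationResult(
        patient_id, True, cls, violated_noncs, violated_csp, n_cs, dept_violated
    )


@dataclass
class CohortLedger:
    """Cohort-level violation and stratification bookkeeping."""

    n_patients: int
    n_needing_sparing: int
    n_successful: int
    n_partially_successful: int
    n_not_feasible: int
    cumulative_violations_noncs: int
    cumulative_violations_csp: int
    violations_noncs_unsuccessful_group: int
    violations_csp_unsuccessful_group: int

    @property
    def pct_needing_sparing(self) -> float:
        return 100.0 * self.n_needing_sparing / self.n_patients

    @property
    def pct_successful_of_needing(self) -> float:
        if self.n_needing_sparing == 0:
            return float("nan")
        return 100.0 * self.n_successful / self.n_needing_sparing


def violation_ledger(stratifications: list[StratificationResult]) -> CohortLedger:
    """Summarise a cohort of stratifications (before/after violation totals).

    The *unsuccessful group* totals count CS-constraint violations cumulated
    over the patients whose CSP remained partially successful or infeasible —
    the before/after comparison for exactly that subgroup.
    """
    if not stratifications:
        raise ValueError("violation_ledger needs at least one patient")
    partial = [
        s
        for s in stratifications
        if s.csp_class in (CSPClass.PARTIALLY_SUCCESSFUL, CSPClass.NOT_FEASIBLE)
    ]
    return CohortLedger(
        n_patients=len(stratifications),
        n_needing_sparing=sum(s.needs_sparing for s in stratifications),
        n_successful=sum(
            s.csp_class is CSPClass.SUCCESSFUL for s in stratifications
        ),
        n_partially_successful=sum(
            s.csp_class is CSPClass.PARTIALLY_SUCCESSFUL for s in stratifications
        ),
        n_not_feasible=sum(
            s.csp_class is CSPClass.NOT_FEASIBLE for s in stratifications
        ),
        cumulative_violations_noncs=sum(s.n_violated_noncs for s in stratifications),
        cumulative_violations_csp=sum(s.n_violated_csp for s in stratifications),
        violations_noncs_unsuccessful_group=sum(s.n_violated_noncs for s in partial),
        violations_csp_unsuccessful_group=sum(s.n_violated_csp for s in partial),
    )


def stratify_bundle(
    bundle: PatientBundle,
    cs_table: list[ConstraintSpec] | None = None,
    departmental_table: list[ConstraintSpec] | None = None,
) -> StratificationResult:
    """Convenience: evaluate both plans of a bundle and stratify the patient."""
    cs_table = cs_table if cs_table is not None else cs_constraint_table()
    departmental_table = (
        departmental_table
        if departmental_table is not None
        else departmental_constraint_table()
    )
    noncs = evaluate_plan(bundle, PLAN_NONCS, cs_table)
    csp = dept_csp = None
    if PLAN_CSP in bundle.doses:
        csp = evaluate_plan(bundle, PLAN_CSP, cs_table)
        dept_csp = evaluate_plan(bundle, PLAN_CSP, departmental_table)
    return stratify(bundle.patient_id, noncs, csp, dept_csp)


__all__ = [
    "CSPClass",
    "CohortLedger",
    "ConstraintResult",
    "ConstraintSpec",
    "ConstraintStatus",
    "StratificationResult",
    "cs_constraint_table",
    "departmental_constraint_table",
    "evaluate_plan",
    "load_constraint_table",
    "stratify",
    "stratify_bundle",
    "violation_ledger",
]
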