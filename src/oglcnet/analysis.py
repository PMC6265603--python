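"""Comparative experiments: fold changes, direction calls, summary tables.

Every comparison is a pair of deterministic simulations (a baseline and a
perturbed condition) reduced to scalar readouts.  The default readout is
the mean over the last 20% of the horizon, which damps transients while
staying close to the quasi-steady terminal activity the time-course plots
show.

Direction thresholds: a fold >= 1.2 is called ``up``, <= 0.8 ``down``,
anything between ``no_change``.  The models carry no direction thresholds
of their own, so these are chosen symmetric on the log scale.

Fold-change conventions (both appear in the field and in our reports):
``fold`` is always perturbed/baseline; a "reduction factor" is the inverse
baseline/perturbed.  Report footers restate which is which.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .dynamics import SimulationSettings, Trajectory, readout, simulate
from .errors import OglcnetError, UnknownElementError
from .interventions import Intervention, InterventionPlan, apply_plan
from .models import VariantSpec, build_model, default_config

__all__ = [
    "FoldChangeReport",
    "SummaryTable",
    "fold_change",
    "run_case",
    "table1_directions",
    "CASES",
]

UP_THRESHOLD = 1.2
DOWN_THRESHOLD = 0.8
EPSILON = 1e-9

#: Readout places reported by every case comparison.
CASE_READOUTS = ("ogt", "cell_survival", "akt_active", "glut4_membrane", "irs1_active")

#: The six named in-silico experiments: (baseline, interventions on cancer).
CASES = {
    "hyperglycemia": None,  # special: normal vs cancer variant
    "shrna": ("shrna",),
    "bzx": ("bzx",),
    "metformin": ("metformin",),
    "shrna_bzx": ("shrna", "bzx"),
    "bzx_metformin": ("bzx", "metformin"),
}

FOOTER = (
    "fold = perturbed/baseline; reduction factor = baseline/perturbed "
    "(an 'n-fold decrease' means the reduction factor reached n)."
)


class UndefinedFoldError(OglcnetError):
    """Baseline readout below epsilon: the fold ratio is not defined."""


@dataclass(frozen=True)
class FoldChangeReport:
    readout: str
    baseline: float
    perturbed: float
    fold: float
    direction: str
    context: tuple[str, str]

    @property
    def reduction_factor(self) -> float:
        return 1.0 / self.fold if self.fold > 0 else float("inf")


@dataclass(frozen=True)
class SummaryTable:
    """Rows of (condition, readout, value/direction) plus provenance."""

    rows: tuple[Mapping, ...]
    provenance: Mapping
    footer: str = FOOTER

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.rows))

    def to_csv(self, destination) -> None:
        self.to_frame().to_csv(destination, index=False)

    def to_text(self) -> str:
        body = self.to_frame().to_string(index=False)
        prov = ", ".join(f"{k}={v}" for k, v in sorted(self.provenance.items()))
        return f"{body}\n\n{self.footer}\n[{prov}]"


def _direction(fold: float) -> str:
    if fold >= UP_THRESHOLD:
        return "up"
    if fold <= DOWN_THRESHOLD:
        return "down"
    return "no_change"


def fold_change(
    baseline_traj: Trajectory,
    perturbed_traj: Trajectory,
    readout_place: str,
    mode: str = "mean_tail",
) -> FoldChangeReport:
    """Perturbed-over-baseline activity ratio of one readout place."""
    base = readout(baseline_traj, readout_place, mode=mode)
    pert = readout(perturbed_traj, readout_place, mode=mode)
    if base < EPSILON:
        raise UndefinedFoldError(
            f"baseline readout of {readout_place!r} is {base:.3e} < {EPSILON:g}; "
            "fold change undefined"
        )
    fold = pert / base
    return FoldChangeReport(
        readout=readout_place,
        baseline=base,
        perturbed=pert,
        fold=fold,
        direction=_direction(fold),
        context=(baseline_traj.net_name, perturbed_traj.net_name),
    )


def _config_hash(*objs) -> str:
    payload = json.dumps(objs, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _provenance(settings: SimulationSettings, overrides: Mapping | None) -> dict:
    return {
        "t_end": settings.t_end,
        "n_points": settings.n_points,
        "config_hash": _config_hash(
            default_config("normal_adipocyte"),
            default_config("insulin_resistant_adipocyte"),
            default_config("cancer_hyperglycemia"),
            dict(overrides or {}),
        ),
    }


def run_case(
    case_id: str,
    settings: SimulationSettings | None = None,
    overrides: Mapping | None = None,
    mode: str = "mean_tail",
) -> SummaryTable:
    """Run one named comparison and report folds for the standard readouts.

    ``hyperglycemia`` compares the normal variant (baseline) with the
    hyperglycemic cancer variant; every drug case compares the cancer
    variant (baseline/control) with cancer plus the intervention(s).
    """
    if case_id not in CASES:
        raise UnknownElementError(
            f"unknown case {case_id!r}; expected one of {sorted(CASES)}"
        )
    settings = settings or SimulationSettings()
    overrides = dict(overrides or {})
    if case_id == "hyperglycemia":
        base_net = build_model(VariantSpec("normal_adipocyte", overrides))
        pert_net = build_model(VariantSpec("cancer_hyperglycemia", overrides))
    else:
        base_net = build_model(VariantSpec("cancer_hyperglycemia", overrides))
        plan = InterventionPlan(
            VariantSpec("cancer_hyperglycemia", overrides),
            tuple(Intervention(kind) for kind in CASES[case_id]),
        )
        pert_net = apply_plan(plan)
    base_traj = simulate(base_net, settings)
    pert_traj = simulate(pert_net, settings)
    rows = []
    for place in CASE_READOUTS:
        rep = fold_change(base_traj, pert_traj, place, mode=mode)
        rows.append(
            {
                "case": case_id,
                "readout": place,
                "baseline": rep.baseline,
                "perturbed": rep.perturbed,
                "fold": rep.fold,
                "reduction_factor": rep.reduction_factor,
                "direction": rep.direction,
                "baseline_condition": rep.context[0],
                "perturbed_condition": rep.context[1],
            }
        )
    return SummaryTable(rows=tuple(rows), provenance=_provenance(settings, overrides))


#: Table-1 readout labels in report order.
_TABLE1_READOUTS = (
    ("irs1_active", "IRS-1"),
    ("akt_active", "Akt"),
    ("glut4_membrane", "GLUT-4"),
    ("cell_survival", "cell survival"),
)


def table1_directions(
    settings: SimulationSettings | None = None,
    overrides: Mapping | None = None,
) -> SummaryTable:
    """Sign matrix of the disease comparisons.

    The diabetes column compares the insulin-resistant adipocyte against
    the normal one; the breast-cancer column compares the hyperglycemic
    cancer cell against the normal adipocyte.  IRS-1 in the cancer cell is
    marked not-applicable (OGT is not wired to IRS-1 in that variant; no
    experimental reference data).
    """
    settings = settings or SimulationSettings()
    overrides = dict(overrides or {})
    trajs = {
        v: simulate(build_model(VariantSpec(v, overrides)), settings)
        for v in ("normal_adipocyte", "insulin_resistant_adipocyte",
                  "cancer_hyperglycemia")
    }
    rows = []
    for place, label in _TABLE1_READOUTS:
        row = {"readout": label, "place": place}
        for column, variant in (
            ("diabetes", "insulin_resistant_adipocyte"),
            ("breast_cancer", "cancer_hyperglycemia"),
        ):
            if column == "breast_cancer" and place == "irs1_active":
                row[column] = "n/a"
                row[f"{column}_fold"] = float("nan")
                continue
            rep = fold_change(trajs["normal_adipocyte"], trajs[variant], place)
            row[column] = {"up": "↑", "down": "↓"}.get(
                rep.direction, "no_change"
            )
            row[f"{column}_fold"] = rep.fold
        rows.append(row)
    return SummaryTable(rows=tuple(rows), provenance=_provenance(settings, overrides))


def table2_folds(
    settings: SimulationSettings | None = None,
    overrides: Mapping | None = None,
) -> SummaryTable:
    """OGT and proliferation effect sizes for all six cases, one table.

    Hyperglycemia is reported as a fold increase (perturbed/baseline);
    the drug cases as reduction factors (control/perturbed), except that
    shRNA's OGT effect is conventionally quoted as the residual ratio.
    """
    settings = settings or SimulationSettings()
    rows = []
    for case_id in CASES:
        table = run_case(case_id, settings=settings, overrides=overrides)
        by_readout = {r["readout"]: r for r in table.rows}
        ogt, surv = by_readout["ogt"], by_readout["cell_survival"]
        if case_id == "hyperglycemia":
            ogt_value, surv_value = ogt["fold"], surv["fold"]
            convention = "fold increase"
        else:
            ogt_value = (
                ogt["fold"] if case_id in ("shrna", "shrna_bzx")
                else ogt["reduction_factor"]
            )
            surv_value = surv["reduction_factor"]
            convention = "reduction factor (shRNA OGT column: residual ratio)"
        rows.append(
            {
                "case": case_id,
                "ogt": ogt_value,
                "ogt_direction": ogt["direction"],
                "cell_proliferation": surv_value,
                "proliferation_direction": surv["direction"],
                "convention": convention,
            }
        )
    return SummaryTable(rows=tuple(rows), provenance=_provenance(settings, overrides))
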