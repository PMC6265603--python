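"""Declarative perturbations: shRNA knockdown, BZX inhibition, Metformin.

Each intervention is a structural edit applied to a *copy* of a built
pathway net (the input net is never mutated):

* ``shrna`` — adds an ``shrna`` place holding the dose and a degradation
  sink that consumes shRNA together with OGT mRNA.  Stoichiometric: each
  silencing event spends one token of each, so the dose bounds the depth
  of the knockdown.
* ``bzx`` — adds a ``bzx`` place and an irreversible sequestration
  transition consuming BZX together with OGT into an inert
  ``ogt_bzx_complex`` (the covalent suicide-inhibitor mechanism; the
  complex is never reopened).
* ``metformin`` — adds a ``metformin`` place with a slow maintaining
  source and a single inhibitory arc onto the proliferation transition.
  Metformin touches nothing else, so OGT dynamics are unchanged.

Default doses and mechanism rate constants come from the shipped config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .core import Arc, PetriNet, Place, Transition, require_valid
from .dynamics import SimulationSettings, readout, simulate
from .errors import InterventionError
from .models import VariantSpec, build_model, shipped_defaults

__all__ = [
    "Intervention",
    "InterventionPlan",
    "apply_intervention",
    "apply_plan",
    "dose_sweep",
]

KINDS = ("shrna", "bzx", "metformin")


def _defaults():
    return shipped_defaults()["interventions"]


@dataclass(frozen=True)
class Intervention:
    """One perturbation; ``dose_tokens`` is the drug/RNA place's initial level.

    ``dose_tokens=None`` selects the shipped default dose.  ``extra`` may
    override the mechanism rate constant (key ``rate``) or, for metformin,
    the inhibitory-arc weight (key ``gate_weight``).
    """

    kind: str
    dose_tokens: float | None = None
    extra: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in KINDS:
            raise InterventionError(
                f"unknown intervention kind {self.kind!r}; expected one of {KINDS}"
            )
        if self.dose_tokens is not None and self.dose_tokens < 0:
            raise InterventionError(f"dose_tokens must be >= 0, got {self.dose_tokens}")
        unknown = set(self.extra) - {"rate", "gate_weight"}
        if unknown:
            raise InterventionError(f"unknown extra key(s): {sorted(unknown)}")

    @property
    def dose(self) -> float:
        if self.dose_tokens is not None:
            return float(self.dose_tokens)
        return float(_defaults()["doses"][self.kind])


@dataclass(frozen=True)
class InterventionPlan:
    """A base variant plus one or two interventions of distinct kinds."""

    base_variant: VariantSpec | str
    interventions: tuple[Intervention, ...] = ()

    def __post_init__(self):
        base = self.base_variant
        if isinstance(base, str):
            base = VariantSpec(base)
            object.__setattr__(self, "base_variant", base)
        object.__setattr__(self, "interventions", tuple(self.interventions))
        kinds = [iv.kind for iv in self.interventions]
        if len(kinds) > 2:
            raise InterventionError("a plan holds at most two interventions")
        if len(set(kinds)) != len(kinds):
            raise InterventionError(f"duplicate intervention kinds in plan: {kinds}")


def _require_place(net: PetriNet, place_id: str, kind: str) -> None:
    if place_id not in net.place_ids:
        raise InterventionError(
            f"{kind} intervention needs place {place_id!r}, absent from net "
            f"{net.name!r}"
        )


def apply_intervention(net: PetriNet, iv: Intervention) -> PetriNet:
    """Return a new validating net with the perturbation wired in."""
    cfg = _defaults()
    dose = iv.dose
    places = list(net.places)
    transitions = list(net.transitions)
    arcs = list(net.arcs)

    if iv.kind == "shrna":
        _require_place(net, "ogt_mrna", iv.kind)
        rate = float(iv.extra.get("rate", cfg["rates"]["degrade_ogt_mrna"]))
        places.append(Place("shrna", "shRNA against OGT mRNA",
                            initial_tokens=dose, role_tag="rna"))
        transitions.append(
            Transition("degrade_ogt_mrna", "shRNA-guided OGT mRNA degradation",
                       rate_constant=rate, kind="sink")
        )
        arcs += [Arc("shrna", "degrade_ogt_mrna"),
                 Arc("ogt_mrna", "degrade_ogt_mrna")]
    elif iv.kind == "bzx":
        _require_place(net, "ogt", iv.kind)
        rate = float(iv.extra.get("rate", cfg["rates"]["sequester_ogt"]))
        places.append(Place("bzx", "BZX (suicide OGT inhibitor)",
                            initial_tokens=dose, role_tag="drug"))
        places.append(Place("ogt_bzx_complex", "inert OGT-BZX adduct",
                            initial_tokens=0.0, role_tag="drug"))
        transitions.append(
            Transition("sequester_ogt", "covalent OGT-BZX complex formation",
                       rate_constant=rate)
        )
        arcs += [Arc("bzx", "sequester_ogt"), Arc("ogt", "sequester_ogt"),
                 Arc("sequester_ogt", "ogt_bzx_complex")]
    else:  # metformin
        if "proliferate" not in net.transition_ids:
            raise InterventionError(
                f"metformin intervention needs the proliferation transition, "
                f"absent from net {net.name!r}"
            )
        weight = float(iv.extra.get("gate_weight", cfg["metformin_gate_weight"]))
        upkeep = float(
            iv.extra.get("rate", cfg["rates"]["metformin_upkeep_per_dose"])
        ) * dose
        places.append(Place("metformin", "Metformin",
                            initial_tokens=dose, role_tag="drug"))
        if upkeep > 0:
            transitions.append(
                Transition("src_metformin", "metformin replenishment",
                           rate_constant=upkeep, kind="source")
            )
            arcs.append(Arc("src_metformin", "metformin"))
        arcs.append(
            Arc("metformin", "proliferate", weight=weight, arc_type="inhibitory")
        )

    out = PetriNet(places=tuple(places), transitions=tuple(transitions),
                   arcs=tuple(arcs), name=f"{net.name}+{iv.kind}")
    require_valid(out)
    return out


def apply_plan(plan: InterventionPlan) -> PetriNet:
    """Build the base variant and fold the interventions in, left to right.

    The shipped kinds touch disjoint parts of the net, so the result does
    not depend on the order of application (up to element order).
    """
    net = build_model(plan.base_variant)
    for iv in plan.interventions:
        net = apply_intervention(net, iv)
    return net


def dose_sweep(
    plan: InterventionPlan,
    kind: str,
    doses: Sequence[float],
    readout_place: str,
    settings: SimulationSettings | None = None,
    mode: str = "final",
) -> list[tuple[float, float]]:
    """Re-simulate the plan at each dose of one intervention kind.

    The swept kind replaces (or is appended to) the plan's interventions;
    every dose uses the same settings.  Returns (dose, readout) pairs in
    increasing dose order.  The default ``final`` mode reads terminal
    activity, matching dose-escalation time courses.
    """
    if not len(doses):
        raise ValueError("doses must be nonempty")
    if any(d < 0 for d in doses):
        raise ValueError("doses must be nonnegative")
    settings = settings or SimulationSettings()
    others = tuple(iv for iv in plan.interventions if iv.kind != kind)
    results = []
    for dose in sorted(float(d) for d in doses):
        swept = InterventionPlan(plan.base_variant, others + (Intervention(kind, dose),))
        traj = simulate(apply_plan(swept), settings)
        results.append((dose, readout(traj, readout_place, mode=mode)))
    return results
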