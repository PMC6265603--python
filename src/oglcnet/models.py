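"""Programmatic builders for the three PI3K/Akt-OGT pathway variants.

The insulin signalling chain is shared by all variants:

    insulin -> insulin receptor -> receptor complex -> IRS-1 -> PI3K
    -> PIP3 -> (PDK1, mTORC2) -> Akt -> {GLUT4 translocation, survival}

alongside the hexosamine branch glucose -> UDP-GlcNAc -> OGT (with OGT
mRNA supplying the enzyme and OGA as its antagonist).  Signalling proteins
are modelled as active/inactive place pairs connected by activation and
deactivation transitions; "activity" always means the active-place token
level.  Catalysts (receptor, PDK1, mTORC2, OGT, OGA, upstream active
kinases) appear on both sides of the transitions they drive, so their own
marking stays constant unless something else consumes them.

The three variants differ in how OGT couples to the chain:

* ``normal_adipocyte`` — O-GlcNAc cycling on IRS-1 and Akt is present but
  weak and balanced by OGA; insulin signalling proceeds normally.
* ``insulin_resistant_adipocyte`` — same wiring, but OGT is elevated and
  the OGT-driven deactivation of IRS-1 and Akt runs at strongly elevated
  rate constants, dampening the whole cascade.
* ``cancer_hyperglycemia`` — glucose supply is elevated, feeding
  UDP-GlcNAc and hence OGT; here O-GlcNAcylation *activates* Akt, and OGT
  additionally boosts GLUT4 surface delivery and the proliferation
  transition.  OGT does not touch IRS-1 in this variant.

All initial markings and rate constants come from the shipped
``data/defaults.yaml`` (the single source of truth); ``VariantSpec``
overrides are applied on top.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import networkx as nx
import numpy as np
import yaml

from .core import Arc, PetriNet, Place, Transition, require_valid
from .errors import ConfigError

__all__ = ["VARIANTS", "VariantSpec", "build_model", "default_config", "random_net"]

VARIANTS = (
    "normal_adipocyte",
    "insulin_resistant_adipocyte",
    "cancer_hyperglycemia",
)

_PLACES: tuple[tuple[str, str, str], ...] = (
    # (id, human name, role tag)
    ("insulin", "Insulin", "protein"),
    ("insulin_receptor", "Insulin receptor", "protein"),
    ("complex1", "Insulin-receptor complex", "protein"),
    ("irs1_inactive", "IRS-1 (inactive)", "protein"),
    ("irs1_active", "IRS-1 (active)", "protein"),
    ("pi3k_inactive", "PI3K (inactive)", "protein"),
    ("pi3k_active", "PI3K (active)", "protein"),
    ("pip3", "PIP3", "metabolite"),
    ("pdk1", "PDK1", "enzyme"),
    ("mtorc2", "mTORC2", "enzyme"),
    ("akt_inactive", "Akt (inactive)", "protein"),
    ("akt_active", "Akt (active)", "protein"),
    ("glut4_internal", "GLUT4 (internal)", "protein"),
    ("glut4_membrane", "GLUT4 (membrane)", "protein"),
    ("cell_survival", "Cell survival / proliferation", "process-readout"),
    ("glucose", "Glucose", "metabolite"),
    ("udp_glcnac", "UDP-GlcNAc", "metabolite"),
    ("ogt_mrna", "OGT mRNA", "rna"),
    ("ogt", "OGT", "enzyme"),
    ("oga", "OGA", "enzyme"),
)


def _rxn(tid, name, *, consumes=(), produces=(), catalysts=(), kind="internal"):
    """One transition spec: catalysts get both an input and an output arc."""
    return (tid, name, kind, tuple(consumes), tuple(produces), tuple(catalysts))


_BACKBONE = (
    _rxn("src_insulin", "insulin secretion", produces=["insulin"], kind="source"),
    _rxn("dec_insulin", "insulin clearance", consumes=["insulin"], kind="sink"),
    _rxn("bind_receptor", "receptor autophosphorylation",
         consumes=["insulin"], produces=["complex1"], catalysts=["insulin_receptor"]),
    _rxn("dec_complex1", "receptor complex dissociation",
         consumes=["complex1"], kind="sink"),
    _rxn("act_irs1", "IRS-1 phosphorylation",
         consumes=["irs1_inactive"], produces=["irs1_active"], catalysts=["complex1"]),
    _rxn("deact_irs1", "IRS-1 dephosphorylation",
         consumes=["irs1_active"], produces=["irs1_inactive"]),
    _rxn("act_pi3k", "PI3K activation",
         consumes=["pi3k_inactive"], produces=["pi3k_active"], catalysts=["irs1_active"]),
    _rxn("deact_pi3k", "PI3K deactivation",
         consumes=["pi3k_active"], produces=["pi3k_inactive"]),
    _rxn("syn_pip3", "PIP3 production", produces=["pip3"], catalysts=["pi3k_active"]),
    _rxn("dec_pip3", "PIP3 dephosphorylation", consumes=["pip3"], kind="sink"),
    _rxn("act_akt", "Akt phosphorylation (T308/S473)",
         consumes=["akt_inactive"], produces=["akt_active"],
         catalysts=["pip3", "pdk1", "mtorc2"]),
    _rxn("deact_akt", "Akt dephosphorylation",
         consumes=["akt_active"], produces=["akt_inactive"]),
    _rxn("internalize_glut4", "GLUT4 internalisation",
         consumes=["glut4_membrane"], produces=["glut4_internal"]),
    _rxn("dec_survival", "survival signal decay",
         consumes=["cell_survival"], kind="sink"),
    _rxn("src_glucose", "glucose supply", produces=["glucose"], kind="source"),
    _rxn("dec_glucose", "glucose consumption (glycolysis etc.)",
         consumes=["glucose"], kind="sink"),
    _rxn("hbp_flux", "hexosamine biosynthetic flux",
         consumes=["glucose"], produces=["udp_glcnac"]),
    _rxn("dec_udp", "UDP-GlcNAc turnover", consumes=["udp_glcnac"], kind="sink"),
    _rxn("transcribe_ogt", "OGT transcription", produces=["ogt_mrna"], kind="source"),
    _rxn("dec_ogt_mrna", "OGT mRNA decay", consumes=["ogt_mrna"], kind="sink"),
    _rxn("syn_ogt", "OGT synthesis / UDP-GlcNAc charging",
         consumes=["udp_glcnac"], produces=["ogt"], catalysts=["ogt_mrna"]),
    _rxn("dec_ogt", "OGT decay", consumes=["ogt"], kind="sink"),
)

# O-GlcNAc cycling on IRS-1 and Akt: deactivating in adipocytes (normal
# and insulin resistant), reversed by OGA.
_ADIPOCYTE_EXTRA = (
    _rxn("oglcnac_irs1", "IRS-1 O-GlcNAcylation (deactivating)",
         consumes=["irs1_active"], produces=["irs1_inactive"], catalysts=["ogt"]),
    _rxn("deglcnac_irs1", "IRS-1 de-O-GlcNAcylation",
         consumes=["irs1_inactive"], produces=["irs1_active"], catalysts=["oga"]),
    _rxn("oglcnac_akt", "Akt O-GlcNAcylation (deactivating)",
         consumes=["akt_active"], produces=["akt_inactive"], catalysts=["ogt"]),
    _rxn("deglcnac_akt", "Akt de-O-GlcNAcylation",
         consumes=["akt_inactive"], produces=["akt_active"], catalysts=["oga"]),
    _rxn("translocate_glut4", "GLUT4 translocation to membrane",
         consumes=["glut4_internal"], produces=["glut4_membrane"],
         catalysts=["akt_active"]),
    _rxn("proliferate", "cell survival signalling",
         produces=["cell_survival"], catalysts=["akt_active"]),
)

# In the hyperglycemic cancer cell O-GlcNAcylation activates Akt, and OGT
# boosts GLUT4 delivery and proliferation; IRS-1 is not an OGT target here.
_CANCER_EXTRA = (
    _rxn("ogt_boost_akt", "Akt O-GlcNAcylation (activating)",
         consumes=["akt_inactive"], produces=["akt_active"], catalysts=["ogt"]),
    _rxn("oga_damp_akt", "Akt de-O-GlcNAcylation",
         consumes=["akt_active"], produces=["akt_inactive"], catalysts=["oga"]),
    _rxn("translocate_glut4", "OGT-boosted GLUT4 translocation",
         consumes=["glut4_internal"], produces=["glut4_membrane"],
         catalysts=["akt_active", "ogt"]),
    _rxn("proliferate", "OGT-boosted proliferation signalling",
         produces=["cell_survival"], catalysts=["akt_active", "ogt"]),
)

_TOPOLOGY = {
    "normal_adipocyte": _BACKBONE + _ADIPOCYTE_EXTRA,
    "insulin_resistant_adipocyte": _BACKBONE + _ADIPOCYTE_EXTRA,
    "cancer_hyperglycemia": _BACKBONE + _CANCER_EXTRA,
}


@dataclass(frozen=True)
class VariantSpec:
    """A pathway variant plus marking/rate overrides on top of the defaults.

    ``config`` maps place ids to initial token levels and transition ids to
    rate constants, either as one flat mapping or as
    ``{"places": {...}, "rates": {...}}``.
    """

    variant: str
    config: Mapping = field(default_factory=dict)

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ConfigError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )


def _load_defaults() -> dict:
    text = resources.files("oglcnet").joinpath("data/defaults.yaml").read_text()
    return yaml.safe_load(text)


_DEFAULTS_CACHE: dict | None = None


def shipped_defaults() -> dict:
    """The parsed shipped configuration file (deep-copied on every call)."""
    global _DEFAULTS_CACHE
    if _DEFAULTS_CACHE is None:
        _DEFAULTS_CACHE = _load_defaults()
    return copy.deepcopy(_DEFAULTS_CACHE)


def default_config(variant: str) -> dict:
    """Shipped default marking/rate map for one variant.

    Returns ``{"places": {place_id: tokens}, "rates": {transition_id: k}}``
    restricted to the ids that variant actually contains.
    """
    if variant not in VARIANTS:
        raise ConfigError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    raw = shipped_defaults()["variants"][variant]
    tids = {spec[0] for spec in _TOPOLOGY[variant]}
    pids = {pid for pid, _, _ in _PLACES}
    places = {pid: float(v) for pid, v in raw["places"].items() if pid in pids}
    rates = {tid: float(v) for tid, v in raw["rates"].items() if tid in tids}
    missing = tids - set(rates)
    if missing:  # defensive: shipped file must cover every transition
        raise ConfigError(f"defaults.yaml lacks rates for {sorted(missing)}")
    return {"places": places, "rates": rates}


def _normalise_overrides(config: Mapping, pids: set[str], tids: set[str]):
    """Split a flat or nested override map into (place, rate) overrides."""
    if not config:
        return {}, {}
    if set(config) <= {"places", "rates"}:
        places = dict(config.get("places", {}))
        rates = dict(config.get("rates", {}))
    else:
        places, rates = {}, {}
        for key, value in config.items():
            if key in pids:
                places[key] = value
            else:
                rates[key] = value
    unknown = (set(places) - pids) | (set(rates) - tids)
    if unknown:
        raise ConfigError(
            f"override(s) reference unknown id(s): {sorted(unknown)}; "
            f"valid places: {sorted(pids)}; valid transitions: {sorted(tids)}"
        )
    bad = {k: v for k, v in {**places, **rates}.items()
           if not isinstance(v, (int, float)) or isinstance(v, bool)}
    if bad:
        raise ConfigError(f"override values must be numbers, got {bad}")
    return {k: float(v) for k, v in places.items()}, {
        k: float(v) for k, v in rates.items()
    }


def build_model(spec: VariantSpec | str) -> PetriNet:
    """Build one pathway variant as a validating continuous Petri net."""
    if isinstance(spec, str):
        spec = VariantSpec(spec)
    topology = _TOPOLOGY[spec.variant]
    tids = {s[0] for s in topology}
    pids = {pid for pid, _, _ in _PLACES}
    cfg = default_config(spec.variant)
    place_over, rate_over = _normalise_overrides(spec.config, pids, tids)
    tokens = {**cfg["places"], **place_over}
    rates = {**cfg["rates"], **rate_over}

    places = tuple(
        Place(id=pid, name=name, initial_tokens=tokens[pid], role_tag=tag)
        for pid, name, tag in _PLACES
    )
    transitions, arcs = [], []
    for tid, name, kind, consumes, produces, catalysts in topology:
        transitions.append(
            Transition(id=tid, name=name, rate_constant=rates[tid], kind=kind)
        )
        for pid in consumes:
            arcs.append(Arc(source=pid, target=tid))
        for pid in produces:
            arcs.append(Arc(source=tid, target=pid))
        for pid in catalysts:
            arcs.append(Arc(source=pid, target=tid))
            arcs.append(Arc(source=tid, target=pid))
    net = PetriNet(
        places=places,
        transitions=tuple(transitions),
        arcs=tuple(arcs),
        name=spec.variant,
    )
    require_valid(net)
    return net


def random_net(n_places: int, n_transitions: int, seed: int) -> PetriNet:
    """Seed-deterministic random connected net, for engine testing.

    Arc weights are 1, initial tokens uniform on [0, 5], roughly 10% of
    place->transition arcs are inhibitory, rate constants uniform on
    [0.1, 1].
    """
    if n_places < 1:
        raise ValueError("n_places must be >= 1")
    if n_transitions < 0:
        raise ValueError("n_transitions must be >= 0")
    rng = np.random.default_rng(seed)
    places = tuple(
        Place(id=f"p{i}", initial_tokens=float(np.round(rng.uniform(0, 5), 3)))
        for i in range(n_places)
    )
    transitions = tuple(
        Transition(id=f"t{j}", rate_constant=float(np.round(rng.uniform(0.1, 1), 3)))
        for j in range(n_transitions)
    )
    arc_set: set[tuple[str, str, str]] = set()
    for j in range(n_transitions):
        tid = f"t{j}"
        for pid in rng.choice(n_places, size=rng.integers(1, min(n_places, 2) + 1),
                              replace=False):
            kind = "inhibitory" if rng.random() < 0.1 else "standard"
            arc_set.add((f"p{pid}", tid, kind))
        for pid in rng.choice(n_places, size=rng.integers(1, min(n_places, 2) + 1),
                              replace=False):
            arc_set.add((tid, f"p{pid}", "standard"))
    # stitch components together so the net is weakly connected: attach
    # every stray component to the one containing transition t0
    if n_transitions > 0:
        while True:
            g = nx.Graph()
            g.add_nodes_from(p.id for p in places)
            g.add_nodes_from(t.id for t in transitions)
            g.add_edges_from((s, t) for s, t, _ in arc_set)
            comps = sorted(nx.connected_components(g), key=lambda c: sorted(c))
            if len(comps) == 1:
                break
            home = next(c for c in comps if "t0" in c)
            stray = sorted(next(c for c in comps if c is not home))
            stray_place = next((x for x in stray if x.startswith("p")), None)
            if stray_place is not None:
                arc_set.add((stray_place, "t0", "standard"))
            else:  # component of bare transitions: wire one to a place
                arc_set.add((stray[0], "p0", "standard"))
    # drop duplicate standard/inhibitory pairs on the same (p, t) edge
    cleaned = {}
    for s, t, kind in sorted(arc_set):
        cleaned[(s, t)] = kind if (s, t) not in cleaned else "standard"
    arcs = tuple(
        Arc(source=s, target=t, arc_type=kind) for (s, t), kind in sorted(cleaned.items())
    )
    net = PetriNet(places=places, transitions=transitions, arcs=arcs,
                   name=f"random-{seed}")
    require_valid(net)
    return net
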