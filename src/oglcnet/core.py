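"""Petri net data model, structural validation and invariant analysis.

A continuous place/transition net is a bipartite graph: places carry
nonnegative real token levels (relative activity of a protein, drug,
metabolite ...), transitions are the processes that move tokens along
weighted arcs.  Inhibitory arcs run from a place to a transition only and
suppress its firing without moving tokens.

The structural layer here is purely combinatorial; the continuous firing
semantics live in :mod:`oglcnet.dynamics`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Iterable, Mapping

import numpy as np

from .errors import InvalidNetError, UnknownElementError

__all__ = [
    "Place",
    "Transition",
    "Arc",
    "PetriNet",
    "Marking",
    "Violation",
    "validate_net",
    "incidence_matrix",
    "p_invariants",
]

#: Allowed reporting colour-group tags for places.
ROLE_TAGS = frozenset(
    {"protein", "enzyme", "drug", "rna", "metabolite", "process-readout"}
)

TRANSITION_KINDS = frozenset({"internal", "source", "sink"})
ARC_TYPES = frozenset({"standard", "inhibitory"})


@dataclass(frozen=True)
class Place:
    """An entity (protein, drug, metabolite...) holding real-valued tokens.

    ``initial_tokens`` is a relative activity level, not a concentration:
    the models in this package only support statements about relative
    change between conditions.
    """

    id: str
    name: str = ""
    initial_tokens: float = 0.0
    role_tag: str | None = None

    def __post_init__(self):
        if not self.name:
            object.__setattr__(self, "name", self.id)


@dataclass(frozen=True)
class Transition:
    """A process (reaction, transport, synthesis, decay ...).

    ``kind`` distinguishes internal transitions from *source* transitions
    (no inputs: constant supply/synthesis) and *sink* transitions (no
    outputs: decay or dissociation out of the system).
    """

    id: str
    name: str = ""
    rate_constant: float = 1.0
    kind: str = "internal"

    def __post_init__(self):
        if not self.name:
            object.__setattr__(self, "name", self.id)


@dataclass(frozen=True)
class Arc:
    """A weighted arc between one place and one transition.

    ``weight`` is the multiplicity (default 1).  Inhibitory arcs are
    place->transition only and never move tokens.
    """

    source: str
    target: str
    weight: float = 1.0
    arc_type: str = "standard"


@dataclass(frozen=True)
class PetriNet:
    """The quadruple (P, T, f, m0) of a place/transition net."""

    places: tuple[Place, ...]
    transitions: tuple[Transition, ...]
    arcs: tuple[Arc, ...]
    name: str = "net"

    def __post_init__(self):
        object.__setattr__(self, "places", tuple(self.places))
        object.__setattr__(self, "transitions", tuple(self.transitions))
        object.__setattr__(self, "arcs", tuple(self.arcs))

    # -- lookups ---------------------------------------------------------
    @property
    def place_ids(self) -> tuple[str, ...]:
        return tuple(p.id for p in self.places)

    @property
    def transition_ids(self) -> tuple[str, ...]:
        return tuple(t.id for t in self.transitions)

    def place(self, place_id: str) -> Place:
        for p in self.places:
            if p.id == place_id:
                return p
        raise UnknownElementError(f"no place {place_id!r} in net {self.name!r}")

    def transition(self, transition_id: str) -> Transition:
        for t in self.transitions:
            if t.id == transition_id:
                return t
        raise UnknownElementError(
            f"no transition {transition_id!r} in net {self.name!r}"
        )

    def place_index(self, place_id: str) -> int:
        try:
            return self.place_ids.index(place_id)
        except ValueError:
            raise UnknownElementError(
                f"no place {place_id!r} in net {self.name!r}"
            ) from None

    def input_arcs(self, transition_id: str) -> tuple[Arc, ...]:
        """Standard arcs place->transition feeding ``transition_id``."""
        return tuple(
            a
            for a in self.arcs
            if a.target == transition_id and a.arc_type == "standard"
        )

    def output_arcs(self, transition_id: str) -> tuple[Arc, ...]:
        return tuple(
            a
            for a in self.arcs
            if a.source == transition_id and a.arc_type == "standard"
        )

    def inhibitor_arcs(self, transition_id: str) -> tuple[Arc, ...]:
        return tuple(
            a
            for a in self.arcs
            if a.target == transition_id and a.arc_type == "inhibitory"
        )

    def initial_marking(self) -> "Marking":
        return Marking({p.id: p.initial_tokens for p in self.places})

    # -- functional updates (nets are immutable) -------------------------
    def with_name(self, name: str) -> "PetriNet":
        return replace(self, name=name)

    def structural_key(self):
        """Order-insensitive canonical form, for equality up to element order."""
        return (
            frozenset(self.places),
            frozenset(self.transitions),
            frozenset(self.arcs),
        )


@dataclass(frozen=True)
class Marking:
    """Assignment of nonnegative real token levels to every place."""

    values: Mapping[str, float]

    def __post_init__(self):
        object.__setattr__(self, "values", dict(self.values))

    def __getitem__(self, place_id: str) -> float:
        try:
            return self.values[place_id]
        except KeyError:
            raise UnknownElementError(f"no place {place_id!r} in marking") from None

    def as_vector(self, net: PetriNet) -> np.ndarray:
        missing = set(net.place_ids) - set(self.values)
        extra = set(self.values) - set(net.place_ids)
        if missing or extra:
            raise UnknownElementError(
                f"marking does not cover net {net.name!r}: "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )
        return np.array([self.values[p] for p in net.place_ids], dtype=float)


@dataclass(frozen=True)
class Violation:
    """One broken structural rule, naming the offending element."""

    rule: str
    element: str
    detail: str = ""

    def __str__(self):
        msg = f"{self.rule}: {self.element}"
        return f"{msg} ({self.detail})" if self.detail else msg


def validate_net(net: PetriNet) -> list[Violation]:
    """Check every structural invariant; violations are data, not exceptions.

    Returns an empty list iff the net is well formed: unique ids, bipartite
    arcs, inhibitory arcs place->transition only, nonnegative markings,
    positive rates and weights, source/sink arity, no duplicate arcs, at
    least one place.
    """
    violations: list[Violation] = []
    pids = [p.id for p in net.places]
    tids = [t.id for t in net.transitions]
    pset, tset = set(pids), set(tids)

    if not net.places:
        violations.append(Violation("empty net", net.name, "at least one place required"))
    for dup in _duplicates(pids):
        violations.append(Violation("duplicate place id", dup))
    for dup in _duplicates(tids):
        violations.append(Violation("duplicate transition id", dup))
    for shared in pset & tset:
        violations.append(
            Violation("id shared between place and transition", shared)
        )

    for p in net.places:
        if p.initial_tokens < 0:
            violations.append(
                Violation("negative initial tokens", p.id, f"{p.initial_tokens}")
            )
        if p.role_tag is not None and p.role_tag not in ROLE_TAGS:
            violations.append(
                Violation("unknown role tag", p.id, repr(p.role_tag))
            )

    for t in net.transitions:
        if not t.rate_constant > 0:
            violations.append(
                Violation("non-positive rate constant", t.id, f"{t.rate_constant}")
            )
        if t.kind not in TRANSITION_KINDS:
            violations.append(Violation("unknown transition kind", t.id, repr(t.kind)))

    seen_arcs: set[tuple[str, str, str]] = set()
    for a in net.arcs:
        label = f"{a.source}->{a.target}"
        src_p, src_t = a.source in pset, a.source in tset
        dst_p, dst_t = a.target in pset, a.target in tset
        if not (src_p or src_t):
            violations.append(Violation("dangling arc endpoint", label, a.source))
            continue
        if not (dst_p or dst_t):
            violations.append(Violation("dangling arc endpoint", label, a.target))
            continue
        if (src_p and dst_p) or (src_t and dst_t):
            violations.append(Violation("non-bipartite arc", label))
            continue
        if a.arc_type not in ARC_TYPES:
            violations.append(Violation("unknown arc type", label, repr(a.arc_type)))
            continue
        if a.arc_type == "inhibitory" and not (src_p and dst_t):
            violations.append(Violation("inhibitory arc direction", label))
            continue
        if not a.weight > 0:
            violations.append(Violation("non-positive arc weight", label, f"{a.weight}"))
        key = (a.source, a.target, a.arc_type)
        if key in seen_arcs:
            violations.append(Violation("duplicate arc", label, a.arc_type))
        seen_arcs.add(key)

    # source/sink arity depends on resolved arcs, so check last; an
    # inhibitory arc gates but does not consume, so it may target a source
    for t in net.transitions:
        if t.kind == "source" and any(
            a.target == t.id and a.arc_type == "standard"
            for a in net.arcs
            if a.source in pset
        ):
            violations.append(Violation("source transition has inputs", t.id))
        if t.kind == "sink" and any(a.source == t.id for a in net.arcs):
            violations.append(Violation("sink transition has outputs", t.id))
    return violations


def require_valid(net: PetriNet) -> None:
    """Raise :class:`InvalidNetError` naming the first violation, if any."""
    violations = validate_net(net)
    if violations:
        raise InvalidNetError(violations)


def incidence_matrix(net: PetriNet) -> np.ndarray:
    """The |P| x |T| token-flow matrix C.

    ``C[p, t]`` is the net number of tokens transition ``t`` adds to place
    ``p`` per firing: output weights minus input weights.  Inhibitory arcs
    move no tokens and contribute nothing.
    """
    require_valid(net)
    p_index = {p: i for i, p in enumerate(net.place_ids)}
    t_index = {t: j for j, t in enumerate(net.transition_ids)}
    C = np.zeros((len(p_index), len(t_index)))
    for a in net.arcs:
        if a.arc_type != "standard":
            continue
        if a.source in p_index:  # place -> transition: consumption
            C[p_index[a.source], t_index[a.target]] -= a.weight
        else:  # transition -> place: production
            C[p_index[a.target], t_index[a.source]] += a.weight
    return C


def p_invariants(net: PetriNet) -> list[np.ndarray]:
    """Minimal-support nonnegative vectors x with x^T C = 0.

    The weighted token sum x . m is conserved along every trajectory of the
    net, which makes these vectors the structural conservation laws (e.g.
    an active/inactive protein pair whose total is fixed).  Computed with
    the classical Farkas/Fourier-Motzkin elimination over exact rationals,
    so the returned integer vectors satisfy x^T C = 0 exactly.

    Returns a generating set of minimal-support invariants, possibly empty
    (source/sink transitions break conservation for the places they touch).
    """
    C = incidence_matrix(net)
    n_places, n_trans = C.shape
    frac = np.vectorize(Fraction)
    # rows of [C | I]; eliminate the C columns one at a time keeping
    # nonnegative combinations only
    rows: list[tuple[tuple[Fraction, ...], tuple[Fraction, ...]]] = [
        (tuple(frac(C[i, :])), tuple(Fraction(int(i == j)) for j in range(n_places)))
        for i in range(n_places)
    ]
    for col in range(n_trans):
        zero, pos, neg = [], [], []
        for left, right in rows:
            v = left[col]
            (zero if v == 0 else pos if v > 0 else neg).append((left, right))
        new_rows = list(zero)
        for pl, pr in pos:
            for nl, nr in neg:
                a, b = -nl[col], pl[col]  # both positive
                left = tuple(a * x + b * y for x, y in zip(pl, nl))
                right = tuple(a * x + b * y for x, y in zip(pr, nr))
                new_rows.append((left, right))
        rows = new_rows
    # normalise to coprime integer vectors, deduplicate
    candidates: dict[tuple[int, ...], np.ndarray] = {}
    for _, right in rows:
        if all(v == 0 for v in right):
            continue
        denom = np.lcm.reduce([f.denominator for f in right])
        ints = np.array([int(f * denom) for f in right], dtype=object)
        g = np.gcd.reduce([abs(int(v)) for v in ints if v != 0])
        ints = ints // g
        candidates[tuple(int(v) for v in ints)] = ints.astype(float)
    # keep minimal-support vectors only
    supports = {k: frozenset(i for i, v in enumerate(k) if v != 0) for k in candidates}
    minimal = []
    for k, sup in supports.items():
        if not any(
            other != k and supports[other] < sup or
            (other != k and supports[other] == sup and other < k)
            for other in supports
        ):
            minimal.append(candidates[k])
    minimal.sort(key=lambda v: tuple(v))
    return minimal


def _duplicates(items: Iterable[str]) -> list[str]:
    seen, dups = set(), []
    for x in items:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    return dups
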