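"""Continuous firing semantics and numerical time-course simulation.

Each transition fires continuously at a mass-action rate

    v_t = k_t * prod_p m_p^{w(p,t)} * prod_q g(m_q, w(q,t))

where the first product runs over standard input arcs (kinetic order =
arc weight), the second over inhibitory arcs, and ``g`` is the inhibition
gate.  Source transitions have no inputs and fire at the constant rate
k_t.  The induced ODE over the marking vector is dm/dt = C v(m), with C
the incidence matrix: inhibitory arcs gate rates but never move tokens.

The inhibition gate is smooth by default,

    g(m, w) = w^h / (w^h + m^h)

a decreasing sigmoid equal to 1/2 when the inhibitor marking reaches the
arc weight, with steepness ``h`` (default 4).  A discontinuous hard gate
(1 if m < w else 0) is available for semantics checks; the smooth form is
the default because a discontinuous right-hand side defeats adaptive
stiff integrators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .core import Marking, PetriNet, incidence_matrix, require_valid
from .errors import SimulationError, UnknownElementError

__all__ = [
    "SimulationSettings",
    "Trajectory",
    "transition_rate",
    "ode_rhs",
    "simulate",
    "readout",
]

READOUT_MODES = ("final", "mean_tail", "max")
#: Fraction of the time grid (from the end) averaged by ``mean_tail``.
TAIL_FRACTION = 0.2


@dataclass(frozen=True)
class SimulationSettings:
    """Integration horizon, grid and tolerances.

    Time is dimensionless ("time units"): the underlying models are
    qualitative and carry no absolute time calibration.
    """

    t_end: float = 100.0
    n_points: int = 201
    rel_tol: float = 1e-6
    abs_tol: float = 1e-9
    inhibition_steepness: float = 4.0
    hard_gate: bool = False

    def __post_init__(self):
        if not self.t_end > 0:
            raise ValueError(f"t_end must be positive, got {self.t_end}")
        if self.n_points < 2:
            raise ValueError(f"n_points must be >= 2, got {self.n_points}")
        if not (self.rel_tol > 0 and self.abs_tol > 0):
            raise ValueError("tolerances must be positive")
        if not self.inhibition_steepness > 0:
            raise ValueError("inhibition_steepness must be positive")


@dataclass(frozen=True)
class Trajectory:
    """Time-indexed matrix of markings; rows align with ``times``."""

    times: np.ndarray
    markings: np.ndarray
    place_ids: tuple[str, ...]
    net_name: str = "net"

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "markings", np.asarray(self.markings, dtype=float))
        object.__setattr__(self, "place_ids", tuple(self.place_ids))

    def column(self, place_id: str) -> np.ndarray:
        try:
            j = self.place_ids.index(place_id)
        except ValueError:
            raise UnknownElementError(
                f"no place {place_id!r} in trajectory of {self.net_name!r}"
            ) from None
        return self.markings[:, j]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.markings, columns=list(self.place_ids))
        df.insert(0, "time", self.times)
        return df

    def to_csv(self, destination) -> None:
        """Write ``time,<place_id>,...`` rows at full precision."""
        self.to_frame().to_csv(destination, index=False, float_format="%.17g")


def _gate(m: np.ndarray, w: np.ndarray, steepness: float, hard: bool) -> np.ndarray:
    if hard:
        return (m < w).astype(float)
    wh = w**steepness
    return wh / (wh + np.maximum(m, 0.0) ** steepness)


class _Compiled:
    """Vectorised rate evaluation for one net (index-based, no dict lookups)."""

    def __init__(self, net: PetriNet, settings: SimulationSettings):
        self.net = net
        self.C = incidence_matrix(net)
        self.k = np.array([t.rate_constant for t in net.transitions])
        p_index = {p: i for i, p in enumerate(net.place_ids)}
        t_index = {t: j for j, t in enumerate(net.transition_ids)}
        n_p, n_t = self.C.shape
        # kinetic-order matrix W[t, p] for standard input arcs and the
        # inhibitor weight matrix (nan where no inhibitory arc)
        self.W = np.zeros((n_t, n_p))
        self.inh_w = np.full((n_t, n_p), np.nan)
        for a in net.arcs:
            if a.source in p_index and a.target in t_index:
                if a.arc_type == "standard":
                    self.W[t_index[a.target], p_index[a.source]] += a.weight
                else:
                    self.inh_w[t_index[a.target], p_index[a.source]] = a.weight
        self.has_inputs = self.W.any(axis=1)
        self.inh_mask = ~np.isnan(self.inh_w)
        self.steepness = settings.inhibition_steepness
        self.hard = settings.hard_gate

    def rates(self, m: np.ndarray) -> np.ndarray:
        mm = np.maximum(m, 0.0)
        # prod_p m_p^W[t,p]; 0^0 = 1 handled by where-mask
        with np.errstate(divide="ignore", invalid="ignore"):
            logs = np.where(self.W != 0, self.W * np.log(np.maximum(mm, 1e-300)), 0.0)
        v = self.k * np.exp(logs.sum(axis=1))
        # exact zero when an input place is exactly empty
        empty = (mm == 0.0)
        if empty.any():
            v = np.where((self.W[:, empty] != 0).any(axis=1), 0.0, v)
        if self.inh_mask.any():
            g = np.ones_like(self.inh_w)
            g[self.inh_mask] = _gate(
                np.broadcast_to(mm, self.inh_w.shape)[self.inh_mask],
                self.inh_w[self.inh_mask],
                self.steepness,
                self.hard,
            )
            v = v * g.prod(axis=1)
        return v

    def rhs(self, m: np.ndarray) -> np.ndarray:
        return self.C @ self.rates(m)


def transition_rate(
    net: PetriNet,
    marking: Marking,
    transition_id: str,
    settings: SimulationSettings | None = None,
) -> float:
    """Continuous firing rate of one transition at the given marking."""
    settings = settings or SimulationSettings()
    net.transition(transition_id)  # raises UnknownElementError
    compiled = _Compiled(net, settings)
    m = marking.as_vector(net)
    j = net.transition_ids.index(transition_id)
    return float(compiled.rates(m)[j])


def ode_rhs(
    net: PetriNet,
    marking: Marking,
    settings: SimulationSettings | None = None,
) -> np.ndarray:
    """Token-balance derivative dm/dt = C v(m), ordered as ``net.place_ids``."""
    settings = settings or SimulationSettings()
    compiled = _Compiled(net, settings)
    return compiled.rhs(marking.as_vector(net))


def simulate(net: PetriNet, settings: SimulationSettings | None = None) -> Trajectory:
    """Integrate the net's ODE from its initial marking.

    Deterministic given (net, settings).  Uses LSODA (adaptive,
    stiff-capable) with dense output sampled on a uniform grid.  Small
    negative excursions (an artefact of finite tolerances) are clipped to
    zero; excursions beyond ``100 * abs_tol`` abort with a
    :class:`SimulationError` because they indicate a modelling bug rather
    than roundoff.
    """
    settings = settings or SimulationSettings()
    require_valid(net)
    compiled = _Compiled(net, settings)
    m0 = net.initial_marking().as_vector(net)
    t_eval = np.linspace(0.0, settings.t_end, settings.n_points)
    sol = solve_ivp(
        lambda t, y: compiled.rhs(y),
        (0.0, settings.t_end),
        m0,
        method="LSODA",
        t_eval=t_eval,
        rtol=settings.rel_tol,
        atol=settings.abs_tol,
    )
    if not sol.success:
        raise SimulationError(f"integration failed: {sol.message}", time=sol.t[-1] if len(sol.t) else 0.0)
    y = sol.y.T
    threshold = 100.0 * settings.abs_tol
    worst = y.min()
    if worst < -threshold:
        i, j = np.unravel_index(np.argmin(y), y.shape)
        raise SimulationError(
            f"marking of {net.place_ids[j]!r} went negative ({worst:.3e})",
            time=float(sol.t[i]),
        )
    y = np.clip(y, 0.0, None)
    y[0, :] = m0
    return Trajectory(times=sol.t, markings=y, place_ids=net.place_ids, net_name=net.name)


def readout(traj: Trajectory, place_id: str, mode: str = "mean_tail") -> float:
    """Scalar summary of one place's trajectory.

    ``mean_tail`` (the default used for fold-change reporting) averages the
    last 20% of the time grid, damping transients; ``final`` takes the last
    sample; ``max`` the running maximum.
    """
    if mode not in READOUT_MODES:
        raise ValueError(f"unknown readout mode {mode!r}; expected one of {READOUT_MODES}")
    series = traj.column(place_id)
    if mode == "final":
        return float(series[-1])
    if mode == "max":
        return float(series.max())
    n_tail = max(1, int(np.ceil(TAIL_FRACTION * len(series))))
    return float(series[-n_tail:].mean())


def euler_simulate(net: PetriNet, t_end: float, h: float,
                   settings: SimulationSettings | None = None) -> np.ndarray:
    """Fixed-step explicit Euler endpoint, used as an independent oracle.

    Deliberately naive: one forward step at a time with clipping at zero,
    no adaptivity.  Returns the marking vector at ``t_end``.
    """
    settings = settings or SimulationSettings()
    compiled = _Compiled(net, settings)
    m = net.initial_marking().as_vector(net)
    n_steps = int(round(t_end / h))
    for _ in range(n_steps):
        m = np.maximum(m + h * compiled.rhs(m), 0.0)
    return m
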