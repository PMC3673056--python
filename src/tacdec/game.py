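"""Three-strategy deception game and its replicator dynamics.

An infinite, well-mixed population plays an iterated prisoner's dilemma with
three fixed strategies:

* conditional cooperators (CC), who aim to cooperate only with partners they
  assess as cooperative but slip up and cooperate with an identified defector
  in a fraction ``s`` of interactions;
* tactical deceivers (TD), who always defect but pay a cost ``d`` to conceal
  it, escaping detection with probability ``q``;
* honest defectors (HD), who always defect openly.

A CC therefore cooperates with a TD in a fraction ``q + s - q*s`` of their
interactions. Cooperating bestows benefit ``b`` on the partner at cost ``c``
to self. Per-round expected payoffs are

    pi_CC = (b - c) x_CC - c (q + s - q s) x_TD - c s x_HD
    pi_TD = b (q + s - q s) x_CC - d
    pi_HD = b s x_CC

and frequencies evolve by the replicator equation
``dx_i/dt = x_i (pi_i - sum_j pi_j x_j)``. Deception efficiency ``q`` is
either a constant or negatively frequency dependent, ``q = 1 - x_TD``
(detection improves as deceivers become common).

The analysis is restricted to the region ``b - c > s b > 0``, ``0 < s < 1``,
``c > d > 0`` (CC and HD are mutually uninvadable, HD dominates TD).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import fsolve

__all__ = [
    "GameError",
    "GameParameterError",
    "DegenerateCaseError",
    "NotAFixedPointError",
    "IntegrationError",
    "MultipleEquilibriaError",
    "GameParams",
    "PopulationState",
    "PayoffVector",
    "Trajectory",
    "EquilibriumReport",
    "RegimeClassification",
    "InvasionMatrix",
    "SweepGrid",
    "effective_coop_fraction",
    "payoffs",
    "replicator_rhs",
    "integrate",
    "classify_regime",
    "find_mixed_equilibrium",
    "find_interior_fixed_points",
    "invasion_analysis",
    "jacobian_stability",
    "sweep_equilibrium",
]

STRATEGIES = ("CC", "TD", "HD")

#: eigenvalue real parts below -STABILITY_TOL => stable, above +STABILITY_TOL
#: => unstable, in between => marginal (reported, never silently binned).
STABILITY_TOL = 1e-8


class GameError(ValueError):
    """Base class for domain errors in the game module."""


class GameParameterError(GameError):
    """Parameters violate the model's constraint set."""


class DegenerateCaseError(GameError):
    """A classification sits on a knife edge (difference within tolerance)."""


class NotAFixedPointError(GameError):
    """Stability analysis requested at a state that is not a fixed point."""


class IntegrationError(GameError):
    """The ODE solver failed or produced an inadmissible state."""


class MultipleEquilibriaError(GameError):
    """More than one stable mixed equilibrium found (structurally unexpected)."""


@dataclass(frozen=True)
class GameParams:
    """Constants of the deception game.

    Parameters
    ----------
    b, c : float
        Benefit received from / cost paid for a cooperative act (payoff units).
    s : float
        Fraction of rounds in which a CC cooperates with an *identified*
        defector (imperfect conditionality), in (0, 1).
    d : float
        Cost of tactical deception (payoff units), 0 < d < c.
    q_mode : {"constant", "freq_dependent"}
        Whether deception efficiency is a constant ``q`` or ``1 - x_TD``.
    q : float, optional
        Constant deception efficiency in (0, 1]; required iff
        ``q_mode == "constant"``.
    """

    b: float
    c: float
    s: float
    d: float
    q_mode: Literal["constant", "freq_dependent"] = "constant"
    q: float | None = None

    def __post_init__(self) -> None:
        b, c, s, d = self.b, self.c, self.s, self.d
        if not (0.0 < s < 1.0):
            raise GameParameterError(f"require 0 < s < 1, got s={s}")
        if not (b - c > s * b > 0.0):
            raise GameParameterError(
                f"require b - c > s*b > 0 (bistability constraint), got "
                f"b-c={b - c}, s*b={s * b}"
            )
        if not (c > d > 0.0):
            raise GameParameterError(f"require c > d > 0, got c={c}, d={d}")
        if self.q_mode == "constant":
            if self.q is None or not (0.0 < self.q <= 1.0):
                raise GameParameterError(
                    f"constant q_mode requires 0 < q <= 1, got q={self.q}"
                )
        elif self.q_mode == "freq_dependent":
            if self.q is not None:
                raise GameParameterError(
                    "q must be omitted when q_mode='freq_dependent' (q = 1 - x_TD)"
                )
        else:
            raise GameParameterError(f"unknown q_mode {self.q_mode!r}")

    def q_at(self, x_td: float) -> float:
        """Deception efficiency at deceiver frequency ``x_td``."""
        if self.q_mode == "constant":
            return float(self.q)  # type: ignore[arg-type]
        return 1.0 - x_td


SIMPLEX_TOL = 1e-9


@dataclass(frozen=True)
class PopulationState:
    """A point on the 3-simplex of strategy frequencies."""

    x_cc: float
    x_td: float
    x_hd: float

    def __post_init__(self) -> None:
        for name, x in zip(STRATEGIES, self.as_array()):
            if not (-1e-12 <= x <= 1.0 + 1e-12):
                raise GameError(f"frequency x_{name} = {x} outside [0, 1]")
        total = self.x_cc + self.x_td + self.x_hd
        if abs(total - 1.0) > SIMPLEX_TOL:
            raise GameError(f"frequencies sum to {total}, not 1 (tol {SIMPLEX_TOL})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x_cc, self.x_td, self.x_hd], dtype=float)

    @classmethod
    def from_array(cls, x: np.ndarray) -> "PopulationState":
        return cls(float(x[0]), float(x[1]), float(x[2]))


@dataclass(frozen=True)
class PayoffVector:
    """Expected per-round payoffs of the three strategies."""

    pi_cc: float
    pi_td: float
    pi_hd: float

    def as_array(self) -> np.ndarray:
        return np.array([self.pi_cc, self.pi_td, self.pi_hd], dtype=float)


@dataclass(frozen=True)
class Trajectory:
    """A replicator orbit sampled at increasing times."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), 3)
    params: GameParams

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise GameError("trajectory times must be strictly increasing")
        sums = self.states.sum(axis=1)
        if np.max(np.abs(sums - 1.0)) > SIMPLEX_TOL or np.min(self.states) < -1e-12:
            raise GameError("trajectory states violate the simplex invariant")

    @property
    def terminal_state(self) -> PopulationState:
        return PopulationState.from_array(self.states[-1])


@dataclass(frozen=True)
class EquilibriumReport:
    """An equilibrium, its location and local stability on the simplex.

    ``eigenvalues`` are those of the replicator Jacobian restricted to the
    simplex tangent plane. ``stable`` means both real parts < -STABILITY_TOL;
    ``marginal`` flags eigenvalues within the tolerance band. For the CC-TD
    mixed equilibrium, ``hd_invadable`` records whether a rare honest defector
    can invade (it can iff b(1-s) x_CC*^2 < d) and ``hd_margin`` stores
    b(1-s) x_CC*^2 - d.
    """

    state: PopulationState
    kind: Literal["vertex", "edge", "interior"]
    eigenvalues: tuple[complex, complex]
    stable: bool
    marginal: bool = False
    hd_invadable: bool | None = None
    hd_margin: float | None = None


@dataclass(frozen=True)
class RegimeClassification:
    """Outcome class of the constant-q model."""

    td_dominates_cc: bool
    cc_is_nash: bool
    hd_is_nash: bool
    label: Literal["cooperation_collapse", "bistable_honest"]


@dataclass(frozen=True)
class InvasionMatrix:
    """Pairwise invasion of monomorphic populations.

    ``invades[i, j]`` is True when a rare strategy ``STRATEGIES[i]`` earns
    strictly more than resident ``STRATEGIES[j]`` at the resident's vertex;
    exact payoff ties are flagged in ``neutral`` instead.
    """

    invades: np.ndarray
    neutral: np.ndarray
    strategies: tuple[str, ...] = STRATEGIES


@dataclass(frozen=True)
class SweepGrid:
    """Mixed-equilibrium CC frequency over a (b, d) grid at fixed s, c.

    ``x_cc_star`` is NaN where no stable, HD-resistant mixed equilibrium
    exists (or the parameter combination violates the constraint set);
    ``failures`` records per-cell reasons.
    """

    b_values: np.ndarray
    d_values: np.ndarray
    x_cc_star: np.ndarray  # shape (len(b_values), len(d_values))
    s: float
    c: float
    failures: dict = field(default_factory=dict)

    def to_long_frame(self):
        """Long-format table (b, d, s, x_cc_star, stable, hd_invadable)."""
        import pandas as pd

        rows = []
        for i, b in enumerate(self.b_values):
            for j, d in enumerate(self.d_values):
                v = self.x_cc_star[i, j]
                rows.append(
                    {
                        "b": b,
                        "d": d,
                        "s": self.s,
                        "x_cc_star": v,
                        "stable": bool(np.isfinite(v)),
                        "hd_invadable": (
                            self.failures.get((i, j)) == "hd_invadable"
                        ),
                    }
                )
        return pd.DataFrame(rows)


def effective_coop_fraction(q: float, s: float) -> float:
    """Fraction of interactions in which a CC cooperates with a TD.

    A TD escapes detection with probability ``q``; if detected, the CC still
    slips into cooperation in fraction ``s`` of rounds, giving ``q + s - q*s``.
    """
    if not (0.0 <= q <= 1.0):
        raise GameParameterError(f"q must lie in [0, 1], got {q}")
    if not (0.0 <= s < 1.0):
        raise GameParameterError(f"s must lie in [0, 1), got {s}")
    return q + s - q * s


def _payoffs_raw(x: np.ndarray, params: GameParams) -> np.ndarray:
    """Payoffs as polynomials in the (unvalidated) frequency vector."""
    b, c, s, d = params.b, params.c, params.s, params.d
    q = params.q_at(x[1])
    eff = q + s - q * s
    pi_cc = (b - c) * x[0] - c * eff * x[1] - c * s * x[2]
    pi_td = b * eff * x[0] - d
    pi_hd = b * s * x[0]
    return np.array([pi_cc, pi_td, pi_hd])


def payoffs(state: PopulationState, params: GameParams) -> PayoffVector:
    """Expected per-round payoffs of CC, TD and HD at ``state``."""
    pi = _payoffs_raw(state.as_array(), params)
    return PayoffVector(*pi)


def _rhs_raw(x: np.ndarray, params: GameParams) -> np.ndarray:
    pi = _payoffs_raw(x, params)
    mean = float(pi @ x)
    return x * (pi - mean)


def replicator_rhs(state: PopulationState, params: GameParams) -> np.ndarray:
    """Rates of change ``x_i (pi_i - mean payoff)``; components sum to 0."""
    return _rhs_raw(state.as_array(), params)


def integrate(
    state0: PopulationState,
    params: GameParams,
    t_end: float,
    rel_tol: float = 1e-8,
    abs_tol: float = 1e-10,
    n_points: int = 501,
) -> Trajectory:
    """Integrate the replicator dynamics from ``state0`` to time ``t_end``.

    Uses an adaptive Runge-Kutta solver; reported states are cleaned by
    clipping boundary undershoots no larger than ``max(1e-12, 10 * abs_tol)``
    to zero and renormalising. Larger violations raise ``IntegrationError``
    with diagnostics, as do solver failures.
    """
    if t_end <= 0:
        raise GameError(f"t_end must be positive, got {t_end}")
    sol = solve_ivp(
        lambda _t, x: _rhs_raw(x, params),
        (0.0, float(t_end)),
        state0.as_array(),
        method="RK45",
        rtol=rel_tol,
        atol=abs_tol,
        t_eval=np.linspace(0.0, float(t_end), n_points),
    )
    if not sol.success:
        raise IntegrationError(f"ODE solver failed: {sol.message}")
    states = sol.y.T.copy()
    clip = max(1e-12, 10.0 * abs_tol)
    worst = float(states.min())
    if worst < -clip:
        raise IntegrationError(
            f"frequency undershot the simplex boundary by {worst} "
            f"(clip threshold {clip}); tighten tolerances"
        )
    np.clip(states, 0.0, None, out=states)
    states /= states.sum(axis=1, keepdims=True)
    return Trajectory(times=sol.t.copy(), states=states, params=params)


def classify_regime(params: GameParams, tol: float = 1e-12) -> RegimeClassification:
    """Classify the constant-q model by whether TDs dominate CCs.

    TDs dominate CCs iff ``b(q + s - q s) - d > b - c``; then a rare TD
    destabilises the CC vertex and honest defection is the only Nash
    equilibrium (cooperation collapses). Otherwise CC and HD are both Nash
    equilibria. Knife-edge cases (difference within ``tol``) raise
    ``DegenerateCaseError`` rather than being silently classified.
    """
    if params.q_mode != "constant":
        raise GameParameterError("classify_regime applies to the constant-q model")
    b, c, s, d, q = params.b, params.c, params.s, params.d, float(params.q)
    gap = b * effective_coop_fraction(q, s) - d - (b - c)
    if abs(gap) <= tol:
        raise DegenerateCaseError(
            f"b(q+s-qs) - d - (b-c) = {gap}: boundary between regimes"
        )
    dominates = gap > 0
    return RegimeClassification(
        td_dominates_cc=dominates,
        cc_is_nash=not dominates,
        hd_is_nash=True,
        label="cooperation_collapse" if dominates else "bistable_honest",
    )


def _reduced_jacobian(x: np.ndarray, params: GameParams, h: float = 1e-6) -> np.ndarray:
    """Jacobian of the dynamics in (x_CC, x_TD) with x_HD = 1 - x_CC - x_TD.

    Central differences are exact up to O(h^2) * (third derivative); the
    right-hand side is cubic in x so the error is ~1e-12 at h=1e-6.
    """

    def red(u: np.ndarray) -> np.ndarray:
        full = np.array([u[0], u[1], 1.0 - u[0] - u[1]])
        return _rhs_raw(full, params)[:2]

    u0 = x[:2]
    jac = np.empty((2, 2))
    for k in range(2):
        e = np.zeros(2)
        e[k] = h
        jac[:, k] = (red(u0 + e) - red(u0 - e)) / (2.0 * h)
    return jac


def jacobian_stability(
    state: PopulationState,
    params: GameParams,
    fixed_point_tol: float = 1e-8,
) -> EquilibriumReport:
    """Linear stability of a fixed point, on the simplex tangent plane.

    The two eigenvalues are those of the Jacobian of the reduced
    (x_CC, x_TD) system. ``stable`` requires both real parts below
    -STABILITY_TOL; real parts inside the tolerance band mark the report
    ``marginal`` (and not stable).
    """
    x = state.as_array()
    resid = float(np.max(np.abs(_rhs_raw(x, params))))
    if resid > fixed_point_tol:
        raise NotAFixedPointError(
            f"replicator_rhs has max component {resid} > {fixed_point_tol}"
        )
    eig = np.linalg.eigvals(_reduced_jacobian(x, params))
    re = np.real(eig)
    stable = bool(np.all(re < -STABILITY_TOL))
    marginal = bool(np.any(np.abs(re) <= STABILITY_TOL))
    n_zero = int(np.sum(np.abs(x) > 1e-9))
    kind = "vertex" if n_zero == 1 else ("edge" if n_zero == 2 else "interior")
    return EquilibriumReport(
        state=state,
        kind=kind,
        eigenvalues=(complex(eig[0]), complex(eig[1])),
        stable=stable and not marginal,
        marginal=marginal,
    )


def _edge_quadratic(params: GameParams) -> tuple[float, float, float]:
    """Coefficients (A, B, C) of A t^2 + B t + C = pi_TD - pi_CC on the
    CC-TD edge with q = 1 - x_TD, in t = x_TD."""
    b, c, s, d = params.b, params.c, params.s, params.d
    return (b - c) * (1.0 - s), -b * (1.0 - s), c - d


def find_mixed_equilibrium(
    params: GameParams, boundary_tol: float = 1e-10
) -> EquilibriumReport | None:
    """Stable mixed CC-TD equilibrium of the frequency-dependent model.

    With q = 1 - x_TD, payoff equality pi_CC = pi_TD on the edge x_HD = 0
    reduces to the quadratic (b-c)(1-s) t^2 - b(1-s) t + (c-d) = 0 in
    t = x_TD. Interior roots in (0, 1) are candidate mixed equilibria; the
    flow along the edge stabilises at most one of them (the smaller root),
    which is returned with its tangent-plane eigenvalues and the
    honest-defector invasion check b(1-s) x_CC*^2 > d. Roots at 0 or 1 are
    boundary equilibria, not mixtures. Returns None when no interior root is
    edge-attracting.
    """
    if params.q_mode != "freq_dependent":
        raise GameParameterError(
            "mixed CC-TD equilibria require q_mode='freq_dependent'"
        )
    b, s, d = params.b, params.s, params.d
    A, B, C = _edge_quadratic(params)
    disc = B * B - 4.0 * A * C
    if disc < 0:
        return None
    roots = [(-B - math.sqrt(disc)) / (2.0 * A), (-B + math.sqrt(disc)) / (2.0 * A)]
    interior = [t for t in roots if boundary_tol < t < 1.0 - boundary_tol]
    # Edge flow is dt/dtau = t(1-t)(pi_TD - pi_CC) = t(1-t)(A t^2 + B t + C);
    # a root attracts along the edge iff the quadratic's slope there is < 0.
    attracting = [t for t in interior if 2.0 * A * t + B < 0.0]
    if len(attracting) > 1:
        raise MultipleEquilibriaError(
            f"{len(attracting)} edge-stable mixed equilibria found: {attracting}"
        )
    if not attracting:
        return None
    t = attracting[0]
    x_cc = 1.0 - t
    state = PopulationState(x_cc, t, 0.0)
    rep = jacobian_stability(state, params)
    margin = b * (1.0 - s) * x_cc**2 - d
    return EquilibriumReport(
        state=state,
        kind="edge",
        eigenvalues=rep.eigenvalues,
        stable=rep.stable,
        marginal=rep.marginal,
        hd_invadable=bool(margin < 0.0),
        hd_margin=margin,
    )


def invasion_analysis(params: GameParams, tol: float = 1e-12) -> InvasionMatrix:
    """Pairwise invasion of monomorphic populations from rare-mutant payoffs.

    Entry (i, j) compares the payoff of a rare strategy i against resident j
    at the resident's vertex; i invades iff its payoff strictly exceeds the
    resident's. Payoff ties within ``tol`` are flagged neutral. Under
    frequency-dependent deception efficiency, q is evaluated at the resident's
    deceiver frequency (q = 1 at the CC vertex, q = 0 at the TD vertex).
    """
    invades = np.zeros((3, 3), dtype=bool)
    neutral = np.zeros((3, 3), dtype=bool)
    for j in range(3):
        vertex = np.zeros(3)
        vertex[j] = 1.0
        pi = _payoffs_raw(vertex, params)
        for i in range(3):
            if i == j:
                continue
            diff = pi[i] - pi[j]
            if abs(diff) <= tol:
                neutral[i, j] = True
            elif diff > 0:
                invades[i, j] = True
    return InvasionMatrix(invades=invades, neutral=neutral)


def find_interior_fixed_points(
    params: GameParams,
    n_starts: int = 32,
    seed: int = 0,
    interior_tol: float = 1e-6,
) -> list[EquilibriumReport]:
    """All fixed points with every strategy above ``interior_tol``.

    Combines the analytic candidate of the constant-q model (payoff
    equalisation is linear in the frequencies once q is fixed) with seeded
    multi-start root finding on the reduced dynamics, deduplicated.
    """
    candidates: list[np.ndarray] = []
    if params.q_mode == "constant":
        b, c, s, d, q = params.b, params.c, params.s, params.d, float(params.q)
        eff = effective_coop_fraction(q, s)
        # pi_TD = pi_HD fixes x_CC; pi_CC = pi_HD is then linear in x_TD.
        x_cc = d / (b * q * (1.0 - s))
        if 0.0 < x_cc < 1.0:
            denom = c * (eff - s)
            x_td = ((b - c - b * s) * x_cc - c * s * (1.0 - x_cc)) / denom
            candidates.append(np.array([x_cc, x_td, 1.0 - x_cc - x_td]))
    rng = np.random.default_rng(seed)
    starts = rng.dirichlet(np.ones(3), size=n_starts)

    def red(u: np.ndarray) -> np.ndarray:
        return _rhs_raw(np.array([u[0], u[1], 1.0 - u[0] - u[1]]), params)[:2]

    for u0 in starts[:, :2]:
        u, info, ok, _ = fsolve(red, u0, full_output=True)
        if ok == 1 and np.max(np.abs(info["fvec"])) < 1e-12:
            candidates.append(np.array([u[0], u[1], 1.0 - u[0] - u[1]]))
    reports: list[EquilibriumReport] = []
    seen: list[np.ndarray] = []
    for x in candidates:
        if np.min(x) < interior_tol or np.max(x) > 1.0 - interior_tol:
            continue
        if np.max(np.abs(_rhs_raw(x, params))) > 1e-10:
            continue
        if any(np.max(np.abs(x - y)) < 1e-7 for y in seen):
            continue
        seen.append(x)
        reports.append(jacobian_stability(PopulationState.from_array(x), params))
    return reports


def sweep_equilibrium(
    b_values: np.ndarray,
    d_values: np.ndarray,
    s: float,
    c: float,
    cache: dict | None = None,
) -> SweepGrid:
    """Map the stable, HD-resistant mixed equilibrium over a (b, d) grid.

    Cells where the parameter combination violates the constraint set, where
    no interior equilibrium exists, where it is not stable on the simplex, or
    where honest defectors can invade it are NaN; the reason is recorded in
    ``failures`` keyed by (i, j). ``cache`` (keyed by (b, d, s, c)) allows a
    sweep to be resumed or refined without recomputation.
    """
    b_values = np.asarray(b_values, dtype=float)
    d_values = np.asarray(d_values, dtype=float)
    grid = np.full((b_values.size, d_values.size), np.nan)
    failures: dict = {}
    if cache is None:
        cache = {}
    for i, b in enumerate(b_values):
        for j, d in enumerate(d_values):
            key = (float(b), float(d), float(s), float(c))
            if key in cache:
                value, reason = cache[key]
            else:
                value, reason = _sweep_cell(b, d, s, c)
                cache[key] = (value, reason)
            grid[i, j] = value
            if reason is not None:
                failures[(i, j)] = reason
    return SweepGrid(
        b_values=b_values, d_values=d_values, x_cc_star=grid, s=s, c=c,
        failures=failures,
    )


def _sweep_cell(b: float, d: float, s: float, c: float):
    try:
        params = GameParams(b=b, c=c, s=s, d=d, q_mode="freq_dependent")
    except GameParameterError as exc:
        return np.nan, f"invalid_params: {exc}"
    rep = find_mixed_equilibrium(params)
    if rep is None:
        return np.nan, "no_mixed_equilibrium"
    if rep.hd_invadable:
        return np.nan, "hd_invadable"
    if not rep.stable:
        return np.nan, "unstable"
    return rep.state.x_cc, None
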