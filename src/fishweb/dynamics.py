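"""Seasonal bioenergetic consumer-resource dynamics (ATN model).

Biomasses (µgC/L) evolve through 100-day growing seasons.  Autotrophs
grow logistically against a shared carrying capacity K and lose biomass
to grazing; consumers pay a maintenance cost proportional to their
mass-specific metabolic rate x_i, gain through a saturating normalized
functional response, and lose biomass to their own predators:

    autotroph i:  dB_i/dt = r_i (1 - sum_auto B_j / K) B_i
                            - sum_cons x_j y B_j F_ji e_ji
    consumer  i:  dB_i/dt = -f_m x_i B_i
                            + sum_prey f_a x_i y B_i F_ij
                            - sum_cons x_j y B_j F_ji e_ji

with the normalized functional response

    F_ij = w_ij B_j^h / ( B0_ij^h
                          + sum_k c_kj p_ik B_k B0_kj^h
                          + sum_l w_il B_l^h )

where w_ij = 1/P_i is a uniform preference over the P_i prey of i,
h is the Hill exponent, B0 the half-saturation density, c_kj predator
interference and p_ik the fraction of i's resources shared with k.

The assimilation efficiency enters the predation-loss term as a
multiplier by default (the form printed alongside the equations above);
``loss_efficiency_form="divide"`` switches to the conventional ATN form
where consumption is divided by efficiency.

At each season's end, nodes below the extinction threshold are zeroed;
in the life-history-linked model the annual Leslie step then moves fish
biomass between stages (which can revive a zeroed stage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.stats import truncnorm

from .lifehistory import Community, apply_annual_transition, leslie_matrix

__all__ = [
    "DynamicsParams",
    "StateTrajectory",
    "MODEL_TYPES",
    "draw_growth_rates",
    "draw_initial_conditions",
    "initial_biomass",
    "resource_overlap",
    "functional_response",
    "derivatives",
    "make_rhs",
    "integrate_season",
    "run_simulation",
]

MODEL_TYPES = ("original", "unlinked", "linked")


@dataclass
class DynamicsParams:
    """All bioenergetic constants.

    Defaults follow the standard aquatic ATN parameterisation: shared
    autotroph carrying capacity K = 540 µgC/L; intrinsic growth rates
    r ~ N(0.9, 0.2^2) truncated to [0.6, 1.2] d^-1; maximum consumption
    y = 10 d^-1; assimilation efficiency 0.45 on autotroph prey and
    0.85 otherwise; Hill exponent 1.2; growth fraction f_a = 0.4 and
    maintenance fraction f_m = 0.1.  The half-saturation density B0 and
    the interference coefficients c are the least certain constants and
    are fully configurable; defaults are a uniform B0 = 80 µgC/L (order
    of magnitude consistent with K) and c = 0 (no interference).
    """

    K_cap: float = 540.0
    r_mean: float = 0.9
    r_sd: float = 0.2
    r_bounds: tuple[float, float] = (0.6, 1.2)
    y_max: float = 10.0
    e_autotroph: float = 0.45
    e_heterotroph: float = 0.85
    hill: float = 1.2
    f_a: float = 0.4
    f_m: float = 0.1
    B0: float = 80.0
    c_interference: float = 0.0
    extinction_threshold: float = 1e-6
    season_days: float = 100.0
    samples_per_season: int = 100
    loss_efficiency_form: str = "multiply"  # or "divide"
    leslie_stay: float = 0.1
    leslie_advance: float = 0.9
    init_biomass_range: tuple[float, float] = (5.0, 500.0)
    rtol: float = 1e-6
    atol: float = 1e-9
    solver: str = "LSODA"

    def __post_init__(self) -> None:
        if self.B0 <= 0:
            raise ValueError("B0 must be positive")
        if not (0 < self.e_autotroph <= 1 and 0 < self.e_heterotroph <= 1):
            raise ValueError("assimilation efficiencies must be in (0, 1]")
        if self.hill < 1:
            raise ValueError("Hill exponent must be >= 1")
        if min(self.K_cap, self.y_max, self.f_a, self.f_m) < 0:
            raise ValueError("rates must be non-negative")
        if self.loss_efficiency_form not in ("multiply", "divide"):
            raise ValueError("loss_efficiency_form must be 'multiply' or 'divide'")


@dataclass
class StateTrajectory:
    """Per-run record: annual summaries plus optional daily samples."""

    years: int
    node_species: np.ndarray
    node_stage: np.ndarray
    year_end: np.ndarray  # (years, nodes) biomass at each season's end
    annual_mean: np.ndarray  # (years, nodes) season-mean biomass
    events: list[tuple[int, str]] = field(default_factory=list)
    daily: np.ndarray | None = None  # (years*samples, nodes) if recorded
    failed: bool = False
    fail_year: int | None = None


def draw_growth_rates(
    n_autotrophs: int, rng: np.random.Generator, params: DynamicsParams
) -> np.ndarray:
    """Per-autotroph intrinsic growth rates, truncated normal."""
    lo, hi = params.r_bounds
    a = (lo - params.r_mean) / params.r_sd
    b = (hi - params.r_mean) / params.r_sd
    return truncnorm.rvs(
        a, b, loc=params.r_mean, scale=params.r_sd, size=n_autotrophs,
        random_state=rng,
    )


def draw_initial_conditions(
    n_species: int, rng: np.random.Generator, params: DynamicsParams
) -> np.ndarray:
    """One biomass draw per original species, Uniform over the
    configured range (µgC/L)."""
    lo, hi = params.init_biomass_range
    return rng.uniform(lo, hi, size=n_species)


def initial_biomass(community: Community, species_draws: np.ndarray) -> np.ndarray:
    """Map per-species draws onto community nodes.

    Unstaged nodes take their species' draw directly; in staged
    communities a fish species' draw is split equally across its four
    stages so all model types start from matched species totals.
    """
    B = species_draws[community.species].astype(float).copy()
    for sp, idx in community.stage_nodes.items():
        B[idx] = species_draws[sp] / idx.size
    return B


def resource_overlap(A: np.ndarray) -> np.ndarray:
    """p_ik = |prey(i) & prey(k)| / |prey(i)|; zero rows for basal."""
    A = np.asarray(A, dtype=float)
    shared = A @ A.T
    P = A.sum(axis=1)
    p = np.zeros_like(shared)
    cons = P > 0
    p[cons] = shared[cons] / P[cons, None]
    return p


class _RHSContext:
    """Precomputed arrays for the season right-hand side."""

    def __init__(self, community: Community, params: DynamicsParams,
                 r_autotroph: np.ndarray):
        A = community.A.astype(bool)
        N = A.shape[0]
        P = A.sum(axis=1).astype(float)
        omega = np.zeros((N, N))
        cons = P > 0
        omega[cons] = A[cons] / P[cons, None]
        auto = community.is_autotroph
        if r_autotroph.size != int(auto.sum()):
            raise ValueError("one growth rate per autotroph required")

        e = np.where(auto[None, :], params.e_autotroph, params.e_heterotroph)
        loss_eff = e if params.loss_efficiency_form == "multiply" else 1.0 / e
        self.loss_eff_masked = np.where(A, loss_eff, 0.0)

        self.A = A
        self.omega = omega
        self.auto = auto
        self.x = community.x
        self.h = params.hill
        self.y = params.y_max
        self.f_a = params.f_a
        self.f_m = params.f_m
        self.K = params.K_cap
        self.r = r_autotroph
        self.B0h = params.B0 ** params.hill
        if params.c_interference != 0.0:
            p = resource_overlap(A)
            # I_ij = sum_k p_ik * (c * B0^h * A)_kj * B_k
            self.interf_w = params.c_interference * self.B0h * A
            self.p = p
        else:
            self.interf_w = None
            self.p = None

    def rhs(self, t: float, B: np.ndarray) -> np.ndarray:
        Bc = np.maximum(B, 0.0)
        Bh = Bc ** self.h
        s1 = self.omega @ Bh  # summed prey term per consumer
        if self.interf_w is None:
            denom = self.B0h + s1
            F = self.omega * (Bh[None, :] / denom[:, None])
        else:
            interf = self.p @ (self.interf_w * Bc[:, None])
            denom = self.B0h + interf + s1[:, None]
            F = self.omega * Bh[None, :] / denom
        np.nan_to_num(F, copy=False)
        intake = self.f_a * self.x * self.y * Bc * F.sum(axis=1)
        predators = (self.x * self.y * Bc) @ (F * self.loss_eff_masked)
        dB = intake - self.f_m * self.x * Bc - predators
        Ba = Bc[self.auto]
        dB[self.auto] += self.r * (1.0 - Ba.sum() / self.K) * Ba
        return dB


def make_rhs(community: Community, params: DynamicsParams,
             r_autotroph: np.ndarray):
    """Return the dB/dt callable f(t, B) for this community."""
    return _RHSContext(community, params, r_autotroph).rhs


def derivatives(B: np.ndarray, community: Community, params: DynamicsParams,
                r_autotroph: np.ndarray) -> np.ndarray:
    """One right-hand-side evaluation (convenience wrapper)."""
    return make_rhs(community, params, r_autotroph)(0.0, np.asarray(B, float))


def functional_response(B: np.ndarray, i: int, j: int, community: Community,
                        params: DynamicsParams) -> float:
    """F_ij for consumer i on resource j at state B (0 if i does not
    eat j)."""
    ctx = _RHSContext(
        community, params, np.zeros(int(community.is_autotroph.sum()))
    )
    Bc = np.maximum(np.asarray(B, float), 0.0)
    Bh = Bc ** ctx.h
    s1 = ctx.omega @ Bh
    if ctx.interf_w is None:
        denom = ctx.B0h + s1[i]
    else:
        interf = ctx.p @ (ctx.interf_w * Bc[:, None])
        denom = ctx.B0h + interf[i, j] + s1[i]
    return float(ctx.omega[i, j] * Bh[j] / denom)


class IntegrationFailure(RuntimeError):
    """Solver failure or non-finite state inside a season."""


def integrate_season(
    B_start: np.ndarray,
    community: Community,
    params: DynamicsParams,
    r_autotroph: np.ndarray,
    rhs=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate one growing season.

    Returns ``(samples, B_end)`` where ``samples`` has one row per
    output day.  Negative excursions are clamped to zero; nodes below
    the extinction threshold at season end are zeroed.
    """
    if np.any(np.asarray(B_start) < 0):
        raise ValueError("biomass must be non-negative")
    if rhs is None:
        rhs = make_rhs(community, params, r_autotroph)
    t_eval = np.linspace(0.0, params.season_days, params.samples_per_season + 1)
    sol = solve_ivp(
        rhs, (0.0, params.season_days), np.asarray(B_start, dtype=float),
        method=params.solver, t_eval=t_eval, rtol=params.rtol, atol=params.atol,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise IntegrationFailure(f"season integration failed: {sol.message}")
    samples = np.maximum(sol.y.T, 0.0)
    B_end = samples[-1].copy()
    B_end[B_end < params.extinction_threshold] = 0.0
    return samples, B_end


def run_simulation(
    community: Community,
    model_type: str,
    years: int,
    params: DynamicsParams,
    B_init: np.ndarray,
    r_autotroph: np.ndarray,
    record_daily: bool = False,
) -> StateTrajectory:
    """Run `years` seasons; the linked model applies the annual Leslie
    step after each season's extinction thresholding.

    A solver failure flags the trajectory (``failed=True``) rather than
    raising, so ensemble bookkeeping can count it.
    """
    if model_type not in MODEL_TYPES:
        raise ValueError(f"model_type must be one of {MODEL_TYPES}")
    if model_type in ("unlinked", "linked") and not community.staged:
        raise ValueError(f"{model_type} model requires a staged community")
    if model_type == "original" and community.staged:
        raise ValueError("original model requires an unstaged community")

    N = community.size
    L = leslie_matrix(params.leslie_stay, params.leslie_advance)
    rhs = make_rhs(community, params, r_autotroph)
    year_end = np.zeros((years, N))
    annual_mean = np.zeros((years, N))
    daily: list[np.ndarray] = []
    events: list[tuple[int, str]] = []
    traj = StateTrajectory(
        years=years, node_species=community.species, node_stage=community.stage,
        year_end=year_end, annual_mean=annual_mean, events=events,
    )

    alive = np.asarray(B_init, dtype=float) >= params.extinction_threshold
    B = np.where(alive, B_init, 0.0)
    for year in range(years):
        try:
            samples, B = integrate_season(B, community, params, r_autotroph, rhs=rhs)
        except IntegrationFailure as exc:
            events.append((year, f"solver_failure: {exc}"))
            traj.failed = True
            traj.fail_year = year
            break
        newly_dead = alive & (B == 0.0)
        for node in np.flatnonzero(newly_dead):
            events.append((year, f"extinction: node {node}"))
        alive &= B > 0.0
        annual_mean[year] = samples[:-1].mean(axis=0)
        if model_type == "linked":
            B = apply_annual_transition(B, community, L)
            revived = ~alive & (B >= params.extinction_threshold)
            for node in np.flatnonzero(revived):
                events.append((year, f"revival: node {node}"))
            alive |= revived
        year_end[year] = B
        if record_daily:
            daily.append(samples[:-1])
    if record_daily and daily:
        traj.daily = np.vstack(daily)
    return traj
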