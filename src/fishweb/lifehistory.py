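"""Fish life-history staging: von Bertalanffy stage weights, stage
insertion into the web, and the annual Leslie growth/reproduction step.

Each fish species is split into four life-history stages (t = 0..3).
The adult stage (t_max = 3) keeps the species' original relative mass
W_max and its niche triple; the three younger stages get weights from
an isometric von Bertalanffy growth curve

    W(t) = W_inf * (1 - exp(-K * (t - t0)))**3

with curvature K = 3 / t_max and adults at 90% of asymptotic weight
(W_max / W_inf = 0.9).  Those two printed constraints pin the age
offset: t0 = t_max + ln(1 - 0.9**(1/3)) / K.

A stage's weight maps back to a niche value through the web's own
mass -> trophic-position -> niche relation (T = 1 + log_Z M, then a
least-squares linear fit of n on T across the original nodes), after
which the stage receives a feeding range by the niche rule, reusing the
species' range fraction.  Once a year the season dynamics pause and a
biomass-conserving Leslie matrix moves 90% of each stage's biomass to
the next stage (adults spawn 90% into newborns) while 10% remains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .trophic import AUTOTROPH, FISH, TrophicAnnotation, metabolic_rate
from .webgen import NicheWeb, adjacency_from_ranges

__all__ = [
    "StageStructure",
    "Community",
    "EmptyStageDiet",
    "ADULT_FRACTION",
    "vb_stage_weights",
    "stage_niche_value",
    "fit_niche_position_map",
    "insert_stages",
    "community_from_web",
    "leslie_matrix",
    "apply_annual_transition",
]

#: Adults sit at this fraction of asymptotic weight.
ADULT_FRACTION = 0.9
DEFAULT_T_MAX = 3
_NICHE_EPS = 1e-6


class EmptyStageDiet(RuntimeError):
    """An inserted life-history stage ended up with no prey; the web is
    rejected (default policy) so ensembles only contain feedable fish."""


@dataclass
class StageStructure:
    """Von Bertalanffy stage sizing for one fish species."""

    t_max: int
    K_vb: float
    t0: float
    W_inf: float
    W: np.ndarray  # stage weights, t = 0..t_max
    adult_fraction: float = ADULT_FRACTION


def vb_stage_weights(W_max: float, t_max: int = DEFAULT_T_MAX) -> StageStructure:
    """Size the ``t_max + 1`` stages of a species of adult mass W_max.

    K = 3 / t_max and W(t_max) = 0.9 * W_inf fix the curve; t0 follows
    in closed form from exp(-K * (t_max - t0)) = 1 - 0.9**(1/3).
    """
    if t_max <= 0:
        raise ValueError("t_max must be a positive integer")
    if W_max <= 0:
        raise ValueError("W_max must be positive")
    K = 3.0 / t_max
    W_inf = W_max / ADULT_FRACTION
    t0 = t_max + math.log(1.0 - ADULT_FRACTION ** (1.0 / 3.0)) / K
    t = np.arange(t_max + 1, dtype=float)
    W = W_inf * (1.0 - np.exp(-K * (t - t0))) ** 3
    return StageStructure(t_max=t_max, K_vb=K, t0=t0, W_inf=W_inf, W=W)


def fit_niche_position_map(
    n: np.ndarray, T: np.ndarray
) -> tuple[float, float]:
    """Least-squares linear fit of niche value on trophic position
    across the original nodes; returns (intercept, slope)."""
    T = np.asarray(T, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.ptp(T) == 0:
        raise ValueError("degenerate fit: all trophic positions equal")
    slope, intercept = np.polyfit(T, n, 1)
    return float(intercept), float(slope)


def stage_niche_value(
    M_stage: float, intercept: float, slope: float, Z: float
) -> float:
    """Approximate a stage's niche value from its weight.

    The stage's implied trophic position is T = 1 + log_Z(M); the web's
    fitted n-on-T line converts that to a niche value, clamped to (0, 1).
    """
    T_stage = 1.0 + math.log(M_stage) / math.log(Z)
    n_stage = intercept + slope * T_stage
    return float(np.clip(n_stage, _NICHE_EPS, 1.0 - _NICHE_EPS))


@dataclass
class Community:
    """A web ready for bioenergetic dynamics, staged or not.

    Every node carries a niche triple, guild, relative mass and
    mass-specific metabolic rate.  In a staged community each fish
    species contributes four nodes (stages 0..3, adults = stage 3);
    ``stage[i] = -1`` marks unstaged nodes.
    """

    n: np.ndarray
    r: np.ndarray
    c: np.ndarray
    A: np.ndarray
    guild: np.ndarray
    M: np.ndarray
    x: np.ndarray
    species: np.ndarray  # original species id per node
    stage: np.ndarray  # stage index, -1 for unstaged nodes
    fish_species: list[int]
    stage_nodes: dict[int, np.ndarray] = field(default_factory=dict)
    stage_structures: dict[int, StageStructure] = field(default_factory=dict)
    staged: bool = False

    @property
    def size(self) -> int:
        return self.n.size

    @property
    def is_autotroph(self) -> np.ndarray:
        return self.guild == AUTOTROPH

    @property
    def fish_nodes_of(self) -> dict[int, np.ndarray]:
        """Node indices belonging to each fish species."""
        if self.staged:
            return self.stage_nodes
        return {sp: np.array([sp]) for sp in self.fish_species}


def community_from_web(web: NicheWeb, ann: TrophicAnnotation) -> Community:
    """Wrap an unstaged web (the 'original' ATN model) as a Community."""
    fish = [int(i) for i in np.flatnonzero(ann.guild == FISH)]
    S = web.S
    return Community(
        n=web.n.copy(), r=web.r.copy(), c=web.c.copy(), A=web.A.copy(),
        guild=ann.guild.copy(), M=ann.M.copy(), x=ann.x.copy(),
        species=np.arange(S), stage=np.full(S, -1), fish_species=fish,
        staged=False,
    )


def insert_stages(
    web: NicheWeb,
    ann: TrophicAnnotation,
    seed: int,
    t_max: int = DEFAULT_T_MAX,
    allow_conspecific_predation: bool = True,
    reject_empty_diet: bool = True,
) -> Community:
    """Split every fish species into ``t_max + 1`` life-history stages.

    The adult stage keeps the species' node (niche triple and diet over
    the original nodes unchanged).  Younger stages are appended as new
    nodes: stage mass from the von Bertalanffy curve, niche value from
    the fitted mass->T->n map, range width from the species' own range
    fraction ``x = r / n``, range center drawn Uniform(r/2, n) from a
    species-deterministic sub-seed.  Adjacency is then rebuilt from all
    niche triples, so stages both eat and are eaten by range membership.

    Deterministic given (web, seed): repeated calls are bit-identical.
    """
    fish = [int(i) for i in np.flatnonzero(ann.guild == FISH)]
    if not fish:
        raise ValueError("web has no fish species to stage")
    intercept, slope = fit_niche_position_map(web.n, ann.T)

    n = list(web.n)
    r = list(web.r)
    c = list(web.c)
    guild = list(ann.guild)
    M = list(ann.M)
    species = list(range(web.S))
    stage = [-1] * web.S

    stage_nodes: dict[int, np.ndarray] = {}
    stage_structures: dict[int, StageStructure] = {}
    for sp in fish:
        struct = vb_stage_weights(float(ann.M[sp]), t_max=t_max)
        stage_structures[sp] = struct
        x_frac = float(web.r[sp] / web.n[sp])
        rng_sp = np.random.default_rng([int(seed) % 2**31, int(sp)])
        idx = []
        for t in range(t_max):  # younger stages are new nodes
            m_st = float(struct.W[t])
            n_st = stage_niche_value(m_st, intercept, slope, ann.Z)
            r_st = x_frac * n_st
            c_st = float(rng_sp.uniform(r_st / 2.0, n_st))
            idx.append(len(n))
            n.append(n_st)
            r.append(r_st)
            c.append(c_st)
            guild.append(FISH)
            M.append(m_st)
            species.append(sp)
            stage.append(t)
        idx.append(sp)  # adult stage = the original node
        stage[sp] = t_max
        M[sp] = float(struct.W[t_max])
        stage_nodes[sp] = np.array(idx)

    n_arr = np.array(n)
    r_arr = np.array(r)
    c_arr = np.array(c)
    guild_arr = np.array(guild, dtype=object)
    M_arr = np.array(M)
    species_arr = np.array(species)
    stage_arr = np.array(stage)

    A = adjacency_from_ranges(n_arr, r_arr, c_arr)
    if not allow_conspecific_predation:
        for sp in fish:
            idx = stage_nodes[sp]
            A[np.ix_(idx, idx)] = False

    x_arr = metabolic_rate(M_arr, guild_arr)

    if reject_empty_diet:
        off = A.copy()
        np.fill_diagonal(off, False)
        for sp in fish:
            for node in stage_nodes[sp]:
                if not off[node].any():
                    raise EmptyStageDiet(
                        f"stage {stage_arr[node]} of fish species {sp} has no prey"
                    )

    return Community(
        n=n_arr, r=r_arr, c=c_arr, A=A, guild=guild_arr, M=M_arr, x=x_arr,
        species=species_arr, stage=stage_arr, fish_species=fish,
        stage_nodes=stage_nodes, stage_structures=stage_structures, staged=True,
    )


def leslie_matrix(stay: float = 0.1, advance: float = 0.9,
                  n_stages: int = DEFAULT_T_MAX + 1) -> np.ndarray:
    """Annual stage-transition matrix (columns = source stage).

    Each stage keeps ``stay`` of its biomass and passes ``advance`` to
    the next stage; the terminal stage passes ``advance`` to stage 0 as
    newborns.  Columns sum to one, so the step conserves biomass.
    """
    if not (0.0 <= stay <= 1.0 and 0.0 <= advance <= 1.0):
        raise ValueError("stay and advance must be in [0, 1]")
    if abs(stay + advance - 1.0) > 1e-12:
        raise ValueError("stay + advance must equal 1")
    L = np.zeros((n_stages, n_stages))
    np.fill_diagonal(L, stay)
    for t in range(n_stages - 1):
        L[t + 1, t] = advance
    L[0, n_stages - 1] = advance
    return L


def apply_annual_transition(
    B: np.ndarray, community: Community, L: np.ndarray
) -> np.ndarray:
    """Apply the Leslie step to every fish species; other nodes are
    untouched.  Returns a new biomass vector."""
    if np.any(B < 0):
        raise ValueError("biomass must be non-negative")
    out = B.copy()
    for sp, idx in community.stage_nodes.items():
        out[idx] = L @ B[idx]
    return out
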