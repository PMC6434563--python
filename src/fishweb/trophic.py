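"""Trophic positions, guild assignment and allometric rates.

Each node gets three trophic-position metrics: the shortest chain to a
basal species plus one (T1), the prey-averaged position (T2, one plus
the mean position of its prey, solved exactly as a linear system so
feeding loops and cannibalism are handled), and their average, the
short-weighted position T.  Relative body mass follows from T through
the consumer-resource allometric ratio Z as ``M = Z**(T - 1)`` (basal
species have mass 1), and mass-specific metabolic rates follow
Kleiber-style scaling per guild:

    x = 0                    autotrophs
    x = 0.314 * M**-0.15     invertebrates
    x = 0.88  * M**-0.11     fish

Guilds: basal nodes are autotrophs; the three non-basal nodes with the
highest T are fish (the most apex predators); everything else is an
invertebrate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .webgen import NicheWeb

__all__ = [
    "AUTOTROPH",
    "INVERTEBRATE",
    "FISH",
    "TrophicAnnotation",
    "SingularTrophicSystem",
    "shortest_trophic_level",
    "prey_averaged_position",
    "short_weighted_position",
    "assign_guilds",
    "body_mass",
    "metabolic_rate",
    "annotate",
    "annotation_to_tsv",
]

AUTOTROPH = "autotroph"
INVERTEBRATE = "invertebrate"
FISH = "fish"

DEFAULT_Z = 100.0
N_FISH_SPECIES = 3


class SingularTrophicSystem(RuntimeError):
    """The prey-averaged linear system has no unique solution; the web
    is rejected rather than patched."""


@dataclass
class TrophicAnnotation:
    """Per-node trophic and allometric annotation of a web."""

    T1: np.ndarray
    T2: np.ndarray
    T: np.ndarray
    guild: np.ndarray  # dtype=object, values in {autotroph, invertebrate, fish}
    M: np.ndarray
    x: np.ndarray
    Z: float

    @property
    def is_fish(self) -> np.ndarray:
        return self.guild == FISH

    @property
    def is_basal(self) -> np.ndarray:
        return self.guild == AUTOTROPH


def _basal_mask(A: np.ndarray) -> np.ndarray:
    # no prey at all: a cannibal eating only itself is not an autotroph
    return ~np.asarray(A, dtype=bool).any(axis=1)


def shortest_trophic_level(A: np.ndarray) -> np.ndarray:
    """T1: 1 for basal nodes, else 1 + min over prey, by breadth-first
    relaxation from the basal set.  Self-links are ignored (a self-loop
    can never shorten a path)."""
    A = np.asarray(A, dtype=bool)
    basal = _basal_mask(A)
    A = A.copy()
    np.fill_diagonal(A, False)
    S = A.shape[0]
    T1 = np.full(S, np.inf)
    T1[basal] = 1.0
    frontier = list(np.flatnonzero(basal))
    while frontier:
        nxt = []
        for j in frontier:
            for i in np.flatnonzero(A[:, j]):
                if T1[i] == np.inf:
                    T1[i] = T1[j] + 1.0
                    nxt.append(i)
        frontier = nxt
    if np.isinf(T1).any():
        bad = np.flatnonzero(np.isinf(T1)).tolist()
        raise ValueError(f"nodes {bad} have no path to a basal species")
    return T1


def prey_averaged_position(A: np.ndarray) -> np.ndarray:
    """T2: solve T2_i = 1 + mean over prey of T2_j with basal T2 = 1.

    Cannibalistic self-links are kept in the average (they are links).
    The linear solve handles loops exactly.
    """
    A = np.asarray(A, dtype=bool)
    S = A.shape[0]
    basal = _basal_mask(A)
    P = A.sum(axis=1).astype(float)
    # (I - D^-1 A) T2 = 1 for consumers; T2 = 1 for basal nodes.
    M = np.eye(S)
    rhs = np.ones(S)
    cons = ~basal
    M[cons] -= A[cons] / P[cons, None]
    try:
        with np.errstate(all="raise"):
            T2 = np.linalg.solve(M, rhs)
    except (np.linalg.LinAlgError, FloatingPointError) as exc:
        raise SingularTrophicSystem(f"prey-averaged system is singular: {exc}")
    if not np.all(np.isfinite(T2)):
        raise SingularTrophicSystem("prey-averaged solution not finite")
    return T2


def short_weighted_position(T1: np.ndarray, T2: np.ndarray) -> np.ndarray:
    T1 = np.asarray(T1, dtype=float)
    T2 = np.asarray(T2, dtype=float)
    if T1.shape != T2.shape:
        raise ValueError("T1 and T2 must have the same length")
    return (T1 + T2) / 2.0


def assign_guilds(
    A: np.ndarray,
    T: np.ndarray,
    n: np.ndarray | None = None,
    n_fish: int = N_FISH_SPECIES,
) -> np.ndarray:
    """Autotrophs are prey-less nodes; the ``n_fish`` non-basal nodes of
    highest T are fish; the rest are invertebrates.

    Ties at the fish cutoff break by higher niche value ``n``, then
    lower node id, so assignment is deterministic and seed-independent.
    """
    A = np.asarray(A, dtype=bool)
    S = A.shape[0]
    basal = _basal_mask(A)
    consumers = np.flatnonzero(~basal)
    if consumers.size < n_fish:
        raise ValueError(
            f"need at least {n_fish} non-basal nodes, have {consumers.size}"
        )
    nv = np.zeros(S) if n is None else np.asarray(n, dtype=float)
    order = sorted(consumers, key=lambda i: (-T[i], -nv[i], i))
    guild = np.full(S, INVERTEBRATE, dtype=object)
    guild[basal] = AUTOTROPH
    guild[order[:n_fish]] = FISH
    return guild


def body_mass(T: np.ndarray, Z: float = DEFAULT_Z) -> np.ndarray:
    """Relative body mass ``M = Z**(T - 1)``; basal species (T = 1)
    anchor the scale at M = 1."""
    if Z <= 0:
        raise ValueError("Z must be positive")
    return np.power(Z, np.asarray(T, dtype=float) - 1.0)


def metabolic_rate(M: np.ndarray, guild: np.ndarray) -> np.ndarray:
    """Mass-specific metabolic rate per guild (per day per unit mass)."""
    M = np.atleast_1d(np.asarray(M, dtype=float))
    guild = np.atleast_1d(np.asarray(guild, dtype=object))
    x = np.zeros_like(M)
    inv = guild == INVERTEBRATE
    fish = guild == FISH
    if np.any((inv | fish) & (M <= 0)):
        raise ValueError("consumer nodes require positive body mass")
    x[inv] = 0.314 * M[inv] ** -0.15
    x[fish] = 0.88 * M[fish] ** -0.11
    return x


def annotate(web: NicheWeb, Z: float = DEFAULT_Z) -> TrophicAnnotation:
    """Full annotation pipeline for a validated web."""
    T1 = shortest_trophic_level(web.A)
    T2 = prey_averaged_position(web.A)
    T = short_weighted_position(T1, T2)
    guild = assign_guilds(web.A, T, web.n)
    M = body_mass(T, Z)
    M[guild == AUTOTROPH] = 1.0
    x = metabolic_rate(M, guild)
    return TrophicAnnotation(T1=T1, T2=T2, T=T, guild=guild, M=M, x=x, Z=Z)


def annotation_to_tsv(web: NicheWeb, ann: TrophicAnnotation) -> str:
    header = "id\tn\tguild\tT1\tT2\tT\tM\tx"
    rows = [
        f"{i}\t{web.n[i]:.6g}\t{ann.guild[i]}\t{ann.T1[i]:.6g}\t{ann.T2[i]:.6g}"
        f"\t{ann.T[i]:.6g}\t{ann.M[i]:.6g}\t{ann.x[i]:.6g}"
        for i in range(web.S)
    ]
    return "\n".join([header, *rows]) + "\n"
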