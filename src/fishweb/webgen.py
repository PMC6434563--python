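"""Niche-model food-web generation and structural validation.

The niche model places every species on a one-dimensional niche axis
(niche value ``n_i ~ Uniform(0, 1)``, read as relative body size) and
gives each a contiguous diet interval.  The interval width is
``r_i = x_i * n_i`` with ``x_i ~ Beta(1, beta)`` where
``beta = (1 - 2C) / (2C)`` is chosen so the expected connectance of the
web equals the target ``C``; the interval center is drawn
``c_i ~ Uniform(r_i / 2, n_i)``.  A species eats every species whose
niche value falls inside its interval — nothing else.

Raw draws are rejection-sampled against four realism rules: no isolated
species, every species is supported by a basal (autotroph) food chain,
the web is a single connected component, and the realized connectance
``L / S**2`` is within a configured relative tolerance of the target.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "NicheWeb",
    "ValidationReport",
    "WebGenerationError",
    "draw_niche_web",
    "validate_web",
    "generate_valid_web",
    "realized_connectance",
    "adjacency_from_ranges",
    "web_to_json",
    "web_from_json",
    "web_to_edgelist",
]

#: Default relative tolerance on |L/S^2 - C| / C for rule (d).
DEFAULT_CONNECTANCE_TOL = 0.05


class WebGenerationError(RuntimeError):
    """Raised when rejection sampling cannot produce a valid web."""


@dataclass
class NicheWeb:
    """A structural niche-model food web.

    Attributes
    ----------
    S : int
        Species count.
    C_target : float
        Target connectance in (0, 0.5).
    n, r, c : ndarray of shape (S,)
        Niche value, diet-range width and diet-range center per node.
    A : ndarray of shape (S, S), dtype bool
        Adjacency; ``A[i, j]`` is True iff consumer ``i`` eats resource
        ``j``.  Self-links (cannibalism) are permitted.
    seed : int or None
        Record of the seed used for the accepted draw (bookkeeping only).
    attempts : int
        Number of raw draws consumed before this web was accepted.
    """

    S: int
    C_target: float
    n: np.ndarray
    r: np.ndarray
    c: np.ndarray
    A: np.ndarray
    seed: int | None = None
    attempts: int = 1

    @property
    def n_links(self) -> int:
        return int(self.A.sum())

    def prey_of(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.A[i])

    def consumers_of(self, j: int) -> np.ndarray:
        return np.flatnonzero(self.A[:, j])

    @property
    def basal(self) -> np.ndarray:
        """Boolean mask of basal nodes (no prey at all; a cannibal is
        not an autotroph)."""
        return ~self.A.any(axis=1)


@dataclass
class ValidationReport:
    """Outcome of the four structural realism rules."""

    no_isolated_nodes: bool
    basal_reachable: bool
    connected: bool
    connectance_ok: bool
    realized_connectance: float
    failing: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return (
            self.no_isolated_nodes
            and self.basal_reachable
            and self.connected
            and self.connectance_ok
        )


def _beta_shape(C: float) -> float:
    return (1.0 - 2.0 * C) / (2.0 * C)


def adjacency_from_ranges(n: np.ndarray, r: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Build adjacency purely from niche triples: i eats j iff n_j is in
    [c_i - r_i/2, c_i + r_i/2]."""
    lo = (c - r / 2.0)[:, None]
    hi = (c + r / 2.0)[:, None]
    return (n[None, :] >= lo) & (n[None, :] <= hi)


def draw_niche_web(S: int, C: float, rng: np.random.Generator) -> NicheWeb:
    """Draw one raw (unvalidated) niche-model web.

    Parameters
    ----------
    S : int
        Species richness, at least 2.
    C : float
        Target connectance, in (0, 0.5) so the Beta shape
        ``beta = (1 - 2C) / (2C)`` is positive.
    rng : numpy.random.Generator
        Source of randomness.
    """
    if not (isinstance(S, (int, np.integer)) and S >= 2):
        raise ValueError(f"S must be an integer >= 2, got {S!r}")
    if not (0.0 < C < 0.5):
        raise ValueError(f"C must be in (0, 0.5), got {C!r}")
    beta = _beta_shape(C)
    n = rng.uniform(0.0, 1.0, size=S)
    x = rng.beta(1.0, beta, size=S)
    r = x * n
    c = rng.uniform(r / 2.0, n)
    A = adjacency_from_ranges(n, r, c)
    return NicheWeb(S=S, C_target=C, n=n, r=r, c=c, A=A)


def realized_connectance(web: NicheWeb) -> float:
    """Directed links over S**2 ordered pairs, self-links included."""
    return web.n_links / web.S**2


def _basal_reachable_mask(A: np.ndarray) -> np.ndarray:
    """For each node, can a basal (autotroph) node be reached by
    following prey links?

    A basal node has no prey at all — a species eating only itself is
    not an autotroph.  The search itself ignores self-loops, which
    never bring a path closer to a basal node.
    """
    basal = ~np.asarray(A, dtype=bool).any(axis=1)
    A = A.copy()
    np.fill_diagonal(A, False)
    reach = basal.copy()
    # BFS relaxation upward from basal nodes along consumer links.
    queue = deque(np.flatnonzero(basal))
    while queue:
        j = queue.popleft()
        for i in np.flatnonzero(A[:, j]):
            if not reach[i]:
                reach[i] = True
                queue.append(i)
    return reach


def validate_web(
    web: NicheWeb, tol: float = DEFAULT_CONNECTANCE_TOL
) -> ValidationReport:
    """Check the four structural realism rules.

    (a) no isolated node (every node has at least one in- or out-link,
    self-links ignored); (b) every node can reach a basal node through
    prey links; (c) the web is one connected component as an undirected
    graph; (d) realized connectance within relative ``tol`` of target.
    """
    A = web.A.copy()
    np.fill_diagonal(A, False)

    degree = A.any(axis=0) | A.any(axis=1)
    rule_a = bool(degree.all())

    rule_b = bool(_basal_reachable_mask(web.A).all())

    G = nx.from_numpy_array(A | A.T)
    rule_c = nx.is_connected(G) if web.S > 0 else False

    Lc = realized_connectance(web)
    if web.C_target > 0:
        rule_d = abs(Lc - web.C_target) / web.C_target <= tol
    else:
        rule_d = Lc == 0.0

    failing = [
        name
        for ok, name in [
            (rule_a, "no_isolated_nodes"),
            (rule_b, "basal_reachable"),
            (rule_c, "connected"),
            (rule_d, "connectance_ok"),
        ]
        if not ok
    ]
    return ValidationReport(rule_a, rule_b, rule_c, rule_d, Lc, failing)


def generate_valid_web(
    S: int,
    C: float,
    rng: np.random.Generator,
    max_attempts: int = 10_000,
    tol: float = DEFAULT_CONNECTANCE_TOL,
) -> NicheWeb:
    """Rejection-sample raw webs until one passes :func:`validate_web`.

    Raises
    ------
    WebGenerationError
        After ``max_attempts`` rejections, naming the most common
        failing rule.
    """
    if max_attempts < 1:
        raise ValueError("max_attempts must be >= 1")
    fail_counts: dict[str, int] = {}
    for attempt in range(1, max_attempts + 1):
        web = draw_niche_web(S, C, rng)
        report = validate_web(web, tol=tol)
        if report.passed:
            web.attempts = attempt
            return web
        for name in report.failing:
            fail_counts[name] = fail_counts.get(name, 0) + 1
    worst = max(fail_counts, key=fail_counts.get)
    raise WebGenerationError(
        f"no valid web in {max_attempts} attempts at S={S}, C={C}; "
        f"most common failing rule: {worst} ({fail_counts[worst]} times)"
    )


# ---------------------------------------------------------------------------
# serialization

def web_to_json(web: NicheWeb) -> str:
    links = [[int(i), int(j)] for i, j in zip(*np.nonzero(web.A))]
    record = {
        "S": web.S,
        "C_target": web.C_target,
        "seed": web.seed,
        "nodes": [
            {"id": i, "n": float(web.n[i]), "r": float(web.r[i]), "c": float(web.c[i])}
            for i in range(web.S)
        ],
        "links": links,
    }
    return json.dumps(record, indent=1)


def web_from_json(text: str) -> NicheWeb:
    record = json.loads(text)
    S = record["S"]
    n = np.zeros(S)
    r = np.zeros(S)
    c = np.zeros(S)
    for node in record["nodes"]:
        i = node["id"]
        n[i], r[i], c[i] = node["n"], node["r"], node["c"]
    A = np.zeros((S, S), dtype=bool)
    for i, j in record["links"]:
        A[i, j] = True
    return NicheWeb(S=S, C_target=record["C_target"], n=n, r=r, c=c, A=A,
                    seed=record.get("seed"))


def web_to_edgelist(web: NicheWeb) -> str:
    """Edge list TSV, consumer<TAB>resource, 0-based ids."""
    lines = [f"{i}\t{j}" for i, j in zip(*np.nonzero(web.A))]
    return "\n".join(lines) + ("\n" if lines else "")
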