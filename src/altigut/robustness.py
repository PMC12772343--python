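"""Attack-tolerance robustness and stratum-wise group comparisons.

Robustness of a co-occurrence network is the proportion of nodes
remaining after removing a fraction (default 50%) of nodes uniformly at
random, followed by secondary extinction: any surviving node left with
zero edges is also removed.  Because deleting an isolated node removes
no edges, the extinction cascade resolves in a single pass over the
induced subgraph.

Stratum comparisons use Welch's heteroscedastic ANOVA followed by
Games-Howell post hoc tests (studentized-range reference distribution).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats


def _adjacency(network: nx.Graph) -> tuple[list, np.ndarray]:
    nodes = list(network.nodes)
    A = nx.to_numpy_array(network, nodelist=nodes, weight=None).astype(bool)
    return nodes, A


def _surviving_fraction(A: np.ndarray, removed_idx: np.ndarray) -> float:
    N = A.shape[0]
    surv = np.ones(N, dtype=bool)
    surv[removed_idx] = False
    sub = A[np.ix_(surv, surv)]
    # one pass suffices: removing a degree-0 node frees no edges
    connected = sub.sum(axis=1) > 0
    return float(connected.sum()) / N


def robustness_once(network: nx.Graph, fraction: float = 0.5, rng=None, removal=None) -> float:
    """One robustness replicate: remove floor(fraction*N) random nodes,
    apply secondary extinction, return remaining proportion.

    ``removal`` may name an explicit node set to remove (used for
    exhaustive enumeration); otherwise nodes are drawn with ``rng``.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    nodes, A = _adjacency(network)
    N = len(nodes)
    if N < 2:
        raise ValueError("network must have at least 2 nodes")
    if removal is not None:
        pos = {node: i for i, node in enumerate(nodes)}
        removed = np.asarray([pos[n] for n in removal], dtype=int)
    else:
        rng = np.random.default_rng(rng)
        removed = rng.choice(N, size=int(np.floor(fraction * N)), replace=False)
    return _surviving_fraction(A, removed)


@dataclass
class RobustnessResult:
    stratum: str | None
    removal_fraction: float
    n_iterations: int
    values: np.ndarray = field(repr=False)
    mean: float = 0.0
    sd: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stratum": self.stratum,
                "iteration": np.arange(1, self.n_iterations + 1),
                "robustness": self.values,
            }
        )


def robustness_distribution(
    network: nx.Graph, fraction: float = 0.5, n_iter: int = 100, seed=None
) -> RobustnessResult:
    """``n_iter`` independent robustness replicates from a seeded stream."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    nodes, A = _adjacency(network)
    N = len(nodes)
    if N < 2:
        raise ValueError("network must have at least 2 nodes")
    rng = np.random.default_rng(seed)
    n_remove = int(np.floor(fraction * N))
    values = np.empty(n_iter)
    for i in range(n_iter):
        removed = rng.choice(N, size=n_remove, replace=False)
        values[i] = _surviving_fraction(A, removed)
    return RobustnessResult(
        stratum=network.graph.get("stratum"),
        removal_fraction=fraction,
        n_iterations=n_iter,
        values=values,
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if n_iter > 1 else 0.0,
    )


def _validate_groups(groups) -> dict[str, np.ndarray]:
    if isinstance(groups, dict):
        items = groups.items()
    else:
        items = ((f"group{i + 1}", g) for i, g in enumerate(groups))
    out = {}
    for name, g in items:
        arr = np.asarray(g, dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
        if arr.var(ddof=1) == 0:
            raise ValueError(f"group {name!r} has zero variance")
        out[str(name)] = arr
    if len(out) < 2:
        raise ValueError("need at least 2 groups")
    return out


@dataclass
class WelchAnovaResult:
    F: float
    df1: float
    df2: float
    p: float

    def to_dict(self) -> dict:
        return asdict(self)


def welch_anova(groups) -> WelchAnovaResult:
    """Welch's heteroscedastic one-way ANOVA.

    Uses weights w_i = n_i / s_i^2 and the Welch-Satterthwaite
    denominator degrees of freedom.
    """
    gs = _validate_groups(groups)
    k = len(gs)
    n = np.array([g.size for g in gs.values()], dtype=float)
    m = np.array([g.mean() for g in gs.values()])
    s2 = np.array([g.var(ddof=1) for g in gs.values()])
    w = n / s2
    W = w.sum()
    mw = (w * m).sum() / W
    A = (w * (m - mw) ** 2).sum() / (k - 1)
    lam = 3.0 * ((1 - w / W) ** 2 / (n - 1)).sum() / (k**2 - 1)
    F = A / (1 + 2 * lam * (k - 2) / 3.0)
    df1 = float(k - 1)
    df2 = 1.0 / lam
    p = float(stats.f.sf(F, df1, df2))
    return WelchAnovaResult(F=float(F), df1=df1, df2=df2, p=p)


def games_howell(groups, alpha: float = 0.05) -> pd.DataFrame:
    """Games-Howell post hoc tests for all group pairs.

    Per pair: Welch t statistic, Welch-Satterthwaite df, and p from the
    studentized-range distribution with k groups at q = |t| * sqrt(2).
    No further multiplicity correction is applied (the range
    distribution embeds family-wise control).
    """
    gs = _validate_groups(groups)
    k = len(gs)
    rows = []
    for (na, a), (nb, b) in itertools.combinations(gs.items(), 2):
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        diff = a.mean() - b.mean()
        se = np.sqrt(va + vb)
        t = diff / se
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        p = float(np.clip(stats.studentized_range.sf(np.abs(t) * np.sqrt(2.0), k, df), 0.0, 1.0))
        rows.append(
            {
                "group_a": na,
                "group_b": nb,
                "mean_diff": float(diff),
                "t": float(t),
                "df": float(df),
                "p_adj_gh": p,
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class GroupTestResult:
    omnibus: WelchAnovaResult
    pairwise: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "omnibus_F": self.omnibus.F,
            "df1": self.omnibus.df1,
            "df2": self.omnibus.df2,
            "p_omnibus": self.omnibus.p,
            "pairwise": self.pairwise.to_dict(orient="records"),
        }


def compare_groups(groups, alpha: float = 0.05) -> GroupTestResult:
    """Omnibus Welch ANOVA plus Games-Howell pairwise comparisons."""
    return GroupTestResult(
        omnibus=welch_anova(groups),
        pairwise=games_howell(groups, alpha=alpha),
    )
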