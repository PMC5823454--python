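"""Comorbidity-network construction and network statistics.

Nodes are chronic conditions observed at least once in a stratum; an edge
joins two conditions whose pairwise association — the phi coefficient, i.e.
the Pearson correlation of the two binary indicators — is significant at
``alpha`` (default 0.01, the conventional threshold under multiple
correlation testing).  Edges are signed: negative associations are kept and
carry ``polarity="negative"``; a flag restricts to positive-only edges.

Statistics follow the comorbidome conventions: density ``2E/(N(N-1))``,
degree median and interquartile range, the degree histogram, and hubs
defined as nodes at or above the upper quartile of the degree distribution
(nearest-rank convention, ties included).  Percentile bootstrap confidence
intervals resample *persons* with replacement and rebuild the network per
replicate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import DiseaseCatalog, PersonRecord
from .errors import DomainError

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.01
DEFAULT_BOOTSTRAP_REPLICATES = 1000


@dataclass(frozen=True)
class EdgeRecord:
    disease_a: str
    disease_b: str
    weight: float  # phi coefficient in [-1, 1]
    p_value: float

    @property
    def polarity(self) -> str:
        return "positive" if self.weight > 0 else "negative"


@dataclass
class ComorbidityNetwork:
    nodes: list[str]  # diseases with >= 1 case in the stratum
    edges: list[EdgeRecord]
    stratum_label: str
    n_persons: int
    node_prevalence: dict[str, float] = field(default_factory=dict)
    n_skipped_pairs: int = 0  # zero-variance pairs with undefined phi

    def degree_by_node(self) -> dict[str, int]:
        deg = {n: 0 for n in self.nodes}
        for e in self.edges:
            deg[e.disease_a] += 1
            deg[e.disease_b] += 1
        return deg

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(stratum=self.stratum_label, n_persons=self.n_persons)
        deg = self.degree_by_node()
        stats = network_stats(self) if len(self.nodes) >= 2 else None
        hub_ids = {h[0] for h in stats.hubs} if stats else set()
        for n in self.nodes:
            g.add_node(
                n,
                prevalence=float(self.node_prevalence.get(n, float("nan"))),
                degree=deg[n],
                hub=n in hub_ids,
            )
        for e in self.edges:
            g.add_edge(
                e.disease_a, e.disease_b,
                weight=float(e.weight), p=float(e.p_value), polarity=e.polarity,
            )
        return g

    def write_gexf(self, path: str | Path) -> None:
        nx.write_gexf(self.to_networkx(), path)

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def edge_list_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "disease_a": [e.disease_a for e in self.edges],
                "disease_b": [e.disease_b for e in self.edges],
                "weight": [e.weight for e in self.edges],
                "p_value": [e.p_value for e in self.edges],
                "polarity": [e.polarity for e in self.edges],
            }
        )


def phi_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Phi coefficient of two binary vectors with its chi-square p-value.

    ``phi = (ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d))`` from the 2x2 table; the
    p-value is ``P(chi2_1 >= n * phi^2)``.  Raises :class:`DomainError` when
    either vector is constant (the correlation is undefined).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise DomainError("vectors must have equal length")
    n = x.size
    if n < 2:
        raise DomainError("need at least 2 observations")
    n1x, n1y = int(x.sum()), int(y.sum())
    if n1x in (0, n) or n1y in (0, n):
        raise DomainError("zero-variance vector: phi undefined")
    a = int(np.dot(x.astype(np.int64), y.astype(np.int64)))
    num = n * a - n1x * n1y
    den = math.sqrt(n1x * (n - n1x)) * math.sqrt(n1y * (n - n1y))
    phi = num / den
    p = float(sps.chi2.sf(n * phi * phi, df=1))
    return float(phi), p


def _phi_matrix(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs phi and p-values for a binary matrix (persons x diseases).

    Returns ``(phi, pvals, defined)`` square arrays; ``defined`` is False for
    pairs involving a constant column (phi undefined there).
    """
    n, d = x.shape
    xf = x.astype(np.float64)
    n1 = xf.sum(axis=0)
    co = xf.T @ xf  # pairwise co-occurrence counts
    num = n * co - np.outer(n1, n1)
    var = n1 * (n - n1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = num / np.sqrt(np.outer(var, var))
        pvals = sps.chi2.sf(n * phi * phi, df=1)
    defined = (var > 0)[:, None] & (var > 0)[None, :]
    return phi, pvals, defined


def build_network(
    cohort: Sequence[PersonRecord] | np.ndarray,
    catalog: DiseaseCatalog,
    alpha: float = DEFAULT_ALPHA,
    *,
    stratum_label: str = "all",
    positive_only: bool = False,
    bh_correction: bool = False,
    method: str = "chi2",
) -> ComorbidityNetwork:
    """Build the significance-thresholded comorbidity network of a stratum.

    ``cohort`` may be a list of :class:`PersonRecord` or a prebuilt binary
    matrix (persons x catalog diseases).  ``method="fisher"`` replaces the
    chi-square p-value with a two-sided Fisher exact p (for small strata);
    ``bh_correction`` applies Benjamini-Hochberg across defined pairs before
    thresholding at ``alpha``.
    """
    if isinstance(cohort, np.ndarray):
        x = cohort
    else:
        if len(cohort) == 0:
            raise DomainError("cannot build a network from an empty cohort")
        x = np.vstack([r.diseases for r in cohort])
    if x.shape[0] == 0:
        raise DomainError("cannot build a network from an empty cohort")
    n, d = x.shape
    ids = catalog.condition_ids
    n1 = x.sum(axis=0)
    nodes = [ids[j] for j in range(d) if n1[j] >= 1]
    prevalence = {ids[j]: float(n1[j]) / n for j in range(d) if n1[j] >= 1}

    phi, pvals, defined = _phi_matrix(x)
    if method == "fisher":
        from .stats import fisher_exact_2x2

        xf = x.astype(np.int64)
        co = xf.T @ xf
        for i in range(d):
            for j in range(i + 1, d):
                if defined[i, j]:
                    a = int(co[i, j])
                    b = int(n1[i] - a)
                    c = int(n1[j] - a)
                    pvals[i, j] = pvals[j, i] = fisher_exact_2x2(a, b, c, n - a - b - c)
    elif method != "chi2":
        raise ValueError(f"unknown edge test method {method!r}")

    iu, ju = np.triu_indices(d, k=1)
    pair_defined = defined[iu, ju]
    pair_p = pvals[iu, ju]
    if bh_correction:
        from statsmodels.stats.multitest import multipletests

        mask = pair_defined
        adj = np.full(pair_p.shape, np.nan)
        if mask.any():
            adj[mask] = multipletests(pair_p[mask], method="fdr_bh")[1]
        pair_p = adj

    n_skipped = int((~pair_defined & ((n1[iu] + n1[ju]) > 0)).sum())
    if n_skipped:
        logger.info("%s: skipped %d zero-variance pairs", stratum_label, n_skipped)

    edges: list[EdgeRecord] = []
    keep = pair_defined & (pair_p <= alpha)
    if positive_only:
        keep &= phi[iu, ju] > 0
    for i, j in zip(iu[keep], ju[keep]):
        edges.append(EdgeRecord(ids[i], ids[j], float(phi[i, j]), float(pvals[i, j])))
    return ComorbidityNetwork(
        nodes=nodes,
        edges=edges,
        stratum_label=stratum_label,
        n_persons=n,
        node_prevalence=prevalence,
        n_skipped_pairs=n_skipped,
    )


def nearest_rank_quantile(sorted_values: np.ndarray, q: float) -> float:
    """Type-1 (nearest-rank) sample quantile of pre-sorted values."""
    n = len(sorted_values)
    rank = max(int(math.ceil(q * n)), 1)
    return float(sorted_values[rank - 1])


@dataclass
class NetworkStats:
    n_nodes: int
    n_edges: int
    density: float
    degree_median: float
    degree_q1: float
    degree_q3: float
    mean_degree: float
    degree_histogram: dict[int, int]
    hub_threshold: float
    hubs: list[tuple[str, int, float]]  # (disease, degree, prevalence) sorted

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "density": self.density,
            "degree_median": self.degree_median,
            "degree_iqr": [self.degree_q1, self.degree_q3],
            "mean_degree": self.mean_degree,
            "degree_histogram": {str(k): v for k, v in sorted(self.degree_histogram.items())},
            "hub_threshold": self.hub_threshold,
            "hubs": [list(h) for h in self.hubs],
        }


def network_stats(net: ComorbidityNetwork) -> NetworkStats:
    """Density, degree summaries, histogram, and the upper-quartile hub set.

    Hubs are nodes with degree >= the nearest-rank 75th percentile, sorted by
    degree descending with ties broken by prevalence descending then id.
    """
    n = len(net.nodes)
    if n < 2:
        raise DomainError("density undefined for networks with fewer than 2 nodes")
    deg = net.degree_by_node()
    degrees = np.sort(np.array(list(deg.values())))
    e = len(net.edges)
    density = 2.0 * e / (n * (n - 1))
    q1 = nearest_rank_quantile(degrees, 0.25)
    q3 = nearest_rank_quantile(degrees, 0.75)
    hist: dict[int, int] = {}
    for k in deg.values():
        hist[k] = hist.get(k, 0) + 1
    hubs = [
        (node, deg[node], float(net.node_prevalence.get(node, float("nan"))))
        for node in net.nodes
        if deg[node] >= q3
    ]
    hubs.sort(key=lambda h: (-h[1], -(h[2] if h[2] == h[2] else -1.0), h[0]))
    return NetworkStats(
        n_nodes=n,
        n_edges=e,
        density=density,
        degree_median=float(np.median(degrees)),
        degree_q1=q1,
        degree_q3=q3,
        mean_degree=float(degrees.mean()),
        degree_histogram=hist,
        hub_threshold=q3,
        hubs=hubs,
    )


def hub_degree_share(stats: NetworkStats) -> float:
    """Fraction of all edge endpoints held by hub nodes:
    ``sum(hub degrees) / (2 * n_edges)``."""
    if stats.n_edges == 0:
        raise DomainError("hub degree share undefined with no edges")
    return sum(h[1] for h in stats.hubs) / (2.0 * stats.n_edges)


@dataclass
class ScaleFreeReport:
    degenerate: bool
    skewness: float
    powerlaw_exponent: float | None = None
    geometric_p: float | None = None
    loglik_powerlaw: float | None = None
    loglik_geometric: float | None = None

    @property
    def loglik_difference(self) -> float | None:
        """Positive values favor the heavy-tailed (power-law) fit."""
        if self.degenerate:
            return None
        return self.loglik_powerlaw - self.loglik_geometric


def _zeta_loglik(alpha: float, degrees: np.ndarray) -> float:
    """Log-likelihood of the zeta (discrete power-law) distribution on k>=1."""
    from scipy.special import zeta

    return float(-alpha * np.sum(np.log(degrees)) - degrees.size * np.log(zeta(alpha, 1)))


def scale_free_diagnostics(stats: NetworkStats, min_degree: int = 1) -> ScaleFreeReport:
    """Heavy-tail diagnostics for the degree distribution.

    Compares the maximized log-likelihood of a discrete power law (zeta
    distribution) against a geometric fit on degrees >= ``min_degree``; a
    positive difference flags a heavier-than-exponential right tail.
    """
    degrees = np.concatenate(
        [np.full(c, k) for k, c in stats.degree_histogram.items()]
    ).astype(float)
    if np.ptp(degrees) == 0:
        return ScaleFreeReport(degenerate=True, skewness=0.0)
    skewness = float(sps.skew(degrees))
    tail = degrees[degrees >= min_degree]
    if tail.size < 3 or np.ptp(tail) == 0:
        return ScaleFreeReport(degenerate=True, skewness=skewness)

    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda a: -_zeta_loglik(a, tail), bounds=(1.01, 12.0), method="bounded"
    )
    alpha_hat = float(res.x)
    ll_pl = _zeta_loglik(alpha_hat, tail)
    # geometric on support {1, 2, ...}: MLE p = 1/mean
    p_hat = 1.0 / tail.mean()
    ll_geom = float(np.sum((tail - 1) * np.log1p(-p_hat) + np.log(p_hat)))
    return ScaleFreeReport(
        degenerate=False,
        skewness=skewness,
        powerlaw_exponent=alpha_hat,
        geometric_p=p_hat,
        loglik_powerlaw=ll_pl,
        loglik_geometric=ll_geom,
    )


@dataclass
class BootstrapCI:
    statistic_name: str
    point: float
    lower95: float
    upper95: float
    n_replicates: int
    seed: int


_STAT_FUNCS: dict[str, Callable[[NetworkStats], float]] = {
    "density": lambda s: s.density,
    "mean_degree": lambda s: s.mean_degree,
    "degree_median": lambda s: s.degree_median,
    "n_edges": lambda s: float(s.n_edges),
}


def bootstrap_network_statistic(
    cohort: Sequence[PersonRecord] | np.ndarray,
    catalog: DiseaseCatalog,
    statistic: str | Callable[[NetworkStats], float] = "density",
    B: int = DEFAULT_BOOTSTRAP_REPLICATES,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
) -> BootstrapCI:
    """Percentile bootstrap CI for a network statistic.

    Persons (rows) are resampled with replacement ``B`` times and the
    network is rebuilt per replicate; the 2.5/97.5 percentiles of the
    replicate statistics form the interval.  Deterministic for a fixed seed.
    """
    if B < 2:
        raise DomainError("bootstrap needs at least 2 replicates")
    if callable(statistic):
        func, name = statistic, getattr(statistic, "__name__", "custom")
    else:
        try:
            func, name = _STAT_FUNCS[statistic], statistic
        except KeyError:
            raise DomainError(f"unknown statistic {statistic!r}") from None
    x = cohort if isinstance(cohort, np.ndarray) else np.vstack([r.diseases for r in cohort])
    rng = np.random.default_rng(seed)
    point = func(network_stats(build_network(x, catalog, alpha)))
    values = np.empty(B)
    n = x.shape[0]
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        values[b] = func(network_stats(build_network(x[idx], catalog, alpha)))
    lower, upper = np.percentile(values, [2.5, 97.5])
    return BootstrapCI(
        statistic_name=name,
        point=float(point),
        lower95=float(lower),
        upper95=float(upper),
        n_replicates=B,
        seed=seed,
    )
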