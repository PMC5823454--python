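"""Age-stratified network comparison: the early-aging engine.

Both groups are split into the five incremental age brackets and a
comorbidity network is built per (group, bracket) cell.  Cells are compared
by one-way ANOVA on their node-degree samples (degree metrics), or by
two-proportion Fisher tests (density as the fraction of possible edges
present; pooled elder-disease prevalence).  A COPD bracket whose metric is
statistically indistinguishable (p > 0.05) from an older control bracket
exhibits an aging lag, quantified as the difference of bracket midpoints.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import (
    BRACKETS,
    BRACKET_LABELS,
    DiseaseCatalog,
    PersonRecord,
    assign_bracket,
)
from .errors import DomainError
from .network import ComorbidityNetwork, NetworkStats, build_network, network_stats
from .stats import fisher_exact_2x2

logger = logging.getLogger(__name__)

EQUIVALENCE_ALPHA = 0.05

_MIDPOINT = {b.label: b.midpoint for b in BRACKETS}

Cell = tuple[str, str]  # (group, bracket label)


@dataclass
class GridCell:
    network: ComorbidityNetwork
    stats: NetworkStats | None  # None when the cell has < 2 nodes
    n_persons: int
    elder_cases: int  # total elder-disease indications in the cell
    elder_denominator: int  # persons x number of elder diseases
    matrix: np.ndarray | None = None  # persons x diseases, for size-matched rebuilds


@dataclass
class StratifiedNetworkGrid:
    cells: dict[Cell, GridCell]
    empty_cells: list[Cell] = field(default_factory=list)
    catalog: DiseaseCatalog | None = None
    alpha: float = 0.01
    seed: int = 0  # drives the deterministic size-matched subsamples

    def stats(self, cell: Cell) -> NetworkStats:
        if cell not in self.cells:
            raise DomainError(f"cell {cell} is empty or absent")
        st = self.cells[cell].stats
        if st is None:
            raise DomainError(f"cell {cell} has too few nodes for statistics")
        return st

    def degrees(self, cell: Cell) -> np.ndarray:
        if cell not in self.cells:
            raise DomainError(f"cell {cell} is empty or absent")
        return np.array(list(self.cells[cell].network.degree_by_node().values()), float)

    def to_frame(self) -> pd.DataFrame:
        """Fig-2-shaped summary: one row per metric, columns = group x bracket."""
        metrics = ["n_persons", "n_nodes", "n_edges", "density", "mean_degree"]
        data: dict[str, list] = {}
        for grp in ("copd", "control"):
            for label in BRACKET_LABELS:
                cell = (grp, label)
                col = f"{grp}:{label}"
                if cell not in self.cells:
                    data[col] = [np.nan] * len(metrics)
                    continue
                gc = self.cells[cell]
                st = gc.stats
                data[col] = [
                    gc.n_persons,
                    len(gc.network.nodes),
                    len(gc.network.edges),
                    st.density if st else np.nan,
                    st.mean_degree if st else np.nan,
                ]
        return pd.DataFrame(data, index=metrics)


def build_grid(
    cohort: Sequence[PersonRecord],
    catalog: DiseaseCatalog,
    alpha: float = 0.01,
    seed: int = 0,
    **network_kwargs,
) -> StratifiedNetworkGrid:
    """One comorbidity network + statistics per (group, age-bracket) cell.

    Empty cells are flagged, not fatal.  Deterministic for a fixed cohort,
    invariant to person order.  ``seed`` drives the subsampling used by
    size-matched cell comparisons.
    """
    cells: dict[Cell, GridCell] = {}
    empty: list[Cell] = []
    elder_idx = catalog.elder_indices
    for grp in ("copd", "control"):
        for bracket in BRACKETS:
            cell = (grp, bracket.label)
            members = [
                r for r in cohort if r.group == grp and assign_bracket(r.age) is bracket
            ]
            if not members:
                empty.append(cell)
                logger.warning("stratum %s is empty", cell)
                continue
            x = np.vstack([r.diseases for r in members])
            net = build_network(
                x, catalog, alpha, stratum_label=f"{grp}:{bracket.label}", **network_kwargs
            )
            st = network_stats(net) if len(net.nodes) >= 2 else None
            cells[cell] = GridCell(
                network=net,
                stats=st,
                n_persons=len(members),
                elder_cases=int(x[:, elder_idx].sum()),
                elder_denominator=len(members) * len(elder_idx),
                matrix=x,
            )
    return StratifiedNetworkGrid(
        cells=cells, empty_cells=empty, catalog=catalog, alpha=alpha, seed=seed
    )


@dataclass(frozen=True)
class DegreeComparisonResult:
    pair: tuple[Cell, Cell]
    statistic: float
    p_value: float
    equivalent: bool  # p > 0.05: no detectable difference


def _subsampled_cell(grid: StratifiedNetworkGrid, cell: Cell, n_target: int):
    """The cell's network (and elder counts) rebuilt on a deterministic
    person subsample of size ``n_target``.

    The subsample seed depends only on the cell, the target size, and the
    grid seed, so comparisons are symmetric in the pair.
    """
    gc = grid.cells[cell]
    if gc.n_persons <= n_target or gc.matrix is None or grid.catalog is None:
        return gc.network, gc.elder_cases, gc.elder_denominator
    tag = f"{cell}|{n_target}|{grid.seed}"
    rng = np.random.default_rng(zlib.crc32(tag.encode()))
    idx = rng.choice(gc.n_persons, size=n_target, replace=False)
    x = gc.matrix[idx]
    net = build_network(
        x, grid.catalog, grid.alpha, stratum_label=f"{cell[0]}:{cell[1]}@{n_target}"
    )
    elder_idx = grid.catalog.elder_indices
    return net, int(x[:, elder_idx].sum()), n_target * len(elder_idx)


def _comparison_cells(grid, cell_a: Cell, cell_b: Cell, size_matched: bool):
    for cell in (cell_a, cell_b):
        if cell not in grid.cells:
            raise DomainError(f"cell {cell} is empty or absent")
    if not size_matched:
        gc_a, gc_b = grid.cells[cell_a], grid.cells[cell_b]
        return (
            (gc_a.network, gc_a.elder_cases, gc_a.elder_denominator),
            (gc_b.network, gc_b.elder_cases, gc_b.elder_denominator),
        )
    n = min(grid.cells[cell_a].n_persons, grid.cells[cell_b].n_persons)
    return _subsampled_cell(grid, cell_a, n), _subsampled_cell(grid, cell_b, n)


def compare_degree_distributions(
    grid: StratifiedNetworkGrid,
    cell_a: Cell,
    cell_b: Cell,
    welch: bool = False,
    size_matched: bool = True,
) -> DegreeComparisonResult:
    """One-way ANOVA (or Welch t with ``welch=True``) on the node-degree
    samples of two cells; ``equivalent`` when p > 0.05.

    By default the larger cell is first subsampled (deterministically) to
    the smaller cell's person count and its network rebuilt, so that the
    comparison reflects the strata's association structure rather than the
    edge-detection power that grows with sample size.
    """
    (net_a, _, _), (net_b, _, _) = _comparison_cells(grid, cell_a, cell_b, size_matched)
    deg_a = np.array(list(net_a.degree_by_node().values()), float)
    deg_b = np.array(list(net_b.degree_by_node().values()), float)
    if len(deg_a) < 2 or len(deg_b) < 2:
        raise DomainError("degree comparison needs >= 2 nodes per cell")
    if np.array_equal(np.sort(deg_a), np.sort(deg_b)):
        # identical samples: zero between-group variance, no difference
        return DegreeComparisonResult((cell_a, cell_b), 0.0, 1.0, True)
    if welch:
        stat, p = sps.ttest_ind(deg_a, deg_b, equal_var=False)
    else:
        stat, p = sps.f_oneway(deg_a, deg_b)
    return DegreeComparisonResult(
        (cell_a, cell_b), float(stat), float(p), bool(p > EQUIVALENCE_ALPHA)
    )


def _proportion_equivalence(
    k_a: int, n_a: int, k_b: int, n_b: int, pair: tuple[Cell, Cell]
) -> DegreeComparisonResult:
    p = fisher_exact_2x2(k_a, n_a - k_a, k_b, n_b - k_b)
    return DegreeComparisonResult(pair, float("nan"), p, bool(p > EQUIVALENCE_ALPHA))


def compare_cells(
    grid: StratifiedNetworkGrid,
    cell_a: Cell,
    cell_b: Cell,
    metric: str,
    welch: bool = False,
    size_matched: bool = True,
) -> DegreeComparisonResult:
    """Equivalence comparison of two cells on a named metric.

    ``degree``: ANOVA on node degrees.  ``density``: Fisher test on
    (edges present, possible pairs).  ``elder_prevalence``: Fisher test on
    pooled elder-disease cases over person-disease slots.  ``size_matched``
    equalizes the cells' person counts first (see
    :func:`compare_degree_distributions`).
    """
    if metric == "degree":
        return compare_degree_distributions(
            grid, cell_a, cell_b, welch=welch, size_matched=size_matched
        )
    cells = _comparison_cells(grid, cell_a, cell_b, size_matched)
    if metric == "density":
        (net_a, _, _), (net_b, _, _) = cells
        e_a, n_a = len(net_a.edges), len(net_a.nodes)
        e_b, n_b = len(net_b.edges), len(net_b.nodes)
        if n_a < 2 or n_b < 2:
            raise DomainError("density comparison needs >= 2 nodes per cell")
        return _proportion_equivalence(
            e_a, n_a * (n_a - 1) // 2, e_b, n_b * (n_b - 1) // 2, (cell_a, cell_b)
        )
    if metric == "elder_prevalence":
        (_, k_a, n_a), (_, k_b, n_b) = cells
        return _proportion_equivalence(k_a, n_a, k_b, n_b, (cell_a, cell_b))
    raise DomainError(f"unknown metric {metric!r}")


@dataclass
class AgingLagEstimate:
    metric_name: str
    copd_bracket: str
    matched_control_brackets: list[str]
    lag_years: float | None  # midpoint shift of the closest match; None if no match

    @property
    def best_match(self) -> str | None:
        return self.matched_control_brackets[0] if self.matched_control_brackets else None


def estimate_aging_lag(
    grid: StratifiedNetworkGrid, metric: str = "degree", welch: bool = False
) -> list[AgingLagEstimate]:
    """For each COPD bracket, find the control bracket(s) whose metric is
    statistically indistinguishable (equivalence p > 0.05).

    The lag is the smallest bracket-midpoint shift consistent with
    equivalence: the matched list is ordered by age distance (ties broken
    by larger equivalence p), and the lag is the midpoint difference of the
    closest match relative to the same-age bracket, positive when the
    matched control bracket is older.
    """
    estimates = []
    for label in BRACKET_LABELS:
        copd_cell = ("copd", label)
        if copd_cell not in grid.cells:
            continue
        matches: list[tuple[float, float, str]] = []
        for ctrl_label in BRACKET_LABELS:
            ctrl_cell = ("control", ctrl_label)
            if ctrl_cell not in grid.cells:
                continue
            try:
                res = compare_cells(grid, copd_cell, ctrl_cell, metric, welch=welch)
            except DomainError:
                continue
            if res.equivalent:
                distance = abs(_MIDPOINT[ctrl_label] - _MIDPOINT[label])
                matches.append((distance, -res.p_value, ctrl_label))
        matches.sort()
        lag = _MIDPOINT[matches[0][2]] - _MIDPOINT[label] if matches else None
        estimates.append(
            AgingLagEstimate(
                metric_name=metric,
                copd_bracket=label,
                matched_control_brackets=[m[2] for m in matches],
                lag_years=lag,
            )
        )
    return estimates


def hub_overlap(
    stats_a: NetworkStats, stats_b: NetworkStats
) -> tuple[int, list[tuple[str, int]], list[tuple[str, int]]]:
    """Hub-set intersection size and the degree-sorted unique hubs of each
    network (by disease identifier)."""
    hubs_a = {h[0]: h[1] for h in stats_a.hubs}
    hubs_b = {h[0]: h[1] for h in stats_b.hubs}
    shared = len(set(hubs_a) & set(hubs_b))
    unique_a = sorted(
        ((d, k) for d, k in hubs_a.items() if d not in hubs_b), key=lambda t: (-t[1], t[0])
    )
    unique_b = sorted(
        ((d, k) for d, k in hubs_b.items() if d not in hubs_a), key=lambda t: (-t[1], t[0])
    )
    return shared, unique_a, unique_b


def elder_trajectories(
    cohort: Sequence[PersonRecord],
    catalog: DiseaseCatalog,
    grid: StratifiedNetworkGrid | None = None,
) -> pd.DataFrame:
    """Per elder disease and bracket: both groups' prevalences, the Fisher
    exact two-sided p, and the disease's degree in each cell network.

    Diseases absent from a whole bracket get a NaN p-value (flagged
    undefined)."""
    elder_ids = [catalog.condition_ids[i] for i in catalog.elder_indices]
    idx = {catalog.condition_ids[i]: i for i in catalog.elder_indices}
    x = np.vstack([r.diseases for r in cohort])
    groups = np.array([r.group for r in cohort])
    brackets = np.array([assign_bracket(r.age).label for r in cohort])

    rows = []
    for did in elder_ids:
        j = idx[did]
        for label in BRACKET_LABELS:
            in_b = brackets == label
            row: dict = {"disease": did, "bracket": label}
            counts = {}
            for grp in ("copd", "control"):
                mask = in_b & (groups == grp)
                denom = int(mask.sum())
                num = int(x[mask, j].sum()) if denom else 0
                counts[grp] = (num, denom)
                row[f"prevalence_{grp}"] = num / denom if denom else float("nan")
                degree = float("nan")
                if grid is not None and (grp, label) in grid.cells:
                    degree = grid.cells[(grp, label)].network.degree_by_node().get(did, 0)
                row[f"degree_{grp}"] = degree
            (nc, dc), (nn, dn) = counts["copd"], counts["control"]
            if dc and dn and (nc + nn) > 0:
                row["p_value"] = fisher_exact_2x2(nc, dc - nc, nn, dn - nn)
            else:
                row["p_value"] = float("nan")
            rows.append(row)
    return pd.DataFrame(rows)
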