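"""Published summary inputs from the EpiChron COPD comorbidity-network study.

The person-level records behind that study are not deposited, but its
printed summary tables are usable as inputs: headline cohort counts, and the
hub table (top-30 connected diseases with prevalence and degree for each
group).  These drive the worked examples — death and smoker fractions,
bracket shares, hub-set overlap, and the hub degree share — recomputed by
the package's own functions.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .network import NetworkStats

#: Headline printed counts of the reference cohort (year 2011, age >= 40,
#: matched groups of equal size).
REFERENCE_COUNTS: dict[str, int] = {
    "n_per_group": 27617,
    "deaths_copd": 5247,
    "deaths_control": 2911,
    "control_smokers": 1914,
    "bracket_40_55_per_group": 3267,
    "nodes_copd": 119,
    "nodes_control": 118,
    "edges_copd": 1917,
    "edges_control": 1685,
}


def load_hub_table() -> pd.DataFrame:
    """The published hub table: group, rank, condition_id, prevalence (%),
    degree, for the 30 hubs of each group's network."""
    path = Path(__file__).parent / "data" / "epichron_hub_table.csv"
    return pd.read_csv(path)


def hub_stats_from_table(group: str) -> NetworkStats:
    """A partial :class:`NetworkStats` view of one group's published network.

    Only the fields derivable from the printed table and counts are
    meaningful (``n_nodes``, ``n_edges``, ``hubs``, ``hub_threshold``); the
    degree-distribution summaries of the full network were not printed per
    node and are left NaN.  Sufficient for ``hub_overlap`` and
    ``hub_degree_share``.
    """
    if group not in ("copd", "control"):
        raise ValueError(f"unknown group {group!r}")
    table = load_hub_table()
    sub = table[table["group"] == group].sort_values("rank")
    hubs = [
        (row.condition_id, int(row.degree), float(row.prevalence_pct) / 100.0)
        for row in sub.itertuples(index=False)
    ]
    nan = float("nan")
    return NetworkStats(
        n_nodes=REFERENCE_COUNTS[f"nodes_{group}"],
        n_edges=REFERENCE_COUNTS[f"edges_{group}"],
        density=2.0
        * REFERENCE_COUNTS[f"edges_{group}"]
        / (REFERENCE_COUNTS[f"nodes_{group}"] * (REFERENCE_COUNTS[f"nodes_{group}"] - 1)),
        degree_median=nan,
        degree_q1=nan,
        degree_q3=nan,
        mean_degree=nan,
        degree_histogram={},
        hub_threshold=min(h[1] for h in hubs),
        hubs=hubs,
    )
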