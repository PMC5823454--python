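"""Cohort-level descriptive and inferential statistics.

Prevalence tables with Fisher exact group comparisons, comorbidity-count
distributions by 5-year age band (top-coded at >= 8 conditions), the 3-year
mortality logistic model, and the smokers subgroup extraction with 1:1
age/sex matching.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import hypergeom

from .cohort import (
    BRACKET_LABELS,
    DiseaseCatalog,
    PersonRecord,
    assign_bracket,
    comorbidity_count,
)
from .errors import DomainError

TOP_CODE = 8  # comorbidity counts of 8+ are pooled in distributions


def fisher_exact_2x2(a: int, b: int, c: int, d: int, mid_p: bool = False) -> float:
    """Two-sided Fisher exact p-value for the table [[a, b], [c, d]].

    Sums hypergeometric probabilities no larger than the observed table's
    (minimum-likelihood convention).  A zero margin makes every table equally
    likely, so p = 1 by convention.  ``mid_p`` subtracts half the observed
    table's probability (the mid-p variant).
    """
    if min(a, b, c, d) < 0:
        raise DomainError("counts must be nonnegative")
    n = a + b + c + d
    if n == 0:
        raise DomainError("empty table")
    row1, col1 = a + b, a + c
    if row1 == 0 or col1 == 0 or row1 == n or col1 == n:
        return 1.0
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = hypergeom.pmf(support, n, col1, row1)
    p_obs = hypergeom.pmf(a, n, col1, row1)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    if mid_p:
        p -= 0.5 * float(p_obs)
    return min(p, 1.0)


@dataclass
class PrevalenceTable:
    rows: pd.DataFrame  # disease, group, bracket, numerator, denominator, prevalence
    comparisons: pd.DataFrame  # disease, bracket, p_value, significant

    def significant_fraction(self, alpha: float = 0.05) -> float:
        comp = self.comparisons.dropna(subset=["p_value"])
        return float((comp["p_value"] <= alpha).mean()) if len(comp) else float("nan")


def prevalence_table(
    cohort: Sequence[PersonRecord],
    catalog: DiseaseCatalog,
    by_bracket: bool = False,
    significance: float = 0.05,
    mid_p: bool = False,
) -> PrevalenceTable:
    """Per-disease prevalence in each group with Fisher exact comparisons.

    With ``by_bracket`` the table is additionally stratified by age bracket;
    the unstratified rows are always present under bracket label "all".
    Diseases absent from both groups in a stratum get an undefined (NaN)
    p-value.
    """
    x = np.vstack([r.diseases for r in cohort])
    groups = np.array([r.group for r in cohort])
    brackets = np.array([assign_bracket(r.age).label for r in cohort])
    ids = catalog.condition_ids

    strata: list[str] = ["all"] + (list(BRACKET_LABELS) if by_bracket else [])
    rows, comps = [], []
    for stratum in strata:
        in_stratum = np.ones(len(cohort), bool) if stratum == "all" else brackets == stratum
        counts = {}
        for grp in ("copd", "control"):
            mask = in_stratum & (groups == grp)
            denom = int(mask.sum())
            nums = x[mask].sum(axis=0) if denom else np.zeros(len(ids), int)
            counts[grp] = (nums, denom)
            for j, did in enumerate(ids):
                rows.append(
                    {
                        "disease": did,
                        "group": grp,
                        "bracket": stratum,
                        "numerator": int(nums[j]),
                        "denominator": denom,
                        "prevalence": float(nums[j]) / denom if denom else float("nan"),
                    }
                )
        (n_copd, d_copd), (n_ctrl, d_ctrl) = counts["copd"], counts["control"]
        run_tests = d_copd > 1 and d_ctrl > 1
        for j, did in enumerate(ids):
            if not run_tests or (n_copd[j] == 0 and n_ctrl[j] == 0):
                p = float("nan")
            else:
                p = fisher_exact_2x2(
                    int(n_copd[j]), d_copd - int(n_copd[j]),
                    int(n_ctrl[j]), d_ctrl - int(n_ctrl[j]),
                    mid_p=mid_p,
                )
            comps.append(
                {
                    "disease": did,
                    "bracket": stratum,
                    "p_value": p,
                    "significant": bool(p <= significance) if p == p else False,
                }
            )
    return PrevalenceTable(rows=pd.DataFrame(rows), comparisons=pd.DataFrame(comps))


def _age_band(age: int) -> str:
    lo = min((age // 5) * 5, 95)
    return f"{lo}+" if lo == 95 else f"{lo}-{lo + 4}"


@dataclass
class CountDistribution:
    table: pd.DataFrame  # group, band, count_category, n, proportion
    summary: pd.DataFrame  # group: mean, sd, ci95_low, ci95_high, n

    def proportion_at_least(self, group: str, band: str, k: int) -> float:
        sub = self.table[(self.table["group"] == group) & (self.table["band"] == band)]
        cats = sub["count_category"].to_numpy()
        keep = np.array([c >= k for c in cats])
        return float(sub.loc[keep, "proportion"].sum())


def count_distribution(
    cohort: Sequence[PersonRecord], catalog: DiseaseCatalog
) -> CountDistribution:
    """Comorbidity-count histograms per group and 5-year age band.

    Counts exclude the index diagnosis and are top-coded at >= 8.  The
    summary gives each group's mean count with SD and the normal-theory 95%
    CI of the mean.
    """
    recs = pd.DataFrame(
        {
            "group": [r.group for r in cohort],
            "band": [_age_band(r.age) for r in cohort],
            "count": [comorbidity_count(r, catalog) for r in cohort],
        }
    )
    recs["count_category"] = recs["count"].clip(upper=TOP_CODE)
    rows = []
    for (grp, band), sub in recs.groupby(["group", "band"], sort=True):
        total = len(sub)
        for cat, n in sub["count_category"].value_counts().sort_index().items():
            rows.append(
                {
                    "group": grp,
                    "band": band,
                    "count_category": int(cat),
                    "n": int(n),
                    "proportion": n / total,
                }
            )
    summaries = []
    for grp, sub in recs.groupby("group"):
        mean = sub["count"].mean()
        sd = sub["count"].std(ddof=1)
        sem = sd / np.sqrt(len(sub))
        summaries.append(
            {
                "group": grp,
                "mean": mean,
                "sd": sd,
                "ci95_low": mean - 1.96 * sem,
                "ci95_high": mean + 1.96 * sem,
                "n": len(sub),
            }
        )
    return CountDistribution(table=pd.DataFrame(rows), summary=pd.DataFrame(summaries))


@dataclass
class MortalityModel:
    """Fitted 3-year mortality logit: died ~ age/10 + comorbidity count + copd."""

    coefficients: dict[str, float]
    odds_ratios: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    n_deaths: dict[str, int]
    converged: bool

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients,
            "odds_ratios": self.odds_ratios,
            "ci95": {k: list(v) for k, v in self.ci95.items()},
            "n_deaths": self.n_deaths,
            "converged": self.converged,
        }


MORTALITY_COVARIATES = ("age_per_10y", "n_comorbidities", "copd")


def fit_mortality_model(
    cohort: Sequence[PersonRecord], catalog: DiseaseCatalog
) -> MortalityModel:
    """Maximum-likelihood logistic fit of 3-year death on age (per decade),
    comorbidity count, and the index-diagnosis indicator, with Wald 95% CIs
    on the odds ratios."""
    import statsmodels.api as sm

    y = np.array([r.died_3y for r in cohort], float)
    if y.min() == y.max():
        raise DomainError("both death outcomes must be present to fit the model")
    design = pd.DataFrame(
        {
            "age_per_10y": [r.age / 10.0 for r in cohort],
            "n_comorbidities": [float(comorbidity_count(r, catalog)) for r in cohort],
            "copd": [float(r.group == "copd") for r in cohort],
        }
    )
    exog = sm.add_constant(design, has_constant="add")
    result = sm.Logit(y, exog).fit(disp=0, maxiter=200)
    params = result.params
    conf = result.conf_int(alpha=0.05)
    if not result.mle_retvals.get("converged", False) or np.abs(params).max() > 50:
        worst = design.columns[int(np.abs(params[1:]).argmax())]
        raise DomainError(f"possible separation / non-convergence on covariate {worst!r}")
    groups = np.array([r.group for r in cohort])
    deaths = {
        grp: int(y[groups == grp].sum()) for grp in ("copd", "control") if (groups == grp).any()
    }
    names = ["intercept", *MORTALITY_COVARIATES]
    return MortalityModel(
        coefficients={n: float(p) for n, p in zip(names, params)},
        odds_ratios={n: float(np.exp(p)) for n, p in zip(names[1:], params[1:])},
        ci95={
            n: (float(np.exp(conf.iloc[i + 1, 0])), float(np.exp(conf.iloc[i + 1, 1])))
            for i, n in enumerate(names[1:])
        },
        n_deaths=deaths,
        converged=True,
    )


@dataclass
class SmokersSubgroupReport:
    n_control_smokers: int
    n_matched: int
    n_unmatched: int
    mean_count_copd: float
    mean_count_control: float
    count_p_value: float
    death_fraction_copd: float
    death_fraction_control: float
    death_p_value: float


def smokers_subgroup(
    cohort: Sequence[PersonRecord],
    catalog: DiseaseCatalog,
    seed: int = 0,
    welch: bool = True,
) -> tuple[list[PersonRecord], SmokersSubgroupReport]:
    """Extract confirmed non-COPD smokers and 1:1 age/sex match them to
    randomly drawn COPD patients; rerun the count and mortality contrasts.

    Matching is exact on (age-year, sex) with a seeded uniform draw among
    candidates; control smokers without an available match are reported and
    dropped.
    """
    rng = np.random.default_rng(seed)
    control_smokers = [r for r in cohort if r.group == "control" and r.smoker]
    copd_pool: dict[tuple[int, str], list[PersonRecord]] = {}
    for r in cohort:
        if r.group == "copd":
            copd_pool.setdefault((r.age, r.sex), []).append(r)
    for key in sorted(copd_pool, key=lambda k: (k[0], k[1])):
        rng.shuffle(copd_pool[key])

    matched: list[PersonRecord] = []
    unmatched = 0
    for ctrl in control_smokers:
        pool = copd_pool.get((ctrl.age, ctrl.sex), [])
        if pool:
            matched.append(pool.pop())
            matched.append(ctrl)
        else:
            unmatched += 1

    sub_copd = [r for r in matched if r.group == "copd"]
    sub_ctrl = [r for r in matched if r.group == "control"]
    if not sub_copd:
        report = SmokersSubgroupReport(
            n_control_smokers=len(control_smokers),
            n_matched=0,
            n_unmatched=unmatched,
            mean_count_copd=float("nan"),
            mean_count_control=float("nan"),
            count_p_value=float("nan"),
            death_fraction_copd=float("nan"),
            death_fraction_control=float("nan"),
            death_p_value=float("nan"),
        )
        return [], report

    counts_copd = np.array([comorbidity_count(r, catalog) for r in sub_copd], float)
    counts_ctrl = np.array([comorbidity_count(r, catalog) for r in sub_ctrl], float)
    if welch:
        count_p = float(sps.ttest_ind(counts_copd, counts_ctrl, equal_var=False).pvalue)
    else:
        count_p = float(sps.ranksums(counts_copd, counts_ctrl).pvalue)
    deaths_copd = sum(r.died_3y for r in sub_copd)
    deaths_ctrl = sum(r.died_3y for r in sub_ctrl)
    death_p = fisher_exact_2x2(
        deaths_copd, len(sub_copd) - deaths_copd, deaths_ctrl, len(sub_ctrl) - deaths_ctrl
    )
    report = SmokersSubgroupReport(
        n_control_smokers=len(control_smokers),
        n_matched=len(sub_copd),
        n_unmatched=unmatched,
        mean_count_copd=float(counts_copd.mean()),
        mean_count_control=float(counts_ctrl.mean()),
        count_p_value=count_p,
        death_fraction_copd=deaths_copd / len(sub_copd),
        death_fraction_control=deaths_ctrl / len(sub_ctrl),
        death_p_value=death_p,
    )
    return matched, report
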