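"""Synthetic matched COPD/control cohort generator.

Real EMR cohorts of this kind are not publicly deposited, so the pipeline is
exercised on synthetic cohorts that reproduce the statistical structure the
analysis assumes:

* demographics matched by construction — every control is a demographic
  clone (same age, same sex) of one case;
* age-bracket shares and the 70/30 male/female split of the reference
  population;
* per-disease prevalence that increases with age on a probit scale;
* correlated disease co-occurrence via a Gaussian latent-factor threshold
  model, which produces positive phi associations inside factor blocks and
  the degree heterogeneity ("hub" structure) the network stage looks for;
* early aging as a pure age shift: a case of age ``a`` draws diseases as a
  control of age ``a + delta`` would (default delta = 15 years, the midpoint
  of the reported 10-to-20-year lag);
* 3-year mortality from a logit-linear model in age, comorbidity count and
  case status, with the intercept calibrated to an 11% control death
  fraction.

The model: person-level latent factors ``u ~ N(0, I_K)``; disease ``d`` is
present with probability ``Phi(lambda_d . u + b_d + s_d (age_eff - 40))``
given ``u``, where ``age_eff = age + delta`` for cases.  The marginal
prevalence has the closed form ``Phi((b_d + s_d (age_eff-40)) /
sqrt(1 + |lambda_d|^2))``; :func:`prevalence_closed_form` evaluates the
defining integral by Gauss-Hermite quadrature and serves as the generator's
independent ground truth in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.special import expit, ndtr, ndtri

from .cohort import DiseaseCatalog, PersonRecord, default_catalog
from .errors import ConfigError

#: Age-bracket population shares of the matched control group
#: (40-55, 56-65, 66-75, 76-85, >85).
DEFAULT_BRACKET_WEIGHTS = (0.12, 0.20, 0.33, 0.27, 0.08)

#: Sampling ranges (inclusive) for integer age within each bracket; the
#: open-ended top bracket is truncated at 95.
_BRACKET_AGE_RANGES = ((40, 55), (56, 65), (66, 75), (76, 85), (86, 95))

#: 3-year mortality odds ratios: per 10 years of age, per comorbidity,
#: for carrying the index diagnosis.
DEFAULT_MORTALITY_ORS = (2.75, 1.09, 1.65)


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic-cohort generator.

    ``loadings`` (diseases x factors), ``intercepts`` (probit scale at age
    40) and ``age_slopes`` (probit units per year) default to a deterministic
    scheme built from the catalog by :func:`default_disease_params`.
    ``mortality_beta0`` of ``None`` requests calibration of the intercept to
    ``control_death_fraction``.
    """

    n_per_group: int = 27617
    seed: int = 0
    bracket_weights: tuple[float, ...] = DEFAULT_BRACKET_WEIGHTS
    male_fraction: float = 0.70
    n_factors: int = 3
    loadings: np.ndarray | None = None
    intercepts: np.ndarray | None = None
    age_slopes: np.ndarray | None = None
    aging_shift_delta: float = 15.0
    mortality_ors: tuple[float, float, float] = DEFAULT_MORTALITY_ORS
    mortality_beta0: float | None = None
    control_death_fraction: float = 0.11
    smoker_prob_by_group: tuple[float, float] = (0.21, 0.07)  # (copd, control)

    def validate(self, catalog: DiseaseCatalog) -> None:
        if self.n_per_group < 1:
            raise ConfigError("n_per_group must be >= 1")
        w = np.asarray(self.bracket_weights, dtype=float)
        if w.shape != (5,) or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ConfigError("bracket_weights must be 5 nonnegative values summing to 1")
        for name, p in (
            ("male_fraction", self.male_fraction),
            ("smoker_prob copd", self.smoker_prob_by_group[0]),
            ("smoker_prob control", self.smoker_prob_by_group[1]),
            ("control_death_fraction", self.control_death_fraction),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be a probability, got {p}")
        if self.aging_shift_delta < 0:
            raise ConfigError("aging_shift_delta must be >= 0")
        if any(r <= 0 for r in self.mortality_ors):
            raise ConfigError("mortality odds ratios must be positive")
        d = len(catalog)
        for name, arr, shape in (
            ("loadings", self.loadings, (d, self.n_factors)),
            ("intercepts", self.intercepts, (d,)),
            ("age_slopes", self.age_slopes, (d,)),
        ):
            if arr is not None and np.asarray(arr).shape != shape:
                raise ConfigError(f"{name} must have shape {shape}")


def default_disease_params(
    catalog: DiseaseCatalog, n_factors: int = 3
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic default latent-model parameters for a catalog.

    Each non-index disease loads on a single factor (cycling through the
    factors in catalog order) with magnitude decaying geometrically from 1.0
    to 0.25 across the catalog, so earlier (more common) diseases are the
    hub-prone ones.  Marginal prevalence at the reference age of 70 decays
    geometrically over a short common head (40% to 2% across the first 20
    conditions) and a long rare tail (2% to 0.1%), spanning the two-to-three
    orders of magnitude seen in chronic-condition catalogs; probit slopes of
    0.008-0.024 per year give the age-increasing prevalence the early-aging
    comparison relies on.  The index entry is left out of the latent model
    (its column is set by group membership) and gets zeroed parameters.
    """
    d = len(catalog)
    loadings = np.zeros((d, n_factors))
    intercepts = np.zeros(d)
    slopes = np.zeros(d)
    others = [i for i in range(d) if i != catalog.copd_index]
    m = len(others)
    n_head = min(20, m)  # a short head of common diseases, a long rare tail
    for rank, i in enumerate(others):
        frac = rank / max(m - 1, 1)
        magnitude = 1.0 * (0.25 / 1.0) ** frac
        loadings[i, rank % n_factors] = magnitude
        # marginal prevalence at the reference age of 70, then probit-linear
        # in age; calibrated so the control mean comorbidity count lands near
        # the 3-to-5 range typical of chronic-condition cohorts of this age
        if rank < n_head:
            p70 = 0.40 * (0.02 / 0.40) ** (rank / max(n_head - 1, 1))
        else:
            tail_frac = (rank - n_head) / max(m - n_head - 1, 1)
            p70 = 0.02 * (0.001 / 0.02) ** tail_frac
        s_marginal = 0.008 + 0.004 * (rank % 5)
        b40_marginal = ndtri(p70) - 30.0 * s_marginal
        scale = np.sqrt(1.0 + magnitude**2)
        intercepts[i] = b40_marginal * scale
        slopes[i] = s_marginal * scale
    return loadings, intercepts, slopes


@lru_cache(maxsize=8)
def _hermgauss(n_quad: int) -> tuple[np.ndarray, np.ndarray]:
    return np.polynomial.hermite.hermgauss(n_quad)


def _resolved_params(
    config: GeneratorConfig, catalog: DiseaseCatalog
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if config.loadings is None or config.intercepts is None or config.age_slopes is None:
        lam, b, s = default_disease_params(catalog, config.n_factors)
        lam = lam if config.loadings is None else np.asarray(config.loadings, float)
        b = b if config.intercepts is None else np.asarray(config.intercepts, float)
        s = s if config.age_slopes is None else np.asarray(config.age_slopes, float)
        return lam, b, s
    return (
        np.asarray(config.loadings, float),
        np.asarray(config.intercepts, float),
        np.asarray(config.age_slopes, float),
    )


def prevalence_closed_form(
    disease: str, age: float, group: str, config: GeneratorConfig,
    catalog: DiseaseCatalog | None = None, n_quad: int = 61,
) -> float:
    """Exact marginal prevalence of ``disease`` at ``age`` in ``group``.

    Evaluates ``integral Phi(sigma*u + eta) dN(u)`` by Gauss-Hermite
    quadrature, with ``sigma = |lambda_d|`` and ``eta`` the probit linear
    predictor at the group's effective age.  This is the generator's ground
    truth, independent of the sampling path.
    """
    catalog = catalog if catalog is not None else default_catalog()
    idx = catalog.index_of(disease)  # raises KeyError for unknown disease
    if idx == catalog.copd_index:
        return 1.0 if group == "copd" else 0.0
    lam, b, s = _resolved_params(config, catalog)
    age_eff = age + (config.aging_shift_delta if group == "copd" else 0.0)
    eta = b[idx] + s[idx] * (age_eff - 40.0)
    sigma = float(np.linalg.norm(lam[idx]))
    nodes, weights = _hermgauss(n_quad)
    # change of variables u = sqrt(2) x: int Phi(sigma u + eta) phi(u) du
    vals = ndtr(sigma * np.sqrt(2.0) * nodes + eta)
    return float(np.sum(weights * vals) / np.sqrt(np.pi))


def _sample_demographics(config: GeneratorConfig, rng: np.random.Generator):
    n = config.n_per_group
    bracket_idx = rng.choice(5, size=n, p=np.asarray(config.bracket_weights, float))
    lo = np.array([r[0] for r in _BRACKET_AGE_RANGES])
    hi = np.array([r[1] for r in _BRACKET_AGE_RANGES])
    ages = rng.integers(lo[bracket_idx], hi[bracket_idx] + 1)
    male = rng.random(n) < config.male_fraction
    return ages.astype(int), male


def _sample_disease_matrix(
    ages: np.ndarray, shift: float, lam: np.ndarray, b: np.ndarray, s: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    n = len(ages)
    u = rng.standard_normal((n, lam.shape[1]))
    eta = u @ lam.T + b[None, :] + s[None, :] * (ages + shift - 40.0)[:, None]
    return (rng.random((n, lam.shape[0])) < ndtr(eta)).astype(np.uint8)


def simulate_cohort(
    config: GeneratorConfig, catalog: DiseaseCatalog | None = None
) -> tuple[list[PersonRecord], DiseaseCatalog]:
    """Generate a matched case/control cohort of ``2 * n_per_group`` people.

    Cases come first, then their demographic clones; a fixed seed yields
    bit-identical output.  Mortality is drawn as part of the simulation (see
    :func:`simulate_mortality` for the model).
    """
    catalog = catalog if catalog is not None else default_catalog()
    config.validate(catalog)
    rng = np.random.default_rng(config.seed)
    lam, b, s = _resolved_params(config, catalog)

    ages, male = _sample_demographics(config, rng)
    x_copd = _sample_disease_matrix(ages, config.aging_shift_delta, lam, b, s, rng)
    x_ctrl = _sample_disease_matrix(ages, 0.0, lam, b, s, rng)
    x_copd[:, catalog.copd_index] = 1
    x_ctrl[:, catalog.copd_index] = 0
    p_smoke = config.smoker_prob_by_group
    smoker_copd = rng.random(config.n_per_group) < p_smoke[0]
    smoker_ctrl = rng.random(config.n_per_group) < p_smoke[1]
    # hospitalization is descriptive only: rare in controls, less so in cases
    hosp_copd = rng.random(config.n_per_group) < 0.046
    hosp_ctrl = rng.random(config.n_per_group) < 0.003

    records: list[PersonRecord] = []
    for grp, prefix, x, smoker, hosp in (
        ("copd", "P", x_copd, smoker_copd, hosp_copd),
        ("control", "C", x_ctrl, smoker_ctrl, hosp_ctrl),
    ):
        for i in range(config.n_per_group):
            records.append(
                PersonRecord(
                    person_id=f"{prefix}{i + 1:06d}",
                    age=int(ages[i]),
                    sex="male" if male[i] else "female",
                    group=grp,
                    smoker=bool(smoker[i]),
                    died_3y=False,
                    hospitalized_prior_year=bool(hosp[i]),
                    diseases=x[i],
                )
            )
    records = simulate_mortality(records, config, catalog, rng=rng)
    return records, catalog


def mortality_linear_predictor(
    records: Sequence[PersonRecord], catalog: DiseaseCatalog, config: GeneratorConfig
) -> np.ndarray:
    """Linear predictor (without intercept) of the 3-year mortality model:
    ``ln(OR_age)/10 * age + ln(OR_count) * comorbidities + ln(OR_copd) * copd``."""
    or_age10, or_count, or_copd = config.mortality_ors
    ages = np.array([r.age for r in records], float)
    counts = np.array(
        [r.diseases.sum() - r.diseases[catalog.copd_index] for r in records], float
    )
    is_copd = np.array([r.group == "copd" for r in records], float)
    return (
        np.log(or_age10) / 10.0 * ages + np.log(or_count) * counts + np.log(or_copd) * is_copd
    )


def calibrate_mortality_intercept(
    linpred_controls: np.ndarray, target: float, tol: float = 1e-10
) -> float:
    """Bisection for the intercept giving a mean control death probability of
    ``target``; the mean of expit is monotone in the intercept."""
    lo, hi = -40.0, 10.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if float(np.mean(expit(mid + linpred_controls))) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def simulate_mortality(
    records: Sequence[PersonRecord],
    config: GeneratorConfig,
    catalog: DiseaseCatalog | None = None,
    rng: np.random.Generator | None = None,
) -> list[PersonRecord]:
    """Draw ``died_3y`` for every record from the logit-linear model.

    With ``mortality_beta0=None`` the intercept is calibrated so the mean
    predicted control death probability equals ``control_death_fraction``.
    """
    catalog = catalog if catalog is not None else default_catalog()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    linpred = mortality_linear_predictor(records, catalog, config)
    if config.mortality_beta0 is None:
        is_ctrl = np.array([r.group == "control" for r in records])
        ref = linpred[is_ctrl] if is_ctrl.any() else linpred
        beta0 = calibrate_mortality_intercept(ref, config.control_death_fraction)
    else:
        beta0 = config.mortality_beta0
    p_death = expit(beta0 + linpred)
    died = rng.random(len(records)) < p_death
    return [replace(r, died_3y=bool(d)) for r, d in zip(records, died)]
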