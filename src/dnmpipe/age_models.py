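"""Parental-age regression of mutation counts and longevity models.

The count of DNMs in trio i is modeled as Poisson with per-site mean
beta_N * N_sites_i + beta_p * Z_p_i, where N_sites_i = 2 * C_i * G_i is
the diploid callable genome size and Z_p_i = N_sites_i * X_p_i folds the
paternal age into the exposure. Fitting with an identity link and no
intercept makes beta_N the per-site baseline rate and beta_p the per-site
per-year paternal age effect; beta_p times a diploid genome length is the
familiar "additional mutations per year of paternal age".

Two longevity models translate a reference-species fit (e.g. human) to a
target species (e.g. cat):

* total longevity — mutations accumulate with calendar age from birth, so
  the reference fit is evaluated at the target's calendar age;
* reproductive longevity — a fixed pre-puberty count plus accumulation
  only after sexual maturity, so species are compared at equal
  post-puberty elapsed time: the reference fit is evaluated at
  (age - puberty_target) + puberty_reference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .glm import PoissonIdentityFit, fit_poisson_identity
from .model import LongevityConfig, TrioRecord

log = logging.getLogger(__name__)


@dataclass
class AgeRegressionFit:
    """Coefficients of the no-intercept identity-link Poisson age model."""

    beta_N: float
    beta_p: float
    beta_m: Optional[float]
    cov: np.ndarray
    loglik: float
    n_obs: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def build_design(trios: Sequence[TrioRecord]) -> pd.DataFrame:
    """Design rows (y, N_sites, Z_p, Z_m) for the age regression.

    Trios without a recorded paternal age are dropped (with a log message);
    they still count toward rate aggregation, just not the regression.
    """
    rows, dropped = [], []
    for t in trios:
        if t.paternal_age is None:
            dropped.append(t.proband)
            continue
        n_sites = t.callable_diploid_sites
        rows.append(
            {
                "trio": t.proband,
                "y": t.n_mutations,
                "N_sites": n_sites,
                "Z_p": n_sites * t.paternal_age,
                "Z_m": n_sites * t.maternal_age if t.maternal_age is not None else np.nan,
                "X_p": t.paternal_age,
                "X_m": t.maternal_age,
            }
        )
    if dropped:
        log.info("excluded %d trio(s) without ages from regression: %s", len(dropped), dropped)
    if not rows:
        raise ValueError("no trios with recorded parental ages")
    return pd.DataFrame(rows)


def fit_identity_poisson(
    design: pd.DataFrame, include_maternal: bool = False
) -> AgeRegressionFit:
    """Fit the no-intercept identity-link Poisson age regression."""
    cols = ["N_sites", "Z_p"] + (["Z_m"] if include_maternal else [])
    sub = design.dropna(subset=cols)
    X = sub[cols].to_numpy(dtype=float)
    y = sub["y"].to_numpy(dtype=float)
    fit = fit_poisson_identity(X, y)
    return AgeRegressionFit(
        beta_N=float(fit.beta[0]),
        beta_p=float(fit.beta[1]) if len(fit.beta) > 1 else 0.0,
        beta_m=float(fit.beta[2]) if include_maternal else None,
        cov=fit.cov,
        loglik=fit.loglik,
        n_obs=fit.n_obs,
    )


def scale_effect(
    fit: AgeRegressionFit, diploid_genome_bp: float = 5e9, ci_z: float = 1.96
) -> tuple[float, tuple[float, float]]:
    """Paternal-age effect as total additional mutations per year.

    Multiplies the per-site coefficient beta_p by a diploid genome length
    (default 2 x 2.5 Gb) with a Wald interval from the coefficient SE.
    """
    se_p = math.sqrt(fit.cov[1, 1])
    eff = fit.beta_p * diploid_genome_bp
    half = ci_z * se_p * diploid_genome_bp
    return eff, (eff - half, eff + half)


def predict_rate_at_age(
    fit: AgeRegressionFit, age: float, ci_z: float = 1.96
) -> tuple[float, tuple[float, float]]:
    """Per-site per-generation rate beta_N + beta_p * age with a
    delta-method interval."""
    if age < 0:
        raise ValueError("age must be >= 0")
    g = np.array([1.0, age])
    rate = fit.beta_N + fit.beta_p * age
    var = float(g @ fit.cov[:2, :2] @ g)
    half = ci_z * math.sqrt(max(var, 0.0))
    return rate, (rate - half, rate + half)


@dataclass
class LongevityPrediction:
    age: float
    total_model_rate: float
    reproductive_model_rate: float
    extrapolated: bool


def longevity_predictions(
    fit_ref: AgeRegressionFit,
    ages: Sequence[float],
    cfg: Optional[LongevityConfig] = None,
) -> list[LongevityPrediction]:
    """Per-site rates predicted for target-species ages under both models.

    ``fit_ref`` was fitted on the reference species whose puberty age is
    ``cfg.puberty_age_reference``; ``ages`` are calendar ages in the target
    species. The total model evaluates the reference fit at the calendar
    age; the reproductive model at equal post-puberty elapsed time. Ages
    below the target's puberty age are flagged as extrapolated.
    """
    cfg = cfg or LongevityConfig()
    out = []
    for age in ages:
        mapped = (age - cfg.puberty_age_target) + cfg.puberty_age_reference
        out.append(
            LongevityPrediction(
                age=age,
                total_model_rate=predict_rate_at_age(fit_ref, age)[0],
                reproductive_model_rate=predict_rate_at_age(fit_ref, max(mapped, 0.0))[0],
                extrapolated=age < cfg.puberty_age_target,
            )
        )
    return out


def compare_models_residuals(
    observed: Sequence[tuple[float, float]],
    predictions: Sequence[LongevityPrediction],
) -> tuple[float, float]:
    """Paired t-test of absolute residuals: total vs reproductive model.

    ``observed`` is (age, observed per-site rate) per trio, matched by
    position with ``predictions``. A positive statistic means the total
    model's residuals are larger, i.e. the reproductive model fits better.
    """
    if len(observed) < 3 or len(observed) != len(predictions):
        raise ValueError("need >= 3 matched (observation, prediction) pairs")
    obs = np.array([r for _, r in observed], dtype=float)
    res_total = np.abs(obs - np.array([p.total_model_rate for p in predictions]))
    res_repro = np.abs(obs - np.array([p.reproductive_model_rate for p in predictions]))
    diff = res_total - res_repro
    if np.all(diff == 0.0):
        return 0.0, 1.0
    t, p = stats.ttest_rel(res_total, res_repro)
    return float(t), float(p)


def fit_phased_age_model(
    counts: Sequence[int],
    ages: Sequence[float],
    phased_fraction: float = 1.0,
) -> tuple[float, float, tuple[float, float]]:
    """Unadjusted per-parent regression on phased mutation counts.

    Fits count_i ~ Poisson(b0 + b1 * age_i) (identity link, intercept) and
    rescales the slope by the inverse phased fraction, since only that
    fraction of the true per-offspring mutations was assignable to the
    parent. Returns (b0, b1_rescaled, Wald 95% CI on the rescaled slope).
    """
    if not (0.0 < phased_fraction <= 1.0):
        raise ValueError("phased_fraction must be in (0, 1]")
    y = np.asarray(counts, dtype=float)
    X = np.column_stack([np.ones_like(y), np.asarray(ages, dtype=float)])
    fit = fit_poisson_identity(X, y)
    b0, b1 = fit.beta
    se1 = fit.se[1]
    b1s = b1 / phased_fraction
    half = 1.96 * se1 / phased_fraction
    return float(b0), float(b1s), (float(b1s - half), float(b1s + half))
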