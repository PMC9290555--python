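"""The mutation spectrum as a function of parental age.

The spectrum — the distribution of DNMs over the six strand-collapsed
substitution classes — is treated as a function-valued trait. For each
parent and class c, the per-offspring count is modeled as
N_c ~ Poisson(beta0_c + beta1_c * X), X the parent's age at conception
(identity link: coefficients are counts). Summing per-class predictions
over both parents and normalizing yields a predicted spectrum at any pair
of parental ages:

    f(X_mother, X_father) = (N_mother(X_mother) + N_father(X_father)) / total

A reference-species fit (e.g. a large human cohort, or its synthetic
surrogate) can then be read out at a target species' parental ages either
directly (total longevity) or shifted by the reference's time to puberty
(reproductive longevity), and compared with an observed spectrum via RMSE
with bootstrap confidence intervals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .glm import FitError, fit_poisson_identity
from .model import MUTATION_CLASSES

log = logging.getLogger(__name__)

PARENTS = ("paternal", "maternal")


@dataclass
class SpectrumClassFit:
    """Per-class linear Poisson coefficients for one parent."""

    parent: str
    coef: dict[str, tuple[float, float]]  # class -> (beta0, beta1)
    se: dict[str, tuple[float, float]]
    n_probands: int

    def predicted_counts(self, age: float) -> np.ndarray:
        """Predicted per-class counts at one parental age (floored at 0)."""
        out = np.array([self.coef[c][0] + self.coef[c][1] * age for c in MUTATION_CLASSES])
        return np.maximum(out, 0.0)


@dataclass
class SpectrumPrediction:
    mother_age: float
    father_age: float
    counts: np.ndarray  # per-class, both parents summed
    f: np.ndarray  # normalized spectrum, sums to 1

    def as_dict(self) -> dict[str, float]:
        return dict(zip(MUTATION_CLASSES, self.f))


def _proband_class_counts(
    table: pd.DataFrame, parent: str, probands: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """(ages, counts[class]) arrays over all probands, zeros included."""
    age_col = "father_age" if parent == "paternal" else "mother_age"
    sub = table[table["parent"] == parent]
    pivot = (
        sub.groupby(["proband", "class"]).size().unstack(fill_value=0)
        if len(sub)
        else pd.DataFrame()
    )
    counts = np.zeros((len(probands), len(MUTATION_CLASSES)), dtype=float)
    for j, cls in enumerate(MUTATION_CLASSES):
        if cls in getattr(pivot, "columns", []):
            counts[:, j] = (
                pivot[cls].reindex(probands["proband"]).fillna(0).to_numpy()
            )
    ages = probands[age_col].to_numpy(dtype=float)
    return ages, counts


def proband_frame(table: pd.DataFrame) -> pd.DataFrame:
    """Unique probands with their parental ages, derived from a DNM table."""
    return (
        table[["proband", "father_age", "mother_age"]]
        .drop_duplicates("proband")
        .reset_index(drop=True)
    )


def fit_class_regressions(
    table: pd.DataFrame, probands: Optional[pd.DataFrame] = None
) -> dict[str, SpectrumClassFit]:
    """Fit the 12 per-parent, per-class linear Poisson regressions.

    ``table`` has one row per phased mutation: proband, class, parent
    (paternal/maternal), father_age, mother_age. ``probands`` optionally
    supplies the proband universe (proband, father_age, mother_age) so that
    probands with zero mutations in a class — or zero mutations at all —
    contribute their zeros; by default it is derived from the table.
    Classes absent from the data get a zero fit with a warning.
    """
    if probands is None:
        probands = proband_frame(table)
    if len(probands) < 2:
        raise ValueError("need at least 2 probands")
    fits: dict[str, SpectrumClassFit] = {}
    for parent in PARENTS:
        ages, counts = _proband_class_counts(table, parent, probands)
        if np.unique(ages).size < 2:
            raise ValueError(f"need >= 2 distinct {parent} ages")
        X = np.column_stack([np.ones_like(ages), ages])
        coef: dict[str, tuple[float, float]] = {}
        se: dict[str, tuple[float, float]] = {}
        for j, cls in enumerate(MUTATION_CLASSES):
            y = counts[:, j]
            if y.sum() == 0:
                log.warning("class %s absent for %s parent; zero fit", cls, parent)
                coef[cls] = (0.0, 0.0)
                se[cls] = (0.0, 0.0)
                continue
            try:
                fit = fit_poisson_identity(X, y)
            except FitError as exc:
                raise FitError(f"class {cls} ({parent}): {exc}") from exc
            coef[cls] = (float(fit.beta[0]), float(fit.beta[1]))
            se[cls] = (float(fit.se[0]), float(fit.se[1]))
        fits[parent] = SpectrumClassFit(
            parent=parent, coef=coef, se=se, n_probands=len(probands)
        )
    return fits


def predict_spectrum(
    fits: dict[str, SpectrumClassFit], mother_age: float, father_age: float
) -> SpectrumPrediction:
    """Predicted spectrum at one pair of parental ages (sums to 1)."""
    counts = fits["paternal"].predicted_counts(father_age) + fits[
        "maternal"
    ].predicted_counts(mother_age)
    total = counts.sum()
    if total <= 0:
        raise ValueError("total predicted mutation count is not positive")
    return SpectrumPrediction(
        mother_age=mother_age, father_age=father_age, counts=counts, f=counts / total
    )


def longevity_spectrum(
    fits: dict[str, SpectrumClassFit],
    target_mother_age: float,
    target_father_age: float,
    model: str = "reproductive",
    shift_years: float = 13.0,
) -> SpectrumPrediction:
    """Spectrum predicted for a target species under a longevity model.

    ``total``: evaluate the reference fits at the target's calendar ages.
    ``reproductive``: shift both ages by the reference species' time to
    puberty (default 13 years), comparing at equal post-puberty time.
    """
    if model == "total":
        ma, fa = target_mother_age, target_father_age
    elif model == "reproductive":
        ma, fa = target_mother_age + shift_years, target_father_age + shift_years
    else:
        raise ValueError(f"model must be 'total' or 'reproductive', got {model!r}")
    return predict_spectrum(fits, ma, fa)


def spectrum_rmse(pred: SpectrumPrediction, observed_counts: dict[str, int]) -> float:
    """Root mean square error between predicted and observed spectra, in
    percentage points over the six classes."""
    obs = np.array([observed_counts.get(c, 0) for c in MUTATION_CLASSES], dtype=float)
    if obs.sum() <= 0:
        raise ValueError("observed spectrum has no mutations")
    p_hat = obs / obs.sum()
    return float(np.sqrt(np.mean((pred.f - p_hat) ** 2)) * 100.0)


def bootstrap_rmse_ci(
    table: pd.DataFrame,
    observed_counts: dict[str, int],
    target_mother_age: float,
    target_father_age: float,
    model: str = "reproductive",
    shift_years: float = 13.0,
    n_boot: int = 1000,
    seed: int = 0,
    probands: Optional[pd.DataFrame] = None,
) -> tuple[float, float, float]:
    """RMSE point estimate with a percentile bootstrap interval.

    Probands are resampled with replacement; all 12 regressions are refit
    per replicate and the RMSE to the observed spectrum recomputed. CI is
    the 2.5/97.5 percentile. Replicates whose refit fails are dropped and
    counted; more than 5% dropped is an error. Reproducible given ``seed``.
    """
    if probands is None:
        probands = proband_frame(table)
    fits = fit_class_regressions(table, probands)
    point = spectrum_rmse(
        longevity_spectrum(fits, target_mother_age, target_father_age, model, shift_years),
        observed_counts,
    )
    rng = np.random.default_rng(seed)
    vals = []
    dropped = 0
    n = len(probands)
    by_proband = {p: g for p, g in table.groupby("proband")}
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        resampled = probands.iloc[idx].reset_index(drop=True)
        # relabel so duplicated probands stay distinct observations
        new_ids = [f"b{k}" for k in range(n)]
        parts = []
        for new_id, orig in zip(new_ids, resampled["proband"]):
            g = by_proband.get(orig)
            if g is not None and len(g):
                gg = g.copy()
                gg.attrs = {}  # keep concat clear of unhashable attrs payloads
                gg["proband"] = new_id
                parts.append(gg)
        rtable = pd.concat(parts, ignore_index=True) if parts else table.iloc[0:0]
        rprobands = resampled.assign(proband=new_ids)
        try:
            rfits = fit_class_regressions(rtable, rprobands)
            pred = longevity_spectrum(
                rfits, target_mother_age, target_father_age, model, shift_years
            )
            vals.append(spectrum_rmse(pred, observed_counts))
        except (FitError, ValueError):
            dropped += 1
    if dropped > 0.05 * n_boot:
        raise FitError(f"{dropped}/{n_boot} bootstrap replicates failed to converge")
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return point, float(lo), float(hi)


def wilson_interval(k: int, n: int, z: float = 1.96) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion k/n.

    Better coverage than the Wald interval near 0 or 1; always within
    [0, 1] and always containing k/n.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    if not (0 <= k <= n):
        raise ValueError("require 0 <= k <= n")
    p = k / n
    denom = 1.0 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = (z / denom) * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n))
    return max(center - half, 0.0), min(center + half, 1.0)


def observed_spectrum_with_ci(
    counts: dict[str, int], z: float = 1.96
) -> pd.DataFrame:
    """Observed class proportions with Wilson 95% intervals (one row per
    class) — the tabular form behind a spectrum bar plot."""
    total = sum(counts.get(c, 0) for c in MUTATION_CLASSES)
    rows = []
    for c in MUTATION_CLASSES:
        k = counts.get(c, 0)
        lo, hi = wilson_interval(k, total, z)
        rows.append({"class": c, "count": k, "proportion": k / total, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)
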