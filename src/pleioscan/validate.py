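"""Cross-validation, Fisher's p-value combination, replication thresholds
and power analysis for the association scan.

Fisher's method combines k independent per-fold p-values as
``chi2 = -2 * sum(ln p)`` referred to a chi-square distribution with 2k
degrees of freedom.  Analytic power uses the variance-ratio normal
approximation for the logistic Wald test of an additive genotype
(predictor variance 2*maf*(1-maf) under Hardy-Weinberg), validated
against a Monte-Carlo oracle in :func:`empirical_power`.
"""

from __future__ import annotations

import logging
import sys
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

from .phecodes import CASE, CONTROL
from .scan import fit_logistic

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Folds and Fisher combination
# ---------------------------------------------------------------------------


def kfold_partition(person_ids: Sequence, k: int = 5, seed: int = 0) -> List[np.ndarray]:
    """Randomly partition persons into k disjoint folds of near-equal size.

    Fold sizes differ by at most one; the partition is fully determined
    by the seed.
    """
    ids = np.asarray(list(person_ids))
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(ids) < k:
        raise ValueError(f"need at least k={k} persons, have {len(ids)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    return [ids[chunk] for chunk in np.array_split(perm, k)]


def fisher_combine(p_values: Iterable[float]) -> Tuple[float, int, float]:
    """Combine independent p-values with Fisher's method.

    Returns ``(chi2, df, combined_p)`` with ``chi2 = -2 * sum(ln p)`` and
    ``df = 2k``.  Exact zeros are clamped to the smallest positive normal
    float with a warning (``-2 ln 0`` is infinite).
    """
    ps = np.asarray(list(p_values), dtype=float)
    if ps.size == 0:
        raise ValueError("cannot combine an empty list of p-values")
    if np.any((ps < 0) | (ps > 1)) or np.any(~np.isfinite(ps)):
        raise ValueError("p-values must lie in [0, 1]")
    n_zero = int((ps == 0).sum())
    if n_zero:
        logger.warning("clamping %d zero p-values to float minimum for Fisher's method", n_zero)
        ps = np.maximum(ps, sys.float_info.min)
    chi2 = float(-2.0 * np.sum(np.log(ps)))
    df = 2 * ps.size
    return chi2, df, float(chi2_dist.sf(chi2, df))


def replication_threshold(n_variants: int, alpha_base: float = 0.05) -> float:
    """Replication significance level alpha_base / (number of replicated variants)."""
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    return alpha_base / n_variants


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


def cross_validate(
    pairs: Sequence[Tuple[str, float]],
    dosages: pd.DataFrame,
    assignments: pd.DataFrame,
    covariates: pd.DataFrame,
    k: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Five-fold cross-validation of significant variant-phecode pairs.

    The cohort is partitioned at random into k folds; each fold is used
    once to test the association, and the per-fold p-values are combined
    with Fisher's method.  Folds where the fit fails (e.g. a single-class
    outcome in a small fold) have their p recorded missing and the
    degrees of freedom reduced accordingly.  With ``k=1`` the combined p
    equals the full-sample p.

    Returns one row per pair: fold p-values, Fisher chi2, df, combined p.
    """
    persons = assignments.index.to_numpy()
    folds = kfold_partition(persons, k, seed) if k >= 2 else [persons]
    rows = []
    for rsid, phecode in pairs:
        fold_ps: List[float] = []
        for fold in folds:
            status = assignments.loc[fold, phecode]
            mask = status.isin([CASE, CONTROL])
            sub = status[mask]
            y = (sub == CASE).astype(float).to_numpy()
            d = dosages.loc[sub.index, rsid].to_numpy()
            cov = covariates.loc[sub.index]
            try:
                f = fit_logistic(y, d, cov)
                fold_ps.append(f.p if f.converged else np.nan)
            except ValueError as exc:
                logger.warning("fold failed for %s x %s: %s", rsid, phecode, exc)
                fold_ps.append(np.nan)
        usable = [p for p in fold_ps if np.isfinite(p)]
        if usable:
            chi2, df, combined = fisher_combine(usable)
        else:
            chi2, df, combined = np.nan, 0, np.nan
        rows.append(
            dict(rsid=rsid, phecode=phecode, fold_p=fold_ps, chi2=chi2, df=df,
                 combined_p=combined, n_folds_used=len(usable))
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Power
# ---------------------------------------------------------------------------


@dataclass
class PowerSpec:
    """Design of a single variant-phecode power calculation."""

    n: int
    maf: float
    odds_ratio: float
    case_fraction: float
    alpha: float = 4.1e-5

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (0.0 < self.maf <= 0.5):
            raise ValueError("maf must be in (0, 0.5]")
        if self.odds_ratio <= 0:
            raise ValueError("odds_ratio must be > 0")
        if not (0.0 < self.case_fraction < 1.0):
            raise ValueError("case_fraction must be in (0, 1)")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")


def analytic_power(spec: PowerSpec) -> float:
    """Two-sided asymptotic power of the additive-dosage logistic Wald test.

    Normal approximation with noncentrality
    ``|ln OR| * sqrt(n * cf*(1-cf) * 2*maf*(1-maf))`` where cf is the
    case fraction; at OR = 1 this returns alpha exactly.
    """
    mu = abs(np.log(spec.odds_ratio)) * np.sqrt(
        spec.n * spec.case_fraction * (1.0 - spec.case_fraction)
        * 2.0 * spec.maf * (1.0 - spec.maf)
    )
    z = norm.isf(spec.alpha / 2.0)
    return float(norm.sf(z - mu) + norm.cdf(-z - mu))


def _solve_intercept(beta: float, maf: float, case_fraction: float) -> float:
    """Intercept giving the target marginal case fraction under HWE."""
    g = np.array([0.0, 1.0, 2.0])
    w = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])

    def marginal(b0: float) -> float:
        return float(np.sum(w * expit(b0 + beta * g)) - case_fraction)

    return brentq(marginal, -30.0, 30.0)


def empirical_power(
    spec: PowerSpec, n_reps: int = 500, seed: int = 0
) -> Tuple[float, Tuple[float, float]]:
    """Monte-Carlo power of the additive logistic Wald test.

    Genotypes are drawn under Hardy-Weinberg from the MAF, outcomes from
    the logistic model with intercept solved to hit the case fraction;
    each replicate fits the logistic regression (on genotype-level
    aggregated counts, which is sufficient for this model) and tests the
    slope at ``alpha``.  Returns the rejection proportion and its exact
    (Clopper-Pearson) 95% binomial confidence interval.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    rng = np.random.default_rng(seed)
    beta = float(np.log(spec.odds_ratio))
    b0 = _solve_intercept(beta, spec.maf, spec.case_fraction)
    g_levels = np.array([0.0, 1.0, 2.0])
    probs_g = np.array([(1 - spec.maf) ** 2, 2 * spec.maf * (1 - spec.maf), spec.maf**2])
    p_case = expit(b0 + beta * g_levels)
    X = sm.add_constant(pd.DataFrame({"dosage": g_levels}), has_constant="add")

    rejections = 0
    for _ in range(n_reps):
        n_g = rng.multinomial(spec.n, probs_g)
        cases = rng.binomial(n_g, p_case)
        present = n_g > 0
        if present.sum() < 2:
            continue
        endog = np.column_stack([cases[present], n_g[present] - cases[present]])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(endog, X[present], family=sm.families.Binomial()).fit()
            if res.pvalues["dosage"] < spec.alpha:
                rejections += 1
        except Exception:  # degenerate replicate counts as a non-rejection
            continue

    est = rejections / n_reps
    ci = sm.stats.proportion_confint(rejections, n_reps, alpha=0.05, method="beta")
    return est, (float(ci[0]), float(ci[1]))
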