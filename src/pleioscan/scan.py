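"""The per-variant x per-phecode logistic association scan.

The core object is :class:`PhewasScan`, a model built from phecode
case/control assignments, genotype dosages and a covariate frame; its
:meth:`~PhewasScan.fit` returns a :class:`PhewasResults` carrying one
row per (variant, phecode) pair with the additive-model log-odds beta,
SE, odds ratio, Wald p-value and case/control counts, plus a
``summary()`` table and Bonferroni-thresholded hit selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .config import PipelineConfig
from .phecodes import CASE, CONTROL

logger = logging.getLogger(__name__)


@dataclass
class LogisticFit:
    """One maximum-likelihood logistic fit of outcome on dosage."""

    beta: float
    se: float
    p: float
    odds_ratio: float
    converged: bool
    separated: bool
    n_case: int
    n_control: int


def fit_logistic(
    outcome: np.ndarray,
    dosage: np.ndarray,
    covariates: Optional[pd.DataFrame] = None,
    maxiter: int = 100,
    use_lrt: bool = False,
) -> LogisticFit:
    """Additive-model logistic regression with a Wald test on dosage.

    Non-convergence and complete separation are flagged (p set to NaN),
    never silently reported as significant.  ``use_lrt`` swaps the Wald
    p-value for a likelihood-ratio test against the dosage-free model.
    """
    y = np.asarray(outcome, dtype=float)
    d = np.asarray(dosage, dtype=float)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("outcome has a single class; logistic fit impossible")
    if not np.all(np.isin(classes, [0.0, 1.0])):
        raise ValueError("outcome must be binary 0/1")
    X = pd.DataFrame({"dosage": d})
    if covariates is not None:
        X = pd.concat([X.reset_index(drop=True), covariates.reset_index(drop=True)], axis=1)
    X = sm.add_constant(X, has_constant="add")
    n_case = int(y.sum())
    n_control = int(len(y) - n_case)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=maxiter, warn_convergence=False)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return LogisticFit(np.nan, np.nan, np.nan, np.nan, False, True, n_case, n_control)

    beta = float(res.params["dosage"])
    se = float(res.bse["dosage"])
    converged = bool(res.mle_retvals.get("converged", False))
    # quasi-separation: runaway coefficient or exploding SE
    separated = (not np.isfinite(se)) or se > 1e3 or abs(beta) > 15.0
    if separated or not converged:
        return LogisticFit(beta, se, np.nan, np.nan, False, separated, n_case, n_control)
    if use_lrt:
        reduced = sm.Logit(y, X.drop(columns="dosage")).fit(disp=0, maxiter=maxiter)
        from scipy.stats import chi2

        lr = 2.0 * (res.llf - reduced.llf)
        p = float(chi2.sf(max(lr, 0.0), 1))
    else:
        p = float(res.pvalues["dosage"])
    return LogisticFit(beta, se, p, float(np.exp(beta)), True, False, n_case, n_control)


def bonferroni_threshold(n_phecodes: int, alpha_base: float = 0.05) -> float:
    """Family-wise significance level alpha_base / (number of tested phecodes)."""
    if n_phecodes < 1:
        raise ValueError("n_phecodes must be >= 1")
    return alpha_base / n_phecodes


def significant_hits(results: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Converged rows with p strictly below alpha, sorted ascending by p."""
    if results.empty:
        return results
    hits = results[(results["converged"]) & (results["p"] < alpha)]
    return hits.sort_values("p", kind="stable")


def build_covariates(
    median_event_age: pd.Series,
    demographics: pd.DataFrame,
    pcs: pd.DataFrame,
    include_site: bool = False,
) -> pd.DataFrame:
    """Assemble the scan covariate frame: median event age, sex, PCs and
    (optionally) reference-coded site indicator columns."""
    cov = pd.DataFrame({"median_event_age": median_event_age, "sex": demographics["sex"]})
    cov = cov.join(pcs)
    if include_site:
        dummies = pd.get_dummies(demographics["site"], prefix="site", drop_first=True)
        cov = cov.join(dummies.astype(float))
    return cov


class PhewasScan:
    """Model object for the variant x phecode association scan.

    Parameters
    ----------
    dosages : person x rsid dosage matrix (alt-allele dosage in [0, 2]).
    assignments : person x phecode status matrix (1 case, 0 control,
        negative codes excluded); only persons present here are scanned.
    covariates : person-indexed frame (median event age, sex, PCs, ...).
    phecodes, variants : optional restriction of the scan grid; defaults
        to every assignment column / dosage column.
    config : thresholds, used for the Bonferroni base level.
    """

    def __init__(
        self,
        dosages: pd.DataFrame,
        assignments: pd.DataFrame,
        covariates: pd.DataFrame,
        phecodes: Optional[Sequence] = None,
        variants: Optional[Sequence[str]] = None,
        config: Optional[PipelineConfig] = None,
    ):
        self.config = config or PipelineConfig()
        self.phecodes = list(phecodes) if phecodes is not None else list(assignments.columns)
        self.variants = list(variants) if variants is not None else list(dosages.columns)
        persons = assignments.index
        self.assignments = assignments
        self.dosages = dosages.reindex(persons)
        self.covariates = covariates.reindex(persons)
        if self.covariates.isna().any().any():
            raise ValueError("missing covariate values among scanned persons")

    def fit(self, use_lrt: bool = False) -> "PhewasResults":
        """Fit one logistic model per (variant, phecode) pair.

        Excluded persons are removed per phecode before fitting; a failed
        or separated fit is flagged in its row, never aborts the scan.
        """
        rows = []
        for ph in self.phecodes:
            status = self.assignments[ph]
            mask = status.isin([CASE, CONTROL]).to_numpy()
            y = (status.to_numpy()[mask] == CASE).astype(float)
            cov = self.covariates.loc[mask]
            for rsid in self.variants:
                d = self.dosages[rsid].to_numpy()[mask]
                try:
                    f = fit_logistic(y, d, cov, use_lrt=use_lrt)
                except ValueError as exc:
                    logger.warning("skipping %s x %s: %s", rsid, ph, exc)
                    f = LogisticFit(np.nan, np.nan, np.nan, np.nan, False, False,
                                    int(y.sum()), int(len(y) - y.sum()))
                rows.append(
                    dict(rsid=rsid, phecode=ph, n_case=f.n_case, n_control=f.n_control,
                         beta=f.beta, se=f.se, odds_ratio=f.odds_ratio, p=f.p,
                         converged=f.converged, separated=f.separated)
                )
        results = pd.DataFrame(rows)
        return PhewasResults(self, results)


class PhewasResults:
    """Fitted scan results: one row per (variant, phecode) pair."""

    def __init__(self, model: PhewasScan, results: pd.DataFrame):
        self.model = model
        self.results = results

    @property
    def n_phecodes(self) -> int:
        return len(self.model.phecodes)

    @property
    def bonferroni_alpha(self) -> float:
        return bonferroni_threshold(self.n_phecodes, self.model.config.alpha_base)

    def significant_hits(self, alpha: Optional[float] = None) -> pd.DataFrame:
        """Converged associations with p < alpha (default: Bonferroni)."""
        return significant_hits(self.results, self.bonferroni_alpha if alpha is None else alpha)

    def summary(self) -> str:
        n_conv = int(self.results["converged"].sum())
        alpha = self.bonferroni_alpha
        hits = self.significant_hits()
        lines = [
            "PheWAS scan results",
            "===================",
            f"variants tested:   {len(self.model.variants)}",
            f"phecodes tested:   {self.n_phecodes}",
            f"pairs fitted:      {len(self.results)} ({n_conv} converged)",
            f"Bonferroni alpha:  {alpha:.3e}",
            f"significant hits:  {len(hits)}",
        ]
        if len(hits):
            lines.append("")
            lines.append(
                hits[["rsid", "phecode", "n_case", "n_control", "odds_ratio", "p"]]
                .to_string(index=False, float_format=lambda v: f"{v:.4g}")
            )
        return "\n".join(lines)


def run_phewas(
    dosages: pd.DataFrame,
    assignments: pd.DataFrame,
    covariates: pd.DataFrame,
    phecodes: Optional[Sequence] = None,
    variants: Optional[Sequence[str]] = None,
    config: Optional[PipelineConfig] = None,
) -> PhewasResults:
    """Functional front door: build a :class:`PhewasScan` and fit it."""
    return PhewasScan(dosages, assignments, covariates, phecodes, variants, config).fit()


def adjusted_association(
    dosage: pd.Series,
    outcome: pd.Series,
    adjuster: pd.Series,
    covariates: Optional[pd.DataFrame] = None,
) -> LogisticFit:
    """Logistic association of outcome on dosage with one extra adjuster.

    The adjuster is either a binary phecode status or a continuous LDL-C
    level; adjusting an outcome for itself is rejected, and a constant
    adjuster is dropped with a warning.
    """
    df = pd.DataFrame({"dosage": dosage, "outcome": outcome, "adjuster": adjuster}).dropna()
    if df["outcome"].equals(df["adjuster"]):
        raise ValueError("cannot adjust an outcome for itself")
    cov = covariates.reindex(df.index) if covariates is not None else pd.DataFrame(index=df.index)
    if df["adjuster"].nunique() <= 1:
        logger.warning("constant adjuster dropped from the model")
    else:
        cov = cov.copy()
        cov["adjuster"] = df["adjuster"]
    return fit_logistic(df["outcome"].to_numpy(), df["dosage"].to_numpy(), cov)
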