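"""LDL-C phenotype preparation, covariate PCs and the variant-selection cascades.

The primary cascade keeps variants that lie inside the PCSK9/APOB/LDLR
gene boundaries, have imputation r^2 > 0.4 and MAF > 1%, are associated
with LDL-C at genome-wide significance (p < 5e-8), and survive greedy LD
pruning at r^2 < 0.3 with the strongest LDL-C association retained per
linked group.  The secondary cascade instead keeps missense variants NOT
associated with LDL-C.  LD r^2 throughout is squared Pearson correlation
of dosages (genotypic r^2).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import GENE_REGIONS, GeneRegion, PipelineConfig

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# LDL-C phenotype
# ---------------------------------------------------------------------------


def prepare_ldl(measurements: pd.DataFrame, factor: float = 0.75) -> pd.Series:
    """Per-person adjusted LDL-C in mg/dL.

    If a person has any pre-treatment (off-LLM) measurements, their
    adjusted LDL-C is the median of those; otherwise the median of the
    on-treatment measurements divided by ``factor`` (default 0.75,
    back-correcting the assumed 25% statin reduction).  Non-positive
    values are rejected with a warning; persons with no usable
    measurements are absent from the result.
    """
    meas = measurements.copy()
    bad = meas["value"] <= 0
    if bad.any():
        logger.warning("rejecting %d non-positive LDL-C measurements", int(bad.sum()))
        meas = meas[~bad]
    if meas.empty:
        return pd.Series(dtype=float, name="ldl_adj")
    pre = meas[meas["on_llm"] == 0].groupby("person")["value"].median()
    on = meas[meas["on_llm"] != 0].groupby("person")["value"].median() / factor
    only_on = on.index.difference(pre.index)
    out = pd.concat([pre, on.loc[only_on]]).sort_index()
    out.name = "ldl_adj"
    out.index.name = "person"
    return out


# ---------------------------------------------------------------------------
# Relatedness pruning
# ---------------------------------------------------------------------------


def prune_relatives(
    pairs: pd.DataFrame,
    cohort: Iterable,
    threshold: float = 0.5,
    seed: int = 0,
) -> pd.Index:
    """Randomly drop one member of every related pair with pi-hat >= threshold.

    Pair order is shuffled with the seed; each flagged pair still intact
    loses one member at random, which cascades over the relatedness graph
    until no retained pair exceeds the threshold.  Returns the retained
    person index.
    """
    cohort = pd.Index(cohort)
    retained = set(cohort)
    flagged = pairs[pairs["pi_hat"] >= threshold]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(flagged))
    rows = flagged.iloc[order]
    for a, b in zip(rows["person_a"], rows["person_b"]):
        if a in retained and b in retained:
            retained.discard(a if rng.random() < 0.5 else b)
    return cohort[cohort.isin(retained)]


# ---------------------------------------------------------------------------
# Principal components
# ---------------------------------------------------------------------------


def compute_pcs(dosages: pd.DataFrame, n_pcs: int = 2) -> Tuple[pd.DataFrame, np.ndarray]:
    """Ancestry principal components from standardised dosages.

    Columns are centred at 2p and scaled by sqrt(2p(1-p)) with p the alt
    allele frequency (the usual genotype standardisation); scores come
    from the SVD of the standardised matrix.  Returns ``(scores,
    variance_explained)`` with one PC column per component.
    """
    X = dosages.to_numpy(dtype=float)
    p = X.mean(axis=0) / 2.0
    var = 2.0 * p * (1.0 - p)
    keep = (var > 0) & (X.std(axis=0) > 0)
    if keep.sum() < n_pcs:
        raise ValueError(
            f"need >= {n_pcs} variants with nonzero variance, have {int(keep.sum())}"
        )
    Z = (X[:, keep] - 2.0 * p[keep]) / np.sqrt(var[keep])
    U, S, _ = np.linalg.svd(Z, full_matrices=False)
    scores = U[:, :n_pcs] * S[:n_pcs]
    # sign convention: largest-magnitude loading positive, for determinism
    for j in range(n_pcs):
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    explained = (S**2) / np.sum(S**2)
    cols = [f"PC{j + 1}" for j in range(n_pcs)]
    return pd.DataFrame(scores, index=dosages.index, columns=cols), explained[:n_pcs]


# ---------------------------------------------------------------------------
# LDL-C association
# ---------------------------------------------------------------------------


@dataclass
class LdlAssociation:
    """OLS additive-model LDL-C association for one variant."""

    beta: float
    se: float
    p: float
    n: int
    estimable: bool = True


def ldl_association(
    dosage: pd.Series,
    ldl: pd.Series,
    covariates: Optional[pd.DataFrame] = None,
    min_n: int = 30,
) -> LdlAssociation:
    """Per-alt-allele OLS effect of dosage on adjusted LDL-C (mg/dL).

    Covariates (age, sex, LLM status, PCs) enter additively; the Wald
    p-value is on the dosage coefficient.  Rank-deficient designs are
    flagged non-estimable rather than silently reported.
    """
    df = pd.DataFrame({"dosage": dosage, "ldl": ldl})
    if covariates is not None:
        df = df.join(covariates, how="inner")
    df = df.dropna()
    if len(df) < min_n:
        raise ValueError(f"need >= {min_n} complete observations, have {len(df)}")
    X = sm.add_constant(df.drop(columns="ldl"), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        logger.warning("rank-deficient LDL design; association not estimable")
        return LdlAssociation(np.nan, np.nan, np.nan, len(df), estimable=False)
    res = sm.OLS(df["ldl"], X).fit()
    return LdlAssociation(
        beta=float(res.params["dosage"]),
        se=float(res.bse["dosage"]),
        p=float(res.pvalues["dosage"]),
        n=int(res.nobs),
    )


def ldl_scan(
    dosages: pd.DataFrame,
    ldl: pd.Series,
    covariates: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Run :func:`ldl_association` for every variant; one row per rsid."""
    rows = {}
    for rsid in dosages.columns:
        a = ldl_association(dosages[rsid], ldl, covariates)
        rows[rsid] = dict(beta=a.beta, se=a.se, p=a.p, n=a.n, estimable=a.estimable)
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "rsid"
    return out


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------


def pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Raises for constant vectors, where LD is undefined.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors differ in length")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("LD r2 undefined for a constant dosage vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _r2_matrix(dosages: pd.DataFrame, rsids: Sequence[str]) -> np.ndarray:
    X = dosages[list(rsids)].to_numpy(dtype=float)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        const = [r for r, s in zip(rsids, sd) if s == 0]
        raise ValueError(f"constant dosage for {const}; LD undefined")
    C = np.corrcoef(X, rowvar=False)
    C = np.atleast_2d(C)
    return C * C


# ---------------------------------------------------------------------------
# Selection cascades
# ---------------------------------------------------------------------------


def recompute_maf(dosages: pd.DataFrame) -> pd.Series:
    """Alt-allele frequency folded at 0.5, recomputed from dosages."""
    p = dosages.mean(axis=0) / 2.0
    return np.minimum(p, 1.0 - p).rename("maf")


def _in_any_region(variants: pd.DataFrame, regions: Dict[str, GeneRegion]) -> pd.Series:
    inside = pd.Series(False, index=variants.index)
    for region in regions.values():
        inside |= (variants["chrom"].astype(str) == region.chrom) & variants["pos"].between(
            region.start, region.end
        )
    return inside


def _cascade(
    variants: pd.DataFrame,
    dosages: pd.DataFrame,
    ldl_stats: pd.DataFrame,
    regions: Dict[str, GeneRegion],
    config: PipelineConfig,
    *,
    missense_only: bool,
    ldl_associated: bool,
) -> Tuple[List[str], pd.DataFrame]:
    """Shared filter cascade; returns (selected rsids, audit table)."""
    audit = pd.DataFrame(index=variants.index)
    audit.index.name = "rsid"
    maf = recompute_maf(dosages[variants.index])

    audit["in_region"] = _in_any_region(variants, regions)
    audit["imputation_ok"] = variants["imputation_r2"] > config.imputation_r2_min
    audit["maf_ok"] = maf > config.maf_min
    p = ldl_stats["p"].reindex(variants.index)
    if ldl_associated:
        audit["ldl_ok"] = p < config.ldl_p_max
    else:
        audit["ldl_ok"] = ~(p < config.ldl_p_max)  # not significantly associated
    if missense_only:
        audit["annotation_ok"] = variants["annotation"].str.lower() == "missense"
    else:
        audit["annotation_ok"] = True
    pre_ld = audit.all(axis=1)

    # greedy LD pruning: strongest LDL-C association first, ties by rsid
    order = (
        pd.DataFrame({"p": p[pre_ld].to_numpy(), "rsid": p[pre_ld].index.to_numpy()})
        .sort_values(["p", "rsid"], kind="stable")["rsid"]
        .tolist()
    )
    selected: List[str] = []
    ld_pass = pd.Series(False, index=variants.index)
    for rsid in order:
        ok = all(
            pairwise_r2(dosages[rsid].to_numpy(), dosages[kept].to_numpy()) < config.ld_r2_max
            for kept in selected
        )
        if ok:
            selected.append(rsid)
            ld_pass[rsid] = True
    audit["ld_ok"] = ld_pass
    audit["selected"] = pre_ld & ld_pass
    audit["maf"] = maf
    audit["ldl_p"] = p
    return selected, audit


def select_primary_variants(
    variants: pd.DataFrame,
    dosages: pd.DataFrame,
    ldl_stats: pd.DataFrame,
    regions: Optional[Dict[str, GeneRegion]] = None,
    config: Optional[PipelineConfig] = None,
) -> Tuple[List[str], pd.DataFrame]:
    """Primary cascade: LDL-C-associated variants inside the gene regions.

    Order of filters: gene boundary (1-based inclusive) -> imputation
    r^2 > 0.4 -> MAF > 1% -> LDL-C p < 5e-8 -> greedy LD pruning keeping,
    within any linked group, the variant with the strongest LDL-C
    association.  An empty result is valid.  Returns ``(selected rsids,
    audit table)`` with per-stage pass/fail flags.
    """
    regions = regions or GENE_REGIONS
    config = config or PipelineConfig()
    return _cascade(
        variants, dosages, ldl_stats, regions, config,
        missense_only=False, ldl_associated=True,
    )


def select_secondary_variants(
    variants: pd.DataFrame,
    dosages: pd.DataFrame,
    ldl_stats: pd.DataFrame,
    regions: Optional[Dict[str, GeneRegion]] = None,
    config: Optional[PipelineConfig] = None,
) -> Tuple[List[str], pd.DataFrame]:
    """Secondary cascade: missense variants NOT associated with LDL-C.

    Same filters as the primary cascade but requires annotation
    "missense" and LDL-C p >= the genome-wide threshold.
    """
    regions = regions or GENE_REGIONS
    config = config or PipelineConfig()
    return _cascade(
        variants, dosages, ldl_stats, regions, config,
        missense_only=True, ldl_associated=False,
    )


# ---------------------------------------------------------------------------
# LD group dissection
# ---------------------------------------------------------------------------


def ld_group(
    dosages: pd.DataFrame,
    index_variant: str,
    candidates: Optional[Sequence[str]] = None,
    r2_link: float = 0.3,
    r2_tight: float = 0.98,
) -> pd.DataFrame:
    """Variants linked to an index variant, partitioned into tight groups.

    Returns the candidates with r^2 > ``r2_link`` to the index variant,
    with their r^2 to the index and a ``group`` id from single-linkage
    clustering (connected components) at r^2 > ``r2_tight``.  The index
    variant itself is not part of the returned set.
    """
    if candidates is None:
        candidates = [c for c in dosages.columns if c != index_variant]
    if index_variant not in dosages.columns:
        raise KeyError(f"index variant {index_variant} not in dosage matrix")
    idx_vec = dosages[index_variant].to_numpy(dtype=float)
    if np.ptp(idx_vec) == 0:
        raise ValueError("index variant has constant dosage")
    linked = [c for c in candidates if pairwise_r2(idx_vec, dosages[c].to_numpy()) > r2_link]
    if not linked:
        return pd.DataFrame(columns=["r2_to_index", "group"])
    R2 = _r2_matrix(dosages, linked)
    # single-linkage at r2 > r2_tight == connected components of the graph
    k = len(linked)
    group = -np.ones(k, dtype=int)
    g = 0
    for i in range(k):
        if group[i] >= 0:
            continue
        stack = [i]
        group[i] = g
        while stack:
            u = stack.pop()
            for v in range(k):
                if group[v] < 0 and R2[u, v] > r2_tight:
                    group[v] = g
                    stack.append(v)
        g += 1
    out = pd.DataFrame(
        {
            "r2_to_index": [pairwise_r2(idx_vec, dosages[c].to_numpy()) for c in linked],
            "group": group,
        },
        index=pd.Index(linked, name="rsid"),
    )
    return out.sort_values(["group", "r2_to_index"], ascending=[True, False], kind="stable")
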