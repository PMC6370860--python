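"""Shared fixtures: small cohorts, the null-cohort scan and the
parameter-recovery pipeline run (session-scoped, they are the expensive
simulations several test modules interrogate)."""

import numpy as np
import pandas as pd
import pytest

import pleioscan as ps
from pleioscan import phecodes as ph
from pleioscan import scan as sc
from pleioscan import selection as sel


@pytest.fixture(scope="session")
def small_cohort():
    """Reference study design at n=1200: all tables populated."""
    cfg = ps.default_simulation_config(n_individuals=1200, seed=11)
    return ps.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_scan():
    """Scan of 10 variants against 200 genuinely null phecodes (n=5000).

    Returns (results_frame, n_phecodes): every p-value should behave like
    a Uniform(0, 1) draw.
    """
    cfg = ps.null_simulation_config(
        n_individuals=5000, n_phecodes=200, n_variants=10, seed=0
    )
    cohort = ps.simulate_cohort(cfg)
    counts = ph.map_icd_to_phecodes(cohort.events, cohort.phecode_map)
    asg = ph.assign_case_control(counts, cohort.phecode_map, cohort=cohort.dosages.index)
    asg = ph.filter_adults(asg, cohort.demographics, cohort.events)
    kept, _ = ph.filter_phecodes(asg, min_cases=200)
    persons = asg.index
    pcs, _ = sel.compute_pcs(cohort.dosages.loc[persons])
    ages = ph.median_event_ages(cohort.events, cohort.demographics.loc[persons])
    cov = sc.build_covariates(ages, cohort.demographics.loc[persons], pcs)
    results = sc.PhewasScan(
        cohort.dosages.loc[persons], asg[kept], cov,
        phecodes=kept, variants=list(cohort.dosages.columns),
    ).fit()
    return results.results, len(kept)


@pytest.fixture(scope="session")
def recovery_run():
    """Full-scale (n=5e4) pipeline run on the recovery design.

    The design plants an LDL-C beta of -12.97 mg/dL on a MAF-0.10 variant
    and a pleiotropic odds ratio of 1.5 on one phecode.
    Returns (cohort, pipeline_output).
    """
    cfg = ps.recovery_simulation_config(n_individuals=50_000, seed=1)
    cohort = ps.simulate_cohort(cfg)
    out = ps.run_pipeline(cohort)
    return cohort, out


@pytest.fixture(scope="session")
def null_cv_pvalues():
    """Fisher-combined five-fold cross-validation p-values for a null
    variant-phecode pair across 200 seeds."""
    from pleioscan import cross_validate

    combined = []
    for seed in range(200):
        rng = np.random.default_rng(seed)
        n = 600
        dosages = pd.DataFrame({"rs1": rng.binomial(2, 0.3, n).astype(float)},
                               index=pd.RangeIndex(n, name="person"))
        asg = pd.DataFrame({101.1: rng.binomial(1, 0.3, n)}, index=dosages.index)
        cv = cross_validate([("rs1", 101.1)], dosages, asg,
                            pd.DataFrame(index=dosages.index), k=5, seed=seed)
        combined.append(cv.loc[0, "combined_p"])
    return np.asarray(combined)


@pytest.fixture()
def cascade_fixture():
    """Hand-built six-variant fixture for the selection cascade.

    Expected trace with default thresholds:
      v1  inside PCSK9, imp .9, MAF .2, p 1e-30  -> selected
      v2  inside PCSK9, imp .9, MAF .2, p 1e-20, r2(v1) ~ 1 -> LD-pruned
      v3  inside APOB,  imp .3                  -> fails imputation
      v4  inside APOB,  imp .9, MAF .005        -> fails MAF
      v5  inside LDLR,  imp .9, MAF .3, p 1e-3  -> fails LDL association
      v6  outside all regions                   -> fails gene boundary
    """
    rng = np.random.default_rng(42)
    n = 400
    v1 = rng.binomial(2, 0.2, n).astype(float)
    v2 = v1.copy()
    flip = rng.choice(n, 8, replace=False)      # a few flips, r2 stays ~0.9
    v2[flip] = rng.binomial(2, 0.2, 8)
    v3 = rng.binomial(2, 0.3, n).astype(float)
    v4 = np.zeros(n)
    v4[:2] = 1.0                                # MAF 0.0025
    v5 = rng.binomial(2, 0.3, n).astype(float)
    v6 = rng.binomial(2, 0.4, n).astype(float)
    dosages = pd.DataFrame(
        {"v1": v1, "v2": v2, "v3": v3, "v4": v4, "v5": v5, "v6": v6},
        index=pd.RangeIndex(n, name="person"),
    )
    variants = pd.DataFrame(
        {
            "chrom": ["1", "1", "2", "2", "19", "7"],
            "pos": [55505647, 55519015, 21233972, 21263900, 11202306, 1000],
            "annotation": ["missense", "intron", "missense", "missense",
                           "regulatory_intron", "intron"],
            "imputation_r2": [0.9, 0.9, 0.3, 0.9, 0.9, 0.9],
        },
        index=pd.Index([f"v{i}" for i in range(1, 7)], name="rsid"),
    )
    ldl_stats = pd.DataFrame(
        {"p": [1e-30, 1e-20, 1e-12, 1e-12, 1e-3, 1e-12],
         "beta": [-12.0, -11.0, -5.0, -5.0, -1.0, -5.0]},
        index=variants.index,
    )
    return dosages, variants, ldl_stats
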