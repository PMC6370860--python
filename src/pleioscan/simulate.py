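"""Synthetic genotype+EHR cohort generator with a ground-truth ledger.

The generator emits every input the PheWAS pipeline consumes — genotype
dosages with imputation-quality metadata, LDL-C measurements with
lipid-lowering-medication (LLM) flags, ICD-9 event streams driven by
phecode liabilities, demographics, a relatedness pair table and a
miniature ICD-9-to-phecode map — together with a :class:`TruthLedger`
recording the planted effects, so every downstream stage can be tested
for parameter recovery without any external data.

LD structure uses block-wise latent haplotype copying: haplotypes in a
block copy a shared latent allele with probability ``c = r2 ** 0.25``,
which for equal within-block allele frequencies gives pairwise dosage
correlation r^2 equal to the block target.  Dates are integer day
offsets from the epoch (year 2000); only distinct-date logic matters
downstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import (
    DAYS_PER_YEAR,
    EPOCH_YEAR,
    GENE_REGIONS,
    PhecodeSpec,
    SimulationConfig,
)

# Independent substreams per stage so output does not depend on call order.
_STREAM_GENO = 1
_STREAM_LDL = 2
_STREAM_ICD = 3
_STREAM_DEMO = 4

#: ICD-9 suffix cycle used when synthesising component codes for a family.
_SUFFIX_CYCLE = ["0", "4", "8", "2", "6", "1", "5", "9", "3", "7"]


@dataclass
class TruthLedger:
    """Ground truth planted into a synthetic cohort.

    ``variants`` has one row per simulated variant (target and realized
    MAF, true LDL-C beta); ``phecode_effects`` one row per planted
    (variant, phecode) odds ratio; ``related_pairs`` the planted
    first-degree pairs; ``latent_ldl`` each person's pre-treatment LDL-C;
    ``affection`` the true person x phecode disease status.
    """

    variants: pd.DataFrame
    phecode_effects: pd.DataFrame
    related_pairs: pd.DataFrame
    latent_ldl: pd.Series
    on_llm: pd.Series
    affection: pd.DataFrame


@dataclass
class SyntheticCohort:
    """All generated tables for one simulated cohort."""

    config: SimulationConfig
    dosages: pd.DataFrame          # person x rsid, values in [0, 2]
    variants: pd.DataFrame         # indexed by rsid
    measurements: pd.DataFrame     # person, date, value, on_llm
    events: pd.DataFrame           # person, code, date
    demographics: pd.DataFrame     # indexed by person: sex, birth_year, site
    relatedness: pd.DataFrame      # person_a, person_b, pi_hat
    phecode_map: pd.DataFrame      # icd9, phecode, exclusion_low, exclusion_high
    truth: TruthLedger


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def simulate_genotypes(
    config: SimulationConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate LD-blocked genotype dosages.

    Returns ``(dosages, variants, relatedness)``: an n x m dosage matrix
    (row per person, column per rsid, entries 0/1/2), a variant table
    carrying positions inside the gene boundaries, annotations, emitted
    imputation r^2 and both target and realized MAF, and the planted
    first-degree relatedness pairs with noisy IBD pi-hat near 0.5.
    """
    if not config.variant_specs:
        raise ValueError("no variant_specs in config")
    rng = _rng(config, _STREAM_GENO)
    n = config.n_individuals
    specs = config.variant_specs
    m = len(specs)

    haps = np.empty((2 * n, m), dtype=np.int8)
    blocks: Dict[str, List[int]] = {}
    for j, spec in enumerate(specs):
        blocks.setdefault(spec.ld_block, []).append(j)

    for block, idx in blocks.items():
        ps = np.array([specs[j].maf for j in idx])
        if len(idx) == 1:
            haps[:, idx[0]] = rng.random(2 * n) < ps[0]
            continue
        r2 = config.ld_block_r2.get(block, 0.8)
        c = r2 ** 0.25
        q = float(ps.mean())
        latent = rng.random(2 * n) < q
        for p_j, j in zip(ps, idx):
            copy = rng.random(2 * n) < c
            fresh = rng.random(2 * n) < p_j
            haps[:, j] = np.where(copy, latent, fresh)

    # Plant first-degree (parent -> child) pairs: the child's first
    # haplotype is a per-locus transmission from the parent's genotype.
    pairs: List[Tuple[int, int, float]] = []
    if config.n_related_pairs > 0:
        people = rng.choice(n, size=2 * config.n_related_pairs, replace=False)
        for k in range(config.n_related_pairs):
            parent, child = int(people[2 * k]), int(people[2 * k + 1])
            pick = rng.random(m) < 0.5
            haps[2 * child] = np.where(pick, haps[2 * parent], haps[2 * parent + 1])
            pi_hat = float(np.clip(0.5 + rng.normal(0.0, 0.02), 0.0, 1.0))
            pairs.append((parent, child, pi_hat))

    dosages = pd.DataFrame(
        (haps[0::2] + haps[1::2]).astype(float),
        index=pd.RangeIndex(n, name="person"),
        columns=[s.rsid for s in specs],
    )

    variants = _variant_table(specs, dosages)
    relatedness = pd.DataFrame(pairs, columns=["person_a", "person_b", "pi_hat"])
    return dosages, variants, relatedness


def _variant_table(specs, dosages: pd.DataFrame) -> pd.DataFrame:
    rows = []
    per_gene: Dict[str, int] = {}
    counts: Dict[str, int] = {}
    for s in specs:
        counts[s.gene] = counts.get(s.gene, 0) + 1
    for s in specs:
        region = GENE_REGIONS[s.gene]
        i = per_gene.get(s.gene, 0)
        per_gene[s.gene] = i + 1
        span = region.end - region.start
        pos = region.start + int(round((i + 1) * span / (counts[s.gene] + 1)))
        alt_freq = float(dosages[s.rsid].mean() / 2.0)
        rows.append(
            dict(
                rsid=s.rsid,
                gene=s.gene,
                chrom=region.chrom,
                pos=pos,
                ref="G",
                alt="T",
                annotation=s.annotation,
                target_maf=s.maf,
                maf=min(alt_freq, 1.0 - alt_freq),
                imputation_r2=s.imputation_r2,
                ld_block=s.ld_block,
            )
        )
    return pd.DataFrame(rows).set_index("rsid")


# ---------------------------------------------------------------------------
# LDL-C measurements
# ---------------------------------------------------------------------------


def simulate_ldl(
    dosages: pd.DataFrame, config: SimulationConfig
) -> Tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Simulate LDL-C measurements (mg/dL) with LLM treatment flags.

    Latent pre-treatment LDL-C is ``intercept + sum(beta * dosage) +
    N(0, ldl_sd)`` per person.  A fraction ``llm_probability`` of persons
    is on lipid-lowering medication: all their measurements are scaled by
    ``llm_reduction`` (default 0.75, i.e. a 25% on-treatment drop) and
    flagged.  Every person receives at least one measurement.

    Returns ``(measurements, latent_ldl, on_llm)``.
    """
    rng = _rng(config, _STREAM_LDL)
    n = len(dosages)
    betas = np.array([s.ldl_beta for s in config.variant_specs])
    latent = (
        config.ldl_intercept
        + dosages.to_numpy() @ betas
        + rng.normal(0.0, config.ldl_sd, size=n)
    )
    on_llm = rng.random(n) < config.llm_probability

    lo, hi = config.measurements_range
    n_meas = rng.integers(lo, hi + 1, size=n)
    person = np.repeat(dosages.index.to_numpy(), n_meas)
    total = int(n_meas.sum())
    day_lo, day_hi = config.event_day_range
    dates = rng.integers(day_lo, day_hi + 1, size=total)
    values = latent[np.repeat(np.arange(n), n_meas)] + rng.normal(
        0.0, config.ldl_meas_sd, size=total
    )
    flags = on_llm[np.repeat(np.arange(n), n_meas)]
    values = np.where(flags, values * config.llm_reduction, values)

    measurements = pd.DataFrame(
        {"person": person, "date": dates, "value": values, "on_llm": flags.astype(int)}
    )
    latent_s = pd.Series(latent, index=dosages.index, name="latent_ldl")
    on_llm_s = pd.Series(on_llm, index=dosages.index, name="on_llm")
    return measurements, latent_s, on_llm_s


# ---------------------------------------------------------------------------
# Phecode map
# ---------------------------------------------------------------------------


def make_phecode_map(config: SimulationConfig) -> pd.DataFrame:
    """Build the miniature ICD-9 -> phecode map for the configured phecodes.

    Each phecode receives ``n_codes`` synthetic component ICD-9 codes named
    ``<family>.<suffix>`` with suffixes cycled within the integer family,
    so e.g. the first two-code phecode in family 272 owns "272.0" and
    "272.4".  Every ICD-9 code maps to exactly one phecode and every
    phecode's exclusion range contains itself.
    """
    rows = []
    family_counter: Dict[int, int] = {}
    seen: Dict[str, float] = {}
    for spec in config.phecode_specs:
        fam = int(spec.phecode)
        for _ in range(spec.n_codes):
            k = family_counter.get(fam, 0)
            family_counter[fam] = k + 1
            if k < len(_SUFFIX_CYCLE):
                suffix = _SUFFIX_CYCLE[k]
            else:  # very large families: two-digit suffixes
                suffix = f"{k:02d}"
            icd9 = f"{fam}.{suffix}"
            if icd9 in seen:
                raise ValueError(f"duplicate ICD-9 code generated: {icd9}")
            seen[icd9] = spec.phecode
            rows.append(
                dict(
                    icd9=icd9,
                    phecode=spec.phecode,
                    exclusion_low=spec.exclusion_low,
                    exclusion_high=spec.exclusion_high,
                )
            )
    return pd.DataFrame(rows, columns=["icd9", "phecode", "exclusion_low", "exclusion_high"])


# ---------------------------------------------------------------------------
# ICD-9 events and demographics
# ---------------------------------------------------------------------------


def simulate_icd_events(
    dosages: pd.DataFrame,
    config: SimulationConfig,
    phecode_map: Optional[pd.DataFrame] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate ICD-9 event streams and demographics.

    Per phecode, disease status is drawn from a logistic liability with
    the configured baseline prevalence and planted per-variant log-odds
    effects (dosages are mean-centred so the marginal prevalence stays at
    baseline).  Affected persons emit two component codes on distinct
    dates, except a ``single_code_noise_rate`` fraction who emit exactly
    one; a fraction of unaffected persons emit one code from a *different*
    phecode inside the exclusion range; a small fraction of everyone emits
    an unmapped wellness code.

    Returns ``(events, demographics, affection)``.
    """
    if phecode_map is None:
        phecode_map = make_phecode_map(config)
    rng = _rng(config, _STREAM_ICD)
    n = len(dosages)
    persons = dosages.index.to_numpy()
    day_lo, day_hi = config.event_day_range
    n_days = day_hi - day_lo + 1

    codes_by_phecode: Dict[float, List[str]] = {
        ph: grp["icd9"].tolist() for ph, grp in phecode_map.groupby("phecode")
    }

    ev_person: List[np.ndarray] = []
    ev_code: List[np.ndarray] = []
    ev_date: List[np.ndarray] = []
    affection_cols: Dict[float, np.ndarray] = {}

    d = dosages.to_numpy()
    centred = d - d.mean(axis=0, keepdims=True)
    col = {rsid: j for j, rsid in enumerate(dosages.columns)}

    for spec in config.phecode_specs:
        codes = codes_by_phecode.get(spec.phecode)
        if not codes:
            raise ValueError(f"phecode {spec.phecode} has no mapped ICD-9 codes")
        eta = np.full(n, logit(spec.prevalence))
        for rsid, orr in spec.effects.items():
            eta += np.log(orr) * centred[:, col[rsid]]
        affected = rng.random(n) < expit(eta)
        affection_cols[spec.phecode] = affected.astype(int)

        aff_idx = np.flatnonzero(affected)
        if aff_idx.size:
            single = rng.random(aff_idx.size) < config.single_code_noise_rate
            d1 = rng.integers(day_lo, day_hi + 1, size=aff_idx.size)
            # second date guaranteed distinct from the first
            d2 = day_lo + (d1 - day_lo + 1 + rng.integers(0, n_days - 1, size=aff_idx.size)) % n_days
            c1 = rng.choice(codes, size=aff_idx.size)
            c2 = rng.choice(codes, size=aff_idx.size)
            ev_person.append(persons[aff_idx])
            ev_code.append(c1)
            ev_date.append(d1)
            keep = ~single
            ev_person.append(persons[aff_idx[keep]])
            ev_code.append(c2[keep])
            ev_date.append(d2[keep])

        # exclusion-range noise: unaffected persons pick up one code of a
        # *sibling* phecode within the exclusion range (if any exists)
        related_codes = [
            c
            for ph, cs in codes_by_phecode.items()
            if ph != spec.phecode and spec.exclusion_low <= ph <= spec.exclusion_high
            for c in cs
        ]
        if related_codes and config.exclusion_code_rate > 0:
            unaff_idx = np.flatnonzero(~affected)
            hit = unaff_idx[rng.random(unaff_idx.size) < config.exclusion_code_rate]
            if hit.size:
                ev_person.append(persons[hit])
                ev_code.append(rng.choice(related_codes, size=hit.size))
                ev_date.append(rng.integers(day_lo, day_hi + 1, size=hit.size))

    if config.unmapped_code_rate > 0:
        hit = np.flatnonzero(rng.random(n) < config.unmapped_code_rate)
        if hit.size:
            ev_person.append(persons[hit])
            ev_code.append(np.full(hit.size, "V70.0"))
            ev_date.append(rng.integers(day_lo, day_hi + 1, size=hit.size))

    if ev_person:
        events = pd.DataFrame(
            {
                "person": np.concatenate(ev_person),
                "code": np.concatenate(ev_code),
                "date": np.concatenate(ev_date).astype(int),
            }
        ).sort_values(["person", "date"], kind="stable").reset_index(drop=True)
    else:
        events = pd.DataFrame(columns=["person", "code", "date"])

    affection = pd.DataFrame(affection_cols, index=dosages.index)
    demographics = _simulate_demographics(dosages, config)
    return events, demographics, affection


def _simulate_demographics(dosages: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    rng = _rng(config, _STREAM_DEMO)
    n = len(dosages)
    y_lo, y_hi = config.birth_year_range
    labels = [s[0] for s in config.sites]
    weights = np.array([s[1] for s in config.sites], dtype=float)
    weights = weights / weights.sum()
    return pd.DataFrame(
        {
            "sex": (rng.random(n) < config.female_fraction).astype(int),
            "birth_year": rng.integers(y_lo, y_hi + 1, size=n),
            "site": rng.choice(labels, size=n, p=weights),
        },
        index=dosages.index,
    )


# ---------------------------------------------------------------------------
# Full cohort
# ---------------------------------------------------------------------------


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate the full linked cohort plus its ground-truth ledger."""
    dosages, variants, relatedness = simulate_genotypes(config)
    phecode_map = make_phecode_map(config)
    measurements, latent_ldl, on_llm = simulate_ldl(dosages, config)
    events, demographics, affection = simulate_icd_events(dosages, config, phecode_map)

    truth_variants = variants[["gene", "target_maf", "maf"]].copy()
    truth_variants["ldl_beta"] = [s.ldl_beta for s in config.variant_specs]
    effects = [
        dict(phecode=ph.phecode, rsid=rsid, odds_ratio=orr)
        for ph in config.phecode_specs
        for rsid, orr in ph.effects.items()
    ]
    truth = TruthLedger(
        variants=truth_variants,
        phecode_effects=pd.DataFrame(effects, columns=["phecode", "rsid", "odds_ratio"]),
        related_pairs=relatedness.copy(),
        latent_ldl=latent_ldl,
        on_llm=on_llm,
        affection=affection,
    )
    return SyntheticCohort(
        config=config,
        dosages=dosages,
        variants=variants,
        measurements=measurements,
        events=events,
        demographics=demographics,
        relatedness=relatedness,
        phecode_map=phecode_map,
        truth=truth,
    )
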