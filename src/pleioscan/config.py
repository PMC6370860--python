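"""Configuration and study-design objects for the PheWAS pipeline.

The pipeline mirrors a gene-centred phenome-wide association study of
LDL-C-related variants in the three familial-hypercholesterolemia genes
*PCSK9*, *APOB* and *LDLR*: candidate variants are screened by imputation
quality, minor allele frequency, LDL-C association and linkage
disequilibrium, and the survivors are tested against ICD-9-derived phecode
case/control phenotypes with additive-model logistic regression.

Two configuration objects drive everything: :class:`PipelineConfig` holds
the analysis thresholds, and :class:`SimulationConfig` describes the
synthetic genotype+EHR cohort used to exercise the pipeline end to end.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

#: Day 0 of the synthetic event calendar corresponds to this year; event
#: dates are integer day offsets and ages are derived with 365-day years.
EPOCH_YEAR = 2000
DAYS_PER_YEAR = 365


@dataclass(frozen=True)
class GeneRegion:
    """A 1-based, both-ends-inclusive genomic interval for a gene (hg19)."""

    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"GeneRegion {self.gene}: start {self.start} > end {self.end}")

    def contains(self, chrom: str, pos: int) -> bool:
        return str(chrom) == self.chrom and self.start <= int(pos) <= self.end


#: NCBI hg19 gene boundaries used for the primary/secondary variant cascades.
GENE_REGIONS: Dict[str, GeneRegion] = {
    "PCSK9": GeneRegion("PCSK9", "1", 55505149, 55530526),
    "APOB": GeneRegion("APOB", "2", 21224301, 21266945),
    "LDLR": GeneRegion("LDLR", "19", 11200037, 11244506),
}


@dataclass
class PipelineConfig:
    """Thresholds for the variant-selection cascade and the phecode scan.

    Defaults are the study's stated criteria: imputation r^2 > 0.4,
    MAF > 1%, LDL-C association p < 5e-8, LD pruning at r^2 < 0.3,
    tight LD groups at r^2 > 0.98, >=200 cases per analyzed phecode,
    first-degree relatedness pruning at IBD pi-hat >= 0.5, on-statin
    LDL-C back-correction by /0.75, adults only (age > 18), and two
    ancestry principal components as covariates.
    """

    imputation_r2_min: float = 0.4
    maf_min: float = 0.01
    ldl_p_max: float = 5e-8
    ld_r2_max: float = 0.3
    ld_group_tight_r2: float = 0.98
    min_cases: int = 200
    ibd_threshold: float = 0.5
    llm_adjust_factor: float = 0.75
    adult_age_min: int = 18
    n_pcs: int = 2
    alpha_base: float = 0.05

    def __post_init__(self) -> None:
        for name, lo, hi in [
            ("imputation_r2_min", 0.0, 1.0),
            ("maf_min", 0.0, 0.5),
            ("ldl_p_max", 0.0, 1.0),
            ("ld_r2_max", 0.0, 1.0),
            ("ld_group_tight_r2", 0.0, 1.0),
            ("ibd_threshold", 0.0, 1.0),
            ("alpha_base", 0.0, 1.0),
        ]:
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if not (0.0 < self.llm_adjust_factor <= 1.0):
            raise ValueError("llm_adjust_factor must be in (0, 1]")
        if self.min_cases < 1 or self.n_pcs < 1:
            raise ValueError("min_cases and n_pcs must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown PipelineConfig keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class VariantSpec:
    """Ground-truth description of one simulated variant.

    ``ldl_beta`` is the additive per-alt-allele effect on LDL-C in mg/dL;
    ``ld_block`` groups variants that share a latent haplotype signal.
    """

    rsid: str
    gene: str
    maf: float
    ldl_beta: float = 0.0
    annotation: str = "intron"
    imputation_r2: float = 0.99
    ld_block: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"{self.rsid}: MAF {self.maf} outside (0, 0.5]")
        if not (0.0 <= self.imputation_r2 <= 1.0):
            raise ValueError(f"{self.rsid}: imputation r2 outside [0, 1]")
        if self.gene not in GENE_REGIONS:
            raise ValueError(f"{self.rsid}: unknown gene {self.gene!r}")
        if self.ld_block is None:
            self.ld_block = self.rsid


@dataclass
class PhecodeSpec:
    """Ground-truth description of one simulated phecode phenotype.

    ``effects`` maps rsid -> per-alt-allele odds ratio on liability; the
    exclusion range defaults to the phecode's integer family
    [floor(code), floor(code) + 0.99].
    """

    phecode: float
    prevalence: float
    effects: Dict[str, float] = field(default_factory=dict)
    label: str = ""
    n_codes: int = 2
    exclusion_low: Optional[float] = None
    exclusion_high: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError(f"phecode {self.phecode}: prevalence outside (0, 1)")
        if self.n_codes < 1:
            raise ValueError("n_codes must be >= 1")
        for rsid, orr in self.effects.items():
            if orr <= 0:
                raise ValueError(f"phecode {self.phecode}: OR for {rsid} must be > 0")
        fam = float(int(self.phecode))
        if self.exclusion_low is None:
            self.exclusion_low = fam
        if self.exclusion_high is None:
            self.exclusion_high = fam + 0.99
        if not (self.exclusion_low <= self.phecode <= self.exclusion_high):
            raise ValueError(
                f"phecode {self.phecode} outside its own exclusion range "
                f"[{self.exclusion_low}, {self.exclusion_high}]"
            )


@dataclass
class SimulationConfig:
    """Full description of the synthetic genotype+EHR cohort.

    The generator plants additive LDL-C effects (mg/dL), phecode-liability
    log-odds effects, LD-blocked genotypes, first-degree relative pairs and
    lipid-lowering-medication (LLM) treatment with a 25% on-treatment LDL-C
    reduction; the same seed reproduces the cohort byte for byte.
    """

    n_individuals: int = 5000
    seed: int = 0
    variant_specs: List[VariantSpec] = field(default_factory=list)
    ld_block_r2: Dict[str, float] = field(default_factory=dict)
    phecode_specs: List[PhecodeSpec] = field(default_factory=list)
    llm_probability: float = 0.237
    llm_reduction: float = 0.75
    n_related_pairs: int = 0
    sites: List[Tuple[str, float]] = field(
        default_factory=lambda: [("site_a", 0.4), ("site_b", 0.35), ("site_c", 0.25)]
    )
    single_code_noise_rate: float = 0.05
    exclusion_code_rate: float = 0.02
    unmapped_code_rate: float = 0.01
    ldl_intercept: float = 130.0
    ldl_sd: float = 30.0
    ldl_meas_sd: float = 5.0
    measurements_range: Tuple[int, int] = (1, 3)
    birth_year_range: Tuple[int, int] = (1920, 2000)
    event_day_range: Tuple[int, int] = (0, 4999)
    female_fraction: float = 0.54

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if not (0.0 < self.llm_reduction <= 1.0):
            raise ValueError("llm_reduction must be in (0, 1]")
        for name in ("llm_probability", "single_code_noise_rate",
                     "exclusion_code_rate", "unmapped_code_rate", "female_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_related_pairs < 0:
            raise ValueError("n_related_pairs must be >= 0")
        if 2 * self.n_related_pairs > self.n_individuals:
            raise ValueError("too many related pairs for cohort size")
        for blk, r2 in self.ld_block_r2.items():
            if not (0.0 <= r2 <= 1.0):
                raise ValueError(f"ld_block_r2[{blk}]={r2} outside [0, 1]")
        rsids = [v.rsid for v in self.variant_specs]
        if len(rsids) != len(set(rsids)):
            raise ValueError("duplicate rsids in variant_specs")
        known = set(rsids)
        for ph in self.phecode_specs:
            bad = set(ph.effects) - known
            if bad:
                raise ValueError(f"phecode {ph.phecode}: effects on unknown variants {sorted(bad)}")

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sites"] = [list(s) for s in self.sites]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["variant_specs"] = [VariantSpec(**v) for v in d.get("variant_specs", [])]
        d["phecode_specs"] = [PhecodeSpec(**p) for p in d.get("phecode_specs", [])]
        if "sites" in d:
            d["sites"] = [tuple(s) for s in d["sites"]]
        for key in ("measurements_range", "birth_year_range", "event_day_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Named study designs
# ---------------------------------------------------------------------------


def marker_variant_specs(k: int, prefix: str = "rs7") -> List[VariantSpec]:
    """LDL-neutral intronic marker variants spread across the three genes.

    Principal components are estimated from the full dosage matrix; with
    only a handful of candidate variants the leading PCs load heavily on
    individual candidates and conditioning on them distorts single-variant
    effects.  A few dozen neutral markers dilute the loadings, mimicking
    the genome-wide marker sets PCs are computed from in practice.
    """
    mafs = [0.08, 0.14, 0.21, 0.27, 0.33, 0.38, 0.44, 0.50]
    return [
        VariantSpec(f"{prefix}{i:06d}", ["PCSK9", "APOB", "LDLR"][i % 3],
                    mafs[i % len(mafs)], 0.0, "intron", 0.99)
        for i in range(k)
    ]


def default_simulation_config(n_individuals: int = 5000, seed: int = 0) -> SimulationConfig:
    """The reference synthetic cohort.

    Ten variants mirror the selected PCSK9/APOB/LDLR panel — minor allele
    frequencies, mg/dL LDL-C betas and functional annotations on the
    published scale — each in its own LD block.  Phecodes cover the lipid
    family (272.*, with exclusion-range structure), myopia with a planted
    protective LDLR effect, and null phenotypes (type 2 diabetes, cataract)
    so that both true and absent pleiotropy are represented.
    """
    variants = [
        VariantSpec("rs11591147", "PCSK9", 0.014, -12.97, "missense", 0.95),
        VariantSpec("rs639750", "PCSK9", 0.327, -1.82, "intron", 0.99),
        VariantSpec("rs533617", "APOB", 0.038, -4.40, "missense", 0.92),
        VariantSpec("rs531819", "APOB", 0.155, -4.07, "intron", 0.98),
        VariantSpec("rs1367117", "APOB", 0.316, 3.52, "missense", 0.99),
        VariantSpec("rs6511720", "LDLR", 0.114, -5.79, "regulatory_intron", 0.97),
        VariantSpec("rs6511721", "LDLR", 0.483, 1.73, "intron", 0.99),
        VariantSpec("rs2738447", "LDLR", 0.415, -1.67, "nmd_transcript", 0.98),
        VariantSpec("rs72658867", "LDLR", 0.011, -10.20, "splice_region", 0.85),
        VariantSpec("rs5742911", "LDLR", 0.307, -1.79, "three_prime_utr", 0.96),
    ] + marker_variant_specs(30)
    phecodes = [
        PhecodeSpec(272.1, 0.30, {"rs11591147": 0.64, "rs531819": 0.88,
                                  "rs1367117": 1.07, "rs6511720": 0.83,
                                  "rs6511721": 1.07}, "hyperlipidemia"),
        PhecodeSpec(272.11, 0.18, {"rs11591147": 0.60, "rs531819": 0.87,
                                   "rs6511720": 0.80}, "hypercholesterolemia", n_codes=1),
        PhecodeSpec(367.1, 0.08, {"rs6511720": 0.85}, "myopia"),
        PhecodeSpec(250.2, 0.12, {}, "type_2_diabetes"),
        PhecodeSpec(366.1, 0.10, {}, "cataract"),
        PhecodeSpec(411.1, 0.15, {"rs639750": 0.96}, "ischemic_heart_disease"),
    ]
    return SimulationConfig(
        n_individuals=n_individuals,
        seed=seed,
        variant_specs=variants,
        phecode_specs=phecodes,
        n_related_pairs=max(2, n_individuals // 200),
    )


def null_simulation_config(
    n_individuals: int = 5000,
    n_phecodes: int = 200,
    n_variants: int = 10,
    seed: int = 0,
) -> SimulationConfig:
    """A cohort with no planted genetic effects on any phecode.

    Used to check the scan's type-I error: every variant-phecode p-value
    should be uniform.  Variants keep LDL-C effects (so the selection
    cascade has something to find) but all phecode liabilities are purely
    baseline.  Each phecode lives in its own integer family so exclusion
    ranges do not couple phenotypes.
    """
    mafs = [0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40, 0.45, 0.50]
    variants = [
        VariantSpec(f"rs9{i:06d}", ["PCSK9", "APOB", "LDLR"][i % 3],
                    mafs[i % len(mafs)], ldl_beta=-4.0)
        for i in range(n_variants)
    ]
    phecodes = [
        PhecodeSpec(float(100 + i) + 0.1, 0.15, {}, f"null_{i}", n_codes=1)
        for i in range(n_phecodes)
    ]
    return SimulationConfig(
        n_individuals=n_individuals,
        seed=seed,
        variant_specs=variants,
        phecode_specs=phecodes,
        n_related_pairs=0,
        single_code_noise_rate=0.0,
        exclusion_code_rate=0.0,
    )


def recovery_simulation_config(n_individuals: int = 50_000, seed: int = 0) -> SimulationConfig:
    """Parameter-recovery experiment at full cohort scale.

    One common variant carries the strongest published LDL-C effect
    (-12.97 mg/dL per alt allele) at MAF 0.10 — common enough that the
    n = 5e4 design estimates the slope with SE ~0.3 mg/dL — plus a planted
    pleiotropic odds ratio of 1.5 on one phecode against a background of
    null phecodes.
    """
    variants = [
        VariantSpec("rs11591147", "PCSK9", 0.10, -12.97, "missense", 0.95),
        VariantSpec("rs6511720", "LDLR", 0.114, -5.79, "regulatory_intron", 0.97),
    ]
    variants += marker_variant_specs(48)
    phecodes = [PhecodeSpec(272.1, 0.20, {"rs11591147": 1.5}, "hyperlipidemia", n_codes=1)]
    phecodes += [
        PhecodeSpec(float(300 + i) + 0.1, 0.15, {}, f"null_{i}", n_codes=1) for i in range(5)
    ]
    return SimulationConfig(
        n_individuals=n_individuals,
        seed=seed,
        variant_specs=variants,
        phecode_specs=phecodes,
        n_related_pairs=0,
        single_code_noise_rate=0.0,
        exclusion_code_rate=0.0,
    )
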