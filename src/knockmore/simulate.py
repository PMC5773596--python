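"""Synthetic inputs for every pipeline stage.

Three generators emulate the statistical structure of the study inputs:

* multi-center knockout phenotyping cohorts (seven metabolic parameters,
  sex- and center-stratified, body-mass-coupled VO2/metabolic rate,
  configurable multiplicative knockout effects, lognormal noise);
* promoter sequences with planted ordered TFBS cassettes at bounded
  inter-site distances, plus a truth table of planted coordinates;
* SNP x trait p-value matrices with planted multi-trait signal
  (null p-values i.i.d. uniform; signal -ln p exponential with mean > 1).

All outputs are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pwm import Pwm, revcomp

PARAMETERS = ("T0", "AUC", "TG", "BM", "VO2", "MR", "RER")
SEXES = ("f", "m")

#: wild-type baselines per (parameter, sex); center factors multiply these
_BASELINES = {
    ("T0", "f"): 110.0, ("T0", "m"): 125.0,        # mg/dl
    ("AUC", "f"): 19000.0, ("AUC", "m"): 23000.0,  # (mg/dl)·min
    ("TG", "f"): 130.0, ("TG", "m"): 155.0,        # mg/dl
    ("BM", "f"): 22.0, ("BM", "m"): 28.0,          # g
    ("RER", "f"): 0.85, ("RER", "m"): 0.85,
}
_VO2_INTERCEPT = 40.0   # ml/h at zero mass, before mass coupling
_MR_INTERCEPT = 0.20    # kcal/h
_MR_SLOPE_FRACTION = 0.012  # kcal/h per g, relative to VO2 mass slope


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class PhenoSimConfig:
    """Configuration of the knockout phenotyping simulation.

    ``effect_table`` maps gene -> (parameter, sex, multiplicative effect)
    or a list of such tuples; effects scale the affected parameter in
    mutants of that sex only. ``ratio_noise_cv`` is the coefficient of
    variation of the lognormal measurement noise, ``mass_slope`` couples
    VO2 (ml/h per g) to mean body mass so that mass explains most of the
    VO2/MR variance, as in real indirect-calorimetry data.
    """

    n_genes: int
    n_mut_per_sex: int = 7
    n_wt_per_sex: int = 50
    centers: tuple[str, ...] = ("C1", "C2", "C3")
    effect_table: dict = field(default_factory=dict)
    ratio_noise_cv: float = 0.1
    mass_slope: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_mut_per_sex < 1 or self.n_wt_per_sex < 1:
            raise ConfigError("counts must be >= 1")
        if self.ratio_noise_cv < 0:
            raise ConfigError("ratio_noise_cv must be >= 0")
        if not self.centers:
            raise ConfigError("need at least one center")
        normalized: dict[str, list[tuple[str, str, float]]] = {}
        for gene, effs in self.effect_table.items():
            if isinstance(effs, tuple) and len(effs) == 3 \
                    and not isinstance(effs[0], tuple):
                effs = [effs]
            for param, sex, eff in effs:
                if param not in PARAMETERS:
                    raise ConfigError(f"unknown parameter {param!r}")
                if sex not in SEXES:
                    raise ConfigError(f"unknown sex {sex!r}")
                if eff <= 0:
                    raise ConfigError("effects must be > 0")
                normalized.setdefault(gene, []).append((param, sex, eff))
        self.effect_table = normalized

    def gene_names(self) -> list[str]:
        return [f"gene{i:05d}" for i in range(self.n_genes)]


def _lognorm_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


def simulate_phenotypes(config: PhenoSimConfig) -> pd.DataFrame:
    """Simulate the per-mouse phenotyping table.

    Genes are assigned round-robin to centers (one center per gene, as in
    consortium practice); each center/sex stratum has its own wild-type
    cohort. Returns one row per mouse with columns mouse_id, gene,
    genotype, zygosity, sex, center, the seven parameters, and
    mean_body_mass.
    """
    genes = config.gene_names()
    for gene in config.effect_table:
        if gene not in genes:
            raise ConfigError(f"effect for unknown gene {gene!r}")
    rng = np.random.default_rng(config.seed)
    sigma = _lognorm_sigma(config.ratio_noise_cv)
    center_factor = {c: 1.0 + 0.04 * i
                     for i, c in enumerate(config.centers)}
    rows: list[dict] = []
    counter = 0

    def make_animal(gene: str, genotype: str, zygosity: str, sex: str,
                    center: str) -> None:
        nonlocal counter
        f = center_factor[center]
        noise = rng.lognormal(0.0, sigma, size=6) if sigma > 0 \
            else np.ones(6)
        # calorimetry noise is kept small so body mass stays the major
        # determinant of VO2/MR variability (premise of the residual model)
        if sigma > 0:
            noise[4:6] = noise[4:6] ** 0.25
        effects = {p: e for p, s, e in config.effect_table.get(gene, [])
                   if s == sex} if genotype == "mut" else {}
        mass = _BASELINES[("BM", sex)] * f * noise[0] * effects.get("BM", 1.0)
        t0 = _BASELINES[("T0", sex)] * f * noise[1] * effects.get("T0", 1.0)
        auc = _BASELINES[("AUC", sex)] * f * noise[2] * effects.get("AUC", 1.0)
        tg = _BASELINES[("TG", sex)] * f * noise[3] * effects.get("TG", 1.0)
        vo2 = (_VO2_INTERCEPT * f + config.mass_slope * mass) \
            * noise[4] * effects.get("VO2", 1.0)
        mr = (_MR_INTERCEPT * f
              + _MR_SLOPE_FRACTION * config.mass_slope * mass) \
            * noise[5] * effects.get("MR", 1.0)
        rer_target = np.clip(_BASELINES[("RER", sex)]
                             * (noise[1] ** 0.25)
                             * effects.get("RER", 1.0), 0.7, 1.0)
        vco2 = rer_target * vo2
        rows.append({
            "mouse_id": f"m{counter:07d}", "gene": gene,
            "genotype": genotype, "zygosity": zygosity, "sex": sex,
            "center": center, "T0": t0, "AUC": auc, "TG": tg, "BM": mass,
            "VO2": vo2, "MR": mr, "RER": vco2 / vo2,
            "mean_body_mass": mass,
        })
        counter += 1

    for center in config.centers:
        for sex in SEXES:
            for _ in range(config.n_wt_per_sex):
                make_animal("WT", "wt", "wt", sex, center)
    for i, gene in enumerate(genes):
        center = config.centers[i % len(config.centers)]
        for sex in SEXES:
            for _ in range(config.n_mut_per_sex):
                make_animal(gene, "mut", "hom", sex, center)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# promoters


@dataclass
class PlantedCassette:
    """One cassette to plant: ordered (pwm_id, strand) elements, one
    start-to-start distance range per adjacent pair, and the promoter ids
    that carry it."""

    elements: list[tuple[str, str]]
    distance_ranges: list[tuple[int, int]]
    carriers: list[str]
    cassette_id: str = "planted"

    def __post_init__(self) -> None:
        if len(self.distance_ranges) != len(self.elements) - 1:
            raise ConfigError("need one distance range per adjacent pair")


@dataclass
class PromoterSimConfig:
    n_promoters: int = 20
    promoter_length: int = 601
    gc_content: float = 0.5
    planted_cassettes: list[PlantedCassette] = field(default_factory=list)
    seed: int = 0
    ids: list[str] | None = None  # overrides the generated promoter names

    def __post_init__(self) -> None:
        if self.ids is not None:
            self.n_promoters = len(self.ids)
        if self.n_promoters < 1 or self.promoter_length < 1:
            raise ConfigError("counts must be >= 1")
        if not (0 < self.gc_content < 1):
            raise ConfigError("gc_content must be in (0, 1)")

    def promoter_ids(self) -> list[str]:
        if self.ids is not None:
            return list(self.ids)
        return [f"gene{i:04d}|promoter_1" for i in range(self.n_promoters)]


def simulate_promoters(config: PromoterSimConfig, pwms: dict[str, Pwm],
                       ) -> tuple[dict[str, str], pd.DataFrame]:
    """Simulate promoter sequences with planted cassettes.

    Background is i.i.d. bases at the configured GC content. Carrier
    promoters receive the planted elements (PWM consensus, reverse
    complemented on strand '-') in order, with start-to-start gaps drawn
    uniformly inside the stated ranges. Returns the sequences and a truth
    table (promoter_id, cassette_id, pwm_id, start, end, strand; 0-based
    half-open coordinates).
    """
    rng = np.random.default_rng(config.seed)
    gc = config.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    ids = config.promoter_ids()
    known = set(ids)
    seqs = {}
    for pid in ids:
        seqs[pid] = list("".join(
            np.random.default_rng(rng.integers(2 ** 31)).choice(
                list("ACGT"), size=config.promoter_length, p=probs)))
    truth_rows = []
    for cas in config.planted_cassettes:
        for pwm_id, _ in cas.elements:
            if pwm_id not in pwms:
                raise ConfigError(f"planted element references unknown "
                                  f"PWM {pwm_id!r}")
        for pid in cas.carriers:
            if pid not in known:
                raise ConfigError(f"unknown carrier promoter {pid!r}")
            gaps = [int(rng.integers(lo, hi + 1))
                    for lo, hi in cas.distance_ranges]
            for gap, (pwm_id, _) in zip(gaps, cas.elements):
                if gap < len(pwms[pwm_id]):
                    raise ConfigError(
                        "distance range allows overlapping planted "
                        f"elements (gap {gap} < PWM length "
                        f"{len(pwms[pwm_id])})")
            span = sum(gaps) + len(pwms[cas.elements[-1][0]])
            if span > config.promoter_length:
                raise ConfigError(
                    f"planted span {span} exceeds promoter length "
                    f"{config.promoter_length}")
            start = int(rng.integers(0, config.promoter_length - span + 1))
            pos = start
            for j, (pwm_id, strand) in enumerate(cas.elements):
                site = pwms[pwm_id].consensus
                if strand == "-":
                    site = revcomp(site)
                seqs[pid][pos:pos + len(site)] = list(site)
                truth_rows.append({
                    "promoter_id": pid, "cassette_id": cas.cassette_id,
                    "pwm_id": pwm_id, "start": pos,
                    "end": pos + len(site), "strand": strand,
                })
                if j < len(gaps):
                    pos += gaps[j]
    truth = pd.DataFrame(
        truth_rows, columns=["promoter_id", "cassette_id", "pwm_id",
                             "start", "end", "strand"])
    return {pid: "".join(s) for pid, s in seqs.items()}, truth


# ---------------------------------------------------------------------------
# GWAS p-value matrices


@dataclass
class GwasSimConfig:
    """``signal_snps`` maps snp_id -> decay rate lambda > 1: for signal
    SNPs, -ln p is exponential with mean lambda, so small p-values are
    enriched across traits; null SNPs have i.i.d. uniform p-values."""

    n_snps: int = 1000
    n_traits: int = 16
    signal_snps: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_traits < 2:
            raise ConfigError("n_traits must be >= 2")
        if self.n_snps < 1:
            raise ConfigError("n_snps must be >= 1")
        for snp, lam in self.signal_snps.items():
            if lam <= 0:
                raise ConfigError(f"lambda for {snp} must be > 0")

    def snp_ids(self) -> list[str]:
        return [f"snp{i:06d}" for i in range(self.n_snps)]


def simulate_gwas_pvalues(config: GwasSimConfig) -> pd.DataFrame:
    """SNP x trait p-value matrix; index snp_id, one column per trait."""
    ids = config.snp_ids()
    known = set(ids)
    for snp in config.signal_snps:
        if snp not in known:
            raise ConfigError(f"signal for unknown SNP {snp!r}")
    rng = np.random.default_rng(config.seed)
    pvals = rng.uniform(size=(config.n_snps, config.n_traits))
    index = pd.Index(ids, name="snp_id")
    for snp, lam in config.signal_snps.items():
        x = rng.exponential(scale=lam, size=config.n_traits)
        pvals[index.get_loc(snp)] = np.exp(-x)
    cols = [f"trait_{t + 1:02d}" for t in range(config.n_traits)]
    return pd.DataFrame(pvals, index=index, columns=cols)
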