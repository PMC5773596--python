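"""Cross-phenotype meta-analysis (CPMA) of GWAS summary p-values.

For one SNP with p-values across n traits, let x_i = -ln p_i. Under the
null of no cross-phenotype association the p-values are uniform, so the
x_i are Exponential(1). CPMA is the likelihood-ratio test of rate 1
against the exponential MLE lambda_hat = n / sum(x_i):

    statistic = 2 * (n * ln(lambda_hat) - n + sum(x_i))

The statistic is referred to a chi-square with 1 degree of freedom and
reported as score = -log10 of the upper tail probability; SNPs with score
above 3.1 are flagged as cross-phenotype associated. Departures in either
direction (lambda_hat above or below 1) yield a positive statistic.

The module also carries the SNP quality-control filter (MAF, call rate,
bi-allelic, LD pruning) and the p-value significance classes used to bin
lookup results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

P_FLOOR = 1e-300
P_CEIL = 1.0 - 1e-16
DEFAULT_SCORE_THRESHOLD = 3.1

#: p-value class bounds: genome-wide, lookup-corrected, suggestive, nominal
CLASS_BOUNDS = (5e-8, 2.59e-6, 1e-3, 0.05)
CLASS_NAMES = ("genome-wide", "lookup-corrected", "suggestive", "nominal",
               "weak")


@dataclass(frozen=True)
class SnpRecord:
    snp_id: str
    maf: float
    call_rate: float
    biallelic: bool = True
    ld_r_max: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.maf <= 0.5):
            raise ValueError(f"{self.snp_id}: MAF must be in [0, 0.5]")
        if not (0 <= self.call_rate <= 1):
            raise ValueError(f"{self.snp_id}: call rate must be in [0, 1]")


@dataclass(frozen=True)
class CpmaResult:
    snp_id: str
    n_traits: int
    lambda_hat: float
    statistic: float
    score: float
    significant: bool


def _chi2_1_tail_score(statistic):
    """-log10 of the chi-square(1 df) upper tail, stable for huge values
    via the normal-tail identity sf(x) = 2 * Phi(-sqrt(x))."""
    from scipy.special import log_ndtr

    statistic = np.asarray(statistic, dtype=float)
    log_sf = np.log(2.0) + log_ndtr(-np.sqrt(statistic))
    score = np.where(statistic > 0, -log_sf / np.log(10.0), 0.0)
    return score if score.ndim else float(score)


def snp_qc_filter(snps: list[SnpRecord], maf_min: float = 0.05,
                  call_rate_min: float = 0.75, ld_r_max: float = 0.8,
                  ld_matrix: np.ndarray | None = None) -> list[SnpRecord]:
    """Quality-control filter: common, bi-allelic, well-called, non-linked.

    A SNP is retained iff it is bi-allelic, MAF >= ``maf_min`` and call
    rate >= ``call_rate_min`` (both inclusive), and its correlation to
    every previously retained SNP is below ``ld_r_max``. LD pruning is
    greedy in input order, either from the ``ld_matrix`` (square, aligned
    with the input) or from each record's precomputed ``ld_r_max`` field.
    """
    retained: list[SnpRecord] = []
    retained_idx: list[int] = []
    for i, snp in enumerate(snps):
        if not snp.biallelic or snp.maf < maf_min \
                or snp.call_rate < call_rate_min:
            continue
        if ld_matrix is not None:
            if any(abs(ld_matrix[i, j]) >= ld_r_max for j in retained_idx):
                continue
        elif snp.ld_r_max >= ld_r_max:
            continue
        retained.append(snp)
        retained_idx.append(i)
    return retained


def cpma(pvalues, snp_id: str = "",
         score_threshold: float = DEFAULT_SCORE_THRESHOLD) -> CpmaResult:
    """CPMA likelihood-ratio statistic for one SNP's trait p-values."""
    p = np.clip(np.asarray(pvalues, dtype=float), P_FLOOR, P_CEIL)
    n = p.size
    if n < 2:
        raise ValueError("CPMA needs p-values for at least 2 traits")
    x = -np.log(p)
    total = x.sum()
    lam = n / total
    statistic = max(2.0 * (n * np.log(lam) - n + total), 0.0)
    score = _chi2_1_tail_score(statistic)
    return CpmaResult(snp_id, int(n), float(lam), float(statistic),
                      float(score), bool(score > score_threshold))


def cpma_matrix(matrix: pd.DataFrame,
                score_threshold: float = DEFAULT_SCORE_THRESHOLD,
                ) -> pd.DataFrame:
    """Apply :func:`cpma` to every row of a SNP x trait p-value matrix.

    Rows with missing entries are dropped (no imputation). Returns one row
    per SNP with columns snp_id, n_traits, lambda_hat, statistic, score,
    significant and min_p_class (the significance class of the smallest
    trait p-value).
    """
    if matrix.shape[1] < 2:
        raise ValueError("p-value matrix needs at least 2 trait columns")
    clean = matrix.dropna(axis=0)
    vals = np.clip(clean.to_numpy(float), P_FLOOR, P_CEIL)
    n = vals.shape[1]
    x = -np.log(vals)
    total = x.sum(axis=1)
    lam = n / total
    statistic = np.maximum(2.0 * (n * np.log(lam) - n + total), 0.0)
    score = _chi2_1_tail_score(statistic)
    return pd.DataFrame({
        "snp_id": clean.index,
        "n_traits": n,
        "lambda_hat": lam,
        "statistic": statistic,
        "score": score,
        "significant": score > score_threshold,
        "min_p_class": [classify_pvalue(p) for p in vals.min(axis=1)],
    }).reset_index(drop=True)


def classify_pvalue(p: float) -> str:
    """Bin a p-value into the lookup significance classes.

    genome-wide (p <= 5e-8), lookup-corrected (<= 2.59e-6, the Bonferroni
    level for the full SNP lookup), suggestive (<= 1e-3), nominal
    (<= 0.05), else weak. The classes partition (0, 1].
    """
    if not (0 < p <= 1):
        raise ValueError("p must be in (0, 1]")
    for bound, name in zip(CLASS_BOUNDS, CLASS_NAMES):
        if p <= bound:
            return name
    return CLASS_NAMES[-1]


def bonferroni_threshold(alpha: float = 0.05, n_tests: int = 1) -> float:
    """Per-test significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    return alpha / n_tests
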