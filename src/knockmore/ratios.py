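"""Mutant/wild-type ratio pipeline.

From the per-mouse phenotyping table to the 28 strong-phenotype gene lists:
strain de-duplication, body-mass residual adjustment of VO2 and metabolic
rate, per-(gene, center, sex) mean mutant/wild-type ratios, 5%/95%
percentile outlier calling per (parameter, sex), permutation enrichment of
candidate gene sets, and annotation-based novelty classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

PARAMETERS = ("T0", "AUC", "TG", "BM", "VO2", "MR", "RER")
SEXES = ("f", "m")
WT_SENTINEL = "WT"

#: one-tailed 5% critical multiplier (standard normal 0.95 quantile)
TAIL_SD_MULTIPLIER = 1.645


def sd_thresholds(mean: float, sd: float) -> tuple[float, float]:
    """Critical values for the 5% tails, ``mean ± 1.645 · sd``.

    The multiplier approximates p < 0.05 per tail (p < 0.1 both tails
    together) under a normal reference.
    """
    if sd <= 0:
        raise ValueError("sd must be > 0")
    return mean - TAIL_SD_MULTIPLIER * sd, mean + TAIL_SD_MULTIPLIER * sd


def dedupe_strains(records: pd.DataFrame) -> pd.DataFrame:
    """Keep one strain per gene.

    Homozygotes are preferred over heterozygotes, and a genotype phenotyped
    in both sexes is preferred over sex-discordant genotypes. Wild-type
    reference animals are retained; any residual same-gene duplicates
    (reference-strain style) are retained and flagged in the
    ``duplicate_retained`` column.
    """
    records = records.copy()
    records["duplicate_retained"] = False
    wt = records[records["genotype"] == "wt"]
    mut = records[records["genotype"] == "mut"]
    kept = [wt]
    for gene, grp in mut.groupby("gene", sort=False):
        zygs = grp["zygosity"].unique()
        if len(zygs) == 1:
            kept.append(grp)
            continue

        def rank(z: str) -> tuple[int, int]:
            sub = grp[grp["zygosity"] == z]
            both_sexes = sub["sex"].nunique() == 2
            return (int(both_sexes), int(z == "hom"))

        ranked = sorted(zygs, key=rank, reverse=True)
        best = ranked[0]
        ties = [z for z in zygs if rank(z) == rank(best)]
        sub = grp[grp["zygosity"].isin(ties)].copy()
        if len(ties) > 1:
            sub["duplicate_retained"] = True
        kept.append(sub)
    return pd.concat(kept, ignore_index=True)


def adjust_mass_dependent(records: pd.DataFrame, parameter: str,
                          ) -> pd.DataFrame:
    """Replace VO2 or metabolic rate by its body-mass-independent residual.

    Per (center, sex) stratum, mutants and wild types jointly, an ordinary
    least-squares line of the parameter on mean body mass is fitted; the
    adjusted value is the residual plus the prediction at the stratum mean
    body mass (equivalently the stratum mean of the parameter), so adjusted
    values keep the scale of the raw measurement but are uncorrelated with
    body mass. Strata with fewer than 3 animals are left unadjusted with a
    warning.
    """
    if parameter not in ("VO2", "MR"):
        raise ValueError("mass adjustment applies to VO2 and MR only")
    out = records.copy()
    for (center, sex), idx in out.groupby(["center", "sex"]).groups.items():
        sub = out.loc[idx]
        mask = sub[parameter].notna() & sub["mean_body_mass"].notna()
        if mask.sum() < 3:
            warnings.warn(
                f"stratum ({center}, {sex}): fewer than 3 animals, "
                f"{parameter} not adjusted", stacklevel=2)
            continue
        y = sub.loc[mask, parameter].to_numpy(float)
        x = sub.loc[mask, "mean_body_mass"].to_numpy(float)
        slope, intercept = np.polyfit(x, y, 1)
        out.loc[sub.index[mask], parameter] = y - slope * (x - x.mean())
    return out


def compute_ratio_table(records: pd.DataFrame, min_group_size: int = 7,
                        qc_bounds: dict[str, tuple[float, float]] | None = None,
                        ) -> pd.DataFrame:
    """Mean mutant/wild-type ratios per (gene, parameter, sex, center).

    ``qc_bounds`` optionally maps parameter -> (low, high) validity bounds;
    values outside are treated as missing (the screen's quality-control
    step). Rows with fewer than ``min_group_size`` mutants are dropped; a
    wild-type mean of zero rejects the row (collected in the returned
    frame's ``attrs['rejected']``).
    """
    records = records.copy()
    if qc_bounds:
        for param, (lo, hi) in qc_bounds.items():
            bad = (records[param] < lo) | (records[param] > hi)
            records.loc[bad, param] = np.nan
    melted = records.melt(
        id_vars=["gene", "genotype", "sex", "center"],
        value_vars=list(PARAMETERS), var_name="parameter")
    melted = melted.dropna(subset=["value"])
    wt = melted[melted["genotype"] == "wt"] \
        .groupby(["center", "sex", "parameter"])["value"] \
        .agg(wt_mean="mean", n_wt="count").reset_index()
    mut = melted[melted["genotype"] == "mut"] \
        .groupby(["gene", "center", "sex", "parameter"])["value"] \
        .agg(mut_mean="mean", n_mut="count").reset_index()
    mut = mut[mut["n_mut"] >= min_group_size]
    merged = mut.merge(wt, on=["center", "sex", "parameter"], how="left")
    bad = ~np.isfinite(merged["wt_mean"]) | (merged["wt_mean"] == 0)
    rejected = [(r.gene, r.parameter, r.sex, r.center,
                 "wild-type mean zero or missing")
                for r in merged[bad].itertuples()]
    good = merged[~bad].copy()
    good["ratio"] = good["mut_mean"] / good["wt_mean"]
    good["n_wt"] = good["n_wt"].astype(int)
    table = good[["gene", "parameter", "sex", "center", "ratio",
                  "n_mut", "n_wt"]].sort_values(
        ["gene", "parameter", "sex", "center"]).reset_index(drop=True)
    table.attrs["rejected"] = rejected
    return table


@dataclass
class GeneListSet:
    """The outlier gene lists, keyed by (parameter, sex, tail)."""

    lists: dict[tuple[str, str, str], pd.DataFrame]
    lower: float
    upper: float

    @property
    def strong_genes(self) -> set[str]:
        out: set[str] = set()
        for df in self.lists.values():
            out.update(df["gene"])
        return out

    def genes(self, parameter: str, sex: str, tail: str) -> list[str]:
        key = (parameter, sex, tail)
        if key not in self.lists:
            return []
        return sorted(self.lists[key]["gene"].unique())

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for (param, sex, tail), df in sorted(self.lists.items()):
            sub = df.copy()
            sub.insert(0, "tail", tail)
            sub.insert(0, "sex", sex)
            sub.insert(0, "parameter", param)
            frames.append(sub)
        if not frames:
            return pd.DataFrame(
                columns=["parameter", "sex", "tail", "gene", "ratio"])
        return pd.concat(frames, ignore_index=True)


def call_outliers(ratio_table: pd.DataFrame, lower: float = 0.05,
                  upper: float = 0.95, min_genes: int = 20) -> GeneListSet:
    """Flag genes below the ``lower`` / above the ``upper`` empirical
    percentile of each pooled (parameter, sex) ratio distribution.

    Per-center rows of multi-center genes all enter the pooled
    distribution. Cutoff comparisons are strict, which keeps the combined
    flag rate at or below (lower + 1 - upper) even under heavy ties.
    Distributions with fewer than ``min_genes`` genes are skipped with a
    warning.
    """
    if not (0 < lower < upper < 1):
        raise ValueError("need 0 < lower < upper < 1")
    lists: dict[tuple[str, str, str], pd.DataFrame] = {}
    for (param, sex), sub in ratio_table.groupby(["parameter", "sex"]):
        if sub["gene"].nunique() < min_genes:
            warnings.warn(
                f"({param}, {sex}): fewer than {min_genes} genes, skipped",
                stacklevel=2)
            continue
        vals = sub["ratio"].to_numpy(float)
        lo_cut = np.quantile(vals, lower)
        hi_cut = np.quantile(vals, upper)
        low = sub[sub["ratio"] < lo_cut]
        high = sub[sub["ratio"] > hi_cut]
        cols = ["gene", "ratio", "center"]
        lists[(param, sex, "low")] = low[cols].reset_index(drop=True)
        lists[(param, sex, "high")] = high[cols].reset_index(drop=True)
    return GeneListSet(lists, lower, upper)


@dataclass(frozen=True)
class PermutationResult:
    observed_fraction: float
    n_permutations: int
    p_value: float
    seed: int
    band: tuple[float, float]


def permutation_enrichment(candidate_genes: set[str] | list[str],
                           ratio_table: pd.DataFrame,
                           band: tuple[float, float] = (0.05, 0.95),
                           n_permutations: int = 10_000,
                           seed: int = 0) -> PermutationResult:
    """Permutation test for outlier enrichment of a candidate gene set.

    The observed statistic is the fraction of candidate genes falling in
    the outlier band of at least one (parameter, sex) distribution. The
    null shuffles the gene-to-ratio assignment within each distribution
    (which preserves every distribution's shape and tail counts) and
    recomputes the fraction; the one-sided p-value uses the add-one
    estimator (#null >= observed + 1) / (n + 1), so p is never 0.
    """
    candidates = sorted(set(candidate_genes))
    if not candidates:
        raise ValueError("candidate gene set is empty")
    all_genes = set(ratio_table["gene"])
    missing = [g for g in candidates if g not in all_genes]
    if missing:
        raise ValueError(f"candidate genes absent from ratio table: "
                         f"{missing[:5]}...")
    lower, upper = band
    cand_index = {g: i for i, g in enumerate(candidates)}
    strata = []
    observed_hit = np.zeros(len(candidates), dtype=bool)
    for (_param, _sex), sub in ratio_table.groupby(["parameter", "sex"]):
        vals = sub["ratio"].to_numpy(float)
        genes = sub["gene"].to_numpy()
        lo_cut = np.quantile(vals, lower)
        hi_cut = np.quantile(vals, upper)
        flagged = (vals < lo_cut) | (vals > hi_cut)
        k = int(flagged.sum())
        row_of_cand = np.flatnonzero(np.isin(genes, candidates))
        for r in np.flatnonzero(flagged):
            if genes[r] in cand_index:
                observed_hit[cand_index[genes[r]]] = True
        if k > 0 and len(row_of_cand) > 0:
            strata.append((len(vals), k, row_of_cand,
                           np.array([cand_index[genes[r]]
                                     for r in row_of_cand])))
    observed = observed_hit.mean()
    rng = np.random.default_rng(seed)
    null_ge = 0
    done = 0
    while done < n_permutations:
        batch = min(n_permutations - done,
                    max(1, int(2e7 // max(sum(s[0] for s in strata), 1))))
        hit = np.zeros((batch, len(candidates)), dtype=bool)
        for n_rows, k, cand_rows, cand_ids in strata:
            u = rng.random((batch, n_rows))
            thresh = np.partition(u, k - 1, axis=1)[:, k - 1]
            flags = u[:, cand_rows] <= thresh[:, None]
            np.logical_or.at(hit, (slice(None), cand_ids), flags)
        frac = hit.mean(axis=1)
        null_ge += int((frac >= observed - 1e-12).sum())
        done += batch
    p = (null_ge + 1) / (n_permutations + 1)
    return PermutationResult(float(observed), n_permutations, float(p),
                             seed, band)


def annotate_novelty(genes: set[str] | list[str],
                     annotations: pd.DataFrame) -> dict[str, str]:
    """Classify genes as known-metabolic / known-nonmetabolic / unannotated.

    ``annotations`` is a tidy table with columns gene, source (MP, GO,
    KEGG, or other), metabolic (bool) and impc (bool, MP rows sourced from
    the screen itself). Screen-derived MP rows are discarded first to avoid
    circular discovery. A gene with a (non-screen) metabolic MP term, or a
    metabolic GO biological-process / KEGG Metabolism membership, is
    known-metabolic; a gene with any other annotation (e.g. GO molecular
    function only) is known-nonmetabolic; a gene absent from every table is
    unannotated.
    """
    required = {"gene", "source", "metabolic"}
    if not required.issubset(annotations.columns):
        raise ValueError(f"annotation table needs columns {required}")
    ann = annotations.copy()
    if "impc" in ann.columns:
        ann = ann[~((ann["source"] == "MP") & ann["impc"].astype(bool))]
    out: dict[str, str] = {}
    by_gene = dict(iter(ann.groupby("gene")))
    for gene in genes:
        rows = by_gene.get(gene)
        if rows is None or rows.empty:
            out[gene] = "unannotated"
            continue
        mp_metabolic = ((rows["source"] == "MP")
                        & rows["metabolic"]).any()
        gokegg_metabolic = (rows["source"].isin(["GO", "KEGG"])
                            & rows["metabolic"]).any()
        if mp_metabolic or gokegg_metabolic:
            out[gene] = "known-metabolic"
        else:
            out[gene] = "known-nonmetabolic"
    return out
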