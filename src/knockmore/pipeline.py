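"""End-to-end orchestration: synthetic inputs through every analysis stage.

The run follows the study's stage order — phenotype ratios, outlier gene
lists, permutation enrichment, cross-phenotype GWAS scoring, promoter
cassette mining and enrichment, network construction, and cassette-based
phenotype prediction — and records a manifest (config hash, seeds,
versions) so identical configurations reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io, mining, networks, pwm, ratios, simulate
from .cpma import cpma_matrix

STAGES = ("simulate", "ratios", "outliers", "permtest", "cpma", "mine",
          "network", "validate")

_DEFAULTS: dict = {
    "seed": 0,
    "stages": list(STAGES),
    "phenotypes": {"n_genes": 200, "n_mut_per_sex": 7, "n_wt_per_sex": 50,
                   "centers": ["C1", "C2", "C3"], "ratio_noise_cv": 0.1,
                   "mass_slope": 1.5, "n_effect_genes": 10,
                   "effect_size": 1.6},
    "outliers": {"lower": 0.05, "upper": 0.95},
    "permtest": {"n_permutations": 10000, "band": [0.05, 0.95]},
    "gwas": {"n_snps": 2000, "n_traits": 16, "n_signal": 20,
             "signal_lambda": 3.0, "score_threshold": 3.1},
    "promoters": {"length": 601, "gc_content": 0.5, "n_carriers": 5,
                  "min_score": 0.85},
    "mining": {"min_elements": 3, "max_elements": 6, "quorum": 3,
               "dist_var": 20, "min_dist": 10},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run (YAML-backed)."""

    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.options = _merge(_DEFAULTS, self.options)
        unknown = set(self.options["stages"]) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def __getitem__(self, key: str):
        return self.options[key]

    @property
    def seed(self) -> int:
        return int(self.options["seed"])

    def hash(self) -> str:
        canon = json.dumps(self.options, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _demo_pwms() -> dict[str, pwm.Pwm]:
    """A small, nearly deterministic PWM library for synthetic runs."""
    # consensi chosen non-palindromic so strand calls are unambiguous
    consensi = {"TFA": "TGACGTAA", "TFB": "CACGTGAC", "TFC": "GGGCGGGA",
                "TFD": "TTTCGCGC", "TFE": "ATGCAAAT"}
    out = {}
    for name, cons in consensi.items():
        mat = np.full((len(cons), 4), 0.02)
        for i, base in enumerate(cons):
            mat[i, "ACGT".index(base)] = 0.94
        out[name] = pwm.Pwm(name, mat)
    return out


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the configured stages in order; returns the manifest.

    A disabled stage makes every downstream stage that consumes its output
    fail fast with the stage name. Outputs are TSV/FASTA/GraphML files in
    ``outdir`` plus ``manifest.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    opts = config.options
    stages = list(opts["stages"])
    seed = config.seed
    state: dict = {}
    manifest: dict = {
        "config_hash": config.hash(), "seed": seed,
        "package_version": __version__,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "stages": stages, "outputs": {},
    }

    def need(key: str, stage: str, producer: str):
        if key not in state:
            raise RuntimeError(
                f"stage '{stage}' requires output of disabled stage "
                f"'{producer}'")
        return state[key]

    def save(name: str, writer, *args) -> None:
        writer(*args, outdir / name)
        manifest["outputs"][name] = name  # relative: manifests reproduce

    if "simulate" in stages:
        ph = opts["phenotypes"]
        genes = [f"gene{i:05d}" for i in range(ph["n_genes"])]
        effect_genes = genes[:ph["n_effect_genes"]]
        rng = np.random.default_rng(seed)
        effects = {}
        for g in effect_genes:
            param = str(rng.choice(["T0", "AUC", "TG", "BM"]))
            sex = str(rng.choice(["f", "m"]))
            direction = rng.choice([1.0, -1.0])
            eff = ph["effect_size"] if direction > 0 else 1 / ph["effect_size"]
            effects[g] = (param, sex, eff)
        pheno_cfg = simulate.PhenoSimConfig(
            n_genes=ph["n_genes"], n_mut_per_sex=ph["n_mut_per_sex"],
            n_wt_per_sex=ph["n_wt_per_sex"], centers=tuple(ph["centers"]),
            effect_table=effects, ratio_noise_cv=ph["ratio_noise_cv"],
            mass_slope=ph["mass_slope"], seed=seed)
        state["phenotypes"] = simulate.simulate_phenotypes(pheno_cfg)
        state["effect_genes"] = effect_genes
        save("phenotypes.tsv", io.write_phenotypes, state["phenotypes"])

    if "ratios" in stages:
        records = need("phenotypes", "ratios", "simulate")
        records = ratios.dedupe_strains(records)
        for param in ("VO2", "MR"):
            records = ratios.adjust_mass_dependent(records, param)
        table = ratios.compute_ratio_table(records)
        state["ratio_table"] = table
        save("ratios.tsv", io.write_table, table)

    if "outliers" in stages:
        table = need("ratio_table", "outliers", "ratios")
        ol = opts["outliers"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lists = ratios.call_outliers(table, ol["lower"], ol["upper"])
        state["gene_lists"] = lists
        save("gene_lists.tsv", io.write_table, lists.to_frame())

    if "permtest" in stages:
        table = need("ratio_table", "permtest", "ratios")
        candidates = [g for g in need("effect_genes", "permtest",
                                      "simulate")
                      if g in set(table["gene"])]
        pt = opts["permtest"]
        result = ratios.permutation_enrichment(
            candidates, table, band=tuple(pt["band"]),
            n_permutations=pt["n_permutations"], seed=seed + 1)
        state["permutation"] = result
        save("permutation.tsv", io.write_table, pd.DataFrame([{
            "observed_fraction": result.observed_fraction,
            "n_permutations": result.n_permutations,
            "p_value": result.p_value, "seed": result.seed,
            "band": f"{result.band[0]}/{result.band[1]}"}]))

    if "cpma" in stages:
        gw = opts["gwas"]
        snp_ids = [f"snp{i:06d}" for i in range(gw["n_snps"])]
        gwas_cfg = simulate.GwasSimConfig(
            n_snps=gw["n_snps"], n_traits=gw["n_traits"],
            signal_snps={s: gw["signal_lambda"]
                         for s in snp_ids[:gw["n_signal"]]},
            seed=seed + 2)
        matrix = simulate.simulate_gwas_pvalues(gwas_cfg)
        save("gwas_pvalues.tsv", io.write_gwas_matrix, matrix)
        cpma_table = cpma_matrix(matrix, gw["score_threshold"])
        state["cpma"] = cpma_table
        save("cpma.tsv", io.write_table, cpma_table)

    if "mine" in stages:
        lists = need("gene_lists", "mine", "outliers")
        pr = opts["promoters"]
        mn = opts["mining"]
        # mine the largest outlier list's promoters for shared cassettes
        key = max(lists.lists, key=lambda k: len(lists.lists[k]))
        test_genes = sorted(lists.lists[key]["gene"].unique())
        all_genes = sorted(set(need("ratio_table", "mine",
                                    "ratios")["gene"]))
        promoter_ids = [f"{g}|promoter_1" for g in all_genes]
        carriers = [f"{g}|promoter_1"
                    for g in test_genes[:pr["n_carriers"]]]
        pwms = _demo_pwms()
        planted = simulate.PlantedCassette(
            elements=[("TFA", "+"), ("TFB", "+"), ("TFC", "-")],
            distance_ranges=[(15, 25), (20, 30)], carriers=carriers,
            cassette_id="demo")
        prom_cfg = simulate.PromoterSimConfig(
            promoter_length=pr["length"], gc_content=pr["gc_content"],
            planted_cassettes=[planted], seed=seed + 3, ids=promoter_ids)
        promoters, truth = simulate.simulate_promoters(prom_cfg, pwms)
        save("promoters.fasta", io.write_fasta, promoters)
        save("planted_truth.tsv", io.write_table, truth)
        scans = pwm.scan_promoters(promoters, pwms,
                                   min_score=pr["min_score"])
        params = mining.MiningParams(
            min_elements=mn["min_elements"],
            max_elements=mn["max_elements"], quorum=mn["quorum"],
            dist_var=mn["dist_var"], min_dist=mn["min_dist"])
        test_scans = {f"{g}|promoter_1": scans[f"{g}|promoter_1"]
                      for g in test_genes}
        cassettes = mining.mine_cassettes(test_scans, params)
        save("cassettes.txt", io.write_cassettes, cassettes)
        param_name, sex, tail = key
        sets = mining.build_more_sets(cassettes, (param_name, sex, tail))
        save("more_sets.txt", io.write_more_sets, sets)
        opposite = (param_name, sex, "low" if tail == "high" else "high")
        opp_genes = [g for g in lists.lists.get(
            opposite, pd.DataFrame(columns=["gene"]))["gene"].unique()]
        lengths = {pid: len(s) for pid, s in promoters.items()}
        pwm_lengths = {name: len(p) for name, p in pwms.items()}
        enrich_rows = []
        for s in sets:
            res = mining.enrichment(
                s, test_scans, scans,
                control_scans={f"{g}|promoter_1":
                               scans[f"{g}|promoter_1"]
                               for g in opp_genes} or None,
                promoter_lengths=lengths, pwm_lengths=pwm_lengths)
            enrich_rows.append({
                "set_id": s.id, "target_count": res.target_count,
                "expected": res.expected, "ratio": res.ratio,
                "associated": res.associated,
                "control_ratio": res.control_ratio})
        enrich_table = pd.DataFrame(
            enrich_rows, columns=["set_id", "target_count", "expected",
                                  "ratio", "associated", "control_ratio"])
        save("enrichment.tsv", io.write_table, enrich_table)
        state.update(promoters=promoters, scans=scans, sets=sets,
                     enrichment=enrich_table, mined_key=key,
                     promoter_lengths=lengths, pwm_lengths=pwm_lengths)

    if "network" in stages:
        sets = need("sets", "network", "mine")
        enrich_table = state["enrichment"]
        scans = state["scans"]
        associated = set(
            enrich_table[enrich_table["associated"]]["set_id"])
        rows = []
        for s in sets:
            if s.id not in associated:
                continue
            tag = "-".join(s.phenotype_tag[:2]) + s.phenotype_tag[2][0] \
                if s.phenotype_tag else "na"
            hits = mining.match_cassette(
                s, scans, promoter_lengths=state["promoter_lengths"],
                pwm_lengths=state["pwm_lengths"])
            for pid, hit in hits.items():
                if hit:
                    rows.append({"set_id": s.id, "sub_phenotype": tag,
                                 "gene": pid.split("|")[0]})
        membership = pd.DataFrame(
            rows, columns=["set_id", "sub_phenotype", "gene"])
        net = networks.build_more_network(membership)
        state["network"] = net
        state["set_membership"] = membership
        save("more_network.graphml", networks.write_graphml, net)
        save("more_network_edges.tsv", io.write_table,
             networks.network_to_edge_frame(net))

    if "validate" in stages:
        sets = need("sets", "validate", "mine")
        scans = state["scans"]
        lists = need("gene_lists", "validate", "outliers")
        strong = lists.strong_genes
        counts: dict[str, int] = {}
        for s in sets:
            hits = mining.match_cassette(
                s, scans, promoter_lengths=state["promoter_lengths"],
                pwm_lengths=state["pwm_lengths"])
            for pid, hit in hits.items():
                gene = pid.split("|")[0]
                counts[gene] = counts.get(gene, 0) + int(hit)
        flags = {g: g in strong for g in counts}
        try:
            result = networks.validate_prediction(counts, flags)
            validation = pd.DataFrame([{
                "matched_with_phenotype": result.table[0][0],
                "matched_without": result.table[0][1],
                "unmatched_with_phenotype": result.table[1][0],
                "unmatched_without": result.table[1][1],
                "fraction_matched": result.fraction_matched,
                "fraction_unmatched": result.fraction_unmatched,
                "fisher_p": result.p_value}])
        except ValueError as err:
            validation = pd.DataFrame([{"error": str(err)}])
        state["validation"] = validation
        save("validation.tsv", io.write_table, validation)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    state["manifest"] = manifest
    return state
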