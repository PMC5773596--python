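"""Shared readers and writers for the pipeline's file formats.

Tables are tab-separated text; promoters are FASTA; TFBS matches use a
BED-like layout (0-based half-open, strand column); cassettes and MORE
sets use a small block text format that round-trips bit-exactly.
"""

from __future__ import annotations

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .mining import MoreCassette, MoreSet
from .pwm import TfbsMatch

PHENOTYPE_COLUMNS = ["mouse_id", "gene", "genotype", "zygosity", "sex",
                     "center", "T0", "AUC", "TG", "BM", "VO2", "MR", "RER",
                     "mean_body_mass"]


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"mouse_id": str, "gene": str})
    missing = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_gwas_matrix(path) -> pd.DataFrame:
    """SNP x trait p-value matrix: first column snp_id, one per trait."""
    return pd.read_csv(path, sep="\t", index_col="snp_id")


def write_gwas_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    SeqIO.write((SeqRecord(Seq(s), id=pid, description="")
                 for pid, s in seqs.items()), str(path), "fasta")


def read_matches(path) -> list[TfbsMatch]:
    """BED-like TSV: promoter_id, start, end, pwm_id, score, strand."""
    df = pd.read_csv(path, sep="\t")
    return [TfbsMatch(r.promoter_id, r.pwm_id, int(r.start), int(r.end),
                      r.strand, float(r.score))
            for r in df.itertuples()]


def write_matches(matches: list[TfbsMatch], path) -> None:
    pd.DataFrame(
        [(m.promoter_id, m.start, m.end, m.pwm_id, m.score, m.strand)
         for m in matches],
        columns=["promoter_id", "start", "end", "pwm_id", "score",
                 "strand"]).to_csv(path, sep="\t", index=False,
                                   float_format="%.6f")


# ---------------------------------------------------------------------------
# cassette / MORE set block format


def _format_cassette(c: MoreCassette, label: str) -> str:
    lines = [f">cassette {label}",
             "elements\t" + " ".join(f"{p}:{s}" for p, s in c.elements),
             "ranges\t" + " ".join(f"{lo}-{hi}"
                                   for lo, hi in c.distance_ranges),
             "support\t" + ",".join(sorted(c.support))]
    return "\n".join(lines)


def write_cassettes(cassettes: list[MoreCassette], path) -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(cassettes):
            fh.write(_format_cassette(c, f"c{i:04d}") + "\n")


def _parse_cassette_block(lines: list[str]) -> MoreCassette:
    fields = {}
    for line in lines:
        key, _, val = line.partition("\t")
        fields[key] = val
    elements = tuple(tuple(tok.rsplit(":", 1))
                     for tok in fields["elements"].split())
    ranges = tuple(tuple(int(x) for x in tok.split("-"))
                   for tok in fields["ranges"].split())
    support = frozenset(fields["support"].split(","))
    return MoreCassette(elements, ranges, support)


def read_cassettes(path) -> list[MoreCassette]:
    cassettes = []
    block: list[str] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith(">cassette"):
                if block:
                    cassettes.append(_parse_cassette_block(block))
                block = []
            elif line:
                block.append(line)
    if block:
        cassettes.append(_parse_cassette_block(block))
    return cassettes


def write_more_sets(sets: list[MoreSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            tag = "" if s.phenotype_tag is None \
                else "\t" + "/".join(s.phenotype_tag)
            fh.write(f">set {s.id}{tag}\n")
            for j, c in enumerate(s.cassettes):
                fh.write(_format_cassette(c, f"{s.id}.{j}") + "\n")


def read_more_sets(path) -> list[MoreSet]:
    sets: list[MoreSet] = []
    block: list[str] = []

    def flush_block() -> None:
        if block and sets:
            sets[-1].cassettes.append(_parse_cassette_block(block))
        block.clear()

    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith(">set "):
                flush_block()
                rest = line[len(">set "):]
                sid, _, tag = rest.partition("\t")
                tag_tuple = tuple(tag.split("/")) if tag else None
                sets.append(MoreSet(sid, [], tag_tuple))
            elif line.startswith(">cassette"):
                flush_block()
            elif line:
                block.append(line)
    flush_block()
    return sets
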