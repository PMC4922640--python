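"""Plain-text readers and writers (BED, TSV) for every pipeline artifact.

All coordinates on disk follow BED conventions (0-based, half-open), which
is also the package's internal convention, so no shifting occurs.  Gene
models use a tab-delimited format with comma-joined exon coordinate lists.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotate import AnnotationTrack
from .genome import GenomeSpec, validate_sample_sheet
from .synthetic import DEGene, SpikedWindow, TruthTable
from .windows import CountMatrix

__all__ = [
    "read_bed3", "write_bed3",
    "read_genome_tsv", "write_genome_tsv",
    "read_sample_sheet", "write_sample_sheet",
    "read_gene_models", "write_gene_models",
    "load_annotation", "read_counts_tsv", "write_counts_tsv",
    "read_truth_tsv", "write_truth_tsv",
    "write_results_tsv", "write_ram_bed",
]


def read_bed3(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2],
        names=["chrom", "start", "end"], comment="#",
    )
    return df.astype({"start": np.int64, "end": np.int64})


def write_bed3(df: pd.DataFrame, path):
    df[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def write_genome_tsv(genome: GenomeSpec, path):
    genome.to_frame().assign(
        x_like=[c in genome.x_like for c in genome.chrom_names],
        y_like=[c == genome.y_like for c in genome.chrom_names],
    ).to_csv(path, sep="\t", index=False)


def read_genome_tsv(path) -> GenomeSpec:
    df = pd.read_csv(path, sep="\t")
    y = df.loc[df.get("y_like", False) == True, "chrom"]  # noqa: E712
    return GenomeSpec(
        chrom_names=tuple(df["chrom"]),
        chrom_lengths=tuple(df["length"]),
        x_like=frozenset(df.loc[df.get("x_like", False) == True, "chrom"]),  # noqa: E712
        y_like=None if y.empty else str(y.iloc[0]),
    )


def write_sample_sheet(sheet: pd.DataFrame, path):
    sheet.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    return validate_sample_sheet(pd.read_csv(path, sep="\t"))


def write_gene_models(genes: pd.DataFrame, path):
    out = genes.copy()
    out["exon_starts"] = [",".join(map(str, x)) for x in out["exon_starts"]]
    out["exon_ends"] = [",".join(map(str, x)) for x in out["exon_ends"]]
    out.to_csv(path, sep="\t", index=False)


def read_gene_models(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("exon_starts", "exon_ends"):
        df[col] = [
            tuple(int(v) for v in str(x).split(",")) if str(x) else ()
            for x in df[col]
        ]
    return df


def load_annotation(cgi_bed=None, repeat_bed=None, gene_models_tsv=None) -> AnnotationTrack:
    def as_dict(bed):
        if bed is None:
            return {}
        df = read_bed3(bed)
        return {
            str(c): list(zip(g["start"], g["end"]))
            for c, g in df.groupby("chrom", observed=True)
        }

    genes = read_gene_models(gene_models_tsv) if gene_models_tsv else None
    return AnnotationTrack(cgi=as_dict(cgi_bed), repeats=as_dict(repeat_bed), genes=genes)


def write_counts_tsv(cm: CountMatrix, path):
    out = cm.windows.copy()
    for j, s in enumerate(cm.samples):
        out[s] = cm.counts[:, j]
    with open(path, "w") as fh:
        fh.write("# lib_sizes\t" + "\t".join(f"{s}={int(n)}" for s, n in zip(cm.samples, cm.lib_sizes)) + "\n")
        out.to_csv(fh, sep="\t", index=False)


def read_counts_tsv(path) -> CountMatrix:
    with open(path) as fh:
        header = fh.readline()
        lib = {}
        if header.startswith("# lib_sizes"):
            for tok in header.strip().split("\t")[1:]:
                k, v = tok.split("=")
                lib[k] = float(v)
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    samples = [c for c in df.columns if c not in ("chrom", "start", "end")]
    counts = df[samples].to_numpy()
    lib_sizes = np.array([lib.get(s, counts[:, j].sum()) for j, s in enumerate(samples)])
    return CountMatrix(
        windows=df[["chrom", "start", "end"]].reset_index(drop=True),
        samples=samples,
        counts=counts,
        lib_sizes=lib_sizes,
    )


def write_truth_tsv(truth: TruthTable, path):
    rows = [
        ("spike", w.chrom, w.start, w.end, w.log2fc, w.comparison, "")
        for w in truth.spiked_windows
    ]
    rows += [("de_gene", g.gene_id, "", "", g.log2fc, g.comparison, "") for g in truth.de_genes]
    rows += [
        ("coupling", c, s, e, "", "", gene)
        for (c, s, e), gene in truth.coupling.items()
    ]
    pd.DataFrame(
        rows, columns=["kind", "chrom_or_gene", "start", "end", "log2fc", "comparison", "gene_id"]
    ).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> TruthTable:
    df = pd.read_csv(path, sep="\t")
    truth = TruthTable()
    for _, r in df.iterrows():
        if r["kind"] == "spike":
            truth.spiked_windows.append(
                SpikedWindow(
                    str(r["chrom_or_gene"]), int(r["start"]), int(r["end"]),
                    float(r["log2fc"]), str(r["comparison"]),
                )
            )
        elif r["kind"] == "de_gene":
            truth.de_genes.append(
                DEGene(str(r["chrom_or_gene"]), float(r["log2fc"]), str(r["comparison"]))
            )
        else:
            truth.coupling[(str(r["chrom_or_gene"]), int(r["start"]), int(r["end"]))] = str(
                r["gene_id"]
            )
    return truth


def write_results_tsv(results: pd.DataFrame, path):
    results.to_csv(path, sep="\t", index=False)


def write_ram_bed(rams: pd.DataFrame, path):
    """RAMs as BED6: name=comparison, score=-10*log10(p) (capped 1000)."""
    if rams.empty:
        open(path, "w").close()
        return
    score = np.minimum(1000, np.round(-10 * np.log10(np.maximum(rams["p"], 1e-100)))).astype(int)
    out = pd.DataFrame(
        {
            "chrom": rams["chrom"], "start": rams["start"], "end": rams["end"],
            "name": rams["comparison"], "score": score, "strand": ".",
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)
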