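"""Integrate methylation calls with RNA-seq differential expression.

Couples half of the spiked methylation regions to genes whose expression
moves in the opposite direction (promoter hypermethylation with reduced
expression and vice versa), runs gene-level NB differential expression
with TMM normalization (FDR < 0.10, 2-fold flagging), and reports genes
whose expression change opposes a RAM within 5 kb of their TSS.
"""

import pandas as pd

from ramscan import (
    PipelineConfig,
    count_reads,
    integrate,
    nearest_tss,
    random_truth,
    rnaseq_de,
    run_pipeline,
    simulate_expression_counts,
    simulate_genome,
    simulate_methylation_reads,
    simulate_sample_sheet,
)

genome, track = simulate_genome(
    n_chroms=1, mean_length_bp=250_000, cgi_density=5e-5,
    gene_density=8e-5, repeat_fraction=0.2, seed=21,
)
sheet = simulate_sample_sheet(6, seed=21)
truth = random_truth(
    genome, n_spikes=20, log2fc=2.0, comparison="nd_vs_high", seed=21,
    annotations=track, couple_fraction=0.5, expr_log2fc=1.5,
)

depth = 25 * sum(-(-L // 50) for L in genome.chrom_lengths)
reads = simulate_methylation_reads(
    genome, track, sheet, depth, cgi_enrichment_factor=1.0,
    truth=truth, dispersion=0.1, seed=21,
)
cm = count_reads(genome, reads)
groups = sheet.set_index("id").loc[cm.samples, "group"].to_numpy()
_, rams = run_pipeline(cm, groups, ("non_detect", "high"), PipelineConfig(),
                       comparison="nd_vs_high")
rams = pd.concat([rams, nearest_tss(rams, track)], axis=1)

# RNA-seq on an N=4-per-group subset; transcriptome = annotated genes plus
# null padding so normalization sees a mostly-null composition
sub = sheet.groupby("group", group_keys=False).head(4)
expr_genes = pd.concat(
    [track.genes[["gene_id"]],
     pd.DataFrame({"gene_id": [f"null{i:04d}" for i in range(300)]})],
    ignore_index=True,
)
expr_counts = simulate_expression_counts(
    expr_genes, sub, truth, baseline_mean=100, dispersion=0.1, seed=21
)
expr_groups = sub.set_index("id").loc[expr_counts.columns, "group"].to_numpy()
expr = rnaseq_de(expr_counts, expr_groups, ("non_detect", "high"))

cands = integrate(rams, expr)
truth_genes = {dg.gene_id for dg in truth.de_genes}
print(f"DE genes (FDR<0.10, 2-fold): {int(expr['is_de'].sum())} of {len(expr)} tested")
print(f"integration candidates: {len(cands)}")
print(f"truth-coupled genes recovered: {len(set(cands['gene_id']) & truth_genes)}"
      f"/{len(truth_genes)}")
if len(cands):
    print(cands[["gene_id", "methylation_direction", "expression_direction",
                 "expression_log2FC"]].head(5).to_string(index=False))
# Each candidate pairs a gene with its strongest nearby RAM of opposite
# effect sign -- the inverse methylation-expression relation.
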