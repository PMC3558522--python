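"""Generate the synthetic UCE cohort and write its raw inputs.

Emits per-taxon contig FASTAs, the reference locus set, per-locus
alignments, the true species/gene trees and the truth tables that the
later scripts score against.
"""
import pandas as pd

from common import RESULTS, STUDY, study_dataset
from ucephylo import io

out = RESULTS / "synthetic"
out.mkdir(parents=True, exist_ok=True)

data = study_dataset()

io.write_contigs(data.contigs, out / "contigs")
io.write_fasta(data.reference, out / "reference_loci.fasta")
aln_dir = out / "alignments"
aln_dir.mkdir(exist_ok=True)
for aln in data.alignments:
    io.write_locus_alignment(aln, aln_dir / f"{aln.locus_id}.fasta")
io.write_newick(data.truth.species_tree, out / "true_species_tree.nwk")
io.write_tree_list(data.truth.gene_trees, out / "true_gene_trees.nwk")
io.write_tsv(data.truth.presence, out / "truth_presence.tsv", index=True)
io.write_tsv(pd.DataFrame(data.truth.paralog_injections,
                          columns=["taxon", "contig", "locus_a", "locus_b"]),
             out / "truth_paralogs.tsv")

n_contigs = sum(len(c) for c in data.contigs.values())
print(f"simulated {STUDY.n_taxa} taxa x {STUDY.n_loci} loci "
      f"(seed {STUDY.seed})")
print(f"  contigs written: {n_contigs} "
      f"({len(data.truth.paralog_injections)} injected chimeras)")
print(f"  presence fraction: {data.truth.presence.values.mean():.3f} "
      f"(dropout {STUDY.dropout_prob})")
print(f"  shared-indel truth events: "
      f"{sum(1 for e in data.truth.indel_events if len(e.taxa) >= 2)}")
print(f"outputs under {out}")
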