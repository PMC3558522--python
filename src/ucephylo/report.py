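"""Pipeline orchestration, enrichment summary statistics, and exports.

``summarize_sample`` reproduces the descriptive statistics a target-
enrichment study reports per sample: contig counts and sizes, the number
of contigs matching reference UCE loci, the number removed as potential
paralogs, and the on-target fractions (UCE contigs / all contigs, and —
when read counts are supplied — reads in UCE contigs / all reads).

``run_pipeline`` drives the whole synthetic-data workflow:
simulate -> match -> supermatrix -> model selection -> gene trees ->
STAR + bootstrap -> indel mapping, writing standard-format outputs and a
run log. It is deterministic given (config, seed).
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import pandas as pd

from . import indels as indels_mod
from . import io, match as match_mod, matrix as matrix_mod, models, star, trees
from .simulate import SimulatedData, SimulationConfig, simulate_dataset

log = logging.getLogger(__name__)


@dataclass
class SampleSummary:
    taxon: str
    n_contigs: int
    avg_contig_size: float
    n_uce_contigs: int
    avg_uce_contig_size: float
    n_multilocus_contigs: int
    contigs_on_target: float
    n_reads: Optional[int] = None
    reads_on_target: Optional[float] = None


def percent(numerator: int, denominator: int) -> int:
    """Whole-number percentage, as support summaries print it."""
    if denominator == 0:
        raise ValueError("zero denominator")
    return round(100.0 * numerator / denominator)


def on_target_fraction(numerator: int, denominator: int) -> float:
    """On-target fraction rounded to 2 decimals; 0 when the denominator is
    zero (with a notice)."""
    if denominator == 0:
        log.info("on-target fraction undefined (zero denominator); using 0")
        return 0.0
    return round(numerator / denominator, 2)


def summarize_sample(
    taxon: str,
    contigs: Mapping[str, str],
    db: match_mod.TaxonLocusDB,
    n_reads: Optional[int] = None,
    reads_in_uce_contigs: Optional[int] = None,
) -> SampleSummary:
    n_contigs = len(contigs)
    uce_ids = {m.contig_id for (t, _), m in db.accepted.items() if t == taxon}
    n_multi = len(db.removed_multilocus_contigs.get(taxon, []))
    sizes = [len(s) for s in contigs.values()]
    uce_sizes = [len(s) for c, s in contigs.items() if c in uce_ids]
    reads_frac = None
    if n_reads is not None and reads_in_uce_contigs is not None:
        reads_frac = on_target_fraction(reads_in_uce_contigs, n_reads)
    return SampleSummary(
        taxon=taxon,
        n_contigs=n_contigs,
        avg_contig_size=round(sum(sizes) / n_contigs, 1) if n_contigs else 0.0,
        n_uce_contigs=len(uce_ids),
        avg_uce_contig_size=(round(sum(uce_sizes) / len(uce_sizes), 1)
                             if uce_sizes else 0.0),
        n_multilocus_contigs=n_multi,
        contigs_on_target=on_target_fraction(len(uce_ids), n_contigs),
        n_reads=n_reads,
        reads_on_target=reads_frac,
    )


def summaries_to_frame(summaries: Sequence[SampleSummary]) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in summaries])


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Flat configuration for an end-to-end synthetic run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    min_identity: float = 0.80
    min_locus_fraction: float = 0.80
    kmer_size: int = 15
    max_missing_fraction: float = 0.5
    n_bootstrap: int = 100
    collapse_threshold: float = 40.0
    run_models: bool = True
    run_star: bool = True
    run_indels: bool = True
    max_model_loci: Optional[int] = None  # cap AICc selection for large runs

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        flat = io.load_config(path)
        sim = SimulationConfig.from_dict(flat)
        kwargs = {k: v for k, v in flat.items()
                  if k in cls.__dataclass_fields__ and k != "simulation"}
        return cls(simulation=sim, **kwargs)


@dataclass
class PipelineResult:
    data: SimulatedData
    db: match_mod.TaxonLocusDB
    retained_loci: List[matrix_mod.LocusAlignment]
    supermatrix: matrix_mod.SuperMatrix
    model_fits: List[models.ModelFit]
    partitions: Dict[str, List[str]]
    gene_trees: List
    star_result: Optional[star.SpeciesTreeResult]
    indel_events: List
    clade_map: Optional[indels_mod.CladeSupportMap]
    summaries: List[SampleSummary]


def run_pipeline(config: PipelineConfig, outdir=None) -> PipelineResult:
    """Execute the configured stages end-to-end on synthetic data. Any
    stage failure is re-raised with the stage name."""
    stage = "simulate"
    try:
        data = simulate_dataset(config.simulation)
        outgroup = config.simulation.outgroup_name

        stage = "match"
        reference = match_mod.ReferenceLocusSet(data.reference)
        matches = match_mod.match_contigs(
            data.contigs, reference,
            min_identity=config.min_identity,
            min_locus_fraction=config.min_locus_fraction,
            kmer_size=config.kmer_size)
        db = match_mod.filter_duplicates(matches)

        stage = "matrix"
        retained = matrix_mod.filter_by_completeness(
            data.alignments, config.max_missing_fraction, data.taxa)
        sm = matrix_mod.build_supermatrix(retained, data.taxa)

        stage = "models"
        fits: List[models.ModelFit] = []
        parts: Dict[str, List[str]] = {}
        if config.run_models:
            cap = config.max_model_loci or len(retained)
            for aln in retained[:cap]:
                try:
                    fits.append(models.select_model_aicc(aln))
                except models.TooFewTaxaError as err:
                    log.info("model selection skipped: %s", err)
            parts = models.group_into_partitions(fits)

        stage = "genetrees"
        gene_trees = []
        for aln in retained:
            gt = trees.gene_tree_from_alignment(aln, outgroup=outgroup)
            if gt is not None:
                gene_trees.append((aln.locus_id, gt))

        stage = "star"
        star_result = None
        if config.run_star:
            star_result = star.multilocus_bootstrap(
                retained, config.n_bootstrap,
                seed=config.simulation.seed, outgroup=outgroup)

        stage = "indels"
        events: List = []
        clade_map = None
        if config.run_indels:
            ingroup = [t for t in data.taxa if t != outgroup]
            events = indels_mod.find_shared_indels(
                retained, ingroup=ingroup, outgroup=outgroup)
            ref_tree = (star_result.tree if star_result is not None
                        else data.truth.species_tree)
            clade_map = indels_mod.map_to_tree(events, ref_tree, ingroup)

        stage = "summarize"
        summaries = [summarize_sample(tx, data.contigs[tx], db)
                     for tx in data.taxa]
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    result = PipelineResult(
        data=data, db=db, retained_loci=retained, supermatrix=sm,
        model_fits=fits, partitions=parts,
        gene_trees=gene_trees, star_result=star_result,
        indel_events=events, clade_map=clade_map, summaries=summaries)
    if outdir is not None:
        export(result, config, outdir)
    return result


def export(result: PipelineResult, config: PipelineConfig, outdir) -> None:
    """Write all stage outputs in standard formats plus a run log."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    data = result.data

    io.write_contigs(data.contigs, out / "contigs")
    io.write_fasta(data.reference, out / "reference_loci.fasta")
    aln_dir = out / "alignments"
    aln_dir.mkdir(exist_ok=True)
    for aln in data.alignments:
        io.write_locus_alignment(aln, aln_dir / f"{aln.locus_id}.fasta")
    io.write_newick(data.truth.species_tree, out / "true_species_tree.nwk")
    io.write_tsv(data.truth.presence, out / "truth_presence.tsv", index=True)

    io.write_tsv(io.db_to_frame(result.db), out / "taxon_locus_db.tsv")
    removed = [{"taxon": t, "contig": c}
               for t, cs in result.db.removed_multilocus_contigs.items()
               for c in cs]
    io.write_tsv(pd.DataFrame(removed, columns=["taxon", "contig"]),
                 out / "removed_multilocus_contigs.tsv")

    io.write_phylip(result.supermatrix, out / "supermatrix.phy")
    io.write_nexus(result.supermatrix, out / "supermatrix.nex")
    stats = pd.DataFrame([{
        "n_taxa": len(result.supermatrix.taxa),
        "n_loci": len(result.supermatrix.partitions),
        "total_length": result.supermatrix.total_length,
        "completeness": round(result.supermatrix.completeness, 4),
        "n_informative": result.supermatrix.n_informative,
    }])
    io.write_tsv(stats, out / "supermatrix_stats.tsv")

    if result.model_fits:
        fits = pd.DataFrame([{
            "locus": f.locus_id, "model": f.model.name,
            "lnL": round(f.lnL, 4), "k": f.k, "n": f.n_sites,
            "AICc": round(f.aicc, 4)} for f in result.model_fits])
        io.write_tsv(fits, out / "model_fits.tsv")
        io.write_raxml_partitions(result.partitions, result.supermatrix,
                                  out / "partitions.txt")

    if result.gene_trees:
        io.write_tree_list([t for _, t in result.gene_trees],
                           out / "gene_trees.nwk")
    if result.star_result is not None:
        io.write_newick(result.star_result.tree, out / "star_tree.nwk")
        collapsed = star.collapse(result.star_result.tree,
                                  config.collapse_threshold)
        io.write_newick(collapsed, out / "star_tree_collapsed.nwk")
        sup = pd.DataFrame(
            [{"split": "|".join(sorted(s)), "support": v}
             for s, v in sorted(result.star_result.support.items(),
                                key=lambda kv: -kv[1])])
        io.write_tsv(sup, out / "star_support.tsv")

    if result.indel_events:
        io.write_tsv(io.events_to_frame(result.indel_events),
                     out / "indel_events.tsv")

    io.write_tsv(summaries_to_frame(result.summaries),
                 out / "sample_summaries.tsv")

    run_log = {
        "seed": config.simulation.seed,
        "config": {**asdict(config.simulation),
                   **{k: v for k, v in asdict(config).items()
                      if k != "simulation"}},
        "n_matches_accepted": len(result.db.accepted),
        "n_loci_retained": len(result.retained_loci),
        "n_gene_trees": len(result.gene_trees),
        "n_indel_events": len(result.indel_events),
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2))
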