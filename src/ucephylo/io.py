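"""Readers and writers for the pipeline's standard formats.

FASTA via Biopython, Newick via dendropy, relaxed PHYLIP and NEXUS
(data + sets blocks) for external concatenated analyses, TSV ledgers via
pandas, and a flat ``key: value`` YAML config. All sequence coordinates in
files are 0-based half-open except the RAxML-style partition file, which is
1-based inclusive as that format requires.
"""
from __future__ import annotations

import re
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import dendropy
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .matrix import LocusAlignment, SuperMatrix

_RESERVED = re.compile(r"[\s()\[\]{}:;,'\"]")


def sanitize_name(name: str) -> str:
    return _RESERVED.sub("_", name)


def sanitize_names(names: Iterable[str]) -> Dict[str, str]:
    """Map original -> sanitized, guaranteed unique."""
    out: Dict[str, str] = {}
    used = set()
    for n in names:
        s = sanitize_name(n)
        base, i = s, 1
        while s in used:
            i += 1
            s = f"{base}_{i}"
        used.add(s)
        out[n] = s
    return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_locus_alignment(aln: LocusAlignment, path) -> None:
    write_fasta(aln.sequences, path)


def read_locus_alignment(path, locus_id: Optional[str] = None
                         ) -> LocusAlignment:
    p = Path(path)
    return LocusAlignment(locus_id or p.stem, read_fasta(p))


def write_contigs(contigs: Mapping[str, Mapping[str, str]], outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for taxon, seqs in contigs.items():
        write_fasta(seqs, outdir / f"{sanitize_name(taxon)}.contigs.fasta")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick",
               suppress_rooting=True, unquoted_underscores=True)


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_tree_list(trees: Sequence[dendropy.Tree], path) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.as_string(schema="newick", suppress_rooting=True,
                                 unquoted_underscores=True).strip() + "\n")


# ---------------------------------------------------------------------------
# supermatrix exports
# ---------------------------------------------------------------------------

def write_phylip(sm: SuperMatrix, path) -> Dict[str, str]:
    """Relaxed PHYLIP; returns the taxon-name sanitisation mapping."""
    mapping = sanitize_names(sm.taxa)
    with open(path, "w") as fh:
        fh.write(f" {len(sm.taxa)} {sm.total_length}\n")
        for tx in sm.taxa:
            fh.write(f"{mapping[tx]}  {sm.sequences[tx]}\n")
    return mapping


def read_phylip(path) -> Tuple[List[str], Dict[str, str]]:
    with open(path) as fh:
        header = fh.readline().split()
        n, ncol = int(header[0]), int(header[1])
        taxa, seqs = [], {}
        for line in fh:
            if not line.strip():
                continue
            name, seq = line.split(None, 1)
            taxa.append(name)
            seqs[name] = seq.strip()
    if len(taxa) != n or any(len(s) != ncol for s in seqs.values()):
        raise ValueError("malformed PHYLIP file")
    return taxa, seqs


def write_nexus(sm: SuperMatrix, path) -> Dict[str, str]:
    """NEXUS with a data block and a sets block of per-locus charsets."""
    mapping = sanitize_names(sm.taxa)
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nbegin data;\n")
        fh.write(f"  dimensions ntax={len(sm.taxa)} nchar={sm.total_length};\n")
        fh.write("  format datatype=dna missing=? gap=-;\n  matrix\n")
        for tx in sm.taxa:
            fh.write(f"    {mapping[tx]}  {sm.sequences[tx]}\n")
        fh.write("  ;\nend;\n\nbegin sets;\n")
        for lid, (s, e) in sm.partitions.items():
            fh.write(f"  charset {sanitize_name(lid)} = {s + 1}-{e};\n")
        fh.write("end;\n")
    return mapping


def read_nexus_charsets(path) -> Dict[str, Tuple[int, int]]:
    """Charset intervals from a sets block, back in 0-based half-open form."""
    out: Dict[str, Tuple[int, int]] = {}
    pat = re.compile(r"charset\s+(\S+)\s*=\s*(\d+)-(\d+)\s*;")
    for m in pat.finditer(Path(path).read_text()):
        out[m.group(1)] = (int(m.group(2)) - 1, int(m.group(3)))
    return out


def write_raxml_partitions(partitions: Mapping[str, Sequence[str]],
                           sm: SuperMatrix, path) -> None:
    """RAxML-style partition file: one line per model group, 1-based
    inclusive locus intervals."""
    with open(path, "w") as fh:
        for model, loci in partitions.items():
            ivs = ", ".join(f"{sm.partitions[l][0] + 1}-{sm.partitions[l][1]}"
                            for l in loci if l in sm.partitions)
            if ivs:
                fh.write(f"DNA, {sanitize_name(model)} = {ivs}\n")


# ---------------------------------------------------------------------------
# TSV ledgers
# ---------------------------------------------------------------------------

def write_tsv(frame: pd.DataFrame, path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index)


def read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)


def db_to_frame(db) -> pd.DataFrame:
    rows = [
        {"taxon": t, "locus": l, "contig": m.contig_id,
         "identity": round(m.identity, 4),
         "fraction": round(m.aligned_fraction_of_locus, 4)}
        for (t, l), m in sorted(db.accepted.items())
    ]
    return pd.DataFrame(rows, columns=["taxon", "locus", "contig",
                                       "identity", "fraction"])


def events_to_frame(events, classification: Optional[Mapping] = None
                    ) -> pd.DataFrame:
    rows = []
    for ev in events:
        rows.append({
            "locus": ev.locus_id, "start": ev.start, "end": ev.end,
            "length": ev.length,
            "taxa": ",".join(sorted(ev.sharing_taxa)),
            "outgroup_state": ev.outgroup_state,
        })
    return pd.DataFrame(rows, columns=["locus", "start", "end", "length",
                                       "taxa", "outgroup_state"])


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    """Flat ``key: value`` YAML config."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError("config must be a flat key: value mapping")
    return data


def save_config(cfg: Mapping, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, default_flow_style=False,
                       sort_keys=True)
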