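"""Readers and writers for the standard formats the pipeline consumes."""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .simulate import ReadSet, RefRecord, TERecord

TE_CLASSES = ("DNA", "LINE", "SINE", "LTR", "Helitron")

# RepeatMasker-style class strings -> the five TE classes quantified here
_CLASS_ALIASES = {
    "DNA": "DNA", "TIR": "DNA",
    "LINE": "LINE", "SINE": "SINE",
    "LTR": "LTR",
    "RC": "Helitron", "HELITRON": "Helitron",
}


def _open(path):
    path = str(path)
    return gzip.open(path, "rt") if path.endswith(".gz") else open(path)


def read_fastq(path: str | Path) -> ReadSet:
    names, seqs = [], []
    with _open(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            names.append(rec.description)
            seqs.append(str(rec.seq).upper())
    if not seqs:
        raise ValueError(f"no reads in {path}")
    n = len(seqs)
    return ReadSet(names=names, seqs=seqs, sources=[""] * n,
                   positions=np.zeros(n, dtype=np.int64),
                   strands=np.zeros(n, dtype=np.uint8))


def read_fasta(path: str | Path) -> dict[str, str]:
    with _open(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    with _open(path) as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


def read_te_library(path: str | Path) -> list[TERecord]:
    """TE library FASTA with ``name#Class/Family`` headers.

    Classes that do not map to the five quantified TE classes are kept verbatim
    so downstream annotation can route their hits to the unknown-repeat bucket.
    """
    out = []
    with _open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            header = rec.id
            name, te_class, family = header, "unknown", ""
            if "#" in header:
                name, rest = header.split("#", 1)
                cls = rest.split("/", 1)
                te_class = _CLASS_ALIASES.get(cls[0].upper(), cls[0])
                family = cls[1] if len(cls) > 1 else ""
            out.append(TERecord(name=name, te_class=te_class, family=family,
                                seq=str(rec.seq).upper()))
    if not out:
        raise ValueError(f"empty TE library: {path}")
    return out


def read_gff3_genes(path: str | Path) -> pd.DataFrame:
    """Gene records from a GFF3 file (0-based half-open internally).

    Returns columns gene_id, scaffold, start, end, strand, rank; ranks are
    consecutive per scaffold in start order.
    """
    rows = []
    with _open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID") or attrs.get("Name")
            rows.append(dict(gene_id=gid, scaffold=f[0], start=int(f[3]) - 1,
                             end=int(f[4]), strand=f[6]))
    if not rows:
        raise ValueError(f"no gene features in {path}")
    return add_gene_ranks(pd.DataFrame(rows))


def add_gene_ranks(genes: pd.DataFrame) -> pd.DataFrame:
    genes = genes.sort_values(["scaffold", "start"]).reset_index(drop=True)
    genes["rank"] = genes.groupby("scaffold").cumcount()
    return genes


def read_reference_labels(path: str | Path) -> dict[str, str]:
    labels = {}
    with _open(path) as fh:
        for line in fh:
            rec_id, label = line.rstrip("\n").split("\t")
            labels[rec_id] = label
    return labels


def load_reference_db(fasta: str | Path, labels: str | Path) -> list[RefRecord]:
    lab = read_reference_labels(labels)
    seqs = read_protein_fasta(fasta)
    return [RefRecord(id=rid, label=lab[rid], seq=seq)
            for rid, seq in seqs.items() if rid in lab]
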