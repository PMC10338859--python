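"""File-format helpers: FASTA, FASTQ, BED6, GFF3.

Conventions: all in-memory coordinates are 0-based half-open.  BED6 is written
as-is; GFF3 is converted to/from 1-based inclusive on write/read.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]

_RC = str.maketrans("ACGTUacgtu", "TGCAATGCAA")


def revcomp(seq: str) -> str:
    """Reverse complement (DNA alphabet; U treated as T)."""
    return seq.translate(_RC)[::-1]


def write_fasta(sequences: dict[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, os.fspath(path), "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(os.fspath(path), "fasta")}


def write_fastq(reads: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    """Write ``(read_id, sequence)`` pairs with uniform placeholder qualities."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def iter_fastq(path: str | os.PathLike) -> Iterator[tuple[str, str]]:
    for rec in SeqIO.parse(os.fspath(path), "fastq"):
        yield rec.id, str(rec.seq).upper()


def write_bed6(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.loc[:, BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed6(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=BED6_COLUMNS, dtype={"chrom": str, "name": str})
    bad = df[(df.start < 0) | (df.start >= df.end)]
    if len(bad):
        raise ValueError(f"malformed BED interval: {bad.iloc[0].tolist()}")
    return df


def write_gff3(genes: pd.DataFrame, features: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write gene models as GFF3 (1-based inclusive on disk).

    ``genes``: gene_id, chrom, start, end, strand, biotype (0-based half-open).
    ``features``: gene_id, chrom, type, start, end, strand.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.itertuples():
            fh.write(
                f"{g.chrom}\tprclip\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};gene_id={g.gene_id};gene_biotype={g.biotype}\n"
            )
            sub = features[features.gene_id == g.gene_id]
            for i, f in enumerate(sub.itertuples()):
                fh.write(
                    f"{f.chrom}\tprclip\t{f.type}\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t"
                    f"ID={g.gene_id}.{f.type}.{i};Parent={g.gene_id}\n"
                )


def read_gff3(path: str | os.PathLike) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a GFF3 annotation into (genes, features) frames, 0-based half-open."""
    db = gffutils.create_db(
        os.fspath(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes, feats = [], []
    for g in db.features_of_type("gene"):
        gid = g.attributes.get("gene_id", [g.id])[0]
        biotype = g.attributes.get("gene_biotype", ["protein_coding"])[0]
        genes.append((gid, g.seqid, g.start - 1, g.end, g.strand, biotype))
    for ftype in ("exon", "CDS", "five_prime_UTR", "three_prime_UTR"):
        for f in db.features_of_type(ftype):
            parents = f.attributes.get("Parent", [])
            gid = parents[0] if parents else f.attributes.get("gene_id", [f.id])[0]
            feats.append((gid, f.seqid, ftype, f.start - 1, f.end, f.strand))
    genes_df = pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end", "strand", "biotype"])
    feats_df = pd.DataFrame(feats, columns=["gene_id", "chrom", "type", "start", "end", "strand"])
    if genes_df.empty:
        raise ValueError(f"no gene features found in {path}")
    return genes_df, feats_df
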