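"""Raw reads + alignments -> unique, strand-aware crosslink events.

Stages, mirroring standard iCLIP processing: demultiplex by experimental
barcode (UMI retained as metadata, barcode/UMI stripped from the insert and
the 3' adaptor trimmed); collapse PCR duplicates on (reference, start,
strand, UMI); assign each unique cDNA's crosslink site as the nucleotide
immediately 5' of its aligned 5' end — the truncation model, in which reverse
transcription stops one nucleotide short of the crosslinked base.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import pandas as pd
import pysam

from prclip import io as pio


@dataclass
class LibraryLayout:
    """Read structure: experimental barcode, then UMI, then insert (+3' adaptor)."""

    barcode_map: dict[str, str]  # barcode sequence -> sample name
    umi_length: int
    max_barcode_mismatches: int = 0
    three_prime_adaptor: str = ""
    min_insert_length: int = 18

    def __post_init__(self):
        if not self.barcode_map:
            raise ValueError("barcode map is empty")
        lengths = {len(b) for b in self.barcode_map}
        if len(lengths) != 1:
            raise ValueError("all barcodes must share one length")
        self.barcode_length = lengths.pop()
        bcs = list(self.barcode_map)
        for i, b1 in enumerate(bcs):
            for b2 in bcs[i + 1 :]:
                dist = sum(x != y for x, y in zip(b1, b2))
                if dist <= 2 * self.max_barcode_mismatches:
                    raise ValueError(
                        f"barcodes {b1}/{b2} not distinguishable at "
                        f"{self.max_barcode_mismatches} mismatches"
                    )

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "LibraryLayout":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            barcode_map=d["barcode_map"],
            umi_length=int(d["umi_length"]),
            max_barcode_mismatches=int(d.get("max_barcode_mismatches", 0)),
            three_prime_adaptor=d.get("three_prime_adaptor", ""),
            min_insert_length=int(d.get("min_insert_length", 18)),
        )


@dataclass
class DemuxResult:
    #: sample -> frame with columns read_id, umi, insert
    assigned: dict[str, pd.DataFrame]
    unassigned: int
    too_short: int = 0

    def report(self) -> pd.DataFrame:
        rows = [{"sample": s, "reads": len(df)} for s, df in self.assigned.items()]
        rows.append({"sample": "(unassigned)", "reads": self.unassigned})
        rows.append({"sample": "(too_short)", "reads": self.too_short})
        return pd.DataFrame(rows)


def _trim_adaptor(seq: str, adaptor: str, min_overlap: int = 3) -> str:
    """Remove a 3' adaptor: full match anywhere, else adaptor-prefix overlap
    at the read's 3' end."""
    if not adaptor:
        return seq
    i = seq.find(adaptor)
    if i >= 0:
        return seq[:i]
    for k in range(min(len(adaptor), len(seq)) - 1, min_overlap - 1, -1):
        if seq.endswith(adaptor[:k]):
            return seq[: len(seq) - k]
    return seq


def _match_barcode(bc: str, layout: LibraryLayout) -> str | None:
    if bc in layout.barcode_map:
        return layout.barcode_map[bc]
    if layout.max_barcode_mismatches > 0:
        for cand, sample in layout.barcode_map.items():
            if sum(x != y for x, y in zip(bc, cand)) <= layout.max_barcode_mismatches:
                return sample
    return None


def demultiplex(reads, layout: LibraryLayout) -> DemuxResult:
    """Assign reads to samples by experimental barcode.

    ``reads``: iterable of (read_id, sequence) or a FASTQ path.  The barcode
    and UMI are stripped from the stored insert (UMI kept as metadata) and
    the 3' adaptor is trimmed.  Inserts shorter than ``min_insert_length``
    after trimming are discarded and counted.
    """
    if isinstance(reads, (str, os.PathLike)):
        reads = pio.iter_fastq(reads)
    nb, nu = layout.barcode_length, layout.umi_length
    per_sample: dict[str, list[tuple[str, str, str]]] = {s: [] for s in layout.barcode_map.values()}
    unassigned = too_short = 0
    for rid, seq in reads:
        sample = _match_barcode(seq[:nb], layout)
        if sample is None:
            unassigned += 1
            continue
        umi = seq[nb : nb + nu]
        insert = _trim_adaptor(seq[nb + nu :], layout.three_prime_adaptor)
        if len(insert) < layout.min_insert_length:
            too_short += 1
            continue
        per_sample[sample].append((rid, umi, insert))
    assigned = {
        s: pd.DataFrame(rows, columns=["read_id", "umi", "insert"]) for s, rows in per_sample.items()
    }
    return DemuxResult(assigned=assigned, unassigned=unassigned, too_short=too_short)


def read_alignments(path: str | os.PathLike, min_mapq: int = 20) -> pd.DataFrame:
    """Load alignments as a frame (read_id, chrom, start, end, strand).

    BED6: intervals taken as-is (all treated as uniquely mapping).  SAM/BAM:
    unmapped, secondary and supplementary records and records with mapping
    quality below ``min_mapq`` are excluded — the uniquely-mapping filter
    without relying on aligner-specific uniqueness tags.
    """
    path = os.fspath(path)
    if path.endswith((".sam", ".bam", ".cram")):
        rows = []
        with pysam.AlignmentFile(path, check_sq=False) as fh:
            for rec in fh:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                if rec.mapping_quality < min_mapq:
                    continue
                rows.append(
                    (
                        rec.query_name,
                        rec.reference_name,
                        rec.reference_start,
                        rec.reference_end,
                        "-" if rec.is_reverse else "+",
                    )
                )
        return pd.DataFrame(rows, columns=["read_id", "chrom", "start", "end", "strand"])
    bed = pio.read_bed6(path)
    return bed.rename(columns={"name": "read_id"})[["read_id", "chrom", "start", "end", "strand"]]


def collapse_duplicates(aligned: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Collapse PCR duplicates to one representative per (chrom, start,
    strand, UMI) group.  Reads without a UMI are rejected and counted.
    Idempotent.  Returns (unique frame with duplicate_count, stats)."""
    required = {"chrom", "start", "strand", "umi"}
    if not required.issubset(aligned.columns):
        raise ValueError(f"alignment frame must have columns {sorted(required)}")
    missing = aligned.umi.isna() | (aligned.umi == "")
    rejected = int(missing.sum())
    ok = aligned[~missing]
    key = ["chrom", "start", "strand", "umi"]
    grouped = ok.groupby(key, sort=False, as_index=False)
    unique = grouped.first()
    unique["duplicate_count"] = grouped.size()["size"].to_numpy()
    stats = {
        "input_reads": int(len(aligned)),
        "rejected_no_umi": rejected,
        "unique_cdnas": int(len(unique)),
    }
    return unique, stats


def assign_crosslink_sites(
    unique: pd.DataFrame, reference_lengths: dict[str, int] | None = None
) -> tuple[pd.DataFrame, int]:
    """Crosslink site = nucleotide preceding the cDNA 5' end.

    Plus strand: position = start - 1; minus strand: position = end.  Reads
    whose site would fall outside the reference are dropped and counted.
    Returns (events frame with chrom/position/strand, n_dropped).
    """
    df = unique.copy()
    plus = df.strand == "+"
    df["position"] = df["end"].where(~plus, df["start"] - 1)
    keep = df.position >= 0
    if reference_lengths:
        lens = df.chrom.map(reference_lengths)
        keep &= df.position < lens
    dropped = int((~keep).sum())
    events = df.loc[keep, [c for c in df.columns if c in ("read_id", "chrom", "position", "strand", "umi", "sample", "duplicate_count")]]
    return events.reset_index(drop=True), dropped


def extract_events(
    fastq: str | os.PathLike,
    alignments: str | os.PathLike | pd.DataFrame,
    layout: LibraryLayout,
    reference_lengths: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """FASTQ + alignments -> per-sample unique crosslink events.

    Joins demultiplexed reads (sample, UMI) to their alignments by read id,
    collapses duplicates per sample and assigns crosslink sites.  Returns
    (events frame with sample/chrom/position/strand/duplicate_count, report).
    """
    demux = demultiplex(fastq, layout)
    if isinstance(alignments, pd.DataFrame):
        aln = alignments
    else:
        aln = read_alignments(alignments)
    all_events = []
    report_rows = []
    for sample, reads in demux.assigned.items():
        merged = reads.merge(aln, on="read_id", how="inner")
        unique, stats = collapse_duplicates(merged)
        events, dropped = assign_crosslink_sites(unique, reference_lengths)
        events.insert(0, "sample", sample)
        all_events.append(events)
        report_rows.append(
            {
                "sample": sample,
                "demux_reads": len(reads),
                "aligned_reads": len(merged),
                "unique_cdnas": stats["unique_cdnas"],
                "rejected_no_umi": stats["rejected_no_umi"],
                "boundary_dropped": dropped,
                "events": len(events),
            }
        )
    report = pd.DataFrame(report_rows)
    report.loc[len(report)] = {
        "sample": "(unassigned)",
        "demux_reads": demux.unassigned,
        "aligned_reads": 0,
        "unique_cdnas": 0,
        "rejected_no_umi": 0,
        "boundary_dropped": 0,
        "events": 0,
    }
    return pd.concat(all_events, ignore_index=True), report


def events_to_bed(events: pd.DataFrame) -> pd.DataFrame:
    """One BED6 row per event: name = sample, score = 1."""
    return pd.DataFrame(
        {
            "chrom": events.chrom,
            "start": events.position,
            "end": events.position + 1,
            "name": events["sample"],
            "score": 1,
            "strand": events.strand,
        }
    )
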