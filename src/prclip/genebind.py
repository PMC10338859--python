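"""Gene-level binding quantification, bound-gene filtering, region annotation.

A gene is called bound when it carries at least ``min_events`` unique
crosslink events in the crosslinked DPR sample and the depth-normalized
(CPM) signal in each control condition (non-crosslinked and tag-only) stays
below ``max_control_fraction`` of the DPR signal.  Crosslink events are also
classified into genomic region classes with the precedence
CDS > 5'UTR > 3'UTR > non-coding-RNA exon > intron > intergenic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

REGION_PRECEDENCE = ("CDS", "five_prime_UTR", "three_prime_UTR", "ncRNA_exon", "intron", "intergenic")


def count_gene_events(events: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Per-gene, per-sample unique-event counts.

    An event counts toward a gene iff its position lies within the gene span
    (half-open) on the same strand.  Events outside all genes are tallied in
    an ``(intergenic)`` row.  Columns are samples, rows gene ids.
    """
    for col in ("gene_id", "chrom", "start", "end", "strand"):
        if col not in genes.columns:
            raise ValueError(f"malformed annotation: missing column {col!r}")
    bad = genes[(genes.start < 0) | (genes.start >= genes.end)]
    if len(bad):
        raise ValueError(f"malformed annotation record: {bad.iloc[0].to_dict()}")
    trees: dict[tuple[str, str], IntervalTree] = {}
    for g in genes.itertuples():
        trees.setdefault((g.chrom, g.strand), IntervalTree()).addi(g.start, g.end, g.gene_id)
    samples = sorted(events["sample"].unique())
    index = list(genes.gene_id) + ["(intergenic)"]
    out = pd.DataFrame(0, index=pd.Index(index, name="gene_id"), columns=samples, dtype=int)
    for row in events.itertuples():
        tree = trees.get((row.chrom, row.strand))
        hits = tree[row.position] if tree is not None else set()
        if hits:
            for h in hits:
                out.loc[h.data, row.sample] += 1
        else:
            out.loc["(intergenic)", row.sample] += 1
    return out


def summarize_binding(
    counts: pd.DataFrame,
    pr_samples: list[str],
    control_samples: list[str],
    min_events: int = 200,
    max_control_fraction: float = 0.10,
    normalization: str = "counts",
) -> pd.DataFrame:
    """Build the per-gene binding summary table.

    Event counts of the DPR-crosslinked samples (``pr_samples``) are pooled.
    The control fraction is the max over control samples of the gene's
    control/PR signal ratio.  With ``normalization="counts"`` (default) the
    ratio uses unique-event counts, so a control library's low yield — the
    hallmark of a non-crosslinked or tag-only condition — counts as evidence
    of specificity; with ``"cpm"`` each sample is first scaled to counts per
    million, asking instead whether the gene's *share* of the control
    library is below the threshold.  ``bound`` requires events_PR >=
    min_events and control_fraction < max_control_fraction.  The
    normalization used is recorded in ``summary.attrs``.
    """
    if normalization not in ("counts", "cpm"):
        raise ValueError("normalization must be 'counts' or 'cpm'")
    totals = counts.sum(axis=0)
    if (totals[pr_samples] == 0).any():
        raise ValueError("a PR sample has zero events")
    cpm = counts * 1e6 / totals
    gene_rows = counts.index != "(intergenic)"
    events_pr = counts.loc[gene_rows, pr_samples].sum(axis=1)
    cpm_pr = cpm.loc[gene_rows, pr_samples].sum(axis=1)
    bad = (cpm_pr == 0) & (events_pr > 0)
    if bad.any():
        raise ValueError(f"internal inconsistency: zero CPM with nonzero events at {list(counts.index[gene_rows][bad])}")
    summary = pd.DataFrame({"events_PR": events_pr, "cpm_PR": cpm_pr})
    frac = pd.DataFrame(index=summary.index)
    for ctl in control_samples:
        summary[f"events_{ctl}"] = counts.loc[gene_rows, ctl]
        summary[f"cpm_{ctl}"] = cpm.loc[gene_rows, ctl]
        if normalization == "cpm":
            num, den = cpm.loc[gene_rows, ctl].to_numpy(float), cpm_pr.to_numpy(float)
        else:
            num = counts.loc[gene_rows, ctl].to_numpy(float)
            den = events_pr.to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            frac[ctl] = np.where(den > 0, num / den, np.where(num > 0, np.inf, 0.0))
    summary["control_fraction"] = frac.max(axis=1) if control_samples else 0.0
    summary["bound"] = (summary.events_PR >= min_events) & (summary.control_fraction < max_control_fraction)
    summary.attrs["normalization"] = normalization
    return summary


def filter_bound_genes(
    summary: pd.DataFrame, min_events: int = 200, max_control_fraction: float = 0.10
) -> pd.DataFrame:
    """Bound-gene list: events_PR >= min_events and control_fraction <
    max_control_fraction, sorted by events_PR descending."""
    bound = (summary.events_PR >= min_events) & (summary.control_fraction < max_control_fraction)
    return summary[bound].sort_values("events_PR", ascending=False)


def _feature_trees(genes: pd.DataFrame, features: pd.DataFrame) -> dict:
    trees: dict[tuple[str, str, str], IntervalTree] = {}

    def add(chrom, strand, cls, start, end):
        trees.setdefault((chrom, strand, cls), IntervalTree()).addi(start, end, cls)

    biotype = genes.set_index("gene_id").biotype
    for f in features.itertuples():
        if f.type in ("CDS", "five_prime_UTR", "three_prime_UTR"):
            add(f.chrom, f.strand, f.type, f.start, f.end)
        elif f.type == "exon" and biotype.get(f.gene_id, "protein_coding") != "protein_coding":
            add(f.chrom, f.strand, "ncRNA_exon", f.start, f.end)
    for g in genes.itertuples():
        add(g.chrom, g.strand, "gene_span", g.start, g.end)
    return trees


def annotate_regions(
    events: pd.DataFrame,
    genes: pd.DataFrame,
    features: pd.DataFrame,
    precedence: tuple[str, ...] = REGION_PRECEDENCE,
) -> tuple[pd.Series, pd.Series]:
    """Classify each event into exactly one genomic region class.

    Returns (per-event class Series, class-proportion Series summing to 1).
    An event inside a gene span but no annotated exonic feature is intronic.
    """
    known = set(genes.chrom)
    unknown = set(events.chrom) - known
    if unknown:
        raise ValueError(f"events on unknown reference(s): {sorted(unknown)}")
    trees = _feature_trees(genes, features)
    classes = []
    for row in events.itertuples():
        cls = "intergenic"
        for cand in precedence:
            if cand == "intron":
                t = trees.get((row.chrom, row.strand, "gene_span"))
                if t is not None and t[row.position]:
                    cls = "intron"
                    break
            elif cand == "intergenic":
                break
            else:
                t = trees.get((row.chrom, row.strand, cand))
                if t is not None and t[row.position]:
                    cls = cand
                    break
        classes.append(cls)
    ser = pd.Series(classes, index=events.index, name="region")
    props = ser.value_counts(normalize=True).reindex(list(precedence), fill_value=0.0)
    return ser, props
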