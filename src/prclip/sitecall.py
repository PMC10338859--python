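"""CPM normalization, sample QC and permutation-FDR crosslink-site calling.

A crosslink site's score is the number of events in a +/-w nt window around
it.  Significance is assessed per gene against a permutation null in which
the gene's n events are redistributed uniformly at random over the gene's
positions: for each observed event position p,

    FDR(p) = min(1, E_perm[# permuted event-positions with score >= s(p)]
                    / # observed event-positions with score >= s(p))

made monotone non-increasing in score by a cumulative minimum from high
score to low.  Positions are retained at FDR < threshold.  Events outside
any annotated gene are tested within fixed-width intergenic tiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CrosslinkTrack:
    """Per-position unique crosslink-event counts for one sample."""

    counts: pd.DataFrame  # chrom, strand, position, count
    sample: str = ""

    def __post_init__(self):
        if len(self.counts) and (self.counts["count"] < 1).any():
            raise ValueError("stored positions must have count >= 1")

    @classmethod
    def from_events(cls, events: pd.DataFrame, sample: str = "") -> "CrosslinkTrack":
        counts = (
            events.groupby(["chrom", "strand", "position"], as_index=False)
            .size()
            .rename(columns={"size": "count"})
        )
        return cls(counts=counts, sample=sample)

    @property
    def total_events(self) -> int:
        return int(self.counts["count"].sum())


def cpm_normalize(track: CrosslinkTrack) -> pd.DataFrame:
    """Counts-per-million track: value(p) = count(p) * 1e6 / total events."""
    total = track.total_events
    if total == 0:
        raise ValueError("cannot CPM-normalize an empty track")
    out = track.counts.copy()
    out["cpm"] = out["count"] * 1e6 / total
    return out


def sample_qc(track: CrosslinkTrack, min_events: int = 300_000) -> dict:
    """Unique-event depth QC: pass iff total events >= ``min_events``.

    The default threshold is the depth below which a sample is excluded from
    gene-level analysis.
    """
    total = track.total_events
    return {
        "sample": track.sample,
        "unique_crosslink_events": total,
        "min_events": min_events,
        "pass": total >= min_events,
    }


def call_significant_sites(
    positions: np.ndarray,
    gene_span: tuple[int, int],
    half_window: int = 3,
    n_perm: int = 100,
    fdr_threshold: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Permutation-FDR site calling within one gene.

    ``positions``: genomic coordinates of the gene's events (one entry per
    event; repeats mean multiple events at a position).  Returns a frame with
    one row per distinct event position: position, count, window_score, fdr,
    significant.  FDR is evaluated only at observed event positions; tied
    scores share one FDR value.
    """
    gs, ge = gene_span
    glen = ge - gs
    if glen <= 0:
        raise ValueError(f"empty gene span {gene_span}")
    positions = np.asarray(positions, dtype=np.int64)
    cols = ["position", "count", "window_score", "fdr", "significant"]
    if len(positions) == 0:
        return pd.DataFrame(columns=cols)
    if positions.min() < gs or positions.max() >= ge:
        raise ValueError("event positions outside the gene span")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    counts = np.bincount(positions - gs, minlength=glen)
    n = int(counts.sum())
    kernel = np.ones(2 * half_window + 1)
    score = np.convolve(counts, kernel, mode="same")
    obs_idx = np.nonzero(counts)[0]
    obs_scores = score[obs_idx]

    uniq = np.unique(obs_scores)  # ascending
    sorted_obs = np.sort(obs_scores)
    # observed event-positions with score >= s, per unique score s
    obs_ge = len(sorted_obs) - np.searchsorted(sorted_obs, uniq, side="left")

    perm_ge = np.zeros(len(uniq))
    p_uniform = np.full(glen, 1.0 / glen)
    for _ in range(n_perm):
        pcounts = rng.multinomial(n, p_uniform)
        pscore = np.convolve(pcounts, kernel, mode="same")
        pvals = np.sort(pscore[pcounts > 0])
        perm_ge += len(pvals) - np.searchsorted(pvals, uniq, side="left")
    perm_ge /= n_perm

    fdr_by_score = np.minimum(1.0, perm_ge / obs_ge)
    # monotone non-increasing in score: a higher score never reports a worse
    # FDR than any lower one (running minimum over ascending scores)
    fdr_by_score = np.minimum.accumulate(fdr_by_score)
    score_to_fdr = dict(zip(uniq, fdr_by_score))
    fdr = np.array([score_to_fdr[s] for s in obs_scores])

    return pd.DataFrame(
        {
            "position": obs_idx + gs,
            "count": counts[obs_idx],
            "window_score": obs_scores,
            "fdr": fdr,
            "significant": fdr < fdr_threshold,
        }
    )[cols]


def call_sites(
    events: pd.DataFrame,
    genes: pd.DataFrame,
    half_window: int = 3,
    n_perm: int = 100,
    fdr_threshold: float = 0.05,
    seed: int | None = 0,
    intergenic_tile: int = 10_000,
    keep_all: bool = False,
) -> pd.DataFrame:
    """Genome-wide site calling: per annotated gene, then per intergenic tile.

    ``events``: chrom, position, strand.  ``genes``: gene_id, chrom, start,
    end, strand.  Events not inside any same-strand gene are grouped into
    fixed-width tiles (``intergenic_tile`` nt) serving as pseudo-genes.
    Returns significant sites only unless ``keep_all``.
    """
    rng = np.random.default_rng(seed)
    ev = events.copy()
    ev["gene_id"] = None
    for g in genes.sort_values(["chrom", "start"]).itertuples():
        mask = (
            (ev.chrom == g.chrom)
            & (ev.strand == g.strand)
            & (ev.position >= g.start)
            & (ev.position < g.end)
        )
        ev.loc[mask & ev.gene_id.isna(), "gene_id"] = g.gene_id

    results = []
    gspans = genes.set_index("gene_id")
    for gid, grp in ev[ev.gene_id.notna()].groupby("gene_id", sort=True):
        g = gspans.loc[gid]
        res = call_significant_sites(
            grp.position.to_numpy(), (int(g.start), int(g.end)), half_window, n_perm, fdr_threshold, rng
        )
        res.insert(0, "gene_id", gid)
        res.insert(1, "chrom", g.chrom)
        res["strand"] = g.strand
        results.append(res)

    inter = ev[ev.gene_id.isna()].copy()
    if len(inter):
        inter["tile"] = inter.position // intergenic_tile
        for (chrom, strand, tile), grp in inter.groupby(["chrom", "strand", "tile"], sort=True):
            span = (int(tile * intergenic_tile), int((tile + 1) * intergenic_tile))
            res = call_significant_sites(
                grp.position.to_numpy(), span, half_window, n_perm, fdr_threshold, rng
            )
            res.insert(0, "gene_id", f"intergenic:{chrom}:{span[0]}-{span[1]}:{strand}")
            res.insert(1, "chrom", chrom)
            res["strand"] = strand
            results.append(res)

    if not results:
        return pd.DataFrame(
            columns=["gene_id", "chrom", "position", "count", "window_score", "fdr", "significant", "strand"]
        )
    out = pd.concat(results, ignore_index=True)
    return out if keep_all else out[out.significant].reset_index(drop=True)


def sites_to_bed(sites: pd.DataFrame, score_cap: float = 1000.0) -> pd.DataFrame:
    """BED6 of sites; score = -10*log10(FDR), capped (FDR 0 maps to the cap)."""
    with np.errstate(divide="ignore"):
        score = np.minimum(-10.0 * np.log10(sites.fdr.to_numpy()), score_cap)
    return pd.DataFrame(
        {
            "chrom": sites.chrom,
            "start": sites.position,
            "end": sites.position + 1,
            "name": sites.gene_id,
            "score": np.round(score, 2),
            "strand": sites.strand,
        }
    )
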