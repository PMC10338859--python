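"""Pentamer enrichment around crosslink sites with a matched background.

Foreground windows span 5 nt upstream to 30 nt downstream of each
significant crosslink site (36 nt, transcript orientation, RNA sense).
Background windows of the same length are drawn uniformly from the same
genes, matched 1:1 per gene, restricted to spans overlapping no significant
site.  Each of the 1,024 pentamers is tested with a one-sided Fisher exact
test on window presence/absence counts (does the pentamer occur in more
foreground than background windows than expected), computed in log space so
that extremely small p-values (far below double underflow) remain exact;
correction is Bonferroni over the 1,024 tests.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom

from prclip import io as pio

RNA_ALPHABET = "ACGU"
ALL_PENTAMERS = ["".join(p) for p in product(RNA_ALPHABET, repeat=5)]

_IUPAC_RNA = {
    "A": "A", "C": "C", "G": "G", "U": "U", "T": "U",
    "R": "[AG]", "Y": "[CU]", "S": "[CG]", "W": "[AU]", "K": "[GU]", "M": "[AC]",
    "B": "[CGU]", "D": "[AGU]", "H": "[ACU]", "V": "[ACG]", "N": "[ACGU]",
}


def iupac_regex(motif: str) -> re.Pattern:
    """Compile an IUPAC-degenerate RNA motif (e.g. GANGA) to a regex."""
    try:
        pat = "".join(_IUPAC_RNA[c] for c in motif.upper())
    except KeyError as e:
        raise ValueError(f"invalid IUPAC code {e.args[0]!r} in motif {motif!r}") from None
    return re.compile(pat)


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Substring [start, end) from a dict of sequences or a pyfaidx.Fasta."""
    if isinstance(genome, dict):
        return genome[chrom][start:end].upper()
    return str(genome[chrom][start:end]).upper()


def _to_rna(seq: str, strand: str) -> str:
    if strand == "-":
        seq = pio.revcomp(seq)
    return seq.upper().replace("T", "U")


@dataclass
class MotifWindowSet:
    """Equal-length RNA-sense windows with their source genes."""

    windows: list[str]
    gene_ids: list[str]
    origin: str  # foreground | background
    n_dropped: int = 0
    length: int = field(init=False)

    def __post_init__(self):
        lengths = {len(w) for w in self.windows}
        if len(lengths) > 1:
            raise ValueError("windows of unequal length")
        self.length = lengths.pop() if lengths else 0

    def __len__(self) -> int:
        return len(self.windows)


def extract_windows(
    sites: pd.DataFrame,
    genome,
    genes: pd.DataFrame,
    upstream: int = 5,
    downstream: int = 30,
) -> MotifWindowSet:
    """Foreground windows: site-5 .. site+30 in transcript orientation.

    Plus-strand site p maps to genomic [p-5, p+31); minus strand to
    [p-30, p+6), reverse-complemented.  Windows truncated by their gene's
    ends are dropped and counted.
    """
    spans = genes.set_index("gene_id")[["start", "end"]]
    wlen = upstream + downstream + 1
    windows, gids, dropped = [], [], 0
    for s in sites.itertuples():
        g = spans.loc[s.gene_id]
        if s.strand == "+":
            a, b = s.position - upstream, s.position + downstream + 1
        else:
            a, b = s.position - downstream, s.position + upstream + 1
        if a < g.start or b > g.end:
            dropped += 1
            continue
        if s.chrom not in (genome.keys() if isinstance(genome, dict) else genome):
            raise ValueError(f"no reference sequence for {s.chrom}")
        seq = _to_rna(_fetch(genome, s.chrom, a, b), s.strand)
        assert len(seq) == wlen
        windows.append(seq)
        gids.append(s.gene_id)
    return MotifWindowSet(windows, gids, "foreground", n_dropped=dropped)


def sample_background_windows(
    sites: pd.DataFrame,
    genome,
    genes: pd.DataFrame,
    foreground: MotifWindowSet,
    rng: np.random.Generator | int | None = 0,
    window_length: int | None = None,
) -> MotifWindowSet:
    """Background windows from the foreground genes, avoiding significant sites.

    A start is eligible iff its window lies inside the gene and overlaps no
    significant crosslink site.  Per-gene multiplicity matches the
    foreground; genes with no eligible position are skipped with a warning
    and their multiplicity reassigned uniformly over the pooled eligible
    positions of the remaining genes.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    wlen = window_length or foreground.length
    spans = genes.set_index("gene_id")[["start", "end", "strand", "chrom"]]
    need = Counter(foreground.gene_ids)
    site_pos = {gid: grp.position.to_numpy() for gid, grp in sites.groupby("gene_id")}

    candidate_genes = sorted(set(need) | set(sites.gene_id.unique()) & set(spans.index))
    eligible: dict[str, np.ndarray] = {}
    for gid in candidate_genes:
        g = spans.loc[gid]
        n_starts = int(g.end - g.start) - wlen + 1
        if n_starts <= 0:
            eligible[gid] = np.empty(0, dtype=np.int64)
            continue
        ok = np.ones(n_starts, dtype=bool)
        for p in site_pos.get(gid, ()):
            lo = max(int(p) - wlen + 1, int(g.start)) - int(g.start)
            hi = min(int(p), int(g.end) - wlen) - int(g.start)
            if hi >= lo:
                ok[lo : hi + 1] = False
        eligible[gid] = np.nonzero(ok)[0] + int(g.start)

    windows, gids = [], []
    shortfall = 0
    for gid in sorted(need):
        starts = eligible[gid]
        if len(starts) == 0:
            warnings.warn(f"gene {gid} has no background-eligible position; reassigning {need[gid]} windows")
            shortfall += need[gid]
            continue
        g = spans.loc[gid]
        for s in rng.choice(starts, size=need[gid], replace=True):
            windows.append(_to_rna(_fetch(genome, g.chrom, int(s), int(s) + wlen), g.strand))
            gids.append(gid)
    if shortfall:
        pool = [(gid, s) for gid in candidate_genes if len(eligible[gid]) for s in eligible[gid]]
        if not pool:
            raise ValueError("no background-eligible position in any gene")
        idx = rng.choice(len(pool), size=shortfall, replace=True)
        for i in idx:
            gid, s = pool[i]
            g = spans.loc[gid]
            windows.append(_to_rna(_fetch(genome, g.chrom, int(s), int(s) + wlen), g.strand))
            gids.append(gid)
    return MotifWindowSet(windows, gids, "background")


def log10_hypergeom_sf_all(N: int, K: int, n: int) -> tuple[int, np.ndarray]:
    """Upper-tail log10 P(X >= k) for every feasible k of Hypergeom(N, K, n).

    Returns ``(kmin, tails)`` where ``tails[i]`` is the tail at ``k = kmin+i``
    (``kmin`` the smallest feasible count).  Working in log space keeps
    p-values far below double underflow (e.g. 1e-930) representable.
    """
    kmin, kmax = max(0, n + K - N), min(K, n)
    ks = np.arange(kmin, kmax + 1)
    lp = hypergeom.logpmf(ks, N, K, n)
    tails = np.logaddexp.accumulate(lp[::-1])[::-1] / np.log(10.0)
    tails[0] = 0.0  # P(X >= kmin) is exactly 1
    return kmin, tails


def log10_hypergeom_sf(k: int, N: int, K: int, n: int) -> float:
    """log10 P(X >= k) for X ~ Hypergeom(N, K, n), exact in log space."""
    kmin, tails = log10_hypergeom_sf_all(N, K, n)
    if k <= kmin:
        return 0.0
    if k >= kmin + len(tails):
        return -np.inf
    return float(tails[k - kmin])


def _presence_counts(windows: list[str], k: int = 5) -> Counter:
    counts: Counter = Counter()
    for w in windows:
        counts.update({w[i : i + k] for i in range(len(w) - k + 1)})
    return counts


def pentamer_enrichment(foreground: MotifWindowSet, background: MotifWindowSet) -> pd.DataFrame:
    """One-sided Fisher exact enrichment of every pentamer in the foreground.

    For each pentamer the 2x2 table (fg_with, fg_without, bg_with, bg_without)
    counts windows containing >= 1 occurrence (presence, not occurrence
    totals).  The one-sided p is the hypergeometric upper tail computed in
    log space; ``p_bonferroni`` applies a factor 1,024.  Sorted by p
    ascending, ties broken by fg_with descending then lexicographically.
    """
    if len(foreground) == 0 or len(background) == 0:
        raise ValueError("foreground and background must be non-empty")
    if foreground.length < 5 or background.length < 5:
        raise ValueError("window length < 5")
    nf, nb = len(foreground), len(background)
    fgc = _presence_counts(foreground.windows)
    bgc = _presence_counts(background.windows)
    rows = []
    for pent in ALL_PENTAMERS:
        fw = fgc.get(pent, 0)
        bw = bgc.get(pent, 0)
        lp = log10_hypergeom_sf(fw, nf + nb, fw + bw, nf)
        rows.append((pent, fw, nf - fw, bw, nb - bw, lp))
    df = pd.DataFrame(rows, columns=["pentamer", "fg_with", "fg_without", "bg_with", "bg_without", "log10_p"])
    df["log10_p_bonferroni"] = np.minimum(df.log10_p + np.log10(len(ALL_PENTAMERS)), 0.0)
    df["p_value"] = np.power(10.0, df.log10_p)  # underflows to 0 for extreme tails
    df["p_bonferroni"] = np.power(10.0, df.log10_p_bonferroni)
    df = df.sort_values(
        ["log10_p", "fg_with", "pentamer"], ascending=[True, False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def format_log10_p(log10_p: float, digits: int = 1) -> str:
    """Render a log10 p-value as a scientific-notation string (e.g. '3.1e-930')."""
    if log10_p == 0.0:
        return "1"
    if not np.isfinite(log10_p):
        return "0"
    exp = int(np.floor(log10_p))
    mant = 10.0 ** (log10_p - exp)
    mant = round(mant, digits)
    if mant >= 10.0:
        mant /= 10.0
        exp += 1
    return f"{mant:.{digits}f}e{exp}"


def positional_profile(
    pentamer: str,
    sites: pd.DataFrame,
    genome,
    genes: pd.DataFrame,
    offset_range: int = 50,
) -> pd.DataFrame:
    """Fraction of sites with a motif occurrence starting at each offset.

    Offsets run -offset_range..+offset_range in transcript orientation
    relative to the crosslink site.  Supports IUPAC-degenerate motifs
    (e.g. GANGA).  A site is excluded only at offsets whose motif span falls
    outside its gene.  Returns columns offset, n_sites, n_with, fraction.
    """
    pat = iupac_regex(pentamer)
    mlen = len(pentamer)
    spans = genes.set_index("gene_id")[["start", "end"]]
    offsets = np.arange(-offset_range, offset_range + 1)
    n_sites = np.zeros(len(offsets), dtype=int)
    n_with = np.zeros(len(offsets), dtype=int)
    for s in sites.itertuples():
        g = spans.loc[s.gene_id]
        # transcript-orientation span covering all offsets plus motif length
        if s.strand == "+":
            a = max(int(g.start), s.position - offset_range)
            b = min(int(g.end), s.position + offset_range + mlen)
            seq = _to_rna(_fetch(genome, s.chrom, a, b), "+")
            first_off = a - s.position
        else:
            a = max(int(g.start), s.position - offset_range - mlen + 1)
            b = min(int(g.end), s.position + offset_range + 1)
            seq = _to_rna(_fetch(genome, s.chrom, a, b), "-")
            first_off = s.position - (b - 1)
        # scan every start so overlapping occurrences are counted
        hits = {i + first_off for i in range(len(seq) - mlen + 1) if pat.match(seq, i)}
        valid = (offsets >= first_off) & (offsets + mlen <= first_off + len(seq))
        n_sites += valid
        for j, o in enumerate(offsets):
            if valid[j] and o in hits:
                n_with[j] += 1
    frac = np.divide(n_with, n_sites, out=np.zeros(len(offsets)), where=n_sites > 0)
    return pd.DataFrame({"offset": offsets, "n_sites": n_sites, "n_with": n_with, "fraction": frac})


def motif_track(
    gene_id: str,
    genome,
    genes: pd.DataFrame,
    motif: str = "GANGA",
    cpm_track: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-position motif-start indicator for one gene, with optional CPM overlay.

    Positions are gene-orientation offsets (0 = transcript 5' end).  When a
    CPM-normalized crosslink track is supplied its values are aligned onto
    the same axis, suitable for genome-browser-style plotting.
    """
    g = genes.set_index("gene_id").loc[gene_id]
    seq = _to_rna(_fetch(genome, g.chrom, int(g.start), int(g.end)), g.strand)
    pat = iupac_regex(motif)
    L = len(seq)
    ind = np.zeros(L, dtype=bool)
    for i in range(L - len(motif) + 1):
        if pat.match(seq, i):
            ind[i] = True
    out = pd.DataFrame({"offset": np.arange(L), "motif_start": ind})
    if cpm_track is not None:
        cpm = np.zeros(L)
        sel = cpm_track[
            (cpm_track.chrom == g.chrom)
            & (cpm_track.strand == g.strand)
            & (cpm_track.position >= g.start)
            & (cpm_track.position < g.end)
        ]
        for row in sel.itertuples():
            off = row.position - int(g.start) if g.strand == "+" else int(g.end) - 1 - row.position
            cpm[off] += row.cpm
        out["cpm"] = cpm
    return out
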