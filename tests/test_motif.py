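"""Pentamer enrichment, background matching, positional profiles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

from prclip import motif
from prclip.motif import MotifWindowSet

GENES = pd.DataFrame(
    [
        ("g+", "chr1", 50, 450, "+", "protein_coding"),
        ("g-", "chr1", 500, 900, "-", "protein_coding"),
    ],
    columns=["gene_id", "chrom", "start", "end", "strand", "biotype"],
)


def sites(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "position", "strand"])


@pytest.fixture(scope="module")
def toy_genome():
    rng = np.random.default_rng(77)
    return {"chr1": "".join(np.array(list("ACGT"))[rng.integers(0, 4, 1000)])}


class TestWindowExtraction:
    def test_plus_strand_window_arithmetic(self, toy_genome):
        ws = motif.extract_windows(sites([("g+", "chr1", 100, "+")]), toy_genome, GENES)
        expect = toy_genome["chr1"][95:131].replace("T", "U")
        assert ws.windows == [expect]
        assert ws.length == 36

    def test_minus_strand_window_reverse_complemented(self, toy_genome):
        from prclip.io import revcomp

        ws = motif.extract_windows(sites([("g-", "chr1", 600, "-")]), toy_genome, GENES)
        expect = revcomp(toy_genome["chr1"][570:606]).replace("T", "U")
        assert ws.windows == [expect]

    def test_window_truncated_by_gene_end_dropped_and_counted(self, toy_genome):
        ws = motif.extract_windows(sites([("g+", "chr1", 52, "+")]), toy_genome, GENES)
        assert len(ws) == 0 and ws.n_dropped == 1


class TestBackgroundSampling:
    def test_matched_multiplicity_and_site_avoidance(self, toy_genome):
        fg_sites = sites([("g+", "chr1", 200, "+"), ("g+", "chr1", 300, "+")])
        fg = motif.extract_windows(fg_sites, toy_genome, GENES)
        bg = motif.sample_background_windows(fg_sites, toy_genome, GENES, fg, rng=0)
        assert len(bg) == len(fg)
        assert set(bg.gene_ids) == {"g+"}

    def test_fully_tiled_gene_contributes_none_with_warning(self, toy_genome):
        dense = sites([("g+", "chr1", p, "+") for p in range(55, 445, 5)])
        fg = motif.extract_windows(dense.iloc[:4], toy_genome, GENES)
        other = sites([("g-", "chr1", 700, "-")])
        combined = pd.concat([dense, other])
        fg2 = MotifWindowSet(fg.windows, ["g+"] * len(fg), "foreground")
        with pytest.warns(UserWarning, match="no background-eligible"):
            bg = motif.sample_background_windows(combined, toy_genome, GENES, fg2, rng=0)
        assert len(bg) == len(fg2)
        assert set(bg.gene_ids) == {"g-"}  # multiplicity reassigned

    def test_fixed_seed_reproduces_background(self, toy_genome):
        fg_sites = sites([("g+", "chr1", 200, "+")])
        fg = motif.extract_windows(fg_sites, toy_genome, GENES)
        a = motif.sample_background_windows(fg_sites, toy_genome, GENES, fg, rng=4)
        b = motif.sample_background_windows(fg_sites, toy_genome, GENES, fg, rng=4)
        assert a.windows == b.windows

    def test_background_windows_avoid_all_sites(self, toy_genome):
        fg_sites = sites([("g+", "chr1", 200, "+"), ("g+", "chr1", 260, "+")])
        fg = motif.extract_windows(fg_sites, toy_genome, GENES)
        rng = np.random.default_rng(1)
        for _ in range(10):
            bg = motif.sample_background_windows(fg_sites, toy_genome, GENES, fg, rng=rng)
            for w in bg.windows:
                idx = toy_genome["chr1"].find(w.replace("U", "T"))
                assert idx >= 0  # plus-strand gene: window is a genome substring
                for p in (200, 260):
                    assert not (idx <= p < idx + 36)


def exact_upper_tail(a, b, c, d):
    """Exact one-sided Fisher p via integer enumeration of extreme tables."""
    N, K, n = a + b + c + d, a + c, a + b
    kmin, kmax = max(0, n + K - N), min(K, n)
    nums = [math.comb(K, k) * math.comb(N - K, n - k) for k in range(kmin, kmax + 1)]
    return sum(nums[a - kmin :]) / sum(nums)


class TestFisherExact:
    def test_agrees_with_enumeration_oracle_on_moderate_tables(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 13, size=4)
            if a + b == 0 or c + d == 0:
                continue
            lp = motif.log10_hypergeom_sf(a, a + b + c + d, a + c, a + b)
            assert 10.0**lp == pytest.approx(exact_upper_tail(a, b, c, d), rel=1e-12)

    def test_agrees_with_scipy_fisher_exact(self):
        for table in [(8, 2, 2, 8), (5, 5, 5, 5), (12, 3, 1, 20), (0, 10, 5, 5)]:
            a, b, c, d = table
            p_scipy = fisher_exact([[a, b], [c, d]], alternative="greater")[1]
            lp = motif.log10_hypergeom_sf(a, a + b + c + d, a + c, a + b)
            assert 10.0**lp == pytest.approx(p_scipy, rel=1e-9)

    def test_extreme_table_stays_finite_in_log_space(self):
        # all 2000 foreground windows contain the motif, none of background
        lp = motif.log10_hypergeom_sf(2000, 4000, 2000, 2000)
        assert np.isfinite(lp) and lp < -600  # far below float underflow in p


class TestPentamerEnrichment:
    def winset(self, seqs, origin):
        return MotifWindowSet(list(seqs), ["g"] * len(seqs), origin)

    def test_identical_sets_are_null(self):
        rng = np.random.default_rng(5)
        wins = ["".join(np.array(list("ACGU"))[rng.integers(0, 4, 36)]) for _ in range(50)]
        res = motif.pentamer_enrichment(self.winset(wins, "foreground"), self.winset(wins, "background"))
        assert (res.log10_p >= np.log10(0.5) - 1e-9).all()
        assert (res.p_bonferroni >= 0.999).all()

    def test_perfectly_separating_pentamer_ranks_first(self):
        rng = np.random.default_rng(9)
        alpha = np.array(list("ACGU"))

        def rand36():
            return "".join(alpha[rng.integers(0, 4, 36)])

        fg = []
        for _ in range(100):
            w = list(rand36())
            i = rng.integers(0, 32)
            w[i : i + 5] = "GAAGA"
            fg.append("".join(w))
        bg = []
        while len(bg) < 100:
            w = rand36()
            if "GAAGA" not in w:
                bg.append(w)
        res = motif.pentamer_enrichment(self.winset(fg, "foreground"), self.winset(bg, "background"))
        top = res.iloc[0]
        assert top.pentamer == "GAAGA"
        assert top.fg_with == 100 and top.bg_with == 0
        # p equals the hypergeometric point mass of the fully-polarized table
        expect = 1.0 / math.comb(200, 100)
        assert 10.0**top.log10_p == pytest.approx(expect, rel=1e-9)

    def test_counts_partition_window_sets(self):
        rng = np.random.default_rng(6)
        fg = ["".join(np.array(list("ACGU"))[rng.integers(0, 4, 36)]) for _ in range(30)]
        bg = ["".join(np.array(list("ACGU"))[rng.integers(0, 4, 36)]) for _ in range(40)]
        res = motif.pentamer_enrichment(self.winset(fg, "foreground"), self.winset(bg, "background"))
        assert (res.fg_with + res.fg_without == 30).all()
        assert (res.bg_with + res.bg_without == 40).all()
        assert sorted(res["rank"]) == list(range(1, 1025))

    def test_bonferroni_is_1024x_in_log_space(self):
        fg = ["GAAGA" + "C" * 31] * 20
        bg = ["CCCCC" + "A" * 31] * 20
        res = motif.pentamer_enrichment(self.winset(fg, "foreground"), self.winset(bg, "background"))
        row = res.set_index("pentamer").loc["GAAGA"]
        assert row.log10_p_bonferroni == pytest.approx(row.log10_p + np.log10(1024))

    def test_short_windows_rejected(self):
        with pytest.raises(ValueError):
            motif.pentamer_enrichment(self.winset(["ACG"], "foreground"), self.winset(["ACG"], "background"))

    def test_p_value_formatting(self):
        assert motif.format_log10_p(-929.509) == "3.1e-930"
        assert motif.format_log10_p(0.0) == "1"
        assert motif.format_log10_p(np.log10(0.05)) == "5.0e-2"


class TestPositionalProfile:
    def test_planted_offset_gives_unit_fraction(self):
        genome = {"chr1": "T" * 200 + "A" + "GAAGA".replace("U", "T") + "T" * 200}
        genes = pd.DataFrame(
            [("g", "chr1", 100, 300, "+", "protein_coding")],
            columns=["gene_id", "chrom", "start", "end", "strand", "biotype"],
        )
        ss = sites([("g", "chr1", 200, "+")])
        prof = motif.positional_profile("GAAGA", ss, genome, genes, offset_range=10)
        frac = prof.set_index("offset").fraction
        assert frac.loc[1] == 1.0
        assert frac.drop(index=1).max() == 0.0

    def test_absent_pentamer_gives_zero_profile(self, toy_genome):
        genome = {"chr1": "A" * 1000}
        ss = sites([("g+", "chr1", 100, "+")])
        prof = motif.positional_profile("GAAGA", ss, genome, GENES, offset_range=20)
        assert (prof.fraction == 0).all()

    def test_gene_boundary_excludes_site_at_offending_offsets_only(self, toy_genome):
        ss = sites([("g+", "chr1", 60, "+")])  # 10 nt from the gene 5' end
        prof = motif.positional_profile("GAAGA", ss, toy_genome, GENES, offset_range=20)
        p = prof.set_index("offset")
        assert p.n_sites.loc[-20] == 0 and p.n_sites.loc[-10] == 1

    def test_degenerate_motif_profile_on_boosted_data(self, tx_small, libraries):
        from prclip import sitecall

        lib = libraries["PR-crosslinked"]
        ev = lib.events.rename(columns={"pos": "position"})
        sig = sitecall.call_sites(ev[["chrom", "position", "strand"]], tx_small.genes, seed=0)
        sig = sig[~sig.gene_id.str.startswith("intergenic:")]
        prof = motif.positional_profile("GAAGA", sig, tx_small.sequences, tx_small.genes)
        p = prof.set_index("offset").fraction
        # the generator places crosslinks 0-5 nt 5' of a planted motif start,
        # so enrichment concentrates at offsets 0..+5
        near = p.loc[0:5].mean()
        outside = pd.concat([p.loc[:-6], p.loc[31:]]).mean()
        assert near > outside + 0.05
        assert p.loc[-5:30].mean() > outside  # whole window still elevated


class TestMotifTrack:
    def test_gagaa_repeats_match_gan_ga_with_period_five(self):
        genome = {"chr1": "GAGAA" * 40}
        genes = pd.DataFrame(
            [("g", "chr1", 0, 200, "+", "protein_coding")],
            columns=["gene_id", "chrom", "start", "end", "strand", "biotype"],
        )
        track = motif.motif_track("g", genome, genes, motif="GANGA")
        hits = track.offset[track.motif_start].to_numpy()
        assert (hits % 5 == 2).all() and len(hits) == 40 - 1

    def test_sequence_without_g_has_empty_indicator(self):
        genome = {"chr1": "ACAUACUA".replace("U", "T") * 30}
        genes = pd.DataFrame(
            [("g", "chr1", 0, 100, "+", "protein_coding")],
            columns=["gene_id", "chrom", "start", "end", "strand", "biotype"],
        )
        track = motif.motif_track("g", genome, genes, motif="GANGA")
        assert not track.motif_start.any()

    def test_cpm_overlay_conserves_gene_mass(self, tx_small, libraries):
        from prclip import sitecall

        lib = libraries["PR-crosslinked"]
        ev = lib.events.rename(columns={"pos": "position"})
        track = sitecall.cpm_normalize(sitecall.CrosslinkTrack.from_events(ev, "PR"))
        gid = tx_small.genes.gene_id.iloc[0]
        g = tx_small.genes.set_index("gene_id").loc[gid]
        mass = track[
            (track.position >= g.start) & (track.position < g.end) & (track.strand == g.strand)
        ].cpm.sum()
        mt = motif.motif_track(gid, tx_small.sequences, tx_small.genes, cpm_track=track)
        assert mt.cpm.sum() == pytest.approx(mass)

    def test_invalid_iupac_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            motif.iupac_regex("GA?GA")
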