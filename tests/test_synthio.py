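"""Synthetic-data generator: transcriptome, CLIP libraries, BLI traces."""

import numpy as np
import pytest
from scipy import stats

from prclip import io as pio
from prclip import synthio
from prclip.bli import association_response


class TestTranscriptome:
    def test_zero_density_plants_no_motifs(self):
        spec = synthio.TranscriptomeSpec(
            n_genes=1, gene_length_range=(1000, 1000), motif_density=0.0, seed=3
        )
        tx = synthio.build_transcriptome(spec)
        assert len(tx.genes) == 1
        assert len(tx.motifs) == 0

    def test_planted_motifs_spell_motif_on_gene_strand(self, tx_small):
        for m in tx_small.motifs.itertuples():
            s = tx_small.sequences[m.chrom][m.start : m.start + 5]
            if m.strand == "-":
                s = pio.revcomp(s)
            assert s == "GAAGA"

    def test_motif_count_tracks_density(self):
        spec = synthio.TranscriptomeSpec(
            n_genes=30, gene_length_range=(1000, 1000), motif_density=2.0, seed=5
        )
        tx = synthio.build_transcriptome(spec)
        per_gene = len(tx.motifs) / 30
        assert 1.2 < per_gene < 2.8  # Poisson(2) mean over 30 genes

    def test_gc_content_within_sampling_tolerance(self):
        spec = synthio.TranscriptomeSpec(
            n_genes=2, gene_length_range=(5000, 5000), gc_content=0.6, motif_density=0.0, seed=4
        )
        tx = synthio.build_transcriptome(spec)
        seq = next(iter(tx.sequences.values()))
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.6) < 0.02

    def test_gene_models_non_overlapping_and_exons_ordered(self, tx_small):
        g = tx_small.genes.sort_values("start")
        assert (g.start.to_numpy()[1:] >= g.end.to_numpy()[:-1]).all()
        for gid, sub in tx_small.features[tx_small.features.type == "exon"].groupby("gene_id"):
            ex = sub.sort_values("start")
            assert (ex.start.to_numpy()[1:] >= ex.end.to_numpy()[:-1]).all()
            span = tx_small.genes.set_index("gene_id").loc[gid]
            assert ex.start.min() >= span.start and ex.end.max() <= span.end

    def test_same_seed_gives_byte_identical_outputs(self, tmp_path):
        spec = synthio.TranscriptomeSpec(n_genes=3, gene_length_range=(800, 1200), seed=9)
        for d in ("a", "b"):
            synthio.build_transcriptome(spec).write(tmp_path / d)
        for name in ("genome.fa", "genes.gff3"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_invalid_motif_rejected(self):
        with pytest.raises(ValueError, match="non-ACGU"):
            synthio.build_transcriptome(synthio.TranscriptomeSpec(motif="GAXGA"))

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            synthio.TranscriptomeSpec(n_genes=0).validate()
        with pytest.raises(ValueError):
            synthio.TranscriptomeSpec(gc_content=1.5).validate()


class TestClipLibrary:
    def test_uniform_placement_without_boost(self):
        spec = synthio.TranscriptomeSpec(
            n_genes=1, gene_length_range=(1000, 1000), motif_density=0.0, seed=2
        )
        tx = synthio.build_transcriptome(spec)
        cfg = synthio.ClipSimConfig(n_events=10_000, motif_boost=1.0, read_length=30, seed=2)
        lib = synthio.simulate_clip_library(tx, cfg, "PR-crosslinked", make_reads=False)
        g = tx.genes.iloc[0]
        counts = np.bincount(lib.events.pos.to_numpy() - g.start, minlength=g.end - g.start)
        assert stats.chisquare(counts).pvalue > 0.01

    def test_motif_proximal_fraction_matches_rate_model(self, tx_small):
        """With per-position rate boost B over the 6-nt proximity windows the
        expected proximal fraction is the boosted weight mass over the total
        weight mass; the empirical draw must sit within binomial error."""
        cfg = synthio.ClipSimConfig(n_events=20_000, motif_boost=50.0, seed=13)
        lib = synthio.simulate_clip_library(tx_small, cfg, "PR-crosslinked", make_reads=False)
        prox = set()
        total_positions = 0
        boosted = 0
        for g in tx_small.genes.itertuples():
            total_positions += g.end - g.start
            for m in tx_small.motifs[tx_small.motifs.gene_id == g.gene_id].itertuples():
                lo, hi = (m.start - 5, m.start + 1) if g.strand == "+" else (m.start + 4, m.start + 10)
                for p in range(max(lo, g.start), min(hi, g.end)):
                    prox.add((p, g.strand))
            boosted = len(prox)
        expected = 50.0 * boosted / (50.0 * boosted + (total_positions - boosted))
        hit = np.mean([(p, s) in prox for p, s in zip(lib.events.pos, lib.events.strand)])
        se = np.sqrt(expected * (1 - expected) / len(lib.events))
        assert abs(hit - expected) < 5 * se

    def test_duplication_and_umi_conservation(self, libraries, clip_config):
        lib = libraries["PR-crosslinked"]
        assert lib.n_unique == clip_config.n_events
        assert len(lib.reads) == lib.events.n_dup.sum()  # reads = sum of duplicate counts
        ratio = lib.total_reads / lib.n_unique
        assert abs(ratio - clip_config.pcr_duplication_mean) < 0.1
        pairs = lib.events[["pos", "strand", "umi"]].drop_duplicates()
        assert len(pairs) == clip_config.n_events

    def test_read_is_barcode_umi_then_truncated_cdna(self, tx_small, libraries, clip_config):
        lib = libraries["PR-crosslinked"]
        genome = tx_small.sequences["chr1"]
        bc = clip_config.barcode_map["PR-crosslinked"]
        L = clip_config.read_length
        read_seq = dict(lib.reads)
        for ev in lib.events.head(50).itertuples():
            seq = read_seq[f"{ev.event_id}.d0"]
            assert seq.startswith(bc + ev.umi)
            insert = seq[len(bc) + clip_config.umi_length : len(bc) + clip_config.umi_length + L]
            if ev.strand == "+":
                assert insert == genome[ev.pos + 1 : ev.pos + 1 + L]
            else:
                assert insert == pio.revcomp(genome[ev.pos - L : ev.pos])

    def test_controls_are_low_yield_and_unboosted(self, libraries, clip_config):
        n_ctrl = round(clip_config.n_events * clip_config.control_rate_fraction)
        for kind in ("PR-noncrosslinked", "GA-crosslinked", "FLAG-crosslinked"):
            assert libraries[kind].n_unique == n_ctrl

    def test_read_length_longer_than_shortest_gene_rejected(self, tx_small):
        cfg = synthio.ClipSimConfig(n_events=10, read_length=10_000)
        with pytest.raises(ValueError, match="read_length"):
            synthio.simulate_clip_library(tx_small, cfg, "PR-crosslinked")

    def test_seed_determinism(self, tx_small):
        cfg = synthio.ClipSimConfig(n_events=500, seed=21)
        a = synthio.simulate_clip_library(tx_small, cfg, "PR-crosslinked")
        b = synthio.simulate_clip_library(tx_small, cfg, "PR-crosslinked")
        assert a.events.equals(b.events)
        assert a.reads == b.reads


class TestBliSimulation:
    def test_noiseless_trace_obeys_closed_form(self):
        traces, truth = synthio.simulate_bli_dataset(noise_sd=0.0, replicates=1, seed=0)
        for conc, tr in traces.groupby("concentration_M"):
            expect = association_response(
                tr.time_s.to_numpy(), conc, truth["ka"], truth["kd_off"], truth["Rmax"]
            )
            np.testing.assert_allclose(tr.response.to_numpy(), expect, rtol=1e-12)

    def test_response_at_kd_approaches_half_rmax(self):
        kd = 2.6e-9
        r = association_response(np.array([1e7]), kd, 1e5, 2.6e-4, 1.0)
        assert abs(r[0] - 0.5) < 1e-9

    def test_zero_concentration_gives_zero_response(self):
        r = association_response(np.linspace(0, 100, 10), 0.0, 1e5, 1e-3, 1.0)
        np.testing.assert_array_equal(r, 0.0)

    def test_half_time_closed_form(self):
        ka, kd_off, conc = 1e5, 2.6e-4, 1e-8
        kobs = ka * conc + kd_off
        t_half = np.log(2) / kobs
        req = association_response(np.array([1e9]), conc, ka, kd_off, 1.0)[0]
        r = association_response(np.array([t_half]), conc, ka, kd_off, 1.0)[0]
        assert abs(r - req / 2) < 1e-12

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            synthio.simulate_bli_dataset(concentrations=())
        with pytest.raises(ValueError):
            synthio.simulate_bli_dataset(true_ka=-1.0)
        with pytest.raises(ValueError):
            synthio.simulate_bli_dataset(concentrations=(0.0, 1e-9))
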