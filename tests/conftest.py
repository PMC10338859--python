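import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from prclip import readproc, synthio

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tx_small():
    """Six genes of ~2 kb with planted GAAGA motifs at 2/kb."""
    spec = synthio.TranscriptomeSpec(n_genes=6, gene_length_range=(1500, 2500), seed=11)
    return synthio.build_transcriptome(spec)


@pytest.fixture(scope="session")
def clip_config():
    return synthio.ClipSimConfig(n_events=10_000, seed=11)


@pytest.fixture(scope="session")
def libraries(tx_small, clip_config):
    """One simulated library per condition (PR + controls + comparison)."""
    return synthio.simulate_experiment(tx_small, clip_config)


@pytest.fixture(scope="session")
def default_layout(clip_config):
    return readproc.LibraryLayout(
        barcode_map={v: k for k, v in synthio.DEFAULT_BARCODE_MAP.items()},
        umi_length=clip_config.umi_length,
        three_prime_adaptor=clip_config.three_prime_adaptor,
    )


@pytest.fixture(scope="session")
def extracted(tx_small, libraries, default_layout):
    """Events recovered by the full demux/dedup/assignment chain."""
    reads = [r for lib in libraries.values() for r in lib.reads]
    aln = pd.concat([lib.alignments for lib in libraries.values()], ignore_index=True)
    aln = aln.rename(columns={"name": "read_id"})[["read_id", "chrom", "start", "end", "strand"]]
    ref_lengths = {k: len(v) for k, v in tx_small.sequences.items()}
    return readproc.extract_events(iter(reads), aln, default_layout, ref_lengths)


def truth_track(lib) -> pd.Series:
    """Ground-truth per-position event counts for a simulated library."""
    t = lib.events.groupby(["chrom", "pos", "strand"]).size().sort_index()
    t.index.names = ["chrom", "position", "strand"]
    return t
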