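"""Configuration, orchestration and report generation.

One validated config drives the full chain
simulate -> extract -> QC -> site calling -> gene-level binding -> motif
(optionally -> BLI), with every output carrying a provenance block
(parameters, seeds, package version).  Reruns with an identical config are
bit-identical.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

import prclip
from prclip import genebind, motif, readproc, sitecall, synthio
from prclip import io as pio


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {e}" for e in errors))


DEFAULT_CONFIG: dict = {
    "mode": "synthetic",
    "seed": 0,
    "transcriptome": {
        "n_genes": 20,
        "gene_length_range": [4500, 5500],
        "exon_count_range": [1, 4],
        "gc_content": 0.45,
        "motif": "GAAGA",
        "motif_density": 2.0,
    },
    "clip": {
        "n_events": 50_000,
        "motif_boost": 50.0,
        "proximity_window": 5,
        "pcr_duplication_mean": 3.0,
        "read_length": 36,
        "umi_length": 6,
        "control_rate_fraction": 0.05,
    },
    "qc": {"min_events": 300_000, "enforce": "warn"},
    "sitecall": {"half_window": 3, "n_perm": 100, "fdr_threshold": 0.05},
    "genebind": {"min_events": 200, "max_control_fraction": 0.10, "normalization": "counts"},
    "motif": {"upstream": 5, "downstream": 30, "offset_range": 50},
    "bli": {"enabled": False, "noise_sd": 0.01, "replicates": 3},
    "inputs": {},  # real-data mode: fastq, alignments, layout, genome, annotation
    "samples": {
        "pr": "PR-crosslinked",
        "controls": ["PR-noncrosslinked", "FLAG-crosslinked"],
        "comparisons": ["GA-crosslinked"],
    },
}

_RANGES = {
    ("sitecall", "fdr_threshold"): (0.0, 1.0),
    ("sitecall", "half_window"): (0, 1000),
    ("sitecall", "n_perm"): (1, 1_000_000),
    ("genebind", "max_control_fraction"): (0.0, 1.0),
    ("genebind", "min_events"): (0, 10**9),
    ("qc", "min_events"): (0, 10**12),
    ("clip", "control_rate_fraction"): (0.0, 1.0),
    ("clip", "motif_boost"): (1.0, 1e9),
    ("transcriptome", "gc_content"): (0.0, 1.0),
}


@dataclass
class RunConfig:
    raw: dict = field(default_factory=lambda: json.loads(json.dumps(DEFAULT_CONFIG)))

    def __getitem__(self, key):
        return self.raw[key]


def _merge(base: dict, override: dict, errors: list[str], path: str = "") -> dict:
    out = dict(base)
    for k, v in override.items():
        here = f"{path}.{k}" if path else k
        if k not in base:
            errors.append(f"unknown key: {here}")
            continue
        if isinstance(base[k], dict) and isinstance(v, dict):
            out[k] = _merge(base[k], v, errors, here)
        else:
            out[k] = v
    return out


def validate_config(config: dict | str | os.PathLike | None = None) -> RunConfig:
    """Validate a config mapping (or YAML path) against the documented schema.

    Unknown keys are rejected; out-of-range parameters and missing input
    files are reported together, each named by its key path.
    """
    if config is None:
        config = {}
    if isinstance(config, (str, os.PathLike)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    errors: list[str] = []
    merged = _merge(DEFAULT_CONFIG, config, errors)
    for (sect, key), (lo, hi) in _RANGES.items():
        v = merged[sect][key]
        if not (lo <= v <= hi):
            errors.append(f"{sect}.{key}={v} outside [{lo}, {hi}]")
    if merged["mode"] not in ("synthetic", "real"):
        errors.append(f"mode={merged['mode']!r} not one of synthetic|real")
    if merged["qc"]["enforce"] not in ("warn", "strict"):
        errors.append(f"qc.enforce={merged['qc']['enforce']!r} not one of warn|strict")
    if merged["mode"] == "real":
        needed = ("fastq", "alignments", "layout", "genome", "annotation")
        for key in needed:
            path = merged["inputs"].get(key)
            if not path:
                errors.append(f"inputs.{key} required in real mode")
            elif not os.path.exists(path):
                errors.append(f"inputs.{key}: no such file {path}")
        sheet = merged["samples"]
        if not sheet.get("pr"):
            errors.append("samples.pr: missing sample-sheet entry for the crosslinked sample")
    if errors:
        raise ConfigError(errors)
    return RunConfig(raw=merged)


class QCFailure(RuntimeError):
    pass


@dataclass
class PipelineResult:
    config: RunConfig
    qc: pd.DataFrame
    extract_report: pd.DataFrame
    sites: pd.DataFrame
    gene_summary: pd.DataFrame
    bound_genes: pd.DataFrame
    region_proportions: pd.Series
    pentamers: pd.DataFrame
    bli_fits: pd.DataFrame | None
    outdir: str | None


def _provenance(cfg: RunConfig) -> dict:
    return {"package": "prclip", "version": prclip.__version__, "config": cfg.raw}


def run_pipeline(config: RunConfig | dict | None = None, outdir: str | None = None) -> PipelineResult:
    """Execute the full analysis per the config; optionally write the bundle.

    Synthetic mode generates a transcriptome and one library per condition,
    then runs extraction, QC, site calling on the crosslinked sample,
    gene-level binding against the controls, and pentamer enrichment.  Any
    stage failure raises with the stage name.
    """
    cfg = config if isinstance(config, RunConfig) else validate_config(config)
    seed = int(cfg["seed"])
    stage = "simulate"
    try:
        if cfg["mode"] == "synthetic":
            tx, libraries = simulate_inputs(cfg)
            layout = readproc.LibraryLayout(
                barcode_map={v: k for k, v in synthio.DEFAULT_BARCODE_MAP.items()},
                umi_length=int(cfg["clip"]["umi_length"]),
                three_prime_adaptor=synthio.ClipSimConfig().three_prime_adaptor,
            )
            reads = [r for lib in libraries.values() for r in lib.reads]
            aln = pd.concat([lib.alignments for lib in libraries.values()], ignore_index=True)
            aln = aln.rename(columns={"name": "read_id"})[["read_id", "chrom", "start", "end", "strand"]]
            genes, features = tx.genes, tx.features
            genome = tx.sequences
        else:
            from pyfaidx import Fasta

            inputs = cfg["inputs"]
            layout = readproc.LibraryLayout.from_json(inputs["layout"])
            reads = inputs["fastq"]
            aln = readproc.read_alignments(inputs["alignments"])
            genes, features = pio.read_gff3(inputs["annotation"])
            genome = {k: str(v[:]) for k, v in Fasta(inputs["genome"]).items()}

        stage = "extract"
        ref_lengths = {k: len(v) for k, v in genome.items()}
        if isinstance(reads, list):
            events, extract_report = readproc.extract_events(iter(reads), aln, layout, ref_lengths)
        else:
            events, extract_report = readproc.extract_events(reads, aln, layout, ref_lengths)

        stage = "qc"
        qc_rows = []
        for sample, grp in events.groupby("sample"):
            qc_rows.append(sitecall.sample_qc(sitecall.CrosslinkTrack.from_events(grp, sample), cfg["qc"]["min_events"]))
        qc = pd.DataFrame(qc_rows)
        pr_sample = cfg["samples"]["pr"]
        pr_qc = qc[qc["sample"] == pr_sample]
        if cfg["qc"]["enforce"] == "strict" and not bool(pr_qc["pass"].all()):
            raise QCFailure(
                f"sample {pr_sample!r} below the minimum of {cfg['qc']['min_events']} unique crosslink events"
            )

        stage = "callsites"
        pr_events = events[events["sample"] == pr_sample]
        sites = sitecall.call_sites(
            pr_events,
            genes,
            half_window=cfg["sitecall"]["half_window"],
            n_perm=cfg["sitecall"]["n_perm"],
            fdr_threshold=cfg["sitecall"]["fdr_threshold"],
            seed=seed,
        )

        stage = "genebind"
        counts = genebind.count_gene_events(events, genes)
        summary = genebind.summarize_binding(
            counts,
            pr_samples=[pr_sample],
            control_samples=[s for s in cfg["samples"]["controls"] if s in counts.columns],
            min_events=cfg["genebind"]["min_events"],
            max_control_fraction=cfg["genebind"]["max_control_fraction"],
            normalization=cfg["genebind"]["normalization"],
        )
        bound = genebind.filter_bound_genes(
            summary, cfg["genebind"]["min_events"], cfg["genebind"]["max_control_fraction"]
        )
        _, proportions = genebind.annotate_regions(pr_events, genes, features)

        stage = "motif"
        genic_sites = sites[~sites.gene_id.str.startswith("intergenic:")]
        fg = motif.extract_windows(
            genic_sites, genome, genes, cfg["motif"]["upstream"], cfg["motif"]["downstream"]
        )
        bg = motif.sample_background_windows(genic_sites, genome, genes, fg, rng=np.random.default_rng(seed + 1))
        pentamers = motif.pentamer_enrichment(fg, bg)

        bli_fits = None
        if cfg["bli"]["enabled"]:
            stage = "bli"
            traces, _ = synthio.simulate_bli_dataset(
                noise_sd=cfg["bli"]["noise_sd"], replicates=cfg["bli"]["replicates"], seed=seed
            )
            from prclip.bli import fit_bli_experiment

            bli_fits = fit_bli_experiment(traces)
    except QCFailure:
        raise
    except Exception as e:  # annotate failures with the stage that died
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    result = PipelineResult(
        config=cfg,
        qc=qc,
        extract_report=extract_report,
        sites=sites,
        gene_summary=summary,
        bound_genes=bound,
        region_proportions=proportions,
        pentamers=pentamers,
        bli_fits=bli_fits,
        outdir=outdir,
    )
    if outdir is not None:
        write_bundle(result, outdir)
    return result


def simulate_inputs(cfg: RunConfig) -> tuple[synthio.Transcriptome, dict[str, synthio.ClipLibrary]]:
    t = cfg["transcriptome"]
    spec = synthio.TranscriptomeSpec(
        n_genes=t["n_genes"],
        gene_length_range=tuple(t["gene_length_range"]),
        exon_count_range=tuple(t["exon_count_range"]),
        gc_content=t["gc_content"],
        motif=t["motif"],
        motif_density=t["motif_density"],
        seed=int(cfg["seed"]),
    )
    tx = synthio.build_transcriptome(spec)
    c = cfg["clip"]
    sim = synthio.ClipSimConfig(
        n_events=c["n_events"],
        motif_boost=c["motif_boost"],
        proximity_window=c["proximity_window"],
        pcr_duplication_mean=c["pcr_duplication_mean"],
        read_length=c["read_length"],
        umi_length=c["umi_length"],
        control_rate_fraction=c["control_rate_fraction"],
        seed=int(cfg["seed"]),
    )
    kinds = tuple([cfg["samples"]["pr"]] + cfg["samples"]["controls"] + cfg["samples"]["comparisons"])
    return tx, synthio.simulate_experiment(tx, sim, kinds)


def motif_recovery_experiment(
    seed: int = 0,
    n_events: int = 50_000,
    motif_boost: float = 50.0,
    n_genes: int = 20,
    gene_length_range: tuple[int, int] = (4500, 5500),
    foreground: str = "significant",
    max_sites: int = 2000,
) -> dict:
    """Generator -> site calling -> pentamer enrichment, for one seed.

    The calibration experiment behind motif-recovery checks: simulate a
    crosslinked library on a fresh transcriptome, take crosslink sites
    (``foreground="significant"``: permutation-FDR calls; ``"events"``: a
    random subsample of event positions, the appropriate choice under a
    motif-blind library where few or no sites reach significance), and rank
    all 1,024 pentamers against the matched background.  Returns the planted
    motif's rank and Bonferroni log10 p plus the top-ranked pentamer.
    """
    spec = synthio.TranscriptomeSpec(
        n_genes=n_genes, gene_length_range=gene_length_range, seed=seed
    )
    tx = synthio.build_transcriptome(spec)
    sim = synthio.ClipSimConfig(n_events=n_events, motif_boost=motif_boost, seed=seed)
    lib = synthio.simulate_clip_library(tx, sim, "PR-crosslinked", make_reads=False)
    ev = lib.events.rename(columns={"pos": "position"})
    if foreground == "significant":
        sites = sitecall.call_sites(ev[["chrom", "position", "strand"]], tx.genes, seed=seed)
        sites = sites[~sites.gene_id.str.startswith("intergenic:")]
    else:
        sites = ev[["gene_id", "chrom", "position", "strand"]]
    if len(sites) > max_sites:
        sites = sites.sample(n=max_sites, random_state=seed)
    fg = motif.extract_windows(sites, tx.sequences, tx.genes)
    bg = motif.sample_background_windows(
        sites, tx.sequences, tx.genes, fg, rng=np.random.default_rng(seed + 7)
    )
    table = motif.pentamer_enrichment(fg, bg)
    row = table.set_index("pentamer").loc[spec.motif]
    return {
        "rank": int(row["rank"]),
        "log10_p_bonferroni": float(row.log10_p_bonferroni),
        "n_sites": int(len(sites)),
        "top_pentamer": table.iloc[0].pentamer,
    }


def write_bundle(result: PipelineResult, outdir: str) -> dict[str, str]:
    """Write the report bundle: TSVs, BED, provenance JSON and a text report."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def tsv(name, df, index=False):
        paths[name] = os.path.join(outdir, f"{name}.tsv")
        df.to_csv(paths[name], sep="\t", index=index)

    tsv("qc", result.qc)
    tsv("extract_report", result.extract_report)
    tsv("significant_sites", result.sites)
    tsv("gene_binding_summary", result.gene_summary, index=True)
    tsv("bound_genes", result.bound_genes, index=True)
    tsv("region_proportions", result.region_proportions.rename("fraction").to_frame(), index=True)
    tsv("pentamer_enrichment", result.pentamers)
    if result.bli_fits is not None:
        tsv("bli_fits", result.bli_fits)
    if len(result.sites):
        paths["sites_bed"] = os.path.join(outdir, "significant_sites.bed")
        pio.write_bed6(sitecall.sites_to_bed(result.sites), paths["sites_bed"])
    paths["provenance"] = os.path.join(outdir, "provenance.json")
    with open(paths["provenance"], "w") as fh:
        json.dump(_provenance(result.config), fh, indent=1, sort_keys=True)
    paths["report"] = os.path.join(outdir, "report.txt")
    with open(paths["report"], "w") as fh:
        fh.write(render_report(result))
    return paths


def render_report(result: PipelineResult) -> str:
    top = result.pentamers.iloc[0]
    lines = [
        "prclip run report",
        "=================",
        "",
        "Sample QC (unique crosslink events):",
        result.qc.to_string(index=False),
        "",
        f"Significant crosslink sites: {len(result.sites)}",
        f"Bound genes: {len(result.bound_genes)}",
        "",
        "Genomic region distribution of crosslink events:",
        result.region_proportions.to_string(),
        "",
        f"Top enriched pentamer: {top.pentamer} "
        f"(p = {motif.format_log10_p(float(top.log10_p))}, "
        f"Bonferroni p = {motif.format_log10_p(float(top.log10_p_bonferroni))})",
        "",
    ]
    if result.bli_fits is not None:
        lines += ["BLI steady-state fits:", result.bli_fits.to_string(index=False), ""]
    return "\n".join(lines)
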