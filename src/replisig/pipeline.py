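"""Run configuration and stage orchestration for the command-line pipeline.

Each stage is a pure function of (inputs, config, seed) writing TSV/JSON
artifacts into the run directory; ``run_full`` chains
simulate-or-load -> regions -> catalog -> extract-or-load-signatures ->
decompose -> stats and records a manifest with the config hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import catalog as cat
from . import extraction, io, regions, simulate, stats
from .exposures import ExposureDecomposer
from .mutation_types import TYPE192_LABELS


@dataclass
class RunConfig:
    """All pipeline tunables; defaults follow the published analysis where
    it states a value (domain width 20 kbp, slope threshold 250 rtu/Mb,
    1-kbp origin bins, up to 1000 per side, K in [2,7], stability >= 0.8,
    exposure filter 0.2, 27 clusters, 0.5% direction-mass threshold, 0.5%
    prune tolerance, 1000 perturbations at 5% noise with 0.3 instability,
    minimal exposure 10, Tukey k = 2)."""

    # inputs (any may be produced by the simulate stage instead)
    genome_fasta: str | None = None
    mutations: str | None = None
    domains_bed: str | None = None
    timing_bedgraph: str | None = None
    origins_bed: str | None = None
    masks_bed: str | None = None
    reference_signatures: str | None = None
    directional_signatures: str | None = None
    outdir: str = "replisig_run"

    # regions
    domain_width: int = 20_000
    slope_threshold: float = 250.0
    invert_direction: bool = False
    higher_rtu_is_earlier: bool = False
    origin_bin_width: int = 1_000
    origin_max_bins: int = 1_000

    # extraction
    k_min: int = 2
    k_max: int = 7
    n_resamples: int = 100
    n_restarts: int = 10
    stability_min: float = 0.8
    exposure_filter: float = 0.2
    n_clusters: int = 27
    direction_min_mass: float = 0.005

    # exposures
    prune_tol: float = 0.005
    robustness: bool = False
    n_perturb: int = 1_000
    noise_frac: float = 0.05
    instability: float = 0.3
    epsilon: float = 1.0

    # statistics
    min_exposure: float = 10.0
    tukey_k: float = 2.0

    # simulation
    seed: int = 0
    n_samples: int = 40
    n_signatures: int = 5
    mutations_per_sample: int = 10_000
    asymmetry_ratio: float = 3.0
    quartile_multipliers: tuple = simulate.DEFAULT_QUARTILE_MULTIPLIERS
    n_chrom: int = 2
    chrom_length: int = 4_000_000
    gc_bias: float = 0.41
    replicon_length: int = 1_000_000

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "quartile_multipliers" in data:
            data["quartile_multipliers"] = tuple(data["quartile_multipliers"])
        return cls(**data)

    def config_hash(self) -> str:
        payload = yaml.safe_dump(
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in dataclasses.asdict(self).items()},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _outdir(config: RunConfig) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _load_genome(config: RunConfig):
    import pyfaidx

    fa = pyfaidx.Fasta(config.genome_fasta)
    return {name: str(fa[name][:]) for name in fa.keys()}


def run_simulate(config: RunConfig) -> dict:
    """Generate and write a fully specified synthetic study."""
    out = _outdir(config)
    rng = np.random.default_rng(config.seed)
    genome = simulate.make_genome(
        seed=int(rng.integers(2**31)), n_chrom=config.n_chrom,
        chrom_length=config.chrom_length, gc_bias=config.gc_bias,
    )
    domains, profile, origins = simulate.make_domains(
        genome, domain_width=config.domain_width,
        replicon_length=config.replicon_length,
    )
    truth = simulate.make_truth(
        n_samples=config.n_samples, n_signatures=config.n_signatures,
        seed=int(rng.integers(2**31)), asymmetry_ratio=config.asymmetry_ratio,
        quartile_multipliers=config.quartile_multipliers,
    )
    mutations = simulate.make_cohort(
        genome, domains, truth,
        mutations_per_sample=config.mutations_per_sample,
        seed=int(rng.integers(2**31)),
    )
    io.write_fasta(genome, out / "genome.fa")
    io.write_domains(domains, out / "domains.bed")
    io.write_timing_bedgraph(profile, out / "timing.bedgraph")
    io.write_bed(origins, out / "origins.bed")
    io.write_mutations_tsv(mutations, out / "mutations.tsv")
    io.write_directional_signatures(truth.signatures, out / "true_signatures.tsv")
    io.write_json(truth.to_dict(), out / "truth.json")
    return {"n_mutations": int(len(mutations)), "n_domains": len(domains)}


def run_regions(config: RunConfig) -> dict:
    """Derive domains from a timing profile; write domains and quartiles."""
    out = _outdir(config)
    profile = io.read_timing_bedgraph(config.timing_bedgraph or out / "timing.bedgraph")
    domains = regions.derive_domains_from_timing(
        profile, domain_width=config.domain_width,
        slope_threshold=config.slope_threshold,
        invert_direction=config.invert_direction,
    )
    io.write_domains(domains, out / "derived_domains.bed")
    quart = regions.assign_timing_quartiles(
        domains, higher_rtu_is_earlier=config.higher_rtu_is_earlier
    )
    with open(out / "quartiles.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\tquartile\n")
        for d in domains:
            fh.write(f"{d.interval.chrom}\t{d.interval.start}\t{d.interval.end}\t{quart[d]}\n")
    return {"n_domains": len(domains)}


def _read_inputs(config: RunConfig):
    out = _outdir(config)
    genome_path = config.genome_fasta or str(out / "genome.fa")
    import pyfaidx

    fa = pyfaidx.Fasta(genome_path)
    genome = {name: str(fa[name][:]) for name in fa.keys()}
    mpath = config.mutations or str(out / "mutations.tsv")
    mutations = (
        io.read_mutations_vcf(mpath) if str(mpath).endswith(".vcf")
        else io.read_mutations_tsv(mpath)
    )
    dpath = config.domains_bed or str(out / "domains.bed")
    domains = io.read_domains(dpath)
    masks = io.read_bed(config.masks_bed) if config.masks_bed else []
    return genome, mutations, domains, masks


def run_catalog(config: RunConfig) -> dict:
    """Build whole-cohort and per-quartile strand catalogs."""
    out = _outdir(config)
    genome, mutations, domains, masks = _read_inputs(config)
    quart = regions.assign_timing_quartiles(
        domains, higher_rtu_is_earlier=config.higher_rtu_is_earlier
    )
    catalog, drop = cat.build_catalog(mutations, domains, masks=masks, genome=genome)
    io.write_catalog(catalog, out / "catalog.tsv")
    drop.to_csv(out / "drop_log.tsv", sep="\t", index=False)
    strata, _ = cat.build_catalog(
        mutations, domains, masks=masks, genome=genome, stratify_by=quart
    )
    for label, c in strata.items():
        io.write_catalog(c, out / f"catalog_{label}.tsv")
    freqs = cat.count_trinucleotides(genome, domains, masks=masks)
    io.write_json(
        {"leading": freqs.leading, "lagging": freqs.lagging, "genome": freqs.genome},
        out / "trinucleotide_counts.json",
    )
    return {"n_samples": int(catalog.shape[0]), "total_counts": int(catalog.to_numpy().sum())}


def _load_freqs(out: Path) -> cat.TrinucFrequencies:
    import json

    with open(out / "trinucleotide_counts.json") as fh:
        d = json.load(fh)
    return cat.TrinucFrequencies(
        np.array(d["leading"]), np.array(d["lagging"]), np.array(d["genome"])
    )


def run_extract(config: RunConfig) -> dict:
    """Extract strand signatures, cluster, and annotate directions."""
    out = _outdir(config)
    catalog = io.read_catalog(out / "catalog.tsv")
    model = extraction.StrandSignatureNMF(
        k_range=(config.k_min, config.k_max),
        n_resamples=config.n_resamples, n_restarts=config.n_restarts,
        stability_min=config.stability_min,
        exposure_filter=config.exposure_filter,
        random_state=config.seed,
    ).fit(catalog)
    freqs = _load_freqs(out)
    sigs = cat.normalize_catalog(model.signatures_, freqs, on_zero="pseudocount")
    sigs = sigs / sigs.sum(axis=0, keepdims=True)
    sig_frame = pd.DataFrame(
        sigs, index=list(TYPE192_LABELS),
        columns=[f"extracted_{j}" for j in range(sigs.shape[1])],
    )
    sig_frame.to_csv(out / "strand_signatures.tsv", sep="\t", index_label="type")
    reference = (
        io.read_reference_signatures(config.reference_signatures)
        if config.reference_signatures else None
    )
    pool_size = sigs.shape[1] + (0 if reference is None else reference.shape[1])
    clusters = extraction.cluster_with_reference(
        sig_frame, reference, n_clusters=min(config.n_clusters, pool_size)
    )
    directional = [
        extraction.annotate_direction(c, min_mass_frac=config.direction_min_mass)
        for c in clusters
    ]
    io.write_directional_signatures(directional, out / "directional_signatures.tsv")
    io.write_json(
        {
            "selected_K": model.model_selection_.K,
            "error": model.model_selection_.error,
            "stability": model.model_selection_.stability,
            "objective": model.model_selection_.objective,
            "meets_stability": bool(model.model_selection_.meets_stability),
            "path": [
                {"K": ms.K, "error": ms.error, "stability": ms.stability,
                 "objective": ms.objective}
                for ms in model.selection_path_
            ],
            "n_retained": model.n_signatures_,
        },
        out / "model_selection.json",
    )
    return {"selected_K": model.model_selection_.K, "n_signatures": len(directional)}


def _decompose_catalog(path: Path, sigs, freqs, config: RunConfig) -> pd.DataFrame:
    catalog = io.read_catalog(path)
    normed = cat.normalize_catalog(catalog, freqs, on_zero="pseudocount")
    dec = ExposureDecomposer(
        signatures=sigs, prune=True, prune_tol=config.prune_tol,
        robustness=config.robustness, n_perturb=config.n_perturb,
        noise_frac=config.noise_frac, instability=config.instability,
        epsilon=config.epsilon, random_state=config.seed,
    ).fit()
    return dec.transform(normed)


def run_decompose(config: RunConfig) -> dict:
    """Matching/inverse exposures, whole-genome and per quartile."""
    out = _outdir(config)
    sig_path = config.directional_signatures or str(out / "directional_signatures.tsv")
    sigs = io.read_directional_signatures(sig_path)
    freqs = _load_freqs(out)
    table = _decompose_catalog(out / "catalog.tsv", sigs, freqs, config)
    table.to_csv(out / "exposures.tsv", sep="\t", index=False)
    for q in ("Q1", "Q2", "Q3", "Q4"):
        qpath = out / f"catalog_{q}.tsv"
        if qpath.exists():
            qt = _decompose_catalog(qpath, sigs, freqs, config)
            qt.to_csv(out / f"exposures_{q}.tsv", sep="\t", index=False)
    return {"n_rows": int(len(table))}


def run_stats(config: RunConfig) -> dict:
    """Cohort asymmetry and replication-timing trend summaries."""
    out = _outdir(config)
    table = pd.read_csv(out / "exposures.tsv", sep="\t")
    asym = stats.cohort_asymmetry(table, min_exposure=config.min_exposure)
    asym.to_csv(out / "asymmetry_summary.tsv", sep="\t", index=False)
    qframes = []
    for qi, q in enumerate(("Q1", "Q2", "Q3", "Q4"), start=1):
        qpath = out / f"exposures_{q}.tsv"
        if qpath.exists():
            qf = pd.read_csv(qpath, sep="\t")
            qf["quartile"] = qi
            qframes.append(qf)
    result = {"n_signatures": int(len(asym))}
    if qframes:
        trend, means = stats.timing_trend(
            pd.concat(qframes, ignore_index=True), min_exposure=config.min_exposure
        )
        trend.to_csv(out / "timing_trend.tsv", sep="\t", index=False)
        means.to_csv(out / "quartile_means.tsv", sep="\t", index=False)
        result["n_trend_signatures"] = int(len(trend))
    io.write_json(result, out / "stats_report.json")
    return result


def run_full(config: RunConfig, simulate_inputs: bool = True) -> dict:
    """Chain the stages end to end and write a run manifest."""
    out = _outdir(config)
    report: dict = {"config_hash": config.config_hash(), "seed": config.seed}
    if simulate_inputs and config.mutations is None:
        report["simulate"] = run_simulate(config)
    report["catalog"] = run_catalog(config)
    if config.directional_signatures is None:
        report["extract"] = run_extract(config)
    report["decompose"] = run_decompose(config)
    report["stats"] = run_stats(config)
    io.write_json(report, out / "manifest.json")
    return report
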