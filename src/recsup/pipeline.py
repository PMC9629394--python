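"""End-to-end orchestration of the recombination-suppression analyses.

``run`` drives the stages — synthetic-data generation, genetic-map
comparison, satellite clustering, DNA-shape analysis, LTR insertion dating
with enrichment scanning, and collinearity/divergence calling — writing
per-stage tables plus one machine-readable ``summary.json`` and a run log.
Every stage can be toggled; every threshold the analyses use surfaces as a
named configuration key with its standard default.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import sys
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import collinearity, dnashape, ltrage, mapcomp, satclust, synth

__all__ = ["RunConfig", "validate_config", "run"]

SCHEMA_VERSION = "1.0"

log = logging.getLogger("recsup")


@dataclass
class RunConfig:
    """All pipeline knobs; defaults are the analyses' standard values."""

    seed: int = 0
    out_dir: str = "recsup_out"
    # stage toggles
    synth: bool = True
    mapcomp: bool = True
    satclust: bool = True
    shape: bool = True
    ltrage: bool = True
    collinearity: bool = True
    # inputs (filled from the synth stage when enabled)
    map_test: str = ""
    map_refs: list[str] = field(default_factory=list)
    trf_table: str = ""
    fasta: str = ""
    gff: str = ""
    paf: str = ""
    # mapcomp
    ratio_min: float = 3.0
    fold_over_coeff: float = 2.0
    # satclust
    merge_gap: int = 100
    min_cluster_len: int = 1000
    base_period: int = 118
    period_tol: int = 4
    pool_gap: int = 200_000
    # shape
    curvature_window: int = 40
    curvature_step: int = 1
    dft_fs: int = 1024
    twist_deg: float = 34.3
    # ltrage
    min_ltr_length: int = 180
    fragment: int = 150
    mu: float = 1.3e-8
    young_threshold: int | None = None  # None: derive from the fitted model
    n_components: int | None = None  # None: minimum-BIC over 1..4
    enrich_window: int = 10
    enrich_step: int = 1
    # collinearity
    min_frag_len: int = 3000
    min_frag_identity: float = 75.0
    hdr_min: int = 50_000
    indel_min: int = 50_000
    collinear_slop: int = 10_000
    coverage_min_similarity: float = 80.0
    coverage_window: int = 10_000

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        issues = validate_config(data)
        hard = [i for i in issues if i.startswith("unknown") is False]
        if hard:
            raise ValueError("; ".join(hard))
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in data.items() if k in known})


def validate_config(config: "RunConfig | dict") -> list[str]:
    """Collect configuration issues (unknown keys, out-of-range values)."""
    if isinstance(config, RunConfig):
        data = dataclasses.asdict(config)
        extra: list[str] = []
    else:
        known = {f.name for f in dataclasses.fields(RunConfig)}
        extra = [f"unknown key: {k}" for k in config if k not in known]
        data = {**{f.name: f.default for f in dataclasses.fields(RunConfig)
                   if f.default is not dataclasses.MISSING}, **config}
    issues = list(extra)
    positive = [
        "ratio_min", "fold_over_coeff", "min_cluster_len", "base_period",
        "curvature_window", "dft_fs", "fragment", "mu", "enrich_window",
        "min_frag_len", "hdr_min", "indel_min", "coverage_window",
    ]
    for key in positive:
        if key in data and data[key] is not None and data[key] <= 0:
            issues.append(f"{key} must be positive, got {data[key]}")
    for key in ("merge_gap", "pool_gap", "collinear_slop", "min_frag_identity"):
        if key in data and data[key] is not None and data[key] < 0:
            issues.append(f"{key} must be >= 0, got {data[key]}")
    return issues


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                log.info("stage %s: start", name)
                out = fn(*args, **kwargs)
                log.info("stage %s: done", name)
                return out
            except Exception as exc:
                raise RuntimeError(f"stage {name} failed: {exc}") from exc
        return wrapped
    return deco


@_stage("synth")
def _run_synth(cfg: RunConfig, out: str) -> dict:
    spec = synth.default_spec(seed=cfg.seed)
    pair = synth.make_chromosome_pair(spec)
    paths = pair.write(os.path.join(out, "synth"))
    cfg.map_refs = [paths["map_ref.tsv"]]
    cfg.map_test = paths["map_test.tsv"]
    cfg.trf_table = paths["satellites.dat"]
    cfg.fasta = paths["genomeA.fasta"]
    cfg.gff = paths["elements.gff3"]
    cfg.paf = paths["alignments.paf"]
    return {
        "chrom_length": spec.chrom_length,
        "n_ltr_elements": len(spec.ltr_elements),
        "n_satellite_arrays": len(spec.satellite_pools),
        "n_indels": len(spec.indels),
        "inversion": list(spec.inversion) if spec.inversion else None,
        "planted_pools": [
            {"span": list(p["span"]), "size": p["size"]} for p in pair.pools_truth
        ],
    }


@_stage("mapcomp")
def _run_mapcomp(cfg: RunConfig) -> dict:
    test = mapcomp.read_map(cfg.map_test)
    refs = [mapcomp.read_map(p) for p in cfg.map_refs]
    coeffs = [mapcomp.reduction_coefficient(r, test) for r in refs]
    regions = mapcomp.detect_suppression_consensus(
        test, refs, ratio_min=cfg.ratio_min, fold_over_coeff=cfg.fold_over_coeff
    )
    out_regions = []
    for reg in regions:
        entry = {
            "flank_left": reg.flank_left,
            "flank_right": reg.flank_right,
            "mean_ratio": round(reg.mean_ratio, 3),
            "n_intervals": reg.n_intervals,
        }
        if reg.flank_left in test.bp and reg.flank_right in test.bp:
            anc = mapcomp.anchor_region(
                (reg.flank_left, *test.bp[reg.flank_left]),
                (reg.flank_right, *test.bp[reg.flank_right]),
            )
            entry["physical_span_bp"] = anc["span_bp"]
            entry["physical_span_mb"] = anc["span_mb"]
        out_regions.append(entry)
    return {
        "reduction_coefficients": [round(c, 3) for c in coeffs],
        "suppression_regions": out_regions,
    }


def _read_fasta_first(path: str) -> str:
    from Bio import SeqIO

    return str(next(SeqIO.parse(path, "fasta")).seq)


@_stage("satclust")
def _run_satclust(cfg: RunConfig) -> dict:
    hits = satclust.parse_trf(cfg.trf_table)
    clusters = satclust.cluster_hits(
        hits, merge_gap=cfg.merge_gap, min_len=cfg.min_cluster_len
    )
    seq = _read_fasta_first(cfg.fasta) if cfg.fasta else ""
    # family reference: the most frequent monomer-length motif among hits
    monomers = [h.motif for h in hits
                if abs(h.period - cfg.base_period) <= cfg.period_tol]
    reference = max(monomers, key=monomers.count) if monomers else ""
    cl_rows = []
    for c in clusters:
        satclust.classify_period(c, base=cfg.base_period, tol=cfg.period_tol)
        if seq and reference and c.family_class != "other":
            satclust.consensus_and_orientation(c, seq, reference)
        cl_rows.append(
            {
                "span": list(c.span),
                "length": c.total_length,
                "class": c.family_class,
                "orientation": c.orientation,
                "identity": round(c.identity, 1),
            }
        )
    pools = satclust.group_pools(clusters, pool_gap=cfg.pool_gap)
    return {
        "n_hits": len(hits),
        "n_clusters": len(clusters),
        "clusters": cl_rows,
        "pools": [
            {"span": list(p.span), "total_satdna": p.total_satdna,
             "n_clusters": len(p.clusters)}
            for p in pools
        ],
    }


@_stage("shape")
def _run_shape(cfg: RunConfig, motif: str) -> dict:
    array = motif * 30
    profile = dnashape.curvature_profile(
        array, window=cfg.curvature_window, step=cfg.curvature_step,
        twist_deg=cfg.twist_deg,
    )
    spectrum = dnashape.dft_spectrum(profile.values, fs=cfg.dft_fs)
    interesting = spectrum.power[2:].argmax() + 2  # skip near-DC leakage bins
    tracts = dnashape.find_tracts(array)
    phase = (
        dnashape.tract_phase_shift(tracts, fs=cfg.dft_fs)
        if tracts.a_tracts and tracts.t_tracts
        else None
    )
    return {
        "motif_length": len(motif),
        "n_a_tracts_per_motif": len(dnashape.find_tracts(motif).a_tracts),
        "mean_curvature_deg_per_turn": round(float(profile.values.mean()), 3),
        "dominant_bin": int(interesting),
        "dominant_period_bp": round(dnashape.bin_to_period(int(interesting),
                                                           cfg.dft_fs), 1),
        "motif_period_bin": dnashape.period_to_bin(len(motif), cfg.dft_fs),
        "at_phase_shift_deg": round(phase, 1) if phase is not None else None,
    }


@_stage("ltrage")
def _run_ltrage(cfg: RunConfig) -> dict:
    elements = ltrage.read_gff3_elements(cfg.gff)
    seq = _read_fasta_first(cfg.fasta)
    kept = []
    for el in elements:
        if el.ltr_length < cfg.min_ltr_length:
            log.warning("element %s skipped: LTR %d bp < %d",
                        el.id, el.ltr_length, cfg.min_ltr_length)
            continue
        k, events, _ = ltrage.align_ltrs(
            seq[el.ltr5[0] : el.ltr5[1]],
            seq[el.ltr3[0] : el.ltr3[1]],
            fragment=cfg.fragment,
        )
        el.k, el.events = k, events
        kept.append(el)
    dist = ltrage.mismatch_histogram(kept)
    model = ltrage.fit_divergence_model(
        dist, n_components=cfg.n_components, seed=cfg.seed
    )
    threshold = (
        cfg.young_threshold
        if cfg.young_threshold is not None
        else ltrage.threshold_from_model(model)
    )
    ltrage.classify_age(kept, threshold, mu=cfg.mu, fragment=cfg.fragment)
    scan = ltrage.enrichment_scan(
        kept, window=cfg.enrich_window, step=cfg.enrich_step
    )
    sig = [w for w in scan.windows if min(w["p_over"], w["p_under"]) < 0.05]
    lam, w, r2 = model.mixture
    return {
        "n_elements": len(kept),
        "histogram": {str(k): v for k, v in dist.counts.items()},
        "nbd": {"r": round(model.nbd[0], 4), "p": round(model.nbd[1], 4)}
        if model.overdispersed
        else {"r": None, "p": None, "note": "not overdispersed"},
        "gamma": {"shape": round(model.gamma[0], 4),
                  "scale": round(model.gamma[1], 4),
                  "mode": round(model.gamma_mode, 4)},
        "mixture": {"lambdas": [round(x, 3) for x in lam],
                    "weights": [round(x, 3) for x in w],
                    "r2": round(r2, 4)},
        "young_threshold": threshold,
        "age_threshold_years": round(threshold / (2 * cfg.mu * cfg.fragment)),
        "n_young": scan.n_young,
        "n_windows": len(scan.windows),
        "significant_windows": [
            {"span": list(map(int, w["span"])), "n_young": w["n_young"],
             "p_over": round(w["p_over"], 4), "p_under": round(w["p_under"], 4)}
            for w in sig
        ],
    }


@_stage("collinearity")
def _run_collinearity(cfg: RunConfig) -> dict:
    frags = collinearity.read_paf(cfg.paf)
    if not frags:
        return {"n_fragments": 0}
    qry_len = ref_len = 0
    with open(cfg.paf) as fh:
        first = fh.readline().split("\t")
        qry_len, ref_len = int(first[1]), int(first[6])
    kept = collinearity.filter_fragments(
        frags, min_len=cfg.min_frag_len, min_identity=cfg.min_frag_identity
    )
    chain = collinearity.chain_fragments(kept)
    calls = collinearity.call_divergence(
        chain, qry_len, ref_len,
        hdr_min=cfg.hdr_min, indel_min=cfg.indel_min,
        collinear_slop=cfg.collinear_slop,
    )
    cov = collinearity.coverage_map(
        kept, ref_len, min_similarity=cfg.coverage_min_similarity,
        window=cfg.coverage_window,
    )
    return {
        "n_fragments": len(frags),
        "n_after_filter": len(kept),
        "chain_strand": chain.strand,
        "chain_fragments": len(chain.fragments),
        "chain_total_aligned": chain.total_aligned,
        "divergence_calls": [
            {"kind": c.kind, "ref_span": list(c.ref_span),
             "qry_span": list(c.qry_span),
             "ref_gap": c.ref_gap, "qry_gap": c.qry_gap}
            for c in calls
        ],
        "mean_coverage": round(float(np.mean(cov)), 4),
    }


def run(config: RunConfig) -> str:
    """Execute the enabled stages; returns the report directory.

    Writes ``summary.json`` (stable, versioned schema) and ``run.log``.
    A stage failure aborts the run naming the stage and cause.
    """
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid configuration: " + "; ".join(issues))
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    handler = logging.FileHandler(os.path.join(out, "run.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    if not log.handlers or all(isinstance(h, logging.FileHandler) for h in log.handlers):
        stream = logging.StreamHandler(sys.stderr)
        log.addHandler(stream)

    path_keys = {"out_dir", "map_test", "map_refs", "trf_table", "fasta",
                 "gff", "paf"}
    summary: dict = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items()
            if k not in path_keys
        },
    }
    try:
        if config.synth:
            summary["synth"] = _run_synth(config, out)
        if config.mapcomp and config.map_test and config.map_refs:
            summary["mapcomp"] = _run_mapcomp(config)
        if config.satclust and config.trf_table:
            summary["satclust"] = _run_satclust(config)
        if config.shape:
            motif = synth.make_motif(seed=config.seed * 1000)
            summary["shape"] = _run_shape(config, motif)
        if config.ltrage and config.gff and config.fasta:
            summary["ltrage"] = _run_ltrage(config)
        if config.collinearity and config.paf:
            summary["collinearity"] = _run_collinearity(config)
    finally:
        log.removeHandler(handler)
        handler.close()

    with open(os.path.join(out, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
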