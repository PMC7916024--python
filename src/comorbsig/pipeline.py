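"""End-to-end orchestration: simulate -> DGE/meta -> overlap -> hubs -> enrichment.

A single :class:`RunConfig` (constructible from YAML) drives a reproducible
run: the multi-cohort disease arm is combined by effect-size meta-analysis,
the single-cohort arm by the moderated t-test; the two signatures are
compared by directional overlap statistics over the shared gene universe;
the concordant genes seed a network whose top-degree nodes are reported as
hubs; and the concordant lists are tested for gene-set and TF-regulon
over-representation.  Every stage writes a TSV and the run ends with a
manifest of config hash, per-file checksums and wall-clock times, which is
byte-reproducible under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .enrichment import cluster_terms, enrichment_table, ora, tf_enrichment
from .io_formats import ValidationError, write_results_tsv
from .network_hubs import build_network, hub_table, select_hubs
from .normalize_dge import call_degs, moderated_t_test, normalize_dataset
from .meta_analysis import run_meta
from .signature_overlap import Signature, overlap_table, partition_overlap
from .synthetic_data import SynthSpec, simulate_all

logger = logging.getLogger("comorbsig")

__all__ = ["RunConfig", "RunManifest", "run_all"]


@dataclass
class RunConfig:
    """Thresholds, seed and output location of one pipeline run."""

    synth: SynthSpec = field(default_factory=SynthSpec)
    dge_fdr: float = 0.1
    bonferroni_alpha: float = 0.05
    hub_fraction: float = 0.2
    kappa_threshold: float = 0.3
    normalization: str = "quantile"  # synthetic data is already log-scale
    seed: int = 0
    outdir: str = "comorbsig_run"

    def __post_init__(self) -> None:
        for name in ("bonferroni_alpha", "hub_fraction", "kappa_threshold"):
            value = getattr(self, name)
            if not 0 < value <= 1:
                raise ValidationError(f"{name} must lie in (0, 1]")
        if not 0 <= self.dge_fdr <= 1:
            raise ValidationError("dge_fdr must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        synth_raw = raw.pop("synth", {})
        preset = raw.pop("preset", None)
        if preset == "full_scale":
            synth = SynthSpec.full_scale(**synth_raw)
        else:
            synth = SynthSpec(**synth_raw)
        return cls(synth=synth, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunManifest:
    """Provenance record of one run: config hash, checksums, timings."""

    config_hash: str
    version: str
    seed: int
    checksums: dict[str, str]
    wall_clock: dict[str, float]
    summary: dict

    def write(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        # wall-clock varies between runs; keep it out of the reproducible core
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True), encoding="utf-8")

    def reproducible_core(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "checksums": self.checksums,
            "summary": self.summary,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _empty_signature(disease_id: str, background: frozenset[str]) -> Signature:
    return Signature(disease_id, frozenset(), frozenset(), background)


def run_all(config: RunConfig) -> RunManifest:
    """Execute the full synthetic-study pipeline and write all outputs.

    Stages: simulate, normalize, meta-analysis (disease A), moderated-t DGE
    (disease B), directional signature overlap, hub detection on the
    common-DEG network, gene-set and TF-regulon enrichment of the concordant
    lists.  A failing stage aborts with its name; outputs written so far are
    left with a ``.partial`` marker file alongside.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    partial_marker = outdir / ".partial"
    partial_marker.write_text("run in progress\n", encoding="utf-8")

    checksums: dict[str, str] = {}
    timings: dict[str, float] = {}
    summary: dict = {}
    stage = "simulate"

    def emit(name: str, table: pd.DataFrame) -> None:
        path = outdir / name
        write_results_tsv(table, path)
        checksums[name] = _sha256(path)

    try:
        t0 = time.perf_counter()
        sim = simulate_all(config.synth, seed=config.seed)
        truth = sim["truth"]
        background = frozenset(truth.genes)
        timings[stage] = time.perf_counter() - t0

        stage = "normalize"
        t0 = time.perf_counter()
        datasets_a = [normalize_dataset(ds, config.normalization) for ds in sim["datasets_a"]]
        datasets_b = [normalize_dataset(ds, config.normalization) for ds in sim["datasets_b"]]
        timings[stage] = time.perf_counter() - t0

        stage = "meta_disease_a"
        t0 = time.perf_counter()
        meta_table, sig_a = run_meta(
            datasets_a, fdr_threshold=config.dge_fdr, disease_id="disease_A"
        )
        emit("meta_disease_a.tsv", meta_table)
        timings[stage] = time.perf_counter() - t0

        stage = "dge_disease_b"
        t0 = time.perf_counter()
        if len(datasets_b) == 1:
            dge_table = moderated_t_test(datasets_b[0])
            sig_b = call_degs(
                dge_table, fdr_threshold=config.dge_fdr, disease_id="disease_B",
                background=frozenset(datasets_b[0].gene_ids),
            )
        else:
            dge_table, sig_b = run_meta(
                datasets_b, fdr_threshold=config.dge_fdr, disease_id="disease_B"
            )
        emit("dge_disease_b.tsv", dge_table)
        timings[stage] = time.perf_counter() - t0

        stage = "overlap"
        t0 = time.perf_counter()
        shared = sig_a.background & sig_b.background
        sig_a = Signature("disease_A", sig_a.up & shared, sig_a.down & shared, shared)
        sig_b = Signature("disease_B", sig_b.up & shared, sig_b.down & shared, shared)
        overlaps = partition_overlap(sig_a, sig_b)
        emit("overlap.tsv", overlap_table(overlaps))
        by_label = {o.partition: o for o in overlaps}
        concordant = sorted(
            set(by_label["up_up"].overlap_genes) | set(by_label["down_down"].overlap_genes)
        )
        summary["n_deg_disease_a"] = len(sig_a)
        summary["n_deg_disease_b"] = len(sig_b)
        summary["overlap_partitions"] = {o.partition: o.k for o in overlaps}
        timings[stage] = time.perf_counter() - t0

        stage = "hubs"
        t0 = time.perf_counter()
        common_sig = Signature(
            "common",
            frozenset(by_label["up_up"].overlap_genes),
            frozenset(by_label["down_down"].overlap_genes),
            shared,
        )
        if concordant:
            network = build_network(common_sig, sim["edges"])
            hubs = select_hubs(network, fraction=config.hub_fraction)
            emit("hubs.tsv", hub_table(network, hubs))
            summary["n_network_nodes"] = len(network)
            summary["n_hubs"] = len(hubs)
        else:
            emit("hubs.tsv", pd.DataFrame(columns=["node", "role", "degree", "is_hub"]))
            summary["n_network_nodes"] = 0
            summary["n_hubs"] = 0
        timings[stage] = time.perf_counter() - t0

        stage = "enrichment"
        t0 = time.perf_counter()
        if concordant:
            rows = ora(set(concordant), sim["gene_sets"], set(shared))
            clusters = cluster_terms(
                rows, sim["gene_sets"], set(shared),
                similarity_threshold=config.kappa_threshold, alpha=config.bonferroni_alpha,
            )
            emit("enrichment.tsv", enrichment_table(rows, clusters))
            summary["n_significant_terms"] = sum(
                r.p_bonf < config.bonferroni_alpha for r in rows
            )
            summary["n_term_clusters"] = len(clusters)
        else:
            emit("enrichment.tsv", enrichment_table([]))
            summary["n_significant_terms"] = 0
            summary["n_term_clusters"] = 0
        timings[stage] = time.perf_counter() - t0

        stage = "tf_enrichment"
        t0 = time.perf_counter()
        if concordant:
            tf_rows = tf_enrichment(set(concordant), sim["regulons"], set(shared))
            emit("tf_enrichment.tsv", enrichment_table(tf_rows))
            summary["n_significant_tfs"] = sum(
                r.p_bonf < config.bonferroni_alpha for r in tf_rows
            )
        else:
            emit("tf_enrichment.tsv", enrichment_table([]))
            summary["n_significant_tfs"] = 0
        timings[stage] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    config_dict = config.to_dict()
    config_dict.pop("outdir", None)  # output location does not affect results
    config_blob = json.dumps(config_dict, sort_keys=True).encode()
    manifest = RunManifest(
        config_hash=hashlib.sha256(config_blob).hexdigest(),
        version=__version__,
        seed=config.seed,
        checksums=checksums,
        wall_clock=timings,
        summary=summary,
    )
    manifest.write(outdir / "manifest.json")
    partial_marker.unlink(missing_ok=True)
    return manifest
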