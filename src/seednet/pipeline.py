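"""End-to-end orchestration: synth/load -> build -> metrics -> keys -> enrich.

One :class:`RunConfig` drives the whole analysis; every stage writes its
artifact under the output directory and the run ends with a
machine-readable ``summary.json`` whose counts are asserted to agree
with the written artifacts. Defaults encode the reference analysis
choices: ortholog e-value cutoff 0.5, induced first-neighbor expansion,
Top-50 ranking on the (degree, betweenness) and (closeness, radiality)
pairs, enrichment at p < 0.001 with the 100-gene generic-term filter.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd
import yaml

from . import __version__
from . import centrality as cm
from . import enrichment as em
from . import io as sio
from . import keys as km
from . import network as nm
from . import synthetic as sm
from .exceptions import ConfigurationError, SeedNetError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (synthetic or file-based inputs)."""

    out_dir: str = "seednet_run"
    synthetic: sm.SyntheticConfig | None = None
    network_path: str | None = None
    network_dialect: str = "sif"
    daps_path: str | None = None
    hits_path: str | None = None
    annotations_path: str | None = None
    term_labels_path: str | None = None
    e_cutoff: float = 0.5
    expansion: str = "induced"
    k: int = 50
    pairs: tuple[tuple[str, str], ...] = km.DEFAULT_METRIC_PAIRS
    p_threshold: float = 1e-3
    max_term_size: int = 100
    keywords: tuple[str, ...] = km.DEFAULT_KEYWORDS
    uppercase_ids: bool = False
    make_plots: bool = False
    rng_seed: int = 0

    def as_dict(self) -> dict:
        d = asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = self.synthetic.as_dict()
        d["pairs"] = [list(p) for p in self.pairs]
        d["keywords"] = list(self.keywords)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("synthetic") is not None:
            d["synthetic"] = sm.SyntheticConfig.from_dict(d["synthetic"])
        if "pairs" in d:
            d["pairs"] = tuple(tuple(p) for p in d["pairs"])
        if "keywords" in d:
            d["keywords"] = tuple(d["keywords"])
        return cls(**d)


def load_run_config(path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        return validate_config(RunConfig.from_dict(yaml.safe_load(fh)))


def validate_config(config: RunConfig) -> RunConfig:
    """Check thresholds, modes and referenced files; returns the config."""
    if config.e_cutoff <= 0:
        raise ConfigurationError(f"e_cutoff must be > 0, got {config.e_cutoff}")
    if config.k < 1:
        raise ConfigurationError(f"k must be >= 1, got {config.k}")
    if config.p_threshold <= 0 or config.max_term_size <= 0:
        raise ConfigurationError(
            "p_threshold and max_term_size must be positive")
    if config.expansion not in nm.EXPANSION_MODES:
        raise ConfigurationError(
            f"expansion must be one of {nm.EXPANSION_MODES}, got {config.expansion!r}")
    if not config.keywords:
        raise ConfigurationError("keywords must be non-empty")
    if config.synthetic is not None:
        config.synthetic.validate()
    else:
        for name in ("network_path", "daps_path", "hits_path"):
            p = getattr(config, name)
            if p is None:
                raise ConfigurationError(f"{name} is required without a synthetic config")
            if not Path(p).exists():
                raise ConfigurationError(f"{name}: no such file: {p}")
        for name in ("annotations_path", "term_labels_path"):
            p = getattr(config, name)
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"{name}: no such file: {p}")
    return config


def config_hash(config: RunConfig) -> str:
    """Fingerprint of the analysis-relevant configuration.

    The output directory is excluded: two runs of the same analysis into
    different locations share a hash (and, by design, byte-identical
    artifacts).
    """
    d = config.as_dict()
    d.pop("out_dir", None)
    canonical = json.dumps(d, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode()).hexdigest()


def log_provenance(config: RunConfig, out_dir: Path) -> dict:
    """Stamp versions, seed and config hash; stable for identical configs."""
    import numpy
    import scipy

    record = {
        "seednet_version": __version__,
        "python_version": platform.python_version(),
        "networkx_version": nx.__version__,
        "numpy_version": numpy.__version__,
        "scipy_version": scipy.__version__,
        "pandas_version": pd.__version__,
        "rng_seed": config.rng_seed,
        "config_hash": config_hash(config),
    }
    _write_json(record, out_dir / "provenance.json")
    return record


def _write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _write_mapping(mapping: nm.SeedMapping, daps, path) -> None:
    by_query = {d.query_id: d for d in daps}
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("query_id\tstatus\tsubject_id\te_value\tbit_score\tregulation\n")
        for d in daps:
            q = d.query_id
            if q in mapping.mapped:
                h = mapping.hit_used[q]
                fh.write(f"{q}\tmapped\t{h.subject_id}\t{h.e_value:.3e}\t"
                         f"{h.bit_score:.1f}\t{d.regulation}\n")
            else:
                fh.write(f"{q}\tunmapped\t\t\t\t{d.regulation}\n")


def _write_enrichment(results, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("term_id\tnamespace\tN\tB\tn\tb\tp_value\tenrichment_ratio\tq_value\n")
        for r in results:
            q = "" if r.q_value is None else f"{r.q_value:.6e}"
            fh.write(f"{r.term_id}\t{r.namespace}\t{r.N}\t{r.B}\t{r.n}\t{r.b}\t"
                     f"{r.p_value:.6e}\t{r.enrichment_ratio:.4f}\t{q}\n")


def _stage(name: str):
    logger.info("stage: %s", name)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order and return the run summary dict.

    Any stage failure is re-raised wrapped with the stage name; partial
    outputs written so far are retained for debugging.
    """
    validate_config(config)
    out = sio.ensure_dir(config.out_dir)

    handler = logging.FileHandler(out / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("seednet")
    root.addHandler(handler)
    stage = "setup"
    try:
        log_provenance(config, out)
        with open(out / "config.yaml", "w", encoding="utf-8", newline="\n") as fh:
            yaml.safe_dump(config.as_dict(), fh, sort_keys=True)

        stage = "inputs"
        _stage(stage)
        bundle = None
        annotations = None
        term_labels = None
        if config.synthetic is not None:
            bundle = sm.generate_bundle(config.synthetic)
            sm.write_bundle(bundle, out / "bundle")
            network, daps, hits = bundle.network, bundle.daps, bundle.ortholog_hits
            annotations = bundle.annotations
        else:
            pairs = sio.read_edge_list(config.network_path,
                                       dialect=config.network_dialect,
                                       uppercase_ids=config.uppercase_ids)
            network = nm.build_network(pairs)
            daps = sio.read_dap_table(config.daps_path)
            hits = sio.read_blast_tabular(config.hits_path,
                                          uppercase_ids=config.uppercase_ids)
            if config.annotations_path:
                if config.term_labels_path:
                    term_labels = sio.read_term_labels(config.term_labels_path)
                annotations = sio.read_annotations(config.annotations_path,
                                                   term_labels=term_labels)

        stage = "map_seeds"
        _stage(stage)
        mapping = nm.map_seeds(daps, hits, network, e_cutoff=config.e_cutoff)
        _write_mapping(mapping, daps, out / "mapping.tsv")

        stage = "subnetworks"
        _stage(stage)
        core = nm.core_subnetwork(network, mapping.mapped_nodes)
        sio.write_edge_list(core.edges, out / "core.sif")
        pgn = nm.expand_first_neighbors(network, mapping.mapped_nodes,
                                        mode=config.expansion)
        sio.write_edge_list(pgn.edges, out / "pgn.sif")
        giant, small = nm.giant_component(pgn)
        sio.write_edge_list(giant.edges, out / "pgn_giant.sif")
        _write_json({"small_cluster_sizes": [len(c) for c in small],
                     "small_clusters": [sorted(c) for c in small]},
                    out / "small_clusters.json")

        stage = "centrality"
        _stage(stage)
        table = cm.compute_centrality_table(giant)
        table.to_csv(out / "centrality.tsv", sep="\t", float_format="%.10g")
        corr = km.metric_correlations(table)
        corr.to_csv(out / "correlations.tsv", sep="\t", float_format="%.6f")
        try:
            exponent, r2 = cm.fit_power_law(list(table["degree"]))
            degree_fit = {"exponent": round(exponent, 6), "r_squared": round(r2, 6)}
        except ValidationError:
            degree_fit = None

        stage = "key_selection"
        _stage(stage)
        report = km.build_key_report(
            table, k=config.k, pairs=config.pairs, annotations=annotations,
            keywords=config.keywords, mapping=mapping, daps=daps)
        keys_dir = sio.ensure_dir(out / "keys")
        for metric, s in report.topk.items():
            sio.write_gene_list(s, keys_dir / f"topk_{metric}.txt")
        for label, s in report.pair_sets.items():
            sio.write_gene_list(s, keys_dir / f"pair_{label.replace('+', '_')}.txt")
        sio.write_gene_list(report.candidates, keys_dir / "candidates.txt")
        with open(keys_dir / "key_proteins.tsv", "w", encoding="utf-8",
                  newline="\n") as fh:
            fh.write("node\tmatched_keyword\n")
            for node in sorted(report.key_proteins):
                fh.write(f"{node}\t{report.matched_keywords[node]}\n")
        with open(keys_dir / "dap_overlap.tsv", "w", encoding="utf-8",
                  newline="\n") as fh:
            fh.write("node\tquery_id\tregulation\n")
            for o in report.dap_overlap:
                fh.write(f"{o.node}\t{o.query_id}\t{o.regulation}\n")

        stage = "enrichment"
        _stage(stage)
        enrichment_results = []
        if annotations is not None:
            enrichment_results = em.enrich(
                set(giant.nodes), set(network.nodes), annotations,
                p_threshold=config.p_threshold,
                max_term_size=config.max_term_size)
            _write_enrichment(enrichment_results, out / "enrichment.tsv")
        esummary = em.summarize_enrichment(enrichment_results)

        stage = "plots"
        if config.make_plots:
            _stage(stage)
            from . import plots
            plots.degree_ccdf_plot(list(table["degree"]), out / "degree_ccdf.png")
            plots.correlation_heatmap(corr, out / "correlation_heatmap.png")

        stage = "summary"
        _stage(stage)
        reg = km.regulation_counts(report.dap_overlap)
        summary = {
            "config_hash": config_hash(config),
            "rng_seed": config.rng_seed,
            "seeds": {
                "total": len(daps),
                "mapped": len(mapping.mapped),
                "unmapped": len(mapping.unmapped),
                "distinct_mapped_nodes": len(mapping.mapped_nodes),
            },
            "network": {"nodes": network.number_of_nodes(),
                        "edges": network.number_of_edges()},
            "core": {"nodes": core.number_of_nodes(),
                     "edges": core.number_of_edges()},
            "pgn": {"nodes": pgn.number_of_nodes(),
                    "edges": pgn.number_of_edges()},
            "giant": {"nodes": giant.number_of_nodes(),
                      "edges": giant.number_of_edges(),
                      "diameter": table.attrs["diameter"]},
            "small_cluster_sizes": [len(c) for c in small],
            "degree_fit": degree_fit,
            "topk_sizes": {m: len(s) for m, s in report.topk.items()},
            "pair_set_sizes": {l: len(s) for l, s in report.pair_sets.items()},
            "candidate_count": len(report.candidates),
            "key_protein_count": len(report.key_proteins),
            "venn": {"only_first": report.venn[0], "only_second": report.venn[1],
                     "both": report.venn[2]},
            "dap_overlap": {"total": len(report.dap_overlap),
                            "up": reg["up"], "down": reg["down"]},
            "enrichment": {"total": esummary.total, "MF": esummary.mf,
                           "BP": esummary.bp},
        }
        _check_summary_identities(summary, report, mapping, pgn)
        _write_json(summary, out / "summary.json")
        return summary
    except SeedNetError as exc:
        raise SeedNetError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()


def _check_summary_identities(summary: dict, report: km.KeyProteinReport,
                              mapping: nm.SeedMapping, pgn: nx.Graph) -> None:
    s = summary
    assert s["seeds"]["mapped"] + s["seeds"]["unmapped"] == s["seeds"]["total"]
    assert s["pgn"]["nodes"] == s["giant"]["nodes"] + sum(s["small_cluster_sizes"])
    assert report.key_proteins <= report.candidates
    v = s["venn"]
    assert v["only_first"] + v["only_second"] + v["both"] <= s["key_protein_count"]
    assert s["dap_overlap"]["up"] + s["dap_overlap"]["down"] == s["dap_overlap"]["total"]
    assert s["enrichment"]["MF"] + s["enrichment"]["BP"] == s["enrichment"]["total"]
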