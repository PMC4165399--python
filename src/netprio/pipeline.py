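"""End-to-end orchestration: expression contrasts -> DEGs -> parent network
-> subnetworks -> topology -> RWR layers -> enrichment comparison.

A single YAML config drives the run.  Exactly one of two input blocks must be
present: ``synthetic`` (all generator parameters; one master seed derives the
per-stage RNG seeds) or ``input`` (paths to expression matrices, PPI edge
lists and a GMT collection).  Re-running with the same config reproduces
byte-identical outputs; a JSON manifest records parameters, seeds and file
checksums.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import deg as deg_mod
from . import enrichment as enr_mod
from . import network as net_mod
from . import rwr as rwr_mod
from . import subnetwork as sub_mod
from . import synthetic as syn_mod
from . import topology as top_mod
from .errors import InvalidParameterError

log = logging.getLogger(__name__)

DEFAULTS: dict[str, Any] = {
    "output_dir": "netprio_out",
    "deg": {"threshold": 1.5},
    "rwr": {"seed_gene": "auto", "restart": 0.7, "tolerance": 1e-10,
            "max_iterations": 10_000},
    "enrichment": {"alpha": 0.05, "overlap_cutoff": 0.6, "method": "fisher"},
}


@dataclass(frozen=True)
class PipelineConfig:
    """Validated run configuration (see :data:`DEFAULTS` for the constants)."""

    raw: dict[str, Any]

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        merged = copy.deepcopy(DEFAULTS)
        for key, value in (data or {}).items():
            if isinstance(value, dict) and isinstance(merged.get(key), dict):
                merged[key].update(value)
            else:
                merged[key] = value
        cfg = cls(raw=merged)
        problems = cfg.problems()
        if problems:
            raise InvalidParameterError("invalid config: " + "; ".join(problems))
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def problems(self) -> list[str]:
        return _problems(self.raw)

    def __getitem__(self, key: str) -> Any:
        return self.raw[key]


def _problems(cfg: dict[str, Any]) -> list[str]:
    problems: list[str] = []
    has_syn = "synthetic" in cfg and cfg["synthetic"] is not None
    has_input = "input" in cfg and cfg["input"] is not None
    if has_syn == has_input:
        problems.append("exactly one of the 'synthetic' and 'input' blocks must be present")
    threshold = cfg.get("deg", {}).get("threshold", 1.5)
    if not isinstance(threshold, (int, float)) or not threshold > 1:
        problems.append(f"deg threshold must exceed 1, got {threshold}")
    rwr = cfg.get("rwr", {})
    r = rwr.get("restart", 0.7)
    if not (isinstance(r, (int, float)) and 0 < r <= 1):
        problems.append(f"rwr restart probability must lie in (0, 1], got {r}")
    tol = rwr.get("tolerance", 1e-10)
    if not (isinstance(tol, (int, float)) and tol > 0):
        problems.append(f"rwr tolerance must be positive, got {tol}")
    seed_gene = rwr.get("seed_gene")
    if not seed_gene:
        problems.append("rwr seed_gene is required ('auto' allowed with synthetic input)")
    elif seed_gene == "auto" and has_input:
        problems.append("rwr seed_gene 'auto' is only valid with synthetic input")
    enrich = cfg.get("enrichment", {})
    alpha = enrich.get("alpha", 0.05)
    if not (isinstance(alpha, (int, float)) and 0 < alpha):
        problems.append(f"enrichment alpha must be positive, got {alpha}")
    cutoff = enrich.get("overlap_cutoff", 0.6)
    if not (isinstance(cutoff, (int, float)) and 0 <= cutoff <= 1):
        problems.append(f"enrichment overlap_cutoff must lie in [0, 1], got {cutoff}")
    if enrich.get("method", "fisher") not in ("fisher", "ease"):
        problems.append(f"enrichment method must be fisher or ease, got {enrich.get('method')}")
    if has_syn:
        syn = cfg["synthetic"]
        if "seed" not in syn:
            problems.append("synthetic block requires an integer 'seed'")
        net = syn.get("network", {})
        if net.get("n_nodes", 0) <= net.get("edges_per_new_node", 1):
            problems.append("synthetic network needs n_nodes > edges_per_new_node")
    if has_input:
        inp = cfg["input"]
        if not inp.get("expression_a"):
            problems.append("input block requires expression_a (TSV gene/control/case)")
        if not inp.get("networks"):
            problems.append("input block requires at least one network file")
        if not inp.get("gmt"):
            problems.append("input block requires a gmt gene-set file")
    return problems


def validate(config_path: str | Path) -> list[str]:
    """Schema-check a config file without executing anything."""
    data = yaml.safe_load(Path(config_path).read_text()) or {}
    merged = copy.deepcopy(DEFAULTS)
    for key, value in data.items():
        if isinstance(value, dict) and isinstance(merged.get(key), dict):
            merged[key].update(value)
        else:
            merged[key] = value
    return _problems(merged)


def demo_config_path() -> Path:
    """Path of the shipped synthetic demo configuration."""
    return Path(__file__).parent / "data" / "demo.yaml"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(payload: Any, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


@dataclass
class PipelineResult:
    outdir: Path
    manifest: dict[str, Any]
    degs: dict[str, deg_mod.DEGTable] = field(default_factory=dict)
    rwr: dict[str, rwr_mod.RWRResult] = field(default_factory=dict)
    charts: dict[str, enr_mod.EnrichmentResult] = field(default_factory=dict)
    truths: dict[str, syn_mod.SyntheticTruth] = field(default_factory=dict)


def _load_inputs(cfg: PipelineConfig, outdir: Path):
    """Return (parent network, contrasts {name: ExpressionPair-or-DEG source},
    gene-set collection, truths)."""
    truths: dict[str, syn_mod.SyntheticTruth] = {}
    if cfg.raw.get("synthetic"):
        syn = cfg["synthetic"]
        master = int(syn["seed"])
        net_cfg = syn.get("network", {})
        parent = syn_mod.generate_scale_free_network(
            n_nodes=int(net_cfg.get("n_nodes", 2000)),
            edges_per_new_node=int(net_cfg.get("edges_per_new_node", 2)),
            rng_seed=master,
        )
        expr = syn.get("expression", {})
        kwargs = dict(
            n_up=int(expr.get("n_up", 50)),
            n_down=int(expr.get("n_down", 50)),
            fc_low=float(expr.get("fc_low", 1.8)),
            fc_high=float(expr.get("fc_high", 3.0)),
            noise_sd=float(expr.get("noise_sd", 0.3)),
        )
        pair_a, truth_a = syn_mod.generate_expression_pair(
            parent, rng_seed=master + 1, labels=("control", "condA"), **kwargs)
        pair_b, truth_b = syn_mod.generate_expression_pair(
            parent, rng_seed=master + 2, labels=("control", "condB"), **kwargs)
        truths["A_vs_control"], truths["B_vs_control"] = truth_a, truth_b
        gs = syn.get("gene_sets", {})
        collection = syn_mod.generate_gene_sets(
            sorted(parent.nodes),
            n_sets=int(gs.get("n_sets", 40)),
            size_low=int(gs.get("size_low", 10)),
            size_high=int(gs.get("size_high", 80)),
            rng_seed=master + 3,
        )
        net_mod.write_edge_list(parent, outdir / "networks" / "parent.tsv")
        deg_mod.write_expression_tsv(pair_a, outdir / "degs" / "expression_A.tsv")
        deg_mod.write_expression_tsv(pair_b, outdir / "degs" / "expression_B.tsv")
        truth_a.write_json(outdir / "degs" / "truth_A.json")
        truth_b.write_json(outdir / "degs" / "truth_B.json")
        enr_mod.write_gmt(collection, outdir / "enrichment" / "gene_sets.gmt")
        pairs = {"A_vs_control": pair_a, "B_vs_control": pair_b}
    else:
        inp = cfg["input"]
        networks = [
            net_mod.read_edge_list(item["path"], dialect=item.get("dialect", "generic-tsv"))
            for item in inp["networks"]
        ]
        parent = net_mod.integrate(networks)
        pairs = {"A_vs_control": deg_mod.read_expression_tsv(inp["expression_a"])}
        if inp.get("expression_b"):
            pairs["B_vs_control"] = deg_mod.read_expression_tsv(inp["expression_b"])
        collection = enr_mod.read_gmt(inp["gmt"])
    return parent, pairs, collection, truths


def _pick_seed_gene(cfg_seed: str, subnet: sub_mod.Subnetwork, mapped: set[str]) -> str:
    if cfg_seed != "auto":
        return cfg_seed
    # auto: the mapped DEG with the highest degree in the subnetwork
    return max(mapped, key=lambda g: (subnet.graph.degree(g), g))


def run(config: PipelineConfig | dict | str | Path, outdir: str | Path | None = None) -> PipelineResult:
    """Execute the full workflow and write the result bundle.

    Produces, per contrast: DEG table, subnetwork files, topology report,
    RWR score/layer tables, and an enrichment chart; plus a chart comparison
    across contrasts and a manifest with parameters, seeds and checksums.
    """
    if isinstance(config, (str, Path)):
        config = PipelineConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    outdir = Path(outdir if outdir is not None else config.raw["output_dir"])
    for sub in ("degs", "networks", "topology", "rwr", "enrichment"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    result = PipelineResult(outdir=outdir, manifest={})
    timings: dict[str, float] = {}
    stage = "load-inputs"
    try:
        t0 = time.perf_counter()
        parent, pairs, collection, truths = _load_inputs(config, outdir)
        result.truths = truths
        timings[stage] = time.perf_counter() - t0

        stage = "deg"
        t0 = time.perf_counter()
        threshold = float(config["deg"]["threshold"])
        contrasts: dict[str, deg_mod.DEGTable] = {
            name: deg_mod.degs_from_pair(pair, threshold) for name, pair in pairs.items()
        }
        if len(pairs) == 2:
            a, b = pairs["A_vs_control"], pairs["B_vs_control"]
            contrasts["A_vs_B"] = deg_mod.contrast_profiles(a, b, threshold)
        for name, table in contrasts.items():
            table.write_tsv(outdir / "degs" / f"{name}.degs.tsv")
        result.degs = contrasts
        timings[stage] = time.perf_counter() - t0

        background = collection.all_members() & set(parent.nodes) \
            if config.raw.get("synthetic") else collection.all_members()
        rwr_cfg, enr_cfg = config["rwr"], config["enrichment"]
        comparison_charts: dict[str, enr_mod.EnrichmentResult] = {}

        for name, table in contrasts.items():
            stage = f"subnetwork[{name}]"
            t0 = time.perf_counter()
            mapped, unmapped = sub_mod.map_degs(parent, table)
            _write_json(
                {"mapped": sorted(mapped), "unmapped": sorted(unmapped)},
                outdir / "networks" / f"{name}.mapping.json",
            )
            if not mapped:
                log.warning("contrast %s: no DEG mapped to the parent network", name)
                continue
            fn_sub = sub_mod.first_neighbor_subnetwork(parent, mapped, table.directions)
            dd_sub = sub_mod.deg_deg_subnetwork(parent, mapped, table.directions)
            dd_core = sub_mod.largest_component(dd_sub)
            fn_sub.write(outdir / "networks" / f"{name}.first_neighbor")
            dd_sub.write(outdir / "networks" / f"{name}.deg_deg")
            _write_json(
                {"first_neighbor": fn_sub.summary(), "deg_deg": dd_sub.summary(),
                 "deg_deg_largest_component": dd_core.summary()},
                outdir / "networks" / f"{name}.summary.json",
            )
            timings[stage] = time.perf_counter() - t0

            stage = f"topology[{name}]"
            t0 = time.perf_counter()
            report = top_mod.topology_report(fn_sub.graph)
            _write_json(report.to_dict(), outdir / "topology" / f"{name}.report.json")
            dist = top_mod.degree_distribution(fn_sub.graph)
            with (outdir / "topology" / f"{name}.degree_distribution.tsv").open("w") as fh:
                fh.write("degree\tcount\n")
                for k, c in dist.points:
                    fh.write(f"{k}\t{c}\n")
            timings[stage] = time.perf_counter() - t0

            stage = f"rwr[{name}]"
            t0 = time.perf_counter()
            seed_gene = _pick_seed_gene(rwr_cfg["seed_gene"], fn_sub, mapped)
            params = rwr_mod.RWRParams(
                restart_probability=float(rwr_cfg["restart"]),
                tolerance=float(rwr_cfg["tolerance"]),
                max_iterations=int(rwr_cfg["max_iterations"]),
            )
            rwr_result = rwr_mod.run_rwr(fn_sub.graph, {seed_gene}, params)
            result.rwr[name] = rwr_result
            rwr_mod.rank_table(rwr_result).to_csv(
                outdir / "rwr" / f"{name}.scores.tsv", sep="\t", index=False,
                float_format="%.10g")
            rwr_mod.rank_genes(rwr_result, table).to_csv(
                outdir / "rwr" / f"{name}.deg_ranking.tsv", sep="\t", index=False,
                float_format="%.10g")
            timings[stage] = time.perf_counter() - t0

            stage = f"enrichment[{name}]"
            t0 = time.perf_counter()
            chart = enr_mod.annotation_chart(
                table.genes, collection, background, method=enr_cfg["method"])
            significant = enr_mod.filter_significant(chart, float(enr_cfg["alpha"]))
            chart.write_tsv(outdir / "enrichment" / f"{name}.chart.tsv")
            significant.write_tsv(outdir / "enrichment" / f"{name}.chart.significant.tsv")
            edges, nodes = enr_mod.enrichment_map_edges(
                significant, collection, cutoff=float(enr_cfg["overlap_cutoff"]))
            edges.to_csv(outdir / "enrichment" / f"{name}.map_edges.tsv",
                         sep="\t", index=False, float_format="%.6g")
            nodes.to_csv(outdir / "enrichment" / f"{name}.map_nodes.tsv",
                         sep="\t", index=False, float_format="%.6g")
            result.charts[name] = significant
            comparison_charts[name] = significant
            timings[stage] = time.perf_counter() - t0

        stage = "chart-comparison"
        if "A_vs_control" in comparison_charts and "B_vs_control" in comparison_charts:
            t0 = time.perf_counter()
            unique_a, unique_b, shared = enr_mod.compare_charts(
                comparison_charts["A_vs_control"], comparison_charts["B_vs_control"])
            _write_json(
                {"unique_to_A": sorted(unique_a), "unique_to_B": sorted(unique_b),
                 "shared": sorted(shared)},
                outdir / "enrichment" / "chart_comparison.json",
            )
            timings[stage] = time.perf_counter() - t0
    except Exception as exc:
        failed_marker.write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    stage = "manifest"
    checksums = {
        str(p.relative_to(outdir)): _sha256(p)
        for p in sorted(outdir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "config": config.raw,
        "checksums": checksums,
        "timings_seconds": {k: round(v, 4) for k, v in timings.items()},
    }
    _write_json(manifest, outdir / "manifest.json")
    result.manifest = manifest
    return result
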