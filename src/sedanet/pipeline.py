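"""End-to-end orchestration of the sedaDNA network analysis.

Stage order: habitat split -> prevalence/abundance filter -> fixed-depth
resampling (pelagic and benthic branches separately) -> proxy
interpolation and young-end tail fill -> per-family environmental
tagging -> Spearman network, modules and neighbour/degree analyses ->
copula marginals, residuals and lambda path -> Jaccard-vs-null network
comparison -> stratigraphic diagnostics.  Only the pelagic branch feeds
the networks; the benthic branch contributes the stratigraphic ratios.
Every artifact is written under the run directory with a manifest
recording the configuration and seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import null_overlap
from .copula import dunn_smyth_residuals, fit_marginals, lambda_path
from .io import (InputError, export_network, read_annotation, read_count_table,
                 read_proxy_csv, split_by_habitat, write_count_table)
from .proxies import correlate_env, interpolate_to_ages, tail_fill
from .resample import filter_families, rarefy
from .spearman import (annotate_nodes, build_network, compare_degrees,
                       find_modules, neighbor_composition, pairwise_spearman)
from .strat import acf_screen, coniss, display_filter, group_ratio, pb_ratio

log = logging.getLogger("sedanet")


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, with defaults mirroring the analysis of
    the Kamchatka-slope record this package reimplements."""

    counts: str = "counts.tsv"
    annotation: str = "annotation.tsv"
    ip25: str = "ip25.csv"
    sst: str = "sst.csv"
    outdir: str = "run"
    # filter
    min_samples: int = 3
    min_total: int = 10
    # resampling; depths may be an int or "min" (per-branch minimum total)
    depth_pelagic: int | str = 6593
    depth_benthic: int | str = 1839
    n_iter: int = 500
    replace: bool = False
    # associations / Spearman network
    alpha: float = 0.1
    rho_min: float = 0.4
    module_method: str = "components"
    # copula
    marginal_family: str = "nb"
    lambda_headline: float = 0.51
    lambda_grid: list[float] = field(
        default_factory=lambda: list(np.round(np.arange(0.1, 1.01, 0.1), 2)))
    # comparison
    n_reps: int = 10
    n_swaps: int | None = None
    # diagnostics
    display_min_prop: float = 0.015
    acf_max_lag: int = 5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def _resolve_depth(depth, totals: pd.Series, branch: str) -> int:
    if depth == "min":
        d = int(totals.min())
        log.info("%s branch: resampling depth 'min' -> %d", branch, d)
        return d
    return int(depth)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write all artifacts; returns the run directory."""
    out = Path(config.outdir)
    (out / "diagnostics").mkdir(parents=True, exist_ok=True)
    seeds = {k: config.seed + i for i, k in enumerate(
        ["rarefy_pelagic", "rarefy_benthic", "residuals", "compare"])}

    cm = read_count_table(config.counts)
    ann = read_annotation(config.annotation)
    ip25 = read_proxy_csv(config.ip25, name="IP25")
    sst = read_proxy_csv(config.sst, name="SST")

    # --- habitat split, filter, resample --------------------------------
    pel, ben = split_by_habitat(cm, ann)
    log.info("split: %d pelagic / %d benthic families", *map(len, (
        pel.families, ben.families)))
    branches = {}
    filtered = {}
    for name, branch, depth_cfg, seed_key in (
            ("pelagic", pel, config.depth_pelagic, "rarefy_pelagic"),
            ("benthic", ben, config.depth_benthic, "rarefy_benthic")):
        filt = filter_families(branch, config.min_samples, config.min_total)
        log.info("%s: %d -> %d families after filter", name,
                 len(branch.families), len(filt.families))
        depth = _resolve_depth(depth_cfg, filt.sample_totals(), name)
        rs = rarefy(filt, depth, n_iter=config.n_iter, seed=seeds[seed_key],
                    replace=config.replace)
        branches[name] = rs
        filtered[name] = filt
        agg = rs.aggregate.copy()
        agg.insert(0, "age", rs.ages)
        agg.to_csv(out / f"resampled_{name}.tsv", sep="\t",
                   index_label="sample")
        write_count_table(filt, out / f"filtered_{name}.tsv")
    pel_rs = branches["pelagic"]
    ages = pel_rs.ages.to_numpy()

    # --- proxies and environmental tagging ------------------------------
    ip25_interp = tail_fill(interpolate_to_ages(ip25, ages))
    sst_interp = tail_fill(interpolate_to_ages(sst, ages))
    env = pd.DataFrame({"IP25": ip25_interp, "SST": sst_interp},
                       index=pel_rs.aggregate.index)
    env.to_csv(out / "proxies_interpolated.tsv", sep="\t",
               index_label="sample")
    assoc = pd.concat([
        correlate_env(pel_rs.aggregate, ip25_interp, "IP25", "ice",
                      alpha=config.alpha, rho_min=config.rho_min),
        correlate_env(pel_rs.aggregate, sst_interp, "SST", "warm",
                      alpha=config.alpha, rho_min=config.rho_min),
    ], ignore_index=True)
    assoc.to_csv(out / "env_associations.tsv", sep="\t", index=False)
    tags: dict[str, str] = {}
    for _, row in assoc.iterrows():
        if row["tag"] != "none":
            tags.setdefault(row["family"], row["tag"])

    # --- Spearman network ------------------------------------------------
    cr = pairwise_spearman(pel_rs.aggregate)
    net = build_network(cr, rho_min=config.rho_min, alpha=config.alpha)
    modules = find_modules(net, method=config.module_method)
    abundance = pel_rs.aggregate.sum(axis=0)
    annotate_nodes(net, abundance=abundance, ann=ann, env_tags=tags,
                   modules=modules)
    export_network(net, out / "network_spearman.graphml")
    export_network(net, out / "network_spearman_edges.tsv", format="tsv")
    pd.Series(modules, name="module").rename_axis("family").to_csv(
        out / "modules.tsv", sep="\t")
    log.info("Spearman network: %d nodes, %d edges, %d modules",
             net.number_of_nodes(), net.number_of_edges(),
             len(set(modules.values())))

    neighbor_tables = {}
    degree_tests = {}
    for tag_name in ("ice", "warm"):
        seed_fams = [f for f, t in tags.items() if t == tag_name and f in net]
        if not seed_fams:
            continue
        rep = neighbor_composition(net, seed_fams, ann)
        neighbor_tables[tag_name] = rep
        rep.table.rename_axis("functional_group").to_frame("links").to_csv(
            out / f"neighbors_{tag_name}.tsv", sep="\t")
        others = [f for f in net.nodes if f not in seed_fams]
        if len(seed_fams) >= 2 and len(others) >= 2:
            degree_tests[tag_name] = compare_degrees(net, seed_fams, others)

    # --- copula network ---------------------------------------------------
    counts_int = pel_rs.aggregate.round().astype(int)
    fits = fit_marginals(counts_int, env, family_model=config.marginal_family)
    scores = dunn_smyth_residuals(fits, counts_int, seed=seeds["residuals"])
    grid = sorted(set(config.lambda_grid) | {config.lambda_headline})
    graphs = lambda_path(scores, grid=grid)
    edge_counts = []
    for g in graphs:
        export_network(g.to_graph(), out / f"copula_lambda_{g.lam:g}.graphml")
        edge_counts.append({"lambda": g.lam, "n_edges": len(g.edges)})
    pd.DataFrame(edge_counts).to_csv(out / "copula_edge_counts.tsv",
                                     sep="\t", index=False)

    # --- comparison -------------------------------------------------------
    report = null_overlap(net.edges(), graphs, n_reps=config.n_reps,
                          seed=seeds["compare"], n_swaps=config.n_swaps)
    report.to_frame().to_csv(out / "comparison.tsv", sep="\t", index=False)

    # --- stratigraphic diagnostics ---------------------------------------
    diag = out / "diagnostics"
    # p:b ratio on the raw filtered counts — rarefied branches have fixed
    # row totals, which would make the ratio a constant
    ratios = pd.DataFrame({
        "age": ages,
        "pelagic_benthic_ratio": pb_ratio(
            filtered["pelagic"], filtered["benthic"]).to_numpy(),
        "phototroph_ratio": group_ratio(
            pel_rs.aggregate, ann, "phototrophic bacteria",
            ["centric diatoms", "pennate diatoms"]).to_numpy(),
    }, index=pel_rs.aggregate.index)
    ratios.to_csv(diag / "ratios.tsv", sep="\t", index_label="sample")
    acf_screen(pel_rs.aggregate, max_lag=config.acf_max_lag).to_csv(
        diag / "acf_flags.tsv", sep="\t")
    shown = display_filter(pel_rs.aggregate, config.min_samples,
                           config.display_min_prop)
    cres = coniss(pel_rs.aggregate[shown] if shown else pel_rs.aggregate)
    pd.DataFrame(cres.merges, columns=["left", "right", "increment"]).assign(
        height=cres.heights).to_csv(diag / "coniss_merges.tsv", sep="\t",
                                    index=False)
    pd.Series(shown, name="family").to_csv(diag / "displayed_families.tsv",
                                           sep="\t", index=False)

    # --- manifest ---------------------------------------------------------
    cfg = config.to_dict()
    manifest = {
        "version": __version__,
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
        "seeds": seeds,
        "spearman": {"nodes": net.number_of_nodes(),
                     "edges": net.number_of_edges(),
                     "modules": len(set(modules.values()))},
        "copula_edges": {str(e["lambda"]): e["n_edges"] for e in edge_counts},
        "degree_tests": {k: vars(v) for k, v in degree_tests.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out
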