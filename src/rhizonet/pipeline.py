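"""End-to-end pipeline: simulate/load -> network -> roles -> robustness -> metrics.

``run_pipeline`` executes the stages named in a configuration mapping and
writes every artefact (tables, GraphML, JSON reports) under an output
directory, together with a machine-readable ``summary.json``.  A single
integer seed is fanned out deterministically to every randomised stage,
so a fixed seed makes the whole bundle reproducible byte for byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, metrics, network as net, robustness as rob, roles as rl
from .errors import StageError, ValidationError
from .simulate import CommunityConfig, generate_community

logger = logging.getLogger("rhizonet")

STAGE_SEEDS = ("simulate", "robustness", "metrics")


def _fan_out_seed(seed: int | None) -> dict[str, int | None]:
    """Derive one independent child seed per randomised stage (< 2**31)."""
    if seed is None:
        return {s: None for s in STAGE_SEEDS}
    children = np.random.SeedSequence(seed).spawn(len(STAGE_SEEDS))
    return {s: int(c.generate_state(1)[0] % 2**31) for s, c in zip(STAGE_SEEDS, children)}


def _round_floats(obj, ndigits: int = 10):
    """Stable float formatting so summary files are byte-identical across runs."""
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def run_pipeline(config: dict, out_dir) -> dict:
    """Run the configured stages and return the summary mapping.

    ``config`` keys: ``seed`` (int), exactly one of ``simulate`` (community
    generator overrides, may be empty) or ``input`` (paths ``otu_table``,
    ``metadata``, optional ``orientation``), plus optional ``network``,
    ``roles``, ``robustness`` and ``metrics`` sections.  Any stage failure
    is re-raised as a StageError naming the stage.
    """
    if "simulate" not in config and "input" not in config:
        raise ValidationError("config must provide either a 'simulate' or an 'input' section")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _fan_out_seed(config.get("seed"))
    summary: dict = {"seed": config.get("seed")}

    # ---- stage: simulate / load -------------------------------------------
    truth = None
    try:
        if "simulate" in config:
            cfg = CommunityConfig(**{**(config["simulate"] or {}), "seed": seeds["simulate"]})
            table, metadata, truth = generate_community(cfg)
            io.write_otu_table(table, out / "otu_table.tsv")
            io.write_sample_metadata(metadata, out / "metadata.tsv")
            with open(out / "ground_truth.json", "w") as fh:
                json.dump(
                    {
                        "module_of": truth.module_of,
                        "keystones": truth.keystones,
                        "keystone_modules": truth.keystone_modules,
                    },
                    fh, indent=2, sort_keys=True,
                )
            summary["simulate"] = {
                "n_taxa": cfg.n_taxa,
                "n_samples": cfg.n_samples,
                "n_modules": cfg.n_modules,
                "n_keystones": cfg.n_keystones,
                "stage_seed": seeds["simulate"],
            }
        else:
            paths = config["input"]
            table = io.read_otu_table(paths["otu_table"],
                                      orientation=paths.get("orientation", "auto"))
            metadata = io.read_sample_metadata(paths["metadata"])
            metadata = io.align_metadata(table, metadata)
            summary["input"] = {"n_taxa": table.shape[0], "n_samples": table.shape[1]}
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError("simulate", exc) from exc

    # ---- stage: network ----------------------------------------------------
    try:
        ncfg = config.get("network", {})
        corr = net.spearman_matrix(
            table,
            prevalence_min=ncfg.get("prevalence_min", 0.0),
            abundance_min=ncfg.get("abundance_min", 0.0),
        )
        graph = net.build_network(
            corr,
            r_threshold=ncfg.get("r_threshold", 0.7),
            p_threshold=ncfg.get("p_threshold", 0.01),
            use_adjusted=ncfg.get("use_adjusted", True),
        )
        io.write_network(graph, out / "network.graphml", "graphml")
    except Exception as exc:
        raise StageError("network", exc) from exc

    # ---- stage: roles ------------------------------------------------------
    try:
        rcfg = config.get("roles", {})
        if graph.number_of_nodes():
            partition = rl.detect_modules(graph, method=rcfg.get("method", "louvain"))
            role_df = rl.node_roles(graph, partition,
                                    z_cut=rcfg.get("z_cut", rl.Z_CUT_DEFAULT),
                                    p_cut=rcfg.get("p_cut", rl.P_CUT_DEFAULT))
            role_df.to_csv(out / "roles.tsv", sep="\t")
            for node in graph.nodes():
                graph.nodes[node]["module"] = int(partition.membership[node])
                graph.nodes[node]["Z"] = float(role_df.loc[node, "Z"])
                graph.nodes[node]["P"] = float(role_df.loc[node, "P"])
                graph.nodes[node]["role"] = str(role_df.loc[node, "role"])
            io.write_network(graph, out / "network.graphml", "graphml")
            keystones = role_df.index[role_df["keystone"]].tolist()
            stats = net.topology_summary(graph, partition.membership)
        else:
            partition, role_df, keystones = None, None, []
            stats = None
        summary["network"] = stats.as_dict() if stats else {"n_nodes": 0, "n_edges": 0}
        summary["roles"] = {
            "n_modules": len(partition.sizes) if partition else 0,
            "modularity": partition.modularity if partition else None,
            "keystones": [str(k) for k in keystones],
        }
        with open(out / "topology.json", "w") as fh:
            json.dump(_round_floats(summary["network"]), fh, indent=2, sort_keys=True)
    except Exception as exc:
        raise StageError("roles", exc) from exc

    # ---- stage: robustness -------------------------------------------------
    try:
        bcfg = config.get("robustness", {})
        if keystones and graph.number_of_nodes() > len(keystones):
            report = rob.keystone_removal_test(
                graph, keystones, n_null=bcfg.get("n_null", 999), seed=seeds["robustness"]
            )
            summary["robustness"] = report.as_dict()
            with open(out / "removal_test.json", "w") as fh:
                json.dump(_round_floats(report.as_dict()), fh, indent=2, sort_keys=True)
            curve = rob.robustness_curve(graph, strategy="degree-ranked",
                                         n_remove=min(20, graph.number_of_nodes() - 1))
            pd.DataFrame(
                {"removed": curve.removed_counts, "natural_connectivity": curve.connectivity}
            ).to_csv(out / "robustness_curve.tsv", sep="\t", index=False)
        else:
            summary["robustness"] = {"note": "no keystones detected; removal test skipped"}
    except Exception as exc:
        raise StageError("robustness", exc) from exc

    # ---- stage: metrics ----------------------------------------------------
    try:
        mcfg = config.get("metrics", {})
        depth = mcfg.get("rarefaction_depth")
        if depth is None:
            depth = int(table.counts.sum(axis=0).min())
        div = metrics.alpha_diversity(table, rarefaction_depth=depth, seed=seeds["metrics"])
        div.to_csv(out / "diversity.tsv", sep="\t")
        dist = metrics.bray_curtis(table)
        dist.to_csv(out / "bray_curtis.tsv", sep="\t")
        coords = metrics.pcoa(dist, k=2)
        coords.coordinates.to_csv(out / "pcoa.tsv", sep="\t")
        grouping = metadata["nematode_added"].astype(str)
        r_stat, p_val = metrics.anosim(dist, grouping,
                                       n_perm=mcfg.get("anosim_permutations", 999),
                                       seed=seeds["metrics"])
        pressure = metrics.predation_pressure(metadata, scale=mcfg.get("pressure_scale", 1.0))
        pressure.to_csv(out / "predation_pressure.tsv", sep="\t")
        summary["metrics"] = {
            "rarefaction_depth": depth,
            "shannon_mean": float(div["shannon"].mean()),
            "chao1_mean": float(div["chao1"].mean()),
            "anosim_R": r_stat,
            "anosim_p": p_val,
            "pcoa_axis1_proportion": float(coords.proportion_explained[0]),
            "predation_pressure_by_group": {
                str(g): float(v)
                for g, v in pressure["pressure"].groupby(grouping).mean().items()
            },
        }
    except Exception as exc:
        raise StageError("metrics", exc) from exc

    summary = _round_floats(summary)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
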