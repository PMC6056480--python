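"""End-to-end orchestration: normalize -> binarize -> synthesize logic ->
validate -> infer -> select -> integrate -> simulate -> perturb.

A run is configured by a YAML file (or an equivalent dict), executes the
stages in order, writes every intermediate artifact plus a MANIFEST of
completed stages and a ``summary.json``, and is deterministic under fixed
seeds.  Any stage failure aborts with the stage name; artifacts of
completed stages are retained.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .binarize import (binarize, bimodality_report,
                       category_independence_test, logcpm_normalize,
                       read_expression, write_expression)
from .inference import (infer_candidate_functions, select_functions,
                        validate_functions)
from .logic import (model_to_network, read_functions, synthesize_logic,
                    write_functions, write_model)
from .network import (integrate_networks, network_stats, read_annotations,
                      read_network, write_network)
from .simulate import perturbation_experiment, sample_attractors
from .synth import SynthConfig, pluripotency_fixture, snapshot_expression

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Run configuration; every field has a workable default so that
    ``use_fixture: true`` alone yields a complete run."""

    outdir: str = "pipeline_out"
    use_fixture: bool = True
    edges: str | None = None
    annotations: str | None = None
    rules: str | None = None
    expression: str | None = None
    counts: str | None = None           # raw counts -> logCPM normalize
    synthetic_expression: dict = dc_field(default_factory=lambda: {
        "n_cells": 10, "n_steps": 12, "seed": 0})
    binarization: dict = dc_field(default_factory=lambda: {
        "seed": 0, "correction": False})
    inference: dict = dc_field(default_factory=lambda: {
        "enabled": True, "max_k": 3})
    simulation: dict = dc_field(default_factory=lambda: {
        "n_starts": 100, "seed": 0})
    knockdowns: list = dc_field(default_factory=lambda: [
        ["POU5F1"], ["NANOG"], ["POU5F1", "NANOG"]])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            if isinstance(getattr(cfg, key), dict) and isinstance(value, dict):
                getattr(cfg, key).update(value)
            else:
                setattr(cfg, key, value)
        if int(cfg.simulation.get("n_starts", 100)) < 1:
            raise ValueError("simulation.n_starts must be >= 1")
        return cfg


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig | Mapping[str, Any] | str | Path,
                 ) -> dict[str, Any]:
    """Execute the configured workflow; returns the summary dict."""
    if isinstance(config, (str, Path)):
        config = PipelineConfig.from_yaml(config)
    elif isinstance(config, Mapping):
        config = PipelineConfig.from_dict(config)

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    summary: dict[str, Any] = {"schema_version": 1,
                               "pluribool_version": __version__}

    def finish_stage(name: str) -> None:
        manifest.append(name)
        (out / "MANIFEST").write_text("\n".join(manifest) + "\n")
        logger.info("stage %s complete", name)

    stage = "load_network"
    try:
        if config.use_fixture:
            network, topo_model = pluripotency_fixture()
        else:
            network = read_network(config.edges, config.annotations)
            topo_model = (read_functions(config.rules) if config.rules
                          else None)
        stats = network_stats(network)
        summary["network"] = {
            "nodes": stats.n_nodes, "edges": stats.n_edges,
            "self_loops": stats.n_self_loops,
            "positive_self_loops": stats.n_self_activations,
            "interactions": stats.n_interactions,
        }
        annotations = {n.name: n.category for n in network.nodes}
        for kd in config.knockdowns:
            missing = [g for g in kd if g not in network]
            if missing:
                raise ValueError(f"knockdown genes not in network: {missing}")
        finish_stage(stage)

        stage = "expression"
        if config.counts:
            counts = pd.read_csv(config.counts, sep="\t", index_col=0)
            expression = logcpm_normalize(counts)
        elif config.expression:
            expression = read_expression(config.expression)
        else:
            syn = dict(config.synthetic_expression)
            expression, _ = snapshot_expression(
                n_cells=int(syn.get("n_cells", 10)),
                n_steps=int(syn.get("n_steps", 12)),
                seed=int(syn.get("seed", 0)),
                config=SynthConfig(seed=int(syn.get("seed", 0))),
            )
        write_expression(expression, out / "expression.tsv")
        finish_stage(stage)

        stage = "binarize"
        seed = int(config.binarization.get("seed", 0))
        binarized = binarize(expression, seed=seed)
        binarized.write(out / "binarized_states.tsv",
                        out / "binarization_thresholds.tsv")
        report = bimodality_report(expression)
        report.amplitude.to_frame().assign(modality=report.modality).to_csv(
            out / "bimodality.tsv", sep="\t", index_label="gene")
        gene_states = binarized.gene_states()
        test = category_independence_test(
            gene_states, annotations,
            correction=bool(config.binarization.get("correction", False)))
        summary["binarization"] = {
            "bimodal_genes": len(report.bimodal_genes()),
            "chi2_statistic": test.statistic,
            "chi2_df": test.df,
            "chi2_p_value": test.p_value,
            "correction": bool(config.binarization.get("correction", False)),
        }
        finish_stage(stage)

        stage = "logic"
        if topo_model is None:
            topo_model = synthesize_logic(network)
        write_functions(topo_model, out / "topology_rules.txt")
        finish_stage(stage)

        stage = "validate"
        report_fp = validate_functions(topo_model, binarized,
                                       mode="fixed_point")
        summary["validation"] = {
            "mode": report_fp.mode,
            "validated": report_fp.n_validated,
            "violated": report_fp.n_violated,
            "fraction_validated": report_fp.fraction_validated,
        }
        finish_stage(stage)

        model = topo_model
        if config.inference.get("enabled", True):
            stage = "infer"
            candidates = infer_candidate_functions(
                binarized.states, max_k=int(config.inference.get("max_k", 3)))
            candidates.to_json(out / "candidates.json", max_per_gene=10)
            finish_stage(stage)

            stage = "integrate"
            reconstructed = select_functions(candidates, topo_model)
            write_functions(reconstructed, out / "reconstructed_rules.txt")
            inferred_net = model_to_network(reconstructed, annotations)
            # non-monotone inferred rules yield sign-less regulators; only
            # signed novel interactions can enter the veto-rule re-synthesis
            from .network import UNDEFINED, SignedNetwork
            inferred_net = SignedNetwork(
                inferred_net.nodes,
                (e for e in inferred_net.interactions
                 if e.sign != UNDEFINED or network.has_interaction(
                     e.source, e.target)),
            )
            integrated, integration = integrate_networks(network, inferred_net)
            write_network(integrated, out / "integrated_edges.tsv",
                          out / "integrated_annotations.tsv")
            model = synthesize_logic(integrated)
            write_functions(model, out / "integrated_rules.txt")
            summary["integration"] = {
                "novel_interactions": len(integration.added),
                "signs_resolved": len(integration.sign_resolved),
                "conflicts": len(integration.conflicts),
            }
            finish_stage(stage)

        stage = "simulate"
        n_starts = int(config.simulation.get("n_starts", 100))
        sim_seed = int(config.simulation.get("seed", 0))
        aset = sample_attractors(model, n_starts=n_starts, seed=sim_seed)
        rows = []
        for i, att in enumerate(aset.attractors):
            col = att.collapsed
            rows.append({"attractor": i, "basin_weight": att.basin_weight,
                         "cycle_length": len(att.states),
                         **{g: col[g] for g in model.genes}})
        pd.DataFrame(rows).to_csv(out / "attractors.tsv", sep="\t",
                                  index=False)
        max_col = aset.max_basin.collapsed
        summary["simulation"] = {
            "n_starts": n_starts, "seed": sim_seed,
            "n_attractors": len(aset.attractors),
            "max_basin_weight": aset.max_basin.basin_weight,
            "max_basin_core": {g: max_col[g]
                               for g in ("POU5F1", "SOX2", "NANOG")
                               if g in max_col},
        }
        finish_stage(stage)

        stage = "perturb"
        knockdowns = [list(kd) for kd in config.knockdowns]
        summary["knockdowns"] = []
        for kd in knockdowns:
            res = perturbation_experiment(model, kd, n_starts=n_starts,
                                          seed=sim_seed)
            label = "+".join(res.knocked)
            frame = pd.DataFrame({
                "gene": list(model.genes),
                "unperturbed": [res.unperturbed[g] for g in model.genes],
                "perturbed": [res.perturbed[g] for g in model.genes],
                "change": [res.changes[g] for g in model.genes],
            })
            frame.to_csv(out / f"knockdown_{label}.tsv", sep="\t",
                         index=False)
            summary["knockdowns"].append({
                "knocked": list(res.knocked),
                "n_up": len(res.upregulated),
                "n_down": len(res.downregulated),
                "n_changed": res.n_changed,
                "up": res.upregulated,
                "down": res.downregulated,
                "oscillating": res.oscillating,
            })
        finish_stage(stage)
    except Exception as err:  # noqa: BLE001 - annotate failing stage
        raise StageError(stage, err) from err

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
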