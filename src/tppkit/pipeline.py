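"""Pipeline orchestration: simulate -> fit -> nparc -> annotate -> integrate.

A single YAML-serializable configuration drives the run; each enabled stage
writes its tables under the output directory, and the run ends with a
machine-readable ``run_summary.json`` plus the resolved configuration
(``run_config.yaml``) for provenance.  Identical configuration and seed give
identical outputs.  Every filtered record is accounted for in the summary
counts; nothing is dropped silently.
"""

from __future__ import annotations

import json
import logging
from copy import deepcopy
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .compounds import (
    deduplicate_across_modes,
    filter_binding_components,
    filter_main_components,
    load_packaged_table,
    read_compound_table,
)
from .melting import delta_tm, fit_all_profiles, read_melt_table
from .network import degree_ranking, docking_threshold_filter, isolate_filter, load_edge_list
from .nparc import hit_counts, nparc_table
from .simulate import SimulationConfig, simulate_dataset, write_melt_table

logger = logging.getLogger("tppkit")

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "output_dir": "tppkit_out",
    "stages": {"simulate": True, "fit": True, "nparc": True, "annotate": True, "integrate": False},
    "simulate": {
        "n_proteins": 100,
        "shift_fraction": 0.1,
        "delta_tm_mean": 3.0,
        "delta_tm_sd": 1.0,
        "noise_sd": 0.05,
    },
    "fit": {"melt_table": None, "r2_min": 0.8, "plateau_max": 0.3},
    "nparc": {"alpha": 0.05, "marked_alpha": 0.01, "adj_alpha": 0.1},
    "annotate": {
        "negative_table": None,   # None -> packaged reference tables
        "positive_table": None,
        "binding_table": None,
        "blank_table": None,
        "score_min": 80.0,
        "ratio_min": 20.0,
        "binding_score_min": 70.0,
    },
    "integrate": {
        "edge_list": None,
        "docking_table": None,    # None -> packaged docking table
        "xp_max": -6.0,
        "dg_max": -30.0,
    },
}


def merged_config(overrides: dict | None = None) -> dict:
    cfg = deepcopy(DEFAULT_CONFIG)
    for key, value in (overrides or {}).items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def validate_config(config: dict) -> list[str]:
    """Return a list of human-readable violations; empty means usable."""
    violations: list[str] = []
    stages = config.get("stages", {})
    for alpha_key in ("alpha", "marked_alpha", "adj_alpha"):
        val = config.get("nparc", {}).get(alpha_key)
        if val is not None and not (0 < val < 1):
            violations.append(f"nparc.{alpha_key} must lie in (0, 1), got {val}")
    sim = config.get("simulate", {})
    if sim.get("noise_sd") is not None and sim["noise_sd"] < 0:
        violations.append(f"simulate.noise_sd must be >= 0, got {sim['noise_sd']}")
    if sim.get("shift_fraction") is not None and not (0 <= sim["shift_fraction"] <= 1):
        violations.append(f"simulate.shift_fraction must lie in [0, 1], got {sim['shift_fraction']}")
    if sim.get("n_proteins") is not None and sim["n_proteins"] < 1:
        violations.append(f"simulate.n_proteins must be positive, got {sim['n_proteins']}")
    fit_cfg = config.get("fit", {})
    if fit_cfg.get("r2_min") is not None and not (0 <= fit_cfg["r2_min"] <= 1):
        violations.append(f"fit.r2_min must lie in [0, 1], got {fit_cfg['r2_min']}")
    # referenced input files must exist before anything runs
    file_refs = [
        ("fit.melt_table", fit_cfg.get("melt_table"), stages.get("fit") and not stages.get("simulate")),
        ("annotate.negative_table", config.get("annotate", {}).get("negative_table"), stages.get("annotate")),
        ("annotate.positive_table", config.get("annotate", {}).get("positive_table"), stages.get("annotate")),
        ("annotate.binding_table", config.get("annotate", {}).get("binding_table"), stages.get("annotate")),
        ("integrate.edge_list", config.get("integrate", {}).get("edge_list"), stages.get("integrate")),
        ("integrate.docking_table", config.get("integrate", {}).get("docking_table"), stages.get("integrate")),
    ]
    for name, path, needed in file_refs:
        if path is not None and needed and not Path(path).is_file():
            violations.append(f"{name}: file not found: {path}")
    return violations


def run_pipeline(config: dict | None = None, output_dir: str | Path | None = None) -> dict:
    """Execute the enabled stages in dependency order and return the summary.

    Raises :class:`PipelineError` naming the first failing stage; the summary
    written up to that point marks the stage as failed.
    """
    cfg = merged_config(config or {})
    if output_dir is not None:
        cfg["output_dir"] = str(output_dir)
    violations = validate_config(cfg)
    if violations:
        raise ValueError("invalid configuration: " + "; ".join(violations))

    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    stages = cfg["stages"]
    summary: dict = {"version": __version__, "seed": cfg["seed"], "stages": {}}

    melt = None
    fits = None
    try:
        if stages.get("simulate"):
            sim_cfg = SimulationConfig(seed=cfg["seed"], **cfg["simulate"])
            melt, truth = simulate_dataset(sim_cfg)
            write_melt_table(melt, out / "melt_table.tsv")
            truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
            summary["stages"]["simulate"] = {
                "n_proteins": sim_cfg.n_proteins,
                "n_rows": int(len(melt)),
                "n_shifters": int(truth["is_shifter"].sum()),
            }
            logger.info("simulate: %d proteins, %d rows", sim_cfg.n_proteins, len(melt))

        if stages.get("fit"):
            if melt is None:
                melt = read_melt_table(cfg["fit"]["melt_table"])
            fits = fit_all_profiles(
                melt, r2_min=cfg["fit"]["r2_min"], plateau_max=cfg["fit"]["plateau_max"]
            )
            fits.to_csv(out / "fit_table.tsv", sep="\t", index=False)
            shifts = delta_tm(fits)
            shifts.to_csv(out / "delta_tm.tsv", sep="\t", index=False)
            summary["stages"]["fit"] = {
                "n_profiles": int(len(fits)),
                "n_valid": int(fits["valid"].sum()),
                "n_pass_filter": int(fits["passes_filter"].sum()),
                "n_delta_tm": int(len(shifts)),
            }
            logger.info("fit: %d profiles, %d pass filter", len(fits), fits["passes_filter"].sum())

        if stages.get("nparc"):
            if melt is None:
                melt = read_melt_table(cfg["fit"]["melt_table"])
            ncfg = cfg["nparc"]
            results = nparc_table(
                melt, alpha=ncfg["alpha"], marked_alpha=ncfg["marked_alpha"],
                adj_alpha=ncfg["adj_alpha"],
            )
            results.to_csv(out / "nparc_results.tsv", sep="\t", index=False)
            counts = hit_counts(
                results, alpha=ncfg["alpha"], marked_alpha=ncfg["marked_alpha"],
                adj_alpha=ncfg["adj_alpha"],
            )
            (out / "nparc_summary.json").write_text(json.dumps(counts, indent=2))
            summary["stages"]["nparc"] = counts
            logger.info("nparc: %s", counts)

        if stages.get("annotate"):
            acfg = cfg["annotate"]
            neg = (read_compound_table(acfg["negative_table"]) if acfg["negative_table"]
                   else load_packaged_table("table1_negative"))
            pos = (read_compound_table(acfg["positive_table"]) if acfg["positive_table"]
                   else load_packaged_table("table2_positive"))
            neg_kept = filter_main_components(neg, acfg["score_min"], acfg["ratio_min"])
            pos_kept = filter_main_components(pos, acfg["score_min"], acfg["ratio_min"])
            unique = deduplicate_across_modes(neg_kept, pos_kept)
            unique.to_csv(out / "unique_compounds.tsv", sep="\t", index=False)
            binding = (read_compound_table(acfg["binding_table"]) if acfg["binding_table"]
                       else load_packaged_table("table3_binding"))
            blank = read_compound_table(acfg["blank_table"]) if acfg["blank_table"] else None
            binding_kept = filter_binding_components(binding, blank, acfg["binding_score_min"])
            binding_kept.to_csv(out / "binding_compounds.tsv", sep="\t", index=False)
            summary["stages"]["annotate"] = {
                "n_negative_in": int(len(neg)),
                "n_negative_kept": int(len(neg_kept)),
                "n_positive_in": int(len(pos)),
                "n_positive_kept": int(len(pos_kept)),
                "n_unique": int(len(unique)),
                "n_binding_in": int(len(binding)),
                "n_binding_kept": int(len(binding_kept)),
            }
            logger.info("annotate: %d unique compounds", len(unique))

        if stages.get("integrate"):
            icfg = cfg["integrate"]
            stage_summary: dict = {}
            if icfg["edge_list"]:
                net = isolate_filter(load_edge_list(icfg["edge_list"]))
                ranking = degree_ranking(net)
                ranking.to_csv(out / "degree_ranking.tsv", sep="\t", index=False)
                stage_summary.update(
                    n_nodes=int(net.number_of_nodes()),
                    n_edges=int(net.number_of_edges()),
                    top_target=str(ranking["symbol"].iloc[0]),
                )
            docking = (read_compound_table(icfg["docking_table"]) if icfg["docking_table"]
                       else load_packaged_table("table4_docking"))
            flagged = docking_threshold_filter(docking, icfg["xp_max"], icfg["dg_max"])
            flagged.to_csv(out / "docking_flags.tsv", sep="\t", index=False)
            stage_summary["n_docking"] = int(len(flagged))
            stage_summary["n_stable_binding"] = int(flagged["stable_binding"].sum())
            summary["stages"]["integrate"] = stage_summary
            logger.info("integrate: %s", stage_summary)
    except Exception as exc:
        failed = _current_stage(summary, stages)
        summary["failed_stage"] = failed
        (out / "run_summary.json").write_text(json.dumps(summary, indent=2))
        raise PipelineError(f"stage {failed!r} failed: {exc}") from exc

    (out / "run_summary.json").write_text(json.dumps(summary, indent=2))
    (out / "run_config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=False))
    return summary


def _current_stage(summary: dict, stages: dict) -> str:
    order = ["simulate", "fit", "nparc", "annotate", "integrate"]
    done = set(summary["stages"])
    for name in order:
        if stages.get(name) and name not in done:
            return name
    return "unknown"
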