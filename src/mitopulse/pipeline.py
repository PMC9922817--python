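"""Configuration-driven end-to-end runs chaining the analysis stages.

A run configuration is a flat key-value mapping (typically a YAML file):
simulate (optional) -> quantify -> classify -> chase (optional) ->
module summaries -> enrichment (optional). Every output table carries a
header comment with the package version, seed and a hash of the
configuration, and a rerun with the same configuration is bit-identical.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chase import chase_group_comparison, chase_scores
from .complexes import load_annotation, summarize_by_category, summarize_by_module
from .enrichment import fisher_enrichment
from .io import config_hash, read_evidence, write_table
from .quant import quantify_psilac, volcano_table
from .simulate import default_chase_scenario, default_psilac_scenario

logger = logging.getLogger(__name__)

_DEFAULTS = {
    "seed": 0,
    "design": "psilac",
    "replicates": 2,
    "swap_replicates": "r2",
    "simulate": True,
    "n_proteins": 1000,
    "evidence": None,
    "chase_evidence": None,
    "annotation": None,
    "terms": None,
    "out_dir": "mitopulse_out",
    "log_level": "INFO",
}


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration with the raw mapping retained for hashing."""

    values: Mapping[str, object]

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: Mapping[str, object]) -> "RunConfig":
        merged = {**_DEFAULTS, **dict(raw)}
        unknown = set(merged) - set(_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("evidence", "chase_evidence", "annotation", "terms"):
            path = merged.get(key)
            if path is not None and not os.path.exists(str(path)):
                raise ValueError(f"config {key}: path {path!r} does not exist")
        if not merged["simulate"] and merged["evidence"] is None:
            raise ValueError("either simulate: true or an evidence path is required")
        return cls(values=merged)

    def __getitem__(self, key: str):
        return self.values[key]

    @property
    def hash(self) -> str:
        return config_hash(self.values)


def _swap_map(config: RunConfig) -> dict[str, str]:
    swapped = {
        token.strip()
        for token in str(config["swap_replicates"] or "").split(",")
        if token.strip()
    }
    return {
        f"r{i}": ("M" if f"r{i}" in swapped else "H")
        for i in range(1, int(config["replicates"]) + 1)
    }


def run_pipeline(config: RunConfig | Mapping[str, object]) -> dict[str, pd.DataFrame]:
    """Execute the configured stages; write tables under ``out_dir``.

    Returns the in-memory outputs keyed by stage name. Any stage failure
    propagates with the stage named in the log.
    """
    if not isinstance(config, RunConfig):
        config = RunConfig.from_mapping(config)
    logging.basicConfig(level=str(config["log_level"]))
    out_dir = str(config["out_dir"])
    os.makedirs(out_dir, exist_ok=True)
    seed = int(config["seed"])
    chash = config.hash
    outputs: dict[str, pd.DataFrame] = {}

    def write(name: str, frame: pd.DataFrame) -> None:
        write_table(frame, os.path.join(out_dir, name), seed=seed, config_hash=chash)

    # --- evidence -----------------------------------------------------
    logger.info("stage: evidence")
    annotation = None
    if config["evidence"] is not None:
        evidence = read_evidence(str(config["evidence"]))
    else:
        scenario = default_psilac_scenario(
            seed,
            n_proteins=int(config["n_proteins"]),
            n_replicates=int(config["replicates"]),
        )
        evidence = scenario.generate()
        annotation = scenario.annotation_table()
        write("evidence.tsv", evidence)
        write("truth.tsv", scenario.truth_table())
    outputs["evidence"] = evidence
    if config["annotation"] is not None:
        annotation = load_annotation(str(config["annotation"]))
    elif annotation is None:
        annotation = load_annotation()

    # --- quantify -----------------------------------------------------
    logger.info("stage: quantify")
    results = quantify_psilac(evidence, _swap_map(config))
    volcano = volcano_table(results, annotation)
    write("results.tsv", results)
    write("volcano.tsv", volcano)
    outputs["results"] = results
    outputs["volcano"] = volcano

    # --- category and module summaries --------------------------------
    logger.info("stage: modules")
    outputs["categories"] = summarize_by_category(results, annotation)
    write("category_summary.tsv", outputs["categories"])
    module_frames = []
    for complex_label in ("CI", "CIII", "CIV", "CV"):
        try:
            module_frames.append(summarize_by_module(results, annotation, complex_label))
        except ValueError:
            continue
    if module_frames:
        outputs["modules"] = pd.concat(module_frames, ignore_index=True)
        write("module_summary.tsv", outputs["modules"])

    # --- chase (optional) ----------------------------------------------
    if config["chase_evidence"] is not None:
        logger.info("stage: chase")
        chase_ev = read_evidence(str(config["chase_evidence"]))
        hm = dict(zip(results["protein_id"], results["mean_log2_fc"]))
        scores = chase_scores(chase_ev, psilac_log2_hm=hm)
        outputs["chase_scores"] = scores
        outputs["chase_comparison"] = chase_group_comparison(scores)
        write("chase_scores.tsv", scores)
        write("chase_comparison.tsv", outputs["chase_comparison"])

    # --- enrichment (optional) -----------------------------------------
    if config["terms"] is not None:
        logger.info("stage: enrich")
        terms = pd.read_csv(str(config["terms"]), sep="\t", comment="#")
        background = list(results["protein_id"])
        foreground = list(
            results.loc[
                (results["fdr"] < 0.05) & (results["mean_log2_fc"] < 0), "protein_id"
            ]
        )
        if foreground:
            enr = fisher_enrichment(foreground, background, terms)
            outputs["enrichment"] = enr
            write("enrichment.tsv", enr)
    return outputs
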