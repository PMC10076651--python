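"""End-to-end pipeline: preprocess -> estimate -> communities -> centrality
-> stability -> (optional) group comparison, with diff-able text artifacts
and a run manifest.

Artifacts written to the output directory:

- ``transformed.csv``   nonparanormal-transformed item matrix
- ``network.json``      full NetworkModel (weights, penalty path, EBIC path)
- ``weights.csv``       full symmetric weight matrix
- ``edges.csv``         nonzero edge list sorted by |weight|
- ``centrality.csv``    EI, BEI, predictability, z-scores, community
- ``redundancy.json``   flagged redundant item pairs (if enabled)
- ``stability.json``    edge CIs and/or CS coefficients (if enabled)
- ``nct.json``          network comparison test results (if enabled)
- ``manifest.json``     versions, seeds, parameters, summary counts
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ggm import correlation, ebic_select
from .metrics import centrality_table, two_group_split, walktrap
from .nct import compare_networks
from .preprocess import find_redundant_pairs, npn_transform
from .simulate import ItemResponseTable, simulate_dataset, study_config
from .stability import bootstrap_edges, case_dropping_cs

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("symptomnet")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclass
class PipelineConfig:
    """Configuration for one reproducible pipeline run.

    Either ``input_csv`` (wide item-response table with MBI-*/D* columns and
    optionally a grouping column) or ``simulate=True`` (default study-shaped
    synthetic data) supplies the input.
    """

    output_dir: str = "symptomnet_run"
    input_csv: str | None = None
    group_col: str | None = None
    simulate: bool = False
    n_respondents: int = 1322
    seed: int = 0
    gamma: float = 0.5
    n_lambda: int = 100
    redundancy: bool = True
    redundancy_threshold: float = 0.25
    redundancy_alpha: float = 0.05
    stability: str | None = None  # None | "edges" | "ei" | "bei"
    nboot: int = 1000
    cs_nboot: int = 2000
    nct: bool = False
    n_perm: int = 1000
    walktrap_steps: int = 4

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _stage(name):
    def wrap(fn, *args, **kwargs):
        logger.info("stage %s ...", name)
        try:
            return fn(*args, **kwargs)
        except Exception as err:
            raise PipelineError(name, str(err)) from err

    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    from importlib.metadata import version as _dist_version

    try:
        _pkg_version = _dist_version("symptomnet")
    except Exception:
        _pkg_version = "unknown"
    manifest: dict = {
        "package": {"symptomnet": _pkg_version, "numpy": np.__version__,
                    "pandas": pd.__version__},
        "parameters": asdict(config),
    }

    # --- input -----------------------------------------------------------
    group_labels = None
    if config.simulate:
        gen = study_config(n_respondents=config.n_respondents, seed=config.seed)
        table, truth = _stage("simulate")(simulate_dataset, gen)
        truth.to_json(out / "truth.json")
        table.to_csv(out / "responses.csv")
    elif config.input_csv:
        def load():
            df = pd.read_csv(config.input_csv)
            nonlocal group_labels
            if config.group_col:
                if config.group_col not in df.columns:
                    raise ValueError(f"group column {config.group_col!r} missing")
                group_labels = df[config.group_col]
                df = df.drop(columns=[config.group_col])
            from .simulate import infer_item_metadata

            return ItemResponseTable(responses=df, items=infer_item_metadata(df))

        table = _stage("load")(load)
    else:
        raise PipelineError("load", "either input_csv or simulate must be set")

    # --- preprocess ------------------------------------------------------
    if config.redundancy:
        report = _stage("redundancy")(
            find_redundant_pairs,
            table,
            threshold=config.redundancy_threshold,
            alpha=config.redundancy_alpha,
        )
        (out / "redundancy.json").write_text(
            json.dumps(
                {
                    "flagged": [[i, j, prop] for i, j, prop in report.flagged],
                    "threshold": report.threshold,
                    "alpha": report.alpha,
                    "cor_min": report.cor_min,
                }
            )
        )
    transformed = _stage("preprocess")(npn_transform, table)
    transformed.values.to_csv(out / "transformed.csv", index=False)

    # --- estimate --------------------------------------------------------
    def estimate():
        S = correlation(transformed)
        return ebic_select(S, gamma=config.gamma, n_lambda=config.n_lambda)

    model = _stage("estimate")(estimate)
    model.to_json(out / "network.json")
    pd.DataFrame(model.weights, index=model.labels, columns=model.labels).to_csv(
        out / "weights.csv"
    )
    model.edge_list().to_csv(out / "edges.csv", index=False)

    # --- communities & centrality ---------------------------------------
    communities = _stage("communities")(walktrap, model, steps=config.walktrap_steps)
    cent = _stage("centrality")(
        centrality_table,
        model,
        table=transformed,
        groups=two_group_split(model.labels),
        communities=communities,
    )
    cent.to_csv(out / "centrality.csv", index=False)

    # --- stability -------------------------------------------------------
    if config.stability:
        stab: dict = {}
        if config.stability == "edges":
            summary = _stage("stability")(
                bootstrap_edges,
                table,
                nboot=config.nboot,
                seed=config.seed,
                gamma=config.gamma,
                n_lambda=config.n_lambda,
            )
            stab["edges"] = summary.edge_table().to_dict(orient="list")
        else:
            cs = _stage("stability")(
                case_dropping_cs,
                table,
                statistic=config.stability,
                nboot=config.cs_nboot,
                seed=config.seed,
                gamma=config.gamma,
                n_lambda=config.n_lambda,
            )
            stab["cs"] = {
                "statistic": cs.statistic,
                "cs_coefficient": cs.cs_coefficient,
                "grid": list(cs.grid),
            }
        (out / "stability.json").write_text(json.dumps(stab))

    # --- network comparison ---------------------------------------------
    if config.nct:
        if group_labels is None:
            raise PipelineError("nct", "nct requires a grouping column")
        values = sorted(pd.Series(group_labels).unique())
        if len(values) != 2:
            raise PipelineError("nct", f"grouping column must have 2 levels, got {values}")
        df = table.responses
        res = _stage("nct")(
            compare_networks,
            df[np.asarray(group_labels) == values[0]],
            df[np.asarray(group_labels) == values[1]],
            n_perm=config.n_perm,
            seed=config.seed,
            gamma=config.gamma,
            n_lambda=config.n_lambda,
        )
        (out / "nct.json").write_text(
            json.dumps(
                {
                    "groups": [str(v) for v in values],
                    "m_statistic": res.m_statistic,
                    "s_statistic": res.s_statistic,
                    "global_strength": [res.global_strength_a, res.global_strength_b],
                    "p_value_m": res.p_value_m,
                    "p_value_s": res.p_value_s,
                    "n_permutations": res.n_permutations,
                }
            )
        )

    # --- manifest --------------------------------------------------------
    p = model.p
    manifest["summary"] = {
        "n_respondents": len(table.responses),
        "n_nodes": p,
        "potential_edges": p * (p - 1) // 2,
        "nonzero_edges": model.edge_count(),
        "edge_density": round(model.density(), 4),
        "n_communities": communities.n_communities,
        "lambda_selected": model.lambda_selected,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("run complete: %s", manifest["summary"])
    return manifest
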