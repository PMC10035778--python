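"""End-to-end orchestration of the network intervention analysis.

Stage order: minimum-session filter -> node-redundancy screen -> change
scores -> propensity matching -> variant grid of moderated networks ->
bootstrap stability (residual model on the matched sample) -> total-score
and per-symptom inference -> cross-variant comparison. Every artifact is
written under the output directory together with a machine-readable run
manifest (config, seeds, filter counts), from which the whole bundle is
regenerable.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .change import ChangeSpec, compute_change
from .compare import compare_direct, default_grid, run_variant_grid
from .inference import ancova_totals, per_symptom_tests
from .items import item_columns
from .matching import MatchConfig, estimate_propensity, match
from .network import RedundancyConfig, bootstrap_network, redundancy_check
from .simulate import CohortConfig, filter_min_sessions, generate_cohort, read_cohort_csv

__all__ = ["RunConfig", "run_pipeline", "stage_seeds"]

_STAGES = ("simulate", "matching", "network", "bootstrap")


def stage_seeds(seed: int) -> dict:
    """Fan one run seed out to independent per-stage seeds (< 2**31)."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1, dtype=np.uint64)[0] % (2**31 - 1))
        for name, child in zip(_STAGES, children)
    }


@dataclass
class RunConfig:
    """Everything needed to reproduce one run.

    Either ``input_csv`` (a cohort in the standard layout) or ``cohort`` (a
    generating configuration) must be supplied. ``grid`` is a list of
    (method, baseline, sample) cells; ``None`` means the full default
    analysis grid.
    """

    seed: int
    output_dir: str = "symptomnet_run"
    input_csv: str | None = None
    cohort: CohortConfig | None = None
    min_sessions: int = 5
    grid: list | None = None
    caliper: float = 0.25
    folds: int = 10
    l1_ratios: tuple = (0.25, 0.5, 0.75, 1.0)
    n_alphas: int = 40
    n_boot: int = 1000
    bootstrap_variant: tuple = ("RC", "session2", "matched")
    redundancy: RedundancyConfig = field(default_factory=RedundancyConfig)

    def __post_init__(self) -> None:
        if self.input_csv is None and self.cohort is None:
            raise ValueError("provide input_csv or a cohort configuration")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage, write the artifact bundle, return it in memory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "config": _jsonable(config),
        "counts": {},
    }

    def _fail(stage, err):
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    # --- cohort ---------------------------------------------------------
    if config.input_csv:
        cohort = read_cohort_csv(config.input_csv)
    else:
        cohort = generate_cohort(config.cohort.replace(seed=seeds["simulate"]))
    manifest["counts"]["input"] = len(cohort)
    cohort = filter_min_sessions(cohort, config.min_sessions)
    manifest["counts"]["after_min_sessions"] = len(cohort)
    manifest["counts"]["per_arm"] = (
        cohort["treatment"].value_counts().sort_index().to_dict()
    )
    cohort.to_csv(out / "cohort_filtered.csv", index=False)

    # --- node redundancy (cross-sectional, each timepoint) --------------
    try:
        redundancy = {
            sess: redundancy_check(cohort[item_columns(sess)], config.redundancy)
            .to_dict(orient="records")
            for sess in ("s1", "s2", "final")
        }
    except Exception as err:
        _fail("redundancy", err)
    (out / "redundancy.json").write_text(json.dumps(_jsonable(redundancy), indent=1))
    manifest["counts"]["redundant_pairs"] = {
        k: len(v) for k, v in redundancy.items()
    }

    # --- change scores ---------------------------------------------------
    try:
        for method, baseline in {(m, b) for m, b, _ in (config.grid or default_grid())}:
            spec = ChangeSpec(method, baseline)
            sess = "s1" if baseline == "session1" else "s2"
            cm = compute_change(
                cohort[item_columns(sess)].set_axis(item_columns("final"), axis=1),
                cohort[item_columns("final")],
                spec,
            )
            cm.to_csv(out / f"change_{spec.label()}.csv")
    except Exception as err:
        _fail("change_scores", err)

    # --- matching --------------------------------------------------------
    try:
        propensity = estimate_propensity(cohort)
        matched = match(cohort, propensity, MatchConfig(caliper=config.caliper))
    except Exception as err:
        _fail("matching", err)
    matched.pairs_to_csv(out / "matched_pairs.csv")
    matched.balance_to_json(out / "balance.json")
    manifest["counts"]["matched_pairs"] = len(matched)

    # --- variant grid ----------------------------------------------------
    grid = config.grid if config.grid is not None else default_grid()
    try:
        networks = run_variant_grid(
            cohort,
            grid=grid,
            matched_ids=matched.matched_ids,
            seed=seeds["network"],
            folds=config.folds,
            l1_ratios=config.l1_ratios,
            n_alphas=config.n_alphas,
        )
    except Exception as err:
        _fail("network_grid", err)
    for label, net in networks.items():
        net.to_json(out / f"network_{label}.json")
        net.to_edge_list().to_csv(out / f"edges_{label}.csv", index=False)

    # --- bootstrap stability ---------------------------------------------
    boot = None
    if config.n_boot > 0:
        method, baseline, sample = config.bootstrap_variant
        data = (
            cohort[cohort["patient_id"].isin(set(matched.matched_ids))]
            if sample == "matched"
            else cohort
        )
        sess = "s1" if baseline == "session1" else "s2"
        cm = compute_change(
            data[item_columns(sess)].set_axis(item_columns("final"), axis=1),
            data[item_columns("final")],
            ChangeSpec(method, baseline),
        )
        try:
            boot = bootstrap_network(
                cm.values,
                data["treatment"].to_numpy(),
                n_boot=config.n_boot,
                seed=seeds["bootstrap"],
                folds=config.folds,
                l1_ratios=config.l1_ratios,
                n_alphas=config.n_alphas,
            )
        except Exception as err:
            _fail("bootstrap", err)
        boot.to_frame().to_csv(out / "bootstrap_stability.csv", index=False)
        manifest["counts"]["bootstrap_failed"] = boot.n_failed

    # --- total-score and per-symptom inference ---------------------------
    try:
        inference = {}
        for scale, cols in (
            ("phq9", item_columns("final")[:9]),
            ("gad7", item_columns("final")[9:]),
        ):
            base_cols = [c.replace("_final", "_s2") for c in cols]
            res = ancova_totals(
                cohort[cols].sum(axis=1),
                cohort[base_cols].sum(axis=1),
                cohort["treatment"],
            )
            inference[f"{scale}_ancova_s2"] = _jsonable(res)
        symptoms = per_symptom_tests(
            cohort[item_columns("final")],
            cohort[item_columns("s2")],
            cohort["treatment"],
        )
        symptoms.to_csv(out / "per_symptom_tests.csv", index=False)
    except Exception as err:
        _fail("inference", err)
    (out / "ancova.json").write_text(json.dumps(inference, indent=1))

    # --- comparison -------------------------------------------------------
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = compare_direct(networks)
    except Exception as err:
        _fail("comparison", err)
    report.to_csv(out / "direct_corr.csv", out / "moderation_corr.csv")
    report.to_json(out / "comparison.json")

    (out / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=1))
    return {
        "cohort": cohort,
        "redundancy": redundancy,
        "matched": matched,
        "networks": networks,
        "bootstrap": boot,
        "inference": inference,
        "per_symptom": symptoms,
        "comparison": report,
        "manifest": manifest,
    }
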