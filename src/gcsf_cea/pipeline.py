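"""End-to-end pipeline: cohort → matching → models → CEA → DSA → PSA → CEAC.

Every stage writes plain-text artifacts (CSV/JSON) into the output
directory, and a run manifest records the seed, configuration hash and the
files produced, so a run is fully reproducible from its manifest.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .analyze import run_base_case
from .cohort import CohortProfile, generate_cohort, summarize_cohort
from .lifetable import life_table_from_config
from .matching import balance_table, estimate_propensity, match_1to1
from .params import ParameterSet, parameters_from_mapping, load_config
from .sensitivity import (ce_plane, ceac, default_dsa_ranges, default_psa_specs,
                          one_way_dsa, probability_cost_effective, run_psa,
                          tornado_frame)


@dataclass
class RunConfig:
    """Settings of one pipeline run."""

    config_path: str | None = None      # None -> packaged default configuration
    output_dir: str = "results"
    seed: int = 0
    n_psa_draws: int = 1000
    wtp_grid: list = field(default_factory=lambda: list(
        np.arange(0.0, 200_001.0, 10_000.0)))
    caliper: float | str | None = "auto"


def config_hash(cfg: dict) -> str:
    canon = yaml.safe_dump(cfg, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(run: RunConfig) -> dict:
    """Execute the whole analysis and write all artifacts.

    Returns a result bundle: the manifest dict plus in-memory objects
    (base-case result, PSA cloud, matched cohort).
    """
    cfg = load_config(run.config_path)
    params = parameters_from_mapping(cfg)
    profile = CohortProfile.from_mapping(cfg["cohort"])
    life_table = life_table_from_config(cfg["life_table"], params.start_age)

    out = Path(run.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def save(df, name: str) -> None:
        df.to_csv(out / name, index=False)
        written.append(name)

    def save_json(obj, name: str) -> None:
        with open(out / name, "w", encoding="utf-8") as fh:
            json.dump(obj, fh, indent=2,
                      default=lambda o: o.item() if hasattr(o, "item") else str(o))
        written.append(name)

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    # --- synthetic cohort & matching ---------------------------------
    def _cohort():
        records = generate_cohort(profile, seed=run.seed)
        save(records, "cohort.csv")
        summary = summarize_cohort(records).reset_index()
        save(summary, "cohort_summary.csv")
        return records

    records = stage("cohort", _cohort)

    def _matching():
        scores = estimate_propensity(records)
        matched = match_1to1(records, scores, caliper=run.caliper,
                             seed=run.seed)
        save(matched.to_frame(), "matched_pairs.csv")
        if matched.n_matched_per_arm:
            bal = balance_table(records, matched).reset_index()
            save(bal, "balance_table.csv")
        return matched

    matched = stage("matching", _matching)

    # --- Markov models and base-case CEA -----------------------------
    def _base():
        res = run_base_case(params, life_table)
        save(res.summary_table(), "base_case.csv")
        save_json({
            "chemo": {a: res.chemo[a].as_dict() for a in res.chemo},
            "postchemo": {a: res.postchemo[a].as_dict() for a in res.postchemo},
            "cea_chemo": res.cea_chemo.as_dict(),
            "cea_postchemo": res.cea_postchemo.as_dict(),
            "cea_total": res.cea_total.as_dict(),
        }, "base_case.json")
        for arm in ("PEG", "RHG"):
            save(res.chemo[arm].trace.to_frame(), f"chemo_trace_{arm.lower()}.csv")
            save(res.postchemo[arm].trace.to_frame(),
                 f"postchemo_trace_{arm.lower()}.csv")
        return res

    base = stage("base_case", _base)

    # --- deterministic sensitivity -----------------------------------
    def _dsa():
        ranges = default_dsa_ranges(params)
        frames = {}
        for outcome in ("incremental_cost", "incremental_qaly_total"):
            entries = one_way_dsa(params, life_table, ranges, outcome)
            frames[outcome] = tornado_frame(entries)
            save(frames[outcome], f"tornado_{outcome}.csv")
        return frames

    stage("dsa", _dsa)

    # --- probabilistic sensitivity -----------------------------------
    cloud = None
    if run.n_psa_draws > 0:
        def _psa():
            psa_cfg = cfg.get("psa", {})
            specs = default_psa_specs(
                params, explicit=psa_cfg.get("explicit"),
                se_fraction=psa_cfg.get("default_se_fraction", 0.15))
            c = run_psa(params, life_table, specs,
                        n_draws=run.n_psa_draws, seed=run.seed)
            save(ce_plane(c), "ce_plane.csv")
            save(ceac(c, run.wtp_grid), "ceac.csv")
            return c

        cloud = stage("psa", _psa)

    manifest = {
        "package_version": __version__,
        "seed": run.seed,
        "config_hash": config_hash(cfg),
        "n_psa_draws": run.n_psa_draws,
        "n_matched_per_arm": matched.n_matched_per_arm,
        "wtp_per_qaly": params.wtp_per_qaly,
        "delta_cost": base.delta_cost,
        "delta_qalys_chemo": base.delta_qalys_chemo,
        "delta_qalys_postchemo": base.delta_qalys_postchemo,
        "icer_chemo": base.cea_chemo.icer,
        "icer_total": base.cea_total.icer,
        "probability_cost_effective_at_wtp": (
            probability_cost_effective(cloud, params.wtp_per_qaly)
            if cloud is not None and cloud.n else None),
        "outputs": sorted(written),
    }
    save_json(manifest, "manifest.json")
    return {"manifest": manifest, "base_case": base, "psa_cloud": cloud,
            "matched": matched, "records": records, "params": params,
            "life_table": life_table}
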