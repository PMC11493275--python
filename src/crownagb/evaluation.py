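"""Scenario assembly, train/test splitting, and the 7 x 9 fit matrix.

Seven plot combinations are evaluated: single plots, within-type
mixtures, and the full conifer + broadleaf pool.  Every model form is
fitted on a random 70% of each scenario's trees and scored on both the
training set and the 30% hold-out.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import allometry
from .allometry import MODEL_CODES, evaluate, fit_model, model_predict

__all__ = ["SCENARIO_PLOTS", "ScenarioSpec", "RunConfig",
           "add_reference_agb", "assemble_scenario", "split_indices",
           "run_scenario", "run_matrix", "summarize"]

#: Plot membership of the seven evaluation scenarios.
SCENARIO_PLOTS: Dict[int, Tuple[int, ...]] = {
    1: (1,),
    2: (2,),
    3: (1, 2),
    4: (3,),
    5: (4,),
    6: (3, 4),
    7: (1, 2, 3, 4),
}

SCENARIO_DESCRIPTIONS = {
    1: "shorter conifer",
    2: "taller conifer",
    3: "mixed tall and short conifer",
    4: "taller broadleaf",
    5: "shorter broadleaf",
    6: "mixed tall and short broadleaf",
    7: "mixed conifer-broadleaf",
}


@dataclass
class ScenarioSpec:
    scenario_id: int
    plots: Tuple[int, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if self.scenario_id in SCENARIO_PLOTS and \
                tuple(self.plots) != SCENARIO_PLOTS[self.scenario_id]:
            raise ValueError(
                f"scenario {self.scenario_id} must use plots "
                f"{SCENARIO_PLOTS[self.scenario_id]}")

    @classmethod
    def standard(cls, scenario_id: int) -> "ScenarioSpec":
        return cls(scenario_id, SCENARIO_PLOTS[scenario_id],
                   SCENARIO_DESCRIPTIONS[scenario_id])


@dataclass
class RunConfig:
    split_fraction: float = 0.7
    split_seed: int = 0
    models: Sequence[str] = MODEL_CODES
    scenarios: Sequence[int] = tuple(SCENARIO_PLOTS)
    clip_negative: bool = False
    stratify_by_plot: bool = False
    replicates: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")
        bad = [m for m in self.models if m not in MODEL_CODES]
        if bad:
            raise ValueError(f"unknown model codes: {bad}")


def add_reference_agb(trees: pd.DataFrame) -> pd.DataFrame:
    """Attach reference biomass (W_ref_kg) computed from species allometry.

    Rows that already carry a finite W_ref_kg keep it.
    """
    out = trees.reset_index(drop=True).copy()
    w = np.empty(len(out))
    for sp, grp in out.groupby("species"):
        w[grp.index.to_numpy()] = allometry.reference_agb(
            sp, grp["DBH_cm"].to_numpy(), grp["H_m"].to_numpy())
    if "W_ref_kg" in out.columns:
        have = out["W_ref_kg"].notna().to_numpy()
        w[have] = out["W_ref_kg"].to_numpy()[have]
    out["W_ref_kg"] = w
    return out


def assemble_scenario(trees: pd.DataFrame, spec: ScenarioSpec
                      ) -> pd.DataFrame:
    """Concatenate the scenario's plots, stably ordered by (plot, tree_id)."""
    sub = trees[trees["plot_id"].isin(spec.plots)]
    return sub.sort_values(["plot_id", "tree_id"],
                           kind="stable").reset_index(drop=True)


def _n_train(n: int, fraction: float) -> int:
    # round-half-even keeps the split platform-stable
    return int(round(fraction * n))


def split_indices(n: int, fraction: float, seed: int,
                  groups: Optional[np.ndarray] = None
                  ) -> Tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test index sets; reproducible by seed.

    With ``groups``, the fraction is applied within each group
    (stratified split).
    """
    rng = np.random.default_rng(seed)
    if groups is None:
        perm = rng.permutation(n)
        k = _n_train(n, fraction)
        return np.sort(perm[:k]), np.sort(perm[k:])
    groups = np.asarray(groups)
    train, test = [], []
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        perm = rng.permutation(len(idx))
        k = _n_train(len(idx), fraction)
        train.append(idx[perm[:k]])
        test.append(idx[perm[k:]])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def run_scenario(data: pd.DataFrame, scenario_id: int,
                 config: RunConfig) -> List[dict]:
    """Fit every requested model on one assembled scenario dataset."""
    h = data["H_m"].to_numpy()
    r = data["R_m"].to_numpy()
    w = data["W_ref_kg"].to_numpy()
    groups = data["plot_id"].to_numpy() if config.stratify_by_plot else None
    train, test = split_indices(len(data), config.split_fraction,
                                config.split_seed, groups)
    rows = []
    for code in config.models:
        row = {
            "scenario": scenario_id, "model": code,
            "n_train": len(train), "n_test": len(test),
            "split_seed": config.split_seed, "converged": False,
            "flag": "",
        }
        n_coef = 3 if code == "Eq9" else 2
        if len(train) < n_coef + 1:
            row["flag"] = "insufficient_n"
            rows.append(row)
            continue
        try:
            fit = fit_model(code, h[train], r[train], w[train])
        except (ValueError, np.linalg.LinAlgError) as exc:
            row["flag"] = f"fit_error: {exc}"
            rows.append(row)
            continue
        row["converged"] = fit.converged
        for i, name in enumerate("abc"[:n_coef]):
            row[name] = fit.spec.coefficients[i]
        for part, idx in (("train", train), ("test", test)):
            if len(idx) < 2:
                continue
            pred = model_predict(fit.spec, h[idx], r[idx])
            if config.clip_negative:
                pred = np.maximum(pred, 0.0)
            m = evaluate(pred, w[idx])
            row[f"r2_{part}"] = m.r2
            row[f"rmse_{part}"] = m.rmse
            row[f"rrmse_{part}"] = m.rrmse
        rows.append(row)
    return rows


def run_matrix(trees: pd.DataFrame, config: RunConfig = None
               ) -> pd.DataFrame:
    """All requested scenarios x models as one tidy result table.

    Adds a per-scenario rank column (1 = best hold-out R^2).  Rows that
    could not be fitted stay in the table with a flag.
    """
    config = config or RunConfig()
    if "W_ref_kg" not in trees.columns or trees["W_ref_kg"].isna().any():
        trees = add_reference_agb(trees)
    rows: List[dict] = []
    for sid in config.scenarios:
        spec = ScenarioSpec.standard(sid)
        data = assemble_scenario(trees, spec)
        rows.extend(run_scenario(data, sid, config))
    out = pd.DataFrame(rows)
    if "r2_test" in out.columns:
        out["rank"] = out.groupby("scenario")["r2_test"] \
            .rank(ascending=False, method="min")
    return out


def run_replicates(trees: pd.DataFrame, config: RunConfig,
                   base_seed: int = 0) -> pd.DataFrame:
    """Mean and SD of the metrics over ``config.replicates`` split seeds."""
    frames = []
    for k in range(config.replicates):
        cfg = RunConfig(
            split_fraction=config.split_fraction,
            split_seed=base_seed + k, models=config.models,
            scenarios=config.scenarios, clip_negative=config.clip_negative,
            stratify_by_plot=config.stratify_by_plot)
        frames.append(run_matrix(trees, cfg))
    allf = pd.concat(frames, ignore_index=True)
    metric_cols = [c for c in allf.columns
                   if c.startswith(("r2_", "rmse_", "rrmse_"))]
    return allf.groupby(["scenario", "model"])[metric_cols] \
        .agg(["mean", "std"]).reset_index()


def summarize(results: pd.DataFrame) -> str:
    """Plain-text per-scenario ranking of the fitted models."""
    lines = []
    for sid, grp in results.groupby("scenario"):
        desc = SCENARIO_DESCRIPTIONS.get(int(sid), "")
        lines.append(f"Scenario {sid} ({desc}):")
        grp = grp.sort_values("r2_test", ascending=False, na_position="last")
        for _, row in grp.iterrows():
            if row.get("flag"):
                lines.append(f"  {row['model']}: {row['flag']}")
                continue
            lines.append(
                f"  {row['model']}: R2={row.get('r2_test', float('nan')):.4f}"
                f" RMSE={row.get('rmse_test', float('nan')):.2f} kg"
                f" rRMSE={row.get('rrmse_test', float('nan')):.2f}%")
        lines.append("")
    return "\n".join(lines)


def plot_fit(data: pd.DataFrame, code: str, coefficients, path) -> None:
    """Scatter of reference W against the model's predictor with the
    fitted curve overlaid; written to ``path`` (PNG/PDF by extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .allometry import ModelSpec, predictor

    h = data["H_m"].to_numpy()
    r = data["R_m"].to_numpy()
    w = data["W_ref_kg"].to_numpy()
    x = predictor(code, h, r)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, w, s=12, alpha=0.6, label="reference")
    order = np.argsort(x)
    spec = ModelSpec(code, tuple(coefficients))
    ax.plot(x[order], model_predict(spec, h[order], r[order]),
            color="C3", label=code)
    ax.set_xlabel("model predictor")
    ax.set_ylabel("W (kg)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_results(results: pd.DataFrame, out_dir) -> None:
    """fit_results.csv / .json and a ranked plain-text summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results.to_csv(out_dir / "fit_results.csv", index=False)
    results.to_json(out_dir / "fit_results.json", orient="records", indent=2)
    (out_dir / "summary.txt").write_text(summarize(results))
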