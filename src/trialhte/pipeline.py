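"""End-to-end pipeline: impute -> forest -> AIPW -> omnibus -> parametric
baseline -> CATE exploration -> Rubin pooling, with machine-readable outputs.

Outputs written to the configured directory:

* ``forest_plot.csv``      — group ATEs per (method, subgroup variable, level)
* ``individual_cates.csv`` — per-patient CATEs with CIs, sorted by estimate
* ``cate_summary.json``    — headline shares (negative estimates, CIs
  excluding zero) and the CATE range
* ``omnibus.json``         — calibration/heterogeneity test
* ``subgroup_tree.json`` / ``subgroup_tree.txt`` / ``leaf_table.csv``
                           — full-sample cp-pruned CART on the CATEs
* ``honest_tree.json`` / ``honest_leaf_table.csv``
                           — CART grown on a seeded half, leaf effects
  re-estimated on the held-out half (valid CIs)
* ``r2_comparison.csv``    — explained variation of OLS / CART / best-tree
  summaries, in- and out-of-sample, with leaf counts
* ``rubin_combined.json``  — Rubin-pooled overall effects (when m >= 2)
* ``run_log.json``         — config echo, derived stage seeds, versions

Reruns under an identical config reproduce every output byte for byte: the
single global seed deterministically derives one sub-seed per stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .aggregate import aipw_scores, group_ate
from .baseline import SeparationError, logistic_group_ate
from .calibration import omnibus_test
from .explore import (best_tree, fit_pruned_cart, honest_subgroup_ates,
                      r2_explained, second_stage_ols)
from .forest import CausalForest, ForestConfig
from .impute import mice_impute, pool_cate_frames, rubin_combine
from .simulate import (SimulationConfig, covariate_columns, generate_trial,
                       quintile_bins, read_trial)

logger = logging.getLogger("trialhte")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline",
           "forest_plot_table", "DEFAULT_SUBGROUPS"]

#: the emulated trial's prespecified seven subgroup variables plus the nine
#: additional ones considered post hoc (quintiles formed for continuous ones)
DEFAULT_SUBGROUPS = [
    "age", "chronic_hypertension", "chronic_heart_failure",
    "atherosclerotic_disease", "icnarc_predicted_risk", "sepsis3",
    "vasopressor_type",
    "male", "ethnicity", "prior_dependency", "map_randomization",
    "admission_source", "apache_ii", "icnarc_physiology", "cpr_24h", "sofa",
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run (seed mandatory by design)."""

    seed: int = 0
    input_csv: str | None = None
    simulation: SimulationConfig | None = None
    subgroups: list[str] = field(default_factory=lambda: list(DEFAULT_SUBGROUPS))
    forest: ForestConfig = field(default_factory=ForestConfig)
    propensity: float = 0.5
    cp: float = 0.2
    max_tree_leaves: int = 10
    minN_ladder: list[int] = field(default_factory=lambda: [1, 50, 100, 200])
    best_tree_num: int = 200
    m: int = 1
    mice_iterations: int = 10
    bootstrap_B: int = 200
    output_dir: str = "trialhte_out"

    def stage_seed(self, stage: str) -> int:
        h = zlib.crc32(stage.encode())
        return int(np.random.SeedSequence(
            [self.seed & 0x7FFFFFFF, h]).generate_state(1)[0] % (2 ** 31))

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        d["forest"] = dataclasses.asdict(self.forest)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("simulation") is not None:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if d.get("forest") is not None and not isinstance(
                d["forest"], ForestConfig):
            fd = dict(d["forest"])
            if fd.get("max_depth") in ("none", "None"):
                fd["max_depth"] = None
            d["forest"] = ForestConfig(**fd)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _level_masks(trial: pd.DataFrame, var: str) -> dict[str, np.ndarray]:
    """Per-level boolean masks; continuous variables become sample quintiles
    (ties to the lower quintile)."""
    s = trial[var]
    if isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == object:
        vals = s.astype(str)
        levels = (list(s.cat.categories)
                  if isinstance(s.dtype, pd.CategoricalDtype)
                  else sorted(vals.unique()))
        return {str(lv): (vals == str(lv)).to_numpy() for lv in levels
                if (vals == str(lv)).any()}
    arr = np.asarray(s, dtype=float)
    uniq = np.unique(arr[~np.isnan(arr)])
    if len(uniq) <= 2 and set(uniq) <= {0.0, 1.0}:
        return {"no": arr == 0, "yes": arr == 1}
    q = quintile_bins(arr)
    return {f"q{k}": q == k for k in range(1, 6) if (q == k).any()}


def forest_plot_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble and validate the forest-plot table.

    One row per (method, subgroup variable, level); duplicates are an error.
    """
    if not rows:
        raise ValueError("no group ATE rows supplied")
    df = pd.DataFrame(rows, columns=["method", "subgroup_variable", "level",
                                     "n", "estimate", "se", "ci_low",
                                     "ci_high"])
    dup = df.duplicated(["method", "subgroup_variable", "level"])
    if dup.any():
        bad = df.loc[dup, ["method", "subgroup_variable", "level"]]
        raise ValueError(f"duplicate forest-plot rows:\n{bad}")
    return df


def _json_write(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True,
                               default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _analyze_one(trial: pd.DataFrame, config: PipelineConfig,
                 forest_seed: int):
    """Forest + AIPW + omnibus + group ATEs for one completed dataset."""
    fcfg = dataclasses.replace(config.forest, seed=forest_seed)
    model = CausalForest.from_dataframe(trial, propensity=config.propensity,
                                        config=fcfg)
    results = model.fit()
    cate = results.predict_oob()
    cate.insert(0, "patient_id", trial["patient_id"].to_numpy()
                if "patient_id" in trial.columns else np.arange(len(trial)))
    scores = aipw_scores(results)
    omni = omnibus_test(scores)

    plot_rows = []
    overall = group_ate(scores, None, "overall")
    plot_rows.append({"method": overall.method, "subgroup_variable": "overall",
                      "level": "all", **_ate_cells(overall)})
    boot_seed = config.stage_seed("bootstrap")
    log_overall = logistic_group_ate(
        trial, np.ones(len(trial)), "overall",
        B_boot=config.bootstrap_B, seed=boot_seed)
    plot_rows.append({"method": log_overall.method,
                      "subgroup_variable": "overall", "level": "all",
                      **_ate_cells(log_overall)})
    for var in config.subgroups:
        if var not in trial.columns:
            raise ValueError(f"subgroup variable {var!r} not in the data")
        for k, (level, mask) in enumerate(_level_masks(trial, var).items()):
            res = group_ate(scores, mask, f"{var}={level}")
            plot_rows.append({"method": res.method, "subgroup_variable": var,
                              "level": level, **_ate_cells(res)})
            try:
                lres = logistic_group_ate(
                    trial, mask, f"{var}={level}",
                    B_boot=config.bootstrap_B,
                    seed=(boot_seed + 1000 * k + zlib.crc32(var.encode()))
                    % (2 ** 31))
                plot_rows.append({"method": lres.method,
                                  "subgroup_variable": var, "level": level,
                                  **_ate_cells(lres)})
            except (SeparationError, RuntimeError) as exc:
                logger.warning("logistic fit for %s=%s not estimable: %s",
                               var, level, exc)
                plot_rows.append({"method": "logistic_gcomp",
                                  "subgroup_variable": var, "level": level,
                                  "n": int(mask.sum()), "estimate": np.nan,
                                  "se": np.nan, "ci_low": np.nan,
                                  "ci_high": np.nan})
    return results, cate, scores, omni, plot_rows, overall


def _ate_cells(res) -> dict:
    return {"n": res.n_group, "estimate": res.estimate, "se": res.se,
            "ci_low": res.ci_low, "ci_high": res.ci_high}


def _explore(trial, cate, scores, config: PipelineConfig, outdir: Path):
    """Second-stage OLS, pruned CART, honest split-sample tree, best trees."""
    from .simulate import encode_covariates

    cov = covariate_columns(trial)
    X, names = encode_covariates(trial, cov)
    tau = cate["tau_hat"].to_numpy()

    tree = fit_pruned_cart(tau, X, cp=config.cp, names=names,
                           max_leaves=config.max_tree_leaves)
    tree.to_json(outdir / "subgroup_tree.json")
    (outdir / "subgroup_tree.txt").write_text(tree.to_text() + "\n")
    tree.leaf_table().to_csv(outdir / "leaf_table.csv", index=False)

    # honest split-sample variant: identify subgroups on one half,
    # re-estimate leaf effects with the held-out half's AIPW scores
    rng = np.random.default_rng(config.stage_seed("honest_split"))
    n = len(tau)
    perm = rng.permutation(n)
    a, b = perm[: n // 2], perm[n // 2:]
    htree = fit_pruned_cart(tau[a], X[a], cp=config.cp, names=names,
                            max_leaves=config.max_tree_leaves)
    held_scores = dataclasses.replace(
        scores, gamma=scores.gamma[b], tau_oob=scores.tau_oob[b],
        m0=scores.m0[b], m1=scores.m1[b],
        d=None if scores.d is None else scores.d[b])
    htree = honest_subgroup_ates(htree, held_scores, X[b], names=names)
    htree.to_json(outdir / "honest_tree.json")
    htree.leaf_table().to_csv(outdir / "honest_leaf_table.csv", index=False)

    # explained-variation ladder (in-sample = half a, out-of-sample = half b)
    r2_rows = []
    ols = second_stage_ols(tau[a], X[a], names=names)
    r2_rows.append({
        "method": "ols", "detail": "linear",
        "n_subgroups": np.nan,
        "r2_in_sample": r2_explained(ols.predict(X[a], names), tau[a]),
        "r2_out_of_sample": r2_explained(ols.predict(X[b], names), tau[b],
                                         "out_of_sample"),
    })
    cart_a = fit_pruned_cart(tau[a], X[a], cp=config.cp, names=names,
                             max_leaves=config.max_tree_leaves)
    r2_rows.append({
        "method": "cart", "detail": f"cp={config.cp}",
        "n_subgroups": cart_a.leaf_count,
        "r2_in_sample": r2_explained(cart_a.predict(X[a]), tau[a]),
        "r2_out_of_sample": r2_explained(cart_a.predict(X[b]), tau[b],
                                         "out_of_sample"),
    })
    bt_seed = config.stage_seed("best_tree")
    for minN in config.minN_ladder:
        bt = best_tree(tau[a], X[a], minN=minN,
                       num_trees=config.best_tree_num, seed=bt_seed,
                       names=names)
        r2_rows.append({
            "method": "best_tree", "detail": f"minN={minN}",
            "n_subgroups": bt.leaf_count,
            "r2_in_sample": r2_explained(bt.predict(X[a]), tau[a]),
            "r2_out_of_sample": r2_explained(bt.predict(X[b]), tau[b],
                                             "out_of_sample"),
        })
    pd.DataFrame(r2_rows).to_csv(outdir / "r2_comparison.csv", index=False)
    return tree, htree


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the result bundle; returns artifact paths."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    audit: dict = {"stages": {}, "config": config.to_dict()}

    # ---- load or simulate -------------------------------------------------
    stage = "load"
    try:
        if config.input_csv:
            trial = read_trial(config.input_csv)
        else:
            sim = config.simulation or SimulationConfig(
                seed=config.stage_seed("simulate"))
            trial = generate_trial(sim)
            audit["stages"]["simulate"] = {
                "seed": sim.seed, "n": sim.n,
                "clip_count": trial.attrs.get("clip_count", 0)}
        missing = [v for v in config.subgroups if v not in trial.columns]
        if missing:
            raise ValueError(f"subgroup variables missing from data: {missing}")
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- imputation -------------------------------------------------------
    stage = "impute"
    try:
        has_missing = trial[covariate_columns(trial)].isna().any().any()
        if has_missing or config.m > 1:
            imp = mice_impute(trial, m=config.m,
                              iterations=config.mice_iterations,
                              seed=config.stage_seed("impute"))
            tables = imp.tables
            audit["stages"]["impute"] = {"m": imp.m,
                                         "methods": imp.methods,
                                         "iterations": imp.iterations}
        else:
            tables = [trial]
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- per-imputation analysis -----------------------------------------
    stage = "forest"
    try:
        per_imp = []
        for j, tab in enumerate(tables):
            seed_j = (config.stage_seed("forest") + j) % (2 ** 31)
            per_imp.append(_analyze_one(tab, config, seed_j))
        results, cate, scores, omni, plot_rows, overall = per_imp[0]
        audit["stages"]["forest"] = {
            "num_trees": results.ensemble.num_trees,
            "covariates_fitted": results.retained_,
            "single_pass": results.single_pass,
            "importance_filter": "disabled (multiplier 0): single-pass forest"
            if config.forest.importance_multiplier == 0
            else f"multiplier {config.forest.importance_multiplier}",
        }
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- pooling across imputations ---------------------------------------
    stage = "rubin"
    try:
        if len(per_imp) >= 2:
            ests = [p[5].estimate for p in per_imp]
            vars_ = [p[5].se ** 2 for p in per_imp]
            pooled_overall = rubin_combine(ests, vars_)
            cate = pool_cate_frames([p[1] for p in per_imp])
            _json_write(outdir / "rubin_combined.json", {
                "overall_ate_aipw": pooled_overall.to_dict(),
                "omnibus_ate_coefficient": rubin_combine(
                    [p[3].ate_coefficient for p in per_imp],
                    [p[3].ate_se ** 2 for p in per_imp]).to_dict(),
            })
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- tables -----------------------------------------------------------
    stage = "report"
    try:
        plot = forest_plot_table(plot_rows)
        plot.to_csv(outdir / "forest_plot.csv", index=False)

        ordered = cate.sort_values(["tau_hat", "patient_id"],
                                   kind="mergesort").reset_index(drop=True)
        ordered.to_csv(outdir / "individual_cates.csv", index=False)
        share_negative = float((cate["tau_hat"] < 0).mean())
        share_ci_below0 = float((cate["ci_high"] < 0).mean())
        share_ci_incl0 = float(((cate["ci_low"] <= 0)
                                & (cate["ci_high"] >= 0)).mean())
        _json_write(outdir / "cate_summary.json", {
            "n": len(cate),
            "cate_min": float(cate["tau_hat"].min()),
            "cate_max": float(cate["tau_hat"].max()),
            "share_negative_estimates": share_negative,
            "share_ci_excluding_zero_below": share_ci_below0,
            "share_ci_including_zero": share_ci_incl0,
            "overall_arr_pp": -100.0 * overall.estimate,
            "overall_arr_se_pp": 100.0 * overall.se,
        })
        _json_write(outdir / "omnibus.json", omni.to_dict())
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- CATE exploration --------------------------------------------------
    stage = "explore"
    try:
        tree, htree = _explore(tables[0], cate, scores, config, outdir)
        audit["stages"]["explore"] = {
            "cart_leaves": tree.leaf_count,
            "honest_cart_leaves": htree.leaf_count,
        }
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- run log ----------------------------------------------------------
    import sklearn
    import statsmodels

    audit["versions"] = {
        "trialhte": "0.1.0",
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "sklearn": sklearn.__version__,
        "statsmodels": statsmodels.__version__,
    }
    audit["stage_seeds"] = {s: config.stage_seed(s) for s in
                            ("simulate", "impute", "forest", "bootstrap",
                             "honest_split", "best_tree")}
    _json_write(outdir / "run_log.json", audit)

    artifacts = ["forest_plot.csv", "individual_cates.csv",
                 "cate_summary.json", "omnibus.json", "subgroup_tree.json",
                 "subgroup_tree.txt", "leaf_table.csv", "honest_tree.json",
                 "honest_leaf_table.csv", "r2_comparison.csv", "run_log.json"]
    if len(per_imp) >= 2:
        artifacts.append("rubin_combined.json")
    return {name: outdir / name for name in artifacts}
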