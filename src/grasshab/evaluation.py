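"""Final-model evaluation, suitability mapping and the end-to-end pipeline.

Replicated random-subsample evaluation of the selected candidate (AUC,
omission curves), cell-wise mean logistic suitability mapping, the
four-class suitability classification (breaks 0.25 / 0.5 / 0.75) and
area accounting in km², plus a config-driven pipeline that chains
simulation, screening, calibration, replicated fitting and mapping.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import rankdata

from . import calibration, maxent, screening, synthetic
from .raster import EnvStack, Raster, write_geotiff

__all__ = [
    "auc",
    "ReplicateSummary",
    "replicate_runs",
    "omission_curve",
    "classify_suitability",
    "area_table",
    "run_pipeline",
    "CLASS_LABELS",
]

CLASS_LABELS = ("unsuitable", "low", "moderate", "high")
DEFAULT_BREAKS = (0.25, 0.5, 0.75)


def auc(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC: probability a random presence
    outscores a random background point, ties counting one half."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("empty score set")
    ranks = rankdata(np.concatenate([p, b]))
    u = ranks[:p.size].sum() - p.size * (p.size + 1) / 2.0
    return float(u / (p.size * b.size))


@dataclass
class ReplicateSummary:
    """Metrics and mean suitability raster across replicate subsample runs."""

    train_auc: np.ndarray
    test_auc: np.ndarray
    seeds: np.ndarray
    mean_suitability: Raster
    models: list = field(default_factory=list)
    n_requested: int = 0
    n_failed: int = 0

    @property
    def n_effective(self) -> int:
        return len(self.train_auc)

    @property
    def mean_train_auc(self) -> float:
        return float(np.mean(self.train_auc))

    @property
    def mean_test_auc(self) -> float:
        return float(np.mean(self.test_auc))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "replicate": np.arange(self.n_effective),
            "seed": self.seeds,
            "train_auc": self.train_auc,
            "test_auc": self.test_auc,
        })


def _predict_surface(model: maxent.MaxEntModel, stack: EnvStack) -> np.ndarray:
    idx = stack.valid_indices()
    table = stack.table(idx[:, 0], idx[:, 1])
    vals = maxent.predict_logistic(model, table)
    out = np.full(stack.grid.shape, np.nan)
    out[idx[:, 0], idx[:, 1]] = vals
    return out


def replicate_runs(spec: calibration.CandidateSpec, occ: synthetic.OccurrenceSet,
                   stack: EnvStack, n_reps: int = 100,
                   test_fraction: float = 0.25, base_seed: int = 0,
                   n_background: int = maxent.MAX_BACKGROUND,
                   n_knots: int = maxent.DEFAULT_KNOTS,
                   keep_models: bool = True,
                   fit_kwargs: dict | None = None) -> ReplicateSummary:
    """Replicated random-subsample evaluation of one candidate.

    Each replicate draws a fresh seeded train/test split, fits the
    model, and contributes its logistic surface to the cell-wise mean.
    Replicates whose fit fails are skipped and counted.
    """
    fkw = fit_kwargs or {}
    bg = maxent.sample_background(stack, n_background, seed=base_seed)
    bg_table = stack.table(bg.rows, bg.cols)
    surfaces = []
    train_aucs, test_aucs, seeds, models = [], [], [], []
    n_failed = 0
    for rep in range(n_reps):
        seed = base_seed + rep
        train, test = calibration.split_data(occ, test_fraction, seed=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            features = maxent.build_features(stack, train, bg, fc=spec.fc,
                                             n_knots=n_knots)
        try:
            model = maxent.fit(features, rm=spec.rm, **fkw)
        except maxent.ConvergenceError:
            n_failed += 1
            continue
        test_table = stack.table(test.rows, test.cols)
        train_scores = maxent.predict_raw(model, features.presence_table)
        test_scores = maxent.predict_raw(model, test_table)
        bg_scores = maxent.predict_raw(model, bg_table)
        train_aucs.append(auc(train_scores, bg_scores))
        test_aucs.append(auc(test_scores, bg_scores))
        seeds.append(seed)
        surfaces.append(_predict_surface(model, stack))
        if keep_models:
            models.append((model, features))
    if not surfaces:
        raise RuntimeError("every replicate fit failed")
    with warnings.catch_warnings():
        # nodata cells are NaN in every replicate surface by construction
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_surface = np.nanmean(np.stack(surfaces), axis=0)
    return ReplicateSummary(
        train_auc=np.array(train_aucs), test_auc=np.array(test_aucs),
        seeds=np.array(seeds),
        mean_suitability=Raster(mean_surface, stack.grid),
        models=models, n_requested=n_reps, n_failed=n_failed,
    )


def omission_curve(test_scores: np.ndarray, train_scores: np.ndarray,
                   n_thresholds: int = 101) -> pd.DataFrame:
    """Omission against the training-quantile threshold sweep.

    At quantile level q the threshold is the q-quantile of training
    presence scores; predicted omission equals q by construction, and
    test/train omission are the observed fractions below the threshold.
    """
    test = np.asarray(test_scores, dtype=float)
    train = np.asarray(train_scores, dtype=float)
    if test.size == 0 or train.size == 0:
        raise ValueError("empty score set")
    levels = np.linspace(0.0, 1.0, n_thresholds)
    thresholds = np.quantile(train, levels)
    rows = []
    for q, t in zip(levels, thresholds):
        rows.append({
            "quantile_level": q,
            "threshold": t,
            "predicted_omission": q,
            "train_omission": float(np.mean(train < t)),
            "test_omission": float(np.mean(test < t)),
        })
    return pd.DataFrame(rows)


def classify_suitability(prob: Raster,
                         breaks: tuple[float, float, float] = DEFAULT_BREAKS
                         ) -> Raster:
    """Classify probabilities into unsuitable/low/moderate/high.

    Half-open upward-inclusive bins: [0, b1) -> 0, [b1, b2) -> 1,
    [b2, b3) -> 2, [b3, 1] -> 3. Nodata propagates.
    """
    b = tuple(float(x) for x in breaks)
    if len(b) != 3 or not (0 < b[0] < b[1] < b[2] < 1):
        raise ValueError("breaks must be strictly increasing within (0, 1)")
    data = prob.data
    finite = ~np.isnan(data)
    if finite.any() and (np.nanmin(data) < 0 or np.nanmax(data) > 1):
        raise ValueError("probability raster has values outside [0, 1]")
    classes = np.digitize(data, b, right=False).astype(float)
    classes[~finite] = np.nan
    return Raster(classes, prob.grid, categorical=True)


def area_table(classes: Raster) -> pd.DataFrame:
    """Per-class area (km²) and percentage of the classified area.

    Cell areas come from the grid geometry: cell² for planar-km grids,
    per-row cosine-latitude correction for geographic grids.
    Percentages are reported to two decimals and sum to 100 within
    rounding.
    """
    grid = classes.grid
    row_areas = grid.cell_areas_km2()
    data = classes.data
    areas = []
    for code in range(len(CLASS_LABELS)):
        hit = data == code
        areas.append(float((hit.sum(axis=1) * row_areas).sum()))
    total = sum(areas)
    if total == 0:
        raise ValueError("no classified cells")
    return pd.DataFrame({
        "class": CLASS_LABELS,
        "code": range(len(CLASS_LABELS)),
        "area_km2": areas,
        "percent": shares_from_areas(areas),
    })


def shares_from_areas(areas: list[float]) -> list[float]:
    """Class percentage shares to two decimals, summing to exactly 100.

    Naive per-class rounding can drift off 100 by up to 0.02; the
    residual is assigned largest-remainder style in 0.01 steps.
    """
    total = float(sum(areas))
    if total <= 0:
        raise ValueError("total area must be positive")
    exact = [100.0 * a / total for a in areas]
    shares = [round(s, 2) for s in exact]
    residual = round(100.0 - sum(shares), 2)
    if residual:
        order = sorted(range(len(shares)),
                       key=lambda i: shares[i] - exact[i],
                       reverse=residual < 0)
        step = 0.01 if residual > 0 else -0.01
        for k in range(int(round(abs(residual) / 0.01))):
            i = order[k % len(order)]
            shares[i] = round(shares[i] + step, 2)
    return shares


# --------------------------------------------------------------------------
# End-to-end pipeline
# --------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {},            # SimConfig overrides; set to None to load data
    "data": None,              # {"layers": {name: {path, kind}}, "occurrences": path}
    "screening": {"threshold": 0.8, "sample_size": 0},
    "background": 10_000,
    "calibration": {
        "enabled": True,
        "rm_start": 0.5, "rm_stop": 4.0, "rm_step": 0.5,
        "fc_list": ["L", "LQ", "LQH", "LQPH"],
        "omission_max": 0.08, "alpha": 0.05,
        "proc_iters": 500, "e_level": 0.05,
    },
    "model": {"rm": 1.0, "fc": "LQPH"},   # direct-fit path when calibration off
    "replicates": {"n": 10, "test_fraction": 0.25},
    "n_knots": maxent.DEFAULT_KNOTS,
    "breaks": list(DEFAULT_BREAKS),
}


def _merged_config(config: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, value in (config or {}).items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def _load_stack_from_paths(data_cfg: dict) -> tuple[EnvStack, synthetic.OccurrenceSet]:
    from .raster import read_geotiff

    layers = data_cfg["layers"]
    stack = None
    for name, entry in layers.items():
        raster = read_geotiff(entry["path"])
        kind = entry.get("kind",
                         "categorical" if raster.categorical else "continuous")
        if stack is None:
            stack = EnvStack(raster.grid)
        stack.add(name, raster.data, kind)
    occ_df = pd.read_csv(data_cfg["occurrences"])
    occ = synthetic.OccurrenceSet.from_dataframe(occ_df, stack.grid)
    return stack, occ


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Run simulate -> screen -> calibrate -> replicate fit -> map.

    ``config`` is a dict or a YAML file path; outputs (tables, rasters,
    model files, run manifest) land in ``out_dir``. Any stage failure
    raises with the stage named; earlier outputs are preserved.
    Returns the run manifest.
    """
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text()) or {}
    cfg = _merged_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict = {"seed": seed, "stages": {}, "files": []}

    def _record(path: Path) -> None:
        manifest["files"].append(path.name)

    def _stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrap

    # --- simulate or load -------------------------------------------------
    if cfg.get("data"):
        stack, occ = _stage("load")(_load_stack_from_paths, cfg["data"])
        manifest["stages"]["load"] = {"layers": stack.names,
                                      "n_occurrences": len(occ)}
    else:
        sim_kwargs = dict(cfg.get("simulate") or {})
        sim_kwargs.setdefault("seed", seed)
        for key in ("continuous", "categorical"):
            if key in sim_kwargs:
                sim_kwargs[key] = {
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in sim_kwargs[key].items()}
        if "corr_targets" in sim_kwargs:
            sim_kwargs["corr_targets"] = {
                tuple(k.split(":")) if isinstance(k, str) else tuple(k): v
                for k, v in sim_kwargs["corr_targets"].items()}
        sim_cfg = synthetic.SimConfig(**sim_kwargs)
        stack = _stage("simulate")(synthetic.generate_env_stack, sim_cfg)
        truth = synthetic.default_truth()
        occ = _stage("simulate")(synthetic.sample_occurrences, stack, truth,
                                 sim_cfg)
        synthetic.write_fixture(stack, occ, truth, out / "fixture")
        manifest["stages"]["simulate"] = {
            "grid": [sim_cfg.nrows, sim_cfg.ncols],
            "n_occurrences": len(occ),
        }

    # --- screening --------------------------------------------------------
    scr = cfg["screening"]
    cm = _stage("screen")(screening.pearson_matrix, stack,
                          sample_size=int(scr.get("sample_size", 0)),
                          seed=seed)
    retained_cont, drop_log = _stage("screen")(
        screening.prune_correlated, cm, float(scr.get("threshold", 0.8)))
    retained = retained_cont + stack.categorical_names
    cm.to_dataframe().to_csv(out / "correlation_matrix.csv")
    _record(out / "correlation_matrix.csv")
    (out / "retained_variables.txt").write_text("\n".join(retained) + "\n")
    _record(out / "retained_variables.txt")
    (out / "screening_log.txt").write_text(
        "\n".join(
            f"dropped {d['dropped']} (|r|={abs(d['pair_r']):.3f} with "
            f"{d['kept']}; mean|r| {d['mean_abs_r_dropped']:.3f} vs "
            f"{d['mean_abs_r_kept']:.3f})" for d in drop_log
        ) + ("\n" if drop_log else "no variables dropped\n"))
    _record(out / "screening_log.txt")
    manifest["stages"]["screen"] = {"retained": retained,
                                    "dropped": [d["dropped"] for d in drop_log]}

    screened = EnvStack(stack.grid)
    for name in retained:
        screened.add(name, stack.layer(name), stack.kind(name))
    stack = screened

    n_bg = int(cfg["background"])
    n_knots = int(cfg["n_knots"])

    # --- calibration ------------------------------------------------------
    cal = cfg["calibration"]
    if cal.get("enabled", True):
        cands = calibration.enumerate_candidates(
            float(cal["rm_start"]), float(cal["rm_stop"]),
            float(cal["rm_step"]), cal.get("fc_list"))
        results = _stage("calibrate")(
            calibration.run_calibration, stack, occ, cands,
            n_background=n_bg, e_level=float(cal.get("e_level", 0.05)),
            proc_iters=int(cal.get("proc_iters", 500)), seed=seed,
            n_knots=n_knots)
        calibration.results_table(results).to_csv(
            out / "candidates.csv", index=False, float_format="%.10g")
        _record(out / "candidates.csv")
        best, counts = _stage("select")(
            calibration.select_best, results,
            omission_max=float(cal.get("omission_max", 0.08)),
            alpha=float(cal.get("alpha", 0.05)))
        spec = best.spec
        (out / "selection_report.txt").write_text(
            "candidate models: {candidates}\nfitted: {fitted}\n"
            "statistically significant: {significant}\n"
            "omission <= cut: {low_omission}\nAICc-eligible: {aicc_eligible}\n"
            .format(**counts)
            + f"selected: RM={spec.rm:g} FC={spec.fc} "
              f"(AICc={best.aicc:.4f}, omission={best.omission:.4f}, "
              f"p={best.p_value:.4g}, k={best.k})\n")
        _record(out / "selection_report.txt")
        manifest["stages"]["calibrate"] = {**counts,
                                           "selected": {"rm": spec.rm,
                                                        "fc": spec.fc}}
    else:
        spec = calibration.CandidateSpec(rm=float(cfg["model"]["rm"]),
                                         fc=cfg["model"]["fc"])
        manifest["stages"]["calibrate"] = {"skipped": True,
                                           "selected": {"rm": spec.rm,
                                                        "fc": spec.fc}}

    # --- replicated final fit --------------------------------------------
    rep = cfg["replicates"]
    summary = _stage("replicate")(
        replicate_runs, spec, occ, stack, n_reps=int(rep.get("n", 10)),
        test_fraction=float(rep.get("test_fraction", 0.25)),
        base_seed=seed, n_background=n_bg, n_knots=n_knots)
    summary.to_frame().to_csv(out / "replicates.csv", index=False,
                              float_format="%.10g")
    _record(out / "replicates.csv")
    manifest["stages"]["replicate"] = {
        "n_effective": summary.n_effective,
        "n_failed": summary.n_failed,
        "mean_train_auc": summary.mean_train_auc,
        "mean_test_auc": summary.mean_test_auc,
    }

    # --- importance, contributions, response curves -----------------------
    model, features = summary.models[0]
    maxent.write_model(model, out / "model.lambdas.txt")
    _record(out / "model.lambdas.txt")
    imp = maxent.permutation_importance(model, features, seed=seed)
    contrib = maxent.percent_contribution(model)
    imp.merge(contrib, on="variable").to_csv(
        out / "importance.csv", index=False, float_format="%.10g")
    _record(out / "importance.csv")
    models_only = [m for m, _ in summary.models]
    for var in model.variables:
        curve = maxent.response_curve(models_only, features, var)
        curve.to_csv(out / f"response_{var}.csv", index=False,
                     float_format="%.10g")
        _record(out / f"response_{var}.csv")

    # --- mapping ----------------------------------------------------------
    prob = summary.mean_suitability
    write_geotiff(out / "suitability.tif", prob)
    _record(out / "suitability.tif")
    classes = _stage("map")(classify_suitability, prob,
                            tuple(cfg["breaks"]))
    write_geotiff(out / "suitability_classes.tif", classes)
    _record(out / "suitability_classes.tif")
    areas = _stage("map")(area_table, classes)
    areas.to_csv(out / "area_table.csv", index=False, float_format="%.10g")
    _record(out / "area_table.csv")
    manifest["stages"]["map"] = {
        "areas_km2": dict(zip(areas["class"], areas["area_km2"])),
        "percent": dict(zip(areas["class"], areas["percent"])),
    }

    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
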