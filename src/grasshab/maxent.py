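"""Presence-only maximum-entropy (MaxEnt) modelling core.

The model is the Gibbs distribution over the background universe,

    P_w(x) = exp(sum_i w_i f_i(x)) / Z_w,   Z_w = sum_bg exp(sum_i w_i f_i),

fitted by minimising the L1-regularized negative mean presence
log-likelihood

    L(w) = log Z_w - mean_presence(sum_i w_i f_i) + sum_j RM * beta_j |w_j|.

Features are the classic MaxEnt classes — linear (L), quadratic (Q),
product (P), threshold (T) and hinge (H) transforms of covariates
scaled to [0, 1] over the background, plus one indicator per observed
level of each categorical covariate. The objective is convex and
non-smooth; it is solved by cyclic proximal-Newton coordinate descent
with soft-thresholding, which handles the L1 term exactly and yields
sharp Karush-Kuhn-Tucker (KKT) certificates:

    |E_model f_j - mean_presence f_j| <= RM * beta_j  for every feature,
    with equality whenever w_j != 0.

The logistic suitability output is the entropy-based transform
r * e^H / (1 + r * e^H) of the raw score r, H being the entropy of the
fitted background distribution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .raster import EnvStack
from .synthetic import OccurrenceSet

__all__ = [
    "BackgroundSample",
    "Feature",
    "FeatureSet",
    "MaxEntModel",
    "ConvergenceError",
    "sample_background",
    "build_features",
    "fit",
    "predict_raw",
    "predict_logistic",
    "response_curve",
    "permutation_importance",
    "percent_contribution",
    "jackknife_gains",
    "training_gain",
    "write_model",
    "read_model",
]

MAX_BACKGROUND = 10_000
DEFAULT_KNOTS = 20

# Default per-class regularization schedules, interpolated by presence
# sample size: (sample sizes, beta values). These follow the published
# MaxEnt defaults in spirit; exact tables are configurable via the
# ``beta_tables`` argument of build_features.
BETA_TABLES: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    "lqp": ((0, 10, 30, 100), (1.0, 1.0, 0.2, 0.05)),
    "categorical": ((0, 10, 17), (0.65, 0.5, 0.25)),
    "threshold": ((0, 100), (2.0, 1.0)),
    "hinge": ((0, 1), (0.5, 0.5)),
}
# Features are scaled to [0,1]; presence standard deviations below this
# floor are clamped so beta_j stays strictly positive.
_STD_FLOOR = 0.05


class ConvergenceError(RuntimeError):
    """Fit failed to converge; carries the per-sweep objective trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class BackgroundSample:
    """Seeded uniform sample of valid cells representing available habitat."""

    rows: np.ndarray
    cols: np.ndarray
    x: np.ndarray
    y: np.ndarray
    seed: int

    def __len__(self) -> int:
        return len(self.rows)


def sample_background(stack: EnvStack, n: int = MAX_BACKGROUND,
                      seed: int = 0) -> BackgroundSample:
    """Uniform sample (without replacement) of valid cells, capped at 10,000.

    Presence cells are not excluded, matching MaxEnt convention.
    """
    idx = stack.valid_indices()
    n = min(n, MAX_BACKGROUND, len(idx))
    if n < 2:
        raise ValueError("need at least 2 valid cells for a background sample")
    rng = np.random.default_rng(seed)
    take = rng.choice(len(idx), size=n, replace=False)
    rows, cols = idx[take, 0], idx[take, 1]
    xy = np.array([stack.grid.cell_center(r, c) for r, c in zip(rows, cols)])
    return BackgroundSample(rows=rows, cols=cols, x=xy[:, 0], y=xy[:, 1],
                            seed=seed)


@dataclass(frozen=True)
class Feature:
    """One model feature traced back to its source covariate(s)."""

    name: str
    fclass: str  # linear|quadratic|product|threshold|hinge|hinge_rev|categorical
    variables: tuple[str, ...]
    knot: float | None = None
    level: float | None = None

    @property
    def beta_class(self) -> str:
        if self.fclass in ("linear", "quadratic", "product"):
            return "lqp"
        if self.fclass == "threshold":
            return "threshold"
        if self.fclass in ("hinge", "hinge_rev"):
            return "hinge"
        return "categorical"


def _interp_beta(table: tuple[tuple[float, ...], tuple[float, ...]],
                 m: int) -> float:
    sizes, betas = table
    return float(np.interp(m, sizes, betas))


def _feature_columns(features: list[Feature], scaling: dict[str, tuple[float, float]],
                     table: dict[str, np.ndarray]) -> np.ndarray:
    """Design matrix for the given covariate table (values clamped to the
    training [0,1] scaled range)."""
    z: dict[str, np.ndarray] = {}
    for var, (lo, hi) in scaling.items():
        z[var] = np.clip((np.asarray(table[var], dtype=float) - lo) / (hi - lo),
                         0.0, 1.0)
    n = len(next(iter(table.values())))
    out = np.empty((n, len(features)))
    for j, f in enumerate(features):
        if f.fclass == "linear":
            out[:, j] = z[f.variables[0]]
        elif f.fclass == "quadratic":
            out[:, j] = z[f.variables[0]] ** 2
        elif f.fclass == "product":
            out[:, j] = z[f.variables[0]] * z[f.variables[1]]
        elif f.fclass == "threshold":
            out[:, j] = (z[f.variables[0]] > f.knot).astype(float)
        elif f.fclass == "hinge":
            out[:, j] = np.clip((z[f.variables[0]] - f.knot) / (1.0 - f.knot),
                                0.0, 1.0)
        elif f.fclass == "hinge_rev":
            out[:, j] = np.clip((f.knot - z[f.variables[0]]) / f.knot, 0.0, 1.0)
        else:  # categorical indicator on the raw level code
            out[:, j] = (np.asarray(table[f.variables[0]], dtype=float)
                         == f.level).astype(float)
    return out


@dataclass
class FeatureSet:
    """Expanded features with design values at presences and background."""

    features: list[Feature]
    scaling: dict[str, tuple[float, float]]
    beta: np.ndarray                       # per-feature beta_j (RM excluded)
    Fp: np.ndarray                         # (n_presence, J)
    Fb: np.ndarray                         # (n_background, J)
    presence_table: dict[str, np.ndarray]  # raw covariates at presences
    background_table: dict[str, np.ndarray]
    fc: str
    n_rejected: int = 0
    n_collapsed: int = 0
    dropped_constant: list[str] = field(default_factory=list)

    @property
    def n_presence(self) -> int:
        return self.Fp.shape[0]

    @property
    def n_background(self) -> int:
        return self.Fb.shape[0]

    @property
    def variables(self) -> list[str]:
        seen: list[str] = []
        for f in self.features:
            for v in f.variables:
                if v not in seen:
                    seen.append(v)
        return seen

    def design(self, table: dict[str, np.ndarray]) -> np.ndarray:
        return _feature_columns(self.features, self.scaling, table)

    def subset(self, variables: list[str]) -> "FeatureSet":
        """Restriction to features sourced entirely from ``variables``."""
        keep = [j for j, f in enumerate(self.features)
                if all(v in variables for v in f.variables)]
        return FeatureSet(
            features=[self.features[j] for j in keep],
            scaling={v: s for v, s in self.scaling.items() if v in variables},
            beta=self.beta[keep],
            Fp=self.Fp[:, keep],
            Fb=self.Fb[:, keep],
            presence_table=self.presence_table,
            background_table=self.background_table,
            fc=self.fc,
            n_rejected=self.n_rejected,
            n_collapsed=self.n_collapsed,
        )


def _normalize_fc(fc) -> str:
    """Canonical feature-combination string in conventional L-Q-P-T-H order."""
    if isinstance(fc, str):
        letters = set(fc.upper())
    else:
        letters = {str(c).upper() for c in fc}
    if not letters or not letters <= set("LQPTH"):
        raise ValueError(f"invalid feature-class combination {fc!r}")
    return "".join(c for c in "LQPTH" if c in letters)


def build_features(stack: EnvStack, occ: OccurrenceSet, bg: BackgroundSample,
                   fc="LQPTH", n_knots: int = DEFAULT_KNOTS,
                   beta_tables: dict | None = None) -> FeatureSet:
    """Expand covariates into the requested MaxEnt feature classes.

    Occurrences falling outside the grid or on nodata are rejected (with
    a count kept), duplicate presences within one cell are collapsed,
    continuous features are scaled to [0, 1] by background min/max, and
    per-feature regularization weights beta_j are assigned from the
    class schedules interpolated at the presence sample size.
    """
    combo = _normalize_fc(fc)
    tables = beta_tables or BETA_TABLES
    valid = stack.valid_mask
    grid = stack.grid

    inside, rejected = [], 0
    for xi, yi in zip(occ.x, occ.y):
        r, c = grid.index_of(xi, yi)
        if 0 <= r < grid.nrows and 0 <= c < grid.ncols and valid[r, c]:
            inside.append((r, c))
        else:
            rejected += 1
    if rejected:
        warnings.warn(f"rejected {rejected} occurrence(s) outside the grid "
                      "or on nodata cells")
    unique_cells = sorted(set(inside))
    collapsed = len(inside) - len(unique_cells)
    if collapsed:
        warnings.warn(f"collapsed {collapsed} duplicate presence cell(s)")
    if not unique_cells:
        raise ValueError("no usable presence points")
    prow = np.array([rc[0] for rc in unique_cells])
    pcol = np.array([rc[1] for rc in unique_cells])

    presence_table = stack.table(prow, pcol)
    background_table = stack.table(bg.rows, bg.cols)

    scaling: dict[str, tuple[float, float]] = {}
    dropped: list[str] = []
    for var in stack.continuous_names:
        lo = float(np.min(background_table[var]))
        hi = float(np.max(background_table[var]))
        if hi <= lo:
            dropped.append(var)
            warnings.warn(f"variable {var!r} is constant over the background; "
                          "its features are dropped")
            continue
        scaling[var] = (lo, hi)

    cont = [v for v in stack.continuous_names if v in scaling]
    features: list[Feature] = []
    qlev = (np.arange(n_knots) + 1.0) / (n_knots + 1.0)
    for var in cont:
        lo, hi = scaling[var]
        zbg = np.clip((background_table[var] - lo) / (hi - lo), 0.0, 1.0)
        if "L" in combo:
            features.append(Feature(f"{var}", "linear", (var,)))
        if "Q" in combo:
            features.append(Feature(f"{var}^2", "quadratic", (var,)))
        if "T" in combo or "H" in combo:
            knots = np.unique(np.quantile(zbg, qlev))
            knots = knots[(knots > 0.0) & (knots < 1.0)]
            if "T" in combo:
                for k in knots:
                    features.append(Feature(f"{var}>{k:.4g}", "threshold",
                                            (var,), knot=float(k)))
            if "H" in combo:
                for k in knots:
                    features.append(Feature(f"{var}|h{k:.4g}", "hinge",
                                            (var,), knot=float(k)))
                    features.append(Feature(f"{var}|h'{k:.4g}", "hinge_rev",
                                            (var,), knot=float(k)))
    if "P" in combo:
        for i, a in enumerate(cont):
            for b in cont[i + 1:]:
                features.append(Feature(f"{a}*{b}", "product", (a, b)))
    for var in stack.categorical_names:
        levels = np.unique(np.concatenate([
            background_table[var], presence_table[var]]))
        levels = levels[~np.isnan(levels)]
        for lev in levels:
            features.append(Feature(f"{var}={int(lev)}", "categorical",
                                    (var,), level=float(lev)))

    Fp = _feature_columns(features, scaling, presence_table)
    Fb = _feature_columns(features, scaling, background_table)
    combined = np.vstack([Fp, Fb])
    keep = combined.std(axis=0) > 0.0
    if not keep.all():
        features = [f for f, k in zip(features, keep) if k]
        Fp, Fb = Fp[:, keep], Fb[:, keep]

    m = Fp.shape[0]
    beta = np.empty(len(features))
    for j, f in enumerate(features):
        base = _interp_beta(tables[f.beta_class], m)
        s = max(float(np.std(Fp[:, j])), _STD_FLOOR)
        beta[j] = base * s / math.sqrt(m)
    return FeatureSet(features=features, scaling=scaling, beta=beta,
                      Fp=Fp, Fb=Fb, presence_table=presence_table,
                      background_table=background_table, fc=combo,
                      n_rejected=rejected, n_collapsed=collapsed,
                      dropped_constant=dropped)


@dataclass
class MaxEntModel:
    """Fitted maximum-entropy model.

    ``log_z`` normalizes raw scores so they sum to 1 over the background
    universe the model was trained on; ``entropy`` is the Shannon
    entropy of that fitted distribution and parameterizes the logistic
    output transform.
    """

    features: list[Feature]
    scaling: dict[str, tuple[float, float]]
    weights: np.ndarray
    log_z: float
    entropy: float
    rm: float
    fc: str
    beta: np.ndarray
    converged: bool
    n_iter: int
    objective_trace: list[float]
    contribution_trace: dict[str, float] | None = None
    categorical_modes: dict[str, float] = field(default_factory=dict)

    @property
    def n_active(self) -> int:
        return int(np.count_nonzero(self.weights))

    @property
    def variables(self) -> list[str]:
        seen: list[str] = []
        for f in self.features:
            for v in f.variables:
                if v not in seen:
                    seen.append(v)
        return seen

    def linear_predictor(self, table: dict[str, np.ndarray]) -> np.ndarray:
        F = _feature_columns(self.features, self.scaling, table)
        return F @ self.weights


def _objective(eta_b: np.ndarray, eta_p_mean: float, w: np.ndarray,
               lam: np.ndarray) -> float:
    return float(logsumexp(eta_b) - eta_p_mean + np.dot(lam, np.abs(w)))


def fit(features: FeatureSet, rm: float = 1.0, tol: float = 1e-7,
        max_iter: int = 5000, kkt_tol: float = 1e-8,
        trace_contributions: bool = True) -> MaxEntModel:
    """Fit the L1-penalized Gibbs model by proximal-Newton coordinate descent.

    Each sweep computes every feature's KKT residual with one matrix
    product and visits only violating coordinates, largest first. The
    fit converges when the maximum KKT residual falls below ``kkt_tol``
    (which certifies the regularization bound to that accuracy); if the
    relative objective change stays below ``tol`` for many sweeps while
    violations persist, or ``max_iter`` is exhausted, a
    :class:`ConvergenceError` carrying the objective trace is raised.
    """
    if features.n_presence < 1:
        raise ValueError("need at least one presence")
    if features.n_background < 2:
        raise ValueError("need at least two background points")
    if rm <= 0:
        raise ValueError("regularization multiplier must be positive")

    Fp, Fb = features.Fp, features.Fb
    J = Fb.shape[1]
    lam = rm * features.beta
    pbar = Fp.mean(axis=0)
    w = np.zeros(J)
    eta_b = np.zeros(Fb.shape[0])
    eta_p_mean = 0.0
    contrib: dict[str, float] = {v: 0.0 for v in features.variables}

    obj = _objective(eta_b, eta_p_mean, w, lam)
    trace = [obj]
    q = np.full(Fb.shape[0], 1.0 / Fb.shape[0])
    pen = 0.0  # running sum lam . |w|
    converged = False
    it = 0

    def _violations() -> np.ndarray:
        gvec = q @ Fb - pbar
        return np.where(
            w == 0.0,
            np.maximum(np.abs(gvec) - lam, 0.0),
            np.abs(gvec + np.sign(w) * lam),
        )

    def _refresh_q(eta: np.ndarray) -> np.ndarray:
        e = np.exp(eta - eta.max())
        return e / e.sum()

    def _cd_pass(viol: np.ndarray) -> int:
        """Proximal-Newton coordinate updates on the worst violators."""
        nonlocal w, eta_b, eta_p_mean, pen, obj, q
        n_moved = 0
        work_thr = max(kkt_tol, 0.1 * float(viol.max()))
        for j in np.argsort(-viol):
            if viol[j] < work_thr:
                break
            fj = Fb[:, j]
            Ef = float(q @ fj)
            g = Ef - pbar[j]
            h = float(q @ (fj * fj)) - Ef * Ef
            h = max(h, 1e-12)
            target = w[j] - g / h
            thr = lam[j] / h
            w_new = math.copysign(max(abs(target) - thr, 0.0), target)
            delta = w_new - w[j]
            if delta == 0.0:
                continue
            delta = max(min(delta, 5.0), -5.0)
            # Backtrack on the true objective (Newton step may overshoot).
            for _ in range(40):
                cand_eta_b = eta_b + delta * fj
                cand_eta_p = eta_p_mean + delta * pbar[j]
                cand_pen = pen + lam[j] * (abs(w[j] + delta) - abs(w[j]))
                cand_obj = (float(logsumexp(cand_eta_b)) - cand_eta_p
                            + cand_pen)
                if cand_obj <= obj + 1e-15:
                    break
                delta *= 0.5
            else:
                continue
            drop = obj - cand_obj
            w[j] += delta
            eta_b = cand_eta_b
            eta_p_mean = cand_eta_p
            pen = cand_pen
            obj = cand_obj
            q = _refresh_q(eta_b)
            n_moved += 1
            if trace_contributions and drop > 0:
                share = drop / len(features.features[j].variables)
                for v in features.features[j].variables:
                    contrib[v] += share
        return n_moved

    def _newton_pass() -> int:
        """Orthant-wise Newton steps on the working set (support plus the
        worst violators); returns the number of accepted steps."""
        nonlocal w, eta_b, eta_p_mean, pen, obj, q
        ridge = 1e-10
        accepted = 0
        for _ in range(15):
            viol = _violations()
            if float(viol.max()) <= kkt_tol:
                break
            support = np.flatnonzero(w != 0.0)
            violators = np.flatnonzero((w == 0.0) & (viol > kkt_tol))
            if len(violators) > 50:
                violators = violators[np.argsort(-viol[violators])[:50]]
            S = np.union1d(support, violators)
            if len(S) == 0:
                break
            FbS = Fb[:, S]
            gvec = q @ FbS - pbar[S]
            signs = np.where(w[S] != 0.0, np.sign(w[S]), -np.sign(gvec))
            grad = gvec + lam[S] * signs
            EfS = q @ FbS
            H = (FbS.T * q) @ FbS - np.outer(EfS, EfS)
            diag_scale = max(float(np.mean(np.diag(H))), 1e-12)
            H[np.diag_indices_from(H)] += ridge * diag_scale
            try:
                step = np.linalg.solve(H, -grad)
            except np.linalg.LinAlgError:
                ridge *= 1e3
                if ridge > 1e-1:
                    break
                continue
            improved = False
            t = 1.0
            for _ in range(30):
                w_cand = w[S] + t * step
                # Clip sign crossings to zero (orthant projection).
                w_cand[np.sign(w_cand) == -signs] = 0.0
                delta_w = w_cand - w[S]
                cand_eta_b = eta_b + FbS @ delta_w
                cand_eta_p = eta_p_mean + float(pbar[S] @ delta_w)
                cand_pen = pen + float(
                    lam[S] @ (np.abs(w_cand) - np.abs(w[S])))
                cand_obj = (float(logsumexp(cand_eta_b)) - cand_eta_p
                            + cand_pen)
                if cand_obj <= obj - 1e-16:
                    improved = True
                    break
                t *= 0.5
            if not improved:
                ridge *= 1e3  # Levenberg-style damping before retrying
                if ridge > 1e-1:
                    break
                continue
            accepted += 1
            ridge = max(ridge / 10.0, 1e-10)
            w[S] = w_cand
            eta_b = cand_eta_b
            eta_p_mean = cand_eta_p
            pen = cand_pen
            obj = cand_obj
            q = _refresh_q(eta_b)
        return accepted

    for it in range(1, max_iter + 1):
        viol = _violations()
        max_viol = float(viol.max())
        if max_viol <= kkt_tol:
            converged = True
            break
        n_moved = _cd_pass(viol)
        # Newton tail: near the optimum (or periodically on hard problems)
        # dense steps on the working set reach the KKT certificate far
        # faster than more coordinate sweeps.
        n_newton = 0
        if max_viol < 3e-2 or it % 5 == 0:
            n_newton = _newton_pass()
        trace.append(obj)
        if n_moved == 0 and n_newton == 0:
            # No step improves the objective: we are at the numerical
            # floor. Accept if the certificate is still tight, else fail.
            residual = float(_violations().max())
            if residual <= max(kkt_tol, 1e-7):
                converged = True
                break
            raise ConvergenceError(
                f"optimizer stalled after {it} sweeps with KKT residual "
                f"{residual:.3g}", trace)
    if not converged:
        raise ConvergenceError(
            f"fit did not converge in {it} sweeps "
            f"(last objective {obj:.6g}, KKT residual "
            f"{float(_violations().max()):.3g})", trace)

    log_z = float(logsumexp(eta_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy = float(-np.sum(q * np.log(np.where(q > 0, q, 1.0))))
    modes = {}
    for var, vals in features.background_table.items():
        if var not in features.scaling:  # categorical
            levs, counts = np.unique(vals[~np.isnan(vals)], return_counts=True)
            if len(levs):
                modes[var] = float(levs[np.argmax(counts)])
    return MaxEntModel(
        features=list(features.features), scaling=dict(features.scaling),
        weights=w, log_z=log_z, entropy=entropy, rm=rm, fc=features.fc,
        beta=features.beta.copy(), converged=True, n_iter=it,
        objective_trace=trace,
        contribution_trace=contrib if trace_contributions else None,
        categorical_modes=modes,
    )


def predict_raw(model: MaxEntModel, table: dict[str, np.ndarray]) -> np.ndarray:
    """Raw Gibbs scores, normalized so the training background sums to 1."""
    eta = model.linear_predictor(table)
    return np.exp(eta - model.log_z)


def predict_logistic(model: MaxEntModel, table: dict[str, np.ndarray]
                     ) -> np.ndarray:
    """Logistic suitability in (0, 1): r e^H / (1 + r e^H)."""
    r = predict_raw(model, table)
    s = r * math.exp(model.entropy)
    return s / (1.0 + s)


def training_gain(model: MaxEntModel, features: FeatureSet) -> float:
    """Regularized training gain: log m_bg minus the penalized objective.

    Equals log m_bg for the null (uniform) model and grows as the model
    concentrates probability on presences.
    """
    eta_b = features.Fb @ model.weights
    eta_p_mean = float(features.Fp.mean(axis=0) @ model.weights)
    obj = _objective(eta_b, eta_p_mean, model.weights, model.rm * features.beta)
    return float(math.log(features.n_background) - obj)


def response_curve(models, features: FeatureSet, variable: str,
                   n_grid: int = 100) -> pd.DataFrame:
    """Mean +/- sd logistic response to one variable across replicate models.

    The variable sweeps its background range while the other continuous
    variables sit at their background means and categorical variables at
    their modal level.
    """
    if isinstance(models, MaxEntModel):
        models = [models]
    model0 = models[0]
    if variable not in model0.variables:
        raise ValueError(f"variable {variable!r} is not in the model")
    bt = features.background_table
    if variable in features.scaling:
        lo = float(np.min(bt[variable]))
        hi = float(np.max(bt[variable]))
        sweep = np.linspace(lo, hi, n_grid)
    else:
        sweep = np.unique(bt[variable][~np.isnan(bt[variable])])
    table: dict[str, np.ndarray] = {}
    for var, vals in bt.items():
        if var == variable:
            table[var] = sweep
        elif var in features.scaling:
            table[var] = np.full(len(sweep), float(np.mean(vals)))
        else:
            levs, counts = np.unique(vals[~np.isnan(vals)], return_counts=True)
            table[var] = np.full(len(sweep), float(levs[np.argmax(counts)]))
    preds = np.stack([predict_logistic(m, table) for m in models])
    return pd.DataFrame({
        "value": sweep,
        "suitability_mean": preds.mean(axis=0),
        "suitability_sd": preds.std(axis=0, ddof=0),
    })


def permutation_importance(model: MaxEntModel, features: FeatureSet,
                           seed: int = 0) -> pd.DataFrame:
    """Permutation ("exchange") importance per variable, normalized to 100.

    Each variable's values are permuted jointly across the presence and
    background rows, the training AUC is recomputed, and the AUC drops
    (floored at zero) are normalized to percentages.
    """
    from .evaluation import auc  # deferred: evaluation imports this module

    if features.n_presence < 2:
        raise ValueError("need at least 2 presences for permutation importance")
    rng = np.random.default_rng(seed)
    m = features.n_presence
    combined = {v: np.concatenate([features.presence_table[v],
                                   features.background_table[v]])
                for v in features.presence_table}
    eta = _feature_columns(model.features, model.scaling, combined) @ model.weights
    base = auc(eta[:m], eta[m:])
    drops = {}
    for var in model.variables:
        perm = dict(combined)
        perm[var] = rng.permutation(combined[var])
        eta_p = _feature_columns(model.features, model.scaling, perm) @ model.weights
        drops[var] = max(base - auc(eta_p[:m], eta_p[m:]), 0.0)
    total = sum(drops.values())
    if total > 0:
        pct = {v: 100.0 * d / total for v, d in drops.items()}
    else:
        pct = {v: 0.0 for v in drops}
    return pd.DataFrame({
        "variable": list(pct),
        "permutation_importance": list(pct.values()),
    }).sort_values("permutation_importance", ascending=False,
                   ignore_index=True)


def percent_contribution(model: MaxEntModel) -> pd.DataFrame:
    """Per-variable percent contribution from the fit's gain-attribution trace.

    Objective improvements during coordinate descent are attributed to
    the variable(s) behind the updated feature (products split equally)
    and normalized to sum 100.
    """
    if model.contribution_trace is None:
        raise ValueError(
            "fit was run without contribution tracing; refit with "
            "trace_contributions=True"
        )
    contrib = model.contribution_trace
    total = sum(contrib.values())
    if total > 0:
        pct = {v: 100.0 * c / total for v, c in contrib.items()}
    else:
        pct = {v: 0.0 for v in contrib}
    return pd.DataFrame({
        "variable": list(pct),
        "percent_contribution": list(pct.values()),
    }).sort_values("percent_contribution", ascending=False, ignore_index=True)


def jackknife_gains(features: FeatureSet, rm: float = 1.0,
                    **fit_kwargs) -> pd.DataFrame:
    """Jackknife of regularized training gain per variable.

    Fits the full model, each model with a single variable in isolation,
    and each model with that variable omitted; reports the gains. The
    full-model row carries the full gain in both columns.
    """
    variables = features.variables
    if len(variables) < 2:
        raise ValueError("jackknife needs at least 2 variables")
    full_model = fit(features, rm=rm, trace_contributions=False, **fit_kwargs)
    full_gain = training_gain(full_model, features)
    rows = []
    for var in variables:
        only = features.subset([var])
        without = features.subset([v for v in variables if v != var])
        g_only = (training_gain(fit(only, rm=rm, trace_contributions=False,
                                    **fit_kwargs), only)
                  if only.features else 0.0)
        g_without = training_gain(
            fit(without, rm=rm, trace_contributions=False, **fit_kwargs),
            without)
        rows.append({"variable": var, "gain_only": g_only,
                     "gain_without": g_without})
    df = pd.DataFrame(rows)
    df.attrs["full_gain"] = full_gain
    return df


def write_model(model: MaxEntModel, path: str | Path) -> None:
    """Serialize a model as a plain-text lambdas-style file."""
    lines = [
        f"# grasshab maxent model",
        f"rm\t{model.rm!r}",
        f"fc\t{model.fc}",
        f"log_z\t{model.log_z!r}",
        f"entropy\t{model.entropy!r}",
    ]
    for var, (lo, hi) in model.scaling.items():
        lines.append(f"scale\t{var}\t{lo!r}\t{hi!r}")
    for f, wgt, b in zip(model.features, model.weights, model.beta):
        knot = "" if f.knot is None else repr(f.knot)
        level = "" if f.level is None else repr(f.level)
        lines.append("feature\t{}\t{}\t{}\t{}\t{}\t{}\t{}".format(
            f.name, f.fclass, ",".join(f.variables), knot, level,
            repr(float(wgt)), repr(float(b))))
    for var, mode in model.categorical_modes.items():
        lines.append(f"mode\t{var}\t{mode!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_model(path: str | Path) -> MaxEntModel:
    """Load a model written by :func:`write_model`."""
    meta: dict[str, str] = {}
    scaling: dict[str, tuple[float, float]] = {}
    modes: dict[str, float] = {}
    features: list[Feature] = []
    weights: list[float] = []
    betas: list[float] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        key = parts[0]
        if key == "scale":
            scaling[parts[1]] = (float(parts[2]), float(parts[3]))
        elif key == "feature":
            _, name, fclass, vars_, knot, level, wgt, b = parts
            features.append(Feature(
                name=name, fclass=fclass, variables=tuple(vars_.split(",")),
                knot=float(knot) if knot else None,
                level=float(level) if level else None))
            weights.append(float(wgt))
            betas.append(float(b))
        elif key == "mode":
            modes[parts[1]] = float(parts[2])
        else:
            meta[key] = parts[1]
    return MaxEntModel(
        features=features, scaling=scaling, weights=np.array(weights),
        log_z=float(meta["log_z"]), entropy=float(meta["entropy"]),
        rm=float(meta["rm"]), fc=meta["fc"], beta=np.array(betas),
        converged=True, n_iter=0, objective_trace=[],
        contribution_trace=None, categorical_modes=modes,
    )
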