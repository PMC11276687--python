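"""Candidate-model calibration and selection.

Enumerates a grid of regularization multipliers (RM) crossed with
feature-class (FC) combinations, scores every candidate on one fixed
train/test split by partial-ROC significance, omission rate and AICc,
and selects the best model: statistically significant candidates with
omission at most the acceptance cut (default 8%), minimum AICc, ties
broken by fewer parameters then smaller RM.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import maxent
from .raster import EnvStack
from .synthetic import OccurrenceSet

__all__ = [
    "CandidateSpec",
    "CandidateResult",
    "SelectionError",
    "default_fc_list",
    "enumerate_candidates",
    "split_data",
    "omission_rate",
    "partial_roc",
    "aicc",
    "select_best",
    "run_calibration",
]


@dataclass(frozen=True)
class CandidateSpec:
    """One RM x FC candidate."""

    rm: float
    fc: str

    def __post_init__(self) -> None:
        if self.rm <= 0:
            raise ValueError("RM must be positive")
        object.__setattr__(self, "fc", maxent._normalize_fc(self.fc))

    @property
    def label(self) -> str:
        return f"RM{self.rm:g}_{self.fc}"


@dataclass
class CandidateResult:
    """Metrics of one calibrated candidate."""

    spec: CandidateSpec
    p_value: float
    omission: float
    aicc: float
    k: int
    test_auc: float
    train_auc: float
    error: str | None = None

    def to_row(self) -> dict:
        return {
            "rm": self.spec.rm, "fc": self.spec.fc, "p_value": self.p_value,
            "omission": self.omission, "aicc": self.aicc, "k": self.k,
            "test_auc": self.test_auc, "train_auc": self.train_auc,
            "error": self.error or "",
        }


class SelectionError(RuntimeError):
    """No candidate survived the filters; carries the least-bad candidate."""

    def __init__(self, message: str, least_bad: CandidateResult,
                 stage_counts: dict):
        super().__init__(message)
        self.least_bad = least_bad
        self.stage_counts = stage_counts


def default_fc_list() -> list[str]:
    """The 29 feature-class combinations used for calibration.

    All 31 non-empty subsets of {L, Q, P, T, H} minus the bare product
    and bare threshold singletons, which are not meaningful alone.
    """
    combos = []
    for r in range(1, 6):
        for sub in itertools.combinations("LQPTH", r):
            combo = "".join(sub)
            if combo in ("P", "T"):
                continue
            combos.append(combo)
    return combos


def enumerate_candidates(rm_start: float = 0.1, rm_stop: float = 4.0,
                         rm_step: float = 0.1,
                         fc_list: list[str] | None = None
                         ) -> list[CandidateSpec]:
    """Cartesian product of the RM grid and FC combinations.

    RM values are rounded to the step's decimal precision; duplicate FC
    combos are deduplicated with a warning.
    """
    if rm_step <= 0:
        raise ValueError("rm_step must be positive")
    if rm_stop < rm_start:
        raise ValueError("empty RM range")
    decimals = max(0, -int(np.floor(np.log10(rm_step))))
    n = int(round((rm_stop - rm_start) / rm_step)) + 1
    rms = [round(rm_start + i * rm_step, decimals) for i in range(n)]
    rms = [r for r in rms if r > 0]
    if not rms:
        raise ValueError("empty RM range")
    fcs_in = fc_list if fc_list is not None else default_fc_list()
    fcs: list[str] = []
    for fc in (maxent._normalize_fc(f) for f in fcs_in):
        if fc in fcs:
            warnings.warn(f"duplicate feature combination {fc!r} ignored")
        else:
            fcs.append(fc)
    if not fcs:
        raise ValueError("no feature combinations given")
    return [CandidateSpec(rm=r, fc=f) for r in rms for f in fcs]


def split_data(occ: OccurrenceSet, test_fraction: float = 0.25,
               seed: int = 0) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Seeded random train/test partition of the presences.

    |test| = round(fraction x n); the split is disjoint and exhaustive.
    """
    n = len(occ)
    if n < 4:
        raise ValueError("need at least 4 presences to split")
    n_test = int(round(test_fraction * n))
    if n_test < 1 or n_test >= n:
        raise ValueError(
            f"test fraction {test_fraction} gives an empty train or test set"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])

    def take(idx):
        return OccurrenceSet(x=occ.x[idx], y=occ.y[idx],
                             density=occ.density[idx],
                             rows=occ.rows[idx], cols=occ.cols[idx])

    return take(train_idx), take(test_idx)


def omission_rate(test_scores: np.ndarray, train_scores: np.ndarray,
                  e_level: float = 0.05) -> float:
    """Fraction of test presences scoring below the training threshold.

    The threshold is the E-quantile of training presence scores (default
    E = 5%), the conventional calibrated-omission rule.
    """
    test_scores = np.asarray(test_scores, dtype=float)
    if test_scores.size == 0:
        raise ValueError("empty test scores")
    thr = float(np.quantile(np.asarray(train_scores, dtype=float), e_level))
    return float(np.mean(test_scores < thr))


def partial_roc(test_scores: np.ndarray, background_scores: np.ndarray,
                e_level: float = 0.05, iters: int = 500,
                seed: int = 0) -> float:
    """Bootstrap partial-ROC significance test.

    The AUC ratio compares the model's partial ROC (restricted to
    omission <= E) against the random-prediction diagonal; each
    bootstrap resamples 50% of the test points with replacement and
    p is the fraction of bootstrap ratios <= 1 (H0: no better than
    random).
    """
    if iters < 100:
        raise ValueError("need at least 100 bootstrap iterations")
    test = np.asarray(test_scores, dtype=float)
    bg = np.asarray(background_scores, dtype=float)
    if test.size == 0 or bg.size == 0:
        raise ValueError("empty score set")
    if np.ptp(test) == 0 and np.ptp(bg) == 0:
        warnings.warn("degenerate (constant) scores; partial ROC p = 1")
        return 1.0
    # Threshold sweep (descending) over the background score distribution,
    # extended past the extremes so the curve runs from (0, 0) to (1, 1).
    thresholds = np.unique(np.quantile(bg, np.linspace(0.0, 1.0, 201)))
    thresholds = np.concatenate([
        [max(thresholds[-1], test.max()) + 1.0], thresholds[::-1],
        [min(thresholds[0], test.min()) - 1.0]])
    # Fraction of background predicted present at each threshold.
    area = np.array([(bg >= t).mean() for t in thresholds])
    rng = np.random.default_rng(seed)
    half = max(1, test.size // 2)
    s_min = 1.0 - e_level
    ratios = np.empty(iters)
    # Interpolated empirical quantiles (plotting positions i/(n+1)) give a
    # continuous sensitivity curve; a step ECDF biases the small-sample
    # AUC ratio upward because sensitivity near 1-E is then quantized.
    pp = np.arange(1, half + 1) / (half + 1)
    for i in range(iters):
        boot = np.sort(rng.choice(test, size=half, replace=True))
        sens = 1.0 - np.interp(thresholds, boot, pp, left=0.0, right=1.0)
        # Clip the curve at sensitivity = 1 - E, interpolating the crossing
        # so small test samples are not biased by the sensitivity grid.
        k = int(np.argmax(sens >= s_min))
        if sens[k] < s_min:
            ratios[i] = 1.0
            continue
        a, s = area[k:], sens[k:]
        if k > 0 and sens[k] > s_min and sens[k] > sens[k - 1]:
            frac = (s_min - sens[k - 1]) / (sens[k] - sens[k - 1])
            a0 = area[k - 1] + frac * (area[k] - area[k - 1])
            a = np.concatenate([[a0], a])
            s = np.concatenate([[s_min], s])
        denom = np.trapezoid(a, a)
        ratios[i] = np.trapezoid(s, a) / denom if denom > 0 else 1.0
    return float(np.mean(ratios <= 1.0))


def aicc(model: maxent.MaxEntModel, presence_table: dict) -> float:
    """Sample-size-corrected AIC from the presence likelihood.

    AICc = -2 sum ln(raw) + 2k + 2k(k+1)/(n-k-1) with k the number of
    non-zero weights and raw the background-normalized Gibbs score.
    Returns +inf (candidate ineligible) when n <= k + 1.
    """
    raw = maxent.predict_raw(model, presence_table)
    n = len(raw)
    k = model.n_active
    if n - k - 1 <= 0:
        return float("inf")
    ll = float(np.sum(np.log(raw)))
    return -2.0 * ll + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def select_best(results: list[CandidateResult], omission_max: float = 0.08,
                alpha: float = 0.05) -> tuple[CandidateResult, dict]:
    """Filter candidates and pick the winner.

    Filters: partial-ROC p < alpha, then omission <= omission_max, then
    minimum AICc; ties broken by smaller parameter count k, then smaller
    RM. Returns the winning result plus per-stage survivor counts.
    Raises :class:`SelectionError` (carrying the least-bad candidate)
    when nothing survives.
    """
    if not results:
        raise ValueError("no candidate results")
    usable = [r for r in results if r.error is None]
    significant = [r for r in usable if r.p_value < alpha]
    low_omission = [r for r in significant if r.omission <= omission_max]
    eligible = [r for r in low_omission if np.isfinite(r.aicc)]
    counts = {
        "candidates": len(results),
        "fitted": len(usable),
        "significant": len(significant),
        "low_omission": len(low_omission),
        "aicc_eligible": len(eligible),
    }
    if not eligible:
        least_bad = min(
            usable or results,
            key=lambda r: (r.p_value, r.omission,
                           r.aicc if np.isfinite(r.aicc) else np.inf),
        )
        raise SelectionError(
            "no candidate passed significance + omission + AICc filters",
            least_bad, counts)
    best = min(eligible, key=lambda r: (r.aicc, r.k, r.spec.rm))
    return best, counts


def run_calibration(stack: EnvStack, occ: OccurrenceSet,
                    candidates: list[CandidateSpec],
                    n_background: int = maxent.MAX_BACKGROUND,
                    test_fraction: float = 0.25,
                    e_level: float = 0.05,
                    proc_iters: int = 500,
                    seed: int = 0,
                    n_knots: int = maxent.DEFAULT_KNOTS,
                    fit_kwargs: dict | None = None
                    ) -> list[CandidateResult]:
    """Fit and score every candidate on one fixed train/test split.

    A single split (not replicated subsampling) keeps the grid
    tractable; the selected model is re-fit with replicates afterwards.
    Candidates whose fit fails are flagged rather than aborting the grid.
    """
    from .evaluation import auc

    fkw = fit_kwargs or {}
    bg = maxent.sample_background(stack, n_background, seed=seed)
    train, test = split_data(occ, test_fraction=test_fraction, seed=seed)
    results: list[CandidateResult] = []
    feature_cache: dict[str, maxent.FeatureSet] = {}
    for spec in candidates:
        if spec.fc not in feature_cache:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                feature_cache[spec.fc] = maxent.build_features(
                    stack, train, bg, fc=spec.fc, n_knots=n_knots)
        features = feature_cache[spec.fc]
        try:
            model = maxent.fit(features, rm=spec.rm,
                               trace_contributions=False, **fkw)
        except (maxent.ConvergenceError, ValueError) as exc:
            results.append(CandidateResult(
                spec=spec, p_value=np.nan, omission=np.nan, aicc=np.nan,
                k=0, test_auc=np.nan, train_auc=np.nan, error=str(exc)))
            continue
        test_table = stack.table(test.rows, test.cols)
        train_scores = maxent.predict_raw(model, features.presence_table)
        test_scores = maxent.predict_raw(model, test_table)
        bg_scores = maxent.predict_raw(model, features.background_table)
        all_presence = {
            v: np.concatenate([features.presence_table[v], test_table[v]])
            for v in test_table
        }
        results.append(CandidateResult(
            spec=spec,
            p_value=partial_roc(test_scores, bg_scores, e_level=e_level,
                                iters=proc_iters, seed=seed),
            omission=omission_rate(test_scores, train_scores,
                                   e_level=e_level),
            aicc=aicc(model, all_presence),
            k=model.n_active,
            test_auc=auc(test_scores, bg_scores),
            train_auc=auc(train_scores, bg_scores),
        ))
    return results


def results_table(results: list[CandidateResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])
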