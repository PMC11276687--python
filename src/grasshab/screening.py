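"""Multicollinearity screening by pairwise Pearson correlation.

Highly cross-correlated covariates carry redundant information and make
variable-importance readouts unstable, so only one member of each
strongly correlated set (|r| above a threshold, default 0.8, strict
inequality) is kept. Categorical layers bypass the screen: Pearson r is
undefined for unordered categories, and they are always retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import EnvStack

__all__ = ["CorrelationMatrix", "pearson_matrix", "prune_correlated"]


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson-r matrix over sampled valid cells.

    Entries involving a zero-variance variable are NaN and the variable
    is listed in ``degenerate``.
    """

    variables: list[str]
    r: np.ndarray
    sample_size: int
    degenerate: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        k = len(self.variables)
        if self.r.shape != (k, k):
            raise ValueError("matrix shape does not match variable count")

    def lookup(self, a: str, b: str) -> float:
        return float(self.r[self.variables.index(a), self.variables.index(b)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.variables, columns=self.variables)


def pearson_matrix(stack: EnvStack, sample_size: int = 0,
                   seed: int = 0) -> CorrelationMatrix:
    """Pearson correlations among continuous layers over valid cells.

    ``sample_size`` = 0 uses every valid cell; otherwise a seeded uniform
    sample without replacement of that many cells. Zero-variance
    variables get NaN rows/columns (diagonal stays 1) and are reported.
    """
    names = stack.continuous_names
    if len(names) < 2:
        raise ValueError("need at least 2 continuous variables")
    idx = stack.valid_indices()
    if sample_size:
        if sample_size > len(idx):
            raise ValueError(
                f"sample_size {sample_size} exceeds {len(idx)} valid cells"
            )
        rng = np.random.default_rng(seed)
        idx = idx[rng.choice(len(idx), size=sample_size, replace=False)]
    rows, cols = idx[:, 0], idx[:, 1]
    X = np.column_stack([stack.layer(n)[rows, cols] for n in names])
    sd = X.std(axis=0)
    degenerate = [n for n, s in zip(names, sd) if s == 0.0]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    for n in degenerate:
        i = names.index(n)
        r[i, :] = np.nan
        r[:, i] = np.nan
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(variables=names, r=r, sample_size=len(idx),
                             degenerate=degenerate)


def prune_correlated(cm: CorrelationMatrix, threshold: float = 0.8
                     ) -> tuple[list[str], list[dict]]:
    """Greedy elimination of collinear variables.

    While any pair has |r| strictly above the threshold, the member of
    the worst pair with the larger mean absolute correlation to all
    remaining variables is dropped (ties broken by variable-name order).
    Returns the retained list plus a decision log recording every drop
    and its justifying pair.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    names = list(cm.variables)
    if not names:
        return [], []
    r = np.abs(cm.r.copy())
    np.fill_diagonal(r, 0.0)
    r = np.nan_to_num(r, nan=0.0)  # degenerate variables never trigger drops
    alive = list(range(len(names)))
    log: list[dict] = []
    while True:
        sub = r[np.ix_(alive, alive)]
        if sub.size == 0 or np.nanmax(sub) <= threshold:
            break
        i_loc, j_loc = np.unravel_index(np.argmax(sub), sub.shape)
        i, j = alive[i_loc], alive[j_loc]
        # Mean |r| of each member to the other remaining variables.
        mean_i = sub[i_loc].sum() / max(len(alive) - 1, 1)
        mean_j = sub[j_loc].sum() / max(len(alive) - 1, 1)
        if mean_i > mean_j:
            drop = i
        elif mean_j > mean_i:
            drop = j
        else:
            drop = max(i, j, key=lambda k: names[k])
        keep = j if drop == i else i
        log.append({
            "dropped": names[drop],
            "kept": names[keep],
            "pair_r": float(cm.r[i, j]),
            "mean_abs_r_dropped": float(mean_i if drop == i else mean_j),
            "mean_abs_r_kept": float(mean_j if drop == i else mean_i),
        })
        alive.remove(drop)
    return [names[k] for k in alive], log
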