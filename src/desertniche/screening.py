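"""Environmental-factor screening: ensemble importance and VIF filtering.

Screening fits a seeded random-forest regressor of the response on the
factor table augmented with *shadow* factors — row-permuted copies of every
real factor that by construction carry no signal.  Model-agnostic
permutation importance is computed for all columns; a real factor whose
importance exceeds the mean shadow importance ("Mean") has high
contribution, and one exceeding the maximum shadow importance ("MAX") has
very high contribution.

Multicollinearity among retained factors is then removed by iterative
variance-inflation-factor filtering: VIF_j = 1/(1 - R2_j) where R2_j comes
from regressing factor j on all other factors (with intercept); while any
VIF >= 10 the single worst factor is dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

logger = logging.getLogger(__name__)


@dataclass
class ImportanceReport:
    response: str
    factor_importances: dict[str, float]
    shadow_mean: float
    shadow_max: float
    high_set: list[str]
    very_high_set: list[str]
    seed: int
    n_trees: int

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "factor_importances": self.factor_importances,
            "shadow_mean": self.shadow_mean, "shadow_max": self.shadow_max,
            "high_set": self.high_set, "very_high_set": self.very_high_set,
            "seed": self.seed, "n_trees": self.n_trees,
        }


@dataclass
class VIFReport:
    retained: list[str]
    removed: list[tuple[str, float]] = field(default_factory=list)
    final_vifs: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"retained": self.retained,
                "removed": [[f, v] for f, v in self.removed],
                "final_vifs": self.final_vifs}


def importance_screen(X: pd.DataFrame, y, n_trees: int = 500,
                      seed: int = 0, response: str = "",
                      n_repeats: int = 10,
                      n_shadow_repeats: int = 9) -> ImportanceReport:
    """Screen factors against shadow-feature importance thresholds.

    Each factor gets ``n_shadow_repeats`` independently permuted shadow
    copies.  With a single copy the maximum importance would land on a real
    factor half the time under a null response (real and shadow columns are
    exchangeable); nine copies per factor put ~90% of the null probability
    mass on the shadow side, making "importance > MAX" a usable
    very-high-contribution threshold.

    Deterministic for a fixed seed and input ordering: the shadow
    permutations, the forest, and the permutation importance all derive
    from ``seed``.
    """
    y = np.asarray(y, dtype=float)
    if X.isna().any().any() or np.isnan(y).any():
        raise ValueError("X and y must not contain missing values")
    n, m = X.shape
    if n < 10:
        raise ValueError(f"need at least 10 rows, got {n}")
    if len(y) != n:
        raise ValueError("X and y row counts differ")
    if np.ptp(y) == 0:
        raise ValueError("response is constant; importance is undefined")
    if n < 2 * m:
        logger.warning("only %d rows for %d factors; importances will be "
                       "noisy", n, m)

    rng = np.random.default_rng(seed)
    shadow = pd.DataFrame(
        {f"shadow_{c}_{k}": rng.permutation(X[c].to_numpy())
         for k in range(n_shadow_repeats) for c in X.columns},
        index=X.index)
    augmented = pd.concat([X, shadow], axis=1)

    forest = RandomForestRegressor(n_estimators=n_trees,
                                   random_state=int(seed) % (2 ** 31),
                                   n_jobs=1)
    forest.fit(augmented.to_numpy(), y)
    imp = permutation_importance(forest, augmented.to_numpy(), y,
                                 n_repeats=n_repeats,
                                 random_state=int(seed) % (2 ** 31),
                                 n_jobs=1).importances_mean

    real = dict(zip(X.columns, imp[:m].astype(float)))
    shadow_imp = imp[m:]
    shadow_mean = float(shadow_imp.mean())
    shadow_max = float(shadow_imp.max())
    high = [c for c, v in real.items() if v > shadow_mean]
    very_high = [c for c, v in real.items() if v > shadow_max]
    return ImportanceReport(response=response, factor_importances=real,
                            shadow_mean=shadow_mean, shadow_max=shadow_max,
                            high_set=high, very_high_set=very_high,
                            seed=int(seed), n_trees=int(n_trees))


def _r_squared(y: np.ndarray, X: np.ndarray) -> float:
    """R^2 of an intercept-included least-squares fit of y on X."""
    design = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    tss = ((y - y.mean()) ** 2).sum()
    if tss == 0:
        return 0.0
    return 1.0 - float((resid ** 2).sum() / tss)


def vif(X: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factor of every column (+inf if perfectly collinear)."""
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least 2 columns")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("VIF needs more rows than columns")
    arr = X.to_numpy(dtype=float)
    out: dict[str, float] = {}
    for j, col in enumerate(X.columns):
        others = np.delete(arr, j, axis=1)
        r2 = _r_squared(arr[:, j], others)
        out[col] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def vif_filter(X: pd.DataFrame, threshold: float = 10.0) -> VIFReport:
    """Iteratively drop the worst-VIF factor until all VIFs < threshold.

    Ties on the maximum VIF are broken toward the later column (rightmost
    in the current ordering), making removal deterministic.
    """
    cols = list(X.columns)
    removed: list[tuple[str, float]] = []
    while len(cols) > 1:
        vifs = vif(X[cols])
        worst_val = max(vifs.values())
        if worst_val < threshold:
            break
        # later-column tie-break: scan right to left
        worst = next(c for c in reversed(cols) if vifs[c] == worst_val)
        removed.append((worst, worst_val))
        cols.remove(worst)
        logger.info("vif_filter removed %s (VIF %.3g)", worst, worst_val)
    final = vif(X[cols]) if len(cols) > 1 else {c: 1.0 for c in cols}
    return VIFReport(retained=cols, removed=removed,
                     final_vifs={c: float(v) for c, v in final.items()})
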