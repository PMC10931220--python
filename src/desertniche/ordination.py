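"""Redundancy analysis with permutation tests and forward selection.

RDA is the constrained ordination obtained by a principal-component
decomposition of the fitted values of a multivariate linear regression of
the (Hellinger-transformed, column-centred) response matrix Y on the
standardized factor matrix X.  Canonical eigenvalues partition the variance
explained by X; residual eigenvalues partition the rest, and the two blocks
sum to the total variance of Y exactly.

Significance uses the vegan-style permutation pseudo-F,

    F = (SS_canonical / m) / (SS_residual / (n - m - 1)),

with the response rows permuted under a fixed seed and the add-one p-value
rule p = (1 + #{F_perm >= F_obs}) / (1 + n_perm), so p is never zero and
bottoms out at 1/(n_perm + 1).

Forward selection uses the double stopping rule of permutation-gated
greedy selection: (0) selection only starts if the full model's global
permutation test is significant at alpha — without this gate, picking the
best of many candidates and then testing it inflates the type-I error;
(1) at each step the candidate with the largest adjusted-R2 (Ezekiel) gain
is admitted if its conditional permutation test — a partial RDA of the
candidate given the already-selected factors — has p <= alpha; (2) the
loop stops once the selected model's adjusted R2 reaches the full model's
adjusted R2 (the ceiling beyond which gains are indistinguishable from
overfitting).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class RDAResult:
    canonical_eigenvalues: np.ndarray
    residual_eigenvalues: np.ndarray
    proportion_explained_per_axis: np.ndarray  # canonical / total variance
    cumulative_first_two: float  # share of constrained variance on axes 1-2
    r2: float
    adjusted_r2: float
    site_scores: np.ndarray
    species_scores: np.ndarray
    biplot_scores: np.ndarray  # factors x canonical axes, correlation scaling
    n_samples: int
    n_factors: int

    @property
    def total_variance(self) -> float:
        return float(self.canonical_eigenvalues.sum()
                     + self.residual_eigenvalues.sum())


@dataclass
class PermutationTest:
    pseudo_F: float
    p_value: float
    n_permutations: int
    seed: int


@dataclass
class ForwardSelectionStep:
    factor: str
    r2_contribution: float
    pseudo_F: float
    p_value: float
    order: int


def hellinger(Y) -> np.ndarray:
    """Row-wise square-root-of-proportions transform.

    Every output row has unit sum of squares; all-zero rows are undefined
    and raise, naming the offending row.
    """
    Y = np.asarray(Y, dtype=float)
    if (Y < 0).any():
        raise ValueError("Hellinger transform needs non-negative entries")
    row_sums = Y.sum(axis=1)
    zero = np.flatnonzero(row_sums == 0)
    if zero.size:
        raise ValueError(f"all-zero row(s) at index {zero.tolist()}: "
                         "Hellinger transform undefined")
    return np.sqrt(Y / row_sums[:, None])


def standardize(X) -> np.ndarray:
    """Column-wise z-scores (ddof=1), the factor preprocessing for RDA."""
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("constant factor column(s) cannot be standardized")
    return (X - X.mean(axis=0)) / sd


def adjusted_r2(r2: float, n: int, m: int) -> float:
    """Ezekiel adjustment: 1 - (1 - R2)(n - 1)/(n - m - 1)."""
    if n - m - 1 <= 0:
        raise ValueError("need n > m + 1 for the adjusted R2")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


def _fitted_and_residual(Yc: np.ndarray, X: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares fit of centred Y on X with intercept."""
    design = np.column_stack([np.ones(len(Yc)), X])
    coef, *_ = np.linalg.lstsq(design, Yc, rcond=None)
    fitted = design @ coef
    return fitted, Yc - fitted


def rda_fit(Y, X, factor_names: list[str] | None = None) -> RDAResult:
    """Redundancy analysis of response matrix Y constrained by factors X."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim == 2 and X.shape[0] == 1 and Y.shape[0] > 1:
        X = X.T
    n, m = X.shape
    if Y.shape[0] != n:
        raise ValueError("Y and X must share rows")
    if n <= m + 1:
        raise ValueError("need more samples than factors + 1")
    design = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(design) < m + 1:
        raise ValueError("factor matrix is rank deficient (collinear); "
                         "run vif_filter first")

    Yc = Y - Y.mean(axis=0)
    fitted, resid = _fitted_and_residual(Yc, X)

    # canonical block: PCA of the fitted values
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    can_eig = s ** 2 / (n - 1)
    n_axes = min(m, Y.shape[1])
    can_eig = can_eig[:n_axes]
    u, s, vt = u[:, :n_axes], s[:n_axes], vt[:n_axes]

    _, s_r, _ = np.linalg.svd(resid, full_matrices=False)
    res_eig = s_r ** 2 / (n - 1)
    res_eig = res_eig[res_eig > 1e-12 * max(res_eig.max(initial=0.0), 1.0)]

    total = float((Yc ** 2).sum()) / (n - 1)
    r2 = float(can_eig.sum() / total) if total > 0 else 0.0
    site = u * s  # constrained site scores (linear-combination scores)
    can_sum = float(can_eig.sum())
    cum2 = float(can_eig[:2].sum() / can_sum) if can_sum > 0 else 0.0

    # correlation (type-2) biplot scores of the factors on the canonical axes
    biplot = np.zeros((m, n_axes))
    for k in range(n_axes):
        if s[k] > 1e-10:
            for j in range(m):
                xj = X[:, j]
                if xj.std() > 0 and site[:, k].std() > 0:
                    biplot[j, k] = np.corrcoef(xj, site[:, k])[0, 1]

    return RDAResult(
        canonical_eigenvalues=can_eig,
        residual_eigenvalues=res_eig,
        proportion_explained_per_axis=can_eig / total if total > 0 else can_eig,
        cumulative_first_two=cum2,
        r2=r2,
        adjusted_r2=adjusted_r2(r2, n, m),
        site_scores=site,
        species_scores=vt.T,
        biplot_scores=biplot,
        n_samples=n, n_factors=m,
    )


def _ss_parts(Yc: np.ndarray, Q: np.ndarray) -> tuple[float, float]:
    """(canonical SS, residual SS) given an orthonormal basis Q of centred X."""
    proj = Q.T @ Yc
    ss_tot = float((Yc ** 2).sum())
    ss_can = float((proj ** 2).sum())
    return ss_can, ss_tot - ss_can


def _centered_basis(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    q, r = np.linalg.qr(Xc)
    keep = np.abs(np.diag(r)) > 1e-10 * max(np.abs(np.diag(r)).max(), 1.0)
    return q[:, keep]


def permutation_test(Y, X, n_permutations: int = 999,
                     seed: int = 0) -> PermutationTest:
    """Global pseudo-F permutation test of the RDA model."""
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations")
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, m = X.shape
    Yc = Y - Y.mean(axis=0)
    Q = _centered_basis(X)

    def pseudo_f(yc: np.ndarray) -> float:
        ss_can, ss_res = _ss_parts(yc, Q)
        if ss_res <= 0:
            return np.inf
        return (ss_can / m) / (ss_res / (n - m - 1))

    f_obs = pseudo_f(Yc)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if pseudo_f(Yc[perm]) >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return PermutationTest(pseudo_F=float(f_obs), p_value=float(p),
                           n_permutations=int(n_permutations), seed=int(seed))


def _r2_of(Yc: np.ndarray, X: np.ndarray) -> float:
    Q = _centered_basis(X)
    ss_can, ss_res = _ss_parts(Yc, Q)
    tot = ss_can + ss_res
    return ss_can / tot if tot > 0 else 0.0


def _conditional_test(Yc: np.ndarray, X_sel: np.ndarray | None,
                      x_new: np.ndarray, n_permutations: int,
                      rng: np.random.Generator) -> tuple[float, float]:
    """Partial permutation test of one candidate given selected factors.

    Both the response and the candidate are residualized on the selected
    block, then the candidate's marginal pseudo-F is permuted.
    """
    n = len(Yc)
    if X_sel is not None and X_sel.shape[1] > 0:
        Qs = _centered_basis(X_sel)
        Yr = Yc - Qs @ (Qs.T @ Yc)
        xr = x_new - x_new.mean()
        xr = xr - Qs @ (Qs.T @ xr)
        n_cond = X_sel.shape[1]
    else:
        Yr = Yc.copy()
        xr = x_new - x_new.mean()
        n_cond = 0
    norm = np.linalg.norm(xr)
    if norm < 1e-12:
        return 0.0, 1.0
    q = (xr / norm)[:, None]
    df_res = n - n_cond - 1 - 1

    def f_of(y: np.ndarray) -> float:
        ss_can, ss_res = _ss_parts(y - y.mean(axis=0), q)
        if ss_res <= 0:
            return np.inf
        return ss_can / (ss_res / df_res)

    f_obs = f_of(Yr)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if f_of(Yr[perm]) >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return float(f_obs), float(p)


def forward_select(Y, X: pd.DataFrame, alpha: float = 0.05,
                   n_permutations: int = 999, seed: int = 0,
                   ) -> tuple[list[ForwardSelectionStep], RDAResult | None]:
    """Greedy forward selection of factors with the double stopping rule.

    Returns the ordered admission steps (factor, unadjusted R2 gain,
    conditional pseudo-F, p) and the RDA of the selected model (None when
    nothing is admitted).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    names = list(X.columns)
    Xa = X.to_numpy(dtype=float)
    n = len(Y)
    Yc = Y - Y.mean(axis=0)
    full_adj = adjusted_r2(_r2_of(Yc, Xa), n, Xa.shape[1])
    rng = np.random.default_rng(seed)

    # gate 0: the full model itself must be significant, otherwise greedy
    # best-of-many candidate picking inflates the type-I error
    global_test = permutation_test(Y, Xa, n_permutations=n_permutations,
                                   seed=int(rng.integers(2 ** 31)))
    if global_test.p_value > alpha:
        logger.info("forward_select stop: global model not significant "
                    "(p = %.4g)", global_test.p_value)
        return [], None

    selected: list[int] = []
    steps: list[ForwardSelectionStep] = []
    r2_current = 0.0
    adj_current = 0.0
    while len(selected) < len(names):
        candidates = [j for j in range(len(names)) if j not in selected]
        best_j, best_r2 = None, -np.inf
        for j in candidates:
            cols = selected + [j]
            r2_j = _r2_of(Yc, Xa[:, cols])
            if r2_j > best_r2:
                best_j, best_r2 = j, r2_j
        assert best_j is not None
        adj_new = adjusted_r2(best_r2, n, len(selected) + 1)
        if adj_new <= adj_current and selected:
            break
        X_sel = Xa[:, selected] if selected else None
        f_stat, p = _conditional_test(Yc, X_sel, Xa[:, best_j],
                                      n_permutations, rng)
        if p > alpha:
            break
        steps.append(ForwardSelectionStep(
            factor=names[best_j], r2_contribution=float(best_r2 - r2_current),
            pseudo_F=f_stat, p_value=p, order=len(steps) + 1))
        selected.append(best_j)
        r2_current = best_r2
        adj_current = adj_new
        if adj_current >= full_adj:
            logger.info("forward_select stop: selected model reached the "
                        "full-model adjusted R2 ceiling")
            break

    final = None
    if selected:
        final = rda_fit(Y, Xa[:, selected],
                        factor_names=[names[j] for j in selected])
    return steps, final


def factor_fit(result: RDAResult, X: pd.DataFrame, n_permutations: int = 999,
               seed: int = 0) -> pd.DataFrame:
    """Per-factor fit onto the first two canonical axes (envfit-style).

    For each factor: the direction cosines of its least-squares vector in
    the RDA1/RDA2 plane, the squared correlation r2 of that fit, and a
    permutation p-value (factor values permuted).
    """
    axes = result.site_scores[:, :2]
    if axes.shape[1] < 2:
        axes = np.column_stack([axes, np.zeros(len(axes))])
    rng = np.random.default_rng(seed)
    Q = _centered_basis(axes)
    rows = []
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        xc = x - x.mean()
        ss = float((xc ** 2).sum())
        if ss == 0:
            rows.append({"factor": col, "RDA1": 0.0, "RDA2": 0.0,
                         "r2": 0.0, "p": 1.0})
            continue
        proj = Q.T @ xc
        r2_obs = float((proj ** 2).sum() / ss)
        coef, *_ = np.linalg.lstsq(np.column_stack([np.ones(len(x)), axes]),
                                   xc, rcond=None)
        direction = coef[1:3]
        nrm = np.linalg.norm(direction)
        direction = direction / nrm if nrm > 0 else direction
        exceed = 0
        for _ in range(n_permutations):
            xp = xc[rng.permutation(len(xc))]
            if float(((Q.T @ xp) ** 2).sum() / ss) >= r2_obs:
                exceed += 1
        rows.append({"factor": col, "RDA1": float(direction[0]),
                     "RDA2": float(direction[1]), "r2": r2_obs,
                     "p": (1 + exceed) / (1 + n_permutations)})
    return pd.DataFrame(rows)
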