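"""Yield prediction and population statistics over the i-trait table.

* Stepwise linear regression (forward selection with backward
  elimination on partial-F probabilities; entry p = 0.05, removal
  p = 0.10) predicts yield per trait group and pooled.
* Mantel and partial Mantel permutation tests relate the grain-trait
  distance matrix to the distance matrices of other trait groups
  (Euclidean distances, 9,999 permutations, upper-tail p).
* Kruskal-Wallis omnibus tests with pairwise Wilcoxon rank-sum
  follow-ups compare trait distributions between population groups;
  pairwise tests run only when the omnibus is significant at 0.05, and
  both unadjusted and Holm-adjusted p-values are reported.
* PCA on the trait correlation matrix (columns standardised, i.e. the
  R convention ``scale = TRUE``) yields Organ_PC and Time_PC scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from . import registry

DEFAULT_ENTRY_P = 0.05
DEFAULT_REMOVAL_P = 0.10
DEFAULT_N_PERM = 9_999


# ---------------------------------------------------------------------------
# stepwise regression
# ---------------------------------------------------------------------------

@dataclass
class StepwiseResult:
    """Outcome of forward-with-backward-elimination stepping.

    ``trace`` logs every ("add"|"remove", trait, p) step; replaying it
    against the same data reproduces the final coefficients.
    """

    selected: list[str]
    coefficients: dict[str, float]  # includes "intercept"
    r2: float
    entry_p: float
    removal_p: float
    trace: list[tuple[str, str, float]] = field(default_factory=list)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        y = np.full(len(X), self.coefficients["intercept"])
        for t in self.selected:
            y = y + self.coefficients[t] * X[t].to_numpy(dtype=float)
        return y


def _ols_pvalues(y: np.ndarray, X: pd.DataFrame) -> tuple[pd.Series, float]:
    """Two-sided coefficient p-values (equivalent to partial F) and R^2."""
    design = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.OLS(y, design).fit()
    pvals = pd.Series(fit.pvalues[1:], index=list(X.columns))
    return pvals, float(fit.rsquared)


def stepwise_regression(
    X: pd.DataFrame,
    y,
    entry_p: float = DEFAULT_ENTRY_P,
    removal_p: float = DEFAULT_REMOVAL_P,
    order: list[str] | None = None,
) -> StepwiseResult:
    """Classic stepwise variable selection on partial-F probabilities.

    At each cycle the candidate with the smallest entry p-value (the
    significance of its coefficient when added to the current model) is
    added if p <= ``entry_p``; included variables whose p-value has
    risen to >= ``removal_p`` are then removed, worst first. Ties are
    broken deterministically by ``order`` (default: trait-registry
    order for registry traits, column order otherwise). Candidates with
    zero variance are dropped with a warning.
    """
    y = np.asarray(y, dtype=float)
    if len(X) != len(y):
        raise ValueError("X and y length mismatch")
    if len(y) < 3:
        raise ValueError("stepwise regression needs at least 3 samples")
    if np.all(y == y[0]):
        raise ValueError("y is constant; nothing to model")
    X = X.astype(float)
    variances = X.var(axis=0, ddof=1)
    dead = [c for c in X.columns if not np.isfinite(variances[c]) or variances[c] == 0 or X[c].isna().any()]
    if dead:
        warnings.warn(f"dropping zero-variance or incomplete candidates: {dead}", stacklevel=2)
        X = X.drop(columns=dead)
    if order is None:
        names = set(registry.trait_names())
        if all(c in names for c in X.columns):
            order = sorted(X.columns, key=registry.registry_index)
        else:
            order = list(X.columns)
    cols = [c for c in order if c in X.columns]

    sstot = float(np.sum((y - y.mean()) ** 2))
    selected: list[str] = []
    trace: list[tuple[str, str, float]] = []
    while True:
        changed = False
        # forward step: best candidate by entry p-value; skipped once the
        # model is numerically saturated (zero residual variance makes
        # partial-F probabilities meaningless)
        saturated = False
        if selected:
            fit_now = sm.OLS(y, sm.add_constant(X[selected].to_numpy(float), has_constant="add")).fit()
            saturated = fit_now.ssr <= 1e-10 * sstot
        best, best_p = None, np.inf
        for c in cols if not saturated else []:
            if c in selected:
                continue
            if len(selected) + 2 >= len(y):  # keep the model identifiable
                break
            pvals, _ = _ols_pvalues(y, X[selected + [c]])
            p = pvals[c]
            if np.isfinite(p) and p < best_p:
                best, best_p = c, p
        if best is not None and best_p <= entry_p:
            selected.append(best)
            trace.append(("add", best, float(best_p)))
            changed = True
        # backward steps: remove while the worst included p >= removal_p
        while len(selected) > 0:
            pvals, _ = _ols_pvalues(y, X[selected])
            pv = pvals.reindex(selected)
            if pv.isna().all():
                break
            worst = pv.idxmax()
            worst_p = pv.max()
            if np.isfinite(worst_p) and worst_p >= removal_p:
                selected.remove(worst)
                trace.append(("remove", worst, float(worst_p)))
                changed = True
            else:
                break
        if not changed:
            break

    if selected:
        design = sm.add_constant(X[selected].to_numpy(dtype=float), has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.OLS(y, design).fit()
        coefs = {"intercept": float(fit.params[0])}
        coefs.update({t: float(b) for t, b in zip(selected, fit.params[1:])})
        r2 = float(fit.rsquared)
    else:
        coefs = {"intercept": float(np.mean(y))}
        r2 = 0.0
    return StepwiseResult(selected, coefs, r2, entry_p, removal_p, trace)


def variance_explained_by_group(
    table: pd.DataFrame,
    y,
    groups: tuple[str, ...] = registry.YIELD_PREDICTOR_GROUPS,
    entry_p: float = DEFAULT_ENTRY_P,
    removal_p: float = DEFAULT_REMOVAL_P,
) -> pd.DataFrame:
    """Stepwise yield R^2 per trait group and for all groups pooled.

    Rows are one per group plus ``"pooled"``; columns report the R^2,
    the number of selected traits and their names. Plants with missing
    candidate values are dropped per group (complete-case).
    """
    recs = []
    pooled_cols: list[str] = []
    for g in groups:
        cols = [c for c in registry.traits_in_group(g) if c in table.columns]
        if not cols:
            raise ValueError(f"empty trait group {g!r}")
        pooled_cols.extend(cols)
        sub = table[cols].dropna()
        res = stepwise_regression(sub, pd.Series(y, index=table.index).loc[sub.index], entry_p, removal_p)
        recs.append({"group": g, "r2": res.r2, "n_selected": len(res.selected), "selected": ";".join(res.selected)})
    sub = table[pooled_cols].dropna()
    res = stepwise_regression(sub, pd.Series(y, index=table.index).loc[sub.index], entry_p, removal_p)
    recs.append({"group": "pooled", "r2": res.r2, "n_selected": len(res.selected), "selected": ";".join(res.selected)})
    return pd.DataFrame.from_records(recs).set_index("group")


# ---------------------------------------------------------------------------
# Mantel tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MantelResult:
    """Permutation Mantel correlation between two distance matrices."""

    r: float
    p: float
    n_perm: int
    partial: str | None = None


def euclidean_distance_matrix(data: pd.DataFrame | np.ndarray, standardize: bool = True) -> np.ndarray:
    """Pairwise Euclidean distances between sample rows.

    Columns are standardised first by default so that traits on large
    scales do not dominate the distances.
    """
    a = np.asarray(data, dtype=float)
    if standardize:
        sd = a.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        a = (a - a.mean(axis=0)) / sd
    from scipy.spatial.distance import pdist, squareform

    return squareform(pdist(a, metric="euclidean"))


def _check_distance_matrix(D: np.ndarray, name: str) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError(f"{name} must be a square matrix")
    if not np.allclose(D, D.T):
        raise ValueError(f"{name} is not symmetric")
    if not np.allclose(np.diag(D), 0.0):
        raise ValueError(f"{name} must have a zero diagonal")
    return D


def _lower(D: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(D.shape[0], k=-1)
    return D[i, j]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    return float(a @ b / denom) if denom > 0 else np.nan


def mantel_test(D1, D2, n_perm: int = DEFAULT_N_PERM, seed: int | None = 0) -> MantelResult:
    """Mantel correlation with an upper-tail permutation p-value.

    r is the Pearson correlation of the lower-triangle vectors; rows
    and columns of D2 are permuted jointly;
    p = (1 + #{r_perm >= r_obs}) / (n_perm + 1).
    """
    D1 = _check_distance_matrix(D1, "D1")
    D2 = _check_distance_matrix(D2, "D2")
    if D1.shape != D2.shape:
        raise ValueError("distance matrices differ in size")
    n = D1.shape[0]
    v1 = _lower(D1)
    r_obs = _pearson(v1, _lower(D2))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        rp = _pearson(v1, _lower(D2[np.ix_(p, p)]))
        if rp >= r_obs:
            count += 1
    return MantelResult(r=r_obs, p=(1 + count) / (n_perm + 1), n_perm=n_perm)


def partial_mantel(D1, D2, D3, n_perm: int = DEFAULT_N_PERM, seed: int | None = 0) -> MantelResult:
    """Partial Mantel: correlation of D1 and D2 controlling for D3.

    The lower-triangle vectors of D1 and D2 are each residualised on
    D3's vector; the permutation scheme permutes D2 jointly and
    re-residualises it each time.
    """
    D1 = _check_distance_matrix(D1, "D1")
    D2 = _check_distance_matrix(D2, "D2")
    D3 = _check_distance_matrix(D3, "D3")
    if not (D1.shape == D2.shape == D3.shape):
        raise ValueError("distance matrices differ in size")
    n = D1.shape[0]
    v3 = _lower(D3)

    def resid(v: np.ndarray) -> np.ndarray:
        A = np.column_stack([np.ones_like(v3), v3])
        beta, *_ = np.linalg.lstsq(A, v, rcond=None)
        return v - A @ beta

    r1 = resid(_lower(D1))
    r_obs = _pearson(r1, resid(_lower(D2)))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        rp = _pearson(r1, resid(_lower(D2[np.ix_(p, p)])))
        if rp >= r_obs:
            count += 1
    return MantelResult(r=r_obs, p=(1 + count) / (n_perm + 1), n_perm=n_perm, partial="D3")


def mantel_by_group(
    table: pd.DataFrame,
    groups: tuple[str, ...] = registry.YIELD_PREDICTOR_GROUPS,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Mantel correlation of the grain-trait distances with each group.

    Distance matrices are Euclidean on the standardised complete-case
    trait submatrices.
    """
    grain_cols = registry.traits_in_group("grain")
    out = []
    for i, g in enumerate(groups):
        cols = [c for c in registry.traits_in_group(g) if c in table.columns]
        sub = table[grain_cols + cols].dropna()
        Dg = euclidean_distance_matrix(sub[grain_cols])
        Dt = euclidean_distance_matrix(sub[cols])
        res = mantel_test(Dg, Dt, n_perm=n_perm, seed=None if seed is None else seed + i)
        out.append({"group": g, "r": res.r, "p": res.p, "n_perm": res.n_perm, "n_samples": len(sub)})
    return pd.DataFrame.from_records(out).set_index("group")


# ---------------------------------------------------------------------------
# Kruskal-Wallis and pairwise Wilcoxon
# ---------------------------------------------------------------------------

def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Rank-based omnibus test with tie correction; returns (H, p).

    All-tied data yield H = 0, p = 1 with a warning.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) < 2 for s in samples):
        small = [str(g) for g, s in zip(labels, samples) if len(s) < 2]
        raise ValueError(f"group(s) with fewer than 2 observations: {small}")
    if np.all(values == values[0]):
        warnings.warn("all values tied; Kruskal-Wallis H set to 0, p to 1", stacklevel=2)
        return 0.0, 1.0
    H, p = sps.kruskal(*samples)
    return float(H), float(p)


def pairwise_wilcoxon(values, groups, alpha: float = 0.05, adjust: str = "holm") -> pd.DataFrame:
    """Pairwise two-sided rank-sum tests, gated on the omnibus test.

    Runs only when the Kruskal-Wallis p-value is below ``alpha``
    (otherwise an empty table is returned). Reports unadjusted and
    Holm-adjusted p-values for every group pair.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    _, omni_p = kruskal_wallis(values, groups)
    cols = ["group1", "group2", "n1", "n2", "statistic", "p", "p_adjusted"]
    if omni_p >= alpha:
        return pd.DataFrame(columns=cols)
    labels = list(pd.unique(groups))
    recs = []
    for g1, g2 in combinations(labels, 2):
        a, b = values[groups == g1], values[groups == g2]
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        recs.append({"group1": g1, "group2": g2, "n1": len(a), "n2": len(b), "statistic": float(stat), "p": float(p)})
    df = pd.DataFrame.from_records(recs)
    from statsmodels.stats.multitest import multipletests

    df["p_adjusted"] = multipletests(df["p"].to_numpy(), method=adjust)[1]
    return df[cols]


# ---------------------------------------------------------------------------
# PCA on the trait correlation matrix
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Correlation-matrix PCA of a trait subset.

    Loadings columns are orthonormal eigenvectors of the correlation
    matrix; ``variance_fraction`` sums to 1 over all components; scores
    are the standardised data projected on the loadings. Component
    signs are fixed so each loading column's largest-magnitude entry is
    positive.
    """

    loadings: pd.DataFrame
    variance_fraction: np.ndarray
    scores: pd.DataFrame
    dimension_tag: str


def pca_traits(table: pd.DataFrame, dimension_tag: str = "Organ_PC", columns=None) -> PCAResult:
    """PCA of a registry trait subset via its correlation matrix.

    ``dimension_tag`` selects the 26 organ-dimension traits
    ("Organ_PC") or the 32 temporal-dimension traits ("Time_PC") unless
    ``columns`` overrides the subset. The input must be complete-case;
    constant columns are rejected by name.
    """
    if columns is None:
        if dimension_tag == "Organ_PC":
            columns = [c for c in registry.ORGAN_PC_TRAITS if c in table.columns]
        elif dimension_tag == "Time_PC":
            columns = [c for c in registry.TIME_PC_TRAITS if c in table.columns]
        else:
            raise ValueError("dimension_tag must be 'Organ_PC' or 'Time_PC' when columns is None")
    sub = table[list(columns)]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ValueError(f"missing values in {bad}; apply a complete-case filter first")
    if len(sub) < 3:
        raise ValueError("PCA needs at least 3 samples")
    X = sub.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    const = [c for c, s in zip(sub.columns, sd) if s == 0 or not np.isfinite(s)]
    if const:
        raise ValueError(f"constant (zero-variance) trait(s): {const}")
    Z = (X - X.mean(axis=0)) / sd
    corr = (Z.T @ Z) / (len(Z) - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    # deterministic sign: largest-magnitude loading positive per component
    for j in range(evecs.shape[1]):
        i = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    frac = evals / evals.sum()
    comp = [f"{dimension_tag}{i + 1}" for i in range(evecs.shape[1])]
    loadings = pd.DataFrame(evecs, index=list(sub.columns), columns=comp)
    scores = pd.DataFrame(Z @ evecs, index=sub.index, columns=comp)
    return PCAResult(loadings=loadings, variance_fraction=frac, scores=scores, dimension_tag=dimension_tag)
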