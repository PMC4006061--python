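"""Hypothesis tests for size, shape, and allometry.

Size differences are tested with two-way (group x sex) Type III ANOVA;
shape differences with MANOVA/MANCOVA on retained PC scores using
Wilks' lambda and Rao's F approximation (exact when the smaller of the
response/hypothesis dimensions is at most 2); pairwise group contrasts
with permutation tests on Procrustes distances between mean shapes (or
mean differences for size) under sequential-Bonferroni (Holm) control;
allometry by multivariate regression of shape on centroid size with a
permutation test; and group separation by linear discriminant analysis
with leave-one-out cross-validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .errors import DesignError
from .procrustes import ProcrustesFit, procrustes_distance


# ---------------------------------------------------------------------------
# result containers


@dataclass
class EffectTestResult:
    """One multivariate effect: Wilks' lambda with Rao's F approximation.

    ``eta_squared`` is the multivariate partial form 1 - lambda.
    """

    effect: str
    wilks_lambda: float
    f: float
    df1: float
    df2: float
    p: float
    eta_squared: float

    def to_dict(self) -> dict:
        return {
            "Effect": self.effect,
            "Wilks' Lambda": self.wilks_lambda,
            "F": self.f,
            "Hypothesis df": self.df1,
            "Error df": self.df2,
            "Sig.": self.p,
            "Eta Squared": self.eta_squared,
        }


@dataclass
class AnovaTable:
    """Type III ANOVA table (SS, df, MS, F, p per effect)."""

    table: pd.DataFrame

    def row(self, effect: str) -> dict:
        r = self.table.loc[effect]
        return {
            "ss": float(r["SS"]),
            "df": int(r["df"]),
            "ms": float(r["MS"]),
            "f": float(r["F"]) if np.isfinite(r["F"]) else math.nan,
            "p": float(r["p"]) if np.isfinite(r["p"]) else math.nan,
        }


@dataclass
class PairwiseTestMatrix:
    """All pairwise group contrasts with Holm-adjusted permutation p-values.

    ``pairs`` maps an (a, b) tuple to a dict with keys ``statistic``,
    ``percent_explained``, ``p_raw``, ``p_adjusted`` and ``significant``.
    """

    groups: list[str]
    pairs: dict[tuple[str, str], dict]
    statistic: str
    n_perm: int
    alpha: float

    def get(self, a: str, b: str) -> dict:
        return self.pairs[(a, b)] if (a, b) in self.pairs else self.pairs[(b, a)]

    def to_frame(self) -> pd.DataFrame:
        """Matrix layout: upper triangle percent explained, lower triangle p."""
        g = self.groups
        out = pd.DataFrame("-", index=g, columns=g, dtype=object)
        for (a, b), d in self.pairs.items():
            i, j = g.index(a), g.index(b)
            i, j = min(i, j), max(i, j)
            out.iloc[i, j] = f"{d['percent_explained']:.2f}%"
            out.iloc[j, i] = f"{d['p_adjusted']:.4f}"
        return out


@dataclass
class AllometryResult:
    """Multivariate regression of shape on centroid size."""

    percent_predicted: float
    p_permutation: float
    coefficients: np.ndarray  # shape change (tangent vector) per mm CS


@dataclass
class DiscriminantResult:
    """Linear discriminant analysis with leave-one-out cross-validation."""

    classes: list[str]
    confusion_resub: np.ndarray
    confusion_loo: np.ndarray
    accuracy_resub: float
    accuracy_loo: float
    wilks: EffectTestResult


# ---------------------------------------------------------------------------
# design-matrix helpers (sum-to-zero coding, Type III cross-products)


def _sum_code(labels: np.ndarray, levels: list) -> np.ndarray:
    """Sum-to-zero (deviation) coding: len(levels) - 1 columns."""
    n = len(labels)
    cols = np.zeros((n, len(levels) - 1))
    for j, lev in enumerate(levels[:-1]):
        cols[labels == lev, j] = 1.0
    cols[labels == levels[-1], :] = -1.0
    return cols


def _interaction(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.einsum("ni,nj->nij", a, b).reshape(len(a), -1)


def _wilks_from_design(
    Y: np.ndarray, X: np.ndarray, effect_cols: dict[str, list[int]]
) -> tuple[dict[str, float], int]:
    """Wilks' lambda per effect from Type III cross-product matrices.

    For each effect, H = (L B)' (L G L')^{-1} (L B) with G = (X'X)^{-1}
    and L selecting the effect's coefficient rows; E is the residual
    cross-product of the full model. Returns lambdas and the residual df.
    """
    n, _ = Y.shape
    XtX = X.T @ X
    rank = np.linalg.matrix_rank(XtX)
    if rank < X.shape[1]:
        raise DesignError("design matrix is rank deficient (empty cell?)")
    G = np.linalg.inv(XtX)
    B = G @ X.T @ Y
    resid = Y - X @ B
    E = resid.T @ resid
    sign, logdetE = np.linalg.slogdet(E)
    if sign <= 0:
        raise DesignError(
            "singular error matrix: reduce the number of response variables (PCs)"
        )
    lambdas = {}
    for name, cols in effect_cols.items():
        LB = B[cols]
        LGL = G[np.ix_(cols, cols)]
        H = LB.T @ np.linalg.solve(LGL, LB)
        sign2, logdetEH = np.linalg.slogdet(E + H)
        lambdas[name] = float(np.exp(logdetE - logdetEH)) if sign2 > 0 else 0.0
    return lambdas, n - X.shape[1]


# ---------------------------------------------------------------------------
# operations


def two_way_anova(values, group, sex, include_interaction: bool = True) -> AnovaTable:
    """Two-way Type III ANOVA of a scalar response on group x sex.

    Uses sum-to-zero contrasts, so with balanced data Type III sums of
    squares coincide with sequential (Type I) sums of squares.
    """
    y = np.asarray(values, dtype=float)[:, None]
    group = np.asarray(group)
    sex = np.asarray(sex)
    g_levels = sorted(set(group.tolist()))
    s_levels = sorted(set(sex.tolist()))
    if len(g_levels) < 2 or len(s_levels) < 2:
        raise DesignError("both factors need at least 2 levels")
    for gl in g_levels:
        for sl in s_levels:
            if include_interaction and not np.any((group == gl) & (sex == sl)):
                raise DesignError(f"empty cell ({gl}, {sl}) with interaction requested")
    Xg = _sum_code(group, g_levels)
    Xs = _sum_code(sex, s_levels)
    parts = [np.ones((len(y), 1)), Xg, Xs]
    effect_cols = {
        "groups": list(range(1, 1 + Xg.shape[1])),
        "sex": list(range(1 + Xg.shape[1], 1 + Xg.shape[1] + Xs.shape[1])),
    }
    if include_interaction:
        Xi = _interaction(Xg, Xs)
        start = 1 + Xg.shape[1] + Xs.shape[1]
        effect_cols["groups:sex"] = list(range(start, start + Xi.shape[1]))
        parts.append(Xi)
    X = np.hstack(parts)

    XtX = X.T @ X
    G = np.linalg.inv(XtX)
    B = G @ X.T @ y
    resid = y - X @ B
    ss_res = float((resid.T @ resid).item())
    df_res = len(y) - X.shape[1]

    ms_res = ss_res / df_res if df_res > 0 else math.nan
    rows = {}
    for name, cols in effect_cols.items():
        LB = B[cols]
        LGL = G[np.ix_(cols, cols)]
        ss = float((LB.T @ np.linalg.solve(LGL, LB)).item())
        df = len(cols)
        ms = ss / df
        f = ms / ms_res if ms_res and np.isfinite(ms_res) else math.nan
        p = stats.f.sf(f, df, df_res) if np.isfinite(f) else math.nan
        rows[name] = [ss, df, ms, f, p]
    rows["residual"] = [ss_res, df_res, ss_res / df_res, math.nan, math.nan]
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["SS", "df", "MS", "F", "p"]
    )
    return AnovaTable(table)


def rao_f(
    wilks_lambda: float, p_responses: int, q_hypothesis: int, df_residual: float
) -> tuple[float, float, float]:
    """Rao's F approximation for Wilks' lambda.

    With p response variables, q hypothesis degrees of freedom and
    residual df n_e, the statistic

        F = ((1 - L^(1/t)) / L^(1/t)) * (df2 / df1)

    with df1 = p q, t = sqrt((p^2 q^2 - 4) / (p^2 + q^2 - 5)) (t = 1 when
    p q <= 3 or the denominator is non-positive), w = n_e - (p - q + 1)/2
    and df2 = w t - p q / 2 + 1, follows an F(df1, df2) distribution
    approximately — exactly when min(p, q) <= 2.
    """
    p, q = p_responses, q_hypothesis
    if not (0 < wilks_lambda <= 1):
        raise ValueError(f"wilks_lambda must be in (0, 1], got {wilks_lambda}")
    if df_residual <= p:
        raise DesignError(
            f"residual df ({df_residual}) must exceed the response count ({p})"
        )
    denom = p * p + q * q - 5
    if p * q <= 3 or denom <= 0:
        t = 1.0
    else:
        t = math.sqrt((p * p * q * q - 4) / denom)
    df1 = float(p * q)
    w = df_residual - (p - q + 1) / 2
    df2 = w * t - p * q / 2 + 1
    lam_t = wilks_lambda ** (1 / t)
    f = ((1 - lam_t) / lam_t) * (df2 / df1)
    return f, df1, df2


def _effect_results(
    lambdas: dict[str, float], p_responses: int, effect_q: dict[str, int], df_residual: int
) -> list[EffectTestResult]:
    out = []
    for name, lam in lambdas.items():
        f, df1, df2 = rao_f(lam, p_responses, effect_q[name], df_residual)
        p_val = float(stats.f.sf(f, df1, df2))
        out.append(
            EffectTestResult(
                effect=name,
                wilks_lambda=lam,
                f=f,
                df1=df1,
                df2=df2,
                p=p_val,
                eta_squared=1.0 - lam,
            )
        )
    return out


def manova(scores, group, sex, include_interaction: bool = True) -> list[EffectTestResult]:
    """Two-way MANOVA of PC scores on group x sex (Wilks/Rao, Type III)."""
    Y = np.asarray(scores, dtype=float)
    group = np.asarray(group)
    sex = np.asarray(sex)
    g_levels = sorted(set(group.tolist()))
    s_levels = sorted(set(sex.tolist()))
    Xg = _sum_code(group, g_levels)
    Xs = _sum_code(sex, s_levels)
    parts = [np.ones((len(Y), 1)), Xg, Xs]
    effect_cols = {
        "groups": list(range(1, 1 + Xg.shape[1])),
        "sex": list(range(1 + Xg.shape[1], 1 + Xg.shape[1] + Xs.shape[1])),
    }
    effect_q = {"groups": Xg.shape[1], "sex": Xs.shape[1]}
    if include_interaction:
        Xi = _interaction(Xg, Xs)
        start = 1 + Xg.shape[1] + Xs.shape[1]
        effect_cols["groups:sex"] = list(range(start, start + Xi.shape[1]))
        effect_q["groups:sex"] = Xi.shape[1]
        parts.append(Xi)
    X = np.hstack(parts)
    lambdas, df_res = _wilks_from_design(Y, X, effect_cols)
    return _effect_results(lambdas, Y.shape[1], effect_q, df_res)


def mancova(
    scores, group, covariate_cs, include_interaction: bool = False
) -> list[EffectTestResult]:
    """MANCOVA of PC scores on groups with a centroid-size covariate.

    Without interaction the model is groups + CS (common slope); with
    interaction a per-group slope is fitted and the groups x CS effect
    tests slope homogeneity.
    """
    Y = np.asarray(scores, dtype=float)
    group = np.asarray(group)
    cs = np.asarray(covariate_cs, dtype=float)
    if np.ptp(cs) == 0:
        raise DesignError("covariate is constant")
    g_levels = sorted(set(group.tolist()))
    Xg = _sum_code(group, g_levels)
    csc = (cs - cs.mean())[:, None]
    parts = [np.ones((len(Y), 1)), Xg, csc]
    ncolg = Xg.shape[1]
    effect_cols = {
        "groups": list(range(1, 1 + ncolg)),
        "cs": [1 + ncolg],
    }
    effect_q = {"groups": ncolg, "cs": 1}
    if include_interaction:
        Xi = _interaction(Xg, csc)
        start = 2 + ncolg
        effect_cols["groups:cs"] = list(range(start, start + Xi.shape[1]))
        effect_q["groups:cs"] = Xi.shape[1]
        parts.append(Xi)
    X = np.hstack(parts)
    lambdas, df_res = _wilks_from_design(Y, X, effect_cols)
    return _effect_results(lambdas, Y.shape[1], effect_q, df_res)


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down (sequential Bonferroni) adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        val = min((m - rank) * p[idx], 1.0)
        running = max(running, val)
        adj[idx] = running
    return adj


def _pair_percent_explained(Y: np.ndarray, labels: np.ndarray, a, b) -> float:
    """Between-group SS / total SS on the two-group subsample (x100)."""
    rows = (labels == a) | (labels == b)
    Ysub = Y[rows]
    lsub = labels[rows]
    grand = Ysub.mean(axis=0)
    sst = float(np.sum((Ysub - grand) ** 2))
    ssb = 0.0
    for g in (a, b):
        sel = Ysub[lsub == g]
        ssb += len(sel) * float(np.sum((sel.mean(axis=0) - grand) ** 2))
    return 100.0 * ssb / sst if sst > 0 else 0.0


def pairwise_permutation_tests(
    fit_or_values,
    labels,
    statistic: str = "procrustes_distance",
    n_perm: int = 10000,
    seed: int = 0,
    alpha: float = 0.05,
    groups=None,
) -> PairwiseTestMatrix:
    """Permutation tests for all pairwise group contrasts.

    ``statistic="procrustes_distance"`` (shape): the Procrustes distance
    between the two group mean shapes, recomputed under label permutation
    within the pair subsample. ``statistic="mean_difference"`` (size):
    the absolute difference of group means of a scalar response.
    p = (number of permuted statistics >= observed + 1) / (n_perm + 1);
    Holm adjustment is applied across all pairs.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    labels = np.asarray(labels)
    if statistic == "procrustes_distance":
        if not isinstance(fit_or_values, ProcrustesFit):
            raise TypeError("shape statistic requires a ProcrustesFit")
        data = fit_or_values.aligned
        Yflat = data.reshape(len(data), -1)

        def stat(rows_a, rows_b):
            return procrustes_distance(data[rows_a].mean(axis=0), data[rows_b].mean(axis=0))

    elif statistic == "mean_difference":
        data = np.asarray(fit_or_values, dtype=float)
        Yflat = data[:, None]

        def stat(rows_a, rows_b):
            return abs(float(data[rows_a].mean() - data[rows_b].mean()))

    else:
        raise ValueError("statistic must be 'procrustes_distance' or 'mean_difference'")

    if groups is None:
        groups = sorted(set(labels.tolist()))
    rng = np.random.default_rng(seed)
    pairs: dict[tuple[str, str], dict] = {}
    for a, b in combinations(groups, 2):
        idx_a = np.nonzero(labels == a)[0]
        idx_b = np.nonzero(labels == b)[0]
        if len(idx_a) < 2 or len(idx_b) < 2:
            raise DesignError(f"pair ({a}, {b}): both groups need at least 2 specimens")
        observed = stat(idx_a, idx_b)
        pool = np.concatenate([idx_a, idx_b])
        na = len(idx_a)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pool)
            if stat(perm[:na], perm[na:]) >= observed:
                count += 1
        pairs[(a, b)] = {
            "statistic": observed,
            "percent_explained": _pair_percent_explained(Yflat, labels, a, b),
            "p_raw": (count + 1) / (n_perm + 1),
        }
    adj = holm_adjust([d["p_raw"] for d in pairs.values()])
    for d, pa in zip(pairs.values(), adj):
        d["p_adjusted"] = float(pa)
        d["significant"] = bool(pa <= alpha)
    return PairwiseTestMatrix(
        groups=list(groups), pairs=pairs, statistic=statistic, n_perm=n_perm, alpha=alpha
    )


def allometry_regression(
    tangent_coords, cs, n_perm: int = 10000, seed: int = 0
) -> AllometryResult:
    """Multivariate regression of shape on centroid size (allometry).

    ``percent_predicted`` is the share of total shape variance captured
    by the fitted regression; the permutation p-value shuffles CS against
    shapes and counts permuted shares >= observed.
    """
    Y = np.asarray(tangent_coords, dtype=float)
    x = np.asarray(cs, dtype=float)
    if len(Y) < 4:
        raise DesignError("allometry regression needs at least 4 specimens")
    if np.ptp(x) == 0:
        raise DesignError("centroid size is constant")
    Yc = Y - Y.mean(axis=0)
    sst = float(np.sum(Yc**2))

    def percent(xv: np.ndarray) -> tuple[float, np.ndarray]:
        xc = xv - xv.mean()
        sxx = float(xc @ xc)
        beta = (xc @ Yc) / sxx
        ss_pred = sxx * float(beta @ beta)
        return (100.0 * ss_pred / sst if sst > 0 else 0.0), beta

    observed, beta = percent(x)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        val, _ = percent(rng.permutation(x))
        if val >= observed:
            count += 1
    return AllometryResult(
        percent_predicted=observed,
        p_permutation=(count + 1) / (n_perm + 1),
        coefficients=beta,
    )


def size_correct(tangent_coords, cs, groups) -> np.ndarray:
    """Remove the pooled within-group allometric component from shapes.

    A common slope is estimated from within-group covariances of shape
    with CS (so group mean differences do not leak into the slope), and
    each shape is corrected to the grand-mean CS:
    ``Y_i - b (cs_i - mean(cs))``. Group differences are preserved except
    for the part attributable to CS differences along the allometric
    vector; within groups the corrected shapes have no CS-predictable
    variance.
    """
    Y = np.asarray(tangent_coords, dtype=float)
    x = np.asarray(cs, dtype=float)
    groups = np.asarray(groups)
    sxx = 0.0
    sxy = np.zeros(Y.shape[1])
    for g in set(groups.tolist()):
        rows = groups == g
        xc = x[rows] - x[rows].mean()
        Yc = Y[rows] - Y[rows].mean(axis=0)
        sxx += float(xc @ xc)
        sxy += xc @ Yc
    if sxx == 0:
        raise DesignError("centroid size is constant within every group")
    b = sxy / sxx
    return Y - np.outer(x - x.mean(), b)


def lda_crossval(scores, labels, priors: str = "equal") -> DiscriminantResult:
    """Linear discriminant analysis with leave-one-out cross-validation.

    Fits an LDA with pooled within-group covariance, reports the
    resubstitution and leave-one-out confusion matrices (each fold refits
    without the held-out specimen) and the Wilks' lambda test of group
    separation with Rao's F degrees of freedom.
    """
    Y = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    g = len(classes)
    n, p = Y.shape
    if g < 2:
        raise DesignError("discriminant analysis needs at least 2 groups")
    if n - g <= p:
        raise DesignError(
            f"pooled covariance singular: n - groups = {n - g} must exceed p = {p}; "
            "use fewer PCs"
        )
    prior_vec = np.full(g, 1.0 / g) if priors == "equal" else None

    def fit_predict(train_idx, test_idx):
        lda = LinearDiscriminantAnalysis(solver="svd", priors=prior_vec)
        lda.fit(Y[train_idx], labels[train_idx])
        return lda.predict(Y[test_idx])

    all_idx = np.arange(n)
    pred_resub = fit_predict(all_idx, all_idx)
    pred_loo = np.empty(n, dtype=labels.dtype)
    for i in range(n):
        train = np.delete(all_idx, i)
        pred_loo[i] = fit_predict(train, [i])[0]

    def confusion(pred):
        M = np.zeros((g, g), dtype=int)
        for true, hat in zip(labels, pred):
            M[classes.index(true), classes.index(hat)] += 1
        return M

    conf_r = confusion(pred_resub)
    conf_l = confusion(pred_loo)

    # Wilks test of group separation (one-way MANOVA)
    grand = Y.mean(axis=0)
    E = np.zeros((p, p))
    H = np.zeros((p, p))
    for c in classes:
        sub = Y[labels == c]
        m = sub.mean(axis=0)
        E += (sub - m).T @ (sub - m)
        H += len(sub) * np.outer(m - grand, m - grand)
    sign, logdetE = np.linalg.slogdet(E)
    sign2, logdetEH = np.linalg.slogdet(E + H)
    lam = float(np.exp(logdetE - logdetEH))
    f, df1, df2 = rao_f(lam, p, g - 1, n - g)
    wilks = EffectTestResult(
        effect="groups",
        wilks_lambda=lam,
        f=f,
        df1=df1,
        df2=df2,
        p=float(stats.f.sf(f, df1, df2)),
        eta_squared=1.0 - lam,
    )
    return DiscriminantResult(
        classes=classes,
        confusion_resub=conf_r,
        confusion_loo=conf_l,
        accuracy_resub=float(np.trace(conf_r)) / n,
        accuracy_loo=float(np.trace(conf_l)) / n,
        wilks=wilks,
    )
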