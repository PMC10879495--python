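"""Statistical layer: mixed models, sequential testing, summaries.

**Mixed model.** ``sqrt_nss ~ group * category + (1 | subject) +
(1 | category)`` — fixed effects for the group-by-category interaction
with treatment coding (reference: HC, congruent), crossed random
intercepts for subject and image category, fitted by REML.  With two
variance components the covariance is ``V = sigma^2 I + tau_s Z_s Z_s' +
tau_c Z_c Z_c'``; profiling the residual variance and the fixed effects
leaves a two-parameter REML criterion in the variance ratios, evaluated in
O(q^3) per step via the Woodbury identity after a single pass of
cross-product precomputation (q = subjects + categories).  Fixed-effect
tests use Satterthwaite-approximated denominator degrees of freedom:
``df = 2 f^2 / (g' A g)`` where ``f = Var(c'beta)``, ``g`` its gradient in
the variance parameters and ``A`` the inverse observed information of the
REML likelihood (both by central finite differences).

**Sequential closed testing.** Per-fixation-index two-sample t-tests on
per-subject mean durations, in ascending index order; index ``k`` is
*declared* significant iff tests 1..k all rejected at ``alpha``.  Because
any declaration requires the first test to reject, the familywise error
under the global null is the level of a single test, i.e. controlled at
``alpha``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

__all__ = [
    "LMEResult", "SequentialTestResult", "fit_lme", "sequential_duration_test",
    "two_sample_summary_test", "correlate_clinical",
]


# ---------------------------------------------------------------------------
# Crossed-intercept REML
# ---------------------------------------------------------------------------


class _Blocks(NamedTuple):
    """Sufficient cross-products for the Woodbury evaluation."""

    XtX: np.ndarray
    XtZ: np.ndarray
    ZtZ: np.ndarray
    Xty: np.ndarray
    Zty: np.ndarray
    yty: float
    n: int
    p: int
    sizes: tuple[int, ...]  # columns of Z per random factor


def _indicator(codes: np.ndarray, n_levels: int) -> np.ndarray:
    Z = np.zeros((codes.size, n_levels))
    Z[np.arange(codes.size), codes] = 1.0
    return Z


def _precompute(X: np.ndarray, Zs: Sequence[np.ndarray], y: np.ndarray) -> _Blocks:
    Z = np.hstack(Zs)
    return _Blocks(
        XtX=X.T @ X, XtZ=X.T @ Z, ZtZ=Z.T @ Z,
        Xty=X.T @ y, Zty=Z.T @ y, yty=float(y @ y),
        n=X.shape[0], p=X.shape[1], sizes=tuple(z.shape[1] for z in Zs))


def _woodbury_pieces(b: _Blocks, lams: Sequence[float]):
    """Return (XtVX, XtVy, ytVy, logdetS) for V0 = I + Z diag(lam) Z'."""
    lam_cols = np.concatenate([np.full(sz, lam) for sz, lam in zip(b.sizes, lams)])
    sq = np.sqrt(lam_cols)
    S = np.eye(len(sq)) + sq[:, None] * b.ZtZ * sq[None, :]
    cho = linalg.cho_factor(S, lower=True)
    logdetS = 2.0 * float(np.log(np.diag(cho[0])).sum())
    Ux = b.XtZ * sq[None, :]
    uy = sq * b.Zty
    SinvUxT = linalg.cho_solve(cho, Ux.T)
    Sinvuy = linalg.cho_solve(cho, uy)
    XtVX = b.XtX - Ux @ SinvUxT
    XtVy = b.Xty - Ux @ Sinvuy
    ytVy = b.yty - float(uy @ Sinvuy)
    return XtVX, XtVy, ytVy, logdetS


def _profiled_fit(b: _Blocks, lams: Sequence[float]):
    XtVX, XtVy, ytVy, logdetS = _woodbury_pieces(b, lams)
    beta = linalg.solve(XtVX, XtVy, assume_a="pos")
    rss = max(ytVy - float(XtVy @ beta), 1e-300)
    sign, logdetXtVX = np.linalg.slogdet(XtVX)
    crit = (b.n - b.p) * math.log(rss) + logdetS + logdetXtVX
    return crit, beta, rss, XtVX


def _reml_loglik(b: _Blocks, theta: np.ndarray, active: np.ndarray) -> float:
    """Unprofiled REML log-likelihood in theta = (sigma2, tau_active...)."""
    sigma2 = theta[0]
    if sigma2 <= 0 or np.any(theta[1:] < 0):
        return -np.inf
    taus = np.zeros(len(active))
    taus[active] = theta[1:]
    lams = taus / sigma2
    XtVX, XtVy, ytVy, logdetS = _woodbury_pieces(b, lams)
    beta = linalg.solve(XtVX, XtVy, assume_a="pos")
    rss = ytVy - float(XtVy @ beta)
    _, logdetXtVX = np.linalg.slogdet(XtVX)
    return -0.5 * ((b.n - b.p) * math.log(sigma2) + logdetS + logdetXtVX
                   + rss / sigma2)


def _satterthwaite(b: _Blocks, sigma2: float, taus: np.ndarray,
                   boundary_tol: float) -> np.ndarray:
    """Per-coefficient Satterthwaite df at the REML estimate."""
    active = taus > boundary_tol
    theta = np.concatenate([[sigma2], taus[active]])
    m = len(theta)

    def var_beta(th: np.ndarray) -> np.ndarray:
        t = np.zeros(len(taus))
        t[active] = th[1:]
        XtVX, _, _, _ = _woodbury_pieces(b, t / th[0])
        return th[0] * np.diag(linalg.inv(XtVX))

    steps = np.maximum(np.abs(theta) * 1e-4, 1e-12)

    # gradient of Var(beta_j) w.r.t. theta, all coefficients at once
    grads = np.zeros((m, b.p))
    for i in range(m):
        up, dn = theta.copy(), theta.copy()
        up[i] += steps[i]
        dn[i] = max(dn[i] - steps[i], 1e-300)
        grads[i] = (var_beta(up) - var_beta(dn)) / (up[i] - dn[i])

    # observed information of the REML likelihood
    H = np.zeros((m, m))
    f0 = _reml_loglik(b, theta, active)
    for i in range(m):
        for j in range(i, m):
            ei = np.zeros(m); ei[i] = steps[i]
            ej = np.zeros(m); ej[j] = steps[j]
            if i == j:
                fpp = _reml_loglik(b, theta + ei, active)
                fmm = _reml_loglik(b, theta - ei, active)
                H[i, i] = (fpp - 2 * f0 + fmm) / steps[i] ** 2
            else:
                fpp = _reml_loglik(b, theta + ei + ej, active)
                fpm = _reml_loglik(b, theta + ei - ej, active)
                fmp = _reml_loglik(b, theta - ei + ej, active)
                fmm = _reml_loglik(b, theta - ei - ej, active)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    try:
        A = linalg.inv(-H)
    except linalg.LinAlgError:
        A = linalg.pinv(-H)

    f = var_beta(theta)
    df = np.empty(b.p)
    for j in range(b.p):
        g = grads[:, j]
        denom = float(g @ A @ g)
        df[j] = 2.0 * f[j] ** 2 / denom if denom > 0 else b.n - b.p
    return np.clip(df, 1.0, b.n - b.p)


@dataclass
class LMEResult:
    """REML fit of the crossed-random-intercept model."""

    fixed_effects: pd.DataFrame
    variance_components: dict[str, float]
    icc: float
    r2_marginal: float
    r2_conditional: float
    n_obs: int
    n_levels: dict[str, int]
    singular: bool
    converged: bool
    optimizer: dict = field(default_factory=dict)


def _design(table: pd.DataFrame, response: str, group_col: str, category_col: str,
            subject_col: str, group_ref: str, category_ref: str):
    t = table.dropna(subset=[response]).reset_index(drop=True)
    groups = sorted(t[group_col].unique(), key=lambda g: (g != group_ref, g))
    cats = sorted(t[category_col].unique(), key=lambda c: (c != category_ref, c))
    if groups[0] != group_ref or cats[0] != category_ref:
        raise ValueError("reference level absent from the data")
    if len(groups) < 2 or len(cats) < 2:
        raise ValueError("need >= 2 groups and >= 2 categories")
    y = t[response].to_numpy(dtype=float)
    n = len(t)
    g_dummy = (t[group_col] == groups[1]).to_numpy(dtype=float)
    cols = [np.ones(n), g_dummy]
    names = ["(Intercept)", groups[1]]
    for c in cats[1:]:
        d = (t[category_col] == c).to_numpy(dtype=float)
        cols.append(d)
        names.append(c)
    for c in cats[1:]:
        d = (t[category_col] == c).to_numpy(dtype=float)
        cols.append(g_dummy * d)
        names.append(f"{groups[1]} x {c}")
    X = np.column_stack(cols)
    subj_codes, subj_levels = pd.factorize(t[subject_col], sort=True)
    cat_codes, cat_levels = pd.factorize(t[category_col], sort=True)
    Zs = _indicator(subj_codes, len(subj_levels))
    Zc = _indicator(cat_codes, len(cat_levels))
    return t, y, X, names, Zs, Zc, len(subj_levels), len(cat_levels)


def fit_lme(table: pd.DataFrame, response: str = "sqrt_nss",
            group_col: str = "group", category_col: str = "category",
            subject_col: str = "subject_id", group_ref: str = "HC",
            category_ref: str = "congruent", ci_level: float = 0.95) -> LMEResult:
    """Fit ``response ~ group * category + (1|subject) + (1|category)`` by REML.

    Returns term-level estimates with Satterthwaite t-tests and confidence
    intervals, variance components, ICC and marginal/conditional R^2.  A
    variance component estimated at (numerically) zero flags the fit as
    singular; this is reported, not raised.
    """
    t, y, X, names, Zs, Zc, n_subj, n_cat = _design(
        table, response, group_col, category_col, subject_col, group_ref, category_ref)
    if t.groupby(group_col)[subject_col].nunique().min() < 2:
        raise ValueError("need >= 2 subjects per group")
    b = _precompute(X, [Zs, Zc], y)

    # A random factor whose indicator columns lie inside the fixed-effect
    # column space (e.g. a category intercept alongside category fixed
    # effects) leaves the REML criterion exactly flat in its variance: the
    # component is unidentified and is pinned at zero, mirroring the
    # conventional "tau00 = 0" report of mixed-model software.
    identified = []
    for Zf in (Zs, Zc):
        coef, *_ = np.linalg.lstsq(X, Zf, rcond=None)
        resid = Zf - X @ coef
        identified.append(np.linalg.norm(resid) > 1e-8 * np.linalg.norm(Zf))
    identified = np.asarray(identified)
    n_free = int(identified.sum())

    def objective(s: np.ndarray) -> float:
        lams = np.zeros(2)
        lams[identified] = np.exp(np.clip(s, -30.0, 10.0))
        try:
            return _profiled_fit(b, lams)[0]
        except linalg.LinAlgError:
            return np.inf

    best = None
    starts = ([[-2.0] * n_free, [0.0] + [-4.0] * (n_free - 1), [-6.0] * n_free]
              if n_free else [[]])
    for x0 in starts:
        if n_free == 0:
            best = optimize.OptimizeResult(x=np.array([]), fun=objective(np.array([])),
                                           success=True, nfev=1)
            break
        res = optimize.minimize(objective, x0, method="Nelder-Mead",
                                options=dict(xatol=1e-8, fatol=1e-10, maxfev=4000))
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"REML optimization failed: {best}")
    lams = np.zeros(2)
    lams[identified] = np.exp(np.clip(best.x, -30.0, 10.0))
    lams = np.where(lams < 1e-10, 0.0, lams)
    crit, beta, rss, XtVX = _profiled_fit(b, lams)
    sigma2 = rss / (b.n - b.p)
    taus = lams * sigma2
    total_var = sigma2 + taus.sum()
    singular = bool(np.any(taus / total_var < 1e-6))

    df = _satterthwaite(b, sigma2, taus, boundary_tol=1e-8 * total_var)
    se = np.sqrt(sigma2 * np.diag(linalg.inv(XtVX)))
    tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    tcrit = stats.t.ppf(0.5 + ci_level / 2.0, df)
    fixed = pd.DataFrame({
        "term": names, "estimate": beta, "se": se, "df": df, "t": tstat,
        "ci_low": beta - tcrit * se, "ci_high": beta + tcrit * se, "p": pvals,
    })

    var_fixed = float(np.var(X @ beta))
    denom = var_fixed + taus.sum() + sigma2
    result = LMEResult(
        fixed_effects=fixed,
        variance_components={"residual": sigma2, "subject": taus[0], "category": taus[1]},
        icc=float(taus.sum() / (taus.sum() + sigma2)),
        r2_marginal=var_fixed / denom,
        r2_conditional=(var_fixed + taus.sum()) / denom,
        n_obs=b.n,
        n_levels={"subject": n_subj, "category": n_cat},
        singular=singular,
        converged=bool(best.success),
        optimizer=dict(criterion=crit, n_eval=int(best.nfev),
                       log_lambda=list(np.asarray(best.x, dtype=float)),
                       unidentified=[name for name, ok in
                                     zip(("subject", "category"), identified) if not ok]),
    )
    return result


# ---------------------------------------------------------------------------
# Sequential closed testing
# ---------------------------------------------------------------------------


@dataclass
class SequentialTestResult:
    """Closed sequential t-tests of group duration differences by index.

    ``declared_significant`` at index k requires *all* tests 1..k to have
    rejected; it is therefore non-increasing and the familywise error under
    the global null equals the single-test level.
    """

    per_index: pd.DataFrame
    stop_index: int | None
    alpha: float
    groups: tuple[str, str]

    @property
    def any_declared(self) -> bool:
        return bool(self.per_index["declared_significant"].any())


def sequential_duration_test(means: pd.DataFrame, alpha: float = 0.05,
                             groups: tuple[str, str] = ("HC", "SCHZ"),
                             equal_var: bool = False,
                             value_col: str = "mean_duration_ms"
                             ) -> SequentialTestResult:
    """Run the closed sequential procedure on per-subject index means.

    ``means`` is tidy: group, subject_id, fix_index, ``value_col`` (one row
    per subject per index).  Tests run in ascending index order; the tested
    range ends at the first index where either group has fewer than two
    subjects.  ``t`` is ``mean(groups[0]) - mean(groups[1])`` (Welch by
    default).
    """
    g1, g2 = groups
    rows = []
    declared = True
    stop_index = None
    for k in sorted(means["fix_index"].unique()):
        sub = means[means["fix_index"] == k]
        a = sub.loc[sub["group"] == g1, value_col].to_numpy(dtype=float)
        b = sub.loc[sub["group"] == g2, value_col].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            break  # end of the testable range
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        rejected = bool(res.pvalue < alpha)
        declared = declared and rejected
        if not rejected and stop_index is None:
            stop_index = int(k)
        rows.append((int(k), len(a), len(b), float(res.statistic),
                     float(res.pvalue), rejected, declared))
    per_index = pd.DataFrame(
        rows, columns=["fix_index", "n1", "n2", "t_stat", "p",
                       "rejected", "declared_significant"])
    return SequentialTestResult(per_index, stop_index, alpha, groups)


# ---------------------------------------------------------------------------
# Simple summaries
# ---------------------------------------------------------------------------


class TwoSampleResult(NamedTuple):
    t_stat: float
    df: float
    p: float


def two_sample_summary_test(values_by_group: Mapping[str, Sequence[float]]
                            | tuple[Sequence[float], Sequence[float]]
                            ) -> TwoSampleResult:
    """Welch two-sample t-test on per-subject summary values.

    Degrees of freedom follow Welch-Satterthwaite.  Raises when both
    groups are constant (the statistic is undefined).
    """
    if isinstance(values_by_group, Mapping):
        items = list(values_by_group.values())
    else:
        items = list(values_by_group)
    if len(items) != 2:
        raise ValueError("exactly two groups required")
    a = np.asarray(items[0], dtype=float)
    b = np.asarray(items[1], dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return TwoSampleResult(0.0, float(len(a) + len(b) - 2), 1.0)
        raise ValueError("zero variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=False)
    return TwoSampleResult(float(res.statistic), float(res.df), float(res.pvalue))


def correlate_clinical(oculomotor: pd.DataFrame, clinical: pd.DataFrame,
                       alpha: float = 0.001,
                       metrics: Sequence[str] | None = None,
                       clinical_vars: Sequence[str] | None = None,
                       by_group: bool = True) -> pd.DataFrame:
    """Pearson correlations between oculomotor metrics and clinical variables.

    Missing clinical values are pairwise-deleted (and counted); cells with
    fewer than three complete pairs, or a constant column, are reported as
    unavailable rather than raising.  ``alpha`` flags significance (a
    conservative level absorbs the many comparisons).
    """
    merged = oculomotor.merge(clinical, on="subject_id", how="inner",
                              suffixes=("", "_clin"))
    if metrics is None:
        metrics = [c for c in ("mean_fix_count_per_image", "mean_fix_duration_ms",
                               "sdd_px") if c in merged.columns]
    if clinical_vars is None:
        clinical_vars = [c for c in clinical.columns
                         if c != "subject_id"
                         and pd.api.types.is_numeric_dtype(clinical[c])]
    group_iter = (merged.groupby("group", observed=True)
                  if by_group and "group" in merged.columns
                  else [("all", merged)])
    rows = []
    for gname, sub in group_iter:
        for metric in metrics:
            for var in clinical_vars:
                pair = sub[[metric, var]].apply(pd.to_numeric, errors="coerce")
                n_missing = int(pair.isna().any(axis=1).sum())
                pair = pair.dropna()
                n = len(pair)
                if n < 3 or pair[metric].std() == 0 or pair[var].std() == 0:
                    rows.append((gname, metric, var, n, n_missing,
                                 np.nan, np.nan, False, False))
                    continue
                r, p = stats.pearsonr(pair[metric], pair[var])
                rows.append((gname, metric, var, n, n_missing,
                             float(r), float(p), bool(p < alpha), True))
    return pd.DataFrame(rows, columns=[
        "group", "metric", "clinical_var", "n", "n_missing", "r", "p",
        "significant", "available"])
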