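"""Group-level inference: t tests, effect-size CIs, mixed ANCOVA.

The centerpiece is :func:`mixed_ancova`, a mixed repeated-measures analysis
of covariance for split-plot designs: within-subject factors (e.g. Emotion
Type, Intensity bin), categorical between-subject factors (Age group,
Gender) and continuous covariates (trait anxiety).  It follows the
classical univariate approach computed through the multivariate layout:

1. Responses are arranged subject × within-cell (Y, n × p) and the
   between-subject design matrix X is built with effects-coded categorical
   factors and centered covariates, giving Type III sums of squares.
2. Each within-subject effect corresponds to an orthonormal contrast
   matrix C (p × c); for every between term with coefficient rows L the
   hypothesis and error cross-product matrices are
   H = (L B C)' [L (X'X)⁻¹ L']⁻¹ (L B C)  and  E = C' Y' (I − P_X) Y C,
   and the univariate F uses tr(H) and tr(E) with degrees of freedom
   multiplied by c.
3. Sphericity: for within effects with c ≥ 2 a Greenhouse–Geisser epsilon
   ε = tr(Σ)² / (c · tr(Σ²)) with Σ = E/df_error is estimated and applied
   to the degrees of freedom, by default only when Mauchly's test rejects
   sphericity at α = .05.
4. Effect sizes are partial η² = SS_eff / (SS_eff + SS_err) with
   confidence intervals from inverting the noncentral F distribution for
   the noncentrality parameter.

t tests report Cohen's d (pooled-SD for independent groups, d_z = mean
difference / SD of differences for paired and one-sample contrasts) with
CIs by noncentral-t inversion.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult", "welch_t", "paired_t", "one_sample_t",
    "cohens_d_ci", "eta_sq_ci", "mixed_ancova",
]


@dataclass
class TestResult:
    """A single statistical test: statistic, df, p, effect size with CI."""

    statistic: float
    df: float
    p: float
    effect_size: float
    effect_name: str
    effect_ci: tuple[float, float]
    ci_level: float
    n: tuple[int, ...]
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# noncentral-distribution confidence intervals

def _invert_ncp(cdf, target: float, lo: float, hi: float) -> float:
    """Solve cdf(ncp) = target for the noncentrality parameter.

    ``cdf`` must be nonincreasing in the noncentrality; the bracket is
    expanded outward until it straddles the target.
    """
    for _ in range(200):
        if cdf(lo) >= target >= cdf(hi):
            break
        if cdf(lo) < target:
            lo -= 2 * max(abs(lo), 1.0)
        if cdf(hi) > target:
            hi += 2 * max(abs(hi), 1.0)
    return float(optimize.brentq(lambda nc: cdf(nc) - target, lo, hi, xtol=1e-10))


def _nct_cdf(t: float, df: float, nc: float) -> float:
    value = stats.nct.cdf(t, df, nc)
    if np.isnan(value):  # scipy underflows at extreme noncentralities
        # Satterthwaite-style normal approximation, monotone in nc
        z = (t * (1 - 1 / (4 * df)) - nc) / np.sqrt(1 + t * t / (2 * df))
        value = stats.norm.cdf(z)
    return float(value)


def _ncp_ci_t(t: float, df: float, level: float) -> tuple[float, float]:
    alpha = 1.0 - level / 100.0
    cdf = lambda nc: _nct_cdf(t, df, nc)
    lo = _invert_ncp(cdf, 1.0 - alpha / 2.0, t - 1.0, t)
    hi = _invert_ncp(cdf, alpha / 2.0, t, t + 1.0)
    return lo, hi


def _ncp_ci_f(F: float, df1: float, df2: float, level: float) -> tuple[float, float]:
    alpha = 1.0 - level / 100.0
    cdf = lambda nc: stats.ncf.cdf(F, df1, df2, nc) if nc > 0 else stats.f.cdf(F, df1, df2)
    lo = 0.0 if cdf(0.0) < 1.0 - alpha / 2.0 else _invert_ncp(cdf, 1.0 - alpha / 2.0, 0.0, 1.0)
    hi = 0.0 if cdf(0.0) < alpha / 2.0 else _invert_ncp(cdf, alpha / 2.0, max(lo, 0.0), lo + 1.0)
    return lo, hi


def cohens_d_ci(d: float, n_a: int, n_b: int | None = None,
                level: float = 95.0) -> tuple[float, float]:
    """CI for Cohen's d by noncentral-t inversion.

    Two-sample (pooled-SD d) when ``n_b`` is given; one-sample / paired d_z
    when it is None.
    """
    if not 0 < level < 100:
        raise ValueError("level must be in (0, 100)")
    if n_b is None:
        scale, df = np.sqrt(n_a), n_a - 1
    else:
        scale, df = np.sqrt(n_a * n_b / (n_a + n_b)), n_a + n_b - 2
    lo, hi = _ncp_ci_t(d * scale, df, level)
    return lo / scale, hi / scale


def eta_sq_ci(F: float, df_num: float, df_den: float,
              level: float = 90.0) -> tuple[float, float]:
    """CI for partial η² by noncentral-F inversion.

    The noncentrality bounds λ are mapped to the effect-size scale via
    η² = λ / (λ + df_num + df_den + 1).
    """
    if not np.isfinite(F) or not np.isfinite(df_num) or not np.isfinite(df_den):
        raise ValueError("F and degrees of freedom must be finite")
    lo, hi = _ncp_ci_f(F, df_num, df_den, level)
    to_eta = lambda lam: lam / (lam + df_num + df_den + 1.0)
    return to_eta(lo), to_eta(hi)


# ---------------------------------------------------------------------------
# t tests

def welch_t(group_a, group_b, *, ci_level: float = 95.0) -> TestResult:
    """Unequal-variance two-sample t test with Satterthwaite df.

    Effect size is pooled-SD Cohen's d with a noncentral-t CI.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("zero variance in both groups")
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    sp = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    d = (a.mean() - b.mean()) / sp
    return TestResult(float(t), float(df), float(p), float(d), "cohen_d",
                      cohens_d_ci(d, na, nb, ci_level), ci_level, (na, nb))


def one_sample_t(values, mu0: float = 0.0, *, ci_level: float = 95.0) -> TestResult:
    """One-sample t test against ``mu0``; effect size d_z with CI."""
    x = np.asarray(values, float)
    n = len(x)
    if n < 2:
        raise ValueError("need n >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    d = (x.mean() - mu0) / sd
    t = d * np.sqrt(n)
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return TestResult(float(t), float(n - 1), float(p), float(d), "cohen_dz",
                      cohens_d_ci(d, n, None, ci_level), ci_level, (n,))


def paired_t(values_a, values_b, *, ci_level: float = 95.0) -> TestResult:
    """Paired t test on a − b; primary effect size d_z, pooled d in extras."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    res = one_sample_t(a - b, 0.0, ci_level=ci_level)
    sp = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    res.extra["cohen_d_pooled"] = float((a.mean() - b.mean()) / sp) if sp > 0 else np.nan
    return res


# ---------------------------------------------------------------------------
# mixed repeated-measures ANCOVA

def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k × (k−1) Helmert-style orthonormal contrast matrix (⊥ to ones)."""
    C = np.zeros((k, k - 1))
    for j in range(k - 1):
        C[: j + 1, j] = 1.0
        C[j + 1, j] = -(j + 1.0)
        C[:, j] /= np.linalg.norm(C[:, j])
    return C


def _effects_code(series: pd.Series) -> tuple[np.ndarray, list]:
    """Sum-to-zero (effects) coding; last level carries −1 rows."""
    levels = list(pd.unique(series))
    if len(levels) < 2:
        raise ValueError(f"between factor {series.name!r} needs >= 2 levels")
    k = len(levels)
    codes = pd.Categorical(series, categories=levels).codes
    X = np.zeros((len(series), k - 1))
    for j in range(k - 1):
        X[codes == j, j] = 1.0
        X[codes == k - 1, j] = -1.0
    return X, levels


def _gg_epsilon(sigma: np.ndarray) -> float:
    c = sigma.shape[0]
    return float(np.trace(sigma) ** 2 / (c * np.trace(sigma @ sigma)))


def _mauchly_p(sigma: np.ndarray, df_error: int) -> float:
    """Mauchly's sphericity test on the contrast-space covariance."""
    c = sigma.shape[0]
    if c < 2:
        return np.nan
    eig = np.linalg.eigvalsh(sigma)
    if np.any(eig <= 0):
        return 0.0
    W = np.prod(eig) / (np.mean(eig) ** c)
    chi2 = -(df_error - (2 * c ** 2 + c + 2) / (6.0 * c)) * np.log(W)
    return float(stats.chi2.sf(chi2, c * (c + 1) // 2 - 1))


def _subject_table(data: pd.DataFrame, subject: str, cols: list[str]) -> pd.DataFrame:
    sub = data[[subject] + cols].drop_duplicates()
    if sub[subject].duplicated().any():
        bad = sub.loc[sub[subject].duplicated(), subject].iloc[0]
        raise ValueError(f"subject {bad!r} has inconsistent between-subject values")
    return sub.set_index(subject)


def mixed_ancova(data: pd.DataFrame, dv: str, subject: str,
                 within: list[str] | tuple[str, ...] = (),
                 between: list[str] | tuple[str, ...] = (),
                 covariates: list[str] | tuple[str, ...] = (),
                 *, gg: str = "mauchly", sphericity_alpha: float = 0.05,
                 ci_level: float = 90.0) -> pd.DataFrame:
    """Mixed repeated-measures ANCOVA with Type III sums of squares.

    Parameters
    ----------
    data
        Long-format table, one row per subject × within-cell.
    dv, subject
        Column names of the response and the subject identifier.
    within, between, covariates
        Within-subject factors, categorical between-subject factors, and
        continuous covariates (centered internally).
    gg
        Greenhouse–Geisser policy for within effects with ≥ 2 contrast
        dimensions (i.e. ≥ 3 within cells): ``"mauchly"`` applies the
        correction when Mauchly's test rejects at ``sphericity_alpha``,
        ``"always"`` applies it unconditionally, ``"never"`` disables it.
    ci_level
        Confidence level (percent) for the partial η² intervals.

    Returns
    -------
    DataFrame with one row per effect: F, df_num, df_den, p, partial_eta_sq
    and its CI, gg_epsilon, mauchly_p and whether the correction was
    applied.  Missing or duplicated cells raise; nothing is imputed.
    """
    if gg not in ("mauchly", "always", "never"):
        raise ValueError("gg must be 'mauchly', 'always' or 'never'")
    within, between, covariates = list(within), list(between), list(covariates)

    # --- response matrix (n subjects × p within cells)
    if within:
        try:
            wide = data.pivot(index=subject, columns=within, values=dv)
        except ValueError as err:
            raise ValueError(f"duplicate subject × within-cell rows: {err}") from err
        levels = [list(pd.unique(data[w])) for w in within]
        full_cols = (pd.MultiIndex.from_product(levels, names=within)
                     if len(within) > 1 else pd.Index(levels[0], name=within[0]))
        wide = wide.reindex(columns=full_cols)
    else:
        wide = data.set_index(subject)[[dv]]
        if wide.index.duplicated().any():
            raise ValueError("duplicate rows per subject with no within factor")
        levels = []
    if wide.isna().any().any():
        raise ValueError("missing within-subject cells; complete data required")
    Y = wide.to_numpy(float)
    n, p = Y.shape

    # --- between-subject design matrix, Type III via effects coding
    info = _subject_table(data, subject, between + covariates).loc[wide.index]
    X_parts = [np.ones((n, 1))]
    terms: list[tuple[str, slice]] = []
    col = 1
    for b in between:
        Xb, _ = _effects_code(info[b])
        X_parts.append(Xb)
        terms.append((b, slice(col, col + Xb.shape[1])))
        col += Xb.shape[1]
    for cv in covariates:
        x = pd.to_numeric(info[cv], errors="raise").to_numpy(float)
        if x.std() == 0:
            logger.warning("covariate %r is constant; dropped from the model", cv)
            continue
        X_parts.append((x - x.mean())[:, None])
        terms.append((cv, slice(col, col + 1)))
        col += 1
    X = np.hstack(X_parts)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("collinear between-subject design (rank-deficient)")
    df_error = n - rank
    if df_error < 1:
        raise ValueError("no error degrees of freedom")

    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y
    resid = Y - X @ B

    # --- within-effect contrast sets (empty subset = between-subject tests)
    k_levels = [len(lv) for lv in levels]
    contrasts = [_orthonormal_contrasts(k) for k in k_levels]
    units = [np.ones((k, 1)) / np.sqrt(k) for k in k_levels]

    def kron_chain(mats):
        out = np.ones((1, 1))
        for m in mats:
            out = np.kron(out, m)
        return out

    rows = []
    for r in range(len(within) + 1):
        for subset in itertools.combinations(range(len(within)), r):
            C = kron_chain([contrasts[i] if i in subset else units[i]
                            for i in range(len(within))])
            c = C.shape[1]
            E = C.T @ resid.T @ resid @ C
            ss_err = float(np.trace(E))
            sigma = E / df_error
            eps = _gg_epsilon(sigma) if c >= 2 else np.nan
            w_p = _mauchly_p(sigma, df_error) if c >= 2 else np.nan
            apply_gg = (c >= 2 and gg != "never"
                        and (gg == "always" or (np.isfinite(w_p) and w_p < sphericity_alpha)))
            within_name = " × ".join(within[i] for i in subset)

            for term, sl in ([("Intercept", slice(0, 1))] if subset else []) + terms:
                L = np.eye(X.shape[1])[sl]
                a = L.shape[0]
                LB = L @ B @ C
                H = LB.T @ np.linalg.inv(L @ XtX_inv @ L.T) @ LB
                ss_eff = float(np.trace(H))
                df1, df2 = a * c, df_error * c
                ms_ratio = (ss_eff / df1) / (ss_err / df2)
                adj = eps if apply_gg else 1.0
                p_val = float(stats.f.sf(ms_ratio, df1 * adj, df2 * adj))
                eta = ss_eff / (ss_eff + ss_err)
                ci = eta_sq_ci(ms_ratio, df1 * adj, df2 * adj, ci_level)
                name = (within_name if term == "Intercept"
                        else f"{term} × {within_name}" if within_name else term)
                rows.append({
                    "effect": name, "F": float(ms_ratio),
                    "df_num": df1 * adj, "df_den": df2 * adj, "p": p_val,
                    "ss_effect": ss_eff, "ss_error": ss_err,
                    "partial_eta_sq": float(eta),
                    "eta_ci_low": ci[0], "eta_ci_high": ci[1],
                    "ci_level": ci_level,
                    "gg_epsilon": eps, "mauchly_p": w_p,
                    "sphericity_corrected": bool(apply_gg),
                })
    return pd.DataFrame(rows)
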