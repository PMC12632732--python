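"""Inferential layer: split-plot repeated-measures ANOVA with
Greenhouse-Geisser correction, Bonferroni pairwise comparisons, pooled
Cohen's d, and summary-statistic t-tests.

The ANOVA follows the classical univariate split-plot decomposition as
implemented by the major statistical packages: subject cell means are
projected onto orthonormal within-subject contrasts, a multivariate
linear model is fit against the (effect-coded) between-subjects design,
and each within effect is tested with the averaged-F statistic whose
error stratum is the subject-by-effect interaction. Effect coding plus
the generalized-inverse hypothesis matrices yields Type III sums of
squares for the between factor under unequal group sizes.

Greenhouse-Geisser epsilon for an effect with c orthonormal contrasts is

    eps = tr(Sigma)^2 / (c * tr(Sigma @ Sigma)),  1/c <= eps <= 1,

where Sigma is the contrast-projected error covariance; the corrected p
comes from F(eps*df1, eps*df2). Epsilon is identically 1 for two-level
factors. Mauchly's sphericity test is reported alongside as the flag
for when the correction matters.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats as sps

MPH_TO_MPS = 0.44704  # exact: 1609.344 m per mile / 3600 s


# ---------------------------------------------------------------------------
# small summary-statistic tools


def cv_percent(values) -> float:
    """Coefficient of variation, sample SD (n-1) / mean x 100."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two values")
    mean = arr.mean()
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float(arr.std(ddof=1) / mean * 100.0)


def cohens_d_pooled(m1, s1, n1, m2, s2, n2) -> float:
    """Cohen's d with the pooled (n-1 weighted) standard deviation."""
    if min(n1, n2) < 2:
        raise ValueError("need n >= 2 per group")
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be non-negative")
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    if sp2 <= 0:
        raise ValueError("zero pooled standard deviation")
    return float((m1 - m2) / np.sqrt(sp2))


def ttest_from_summary(m1, s1, n1, m2, s2, n2) -> tuple[float, int, float]:
    """Pooled-variance Student t-test from group summaries.

    Returns (t, df, two-tailed p) with df = n1 + n2 - 2.
    """
    if min(n1, n2) < 2:
        raise ValueError("need n >= 2 per group")
    df = int(n1 + n2 - 2)
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    if sp2 <= 0:
        raise ValueError("zero pooled variance")
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = (m1 - m2) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), df, float(p)


def mph_to_mps(speed_mph: float) -> float:
    """Miles per hour to metres per second."""
    return float(speed_mph) * MPH_TO_MPS


def partial_eta_sq(f: float, df1: float, df2: float) -> float:
    """Partial eta squared from an F statistic: F*df1 / (F*df1 + df2)."""
    return float(f * df1 / (f * df1 + df2))


# ---------------------------------------------------------------------------
# split-plot repeated-measures ANOVA


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k, k-1) orthonormal basis of the contrast space (orthogonal to 1)."""
    base = np.column_stack([np.ones(k) / np.sqrt(k), np.eye(k)[:, : k - 1]])
    q, _ = np.linalg.qr(base)
    return q[:, 1:]


def _effect_code_groups(groups: pd.Series, levels: list) -> np.ndarray:
    """Effect (deviation) coding: g-1 columns, last level coded -1."""
    n, g = len(groups), len(levels)
    x = np.zeros((n, g - 1))
    for j, lev in enumerate(levels[:-1]):
        x[:, j] = (groups == lev).astype(float)
    x[(groups == levels[-1]).to_numpy()] = -1.0
    return x


def _mauchly(sigma: np.ndarray, df_err: int) -> tuple[float, float]:
    c = sigma.shape[0]
    if c < 2:
        return 1.0, 1.0
    tr = np.trace(sigma)
    if tr <= 0:
        return float("nan"), float("nan")
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return 0.0, 0.0
    log_w = logdet - c * np.log(tr / c)
    f = 1.0 - (2.0 * c**2 + c + 2.0) / (6.0 * c * df_err)
    chi2 = -f * df_err * log_w
    df_m = c * (c + 1) // 2 - 1
    return float(np.exp(log_w)), float(sps.chi2.sf(chi2, df_m))


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: str | list[str],
    subject: str,
    between: str | None = None,
) -> pd.DataFrame:
    """Split-plot (mixed) repeated-measures ANOVA.

    Parameters
    ----------
    data : long table, one value per subject x within-cell
    dv : value column
    within : one or two within-subject factor columns
    subject : subject identifier column
    between : optional between-subjects factor (e.g. diagnostic group)

    Returns a table with one row per effect: F, uncorrected (df1, df2),
    Greenhouse-Geisser epsilon, uncorrected and GG-corrected p, partial
    eta squared, and Mauchly's W and p for the effect's error stratum.
    The within design must be complete for every subject; group sizes
    may differ (the between effect is then Type III).
    """
    within = [within] if isinstance(within, str) else list(within)
    if not 1 <= len(within) <= 2:
        raise ValueError("one or two within factors supported")

    dup = data.groupby([subject, *within], sort=True).size()
    if (dup > 1).any():
        raise ValueError("more than one value per subject x cell")
    wide = data.pivot_table(index=subject, columns=within, values=dv, sort=True)
    if wide.isna().any().any():
        raise ValueError("incomplete within design (missing cells)")
    subjects = wide.index
    n = len(subjects)
    y = wide.to_numpy()

    # within-factor level counts in the pivot's (sorted, first factor
    # slowest) cell order
    if len(within) == 1:
        k_levels = [wide.columns.size]
    else:
        k_levels = [len(lv) for lv in wide.columns.levels]
        if int(np.prod(k_levels)) != wide.columns.size:
            raise ValueError("within design is not fully crossed")
    p_cells = y.shape[1]

    # between-subjects design (effect coded)
    if between is not None:
        grp = data.groupby(subject, sort=True)[between].agg(
            lambda s: s.unique()[0] if s.nunique() == 1 else np.nan
        )
        grp = grp.loc[subjects]
        if grp.isna().any():
            raise ValueError("subjects must belong to exactly one group")
        g_levels = sorted(grp.unique())
        if min((grp == lev).sum() for lev in g_levels) < 2:
            raise ValueError("need at least two subjects per group")
        x = np.column_stack([np.ones(n), _effect_code_groups(grp, g_levels)])
    else:
        g_levels = []
        x = np.ones((n, 1))
    q = x.shape[1]
    if n <= q:
        raise ValueError("not enough subjects for the between design")
    xtx = x.T @ x
    xtx_inv = np.linalg.inv(xtx)

    contrasts = [_orthonormal_contrasts(k) for k in k_levels]
    means = [np.ones(k)[:, None] / np.sqrt(k) for k in k_levels]

    def _kron(mats):
        out = mats[0]
        for m in mats[1:]:
            out = np.kron(out, m)
        return out

    def _test(u: np.ndarray, l_rows: np.ndarray) -> dict:
        b = xtx_inv @ x.T @ u
        sscp_err = u.T @ u - b.T @ xtx @ b
        df_err = n - q
        lb = l_rows @ b
        middle = np.linalg.inv(l_rows @ xtx_inv @ l_rows.T)
        h = lb.T @ middle @ lb
        c = u.shape[1]
        r = l_rows.shape[0]
        df1, df2 = c * r, c * df_err
        ss_h, ss_e = float(np.trace(h)), float(np.trace(sscp_err))
        f = (ss_h / df1) / (ss_e / df2)
        sigma = sscp_err / df_err
        if c > 1:
            tr2 = float(np.trace(sigma)) ** 2
            eps = tr2 / (c * float(np.trace(sigma @ sigma)))
            eps = min(1.0, max(eps, 1.0 / c))
        else:
            eps = 1.0
        w, w_p = _mauchly(sigma, df_err)
        return {
            "F": f,
            "df1": df1,
            "df2": df2,
            "gg_epsilon": eps,
            "p_uncorrected": float(sps.f.sf(f, df1, df2)),
            "p_gg": float(sps.f.sf(f, eps * df1, eps * df2)),
            "partial_eta_sq": partial_eta_sq(f, df1, df2),
            "mauchly_w": w,
            "mauchly_p": w_p,
            "ss_effect": ss_h,
            "ss_error": ss_e,
        }

    l_int = np.eye(q)[[0]]
    l_grp = np.eye(q)[1:] if between is not None else None
    rows = []

    if between is not None:
        u0 = y @ _kron(means)
        rows.append({"effect": between, **_test(u0, l_grp)})

    for n_fac in (1, 2):
        for combo in itertools.combinations(range(len(within)), n_fac):
            if n_fac > len(within):
                continue
            mats = [contrasts[i] if i in combo else means[i]
                    for i in range(len(within))]
            u = y @ _kron(mats)
            name = " * ".join(within[i] for i in combo)
            rows.append({"effect": name, **_test(u, l_int)})
            if between is not None:
                rows.append({"effect": f"{name} * {between}", **_test(u, l_grp)})

    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pairwise comparisons


def pairwise_bonferroni(
    data: pd.DataFrame,
    dv: str,
    factor: str,
    subject: str,
    paired: bool | None = None,
) -> pd.DataFrame:
    """All pairwise level comparisons with Bonferroni correction.

    Paired t-tests when each subject contributes to multiple levels
    (within factor), independent pooled-variance t otherwise; set
    ``paired`` to override the inference. Corrected p = raw p x number
    of pairs, capped at 1. Effect size is pooled-SD Cohen's d.
    """
    levels = sorted(data[factor].unique())
    if len(levels) < 2:
        raise ValueError("factor needs at least two levels")
    cell = data.groupby([subject, factor], sort=True)[dv].mean().unstack(factor)
    if paired is None:
        paired = cell.notna().sum(axis=1).gt(1).any()

    pairs = list(itertools.combinations(levels, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        if paired:
            sub = cell[[a, b]].dropna()
            va, vb = sub[a].to_numpy(), sub[b].to_numpy()
            if len(va) < 2:
                raise ValueError(f"not enough paired subjects for {a} vs {b}")
            diff = va - vb
            sd = diff.std(ddof=1)
            if sd == 0:
                t, p, df = 0.0, 1.0, len(diff) - 1
            else:
                t, p = sps.ttest_rel(va, vb)
                df = len(diff) - 1
        else:
            va = cell[a].dropna().to_numpy()
            vb = cell[b].dropna().to_numpy()
            t, p = sps.ttest_ind(va, vb, equal_var=True)
            df = len(va) + len(vb) - 2
            if np.isnan(t):
                t, p = 0.0, 1.0
        try:
            d = cohens_d_pooled(va.mean(), va.std(ddof=1), len(va),
                                vb.mean(), vb.std(ddof=1), len(vb))
        except ValueError:  # zero pooled SD: no spread, no standardized effect
            d = 0.0
        rows.append({
            "level_a": a, "level_b": b,
            "mean_a": float(va.mean()), "mean_b": float(vb.mean()),
            "mean_diff": float(va.mean() - vb.mean()),
            "t": float(t), "df": int(df),
            "p_raw": float(p), "p_bonferroni": float(min(1.0, p * m)),
            "cohens_d": d, "n_comparisons": m, "paired": paired,
        })
    return pd.DataFrame(rows)
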