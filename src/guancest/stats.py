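"""Statistical layer: two-sided Student's t-test, Kendall's tau-b with tie
handling, ANCOVA of region signal on severity adjusted for age and sex, and
descriptive summaries.

Conventions follow the clinical-neuroimaging reporting style this pipeline
reproduces: pooled-variance Student's t (Welch available as an option), no
multiple-comparison correction in the primary outputs (regions are
pre-selected; an optional Benjamini-Hochberg column can be added to result
tables but never gates anything), sex coded F=0 / M=1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


@dataclass
class TTestResult:
    t_stat: float
    df: float
    p_two_sided: float
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int


@dataclass
class KendallResult:
    tau_b: float
    p_value: float
    n: int
    concordant: int
    discordant: int
    ties_x: int        # pairs tied in x only
    ties_y: int        # pairs tied in y only
    ties_xy: int       # pairs tied in both


@dataclass
class AncovaResult:
    """OLS of y on [1, severity, age, sex].  ``params`` etc. are indexed by
    ("intercept", "severity", "age", "sex")."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    n: int
    df_resid: int

    def fitted_line(self, sex: str, severity: np.ndarray, fixed_age: float) -> np.ndarray:
        """Fitted mean response along a severity grid at a fixed age; the two
        sex lines differ by exactly the sex coefficient."""
        s = {"F": 0.0, "M": 1.0}[sex]
        sev = np.asarray(severity, dtype=float)
        return (self.params["intercept"] + self.params["severity"] * sev
                + self.params["age"] * fixed_age + self.params["sex"] * s)


def two_sample_ttest(a, b, welch: bool = False) -> TTestResult:
    """Two-sided two-sample t-test (pooled-variance Student by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    if welch:
        se2 = va / na + vb / nb
        if se2 == 0:
            t, df, p = (0.0, na + nb - 2, 1.0) if ma == mb else (math.inf, na + nb - 2, 0.0)
        else:
            t = (ma - mb) / math.sqrt(se2)
            df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
            p = 2.0 * sps.t.sf(abs(t), df)
    else:
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        if sp2 == 0:
            t, p = (0.0, 1.0) if ma == mb else (math.inf, 0.0)
        else:
            t = (ma - mb) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
            p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(float(t), float(df), float(p), float(ma),
                       float(math.sqrt(va)), int(na), float(mb),
                       float(math.sqrt(vb)), int(nb))


def _pair_counts(x: np.ndarray, y: np.ndarray, chunk: int = 512) -> tuple:
    """Concordant/discordant/tie pair counts over all n(n-1)/2 pairs,
    chunked O(n^2) — exact, fine up to a few thousand points."""
    n = x.size
    C = D = tx = ty = txy = 0
    for i0 in range(0, n, chunk):
        xi = x[i0:i0 + chunk, None]
        yi = y[i0:i0 + chunk, None]
        # pairs (i, j) with j > i
        dx = np.sign(x[None, :] - xi)
        dy = np.sign(y[None, :] - yi)
        iu = np.triu(np.ones_like(dx, dtype=bool), k=i0 + 1)[:, :n]
        s = dx * dy
        C += int(((s > 0) & iu).sum())
        D += int(((s < 0) & iu).sum())
        txy += int(((dx == 0) & (dy == 0) & iu).sum())
        tx += int(((dx == 0) & (dy != 0) & iu).sum())
        ty += int(((dy == 0) & (dx != 0) & iu).sum())
    return C, D, tx, ty, txy


def kendall_tau_b(x, y, exact_max_n: int = 10) -> KendallResult:
    """Kendall's tau-b by explicit pair counting with tie corrections.

    tau_b = (C - D) / sqrt((n0 - n1)(n0 - n2)) with n0 = n(n-1)/2 and
    n1/n2 the tied-pair counts in x/y.  The p-value uses the tie-adjusted
    normal approximation of the S = C - D statistic; for small untied
    samples (n <= exact_max_n) the exact null distribution is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("a variable with all ties has no rank correlation")

    C, D, tx, ty, txy = _pair_counts(x, y)
    n0 = n * (n - 1) // 2
    n1 = tx + txy
    n2 = ty + txy
    tau_b = (C - D) / math.sqrt((n0 - n1) * (n0 - n2))

    has_ties = (n1 + n2) > 0
    if not has_ties and n <= exact_max_n:
        # exact null distribution of tau for untied data
        p = float(sps.kendalltau(x, y, method="exact").pvalue)
    else:
        _, cnt_x = np.unique(x, return_counts=True)
        _, cnt_y = np.unique(y, return_counts=True)

        def v(cnts, f):
            return float(sum(f(int(t)) for t in cnts))

        v0 = n * (n - 1) * (2 * n + 5)
        vt = v(cnt_x, lambda t: t * (t - 1) * (2 * t + 5))
        vu = v(cnt_y, lambda t: t * (t - 1) * (2 * t + 5))
        v1 = (v(cnt_x, lambda t: t * (t - 1)) * v(cnt_y, lambda t: t * (t - 1))
              / (2.0 * n * (n - 1)))
        v2 = (v(cnt_x, lambda t: t * (t - 1) * (t - 2))
              * v(cnt_y, lambda t: t * (t - 1) * (t - 2))
              / (9.0 * n * (n - 1) * (n - 2)))
        var_s = (v0 - vt - vu) / 18.0 + v1 + v2
        z = (C - D) / math.sqrt(var_s) if var_s > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
    return KendallResult(float(tau_b), float(p), int(n), C, D, tx, ty, txy)


def ancova_fit(y, severity, age, sex) -> AncovaResult:
    """OLS of the region value on severity, age and sex (F=0, M=1).

    Per-coefficient two-sided p-values come from the t distribution with
    n - 4 degrees of freedom; the design must be full rank.
    """
    y = np.asarray(y, dtype=float)
    sev = np.asarray(severity, dtype=float)
    age = np.asarray(age, dtype=float)
    sex = np.asarray([{"F": 0.0, "M": 1.0}.get(s, s) for s in sex], dtype=float)
    n = y.size
    if not (sev.size == age.size == sex.size == n):
        raise ValueError("all inputs must be equally long")
    if n <= 4:
        raise ValueError("need n > 4 for a 4-parameter model")
    X = np.column_stack([np.ones(n), sev, age, sex])
    if np.linalg.matrix_rank(X) < 4:
        raise ValueError("rank-deficient design (e.g. single-sex cohort)")
    names = ["intercept", "severity", "age", "sex"]
    fit = sm.OLS(y, pd.DataFrame(X, columns=names)).fit()
    return AncovaResult(params=fit.params, bse=fit.bse, pvalues=fit.pvalues,
                        n=int(n), df_resid=int(fit.df_resid))


def descriptive_summary(values, kind: str = "mean_sd") -> str:
    """'mean_sd' -> "m ± s" (sample SD); 'median_range' -> "med (min;max)"."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")

    def fmt(u):
        return f"{u:.2f}".rstrip("0").rstrip(".")

    if kind == "mean_sd":
        if v.size == 1:
            import warnings
            warnings.warn("single value: SD reported as 0")
            return f"{fmt(v[0])} ± 0"
        return f"{fmt(v.mean())} ± {fmt(v.std(ddof=1))}"
    if kind == "median_range":
        return f"{fmt(np.median(v))} ({fmt(v.min())};{fmt(v.max())})"
    raise ValueError("kind must be 'mean_sd' or 'median_range'")
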