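"""Goodness-of-fit, validation, genotype-comparison, and trait-yield stats.

AIC/BIC use the standard SSE-based forms n*ln(SSE/n)+2p and
n*ln(SSE/n)+p*ln(n).  PRESS uses the leave-one-out closed form
e_i/(1-h_ii) when a linear design matrix is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "FitMetrics",
    "ValidationStats",
    "TukeyGrouping",
    "YieldFit",
    "error_percent",
    "fit_metrics",
    "validation_stats",
    "pearson_r",
    "paired_t_test",
    "anova_tukey",
    "fit_yield_cubic",
]


@dataclass(frozen=True)
class FitMetrics:
    n: int
    p: int
    r2: float
    rmse: float
    press: float
    aic: float
    bic: float
    ase: float


@dataclass(frozen=True)
class ValidationStats:
    mean_error: float
    sd_error: float
    r2: float


@dataclass(frozen=True)
class TukeyGrouping:
    groups: tuple[str, ...]
    means: tuple[float, ...]
    letters: tuple[str, ...]
    alpha: float = 0.05

    def as_dict(self) -> dict[str, tuple[float, str]]:
        return {
            g: (m, l) for g, m, l in zip(self.groups, self.means, self.letters)
        }


@dataclass(frozen=True)
class YieldFit:
    coefficients: tuple[float, float, float, float]  # intercept, x, x^2, x^3
    r2: float
    model_p: float

    @property
    def significant(self) -> bool:
        return self.model_p < 0.05


def error_percent(manual: float, estimated: float) -> float:
    """Signed percentage error, 100*(manual - estimated)/manual."""
    if manual == 0:
        raise ZeroDivisionError("manual trait value is zero")
    return 100.0 * (manual - estimated) / manual


def fit_metrics(observed, predicted, p: int, design=None) -> FitMetrics:
    """R2, RMSE, PRESS, AIC, BIC, ASE for a fitted model with p parameters.

    ``design`` is the n x p model matrix (including the intercept column);
    when given, PRESS is computed from the closed-form leave-one-out
    residuals of the OLS fit of observed on that design.  Without it, PRESS
    is NaN.
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("observed and predicted must have equal length")
    n = len(y)
    if n <= p:
        raise ValueError(f"n={n} must exceed parameter count p={p}")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("observed values have zero variance")
    sse = float(np.sum((y - yhat) ** 2))
    press = float("nan")
    if design is not None:
        X = np.asarray(design, dtype=float)
        if X.shape[0] != n:
            raise ValueError("design matrix row count mismatch")
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        # hat diagonal via pinv: h_ii = x_i (X'X)^-1 x_i'
        xtx_inv = np.linalg.pinv(X.T @ X)
        h = np.einsum("ij,jk,ik->i", X, xtx_inv, X)
        press = float(np.sum((resid / (1.0 - h)) ** 2))
    return FitMetrics(
        n=n,
        p=p,
        r2=1.0 - sse / sst,
        rmse=float(np.sqrt(sse / (n - p))),
        press=press,
        aic=float(n * np.log(sse / n) + 2 * p) if sse > 0 else float("-inf"),
        bic=float(n * np.log(sse / n) + p * np.log(n)) if sse > 0 else float("-inf"),
        ase=sse / n,
    )


def validation_stats(observed, predicted) -> ValidationStats:
    """Mean and SD of (predicted - observed), and R2 as squared correlation.

    With zero error variance the correlation is undefined; R2 is reported
    as 1.0 when predictions match observations up to a constant shift.
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("observed and predicted must have equal length")
    if len(y) < 3:
        raise ValueError("need at least 3 pairs")
    err = yhat - y
    sd = float(np.std(err, ddof=1))
    if np.std(y) == 0 or np.std(yhat) == 0:
        r2 = float("nan")
    elif sd == 0:
        r2 = 1.0
    else:
        r2 = float(stats.pearsonr(y, yhat).statistic ** 2)
    return ValidationStats(mean_error=float(err.mean()), sd_error=sd, r2=r2)


def pearson_r(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need equal-length samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance sample")
    return float(stats.pearsonr(x, y).statistic)


def paired_t_test(a, b) -> tuple[float, float]:
    """Two-sided paired t test; returns (t, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need equal-length samples with n >= 2")
    if np.std(a - b) == 0:
        raise ValueError("differences have zero variance")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def _compact_letter_display(
    groups: list[str], not_different: set[frozenset[str]]
) -> dict[str, str]:
    """Insert-absorb compact letter display from pairwise non-significance."""
    letter_sets: list[set[str]] = []
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1 :]:
            if frozenset((g1, g2)) in not_different:
                if not any(g1 in s and g2 in s for s in letter_sets):
                    letter_sets.append({g1, g2})
    # each group needs at least one letter
    for g in groups:
        if not any(g in s for s in letter_sets):
            letter_sets.append({g})
    # absorb: grow sets with members that are non-different from everyone in it
    changed = True
    while changed:
        changed = False
        for s in letter_sets:
            for g in groups:
                if g not in s and all(
                    frozenset((g, m)) in not_different for m in s
                ):
                    s.add(g)
                    changed = True
    # drop sets fully contained in another
    letter_sets = [
        s
        for i, s in enumerate(letter_sets)
        if not any(s < t for j, t in enumerate(letter_sets) if i != j)
    ]
    # dedupe while preserving order
    seen: list[set[str]] = []
    for s in letter_sets:
        if s not in seen:
            seen.append(s)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, s in zip(alphabet, seen):
        for g in groups:
            if g in s:
                out[g] += letter
    return out


def anova_tukey(
    values_by_group: dict[str, "np.ndarray | list[float]"], alpha: float = 0.05
) -> tuple[float, float, TukeyGrouping]:
    """One-way ANOVA plus Tukey-Kramer comparisons with letter groups."""
    groups = list(values_by_group)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    samples = [np.asarray(values_by_group[g], dtype=float) for g in groups]
    for g, s in zip(groups, samples):
        if len(s) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    f_stat, p_val = stats.f_oneway(*samples)
    tk = stats.tukey_hsd(*samples)
    not_different: set[frozenset[str]] = set()
    for i, g1 in enumerate(groups):
        for j, g2 in enumerate(groups):
            if i < j and tk.pvalue[i, j] >= alpha:
                not_different.add(frozenset((g1, g2)))
    letters = _compact_letter_display(groups, not_different)
    grouping = TukeyGrouping(
        groups=tuple(groups),
        means=tuple(float(s.mean()) for s in samples),
        letters=tuple(letters[g] for g in groups),
        alpha=alpha,
    )
    return float(f_stat), float(p_val), grouping


def fit_yield_cubic(trait_values, yields) -> YieldFit:
    """OLS cubic polynomial of yield on a trait, with overall model F test."""
    x = np.asarray(trait_values, dtype=float)
    y = np.asarray(yields, dtype=float)
    if len(x) != len(y) or len(x) < 5:
        raise ValueError("need at least 5 paired points")
    if np.ptp(x) == 0:
        raise ValueError("constant trait: degenerate design")
    X = np.column_stack([np.ones_like(x), x, x**2, x**3])
    if np.linalg.matrix_rank(X) < 4:
        raise np.linalg.LinAlgError("rank-deficient cubic design")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    yhat = X @ coef
    sse = float(np.sum((y - yhat) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    n = len(y)
    df_model, df_resid = 3, n - 4
    if df_resid <= 0 or sse == 0:
        model_p = 0.0 if sst > 0 else 1.0
    elif sst == sse:
        model_p = 1.0
    else:
        f_stat = ((sst - sse) / df_model) / (sse / df_resid)
        model_p = float(stats.f.sf(f_stat, df_model, df_resid))
    return YieldFit(
        coefficients=tuple(float(c) for c in coef), r2=max(r2, 0.0), model_p=model_p
    )
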