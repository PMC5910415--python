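"""Model selection and group statistics for fitted diffusivities.

The four kinetic models are compared with the Akaike information
criterion. Because the fit minimises a plain sum of squared differences
(SSD), the default criterion uses the Gaussian-likelihood form

    AIC = n·ln(SSD/n) + 2k,

which ranks models identically to least-squares maximum likelihood and is
comparable across data sets. ``mode="as_printed"`` instead evaluates
AIC = 2k + 2·SSD, treating the SSD itself as the negative log-likelihood
(a published shorthand; it is dimensionful, so use it only within one
data set). AICc adds the small-sample correction 2k(k+1)/(n−k−1) and is
selected automatically when n/k ≤ 40.

Group comparisons of estimated diffusion coefficients wrap the standard
scipy tests (Student/Welch t, Mann–Whitney U, Wilcoxon signed-rank) with
a Shapiro–Wilk normality gate reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import FRAPFitResult

__all__ = [
    "aic",
    "aicc",
    "choose_criterion",
    "ModelComparison",
    "select_model",
    "r_squared",
    "compare_groups",
    "normality",
]


def aic(ssd: float, k: int, n: int | None = None, mode: str = "gaussian") -> float:
    """Akaike information criterion from a least-squares fit."""
    if ssd < 0:
        raise ValueError("SSD must be non-negative")
    if mode == "as_printed":
        return 2.0 * k + 2.0 * ssd
    if mode == "gaussian":
        if n is None or n <= 0:
            raise ValueError("gaussian AIC needs the data-point count n")
        return n * np.log(max(ssd, 1e-300) / n) + 2.0 * k
    raise ValueError(f"unknown AIC mode {mode!r}")


def aicc(ssd: float, k: int, n: int, mode: str = "gaussian") -> float:
    """Corrected AIC for small samples: AIC + 2k(k+1)/(n−k−1)."""
    if n <= k + 1:
        raise ValueError("AICc requires n > k + 1")
    return aic(ssd, k, n, mode=mode) + 2.0 * k * (k + 1) / (n - k - 1)


def choose_criterion(n: int, k: int) -> str:
    """Rule of thumb: plain AIC iff n/k > 40, else the corrected AICc."""
    if k <= 0:
        raise ValueError("k must be positive")
    return "AIC" if n / k > 40 else "AICc"


@dataclass
class ModelComparison:
    table: pd.DataFrame  # per model: k, ssd, criterion value, delta, weight
    selected: str
    criterion_used: str

    def __repr__(self):
        return (
            f"ModelComparison(selected={self.selected!r}, "
            f"criterion={self.criterion_used})\n{self.table}"
        )


def select_model(
    fits: list[FRAPFitResult],
    n: int | None = None,
    criterion: str | None = None,
    mode: str = "gaussian",
) -> ModelComparison:
    """Rank fitted models by (corrected) AIC and Akaike weights.

    All fits must be to the same data. The criterion is chosen by the
    n/k > 40 rule from the largest model unless forced. Akaike weights are
    w_i = exp(−Δ_i/2)/Σ_j exp(−Δ_j/2).
    """
    if not fits:
        raise ValueError("empty fit list")
    if n is None:
        n = fits[0].nobs
    if any(f.nobs != n for f in fits):
        raise ValueError("fits are not on identical data (n differs)")
    if criterion is None:
        criterion = choose_criterion(n, max(f.k_params for f in fits))
    values = []
    for f in fits:
        if criterion == "AICc":
            values.append(aicc(f.ssd, f.k_params, n, mode=mode))
        else:
            values.append(aic(f.ssd, f.k_params, n, mode=mode))
    values = np.asarray(values, dtype=float)
    delta = values - values.min()
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    table = pd.DataFrame(
        {
            "model": [f.model.kinetics for f in fits],
            "k": [f.k_params for f in fits],
            "ssd": [f.ssd for f in fits],
            criterion.lower(): values,
            "delta": delta,
            "weight": w,
        }
    ).sort_values("delta", ignore_index=True)
    selected = table.loc[0, "model"]
    return ModelComparison(table=table, selected=str(selected), criterion_used=criterion)


def r_squared(model_curve: np.ndarray, data_curve: np.ndarray) -> float:
    """Coefficient of determination 1 − Σ(m−d)²/Σ(d−d̄)²."""
    m = np.asarray(model_curve, dtype=float)
    d = np.asarray(data_curve, dtype=float)
    if d.size < 2:
        raise ValueError("need at least two data points")
    ss_tot = float(((d - d.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("zero data variance")
    ss_res = float(((m - d) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def normality(sample, alpha: float = 0.05):
    """Shapiro–Wilk normality test; returns (statistic, p, normal?)."""
    stat, p = stats.shapiro(np.asarray(sample, dtype=float))
    return float(stat), float(p), bool(p > alpha)


def compare_groups(a, b, test: str = "welch") -> dict:
    """Two-sided comparison of two groups of estimated diffusivities.

    ``test`` ∈ {t, welch, mannwhitney, wilcoxon}. The Shapiro–Wilk gate on
    each sample is reported alongside so the parametric tests can be
    judged appropriate or not.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if test == "t":
        stat, p = stats.ttest_ind(a, b, equal_var=True)
    elif test == "welch":
        stat, p = stats.ttest_ind(a, b, equal_var=False)
    elif test == "mannwhitney":
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    elif test == "wilcoxon":
        if len(a) != len(b):
            raise ValueError("wilcoxon is a paired test: samples must have equal length")
        stat, p = stats.wilcoxon(a, b)
    else:
        raise ValueError(f"unknown test {test!r}")
    out = {"test": test, "statistic": float(stat), "p_value": float(p)}
    for name, sample in (("a", a), ("b", b)):
        if len(sample) >= 3:
            s, pp, ok = normality(sample)
            out[f"shapiro_{name}"] = {"statistic": s, "p_value": pp, "normal": ok}
    return out
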