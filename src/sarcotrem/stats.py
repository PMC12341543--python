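"""Two-group test routing and force-frequency curve comparison.

The routing decision tree mirrors the standard two-sample workflow in
muscle-physiology studies: normality is checked per group (D'Agostino &
Pearson; Shapiro-Wilk fallback below its n >= 8 minimum), variances are
compared with an F test, and the comparison runs as Student's t (both
normal, similar variance), Welch's t (normal, unequal variance) or
Mann-Whitney U (non-normal). Force-frequency curves are compared with a
two-way fixed-effects ANOVA (group x frequency) on animal-level peak
forces followed by per-frequency contrasts with Šídák adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

ALPHA_DEFAULT = 0.05
_DAGOSTINO_MIN_N = 8


def significance_stars(p: float) -> str:
    """Figure-legend star convention."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def sidak_adjust(p: float | np.ndarray, m: int) -> float | np.ndarray:
    """Šídák multiple-comparison adjustment: 1 - (1 - p)^m."""
    if m < 1:
        raise ValueError("m must be at least 1")
    return 1.0 - (1.0 - np.asarray(p, dtype=float)) ** m


@dataclass
class GroupComparison:
    """A routed two-group comparison and its provenance."""

    chosen_test: str  # student_t | welch_t | mann_whitney
    p_value: float
    statistic: float
    normality_p: tuple[float, float]
    variance_p: float
    normality_test: str  # dagostino_pearson | shapiro (small-n fallback)
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    n_a: int
    n_b: int
    alpha: float = ALPHA_DEFAULT

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)

    def summary(self) -> str:
        return (
            f"{self.chosen_test}: p = {self.p_value:.4g} ({self.stars}); "
            f"group A {self.mean_a:.4g} ± {self.sem_a:.4g} (n={self.n_a}), "
            f"group B {self.mean_b:.4g} ± {self.sem_b:.4g} (n={self.n_b})"
        )


def _normality_p(x: np.ndarray) -> tuple[float, str]:
    if x.size >= _DAGOSTINO_MIN_N:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return float(sps.normaltest(x).pvalue), "dagostino_pearson"
    return float(sps.shapiro(x).pvalue), "shapiro"


def _f_test_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided F test for equality of variances."""
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va >= vb:
        f, d1, d2 = va / vb, a.size - 1, b.size - 1
    else:
        f, d1, d2 = vb / va, b.size - 1, a.size - 1
    return float(min(1.0, 2.0 * sps.f.sf(f, d1, d2)))


def route_and_test(
    a: np.ndarray, b: np.ndarray, alpha: float = ALPHA_DEFAULT
) -> GroupComparison:
    """Route a two-group comparison through the normality/variance tree.

    Both groups normal (p >= alpha) with similar variances -> Student's
    two-tailed t; normality failed in either group -> Mann-Whitney U;
    normality passed but variances differ -> Welch's two-tailed t.
    Groups smaller than 8 fall back to Shapiro-Wilk for the normality
    check (the D'Agostino-Pearson statistic is undefined there), flagged
    in ``normality_test``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.var() == 0 and b.var() == 0 and a.mean() == b.mean():
        raise ValueError("all values identical in both groups")

    pn_a, test_name_a = _normality_p(a)
    pn_b, test_name_b = _normality_p(b)
    normality_test = (
        test_name_a if test_name_a == test_name_b else "mixed"
    )
    p_var = _f_test_p(a, b)

    if pn_a < alpha or pn_b < alpha:
        chosen = "mann_whitney"
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
    elif p_var < alpha:
        chosen = "welch_t"
        res = sps.ttest_ind(a, b, equal_var=False)
    else:
        chosen = "student_t"
        res = sps.ttest_ind(a, b, equal_var=True)

    return GroupComparison(
        chosen_test=chosen,
        p_value=float(res.pvalue),
        statistic=float(res.statistic),
        normality_p=(pn_a, pn_b),
        variance_p=p_var,
        normality_test=normality_test,
        mean_a=float(a.mean()),
        sem_a=float(sps.sem(a)),
        mean_b=float(b.mean()),
        sem_b=float(sps.sem(b)),
        n_a=int(a.size),
        n_b=int(b.size),
        alpha=alpha,
    )


def curve_comparison(
    df: pd.DataFrame,
    group_col: str = "group",
    freq_col: str = "freq_hz",
    value_col: str = "value",
) -> pd.DataFrame:
    """Two-way ANOVA (group x frequency) plus Šídák per-frequency contrasts.

    ``df`` holds one row per animal per frequency (animal-level peak
    forces). Returns a per-frequency table with the raw contrast p, the
    Šídák-adjusted p (m = number of frequencies) and significance stars.
    """
    groups = sorted(df[group_col].unique())
    if len(groups) != 2:
        raise ValueError("curve comparison requires exactly 2 groups")
    freqs = sorted(df[freq_col].unique())
    if len(freqs) < 2:
        raise ValueError("need a common grid of at least 2 frequencies")
    counts = df.groupby([group_col, freq_col]).size()
    if len(counts) != 2 * len(freqs):
        raise ValueError("missing group x frequency cells")
    if counts.min() < 2:
        raise ValueError("need at least 2 animals per group and frequency")

    data = df.rename(
        columns={group_col: "g", freq_col: "f", value_col: "y"}
    ).copy()
    model = smf.ols("y ~ C(g) * C(f)", data=data).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    mse = model.mse_resid
    dof = model.df_resid

    rows = []
    m = len(freqs)
    for f in freqs:
        sub = data[data["f"] == f]
        ya = sub.loc[sub["g"] == groups[0], "y"].to_numpy()
        yb = sub.loc[sub["g"] == groups[1], "y"].to_numpy()
        diff = ya.mean() - yb.mean()
        se = np.sqrt(mse * (1 / ya.size + 1 / yb.size))
        if se == 0:
            p = 1.0 if diff == 0 else 0.0
            tval = 0.0 if diff == 0 else np.inf
        else:
            tval = diff / se
            p = float(2 * sps.t.sf(abs(tval), dof))
        p_adj = float(sidak_adjust(p, m))
        rows.append(
            {
                "freq_hz": f,
                f"mean_{groups[0]}": ya.mean(),
                f"mean_{groups[1]}": yb.mean(),
                "diff": diff,
                "t": tval,
                "p": p,
                "p_adj": p_adj,
                "stars": significance_stars(p_adj),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["anova"] = anova
    return out


def type_one_error_check(
    n_sims: int = 2000,
    n_per_group: int = 20,
    alpha: float = ALPHA_DEFAULT,
    sd_ratio: float = 1.0,
    seed: int = 0,
) -> float:
    """Empirical type-I error of the routed procedure under a normal null.

    Draws both groups from the same normal mean (the second group's SD
    scaled by ``sd_ratio`` to probe the Welch route) and reports the
    fraction of simulations declared significant.
    """
    if n_sims < 1000:
        raise ValueError("need at least 1000 simulations for a stable rate")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sims):
        a = rng.normal(0.0, 1.0, n_per_group)
        b = rng.normal(0.0, sd_ratio, n_per_group)
        if alpha <= 0:
            continue
        if route_and_test(a, b, alpha=alpha).p_value < alpha:
            hits += 1
    return hits / n_sims
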