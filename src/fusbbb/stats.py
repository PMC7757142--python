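"""Group-comparison statistics for the 2x2 (genotype x treatment) design.

Peak acoustic pressures and initial enhancement ratios are compared with a
two-way ANOVA (Type-III sums of squares, with interaction), Tukey-Kramer
HSD over the four cells, and a two-sided Grubbs test for outliers. Focal
spots are the unit of replication, matching the study design; no mouse-level
clustering is modeled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class AnovaEffect:
    name: str
    sum_sq: float
    df: int
    F: float
    p_value: float


@dataclass(frozen=True)
class AnovaResult:
    """Two-way ANOVA decomposition with interaction."""

    genotype: AnovaEffect
    treatment: AnovaEffect
    interaction: AnovaEffect
    residual_sum_sq: float
    residual_df: int
    total_sum_sq: float

    def effects(self) -> list[AnovaEffect]:
        return [self.genotype, self.treatment, self.interaction]

    def to_frame(self) -> pd.DataFrame:
        rows = [e.__dict__ for e in self.effects()]
        rows.append(
            {
                "name": "residual",
                "sum_sq": self.residual_sum_sq,
                "df": self.residual_df,
                "F": np.nan,
                "p_value": np.nan,
            }
        )
        return pd.DataFrame(rows)


def _design(data: pd.DataFrame, value: str, factor_a: str, factor_b: str):
    y = data[value].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("values must be finite")
    levels_a = sorted(data[factor_a].unique())
    levels_b = sorted(data[factor_b].unique())
    if len(levels_a) != 2 or len(levels_b) != 2:
        raise ValueError("both factors must have exactly 2 levels")
    a = np.where(data[factor_a].to_numpy() == levels_a[0], 1.0, -1.0)
    b = np.where(data[factor_b].to_numpy() == levels_b[0], 1.0, -1.0)
    for la in (1.0, -1.0):
        for lb in (1.0, -1.0):
            if not np.any((a == la) & (b == lb)):
                raise ValueError("every cell of the 2x2 design must be populated")
    return y, a, b, levels_a, levels_b


def _sse(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def two_way_anova(
    data: pd.DataFrame,
    value: str = "value",
    factor_a: str = "genotype",
    factor_b: str = "treatment",
) -> AnovaResult:
    """Type-III two-way ANOVA with interaction on a 2x2 design.

    Effect-coded (+1/-1) contrasts; each effect's sum of squares is the
    increase in residual SS when that term is dropped from the full model,
    which for the 2x2 case is the Type-III decomposition and handles
    unbalanced cells. F = MS_effect / MS_residual with 1 df per effect.
    A fully degenerate dataset (zero residual variance and zero effect SS)
    reports F = 0, p = 1 by convention.
    """
    y, a, b, *_ = _design(data, value, factor_a, factor_b)
    n = y.size
    ones = np.ones(n)
    cols = {"genotype": a, "treatment": b, "interaction": a * b}
    X_full = np.column_stack([ones, a, b, a * b])
    sse_full = _sse(X_full, y)
    df_resid = n - 4
    if df_resid <= 0:
        raise ValueError("need more than one observation per cell")
    # guard against round-off on degenerate (constant) data
    tiny = 1e-12 * max(float(y @ y), 1.0)
    if sse_full < tiny:
        sse_full = 0.0
    mse = sse_full / df_resid

    effects = {}
    for name, col in cols.items():
        X_drop = np.column_stack([ones] + [c for k, c in cols.items() if k != name])
        ss = max(_sse(X_drop, y) - sse_full, 0.0)
        if ss < tiny:
            ss = 0.0
        if mse == 0.0:
            F, p = (0.0, 1.0) if ss == 0.0 else (np.inf, 0.0)
        else:
            F = (ss / 1.0) / mse
            p = float(sps.f.sf(F, 1, df_resid))
        effects[name] = AnovaEffect(name=name, sum_sq=ss, df=1, F=float(F), p_value=p)

    total_ss = float(((y - y.mean()) ** 2).sum())
    return AnovaResult(
        genotype=effects["genotype"],
        treatment=effects["treatment"],
        interaction=effects["interaction"],
        residual_sum_sq=sse_full,
        residual_df=df_resid,
        total_sum_sq=total_ss,
    )


def tukey_hsd(
    data: pd.DataFrame,
    value: str = "value",
    factor_a: str = "genotype",
    factor_b: str = "treatment",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tukey-Kramer HSD over the four genotype x treatment cells.

    All six pairwise cell comparisons, adjusted with the studentized range
    distribution (k = 4 means, residual df pooled across cells); the
    Tukey-Kramer standard error handles unequal cell sizes. Returns a table
    with mean difference, adjusted p and a significance flag at ``alpha``.
    """
    y, a, b, levels_a, levels_b = _design(data, value, factor_a, factor_b)
    cells = {}
    for la, sa in zip((1.0, -1.0), levels_a):
        for lb, sb in zip((1.0, -1.0), levels_b):
            label = f"{sa}:{sb}"
            cells[label] = y[(a == la) & (b == lb)]
    k = len(cells)
    n_total = y.size
    df_resid = n_total - k
    sse = sum(float(((v - v.mean()) ** 2).sum()) for v in cells.values())
    mse = sse / df_resid

    rows = []
    labels = list(cells)
    for i in range(k):
        for j in range(i + 1, k):
            vi, vj = cells[labels[i]], cells[labels[j]]
            diff = float(vi.mean() - vj.mean())
            se = np.sqrt(mse / 2.0 * (1.0 / vi.size + 1.0 / vj.size))
            if se == 0.0:
                q = 0.0 if diff == 0.0 else np.inf
            else:
                q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, k, df_resid)) if np.isfinite(q) else 0.0
            rows.append(
                {
                    "group_1": labels[i],
                    "group_2": labels[j],
                    "mean_diff": diff,
                    "q": float(q),
                    "p_adj": p,
                    "significant": p < alpha,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GrubbsResult:
    is_outlier: bool
    statistic: float
    critical_value: float
    index: int | None


def grubbs_test(values, alpha: float = 0.05) -> GrubbsResult:
    """Two-sided Grubbs test for a single outlier.

    G = max|x_i - mean| / s with the sample (n-1) standard deviation; the
    critical value is ((n-1)/sqrt(n)) * sqrt(t^2 / (n - 2 + t^2)) with t the
    upper alpha/(2n) quantile of the t distribution on n-2 df. A constant
    vector (zero SD) reports no outlier.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Grubbs test requires at least 3 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    s = x.std(ddof=1)
    if s == 0.0:
        return GrubbsResult(False, 0.0, np.nan, None)
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    g = float(dev[idx] / s)
    n = x.size
    t = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    g_crit = float((n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2)))
    return GrubbsResult(g > g_crit, g, g_crit, idx if g > g_crit else None)
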