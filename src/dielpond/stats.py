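"""Morning-vs-afternoon group comparisons and a Spearman correlation screen.

`compare_groups` implements the assumption-driven decision tree common in
field biogeochemistry: test normality (Shapiro–Wilk on pooled within-group
residuals) and homoscedasticity (Levene, median-centred / Brown–Forsythe);
when both pass at ``alpha_assumption`` run a one-way ANOVA, otherwise fall
back to the non-parametric Kruskal–Wallis test.  The path actually taken is
reported so a reader can audit the choice.

`spearman_matrix` computes the pairwise Spearman rank correlation of a wide
variable table with pairwise-complete handling of missing values, two-sided
p-values and a significance mask.  No multiple-testing correction by default
(optional Benjamini–Hochberg), since single-screen usage reports raw p.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

__all__ = ["GroupComparison", "CorrelationMatrix", "compare_groups", "spearman_matrix"]

#: Minimum complete pairs for a Spearman entry.
MIN_PAIRS = 4


@dataclass(frozen=True)
class GroupComparison:
    """Outcome of the assumption-driven two-path comparison."""

    variable: str
    test_used: str  # 'anova' | 'kruskal_wallis'
    statistic: float
    p_value: float
    shapiro_p: float
    levene_p: float
    significant: bool
    alpha: float
    alpha_assumption: float
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "test_used": self.test_used,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "shapiro_p": self.shapiro_p,
            "levene_p": self.levene_p,
            "significant": self.significant,
            "flags": list(self.flags),
        }


def compare_groups(
    values,
    groups,
    alpha: float = 0.05,
    alpha_assumption: float = 0.05,
    variable: str = "",
) -> GroupComparison:
    """Compare a numeric variable across groups via the decision tree.

    Requires at least two groups with >=2 observations each.  Constant data
    make the assumption tests undefined; such cases fall through to
    Kruskal–Wallis with a flag (and, if every value is identical, report
    p = 1 with a second flag rather than erroring).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.size != groups.size:
        raise ValidationError("values and groups must be equal length")
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValidationError("need at least two groups")
    samples = [values[groups == g] for g in labels]
    for g, s in zip(labels, samples):
        if s.size < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 observations")

    flags: list[str] = []
    residuals = np.concatenate([s - s.mean() for s in samples])
    if np.allclose(residuals, residuals[0]):
        shapiro_p = np.nan
        flags.append("assumptions-undefined-constant-data")
    else:
        shapiro_p = float(sps.shapiro(residuals).pvalue)

    try:
        # duplicate-sized groups make the median-centred statistic degenerate
        # (zero within-group deviation variance); suppress the benign warning
        with np.errstate(divide="ignore", invalid="ignore"):
            levene_p = float(sps.levene(*samples, center="median").pvalue)
        if not np.isfinite(levene_p):
            raise ValueError("levene undefined")
    except Exception:
        levene_p = np.nan
        if "assumptions-undefined-constant-data" not in flags:
            flags.append("levene-undefined")

    parametric = (
        np.isfinite(shapiro_p)
        and np.isfinite(levene_p)
        and shapiro_p >= alpha_assumption
        and levene_p >= alpha_assumption
    )

    if parametric:
        stat, p = sps.f_oneway(*samples)
        test = "anova"
    else:
        test = "kruskal_wallis"
        try:
            with np.errstate(divide="ignore", invalid="ignore"):
                stat, p = sps.kruskal(*samples)
            if not (np.isfinite(stat) and np.isfinite(p)):
                raise ValueError("kruskal undefined")
        except ValueError:
            # all observations identical: no evidence of any group effect
            stat, p = 0.0, 1.0
            flags.append("all-values-identical")

    return GroupComparison(
        variable=variable,
        test_used=test,
        statistic=float(stat),
        p_value=float(p),
        shapiro_p=shapiro_p,
        levene_p=levene_p,
        significant=bool(p < alpha),
        alpha=alpha,
        alpha_assumption=alpha_assumption,
        flags=tuple(flags),
    )


@dataclass(frozen=True)
class CorrelationMatrix:
    """Spearman rho / p matrices with a significance mask.

    ``rho`` is symmetric with unit diagonal; entries with fewer than
    `MIN_PAIRS` complete pairs are NaN and listed in ``flags``.
    """

    variables: tuple[str, ...]
    rho: pd.DataFrame
    p: pd.DataFrame
    n_pairs: pd.DataFrame
    significant: pd.DataFrame
    alpha: float
    flags: tuple[str, ...] = ()


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values for a flat array (NaN-safe)."""
    out = np.full_like(p, np.nan, dtype=float)
    ok = np.isfinite(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv)
    ranked = pv[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


def spearman_matrix(
    table: pd.DataFrame, alpha: float = 0.05, adjust: bool = False
) -> CorrelationMatrix:
    """Pairwise Spearman rank correlations of a wide observations table.

    Columns are variables, rows observations.  Missing values are handled
    pairwise-complete; ties get average ranks (scipy convention).  With
    ``adjust=True`` the mask uses Benjamini–Hochberg adjusted p-values.
    """
    cols = [str(c) for c in table.columns]
    k = len(cols)
    if k < 2:
        raise ValidationError("need at least two variables")
    rho = np.eye(k)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    flags: list[str] = []
    data = table.to_numpy(dtype=float)
    for i in range(k):
        n[i, i] = int(np.isfinite(data[:, i]).sum())
        for j in range(i + 1, k):
            ok = np.isfinite(data[:, i]) & np.isfinite(data[:, j])
            n[i, j] = n[j, i] = int(ok.sum())
            if ok.sum() < MIN_PAIRS:
                rho[i, j] = rho[j, i] = np.nan
                flags.append(f"insufficient-pairs:{cols[i]}~{cols[j]}")
                continue
            r, pv = sps.spearmanr(data[ok, i], data[ok, j])
            rho[i, j] = rho[j, i] = float(r)
            p[i, j] = p[j, i] = float(pv)

    p_for_mask = p
    if adjust:
        iu = np.triu_indices(k, 1)
        adj_flat = _bh_adjust(p[iu])
        p_for_mask = np.full((k, k), np.nan)
        p_for_mask[iu] = adj_flat
        p_for_mask = np.where(np.isnan(p_for_mask), p_for_mask.T, p_for_mask)

    sig = np.where(np.isfinite(p_for_mask), p_for_mask < alpha, False)
    np.fill_diagonal(sig, False)

    idx = pd.Index(cols)
    return CorrelationMatrix(
        variables=tuple(cols),
        rho=pd.DataFrame(rho, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n_pairs=pd.DataFrame(n, index=idx, columns=idx),
        significant=pd.DataFrame(sig.astype(bool), index=idx, columns=idx),
        alpha=alpha,
        flags=tuple(flags),
    )
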