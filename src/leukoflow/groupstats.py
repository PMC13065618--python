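"""Univariate group comparisons and biomarker-descriptor correlation matrices.

One-way ANOVA per variable followed by Tukey's honestly-significant-
difference post hoc test, computed on the studentized-range distribution
with the Tukey-Kramer standard error (equivalently, the harmonic-mean
group size for unbalanced cells).  Correlations are pairwise-complete
Pearson or Spearman with the usual p-value transforms.  Raw p-values are
reported by default; a Benjamini-Hochberg switch exists for the large
correlation screens but is off by default.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class AnovaTukeyResult:
    """Per-variable ANOVA F/p plus the pairwise matrix of Tukey adjusted p."""

    anova: pd.DataFrame                      # index: variable; columns: F, p
    tukey: dict[str, pd.DataFrame]           # variable -> groups x groups adjusted p
    group_means: dict[str, pd.Series]        # variable -> per-group mean
    skipped: list[str]

    def tidy(self) -> pd.DataFrame:
        """Long-format table: variable, comparison, statistic, p, adjusted p."""
        rows = []
        for var in self.anova.index:
            rows.append({"variable": var, "comparison": "ANOVA",
                         "statistic": self.anova.loc[var, "F"],
                         "p": self.anova.loc[var, "p"], "p_adj": np.nan})
            tk = self.tukey[var]
            for g1, g2 in itertools.combinations(tk.index, 2):
                means = self.group_means[var]
                rows.append({"variable": var, "comparison": f"{g1} vs {g2}",
                             "statistic": means[g1] - means[g2],
                             "p": np.nan, "p_adj": tk.loc[g1, g2]})
        return pd.DataFrame(rows)


def anova_tukey(table: pd.DataFrame, variables: list[str],
                group_col: str = "group", groups: list[str] | None = None) -> AnovaTukeyResult:
    """One-way ANOVA and Tukey HSD per variable.

    Missing values are dropped per variable; a variable with an empty
    group (or a group with < 2 observations) is skipped with a warning.
    Tukey adjusted p-values come from the studentized-range distribution
    with ``k`` groups and the pooled within-group df; the pairwise SE uses
    the Tukey-Kramer form ``sqrt(MSW/2 * (1/ni + 1/nj))``.
    """
    if groups is None:
        groups = list(pd.unique(table[group_col]))
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")

    anova_rows = {}
    tukey: dict[str, pd.DataFrame] = {}
    means: dict[str, pd.Series] = {}
    skipped: list[str] = []
    for var in variables:
        samples = []
        ok = True
        for g in groups:
            vals = table.loc[table[group_col] == g, var].dropna().to_numpy(dtype=float)
            if len(vals) < 2:
                ok = False
                break
            samples.append(vals)
        if not ok:
            logger.warning("variable %s skipped: a group has < 2 observations", var)
            skipped.append(var)
            continue

        k = len(samples)
        n_total = sum(len(s) for s in samples)
        grand = np.concatenate(samples).mean()
        ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
        ss_within = sum(np.sum((s - s.mean()) ** 2) for s in samples)
        df_b, df_w = k - 1, n_total - k
        msb = ss_between / df_b
        msw = ss_within / df_w
        if msw == 0:
            F = 0.0 if msb == 0 else np.inf
            p = 1.0 if msb == 0 else 0.0
        else:
            F = msb / msw
            p = float(stats.f.sf(F, df_b, df_w))
        anova_rows[var] = {"F": float(F), "p": p}

        padj = pd.DataFrame(np.ones((k, k)), index=groups, columns=groups)
        for (i, si), (j, sj) in itertools.combinations(enumerate(samples), 2):
            se = np.sqrt(msw / 2.0 * (1.0 / len(si) + 1.0 / len(sj)))
            if se == 0:
                pval = 1.0 if si.mean() == sj.mean() else 0.0
            else:
                q = abs(si.mean() - sj.mean()) / se
                pval = float(stats.studentized_range.sf(q, k, df_w))
            padj.iloc[i, j] = padj.iloc[j, i] = pval
        tukey[var] = padj
        means[var] = pd.Series({g: s.mean() for g, s in zip(groups, samples)})

    return AnovaTukeyResult(anova=pd.DataFrame(anova_rows).T, tukey=tukey,
                            group_means=means, skipped=skipped)


def correlations(table: pd.DataFrame, set_a: list[str], set_b: list[str],
                 method: str = "pearson", min_n: int = 4,
                 bh_adjust: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete correlation matrices between two variable sets.

    Returns ``(coefficients, p_values)`` of shape ``|set_a| x |set_b|``.
    Pearson p-values use the t transform; Spearman works on average ranks.
    Pairs with fewer than ``min_n`` complete observations, or with a
    constant column, yield NaN (logged).  With ``bh_adjust=True`` the
    p-value matrix is Benjamini-Hochberg adjusted across all pairs.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    coef = pd.DataFrame(np.nan, index=set_a, columns=set_b)
    pval = pd.DataFrame(np.nan, index=set_a, columns=set_b)
    for a in set_a:
        for b in set_b:
            pair = table[[a, b]].dropna()
            if len(pair) < min_n:
                logger.warning("correlation %s-%s: only %d complete pairs", a, b, len(pair))
                continue
            xa = pair[a].to_numpy(dtype=float)
            xb = pair[b].to_numpy(dtype=float)
            if np.std(xa) == 0 or np.std(xb) == 0:
                logger.warning("correlation %s-%s: constant column", a, b)
                continue
            if method == "pearson":
                r, p = stats.pearsonr(xa, xb)
            else:
                r, p = stats.spearmanr(xa, xb)
            coef.loc[a, b] = r
            pval.loc[a, b] = p
    if bh_adjust:
        flat = pval.to_numpy().ravel()
        mask = np.isfinite(flat)
        adj = np.full_like(flat, np.nan)
        if mask.sum():
            adj[mask] = stats.false_discovery_control(flat[mask], method="bh")
        pval = pd.DataFrame(adj.reshape(pval.shape), index=set_a, columns=set_b)
    return coef, pval
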