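"""Statistical layer on DSS tables and phospho-marker tables.

Covers the downstream analyses of the screen: IgG-normalised signalling
fold-changes with (paired) t-tests, Holm-corrected Pearson correlation
matrices across markers, two-way ANOVA of DSS with cell line and AAF
stimulation as factors plus Tukey HSD post-hoc comparisons among AAF
levels, and Ward-d2 hierarchical clustering for heatmap export.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy import stats as sps
from skbio.tree import TreeNode
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "holm",
    "normalize_markers",
    "marker_tests",
    "correlation_matrix",
    "anova2_tukey",
    "cluster_ward",
    "ClusterResult",
]


def holm(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (family-wise error control)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def normalize_markers(
    table: pd.DataFrame,
    igg_col: str = "IgG",
    method: str = "log2_igg",
    cofactor: float = 5.0,
) -> pd.DataFrame:
    """Fold-change table from a median-fluorescence table.

    Default is the log2 ratio to the IgG control of the same sample,
    ``log2(median / median_IgG)``; ``method="arcsinh"`` instead applies
    ``arcsinh(x / cofactor) - arcsinh(igg / cofactor)`` for flow-like data.
    The unstimulated control row is retained for contrast.  Nonpositive
    medians fail with the offending cells listed.
    """
    if igg_col not in table.columns:
        raise ValueError(f"IgG control column {igg_col!r} missing")
    values = table.drop(columns=[igg_col])
    igg = table[igg_col]
    if method == "log2_igg":
        bad = [(r, c) for r in table.index for c in table.columns
               if not table.loc[r, c] > 0]
        if bad:
            raise ValueError(f"nonpositive medians at {bad[:10]}")
        return np.log2(values.div(igg, axis=0))
    if method == "arcsinh":
        return np.arcsinh(values / cofactor).sub(np.arcsinh(igg / cofactor), axis=0)
    raise ValueError(f"unknown normalisation method {method!r}")


def marker_tests(
    fold_changes: pd.DataFrame,
    control_row: str = "media",
    paired_control: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-marker tests of stimulated fold-changes against the control.

    One-sample two-sided t-test of the stimulated values against the control
    row's value, or a paired t-test when a matched control table is given.
    P-values are Holm-adjusted across the marker panel.  Zero-variance
    samples with a nonzero mean difference are reported as the limit case
    (p = 0) with a flag.
    """
    stimulated = fold_changes.drop(index=control_row)
    if len(stimulated) < 3:
        raise ValueError("need >= 3 stimulated samples per marker")
    rows = []
    for marker in fold_changes.columns:
        x = stimulated[marker].to_numpy(dtype=float)
        flag = ""
        if paired_control is not None:
            y = paired_control.drop(index=control_row)[marker].to_numpy(dtype=float)
            diffs = x - y
            mean_diff = diffs.mean()
            if np.allclose(diffs.std(ddof=1), 0.0):
                tstat, p = _degenerate_t(mean_diff)
                flag = "zero_variance"
            else:
                tstat, p = sps.ttest_rel(x, y)
        else:
            mu0 = float(fold_changes.loc[control_row, marker])
            mean_diff = x.mean() - mu0
            if np.allclose(x.std(ddof=1), 0.0):
                tstat, p = _degenerate_t(mean_diff)
                flag = "zero_variance"
            else:
                tstat, p = sps.ttest_1samp(x, popmean=mu0)
        rows.append({"marker": marker, "mean_diff": float(mean_diff),
                     "t": float(tstat), "p": float(p), "flag": flag})
    out = pd.DataFrame(rows)
    out["p_holm"] = holm(out["p"].to_numpy())
    out["significant"] = out["p_holm"] < alpha
    return out


def _degenerate_t(mean_diff: float) -> tuple[float, float]:
    if mean_diff == 0.0:
        return 0.0, 1.0
    return float(np.sign(mean_diff) * np.inf), 0.0


def correlation_matrix(
    fold_changes: pd.DataFrame,
    control_row: str | None = "media",
    alpha: float = 0.05,
):
    """Pearson correlations between markers with Holm-adjusted p-values.

    Returns ``(r, p_adj, significant)`` DataFrames over marker pairs;
    the Holm family is the set of unique off-diagonal pairs.  Constant
    columns yield undefined correlations, masked as NaN.
    """
    data = fold_changes.drop(index=control_row) if control_row in fold_changes.index else fold_changes
    if len(data) < 4:
        raise ValueError("need >= 4 samples for correlation testing")
    markers = list(data.columns)
    m = len(markers)
    r = np.eye(m)
    p = np.zeros((m, m))
    constant = [c for c in markers if np.allclose(data[c].std(ddof=1), 0.0)]
    pairs, raw_p = [], []
    for i in range(m):
        for j in range(i + 1, m):
            if markers[i] in constant or markers[j] in constant:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            rij, pij = sps.pearsonr(data[markers[i]], data[markers[j]])
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
            pairs.append((i, j))
            raw_p.append(pij)
    p_adj = np.full((m, m), np.nan)
    np.fill_diagonal(p_adj, 0.0)
    if raw_p:
        adj = holm(raw_p)
        for (i, j), a in zip(pairs, adj):
            p_adj[i, j] = p_adj[j, i] = a
    r_df = pd.DataFrame(r, index=markers, columns=markers)
    p_df = pd.DataFrame(p_adj, index=markers, columns=markers)
    sig = p_df < alpha
    np.fill_diagonal(sig.values, False)
    return r_df, p_df, sig


def anova2_tukey(
    data: pd.DataFrame,
    response: str = "dss",
    factor_a: str = "cell_line",
    factor_b: str = "condition",
    interaction: bool = False,
    control_level: str | None = None,
):
    """Two-way ANOVA of DSS with Tukey HSD post-hoc on the second factor.

    Fits the additive model (type-II sums of squares) by default -- the
    screens often yield one DSS per condition per run, leaving no
    replication for an interaction term; ``interaction=True`` fits the full
    model.  Tukey HSD compares all pairs of ``factor_b`` levels (AAF
    stimulations vs media) using the model's residual mean square and the
    studentized-range distribution.

    Returns ``(anova_table, tukey_table)``.
    """
    for col in (response, factor_a, factor_b):
        if col not in data.columns:
            raise ValueError(f"column {col!r} missing")
    counts = data.groupby([factor_a, factor_b], observed=True).size()
    if (counts < 1).any() or counts.index.size < (
        data[factor_a].nunique() * data[factor_b].nunique()
    ):
        full = pd.MultiIndex.from_product(
            [data[factor_a].unique(), data[factor_b].unique()]
        )
        empty = sorted(set(full) - set(counts.index))
        raise ValueError(f"design not estimable; empty cells: {empty[:10]}")
    op = "*" if interaction else "+"
    model = ols(
        f"Q('{response}') ~ C(Q('{factor_a}')) {op} C(Q('{factor_b}'))", data=data
    ).fit()
    table = anova_lm(model, typ=2)
    table = table.rename(index={
        f"C(Q('{factor_a}'))": factor_a,
        f"C(Q('{factor_b}'))": factor_b,
        f"C(Q('{factor_a}')):C(Q('{factor_b}'))": f"{factor_a}:{factor_b}",
    })

    mse = model.mse_resid
    df_resid = int(model.df_resid)
    groups = data.groupby(factor_b, observed=True)[response]
    means = groups.mean()
    ns = groups.size()
    levels = sorted(means.index)
    k = len(levels)
    rows = []
    for a_i in range(k):
        for b_i in range(a_i + 1, k):
            la, lb = levels[a_i], levels[b_i]
            if control_level is not None and control_level not in (la, lb):
                continue
            diff = means[la] - means[lb]
            se = np.sqrt(mse / 2.0 * (1.0 / ns[la] + 1.0 / ns[lb]))
            q = abs(diff) / se
            p_adj = float(sps.studentized_range.sf(q, k, df_resid))
            rows.append({
                "level_a": la, "level_b": lb, "diff": float(diff),
                "se": float(se), "q": float(q), "p_adj": p_adj,
                "reject": p_adj < 0.05,
            })
    return table, pd.DataFrame(rows)


@dataclass(frozen=True)
class ClusterResult:
    """Ward-d2 hierarchical clustering output for heatmap export."""

    linkage: np.ndarray
    labels: tuple
    leaf_order: tuple
    newick: str

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def cluster_ward(table: pd.DataFrame) -> ClusterResult:
    """Agglomerative clustering of table rows: Euclidean distance, Ward-d2.

    Returns merge heights, the leaf ordering for heatmaps and a Newick
    serialisation of the dendrogram.  Missing values fail with a pointer to
    complete-case extraction.
    """
    if table.isna().any().any():
        raise ValueError(
            "matrix contains missing values; extract a complete-case "
            "submatrix before clustering"
        )
    x = table.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need >= 2 rows to cluster")
    z = sch.linkage(x, method="ward", metric="euclidean")
    labels = tuple(str(i) for i in table.index)
    order = tuple(labels[i] for i in sch.leaves_list(z))
    tree = TreeNode.from_linkage_matrix(z, list(labels))
    buf = _io.StringIO()
    tree.write(buf)
    return ClusterResult(linkage=z, labels=labels, leaf_order=order,
                         newick=buf.getvalue().strip())
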