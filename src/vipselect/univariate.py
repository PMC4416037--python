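"""Confirmatory nonparametric tests and two-way hierarchical clustering.

The multivariate selection is confirmed feature by feature with rank-based
tests: a Kruskal-Wallis test across all classes and two-sided
Wilcoxon-Mann-Whitney tests for every class pair.  P-values are reported
nominally -- no multiplicity correction enters any selection step -- but a
Benjamini-Hochberg column is emitted alongside for the reader.

With the small group sizes typical of such designs (4-5 animals per class)
the pairwise tests run in exact mode: the two-sided p-value is the fraction
of all C(n, n1) group assignments whose rank-sum statistic is at least as far
from its null mean as the observed one.  This enumeration handles ties
correctly; larger samples fall back to the normal approximation with tie
correction and continuity correction.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .preprocess import FeatureTable


class UnivariateError(ValueError):
    """Raised on degenerate group structures."""


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

def _group_values(values, labels):
    values = np.asarray(values, dtype=float)
    labels = [str(c) for c in labels]
    if len(labels) != values.size:
        raise UnivariateError("values and labels must have equal length")
    order: dict = {}
    for c in labels:
        order.setdefault(c, []).append(True)
    groups = {c: values[[i for i, l in enumerate(labels) if l == c]] for c in order}
    for c, g in groups.items():
        if g.size == 0:
            raise UnivariateError(f"class {c!r} has no observations")
    return groups


def _h_from_rank_sums(rank_sums, sizes, n, tie_term):
    h = 12.0 / (n * (n + 1)) * np.sum(rank_sums**2 / sizes) - 3.0 * (n + 1)
    return h / tie_term if tie_term > 0 else 0.0


def kruskal_wallis(values, labels, method: str = "asymptotic"):
    """Kruskal-Wallis H with tie correction.

    ``method="asymptotic"`` (default, as used for the reported p-values)
    refers H to chi-square with k-1 degrees of freedom.  ``method="exact"``
    enumerates every distinct assignment of the pooled observations to the
    group sizes and returns the fraction with H at least as large; feasible
    for total n up to ~12.

    Returns ``(H, p)``.  If all observations are identical, H = 0 and p = 1.
    """
    groups = _group_values(values, labels)
    if len(groups) < 2:
        raise UnivariateError("Kruskal-Wallis needs at least two classes")
    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    if method == "asymptotic":
        h, p = stats.kruskal(*groups.values())
        return float(h), float(p)
    if method != "exact":
        raise UnivariateError("method must be 'asymptotic' or 'exact'")

    n = pooled.size
    if n > 12:
        raise UnivariateError("exact Kruskal-Wallis limited to n <= 12")
    ranks = stats.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    sizes = np.array([g.size for g in groups.values()], dtype=float)
    h_obs = _h_from_rank_sums(
        np.array(
            [ranks[s].sum() for s in _group_slices(sizes)]
        ),
        sizes,
        n,
        tie_term,
    )
    # Enumerate assignments: choose indices for group 1 from all, group 2 from
    # the remainder, and so on; the last group is forced.
    total = 0
    extreme = 0
    for rank_sums in _assignment_rank_sums(ranks, sizes.astype(int)):
        total += 1
        if _h_from_rank_sums(rank_sums, sizes, n, tie_term) >= h_obs - 1e-12:
            extreme += 1
    return float(h_obs), extreme / total


def _group_slices(sizes):
    out, start = [], 0
    for s in sizes.astype(int):
        out.append(slice(start, start + s))
        start += s
    return out


def _assignment_rank_sums(ranks, sizes):
    """Yield rank-sum vectors for every distinct assignment into the groups."""
    n = ranks.size
    all_idx = tuple(range(n))

    def rec(avail, k):
        if k == len(sizes) - 1:
            yield (sum(ranks[list(avail)]),)
            return
        for chosen in combinations(avail, sizes[k]):
            rest = tuple(i for i in avail if i not in set(chosen))
            s = sum(ranks[list(chosen)])
            for tail in rec(rest, k + 1):
                yield (s, *tail)

    for sums in rec(all_idx, 0):
        yield np.asarray(sums, dtype=float)


# ---------------------------------------------------------------------------
# Wilcoxon-Mann-Whitney
# ---------------------------------------------------------------------------

def _rank_sum_exact_p(a, b):
    """Exact two-sided rank-sum p by full enumeration (tie-safe).

    The permutation distribution of U is symmetric about n1*n2/2, so the
    two-sided p is the fraction of assignments with |U - n1*n2/2| at least as
    large as observed.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n1, n2 = a.size, b.size
    ranks = stats.rankdata(pooled)
    mu = n1 * n2 / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    d_obs = abs(u_obs - mu)
    extreme = 0
    for chosen in combinations(range(n1 + n2), n1):
        u = ranks[list(chosen)].sum() - n1 * (n1 + 1) / 2.0
        if abs(u - mu) >= d_obs - 1e-12:
            extreme += 1
    return float(u_obs), extreme / comb(n1 + n2, n1)


def pairwise_wilcoxon(
    values, labels, exact_max_n: int = 12
) -> pd.DataFrame:
    """Two-sided Wilcoxon-Mann-Whitney test for every unordered class pair.

    Pairs with combined size at most ``exact_max_n`` use the exact
    enumeration; larger pairs use the normal approximation with tie and
    continuity correction.  Pairs where either class has fewer than two
    observations are skipped and flagged.  Nominal p-values; the ``mode``
    column records which computation each pair used.
    """
    groups = _group_values(values, labels)
    names = list(groups)
    rows = []
    for a_name, b_name in combinations(names, 2):
        a, b = groups[a_name], groups[b_name]
        if a.size < 2 or b.size < 2:
            rows.append((a_name, b_name, np.nan, np.nan, "skipped"))
            continue
        if a.size + b.size <= exact_max_n:
            u, p = _rank_sum_exact_p(a, b)
            mode = "exact"
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="asymptotic")
            u, p = float(res.statistic), float(res.pvalue)
            mode = "normal"
        rows.append((a_name, b_name, u, p, mode))
    return pd.DataFrame(
        rows, columns=["class_a", "class_b", "U", "p", "mode"]
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (reported alongside, never used
    for selection)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def feature_stats(
    table: FeatureTable, features=None, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-feature Kruskal-Wallis and pairwise Wilcoxon summary table.

    One row per (selected) feature: H, the KW p-value, its BH-adjusted value,
    and one column per class pair with the Wilcoxon p.
    """
    names = list(features) if features is not None else table.feature_names
    col_idx = {n: j for j, n in enumerate(table.feature_names)}
    missing = [n for n in names if n not in col_idx]
    if missing:
        raise UnivariateError(f"features not in table: {missing[:5]}")
    kw_h, kw_p, pair_cols = [], [], {}
    for name in names:
        x = table.values[:, col_idx[name]]
        h, p = kruskal_wallis(x, table.class_labels)
        kw_h.append(h)
        kw_p.append(p)
        pw = pairwise_wilcoxon(x, table.class_labels)
        for _, row in pw.iterrows():
            key = f"WMW_p[{row.class_a}|{row.class_b}]"
            pair_cols.setdefault(key, []).append(row.p)
    df = pd.DataFrame({"feature": names, "KW_H": kw_h, "KW_p": kw_p})
    df["KW_BH_q"] = bh_adjust(df["KW_p"].to_numpy())
    for key, col in pair_cols.items():
        df[key] = col
    df.attrs["alpha"] = alpha
    df.attrs["multiplicity"] = (
        "nominal p-values; BH column informational only"
    )
    return df


# ---------------------------------------------------------------------------
# Two-way hierarchical clustering
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ClusterResult:
    row_order: np.ndarray
    col_order: np.ndarray
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None
    flags: list


def two_way_cluster(
    table: FeatureTable,
    features=None,
    method: str = "ward",
    metric: str = "euclidean",
) -> ClusterResult:
    """Agglomerative clustering of samples and of features (heatmap orders).

    Euclidean distance with Ward linkage by default.  Returns leaf orders and
    linkage trees for both axes; a single sample or single feature yields the
    trivial ordering with a flag instead of an error.
    """
    if features is not None:
        sub = table.subset_features(list(features))
    else:
        sub = table
    M = sub.values
    flags = []
    if M.shape[1] == 0:
        raise UnivariateError("feature subset is empty")

    def axis_cluster(data, what):
        if data.shape[0] < 2:
            flags.append(f"single {what}: trivial order")
            return np.arange(data.shape[0]), None
        Z = hierarchy.linkage(data, method=method, metric=metric)
        return hierarchy.leaves_list(Z), Z

    row_order, row_Z = axis_cluster(M, "sample")
    col_order, col_Z = axis_cluster(M.T, "feature")
    return ClusterResult(row_order, col_order, row_Z, col_Z, flags)


def plot_heatmap(
    table: FeatureTable, cluster: ClusterResult, path, features=None, cmap="coolwarm"
):
    """Basic clustered heatmap image (samples x features, reordered)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = table.subset_features(list(features)) if features is not None else table
    M = sub.values[np.ix_(cluster.row_order, cluster.col_order)]
    fig, ax = plt.subplots(
        figsize=(max(6, 0.12 * M.shape[1]), max(4, 0.25 * M.shape[0]))
    )
    im = ax.imshow(M, aspect="auto", cmap=cmap)
    ax.set_yticks(range(M.shape[0]))
    ax.set_yticklabels([sub.sample_ids[i] for i in cluster.row_order], fontsize=6)
    ax.set_xticks([])
    ax.set_xlabel(f"{M.shape[1]} features (clustered)")
    fig.colorbar(im, ax=ax, label="scaled abundance")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
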