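"""Temporal attribution of dTs components by dynamic time warping, and
seasonal between-site significance testing.

Each degC-converted component of the daily dTs decomposition is compared
with dTs_cal using classic dynamic time warping (absolute-difference local
cost, symmetric steps, no window). Because every component is already in
the common temperature unit, series are not z-normalized; raw DTW
distances are divided by the optimal warping-path length and then min-max
scaled within each (site pair, layer, season) group so components can be
ranked on a common [0, 1] scale (0 = temporally closest to dTs_cal).

Between-site seasonal differences are tested with one-way ANOVA + Tukey
HSD when Shapiro-Wilk normality and Levene homoscedasticity both hold at
alpha, and with Kruskal-Wallis + Dunn's test (Holm-adjusted) otherwise; a
compact letter display summarizes the post hoc decisions.
"""

from __future__ import annotations

import itertools
import logging
import string

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .ts_decomposition import COMPONENTS

log = logging.getLogger("ecoforcing")

MIN_SEGMENT = 3       # shortest gap-free segment DTW will accept
MIN_GROUP_DAYS = 10   # fewest kept days for a ranking group


# ---------------------------------------------------------------------------
# Dynamic time warping
# ---------------------------------------------------------------------------

def dtw_distance(series_a, series_b, return_path_length: bool = False):
    """Classic DTW distance between two gap-free series.

    Absolute-difference local cost, symmetric step pattern (diagonal,
    horizontal, vertical; each cell's cost counted once), no window
    constraint. Returns NaN for series shorter than 3. With
    ``return_path_length`` also returns the number of cells on the optimal
    path (ties broken deterministically: diagonal first).
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    n, m = len(a), len(b)
    if n < MIN_SEGMENT or m < MIN_SEGMENT or np.isnan(a).any() or np.isnan(b).any():
        return (np.nan, np.nan) if return_path_length else np.nan

    cost = np.abs(a[:, None] - b[None, :])
    acc = np.full((n, m), np.inf)
    acc[0, 0] = cost[0, 0]
    for j in range(1, m):
        acc[0, j] = acc[0, j - 1] + cost[0, j]
    for i in range(1, n):
        acc[i, 0] = acc[i - 1, 0] + cost[i, 0]
        row_prev = acc[i - 1]
        row = acc[i]
        for j in range(1, m):
            row[j] = cost[i, j] + min(row_prev[j - 1], row_prev[j],
                                      row[j - 1])
    dist = float(acc[n - 1, m - 1])
    if not return_path_length:
        return dist
    # backtrack, preferring diagonal on ties
    i, j, steps = n - 1, m - 1, 1
    while (i, j) != (0, 0):
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            candidates = ((acc[i - 1, j - 1], i - 1, j - 1),
                          (acc[i - 1, j], i - 1, j),
                          (acc[i, j - 1], i, j - 1))
            _, i, j = min(candidates, key=lambda c: c[0])
        steps += 1
    return dist, steps


def dtw_with_gaps(series_a: pd.Series, series_b: pd.Series):
    """DTW across series with gaps: split, warp per segment, recombine.

    Rows where either series is NaN split both into aligned gap-free
    segments; segments shorter than 3 are skipped. Returns (total
    distance, total path length, n days used); distances and path lengths
    add across segments, which length-weights the per-path-length
    normalization.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    valid = np.isfinite(a) & np.isfinite(b)
    total_dist = 0.0
    total_path = 0
    n_used = 0
    # contiguous runs of valid days
    for _, run in itertools.groupby(enumerate(valid), key=lambda t: t[1]):
        run = list(run)
        if not run[0][1]:
            continue
        idx = [t[0] for t in run]
        if len(idx) < MIN_SEGMENT:
            continue
        d, p = dtw_distance(a[idx], b[idx], return_path_length=True)
        total_dist += d
        total_path += p
        n_used += len(idx)
    if n_used == 0:
        return np.nan, np.nan, 0
    return total_dist, total_path, n_used


def normalized_component_ranking(decomp: pd.DataFrame,
                                 grouping=("site_pair", "layer", "season")
                                 ) -> pd.DataFrame:
    """Rank dTs components by temporal similarity to dTs_cal per group.

    For each group with at least 10 kept days, the DTW distance of each
    component series against dTs_cal is divided by its warping-path
    length, then min-max scaled across the eight components to [0, 1].
    Rank 1 is the closest component; ties break by component name order.
    """
    grouping = list(grouping)
    rows = []
    for key, grp in decomp.groupby(grouping):
        if not isinstance(key, tuple):
            key = (key,)
        grp = grp.sort_values("date") if "date" in grp.columns else grp
        if grp["dTs_cal"].notna().sum() < MIN_GROUP_DAYS:
            log.info("normalized_component_ranking: group %s skipped "
                     "(too few days)", key)
            continue
        raw = {}
        for comp in COMPONENTS:
            dist, path, n_used = dtw_with_gaps(grp[comp], grp["dTs_cal"])
            raw[comp] = (dist / path if n_used else np.nan, dist, n_used)
        per_path = np.array([raw[c][0] for c in COMPONENTS])
        lo, hi = np.nanmin(per_path), np.nanmax(per_path)
        span = hi - lo
        norm = (per_path - lo) / span if span > 0 else np.zeros_like(per_path)
        order = sorted(range(len(COMPONENTS)),
                       key=lambda i: (norm[i], COMPONENTS[i]))
        ranks = np.empty(len(COMPONENTS), dtype=int)
        for r, i in enumerate(order, start=1):
            ranks[i] = r
        for i, comp in enumerate(COMPONENTS):
            rows.append((*key, comp, raw[comp][1], float(norm[i]),
                         int(ranks[i]), raw[comp][2]))
    return pd.DataFrame(rows, columns=grouping + [
        "component", "dtw_raw", "dtw_normalized", "rank", "n_days"])


# ---------------------------------------------------------------------------
# Seasonal significance tests
# ---------------------------------------------------------------------------

def _dunn_holm(groups: dict, alpha: float):
    """Dunn's rank-based pairwise test with Holm adjustment.

    Returns {(site_i, site_j): adjusted p} for i < j in sorted name order.
    """
    names = sorted(groups)
    pooled = np.concatenate([groups[g] for g in names])
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    mean_ranks, sizes = {}, {}
    pos = 0
    for g in names:
        k = len(groups[g])
        mean_ranks[g] = ranks[pos:pos + k].mean()
        sizes[g] = k
        pos += k

    pairs = list(itertools.combinations(names, 2))
    pvals = []
    for gi, gj in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[gi] + 1.0 / sizes[gj]))
        z = (mean_ranks[gi] - mean_ranks[gj]) / se
        pvals.append(2.0 * stats.norm.sf(abs(z)))
    adj = multipletests(pvals, alpha=alpha, method="holm")[1]
    return dict(zip(pairs, adj))


def _letters(names, different: set) -> dict:
    """Compact letter display: groups share a letter iff not different.

    Letters cover the maximal cliques of the 'not significantly different'
    graph, in deterministic order.
    """
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(names)
    for a, b in itertools.combinations(sorted(names), 2):
        if (a, b) not in different and (b, a) not in different:
            g.add_edge(a, b)
    cliques = sorted((sorted(c) for c in nx.find_cliques(g)),
                     key=lambda c: (names.index(c[0]), c))
    out = {n: "" for n in names}
    for letter, clique in zip(string.ascii_lowercase, cliques):
        for n in clique:
            out[n] += letter
    return out


def seasonal_group_test(values, site_labels, alpha: float = 0.05,
                        min_n: int = 8) -> dict | None:
    """Between-site test of daily values for one variable x layer x season.

    Shapiro-Wilk (per site) and Levene tests at ``alpha`` choose the
    branch: one-way ANOVA with Tukey HSD when all sites look normal with
    homogeneous variances, Kruskal-Wallis with Dunn-Holm otherwise.
    Returns the test name, statistic, p-value, pairwise adjusted p-values
    and a compact letter display; None when fewer than 3 sites or any site
    has fewer than ``min_n`` days.
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "site": np.asarray(site_labels)}).dropna()
    groups = {s: g["value"].to_numpy() for s, g in df.groupby("site")}
    names = sorted(groups)
    if len(names) < 3 or any(len(groups[s]) < min_n for s in names):
        return None

    # degenerate (zero-spread) groups: distribution tests are undefined
    if any(np.ptp(groups[s]) == 0 for s in names):
        means = {s: float(np.mean(groups[s])) for s in names}
        pairwise = {(a, b): (0.0 if means[a] != means[b] else 1.0)
                    for a, b in itertools.combinations(names, 2)}
        different = {p for p, padj in pairwise.items() if padj < alpha}
        return {"test": "degenerate", "statistic": np.nan,
                "pvalue": 0.0 if different else 1.0,
                "pairwise_adjusted_p": pairwise,
                "letters": _letters(names, different),
                "n_per_site": {s: int(len(groups[s])) for s in names}}

    normal = all(stats.shapiro(groups[s]).pvalue > alpha for s in names)
    homosced = stats.levene(*[groups[s] for s in names]).pvalue > alpha

    if normal and homosced:
        test = "ANOVA"
        res = stats.f_oneway(*[groups[s] for s in names])
        stat, p = float(res.statistic), float(res.pvalue)
        tk = pairwise_tukeyhsd(df["value"], df["site"], alpha=alpha)
        pairwise = {}
        for (gi, gj), padj in zip(
                itertools.combinations(tk.groupsunique, 2),
                tk.pvalues):
            pairwise[(str(gi), str(gj))] = float(padj)
    else:
        test = "Kruskal-Wallis"
        res = stats.kruskal(*[groups[s] for s in names])
        stat, p = float(res.statistic), float(res.pvalue)
        pairwise = _dunn_holm(groups, alpha)

    different = {pair for pair, padj in pairwise.items() if padj < alpha}
    return {
        "test": test, "statistic": stat, "pvalue": p,
        "pairwise_adjusted_p": pairwise,
        "letters": _letters(names, different),
        "n_per_site": {s: int(len(groups[s])) for s in names},
    }


def seasonal_tests_table(daily: pd.DataFrame, variables,
                         alpha: float = 0.05) -> pd.DataFrame:
    """Run seasonal_group_test per variable x layer x season."""
    rows = []
    for var in variables:
        for (layer, season), grp in daily.groupby(["layer", "season"]):
            res = seasonal_group_test(grp[var], grp["site_id"], alpha=alpha)
            if res is None:
                continue
            rows.append({
                "variable": var, "layer": layer, "season": season,
                "test": res["test"], "statistic": res["statistic"],
                "pvalue": res["pvalue"],
                "letters": ";".join(f"{s}:{l}" for s, l
                                    in sorted(res["letters"].items())),
            })
    return pd.DataFrame(rows)
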