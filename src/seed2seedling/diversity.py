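"""Rarefaction and alpha diversity: Chao1, Faith's PD, and group tests.

Rarefaction subsamples reads without replacement to a fixed depth (samples
below depth are dropped, mirroring the study's single rarefied data set).
Chao1 is the bias-corrected estimator S_obs + F1(F1-1)/(2(F2+1)); Faith's
PD is the branch length of the minimal subtree spanning the observed tips,
root-inclusive by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

from .tables_io import FeatureTable, ValidationError

logger = logging.getLogger("seed2seedling")

METRICS = ("chao1", "faith_pd", "observed_richness")


def rarefy(table: FeatureTable, depth: int, rng: np.random.Generator) -> FeatureTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped (and logged), never
    scaled up. Raises if no sample survives.
    """
    if depth <= 0:
        raise ValidationError("rarefaction depth must be positive")
    totals = table.counts.sum(axis=1)
    keep = totals[totals >= depth].index
    dropped = [s for s in table.counts.index if s not in set(keep)]
    if dropped:
        logger.warning("rarefy: dropped %d samples below depth %d: %s", len(dropped), depth, dropped)
    if len(keep) == 0:
        raise ValidationError(f"no samples survive rarefaction at depth {depth}")
    rows = []
    for s in keep:
        counts = table.counts.loc[s].to_numpy()
        if counts.sum() == depth:
            rows.append(counts)
        else:
            rows.append(rng.multivariate_hypergeometric(counts, depth))
    rare = pd.DataFrame(np.vstack(rows), index=keep, columns=table.counts.columns)
    return FeatureTable(rare, table.metadata.loc[keep].copy(), table.taxonomy)


def observed_richness(counts) -> float:
    v = np.asarray(counts)
    return float((v > 0).sum())


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness from one sample's integer counts.

    S_obs + F1(F1-1)/(2(F2+1)), with F1/F2 the singleton/doubleton counts;
    equals S_obs when there are no singletons, and 0 for an empty sample.
    """
    v = np.asarray(counts)
    if np.any(v < 0) or np.any(v != np.floor(v)):
        raise ValidationError("Chao1 is undefined on negative or non-integer counts")
    s_obs = float((v > 0).sum())
    f1 = float((v == 1).sum())
    f2 = float((v == 2).sum())
    return s_obs + f1 * (f1 - 1.0) / (2.0 * (f2 + 1.0))


def faith_pd(present_asvs, tree, include_root: bool = True) -> float:
    """Faith's phylogenetic diversity of a set of present tips.

    Sum of branch lengths of the minimal subtree spanning the present tips,
    including the path up to the root by default (``include_root=False``
    stops at the most recent common ancestor of the present set).
    """
    present = {str(a) for a in present_asvs}
    if not present:
        return 0.0
    tip_map = {t.name: t for t in tree.tips()}
    missing = sorted(present - tip_map.keys())
    if missing:
        raise ValidationError(f"present ASVs missing from tree: {missing}")
    # union of edges on tip-to-root paths; each node "owns" its parent edge
    covered = set()
    for name in present:
        node = tip_map[name]
        while node.parent is not None and id(node) not in covered:
            covered.add(id(node))
            node = node.parent
    lengths = {id(n): (n.length or 0.0) for n in tree.traverse() if n.parent is not None}
    total = sum(lengths[i] for i in covered)
    if not include_root:
        # subtract the stem path from the MRCA of the present set to the root
        mrca = tree.lca([tip_map[n] for n in present]) if len(present) > 1 else tip_map[next(iter(present))]
        node = mrca
        while node.parent is not None:
            total -= lengths[id(node)]
            node = node.parent
    return float(total)


@dataclass
class AlphaResult:
    sample_id: str
    metric: str
    value: float
    depth: int | None = None


def alpha_frame(
    table: FeatureTable,
    tree=None,
    metrics=("chao1", "observed_richness"),
    depth: int | None = None,
) -> pd.DataFrame:
    """One row per sample x metric. Faith's PD uses presence (count > 0)."""
    bad = sorted(set(metrics) - set(METRICS))
    if bad:
        raise ValidationError(f"unknown metrics: {bad}")
    if "faith_pd" in metrics and tree is None:
        raise ValidationError("faith_pd requested but no tree supplied")
    rows = []
    for s in table.sample_ids:
        v = table.counts.loc[s]
        for m in metrics:
            if m == "chao1":
                val = chao1(v)
            elif m == "observed_richness":
                val = observed_richness(v)
            else:
                val = faith_pd(set(v.index[v > 0]), tree)
            rows.append(AlphaResult(s, m, val, depth))
    return pd.DataFrame([r.__dict__ for r in rows])


@dataclass
class GroupTestResult:
    method: str
    statistic: float
    pvalue: float
    group_means: dict
    table: pd.DataFrame | None = None


def group_difference_test(values, grouping, method: str = "anova") -> GroupTestResult:
    """Test differences of an alpha-diversity estimator between groups.

    ``grouping`` is one factor (Series/array) or a DataFrame of factors; a
    multi-factor ANOVA uses fixed effects with type-I (sequential) sums of
    squares in column order. ``ttest``/``wilcoxon`` require exactly two
    groups; ``wilcoxon`` is the rank-sum (Mann-Whitney) test.
    """
    values = pd.Series(np.asarray(values, dtype=float))
    if isinstance(grouping, pd.DataFrame):
        factors = grouping.reset_index(drop=True)
    else:
        factors = pd.DataFrame({"group": np.asarray(grouping)})
    if len(factors) != len(values):
        raise ValidationError("values and grouping differ in length")

    if method == "anova" and factors.shape[1] > 1:
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        df = factors.copy()
        df["value"] = values.to_numpy()
        formula = "value ~ " + " + ".join(f"C({c})" for c in factors.columns)
        fit = smf.ols(formula, data=df).fit()
        tab = sm.stats.anova_lm(fit, typ=1)
        means = df.groupby(list(factors.columns))["value"].mean().to_dict()
        first = tab.index[0]
        return GroupTestResult("anova", float(tab.loc[first, "F"]), float(tab.loc[first, "PR(>F)"]), means, tab)

    key = factors.iloc[:, 0]
    groups = [values[key.to_numpy() == g].to_numpy() for g in pd.unique(key)]
    means = {g: float(np.mean(v)) for g, v in zip(pd.unique(key), groups)}
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    if method in ("anova", "ttest") and any(len(g) < 2 for g in groups):
        raise ValidationError("variance-based tests need >= 2 observations per group")
    if method == "anova":
        stat, p = st.f_oneway(*groups)
    elif method == "ttest":
        if len(groups) != 2:
            raise ValidationError("ttest needs exactly 2 groups")
        stat, p = st.ttest_ind(groups[0], groups[1])
    elif method == "wilcoxon":
        if len(groups) != 2:
            raise ValidationError("wilcoxon needs exactly 2 groups")
        res = st.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
        stat, p = res.statistic, res.pvalue
    else:
        raise ValidationError(f"unknown method {method!r}")
    if not np.isfinite(p):  # identical constant groups: no evidence of difference
        stat, p = 0.0, 1.0
    return GroupTestResult(method, float(stat), float(p), means)
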