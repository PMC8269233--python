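"""Beta diversity: log10+1 transform, Bray-Curtis, PCoA, dispersion, PERMANOVA.

PERMANOVA partitions the total sum of squares of a distance matrix
sequentially over an ordered term list (type-I, adonis2-style "by terms"),
reporting per-term R^2 and a permutation p-value under free row
permutation. Multivariate dispersion (betadisper) embeds samples by PCoA
keeping negative eigenvalues and measures distance to group centroids with
the imaginary-axis correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
from skbio import DistanceMatrix

from .tables_io import FeatureTable, ValidationError


def log10p1_transform(table) -> pd.DataFrame:
    """Elementwise log10(x + 1) of a count table or matrix."""
    counts = table.counts if isinstance(table, FeatureTable) else pd.DataFrame(table)
    if (counts.to_numpy() < 0).any():
        raise ValidationError("log10+1 transform requires non-negative input")
    return np.log10(counts + 1.0)


def bray_curtis(matrix: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between sample rows.

    BC(i,j) = sum|x_ik - x_jk| / sum(x_ik + x_jk). A pair of all-zero
    samples has undefined BC; it is set to 0 with a warning (cannot occur
    after rarefaction).
    """
    df = pd.DataFrame(matrix)
    x = df.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValidationError("Bray-Curtis needs at least 2 samples")
    if (x < 0).any():
        raise ValidationError("Bray-Curtis requires non-negative input")
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    den = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    zero = den == 0
    if zero.sum() > x.shape[0]:  # off-diagonal zero-denominator pairs
        warnings.warn("all-zero sample pair(s): Bray-Curtis set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(zero, 0.0, num / np.where(zero, 1.0, den))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=[str(i) for i in df.index])


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    """PCoA embedding with signed eigenvalues.

    ``coordinates`` holds the real axes (eigenvalue > 0, scaled by sqrt of
    the eigenvalue); ``imaginary_coordinates`` the axes of negative
    eigenvalues scaled by sqrt(-eigenvalue); no Cailliez/Lingoes correction
    is applied.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    imaginary_coordinates: pd.DataFrame = field(default_factory=pd.DataFrame)


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def pcoa(dm: DistanceMatrix, eig_tol: float = 1e-10) -> OrdinationResult:
    """Classical metric scaling of a distance matrix.

    Eigendecomposition of the Gower-centered matrix -1/2 J D^2 J; negative
    eigenvalues are reported, not corrected.
    """
    d = np.asarray(dm.data, dtype=float)
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValidationError("distance matrix must be symmetric")
    g = _gower_center(d)
    vals, vecs = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    scale = np.max(np.abs(vals)) if vals.size else 1.0
    pos = vals > eig_tol * max(scale, 1.0)
    neg = vals < -eig_tol * max(scale, 1.0)
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    imag = vecs[:, neg] * np.sqrt(-vals[neg])
    ids = list(dm.ids)
    prop = vals[pos] / vals[pos].sum() if pos.any() else np.array([])
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=ids, columns=[f"PC{i+1}" for i in range(coords.shape[1])]),
        eigenvalues=vals,
        proportion_explained=prop,
        imaginary_coordinates=pd.DataFrame(imag, index=ids, columns=[f"NC{i+1}" for i in range(imag.shape[1])]),
    )


# ---------------------------------------------------------------------------
# betadisper
# ---------------------------------------------------------------------------

@dataclass
class DispersionResult:
    distances: pd.Series
    grouping: pd.Series
    statistic: float | None
    pvalue: float | None


def betadisper(dm: DistanceMatrix, grouping) -> DispersionResult:
    """Distance of each sample to its group centroid in PCoA space.

    Real-axis squared distances minus the imaginary-axis contribution
    (Anderson's correction), clipped at zero. With exactly two groups a
    Wilcoxon rank-sum test compares the dispersion profiles; more than two
    groups is an error (use pairwise calls).
    """
    grouping = pd.Series(grouping)
    if len(grouping) != len(dm.ids):
        raise ValidationError("grouping length must match distance matrix")
    grouping.index = list(dm.ids)
    levels = list(pd.unique(grouping))
    if len(levels) > 2:
        raise ValidationError("more than 2 groups: run pairwise betadisper comparisons")
    ord_res = pcoa(dm)
    real = ord_res.coordinates.to_numpy()
    imag = ord_res.imaginary_coordinates.to_numpy()
    d2 = np.zeros(len(dm.ids))
    for lev in levels:
        idx = np.asarray(grouping == lev)
        cr = real[idx].mean(axis=0) if real.size else np.zeros(0)
        ci = imag[idx].mean(axis=0) if imag.size else np.zeros(0)
        dr = ((real[idx] - cr) ** 2).sum(axis=1) if real.size else 0.0
        di = ((imag[idx] - ci) ** 2).sum(axis=1) if imag.size else 0.0
        d2[idx] = np.clip(dr - di, 0.0, None)
    dist = pd.Series(np.sqrt(d2), index=list(dm.ids))
    stat = p = None
    if len(levels) == 2:
        a = dist[np.asarray(grouping == levels[0])]
        b = dist[np.asarray(grouping == levels[1])]
        res = st.mannwhitneyu(a, b, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
    return DispersionResult(dist, grouping, stat, p)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _term_columns(term: str, metadata: pd.DataFrame) -> np.ndarray:
    """Model-matrix columns for one term; ':' crosses factors.

    Factors enter as full one-hot codings (products span the complete
    cross-classification); the progressive orthogonalization against
    earlier terms and the intercept yields the correct degrees of freedom,
    so an interaction listed without its main effects absorbs the full
    cell-means space, matching sequential adonis2 models.
    """
    parts = term.split(":")
    blocks = []
    for p in parts:
        if p not in metadata.columns:
            raise ValidationError(f"term {term!r}: no metadata column {p!r}")
        col = metadata[p]
        if pd.api.types.is_numeric_dtype(col):
            blocks.append(col.to_numpy(dtype=float)[:, None])
        else:
            levels = sorted(pd.unique(col.astype(str)))
            blocks.append(np.column_stack(
                [(col.astype(str) == l).to_numpy(float) for l in levels]))
    out = blocks[0]
    for b in blocks[1:]:
        out = np.einsum("ij,ik->ijk", out, b).reshape(len(out), -1)
    return out


def permanova(
    dm: DistanceMatrix,
    metadata: pd.DataFrame,
    terms: list[str],
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Sequential (type-I) distance-based PERMANOVA over an ordered term list.

    Total SS is the trace of the Gower-centered matrix; each term's SS is
    the increment in explained trace of its projection. p-values use free
    permutation of rows with the conservative ">=" tie rule:
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm). Terms aliased by earlier
    terms get 0 df and no test.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    rng = rng or np.random.default_rng(0)
    ids = list(dm.ids)
    md = metadata.loc[ids]
    n = len(ids)
    g = _gower_center(np.asarray(dm.data, dtype=float))
    ss_total = float(np.trace(g))

    # progressive orthonormal basis; per-term column blocks
    basis = np.ones((n, 1)) / np.sqrt(n)
    blocks: list[np.ndarray] = []
    dfs: list[int] = []
    tol = 1e-9
    for term in terms:
        x = _term_columns(term, md)
        q_new = []
        for j in range(x.shape[1]):
            v = x[:, j].astype(float)
            stack = np.column_stack([basis] + q_new) if q_new else basis
            v = v - stack @ (stack.T @ v)
            v = v - stack @ (stack.T @ v)  # re-orthogonalize
            norm = np.linalg.norm(v)
            if norm > tol * max(1.0, np.linalg.norm(x[:, j])):
                q_new.append(v / norm)
        q_new = np.column_stack(q_new) if q_new else np.zeros((n, 0))
        blocks.append(q_new)
        dfs.append(q_new.shape[1])
        if q_new.shape[1]:
            basis = np.column_stack([basis, q_new])

    df_model = sum(dfs)
    df_res = n - 1 - df_model
    qall = np.column_stack([b for b in blocks if b.shape[1]]) if df_model else np.zeros((n, 0))
    slices = []
    start = 0
    for d in dfs:
        slices.append(slice(start, start + d))
        start += d

    def term_ss(g_mat: np.ndarray) -> np.ndarray:
        if not df_model:
            return np.zeros(len(terms))
        m = np.einsum("ij,ik,kj->j", qall, g_mat, qall)  # diag(Q^T G Q)
        return np.array([m[s].sum() for s in slices])

    ss_terms = term_ss(g)
    ss_res = ss_total - ss_terms.sum()

    def f_stats(ss_t: np.ndarray, ss_r: float) -> np.ndarray:
        out = np.full(len(terms), np.nan)
        for i, d in enumerate(dfs):
            if d and df_res > 0 and ss_r > 0:
                out[i] = (ss_t[i] / d) / (ss_r / df_res)
        return out

    f_obs = f_stats(ss_terms, ss_res)
    exceed = np.zeros(len(terms))
    tested = np.isfinite(f_obs)
    if tested.any():
        for _ in range(n_perm):
            perm = rng.permutation(n)
            gp = g[np.ix_(perm, perm)]
            ss_p = term_ss(gp)
            fp = f_stats(ss_p, ss_total - ss_p.sum())
            exceed += np.where(tested & (fp >= f_obs - 1e-12), 1.0, 0.0)
    pvals = np.where(tested, (1.0 + exceed) / (1.0 + n_perm), np.nan)

    rows = []
    for i, term in enumerate(terms):
        rows.append({
            "term": term, "df": dfs[i], "SumOfSqs": ss_terms[i],
            "R2": ss_terms[i] / ss_total if ss_total > 0 else 0.0,
            "F": f_obs[i], "p": pvals[i],
        })
    rows.append({"term": "Residual", "df": df_res, "SumOfSqs": ss_res,
                 "R2": ss_res / ss_total if ss_total > 0 else 0.0,
                 "F": np.nan, "p": np.nan})
    rows.append({"term": "Total", "df": n - 1, "SumOfSqs": ss_total,
                 "R2": 1.0, "F": np.nan, "p": np.nan})
    out = pd.DataFrame(rows).set_index("term")
    assert abs(out.loc[out.index != "Total", "R2"].sum() - 1.0) < 1e-9 or ss_total == 0
    return out
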