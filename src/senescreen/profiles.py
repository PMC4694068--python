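"""Induction-profile analytics: rescaling, Spearman correlograms, clustering.

Fold-change matrices (kinases × genes) admit three representations:

``linear``
    the canonical fold changes from :mod:`senescreen.qpcr`;
``log2``
    elementwise log2, the usual heatmap scale;
``scaled01``
    per-gene min-max "% induction": a fold change of 1 maps to 0, the gene's
    maximum fold change maps to 1, and values below 1 clip to 0 (the scale is
    defined on the [1, max] interval only).

Correlations are computed *between genes, across kinases* with Spearman's
rank correlation (midranks for ties) and two-sided p-values from the
t-statistic ``t = ρ·sqrt((n−2)/(1−ρ²))`` on n−2 degrees of freedom; an exact
permutation p-value is available for small n.  Genes are clustered
agglomeratively on the correlation distance 1 − ρ with average linkage.
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform

#: Largest sample count for which exact permutation p-values are enumerated.
EXACT_PERM_MAX_N = 9


def scale_induction(fc_column) -> np.ndarray:
    """Min-max rescale one gene's fold changes to a [0, 1] induction scale.

    ``s_i = (fc_i − 1) / (fc_max − 1)`` when ``fc_max > 1``, clipped below at
    0 (fold changes under 1 carry no induction); if no value exceeds 1 the
    whole column is 0.  Nonpositive fold changes are a hard error.
    """
    x = np.asarray(fc_column, dtype=float)
    if x.size == 0:
        raise ValueError("empty fold-change column")
    if not np.isfinite(x).all() or (x <= 0).any():
        raise ValueError("fold changes must be finite and > 0")
    fc_max = x.max()
    if fc_max <= 1:
        return np.zeros_like(x)
    s = (x - 1.0) / (fc_max - 1.0)
    if (s < 0).any():
        warnings.warn(
            "fold changes below 1 clipped to 0 on the induction scale",
            UserWarning,
            stacklevel=2,
        )
    return np.clip(s, 0.0, 1.0)


def scale_matrix(fc: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`scale_induction` per gene column; tagged ``scaled01``."""
    out = fc.apply(lambda col: pd.Series(scale_induction(col), index=col.index))
    out.attrs["representation"] = "scaled01"
    return out


def log2_matrix(fc: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2 of a fold-change matrix; the control row maps to 0."""
    vals = fc.to_numpy(dtype=float)
    if not np.isfinite(vals).all() or (vals <= 0).any():
        raise ValueError("fold changes must be finite and > 0")
    out = pd.DataFrame(np.log2(vals), index=fc.index, columns=fc.columns)
    out.attrs["representation"] = "log2"
    return out


@dataclass
class CorrelationResult:
    """Pairwise Spearman correlations between genes across kinases.

    ``rho`` and ``p`` are symmetric gene × gene DataFrames; the diagonal of
    ``rho`` is 1 and of ``p`` is 1 by convention.  ``n`` is the common number
    of observations (kinases).  Undefined correlations (constant columns)
    appear as NaN, never as a silent 0.
    """

    variables: list[str]
    rho: pd.DataFrame
    p: pd.DataFrame
    n: int

    def to_long(self) -> pd.DataFrame:
        """Long format (var_a, var_b, rho, p, n), upper triangle only."""
        rows = []
        for i, a in enumerate(self.variables):
            for b in self.variables[i + 1 :]:
                rows.append((a, b, self.rho.loc[a, b], self.p.loc[a, b], self.n))
        return pd.DataFrame(rows, columns=["var_a", "var_b", "rho", "p", "n"])


def _exact_perm_p(rx: np.ndarray, ry: np.ndarray) -> float:
    """Two-sided exact permutation p for Spearman ρ of two rank vectors."""
    n = rx.size
    cx = rx - rx.mean()
    cy = ry - ry.mean()
    denom = math.sqrt((cx**2).sum() * (cy**2).sum())
    if denom == 0:
        return float("nan")
    obs = abs(float(cx @ cy))
    hits = 0
    total = 0
    for perm in itertools.permutations(cy):
        total += 1
        if abs(float(cx @ np.array(perm))) >= obs - 1e-12:
            hits += 1
    return hits / total


def spearman_matrix(m: pd.DataFrame, p_mode: str = "t") -> CorrelationResult:
    """Spearman correlation matrix between the columns of ``m``.

    ρ is the Pearson correlation of midrank-transformed columns; p-values are
    two-sided from the t approximation (``p_mode="t"``, the default) or by
    exhaustive permutation for small n (``p_mode="exact"``, n ≤ 9).  Rank
    invariance makes the result identical for linear, log2 or any other
    strictly monotone representation of the fold changes.

    Constant columns have no rank variance: their correlations are reported
    as NaN with a warning.
    """
    n = len(m)
    if n < 3:
        raise ValueError("need at least 3 observations (kinases) per pair")
    if m.isna().any().any():
        raise ValueError("matrix must be complete (no NaN)")
    if p_mode not in ("t", "exact"):
        raise ValueError("p_mode must be 't' or 'exact'")
    if p_mode == "exact" and n > EXACT_PERM_MAX_N:
        raise ValueError(f"exact permutation p limited to n <= {EXACT_PERM_MAX_N}")
    genes = list(m.columns)
    vals = m.to_numpy(dtype=float)
    ranks = np.apply_along_axis(stats.rankdata, 0, vals)  # midranks for ties
    sd = ranks.std(axis=0)
    constant = sd == 0
    if constant.any():
        names = [g for g, c in zip(genes, constant) if c]
        warnings.warn(
            f"constant column(s) {names}: Spearman ρ undefined, reported as NaN",
            UserWarning,
            stacklevel=2,
        )
    k = len(genes)
    rho = np.full((k, k), np.nan)
    ok = ~constant
    if ok.sum() >= 1:
        sub = np.corrcoef(ranks[:, ok], rowvar=False)
        sub = np.atleast_2d(sub)
        rho[np.ix_(ok, ok)] = sub
    np.fill_diagonal(rho, 1.0)
    rho = np.clip(rho, -1.0, 1.0)
    # snap float-noise |rho| ~ 1 (identical/reversed rankings) to exact +/-1
    near_one = np.abs(np.abs(rho) - 1.0) < 5e-15
    rho[near_one] = np.sign(rho[near_one])

    p = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            r = rho[i, j]
            if np.isnan(r):
                continue
            if p_mode == "exact":
                p[i, j] = p[j, i] = _exact_perm_p(ranks[:, i], ranks[:, j])
            elif abs(r) >= 1.0:
                p[i, j] = p[j, i] = 0.0
            else:
                t = r * math.sqrt((n - 2) / (1.0 - r * r))
                p[i, j] = p[j, i] = 2.0 * stats.t.sf(abs(t), n - 2)
    np.fill_diagonal(p, 1.0)
    return CorrelationResult(
        variables=genes,
        rho=pd.DataFrame(rho, index=genes, columns=genes),
        p=pd.DataFrame(p, index=genes, columns=genes),
        n=n,
    )


@dataclass
class DendrogramResult:
    """Agglomerative clustering of genes by induction profile.

    Wraps a SciPy linkage matrix together with the leaf labels, the distance
    metric and linkage names.  ``merges`` lists (node_a, node_b, height,
    size) for each of the leaves − 1 agglomerations.
    """

    linkage_matrix: np.ndarray
    labels: list[str]
    metric: str = "1 - spearman rho"
    method: str = "average"

    @property
    def merges(self) -> list[tuple[int, int, float, int]]:
        return [
            (int(a), int(b), float(h), int(s)) for a, b, h, s in self.linkage_matrix
        ]

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in leaves_list(self.linkage_matrix)]

    def cut(self, n_clusters: int) -> pd.Series:
        """Flat cluster labels (1..n_clusters) from cutting the tree."""
        flat = fcluster(self.linkage_matrix, t=n_clusters, criterion="maxclust")
        return pd.Series(flat, index=self.labels, name="cluster")

    def to_newick(self) -> str:
        """Newick string with leaf labels and branch lengths."""
        from skbio.tree import TreeNode  # deferred: heavy import

        tree = TreeNode.from_linkage_matrix(self.linkage_matrix, self.labels)
        return str(tree).strip()


def cluster_profiles(
    m: pd.DataFrame, metric: str = "spearman", method: str = "average"
) -> DendrogramResult:
    """Cluster gene columns on correlation distance 1 − ρ, average linkage.

    Deterministic: the first merge joins the most correlated gene pair.  An
    undefined pairwise correlation (constant column) is a hard error — drop
    constant columns before clustering.
    """
    if m.shape[1] < 2:
        raise ValueError("need at least 2 gene columns to cluster")
    if metric != "spearman":
        raise ValueError("only the Spearman correlation distance is supported")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        corr = spearman_matrix(m)
    rho = corr.rho.to_numpy()
    if np.isnan(rho).any():
        raise ValueError(
            "undefined pairwise correlation (constant column); drop constant "
            "columns before clustering"
        )
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = linkage(condensed, method=method)
    return DendrogramResult(
        linkage_matrix=Z,
        labels=list(m.columns),
        metric="1 - spearman rho",
        method=method,
    )
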