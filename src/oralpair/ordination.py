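"""Distances, PCoA, silhouettes, hierarchical clustering, and the ordination
parameter sweep.

The sweep mirrors how an ordination model is chosen for a paired cohort: for
every (transform, distance) combination it records the Spearman correlation
of the first axis with library size (an artifact signal to minimise), the
median silhouette width within each specimen type (separation to maximise)
and the percent variance of the first two axes, then ranks combinations
lexicographically by (|rho| ascending, silhouette sum descending).
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from .tables import CountTable, SampleMetadata
from .transforms import AbundanceMatrix, as_matrix, clr, tss

METRICS = ("bray_curtis", "jaccard", "euclidean")


@dataclasses.dataclass
class DistanceMatrix:
    samples: list[str]
    values: np.ndarray  # symmetric, zero diagonal
    metric: str


@dataclasses.dataclass
class OrdinationResult:
    samples: list[str]
    coordinates: np.ndarray  # samples x axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    percent_variance: np.ndarray  # over positive eigenvalues only
    rho_axis1_library: float | None = None
    silhouette_by_type: dict | None = None
    truncated: bool = False


def distance_matrix(am: AbundanceMatrix, metric: str) -> DistanceMatrix:
    """Pairwise sample distances on the columns of ``am``.

    Jaccard operates on presence/absence of the values; Bray-Curtis requires
    non-negative values and errors on a pair of all-zero samples.
    """
    if metric not in METRICS:
        raise ValueError(f"unsupported metric {metric!r}")
    X = am.values.T  # samples x taxa
    if metric == "euclidean":
        d = squareform(pdist(X, "euclidean"))
    elif metric == "jaccard":
        d = squareform(pdist(X != 0, "jaccard"))
    else:
        if np.any(X < 0):
            raise ValueError("bray_curtis requires non-negative values")
        totals = X.sum(axis=1)
        zero = np.flatnonzero(totals == 0)
        if zero.size >= 2:
            a, b = am.samples[zero[0]], am.samples[zero[1]]
            raise ValueError(f"bray_curtis undefined for all-zero pair ({a!r}, {b!r})")
        d = squareform(pdist(X, "braycurtis"))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(am.samples), d, metric)


def pcoa(d: DistanceMatrix, n_axes: int = 2) -> OrdinationResult:
    """Classical (metric) multidimensional scaling by Gower double-centering.

    Negative eigenvalues are reported but excluded from the coordinates and
    from the percent-variance denominator.  Each retained axis is oriented so
    that its largest-magnitude coordinate is positive.
    """
    if n_axes < 1:
        raise ValueError("n_axes must be >= 1")
    D = d.values
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    B = (B + B.T) / 2.0
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-10, 1e-10 * abs(eigval[0]) if eigval.size else 0.0)
    pos = eigval > tol
    n_pos = int(pos.sum())
    truncated = n_axes > n_pos
    k = min(n_axes, n_pos)
    coords = eigvec[:, :k] * np.sqrt(eigval[:k])
    for j in range(k):
        i_max = int(np.argmax(np.abs(coords[:, j])))
        if coords[i_max, j] < 0:
            coords[:, j] = -coords[:, j]
    pos_sum = eigval[pos].sum()
    pct = (eigval[:k] / pos_sum * 100.0) if pos_sum > 0 else np.zeros(k)
    return OrdinationResult(list(d.samples), coords, eigval, pct, truncated=truncated)


def silhouette_by_group(d: DistanceMatrix, groups: Mapping[str, str]) -> dict[str, float]:
    """Median per-sample silhouette width per group.

    s = (b - a) / max(a, b) with a = mean within-group distance (self
    excluded) and b = min over other groups of the mean distance to that
    group.  Singletons and the fully degenerate a = b = 0 case score 0.
    """
    labels = np.array([groups[s] for s in d.samples])
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least two groups")
    D = d.values
    sil = np.zeros(len(labels))
    for i in range(len(labels)):
        own = labels[i]
        own_mask = labels == own
        n_own = own_mask.sum()
        if n_own == 1:
            sil[i] = 0.0
            continue
        a = D[i, own_mask].sum() / (n_own - 1)
        b = min(D[i, labels == g].mean() for g in uniq if g != own)
        denom = max(a, b)
        sil[i] = 0.0 if denom == 0 else (b - a) / denom
    return {g: float(np.median(sil[labels == g])) for g in uniq}


def spearman_axis_vs_library(ordn: OrdinationResult, md: SampleMetadata) -> float:
    """Spearman rho between axis-1 coordinates and library size (NaN if undefined)."""
    if ordn.coordinates.shape[1] < 1:
        raise ValueError("ordination has no axes")
    axis1 = ordn.coordinates[:, 0]
    lib = md.frame.loc[ordn.samples, "library_size"].to_numpy(dtype=float)
    if np.all(axis1 == axis1[0]) or np.all(lib == lib[0]):
        return float("nan")
    rho, _ = stats.spearmanr(axis1, lib)
    return float(rho)


_TRANSFORMS: dict[str, Callable[[CountTable], AbundanceMatrix]] = {
    "tss": tss,
    "clr": clr,
    "raw": as_matrix,
}

#: combinations whose distance is undefined or degenerate on the transform
_INVALID = {
    ("clr", "bray_curtis"): "bray_curtis requires non-negative values",
    ("clr", "jaccard"): "jaccard presence/absence is degenerate on dense clr values",
}


def ordination_sweep(
    ct: CountTable,
    md: SampleMetadata,
    transforms: tuple[str, ...] = ("tss", "clr"),
    metrics: tuple[str, ...] = METRICS,
    n_axes: int = 2,
) -> pd.DataFrame:
    """Evaluate every (transform, metric) combination and rank them.

    Ranking is lexicographic: ascending |rho(axis1, library size)| then
    descending sum of per-type median silhouettes.  Skipped combinations are
    kept in the table with the reason and no rank.
    """
    if not transforms or not metrics:
        raise ValueError("transform and metric grids must be non-empty")
    groups = md.frame["specimen_type"].to_dict()
    rows = []
    for tr in transforms:
        if tr not in _TRANSFORMS:
            raise ValueError(f"unsupported transform {tr!r}")
        am = _TRANSFORMS[tr](ct)
        for metric in metrics:
            row: dict = {"transform": tr, "metric": metric}
            reason = _INVALID.get((tr, metric))
            if reason is None:
                try:
                    d = distance_matrix(am, metric)
                    ordn = pcoa(d, n_axes=n_axes)
                    rho = spearman_axis_vs_library(ordn, md)
                    sil = silhouette_by_group(d, groups)
                except ValueError as exc:
                    reason = str(exc)
            if reason is not None:
                row.update({"skipped": reason})
                rows.append(row)
                continue
            if np.isnan(rho):
                row.update({"skipped": "axis-1/library correlation undefined"})
                rows.append(row)
                continue
            row.update(
                {
                    "rho": rho,
                    "abs_rho": abs(rho),
                    "silhouette_plaque": sil.get("plaque", np.nan),
                    "silhouette_abscess": sil.get("abscess", np.nan),
                    "silhouette_sum": sil.get("plaque", 0.0) + sil.get("abscess", 0.0),
                    "pct_axis1": ordn.percent_variance[0] if len(ordn.percent_variance) > 0 else np.nan,
                    "pct_axis2": ordn.percent_variance[1] if len(ordn.percent_variance) > 1 else np.nan,
                    "skipped": "",
                }
            )
            rows.append(row)
    table = pd.DataFrame(rows)
    ok = table[table["skipped"] == ""].copy() if "skipped" in table else table.iloc[0:0]
    if len(ok) == 0:
        raise ValueError("every sweep combination was skipped")
    ok = ok.sort_values(["abs_rho", "silhouette_sum"], ascending=[True, False], kind="stable")
    ranks = {idx: r + 1 for r, idx in enumerate(ok.index)}
    table["rank"] = [ranks.get(i, np.nan) for i in table.index]
    table["top"] = table["rank"] == 1
    return table.reset_index(drop=True)


def hierarchical_cluster(am: AbundanceMatrix) -> tuple[np.ndarray, list[str]]:
    """Average-linkage clustering of samples on 1 - Pearson r of log abundances.

    ``am`` should be TSS values; a per-matrix pseudocount of half the smallest
    nonzero value is added before the log.  Returns (scipy linkage matrix,
    sample ids).
    """
    X = am.values
    if X.shape[1] < 2:
        raise ValueError("need at least two samples to cluster")
    nz = X[X > 0]
    pseudo = (nz.min() / 2.0) if nz.size else 1e-9
    L = np.log(X + pseudo)
    sd = L.std(axis=0)
    if np.any(sd == 0):
        bad = am.samples[int(np.argmax(sd == 0))]
        raise ValueError(f"sample {bad!r} has zero variance after log transform")
    corr = np.corrcoef(L.T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="average")
    return Z, list(am.samples)
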