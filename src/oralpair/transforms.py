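"""Compositional transforms, alpha diversity, and paired-test machinery.

Three transforms are exposed, each tagged on the returned matrix:

* ``tss`` — total-sum scaling (relative abundance): columns divided by their
  sums.
* ``clr`` — centered log-ratio on half-count-shifted counts:
  ``ln(x + c) - mean(ln(x + c))`` per column, pseudocount ``c = 0.5``.
* ``css_log`` — a cumulative-sum-scaling dialect: per sample, counts are
  divided by the sum of counts at or below the chosen quantile of that
  sample's nonzero counts, rescaled by a constant, then shifted-log
  transformed ``ln(x + 1)``.

The Wilcoxon signed-rank test uses the exact null distribution (dynamic
program over rank sums, identical to enumerating all 2^n sign patterns)
whenever n <= 25 effective pairs and the absolute differences are tie-free,
and otherwise a normal approximation with mid-ranks, tie correction and
continuity correction.  Natural logs throughout (Shannon, CLR).
"""

from __future__ import annotations

import dataclasses
import math
from functools import lru_cache

import numpy as np
from scipy import stats

from .tables import CountTable


@dataclasses.dataclass
class AbundanceMatrix:
    values: np.ndarray  # taxa x samples, float
    taxa: list[str]
    samples: list[str]
    transform: str  # "raw" | "tss" | "clr" | "css_log"


def as_matrix(ct: CountTable) -> AbundanceMatrix:
    return AbundanceMatrix(ct.counts.astype(float), list(ct.taxa), list(ct.samples), "raw")


def tss(ct: CountTable) -> AbundanceMatrix:
    """Relative abundance: each sample column divided by its total."""
    totals = ct.counts.sum(axis=0)
    if np.any(totals <= 0):
        bad = ct.samples[int(np.argmax(totals <= 0))]
        raise ValueError(f"sample {bad!r} has zero total count; cannot TSS-normalize")
    vals = ct.counts / totals
    return AbundanceMatrix(vals, list(ct.taxa), list(ct.samples), "tss")


def clr(ct: CountTable, pseudocount: float = 0.5) -> AbundanceMatrix:
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    logs = np.log(ct.counts + pseudocount)
    vals = logs - logs.mean(axis=0, keepdims=True)
    return AbundanceMatrix(vals, list(ct.taxa), list(ct.samples), "clr")


def _css_scale(col: np.ndarray, quantile: float) -> float:
    nz = col[col > 0]
    if nz.size == 0:
        raise ValueError("sample with all-zero counts; cannot CSS-normalize")
    q = np.quantile(nz, quantile)
    return float(col[col <= q].sum())


def css_log(ct_or_values, quantile: float = 0.5, scale_const: float = 1000.0) -> AbundanceMatrix:
    """Cumulative-sum scaling followed by ln(x + 1)."""
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    if isinstance(ct_or_values, CountTable):
        values = ct_or_values.counts.astype(float)
        taxa, samples = list(ct_or_values.taxa), list(ct_or_values.samples)
    else:
        values = np.asarray(ct_or_values, dtype=float)
        taxa = [f"t{i}" for i in range(values.shape[0])]
        samples = [f"s{j}" for j in range(values.shape[1])]
    scales = np.array([_css_scale(values[:, j], quantile) for j in range(values.shape[1])])
    vals = np.log(values / scales * scale_const + 1.0)
    return AbundanceMatrix(vals, taxa, samples, "css_log")


def css_scaled(values: np.ndarray, quantile: float = 0.5, scale_const: float = 1000.0) -> np.ndarray:
    """CSS scaling only (no log shift), for engines that apply their own log."""
    values = np.asarray(values, dtype=float)
    scales = np.array([_css_scale(values[:, j], quantile) for j in range(values.shape[1])])
    return values / scales * scale_const


def shannon(ct: CountTable) -> np.ndarray:
    """Shannon index H = -sum p ln p per sample (natural log)."""
    totals = ct.counts.sum(axis=0)
    if np.any(totals <= 0):
        bad = ct.samples[int(np.argmax(totals <= 0))]
        raise ValueError(f"sample {bad!r} has zero total count")
    p = ct.counts / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return -terms.sum(axis=0)


def observed_richness(ct: CountTable) -> np.ndarray:
    return (ct.counts > 0).sum(axis=0)


@dataclasses.dataclass
class PairedTestResult:
    statistic: float  # signed-rank sum W+ (sum of ranks of positive differences)
    n_effective: int
    p_value: float
    method: str  # "exact" | "normal_approx"
    degenerate: bool = False  # all differences zero


@lru_cache(maxsize=64)
def _exact_wplus_pmf(n: int) -> np.ndarray:
    """Null pmf of W+ for n tie-free pairs via DP (counts / 2^n)."""
    max_w = n * (n + 1) // 2
    counts = np.zeros(max_w + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        new = counts.copy()
        new[r:] += counts[:-r] if r > 0 else counts
        counts = new
    return counts / 2.0**n


def exact_signed_rank_p(w_plus: float, n: int) -> float:
    """Two-sided exact p for integer W+ with tie-free ranks 1..n."""
    pmf = _exact_wplus_pmf(n)
    w = int(round(w_plus))
    lower = pmf[: w + 1].sum()
    upper = pmf[w:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def wilcoxon_signed_rank(diffs: np.ndarray) -> PairedTestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped.  If every difference is zero the result is
    degenerate with p = 1.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return PairedTestResult(0.0, 0, 1.0, "exact", degenerate=True)
    absd = np.abs(d)
    ranks = stats.rankdata(absd)
    w_plus = float(ranks[d > 0].sum())
    has_ties = np.unique(absd).size < n
    if n <= 25 and not has_ties:
        return PairedTestResult(w_plus, n, exact_signed_rank_p(w_plus, n), "exact")
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(absd, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return PairedTestResult(w_plus, n, 1.0, "normal_approx", degenerate=True)
    # continuity correction: shrink |W+ - mean| by 0.5 toward the mean
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / math.sqrt(var)
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return PairedTestResult(w_plus, n, p, "normal_approx")


def signed_rank_p_rows(diffs: np.ndarray) -> np.ndarray:
    """Row-wise two-sided signed-rank p-values for a (features x pairs) matrix.

    Same branch rules as :func:`wilcoxon_signed_rank`; vectorised over rows
    via the cached exact distribution so Monte-Carlo engines stay fast.
    """
    diffs = np.asarray(diffs, dtype=float)
    out = np.empty(diffs.shape[0])
    for i, row in enumerate(diffs):
        out[i] = wilcoxon_signed_rank(row).p_value
    return out


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(adjusted, 1.0)
    return q
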