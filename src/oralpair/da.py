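"""Paired differential abundance with a three-method consensus vote.

Three routes to a per-taxon significance call:

* :func:`paired_wilcoxon_per_taxon` — signed-rank test on per-patient
  differences of TSS values, BH-corrected across taxa.
* :func:`engine_clr_wilcoxon` — a Monte-Carlo compositional engine: per
  instance, each sample's composition is drawn from Dirichlet(counts + 0.5),
  CSS-scaled, log10-transformed, and paired-signed-rank tested per taxon;
  the reported p is the mean over instances (a posterior-expected p).
* :func:`engine_linear_model` — OLS of css_log abundance on a specimen-type
  indicator with per-patient intercepts, honouring the pairing.

Consensus tiers follow the agreement count: significant in all supplied
methods (>= 3 supplied) = high, all-but-one = medium, exactly one = low,
otherwise none.  Methods that disagree on the direction of a taxon they both
call significant demote it to none with a conflict flag.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .tables import CountTable, SampleMetadata, paired_arrays
from .transforms import bh_fdr, css_scaled, css_log, signed_rank_p_rows, tss, wilcoxon_signed_rank

Q_THRESHOLD = 0.05


@dataclasses.dataclass
class PairedCohort:
    """A filtered count table plus metadata with validated patient pairing."""

    ct: CountTable
    md: SampleMetadata

    def __post_init__(self) -> None:
        self.md.pairs()  # raises PairingError if malformed

    @property
    def n_pairs(self) -> int:
        return len(self.md.pairs())


def _effects_and_directions(plaque: np.ndarray, abscess: np.ndarray) -> tuple[np.ndarray, list[str]]:
    diffs = plaque - abscess
    effects = np.median(diffs, axis=1)
    directions = ["plaque" if e > 0 else "abscess" if e < 0 else "none" for e in effects]
    return effects, directions


def paired_wilcoxon_per_taxon(cohort: PairedCohort) -> pd.DataFrame:
    """Per-taxon signed-rank test on paired TSS differences (plaque - abscess)."""
    if cohort.n_pairs < 5:
        raise ValueError("need at least 5 pairs for the paired test")
    vals = tss(cohort.ct).values
    _, plaque, abscess = paired_arrays(cohort.ct, cohort.md, vals)
    diffs = plaque - abscess
    results = [wilcoxon_signed_rank(row) for row in diffs]
    p = np.array([r.p_value for r in results])
    q = bh_fdr(p)
    effects, directions = _effects_and_directions(plaque, abscess)
    return pd.DataFrame(
        {
            "taxon": cohort.ct.taxa,
            "effect": effects,
            "direction": directions,
            "p": p,
            "q": q,
            "significant": q < Q_THRESHOLD,
            "degenerate": [r.degenerate for r in results],
        }
    ).set_index("taxon")


def top_k_by_median_difference(report: pd.DataFrame, k: int = 15) -> pd.DataFrame:
    """Top-k significant taxa by |median paired difference|.

    Ties break by q ascending then taxon name.  Returns fewer than k rows
    (all significant taxa) when fewer reach significance.
    """
    sig = report[report["q"] < Q_THRESHOLD].copy()
    sig["abs_effect"] = sig["effect"].abs()
    sig = (
        sig.reset_index()
        .sort_values(["abs_effect", "q", "taxon"], ascending=[False, True, True], kind="stable")
        .set_index("taxon")
    )
    return sig.drop(columns=["abs_effect"]).head(k)


def enrichment_tallies(cohort: PairedCohort) -> pd.DataFrame:
    """Per taxon: number of pairs with plaque TSS higher, lower, and tied."""
    vals = tss(cohort.ct).values
    _, plaque, abscess = paired_arrays(cohort.ct, cohort.md, vals)
    return pd.DataFrame(
        {
            "taxon": cohort.ct.taxa,
            "n_plaque_higher": (plaque > abscess).sum(axis=1),
            "n_abscess_higher": (plaque < abscess).sum(axis=1),
            "n_tied": (plaque == abscess).sum(axis=1),
        }
    ).set_index("taxon")


def engine_clr_wilcoxon(
    cohort: PairedCohort, n_mc: int = 128, seed: int = 0
) -> pd.DataFrame:
    """Monte-Carlo Dirichlet-instance engine (CSS + log10 + paired signed-rank)."""
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    rng = np.random.default_rng(seed)
    counts = cohort.ct.counts.astype(float)
    n_taxa, n_samples = counts.shape
    pairs = cohort.md.pairs()
    col = {s: i for i, s in enumerate(cohort.ct.samples)}
    p_idx = [col[pairs.loc[pid, "plaque"]] for pid in pairs.index]
    a_idx = [col[pairs.loc[pid, "abscess"]] for pid in pairs.index]

    # taxa whose raw counts are identical in every pair carry no paired signal;
    # any call on them would be pure resampling noise, so they are fixed at p=1
    no_signal = np.all(counts[:, p_idx] == counts[:, a_idx], axis=1)

    p_sum = np.zeros(n_taxa)
    for _ in range(n_mc):
        gam = rng.standard_gamma(counts + 0.5)
        comp = gam / gam.sum(axis=0, keepdims=True)
        scaled = css_scaled(comp)
        logged = np.log10(scaled)
        diffs = logged[:, p_idx] - logged[:, a_idx]
        p_sum += signed_rank_p_rows(diffs)
    p = np.where(no_signal, 1.0, p_sum / n_mc)
    q = bh_fdr(p)
    vals = tss(cohort.ct).values
    _, plaque, abscess = paired_arrays(cohort.ct, cohort.md, vals)
    effects, directions = _effects_and_directions(plaque, abscess)
    return pd.DataFrame(
        {
            "taxon": cohort.ct.taxa,
            "effect": effects,
            "direction": directions,
            "p": p,
            "q": q,
            "significant": q < Q_THRESHOLD,
        }
    ).set_index("taxon")


def paired_ols(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS of each row of Y on specimen type with per-patient intercepts.

    ``Y`` is features x (2 * n_pairs), columns ordered (plaque, abscess) per
    patient.  Returns (type coefficient, two-sided p, degenerate flag).  For
    this balanced design the coefficient equals the mean per-patient
    difference; p comes from the t distribution at the residual df.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n_obs = Y.shape[1]
    if n_obs % 2 or n_obs < 4:
        raise ValueError("paired_ols needs >= 2 pairs (rank-deficient otherwise)")
    n_pairs = n_obs // 2
    X = np.zeros((n_obs, 1 + n_pairs))
    X[:, 0] = 1.0
    X[::2, 1] = 1.0  # specimen-type indicator (plaque columns)
    for j in range(1, n_pairs):
        X[2 * j : 2 * j + 2, 1 + j] = 1.0
    df_resid = n_obs - X.shape[1]
    XtX_inv = np.linalg.pinv(X.T @ X)
    H = XtX_inv @ X.T
    betas = Y @ H.T  # features x params
    resid = Y - betas @ X.T
    sigma2 = (resid**2).sum(axis=1) / df_resid
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[1, 1], 0.0))
    coef = betas[:, 1]
    degenerate = se <= 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(degenerate, 0.0, coef / np.where(degenerate, 1.0, se))
    p = np.where(degenerate, 1.0, 2.0 * stats.t.sf(np.abs(tstat), df_resid))
    return coef, p, degenerate


def engine_linear_model(cohort: PairedCohort) -> pd.DataFrame:
    """OLS of css_log abundance on specimen type with per-patient intercepts.

    The type coefficient is the plaque-minus-abscess shift; for a balanced
    paired design it equals the mean per-patient difference, and its t-test
    against the residual degrees of freedom gives the p-value.
    """
    pairs = cohort.md.pairs()
    if len(pairs) < 2:
        raise ValueError("linear-model engine needs >= 2 pairs (rank-deficient otherwise)")
    am = css_log(cohort.ct)
    col = {s: i for i, s in enumerate(cohort.ct.samples)}
    sample_order = [
        col[pairs.loc[pid, stype]] for pid in pairs.index for stype in ("plaque", "abscess")
    ]
    Y = am.values[:, sample_order]  # taxa x (2*n_pairs), (plaque, abscess) per patient
    coef, p, degenerate = paired_ols(Y)
    q = bh_fdr(p)
    vals = tss(cohort.ct).values
    _, plaque, abscess = paired_arrays(cohort.ct, cohort.md, vals)
    effects, directions = _effects_and_directions(plaque, abscess)
    return pd.DataFrame(
        {
            "taxon": cohort.ct.taxa,
            "coef": coef,
            "effect": effects,
            "direction": directions,
            "p": p,
            "q": q,
            "significant": q < Q_THRESHOLD,
            "degenerate": degenerate,
        }
    ).set_index("taxon")


def consensus_tier(
    flags: Mapping[str, Mapping[str, bool]],
    directions: Mapping[str, Mapping[str, str]],
) -> pd.DataFrame:
    """Vote per-method significance calls into confidence tiers.

    ``flags[method][taxon]`` is the significance call; ``directions`` gives
    each method's direction for taxa it calls significant.  Taxa absent from
    a method's map count as not significant for that method.
    """
    if not flags:
        raise ValueError("need at least one method")
    methods = list(flags)
    n_methods = len(methods)
    taxa = sorted(set().union(*[set(f) for f in flags.values()]))
    rows = []
    for t in taxa:
        calls = [bool(flags[m].get(t, False)) for m in methods]
        n_sig = sum(calls)
        dirs = {
            directions[m][t]
            for m, c in zip(methods, calls)
            if c and m in directions and t in directions[m]
        } - {"none"}
        conflict = len(dirs) > 1
        if conflict:
            tier = "none"
        elif n_sig == n_methods and n_methods >= 3:
            tier = "high"
        elif n_sig == n_methods - 1 and n_sig >= 1 or (n_methods == 3 and n_sig == 2):
            tier = "medium"
        elif n_sig == 1:
            tier = "low"
        else:
            tier = "none"
        rows.append(
            {
                "taxon": t,
                "n_significant": n_sig,
                "tier": tier,
                "direction": dirs.pop() if len(dirs) == 1 else "none",
                "direction_conflict": conflict,
                **{f"sig_{m}": c for m, c in zip(methods, calls)},
            }
        )
    return pd.DataFrame(rows).set_index("taxon")


def read_external_calls(path) -> tuple[dict[str, bool], dict[str, str]]:
    """Import an external call set: TSV of (taxon, significant, direction)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for colname in ("taxon", "significant", "direction"):
        if colname not in df.columns:
            raise ValueError(f"external call set missing column {colname!r}")
    flags = {
        r["taxon"]: str(r["significant"]).strip().lower() in ("1", "true", "yes")
        for _, r in df.iterrows()
    }
    dirs = {r["taxon"]: r["direction"] for _, r in df.iterrows()}
    return flags, dirs


def run_consensus(
    cohort: PairedCohort, n_mc: int = 128, seed: int = 0
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Run the three built-in methods and vote tiers; returns (tiers, reports)."""
    reports = {
        "wilcoxon": paired_wilcoxon_per_taxon(cohort),
        "clr_wilcoxon": engine_clr_wilcoxon(cohort, n_mc=n_mc, seed=seed),
        "linear_model": engine_linear_model(cohort),
    }
    flags = {m: r["significant"].to_dict() for m, r in reports.items()}
    dirs = {m: r["direction"].to_dict() for m, r in reports.items()}
    tiers = consensus_tier(flags, dirs)
    return tiers, reports
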