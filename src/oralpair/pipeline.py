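"""End-to-end orchestration: three input TSVs -> a results directory.

Stages run in order — filter, rank agglomeration, alpha diversity, the
ordination sweep plus the chosen ordination and clustering, paired
differential abundance with consensus tiers, scaling/K selection and the
final topic model, cross-validated classification, and (when a pathway map
is supplied) over-representation.  Every artifact is a TSV or JSON file; a
manifest records config, seed, and the SHA-256 of every output so two runs
at the same seed can be compared hash-for-hash.

A light resume mechanism skips a stage when all its outputs exist and the
manifest on disk recorded the same stage-input hash (config + upstream
hashes); deleting downstream outputs therefore re-runs only those stages.

Randomness: one global seed fans out to per-stage seeds derived by hashing
the stage name, so adding a stage never perturbs another stage's stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import classify, da, lda, ordination as ordn, tables, transforms


@dataclasses.dataclass
class RunConfig:
    counts: Path
    metadata: Path
    taxonomy: Path
    out_dir: Path
    contaminants: Path | None = None
    pathway_map: Path | None = None
    sig_items: Path | None = None  # optional: significant item ids for ORA (one per line)
    ranks: tuple[str, ...] = ("phylum", "genus", "species")
    da_rank: str = "genus"
    min_reads: int = 1000
    q_threshold: float = 0.05
    k_grid: tuple[int, ...] = tuple(range(2, 13))
    s_grid: tuple[int, ...] = (10, 100, 1000, 10000)
    k_for_scaling: int = 6
    lda_iterations: int = 2000
    lda_burn_in: int = 1000
    lda_thin: int = 50
    selection_iterations: int = 800
    selection_burn_in: int = 400
    selection_thin: int = 40
    n_mc: int = 128
    sweep_transforms: tuple[str, ...] = ("tss", "clr")
    sweep_metrics: tuple[str, ...] = ("bray_curtis", "jaccard", "euclidean")
    n_folds: int = 4
    seed: int = 0


def validate_config(cfg: RunConfig) -> list[str]:
    """Check every invariant; return all violations at once (empty = ok)."""
    errors = []
    if not 0 < cfg.q_threshold < 1:
        errors.append(f"q_threshold must lie in (0,1), got {cfg.q_threshold}")
    if cfg.min_reads < 0:
        errors.append(f"min_reads must be >= 0, got {cfg.min_reads}")
    if not cfg.k_grid:
        errors.append("k_grid must be non-empty")
    elif min(cfg.k_grid) < 2:
        errors.append("k_grid entries must be >= 2")
    if not cfg.s_grid:
        errors.append("s_grid must be non-empty")
    if not cfg.ranks:
        errors.append("ranks must be non-empty")
    for r in cfg.ranks:
        if r not in tables.RANKS:
            errors.append(f"unknown rank {r!r}")
    if cfg.da_rank not in tables.RANKS:
        errors.append(f"unknown da_rank {cfg.da_rank!r}")
    if cfg.lda_iterations <= cfg.lda_burn_in:
        errors.append("lda_iterations must exceed lda_burn_in")
    if cfg.selection_iterations <= cfg.selection_burn_in:
        errors.append("selection_iterations must exceed selection_burn_in")
    if cfg.n_folds < 2:
        errors.append("n_folds must be >= 2")
    if not cfg.sweep_transforms or not cfg.sweep_metrics:
        errors.append("sweep grids must be non-empty")
    return errors


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the global seed and the stage name."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class _Run:
    """Bookkeeping for one pipeline run (manifest, log, resume)."""

    def __init__(self, cfg: RunConfig):
        self.cfg = cfg
        self.out = Path(cfg.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "config": {k: str(v) if isinstance(v, Path) else v for k, v in dataclasses.asdict(cfg).items()},
            "seed": cfg.seed,
            "stages": {},
            "files": {},
        }
        self.previous = None
        mpath = self.out / "manifest.json"
        if mpath.exists():
            try:
                self.previous = json.loads(mpath.read_text())
            except json.JSONDecodeError:
                self.previous = None
        self.log: list[dict] = []

    def input_hash(self, stage: str, upstream: Sequence[str]) -> str:
        h = hashlib.sha256()
        h.update(json.dumps(self.manifest["config"], sort_keys=True).encode())
        for name in upstream:
            h.update(name.encode())
            h.update(self.manifest["files"].get(name, "").encode())
        return h.hexdigest()

    def can_skip(self, stage: str, in_hash: str, outputs: Sequence[str]) -> bool:
        if self.previous is None:
            return False
        prev = self.previous.get("stages", {}).get(stage)
        if not prev or prev.get("input_hash") != in_hash:
            return False
        for name in outputs:
            p = self.out / name
            if not p.exists() or _sha256(p) != self.previous.get("files", {}).get(name):
                return False
        return True

    def record(self, stage: str, in_hash: str, outputs: Sequence[str], cached: bool, t0: float) -> None:
        for name in outputs:
            self.manifest["files"][name] = _sha256(self.out / name)
        self.manifest["stages"][stage] = {"input_hash": in_hash, "outputs": list(outputs)}
        self.log.append(
            {"stage": stage, "cached": cached, "seconds": round(time.time() - t0, 3),
             "outputs": list(outputs)}
        )

    def flush(self) -> None:
        (self.out / "manifest.json").write_text(json.dumps(self.manifest, indent=1, sort_keys=True))
        (self.out / "run_log.json").write_text(json.dumps(self.log, indent=1))


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dict."""
    errors = validate_config(cfg)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    run = _Run(cfg)
    out = run.out

    def _write_df(df: pd.DataFrame, name: str, index_label: str | None = None) -> str:
        df.to_csv(out / name, sep="\t", index_label=index_label)
        return name

    # ---- stage: filter -------------------------------------------------
    stage = "filter"
    t0 = time.time()
    try:
        ct, md, tax = tables.read_tables(cfg.counts, cfg.metadata, cfg.taxonomy)
        contaminants: list[str] = []
        if cfg.contaminants:
            contaminants = [
                line.strip() for line in Path(cfg.contaminants).read_text().splitlines()
                if line.strip() and not line.startswith("#")
            ]
        ct, md, flog = tables.filter_cohort(ct, md, contaminants, cfg.min_reads)
        tables.write_tables(out / "filtered", ct, md, tax)
        tables.write_filter_log(flog, out / "filter_log.jsonl")
        outputs = ["filtered/counts.tsv", "filtered/metadata.tsv", "filtered/taxonomy.tsv", "filter_log.jsonl"]
        run.record(stage, run.input_hash(stage, []), outputs, False, t0)
    except Exception as exc:
        run.flush()
        raise PipelineError(stage, exc) from exc

    ranked = {r: tables.agglomerate(ct, tax, r) for r in cfg.ranks}
    cohort_by_rank = {r: da.PairedCohort(ranked[r], md) for r in cfg.ranks}
    da_rank_ct = ranked.get(cfg.da_rank) or tables.agglomerate(ct, tax, cfg.da_rank)
    da_cohort = da.PairedCohort(da_rank_ct, md)

    # ---- stage: alpha diversity ----------------------------------------
    stage = "alpha"
    t0 = time.time()
    in_hash = run.input_hash(stage, ["filtered/counts.tsv", "filtered/metadata.tsv"])
    outputs = ["alpha_diversity.tsv", "alpha_tests.tsv"]
    skipped = run.can_skip(stage, in_hash, outputs)
    if not skipped:
        try:
            adf = pd.DataFrame(
                {
                    "sample_id": ct.samples,
                    "shannon": transforms.shannon(ct),
                    "observed_richness": transforms.observed_richness(ct),
                }
            ).set_index("sample_id")
            _write_df(adf, outputs[0])
            rows = []
            for metric in ("shannon", "observed_richness"):
                vals = adf[metric].to_numpy(dtype=float)[None, :]
                _, pl, ab = tables.paired_arrays(ct, md, vals)
                res = transforms.wilcoxon_signed_rank((pl - ab)[0])
                rows.append({"metric": metric, "W": res.statistic, "n": res.n_effective,
                             "p": res.p_value, "method": res.method})
            _write_df(pd.DataFrame(rows).set_index("metric"), outputs[1])
        except Exception as exc:
            run.flush()
            raise PipelineError(stage, exc) from exc
    run.record(stage, in_hash, outputs, skipped, t0)

    # ---- stage: ordination ---------------------------------------------
    stage = "ordination"
    t0 = time.time()
    in_hash = run.input_hash(stage, ["filtered/counts.tsv", "filtered/metadata.tsv"])
    outputs = ["ordination_sweep.tsv", "ordination_coords.tsv", "hclust.tsv"]
    skipped = run.can_skip(stage, in_hash, outputs)
    if not skipped:
        try:
            ct_rank = ranked.get(cfg.da_rank, ct)
            sweep = ordn.ordination_sweep(ct_rank, md, cfg.sweep_transforms, cfg.sweep_metrics)
            _write_df(sweep, outputs[0], index_label="combo")
            am = transforms.tss(ct_rank)
            d = ordn.distance_matrix(am, "bray_curtis")
            res = ordn.pcoa(d, n_axes=2)
            res.rho_axis1_library = ordn.spearman_axis_vs_library(res, md)
            res.silhouette_by_type = ordn.silhouette_by_group(d, md.frame["specimen_type"].to_dict())
            coords = pd.DataFrame(res.coordinates, index=res.samples,
                                  columns=[f"axis{i+1}" for i in range(res.coordinates.shape[1])])
            coords["specimen_type"] = md.frame.loc[res.samples, "specimen_type"]
            _write_df(coords, outputs[1], index_label="sample_id")
            Z, ids = ordn.hierarchical_cluster(am)
            zdf = pd.DataFrame(Z, columns=["left", "right", "height", "size"])
            _write_df(zdf, outputs[2], index_label="merge")
        except Exception as exc:
            run.flush()
            raise PipelineError(stage, exc) from exc
    run.record(stage, in_hash, outputs, skipped, t0)

    # ---- stage: differential abundance ---------------------------------
    stage = "da"
    t0 = time.time()
    in_hash = run.input_hash(stage, ["filtered/counts.tsv", "filtered/metadata.tsv"])
    outputs = ["da_report.tsv", "da_tiers.tsv", "da_top15.tsv", "enrichment_tallies.tsv"]
    skipped = run.can_skip(stage, in_hash, outputs)
    if not skipped:
        try:
            tiers, reports = da.run_consensus(
                da_cohort, n_mc=cfg.n_mc, seed=stage_seed(cfg.seed, "da")
            )
            merged = reports["wilcoxon"].add_prefix("wilcoxon_")
            for m in ("clr_wilcoxon", "linear_model"):
                merged = merged.join(reports[m].add_prefix(f"{m}_"))
            _write_df(merged, outputs[0], index_label="taxon")
            _write_df(tiers, outputs[1], index_label="taxon")
            _write_df(da.top_k_by_median_difference(reports["wilcoxon"]), outputs[2], index_label="taxon")
            _write_df(da.enrichment_tallies(da_cohort), outputs[3], index_label="taxon")
        except Exception as exc:
            run.flush()
            raise PipelineError(stage, exc) from exc
    run.record(stage, in_hash, outputs, skipped, t0)

    # ---- stage: topics --------------------------------------------------
    stage = "topics"
    t0 = time.time()
    in_hash = run.input_hash(stage, ["filtered/counts.tsv", "filtered/metadata.tsv"])
    outputs = [
        "scale_selection.tsv", "k_selection.tsv", "lda_model.json",
        "topic_gamma.tsv", "topic_beta.tsv", "topic_associations.tsv",
        "topic_drivers.tsv", "gamma_embedding.tsv", "embedding_silhouettes.json",
    ]
    skipped = run.can_skip(stage, in_hash, outputs)
    if not skipped:
        try:
            seed_t = stage_seed(cfg.seed, "topics")
            sel_kwargs = dict(
                iterations=cfg.selection_iterations,
                burn_in=cfg.selection_burn_in,
                thin=cfg.selection_thin,
            )
            S, sdiag = lda.select_scaling_factor(
                da_rank_ct, md, cfg.k_for_scaling, cfg.s_grid, seed=seed_t, **sel_kwargs
            )
            _write_df(sdiag.set_index("S"), outputs[0])
            corpus = lda.build_scaled_corpus(da_rank_ct, S)
            curve = lda.k_selection(corpus, cfg.k_grid, seed=seed_t, **sel_kwargs)
            kdf = curve.metrics.copy()
            kdf["chosen"] = [k == curve.chosen_k for k in curve.k_grid]
            _write_df(kdf, outputs[1], index_label="K")
            model = lda.fit_lda_gibbs(
                corpus, curve.chosen_k, iterations=cfg.lda_iterations,
                burn_in=cfg.lda_burn_in, thin=cfg.lda_thin, seed=seed_t,
            )
            model.to_json(out / outputs[2])
            gdf = pd.DataFrame(model.gamma, index=model.docs,
                               columns=[f"topic_{k+1}" for k in range(model.K)])
            _write_df(gdf, outputs[3], index_label="sample_id")
            bdf = pd.DataFrame(model.beta.T, index=model.vocab,
                               columns=[f"topic_{k+1}" for k in range(model.K)])
            _write_df(bdf, outputs[4], index_label="taxon")
            assoc = lda.topic_type_association(model, md)
            _write_df(assoc, outputs[5], index_label="topic")
            drivers = lda.topic_drivers(model)
            ddf = pd.concat(
                [d.assign(topic=t) for t, d in drivers.items()]
            ).reset_index().set_index(["topic", "taxon"])
            _write_df(ddf, outputs[6])
            emb, sil = lda.embed_gamma(model, md, seed=seed_t)
            _write_df(emb, outputs[7], index_label="sample_id")
            (out / outputs[8]).write_text(json.dumps(sil, sort_keys=True))
        except Exception as exc:
            run.flush()
            raise PipelineError(stage, exc) from exc
    run.record(stage, in_hash, outputs, skipped, t0)

    # ---- stage: classify -------------------------------------------------
    stage = "classify"
    t0 = time.time()
    in_hash = run.input_hash(stage, ["filtered/counts.tsv", "filtered/metadata.tsv"])
    outputs = ["cv_auc.tsv", "cv_importance_ranks.tsv"]
    skipped = run.can_skip(stage, in_hash, outputs)
    if not skipped:
        try:
            cv = classify.kfold_classify(
                da_cohort, n_folds=cfg.n_folds, seed=stage_seed(cfg.seed, "classify")
            )
            aucdf = pd.DataFrame(
                {"fold": [f"fold_{i+1}" for i in range(cv.n_folds)], "auc": cv.fold_auc,
                 "held_out": [",".join(h) for h in cv.held_out]}
            ).set_index("fold")
            _write_df(aucdf, outputs[0])
            _write_df(cv.importance_ranks, outputs[1], index_label="taxon")
        except Exception as exc:
            run.flush()
            raise PipelineError(stage, exc) from exc
    run.record(stage, in_hash, outputs, skipped, t0)

    # ---- stage: enrichment (optional) ------------------------------------
    if cfg.pathway_map is not None:
        stage = "enrich"
        t0 = time.time()
        in_hash = run.input_hash(stage, ["da_tiers.tsv"])
        outputs = ["over_representation.tsv"]
        skipped = run.can_skip(stage, in_hash, outputs)
        if not skipped:
            try:
                sets, names = classify.read_pathway_map(cfg.pathway_map)
                background = set().union(*sets.values()) if sets else set()
                if cfg.sig_items is not None:
                    sig = {
                        line.strip() for line in Path(cfg.sig_items).read_text().splitlines()
                        if line.strip()
                    }
                else:
                    tiers_df = pd.read_csv(out / "da_tiers.tsv", sep="\t", index_col=0)
                    sig = set(tiers_df.index[tiers_df["tier"].isin(["high", "medium"])])
                sig &= background
                ora = classify.over_representation(sig, background, sets)
                if names:
                    ora["pathway_name"] = [names.get(p, "") for p in ora.index]
                _write_df(ora, outputs[0], index_label="pathway")
            except Exception as exc:
                run.flush()
                raise PipelineError(stage, exc) from exc
        run.record(stage, in_hash, outputs, skipped, t0)

    run.flush()
    return run.manifest
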