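"""Synthetic paired plaque/abscess cohorts from a latent-topic model.

Each patient contributes one plaque and one abscess sample.  Communities are
multinomial draws from mixtures of latent topics (probability distributions
over taxa).  Topics come in three classes — plaque-specific, abscess-specific
and shared — and a patient's two samples share a single base topic-weight
draw, which induces the intra-patient correlation real paired specimens show.
Specimen type then re-splits only the *type-specific* portion of that base
mass: own-type topics receive fraction ``type_bias`` of it, the other type's
topics the remainder, each distributed proportionally within its group and
shared topics untouched.  At ``type_bias = 0.5`` the two members of a pair
have identical expected weights (a true null); as ``type_bias -> 1`` plaque
samples carry only plaque + shared topics.

Contaminant taxa (uniform relative abundance 1e-3 per contaminant in every
specimen) and blank control samples (containing only contaminants) are added
so the cohort-filtering rules are exercisable.  Library sizes are log-normal.

Ground truth records the topic-taxon matrix, per-sample topic weights, topic
classes, and the taxa that are truly differentially abundant: a taxon is
"enriched" toward a type when its mean probability across that type's topics
exceeds 4x its mean across the other type's topics AND is at least the
uniform level 1/n_taxa (the floor excludes taxa whose absolute abundance is
too small to matter at any realistic sequencing depth).
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import CountTable, SampleMetadata, TaxonomyMap, write_tables

ENRICHMENT_RATIO = 4.0


class GeneratorConfigError(ValueError):
    """A GeneratorConfig invariant is violated."""


@dataclasses.dataclass
class GeneratorConfig:
    n_patients: int = 25
    n_taxa: int = 150
    k_true: int = 6
    n_plaque_topics: int = 2
    n_abscess_topics: int = 1
    n_shared_topics: int = 3
    topic_concentration: float = 0.05
    membership_concentration: float = 0.5
    type_bias: float = 0.8
    library_size_log_mean: float = math.log(20000.0)
    library_size_log_sd: float = 0.35
    n_blanks: int = 2
    n_contaminants: int = 5
    contaminant_abundance: float = 1e-3
    seed: int = 0

    def validate(self) -> None:
        if self.n_plaque_topics + self.n_abscess_topics + self.n_shared_topics != self.k_true:
            raise GeneratorConfigError(
                "n_plaque_topics + n_abscess_topics + n_shared_topics must equal k_true "
                f"({self.n_plaque_topics}+{self.n_abscess_topics}+{self.n_shared_topics}"
                f" != {self.k_true})"
            )
        if self.topic_concentration <= 0 or self.membership_concentration <= 0:
            raise GeneratorConfigError("concentration parameters must be > 0")
        if not 0 < self.type_bias < 1:
            raise GeneratorConfigError("type_bias must lie strictly between 0 and 1")
        for field in ("n_patients", "n_taxa", "k_true"):
            if getattr(self, field) < 1:
                raise GeneratorConfigError(f"{field} must be >= 1")
        if self.n_blanks < 0 or self.n_contaminants < 0:
            raise GeneratorConfigError("n_blanks and n_contaminants must be >= 0")
        if self.library_size_log_sd < 0:
            raise GeneratorConfigError("library_size_log_sd must be >= 0")


@dataclasses.dataclass
class SyntheticTruth:
    topic_taxon: np.ndarray  # k_true x n_taxa, rows sum to 1
    sample_topic: pd.DataFrame | None  # filled in by sample_cohort (samples x topics)
    topic_class: list[str]  # per topic: plaque | abscess | shared
    enriched_taxa: dict[str, str]  # taxon id -> plaque | abscess
    contaminant_taxa: list[str]
    taxa: list[str]

    def to_json(self, path: Path) -> None:
        payload = {
            "topic_taxon": self.topic_taxon.tolist(),
            "topic_class": self.topic_class,
            "enriched_taxa": self.enriched_taxa,
            "contaminant_taxa": self.contaminant_taxa,
            "taxa": self.taxa,
            "sample_topic": None
            if self.sample_topic is None
            else {
                "index": list(self.sample_topic.index),
                "values": self.sample_topic.to_numpy().tolist(),
            },
        }
        Path(path).write_text(json.dumps(payload))


def _derive_enriched(
    topic_taxon: np.ndarray, topic_class: list[str], taxa: list[str], n_taxa: int
) -> dict[str, str]:
    cls = np.array(topic_class)
    enriched: dict[str, str] = {}
    if not ((cls == "plaque").any() and (cls == "abscess").any()):
        return enriched
    mean_p = topic_taxon[cls == "plaque"].mean(axis=0)
    mean_a = topic_taxon[cls == "abscess"].mean(axis=0)
    floor = 1.0 / n_taxa
    for t, mp, ma in zip(taxa, mean_p, mean_a):
        if mp > ENRICHMENT_RATIO * ma and mp >= floor:
            enriched[t] = "plaque"
        elif ma > ENRICHMENT_RATIO * mp and ma >= floor:
            enriched[t] = "abscess"
    return enriched


def generate_truth(cfg: GeneratorConfig) -> SyntheticTruth:
    """Draw topic-taxon distributions and derive the ground-truth labels."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    taxa = [f"taxon_{i:04d}" for i in range(cfg.n_taxa)]
    topic_taxon = rng.dirichlet(
        np.full(cfg.n_taxa, cfg.topic_concentration), size=cfg.k_true
    )
    topic_class = (
        ["plaque"] * cfg.n_plaque_topics
        + ["abscess"] * cfg.n_abscess_topics
        + ["shared"] * cfg.n_shared_topics
    )
    enriched = _derive_enriched(topic_taxon, topic_class, taxa, cfg.n_taxa)
    contaminants = [f"contam_{i:02d}" for i in range(cfg.n_contaminants)]
    return SyntheticTruth(topic_taxon, None, topic_class, enriched, contaminants, taxa)


def _pair_weights(base: np.ndarray, topic_class: list[str], own: str, bias: float) -> np.ndarray:
    """Re-split the type-specific mass of a base draw toward ``own`` type."""
    cls = np.array(topic_class)
    other = "abscess" if own == "plaque" else "plaque"
    own_idx = cls == own
    oth_idx = cls == other
    if not own_idx.any() or not oth_idx.any():
        return base.copy()
    w = base.copy()
    type_mass = base[own_idx].sum() + base[oth_idx].sum()
    own_sum, oth_sum = base[own_idx].sum(), base[oth_idx].sum()
    if type_mass <= 0:
        return w
    if own_sum > 0:
        w[own_idx] = base[own_idx] / own_sum * type_mass * bias
    else:  # degenerate draw: spread evenly
        w[own_idx] = type_mass * bias / own_idx.sum()
    if oth_sum > 0:
        w[oth_idx] = base[oth_idx] / oth_sum * type_mass * (1 - bias)
    else:
        w[oth_idx] = type_mass * (1 - bias) / oth_idx.sum()
    return w


def sample_cohort(
    truth: SyntheticTruth, cfg: GeneratorConfig
) -> tuple[CountTable, SampleMetadata]:
    """Draw the paired cohort (plus blanks) from the truth; fills truth.sample_topic."""
    cfg.validate()
    if truth.topic_taxon.shape != (cfg.k_true, cfg.n_taxa):
        raise GeneratorConfigError("truth is inconsistent with cfg dimensions")
    rng = np.random.default_rng([cfg.seed, 1])

    all_taxa = truth.taxa + truth.contaminant_taxa
    sample_ids: list[str] = []
    records = []
    cols = []
    weights_rows = {}
    contam_total = cfg.contaminant_abundance * cfg.n_contaminants
    if contam_total >= 1.0:
        raise GeneratorConfigError("contaminant abundance mass must be < 1")

    for i in range(cfg.n_patients):
        pid = f"patient_{i:03d}"
        base = rng.dirichlet(np.full(cfg.k_true, cfg.membership_concentration))
        for stype in ("plaque", "abscess"):
            w = _pair_weights(base, truth.topic_class, stype, cfg.type_bias)
            w = w / w.sum()
            sid = f"{pid}_{stype}"
            depth = max(1, int(round(rng.lognormal(cfg.library_size_log_mean, cfg.library_size_log_sd))))
            p_real = w @ truth.topic_taxon
            p_full = np.concatenate(
                [p_real * (1 - contam_total), np.full(cfg.n_contaminants, cfg.contaminant_abundance)]
            )
            counts = rng.multinomial(depth, p_full / p_full.sum())
            sample_ids.append(sid)
            cols.append(counts)
            weights_rows[sid] = w
            records.append({"sample_id": sid, "patient_id": pid, "specimen_type": stype})

    for b in range(cfg.n_blanks):
        sid = f"blank_{b:02d}"
        depth = max(1, int(round(rng.lognormal(cfg.library_size_log_mean - 3.0, cfg.library_size_log_sd))))
        p_full = np.zeros(len(all_taxa))
        if cfg.n_contaminants:
            p_full[cfg.n_taxa:] = 1.0 / cfg.n_contaminants
        else:
            p_full[:] = 1.0 / len(all_taxa)
        counts = rng.multinomial(depth, p_full)
        sample_ids.append(sid)
        cols.append(counts)
        records.append({"sample_id": sid, "patient_id": sid, "specimen_type": "blank"})

    counts = np.stack(cols, axis=1)
    ct = CountTable(all_taxa, sample_ids, counts)
    mdf = pd.DataFrame.from_records(records).set_index("sample_id")
    mdf["library_size"] = ct.library_sizes.astype(int)
    md = SampleMetadata(mdf)
    truth.sample_topic = pd.DataFrame(
        np.stack([weights_rows[s] for s in weights_rows]),
        index=list(weights_rows),
        columns=[f"topic_{k+1}" for k in range(cfg.k_true)],
    )
    return ct, md


def synthetic_taxonomy(truth: SyntheticTruth, species_per_genus: int = 2, genera_per_phylum: int = 10) -> TaxonomyMap:
    """Deterministic plausible lineage table for the synthetic taxa."""
    tax: TaxonomyMap = {}
    for i, t in enumerate(truth.taxa):
        g = i // species_per_genus
        ph = g // genera_per_phylum
        tax[t] = {"phylum": f"Phylum_{ph:02d}", "genus": f"Genus_{g:03d}", "species": t}
    for c in truth.contaminant_taxa:
        tax[c] = {"phylum": "Phylum_contam", "genus": "Genus_contam", "species": c}
    return tax


def generate_cohort(cfg: GeneratorConfig) -> tuple[CountTable, SampleMetadata, TaxonomyMap, SyntheticTruth]:
    """Convenience: truth + cohort + taxonomy in one deterministic call."""
    truth = generate_truth(cfg)
    ct, md = sample_cohort(truth, cfg)
    tax = synthetic_taxonomy(truth)
    return ct, md, tax, truth


def write_cohort(cfg: GeneratorConfig, out_dir: Path) -> dict[str, Path]:
    """Write counts/metadata/taxonomy TSVs plus truth JSON into ``out_dir``."""
    ct, md, tax, truth = generate_cohort(cfg)
    out_dir = Path(out_dir)
    paths = write_tables(out_dir, ct, md, tax)
    truth_path = out_dir / "truth.json"
    truth.to_json(truth_path)
    paths["truth"] = truth_path
    return paths
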