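"""Count-table IO, cohort filtering, and taxonomic rank agglomeration.

The pipeline's substrate is a taxa x samples table of non-negative integer
counts, a per-sample metadata table (patient id, specimen type), and a
taxonomy lineage map (phylum/genus/species per taxon).  Everything is stored
as plain tab-separated text so fixtures stay human-readable.

Cohort filtering applies, in order: (1) removal of listed contaminant taxa,
(2) removal of taxa observed only in blank (PCR/reagent control) samples,
(3) removal of the blank samples themselves, and (4) removal of any patient
pair in which either member has a library of <= ``min_reads`` total reads
(strictly more than the threshold is required to be retained).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

RANKS = ("phylum", "genus", "species")
SPECIMEN_TYPES = ("plaque", "abscess", "blank")


class TableFormatError(ValueError):
    """Malformed input table (ragged rows, negative counts, duplicate ids...)."""


class PairingError(ValueError):
    """Metadata does not describe one plaque + one abscess sample per patient."""


class EmptyCohortError(ValueError):
    """Filtering removed every sample or every taxon."""


@dataclasses.dataclass
class CountTable:
    """Taxa x samples matrix of non-negative integer counts."""

    taxa: list[str]
    samples: list[str]
    counts: np.ndarray  # shape (n_taxa, n_samples), integer

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.taxa), len(self.samples)):
            raise TableFormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.samples)} samples"
            )
        if len(set(self.taxa)) != len(self.taxa):
            raise TableFormatError("duplicate taxon ids")
        if len(set(self.samples)) != len(self.samples):
            raise TableFormatError("duplicate sample ids")
        if np.any(self.counts < 0):
            t, s = np.argwhere(self.counts < 0)[0]
            raise TableFormatError(
                f"negative count at taxon {self.taxa[t]!r}, sample {self.samples[s]!r}"
            )

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def subset_taxa(self, keep: Sequence[str]) -> "CountTable":
        idx = [self.taxa.index(t) for t in keep]
        return CountTable(list(keep), list(self.samples), self.counts[idx, :])

    def subset_samples(self, keep: Sequence[str]) -> "CountTable":
        idx = [self.samples.index(s) for s in keep]
        return CountTable(list(self.taxa), list(keep), self.counts[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxa, columns=self.samples)


@dataclasses.dataclass
class SampleMetadata:
    """Per-sample patient id, specimen type and (recomputed) library size."""

    frame: pd.DataFrame  # index: sample_id; columns: patient_id, specimen_type, library_size

    def __post_init__(self) -> None:
        required = {"patient_id", "specimen_type"}
        missing = required - set(self.frame.columns)
        if missing:
            raise TableFormatError(f"metadata missing columns: {sorted(missing)}")
        bad = set(self.frame["specimen_type"]) - set(SPECIMEN_TYPES)
        if bad:
            raise TableFormatError(f"unknown specimen types: {sorted(bad)}")

    @property
    def samples(self) -> list[str]:
        return list(self.frame.index)

    def subset(self, keep: Sequence[str]) -> "SampleMetadata":
        return SampleMetadata(self.frame.loc[list(keep)].copy())

    def blanks(self) -> list[str]:
        return list(self.frame.index[self.frame["specimen_type"] == "blank"])

    def pairs(self) -> pd.DataFrame:
        """One row per patient with plaque/abscess sample ids (validates pairing)."""
        nb = self.frame[self.frame["specimen_type"] != "blank"]
        rows = {}
        for sid, row in nb.iterrows():
            rows.setdefault(row["patient_id"], {})[row["specimen_type"]] = sid
        records = []
        for pid in sorted(rows):
            got = rows[pid]
            if set(got) != {"plaque", "abscess"}:
                raise PairingError(
                    f"patient {pid!r} has specimen types {sorted(got)}, "
                    "expected exactly one plaque and one abscess sample"
                )
            records.append({"patient_id": pid, "plaque": got["plaque"], "abscess": got["abscess"]})
        counts = nb.groupby(["patient_id", "specimen_type"]).size()
        if (counts > 1).any():
            pid = counts[counts > 1].index[0][0]
            raise PairingError(f"patient {pid!r} has duplicated specimen types")
        return pd.DataFrame.from_records(records).set_index("patient_id")


TaxonomyMap = dict  # taxon id -> {"phylum": str, "genus": str, "species": str}

#: placeholder prefix for lineage fields that carry no classification
UNCLASSIFIED = "unclassified"


def _read_tsv(path: Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise TableFormatError(f"missing input file: {path}")
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise TableFormatError(f"cannot parse {path}: {exc}") from exc


def read_tables(
    counts_path: Path, metadata_path: Path, taxonomy_path: Path
) -> tuple[CountTable, SampleMetadata, TaxonomyMap]:
    """Read and validate the three pipeline TSVs.

    Library sizes are always recomputed from the count columns; if the
    metadata declares a ``library_size`` column that disagrees, that is an
    error (a declared size is a checksum, not a free parameter).
    """
    cdf = _read_tsv(counts_path)
    try:
        counts = cdf.to_numpy(dtype=float)
    except ValueError as exc:
        raise TableFormatError(f"non-numeric count in {counts_path}: {exc}") from exc
    if np.any(counts != np.round(counts)):
        t, s = np.argwhere(counts != np.round(counts))[0]
        raise TableFormatError(
            f"non-integer count at taxon {cdf.index[t]!r}, sample {cdf.columns[s]!r}"
        )
    if np.any(counts < 0):
        t, s = np.argwhere(counts < 0)[0]
        raise TableFormatError(
            f"negative count at taxon {cdf.index[t]!r}, sample {cdf.columns[s]!r}"
        )
    ct = CountTable(list(cdf.index), list(cdf.columns), counts.astype(np.int64))

    mdf = _read_tsv(metadata_path)
    lib = pd.Series(ct.library_sizes, index=ct.samples)
    missing = set(ct.samples) - set(mdf.index)
    if missing:
        raise TableFormatError(f"samples missing from metadata: {sorted(missing)}")
    mdf = mdf.loc[ct.samples].copy()
    if "library_size" in mdf.columns:
        declared = mdf["library_size"].astype(int)
        bad = declared[declared != lib]
        if len(bad):
            raise TableFormatError(
                f"declared library_size for sample {bad.index[0]!r} is "
                f"{bad.iloc[0]}, counts sum to {lib[bad.index[0]]}"
            )
    mdf["library_size"] = lib.astype(int)
    md = SampleMetadata(mdf)

    tdf = _read_tsv(taxonomy_path)
    for col in ("phylum", "genus", "species"):
        if col not in tdf.columns:
            raise TableFormatError(f"taxonomy missing column {col!r}")
    tax: TaxonomyMap = {
        tid: {r: str(row[r]) for r in ("phylum", "genus", "species")}
        for tid, row in tdf.iterrows()
    }
    missing_tax = set(ct.taxa) - set(tax)
    if missing_tax:
        raise TableFormatError(f"taxa missing from taxonomy: {sorted(missing_tax)[:5]}")
    return ct, md, tax


def write_tables(
    out_dir: Path, ct: CountTable, md: SampleMetadata, tax: TaxonomyMap
) -> dict[str, Path]:
    """Write counts.tsv / metadata.tsv / taxonomy.tsv into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out_dir / "counts.tsv",
        "metadata": out_dir / "metadata.tsv",
        "taxonomy": out_dir / "taxonomy.tsv",
    }
    ct.to_frame().to_csv(paths["counts"], sep="\t", index_label="taxon_id")
    md.frame.to_csv(paths["metadata"], sep="\t", index_label="sample_id")
    tdf = pd.DataFrame.from_dict(tax, orient="index")[["phylum", "genus", "species"]]
    tdf.to_csv(paths["taxonomy"], sep="\t", index_label="taxon_id")
    return paths


@dataclasses.dataclass
class FilterLogEntry:
    kind: str  # "taxon" | "sample"
    id: str
    rule: str


def write_filter_log(entries: list[FilterLogEntry], path: Path) -> None:
    with open(path, "w") as fh:
        for e in entries:
            fh.write(json.dumps(dataclasses.asdict(e)) + "\n")


def filter_cohort(
    ct: CountTable,
    md: SampleMetadata,
    contaminants: Iterable[str] = (),
    min_reads: int = 1000,
) -> tuple[CountTable, SampleMetadata, list[FilterLogEntry]]:
    """Apply the four cohort-filtering rules in order; log every removal.

    The depth rule is strict: a pair is retained only if both members have
    strictly more than ``min_reads`` total reads, and dropping one member
    drops the pair.
    """
    log: list[FilterLogEntry] = []
    contaminants = set(contaminants)

    keep_taxa = [t for t in ct.taxa if t not in contaminants]
    for t in ct.taxa:
        if t in contaminants:
            log.append(FilterLogEntry("taxon", t, "contaminant_list"))
    ct = ct.subset_taxa(keep_taxa)

    blank_ids = md.blanks()
    blank_idx = [ct.samples.index(s) for s in blank_ids if s in ct.samples]
    nonblank_idx = [i for i in range(len(ct.samples)) if i not in blank_idx]
    if blank_idx:
        in_blank = ct.counts[:, blank_idx].sum(axis=1) > 0
        in_nonblank = ct.counts[:, nonblank_idx].sum(axis=1) > 0
        blank_only = in_blank & ~in_nonblank
        keep_taxa = [t for t, drop in zip(ct.taxa, blank_only) if not drop]
        for t, drop in zip(ct.taxa, blank_only):
            if drop:
                log.append(FilterLogEntry("taxon", t, "blank_only"))
        ct = ct.subset_taxa(keep_taxa)

    keep_samples = [s for s in ct.samples if s not in blank_ids]
    for s in blank_ids:
        log.append(FilterLogEntry("sample", s, "blank_sample"))
    ct = ct.subset_samples(keep_samples)
    md = md.subset(keep_samples)

    lib = pd.Series(ct.library_sizes, index=ct.samples)
    pairs = md.pairs()
    drop_samples: list[str] = []
    for pid, row in pairs.iterrows():
        if lib[row["plaque"]] <= min_reads or lib[row["abscess"]] <= min_reads:
            drop_samples.extend([row["plaque"], row["abscess"]])
            for sid in (row["plaque"], row["abscess"]):
                log.append(FilterLogEntry("sample", sid, f"pair_depth<={min_reads}"))
    keep_samples = [s for s in ct.samples if s not in set(drop_samples)]
    ct = ct.subset_samples(keep_samples)
    md = md.subset(keep_samples)

    if not ct.samples or not ct.taxa:
        raise EmptyCohortError("empty cohort after filtering")
    md.frame["library_size"] = ct.library_sizes.astype(int)
    return ct, md, log


def agglomerate(ct: CountTable, tax: TaxonomyMap, rank: str) -> CountTable:
    """Sum counts over taxa sharing the same label at ``rank``.

    Taxa unclassified at the rank are pooled under one placeholder per
    parent lineage, so per-sample totals are conserved exactly.  Output rows
    follow first occurrence order of each label in the input.
    """
    if rank not in RANKS:
        raise ValueError(f"unsupported rank {rank!r}; expected one of {RANKS}")
    parent_of = {"phylum": None, "genus": "phylum", "species": "genus"}[rank]
    labels: list[str] = []
    for t in ct.taxa:
        lineage = tax[t]
        label = lineage.get(rank, "")
        if not label or str(label).lower().startswith(UNCLASSIFIED) or str(label) == "nan":
            parent = lineage.get(parent_of, "") if parent_of else ""
            label = f"{UNCLASSIFIED}_{parent}" if parent else UNCLASSIFIED
        labels.append(str(label))
    order: list[str] = []
    index: dict[str, int] = {}
    for lbl in labels:
        if lbl not in index:
            index[lbl] = len(order)
            order.append(lbl)
    out = np.zeros((len(order), len(ct.samples)), dtype=ct.counts.dtype)
    for row, lbl in zip(ct.counts, labels):
        out[index[lbl]] += row
    return CountTable(order, list(ct.samples), out)


def paired_arrays(
    ct: CountTable, md: SampleMetadata, values: np.ndarray | None = None
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Return (patients, plaque matrix, abscess matrix), taxa x n_pairs.

    ``values`` defaults to the raw counts; pass a transformed matrix aligned
    with ``ct`` to pair e.g. TSS values.
    """
    if values is None:
        values = ct.counts
    pairs = md.pairs()
    col = {s: i for i, s in enumerate(ct.samples)}
    patients = list(pairs.index)
    p_idx = [col[pairs.loc[pid, "plaque"]] for pid in patients]
    a_idx = [col[pairs.loc[pid, "abscess"]] for pid in patients]
    return patients, values[:, p_idx], values[:, a_idx]
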