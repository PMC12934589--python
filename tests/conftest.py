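import numpy as np
import pandas as pd
import pytest

import oralpair as op
from oralpair.da import PairedCohort


@pytest.fixture
def tiny_tables():
    """Hand-built 3-taxon x 4-sample paired cohort (2 patients)."""
    taxa = ["tA", "tB", "tC"]
    samples = ["p1_plaque", "p1_abscess", "p2_plaque", "p2_abscess"]
    counts = np.array(
        [
            [10, 0, 5, 3],
            [0, 7, 2, 2],
            [4, 1, 0, 6],
        ]
    )
    ct = op.CountTable(taxa, samples, counts)
    md = op.SampleMetadata(
        pd.DataFrame(
            {
                "patient_id": ["p1", "p1", "p2", "p2"],
                "specimen_type": ["plaque", "abscess", "plaque", "abscess"],
                "library_size": counts.sum(axis=0),
            },
            index=pd.Index(samples, name="sample_id"),
        )
    )
    tax = {
        "tA": {"phylum": "PhX", "genus": "GenA", "species": "tA"},
        "tB": {"phylum": "PhX", "genus": "GenA", "species": "tB"},
        "tC": {"phylum": "PhY", "genus": "GenC", "species": "tC"},
    }
    return ct, md, tax


@pytest.fixture(scope="session")
def standard_cohort():
    """The study-condition synthetic cohort (25 pairs, 150 taxa, 6 topics), filtered."""
    cfg = op.GeneratorConfig(seed=101)
    ct, md, tax, truth = op.generate_cohort(cfg)
    ct, md, _ = op.filter_cohort(ct, md, truth.contaminant_taxa)
    return ct, md, tax, truth


@pytest.fixture(scope="session")
def standard_paired(standard_cohort):
    ct, md, tax, truth = standard_cohort
    return PairedCohort(ct, md), truth


def make_cohort(seed, type_bias=0.8, n_patients=25, n_taxa=150, **kwargs):
    cfg = op.GeneratorConfig(
        seed=seed, type_bias=type_bias, n_patients=n_patients, n_taxa=n_taxa, **kwargs
    )
    ct, md, tax, truth = op.generate_cohort(cfg)
    ct, md, _ = op.filter_cohort(ct, md, truth.contaminant_taxa)
    return ct, md, tax, truth
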