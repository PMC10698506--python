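"""Shared fixtures: small synthetic genomes/cohorts generated at test time."""
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from paradel.annotation import GenomeLayout
from paradel.pipeline import AnalysisConfig, run_analysis
from paradel.simulate import SimulationConfig, simulate_annotation, simulate_cohort


def desk_config(**overrides) -> SimulationConfig:
    """Down-scaled study conditions for fast unit tests (same model, smaller
    genome/cohort)."""
    base = dict(n_chromosomes=6, n_genes=4000, n_samples=250, n_tsgs=20,
                n_other_drivers=30, n_fragile_sites=5,
                hd_events_per_tumor=5.0, loh_events_per_tumor=5.0)
    base.update(overrides)
    return replace(SimulationConfig(), **base)


@pytest.fixture(scope="session")
def small_annotation():
    return simulate_annotation(desk_config(), seed=101)


@pytest.fixture(scope="session")
def small_cohort(small_annotation):
    segments, truth = simulate_cohort(small_annotation, seed=202)
    return segments, truth


@pytest.fixture(scope="session")
def small_analysis(small_annotation, small_cohort):
    segments, _ = small_cohort
    ann = small_annotation
    return run_analysis(ann.genes, ann.annotations, ann.layout, ann.fragile_sites,
                        {"sim": segments}, with_regression=False)


@pytest.fixture(scope="session")
def default_scale_run():
    """One cohort at the full study scale (22 chromosomes, 20,000 genes,
    2,000 tumors); shared across the acceptance checks that need it."""
    cfg = SimulationConfig()
    ann = simulate_annotation(cfg, seed=11)
    segments, truth = simulate_cohort(ann, seed=12)
    res = run_analysis(ann.genes, ann.annotations, ann.layout, ann.fragile_sites,
                       {"sim": segments})
    return ann, segments, truth, res


@pytest.fixture()
def toy_layout():
    return GenomeLayout(chrom_lengths={"1": 200_000_000, "2": 150_000_000},
                        centromeres={"1": (99_000_000, 101_000_000),
                                     "2": (74_000_000, 76_000_000)})


@pytest.fixture()
def toy_genes():
    return pd.DataFrame({
        "gene_id": ["G1", "G2", "G3", "GX"],
        "symbol": ["G1", "G2", "G3", "GX"],
        "chrom": ["1", "1", "2", "X"],
        "start": [1_000_000, 5_000_000, 10_000_000, 1_000],
        "end": [1_050_000, 5_200_000, 10_100_000, 2_000],
        "length": [50_001, 200_001, 100_001, 1_001],
        "autosomal": [True, True, True, False],
    })
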