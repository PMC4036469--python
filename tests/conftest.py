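"""Shared fixtures: small seeded synthetic cohorts and derived signatures.

Unit tests run on a reduced simulation (2,000 genes, 80 planted per
allele) to stay fast; the acceptance tests build the full-size study
conditions themselves.
"""

from __future__ import annotations

import pandas as pd
import pytest

from xsig.preprocess import collapse_probesets, median_center_iqr_normalize
from xsig.signature import ALLELES, build_signature, derive_allele_gene_lists, \
    fit_allele_models
from xsig.simulate import SimConfig, make_homolog_map, simulate_gemm_cohort


SMALL = dict(n_genes=2000, n_planted_per_allele=80, human_cohort_size=200,
             n_background_genes=300)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(seed=11, **SMALL)


@pytest.fixture(scope="session")
def gemm_small(small_config):
    """(probeset expr, annotation, design, truth) for the small cohort."""
    return simulate_gemm_cohort(small_config)


@pytest.fixture(scope="session")
def genes_small(gemm_small):
    expr, ann, _, _ = gemm_small
    return collapse_probesets(expr, ann)


@pytest.fixture(scope="session")
def effects_small(gemm_small, genes_small):
    _, _, design, _ = gemm_small
    return fit_allele_models(genes_small, design)


@pytest.fixture(scope="session")
def signatures_small(effects_small):
    lists = derive_allele_gene_lists(effects_small, alpha=0.01)
    return {a: build_signature(a, lists[a], effects_small, k=40)
            for a in ALLELES}


@pytest.fixture(scope="session")
def norm_small(genes_small) -> pd.DataFrame:
    return median_center_iqr_normalize(genes_small)


@pytest.fixture(scope="session")
def homologs_small(genes_small) -> pd.DataFrame:
    return make_homolog_map(genes_small.index, seed=11)
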