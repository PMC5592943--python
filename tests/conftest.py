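"""Shared fixtures: simulated miRIL populations at two scales.

``small_*`` fixtures are cheap and used by most unit tests; the
``default_*`` family is the full study-scale data set (33 lines,
5000 extra features on top of the 8480-gene reference panel) shared by
the parameter-recovery and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import mirileqtl as mq


@pytest.fixture(scope="session")
def small_genotypes() -> mq.GenotypeMatrix:
    """33 lines on two chromosomes; fast."""
    return mq.simulate_miril_genotypes(
        n_lines=33,
        chromosomes=[("1", 12_000_000), ("2", 12_000_000)],
        marker_spacing=500_000,
        selected_locus=("2", 6_000_000),
        seed=11,
    )


@pytest.fixture(scope="session")
def default_genotypes() -> mq.GenotypeMatrix:
    return mq.simulate_miril_genotypes(n_lines=33, seed=101)


@pytest.fixture(scope="session")
def default_panel(default_genotypes) -> mq.ReferenceCisPanel:
    return mq.simulate_reference_cis_panel(default_genotypes, seed=102)


@pytest.fixture(scope="session")
def default_architecture(default_genotypes, default_panel) -> mq.TrueArchitecture:
    return mq.plant_architecture(
        default_genotypes, n_features=5000, panel=default_panel, seed=103
    )


@pytest.fixture(scope="session")
def default_expression(default_genotypes, default_architecture) -> mq.ExpressionMatrix:
    return mq.simulate_expression(default_genotypes, default_architecture, seed=104)


@pytest.fixture(scope="session")
def default_map(default_expression, default_panel) -> mq.GenotypeMatrix:
    """Informative expression-marker map derived from the default data."""
    centered = mq.center_on_parents(default_expression)
    calls = mq.call_expression_markers(centered, default_panel)
    qc = mq.qc_filter_markers(calls, default_expression.parental_genotype)
    geno, _ = mq.impute_and_extend(qc)
    pruned, _ = mq.prune_informative_markers(geno)
    return pruned


@pytest.fixture(scope="session")
def default_records(default_expression, default_map) -> pd.DataFrame:
    """Classified eQTL records at the headline threshold of 3.2."""
    scanm = mq.scan(default_expression, default_map)
    rec = mq.call_peaks(scanm, default_expression.features, threshold=3.2)
    return mq.classify_cis_trans(rec)


def balanced_genotypes(n_strains: int, n_markers: int, seed: int) -> mq.GenotypeMatrix:
    """Direct (non-meiotic) genotype matrix with independent 0/1 markers."""
    rng = np.random.default_rng(seed)
    calls = pd.DataFrame(
        rng.integers(0, 2, size=(n_strains, n_markers)).astype(float),
        index=[f"s{i}" for i in range(n_strains)],
        columns=[f"c1:{(j + 1) * 1000}" for j in range(n_markers)],
    )
    markers = pd.DataFrame(
        {
            "marker_id": calls.columns,
            "chrom": "c1",
            "pos_bp": [(j + 1) * 1000 for j in range(n_markers)],
        }
    )
    return mq.GenotypeMatrix(calls=calls, markers=markers)
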