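import numpy as np
import pandas as pd
import pytest

from twaskit import (
    SimulationConfig,
    TrainingConfig,
    gene_annotations,
    simulate_expression_panel,
    simulate_genotype_panel,
    train_model_database,
)
from twaskit.panel import GenotypePanel


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(seed=7, n_subjects=300, n_genes=12)


@pytest.fixture(scope="session")
def small_panel(small_cfg):
    return simulate_genotype_panel(small_cfg)


@pytest.fixture(scope="session")
def small_expression(small_cfg, small_panel):
    return simulate_expression_panel(small_panel, small_cfg)


@pytest.fixture(scope="session")
def small_db(small_cfg, small_panel, small_expression):
    expr, _ = small_expression
    db, skipped = train_model_database(
        small_panel,
        expr,
        gene_annotations(small_cfg),
        TrainingConfig(cv_scheme="kfold", seed=7),
    )
    assert len(db) > 0
    return db


def make_panel(variant_rows, dosages, subjects=None):
    """Hand-built panel: variant_rows = (id, chrom, pos, ref, alt, info_r2)."""
    variants = pd.DataFrame(
        variant_rows,
        columns=["variant_id", "chromosome", "position", "ref", "alt", "info_r2"],
    ).set_index("variant_id")
    return GenotypePanel(
        variants=variants, dosages=np.asarray(dosages, dtype=float), subjects=subjects
    )
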