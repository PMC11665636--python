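import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from grnimpute import (
    EqtlCatalog,
    ExpressionMatrix,
    GenotypeMatrix,
    PipelineConfig,
    simulate_dataset,
    split_samples,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """30 genes, 300 haploid samples, default effect scales."""
    geno, expr, catalog, truth = simulate_dataset(30, 300, seed=11)
    return geno, expr, catalog, truth


@pytest.fixture(scope="session")
def small_split(small_dataset):
    geno, expr, catalog, truth = small_dataset
    split = split_samples(geno.sample_ids, 0.8, seed=11)
    return {
        "geno_train": geno.restrict_samples(split.train_ids),
        "expr_train": expr.restrict_samples(split.train_ids),
        "geno_test": geno.restrict_samples(split.test_ids),
        "expr_test": expr.restrict_samples(split.test_ids),
        "catalog": catalog,
        "truth": truth,
        "config": PipelineConfig(seed=11),
    }


@pytest.fixture
def tiny_tables():
    """Hand-built 4-sample genotype/expression/catalog trio."""
    geno = GenotypeMatrix(
        pd.DataFrame(
            {"v1": [0, 1, 1, 0], "v2": [1, 0, 1, 0]},
            index=["s1", "s2", "s3", "s4"],
        ),
        ploidy=1,
    )
    expr = ExpressionMatrix(
        pd.DataFrame(
            {"gA": [0.1, 1.2, 0.9, -0.3], "gB": [1.0, 0.2, 0.5, 0.7]},
            index=["s1", "s2", "s3", "s4"],
        )
    )
    catalog = EqtlCatalog({"gA": ("v1",), "gB": ("v2",)})
    return geno, expr, catalog
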