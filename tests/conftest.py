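import warnings

import numpy as np
import pytest

from salexpr import pipeline
from salexpr import synthdata as sd
from salexpr.datatypes import ExpressionMatrix


@pytest.fixture(scope="session")
def small_geno():
    return sd.simulate_genotypes(
        n_accessions=60,
        chrom_lengths={"chr1": 8_000_000, "chr2": 8_000_000},
        n_snps=400,
        seed=11,
        n_subpops=2,
        fst=0.25,
    )


@pytest.fixture(scope="session")
def small_config():
    cfg = pipeline.default_config(23)
    cfg["genotypes"].update(
        n_accessions=60, n_snps=800,
        chrom_lengths={f"chr{i}": 12_000_000 for i in range(1, 4)},
    )
    cfg["architecture"].update(n_genes=200, hotspot_targets=35)
    cfg["fitness"].update(n_normal_only=8, n_saline_only=8, n_shared=4,
                          n_stabilizing=4)
    cfg["annotations"].update(n_terms=15, size_dist=["uniform", 20, 30])
    cfg["ld_test"]["n_perm"] = 200
    return cfg


@pytest.fixture(scope="session")
def small_study(small_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pipeline.simulate_study(small_config)


def make_expression(values, environment=None, accession=None, block=None):
    """Minimal ExpressionMatrix around a plain value matrix."""
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    return ExpressionMatrix(
        plant_ids=np.asarray([f"p{i}" for i in range(n)], object),
        accession=np.asarray(
            accession if accession is not None else [f"a{i}" for i in range(n)],
            object,
        ),
        environment=np.asarray(
            environment if environment is not None else ["normal"] * n, object
        ),
        block=np.asarray(block if block is not None else np.ones(n, int)),
        transcript_ids=np.asarray([f"t{j}" for j in range(k)], object),
        values=values,
    )
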