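import numpy as np
import pandas as pd
import pytest

import rstab


@pytest.fixture
def tiny_config():
    """A small but fully structured study: 2 populations, causal SNP 0."""
    return rstab.SimulationConfig(
        n_samples=30, n_pops=2, fst=0.1, n_snps=100, n_genes=200,
        effect_size=0.2, causal_snp_index=0, seed=7,
    )


@pytest.fixture
def tiny_study(tiny_config):
    genotypes = rstab.simulate_genotypes(tiny_config)
    halflife = rstab.simulate_halflife_table(tiny_config)
    expr = rstab.simulate_expression(genotypes, halflife, tiny_config)
    return genotypes, halflife, expr


def make_expression(values, gene_ids=None, sample_ids=None) -> pd.DataFrame:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                        columns=pd.Index(sample_ids, name="sample_id"))


def make_classification(long_ids, short_ids, scheme="half_life_threshold") -> pd.DataFrame:
    ids = list(long_ids) + list(short_ids)
    groups = ["LONG"] * len(long_ids) + ["SHORT"] * len(short_ids)
    return pd.DataFrame({"group": groups, "scheme": scheme},
                        index=pd.Index(ids, name="gene_id"))
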