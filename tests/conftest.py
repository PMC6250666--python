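import numpy as np
import pandas as pd
import pytest

from nephroqtl import eqtl, qc, synth


@pytest.fixture(scope="session")
def small_config():
    return synth.SimulationConfig(
        seed=11, n_samples_study1=80, n_samples_study2=50,
        n_blocks=12, snps_per_block=8, n_genes=8,
        frac_egenes=0.5, fixed_effect_size=1.0,
        expression_scale="sd",
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    geno = synth.simulate_genotypes(small_config)
    expr, truth = synth.simulate_expression(geno, small_config)
    return geno, expr, truth


def make_studies(geno, expr, n_pcs=3):
    """Assemble per-study StudyData with age/sex + genotype PCs."""
    studies = []
    for label in ("S1", "S2"):
        ids = geno.samples.index[geno.samples["study"] == label]
        sub = geno.subset_samples(ids)
        cov = pd.concat(
            [sub.samples[["age", "sex"]].astype(float), qc.genotype_pcs(sub, k=n_pcs)],
            axis=1,
        )
        studies.append(
            eqtl.StudyData(expr.values[list(ids)], sub.dosages, cov)
        )
    return studies


@pytest.fixture(scope="session")
def small_scan(small_dataset):
    geno, expr, _ = small_dataset
    studies = make_studies(geno, expr)
    pairs = eqtl.map_cis_pairs(expr.genes, geno.variants)
    meta = eqtl.run_cis_eqtl(studies, expr.genes, geno.variants, pairs=pairs)
    return studies, pairs, meta
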