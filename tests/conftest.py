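"""Shared fixtures: tiny chromosomes and small seeded synthetic datasets."""

import numpy as np
import pytest

import dosagescope as ds


@pytest.fixture
def circle100():
    """A 100 bp circle with oriC at 0 and ter at the antipode (50)."""
    return ds.CircularChromosome("toy", 100, oriC=0)


@pytest.fixture
def small_cfg():
    """A desk-scale simulation: 0.5 Mb, 300 genes, default noise."""
    return ds.SimulationConfig(L=500_000, n_genes=300, coverage_window=2500,
                               seed=7)


@pytest.fixture
def noiseless_cfg():
    """Noiseless variant for exact planted-truth identities."""
    return ds.SimulationConfig(L=500_000, n_genes=300, coverage_window=2500,
                               coverage_noise_sd=0.0, replicate_noise_sd=0.0,
                               seed=7)


@pytest.fixture
def fitted_model(noiseless_cfg):
    chrom, _ = ds.simulate_genome(noiseless_cfg)
    cov_e, cov_s = ds.simulate_coverage(noiseless_cfg, chrom)
    prof = ds.compute_mfa_profile(cov_e, cov_s, noiseless_cfg.coverage_window,
                                  noiseless_cfg.coverage_window)
    return ds.fit_copy_number_model(prof, chrom)


def flat_model_like(model):
    """A flat (copy number 1 everywhere) model on the same axis."""
    return ds.CopyNumberModel(model.length, model.oriC_est, model.ter_est,
                              0.0, 0.0, (0.0, 0.0), (0.0, 0.0), flat=True)
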