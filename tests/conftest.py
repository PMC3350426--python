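"""Shared fixtures: small simulated experiments with known truth."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from liverdev import synthdata
from liverdev.design import ExperimentDesign
from liverdev.synthdata import NoiseParams

ALL_SI = {"male-specific": 0.0, "female-specific": 0.0, "sex-independent": 1.0}


def make_null_truth(n: int, seed: int):
    """Sex-independent genes with no developmental change: every comparison
    is a self-self comparison in truth."""
    return synthdata.generate_truth(
        n, ALL_SI, seed=seed,
        dev_probs_male={"none": 1.0}, dev_probs_female={"none": 1.0},
    )


@pytest.fixture(scope="session")
def noiseless_noise() -> NoiseParams:
    return NoiseParams(sigma_add=0.0, sigma_mult=0.0, dye_bias_amplitude=0.0,
                       background_mean=0.5, background_sd=0.0,
                       frac_low_expressed=0.0)


@pytest.fixture(scope="session")
def small_truth():
    return synthdata.generate_truth(400, seed=7)


@pytest.fixture(scope="session")
def small_design():
    return ExperimentDesign(n_probes=420, n_redundant_genes=20, seed=7)


@pytest.fixture(scope="session")
def noiseless_arrays(small_truth, small_design, noiseless_noise):
    return synthdata.simulate_arrays(small_truth, small_design, noiseless_noise)


@pytest.fixture(scope="session")
def null_comparison_summary():
    """Summary of one self-self comparison under realistic noise."""
    from liverdev import arraynorm

    truth = make_null_truth(4000, seed=11)
    design = ExperimentDesign(n_probes=4000, n_redundant_genes=0, seed=11)
    noise = NoiseParams()
    arrays = synthdata.simulate_arrays(truth, design, noise)
    arrs = [a for a in arrays if a.comparison_id == "M3vF3"]
    summary = arraynorm.summarize_comparison(arrs, noise.sigma_add,
                                             noise.sigma_mult)
    low = synthdata.low_expressed_probes(design, noise)
    return summary, low
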