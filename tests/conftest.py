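import numpy as np
import pytest

from tagident import bayes_model, synthetic
from tagident.io_formats import Peak, Spectrum


@pytest.fixture
def simple_spectrum() -> Spectrum:
    peaks = [Peak(100.0, 10.0), Peak(200.0, 40.0), Peak(300.0, 90.0), Peak(400.0, 5.0)]
    return Spectrum(peaks=peaks, precursor_mz=500.0, precursor_charge=2, identifier="s1")


def ladder_spectrum(peptide: str, charge: int = 2, seed: int = 0) -> Spectrum:
    """Deterministic noise-free full-ladder spectrum of a peptide."""
    params = synthetic.noise_free_params(seed)
    spec, _ = synthetic.simulate_spectrum(peptide, charge, params, identifier=f"ladder|{peptide}")
    return spec


@pytest.fixture(scope="session")
def small_benchmark():
    """Small noise-free benchmark reused by unit tests (deterministic)."""
    params = synthetic.noise_free_params(seed=11)
    params.n_proteins = 60
    proteins, annotated = synthetic.generate_benchmark(params, 30)
    return proteins, annotated


@pytest.fixture(scope="session")
def trained_models(small_benchmark):
    _, annotated = small_benchmark
    return bayes_model.train(annotated)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
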