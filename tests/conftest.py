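"""Shared fixtures: the default nested-sphere study bundle.

Expensive objects (BEM transfer matrices, the focal candidate scan) are
session-scoped; tests must not mutate them.
"""

import numpy as np
import pytest
from hypothesis import settings as hyp_settings

hyp_settings.register_profile("deterministic", derandomize=True)
hyp_settings.load_profile("deterministic")

from cardinv import edl_inverse as EDL
from cardinv import forward as F
from cardinv import sources as S
from cardinv.edl_inverse import _fit_grid


@pytest.fixture(scope="session")
def dataset():
    """Default fixture bundle: geometry, T, A, truth timing, ECGs (seed 1)."""
    return S.generate_dataset(S.DatasetConfig(), seed=1)


@pytest.fixture(scope="session")
def model(dataset):
    return dataset.model


@pytest.fixture(scope="session")
def myocardial(dataset):
    return dataset.myocardial


@pytest.fixture(scope="session")
def tm_ep(dataset):
    return dataset.tm_ep


@pytest.fixture(scope="session")
def tm_edl(dataset):
    return dataset.tm_edl


@pytest.fixture(scope="session")
def template(dataset):
    return dataset.config.template


@pytest.fixture(scope="session")
def tm_ep_both(model):
    """EP transfer with the endocardium appended to the source registry."""
    return F.build_ep_transfer(model, include_endocardium=model.endocardium)


@pytest.fixture(scope="session")
def epi_truth_egms(dataset, template):
    """Truth epicardial electrograms (template-shaped) on the epi sheet."""
    nepi = dataset.tm_ep.n_sources
    timing = S.SourceTiming(tau=dataset.truth.tau[:nepi],
                            rho=dataset.truth.rho[:nepi])
    return S.template_electrograms(timing, template,
                                   dataset.ecg_clean.time_axis())


@pytest.fixture(scope="session")
def ep_forward_ecg(dataset, epi_truth_egms):
    """Noiseless body-surface ECG generated through the EP forward model."""
    tm = dataset.tm_ep
    return S.SignalSet(labels=list(tm.electrode_labels),
                       rate_hz=dataset.ecg_clean.rate_hz,
                       samples=tm.matrix @ epi_truth_egms.samples,
                       kind="ECG")


@pytest.fixture(scope="session")
def candidate_scan(dataset, template):
    """Focal fastest-route candidate scan for the default fixture."""
    config = EDL.EDLConfig()
    fit_t, _ = _fit_grid(dataset.ecg_clean, config.stride_ms)
    return EDL.CandidateScan(dataset.tm_edl, template, dataset.myocardial,
                             config, fit_t)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
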