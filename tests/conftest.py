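import numpy as np
import pytest

from fidmrsi.basis import (
    METABOLITE_SCAN,
    build_basis_set,
    default_resonance_table,
    fid_to_spectrum,
)
from fidmrsi.phantom import assign_truth_concentrations, build_phantom, synthesize_subject


@pytest.fixture(scope="session")
def met_basis():
    return build_basis_set(default_resonance_table(), METABOLITE_SCAN)


@pytest.fixture(scope="session")
def small_phantom():
    ph = build_phantom((16, 16, 8), seed=1)
    assign_truth_concentrations(ph, n_subjects=3, inter_subject_cv=10.0, seed=2)
    return ph


@pytest.fixture(scope="session")
def noiseless_subject(small_phantom, met_basis):
    return synthesize_subject(small_phantom, 0, met_basis, noise_sd=0.0, seed=3)


@pytest.fixture(scope="session")
def lipid_subject(small_phantom, met_basis):
    """Same subject, same seed, but with scalp lipid contamination."""
    return synthesize_subject(
        small_phantom, 0, met_basis, noise_sd=0.0, lipid_amplitude=5.0, seed=3
    )


@pytest.fixture(scope="session")
def noiseless_spectra(noiseless_subject, met_basis):
    spec, ppm = fid_to_spectrum(noiseless_subject.metabolite_fids, met_basis.sampling_bandwidth)
    return spec, ppm


@pytest.fixture(scope="session")
def gm_voxel(small_phantom):
    """Index of a strongly GM-dominated brain voxel."""
    return tuple(np.argwhere((small_phantom.f_gm > 0.9) & small_phantom.brain_mask)[0])
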