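import numpy as np
import pytest

import eegstates as es


@pytest.fixture(scope="session")
def montage16():
    return es.generate_montage(16, seed=2)


@pytest.fixture(scope="session")
def montage32():
    return es.generate_montage(32, seed=1)


@pytest.fixture(scope="session")
def templates32(montage32):
    return es.generate_templates(4, montage32, seed=7)


@pytest.fixture(scope="session")
def small_spec():
    """A fast spec for plumbing tests (not the study-scale conditions)."""
    return es.SimSpec(n_hc=3, n_pd=3, n_channels=16, record_length=20.0)


@pytest.fixture(scope="session")
def noisy_subject(montage32, templates32):
    """One 300-s subject at the study conditions (snr 10 dB, fs 250)."""
    spec = es.SimSpec()
    seq = es.generate_state_sequence(spec, "PD_OFF", seed=41)
    rec = es.synthesize_eeg(templates32, seq, spec, seed=42, montage=montage32)
    return spec, seq, es.average_reference(rec)


def rle(labels):
    """Run lengths of a 1-D integer sequence (helper for ground-truth dwell)."""
    labels = np.asarray(labels)
    change = np.flatnonzero(np.diff(labels) != 0) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    return labels[starts], ends - starts
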