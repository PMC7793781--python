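import numpy as np
import pytest

from gpdcpipe import preprocess, synth
from gpdcpipe.sessions import SessionRecording


@pytest.fixture(scope="session")
def coupled_model():
    """VAR(1) with one planted directed edge AF07 → TP10 (strength 0.4)."""
    return synth.make_var_model([("AF07", "TP10", 0.4)], base_diag=0.5)


@pytest.fixture(scope="session")
def clean_session(coupled_model):
    return synth.generate_session(
        coupled_model, 90.0, synth.ArtifactPlan(), "Preparation", seed=11,
        session_id="clean90",
    )


@pytest.fixture(scope="session")
def clean_epochs(clean_session):
    return preprocess.preprocess_session(clean_session)


def make_recording(duration_s, seed=0, eeg_sd=5.0, session_id="short",
                   stage="Preparation"):
    """Directly assembled short recording (bypasses the generator's
    minimum-duration precondition) with benign Gaussian streams."""
    rng = np.random.default_rng(seed)
    n_e = int(round(duration_s * 220))
    n_a = int(round(duration_s * 50))
    n_c = int(round(duration_s * 10))
    return SessionRecording(
        session_id=session_id,
        participant_id="P1",
        stage=stage,
        eeg=rng.normal(0, eeg_sd, (4, n_e)),
        accel=rng.normal(0, 0.05, (3, n_a)),
        contact=np.ones((4, n_c), dtype=int),
    )


def naive_sampen(x, m=2, r_factor=0.2):
    """Brute-force O(N²) Sample Entropy by literal template counting."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    sd = x.std()
    if sd == 0:
        return float("nan")
    r = r_factor * sd
    nt = n - m
    a = b = 0
    for i in range(nt):
        for j in range(nt):
            if i == j:
                continue
            dm = max(abs(x[i + k] - x[j + k]) for k in range(m))
            if dm <= r:
                b += 1
                if max(dm, abs(x[i + m] - x[j + m])) <= r:
                    a += 1
    if a == 0 or b == 0:
        return float("nan")
    return float(-np.log(a / b))
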