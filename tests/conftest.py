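import numpy as np
import pytest

from emgbicoh.hosa import HosaParams
from emgbicoh.records import EmgRecord
from emgbicoh.synth import CohortSpec, QpcSpec, generate_cohort, generate_qpc_signal

TINY_PARAMS = HosaParams(nfft=16, seg_len=16, overlap_frac=0.0)


@pytest.fixture(scope="session")
def coupled_record() -> EmgRecord:
    """Fully phase-coupled (lambda=1) noiseless test signal, 64 segments."""
    spec = QpcSpec(f1=60.0, f2=90.0, coupling=1.0)
    return generate_qpc_signal(spec, 64 * 512, 1500.0, seed=11, block_len=512)


@pytest.fixture(scope="session")
def uncoupled_record() -> EmgRecord:
    """Same components with independent sum-phase (lambda=0), 128 segments."""
    spec = QpcSpec(f1=60.0, f2=90.0, coupling=0.0)
    return generate_qpc_signal(spec, 128 * 512, 1500.0, seed=12, block_len=512)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small cohort: 3+3 subjects, 2 trials, 2 muscles, 2 s trials."""
    spec = CohortSpec(
        n_subjects_per_class=3,
        trials_per_subject=2,
        trial_duration_s=2.0,
        muscles=("BF", "MG"),
        seed=5,
    )
    return generate_cohort(spec)


def tiny_random_record(seed: int, n: int = 80, fs: float = 32.0) -> EmgRecord:
    rng = np.random.default_rng(seed)
    return EmgRecord(samples=rng.normal(size=n), fs=fs)
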