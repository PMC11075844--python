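"""Synthetic phase-coupled EMG cohorts.

Bicoherence detects quadratic phase coupling (QPC): power at a sum frequency
f1+f2 whose phase equals the sum of the component phases. The generator here
produces exactly that structure with a controllable coupled fraction
``lambda``, so the whole downstream pipeline (filtering, bicoherence,
imaging, classification) has a ground truth: ``lambda=1`` drives the
coupled-bin bicoherence to 1 asymptotically, ``lambda=0`` to 0.

A cohort mimics the structure of a gait-lab walking study: two balanced
classes (Normal / KOA), ten subjects per class, five walking trials per
subject, five knee-spanning muscles per trial, sampled at 1500 Hz, with a
1 Hz raised-cosine burst envelope standing in for gait cycles. The two
classes differ only in coupling strength.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import MUSCLES, EmgRecord

__all__ = [
    "QpcSpec",
    "CohortSpec",
    "generate_qpc_signal",
    "generate_cohort",
    "DEFAULT_CLASS_QPC",
]


@dataclass(frozen=True)
class QpcSpec:
    """Parameters of one quadratically phase-coupled test signal.

    Parameters
    ----------
    f1, f2 : float
        Component frequencies in Hz, ``0 < f1 < f2``. A third component sits
        at ``f1 + f2``.
    coupling : float
        Fraction ``lambda`` in [0, 1] of realization blocks in which the sum
        component's phase is locked to ``phi1 + phi2``; elsewhere it is an
        independent uniform draw.
    amplitudes : tuple of float
        Amplitudes of the f1, f2 and f1+f2 components.
    snr_db : float
        Signal-to-noise ratio of the added white Gaussian noise in dB;
        ``math.inf`` disables noise.
    envelope_rate : float
        Rate in Hz of the raised-cosine burst amplitude envelope emulating
        gait cycles; 0 disables the envelope.
    """

    f1: float = 80.0
    f2: float = 140.0
    coupling: float = 0.5
    amplitudes: tuple[float, float, float] = (1.0, 1.0, 1.0)
    snr_db: float = math.inf
    envelope_rate: float = 0.0

    def validate(self, fs: float) -> None:
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError(f"coupling must be in [0, 1], got {self.coupling}")
        if not 0 < self.f1 < self.f2:
            raise ValueError(f"need 0 < f1 < f2, got f1={self.f1}, f2={self.f2}")
        if self.f1 + self.f2 >= fs / 2:
            raise ValueError(
                f"f1 + f2 = {self.f1 + self.f2} Hz aliases at fs = {fs} Hz "
                "(must be below fs/2)"
            )
        if len(self.amplitudes) != 3:
            raise ValueError("amplitudes must have three entries (f1, f2, f1+f2)")


#: Class-conditional coupling: weak residual coupling for Normal, strong for KOA.
DEFAULT_CLASS_QPC: dict[str, QpcSpec] = {
    "Normal": QpcSpec(coupling=0.2, snr_db=10.0, envelope_rate=1.0),
    "KOA": QpcSpec(coupling=0.9, snr_db=10.0, envelope_rate=1.0),
}


@dataclass(frozen=True)
class CohortSpec:
    """Layout of a synthetic two-class walking cohort."""

    n_subjects_per_class: int = 10
    trials_per_subject: int = 5
    trial_duration_s: float = 5.0
    fs: float = 1500.0
    muscles: tuple[str, ...] = MUSCLES
    class_qpc: dict[str, QpcSpec] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_QPC)
    )
    seed: int = 0

    def validate(self) -> None:
        if self.trials_per_subject < 1:
            raise ValueError("trials_per_subject must be >= 1")
        if self.n_subjects_per_class < 1:
            raise ValueError("n_subjects_per_class must be >= 1")
        if not self.muscles:
            raise ValueError("muscle list must be non-empty")
        for label, spec in self.class_qpc.items():
            spec.validate(self.fs)
            for f in (spec.f1, spec.f2):
                if self.fs <= 2 * f:
                    raise ValueError(
                        f"fs = {self.fs} must exceed twice every component "
                        f"frequency ({label}: {f} Hz)"
                    )


def _qpc_samples(
    spec: QpcSpec,
    n_samples: int,
    fs: float,
    rng: np.random.Generator,
    block_len: int,
) -> np.ndarray:
    t = np.arange(n_samples) / fs
    n_blocks = -(-n_samples // block_len)  # ceil
    a1, a2, a3 = spec.amplitudes
    f3 = spec.f1 + spec.f2
    x = np.empty(n_samples)
    for b in range(n_blocks):
        sl = slice(b * block_len, min((b + 1) * block_len, n_samples))
        phi1, phi2 = rng.uniform(0.0, 2 * np.pi, size=2)
        if rng.random() < spec.coupling:
            phi3 = phi1 + phi2
        else:
            phi3 = rng.uniform(0.0, 2 * np.pi)
        tb = t[sl]
        x[sl] = (
            a1 * np.cos(2 * np.pi * spec.f1 * tb + phi1)
            + a2 * np.cos(2 * np.pi * spec.f2 * tb + phi2)
            + a3 * np.cos(2 * np.pi * f3 * tb + phi3)
        )
    if spec.envelope_rate > 0:
        x *= np.sin(np.pi * spec.envelope_rate * t) ** 2
    if math.isfinite(spec.snr_db):
        p_signal = float(np.mean(x**2))
        p_noise = p_signal / 10.0 ** (spec.snr_db / 10.0)
        x = x + rng.normal(0.0, math.sqrt(p_noise), size=n_samples)
    return x


def generate_qpc_signal(
    spec: QpcSpec,
    n_samples: int,
    fs: float,
    seed: int,
    block_len: int = 128,
    **labels,
) -> EmgRecord:
    """Generate one quadratically phase-coupled test record.

    Phases are redrawn independently every ``block_len`` samples so that
    segment-averaged estimators see independent realizations; ``block_len``
    should match the bicoherence segment length (it defaults to the
    estimator's default of 128 samples).
    """
    spec.validate(fs)
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = np.random.default_rng(seed)
    x = _qpc_samples(spec, n_samples, fs, rng, block_len)
    return EmgRecord(samples=x, fs=fs, **labels)


def _subject_jitter(spec: QpcSpec, rng: np.random.Generator) -> QpcSpec:
    """Small seeded per-subject perturbation: +-5% amplitudes, +-2 Hz frequencies."""
    amps = tuple(a * (1.0 + rng.uniform(-0.05, 0.05)) for a in spec.amplitudes)
    df1, df2 = rng.uniform(-2.0, 2.0, size=2)
    return QpcSpec(
        f1=spec.f1 + df1,
        f2=spec.f2 + df2,
        coupling=spec.coupling,
        amplitudes=amps,
        snr_db=spec.snr_db,
        envelope_rate=spec.envelope_rate,
    )


def generate_cohort(
    spec: CohortSpec, block_len: int = 128
) -> tuple[list[EmgRecord], pd.DataFrame]:
    """Generate a full two-class cohort and its manifest.

    Returns ``n_subjects_per_class * trials_per_subject * len(muscles)``
    records per class, plus a manifest DataFrame with one row per record
    (columns ``record_index, subject_id, muscle, class_label, trial_id``).
    Identical ``spec`` (including seed) reproduces the cohort exactly.
    """
    spec.validate()
    n_samples = int(round(spec.trial_duration_s * spec.fs))
    root = np.random.SeedSequence(spec.seed)
    records: list[EmgRecord] = []
    rows = []
    class_seeds = root.spawn(len(spec.class_qpc))
    for cls_seq, (class_label, qpc) in zip(class_seeds, spec.class_qpc.items()):
        subj_seqs = cls_seq.spawn(spec.n_subjects_per_class)
        for s_idx, subj_seq in enumerate(subj_seqs):
            subject_id = f"{class_label[0]}{s_idx + 1:02d}"
            subj_rng = np.random.default_rng(subj_seq)
            subj_qpc = _subject_jitter(qpc, subj_rng)
            for trial in range(spec.trials_per_subject):
                trial_id = f"t{trial + 1}"
                for muscle in spec.muscles:
                    x = _qpc_samples(
                        subj_qpc, n_samples, spec.fs, subj_rng, block_len
                    )
                    rec = EmgRecord(
                        samples=x,
                        fs=spec.fs,
                        subject_id=subject_id,
                        muscle=muscle,
                        class_label=class_label,
                        trial_id=trial_id,
                    )
                    rows.append(
                        {
                            "record_index": len(records),
                            "subject_id": subject_id,
                            "muscle": muscle,
                            "class_label": class_label,
                            "trial_id": trial_id,
                        }
                    )
                    records.append(rec)
    manifest = pd.DataFrame(rows)
    return records, manifest
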