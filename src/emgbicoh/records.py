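"""Surface-EMG records and their plain-text on-disk form.

A record is one muscle's sample stream plus acquisition metadata. On disk a
record is a single-column float text file ``<name>.txt`` with a JSON sidecar
``<name>.json`` carrying sampling rate and labels, so recordings survive in
any text editor and under version control.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

MUSCLES = ("BF", "MG", "RF", "ST", "VM")
CLASSES = ("Normal", "KOA")

#: JSON sidecar keys that must be present when reading a record.
SIDECAR_FIELDS = ("fs", "subject_id", "muscle", "class_label", "trial_id")


class FormatError(ValueError):
    """A record file or sidecar does not match the expected layout."""


@dataclass
class EmgRecord:
    """One muscle's EMG sample stream.

    Parameters
    ----------
    samples : ndarray of float
        Signal in arbitrary (amplifier) units.
    fs : float
        Sampling rate in Hz.
    subject_id, muscle, class_label, trial_id : str
        Provenance labels. ``muscle`` is one of BF, MG, RF, ST, VM
        (biceps femoris, medial gastrocnemius, rectus femoris,
        semitendinosus, vastus medialis); ``class_label`` is Normal or KOA.
    """

    samples: np.ndarray
    fs: float
    subject_id: str = ""
    muscle: str = ""
    class_label: str = ""
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("samples must be a 1-D sequence of length >= 2")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def with_samples(self, samples: np.ndarray) -> "EmgRecord":
        """New record with the same metadata but different samples."""
        return replace(self, samples=np.asarray(samples, dtype=float))

    def meta(self) -> dict:
        return {
            "fs": self.fs,
            "subject_id": self.subject_id,
            "muscle": self.muscle,
            "class_label": self.class_label,
            "trial_id": self.trial_id,
        }


def write_record(record: EmgRecord, path: str | Path) -> Path:
    """Write *record* as float text plus a JSON sidecar.

    ``path`` may end in ``.txt`` or be extension-free; the sidecar is written
    next to it with the same stem and ``.json``. Samples are written with
    ``repr``-exact precision so a round trip is bit-identical.
    """
    path = Path(path)
    if path.suffix != ".txt":
        path = path.with_suffix(".txt")
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="\n") as fh:
        for v in record.samples:
            fh.write(f"{float(v)!r}\n")
    sidecar = path.with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump(record.meta(), fh, indent=2)
        fh.write("\n")
    return path


def read_record(path: str | Path) -> EmgRecord:
    """Read a record written by :func:`write_record`.

    Tolerates CRLF/LF line endings and blank trailing lines. Raises
    :class:`FormatError` if the sidecar is missing required fields and
    ``ValueError`` on non-numeric samples.
    """
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FormatError(f"missing sidecar {sidecar}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    for key in SIDECAR_FIELDS:
        if key not in meta:
            raise FormatError(f"sidecar {sidecar} missing required field {key!r}")
    values = []
    with open(path, newline=None) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                values.append(float(line))
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric sample {line!r}"
                ) from exc
    return EmgRecord(samples=np.array(values, dtype=float), **meta)
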