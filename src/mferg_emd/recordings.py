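"""Domain types and tabular I/O for multifocal ERG recordings.

A recording holds the 61 first-order-kernel sector traces of one eye
(84 samples at 1017 Hz by default, amplitudes in nV).  The on-disk
interchange format is a long-form CSV with one row per sample:

    subject_id,group,eye,sector,sample_index,value_nV

Sample indices are 0-based; the time of sample ``m`` is
``m / sampling_rate_hz`` seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

N_SECTORS = 61
DEFAULT_N_SAMPLES = 84
DEFAULT_SAMPLING_RATE_HZ = 1017.0

GROUPS = ("control", "patient")
EYES = ("right", "left")

CSV_COLUMNS = ["subject_id", "group", "eye", "sector", "sample_index", "value_nV"]


class ValidationError(ValueError):
    """A cohort file or recording violates the format contract."""


@dataclass
class MfERGRecording:
    """One subject's 61 sector traces plus acquisition metadata.

    ``sectors`` maps sector index (1..61) to a trace of ``n_samples``
    amplitudes in nV.  The mapping is allowed to be malformed so that
    :func:`validate_recording` can report violations instead of raising.
    """

    subject_id: str
    group: str
    sectors: dict[int, np.ndarray]
    eye: str = "right"
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ
    n_samples: int = DEFAULT_N_SAMPLES

    def sector(self, index: int) -> np.ndarray:
        return self.sectors[index]

    def as_array(self) -> np.ndarray:
        """Stack traces into a (61, n_samples) array ordered by sector index."""
        return np.stack([self.sectors[s] for s in range(1, N_SECTORS + 1)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MfERGRecording):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.group == other.group
            and self.eye == other.eye
            and self.sampling_rate_hz == other.sampling_rate_hz
            and self.n_samples == other.n_samples
            and set(self.sectors) == set(other.sectors)
            and all(
                np.array_equal(self.sectors[s], other.sectors[s]) for s in self.sectors
            )
        )


@dataclass
class Cohort:
    """A list of recordings sharing geometry (sampling rate, trace length)."""

    recordings: list[MfERGRecording] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.recordings)

    def __iter__(self):
        return iter(self.recordings)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return self.recordings == other.recordings

    @property
    def controls(self) -> list[MfERGRecording]:
        return [r for r in self.recordings if r.group == "control"]

    @property
    def patients(self) -> list[MfERGRecording]:
        return [r for r in self.recordings if r.group == "patient"]

    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.recordings]

    def validate(self) -> list[str]:
        """All invariant violations across the cohort, as human-readable strings."""
        violations: list[str] = []
        ids = self.subject_ids()
        for sid in sorted({i for i in ids if ids.count(i) > 1}):
            violations.append(f"duplicate subject_id {sid!r}")
        rates = {r.sampling_rate_hz for r in self.recordings}
        if len(rates) > 1:
            violations.append(f"mixed sampling rates {sorted(rates)}")
        lengths = {r.n_samples for r in self.recordings}
        if len(lengths) > 1:
            violations.append(f"mixed trace lengths {sorted(lengths)}")
        for rec in self.recordings:
            violations.extend(validate_recording(rec))
        return violations


def validate_recording(rec: MfERGRecording) -> list[str]:
    """Return the list of invariant violations (empty iff the recording is valid).

    Never raises on a malformed-but-parseable recording.
    """
    v: list[str] = []
    who = f"subject {rec.subject_id!r}"
    if rec.group not in GROUPS:
        v.append(f"{who}: unknown group {rec.group!r} (expected one of {GROUPS})")
    if rec.eye not in EYES:
        v.append(f"{who}: unknown eye {rec.eye!r} (expected one of {EYES})")
    if not rec.sampling_rate_hz > 0:
        v.append(f"{who}: sampling_rate_hz must be positive, got {rec.sampling_rate_hz}")
    expected = set(range(1, N_SECTORS + 1))
    present = set(rec.sectors)
    missing = sorted(expected - present)
    extra = sorted(present - expected)
    if missing:
        v.append(f"{who}: missing sector(s) {missing}")
    for s in extra:
        v.append(f"{who}: unexpected sector {s} (valid sectors are 1..{N_SECTORS})")
    for s in sorted(present & expected):
        trace = np.asarray(rec.sectors[s], dtype=float)
        if trace.ndim != 1 or trace.shape[0] != rec.n_samples:
            v.append(
                f"{who}: sector {s} has {trace.size} samples, expected {rec.n_samples}"
            )
        elif not np.all(np.isfinite(trace)):
            v.append(f"{who}: sector {s} contains non-finite values")
    return v


def _recording_to_frame(rec: MfERGRecording) -> pd.DataFrame:
    rows = []
    for s in sorted(rec.sectors):
        trace = np.asarray(rec.sectors[s], dtype=float)
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": rec.subject_id,
                    "group": rec.group,
                    "eye": rec.eye,
                    "sector": s,
                    "sample_index": np.arange(trace.size),
                    "value_nV": trace,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort to long-form CSV (one row per sample, full float precision)."""
    path = Path(path)
    if len(cohort) == 0:
        frame = pd.DataFrame(columns=CSV_COLUMNS)
    else:
        frame = pd.concat(
            [_recording_to_frame(r) for r in cohort.recordings], ignore_index=True
        )
    # default float formatting uses the shortest round-trippable repr
    frame.to_csv(path, index=False)


def read_cohort(
    path: str | Path,
    *,
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
    strict: bool = True,
) -> Cohort:
    """Read a long-form CSV cohort file and validate it.

    Parameters
    ----------
    sampling_rate_hz:
        The format does not carry the sampling rate; supply it here
        (default 1017 Hz).
    strict:
        When True (default) raise :class:`ValidationError` on any invariant
        violation; when False return the cohort as parsed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    missing_cols = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise ValidationError(f"{path}: missing column(s) {missing_cols}")

    recordings: list[MfERGRecording] = []
    n_samples: int | None = None
    for sid, sub in frame.groupby("subject_id", sort=True):
        groups = sub["group"].unique()
        eyes = sub["eye"].unique()
        sectors: dict[int, np.ndarray] = {}
        for sector, block in sub.groupby("sector", sort=True):
            block = block.sort_values("sample_index")
            idx = block["sample_index"].to_numpy()
            if not np.array_equal(idx, np.arange(idx.size)):
                raise ValidationError(
                    f"subject {sid!r} sector {sector}: sample_index must be "
                    f"contiguous from 0"
                )
            sectors[int(sector)] = block["value_nV"].to_numpy(dtype=float)
        if n_samples is None:
            n_samples = max((t.size for t in sectors.values()), default=0)
        rec = MfERGRecording(
            subject_id=str(sid),
            group=str(groups[0]),
            eye=str(eyes[0]),
            sectors=sectors,
            sampling_rate_hz=sampling_rate_hz,
            n_samples=n_samples,
        )
        recordings.append(rec)

    cohort = Cohort(recordings)
    if strict:
        violations = cohort.validate()
        if violations:
            raise ValidationError(
                f"{path}: invalid cohort:\n  " + "\n  ".join(violations)
            )
    return cohort


def cohort_from_arrays(
    specs: Iterable[tuple[str, str, np.ndarray]],
    *,
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
) -> Cohort:
    """Build a cohort from ``(subject_id, group, (61, n) array)`` triples."""
    recs = []
    for sid, group, arr in specs:
        arr = np.asarray(arr, dtype=float)
        sectors = {s + 1: arr[s] for s in range(arr.shape[0])}
        recs.append(
            MfERGRecording(
                subject_id=sid,
                group=group,
                sectors=sectors,
                sampling_rate_hz=sampling_rate_hz,
                n_samples=arr.shape[1],
            )
        )
    return Cohort(recs)
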