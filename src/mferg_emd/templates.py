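"""Normative database: per-sector average traces from control subjects.

The template for sector S is the sample-wise arithmetic mean of the
control subjects' sector-S traces.  When a control subject is itself being
evaluated, a leave-one-out (LOO) variant excluding that subject is used to
avoid biasing the comparison; patients are always evaluated against the
full template.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .recordings import MfERGRecording, N_SECTORS


@dataclass
class NormativeTemplate:
    """Per-sector mean control traces, with provenance."""

    sector_templates: dict[int, np.ndarray]
    source_ids: list[str]
    excluded_id: str | None = None

    @property
    def n_samples(self) -> int:
        return next(iter(self.sector_templates.values())).shape[0]

    @property
    def ref(self) -> str:
        """Identifier recording which template a result was computed against."""
        if self.excluded_id is None:
            return f"full[n={len(self.source_ids)}]"
        return f"loo[n={len(self.source_ids)},excluded={self.excluded_id}]"

    def sector(self, index: int) -> np.ndarray:
        return self.sector_templates[index]


def _check_geometry(controls: list[MfERGRecording]) -> None:
    rates = {r.sampling_rate_hz for r in controls}
    lengths = {r.n_samples for r in controls}
    if len(rates) > 1:
        raise ValueError(f"controls have mixed sampling rates: {sorted(rates)}")
    if len(lengths) > 1:
        raise ValueError(f"controls have mixed trace lengths: {sorted(lengths)}")


def build_template(controls: list[MfERGRecording]) -> NormativeTemplate:
    """Sample-wise mean over all control recordings, per sector."""
    if len(controls) < 2:
        raise ValueError(f"need at least 2 control recordings, got {len(controls)}")
    _check_geometry(controls)
    stacks = np.stack([r.as_array() for r in controls])  # (n_controls, 61, n)
    mean = stacks.mean(axis=0)
    return NormativeTemplate(
        sector_templates={s + 1: mean[s] for s in range(N_SECTORS)},
        source_ids=[r.subject_id for r in controls],
    )


def build_loo_template(
    controls: list[MfERGRecording], excluded: str
) -> NormativeTemplate:
    """Mean over the controls other than ``excluded`` (leave-one-out)."""
    ids = [r.subject_id for r in controls]
    if excluded not in ids:
        raise ValueError(f"subject {excluded!r} not among controls {ids}")
    if len(controls) < 3:
        raise ValueError(
            f"leave-one-out needs at least 3 controls, got {len(controls)}"
        )
    retained = [r for r in controls if r.subject_id != excluded]
    template = build_template(retained)
    template.excluded_id = excluded
    return template


def write_template(template: NormativeTemplate, path: str | Path) -> None:
    """Export as long CSV (sector, sample_index, value_nV)."""
    rows = []
    for s in sorted(template.sector_templates):
        trace = template.sector_templates[s]
        rows.append(
            pd.DataFrame(
                {
                    "sector": s,
                    "sample_index": np.arange(trace.size),
                    "value_nV": trace,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_template(path: str | Path) -> NormativeTemplate:
    frame = pd.read_csv(path, float_precision="round_trip")
    sectors = {
        int(s): block.sort_values("sample_index")["value_nV"].to_numpy(dtype=float)
        for s, block in frame.groupby("sector")
    }
    return NormativeTemplate(sector_templates=sectors, source_ids=[])
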