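"""Per-sector adaptive EMD filter.

Each sector trace is decomposed into 4 IMFs plus residue, and the four
partial reconstructions (suffix sums of the IMF sequence plus residue) are
compared against the normative template for the same sector.  The
reconstruction with the highest Pearson correlation with the template is
kept as the filtered trace.  When all four correlations are negative (or
undefined, e.g. a constant reconstruction), the sector is flagged
non-analyzable (NaS) — typical of heavily noise-contaminated records.

Conventions the selection rule itself does not fix:

* ties in correlation (within 1e-12) go to the smaller k, retaining more
  signal content;
* an undefined correlation (zero-variance reconstruction) counts as
  negative for the NaS rule;
* a correlation of exactly 0 is not negative — such a sector is kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import emd
from .recordings import MfERGRecording
from .templates import NormativeTemplate

TIE_TOL = 1e-12


@dataclass
class SectorFilterResult:
    """Outcome of filtering one sector: a kept reconstruction or NaS."""

    trace: np.ndarray | None
    chosen_k: int | None
    correlation: float | None
    correlations: tuple[float | None, ...] = ()
    imf_energy_fraction: float | None = None

    @property
    def is_nas(self) -> bool:
        return self.trace is None


@dataclass
class FilteredRecording:
    """Filtered sector traces for one subject, plus provenance."""

    subject_id: str
    group: str
    sectors: dict[int, SectorFilterResult]
    template_ref: str = ""

    @property
    def nas_sectors(self) -> list[int]:
        return sorted(s for s, r in self.sectors.items() if r.is_nas)

    def sector_traces(self) -> dict[int, np.ndarray | None]:
        """Sector -> filtered trace, with None marking NaS sectors."""
        return {s: r.trace for s, r in self.sectors.items()}


def _pearson(a: np.ndarray, b: np.ndarray) -> float | None:
    """Sample Pearson correlation; None when either input has zero variance."""
    a = a - a.mean()
    b = b - b.mean()
    na = float(np.sqrt(np.sum(a * a)))
    nb = float(np.sqrt(np.sum(b * b)))
    if na == 0.0 or nb == 0.0:
        return None
    return float(np.dot(a, b) / (na * nb))


def filter_sector(
    trace: np.ndarray,
    template_trace: np.ndarray,
    *,
    sd_threshold: float = emd.DEFAULT_SD_THRESHOLD,
    max_sift: int = emd.DEFAULT_MAX_SIFT,
) -> SectorFilterResult:
    """Pick the partial reconstruction best correlated with the template.

    One EMD per sector; four candidate suffix sums; arg-max of the Pearson
    correlation with the template.  Returns a NaS result when every
    correlation is negative or undefined.
    """
    trace = np.asarray(trace, dtype=float)
    template_trace = np.asarray(template_trace, dtype=float)
    if trace.shape != template_trace.shape:
        raise ValueError(
            f"trace length {trace.shape} != template length {template_trace.shape}"
        )
    imfset = emd.decompose(trace, sd_threshold=sd_threshold, max_sift=max_sift)
    candidates = emd.partial_reconstructions(imfset)
    corrs = tuple(_pearson(c, template_trace) for c in candidates)
    try:
        efrac = emd.energy_fraction(imfset)
    except ValueError:
        efrac = None

    best_k: int | None = None
    best_corr = -np.inf
    for k, corr in enumerate(corrs, start=1):
        if corr is None:
            continue
        if corr > best_corr + TIE_TOL:
            best_corr = corr
            best_k = k
    if best_k is None or best_corr < 0.0:
        return SectorFilterResult(
            trace=None,
            chosen_k=None,
            correlation=None,
            correlations=corrs,
            imf_energy_fraction=efrac,
        )
    return SectorFilterResult(
        trace=candidates[best_k - 1],
        chosen_k=best_k,
        correlation=best_corr,
        correlations=corrs,
        imf_energy_fraction=efrac,
    )


def filter_recording(
    rec: MfERGRecording,
    template: NormativeTemplate,
    *,
    sd_threshold: float = emd.DEFAULT_SD_THRESHOLD,
    max_sift: int = emd.DEFAULT_MAX_SIFT,
) -> FilteredRecording:
    """Apply :func:`filter_sector` independently to each of the 61 sectors."""
    results: dict[int, SectorFilterResult] = {}
    for s in sorted(rec.sectors):
        try:
            results[s] = filter_sector(
                rec.sectors[s],
                template.sector(s),
                sd_threshold=sd_threshold,
                max_sift=max_sift,
            )
        except Exception as exc:  # re-raise with sector context
            raise type(exc)(f"sector {s}: {exc}") from exc
    return FilteredRecording(
        subject_id=rec.subject_id,
        group=rec.group,
        sectors=results,
        template_ref=template.ref,
    )


def imf_usage_table(filtered: list[FilteredRecording]):
    """Percentages of sectors by chosen k (1..4) and NaS, per group.

    Returns a pandas DataFrame with rows ``k=1..k=4, NaS`` and one column
    per group; each column sums to 100.
    """
    import pandas as pd

    rows = ["k=1", "k=2", "k=3", "k=4", "NaS"]
    counts: dict[str, np.ndarray] = {}
    for fr in filtered:
        col = counts.setdefault(fr.group, np.zeros(5))
        for res in fr.sectors.values():
            if res.is_nas:
                col[4] += 1
            else:
                col[res.chosen_k - 1] += 1
    data = {
        group: 100.0 * col / col.sum() for group, col in sorted(counts.items())
    }
    return pd.DataFrame(data, index=rows)
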