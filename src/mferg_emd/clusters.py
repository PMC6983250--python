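"""Sector clustering and per-cluster analysis features.

The 61 hexagonal sectors of the stimulus array are grouped into 10
clusters: the whole field (SUM), five concentric eccentricity rings
R1..R5 (sizes 1, 6, 12, 18, 24), and four quadrants (IN, SN, ST, IT —
inferior/superior nasal/temporal) of 15 sectors each over the 60
non-central sectors.  Cluster traces are sample-wise means of their
member sectors; sectors flagged non-analyzable are excluded from the
mean.

Two features are computed per cluster: the Pearson correlation with the
corresponding template cluster trace (on raw and on filtered signals) and
the N1 trough amplitude (on raw signals), defined as |baseline − minimum
in the 9–32 ms window| with the baseline the mean of all samples before
9 ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .recordings import Cohort, N_SECTORS
from .adaptive_filter import FilteredRecording
from .templates import NormativeTemplate

RING_NAMES = ("R1", "R2", "R3", "R4", "R5")
QUADRANT_NAMES = ("IN", "SN", "ST", "IT")
CLUSTER_NAMES = ("SUM",) + RING_NAMES + QUADRANT_NAMES

FEATURES = ("A_N1", "PCC_RAW", "PCC_EMD")

N1_WINDOW_MS = (9.0, 32.0)


class LayoutError(ValueError):
    pass


@dataclass(frozen=True)
class ClusterLayout:
    """Mapping cluster name -> set of member sector indices."""

    clusters: dict[str, frozenset[int]]

    def __getitem__(self, name: str) -> frozenset[int]:
        return self.clusters[name]

    def validate(self) -> None:
        all_sectors = frozenset(range(1, N_SECTORS + 1))
        if self["SUM"] != all_sectors:
            raise LayoutError("SUM must contain all 61 sectors")
        rings = [self[r] for r in RING_NAMES]
        if frozenset().union(*rings) != all_sectors or sum(map(len, rings)) != N_SECTORS:
            raise LayoutError("rings R1..R5 must partition sectors 1..61")
        quads = [self[q] for q in QUADRANT_NAMES]
        if sum(map(len, quads)) != len(frozenset().union(*quads)):
            raise LayoutError("quadrants must be pairwise disjoint")
        if not frozenset().union(*quads) <= all_sectors:
            raise LayoutError("quadrant members must be valid sector indices")


def _hex_positions() -> list[tuple[int, float, float]]:
    """(ring, x, y) for the 61 hexagon centres, rings 0..4 (flat-top axial grid)."""
    cells = []
    for q in range(-4, 5):
        for r in range(-4, 5):
            ring = (abs(q) + abs(r) + abs(q + r)) // 2
            if ring <= 4:
                x = 1.5 * q
                y = math.sqrt(3.0) * (r + q / 2.0)
                cells.append((ring, x, y))
    return cells


def default_layout() -> ClusterLayout:
    """The standard 61-hexagon geometry: rings of 1/6/12/18/24 sectors and
    four 15-sector quadrants over the non-central sectors.

    Sector numbering is ring-by-ring from the centre outward, counter-
    clockwise from the positive horizontal axis.  Quadrants are split by
    the vertical and horizontal meridians; sectors falling on a meridian
    are assigned by rank order around the circle so each quadrant has
    exactly 15 members.
    """
    cells = _hex_positions()

    def angle(x: float, y: float) -> float:
        return math.atan2(y, x) % (2.0 * math.pi)

    # number sectors: ring, then angle
    ordered = sorted(cells, key=lambda c: (c[0], angle(c[1], c[2])))
    sectors = {i + 1: c for i, c in enumerate(ordered)}

    rings: dict[str, set[int]] = {r: set() for r in RING_NAMES}
    for idx, (ring, _x, _y) in sectors.items():
        if ring > 0:
            rings[f"R{ring + 1}"].add(idx)
    rings["R1"] = {1}

    # quadrants: sort the 60 peripheral sectors by angle (ring breaks ties on
    # the meridians) and cut into four consecutive runs of 15
    peripheral = sorted(
        (i for i in sectors if i != 1),
        key=lambda i: (angle(sectors[i][1], sectors[i][2]), sectors[i][0]),
    )
    runs = [frozenset(peripheral[15 * j : 15 * (j + 1)]) for j in range(4)]
    # angular runs start at the +x axis and go counter-clockwise; for a right
    # eye the nasal hemifield is temporal-retina side, but cluster identity is
    # positional only: SN upper-left, ST upper-right, IT lower-right, IN lower-left
    quadrants = {"ST": runs[0], "SN": runs[1], "IN": runs[2], "IT": runs[3]}

    clusters: dict[str, frozenset[int]] = {
        "SUM": frozenset(range(1, N_SECTORS + 1)),
        **{name: frozenset(members) for name, members in rings.items()},
        **quadrants,
    }
    layout = ClusterLayout(clusters)
    layout.validate()
    return layout


def write_layout(layout: ClusterLayout, path: str | Path) -> None:
    """Export as editable CSV ``sector,ring,quadrant`` (quadrant empty when none)."""
    ring_of = {s: r for r in RING_NAMES for s in layout[r]}
    quad_of = {s: q for q in QUADRANT_NAMES for s in layout[q]}
    frame = pd.DataFrame(
        {
            "sector": range(1, N_SECTORS + 1),
            "ring": [ring_of[s] for s in range(1, N_SECTORS + 1)],
            "quadrant": [quad_of.get(s, "") for s in range(1, N_SECTORS + 1)],
        }
    )
    frame.to_csv(path, index=False)


def read_layout(path: str | Path) -> ClusterLayout:
    frame = pd.read_csv(path, keep_default_na=False)
    clusters: dict[str, set[int]] = {name: set() for name in CLUSTER_NAMES}
    for _, row in frame.iterrows():
        s = int(row["sector"])
        clusters["SUM"].add(s)
        clusters[str(row["ring"])].add(s)
        q = str(row["quadrant"])
        if q:
            clusters[q].add(s)
    layout = ClusterLayout({k: frozenset(v) for k, v in clusters.items()})
    layout.validate()
    return layout


@dataclass
class ClusterSignal:
    """Sample-wise mean trace over the usable member sectors of a cluster."""

    cluster: str
    trace: np.ndarray | None
    n_sectors_used: int
    n_sectors_excluded: int

    @property
    def defined(self) -> bool:
        return self.trace is not None


def average_cluster(
    sector_traces: dict[int, np.ndarray | None],
    layout: ClusterLayout,
    cluster: str,
) -> ClusterSignal:
    """Mean over the cluster's member sectors, skipping NaS (None) entries."""
    members = layout[cluster]
    used = [sector_traces[s] for s in sorted(members) if sector_traces[s] is not None]
    n_excluded = len(members) - len(used)
    if not used:
        return ClusterSignal(cluster, None, 0, n_excluded)
    return ClusterSignal(
        cluster, np.mean(used, axis=0), len(used), n_excluded
    )


def pearson_corr(a: np.ndarray, b: np.ndarray) -> float | None:
    """Sample Pearson correlation; None if either trace has zero variance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need at least 2 samples")
    ac = a - a.mean()
    bc = b - b.mean()
    na = float(np.sqrt(np.sum(ac * ac)))
    nb = float(np.sqrt(np.sum(bc * bc)))
    if na == 0.0 or nb == 0.0:
        return None
    return float(np.clip(np.dot(ac, bc) / (na * nb), -1.0, 1.0))


def n1_amplitude(trace: np.ndarray, sampling_rate_hz: float) -> float:
    """N1 trough amplitude in nV: |baseline − min over the 9–32 ms window|.

    The baseline is the mean of all samples strictly before 9 ms (a
    pre-trough convention, invariant to the trough itself).
    """
    trace = np.asarray(trace, dtype=float)
    t_ms = 1000.0 * np.arange(trace.size) / sampling_rate_hz
    lo, hi = N1_WINDOW_MS
    if t_ms[-1] < hi:
        raise ValueError(
            f"trace covers only {t_ms[-1]:.1f} ms; N1 window extends to {hi} ms"
        )
    window = trace[(t_ms >= lo) & (t_ms <= hi)]
    baseline = float(trace[t_ms < lo].mean())
    return abs(baseline - float(window.min()))


def template_cluster_traces(
    template: NormativeTemplate, layout: ClusterLayout
) -> dict[str, np.ndarray]:
    """Cluster-average the template (all members; templates have no NaS)."""
    traces: dict[int, np.ndarray | None] = dict(template.sector_templates)
    return {
        name: average_cluster(traces, layout, name).trace for name in CLUSTER_NAMES
    }


def feature_table(
    cohort: Cohort,
    filtered: dict[str, FilteredRecording],
    templates: dict[str, NormativeTemplate],
    layout: ClusterLayout,
) -> pd.DataFrame:
    """Per-subject, per-cluster analysis features.

    For every subject and each of the 10 clusters: ``A_N1`` (on the raw
    cluster average), ``PCC_RAW`` (raw cluster average vs template cluster
    average) and ``PCC_EMD`` (filtered cluster average vs template cluster
    average).  ``templates`` maps subject_id to the template that subject
    is evaluated against (leave-one-out for controls, full for patients).

    Returns a DataFrame with columns
    ``subject_id, group, cluster, feature, value, defined``.
    """
    rows = []
    tem_cluster_cache: dict[str, dict[str, np.ndarray]] = {}
    for rec in cohort:
        template = templates[rec.subject_id]
        if template.ref not in tem_cluster_cache:
            tem_cluster_cache[template.ref] = template_cluster_traces(template, layout)
        tem_clusters = tem_cluster_cache[template.ref]

        raw_traces: dict[int, np.ndarray | None] = dict(rec.sectors)
        emd_traces = filtered[rec.subject_id].sector_traces()

        for cluster in CLUSTER_NAMES:
            raw_sig = average_cluster(raw_traces, layout, cluster)
            emd_sig = average_cluster(emd_traces, layout, cluster)
            tem_trace = tem_clusters[cluster]

            a_n1 = (
                n1_amplitude(raw_sig.trace, rec.sampling_rate_hz)
                if raw_sig.defined
                else None
            )
            pcc_raw = (
                pearson_corr(raw_sig.trace, tem_trace) if raw_sig.defined else None
            )
            pcc_emd = (
                pearson_corr(emd_sig.trace, tem_trace) if emd_sig.defined else None
            )
            for feature, value in (
                ("A_N1", a_n1),
                ("PCC_RAW", pcc_raw),
                ("PCC_EMD", pcc_emd),
            ):
                rows.append(
                    {
                        "subject_id": rec.subject_id,
                        "group": rec.group,
                        "cluster": cluster,
                        "feature": feature,
                        "value": np.nan if value is None else value,
                        "defined": value is not None,
                    }
                )
    return pd.DataFrame(rows)
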