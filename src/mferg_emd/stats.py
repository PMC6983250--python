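"""Two-group comparison and discrimination summary per cluster x feature.

For each cluster and feature the control and patient value sets are
compared with a normality-gated two-sample test — Welch's t-test when both
groups pass Shapiro–Wilk at alpha = 0.05, otherwise the Mann–Whitney U
test (normal approximation with tie correction) — and discrimination is
quantified by the rank-based AUC (probability that a randomly drawn
patient/control pair is ordered in the expected direction, ties counting
one half).

The expected direction is fixed a priori per feature: correlation
features run higher in controls (``control_high``); the N1 amplitude runs
higher in patients (``patient_high``).  No multiple-testing correction is
applied; p-values are reported raw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA_NORMALITY = 0.05

FEATURE_DIRECTION = {
    "A_N1": "patient_high",
    "PCC_RAW": "control_high",
    "PCC_EMD": "control_high",
}


def shapiro_wilk_p(values) -> float:
    """Shapiro–Wilk normality p-value (Royston's approximation via scipy)."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError(f"Shapiro–Wilk needs at least 3 values, got {x.size}")
    if x.size > 5000:
        raise ValueError("Shapiro–Wilk p-value unreliable above n = 5000")
    if np.ptp(x) == 0.0:
        raise ValueError("constant sample: normality test undefined")
    return float(sps.shapiro(x).pvalue)


def mann_whitney_p(a, b) -> float:
    """Two-sided Mann–Whitney U p (normal approximation, tie-corrected)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.ptp(np.concatenate([a, b])) == 0.0:
        return 1.0  # all values tied: no evidence of a shift
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def compare_groups(control_values, patient_values) -> dict:
    """Normality-gated two-sample test; returns ``{test_used, p_value}``.

    Welch's t-test when both groups pass Shapiro–Wilk (p >= 0.05); the
    Mann–Whitney U test otherwise.  A constant group cannot pass the
    normality gate and falls through to Mann–Whitney.
    """
    c = np.asarray(control_values, dtype=float)
    p = np.asarray(patient_values, dtype=float)
    if c.size < 3 or p.size < 3:
        raise ValueError(
            f"need at least 3 values per group, got {c.size} and {p.size}"
        )

    def normal(x: np.ndarray) -> bool:
        try:
            return shapiro_wilk_p(x) >= ALPHA_NORMALITY
        except ValueError:
            return False

    if normal(c) and normal(p):
        if np.ptp(c) == 0.0 and np.ptp(p) == 0.0:
            pval = 1.0 if c.mean() == p.mean() else 0.0
        else:
            pval = float(sps.ttest_ind(c, p, equal_var=False).pvalue)
        return {"test_used": "t_test", "p_value": pval}
    return {"test_used": "mann_whitney", "p_value": mann_whitney_p(c, p)}


def auc(control_values, patient_values, direction: str) -> float:
    """Rank-based AUC: fraction of (patient, control) pairs ordered as expected.

    ``direction`` is ``"control_high"`` or ``"patient_high"``; ties count
    0.5.  Equivalent to the normalized Mann–Whitney U statistic.
    """
    if direction not in ("control_high", "patient_high"):
        raise ValueError(f"unknown direction {direction!r}")
    c = np.asarray(control_values, dtype=float)
    p = np.asarray(patient_values, dtype=float)
    if c.size == 0 or p.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([c, p])
    ranks = sps.rankdata(combined)
    # P(patient > control) + 0.5 P(tie), via the rank-sum identity
    r_p = ranks[c.size :].sum()
    auc_patient_high = (r_p - p.size * (p.size + 1) / 2.0) / (c.size * p.size)
    if direction == "patient_high":
        return float(auc_patient_high)
    return float(1.0 - auc_patient_high)


@dataclass
class ComparisonResult:
    cluster: str
    feature: str
    mean_control: float
    sd_control: float
    mean_patient: float
    sd_patient: float
    test_used: str
    p_value: float
    auc: float
    direction: str
    available: bool = True


def summarize(
    features: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """One comparison per cluster x feature, plus the mean AUC per feature.

    ``features`` is the long-form table from
    :func:`mferg_emd.clusters.feature_table`.  A cluster x feature cell
    with fewer than 3 defined values in either group is emitted with test
    and p flagged unavailable and is excluded from the mean AUC.

    Returns ``(summary_frame, {feature: mean_auc})``.
    """
    rows: list[ComparisonResult] = []
    defined = features[features["defined"]]
    clusters = list(dict.fromkeys(features["cluster"]))
    feature_names = list(dict.fromkeys(features["feature"]))
    for cluster in clusters:
        for feature in feature_names:
            cell = defined[
                (defined["cluster"] == cluster) & (defined["feature"] == feature)
            ]
            c = cell.loc[cell["group"] == "control", "value"].to_numpy()
            p = cell.loc[cell["group"] == "patient", "value"].to_numpy()
            direction = FEATURE_DIRECTION.get(feature, "patient_high")
            base = dict(
                cluster=cluster,
                feature=feature,
                mean_control=float(np.mean(c)) if c.size else np.nan,
                sd_control=float(np.std(c, ddof=1)) if c.size > 1 else np.nan,
                mean_patient=float(np.mean(p)) if p.size else np.nan,
                sd_patient=float(np.std(p, ddof=1)) if p.size > 1 else np.nan,
                direction=direction,
            )
            if c.size < 3 or p.size < 3:
                rows.append(
                    ComparisonResult(
                        **base,
                        test_used="unavailable",
                        p_value=np.nan,
                        auc=np.nan,
                        available=False,
                    )
                )
                continue
            test = compare_groups(c, p)
            rows.append(
                ComparisonResult(
                    **base,
                    test_used=test["test_used"],
                    p_value=test["p_value"],
                    auc=auc(c, p, direction),
                )
            )
    summary = pd.DataFrame([r.__dict__ for r in rows])
    mean_auc = {
        feature: float(
            summary.loc[
                (summary["feature"] == feature) & summary["available"], "auc"
            ].mean()
        )
        for feature in feature_names
    }
    return summary, mean_auc
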