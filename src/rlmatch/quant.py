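"""Normalization, detection flags and differential statistics.

The quantitative core of the pipeline: per-sample total-intensity
scaling of iBAQ values (relative iBAQ), quantifiability calls per
condition, and a per-protein volcano computation — iN/hiPSC ratio of
condition means against a two-sample test p-value across culture
batches.

Zeros are "not detected". A global intensity floor (half the smallest
positive normalized intensity by default) is applied inside logarithms
and to both the numerator and denominator of the ratio, so one-sided
detections produce large finite fold changes instead of infinities and
swapping the condition labels exactly negates every log2 ratio.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import Condition, DataError, QuantMatrix, NORMALIZATION_CONSTANT

logger = logging.getLogger("rlmatch")

__all__ = [
    "DetectionClass",
    "DifferentialRecord",
    "MarkerPanel",
    "normalize_ibaq",
    "detection_flags",
    "compute_floor",
    "differential",
    "volcano_table",
    "default_marker_panels",
    "marker_panel_summary",
    "student_t_pvalue",
    "welch_t_pvalue",
]


class DetectionClass(str, Enum):
    """Where a protein is quantifiable: both states, one, or neither."""

    both = "both"
    A_only = "A_only"
    B_only = "B_only"
    neither = "neither"


@dataclass(frozen=True)
class DifferentialRecord:
    """Per-protein differential summary between the two cell states.

    ``ratio_B_over_A`` is the floored ratio of condition means of
    normalized intensity (iN over hiPSC with the default display names);
    ``p_value`` comes from a two-sample test on log10 intensities across
    batches. ``n_detected`` counts batches with nonzero intensity per
    condition, in (A, B) order.
    """

    accession: str
    gene_symbol: str
    mean_norm_intensity_A: float
    mean_norm_intensity_B: float
    ratio_B_over_A: float
    log2_ratio: float
    p_value: float
    n_detected_A: int
    n_detected_B: int
    detection_class: DetectionClass

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise DataError(f"p_value out of [0,1]: {self.p_value}")
        if self.ratio_B_over_A <= 0:
            raise DataError("ratio_B_over_A must be positive")

    def quantifiable_in(self, condition: Condition) -> bool:
        if condition == Condition.A:
            return self.detection_class in (DetectionClass.both, DetectionClass.A_only)
        return self.detection_class in (DetectionClass.both, DetectionClass.B_only)


def normalize_ibaq(qm: QuantMatrix) -> QuantMatrix:
    """Scale each sample column to sum to 1 (relative iBAQ fractions).

    Zeros remain zeros. An all-zero sample column is a hard error naming
    the sample (nothing was quantified, the sample carries no signal).
    """
    if qm.normalized:
        raise DataError("matrix is already normalized")
    sums = qm.intensities.sum(axis=0)
    for s, total in zip(qm.samples, sums):
        if total <= 0:
            raise DataError(f"sample {s.sample_id!r} has an all-zero intensity column")
    values = qm.intensities / sums * NORMALIZATION_CONSTANT
    return QuantMatrix(
        accessions=list(qm.accessions),
        gene_symbols=list(qm.gene_symbols),
        intensities=values,
        samples=list(qm.samples),
        normalized=True,
    )


def detection_flags(qm: QuantMatrix, min_batches: int = 1) -> pd.DataFrame:
    """Per-protein detection class and per-condition detected-batch counts.

    A protein is quantifiable in a condition iff it is nonzero in at
    least ``min_batches`` batches of that condition.
    """
    n_batches = len(qm.batches)
    if not (1 <= min_batches <= n_batches):
        raise DataError(
            f"min_batches must be in [1, {n_batches}], got {min_batches}"
        )
    n_a = (qm.condition_values(Condition.A) > 0).sum(axis=1)
    n_b = (qm.condition_values(Condition.B) > 0).sum(axis=1)
    quant_a = n_a >= min_batches
    quant_b = n_b >= min_batches
    classes = np.where(
        quant_a & quant_b,
        DetectionClass.both.value,
        np.where(
            quant_a,
            DetectionClass.A_only.value,
            np.where(quant_b, DetectionClass.B_only.value, DetectionClass.neither.value),
        ),
    )
    return pd.DataFrame(
        {
            "accession": qm.accessions,
            "n_detected_A": n_a.astype(int),
            "n_detected_B": n_b.astype(int),
            "detection_class": classes,
        }
    )


def compute_floor(
    qm: QuantMatrix, floor_quantile: float = 0.0, floor_factor: float = 0.5
) -> float:
    """Global intensity floor for ratios and log transforms.

    ``floor_factor`` times the ``floor_quantile`` quantile of all
    positive normalized intensities; the default (quantile 0, factor
    0.5) is half the smallest positive value, guaranteeing the floor
    sits below every observed intensity.
    """
    if not (0.0 <= floor_quantile <= 1.0):
        raise DataError("floor_quantile must be in [0, 1]")
    if floor_factor <= 0:
        raise DataError("floor_factor must be positive")
    positive = qm.intensities[qm.intensities > 0]
    if positive.size == 0:
        raise DataError("matrix has no positive intensities")
    return floor_factor * float(np.quantile(positive, floor_quantile))


def _t_pvalue(a: Sequence[float], b: Sequence[float], equal_var: bool) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DataError("two-sample t-test needs >=2 values per group")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        return 1.0 if math.isclose(a.mean(), b.mean(), rel_tol=1e-12, abs_tol=0.0) else 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = stats.ttest_ind(a, b, equal_var=equal_var).pvalue
    if math.isnan(p):  # degenerate edge cases at tiny n
        return 1.0 if math.isclose(a.mean(), b.mean(), rel_tol=1e-12, abs_tol=0.0) else 0.0
    return float(min(max(p, 0.0), 1.0))


def student_t_pvalue(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided pooled-variance two-sample t-test (the default test).

    Exactly calibrated under the null with equal group variances even at
    n=3 per group. When both groups have zero variance the statistic is
    undefined; we return 1.0 if the group means coincide (no evidence of
    change) and 0.0 if they differ (change with no within-group noise).
    """
    return _t_pvalue(a, b, equal_var=True)


def welch_t_pvalue(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Welch (unequal-variance) t-test p-value.

    Robust to unequal group variances but conservative at very small n;
    the same degenerate-input conventions as :func:`student_t_pvalue`.
    """
    return _t_pvalue(a, b, equal_var=False)


def _mannwhitney_pvalue(a: Sequence[float], b: Sequence[float]) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    return float(min(max(p, 0.0), 1.0))


def differential(
    qm_normalized: QuantMatrix,
    floor_quantile: float = 0.0,
    floor_factor: float = 0.5,
    test: Literal["student", "welch", "mannwhitney"] = "student",
    min_batches: int = 1,
    adjust: Literal["none", "bh"] = "none",
) -> list[DifferentialRecord]:
    """Per-protein condition means, floored B/A ratio and p-value.

    The ratio is ``max(mean_B, floor) / max(mean_A, floor)`` with the
    floor from :func:`compute_floor`, so one-sided detections yield
    large finite ratios and label-swapping negates every log2 ratio.
    The p-value is a two-sample test on ``log10(intensity + floor)``
    across batches: Student's pooled t by default (exactly calibrated
    at the n=3 design; Welch is available for unequal-variance designs,
    and a rank test for larger ones — it degenerates at n=3 per group).
    Proteins undetected in both conditions are excluded. With fewer
    than 2 batches in a condition the p-value is the sentinel 1.0, with
    a warning; ratios are still computed.

    ``adjust="bh"`` replaces p-values by Benjamini-Hochberg adjusted
    values across the returned records (off by default: the volcano is
    conventionally drawn on raw p-values).
    """
    if not qm_normalized.normalized:
        raise DataError("differential() requires a normalized matrix")
    flags = detection_flags(qm_normalized, min_batches=min_batches)
    floor = compute_floor(qm_normalized, floor_quantile, floor_factor)

    vals_a = qm_normalized.condition_values(Condition.A)
    vals_b = qm_normalized.condition_values(Condition.B)
    few_batches = vals_a.shape[1] < 2 or vals_b.shape[1] < 2
    if few_batches:
        warnings.warn(
            "fewer than 2 batches in a condition: p-values set to sentinel 1.0",
            stacklevel=2,
        )

    test_fn = {
        "student": student_t_pvalue,
        "welch": welch_t_pvalue,
        "mannwhitney": _mannwhitney_pvalue,
    }[test]

    records: list[DifferentialRecord] = []
    for i, (acc, sym) in enumerate(zip(qm_normalized.accessions, qm_normalized.gene_symbols)):
        det = DetectionClass(flags.at[i, "detection_class"])
        if det == DetectionClass.neither:
            continue
        mean_a = float(vals_a[i].mean())
        mean_b = float(vals_b[i].mean())
        ratio = max(mean_b, floor) / max(mean_a, floor)
        if few_batches:
            p = 1.0
        else:
            p = test_fn(np.log10(vals_a[i] + floor), np.log10(vals_b[i] + floor))
        records.append(
            DifferentialRecord(
                accession=acc,
                gene_symbol=sym,
                mean_norm_intensity_A=mean_a,
                mean_norm_intensity_B=mean_b,
                ratio_B_over_A=ratio,
                log2_ratio=math.log2(ratio),
                p_value=p,
                n_detected_A=int(flags.at[i, "n_detected_A"]),
                n_detected_B=int(flags.at[i, "n_detected_B"]),
                detection_class=det,
            )
        )

    if adjust == "bh" and records:
        from statsmodels.stats.multitest import multipletests

        adjusted = multipletests([r.p_value for r in records], method="fdr_bh")[1]
        records = [
            DifferentialRecord(
                **{**r.__dict__, "p_value": float(min(q, 1.0))}
            )
            for r, q in zip(records, adjusted)
        ]
    return records


def differential_frame(records: Sequence[DifferentialRecord]) -> pd.DataFrame:
    """Flat table of differential records (stable column order)."""
    cols = [
        "accession",
        "gene_symbol",
        "mean_norm_intensity_A",
        "mean_norm_intensity_B",
        "ratio_B_over_A",
        "log2_ratio",
        "p_value",
        "n_detected_A",
        "n_detected_B",
        "detection_class",
    ]
    return pd.DataFrame(
        [
            {c: (getattr(r, c).value if c == "detection_class" else getattr(r, c)) for c in cols}
            for r in records
        ],
        columns=cols,
    )


def volcano_table(records: Sequence[DifferentialRecord]) -> pd.DataFrame:
    """Volcano-plot export: log2 ratio vs -log10 p, finite values only."""
    rows = []
    for r in records:
        if r.detection_class == DetectionClass.neither:
            continue
        mlp = -math.log10(r.p_value) if r.p_value > 0 else math.inf
        if not (math.isfinite(r.log2_ratio) and math.isfinite(mlp)):
            continue
        rows.append(
            {
                "accession": r.accession,
                "gene_symbol": r.gene_symbol,
                "log2_ratio": r.log2_ratio,
                "minus_log10_p": mlp,
            }
        )
    return pd.DataFrame(
        rows, columns=["accession", "gene_symbol", "log2_ratio", "minus_log10_p"]
    )


@dataclass(frozen=True)
class MarkerPanel:
    """A named panel of differentiation-QC marker genes."""

    panel_name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise DataError(f"marker panel {self.panel_name!r} has no members")


def default_marker_panels() -> list[MarkerPanel]:
    """Differentiation-QC panels: pluripotency, neuronal/synaptic, housekeeping."""
    return [
        MarkerPanel("pluripotency", ("OCT4", "SOX2", "LIN28A")),
        MarkerPanel("neuronal_synaptic", ("SYP", "SHANK2", "SNCA")),
        MarkerPanel("housekeeping", ("ATP5F1A", "TUBA1A")),
    ]


def marker_panel_summary(
    qm_normalized: QuantMatrix,
    panels: Sequence[MarkerPanel] | None = None,
    fold_threshold: float = 2.0,
    floor_quantile: float = 0.0,
    floor_factor: float = 0.5,
) -> tuple[pd.DataFrame, dict[str, str], dict[str, list[str]]]:
    """Mean +/- SEM of normalized intensity per marker and condition.

    Markers resolve to accessions case-insensitively by gene symbol;
    unresolvable members are reported under the returned ``unresolved``
    mapping, not fatal. Each panel also gets a qualitative call using
    the same floored-ratio machinery as :func:`differential`: the
    geometric-mean B/A ratio over resolved markers against
    ``fold_threshold`` -> ``enriched-in-B`` / ``enriched-in-A`` /
    ``balanced``.
    """
    if not qm_normalized.normalized:
        raise DataError("marker_panel_summary() requires a normalized matrix")
    if panels is None:
        panels = default_marker_panels()
    floor = compute_floor(qm_normalized, floor_quantile, floor_factor)
    by_symbol: dict[str, list[int]] = {}
    for i, sym in enumerate(qm_normalized.gene_symbols):
        by_symbol.setdefault(sym.upper(), []).append(i)

    vals = {
        Condition.A: qm_normalized.condition_values(Condition.A),
        Condition.B: qm_normalized.condition_values(Condition.B),
    }
    rows = []
    calls: dict[str, str] = {}
    unresolved: dict[str, list[str]] = {}
    for panel in panels:
        log_ratios: list[float] = []
        missing: list[str] = []
        for marker in panel.members:
            idxs = by_symbol.get(marker.upper())
            if not idxs:
                missing.append(marker)
                continue
            for i in idxs:
                means = {}
                for cond in (Condition.A, Condition.B):
                    x = vals[cond][i]
                    means[cond] = float(x.mean())
                    sem = float(x.std(ddof=1) / math.sqrt(x.size)) if x.size > 1 else 0.0
                    rows.append(
                        {
                            "panel": panel.panel_name,
                            "marker": marker,
                            "accession": qm_normalized.accessions[i],
                            "condition": cond.display_name,
                            "mean": means[cond],
                            "sem": sem,
                            "n": int(x.size),
                        }
                    )
                ratio = max(means[Condition.B], floor) / max(means[Condition.A], floor)
                log_ratios.append(math.log2(ratio))
        if missing:
            unresolved[panel.panel_name] = missing
        if not log_ratios:
            warnings.warn(
                f"marker panel {panel.panel_name!r} empty after symbol resolution",
                stacklevel=2,
            )
            calls[panel.panel_name] = "unresolved"
            continue
        gm_log2 = float(np.mean(log_ratios))
        if gm_log2 >= math.log2(fold_threshold):
            calls[panel.panel_name] = "enriched-in-B"
        elif gm_log2 <= -math.log2(fold_threshold):
            calls[panel.panel_name] = "enriched-in-A"
        else:
            calls[panel.panel_name] = "balanced"
    summary = pd.DataFrame(
        rows, columns=["panel", "marker", "accession", "condition", "mean", "sem", "n"]
    )
    return summary, calls, unresolved
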