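"""Array quality metrics: RLE, NUSE, simplified Affymetrix-style metrics,
and per-array report assembly.

RLE (relative log expression) and NUSE (normalized unscaled standard error)
are relative, multi-array metrics computed from a probe-level-model fit;
GNUSE (see the frozen-reference module) replaces NUSE's batch median-SE
denominator with a frozen reference vector and is the single-array,
absolute counterpart.  All quantiles and IQRs use linear interpolation
between order statistics.
"""

from __future__ import annotations

import numpy as np

from .core_data import (ArrayQuality, ExpressionSet, FrozenReference,
                        ProbeLevelData, QualityReport, ValidationError)
from .frozen_reference import gnuse_multi

DEFAULT_GNUSE_THRESHOLD = 1.25  # flags arrays ~25% less precise than typical
PERCENTILE_METHOD = "linear"


def rle(fit: ExpressionSet) -> np.ndarray:
    """Relative log expression: theta_hat minus its across-array median.

    A median RLE far from zero means more genes appear up- than
    down-regulated (or vice versa) on that array; a large IQR means most
    genes appear differentially expressed — both biologically implausible
    on a good array.
    """
    if len(fit.array_ids) < 2:
        raise ValidationError("RLE needs >= 2 arrays (relative metric)")
    med = np.median(fit.theta_hat, axis=1, keepdims=True)
    return fit.theta_hat - med


def nuse(fit: ExpressionSet) -> np.ndarray:
    """Normalized unscaled standard error: SE over its across-array median."""
    if len(fit.array_ids) < 2:
        raise ValidationError("NUSE needs >= 2 arrays (relative metric)")
    med = np.median(fit.se, axis=1, keepdims=True)
    if np.any(med <= 0):
        raise ValidationError("zero median SE")
    return fit.se / med


def summarize(metric: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-array (median, IQR) of a probeset x array metric matrix."""
    metric = np.asarray(metric, dtype=float)
    med = np.median(metric, axis=0)
    q75, q25 = np.percentile(metric, [75, 25], axis=0, method=PERCENTILE_METHOD)
    return med, q75 - q25


def _zone_of(xy: tuple[int, int], row_edges: np.ndarray, col_edges: np.ndarray) -> tuple[int, int]:
    r = min(int(np.searchsorted(row_edges, xy[0], side="right")) - 1, len(row_edges) - 2)
    c = min(int(np.searchsorted(col_edges, xy[1], side="right")) - 1, len(col_edges) - 2)
    return max(r, 0), max(c, 0)


def affy_metrics(data: ProbeLevelData, zones: int | None = None,
                 present_quantile: float = 50.0) -> dict[str, np.ndarray]:
    """Simplified single-array metrics in the MAS5 spirit.

    avg_background: mean over grid zones of the 2nd percentile of linear
    intensities (whole array when zones == 1).  scale_factor: the median
    feature intensity (the literal definition used here; MAS5's trimmed-mean
    scaling constant differs).  percent_present: percent of probesets whose
    median probe intensity is strictly greater than the array's
    ``present_quantile`` percentile — a documented simplified detection call
    (``simplified_quantile``) replacing the MM-probe Wilcoxon test.
    """
    if zones is None:
        zones = 4 if data.probe_xy is not None else 1
    if zones < 1:
        raise ValidationError("zones must be >= 1")
    if zones > 1 and data.probe_xy is None:
        raise ValidationError("zones > 1 requires probe coordinates")
    X = data.intensities if not data.log2_scale else 2.0 ** data.intensities

    if zones == 1:
        avg_background = np.percentile(X, 2, axis=0, method=PERCENTILE_METHOD)
    else:
        coords = np.array([data.probe_xy[p] for p in data.probe_ids])
        row_edges = np.linspace(coords[:, 0].min(), coords[:, 0].max() + 1, zones + 1)
        col_edges = np.linspace(coords[:, 1].min(), coords[:, 1].max() + 1, zones + 1)
        zone_ids = np.array([
            _zone_of(tuple(c), row_edges, col_edges)[0] * zones
            + _zone_of(tuple(c), row_edges, col_edges)[1]
            for c in coords
        ])
        percs = []
        for z in np.unique(zone_ids):
            percs.append(np.percentile(X[zone_ids == z], 2, axis=0,
                                       method=PERCENTILE_METHOD))
        avg_background = np.mean(percs, axis=0)

    scale_factor = np.median(X, axis=0)

    probeset_ids = data.probeset_ids
    pos = {g: i for i, g in enumerate(probeset_ids)}
    gidx = np.array([pos[data.probeset_of[p]] for p in data.probe_ids])
    thresh = np.percentile(X, present_quantile, axis=0, method=PERCENTILE_METHOD)
    present = np.zeros(len(data.array_ids))
    for g in range(len(probeset_ids)):
        med = np.median(X[gidx == g], axis=0)
        present += med > thresh   # strict: ties are not called present
    percent_present = 100.0 * present / len(probeset_ids)

    return {"avg_background": avg_background, "scale_factor": scale_factor,
            "percent_present": percent_present}


def build_report(fit: ExpressionSet | None, data: ProbeLevelData,
                 reference: FrozenReference | None = None,
                 threshold: float = DEFAULT_GNUSE_THRESHOLD,
                 zones: int | None = None,
                 present_quantile: float = 50.0) -> QualityReport:
    """Assemble a per-array quality report.

    RLE/NUSE summaries need a multi-array fit; GNUSE summaries need a frozen
    reference.  Arrays are flagged poor quality iff their median GNUSE
    strictly exceeds ``threshold``; without a reference the flag is left
    unset (absence of evidence is not acceptability).
    """
    array_ids = list(data.array_ids)
    am = affy_metrics(data, zones=zones, present_quantile=present_quantile)

    rle_med = rle_iqr = nuse_med = nuse_iqr = None
    if fit is not None and len(fit.array_ids) >= 2:
        rle_med, rle_iqr = summarize(rle(fit))
        nuse_med, nuse_iqr = summarize(nuse(fit))
    gnuse_med = gnuse_iqr = None
    if fit is not None and reference is not None:
        gnuse_med, gnuse_iqr = summarize(gnuse_multi(fit, reference))

    def pick(vec, j):
        return None if vec is None else float(vec[j])

    arrays = []
    for j, aid in enumerate(array_ids):
        arrays.append(ArrayQuality(
            array_id=aid,
            rle_median=pick(rle_med, j), rle_iqr=pick(rle_iqr, j),
            nuse_median=pick(nuse_med, j), nuse_iqr=pick(nuse_iqr, j),
            gnuse_median=pick(gnuse_med, j), gnuse_iqr=pick(gnuse_iqr, j),
            avg_background=float(am["avg_background"][j]),
            scale_factor=float(am["scale_factor"][j]),
            percent_present=float(am["percent_present"][j]),
        ))
    return QualityReport(arrays=arrays, threshold_used=threshold)
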