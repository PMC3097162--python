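"""Domain containers and plain-text readers/writers.

Probe-level intensities travel as TSV (probe x array, linear scale) with a
separate probe -> probeset annotation TSV; fitted expression sets as a pair
of TSV matrices plus JSON metadata; frozen references and quality reports as
JSON with an explicit schema version. Probe order in the annotation file is
canonical: every matrix is aligned to it so frozen parameters reproduce
bit-exactly across machines.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SCHEMA_VERSION = 1


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ProbeLevelData:
    """Probe x array intensity matrix with probe -> probeset annotation.

    ``intensities`` is linear-scale unless ``log2_scale`` is True (set by
    normalization).  Every probe maps to exactly one probeset and every
    probeset has at least two probes, so the additive probe-effect model is
    identifiable.
    """

    intensities: np.ndarray
    probe_ids: list[str]
    array_ids: list[str]
    probeset_of: dict[str, str]
    probe_xy: dict[str, tuple[int, int]] | None = None
    log2_scale: bool = False

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (len(self.probe_ids), len(self.array_ids)):
            raise ValidationError(
                f"intensity shape {self.intensities.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.array_ids)} arrays"
            )
        if len(set(self.probe_ids)) != len(self.probe_ids):
            dupes = sorted({p for p in self.probe_ids if self.probe_ids.count(p) > 1})
            raise ValidationError(f"duplicate probe ids: {dupes[:5]}")
        if len(set(self.array_ids)) != len(self.array_ids):
            raise ValidationError("duplicate array ids")
        missing = [p for p in self.probe_ids if p not in self.probeset_of]
        if missing:
            raise ValidationError(
                f"probes missing from annotation: {missing[:5]}"
                + ("..." if len(missing) > 5 else "")
            )
        if not self.log2_scale:
            bad = np.argwhere(~(self.intensities > 0))
            if bad.size:
                i, j = bad[0]
                raise ValidationError(
                    f"non-positive intensity for probe {self.probe_ids[i]!r} "
                    f"on array {self.array_ids[j]!r} (log2 undefined)"
                )
        counts: dict[str, int] = {}
        for p in self.probe_ids:
            counts[self.probeset_of[p]] = counts.get(self.probeset_of[p], 0) + 1
        small = sorted(g for g, c in counts.items() if c < 2)
        if small:
            raise ValidationError(f"probesets with < 2 probes: {small[:5]}")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_arrays(self) -> int:
        return len(self.array_ids)

    @property
    def probeset_ids(self) -> list[str]:
        """Probesets in order of first appearance along the probe axis."""
        seen: dict[str, None] = {}
        for p in self.probe_ids:
            seen.setdefault(self.probeset_of[p], None)
        return list(seen)

    def log2(self) -> np.ndarray:
        """Intensities on the log2 scale regardless of stored scale."""
        return self.intensities if self.log2_scale else np.log2(self.intensities)

    def subset_arrays(self, keep: Sequence[str]) -> "ProbeLevelData":
        idx = [self.array_ids.index(a) for a in keep]
        return ProbeLevelData(
            intensities=self.intensities[:, idx].copy(),
            probe_ids=list(self.probe_ids),
            array_ids=list(keep),
            probeset_of=dict(self.probeset_of),
            probe_xy=dict(self.probe_xy) if self.probe_xy else None,
            log2_scale=self.log2_scale,
        )


@dataclass
class ExpressionSet:
    """Probeset x array expression estimates and standard errors (log2)."""

    theta_hat: np.ndarray
    se: np.ndarray
    probeset_ids: list[str]
    array_ids: list[str]
    phi_hat: dict[str, float] | None = None
    residuals: np.ndarray | None = None
    weights: np.ndarray | None = None
    probe_ids: list[str] | None = None
    converged: np.ndarray | None = None  # per-probeset bool

    def __post_init__(self) -> None:
        self.theta_hat = np.asarray(self.theta_hat, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        shape = (len(self.probeset_ids), len(self.array_ids))
        if self.theta_hat.shape != shape or self.se.shape != shape:
            raise ValidationError("theta_hat/se shape mismatch with ids")
        if not np.all(self.se > 0):
            raise ValidationError("standard errors must be strictly positive")

    def subset_arrays(self, keep: Sequence[str]) -> "ExpressionSet":
        idx = [self.array_ids.index(a) for a in keep]
        return ExpressionSet(
            theta_hat=self.theta_hat[:, idx].copy(),
            se=self.se[:, idx].copy(),
            probeset_ids=list(self.probeset_ids),
            array_ids=list(keep),
            phi_hat=dict(self.phi_hat) if self.phi_hat else None,
        )


@dataclass
class FrozenReference:
    """Frozen parameters for single-array preprocessing and GNUSE scoring.

    ``median_se`` is the per-probeset median standard error across the
    reference batch (the GNUSE denominator); ``frozen_quantiles`` the mean
    sorted log2 intensity vector used to normalize new arrays; ``phi_hat``
    the frozen probe effects.
    """

    platform_tag: str
    probeset_ids: list[str]
    median_se: dict[str, float]
    frozen_quantiles: np.ndarray
    phi_hat: dict[str, float]
    probe_ids: list[str]
    probeset_of: dict[str, str]
    n_reference_arrays: int

    def __post_init__(self) -> None:
        self.frozen_quantiles = np.asarray(self.frozen_quantiles, dtype=float)
        if any(v <= 0 for v in self.median_se.values()):
            raise ValidationError("median_se must be strictly positive")
        if np.any(np.diff(self.frozen_quantiles) < 0):
            raise ValidationError("frozen_quantiles must be nondecreasing")
        if len(self.frozen_quantiles) != len(self.probe_ids):
            raise ValidationError("frozen_quantiles length != number of probes")
        if set(self.probeset_of.values()) != set(self.probeset_ids):
            raise ValidationError("probeset_of inconsistent with probeset_ids")
        if set(self.probeset_of) != set(self.phi_hat):
            raise ValidationError("phi_hat probes inconsistent with annotation")


@dataclass
class ArrayQuality:
    """Per-array metric summaries; None marks a metric that was not computed."""

    array_id: str
    rle_median: float | None = None
    rle_iqr: float | None = None
    nuse_median: float | None = None
    nuse_iqr: float | None = None
    gnuse_median: float | None = None
    gnuse_iqr: float | None = None
    avg_background: float | None = None
    scale_factor: float | None = None
    percent_present: float | None = None
    poor_quality_flag: bool | None = None


@dataclass
class QualityReport:
    """Collection of per-array quality summaries plus the flag threshold.

    ``poor_quality_flag`` is True iff gnuse_median > threshold_used (strict);
    it stays None when GNUSE was not computed — absence of evidence is not
    acceptability.
    """

    arrays: list[ArrayQuality]
    threshold_used: float
    detection_method: str = "simplified_quantile"

    def __post_init__(self) -> None:
        for a in self.arrays:
            for name in ("rle_iqr", "nuse_iqr", "gnuse_iqr"):
                v = getattr(a, name)
                if v is not None and v < 0:
                    raise ValidationError(f"{name} < 0 for array {a.array_id}")
            if a.percent_present is not None and not 0 <= a.percent_present <= 100:
                raise ValidationError(f"percent_present outside [0,100] for {a.array_id}")
            if a.gnuse_median is not None:
                expected = a.gnuse_median > self.threshold_used
                if a.poor_quality_flag is None:
                    a.poor_quality_flag = expected
                elif a.poor_quality_flag != expected:
                    raise ValidationError(
                        f"flag inconsistent with threshold for {a.array_id}"
                    )
            elif a.poor_quality_flag is not None:
                raise ValidationError(
                    f"flag set without gnuse_median for {a.array_id}"
                )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path) -> tuple[list[str], dict[str, str], dict[str, tuple[int, int]] | None]:
    """Read probe annotation TSV: probe_id, probeset_id[, row, col]."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    probe_ids = df.iloc[:, 0].tolist()
    probeset_of = dict(zip(probe_ids, df.iloc[:, 1]))
    probe_xy = None
    if df.shape[1] >= 4:
        probe_xy = {
            p: (int(r), int(c))
            for p, r, c in zip(probe_ids, df.iloc[:, 2], df.iloc[:, 3])
        }
    return probe_ids, probeset_of, probe_xy


def read_probe_table(path: str | Path, annotation_path: str | Path) -> ProbeLevelData:
    """Read a linear-scale probe intensity TSV plus its annotation.

    The annotation's probe order is canonical; intensity rows are realigned
    to it.  Probes present in the table but absent from the annotation are an
    error, as are non-positive intensities, duplicate probes and probesets
    with fewer than two probes.
    """
    probe_ids, probeset_of, probe_xy = read_annotation(annotation_path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str},
                     float_precision="round_trip")
    table_probes = [str(p) for p in df.index]
    if len(set(table_probes)) != len(table_probes):
        dupes = sorted({p for p in table_probes if table_probes.count(p) > 1})
        raise ValidationError(f"duplicate probe ids in table: {dupes[:5]}")
    unknown = [p for p in table_probes if p not in probeset_of]
    if unknown:
        raise ValidationError(f"probes not in annotation: {unknown[:5]}")
    missing = [p for p in probe_ids if p not in set(table_probes)]
    if missing:
        raise ValidationError(f"annotated probes missing from table: {missing[:5]}")
    df = df.loc[probe_ids]
    return ProbeLevelData(
        intensities=df.to_numpy(dtype=float),
        probe_ids=probe_ids,
        array_ids=[str(a) for a in df.columns],
        probeset_of=probeset_of,
        probe_xy=probe_xy,
    )


def write_probe_table(data: ProbeLevelData, path: str | Path,
                      annotation_path: str | Path | None = None) -> None:
    """Write intensities as TSV (`probe_id<TAB>array...`), full precision."""
    df = pd.DataFrame(data.intensities, index=data.probe_ids, columns=data.array_ids)
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", float_format="%.17g")
    if annotation_path is not None:
        write_annotation(data, annotation_path)


def write_annotation(data: ProbeLevelData, path: str | Path) -> None:
    cols = {"probe_id": data.probe_ids,
            "probeset_id": [data.probeset_of[p] for p in data.probe_ids]}
    if data.probe_xy is not None:
        cols["row"] = [data.probe_xy[p][0] for p in data.probe_ids]
        cols["col"] = [data.probe_xy[p][1] for p in data.probe_ids]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def write_expression_set(fit: ExpressionSet, prefix: str | Path) -> None:
    """Write theta/se TSV matrices plus JSON metadata under ``prefix``."""
    prefix = Path(prefix)
    for name, mat in (("theta", fit.theta_hat), ("se", fit.se)):
        df = pd.DataFrame(mat, index=fit.probeset_ids, columns=fit.array_ids)
        df.index.name = "probeset_id"
        df.to_csv(f"{prefix}.{name}.tsv", sep="\t", float_format="%.17g")
    if fit.residuals is not None and fit.probe_ids is not None:
        df = pd.DataFrame(fit.residuals, index=fit.probe_ids, columns=fit.array_ids)
        df.index.name = "probe_id"
        df.to_csv(f"{prefix}.residuals.tsv", sep="\t", float_format="%.17g")
    meta = {
        "schema_version": SCHEMA_VERSION,
        "phi_hat": fit.phi_hat,
        "converged": None if fit.converged is None else [bool(c) for c in fit.converged],
    }
    Path(f"{prefix}.meta.json").write_text(json.dumps(meta, indent=1))


def write_reference(ref: FrozenReference, path: str | Path) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "platform_tag": ref.platform_tag,
        "probeset_ids": ref.probeset_ids,
        "median_se": ref.median_se,
        "frozen_quantiles": ref.frozen_quantiles.tolist(),
        "phi_hat": ref.phi_hat,
        "probe_ids": ref.probe_ids,
        "probeset_of": ref.probeset_of,
        "n_reference_arrays": ref.n_reference_arrays,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_reference(path: str | Path) -> FrozenReference:
    doc = json.loads(Path(path).read_text())
    return FrozenReference(
        platform_tag=doc["platform_tag"],
        probeset_ids=doc["probeset_ids"],
        median_se=doc["median_se"],
        frozen_quantiles=np.asarray(doc["frozen_quantiles"], dtype=float),
        phi_hat=doc["phi_hat"],
        probe_ids=doc["probe_ids"],
        probeset_of=doc["probeset_of"],
        n_reference_arrays=doc["n_reference_arrays"],
    )


_REPORT_FIELDS = ("rle_median", "rle_iqr", "nuse_median", "nuse_iqr",
                  "gnuse_median", "gnuse_iqr", "avg_background",
                  "scale_factor", "percent_present", "poor_quality_flag")


def write_report(report: QualityReport, path: str | Path) -> None:
    """Write a quality report as JSON, one record per array."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "threshold_used": report.threshold_used,
        "detection_method": report.detection_method,
        "arrays": [
            {"array_id": a.array_id, **{f: getattr(a, f) for f in _REPORT_FIELDS}}
            for a in report.arrays
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_report(path: str | Path) -> QualityReport:
    doc = json.loads(Path(path).read_text())
    arrays = [
        ArrayQuality(array_id=rec["array_id"],
                     **{f: rec.get(f) for f in _REPORT_FIELDS})
        for rec in doc["arrays"]
    ]
    return QualityReport(arrays=arrays, threshold_used=doc["threshold_used"],
                         detection_method=doc.get("detection_method",
                                                  "simplified_quantile"))
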