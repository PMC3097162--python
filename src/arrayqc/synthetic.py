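"""Synthetic probe-level data under the log-additive intensity model.

Log2 intensity of probe p (in probeset g) on array a is

    Y_pa = K_a + theta_ga + phi_p + eps_pa,      eps_pa ~ N(0, sd_a)

with K_a an array effect (the reason normalization exists), theta_ga the
log2 expression of the transcript, phi_p a probe affinity effect summing to
zero within each probeset, and Gaussian measurement error whose standard
deviation is inflated for injected poor-quality arrays.  Linear-scale
intensities are 2**Y.  Optional defects: a heavy-tailed contamination
mixture (a fraction of probe values with sd x10) and a contiguous spatial
blob offset on a probe grid, emulating the regional artifacts seen in
residual images of real degraded arrays.

All randomness flows from a single integer seed; each operation derives its
own substream deterministically from (seed, operation name), so the same
config is bit-reproducible regardless of call order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_data import ProbeLevelData, ValidationError

# variance components reported for the public-survey quality analysis:
# lab variance 0.0162, sample-type variance 0.0035 (lab > 4x sample type)
PUBLIC_SURVEY_LAB_VAR = 0.0162
PUBLIC_SURVEY_SAMPLE_TYPE_VAR = 0.0035


def _rng(seed: int, operation: str) -> np.random.Generator:
    """Deterministic substream for (seed, operation)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(operation.encode())])
    )


@dataclass
class SimConfig:
    """Generator parameters; defaults are the package's standard study
    conditions (see docs/methods.md for the reasoning behind each value)."""

    n_probesets: int = 200
    probes_per_set: int = 4
    n_arrays: int = 8
    baseline_sd: float = 0.5        # log2 measurement noise sd of a good array
    bad_arrays: tuple[int, ...] = ()  # array indices with inflated noise
    bad_multiplier: float = 3.0
    n_de: int = 0                   # differentially expressed probesets
    de_effect: float = 0.0          # log2 fold change added in group B
    n_tissues: int = 1              # contiguous blocks of replicate arrays
    tissue_effect_sd: float = 1.0   # per-probeset log2 spread across tissues
    seed: int = 0
    platform_seed: int = 0          # fixes probe effects & baselines (the "chip design")
    array_effect_sd: float = 0.2    # sd of K_a
    phi_sd: float = 1.0             # sd of probe effects before centering
    expr_range: tuple[float, float] = (4.0, 12.0)  # baseline log2 expression
    outlier_fraction: float = 0.0   # heavy-tail contamination mixture
    outlier_multiplier: float = 10.0
    with_grid: bool = False         # assign probes to a square grid
    blob_arrays: tuple[int, ...] = ()
    blob_offset: float = 0.0        # log2 offset added inside the blob
    blob_fraction: float = 0.15     # fraction of grid side covered by blob


@dataclass
class SyntheticTruth:
    """Ground truth behind one simulated data set."""

    theta: np.ndarray               # probeset x array, log2
    phi: dict[str, float]           # sums to zero within each probeset
    K: np.ndarray                   # per-array effect
    noise_sd: np.ndarray            # per-array residual sd
    bad_arrays: set[str]
    de_probesets: dict[str, float]  # probeset -> group effect size
    group_of: dict[str, str] = field(default_factory=dict)
    tissue_of: dict[str, str] = field(default_factory=dict)
    lab_of: dict[str, str] = field(default_factory=dict)
    sample_type_of: dict[str, str] = field(default_factory=dict)
    lab_sd: float = 0.0
    sample_type_sd: float = 0.0
    probeset_ids: list[str] = field(default_factory=list)
    array_ids: list[str] = field(default_factory=list)


def _validate(config: SimConfig) -> None:
    if config.n_probesets < 1 or config.probes_per_set < 2 or config.n_arrays < 1:
        raise ValidationError("counts below minimal valid sizes")
    if config.bad_multiplier <= 1:
        raise ValidationError("bad_multiplier must be > 1")
    if any(a < 0 or a >= config.n_arrays for a in config.bad_arrays):
        raise ValidationError("bad array index out of range")
    if config.n_de > config.n_probesets:
        raise ValidationError("n_de exceeds number of probesets")
    if config.baseline_sd < 0:
        raise ValidationError("baseline_sd must be >= 0")


def simulate(config: SimConfig) -> tuple[ProbeLevelData, SyntheticTruth]:
    """Draw one probe-level data set (linear scale) plus its ground truth.

    When ``n_de > 0`` arrays are split into two equal-as-possible groups
    ("A" first half, "B" second half) and ``de_effect`` is added to theta of
    the DE probesets in group B.

    Probe effects and baseline expression levels are drawn from
    ``platform_seed`` (they model fixed physical properties of the chip
    design and the transcriptome), so data sets sharing a platform_seed are
    mutually comparable — in particular, arrays can be scored against a
    frozen reference built from a different simulation of the same
    platform.  Everything else (noise, array effects, DE probeset choice,
    defects) is drawn from ``seed``.
    """
    _validate(config)
    rng = _rng(config.seed, "simulate")
    platform_rng = _rng(config.platform_seed, "platform")
    G, P, A = config.n_probesets, config.probes_per_set, config.n_arrays
    probeset_ids = [f"ps{g:05d}" for g in range(G)]
    probe_ids = [f"ps{g:05d}_p{p}" for g in range(G) for p in range(P)]
    array_ids = [f"arr{a:03d}" for a in range(A)]
    probeset_of = {f"ps{g:05d}_p{p}": f"ps{g:05d}" for g in range(G) for p in range(P)}

    baseline = platform_rng.uniform(*config.expr_range, size=G)
    theta = np.tile(baseline[:, None], (1, A))

    tissue_of: dict[str, str] = {}
    if config.n_tissues > 1:
        if A % config.n_tissues != 0:
            raise ValidationError("n_arrays must be a multiple of n_tissues")
        per = A // config.n_tissues
        tissue_theta = rng.normal(0.0, config.tissue_effect_sd,
                                  size=(G, config.n_tissues))
        for a, aid in enumerate(array_ids):
            t = a // per
            tissue_of[aid] = f"tissue{t:02d}"
            theta[:, a] += tissue_theta[:, t]

    group_of: dict[str, str] = {}
    de_probesets: dict[str, float] = {}
    if config.n_de > 0:
        half = A // 2
        for a, aid in enumerate(array_ids):
            group_of[aid] = "A" if a < half else "B"
        de_idx = rng.choice(G, size=config.n_de, replace=False)
        for g in np.sort(de_idx):
            de_probesets[probeset_ids[g]] = config.de_effect
            theta[g, half:] += config.de_effect

    phi = platform_rng.normal(0.0, config.phi_sd, size=(G, P))
    phi -= phi.mean(axis=1, keepdims=True)
    K = rng.normal(0.0, config.array_effect_sd, size=A) if config.array_effect_sd > 0 \
        else np.zeros(A)

    noise_sd = np.full(A, config.baseline_sd)
    for a in config.bad_arrays:
        noise_sd[a] *= config.bad_multiplier

    eps_sd = np.broadcast_to(noise_sd, (G * P, A)).copy()
    if config.outlier_fraction > 0:
        mask = rng.random((G * P, A)) < config.outlier_fraction
        eps_sd[mask] *= config.outlier_multiplier
    eps = rng.normal(0.0, 1.0, size=(G * P, A)) * eps_sd

    gidx = np.repeat(np.arange(G), P)
    log2_y = K[None, :] + theta[gidx, :] + phi.reshape(-1)[:, None] + eps

    probe_xy = None
    if config.with_grid:
        side = int(np.ceil(np.sqrt(G * P)))
        probe_xy = {pid: (i // side, i % side) for i, pid in enumerate(probe_ids)}
        if config.blob_arrays and config.blob_offset != 0.0:
            blob_side = max(1, int(round(config.blob_fraction * side)))
            r0 = rng.integers(0, max(1, side - blob_side + 1))
            c0 = rng.integers(0, max(1, side - blob_side + 1))
            in_blob = np.array([
                r0 <= probe_xy[pid][0] < r0 + blob_side
                and c0 <= probe_xy[pid][1] < c0 + blob_side
                for pid in probe_ids
            ])
            for a in config.blob_arrays:
                log2_y[in_blob, a] += config.blob_offset

    data = ProbeLevelData(
        intensities=2.0 ** log2_y,
        probe_ids=probe_ids,
        array_ids=array_ids,
        probeset_of=probeset_of,
        probe_xy=probe_xy,
    )
    truth = SyntheticTruth(
        theta=theta,
        phi={pid: float(phi.reshape(-1)[i]) for i, pid in enumerate(probe_ids)},
        K=K,
        noise_sd=noise_sd,
        bad_arrays={array_ids[a] for a in config.bad_arrays},
        de_probesets=de_probesets,
        group_of=group_of,
        tissue_of=tissue_of,
        probeset_ids=probeset_ids,
        array_ids=array_ids,
    )
    return data, truth


def simulate_spikein(config: SimConfig, n_spike: int = 16,
                     spike_log_fc: float = 0.5) -> tuple[ProbeLevelData, SyntheticTruth]:
    """Two equal groups differing only in ``n_spike`` spiked probesets.

    Mirrors the classic spike-in experiment design: two groups of replicate
    hybridizations identical except for a known set of transcripts at a
    known log2 fold change, so true and false positives are computable.
    """
    if config.n_arrays % 2 != 0:
        raise ValidationError("spike-in design needs even group sizes")
    if n_spike >= config.n_probesets:
        raise ValidationError("n_spike must be smaller than n_probesets")
    cfg = replace(config, n_de=n_spike, de_effect=spike_log_fc)
    return simulate(cfg)


def simulate_quality_sources(n_labs: int = 120, n_sample_types: int = 10,
                             arrays_per_cell: int = 4, mu: float = 1.0,
                             lab_sd: float = PUBLIC_SURVEY_LAB_VAR ** 0.5,
                             sample_type_sd: float = PUBLIC_SURVEY_SAMPLE_TYPE_VAR ** 0.5,
                             resid_sd: float = 0.1,
                             seed: int = 0) -> pd.DataFrame:
    """Per-array quality responses under a crossed two-factor random model.

    response_i = mu + S_j + L_k + eps_i with S_j ~ N(0, sample_type_sd^2)
    drawn once per sample type, L_k ~ N(0, lab_sd^2) once per lab, and
    independent residual noise per array.  Defaults reproduce the
    public-survey variance preset (lab variance 0.0162 vs sample-type
    variance 0.0035) with a balanced 120-lab x 10-type x 4-replicate design.
    """
    if arrays_per_cell < 1:
        raise ValidationError("arrays_per_cell must be >= 1")
    if min(lab_sd, sample_type_sd, resid_sd) < 0:
        raise ValidationError("standard deviations must be >= 0")
    rng = _rng(seed, "simulate_quality_sources")
    S = rng.normal(0.0, sample_type_sd, size=n_sample_types)
    L = rng.normal(0.0, lab_sd, size=n_labs)
    rows = []
    i = 0
    for k in range(n_labs):
        for j in range(n_sample_types):
            eps = rng.normal(0.0, resid_sd, size=arrays_per_cell)
            for r in range(arrays_per_cell):
                rows.append((f"arr{i:05d}", f"lab{k:03d}", f"type{j:02d}",
                             mu + S[j] + L[k] + eps[r]))
                i += 1
    return pd.DataFrame(rows, columns=["array_id", "lab", "sample_type", "response"])
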