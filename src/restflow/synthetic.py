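"""Synthetic six-condition beadarray datasets with known ground truth.

The generator emulates a single-replicate expression experiment contrasting
no flow (NF), rest-inserted flow (RF) and continuous flow (CF) at two time
points.  Each detected gene owns a true common score x'* and differential
score y'* in the rotated frame; the inverse 45-degree rotation yields true
time-averaged ratios (x, y), independent Gaussian noise is added per time
point, and linear-scale intensities are emitted as

    NF_t = 2^b,  CF_t = 2^(b + x_t),  RF_t = 2^(b + y_t)

with b the probe's baseline log2 intensity.  Ground truth (true scores and
planted-set membership) travels with the dataset so that parameter-recovery
tests can close the loop through the analysis pipeline.

True x'* scores are drawn from a truncated standard normal and true y'*
scores from a truncated Laplace (heavier mass near zero, mimicking the
observation that differential changes are dominated by many small
perturbations); both are affinely rescaled so their sample spans equal the
configured extents exactly.  The distributions are configurable.
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .preprocess import UNNAMED_PREFIX
from .transform import CONDITIONS, rotate_inverse
from .enrichment import GeneSetCollection

__all__ = ["PlantedSet", "SimConfig", "RawDataset", "generate_dataset", "planted_collection"]

_TRUNC_NORMAL_BOUND = 3.0  # standard deviations
_TRUNC_LAPLACE_BOUND = 4.0  # Laplace scale units


@dataclasses.dataclass(frozen=True)
class PlantedSet:
    """A gene set to plant in one tail of the differential (y') axis."""

    name: str
    n_genes: int
    tail: str  # "up" or "down"
    effect_size: float  # log2-ratio shift applied to true y'

    def __post_init__(self) -> None:
        if self.tail not in ("up", "down"):
            raise ValueError(f"tail must be 'up' or 'down', got {self.tail!r}")
        if self.n_genes < 1:
            raise ValueError("planted set needs at least one gene")
        if not math.isfinite(self.effect_size) or self.effect_size < 0:
            raise ValueError("effect_size must be finite and non-negative")


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Generator parameters.

    Defaults describe the emulated study conditions: ~45k probes of which
    ~34.6% pass detection, ~23.7% of probes without usable symbols, rotated
    signal spans of 0.52 (common) and 0.29 (differential) log2-ratio units,
    and small independent per-time-point ratio noise.
    """

    n_probes: int = 45281
    frac_detected: float = 0.346
    frac_unannotated: float = 0.237
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    low_intensity_frac: float = 0.05  # share of undetected probes near the floor
    common_extent: float = 0.52
    differential_extent: float = 0.29
    noise_var_per_timepoint: float = 1e-3
    common_dist: str = "truncnorm"
    differential_dist: str = "trunclaplace"
    planted_sets: tuple[PlantedSet, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")
        for name in ("frac_detected", "frac_unannotated", "low_intensity_frac"):
            value = getattr(self, name)
            if not math.isfinite(value) or not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
        for name in ("common_extent", "differential_extent", "noise_var_per_timepoint"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {value!r}")
        for name in ("baseline_log2_mean", "baseline_log2_sd"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.baseline_log2_sd < 0:
            raise ValueError("baseline_log2_sd must be >= 0")
        names = [p.name for p in self.planted_sets]
        if len(names) != len(set(names)):
            raise ValueError("planted set names must be unique")


@dataclasses.dataclass
class RawDataset:
    """Raw simulated (or loaded) six-condition dataset.

    ``intensities`` and ``detection_p`` are probe x 6 frames with the fixed
    condition order NF0, NF1, RF0, RF1, CF0, CF1; ``annotations`` maps probe
    id to gene symbol (unannotated probes carry the reserved prefix);
    ``truth`` (simulated data only) holds per-probe true scores and planted
    set membership.
    """

    intensities: pd.DataFrame
    detection_p: pd.DataFrame
    annotations: pd.Series
    truth: pd.DataFrame | None = None


def _bounded_scores(rng: np.random.Generator, n: int, extent: float, kind: str) -> np.ndarray:
    """Draw n symmetric zero-mean bounded scores with sample span == extent."""
    if n == 0:
        return np.empty(0)
    if extent == 0.0 or n == 1:
        return np.zeros(n)
    if kind == "truncnorm":
        raw = rng.normal(size=n)
        bound = _TRUNC_NORMAL_BOUND
        redraw = np.abs(raw) > bound
        while redraw.any():
            raw[redraw] = rng.normal(size=int(redraw.sum()))
            redraw = np.abs(raw) > bound
    elif kind == "trunclaplace":
        raw = rng.laplace(size=n)
        bound = _TRUNC_LAPLACE_BOUND
        redraw = np.abs(raw) > bound
        while redraw.any():
            raw[redraw] = rng.laplace(size=int(redraw.sum()))
            redraw = np.abs(raw) > bound
    else:
        raise ValueError(f"unknown score distribution {kind!r}")
    span = raw.max() - raw.min()
    if span == 0.0:
        return np.zeros(n)
    return -extent / 2.0 + (raw - raw.min()) * (extent / span)


def generate_dataset(config: SimConfig) -> RawDataset:
    """Generate a seeded six-condition raw dataset with ground truth.

    Identical seeds give bit-identical output.  Undetected probes receive
    detection p-values >= 0.01 in every sample and low baselines (a
    configurable stratum sits below the flooring threshold); detected
    probes receive a sub-0.01 p-value in one random sample.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_probes
    probe_ids = pd.Index([f"PRB_{i:07d}" for i in range(1, n + 1)], name="probe_id")

    detected = rng.random(n) < config.frac_detected
    unannotated = rng.random(n) < config.frac_unannotated
    symbols = np.array(
        [
            f"{UNNAMED_PREFIX}{i:06d}" if unannotated[i] else f"GENE{i:06d}"
            for i in range(n)
        ],
        dtype=object,
    )
    annotations = pd.Series(symbols, index=probe_ids, name="symbol")

    # Baselines: detected probes sit well above the floor; undetected probes
    # are dimmer, with a stratum near/below the floor to exercise flooring.
    baselines = np.empty(n)
    baselines[detected] = rng.normal(
        config.baseline_log2_mean, config.baseline_log2_sd, int(detected.sum())
    )
    n_undet = int((~detected).sum())
    dim = rng.normal(
        config.baseline_log2_mean - 4.0, config.baseline_log2_sd, n_undet
    )
    low = rng.random(n_undet) < config.low_intensity_frac
    dim[low] = rng.normal(1.0, 0.5, int(low.sum()))
    baselines[~detected] = dim

    # True rotated scores for detected genes.
    nd = int(detected.sum())
    x_prime_true = _bounded_scores(rng, nd, config.common_extent, config.common_dist)
    y_prime_true = _bounded_scores(
        rng, nd, config.differential_extent, config.differential_dist
    )

    # Plant gene sets in the requested differential tails (detected and
    # annotated genes only, disjoint across sets).
    planted_label = np.full(nd, "", dtype=object)
    detected_idx = np.flatnonzero(detected)
    eligible = np.flatnonzero(~unannotated[detected_idx])  # positions within detected
    total_planted = sum(p.n_genes for p in config.planted_sets)
    if total_planted > len(eligible):
        raise ValueError(
            f"planted sets need {total_planted} genes but only "
            f"{len(eligible)} detected annotated genes exist"
        )
    if total_planted:
        chosen = rng.choice(eligible, size=total_planted, replace=False)
        offset = 0
        for planted in config.planted_sets:
            members = chosen[offset : offset + planted.n_genes]
            offset += planted.n_genes
            sign = 1.0 if planted.tail == "up" else -1.0
            y_prime_true[members] += sign * planted.effect_size
            planted_label[members] = planted.name

    x_true, y_true = rotate_inverse(x_prime_true, y_prime_true)

    # Independent per-time-point noise on the four log ratios.
    noise_sd = math.sqrt(config.noise_var_per_timepoint)
    eps = rng.normal(0.0, noise_sd, (nd, 4)) if noise_sd > 0 else np.zeros((nd, 4))
    x0 = x_true + eps[:, 0]
    x1 = x_true + eps[:, 1]
    y0 = y_true + eps[:, 2]
    y1 = y_true + eps[:, 3]

    log2_int = np.tile(baselines[:, None], (1, 6))
    log2_int[detected_idx, 2] += y0
    log2_int[detected_idx, 3] += y1
    log2_int[detected_idx, 4] += x0
    log2_int[detected_idx, 5] += x1
    if n_undet and noise_sd > 0:
        log2_int[~detected] += rng.normal(0.0, noise_sd, (n_undet, 6))
    intensities = pd.DataFrame(
        np.exp2(log2_int), index=probe_ids, columns=list(CONDITIONS)
    )

    detection_p = pd.DataFrame(
        rng.uniform(0.01, 1.0, (n, 6)), index=probe_ids, columns=list(CONDITIONS)
    )
    hit_col = rng.integers(0, 6, nd)
    detection_p.values[detected_idx, hit_col] = rng.uniform(0.0, 0.01, nd)

    truth = pd.DataFrame(
        {
            "symbol": symbols,
            "detected": detected,
            "x_true": np.nan,
            "y_true": np.nan,
            "x_prime_true": np.nan,
            "y_prime_true": np.nan,
            "planted_set": "",
        },
        index=probe_ids,
    )
    truth.loc[truth.index[detected_idx], "x_true"] = x_true
    truth.loc[truth.index[detected_idx], "y_true"] = y_true
    truth.loc[truth.index[detected_idx], "x_prime_true"] = x_prime_true
    truth.loc[truth.index[detected_idx], "y_prime_true"] = y_prime_true
    truth.loc[truth.index[detected_idx], "planted_set"] = planted_label

    return RawDataset(
        intensities=intensities,
        detection_p=detection_p,
        annotations=annotations,
        truth=truth,
    )


def planted_collection(
    dataset: RawDataset,
    *,
    n_decoy_sets: int = 30,
    decoy_size_range: tuple[int, int] = (20, 100),
    seed: int = 0,
) -> GeneSetCollection:
    """Gene-set collection of the dataset's planted sets plus random decoys.

    Decoy sets are drawn uniformly from detected annotated genes, giving the
    enrichment sweep a realistic null background.  The universe is the set
    of detected annotated symbols.
    """
    if dataset.truth is None:
        raise ValueError("dataset has no ground truth; cannot build planted collection")
    rng = np.random.default_rng(seed)
    truth = dataset.truth
    analyzed = truth.loc[
        truth["detected"] & ~truth["symbol"].str.startswith(UNNAMED_PREFIX)
    ]
    universe = analyzed["symbol"].tolist()
    sets: list[tuple[str, list[str]]] = []
    for name, block in analyzed.groupby("planted_set"):
        if name:
            sets.append((str(name), block["symbol"].tolist()))
    lo, hi = decoy_size_range
    for i in range(n_decoy_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=min(size, len(universe)), replace=False)
        sets.append((f"DECOY_{i:03d}", list(members)))
    return GeneSetCollection.from_sets(sets, universe)
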