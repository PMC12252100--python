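"""Beat-level ECG preprocessing: AAMI-5 label mapping, R-peak-centred
segmentation, wavelet denoising, min-max normalization and dataset splitting.

Conventions used throughout: 0-based sample indices and half-open windows.
A beat window spans [r - half_width, r + half_width), giving 2*half_width
samples with the R sample at index half_width; windows crossing either
record edge are dropped (and counted, never silently).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pywt

from .dataset import CLASSES, BeatDataset

logger = logging.getLogger(__name__)


class DegenerateSegmentError(ValueError):
    """Raised for a constant segment, which min-max normalization cannot scale."""


# --------------------------------------------------------------------------
# AAMI class mapping
# --------------------------------------------------------------------------

#: MIT-BIH beat symbol -> AAMI class for the 15 source annotation codes:
#: N: normal, left/right bundle branch block;
#: S: atrial premature, aberrated atrial premature, nodal premature,
#:    supraventricular premature, atrial escape, nodal escape;
#: V: premature ventricular contraction, ventricular escape;
#: F: fusion of ventricular and normal;
#: Q: paced, fusion of paced and normal, unclassifiable.
DEFAULT_CLASS_MAP: dict[str, str] = {
    "N": "N", "L": "N", "R": "N",
    "A": "S", "a": "S", "J": "S", "S": "S", "e": "S", "j": "S",
    "V": "V", "E": "V",
    "F": "F",
    "/": "Q", "f": "Q", "Q": "Q",
}

assert len(DEFAULT_CLASS_MAP) == 15


def map_symbol(symbol: str, class_map: dict[str, str] | None = None) -> str:
    """Map one MIT-BIH beat annotation symbol to its AAMI class."""
    class_map = DEFAULT_CLASS_MAP if class_map is None else class_map
    try:
        return class_map[symbol]
    except KeyError:
        raise KeyError(
            f"unknown beat annotation symbol {symbol!r}; not in the "
            f"{len(class_map)}-symbol class map"
        ) from None


# --------------------------------------------------------------------------
# record / segment types
# --------------------------------------------------------------------------


@dataclass
class EcgRecord:
    record_id: str
    signal: np.ndarray                      # mV
    fs: float
    annotations: list[tuple[int, str]]      # (r_index, MIT-BIH beat symbol)

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        idx = [r for r, _ in self.annotations]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("annotation r_indices must be strictly increasing")
        if idx and (idx[0] < 0 or idx[-1] >= len(self.signal)):
            raise ValueError("annotation r_indices must lie within the signal")


@dataclass
class BeatSegment:
    values: np.ndarray
    label: str              # AAMI class
    record_id: str
    r_index: int


@dataclass
class WaveletSpec:
    """Discrete-wavelet denoising settings.

    Defaults are the standard ECG choice: Daubechies-4, 3 decomposition
    levels (comfortable for 300-sample segments), soft thresholding with the
    universal threshold sigma*sqrt(2 ln N), sigma estimated from the median
    absolute deviation of the level-1 detail coefficients."""

    wavelet_name: str = "db4"
    level: int = 3
    threshold_rule: str = "soft"
    sigma_estimator: str = "mad_level1"

    def __post_init__(self):
        if self.level < 1:
            raise ValueError("decomposition level must be >= 1")
        if self.threshold_rule not in ("soft", "hard"):
            raise ValueError("threshold_rule must be 'soft' or 'hard'")
        if self.sigma_estimator != "mad_level1":
            raise ValueError("only the 'mad_level1' sigma estimator is implemented")


@dataclass
class SplitSpec:
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0
    stratified: bool = False

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {self.fractions}")
        if any(not (0.0 < f < 1.0) for f in self.fractions):
            raise ValueError("each split fraction must lie in (0, 1)")


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------


def segment_record(record: EcgRecord, half_width: int = 150,
                   class_map: dict[str, str] | None = None
                   ) -> tuple[list[BeatSegment], int]:
    """Cut one window per beat annotation; returns (segments, n_dropped).

    Windows of 2*half_width samples centred so the R sample sits at index
    half_width; beats whose window crosses a record edge are dropped and
    counted.  Invariant: len(segments) + n_dropped == len(annotations).
    """
    if half_width < 1:
        raise ValueError("half_width must be >= 1")
    segments: list[BeatSegment] = []
    dropped = 0
    n = len(record.signal)
    for r, symbol in record.annotations:
        lo, hi = r - half_width, r + half_width
        if lo < 0 or hi > n:
            dropped += 1
            continue
        segments.append(BeatSegment(record.signal[lo:hi].copy(),
                                    map_symbol(symbol, class_map),
                                    record.record_id, r))
    return segments, dropped


def dwt_denoise(values: np.ndarray, spec: WaveletSpec | None = None,
                threshold_scale: float = 1.0) -> np.ndarray:
    """Wavelet shrinkage: decompose, threshold the detail coefficients
    (approximation untouched), reconstruct.  `threshold_scale` scales the
    universal threshold (0 gives perfect reconstruction)."""
    spec = WaveletSpec() if spec is None else spec
    values = np.asarray(values, dtype=np.float64)
    wavelet = pywt.Wavelet(spec.wavelet_name)
    max_level = pywt.dwt_max_level(len(values), wavelet.dec_len)
    if spec.level > max_level:
        raise ValueError(
            f"decomposition level {spec.level} infeasible for length "
            f"{len(values)} with {spec.wavelet_name}; maximum feasible level is {max_level}"
        )
    coeffs = pywt.wavedec(values, wavelet, level=spec.level)
    detail1 = coeffs[-1]
    sigma = np.median(np.abs(detail1 - np.median(detail1))) / 0.6745
    thr = threshold_scale * sigma * math.sqrt(2.0 * math.log(len(values)))
    denoised = [coeffs[0]] + [pywt.threshold(c, thr, mode=spec.threshold_rule)
                              for c in coeffs[1:]]
    return pywt.waverec(denoised, wavelet)[: len(values)]


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """(x - min) / (max - min): rescales into [0, 1] with the minimum mapped
    exactly to 0 and the maximum to 1.  Idempotent."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("cannot normalize an empty segment")
    lo, hi = values.min(), values.max()
    if hi == lo:
        raise DegenerateSegmentError(
            "constant segment (max == min); drop the beat and log it"
        )
    return (values - lo) / (hi - lo)


def preprocess_records(records: list[EcgRecord], half_width: int = 150,
                       wavelet: WaveletSpec | None = None,
                       denoise: bool = True,
                       class_map: dict[str, str] | None = None) -> BeatDataset:
    """Full per-beat pipeline: segment -> (optional) wavelet denoise ->
    min-max normalize.  Degenerate (constant) segments are dropped and
    logged, never silently ignored."""
    feats, labels, rec_ids, r_idx = [], [], [], []
    n_dropped_edges = 0
    n_dropped_flat = 0
    for record in records:
        segments, dropped = segment_record(record, half_width, class_map)
        n_dropped_edges += dropped
        for seg in segments:
            values = dwt_denoise(seg.values, wavelet) if denoise else seg.values
            try:
                values = minmax_normalize(values)
            except DegenerateSegmentError:
                n_dropped_flat += 1
                continue
            feats.append(values)
            labels.append(seg.label)
            rec_ids.append(seg.record_id)
            r_idx.append(seg.r_index)
    if n_dropped_edges or n_dropped_flat:
        logger.info("dropped %d edge-clipped and %d constant segments",
                    n_dropped_edges, n_dropped_flat)
    if not feats:
        return BeatDataset(np.empty((0, 2 * half_width)), np.empty(0, dtype="<U1"))
    return BeatDataset(np.stack(feats), np.array(labels),
                       record_id=np.array(rec_ids), r_index=np.array(r_idx))


def split_sizes(n: int, fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
                ) -> tuple[int, int, int]:
    """(train, val, test) sizes: val and test take the ceiling of their
    fractions, train takes the remainder.  For n = 109,447 at 60/20/20 this
    yields (65,667, 21,890, 21,890)."""
    val = math.ceil(fractions[1] * n)
    test = math.ceil(fractions[2] * n)
    train = n - val - test
    if train <= 0:
        raise ValueError(f"n = {n} too small for fractions {fractions}")
    return train, val, test


def split_dataset(dataset: BeatDataset, spec: SplitSpec | None = None) -> BeatDataset:
    """Assign disjoint, exhaustive train/val/test tags by seeded shuffle.

    Beat-level (intra-patient) split: beats from one record may land in
    different sets.  With `stratified` the ceiling rule is applied within
    each class."""
    spec = SplitSpec() if spec is None else spec
    n = len(dataset)
    if n < 5:
        raise ValueError(f"need at least 5 beats to split, got {n}")
    rng = np.random.default_rng(spec.seed)
    tags = np.full(n, "", dtype="<U5")

    def assign(indices: np.ndarray) -> None:
        perm = indices[rng.permutation(len(indices))]
        tr, va, te = split_sizes(len(indices), spec.fractions)
        tags[perm[:tr]] = "train"
        tags[perm[tr : tr + va]] = "val"
        tags[perm[tr + va :]] = "test"

    if spec.stratified:
        for cls in CLASSES:
            idx = np.flatnonzero(dataset.y == cls)
            if len(idx):
                assign(idx)
    else:
        assign(np.arange(n))
    return BeatDataset(dataset.X, dataset.y, tags, dataset.record_id, dataset.r_index)
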