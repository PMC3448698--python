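"""Probe-level normalization across arrays.

Two methods, selected by name:

``median_scale``
    Each array is rescaled so its median probe intensity equals the
    baseline array's median.

``invariant_set``
    For each array, probes whose across-array rank-difference proportion
    against the baseline is small are selected iteratively; a monotone
    piecewise-linear curve fitted through that invariant set maps every
    intensity onto the baseline scale. This is the rank-invariant-set
    normalization used for probe-level array data before model fitting.

The baseline array may be given explicitly or chosen automatically as the
array whose overall median is closest to the median of the per-array
medians.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.isotonic import IsotonicRegression

from .containers import ProbeLevelMatrix


class _MonotoneCurve:
    """Monotone piecewise-linear map through smoothed (x, y) knots.

    Knots are the per-quantile-bin medians of the invariant-set scatter,
    made non-decreasing by isotonic regression; between knots the map
    interpolates linearly, beyond them it extrapolates with the end-segment
    slopes (so extreme intensities are rescaled, not clipped to a constant).
    """

    def __init__(self, x: np.ndarray, y: np.ndarray, n_bins: int):
        order = np.argsort(x, kind="stable")
        chunks_x = np.array_split(x[order], n_bins)
        chunks_y = np.array_split(y[order], n_bins)
        bx = np.array([np.median(c) for c in chunks_x if len(c)])
        by = np.array([np.median(c) for c in chunks_y if len(c)])
        bx, keep = np.unique(bx, return_index=True)
        by = by[keep]
        by = IsotonicRegression(increasing=True).fit_transform(bx, by)
        self.bx, self.by = bx, by

    def predict(self, values: np.ndarray) -> np.ndarray:
        bx, by = self.bx, self.by
        out = np.interp(values, bx, by)
        if len(bx) >= 2:
            lo = values < bx[0]
            hi = values > bx[-1]
            slope_lo = (by[1] - by[0]) / (bx[1] - bx[0])
            slope_hi = (by[-1] - by[-2]) / (bx[-1] - bx[-2])
            out[lo] = by[0] + (values[lo] - bx[0]) * slope_lo
            out[hi] = by[-1] + (values[hi] - bx[-1]) * slope_hi
        return np.maximum(out, 0.0)

__all__ = ["ProbeNormalizer", "normalize_probe_level", "choose_baseline"]

logger = logging.getLogger(__name__)


def choose_baseline(intensities: pd.DataFrame) -> str:
    """Array whose overall median is the median of the per-array medians."""
    medians = intensities.median(axis=0)
    centre = medians.median()
    return medians.index[int(np.argmin(np.abs(medians.values - centre)))]


class ProbeNormalizer(TransformerMixin, BaseEstimator):
    """Scale probe-level arrays onto a common baseline.

    Parameters
    ----------
    method : {'median_scale', 'invariant_set'}
        Normalization method (see module docstring).
    baseline : sample id or 'auto'
        Baseline array; 'auto' picks the array with the median of medians.
    rank_tol : float
        invariant_set only — maximum allowed |rank difference| / n for a
        probe to stay in the invariant set.
    min_invariant : int or None
        invariant_set only — floor on the invariant-set size; below it the
        sample falls back to median scaling with a logged warning. Default
        ``max(100, 1% of probes)``.
    max_iter : int
        invariant_set only — maximum selection iterations.

    Fitted attributes: ``baseline_``, ``scale_factors_`` (median_scale),
    ``invariant_sets_`` and ``curves_`` (invariant_set).
    """

    def __init__(self, method: str = "median_scale", baseline: str = "auto",
                 rank_tol: float = 0.02, min_invariant=None, max_iter: int = 10):
        self.method = method
        self.baseline = baseline
        self.rank_tol = rank_tol
        self.min_invariant = min_invariant
        self.max_iter = max_iter

    # -- sklearn surface --------------------------------------------------
    def fit(self, X, y=None):
        intensities = X.intensities if isinstance(X, ProbeLevelMatrix) else X
        if self.method not in ("median_scale", "invariant_set"):
            raise ValueError(f"unknown normalization method {self.method!r}")
        if intensities.shape[1] < 2:
            raise ValueError("normalization needs >= 2 samples")
        if (intensities.values < 0).any():
            raise ValueError("negative intensities")
        zero = intensities.columns[(intensities == 0).all(axis=0)]
        if len(zero):
            raise ValueError(f"sample {zero[0]!r} is all-zero")

        self.baseline_ = (choose_baseline(intensities)
                          if self.baseline == "auto" else self.baseline)
        if self.baseline_ not in intensities.columns:
            raise ValueError(f"baseline sample {self.baseline_!r} not in data")

        medians = intensities.median(axis=0)
        self.scale_factors_ = medians[self.baseline_] / medians
        if self.method == "invariant_set":
            self._fit_invariant(intensities)
        return self

    def transform(self, X):
        data = X if isinstance(X, ProbeLevelMatrix) else None
        intensities = X.intensities if data is not None else X
        if self.method == "median_scale":
            out = intensities * self.scale_factors_
        else:
            out = intensities.copy()
            for sample in intensities.columns:
                if sample == self.baseline_:
                    continue
                curve = self.curves_.get(sample)
                if curve is None:  # fallback sample
                    out[sample] = intensities[sample] * self.scale_factors_[sample]
                else:
                    out[sample] = curve.predict(intensities[sample].values)
        out = out.clip(lower=0.0)
        if data is not None:
            return ProbeLevelMatrix(out, data.probe_map.copy(), data.sample_groups.copy())
        return out

    # -- invariant-set machinery ------------------------------------------
    def _fit_invariant(self, intensities: pd.DataFrame) -> None:
        n_probes = intensities.shape[0]
        floor = (max(100, n_probes // 100)
                 if self.min_invariant is None else int(self.min_invariant))
        base = intensities[self.baseline_].values
        self.invariant_sets_ = {}
        self.curves_ = {}
        for sample in intensities.columns:
            if sample == self.baseline_:
                continue
            values = intensities[sample].values
            idx = np.arange(n_probes)
            too_small = False
            for _ in range(self.max_iter):
                m = len(idx)
                prd = np.abs(rankdata(base[idx]) - rankdata(values[idx])) / m
                keep = idx[prd < self.rank_tol]
                if len(keep) < floor:
                    too_small = True
                    break
                shrunk = len(keep) < 0.99 * len(idx)
                idx = keep
                if not shrunk:
                    break
            if too_small or len(idx) < floor:
                warnings.warn(
                    f"invariant set for sample {sample!r} below floor ({len(idx)} < {floor}); "
                    "falling back to median scaling for this sample"
                )
                logger.warning("invariant-set fallback to median_scale for sample %s", sample)
                continue
            n_bins = int(np.clip(len(idx) // 40, 10, 100))
            self.invariant_sets_[sample] = idx
            self.curves_[sample] = _MonotoneCurve(values[idx], base[idx], n_bins)


def normalize_probe_level(data: ProbeLevelMatrix, method: str = "median_scale",
                          baseline: str = "auto", **kwargs) -> ProbeLevelMatrix:
    """Normalize a probe-level matrix across arrays (functional wrapper)."""
    return ProbeNormalizer(method=method, baseline=baseline, **kwargs).fit(data).transform(data)
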