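"""Internal-consistency f-ratio over probe-set member probes.

Each member probe is z-scored across the sample series; the f-ratio is the
variance between per-sample means of those z-scores divided by the variance
of the member probes within samples:

    z_js = (x_js - mean_s x_j.) / sd_s x_j.         (sd with S-1)
    m_s  = mean_j z_js
    between = Var_s(m_s)                            (denominator S-1)
    within  = sum_s sum_j (z_js - m_s)^2 / (S (J-1))
    f = between / within                            (within = 0 -> +inf)

Coherent probe sets — member probes moving together across samples — have
between-variance close to the (unit) probe variance and small
within-variance, so f exceeds 1; independent-noise sets concentrate near
1/J, far below 1. The screening filter keeps probe sets with f strictly
greater than a cutoff (default 1.0).

Note this deliberately omits the J multiplier of a classical one-way ANOVA
mean square: with the multiplier the null expectation is ~1 and a 1.0
cutoff could not separate coherent sets from noise. The classical scaling is
available via ``scaling='classical'``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import ProbeLevelMatrix

__all__ = [
    "zscore_probes",
    "f_ratio",
    "compute_f_ratios",
    "consistency_filter",
    "export_probe_trajectories",
    "FRatioFilter",
]


def zscore_probes(data: ProbeLevelMatrix, probeset_id) -> tuple[pd.DataFrame, list]:
    """Z-score the member probes of one probe set across the sample series.

    Probes constant across samples carry no trajectory information and are
    dropped (returned separately). Raises if fewer than 2 usable probes
    remain.
    """
    probes = data.probes_of(probeset_id)
    if len(probes) == 0:
        raise KeyError(f"unknown probe set {probeset_id!r}")
    x = data.intensities.loc[probes]
    sd = x.std(axis=1, ddof=1)
    dropped = list(x.index[sd == 0.0])
    usable = x.index[sd > 0.0]
    if len(usable) < 2:
        raise ValueError(
            f"probe set {probeset_id!r} has {len(usable)} probe(s) with "
            "across-sample variance; need >= 2"
        )
    z = x.loc[usable].sub(x.loc[usable].mean(axis=1), axis=0).div(sd[usable], axis=0)
    return z, dropped


def f_ratio(z, scaling: str = "plain") -> float:
    """f-ratio of a probe × sample z-score matrix (see module docstring)."""
    z = np.asarray(z, dtype=float)
    if z.ndim != 2 or z.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 probes")
    J, S = z.shape
    if S < 3:
        raise ValueError("need >= 3 samples (between-variance needs >= 2 "
                         "degrees of freedom after z-scoring)")
    if scaling not in ("plain", "classical"):
        raise ValueError(f"unknown scaling {scaling!r}")
    m = z.mean(axis=0)
    between = m.var(ddof=1)
    within = ((z - m) ** 2).sum() / (S * (J - 1))
    if scaling == "classical":
        between *= J
    # rounding dust from exactly coherent probes counts as zero within-variance
    if within <= 1e-12 * max(between, 1.0):
        return np.inf if between > 0.0 else 0.0
    return float(between / within)


def _f_ratio_batch(z: np.ndarray, scaling: str = "plain") -> np.ndarray:
    """Vectorized f-ratio over a (G, J, S) stack of z-scored sets.

    NaN rows (dropped probes) are ignored; sets with < 2 usable probes
    yield NaN.
    """
    usable = ~np.isnan(z).all(axis=2)                       # (G, J)
    J_used = usable.sum(axis=1).astype(float)               # (G,)
    z0 = np.nan_to_num(z, nan=0.0)
    S = z.shape[2]
    m = z0.sum(axis=1) / np.maximum(J_used, 1.0)[:, None]   # (G, S)
    between = m.var(axis=1, ddof=1)
    resid = np.where(usable[:, :, None], z0 - m[:, None, :], 0.0)
    within = (resid ** 2).sum(axis=(1, 2)) / (S * np.maximum(J_used - 1.0, 1.0))
    if scaling == "classical":
        between = between * J_used
    with np.errstate(divide="ignore", invalid="ignore"):
        f = between / within
    zero_within = within <= 1e-12 * np.maximum(between, 1.0)
    f = np.where(zero_within, np.where(between > 0.0, np.inf, 0.0), f)
    return np.where(J_used < 2, np.nan, f)


def compute_f_ratios(data: ProbeLevelMatrix, probeset_ids=None,
                     scaling: str = "plain", by_group: bool = False) -> pd.DataFrame:
    """f-ratios for many probe sets at once.

    Returns a table indexed by probe-set id with columns ``f_ratio``,
    ``n_probes_used`` and ``n_dropped`` (probes constant across samples).
    ``by_group=True`` replaces per-sample means by group means in the
    between-variance (the group-mean variant of the statistic).
    """
    if scaling not in ("plain", "classical"):
        raise ValueError(f"unknown scaling {scaling!r}")
    if probeset_ids is None:
        probeset_ids = data.probeset_ids
    wanted = list(probeset_ids)
    sub = data.subset_probesets(wanted)
    values = np.asarray(sub.intensities.values, dtype=float)
    S = values.shape[1]

    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z_all = (values - mean) / sd
    z_rows = np.where(sd > 0.0, z_all, np.nan)

    if by_group:
        # average replicate columns within each group before the f computation
        group_labels = sub.sample_groups.values
        groups = list(dict.fromkeys(group_labels))
        z_rows = np.column_stack([
            np.nanmean(z_rows[:, group_labels == g], axis=1) for g in groups
        ]) if len(groups) >= 3 else z_rows
        S = z_rows.shape[1]

    codes, probesets = pd.factorize(sub.probe_map.values)
    counts = np.bincount(codes)
    row_order = np.argsort(codes, kind="stable")
    starts = np.concatenate([[0], np.cumsum(counts)])

    f = np.full(len(probesets), np.nan)
    used = np.zeros(len(probesets), dtype=int)
    dropped = np.zeros(len(probesets), dtype=int)
    for J in np.unique(counts):
        sets = np.flatnonzero(counts == J)
        rows = np.concatenate([row_order[starts[g]:starts[g + 1]] for g in sets])
        zb = z_rows[rows].reshape(len(sets), J, -1)
        f[sets] = _f_ratio_batch(zb, scaling=scaling)
        usable = ~np.isnan(zb).all(axis=2)
        used[sets] = usable.sum(axis=1)
        dropped[sets] = J - used[sets]

    out = pd.DataFrame(
        {"f_ratio": f, "n_probes_used": used, "n_dropped": dropped},
        index=pd.Index(probesets, name="probeset_id"),
    )
    return out.loc[wanted]


def consistency_filter(f_ratios, cutoff: float = 1.0) -> list:
    """Probe-set ids with f-ratio strictly greater than ``cutoff``.

    +inf (perfectly coherent degenerate sets) passes; exactly ``cutoff``
    fails; input order is preserved. Accepts the table from
    :func:`compute_f_ratios` or a Series id → f.
    """
    series = f_ratios["f_ratio"] if isinstance(f_ratios, pd.DataFrame) else f_ratios
    return list(series.index[series.values > cutoff])


def export_probe_trajectories(data: ProbeLevelMatrix, probeset_id, sample_order=None,
                              group_boundaries=(), values: str = "z") -> pd.DataFrame:
    """Long-format member-probe trajectories for eXintegrator-style plots.

    One row per (probe, sample) with the block index implied by
    ``group_boundaries`` — positions after which a vertical separator falls,
    e.g. ``(3, 6, 9)`` for 12 samples → 4 blocks. ``values='raw'``
    round-trips the input intensities exactly; ``'z'`` exports the z-scored
    trajectories.
    """
    if values not in ("z", "raw"):
        raise ValueError(f"unknown values mode {values!r}")
    if sample_order is None:
        sample_order = list(data.samples)
    unknown = [s for s in sample_order if s not in data.samples]
    if unknown:
        raise ValueError(f"unknown sample {unknown[0]!r} in sample order")

    if values == "z":
        mat, _ = zscore_probes(data, probeset_id)
    else:
        mat = data.intensities.loc[data.probes_of(probeset_id)]
        if len(mat) == 0:
            raise KeyError(f"unknown probe set {probeset_id!r}")
    mat = mat[list(sample_order)]

    boundaries = sorted(group_boundaries)
    block_of = np.searchsorted(boundaries, np.arange(len(sample_order)), side="right")
    rows = []
    for probe in mat.index:
        for pos, sample in enumerate(sample_order):
            rows.append((probe, sample, data.sample_groups[sample],
                         int(block_of[pos]), mat.at[probe, sample]))
    return pd.DataFrame(rows, columns=["probe_id", "sample_id", "group", "block", "value"])


class FRatioFilter(BaseEstimator):
    """Feature-selection-style wrapper: fit f-ratios, select coherent sets.

    Parameters: ``cutoff`` (strict lower bound, default 1.0), ``scaling``
    ('plain' or 'classical'), ``by_group`` (between-variance over group
    means instead of sample means). Fitted attributes: ``f_ratios_``
    (table), ``support_`` (boolean Series), ``passing_ids_``.
    """

    def __init__(self, cutoff: float = 1.0, scaling: str = "plain", by_group: bool = False):
        self.cutoff = cutoff
        self.scaling = scaling
        self.by_group = by_group

    def fit(self, X: ProbeLevelMatrix, y=None, probeset_ids=None):
        self.f_ratios_ = compute_f_ratios(X, probeset_ids, self.scaling, self.by_group)
        self.support_ = self.f_ratios_["f_ratio"] > self.cutoff
        self.passing_ids_ = consistency_filter(self.f_ratios_, self.cutoff)
        return self

    def get_support(self) -> np.ndarray:
        return self.support_.values

    def transform(self, probeset_ids) -> list:
        """Restrict a candidate id list to the coherent probe sets."""
        passing = set(self.passing_ids_)
        return [i for i in probeset_ids if i in passing]
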