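"""Two-class unpaired SAM screen with permutation FDR.

The per-probe-set statistic is the regularized relative difference

    d = r / (s + s0),    r = mean(group2) - mean(group1),
    s = sqrt( a * [SS_within(group1) + SS_within(group2)] ),
    a = (1/n1 + 1/n2) / (n1 + n2 - 2),

so that with s0 = 0, d is exactly the pooled two-sample t statistic. The
fudge factor s0 is chosen to minimize the coefficient of variation of the
median absolute deviation of d across windows of the scatter s. The null
distribution comes from relabeling the pooled samples: when the number of
distinct label splits is no larger than the requested permutation count the
splits are enumerated exhaustively (e.g. C(6,3) = 20 for 3 + 3 samples),
otherwise splits are drawn uniformly with replacement. Probe sets are called
up when their sorted d exceeds the null expectation d̄ by more than δ AND
their linear fold change clears the fold gate; the median FDR at δ is the
median over permutations of the null exceedance count, deflated by the
estimated null proportion π0 and divided by the number of calls. δ itself is
tuned on a grid to the smallest value whose median FDR is below the target
(default 0.01).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "sam_statistic",
    "estimate_s0",
    "sam_permutation_test",
    "fold_change",
    "estimate_pi0",
    "call_significant",
    "build_delta_table",
    "choose_delta",
    "PermutationNull",
    "CallResult",
    "SamResult",
    "SamScreen",
]


# ---------------------------------------------------------------------------
# statistic

def _group_values(theta: pd.DataFrame, groups: pd.Series, label):
    cols = theta.columns[groups.loc[theta.columns].values == label]
    if len(cols) < 2:
        raise ValueError(f"group {label!r} needs >= 2 samples, has {len(cols)}")
    return theta[cols].values


def _r_and_s(x1: np.ndarray, x2: np.ndarray):
    n1, n2 = x1.shape[1], x2.shape[1]
    r = x2.mean(axis=1) - x1.mean(axis=1)
    ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss += ((x2 - x2.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    a = (1.0 / n1 + 1.0 / n2) / (n1 + n2 - 2)
    s = np.sqrt(a * ss)
    return r, s


def _d_from_rs(r: np.ndarray, s: np.ndarray, s0: float) -> np.ndarray:
    denom = s + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = r / denom
        # zero scatter with s0 = 0: signed-infinity sentinel (0 when r = 0 too)
        d = np.where(denom > 0, d, np.sign(r) * np.inf)
    return np.where((denom > 0) | (r != 0), d, 0.0)


def sam_statistic(theta: pd.DataFrame, groups: pd.Series, group1, group2,
                  s0: float = 0.0) -> pd.DataFrame:
    """Per-probe-set relative difference d, scatter s and raw difference r.

    ``group2`` is the target group: positive d means higher in group2.
    """
    x1 = _group_values(theta, groups, group1)
    x2 = _group_values(theta, groups, group2)
    r, s = _r_and_s(x1, x2)
    return pd.DataFrame({"r": r, "s": s, "d": _d_from_rs(r, s, s0)}, index=theta.index)


def estimate_s0(r, s, n_bins: int | None = None) -> float:
    """Tusher-style fudge factor: the percentile of s (0,5,...,100) whose
    d = r/(s+s0) has the most uniform spread across windows of s.

    Spread per window is the median absolute deviation of d; uniformity is
    the coefficient of variation of those MADs. Zero-scatter probe sets are
    excluded. Ties resolve to the smallest candidate; all-equal s returns 0
    with a warning. Deterministic.
    """
    r = np.asarray(r, dtype=float)
    s = np.asarray(s, dtype=float)
    keep = s > 0
    r, s = r[keep], s[keep]
    if len(s) == 0 or np.all(s == s[0]):
        warnings.warn("degenerate scatter values; returning s0 = 0")
        return 0.0
    if len(s) < 100:
        warnings.warn(f"s0 estimated from only {len(s)} probe sets; "
                      "recommend >= 100")
    if n_bins is None:
        n_bins = int(min(100, max(2, len(s) // 25)))
    edges = np.quantile(s, np.linspace(0, 1, n_bins + 1))
    bin_idx = np.clip(np.searchsorted(edges[1:-1], s, side="right"), 0, n_bins - 1)
    bins = [np.flatnonzero(bin_idx == b) for b in range(n_bins)]
    bins = [b for b in bins if len(b) >= 2]

    candidates = np.concatenate([[0.0], np.percentile(s, np.arange(0, 101, 5))])
    best_cv, best = np.inf, candidates[0]
    for cand in candidates:
        d = r / (s + cand)
        mads = np.array([np.median(np.abs(d[b] - np.median(d[b]))) for b in bins])
        mean = mads.mean()
        cv = mads.std(ddof=1) / mean if mean > 0 else np.inf
        if cv < best_cv:  # strict: ties keep the smaller (earlier) candidate
            best_cv, best = cv, float(cand)
    return best


# ---------------------------------------------------------------------------
# permutation null

@dataclass
class PermutationNull:
    """Sorted null statistics d* per permutation and their column means d̄."""

    d_star: np.ndarray        # (n_perm, G), each row sorted ascending
    d_bar: np.ndarray         # (G,) expected order statistics
    n_permutations: int
    exhaustive: bool
    n_distinct: int


def _label_splits(n: int, n1: int, n_permutations: int, rng: np.random.Generator):
    """Index sets (positions of group1) for each permutation."""
    n_distinct = comb(n, n1)
    if n_distinct <= n_permutations:
        return [np.array(c) for c in combinations(range(n), n1)], True, n_distinct
    splits = [np.sort(rng.permutation(n)[:n1]) for _ in range(n_permutations)]
    return splits, False, n_distinct


def sam_permutation_test(theta: pd.DataFrame, groups: pd.Series, group1, group2,
                         n_permutations: int = 800, seed: int = 0,
                         s0: float = 0.0) -> PermutationNull:
    """Permutation null of d by relabeling the pooled two-group samples.

    When the number of distinct splits C(n1+n2, n1) does not exceed
    ``n_permutations`` every split is used exactly once (exhaustive,
    variance-free); otherwise ``n_permutations`` splits are sampled
    uniformly. Deterministic under a fixed seed.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    x1 = _group_values(theta, groups, group1)
    x2 = _group_values(theta, groups, group2)
    pooled = np.hstack([x1, x2])
    n1, n = x1.shape[1], pooled.shape[1]

    rng = np.random.default_rng(seed)
    splits, exhaustive, n_distinct = _label_splits(n, n1, n_permutations, rng)
    all_idx = np.arange(n)
    d_star = np.empty((len(splits), pooled.shape[0]))
    for p, idx1 in enumerate(splits):
        idx2 = np.setdiff1d(all_idx, idx1, assume_unique=True)
        r, s = _r_and_s(pooled[:, idx1], pooled[:, idx2])
        d_star[p] = np.sort(_d_from_rs(r, s, s0))
    return PermutationNull(
        d_star=d_star,
        d_bar=d_star.mean(axis=0),
        n_permutations=len(splits),
        exhaustive=exhaustive,
        n_distinct=n_distinct,
    )


# ---------------------------------------------------------------------------
# calling and FDR

def fold_change(theta: pd.DataFrame, groups: pd.Series, group1, group2,
                floor: float = 1.0) -> pd.Series:
    """Linear-scale fold change (group2 mean + floor) / (group1 mean + floor).

    The additive floor keeps ratios stable when expression indices are near
    zero.
    """
    x1 = _group_values(theta, groups, group1).mean(axis=1)
    x2 = _group_values(theta, groups, group2).mean(axis=1)
    return pd.Series((x2 + floor) / (x1 + floor), index=theta.index, name="fold_change")


def estimate_pi0(d, d_star: np.ndarray) -> float:
    """Null-proportion estimate from the quartile window of the permuted d*.

    π0 = min(1, [share of observed d inside the (q25, q75) interval of all
    permuted d*] / 0.5); floored at 1/G so the FDR numerator never vanishes
    by a degenerate estimate.
    """
    d = np.asarray(d, dtype=float)
    q25, q75 = np.percentile(d_star[np.isfinite(d_star)], [25, 75])
    inside = np.mean((d >= q25) & (d <= q75))
    return float(min(1.0, max(inside / 0.5, 1.0 / max(len(d), 1))))


@dataclass
class CallResult:
    called: np.ndarray          # boolean, original probe-set order
    n_called: int
    median_fdr: float
    cutup: float = np.nan
    cutdown: float = np.nan


def call_significant(d, d_bar: np.ndarray, delta: float, fold_change=None,
                     fold_min: float = 2.0, direction: str = "up",
                     d_star: np.ndarray | None = None,
                     pi0: float = 1.0) -> CallResult:
    """Call probe sets at band half-width δ with a conjunctive fold gate.

    In rank space (d sorted ascending, aligned with d̄), a set is called up
    when d_(i) − d̄_(i) > δ and its fold change ≥ fold_min; with
    ``direction='both'`` the mirrored rule calls sets down when
    d_(i) − d̄_(i) < −δ and fold change ≤ 1/fold_min. The median FDR is
    median over permutations of #{d* ≥ cutup} (+ #{d* ≤ cutdown}), times π0,
    divided by the number of calls, clipped to [0, 1]; zero calls give 0.
    """
    if direction not in ("up", "both"):
        raise ValueError(f"unknown direction {direction!r}")
    d = np.asarray(d, dtype=float)
    order = np.argsort(d, kind="stable")
    d_sorted = d[order]
    diff = d_sorted - d_bar

    fold = np.ones_like(d) if fold_change is None else np.asarray(fold_change, dtype=float)
    fold_sorted = fold[order]

    up = (diff > delta) & (fold_sorted >= fold_min)
    down = np.zeros_like(up)
    if direction == "both":
        down = (diff < -delta) & (fold_sorted <= 1.0 / fold_min)

    called_sorted = up | down
    n_called = int(called_sorted.sum())
    called = np.zeros_like(called_sorted)
    called[order] = called_sorted

    if n_called == 0 or d_star is None:
        return CallResult(called=called, n_called=n_called, median_fdr=0.0)

    cutup = d_sorted[up].min() if up.any() else np.inf
    cutdown = d_sorted[down].max() if down.any() else -np.inf
    null_counts = (d_star >= cutup).sum(axis=1)
    if direction == "both":
        null_counts = null_counts + (d_star <= cutdown).sum(axis=1)
    fdr = float(np.median(null_counts)) * pi0 / n_called
    return CallResult(called=called, n_called=n_called,
                      median_fdr=float(min(fdr, 1.0)),
                      cutup=cutup, cutdown=cutdown)


def build_delta_table(d, d_bar, fold_change=None, fold_min: float = 2.0,
                      direction: str = "up", d_star: np.ndarray | None = None,
                      pi0: float = 1.0, n_steps: int = 200) -> pd.DataFrame:
    """δ grid (0 → max|d−d̄|, ``n_steps`` points) with calls and median FDR."""
    d = np.asarray(d, dtype=float)
    diff = np.abs(d[np.argsort(d, kind="stable")] - d_bar)
    top = np.nanmax(diff[np.isfinite(diff)]) if np.isfinite(diff).any() else 1.0
    grid = np.linspace(0.0, top, n_steps)
    rows = []
    for delta in grid:
        res = call_significant(d, d_bar, delta, fold_change, fold_min,
                               direction, d_star, pi0)
        rows.append((delta, res.n_called, res.median_fdr))
    return pd.DataFrame(rows, columns=["delta", "n_called", "median_fdr"])


def choose_delta(delta_table: pd.DataFrame, target_fdr: float = 0.01) -> float:
    """Smallest δ on the grid whose median FDR is below ``target_fdr``.

    With a (weakly) monotone table this maximizes the number of calls
    subject to the FDR bound. If no δ qualifies, the grid maximum is
    returned with a warning (it yields zero calls on a monotone table).
    """
    ok = delta_table[delta_table["median_fdr"] < target_fdr]
    if len(ok) == 0:
        warnings.warn(f"no delta reaches median FDR < {target_fdr}; "
                      "returning grid maximum")
        return float(delta_table["delta"].max())
    return float(ok["delta"].iloc[0])


# ---------------------------------------------------------------------------
# estimator

@dataclass
class SamResult:
    """Per-probe-set SAM results plus the screen's global quantities."""

    table: pd.DataFrame          # d, s, r, expected_d, fold_change, called, direction
    s0: float
    delta: float
    median_fdr: float
    pi0: float
    n_permutations: int
    delta_table: pd.DataFrame = field(repr=False, default=None)

    @property
    def called_ids(self) -> list:
        return list(self.table.index[self.table["called"]])


class SamScreen(BaseEstimator):
    """Full SAM differential screen between two sample groups.

    Parameters mirror the screen's knobs: permutation count (cap; exhaustive
    enumeration below it), fudge factor (``'auto'`` = CV-minimizing
    estimate), fold gate on linear expression indices, target median FDR for
    the δ search, and calling direction (``'up'`` = higher in ``group2``).

    Fit on an expression-index matrix (probe sets × samples) with the
    sample → group mapping as ``y``. Fitted attributes: ``d_``, ``s_``,
    ``r_``, ``s0_``, ``expected_d_``, ``fold_change_``, ``pi0_``,
    ``delta_``, ``delta_table_``, ``called_``, ``median_fdr_``, ``null_``,
    ``result_``.
    """

    def __init__(self, group1, group2, n_permutations: int = 800, seed: int = 0,
                 s0="auto", fold_min: float = 2.0, fold_floor: float = 1.0,
                 target_fdr: float = 0.01, direction: str = "up",
                 delta=None, n_delta: int = 200, pi0="auto"):
        self.group1 = group1
        self.group2 = group2
        self.n_permutations = n_permutations
        self.seed = seed
        self.s0 = s0
        self.fold_min = fold_min
        self.fold_floor = fold_floor
        self.target_fdr = target_fdr
        self.direction = direction
        self.delta = delta
        self.n_delta = n_delta
        self.pi0 = pi0

    def fit(self, X: pd.DataFrame, y: pd.Series):
        theta, groups = X, pd.Series(y, index=X.columns) if not isinstance(y, pd.Series) else y
        stats = sam_statistic(theta, groups, self.group1, self.group2, s0=0.0)
        r, s = stats["r"].values, stats["s"].values
        self.s0_ = estimate_s0(r, s) if self.s0 == "auto" else float(self.s0)
        d = _d_from_rs(r, s, self.s0_)

        null = sam_permutation_test(theta, groups, self.group1, self.group2,
                                    self.n_permutations, self.seed, self.s0_)
        self.pi0_ = estimate_pi0(d, null.d_star) if self.pi0 == "auto" else float(self.pi0)
        fold = fold_change(theta, groups, self.group1, self.group2, self.fold_floor)

        self.delta_table_ = build_delta_table(d, null.d_bar, fold.values,
                                              self.fold_min, self.direction,
                                              null.d_star, self.pi0_, self.n_delta)
        self.delta_ = (choose_delta(self.delta_table_, self.target_fdr)
                       if self.delta is None else float(self.delta))
        res = call_significant(d, null.d_bar, self.delta_, fold.values,
                               self.fold_min, self.direction, null.d_star, self.pi0_)

        order = np.argsort(d, kind="stable")
        expected = np.empty_like(d)
        expected[order] = null.d_bar

        self.d_ = pd.Series(d, index=theta.index, name="d")
        self.r_ = pd.Series(r, index=theta.index, name="r")
        self.s_ = pd.Series(s, index=theta.index, name="s")
        self.expected_d_ = pd.Series(expected, index=theta.index, name="expected_d")
        self.fold_change_ = fold
        self.called_ = pd.Series(res.called, index=theta.index, name="called")
        self.median_fdr_ = res.median_fdr
        self.null_ = null
        self.result_ = SamResult(
            table=pd.DataFrame({
                "d": self.d_, "s": self.s_, "r": self.r_,
                "expected_d": self.expected_d_,
                "fold_change": self.fold_change_,
                "called": self.called_,
                "direction": np.where(d >= 0, "up", "down"),
            }),
            s0=self.s0_, delta=self.delta_, median_fdr=self.median_fdr_,
            pi0=self.pi0_, n_permutations=null.n_permutations,
            delta_table=self.delta_table_,
        )
        return self

    def predict(self, X=None) -> pd.Series:
        """Boolean significance calls for the fitted probe sets."""
        return self.called_
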