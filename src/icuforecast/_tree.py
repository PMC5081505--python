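"""Shared binary-tree machinery for the survival and regression forests.

Both forests grow axis-aligned binary trees over a small number of
small-cardinality predictors (SOFA subscores 0-4, days admitted). Split
search therefore pre-bins every predictor onto its global grid of distinct
values once per fit; inside a node, a single ``bincount`` over (feature,
value-bin, time) tables scores *every* midpoint cut of every candidate
variable at once with cumulative sums, which keeps tree growth fast without
compiled code.

Conventions shared by both forests:

* candidate cut values are midpoints between consecutive distinct values of
  the variable present in the node; a case goes left when ``x <= threshold``;
* ties in the split criterion break deterministically to the lowest variable
  index, then the lowest cut value — so trees are invariant to row order;
* node sample index arrays carry bootstrap multiplicity (a row drawn twice
  appears twice).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

try:  # optional compiled fast path for the log-rank node scan
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is normally available
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(fn):
            return fn

        return wrap

__all__ = [
    "Tree",
    "BinnedFeatures",
    "grow_tree",
    "route",
    "best_logrank_split",
    "best_rss_split",
]


@dataclass
class Tree:
    """Flat array representation of one binary tree.

    ``feature[i] < 0`` marks a leaf; then ``leaf_id[i]`` indexes the
    forest-specific payload list (a step function or a scalar mean).
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    leaf_id: np.ndarray

    @property
    def n_leaves(self) -> int:
        return int(np.sum(self.feature < 0))

    def to_dict(self) -> dict:
        return {
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "left": self.left.tolist(),
            "right": self.right.tolist(),
            "leaf_id": self.leaf_id.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Tree":
        return cls(
            feature=np.asarray(d["feature"], dtype=int),
            threshold=np.asarray(d["threshold"], dtype=float),
            left=np.asarray(d["left"], dtype=int),
            right=np.asarray(d["right"], dtype=int),
            leaf_id=np.asarray(d["leaf_id"], dtype=int),
        )


class BinnedFeatures:
    """Predictors mapped once onto their global grids of distinct values."""

    def __init__(self, X: np.ndarray):
        self.X = np.asarray(X, dtype=float)
        n, p = self.X.shape
        self.uvs = [np.unique(self.X[:, j]) for j in range(p)]
        self.vmax = max((len(uv) for uv in self.uvs), default=0)
        self.codes = np.empty((n, p), dtype=np.int64)
        for j, uv in enumerate(self.uvs):
            self.codes[:, j] = np.searchsorted(uv, self.X[:, j])

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def grow_tree(
    X: np.ndarray,
    idx_root: np.ndarray,
    split_fn: Callable[[np.ndarray, int], Optional[tuple[int, float]]],
    leaf_fn: Callable[[np.ndarray], object],
) -> tuple[Tree, list]:
    """Grow one tree.

    ``split_fn(idx, depth)`` returns ``(feature, threshold)`` or ``None`` to
    make the node terminal; ``leaf_fn(idx)`` builds the terminal payload.
    Nodes are processed in deterministic preorder (left child first) so any
    RNG consumed inside ``split_fn`` is replayed identically across runs.
    """
    feature: list[int] = []
    threshold: list[float] = []
    left: list[int] = []
    right: list[int] = []
    leaf_id: list[int] = []
    payloads: list = []

    def new_node() -> int:
        feature.append(-1)
        threshold.append(0.0)
        left.append(-1)
        right.append(-1)
        leaf_id.append(-1)
        return len(feature) - 1

    root = new_node()
    stack: list[tuple[int, np.ndarray, int]] = [(root, idx_root, 0)]
    while stack:
        nid, idx, depth = stack.pop()
        split = split_fn(idx, depth)
        if split is None:
            leaf_id[nid] = len(payloads)
            payloads.append(leaf_fn(idx))
            continue
        f, thr = split
        mask = X[idx, f] <= thr
        feature[nid] = f
        threshold[nid] = thr
        lnid, rnid = new_node(), new_node()
        left[nid], right[nid] = lnid, rnid
        stack.append((rnid, idx[~mask], depth + 1))
        stack.append((lnid, idx[mask], depth + 1))
    tree = Tree(
        feature=np.asarray(feature, dtype=int),
        threshold=np.asarray(threshold, dtype=float),
        left=np.asarray(left, dtype=int),
        right=np.asarray(right, dtype=int),
        leaf_id=np.asarray(leaf_id, dtype=int),
    )
    return tree, payloads


def route(tree: Tree, X: np.ndarray) -> np.ndarray:
    """Drop every row of ``X`` through the tree; return its leaf id."""
    n = len(X)
    out = np.empty(n, dtype=int)
    stack: list[tuple[int, np.ndarray]] = [(0, np.arange(n))]
    while stack:
        nid, idx = stack.pop()
        if len(idx) == 0:
            continue
        f = tree.feature[nid]
        if f < 0:
            out[idx] = tree.leaf_id[nid]
            continue
        mask = X[idx, f] <= tree.threshold[nid]
        stack.append((tree.left[nid], idx[mask]))
        stack.append((tree.right[nid], idx[~mask]))
    return out


def _threshold_for_cut(
    binned: BinnedFeatures, value_counts: np.ndarray, f: int, k: int
) -> float:
    """Midpoint between the node's largest value <= bin k and smallest > k."""
    present = np.nonzero(value_counts)[0]
    lo = present[present <= k].max()
    hi = present[present > k].min()
    uv = binned.uvs[f]
    return float((uv[lo] + uv[hi]) / 2.0)


@njit(cache=True)
def _logrank_scan(sub, ti, ev, n_times, vmax, d0, min_size):  # pragma: no cover
    """Scan every (feature, cut) pair of a node; see best_logrank_split.

    ``sub`` is (m, n) feature-major value-bin codes. Returns the row-major
    first maximizer (lowest feature index, then lowest cut bin) of the
    absolute standardized log-rank statistic among valid cuts.
    """
    m, n = sub.shape
    A = np.zeros((m, vmax, n_times), dtype=np.int64)
    D = np.zeros((m, vmax, n_times), dtype=np.int64)
    d_t = np.zeros(n_times, dtype=np.int64)
    a_t = np.zeros(n_times, dtype=np.int64)
    for s in range(n):
        t = ti[s]
        a_t[t] += 1
        if ev[s]:
            d_t[t] += 1
        for f in range(m):
            v = sub[f, s]
            A[f, v, t] += 1
            if ev[s]:
                D[f, v, t] += 1
    n_at = np.empty(n_times, dtype=np.int64)
    acc = 0
    for t in range(n_times - 1, -1, -1):
        acc += a_t[t]
        n_at[t] = acc
    best_score = -1.0
    best_f = -1
    best_k = -1
    Dc = np.empty(n_times, dtype=np.int64)
    Ac = np.empty(n_times, dtype=np.int64)
    n1_at = np.empty(n_times, dtype=np.int64)
    for f in range(m):
        for t in range(n_times):
            Dc[t] = 0
            Ac[t] = 0
        left_n = 0
        distinct_left = 0
        for k in range(vmax - 1):
            for t in range(n_times):
                if D[f, k, t] > 0 and Dc[t] == 0:
                    distinct_left += 1
                Dc[t] += D[f, k, t]
                Ac[t] += A[f, k, t]
                left_n += A[f, k, t]
            if left_n < min_size or n - left_n < min_size:
                continue
            if distinct_left <= d0:
                continue
            distinct_right = 0
            for t in range(n_times):
                if d_t[t] - Dc[t] > 0:
                    distinct_right += 1
            if distinct_right <= d0:
                continue
            acc = 0
            for t in range(n_times - 1, -1, -1):
                acc += Ac[t]
                n1_at[t] = acc
            u = 0.0
            var = 0.0
            for t in range(n_times):
                d = d_t[t]
                if d == 0:
                    continue
                nm = n_at[t]
                frac = n1_at[t] / nm
                u += Dc[t] - d * frac
                if nm > 1:
                    var += d * frac * (1.0 - frac) * (nm - d) / (nm - 1.0)
            if var > 0.0:
                score = abs(u) / np.sqrt(var)
                if score > best_score:
                    best_score = score
                    best_f = f
                    best_k = k
    return best_f, best_k, best_score


def best_logrank_split(
    binned: BinnedFeatures,
    t_idx: np.ndarray,
    events: np.ndarray,
    idx: np.ndarray,
    feats: np.ndarray,
    n_times: int,
    min_child_unique_deaths: int,
    min_child_size: int = 1,
    force_numpy: bool = False,
) -> Optional[tuple[int, float, float]]:
    """Best split by |standardized log-rank| over candidate features.

    Builds (feature, value-bin, time) event/at-risk tables for the node and
    scores every cut simultaneously (compiled scan when numba is available,
    vectorized numpy otherwise; ``force_numpy`` pins the numpy path for
    cross-checks). A cut is valid only when both children hold at least
    ``min_child_size`` cases, both would hold strictly more than
    ``min_child_unique_deaths`` distinct event times, and the log-rank
    variance is positive. Returns ``(feature, threshold, |statistic|)`` or
    ``None`` when no valid cut exists.
    """
    if _HAVE_NUMBA and not force_numpy:
        vmax = binned.vmax
        if vmax < 2:
            return None
        sub = np.ascontiguousarray(binned.codes[idx][:, feats].T)
        f_i, k, score = _logrank_scan(
            sub,
            t_idx[idx].astype(np.int64),
            events[idx],
            n_times,
            vmax,
            min_child_unique_deaths,
            min_child_size,
        )
        if f_i < 0:
            return None
        f = int(feats[f_i])
        counts = np.bincount(sub[f_i], minlength=vmax)
        thr = _threshold_for_cut(binned, counts, f, int(k))
        return f, thr, float(score)
    return _best_logrank_split_numpy(
        binned, t_idx, events, idx, feats, n_times,
        min_child_unique_deaths, min_child_size,
    )


def _best_logrank_split_numpy(
    binned: BinnedFeatures,
    t_idx: np.ndarray,
    events: np.ndarray,
    idx: np.ndarray,
    feats: np.ndarray,
    n_times: int,
    min_child_unique_deaths: int,
    min_child_size: int = 1,
) -> Optional[tuple[int, float, float]]:
    vmax = binned.vmax
    if vmax < 2:
        return None
    m = len(feats)
    n = len(idx)
    ti = t_idx[idx]
    ev = events[idx]
    d_t = np.bincount(ti[ev], minlength=n_times).astype(float)
    event_cols = d_t > 0
    if not event_cols.any():
        return None
    a_t = np.bincount(ti, minlength=n_times)
    n_at = a_t[::-1].cumsum()[::-1].astype(float)  # at risk at each time

    sub = binned.codes[np.ix_(idx, feats)]  # (n, m)
    offsets = (np.arange(m) * vmax)[None, :]
    code = (sub + offsets) * n_times + ti[:, None]
    size = m * vmax * n_times
    A = np.bincount(code.ravel(), minlength=size).reshape(m, vmax, n_times)
    D = np.bincount(code[ev].ravel(), minlength=size).reshape(m, vmax, n_times)

    D1 = D.cumsum(axis=1)[:, :-1, :]  # left-child tables per cut bin
    A1 = A.cumsum(axis=1)[:, :-1, :]
    n1_at = A1[:, :, ::-1].cumsum(axis=2)[:, :, ::-1].astype(float)

    dm = d_t[event_cols]
    nm = n_at[event_cols]
    d1 = D1[:, :, event_cols].astype(float)
    frac = n1_at[:, :, event_cols] / nm
    u = (d1 - dm * frac).sum(axis=2)  # (m, vmax-1)
    denom = np.where(nm > 1.0, nm - 1.0, 1.0)
    var = (dm * frac * (1.0 - frac) * (nm - dm) / denom * (nm > 1.0)).sum(axis=2)

    deaths_left = (D1 > 0).sum(axis=2)
    deaths_right = ((d_t[None, None, :] > D1)).sum(axis=2)
    n_left = A1.sum(axis=2)
    valid = (
        (var > 0.0)
        & (deaths_left > min_child_unique_deaths)
        & (deaths_right > min_child_unique_deaths)
        & (n_left >= min_child_size)
        & (n - n_left >= min_child_size)
    )
    if not valid.any():
        return None
    score = np.where(valid, np.abs(u) / np.sqrt(np.where(var > 0, var, 1.0)), -np.inf)
    flat = int(np.argmax(score))  # row-major: lowest feature, then lowest cut
    i, k = divmod(flat, vmax - 1)
    f = int(feats[i])
    thr = _threshold_for_cut(binned, A[i].sum(axis=1), f, k)
    return f, thr, float(score[i, k])


def best_rss_split(
    binned: BinnedFeatures,
    y: np.ndarray,
    idx: np.ndarray,
    feats: np.ndarray,
) -> Optional[tuple[int, float, float]]:
    """Best split by residual-sum-of-squares reduction over candidate features.

    Returns ``(feature, threshold, gain)`` with ``gain > 0``, or ``None``
    when no cut reduces the RSS (e.g. constant target or constant features).
    """
    vmax = binned.vmax
    if vmax < 2:
        return None
    m = len(feats)
    n = len(idx)
    ys = y[idx]
    s_tot = ys.sum()
    parent_fit = s_tot * s_tot / n

    sub = binned.codes[np.ix_(idx, feats)]
    offsets = (np.arange(m) * vmax)[None, :]
    code = (sub + offsets).ravel()
    size = m * vmax
    counts = np.bincount(code, minlength=size).reshape(m, vmax).astype(float)
    # code is row-major over (sample, feature), so each y repeats m times
    sums = np.bincount(
        code, weights=np.repeat(ys, m), minlength=size
    ).reshape(m, vmax)

    c1 = counts.cumsum(axis=1)[:, :-1]
    s1 = sums.cumsum(axis=1)[:, :-1]
    c2 = n - c1
    s2 = s_tot - s1
    valid = (c1 > 0) & (c2 > 0)
    safe_c1 = np.where(c1 > 0, c1, 1.0)
    safe_c2 = np.where(c2 > 0, c2, 1.0)
    gain = np.where(valid, s1 * s1 / safe_c1 + s2 * s2 / safe_c2 - parent_fit, -np.inf)
    flat = int(np.argmax(gain))
    i, k = divmod(flat, vmax - 1)
    if not np.isfinite(gain[i, k]) or gain[i, k] <= 1e-12:
        return None
    f = int(feats[i])
    thr = _threshold_for_cut(binned, counts[i], f, k)
    return f, thr, float(gain[i, k])
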