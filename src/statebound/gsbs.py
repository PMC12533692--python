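"""Greedy state boundary search (GSBS) and t-distance model selection.

A *neural state* is a temporarily stable multivariate activity pattern in a
local region; its transitions are state boundaries.  Given a time × channels
matrix, the greedy search iteratively adds boundaries (or a boundary pair
delimiting one full new state) wherever they most increase the fit criterion
— the mean, over timepoints, of the Pearson correlation between the
timepoint's channel pattern and the mean pattern of its state — optionally
adjusting each existing boundary by one sample after every iteration.

The number of states is selected with the *t-distance*: a two-sample t
statistic contrasting correlations of within-state timepoint pairs against
pairs spanning two consecutive states, maximized over the number of states k.
Because single-channel-montage recordings make k noisy per 30-s block, the
selection is stabilized across blocks: the t-distance curves are averaged to
pick a global k*, and each block then uses its curve's peak closest to k*.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "GreedyStateSegmentation",
    "timepoint_correlation_matrix",
    "greedy_segment",
    "tdistance",
    "tdistance_curve",
    "select_nstates_global",
    "select_nstates_block",
    "find_peaks",
]


def _standardize_rows(M: np.ndarray) -> np.ndarray:
    """Z-score each row across columns (population SD); zero-SD rows -> zeros."""
    mu = M.mean(axis=1, keepdims=True)
    sd = M.std(axis=1, keepdims=True)
    out = np.zeros_like(M, dtype=float)
    np.divide(M - mu, sd, out=out, where=sd > 0)
    return out


def timepoint_correlation_matrix(X: np.ndarray) -> np.ndarray:
    """T×T Pearson correlations between channel patterns at pairs of timepoints."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("X must be (n_timepoints, n_channels) with >= 2 channels")
    if (X.std(axis=1) == 0).any():
        t = int(np.flatnonzero(X.std(axis=1) == 0)[0])
        raise ValueError(f"zero-variance channel pattern at timepoint {t}")
    Z = _standardize_rows(X)
    C = (Z @ Z.T) / X.shape[1]
    np.fill_diagonal(C, 1.0)
    return np.clip(C, -1.0, 1.0)


class GreedyStateSegmentation(BaseEstimator):
    """Segment a time × channels matrix into contiguous neural states.

    Parameters
    ----------
    k_max : int or None
        Largest number of states on the greedy path.  ``None`` uses
        ``floor(T / 2)``, the recommended ceiling.
    finetune : {0, 1}
        If 1, after each iteration every boundary may shift by one sample
        when that improves the fit (one sweep per iteration).
    pair_search : {"two_stage", "exhaustive"}
        How the boundary pair delimiting a candidate new state is found.
        ``"two_stage"`` places the best single boundary, then the best
        completing boundary inside the state that was split; ``"exhaustive"``
        scans all ordered pairs (quadratic per state — small inputs only).
        A pair is kept only when it strictly beats the single boundary; ties
        anywhere resolve to the earliest candidate index.
    compute_tdistance : bool
        Compute the t-distance curve over the greedy path during :meth:`fit`.

    Attributes
    ----------
    path_ : dict[int, np.ndarray]
        Greedy path: number of states k -> sorted boundary indices (k−1 of
        them).  A boundary index is the first sample of a new state.
    fits_ : dict[int, float]
        Fit criterion at each k on the path.
    tdist_ : dict[int, float]
        t-distance at each k ≥ 2 on the path (``compute_tdistance=True``).
    n_states_ : int
        argmax of the t-distance curve (ties -> smallest k).
    boundaries_ : np.ndarray
        Boundaries of the selected segmentation.
    """

    def __init__(
        self,
        k_max: int | None = None,
        finetune: int = 1,
        pair_search: str = "two_stage",
        compute_tdistance: bool = True,
    ):
        self.k_max = k_max
        self.finetune = finetune
        self.pair_search = pair_search
        self.compute_tdistance = compute_tdistance

    # ------------------------------------------------------------- internals
    def _contrib(self, i: int, j: int) -> float:
        """Sum over t in [i, j) of corr(x_t, mean pattern of [i, j))."""
        m = (self._P[j] - self._P[i]) / (j - i)
        mu, sd = m.mean(), m.std()
        if sd == 0:
            return 0.0
        zm = (m - mu) / sd
        return float((self._ZP[j] - self._ZP[i]) @ zm) / self._C

    def _split_scores(self, s: int, e: int) -> tuple[np.ndarray, np.ndarray]:
        """Fit-sum gain of every single split of state [s, e); returns (b, gain)."""
        b = np.arange(s + 1, e)
        if b.size == 0:
            return b, np.empty(0)
        P, ZP, C = self._P, self._ZP, self._C
        base = self._seg_contrib[(s, e)]

        def seg(i0, j0):
            # i0/j0: arrays of segment starts/ends
            lens = (j0 - i0).astype(float)[:, None]
            m = (P[j0] - P[i0]) / lens
            zm = _standardize_rows(m)
            return np.einsum("ij,ij->i", ZP[j0] - ZP[i0], zm) / C

        left = seg(np.full(b.size, s), b)
        right = seg(b, np.full(b.size, e))
        return b, left + right - base

    def _fit_total(self, boundaries: Sequence[int]) -> float:
        edges = [0, *boundaries, self._T]
        return sum(self._contrib(i, j) for i, j in zip(edges, edges[1:])) / self._T

    def _refresh_contribs(self, boundaries: Sequence[int]) -> None:
        edges = [0, *boundaries, self._T]
        self._seg_contrib = {
            (i, j): self._contrib(i, j) for i, j in zip(edges, edges[1:])
        }

    def _finetune_sweep(self, boundaries: list[int]) -> list[int]:
        """One sweep: move each boundary ±1 sample if it improves the fit."""
        T = self._T
        for idx in range(len(boundaries)):
            b = boundaries[idx]
            lo = boundaries[idx - 1] if idx > 0 else 0
            hi = boundaries[idx + 1] if idx + 1 < len(boundaries) else T
            best_b, best_v = b, self._contrib(lo, b) + self._contrib(b, hi)
            for nb in (b - 1, b + 1):
                if lo < nb < hi:
                    v = self._contrib(lo, nb) + self._contrib(nb, hi)
                    if v > best_v + 1e-12:
                        best_b, best_v = nb, v
            boundaries[idx] = best_b
        return boundaries

    # ------------------------------------------------------------------ API
    def fit(self, X: np.ndarray, y=None) -> "GreedyStateSegmentation":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2D (n_timepoints, n_channels)")
        T, C = X.shape
        if T < 4:
            raise ValueError("need at least 4 timepoints")
        if C < 2:
            raise ValueError("need at least 2 channels")
        if self.finetune not in (0, 1):
            raise ValueError("finetune must be 0 or 1")
        if self.pair_search not in ("two_stage", "exhaustive"):
            raise ValueError("pair_search must be 'two_stage' or 'exhaustive'")
        k_max = self.k_max if self.k_max is not None else T // 2
        if k_max < 2:
            raise ValueError("k_max must be >= 2")
        k_max = min(k_max, T // 2)

        self._T, self._C = T, C
        self._P = np.vstack([np.zeros(C), np.cumsum(X, axis=0)])
        Z = _standardize_rows(X)
        if (X.std(axis=1) == 0).any():
            raise ValueError("zero-variance channel pattern; cannot correlate")
        self._ZP = np.vstack([np.zeros(C), np.cumsum(Z, axis=0)])

        boundaries: list[int] = []
        self._refresh_contribs(boundaries)
        path: dict[int, np.ndarray] = {1: np.array([], dtype=np.int64)}
        fits: dict[int, float] = {1: self._fit_total(boundaries)}

        while len(boundaries) + 1 < k_max:
            edges = [0, *boundaries, T]
            best = None  # (gain, b, (state_s, state_e))
            g_other = -np.inf  # best single gain outside the split state
            for s, e in zip(edges, edges[1:]):
                b, gain = self._split_scores(s, e)
                if b.size == 0:
                    continue
                i = int(np.argmax(gain))  # argmax returns earliest on ties
                if best is None or gain[i] > best[0] + 1e-12:
                    if best is not None:
                        g_other = max(g_other, best[0])
                    best = (float(gain[i]), int(b[i]), (s, e))
                else:
                    g_other = max(g_other, float(gain[i]))
            if best is None:
                break
            gain1, b1, (s, e) = best

            if self.pair_search == "exhaustive":
                new_bounds = self._exhaustive_step(boundaries)
            else:
                new_bounds = self._two_stage_step(boundaries, b1, s, e, g_other,
                                                  path, fits, k_max)
            boundaries = new_bounds
            if self.finetune:
                boundaries = self._finetune_sweep(boundaries)
            self._refresh_contribs(boundaries)
            k = len(boundaries) + 1
            path[k] = np.asarray(boundaries, dtype=np.int64)
            fits[k] = self._fit_total(boundaries)

        self.path_ = path
        self.fits_ = fits
        self.n_timepoints_ = T
        if self.compute_tdistance:
            corr = timepoint_correlation_matrix(X)
            self.tdist_ = tdistance_curve(corr, path)
            finite = {k: v for k, v in self.tdist_.items() if np.isfinite(v)}
            if finite:
                best_t = max(finite.values())
                self.n_states_ = min(k for k, v in finite.items()
                                     if v >= best_t - 1e-12)
            else:
                self.n_states_ = 1
            self.boundaries_ = path[self.n_states_]
        else:
            self.tdist_ = {}
            self.n_states_ = max(path)
            self.boundaries_ = path[self.n_states_]
        # release fit-time scratch
        del self._P, self._ZP, self._seg_contrib
        return self

    def _two_stage_step(self, boundaries, b1, s, e, g_other, path, fits, k_max):
        """Best single boundary, then (maybe) the completing pair boundary.

        The completing boundary — the best split of either child of the state
        just split — is only added when its gain beats the best single-
        boundary gain available in any *other* state (``g_other``): placing it
        then merely anticipates the next greedy step, so the iteration has
        effectively placed one full new state.  Without that guard the pair
        step would systematically admit noise-level boundaries.  The
        intermediate single-boundary segmentation is recorded so the greedy
        path has an entry at every k.
        """
        new = sorted([*boundaries, b1])
        k = len(new) + 1
        if k not in path:
            path[k] = np.asarray(new, dtype=np.int64)
            fits[k] = self._fit_total(new)
        if k >= k_max:
            return new
        # completing boundary = best single split of either child state
        self._refresh_contribs(new)
        best2 = None
        for cs, ce in ((s, b1), (b1, e)):
            b, gain = self._split_scores(cs, ce)
            if b.size == 0:
                continue
            i = int(np.argmax(gain))
            if best2 is None or gain[i] > best2[0] + 1e-12:
                best2 = (float(gain[i]), int(b[i]))
        if best2 is not None and best2[0] > 1e-12 and best2[0] > g_other + 1e-12:
            return sorted([*new, best2[1]])
        return new

    def _exhaustive_step(self, boundaries):
        """Scan all single boundaries and all pairs within one state; max fit.

        Quadratic per state; intended for small inputs and as the oracle for
        the two-stage search.  A pair wins only when its joint gain strictly
        beats two sequential single placements (the best single now plus the
        best single after it), so that more boundaries are never admitted for
        noise-level gains; ties between candidates go to the earliest indices.
        """
        edges = [0, *boundaries, self._T]
        best_single = None  # (gain, b)
        best_pair = None    # (gain, (p, q))
        for s, e in zip(edges, edges[1:]):
            b, gain = self._split_scores(s, e)
            if b.size == 0:
                continue
            i = int(np.argmax(gain))
            if best_single is None or gain[i] > best_single[0] + 1e-12:
                best_single = (float(gain[i]), int(b[i]))
            base = self._seg_contrib[(s, e)]
            for pi, p in enumerate(b):
                # segments [s,p),[p,q),[q,e): reuse split scores of [p, e)
                left = self._contrib(s, p)
                q = np.arange(p + 1, e)
                if q.size == 0:
                    continue
                lens = (q - p).astype(float)[:, None]
                m = (self._P[q] - self._P[p]) / lens
                zm = _standardize_rows(m)
                mid = np.einsum("ij,ij->i", self._ZP[q] - self._ZP[p], zm) / self._C
                m2 = (self._P[e] - self._P[q]) / (e - q).astype(float)[:, None]
                zm2 = _standardize_rows(m2)
                rgt = np.einsum("ij,ij->i", self._ZP[e] - self._ZP[q], zm2) / self._C
                g = left + mid + rgt - base
                j = int(np.argmax(g))
                if best_pair is None or g[j] > best_pair[0] + 1e-12:
                    best_pair = (float(g[j]), (int(p), int(q[j])))
        if best_pair is not None:
            # gain of the best single boundary after placing best_single
            with_single = sorted([*boundaries, best_single[1]])
            self._refresh_contribs(with_single)
            g_after = -np.inf
            edges2 = [0, *with_single, self._T]
            for s, e in zip(edges2, edges2[1:]):
                b, gain = self._split_scores(s, e)
                if b.size:
                    g_after = max(g_after, float(gain.max()))
            self._refresh_contribs(boundaries)
            if best_pair[0] > best_single[0] + max(g_after, 0.0) + 1e-12:
                return sorted([*boundaries, *best_pair[1]])
        return sorted([*boundaries, best_single[1]])

    def state_labels(self, k: int | None = None) -> np.ndarray:
        """Per-timepoint state index for the k-state segmentation on the path."""
        check_is_fitted(self, "path_")
        k = self.n_states_ if k is None else k
        if k not in self.path_:
            raise ValueError(f"k={k} not on the greedy path")
        labels = np.zeros(self.n_timepoints_, dtype=np.int64)
        for b in self.path_[k]:
            labels[b:] += 1
        return labels

    def predict(self, X=None) -> np.ndarray:
        """State labels of the fitted (selected) segmentation."""
        return self.state_labels()


def greedy_segment(
    X: np.ndarray,
    k_max: int | None = None,
    finetune: int = 1,
    pair_search: str = "two_stage",
) -> dict[int, np.ndarray]:
    """Greedy path of segmentations for k = 1..k_max (thin estimator wrapper)."""
    est = GreedyStateSegmentation(
        k_max=k_max, finetune=finetune, pair_search=pair_search,
        compute_tdistance=False,
    ).fit(X)
    return est.path_


# ----------------------------------------------------------------- t-distance
class _Sat:
    """Summed-area tables of a correlation matrix and its square."""

    def __init__(self, corr: np.ndarray):
        T = corr.shape[0]
        self.T = T
        self.S = np.zeros((T + 1, T + 1))
        self.S[1:, 1:] = corr.cumsum(axis=0).cumsum(axis=1)
        self.Q = np.zeros((T + 1, T + 1))
        self.Q[1:, 1:] = (corr**2).cumsum(axis=0).cumsum(axis=1)

    def block(self, A, i0, i1, j0, j1):
        return A[i1, j1] - A[i0, j1] - A[i1, j0] + A[i0, j0]


def _pool_moments(sat: _Sat, boundaries: np.ndarray):
    """(n, sum, sumsq) of the within-state and consecutive-between pools."""
    edges = np.concatenate(([0], np.asarray(boundaries, dtype=np.int64), [sat.T]))
    nw = sw = qw = 0.0
    nb = sb = qb = 0.0
    for a, b in zip(edges, edges[1:]):
        L = b - a
        if L >= 2:
            nw += L * (L - 1) / 2
            sw += (sat.block(sat.S, a, b, a, b) - L) / 2  # diagonal entries are 1
            qw += (sat.block(sat.Q, a, b, a, b) - L) / 2
    for (a, b), (b2, c) in zip(zip(edges, edges[1:]), zip(edges[1:], edges[2:])):
        nb += (b - a) * (c - b)
        sb += sat.block(sat.S, a, b, b, c)
        qb += sat.block(sat.Q, a, b, b, c)
    return (nw, sw, qw), (nb, sb, qb)


def _student_t(m1, v1, n1, m2, v2, n2) -> float:
    df = n1 + n2 - 2
    if df <= 0:
        return np.nan
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    if sp2 <= 0:
        if np.isclose(m1, m2):
            return 0.0
        return np.inf if m1 > m2 else -np.inf
    return float((m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2)))


def tdistance(
    boundaries: Sequence[int],
    corr_matrix: np.ndarray,
    _sat: _Sat | None = None,
) -> float:
    """Two-sample t contrasting within-state vs consecutive-between correlations.

    Pools the Pearson correlations of all timepoint pairs falling inside one
    state against all pairs spanning two *consecutive* states (pairs spanning
    non-adjacent states are excluded), and returns the pooled-variance Student
    t statistic.  NaN when either pool is empty or the test is undefined.
    """
    boundaries = np.asarray(boundaries, dtype=np.int64)
    if boundaries.size < 1:
        raise ValueError("t-distance needs at least 2 states")
    sat = _sat if _sat is not None else _Sat(np.asarray(corr_matrix, dtype=float))
    (nw, sw, qw), (nb, sb, qb) = _pool_moments(sat, boundaries)
    if nw < 1 or nb < 1:
        return np.nan
    mw, mb = sw / nw, sb / nb
    vw = (qw - nw * mw**2) / (nw - 1) if nw > 1 else 0.0
    vb = (qb - nb * mb**2) / (nb - 1) if nb > 1 else 0.0
    return _student_t(mw, max(vw, 0.0), nw, mb, max(vb, 0.0), nb)


def tdistance_curve(
    corr_matrix: np.ndarray, path: Mapping[int, np.ndarray]
) -> dict[int, float]:
    """t-distance at every k ≥ 2 on a greedy path (shared summed-area tables)."""
    sat = _Sat(np.asarray(corr_matrix, dtype=float))
    return {k: tdistance(b, corr_matrix, _sat=sat)
            for k, b in sorted(path.items()) if k >= 2}


# ------------------------------------------------------------ model selection
def select_nstates_global(curves: Sequence[Mapping[int, float]]) -> int:
    """argmax k of the across-block mean t-distance curve (ties -> smallest k).

    Curves are averaged on the union k grid; a k missing (or non-finite) in
    some curves is averaged over the curves that define it, with a warning.
    """
    if len(curves) < 1:
        raise ValueError("need at least one t-distance curve")
    ks = sorted({k for c in curves for k in c})
    if not ks:
        raise ValueError("empty t-distance curves")
    mean_curve = {}
    ragged = False
    for k in ks:
        vals = [c[k] for c in curves if k in c and np.isfinite(c[k])]
        if len(vals) != len(curves):
            ragged = True
        if vals:
            mean_curve[k] = float(np.mean(vals))
    if ragged:
        warnings.warn("t-distance curves do not share a full k grid; "
                      "missing values ignored", stacklevel=2)
    best = max(mean_curve.values())
    return min(k for k, v in mean_curve.items() if v >= best - 1e-12)


def find_peaks(curve: Mapping[int, float]) -> list[int]:
    """Peaks of a t-distance curve by the plateau-aware definition.

    A peak is any point, or a pair of adjacent points with the exact same
    value, whose neighbors on both sides are strictly lower.  A plateau pair
    is represented by its lower k.  Endpoints cannot be peaks.
    """
    ks = sorted(k for k, v in curve.items() if np.isfinite(curve[k]))
    vals = [curve[k] for k in ks]
    peaks = []
    i = 1
    while i < len(ks) - 1:
        if vals[i - 1] < vals[i] and vals[i] > vals[i + 1]:
            peaks.append(ks[i])
            i += 1
        elif (i + 2 <= len(ks) - 1 and vals[i - 1] < vals[i]
              and vals[i] == vals[i + 1] and vals[i + 1] > vals[i + 2]):
            peaks.append(ks[i])
            i += 2
        else:
            i += 1
    return peaks


def select_nstates_block(curve: Mapping[int, float], k_star: int) -> int:
    """The curve's peak closest to the global k*; per-block stabilization.

    Among all peaks the k minimizing ``|k − k_star|`` is returned
    (equidistant peaks -> the smaller k).  A curve with no peak (monotone)
    falls back to its own argmax, with a warning.
    """
    if len(curve) < 3:
        raise ValueError("curve needs at least 3 points")
    peaks = find_peaks(curve)
    if not peaks:
        warnings.warn("no peak in t-distance curve; falling back to argmax",
                      stacklevel=2)
        finite = {k: v for k, v in curve.items() if np.isfinite(v)}
        best = max(finite.values())
        return min(k for k, v in finite.items() if v >= best - 1e-12)
    dist = np.abs(np.asarray(peaks) - k_star)
    order = np.lexsort((peaks, dist))
    return int(peaks[order[0]])
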