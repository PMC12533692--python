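"""Gaussian match between boundary timelines, delay scans, and permutation nulls.

The *Gaussian match* quantifies how well the marks of a seed timeline align
with the marks of another timeline: each seed mark contributes the amplitude
of a unit-height Gaussian (SD 332 ms by default) evaluated at the distance to
the temporally closest mark in the other timeline, and the match is the mean
contribution over seed marks.  It is deliberately non-commutative — the seed
choice encodes which timeline's marks must be accounted for.

Because genuine neural responses lag the stimulus (and regions lag each
other), the match is scanned over a grid of delays in 1/64-s steps; the
*optimal delay* is the argmax.  Chance level is estimated by shuffling the
state durations of one timeline and re-measuring the max-over-delays match,
giving the *relative Gaussian match* ``(data − null) / (1 − null)`` which is
~0 at chance and 1 for perfect alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .timelines import BoundaryTimeline

__all__ = [
    "MatchConfig",
    "MatchCurve",
    "RelativeMatchResult",
    "gaussian_weight",
    "gaussian_match",
    "choose_seed",
    "delay_scan",
    "shuffle_states",
    "relative_match",
]

logger = logging.getLogger(__name__)


@dataclass
class MatchConfig:
    """Parameters of the Gaussian match and its delay/permutation machinery.

    sigma_s
        SD of the match Gaussian in seconds (0.332 s).  Chosen to balance
        counting genuinely co-occurring boundaries against inflating the
        chance-level match.
    rate_hz
        Grid rate; delays move in steps of ``1/rate_hz``.
    stimulus_delay_range_s / neural_delay_range_s
        Delay ranges scanned when comparing a stimulus timeline to a neural
        one (stimulus shifted forward only) and when comparing two neural
        timelines (either may lead).  Endpoints are truncated to the last
        whole grid step inside the range.
    n_perm
        Number of state-shuffle permutations for the null.
    pooling
        ``"pooled"`` averages match contributions over all seed marks across
        blocks; ``"per_block"`` averages block means.
    """

    sigma_s: float = 0.332
    rate_hz: float = 64.0
    stimulus_delay_range_s: tuple[float, float] = (0.0, 0.600)
    neural_delay_range_s: tuple[float, float] = (-0.600, 0.600)
    n_perm: int = 1000
    pooling: str = "pooled"

    def __post_init__(self) -> None:
        if self.sigma_s <= 0:
            raise ValueError("sigma_s must be positive")
        if not (self.stimulus_delay_range_s[0] <= 0 <= self.stimulus_delay_range_s[1]):
            raise ValueError("delay ranges must contain 0")
        if not (self.neural_delay_range_s[0] <= 0 <= self.neural_delay_range_s[1]):
            raise ValueError("delay ranges must contain 0")

    @property
    def sigma_samples(self) -> float:
        return self.sigma_s * self.rate_hz

    def delay_grid(self, mode: str) -> np.ndarray:
        """Integer-sample delay grid for ``mode``; 600 ms truncates to 38 samples."""
        if mode == "stimulus_vs_neural":
            lo, hi = self.stimulus_delay_range_s
        elif mode == "neural_vs_neural":
            lo, hi = self.neural_delay_range_s
        else:
            raise ValueError(f"unknown mode {mode!r}")
        lo_n = int(np.ceil(lo * self.rate_hz - 1e-9))
        hi_n = int(np.floor(hi * self.rate_hz + 1e-9))
        return np.arange(lo_n, hi_n + 1, dtype=np.int64)


@dataclass
class MatchCurve:
    """Gaussian match as a function of delay, with its argmax."""

    delays_samples: np.ndarray
    values: np.ndarray
    rate_hz: float

    @property
    def delays_s(self) -> np.ndarray:
        return self.delays_samples / self.rate_hz

    @property
    def optimal_delay(self) -> int:
        """Argmax delay in samples; ties resolve to smallest |delay|, then smallest."""
        v = self.values
        best = np.flatnonzero(v >= v.max() - 1e-15)
        cand = self.delays_samples[best]
        order = np.lexsort((cand, np.abs(cand)))
        return int(cand[order[0]])

    @property
    def optimal_delay_s(self) -> float:
        return self.optimal_delay / self.rate_hz

    @property
    def max_match(self) -> float:
        return float(self.values.max())


@dataclass
class RelativeMatchResult:
    """Max-over-delays match, its permutation null, and the chance-normalized match."""

    match_data: float
    match_null: float
    relative: float
    optimal_delay: int
    rate_hz: float
    perm_maxima: np.ndarray = field(repr=False)
    curve: MatchCurve | None = field(default=None, repr=False)

    @property
    def optimal_delay_s(self) -> float:
        return self.optimal_delay / self.rate_hz


def gaussian_weight(delta_s, sigma_s: float = 0.332):
    """Unit-amplitude Gaussian evaluated at temporal distance ``delta_s``."""
    if sigma_s <= 0:
        raise ValueError("sigma_s must be positive")
    delta_s = np.asarray(delta_s, dtype=float)
    out = np.exp(-(delta_s**2) / (2.0 * sigma_s**2))
    return float(out) if out.ndim == 0 else out


def _match_sums(
    seed: BoundaryTimeline,
    other: BoundaryTimeline,
    delays: np.ndarray,
    sigma_samples: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """Per-delay (sum of weights, count of contributing seed marks).

    The seed marks are shifted by each delay within their block; marks shifted
    past a block edge, and marks in blocks where ``other`` has no marks, drop
    out of the average.  Also returns per-block sums/counts for per-block
    pooling, and the number of seed marks skipped because their block had no
    marks in ``other``.
    """
    n_d = delays.size
    sums = np.zeros(n_d)
    counts = np.zeros(n_d, dtype=np.int64)
    block_sums, block_counts = [], []
    n_empty_other = 0
    for b, marks in seed.blocks.items():
        if marks.size == 0:
            continue
        o = other.blocks.get(b, np.empty(0, dtype=np.int64))
        if o.size == 0:
            n_empty_other += marks.size
            continue
        q = marks[:, None] + delays[None, :]  # (n_marks, n_delays)
        valid = (q >= 0) & (q < seed.block_samples)
        idx = np.searchsorted(o, q)
        left = o[np.clip(idx - 1, 0, o.size - 1)]
        right = o[np.clip(idx, 0, o.size - 1)]
        dist = np.minimum(np.abs(q - left), np.abs(right - q))
        w = np.exp(-(dist.astype(float) ** 2) / (2.0 * sigma_samples**2))
        w[~valid] = 0.0
        s = w.sum(axis=0)
        c = valid.sum(axis=0)
        sums += s
        counts += c
        block_sums.append(s)
        block_counts.append(c)
    return sums, counts, np.array(block_sums), np.array(block_counts), n_empty_other


def _mean_match(
    sums, counts, block_sums, block_counts, pooling: str
) -> np.ndarray:
    if pooling == "pooled":
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    if pooling == "per_block":
        with np.errstate(invalid="ignore", divide="ignore"):
            per = np.where(block_counts > 0, block_sums / np.maximum(block_counts, 1),
                           np.nan)
        return np.nanmean(per, axis=0)
    raise ValueError(f"unknown pooling {pooling!r}")


def gaussian_match(
    seed: BoundaryTimeline,
    other: BoundaryTimeline,
    cfg: MatchConfig | None = None,
) -> float:
    """Mean Gaussian weight of each seed mark's closest mark in ``other``.

    Closest-mark search never crosses block edges.  Seed marks in a block
    where ``other`` has no marks are excluded from the mean (their count is
    logged) rather than contributing an arbitrary near-zero weight.
    """
    cfg = cfg or MatchConfig(rate_hz=seed.rate_hz)
    if seed.n_marks == 0:
        raise ValueError("seed timeline has no marks")
    zero = np.zeros(1, dtype=np.int64)
    sums, counts, bs, bc, n_skip = _match_sums(seed, other, zero, cfg.sigma_samples)
    if n_skip:
        logger.info("gaussian_match: %d seed marks in blocks with empty other", n_skip)
    if counts.sum() == 0:
        raise ValueError("no seed mark has a counterpart block with marks")
    return float(_mean_match(sums, counts, bs, bc, cfg.pooling)[0])


def choose_seed(
    a: BoundaryTimeline, b: BoundaryTimeline, mode: str
) -> tuple[BoundaryTimeline, BoundaryTimeline]:
    """Select the seed timeline for a comparison.

    Stimulus mode seeds the stimulus-feature timeline (extra neural boundaries
    must not penalize the match); neural-vs-neural mode seeds the timeline
    with fewer marks (so a denser region cannot penalize it).  Ties keep the
    first argument as seed.
    """
    if a.n_marks == 0 or b.n_marks == 0:
        raise ValueError("both timelines must have at least one mark")
    if mode == "stimulus_vs_neural":
        if a.provenance == "stimulus_feature":
            return a, b
        if b.provenance == "stimulus_feature":
            return b, a
        return a, b
    if mode == "neural_vs_neural":
        return (b, a) if b.n_marks < a.n_marks else (a, b)
    raise ValueError(f"unknown mode {mode!r}")


def delay_scan(
    seed: BoundaryTimeline,
    other: BoundaryTimeline,
    cfg: MatchConfig | None = None,
    mode: str = "stimulus_vs_neural",
) -> MatchCurve:
    """Gaussian match over the delay grid; the seed is shifted by each delay.

    A positive delay moves the seed's marks later in time, so for a stimulus
    seed the optimal delay estimates how long after the stimulus feature the
    aligned neural boundaries occur.
    """
    cfg = cfg or MatchConfig(rate_hz=seed.rate_hz)
    if seed.n_marks == 0:
        raise ValueError("seed timeline has no marks")
    delays = cfg.delay_grid(mode)
    sums, counts, bs, bc, _ = _match_sums(seed, other, delays, cfg.sigma_samples)
    if not (counts > 0).any():
        raise ValueError("seed timeline empties out at every scanned delay")
    values = _mean_match(sums, counts, bs, bc, cfg.pooling)
    ok = np.isfinite(values)
    return MatchCurve(delays_samples=delays[ok], values=values[ok],
                      rate_hz=cfg.rate_hz)


def shuffle_states(
    t: BoundaryTimeline, rng: np.random.Generator
) -> BoundaryTimeline:
    """Randomly permute, per block, the durations of the states between marks.

    The inter-boundary durations (including the leading and trailing partial
    states) are permuted and boundaries rebuilt from their cumulative sums,
    preserving each block's mark count and duration multiset.  This is the
    null model for the relative Gaussian match: it keeps the rhythm statistics
    of the segmentation while destroying alignment.
    """
    blocks = {}
    for b, marks in t.blocks.items():
        if marks.size == 0:
            blocks[b] = marks.copy()
            continue
        edges = np.concatenate(([0], marks, [t.block_samples]))
        durations = np.diff(edges)
        rng.shuffle(durations)
        blocks[b] = np.cumsum(durations)[:-1]
    return BoundaryTimeline(
        rate_hz=t.rate_hz,
        block_samples=t.block_samples,
        blocks=blocks,
        provenance=t.provenance,
        n_offsets_only=None,
        meta=dict(t.meta, shuffled=True),
    )


def relative_match(
    seed: BoundaryTimeline,
    other: BoundaryTimeline,
    cfg: MatchConfig | None = None,
    mode: str = "stimulus_vs_neural",
    shuffle_target: str = "other",
    rng: np.random.Generator | int | None = None,
) -> RelativeMatchResult:
    """Chance-normalized maximum Gaussian match.

    ``match_data`` is the max over the delay grid on the real timelines.  For
    each of ``cfg.n_perm`` permutations the ``shuffle_target`` timeline
    (``"other"`` — the neural timeline when comparing against a stimulus seed,
    the non-seed region otherwise — or ``"seed"``) is state-shuffled and the
    max-over-delays match recomputed; ``match_null`` is the mean of these
    permutation maxima and ``relative = (data − null) / (1 − null)``.
    """
    cfg = cfg or MatchConfig(rate_hz=seed.rate_hz)
    if cfg.n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if shuffle_target not in ("seed", "other"):
        raise ValueError("shuffle_target must be 'seed' or 'other'")
    rng = np.random.default_rng(rng)

    curve = delay_scan(seed, other, cfg, mode)
    match_data = curve.max_match

    maxima = np.empty(cfg.n_perm)
    for p in range(cfg.n_perm):
        if shuffle_target == "other":
            s, o = seed, shuffle_states(other, rng)
        else:
            s, o = shuffle_states(seed, rng), other
        maxima[p] = delay_scan(s, o, cfg, mode).max_match
    match_null = float(maxima.mean())
    if match_null >= 1.0 - 1e-12:
        raise ValueError("degenerate permutation null: match_null = 1")
    relative = (match_data - match_null) / (1.0 - match_null)
    return RelativeMatchResult(
        match_data=match_data,
        match_null=match_null,
        relative=float(relative),
        optimal_delay=curve.optimal_delay,
        rate_hz=cfg.rate_hz,
        perm_maxima=maxima,
        curve=curve,
    )
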