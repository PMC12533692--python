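"""Ground-truthed synthetic cohorts for end-to-end pipeline testing.

The generator emulates the statistical structure the analyses assume: per
speech block and per region, multichannel recordings whose channel pattern is
piecewise-stable (a new i.i.d. Gaussian mean pattern per state, unit norm)
plus white noise; the high-level region shares a fraction of the low-level
region's boundaries at a planted signed lag; and a clause-like event table
whose on-/offsets precede the neural boundaries by planted per-region delays
with jitter, plus spurious and missing events.

Defaults are the study conditions: 64 Hz, 30-s blocks, 6 speech blocks,
noise SD 0.3 relative to unit-norm patterns, 70% shared boundaries, an inter
-region lag of −123 ms (high-level earlier), and a 150-ms stimulus→low-level
delay.  Recordings are emitted post-preprocessing (64 Hz, z-scored) by
default; raw mode emits 512 Hz data with line noise, drift and spikes to
exercise the cleaning chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .timelines import BlockSchedule, BoundaryTimeline, boundaries_to_timeline

__all__ = [
    "SyntheticSpec",
    "SyntheticGroundTruth",
    "SyntheticSubject",
    "generate_block",
    "generate_stimulus_events",
    "generate_subject",
    "generate_cohort",
    "generate_raw_subject",
    "truth_timeline",
]


@dataclass
class SyntheticSpec:
    """Planted parameters of a synthetic cohort.

    ``inter_roi_lag_s`` is the time of high-level boundaries relative to the
    shared low-level boundaries (negative = high-level earlier).  The
    stimulus events are placed ``stimulus_delay_s`` *before* the low-level
    boundaries they generate, so the implied high-level delay is
    ``stimulus_delay_s + inter_roi_lag_s``.
    """

    n_subjects: int = 10
    n_blocks: int = 6
    block_s: float = 30.0
    rate_hz: float = 64.0
    channels_per_roi: int = 12
    n_states_range: tuple[int, int] = (15, 40)
    min_state_samples: int = 8
    noise_sd: float = 0.3
    pattern_model: str = "gaussian"  # or "orthogonal" (needs n_states <= channels)
    shared_boundary_fraction: float = 0.7
    inter_roi_lag_s: float = -0.123
    stimulus_delay_s: float = 0.150
    event_fraction: float = 0.5
    stimulus_locked: bool = True  # False: events at random times (null cohorts)
    event_jitter_samples: float = 1.0
    extra_event_rate: float = 0.05
    drop_event_rate: float = 0.05
    ar_noise: float = 0.0
    # raw mode (512 Hz with artifacts, for the preprocessing chain)
    raw_rate_hz: float = 512.0
    line_amp: float = 1.0
    drift_amp: float = 4.0
    spike_rate: float = 2e-4
    spike_amp: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_state_samples < 2:
            raise ValueError("min state duration must be >= 2 samples")
        if abs(self.inter_roi_lag_s) > 0.600 or not 0 <= self.stimulus_delay_s <= 0.600:
            raise ValueError("lags and delays must be within ±600 ms")
        for r in (self.shared_boundary_fraction, self.event_fraction,
                  self.extra_event_rate, self.drop_event_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("fractions and rates must be in [0, 1]")

    @property
    def block_samples(self) -> int:
        return int(round(self.block_s * self.rate_hz))

    def to_manifest(self) -> dict:
        return asdict(self)

    @classmethod
    def from_manifest(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        d["n_states_range"] = tuple(d["n_states_range"])
        return cls(**d)


@dataclass
class SyntheticGroundTruth:
    """Planted boundaries, lag, delays and designated event marks."""

    boundaries: dict  # (block_index, roi) -> np.ndarray of boundary samples
    shared: dict      # block_index -> np.ndarray of shared low-level boundaries
    event_marks: dict  # block_index -> designated low-level boundary samples
    inter_roi_lag_s: float = 0.0
    stimulus_delay_s: float = 0.0
    seed: int | None = None


@dataclass
class SyntheticSubject:
    subject_id: str
    data: dict  # block_index -> {roi: (T, C) array}
    events: pd.DataFrame
    truth: SyntheticGroundTruth
    schedule: BlockSchedule
    spec: SyntheticSpec = field(repr=False)


def _draw_boundaries(n_states: int, T: int, min_dur: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Uniform composition of T into n_states parts of at least min_dur."""
    extra = T - n_states * min_dur
    if extra < 0:
        raise ValueError(
            f"cannot fit {n_states} states of >= {min_dur} samples in {T}")
    if n_states == 1:
        return np.empty(0, dtype=np.int64)
    bars = np.sort(rng.choice(extra + n_states - 1, size=n_states - 1,
                              replace=False))
    durations = np.diff(np.concatenate(([-1], bars, [extra + n_states - 1]))) - 1 \
        + min_dur
    return np.cumsum(durations)[:-1].astype(np.int64)


def _emit_states(boundaries: np.ndarray, T: int, C: int, noise_sd: float,
                 rng: np.random.Generator, ar: float = 0.0,
                 pattern_model: str = "gaussian") -> np.ndarray:
    """Piecewise-stable unit-norm patterns plus (optionally AR(1)) noise, z-scored.

    ``pattern_model="gaussian"`` draws an independent unit-norm Gaussian mean
    pattern per state (adjacent states may correlate by chance, as real
    regions do); ``"orthogonal"`` draws mutually orthonormal patterns —
    cleanly separated states for recovery benchmarks.
    """
    edges = np.concatenate(([0], boundaries, [T]))
    n_states = len(edges) - 1
    if pattern_model == "orthogonal":
        if n_states > C:
            raise ValueError("orthogonal patterns need n_states <= channels")
        Q, _ = np.linalg.qr(rng.standard_normal((C, n_states)))
        pats = Q.T
    elif pattern_model == "gaussian":
        pats = rng.standard_normal((n_states, C))
        pats /= np.linalg.norm(pats, axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown pattern_model {pattern_model!r}")
    X = np.empty((T, C))
    for i, (a, b) in enumerate(zip(edges, edges[1:])):
        X[a:b] = pats[i]
    noise = rng.standard_normal((T, C))
    if ar > 0:
        for t in range(1, T):
            noise[t] = ar * noise[t - 1] + np.sqrt(1 - ar**2) * noise[t]
    X = X + noise_sd * noise
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - X.mean(axis=0)) / sd


def generate_block(
    spec: SyntheticSpec, rng: np.random.Generator
) -> tuple[dict[str, np.ndarray], dict]:
    """One speech block for both regions plus its ground truth.

    Low-level boundaries are drawn first; the high-level region copies a
    shared fraction of them shifted by the planted lag (clipped to the
    block), and replaces the rest with independent boundaries.
    """
    T = spec.block_samples
    n_states = int(rng.integers(spec.n_states_range[0],
                                spec.n_states_range[1] + 1))
    low = _draw_boundaries(n_states, T, spec.min_state_samples, rng)

    lag = int(round(spec.inter_roi_lag_s * spec.rate_hz))
    n_shared = int(round(spec.shared_boundary_fraction * low.size))
    shared_idx = np.sort(rng.choice(low.size, size=n_shared, replace=False)) \
        if low.size else np.empty(0, dtype=int)
    shared = low[shared_idx]
    high_shared = np.clip(shared + lag, 1, T - 1)

    n_indep = low.size - n_shared
    taken = set(high_shared.tolist())
    indep = []
    while len(indep) < n_indep:
        c = int(rng.integers(1, T))
        if all(abs(c - t) >= spec.min_state_samples for t in taken):
            indep.append(c)
            taken.add(c)
    high = np.unique(np.concatenate([high_shared, np.array(indep, dtype=np.int64)])
                     ).astype(np.int64)

    data = {
        "low": _emit_states(low, T, spec.channels_per_roi, spec.noise_sd, rng,
                            spec.ar_noise, spec.pattern_model),
        "high": _emit_states(high, T, spec.channels_per_roi, spec.noise_sd, rng,
                             spec.ar_noise, spec.pattern_model),
    }
    truth = {"low": low, "high": high, "shared": shared}
    return data, truth


def generate_stimulus_events(
    truth: SyntheticGroundTruth,
    spec: SyntheticSpec,
    rng: np.random.Generator,
    schedule: BlockSchedule,
) -> tuple[pd.DataFrame, dict]:
    """Clause-like event table locked to a subset of the planted boundaries.

    A fraction of the *shared* low-level boundaries is designated as clause
    on-/offset marks, placed at ``boundary_time − stimulus_delay_s`` with
    Gaussian jitter; spurious marks are inserted and a fraction dropped.
    Consecutive marks within a block are paired into (onset, offset) events.
    Returns the event table and the designated marks per block.
    """
    speech = schedule.speech_blocks[: spec.n_blocks]
    rows = []
    designated: dict[int, np.ndarray] = {}
    delay = spec.stimulus_delay_s * spec.rate_hz
    for blk in speech:
        if spec.stimulus_locked:
            pool = truth.shared[blk.index]
        else:
            # null cohorts: mark count set by the region's boundary count,
            # but marks placed independently of the boundaries
            pool = truth.boundaries[(blk.index, "low")]
        n_ev = int(round(spec.event_fraction * pool.size))
        pick = np.sort(rng.choice(pool.size, size=n_ev, replace=False)) \
            if pool.size else np.empty(0, dtype=int)
        marks = pool[pick].astype(float)
        designated[blk.index] = pool[pick].copy()
        if not spec.stimulus_locked:
            marks = np.sort(rng.uniform(0, spec.block_samples, marks.size))
        stim = marks - delay
        if spec.event_jitter_samples > 0:
            stim = stim + rng.normal(0.0, spec.event_jitter_samples, stim.size)
        if spec.drop_event_rate > 0:
            stim = stim[rng.random(stim.size) >= spec.drop_event_rate]
        n_extra = rng.binomial(max(stim.size, 1), spec.extra_event_rate)
        if n_extra:
            stim = np.concatenate([stim, rng.uniform(0, spec.block_samples,
                                                     n_extra)])
        stim = np.unique(np.clip(np.round(stim), 0, spec.block_samples - 1))
        # pair consecutive marks into events; an odd trailing mark is dropped
        for on, off in zip(stim[0::2], stim[1::2]):
            if off > on:
                rows.append(("clause",
                             blk.start_s + on / spec.rate_hz,
                             blk.start_s + off / spec.rate_hz,
                             ""))
    events = pd.DataFrame(rows, columns=["feature", "onset_s", "offset_s",
                                         "label"])
    return events, designated


def generate_subject(
    spec: SyntheticSpec, rng: np.random.Generator, subject_id: str = "sub-00"
) -> SyntheticSubject:
    """One subject: per-block two-region recordings, events, and ground truth."""
    schedule = BlockSchedule.default()
    speech = schedule.speech_blocks[: spec.n_blocks]
    data, boundaries, shared = {}, {}, {}
    for blk in speech:
        d, tr = generate_block(spec, rng)
        data[blk.index] = d
        boundaries[(blk.index, "low")] = tr["low"]
        boundaries[(blk.index, "high")] = tr["high"]
        shared[blk.index] = tr["shared"]
    truth = SyntheticGroundTruth(
        boundaries=boundaries,
        shared=shared,
        event_marks={},
        inter_roi_lag_s=spec.inter_roi_lag_s,
        stimulus_delay_s=spec.stimulus_delay_s,
    )
    events, designated = generate_stimulus_events(truth, spec, rng, schedule)
    truth.event_marks = designated
    return SyntheticSubject(subject_id=subject_id, data=data, events=events,
                            truth=truth, schedule=schedule, spec=spec)


def generate_cohort(spec: SyntheticSpec) -> tuple[list[SyntheticSubject], dict]:
    """Independent subjects from one seed sequence, with a manifest."""
    if spec.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_subjects)
    subjects = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        sub = generate_subject(spec, rng, subject_id=f"sub-{i:02d}")
        sub.truth.seed = int(child.generate_state(1)[0] % (2**31))
        subjects.append(sub)
    manifest = {"spec": spec.to_manifest(),
                "subject_seeds": [s.truth.seed for s in subjects]}
    return subjects, manifest


def truth_timeline(sub: SyntheticSubject, roi: str) -> BoundaryTimeline:
    """Planted neural boundary timeline of one region."""
    blocks = {b: v for (b, r), v in sub.truth.boundaries.items() if r == roi}
    return boundaries_to_timeline(blocks, sub.spec.block_samples,
                                  sub.spec.rate_hz)


# --------------------------------------------------------------------- raw mode
def generate_raw_subject(
    spec: SyntheticSpec, rng: np.random.Generator, subject_id: str = "sub-00"
) -> tuple[np.ndarray, pd.DataFrame, SyntheticSubject]:
    """Raw-mode recording: 512 Hz, full schedule, with injected artifacts.

    The clean 64-Hz subject is generated first; its per-block state patterns
    are held piecewise-constant at the raw rate across the speech blocks
    (music blocks carry plain noise), then 50-Hz line noise, slow drift and
    random spikes are added.  Channels comprise both regions plus two
    non-ROI channels and one bad channel, with a matching channel table,
    so the recording exercises the full cleaning chain.
    """
    sub = generate_subject(spec, rng, subject_id)
    up = int(round(spec.raw_rate_hz / spec.rate_hz))
    n_raw = int(round(sub.schedule.duration_s * spec.raw_rate_hz))
    C_roi = spec.channels_per_roi
    rois = ["low"] * C_roi + ["high"] * C_roi + ["none"] * 3
    C = len(rois)
    X = 0.2 * rng.standard_normal((n_raw, C))

    for blk_idx, d in sub.data.items():
        blk = sub.schedule.blocks[blk_idx]
        i0 = int(round(blk.start_s * spec.raw_rate_hz))
        both = np.concatenate([d["low"], d["high"]], axis=1)  # (T64, 2*C_roi)
        X[i0:i0 + both.shape[0] * up, : 2 * C_roi] += np.repeat(both, up, axis=0)

    t = np.arange(n_raw) / spec.raw_rate_hz
    X += spec.line_amp * np.sin(2 * np.pi * 50.0 * t)[:, None] \
        * rng.uniform(0.5, 1.5, C)[None, :]
    X += spec.drift_amp * np.sin(2 * np.pi * 0.03 * t
                                 + rng.uniform(0, 2 * np.pi))[:, None]
    spikes = rng.random((n_raw, C)) < spec.spike_rate
    X[spikes] += spec.spike_amp * rng.choice([-1, 1], size=int(spikes.sum()))
    X[:, -1] = 100.0 * rng.standard_normal(n_raw)  # bad channel

    table = pd.DataFrame({
        "name": [f"ch{i:02d}" for i in range(C)],
        "brodmann": [41] * C_roi + [44] * C_roi + [0, 0, 0],
        "roi": rois,
        "status": ["good"] * (C - 1) + ["bad"],
    })
    return X, table, sub
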