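"""Subject- and group-level orchestration of the boundary-alignment analyses.

Per subject: greedy segmentation of every speech block with cross-block
stabilization of the number of states, neural boundary timelines per region,
chance-normalized Gaussian matches against stimulus features and between
regions, and optimal delays.  At the group level: nonparametric Wilcoxon
signed-rank tests (exact for small n), the delay contrast between regions,
and the matched-state-count control analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .gsbs import (
    GreedyStateSegmentation,
    select_nstates_block,
    select_nstates_global,
)
from .match import (
    MatchConfig,
    RelativeMatchResult,
    choose_seed,
    relative_match,
)
from .timelines import BoundaryTimeline, boundaries_to_timeline

__all__ = [
    "GroupTest",
    "SubjectSegmentation",
    "wilcoxon_signed_rank",
    "segment_blocks",
    "median_state_duration_s",
    "run_alignment_analysis",
    "run_inter_roi_analysis",
    "run_delay_contrast",
    "run_matched_nstates_control",
]

logger = logging.getLogger(__name__)


@dataclass
class GroupTest:
    """A Wilcoxon signed-rank group test with its per-subject values."""

    statistic: float
    p_value: float
    tail: str
    n: int
    values: np.ndarray = field(repr=False)


@dataclass
class SubjectSegmentation:
    """Stabilized per-block segmentations of one subject's region."""

    boundaries: dict  # block index -> boundary samples
    k_star: int
    k_per_block: dict
    tdist_curves: dict
    paths: dict  # block index -> greedy path (k -> boundaries)
    timeline: BoundaryTimeline

    @property
    def n_boundaries(self) -> int:
        return int(sum(len(b) for b in self.boundaries.values()))


def wilcoxon_signed_rank(
    values: Sequence[float], alternative: str = "greater"
) -> GroupTest:
    """Wilcoxon signed-rank test against a zero median.

    Zeros are dropped (standard signed-rank convention); the p-value is exact
    for n ≤ 25 without ties and the normal approximation otherwise.
    """
    if alternative not in ("greater", "two_sided"):
        raise ValueError("alternative must be 'greater' or 'two_sided'")
    vals = np.asarray(values, dtype=float)
    vals = vals[vals != 0]
    if vals.size == 0:
        raise ValueError("all values are zero; test undefined")
    if vals.size == 1:
        warnings.warn("single nonzero value; test is degenerate", stacklevel=2)
    alt = "greater" if alternative == "greater" else "two-sided"
    method = "exact" if vals.size <= 25 else "approx"
    res = sps.wilcoxon(vals, alternative=alt, method=method)
    return GroupTest(statistic=float(res.statistic), p_value=float(res.pvalue),
                     tail=alternative, n=int(vals.size), values=vals)


# ---------------------------------------------------------------- segmentation
def segment_blocks(
    blocks: Mapping[int, np.ndarray],
    k_max: int | None = None,
    finetune: int = 1,
    rate_hz: float = 64.0,
) -> SubjectSegmentation:
    """Greedy segmentation of each block with cross-block stabilization.

    Each block's t-distance curve is computed along its greedy path; the
    curves are averaged to choose a global number of states k*, and each
    block then adopts its own curve's peak closest to k*.
    """
    ests = {}
    for b, X in blocks.items():
        ests[b] = GreedyStateSegmentation(k_max=k_max, finetune=finetune).fit(X)
    curves = {b: e.tdist_ for b, e in ests.items()}
    k_star = select_nstates_global(list(curves.values()))
    k_per_block, boundaries = {}, {}
    for b, e in ests.items():
        k_b = select_nstates_block(curves[b], k_star)
        k_per_block[b] = k_b
        boundaries[b] = e.path_[k_b]
    T = next(iter(blocks.values())).shape[0]
    timeline = boundaries_to_timeline(boundaries, T, rate_hz)
    return SubjectSegmentation(
        boundaries=boundaries,
        k_star=k_star,
        k_per_block=k_per_block,
        tdist_curves=curves,
        paths={b: e.path_ for b, e in ests.items()},
        timeline=timeline,
    )


def median_state_duration_s(
    boundaries: Mapping[int, np.ndarray], block_samples: int,
    rate_hz: float = 64.0,
) -> float:
    """Median state duration pooled over all blocks, in seconds."""
    durs = []
    for b in boundaries.values():
        edges = np.concatenate(([0], np.asarray(b), [block_samples]))
        durs.append(np.diff(edges))
    return float(np.median(np.concatenate(durs))) / rate_hz


# ------------------------------------------------------------------- analyses
def run_alignment_analysis(
    neural_timelines: Mapping[str, BoundaryTimeline | None],
    stimulus: BoundaryTimeline | Mapping[str, BoundaryTimeline],
    cfg: MatchConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[GroupTest, dict[str, RelativeMatchResult]]:
    """Stimulus-alignment analysis over a cohort for one feature and region.

    Computes each subject's relative Gaussian match between the stimulus
    feature timeline (seed) and that subject's neural timeline, then a
    one-tailed Wilcoxon signed-rank test on the per-subject relative matches.
    ``stimulus`` is one shared timeline (all subjects saw the same movie) or
    a per-subject mapping (synthetic cohorts).  Subjects with no timeline for
    the region (``None``) are excluded and logged.
    """
    def stim_for(sid):
        return stimulus[sid] if isinstance(stimulus, Mapping) else stimulus

    cfg = cfg or MatchConfig(rate_hz=stim_for(next(iter(neural_timelines))).rate_hz)
    ss = np.random.SeedSequence(rng if isinstance(rng, int) else None)
    children = iter(ss.spawn(len(neural_timelines)))
    per_subject: dict[str, RelativeMatchResult] = {}
    excluded = []
    for sid, tl in neural_timelines.items():
        child = next(children)
        if tl is None or tl.n_marks == 0:
            excluded.append(sid)
            continue
        per_subject[sid] = relative_match(
            stim_for(sid), tl, cfg, mode="stimulus_vs_neural",
            shuffle_target="other", rng=np.random.default_rng(child))
    if excluded:
        logger.info("alignment analysis: excluded subjects %s", excluded)
    rel = [r.relative for r in per_subject.values()]
    group = wilcoxon_signed_rank(rel, alternative="greater")
    return group, per_subject


def run_inter_roi_analysis(
    low: BoundaryTimeline,
    high: BoundaryTimeline,
    cfg: MatchConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> RelativeMatchResult:
    """Between-region relative match with a signed optimal delay.

    The seed is the region with fewer boundaries; the reported optimal delay
    is re-signed to the fixed convention *high-level relative to low-level*:
    negative delay = high-level boundaries earlier (top-down).
    """
    cfg = cfg or MatchConfig(rate_hz=low.rate_hz)
    seed, other = choose_seed(low, high, mode="neural_vs_neural")
    res = relative_match(seed, other, cfg, mode="neural_vs_neural",
                         shuffle_target="other",
                         rng=np.random.default_rng(rng))
    if seed is high:
        res.optimal_delay = -res.optimal_delay
    return res


def run_delay_contrast(
    subjects: Mapping[str, Mapping[str, float]],
) -> tuple[GroupTest, list[str]]:
    """Two-tailed Wilcoxon on per-subject optimal-delay differences.

    ``subjects`` maps subject id to ``{"delay_low_s", "delay_high_s",
    "relative_low", "relative_high"}``.  Only subjects with an above-chance
    relative match (> 0) in *both* regions enter; the per-subject difference
    is ``delay_high − delay_low`` (negative = clause-locked boundaries occur
    earlier in the high-level region).
    """
    eligible = [sid for sid, d in subjects.items()
                if d["relative_low"] > 0 and d["relative_high"] > 0]
    if len(eligible) < 2:
        raise ValueError("fewer than 2 subjects with above-chance match in "
                         "both regions")
    diffs = [subjects[sid]["delay_high_s"] - subjects[sid]["delay_low_s"]
             for sid in eligible]
    logger.info("delay contrast: included subjects %s", eligible)
    group = wilcoxon_signed_rank(diffs, alternative="two_sided")
    return group, eligible


def run_matched_nstates_control(
    seg: SubjectSegmentation,
    target_count: int,
    stimulus: BoundaryTimeline,
    cfg: MatchConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> RelativeMatchResult:
    """Alignment re-run at a non-optimal, matched per-block boundary count.

    Instead of the t-distance-selected k, every block adopts the greedy-path
    solution with ``target_count`` boundaries per block (k = target_count+1;
    the nearest achievable count is used and logged if that k is not on a
    block's path).  Controls whether an alignment result depends on the
    segmentation granularity rather than on the boundary locations.
    """
    boundaries = {}
    for b, path in seg.paths.items():
        k_max = max(path)
        if target_count > k_max - 1:
            raise ValueError(
                f"target_count {target_count} exceeds k_max-1 = {k_max - 1} "
                f"for block {b}")
        want = target_count + 1
        if want not in path:
            avail = np.array(sorted(path))
            want = int(avail[np.argmin(np.abs(avail - want))])
            logger.info("block %s: nearest achievable k = %d", b, want)
        boundaries[b] = path[want]
    tl = boundaries_to_timeline(boundaries, stimulus.block_samples,
                                stimulus.rate_hz)
    cfg = cfg or MatchConfig(rate_hz=stimulus.rate_hz)
    return relative_match(stimulus, tl, cfg, mode="stimulus_vs_neural",
                          shuffle_target="other",
                          rng=np.random.default_rng(rng))
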