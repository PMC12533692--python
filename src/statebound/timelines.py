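"""Boundary timelines on the analysis sampling grid.

A *boundary timeline* is the common currency of all alignment analyses in this
package: a binary marking of a 64 Hz sampling grid, organized per 30-s speech
block, with 1s wherever something of interest begins or ends.  Two provenances
exist — ``stimulus_feature`` timelines built from annotated word/clause on- and
offsets, and ``neural`` timelines built from data-driven state segmentations.

Times are mapped to the grid by nearest-sample rounding (half-up).  Sample
indices are 0-based within each block; blocks are half-open ``[start, end)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Block",
    "BlockSchedule",
    "BoundaryTimeline",
    "make_events",
    "read_events_tsv",
    "build_feature_timeline",
    "shift_timeline",
    "boundaries_to_timeline",
    "count_events",
]

#: Columns of a normalized event table.
EVENT_COLUMNS = ("feature", "onset_s", "offset_s", "label")


@dataclass(frozen=True)
class Block:
    """One 30-s block of the movie stimulus."""

    index: int
    kind: Literal["music", "speech"]
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class BlockSchedule:
    """Ordered, contiguous schedule of alternating music/speech blocks.

    The movie stimulus used here consists of 13 interleaved 30-s blocks,
    starting with music (7 music, 6 speech); only speech blocks carry
    language annotations and are analyzed.
    """

    blocks: tuple[Block, ...]

    def __post_init__(self) -> None:
        prev_end = None
        for i, b in enumerate(self.blocks):
            if b.index != i:
                raise ValueError("block indices must be 0..n-1 in order")
            if b.end_s <= b.start_s:
                raise ValueError(f"block {i} has nonpositive duration")
            if prev_end is not None and not np.isclose(b.start_s, prev_end):
                raise ValueError(f"block {i} is not contiguous with block {i - 1}")
            prev_end = b.end_s

    @classmethod
    def default(cls, n_blocks: int = 13, block_s: float = 30.0) -> "BlockSchedule":
        """Alternating music/speech schedule, music first, equal block lengths."""
        kinds = ["music" if i % 2 == 0 else "speech" for i in range(n_blocks)]
        blocks = tuple(
            Block(i, k, i * block_s, (i + 1) * block_s) for i, k in enumerate(kinds)
        )
        return cls(blocks)

    @property
    def speech_blocks(self) -> tuple[Block, ...]:
        return tuple(b for b in self.blocks if b.kind == "speech")

    @property
    def duration_s(self) -> float:
        return self.blocks[-1].end_s

    def block_of(self, t_s: float) -> Block | None:
        """The block containing time ``t_s`` (half-open intervals), or None."""
        for b in self.blocks:
            if b.start_s <= t_s < b.end_s:
                return b
        return None


def _as_sorted_marks(marks: Iterable[int], n_samples: int) -> np.ndarray:
    arr = np.unique(np.asarray(list(marks), dtype=np.int64))
    if arr.size and (arr[0] < 0 or arr[-1] >= n_samples):
        raise ValueError("mark index outside block")
    return arr


@dataclass
class BoundaryTimeline:
    """Binary boundary marks on the sampling grid, one vector per speech block.

    Parameters
    ----------
    rate_hz : sampling rate of the grid (64 Hz in the published analyses).
    block_samples : number of samples per block (1920 for 30 s at 64 Hz).
    blocks : mapping of speech-block index to the sorted mark indices in that
        block.  Marks are stored sparsely; :meth:`to_dense` yields 0/1 vectors.
    provenance : ``"stimulus_feature"`` or ``"neural"``.
    n_offsets_only : for stimulus timelines, the number of marks that are an
        event offset without a coincident onset of the next event.
    """

    rate_hz: float
    block_samples: int
    blocks: dict[int, np.ndarray]
    provenance: Literal["stimulus_feature", "neural"] = "stimulus_feature"
    n_offsets_only: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.blocks = {
            int(k): _as_sorted_marks(v, self.block_samples)
            for k, v in self.blocks.items()
        }

    @property
    def n_marks(self) -> int:
        return int(sum(v.size for v in self.blocks.values()))

    @property
    def block_indices(self) -> list[int]:
        return sorted(self.blocks)

    def to_dense(self) -> dict[int, np.ndarray]:
        """Per-block 0/1 vectors of length ``block_samples``."""
        out = {}
        for k, marks in self.blocks.items():
            v = np.zeros(self.block_samples, dtype=np.int8)
            v[marks] = 1
            out[k] = v
        return out

    @classmethod
    def from_dense(
        cls, dense: Mapping[int, np.ndarray], rate_hz: float, **kw
    ) -> "BoundaryTimeline":
        blocks = {k: np.flatnonzero(np.asarray(v)) for k, v in dense.items()}
        n = len(next(iter(dense.values())))
        return cls(rate_hz=rate_hz, block_samples=n, blocks=blocks, **kw)

    # ------------------------------------------------------------------ io
    def to_frame(self) -> pd.DataFrame:
        rows = [
            (b, int(s), s / self.rate_hz)
            for b in self.block_indices
            for s in self.blocks[b]
        ]
        return pd.DataFrame(rows, columns=["block", "sample", "time_s"])

    def write_tsv(self, path: str | Path) -> None:
        """Write marks as TSV plus a JSON tally sidecar (``<path>.json``)."""
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        sidecar = {
            "rate_hz": self.rate_hz,
            "block_samples": self.block_samples,
            "provenance": self.provenance,
            "n_marks": self.n_marks,
            "n_offsets_only": self.n_offsets_only,
            "block_indices": self.block_indices,
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "BoundaryTimeline":
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        side = json.loads(Path(str(path) + ".json").read_text())
        blocks = {
            int(b): g["sample"].to_numpy(dtype=np.int64)
            for b, g in df.groupby("block")
        }
        for b in side.get("block_indices", []):  # markless blocks
            blocks.setdefault(int(b), np.empty(0, dtype=np.int64))
        return cls(
            rate_hz=side["rate_hz"],
            block_samples=side["block_samples"],
            blocks=blocks,
            provenance=side["provenance"],
            n_offsets_only=side["n_offsets_only"],
        )


# --------------------------------------------------------------------- events
def make_events(
    records: Sequence[tuple], feature: str | None = None
) -> pd.DataFrame:
    """Build a normalized event table from ``(feature, onset_s, offset_s[, label])``
    tuples (or ``(onset_s, offset_s)`` when ``feature`` is given)."""
    rows = []
    for r in records:
        if feature is not None and len(r) in (2, 3):
            r = (feature, *r)
        f, on, off, *rest = r
        rows.append((f, float(on), float(off), rest[0] if rest else ""))
    df = pd.DataFrame(rows, columns=list(EVENT_COLUMNS))
    return _validate_events(df)


def _validate_events(df: pd.DataFrame) -> pd.DataFrame:
    if (df["onset_s"] >= df["offset_s"]).any():
        bad = df[df["onset_s"] >= df["offset_s"]].index.tolist()
        raise ValueError(f"events with onset >= offset at rows {bad}")
    df = df.sort_values(["feature", "onset_s"], kind="stable").reset_index(drop=True)
    for feat, g in df.groupby("feature"):
        if (g["onset_s"].to_numpy()[1:] < g["offset_s"].to_numpy()[:-1] - 1e-9).any():
            raise ValueError(f"overlapping events within feature {feat!r}")
    return df


def read_events_tsv(path: str | Path, feature: str | None = None) -> pd.DataFrame:
    """Read a BIDS-style events TSV into a normalized event table.

    Accepts either an ``offset`` column or the BIDS ``duration`` convention;
    the feature column may be called ``feature`` or ``trial_type``.  If
    ``feature`` is given, rows are filtered to that feature.
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "onset" not in cols:
        raise ValueError("events TSV must have an 'onset' column")
    out = pd.DataFrame()
    out["onset_s"] = df[cols["onset"]].astype(float)
    if "offset" in cols:
        out["offset_s"] = df[cols["offset"]].astype(float)
    elif "duration" in cols:
        out["offset_s"] = out["onset_s"] + df[cols["duration"]].astype(float)
    else:
        raise ValueError("events TSV must have an 'offset' or 'duration' column")
    feat_col = cols.get("feature") or cols.get("trial_type")
    out["feature"] = df[feat_col].astype(str) if feat_col else "event"
    out["label"] = df[cols["label"]].astype(str) if "label" in cols else ""
    out = out[list(EVENT_COLUMNS)]
    if feature is not None:
        out = out[out["feature"] == feature].reset_index(drop=True)
    return _validate_events(out)


def _round_to_sample(t_rel_s: np.ndarray, rate_hz: float) -> np.ndarray:
    """Nearest-sample rounding, half-up."""
    return np.floor(np.asarray(t_rel_s) * rate_hz + 0.5).astype(np.int64)


def build_feature_timeline(
    events: pd.DataFrame,
    schedule: BlockSchedule,
    rate_hz: float = 64.0,
    on_outside: Literal["drop", "error"] = "drop",
) -> BoundaryTimeline:
    """Binary timeline with a 1 at every event onset and/or offset.

    Each onset and each offset is mapped to the nearest grid sample within its
    speech block; an offset landing on the same grid sample as the next
    event's onset yields a single 1.  Events outside every speech block are
    dropped with a warning (or raise, per ``on_outside``); events spanning a
    block edge are clipped to the block they start in, with a warning.
    Returns the timeline with tallies (total marks, offsets without a
    coincident onset) retained for :func:`count_events`.
    """
    events = _validate_events(events.copy())
    speech = schedule.speech_blocks
    block_samples = int(round(speech[0].duration_s * rate_hz))
    onset_marks: dict[int, set] = {b.index: set() for b in speech}
    offset_marks: dict[int, set] = {b.index: set() for b in speech}

    n_dropped = n_clipped = 0
    for _, ev in events.iterrows():
        blk = schedule.block_of(ev["onset_s"])
        if blk is None or blk.kind != "speech":
            n_dropped += 1
            continue
        onset, offset = ev["onset_s"], ev["offset_s"]
        if offset > blk.end_s:
            offset = blk.end_s
            n_clipped += 1
        s_on = int(_round_to_sample(onset - blk.start_s, rate_hz))
        s_off = int(_round_to_sample(offset - blk.start_s, rate_hz))
        s_on = min(s_on, block_samples - 1)
        s_off = min(s_off, block_samples - 1)
        onset_marks[blk.index].add(s_on)
        offset_marks[blk.index].add(s_off)

    if n_dropped:
        msg = f"{n_dropped} events outside speech blocks"
        if on_outside == "error":
            raise ValueError(msg)
        warnings.warn(msg + "; dropped", stacklevel=2)
    if n_clipped:
        warnings.warn(f"{n_clipped} events clipped to block edge", stacklevel=2)

    blocks = {
        b: np.array(sorted(onset_marks[b] | offset_marks[b]), dtype=np.int64)
        for b in onset_marks
    }
    n_offsets_only = sum(
        len(offset_marks[b] - onset_marks[b]) for b in offset_marks
    )
    return BoundaryTimeline(
        rate_hz=rate_hz,
        block_samples=block_samples,
        blocks=blocks,
        provenance="stimulus_feature",
        n_offsets_only=n_offsets_only,
    )


def shift_timeline(t: BoundaryTimeline, delay_samples: int) -> BoundaryTimeline:
    """Move every mark by ``delay_samples`` within its block.

    Marks shifted past a block edge are dropped rather than wrapped: blocks
    are separate stretches of the recording and wrapping would fabricate
    cross-block alignments.
    """
    if abs(delay_samples) > t.block_samples:
        raise ValueError("|delay_samples| exceeds block length")
    blocks = {}
    for b, marks in t.blocks.items():
        m = marks + int(delay_samples)
        blocks[b] = m[(m >= 0) & (m < t.block_samples)]
    return BoundaryTimeline(
        rate_hz=t.rate_hz,
        block_samples=t.block_samples,
        blocks=blocks,
        provenance=t.provenance,
        n_offsets_only=None,
        meta=dict(t.meta, shifted_by=int(delay_samples)),
    )


def boundaries_to_timeline(
    boundaries_per_block: Mapping[int, Sequence[int]],
    block_samples: int,
    rate_hz: float = 64.0,
) -> BoundaryTimeline:
    """Neural timeline with a 1 at each state-boundary sample.

    A boundary is the first sample of a new state; the block start is not a
    mark.  ``boundaries_per_block`` maps speech-block index to the boundary
    indices of that block's segmentation.
    """
    blocks = {int(b): np.asarray(v, dtype=np.int64) for b, v in
              boundaries_per_block.items()}
    return BoundaryTimeline(
        rate_hz=rate_hz,
        block_samples=block_samples,
        blocks=blocks,
        provenance="neural",
        n_offsets_only=None,
    )


def count_events(t: BoundaryTimeline) -> tuple[int, int]:
    """``(total marks, offsets-without-coincident-onset)`` of a stimulus timeline."""
    if t.provenance != "stimulus_feature" or t.n_offsets_only is None:
        raise ValueError(
            "offset tallies are only defined for stimulus-feature timelines "
            "built with tallies retained"
        )
    return t.n_marks, t.n_offsets_only
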