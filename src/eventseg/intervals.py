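"""Boundary / no-boundary interval construction.

Button presses mark perceived event boundaries.  The movie timeline is cut
into 2-s bins; bins holding a (pruned) response are Boundary Intervals (BI),
the rest are No-Boundary Intervals (NBI).  Per clip, NBI are sampled to match
the BI count, each NBI receives a virtual marker copying its partner's
within-bin offset, and every segment is realigned so the marker sits at the
center of a [-1 s, +1 s] window.  This module is pure timeline arithmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_MIN_GAP = 4.0  # seconds between kept responses
DEFAULT_BIN_WIDTH = 2.0
HALF_WINDOW = 1.0  # realigned windows span [marker-1, marker+1]


@dataclass(frozen=True)
class ClipSpec:
    """One movie clip: [start, end) in seconds of movie time."""

    clip_id: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"clip {self.clip_id}: end must exceed start")


def default_clips(boundaries=(0.0, 600.0, 1200.0, 1800.0)) -> list[ClipSpec]:
    """Three 10-minute clips by default."""
    return [
        ClipSpec(f"clip{i + 1}", boundaries[i], boundaries[i + 1])
        for i in range(len(boundaries) - 1)
    ]


def validate_clips(clips: list[ClipSpec]) -> None:
    for a, b in zip(clips, clips[1:]):
        if b.start < a.end:
            raise ValueError(f"clips {a.clip_id} and {b.clip_id} overlap or are unordered")


def prune_responses(times, min_gap: float = DEFAULT_MIN_GAP) -> np.ndarray:
    """Greedy left-to-right pruning: keep a response iff it is at least
    ``min_gap`` seconds after the last kept one.

    Prevents the 2-s analysis windows of neighboring responses from
    overlapping after realignment.
    """
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("response times must be sorted ascending")
    kept: list[float] = []
    for x in t:
        if not kept or x - kept[-1] >= min_gap:
            kept.append(float(x))
    return np.asarray(kept)


def classify_bins(
    responses, duration: float, width: float = DEFAULT_BIN_WIDTH
) -> np.ndarray:
    """Boolean BI label per bin; bin b covers [b*width, (b+1)*width).

    An edge response belongs to the later bin (half-open convention).
    """
    t = np.asarray(responses, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative response times")
    n_bins = int(np.ceil(duration / width - 1e-9))
    labels = np.zeros(n_bins, dtype=bool)
    bins = np.floor(t / width).astype(int)
    bins = bins[(bins >= 0) & (bins < n_bins)]
    labels[bins] = True
    return labels


def build_interval_pairs(
    responses, clips: list[ClipSpec], seed: int, width: float = DEFAULT_BIN_WIDTH
) -> pd.DataFrame:
    """Pair BI with count-matched, time-sorted NBI per clip.

    Returns a frame with columns kind, clip_id, pair_id, segment_start,
    marker_time; segment_start = marker_time - 1 (marker-centered window).

    Conventions (the construction is deterministic given the seed):

    * BI whose realigned window would cross a clip edge are dropped with a
      warning.
    * An NBI bin qualifies only if no response falls within 1 s of any point
      of the bin, so its window stays response-free for any copied marker
      offset, and only if its own window cannot cross the clip edge.
    * Per clip, NBI bins are sampled without replacement to the BI count,
      both lists are sorted by time, and the k-th members are paired; the
      NBI marker copies its partner's within-bin offset.
    """
    t = prune_responses(responses)  # idempotent on already-pruned input
    validate_clips(clips)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x4E42]))
    rows = []
    pair_id = 0
    for clip in clips:
        in_clip = t[(t >= clip.start) & (t < clip.end)]
        first_bin = int(np.ceil(clip.start / width - 1e-9))
        last_bin = int(np.floor(clip.end / width + 1e-9))  # exclusive
        # BI bins and markers; drop edge-crossing windows
        bi_bins, bi_markers = [], []
        for resp in in_clip:
            if resp - HALF_WINDOW < clip.start or resp + HALF_WINDOW > clip.end:
                logger.warning(
                    "clip %s: dropping boundary at %.2f s (window crosses clip edge)",
                    clip.clip_id, resp,
                )
                continue
            bi_bins.append(int(resp // width))
            bi_markers.append(resp)
        if not bi_bins:
            logger.warning("clip %s: no boundary intervals", clip.clip_id)
            continue
        bi_bin_set = set(bi_bins)
        # NBI candidates: response-free with 1-s guard, inside clip with margin
        candidates = []
        for b in range(first_bin, last_bin):
            if b in bi_bin_set:
                continue
            lo, hi = b * width, (b + 1) * width
            if lo - HALF_WINDOW < clip.start or hi + HALF_WINDOW > clip.end:
                continue
            if np.any((t > lo - HALF_WINDOW) & (t < hi + HALF_WINDOW)):
                continue
            candidates.append(b)
        if len(candidates) < len(bi_bins):
            raise ValueError(
                f"clip {clip.clip_id}: {len(bi_bins)} boundary intervals but only "
                f"{len(candidates)} eligible no-boundary bins"
            )
        nbi_bins = np.sort(rng.choice(candidates, size=len(bi_bins), replace=False))
        order = np.argsort(bi_markers)
        for k, (bi_idx, nbi_bin) in enumerate(zip(order, nbi_bins)):
            marker = bi_markers[bi_idx]
            offset = marker - bi_bins[bi_idx] * width
            virtual = nbi_bin * width + offset
            rows.append(("BI", clip.clip_id, pair_id + k, marker - HALF_WINDOW, marker))
            rows.append(("NBI", clip.clip_id, pair_id + k, virtual - HALF_WINDOW, virtual))
        pair_id += len(bi_bins)
    return pd.DataFrame(
        rows, columns=["kind", "clip_id", "pair_id", "segment_start", "marker_time"]
    )


def read_responses_tsv(path) -> pd.DataFrame:
    """Responses TSV with columns subject, clip, time."""
    df = pd.read_csv(path, sep="\t")
    missing = {"subject", "time"} - set(df.columns)
    if missing:
        raise ValueError(f"responses TSV missing columns: {sorted(missing)}")
    return df


def write_interval_set(intervals: pd.DataFrame, path) -> None:
    intervals.to_csv(path, sep="\t", index=False)
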