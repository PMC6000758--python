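"""Windowed GC skew, cumulative skew and replichore extrema.

GC skew is (G − C)/(G + C) per window (0 when a window has no G or C;
N bases are ignored entirely).  On circular bacterial chromosomes the
cumulative skew typically peaks near the replication terminus and dips
near the origin, so its argmax/argmin locate the replichore boundaries.
Windows wrap past the end of the sequence (circular topology);
positions are reported as 0-based window midpoints.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

_VALID = frozenset("ACGTN")


@dataclass(frozen=True)
class SkewProfile:
    window_size: int
    step: int
    sequence_length: int
    midpoints: np.ndarray          # 0-based window midpoints (bp)
    skew: np.ndarray               # per-window (G-C)/(G+C)
    cumulative: np.ndarray         # running sum of skew

    @property
    def max_cumulative_position(self) -> int:
        imax, _ = cumulative_extrema(self.skew)
        return int(self.midpoints[imax])

    @property
    def min_cumulative_position(self) -> int:
        _, imin = cumulative_extrema(self.skew)
        return int(self.midpoints[imin])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "midpoint": self.midpoints,
                "skew": self.skew,
                "cumulative": self.cumulative,
            }
        )


def default_window(sequence_length: int) -> int:
    """Auto window: 1/1000 of the sequence, at least 100 bp."""
    return max(100, sequence_length // 1000)


def windowed_skew(
    sequence: str,
    window_size: int | None = None,
    step: int | None = None,
) -> SkewProfile:
    """Per-window GC skew over a circular sequence.

    Windows start at 0, step, 2·step, … for ceil(L/step) windows and
    wrap around the end.  With step == window_size (the default) the
    windows tile the sequence exactly when L is a multiple.
    """
    seq = sequence.upper()
    L = len(seq)
    if L == 0:
        raise ValueError("empty sequence")
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"invalid bases: {''.join(sorted(bad))}")
    if window_size is None:
        window_size = default_window(L)
    if step is None:
        step = window_size
    if window_size < 1 or step < 1:
        raise ValueError("window_size and step must be >= 1")
    if window_size > L:
        raise ValueError("window_size exceeds sequence length")
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    doubled = np.concatenate([arr, arr])  # circular wrap
    g = np.concatenate([[0], np.cumsum(doubled == ord("G"))])
    c = np.concatenate([[0], np.cumsum(doubled == ord("C"))])
    n_windows = -(-L // step)  # ceil
    starts = np.arange(n_windows) * step
    ends = starts + window_size
    gs = g[ends] - g[starts]
    cs = c[ends] - c[starts]
    denom = gs + cs
    with np.errstate(invalid="ignore", divide="ignore"):
        skew = np.where(denom > 0, (gs - cs) / np.where(denom > 0, denom, 1), 0.0)
    midpoints = (starts + window_size // 2) % L
    return SkewProfile(
        window_size=window_size,
        step=step,
        sequence_length=L,
        midpoints=midpoints,
        skew=skew.astype(float),
        cumulative=np.cumsum(skew),
    )


def cumulative_extrema(skew: np.ndarray) -> tuple[int, int]:
    """(argmax, argmin) window indices of the running skew sum.

    Ties are broken toward the smallest index.
    """
    skew = np.asarray(skew, dtype=float)
    if skew.size == 0:
        raise ValueError("empty skew series")
    cum = np.cumsum(skew)
    return int(np.argmax(cum)), int(np.argmin(cum))


def write_skew_report(profile: SkewProfile, tsv_path: str | Path,
                      extrema_path: str | Path | None = None) -> None:
    """Skew TSV (midpoint, skew, cumulative; 0-based midpoints) + extrema JSON."""
    with open(tsv_path, "w") as fh:
        fh.write("# coordinates are 0-based window midpoints\n")
        profile.to_frame().to_csv(fh, sep="\t", index=False)
    if extrema_path is not None:
        Path(extrema_path).write_text(
            json.dumps(
                {
                    "window_size": profile.window_size,
                    "step": profile.step,
                    "max_cumulative_position": profile.max_cumulative_position,
                    "min_cumulative_position": profile.min_cumulative_position,
                },
                indent=1,
            )
        )
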