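"""IPD (interpulse duration) validation of non-B motif predictions.

High-likelihood motif hits (>= 2 asterisks) are expanded to fixed-size
windows centered on the hit midpoint; per-base IPD values are stacked
over all windows and averaged lengthwise into a meta-profile. An
elevated profile center relative to the flanks supports the sequence
predictions. Alignment and kinetics extraction are upstream of this
module: the IPD track is ingested per-base (bedGraph/TSV), with NaN for
positions lacking values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nonb_motifs import MotifHit
from .seqio import Interval

__all__ = [
    "IpdTrack",
    "MetaProfile",
    "centered_windows",
    "meta_profile",
    "center_fold_enrichment",
]


@dataclass
class IpdTrack:
    """Per-base IPD values for one contig; NaN marks missing positions."""

    contig_id: str
    values: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        finite = self.values[~np.isnan(self.values)]
        if finite.size and finite.min() < 0:
            raise ValueError("IPD values must be nonnegative where present")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class MetaProfile:
    """Lengthwise average of IPD values over motif-centered windows."""

    window_len: int
    mean_profile: np.ndarray
    n_windows_used: int
    n_windows_filtered: int

    def __post_init__(self) -> None:
        if len(self.mean_profile) != self.window_len:
            raise ValueError("profile length must equal window_len")


def centered_windows(
    hits: list[MotifHit],
    contig_length: int,
    window_len: int = 300,
    min_stars: int = 2,
) -> tuple[list[Interval], int]:
    """One *window_len* window per qualifying hit, centered on its midpoint.

    Hits below *min_stars* and minus-strand hits are excluded (the IPD
    track is positive-strand). Windows truncated by contig edges are
    dropped; the second return value counts the drops.
    """
    windows: list[Interval] = []
    n_dropped = 0
    half = window_len // 2
    for hit in hits:
        if hit.stars < min_stars or hit.interval.strand == "-":
            continue
        center = (hit.interval.start + hit.interval.end) // 2
        start = center - half
        end = start + window_len
        if start < 0 or end > contig_length:
            n_dropped += 1
            continue
        windows.append(Interval(hit.interval.contig_id, start, end, "+"))
    return windows, n_dropped


def meta_profile(
    track: IpdTrack, windows: list[Interval], window_len: int = 300
) -> MetaProfile:
    """Average IPD lengthwise over *windows*, skipping all-missing windows.

    Missing values are ignored position-wise in the remaining windows.
    Raises when every window is filtered out.
    """
    stacked = []
    n_filtered = 0
    for w in windows:
        if w.length != window_len:
            raise ValueError(f"window {w} is not {window_len} bp")
        vals = track.values[w.start : w.end]
        if np.all(np.isnan(vals)):
            n_filtered += 1
            continue
        stacked.append(vals)
    if not stacked:
        raise ValueError(
            f"all {len(windows)} windows contained no IPD values "
            f"({n_filtered} filtered)"
        )
    with np.errstate(invalid="ignore"):
        profile = np.nanmean(np.vstack(stacked), axis=0)
    return MetaProfile(window_len, profile, len(stacked), n_filtered)


def center_fold_enrichment(profile: MetaProfile, core: int = 50) -> float:
    """Mean over the central *core* positions / mean over the flanks."""
    if core >= profile.window_len:
        raise ValueError("core must be smaller than the window")
    n = profile.window_len
    lo = (n - core) // 2
    hi = lo + core
    center = profile.mean_profile[lo:hi]
    flanks = np.concatenate(
        (profile.mean_profile[:lo], profile.mean_profile[hi:])
    )
    flank_mean = float(np.nanmean(flanks))
    if flank_mean == 0 or np.isnan(flank_mean):
        raise ValueError("flank mean is zero or undefined")
    return float(np.nanmean(center)) / flank_mean
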