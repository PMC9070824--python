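"""Inverted-repeat (dyad symmetry) detection and the dyad-density statistic.

An inverted repeat is a left arm, an optional gap, and a right arm that
is the exact reverse complement of the left arm. Only *maximal*
occurrences are reported: extending both arms outward by one base would
break complementarity (or exceed ``max_stem``), and the gap cannot be
shrunk by growing the arms inward. N never pairs with anything.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import Contig

__all__ = [
    "DyadParams",
    "InvertedRepeat",
    "find_inverted_repeats",
    "dyad_coverage",
    "dyad_density",
]

# Watson-Crick pairs only; N pairs with nothing.
_PAIR = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


def _pairs(a: str, b: str) -> bool:
    return (a, b) in _PAIR


@dataclass(frozen=True)
class DyadParams:
    """Finder parameters (defaults follow the standard palindrome scan)."""

    min_stem: int = 5
    max_stem: int = 100
    gap_limit: int = 20
    allow_overlap: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.min_stem <= self.max_stem:
            raise ValueError("require 1 <= min_stem <= max_stem")
        if self.gap_limit < 0:
            raise ValueError("gap_limit must be >= 0")


@dataclass(frozen=True)
class InvertedRepeat:
    """One dyad symmetry occurrence: two arms around a gap."""

    contig_id: str
    left_start: int
    arm_len: int
    gap_len: int

    @property
    def right_start(self) -> int:
        return self.left_start + self.arm_len + self.gap_len

    @property
    def end(self) -> int:
        """Exclusive end of the right arm."""
        return self.right_start + self.arm_len

    @property
    def span(self) -> int:
        return self.end - self.left_start


def find_inverted_repeats(
    contig: Contig, params: DyadParams = DyadParams()
) -> list[InvertedRepeat]:
    """All maximal inverted repeats in *contig* under *params*.

    Scans every (gap start, gap length) center and extends arms outward
    as far as complementarity allows, capped at ``max_stem``. A center's
    occurrence is suppressed when its arms could instead grow inward
    (shrinking the gap by two), because the shrunken-gap center reports
    the longer-armed occurrence. Overlapping occurrences are kept when
    ``allow_overlap`` (default); otherwise a greedy longest-first
    non-overlapping subset is returned.
    """
    seq = contig.seq
    n = len(seq)
    out: list[InvertedRepeat] = []
    if n < 2 * params.min_stem:
        return out
    for gap in range(params.gap_limit + 1):
        # m = start of the gap; left arm ends at m, right arm starts at m+gap
        for m in range(1, n - gap):
            k = 0
            while (
                k < params.max_stem
                and m - 1 - k >= 0
                and m + gap + k < n
                and _pairs(seq[m - 1 - k], seq[m + gap + k])
            ):
                k += 1
            if k < params.min_stem:
                continue
            # inward-extension check: growing arms into the gap yields a
            # strictly longer occurrence found at center (m+1, gap-2)
            if (
                gap >= 2
                and k + 1 <= params.max_stem
                and _pairs(seq[m], seq[m + gap - 1])
            ):
                continue
            out.append(InvertedRepeat(contig.id, m - k, k, gap))
    out.sort(key=lambda ir: (ir.left_start, ir.end, ir.gap_len))
    if not params.allow_overlap:
        out = _greedy_nonoverlap(out)
    return out


def _greedy_nonoverlap(irs: list[InvertedRepeat]) -> list[InvertedRepeat]:
    chosen: list[InvertedRepeat] = []
    occupied: list[tuple[int, int]] = []
    for ir in sorted(irs, key=lambda r: (-r.arm_len, r.left_start)):
        if all(ir.end <= s or ir.left_start >= e for s, e in occupied):
            chosen.append(ir)
            occupied.append((ir.left_start, ir.end))
    chosen.sort(key=lambda r: (r.left_start, r.end))
    return chosen


def dyad_coverage(
    contig: Contig,
    irs: list[InvertedRepeat],
    count_mode: str = "binary",
) -> np.ndarray:
    """Per-base dyad arm coverage of *contig*.

    ``binary`` (default): 1 where the base lies inside an arm of at
    least one inverted repeat, 0 elsewhere — gap/loop bases count 0.
    ``multiplicity``: sum of covering arms instead of a 0/1 indicator.
    """
    if count_mode not in ("binary", "multiplicity"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    track = np.zeros(contig.length, dtype=np.int64)
    for ir in irs:
        if ir.contig_id != contig.id:
            raise ValueError(f"IR on {ir.contig_id!r} does not belong to {contig.id!r}")
        if ir.left_start < 0 or ir.end > contig.length:
            raise ValueError("inverted repeat out of contig bounds")
        track[ir.left_start : ir.left_start + ir.arm_len] += 1
        track[ir.right_start : ir.end] += 1
    if count_mode == "binary":
        track = (track > 0).astype(np.int64)
    return track


def dyad_density(track: np.ndarray) -> float:
    """Mean of a per-base coverage track; for binary tracks, in [0, 1]."""
    if len(track) == 0:
        raise ValueError("dyad_density of an empty track is undefined")
    return float(np.mean(track))
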