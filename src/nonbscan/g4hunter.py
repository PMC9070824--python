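"""G-quadruplex propensity scoring (G4Hunter-style), hit calling, density.

Per-base scores reward G-richness and penalise C-richness: every G in a
maximal G-run of length n scores +min(n, 4), every C in a C-run scores
-min(n, 4), and A/T/N score 0. Windowed means above a threshold in
absolute value call G4-prone regions; the sign gives the G-rich strand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import Contig, Interval

__all__ = [
    "G4Params",
    "G4Region",
    "g4_base_scores",
    "g4_window_scores",
    "call_g4_hits",
    "g4_density",
]


@dataclass(frozen=True)
class G4Params:
    window: int = 25
    threshold: float = 1.5

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")


@dataclass(frozen=True)
class G4Region:
    """A merged run of qualifying windows with its extreme window score."""

    interval: Interval
    score: float  # signed extreme window mean; + = G-rich strand


def g4_base_scores(seq: str) -> np.ndarray:
    """Run-length G/C scores per base: G-run of n -> +min(n,4), C-run -> -min(n,4)."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    n = len(seq)
    scores = np.zeros(n, dtype=np.float64)
    i = 0
    while i < n:
        c = seq[i]
        if c in "GC":
            j = i
            while j < n and seq[j] == c:
                j += 1
            val = float(min(j - i, 4))
            scores[i:j] = val if c == "G" else -val
            i = j
        else:
            i += 1
    return scores


def g4_window_scores(base_scores: np.ndarray, params: G4Params = G4Params()) -> np.ndarray:
    """Sliding-window mean, one value per window start (len - window + 1 values)."""
    n = len(base_scores)
    w = params.window
    if n < w:
        import warnings

        warnings.warn(f"sequence length {n} shorter than window {w}; no windows")
        return np.zeros(0, dtype=np.float64)
    cumsum = np.concatenate(([0.0], np.cumsum(base_scores)))
    return (cumsum[w:] - cumsum[:-w]) / w


def call_g4_hits(
    window_scores: np.ndarray,
    params: G4Params = G4Params(),
    contig_id: str = ".",
    signed: str = "both",
) -> list[G4Region]:
    """Merge qualifying windows (|mean| >= threshold) into maximal regions.

    Consecutive/overlapping qualifying windows of the same sign merge;
    each region covers the union of its windows and carries the extreme
    window score. *signed* restricts calls to ``"g"`` (positive),
    ``"c"`` (negative), or ``"both"`` (default).
    """
    if signed not in ("both", "g", "c"):
        raise ValueError(f"invalid signed mode {signed!r}")
    w = params.window
    qual = np.abs(window_scores) >= params.threshold
    if signed == "g":
        qual &= window_scores > 0
    elif signed == "c":
        qual &= window_scores < 0
    regions: list[G4Region] = []
    idx = np.flatnonzero(qual)
    if idx.size == 0:
        return regions
    run_start = idx[0]
    prev = idx[0]
    sign_of = lambda i: 1 if window_scores[i] > 0 else -1
    run_sign = sign_of(idx[0])

    def close(run_start: int, prev: int) -> None:
        span = slice(run_start, prev + 1)
        vals = window_scores[span]
        extreme = vals[np.argmax(np.abs(vals))]
        regions.append(
            G4Region(
                Interval(
                    contig_id,
                    int(run_start),
                    int(prev + w),
                    "+" if extreme > 0 else "-",
                ),
                float(extreme),
            )
        )

    for i in idx[1:]:
        # windows <w apart overlap; same-sign overlapping/adjacent windows merge
        if i - prev <= w and sign_of(i) == run_sign:
            prev = i
        else:
            close(run_start, prev)
            run_start = prev = i
            run_sign = sign_of(i)
    close(run_start, prev)
    return regions


def g4_density(hits: list[G4Region], contig: Contig) -> float:
    """Distinct bases inside hit regions divided by contig length."""
    if contig.length == 0:
        raise ValueError("empty contig")
    if not hits:
        return 0.0
    ivs = sorted((h.interval.start, h.interval.end) for h in hits)
    covered = 0
    cur_s, cur_e = ivs[0]
    for s, e in ivs[1:]:
        if s > cur_e:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    covered += cur_e - cur_s
    return covered / contig.length
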