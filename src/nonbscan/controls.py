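"""GC/length-matched random control segment sampling.

For a given centromere contig, draws n random genomic segments of the
same length from non-centromeric contigs, accepting only segments whose
GC content matches the centromere within a tolerance (relative by
default) and that respect a pairwise-overlap budget: at most
``max_overlapping_pairs`` accepted pairs may overlap, none by more than
``max_pairwise_overlap`` bp. Sampling is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .seqio import Contig, GenomeAssembly, Interval

__all__ = [
    "ControlConstraints",
    "ControlSet",
    "ControlSamplingError",
    "sample_controls",
    "control_metrics",
    "check_controls",
]


class ControlSamplingError(RuntimeError):
    """Raised when n acceptable segments cannot be found."""

    def __init__(self, message: str, found: int, attempts: int, rejections: dict):
        super().__init__(message)
        self.found = found
        self.attempts = attempts
        self.rejections = rejections


@dataclass(frozen=True)
class ControlConstraints:
    gc_tolerance: float = 0.10
    gc_mode: str = "relative"  # or "absolute" (percentage points)
    max_pairwise_overlap: int = 50_000
    max_overlapping_pairs: int = 2

    def __post_init__(self) -> None:
        if self.gc_mode not in ("relative", "absolute"):
            raise ValueError(f"invalid gc_mode {self.gc_mode!r}")
        if self.gc_tolerance < 0:
            raise ValueError("gc_tolerance must be >= 0")

    def gc_bounds(self, centromere_gc: float) -> tuple[float, float]:
        if self.gc_mode == "relative":
            delta = centromere_gc * self.gc_tolerance
        else:
            delta = self.gc_tolerance
        return centromere_gc - delta, centromere_gc + delta


@dataclass
class ControlSet:
    centromere_id: str
    segments: list[Interval]
    seed: int
    constraints: ControlConstraints
    attempts: int = 0
    gc_values: list[float] = field(default_factory=list)

    def manifest(self) -> dict:
        return {
            "centromere_id": self.centromere_id,
            "n": len(self.segments),
            "seed": self.seed,
            "constraints": asdict(self.constraints),
            "attempts": self.attempts,
            "acceptance_rate": len(self.segments) / self.attempts
            if self.attempts
            else 0.0,
            "segments": [
                [iv.contig_id, iv.start, iv.end] for iv in self.segments
            ],
            "gc_values": self.gc_values,
        }

    def write_manifest(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=2)
            fh.write("\n")


def _gc_prefix(contig: Contig) -> tuple[np.ndarray, np.ndarray]:
    arr = np.frombuffer(contig.seq.encode(), dtype=np.uint8)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    is_n = arr == ord("N")
    return (
        np.concatenate(([0], np.cumsum(is_gc))),
        np.concatenate(([0], np.cumsum(is_n))),
    )


def _overlap(a: Interval, b: Interval) -> int:
    if a.contig_id != b.contig_id:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def sample_controls(
    assembly: GenomeAssembly,
    centromere_id: str,
    n: int = 50,
    constraints: ControlConstraints = ControlConstraints(),
    seed: int = 0,
    max_attempts: int | None = None,
) -> ControlSet:
    """Seeded rejection sampling of *n* matched control segments.

    Candidate (contig, start) pairs are uniform over every position
    where a centromere-length segment fits inside a non-centromeric
    contig. Raises :class:`ControlSamplingError` with diagnostics when
    *n* cannot be reached within ``max_attempts`` (default 10,000 * n).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    centromere = assembly[centromere_id]
    seg_len = centromere.length
    target_gc = centromere.gc
    lo, hi = constraints.gc_bounds(target_gc)
    eligible = [
        c
        for c in assembly.background_contigs()
        if c.length >= seg_len
    ]
    if not eligible:
        raise ControlSamplingError(
            f"no non-centromeric contig is at least {seg_len} bp long",
            0,
            0,
            {"no_eligible_contig": 1},
        )
    prefixes = {c.id: _gc_prefix(c) for c in eligible}
    n_positions = np.array([c.length - seg_len + 1 for c in eligible])
    cum_positions = np.cumsum(n_positions)
    total_positions = int(cum_positions[-1])

    rng = np.random.default_rng(seed)
    if max_attempts is None:
        max_attempts = 10_000 * n
    accepted: list[Interval] = []
    gc_values: list[float] = []
    n_overlapping_pairs = 0
    rejections = {"gc": 0, "overlap_bp": 0, "overlap_pairs": 0}
    attempts = 0
    while len(accepted) < n and attempts < max_attempts:
        attempts += 1
        flat = int(rng.integers(total_positions))
        ci = int(np.searchsorted(cum_positions, flat, side="right"))
        start = flat - (int(cum_positions[ci - 1]) if ci else 0)
        contig = eligible[ci]
        end = start + seg_len
        gc_pre, n_pre = prefixes[contig.id]
        gc_count = int(gc_pre[end] - gc_pre[start])
        n_count = int(n_pre[end] - n_pre[start])
        denom = seg_len - n_count
        gc = gc_count / denom if denom else 0.0
        if not lo <= gc <= hi:
            rejections["gc"] += 1
            continue
        cand = Interval(contig.id, start, end, ".")
        overlaps = [_overlap(cand, seg) for seg in accepted]
        if any(ov > constraints.max_pairwise_overlap for ov in overlaps):
            rejections["overlap_bp"] += 1
            continue
        new_pairs = sum(1 for ov in overlaps if ov > 0)
        if n_overlapping_pairs + new_pairs > constraints.max_overlapping_pairs:
            rejections["overlap_pairs"] += 1
            continue
        n_overlapping_pairs += new_pairs
        accepted.append(cand)
        gc_values.append(gc)
    if len(accepted) < n:
        binding = max(rejections, key=rejections.get)
        raise ControlSamplingError(
            f"found only {len(accepted)}/{n} control segments for "
            f"{centromere_id!r} in {attempts} attempts "
            f"(binding constraint: {binding}, rejections: {rejections})",
            len(accepted),
            attempts,
            rejections,
        )
    return ControlSet(
        centromere_id, accepted, seed, constraints, attempts, gc_values
    )


def control_metrics(
    assembly: GenomeAssembly, control_set: ControlSet, metric_fn
) -> list[float]:
    """Apply *metric_fn* (Contig -> number) to each control segment, in order."""
    out = []
    for i, iv in enumerate(control_set.segments):
        seq = assembly.fetch(iv)
        segment = Contig(f"{iv.contig_id}:{iv.start}-{iv.end}", seq)
        try:
            out.append(float(metric_fn(segment)))
        except Exception as exc:
            raise RuntimeError(f"metric failed on control segment {i}: {exc}") from exc
    return out


def check_controls(assembly: GenomeAssembly, control_set: ControlSet) -> list[str]:
    """Re-verify every recorded constraint; returns violation messages."""
    from .seqio import gc_fraction

    problems: list[str] = []
    centromere = assembly[control_set.centromere_id]
    lo, hi = control_set.constraints.gc_bounds(centromere.gc)
    for i, iv in enumerate(control_set.segments):
        if iv.contig_id in assembly.centromere_ids:
            problems.append(f"segment {i} lies on centromere contig {iv.contig_id}")
        if iv.length != centromere.length:
            problems.append(
                f"segment {i} length {iv.length} != centromere {centromere.length}"
            )
        gc = gc_fraction(assembly.fetch(iv))
        if not lo <= gc <= hi:
            problems.append(f"segment {i} GC {gc:.4f} outside [{lo:.4f}, {hi:.4f}]")
    n_pairs = 0
    segs = control_set.segments
    for i in range(len(segs)):
        for j in range(i + 1, len(segs)):
            ov = _overlap(segs[i], segs[j])
            if ov > 0:
                n_pairs += 1
            if ov > control_set.constraints.max_pairwise_overlap:
                problems.append(f"segments {i},{j} overlap by {ov} bp")
    if n_pairs > control_set.constraints.max_overlapping_pairs:
        problems.append(f"{n_pairs} overlapping pairs exceed the allowed maximum")
    return problems
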