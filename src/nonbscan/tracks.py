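"""Per-base track plumbing.

Windowed scan plans and max-reassembly for externally computed
probability tables (SIST-style), element-wise track combination,
cumulative star profiles, interval means, and bedGraph/TSV round trips.

The stress-induced transition engine itself is an external tool; this
module only defines the windowing contract used to drive it and the
ingestion format for its per-base melt / cruciform / Z-DNA
probabilities at a given temperature.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .seqio import Interval

__all__ = [
    "SIST_TEMPERATURES",
    "SIST_STRUCTURES",
    "BaseTrack",
    "SistTable",
    "window_plan",
    "reassemble_max",
    "combine_max",
    "cumulative_star_profile",
    "track_mean",
    "write_bedgraph",
    "read_bedgraph",
    "read_sist_table",
    "write_sist_table",
]

SIST_TEMPERATURES = (18, 22, 25, 30, 35)
SIST_STRUCTURES = ("melt", "cruciform", "zdna")

TRACK_KINDS = ("stars", "probability", "score", "ipd")


@dataclass
class BaseTrack:
    """A per-base numeric vector over a contig."""

    contig_id: str
    values: np.ndarray
    kind: str = "score"

    def __post_init__(self) -> None:
        if self.kind not in TRACK_KINDS:
            raise ValueError(f"unknown track kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.kind == "probability" and (
            np.nanmin(self.values, initial=0.0) < 0
            or np.nanmax(self.values, initial=0.0) > 1
        ):
            raise ValueError("probability track out of [0, 1]")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class SistTable:
    """Per-base structure-transition probabilities at one temperature."""

    contig_id: str
    temperature: int
    melt: np.ndarray
    cruciform: np.ndarray
    zdna: np.ndarray

    def __post_init__(self) -> None:
        if self.temperature not in SIST_TEMPERATURES:
            raise ValueError(
                f"temperature {self.temperature} not in {SIST_TEMPERATURES}"
            )
        for name in SIST_STRUCTURES:
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if arr.min(initial=0.0) < 0 or arr.max(initial=0.0) > 1:
                raise ValueError(f"{name} probabilities out of [0, 1]")
            setattr(self, name, arr)
        if not (len(self.melt) == len(self.cruciform) == len(self.zdna)):
            raise ValueError("structure tracks have mismatched lengths")

    def __len__(self) -> int:
        return len(self.melt)

    def track(self, structure: str) -> np.ndarray:
        if structure not in SIST_STRUCTURES:
            raise ValueError(f"unknown structure {structure!r}")
        return getattr(self, structure)


def window_plan(
    contig_length: int,
    window: int = 5000,
    step: int = 2500,
    long_threshold: int = 10_000,
) -> list[tuple[int, int]]:
    """Sliding-window plan: *window*-bp windows every *step* bp.

    Applied only to sequences longer than *long_threshold*; shorter
    sequences get a single whole-sequence window. The final window is
    truncated at the contig end and every base is covered at least once.
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be positive")
    if step > window:
        raise ValueError("step must not exceed window (bases would be skipped)")
    if contig_length <= 0:
        raise ValueError("contig_length must be positive")
    if contig_length <= long_threshold:
        return [(0, contig_length)]
    plan = []
    start = 0
    while True:
        end = min(start + window, contig_length)
        plan.append((start, end))
        if end >= contig_length:
            break
        start += step
    return plan


def reassemble_max(
    window_tracks: list[np.ndarray], plan: list[tuple[int, int]]
) -> np.ndarray:
    """Per-base maximum over all windows covering each base."""
    if len(window_tracks) != len(plan):
        raise ValueError("one value vector required per planned window")
    length = max(e for _, e in plan)
    out = np.full(length, -np.inf)
    for vec, (s, e) in zip(window_tracks, plan):
        vec = np.asarray(vec, dtype=np.float64)
        if len(vec) != e - s:
            raise ValueError(
                f"vector length {len(vec)} does not match window [{s}, {e})"
            )
        np.maximum(out[s:e], vec, out=out[s:e])
    if np.isneginf(out).any():
        raise ValueError("window plan does not cover every base")
    return out


def combine_max(tracks: list[np.ndarray]) -> np.ndarray:
    """Element-wise maximum of same-length tracks."""
    if not tracks:
        raise ValueError("no tracks")
    length = len(tracks[0])
    if any(len(t) != length for t in tracks):
        raise ValueError("tracks have mismatched lengths")
    out = np.asarray(tracks[0], dtype=np.float64).copy()
    for t in tracks[1:]:
        np.maximum(out, t, out=out)
    return out


def cumulative_star_profile(per_class_tracks: dict[str, np.ndarray]) -> np.ndarray:
    """Per-base sum of asterisk tracks across the seven motif classes."""
    from .nonb_motifs import combine_likelihoods

    return combine_likelihoods(per_class_tracks)


def track_mean(track: np.ndarray, interval: Interval | tuple[int, int] | None = None) -> float:
    """Arithmetic mean over *interval* (whole track when absent)."""
    if interval is not None:
        if isinstance(interval, Interval):
            s, e = interval.start, interval.end
        else:
            s, e = interval
        if not 0 <= s < e <= len(track):
            raise ValueError(f"interval [{s}, {e}) outside track of length {len(track)}")
        track = track[s:e]
    if len(track) == 0:
        raise ValueError("mean of empty interval")
    return float(np.mean(track))


def write_bedgraph(track: BaseTrack, path: str | Path) -> None:
    """bedGraph with adjacent equal values run-length merged; NaN omitted."""
    vals = track.values
    with open(path, "w") as fh:
        i, n = 0, len(vals)
        while i < n:
            if np.isnan(vals[i]):
                i += 1
                continue
            j = i
            while j < n and not np.isnan(vals[j]) and vals[j] == vals[i]:
                j += 1
            fh.write(f"{track.contig_id}\t{i}\t{j}\t{vals[i]:g}\n")
            i = j


def read_bedgraph(
    path: str | Path, contig_lengths: dict[str, int], kind: str = "score"
) -> dict[str, BaseTrack]:
    """Read a bedGraph into per-contig tracks; uncovered positions are NaN."""
    tracks = {
        cid: np.full(length, np.nan) for cid, length in contig_lengths.items()
    }
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cid, s, e, v = line.split("\t")[:4]
            if cid not in tracks:
                raise KeyError(f"unknown contig {cid!r} in {path}")
            tracks[cid][int(s) : int(e)] = float(v)
    return {cid: BaseTrack(cid, vals, kind) for cid, vals in tracks.items()}


# permissive column aliasing: SIST output dialects vary by version
_SIST_ALIASES = {
    "melt": ("melt", "p_melt", "melting", "melted"),
    "cruciform": ("cruciform", "p_cruciform", "cruc"),
    "zdna": ("zdna", "p_zdna", "z-dna", "z_dna"),
}


def read_sist_table(
    path: str | Path,
    contig_id: str | None = None,
    temperature: int | None = None,
    column_map: dict[str, str] | None = None,
) -> SistTable:
    """Read a SIST-style TSV (position, melt, cruciform, zdna).

    Metadata may come from ``# contig=...`` / ``# temperature=...``
    header comments or from the keyword arguments. Positions must be
    contiguous and 1-based or 0-based starting at the first row.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for part in line[1:].strip().split():
                if "=" in part:
                    k, v = part.split("=", 1)
                    meta[k] = v
    contig_id = contig_id or meta.get("contig")
    temperature = temperature if temperature is not None else int(meta.get("temperature", -1))
    if contig_id is None:
        raise ValueError(f"no contig id in {path} header or arguments")
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    cols = {}
    for canon, aliases in _SIST_ALIASES.items():
        mapped = (column_map or {}).get(canon)
        found = mapped if mapped in df.columns else next(
            (a for a in aliases if a in df.columns), None
        )
        if found is None:
            raise ValueError(f"no column for {canon!r} in {path} ({list(df.columns)})")
        cols[canon] = found
    pos_col = next((c for c in ("position", "pos", "base") if c in df.columns), None)
    if pos_col is not None:
        pos = df[pos_col].to_numpy()
        if len(pos) > 1 and not np.all(np.diff(pos) == 1):
            raise ValueError(f"positions not contiguous in {path}")
    return SistTable(
        contig_id,
        temperature,
        df[cols["melt"]].to_numpy(float),
        df[cols["cruciform"]].to_numpy(float),
        df[cols["zdna"]].to_numpy(float),
    )


def write_sist_table(table: SistTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# contig={table.contig_id} temperature={table.temperature}\n")
        fh.write("position\tp_melt\tp_cruciform\tp_zdna\n")
        for i in range(len(table)):
            fh.write(
                f"{i}\t{table.melt[i]:.6g}\t{table.cruciform[i]:.6g}"
                f"\t{table.zdna[i]:.6g}\n"
            )
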