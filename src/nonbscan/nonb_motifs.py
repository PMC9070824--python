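"""Seven-class non-B DNA motif prediction with asterisk likelihoods.

Each class is predicted by a sequence rule on both strands; minus-strand
hits are reported in plus coordinates with strand ``-``. Likelihood is a
1-3 "asterisk" integer per hit (default 2). Within a class, overlapping
hits contribute the maximum stars per base; across classes, per-base
stars are summed.

Classes
-------
APR
    A-phased repeats: >=3 A-tracts (3-9 bp) with tract centers 10-11 bp
    apart (helical phasing).
G4
    G-quadruplex: >=4 runs of >=3 G separated by 1-7 nt loops.
HDNA
    H-DNA (triplex): mirror repeat, arms >=10 bp, spacer <=8 bp, >=90%
    homopurine or homopyrimidine overall.
SLIPPED
    Slipped DNA: exact direct repeat, unit >=10 bp, spacer <=10 bp.
STR
    Short tandem repeat: unit 1-9 bp, >=5 full copies, tract >=15 bp.
TFO
    Triplex-forming oligo target: homopurine tract >=15 bp, >=50% G.
ZDNA
    Z-DNA: >=12 bp of alternating purine-pyrimidine dinucleotides from
    {GC, CG, GT, TG, AC, CA}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import Contig, Interval, revcomp

__all__ = [
    "MOTIF_CLASSES",
    "DEFAULT_STARS",
    "MotifHit",
    "MotifRuleSet",
    "predict_motifs",
    "predict_all",
    "stars_track",
    "combine_likelihoods",
    "class_totals",
]

MOTIF_CLASSES = ("APR", "G4", "HDNA", "SLIPPED", "STR", "TFO", "ZDNA")
DEFAULT_STARS = 2

# classes whose rule is invariant under reverse complement; scanning the
# minus strand would duplicate every plus-strand hit
_STRAND_SYMMETRIC = frozenset({"ZDNA", "STR", "SLIPPED", "HDNA"})

_Z_DINUCS = frozenset({"GC", "CG", "GT", "TG", "AC", "CA"})


@dataclass(frozen=True)
class MotifHit:
    """One predicted non-B motif occurrence."""

    interval: Interval
    motif_class: str
    stars: int = DEFAULT_STARS
    detail: str = ""

    def __post_init__(self) -> None:
        if self.motif_class not in MOTIF_CLASSES:
            raise ValueError(f"unknown motif class {self.motif_class!r}")
        if self.stars not in (1, 2, 3):
            raise ValueError(f"stars must be 1-3, got {self.stars}")


@dataclass(frozen=True)
class MotifRuleSet:
    """Per-class scanning parameters; every class present exactly once."""

    # G4
    g4_min_run: int = 3
    g4_min_runs: int = 4
    g4_loop_min: int = 1
    g4_loop_max: int = 7
    # ZDNA
    zdna_min_dinucs: int = 6
    # STR
    str_unit_min: int = 1
    str_unit_max: int = 9
    str_min_copies: int = 5
    str_min_tract: int = 15
    str_strong_copies: int = 10
    # SLIPPED
    slipped_unit_min: int = 10
    slipped_unit_max: int = 100
    slipped_spacer_max: int = 10
    slipped_strong_unit: int = 20
    # HDNA
    hdna_arm_min: int = 10
    hdna_arm_max: int = 100
    hdna_spacer_max: int = 8
    hdna_purity: float = 0.9
    # TFO
    tfo_min_len: int = 15
    tfo_min_g_frac: float = 0.5
    tfo_strong_len: int = 25
    # APR
    apr_tract_min: int = 3
    apr_tract_max: int = 9
    apr_min_tracts: int = 3
    apr_center_min: float = 10.0
    apr_center_max: float = 11.0
    apr_strong_tracts: int = 4

    def __post_init__(self) -> None:
        if self.g4_min_run < 1 or self.g4_min_runs < 2:
            raise ValueError("invalid G4 rule parameters")
        if not 1 <= self.g4_loop_min <= self.g4_loop_max:
            raise ValueError("invalid G4 loop bounds")
        if not 1 <= self.str_unit_min <= self.str_unit_max:
            raise ValueError("invalid STR unit bounds")
        if self.slipped_unit_min < 1 or self.slipped_spacer_max < 0:
            raise ValueError("invalid SLIPPED parameters")
        if not 0 < self.hdna_purity <= 1:
            raise ValueError("invalid HDNA purity")
        if not self.apr_center_min <= self.apr_center_max:
            raise ValueError("invalid APR spacing bounds")


def _maximal_runs(seq: str, chars: str) -> list[tuple[int, int]]:
    """Half-open spans of maximal runs of characters from *chars*."""
    runs = []
    i, n = 0, len(seq)
    while i < n:
        if seq[i] in chars:
            j = i
            while j < n and seq[j] in chars:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def _scan_g4(seq: str, r: MotifRuleSet) -> list[tuple[int, int, int, str]]:
    runs = [(s, e) for s, e in _maximal_runs(seq, "G") if e - s >= r.g4_min_run]
    hits = []
    i = 0
    while i < len(runs):
        chain = [runs[i]]
        j = i
        while j + 1 < len(runs):
            loop = runs[j + 1][0] - runs[j][1]
            if r.g4_loop_min <= loop <= r.g4_loop_max:
                chain.append(runs[j + 1])
                j += 1
            else:
                break
        if len(chain) >= r.g4_min_runs:
            loops = [chain[k + 1][0] - chain[k][1] for k in range(len(chain) - 1)]
            weak = any(lp > 3 for lp in loops) or (
                len(chain) == 4 and all(e - s == 3 for s, e in chain)
            )
            stars = 2 if weak else 3
            hits.append(
                (chain[0][0], chain[-1][1], stars, f"runs={len(chain)}")
            )
        i = j + 1
    return hits


def _scan_zdna(seq: str, r: MotifRuleSet) -> list[tuple[int, int, int, str]]:
    n = len(seq)
    min_len = 2 * r.zdna_min_dinucs
    hits = []
    i = 0
    while i < n - 1:
        if seq[i : i + 2] in _Z_DINUCS:
            j = i
            while j < n - 1 and seq[j : j + 2] in _Z_DINUCS:
                j += 1
            end = j + 1  # tract [i, end)
            if end - i >= min_len:
                tract = seq[i:end]
                pure = set(tract) <= {"G", "C"}
                hits.append((i, end, 3 if pure else 2, f"len={end - i}"))
            i = end
        else:
            i += 1
    return hits


def _min_period(s: str, below: int) -> int | None:
    """Smallest period of *s* strictly below *below*, or None."""
    n = len(s)
    for p in range(1, min(below, n)):
        if all(s[x] == s[x + p] for x in range(n - p)):
            return p
    return None


def _offset_match_runs(arr: np.ndarray, d: int, min_run: int):
    """Maximal runs of positions p with arr[p] == arr[p+d] (N excluded).

    Yields (start, run_length) for runs at least *min_run* long.
    """
    if d >= len(arr):
        return
    match = (arr[:-d] == arr[d:]) & (arr[:-d] != ord("N"))
    edges = np.diff(np.concatenate(([0], match.view(np.int8), [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    for s, e in zip(starts, ends):
        if e - s >= min_run:
            yield int(s), int(e - s)


def _scan_str(seq: str, r: MotifRuleSet) -> list[tuple[int, int, int, str]]:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    hits = []
    for u in range(r.str_unit_min, r.str_unit_max + 1):
        # tract length = run + u (trailing partial copy included)
        min_run = max(r.str_min_tract, r.str_min_copies * u) - u
        for start, run in _offset_match_runs(arr, u, min_run):
            end = start + run + u
            copies = (end - start) // u
            if _min_period(seq[start:end], u) is None:
                stars = 3 if copies >= r.str_strong_copies else 2
                hits.append((start, end, stars, f"unit={u},copies={copies}"))
    return hits


def _scan_slipped(seq: str, r: MotifRuleSet) -> list[tuple[int, int, int, str]]:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    best: dict[tuple[int, int], tuple[int, int, str]] = {}
    d_max = r.slipped_unit_max + r.slipped_spacer_max
    for d in range(r.slipped_unit_min, d_max + 1):
        min_run = max(r.slipped_unit_min, d - r.slipped_spacer_max)
        for start, run in _offset_match_runs(arr, d, min_run):
            unit = min(run, d)
            spacer = d - unit
            region = (start, start + run + d)
            if not (
                r.slipped_unit_min <= unit <= r.slipped_unit_max
                and spacer <= r.slipped_spacer_max
            ):
                continue
            # a region with a sub-10-bp period is an STR tract, not
            # slipped DNA, whatever offset it was matched at
            if _min_period(seq[region[0] : region[1]], r.slipped_unit_min) is not None:
                continue
            stars = 3 if unit >= r.slipped_strong_unit else 2
            prev = best.get(region)
            if prev is None or unit < prev[0]:
                best[region] = (unit, stars, f"unit={unit},spacer={spacer}")
    return [(s, e, stars, detail) for (s, e), (_, stars, detail) in best.items()]


def _scan_hdna(seq: str, r: MotifRuleSet) -> list[tuple[int, int, int, str]]:
    n = len(seq)
    hits = []
    for spacer in range(r.hdna_spacer_max + 1):
        for m in range(1, n - spacer):
            k = 0
            while (
                k < r.hdna_arm_max
                and m - 1 - k >= 0
                and m + spacer + k < n
                and seq[m - 1 - k] != "N"
                and seq[m - 1 - k] == seq[m + spacer + k]
            ):
                k += 1
            if k < r.hdna_arm_min:
                continue
            # inward extension reachable from the narrower-spacer center
            if (
                spacer >= 2
                and k + 1 <= r.hdna_arm_max
                and seq[m] != "N"
                and seq[m] == seq[m + spacer - 1]
            ):
                continue
            region = seq[m - k : m + spacer + k]
            pur = region.count("A") + region.count("G")
            pyr = region.count("C") + region.count("T")
            tot = len(region)
            frac = max(pur, pyr) / tot
            if frac < r.hdna_purity:
                continue
            stars = 3 if frac == 1.0 else 2
            hits.append(
                (m - k, m + spacer + k, stars, f"arm={k},spacer={spacer}")
            )
    return hits


def _scan_tfo(seq: str, r: MotifRuleSet) -> list[tuple[int, int, int, str]]:
    hits = []
    for s, e in _maximal_runs(seq, "AG"):
        length = e - s
        if length < r.tfo_min_len:
            continue
        g_frac = seq.count("G", s, e) / length
        if g_frac < r.tfo_min_g_frac:
            continue
        stars = 3 if length >= r.tfo_strong_len else 2
        hits.append((s, e, stars, f"len={length},g={g_frac:.2f}"))
    return hits


def _scan_apr(seq: str, r: MotifRuleSet) -> list[tuple[int, int, int, str]]:
    tracts = [
        (s, e)
        for s, e in _maximal_runs(seq, "A")
        if r.apr_tract_min <= e - s <= r.apr_tract_max
    ]
    centers = [(s + e - 1) / 2 for s, e in tracts]
    hits = []
    i = 0
    while i < len(tracts):
        chain = [i]
        j = i
        while j + 1 < len(tracts):
            diff = centers[j + 1] - centers[j]
            if r.apr_center_min <= diff <= r.apr_center_max:
                chain.append(j + 1)
                j += 1
            else:
                break
        if len(chain) >= r.apr_min_tracts:
            stars = 3 if len(chain) >= r.apr_strong_tracts else 2
            hits.append(
                (
                    tracts[chain[0]][0],
                    tracts[chain[-1]][1],
                    stars,
                    f"tracts={len(chain)}",
                )
            )
        i = j + 1
    return hits


_SCANNERS = {
    "APR": _scan_apr,
    "G4": _scan_g4,
    "HDNA": _scan_hdna,
    "SLIPPED": _scan_slipped,
    "STR": _scan_str,
    "TFO": _scan_tfo,
    "ZDNA": _scan_zdna,
}


def predict_motifs(
    contig: Contig,
    motif_class: str,
    rules: MotifRuleSet = MotifRuleSet(),
) -> list[MotifHit]:
    """All maximal occurrences of *motif_class* in *contig*, both strands.

    Minus-strand occurrences (e.g. the C-run form of a G4) are mapped
    back to plus coordinates with strand ``-``. Classes whose rules are
    reverse-complement-invariant are scanned once and reported on ``+``.
    """
    if motif_class not in MOTIF_CLASSES:
        raise ValueError(f"unknown motif class {motif_class!r}")
    if contig.length == 0:
        raise ValueError("contig is empty")
    scanner = _SCANNERS[motif_class]
    raw: list[tuple[int, int, int, str, str]] = [
        (s, e, stars, detail, "+") for s, e, stars, detail in scanner(contig.seq, rules)
    ]
    if motif_class not in _STRAND_SYMMETRIC:
        rc = revcomp(contig.seq)
        n = contig.length
        for s, e, stars, detail in scanner(rc, rules):
            raw.append((n - e, n - s, stars, detail, "-"))
    # a rare palindromic occurrence can surface on both strands at the
    # same coordinates; keep the plus-strand record
    seen: dict[tuple[int, int], tuple[int, int, int, str, str]] = {}
    for rec in sorted(raw, key=lambda t: (t[0], t[1], t[4])):
        seen.setdefault((rec[0], rec[1]), rec)
    return [
        MotifHit(Interval(contig.id, s, e, strand), motif_class, stars, detail)
        for (s, e, stars, detail, strand) in seen.values()
    ]


def predict_all(
    contig: Contig, rules: MotifRuleSet = MotifRuleSet()
) -> dict[str, list[MotifHit]]:
    """Predict every class; returns a class -> hits mapping."""
    return {cls: predict_motifs(contig, cls, rules) for cls in MOTIF_CLASSES}


def stars_track(
    contig: Contig, hits: list[MotifHit], motif_class: str
) -> np.ndarray:
    """Per-base maximum stars over same-class hits; 0 where uncovered."""
    track = np.zeros(contig.length, dtype=np.int64)
    for h in hits:
        if h.motif_class != motif_class:
            raise ValueError(
                f"hit of class {h.motif_class!r} passed to "
                f"stars_track({motif_class!r})"
            )
        stars = h.stars if h.stars else DEFAULT_STARS
        sl = slice(h.interval.start, h.interval.end)
        np.maximum(track[sl], stars, out=track[sl])
    return track


def combine_likelihoods(per_class_tracks: dict[str, np.ndarray]) -> np.ndarray:
    """Element-wise sum of per-class star tracks (cross-class stars add)."""
    tracks = list(per_class_tracks.values())
    if not tracks:
        raise ValueError("no tracks to combine")
    length = len(tracks[0])
    if any(len(t) != length for t in tracks):
        raise ValueError("tracks have mismatched lengths")
    return np.sum(tracks, axis=0)


def class_totals(per_class_hits: dict[str, list[MotifHit]]) -> dict[str, dict]:
    """Distinct covered bp per class plus fractions of the all-class total.

    Feeds the relative-contribution pie chart; fractions are reported as
    0 (with ``undefined=True``) when nothing is covered at all.
    """
    covered: dict[str, int] = {}
    for cls in MOTIF_CLASSES:
        ivs = sorted(
            (h.interval.start, h.interval.end) for h in per_class_hits.get(cls, [])
        )
        total = 0
        cur_s, cur_e = None, None
        for s, e in ivs:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            total += cur_e - cur_s
        covered[cls] = total
    grand = sum(covered.values())
    return {
        cls: {
            "bp": covered[cls],
            "fraction": covered[cls] / grand if grand else 0.0,
            "undefined": grand == 0,
        }
        for cls in MOTIF_CLASSES
    }
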