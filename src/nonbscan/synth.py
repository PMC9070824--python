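"""Synthetic assemblies with planted ground truth.

Generates multi-contig genomes with centromere-like architecture — a
complex "island" flanked by simple-satellite tandem arrays — plus plain
background contigs, planted non-B motifs with exact truth coordinates,
per-base IPD tracks elevated over planted motifs, and per-temperature
structure-probability tables with configurable centromere elevation.

Everything is deterministic given the seed (NumPy PCG64 via
``numpy.random.default_rng``). Planted motifs are verified in place: a
local re-scan must recover the planted coordinates exactly, with guard
bases chosen to stop the motif bleeding into its flanks; placements
that cannot be verified are re-drawn.

The default third satellite monomer is a GC-rich 12-mer *stand-in* for
a dodecamer satellite; no real satellite consensus is bundled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .ipd import IpdTrack
from .nonb_motifs import MOTIF_CLASSES, MotifRuleSet, predict_motifs
from .seqio import Contig, GenomeAssembly, Interval
from .tracks import SIST_STRUCTURES, SIST_TEMPERATURES, SistTable

__all__ = [
    "SynthConfig",
    "PlantedMotif",
    "TruthSet",
    "generate_assembly",
    "generate_ipd",
    "generate_sist_tables",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PlantedMotif:
    interval: Interval
    motif_class: str
    stars: int


@dataclass
class TruthSet:
    """Ground truth emitted alongside a synthetic assembly."""

    planted: list[PlantedMotif] = field(default_factory=list)
    annotations: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict)
    ipd_params: dict = field(default_factory=dict)
    sist_params: dict = field(default_factory=dict)

    def planted_by_class(self, motif_class: str) -> list[PlantedMotif]:
        return [p for p in self.planted if p.motif_class == motif_class]


@dataclass
class SynthConfig:
    seed: int
    # background contigs
    n_background_contigs: int = 3
    background_length: int = 30_000
    background_gc: float = 0.5
    # centromere architecture: satellite flank / island / satellite flank
    n_centromeres: int = 1
    island_length: int = 10_000
    island_gc: float = 0.5
    satellite_flank_length: int = 4_000
    satellite_monomers: tuple[str, ...] = (
        "AATAT",
        "AATAACATAG",
        "ACGGCGCAGCGG",  # configurable GC-rich 12-mer stand-in
    )
    # planted motifs: class -> count, spliced into islands and background
    planted_motifs: dict[str, int] = field(default_factory=dict)
    plant_in: str = "all"  # "island" | "background" | "all"
    motif_min_separation: int = 250
    # IPD track
    ipd_background: float = 1.0
    ipd_elevation: float = 2.2
    ipd_noise_sd: float = 0.0
    ipd_missing_rate: float = 0.05
    # structure-probability tables
    sist_background: dict[str, float] = field(
        default_factory=lambda: {"melt": 0.10, "cruciform": 0.05, "zdna": 0.05}
    )
    sist_elevation: dict[tuple[str, int], float] = field(default_factory=dict)
    sist_concentration: float = 80.0
    temperatures: tuple[int, ...] = SIST_TEMPERATURES

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for cls, count in self.planted_motifs.items():
            if cls not in MOTIF_CLASSES:
                raise ValueError(f"unknown motif class {cls!r}")
            if count < 0:
                raise ValueError("planted counts must be >= 0")
        if self.plant_in not in ("island", "background", "all"):
            raise ValueError(f"invalid plant_in {self.plant_in!r}")
        if not self.satellite_monomers or any(not m for m in self.satellite_monomers):
            raise ValueError("satellite monomers must be non-empty")
        if self.ipd_elevation <= 0:
            raise ValueError("IPD elevation must be > 0")
        for t in self.temperatures:
            if t not in SIST_TEMPERATURES:
                raise ValueError(f"unknown temperature {t}")


def _random_bases(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return rng.choice(_BASES, size=length, p=probs)


def _tandem(monomer: str, length: int) -> np.ndarray:
    copies = length // len(monomer) + 1
    return np.frombuffer((monomer * copies).encode(), dtype=np.uint8)[:length]


# ---------------------------------------------------------------------------
# planted motif sequence builders (plus strand); each returns a DNA string

def _build_g4(rng: np.random.Generator) -> str:
    n_runs = int(rng.integers(4, 6))
    run_len = int(rng.integers(3, 5))
    loop_len = int(rng.integers(1, 4))
    loops = [
        "".join(rng.choice(list("AT"), size=loop_len)) for _ in range(n_runs - 1)
    ]
    parts = []
    for i in range(n_runs):
        parts.append("G" * run_len)
        if i < n_runs - 1:
            parts.append(loops[i])
    return "".join(parts)


def _build_zdna(rng: np.random.Generator) -> str:
    n_dinucs = int(rng.integers(6, 10))
    if rng.random() < 0.5:
        return "GC" * n_dinucs
    return "GT" * n_dinucs


def _build_str(rng: np.random.Generator) -> str:
    unit_len = int(rng.integers(2, 6))
    while True:
        unit = "".join(rng.choice(list("ACGT"), size=unit_len))
        from .nonb_motifs import _min_period

        if _min_period(unit * 3, unit_len) is None:
            break
    copies = int(rng.integers(5, 13))
    while copies * unit_len < 15:
        copies += 1
    return unit * copies


def _build_slipped(rng: np.random.Generator) -> str:
    unit_len = int(rng.integers(10, 26))
    unit = "".join(rng.choice(list("ACGT"), size=unit_len))
    spacer_len = int(rng.integers(1, 9))
    spacer = "".join(rng.choice(list("ACGT"), size=spacer_len))
    return unit + spacer + unit


def _build_hdna(rng: np.random.Generator) -> str:
    arm_len = int(rng.integers(10, 16))
    arm = "".join(rng.choice(list("AG"), size=arm_len, p=[0.6, 0.4]))
    spacer_len = int(rng.integers(0, 4))
    spacer = "".join(rng.choice(list("AG"), size=spacer_len))
    return arm + spacer + arm[::-1]


def _build_tfo(rng: np.random.Generator) -> str:
    # homopurine, >= 50% G, G runs capped at 2 so no G4 arises inside
    length = int(rng.integers(15, 31))
    out = []
    g_run = 0
    for _ in range(length):
        if g_run >= 2:
            out.append("A")
            g_run = 0
        elif rng.random() < 0.6:
            out.append("G")
            g_run += 1
        else:
            out.append("A")
            g_run = 0
    if out.count("G") / length < 0.55:  # margin over the 0.5 rule
        return _build_tfo(rng)
    return "".join(out)


def _build_apr(rng: np.random.Generator) -> str:
    n_tracts = int(rng.integers(3, 6))
    tract_len = int(rng.integers(4, 7))
    spacing = int(rng.integers(10, 12))  # center-to-center, 10 or 11
    gap_len = spacing - tract_len
    parts = []
    for i in range(n_tracts):
        parts.append("A" * tract_len)
        if i < n_tracts - 1:
            parts.append("".join(rng.choice(list("CGT"), size=gap_len)))
    return "".join(parts)


_BUILDERS = {
    "APR": _build_apr,
    "G4": _build_g4,
    "HDNA": _build_hdna,
    "SLIPPED": _build_slipped,
    "STR": _build_str,
    "TFO": _build_tfo,
    "ZDNA": _build_zdna,
}

_SCAN_MARGIN = 130  # covers the longest possible flank interaction


def _verify_plant(
    arr: np.ndarray, start: int, end: int, motif_class: str, rules: MotifRuleSet
) -> int | None:
    """Re-scan locally; return the hit's stars when coordinates are exact."""
    lo = max(0, start - _SCAN_MARGIN)
    hi = min(len(arr), end + _SCAN_MARGIN)
    window = Contig("_verify", arr[lo:hi].tobytes().decode())
    for hit in predict_motifs(window, motif_class, rules):
        if hit.interval.start == start - lo and hit.interval.end == end - lo:
            return hit.stars
    return None


def _plant_motifs(
    rng: np.random.Generator,
    seqs: dict[str, np.ndarray],
    zones: list[tuple[str, int, int]],
    config: SynthConfig,
    rules: MotifRuleSet,
) -> list[PlantedMotif]:
    planted: list[PlantedMotif] = []
    occupied: dict[str, list[tuple[int, int]]] = {cid: [] for cid in seqs}
    sep = config.motif_min_separation
    guard_bases = [ord(b) for b in "ACGT"]
    for motif_class in sorted(config.planted_motifs):
        count = config.planted_motifs[motif_class]
        builder = _BUILDERS[motif_class]
        for _ in range(count):
            placed = False
            for _attempt in range(200):
                motif = builder(rng)
                m = np.frombuffer(motif.encode(), dtype=np.uint8)
                zi = int(rng.integers(len(zones)))
                cid, zlo, zhi = zones[zi]
                usable = zhi - zlo - len(m) - 2 * sep
                if usable <= 0:
                    continue
                start = zlo + sep + int(rng.integers(usable))
                end = start + len(m)
                if any(
                    start - sep < oe and end + sep > os
                    for os, oe in occupied[cid]
                ):
                    continue
                arr = seqs[cid]
                backup = arr[start - 1 : end + 1].copy()
                arr[start:end] = m
                stars = None
                for left, right in product(guard_bases, repeat=2):
                    arr[start - 1] = left
                    arr[end] = right
                    stars = _verify_plant(arr, start, end, motif_class, rules)
                    if stars is not None:
                        break
                if stars is None:
                    arr[start - 1 : end + 1] = backup  # undo and re-draw
                    continue
                occupied[cid].append((start, end))
                planted.append(
                    PlantedMotif(Interval(cid, start, end, "+"), motif_class, stars)
                )
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    f"could not place a {motif_class} motif after 200 attempts; "
                    f"motif density is infeasible for the configured contigs"
                )
    return planted


def generate_assembly(
    config: SynthConfig, rules: MotifRuleSet = MotifRuleSet()
) -> tuple[GenomeAssembly, TruthSet]:
    """Build the synthetic assembly and its ground-truth record."""
    rng = np.random.default_rng(config.seed)
    seqs: dict[str, np.ndarray] = {}
    annotations: dict[str, list[tuple[int, int, str]]] = {}
    centromere_ids = []
    zones: list[tuple[str, int, int]] = []

    for i in range(config.n_centromeres):
        cid = f"cen{i + 1}"
        centromere_ids.append(cid)
        mono_left = config.satellite_monomers[i % len(config.satellite_monomers)]
        mono_right = config.satellite_monomers[(i + 1) % len(config.satellite_monomers)]
        flank = config.satellite_flank_length
        left = _tandem(mono_left, flank)
        island = _random_bases(rng, config.island_length, config.island_gc)
        right = _tandem(mono_right, flank)
        seqs[cid] = np.concatenate([left, island, right])
        annotations[cid] = [
            (0, flank, f"satellite:{mono_left}"),
            (flank, flank + config.island_length, "island"),
            (
                flank + config.island_length,
                flank + config.island_length + flank,
                f"satellite:{mono_right}",
            ),
        ]
        if config.plant_in in ("island", "all"):
            zones.append((cid, flank, flank + config.island_length))

    for i in range(config.n_background_contigs):
        cid = f"bg{i + 1}"
        seqs[cid] = _random_bases(rng, config.background_length, config.background_gc)
        annotations[cid] = [(0, config.background_length, "background")]
        if config.plant_in in ("background", "all"):
            zones.append((cid, 0, config.background_length))

    planted: list[PlantedMotif] = []
    if config.planted_motifs:
        if not zones:
            raise ValueError("no eligible zones to plant motifs into")
        planted = _plant_motifs(rng, seqs, zones, config, rules)

    contigs = [Contig(cid, arr.tobytes().decode()) for cid, arr in seqs.items()]
    assembly = GenomeAssembly(contigs, set(centromere_ids))
    truth = TruthSet(
        planted=planted,
        annotations=annotations,
        ipd_params={
            "background": config.ipd_background,
            "elevation": config.ipd_elevation,
            "noise_sd": config.ipd_noise_sd,
            "missing_rate": config.ipd_missing_rate,
        },
        sist_params={
            "background": dict(config.sist_background),
            "elevation": {f"{s}@{t}": v for (s, t), v in config.sist_elevation.items()},
        },
    )
    return assembly, truth


def generate_ipd(
    assembly: GenomeAssembly, truth: TruthSet, config: SynthConfig
) -> dict[str, IpdTrack]:
    """Per-contig IPD tracks: background level, elevated over planted motifs.

    Noise is multiplicative lognormal (sd on the log scale); a
    configured fraction of positions is set missing (NaN).
    """
    rng = np.random.default_rng([config.seed, 1])
    tracks = {}
    for contig in assembly.contigs:
        vals = np.full(contig.length, float(config.ipd_background))
        for p in truth.planted:
            if p.interval.contig_id == contig.id:
                vals[p.interval.start : p.interval.end] *= config.ipd_elevation
        if config.ipd_noise_sd > 0:
            vals *= rng.lognormal(0.0, config.ipd_noise_sd, size=contig.length)
        if config.ipd_missing_rate > 0:
            missing = rng.random(contig.length) < config.ipd_missing_rate
            vals[missing] = np.nan
        tracks[contig.id] = IpdTrack(contig.id, vals, source="synthetic")
    return tracks


def generate_sist_tables(
    assembly: GenomeAssembly, truth: TruthSet, config: SynthConfig
) -> dict[tuple[str, int], SistTable]:
    """Beta-noise probability tables keyed by (contig id, temperature).

    Centromere contigs are elevated per (structure, temperature) by the
    configured factor; probabilities always stay inside [0, 1].
    """
    rng = np.random.default_rng([config.seed, 2])
    k = config.sist_concentration
    tables: dict[tuple[str, int], SistTable] = {}
    for contig in assembly.contigs:
        for temp in config.temperatures:
            per_structure = {}
            for structure in SIST_STRUCTURES:
                mean = config.sist_background.get(structure, 0.05)
                if contig.id in assembly.centromere_ids:
                    mean *= config.sist_elevation.get((structure, temp), 1.0)
                mean = min(max(mean, 1e-4), 0.999)
                a, b = mean * k, (1 - mean) * k
                per_structure[structure] = rng.beta(a, b, size=contig.length)
            tables[(contig.id, temp)] = SistTable(
                contig.id,
                temp,
                per_structure["melt"],
                per_structure["cruciform"],
                per_structure["zdna"],
            )
    return tables
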