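"""Statistical layer: enrichment tests, outlier trimming, ranking.

The enrichment design compares one centromere contig against ~50
matched control segments. Scalar metrics (dyad density, G4 density) use
a one-sample t-test of the control values against the centromere value
as hypothesized mean; per-base likelihood/probability distributions use
the two-sample Kolmogorov-Smirnov test. Control values are trimmed of
outliers beyond 1.5x the interquartile range before testing; the single
centromere value is never trimmed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .seqio import Interval
from .tracks import SIST_STRUCTURES, SistTable

__all__ = [
    "EnrichmentResult",
    "iqr_trim",
    "one_sample_t",
    "ks_two_sample",
    "rank_by_mean_likelihood",
    "temperature_sweep_report",
    "bh_adjust",
]

DIRECTIONS = ("centromere_higher", "controls_higher", "none")


@dataclass
class EnrichmentResult:
    """One centromere-vs-controls comparison."""

    metric: str
    test: str  # one_sample_t | ks_two_sample
    statistic: float
    p_value: float
    direction: str
    significant: bool
    centromere_value: float | None = None
    control_values: list[float] = field(default_factory=list)
    alpha: float = 0.05
    degenerate: bool = False
    n_trimmed: int = 0

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"invalid direction {self.direction!r}")
        if not 0 <= self.p_value <= 1:
            raise ValueError(f"p-value {self.p_value} out of [0, 1]")

    @property
    def verdict(self) -> str:
        if not self.significant and self.p_value >= self.alpha:
            return "not_significant"
        if self.p_value < self.alpha:
            return (
                "centromere_enriched"
                if self.direction == "centromere_higher"
                else "controls_enriched"
            )
        return "not_significant"


def iqr_trim(
    values, interpolation: str = "linear"
) -> np.ndarray:
    """Drop values beyond 1.5x IQR outside [Q1, Q3]; order preserved.

    Quartiles use linear interpolation between order statistics by
    default (*interpolation* accepts any numpy quantile method). Fewer
    than 4 values are returned unchanged with a warning. The fence test
    is strict, so a zero-IQR sample is never trimmed.
    """
    values = np.asarray(values, dtype=np.float64)
    if len(values) < 4:
        warnings.warn("fewer than 4 values; IQR trimming skipped")
        return values
    q1, q3 = np.percentile(values, [25, 75], method=interpolation)
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return values[(values >= lo) & (values <= hi)]


def one_sample_t(
    control_values,
    centromere_value: float,
    metric: str = "",
    alpha: float = 0.05,
    trim: bool = True,
) -> EnrichmentResult:
    """Two-sided one-sample t-test of controls against the centromere value.

    Direction comes from the sign of (centromere - control mean);
    "enrichment" requires p < alpha AND centromere_higher. A
    zero-variance control sample yields an exact degenerate verdict.
    """
    raw = np.asarray(control_values, dtype=np.float64)
    trimmed = iqr_trim(raw) if trim else raw
    n_trimmed = len(raw) - len(trimmed)
    if len(trimmed) < 3:
        raise ValueError(f"need >= 3 control values after trimming, got {len(trimmed)}")
    mean = float(np.mean(trimmed))
    diff = centromere_value - mean
    direction = (
        "centromere_higher" if diff > 0 else "controls_higher" if diff < 0 else "none"
    )
    if float(np.std(trimmed, ddof=1)) == 0.0:
        p = 0.0 if diff != 0 else 1.0
        return EnrichmentResult(
            metric,
            "one_sample_t",
            np.inf if diff != 0 else 0.0,
            p,
            direction,
            significant=False,
            centromere_value=centromere_value,
            control_values=list(map(float, trimmed)),
            alpha=alpha,
            degenerate=True,
            n_trimmed=n_trimmed,
        )
    t_stat, p = sps.ttest_1samp(trimmed, popmean=centromere_value)
    significant = bool(p < alpha and direction == "centromere_higher")
    return EnrichmentResult(
        metric,
        "one_sample_t",
        float(t_stat),
        float(p),
        direction,
        significant,
        centromere_value=centromere_value,
        control_values=list(map(float, trimmed)),
        alpha=alpha,
        n_trimmed=n_trimmed,
    )


def ks_two_sample(
    sample_a,
    sample_b,
    metric: str = "",
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Two-sided two-sample KS test; *sample_a* is the centromere side.

    D = sup |ECDF_a - ECDF_b| with the asymptotic p-value; direction
    from the comparison of sample means.
    """
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("KS test requires non-empty samples")
    res = sps.ks_2samp(a, b, method="asymp")
    diff = float(np.mean(a) - np.mean(b))
    direction = (
        "centromere_higher" if diff > 0 else "controls_higher" if diff < 0 else "none"
    )
    p = float(res.pvalue)
    if np.isnan(p):  # scipy's asymp path degenerates for tiny samples
        en = np.sqrt(len(a) * len(b) / (len(a) + len(b)))
        p = float(sps.kstwobign.sf(res.statistic * en))
    p = min(p, 1.0)
    significant = bool(p < alpha and direction == "centromere_higher")
    return EnrichmentResult(
        metric,
        "ks_two_sample",
        float(res.statistic),
        p,
        direction,
        significant,
        alpha=alpha,
    )


def rank_by_mean_likelihood(
    combined_tracks: dict[str, np.ndarray],
    units: list[Interval] | None = None,
) -> pd.DataFrame:
    """Rank contigs (or annotated intervals) by mean combined likelihood.

    Rank 1 = highest mean; ties share the minimum rank and are flagged.
    ``percentile`` is rank / number of units.
    """
    rows = []
    if units is None:
        for cid, track in combined_tracks.items():
            if len(track) == 0:
                raise ValueError(f"contig {cid!r} has zero length")
            rows.append((cid, float(np.mean(track))))
    else:
        for iv in units:
            track = combined_tracks[iv.contig_id]
            if iv.end > len(track):
                raise ValueError(f"unit {iv} outside track")
            rows.append(
                (f"{iv.contig_id}:{iv.start}-{iv.end}", float(np.mean(track[iv.start : iv.end])))
            )
    df = pd.DataFrame(rows, columns=["unit", "mean_likelihood"])
    df["rank"] = (
        df["mean_likelihood"].rank(method="min", ascending=False).astype(int)
    )
    df["tied"] = df.duplicated("mean_likelihood", keep=False)
    df["percentile"] = df["rank"] / len(df)
    return df.sort_values("rank", kind="stable").reset_index(drop=True)


def temperature_sweep_report(
    centromere_tables: dict[int, SistTable],
    control_tables: dict[int, list[SistTable]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per temperature x structure: means, KS test, and enrichment verdict.

    Centromere per-base probabilities are compared with the pooled
    per-base probabilities of all controls. Temperatures missing from
    either side are omitted with a warning.
    """
    rows = []
    for temp in sorted(centromere_tables):
        if temp not in control_tables or not control_tables[temp]:
            warnings.warn(f"no control tables at {temp} C; row omitted")
            continue
        cen = centromere_tables[temp]
        for structure in SIST_STRUCTURES:
            cen_vals = cen.track(structure)
            ctl_vals = np.concatenate(
                [t.track(structure) for t in control_tables[temp]]
            )
            res = ks_two_sample(cen_vals, ctl_vals, metric=structure, alpha=alpha)
            rows.append(
                {
                    "temperature": temp,
                    "structure": structure,
                    "centromere_mean": float(np.mean(cen_vals)),
                    "control_mean": float(np.mean(ctl_vals)),
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "verdict": res.verdict,
                }
            )
    return pd.DataFrame(rows)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (report column; never gates)."""
    p = np.asarray(p_values, dtype=np.float64)
    n = len(p)
    order = np.argsort(p)
    adjusted = np.empty(n)
    running = 1.0
    for i in range(n - 1, -1, -1):
        rank = i + 1
        running = min(running, p[order[i]] * n / rank)
        adjusted[order[i]] = running
    return adjusted
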