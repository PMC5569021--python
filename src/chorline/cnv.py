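"""Copy-number profiling from targeted-panel coverage and two-channel arrays.

The caller mirrors the simplest defensible procedure for targeted ("clinical
exome") panel data: per genomic interval, the log2 ratio of the local mean
coverage versus the sample-wide mean coverage, with fixed symmetric cutoffs
(gain when log2 > +0.2, loss when log2 < -0.2, strict inequalities) and no
segmentation or smoothing — every interval is called independently.
Cross-sample consensus profiles report, per interval, the percentage of
samples carrying a gain or a loss.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

GAIN = "gain"
LOSS = "loss"
BALANCED = "balanced"
MISSING = "missing"

#: Approximate hg19 chromosome sizes (bp), autosomes + X/Y.
CHROM_SIZES = {
    "chr1": 249_250_621, "chr2": 243_199_373, "chr3": 198_022_430,
    "chr4": 191_154_276, "chr5": 180_915_260, "chr6": 171_115_067,
    "chr7": 159_138_663, "chr8": 146_364_022, "chr9": 141_213_431,
    "chr10": 135_534_747, "chr11": 135_006_516, "chr12": 133_851_895,
    "chr13": 115_169_878, "chr14": 107_349_540, "chr15": 102_531_392,
    "chr16": 90_354_753, "chr17": 81_195_210, "chr18": 78_077_248,
    "chr19": 59_128_983, "chr20": 63_025_520, "chr21": 48_129_895,
    "chr22": 51_304_566, "chrX": 155_270_560, "chrY": 59_373_566,
}

#: Approximate hg19 centromere midpoints (bp), used only for arm summaries.
CENTROMERES = {
    "chr1": 125_000_000, "chr2": 93_300_000, "chr3": 91_000_000,
    "chr4": 50_400_000, "chr5": 48_400_000, "chr6": 61_000_000,
    "chr7": 59_900_000, "chr8": 45_600_000, "chr9": 49_000_000,
    "chr10": 40_200_000, "chr11": 53_700_000, "chr12": 35_800_000,
    "chr13": 17_900_000, "chr14": 17_600_000, "chr15": 19_000_000,
    "chr16": 36_600_000, "chr17": 24_000_000, "chr18": 17_200_000,
    "chr19": 26_500_000, "chr20": 27_500_000, "chr21": 13_200_000,
    "chr22": 14_700_000, "chrX": 60_600_000, "chrY": 12_500_000,
}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval (BED convention)."""

    chrom: str
    start: int
    end: int
    id: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(f"start must be < end ({self.chrom}:{self.start}-{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class CoverageTrack:
    """Per-interval mean sequencing depth for one sample."""

    sample_id: str
    intervals: list[GenomicInterval]
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        if len(self.depths) != len(self.intervals):
            raise ValueError("one depth per interval required")
        if np.any(self.depths < 0):
            raise ValueError("depths must be non-negative")

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True)
class CallThresholds:
    """Cutoffs for gain/loss calling on log2 ratios.

    gain_cutoff / loss_cutoff are strict inequalities: a ratio exactly at
    the cutoff is balanced. zero_floor replaces -inf for zero-depth
    intervals so downstream arithmetic stays finite. Intervals with depth
    below min_depth are marked missing (excluded from calling).
    """

    gain_cutoff: float = 0.2
    loss_cutoff: float = -0.2
    min_depth: float = 0.0
    zero_floor: float = -8.0

    def __post_init__(self) -> None:
        if not (self.loss_cutoff < 0.0 < self.gain_cutoff):
            raise ValueError("need loss_cutoff < 0 < gain_cutoff")

    def call(self, log2_ratio: float) -> str:
        if np.isnan(log2_ratio):
            return MISSING
        if log2_ratio > self.gain_cutoff:
            return GAIN
        if log2_ratio < self.loss_cutoff:
            return LOSS
        return BALANCED


DEFAULT_THRESHOLDS = CallThresholds()


@dataclass
class CnvProfile:
    """Per-interval log2 ratios and gain/loss/balanced/missing calls."""

    sample_id: str
    intervals: list[GenomicInterval]
    log2_ratio: np.ndarray  # NaN where missing
    calls: np.ndarray       # dtype=object of call strings

    def __post_init__(self) -> None:
        self.log2_ratio = np.asarray(self.log2_ratio, dtype=float)
        self.calls = np.asarray(self.calls, dtype=object)
        if not (len(self.intervals) == len(self.log2_ratio) == len(self.calls)):
            raise ValueError("intervals, ratios and calls must align")

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class ConsensusProfile:
    """Per-interval percentage of samples called gain / loss."""

    intervals: list[GenomicInterval]
    gain_pct: np.ndarray
    loss_pct: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        self.gain_pct = np.asarray(self.gain_pct, dtype=float)
        self.loss_pct = np.asarray(self.loss_pct, dtype=float)
        if not (len(self.intervals) == len(self.gain_pct) == len(self.loss_pct)):
            raise ValueError("intervals and percentages must align")
        for arr in (self.gain_pct, self.loss_pct):
            if np.any((arr < 0) | (arr > 100)):
                raise ValueError("percentages must lie in [0, 100]")
        if np.any(self.gain_pct + self.loss_pct > 100 + 1e-9):
            raise ValueError("gain_pct + loss_pct must not exceed 100")

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class ConcordanceReport:
    """Agreement between two CNV profiles over their shared intervals."""

    n_shared: int
    n_compared: int       # shared intervals where both calls are non-missing
    concordance: float    # fraction of compared intervals with identical call
    confusion: dict[tuple[str, str], int]


def _assign_calls(ratios: np.ndarray, thresholds: CallThresholds) -> np.ndarray:
    return np.array([thresholds.call(r) for r in ratios], dtype=object)


def compute_log2_profile(
    track: CoverageTrack,
    thresholds: CallThresholds = DEFAULT_THRESHOLDS,
    length_weighted: bool = False,
) -> CnvProfile:
    """Call per-interval copy-number state from panel coverage.

    log2_ratio_i = log2(depth_i / mean depth); the sample mean is the
    unweighted arithmetic mean of per-interval depths by default
    (length_weighted=True weights by interval length). Zero-depth intervals
    receive the finite zero_floor ratio; intervals below min_depth are
    marked missing. The profile is invariant to rescaling all depths by a
    positive constant.
    """
    if len(track) == 0:
        raise ValueError("empty coverage track")
    depths = track.depths
    if length_weighted:
        weights = np.array([iv.length for iv in track.intervals], dtype=float)
        mean_depth = float(np.average(depths, weights=weights))
    else:
        mean_depth = float(depths.mean())
    if mean_depth <= 0:
        raise ValueError("no coverage: sample mean depth is zero")

    with np.errstate(divide="ignore"):
        ratios = np.log2(depths / mean_depth)
    ratios[depths == 0] = thresholds.zero_floor
    missing = depths < thresholds.min_depth
    ratios[missing] = np.nan
    return CnvProfile(track.sample_id, list(track.intervals), ratios,
                      _assign_calls(ratios, thresholds))


def call_consensus(profiles: list[CnvProfile]) -> ConsensusProfile:
    """Percentage of samples with a gain (resp. loss) at each interval.

    Missing calls are excluded from both numerator and denominator at that
    interval; an interval missing in every profile reports 0%.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    ref = [iv.key() for iv in profiles[0].intervals]
    for p in profiles[1:]:
        if [iv.key() for iv in p.intervals] != ref:
            raise ValueError(f"profile {p.sample_id!r} has a mismatched interval list")

    calls = np.stack([p.calls for p in profiles])  # samples x intervals
    called = calls != MISSING
    n_called = called.sum(axis=0)
    denom = np.where(n_called > 0, n_called, 1)
    gain_pct = 100.0 * (calls == GAIN).sum(axis=0) / denom
    loss_pct = 100.0 * (calls == LOSS).sum(axis=0) / denom
    return ConsensusProfile(list(profiles[0].intervals), gain_pct, loss_pct,
                            n_samples=len(profiles))


def acgh_log2(
    probes: list[GenomicInterval],
    ch1: np.ndarray,
    ch2: np.ndarray,
    thresholds: CallThresholds = DEFAULT_THRESHOLDS,
    sample_id: str = "acgh",
) -> CnvProfile:
    """Two-channel array profile: log2(ch1/ch2) per probe, same call rules.

    Probes where the reference channel (ch2) is zero are marked missing
    rather than raising; a zero sample channel (ch1) maps to the zero_floor.
    """
    ch1 = np.asarray(ch1, dtype=float)
    ch2 = np.asarray(ch2, dtype=float)
    if not (len(probes) == len(ch1) == len(ch2)):
        raise ValueError("probes and channel intensities must have equal length")
    ratios = np.full(len(probes), np.nan)
    ok = ch2 > 0
    with np.errstate(divide="ignore"):
        ratios[ok] = np.log2(ch1[ok] / ch2[ok])
    ratios[ok & (ch1 == 0)] = thresholds.zero_floor
    return CnvProfile(sample_id, list(probes), ratios,
                      _assign_calls(ratios, thresholds))


def compare_profiles(a: CnvProfile, b: CnvProfile) -> ConcordanceReport:
    """Concordance of two profiles over intervals shared by coordinates.

    Returns the fraction of shared, mutually called (non-missing) intervals
    with identical state, plus full per-state confusion counts. Symmetric
    up to transposition of the confusion table.
    """
    index_b = {iv.key(): i for i, iv in enumerate(b.intervals)}
    pairs = [(i, index_b[iv.key()]) for i, iv in enumerate(a.intervals)
             if iv.key() in index_b]
    if not pairs:
        raise ValueError("profiles share no intervals")
    confusion: Counter[tuple[str, str]] = Counter()
    agree = compared = 0
    for i, j in pairs:
        ca, cb = a.calls[i], b.calls[j]
        confusion[(ca, cb)] += 1
        if ca == MISSING or cb == MISSING:
            continue
        compared += 1
        agree += ca == cb
    concordance = agree / compared if compared else float("nan")
    return ConcordanceReport(len(pairs), compared, concordance, dict(confusion))


def arm_summary(
    profile: CnvProfile,
    centromeres: dict[str, int] | None = None,
    min_fraction: float = 0.5,
) -> list[dict]:
    """Chromosome-arm roll-up of per-interval calls (reporting convenience).

    Each interval is assigned to the p or q arm by its midpoint. An arm is
    labeled aberrant in a direction when strictly more than min_fraction of
    its called intervals agree.
    """
    centromeres = centromeres or CENTROMERES
    arms: dict[tuple[str, str], Counter] = {}
    for iv, call in zip(profile.intervals, profile.calls):
        cen = centromeres.get(iv.chrom)
        if cen is None:
            continue
        arm = "p" if iv.midpoint < cen else "q"
        arms.setdefault((iv.chrom, arm), Counter())[call] += 1
    rows = []
    for (chrom, arm), counts in sorted(arms.items()):
        n_called = sum(v for k, v in counts.items() if k != MISSING)
        state = BALANCED
        for direction in (GAIN, LOSS):
            if n_called and counts[direction] / n_called > min_fraction:
                state = direction
        rows.append({
            "chrom": chrom, "arm": arm, "n_intervals": n_called,
            "gain_fraction": counts[GAIN] / n_called if n_called else 0.0,
            "loss_fraction": counts[LOSS] / n_called if n_called else 0.0,
            "state": state,
        })
    return rows
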