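"""Read-level estimators for prophage induction and transduction genomics.

This module contains the analysis side of the package: integration
percentage from junction-spanning read counts, Fisher exact tests between
timepoints, phage-excluded relative coverage, L0-penalized change-point
segmentation of the capsid-coverage staircase with headful-length and
processivity recovery, detection of the lateral-transduction region, and
plate-count statistics (transduction units, co-transduction frequency,
2^-dCT relative quantification).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genome_model import CircularInterval, GenomeLayout
from .packaging_sim import CoverageTrack
from .readsim import AlignmentRecords, TAG_ATTB, TAG_ATTL

__all__ = [
    "JunctionCounts", "StaircaseFit", "TransductionRecord", "LTRegion",
    "CotransductionResult", "count_junction_reads", "integration_percentage",
    "fisher_timepoints", "relative_coverage", "segment_staircase",
    "estimate_processivity", "detect_lt_region", "transduction_units",
    "cotransduction_frequency", "ddct",
]


# ---------------------------------------------------------------------------
# junction counting / integration percentage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JunctionCounts:
    """Junction-spanning read tallies at one timepoint: chromosome-attL-
    prophage (``n_attL``) vs. chromosome-attB-chromosome (``n_attB``)."""

    timepoint: int
    n_attL: int
    n_attB: int

    def __post_init__(self):
        if self.n_attL < 0 or self.n_attB < 0:
            raise ValueError("junction counts must be >= 0")


def count_junction_reads(records: AlignmentRecords) -> JunctionCounts:
    """Tally attL- and attB-spanning reads from their junction tags."""
    c = records.tag_counts()
    return JunctionCounts(records.timepoint, c[TAG_ATTL], c[TAG_ATTB])


def integration_percentage(c: JunctionCounts) -> float:
    """Percentage of integrated prophage: 100 * attL / (attL + attB)."""
    total = c.n_attL + c.n_attB
    if total == 0:
        raise ValueError("integration percentage undefined: no junction reads")
    return 100.0 * c.n_attL / total


def fisher_timepoints(c1: JunctionCounts, c2: JunctionCounts) -> float:
    """Two-sided Fisher exact test on the 2x2 junction-count table between
    two timepoints (tables at least as improbable as observed)."""
    table = np.array([[c1.n_attL, c1.n_attB], [c2.n_attL, c2.n_attB]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("Fisher test requires all table margins > 0")
    return float(stats.fisher_exact(table, alternative="two-sided").pvalue)


# ---------------------------------------------------------------------------
# relative coverage
# ---------------------------------------------------------------------------

def relative_coverage(depth, phage_mask: np.ndarray | None = None):
    """Depth divided by the mean depth over non-phage windows.

    Accepts a :class:`CoverageTrack` (returning a new track) or a plain
    array plus mask.  The mean of the unmasked output is exactly 1.
    """
    if isinstance(depth, CoverageTrack):
        rel = relative_coverage(depth.values, depth.phage_mask)
        return depth.replace_values(rel)
    depth = np.asarray(depth, dtype=float)
    if phage_mask is None:
        phage_mask = np.zeros(len(depth), dtype=bool)
    un = ~np.asarray(phage_mask, dtype=bool)
    if not un.any():
        raise ValueError("all windows masked: bacterial average undefined")
    mean = depth[un].mean()
    if mean <= 0:
        raise ValueError("zero bacterial coverage: relative coverage undefined")
    return depth / mean


# ---------------------------------------------------------------------------
# staircase segmentation
# ---------------------------------------------------------------------------

def piecewise_constant_dp(y: np.ndarray, penalty: float,
                          min_len: int = 1) -> list[int]:
    """Exact least-squares segmentation of ``y`` with an L0 penalty.

    Minimizes ``sum_j SSE(segment_j) + penalty * n_segments`` over all
    segmentations with segments of at least ``min_len`` points, by dynamic
    programming (O(n^2)).  Returns interior changepoint indices.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 points to segment")
    c1 = np.concatenate([[0.0], np.cumsum(y)])
    c2 = np.concatenate([[0.0], np.cumsum(y * y)])
    F = np.full(n + 1, np.inf)
    F[0] = 0.0
    prev = np.zeros(n + 1, dtype=np.int64)
    for t in range(min_len, n + 1):
        s = np.arange(0, t - min_len + 1)
        seg_len = t - s
        sse = (c2[t] - c2[s]) - (c1[t] - c1[s]) ** 2 / seg_len
        cand = F[s] + sse + penalty
        i = int(np.argmin(cand))
        F[t] = cand[i]
        prev[t] = s[i]
    cps = []
    t = n
    while t > 0:
        t = int(prev[t])
        if t > 0:
            cps.append(t)
    return sorted(cps)


def _auto_penalty(y: np.ndarray, covered: np.ndarray | None = None) -> float:
    """SIC-like default penalty from a robust noise estimate (MAD of first
    differences).  ``covered`` restricts the noise estimate to windows with
    signal, so runs of empty windows beyond the staircase do not deflate it."""
    d = np.diff(y)
    if covered is not None:
        keep = covered[1:] & covered[:-1]
        if keep.sum() >= 10:
            d = d[keep]
    sigma = 1.4826 * np.median(np.abs(d - np.median(d))) / math.sqrt(2)
    sigma = max(sigma, 1e-6)
    # SIC penalty inflated (x20) for read-length-correlated window noise and
    # the ramps that headful-boundary jitter smears across step edges
    return 20.0 * sigma ** 2 * math.log(len(y))


@dataclass
class StaircaseFit:
    """Result of segmenting capsid coverage downstream of the prophage.

    ``changepoints`` are absolute bp positions of the staircase step
    boundaries (including the terminal boundary where the staircase ends);
    ``step_lengths``/``step_heights`` describe each successive headful band.
    The first band is the pac-anchored partial step (headful 1 minus the
    pac-to-attR phage segment), so headful-length statistics use the
    boundary-to-boundary distances, ``np.diff(changepoints)``.
    """

    changepoints: np.ndarray
    step_lengths: np.ndarray
    step_heights: np.ndarray
    processivity_hat: float
    lt_span: int
    lt_read_fraction: float
    window: int

    @property
    def n_steps(self) -> int:
        return len(self.step_heights)

    @property
    def mean_step_length(self) -> float:
        """Mean distance between successive re-initiation boundaries (the
        recovered headful size)."""
        if len(self.changepoints) < 2:
            return float("nan")
        return float(np.mean(np.diff(self.changepoints)))


def _forward_profile(cov: CoverageTrack, layout: GenomeLayout):
    """Window values ordered along the packaging direction from the
    downstream prophage edge, with per-window forward offsets."""
    starts = cov.starts
    centers = starts + (cov.ends - starts) / 2.0
    fd = np.asarray(layout.forward_distance(centers), dtype=float)
    order = np.argsort(fd)
    return order, fd


def segment_staircase(cov: CoverageTrack, layout: GenomeLayout,
                      min_step: int = 5000, max_steps: int = 16,
                      penalty: float | None = None,
                      floor_frac: float = 0.01,
                      span: int | None = None) -> StaircaseFit:
    """Fit the step-down staircase of capsid coverage downstream of attR.

    Coverage windows along the packaging direction are log-transformed and
    segmented by exact L0-penalized dynamic programming; successive
    headfuls appear as piecewise-constant bands whose boundaries recover the
    headful size and whose height ratios recover the re-initiation
    processivity.  Steps below ``floor_frac`` of the first step terminate
    the staircase.
    """
    if min_step >= layout.headful_capacity:
        raise ValueError("min_step must be smaller than the headful capacity")
    w = cov.window
    if span is None:
        span = min(int(1.2 * max_steps * layout.headful_capacity),
                   layout.chromosome_length - layout.prophage_length - w)
    order, fd = _forward_profile(cov, layout)
    sel = order[fd[order] < span]
    y = cov.values[sel]
    if len(y) < 2:
        raise ValueError("need at least 2 coverage windows downstream of attR")
    pos = y[y > 0]
    eps = (pos.min() / 2.0) if len(pos) else 1e-6
    logy = np.log(y + eps)
    if penalty is None:
        penalty = _auto_penalty(logy, covered=y > 0)
    min_len = max(1, min_step // w)
    cps = piecewise_constant_dp(logy, penalty, min_len)
    bounds = [0, *cps, len(y)]
    heights = np.array([y[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])])
    # staircase: leading segments above the floor, capped at max_steps
    floor = floor_frac * heights[0] if len(heights) else 0.0
    k = 0
    while k < len(heights) and k < max_steps and heights[k] >= floor:
        k += 1
    k = max(k, 1)
    # trailing slivers much shorter than a headful are the smeared ramp
    # where the longest series end, not steps of the staircase
    seg_lens = np.diff(bounds)
    while k >= 3 and seg_lens[k - 1] < 0.5 * np.median(seg_lens[1:k - 1]):
        k -= 1
    stair_bounds = np.array(bounds[: k + 1])
    step_heights = heights[:k]
    step_lengths = np.diff(stair_bounds) * w
    cp_off = stair_bounds[1:] * w  # forward offsets of step boundaries (bp)
    L = layout.chromosome_length
    if layout.packaging_direction == 1:
        cp_abs = (layout.attR_pos + cp_off) % L
    else:
        cp_abs = (layout.attL_pos - 1 - cp_off) % L
    lt_span = int(cp_off[-1])
    un = ~cov.phage_mask
    total = cov.values[un].sum()
    in_region = un & (fd < lt_span)
    frac = float(cov.values[in_region].sum() / total) if total > 0 else float("nan")
    proc = float("nan")
    if k >= 2:
        proc = _height_decay(step_heights)
    return StaircaseFit(
        changepoints=cp_abs, step_lengths=step_lengths,
        step_heights=step_heights, processivity_hat=proc,
        lt_span=lt_span, lt_read_fraction=frac, window=w,
    )


def _height_decay(heights: np.ndarray) -> float:
    h = np.asarray(heights, dtype=float)
    if (h <= 0).any():
        h = np.clip(h, h[h > 0].min() if (h > 0).any() else 1e-12, None)
    ratio = (h[-1] / h[0]) ** (1.0 / (len(h) - 1))
    return float(np.clip(ratio, 0.0, 1.0))


def estimate_processivity(fit: StaircaseFit) -> float:
    """Geometric mean of successive step-height ratios, clamped to [0, 1]:
    the per-re-initiation continuation probability implied by the staircase."""
    if fit.n_steps < 2:
        raise ValueError("processivity undefined for a single step")
    return _height_decay(fit.step_heights)


# ---------------------------------------------------------------------------
# LT-region detection
# ---------------------------------------------------------------------------

@dataclass
class LTRegion:
    """Contiguous high-coverage region downstream of attR in the packaging
    direction, with the fraction of bacterial read mass it contains."""

    interval: CircularInterval | None
    span: int
    lt_read_fraction: float
    background: float


def detect_lt_region(cov: CoverageTrack, layout: GenomeLayout,
                     threshold: float = 5.0, smooth_windows: int = 20,
                     max_gap_windows: int = 5,
                     candidate_span: int | None = None) -> LTRegion:
    """Detect the lateral-transduction region in capsid coverage.

    Starting at the downstream prophage edge and walking in the packaging
    direction, the region extends while the smoothed coverage stays at or
    above ``threshold`` times the background (median coverage of bacterial
    windows outside the candidate zone), tolerating gaps up to
    ``max_gap_windows`` smoothed windows.
    """
    w = cov.window
    L = layout.chromosome_length
    if candidate_span is None:
        candidate_span = min(int(0.25 * L), L - layout.prophage_length - w)
    order, fd = _forward_profile(cov, layout)
    un = ~cov.phage_mask
    bg_sel = un & (fd >= candidate_span)
    background = float(np.median(cov.values[bg_sel])) if bg_sel.any() else 0.0
    sel = order[fd[order] < candidate_span]
    y = cov.values[sel]
    if smooth_windows > 1:
        kern = np.ones(smooth_windows) / smooth_windows
        ys = np.convolve(y, kern, mode="same")
    else:
        ys = y
    cut = threshold * background
    ok = (ys >= cut) & (ys > 0) if background > 0 else (ys > 0)
    end = 0
    gap = 0
    for i, flag in enumerate(ok):
        if flag:
            end = i + 1
            gap = 0
        else:
            gap += 1
            if gap > max_gap_windows:
                break
    span = end * w
    interval = None
    if span > 0:
        if layout.packaging_direction == 1:
            interval = CircularInterval.from_length(layout.attR_pos, span, L)
        else:
            interval = CircularInterval.from_length((layout.attL_pos - span) % L, span, L)
    total = cov.values[un].sum()
    in_region = un & (fd < span)
    frac = float(cov.values[in_region].sum() / total) if total > 0 else 0.0
    return LTRegion(interval=interval, span=span, lt_read_fraction=frac,
                    background=background)


# ---------------------------------------------------------------------------
# plate-count statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransductionRecord:
    """Transduction units normalized to an average phage titer of 1e9 PFU."""

    tfu_per_ml: float
    pfu_per_ml: float
    tru_per_1e9_pfu: float
    log10_tru: float
    below_detection: bool


def transduction_units(tfu_per_ml: float, pfu_per_ml: float) -> TransductionRecord:
    """TrU per 1e9 PFU: ``tfu / pfu * 1e9``; a zero transductant count is
    reported as below detection (log undefined)."""
    if pfu_per_ml <= 0:
        raise ValueError("pfu_per_ml must be positive")
    if tfu_per_ml < 0:
        raise ValueError("tfu_per_ml must be >= 0")
    tru = tfu_per_ml / pfu_per_ml * 1e9
    if tru == 0:
        return TransductionRecord(tfu_per_ml, pfu_per_ml, 0.0, float("nan"), True)
    return TransductionRecord(tfu_per_ml, pfu_per_ml, tru, math.log10(tru), False)


@dataclass(frozen=True)
class CotransductionResult:
    percent: float
    ci_low: float
    ci_high: float
    n_double: int
    n_tested: int


def cotransduction_frequency(n_double_resistant: int, n_tested: int,
                             confidence: float = 0.95) -> CotransductionResult:
    """Co-transduction frequency (double-resistant / tested) x 100 %, with
    an exact (Clopper-Pearson) binomial confidence interval."""
    if n_tested <= 0:
        raise ValueError("n_tested must be positive")
    if not 0 <= n_double_resistant <= n_tested:
        raise ValueError("n_double_resistant must be between 0 and n_tested")
    ci = stats.binomtest(n_double_resistant, n_tested).proportion_ci(
        confidence_level=confidence, method="exact")
    return CotransductionResult(
        percent=100.0 * n_double_resistant / n_tested,
        ci_low=100.0 * ci.low, ci_high=100.0 * ci.high,
        n_double=n_double_resistant, n_tested=n_tested,
    )


def ddct(ct_target: float, ct_reference: float) -> float:
    """Relative level by the 2^-dCT method."""
    if not (math.isfinite(ct_target) and math.isfinite(ct_reference)):
        raise ValueError("CT values must be finite")
    return 2.0 ** -(ct_target - ct_reference)
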