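"""Processive headful-packaging simulator.

Converts the molecule census of an induced culture into populations of
packaged capsid fragments.  Lateral-transducing (LT) series start at the
pac site of a still-integrated prophage and run unidirectionally across
attR into the chromosome; generalized-transducing (GT) series start at
pseudo-pac positions drawn uniformly on the chromosome; episomal series
package concatemerized phage DNA.  After each headful the terminase
re-initiates with probability ``processivity``, which is what produces the
step-down coverage staircase of successive headfuls.

Fragments are returned as a :class:`pandas.DataFrame` with one row per
fragment (``FRAGMENT_COLUMNS``); wrapped episomal fragments are split into
two rows sharing a series id and headful index.  Each row carries a
``weight`` so that rare GT series can be importance-oversampled without
biasing any downstream weighted statistic.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_model import CircularInterval, GenomeLayout
from .induction_sim import MoleculePool

__all__ = [
    "PackagingConfig",
    "FRAGMENT_COLUMNS",
    "simulate_packaging",
    "marker_transfer_freq",
    "capsid_coverage",
    "CoverageTrack",
]

FRAGMENT_COLUMNS = [
    "series_id", "headful_index", "origin", "start", "length",
    "phage_bp", "bacterial_bp", "weight", "part",
]

ORIGIN_LT = "LT"
ORIGIN_GT = "GT"
ORIGIN_EPISOMAL = "EPISOMAL"


@dataclass(frozen=True)
class PackagingConfig:
    """Parameters of the headful-packaging stage.

    processivity:
        Probability that a series re-initiates the next headful; the number
        of headfuls per series is truncated-geometric with expectation
        ``(1 - p**max_headfuls) / (1 - p)``.
    max_headfuls:
        Hard cap on headfuls per series.
    headful_noise_sd:
        SD in bp of the drawn headful size (``None``: 1 % of capacity).
    gt_init_prob:
        Probability per chromosome copy per packaging epoch that a GT
        series initiates at a uniform pseudo-pac position.
    series_per_template:
        Mean series launched per available integrated template.
    gt_oversample:
        Importance boost for GT series: simulate ``boost`` times more GT
        series, each carrying weight ``1/boost``.  ``None`` picks a boost
        targeting ``gt_target_series`` simulated series.
    """

    processivity: float = 0.8
    max_headfuls: int = 14
    headful_noise_sd: float | None = None
    gt_init_prob: float = 2e-4
    series_per_template: float = 1.0
    gt_oversample: float | None = 1.0
    gt_target_series: int = 200
    seed: int | None = None

    def __post_init__(self):
        if not 0 <= self.processivity <= 1:
            raise ValueError("processivity must be in [0, 1]")
        if self.max_headfuls < 1:
            raise ValueError("max_headfuls must be >= 1")
        if self.gt_init_prob < 0:
            raise ValueError("gt_init_prob must be >= 0")

    def noise_sd(self, layout: GenomeLayout) -> float:
        if self.headful_noise_sd is None:
            return 0.01 * layout.headful_capacity
        return self.headful_noise_sd

    def expected_series_length(self) -> float:
        p, m = self.processivity, self.max_headfuls
        if p == 1:
            return float(m)
        return (1 - p ** m) / (1 - p)


def _series_lengths(n: int, cfg: PackagingConfig, rng: np.random.Generator) -> np.ndarray:
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    if cfg.processivity >= 1:
        return np.full(n, cfg.max_headfuls, dtype=np.int64)
    if cfg.processivity == 0:
        return np.ones(n, dtype=np.int64)
    raw = rng.geometric(1.0 - cfg.processivity, size=n)
    return np.minimum(raw, cfg.max_headfuls).astype(np.int64)


def _headful_sizes(total: int, layout: GenomeLayout, cfg: PackagingConfig,
                   rng: np.random.Generator) -> np.ndarray:
    H = layout.headful_capacity
    sd = cfg.noise_sd(layout)
    if sd == 0:
        return np.full(total, H, dtype=np.int64)
    sizes = np.rint(rng.normal(H, sd, size=total)).astype(np.int64)
    return np.maximum(sizes, max(1, H // 10))


def _phage_overlap(starts: np.ndarray, lengths: np.ndarray, layout: GenomeLayout) -> np.ndarray:
    """bp of each [start, start+length) fragment overlapping the prophage (circular)."""
    L = layout.chromosome_length
    off = (starts - layout.prophage_start) % L  # fragment start relative to attL
    G = layout.prophage_length
    # overlap of [off, off+len) with [0, G) on circle of length L
    a = np.clip(G - off, 0, lengths)            # overlap without wrapping
    wrap = np.clip(off + lengths - L, 0, G)     # fragment wraps past origin into prophage
    return np.minimum(a + wrap, np.minimum(lengths, G))


def _build_series(n_series: int, anchor_starts: np.ndarray, origin: str,
                  layout: GenomeLayout, cfg: PackagingConfig,
                  rng: np.random.Generator, weight: float,
                  series_id0: int) -> pd.DataFrame:
    """Elongate ``n_series`` processive series from per-series anchor starts."""
    if n_series == 0:
        return pd.DataFrame({c: [] for c in FRAGMENT_COLUMNS})
    L = layout.chromosome_length
    d = layout.packaging_direction
    lens = _series_lengths(n_series, cfg, rng)
    total = int(lens.sum())
    sizes = _headful_sizes(total, layout, cfg, rng)
    series_id = np.repeat(np.arange(series_id0, series_id0 + n_series), lens)
    headful_index = np.concatenate([np.arange(1, k + 1) for k in lens]) if total else np.zeros(0, int)
    # cumulative offset of each fragment within its series
    cum = np.concatenate([[0], np.cumsum(sizes)])[:-1]
    series_first = np.concatenate([[0], np.cumsum(lens)])[:-1]
    cum = cum - np.repeat(cum[series_first], lens)
    anchors = np.repeat(anchor_starts, lens)
    if d == 1:
        starts = (anchors + cum) % L
    else:
        starts = (anchors - cum - sizes + 1) % L
    phage_bp = _phage_overlap(starts, sizes, layout)
    return pd.DataFrame({
        "series_id": series_id,
        "headful_index": headful_index,
        "origin": origin,
        "start": starts,
        "length": sizes,
        "phage_bp": phage_bp,
        "bacterial_bp": sizes - phage_bp,
        "weight": weight,
        "part": 0,
    })


def _episomal_series(n_series: int, layout: GenomeLayout, cfg: PackagingConfig,
                     rng: np.random.Generator, series_id0: int) -> pd.DataFrame:
    """Series on concatemerized phage circles, mapped back onto the prophage
    region of the reference; fragments wrapping the phage circle are split."""
    if n_series == 0:
        return pd.DataFrame({c: [] for c in FRAGMENT_COLUMNS})
    G = layout.prophage_length
    lens = _series_lengths(n_series, cfg, rng)
    total = int(lens.sum())
    sizes = _headful_sizes(total, layout, cfg, rng)
    series_id = np.repeat(np.arange(series_id0, series_id0 + n_series), lens)
    headful_index = np.concatenate([np.arange(1, k + 1) for k in lens]) if total else np.zeros(0, int)
    cum = np.concatenate([[0], np.cumsum(sizes)])[:-1]
    series_first = np.concatenate([[0], np.cumsum(lens)])[:-1]
    cum = cum - np.repeat(cum[series_first], lens)
    u = (layout.pac_offset + cum) % G  # position on the phage unit
    rows = []
    for sid, hidx, u0, size in zip(series_id, headful_index, u, sizes):
        remaining = int(size)
        pos = int(u0)
        part = 0
        while remaining > 0:
            chunk = min(remaining, G - pos)
            rows.append((sid, hidx, ORIGIN_EPISOMAL,
                         (layout.prophage_start + pos) % layout.chromosome_length,
                         chunk, chunk, 0, 1.0, part))
            remaining -= chunk
            pos = 0
            part += 1
    return pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)


def simulate_packaging(pool: MoleculePool, layout: GenomeLayout | None = None,
                       config: PackagingConfig | None = None,
                       timepoint: int | None = None,
                       seed: int | None = None) -> pd.DataFrame:
    """Package the molecule census at ``timepoint`` into capsid fragments.

    LT series launch from the pac site of integrated templates
    (``Poisson(n_integrated * series_per_template)`` series), episomal
    series from the concatemer pool, and GT series from uniform pseudo-pac
    positions with probability ``gt_init_prob`` per chromosome copy.
    """
    layout = layout or pool.layout
    cfg = config or PackagingConfig()
    rng = np.random.default_rng(seed if seed is not None else cfg.seed)
    row = pool.at(timepoint)

    n_lt = int(rng.poisson(row.n_integrated * cfg.series_per_template))
    n_epi = int(rng.poisson(
        row.n_episomal_units * cfg.series_per_template / cfg.expected_series_length()))
    gt_mean = cfg.gt_init_prob * pool.n_chromosomes
    boost = cfg.gt_oversample
    if boost is None:
        boost = max(1.0, cfg.gt_target_series / gt_mean) if gt_mean > 0 else 1.0
    n_gt = int(rng.poisson(gt_mean * boost))

    parts = []
    sid = 0
    lt = _build_series(n_lt, np.full(n_lt, layout.pac_pos), ORIGIN_LT,
                       layout, cfg, rng, 1.0, sid)
    sid += n_lt
    parts.append(lt)
    parts.append(_episomal_series(n_epi, layout, cfg, rng, sid))
    sid += n_epi
    gt_starts = rng.integers(0, layout.chromosome_length, size=n_gt)
    parts.append(_build_series(n_gt, gt_starts, ORIGIN_GT, layout, cfg, rng,
                               1.0 / boost, sid))
    frags = pd.concat(parts, ignore_index=True)
    for col in ("series_id", "headful_index", "start", "length", "phage_bp",
                "bacterial_bp", "part"):
        frags[col] = frags[col].astype(np.int64)
    frags["weight"] = frags["weight"].astype(float)
    return frags


def marker_transfer_freq(fragments: pd.DataFrame, layout: GenomeLayout,
                         marker_pos: int, pfu_equivalents: float | None = None,
                         margin: int = 2000, origin: str | None = None) -> float:
    """Frequency of transducing particles carrying a chromosomal marker.

    A fragment transduces the marker if it fully contains
    ``[marker - margin, marker + margin]`` (the flanking DNA required for
    homologous recombination in the recipient).  The weighted count is
    normalized by ``pfu_equivalents`` (default: total fragment weight, i.e.
    per packaged particle).
    """
    L = layout.chromosome_length
    if not 0 <= marker_pos < L:
        raise ValueError("marker_pos must lie on the chromosome")
    df = fragments if origin is None else fragments[fragments.origin == origin]
    if pfu_equivalents is None:
        pfu_equivalents = float(fragments.weight.sum())
    if pfu_equivalents <= 0:
        raise ValueError("pfu_equivalents must be positive")
    if len(df) == 0:
        return 0.0
    win_start = (marker_pos - margin) % L
    win_len = 2 * margin + 1
    off = (win_start - df.start.to_numpy()) % L
    contained = (off + win_len) <= df.length.to_numpy()
    return float(df.weight.to_numpy()[contained].sum() / pfu_equivalents)


@dataclass
class CoverageTrack:
    """Per-window depth over the chromosome plus a prophage mask."""

    values: np.ndarray
    window: int
    chromosome_length: int
    phage_mask: np.ndarray

    @property
    def starts(self) -> np.ndarray:
        return np.arange(0, self.chromosome_length, self.window)

    @property
    def ends(self) -> np.ndarray:
        return np.minimum(self.starts + self.window, self.chromosome_length)

    def replace_values(self, values: np.ndarray) -> "CoverageTrack":
        return CoverageTrack(np.asarray(values, dtype=float), self.window,
                             self.chromosome_length, self.phage_mask)


def _rasterize(starts: np.ndarray, lengths: np.ndarray, weights: np.ndarray,
               L: int, window: int) -> np.ndarray:
    """Weighted bp-mass per window from circular intervals (diff-array)."""
    diff = np.zeros(L + 1)
    s = starts % L
    e = s + lengths
    wrap = e > L
    np.add.at(diff, s, weights)
    np.add.at(diff, np.minimum(e, L), -weights)
    if wrap.any():
        np.add.at(diff, np.zeros(wrap.sum(), dtype=np.int64), weights[wrap])
        np.add.at(diff, (e[wrap] - L), -weights[wrap])
    per_bp = np.cumsum(diff[:-1])
    n_win = -(-L // window)
    pad = n_win * window - L
    if pad:
        per_bp = np.concatenate([per_bp, np.zeros(pad)])
    return per_bp.reshape(n_win, window).sum(axis=1)


def capsid_coverage(fragments: pd.DataFrame, layout: GenomeLayout,
                    window: int = 100) -> CoverageTrack:
    """Per-window fragment depth: weighted fragment-bp overlapping each tile
    divided by the tile width.  Prophage-internal windows are flagged by the
    mask rather than removed."""
    if window <= 0:
        raise ValueError("window must be positive")
    from .induction_sim import phage_mask
    L = layout.chromosome_length
    if len(fragments) == 0:
        n_win = -(-L // window)
        return CoverageTrack(np.zeros(n_win), window, L, phage_mask(layout, window))
    mass = _rasterize(fragments.start.to_numpy(), fragments.length.to_numpy(),
                      fragments.weight.to_numpy(), L, window)
    widths = np.minimum(window, L - np.arange(0, L, window))
    return CoverageTrack(mass / widths, window, L, phage_mask(layout, window))
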