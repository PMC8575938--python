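"""Alignment-level read simulator (WGS of induced cultures, capsid DNA).

Reads are emitted directly as alignment records — interval on the lysogen
reference plus a junction tag — rather than sequence, since the estimators
only consume coordinates.  Junction-spanning reads (chromosome-attL-prophage
vs. chromosome-attB-chromosome) are sampled from the explicit junction
molecule counts of the pool, so the attL:attB read ratio is an unbiased
readout of the integrated fraction.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_model import GenomeLayout, window_starts
from .induction_sim import MoleculePool, expected_flank_profile, phage_mask
from .packaging_sim import CoverageTrack, _rasterize

__all__ = ["AlignmentRecords", "sample_wgs_reads", "sample_capsid_reads",
           "reads_coverage"]

TAG_NONE = "none"
TAG_ATTL = "attL_spanning"
TAG_ATTB = "attB_spanning"

SOURCE_WGS = "WGS"
SOURCE_CAPSID = "CAPSID"


@dataclass
class AlignmentRecords:
    """Columnar collection of single-end alignment records.

    ``start`` is the leftmost mapped base (0-based); every read in a
    collection has the same ``read_len``.  ``junction_tag`` is one of
    ``none`` / ``attL_spanning`` / ``attB_spanning``; a junction tag is
    assigned iff the read overlaps both sides of the junction by at least
    ``min_overlap`` bp.  ``weight`` carries importance weights through from
    oversampled fragments.
    """

    start: np.ndarray
    junction_tag: np.ndarray
    source: str
    timepoint: int
    read_len: int
    chromosome_length: int
    weight: np.ndarray = field(default=None)

    def __post_init__(self):
        self.start = np.asarray(self.start, dtype=np.int64)
        self.junction_tag = np.asarray(self.junction_tag, dtype=object)
        if self.weight is None:
            self.weight = np.ones(len(self.start))
        self.weight = np.asarray(self.weight, dtype=float)

    def __len__(self) -> int:
        return len(self.start)

    def tag_counts(self) -> dict[str, int]:
        tags, counts = np.unique(self.junction_tag, return_counts=True)
        out = {TAG_NONE: 0, TAG_ATTL: 0, TAG_ATTB: 0}
        out.update(dict(zip(tags.tolist(), counts.tolist())))
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "start": self.start,
            "end": self.start + self.read_len,
            "junction_tag": self.junction_tag,
            "source": self.source,
            "timepoint": self.timepoint,
            "weight": self.weight,
        })


def sample_wgs_reads(pool: MoleculePool, layout: GenomeLayout | None = None,
                     depth: float = 50.0, read_len: int = 75,
                     min_overlap: int = 10, timepoint: int | None = None,
                     window: int = 100, seed: int | None = None) -> AlignmentRecords:
    """Sample WGS reads of an induced culture at one timepoint.

    Reads are drawn proportionally to local molecule abundance: bacterial
    windows at ``n_cells * flank_amp``, prophage windows at the summed
    integrated plus episomal phage copies, and the attL/attB junctions from
    their explicit molecule counts.  ``depth`` is the mean fold coverage of
    the unamplified bacterial baseline.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if read_len <= 2 * min_overlap:
        raise ValueError("read_len must exceed twice min_overlap")
    layout = layout or pool.layout
    rng = np.random.default_rng(seed)
    row = pool.at(timepoint)
    tp = int(row.name)
    L = layout.chromosome_length
    lam = depth / (read_len * pool.n_cells)  # per-copy per-bp read-start rate

    # junction-spanning reads: starts placed so both sides overlap >= min_overlap
    span = read_len - 2 * min_overlap + 1
    n_attL = rng.poisson(lam * row.n_integrated * span)
    n_attB = rng.poisson(lam * row.n_attB * span)
    lo = (layout.attL_pos - (read_len - min_overlap)) % L
    j_starts = (lo + rng.integers(0, span, size=n_attL + n_attB)) % L
    j_tags = np.array([TAG_ATTL] * n_attL + [TAG_ATTB] * n_attB, dtype=object)

    # bulk reads from the per-window abundance profile
    flank = expected_flank_profile(pool, timepoint=tp, window=window)
    mask = phage_mask(layout, window)
    weights = pool.n_cells * flank
    weights[mask] = row.n_integrated + row.n_episomal_units
    starts_w = window_starts(L, window)
    widths = np.minimum(window, L - starts_w)
    n_per_win = rng.poisson(lam * weights * widths)
    b_starts = np.repeat(starts_w, n_per_win) + (
        rng.random(int(n_per_win.sum())) * np.repeat(widths, n_per_win)
    ).astype(np.int64)

    starts = np.concatenate([j_starts, b_starts])
    tags = np.concatenate([j_tags, np.full(len(b_starts), TAG_NONE, dtype=object)])
    order = rng.permutation(len(starts))
    return AlignmentRecords(starts[order], tags[order], SOURCE_WGS, tp,
                            read_len, L)


def sample_capsid_reads(fragments: pd.DataFrame, layout: GenomeLayout,
                        read_len: int = 75, reads_per_kb: float = 1.0,
                        seed: int | None = None,
                        timepoint: int = -1) -> AlignmentRecords:
    """Sample reads uniformly within packaged fragments.

    Per-fragment read counts are ``Poisson(reads_per_kb * length_kb * weight)``
    — importance weights thin the oversampled fragments back to their true
    abundance, so expectations match the unboosted ensemble exactly.
    """
    if reads_per_kb < 0:
        raise ValueError("reads_per_kb must be >= 0")
    rng = np.random.default_rng(seed)
    L = layout.chromosome_length
    if len(fragments) == 0 or reads_per_kb == 0:
        return AlignmentRecords(np.zeros(0, np.int64), np.zeros(0, object),
                                SOURCE_CAPSID, timepoint, read_len, L)
    lens = fragments.length.to_numpy()
    mean = reads_per_kb * lens / 1000.0 * fragments.weight.to_numpy()
    counts = rng.poisson(mean)
    total = int(counts.sum())
    frag_start = np.repeat(fragments.start.to_numpy(), counts)
    frag_len = np.repeat(lens, counts)
    room = np.maximum(frag_len - read_len, 1)
    offs = (rng.random(total) * room).astype(np.int64)
    starts = (frag_start + offs) % L
    return AlignmentRecords(starts, np.full(total, TAG_NONE, dtype=object),
                            SOURCE_CAPSID, timepoint, read_len, L)


def reads_coverage(records: AlignmentRecords, layout: GenomeLayout,
                   window: int = 100) -> CoverageTrack:
    """Per-window read depth (read-bp overlapping each tile / tile width)."""
    L = layout.chromosome_length
    if len(records) == 0:
        n_win = -(-L // window)
        return CoverageTrack(np.zeros(n_win), window, L, phage_mask(layout, window))
    mass = _rasterize(records.start,
                      np.full(len(records), records.read_len, dtype=np.int64),
                      records.weight, L, window)
    widths = np.minimum(window, L - window_starts(L, window))
    return CoverageTrack(mass / widths, window, L, phage_mask(layout, window))
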