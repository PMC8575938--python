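"""Readers and writers for the package's flat-file interfaces.

Layouts travel as flat YAML/JSON blocks, fragments and reads as BED6(+),
coverage as bedGraph, plate counts and molecule pools as TSV.  All
coordinates are 0-based half-open; malformed lines are rejected with their
line numbers.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genome_model import GenomeLayout
from .packaging_sim import FRAGMENT_COLUMNS, CoverageTrack
from .induction_sim import MoleculePool, phage_mask

__all__ = [
    "read_layout", "write_layout", "read_bed", "write_bed",
    "read_bedgraph", "write_bedgraph", "read_counts_tsv",
    "fragments_to_bed", "bed_to_fragments", "write_pool_tsv",
    "coverage_to_bedgraph_frame", "bedgraph_frame_to_coverage",
]

_LAYOUT_FIELDS = {f.name for f in dataclasses.fields(GenomeLayout)}


def write_layout(layout: GenomeLayout, path: str | Path) -> None:
    path = Path(path)
    data = dataclasses.asdict(layout)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


def read_layout(path: str | Path) -> GenomeLayout:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: layout file must contain a flat mapping")
    unknown = set(data) - _LAYOUT_FIELDS
    if unknown:
        raise ValueError(f"{path}: unknown layout fields {sorted(unknown)}")
    for k, v in data.items():
        if not isinstance(v, int):
            raise ValueError(f"{path}: layout field {k!r} must be an integer (bp)")
    return GenomeLayout(**data)


# ---------------------------------------------------------------------------
# BED / bedGraph
# ---------------------------------------------------------------------------

def _check_bed_coords(df: pd.DataFrame, path) -> None:
    bad = df.index[(df["end"] <= df["start"]) | (df["start"] < 0)]
    if len(bad):
        lines = ", ".join(str(i + 1) for i in bad[:5])
        raise ValueError(
            f"{path}: end <= start (is the input 1-based?) on line(s) {lines}")


def read_bed(path: str | Path, extra_cols: tuple[str, ...] = ()) -> pd.DataFrame:
    """Strict BED6(+extra) reader; returns an empty frame for an empty file."""
    path = Path(path)
    names = ["chrom", "start", "end", "name", "score", "strand", *extra_cols]
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=names, dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=names)
    if len(df) == 0:
        return df
    for col in ("start", "end"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            bad = df.index[coerced.isna()]
            raise ValueError(f"{path}: non-numeric {col} on line {bad[0] + 1}")
        df[col] = coerced.astype(np.int64)
    _check_bed_coords(df, path)
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


_ORIGIN_SCORE = {"LT": 0, "GT": 1, "EPISOMAL": 2}
_SCORE_ORIGIN = {v: k for k, v in _ORIGIN_SCORE.items()}


def fragments_to_bed(fragments: pd.DataFrame, layout: GenomeLayout,
                     chrom: str = "chromosome") -> pd.DataFrame:
    """BED6 view of packaged fragments: name ``series:headful[:part]``,
    origin-coded score, strand from the packaging direction.  Fragments that
    wrap the chromosome origin are split into two rows."""
    L = layout.chromosome_length
    rows = []
    strand = "+" if layout.packaging_direction == 1 else "-"
    for f in fragments.itertuples():
        name = f"{f.series_id}:{f.headful_index}"
        if f.part:
            name += f":{f.part}"
        s, e = int(f.start), int(f.start) + int(f.length)
        pieces = [(s, e)] if e <= L else [(s, L), (0, e - L)]
        for ps, pe in pieces:
            rows.append((chrom, ps, pe, name, _ORIGIN_SCORE[f.origin], strand))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def bed_to_fragments(df: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`fragments_to_bed` for non-wrapped rows."""
    out = []
    for r in df.itertuples():
        bits = str(r.name).split(":")
        out.append((int(bits[0]), int(bits[1]), _SCORE_ORIGIN[int(r.score)],
                    int(r.start), int(r.end) - int(r.start), 0, 0, 1.0,
                    int(bits[2]) if len(bits) > 2 else 0))
    return pd.DataFrame(out, columns=FRAGMENT_COLUMNS)


def coverage_to_bedgraph_frame(cov: CoverageTrack, chrom: str = "chromosome") -> pd.DataFrame:
    """Run-length-merged bedGraph rows for a coverage track."""
    vals = cov.values
    starts = cov.starts
    ends = cov.ends
    keep = np.concatenate([[True], vals[1:] != vals[:-1]])
    run_start = starts[keep]
    run_val = vals[keep]
    run_end = np.concatenate([run_start[1:], [ends[-1]]])
    return pd.DataFrame({"chrom": chrom, "start": run_start.astype(np.int64),
                         "end": run_end.astype(np.int64), "value": run_val})


def write_bedgraph(cov: CoverageTrack, path: str | Path, chrom: str = "chromosome") -> None:
    coverage_to_bedgraph_frame(cov, chrom).to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    names = ["chrom", "start", "end", "value"]
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", names=names,
                         dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=names)
    for col in ("start", "end"):
        df[col] = df[col].astype(np.int64)
    _check_bed_coords(df, path)
    return df


def bedgraph_frame_to_coverage(df: pd.DataFrame, layout: GenomeLayout,
                               window: int) -> CoverageTrack:
    """Re-expand a bedGraph frame onto a fixed window grid."""
    L = layout.chromosome_length
    n_win = -(-L // window)
    vals = np.zeros(n_win)
    for r in df.itertuples():
        w0, w1 = int(r.start) // window, -(-int(r.end) // window)
        vals[w0:w1] = r.value
    return CoverageTrack(vals, window, L, phage_mask(layout, window))


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Plate-count table: columns sample, dilution, tfu, pfu."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "dilution", "tfu", "pfu"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_pool_tsv(pool: MoleculePool, path: str | Path) -> None:
    """Molecule census as TSV, one row per timepoint x species."""
    long = pool.counts.reset_index().melt(id_vars="timepoint",
                                          var_name="species", value_name="count")
    long.to_csv(path, sep="\t", index=False)
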