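"""Named end-to-end scenarios binding induction, packaging, read simulation
and estimation, with deterministic per-stage seeding and a machine-readable
summary.

Presets mirror the classic P22 strain panel: SOS-induced wild type, the
heat-inducible repressor mutant, the replication/excision knockouts, lytic
infection, an ES18-like lysogen, and an inducible-excision time sweep.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .genome_model import GenomeLayout
from .induction_sim import InductionConfig, MoleculePool, simulate_induction, expected_flank_profile
from .packaging_sim import PackagingConfig, capsid_coverage, marker_transfer_freq, simulate_packaging
from .readsim import reads_coverage, sample_capsid_reads, sample_wgs_reads
from . import estimators as est

logger = logging.getLogger("headful")

__all__ = ["ScenarioConfig", "preset", "PRESETS", "run_scenario"]


@dataclass(frozen=True)
class ScenarioConfig:
    """Bundle of layout + stage configs + estimator thresholds for one run."""

    name: str
    layout: GenomeLayout
    induction: InductionConfig
    packaging: PackagingConfig = PackagingConfig()
    wgs_depth: float = 50.0
    capsid_reads_per_kb: float = 1.0
    read_len: int = 75
    min_overlap: int = 10
    window: int = 100
    lt_threshold: float = 5.0
    marker_margin: int = 2000
    seed: int = 0

    def stage_seeds(self) -> dict[str, int]:
        """Deterministic per-stage child seeds (< 2**31) derived from seed."""
        stages = ("induction", "packaging", "wgs", "capsid")
        ss = np.random.SeedSequence(self.seed)
        children = ss.spawn(len(stages))
        return {s: int(c.generate_state(1)[0] % (2 ** 31)) for s, c in zip(stages, children)}

    def config_hash(self) -> str:
        blob = json.dumps(_serialize(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _serialize(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _serialize(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, frozenset):
        return sorted(obj)
    if isinstance(obj, (tuple, list)):
        return [_serialize(x) for x in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _base(name: str, **ind_kw) -> ScenarioConfig:
    return ScenarioConfig(
        name=name,
        layout=GenomeLayout.p22_default(),
        induction=InductionConfig(**ind_kw),
        packaging=PackagingConfig(gt_oversample=None),
    )


PRESETS = {
    "P22_SOS_WT": lambda: _base("P22_SOS_WT", mode="SOS"),
    "P22_thermal_tsc": lambda: _base("P22_thermal_tsc", mode="thermal"),
    "P22_dpri": lambda: _base("P22_dpri", mode="SOS", knockouts=frozenset({"pri"})),
    "P22_dint": lambda: _base("P22_dint", mode="SOS", knockouts=frozenset({"int"})),
    "P22_dxis": lambda: _base("P22_dxis", mode="SOS", knockouts=frozenset({"xis"})),
    "P22_infection": lambda: _base("P22_infection", mode="infection"),
    "ES18_SOS_WT": lambda: replace(
        _base("ES18_SOS_WT", mode="SOS", timepoints=(0, 60, 90, 120)),
        layout=GenomeLayout.es18_default()),
}


def preset(name: str, seed: int = 0, **overrides) -> ScenarioConfig:
    """Instantiate a named preset; ``arabinose_sweep(T)`` selects the
    inducible-excision scenario with int/xis expressed at minute ``T``."""
    if name.startswith("arabinose_sweep"):
        t = float(name.partition("(")[2].rstrip(")")) if "(" in name else 0.0
        cfg = arabinose_sweep(t)
    elif name in PRESETS:
        cfg = PRESETS[name]()
    else:
        raise KeyError(f"unknown preset {name!r}; choose from "
                       f"{sorted(PRESETS) + ['arabinose_sweep(T)']}")
    return replace(cfg, seed=seed, **overrides)


def arabinose_sweep(t_arabinose: float, epoch: int = 250) -> ScenarioConfig:
    """Int/Xis expressed in trans at ``t_arabinose`` minutes after SOS
    induction of an excision-deficient lysogen; packaging is assessed at a
    fixed late epoch."""
    ind = InductionConfig(
        mode="SOS",
        timepoints=(0, 60, 120, 180, 240, epoch),
        forced_excision_time=t_arabinose,
        k_exc=0.2,
    )
    return replace(_base("arabinose_sweep"), name=f"arabinose_sweep({t_arabinose:g})",
                   induction=ind)


# ---------------------------------------------------------------------------
# end-to-end runner
# ---------------------------------------------------------------------------

def run_scenario(config: ScenarioConfig, out_dir: str | Path | None = None,
                 write_reads: bool = False) -> dict:
    """Execute induction -> packaging -> read simulation -> all estimators.

    Returns the summary dict; if ``out_dir`` is given, also writes the
    interface files (layout, pools, flank/coverage bedGraphs, fragment BED,
    summary JSON).  Identical config + seed give byte-identical outputs.
    """
    lay = config.layout
    seeds = config.stage_seeds()
    logger.info("scenario %s seed=%d config=%s", config.name, config.seed,
                config.config_hash())

    pool = simulate_induction(config.induction, lay, seed=seeds["induction"])

    # junction counts + integration percentage per timepoint
    integration = {}
    counts = {}
    for i, tp in enumerate(pool.timepoints):
        rec = sample_wgs_reads(pool, lay, depth=config.wgs_depth,
                               read_len=config.read_len,
                               min_overlap=config.min_overlap, timepoint=tp,
                               window=config.window, seed=seeds["wgs"] + i)
        jc = est.count_junction_reads(rec)
        counts[tp] = jc
        tot = jc.n_attL + jc.n_attB
        integration[tp] = est.integration_percentage(jc) if tot else None
    fisher = {}
    tps = pool.timepoints
    for a, b in zip(tps[:-1], tps[1:]):
        ca, cb = counts[a], counts[b]
        try:
            fisher[f"{a}v{b}"] = est.fisher_timepoints(ca, cb)
        except ValueError:
            fisher[f"{a}v{b}"] = None

    # packaging at the last timepoint and capsid sequencing
    frags = simulate_packaging(pool, lay, config.packaging, seed=seeds["packaging"])
    capsid = sample_capsid_reads(frags, lay, read_len=config.read_len,
                                 reads_per_kb=config.capsid_reads_per_kb,
                                 seed=seeds["capsid"])
    cov = reads_coverage(capsid, lay, window=config.window)
    rel = est.relative_coverage(cov) if cov.values[~cov.phage_mask].sum() > 0 else None

    summary: dict = {
        "name": config.name,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_cells": pool.n_cells,
        "timepoints": list(tps),
        "junction_counts": {str(t): [counts[t].n_attL, counts[t].n_attB] for t in tps},
        "integration_percentage": {str(t): integration[t] for t in tps},
        "fisher_p": fisher,
        "pool": {str(t): {k: float(v) for k, v in pool.counts.loc[t].items()} for t in tps},
        "n_fragments": {o: int((frags.origin == o).sum()) for o in ("LT", "GT", "EPISOMAL")},
    }

    if rel is not None and len(frags):
        fit = est.segment_staircase(rel, lay)
        region = est.detect_lt_region(rel, lay, threshold=config.lt_threshold)
        lt_marker = (lay.attR_pos + 10_000) % lay.chromosome_length
        gt_marker = (lay.attR_pos - 1_000_000) % lay.chromosome_length
        f_lt = marker_transfer_freq(frags, lay, lt_marker, margin=config.marker_margin)
        f_gt = marker_transfer_freq(frags, lay, gt_marker, margin=config.marker_margin)
        summary.update({
            "staircase": {
                "n_steps": fit.n_steps,
                "mean_step_length": fit.mean_step_length,
                "processivity_hat": fit.processivity_hat,
                "lt_span": fit.lt_span,
                "step_heights": [float(h) for h in fit.step_heights],
                "changepoints": [int(c) for c in fit.changepoints],
            },
            "lt_region": {
                "span": region.span,
                "lt_read_fraction": region.lt_read_fraction,
                "background": region.background,
            },
            "marker_freq": {
                "lt_first_headful": f_lt,
                "gt_unlinked": f_gt,
                "log10_ratio": (np.log10(f_lt / f_gt) if f_lt > 0 and f_gt > 0 else None),
            },
        })

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        hio.write_layout(lay, out / "layout.yaml")
        hio.write_pool_tsv(pool, out / "molecule_pools.tsv")
        flank = expected_flank_profile(pool, window=config.window)
        from .packaging_sim import CoverageTrack
        from .induction_sim import phage_mask
        ft = CoverageTrack(flank, config.window, lay.chromosome_length,
                           phage_mask(lay, config.window))
        hio.write_bedgraph(ft, out / "flank_amplification.bedgraph")
        hio.write_bed(hio.fragments_to_bed(frags, lay), out / "fragments.bed")
        hio.write_bedgraph(cov, out / "capsid_coverage.bedgraph")
        if rel is not None:
            hio.write_bedgraph(rel, out / "capsid_relative_coverage.bedgraph")
        if write_reads:
            capsid.to_dataframe().to_csv(out / "capsid_reads.tsv", sep="\t", index=False)
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True, default=float) + "\n")
    return summary
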