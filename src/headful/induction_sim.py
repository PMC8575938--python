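"""Stochastic per-cell simulator of the post-induction prophage program.

Each cell of an induced lysogen culture is stepped in 1-minute increments
through de-repression, in situ (theta) replication of the integrated
prophage with escape replication into the flanking chromosome, excision,
episomal amplification of excised circles, and Int-mediated reintegration
of circles into empty attB junctions.  The aggregate census of DNA species
per timepoint is returned as a :class:`MoleculePool`.

The two temporal programs of temperate-phage induction emerge from the
kinetics alone: with thermal induction of a heat-inducible repressor mutant
excision precedes replication (ERP), while SOS induction delays int/xis
expression past the onset of in situ replication (RPE), which is what
permits lateral transduction.

Kinetic constants are phenomenological: they are chosen so the simulator
reproduces the qualitative integration-percentage and coverage trajectories
of induced Salmonella lysogens, and every one of them is exposed on
:class:`InductionConfig`.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome_model import GenomeLayout, window_starts

__all__ = ["InductionConfig", "MoleculePool", "simulate_induction", "expected_flank_profile"]

_MODES = ("SOS", "thermal", "infection")

#: mode-resolved defaults: (derepression mean, sd), spont fraction,
#: int/xis delay, excision rate, reintegration rate
_MODE_DEFAULTS = {
    #            dere_mu dere_sd spont intxis  k_exc reint
    "SOS":       (35.0,   10.0,   0.0,  30.0,  0.05, 0.02),
    "thermal":   (0.0,    0.0,    0.05, 0.0,   0.20, 0.0),
    "infection": (0.0,    0.0,    0.0,  0.0,   0.20, 0.0),
}


@dataclass(frozen=True)
class InductionConfig:
    """Kinetic parameters of the induction simulator.

    Any field left as ``None`` is filled from the mode-resolved default
    table (SOS / thermal / infection differ in de-repression timing, int/xis
    onset, excision rate and reintegration, reflecting the very different
    repressor-inactivation kinetics of the two induction routes).

    Notable parameters
    ------------------
    derepression_mean, derepression_sd:
        Minutes from induction to phage-gene de-repression, drawn per cell
        from a truncated normal (>= 0).  SOS default mean 35 / sd 10
        (repressor autocleavage takes tens of minutes); thermal 0.
    spont_fraction:
        Fraction of cells de-repressed before t=0 (leaky heat-inducible
        mutant); those cells are started ``spont_head_start`` minutes early.
    intxis_delay:
        Minutes from de-repression to excisionase availability (SOS 30,
        thermal 0: int/xis are late vs. immediate in the two programs).
    k_exc:
        Per-copy excision rate (1/min) once excisionase is available,
        saturating at ``exc_sat`` copies per cell (limited excisionase).
    repl_delay, repl_doubling:
        Minutes from de-repression to theta initiation, and minutes per
        in situ doubling of the integrated array.
    copy_cap:
        Per-cell capacity in phage genome equivalents shared by integrated
        copies and the episomal pool: in situ doubling stops once the cell's
        total phage DNA reaches it (replication machinery titration).
    escape_scale:
        Decay length (bp) of the escape-replication amplification gradient
        extending from the prophage edges into the flanking chromosome.
    episomal_amp, episomal_cap:
        Fold amplification of excised circles per ``repl_doubling`` interval
        and the per-cell ceiling on episomal genome equivalents.
    reint_rate, reint_sat:
        Int-mediated reintegration of a circle into an attB junction:
        per-attB per-minute probability ``reint_rate * min(epi, reint_sat)``.
    forced_excision_time:
        If set, models plasmid-complemented int/xis under an inducible
        promoter: excision becomes available for every cell at this absolute
        time (rate ``k_exc``) regardless of de-repression; reintegration is
        disabled (Xis co-expressed).
    knockouts:
        Subset of {"pri", "int", "xis"}.  ``pri`` abolishes all replication;
        ``int`` or ``xis`` abolishes excision (and ``int`` reintegration).
    """

    mode: str = "SOS"
    n_cells: int = 1000
    timepoints: tuple[int, ...] = (0, 30, 60, 90)
    derepression_mean: float | None = None
    derepression_sd: float | None = None
    spont_fraction: float | None = None
    spont_head_start: float = 30.0
    intxis_delay: float | None = None
    k_exc: float | None = None
    exc_sat: float = 4.0
    repl_delay: float = 10.0
    repl_doubling: float = 10.0
    copy_cap: int = 64
    escape_scale: float = 50_000.0
    episomal_amp: float = 4.0
    episomal_cap: float = 400.0
    reint_rate: float | None = None
    reint_sat: float = 20.0
    forced_excision_time: float | None = None
    knockouts: frozenset[str] = frozenset()
    seed: int | None = None

    def __post_init__(self):
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        bad = set(self.knockouts) - {"pri", "int", "xis"}
        if bad:
            raise ValueError(f"unknown knockouts: {sorted(bad)}")
        object.__setattr__(self, "knockouts", frozenset(self.knockouts))
        object.__setattr__(self, "timepoints", tuple(int(t) for t in self.timepoints))
        mu, sd, sp, ix, k, r = _MODE_DEFAULTS[self.mode]
        for name, val in (
            ("derepression_mean", mu),
            ("derepression_sd", sd),
            ("spont_fraction", sp),
            ("intxis_delay", ix),
            ("k_exc", k),
            ("reint_rate", r),
        ):
            if getattr(self, name) is None:
                object.__setattr__(self, name, val)
        if not 0 <= self.spont_fraction <= 1:
            raise ValueError("spont_fraction must be a probability")
        for name in ("k_exc", "intxis_delay", "derepression_sd", "reint_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def resolved_k_exc(self) -> float:
        if "int" in self.knockouts or "xis" in self.knockouts:
            return 0.0
        return self.k_exc

    @property
    def has_replication(self) -> bool:
        return "pri" not in self.knockouts

    @property
    def resolved_reint_rate(self) -> float:
        if "int" in self.knockouts or self.forced_excision_time is not None:
            return 0.0
        return self.reint_rate


@dataclass
class MoleculePool:
    """Per-timepoint census of DNA species for an induced culture.

    ``counts`` is indexed by timepoint (minutes) with columns:

    - ``n_integrated``  attL/attR junction copies (chromosome-attL-prophage)
    - ``n_attB``        empty chr:chr junction copies
    - ``n_circles``     excised circles not (yet) reintegrated
    - ``n_episomal_units``  phage genome equivalents in episomal DNA
    - ``flank_added``   cumulative in situ copies created (escape-replication
      gradient mass)
    - ``exc_pre_repl`` / ``exc_total``  cumulative excision events before the
      cell's first replication event / overall (ERP-vs-RPE discriminator)
    - ``reintegrations``  cumulative circle-to-attB reintegration events
    """

    counts: pd.DataFrame
    layout: GenomeLayout
    config: InductionConfig
    n_cells: int

    @property
    def timepoints(self) -> list[int]:
        return list(self.counts.index)

    def at(self, timepoint: int | None = None) -> pd.Series:
        if timepoint is None:
            timepoint = self.counts.index[-1]
        return self.counts.loc[timepoint]

    def integrated_fraction(self, timepoint: int | None = None) -> float:
        row = self.at(timepoint)
        tot = row.n_integrated + row.n_attB
        if tot == 0:
            return float("nan")
        return row.n_integrated / tot

    @property
    def n_chromosomes(self) -> int:
        return self.n_cells


def simulate_induction(config: InductionConfig, layout: GenomeLayout,
                       seed: int | None = None) -> MoleculePool:
    """Run the per-cell 1-minute-step induction program.

    Per minute and cell, in order: scheduled in situ doubling of the
    integrated array (while total phage DNA is below ``copy_cap``), episomal
    amplification, Bernoulli excision of up to ``exc_sat`` copies, and
    reintegration of circles into attB junctions.  Every excision converts
    one integrated copy into one circle plus one attB junction; every
    reintegration does the reverse.
    """
    cfg = config
    rng = np.random.default_rng(seed if seed is not None else cfg.seed)
    n = cfg.n_cells

    # de-repression times
    tau = np.full(n, 0.0)
    if cfg.derepression_sd > 0:
        tau = rng.normal(cfg.derepression_mean, cfg.derepression_sd, size=n)
        while np.any(tau < 0):  # truncate at zero by redrawing
            bad = tau < 0
            tau[bad] = rng.normal(cfg.derepression_mean, cfg.derepression_sd, size=bad.sum())
    else:
        tau[:] = cfg.derepression_mean
    if cfg.spont_fraction > 0:
        spont = rng.random(n) < cfg.spont_fraction
        tau[spont] = -cfg.spont_head_start

    if cfg.mode == "infection":
        A = np.zeros(n, dtype=np.int64)       # integrated copies
        epi = np.ones(n)                      # injected genome circularises
        circ = np.ones(n, dtype=np.int64)
    else:
        A = np.ones(n, dtype=np.int64)
        epi = np.zeros(n)
        circ = np.zeros(n, dtype=np.int64)
    B = np.zeros(n, dtype=np.int64)           # attB junctions
    added = np.zeros(n)                       # cumulative in situ copies created
    first_repl = np.full(n, np.inf)
    exc_pre = 0
    exc_total = 0
    reint_total = 0

    k = cfg.resolved_k_exc
    p_exc = 1.0 - np.exp(-k) if k > 0 else 0.0
    r_re = cfg.resolved_reint_rate
    eg = cfg.episomal_amp ** (1.0 / cfg.repl_doubling)
    horizon = max(cfg.timepoints)
    t0 = min(0, int(np.floor(tau.min())))
    tp_set = set(cfg.timepoints)
    rows = {}

    def record(t):
        rows[t] = dict(
            n_integrated=int(A.sum()),
            n_attB=int(B.sum()),
            n_circles=int(circ.sum()),
            n_episomal_units=float(epi.sum()),
            flank_added=float(added.sum()),
            exc_pre_repl=int(exc_pre),
            exc_total=int(exc_total),
            reintegrations=int(reint_total),
        )

    for t in range(t0, horizon + 1):
        if t in tp_set:
            record(t)
        s = t - tau
        # (1) scheduled in situ doubling, capacity shared with episomal pool
        if cfg.has_replication:
            due = (s >= cfg.repl_delay) & (
                np.floor(s - cfg.repl_delay) % cfg.repl_doubling < 1.0
            ) & (A > 0)
            if due.any():
                room = np.maximum(cfg.copy_cap - np.floor(epi), A).astype(np.int64)
                newA = np.where(due, np.minimum(2 * A, np.maximum(room, A)), A)
                gained = newA - A
                added += gained
                grew = gained > 0
                first_repl[grew] = np.minimum(first_repl[grew], t)
                A = newA
            # (2) episomal amplification
            egrow = (epi > 0) & (s >= cfg.repl_delay)
            if egrow.any():
                epi = np.where(egrow, np.minimum(epi * eg, cfg.episomal_cap), epi)
                first_repl[egrow] = np.minimum(first_repl[egrow], t)
        # (3) excision
        if p_exc > 0:
            if cfg.forced_excision_time is not None:
                active = (t >= cfg.forced_excision_time) & (A > 0)
            else:
                active = (s >= cfg.intxis_delay) & (A > 0)
            if active.any():
                eligible = np.minimum(A, int(np.ceil(cfg.exc_sat)))
                X = rng.binomial(np.where(active, eligible, 0), p_exc)
                X = np.minimum(X, A)
                nX = int(X.sum())
                if nX:
                    A -= X
                    B += X
                    circ += X
                    epi += X
                    exc_total += nX
                    exc_pre += int(X[first_repl > t].sum())
        # (4) reintegration of circles into attB junctions
        if r_re > 0:
            can = (B > 0) & (circ > 0)
            if can.any():
                p_re = np.clip(r_re * np.minimum(epi, cfg.reint_sat), 0.0, 1.0)
                Y = rng.binomial(np.where(can, B, 0), p_re)
                Y = np.minimum(Y, np.minimum(circ, np.floor(epi).astype(np.int64)))
                nY = int(Y.sum())
                if nY:
                    A += Y
                    B -= Y
                    circ -= Y
                    epi -= Y
                    reint_total += nY

    counts = pd.DataFrame.from_dict(rows, orient="index").loc[list(cfg.timepoints)]
    counts.index.name = "timepoint"
    return MoleculePool(counts=counts, layout=layout, config=cfg, n_cells=n)


def expected_flank_profile(pool: MoleculePool, timepoint: int | None = None,
                           window: int = 100) -> np.ndarray:
    """Per-window escape-replication multiplier along the chromosome.

    Each in situ copy created deposits a two-sided exponential gradient
    ``exp(-d / escape_scale)`` with ``d`` the distance from the nearest
    prophage edge, so the relative amplification of a bacterial window is
    ``1 + (copies created per cell) * exp(-d / escape_scale)``.  Windows
    inside the prophage are returned as 1 (phage abundance is tracked
    separately in the pool).
    """
    lay = pool.layout
    row = pool.at(timepoint)
    c = row.flank_added / pool.n_cells
    L = lay.chromosome_length
    centers = window_starts(L, window) + np.minimum(window, L - window_starts(L, window)) / 2.0
    d_right = (centers - lay.attR_pos) % L
    d_left = (lay.attL_pos - centers) % L
    d = np.minimum(d_left, d_right)
    prof = 1.0 + c * np.exp(-d / pool.config.escape_scale)
    inside = ((centers - lay.prophage_start) % L) < lay.prophage_length
    prof[inside] = 1.0
    return prof


def phage_mask(layout: GenomeLayout, window: int = 100) -> np.ndarray:
    """Boolean mask of windows whose centre lies inside the prophage."""
    L = layout.chromosome_length
    starts = window_starts(L, window)
    centers = starts + np.minimum(window, L - starts) / 2.0
    return ((centers - layout.prophage_start) % L) < layout.prophage_length
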