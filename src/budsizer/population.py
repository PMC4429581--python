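"""Asynchronous culture simulator.

Grows a whole population from a single progenitor: every live cell is
advanced by the same global Euler step, threshold transitions fire per
cell, and completed mitoses split cells into mother and daughter, so the
pedigree of the culture is fully traceable.  Nutrient conditions scale the
``growth`` parameter; the ``OE-CLN`` mutant doubles the CLN transcription
burst probability.

Two engines produce identical results: a vectorised numba kernel (default)
and a plain per-cell reference loop built directly on
:mod:`budsizer.dynamics`.  Both consume one shared array of uniform draws
per global step, with cells in creation (id) order, so a run is
reproducible bit-for-bit from ``(params, condition, n_final, seed)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd
from numba import njit

from .dynamics import (
    G1, S, G2, M, PHASE_NAMES, VOLUME_CLOSURE,
    CellState, CycleRecord, ModelParams,
    area_to_volume, check_transition, divide, step,
)

__all__ = [
    "Condition", "CONDITIONS", "Population",
    "apply_condition", "apply_mutant_oe_cln", "simulate_culture",
]


# ---------------------------------------------------------------------------
# nutrient conditions and mutants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Condition:
    """A nutrient condition: a named multiplier on the growth parameter."""
    name: str
    multiplier: float


#: carbon sources ordered from rich to poor; multipliers are relative to
#: glucose (growth_ethanol = growth_glucose * 0.5, etc.)
CONDITIONS: dict[str, Condition] = {
    "glucose": Condition("glucose", 1.0),
    "galactose": Condition("galactose", 0.77),
    "raffinose": Condition("raffinose", 0.6),
    "ethanol": Condition("ethanol", 0.5),
}


def apply_condition(params: ModelParams,
                    condition: Union[str, Condition]) -> ModelParams:
    """Scale ``growth`` by the condition multiplier; nothing else changes."""
    if isinstance(condition, str):
        try:
            condition = CONDITIONS[condition]
        except KeyError:
            raise ValueError(f"unknown condition {condition!r}") from None
    return params.with_(growth=params.growth * condition.multiplier)


def apply_mutant_oe_cln(params: ModelParams) -> ModelParams:
    """Double CLN expression (the *OE-CLN* mutant, mimicking CLN3
    overexpression) by doubling the CLN burst probability."""
    p = 2.0 * params.p_cln
    if p * params.dt > 1.0:
        raise ValueError("doubled burst probability exceeds 1 per step")
    return params.with_(p_cln=p)


# ---------------------------------------------------------------------------
# vectorised step kernel (mirrors dynamics.step / check_transition exactly)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _step_kernel(n, t_new, phase, phase_entry, am, ad, br, mcln, mclb,
                 cln, clb, t_start, v_start, div_flag, u,
                 growth, kp1, kp2, kr_g1, kam_g1, kad_g1,
                 kr_s, kam_s, kad_s, kd, p_cln, p_clb,
                 threshold, s_dur, m_dur, m_br, m_ba,
                 loc_f, is_model2, dt, sph):  # pragma: no cover - exercised via wrapper
    ndiv = 0
    for i in range(n):
        ph = phase[i]
        # transcription: burst before decay, gated by phase
        m_n = mcln[i]
        if ph == G1 and u[i, 0] < p_cln * dt:
            m_n = m_n + 1.0
        mcln[i] = m_n * (1.0 - kd * dt)
        m_b = mclb[i]
        if ph == G2 and u[i, 1] < p_clb * dt:
            m_b = m_b + 1.0
        mclb[i] = m_b * (1.0 - kd * dt)
        # geometry
        a_m = am[i]
        a_d = ad[i]
        v_m = a_m * math.sqrt(a_m) / sph
        v_d = a_d * math.sqrt(a_d) / sph
        a = a_m + a_d
        v = v_m + v_d
        aov = a / v
        # cyclins (updated mRNA feeds production; translation phase-gated)
        d_cln = -kd * cln[i]
        if ph == G1:
            d_cln += kp1 * mcln[i] * br[i] * aov
        d_clb = -kd * clb[i]
        if ph == G2:
            loc = 1.0
            if is_model2:
                loc = (1.0 - loc_f) + loc_f * (v_d / v)
            d_clb += kp2 * mclb[i] * br[i] * aov * loc
        # biomass allocation by phase
        if ph == G1:
            k_r = kr_g1
            k_am = kam_g1
            k_ad = kad_g1
        else:
            k_r = kr_s
            k_am = kam_s
            k_ad = kad_s
        den = k_r + k_am + k_ad
        base = growth * br[i] * aov
        db_r = base * m_br * (k_r / den)
        db_am = base * m_ba * (k_am / den)
        db_ad = base * m_ba * (k_ad / den)
        cln[i] += dt * d_cln
        clb[i] += dt * d_clb
        br[i] += dt * db_r
        am[i] += dt * db_am   # area increments identified with structural biomass
        ad[i] += dt * db_ad
        # at most one transition per step, evaluated at the new time
        if ph == G1:
            if cln[i] >= threshold:
                phase[i] = S
                phase_entry[i] = t_new
                t_start[i] = t_new
                a_m = am[i]
                a_d = ad[i]
                v_start[i] = (a_m * math.sqrt(a_m) / sph
                              + a_d * math.sqrt(a_d) / sph)
        elif ph == S:
            if t_new - phase_entry[i] >= s_dur:
                phase[i] = G2
                phase_entry[i] = t_new
        elif ph == G2:
            if clb[i] >= threshold:
                phase[i] = M
                phase_entry[i] = t_new
        else:  # M
            if t_new - phase_entry[i] >= m_dur:
                div_flag[i] = True
                ndiv += 1
    return ndiv


# ---------------------------------------------------------------------------
# population container
# ---------------------------------------------------------------------------

class Population:
    """A simulated culture: live-cell state arrays, cycle records, pedigree.

    Cells are stored in creation order; a cell's id equals its array index.
    The population only grows (no cell death), so every index is live.
    """

    _FLOAT_FIELDS = ("phase_entry", "am", "ad", "br", "mcln", "mclb",
                     "cln", "clb", "birth_time", "t_start", "v_start",
                     "cycle_t0", "cycle_v0")

    def __init__(self, params: ModelParams, condition: Condition,
                 n_final: int, seed: int, capacity: int = 256):
        self.params = params              # condition-scaled parameters
        self.condition = condition
        self.n_final = n_final
        self.seed = seed
        self.clock = 0.0
        self.n = 0
        self.records: list[CycleRecord] = []
        self.timeseries: Optional[pd.DataFrame] = None
        cap = max(capacity, 2 * n_final)
        self.phase = np.zeros(cap, dtype=np.int8)
        self.repl_age = np.zeros(cap, dtype=np.int32)
        self.cycle_age = np.zeros(cap, dtype=np.int32)
        self.parent = np.full(cap, -1, dtype=np.int64)
        for name in self._FLOAT_FIELDS:
            setattr(self, name, np.zeros(cap, dtype=np.float64))

    # -- construction -------------------------------------------------------

    def add_cell(self, *, parent: int, age: int, t: float, a_m: float,
                 a_d: float, b_r: float, mcln: float, mclb: float,
                 cln: float, clb: float) -> int:
        i = self.n
        if i >= self.phase.shape[0]:
            self._grow()
        self.phase[i] = G1
        self.repl_age[i] = age
        self.cycle_age[i] = age
        self.parent[i] = parent
        self.phase_entry[i] = t
        self.am[i] = a_m
        self.ad[i] = a_d
        self.br[i] = b_r
        self.mcln[i] = mcln
        self.mclb[i] = mclb
        self.cln[i] = cln
        self.clb[i] = clb
        self.birth_time[i] = t
        self.t_start[i] = np.nan
        self.v_start[i] = np.nan
        self.cycle_t0[i] = t
        self.cycle_v0[i] = area_to_volume(a_m) + area_to_volume(a_d)
        self.n += 1
        return i

    def _grow(self) -> None:
        cap = 2 * self.phase.shape[0]
        for name in ("phase", "repl_age", "cycle_age", "parent",
                     *self._FLOAT_FIELDS):
            arr = getattr(self, name)
            new = np.empty(cap, dtype=arr.dtype)
            new[: arr.shape[0]] = arr
            if name == "parent":
                new[arr.shape[0]:] = -1
            setattr(self, name, new)

    # -- views --------------------------------------------------------------

    @property
    def ages(self) -> np.ndarray:
        """Replicative ages of all live cells."""
        return self.repl_age[: self.n]

    @property
    def volumes(self) -> np.ndarray:
        """Total volumes (mother body + bud) of all live cells."""
        a_m = self.am[: self.n]
        a_d = self.ad[: self.n]
        return (a_m * np.sqrt(a_m) + a_d * np.sqrt(a_d)) / VOLUME_CLOSURE

    @property
    def pedigree(self) -> dict[int, list[int]]:
        """Parent id -> list of children ids (creation order)."""
        tree: dict[int, list[int]] = {}
        for child in range(self.n):
            p = int(self.parent[child])
            if p >= 0:
                tree.setdefault(p, []).append(child)
        return tree

    def records_frame(self) -> pd.DataFrame:
        """All completed cycles as a tidy table (one row per cycle)."""
        cols = ["cell_id", "replicative_age", "role", "t_birth", "t_start",
                "t_division", "v_birth", "v_start", "v_division", "v_bud"]
        df = pd.DataFrame(
            [[getattr(r, c) for c in cols] for r in self.records],
            columns=cols)
        df["t_g1"] = df["t_start"] - df["t_birth"]
        df["t_sg2m"] = df["t_division"] - df["t_start"]
        df["generation_time"] = df["t_division"] - df["t_birth"]
        df["condition"] = self.condition.name
        df["variant"] = self.params.variant
        return df

    def live_frame(self) -> pd.DataFrame:
        """Snapshot of all live cells at the stop time."""
        n = self.n
        return pd.DataFrame({
            "cell_id": np.arange(n),
            "parent_id": self.parent[:n],
            "replicative_age": self.repl_age[:n],
            "phase": [PHASE_NAMES[p] for p in self.phase[:n]],
            "volume": self.volumes,
            "b_r": self.br[:n],
            "birth_time": self.birth_time[:n],
        })


# ---------------------------------------------------------------------------
# simulation driver
# ---------------------------------------------------------------------------

#: progenitor defaults: a newborn-sized G1 cell with unit biosynthetic
#: capacity and empty mRNA/cyclin pools; the population attractor is
#: reached within a few generations so this only shapes the transient
PROGENITOR_AREA = 10.0
PROGENITOR_BR = 1.0


def simulate_culture(params: ModelParams,
                     condition: Union[str, Condition] = "glucose",
                     n_final: int = 1000,
                     seed: int = 0,
                     engine: str = "fast",
                     max_minutes: float = 200000.0,
                     record_timeseries: bool = False,
                     progenitor_area: float = PROGENITOR_AREA,
                     progenitor_br: float = PROGENITOR_BR) -> Population:
    """Grow a culture from one progenitor until ``n_final`` live cells.

    ``params`` are glucose-reference parameters; ``condition`` scales the
    growth rate.  ``engine`` is ``"fast"`` (vectorised numba kernel) or
    ``"reference"`` (per-cell loop over :func:`budsizer.dynamics.step`);
    the two produce identical populations for the same seed.
    """
    if n_final < 1:
        raise ValueError("n_final must be >= 1")
    if isinstance(condition, str):
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}")
        condition = CONDITIONS[condition]
    run_params = apply_condition(params, condition)
    pop = Population(run_params, condition, n_final, seed)
    pop.add_cell(parent=-1, age=0, t=0.0, a_m=progenitor_area, a_d=0.0,
                 b_r=progenitor_br, mcln=0.0, mclb=0.0, cln=0.0, clb=0.0)
    rng = np.random.default_rng(seed)
    if engine == "fast":
        _run_fast(pop, run_params, rng, max_minutes, record_timeseries)
    elif engine == "reference":
        _run_reference(pop, run_params, rng, max_minutes, record_timeseries)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    return pop


def _snapshot(series: list, pop: Population) -> None:
    v = pop.volumes
    series.append((pop.clock, pop.n, float(v.mean()), float(v.std())))


def _finish_timeseries(pop: Population, series: list,
                       record: bool) -> None:
    if record:
        pop.timeseries = pd.DataFrame(
            series, columns=["t", "n_live", "mean_volume", "sd_volume"])


def _runaway(pop: Population, max_minutes: float) -> RuntimeError:
    return RuntimeError(
        f"no stop after {max_minutes:g} simulated minutes: "
        f"{pop.n} of {pop.n_final} cells, {len(pop.records)} divisions; "
        "check parameters (e.g. growth=0 or unreachable thresholds)")


def _run_fast(pop: Population, params: ModelParams, rng,
              max_minutes: float, record_timeseries: bool) -> None:
    p = params
    is_model2 = p.variant == "model2"
    series: list = []
    div_flag = np.zeros(pop.phase.shape[0], dtype=np.bool_)
    while pop.n < pop.n_final:
        if pop.clock >= max_minutes:
            raise _runaway(pop, max_minutes)
        n = pop.n
        if div_flag.shape[0] < pop.phase.shape[0]:
            div_flag = np.zeros(pop.phase.shape[0], dtype=np.bool_)
        u = rng.random((n, 2))
        t_new = pop.clock + p.dt
        ndiv = _step_kernel(
            n, t_new, pop.phase, pop.phase_entry, pop.am, pop.ad, pop.br,
            pop.mcln, pop.mclb, pop.cln, pop.clb, pop.t_start, pop.v_start,
            div_flag, u,
            p.growth, p.k_p1, p.k_p2, p.k_r_g1, p.k_am_g1, p.k_ad_g1,
            p.k_r_sg2m, p.k_am_sg2m, p.k_ad_sg2m, p.k_d, p.p_cln, p.p_clb,
            p.threshold, p.s_dur, p.m_dur, p.m_br, p.m_ba,
            p.clb_localization, is_model2, p.dt, VOLUME_CLOSURE)
        pop.clock = t_new
        if ndiv:
            for i in np.nonzero(div_flag[:n])[0]:
                _divide_fast(pop, int(i), t_new)
                div_flag[i] = False
        if record_timeseries:
            _snapshot(series, pop)
    _finish_timeseries(pop, series, record_timeseries)


def _divide_fast(pop: Population, i: int, t: float) -> None:
    """Array-level division; mirrors dynamics.divide bit-for-bit."""
    a_m = float(pop.am[i])
    a_d = float(pop.ad[i])
    v_m = a_m * math.sqrt(a_m) / VOLUME_CLOSURE
    v_d = a_d * math.sqrt(a_d) / VOLUME_CLOSURE
    v = v_m + v_d
    r = v_d / v
    pop.records.append(CycleRecord(
        cell_id=i,
        replicative_age=int(pop.cycle_age[i]),
        role="daughter" if pop.cycle_age[i] == 0 else "mother",
        t_birth=float(pop.cycle_t0[i]),
        t_start=float(pop.t_start[i]),
        t_division=t,
        v_birth=float(pop.cycle_v0[i]),
        v_start=float(pop.v_start[i]),
        v_division=v,
        v_bud=v_d,
    ))
    pop.add_cell(parent=i, age=0, t=t, a_m=a_d, a_d=0.0,
                 b_r=float(pop.br[i]) * r, mcln=float(pop.mcln[i]) * r,
                 mclb=float(pop.mclb[i]) * r, cln=float(pop.cln[i]) * r,
                 clb=float(pop.clb[i]) * r)
    keep = 1.0 - r
    pop.br[i] *= keep
    pop.mcln[i] *= keep
    pop.mclb[i] *= keep
    pop.cln[i] *= keep
    pop.clb[i] *= keep
    pop.ad[i] = 0.0
    pop.repl_age[i] += 1
    pop.cycle_age[i] = pop.repl_age[i]
    pop.phase[i] = G1
    pop.phase_entry[i] = t
    pop.cycle_t0[i] = t
    pop.cycle_v0[i] = v_m
    pop.t_start[i] = np.nan
    pop.v_start[i] = np.nan


def _run_reference(pop: Population, params: ModelParams, rng,
                   max_minutes: float, record_timeseries: bool) -> None:
    """Per-cell loop over the single-cell model; validation engine."""
    cells: list[CellState] = [CellState(
        id=0, parent_id=None, A_m=pop.am[0], A_d=0.0, B_R=pop.br[0])]
    series: list = []
    while len(cells) < pop.n_final:
        if pop.clock >= max_minutes:
            raise _runaway(pop, max_minutes)
        n = len(cells)
        u = rng.random((n, 2))
        t_new = pop.clock + params.dt
        dividing: list[int] = []
        for i, cell in enumerate(cells):
            step(cell, params, uniforms=(u[i, 0], u[i, 1]))
            if check_transition(cell, params, t_new) == "division":
                dividing.append(i)
        pop.clock = t_new
        for i in dividing:
            mother, daughter, record = divide(cells[i], t_new, len(cells))
            cells.append(daughter)
            pop.records.append(record)
        _sync_reference(pop, cells)
        if record_timeseries:
            _snapshot(series, pop)
    _sync_reference(pop, cells)
    _finish_timeseries(pop, series, record_timeseries)


def _sync_reference(pop: Population, cells: list[CellState]) -> None:
    while pop.n < len(cells):
        c = cells[pop.n]
        pop.add_cell(parent=c.parent_id if c.parent_id is not None else -1,
                     age=c.replicative_age, t=c.birth_time, a_m=c.A_m,
                     a_d=c.A_d, b_r=c.B_R, mcln=c.mCLN, mclb=c.mCLB,
                     cln=c.Cln, clb=c.Clb)
    for i, c in enumerate(cells):
        pop.phase[i] = c.phase
        pop.phase_entry[i] = c.phase_entry_time
        pop.am[i] = c.A_m
        pop.ad[i] = c.A_d
        pop.br[i] = c.B_R
        pop.mcln[i] = c.mCLN
        pop.mclb[i] = c.mCLB
        pop.cln[i] = c.Cln
        pop.clb[i] = c.Clb
        pop.repl_age[i] = c.replicative_age
        pop.cycle_age[i] = c.cycle_start_age
        pop.cycle_t0[i] = c.cycle_start_time
        pop.cycle_v0[i] = c.cycle_birth_volume
        pop.t_start[i] = c.t_start
        pop.v_start[i] = c.v_start
        pop.birth_time[i] = c.birth_time
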