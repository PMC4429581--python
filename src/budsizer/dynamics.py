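"""Single-cell hybrid growth-and-division model of budding yeast.

The cell is described by two spherical compartments (mother body and bud)
whose surface areas grow by deposition of structural biomass, an internal
biosynthetic capacity ``B_R`` (ribosomes, polymerases, metabolic enzymes)
that self-replicates, and a rudimentary cell-cycle engine: one G1 cyclin
proxy (Cln) and one mitotic cyclin proxy (Clb), each translated from a
stochastically transcribed mRNA in its own cell-cycle window (``CLN`` in
G1, ``CLB`` in G2).  Nutrient uptake is proportional to total surface area
and diluted by total volume, so every production flux carries the factor
``B_R * A/V``.  Phase transitions are threshold events: START (G1->S)
fires when Cln reaches a critical molecule number, mitotic entry (G2->M)
when Clb does; S and M have fixed durations.

Two variants differ in a single term: in ``model1`` the Clb mRNA is
translated throughout the cell, in ``model2`` translation is restricted
to the bud, scaling Clb production by the bud volume fraction
``V_d/V`` (the model analogue of bud-localised *CLB2* transcripts).

Integration is forward Euler with a fixed step (1 min by default); the
per-minute transcription burst is Bernoulli(``P_x * dt``), applied before
the first-order decay of the same step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "G1", "S", "G2", "M", "PHASE_NAMES",
    "ModelParams", "CellState", "CycleRecord",
    "PRESETS", "best_fit_params",
    "area_to_volume", "total_geometry", "transcription_step",
    "allocation", "biomass_derivatives", "cyclin_derivatives",
    "step", "check_transition", "divide",
]

# cell-cycle phases (integer codes shared with the vectorised engine)
G1, S, G2, M = 0, 1, 2, 3
PHASE_NAMES = {G1: "G1", S: "S", G2: "G2", M: "M"}

#: closure of the geometric scaling V ∝ A^{3/2}.  Volumes are reported in
#: model units defined by V = A^{3/2} exactly: the closure constant c in
#: V = A^{3/2}/c multiplies every production flux through A/V and is
#: equivalent to rescaling (growth, k_p1, k_p2) by c, so c = 1 is the only
#: convention under which the calibrated rate constants keep their values.
VOLUME_CLOSURE = 1.0


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelParams:
    """Kinetic and structural parameters of the single-cell model.

    Rates are per minute; cyclins and mRNAs are molecule numbers; areas and
    volumes are in internal model units (consistent across all statistics).

    Parameters
    ----------
    variant
        ``"model1"`` (whole-cell Clb translation) or ``"model2"``
        (bud-localised Clb translation).
    growth
        Dimensionless nutrient scaling of all biomass formation fluxes.
    k_p1, k_p2
        Cln / Clb translation rate constants ((min*mol)^-1).
    k_r_g1, k_r_sg2m
        Resource allocation weight toward biosynthetic capacity in G1 and
        in the budded phase (S-G2-M).
    k_am_g1, k_am_sg2m, k_ad_g1, k_ad_sg2m
        Allocation weights toward mother and bud surface growth per phase.
        Wild type grows only the mother body in G1 and only the bud in
        S-G2-M.
    k_d
        First-order degradation rate of proteins and mRNAs (min^-1).
    p_cln, p_clb
        Per-minute probability of a one-molecule transcription burst of the
        CLN / CLB mRNA (min^-1), active only in the cognate phase.
    threshold
        Cyclin molecule number giving critical kinase activity at both the
        G1/S and G2/M transitions.
    s_dur, m_dur
        Fixed durations of S phase and mitosis (min).
    m_br, m_ba
        Constant biomass-mRNA abundances scaling internal/structural
        biomass production (dimensionless, held at 1).
    clb_localization
        Fraction of Clb translation confined to the bud in ``model2``
        (1.0 = fully bud-localised; 0.0 makes model2 identical to model1).
    dt
        Euler integration step (min).
    """

    variant: str = "model2"
    growth: float = 0.029
    k_p1: float = 0.589
    k_p2: float = 1.606
    k_r_g1: float = 4.098
    k_r_sg2m: float = 1.04
    k_am_g1: float = 1.0
    k_am_sg2m: float = 0.0
    k_ad_g1: float = 0.0
    k_ad_sg2m: float = 1.0
    k_d: float = 0.1
    p_cln: float = 0.4
    p_clb: float = 0.4
    threshold: float = 150.0
    s_dur: float = 25.0
    m_dur: float = 5.0
    m_br: float = 1.0
    m_ba: float = 1.0
    clb_localization: float = 1.0
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.variant not in ("model1", "model2"):
            raise ValueError(f"unknown variant {self.variant!r}")
        for name in ("growth", "k_p1", "k_p2", "k_d", "threshold",
                     "s_dur", "m_dur", "m_br", "m_ba", "dt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        for ph in ("g1", "sg2m"):
            ks = [getattr(self, f"k_r_{ph}"), getattr(self, f"k_am_{ph}"),
                  getattr(self, f"k_ad_{ph}")]
            if any(k < 0 for k in ks):
                raise ValueError("allocation weights must be >= 0")
            if sum(ks) <= 0:
                raise ValueError(f"allocation weights in {ph} sum to zero")
        for name in ("p_cln", "p_clb"):
            p = getattr(self, name)
            if not 0.0 <= p * self.dt <= 1.0:
                raise ValueError(f"{name}*dt must lie in [0, 1]")
        if not 0.0 <= self.clb_localization <= 1.0:
            raise ValueError("clb_localization must lie in [0, 1]")
        if self.k_d * self.dt >= 1.0:
            raise ValueError("k_d*dt must be < 1 for a stable Euler step")

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


#: best-fit parameter sets for the two variants (five estimated parameters
#: differ; all structural parameters are shared)
PRESETS: dict[str, ModelParams] = {
    "model1-bestfit": ModelParams(
        variant="model1", growth=0.028, k_p1=0.452, k_p2=0.342,
        k_r_g1=4.92, k_r_sg2m=1.495),
    "model2-bestfit": ModelParams(
        variant="model2", growth=0.029, k_p1=0.589, k_p2=1.606,
        k_r_g1=4.098, k_r_sg2m=1.04),
}


def best_fit_params(variant: str) -> ModelParams:
    """Best-fit parameter preset for ``"model1"`` or ``"model2"``."""
    key = f"{variant}-bestfit"
    if key not in PRESETS:
        raise ValueError(f"unknown variant {variant!r}")
    return PRESETS[key]


# ---------------------------------------------------------------------------
# state containers
# ---------------------------------------------------------------------------

@dataclass
class CellState:
    """Mutable state of one cell (mother body plus attached bud)."""

    id: int = 0
    parent_id: Optional[int] = None
    replicative_age: int = 0
    phase: int = G1
    phase_entry_time: float = 0.0
    A_m: float = 10.0           # mother-body surface area
    A_d: float = 0.0            # bud surface area (0 throughout G1)
    B_R: float = 1.0            # biosynthetic capacity
    mCLN: float = 0.0
    mCLB: float = 0.0
    Cln: float = 0.0
    Clb: float = 0.0
    birth_time: float = 0.0
    birth_volume: float = field(default=None)  # type: ignore[assignment]
    # bookkeeping for the cycle in progress
    cycle_start_time: float = 0.0
    cycle_start_age: int = 0
    cycle_birth_volume: float = field(default=None)  # type: ignore[assignment]
    t_start: float = math.nan    # START time of current cycle
    v_start: float = math.nan    # total volume at START

    def __post_init__(self) -> None:
        if self.A_m <= 0:
            raise ValueError("A_m must be > 0")
        if self.A_d < 0:
            raise ValueError("A_d must be >= 0")
        if self.B_R <= 0:
            raise ValueError("B_R must be > 0")
        v = area_to_volume(self.A_m) + area_to_volume(self.A_d)
        if self.birth_volume is None:
            self.birth_volume = v
        if self.cycle_birth_volume is None:
            self.cycle_birth_volume = v

    @property
    def volume(self) -> float:
        return area_to_volume(self.A_m) + area_to_volume(self.A_d)


@dataclass(frozen=True)
class CycleRecord:
    """One completed cell cycle (birth/START/division times and volumes)."""

    cell_id: int
    replicative_age: int          # age at cycle start; 0 = daughter cycle
    role: str                     # "daughter" or "mother"
    t_birth: float
    t_start: float
    t_division: float
    v_birth: float
    v_start: float
    v_division: float
    v_bud: float                  # bud volume at division

    def __post_init__(self) -> None:
        if not (self.t_birth < self.t_start < self.t_division):
            raise ValueError("cycle times must satisfy birth < START < division")
        for name in ("v_birth", "v_start", "v_division", "v_bud"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.v_bud >= self.v_division:
            raise ValueError("bud volume must be smaller than total volume")

    @property
    def t_g1(self) -> float:
        return self.t_start - self.t_birth

    @property
    def t_sg2m(self) -> float:
        return self.t_division - self.t_start

    @property
    def generation_time(self) -> float:
        return self.t_division - self.t_birth


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def area_to_volume(area: float) -> float:
    """Compartment volume from surface area: ``V = A^{3/2}``.

    Mother body and bud are approximated as separate sphere-like bodies,
    so each compartment's volume scales as its area to the 3/2 power;
    volumes are expressed in the model units fixed by
    :data:`VOLUME_CLOSURE` (see note there on why the constant is 1).
    """
    if area < 0:
        raise ValueError("surface area must be >= 0")
    # written as A*sqrt(A) to match the vectorised kernel bit-for-bit
    return area * math.sqrt(area) / VOLUME_CLOSURE


def total_geometry(state: CellState) -> tuple[float, float, float, float]:
    """Total area and per-compartment volumes ``(A, V_m, V_d, V)``."""
    v_m = area_to_volume(state.A_m)
    v_d = area_to_volume(state.A_d)
    return state.A_m + state.A_d, v_m, v_d, v_m + v_d


# ---------------------------------------------------------------------------
# stochastic transcription
# ---------------------------------------------------------------------------

def transcription_step(mrna: float, active: bool, p_x: float, k_d: float,
                       dt: float, u: float) -> float:
    """One burst-and-decay update of an mRNA count.

    If the gene is in its active phase, a one-molecule burst occurs with
    probability ``p_x * dt`` (decided by the uniform draw ``u``); the burst
    is applied before the first-order Euler decay of the same step.
    """
    if active and u < p_x * dt:
        mrna = mrna + 1.0
    return mrna * (1.0 - k_d * dt)


# ---------------------------------------------------------------------------
# deterministic derivatives
# ---------------------------------------------------------------------------

def allocation(params: ModelParams, phase: int) -> tuple[float, float, float]:
    """Phase-specific allocation weights ``(k_R, k_Am, k_Ad)``."""
    if phase == G1:
        return params.k_r_g1, params.k_am_g1, params.k_ad_g1
    return params.k_r_sg2m, params.k_am_sg2m, params.k_ad_sg2m


def biomass_derivatives(state: CellState, params: ModelParams,
                        phase: Optional[int] = None
                        ) -> tuple[float, float, float]:
    """Time derivatives ``(dB_R, dB_Am, dB_Ad)`` of the biomass pools.

    Each pool receives the fraction ``k_X / (k_R + k_Am + k_Ad)`` of the
    total formation flux ``growth * m_B * B_R * A/V``.
    """
    if phase is None:
        phase = state.phase
    a, _, _, v = total_geometry(state)
    if v <= 0:
        raise ValueError("total volume must be > 0")
    k_r, k_am, k_ad = allocation(params, phase)
    den = k_r + k_am + k_ad
    base = params.growth * state.B_R * (a / v)
    return (base * params.m_br * (k_r / den),
            base * params.m_ba * (k_am / den),
            base * params.m_ba * (k_ad / den))


def cyclin_derivatives(state: CellState, params: ModelParams,
                       phase: Optional[int] = None) -> tuple[float, float]:
    """Time derivatives ``(dCln, dClb)``.

    Translation of each cyclin is confined to the phase whose transition it
    drives (Cln in G1, Clb in G2), matching the phase windows of the
    cognate mRNAs; degradation acts in every phase.  Cln production
    integrates the whole cell's biosynthetic capacity per volume; Clb
    production does the same in ``model1``, while ``model2`` scales it by
    the bud volume fraction ``V_d/V`` (bud-localised translation; a
    partial localisation fraction interpolates linearly).
    """
    if phase is None:
        phase = state.phase
    a, _, v_d, v = total_geometry(state)
    aov = a / v
    d_cln = -params.k_d * state.Cln
    if phase == G1:
        d_cln += params.k_p1 * state.mCLN * state.B_R * aov
    d_clb = -params.k_d * state.Clb
    if phase == G2:
        loc = 1.0
        if params.variant == "model2":
            f = params.clb_localization
            loc = (1.0 - f) + f * (v_d / v)
        d_clb += params.k_p2 * state.mCLB * state.B_R * aov * loc
    return d_cln, d_clb


# ---------------------------------------------------------------------------
# the Euler step and the phase machine
# ---------------------------------------------------------------------------

def step(state: CellState, params: ModelParams, rng=None, t: float = None,
         uniforms: tuple[float, float] = None) -> CellState:
    """Advance one cell by one Euler step of ``params.dt`` minutes (in place).

    Order of sub-updates: phase-gated transcription bursts and mRNA decay,
    cyclin production/decay (using the updated mRNA counts), biomass
    formation, then the area increments are identified with the structural
    biomass increments.  Transition checks are performed afterwards via
    :func:`check_transition`.

    Randomness enters only through two uniform draws (CLN and CLB burst);
    supply either ``rng`` or an explicit ``uniforms`` pair (the population
    engine feeds cells from one shared per-step array).
    """
    if uniforms is None:
        if rng is None:
            raise ValueError("provide rng or uniforms")
        uniforms = (rng.random(), rng.random())
    if not (math.isfinite(state.A_m) and math.isfinite(state.B_R)
            and math.isfinite(state.Cln) and math.isfinite(state.Clb)):
        raise FloatingPointError("non-finite cell state")
    dt = params.dt
    ph = state.phase
    state.mCLN = transcription_step(state.mCLN, ph == G1, params.p_cln,
                                    params.k_d, dt, uniforms[0])
    state.mCLB = transcription_step(state.mCLB, ph == G2, params.p_clb,
                                    params.k_d, dt, uniforms[1])
    d_cln, d_clb = cyclin_derivatives(state, params)
    db_r, db_am, db_ad = biomass_derivatives(state, params, ph)
    state.Cln += dt * d_cln
    state.Clb += dt * d_clb
    state.B_R += dt * db_r
    state.A_m += dt * db_am   # dA^m ≡ dB^Am
    state.A_d += dt * db_ad   # dA^d ≡ dB^Ad
    return state


def check_transition(state: CellState, params: ModelParams,
                     t: float) -> Optional[str]:
    """Fire at most one phase transition at time ``t``.

    G1->S when Cln >= threshold (START; records ``t_start``/``v_start``);
    S->G2 after the fixed S duration; G2->M when Clb >= threshold;
    M completes after the fixed mitosis duration, returning ``"division"``
    (the actual split is done by :func:`divide`).
    """
    ph = state.phase
    if ph == G1:
        if state.Cln >= params.threshold:
            state.phase = S
            state.phase_entry_time = t
            state.t_start = t
            state.v_start = state.volume
            return "START"
    elif ph == S:
        if t - state.phase_entry_time >= params.s_dur:
            state.phase = G2
            state.phase_entry_time = t
            return "S_end"
    elif ph == G2:
        if state.Clb >= params.threshold:
            state.phase = M
            state.phase_entry_time = t
            return "G2M"
    elif ph == M:
        if t - state.phase_entry_time >= params.m_dur:
            return "division"
    return None


def divide(cell: CellState, t: float, next_id: int
           ) -> tuple[CellState, CellState, CycleRecord]:
    """Split a cell at the end of mitosis into mother and daughter.

    The bud detaches and becomes the daughter's body; every soluble
    quantity (B_R, mRNAs, cyclins) is split by the volume ratio of bud to
    whole cell.  The mother's replicative age increments, the daughter
    starts at age 0; both re-enter G1 at time ``t``.  Returns the updated
    mother, the new daughter and the :class:`CycleRecord` of the completed
    cycle.
    """
    if cell.A_d <= 0:
        raise ValueError("cannot divide a cell without a bud")
    v_m = area_to_volume(cell.A_m)
    v_d = area_to_volume(cell.A_d)
    v = v_m + v_d
    r = v_d / v
    record = CycleRecord(
        cell_id=cell.id,
        replicative_age=cell.cycle_start_age,
        role="daughter" if cell.cycle_start_age == 0 else "mother",
        t_birth=cell.cycle_start_time,
        t_start=cell.t_start,
        t_division=t,
        v_birth=cell.cycle_birth_volume,
        v_start=cell.v_start,
        v_division=v,
        v_bud=v_d,
    )
    daughter = CellState(
        id=next_id, parent_id=cell.id, replicative_age=0,
        phase=G1, phase_entry_time=t,
        A_m=cell.A_d, A_d=0.0,
        B_R=cell.B_R * r, mCLN=cell.mCLN * r, mCLB=cell.mCLB * r,
        Cln=cell.Cln * r, Clb=cell.Clb * r,
        birth_time=t, birth_volume=v_d,
        cycle_start_time=t, cycle_start_age=0, cycle_birth_volume=v_d,
    )
    keep = 1.0 - r
    cell.B_R *= keep
    cell.mCLN *= keep
    cell.mCLB *= keep
    cell.Cln *= keep
    cell.Clb *= keep
    cell.A_d = 0.0
    cell.replicative_age += 1
    cell.phase = G1
    cell.phase_entry_time = t
    cell.cycle_start_time = t
    cell.cycle_start_age = cell.replicative_age
    cell.cycle_birth_volume = v_m
    cell.t_start = math.nan
    cell.v_start = math.nan
    return cell, daughter, record
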