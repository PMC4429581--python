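"""Population statistics for simulated cultures.

Operates on the tidy cycle-record table produced by
``Population.records_frame()`` (one row per completed cell cycle with
birth/START/division times and volumes) and on live-population snapshots.
Covers phase durations by pedigree role, growth-rate regressions, size
distributions and their relative variability, division ratios and
generation times by replicative age.

Conventions: population standard deviations (``ddof=0``) throughout;
cycles starting at replicative age 0 are "daughter" cycles, age >= 1
"mother" cycles; "relative variability" of cell size is the standard
deviation of the log2-transformed volumes (scale-invariant; ratios and
orderings are independent of the log base).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PhaseDurationSummary", "SizeStats",
    "phase_durations", "g1_growth_rate", "budded_growth_rate",
    "linear_fit", "start_volume_regression", "bud_volume_regression",
    "relative_variability", "size_stats", "division_ratio_by_age",
    "daughter_birth_volume_by_mother_age", "age_fraction", "budded_cv",
    "generation_time_by_age",
]

GROUPS = ("all", "daughters", "mothers")


def _select(records: pd.DataFrame, group: str) -> pd.DataFrame:
    if group == "all":
        return records
    if group == "daughters":
        return records[records["replicative_age"] == 0]
    if group == "mothers":
        return records[records["replicative_age"] >= 1]
    raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")


# ---------------------------------------------------------------------------
# phase durations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhaseDurationSummary:
    """Mean G1 and budded-phase durations for one pedigree group."""
    condition: str
    variant: str
    group: str
    n: int
    mean_t_g1: float
    mean_t_sg2m: float
    mother_daughter_difference: float  # daughter mean - mother mean (T_SG2M)


def phase_durations(records: pd.DataFrame,
                    group: str = "all") -> PhaseDurationSummary:
    """Mean T_G1 and T_SG2M over the completed cycles of one group.

    T_G1 runs from cycle start (birth or previous division) to START;
    T_SG2M from START to division.  The mother-daughter difference
    (daughter minus mother mean T_SG2M, the Table-3-style contrast) is
    reported alongside whichever group is selected.
    """
    sub = _select(records, group)
    if len(sub) == 0:
        raise ValueError(f"no records in group {group!r}")
    da = _select(records, "daughters")["t_sg2m"]
    mo = _select(records, "mothers")["t_sg2m"]
    diff = float(da.mean() - mo.mean()) if len(da) and len(mo) else np.nan
    return PhaseDurationSummary(
        condition=str(records["condition"].iloc[0]) if "condition" in records else "",
        variant=str(records["variant"].iloc[0]) if "variant" in records else "",
        group=group,
        n=len(sub),
        mean_t_g1=float(sub["t_g1"].mean()),
        mean_t_sg2m=float(sub["t_sg2m"].mean()),
        mother_daughter_difference=diff,
    )


# ---------------------------------------------------------------------------
# growth rates and regressions
# ---------------------------------------------------------------------------

def g1_growth_rate(records: pd.DataFrame) -> pd.Series:
    """Per-cycle G1 growth rate: (V_START - V_birth) / T_G1."""
    t = records["t_g1"]
    if (t <= 0).any():
        raise ValueError("T_G1 must be positive for a growth rate")
    return (records["v_start"] - records["v_birth"]) / t


def budded_growth_rate(records: pd.DataFrame) -> pd.Series:
    """Per-cycle budded-phase growth rate: (V_div - V_START) / T_SG2M."""
    t = records["t_sg2m"]
    if (t <= 0).any():
        raise ValueError("T_SG2M must be positive for a growth rate")
    return (records["v_division"] - records["v_start"]) / t


def linear_fit(x, y) -> tuple[float, float, float]:
    """Least-squares line ``y = slope*x + intercept``; returns
    (slope, intercept, r_squared)."""
    res = sps.linregress(np.asarray(x, float), np.asarray(y, float))
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def start_volume_regression(records: pd.DataFrame
                            ) -> tuple[float, float, float]:
    """Regression of volume at START on the G1 growth rate.

    A positive slope with high R^2 is the growth-rate-dependent G1 sizer
    signature: fast-growing cells commit to division at larger volumes.
    """
    return linear_fit(g1_growth_rate(records), records["v_start"])


def bud_volume_regression(records: pd.DataFrame
                          ) -> tuple[float, float, float]:
    """Regression of bud volume at division on the budded-phase growth
    rate (the G2 bud-sizer signature)."""
    return linear_fit(budded_growth_rate(records), records["v_bud"])


# ---------------------------------------------------------------------------
# size statistics
# ---------------------------------------------------------------------------

def relative_variability(volumes) -> float:
    """Relative variability of cell size: SD of log2-transformed volumes.

    Cell sizes are close to log-normal, so dispersion is measured on the
    log scale, where it is invariant to the absolute volume unit; the
    binary log expresses spread in doublings.
    """
    v = np.asarray(volumes, float)
    if v.size == 0:
        raise ValueError("empty volume array")
    if (v <= 0).any():
        raise ValueError("volumes must be positive")
    return float(np.std(np.log2(v)))


@dataclass(frozen=True)
class SizeStats:
    """Summary of a live-population volume distribution."""
    condition: str
    variant: str
    n: int
    mean_log2_volume: float
    sd_log2_volume: float
    relative_variability: float   # == sd_log2_volume
    mean_volume: float            # linear scale


def size_stats(volumes, condition: str = "", variant: str = "") -> SizeStats:
    lv = np.log2(np.asarray(volumes, float))
    return SizeStats(
        condition=condition, variant=variant, n=lv.size,
        mean_log2_volume=float(lv.mean()),
        sd_log2_volume=float(lv.std()),
        relative_variability=relative_variability(volumes),
        mean_volume=float(np.mean(volumes)),
    )


# ---------------------------------------------------------------------------
# pedigree-resolved statistics
# ---------------------------------------------------------------------------

def division_ratio_by_age(records: pd.DataFrame) -> pd.Series:
    """Mean bud-to-whole-cell volume fraction at division, by the
    replicative age of the dividing cell at cycle start."""
    ratio = records["v_bud"] / records["v_division"]
    return ratio.groupby(records["replicative_age"]).mean()


def daughter_birth_volume_by_mother_age(records: pd.DataFrame) -> pd.Series:
    """Mean volume of new-born daughters by the mother's replicative age.

    Each completed cycle releases one daughter whose birth volume equals
    the bud volume at that division; ages are the dividing cell's age at
    cycle start (0 = a first-time mother's bud).
    """
    return records["v_bud"].groupby(records["replicative_age"]).mean()


def age_fraction(ages, max_age: int) -> float:
    """Fraction of live cells with replicative age <= ``max_age``."""
    a = np.asarray(ages)
    if a.size == 0:
        raise ValueError("empty age array")
    return float((a <= max_age).mean())


def budded_cv(records: pd.DataFrame) -> float:
    """Coefficient of variation (population SD / mean) of T_SG2M."""
    t = records["t_sg2m"].to_numpy(float)
    return float(np.std(t) / np.mean(t))


def generation_time_by_age(records: pd.DataFrame) -> pd.DataFrame:
    """Generation-time distributions per replicative-age class.

    Returns one row per age plus a pooled ``"all"`` row, with counts,
    means and medians of the full cycle duration (birth to division).
    """
    g = records["generation_time"]
    rows = []
    for age, sub in g.groupby(records["replicative_age"]):
        rows.append({"age": age, "n": len(sub),
                     "mean": float(sub.mean()), "median": float(sub.median())})
    rows.append({"age": "all", "n": len(g),
                 "mean": float(g.mean()), "median": float(g.median())})
    return pd.DataFrame(rows)
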