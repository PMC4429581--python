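"""Run configuration, serialisation and miniature test cultures.

A run is fully described by a :class:`RunConfig` (variant, condition,
final cell count, seed, step size, mutant flags); archiving the config
alongside the outputs makes every culture reproducible bit-for-bit.
Cycle records and final-state snapshots are written as plain CSV, run
metadata as JSON, configs as YAML.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from .dynamics import ModelParams, best_fit_params
from .population import (Population, apply_mutant_oe_cln, simulate_culture)

__all__ = [
    "RunConfig", "run_simulation", "write_records", "read_records",
    "make_fixture", "FIXTURE_KINDS",
]

#: column order of the records table (stable across releases)
RECORD_COLUMNS = [
    "cell_id", "replicative_age", "role", "t_birth", "t_start",
    "t_division", "v_birth", "v_start", "v_division", "v_bud",
    "t_g1", "t_sg2m", "generation_time", "condition", "variant",
]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one culture simulation."""

    variant: str = "model2"
    condition: str = "glucose"
    n_final: int = 1000
    seed: int = 0
    dt: float = 1.0
    oe_cln: bool = False
    clb_localization: float = 1.0
    out_dir: Optional[str] = None

    def params(self) -> ModelParams:
        """Resolve to a best-fit parameter set with mutant flags applied."""
        p = best_fit_params(self.variant).with_(
            dt=self.dt, clb_localization=self.clb_localization)
        if self.oe_cln:
            p = apply_mutant_oe_cln(p)
        return p

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def write_records(records: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write the cycle-record table as CSV with a stable column order."""
    cols = [c for c in RECORD_COLUMNS if c in records.columns]
    records.loc[:, cols].to_csv(path, index=False)


def read_records(path: Union[str, Path]) -> pd.DataFrame:
    """Read a cycle-record table written by :func:`write_records`."""
    return pd.read_csv(path)


def run_simulation(config: RunConfig) -> Population:
    """Simulate a culture from a config; write outputs if out_dir is set.

    Outputs: ``records.csv`` (completed cycles), ``final_state.csv``
    (live-cell snapshot), ``config.yaml`` and ``run.json`` (metadata).
    """
    pop = simulate_culture(config.params(), config.condition,
                           n_final=config.n_final, seed=config.seed)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_records(pop.records_frame(), out / "records.csv")
        pop.live_frame().to_csv(out / "final_state.csv", index=False)
        config.to_yaml(out / "config.yaml")
        meta = {
            "variant": config.variant, "condition": config.condition,
            "n_final": config.n_final, "seed": config.seed,
            "stop_time_min": pop.clock, "n_live": int(pop.n),
            "n_records": len(pop.records),
        }
        (out / "run.json").write_text(json.dumps(meta, indent=2))
    return pop


# ---------------------------------------------------------------------------
# miniature cultures for fast deterministic tests
# ---------------------------------------------------------------------------

FIXTURE_KINDS = {
    "model1-glucose": RunConfig(variant="model1", condition="glucose", n_final=150),
    "model2-glucose": RunConfig(variant="model2", condition="glucose", n_final=150),
    "model1-ethanol": RunConfig(variant="model1", condition="ethanol", n_final=100),
    "model2-ethanol": RunConfig(variant="model2", condition="ethanol", n_final=100),
    "model1-galactose": RunConfig(variant="model1", condition="galactose", n_final=100),
    "model1-raffinose": RunConfig(variant="model1", condition="raffinose", n_final=100),
    "model2-oe-cln": RunConfig(variant="model2", condition="glucose",
                               n_final=150, oe_cln=True),
}


def make_fixture(kind: str, seed: int = 0) -> Population:
    """Deterministic miniature culture (100-150 cells) for tests."""
    try:
        cfg = FIXTURE_KINDS[kind]
    except KeyError:
        raise ValueError(
            f"unknown fixture {kind!r}; choose from {sorted(FIXTURE_KINDS)}"
        ) from None
    return run_simulation(
        RunConfig(**{**asdict(cfg), "seed": seed, "out_dir": None}))
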