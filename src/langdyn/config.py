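"""YAML round-trip for simulation configurations.

The file layout is a flat mapping of the model's parameter names (exactly the
symbols used throughout: a1, a2, K1, K2, K, c, c1, c2, alpha, beta, d1, d2)
under ``model``, plus grid/stepping/initial-condition sections::

    model:
      variant: ecology_society
      a1: 0.08
      ...
    grid: {n: 51}
    dt: 0.005
    t_end: 700.0
    snapshot_times: [0, 100, 300, 500, 700]
    seed: 0
    initial_condition:
      kind: bump
      species1: {target_min: 0.0, target_max: 0.9, center: [0.3, 0.3], width: 0.15}
      species2: {target_min: 0.0, target_max: 0.3, center: [0.7, 0.7], width: 0.15}
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .exceptions import ValidationError
from .models import make_model
from .pde import SimulationConfig, build_grid
from .scenarios import ICKind, InitialConditionSpec, SpeciesIC

__all__ = ["load_config", "save_config", "config_to_dict"]


def _species_from_dict(d: dict) -> SpeciesIC:
    return SpeciesIC(
        target_min=float(d["target_min"]),
        target_max=float(d["target_max"]),
        center=tuple(float(x) for x in d.get("center", (0.5, 0.5))),
        width=float(d.get("width", 0.15)),
    )


def load_config(path: str | Path) -> SimulationConfig:
    """Read a :class:`~langdyn.pde.SimulationConfig` from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text())
    try:
        model_raw = dict(raw["model"])
        variant = model_raw.pop("variant")
        model = make_model(variant, **model_raw)
        ic_raw = raw["initial_condition"]
        seed = int(raw.get("seed", 0))
        ic = InitialConditionSpec(
            kind=ICKind(ic_raw["kind"]),
            species1=_species_from_dict(ic_raw["species1"]),
            species2=_species_from_dict(ic_raw["species2"]),
            seed=int(ic_raw.get("seed", seed)),
        )
        return SimulationConfig(
            model=model,
            grid=build_grid(int(raw["grid"]["n"])),
            dt=float(raw["dt"]),
            t_end=float(raw["t_end"]),
            snapshot_times=tuple(float(t) for t in raw["snapshot_times"]),
            ic_spec=ic,
            seed=seed,
        )
    except KeyError as exc:
        raise ValidationError(f"config missing required key: {exc}") from exc


def config_to_dict(config: SimulationConfig) -> dict:
    ic = config.ic_spec
    return {
        "model": {"variant": config.model.variant.value, **config.model.params()},
        "grid": {"n": config.grid.n},
        "dt": config.dt,
        "t_end": config.t_end,
        "snapshot_times": list(config.snapshot_times),
        "seed": config.seed,
        "initial_condition": {
            "kind": ic.kind.value,
            "seed": ic.seed,
            "species1": {
                "target_min": ic.species1.target_min,
                "target_max": ic.species1.target_max,
                "center": list(ic.species1.center),
                "width": ic.species1.width,
            },
            "species2": {
                "target_min": ic.species2.target_min,
                "target_max": ic.species2.target_max,
                "center": list(ic.species2.center),
                "width": ic.species2.width,
            },
        },
    }


def save_config(config: SimulationConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))
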