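"""Structured run configuration, YAML I/O and canonical scenario fixtures.

A run configuration has four sections — ``model`` (calibration inputs and
parameter overrides), ``scenario`` (protocol timing), ``solver`` and ``seed``.
Unknown keys are rejected at every level so typos fail loudly.  The core
model is deterministic; the seed is recorded for provenance only.

``P_min`` and ``alpha_e`` are given in percent in configuration files (the
convention of the experiments being emulated) and converted to fractions at
load time.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .calibrate import BaselineSpec, Model, calibrate
from .core import Geometry, PhysicalConstants
from .glutamate import VesicleParams
from .simulate import (BlockadeWindow, EDProtocol, Protocols,
                       StimulusProtocol)
from .transport import Blockade, TransportParams

__all__ = ["RunConfig", "load_config", "make_fixtures", "config_hash"]


class ConfigError(ValueError):
    """Malformed or unknown configuration content."""


def _take(d: dict, allowed: set[str], where: str) -> dict:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")
    return d


def _overrides(d: dict, cls, where: str) -> dict:
    return _take(dict(d or {}), {f.name for f in fields(cls)}, where)


@dataclass
class RunConfig:
    """Validated run configuration (fractions internally, percent on disk)."""

    alpha_e: float = 0.2
    P_scale: float = 1.0
    constants: dict = field(default_factory=dict)
    geometry: dict = field(default_factory=dict)
    transport: dict = field(default_factory=dict)
    vesicle: dict = field(default_factory=dict)
    baseline: dict = field(default_factory=dict)
    t_end: float = 45.0
    ed: dict | None = None
    stimulus: dict | None = None
    blockades: list = field(default_factory=list)
    rtol: float = 1e-8
    coarse_dt_ms: float = 250.0
    stim_dt_ms: float = 0.1
    bifurcation: dict = field(default_factory=dict)
    seed: int = 0
    description: str = ""

    def build_model(self) -> Model:
        consts = PhysicalConstants(**_overrides(self.constants,
                                                PhysicalConstants, "model.constants"))
        geom_kw = _overrides(self.geometry, Geometry, "model.geometry")
        geom_kw.setdefault("alpha_e", self.alpha_e)
        tp = TransportParams(**_overrides(self.transport, TransportParams,
                                          "model.transport"))
        vp = VesicleParams(**_overrides(self.vesicle, VesicleParams,
                                        "model.vesicle"))
        bs = BaselineSpec(**_overrides(self.baseline, BaselineSpec,
                                       "model.baseline"))
        return calibrate(P_scale=self.P_scale, consts=consts,
                         geom=Geometry(**geom_kw), baseline=bs, tp=tp, vp=vp)

    def build_protocols(self) -> Protocols:
        ed = None
        if self.ed:
            d = _take(dict(self.ed), {"P_min_pct", "t_start", "t_end", "beta"},
                      "scenario.ed")
            ed = EDProtocol(P_min=float(d["P_min_pct"]) / 100.0,
                            t_start=float(d.get("t_start", 5.0)),
                            t_end=float(d.get("t_end", 10.0)),
                            beta=float(d.get("beta", 1.7)))
        stim = None
        if self.stimulus:
            d = _take(dict(self.stimulus),
                      {"amplitude", "onset", "duration_s", "repeats",
                       "interval"}, "scenario.stimulus")
            stim = StimulusProtocol(**{k: v for k, v in d.items()})
        blocks = []
        for i, b in enumerate(self.blockades):
            d = _take(dict(b), {"t_on", "t_off", "factors"},
                      f"scenario.blockades[{i}]")
            blocks.append(BlockadeWindow(t_on=float(d["t_on"]),
                                         t_off=float(d["t_off"]),
                                         blockade=Blockade(dict(d["factors"]))))
        return Protocols(ed=ed, stim=stim, blockades=tuple(blocks))

    def to_dict(self) -> dict:
        d = {
            "description": self.description,
            "model": {
                "alpha_e_pct": self.alpha_e * 100.0,
                "P_scale": self.P_scale,
                "constants": self.constants, "geometry": self.geometry,
                "transport": self.transport, "vesicle": self.vesicle,
                "baseline": self.baseline,
            },
            "scenario": {
                "t_end": self.t_end,
                "ed": self.ed, "stimulus": self.stimulus,
                "blockades": self.blockades,
            },
            "solver": {"rtol": self.rtol, "coarse_dt_ms": self.coarse_dt_ms,
                       "stim_dt_ms": self.stim_dt_ms},
            "bifurcation": self.bifurcation,
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = _take(dict(d), {"description", "model", "scenario", "solver",
                            "bifurcation", "seed"}, "config")
        model = _take(dict(d.get("model", {})),
                      {"alpha_e_pct", "P_scale", "constants", "geometry",
                       "transport", "vesicle", "baseline"}, "model")
        scenario = _take(dict(d.get("scenario", {})),
                         {"t_end", "ed", "stimulus", "blockades"}, "scenario")
        solver = _take(dict(d.get("solver", {})),
                       {"rtol", "coarse_dt_ms", "stim_dt_ms"}, "solver")
        return cls(
            alpha_e=float(model.get("alpha_e_pct", 20.0)) / 100.0,
            P_scale=float(model.get("P_scale", 1.0)),
            constants=model.get("constants") or {},
            geometry=model.get("geometry") or {},
            transport=model.get("transport") or {},
            vesicle=model.get("vesicle") or {},
            baseline=model.get("baseline") or {},
            t_end=float(scenario.get("t_end", 45.0)),
            ed=scenario.get("ed"),
            stimulus=scenario.get("stimulus"),
            blockades=scenario.get("blockades") or [],
            rtol=float(solver.get("rtol", 1e-8)),
            coarse_dt_ms=float(solver.get("coarse_dt_ms", 250.0)),
            stim_dt_ms=float(solver.get("stim_dt_ms", 0.1)),
            bifurcation=d.get("bifurcation") or {},
            seed=int(d.get("seed", 0)),
            description=str(d.get("description", "")),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True,
                              default_flow_style=False)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return RunConfig.from_dict(data)


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the canonical config serialization."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# canonical fixtures
# ---------------------------------------------------------------------------

def _scenarios() -> dict[str, RunConfig]:
    """Baseline plus the six canonical protocol scenarios."""
    ed = lambda pmin, t1: {"P_min_pct": pmin, "t_start": 5.0, "t_end": t1}
    out = {
        "baseline": RunConfig(alpha_e=0.2, t_end=60.0,
                              description="unperturbed baseline hold"),
        "calibration": RunConfig(
            alpha_e=0.8, ed=ed(50.0, 10.0), t_end=45.0,
            description="5-min partial energy deprivation, large ECS"),
        "excitation": RunConfig(
            alpha_e=0.2, t_end=10.0,
            stimulus={"amplitude": 25.0, "onset": 5.0, "duration_s": 10.0},
            description="square-wave stimulation of the neuron at rest"),
        "ed_short_small_ecs": RunConfig(
            alpha_e=0.2, ed=ed(50.0, 10.0), t_end=45.0,
            description="5-min energy deprivation, realistic (small) ECS"),
        "ed_short_large_ecs": RunConfig(
            alpha_e=0.8, ed=ed(50.0, 10.0), t_end=45.0,
            description="5-min energy deprivation, large ECS"),
        "ed_long_small_ecs": RunConfig(
            alpha_e=0.2, ed=ed(50.0, 20.0), t_end=55.0,
            description="15-min energy deprivation, realistic (small) ECS"),
        "ed_long_large_ecs": RunConfig(
            alpha_e=0.8, ed=ed(50.0, 20.0), t_end=55.0,
            description="15-min energy deprivation, large ECS"),
    }
    return out


def make_fixtures(outdir: str | Path) -> list[Path]:
    """Write the canonical scenario configs; regeneration is byte-identical."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, cfg in _scenarios().items():
        p = outdir / f"{name}.yaml"
        p.write_text(cfg.to_yaml())
        paths.append(p)
    return paths
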