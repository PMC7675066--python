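"""Declarative run configuration: one flat file, stage-scoped blocks.

Defaults reproduce the published acquisition and reconstruction parameters
(384-element 11.5 cm arc at -12 cm curvature, 200 poses at 1.8 degrees,
40 MHz sampling, 0.5 mm grid, 1500 m/s, 5th-order 14.5 MHz Butterworth,
k = 10 singular values, sigma_L/sigma_E = 18.5/6.2 degrees, 200 fluence
patches).  Unknown keys are rejected so typos cannot silently fall back to
defaults.  YAML and TOML are both accepted.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["RunConfig", "load_config", "config_hash"]


def _strict(cls, d: dict):
    if d is None:
        return cls()
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown keys in {cls.__name__}: {sorted(unknown)}")
    return cls(**d)


@dataclass(frozen=True)
class ArrayBlock:
    n_elements: int = 384
    arc_length: float = 11.5
    arc_radius: float = 12.0
    elevational_aperture: float = 0.5
    arc_center_polar_deg: float = 45.0


@dataclass(frozen=True)
class PlanBlock:
    n_angles: int = 200
    angular_step: float = 1.8
    sampling_rate: float = 40e6
    n_samples: int = 2080
    sound_speed: float = 1500.0


@dataclass(frozen=True)
class IlluminatorBlock:
    wide_divergence: float = 90.0
    narrow_divergence: float = 0.24


@dataclass(frozen=True)
class OpticsBlock:
    mu_a0: float = 0.2
    mu_s: float = 10.0
    g: float = 0.0


def _freeze(obj):
    if isinstance(obj, (list, tuple)):
        return tuple(_freeze(v) for v in obj)
    return obj


@dataclass(frozen=True)
class GridBlock:
    origin: tuple = (4.786, -1.575, 4.786)  # centers a 64^3, 0.5 mm grid in front of the arc apex
    spacing: float = 0.05
    shape: tuple = (64, 64, 64)

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", _freeze(self.origin))
        object.__setattr__(self, "shape", _freeze(self.shape))


@dataclass(frozen=True)
class PhantomBlock:
    wires: tuple = ()
    background_absorption: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "wires", _freeze(self.wires))


@dataclass(frozen=True)
class NoiseBlock:
    enabled: bool = True
    band_count: int = 8
    band_rank: int = 1
    band_amplitude: float = 3.0
    white_sigma: float = 0.05
    energy_jitter: float = 0.125


@dataclass(frozen=True)
class PreprocessBlock:
    order: int = 5
    cutoff: float = 14.5e6
    k: int = 10
    zero_phase: bool = True


@dataclass(frozen=True)
class ReconBlock:
    directivity: bool = True
    sigma_l: float = 18.5
    sigma_e: float = 6.2
    compensation: bool = True
    epsilon: float = 0.01
    n_patches: int = 200


@dataclass(frozen=True)
class EvalBlock:
    n_shells: int = 50
    profile_p0: tuple | None = None
    profile_p1: tuple | None = None
    normalize: str = "unit-max"

    def __post_init__(self) -> None:
        object.__setattr__(self, "profile_p0", _freeze(self.profile_p0))
        object.__setattr__(self, "profile_p1", _freeze(self.profile_p1))


@dataclass(frozen=True)
class RunConfig:
    array: ArrayBlock = field(default_factory=ArrayBlock)
    plan: PlanBlock = field(default_factory=PlanBlock)
    illuminator: IlluminatorBlock = field(default_factory=IlluminatorBlock)
    optics: OpticsBlock = field(default_factory=OpticsBlock)
    grid: GridBlock = field(default_factory=GridBlock)
    phantom: PhantomBlock = field(default_factory=PhantomBlock)
    noise: NoiseBlock = field(default_factory=NoiseBlock)
    preprocess: PreprocessBlock = field(default_factory=PreprocessBlock)
    reconstruction: ReconBlock = field(default_factory=ReconBlock)
    evaluation: EvalBlock = field(default_factory=EvalBlock)
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d or {})
        blocks = {
            "array": ArrayBlock,
            "plan": PlanBlock,
            "illuminator": IlluminatorBlock,
            "optics": OpticsBlock,
            "grid": GridBlock,
            "phantom": PhantomBlock,
            "noise": NoiseBlock,
            "preprocess": PreprocessBlock,
            "reconstruction": ReconBlock,
            "evaluation": EvalBlock,
        }
        unknown = set(d) - set(blocks) - {"seed"}
        if unknown:
            raise ValueError(f"unknown config blocks: {sorted(unknown)}")
        kwargs = {name: _strict(bcls, d.get(name)) for name, bcls in blocks.items()}
        return cls(seed=int(d.get("seed", 0)), **kwargs)

    def to_dict(self) -> dict:
        def conv(o):
            if isinstance(o, dict):
                return {k: conv(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [conv(v) for v in o]
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            return o

        return conv(dataclasses.asdict(self))

    # ---- factories for the domain objects -------------------------------
    def build_geometry(self):
        from .geometry import build_array

        a = self.array
        return build_array(
            a.n_elements, a.arc_length, a.arc_radius,
            a.elevational_aperture, a.arc_center_polar_deg,
        )

    def build_plan(self):
        from .geometry import AcquisitionPlan

        p = self.plan
        return AcquisitionPlan(
            n_angles=p.n_angles, angular_step=p.angular_step,
            sampling_rate=p.sampling_rate, n_samples=p.n_samples,
            sound_speed=p.sound_speed,
        )

    def build_illuminator(self, geom=None):
        import dataclasses as _dc

        from .geometry import default_illuminator

        il = default_illuminator(geom if geom is not None else self.build_geometry())
        return _dc.replace(
            il,
            wide_divergence=self.illuminator.wide_divergence,
            narrow_divergence=self.illuminator.narrow_divergence,
        )

    def build_optics(self):
        from .optics import derive_optics

        o = self.optics
        return derive_optics(o.mu_a0, o.mu_s, o.g)

    def build_grid(self):
        from .geometry import VoxelGrid

        g = self.grid
        return VoxelGrid(origin=tuple(g.origin), spacing=g.spacing, shape=tuple(g.shape))

    def build_phantom(self):
        from .simulate import PhantomModel

        wires = tuple(
            (tuple(w[0]), tuple(w[1]), float(w[2]), float(w[3]))
            if isinstance(w, (list, tuple))
            else (tuple(w["start"]), tuple(w["end"]), float(w["radius"]), float(w["absorption"]))
            for w in self.phantom.wires
        )
        return PhantomModel(wires=wires, background_absorption=self.phantom.background_absorption)

    def build_noise(self):
        from .simulate import NoiseModel

        n = self.noise
        if not n.enabled:
            return None
        return NoiseModel(
            band_count=n.band_count, band_rank=n.band_rank,
            band_amplitude=n.band_amplitude, white_sigma=n.white_sigma,
            energy_jitter=n.energy_jitter, seed=self.seed,
        )

    def build_directivity(self):
        from .reconstruct import DirectivityModel

        r = self.reconstruction
        if not r.directivity:
            return None
        return DirectivityModel(sigma_L=r.sigma_l, sigma_E=r.sigma_e)


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Read a YAML (or TOML, by extension) config file."""
    p = Path(path)
    if p.suffix in (".toml", ".tml"):
        import tomllib

        d = tomllib.loads(p.read_text())
    else:
        d = yaml.safe_load(p.read_text())
    return RunConfig.from_dict(d)
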