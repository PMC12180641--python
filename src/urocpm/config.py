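"""Configuration: dataclasses mirroring the YAML config file.

A config has sections [lattice], [engine], [cell_types], [contact_energies],
[lineage], [init], [fitness], [classify] and [schedule].  The packaged
``data/default.yaml`` carries the calibrated defaults; user files only need
to override what they change.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from urocpm import constants as C


@dataclass
class LatticeConfig:
    width_um: float = 800.0
    height_um: float = 150.0
    px_per_um: float = 0.8
    bm_rows: int = 2

    @property
    def width_px(self) -> int:
        return int(round(self.width_um * self.px_per_um))

    @property
    def height_px(self) -> int:
        return int(round(self.height_um * self.px_per_um))


@dataclass
class EngineConfig:
    temperature: float = 25.0
    mcs_per_day: int = 500
    lambda_adhesion: float = 1.0
    # Target surface = surface_scale * circumference of a disc with the
    # cell's target area; rasterized discs expose ~3.2 Moore faces per unit
    # of circumference.
    surface_scale: float = 3.2


@dataclass
class CellTypeConfig:
    d_min_um: float
    d_max_um: float
    lambda_volume: float
    lambda_surface: float
    growth_rate: float  # fraction of the type's maximal volume per day
    apoptosis_chance: float  # probability per day

    def area_px(self, d_um: float, px_per_um: float) -> float:
        """Disc area in pixels for a diameter in micrometres."""
        r = 0.5 * d_um * px_per_um
        return math.pi * r * r

    def v_min_px(self, px_per_um: float) -> float:
        return self.area_px(self.d_min_um, px_per_um)

    def v_max_px(self, px_per_um: float) -> float:
        return self.area_px(self.d_max_um, px_per_um)


@dataclass
class LineageConfig:
    p_sym: float = 0.05
    p_asym: float = 0.9
    voiding_interval_hours: float = 6.0
    voiding_washout_p: float = 0.02
    # contact-driven differentiation is checked at this cadence, not every
    # MCS: a one-pixel, sub-hour medium exposure during lattice churn is not
    # "contact with the medium" on the biological timescale
    differentiation_interval_hours: float = 6.0
    # minimum medium faces for "contact with the medium" (I -> U rule)
    medium_contact_faces: int = 12
    contact_inhibition_factor: float = 50.0
    division_orientation: str = "principal"  # or "random"
    # Mitosis fires at Va >= ratio * Vmax: lattice boundary tension keeps a
    # cell's actual volume a few percent below its target, so a literal
    # Va >= Vmax check would deadlock.
    division_trigger_ratio: float = 0.9

    @property
    def p_sym_diff(self) -> float:
        return 1.0 - self.p_sym - self.p_asym


@dataclass
class InitConfig:
    progenitor_fraction: float = 0.12
    cell_width_px: int = 6
    cell_height_px: int = 6
    max_retries: int = 1000


@dataclass
class FitnessConfig:
    column_spacing_um: float = 25.0
    thickness_um: float = 85.0
    fraction_basal: float = 0.10
    fraction_intermediate: float = 0.67
    fraction_umbrella: float = 0.23
    sample_interval_days: float = 0.5
    # Elib counts the in-between layers that are not intermediate ("strict"),
    # or all in-between layers ("all") — ambiguous in the source material.
    elib_mode: str = "strict"
    # Eopt counts stacked cells in the column ("layers"); alternative: pixels
    eopt_min_layers: int = 3
    eopt_max_layers: int = 7
    # a run of fewer rows than this is measurement noise, not a layer
    min_layer_rows: int = 2


@dataclass
class ClassifyConfig:
    window_start_day: float = 20.0
    min_days: float = 100.0
    stable_slope_pct_per_100d: float = 2.0
    chaotic_fa_threshold: float = 0.6
    atrophy_final_frac: float = 0.05


@dataclass
class ScheduleConfig:
    duration_days: float = 720.0
    snapshot_every_days_early: float = 1.0
    snapshot_every_days_late: float = 10.0
    snapshot_switch_day: float = 20.0


@dataclass
class Config:
    lattice: LatticeConfig = field(default_factory=LatticeConfig)
    engine: EngineConfig = field(default_factory=EngineConfig)
    cell_types: dict = field(default_factory=dict)  # name -> CellTypeConfig
    contact_energies: dict = field(default_factory=dict)  # "a-b" -> float
    lineage: LineageConfig = field(default_factory=LineageConfig)
    init: InitConfig = field(default_factory=InitConfig)
    fitness: FitnessConfig = field(default_factory=FitnessConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    # per-lineage-model partial overrides (model ID -> config fragment);
    # some lineage models only hold a healthy tissue with adjusted rates
    model_overrides: dict = field(default_factory=dict)

    # ---- derived arrays consumed by the lattice kernel ----

    def type_params_arrays(self):
        """Per-type parameter vectors indexed by type code (0..5).

        Returns dict of float64 arrays: lambda_volume, lambda_surface,
        v_min_px, v_max_px, growth_rate, apoptosis_chance.
        """
        n = C.N_TYPES
        out = {
            k: np.zeros(n)
            for k in (
                "lambda_volume",
                "lambda_surface",
                "v_min_px",
                "v_max_px",
                "growth_rate",
                "apoptosis_chance",
            )
        }
        rho = self.lattice.px_per_um
        for name, ct in self.cell_types.items():
            code = C.TYPE_CODES[name]
            out["lambda_volume"][code] = ct.lambda_volume
            out["lambda_surface"][code] = ct.lambda_surface
            out["v_min_px"][code] = ct.v_min_px(rho)
            out["v_max_px"][code] = ct.v_max_px(rho)
            out["growth_rate"][code] = ct.growth_rate
            out["apoptosis_chance"][code] = ct.apoptosis_chance
        return out

    def contact_matrix(self) -> np.ndarray:
        """Symmetric 6x6 contact-energy matrix indexed by type code."""
        J = np.zeros((C.N_TYPES, C.N_TYPES))
        seen = set()
        for key, val in self.contact_energies.items():
            a_name, b_name = key.split("-")
            a, b = C.TYPE_CODES[a_name], C.TYPE_CODES[b_name]
            J[a, b] = J[b, a] = float(val)
            seen.add(frozenset((a, b)))
        return J

    def target_surface_px(self, target_volume_px: float) -> float:
        """Target Moore-face surface for a disc of the given pixel area."""
        circumference = 2.0 * math.sqrt(math.pi * max(target_volume_px, 0.0))
        return self.engine.surface_scale * circumference

    # ---- (de)serialisation ----

    def to_dict(self) -> dict:
        d = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name == "cell_types":
                d[f.name] = {k: dataclasses.asdict(ct) for k, ct in v.items()}
            elif f.name in ("contact_energies", "model_overrides"):
                d[f.name] = _deep_copy_dict(v)
            else:
                d[f.name] = dataclasses.asdict(v)
        return d

    def for_model(self, model_id: str) -> "Config":
        """Config with this lineage model's overrides applied (if any)."""
        override = self.model_overrides.get(str(model_id))
        if not override:
            return self
        merged = self.to_dict()
        _deep_merge(merged, override)
        merged["model_overrides"] = {}
        return Config.from_dict(merged)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "Config":
        cfg = cls()
        section_types = {
            "lattice": LatticeConfig,
            "engine": EngineConfig,
            "lineage": LineageConfig,
            "init": InitConfig,
            "fitness": FitnessConfig,
            "classify": ClassifyConfig,
            "schedule": ScheduleConfig,
        }
        for name, typ in section_types.items():
            if name in d and d[name] is not None:
                base = dataclasses.asdict(getattr(cfg, name))
                base.update(d[name])
                setattr(cfg, name, typ(**base))
        if "cell_types" in d:
            cfg.cell_types = {
                k: CellTypeConfig(**v) for k, v in d["cell_types"].items()
            }
        if "contact_energies" in d:
            cfg.contact_energies = {
                k: float(v) for k, v in d["contact_energies"].items()
            }
        if "model_overrides" in d and d["model_overrides"]:
            cfg.model_overrides = _deep_copy_dict(d["model_overrides"])
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.engine.temperature <= 0:
            raise ValueError("engine.temperature must be > 0")
        if self.engine.mcs_per_day <= 0:
            raise ValueError("engine.mcs_per_day must be > 0")
        lg = self.lineage
        if not (0 <= lg.p_sym <= 1 and 0 <= lg.p_asym <= 1 and lg.p_sym + lg.p_asym <= 1):
            raise ValueError("lineage division probabilities must lie in [0,1] and sum to <= 1")
        if not 0 <= self.init.progenitor_fraction < 1:
            raise ValueError("init.progenitor_fraction must be in [0, 1)")
        for name, ct in self.cell_types.items():
            if ct.d_min_um > ct.d_max_um:
                raise ValueError(f"cell type {name}: d_min_um > d_max_um")
        fr = self.fitness
        total = fr.fraction_basal + fr.fraction_intermediate + fr.fraction_umbrella
        if abs(total - 1.0) > 1e-9:
            raise ValueError("fitness volume fractions must sum to 1")
        # all 15 inter-type pairs + 6 self pairs must be defined when any are
        if self.contact_energies:
            need = set()
            names = [C.TYPE_NAMES[c] for c in range(C.N_TYPES)]
            for i, a in enumerate(names):
                for b in names[i:]:
                    need.add(frozenset((a, b)))
            have = {frozenset(k.split("-")) for k in self.contact_energies}
            missing = need - have
            if missing:
                raise ValueError(f"contact_energies missing pairs: {sorted(map(sorted, missing))}")


def _deep_copy_dict(d: dict) -> dict:
    return {k: _deep_copy_dict(v) if isinstance(v, dict) else v for k, v in d.items()}


def _deep_merge(base: dict, override: dict) -> None:
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_merge(base[k], v)
        else:
            base[k] = v


def default_config() -> Config:
    """The packaged default configuration."""
    text = resources.files("urocpm").joinpath("data/default.yaml").read_text()
    return Config.from_dict(yaml.safe_load(text))


def load_config(path=None) -> Config:
    """Load a config file, filling unset values from the packaged defaults."""
    if path is None:
        return default_config()
    user = yaml.safe_load(Path(path).read_text()) or {}
    base = default_config().to_dict()
    for section, val in user.items():
        if isinstance(val, dict) and section in base and isinstance(base[section], dict):
            if section in ("cell_types",):
                for k, v in val.items():
                    base[section].setdefault(k, {}).update(v)
            else:
                base[section].update(val)
        else:
            base[section] = val
    return Config.from_dict(base)
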