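"""Configuration parsing for simulation runs.

The config format is a flat key: value text file (YAML restricted to one
flat mapping).  Unknown keys are rejected so that a typo in a physical
parameter cannot silently fall back to a default.  Cell indices in
protocol-facing fields are 1-based, matching the convention used for the
measurement cells; everything internal is 0-based.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .geometry import CellGeometry, TissueParams

__all__ = ["SimConfig", "load_config", "save_config"]


@dataclass
class SimConfig:
    """Fully resolved simulation configuration with physiological defaults."""

    model: str = "knm"                  # knm | bd
    n_x: int = 15
    n_y: int = 1
    dx_um: float | None = None          # bd only; default = cell length
    dy_um: float | None = None          # bd only; default = cell width
    cell_length_um: float = 120.0
    end_radius_um: float = 6.0
    center_radius_um: float = 7.0
    margin_um: float = 2.0
    sigma_i: float = 4.0
    sigma_e: float = 20.0
    c_m: float = 1.0
    r_g: float = 0.0015
    rg_multiplier: float = 1.0
    membrane: str = "mitchell-schaeffer"
    membrane_overrides: dict = field(default_factory=dict)
    protocol: str = "s1"                # s1 | s1s2
    s2_delay_ms: float = 240.0
    stim_amplitude: float = 40.0
    stim_duration_ms: float = 2.0
    dt_ms: float = 0.01
    duration_ms: float = 50.0
    snapshot_every_ms: float = 1.0
    cv_threshold_mv: float = -20.0
    cv_cell_a: int = 3                  # 1-based measurement cells
    cv_cell_b: int = 13
    solver: str = "direct"
    solver_tol: float = 1e-10
    output_dir: str = "out"

    def __post_init__(self) -> None:
        if self.model not in ("knm", "bd"):
            raise ValueError(f"model must be 'knm' or 'bd', got {self.model!r}")
        if self.protocol not in ("s1", "s1s2"):
            raise ValueError(f"protocol must be 's1' or 's1s2', got {self.protocol!r}")
        positive = {
            "n_x": self.n_x, "n_y": self.n_y, "cell_length_um": self.cell_length_um,
            "end_radius_um": self.end_radius_um, "center_radius_um": self.center_radius_um,
            "margin_um": self.margin_um, "sigma_i": self.sigma_i,
            "sigma_e": self.sigma_e, "c_m": self.c_m, "r_g": self.r_g,
            "rg_multiplier": self.rg_multiplier, "dt_ms": self.dt_ms,
            "snapshot_every_ms": self.snapshot_every_ms,
            "stim_amplitude": self.stim_amplitude,
            "stim_duration_ms": self.stim_duration_ms, "solver_tol": self.solver_tol,
            "cv_cell_a": self.cv_cell_a, "cv_cell_b": self.cv_cell_b,
        }
        for name, value in positive.items():
            if value is None or value <= 0:
                raise ValueError(f"config key {name!r} must be strictly positive, got {value!r}")
        for name, value in (("dx_um", self.dx_um), ("dy_um", self.dy_um)):
            if value is not None and value <= 0:
                raise ValueError(f"config key {name!r} must be strictly positive, got {value!r}")
        if self.duration_ms < 0:
            raise ValueError("duration_ms must be nonnegative")
        if self.s2_delay_ms < 0:
            raise ValueError("s2_delay_ms must be nonnegative")

    def geometry(self) -> CellGeometry:
        return CellGeometry(
            length=self.cell_length_um,
            end_radius=self.end_radius_um,
            center_radius=self.center_radius_um,
            margin=self.margin_um,
        )

    def tissue_params(self) -> TissueParams:
        return TissueParams(
            sigma_i=self.sigma_i, sigma_e=self.sigma_e, c_m=self.c_m,
            r_g=self.r_g, rg_multiplier=self.rg_multiplier,
        )

    def membrane_model(self):
        from .membrane import get_model

        return get_model(self.membrane, **self.membrane_overrides)

    def build_network(self):
        if self.model == "knm":
            from .geometry import build_grid_network

            return build_grid_network(self.n_x, self.n_y, self.geometry(),
                                      self.tissue_params())
        from .bidomain import build_fd_network

        return build_fd_network(self.n_x, self.n_y, self.geometry(),
                                self.tissue_params(), dx=self.dx_um, dy=self.dy_um)

    def build_protocol(self, net):
        from .protocols import s1_protocol, s1_s2_protocol

        if self.protocol == "s1":
            return s1_protocol(net, amplitude=self.stim_amplitude,
                               duration=self.stim_duration_ms)
        return s1_s2_protocol(net, self.s2_delay_ms, amplitude=self.stim_amplitude,
                              duration=self.stim_duration_ms)

    def to_dict(self) -> dict:
        return asdict(self)


_KNOWN_KEYS = {f.name for f in fields(SimConfig)}


def load_config(path) -> SimConfig:
    """Load and validate a flat key: value config file; unknown keys are errors.

    An empty file yields the all-defaults configuration (the 15-cell strand
    with physiological parameters).
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config must be a flat key: value mapping, got {type(data).__name__}")
    unknown = sorted(set(data) - _KNOWN_KEYS)
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(unknown)}")
    return SimConfig(**data)


def save_config(config: SimConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
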