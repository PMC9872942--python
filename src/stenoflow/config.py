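"""Configuration tables: geometry-parameter ranges, cloud sizes, run profiles.

The default :class:`GeometryRanges` encodes the morphometric envelope of a
stenotic carotid bifurcation: common/internal/external carotid diameters,
the ICA–ECA bifurcation angle, and 1–2 stenoses per diseased vessel with
diameter-based severity up to 80% and lesion lengths of 5–20 mm.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import yaml

from .errors import ConfigurationError

#: Branch identifiers: common, internal and external carotid arteries.
CCA, ICA, ECA = "CCA", "ICA", "ECA"
BRANCHES = (CCA, ICA, ECA)


def _check_range(name: str, lo: float, hi: float) -> None:
    if lo > hi:
        raise ConfigurationError(f"range for {name!r} has min {lo} > max {hi}")


@dataclass(frozen=True)
class GeometryRanges:
    """Sampling ranges for the seven vessel/stenosis parameters (mm, degrees).

    Defaults span the adult carotid morphometry used throughout the package:
    CCA 6.7–9.0 mm, ICA 4.6–6.3 mm, ECA 3.8–5.2 mm, bifurcation angle
    20–120 degrees, 1–2 stenoses of severity 0–80% and length 5–20 mm placed
    on the CCA or ICA.
    """

    d_cca: tuple[float, float] = (6.7, 9.0)
    d_ica: tuple[float, float] = (4.6, 6.3)
    d_eca: tuple[float, float] = (3.8, 5.2)
    bifurcation_angle: tuple[float, float] = (20.0, 120.0)
    n_stenoses: tuple[int, int] = (1, 2)
    severity: tuple[float, float] = (0.0, 0.8)
    stenosis_length: tuple[float, float] = (5.0, 20.0)
    branch_lengths: Mapping[str, float] = field(
        default_factory=lambda: {CCA: 40.0, ICA: 40.0, ECA: 35.0}
    )

    def __post_init__(self) -> None:
        for name in ("d_cca", "d_ica", "d_eca", "bifurcation_angle",
                     "n_stenoses", "severity", "stenosis_length"):
            lo, hi = getattr(self, name)
            _check_range(name, lo, hi)
        if not (0.0 <= self.severity[0] and self.severity[1] <= 0.8):
            raise ConfigurationError("severity range must lie within [0, 0.8]")

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeometryRanges":
        kwargs = dict(d)
        for key in ("d_cca", "d_ica", "d_eca", "bifurcation_angle",
                    "n_stenoses", "severity", "stenosis_length"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["branch_lengths"] = dict(self.branch_lengths)
        return d


@dataclass(frozen=True)
class RunProfile:
    """Problem sizes for one end-to-end run.

    ``smoke`` is a seconds-scale plumbing check, ``desk`` a single-CPU study
    at one-tenth-scale clouds, ``full`` mirrors the thousand-model study with
    full-resolution clouds and the reference 1,000-epoch schedule.
    """

    name: str
    n_models: int
    n_cavity: int
    n_fluid: int
    epochs: int
    cavity_subsample: int | None
    fluid_subsample: int | None
    eval_subsample: int | None


PROFILES: dict[str, RunProfile] = {
    "smoke": RunProfile("smoke", n_models=10, n_cavity=300, n_fluid=1200,
                        epochs=3, cavity_subsample=128, fluid_subsample=256,
                        eval_subsample=256),
    "desk": RunProfile("desk", n_models=100, n_cavity=2000, n_fluid=10000,
                       epochs=100, cavity_subsample=512, fluid_subsample=512,
                       eval_subsample=1024),
    "full": RunProfile("full", n_models=1000, n_cavity=40000, n_fluid=220000,
                       epochs=1000, cavity_subsample=None, fluid_subsample=None,
                       eval_subsample=None),
}


def load_ranges(path) -> GeometryRanges:
    """Read a YAML/TOML-style parameter-range table into :class:`GeometryRanges`."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: expected a mapping of parameter ranges")
    return GeometryRanges.from_dict(data)
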