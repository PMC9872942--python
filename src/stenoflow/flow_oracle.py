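"""Reduced-physics steady flow oracle at the systolic-peak instant.

Produces pressure and velocity at the fluid points of a vessel from three
ingredients, standing in for a transient Navier–Stokes solve:

* continuity — the inlet flow splits over the daughters by Murray's law
  (flow ratio equal to the cube of the diameter ratio) and the local mean
  axial speed is Q/A(s);
* a Poiseuille profile — velocity 2·V̄(s)·(1 − (r/R)²) along the local
  centerline tangent, with the direction blended between parent and daughter
  tangents inside the junction transition zone;
* pressure from the integrated Poiseuille gradient 8μQ/(πR⁴) from the point
  to its outlet (gauge, outlets at the reference pressure), plus a lumped
  Young–Tsai-type expansion loss per traversed stenosis,
  ΔP = Kt·(ρ/2)·V̄_up²·(A_up/A_throat − 1)², applied at the distal window edge.

Blood is treated as Newtonian with density 1,060 kg/m³ and viscosity
0.0035 Pa·s; the default inlet mass flow is the systolic-peak value of
0.182 kg/s.  Geometry is in mm; all formulas run in SI and the fields are
stored in Pa and m/s.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, GeometryError
from .config import CCA, ECA, ICA
from .geometry import FluidPointCoordinates, VesselGeometry, VesselSpec

__all__ = ["FluidProperties", "InflowSpec", "FlowField", "split_outflow",
           "compute_field", "reynolds_number"]

_MM = 1e-3  # mm -> m


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian blood: density (kg/m³) and dynamic viscosity (Pa·s)."""

    density: float = 1060.0
    viscosity: float = 0.0035

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be positive")


@dataclass(frozen=True)
class InflowSpec:
    """Systolic-peak inlet boundary condition.

    ``mass_flow_inlet`` is the systolic-peak mass flow (kg/s).  The default
    0.0476 kg/s is the value consistent with a cycle-mean Reynolds number of
    ~346 and a peak Reynolds number of ~2,200 in a 7.318 mm common carotid —
    the upper end of the laminar regime the oracle assumes.
    ``outlet_reference_pressure`` is the absolute outlet pressure at the
    systolic instant, defaulting to a physiological systolic value of
    16 kPa (~120 mmHg), emulating a pressure-waveform outlet boundary.
    """

    mass_flow_inlet: float = 0.0476
    outlet_reference_pressure: float = 16000.0

    def __post_init__(self) -> None:
        if self.mass_flow_inlet <= 0:
            raise ValueError("mass_flow_inlet must be positive")


@dataclass(frozen=True)
class FlowField:
    """Per-point pressure (Pa) and velocity (m/s), matched 1:1 to fluid points."""

    pressure: np.ndarray   # (N2,)
    velocity: np.ndarray   # (N2, 3)

    def __post_init__(self) -> None:
        p = np.asarray(self.pressure, dtype=float)
        v = np.asarray(self.velocity, dtype=float)
        if p.ndim != 1 or v.shape != (len(p), 3):
            raise ValueError("pressure must be (N2,) and velocity (N2, 3)")
        if not (np.all(np.isfinite(p)) and np.all(np.isfinite(v))):
            raise ValueError("flow field contains non-finite values")
        object.__setattr__(self, "pressure", p)
        object.__setattr__(self, "velocity", v)

    @property
    def speed(self) -> np.ndarray:
        return np.linalg.norm(self.velocity, axis=1)


def reynolds_number(diameter: float, mean_velocity: float,
                    props: FluidProperties = FluidProperties()) -> float:
    """Re = rho * V * D / mu (diameter in m, velocity in m/s)."""
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    return props.density * mean_velocity * diameter / props.viscosity


def split_outflow(spec: VesselSpec, q_in: float) -> tuple[float, float]:
    """Murray's-law partition of the inlet volumetric flow over ICA and ECA.

    q_ica/q_eca = (d_ica/d_eca)^3 and q_ica + q_eca = q_in exactly.
    """
    if q_in <= 0:
        raise ValueError("q_in must be positive")
    w_ica = spec.d_ica ** 3
    w_eca = spec.d_eca ** 3
    q_ica = q_in * w_ica / (w_ica + w_eca)
    return q_ica, q_in - q_ica


class _BranchFlow:
    """Per-branch pressure-integral tables in SI units."""

    def __init__(self, geom: VesselGeometry, name: str, q: float,
                 props: FluidProperties, kt: float, use_loss: bool):
        self.name = name
        self.q = q
        b = geom.branches[name]
        self.length_m = b.length * _MM
        s_mm = geom._grid(name)
        r_m = geom.radius(name, s_mm) * _MM
        if np.any(r_m <= 0):  # pragma: no cover - guarded upstream
            raise GeometryError(f"non-positive radius on {name}")
        self.s_m = s_mm * _MM
        self.r_m = r_m
        grad = 8.0 * props.viscosity * q / (np.pi * r_m ** 4)  # Pa/m
        cum = np.concatenate([[0.0], np.cumsum(
            (grad[1:] + grad[:-1]) * 0.5 * np.diff(self.s_m))])
        self._cum = cum  # integral of the gradient from 0 to s
        self.viscous_drop = float(cum[-1])
        # lumped expansion losses: (distal edge s in m, delta-p in Pa)
        self.losses: list[tuple[float, float]] = []
        if use_loss:
            for st in geom.spec.effective_stenoses:
                if st.branch != name:
                    continue
                r0 = b.r0 * _MM
                a_up = np.pi * r0 ** 2
                a_throat = np.pi * (r0 * (1.0 - st.severity)) ** 2
                v_up = q / a_up
                dp = kt * 0.5 * props.density * v_up ** 2 * (a_up / a_throat - 1.0) ** 2
                self.losses.append((st.window[1] * _MM, dp))
        self.total_loss = sum(dp for _, dp in self.losses)

    def pressure_to_outlet(self, s_m: np.ndarray) -> np.ndarray:
        """Viscous + lumped drop accumulated from s to the branch's distal end."""
        drop = self.viscous_drop - np.interp(s_m, self.s_m, self._cum)
        for edge, dp in self.losses:
            drop = drop + dp * (s_m < edge)
        return drop

    def mean_speed(self, s_m: np.ndarray, r_local_m: np.ndarray) -> np.ndarray:
        area = np.pi * r_local_m ** 2
        return self.q / area


def compute_field(spec: VesselSpec, points: FluidPointCoordinates,
                  inflow: InflowSpec = InflowSpec(),
                  props: FluidProperties = FluidProperties(),
                  *, stenosis_loss: bool = True,
                  loss_coefficient: float = 1.0) -> FlowField:
    """Evaluate the reduced-physics systolic-peak field at the fluid points.

    ``stenosis_loss=False`` disables the lumped expansion term, leaving the
    pure Poiseuille integral (used by the closed-form straight-tube checks).
    """
    geom = VesselGeometry(spec)
    pts = points.points
    inside = geom.in_lumen(pts, tol=1e-9)
    if not np.all(inside):
        raise DomainError(f"{int((~inside).sum())} fluid points outside the lumen")

    q_in = inflow.mass_flow_inlet / props.density
    has_daughters = ICA in geom.branches or ECA in geom.branches
    flows: dict[str, float] = {CCA: q_in}
    if has_daughters:
        q_ica, q_eca = split_outflow(spec, q_in)
        flows[ICA], flows[ECA] = q_ica, q_eca
    tables = {name: _BranchFlow(geom, name, flows[name], props,
                                loss_coefficient, stenosis_loss)
              for name in geom.branch_order}

    # apex gauge pressure: outlet reference plus the ICA-path drop
    p_ref = inflow.outlet_reference_pressure
    if has_daughters:
        ref_daughter = ICA if ICA in geom.branches else ECA
        t_ref = tables[ref_daughter]
        p_apex = p_ref + t_ref.viscous_drop + t_ref.total_loss
    else:
        p_apex = p_ref  # single tube: CCA end is the outlet

    n = len(pts)
    pressure = np.empty(n)
    velocity = np.empty((n, 3))
    assigned = np.zeros(n, dtype=bool)

    # daughters take precedence so junction points follow the daughter flow
    daughter_names = [nm for nm in (ICA, ECA) if nm in geom.branches]
    t_cca = geom.branches[CCA].tangent
    transition_m = geom.transition_length * _MM
    for name in daughter_names:
        mask = geom.contains(name, pts, tol=1e-9) & ~assigned
        if not np.any(mask):
            continue
        tbl = tables[name]
        s_mm, d_mm = geom.project(name, pts[mask])
        s_m = np.clip(s_mm, 0.0, None) * _MM
        r_loc = np.interp(s_m, tbl.s_m, tbl.r_m)
        vbar = tbl.mean_speed(s_m, r_loc)
        frac = np.clip(d_mm * _MM / r_loc, 0.0, 1.0)
        mag = 2.0 * vbar * (1.0 - frac ** 2)
        w = np.clip(s_m / transition_m, 0.0, 1.0)[:, None]
        direction = (1.0 - w) * t_cca + w * geom.branches[name].tangent
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        velocity[mask] = mag[:, None] * direction
        pressure[mask] = p_ref + tbl.pressure_to_outlet(s_m)
        assigned |= mask

    mask = ~assigned
    if np.any(mask):
        tbl = tables[CCA]
        s_mm, d_mm = geom.project(CCA, pts[mask])
        s_m = np.clip(s_mm, 0.0, geom.branches[CCA].length) * _MM
        r_loc = np.interp(s_m, tbl.s_m, tbl.r_m)
        vbar = tbl.mean_speed(s_m, r_loc)
        frac = np.clip(d_mm * _MM / r_loc, 0.0, 1.0)
        mag = 2.0 * vbar * (1.0 - frac ** 2)
        velocity[mask] = mag[:, None] * t_cca
        if has_daughters:
            pressure[mask] = p_apex + tbl.pressure_to_outlet(s_m)
        else:
            pressure[mask] = p_ref + tbl.pressure_to_outlet(s_m)
    return FlowField(pressure=pressure, velocity=velocity)
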