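"""Parametric stenotic carotid-bifurcation geometry and point-cloud sampling.

The vessel is modelled as a union of three straight circular tubes (CCA, ICA,
ECA) meeting at a bifurcation apex.  Coordinates are millimetres; the CCA
inlet is centred at the origin with its axis along +z, and the daughter
branches lie in the x–z plane, deviating from the CCA axis by angles that sum
to the bifurcation angle, split proportionally to branch diameters.

Stenoses are axisymmetric cosine-profile constrictions with diameter-based
(NASCET-style) severity: at the throat the local diameter is reduced by the
severity fraction sigma, and the profile returns smoothly to the baseline
radius at the window edges.

Two point clouds are sampled per vessel: a *cavity* cloud on the lumen
surface (geometry carrier, coordinates only) and a *fluid* cloud strictly
inside the lumen (field carrier).  Both are deterministic given a seed.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .config import BRANCHES, CCA, ECA, ICA, GeometryRanges
from .errors import ConfigurationError, DomainError, GeometryError

__all__ = [
    "StenosisSpec", "VesselSpec", "CenterlineTree", "CavityPointCloud",
    "FluidPointCoordinates", "VesselGeometry", "sample_vessel_spec",
    "stenosed_radius", "build_cavity_cloud", "sample_fluid_points",
    "make_postoperative", "straight_tube_spec", "write_ply",
    "write_vtk_polydata",
]

_GRID_DS = 0.02  # mm; quadrature spacing for radius/area/volume integrals


# ---------------------------------------------------------------------------
# Specs


@dataclass(frozen=True)
class StenosisSpec:
    """One axisymmetric constriction on a branch.

    ``center_s`` is the arc-length position (mm) of the throat along the
    branch centerline, ``length`` the axial window (mm) over which the cosine
    profile acts, ``severity`` the fractional diameter reduction at the
    throat (0 = none, 0.8 = 80% stenosis).
    """

    branch: str
    center_s: float
    length: float
    severity: float

    def __post_init__(self) -> None:
        if self.branch not in (CCA, ICA):
            raise ConfigurationError(f"stenosis branch must be CCA or ICA, got {self.branch!r}")
        if not 0.0 <= self.severity <= 0.8:
            raise ConfigurationError(f"severity {self.severity} outside [0, 0.8]")
        if not 5.0 <= self.length <= 20.0:
            raise ConfigurationError(f"stenosis length {self.length} mm outside [5, 20]")

    @property
    def window(self) -> tuple[float, float]:
        return (self.center_s - self.length / 2.0, self.center_s + self.length / 2.0)


@dataclass(frozen=True)
class VesselSpec:
    """Seven-parameter description of one (possibly stenosed) carotid bifurcation."""

    d_cca: float
    d_ica: float
    d_eca: float
    bifurcation_angle: float  # degrees between ICA and ECA courses
    branch_lengths: dict = field(default_factory=lambda: {CCA: 40.0, ICA: 40.0, ECA: 35.0})
    stenoses: tuple[StenosisSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for name, d in (("d_cca", self.d_cca), ("d_ica", self.d_ica), ("d_eca", self.d_eca)):
            if d <= 0:
                raise ConfigurationError(f"{name} must be positive, got {d}")
        if not (self.d_ica < self.d_cca and self.d_eca < self.d_cca):
            raise ConfigurationError("daughter diameters must be smaller than the CCA diameter")
        object.__setattr__(self, "stenoses", tuple(self.stenoses))
        for st in self.stenoses:
            lo, hi = st.window
            length = self.branch_lengths.get(st.branch, 0.0)
            if lo < 0.0 or hi > length:
                raise ConfigurationError(
                    f"stenosis window [{lo:.2f}, {hi:.2f}] mm outside {st.branch} "
                    f"of length {length} mm")

    @property
    def effective_stenoses(self) -> tuple[StenosisSpec, ...]:
        """Stenoses with nonzero severity (a zeroed record marks a removed lesion)."""
        return tuple(st for st in self.stenoses if st.severity > 0.0)

    def to_json(self) -> str:
        d = {
            "d_cca": self.d_cca, "d_ica": self.d_ica, "d_eca": self.d_eca,
            "bifurcation_angle": self.bifurcation_angle,
            "branch_lengths": dict(self.branch_lengths),
            "stenoses": [
                {"branch": s.branch, "center_s": s.center_s,
                 "length": s.length, "severity": s.severity}
                for s in self.stenoses
            ],
            "seed": self.seed,
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "VesselSpec":
        d = json.loads(text)
        stenoses = tuple(StenosisSpec(**s) for s in d.pop("stenoses"))
        return cls(stenoses=stenoses, **d)


def straight_tube_spec(diameter: float = 6.0, length: float = 40.0,
                       stenoses: Sequence[StenosisSpec] = (), seed: int = 0) -> VesselSpec:
    """A degenerate single-branch vessel (zero-length daughters): a straight tube.

    Used for closed-form flow checks; the daughter diameters are placeholders
    and carry no flow because the branches have zero length.
    """
    return VesselSpec(
        d_cca=diameter, d_ica=diameter * 0.6, d_eca=diameter * 0.5,
        bifurcation_angle=0.0,
        branch_lengths={CCA: length, ICA: 0.0, ECA: 0.0},
        stenoses=tuple(stenoses), seed=seed)


# ---------------------------------------------------------------------------
# Geometry engine


@dataclass(frozen=True)
class _Branch:
    name: str
    origin: np.ndarray   # (3,) mm
    tangent: np.ndarray  # (3,) unit
    length: float        # mm
    r0: float            # baseline radius, mm

    def frame(self) -> tuple[np.ndarray, np.ndarray]:
        """Two unit vectors orthogonal to the tangent (deterministic)."""
        t = self.tangent
        helper = np.array([0.0, 1.0, 0.0]) if abs(t[1]) < 0.9 else np.array([1.0, 0.0, 0.0])
        e1 = np.cross(t, helper)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(t, e1)
        return e1, e2


@dataclass(frozen=True)
class CenterlineTree:
    """Per-branch centerline polylines with arc length and baseline radius."""

    branches: tuple[str, ...]
    polylines: dict          # branch -> (M, 3) points, mm
    arc_lengths: dict        # branch -> (M,) s values, mm
    base_radii: dict         # branch -> (M,) r0(s) values, mm
    apex: np.ndarray         # (3,) bifurcation apex, mm


class VesselGeometry:
    """Evaluates radii, memberships and samples point clouds for a VesselSpec."""

    def __init__(self, spec: VesselSpec):
        self.spec = spec
        lengths = spec.branch_lengths
        z = np.array([0.0, 0.0, 1.0])
        apex = z * lengths[CCA]
        total = math.radians(spec.bifurcation_angle)
        # deviation from the CCA axis split proportionally to branch diameters
        a_ica = total * spec.d_ica / (spec.d_ica + spec.d_eca)
        a_eca = total - a_ica
        t_ica = np.array([math.sin(a_ica), 0.0, math.cos(a_ica)])
        t_eca = np.array([-math.sin(a_eca), 0.0, math.cos(a_eca)])
        branches = [_Branch(CCA, np.zeros(3), z, lengths[CCA], spec.d_cca / 2.0)]
        if lengths.get(ICA, 0.0) > 0.0:
            branches.append(_Branch(ICA, apex.copy(), t_ica, lengths[ICA], spec.d_ica / 2.0))
        if lengths.get(ECA, 0.0) > 0.0:
            branches.append(_Branch(ECA, apex.copy(), t_eca, lengths[ECA], spec.d_eca / 2.0))
        self.branches = {b.name: b for b in branches}
        self.branch_order = tuple(b.name for b in branches)
        self.apex = apex
        #: axial extent (mm) of the junction blending zone around the apex
        self.transition_length = spec.d_cca / 2.0
        self._stenoses = {
            name: tuple(st for st in spec.stenoses if st.branch == name)
            for name in self.branch_order
        }

    # -- radii ------------------------------------------------------------

    def radius(self, branch: str, s, *, baseline: bool = False) -> np.ndarray:
        """Stenosed (or baseline) lumen radius r(s) in mm; vectorized over s."""
        b = self._branch(branch)
        s = np.atleast_1d(np.asarray(s, dtype=float))
        r = np.full_like(s, b.r0, dtype=float)
        if baseline:
            return r
        for st in self._stenoses.get(branch, ()):
            if st.severity <= 0.0:
                continue
            lo, hi = st.window
            inside = (s >= lo) & (s <= hi)
            c = 0.5 * (1.0 + np.cos(2.0 * np.pi * (s[inside] - st.center_s) / st.length))
            r[inside] *= 1.0 - st.severity * c
        if np.any(r <= 0.0):
            raise GeometryError(f"non-positive lumen radius on {branch}")
        return r

    def _branch(self, name: str) -> _Branch:
        try:
            return self.branches[name]
        except KeyError:
            raise DomainError(f"vessel has no branch {name!r}") from None

    # -- projections and membership ---------------------------------------

    def project(self, branch: str, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(s, perpendicular distance) of each point w.r.t. the branch axis, mm."""
        b = self._branch(branch)
        rel = np.atleast_2d(points) - b.origin
        s = rel @ b.tangent
        perp = rel - s[:, None] * b.tangent
        return s, np.linalg.norm(perp, axis=1)

    def contains(self, branch: str, points: np.ndarray, *, tol: float = 0.0) -> np.ndarray:
        """Boolean mask: point within the branch's axial slab and inside r(s)·(1+tol)."""
        b = self._branch(branch)
        s, d = self.project(branch, points)
        in_slab = (s >= 0.0) & (s <= b.length)
        mask = np.zeros(len(s), dtype=bool)
        if np.any(in_slab):
            r = self.radius(branch, np.clip(s[in_slab], 0.0, b.length))
            mask[in_slab] = d[in_slab] < r * (1.0 + tol)
        return mask

    def in_lumen(self, points: np.ndarray, *, tol: float = 0.0) -> np.ndarray:
        mask = np.zeros(len(np.atleast_2d(points)), dtype=bool)
        for name in self.branch_order:
            mask |= self.contains(name, points, tol=tol)
        return mask

    # -- integral measures --------------------------------------------------

    def _grid(self, branch: str) -> np.ndarray:
        b = self._branch(branch)
        n = max(2, int(math.ceil(b.length / _GRID_DS)) + 1)
        return np.linspace(0.0, b.length, n)

    def surface_area(self, branch: str, *, baseline: bool = False) -> float:
        s = self._grid(branch)
        r = self.radius(branch, s, baseline=baseline)
        return float(np.trapezoid(2.0 * np.pi * r, s))

    def volume(self, branch: str, *, baseline: bool = False) -> float:
        s = self._grid(branch)
        r = self.radius(branch, s, baseline=baseline)
        return float(np.trapezoid(np.pi * r ** 2, s))

    # -- centerline export --------------------------------------------------

    def centerline_tree(self, ds: float = 0.5) -> CenterlineTree:
        polylines, arcs, radii = {}, {}, {}
        for name in self.branch_order:
            b = self.branches[name]
            n = max(2, int(math.ceil(b.length / ds)) + 1)
            s = np.linspace(0.0, b.length, n)
            polylines[name] = b.origin + s[:, None] * b.tangent
            arcs[name] = s
            radii[name] = np.full(n, b.r0)
        return CenterlineTree(self.branch_order, polylines, arcs, radii, self.apex.copy())

    # -- sampling -----------------------------------------------------------

    def _sample_s(self, branch: str, k: int, rng: np.random.Generator,
                  density: str) -> np.ndarray:
        """Inverse-CDF draw of k arc lengths with density ∝ r0(s) or r(s)^2."""
        s = self._grid(branch)
        if density == "area":
            w = self.radius(branch, s, baseline=True)  # baseline allocation (pairing)
        elif density == "volume":
            w = self.radius(branch, s) ** 2
        else:  # pragma: no cover - internal
            raise ValueError(density)
        cdf = np.concatenate([[0.0], np.cumsum((w[1:] + w[:-1]) * 0.5 * np.diff(s))])
        cdf /= cdf[-1]
        return np.interp(rng.random(k), cdf, s)

    def sample_cavity(self, n_target: int, seed: int) -> np.ndarray:
        """Approximately area-uniform points on the lumen surface (mm).

        Allocation over branches and along s follows the *baseline* (lesion-
        free) surface measure so that a spec and its severity-zeroed twin emit
        clouds that coincide outside the stenosis windows for the same seed;
        each point is then placed at the local stenosed radius.
        """
        if n_target < 100:
            raise ValueError(f"cavity cloud needs n_target >= 100, got {n_target}")
        rng = np.random.default_rng(seed)
        names = list(self.branch_order)
        areas = np.array([self.surface_area(n, baseline=True) for n in names])
        collected: list[np.ndarray] = []
        total = 0
        for _ in range(40):
            deficit = n_target - total
            if deficit <= 0:
                break
            m = max(64, int(math.ceil(1.5 * deficit)))
            counts = rng.multinomial(m, areas / areas.sum())
            for name, k in zip(names, counts):
                if k == 0:
                    continue
                pts = self._emit_surface(name, k, rng)
                keep = np.ones(len(pts), dtype=bool)
                for other in names:
                    if other != name:
                        keep &= ~self.contains(other, pts, tol=-1e-9)
                pts = pts[keep]
                collected.append(pts)
                total += len(pts)
        points = np.concatenate(collected, axis=0)
        if len(points) < int(0.95 * n_target):  # pragma: no cover - defensive
            raise GeometryError("cavity sampling failed to reach the target count")
        if len(points) > n_target:
            idx = rng.choice(len(points), size=n_target, replace=False)
            points = points[idx]
        return np.ascontiguousarray(points)

    def _emit_surface(self, branch: str, k: int, rng: np.random.Generator) -> np.ndarray:
        b = self.branches[branch]
        s = self._sample_s(branch, k, rng, "area")
        theta = rng.random(k) * 2.0 * np.pi
        r = self.radius(branch, s)
        e1, e2 = b.frame()
        radial = np.cos(theta)[:, None] * e1 + np.sin(theta)[:, None] * e2
        return b.origin + s[:, None] * b.tangent + r[:, None] * radial

    def sample_fluid(self, n_target: int, seed: int) -> np.ndarray:
        """Volume-uniform points strictly inside the lumen union (mm)."""
        if n_target < 100:
            raise ValueError(f"fluid cloud needs n_target >= 100, got {n_target}")
        rng = np.random.default_rng(seed)
        names = list(self.branch_order)
        vols = np.array([self.volume(n) for n in names])
        collected: list[np.ndarray] = []
        total = 0
        for _ in range(60):
            deficit = n_target - total
            if deficit <= 0:
                break
            m = max(64, int(math.ceil(1.3 * deficit)))
            counts = rng.multinomial(m, vols / vols.sum())
            for bi, (name, k) in enumerate(zip(names, counts)):
                if k == 0:
                    continue
                b = self.branches[name]
                s = self._sample_s(name, k, rng, "volume")
                theta = rng.random(k) * 2.0 * np.pi
                rho = self.radius(name, s) * np.sqrt(rng.random(k)) * (1.0 - 1e-12)
                e1, e2 = b.frame()
                radial = np.cos(theta)[:, None] * e1 + np.sin(theta)[:, None] * e2
                pts = b.origin + s[:, None] * b.tangent + rho[:, None] * radial
                # union de-duplication: a point belongs to the first branch
                # (in CCA, ICA, ECA order) that contains it
                keep = np.ones(len(pts), dtype=bool)
                for other in names[:bi]:
                    keep &= ~self.contains(other, pts)
                pts = pts[keep]
                collected.append(pts)
                total += len(pts)
        points = np.concatenate(collected, axis=0)
        if len(points) < n_target:  # pragma: no cover - defensive
            raise GeometryError("fluid sampling failed to reach the target count")
        if len(points) > n_target:
            idx = rng.choice(len(points), size=n_target, replace=False)
            points = points[idx]
        return np.ascontiguousarray(points)


# ---------------------------------------------------------------------------
# Cloud containers


@dataclass(frozen=True)
class CavityPointCloud:
    """Lumen-surface points (mm); the geometry carrier fed to the network."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) == 0:
            raise ValueError("cavity cloud must be a non-empty (N1, 3) array")
        if not np.all(np.isfinite(pts)):
            raise ValueError("cavity cloud contains non-finite coordinates")
        object.__setattr__(self, "points", pts)

    @property
    def n1(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class FluidPointCoordinates:
    """Strictly interior points (mm); field values are attached separately."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) == 0:
            raise ValueError("fluid cloud must be a non-empty (N2, 3) array")
        if not np.all(np.isfinite(pts)):
            raise ValueError("fluid cloud contains non-finite coordinates")
        object.__setattr__(self, "points", pts)

    @property
    def n2(self) -> int:
        return len(self.points)


# ---------------------------------------------------------------------------
# Public operations


def sample_vessel_spec(seed: int, ranges: GeometryRanges | None = None,
                       stage: str = "preoperative") -> VesselSpec:
    """Draw one vessel spec uniformly from the configured parameter ranges.

    ``stage="postoperative"`` consumes the identical random stream and then
    drops the stenoses, so the same seed yields the diameters/angle of the
    corresponding preoperative draw.
    """
    if stage not in ("preoperative", "postoperative"):
        raise ConfigurationError(f"unknown stage {stage!r}")
    ranges = ranges or GeometryRanges()
    rng = np.random.default_rng(seed)
    d_cca = rng.uniform(*ranges.d_cca)
    d_ica = rng.uniform(*ranges.d_ica)
    d_eca = rng.uniform(*ranges.d_eca)
    angle = rng.uniform(*ranges.bifurcation_angle)
    lengths = dict(ranges.branch_lengths)
    transition = d_cca / 2.0
    n_sten = int(rng.integers(ranges.n_stenoses[0], ranges.n_stenoses[1] + 1))
    stenoses: list[StenosisSpec] = []
    for _ in range(n_sten):
        for _attempt in range(100):
            branch = (CCA, ICA)[int(rng.integers(0, 2))]
            length = rng.uniform(*ranges.stenosis_length)
            sigma = rng.uniform(*ranges.severity)
            # keep the window inside the branch and clear of the junction zone
            if branch == CCA:
                lo, hi = length / 2.0, lengths[CCA] - length / 2.0 - transition
            else:
                lo, hi = transition + length / 2.0, lengths[ICA] - length / 2.0
            if hi <= lo:
                continue
            center = rng.uniform(lo, hi)
            cand = StenosisSpec(branch, center, length, sigma)
            if all(_disjoint(cand, other) for other in stenoses):
                stenoses.append(cand)
                break
        else:  # pragma: no cover - 100 failed draws
            raise GeometryError("could not place disjoint stenoses in 100 attempts")
    if stage == "postoperative":
        stenoses = []
    return VesselSpec(d_cca=d_cca, d_ica=d_ica, d_eca=d_eca,
                      bifurcation_angle=angle, branch_lengths=lengths,
                      stenoses=tuple(stenoses), seed=int(seed))


def _disjoint(a: StenosisSpec, b: StenosisSpec) -> bool:
    if a.branch != b.branch:
        return True
    return a.window[1] < b.window[0] or b.window[1] < a.window[0]


def stenosed_radius(spec: VesselSpec, branch: str, s) -> np.ndarray:
    """Lumen radius (mm) at arc length s along a branch, after constrictions."""
    geom = VesselGeometry(spec)
    b = geom._branch(branch)
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr < 0.0) or np.any(s_arr > b.length):
        raise DomainError(f"arc length outside [0, {b.length}] mm on {branch}")
    out = geom.radius(branch, s_arr)
    return out if np.ndim(s) else float(out[0])


def build_cavity_cloud(spec: VesselSpec, n_target: int, seed: int) -> CavityPointCloud:
    """Sample the cavity (lumen-surface) point cloud; deterministic given seed."""
    return CavityPointCloud(VesselGeometry(spec).sample_cavity(n_target, seed))


def sample_fluid_points(spec: VesselSpec, n_target: int, seed: int) -> FluidPointCoordinates:
    """Sample volume-uniform interior points; deterministic given seed."""
    return FluidPointCoordinates(VesselGeometry(spec).sample_fluid(n_target, seed))


def make_postoperative(spec: VesselSpec) -> VesselSpec:
    """The surgical twin: identical vessel with every stenosis severity zeroed.

    The zeroed stenosis records are kept so the original throat stations
    remain addressable (e.g. for paired-slab velocity comparisons).
    """
    zeroed = tuple(replace(st, severity=0.0) for st in spec.stenoses)
    return replace(spec, stenoses=zeroed)


# ---------------------------------------------------------------------------
# Writers (points-only exports)


def write_ply(points: np.ndarray, path) -> None:
    """ASCII PLY point cloud (vertices only)."""
    pts = np.asarray(points, dtype=float)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(pts)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("end_header\n")
        np.savetxt(fh, pts, fmt="%.8g")


def write_vtk_polydata(points: np.ndarray, path, point_data: dict | None = None) -> None:
    """Legacy-ASCII VTK polydata with optional scalar/vector point arrays."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nstenoflow point cloud\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {n} double\n")
        np.savetxt(fh, pts, fmt="%.10g")
        fh.write(f"VERTICES {n} {2 * n}\n")
        np.savetxt(fh, np.column_stack([np.ones(n, dtype=int), np.arange(n)]), fmt="%d")
        if point_data:
            fh.write(f"POINT_DATA {n}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr, dtype=float)
                if arr.ndim == 1:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    np.savetxt(fh, arr, fmt="%.10g")
                elif arr.ndim == 2 and arr.shape[1] == 3:
                    fh.write(f"VECTORS {name} double\n")
                    np.savetxt(fh, arr, fmt="%.10g")
                else:
                    raise ValueError(f"point array {name!r} must be (N,) or (N, 3)")
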