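"""Dataset assembly: paired pre/post samples, normalization, 9:1 split, HDF5 I/O.

Four datasets are built from one family of geometry draws — {preoperative,
postoperative} × {velocity, pressure} — so that the four networks see the
same vessels and the same train/test partition.  Each sample couples a
cavity cloud (geometry carrier), fluid coordinates, and the oracle pressure
and velocity fields at those coordinates.

Normalization: coordinates are centred at the per-sample cavity centroid
and scaled by its bounding-sphere radius; the target field is divided by a
single per-dataset scale, the maximum absolute value over the *training*
samples.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from .config import GeometryRanges
from .errors import ConfigurationError
from .flow_oracle import (FluidProperties, FlowField, InflowSpec, compute_field)
from .geometry import (CavityPointCloud, FluidPointCoordinates, VesselSpec,
                       build_cavity_cloud, make_postoperative,
                       sample_fluid_points, sample_vessel_spec)

__all__ = ["Sample", "NormalizationParams", "DatasetBundle", "split_indices",
           "generate_sample_family", "build_dataset", "build_paired_bundles",
           "normalize_sample", "denormalize_field", "save_bundle", "load_bundle"]

SCHEMA_VERSION = 1
STAGES = ("preoperative", "postoperative")
TARGETS = ("velocity", "pressure")


@dataclass(frozen=True)
class Sample:
    """One vessel: cavity cloud, fluid coordinates, and its oracle flow field."""

    spec: VesselSpec
    stage: str
    cavity: CavityPointCloud
    fluid_coords: FluidPointCoordinates
    flow: FlowField

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if len(self.flow.pressure) != self.fluid_coords.n2:
            raise ValueError("field and fluid coordinates differ in length")
        if self.stage == "postoperative" and self.spec.effective_stenoses:
            raise ValueError("postoperative sample still carries an effective stenosis")

    def target_field(self, target: str) -> np.ndarray:
        if target == "velocity":
            return self.flow.velocity
        if target == "pressure":
            return self.flow.pressure[:, None]
        raise ValueError(f"unknown target {target!r}")


@dataclass(frozen=True)
class NormalizationParams:
    """Per-sample coordinate frames plus the per-dataset field affine.

    ``field_offset`` recenters scalar targets that ride on a large constant
    background (absolute pressure): it is the midrange of the training
    values for pressure datasets and 0 for velocity, whose components are
    naturally centred.  ``field_scale`` is the maximum absolute centred
    value over the training samples.
    """

    centers: np.ndarray  # (n_samples, 3) cavity centroids, mm
    scales: np.ndarray   # (n_samples,) bounding-sphere radii, mm
    field_scale: float   # max |target - offset| over training samples
    field_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.field_scale <= 0 or np.any(np.asarray(self.scales) <= 0):
            raise ConfigurationError("normalization scales must be positive")


@dataclass
class DatasetBundle:
    """Samples + target choice + 9:1 split + normalization for one network."""

    samples: list
    target: str
    stage: str
    train_indices: np.ndarray
    test_indices: np.ndarray
    normalization: NormalizationParams
    seed: int
    ranges: GeometryRanges = field(default_factory=GeometryRanges)

    def __post_init__(self) -> None:
        n = len(self.samples)
        both = np.concatenate([self.train_indices, self.test_indices])
        if sorted(both.tolist()) != list(range(n)):
            raise ValueError("train/test indices do not partition the samples")
        if self.target not in TARGETS or self.stage not in STAGES:
            raise ValueError("invalid target or stage")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def split(self, which: str) -> np.ndarray:
        if which == "train":
            return self.train_indices
        if which == "test":
            return self.test_indices
        raise ValueError(f"unknown split {which!r}")


def split_indices(n: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Random 9:1 partition: floor(n/10) test samples, remainder train."""
    if n < 10:
        raise ValueError(f"need at least 10 samples for a 9:1 split, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = n // 10
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic per-sample seeds below 2^31 derived from the run seed."""
    ss = np.random.SeedSequence(seed)
    return ss.generate_state(3 * n, dtype=np.uint32).reshape(n, 3) % (2 ** 31)


def generate_sample_family(n_models: int, seed: int, *,
                           ranges: GeometryRanges | None = None,
                           n_cavity: int = 4000, n_fluid: int = 20000,
                           inflow: InflowSpec = InflowSpec(),
                           props: FluidProperties = FluidProperties(),
                           stenosis_loss: bool = True,
                           loss_coefficient: float = 1.0,
                           ) -> tuple[list, list]:
    """Generate n_models preoperative samples and their postoperative twins.

    The twin of sample i reuses sample i's spec with severities zeroed and the
    same cloud seeds, so cavity points outside the (removed) stenosis windows
    coincide between the two stages.
    """
    if n_models < 1:
        raise ValueError("n_models must be positive")
    ranges = ranges or GeometryRanges()
    seeds = _child_seeds(seed, n_models)
    pre, post = [], []
    for i in range(n_models):
        spec_seed, cav_seed, fl_seed = (int(s) for s in seeds[i])
        spec = sample_vessel_spec(spec_seed, ranges, "preoperative")
        twin = make_postoperative(spec)
        for stage, sp, out in (("preoperative", spec, pre),
                               ("postoperative", twin, post)):
            try:
                cavity = build_cavity_cloud(sp, n_cavity, cav_seed)
                fluid = sample_fluid_points(sp, n_fluid, fl_seed)
                flow = compute_field(sp, fluid, inflow, props,
                                    stenosis_loss=stenosis_loss,
                                    loss_coefficient=loss_coefficient)
            except Exception as exc:
                raise type(exc)(f"sample {i} ({stage}): {exc}") from exc
            out.append(Sample(sp, stage, cavity, fluid, flow))
    return pre, post


def _make_bundle(samples: list, target: str, stage: str, seed: int,
                 ranges: GeometryRanges) -> DatasetBundle:
    train_idx, test_idx = split_indices(len(samples), seed)
    centers = np.stack([s.cavity.points.mean(axis=0) for s in samples])
    scales = np.array([
        float(np.linalg.norm(s.cavity.points - c, axis=1).max())
        for s, c in zip(samples, centers)
    ])
    if target == "pressure":
        tmax = max(float(samples[i].target_field(target).max()) for i in train_idx)
        tmin = min(float(samples[i].target_field(target).min()) for i in train_idx)
        offset = 0.5 * (tmax + tmin)
    else:
        offset = 0.0
    fmax = max(float(np.abs(samples[i].target_field(target) - offset).max())
               for i in train_idx)
    norm = NormalizationParams(centers, scales, fmax, offset)
    return DatasetBundle(samples, target, stage, train_idx, test_idx,
                         norm, seed, ranges)


def build_dataset(n_models: int, stage: str, target: str, seed: int,
                  **family_kwargs) -> DatasetBundle:
    """Build one of the four datasets; same seed ⇒ same vessels and split."""
    if n_models < 10:
        raise ValueError("n_models must be at least 10")
    ranges = family_kwargs.get("ranges") or GeometryRanges()
    pre, post = generate_sample_family(n_models, seed, **family_kwargs)
    samples = pre if stage == "preoperative" else post
    return _make_bundle(samples, target, stage, seed, ranges)


def build_paired_bundles(n_models: int, seed: int, **family_kwargs
                         ) -> dict[tuple[str, str], DatasetBundle]:
    """All four datasets from a single generation pass, keyed (stage, target)."""
    if n_models < 10:
        raise ValueError("n_models must be at least 10")
    ranges = family_kwargs.get("ranges") or GeometryRanges()
    pre, post = generate_sample_family(n_models, seed, **family_kwargs)
    out = {}
    for stage, samples in (("preoperative", pre), ("postoperative", post)):
        for target in TARGETS:
            out[(stage, target)] = _make_bundle(samples, target, stage, seed, ranges)
    return out


# ---------------------------------------------------------------------------
# Normalization


def normalize_sample(sample: Sample, center: np.ndarray, scale: float,
                     field_scale: float, target: str, field_offset: float = 0.0
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(cavity, fluid, field) in the network's normalized frame."""
    if field_scale <= 0:
        raise ConfigurationError("field scale must be positive")
    cav = (sample.cavity.points - center) / scale
    flu = (sample.fluid_coords.points - center) / scale
    y = (sample.target_field(target) - field_offset) / field_scale
    return cav, flu, y


def denormalize_field(y_norm: np.ndarray, field_scale: float,
                      field_offset: float = 0.0) -> np.ndarray:
    return y_norm * field_scale + field_offset


def normalized_arrays(bundle: DatasetBundle, i: int
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalized (cavity, fluid, target field) for sample i of a bundle."""
    norm = bundle.normalization
    return normalize_sample(bundle.samples[i], norm.centers[i],
                            float(norm.scales[i]), norm.field_scale,
                            bundle.target, norm.field_offset)


# ---------------------------------------------------------------------------
# Persistence (single HDF5 archive per bundle)


def save_bundle(bundle: DatasetBundle, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["schema_version"] = SCHEMA_VERSION
        fh.attrs["target"] = bundle.target
        fh.attrs["stage"] = bundle.stage
        fh.attrs["seed"] = bundle.seed
        fh.attrs["ranges"] = json.dumps(bundle.ranges.to_dict())
        fh.create_dataset("train_indices", data=bundle.train_indices)
        fh.create_dataset("test_indices", data=bundle.test_indices)
        fh.create_dataset("norm/centers", data=bundle.normalization.centers)
        fh.create_dataset("norm/scales", data=bundle.normalization.scales)
        fh.attrs["field_scale"] = bundle.normalization.field_scale
        fh.attrs["field_offset"] = bundle.normalization.field_offset
        manifest = []
        for i, s in enumerate(bundle.samples):
            g = fh.create_group(f"samples/{i:06d}")
            g.attrs["spec"] = s.spec.to_json()
            g.attrs["stage"] = s.stage
            g.create_dataset("cavity", data=s.cavity.points)
            g.create_dataset("fluid", data=s.fluid_coords.points)
            g.create_dataset("pressure", data=s.flow.pressure.astype(np.float32))
            g.create_dataset("velocity", data=s.flow.velocity.astype(np.float32))
            manifest.append({"index": i, "n1": s.cavity.n1, "n2": s.fluid_coords.n2})
        fh.attrs["manifest"] = json.dumps(manifest)


def load_bundle(path) -> DatasetBundle:
    try:
        fh = h5py.File(path, "r")
    except OSError as exc:
        raise IOError(f"cannot read bundle {path}: {exc}") from exc
    with fh:
        version = int(fh.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise IOError(f"{path}: unsupported bundle schema version {version}")
        manifest = json.loads(fh.attrs["manifest"])
        samples = []
        for entry in manifest:
            g = fh[f"samples/{entry['index']:06d}"]
            cavity = CavityPointCloud(g["cavity"][()])
            fluid = FluidPointCoordinates(g["fluid"][()])
            if cavity.n1 != entry["n1"] or fluid.n2 != entry["n2"]:
                raise IOError(f"{path}: manifest count mismatch at sample {entry['index']}")
            flow = FlowField(pressure=g["pressure"][()].astype(float),
                            velocity=g["velocity"][()].astype(float))
            samples.append(Sample(VesselSpec.from_json(g.attrs["spec"]),
                                  str(g.attrs["stage"]), cavity, fluid, flow))
        norm = NormalizationParams(fh["norm/centers"][()], fh["norm/scales"][()],
                                   float(fh.attrs["field_scale"]),
                                   float(fh.attrs.get("field_offset", 0.0)))
        return DatasetBundle(samples, str(fh.attrs["target"]), str(fh.attrs["stage"]),
                             fh["train_indices"][()], fh["test_indices"][()],
                             norm, int(fh.attrs["seed"]),
                             GeometryRanges.from_dict(json.loads(fh.attrs["ranges"])))
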