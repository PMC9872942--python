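import numpy as np
import pytest

import stenoflow as sf


@pytest.fixture(scope="session")
def default_ranges():
    return sf.GeometryRanges()


@pytest.fixture(scope="session")
def stenosed_spec():
    """One fixed preoperative bifurcation with a known ICA stenosis."""
    return sf.VesselSpec(
        d_cca=8.0, d_ica=5.4, d_eca=4.4, bifurcation_angle=50.0,
        stenoses=(sf.StenosisSpec("ICA", 22.0, 12.0, 0.5),), seed=7)


@pytest.fixture(scope="session")
def tube_spec():
    """Straight 6 mm tube, no stenosis (closed-form flow checks)."""
    return sf.straight_tube_spec(diameter=6.0, length=40.0)


@pytest.fixture(scope="session")
def small_sample(stenosed_spec):
    """One fully simulated sample at small cloud sizes."""
    cavity = sf.build_cavity_cloud(stenosed_spec, 800, 1)
    fluid = sf.sample_fluid_points(stenosed_spec, 4000, 2)
    field = sf.compute_field(stenosed_spec, fluid)
    from stenoflow.datasets import Sample
    return Sample(stenosed_spec, "preoperative", cavity, fluid, field)


@pytest.fixture(scope="session")
def smoke_bundles():
    """The four smoke-scale datasets from one generation pass (shared)."""
    from stenoflow.datasets import build_paired_bundles
    return build_paired_bundles(20, seed=3, n_cavity=300, n_fluid=1200)
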