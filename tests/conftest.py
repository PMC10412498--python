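import numpy as np
import pytest

from cardioriis.phantom import (PhantomSpec, generate_geometry,
                                generate_motion, generate_valve_traces)

# coarse but fully featured phantom settings used across the unit tests;
# the scenario-level tests use the pipeline defaults instead
COARSE = dict(mesh_h_mm=5.6, mesh_h_fine_mm=2.9, seed=0)


@pytest.fixture(scope="session")
def coarse_spec():
    return PhantomSpec(**COARSE)


@pytest.fixture(scope="session")
def coarse_mesh(coarse_spec):
    return generate_geometry(coarse_spec)


@pytest.fixture(scope="session")
def coarse_motion(coarse_spec, coarse_mesh):
    model, frames, times = generate_motion(coarse_spec, coarse_mesh)
    return model, frames, times


@pytest.fixture(scope="session")
def healthy_traces():
    return generate_valve_traces(PhantomSpec(**COARSE))


@pytest.fixture(scope="session")
def noiseless_traces():
    return generate_valve_traces(PhantomSpec(trace_noise_mm=0.0, **COARSE))


@pytest.fixture(scope="session")
def prolapse_traces():
    spec = PhantomSpec(valve_kind="prolapse", trace_noise_mm=0.0, **COARSE)
    return generate_valve_traces(spec)


@pytest.fixture(scope="session")
def channel():
    from cardioriis.benchmarks import cylinder_channel

    return cylinder_channel(h=1.2e-3)


@pytest.fixture(scope="session")
def hemisphere_cloud():
    """Ring cloud of a hemisphere of radius 10 (analytic area oracle)."""
    from cardioriis.valve import ValvePointCloud

    r = 10.0
    lat = np.linspace(0.0, np.deg2rad(89.0), 32)
    th = np.linspace(0.0, 2 * np.pi, 1000, endpoint=False)
    rings = np.stack(
        [
            np.column_stack(
                [
                    r * np.cos(la) * np.cos(th),
                    r * np.cos(la) * np.sin(th),
                    -r * np.sin(la) * np.ones_like(th),
                ]
            )
            for la in lat
        ]
    )
    return ValvePointCloud(
        raw=np.zeros((1152, 3)),
        profile_azimuths_deg=10.0 * np.arange(36),
        resampled=rings,
        noise_sigma_mm=0.0,
    ), r
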