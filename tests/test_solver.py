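import numpy as np
import pytest

from cardioriis.benchmarks import (TAG_INLET, TAG_OUTLET, cylinder_channel,
                                   membrane_surface)
from cardioriis.slicing import plane_section
from cardioriis.solver import (AorticValveController, BoundaryForcing,
                               FlowState, FlowStepper, FluidProperties,
                               RiisTerm)
from cardioriis.valve import distance_and_delta

PROPS = FluidProperties()


@pytest.fixture(scope="module")
def stepper(channel):
    return FlowStepper(channel.tets, len(channel.nodes), PROPS, les=None)


def channel_bc(channel, dp):
    return dict(
        dirichlet=[(channel.wall_nodes, np.zeros(3))],
        outlet_faces=[(channel.faces_of(TAG_INLET), dp),
                      (channel.faces_of(TAG_OUTLET), 0.0)],
    )


class TestBasics:
    def test_zero_forcing_preserves_zero_state(self, channel, stepper):
        state = FlowState.null(len(channel.nodes))
        for _ in range(3):
            state = stepper.step(channel.nodes, state, dt=1e-3,
                                 **channel_bc(channel, 0.0))
        assert np.abs(state.u).max() < 1e-12
        assert np.abs(state.p).max() < 1e-9

    def test_poiseuille_centerline(self, channel, stepper):
        dp = 20.0
        state = stepper.step(channel.nodes, FlowState.null(len(channel.nodes)),
                             dt=None, u_conv=np.zeros((len(channel.nodes), 3)),
                             **channel_bc(channel, dp))
        umax = dp * channel.radius**2 / (4 * PROPS.mu * channel.length)
        r2 = channel.nodes[:, 0] ** 2 + channel.nodes[:, 1] ** 2
        core = r2 < (0.15 * channel.radius) ** 2
        assert state.u[core, 2].mean() == pytest.approx(umax, rel=0.05)

    def test_energy_decays_without_forcing(self, channel, stepper):
        # start from a developed flow, remove all forcing: kinetic energy
        # must be non-increasing
        state = stepper.step(channel.nodes, FlowState.null(len(channel.nodes)),
                             dt=None, u_conv=np.zeros((len(channel.nodes), 3)),
                             **channel_bc(channel, 20.0))
        ke = [float((state.u**2).sum())]
        for _ in range(5):
            state = stepper.step(channel.nodes, state, dt=1e-3,
                                 **channel_bc(channel, 0.0))
            ke.append(float((state.u**2).sum()))
        assert np.all(np.diff(ke) <= 1e-12)

    def test_nan_input_detected(self, channel, stepper):
        state = FlowState.null(len(channel.nodes))
        state.u[0, 0] = np.nan
        with pytest.raises((FloatingPointError, ValueError)):
            stepper.step(channel.nodes, state, dt=1e-3,
                         **channel_bc(channel, 0.0))


class TestRiis:
    @pytest.fixture(scope="class")
    def membrane(self, channel):
        mv, mf = membrane_surface(channel.radius, channel.length / 2)
        eps = 0.75e-3
        _, delta = distance_and_delta(mv, mf, channel.nodes, eps)
        cent = channel.nodes[channel.tets].mean(axis=1)
        _, dc = distance_and_delta(mv, mf, cent, eps)
        return delta, dc, eps

    def flux(self, channel, state):
        sec = plane_section(channel.nodes, channel.tets,
                            [0, 0, 0.75 * channel.length], [0, 0, 1])
        return sec.flux(channel.nodes, state.u)

    def test_membrane_blocks_and_mismatch_monotone(self, channel, membrane):
        delta, dc, eps = membrane
        dp = 20.0
        n = len(channel.nodes)

        def steady(riis):
            st = FlowStepper(channel.tets, n, PROPS, les=None)
            return st.step(channel.nodes, FlowState.null(n), dt=None,
                           u_conv=np.zeros((n, 3)), riis=riis,
                           **channel_bc(channel, dp))

        q_open = self.flux(channel, steady([]))
        mism = []
        for R in (1e2, 1e3, 1e4):
            s = steady([RiisTerm(delta=delta, resistance=R, eps=eps,
                                 delta_elem=dc)])
            layer = delta > 0
            mism.append(np.linalg.norm(s.u[layer], axis=1).max())
            if R == 1e4:
                assert abs(self.flux(channel, s)) < 0.01 * abs(q_open)
        assert mism[0] > mism[1] > mism[2]


class TestBackflowControl:
    def test_tangential_strongly_zero(self, channel):
        n = len(channel.nodes)
        st = FlowStepper(channel.tets, n, PROPS, les=None)
        out_nodes = np.setdiff1d(np.unique(channel.faces_of(TAG_OUTLET)),
                                 channel.wall_nodes)
        state = st.step(channel.nodes, FlowState.null(n), dt=None,
                        u_conv=np.zeros((n, 3)),
                        tangential_zero=(out_nodes, 2),
                        **channel_bc(channel, 20.0))
        peak = np.linalg.norm(state.u, axis=1).max()
        tang = np.abs(state.u[out_nodes][:, :2]).max()
        assert tang < 1e-10 * peak

    def test_inactive_for_normal_flow(self, channel):
        # Poiseuille outflow is purely axial, so constraining the
        # tangential components barely changes the through-flow
        n = len(channel.nodes)
        out_nodes = np.setdiff1d(np.unique(channel.faces_of(TAG_OUTLET)),
                                 channel.wall_nodes)
        sec = plane_section(channel.nodes, channel.tets,
                            [0, 0, channel.length / 2], [0, 0, 1])
        fluxes = []
        for tz in (None, (out_nodes, 2)):
            st = FlowStepper(channel.tets, n, PROPS, les=None)
            s = st.step(channel.nodes, FlowState.null(n), dt=None,
                        u_conv=np.zeros((n, 3)), tangential_zero=tz,
                        **channel_bc(channel, 20.0))
            fluxes.append(sec.flux(channel.nodes, s.u))
        assert abs(fluxes[1] - fluxes[0]) / abs(fluxes[0]) < 0.01

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            BoundaryForcing(p_atrial=lambda t: 0.0, p_aortic=lambda t: 0.0,
                            backflow_mode="sideways")


class TestAorticController:
    def test_healthy_starts_open(self):
        c = AorticValveController(initially_open=True)
        assert c.state == "open" and c.t_open == 0.0

    def test_opens_on_positive_pressure_jump(self):
        c = AorticValveController(initially_open=False)
        dt = 1e-3
        for k in range(1, 20):
            switched = c.update(k * dt, p_ventricle=50.0 * k, p_aorta=500.0,
                                q_aortic=0.0)
            if switched:
                break
        assert c.state == "open"
        assert c.t_open == pytest.approx(11 * dt)

    def test_closes_on_reversed_developed_flow(self):
        c = AorticValveController(initially_open=True)
        q = [1e-5, 3e-5, 2e-5, -1e-6]
        times = [0.1, 0.2, 0.3, 0.4]
        for t, qq in zip(times, q):
            c.update(t, 1.0, 0.0, qq)
        assert c.state == "closed" and c.t_close == pytest.approx(0.4)

    def test_startup_wiggle_does_not_close(self):
        c = AorticValveController(initially_open=True)
        c.update(0.001, 1.0, 0.0, -1e-7)  # tiny backflow before ejection
        assert c.state == "open"

    def test_no_reopen_after_closure(self):
        c = AorticValveController(initially_open=True)
        c.update(0.1, 1.0, 0.0, 1e-4)
        c.update(0.2, 1.0, 0.0, -1e-4)
        assert c.state == "closed"
        c.update(0.3, 1e5, 0.0, 0.0)
        assert c.state == "closed"
        assert c.rejected_reopen
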