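"""Transfer function, delay filtering, and effective-connectivity assembly."""

import numpy as np
import pytest
from scipy.integrate import quad

from circuitspectra import (
    FrequencyGrid,
    NetworkModel,
    anatomical_matrix,
    delay_factor,
    effective_connectivity,
    solve_selfconsistent,
    transfer_function,
    working_point,
)
from circuitspectra.meanfield import siegert_rate
from circuitspectra.response import transfer_function_at

from conftest import PD_PARAMS, W_UNIT, make_ei_network


class TestTransferFunction:
    MU, SIGMA = 8.0, 5.0

    def test_zero_frequency_equals_rate_slope(self):
        eps = 1e-4
        fd = (siegert_rate(PD_PARAMS, self.MU + eps, self.SIGMA)
              - siegert_rate(PD_PARAMS, self.MU - eps, self.SIGMA)) / (2 * eps)
        h0 = transfer_function_at(PD_PARAMS, self.MU, self.SIGMA, 0.0)
        assert h0.imag == 0
        assert h0.real == pytest.approx(fd, rel=1e-6)
        # and the limit is smooth: a small but nonzero frequency agrees too
        h_small = transfer_function_at(PD_PARAMS, self.MU, self.SIGMA, 2 * np.pi * 1e-3)
        assert abs(h_small - h0) / abs(h0) < 1e-3

    def test_conjugate_symmetry(self):
        for f in (13.0, 64.0, 275.0):
            hp = transfer_function_at(PD_PARAMS, self.MU, self.SIGMA, 2 * np.pi * f)
            hm = transfer_function_at(PD_PARAMS, self.MU, self.SIGMA, -2 * np.pi * f)
            assert hm == pytest.approx(np.conj(hp), rel=1e-10)

    def test_high_frequency_rolloff(self):
        h0 = abs(transfer_function_at(PD_PARAMS, self.MU, self.SIGMA, 0.0))
        h5k = abs(transfer_function_at(PD_PARAMS, self.MU, self.SIGMA, 2 * np.pi * 5000.0))
        assert h5k < 0.05 * h0

    def test_smooth_on_grid(self):
        grid = FrequencyGrid.default(200.0, 2.0)
        tf = transfer_function([PD_PARAMS], [self.MU], [self.SIGMA], grid)
        steps = np.abs(np.diff(tf.H[:, 0]))
        assert np.all(steps < 0.1 * np.abs(tf.H[0, 0]))

    def test_white_noise_variant_differs_at_high_frequency(self):
        w = 2 * np.pi * 300.0
        h_col = transfer_function_at(PD_PARAMS, self.MU, self.SIGMA, w, colored=True)
        h_wn = transfer_function_at(PD_PARAMS, self.MU, self.SIGMA, w, colored=False)
        assert abs(h_col) < abs(h_wn)


class TestDelayFactor:
    def test_zero_frequency_is_one(self):
        assert delay_factor(1.5e-3, 1.0e-3, 0.0) == pytest.approx(1.0)
        assert delay_factor(0.75e-3, 0.0, 0.0) == pytest.approx(1.0)

    def test_point_mass_limit(self):
        w = 2 * np.pi * 64.0
        assert delay_factor(1.5e-3, 0.0, w) == pytest.approx(np.exp(-1j * w * 1.5e-3))

    @pytest.mark.parametrize("d,sd,f", [(1.5e-3, 1.0e-3, 64.0),
                                        (0.75e-3, 1.0e-3, 200.0),
                                        (1.5e-3, 0.4e-3, 30.0)])
    def test_matches_quadrature(self, d, sd, f):
        w = 2 * np.pi * f
        norm = quad(lambda y: np.exp(-((y - d) ** 2) / (2 * sd**2)), 0, np.inf)[0]
        re = quad(lambda y: np.cos(w * y) * np.exp(-((y - d) ** 2) / (2 * sd**2)),
                  0, np.inf)[0] / norm
        im = quad(lambda y: -np.sin(w * y) * np.exp(-((y - d) ** 2) / (2 * sd**2)),
                  0, np.inf)[0] / norm
        assert delay_factor(d, sd, w) == pytest.approx(re + 1j * im, abs=1e-8)

    def test_wider_delays_compress(self):
        """|B| strictly decreases with the delay spread at any fixed omega > 0."""
        for f in (20.0, 64.0, 250.0):
            w = 2 * np.pi * f
            mags = [abs(delay_factor(1.5e-3, sd, w))
                    for sd in (1e-5, 2e-4, 5e-4, 1e-3, 2e-3)]
            assert np.all(np.diff(mags) < 0)

    def test_conjugate_symmetry(self):
        w = 2 * np.pi * 77.0
        assert delay_factor(1.5e-3, 1e-3, -w) == pytest.approx(
            np.conj(delay_factor(1.5e-3, 1e-3, w))
        )


class TestEffectiveConnectivity:
    def test_anatomical_matrix(self, microcircuit):
        MA = anatomical_matrix(microcircuit)
        assert np.array_equal(MA, microcircuit.K * microcircuit.W)
        inh = [j for j, lab in enumerate(microcircuit.labels) if lab.endswith("I")]
        assert np.all(MA[:, inh] <= 0)

    def test_zero_anatomy_gives_zero(self):
        m = make_ei_network(k_ee=0, k_ei=0, k_ie=0, k_ii=0)
        st = solve_selfconsistent(m)
        grid = FrequencyGrid.default(100.0, 10.0)
        tf = transfer_function(m.neuron, st.working_point.mu, st.working_point.sigma, grid)
        Md = effective_connectivity(m, st, tf, grid)
        assert np.allclose(Md.Md, 0)

    def test_zero_frequency_is_real_with_source_sign(self, micro_analysis):
        Md0 = micro_analysis.Md.Md[0]
        assert np.allclose(Md0.imag, 0, atol=1e-12)
        inh = [j for j, lab in enumerate(micro_analysis.model.labels) if lab.endswith("I")]
        assert np.all(Md0[:, inh].real <= 0)

    def test_conjugate_symmetry_in_frequency(self, ei_analysis):
        """Md at -omega equals the conjugate of Md at +omega."""
        m = ei_analysis.model
        st = ei_analysis.state
        from circuitspectra.response import effective_connectivity_at

        w = 2 * np.pi * 45.0
        A = effective_connectivity_at(m, st, w)
        B = effective_connectivity_at(m, st, -w)
        assert np.allclose(B, np.conj(A), rtol=1e-10)

    def test_static_gain_matches_stationary_map(self):
        """Md(0) entries equal the mean-channel gain of the rate map.

        An increment of the source rate changes the target's mean input by
        tau_m*W*K*dr; the induced rate change (sigma held at the operating
        value) is the finite-difference gain that Md(0) must reproduce.
        """
        m = make_ei_network()
        st = solve_selfconsistent(m)
        grid = FrequencyGrid(np.array([0.0, 1.0]))
        tf = transfer_function(m.neuron, st.working_point.mu, st.working_point.sigma, grid)
        Md = effective_connectivity(m, st, tf, grid)
        wp0 = st.working_point
        dr = 1e-4
        for i in range(2):
            for j in range(2):
                r_pert = st.rates.copy()
                r_pert[j] += dr
                mu1 = working_point(m, r_pert).mu[i]
                up = siegert_rate(m.neuron[i], mu1, wp0.sigma[i])
                r_pert[j] -= 2 * dr
                mu2 = working_point(m, r_pert).mu[i]
                dn = siegert_rate(m.neuron[i], mu2, wp0.sigma[i])
                gain = (up - dn) / (2 * dr)
                assert Md.Md[0, i, j].real == pytest.approx(gain, rel=1e-3)

    def test_grid_mismatch_rejected(self, ei_analysis):
        other = FrequencyGrid.default(100.0, 5.0)
        with pytest.raises(ValueError):
            effective_connectivity(ei_analysis.model, ei_analysis.state,
                                   ei_analysis.tf, other)
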