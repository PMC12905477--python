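import math

import numpy as np
import pytest

from hemovasc.impedance import (
    outflow_pressure,
    tree_root_impedance,
    vessel_impedance,
    womersley_factor,
)
from hemovasc.network import BiophysicalParams, StructuredTreeSpec


def bessel_series(nu, z, terms=60):
    """Taylor-series Bessel J_nu for complex z: independent oracle."""
    total = 0j
    for k in range(terms):
        total += (-1) ** k * (z / 2) ** (2 * k + nu) / (
            math.factorial(k) * math.factorial(k + nu)
        )
    return total


class TestWomersley:
    def test_zero_frequency_limit(self):
        assert womersley_factor(0.0, 0.05, 0.03) == pytest.approx(1.0)

    def test_large_argument_decay(self):
        val = womersley_factor(1e6, 0.5, 0.03)
        assert abs(val) < 1e-2

    def test_against_series_oracle(self, rng):
        for _ in range(100):
            omega = 10 ** rng.uniform(-2, 2)
            r0 = 10 ** rng.uniform(-3, -0.7)
            nu = 0.0303
            w0 = 1j**1.5 * r0 * math.sqrt(omega / nu)
            if abs(w0) > 15:  # keep the series oracle well-conditioned
                continue
            expect = 2 * bessel_series(1, w0) / (w0 * bessel_series(0, w0))
            got = womersley_factor(omega, r0, nu)
            assert abs(got - expect) / abs(expect) < 1e-10

    def test_branch_continuity_in_omega(self):
        om = np.linspace(1e-6, 500.0, 4000)
        vals = womersley_factor(om, 0.3, 0.0303)
        assert np.all(np.abs(np.diff(vals)) < 0.05)


class TestVesselImpedance:
    def test_poiseuille_dc(self):
        # 8 mu lrr / (pi r^3) with mu=0.032, lrr=50, r=0.05
        z = vessel_impedance(
            0.0, 0.0, r0=0.05, Eh_over_r0=5e5, rho=1.057,
            nu=0.032 / 1.057, lrr=50.0,
        )
        assert z[0].real == pytest.approx(
            8 * 0.032 * 50 / (math.pi * 0.05**3), rel=1e-12
        )
        assert z[0].imag == 0.0

    def test_dc_offset_identity(self, rng):
        for _ in range(10):
            ZL = complex(rng.uniform(1e3, 1e5), 0)
            r0 = rng.uniform(0.01, 0.2)
            z = vessel_impedance(
                ZL, 0.0, r0=r0, Eh_over_r0=6e5, rho=1.057,
                nu=0.0303, lrr=50.0,
            )
            assert z[0] - ZL == pytest.approx(
                8 * 1.057 * 0.0303 * 50 / (math.pi * r0**3), rel=1e-12
            )

    def test_short_vessel_limit(self):
        ZL = 4e4 + 1e3j
        z = vessel_impedance(
            ZL, 6.28, r0=0.1, Eh_over_r0=6e5, rho=1.057, nu=0.0303,
            lrr=1e-8,
        )
        assert z[0] == pytest.approx(ZL, rel=1e-6)


def brute_force_root_impedance(tree, params, root_radius, m):
    """Non-memoised recursion: independent oracle for small trees."""
    T = params.period_T
    omega = 2.0 * np.pi * np.arange(m // 2 + 1) / T

    def z0(r, depth):
        assert depth < 12, "oracle tree too deep"
        if (tree.alpha * r >= tree.rmin) and (tree.beta * r >= tree.rmin):
            z1 = z0(tree.alpha * r, depth + 1)
            z2 = z0(tree.beta * r, depth + 1)
            ZL = z1 * z2 / (z1 + z2)
        else:
            ZL = np.zeros_like(omega, dtype=complex)
        f = params.small_vessel_stiffness(r)
        return vessel_impedance(
            ZL, omega, r0=r, Eh_over_r0=f, rho=params.rho, nu=params.nu,
            lrr=tree.lrr,
        )

    return z0(root_radius, 0)


class TestTreeImpedance:
    def test_single_vessel_base_case(self, base_params):
        tree = StructuredTreeSpec(alpha=0.9, beta=0.6, lrr=50.0, rmin=0.09)
        # root 0.1: daughters 0.09 and 0.06 -> beta daughter below rmin,
        # so the root is terminal with Z_L = 0
        k = tree_root_impedance(tree, base_params, 0.1, m=16)
        mu = base_params.mu
        assert k.dc_impedance == pytest.approx(
            8 * mu * 50 / (math.pi * 0.1**3), rel=1e-12
        )

    def test_memoised_equals_brute_force(self, base_params):
        tree = StructuredTreeSpec(alpha=0.88, beta=0.61, lrr=45.0, rmin=0.01)
        k = tree_root_impedance(
            tree, base_params, 0.05, m=64, alpha=tree.alpha
        )
        oracle = brute_force_root_impedance(tree, base_params, 0.05, 64)
        rel = np.abs(k.Z_root[:32] - oracle[:32]) / np.abs(oracle[:32])
        assert rel.max() < 1e-12
        # Nyquist bin is forced real by the symmetric completion
        assert k.Z_root[32] == pytest.approx(oracle[32].real, rel=1e-12)

    def test_dc_real_positive_decreasing_in_radius(self, base_params):
        tree = StructuredTreeSpec()
        vals = [
            tree_root_impedance(tree, base_params, r, m=16).dc_impedance
            for r in (0.2, 0.3, 0.45, 0.6)
        ]
        assert all(v > 0 for v in vals)
        assert np.all(np.diff(vals) < 0)

    def test_kernel_real_after_symmetric_completion(self, base_params):
        tree = StructuredTreeSpec()
        k = tree_root_impedance(tree, base_params, 0.3, m=128)
        assert k.z_time.dtype == np.float64
        # kernel sums to the DC impedance: sum(z) * dt = Z(0)
        assert k.z_time.sum() * (k.period_T / k.m) == pytest.approx(
            k.dc_impedance, rel=1e-10
        )

    def test_rmin_refinement_converges(self, base_params):
        # The rmin -> 0 limit exists only when parallel conductance growth
        # beats per-vessel resistance growth (alpha^3 + beta^3 > 1); the
        # daughter scalings' upper corner is in that regime.  Below it,
        # rmin acts as a physical arteriolar cutoff, not a refinement knob.
        tree = lambda rmin: StructuredTreeSpec(alpha=0.94, rmin=rmin)
        z = [
            tree_root_impedance(
                tree(r), base_params, 0.25, m=16, alpha=0.94
            ).dc_impedance
            for r in (8e-3, 4e-3, 2e-3, 1e-3, 5e-4)
        ]
        diffs = np.abs(np.diff(z))
        assert diffs[-1] < diffs[0]


@pytest.fixture(scope="module")
def kernel(base_params):
    return tree_root_impedance(StructuredTreeSpec(), base_params, 0.3, m=64)


class TestOutflowConvolution:
    def test_dc_response(self, kernel):
        p = outflow_pressure(np.full(64, 7.5), kernel)
        assert np.allclose(p, 7.5 * kernel.dc_impedance, rtol=1e-12)

    def test_single_mode_eigenfunction(self, kernel):
        t = np.arange(64) / 64.0
        k = 3
        q = np.cos(2 * np.pi * k * t)
        p = outflow_pressure(q, kernel)
        Z = kernel.Z_root[k]
        expect = np.real(Z * np.exp(2j * np.pi * k * t))
        assert np.allclose(p, expect, atol=1e-9 * abs(Z))

    def test_matches_direct_circular_convolution(self, kernel, rng):
        q = rng.standard_normal(64)
        p = outflow_pressure(q, kernel)
        dt = kernel.period_T / kernel.m
        direct = np.array(
            [
                dt * sum(
                    kernel.z_time[k] * q[(j - k) % 64] for k in range(64)
                )
                for j in range(64)
            ]
        )
        assert np.max(np.abs(p - direct)) < 1e-10 * np.max(np.abs(p))

    def test_length_mismatch(self, kernel):
        with pytest.raises(ValueError):
            outflow_pressure(np.zeros(32), kernel)
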