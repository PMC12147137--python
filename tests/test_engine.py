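"""Bloch-McConnell propagation: closed-form limits, conservation laws,
an independent ODE-integrator oracle, and z-spectrum / fingerprint
phenomenology."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import paragest as pg
from paragest.engine import _recovery_propagator

from conftest import random_sample


def _rest_point(offset=0.0, b1=0.0):
    return pg.SaturationPoint(b1=b1, offset=offset, t_sat=1.0, t_rec=0.0)


class TestPropagation:
    def test_zero_time_is_identity(self, dy_sample):
        a = pg.assemble_bm_matrix(dy_sample, _rest_point())
        state = pg.equilibrium_state(dy_sample)
        assert np.array_equal(pg.propagate(state, a, 0.0), state)

    def test_negative_time_rejected(self, dy_sample):
        a = pg.assemble_bm_matrix(dy_sample, _rest_point())
        with pytest.raises(ValueError):
            pg.propagate(pg.equilibrium_state(dy_sample), a, -1.0)

    def test_equilibrium_is_fixed_point_without_rf(self, library):
        """The generator annihilates the equilibrium state when omega_1=0:
        relaxation vanishes at M0 and exchange satisfies detailed balance."""
        rng = np.random.default_rng(5)
        for n_pools in (0, 1, 2, 3):
            sample = random_sample(rng, n_pools, library) if n_pools else pg.Sample(
                pools=(), concentrations=()
            )
            a = pg.assemble_bm_matrix(sample, _rest_point(offset=3.3))
            eq = pg.equilibrium_state(sample)
            assert np.max(np.abs(a @ eq)) < 1e-12 * max(1.0, np.max(np.abs(a)))

    def test_exchange_conserves_longitudinal_magnetization(self, library):
        """Column sums of the exchange-only part of the Mz sub-matrix
        vanish: what leaves one pool enters another.  Isolated by making
        relaxation negligibly slow."""
        rng = np.random.default_rng(8)
        sample = random_sample(rng, 3, library)
        slow = replace(sample, t1_dia=1e9, t2_dia=1e9, pools=tuple(
            replace(p, t1_free=1e9, t2_free=1e9, t1_bound=1e9, t2_bound=1e9)
            for p in sample.pools
        ))
        a = pg.assemble_bm_matrix(slow, _rest_point())
        mz_idx = [3 * p + 2 for p in range(slow.n_pools + 1)]
        col_sums = a[np.ix_(mz_idx, mz_idx)].sum(axis=0)
        assert np.max(np.abs(col_sums)) < 1e-6  # residual 1/T1 = 1e-9 terms

    def test_detailed_balance_by_construction(self, library):
        sample = pg.generate_sample(["Dy", "Eu"], [0.7, 1.3], library)
        eq = pg.equilibrium_state(sample)
        for i, (pool, c) in enumerate(zip(sample.pools, sample.concentrations)):
            k_f = pool.f * c * pool.k_ex
            assert k_f * eq[2] == pytest.approx(pool.k_ex * eq[3 * (i + 1) + 2])

    def test_t1_recovery_closed_form(self):
        """Single free pool, no RF: Mz(t) = 1 - exp(-t/T1) from Mz(0)=0."""
        sample = pg.Sample(pools=(), concentrations=(), t1_dia=1.3, t2_dia=0.4)
        a = pg.assemble_bm_matrix(sample, _rest_point())
        state = np.zeros(4)
        state[-1] = 1.0
        for t in (0.1, 0.5, 2.0, 9.57):
            mz = pg.propagate(state, a, t)[2]
            assert mz == pytest.approx(1.0 - np.exp(-t / 1.3), abs=1e-10)

    def test_matches_adaptive_ode_integration(self, library):
        """Matrix exponential vs an independent high-accuracy adaptive
        integrator on random 2-pool instances under RF."""
        rng = np.random.default_rng(11)
        for _ in range(10):
            sample = random_sample(rng, 2, library)
            point = pg.SaturationPoint(
                b1=float(rng.uniform(0.5, 4.0)),
                offset=float(rng.uniform(-30, 16)),
                t_sat=1.0,
                t_rec=0.0,
            )
            a = pg.assemble_bm_matrix(sample, point)
            y0 = pg.equilibrium_state(sample)
            t = float(rng.uniform(0.2, 1.0))
            sol = solve_ivp(
                lambda _, y: a @ y, (0.0, t), y0, method="DOP853",
                rtol=1e-11, atol=1e-13,
            )
            assert np.max(np.abs(pg.propagate(y0, a, t) - sol.y[:, -1])) <= 1e-8

    def test_recovery_propagator_ignores_transverse_frame_only(self, dy_sample):
        """After a 9.57 s delay the transverse magnetization is dead and Mz
        has recovered towards equilibrium."""
        prop = _recovery_propagator(dy_sample, 9.57)
        state = pg.equilibrium_state(dy_sample)
        state[0] = 0.5  # stray transverse magnetization
        state[2] = 0.1  # depleted free pool
        out = prop @ state
        assert abs(out[0]) < 1e-4
        assert out[2] == pytest.approx(1.0, abs=1e-3)


class TestZSpectrum:
    def test_no_exchange_spectrum_symmetric(self, library):
        """With every bound fraction zero only direct saturation of the
        free pool remains, which is symmetric about 0 ppm."""
        pool = replace(library["Dy"], f=0.0)
        sample = pg.Sample(pools=(pool,), concentrations=(1.0,))
        offsets = np.linspace(-20, 20, 41)
        z = pg.simulate_zspectrum(sample, offsets, b1=1.75, t_sat=4.0).z_values
        assert np.allclose(z, z[::-1], atol=1e-10)

    def test_dy_dip_at_its_offset(self, dy_sample):
        """A Dy-parameterized sample shows a local minimum at -28.6 ppm."""
        offsets = np.linspace(-35, -20, 31)
        zs = pg.simulate_zspectrum(dy_sample, offsets, b1=1.75, t_sat=4.0)
        assert offsets[np.argmin(zs.z_values)] == pytest.approx(-28.6, abs=0.25)

    def test_dip_depth_nondecreasing_in_saturation_time(self, dy_sample):
        depths = []
        for t_sat in (0.25, 0.5, 1.0, 2.0, 4.0, 8.0):
            z = pg.simulate_zspectrum(dy_sample, [-28.6], b1=1.75, t_sat=t_sat).z_values[0]
            depths.append(1.0 - z)
        assert all(b >= a - 1e-12 for a, b in zip(depths, depths[1:]))

    def test_dip_depth_nondecreasing_in_bound_fraction(self, library):
        depths = []
        for f in (0.001, 0.002, 0.005, 0.01):
            pool = replace(library["Dy"], f=f)
            sample = pg.Sample(pools=(pool,), concentrations=(1.0,))
            z = pg.simulate_zspectrum(sample, [-28.6], b1=1.75, t_sat=4.0).z_values[0]
            depths.append(1.0 - z)
        assert all(b >= a for a, b in zip(depths, depths[1:]))

    def test_dilute_pools_superpose(self, library):
        """At small bound fractions the mixture depletion at each pool's
        offset is the sum of the single-pool depletions (within 5%)."""
        dia = dict(t1_free=1.50, t2_free=0.90)
        dy = replace(library["Dy"], f=5e-4, **dia)
        tb = replace(library["Tb"], f=5e-4, **dia)
        offsets = np.array([-28.6, -22.0])

        def z(pools):
            sample = pg.Sample(pools=pools, concentrations=(1.0,) * len(pools))
            return pg.simulate_zspectrum(sample, offsets, b1=1.75, t_sat=4.0).z_values

        z_base = z(())
        depl_mix = z_base - z((dy, tb))
        depl_sum = (z_base - z((dy,))) + (z_base - z((tb,)))
        assert np.all(np.abs(depl_mix - depl_sum) / depl_sum < 0.05)

    def test_empty_offsets_rejected(self, dy_sample):
        with pytest.raises(ValueError):
            pg.simulate_zspectrum(dy_sample, [], b1=1.75, t_sat=4.0)

    def test_csv_round_trip(self, dy_sample, tmp_path):
        zs = pg.simulate_zspectrum(dy_sample, [-30, -28.6, -27], b1=1.75, t_sat=4.0)
        path = tmp_path / "z.csv"
        zs.to_csv(path)
        back = pg.ZSpectrum.from_csv(path)
        assert np.allclose(back.z_values, zs.z_values, atol=1e-12)
        assert back.b1 == zs.b1 and back.t_sat == zs.t_sat


class TestFingerprint:
    def test_values_bounded_and_reference_maximal(self, library, protocol):
        rng = np.random.default_rng(3)
        for n_pools in (1, 2, 3):
            sample = random_sample(rng, n_pools, library)
            v = pg.simulate_fingerprint(sample, protocol).values
            assert np.all(v >= 0.0) and np.all(v <= 1.0 + 1e-9)
            assert v[0] == pytest.approx(1.0, abs=1e-9)
            assert np.all(v <= v[0] + 1e-9)

    def test_no_exchange_fingerprint_flat_except_direct_saturation(
        self, library, protocol
    ):
        pool = replace(library["Dy"], f=0.0)
        sample = pg.Sample(pools=(pool,), concentrations=(1.0,))
        v = pg.simulate_fingerprint(sample, protocol).values
        offsets = protocol.offsets
        far = np.abs(offsets) > 12
        assert np.all(v[far] > 0.99)

    def test_dy_minima_at_its_protocol_indices(self, dy_sample, protocol):
        """The Dy saturation points (one per power block) are local minima
        of the trajectory."""
        v = pg.simulate_fingerprint(dy_sample, protocol).values
        dy_idx = [i for i, p in enumerate(protocol.points) if p.offset == -28.6]
        assert len(dy_idx) == 2
        assert dy_idx[1] - dy_idx[0] == 15  # one per block at the same rank
        for i in dy_idx:
            assert v[i] < v[i - 1] and v[i] < v[i + 1]

    def test_long_recovery_reduces_to_zspectrum(self, library):
        """With recovery long enough for complete relaxation the carried
        magnetization resets, so each point reproduces the equivalent
        single-offset z-spectrum acquisition."""
        sample = pg.generate_sample(["Dy", "Eu"], [1.0, 1.0], library)
        t_rec = 30.0  # ~28 T1 of this mixture
        # all points share the reference's power: the fingerprint has one
        # reference point, while a z-spectrum is normalized at its own power
        points = tuple(
            pg.SaturationPoint(b1=1.75, offset=off, t_sat=3.0, t_rec=t_rec)
            for off in [200.0, -28.6, -5.4, 2.0]
        )
        prot = pg.AcquisitionProtocol(points=points, reference_offset=200.0)
        fp = pg.simulate_fingerprint(sample, prot)
        for i, p in enumerate(prot.points):
            z = pg.simulate_zspectrum(
                sample, [p.offset], b1=p.b1, t_sat=p.t_sat, t_rec=t_rec
            ).z_values[0]
            assert fp.values[i] == pytest.approx(z, abs=1e-6)

    def test_deterministic(self, dy_sample, protocol):
        a = pg.simulate_fingerprint(dy_sample, protocol)
        b = pg.simulate_fingerprint(dy_sample, protocol)
        assert np.array_equal(a.values, b.values)
        assert a.protocol_id == b.protocol_id == protocol.protocol_id()

    def test_csv_round_trip(self, dy_sample, protocol, tmp_path):
        fp = pg.simulate_fingerprint(dy_sample, protocol)
        path = tmp_path / "fp.csv"
        fp.to_csv(path)
        back = pg.Fingerprint.from_csv(path)
        assert np.allclose(back.values, fp.values, atol=1e-12)
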