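"""Structure factors, chain metrics, and the acid-base analysis layer."""

import math

import numpy as np
import pytest

from pecsim.fixtures import single_chain
from pecsim.langevin import LangevinIntegrator, LangevinParams
from pecsim.observables import (TitrationCurve, apparent_pk_shift, augmented_hh,
                                chain_metrics, dh_activity_shift,
                                ideal_speciation, rigid_rod_rg,
                                structure_factor)
from pecsim.system import new_state


class TestStructureFactor:
    def test_ideal_gas_is_flat(self, rng):
        frames = [rng.uniform(0, 10.0, (200, 3)) for _ in range(40)]
        curve = structure_factor(frames, 10.0, n_max=5)
        assert np.all(np.abs(curve.s_k - 1.0) < 0.35)
        assert np.mean(np.abs(curve.s_k - 1.0)) < 0.1
        assert np.all(np.diff(curve.k) > 0)
        assert np.all(curve.s_k >= 0)

    def test_density_wave_peaks_at_imposed_mode(self, rng):
        L, n = 10.0, 400
        k_star = 2 * math.pi / L * 3
        x = np.zeros((n, 3))
        # rejection-sample x-coordinate with density ~ 1 + cos(k* x)
        count = 0
        while count < n:
            cand = rng.uniform(0, L)
            if rng.uniform(0, 2) < 1 + math.cos(k_star * cand):
                x[count, 0] = cand
                count += 1
        x[:, 1] = rng.uniform(0, L, n)
        x[:, 2] = rng.uniform(0, L, n)
        curve = structure_factor([x], L, n_max=6)
        peak_bin = int(np.argmax(curve.s_k))
        assert curve.k[peak_bin] == pytest.approx(k_star, abs=2 * math.pi / L / 2)

    def test_matches_brute_force_double_loop(self, rng):
        L, n = 7.0, 60
        pos = rng.uniform(0, L, (n, 3))
        curve = structure_factor([pos], L, n_max=3)
        # O(N^2) oracle: S(k) = (1/N) sum_jl exp(i k.(r_j - r_l))
        grid = np.arange(-3, 4)
        nx, ny, nz = np.meshgrid(grid, grid, grid, indexing="ij")
        nvec = np.column_stack([nx.ravel(), ny.ravel(), nz.ravel()])
        nvec = nvec[(np.sum(nvec**2, 1) > 0) & (np.sum(nvec**2, 1) <= 9)]
        kvecs = 2 * math.pi / L * nvec
        svals, kmags = [], []
        for kv in kvecs:
            acc = 0.0
            for j in range(n):
                for l in range(n):
                    acc += math.cos(float(kv @ (pos[j] - pos[l])))
            svals.append(acc / n)
            kmags.append(np.linalg.norm(kv))
        dk = 2 * math.pi / L
        shells = np.floor(np.array(kmags) / dk - 0.5 + 1e-9).astype(int)
        oracle = np.array([np.mean(np.array(svals)[shells == s])
                           for s in sorted(set(shells))])
        assert np.allclose(curve.s_k, oracle, atol=1e-10)

    def test_empty_selection_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            structure_factor([np.zeros((5, 3))], 10.0,
                             subset=np.array([], dtype=int))


class TestChainMetrics:
    def test_rigid_rod_matches_closed_form(self):
        n, b = 12, 0.9
        pos = np.zeros((n, 3))
        pos[:, 2] = np.arange(n) * b
        frames = [pos] * 4
        m = chain_metrics(frames, np.arange(4.0), [np.arange(n)])
        assert m.rg == pytest.approx(rigid_rod_rg(n, b), rel=1e-12)
        assert m.end_to_end == pytest.approx((n - 1) * b)

    def test_frozen_trajectory_has_zero_msd(self):
        pos = np.random.default_rng(0).uniform(0, 5, (6, 3))
        m = chain_metrics([pos] * 10, np.arange(10.0), [np.arange(6)])
        assert np.all(m.msd_com == 0.0)

    def test_free_bead_einstein_relation(self, ideal_model):
        # MSD slope 6 D with D = kT/(gamma m) for a single free particle
        gamma, dt, n_walkers = 2.0, 0.01, 40
        rng = np.random.default_rng(11)
        st = new_state(50.0, np.zeros(n_walkers, dtype=np.int64),
                       np.full((n_walkers, 3), 25.0), lb=1.0, rng=rng)
        integ = LangevinIntegrator(st, ideal_model,
                                   LangevinParams(gamma=gamma, dt=dt))
        frames, times = [], []
        for i in range(800):
            integ.step(20)
            frames.append(st.pos.copy())
            times.append((i + 1) * 20 * dt)
        m = chain_metrics(frames, np.array(times),
                          [np.array([j]) for j in range(n_walkers)])
        sel = (m.msd_time > 2.0) & (m.msd_time < 30.0)
        slope = np.polyfit(m.msd_time[sel], m.msd_com[sel], 1)[0]
        assert slope == pytest.approx(6.0 / gamma, rel=0.15)

    def test_requires_topology(self):
        with pytest.raises(ValueError):
            chain_metrics([np.zeros((3, 3))], np.arange(1.0), [])


class TestIdealSpeciation:
    def test_equal_populations_at_first_pk(self):
        f0, f1, f2 = ideal_speciation(4.2, 4.2, 5.6)
        assert f0 == pytest.approx(f1)

    def test_acid_limit(self):
        f0, f1, f2 = ideal_speciation(-6.0, 4.2, 5.6)
        assert (f0, f1, f2) == pytest.approx((1.0, 0.0, 0.0), abs=1e-9)

    def test_base_limit(self):
        f0, f1, f2 = ideal_speciation(14.0, 4.2, 5.6)
        assert f2 == pytest.approx(1.0, abs=1e-7)

    def test_monoanion_peaks_at_mean_pk(self):
        ph = np.linspace(3.0, 7.0, 401)
        f1 = ideal_speciation(ph, 4.2, 5.6)[1]
        assert ph[np.argmax(f1)] == pytest.approx((4.2 + 5.6) / 2, abs=0.02)

    def test_fractions_sum_to_one_exactly(self):
        ph = np.linspace(0, 14, 57)
        f = np.vstack(ideal_speciation(ph, 4.2, 5.6))
        assert np.allclose(f.sum(axis=0), 1.0, atol=1e-14)

    def test_matches_partition_function_enumeration(self):
        # brute-force: state weights 1, 10^(pH-pK1), 10^(2pH-pK1-pK2)
        for ph in (3.3, 4.9, 6.2):
            w = np.array([1.0, 10 ** (ph - 4.2), 10 ** (2 * ph - 4.2 - 5.6)])
            expected = w / w.sum()
            assert np.allclose(ideal_speciation(ph, 4.2, 5.6), expected,
                               rtol=1e-12)


class TestAugmentedHH:
    def test_half_ionized_at_pk_without_potential(self):
        assert augmented_hh(4.2, 4.2, z=-1, psi=0.0) == pytest.approx(0.5)

    def test_potential_shift_equals_ph_shift(self):
        # z*psi = +ln 10 multiplies the protonated weight by 10, i.e. the
        # whole curve translates by exactly one pH unit (toward higher pH)
        ph = np.linspace(2, 8, 61)
        a_shift = augmented_hh(ph, 4.2, z=-1, psi=-math.log(10.0))
        a_ideal = augmented_hh(ph - 1.0, 4.2, z=-1, psi=0.0)
        assert np.allclose(a_shift, a_ideal, rtol=1e-12)

    def test_shift_direction_flips_with_charge_sign(self):
        up = augmented_hh(4.2, 4.2, z=-1, psi=0.5)
        down = augmented_hh(4.2, 4.2, z=+1, psi=0.5)
        assert up > 0.5 > down


class TestApparentPkShift:
    def test_unshifted_curve_recovers_zero(self):
        ph = np.linspace(2.5, 7.5, 51)
        measured = np.vstack(ideal_speciation(ph, 4.2, 5.6))
        shifts = apparent_pk_shift(ph, measured, 4.2, 5.6)
        assert np.allclose(shifts, 0.0, atol=1e-4)

    def test_constructed_displacement_recovered(self):
        ph = np.linspace(2.5, 7.5, 51)
        measured = np.vstack(ideal_speciation(ph + 0.3, 4.2, 5.6))
        shifts = apparent_pk_shift(ph, measured, 4.2, 5.6)
        assert np.allclose(shifts, -0.3, atol=1e-4)

    def test_titration_curve_container(self):
        ph = np.linspace(3, 7, 21)
        fr = np.vstack(ideal_speciation(ph + 0.2, 4.2, 5.6))
        tc = TitrationCurve(ph=ph, fractions=fr, errors=np.zeros_like(fr))
        assert np.allclose(tc.ideal.sum(axis=0), 1.0)
        assert np.allclose(tc.apparent_pk_shifts(), -0.2, atol=1e-3)


class TestDebyeHueckelShift:
    def test_neutral_state_unshifted(self):
        assert dh_activity_shift(0, 0.05, 2.0) == 0.0

    def test_infinite_dilution_limit(self):
        assert dh_activity_shift(2, 0.0, 2.0) == 0.0
        assert abs(dh_activity_shift(2, 1e-12, 2.0)) < 1e-4

    def test_second_step_shift_exceeds_first(self):
        s1 = dh_activity_shift(1, 0.01, 2.0)
        s2 = dh_activity_shift(2, 0.01, 2.0)
        assert s1 < 0 and s2 < 0
        assert abs(s2) == pytest.approx(2 * abs(s1), rel=1e-12)

    def test_shift_is_toward_lower_ph(self):
        assert dh_activity_shift(1, 0.02, 2.5) < 0


class TestSimulatedTitrationSumRule:
    def test_simulated_fractions_sum_to_one(self, ideal_model):
        # fractions are ratios of counts, so the sum rule is exact
        from pecsim.grxmc import ReactionSampler, ReservoirSpec, constants_from_reservoir

        res = ReservoirSpec(pH=5.0, c_salt_M=0.05, c_solute_M=0.05)
        rxns = constants_from_reservoir(res, ideal_model)
        rng = np.random.default_rng(1)
        st = new_state(12.0, np.zeros(0, dtype=np.int64), np.zeros((0, 3)),
                       lb=1.0, rng=rng)
        sampler = ReactionSampler(ideal_model, rxns)
        sampler.run_block(st, 3000)
        counts = st.counts(ideal_model)[6:9].astype(float)
        if counts.sum() > 0:
            assert counts.sum() == int(counts.sum())
            assert (counts / counts.sum()).sum() == pytest.approx(1.0)
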