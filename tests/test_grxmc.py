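"""Reaction-ensemble sampling: acceptance law, detailed balance, ideal limits."""

import math

import numpy as np
import pytest

from pecsim.grxmc import (ReactionSampler, ReactionSpec, ReservoirSpec,
                          acceptance_probability, calibrate_reservoir,
                          constants_from_reservoir)
from pecsim.observables import ideal_speciation
from pecsim.system import new_state
from pecsim.units import DEFAULT_UNITS

PAIR = ReactionSpec("pair", {"Na+": 1, "Cl-": 1}, 0.0)  # K = 1


class TestAcceptanceProbability:
    def test_infinite_energy_cost_rejects(self):
        assert acceptance_probability({"Na+": 0, "Cl-": 0}, PAIR, 1,
                                      float("inf"), 10.0) == 0.0

    def test_empty_box_pair_insertion(self):
        # K=1, V c_std = 10: argument is 1 * (10*10) = 100 -> min(1, 100) = 1
        p = acceptance_probability({"Na+": 0, "Cl-": 0}, PAIR, 1, 0.0, 10.0)
        assert p == 1.0

    def test_single_pair_deletion(self):
        # reverse of the insertion above: min(1, 1/100)
        p = acceptance_probability({"Na+": 1, "Cl-": 1}, PAIR, -1, 0.0, 10.0)
        assert p == pytest.approx(0.01)

    def test_depleted_species_cannot_be_consumed(self):
        assert acceptance_probability({"Na+": 0, "Cl-": 3}, PAIR, -1, 0.0, 10.0) == 0.0

    def test_forward_backward_ratio_is_exact_weight_ratio(self):
        # detailed balance on enumerated microstates with <= 3 particles:
        # a(o->n)/a(n->o) must equal the exact ratio of stationary weights
        reactions = [
            PAIR,
            ReactionSpec("conv", {"H2SuA": -1, "H+": 1, "HSuA-": 1}, -1.2),
            ReactionSpec("double", {"Na+": 2, "SuA2-": 1}, -0.7),
        ]
        v_cstd = 7.3
        for rxn in reactions:
            for counts in _enumerate_counts(rxn, max_n=3):
                fwd = acceptance_probability(counts, rxn, 1, 0.0, v_cstd)
                after = {k: counts[k] + rxn.stoichiometry.get(k, 0)
                         for k in counts}
                if any(v < 0 for v in after.values()):
                    continue
                back = acceptance_probability(after, rxn, -1, 0.0, v_cstd)
                ratio_exact = rxn.k_gamma * v_cstd**rxn.nu_bar
                for name, nu in rxn.stoichiometry.items():
                    ratio_exact *= (math.gamma(counts[name] + 1)
                                    / math.gamma(counts[name] + nu + 1))
                if back > 0:
                    assert fwd / back == pytest.approx(ratio_exact, rel=1e-12)


def _enumerate_counts(rxn, max_n):
    names = sorted(rxn.stoichiometry)
    from itertools import product

    for combo in product(range(max_n + 1), repeat=len(names)):
        if sum(combo) <= max_n:
            yield dict(zip(names, combo))


class TestReservoirConstants:
    def test_pure_water_neutrality(self):
        res = ReservoirSpec(pH=7.0, c_salt_M=0.0)
        c = res.ideal_concentrations()
        assert c["H+"] == pytest.approx(1e-7)
        assert c["OH-"] == pytest.approx(1e-7)
        assert c["Na+"] == pytest.approx(0.0, abs=1e-20)

    def test_ideal_composition_is_electroneutral(self, model):
        for res in (ReservoirSpec(4.0, 0.1), ReservoirSpec(9.0, 0.05),
                    ReservoirSpec(5.5, 0.2, c_divalent_M=0.01, c_solute_M=0.02)):
            c = res.ideal_concentrations()
            q = sum(c[name] * model.species[name].z for name in c)
            assert q == pytest.approx(0.0, abs=1e-15)

    def test_electroneutrality_constraint_fixes_third_constant(self, model):
        # only two ion-pair constants are independent: K_NaOH K_HCl = K_NaCl K_w
        res = ReservoirSpec(pH=5.0, c_salt_M=0.15)
        k = {r.label: r.ln_k for r in constants_from_reservoir(res, model)}
        assert k["NaOH_in"] + k["HCl_in"] == pytest.approx(
            k["NaCl_in"] + k["water_auto"], rel=1e-12)

    def test_thermodynamic_cycle_closure_for_solute_exchange(self, model):
        # inserting HSuA- + Na+ == insert H2SuA, dissociate, swap H+ for Na+
        res = ReservoirSpec(pH=5.0, c_salt_M=0.1, c_solute_M=0.01)
        k = {r.label: r.ln_k for r in constants_from_reservoir(res, model)}
        lhs = k["NaHSuA_in"]
        rhs = (k["H2SuA_in"] - res.pk_a1 * math.log(10.0)
               + k["NaOH_in"] - k["water_auto"])
        assert lhs == pytest.approx(rhs, rel=1e-12)
        # and the doubly ionized insertion closes through both acidity steps
        lhs2 = k["Na2SuA_in"]
        rhs2 = (k["H2SuA_in"] - (res.pk_a1 + res.pk_a2) * math.log(10.0)
                + 2 * (k["NaOH_in"] - k["water_auto"]))
        assert lhs2 == pytest.approx(rhs2, rel=1e-12)

    def test_monovalent_state_peaks_at_mean_pk(self):
        res = ReservoirSpec(pH=4.9, c_salt_M=0.1, c_solute_M=0.01)
        c = res.ideal_concentrations()
        # at pH = (pK1+pK2)/2 = 4.9 the HSuA- fraction is maximal
        f_here = c["HSuA-"]
        for ph in (4.6, 5.2):
            f = ReservoirSpec(pH=ph, c_salt_M=0.1,
                              c_solute_M=0.01).ideal_concentrations()["HSuA-"]
            assert f < f_here

    def test_monomer_species_rejected_in_reactions(self, model):
        bad = ReactionSpec("bad", {"A-": 1, "Na+": 1}, 0.0)
        with pytest.raises(ValueError, match="exchangeable"):
            bad.validate(model)

    def test_charged_stoichiometry_rejected(self, model):
        with pytest.raises(ValueError, match="neutral"):
            ReactionSpec("bad", {"Na+": 1}, 0.0).validate(model)


class TestIdealGasSampling:
    def _run(self, reactions, model, L, seed, n_blocks, attempts=20):
        rng = np.random.default_rng(seed)
        st = new_state(L, np.zeros(0, dtype=np.int64), np.zeros((0, 3)),
                       lb=1.0, rng=rng)
        sampler = ReactionSampler(model, reactions)
        counts = []
        for i in range(n_blocks):
            sampler.run_block(st, attempts)
            if i >= n_blocks // 5:
                counts.append(st.counts(model))
        return st, np.array(counts)

    def test_pair_counts_match_exact_stationary_law(self, ideal_model):
        # oracle: P(N) ~ x^N / (N!)^2 with x = K (V c_std)^2 (exact
        # normalization by direct summation)
        res = ReservoirSpec(pH=7.0, c_salt_M=0.2)
        rxn = [constants_from_reservoir(res, ideal_model)[0]]
        L = 12.0
        v_cstd = L**3 * DEFAULT_UNITS.reference_density_reduced
        x = rxn[0].k_gamma * v_cstd**2
        ns = np.arange(0, 200)
        logw = ns * math.log(x) - 2 * np.array([math.lgamma(n + 1) for n in ns])
        w = np.exp(logw - logw.max())
        mean_exact = float((ns * w).sum() / w.sum())

        _, counts = self._run(rxn, ideal_model, L, seed=4, n_blocks=3000)
        n_na = counts[:, 0]
        se = n_na.std(ddof=1) / math.sqrt(len(n_na) / 20.0)  # autocorrelation
        assert abs(n_na.mean() - mean_exact) < 3.5 * se

    def test_diprotic_speciation_matches_ideal_law(self, ideal_model):
        res = ReservoirSpec(pH=4.9, c_salt_M=0.05, c_solute_M=0.05)
        rxns = constants_from_reservoir(res, ideal_model)
        _, counts = self._run(rxns, ideal_model, 14.0, seed=2, n_blocks=2500,
                              attempts=12)
        acid = counts[:, 6:9].sum(axis=0).astype(float)
        fractions = acid / acid.sum()
        ideal = np.array(ideal_speciation(4.9, 4.2, 5.6))
        assert np.all(np.abs(fractions - ideal) < 0.05)

    def test_electroneutrality_exact_at_every_step(self, ideal_model):
        res = ReservoirSpec(pH=5.0, c_salt_M=0.1, c_divalent_M=0.01,
                            c_solute_M=0.02)
        rxns = constants_from_reservoir(res, ideal_model)
        rng = np.random.default_rng(6)
        st = new_state(10.0, np.zeros(0, dtype=np.int64), np.zeros((0, 3)),
                       lb=1.0, rng=rng)
        sampler = ReactionSampler(ideal_model, rxns)
        z = ideal_model.charges()
        for _ in range(2000):
            sampler.attempt(st)
            assert float(z[st.spec].sum()) == 0.0

    def test_intensivity_under_volume_doubling(self, ideal_model):
        res = ReservoirSpec(pH=7.0, c_salt_M=0.3)
        rxns = constants_from_reservoir(res, ideal_model)
        means = []
        for L in (10.0, 10.0 * 2 ** (1 / 3)):
            st, counts = self._run(rxns, ideal_model, L, seed=9, n_blocks=2500)
            means.append(counts[:, 0].mean() / st.volume)
        assert means[0] == pytest.approx(means[1], rel=0.06)


class TestCalibration:
    def test_ideal_calibration_recovers_targets(self, ideal_model):
        res = ReservoirSpec(pH=6.0, c_salt_M=0.25)
        rxns = constants_from_reservoir(res, ideal_model)
        out = calibrate_reservoir(ideal_model, rxns, lb=2.0, L=14.0,
                                  n_cycles=1500, steps_per_cycle=0,
                                  mc_attempts_per_cycle=30, equil_cycles=300,
                                  rng=np.random.default_rng(3))
        c_na = out["concentrations_M"]["Na+"]
        assert c_na["mean"] == pytest.approx(0.25, abs=max(4 * c_na["stderr"], 0.02))
        assert out["equilibrated"]
        assert out["ionic_strength_M"] == pytest.approx(0.25, rel=0.1)

    def test_interacting_salt_shifts_above_ideal_target(self, model):
        # Debye-Hueckel activity lowering favors insertions: the measured
        # concentration lies above the ideal-gas target
        res = ReservoirSpec(pH=7.0, c_salt_M=0.15)
        rxns = constants_from_reservoir(res, model)
        out = calibrate_reservoir(model, rxns, lb=2.0, L=12.0,
                                  n_cycles=250, steps_per_cycle=40,
                                  mc_attempts_per_cycle=40, equil_cycles=60,
                                  rng=np.random.default_rng(5))
        c_na = out["concentrations_M"]["Na+"]
        assert c_na["mean"] > 0.15
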