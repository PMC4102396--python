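import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import plantclock as pc
from plantclock.network import (CompiledModel, ConfigurationError, GeneSpec,
                                Genotype, Modification, NetworkDefinition,
                                ParameterSet, RegulatoryEdge, ec_activity)

pos = st.floats(min_value=1e-3, max_value=50.0)


class TestStructure:
    def test_canonical_state_dimension(self, canonical_network):
        assert len(canonical_network.species_names()) == 35

    def test_canonical_parameter_count(self, canonical_network):
        assert len(canonical_network.parameter_names()) == 119

    def test_hand_constrained_count(self, canonical_network):
        hc = canonical_network.hand_constrained
        assert len(hc) == 16
        assert set(hc) <= set(canonical_network.parameter_names())

    def test_hill_exponents_are_integers(self, canonical_network):
        assert all(isinstance(e.h, int) and e.h >= 1 for e in canonical_network.edges)

    def test_activation_only_from_rve8_in_canonical(self, canonical_network):
        acts = {e.regulator for e in canonical_network.edges if e.mode == "activation"}
        assert acts == {"RVE8"}

    def test_edges_resolve(self, canonical_network):
        canonical_network.validate()  # raises on dangling references

    def test_yaml_roundtrip(self, canonical_network, tmp_path):
        canonical_network.to_yaml(tmp_path / "net.yaml")
        back = NetworkDefinition.from_yaml(tmp_path / "net.yaml")
        assert back.species_names() == canonical_network.species_names()
        assert back.parameter_names() == canonical_network.parameter_names()

    def test_variant_flags(self, canonical_network):
        nox = canonical_network.with_variants(nox_activates_cca1=True)
        assert any(e.mode == "activation" and e.regulator == "NOX" for e in nox.edges)
        no_rve8 = canonical_network.with_variants(rve8_present=False)
        assert "RVE8" not in no_rve8.gene_names
        assert len(no_rve8.species_names()) == 33
        assert not any("RVE8" in (e.regulator, e.target) for e in no_rve8.edges)


class TestTranscriptionRate:
    def _net(self):
        genes = (GeneSpec("A"), GeneSpec("R"), GeneSpec("X"))
        edges = (RegulatoryEdge("R", "A", h=1), RegulatoryEdge("X", "A", h=1),
                 RegulatoryEdge("R", "X", mode="activation", h=1))
        return NetworkDefinition("t", genes, edges)

    def _params(self, **kw):
        p = {}
        for g in "ARX":
            p.update({f"v_{g}": 2.0, f"dm_{g}": 0.5, f"p_{g}": 1.0, f"dp_{g}": 0.3})
        p.update({"K_R_A": 1.0, "K_X_A": 1.0, "K_R_X": 1.0, "s_R_X": 3.0})
        p.update(kw)
        return ParameterSet(p)

    def test_no_regulators_gives_basal(self):
        net = self._net()
        assert net.transcription_rate("R", {}, 1, self._params()) == pytest.approx(2.0)

    def test_single_repressor_at_K_halves(self):
        net = self._net()
        rate = net.transcription_rate("X", {"R_n": 1.0}, 1, self._params())
        # repression absent on X; activation from R at K: 1 + s/2
        assert rate == pytest.approx(2.0 * (1 + 3.0 * 0.5))
        rate_a = net.transcription_rate("A", {"R_n": 1.0}, 1, self._params())
        assert rate_a == pytest.approx(2.0 * 0.5)

    def test_two_repressors_and_saturated_activator(self):
        # brute-force factored product: v * 1/2 * 1/2 * (1 + s) at saturation
        net = NetworkDefinition("t2", (GeneSpec("G"), GeneSpec("R1"),
                                       GeneSpec("R2"), GeneSpec("A")),
                                (RegulatoryEdge("R1", "G", h=1),
                                 RegulatoryEdge("R2", "G", h=1),
                                 RegulatoryEdge("A", "G", mode="activation", h=1)))
        p = {}
        for g in ("G", "R1", "R2", "A"):
            p.update({f"v_{g}": 4.0, f"dm_{g}": 0.5, f"p_{g}": 1.0, f"dp_{g}": 0.3})
        p.update({"K_R1_G": 0.7, "K_R2_G": 0.7, "K_A_G": 0.2, "s_A_G": 5.0})
        ps = ParameterSet(p)
        levels = {"R1_n": 0.7, "R2_n": 0.7, "A_n": 2000.0}
        expected = 4.0
        for factor in (0.5, 0.5, 1 + 5.0 * (2000.0 / (0.2 + 2000.0))):
            expected *= factor
        got = net.transcription_rate("G", levels, 1, ps)
        assert got == pytest.approx(expected, rel=1e-6)

    def test_unknown_gene_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            self._net().transcription_rate("NOPE", {}, 1, self._params())

    def test_negative_level_rejected(self):
        with pytest.raises(ValueError):
            self._net().transcription_rate("A", {"R_n": -0.1}, 1, self._params())

    @given(r1=pos, r2=pos)
    @settings(max_examples=50, deadline=None)
    def test_repression_strictly_monotone(self, r1, r2):
        net, params = self._net(), self._params()
        lo, hi = sorted([r1, r2])
        f_lo = net.transcription_rate("A", {"R_n": lo}, 1, params)
        f_hi = net.transcription_rate("A", {"R_n": hi}, 1, params)
        if hi > lo:
            assert f_hi < f_lo
        assert f_lo <= 2.0 and f_hi >= 0.0

    @given(a1=pos, a2=pos)
    @settings(max_examples=50, deadline=None)
    def test_activation_factor_bounded(self, a1, a2):
        net, params = self._net(), self._params()
        lo, hi = sorted([a1, a2])
        f_lo = net.transcription_rate("X", {"R_n": lo}, 1, params)
        f_hi = net.transcription_rate("X", {"R_n": hi}, 1, params)
        assert f_hi >= f_lo                      # nondecreasing
        assert 2.0 <= f_lo <= 2.0 * (1 + 3.0)    # within [1, 1+s] x basal
        zero = net.transcription_rate("X", {"R_n": 0.0}, 1, params)
        assert zero == pytest.approx(2.0)        # factor is 1 with no activator


class TestECActivity:
    P = ParameterSet({"c_NOX": 0.3, "c_E3": 0.1, "K_LUXNOX": 0.5, "K_ELF3": 0.5})

    def test_zero_without_lux_and_nox(self):
        assert ec_activity(0, 0, 5.0, 5.0, self.P) == 0.0

    def test_zero_without_any_elf3(self):
        assert ec_activity(5.0, 5.0, 0, 0, self.P) == 0.0

    def test_free_elf3_is_weak_substitute(self):
        # same total ELF3 presented as free protein instead of complex
        x = 1.0
        full = ec_activity(2.0, 0.0, x, 0.0, self.P)
        free_only = ec_activity(2.0, 0.0, 0.0, x, self.P)
        assert free_only < full
        # ratio equals g(c_E3*x)/g(x) by direct evaluation
        def g(w, K=0.5, h=2):
            return w ** h / (K ** h + w ** h)
        assert free_only / full == pytest.approx(g(0.1 * x) / g(x), rel=1e-9)

    @given(lux=pos, nox=pos, e34=pos, e3=pos, d=pos)
    @settings(max_examples=60, deadline=None)
    def test_monotone_nondecreasing_in_every_argument(self, lux, nox, e34, e3, d):
        base = ec_activity(lux, nox, e34, e3, self.P)
        for bumped in ((lux + d, nox, e34, e3), (lux, nox + d, e34, e3),
                       (lux, nox, e34 + d, e3), (lux, nox, e34, e3 + d)):
            assert ec_activity(*bumped, self.P) >= base - 1e-12

    def test_weights_outside_unit_interval_rejected(self):
        bad = ParameterSet({"c_NOX": 1.5, "c_E3": 0.1, "K_LUXNOX": 0.5, "K_ELF3": 0.5})
        with pytest.raises(ConfigurationError):
            ec_activity(1, 1, 1, 1, bad)


class TestGenotype:
    def test_empty_genotype_is_identity(self, canonical_network):
        out = canonical_network.apply_genotype(Genotype.wild_type())
        assert out == canonical_network

    def test_rve8_single_is_knockdown(self, canonical_network):
        geno = Genotype.from_string("rve8", canonical_network.gene_names)
        out = canonical_network.apply_genotype(geno)
        assert out.gene("RVE8").tx_multiplier == pytest.approx(0.4)

    def test_rve_triple_is_full_knockout(self, canonical_network):
        geno = Genotype.from_string("rve4;rve6;rve8", canonical_network.gene_names)
        out = canonical_network.apply_genotype(geno)
        g = out.gene("RVE8")
        assert g.tx_multiplier == 0.0 and g.translation_multiplier == 0.0

    def test_knockout_zeroes_protein_production(self, canonical_network):
        geno = Genotype.from_string("cca1", canonical_network.gene_names)
        out = canonical_network.apply_genotype(geno)
        g = out.gene("CCA1")
        assert g.tx_multiplier == 0.0 and g.translation_multiplier == 0.0
        # wild-type definition untouched
        assert canonical_network.gene("CCA1").tx_multiplier == 1.0

    def test_overexpression_adds_constitutive_rate(self, canonical_network):
        geno = Genotype.from_string("nox-ox", canonical_network.gene_names)
        out = canonical_network.apply_genotype(geno)
        assert out.gene("NOX").ox_rate > 0

    def test_unknown_gene_rejected(self, canonical_network):
        with pytest.raises(ConfigurationError):
            Genotype.from_string("xyz1", canonical_network.gene_names)

    def test_knockdown_magnitude_bounds(self):
        with pytest.raises(ConfigurationError):
            Modification("RVE8", "knockdown", 1.5)


class TestCompiledRhs:
    def test_canonical_dimension_is_35(self, canonical_network, reference_params):
        cm = CompiledModel(canonical_network)
        rhs = cm.bind(reference_params).rhs_for(1)
        y = np.full(35, 0.2)
        assert rhs(0.0, y).shape == (35,)

    def test_all_zero_state_derivative_is_light_gated_basal(self, toy_network, toy_params):
        cm = CompiledModel(toy_network)
        dydt = cm.bind(toy_params).rhs_for(1)(0.0, np.zeros(6))
        # mRNA derivatives equal basal production; proteins zero
        names = cm.species
        for i, n in enumerate(names):
            if n.endswith("_m"):
                assert dydt[i] == pytest.approx(5.0)
            else:
                assert dydt[i] == pytest.approx(0.0)
        assert np.all(dydt >= 0)

    def test_missing_parameter_named_in_error(self, toy_network, toy_params):
        cm = CompiledModel(toy_network)
        incomplete = {k: v for k, v in toy_params.values.items() if k != "K_A_B"}
        with pytest.raises(ConfigurationError, match="K_A_B"):
            cm.bind(incomplete)

    def test_repressor_bump_decreases_target_mrna_derivative(
            self, canonical_network, reference_params):
        # finite-difference oracle against transcription_rate
        cm = CompiledModel(canonical_network)
        bound = cm.bind(reference_params)
        rhs = bound.rhs_for(0)
        rng = np.random.default_rng(0)
        y = rng.uniform(0.05, 0.5, 35)
        i_toc1_n = cm.index["TOC1_n"]
        i_lhy_m = cm.index["LHY_m"]
        d0 = rhs(0.0, y)[i_lhy_m]
        y2 = y.copy()
        y2[i_toc1_n] += 0.1
        d1 = rhs(0.0, y2)[i_lhy_m]
        assert d1 < d0
        # magnitude matches the scalar transcription algebra
        def tx(yy):
            levels = {s: yy[cm.index[s]] for s in cm.species}
            return canonical_network.transcription_rate("LHY", levels, 0,
                                                        reference_params)
        assert d1 - d0 == pytest.approx(tx(y2) - tx(y), rel=1e-9)

    def test_scalar_and_compiled_transcription_agree_for_all_genes(
            self, canonical_network, reference_params):
        cm = CompiledModel(canonical_network)
        bound = cm.bind(reference_params)
        rng = np.random.default_rng(1)
        y = rng.uniform(0.01, 1.0, 35)
        dydt = bound.rhs_for(1)(0.0, y)
        levels = {s: y[cm.index[s]] for s in cm.species}
        levels["EC"] = bound.ec_value(y)
        for gi, g in enumerate(canonical_network.genes):
            i_m = cm.index[f"{g.name}_m"]
            expected = (canonical_network.transcription_rate(g.name, levels, 1,
                                                             reference_params)
                        - reference_params[f"dm_{g.name}"] * y[i_m])
            assert dydt[i_m] == pytest.approx(expected, rel=1e-9), g.name
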