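"""Model notation, link functions and parameter coding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import msrecap as m
from msrecap.model_spec import parse_formula


class TestLink:
    def test_symmetry_at_half(self):
        assert m.link(0.5) == 0.0
        assert m.invlink(0.0) == 0.5

    def test_round_trip(self):
        for p in (0.84, 0.02, 0.999, 1e-6):
            assert m.invlink(m.link(p)) == pytest.approx(p, abs=1e-12)

    def test_boundary_signalled(self):
        with pytest.raises(ValueError):
            m.link(0.0)
        with pytest.raises(ValueError):
            m.link(1.0)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(-30, 30))
    def test_invlink_monotone_in_unit_interval(self, x):
        y = m.invlink(x)
        assert 0.0 < y < 1.0
        assert m.invlink(x + 0.5) > y


class TestFormulaParsing:
    def test_interaction_expansion(self):
        terms = parse_formula("Col*year+rep+spec")
        assert ["colony"] in terms and ["year"] in terms
        assert ["colony", "year"] in terms
        assert ["rep_status"] in terms and ["species"] in terms

    def test_constant(self):
        assert parse_formula(".") == []

    def test_unknown_factor(self):
        with pytest.raises(m.SpecError):
            parse_formula("banana")

    def test_full_notation(self):
        spec = m.parse_model(
            "phi(juv: year; ad: spec) psi(juv: .; ad: spec) "
            "p(Col*year+rep+spec) alpha(a3+spec)"
        )
        assert spec.recapture == "Col*year+rep+spec"
        assert spec.first_breeding == "a3+spec"
        assert spec.per_class("phi")["juv"] == [["year"]]
        assert spec.per_class("psi")["ad"] == [["species"]]


class TestParameterCounts:
    def test_constant_survival_two_parameters(self, two_species_design):
        spec = m.ModelSpec(
            survival={"juv": ".", "ad": "."},
            movement={"juv": ".", "ad": "."},
        )
        idx = m.build_parameter_index(spec, two_species_design)
        assert idx.families["phi"].n_free == 2

    def test_recapture_interaction_cell_means(self, two_species_design):
        # 2 colonies x 3 recapture occasions
        spec = m.ModelSpec(recapture="Col*year")
        idx = m.build_parameter_index(spec, two_species_design)
        assert idx.families["p"].n_free == 6

    def test_recapture_additive_status_offset(self, two_species_design):
        spec = m.ModelSpec(recapture="Col*year+rep")
        idx = m.build_parameter_index(spec, two_species_design)
        assert idx.families["p"].n_free == 7

    def test_movement_constant_is_direction_specific(self, two_species_design):
        spec = m.ModelSpec(movement={"juv": ".", "ad": "."})
        idx = m.build_parameter_index(spec, two_species_design)
        assert idx.families["psi"].n_free == 4  # 2 directions x 2 classes

    def test_movement_species_adds_cells(self, two_species_design):
        spec = m.ModelSpec(movement={"juv": ".", "ad": "spec"})
        idx = m.build_parameter_index(spec, two_species_design)
        assert idx.families["psi"].n_free == 2 + 4

    def test_skipped_occasion_drops_recapture_cells(self, small_design):
        spec = m.ModelSpec(recapture="year")
        idx = m.build_parameter_index(spec, small_design)
        # 4 recapture occasions, one skipped -> 3 year levels
        assert idx.families["p"].n_free == 3
        rates = idx.resolve(np.zeros(idx.n_free))
        skipped = small_design.occasion_index(1993)
        assert np.all(rates.p[:, :, :, skipped] == 0.0)

    def test_unknown_factor_for_family(self, two_species_design):
        with pytest.raises(m.SpecError):
            m.build_parameter_index(m.ModelSpec(movement={"juv": "year", "ad": "."}),
                                    two_species_design)

    @pytest.mark.parametrize(
        "additive,interactive",
        [("Col+year", "Col*year"), ("rep+spec", "rep*spec"), ("Col+rep+spec", "Col*rep*spec")],
    )
    def test_additive_nested_in_interactive(self, two_species_design, additive, interactive):
        ka = m.build_parameter_index(
            m.ModelSpec(recapture=additive), two_species_design
        ).families["p"].n_free
        ki = m.build_parameter_index(
            m.ModelSpec(recapture=interactive), two_species_design
        ).families["p"].n_free
        assert ka <= ki


class TestCodingInvariance:
    def test_resolved_rates_invariant_to_species_order(self):
        """Permuting factor-level order relabels cells, not the model."""
        d1 = m.StudyDesign(occasion_labels=(1, 2, 3, 4), species=("A", "B"))
        d2 = m.StudyDesign(occasion_labels=(1, 2, 3, 4), species=("B", "A"))
        spec = m.ModelSpec(
            survival={"juv": "spec", "ad": "."},
            movement={"juv": ".", "ad": "spec"},
            recapture="year+spec",
            first_breeding="a3+spec",
        )
        i1 = m.build_parameter_index(spec, d1)
        i2 = m.build_parameter_index(spec, d2)
        assert i1.n_free == i2.n_free
        rng = np.random.default_rng(0)
        # the two codings span the same model space: any rate table reachable
        # in one order is reachable in the other via a beta translation
        beta = rng.normal(size=i1.n_free)
        r1 = i1.resolve(beta)
        # find beta2 matching r1 by solving the linear system on the link scale
        for fam in ("phi", "psi", "alpha", "p"):
            f1, f2 = i1.families[fam], i2.families[fam]
            eta1 = f1.X @ beta[f1.offset:f1.offset + f1.n_free]
            # map cells of d1 onto cells of d2 (species axis swapped)
            grid1 = np.full(int(np.prod(f1.shape)), np.nan)
            grid1[f1.free_cells] = eta1
            g1 = grid1.reshape(f1.shape)
            sp_axis = {"phi": 1, "psi": 2, "alpha": 1, "p": 3}[fam]
            g2 = np.flip(g1, axis=sp_axis)
            target = g2.reshape(-1)[f2.free_cells]
            sol, res, *_ = np.linalg.lstsq(f2.X, target, rcond=None)
            assert np.allclose(f2.X @ sol, target, atol=1e-8)


class TestResolve:
    def test_alpha_age4_forced_to_one(self, small_design):
        idx = m.build_parameter_index(m.ModelSpec(first_breeding="a3"), small_design)
        rates = idx.resolve(np.zeros(idx.n_free))
        assert np.all(rates.alpha[3] == 1.0)

    def test_fixed_slices_resolve_to_constants(self, small_design):
        spec = m.ModelSpec(fixed={"alpha1": 0.0, "p": 1.0})
        idx = m.build_parameter_index(spec, small_design)
        rates = idx.resolve(np.zeros(idx.n_free))
        assert np.all(rates.alpha[0] == 0.0)
        skipped = small_design.occasion_index(1993)
        live = [t for t in range(1, 5) if t != skipped]
        assert np.all(rates.p[:, :, :, live] == 1.0)
        assert np.all(rates.p[:, :, :, skipped] == 0.0)
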