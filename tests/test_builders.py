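"""Model battery builders: exact df values, variants, nesting, purity."""

import pytest

import watershed_sem as ws
from watershed_sem.builders import DEFAULT_CONFIG, WatershedConfig
from watershed_sem.model import REGRESSION, build_parameter_table, model_df


class TestStructuralDegreesOfFreedom:
    """The printed df of every battery model is an analytic consequence of
    its structure: p(p+1)/2 moments minus free parameters."""

    def test_fi_measurement_model(self):
        assert model_df(ws.build_measurement_model(list(DEFAULT_CONFIG.fi_indicators))) == 2

    def test_wm_single_factor(self):
        assert model_df(ws.build_measurement_model(list(DEFAULT_CONFIG.wm_tracts), "WM")) == 35

    def test_ps_dimensionality_models(self):
        models = ws.build_ps_factor_models()
        assert model_df(models["single"]) == 9
        assert model_df(models["speed_consistency"]) == 8
        assert model_df(models["task"]) == 6

    def test_mimic(self):
        assert model_df(ws.build_mimic()) == 20

    def test_full_watershed(self):
        spec = ws.build_full_watershed()
        assert model_df(spec) == 60
        assert build_parameter_table(spec).n_free == 150

    def test_covariate_adjusted_watershed(self):
        cfg = WatershedConfig(covariates=("HT", "Diabetes", "MI", "CVD"))
        assert model_df(ws.build_full_watershed(cfg)) == 100

    def test_inverted_watershed(self):
        assert model_df(ws.build_inverted_watershed()) == 56

    def test_just_identified_measurement(self):
        assert model_df(ws.build_measurement_model(["a", "b", "c"])) == 0

    def test_too_few_indicators_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            ws.build_measurement_model(["a", "b"])


class TestVariants:
    @pytest.mark.parametrize(
        "kind, kwargs, delta_df",
        [
            ("zero_paths", {}, 60),
            ("strongest_only", {"source": "FMin"}, 54),
            ("target_specific", {}, 54),
            # tying 60 paths to one value per source tract imposes 50 constraints
            ("source_specific", {}, 50),
            ("equal_paths", {}, 59),
        ],
    )
    def test_watershed_variant_df_shifts(self, kind, kwargs, delta_df):
        base = ws.build_full_watershed()
        variant = ws.make_variant(base, kind, block="wm_ps", **kwargs)
        assert model_df(variant) - model_df(base) == delta_df

    @pytest.mark.parametrize(
        "kind, kwargs, delta_df",
        [
            ("zero_paths", {}, 6),
            ("equal_paths", {}, 5),
            ("strongest_only", {"source": "CRTspeed"}, 5),
        ],
    )
    def test_mimic_variant_df_shifts(self, kind, kwargs, delta_df):
        base = ws.build_mimic()
        variant = ws.make_variant(base, kind, block="ps_fi", **kwargs)
        assert model_df(variant) - model_df(base) == delta_df

    def test_plus_direct_path_frees_one_df(self):
        base = ws.build_full_watershed()
        aug = ws.make_variant(base, "plus_direct_path", source="FMin")
        assert model_df(base) - model_df(aug) == 1

    def test_unknown_source_rejected(self):
        with pytest.raises(ValueError, match="not a source"):
            ws.make_variant(ws.build_full_watershed(), "strongest_only", source="nope")

    def test_every_variant_nested_in_base(self):
        """Constrained/tied rows of a variant map onto free rows of the base."""
        base = ws.build_full_watershed()
        base_free = build_parameter_table(base).free_row_keys()
        for kind in ("zero_paths", "equal_paths", "strongest_only", "source_specific",
                     "target_specific"):
            kwargs = {"source": "FMin"} if kind == "strongest_only" else {}
            variant = ws.make_variant(base, kind, block="wm_ps", **kwargs)
            vt = build_parameter_table(variant)
            assert vt.free_row_keys() <= base_free
            assert vt.n_free < build_parameter_table(base).n_free


class TestPurityAndSubsets:
    def test_builders_are_pure(self):
        assert ws.build_full_watershed().to_syntax() == ws.build_full_watershed().to_syntax()
        cfg = WatershedConfig(covariates=("a1", "a2"))
        assert ws.build_full_watershed(cfg).to_syntax() == ws.build_full_watershed(cfg).to_syntax()

    def test_subset_enumeration_counts(self):
        assert len(ws.enumerate_tract_subsets(list(DEFAULT_CONFIG.wm_tracts), 6)) == 210
        assert len(ws.enumerate_tract_subsets(["a", "b", "c"], 3)) == 1
        assert len(ws.enumerate_tract_subsets(list("abcde"), 2)) == 10

    def test_subsets_deterministic_lexicographic(self):
        subs = ws.enumerate_tract_subsets(["t1", "t2", "t3"], 2)
        assert [s.wm_tracts for s in subs] == [("t1", "t2"), ("t1", "t3"), ("t2", "t3")]

    def test_k_out_of_range(self):
        with pytest.raises(ValueError, match="out of range"):
            ws.enumerate_tract_subsets(["a", "b"], 3)

    def test_config_rejects_overlapping_levels(self):
        with pytest.raises(ValueError, match="more than one level"):
            WatershedConfig(covariates=("FMin",))

    def test_no_cross_level_residual_structure(self):
        """Hierarchy: no tract->FI, tract->indicator or PS->indicator paths."""
        spec = ws.build_full_watershed()
        wm = set(DEFAULT_CONFIG.wm_tracts)
        ps = set(DEFAULT_CONFIG.ps_variables)
        ind = set(DEFAULT_CONFIG.fi_indicators)
        for par in spec.parameters:
            if par.op == REGRESSION:
                assert not (par.lhs == "FI" and par.rhs in wm)
                assert par.lhs not in ind
            if par.op == "covariance":
                levels = [
                    "wm" if v in wm else "ps" if v in ps else "other"
                    for v in (par.lhs, par.rhs)
                ]
                assert levels[0] == levels[1]
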