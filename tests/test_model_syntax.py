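"""Symbolic model layer: parsing, serialization, parameter counting."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from watershed_sem.model import (
    COVARIANCE,
    LOADING,
    REGRESSION,
    VARIANCE,
    IdentificationError,
    ModelSyntaxError,
    ModelValidationError,
    build_parameter_table,
    model_df,
    parse_model_syntax,
    serialize_model_syntax,
)


class TestParser:
    def test_measurement_statement(self):
        spec = parse_model_syntax("FI =~ C1 + C2 + C3 + C4")
        assert spec.latent_names == ["FI"]
        assert spec.observed_names == ["C1", "C2", "C3", "C4"]
        assert [p.op for p in spec.parameters] == [LOADING] * 4
        table = build_parameter_table(spec)
        first = next(r for r in table.rows if r.key() == ("FI", LOADING, "C1"))
        assert first.fixed == 1.0  # default identification convention

    def test_covariance_and_variance_operators(self):
        spec = parse_model_syntax("A ~~ B\nA ~~ A")
        ops = {p.key(): p for p in spec.parameters}
        assert ops[("A", COVARIANCE, "B")].free
        assert ops[("A", VARIANCE, "A")].free

    def test_premultipliers(self):
        spec = parse_model_syntax("y ~ 0*x1 + b1*x2 + b1*x3 + start(0.3)*x4")
        by_key = {p.key(): p for p in spec.parameters}
        assert by_key[("y", REGRESSION, "x1")].fixed == 0.0
        assert by_key[("y", REGRESSION, "x2")].label == "b1"
        assert by_key[("y", REGRESSION, "x3")].label == "b1"
        assert by_key[("y", REGRESSION, "x4")].start == 0.3

    def test_comments_and_blank_lines(self):
        spec = parse_model_syntax("# header\n\nA ~~ B  # trailing\n")
        assert len(spec.parameters) == 1

    @pytest.mark.parametrize(
        "text, fragment",
        [
            ("y ~* x", "line 1"),
            ("A ~~ B\nA ~~ B", "duplicate"),
            ("y x1 + x2", "no operator"),
        ],
    )
    def test_syntax_errors(self, text, fragment):
        with pytest.raises(ModelSyntaxError, match=fragment):
            parse_model_syntax(text)

    def test_directed_cycle_rejected(self):
        with pytest.raises(ModelValidationError, match="cycle"):
            parse_model_syntax("a ~ b\nb ~ a")


class TestSerialization:
    def test_round_trip_is_byte_stable(self):
        text = (
            "FI =~ C1 + C2 + C3 + C4\n"
            "FI ~ SRTspeed + 0*CRTspeed + b*AVspeed\n"
            "SRTspeed ~~ CRTspeed\n"
        )
        once = serialize_model_syntax(parse_model_syntax(text))
        twice = serialize_model_syntax(parse_model_syntax(once))
        assert once == twice

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        n_obs=st.integers(3, 6),
        edges=st.lists(st.tuples(st.integers(0, 5), st.integers(0, 5)), max_size=8),
        fix=st.lists(st.booleans(), min_size=8, max_size=8),
    )
    def test_round_trip_preserves_parameter_table(self, n_obs, edges, fix):
        """parse -> serialize -> parse yields an identical parameter table."""
        names = [f"v{i}" for i in range(n_obs)]
        lines = [f"F =~ {' + '.join(names[:3])}"]
        for k, (a, b) in enumerate(edges):
            a, b = a % n_obs, b % n_obs
            if a == b or a < 3 or b >= 3:  # acyclic by construction: later -> earlier
                continue
            pre = "0*" if fix[k % len(fix)] else ""
            lines.append(f"{names[b]} ~ {pre}{names[a]}")
        text = "\n".join(dict.fromkeys(lines))
        spec1 = parse_model_syntax(text)
        spec2 = parse_model_syntax(serialize_model_syntax(spec1))
        t1, t2 = build_parameter_table(spec1), build_parameter_table(spec2)
        assert [(r.key(), r.fixed, r.label, r.free_index) for r in t1.rows] == [
            (r.key(), r.fixed, r.label, r.free_index) for r in t2.rows
        ]


class TestParameterTable:
    def test_cfa_free_count(self):
        # 3 free loadings + 4 residual variances + 1 factor variance
        spec = parse_model_syntax("FI =~ C1 + C2 + C3 + C4")
        assert build_parameter_table(spec).n_free == 8

    def test_equality_label_shares_one_index(self):
        text = "FI =~ C1 + C2 + C3 + C4\n" + "\n".join(
            f"FI ~ b*{v}" for v in ["p1", "p2", "p3", "p4", "p5", "p6"]
        )
        table = build_parameter_table(parse_model_syntax(text))
        idx = {r.free_index for r in table.rows if r.label == "b"}
        assert len(idx) == 1

    def test_fixed_path_present_but_not_free(self):
        spec = parse_model_syntax("y ~ 0*x")
        table = build_parameter_table(spec)
        row = next(r for r in table.rows if r.key() == ("y", REGRESSION, "x"))
        assert row.free_index is None and not row.free

    def test_identification_conflict(self):
        text = "F =~ 1*a + b + c\nF ~~ 1*F"
        with pytest.raises(IdentificationError):
            build_parameter_table(parse_model_syntax(text))

    def test_implicit_predictor_covariances(self):
        # MIMIC-style: exogenous observed predictors intercovary freely
        spec = parse_model_syntax("F =~ a + b + c\nF ~ x1 + x2 + x3")
        table = build_parameter_table(spec)
        covs = [r for r in table.rows if r.op == COVARIANCE]
        assert len(covs) == 3 and all(r.free for r in covs)


class TestDegreesOfFreedom:
    def test_watershed_syntax_has_150_free_parameters(self):
        from watershed_sem.builders import build_full_watershed

        spec = parse_model_syntax(build_full_watershed().to_syntax())
        assert build_parameter_table(spec).n_free == 150

    def test_saturated_model_df_zero(self):
        names = ["a", "b", "c", "d"]
        lines = [f"{x} ~~ {y}" for i, x in enumerate(names) for y in names[i:]]
        assert model_df(parse_model_syntax("\n".join(lines))) == 0

    def test_freeing_k_zero_fixed_paths_drops_df_by_k(self):
        base = "F =~ a + b + c + d\nF ~ 0*x1 + 0*x2\n"
        freed = "F =~ a + b + c + d\nF ~ x1 + 0*x2\n"
        assert model_df(parse_model_syntax(base)) - model_df(parse_model_syntax(freed)) == 1

    def test_equality_label_raises_df_by_k_minus_1(self):
        free_text = "F =~ a + b + c + d\nF ~ x1 + x2 + x3\n"
        tied_text = "F =~ a + b + c + d\nF ~ b*x1 + b*x2 + b*x3\n"
        assert (
            model_df(parse_model_syntax(tied_text)) - model_df(parse_model_syntax(free_text)) == 2
        )

    def test_negative_df_warns(self):
        with pytest.warns(UserWarning, match="negative"):
            model_df(parse_model_syntax("a ~~ b"), observed_count=1)
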