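"""Property-language grammar, round-tripping, and evaluation semantics."""

import pytest
from hypothesis import given, settings, strategies as st

from mekfit.network import OBSERVABLE_NAMES, VARIANTS
from mekfit.properties import (
    ComparisonProperty,
    Condition,
    PropertyError,
    PropertySet,
    count_satisfied,
    evaluate_property,
    format_property,
    parse_property,
    read_prop_file,
    write_prop_file,
)


class FakeTrajectory:
    """Observable lookup backed by a dict, for grammar-level tests."""

    def __init__(self, table):
        self.table = table

    def at(self, name, time):
        return self.table[(name, time)]


def trajectories_with(delta):
    """Two variants whose MEK_pRDS at t=300 differ by exactly ``delta``."""
    return {
        "WT": FakeTrajectory({("MEK_pRDS", 300.0): 100.0 + delta}),
        "KO": FakeTrajectory({("MEK_pRDS", 300.0): 100.0}),
    }


class TestGrammar:
    def test_reference_statement_parses(self):
        p = parse_property(
            "WT.MEK_pRDS at time=300 < N78G.MEK_pRDS at time=300"
        )
        assert p.left == Condition("WT", "MEK_pRDS", 300.0)
        assert p.right == Condition("N78G", "MEK_pRDS", 300.0)
        assert p.relation == "<" and p.z == 0

    def test_operator_without_spaces(self):
        p = parse_property(
            "N78G.pERK1_2_wt at time=300>T292D.pERK1_2_wt at time=300"
        )
        assert p.relation == ">" and p.z == 1

    def test_weight_annotation(self):
        p = parse_property(
            "WT.pEGFR at time=60 >= KO.pEGFR at time=60 weight=2.5"
        )
        assert p.weight == 2.5 and p.scale == 0.4

    @pytest.mark.parametrize("line", [
        "WT.bogus at time=300 < WT.bogus at time=300",
        "XX.MEK_pRDS at time=300 < WT.MEK_pRDS at time=300",
        "WT.MEK_pRDS at time=-5 < WT.MEK_pRDS at time=300",
        "WT.MEK_pRDS at 300 < WT.MEK_pRDS at time=300",
        "WT.MEK_pRDS at time=300 <",
        "",
    ])
    def test_invalid_statements_rejected(self, line):
        with pytest.raises(PropertyError):
            parse_property(line)

    def test_z_encoding_covers_all_relations(self):
        for op, z in (("<", 0), ("<=", 0), (">", 1), (">=", 1)):
            p = parse_property(
                f"WT.pEGFR at time=60 {op} KO.pEGFR at time=60"
            )
            assert p.z == z


@st.composite
def property_strategy(draw):
    def cond():
        return Condition(
            draw(st.sampled_from(VARIANTS)),
            draw(st.sampled_from(OBSERVABLE_NAMES)),
            draw(st.floats(0, 1e4, allow_nan=False).map(lambda t: round(t, 3))),
        )
    return ComparisonProperty(
        cond(), cond(),
        draw(st.sampled_from(["<", "<=", ">", ">="])),
        weight=draw(st.floats(1e-3, 1e3, allow_nan=False, allow_infinity=False)),
    )


class TestRoundTrip:
    @settings(max_examples=200, deadline=None)
    @given(property_strategy())
    def test_format_parse_round_trip(self, prop):
        assert parse_property(format_property(prop)) == prop

    def test_prop_file_round_trip(self, tmp_path):
        props = PropertySet([
            parse_property("WT.MEK_pRDS at time=300 < N78G.MEK_pRDS at time=300"),
            parse_property("KO.pEGFR at time=60 >= WT.pEGFR at time=60 weight=3"),
        ])
        path = tmp_path / "x.prop"
        write_prop_file(path, props)
        back = read_prop_file(path)
        assert list(back) == list(props)

    def test_comments_and_blank_lines_ignored(self, tmp_path):
        path = tmp_path / "c.prop"
        path.write_text(
            "# header\n\nWT.pEGFR at time=60 < KO.pEGFR at time=60\n\n"
        )
        assert len(read_prop_file(path)) == 1

    def test_parse_error_carries_line_number(self, tmp_path):
        path = tmp_path / "bad.prop"
        path.write_text("WT.pEGFR at time=60 < KO.pEGFR at time=60\njunk\n")
        with pytest.raises(PropertyError, match="bad.prop:2"):
            read_prop_file(path)


class TestEvaluation:
    def test_tie_counts_as_greater_equal(self):
        trajs = trajectories_with(0.0)
        ge = parse_property("WT.MEK_pRDS at time=300 >= KO.MEK_pRDS at time=300")
        lt = parse_property("WT.MEK_pRDS at time=300 < KO.MEK_pRDS at time=300")
        assert evaluate_property(ge, trajs)["satisfied"]
        assert not evaluate_property(lt, trajs)["satisfied"]

    def test_negative_delta_directions(self):
        trajs = trajectories_with(-5.0)
        lt = parse_property("WT.MEK_pRDS at time=300 < KO.MEK_pRDS at time=300")
        ge = parse_property("WT.MEK_pRDS at time=300 >= KO.MEK_pRDS at time=300")
        assert evaluate_property(lt, trajs)["satisfied"]
        assert not evaluate_property(ge, trajs)["satisfied"]

    @settings(max_examples=100, deadline=None)
    @given(st.floats(-1e6, 1e6, allow_nan=False))
    def test_exactly_one_of_mirror_pair_satisfied(self, delta):
        trajs = trajectories_with(delta)
        lt = parse_property("WT.MEK_pRDS at time=300 < KO.MEK_pRDS at time=300")
        ge = parse_property("WT.MEK_pRDS at time=300 >= KO.MEK_pRDS at time=300")
        r1 = evaluate_property(lt, trajs)["satisfied"]
        r2 = evaluate_property(ge, trajs)["satisfied"]
        assert r1 != r2

    @settings(max_examples=100, deadline=None)
    @given(st.floats(-1e6, 1e6, allow_nan=False).filter(
        lambda d: abs(d) >= 1e-6
    ))
    def test_antisymmetry_of_mirrored_statement(self, delta):
        """Swapping sides and flipping the relation preserves the verdict."""
        trajs = trajectories_with(delta)
        p = parse_property("WT.MEK_pRDS at time=300 > KO.MEK_pRDS at time=300")
        m = p.mirrored()
        assert (
            evaluate_property(p, trajs)["satisfied"]
            == evaluate_property(m, trajs)["satisfied"]
        )

    def test_missing_variant_is_an_error(self):
        p = parse_property("WT.MEK_pRDS at time=300 < KO.MEK_pRDS at time=300")
        with pytest.raises(PropertyError):
            evaluate_property(p, {"WT": FakeTrajectory({("MEK_pRDS", 300.0): 1})})

    def test_count_satisfied(self):
        trajs = trajectories_with(5.0)
        sat = parse_property("WT.MEK_pRDS at time=300 > KO.MEK_pRDS at time=300")
        vio = parse_property("WT.MEK_pRDS at time=300 < KO.MEK_pRDS at time=300")
        assert count_satisfied(PropertySet([]), trajs)[0] == 0
        n, report = count_satisfied(PropertySet([sat, vio]), trajs)
        assert n == 1 and len(report) == 2

    def test_count_invariant_to_statement_order(self):
        trajs = trajectories_with(5.0)
        sat = parse_property("WT.MEK_pRDS at time=300 > KO.MEK_pRDS at time=300")
        vio = parse_property("WT.MEK_pRDS at time=300 < KO.MEK_pRDS at time=300")
        a, _ = count_satisfied(PropertySet([sat, vio, sat]), trajs)
        b, _ = count_satisfied(PropertySet([vio, sat, sat]), trajs)
        assert a == b == 2
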