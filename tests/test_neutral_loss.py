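"""Neutral-loss annotation: worked examples, brute-force oracle, invariants."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

import carotannot as ca
from carotannot.neutral_loss import DEFAULT_LOSSES


def _mz(annotations):
    return {a.fragment_mz: a.component_names for a in annotations}


def brute_force_best(precursor, fragment_mz, tol, max_components):
    """Independent oracle: scan the full combination lattice with plain loops.

    Water up to x3, the other losses up to x1, total components 1..depth;
    pick by (|error|, n_components, lexicographic names).
    """
    losses = {"water": 18.0, "methanol": 32.0, "toluene": 92.0, "xylene": 106.0}
    delta = precursor - fragment_mz
    best = None
    for w, m, t, x in itertools.product(range(4), range(2), range(2), range(2)):
        n = w + m + t + x
        if not 1 <= n <= max_components:
            continue
        names = tuple(sorted(["water"] * w + ["methanol"] * m
                             + ["toluene"] * t + ["xylene"] * x))
        total = 18.0 * w + 32.0 * m + 92.0 * t + 106.0 * x
        key = (abs(delta - total), n, names)
        if best is None or key < best[0]:
            best = (key, names, total)
    if best is not None and best[0][0] <= tol:
        return best[1]
    return None


class TestWorkedExamples:
    def test_trihydroxy_water_ladder(self):
        """A 585.2 precursor losing 1/2/3 waters to 566/549/531."""
        ann, unexp = ca.match_losses(585.2, [ca.MzPeak(m) for m in (566.0, 549.0, 531.0)],
                                     tol=1.5, max_components=3)
        assert _mz(ann) == {566.0: ("water",),
                           549.0: ("water", "water"),
                           531.0: ("water", "water", "water")}
        assert unexp == []

    def test_methoxy_polyene_grammar(self):
        """Water, methanol, 92, 106 and combined methanol+106 losses from m/z 621."""
        frags = [ca.MzPeak(m) for m in (603.0, 589.0, 529.0, 515.0, 483.0)]
        ann, unexp = ca.match_losses(621.0, frags, tol=1.5, max_components=3)
        assert _mz(ann) == {603.0: ("water",), 589.0: ("methanol",),
                           529.0: ("toluene",), 515.0: ("xylene",),
                           483.0: ("methanol", "xylene")}
        assert unexp == []

    def test_no_fragments(self):
        ann, unexp = ca.match_losses(500.0, [], tol=1.5)
        assert ann == [] and unexp == []

    def test_out_of_grammar_fragment_is_unexplained_not_error(self):
        ann, unexp = ca.match_losses(500.0, [ca.MzPeak(430.0)], tol=1.5)
        assert ann == [] and unexp == [430.0]


class TestOracleEquivalence:
    @given(st.floats(300.0, 700.0),
           st.lists(st.floats(1.0, 250.0), min_size=1, max_size=6),
           st.floats(0.2, 2.0),
           st.integers(1, 3))
    @settings(derandomize=True, max_examples=300)
    def test_matches_exhaustive_enumeration(self, precursor, deltas, tol, depth):
        frags = [ca.MzPeak(precursor - d) for d in deltas]
        ann, unexp = ca.match_losses(precursor, frags, tol=tol, max_components=depth)
        annotated = _mz(ann)
        for f in frags:
            expected = brute_force_best(precursor, f.mz, tol, depth)
            if expected is None:
                assert f.mz in unexp
            else:
                assert annotated[f.mz] == expected


class TestInvariants:
    @given(st.floats(300.0, 700.0), st.lists(st.floats(10.0, 200.0),
                                             min_size=1, max_size=6))
    @settings(derandomize=True)
    def test_mass_conservation_is_exact(self, precursor, deltas):
        frags = [ca.MzPeak(precursor - d) for d in deltas]
        ann, _ = ca.match_losses(precursor, frags, tol=1.5)
        for a in ann:
            assert a.fragment_mz + a.total_loss + a.mass_error == pytest.approx(
                precursor, abs=1e-9)

    @given(st.floats(300.0, 700.0),
           st.lists(st.floats(10.0, 200.0), min_size=1, max_size=6),
           st.floats(0.2, 1.0), st.floats(1.0, 2.5))
    @settings(derandomize=True)
    def test_tolerance_monotonicity(self, precursor, deltas, tol_small, tol_big):
        frags = [ca.MzPeak(precursor - d) for d in deltas]
        small, _ = ca.match_losses(precursor, frags, tol=tol_small)
        big, _ = ca.match_losses(precursor, frags, tol=tol_big)
        assert {a.fragment_mz for a in small} <= {a.fragment_mz for a in big}


class TestProfile:
    def test_hydroxyl_count_from_ladder(self):
        ann, unexp = ca.match_losses(585.2, [ca.MzPeak(m) for m in (566.0, 549.0, 531.0)])
        prof = ca.infer_profile(ann, unexp)
        assert prof.n_hydroxyl_observed == 3
        assert not prof.methoxy_observed and not prof.polyene_observed

    def test_gapped_ladder_counts_deepest_rung(self):
        # only the 2-water rung is annotated; the count is still 2
        ann, _ = ca.match_losses(585.0, [ca.MzPeak(549.0)])
        assert ca.infer_profile(ann).n_hydroxyl_observed == 2

    def test_empty_profile(self):
        prof = ca.infer_profile([])
        assert (prof.n_hydroxyl_observed, prof.methoxy_observed,
                prof.polyene_observed) == (0, False, False)

    def test_methoxy_and_polyene_flags(self):
        frags = [ca.MzPeak(m) for m in (603.0, 589.0, 529.0, 515.0, 483.0)]
        ann, _ = ca.match_losses(621.0, frags)
        prof = ca.infer_profile(ann)
        assert prof.n_hydroxyl_observed == 1
        assert prof.methoxy_observed and prof.polyene_observed


def test_custom_loss_table_round_trip(tmp_path):
    path = tmp_path / "losses.csv"
    path.write_text("name,mass,implies,max_mult\nwater,18.0,hydroxyl,3\n"
                    "sulfate,80.0,sulfate,1\n")
    losses = ca.neutral_loss.load_loss_table(path)
    assert [l.name for l in losses] == ["water", "sulfate"]
    ann, _ = ca.match_losses(500.0, [ca.MzPeak(420.0)], losses=losses)
    assert ann[0].component_names == ("sulfate",)


def test_default_grammar_is_the_four_canonical_losses():
    assert [(l.name, l.nominal_mass) for l in DEFAULT_LOSSES] == [
        ("water", 18.0), ("methanol", 32.0), ("toluene", 92.0), ("xylene", 106.0)]
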