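"""Quality tiers, salinity preference ranking, species aggregation, eligibility."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from halomag import (ValidationError, aggregate_species, phylogeny_eligibility,
                     quality_tier, salinity_preference_scores, tier_table,
                     top_n_abundant)


def _profile(rpkg: dict[str, dict[str, float]]) -> pd.DataFrame:
    rows = [{"dataset": d, "mag": m, "rpkg": v}
            for m, per in rpkg.items() for d, v in per.items()]
    return pd.DataFrame(rows)


GROUPS = {"H1": "high", "H2": "high", "M1": "moderate", "M2": "moderate",
          "M3": "moderate"}


class TestQualityTier:
    @pytest.mark.parametrize("completeness,contamination,tier", [
        (92.0, 4.0, "near_complete"),
        (50.0, 9.9, "medium"),
        (49.9, 2.0, "fail"),
        (95.0, 5.0, "medium"),   # strict <5 boundary for near-complete
        (90.0, 4.99, "near_complete"),
        (60.0, 10.0, "fail"),    # strict <10 boundary for medium
    ])
    def test_thresholds(self, completeness, contamination, tier):
        assert quality_tier(completeness, contamination) == tier

    def test_inclusive_boundary_option(self):
        assert quality_tier(95.0, 5.0, strict_boundaries=False) == "near_complete"

    def test_tier_nesting(self, rng):
        """Every near-complete bin also satisfies the medium thresholds."""
        for _ in range(200):
            c = float(rng.uniform(0, 100))
            r = float(rng.uniform(0, 15))
            if quality_tier(c, r) == "near_complete":
                assert c >= 50 and r < 10

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            quality_tier(-1.0, 2.0)
        with pytest.raises(ValidationError):
            quality_tier(50.0, -2.0)

    def test_tier_table_annotates(self):
        df = pd.DataFrame({"mag": ["a", "b"], "completeness": [95.0, 55.0],
                           "contamination": [1.0, 3.0]})
        out = tier_table(df)
        assert list(out["tier"]) == ["near_complete", "medium"]


class TestSalinityScores:
    def test_hand_enumerated_example(self):
        profile = _profile({
            "A": {"H1": 10.0, "H2": 0.0, "M1": 1.0, "M2": 0.0, "M3": 0.0},
            "B": {"H1": 5.0, "H2": 0.0, "M1": 5.0, "M2": 0.0, "M3": 0.0},
            "C": {"H1": 1.0, "H2": 0.0, "M1": 10.0, "M2": 0.0, "M3": 0.0},
        })
        out = salinity_preference_scores(profile, GROUPS).set_index("mag")
        assert out.loc["A", "salinity_score"] == 2    # +3 - 1
        assert out.loc["B", "salinity_score"] == 0    # +2 - 2
        assert out.loc["C", "salinity_score"] == -2   # +1 - 3

    @given(st.lists(st.tuples(st.floats(0, 1e6, allow_nan=False),
                              st.floats(0, 1e6, allow_nan=False)),
                    min_size=1, max_size=30))
    def test_permutation_and_zero_sum_invariants(self, sums):
        profile = _profile({
            f"m{i:02d}": {"H1": h, "H2": 0.0, "M1": mo, "M2": 0.0, "M3": 0.0}
            for i, (h, mo) in enumerate(sums)})
        out = salinity_preference_scores(profile, GROUPS)
        m = len(sums)
        assert sorted(out["pos_rank_score"]) == list(range(1, m + 1))
        assert sorted(out["neg_rank_score"]) == list(range(-m, 0))
        assert out["salinity_score"].sum() == 0

    def test_rank_invariance_under_group_rescaling(self):
        profile = _profile({
            f"m{i}": {"H1": float(v), "H2": 1.0, "M1": float(10 - v),
                      "M2": 0.5, "M3": 0.1}
            for i, v in enumerate([7, 3, 9, 1])})
        base = salinity_preference_scores(profile, GROUPS)
        scaled = profile.copy()
        high = scaled["dataset"].isin(["H1", "H2"])
        scaled.loc[high, "rpkg"] *= 1000.0
        out = salinity_preference_scores(scaled, GROUPS)
        pd.testing.assert_frame_equal(
            base[["mag", "pos_rank_score", "neg_rank_score", "salinity_score"]],
            out[["mag", "pos_rank_score", "neg_rank_score", "salinity_score"]])

    def test_ties_break_by_ascending_id(self):
        profile = _profile({m: {"H1": 1.0, "H2": 1.0, "M1": 1.0, "M2": 1.0,
                                "M3": 1.0} for m in ["b", "a", "c"]})
        out = salinity_preference_scores(profile, GROUPS).set_index("mag")
        assert out.loc["a", "pos_rank_score"] == 3
        assert out.loc["c", "neg_rank_score"] == -1

    def test_missing_group_label_rejected(self):
        profile = _profile({"a": {"H1": 1.0, "X": 2.0}})
        with pytest.raises(ValidationError):
            salinity_preference_scores(profile, {"H1": "high"})


class TestTopN:
    def test_truncation_order_and_ties(self):
        profile = _profile({"a": {"d": 5.0}, "b": {"d": 9.0}, "c": {"d": 5.0}})
        assert top_n_abundant(profile, "d", 10) == ["b", "a", "c"]
        assert top_n_abundant(profile, "d", 1) == ["b"]
        with pytest.raises(ValidationError):
            top_n_abundant(profile, "nope", 3)


class TestAggregateSpecies:
    def _decision(self, codes):
        mags = sorted({m for pair in codes for m in pair})
        mat = pd.DataFrame(0, index=mags, columns=mags)
        for (a, b), code in codes.items():
            mat.loc[a, b] = mat.loc[b, a] = code
        np.fill_diagonal(mat.values, 1)
        return mat

    def test_all_different_keeps_values(self):
        profile = _profile({"a": {"d": 4.0}, "b": {"d": 6.0}})
        mat = self._decision({("a", "b"): 0})
        out = aggregate_species(profile, mat, ["a", "b"])
        assert sorted(out["rpkg"]) == [4.0, 6.0]
        assert set(out["cluster"]) == {"a", "b"}

    def test_same_species_pair_averaged(self):
        profile = _profile({"a": {"d": 4.0}, "b": {"d": 6.0}})
        mat = self._decision({("a", "b"): 1})
        out = aggregate_species(profile, mat, ["a", "b"])
        assert list(out["cluster"]) == ["a|b"]
        assert out["rpkg"].iloc[0] == pytest.approx(5.0)

    def test_transitive_chain_merges_with_might_be_code(self):
        profile = _profile({m: {"d": v} for m, v in
                            zip("abc", [3.0, 6.0, 9.0])})
        mat = self._decision({("a", "b"): 1, ("b", "c"): -1, ("a", "c"): 0})
        out = aggregate_species(profile, mat, ["a", "b", "c"])
        assert list(out["cluster"]) == ["a|b|c"]
        assert out["rpkg"].iloc[0] == pytest.approx(6.0)

    def test_subset_not_covered_rejected(self):
        profile = _profile({"a": {"d": 1.0}})
        mat = self._decision({("a", "b"): 0})
        with pytest.raises(ValidationError):
            aggregate_species(profile, mat, ["a", "z"])


class TestPhylogenyEligibility:
    def _markers(self, spec):
        rows = [{"mag": mag, "marker": m, "length_aa": ln}
                for mag, markers in spec.items() for m, ln in markers]
        return pd.DataFrame(rows)

    def test_eight_of_sixteen_rule(self):
        panel = ["L2", "L3", "L4", "L5", "L6", "L14", "L15", "L16", "L18"]
        spec = {
            "ok": [(m, 80) for m in panel[:8]],
            "too_few": [(m, 200) for m in panel[:7]],
            "short_markers": [(m, 200) for m in panel[:7]] + [("L18", 79), ("L16", 79)],
        }
        eligible = phylogeny_eligibility(self._markers(spec))
        assert eligible == {"ok"}

    def test_duplicate_markers_count_once(self):
        spec = {"dup": [("L2", 100)] * 10 + [("L3", 100)]}
        assert phylogeny_eligibility(self._markers(spec)) == set()

    def test_unknown_marker_rejected(self):
        with pytest.raises(ValidationError):
            phylogeny_eligibility(self._markers({"x": [("L99", 100)]}))
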