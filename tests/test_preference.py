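import numpy as np
import pytest

from tickhab import (
    SurveyDataError,
    availability,
    bailey_classification,
    consensus,
    duncan,
    expected_use,
    ivlev,
    jacobs_ii,
    manly_alpha,
    preference_report,
    use_profile,
)
from tickhab._round import round_half_away
from tickhab.preference import jacobs_decision

from conftest import DRY_COUNTS, HABITATS

# published 1-dp dry-season index tables (habitat order of HABITATS)
PRINTED_IVLEV = {
    "all": (0.4, -0.5, 0.2, 0.9),
    "adults": (0.0, -0.4, 0.1, 0.9),
    "nymph": (0.3, -0.6, 0.1, 0.9),
    "larva": (0.4, -0.5, 0.3, 0.8),
}
PRINTED_JACOBS = {
    "all": (0.4, -0.8, 0.2, 0.9),
    "adults": (0.0, -0.7, 0.1, 0.9),
    "nymph": (0.4, -0.9, 0.1, 1.0),
    "larva": (0.5, -0.8, 0.3, 0.9),
}
PRINTED_ALPHA = {
    "all": (0.1, 0.0, 0.1, 0.8),
    "adults": (0.1, 0.0, 0.1, 0.9),
    "nymph": (0.1, 0.0, 0.0, 0.9),
    "larva": (0.2, 0.0, 0.1, 0.7),
}


def rounded(values, dp=1):
    return tuple(round_half_away(v, dp) for v in values)


class TestIvlev:
    def test_king_grass_dry_total(self, dry_total_profile, area_p):
        E = ivlev(dry_total_profile.r, area_p)
        assert round_half_away(E[3], 1) == 0.9

    def test_equal_use_zero(self):
        r = np.array([0.1, 0.2, 0.3, 0.4])
        assert ivlev(r, r) == pytest.approx(np.zeros(4))

    def test_zero_use_is_minus_one(self):
        E = ivlev(np.array([0.0, 1.0]), np.array([0.5, 0.5]))
        assert E[0] == -1.0

    def test_bounds(self, counts, area_p):
        for group in ("all", "adults", "nymph", "larva"):
            for season in ("dry", "wet"):
                E = ivlev(use_profile(counts, group, season).r, area_p)
                assert (E >= -1).all() and (E <= 1).all()


class TestJacobs:
    def test_riparian_strong_avoidance(self, dry_total_profile, area_p):
        D = jacobs_ii(dry_total_profile.r, area_p)
        assert round_half_away(D[1], 1) == -0.8
        assert jacobs_decision(D[1]) == "strong_avoidance"

    def test_equal_use_indifference(self):
        r = np.array([0.25] * 4)
        D = jacobs_ii(r, r)
        assert D == pytest.approx(np.zeros(4))
        assert jacobs_decision(0.0) == "indifference"

    def test_cocoa_derived_value(self, dry_total_profile, area_p):
        D = jacobs_ii(dry_total_profile.r, area_p)
        assert D[0] == pytest.approx(0.425, abs=5e-4)

    @pytest.mark.parametrize(
        "value,label",
        [
            (-1.0, "strong_avoidance"),
            (-0.5, "strong_avoidance"),
            (-0.49, "moderate_avoidance"),
            (-0.255, "moderate_avoidance"),  # bin gap -> stronger label
            (-0.24, "indifference"),
            (0.24, "indifference"),
            (0.255, "neutral_selection"),  # bin gap -> stronger label
            (0.49, "neutral_selection"),
            (0.5, "strong_selection"),
            (1.0, "strong_selection"),
        ],
    )
    def test_bins(self, value, label):
        assert jacobs_decision(value) == label


class TestManlyAlpha:
    def test_king_grass(self, dry_total_profile, area_p):
        a = manly_alpha(dry_total_profile.r, area_p)
        assert round_half_away(a[3], 1) == 0.8
        assert a[3] == pytest.approx(0.822, abs=5e-4)

    def test_star_grass_derived(self, dry_total_profile, area_p):
        a = manly_alpha(dry_total_profile.r, area_p)
        assert a[2] == pytest.approx(0.064, abs=5e-4)

    def test_sums_to_one(self, counts, area_p):
        for group in ("all", "adults", "nymph", "larva"):
            a = manly_alpha(use_profile(counts, group, "dry").r, area_p)
            assert a.sum() == pytest.approx(1.0, abs=1e-12)

    def test_no_selection_parity(self):
        r = np.array([0.1, 0.2, 0.3, 0.4])
        assert manly_alpha(r, r) == pytest.approx([0.25] * 4)


class TestDuncan:
    def test_parity_at_equal_use(self):
        r = np.array([0.25] * 4)
        assert duncan(r, r) == pytest.approx([0.25] * 4)

    def test_dry_totals_default_formula(self, dry_total_profile, area_p):
        d = duncan(dry_total_profile.r, area_p)
        assert round_half_away(d[0], 1) == 0.5  # Cocoa
        assert round_half_away(d[1], 1) == 0.1  # Riparian

    def test_zero_use_zero(self):
        d = duncan(np.array([0.0, 1.0]), np.array([0.5, 0.5]))
        assert d[0] == 0.0

    def test_custom_formula(self, dry_total_profile, area_p):
        d = duncan(
            dry_total_profile.r, area_p, formula=lambda r, p, k: r / (r + p)
        )
        r, p = dry_total_profile.r, area_p.p
        assert d == pytest.approx(r / (r + p))


class TestBailey:
    def test_king_grass_preference(self, dry_total_profile, area_p):
        E = expected_use(dry_total_profile, area_p).E
        result = bailey_classification(dry_total_profile.O, E)
        assert result[3][2] == "preference"  # 2,738 observed vs 154.1 expected

    def test_riparian_adults_no_preference(self, counts, area_p):
        prof = use_profile(counts, "adults", "dry")
        E = expected_use(prof, area_p).E
        result = bailey_classification(prof.O, E)
        assert result[1][2] == "no_preference"  # 65 observed vs 139.4 expected

    def test_exact_match_is_use(self):
        O = np.array([25, 25, 25, 25])
        result = bailey_classification(O, O.astype(float))
        assert all(dec == "use" for _, _, dec in result)

    def test_intervals_bracket_observed(self, dry_total_profile, area_p):
        E = expected_use(dry_total_profile, area_p).E
        for (lo, hi, _), o in zip(
            bailey_classification(dry_total_profile.O, E), dry_total_profile.O
        ):
            assert lo <= o <= hi


class TestRegressionFullDryMatrix:
    """1-dp reproduction of every printed dry-season Ivlev/Jacobs/alpha cell."""

    @pytest.mark.parametrize("group", ["all", "adults", "nymph", "larva"])
    def test_ivlev(self, counts, area_p, group):
        prof = use_profile(counts, group, "dry")
        assert rounded(ivlev(prof.r, area_p)) == PRINTED_IVLEV[group]

    @pytest.mark.parametrize("group", ["all", "adults", "nymph", "larva"])
    def test_jacobs(self, counts, area_p, group):
        prof = use_profile(counts, group, "dry")
        assert rounded(jacobs_ii(prof.r, area_p)) == PRINTED_JACOBS[group]

    @pytest.mark.parametrize("group", ["all", "adults", "nymph", "larva"])
    def test_alpha(self, counts, area_p, group):
        prof = use_profile(counts, group, "dry")
        assert rounded(manly_alpha(prof.r, area_p)) == PRINTED_ALPHA[group]


class TestConsensus:
    def test_king_grass_unanimous(self, dry_total_profile, area_p):
        _, calls = preference_report(dry_total_profile, area_p)
        king = calls[3]
        assert king.habitat == "King Grass Crop"
        assert king.votes == 5
        assert king.label == "preferred"

    def test_riparian_avoided(self, dry_total_profile, area_p):
        _, calls = preference_report(dry_total_profile, area_p)
        assert calls[1].label == "avoided"
        assert calls[1].votes == 0

    def test_all_indifferent_is_used(self):
        decisions = {
            "duncan": "no_preference",
            "ivlev": "no_preference",
            "bailey": "use",
            "alpha": "no_preference",
            "jacobs_ii": "indifference",
        }
        call = consensus(decisions, "x")
        assert call.label == "used"
        assert call.votes == 0

    def test_needs_three_indices(self):
        with pytest.raises(SurveyDataError):
            consensus({"ivlev": "preference", "alpha": "preference"}, "x")


class TestReportStructure:
    def test_absent_habitats_flagged(self, counts, area_p):
        prof = use_profile(counts, "larva", "wet")  # zeros in first two habitats
        values, _ = preference_report(prof, area_p)
        absent = {v.habitat for v in values if v.decision == "absent"}
        assert absent == {"Cocoa Crop", "Riparian Forest"}

    def test_permutation_invariance(self, habitats, dry_total_profile):
        # decisions must not depend on habitat order
        from tickhab import AvailabilityVector, HabitatSet, UseProfile

        perm = [2, 0, 3, 1]
        names = tuple(habitats.names[i] for i in perm)
        prof2 = UseProfile(
            group="all",
            season="dry",
            names=names,
            O=dry_total_profile.O[perm],
        )
        p = availability(habitats)
        p2 = AvailabilityVector.explicit(p.p[perm], names)
        base_values, base_calls = preference_report(dry_total_profile, p)
        perm_values, perm_calls = preference_report(prof2, p2)
        base = {(v.index, v.habitat): v.decision for v in base_values}
        for v in perm_values:
            assert base[(v.index, v.habitat)] == v.decision
        base_lab = {c.habitat: c.label for c in base_calls}
        for c in perm_calls:
            assert base_lab[c.habitat] == c.label
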