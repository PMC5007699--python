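"""TM acceptance, signal-peptide priority, domain sides and the 8-class map."""

import itertools

import pytest

from lecfam import (
    DomainHit,
    Segment,
    TopologyModel,
    accept_tm_segments,
    classify_orientation,
    domain_side,
    predict_tm_fallback,
    resolve_signal_peptide,
)
from lecfam.topology import classify_protein


def model(*segs, sp_score=None, sp_end=None, pid="p1"):
    return TopologyModel(pid, tuple(Segment(*s) for s in segs), sp_score=sp_score, sp_end=sp_end)


def dhit(start, end, role="lectin_bulb"):
    return DomainHit("p1", "B_lectin", role, start, end, 50.0)


class TestAcceptTm:
    def test_high_scoring_tm_retained(self):
        m = model(("outside", 1, 100, 0.9), ("membrane", 101, 121, 0.95), ("inside", 122, 400, 0.9))
        assert accept_tm_segments(m).n_tm == 1

    def test_tm_at_threshold_retained_below_dropped(self):
        for score, expected in [(0.80, 1), (0.79, 0)]:
            m = model(("outside", 1, 100, 0.9), ("membrane", 101, 121, score), ("inside", 122, 400, 0.9))
            assert accept_tm_segments(m).n_tm == expected

    def test_dropping_only_tm_merges_sides_to_no_tm(self):
        m = model(("outside", 1, 100, 0.9), ("membrane", 101, 121, 0.5), ("inside", 122, 400, 0.9))
        out = accept_tm_segments(m)
        assert out.n_tm == 0
        assert not out.contradictory
        assert out.segments[0].start == 1 and out.segments[-1].end == 400

    def test_three_segments_mixed_scores(self):
        m = model(
            ("outside", 1, 50, 0.9),
            ("membrane", 51, 71, 0.9),
            ("inside", 72, 120, 0.9),
            ("membrane", 121, 141, 0.5),
            ("outside", 142, 200, 0.9),
            ("membrane", 201, 221, 0.85),
            ("inside", 222, 300, 0.9),
        )
        out = accept_tm_segments(m)
        assert out.n_tm == 2

    def test_contradictory_merge_flagged(self):
        # dropping the middle TM leaves inside...inside around a kept TM
        m = model(
            ("inside", 1, 50, 0.9),
            ("membrane", 51, 71, 0.95),
            ("outside", 72, 80, 0.9),
            ("membrane", 81, 101, 0.5),
            ("inside", 102, 300, 0.9),
        )
        out = accept_tm_segments(m)
        assert out.contradictory


class TestSignalPeptide:
    def base(self, sp_score, sp_end=25):
        return model(
            ("inside", 1, 5, 0.9),
            ("membrane", 6, 26, 0.95),
            ("outside", 27, 200, 0.9),
            ("membrane", 201, 221, 0.95),
            ("inside", 222, 400, 0.9),
            sp_score=sp_score,
            sp_end=sp_end,
        )

    def test_sp_priority_decrements_tm_count(self):
        out = resolve_signal_peptide(self.base(0.9))
        assert out.n_tm == 1
        assert out.segments[0].label == "outside"  # mature chain starts extracellular

    def test_sp_below_threshold_ignored(self):
        assert resolve_signal_peptide(self.base(0.69)).n_tm == 2

    def test_sp_at_threshold_applied(self):
        assert resolve_signal_peptide(self.base(0.70)).n_tm == 1

    def test_no_membrane_segments_unchanged(self):
        m = model(("outside", 1, 300, 0.9), sp_score=0.95, sp_end=25)
        assert resolve_signal_peptide(m) == m

    def test_never_increases_tm_count(self):
        for sp in (0.0, 0.5, 0.7, 0.99):
            m = self.base(sp)
            assert resolve_signal_peptide(m).n_tm <= m.n_tm


class TestDomainSide:
    M = model(("outside", 1, 100, 0.9), ("membrane", 101, 121, 0.95), ("inside", 122, 400, 0.9))

    def test_fully_outside_is_extracellular(self):
        assert domain_side(dhit(10, 90), self.M) == "extracellular"

    def test_majority_inside_is_intracellular(self):
        # 60% of the domain in the inside segment, 40% outside
        assert domain_side(dhit(82, 181), self.M) == "intracellular"  # 40 out, 21 membrane, 60 in? recompute below

    def test_exact_even_split_is_membrane_spanning(self):
        # 50 residues outside, 21 membrane, 50 inside
        assert domain_side(dhit(51, 171), self.M) == "membrane_spanning"

    def test_out_of_bounds_raises(self):
        with pytest.raises(ValueError):
            domain_side(dhit(390, 450), self.M)


def test_majority_rule_on_constructed_coordinates():
    m = model(("inside", 1, 60, 0.9), ("membrane", 61, 81, 0.95), ("outside", 82, 200, 0.9))
    # domain covering 1..100: 60 inside, 21 membrane, 19 outside -> inside majority
    assert domain_side(dhit(1, 100), m) == "intracellular"
    # domain covering 41..120: 20 inside, 21 membrane, 39 outside -> no strict majority
    assert domain_side(dhit(41, 120), m) == "membrane_spanning"


class TestClassifyOrientation:
    @pytest.mark.parametrize(
        "n_tm,lectin,kinase,expected",
        [
            (1, "extracellular", "intracellular", "I"),
            (1, "intracellular", "extracellular", "II"),
            (1, "extracellular", "extracellular", "III"),
            (2, "extracellular", "extracellular", "IV"),
            (2, "intracellular", "extracellular", "V"),
            (2, "extracellular", "intracellular", "VI"),
            (3, "extracellular", "intracellular", "VII"),
            (3, "intracellular", "extracellular", "VIII"),
            (0, None, None, "NO_TM"),
            (1, "intracellular", "intracellular", "UNCLASSIFIED"),
            (4, "extracellular", "intracellular", "UNCLASSIFIED"),
            (2, "membrane_spanning", "extracellular", "UNCLASSIFIED"),
        ],
    )
    def test_class_table(self, n_tm, lectin, kinase, expected):
        assert classify_orientation(n_tm, lectin, kinase) == expected

    def test_total_over_enumerated_domain(self):
        """Exhaustive enumeration: every (n_tm 0..4, side^2) combination
        maps to exactly one of the ten labels."""
        sides = ("extracellular", "intracellular", "membrane_spanning")
        valid = {"I", "II", "III", "IV", "V", "VI", "VII", "VIII", "NO_TM", "UNCLASSIFIED"}
        for n_tm, lectin, kinase in itertools.product(range(5), sides, sides):
            assert classify_orientation(n_tm, lectin, kinase) in valid


def test_planted_classes_recovered(small_catalogue):
    """Per-protein orientation classes on a zero-noise catalogue equal the
    planted class labels exactly."""
    from lecfam.domains import LECTIN_ROLES, group_hits

    truth = small_catalogue.ground_truth
    grouped = group_hits(small_catalogue.domain_hits)
    for pid, pt in truth.per_protein.items():
        if not (pt.family and pt.orientation_class):
            continue
        hits = sorted(grouped[pid], key=lambda h: h.start)
        lectin = next(h for h in hits if h.role in LECTIN_ROLES)
        kinase = next(h for h in hits if h.role == "kinase")
        cls, _ = classify_protein(small_catalogue.topology_models[pid], lectin, kinase)
        assert cls == pt.orientation_class


class TestFallbackPredictor:
    def test_polyleucine_stretch_is_one_tm(self):
        seq = "DDEEKKRR" + "L" * 25 + "DDEEKKRR" + "G" * 20
        m = predict_tm_fallback(seq)
        assert m.n_tm == 1

    def test_polyaspartate_has_no_tm(self):
        m = predict_tm_fallback("D" * 80)
        assert m.n_tm == 0

    def test_two_stretches_alternating_sides(self):
        seq = "RRKK" + "E" * 20 + "L" * 25 + "D" * 25 + "L" * 25 + "E" * 30
        m = predict_tm_fallback(seq)
        assert m.n_tm == 2
        sides = [s.label for s in m.segments if s.label != "membrane"]
        assert all(a != b for a, b in zip(sides, sides[1:]))

    def test_short_sequence_raises(self):
        with pytest.raises(ValueError):
            predict_tm_fallback("MKV")
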