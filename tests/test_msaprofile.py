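"""Alignment profiles: coordinate mapping, occurrence counts, spectra."""

import pytest

from resvar import (
    CoordinateError,
    InputError,
    PointMutation,
    ReferenceMismatchError,
    build_profile,
    classify_mutations,
    missense_neighbors,
    mutation_occurrence,
    observed_spectrum,
    report_percent,
    simulate_cds,
)
from resvar.msaprofile import GAP


class TestBuildProfile:
    def test_identical_rows_map_with_offset(self):
        rows = [("r", "ACD"), ("a", "ACD"), ("b", "ACD")]
        profile = build_profile(rows, "r", reference_offset=10)
        assert profile.column_map == {10: 1, 11: 2, 12: 3}
        assert profile.n_rows == 3

    def test_reference_gap_columns_unmapped(self):
        rows = [("r", "A-CD"), ("o", "AWCD")]
        profile = build_profile(rows, "r")
        assert profile.column_map == {1: 1, 2: 3, 3: 4}

    def test_errors(self):
        with pytest.raises(InputError, match="no rows"):
            build_profile([], "r")
        with pytest.raises(InputError, match="ragged"):
            build_profile([("r", "AC"), ("o", "A")], "r")
        with pytest.raises(InputError, match="not found"):
            build_profile([("a", "AC")], "r")
        with pytest.raises(InputError, match="empty"):
            build_profile([("r", "--"), ("o", "AC")], "r")

    def test_column_counts_sum_to_n_rows(self, toy_profile):
        for counts in toy_profile.column_counts:
            assert sum(counts.values()) == toy_profile.n_rows

    def test_row_order_invariance(self, toy_rows):
        profile = build_profile(toy_rows, "ref")
        shuffled = build_profile(toy_rows[::-1], "ref")
        assert shuffled.column_map == profile.column_map
        assert shuffled.column_counts == profile.column_counts


class TestMutationOccurrence:
    def test_absent_mutant_residue(self, toy_profile):
        record = mutation_occurrence(toy_profile, PointMutation("K", 2, "Q"))
        assert record.observed is False and record.count == 0

    def test_single_carrier_frequency(self, toy_profile):
        record = mutation_occurrence(toy_profile, PointMutation("K", 2, "R"))
        assert (record.count, record.n_rows) == (1, 4)
        assert record.frequency == 0.25
        assert record.reported_percent == "25%"

    def test_gap_and_ambiguity_never_match_but_stay_in_denominator(self, toy_profile):
        # column for position 8 holds A, A, A, '-' ; X at position 6 col
        record = mutation_occurrence(toy_profile, PointMutation("A", 7, "W"))
        assert record.n_rows == 4 and record.count == 0

    def test_unmapped_position(self, toy_profile):
        with pytest.raises(CoordinateError, match="position 99"):
            mutation_occurrence(toy_profile, PointMutation("A", 99, "W"))

    def test_wildtype_mismatch_names_expected_and_found(self, toy_profile):
        with pytest.raises(ReferenceMismatchError, match="'M'.*expected 'K'"):
            mutation_occurrence(toy_profile, PointMutation("K", 1, "R"))


class TestReportPercent:
    @pytest.mark.parametrize(
        "count,total,expected",
        [
            (87, 276, "31%"),   # 31.52 truncates, never rounds to 32
            (146, 276, "52%"),  # 52.90 truncates
            (51, 276, "18%"),
            (1, 276, "0.3%"),   # below 1%: one truncated decimal
            (0, 276, "0.0%"),
            (276, 276, "100%"),
        ],
    )
    def test_truncation_convention(self, count, total, expected):
        assert report_percent(count, total) == expected

    def test_zero_total_rejected(self):
        with pytest.raises(InputError):
            report_percent(0, 0)


class TestObservedSpectrum:
    def _monomorphic_profile(self, domain, n=5):
        protein = domain.translation()
        rows = [("ref", protein)] + [(f"s{i}", protein) for i in range(n - 1)]
        return build_profile(rows, "ref")

    def test_monomorphic_family_observes_nothing(self):
        domain = simulate_cds("MKTAYIAKQR", seed=1)
        spectrum = observed_spectrum(self._monomorphic_profile(domain), domain)
        assert spectrum.observed == 0
        assert spectrum.possible == sum(
            len(missense_neighbors(c).reachable) for c in domain.codons
        )

    def test_saturated_columns_reach_upper_bound(self):
        domain = simulate_cds("MKTAY", seed=2)
        protein = domain.translation()
        rows = [("ref", protein)]
        residues = "ACDEFGHIKLMNPQRSTVWY"
        for i, aa in enumerate(residues):
            rows.append((f"s{i}", aa * len(protein)))
        spectrum = observed_spectrum(build_profile(rows, "ref"), domain)
        assert spectrum.observed == spectrum.possible

    def test_observed_subset_consistent_with_occurrence(self, planted_family):
        profile, _ = planted_family
        domain = simulate_cds("MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSR", seed=11)
        spectrum = observed_spectrum(profile, domain)
        assert spectrum.observed == sum(len(s) for _, s in spectrum.detail.values())
        for position, (reachable, seen) in spectrum.detail.items():
            for aa in reachable:
                record = mutation_occurrence(
                    profile, PointMutation(profile.reference_residue(position), position, aa)
                )
                assert record.observed == (aa in seen)

    def test_unmapped_positions_aggregated(self):
        domain = simulate_cds("MKTAYIAKQR", seed=1)
        short = simulate_cds("MKTAY", seed=1)
        profile = self._monomorphic_profile(short)
        with pytest.raises(CoordinateError, match="5 domain positions"):
            observed_spectrum(profile, domain)

    def test_cds_alignment_disagreement_is_an_error(self):
        domain = simulate_cds("MKTAY", seed=1)
        rows = [("ref", "MKWAY"), ("s1", "MKWAY")]
        with pytest.raises(ReferenceMismatchError, match="position|3"):
            observed_spectrum(build_profile(rows, "ref"), domain)

    def test_confidence_masking_drops_columns(self):
        domain = simulate_cds("MKTAY", seed=2)
        protein = domain.translation()
        rows = [("ref", protein), ("s1", protein)]
        confidence = {1: 1.0, 2: 0.2, 3: 1.0, 4: 1.0, 5: 1.0}
        profile = build_profile(rows, "ref", column_confidence=confidence)
        full = observed_spectrum(profile, domain)
        masked = observed_spectrum(profile, domain, min_confidence=0.5)
        dropped = len(missense_neighbors(domain.codon_at(2)).reachable)
        assert masked.possible == full.possible - dropped


class TestClassify:
    def test_empty_list_gives_empty_table(self, toy_profile):
        table = classify_mutations(toy_profile, [], {})
        assert table.counts == {}
        assert table.to_frame().empty

    def test_occurred_novel_split(self, toy_profile):
        muts = [
            PointMutation("K", 2, "R"),  # observed in s2
            PointMutation("Y", 5, "W"),  # observed in s2
            PointMutation("K", 2, "Q"),  # novel
        ]
        labels = {m: ("toy", "resistant") for m in muts}
        table = classify_mutations(toy_profile, muts, labels)
        row = table.counts[("toy", "resistant")]
        assert (row["occurred"], row["novel"], row["total"]) == (2, 1, 3)
        assert table.occurred_and_total("resistant") == (2, 3)

    def test_invalid_mutation_token_reported(self, toy_profile):
        bad = PointMutation("K", 1, "R")  # wt mismatch (ref has M at 1)
        with pytest.raises(InputError, match="K1R"):
            classify_mutations(toy_profile, [bad], {bad: ("toy", "resistant")})


def test_empirical_frequencies_converge_to_planted_targets():
    """Across seeds, realised support frequencies match the 3-sigma binomial band."""
    from resvar import Coupling, SyntheticMsaSpec, simulate_msa

    target, n = 0.25, 400
    sigma = (target * (1 - target) / n) ** 0.5
    freqs = []
    for seed in range(20):
        spec = SyntheticMsaSpec(
            reference="MKTAYIAKQR",
            n_sequences=n,
            seed=seed,
            background_rate=0.0,
            supports={5: ("W", target)},
        )
        rows, truth = simulate_msa(spec)
        profile = build_profile(rows, "reference")
        record = mutation_occurrence(profile, PointMutation("Y", 5, "W"))
        assert record.count == truth.singles[0].count
        freqs.append(record.frequency)
        assert abs(record.frequency - target) < 3 * sigma
    mean_error = abs(sum(freqs) / len(freqs) - target)
    assert mean_error < 2 * sigma / (20**0.5)
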