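"""Null models: background estimation, match probability, binomial test,
codon degeneracy."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from slimscreen import (
    CODON_COUNTS,
    ProteinRecord,
    codon_weight,
    estimate_aa_frequencies,
    expected_p_protein_fraction,
    frequency_codon_correlation,
    load_probe_library,
    observed_vs_expected_test,
    per_window_match_probability,
    shuffle_null_mc,
    uniform_background,
)
from slimscreen.errors import SlimScreenError
from slimscreen.simulate import generate_proteome


class TestBackgroundEstimation:
    def test_plain_counting(self):
        recs = [
            ProteinRecord(accession="A", sequence="AAAA"),
            ProteinRecord(accession="B", sequence="CCCC"),
        ]
        model = estimate_aa_frequencies(recs)
        assert model.frequency("A") == pytest.approx(0.5)
        assert model.frequency("C") == pytest.approx(0.5)
        assert model.frequency("W") == 0.0

    def test_ambiguity_letters_excluded(self):
        model = estimate_aa_frequencies([ProteinRecord(accession="A", sequence="AXA")])
        assert model.frequency("A") == pytest.approx(1.0)

    def test_no_standard_residues_errors(self):
        with pytest.raises(SlimScreenError):
            estimate_aa_frequencies([ProteinRecord(accession="A", sequence="XX")])

    def test_recovers_generating_frequencies_within_3se(self):
        proteome = generate_proteome(n_proteins=200, length_dist=("fixed", 500),
                                     aa_frequencies="uniform", seed=11)
        model = estimate_aa_frequencies(proteome)
        n = 200 * 500
        se = np.sqrt(0.05 * 0.95 / n)
        for aa, f in model.aa_frequencies.items():
            assert abs(f - 0.05) < 3 * se


class TestMatchProbability:
    def test_closed_forms_uniform(self):
        model = uniform_background()
        lib1 = load_probe_library("P17 NFW\n")
        assert per_window_match_probability(lib1, model) == pytest.approx((1 / 20) ** 3)
        lib19 = load_probe_library(
            "".join(f"Px{i} {p}\n" for i, p in enumerate(
                ["NFW", "LFF", "CMW", "DWC", "WHM", "CYF", "MCW", "FWH", "HMY",
                 "YCH", "WFC", "MHW", "NCM", "NWY", "HYW", "FMC", "YWF", "WCH",
                 "MFY"]))
        )
        assert per_window_match_probability(lib19, model) == pytest.approx(19 * (1 / 20) ** 3)

    def test_monotone_in_library_size(self):
        model = uniform_background()
        peps = ["NFW", "LFF", "CMW", "DWC", "WHM"]
        qs = []
        for k in range(1, 6):
            lib = load_probe_library("".join(f"P{i} {p}\n" for i, p in enumerate(peps[:k])))
            qs.append(per_window_match_probability(lib, model))
        assert qs == sorted(qs)
        fracs = [expected_p_protein_fraction([100] * 5, q) for q in qs]
        assert fracs == sorted(fracs)

    def test_expected_fraction_closed_forms(self):
        assert expected_p_protein_fraction([3, 3], 0.5) == pytest.approx(0.5)
        assert expected_p_protein_fraction([1, 2], 0.9) == 0.0
        q = 1.25e-4
        expect = 0.5 * ((1 - (1 - q) ** 8) + (1 - (1 - q) ** 100))
        assert expected_p_protein_fraction([10, 102], q) == pytest.approx(expect)

    def test_exhaustive_enumeration_oracle_two_letter_alphabet(self):
        # 2 probes over {A,B}, f=0.5: exact P(>=1 match in length 10) by
        # enumerating all 2^10 strings, vs the independent-window form.
        probes = {"AAB", "BBA"}
        hit = sum(
            any("".join(s)[i:i + 3] in probes for i in range(8))
            for s in product("AB", repeat=10)
        )
        exact = hit / 2 ** 10
        assert exact == pytest.approx(251 / 256)
        q = 2 * 0.5 ** 3
        approx = 1 - (1 - q) ** 8
        # at q=0.25 the window-independence error is large but bounded;
        # it shrinks quadratically in q (real screens have q ~ 1e-3)
        assert abs(exact - approx) < 0.1


class TestShuffleNull:
    def test_identity_under_single_letter_proteins(self):
        lib = load_probe_library("Pw WWW\n")
        recs = [ProteinRecord(accession=f"A{i}", sequence="WWWW") for i in range(5)]
        fracs = shuffle_null_mc(recs, lib, replicates=10, seed=3)
        assert np.all(fracs == 1.0)

    def test_zero_replicates_rejected(self, tiny_proteome, two_probe_library):
        with pytest.raises(SlimScreenError):
            shuffle_null_mc(tiny_proteome, two_probe_library, replicates=0, seed=1)

    def test_observed_within_null_for_iid_proteome(self, two_probe_library):
        proteome = generate_proteome(n_proteins=150, length_dist=("fixed", 120),
                                     aa_frequencies="uniform", seed=5)
        from slimscreen import classify_p_proteins, profile_proteome

        observed = len(classify_p_proteins(profile_proteome(proteome, two_probe_library))) / 150
        fracs = shuffle_null_mc(proteome, two_probe_library, replicates=60, seed=6)
        lo, hi = np.quantile(fracs, [0.005, 0.995])
        assert lo - 0.05 <= observed <= hi + 0.05


class TestBinomialTest:
    def test_null_center_p_is_one(self):
        s = observed_vs_expected_test(5, 10, 0.5)
        assert s.p_value == pytest.approx(1.0)
        assert s.test_statistic == pytest.approx(0.0)

    def test_tail_doubling_convention(self):
        s = observed_vs_expected_test(0, 20, 0.5)
        assert s.p_value == pytest.approx(2 * 0.5 ** 20)
        assert observed_vs_expected_test(0, 20, 0.5, "less").p_value == pytest.approx(0.5 ** 20)

    def test_degenerate_boundaries(self):
        assert observed_vs_expected_test(20, 20, 1.0).p_value == 1.0
        assert observed_vs_expected_test(0, 20, 0.0).p_value == 1.0
        with pytest.raises(SlimScreenError):
            observed_vs_expected_test(3, 20, 0.0)

    def test_observed_out_of_range(self):
        with pytest.raises(SlimScreenError):
            observed_vs_expected_test(21, 20, 0.5)


class TestCodonDegeneracy:
    @pytest.mark.parametrize(
        "pep,mode,expect",
        [
            ("NFW", "sum", 5),    # 2+2+1; W has a single codon
            ("LFF", "sum", 10),   # 6+2+2; L has six codons
            ("WWW", "product", 1),
            ("LLL", "product", 216),
        ],
    )
    def test_weights(self, pep, mode, expect):
        assert codon_weight(pep, mode) == expect

    def test_codon_counts_total_61(self):
        assert sum(CODON_COUNTS.values()) == 61

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=3, max_size=3))
    @settings(max_examples=100, deadline=None)
    def test_range_and_permutation_invariance(self, pep):
        s = codon_weight(pep, "sum")
        p = codon_weight(pep, "product")
        assert 3 <= s <= 18 and 1 <= p <= 216
        rev = pep[::-1]
        assert codon_weight(rev, "sum") == s
        assert codon_weight(rev, "product") == p

    def test_non_standard_letter_rejected(self):
        with pytest.raises(SlimScreenError):
            codon_weight("NXW")

    def test_correlation_extremes_and_guards(self):
        assert frequency_codon_correlation([1, 2, 3, 4], [3, 5, 9, 12])[0] == pytest.approx(1.0)
        assert frequency_codon_correlation([4, 3, 2, 1], [3, 5, 9, 12])[0] == pytest.approx(-1.0)
        with pytest.raises(SlimScreenError):
            frequency_codon_correlation([1, 2], [3, 4])
        rho, p = frequency_codon_correlation([1.0, 1.0, 1.0], [3, 5, 9])
        assert np.isnan(rho) and np.isnan(p)

    def test_codon_usage_proteome_gives_positive_correlation(self):
        # residues drawn proportionally to codon counts: probes made of
        # highly degenerate residues should occur more often
        from slimscreen import probe_frequency_table, profile_proteome

        lib = load_probe_library(
            "P1 WMW\nP2 CWC\nP3 HYH\nP4 IAI\nP5 TVT\nP6 LSL\nP7 RLR\nP8 SRS\n"
        )
        proteome = generate_proteome(n_proteins=400, length_dist=("fixed", 400),
                                     aa_frequencies="codon_usage", seed=21)
        table = probe_frequency_table(profile_proteome(proteome, lib), proteome)
        freqs = [table.per_window_frequency[pid] for pid in lib.ids]
        weights = [codon_weight(pep, "product") for _, pep in lib]
        rho, _ = frequency_codon_correlation(freqs, weights)
        assert rho > 0
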