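"""Reannealing model, nuclease fragments, peak profiles, interference."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from numtscreen import (
    Region,
    TemplateMixture,
    anneal,
    call_interference,
    dhplc_predict,
    heteroduplex_fraction,
    sn_fragments,
    wave_hs_profile,
)
from numtscreen.duplex import (
    PeakProfile,
    UnsupportedMixtureError,
    combine_profiles,
    fragments_from_offsets,
    merge_peaks,
)

from oracles import mutate_positions, naive_fragments, random_dna


def biallelic(f: float, rng=None, length: int = 330, n_diff: int = 1):
    import random

    rng = rng or random.Random(5)
    a = random_dna(rng, length)
    b = mutate_positions(rng, a, n_diff)
    return TemplateMixture([a, b], [1.0 - f, f])


class TestAnneal:
    @pytest.mark.parametrize(
        "f,expected_het",
        [(0.5, 0.5), (0.0, 0.0), (0.02, 0.0392), (0.05, 0.095)],
    )
    def test_heteroduplex_closed_form(self, f, expected_het):
        duplexes = anneal(biallelic(f))
        assert heteroduplex_fraction(duplexes) == pytest.approx(expected_het)
        assert sum(d.abundance for d in duplexes) == pytest.approx(1.0)

    def test_homoplasmic_single_species(self):
        (d,) = anneal(biallelic(0.0))
        assert d.abundance == 1.0 and not d.is_heteroduplex

    def test_monte_carlo_pairing_agreement(self):
        """Random pairing of 1e5 strand pairs reproduces 2f(1-f) within
        three binomial standard errors."""
        n = 100_000
        rng = np.random.default_rng(42)
        for f in (0.02, 0.05, 0.5):
            strands = rng.random((n, 2)) < f  # True = minor allele
            het = (strands[:, 0] != strands[:, 1]).mean()
            expected = 2 * f * (1 - f)
            se = math.sqrt(expected * (1 - expected) / n)
            assert abs(het - expected) <= 3 * se
            assert heteroduplex_fraction(anneal(biallelic(f))) == pytest.approx(
                expected
            )

    @given(st.floats(0.001, 0.499))
    @settings(derandomize=True, max_examples=50)
    def test_monotone_on_half_open_interval(self, f):
        eps = 0.001
        lo = heteroduplex_fraction(anneal(biallelic(f)))
        hi = heteroduplex_fraction(anneal(biallelic(min(f + eps, 0.5))))
        assert hi > lo

    def test_unequal_lengths_unsupported(self):
        with pytest.raises(UnsupportedMixtureError):
            TemplateMixture(["ACGT", "ACGTA"], [0.5, 0.5])

    def test_mismatch_offsets_recorded(self):
        mix = TemplateMixture(["ACGTACGT", "ACCTACGA"], [0.9, 0.1])
        het = [d for d in anneal(mix) if d.is_heteroduplex]
        assert het[0].mismatch_offsets == (3, 8)


class TestSnFragments:
    def test_published_worked_example(self):
        assert sn_fragments(Region(12566, 12895), [12705]) == [139, 190]

    def test_uncut_when_no_mismatch(self):
        assert sn_fragments(Region(1, 100), []) == [100]

    def test_two_mismatches_interior_intervals(self):
        # the excised mismatch bases shrink the total by one per cut
        assert sn_fragments(Region(1, 100), [20, 50]) == [19, 29, 50]

    def test_boundary_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sn_fragments(Region(1, 100), [1])
        with pytest.raises(ValueError):
            sn_fragments(Region(1, 100), [100])

    def test_origin_spanning_amplicon(self):
        r = Region(16500, 100, circular=True, genome_length=16569)
        # offset of position 30 is 70 + 30 = 100
        assert sn_fragments(r, [30]) == [99, 70]

    @pytest.mark.parametrize("k", [1, 2, 5, 10])
    def test_conservation_and_oracle(self, rng, k):
        """Fragment sizes sum to length - k and match a surviving-position
        enumeration oracle, for random mismatch sets."""
        for _ in range(50):
            L = rng.randint(50, 2000)
            offsets = rng.sample(range(2, L), min(k, L - 2))
            got = fragments_from_offsets(L, offsets)
            assert sum(got) == L - len(offsets)
            assert len(got) == len(offsets) + 1
            assert got == naive_fragments(L, offsets)


class TestWaveProfile:
    def test_half_mixture_cut_profile(self):
        """50 % biallelic 330-bp mixture with the SNP 139 bp in: cut
        profile shows the 139/190 fragments plus the uncut 330 peak."""
        mix = biallelic(0.5)
        # place the single difference at offset 140 exactly
        a = mix.alleles[0]
        b = a[:139] + ("A" if a[139] != "A" else "G") + a[140:]
        mix = TemplateMixture([a, b], [0.5, 0.5])
        profile = wave_hs_profile(anneal(mix), Region(1, 330), cut=True)
        assert [round(s) for s in profile.sizes()] == [139, 190, 330]

    def test_homoplasmic_cut_equals_uncut(self):
        duplexes = anneal(biallelic(0.0))
        cut = wave_hs_profile(duplexes, Region(1, 330), cut=True)
        uncut = wave_hs_profile(duplexes, Region(1, 330), cut=False)
        assert cut.peaks == uncut.peaks

    def test_small_fragments_filtered(self):
        """Mismatches within 100 bp of both ends leave no detectable
        cleavage peak besides the parent size."""
        a = random_dna(__import__("random").Random(9), 150)
        b = mutate_positions(__import__("random").Random(10), a, 0)
        b = a[:74] + ("A" if a[74] != "A" else "G") + a[75:]
        mix = TemplateMixture([a, b], [0.5, 0.5])
        profile = wave_hs_profile(anneal(mix), Region(1, 150), cut=True)
        assert [round(s) for s in profile.sizes()] == [150]
        # the filtered fragments are retained in the raw profile
        assert len(profile.raw_peaks) > len(profile.peaks)

    def test_mass_conservation_before_filter(self, rng):
        for _ in range(20):
            L = rng.randint(120, 600)
            a = random_dna(rng, L)
            b = mutate_positions(rng, a, rng.randint(1, 6))
            mix = TemplateMixture([a, b], [0.8, 0.2])
            for cut in (False, True):
                p = wave_hs_profile(anneal(mix), Region(1, L), cut=cut)
                assert p.raw_total_abundance == pytest.approx(1.0)

    def test_partial_digestion(self):
        mix = biallelic(0.5)
        p = wave_hs_profile(anneal(mix), Region(1, 330), cut=True,
                            digestion_efficiency=0.5)
        full = [ab for s, ab in p.peaks if round(s) == 330]
        # half the heteroduplex mass stays undigested at full length
        assert full[0] == pytest.approx(0.5 + 0.5 * 0.5)


class TestDhplc:
    def test_detection_floor(self):
        assert dhplc_predict(anneal(biallelic(0.5)))
        assert dhplc_predict(anneal(biallelic(0.05)))
        assert not dhplc_predict(anneal(biallelic(0.02)))
        assert not dhplc_predict(anneal(biallelic(0.0)))

    def test_fragment_readout_more_sensitive_than_dhplc(self):
        """At a 2 % minor allele the cleavage-fragment readout still shows
        the two fragment peaks while the heteroduplex readout is below its
        floor -- the sensitivity ordering of the two techniques."""
        mix = biallelic(0.02, length=330)
        duplexes = anneal(mix)
        assert not dhplc_predict(duplexes)
        cut = wave_hs_profile(duplexes, Region(1, 330), cut=True)
        assert len(cut.peaks) >= 2


class TestInterference:
    def make_profile(self, peaks, label="cut"):
        return PeakProfile(sorted(peaks), label, raw_peaks=sorted(peaks))

    def test_extra_peak_calls_interference(self):
        total = self.make_profile([(330.0, 0.9), (150.0, 0.1)])
        mt = self.make_profile([(330.0, 1.0)])
        call = call_interference(total, mt)
        assert call.interference
        assert call.differing_peaks == [(150.0, 0.1, 0.0)]

    def test_identical_profiles_no_call(self):
        p = self.make_profile([(330.0, 0.8), (139.0, 0.1), (190.0, 0.1)])
        assert not call_interference(p, p).interference

    def test_abundance_shift_within_shared_peaks_no_call(self):
        a = self.make_profile([(330.0, 0.8), (139.0, 0.2)])
        b = self.make_profile([(330.0, 0.95), (139.0, 0.05)])
        assert not call_interference(a, b).interference

    def test_sub_tolerance_peak_counts_as_absent(self):
        a = self.make_profile([(330.0, 0.99), (150.0, 0.008)])
        b = self.make_profile([(330.0, 1.0)])
        assert not call_interference(a, b, tolerance=0.01).interference
        assert call_interference(a, b, tolerance=0.005).interference

    def test_mixed_cut_states_rejected(self):
        a = self.make_profile([(330.0, 1.0)], "cut")
        b = self.make_profile([(330.0, 1.0)], "uncut")
        with pytest.raises(ValueError):
            call_interference(a, b)


class TestPeakUtilities:
    def test_merge_within_resolution(self):
        merged = merge_peaks([(100.0, 0.5), (101.0, 0.5), (200.0, 1.0)])
        assert len(merged) == 2
        assert merged[0] == (100.5, 1.0)

    def test_combine_profiles_weights(self):
        a = PeakProfile([(330.0, 1.0)], "uncut", raw_peaks=[(330.0, 1.0)])
        b = PeakProfile([(500.0, 1.0)], "uncut", raw_peaks=[(500.0, 1.0)])
        c = combine_profiles([(a, 0.75), (b, 0.25)])
        assert c.peaks == [(330.0, 0.75), (500.0, 0.25)]
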