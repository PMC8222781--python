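import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from idrscape.composition import (
    DEFAULT_REDUCED_ALPHABET,
    KmerSpectrum,
    RegionSpec,
    group_pair_fraction,
    idr_composition_report,
    kmer_spectrum,
    residue_set_share,
    top_kmers,
    validate_reduced_alphabet,
)
from idrscape.io import STANDARD_AA, ProteinRecord
from idrscape.segmentation import SegmentationParams, segment_idrs

from .oracles import brute_force_kmers


def rec(seq, pid="p"):
    return ProteinRecord(id=pid, sequence=seq)


def whole(record):
    return RegionSpec(record.id, 1, len(record))


class TestResidueSetShare:
    def test_full_share(self):
        r = rec("RGRG")
        assert residue_set_share(r, RegionSpec("p", 1, 4), {"R", "G"}) == 100.0

    def test_region_out_of_bounds(self):
        with pytest.raises(ValueError, match="out of bounds"):
            residue_set_share(rec("RGRG"), RegionSpec("p", 2, 9), {"R"})

    def test_non_standard_query_rejected(self):
        with pytest.raises(ValueError):
            residue_set_share(rec("RGRG"), RegionSpec("p", 1, 4), {"X"})

    @given(st.text(alphabet=STANDARD_AA, min_size=1, max_size=40))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_reversal_invariance_and_monotonicity(self, seq):
        r1, r2 = rec(seq, "a"), rec(seq[::-1], "b")
        small = residue_set_share(r1, whole(r1), {"R", "G"})
        assert small == pytest.approx(residue_set_share(r2, whole(r2), {"R", "G"}))
        bigger = residue_set_share(r1, whole(r1), {"R", "G", "S"})
        assert bigger >= small


class TestKmerSpectrum:
    def test_single_region_2mers(self):
        spec = kmer_spectrum([(rec("GGGG"), RegionSpec("p", 1, 4))], k=2)
        assert spec.counts == {"GG": 3}
        assert spec.frequencies == {"GG": 1.0}

    def test_windows_never_bridge_regions(self):
        a, b = rec("RS", "a"), rec("SR", "b")
        spec = kmer_spectrum([(a, whole(a)), (b, whole(b))], k=2)
        assert spec.counts == {"RS": 1, "SR": 1}

    def test_region_shorter_than_k_contributes_nothing(self):
        a = rec("R", "a")
        spec = kmer_spectrum([(a, whole(a))], k=3)
        assert spec.total == 0 and spec.frequencies == {}

    def test_matches_brute_force_on_random_regions(self):
        rng = np.random.default_rng(7)
        regions, seqs = [], []
        for i in range(10):
            n = int(rng.integers(2, 30))
            seq = "".join(rng.choice(list(STANDARD_AA), size=n))
            r = rec(seq, f"p{i}")
            regions.append((r, whole(r)))
            seqs.append(seq)
        for k in (1, 2, 3):
            assert kmer_spectrum(regions, k).counts == brute_force_kmers(seqs, k)

    @given(
        st.lists(st.text(alphabet=STANDARD_AA, min_size=1, max_size=30),
                 min_size=1, max_size=5),
        st.sampled_from([1, 2, 3]),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_conservation_invariants(self, seqs, k):
        """Frequencies sum to 1 when total > 0 and the total equals
        sum(len - k + 1) over regions of length >= k."""
        regions = [(rec(s, f"p{i}"), whole(rec(s, f"p{i}"))) for i, s in enumerate(seqs)]
        spec = kmer_spectrum(regions, k)
        expected_total = sum(len(s) - k + 1 for s in seqs if len(s) >= k)
        assert spec.total == expected_total
        if expected_total:
            assert sum(spec.frequencies.values()) == pytest.approx(1.0, abs=1e-9)


class TestReducedAlphabet:
    def test_partitions_standard_residues(self):
        validate_reduced_alphabet(DEFAULT_REDUCED_ALPHABET)
        assert set(DEFAULT_REDUCED_ALPHABET) == set(STANDARD_AA)
        groups = {g: [aa for aa, gg in DEFAULT_REDUCED_ALPHABET.items() if gg == g]
                  for g in "123456"}
        assert sorted(groups["1"]) == ["F", "W", "Y"]
        assert sorted(groups["2"]) == ["H", "K", "R"]
        assert sorted(groups["5"]) == ["A", "C", "G", "P", "S", "T"]

    def test_map_then_count_commutes_for_1mers(self):
        seq = "RGSRGSWWKA"
        r = rec(seq)
        reduced = kmer_spectrum([(r, whole(r))], 1, alphabet="reduced")
        standard = kmer_spectrum([(r, whole(r))], 1)
        regrouped: dict[str, int] = {}
        for aa, c in standard.counts.items():
            g = DEFAULT_REDUCED_ALPHABET[aa]
            regrouped[g] = regrouped.get(g, 0) + c
        assert reduced.counts == regrouped


class TestTopKmers:
    def test_tie_broken_lexicographically(self):
        spec = KmerSpectrum(k=2, counts={"AA": 5, "CC": 5, "GG": 1})
        assert [w for w, _ in top_kmers(spec, 2)] == ["AA", "CC"]

    def test_truncates_to_available(self):
        spec = KmerSpectrum(k=2, counts={"GG": 3})
        assert [w for w, _ in top_kmers(spec, 5)] == ["GG"]

    def test_empty_spectrum(self):
        assert top_kmers(KmerSpectrum(k=2, counts={}), 3) == []


class TestGroupPairFraction:
    def test_all_mass_in_groups(self):
        spec = KmerSpectrum(
            k=2, counts={"55": 1, "52": 1, "25": 1, "22": 1}, alphabet="reduced"
        )
        assert group_pair_fraction(spec, {2, 5}) == pytest.approx(100.0)

    def test_no_mass_in_groups(self):
        spec = KmerSpectrum(k=2, counts={"14": 7}, alphabet="reduced")
        assert group_pair_fraction(spec, {2, 5}) == 0.0

    def test_uniform_over_36_pairs(self):
        counts = {f"{a}{b}": 1 for a in "123456" for b in "123456"}
        spec = KmerSpectrum(k=2, counts=counts, alphabet="reduced")
        assert group_pair_fraction(spec, {2, 5}) == pytest.approx(100 * 4 / 36)

    def test_requires_reduced_2mer_spectrum(self):
        with pytest.raises(ValueError):
            group_pair_fraction(KmerSpectrum(k=2, counts={"AA": 1}), {2, 5})


class TestCompositionReport:
    def test_single_rg_idr(self):
        from idrscape.io import ScoreTrack

        seq = "RGRGRG" + "L" * 34
        track = ScoreTrack("p", tuple([0.9] * 6 + [0.1] * 34))
        profile = segment_idrs(track, SegmentationParams(min_len=5, max_gap=2))
        report = idr_composition_report(
            [profile], {"p": rec(seq)}, {"p": "reader"}
        )
        row = report.per_idr_top3.iloc[0]
        assert set(row["top3_residues"]) <= {"R", "G"}
        assert row["top3_joint_share_pct"] == 100.0

    def test_protein_without_idr_contributes_nothing(self):
        from idrscape.io import ScoreTrack

        track = ScoreTrack("p", tuple([0.1] * 40))
        profile = segment_idrs(track, SegmentationParams())
        report = idr_composition_report(
            [profile], {"p": rec("A" * 40)}, {"p": "reader"}
        )
        assert report.spectra[("reader", 1, "standard")].total == 0
        assert report.warnings  # zero-IDR group warned, not an error

    def test_reader_bias_recovered(self, small_cohort):
        """Pooled Reader IDR 1-mer spectrum recovers the generator's planted
        G/S/R/P bias within binomial sampling error."""
        from idrscape.segmentation import segment_idrs as seg
        from idrscape.synthetic import READER_IDR_BIAS

        profiles = [seg(t, SegmentationParams()) for t in small_cohort.tracks]
        report = idr_composition_report(
            profiles,
            {r.id: r for r in small_cohort.records},
            small_cohort.groups,
        )
        spec = report.spectra[("reader", 1, "standard")]
        planted = sum(READER_IDR_BIAS[aa] for aa in "GSRP")
        observed = sum(spec.frequencies.get(aa, 0.0) for aa in "GSRP")
        se = np.sqrt(planted * (1 - planted) / spec.total)
        # segment boundaries extend slightly beyond planted blocks, diluting
        # the bias with background residues; allow a small systematic margin
        assert abs(observed - planted) < 3 * se + 0.01
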