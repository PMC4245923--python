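import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hlarray import (
    AlleleCatalog,
    AlleleSequence,
    CatalogError,
    adjust_probe_length,
    build_probe_set,
    melting_temperature,
    tile_initial_probes,
)
from hlarray.errors import InvalidSequenceError, PositionError

dna = st.text(alphabet="ACGT", min_size=1, max_size=80)


class TestMeltingTemperature:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("A" * 25, 38.004),  # GC-free 25-mer
            ("G" * 25, 79.004),  # all-GC 25-mer
            ("G" * 10 + "C" * 10 + "A" * 20, 68.59),  # 40-mer with 20 G+C
        ],
    )
    def test_hand_evaluated_values(self, seq, expected):
        assert melting_temperature(seq) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("bad", ["", "ACGU", "acgt", "ACGTN"])
    def test_invalid_sequences(self, bad):
        with pytest.raises(InvalidSequenceError):
            melting_temperature(bad)

    @given(dna)
    @settings(max_examples=100, derandomize=True)
    def test_matches_base_count_formula(self, seq):
        gc = seq.count("G") + seq.count("C")
        assert melting_temperature(seq) == pytest.approx(
            64.9 + 41 * (gc - 16.4) / len(seq)
        )

    def test_strictly_increasing_in_gc_at_fixed_length(self):
        # slope is 41/length per additional G or C
        for n in (20, 33, 60):
            tms = [melting_temperature("G" * k + "A" * (n - k)) for k in range(n + 1)]
            diffs = np.diff(tms)
            assert np.all(diffs > 0)
            assert np.allclose(diffs, 41.0 / n)


class TestTiling:
    def test_probe_count_and_overlap(self):
        allele = AlleleSequence("A*01:01", "ACGTA" * 6)  # 30 nt
        probes = tile_initial_probes(allele, 25)
        assert len(probes) == 6
        assert [p.start for p in probes] == list(range(6))
        for a, b in zip(probes, probes[1:]):
            assert a.sequence[1:] == b.sequence[:-1]  # 24-nt overlap

    def test_single_probe_identity_case(self):
        allele = AlleleSequence("A*01:01", "ACGTA" * 5)  # exactly 25 nt
        probes = tile_initial_probes(allele, 25)
        assert len(probes) == 1
        assert probes[0].sequence == allele.sequence

    def test_too_short_sequence(self):
        allele = AlleleSequence("A*01:01", "ACGTACGTACGTACGTACGTACGT")  # 24 nt
        with pytest.raises(PositionError):
            tile_initial_probes(allele, 25)


class TestLengthAdjustment:
    def test_gc_rich_region_shrinks_to_minimum(self):
        # all-G/C: Tm(n) = 105.9 - 672.4/n decreases as n shrinks, still
        # above target at n=20, so the shortest probe is optimal
        allele = AlleleSequence("A*01:01", "GC" * 40)
        probe = adjust_probe_length(allele, 0)
        assert probe.length == 20
        assert probe.tm == pytest.approx(105.9 - 672.4 / 20)

    def test_at_rich_region_extends_to_maximum(self):
        # all-A/T: Tm(n) = 64.9 - 672.4/n rises toward 64.2 with length
        allele = AlleleSequence("A*01:01", "AT" * 40)
        probe = adjust_probe_length(allele, 0)
        assert probe.length == 60

    def test_truncation_at_sequence_end(self):
        allele = AlleleSequence("A*01:01", "GC" * 20)  # 40 nt
        probe = adjust_probe_length(allele, 18)  # 22 nt remain
        assert probe.length >= 20
        assert probe.start + probe.length <= len(allele.sequence)
        probe = adjust_probe_length(allele, 20)  # exactly 20 remain
        assert probe.length == 20

    def test_out_of_range_start(self):
        allele = AlleleSequence("A*01:01", "ACGT" * 10)
        with pytest.raises(PositionError):
            adjust_probe_length(allele, 25)  # < 20 nt remain
        with pytest.raises(PositionError):
            adjust_probe_length(allele, -1)

    @given(st.text(alphabet="ACGT", min_size=70, max_size=90), st.integers(0, 30))
    @settings(max_examples=60, derandomize=True)
    def test_brute_force_minimizer(self, seq, start):
        allele = AlleleSequence("A*01:01", seq)
        probe = adjust_probe_length(allele, start)
        target = 64.2
        feasible = range(20, min(60, len(seq) - start) + 1)
        diffs = {
            n: abs(melting_temperature(seq[start : start + n]) - target) for n in feasible
        }
        best = min(diffs.values())
        assert abs(probe.tm - target) == pytest.approx(best)
        # tie broken toward the shorter probe
        shortest_best = min(n for n, d in diffs.items() if d == pytest.approx(best))
        assert probe.length == shortest_best


class TestProbeSet:
    def test_identical_alleles_collapse(self):
        seq = "ACGTACGTACGTACGTACGTACGTACGTAC"
        cat = AlleleCatalog(
            [AlleleSequence("A*01:01", seq), AlleleSequence("A*01:02", seq)]
        )
        ps = build_probe_set(cat)
        single = build_probe_set(AlleleCatalog([AlleleSequence("A*01:01", seq)]))
        assert ps.n_probes == single.n_probes
        cov = ps.coverage()
        assert all(len(places) == 2 for places in cov.values())

    def test_single_nucleotide_difference_probe_sharing(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        variant = seq[:100] + ("A" if seq[100] != "A" else "C") + seq[101:]
        cat = AlleleCatalog(
            [AlleleSequence("A*01:01", seq), AlleleSequence("A*01:02", variant)]
        )
        ps = build_probe_set(cat)
        p1 = ps.allele_probes["A*01:01"]
        p2 = ps.allele_probes["A*01:02"]
        differ = np.nonzero(p1 != p2)[0]
        # only probes whose window overlaps position 100 can differ
        assert differ.size > 0
        assert differ.min() >= 100 - 59
        assert differ.max() <= 100
        # probes far outside a (max_len-1)-window around the variant are shared
        far = np.concatenate([np.arange(0, 100 - 60), np.arange(101, p1.size)])
        assert np.array_equal(p1[far], p2[far])

    def test_anchored_placement_count(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=100))
        ps = build_probe_set(AlleleCatalog([AlleleSequence("A*01:01", seq)]))
        assert len(ps.allele_probes["A*01:01"]) == 81  # anchors 0..80
        assert ps.n_placements == 81

    def test_duplicate_names_rejected(self):
        a = AlleleSequence("A*01:01", "ACGT" * 10)
        with pytest.raises(CatalogError):
            AlleleCatalog([a, a])

    def test_length_bounds_and_coverage_inverse(self, sim_catalog, sim_probeset):
        ps = sim_probeset
        assert ps.lengths.min() >= 20
        assert ps.lengths.max() <= 60
        # coverage is the exact inverse of the per-allele index
        rebuilt = {a: [0] * len(p) for a, p in ps.allele_probes.items()}
        for pid, places in ps.coverage().items():
            for allele, start in places:
                rebuilt[allele][start] = pid
        for allele, pids in ps.allele_probes.items():
            assert rebuilt[allele] == [int(p) for p in pids]

    def test_unique_fraction_decreases_with_identity(self):
        # families at increasing sequence identity share more probes
        from hlarray import SimConfig, generate_allele_catalog

        fractions = []
        for between in (40, 18, 4):
            cfg = SimConfig(seed=9, n_loci=1, serotypes_per_locus=4,
                            between_serotype_divergence=between)
            cat, _ = generate_allele_catalog(cfg)
            ps = build_probe_set(cat)
            fractions.append(ps.n_probes / ps.n_placements)
        assert fractions[0] > fractions[1] > fractions[2]


def test_probe_tables(sim_probeset, tmp_path):
    pf = sim_probeset.probe_frame()
    lf = sim_probeset.placement_frame()
    assert set(pf.columns) == {"probe_id", "sequence", "length", "tm", "n_placements"}
    assert pf["n_placements"].sum() == len(lf) == sim_probeset.n_placements
    assert pf["sequence"].is_unique
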