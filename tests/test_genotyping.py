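import itertools

import numpy as np
import pytest

from hlarray import (
    AlleleCatalog,
    AlleleSequence,
    allele_avg_wins,
    build_comparison_vector,
    build_probe_set,
    frequency_tiebreak,
    genotype_wins,
    pairwise_wins,
    resolve_ambiguity,
    weight_based_selection,
)
from hlarray.errors import GenotypeError


def _two_allele_instance(n_variants=5, seed=0):
    """Two alleles differing at ``n_variants`` well-separated positions, plus
    signals in which the first allele is 'present' (bright at its probes)."""
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=400))
    variant = list(seq)
    positions = [70 + 65 * i for i in range(n_variants)]
    for p in positions:
        variant[p] = "A" if seq[p] != "A" else "C"
    cat = AlleleCatalog(
        [AlleleSequence("A*01:01", seq), AlleleSequence("A*01:02", "".join(variant))]
    )
    ps = build_probe_set(cat)
    values = np.full(ps.n_probes, 100.0)
    values[ps.allele_probes["A*01:01"]] = 5000.0  # x present, y at background
    return cat, ps, values, positions


class TestAlleleWins:
    def test_identical_probe_tracks_have_no_wins(self):
        seq = "ACGTACGTACGTACGTACGTACGTACGTACGT"
        cat = AlleleCatalog(
            [AlleleSequence("A*01:01", seq), AlleleSequence("A*01:02", seq)]
        )
        ps = build_probe_set(cat)
        avg = allele_avg_wins(["A*01:01", "A*01:02"], np.ones(ps.n_probes), ps)
        assert avg == {"A*01:01": 0.0, "A*01:02": 0.0}

    def test_present_allele_wins_every_discriminating_column(self):
        cat, ps, values, positions = _two_allele_instance()
        wx, wy = pairwise_wins("A*01:01", "A*01:02", values, ps)
        # brute force: count anchors with differing probes and compare signals
        p1, p2 = ps.allele_probes["A*01:01"], ps.allele_probes["A*01:02"]
        expect = sum(
            int(values[a] > values[b]) for a, b in zip(p1, p2) if a != b
        )
        assert wx == expect
        assert wy == 0
        avg = allele_avg_wins(["A*01:01", "A*01:02"], values, ps)
        assert avg["A*01:01"] == wx
        assert avg["A*01:02"] == 0.0

    def test_single_allele_scope(self, sim_probeset):
        avg = allele_avg_wins(["A*01:01"], np.ones(sim_probeset.n_probes), sim_probeset)
        assert avg == {"A*01:01": 0.0}

    def test_present_allele_has_greatest_avg_wins_among_three(
        self, sim_catalog, sim_probeset, sim_config
    ):
        from hlarray import draw_genotype, normalize_signals, simulate_array

        catalog, _ = sim_catalog
        rng = np.random.default_rng(5)
        g = draw_genotype(catalog, rng)
        present = g["A"][0]
        st = present.rsplit(":", 1)[0]
        scope = [a.name for a in catalog.serotype_members(st)]
        s = simulate_array(g, sim_probeset, catalog, sim_config, 1, 2)
        norm = normalize_signals(s.signals)
        avg = allele_avg_wins(scope, norm.values, sim_probeset)
        assert max(avg, key=avg.get) == present


class TestWeightSelection:
    def test_rule_application(self):
        avg = {"x": 30.0, "y": 2.0, "z": 15.0}
        negs = {"x": 5, "y": 40, "z": 5}
        out = weight_based_selection(["x", "y", "z"], avg, negs, {"z": 10.0}, 10.0)
        assert out == ["x"]  # x: 25 > 10; y: -38; z: 10 == 10 rejected (strict)

    def test_boundary_is_strict(self):
        out = weight_based_selection(["x"], {"x": 15.0}, {"x": 5}, None, 10.0)
        assert out == []


class TestGenotypeWins:
    def test_identical_content_rejected(self, sim_probeset):
        g = {"A": ("A*01:01", "A*02:01")}
        with pytest.raises(GenotypeError):
            genotype_wins(g, {"A": ("A*02:01", "A*01:01")}, np.ones(10), sim_probeset)

    def test_three_alleles_rejected(self, sim_probeset):
        with pytest.raises(GenotypeError):
            genotype_wins(
                {"A": ("A*01:01", "A*01:02", "A*01:03")},
                {"A": ("A*01:01",)},
                np.ones(10),
                sim_probeset,
            )

    def test_direct_count_example(self):
        cat, ps, values, _ = _two_allele_instance()
        w1, w2 = genotype_wins(
            {"A": ("A*01:01",)}, {"A": ("A*01:02",)}, values, ps
        )
        assert w1 > 0 and w2 == 0  # present allele wins every differing position

    def test_equal_sums_score_neither(self):
        seq = "ACGTACGTACGTACGTACGTACGTACGTACGT"
        cat = AlleleCatalog(
            [AlleleSequence("A*01:01", seq), AlleleSequence("A*01:02", seq)]
        )
        ps = build_probe_set(cat)
        with pytest.raises(GenotypeError):
            # identical probe content reduces to identical allele sets
            genotype_wins({"A": ("A*01:01",)}, {"A": ("A*01:01",)}, np.ones(ps.n_probes), ps)

    def test_antisymmetry_and_brute_force(self, sim_catalog, sim_probeset, rng):
        """Random small instances agree with an independent position-sum oracle."""
        catalog, _ = sim_catalog
        a_alleles = [a.name for a in catalog.locus_members("A")]
        values = rng.lognormal(6, 1, sim_probeset.n_probes)
        for _ in range(50):
            g1 = {"A": tuple(rng.choice(a_alleles, size=2, replace=False))}
            g2 = {"A": tuple(rng.choice(a_alleles, size=2, replace=False))}
            if sorted(g1["A"]) == sorted(g2["A"]):
                continue
            w1, w2 = genotype_wins(g1, g2, values, sim_probeset)
            # oracle: explicit loop over alignment positions
            e1 = e2 = ties = 0
            tracks = {a: sim_probeset.allele_probes[a] for a in set(g1["A"]) | set(g2["A"])}
            n_pos = len(next(iter(tracks.values())))
            for p in range(n_pos):
                s1 = sum(values[tracks[a][p]] for a in set(g1["A"]))
                s2 = sum(values[tracks[a][p]] for a in set(g2["A"]))
                if s1 > s2:
                    e1 += 1
                elif s2 > s1:
                    e2 += 1
                else:
                    ties += 1
            assert (w1, w2) == (e1, e2)
            assert w1 + w2 == n_pos - ties  # antisymmetry over non-tied positions


class TestResolveAmbiguity:
    def test_pass_through_with_two_candidates_per_locus(self, sim_probeset):
        out = resolve_ambiguity(
            {"A": ["A*01:01", "A*02:01"], "B": ["B*01:01", "B*02:01"]},
            np.ones(sim_probeset.n_probes),
            sim_probeset,
        )
        assert len(out) == 1
        assert out[0][0] == {"A": ("A*01:01", "A*02:01"), "B": ("B*01:01", "B*02:01")}

    def test_empty_locus_rejected(self, sim_probeset):
        with pytest.raises(GenotypeError):
            resolve_ambiguity({"A": []}, np.ones(10), sim_probeset)

    def test_enumeration_cap(self, sim_catalog, sim_probeset):
        catalog, _ = sim_catalog
        cands = {l: [a.name for a in catalog.locus_members(l)][:8] for l in "ABC"}
        with pytest.raises(GenotypeError):
            resolve_ambiguity(
                cands, np.ones(sim_probeset.n_probes), sim_probeset, cap=10
            )

    def test_truth_ranks_first_with_extra_candidate(
        self, sim_catalog, sim_probeset, sim_config
    ):
        from hlarray import draw_genotype, normalize_signals, simulate_array

        catalog, _ = sim_catalog
        rng = np.random.default_rng(11)
        g = draw_genotype(catalog, rng)
        s = simulate_array(g, sim_probeset, catalog, sim_config, 1, 2)
        norm = normalize_signals(s.signals)
        # inject an absent sibling of the first A allele as a third candidate
        st = g["A"][0].rsplit(":", 1)[0]
        sib = next(
            a.name for a in catalog.serotype_members(st) if a.name not in g["A"]
        )
        cands = {
            "A": sorted([*g["A"], sib]),
            "B": sorted(g["B"]),
            "C": sorted(g["C"]),
        }
        out = resolve_ambiguity(cands, norm.values, sim_probeset)
        top = out[0][0]
        assert {l: tuple(sorted(top[l])) for l in top} == {
            l: tuple(sorted(g[l])) for l in g
        }


class TestFrequencyTiebreak:
    GENOS = [
        ({"B": ("B*07:24", "B*35:33")}, 50.0),  # rare pair, higher wins order
        ({"B": ("B*07:02", "B*35:03")}, 50.0),  # common pair
    ]

    def test_common_pair_ranked_first(self):
        freqs = {"B*07:02": 0.08, "B*35:03": 0.03, "B*07:24": 1e-6, "B*35:33": 1e-6}
        out = frequency_tiebreak(self.GENOS, freqs)
        assert out[0][0] == {"B": ("B*07:02", "B*35:03")}

    def test_no_table_preserves_order(self):
        assert frequency_tiebreak(self.GENOS, None) == self.GENOS

    def test_equal_products_stable(self):
        freqs = {a: 0.01 for g, _ in self.GENOS for a in g["B"]}
        assert frequency_tiebreak(self.GENOS, freqs) == self.GENOS


def test_comparison_vector_scope_and_canonical_order(
    sim_catalog, sim_probeset, sim_config
):
    from hlarray import draw_genotype, normalize_signals, simulate_array
    from hlarray.serotyping import locus_allele_negatives
    from hlarray.signals import binarize

    catalog, _ = sim_catalog
    rng = np.random.default_rng(2)
    g = draw_genotype(catalog, rng)
    s = simulate_array(g, sim_probeset, catalog, sim_config, 1, 2)
    norm = normalize_signals(s.signals)
    calls = binarize(norm)
    negs = {
        a: n
        for st_map in [locus_allele_negatives("A", catalog, calls, sim_probeset)]
        for d in st_map.values()
        for a, n in d.items()
    }
    one = build_comparison_vector("A*01", ["A*01"], catalog, norm.values, sim_probeset, negs)
    assert one.scope == "serotype"
    assert one.alleles == sorted(one.alleles)
    two = build_comparison_vector(
        "A-g1", ["A*01", "A*02"], catalog, norm.values, sim_probeset, negs
    )
    assert two.scope == "serogroup"
    assert len(two.vector) == 2 * len(two.alleles)
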