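import numpy as np
import pytest
from Bio import Align
from Bio.Align import substitution_matrices

from cerna_recur.mre_scan import (DEFAULT_SCORING, ScanParams, SeedSite, align_duplex,
                                  duplex_energy, find_seed_sites, pair_score,
                                  predict_targets, revcomp, score_site)

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


def brute_force_scan(mirna, target):
    """Independent window scan: every 6mer-core anchor with its best type."""
    core = "".join(_COMP[b] for b in mirna[1:7])[::-1]
    found = []
    for s in range(len(target) - 5):
        if target[s:s + 6] != core:
            continue
        m8 = s >= 1 and (target[s - 1], mirna[7]) in _WC
        a1 = s + 6 < len(target) and target[s + 6] == "A"
        if m8 and a1:
            found.append(("8mer", s - 1, s + 7))
        elif m8:
            found.append(("7mer-m8", s - 1, s + 6))
        elif a1:
            found.append(("7mer-A1", s, s + 7))
        else:
            found.append(("6mer", s, s + 6))
    return found


def biopython_local_aligner(scoring=DEFAULT_SCORING):
    mat = substitution_matrices.Array("ACGU", dims=2)
    for a in "ACGU":
        for b in "ACGU":
            if (a, b) in _WC:
                mat[a, b] = scoring.match
            elif (a, b) in _WOBBLE:
                mat[a, b] = scoring.wobble
            else:
                mat[a, b] = scoring.mismatch
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = mat
    al.open_gap_score = scoring.gap
    al.extend_gap_score = scoring.gap
    return al


def random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), n))


class TestFindSeedSites:
    def test_worked_8mer_example(self):
        sites = find_seed_sites("UAUGCAUGCAUGCAUGCAUG", "GGGCAUGCAUAGGG")
        assert len(sites) == 1
        assert sites[0].site_type == "8mer"
        assert sites[0].span == (3, 11)

    def test_gc_seed_cannot_match_poly_a(self):
        assert find_seed_sites("UGCGCGCGAAAAAAAAAAA", "A" * 40) == []

    def test_two_disjoint_planted_copies(self):
        m = "UAUGCAUGCAUGCAUGCAUG"
        site = revcomp(m[1:8]) + "A"
        target = "GG" + site + "CCCC" + site + "GG"
        sites = find_seed_sites(m, target)
        assert [s.site_type for s in sites] == ["8mer", "8mer"]
        assert sites[0].span == (2, 10)
        assert sites[1].span == (14, 22)

    @pytest.mark.parametrize("suffix,expected", [
        ("A", "8mer"),      # m8 match and A1
        ("G", "7mer-m8"),   # m8 match, no A1
    ])
    def test_site_type_upgrades(self, suffix, expected):
        m = "UAUGCAUGCAUGCAUGCAUG"
        core7 = revcomp(m[1:8])  # m8 + 6mer core
        sites = find_seed_sites(m, "GG" + core7 + suffix + "GG")
        assert [s.site_type for s in sites] == [expected]

    def test_7mer_a1_and_6mer(self):
        m = "UAUGCAUGCAUGCAUGCAUG"
        core6 = revcomp(m[1:7])
        # force a non-m8 base 5' of the core
        bad5 = "A" if _COMP[m[7]] != "A" else "G"
        sites = find_seed_sites(m, "G" + bad5 + core6 + "A" + "GG")
        assert [s.site_type for s in sites] == ["7mer-A1"]
        sites = find_seed_sites(m, "G" + bad5 + core6 + "G" + "GG")
        assert [s.site_type for s in sites] == ["6mer"]

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(150):
            m = random_rna(rng, int(rng.integers(19, 25)))
            t = random_rna(rng, int(rng.integers(6, 80)))
            got = [(s.site_type, s.start, s.end) for s in find_seed_sites(m, t)]
            assert got == brute_force_scan(m, t)

    def test_short_mirna_rejected(self):
        with pytest.raises(ValueError, match=">= 8 nt"):
            find_seed_sites("UAUGCAU", "GGGCAUGCAUAGGG")

    def test_dna_input_accepted_as_rna(self):
        sites = find_seed_sites("TATGCATGCATGCATGCATG", "GGGCATGCATAGGG")
        assert sites[0].site_type == "8mer"

    def test_non_nucleotide_rejected(self):
        with pytest.raises(ValueError, match="non-RNA"):
            find_seed_sites("UAUGCAUGXAUGCAUGCAUG", "GGGCAUGCAUAGGG")


class TestPairScore:
    def test_perfect_complement_scores_five_per_base(self):
        m = "UAUGCAUGCAUGCAUGCAUG"
        assert align_duplex(m, revcomp(m)).score == 100.0

    def test_no_complementarity_floors_at_zero(self):
        assert align_duplex("A" * 20, "A" * 20).score == 0.0

    def test_equals_biopython_local_alignment_on_random_pairs(self, rng):
        al = biopython_local_aligner()
        for _ in range(150):
            m = random_rna(rng, int(rng.integers(8, 21)))
            t = random_rna(rng, int(rng.integers(6, 21)))
            assert align_duplex(m, t).score == al.score(t, m[::-1])

    def test_window_positions_relative_to_site(self):
        m = "UAUGCAUGCAUGCAUGCAUG"
        planted = revcomp(m[1:]) + "A"
        target = "CCCC" + planted + "CCCC"
        sites = find_seed_sites(m, target)
        site = next(s for s in sites if s.site_type == "8mer")
        score = pair_score(m, target, site, window=30)
        assert score >= 5.0 * (len(m) - 1)

    def test_window_must_cover_seed(self):
        m = "UAUGCAUGCAUGCAUGCAUG"
        target = "GGGCAUGCAUAGGG"
        site = find_seed_sites(m, target)[0]
        with pytest.raises(ValueError, match="window"):
            pair_score(m, target, site, window=4)


class TestDuplexEnergy:
    def test_empty_is_zero(self):
        assert duplex_energy([]) == 0.0

    def test_seed_duplex_hand_sum(self):
        pairs = [("A", "U")] * 4 + [("G", "C")] * 3
        assert duplex_energy(pairs) == -17.0

    def test_wobble_adds_exactly_one(self):
        base = [("A", "U"), ("G", "C")]
        assert duplex_energy(base + [("G", "U")]) == duplex_energy(base) - 1.0

    def test_invalid_pair_rejected(self):
        with pytest.raises(ValueError, match="invalid base pair"):
            duplex_energy([("A", "C")])

    def test_translation_invariance_of_site_scores(self):
        m = "UAUGCAUGCAUGCAUGCAUG"
        planted = revcomp(m[1:]) + "A"
        for pad in (0, 7, 40):
            target = "C" * pad + planted + "C" * 10
            site = next(s for s in find_seed_sites(m, target)
                        if s.site_type == "8mer")
            scored = score_site(m, target, site)
            if pad == 0:
                expected = (scored.pair_score, scored.energy)
            else:
                assert (scored.pair_score, scored.energy) == expected


class TestPredictTargets:
    M = "UAUGCAUGCAUGCAUGCAUG"

    def test_planted_full_site_passes(self):
        target = "CCCC" + revcomp(self.M[1:]) + "A" + "CCCC"
        preds = predict_targets({"m1": self.M}, {"t1": target})
        assert len(preds) == 1
        assert preds[0].passed
        assert preds[0].best_pair_score >= 80
        assert preds[0].best_energy <= -14

    def test_seed_only_with_scrambled_flanks_fails_score_threshold(self):
        # bare 8mer in a poly-C context: strong seed, no 3' support
        target = "CCCCCCCCCCCC" + revcomp(self.M[1:8]) + "A" + "CCCCCCCCCCCC"
        preds = predict_targets({"m1": self.M}, {"t1": target})
        assert len(preds) == 1
        assert not preds[0].passed
        assert preds[0].best_pair_score < 80

    def test_no_seed_site_gives_empty_list(self):
        assert predict_targets({"m1": "UGCGCGCGAAAAAAAAAAA"}, {"t1": "A" * 50}) == []

    def test_id_collision_rejected(self):
        with pytest.raises(ValueError, match="collision"):
            predict_targets({"x": self.M}, {"x": "GGGCAUGCAUAGGG"})

    def test_lenient_thresholds_pass_bare_seed(self):
        target = "CCCCCCCCCCCC" + revcomp(self.M[1:8]) + "A" + "CCCCCCCCCCCC"
        preds = predict_targets({"m1": self.M}, {"t1": target},
                                ScanParams(s_min=30, e_max=-10))
        assert preds[0].passed
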