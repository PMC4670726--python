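import math

import numpy as np
import pytest

from dmotif.io_formats import ProteinRecord, read_tree_string
from dmotif.motif_patterns import class_by_name, default_class_definitions
from dmotif.pssm_model import (
    ALPHABET,
    Background,
    TrainingPeptide,
    build_pssm,
    compute_weights,
    load_model,
    logo_matrix,
    save_model,
    scan_with_pssm,
    score_peptide,
    swissprot_background,
)

LOG2_20 = math.log2(20)


def naive_pssm(groups, background, p):
    """Independent double-loop evaluation of the frequency/score formulas.

    X_i = (sum_s w_s * I(s_i = X) + p * X_b) / (sum_s w_s + p), with the
    within-group weights normalized to 1 so each group has equal weight.
    """
    L = len(next(iter(groups.values()))[0].sequence)
    freqs = {}
    total_w = 0.0
    norm = {}
    for gid, peps in groups.items():
        gw = sum(pep.weight for pep in peps)
        for pep in peps:
            norm[(gid, id(pep))] = pep.weight / gw
            total_w += pep.weight / gw
    for i in range(L):
        for aa in ALPHABET:
            s = 0.0
            for gid, peps in groups.items():
                for pep in peps:
                    if pep.sequence[i] == aa:
                        s += norm[(gid, id(pep))]
            freqs[(i, aa)] = (s + p * background[aa]) / (total_w + p)
    return freqs


def naive_score(freqs, background, peptide):
    return sum(
        math.log2(freqs[(i, aa)] / background[aa]) for i, aa in enumerate(peptide)
    )


class TestWeights:
    def test_single_reference_peptide(self, toy_tree):
        peps = [TrainingPeptide("KRLL", "A", "G1")]
        assert compute_weights(peps, toy_tree, "A") == [1.0]

    def test_equidistant_species_split_evenly(self):
        tree = read_tree_string("(A:1,(B:2,C:2):1);")
        peps = [TrainingPeptide("KRLL", "B", "G1"), TrainingPeptide("KRLL", "C", "G1")]
        assert compute_weights(peps, tree, "A") == [0.5, 0.5]

    def test_distances_one_two_three_normalize(self):
        tree = read_tree_string("(R:0,(A:1,(B:2,C:3):0):0);")
        peps = [TrainingPeptide("K", sp, "G1") for sp in "ABC"]
        w = compute_weights(peps, tree, "R", epsilon=0.0)
        assert np.allclose(w, [1 / 6, 2 / 6, 3 / 6])

    def test_unknown_species_named_in_error(self, toy_tree):
        with pytest.raises(KeyError, match="ZEBRA"):
            compute_weights([TrainingPeptide("K", "ZEBRA", "G")], toy_tree, "A")


class TestBuildPssm:
    def test_single_peptide_no_pseudocount_closed_form(self):
        groups = {"G1": [TrainingPeptide("ACDE", "s", "G1")]}
        model = build_pssm(groups, Background.uniform(), pseudo=0)
        for i, aa in enumerate("ACDE"):
            assert model.frequencies[ALPHABET.index(aa), i] == pytest.approx(1.0)
            assert model.log_odds[ALPHABET.index(aa), i] == pytest.approx(LOG2_20)
        assert score_peptide(model, "ACDE") == pytest.approx(4 * LOG2_20)

    def test_huge_pseudocount_drives_log_odds_to_zero(self):
        groups = {"G1": [TrainingPeptide("ACDE", "s", "G1")]}
        model = build_pssm(groups, swissprot_background(), pseudo=1e9)
        assert np.abs(model.log_odds).max() < 1e-6
        assert abs(score_peptide(model, "WWWW")) < 1e-5

    def test_two_equal_weight_groups_split_column(self):
        groups = {
            "G1": [TrainingPeptide("A", "s1", "G1")],
            "G2": [TrainingPeptide("C", "s2", "G2")],
        }
        model = build_pssm(groups, Background.uniform(), pseudo=0)
        assert model.frequencies[ALPHABET.index("A"), 0] == pytest.approx(0.5)
        assert model.frequencies[ALPHABET.index("C"), 0] == pytest.approx(0.5)

    def test_columns_normalize_for_arbitrary_weights_and_pseudocount(self):
        rng = np.random.default_rng(42)
        for p in (0.0, 0.5, 3.7, "sqrt"):
            groups = {
                f"G{g}": [
                    TrainingPeptide(
                        "".join(rng.choice(list(ALPHABET), size=6)),
                        f"s{g}{j}",
                        f"G{g}",
                        weight=float(rng.uniform(0.1, 5)),
                    )
                    for j in range(int(rng.integers(1, 5)))
                ]
                for g in range(4)
            }
            model = build_pssm(groups, swissprot_background(), pseudo=p)
            assert np.allclose(model.frequencies.sum(axis=0), 1.0, atol=1e-9)

    def test_sqrt_pseudocount_counts_raw_peptides(self):
        groups = {
            "G1": [TrainingPeptide("AA", "s1", "G1"), TrainingPeptide("AC", "s2", "G1")],
            "G2": [TrainingPeptide("CA", "s3", "G2")],
        }
        model = build_pssm(groups)
        assert model.pseudo_count == pytest.approx(math.sqrt(3))

    def test_group_duplication_invariance(self):
        """Duplicating every peptide of one group (weights renormalized
        within the group) leaves the frequencies unchanged."""
        g1 = [TrainingPeptide("AK", "s1", "G1", 2.0), TrainingPeptide("CK", "s2", "G1", 1.0)]
        groups = {"G1": g1, "G2": [TrainingPeptide("AD", "s3", "G2")]}
        doubled = {"G1": g1 + [TrainingPeptide(p.sequence, p.species, p.group_id, p.weight) for p in g1], "G2": groups["G2"]}
        a = build_pssm(groups, Background.uniform(), pseudo=1.0)
        b = build_pssm(doubled, Background.uniform(), pseudo=1.0)
        assert np.allclose(a.frequencies, b.frequencies)

    def test_weight_rescaling_invariance(self):
        g = {
            "G1": [TrainingPeptide("AK", "s1", "G1", 0.3), TrainingPeptide("CK", "s2", "G1", 0.7)]
        }
        scaled = {
            "G1": [TrainingPeptide("AK", "s1", "G1", 3.0), TrainingPeptide("CK", "s2", "G1", 7.0)]
        }
        a = build_pssm(g, swissprot_background(), pseudo=2.0)
        b = build_pssm(scaled, swissprot_background(), pseudo=2.0)
        assert np.allclose(a.log_odds, b.log_odds)

    def test_length_mismatch_rejected(self):
        groups = {"G1": [TrainingPeptide("AC", "s", "G1"), TrainingPeptide("ACD", "t", "G1")]}
        with pytest.raises(ValueError, match="length"):
            build_pssm(groups)

    def test_oracle_equivalence_on_random_instances(self):
        """Frequencies and scores match the double-loop formula evaluation."""
        rng = np.random.default_rng(7)
        bg = swissprot_background()
        for trial in range(20):
            L = int(rng.integers(3, 9))
            groups = {
                f"G{g}": [
                    TrainingPeptide(
                        "".join(rng.choice(list(ALPHABET), size=L)),
                        f"s{g}{j}",
                        f"G{g}",
                        weight=float(rng.uniform(0.05, 4.0)),
                    )
                    for j in range(int(rng.integers(1, 6)))
                ]
                for g in range(int(rng.integers(1, 5)))
            }
            p = float(rng.uniform(0, 5))
            model = build_pssm(groups, bg, pseudo=p)
            expected = naive_pssm(groups, bg, p)
            for i in range(L):
                for aa in ALPHABET:
                    assert model.frequencies[ALPHABET.index(aa), i] == pytest.approx(
                        expected[(i, aa)], abs=1e-9
                    )
            pep = "".join(rng.choice(list(ALPHABET), size=L))
            assert score_peptide(model, pep) == pytest.approx(
                naive_score(expected, bg, pep), abs=1e-9
            )


class TestScoring:
    def test_length_mismatch_rejected(self):
        model = build_pssm({"G1": [TrainingPeptide("ACDE", "s", "G1")]})
        with pytest.raises(ValueError):
            score_peptide(model, "ACDEF")

    def test_scan_ranks_planted_training_peptide_first(self):
        jip1 = class_by_name(default_class_definitions("loose"), "JIP1")
        pep = "RPSSLDL"  # canonical JIP1 geometry: R-phiL(P)-x-x-phiA-x-phiB
        groups = {"G1": [TrainingPeptide(pep, "s", "G1")]}
        model = build_pssm(groups, swissprot_background(), pseudo=1.0)
        records = [
            ProteinRecord("HIT", "GGGGDQG" + pep + "GGDQGG"),
            ProteinRecord("OTH", "GGGGDQG" + "KPAGVGV" + "GGDQGG"),
        ]
        table = scan_with_pssm(model, records, jip1)
        assert table.iloc[0]["protein_id"] == "HIT"
        assert table.iloc[0]["matched_sequence"] == pep

    def test_no_consensus_matches_gives_empty_table(self):
        jip1 = class_by_name(default_class_definitions("loose"), "JIP1")
        model = build_pssm({"G1": [TrainingPeptide("RPSSLDL", "s", "G1")]})
        table = scan_with_pssm(model, [ProteinRecord("A", "GGGGGGGGGG")], jip1)
        assert table.empty

    def test_identical_windows_score_identically(self):
        jip1 = class_by_name(default_class_definitions("loose"), "JIP1")
        model = build_pssm({"G1": [TrainingPeptide("RPSSLDL", "s", "G1")]})
        seq = "GGDQG" + "RPSSLDL" + "GGDQG"
        table = scan_with_pssm(
            model, [ProteinRecord("A", seq), ProteinRecord("B", seq)], jip1
        )
        assert table["score"].nunique() == 1


class TestLogo:
    def test_single_residue_column_with_small_sample_correction(self):
        """A pure column at n=100 has zero entropy, so the information is
        log2(20) minus the small-sample correction 19/(2 ln2 * 100)."""
        model = build_pssm({"G1": [TrainingPeptide("A", "s", "G1")]}, pseudo=0)
        lm = logo_matrix(model, n_peptides=100)
        expected = LOG2_20 - 19.0 / (2.0 * math.log(2.0) * 100)
        assert lm.information[0] == pytest.approx(expected, abs=1e-9)
        assert lm.information[0] == pytest.approx(4.18487, abs=1e-5)
        assert lm.heights[ALPHABET.index("A"), 0] == pytest.approx(expected)

    def test_uniform_column_clamps_to_zero(self):
        groups = {f"G{i}": [TrainingPeptide(aa, f"s{i}", f"G{i}")] for i, aa in enumerate(ALPHABET)}
        model = build_pssm(groups, Background.uniform(), pseudo=0)
        lm = logo_matrix(model, n_peptides=20)
        assert lm.information[0] == 0.0
        assert np.all(lm.heights == 0.0)

    def test_heights_sum_to_information(self):
        rng = np.random.default_rng(3)
        groups = {
            f"G{g}": [
                TrainingPeptide("".join(rng.choice(list(ALPHABET), size=5)), f"s{g}", f"G{g}")
            ]
            for g in range(6)
        }
        model = build_pssm(groups, swissprot_background(), pseudo=0)
        lm = logo_matrix(model)
        assert np.allclose(lm.heights.sum(axis=0), lm.information, atol=1e-9)


def test_model_serialization_round_trip(tmp_path):
    groups = {
        "G1": [TrainingPeptide("KRLLG", "s1", "G1", 0.4), TrainingPeptide("KRILG", "s2", "G1", 0.6)]
    }
    model = build_pssm(groups, swissprot_background(), class_name="JIP1")
    save_model(model, tmp_path / "model")
    back = load_model(tmp_path / "model")
    assert back.length == model.length
    assert np.allclose(back.frequencies, model.frequencies)
    assert np.allclose(back.log_odds, model.log_odds)
    assert back.pseudo_count == model.pseudo_count
    assert back.class_name == "JIP1"
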