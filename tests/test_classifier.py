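import numpy as np
import pytest

import ismvar as iv
from ismvar.classifier import DEGENERATE, variant_spectra
from ismvar.errors import DimensionError, InvalidInputError

from .oracles import spectrum_direct


def toy_spectrum(values):
    values = np.asarray(values, dtype=float)
    n = 2 * values.size
    return iv.InformationalSpectrum(
        frequencies=np.arange(1, values.size + 1) / n,
        amplitudes=values,
        source_length=n,
    )


class TestIsmScores:
    def test_wild_type_against_itself_is_zero(self):
        wt = iv.informational_spectrum(iv.encode_sequence("MKLVAC"))
        matrix = iv.ism_scores(wt, [wt])
        np.testing.assert_allclose(matrix.scores, 0.0, atol=1e-12)

    def test_single_substitution_matches_direct_dft(self):
        wt_seq, variant = "MKLV", iv.parse_variant("K2R")
        mutated = iv.apply_variant(wt_seq, variant)
        wt = iv.informational_spectrum(iv.encode_sequence(wt_seq))
        matrix = iv.ism_scores(wt, variant_spectra(wt_seq, [variant]))
        expected = (spectrum_direct(iv.encode_sequence(mutated))
                    - spectrum_direct(iv.encode_sequence(wt_seq)))
        np.testing.assert_allclose(matrix.scores[0], expected,
                                   rtol=1e-9, atol=1e-12)

    def test_identical_variants_give_identical_rows(self):
        wt_seq = "MKLVACDE"
        v = iv.parse_variant("K2R")
        wt = iv.informational_spectrum(iv.encode_sequence(wt_seq))
        matrix = iv.ism_scores(wt, variant_spectra(wt_seq, [v, v]))
        np.testing.assert_array_equal(matrix.scores[0], matrix.scores[1])

    def test_length_mismatch_rejected(self):
        wt = iv.informational_spectrum(iv.encode_sequence("MKLVAC"))
        other = iv.informational_spectrum(iv.encode_sequence("MKLV"))
        with pytest.raises(DimensionError):
            iv.ism_scores(wt, [other])


class TestSelectFrequency:
    def test_recovers_planted_bin(self, planted_dataset, planted_fit):
        model = planted_fit.model
        assert model is not None
        assert model.frequency_index == planted_dataset.planted_frequency_index
        assert model.p_value < model.alpha
        assert model.frequencies_tested == len(planted_fit.selection.trace)

    def test_selection_matches_exhaustive_per_frequency_oracle(self, planted_fit):
        # oracle: test every column independently, then walk the
        # descending-WT-amplitude order by hand
        wt = planted_fit.wild_type_spectrum
        matrix = planted_fit.score_matrix
        labels = np.asarray(planted_fit.labels)
        order = np.argsort(-wt.amplitudes, kind="stable")
        expected = None
        for col in order:
            _, p = iv.mann_whitney_u(matrix.scores[labels == iv.MUT, col],
                                     matrix.scores[labels == iv.SNP, col])
            if p < 0.05:
                expected = col + 1
                break
        assert planted_fit.model.frequency_index == expected

    def test_alpha_one_selects_top_amplitude_frequency(self, planted_fit):
        wt = planted_fit.wild_type_spectrum
        result = iv.select_frequency(planted_fit.score_matrix, wt,
                                     planted_fit.labels, alpha=1.0)
        assert result.model is not None
        assert result.model.frequencies_tested == 1
        assert result.model.frequency_index == int(wt.amplitudes.argmax()) + 1

    def test_invariant_to_variant_ordering(self, planted_fit, rng):
        wt = planted_fit.wild_type_spectrum
        matrix = planted_fit.score_matrix
        perm = rng.permutation(matrix.n_variants)
        shuffled = iv.ISMScoreMatrix(
            scores=matrix.scores[perm],
            variant_ids=tuple(matrix.variant_ids[i] for i in perm),
            frequencies=matrix.frequencies,
        )
        labels = [planted_fit.labels[i] for i in perm]
        result = iv.select_frequency(shuffled, wt, labels)
        assert result.model.frequency_index == planted_fit.model.frequency_index
        assert result.model.p_value == pytest.approx(planted_fit.model.p_value)

    def test_search_visits_all_columns_when_nothing_significant(self):
        rng = np.random.default_rng(3)
        wt = toy_spectrum(rng.uniform(1, 2, size=12))
        scores = rng.normal(size=(10, 12))
        matrix = iv.ISMScoreMatrix(
            scores=scores, variant_ids=tuple(f"v{i}" for i in range(10)),
            frequencies=wt.frequencies)
        labels = [iv.MUT] * 5 + [iv.SNP] * 5
        result = iv.select_frequency(matrix, wt, labels, alpha=1e-9)
        assert result.model is None
        visited = [e.frequency_index for e in result.trace]
        assert sorted(visited) == list(range(1, 13))
        # strictly descending wild-type amplitude along the trace
        amps = [e.wt_amplitude for e in result.trace]
        assert all(x >= y for x, y in zip(amps, amps[1:]))

    def test_equal_amplitudes_visited_in_ascending_frequency_order(self):
        wt = toy_spectrum([1.0, 1.0, 2.0, 1.0])
        matrix = iv.ISMScoreMatrix(
            scores=np.zeros((4, 4)), variant_ids=("a", "b", "c", "d"),
            frequencies=wt.frequencies)
        result = iv.select_frequency(matrix, wt,
                                     [iv.MUT, iv.MUT, iv.SNP, iv.SNP],
                                     alpha=1e-9)
        assert [e.frequency_index for e in result.trace] == [3, 1, 2, 4]

    def test_single_class_rejected(self, planted_fit):
        with pytest.raises(InvalidInputError):
            iv.select_frequency(planted_fit.score_matrix,
                                planted_fit.wild_type_spectrum,
                                [iv.MUT] * len(planted_fit.labels))


class TestClassifyAndOrientation:
    @pytest.fixture()
    def model(self):
        return iv.ClassifierModel(
            frequency_index=3, frequency=0.3, cutoff_amplitude=2.0,
            orientation=+1, p_value=0.01, alpha=0.05, frequencies_tested=3)

    def test_tie_with_cutoff_is_snp(self, model):
        assert iv.classify(2.0, model) == iv.SNP

    def test_positive_orientation_above_cutoff_is_mut(self, model):
        assert iv.classify(2.5, model) == iv.MUT

    def test_negative_orientation_above_cutoff_is_snp(self, model):
        flipped = iv.ClassifierModel(
            frequency_index=3, frequency=0.3, cutoff_amplitude=2.0,
            orientation=-1, p_value=0.01, alpha=0.05, frequencies_tested=3)
        assert iv.classify(2.5, flipped) == iv.SNP
        assert iv.classify(1.5, flipped) == iv.MUT

    @pytest.mark.parametrize("raw,expected", [(0.37473, -0.37473),
                                              (-0.24349, 0.24349)])
    def test_negative_orientation_flips_score_scale(self, raw, expected):
        flipped = iv.ClassifierModel(
            frequency_index=3, frequency=0.3, cutoff_amplitude=2.0,
            orientation=-1, p_value=0.01, alpha=0.05, frequencies_tested=3)
        assert iv.oriented_score(raw, flipped) == pytest.approx(expected)

    def test_positive_orientation_leaves_score_unchanged(self, model):
        assert iv.oriented_score(0.123, model) == pytest.approx(0.123)

    def test_training_calls_agree_with_oriented_score_sign(self, planted_fit):
        predicted = planted_fit.predicted_labels()
        oriented = planted_fit.oriented_scores()
        for call, score in zip(predicted, oriented):
            assert call == (iv.MUT if score > 0 else iv.SNP)

    def test_model_file_round_trip(self, tmp_path, planted_fit):
        path = tmp_path / "model.tsv"
        model = planted_fit.model
        model.save(path)
        loaded = iv.ClassifierModel.load(path)
        assert loaded.frequency_index == model.frequency_index
        assert loaded.cutoff_amplitude == pytest.approx(model.cutoff_amplitude)
        assert loaded.orientation == model.orientation


class TestCrossValidation:
    def test_all_folds_recover_planted_bin(self):
        ds = iv.generate_planted_dataset(length=300, planted_frequency_index=143,
                                         seed=7)
        folds = iv.cross_validate_frequency(ds.wild_type, list(ds.variants),
                                            k=5, seed=7)
        assert folds == [143] * 5

    def test_two_variants_give_degenerate_splits(self):
        ds = iv.generate_planted_dataset(seed=3)
        tiny = [ds.variants[0], ds.variants[-1]]  # one MUT, one SNP
        folds = iv.cross_validate_frequency(ds.wild_type, tiny, k=5, seed=0)
        assert DEGENERATE in folds

    def test_deterministic_given_seed(self):
        ds = iv.generate_planted_dataset(seed=11)
        a = iv.cross_validate_frequency(ds.wild_type, list(ds.variants),
                                        k=5, seed=5)
        b = iv.cross_validate_frequency(ds.wild_type, list(ds.variants),
                                        k=5, seed=5)
        assert a == b
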