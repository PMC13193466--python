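"""Normalization steps: arithmetic examples, invariants, order enforcement."""

import numpy as np
import pandas as pd
import pytest

import mirtraject as mt
from mirtraject.errors import NormalizationError, StageError
from mirtraject.normalize import background_correct, content_normalize


def make_matrix(values: dict, classes: dict) -> mt.CountMatrix:
    frame = pd.DataFrame(values).T  # rows = probes
    return mt.CountMatrix(frame.astype(float), pd.Series(classes))


class TestBackground:
    def test_direct_arithmetic(self):
        matrix = make_matrix(
            {"m1": [100], "m2": [30], "m3": [5], "NEG_A": [5]},
            {"m1": "Endogenous", "m2": "Endogenous", "m3": "Endogenous",
             "NEG_A": "Negative"},
        )
        out, bg = background_correct(matrix)
        assert bg.iloc[0] == 5.0
        assert list(out.values.loc[["m1", "m2", "m3"], out.sample_ids[0]]) == [
            95.0, 25.0, 0.0,
        ]

    def test_zero_negatives_noop(self):
        matrix = make_matrix(
            {"m1": [100, 7], "NEG_A": [0, 0]},
            {"m1": "Endogenous", "NEG_A": "Negative"},
        )
        out, _ = background_correct(matrix)
        assert (out.values.loc["m1"] == [100.0, 7.0]).all()

    def test_floor_at_zero(self):
        matrix = make_matrix(
            {"m1": [3], "NEG_A": [3]},
            {"m1": "Endogenous", "NEG_A": "Negative"},
        )
        out, _ = background_correct(matrix)
        assert out.values.loc["m1"].iloc[0] == 0.0

    def test_double_application_is_stage_error(self):
        matrix = make_matrix(
            {"m1": [10], "NEG_A": [1]},
            {"m1": "Endogenous", "NEG_A": "Negative"},
        )
        out, _ = background_correct(matrix)
        with pytest.raises(StageError):
            background_correct(out)


SPIKES = dict.fromkeys(mt.NormalizationConfig().spike_ids, "SpikeIn")


class TestSpikein:
    def _matrix(self, spike_means, endo):
        values = {}
        classes = {}
        for i, pid in enumerate(SPIKES):
            values[pid] = [m for m in spike_means]
            classes[pid] = "SpikeIn"
        values["m1"] = endo
        classes["m1"] = "Endogenous"
        return make_matrix(values, classes)

    def test_two_sample_worked_example(self):
        # spike means 10 and 40 -> geometric-mean reference 20, factors 2.0/0.5
        matrix = self._matrix([10, 40], [12, 100])
        out, factors = mt.spikein_normalize(matrix)
        assert factors.tolist() == pytest.approx([2.0, 0.5])
        assert out.values.loc["m1"].tolist() == pytest.approx([24.0, 50.0])

    def test_identical_spike_means_noop(self):
        matrix = self._matrix([30, 30, 30], [5, 6, 7])
        out, factors = mt.spikein_normalize(matrix)
        assert (factors == 1.0).all()
        assert out.values.equals(matrix.values)

    def test_zero_spike_mean_names_sample(self):
        matrix = self._matrix([10, 0], [1, 1])
        with pytest.raises(NormalizationError, match="zero mean spike"):
            mt.spikein_normalize(matrix)


class TestContent:
    def test_two_sample_worked_example(self):
        # content geometric means 8 and 32 -> reference 16, factors 2.0/0.5
        values = {"a": [4, 16], "b": [16, 64]}
        classes = {"a": "Endogenous", "b": "Endogenous"}
        matrix = make_matrix(values, classes)
        out, factors, content_ids = content_normalize(matrix, content_set_size=2)
        assert sorted(content_ids) == ["a", "b"]
        assert factors.tolist() == pytest.approx([2.0, 0.5])

    def test_identical_samples_unit_factors(self):
        matrix = make_matrix(
            {"a": [4, 4], "b": [16, 16]},
            {"a": "Endogenous", "b": "Endogenous"},
        )
        _, factors, _ = content_normalize(matrix)
        assert (factors == 1.0).all()

    def test_hemolysis_probes_never_in_content_set(self, small_cohort):
        _, matrix, _ = small_cohort
        m, _ = background_correct(matrix)
        m, _ = mt.spikein_normalize(m)
        _, _, content_ids = content_normalize(m)
        assert len(content_ids) == 50
        assert not set(content_ids) & set(mt.HEMOLYSIS_PROBES)


class TestQuantile:
    def test_rank_mean_by_hand(self):
        matrix = make_matrix(
            {"a": [1, 4], "b": [2, 5], "c": [3, 6]},
            dict.fromkeys("abc", "Endogenous"),
        )
        out = mt.quantile_normalize(matrix)
        assert out.values["s1" if "s1" in out.sample_ids else out.sample_ids[0]].tolist() == pytest.approx([2.5, 3.5, 4.5])
        assert out.values[out.sample_ids[1]].tolist() == pytest.approx([2.5, 3.5, 4.5])

    def test_identical_samples_unchanged(self):
        matrix = make_matrix(
            {"a": [3, 3], "b": [1, 1], "c": [9, 9]},
            dict.fromkeys("abc", "Endogenous"),
        )
        out = mt.quantile_normalize(matrix)
        pd.testing.assert_frame_equal(out.values, matrix.values)

    def test_sorted_vectors_identical_after(self):
        """Tie-free samples end with exactly identical sorted vectors.

        (With ties the tie-averaging rule intentionally replaces tied order
        statistics by their spanned mean, so the invariant is stated for
        tie-free data.)
        """
        rng = np.random.default_rng(0)
        data = rng.lognormal(4.0, 1.0, size=(40, 6))
        matrix = mt.CountMatrix(
            pd.DataFrame(data, index=[f"m{i}" for i in range(40)],
                         columns=[f"s{j}" for j in range(6)]),
            pd.Series("Endogenous", index=[f"m{i}" for i in range(40)]),
        )
        out = mt.quantile_normalize(matrix)
        sorted_cols = np.sort(out.values.to_numpy(), axis=0)
        assert (sorted_cols == sorted_cols[:, [0]]).all()

    def test_ties_get_mean_of_spanned_values(self):
        matrix = make_matrix(
            {"a": [1, 10], "b": [1, 20], "c": [5, 30]},
            dict.fromkeys("abc", "Endogenous"),
        )
        out = mt.quantile_normalize(matrix)
        col = out.values[out.sample_ids[0]]
        # reference distribution is (5.5, 10.5, 17.5); the tied pair spans
        # ranks 1 and 2 -> both get (5.5 + 10.5)/2
        assert col.loc["a"] == col.loc["b"] == pytest.approx(8.0)
        assert col.loc["c"] == pytest.approx(17.5)

    def test_single_sample_warns_noop(self):
        matrix = make_matrix(
            {"a": [1], "b": [2]}, {"a": "Endogenous", "b": "Endogenous"}
        )
        with pytest.warns(UserWarning):
            out = mt.quantile_normalize(matrix)
        assert out.values.equals(matrix.values)


class TestPipeline:
    def test_stage_tags_full_chain(self, small_normed):
        _, normed, _ = small_normed
        assert normed.stages == (
            "raw", "background", "spikein", "content", "quantile"
        )

    def test_quantile_can_be_disabled(self, small_cohort):
        _, matrix, _ = small_cohort
        cfg = mt.NormalizationConfig(enable_quantile=False)
        out, _ = mt.normalize_pipeline(matrix.copy(), cfg)
        assert out.stages == ("raw", "background", "spikein", "content")

    def test_factors_invert_true_efficiency(self, small_cohort):
        """Spike factors recover 1/e_s; the full product stays strongly
        anti-correlated (content noise over 50 probes dilutes it a little)."""
        _, matrix, truth = small_cohort
        _, factors = mt.normalize_pipeline(matrix.copy())
        log_e = np.log(pd.Series(truth.efficiency))
        spike = np.log(pd.Series(factors.spike_factor))
        r_spike = np.corrcoef(spike, log_e.loc[spike.index])[0, 1]
        assert r_spike <= -0.9
        product = spike + np.log(pd.Series(factors.content_factor))
        r_prod = np.corrcoef(product, log_e.loc[product.index])[0, 1]
        assert r_prod <= -0.75

    def test_no_negative_values_any_stage(self, small_cohort):
        _, matrix, _ = small_cohort
        m, _ = background_correct(matrix)
        assert (m.values.to_numpy() >= 0).all()
        m, _ = mt.spikein_normalize(m)
        assert (m.values.to_numpy() >= 0).all()
        m, _, _ = content_normalize(m)
        assert (m.values.to_numpy() >= 0).all()
        m = mt.quantile_normalize(m)
        assert (m.values.to_numpy() >= 0).all()


class TestScaleInvariance:
    def test_single_sample_rescaling_preserves_all_contrasts(self, small_cohort):
        """Scaling one sample's raw counts by c leaves every between-sample
        contrast unchanged: normalized matrices agree up to one global
        constant (c**(1/n), from the geometric-mean reference), so ratios,
        ranks and case/control log-ratios are exactly invariant.  Stated for
        the zero-background case: with no background floor and no zero
        counts the identity is exact (the 0.5 pseudo-value used for zeros in
        the content geometric mean does not rescale)."""
        _, raw, _ = small_cohort
        values = raw.values.copy()
        target = raw.probe_class.isin(["Endogenous", "SpikeIn"]).to_numpy()
        values.loc[target] += 1.0  # no zero counts
        values.loc[(raw.probe_class == "Negative").to_numpy()] = 0.0
        matrix = mt.CountMatrix(values, raw.probe_class, raw.accession,
                                raw.stages)
        sample = matrix.sample_ids[3]
        scaled_values = matrix.values.copy()
        scaled_values[sample] *= 7.0
        scaled = mt.CountMatrix(
            scaled_values, matrix.probe_class, matrix.accession, matrix.stages
        )
        cfg = mt.NormalizationConfig(enable_quantile=False)
        base, _ = mt.normalize_pipeline(matrix.copy(), cfg)
        pert, _ = mt.normalize_pipeline(scaled, cfg)
        b = base.endogenous.to_numpy()
        p = pert.endogenous.to_numpy()
        mask = b > 0
        ratios = p[mask] / b[mask]
        # single global constant across the whole matrix
        assert ratios.max() - ratios.min() < 1e-9
        # background floor: zeros stay zeros
        assert ((b == 0) == (p == 0)).all()
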