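"""Stage-contrast pipeline: normalization, NB test, classes, ΔΔCt."""

import numpy as np
import pandas as pd
import pytest

from testisscreen.de import (
    classify_expression,
    ddct_quantity,
    nb_stage_test,
    size_factors,
)
from testisscreen.simulate import generate_counts
from testisscreen.tables import CountMatrix, CtTable

CONDITIONS = {
    "s1": "stage1", "s2": "stage1", "s3": "stage1",
    "s4": "stage2", "s5": "stage2", "s6": "stage2",
}


def _matrix(data, genes=None):
    arr = np.asarray(data)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    return CountMatrix(
        counts=pd.DataFrame(arr, index=genes, columns=list(CONDITIONS)),
        conditions=dict(CONDITIONS),
    )


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        cm = _matrix(np.tile([[10], [20], [5]], (1, 6)))
        assert size_factors(cm).to_numpy() == pytest.approx([1.0] * 6)

    def test_doubled_sample_gets_factor_two(self):
        rng = np.random.default_rng(0)
        base = rng.integers(5, 100, size=(200, 1))
        data = np.tile(base, (1, 6))
        data[:, 3] *= 2
        factors = size_factors(_matrix(data))
        assert factors.iloc[3] == pytest.approx(
            2.0 * factors.iloc[0], rel=0.05
        )

    def test_gene_order_invariant(self):
        rng = np.random.default_rng(1)
        data = rng.integers(1, 500, size=(100, 6))
        cm = _matrix(data)
        perm = rng.permutation(100)
        cm_perm = _matrix(data[perm], genes=[f"g{i}" for i in perm])
        assert size_factors(cm).to_numpy() == pytest.approx(
            size_factors(cm_perm).to_numpy()
        )

    def test_all_zero_rows_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            size_factors(_matrix(np.zeros((3, 6), dtype=int)))

    def test_matches_deseq2_median_of_ratios(self):
        pydeseq2 = pytest.importorskip("pydeseq2.preprocessing")
        rng = np.random.default_rng(2)
        data = rng.negative_binomial(10, 0.1, size=(300, 6))
        data[0] = np.maximum(data[0], 1)  # keep one all-nonzero gene
        _, ref = pydeseq2.deseq2_norm(pd.DataFrame(data.T))
        assert size_factors(_matrix(data)).to_numpy() == pytest.approx(
            np.asarray(ref), rel=1e-6
        )


class TestNbStageTest:
    def test_flat_gene_is_unchanged(self):
        data = np.tile([[50], [10]], (1, 6))
        res = nb_stage_test(_matrix(data))
        assert res.loc["g0", "log2fc"] == pytest.approx(0.0)
        assert res.loc["g0", "modulation"] == "unchanged"

    def test_scale_invariance(self):
        cm, _ = generate_counts(
            400, de_fraction=0.1, log2fc=2.0, dispersion=0.05, reps=3, seed=9
        )
        doubled = CountMatrix(counts=cm.counts * 2, conditions=cm.conditions)
        res1 = nb_stage_test(cm)
        res2 = nb_stage_test(doubled)
        # fold changes agree up to the (fixed) pseudocount's diminishing
        # weight; modulation calls are identical
        assert res1["log2fc"].to_numpy() == pytest.approx(
            res2["log2fc"].to_numpy(), abs=0.05
        )
        assert (res1["modulation"] == res2["modulation"]).all()

    def test_up_plus_down_equals_modulated(self):
        cm, _ = generate_counts(
            500, de_fraction=0.2, log2fc=2.0, dispersion=0.05, reps=3, seed=4
        )
        res = nb_stage_test(cm)
        n_up = (res["modulation"] == "up").sum()
        n_down = (res["modulation"] == "down").sum()
        assert n_up + n_down == (res["modulation"] != "unchanged").sum()
        assert (res.loc[res["modulation"] == "up", "log2fc"] > 0).all()
        assert (res.loc[res["modulation"] == "down", "log2fc"] < 0).all()

    def test_planted_signs_recovered(self):
        cm, truth = generate_counts(
            2000, de_fraction=0.05, log2fc=2.0, dispersion=0.05, reps=3,
            seed=11, mean=500.0,
        )
        res = nb_stage_test(cm)
        planted = {g: v for g, v in truth.items() if not g.startswith("__")}
        detected = [
            g for g in planted if res.loc[g, "modulation"] != "unchanged"
        ]
        assert detected, "no planted gene detected at all"
        correct = sum(
            1 for g in detected
            if np.sign(res.loc[g, "log2fc"]) == np.sign(planted[g])
        )
        assert correct / len(detected) >= 0.95

    def test_low_expression_genes_not_tested(self):
        data = np.tile([[0], [500]], (1, 6))
        data[0, 2] = 1  # nearly silent gene
        res = nb_stage_test(_matrix(data), min_base_mean=1.0)
        assert not res.loc["g0", "tested"]
        assert np.isnan(res.loc["g0", "p_raw"])
        assert res.loc["g0", "modulation"] == "unchanged"


class TestClassifyExpression:
    def test_all_zero_gene_is_unexpressed_very_low(self):
        data = np.vstack(
            [np.zeros(6, dtype=int), np.full(6, 500), np.full(6, 50)]
        )
        res = classify_expression(_matrix(data), floor=5.0)
        assert not res.loc["g0", "expressed_both"]
        assert res.loc["g0", "level_class"] == "very low"

    def test_floor_zero_makes_everything_expressed(self):
        data = np.vstack([np.zeros(6, dtype=int), np.full(6, 50)])
        res = classify_expression(_matrix(data), floor=0.0)
        assert res["expressed_both"].all()

    def test_raising_floor_shrinks_expressed_set(self):
        cm, _ = generate_counts(
            300, de_fraction=0.0, log2fc=0.0, dispersion=0.05, reps=3, seed=2
        )
        previous = None
        for floor in (0.0, 1.0, 5.0, 20.0, 100.0):
            expressed = set(
                classify_expression(cm, floor=floor)
                .query("expressed_both").index
            )
            if previous is not None:
                assert expressed <= previous
            previous = expressed

    def test_explicit_cutpoints(self):
        data = np.vstack([np.full(6, v) for v in (1, 20, 60, 200, 900)])
        res = classify_expression(
            _matrix(data), floor=0.0, cutpoints=(10, 50, 100, 500)
        )
        assert list(res["level_class"]) == [
            "very low", "low", "moderate", "high", "very high"
        ]


class TestDdct:
    def _table(self):
        ct = pd.DataFrame(
            {
                "rpl6": [18.0, 18.5],
                "rpl7": [19.0, 19.5],
                "tgt": [24.0, 23.5],
            },
            index=["white", "red_eye"],
        )
        return CtTable(
            ct=ct, reference_genes=("rpl6", "rpl7"),
            calibrator_sample="white",
        )

    def test_calibrator_quantity_is_one(self):
        q = ddct_quantity(self._table())
        assert q.loc["white", "tgt"] == pytest.approx(1.0)

    def test_one_cycle_lower_doubles_quantity(self):
        # red_eye: refs shifted +0.5, target shifted -0.5 => ΔΔCt = -1
        q = ddct_quantity(self._table())
        assert q.loc["red_eye", "tgt"] == pytest.approx(2.0)

    def test_reference_shift_cancels(self):
        table = self._table()
        shifted = table.ct.copy()
        shifted.loc["red_eye"] += 1.0  # refs and target together
        q0 = ddct_quantity(table)
        q1 = ddct_quantity(
            CtTable(ct=shifted, reference_genes=("rpl6", "rpl7"),
                    calibrator_sample="white")
        )
        assert q1.loc["red_eye", "tgt"] == pytest.approx(
            q0.loc["red_eye", "tgt"]
        )

    def test_missing_reference_rejected(self):
        ct = pd.DataFrame(
            {"rpl6": [18.0, np.nan], "tgt": [24.0, 23.0]},
            index=["white", "red_eye"],
        )
        with pytest.raises(ValueError, match="rpl6"):
            CtTable(ct=ct, reference_genes=("rpl6",),
                    calibrator_sample="white")

    def test_bundle_truth_recovered(self, small_bundle):
        q = ddct_quantity(small_bundle.ct_table)
        for gene, per_sample in small_bundle.manifest.ct_true_quantity.items():
            for sample, expected in per_sample.items():
                assert q.loc[sample, gene] == pytest.approx(
                    expected, rel=1e-9
                )
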