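"""QCD and ICC statistics, threshold taxonomy, robust-feature selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import _reference as ref
from radrepro import classify_icc, classify_qcd, icc_two_way, pairwise_icc, qcd, select_robust
from radrepro.reliability import FeatureTable, arm_qcd, count_meeting


class TestQcd:
    def test_constant_positive_values(self):
        assert qcd([5.0] * 6) == 0.0

    def test_hand_quantiles(self):
        assert qcd([10, 20, 30, 40, 50]) == pytest.approx(100.0 / 3.0)

    def test_undefined_when_quartiles_cancel(self):
        assert qcd([-5.0, -1.0, 1.0, 5.0]) is None

    def test_requires_two_values(self):
        with pytest.raises(ValueError):
            qcd([1.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        x=arrays(np.float64, st.integers(3, 20), elements=st.floats(0.1, 1e3)),
        c=st.floats(0.01, 100.0),
    )
    def test_scale_invariance_positive_data(self, x, c):
        q = qcd(x)
        if q is not None:
            assert qcd(c * x) == pytest.approx(q, rel=1e-9, abs=1e-9)


class TestIcc:
    def test_hand_example_eight_ninths(self):
        icc, anova = icc_two_way([[1, 2], [3, 4], [5, 6]])
        assert anova.ms_rows == pytest.approx(8.0)
        assert anova.ms_cols == pytest.approx(1.5)
        assert anova.ms_error == pytest.approx(0.0, abs=1e-12)
        assert icc == pytest.approx(8.0 / 9.0)

    def test_identical_raters_give_one(self):
        col = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        icc, _ = icc_two_way(np.column_stack([col, col]))
        assert icc == pytest.approx(1.0)

    def test_constant_matrix_undefined(self):
        icc, _ = icc_two_way(np.full((4, 2), 3.0))
        assert icc is None

    def test_bruteforce_oracle_on_random_matrices(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 12))
            k = int(rng.integers(2, 5))
            m = rng.normal(size=(n, k)) * rng.uniform(0.5, 10)
            icc, _ = icc_two_way(m)
            assert icc == pytest.approx(ref.icc_bruteforce(m), abs=1e-10)

    def test_agrees_with_pingouin_icc2(self, rng):
        pingouin = pytest.importorskip("pingouin")
        for _ in range(5):
            m = rng.normal(size=(10, 3)) + rng.normal(size=(10, 1))
            icc, _ = icc_two_way(m)
            df = pd.DataFrame(
                {
                    "targets": np.repeat(np.arange(10), 3),
                    "raters": np.tile(np.arange(3), 10),
                    "scores": m.ravel(),
                }
            )
            table = pingouin.intraclass_corr(
                df, targets="targets", raters="raters", ratings="scores"
            )
            sel = table.Type.isin(["ICC2", "ICC(A,1)"])
            want = float(table.loc[sel, "ICC"].iloc[0])
            assert icc == pytest.approx(want, abs=1e-8)

    def test_null_reliability_near_zero(self, rng):
        m = rng.normal(size=(200, 2))
        icc, _ = icc_two_way(m)
        assert abs(icc) < 0.15

    def test_variance_component_recovery(self, rng):
        sigma_s, sigma_r, sigma_e = 1.0, 0.3, 0.5
        n, k = 500, 2
        ests = []
        for _ in range(10):
            subj = rng.normal(0, sigma_s, size=(n, 1))
            rater = rng.normal(0, sigma_r, size=(1, k))
            err = rng.normal(0, sigma_e, size=(n, k))
            icc, _ = icc_two_way(subj + rater + err)
            ests.append(icc)
        truth = sigma_s**2 / (sigma_s**2 + sigma_r**2 + sigma_e**2)
        assert np.mean(ests) == pytest.approx(truth, abs=0.03)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        m=arrays(np.float64, (5, 2), elements=st.floats(-50, 50)),
        shift=st.floats(-100, 100),
    )
    def test_rater_swap_and_shift_invariance(self, m, shift):
        base, _ = icc_two_way(m)
        if base is None:
            return
        swapped, _ = icc_two_way(m[:, ::-1])
        shifted, _ = icc_two_way(m + shift)
        assert swapped == pytest.approx(base, rel=1e-9, abs=1e-9)
        assert shifted == pytest.approx(base, rel=1e-6, abs=1e-6)


class TestThresholds:
    @pytest.mark.parametrize(
        "icc,cls",
        [
            (0.39999, "poor"),
            (0.4, "fair"),
            (0.59, "fair"),
            (0.6, "good"),
            (0.74, "good"),
            (0.75, "excellent"),
            (1.0, "excellent"),
            (None, "undefined"),
        ],
    )
    def test_icc_taxonomy(self, icc, cls):
        assert classify_icc(icc) == cls

    @pytest.mark.parametrize(
        "q,cls",
        [
            (9.99, "small"),
            (10.0, "intermediate"),
            (19.99, "intermediate"),
            (20.0, "large"),
            (None, "undefined"),
        ],
    )
    def test_qcd_taxonomy(self, q, cls):
        assert classify_qcd(q) == cls

    def test_qcd_inclusive_switch(self):
        assert classify_qcd(10.0, inclusive_small=True) == "small"


def _tables(values_by_arm, tissue="tumor"):
    return [
        FeatureTable(arm=arm, tissue=tissue, data=pd.DataFrame(vals))
        for arm, vals in values_by_arm.items()
    ]


class TestPairwise:
    def test_identical_arms_all_ones(self, rng):
        base = pd.DataFrame(rng.normal(size=(6, 3)), columns=list("abc"))
        tables = [
            FeatureTable(arm=f"MR{i}", tissue="tumor", data=base.copy()) for i in (1, 2, 3, 4)
        ]
        records = pairwise_icc(tables)
        assert len(records) == 3 * 6
        assert all(r.icc == pytest.approx(1.0) for r in records)

    def test_six_labels_and_intra_flags(self, rng):
        tables = [
            FeatureTable(
                arm=f"MR{i}", tissue="tumor", data=pd.DataFrame(rng.normal(size=(5, 1)), columns=["f"])
            )
            for i in (1, 2, 3, 4)
        ]
        records = pairwise_icc(tables)
        flags = {r.comparison: r.intra_observer for r in records}
        assert set(flags) == {
            "MR1/MR2",
            "MR1/MR3",
            "MR1/MR4",
            "MR2/MR3",
            "MR2/MR4",
            "MR3/MR4",
        }
        assert flags["MR1/MR2"] and flags["MR3/MR4"]
        assert not any(flags[c] for c in ("MR1/MR3", "MR1/MR4", "MR2/MR3", "MR2/MR4"))

    def test_subject_mismatch_reported(self, rng):
        t1 = FeatureTable(
            "MR1", "tumor", pd.DataFrame(rng.normal(size=(4, 1)), columns=["f"], index=[1, 2, 3, 4])
        )
        t2 = FeatureTable(
            "MR2", "tumor", pd.DataFrame(rng.normal(size=(4, 1)), columns=["f"], index=[1, 2, 3, 5])
        )
        with pytest.raises(ValueError, match="subject sets differ"):
            pairwise_icc([t1, t2])


class TestCountsAndSelection:
    def test_identical_arms_count_everything(self, rng):
        base = pd.DataFrame(
            rng.uniform(10, 11, size=(6, 4)), columns=list("abcd")
        )
        tables = [
            FeatureTable(f"MR{i}", "tumor", base.copy()) for i in (1, 2, 3, 4)
        ]
        records = pairwise_icc(tables)
        qcd_tab = pd.concat([arm_qcd(t) for t in tables], ignore_index=True)
        counts = count_meeting(records, qcd_tab)
        assert all(v == 4 for v in counts["icc"].values())
        assert all(v == 4 for v in counts["qcd"].values())

    def test_impossible_threshold_counts_zero(self, rng):
        base = pd.DataFrame(rng.normal(size=(6, 2)), columns=list("ab"))
        tables = [FeatureTable(f"MR{i}", "tumor", base.copy()) for i in (1, 2)]
        counts = count_meeting(pairwise_icc(tables), icc_threshold=1.01)
        assert all(v == 0 for v in counts["icc"].values())

    def test_one_failing_pair_excludes_feature(self, rng):
        base = pd.DataFrame(rng.uniform(10, 12, size=(8, 2)), columns=["good", "bad"])
        arms = {}
        for i in (1, 2, 3, 4):
            df = base.copy()
            if i == 4:  # destroy agreement of 'bad' in one arm only
                df["bad"] = rng.uniform(10, 12, size=8)
            arms[f"MR{i}"] = df
        tables = [FeatureTable(a, "tumor", d) for a, d in arms.items()]
        records = pairwise_icc(tables)
        qcd_tab = pd.concat([arm_qcd(t) for t in tables], ignore_index=True)
        robust = select_robust(records, records, qcd_tab, qcd_tab)
        assert "good" in robust and "bad" not in robust

    def test_undefined_qcd_never_small(self):
        # symmetric-about-zero feature: quartiles cancel, QCD undefined
        df = pd.DataFrame({"skew": [-5.0, -1.0, 1.0, 5.0]})
        table = FeatureTable("MR1", "tumor", df)
        out = arm_qcd(table)
        assert out.loc[0, "qcd_class"] == "undefined"
        assert np.isnan(out.loc[0, "qcd"])
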