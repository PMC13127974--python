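"""Merging, QC filtering, winsorization, scaling and splitting contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pkmt import preprocess as prep


class TestMerge:
    def test_whitespace_stripped_keys_join(self):
        cl = pd.DataFrame({"name": ["drug A"], "smiles": ["CCO"],
                           "human_CL_mL_min_kg": [3.0]})
        vd = pd.DataFrame({"name": ["drugA "], "smiles": ["CCO"],
                           "human_VDss_L_kg": [0.7]})
        out = prep.merge_cl_vd(cl, vd)
        assert len(out) == 1
        assert out.loc[0, "human_CL_mL_min_kg"] == 3.0
        assert out.loc[0, "human_VDss_L_kg"] == 0.7

    def test_cl_only_keeps_missing_vd(self):
        cl = pd.DataFrame({"name": ["a"], "smiles": ["CCO"],
                           "human_CL_mL_min_kg": [3.0]})
        out = prep.merge_cl_vd(cl, pd.DataFrame())
        assert len(out) == 1
        assert "human_VDss_L_kg" not in out.columns or out["human_VDss_L_kg"].isna().all()

    def test_duplicate_key_raises(self):
        cl = pd.DataFrame({"name": ["a", "a "], "smiles": ["CCO", "C CO"],
                           "human_CL_mL_min_kg": [3.0, 4.0]})
        with pytest.raises(ValueError, match="duplicate"):
            prep.merge_cl_vd(cl, pd.DataFrame())

    def test_neither_target_dropped(self):
        cl = pd.DataFrame({"name": ["a", "b"], "smiles": ["CCO", "CCN"],
                           "human_CL_mL_min_kg": [3.0, np.nan]})
        out = prep.merge_cl_vd(cl, pd.DataFrame())
        assert list(out["name"]) == ["a"]


class TestPhysiologicalFilter:
    @pytest.mark.parametrize("cl,vd,removed", [
        (25.0, 1.0, True),      # CL above bound
        (19.9, 4.9, False),     # strictly below both
        (20.0, 1.0, True),      # inclusive bound
        (3.0, 5.0, True),       # VD inclusive bound
        (np.nan, 4.9, False),   # missing target cannot trigger removal
    ])
    def test_bounds(self, cl, vd, removed):
        df = pd.DataFrame({"human_CL_mL_min_kg": [cl], "human_VDss_L_kg": [vd]})
        kept, n = prep.filter_physiological(df)
        assert (len(kept) == 0) == removed
        assert n == int(removed)

    def test_idempotent(self, small_dataset):
        once, n1 = prep.filter_physiological(small_dataset.table)
        twice, n2 = prep.filter_physiological(once)
        assert n2 == 0
        assert once.equals(twice)


class TestWinsorize:
    def test_matches_percentile_oracle(self):
        vals = pd.Series(np.arange(1.0, 101.0))
        out = prep.winsorize(vals)
        lo, hi = np.percentile(vals, [1, 99])  # independent quantile oracle
        assert out.min() == pytest.approx(lo)
        assert out.max() == pytest.approx(hi)
        interior = (vals > lo) & (vals < hi)
        assert (out[interior] == vals[interior]).all()

    def test_constant_column_unchanged(self):
        vals = pd.Series([2.0] * 10)
        assert prep.winsorize(vals).equals(vals)

    def test_single_value_unchanged(self):
        vals = pd.Series([5.0, np.nan, np.nan])
        out = prep.winsorize(vals)
        assert out[0] == 5.0
        assert out.isna().sum() == 2

    def test_all_missing_warns(self):
        with pytest.warns(UserWarning):
            out = prep.winsorize(pd.Series([np.nan, np.nan]))
        assert out.isna().all()


class TestScaler:
    def test_roundtrip_exact(self, rng):
        df = pd.DataFrame({
            "human_CL_mL_min_kg": rng.lognormal(1, 0.5, 50),
            "rat_CL_mL_min_kg": rng.lognormal(1.5, 0.5, 50),
            "pKa_Acid": rng.uniform(0, 14, 50),
        })
        sc = prep.PKColumnScaler().fit(df)
        back = sc.inverse_transform(sc.transform(df))
        for c in df.columns:
            np.testing.assert_allclose(back[c], df[c], atol=1e-10)

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(min_value=1e-3, max_value=1e4), min_size=3,
                    max_size=40))
    def test_roundtrip_property(self, values):
        df = pd.DataFrame({"human_CL_mL_min_kg": values})
        sc = prep.PKColumnScaler().fit(df)
        back = sc.inverse_column("human_CL_mL_min_kg",
                                 sc.transform_column("human_CL_mL_min_kg",
                                                     np.array(values)))
        np.testing.assert_allclose(back, values, atol=1e-8, rtol=1e-10)

    def test_roles(self):
        df = pd.DataFrame({
            "human_CL_mL_min_kg": [1.0, 2.0],
            "pKa_Acid": [3.0, 4.0],
            "Caco_2_flux": [1.0, 2.0],
        })
        roles = prep.PKColumnScaler.default_roles(df.columns)
        roles["Caco_2_flux"] = "physicochemical"  # prefix still forces exclusion
        sc = prep.PKColumnScaler(column_roles=roles).fit(df)
        assert sc.params_["human_CL_mL_min_kg"]["kind"] == "log1p_standardize"
        assert sc.params_["pKa_Acid"]["kind"] == "standardize_only"
        assert sc.params_["Caco_2_flux"]["kind"] == "excluded"

    def test_zero_variance_guard(self):
        df = pd.DataFrame({"pKa_Acid": [1.0, 1.0, 1.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            sc = prep.PKColumnScaler().fit(df)
        assert sc.params_["pKa_Acid"]["sd"] == 1.0
        out = sc.transform_column("pKa_Acid", np.array([1.0, 1.0]))
        np.testing.assert_allclose(out, 0.0)


class TestSplits:
    def test_sizes_and_partition(self, small_dataset):
        plan = prep.optimize_split(small_dataset.table.head(100),
                                   n_candidates=20, seed=0)
        assert (len(plan.train_idx), len(plan.val_idx), len(plan.test_idx)) \
            == (60, 20, 20)
        plan.validate(100)

    def test_argmin_criterion(self, small_dataset):
        df = small_dataset.table.head(120)
        best = prep.optimize_split(df, n_candidates=30, seed=1)
        # re-enumerate the same candidate stream and check optimality
        rng = np.random.default_rng(1)
        crits = []
        for _ in range(30):
            parts = prep._random_partition(120, (0.6, 0.2, 0.2), rng)
            crits.append(prep.split_similarity_criterion(df, parts))
        assert best.criterion == pytest.approx(min(crits))

    def test_single_candidate_returned(self, small_dataset):
        df = small_dataset.table.head(50)
        plan = prep.optimize_split(df, n_candidates=1, seed=3)
        rng = np.random.default_rng(3)
        parts = prep._random_partition(50, (0.6, 0.2, 0.2), rng)
        np.testing.assert_array_equal(plan.train_idx, parts[0])

    def test_repeated_splits_distinct_and_reproducible(self, small_dataset):
        df = small_dataset.table.head(80)
        plans = prep.repeated_splits(df, k=10, base_seed=5)
        assert len(plans) == 10
        assert len({p.seed for p in plans}) == 10
        again = prep.repeated_splits(df, k=10, base_seed=5)
        for a, b in zip(plans, again):
            np.testing.assert_array_equal(a.train_idx, b.train_idx)
        for p in plans:
            p.validate(80)

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            prep.optimize_split(pd.DataFrame({"human_CL_mL_min_kg": [1.0] * 5}),
                                n_candidates=2, seed=0)
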