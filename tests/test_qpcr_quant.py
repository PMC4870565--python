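from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from stoolmark import (
    CohortMetadata,
    collapse_duplicates,
    compare_groups,
    delta_delta_ct,
    simulate_ct,
)
from stoolmark.qpcr_quant import read_ct_table, write_ct_table


def _ct(rows):
    df = pd.DataFrame(rows, columns=["sample_id", "species", "replicate", "ct"])
    df["censored"] = df["ct"] >= 40.0
    return df


def _mean_ct(pairs):
    """(sample, species, mean_ct) triples -> collapse_duplicates-style frame."""
    return pd.DataFrame(
        [(s, sp, m, 2, False, False) for s, sp, m in pairs],
        columns=["sample_id", "species", "mean_ct", "n_wells", "discordant", "undetected"],
    )


class TestCollapseDuplicates:
    def test_mean_of_wells(self):
        out = collapse_duplicates(_ct([("s1", "sp", 1, 24.1), ("s1", "sp", 2, 24.3)]))
        assert out["mean_ct"].iloc[0] == pytest.approx(24.2)
        assert not out["discordant"].iloc[0]

    def test_discordant_flag_but_retained(self):
        out = collapse_duplicates(
            _ct([("s1", "sp", 1, 24.0), ("s1", "sp", 2, 26.0)]), max_spread=1.0
        )
        assert out["mean_ct"].iloc[0] == pytest.approx(25.0)
        assert out["discordant"].iloc[0]

    def test_all_censored_is_undetected(self):
        out = collapse_duplicates(_ct([("s1", "sp", 1, 40.0), ("s1", "sp", 2, 40.0)]))
        assert out["undetected"].iloc[0]
        assert np.isnan(out["mean_ct"].iloc[0])


class TestDeltaDeltaCt:
    @pytest.mark.parametrize("sample_ct,expected_fold", [(24.0, 1.0), (23.0, 2.0), (27.0, 0.125)])
    def test_fold_change_closed_form(self, sample_ct, expected_fold):
        mean_ct = _mean_ct([("cal", "sp", 24.0), ("s1", "sp", sample_ct)])
        out = delta_delta_ct(mean_ct, "cal").set_index("sample_id")
        assert out.loc["s1", "fold_change"] == expected_fold
        assert out.loc["cal", "fold_change"] == 1.0

    def test_doubling_per_cycle(self):
        mean_ct = _mean_ct([("cal", "sp", 30.0)] + [(f"s{i}", "sp", 30.0 - i) for i in range(1, 6)])
        out = delta_delta_ct(mean_ct, "cal").set_index("sample_id")
        folds = [out.loc[f"s{i}", "fold_change"] for i in range(1, 6)]
        assert folds == [2.0, 4.0, 8.0, 16.0, 32.0]

    def test_reference_species_mode(self):
        mean_ct = _mean_ct(
            [("cal", "sp", 25.0), ("cal", "ref", 20.0), ("s1", "sp", 24.0), ("s1", "ref", 20.0)]
        )
        out = delta_delta_ct(mean_ct, "cal", reference_species="ref").set_index("sample_id")
        assert out.loc["s1", "fold_change"] == 2.0
        assert "ref" not in set(out["species"])

    def test_missing_calibrator_names_species(self):
        mean_ct = _mean_ct([("s1", "spX", 24.0)])
        with pytest.raises(ValueError, match="spX"):
            delta_delta_ct(mean_ct, "cal")

    def test_end_to_end_recovery_noise_free(self):
        """simulate_ct at unit efficiency with power-of-two abundances gives
        exact fold recovery: a 4x depleted species reads 0.25."""
        ab = pd.DataFrame({"sp": [1024.0, 1024.0, 256.0, 256.0]}, index=["c1", "c2", "p1", "p2"])
        ct = simulate_ct(ab, primer_efficiency=1.0, ct_noise_sd=0.0)
        folds = delta_delta_ct(collapse_duplicates(ct), "c1").set_index("sample_id")
        assert folds.loc["p1", "fold_change"] == 0.25
        case_mean = folds.loc[["p1", "p2"], "fold_change"].mean()
        ctrl_mean = folds.loc[["c1", "c2"], "fold_change"].mean()
        assert case_mean / ctrl_mean == 0.25


class TestCompareGroups:
    @staticmethod
    def _meta(controls, cases):
        frame = pd.DataFrame(
            {"group": ["control"] * len(controls) + ["case"] * len(cases),
             "symptom_score": 0.0},
            index=controls + cases,
        )
        return CohortMetadata(frame=frame)

    @staticmethod
    def _folds(species, sample_values):
        return pd.DataFrame(
            [(s, species, np.nan, np.nan, np.nan, v) for s, v in sample_values.items()],
            columns=["sample_id", "species", "mean_ct", "delta_ct", "delta_delta_ct", "fold_change"],
        )

    def test_identical_groups_not_significant(self):
        meta = self._meta(["c1", "c2", "c3"], ["p1", "p2", "p3"])
        folds = self._folds("sp", {s: 1.0 for s in meta.sample_ids})
        out = compare_groups(folds, meta)
        assert not out["significant"].iloc[0]
        assert out["p_value"].iloc[0] > 0.5

    def test_separated_groups_match_exact_permutation_oracle(self):
        """P-value equals exact enumeration of the U statistic's null."""
        ctrl = [2.0, 2.1, 1.9, 2.2]
        case = [0.4, 0.5, 0.3, 0.6]
        meta = self._meta(["c1", "c2", "c3", "c4"], ["p1", "p2", "p3", "p4"])
        folds = self._folds("sp", dict(zip(meta.sample_ids, ctrl + case)))
        out = compare_groups(folds, meta)

        # independent oracle: enumerate all C(8,4) group assignments of the
        # pooled values and count assignments with U at least as extreme
        pooled = np.array(ctrl + case)
        n = len(ctrl)

        def u_stat(idx):
            a = pooled[list(idx)]
            b = np.delete(pooled, list(idx))
            return sum((x > y) + 0.5 * (x == y) for x in a for y in b)

        observed = u_stat(range(n))
        null = [u_stat(c) for c in combinations(range(len(pooled)), n)]
        mid = n * (len(pooled) - n) / 2
        p_exact = np.mean([abs(u - mid) >= abs(observed - mid) for u in null])
        assert out["p_value"].iloc[0] == pytest.approx(p_exact, abs=1e-12)
        assert out["significant"].iloc[0]
        assert out["case_mean"].iloc[0] < out["control_mean"].iloc[0]

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(0)
        meta = self._meta([f"c{i}" for i in range(5)], [f"p{i}" for i in range(5)])
        vals = dict(zip(meta.sample_ids, rng.normal(1, 0.3, 10)))
        folds = self._folds("sp", vals)
        shuffled = folds.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = compare_groups(folds, meta)
        b = compare_groups(shuffled, meta)
        assert a["p_value"].iloc[0] == b["p_value"].iloc[0]

    def test_small_group_skipped_with_warning(self):
        meta = self._meta(["c1"], ["p1", "p2"])
        folds = self._folds("sp", {"c1": 1.0, "p1": 0.5, "p2": 0.4})
        with pytest.warns(UserWarning, match="fewer than 2"):
            out = compare_groups(folds, meta)
        assert out.empty


class TestCtIO:
    def test_round_trip(self, tmp_path):
        ct = _ct([("s1", "sp", 1, 24.1), ("s1", "sp", 2, 24.3)])
        path = tmp_path / "ct.csv"
        write_ct_table(ct, path, seed=1)
        back = read_ct_table(path)
        assert (back["ct"] == ct["ct"]).all()

    def test_out_of_range_ct_rejected(self, tmp_path):
        path = tmp_path / "ct.csv"
        path.write_text("sample_id,species,replicate,ct\ns1,sp,1,41.5\n")
        with pytest.raises(ValueError, match="ct values"):
            read_ct_table(path)
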