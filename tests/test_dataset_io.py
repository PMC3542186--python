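import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hdacpcm import (
    HDAC_PANEL,
    InteractionRecord,
    load_activities,
    scale_response,
    stratified_split,
    to_pic50,
)
from hdacpcm.dataset_io import Split, from_pic50, reset_split


class TestToPic50:
    @pytest.mark.parametrize(
        "ic50_nm, expected",
        [(1000.0, 6.0), (1.0, 9.0), (50.0, 7.30103)],
    )
    def test_known_values(self, ic50_nm, expected):
        assert to_pic50(ic50_nm) == pytest.approx(expected, abs=1e-5)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(ValueError):
            to_pic50(bad)

    @given(st.floats(min_value=1e-3, max_value=1e9), st.floats(min_value=1.01, max_value=10))
    def test_strictly_decreasing(self, ic50, factor):
        assert to_pic50(ic50 * factor) < to_pic50(ic50)

    @given(st.floats(min_value=1e-3, max_value=1e9))
    def test_roundtrip(self, ic50):
        assert from_pic50(to_pic50(ic50)) == pytest.approx(ic50, rel=1e-10)


class TestLoadActivities:
    def test_nonpositive_ic50_filtered(self, tmp_path):
        path = tmp_path / "act.csv"
        path.write_text(
            "compound_id,smiles,target_id,ic50_nm\n"
            "a,CCO,HDAC2,100\n"
            "b,CCO,HDAC2,0\n"
            "c,CCO,HDAC6,250\n"
        )
        records, tally = load_activities(path)
        assert len(records) == 2
        assert tally.total == 1 and tally.nonpositive_ic50 == 1

    def test_bad_smiles_and_unknown_target_counted(self, tmp_path):
        path = tmp_path / "act.csv"
        path.write_text(
            "compound_id,smiles,target_id,ic50_nm\n"
            "a,CCO,HDAC2,100\n"
            "b,not_a_smiles((,HDAC2,10\n"
            "c,CCO,SIRT1,10\n"
        )
        records, tally = load_activities(path)
        assert len(records) == 1
        assert tally.bad_smiles == 1 and tally.unknown_target == 1

    def test_duplicate_pair_rejected(self, tmp_path):
        path = tmp_path / "act.csv"
        path.write_text(
            "compound_id,smiles,target_id,ic50_nm\n"
            "a,CCO,HDAC2,100\n"
            "a,CCO,HDAC2,200\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            load_activities(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_activities(tmp_path / "nope.csv")

    def test_all_rows_invalid_is_error(self, tmp_path):
        path = tmp_path / "act.csv"
        path.write_text("compound_id,smiles,target_id,ic50_nm\na,CCO,HDAC2,-5\n")
        with pytest.raises(ValueError, match="no valid"):
            load_activities(path)

    def test_panel_distribution_counts(self, panel_activity_csv):
        from .conftest import PANEL_COUNTS

        records, tally = load_activities(panel_activity_csv)
        assert tally.total == 0
        counts = {}
        for r in records:
            counts[r.target_id] = counts.get(r.target_id, 0) + 1
        assert counts == PANEL_COUNTS
        assert len(records) == 1275

    def test_smiles_file_join(self, tmp_path):
        act = tmp_path / "act.csv"
        act.write_text("compound_id,target_id,ic50_nm\na,HDAC2,100\n")
        smi = tmp_path / "cmp.smi"
        smi.write_text("c1ccccc1 a\n")
        records, _ = load_activities(act, smiles_file=smi)
        assert records[0].smiles == "c1ccccc1"

    def test_record_pic50_set_on_construction(self):
        r = InteractionRecord("a", "CCO", "HDAC2", ic50=1000.0)
        assert r.pic50 == pytest.approx(6.0)
        with pytest.raises(ValueError):
            InteractionRecord("a", "CCO", "HDAC2", ic50=-1.0)


def _records(sizes: dict[str, int]) -> list[InteractionRecord]:
    recs = []
    k = 0
    for tid, n in sizes.items():
        for _ in range(n):
            recs.append(InteractionRecord(f"c{k}", "CCO", tid, ic50=float(k + 1)))
            k += 1
    return recs


class TestStratifiedSplit:
    @pytest.mark.parametrize(
        "n, n_train",
        [(531, 345), (197, 128), (10, 6)],
    )
    def test_floor_rule_per_stratum(self, n, n_train):
        recs = _records({"T": n})
        summary = stratified_split(recs, 0.65, seed=0)
        assert summary.per_target_counts["T"] == (n, n_train, n - n_train)

    def test_partition_and_near_fraction(self):
        sizes = {"A": 17, "B": 101, "C": 3}
        recs = _records(sizes)
        stratified_split(recs, 0.65, seed=3)
        for tid, n in sizes.items():
            stratum = [r for r in recs if r.target_id == tid]
            n_train = sum(r.split is Split.train for r in stratum)
            n_test = sum(r.split is Split.test for r in stratum)
            assert n_train + n_test == n
            assert abs(n_train - 0.65 * n) < 1

    def test_membership_randomized_by_seed(self):
        recs1, recs2 = _records({"T": 40}), _records({"T": 40})
        stratified_split(recs1, 0.65, seed=1)
        stratified_split(recs2, 0.65, seed=2)
        assert [r.split for r in recs1] != [r.split for r in recs2]

    def test_preconditions(self):
        recs = _records({"T": 10})
        stratified_split(recs, 0.65, seed=0)
        with pytest.raises(ValueError, match="unassigned"):
            stratified_split(recs, 0.65, seed=0)
        reset_split(recs)
        with pytest.raises(ValueError, match="fraction_train"):
            stratified_split(recs, 1.2, seed=0)


class TestScaleResponse:
    def test_two_point_scaling(self):
        recs = [
            InteractionRecord("a", "C", "T", ic50=from_pic50(5.0)),
            InteractionRecord("b", "C", "T", ic50=from_pic50(7.0)),
        ]
        scaling = scale_response(recs, fit_on="all")
        assert scaling.mean == pytest.approx(6.0)
        assert scaling.sd == pytest.approx(math.sqrt(2.0))
        assert [r.y_scaled for r in recs] == pytest.approx([-0.70711, 0.70711], abs=1e-5)

    def test_degenerate(self):
        recs = [InteractionRecord(f"c{i}", "C", "T", ic50=100.0) for i in range(3)]
        with pytest.raises(ValueError, match="degenerate|zero variance"):
            scale_response(recs, fit_on="all")

    def test_roundtrip_identity(self):
        rng = np.random.default_rng(0)
        recs = [
            InteractionRecord(f"c{i}", "C", "T", ic50=float(v))
            for i, v in enumerate(rng.uniform(1, 1e5, 25))
        ]
        scaling = scale_response(recs, fit_on="all")
        for r in recs:
            assert scaling.inverse(r.y_scaled) == pytest.approx(r.pic50, abs=1e-10)

    def test_fit_on_train_excludes_test(self):
        recs = _records({"T": 20})
        stratified_split(recs, 0.5, seed=0)
        scaling = scale_response(recs, fit_on="train")
        train_pic50 = [r.pic50 for r in recs if r.split is Split.train]
        assert scaling.mean == pytest.approx(np.mean(train_pic50))
        assert scaling.sd == pytest.approx(np.std(train_pic50, ddof=1))
        # every record still receives a scaled response
        assert all(np.isfinite(r.y_scaled) for r in recs)


def test_builtin_panel_classes():
    classes = {t.target_id: t.hdac_class.value for t in HDAC_PANEL}
    assert classes == {"HDAC2": "I", "HDAC8": "I", "HDAC4": "IIa", "HDAC7": "IIa", "HDAC6": "IIb"}
    majors = {t.target_id: t.hdac_class.major for t in HDAC_PANEL}
    assert majors["HDAC6"] == "II" and majors["HDAC2"] == "I"
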