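"""Study workflow: eligibility, screening, blinding, scoring, aggregation."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from sonodice import (
    ConcordanceRecord,
    ConfusionAreas,
    EligibilityLabel,
    InsufficientImagesError,
    RunConfig,
    SectorGeometry,
    aggregate,
    blind_and_shuffle,
    make_screening_pool,
    plan_acquisition,
    plan_study,
    score_study,
    screen_and_sample,
    sdi,
    select_eligible,
)
from sonodice.study import records_frame, run_study


def _labels(n_animals, lv_ics):
    labels = []
    for i in range(1, n_animals + 1):
        for ics in range(4, 9):
            seen = {"lv"} if ics in lv_ics else {"apex"}
            labels.append(EligibilityLabel(f"A{i:02d}", ics, frozenset(seen)))
    return labels


class TestSelectEligible:
    def test_all_lv_is_identity(self, small_config):
        manifest = plan_study(small_config, n_animals=2, seed=0)
        out = select_eligible(manifest, _labels(2, {4, 5, 6, 7, 8}))
        assert len(out) == len(manifest)

    def test_no_lv_anywhere_is_empty(self, small_config):
        manifest = plan_study(small_config, n_animals=2, seed=0)
        out = select_eligible(manifest, _labels(2, set()))
        assert len(out) == 0

    def test_two_of_five_spaces_keep_504_images(self, small_config):
        manifest = plan_study(small_config, n_animals=7, seed=0)
        out = select_eligible(manifest, _labels(7, {5, 6}))
        assert len(out) == 2 * 7 * 3 * 12 == 504

    def test_missing_label_names_the_pair(self, small_config):
        manifest = plan_study(small_config, n_animals=2, seed=0)
        labels = [l for l in _labels(2, {5}) if not
                  (l.animal_id == "A02" and l.ics == 7)]
        with pytest.raises(ValueError, match=r"A02.*7"):
            select_eligible(manifest, labels)

    def test_lvot_counts_as_eligible(self):
        lab = EligibilityLabel("A01", 5, frozenset({"lvot", "aortic_root"}))
        assert lab.eligible
        assert not EligibilityLabel("A01", 5, frozenset({"apex"})).eligible


class TestScreenAndSample:
    def test_unflagged_pool_screens_exactly_the_quota(self):
        pool = plan_acquisition(69)
        retained, excluded, n_screened = screen_and_sample(pool, 50, seed=0)
        assert (len(retained), len(excluded), n_screened) == (150, 0, 150)
        assert retained["state"].value_counts().eq(50).all()

    def test_packaged_pool_reproduces_the_screening_log(self):
        """828-image pool, quota 50/state: 160 screened, 10 excluded."""
        pool = make_screening_pool(seed=0)
        assert len(pool) == 828
        retained, excluded, n_screened = screen_and_sample(pool, 50, seed=0)
        assert len(retained) == 150
        assert len(excluded) == 10
        assert n_screened == 160

    def test_packaged_pool_works_across_seeds(self):
        for seed in [1, 7, 123]:
            pool = make_screening_pool(seed=seed)
            retained, excluded, n = screen_and_sample(pool, 50, seed=seed)
            assert (len(retained), len(excluded), n) == (150, 10, 160)

    def test_all_flagged_pool_is_insufficient(self):
        pool = plan_acquisition(69)
        pool["rib_shadow_flag"] = True
        with pytest.raises(InsufficientImagesError, match="pre_arrest"):
            screen_and_sample(pool, 50, seed=0)

    def test_draws_are_deterministic_and_order_independent(self):
        pool = make_screening_pool(seed=5)
        r1, _, _ = screen_and_sample(pool, 50, seed=5)
        shuffled = pool.sample(frac=1.0, random_state=99)
        r2, _, _ = screen_and_sample(shuffled, 50, seed=5)
        assert list(r1["image_path"]) == list(r2["image_path"])


class TestBlindAndShuffle:
    @pytest.fixture
    def retained(self):
        pool = make_screening_pool(seed=2)
        retained, _, _ = screen_and_sample(pool, 50, seed=2)
        return retained

    def test_blinding_key_is_a_bijection(self, retained):
        manifest = blind_and_shuffle(retained, seed=2)
        assert len(set(manifest.codes)) == len(retained)
        by_path = {manifest.decode(c)["image_path"]: c for c in manifest.codes}
        assert len(by_path) == len(retained)
        for _, row in retained.iterrows():
            code = by_path[row["image_path"]]
            meta = manifest.decode(code)
            assert meta["state"] == row["state"]
            assert meta["animal_id"] == row["animal_id"]

    def test_same_seed_same_permutation(self, retained):
        def order(m):
            return [m.decode(c)["image_path"] for c in m.codes]

        m1 = blind_and_shuffle(retained, seed=3)
        m2 = blind_and_shuffle(retained, seed=3)
        m3 = blind_and_shuffle(retained, seed=4)
        assert order(m1) == order(m2)
        assert order(m1) != order(m3)

    def test_packet_leaks_no_state_metadata(self, retained):
        manifest = blind_and_shuffle(retained, seed=2)
        packet = manifest.packet_frame()
        assert list(packet.columns) == ["image_code", "image_path"]
        blob = "".join(manifest.codes).lower()
        for token in ("pre", "arrest", "late", "ics"):
            assert token not in blob

    def test_duplicate_paths_rejected(self, retained):
        doubled = pd.concat([retained, retained.iloc[:1]])
        with pytest.raises(ValueError, match="duplicate"):
            blind_and_shuffle(doubled, seed=0)


def _dummy_masks(codes, shape=(32, 32), offset=0):
    grid = np.zeros(shape, bool)
    grid[8 + offset:14 + offset, 13:19] = True
    return {code: grid for code in codes}


class TestScoreStudy:
    @pytest.fixture
    def manifest(self):
        pool = make_screening_pool(seed=1)
        retained, _, _ = screen_and_sample(pool, 50, seed=1)
        return blind_and_shuffle(retained, seed=1)

    def test_150_images_times_3_reviewers_is_450_records(self, manifest):
        sector = SectorGeometry((32, 32))
        device = _dummy_masks(manifest.codes)
        reviewers = {rid: _dummy_masks(manifest.codes) for rid in ("R1", "R2", "R3")}
        records = score_study(manifest, device, reviewers, sector)
        assert len(records) == 450

    def test_identical_masks_give_unit_sdi(self, manifest):
        sector = SectorGeometry((32, 32))
        device = _dummy_masks(manifest.codes)
        records = score_study(manifest, device, {"R1": device}, sector)
        assert all(r.sdi == 1.0 for r in records)

    def test_missing_reviewer_mask_names_the_code(self, manifest):
        sector = SectorGeometry((32, 32))
        device = _dummy_masks(manifest.codes)
        reviewer = _dummy_masks(manifest.codes)
        victim = manifest.codes[10]
        del reviewer[victim]
        with pytest.raises(ValueError, match=f"{victim}.*R1"):
            score_study(manifest, device, {"R1": reviewer}, sector)


def _record(code, reviewer, tp, fp, fn, tn=0):
    areas = ConfusionAreas(tp=tp, tn=tn, fp=fp, fn=fn, total=tp + tn + fp + fn)
    return ConcordanceRecord(code, reviewer, sdi(areas), areas)


class TestAggregate:
    def test_perfect_agreement_gives_unit_cells(self):
        key = {"IMG0001": {"state": "arrest"}, "IMG0002": {"state": "arrest"}}
        records = [
            _record(code, rid, tp=10, fp=0, fn=0, tn=5)
            for code in key for rid in ("R1", "R2")
        ]
        summary = aggregate(records, key)
        for rid in ("R1", "R2", "mean"):
            mean, sd_, n = summary.cell(rid, "arrest")
            assert (mean, sd_) == (1.0, 0.0)

    def test_hand_computed_mean_and_sd(self):
        """SDIs {0, 1} for one reviewer: mean 0.5, sample SD = 1/√2."""
        key = {"IMG0001": {"state": "arrest"}, "IMG0002": {"state": "arrest"}}
        records = [
            _record("IMG0001", "R1", tp=0, fp=3, fn=2, tn=5),   # SDI 0
            _record("IMG0002", "R1", tp=10, fp=0, fn=0, tn=5),  # SDI 1
        ]
        summary = aggregate(records, key)
        mean, sd_, n = summary.cell("R1", "arrest")
        assert mean == pytest.approx(0.5)
        assert sd_ == pytest.approx(1 / math.sqrt(2))
        assert n == 2

    def test_pooled_row_is_mean_of_reviewer_means(self):
        rng = np.random.default_rng(0)
        key = {f"IMG{i:04d}": {"state": "arrest"} for i in range(1, 13)}
        records = [
            _record(code, rid, tp=int(rng.integers(1, 50)),
                    fp=int(rng.integers(0, 20)), fn=int(rng.integers(0, 20)))
            for code in key for rid in ("R1", "R2", "R3")
        ]
        summary = aggregate(records, key)
        reviewer_means = [summary.cell(r, "arrest")[0] for r in ("R1", "R2", "R3")]
        assert summary.cell("mean", "arrest")[0] == pytest.approx(
            np.mean(reviewer_means)
        )

    def test_cells_match_exact_rational_recomputation(self):
        rng = np.random.default_rng(1)
        states = ["pre_arrest", "arrest"]
        key, records = {}, []
        for i in range(1, 21):
            code = f"IMG{i:04d}"
            key[code] = {"state": states[i % 2]}
            for rid in ("R1", "R2"):
                records.append(
                    _record(code, rid, tp=int(rng.integers(1, 40)),
                            fp=int(rng.integers(0, 15)), fn=int(rng.integers(0, 15)))
                )
        summary = aggregate(records, key)
        for rid in ("R1", "R2"):
            for state in states:
                vals = [
                    Fraction(2 * r.areas.tp,
                             2 * r.areas.tp + r.areas.fp + r.areas.fn)
                    for r in records
                    if r.reviewer_id == rid and key[r.image_code]["state"] == state
                ]
                exact_mean = sum(vals) / len(vals)
                mean, sd_, n = summary.cell(rid, state)
                assert mean == pytest.approx(float(exact_mean), abs=1e-12)
                exact_var = sum((v - exact_mean) ** 2 for v in vals) / (len(vals) - 1)
                assert sd_ == pytest.approx(math.sqrt(float(exact_var)), abs=1e-9)

    def test_empty_cell_is_rejected(self):
        key = {"IMG0001": {"state": "arrest"}, "IMG0002": {"state": "pre_arrest"}}
        records = [
            _record("IMG0001", "R1", tp=5, fp=1, fn=1),
            _record("IMG0002", "R2", tp=5, fp=1, fn=1),
        ]
        with pytest.raises(ValueError, match="no records"):
            aggregate(records, key)


class TestRunStudy:
    def test_smoke_run_emits_quota_records(self):
        cfg = RunConfig.study_scale(quota_per_state=5).with_seed(3)
        report = run_study(cfg)
        assert len(report.records) == 5 * 3 * 3 == 45
        assert set(report.summary.pooled_means()) == {
            "pre_arrest", "arrest", "late_arrest"
        }

    def test_reruns_are_byte_identical(self, tmp_path):
        cfg = RunConfig.study_scale(quota_per_state=4, render_sample_size=0)
        run_study(cfg.with_seed(6), outdir=tmp_path / "a")
        run_study(cfg.with_seed(6), outdir=tmp_path / "b")
        for name in ("records.csv", "summary.csv", "packet.csv", "retained.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes(), name

    def test_report_files_and_blinded_packet(self, tmp_path):
        cfg = RunConfig.study_scale(quota_per_state=3, render_sample_size=2)
        report = run_study(cfg.with_seed(9), outdir=tmp_path)
        assert (tmp_path / "summary.txt").exists()
        assert (tmp_path / "summary.json").exists()
        renders = list((tmp_path / "renderings").glob("*.png"))
        assert len(renders) == 2
        packet = (tmp_path / "packet.csv").read_text().lower()
        for token in ("pre_arrest", "late_arrest", "ics"):
            assert token not in packet

    def test_records_frame_shape(self):
        cfg = RunConfig.study_scale(quota_per_state=3).with_seed(2)
        report = run_study(cfg)
        df = records_frame(report.records)
        assert list(df.columns) == [
            "image_code", "reviewer_id", "tp", "tn", "fp", "fn", "sdi"
        ]
        assert len(df) == 27
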