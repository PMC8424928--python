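"""Synthetic wristband logs and the three cleaning rules."""

import numpy as np
import pytest

from screensim import (
    VisitRecord,
    clean_visit_log,
    durations_by_station,
    gen_visit_log,
    read_visit_log,
    write_visit_log,
)
from screensim.errors import ConfigError


def test_toy_log_cleaning_by_rule():
    """Five complete records {4,5,6,5,31} plus one missing-exit record at one
    station: the incomplete one falls to rule 2, and 31 exceeds twice the
    complete-record mean (2 x 10.2), so exactly four records survive."""
    recs = [
        VisitRecord(i, "X1", "H", 10.0 * i, 10.0 * i + d, 0)
        for i, d in enumerate([4, 5, 6, 5, 31])
    ]
    recs.append(VisitRecord(5, "X1", "H", 60.0, None, 0))
    kept, report = clean_visit_log(recs)
    assert len(kept) == 4
    assert report["rule2_missing_timestamp"] == 1
    assert report["rule3_outlier"] == {"H": 1}
    assert report["thresholds"]["H"] == pytest.approx(2 * 10.2)
    assert sorted(r.duration for r in kept) == [4, 5, 5, 6]


def test_unknown_type_removed_by_rule_one():
    recs = [
        VisitRecord(0, "X1", "H", 0.0, 4.0, 0),
        VisitRecord(1, "ZZ", "H", 0.0, 4.0, 0),
    ]
    kept, report = clean_visit_log(recs)
    assert len(kept) == 1
    assert report["rule1_unknown_type"] == 1


def test_moderate_log_is_untouched():
    recs = [VisitRecord(i, "X1", "H", 0.0, 4.0 + 0.1 * i, 0) for i in range(10)]
    kept, report = clean_visit_log(recs)
    assert len(kept) == 10 and report["removed"] == 0


def test_removal_counts_sum(model, rng):
    log = gen_visit_log(300, model, rng, miss_rate=0.1, outlier_rate=0.05)
    kept, report = clean_visit_log(log)
    removed = (
        report["rule1_unknown_type"]
        + report["rule2_missing_timestamp"]
        + sum(report["rule3_outlier"].values())
    )
    assert removed == report["removed"] == report["input"] - report["kept"]


class TestGenerator:
    def test_single_customer_has_one_record_per_route_step(self, model):
        rng = np.random.default_rng(0)
        log = gen_visit_log(1, model, rng, mix={"X1": 1.0}, miss_rate=0.0, outlier_rate=0.0)
        assert len(log) == 20  # length of the X1 route
        assert [r.station for r in log] == list(model.routes["X1"].steps)

    def test_clean_durations_converge_to_service_means(self, model):
        """Without injected defects, per-station mean durations track the
        generating laws (the heavy-tailed stations within a few percent)."""
        from screensim import analytic_mean

        rng = np.random.default_rng(8)
        log = gen_visit_log(1500, model, rng, miss_rate=0.0, outlier_rate=0.0)
        groups = durations_by_station(log)
        for code in ("B", "L", "H", "J"):
            mean = np.mean(groups[code])
            assert mean == pytest.approx(analytic_mean(model.service[code]), rel=0.03), code

    def test_miss_rate_one_not_allowed_but_high_rate_drops_records(self, model, rng):
        with pytest.raises(ConfigError):
            gen_visit_log(5, model, rng, miss_rate=1.0)
        log = gen_visit_log(200, model, rng, miss_rate=0.5)
        frac_incomplete = np.mean([not r.complete for r in log])
        assert frac_incomplete == pytest.approx(0.5, abs=0.05)

    def test_type_mix_follows_model(self, model, rng):
        log = gen_visit_log(3000, model, rng, miss_rate=0.0, outlier_rate=0.0)
        customers = {r.customer_id: r.type_id for r in log}
        frac_y2 = np.mean([t == "Y2" for t in customers.values()])
        assert frac_y2 == pytest.approx(0.3403, abs=0.03)


def test_cleaning_is_nearly_idempotent(model):
    """Re-cleaning defect-free cleaned data is exactly stable at the
    bounded-support (uniform-law) stations — twice their mean always exceeds
    the upper endpoint — and removes under 1.5% overall: re-trimming only
    nibbles at the heavy lognormal tails whose truncation lowered the mean."""
    uniform_stations = {"B", "C", "K", "L", "M", "P", "U"}
    total = removed_again = 0
    for seed in range(10):
        rng = np.random.default_rng(3000 + seed)
        log = gen_visit_log(150, model, rng, miss_rate=0.0, outlier_rate=0.0)
        kept, _ = clean_visit_log(log)
        kept2, rep2 = clean_visit_log(kept)
        assert not (set(rep2["rule3_outlier"]) & uniform_stations)
        total += len(kept)
        removed_again += len(kept) - len(kept2)
    assert removed_again / total < 0.015


def test_rule3_catches_injected_outliers_at_bounded_stations(model):
    """Inflating 2% of records five-fold at the uniform-law stations is
    always detectable (5x any draw exceeds twice the station mean), and the
    trimming rule removes at least 90% of them."""
    rng = np.random.default_rng(99)
    log = gen_visit_log(800, model, rng, miss_rate=0.0, outlier_rate=0.0)
    uniform_stations = {"B", "C", "K", "L", "M", "P", "U"}
    tampered = []
    flagged = set()
    for i, r in enumerate(log):
        if r.station in uniform_stations and rng.random() < 0.02:
            tampered.append(
                VisitRecord(r.customer_id, r.type_id, r.station, r.entry, r.entry + 5 * r.duration, r.day)
            )
            flagged.add(i)
        else:
            tampered.append(r)
    kept, _ = clean_visit_log(tampered)
    kept_ids = {id(r) for r in kept}
    surviving = sum(1 for i in flagged if id(tampered[i]) in kept_ids)
    assert surviving <= 0.1 * len(flagged)


def test_durations_by_station_grouping():
    recs = [
        VisitRecord(0, "X1", "H", 0.0, 4.0, 0),
        VisitRecord(0, "X1", "J", 4.0, 12.0, 0),
        VisitRecord(1, "X1", "H", 1.0, 6.0, 0),
        VisitRecord(2, "X1", "H", 2.0, None, 0),
    ]
    groups = durations_by_station(recs)
    assert groups["H"] == [4.0, 5.0]
    assert groups["J"] == [8.0]
    assert durations_by_station([]) == {}


def test_csv_round_trip(tmp_path, model, rng):
    log = gen_visit_log(20, model, rng, miss_rate=0.2)
    path = tmp_path / "log.csv"
    write_visit_log(log, path)
    back = read_visit_log(path)
    assert len(back) == len(log)
    for a, b in zip(log, back):
        assert (a.customer_id, a.type_id, a.station) == (b.customer_id, b.type_id, b.station)
        assert (a.entry is None) == (b.entry is None)
        if a.complete and b.complete:
            assert b.duration == pytest.approx(a.duration, abs=1e-3)
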