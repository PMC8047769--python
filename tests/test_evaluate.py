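"""Event-to-box assignment, coverage/efficiency, grid search, mzML timing."""

import math
import textwrap

import numpy as np
import pytest

from ddasim import (ControllerConfig, FragmentationEvent, PeakBoundingBox,
                    ScanTimingModel, assign_events, coverage, efficiency,
                    evaluate_log, generate_mixture, grid_search,
                    ground_truth_boxes, make_controller,
                    mean_scan_times_from_mzml, run_acquisition)


def box(bid, mz0, mz1, rt0, rt1):
    return PeakBoundingBox(id=bid, mz_min=mz0, mz_max=mz1, rt_min=rt0,
                           rt_max=rt1)


def event(i, t, mz):
    return FragmentationEvent(ms2_scan_index=i, time=t, precursor_mz=mz)


class TestAssignEvents:
    BOXES = [box("a", 100.0, 100.5, 10.0, 20.0),
             box("b", 100.4, 100.9, 15.0, 25.0)]

    def test_event_inside_one_box(self):
        a = assign_events([event(0, 12.0, 100.2)], self.BOXES)
        assert a == {0: {"a"}}

    def test_event_outside_all_boxes(self):
        assert assign_events([event(0, 50.0, 100.2)], self.BOXES) == {0: set()}

    def test_corner_is_inclusive(self):
        a = assign_events([event(0, 20.0, 100.5)], self.BOXES)
        assert "a" in a[0]

    def test_overlap_multi_credit_default(self):
        a = assign_events([event(0, 16.0, 100.45)], self.BOXES)
        assert a[0] == {"a", "b"}

    def test_single_credit_takes_nearest_centre(self):
        # centres: a -> 100.25, b -> 100.65; 100.41 is nearer a
        a = assign_events([event(0, 16.0, 100.41)], self.BOXES,
                          single_credit=True)
        assert a[0] == {"a"}

    def test_single_credit_centre_tie_broken_by_id(self):
        # at 100.45 both centres are 0.20 away; lexically smaller id wins
        a = assign_events([event(0, 16.0, 100.45)], self.BOXES,
                          single_credit=True)
        assert a[0] == {"a"}


class TestCoverageAndEfficiency:
    def test_two_events_one_box_counts_once(self):
        boxes = [box("a", 100.0, 101.0, 0.0, 50.0)]
        events = [event(0, 10.0, 100.5), event(1, 20.0, 100.5)]
        assert coverage(events, boxes) == 1

    def test_zero_events(self):
        assert coverage([], [box("a", 1, 2, 0, 1)]) == 0

    def test_random_instance_matches_double_loop(self):
        rng = np.random.default_rng(4)
        boxes = [box(f"b{j}", m, m + 0.5, r, r + 10.0)
                 for j, (m, r) in enumerate(zip(rng.uniform(100, 110, 30),
                                                rng.uniform(0, 90, 30)))]
        events = [event(i, float(rng.uniform(0, 100)),
                        float(rng.uniform(100, 111)))
                  for i in range(60)]
        # O(n*m) oracle
        expected = sum(
            1 for b in boxes
            if any(b.mz_min <= e.precursor_mz <= b.mz_max
                   and b.rt_min <= e.time <= b.rt_max for e in events))
        assert coverage(events, boxes) == expected

    def test_coverage_invariant_to_order(self):
        rng = np.random.default_rng(5)
        boxes = [box(f"b{j}", m, m + 0.5, r, r + 10.0)
                 for j, (m, r) in enumerate(zip(rng.uniform(100, 105, 10),
                                                rng.uniform(0, 90, 10)))]
        events = [event(i, float(rng.uniform(0, 100)),
                        float(rng.uniform(100, 106))) for i in range(20)]
        assert coverage(events, boxes) == \
            coverage(events[::-1], boxes[::-1])

    def test_efficiency_is_exact_ratio(self):
        assert efficiency(7, 20) == 7 / 20

    def test_perfect_efficiency(self):
        assert efficiency(10, 10) == 1.0

    def test_zero_ms2_rejected(self):
        with pytest.raises(ValueError):
            efficiency(0, 0)


class TestEvaluateLog:
    def test_report_identity_and_bookkeeping(self, small_mixture,
                                             small_boxes):
        log = run_acquisition(make_controller("topn"), small_mixture)
        report = evaluate_log(log, small_boxes)
        assert report.efficiency * report.n_ms2 == report.coverage
        assert report.n_scans == report.n_ms1 + report.n_ms2
        assert 0 <= report.coverage <= report.n_boxes
        assert report.per_box_hits and \
            sum(report.per_box_hits.values()) >= report.coverage

    def test_fullscan_run_has_nan_efficiency(self, small_mixture,
                                             small_boxes):
        log = run_acquisition(make_controller("fullscan"), small_mixture)
        report = evaluate_log(log, small_boxes)
        assert report.n_ms2 == 0 and report.coverage == 0
        assert math.isnan(report.efficiency)


class TestGridSearch:
    def test_single_point_grid(self, small_mixture):
        best, table = grid_search("topn", {"N": [5]}, small_mixture)
        assert best == {"N": 5}
        assert len(table) == 1
        assert table.loc[0, "coverage"] >= 0

    def test_degenerate_weighteddew_matches_topn_entry(self, small_mixture):
        timing = ScanTimingModel(0.56, 0.2)
        _, wdew = grid_search("weighteddew", {"t0": [15.0], "t1": [15.0]},
                              small_mixture, timing=timing)
        _, top = grid_search("topn", {"t0": [15.0]}, small_mixture,
                             timing=timing)
        assert wdew.loc[0, "coverage"] == top.loc[0, "coverage"]
        assert wdew.loc[0, "n_ms2"] == top.loc[0, "n_ms2"]

    def test_grid_scores_within_optimal_bound(self, small_mixture,
                                              small_boxes):
        from ddasim import (hopcroft_karp, build_graph, schedule_from_log,
                            mixture_intensity_lookup)
        best, table = grid_search(
            "smartroi", {"alpha": [2.0, 1000.0], "beta": [0.1, 0.5]},
            small_mixture)
        assert len(table) == 4
        # every grid point's coverage is bounded by its run's matching
        lookup = mixture_intensity_lookup(small_mixture)
        for _, row in table.iterrows():
            cfg = ControllerConfig(alpha=row["alpha"], beta=row["beta"])
            log = run_acquisition(make_controller("smartroi", cfg),
                                  small_mixture)
            graph = build_graph(schedule_from_log(log), small_boxes,
                                cfg.min_intensity, lookup)
            assert row["coverage"] <= hopcroft_karp(graph).size

    def test_empty_grid_rejected(self, small_mixture):
        with pytest.raises(ValueError):
            grid_search("topn", {}, small_mixture)
        with pytest.raises(ValueError):
            grid_search("topn", {"N": []}, small_mixture)


MZML_TEMPLATE = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <run id="r">
    <spectrumList count="{count}">
{spectra}
    </spectrumList>
  </run>
</mzML>
"""

SPECTRUM_TEMPLATE = """      <spectrum index="{i}" id="scan={i}" defaultArrayLength="0">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{level}"/>
        <scanList count="1">
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{t}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>
          </scan>
        </scanList>
      </spectrum>"""


def write_minimal_mzml(path, scans):
    """Synthetic minimal mzML (levels + start times only) for parser tests."""
    spectra = "\n".join(
        SPECTRUM_TEMPLATE.format(i=i, level=lvl, t=t / 60.0)
        for i, (lvl, t) in enumerate(scans))
    path.write_text(MZML_TEMPLATE.format(count=len(scans), spectra=spectra))


class TestMzmlScanTimes:
    def test_mean_durations_from_minimal_mzml(self, tmp_path):
        # MS1 scans take 0.6 s, MS2 scans 0.2 s
        scans, t = [], 0.0
        for _ in range(3):
            scans.append((1, t)); t += 0.6
            for _ in range(2):
                scans.append((2, t)); t += 0.2
        scans.append((1, t))  # terminal MS1 so the last gap is defined
        p = tmp_path / "run.mzML"
        write_minimal_mzml(p, scans)
        mean_ms1, mean_ms2 = mean_scan_times_from_mzml(p)
        assert mean_ms1 == pytest.approx(0.6, abs=1e-9)
        assert mean_ms2 == pytest.approx(0.2, abs=1e-9)
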