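"""Continuum classification, cohort ranges and the diagram."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from carbscreen import (MaturityAssessment, RamanParams, SampleRecord,
                        ScreenThresholds, classify, cohort_ranges,
                        continuum_diagram, load_fixture)


def _p(r1, fwhm_d1, fwhm_g=70.0):
    return RamanParams(r1=r1, fwhm_d1=fwhm_d1, fwhm_g=fwhm_g)


def _rec(archean):
    return SampleRecord("x", 3.0 if archean else 0.4)


class TestClassify:
    @pytest.mark.parametrize(
        "r1, fwhm_d1, archean, stage, on_cont, suspect, candidate",
        [
            (0.60, 249.0, False, "stage1", True, False, False),
            (1.58, 61.0, True, "stage2", True, False, False),
            (2.60, 55.0, True, "altered", False, False, False),
            (0.85, 180.0, True, "stage1", True, False, True),
            (0.50, 45.0, True, "stage1", False, True, False),
        ],
    )
    def test_reference_classifications(self, r1, fwhm_d1, archean, stage,
                                       on_cont, suspect, candidate):
        a = classify(_p(r1, fwhm_d1), _rec(archean))
        assert a.stage == stage
        assert a.on_continuum == on_cont
        assert a.graphitization_suspect == suspect
        assert a.best_preserved_candidate == candidate

    def test_temperature_note_set_above_r1_of_one(self):
        assert "300" in classify(_p(1.2, 80.0), _rec(True)).temperature_note
        assert classify(_p(0.8, 200.0), _rec(True)).temperature_note == ""

    def test_non_finite_rejected(self):
        # RamanParams refuses non-finite values at construction; classify
        # still guards in case a mutated/foreign params object slips through
        bad = _p(1.0, 80.0)
        object.__setattr__(bad, "r1", float("nan"))
        with pytest.raises(ValueError):
            classify(bad, _rec(True))

    @settings(max_examples=120, deadline=None)
    @given(r1=st.floats(0.01, 5.0), fwhm=st.floats(6.0, 400.0),
           archean=st.booleans())
    def test_total_exhaustive_and_consistent(self, r1, fwhm, archean):
        """classify is total on finite inputs; the stage partition is
        exhaustive; flags respect their structural implications."""
        a = classify(_p(r1, fwhm), _rec(archean))
        assert a.stage in ("stage1", "stage2", "altered")
        if a.stage == "altered":
            assert not a.best_preserved_candidate
        if a.graphitization_suspect:
            assert not a.on_continuum

    @settings(max_examples=60, deadline=None)
    @given(r1=st.floats(0.01, 4.0), bump=st.floats(0.0, 2.0),
           fwhm=st.floats(6.0, 400.0))
    def test_stage_monotone_in_r1(self, r1, bump, fwhm):
        order = {"stage1": 0, "stage2": 1, "altered": 2}
        lo = classify(_p(r1, fwhm), _rec(True))
        hi = classify(_p(r1 + bump, fwhm), _rec(True))
        assert order[hi.stage] >= order[lo.stage]


class TestFixtureScreen:
    def test_no_altered_no_suspects_archean_all_stage2(self):
        fix = load_fixture()
        assessments = [(fs, classify(fs.params, fs.record)) for fs in fix]
        assert sum(a.stage == "altered" for _, a in assessments) == 0
        assert sum(a.graphitization_suspect for _, a in assessments) == 0
        archean = [a for fs, a in assessments if fs.record.is_archean]
        assert len(archean) == 9
        assert all(a.stage == "stage2" for a in archean)


class TestCohortRanges:
    def test_fixture_reproduces_printed_endpoints(self):
        pairs = [(fs.record, fs.params) for fs in load_fixture()]
        ranges = cohort_ranges(pairs)
        assert ranges["non_archean"]["r1"] == pytest.approx((0.47, 0.97))
        assert ranges["archean"]["r1"] == pytest.approx((1.2, 2.17))
        assert ranges["archean"]["fwhm_d1"] == pytest.approx((59.0, 87.0))
        assert ranges["non_archean"]["fwhm_d1"] == pytest.approx((162.0, 249.0))

    def test_single_sample_group_min_equals_max(self):
        pairs = [(_rec(True), _p(1.5, 70.0))]
        r = cohort_ranges(pairs)["archean"]
        assert r["r1"] == (1.5, 1.5)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            cohort_ranges([])


class TestDiagram:
    def test_fixture_diagram_written(self, tmp_path):
        triples = [(fs.record, fs.params, classify(fs.params, fs.record))
                   for fs in load_fixture()]
        out = continuum_diagram(triples, tmp_path / "fig.png")
        assert out.exists() and out.stat().st_size > 0

    def test_suspect_marker_class_renders(self, tmp_path):
        triples = [
            (_rec(True), _p(1.5, 70.0), classify(_p(1.5, 70.0), _rec(True))),
            (_rec(True), _p(0.5, 45.0), classify(_p(0.5, 45.0), _rec(True))),
        ]
        assert triples[1][2].graphitization_suspect
        out = continuum_diagram(triples, tmp_path / "fig.svg")
        assert "graphitization suspect" in out.read_text()

    def test_empty_input_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            continuum_diagram([], tmp_path / "fig.png")


def test_threshold_invariants_enforced():
    with pytest.raises(ValueError):
        ScreenThresholds(candidate_r1_lo=1.5, candidate_r1_hi=1.0)
    with pytest.raises(ValueError):
        ScreenThresholds(carbonization_r1=(2.0, 1.0))
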