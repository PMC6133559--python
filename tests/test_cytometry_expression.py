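"""Event filtering, size normalization, calibration and summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from noisefit.cytometry_expression import (EmptySampleError,
                                           InsufficientCellsError,
                                           MrnaCalibration, SampleExpression,
                                           aggregate_genotype, correct_batch,
                                           filter_events, fluor_to_mrna,
                                           mad_filter, process_sample,
                                           read_events_csv, size_normalize,
                                           subtract_autofluorescence,
                                           summarize_sample, write_events_csv)
from noisefit.synthetic_data import gen_flow_events


class TestFilterEvents:
    def test_homogeneous_singlets_mostly_retained(self):
        ev = gen_flow_events(1.0, 0.1, 10_000, seed=1)
        kept = filter_events(ev)
        assert len(kept) / len(ev) >= 0.99

    def test_nonpositive_events_always_dropped(self):
        ev = gen_flow_events(1.0, 0.1, 100, seed=2)
        ev.loc[0, "fsc_a"] = 0.0
        kept = filter_events(ev, bounds=(0, 1), density_floor=0)
        assert len(kept) == 99

    def test_identity_configuration(self):
        ev = gen_flow_events(1.0, 0.1, 500, seed=3)
        kept = filter_events(ev, bounds=(0, 1), density_floor=0)
        assert len(kept) == len(ev)

    def test_empty_sample_error(self):
        ev = pd.DataFrame({"fsc_a": [0.0], "fsc_h": [1.0], "fl1": [1.0]})
        with pytest.raises(EmptySampleError):
            filter_events(ev)


class TestSizeNormalize:
    def test_zero_rotation_case(self):
        # points on the ray from the origin through the centroid with
        # the major axis along it: theta = 0, output = ratio of logs
        rng = np.random.default_rng(0)
        L = rng.normal(5.0, 0.2, 1000)
        ev = pd.DataFrame({"fsc_a": 10 ** L, "fl1": 10 ** (0.9 * L)})
        out = size_normalize(ev)
        assert np.allclose(out, 0.9, atol=1e-9)

    def test_size_only_variation_is_removed(self):
        # cells differing only in size: log FL1 = log FSC + const
        rng = np.random.default_rng(1)
        L = rng.normal(5.0, 0.3, 2000)
        ev = pd.DataFrame({"fsc_a": 10 ** L, "fl1": 10 ** (L - 0.5)})
        out = size_normalize(ev)
        var_in = np.var(np.log10(ev["fl1"]))
        assert np.var(out) < var_in / 100

    def test_permutation_invariance(self):
        ev = gen_flow_events(1.0, 0.2, 500, seed=4)
        out = size_normalize(ev)
        shuffled = ev.sample(frac=1.0, random_state=0)
        out2 = size_normalize(shuffled)
        assert np.allclose(np.sort(out), np.sort(out2))

    def test_global_rescaling_preserves_structure(self):
        # a common multiplicative rescale shifts both log channels; the
        # centroid-ray convention changes the rotation slightly but the
        # per-cell ordering is preserved
        ev = gen_flow_events(1.0, 0.2, 2000, seed=5)
        out = size_normalize(ev)
        out2 = size_normalize(ev.assign(fsc_a=ev.fsc_a * 3, fl1=ev.fl1 * 3))
        assert stats.spearmanr(out, out2).statistic > 0.999

    def test_degenerate_input_rejected(self):
        ev = pd.DataFrame({"fsc_a": [10.0] * 5, "fl1": [100.0] * 5})
        with pytest.raises(ValueError, match="degenerate"):
            size_normalize(ev)


class TestCalibration:
    def test_unit_expression_point(self):
        # a*log10(x) + b = 0 at x = 10**(9.586/10.469)
        x = 10 ** (9.586 / 10.469)
        assert fluor_to_mrna(x) == pytest.approx(1.0, abs=1e-9)

    def test_direct_evaluation(self):
        assert fluor_to_mrna(10.0) == pytest.approx(10 ** 0.883, rel=1e-12)

    def test_identity_calibration(self):
        cal = MrnaCalibration(a=1.0, b=0.0)
        x = np.array([0.5, 1.0, 7.3])
        assert np.allclose(fluor_to_mrna(x, cal), x)

    def test_monotone_and_loglinear(self):
        x = np.linspace(0.5, 20, 200)
        y = fluor_to_mrna(x)
        assert (np.diff(y) > 0).all()
        r = np.corrcoef(np.log10(x), np.log10(y))[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_slope_must_be_positive(self):
        with pytest.raises(ValueError):
            MrnaCalibration(a=-1.0, b=0.0)


class TestSummaries:
    def test_noise_metric_arithmetic(self):
        s = SampleExpression(m=1.0, s=0.1, n_cells=1000)
        assert s.noise_strength == pytest.approx(0.01)
        assert s.cv == pytest.approx(0.1)
        assert s.log_cv == pytest.approx(-1.0)
        s2 = SampleExpression(m=2.0, s=1.0, n_cells=1000)
        assert s2.noise_strength == pytest.approx(0.5)
        assert s2.cv == pytest.approx(0.5)

    def test_metric_identities(self):
        s = SampleExpression(m=1.7, s=0.23, n_cells=1000)
        assert s.noise_strength == pytest.approx(s.cv ** 2 * s.m, rel=1e-12)
        assert s.log_cv == pytest.approx(np.log10(s.cv), rel=1e-12)

    def test_constant_input_zero_noise(self):
        s = summarize_sample(np.full(1500, 2.0))
        assert s.s == 0.0
        assert s.noise_strength == 0.0

    def test_cell_floor_enforced(self):
        with pytest.raises(InsufficientCellsError):
            summarize_sample(np.ones(999))


class TestMadFilter:
    def test_outlier_dropped(self):
        keep = mad_filter([1, 1, 1, 1, 100], k=4)
        assert keep.tolist() == [True, True, True, True, False]

    def test_all_equal_all_retained(self):
        assert mad_filter([2.0, 2.0, 2.0], k=4).all()

    def test_tight_replicates_retained(self):
        assert mad_filter([0.99, 1.00, 1.01, 1.02], k=5).all()

    def test_needs_three_values(self):
        with pytest.raises(ValueError):
            mad_filter([1.0, 2.0], k=4)


def _sample(m, s, run, row="A"):
    return SampleExpression(m=m, s=s, n_cells=1000, flow_run=run, row=row)


class TestBatchCorrection:
    def test_identical_controls_identity(self):
        samples = [_sample(1.0, 0.1, "r1"), _sample(1.2, 0.12, "r2")]
        controls = [_sample(1.0, 0.1, "r1"), _sample(1.0, 0.1, "r2")]
        out = correct_batch(samples, controls, factors=("flow_run",))
        for before, after in zip(samples, out):
            assert after.m == pytest.approx(before.m, rel=1e-9)
            assert after.s == pytest.approx(before.s, rel=1e-9)

    def test_planted_run_offsets_removed(self):
        rng = np.random.default_rng(0)
        runs = [f"r{i}" for i in range(6)]
        offsets = {r: (0.1 if i % 2 else 0.0) for i, r in enumerate(runs)}
        controls, samples = [], []
        for r in runs:
            for _ in range(4):
                m = 10 ** (np.log10(1.0) + offsets[r]
                           + rng.normal(0, 0.002))
                controls.append(_sample(m, 0.1 * m, r))
                m2 = 10 ** (np.log10(0.5) + offsets[r]
                            + rng.normal(0, 0.002))
                samples.append(_sample(m2, 0.1 * m2, r))
        corrected = correct_batch(samples, controls, factors=("flow_run",))
        ctrl_corr = correct_batch(controls, controls, factors=("flow_run",))

        def run_var(group):
            by_run = {}
            for s in group:
                by_run.setdefault(s.flow_run, []).append(s.m)
            return np.var([np.mean(v) for v in by_run.values()])

        assert run_var(ctrl_corr) < run_var(controls) / 10
        assert run_var(corrected) < run_var(samples) / 10

    def test_single_batch_identity(self):
        samples = [_sample(1.0, 0.1, "r1"), _sample(2.0, 0.3, "r1")]
        out = correct_batch(samples, samples[:1], factors=("flow_run",))
        for before, after in zip(samples, out):
            assert after.m == pytest.approx(before.m, rel=1e-9)

    def test_missing_batch_named(self):
        samples = [_sample(1.0, 0.1, "r9")]
        controls = [_sample(1.0, 0.1, "r1")]
        with pytest.raises(ValueError, match="r9"):
            correct_batch(samples, controls, factors=("flow_run",))


class TestAutofluorescence:
    def test_zero_blank_identity(self):
        samples = [_sample(1.0, 0.1, "r1")]
        blank = [SampleExpression(m=0.0, s=0.0, n_cells=1000)]
        out = subtract_autofluorescence(samples, blank)
        assert out[0].m == 1.0 and out[0].s == 0.1

    def test_arithmetic(self):
        samples = [_sample(1.05, 0.1, "r1")]
        blank = [SampleExpression(m=0.05, s=0.01, n_cells=1000)]
        out = subtract_autofluorescence(samples, blank)
        assert out[0].m == pytest.approx(1.00)
        assert out[0].s == pytest.approx(0.09)

    def test_null_genotype_near_zero(self):
        blank = [SampleExpression(m=0.051, s=0.012, n_cells=1000),
                 SampleExpression(m=0.049, s=0.008, n_cells=1000)]
        null = [SampleExpression(m=0.050, s=0.010, n_cells=1000)]
        out = subtract_autofluorescence(null, blank)
        assert abs(out[0].m) < 1e-9


class TestAggregate:
    def test_identical_to_reference_is_100pct(self):
        group = [_sample(1.0, 0.1, "r1") for _ in range(6)]
        summ = aggregate_genotype(group, group, genotype_id="g")
        assert summ.median_expression_pct == pytest.approx(100.0)
        assert summ.noise_pct["strength"] == pytest.approx(100.0)
        assert summ.n_replicates == 6

    def test_half_expression_is_50pct(self):
        group = [_sample(0.5, 0.05, "r1") for _ in range(6)]
        ref = [_sample(1.0, 0.1, "r1") for _ in range(6)]
        summ = aggregate_genotype(group, ref)
        assert summ.median_expression_pct == pytest.approx(50.0)


class TestEndToEnd:
    def test_recovery_within_3pct(self):
        # reference-noise conditions at the study's per-sample event count
        ev = gen_flow_events(1.0, 0.1, 10_000, seed=9)
        s = process_sample(ev)
        assert abs(s.m - 1.0) < 0.03
        assert abs(s.noise_strength - 0.01) < 0.0003

    def test_csv_round_trip(self, tmp_path):
        ev = gen_flow_events(1.0, 0.1, 1000, seed=10)
        path = tmp_path / "events.csv"
        write_events_csv(ev, path)
        back = read_events_csv(path)
        pd.testing.assert_frame_equal(ev, back)
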