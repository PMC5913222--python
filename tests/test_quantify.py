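import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from refnorm.io import CqRecord, InsufficientDataError, ValidationError
from refnorm.quantify import (
    FitError,
    InvalidEfficiencyError,
    StandardCurveWarning,
    collapse_replicates,
    fit_standard_curve,
    log2_pfaffl_ratio,
    normalize_dataset,
    pfaffl_ratio,
    remove_outliers,
)
from refnorm.simulate import GeneSpec, QpcrSimConfig, simulate_qpcr

from conftest import make_dataset


class TestStandardCurve:
    def test_perfect_doubling_geometry(self):
        pts = [(x, 30.0 - 3.321928094887362 * x) for x in (0.0, 1.0, 2.0)]
        curve = fit_standard_curve("G", pts)
        assert curve.slope == pytest.approx(-3.321928094887362, abs=1e-9)
        assert curve.efficiency == pytest.approx(2.0, abs=1e-9)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_efficiency_from_slope(self):
        pts = [(x, 30.0 - 3.6 * x) for x in (0.0, 1.0, 2.0, 3.0)]
        curve = fit_standard_curve("G", pts)
        assert curve.efficiency == pytest.approx(10 ** (1 / 3.6), rel=1e-9)
        assert curve.efficiency == pytest.approx(1.8957, abs=1e-4)

    def test_low_r_squared_warns_not_raises(self):
        # noisy series constructed to land below the 0.99 acceptance line
        pts = [(0.0, 30.0), (1.0, 27.5), (2.0, 22.5), (3.0, 21.0)]
        with pytest.warns(StandardCurveWarning, match="0.99"):
            curve = fit_standard_curve("G", pts)
        assert curve.r_squared < 0.99

    def test_noiseless_ols_recovery(self):
        rng = np.random.default_rng(5)
        slope, intercept = -3.45, 31.2
        xs = rng.uniform(0, 4, 8)
        pts = [(x, intercept + slope * x) for x in xs]
        curve = fit_standard_curve("G", pts)
        assert curve.slope == pytest.approx(slope, abs=1e-9)
        assert curve.intercept == pytest.approx(intercept, abs=1e-9)

    def test_insufficient_points(self):
        with pytest.raises(InsufficientDataError):
            fit_standard_curve("G", [(0, 30), (1, 27)])
        with pytest.raises(InsufficientDataError):
            fit_standard_curve("G", [(0, 30), (0, 30.1), (0, 29.9)])

    def test_positive_slope_rejected(self):
        with pytest.raises(FitError):
            fit_standard_curve("G", [(0, 25.0), (1, 27.0), (2, 29.0)])


class TestCollapseReplicates:
    def _record(self, *cqs):
        return CqRecord("s", "RF", "G", "P1", tuple(cqs))

    @pytest.mark.parametrize(
        "reps,passed",
        [
            ((25.00, 25.00), True),   # sd 0
            ((25.00, 25.10), False),  # sd = 0.1/sqrt(2) ~ 0.0707 >= 0.05
            ((25.00, 25.06), True),   # sd ~ 0.0424 < 0.05
        ],
    )
    def test_duplicate_sd_threshold(self, reps, passed):
        c = collapse_replicates(self._record(*reps))
        assert c.passed_qc is passed
        assert c.mean_cq == pytest.approx(np.mean(reps))
        assert c.replicate_sd == pytest.approx(abs(reps[1] - reps[0]) / math.sqrt(2))

    def test_single_replicate_passes_with_zero_sd(self):
        c = collapse_replicates(self._record(24.5))
        assert c.replicate_sd == 0.0 and c.passed_qc


class TestPfafflRatio:
    def test_identical_shifts_cancel(self):
        assert pfaffl_ratio(25, 26, 2.0, 25, 26, 2.0) == pytest.approx(1.0)

    def test_one_cycle_difference_doubles(self):
        assert pfaffl_ratio(24, 26, 2.0, 25, 26, 2.0) == pytest.approx(2.0)

    def test_mixed_efficiencies(self):
        # dCq_t = 1.5 at E 1.9, dCq_r = -0.5 at E 2.0
        r = pfaffl_ratio(27.0, 28.5, 1.9, 29.5, 29.0, 2.0)
        assert r == pytest.approx(1.9**1.5 * 2.0**0.5, rel=1e-12)
        assert r == pytest.approx(3.704, abs=2e-3)

    def test_invalid_efficiency(self):
        with pytest.raises(InvalidEfficiencyError):
            pfaffl_ratio(25, 26, 1.0, 25, 26, 2.0)
        with pytest.raises(InvalidEfficiencyError):
            pfaffl_ratio(25, 26, 2.0, 25, 26, 0.9)

    @given(
        cq_t=st.floats(20, 32), cq_r=st.floats(20, 32),
        e_t=st.floats(1.6, 2.1), e_r=st.floats(1.6, 2.1),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_sample_cq(self, cq_t, cq_r, e_t, e_r):
        """R strictly decreasing in target Cq, increasing in reference Cq."""
        base = log2_pfaffl_ratio(cq_t, 28, e_t, cq_r, 28, e_r)
        assert log2_pfaffl_ratio(cq_t + 0.5, 28, e_t, cq_r, 28, e_r) < base
        assert log2_pfaffl_ratio(cq_t, 28, e_t, cq_r + 0.5, 28, e_r) > base


class TestNormalizeDataset:
    def test_self_normalization_identity(self, small_dataset):
        norm = normalize_dataset(small_dataset, "TGT", "TGT", allow_self=True)
        for v in norm:
            assert v.ratio == pytest.approx(1.0, abs=1e-12)

    def test_global_cq_shift_cancels_at_equal_efficiency(self, small_dataset):
        norm0 = normalize_dataset(small_dataset, "TGT", "REF")
        shifted = {}
        for r in small_dataset.records:
            delta = 0.7 if r.sample_id == "t2" else 0.0
            shifted[(r.sample_id, r.group_label, r.gene_id)] = tuple(
                cq + delta for cq in r.replicate_cq
            )
        ds2 = make_dataset(shifted)
        norm1 = normalize_dataset(ds2, "TGT", "REF")
        r0 = {v.sample_id: v.ratio for v in norm0}
        r1 = {v.sample_id: v.ratio for v in norm1}
        assert r1["t2"] == pytest.approx(r0["t2"], rel=1e-12)

    def test_matches_scalar_recomputation_on_simulated_data(self):
        cfg = QpcrSimConfig(
            genes=[GeneSpec("TGT", 5, -0.2, 1.95), GeneSpec("REF", 8, 0.0, 2.0)],
            n_per_group=6, seed=42,
        )
        ds, _ = simulate_qpcr(cfg)
        eff = {"TGT": 1.95, "REF": 2.0}
        norm = normalize_dataset(ds, "TGT", "REF", eff, control_label="RF")
        # independent scalar recomputation of every ratio
        mean_cq = {}
        for r in ds.records:
            mean_cq[(r.sample_id, r.gene_id)] = float(np.mean(r.replicate_cq))
        controls = [s for s in ds.samples if s.startswith("RF")]
        cal = {
            g: float(np.mean([mean_cq[(s, g)] for s in controls]))
            for g in ("TGT", "REF")
        }
        for v in norm:
            expected = (
                eff["TGT"] ** (cal["TGT"] - mean_cq[(v.sample_id, "TGT")])
                / eff["REF"] ** (cal["REF"] - mean_cq[(v.sample_id, "REF")])
            )
            assert v.ratio == pytest.approx(expected, rel=1e-9)

    def test_qc_failures_excluded_with_reason(self, small_dataset):
        noisy = {}
        for r in small_dataset.records:
            if r.sample_id == "c1" and r.gene_id == "TGT":
                noisy[(r.sample_id, r.group_label, r.gene_id)] = (25.0, 25.3)
            else:
                noisy[(r.sample_id, r.group_label, r.gene_id)] = r.replicate_cq
        ds = make_dataset(noisy)
        norm = normalize_dataset(ds, "TGT", "REF")
        assert "c1" not in {v.sample_id for v in norm}
        assert any(e.sample_id == "c1" and "SD" in e.reason for e in norm.exclusions)

    def test_self_without_flag_rejected(self, small_dataset):
        with pytest.raises(ValidationError):
            normalize_dataset(small_dataset, "TGT", "TGT")


class TestRemoveOutliers:
    def test_all_equal_none_removed(self):
        kept, removed = remove_outliers([2.0] * 5)
        assert removed == [] and kept == [2.0] * 5

    def test_small_n_masking(self):
        # the candidate inflates the SD enough to hide itself
        kept, removed = remove_outliers([1.0, 1.0, 1.0, 1.0, 10.0])
        assert removed == []

    def test_clear_outlier_removed(self):
        values = [1.0] * 9 + [3.0]
        kept, removed = remove_outliers(values)
        assert removed == [9]
        assert kept == [1.0] * 9

    def test_too_few_values(self):
        with pytest.raises(InsufficientDataError):
            remove_outliers([1.0, 2.0])

    @given(st.permutations(list(range(8))))
    @settings(max_examples=30, deadline=None)
    def test_permutation_equivariance(self, perm):
        values = [1.0, 1.1, 0.9, 1.05, 0.95, 1.0, 1.02, 5.0]
        permuted = [values[i] for i in perm]
        _, removed = remove_outliers(permuted)
        removed_values = {permuted[i] for i in removed}
        _, removed_ref = remove_outliers(values)
        assert removed_values == {values[i] for i in removed_ref}
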