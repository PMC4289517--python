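"""QC-RLSC curve fitting, batch correction, integration, filters."""

import numpy as np
import pandas as pd
import pytest

import metabodrift as md
from metabodrift._utils import ValidationError
from metabodrift.correction import (
    LoessParams,
    UncorrectableFeature,
    compute_rsd,
    fit_correction_curve,
)
from metabodrift.filters import (
    REASON_PRESENCE,
    REASON_QC_RSD,
    REASON_RATIO,
    information_filter,
    qa_filter,
)
from metabodrift.matrix import IntegratedMatrix


class TestComputeRsd:
    def test_constant_input_is_zero(self):
        assert compute_rsd([10, 10, 10]) == 0.0

    def test_known_value(self):
        # sample SD 2 over mean 10
        assert compute_rsd([8, 10, 12]) == pytest.approx(20.0)

    def test_insufficient_replicates(self):
        with pytest.raises(ValidationError):
            compute_rsd([5])

    def test_zero_mean(self):
        with pytest.raises(ValidationError):
            compute_rsd([-1.0, 1.0])

    def test_missing_values_ignored(self):
        assert compute_rsd([8, np.nan, 10, 12]) == pytest.approx(20.0)


class TestFitCorrectionCurve:
    positions = np.arange(1, 22)

    def test_constant_qc_gives_constant_curve(self):
        qc = [(p, 5.0) for p in (1, 6, 11, 16, 21)]
        curve = fit_correction_curve(qc, self.positions)
        np.testing.assert_allclose(curve.factors, 5.0)

    def test_linear_trend_matches_least_squares_line(self):
        """Noiseless linear QC trend: the fitted curve equals the
        least-squares line at the QC positions to 1e-6 relative."""
        xs = np.array([1.0, 6.0, 11.0, 16.0, 21.0])
        ys = 100.0 - 2.0 * xs
        curve = fit_correction_curve(list(zip(xs, ys)), self.positions)
        slope, intercept = np.polyfit(xs, ys, 1)
        np.testing.assert_allclose(
            curve.factor_at(xs), slope * xs + intercept, rtol=1e-6
        )
        # spline through collinear points stays linear between QCs
        np.testing.assert_allclose(
            curve.factor_at([8]), slope * 8 + intercept, rtol=1e-6
        )

    def test_too_few_qc_points_flagged(self):
        qc = [(1, 5.0), (6, 5.0), (11, 5.0)]
        with pytest.raises(UncorrectableFeature):
            fit_correction_curve(qc, self.positions, LoessParams(min_qc_points=4))

    def test_constant_extrapolation_outside_terminal_qcs(self):
        xs = np.array([5.0, 9.0, 13.0, 17.0])
        ys = np.array([10.0, 8.0, 6.0, 4.0])
        curve = fit_correction_curve(list(zip(xs, ys)), self.positions)
        np.testing.assert_allclose(curve.factor_at([1, 2, 3, 4]),
                                   curve.factor_at([5])[0])
        np.testing.assert_allclose(curve.factor_at([18, 21]),
                                   curve.factor_at([17])[0])

    def test_non_positive_fit_falls_back_to_median(self):
        xs = np.array([1.0, 6.0, 11.0, 16.0, 21.0])
        ys = np.array([20.0, 10.0, 0.5, 0.2, 0.1])  # would cross zero if
        # extrapolated linearly; force fallback with a steeper descent
        ys = np.array([50.0, 1.0, 50.0, 1.0, -0.0 + 0.001])
        curve = fit_correction_curve(list(zip(xs, ys)), self.positions)
        assert (curve.factors > 0).all()
        if curve.fallback:
            np.testing.assert_allclose(curve.factors, np.median(ys))

    def test_strict_positivity_invariant(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            xs = np.sort(rng.choice(np.arange(1.0, 22.0), size=6, replace=False))
            ys = np.abs(rng.normal(10, 5, size=6)) + 0.1
            curve = fit_correction_curve(list(zip(xs, ys)), self.positions)
            assert (curve.factors > 0).all()


class TestCorrectAndIntegrate:
    def _correct_all(self, batches, **kw):
        out = []
        for b in batches:
            curves, _ = md.fit_batch_curves(b, LoessParams(**kw))
            out.append(md.correct_batch(b, curves))
        return out

    def test_identity_on_clean_data(self, clean_study):
        """Drift-free, noise-free data pass correct -> integrate unchanged."""
        corrected = self._correct_all(clean_study["batches"])
        integ = md.integrate_study(corrected)
        truth = clean_study["truth"].subject_truth()
        values = integ.values.loc[truth.index, truth.columns]
        rel = np.abs(values.to_numpy() / truth.to_numpy() - 1.0)
        assert np.nanmax(rel) < 1e-9

    def test_corrected_qcs_near_unity_before_unnormalization(self, clean_study):
        corrected = self._correct_all(clean_study["batches"])
        for b in corrected:
            np.testing.assert_allclose(
                b.qc_values().to_numpy(dtype=float), 1.0, rtol=1e-9
            )

    def test_missing_curve_sets_feature_missing(self, small_study):
        b = small_study["batches"][0]
        curves, _ = md.fit_batch_curves(b)
        fid = b.feature_ids[0]
        curves = {k: v for k, v in curves.items() if k[0] != fid}
        corrected = md.correct_batch(b, curves)
        assert corrected.values[fid].isna().all()

    def test_integration_order_invariance(self, small_study):
        corrected = self._correct_all(small_study["batches"])
        a = md.integrate_study(corrected)
        b = md.integrate_study(corrected[::-1])
        common = sorted(a.values.index)
        pd.testing.assert_frame_equal(
            a.values.loc[common, sorted(a.values.columns)],
            b.values.loc[common, sorted(b.values.columns)],
        )

    def test_feature_in_single_batch_yields_nan_elsewhere(self, small_study):
        corrected = self._correct_all(small_study["batches"])
        only = corrected[0].feature_ids[0]
        trimmed = corrected[1].copy()
        trimmed.values = trimmed.values.drop(columns=[only])
        trimmed.features = trimmed.features.drop(index=[only])
        integ = md.integrate_study([corrected[0], trimmed])
        subj_b2 = corrected[1].subject_values().index
        assert integ.values.loc[subj_b2, only].isna().all()
        subj_b1 = corrected[0].subject_values().index
        assert integ.values.loc[subj_b1, only].notna().all()


def _toy_integrated(qc_rsds, presences, subject_rsds=None, n_subj=50, n_qc=20,
                    seed=0):
    """Construct an IntegratedMatrix with prescribed per-feature QC RSD,
    presence fraction, and (approximately) subject RSD."""
    rng = np.random.default_rng(seed)
    n_feat = len(qc_rsds)
    cols = [f"F{i:03d}" for i in range(n_feat)]
    qc = np.empty((n_qc, n_feat))
    subj = np.empty((n_subj, n_feat))
    for j, (qr, pres) in enumerate(zip(qc_rsds, presences)):
        # exact sample RSD by construction: scale a fixed-shape vector
        base = rng.normal(0, 1, size=n_qc)
        base = (base - base.mean()) / base.std(ddof=1)
        qc[:, j] = 100.0 + qr * base  # mean 100, sample SD = qr -> RSD = qr %
        sr = 50.0 if subject_rsds is None else subject_rsds[j]
        sbase = rng.normal(0, 1, size=n_subj)
        sbase = (sbase - sbase.mean()) / sbase.std(ddof=1)
        subj[:, j] = 100.0 + sr * sbase
        n_miss = int(round((1 - pres) * n_subj))
        if n_miss:
            subj[:n_miss, j] = np.nan
    values = pd.DataFrame(subj, columns=cols,
                          index=[f"S{i:03d}" for i in range(n_subj)])
    qc_values = pd.DataFrame(qc, columns=cols,
                             index=[f"QC{i:03d}" for i in range(n_qc)])
    features = pd.DataFrame({"platform": "UPLC_pos"}, index=pd.Index(cols))
    return IntegratedMatrix(values=values, qc_values=qc_values, features=features)


class TestFilters:
    def test_rsd_tolerance_platform_dependence(self):
        """QC RSD 25 % fails the 20 % UPLC tolerance but passes 30 % GC."""
        m = _toy_integrated([25.0, 10.0], [1.0, 1.0])
        kept_uplc, rep_u = qa_filter(m, platform="UPLC_pos")
        assert list(kept_uplc.values.columns) == ["F001"]
        assert rep_u.table.loc["F000", "reason"] == REASON_QC_RSD
        kept_gc, _ = qa_filter(m, rsd_tolerance=30.0)
        assert list(kept_gc.values.columns) == ["F000", "F001"]

    def test_presence_boundary(self):
        """79 % presence removed; exactly 80 % retained."""
        m = _toy_integrated([5.0, 5.0], [0.79, 0.80], n_subj=100)
        kept, rep = qa_filter(m, platform="UPLC_pos")
        assert list(kept.values.columns) == ["F001"]
        assert rep.table.loc["F000", "reason"] == REASON_PRESENCE

    def test_known_fail_counts(self):
        """10 features, 3 failing the RSD rule: exactly 7 survive."""
        qc_rsds = [5, 25, 10, 30, 15, 8, 22, 12, 18, 3]
        m = _toy_integrated(qc_rsds, [1.0] * 10)
        kept, rep = qa_filter(m, platform="UPLC_pos")
        assert kept.values.shape[1] == 7
        assert rep.n_out == 7

    def test_information_filter_boundaries(self):
        """Ratio 3.0 retained, 1.4 removed, exactly 1.5 retained (strict).

        Values are chosen so RSDs are exactly representable: QC [8,10,12]
        gives RSD 20 %, subjects scaled multiples give 60 %, 28 %, 30 %.
        """
        qc = pd.DataFrame({
            "F000": [8.0, 10.0, 12.0],
            "F001": [8.0, 10.0, 12.0],
            "F002": [8.0, 10.0, 12.0],
        }, index=["QC1", "QC2", "QC3"])
        subj = pd.DataFrame({
            "F000": [4.0, 10.0, 16.0],   # SD 6, RSD 60 -> ratio 3.0
            "F001": [7.2, 10.0, 12.8],   # SD 2.8, RSD 28 -> ratio 1.4
            "F002": [7.0, 10.0, 13.0],   # SD 3, RSD 30 -> ratio exactly 1.5
        }, index=["S1", "S2", "S3"])
        features = pd.DataFrame({"platform": "UPLC_pos"}, index=qc.columns)
        m = IntegratedMatrix(values=subj, qc_values=qc, features=features)
        kept, rep = information_filter(m)
        assert list(kept.values.columns) == ["F000", "F002"]
        assert rep.table.loc["F001", "reason"] == REASON_RATIO

    def test_zero_qc_rsd_retained(self):
        m = _toy_integrated([0.0, 10.0], [1.0, 1.0], subject_rsds=[5.0, 30.0])
        kept, rep = information_filter(m)
        assert "F000" in kept.values.columns
        assert np.isinf(rep.table.loc["F000", "rsd_ratio"])

    def test_filters_idempotent(self):
        qc_rsds = [5, 25, 10, 30, 15]
        m = _toy_integrated(qc_rsds, [1.0, 1.0, 0.5, 1.0, 0.9])
        once, _ = qa_filter(m, platform="UPLC_pos")
        twice, rep = qa_filter(once, platform="UPLC_pos")
        assert list(twice.values.columns) == list(once.values.columns)
        info_once, _ = information_filter(twice)
        info_twice, _ = information_filter(info_once)
        assert list(info_twice.values.columns) == list(info_once.values.columns)
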