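"""Bead identification, normalization and debarcoding."""

import numpy as np
import pandas as pd
import pytest

from cytopipe.panel import BarcodeScheme, default_scheme
from cytopipe.preprocess import (BarcodeAssignment, NormalizationFactors,
                                 UNASSIGNED, apply_normalization,
                                 assign_barcodes, debarcode, fit_normalization,
                                 identify_beads, mahalanobis_filter,
                                 pooled_bead_reference)
from cytopipe.synthetic import (EventMatrix, SampleMeta, TruthConfig,
                                make_truth, simulate_batch,
                                simulate_doublet_events, simulate_sample,
                                experiment_metas)

CODE_A = (1, 1, 0, 1, 0, 0)
CODE_B = (0, 1, 1, 0, 1, 0)


@pytest.fixture(scope="module")
def drifting_truth():
    # global 2-fold sensitivity decline over the run
    return make_truth(TruthConfig(drift_coeffs=(1.0, -0.5, 0.0)), seed=2)


@pytest.fixture(scope="module")
def flat_truth():
    return make_truth(TruthConfig(drift_coeffs=(1.0,)), seed=2)


def beads_of(ev, mask):
    return EventMatrix(ev.data[mask].reset_index(drop=True), ev.panel)


class TestIdentifyBeads:
    def test_perfect_recall_and_precision(self, flat_truth):
        meta = SampleMeta("mock01", "mock", "PBMC", "UNSTIM",
                          barcode_code=CODE_A)
        ev = simulate_sample(flat_truth, meta, 20_000, 0.05)
        mask = identify_beads(ev)
        is_bead = ev.truth["is_bead"].to_numpy()
        assert (mask & is_bead).sum() == is_bead.sum()      # recall 1.0
        assert (mask & ~is_bead).sum() == 0                 # precision 1.0

    def test_no_beads_gives_empty_mask(self, flat_truth):
        meta = SampleMeta("mock01", "mock", "PBMC", "UNSTIM",
                          barcode_code=CODE_A)
        ev = simulate_sample(flat_truth, meta, 5000, 0.0)
        with pytest.warns(UserWarning, match="bead threshold"):
            mask = identify_beads(ev)
        assert not mask.any()

    def test_requires_bead_channel(self, flat_truth, meta):
        ev = simulate_sample(flat_truth, meta, 100, 0.0)
        with pytest.raises(ValueError):
            identify_beads(ev, bead_channels=[])


class TestNormalization:
    def test_flat_drift_gives_unit_multipliers(self, flat_truth):
        meta = SampleMeta("mock01", "mock", "PBMC", "UNSTIM",
                          barcode_code=CODE_A)
        ev = simulate_sample(flat_truth, meta, 40_000, 0.10)
        beads = beads_of(ev, identify_beads(ev))
        f = fit_normalization(beads, 500)
        np.testing.assert_allclose(f.corrections.to_numpy(), 1.0, rtol=0.05)

    def test_injected_drift_recovered_as_inverse(self, drifting_truth):
        """Fitted multiplier approximates 1/g(t) for the injected g."""
        meta = SampleMeta("mock01", "mock", "PBMC", "UNSTIM",
                          barcode_code=CODE_A)
        ev = simulate_sample(drifting_truth, meta, 60_000, 0.10)
        beads = beads_of(ev, identify_beads(ev))
        f = fit_normalization(beads, 500)
        g = drifting_truth.drift("Bead1", f.time_knots)
        rel = f.corrections["Bead1"].to_numpy() * g
        rel /= rel.mean()     # overall scale set by the reference median
        assert np.abs(rel - 1).max() <= 0.05

    def test_apply_identity_when_multipliers_one(self, flat_truth):
        meta = SampleMeta("mock01", "mock", "PBMC", "UNSTIM",
                          barcode_code=CODE_A)
        ev = simulate_sample(flat_truth, meta, 2000, 0.0)
        chans = ev.panel.bead_channels
        f = NormalizationFactors(
            time_knots=np.array([0.0, 600.0]),
            corrections=pd.DataFrame(np.ones((2, len(chans))), columns=chans),
            reference=pd.Series(1.0, index=chans))
        out = apply_normalization(ev, f)
        pd.testing.assert_frame_equal(out.data, ev.data)

    def test_idempotence_refit_after_apply(self, drifting_truth):
        meta = SampleMeta("mock01", "mock", "PBMC", "UNSTIM",
                          barcode_code=CODE_A)
        ev = simulate_sample(drifting_truth, meta, 60_000, 0.10)
        mask = identify_beads(ev)
        f = fit_normalization(beads_of(ev, mask), 500)
        corrected = apply_normalization(ev, f)
        f2 = fit_normalization(beads_of(corrected, mask), 500)
        assert np.abs(f2.corrections.to_numpy() - 1).max() <= 0.05

    def test_cross_batch_reference_scales_by_ratio(self, flat_truth):
        """Two batches whose bead medians differ 2x get multipliers
        differing by a factor of about 2 under a shared reference."""
        meta = SampleMeta("mock01", "mock", "PBMC", "UNSTIM",
                          barcode_code=CODE_A)
        ev1 = simulate_sample(flat_truth, meta, 30_000, 0.10)
        beads1 = beads_of(ev1, identify_beads(ev1))
        beads2 = beads1.copy()
        for ch in beads2.panel.bead_channels:
            beads2.data[ch] *= 2.0
        ref = pooled_bead_reference([beads1, beads2])
        f1 = fit_normalization(beads1, 500, reference=ref)
        f2 = fit_normalization(beads2, 500, reference=ref)
        ratio = (f1.corrections.to_numpy().mean()
                 / f2.corrections.to_numpy().mean())
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_negative_multiplier_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            NormalizationFactors(
                time_knots=np.array([0.0, 1.0]),
                corrections=pd.DataFrame({"Bead1": [1.0, -0.5]}),
                reference=pd.Series({"Bead1": 1.0}))

    def test_non_increasing_knots_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            NormalizationFactors(
                time_knots=np.array([1.0, 1.0]),
                corrections=pd.DataFrame({"Bead1": [1.0, 1.0]}),
                reference=pd.Series({"Bead1": 1.0}))

    def test_too_few_beads_rejected(self, flat_truth):
        meta = SampleMeta("mock01", "mock", "PBMC", "UNSTIM",
                          barcode_code=CODE_A)
        ev = simulate_sample(flat_truth, meta, 1000, 0.05)
        beads = beads_of(ev, identify_beads(ev))
        with pytest.raises(ValueError, match="window_size"):
            fit_normalization(beads, 500)


@pytest.fixture(scope="module")
def batch16(flat_truth):
    metas = experiment_metas(flat_truth)[0][:16]
    ev, scheme = simulate_batch(flat_truth, metas, n_events=2000,
                                bead_fraction=0.0, doublet_rate=0.02)
    return ev, scheme


class TestAssignBarcodes:
    def test_noiseless_singlet_assignment_exact(self, batch16):
        ev, scheme = batch16
        res = assign_barcodes(ev, scheme)
        singlet = ~ev.truth["is_doublet"].to_numpy()
        got = res.table["sample_id"].to_numpy()[singlet]
        want = ev.truth["sample_id"].to_numpy()[singlet]
        assert (got == want).all()

    def test_doublets_unassigned_low_separation(self, batch16):
        ev, scheme = batch16
        res = assign_barcodes(ev, scheme)
        doublet = ev.truth["is_doublet"].to_numpy()
        tab = res.table[doublet]
        assert (tab["sample_id"] == UNASSIGNED).all()
        assert (tab["separation"] < 0.3).all()

    def test_separation_defined_for_every_event(self, batch16):
        ev, scheme = batch16
        res = assign_barcodes(ev, scheme)
        assert res.table["separation"].notna().all()

    def test_scale_equivariance_in_separated_regime(self, batch16):
        """Doubling one raw barcode channel leaves assignments unchanged."""
        ev, scheme = batch16
        before = assign_barcodes(ev, scheme).table["sample_id"]
        scaled = ev.copy()
        scaled.data["BC3"] *= 2.0
        after = assign_barcodes(scaled, scheme).table["sample_id"]
        assert (before == after).all()

    def test_invalid_scheme_rejected(self):
        with pytest.raises(ValueError, match="k"):
            BarcodeScheme({"s1": (1, 1, 1), "s2": (1, 1, 1)})
        with pytest.raises(ValueError, match="duplicate"):
            BarcodeScheme({"s1": (1, 1, 0), "s2": (1, 1, 0)})


class TestMahalanobisFilter:
    @staticmethod
    def _toy_assignment(n=300, seed=0, outlier_dist=5.0):
        rng = np.random.default_rng(seed)
        r = rng.normal(0.0, 1.0, size=(n, 6))
        r[0] = 0.0                                 # event at the centroid
        r[1] = np.r_[outlier_dist, 0, 0, 0, 0, 0]  # event 5 units out
        table = pd.DataFrame({
            "sample_id": ["s1"] * n, "separation": 1.0,
            "mahalanobis": np.nan, "reason": ""})
        return BarcodeAssignment(table=table, rescaled=r)

    @staticmethod
    def _dummy_events(n, panel_truth):
        meta = SampleMeta("mock01", "mock", "PBMC", "UNSTIM",
                          barcode_code=CODE_A)
        return simulate_sample(panel_truth, meta, n, 0.0)

    def test_centroid_event_retained_with_near_zero_distance(self, flat_truth):
        asg = self._toy_assignment()
        ev = self._dummy_events(300, flat_truth)
        scheme = BarcodeScheme({"s1": CODE_A, "s2": CODE_B})
        out = mahalanobis_filter(ev, asg, scheme, max_dist=30.0)
        assert out.table.loc[0, "sample_id"] == "s1"
        assert out.table.loc[0, "mahalanobis"] < 0.5

    def test_plain_distance_convention_removes_far_event(self, flat_truth):
        """Spherical unit covariance, event 5 units out, plain-distance
        threshold 3: removed (5 > 3)."""
        asg = self._toy_assignment()
        ev = self._dummy_events(300, flat_truth)
        scheme = BarcodeScheme({"s1": CODE_A, "s2": CODE_B})
        out = mahalanobis_filter(ev, asg, scheme, max_dist=3.0, squared=False)
        assert out.table.loc[1, "sample_id"] == UNASSIGNED
        assert out.table.loc[1, "reason"] == "distance"

    def test_contamination_removed_genuine_kept(self, flat_truth):
        """5% of a sample's events swapped for another code's events are
        flagged by the distance filter; genuine losses stay tiny."""
        meta_a = SampleMeta("mock01", "mock", "PBMC", "UNSTIM",
                            barcode_code=CODE_A)
        meta_b = SampleMeta("mock02", "mock", "PBMC", "UNSTIM",
                            barcode_code=CODE_B)
        ev_a = simulate_sample(flat_truth, meta_a, 4000, 0.0)
        ev_b = simulate_sample(flat_truth, meta_b, 200, 0.0)
        data = pd.concat([ev_a.data, ev_b.data], ignore_index=True)
        ev = EventMatrix(data, ev_a.panel)
        scheme = BarcodeScheme({"A": CODE_A, "B": CODE_B})
        n = len(data)
        table = pd.DataFrame({"sample_id": ["A"] * n, "separation": 1.0,
                              "mahalanobis": np.nan, "reason": ""})
        asg = BarcodeAssignment(table=table)
        out = mahalanobis_filter(ev, asg, scheme, max_dist=30.0)
        kept = out.table["sample_id"].to_numpy()
        contaminant = np.arange(n) >= 4000
        assert (kept[contaminant] == UNASSIGNED).mean() >= 0.90
        assert (kept[~contaminant] == UNASSIGNED).mean() <= 0.02

    def test_small_sample_skipped_with_warning(self, flat_truth):
        ev = self._dummy_events(5, flat_truth)
        scheme = BarcodeScheme({"s1": CODE_A, "s2": CODE_B})
        table = pd.DataFrame({"sample_id": ["s1"] * 5, "separation": 1.0,
                              "mahalanobis": np.nan, "reason": ""})
        asg = BarcodeAssignment(table=table,
                                rescaled=np.zeros((5, 6)))
        with pytest.warns(UserWarning, match="skipping"):
            out = mahalanobis_filter(ev, asg, scheme)
        assert (out.table["sample_id"] == "s1").all()


class TestDebarcode:
    def test_partition_and_yield_conservation(self, batch16):
        ev, scheme = batch16
        res = debarcode(ev, scheme)
        n_split = sum(s.n_events for s in res.samples.values())
        n_assigned = res.assignment.assigned.sum()
        assert n_split == n_assigned
        assert res.yield_report["count"].sum() == ev.n_events
        assert res.yield_report["fraction"].sum() == pytest.approx(1.0)

    def test_sixteen_nonempty_outputs(self, batch16):
        ev, scheme = batch16
        res = debarcode(ev, scheme)
        assert len(res.samples) == 16
        assert all(s.n_events > 0 for s in res.samples.values())

    def test_all_doublet_batch_fully_unassigned(self, flat_truth):
        a = SampleMeta("mock01", "mock", "PBMC", "UNSTIM", barcode_code=CODE_A)
        b = SampleMeta("mock02", "mock", "PBMC", "UNSTIM", barcode_code=CODE_B)
        ev = simulate_doublet_events(flat_truth, a, b, 500)
        scheme = BarcodeScheme({"A": CODE_A, "B": CODE_B})
        res = debarcode(ev, scheme)
        assert not res.assignment.assigned.any()

    @pytest.mark.parametrize("cutoffs", [(0.1, 0.3, 0.6), (30.0, 10.0, 3.0)])
    def test_monotone_yield(self, batch16, cutoffs):
        """Raising the separation cutoff or lowering max_dist never raises
        the number of assigned events."""
        ev, scheme = batch16
        vary_sep = cutoffs[0] < 1
        counts = []
        for c in cutoffs:
            if vary_sep:
                res = debarcode(ev, scheme, separation_cutoff=c)
            else:
                res = debarcode(ev, scheme, max_dist=c)
            counts.append(int(res.assignment.assigned.sum()))
        assert counts == sorted(counts, reverse=True)
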