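"""Single-molecule event calling, class assignment and kinetics measures."""

import numpy as np
import pandas as pd
import pytest

from chrombind import smtrack as smt
from chrombind.synthetic import gen_interphase_nucleus, gen_sm_dataset, render_spot_frame


def window_fits(xy, i, j, radius):
    """A window fits a 160-nm-diameter region when every member lies within
    the disc radius of the window centroid (computed naively here)."""
    pts = np.asarray(xy[i : j + 1], dtype=float)
    centroid = pts.mean(axis=0)
    return max(float(np.hypot(*(p - centroid))) for p in pts) <= radius


def brute_force_events(frames, xy, radius, min_frames):
    """Independent oracle: grow every candidate window explicitly.

    Starting from each free localization, the window extends one
    consecutive frame at a time while the full window still fits the
    confinement disc (each extension re-tested from scratch); the first
    violation or frame gap ends it.
    """
    n = len(frames)
    events = []
    i = 0
    while i < n:
        j = i
        while (
            j + 1 < n
            and frames[j + 1] == frames[j] + 1
            and window_fits(xy, i, j + 1, radius)
        ):
            j += 1
        if j - i + 1 >= min_frames:
            events.append((int(frames[i]), j - i + 1))
            i = j + 1
        else:
            i += 1
    return events


def _table(frames, xy, mid=0):
    return pd.DataFrame(
        {"molecule_id": mid, "frame": frames, "x": [p[0] for p in xy], "y": [p[1] for p in xy]}
    )


class TestEventCalling:
    def test_two_close_localizations_make_one_event(self):
        locs = _table([0, 1], [(0.0, 0.0), (100.0, 0.0)])
        events = smt.call_bound_events(locs, scheme="i")
        assert len(events) == 1
        assert events[0].duration == pytest.approx(0.1)  # >= 100 ms in scheme i

    def test_minimal_event_duration_scheme_ii(self):
        locs = _table([0, 1], [(0.0, 0.0), (50.0, 50.0)])
        events = smt.call_bound_events(locs, scheme="ii")
        assert events[0].duration == pytest.approx(1.2)

    def test_distant_localizations_make_no_event(self):
        locs = _table([0, 1], [(0.0, 0.0), (200.0, 0.0)])
        assert smt.call_bound_events(locs, scheme="i") == []

    def test_frame_gap_terminates_event(self):
        locs = _table([0, 1, 3, 4], [(0, 0), (10, 0), (12, 0), (8, 0)])
        events = smt.call_bound_events(locs, scheme="i")
        assert [(e.start_frame, e.n_frames) for e in events] == [(0, 2), (3, 2)]

    def test_unsorted_input_rejected(self):
        locs = _table([1, 0], [(0, 0), (0, 0)])
        with pytest.raises(ValueError, match="sorted"):
            smt.call_bound_events(locs, scheme="i")

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 500))
        # mixture of sticky and jumpy displacement to exercise the criterion
        frames = np.cumsum(rng.choice([1, 1, 1, 2], size=n))
        steps = rng.choice([5.0, 60.0, 300.0], size=(n, 1)) * rng.standard_normal((n, 2))
        xy = np.cumsum(steps, axis=0)
        locs = _table(frames, xy)
        got = [(e.start_frame, e.n_frames) for e in smt.call_bound_events(locs, scheme="i")]
        assert got == brute_force_events(frames, xy, 80.0, 2)

    def test_durations_never_below_scheme_minimum(self):
        ds = gen_sm_dataset(n_molecules=200, frame_count=40, seed=0)
        events = smt.call_bound_events(ds.locs, scheme="i")
        assert all(e.duration >= 0.1 for e in events)
        ds2 = gen_sm_dataset(n_molecules=100, scheme="ii", tau_mean=5.0, frame_count=30, seed=1)
        events2 = smt.call_bound_events(ds2.locs, scheme="ii")
        assert all(e.duration >= 1.2 for e in events2)


class TestChromatinClasses:
    def test_round_trip_against_generator(self):
        nuc = gen_interphase_nucleus(noise_sd=0.0, seed=2)
        # generator labels: 1 high, 2 medium, 3 low; classifier: 3 bright .. 1 dark
        labels, areas = smt.classify_chromatin(
            nuc.dna, nuc.nucleus_mask, thresholds=(100.0, 220.0), pixel_size_um=nuc.pixel_size
        )
        assert np.array_equal(labels == 3, nuc.label_map == 1)
        assert np.array_equal(labels == 2, nuc.label_map == 2)
        assert np.array_equal(labels == 1, nuc.label_map == 3)

    def test_areas_partition_nucleus(self):
        nuc = gen_interphase_nucleus(noise_sd=5.0, seed=3)
        labels, areas = smt.classify_chromatin(
            nuc.dna, nuc.nucleus_mask, thresholds=(100.0, 220.0), pixel_size_um=nuc.pixel_size
        )
        assert sum(areas.values()) == pytest.approx(
            nuc.nucleus_mask.sum() * nuc.pixel_size**2
        )

    def test_constant_image_single_class(self):
        img = np.full((32, 32), 50.0)
        mask = np.ones((32, 32), bool)
        labels, areas = smt.classify_chromatin(img, mask, thresholds=(10.0, 20.0))
        assert areas["bright"] == pytest.approx(32 * 32 * 0.05**2)
        assert areas["dark"] == areas["intermediate"] == 0.0

    def test_unordered_thresholds_rejected(self):
        with pytest.raises(ValueError):
            smt.classify_chromatin(np.ones((8, 8)), np.ones((8, 8), bool), (5.0, 5.0))


class TestAssignEvents:
    def _event(self, start, x_nm, y_nm):
        return smt.BoundEvent(
            molecule_id=0, start_frame=start, n_frames=2, duration=0.1,
            centroid=(x_nm, y_nm), first_loc=(x_nm, y_nm),
        )

    def test_uses_most_recent_preceding_map(self):
        m0 = np.full((10, 10), 3, dtype=np.uint8)  # bright
        m5 = np.full((10, 10), 1, dtype=np.uint8)  # dark after drift
        events = [self._event(2, 250.0, 250.0), self._event(7, 250.0, 250.0)]
        smt.assign_events(events, {0: m0, 5: m5}, pixel_size_um=0.05)
        assert [e.chrom_class for e in events] == ["bright", "dark"]

    def test_no_preceding_dna_frame_unassigned(self):
        events = [self._event(2, 100.0, 100.0)]
        smt.assign_events(events, {5: np.full((10, 10), 2, np.uint8)}, pixel_size_um=0.05)
        assert events[0].chrom_class == "unassigned"

    def test_outside_nucleus_unassigned(self):
        cmap = np.zeros((10, 10), np.uint8)
        events = [self._event(0, 250.0, 250.0)]
        smt.assign_events(events, {0: cmap}, pixel_size_um=0.05)
        assert events[0].chrom_class == "unassigned"


class TestRates:
    def test_psi_on_direct_formula(self):
        assert smt.psi_on_rate(10, 100.0, 1000, 100.0) == pytest.approx(1e-6)
        assert smt.psi_on_rate(0, 100.0, 1000, 100.0) == 0.0

    def test_psi_on_invalid_denominator(self):
        with pytest.raises(ValueError):
            smt.psi_on_rate(1, 0.0, 10, 10.0)

    def test_residence_time_direct_formula(self):
        assert smt.residence_time([2.4, 0, 0, 0], 4) == pytest.approx(0.6)
        assert smt.residence_time([0, 0], 2) == 0.0

    def test_residence_time_bound_denominator(self):
        assert smt.residence_time([2.4, 0, 0, 0], 4, denominator="bound") == pytest.approx(2.4)

    def test_residence_time_validation(self):
        with pytest.raises(ValueError):
            smt.residence_time([1.0], 0)


class TestDetection:
    def test_blank_frame_empty(self):
        img = render_spot_frame([], noise_sd=2.0, seed=0)
        assert smt.detect_spots(img, bg_level=10.0) == []

    def test_single_spot_position_error(self):
        img = render_spot_frame([(20.3, 41.7)], amplitude=400.0, noise_sd=2.0, seed=1)
        dets = smt.detect_spots(img, bg_level=10.0, pixel_size_um=0.05)
        assert len(dets) == 1
        err = np.hypot(dets[0].x - 20.3 * 50, dets[0].y - 41.7 * 50)
        assert err < 20.0  # nm

    def test_two_separated_spots_recovered(self):
        img = render_spot_frame([(15.0, 15.0), (40.0, 45.0)], amplitude=400.0, noise_sd=2.0, seed=2)
        dets = smt.detect_spots(img, bg_level=10.0)
        assert len(dets) == 2

    def test_linking_keeps_immobile_molecules_separate(self):
        rows = []
        for f in range(5):
            rows.append({"frame": f, "x": 100.0, "y": 100.0})
            rows.append({"frame": f, "x": 3000.0, "y": 3000.0})
        linked = smt.link_molecules(pd.DataFrame(rows))
        assert linked["molecule_id"].nunique() == 2
        assert linked.groupby("molecule_id").size().tolist() == [5, 5]


class TestGeneratorKinetics:
    def test_zero_bound_fraction_means_zero_truth(self):
        ds = gen_sm_dataset(
            n_molecules=100, bound_fraction_per_class=(0, 0, 0), frame_count=20, seed=4
        )
        assert all(v == 0 for v in ds.true_psi_on.values())
        assert ds.true_tau_res == 0.0

    def test_immobile_everything_bound_one_event_each(self):
        ds = gen_sm_dataset(
            n_molecules=60,
            bound_fraction_per_class=(1, 1, 1),
            tau_mean=None,
            loc_error_nm=0.0,
            frame_count=20,
            seed=5,
        )
        events = smt.call_bound_events(ds.locs, scheme="i")
        assert len(events) == 60
        assert all(e.n_frames == 20 for e in events)

    def test_psi_estimate_within_three_se(self):
        ds = gen_sm_dataset(
            n_molecules=800,
            bound_fraction_per_class=(0.4, 0.2, 0.05),
            tau_mean=None,
            frame_count=50,
            seed=6,
        )
        events = smt.call_bound_events(ds.locs, scheme="i")
        events = smt.assign_events(events, ds.class_maps, pixel_size_um=ds.pixel_size_um)
        summary = smt.summarize_kinetics(
            events, ds.n_molecules, ds.class_areas, ds.t_recording, "i"
        )
        for c in ("bright", "intermediate", "dark"):
            assert abs(summary.psi_on[c] - ds.true_psi_on[c]) <= 3 * ds.psi_on_se[c]

    def test_invalid_class_areas_rejected(self):
        with pytest.raises(ValueError):
            gen_sm_dataset(class_areas=(0.0, 1.0, 1.0))
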