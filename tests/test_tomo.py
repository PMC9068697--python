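"""Centerline tracing, nearest-neighbour spacing, crossover estimation,
phase analysis, classification and helical averaging."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from filotwist.helix import (
    ACTIN,
    COFILACTIN,
    BundleSpec,
    FilamentSpec,
    HelicalParams,
    build_hexagonal_bundle,
    crossover_length,
)
from filotwist.synth import corrupt_volume, make_centerline, render_volume
from filotwist.tomo import (
    PitchEstimate,
    classify_bundle,
    classify_filament,
    estimate_crossover,
    filter_outliers,
    helical_average,
    nn_distances,
    phase_offset,
    resample_polyline,
    trace_centerlines,
    width_signal,
)


class TestResamplePolyline:
    def test_straight_segment_counts(self):
        poly = np.array([[0, 0, 0], [10, 0, 0]], float)
        out = resample_polyline(poly, 1.0)
        assert len(out) == 11
        assert np.allclose(out[0], poly[0]) and np.allclose(out[-1], poly[-1])

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            resample_polyline(np.array([[0, 0, 0]], float), 1.0)

    def test_arc_chord_sum_converges_to_arc_length(self):
        arc = make_centerline("arc", radius=50.0, sweep_deg=90.0)
        true_len = 50.0 * np.pi / 2
        for spacing, tol in ((2.0, 0.1), (0.25, 0.002)):
            out = resample_polyline(arc, spacing)
            chord_sum = np.linalg.norm(np.diff(out, axis=0), axis=1).sum()
            assert abs(chord_sum - true_len) < tol * true_len


class TestTraceCenterlines:
    def test_recovers_seven_parallel_filaments(self, rendered_hexagon_volume):
        vol, bundle = rendered_hexagon_volume
        traces = trace_centerlines(vol)
        assert len(traces) == 7
        for t in traces:
            # direction via principal component; truth is the x axis
            c = t - t.mean(axis=0)
            direction = np.linalg.svd(c, full_matrices=False)[2][0]
            angle = np.degrees(
                np.arccos(min(1.0, abs(direction[0])))
            )
            assert angle < 2.0

    def test_blank_volume_yields_nothing(self):
        from filotwist.synth import DensityVolume

        vol = DensityVolume(np.zeros((30, 30, 30), np.float32), 1.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert trace_centerlines(vol) == []

    def test_filaments_below_min_separation_merge(self):
        # two filaments 6 nm apart: below the 8 nm filament width rule
        f1 = FilamentSpec("a", make_centerline("straight", length=80.0),
                          COFILACTIN)
        f2 = FilamentSpec(
            "b", make_centerline("straight", length=80.0) + [0, 6.0, 0],
            COFILACTIN,
        )
        vol = render_volume(BundleSpec([f1, f2], 6.0, "none", 0))
        assert len(trace_centerlines(vol)) <= 1


def parallel_lines(n=2, spacing=10.0, length=50.0, step=0.5):
    t = np.arange(0, length + step / 2, step)
    return [
        np.column_stack([t, np.full_like(t, i * spacing), np.zeros_like(t)])
        for i in range(n)
    ]


class TestNNDistances:
    def test_two_parallel_filaments(self):
        res = nn_distances(parallel_lines(spacing=10.0))
        assert res.pre_mean == pytest.approx(10.0)
        assert res.pre_sd == pytest.approx(0.0, abs=1e-9)

    def test_single_filament_rejected(self):
        with pytest.raises(ValueError):
            nn_distances(parallel_lines(n=1))

    def test_hexagon_mean_equals_lattice_constant(self, cofilactin_hexagon):
        pts = [
            resample_polyline(f.centerline, 1.0)
            for f in cofilactin_hexagon.filaments
        ]
        res = nn_distances(pts)
        assert res.pre_mean == pytest.approx(11.5, abs=1e-9)

    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(3)
        clouds = [rng.normal(scale=5.0, size=(100, 3)) + [30 * i, 0, 0]
                  for i in range(5)]
        res = nn_distances(clouds)
        for i, cloud in enumerate(clouds):
            others = np.vstack([c for j, c in enumerate(clouds) if j != i])
            brute = np.sqrt(
                ((cloud[:, None] - others[None]) ** 2).sum(-1)
            ).min(axis=1)
            got = res.records[res.records["filament"] == i].sort_values(
                "point_id"
            )["distance_nm"].to_numpy()
            assert np.allclose(got, brute)

    def test_histogram_counts_sum_to_n(self):
        res = nn_distances(parallel_lines(n=3))
        assert res.hist_counts.sum() == res.post_n


class TestFilterOutliers:
    @staticmethod
    def make_result(values):
        import pandas as pd

        from filotwist.tomo import NNResult, _histogram

        d = np.asarray(values, float)
        edges, counts = _histogram(d)
        rec = pd.DataFrame(
            {
                "point_id": range(len(d)),
                "filament": 0,
                "neighbor_filament": 1,
                "distance_nm": d,
            }
        )
        return NNResult(rec, len(d), float(d.mean()), float(d.std(ddof=1)),
                        len(d), float(d.mean()), float(d.std(ddof=1)),
                        None, None, edges, counts)

    def test_arithmetic_oracle_k3_keeps_everything(self):
        res = filter_outliers(self.make_result([10, 10, 10, 10, 100]), k=3)
        # bounds from mean 28, SD 40.25: 100 < 28 + 120.7
        assert res.post_n == 5
        assert res.bounds[0] == pytest.approx(28 - 3 * 40.249, abs=0.01)

    def test_arithmetic_oracle_k1_removes_extreme(self):
        res = filter_outliers(self.make_result([10, 10, 10, 10, 100]), k=1)
        assert res.post_n == 4
        assert res.post_mean == pytest.approx(10.0)

    def test_all_equal_nothing_removed(self):
        res = filter_outliers(self.make_result([7.0] * 10), k=3)
        assert res.post_n == 10

    def test_provenance_and_single_pass_semantics(self):
        first = filter_outliers(self.make_result([10, 10, 10, 10, 100]), k=1)
        assert first.pre_mean == pytest.approx(28.0)  # pre-filter stats kept
        assert first.post_n <= first.pre_n
        # a second pass recomputes bounds from the new pre-filter stats and
        # may remove more; it must never add records back
        second = filter_outliers(
            self.make_result(first.records["distance_nm"].tolist()), k=1
        )
        assert second.post_n <= first.post_n


class TestWidthSignalAndCrossover:
    def test_zero_twist_ribbon_gives_flat_signal(self):
        ribbon = HelicalParams(2.76, 0.0)
        fil = FilamentSpec("r", make_centerline("straight", length=120.0),
                           ribbon)
        vol = render_volume(BundleSpec([fil], 12.0, "none", 0))
        s, w = width_signal(vol, fil.centerline)
        assert w.std() < 0.02 * w.mean()

    def test_actin_period(self):
        b = build_hexagonal_bundle(0, 12.0, ACTIN,
                                   length=11.5 * crossover_length(ACTIN))
        vol = render_volume(b)
        est = estimate_crossover(width_signal(vol, b.filaments[0].centerline))
        assert est.mean_nm == pytest.approx(crossover_length(ACTIN), abs=0.25)

    def test_pure_sinusoid_period_recovered(self):
        s = np.arange(0, 300.0, 1.0)
        P = 27.0
        est = estimate_crossover((s, 2.0 + 0.3 * np.cos(2 * np.pi * s / P)))
        assert est.mean_nm == pytest.approx(P, abs=0.1)
        assert est.sem_nm < 0.05

    def test_too_few_peaks_flagged_indeterminate(self):
        s = np.arange(0, 20.0, 1.0)
        est = estimate_crossover((s, np.ones_like(s)))
        assert est.indeterminate


class TestPhaseOffset:
    @staticmethod
    def sin_signal(P, phase, span=200.0):
        s = np.arange(0, span, 1.0)
        return s, 2.0 + 0.3 * np.cos(2 * np.pi * s / P + phase)

    def test_identical_signals_in_phase(self):
        sig = self.sin_signal(27.75, 0.0)
        assert phase_offset(sig, sig, 27.75) == pytest.approx(0.0, abs=1e-6)

    def test_half_period_shift_out_of_phase(self):
        a = self.sin_signal(27.75, 0.0)
        b = self.sin_signal(27.75, np.pi)
        assert phase_offset(a, b, 27.75) == pytest.approx(0.5, abs=1e-6)

    def test_symmetry(self):
        a = self.sin_signal(27.75, 0.3)
        b = self.sin_signal(27.75, 1.9)
        assert phase_offset(a, b, 27.75) == pytest.approx(
            phase_offset(b, a, 27.75)
        )

    def test_period_mismatch_rejected(self):
        a = self.sin_signal(27.75, 0.0)
        b = self.sin_signal(37.07, 0.0)
        with pytest.raises(ValueError, match="mismatch"):
            phase_offset(a, b, 27.75)

    def test_rolled_neighbors_are_out_of_phase(self):
        """Two cofilactin filaments rolled 0 and 90 deg: width modulations
        offset by half a crossover (the out-of-phase bundle packing)."""
        L = crossover_length(COFILACTIN)
        cl = make_centerline("straight", length=3.5 * L)
        f0 = FilamentSpec("a", cl, COFILACTIN, roll=0.0)
        f1 = FilamentSpec("b", cl + [0, 12.0, 0], COFILACTIN, roll=90.0)
        vol = render_volume(BundleSpec([f0, f1], 12.0, "none", 0))
        off = phase_offset(
            width_signal(vol, f0.centerline),
            width_signal(vol, f1.centerline),
            L,
        )
        assert off == pytest.approx(0.5, abs=0.02)


class TestClassification:
    @pytest.mark.parametrize(
        "pitch,label",
        [(27.9, "cofilactin"), (37.0, "actin"), (32.0, "indeterminate")],
    )
    def test_thresholds(self, pitch, label):
        est = PitchEstimate("f", np.array([pitch]), 1, pitch, 0.0)
        assert classify_filament(est).label == label

    @given(st.lists(st.floats(20.0, 45.0), min_size=2, max_size=10))
    @settings(deadline=None, max_examples=50)
    def test_monotone_in_pitch(self, pitches):
        order = {"cofilactin": 0, "indeterminate": 1, "actin": 2}
        labels = [
            order[classify_filament(
                PitchEstimate("f", np.array([p]), 1, p, 0.0)
            ).label]
            for p in sorted(pitches)
        ]
        assert labels == sorted(labels)

    def test_bundle_summary(self):
        def member(pitch):
            return classify_filament(
                PitchEstimate("f", np.array([pitch]), 1, pitch, 0.0)
            )

        pure = classify_bundle([member(27.5)] * 3)
        assert pure.label == "pure_cofilactin"
        assert pure.fractions["cofilactin"] == 1.0
        mixed = classify_bundle([member(27.5), member(37.0)])
        assert mixed.label == "mixed"
        assert sum(mixed.fractions.values()) == pytest.approx(1.0)

    def test_indeterminate_estimate_rejected(self):
        est = PitchEstimate("f", np.array([]), 0, np.nan, np.nan,
                            indeterminate=True)
        with pytest.raises(ValueError):
            classify_filament(est)


@pytest.fixture(scope="module")
def filament_volume():
    L = crossover_length(COFILACTIN)
    cl = make_centerline("straight", length=6.5 * L)
    fil = FilamentSpec("a", cl, COFILACTIN)
    vol = render_volume(BundleSpec([fil], 12.0, "none", 0))
    return vol, fil


class TestHelicalAverage:
    def test_noise_free_average_equals_single_particle(self, filament_volume):
        vol, fil = filament_volume
        avg, _ = helical_average(vol, fil, n_particles=40, box=14.0)
        one, _ = helical_average(vol, fil, n_particles=1, box=14.0)
        rms = np.sqrt(np.mean((avg.data - one.data) ** 2))
        assert rms < 0.01 * np.sqrt(np.mean(one.data**2))

    def test_noise_suppression(self, filament_volume):
        vol, fil = filament_volume
        noisy = corrupt_volume(vol, snr=1.0, seed=3)
        ref, _ = helical_average(vol, fil, n_particles=45, box=14.0)
        avg, _ = helical_average(noisy, fil, n_particles=45, box=14.0)
        one, _ = helical_average(noisy, fil, n_particles=1, box=14.0)
        c_avg = np.corrcoef(avg.data.ravel(), ref.data.ravel())[0, 1]
        c_one = np.corrcoef(one.data.ravel(), ref.data.ravel())[0, 1]
        assert c_avg > c_one

    def test_mismatched_twist_blurs_modulation(self, filament_volume):
        vol, fil = filament_volume
        noisy = corrupt_volume(vol, snr=1.0, seed=3)
        _, good = helical_average(noisy, fil, n_particles=45, box=14.0)
        wrong = FilamentSpec("a", fil.centerline, ACTIN)
        _, bad = helical_average(noisy, wrong, n_particles=45, box=14.0)
        assert (
            good["modulation_amplitude_nm"] > bad["modulation_amplitude_nm"]
        )

    def test_oversized_box_rejected(self, filament_volume):
        vol, fil = filament_volume
        with pytest.raises(ValueError):
            helical_average(vol, fil, n_particles=5, box=1000.0)


class TestParameterRecovery:
    """Generator -> analysis round trip over a small condition grid."""

    @pytest.mark.parametrize("preset,lattice", [("fascin", 12.3),
                                                ("cofilactin", 11.5)])
    def test_lattice_constant_recovered(self, preset, lattice):
        from filotwist.pipeline import recover_lattice_spacing

        out = recover_lattice_spacing(preset, seeds=(0,), snr=4.0)
        assert out["mean_nm"] == pytest.approx(lattice, abs=0.3)

    def test_crossover_recovered_under_noise(self):
        from filotwist.pipeline import measure_filament_crossover

        est = measure_filament_crossover(n_crossovers=8, snr=4.0, seed=1,
                                         use_traced_centerline=True)
        assert est.mean_nm == pytest.approx(
            crossover_length(COFILACTIN), abs=0.5
        )
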