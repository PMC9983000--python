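import numpy as np
import pytest

from spatial2dms import (
    FragmentationPattern,
    IonState,
    PrecursorSpecies,
    ScanSchedule,
    TofInstrumentConfig,
    detect_fragments,
    extract_channel_transient,
    fft_magnitude,
    modulation_frequency_tof,
    pattern_intensity,
    run_tof_scan_sequence,
)
from spatial2dms.errors import ChannelLookupError, ConfigurationError


def flat_pattern(zone_length: float) -> FragmentationPattern:
    """A pattern that is 1 everywhere inside the zone (no fringes)."""
    pos = np.array([0.0, zone_length])
    return FragmentationPattern(
        kind="custom_tabulated",
        fringe_spacing=zone_length,
        zone_length=zone_length,
        table=(pos, np.array([1.0, 1.0])),
    )


class TestRunSequence:
    def test_flat_pattern_gives_constant_transients(self, tof_config, small_schedule):
        mixture = [PrecursorSpecies(mz=1000.0, fragments=((400.0, 0.5),))]
        # keep the reference ion inside the zone for the whole schedule
        pattern = flat_pattern(tof_config.zone_length)
        cube, _ = run_tof_scan_sequence(
            mixture, tof_config, pattern, small_schedule, collect_events=False
        )
        tr = extract_channel_transient(cube, 400.0).values
        assert np.ptp(tr) == pytest.approx(0.0, abs=1e-12)
        assert tr[0] == pytest.approx(0.5, abs=1e-12)

    def test_identical_precursors_scale_with_abundance(
        self, tof_config, dual_slit, small_schedule
    ):
        a = PrecursorSpecies(mz=800.0, abundance=1.0, fragments=((300.0, 0.5),))
        b = PrecursorSpecies(mz=800.0, abundance=0.25, fragments=((350.0, 0.5),))
        cube, _ = run_tof_scan_sequence(
            [a, b], tof_config, dual_slit, small_schedule, collect_events=False
        )
        ta = extract_channel_transient(cube, 300.0).values
        tb = extract_channel_transient(cube, 350.0).values
        np.testing.assert_allclose(ta, 4.0 * tb, rtol=1e-12, atol=1e-15)

    def test_single_precursor_matches_brute_force(
        self, tof_config, dual_slit, single_precursor
    ):
        """The cube column equals cos^2(pi (v t - zone_start)/Lambda)
        re-evaluated scan by scan."""
        schedule = ScanSchedule.zone_splitting(tof_config, n_scans=512)
        cube, _ = run_tof_scan_sequence(
            single_precursor, tof_config, dual_slit, schedule, collect_events=False
        )
        sp = single_precursor[0]
        state = IonState.after_kick(sp, tof_config)
        expected = np.empty(schedule.n_scans)
        for k in range(schedule.n_scans):
            delay = schedule.initial_delay + k * schedule.delay_increment
            d = state.lateral_speed * delay - tof_config.zone_start
            expected[k] = sp.abundance * sp.fragments[0][1] * pattern_intensity(
                dual_slit, d
            )
        tr = extract_channel_transient(cube, sp.fragments[0][0]).values
        np.testing.assert_allclose(tr, expected, rtol=0, atol=1e-15)

    def test_deterministic_mode_is_bit_reproducible(
        self, tof_config, dual_slit, small_schedule, single_precursor
    ):
        c1, _ = run_tof_scan_sequence(
            single_precursor, tof_config, dual_slit, small_schedule, collect_events=False
        )
        c2, _ = run_tof_scan_sequence(
            single_precursor, tof_config, dual_slit, small_schedule, collect_events=False
        )
        assert np.array_equal(c1.intensity, c2.intensity)

    def test_stochastic_mode_reproducible_and_requires_seed(
        self, tof_config, dual_slit, small_schedule, single_precursor
    ):
        kw = dict(mode="stochastic", n_ions=100, collect_events=False)
        c1, _ = run_tof_scan_sequence(
            single_precursor, tof_config, dual_slit, small_schedule, seed=7, **kw
        )
        c2, _ = run_tof_scan_sequence(
            single_precursor, tof_config, dual_slit, small_schedule, seed=7, **kw
        )
        c3, _ = run_tof_scan_sequence(
            single_precursor, tof_config, dual_slit, small_schedule, seed=8, **kw
        )
        assert np.array_equal(c1.intensity, c2.intensity)
        assert not np.array_equal(c1.intensity, c3.intensity)
        with pytest.raises(ConfigurationError):
            run_tof_scan_sequence(
                single_precursor, tof_config, dual_slit, small_schedule, **kw
            )

    def test_stochastic_mean_converges_to_deterministic(
        self, tof_config, dual_slit, small_schedule, single_precursor
    ):
        """With 1e4 ions per precursor the binomial error keeps the RMS
        relative deviation from the deterministic intensity below 5% over
        scans with intensity >= 0.1."""
        det, _ = run_tof_scan_sequence(
            single_precursor, tof_config, dual_slit, small_schedule, collect_events=False
        )
        sto, _ = run_tof_scan_sequence(
            single_precursor,
            tof_config,
            dual_slit,
            small_schedule,
            mode="stochastic",
            seed=11,
            n_ions=10_000,
            collect_events=False,
        )
        d = extract_channel_transient(det, 500.0).values
        s = extract_channel_transient(sto, 500.0).values
        mask = d >= 0.1
        rel = (s[mask] - d[mask]) / d[mask]
        assert np.sqrt(np.mean(rel**2)) < 0.05

    def test_dominant_fft_frequency_matches_theory(
        self, tof_config, dual_slit, small_schedule
    ):
        """The demodulated peak sits at modulation_frequency x delay step,
        within one frequency bin, for every precursor."""
        mixture = [
            PrecursorSpecies(mz=mz, fragments=((mz / 2.0, 0.8),))
            for mz in (600.0, 1000.0, 1800.0)
        ]
        cube, _ = run_tof_scan_sequence(
            mixture, tof_config, dual_slit, small_schedule, collect_events=False
        )
        for sp in mixture:
            tr = extract_channel_transient(cube, sp.fragments[0][0])
            spec = fft_magnitude(tr)
            measured = spec.frequency[np.argmax(spec.magnitude)]
            expected = (
                modulation_frequency_tof(dual_slit, sp.mz, 1, tof_config.v_kick)
                * small_schedule.delay_increment
            )
            assert abs(measured - expected) < 1.0 / small_schedule.n_scans

    def test_frequency_sqrt_mz_constant_over_grid(self, tof_config, dual_slit):
        """Measured dominant frequency x sqrt(m/z) is constant over a
        500-3000 Th grid to within one frequency bin."""
        n_scans = 4096
        schedule = ScanSchedule.zone_splitting(tof_config, n_scans=n_scans)
        grid = [500.0, 1000.0, 1732.0, 2400.0, 3000.0]
        mixture = [
            PrecursorSpecies(mz=mz, fragments=((mz * 0.37, 0.8),)) for mz in grid
        ]
        cube, _ = run_tof_scan_sequence(
            mixture, tof_config, dual_slit, schedule, collect_events=False
        )
        products = []
        for mz in grid:
            spec = fft_magnitude(
                extract_channel_transient(cube, mz * 0.37, tolerance=0.01)
            )
            f = spec.frequency[np.argmax(spec.magnitude)]
            products.append(f * np.sqrt(mz))
        for mz, prod in zip(grid, products):
            assert abs(prod - products[1]) / np.sqrt(mz) < 1.0 / n_scans

    def test_event_log_schema_and_csv(
        self, tof_config, dual_slit, single_precursor, tmp_path
    ):
        schedule = ScanSchedule.zone_splitting(tof_config, n_scans=16)
        path = tmp_path / "events.csv"
        cube, events = run_tof_scan_sequence(
            single_precursor, tof_config, dual_slit, schedule, event_log_path=path
        )
        assert list(events.columns) == [
            "scan_index",
            "ion_id",
            "precursor_mz",
            "lateral_position_m",
            "fragmentation_intensity",
        ]
        assert len(events) == 16
        assert path.exists()
        import pandas as pd

        round_trip = pd.read_csv(path)
        assert len(round_trip) == 16

    def test_empty_mixture_rejected(self, tof_config, dual_slit, small_schedule):
        with pytest.raises(ConfigurationError):
            run_tof_scan_sequence([], tof_config, dual_slit, small_schedule)

    def test_zero_kick_rejected(self, dual_slit, small_schedule, single_precursor):
        config = TofInstrumentConfig(v_kick=0.0)
        with pytest.raises(ConfigurationError):
            run_tof_scan_sequence(
                single_precursor, config, dual_slit, small_schedule
            )

    def test_shared_fragment_channels_sum_and_flag(
        self, tof_config, dual_slit, small_schedule
    ):
        shared = 250.0
        a = PrecursorSpecies(mz=900.0, fragments=((shared, 0.5),))
        b = PrecursorSpecies(mz=1400.0, fragments=((shared, 0.5),))
        cube, _ = run_tof_scan_sequence(
            [a, b], tof_config, dual_slit, small_schedule, collect_events=False
        )
        assert shared in cube.metadata["overlapping_channels"]
        only_a, _ = run_tof_scan_sequence(
            [a], tof_config, dual_slit, small_schedule, collect_events=False
        )
        only_b, _ = run_tof_scan_sequence(
            [b], tof_config, dual_slit, small_schedule, collect_events=False
        )
        np.testing.assert_allclose(
            extract_channel_transient(cube, shared).values,
            extract_channel_transient(only_a, shared).values
            + extract_channel_transient(only_b, shared).values,
            rtol=1e-12,
        )


class TestDetectFragments:
    def test_empty_scan(self, tof_config):
        spec = detect_fragments(np.array([]), np.array([]), tof_config)
        assert spec.intensity.size == 0
        assert spec.loss == 0.0

    def test_two_fragments_in_flight_time_order(self, tof_config):
        spec = detect_fragments(
            np.array([400.0, 1600.0]), np.array([1.0, 2.0]), tof_config
        )
        nz = np.nonzero(spec.intensity)[0]
        assert nz.size == 2
        assert spec.intensity[nz[0]] == pytest.approx(1.0)  # lighter arrives first
        assert spec.intensity[nz[1]] == pytest.approx(2.0)

    def test_intensity_conserved_on_random_scan(self, tof_config, rng):
        mz = rng.uniform(100.0, 3000.0, size=50)
        inten = rng.uniform(0.0, 2.0, size=50)
        spec = detect_fragments(mz, inten, tof_config)
        assert spec.intensity.sum() + spec.loss == pytest.approx(
            inten.sum(), rel=1e-9
        )

    def test_out_of_window_tallied(self, tof_config):
        spec = detect_fragments(
            np.array([400.0, 1600.0]),
            np.array([1.0, 2.0]),
            tof_config,
            window=(0.0, 60e-6),  # 1600 Th arrives later than 60 us
        )
        assert spec.loss == pytest.approx(2.0)
        assert spec.intensity.sum() == pytest.approx(1.0)


class TestExtractChannel:
    def test_exact_match_returns_column(self, tof_config, dual_slit, small_schedule):
        mixture = [PrecursorSpecies(mz=1000.0, fragments=((500.0, 0.5), (250.0, 0.3)))]
        cube, _ = run_tof_scan_sequence(
            mixture, tof_config, dual_slit, small_schedule, collect_events=False
        )
        col = np.nonzero(cube.channel_mz == 500.0)[0][0]
        tr = extract_channel_transient(cube, 500.0, tolerance=0.0)
        np.testing.assert_array_equal(tr.values, cube.intensity[:, col])

    def test_wide_tolerance_sums_channels(self, tof_config, dual_slit, small_schedule):
        mixture = [PrecursorSpecies(mz=1000.0, fragments=((500.0, 0.5), (501.0, 0.3)))]
        cube, _ = run_tof_scan_sequence(
            mixture, tof_config, dual_slit, small_schedule, collect_events=False
        )
        tr = extract_channel_transient(cube, 500.5, tolerance=1.0)
        assert tr.matched_channels == (500.0, 501.0)
        np.testing.assert_allclose(
            tr.values,
            extract_channel_transient(cube, 500.0).values
            + extract_channel_transient(cube, 501.0).values,
        )

    def test_missing_channel_names_nearest(self, tof_config, dual_slit, small_schedule):
        mixture = [PrecursorSpecies(mz=1000.0, fragments=((500.0, 0.5),))]
        cube, _ = run_tof_scan_sequence(
            mixture, tof_config, dual_slit, small_schedule, collect_events=False
        )
        with pytest.raises(ChannelLookupError, match="500"):
            extract_channel_transient(cube, 498.0, tolerance=0.0)
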