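"""Simulator: grid geometry, peak law, noise statistics, sensor bank."""

import numpy as np
import pytest

from voltet import (
    ANALYTES,
    SENSOR_ORDER,
    NoiseModel,
    make_grid,
    peak_current,
    default_sensor_bank,
    sensitivity_matrix,
    simulate_sample,
    simulate_voltammogram,
)
from voltet.exceptions import ConfigurationError, DomainError, InvalidGridError
from voltet.simulate import clean_voltammogram


class TestGrid:
    def test_default_cycle(self):
        grid = make_grid(-1.5, 1.5, 752)
        assert grid.n_points == len(grid.potentials) == 752
        assert grid.potentials[0] == grid.potentials[-1] == -1.5
        assert grid.potentials.max() == 1.5

    def test_minimal_cycle(self):
        grid = make_grid(-1, 1, 4)
        assert np.allclose(grid.potentials, [-1, 1, 1, -1])

    def test_implied_step_is_8mV(self):
        # 3 V span over 375 intervals per half-sweep
        assert make_grid(-1.5, 1.5, 752).step == pytest.approx(0.008, rel=1e-12)

    def test_halves_strictly_monotone(self):
        grid = make_grid()
        h = grid.half
        assert np.all(np.diff(grid.potentials[:h]) > 0)
        assert np.all(np.diff(grid.potentials[h:]) < 0)

    @pytest.mark.parametrize("n", [3, 5, 2, 751])
    def test_bad_n_points_rejected(self, n):
        with pytest.raises(InvalidGridError):
            make_grid(-1, 1, n)

    def test_inverted_window_rejected(self):
        with pytest.raises(InvalidGridError):
            make_grid(1.0, -1.0, 8)


class TestPeakCurrent:
    def test_zero_concentration(self):
        assert peak_current(0.0, 3.0, 20.0, 0.0) == 0.0

    def test_worked_value(self):
        assert peak_current(10, 1.0, 50, 0) == pytest.approx(10 / 1.2)

    def test_bounded_by_SK(self):
        assert peak_current(1e9, 2.0, 40.0, 0.0) < 2.0 * 40.0
        assert peak_current(1e9, 2.0, 40.0, 0.0) == pytest.approx(80.0, rel=1e-3)

    def test_monotone_in_concentration(self):
        c = np.linspace(0, 30, 100)
        vals = peak_current(c, 1.5, 50.0, 0.2)
        assert np.all(np.diff(vals) > 0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(DomainError):
            peak_current(-1.0, 1.0, 50.0, 0.0)


class TestVoltammogram:
    def test_blank_is_pure_baseline(self, default_grid, bank):
        params = bank[0]
        vg = simulate_voltammogram(
            params, np.zeros(3), default_grid, NoiseModel(0, 0, seed=0)
        )
        expected = (
            params.baseline_offset * default_grid.direction()
            + params.baseline_slope * default_grid.potentials
        )
        assert np.allclose(vg.currents, expected)

    def test_determinism_same_seed(self, default_grid, bank):
        noise = NoiseModel(sigma_abs=0.2, seed=42)
        a = simulate_voltammogram(bank[1], [5.0, 10.0, 2.0], default_grid, noise)
        b = simulate_voltammogram(bank[1], [5.0, 10.0, 2.0], default_grid, noise)
        assert np.array_equal(a.currents, b.currents)

    def test_saturation_sublinear_doubling(self, default_grid, bank):
        """Peak excess grows with concentration but sublinearly (saturation)."""
        params = bank[0]
        blank = clean_voltammogram(params, np.zeros(3), default_grid)
        lo = clean_voltammogram(params, np.array([12.5, 0, 0]), default_grid) - blank
        hi = clean_voltammogram(params, np.array([25.0, 0, 0]), default_grid) - blank
        assert hi.max() > lo.max()
        assert hi.max() < 2 * lo.max()

    def test_low_concentration_superposition(self, default_grid, bank):
        """Without cross-suppression, a mixture is the sum of single responses."""
        from dataclasses import replace

        params = replace(bank[2], interaction=np.zeros((3, 3)))
        blank = clean_voltammogram(params, np.zeros(3), default_grid)
        mix = clean_voltammogram(params, np.array([0.5, 0.5, 0.5]), default_grid) - blank
        singles = sum(
            clean_voltammogram(params, 0.5 * np.eye(3)[a], default_grid) - blank
            for a in range(3)
        )
        assert np.max(np.abs(mix - singles)) <= 0.01 * np.max(np.abs(singles))

    def test_noise_sd_matches_configuration(self, bank):
        """Replicate blanks reproduce the configured noise SD within 10%."""
        grid = make_grid(-1.5, 1.5, 32)
        sigma = 0.5
        reps = np.vstack(
            [
                simulate_voltammogram(
                    bank[0], np.zeros(3), grid, NoiseModel(sigma, 0.0, seed=k)
                ).currents
                for k in range(1500)
            ]
        )
        sd = reps.std(axis=0, ddof=1)
        assert np.all(np.abs(sd - sigma) <= 0.1 * sigma)


class TestSampleRecord:
    def test_raw_fingerprint_length(self, default_grid, bank):
        rec = simulate_sample([10, 5, 20], bank, default_grid, NoiseModel(seed=1))
        assert len(rec.voltammograms) == 6
        assert len(rec.raw_vector) == 4512

    def test_sensor_order_and_streams_differ(self, default_grid, bank):
        rec = simulate_sample([10, 5, 20], bank, default_grid, NoiseModel(seed=1))
        assert tuple(v.sensor_id for v in rec.voltammograms) == SENSOR_ORDER
        # independent noise: residuals not identical between sensors
        assert not np.array_equal(
            rec.voltammograms[0].currents, rec.voltammograms[1].currents
        )

    def test_duplicate_sensor_rejected(self, default_grid, bank):
        with pytest.raises(ConfigurationError):
            simulate_sample([1, 1, 1], [bank[0]] * 6, default_grid, NoiseModel(seed=0))

    def test_degenerate_equal_bank_identical_traces(self, default_grid, bank):
        from dataclasses import replace

        clones = [replace(bank[0], sensor_id=f"S{i}") for i in range(6)]
        rec = simulate_sample([5, 5, 5], clones, default_grid, NoiseModel(0, 0, seed=0))
        for vg in rec.voltammograms[1:]:
            assert np.array_equal(vg.currents, rec.voltammograms[0].currents)

    def test_analyte_responses_not_collinear(self, default_grid, bank):
        """(25,0,0) and (0,25,0) give non-proportional sensor responses."""
        a = simulate_sample([25, 0, 0], bank, default_grid, NoiseModel(0, 0, seed=0))
        b = simulate_sample([0, 25, 0], bank, default_grid, NoiseModel(0, 0, seed=0))
        for va, vb in zip(a.voltammograms, b.voltammograms):
            cos = np.dot(va.currents, vb.currents) / (
                np.linalg.norm(va.currents) * np.linalg.norm(vb.currents)
            )
            assert cos < 0.999


def test_sensitivity_matrix_full_column_rank(bank):
    S = sensitivity_matrix(bank)
    assert S.shape == (6, 3)
    assert np.linalg.matrix_rank(S) == 3
    # well-conditioned, not merely technically full rank
    assert np.linalg.cond(S) < 50
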