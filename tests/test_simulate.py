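"""Simulator: phase footprints, dose response, population dynamics, determinism."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from holoassay.config import Condition, OpticsConfig, PopulationConfig
from holoassay.simulate import (cell_phase_footprint, hill_effect,
                                render_hologram, render_series,
                                shape_circularity, simulate_population)

ALPHA = 0.19
LAM = 0.532
PITCH = 450.0 / 1024


def patch_dry_mass(patch, pitch):
    return LAM / (2 * math.pi * ALPHA) * patch.sum() * pitch**2


class TestPhaseFootprint:
    @pytest.mark.parametrize(
        "mass,area,ecc,state",
        [
            (300.0, 600.0, 3.0, "spread"),
            (300.0, 450.0, 1.05, "rounded"),
            (20.0, 100.0, 1.5, "debris"),
            (950.0, 380.0, 1.0, "rounded"),
        ],
    )
    def test_encodes_requested_dry_mass(self, mass, area, ecc, state):
        patch = cell_phase_footprint(mass, area, ecc, state, PITCH,
                                     lobes=((3, 0.08, 0.4),))
        assert patch.min() >= 0.0
        assert patch_dry_mass(patch, PITCH) == pytest.approx(mass, rel=0.01)

    def test_zero_mass_gives_zero_patch(self):
        patch = cell_phase_footprint(0.0, 600.0, 2.0, "spread", PITCH)
        assert np.all(patch == 0.0)

    def test_uniform_disc_peak_phase(self):
        # inverse of the dry-mass relation: peak = 2πα/λ · dm/area
        # = 2π·0.19/0.532 · 300/600 = 1.1220 rad (independent hand evaluation)
        patch = cell_phase_footprint(300.0, 600.0, 1.0, "rounded", PITCH,
                                     profile="disc")
        assert patch.max() == pytest.approx(1.1220, abs=0.02)

    def test_subpixel_area_rejected(self):
        with pytest.raises(ValueError, match="4 pixels"):
            cell_phase_footprint(10.0, 3.0 * PITCH**2, 1.0, "debris", PITCH)

    def test_extreme_peak_warns_but_renders(self):
        with pytest.warns(UserWarning, match="4π"):
            patch = cell_phase_footprint(6000.0, 400.0, 1.0, "rounded", PITCH)
        assert patch.max() > 4 * math.pi

    def test_rounded_shape_family_is_round(self):
        assert shape_circularity(1.05) > 0.95
        assert shape_circularity(3.0, ((4, 0.08, 0.0),)) < 0.8


class TestHillEffect:
    def test_definition_points(self):
        assert hill_effect(5.0, 5.0, 2.0) == pytest.approx(0.5)
        assert hill_effect(0.0, 5.0, 2.0) == 0.0
        assert hill_effect(50.0, 5.0, 2.0) == pytest.approx(100.0 / 101.0, rel=1e-9)

    @settings(max_examples=50, derandomize=True)
    @given(
        c1=st.floats(0.0, 1e4),
        c2=st.floats(0.0, 1e4),
        ec50=st.floats(0.01, 1e3),
        hill=st.floats(0.1, 6.0),
    )
    def test_monotone_and_bounded(self, c1, c2, ec50, hill):
        lo, hi = sorted((c1, c2))
        e_lo, e_hi = hill_effect(lo, ec50, hill), hill_effect(hi, ec50, hill)
        assert 0.0 <= e_lo <= e_hi <= 1.0


def _control_pop(**kw):
    defaults = dict(
        conditions=[Condition("medium", "medium", 0.0)],
        n_fov=1,
        n_experiments=1,
        experiment_growth_cv=0.0,
        experiment_count_cv=0.0,
        seed=7,
    )
    defaults.update(kw)
    return PopulationConfig(**defaults)


class TestPopulationDynamics:
    def test_control_growth_matches_exponential(self, optics_small):
        # closed-form oracle: at growth rate 0.06/h the 12-h population mass
        # ratio is e^0.72 ≈ 2.054, up to Monte-Carlo error over >= 20 FOVs
        pop = _control_pop(growth_rate_per_h=0.06, n_fov=20, initial_cell_count=30)
        sim = simulate_population(pop, optics_small)
        ratios = [
            fov.population_dry_mass_pg(12.0) / fov.population_dry_mass_pg(0.0)
            for fov in sim.fovs
        ]
        assert np.mean(ratios) == pytest.approx(math.exp(0.72), rel=0.02)

    def test_forced_lysis_leaves_only_subthreshold_debris(self, optics_small):
        pop = _control_pop(
            conditions=[Condition("det", "detergent", 1e5)],
            lysis_rate_per_h=50.0,
            timepoints_h=(0.0, 1.0),
        )
        sim = simulate_population(pop, optics_small)
        cells = sim.ground_truth.cells
        end = cells[cells.time_h == 1.0]
        assert set(end.state) <= {"debris"}
        assert (end.area_um2 < 350.0).all()
        fov = sim.fovs[0]
        debris_mass = end.dry_mass_pg.sum()
        assert fov.population_dry_mass_pg(1.0) == pytest.approx(debris_mass)
        assert debris_mass < 0.5 * fov.population_dry_mass_pg(0.0)

    def test_no_drug_rounding_leaves_baseline_mitotic_fraction(self, optics_small):
        pop = _control_pop(n_fov=20, initial_cell_count=40,
                           baseline_rounding_prob=0.10)
        sim = simulate_population(pop, optics_small)
        rf = sim.ground_truth.rounded_fraction(12.0)
        pooled = rf.n_rounded.sum() / rf.n_total.sum()
        assert pooled == pytest.approx(0.10, abs=0.03)

    def test_detergent_dose_never_increases_expected_mass(self, optics_small):
        concs = [0.0, 5.0, 25.0, 140.0]
        means = []
        for c in concs:
            agent = "medium" if c == 0 else "detergent"
            pop = _control_pop(
                conditions=[Condition("x", agent, c)], n_fov=20,
                initial_cell_count=25,
            )
            sim = simulate_population(pop, optics_small)
            means.append(
                np.mean([f.population_dry_mass_pg(12.0) for f in sim.fovs])
            )
        assert all(b <= a for a, b in zip(means, means[1:]))

    def test_manifest_totals_match_cell_sums(self, optics_small):
        pop = _control_pop(
            conditions=[Condition("det", "detergent", 20.0)], n_fov=2,
            timepoints_h=(0.0, 4.0, 8.0, 12.0),
        )
        gt = simulate_population(pop, optics_small).ground_truth
        sums = (
            gt.cells[gt.cells.state != "removed"]
            .groupby(["fov", "time_h"])["dry_mass_pg"]
            .sum()
        )
        for (fov, t), total in gt.fov_totals.set_index(["fov", "time_h"])[
            "population_dry_mass_pg"
        ].items():
            assert total == pytest.approx(sums.loc[(fov, t)])

    def test_debris_fragments_below_filter_threshold(self, optics_small):
        pop = _control_pop(conditions=[Condition("det", "detergent", 140.0)],
                           n_fov=3)
        gt = simulate_population(pop, optics_small).ground_truth
        debris = gt.cells[gt.cells.state == "debris"]
        assert len(debris) > 0
        assert (debris.area_um2 < 350.0).all()

    def test_seed_determinism_bit_identical(self, optics_small):
        pop = _control_pop(timepoints_h=(0.0, 6.0, 12.0))
        a = simulate_population(pop, optics_small)
        b = simulate_population(pop, optics_small)
        pd.testing.assert_frame_equal(a.ground_truth.cells, b.ground_truth.cells)
        pa = a.fovs[0].phase_image(12.0).phase
        pb = b.fovs[0].phase_image(12.0).phase
        assert np.array_equal(pa, pb)
        ha = render_hologram(a.fovs[0].phase_image(12.0), optics_small, 0, seed=99)
        hb = render_hologram(b.fovs[0].phase_image(12.0), optics_small, 0, seed=99)
        assert np.array_equal(ha.intensity, hb.intensity)


class TestHologramRendering:
    def test_flat_phase_spectrum_has_three_peaks(self, optics_quiet):
        from holoassay.fields import PhaseImage

        flat = PhaseImage(
            np.zeros((optics_quiet.sensor_rows, optics_quiet.sensor_cols)),
            optics_quiet.pixel_pitch_um,
        )
        holo = render_hologram(flat, optics_quiet, 0, seed=1)
        mag = np.fft.fftshift(np.abs(np.fft.fft2(holo.intensity)))
        from skimage.measure import label

        # off-bin carriers leak over a few neighbouring bins, so count
        # connected spectral clusters: DC and the two conjugate carrier peaks
        clusters = label(mag > 0.05 * mag.max(), connectivity=2)
        assert clusters.max() == 3

    def test_zero_reference_gives_no_fringes(self, optics_quiet, rng):
        from dataclasses import replace

        from holoassay.fields import PhaseImage

        opt = replace(optics_quiet, reference_amplitude=0.0)
        phase = PhaseImage(
            rng.uniform(0, 2, size=(opt.sensor_rows, opt.sensor_cols)),
            opt.pixel_pitch_um,
        )
        holo = render_hologram(phase, opt, 0, seed=1)
        assert np.ptp(holo.intensity) < 1e-12

    def test_frames_share_cell_phase_but_differ_in_artifacts(self, optics_small):
        from holoassay.fields import PhaseImage

        shape = (optics_small.sensor_rows, optics_small.sensor_cols)
        flat = PhaseImage(np.zeros(shape), optics_small.pixel_pitch_um)
        frames = render_series(flat, optics_small, seed=5)
        assert len(frames) == 7
        assert not np.array_equal(frames[0].intensity, frames[1].intensity)

    def test_invalid_frame_index_rejected(self, optics_small):
        from holoassay.fields import PhaseImage

        shape = (optics_small.sensor_rows, optics_small.sensor_cols)
        flat = PhaseImage(np.zeros(shape), optics_small.pixel_pitch_um)
        with pytest.raises(ValueError, match="frame_index"):
            render_hologram(flat, optics_small, 7, seed=1)

    def test_separability_invariant_enforced_in_config(self):
        with pytest.raises(ValueError, match="carrier magnitude"):
            OpticsConfig(carrier_freq=(0.01, 0.01))
        with pytest.raises(ValueError, match="carrier magnitude"):
            OpticsConfig(carrier_freq=(2.0, 2.0))
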