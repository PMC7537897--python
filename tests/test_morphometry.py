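"""Measurement, grouping and statistics against analytic oracles and the
bundled reference tables."""

import itertools

import numpy as np
import pytest

import semmorph as sm
from semmorph.morphometry import (
    MissingObjectError,
    load_reference_axon_diameters,
    load_reference_cell_bodies,
    measure_wall_thickness,
    round_half_away,
)


def _disc_mask(shape, center, radius_px):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius_px**2


class TestLabeling:
    def test_two_disjoint_discs_give_two_records(self):
        lbl = np.zeros((60, 60), dtype=int)
        lbl[_disc_mask((60, 60), (15, 15), 8)] = 1
        lbl[_disc_mask((60, 60), (45, 45), 8)] = 1
        records, label_map, rejected = sm.label_objects(lbl, [1])
        assert len(records) == 2 and rejected == 0
        assert sorted(np.unique(label_map).tolist()) == [0, 1, 2]

    def test_min_area_filter_rejects_and_counts(self):
        lbl = np.zeros((20, 20), dtype=int)
        lbl[5:8, 5:8] = 1  # 9 pixels
        records, _, rejected = sm.label_objects(lbl, [1], min_area=10)
        assert records == [] and rejected == 1

    def test_simulated_bodies_all_recovered(self):
        prims = [
            sm.Body(center=(40 + 60 * (i // 3), 40 + 60 * (i % 3)),
                    outer_diameter_nm=2000, contrast=0.6)
            for i in range(7)
        ]
        _, truth = sm.generate_scene(prims, sm.NoiseModel(), (200, 200), 50.0,
                                     seed=0)
        fg = (truth.label_map > 0).astype(int)
        records, _, _ = sm.label_objects(fg, [1], min_area=4)
        assert len(records) == 7


class TestBodyMeasurement:
    def test_disc_area_and_feret_match_analytic_circle(self):
        label_map = _disc_mask((256, 256), (128, 128), 100).astype(int)
        rec = sm.measure_body(label_map, 1, pixel_size=50.0)
        assert abs(rec.area_um2 - np.pi * 5.0**2) / (np.pi * 25) < 0.01
        assert abs(rec.feret_diameter_um - 10.0) / 10.0 < 0.01
        assert rec.equiv_diameter_um <= rec.feret_diameter_um * 1.01

    def test_single_pixel_unit_conversion(self):
        label_map = np.zeros((5, 5), dtype=int)
        label_map[2, 2] = 1
        rec = sm.measure_body(label_map, 1, pixel_size=50.0)
        assert rec.area_um2 == pytest.approx(0.0025)

    def test_ellipse_feret_between_minor_and_major_axis(self):
        yy, xx = np.ogrid[:200, :300]
        # axes 8 x 4 um at 50 nm/px -> semi-axes 80 / 40 px
        mask = ((xx - 150) / 80.0) ** 2 + ((yy - 100) / 40.0) ** 2 <= 1
        rec = sm.measure_body(mask.astype(int), 1, pixel_size=50.0)
        assert 4.0 < rec.feret_diameter_um < 8.0

    def test_missing_object_id_raises(self):
        with pytest.raises(MissingObjectError):
            sm.measure_body(np.zeros((10, 10), dtype=int), 3, 50.0)

    def test_scale_equivariance_linear_and_quadratic(self):
        label_map = _disc_mask((120, 120), (60, 60), 40).astype(int)
        a = sm.measure_body(label_map, 1, pixel_size=25.0)
        b = sm.measure_body(label_map, 1, pixel_size=50.0)
        assert b.feret_diameter_um == pytest.approx(2 * a.feret_diameter_um)
        assert b.equiv_diameter_um == pytest.approx(2 * a.equiv_diameter_um)
        assert b.area_um2 == pytest.approx(4 * a.area_um2)

    def test_feret_of_disc_rotation_invariant_within_2pct(self):
        from scipy import ndimage as ndi

        base = _disc_mask((150, 150), (75, 75), 50)
        vals = []
        for angle in (0, 15, 30, 45):
            rot = ndi.rotate(base.astype(float), angle, reshape=False,
                             order=1) > 0.5
            vals.append(sm.measure_body(rot.astype(int), 1, 50.0).feret_diameter_um)
        assert (max(vals) - min(vals)) / min(vals) < 0.02


class TestTubeMeasurement:
    def test_straight_tube_width_recovered(self):
        mask = np.zeros((60, 200), bool)
        mask[23:37, 10:190] = True  # 14 px wide
        d, _, kind = sm.measure_tube(mask, 50.0)
        assert abs(d - 700.0) <= 50.0
        assert kind == "axon_tube"

    def test_curved_tube_width_recovered(self):
        yy, xx = np.ogrid[:200, :200]
        r = np.hypot(yy - 195, xx - 195)
        mask = (np.abs(r - 150) <= 7) & (yy < 195) & (xx < 195)
        d, _, kind = sm.measure_tube(mask, 50.0)
        assert abs(d - 700.0) <= 50.0
        assert kind == "axon_tube"

    def test_single_pixel_line_minimal_width(self):
        mask = np.zeros((20, 80), bool)
        mask[10, 5:75] = True
        d, _, _ = sm.measure_tube(mask, 50.0)
        assert abs(d - 50.0) <= 50.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            sm.measure_tube(np.zeros((10, 10), bool), 50.0)

    def test_rendered_axon_population_mean_recovered_within_3_sem(self):
        """Render a population of tubes (mean 700 nm, sd 90 nm), re-measure
        them, and require the recovered mean within 3 SEM of the target."""
        n, mean, sd, px = 200, 700.0, 90.0, 10.0
        diams = sm.sample_axon_population(n, mean, sd, seed=5)
        measured = []
        for d in diams:
            h = int(d / px) + 30
            tube = sm.Tube(centerline=[(h / 2, 12), (h / 2, 188)],
                           lumen_diameter_nm=0.7 * d,
                           wall_thickness_nm=0.15 * d, contrast=0.5)
            _, truth = sm.generate_scene([tube], sm.NoiseModel(), (h, 200),
                                         px, seed=0)
            dm, _, _ = sm.measure_tube(truth.records[0].mask, px)
            measured.append(dm)
        assert abs(np.mean(measured) - mean) <= 3 * sd / np.sqrt(n)


class TestWallThickness:
    def _tube_scene(self, noise_sigma=0.0, seed=0):
        tube = sm.Tube(centerline=[(200, 20), (200, 380)],
                       lumen_diameter_nm=700, wall_thickness_nm=70,
                       contrast=0.5)
        image, _ = sm.generate_scene(
            [tube], sm.NoiseModel(gaussian_sigma=noise_sigma), (400, 400),
            5.0, seed=seed,
        )
        return image

    def test_70nm_wall_recovered_noise_free(self):
        res = measure_wall_thickness(self._tube_scene(), ((90, 200), (160, 200)))
        assert res.detected
        assert abs(res.thickness_nm - 70.0) <= 5.0  # +- 1 px at 5 nm/px

    def test_flat_profile_reports_no_wall(self):
        flat = sm.CalibratedImage(np.full((50, 50), 0.4), 5.0)
        res = measure_wall_thickness(flat, ((5, 25), (45, 25)))
        assert not res.detected and res.thickness_nm is None

    def test_70nm_wall_recovered_under_noise(self):
        res = measure_wall_thickness(self._tube_scene(0.03, seed=42),
                                     ((90, 200), (160, 200)))
        assert res.detected
        assert abs(res.thickness_nm - 70.0) <= 10.0


class TestSizeGroups:
    def test_reference_cell_table_partition_2_4_13(self):
        table = load_reference_cell_bodies()
        labels = sm.classify_size_groups(table["diameter_um"].to_numpy(), 3)
        assert (labels == table["group"].to_numpy()).all()
        counts = {g: (labels == g).sum() for g in ("1A", "1B", "1C")}
        assert counts == {"1A": 2, "1B": 4, "1C": 13}

    def test_well_separated_clusters(self):
        vals = [1, 1, 1, 10, 10, 10, 100, 100]
        labels = sm.classify_size_groups(vals, 3)
        assert list(labels) == ["1C"] * 3 + ["1B"] * 3 + ["1A"] * 2

    def test_k1_puts_everything_in_one_group(self):
        labels = sm.classify_size_groups([3.0, 5.0, 9.0], 1)
        assert set(labels) == {"1A"}

    def test_fewer_values_than_groups_raises(self):
        with pytest.raises(ValueError):
            sm.classify_size_groups([1.0, 2.0], 3)

    def test_matches_exhaustive_contiguous_partition_enumeration(self):
        """Exact-partition oracle: DP equals brute force over all contiguous
        3-partitions of the sorted values (n <= 20)."""
        rng = np.random.default_rng(17)
        for _ in range(5):
            vals = np.sort(rng.uniform(0, 10, 14))
            labels = sm.classify_size_groups(vals, 3)
            dp_cost = sum(
                vals[labels == g].var() * (labels == g).sum()
                for g in set(labels)
            )
            best = np.inf
            n = len(vals)
            for i, j in itertools.combinations(range(1, n), 2):
                parts = [vals[:i], vals[i:j], vals[j:]]
                cost = sum(p.var() * len(p) for p in parts)
                best = min(best, cost)
            assert dp_cost == pytest.approx(best, abs=1e-9)


class TestSummaries:
    def test_group_1a_mean_sd_sem(self):
        mean, sd, sem = sm.summarize_group([15.828, 12.518])
        assert round_half_away(mean, 2) == 14.17
        assert round_half_away(sd, 2) == 2.34
        assert round_half_away(sem, 3) == 1.655

    def test_brain_axon_table_statistics(self):
        ax = load_reference_axon_diameters()
        brain = ax.loc[ax.compartment == "brain", "diameter_nm"]
        mean, sd, sem = sm.summarize_group(brain)
        assert round_half_away(mean, 1) == 717.7
        assert round_half_away(sem, 1) == 24.0

    def test_single_value_has_no_sd_or_sem(self):
        mean, sd, sem = sm.summarize_group([5.0])
        assert mean == 5.0 and sd is None and sem is None

    def test_two_value_sd_identity(self):
        # sd({x, y}) == |x - y| / sqrt(2)
        x, y = 15.828, 12.518
        _, sd, _ = sm.summarize_group([x, y])
        assert sd == pytest.approx(abs(x - y) / np.sqrt(2))

    def test_rounding_is_half_away_from_zero(self):
        assert round_half_away(2.675, 2) == 2.68
        assert round_half_away(-2.675, 2) == -2.68
        assert round_half_away(0.125, 2) == 0.13
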