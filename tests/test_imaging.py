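"""Synthetic micrographs and the droplet quantification pipeline."""

import numpy as np
import pandas as pd
import pytest

import ctdphase as cp
from ctdphase.imaging import significance_tier


def brute_force_otsu(image, nbins=256):
    """Exhaustive search of the between-class-variance maximizer."""
    hist, edges = np.histogram(image.ravel(), bins=nbins, range=(0.0, 1.0))
    total = hist.sum()
    centers = (edges[:-1] + edges[1:]) / 2
    best, best_t = -1.0, centers[0]
    for k in range(1, nbins):
        w0, w1 = hist[:k].sum(), hist[k:].sum()
        if w0 == 0 or w1 == 0:
            continue
        m0 = (hist[:k] * centers[:k]).sum() / w0
        m1 = (hist[k:] * centers[k:]).sum() / w1
        var = w0 / total * w1 / total * (m0 - m1) ** 2
        if var > best:
            best, best_t = var, centers[k - 1]
    return best_t


def _area_errors(records, truth):
    """Relative area error per droplet, matched by nearest centroid."""
    errors = []
    for _, t in truth.iterrows():
        d2 = ((records["centroid-0"] - t["center_row"]) ** 2
              + (records["centroid-1"] - t["center_col"]) ** 2)
        rec = records.loc[d2.idxmin()]
        errors.append(abs(rec["area_px"] - t["area_px_true"])
                      / t["area_px_true"])
    return np.array(errors)


def _grid_specs(radii, shape=(512, 512), spacing=100, **kw):
    specs = []
    positions = [(y, x) for y in range(80, shape[0] - 60, spacing)
                 for x in range(80, shape[1] - 60, spacing)]
    for (y, x), r in zip(positions, radii):
        specs.append(cp.DropletSpec(center=(y, x), radius=r, **kw))
    return specs


class TestGenerateMicrograph:
    def test_empty_spec_zero_noise_is_constant(self):
        img, truth = cp.generate_micrograph([], shape=(64, 64),
                                            background=0.05, noise_sd=0.0)
        assert np.all(img.image == 0.05)
        assert truth.empty

    def test_rasterized_disc_area(self):
        specs = [cp.DropletSpec(center=(100.0, 100.0), radius=10.0)]
        _, truth = cp.generate_micrograph(specs, shape=(200, 200), noise_sd=0.0)
        assert truth.loc[0, "area_px_true"] == pytest.approx(np.pi * 100,
                                                             rel=0.04)

    def test_seeded_regeneration_is_bit_identical(self):
        specs = _grid_specs([8, 10, 12], shape=(256, 256), spacing=90)
        a, _ = cp.generate_micrograph(specs, shape=(256, 256), seed=5)
        b, _ = cp.generate_micrograph(specs, shape=(256, 256), seed=5)
        np.testing.assert_array_equal(a.image, b.image)

    def test_overlapping_droplets_warn(self):
        specs = [cp.DropletSpec(center=(50.0, 50.0), radius=10.0),
                 cp.DropletSpec(center=(55.0, 50.0), radius=10.0)]
        with pytest.warns(UserWarning, match="overlap"):
            cp.generate_micrograph(specs, shape=(100, 100), noise_sd=0.0)

    def test_centre_must_be_inside(self):
        with pytest.raises(ValueError):
            cp.generate_micrograph([cp.DropletSpec(center=(300.0, 10.0),
                                                   radius=5.0)],
                                   shape=(100, 100))


class TestSegmentDroplets:
    def test_otsu_matches_exhaustive_maximizer(self):
        rng = np.random.default_rng(2)
        # bimodal image
        img = np.concatenate([rng.normal(0.2, 0.04, 3000),
                              rng.normal(0.8, 0.05, 1000)])
        img = np.clip(img, 0, 1).reshape(40, 100)
        seg = cp.segment_droplets(cp.Micrograph(img))
        norm = (img - img.min()) / (img.max() - img.min())
        assert seg.threshold == pytest.approx(brute_force_otsu(norm),
                                              abs=1 / 256)

    def test_uniform_image_warns_and_returns_nothing(self):
        with pytest.warns(UserWarning, match="uniform"):
            seg = cp.segment_droplets(cp.Micrograph(np.full((32, 32), 0.4)))
        assert seg.objects.empty

    def test_tiny_object_discarded_by_diameter(self):
        img = np.zeros((64, 64))
        img[30:32, 30:32] = 0.9          # ~2 px equivalent diameter
        seg = cp.segment_droplets(cp.Micrograph(img))
        assert len(seg.objects) == 0

    def test_clean_disc_is_a_single_object(self):
        specs = [cp.DropletSpec(center=(64.0, 64.0), radius=10.0)]
        mg, _ = cp.generate_micrograph(specs, shape=(128, 128), noise_sd=0.0)
        seg = cp.segment_droplets(mg)
        assert len(seg.objects) == 1

    def test_oversize_object_discarded(self):
        specs = [cp.DropletSpec(center=(128.0, 128.0), radius=45.0)]
        mg, _ = cp.generate_micrograph(specs, shape=(256, 256), noise_sd=0.0)
        seg = cp.segment_droplets(mg, diameter_range=(4, 70))
        assert len(seg.objects) == 0     # diameter 90 px > 70


class TestFiltersAndMeasurement:
    @pytest.fixture(scope="class")
    def mixed_segmentation(self):
        specs = [
            cp.DropletSpec(center=(60.0, 60.0), radius=10.0, peak_intensity=0.9),
            cp.DropletSpec(center=(60.0, 180.0), radius=10.0, peak_intensity=0.9,
                           eccentricity=0.9, orientation=0.4),
            cp.DropletSpec(center=(180.0, 60.0), radius=10.0,
                           peak_intensity=0.06),
        ]
        mg, truth = cp.generate_micrograph(specs, shape=(240, 240),
                                           noise_sd=0.0, background=0.0)
        return cp.segment_droplets(mg), truth

    def test_eccentricity_filter_removes_elongated(self, mixed_segmentation):
        seg, _ = mixed_segmentation
        kept = cp.filter_droplets(seg.objects, intensity_range=(0.0, 1.0))
        assert np.all(kept["eccentricity"] <= 0.6)
        assert len(kept) == len(seg.objects) - 1

    def test_intensity_filter_removes_dim(self, mixed_segmentation):
        seg, _ = mixed_segmentation
        kept = cp.filter_droplets(seg.objects, ecc_max=1.0)
        assert np.all(kept["median_intensity"] >= 0.1)

    def test_filters_idempotent_and_commute(self, mixed_segmentation):
        seg, _ = mixed_segmentation
        once = cp.filter_droplets(seg.objects)
        twice = cp.filter_droplets(once)
        pd.testing.assert_frame_equal(once, twice)
        ecc_first = cp.filter_droplets(
            cp.filter_droplets(seg.objects, intensity_range=(0.0, 1.0)),
            ecc_max=2.0)
        int_first = cp.filter_droplets(
            cp.filter_droplets(seg.objects, ecc_max=2.0),
            intensity_range=(0.0, 1.0))
        assert sorted(ecc_first["label"]) == sorted(int_first["label"])

    def test_single_pixel_area_conversion(self):
        objects = pd.DataFrame({"label": [1], "area": [1.0],
                                "intensity_mean": [0.5]})
        measured = cp.measure_droplets(objects)
        assert measured.loc[0, "area_um2"] == pytest.approx(0.010645)

    def test_hundred_pixel_area_conversion(self):
        objects = pd.DataFrame({"label": [1], "area": [100.0],
                                "intensity_mean": [0.5]})
        measured = cp.measure_droplets(objects)
        assert measured.loc[0, "area_um2"] == pytest.approx(1.0645)

    def test_integrated_intensity_of_uniform_object(self):
        img = np.zeros((64, 64))
        img[20:30, 20:30] = 0.8
        seg = cp.segment_droplets(cp.Micrograph(img))
        measured = cp.measure_droplets(seg)
        # normalized image: object pixels are exactly 1.0 after min-max
        assert measured.loc[0, "integrated_intensity"] == pytest.approx(100.0)


class TestEndToEnd:
    def test_count_and_area_recovery(self):
        radii = [6, 8, 10, 12, 9, 7, 11, 8, 10]
        specs = _grid_specs(radii, shape=(512, 512), spacing=120,
                            peak_intensity=0.85)
        mg, truth = cp.generate_micrograph(specs, shape=(512, 512),
                                           background=0.02, noise_sd=0.02,
                                           seed=3)
        records = cp.quantify_micrograph(mg)
        assert len(records) == len(specs)
        rel = _area_errors(records, truth)
        assert np.all(rel < 0.05)

    def test_pipeline_is_deterministic(self):
        specs = _grid_specs([8, 10], shape=(256, 256), spacing=90)
        mg, _ = cp.generate_micrograph(specs, shape=(256, 256), seed=1)
        a = cp.quantify_micrograph(mg)
        b = cp.quantify_micrograph(mg)
        pd.testing.assert_frame_equal(a, b)


class TestSummarizeAssay:
    def _records(self, values_by_condition):
        rows = []
        for cond, measurements in values_by_condition.items():
            for m, vals in enumerate(measurements):
                for v in vals:
                    rows.append({"condition": cond, "measurement": f"m{m}",
                                 "area_um2": v})
        return pd.DataFrame(rows)

    def test_identical_groups_give_t0_p1(self):
        rec = self._records({"a": [[1, 2], [2, 3], [3, 4]],
                             "b": [[1, 2], [2, 3], [3, 4]]})
        summary = cp.summarize_assay(rec)
        t = summary.tests.iloc[0]
        assert t["t"] == 0.0 and t["p"] == 1.0 and t["significance"] == "ns"

    def test_pooled_t_matches_closed_form(self):
        rec = self._records({"a": [[1], [2], [3]], "b": [[4], [5], [6]]})
        summary = cp.summarize_assay(rec)
        t = summary.tests.iloc[0]["t"]
        # medians are (1,2,3) vs (4,5,6): t = -3/sqrt(2/3)
        assert t == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0))

    def test_summary_uses_medians_not_pooled_droplets(self):
        rec = self._records({"a": [[1, 1, 100], [2, 2, 2], [3, 3, 3]]})
        summary = cp.summarize_assay(rec)
        med = summary.medians.set_index("measurement")["median"]
        assert med["m0"] == 1.0          # median, not mean of droplets
        cond = summary.conditions.iloc[0]
        assert cond["mean_of_medians"] == pytest.approx(2.0)
        assert cond["n_measurements"] == 3

    def test_significance_tiers(self):
        assert significance_tier(0.03) == "*"
        assert significance_tier(0.005) == "**"
        assert significance_tier(0.0005) == "***"
        assert significance_tier(0.00005) == "****"
        assert significance_tier(0.2) == "ns"

    def test_errors(self):
        with pytest.raises(ValueError):
            cp.summarize_assay(pd.DataFrame())
        rec = self._records({"a": [[1]], "b": [[2]]})
        with pytest.raises(ValueError, match=">= 2 measurements"):
            cp.summarize_assay(rec)
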