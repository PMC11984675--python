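import numpy as np
import pandas as pd
import pytest

import geosilence as gs
from geosilence.mims import (
    R13C_NATURAL,
    R15N_NATURAL,
    compare_groups,
    detect_globules,
    enrichment_image,
    line_profile,
    mad_dispersion,
    pixel_pca,
    region_mean_enrichment,
    segment_regions,
)
from geosilence.synthetic import IonImageSpec, generate_ion_images


@pytest.fixture(scope="module")
def globule_image():
    planes, truth = generate_ion_images(n_globules=3, globule_radius_px=5, seed=2)
    return planes, truth


@pytest.fixture(scope="module")
def ratios(globule_image):
    planes, _ = globule_image
    c_ratio = enrichment_image(planes["13C"], planes["12C"], R13C_NATURAL)
    n_ratio = enrichment_image(planes["12C15N"], planes["12C14N"], R15N_NATURAL)
    return c_ratio, n_ratio


class TestEnrichmentImage:
    def test_natural_abundance_maps_to_zero(self):
        major = np.full((4, 4), 10_000.0)
        minor = major * R13C_NATURAL
        ratio = enrichment_image(minor, major, R13C_NATURAL)
        assert np.allclose(ratio.enrichment, 0.0)

    def test_doubled_ratio_is_100_percent(self):
        major = np.full((4, 4), 10_000.0)
        ratio = enrichment_image(major * 2 * R13C_NATURAL, major, R13C_NATURAL)
        assert np.allclose(ratio.enrichment, 100.0)

    def test_poisson_null_mean_within_one_percent(self):
        rng = np.random.default_rng(0)
        major = rng.poisson(10_000, size=(100, 100)).astype(float)
        minor = rng.poisson(10_000 * R13C_NATURAL, size=(100, 100)).astype(float)
        ratio = enrichment_image(minor, major, R13C_NATURAL)
        assert abs(np.nanmean(ratio.enrichment)) < 1.0

    def test_low_count_pixels_masked_not_zeroed(self):
        major = np.array([[10_000.0, 5.0]])
        minor = np.array([[112.0, 1.0]])
        ratio = enrichment_image(minor, major, R13C_NATURAL, min_major_counts=100)
        assert ratio.valid[0, 0] and not ratio.valid[0, 1]
        assert np.isnan(ratio.enrichment[0, 1])

    def test_all_invalid_is_an_error(self):
        with pytest.raises(ValueError, match="min_major_counts"):
            enrichment_image(
                np.ones((3, 3)), np.ones((3, 3)), R13C_NATURAL, min_major_counts=100
            )

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        major = rng.poisson(5000, (20, 20)).astype(float)
        minor = rng.poisson(60, (20, 20)).astype(float)
        a = enrichment_image(minor, major, R13C_NATURAL)
        b = enrichment_image(minor * 3, major * 3, R13C_NATURAL)
        assert np.allclose(a.enrichment, b.enrichment, equal_nan=True)


class TestSegmentation:
    def test_recovers_truth_nucleus(self, globule_image):
        planes, truth = globule_image
        masks = segment_regions(planes["31P"], planes["12C14N"])
        intersection = (masks.nucleus & truth["nucleus"]).sum()
        union = (masks.nucleus | truth["nucleus"]).sum()
        assert intersection / union >= 0.9

    def test_uniform_plane_is_an_error(self):
        with pytest.raises(ValueError, match="contrast"):
            segment_regions(np.ones((32, 32)), np.ones((32, 32)))

    def test_cytoplasm_is_cell_minus_nucleus(self, globule_image):
        planes, _ = globule_image
        masks = segment_regions(planes["31P"], planes["12C14N"])
        assert not (masks.nucleus & masks.cytoplasm).any()
        assert not (masks.cytoplasm & masks.background).any()
        assert (masks.nucleus | masks.cytoplasm | masks.background).all()


class TestDispersion:
    def test_constant_image_has_zero_mad(self):
        image = np.full((20, 20), 5.0)
        assert mad_dispersion(image, np.ones((20, 20), dtype=bool)) == 0.0

    def test_hand_computed_reference(self):
        values = np.array([[1.0, 2.0, 3.0, 4.0, 100.0]])
        mask = np.ones_like(values, dtype=bool)
        assert mad_dispersion(values, mask, min_pixels=5) == 1.0

    def test_shift_invariance_and_linear_scaling(self):
        rng = np.random.default_rng(3)
        image = rng.normal(10, 3, (30, 30))
        mask = np.ones((30, 30), dtype=bool)
        base = mad_dispersion(image, mask)
        assert mad_dispersion(image + 42.0, mask) == pytest.approx(base)
        assert mad_dispersion(image * 3.0, mask) == pytest.approx(3 * base)

    def test_too_few_pixels_is_an_error(self):
        with pytest.raises(ValueError, match="pixels"):
            mad_dispersion(np.ones((5, 5)), np.ones((5, 5), dtype=bool))

    def test_globules_increase_nuclear_mad(self):
        results = {}
        for n_globules in (0, 4):
            planes, truth = generate_ion_images(
                n_globules=n_globules, globule_radius_px=6, seed=7
            )
            ratio = enrichment_image(planes["13C"], planes["12C"], R13C_NATURAL)
            results[n_globules] = mad_dispersion(ratio, truth["nucleus"])
        assert results[4] > results[0]


class TestRegionMeans:
    def test_uniform_enrichment(self):
        image = np.full((20, 20), 50.0)
        from geosilence.mims import NuclearMask

        nucleus = np.zeros((20, 20), dtype=bool)
        nucleus[5:15, 5:15] = True
        masks = NuclearMask(
            nucleus=nucleus, cytoplasm=~nucleus, background=np.zeros_like(nucleus)
        )
        means = region_mean_enrichment(image, masks)
        assert means.loc["nucleus", "mean_enrichment"] == 50.0
        assert means.loc["cytoplasm", "mean_enrichment"] == 50.0

    def test_contrasting_regions_recovered(self, globule_image, ratios):
        planes, truth = globule_image
        _, n_ratio = ratios
        masks = segment_regions(planes["31P"], planes["12C14N"])
        means = region_mean_enrichment(n_ratio, masks)
        spec = IonImageSpec()
        assert means.loc["nucleus", "mean_enrichment"] == pytest.approx(
            spec.n15_enrichment[2], abs=25
        )
        assert means.loc["cytoplasm", "mean_enrichment"] == pytest.approx(
            spec.n15_enrichment[1], abs=25
        )


class TestPixelPCA:
    def test_explained_variance_trace_identity(self, globule_image, ratios):
        planes, truth = globule_image
        c_ratio, n_ratio = ratios
        features = {
            "c13": c_ratio.enrichment,
            "n15": n_ratio.enrichment,
            "cn": planes["12C14N"],
            "p": planes["31P"],
            "s": planes["32S"],
        }
        pca = pixel_pca(features, truth["nucleus"])
        assert np.isclose(pca.explained_variance.sum(), len(pca.feature_names), atol=1e-8)

    def test_correlated_features_load_on_first_component(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(40, 40))
        features = {"a": base, "b": 3 * base + 1e-9 * rng.normal(size=(40, 40))}
        pca = pixel_pca(features, np.ones((40, 40), dtype=bool))
        assert pca.explained_variance[0] / pca.explained_variance.sum() > 0.999

    def test_constant_feature_dropped_with_warning(self):
        rng = np.random.default_rng(0)
        features = {
            "a": rng.normal(size=(20, 20)),
            "b": rng.normal(size=(20, 20)),
            "flat": np.ones((20, 20)),
        }
        with pytest.warns(UserWarning, match="flat"):
            pca = pixel_pca(features, np.ones((20, 20), dtype=bool))
        assert pca.feature_names == ["a", "b"]

    def test_globule_pixels_near_lamina_pixels_in_pc_space(self):
        """Globules and condensed lamina share composition, so their pixel
        clouds overlap in PC1/PC2 while background nucleoplasm sits apart."""
        planes, truth = generate_ion_images(
            n_globules=3, globule_radius_px=5, lamina_ring=True, seed=5
        )
        c_ratio = enrichment_image(planes["13C"], planes["12C"], R13C_NATURAL)
        n_ratio = enrichment_image(planes["12C15N"], planes["12C14N"], R15N_NATURAL)
        pca = pixel_pca(
            {
                "c13": c_ratio.enrichment,
                "n15": n_ratio.enrichment,
                "cn": planes["12C14N"],
                "p": planes["31P"],
                "s": planes["32S"],
            },
            truth["nucleus"],
        )
        rows, cols = pca.pixel_index
        kinds = np.where(
            truth["globules"][rows, cols] > 0,
            "globule",
            np.where(truth["lamina"][rows, cols], "lamina", "plain"),
        )
        scores = pca.scores[:, :2]
        centroid = {k: scores[kinds == k].mean(axis=0) for k in np.unique(kinds)}
        d_globule_lamina = np.linalg.norm(centroid["globule"] - centroid["lamina"])
        d_globule_plain = np.linalg.norm(centroid["globule"] - centroid["plain"])
        assert d_globule_lamina < d_globule_plain


class TestLineProfile:
    def test_constant_image_gives_constant_profile(self):
        table = line_profile(np.full((20, 20), 3.0), (10, 2), (10, 17))
        assert np.allclose(table["value"], 3.0)

    def test_reversed_endpoints_reverse_the_profile(self):
        rng = np.random.default_rng(0)
        image = rng.normal(size=(20, 20))
        forward = line_profile(image, (5, 2), (5, 17))["value"].to_numpy()
        backward = line_profile(image, (5, 17), (5, 2))["value"].to_numpy()
        assert np.allclose(forward, backward[::-1])

    def test_profile_across_globule_shows_central_n15_minimum(self):
        planes, truth = generate_ion_images(
            n_globules=1, globule_radius_px=6, seed=3
        )
        n_ratio = enrichment_image(planes["12C15N"], planes["12C14N"], R15N_NATURAL)
        rows, cols = np.nonzero(truth["globules"] == 1)
        cy, cx = rows.mean(), cols.mean()
        table = line_profile(
            np.nan_to_num(n_ratio.enrichment), (cy, cx - 12), (cy, cx + 12),
            width_px=3, pixel_size_nm=100,
        )
        center = table["value"].iloc[len(table) // 2 - 2 : len(table) // 2 + 3].mean()
        flanks = pd.concat([table["value"].iloc[:3], table["value"].iloc[-3:]]).mean()
        assert center < flanks
        assert "distance_um" in table.columns

    def test_zero_length_line_is_an_error(self):
        with pytest.raises(ValueError, match="zero-length"):
            line_profile(np.ones((5, 5)), (2, 2), (2, 2))


class TestGlobuleDetection:
    def test_three_injected_globules_recovered(self, globule_image, ratios):
        planes, truth = globule_image
        c_ratio, n_ratio = ratios
        calls = detect_globules(
            c_ratio, n_ratio, planes["31P"], truth["nucleus"], pixel_size_nm=100
        )
        assert len(calls) == 3
        truth_centers = []
        for k in (1, 2, 3):
            rows, cols = np.nonzero(truth["globules"] == k)
            truth_centers.append((rows.mean(), cols.mean()))
        for call in calls:
            nearest = min(
                np.hypot(call.centroid[0] - ty, call.centroid[1] - tx)
                for ty, tx in truth_centers
            )
            assert nearest <= 2.0

    def test_diameter_recovered_within_20_percent(self):
        # radius 5 px at 100 nm/px -> true diameter 1.0 um
        planes, truth = generate_ion_images(
            n_globules=1, globule_radius_px=5, seed=9
        )
        c_ratio = enrichment_image(planes["13C"], planes["12C"], R13C_NATURAL)
        n_ratio = enrichment_image(planes["12C15N"], planes["12C14N"], R15N_NATURAL)
        calls = detect_globules(
            c_ratio, n_ratio, planes["31P"], truth["nucleus"], pixel_size_nm=100
        )
        assert len(calls) == 1
        assert abs(calls[0].equivalent_diameter_um - 1.0) <= 0.2

    def test_null_nuclei_rarely_produce_calls(self):
        false_positives = 0
        for seed in range(40):
            planes, truth = generate_ion_images(n_globules=0, seed=seed)
            c_ratio = enrichment_image(planes["13C"], planes["12C"], R13C_NATURAL)
            n_ratio = enrichment_image(planes["12C15N"], planes["12C14N"], R15N_NATURAL)
            calls = detect_globules(
                c_ratio, n_ratio, planes["31P"], truth["nucleus"], pixel_size_nm=100
            )
            false_positives += bool(calls)
        assert false_positives / 40 <= 0.05


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=30)
        result = compare_groups(values, values)
        assert result.p_value > 0.9

    def test_normal_samples_use_t_test(self):
        rng = np.random.default_rng(1)
        result = compare_groups(rng.normal(0, 1, 20), rng.normal(5, 1, 20))
        assert result.test == "t-test"
        assert result.p_value < 1e-3

    def test_heavy_tailed_samples_use_mann_whitney(self):
        rng = np.random.default_rng(2)
        heavy = rng.standard_cauchy(40)
        result = compare_groups(heavy, heavy + 0.1)
        assert result.test == "mann-whitney"

    def test_small_groups_are_an_error(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])
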