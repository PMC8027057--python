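"""Isotope ratio quantification, spatial classification and colocalization."""

import numpy as np
import pandas as pd
import pytest

import syntronet as sn
from syntronet.errors import DegenerateDataError, ParameterError
from syntronet.imaging import IonCountScene, TwoChannelImage


# disk of radius 15 um at 0.1 um pixels: the raster centre sits at 15.2 um
def uniform_scene(atom_frac=0.02, counts=200.0, seed=0):
    rois = [
        sn.RoiSpec("ANME-2b", 15.2, 15.2, 1.0),  # disk centre, 15 um from boundary
        sn.RoiSpec("SEEP-SRB1g", 7.0, 15.2, 1.0),  # 6.8 um from boundary
    ]
    return sn.gen_nanosims_scene(15.0, 0.1, rois, sn.uniform_profile(atom_frac), counts, seed=seed)


class TestAtomFraction:
    def test_pure_light_isotope_is_zero(self):
        assert sn.atom_fraction(0, 1000) == 0.0

    def test_equal_counts_give_half(self):
        assert sn.atom_fraction(500, 500) == 0.5

    def test_natural_abundance_arithmetic(self):
        assert 100 * sn.atom_fraction(36, 9964) == pytest.approx(0.36)

    def test_zero_total_is_nan_flagged(self, caplog):
        assert np.isnan(sn.atom_fraction(0, 0))

    def test_ratio_of_sums_equals_count_weighted_mean_of_pixel_fractions(self):
        rng = np.random.default_rng(4)
        c15 = rng.integers(0, 50, 100)
        c14 = rng.integers(1, 500, 100)
        ratio_of_sums = c15.sum() / (c15.sum() + c14.sum())
        weights = c15 + c14
        weighted_mean = np.sum(weights * (c15 / weights)) / weights.sum()
        assert ratio_of_sums == pytest.approx(weighted_mean, rel=1e-12)


class TestRoiAtomPercent:
    def test_two_pixel_hand_ratio_of_sums(self):
        c15 = np.array([[1, 3]])
        c14 = np.array([[99, 97]])
        scene = IonCountScene(
            c14=c14, c15=c15, pixel_size_um=1.0,
            mask=np.ones((1, 2), bool), roi_labels=np.ones((1, 2), np.int64),
            roi_meta=pd.DataFrame(
                [{"roi_id": 1, "taxon": "ANME-2b", "centroid_x_um": 1.0, "centroid_y_um": 0.5}]
            ),
        )
        assert sn.roi_atom_percent(scene, 1) == pytest.approx(2.0)

    def test_uniform_scene_rois_match_pixelwise_ratio(self):
        scene = uniform_scene(atom_frac=0.02, counts=500.0)
        for rid in scene.roi_ids:
            pix = scene.roi_labels == rid
            n_tot = scene.c14[pix].sum() + scene.c15[pix].sum()
            assert n_tot >= 1e5
            est = sn.roi_atom_percent(scene, rid) / 100
            se = np.sqrt(0.02 * 0.98 / n_tot)
            assert abs(est - 0.02) <= 3 * se

    def test_estimator_bias_below_monte_carlo_error(self):
        ests = []
        for seed in range(40):
            scene = uniform_scene(atom_frac=0.02, counts=400.0, seed=seed)
            ests.extend(sn.roi_atom_percent(scene, rid) / 100 for rid in scene.roi_ids)
        ests = np.asarray(ests)
        # unbiasedness as a 3-sigma z-test on the Monte-Carlo mean
        z = (ests.mean() - 0.02) / (ests.std(ddof=1) / np.sqrt(len(ests)))
        assert abs(z) < 3.0

    def test_unknown_roi_rejected(self):
        with pytest.raises(ParameterError):
            sn.roi_atom_percent(uniform_scene(), 99)


class TestInteriorExterior:
    def test_disk_center_is_interior_boundary_is_exterior(self):
        scene = uniform_scene()
        labels = sn.classify_interior_exterior(scene, depth_threshold_um=10.0)
        assert labels[1] == "interior"  # centroid at the disk centre of a 15 um disk
        assert labels[2] == "exterior"

    def test_matches_bruteforce_pixel_scan(self):
        scene = uniform_scene(counts=20.0)
        px = scene.pixel_size_um
        for threshold in (5.0, 10.0):
            labels = sn.classify_interior_exterior(scene, threshold)
            for row in scene.roi_meta.itertuples(index=False):
                best = np.inf
                for i in range(scene.mask.shape[0]):
                    for j in range(scene.mask.shape[1]):
                        if not scene.mask[i, j]:
                            d = np.hypot(
                                (j + 0.5) * px - row.centroid_x_um,
                                (i + 0.5) * px - row.centroid_y_um,
                            )
                            best = min(best, d)
                expected = "interior" if best >= threshold else "exterior"
                assert labels[int(row.roi_id)] == expected


class TestSummaries:
    def test_groups_carry_roi_counts_and_ordering(self):
        profile = sn.linear_gradient_profile(0.004, 0.03, 8.0)
        rois = [
            sn.RoiSpec("ANME-2b", 15.2, 15.2, 1.0),  # interior (15 um deep)
            sn.RoiSpec("ANME-2b", 15.2, 18.0, 1.0),  # interior (12.2 um deep)
            sn.RoiSpec("ANME-2b", 5.0, 15.2, 1.0),  # exterior (4.8 um deep)
            sn.RoiSpec("SEEP-SRB1g", 24.0, 15.2, 1.0),  # exterior (6.2 um deep)
        ]
        scene = sn.gen_nanosims_scene(15.0, 0.1, rois, profile, 200.0, seed=1)
        summary = sn.summarize_rois(scene, depth_threshold_um=10.0)
        anme = summary[summary["taxon"] == "ANME-2b"].set_index("region")
        assert anme.loc["interior", "n"] == 2 and anme.loc["exterior", "n"] == 1
        # planted inward-increasing gradient: interior group more enriched
        assert anme.loc["interior", "mean_atom_percent"] > anme.loc["exterior", "mean_atom_percent"]

    def test_identical_rois_have_zero_dispersion(self):
        c = np.full((1, 4), 50)
        scene = IonCountScene(
            c14=c, c15=c, pixel_size_um=1.0, mask=np.ones((1, 4), bool),
            roi_labels=np.array([[1, 1, 2, 2]]),
            roi_meta=pd.DataFrame(
                [
                    {"roi_id": 1, "taxon": "t", "centroid_x_um": 1.0, "centroid_y_um": 0.5},
                    {"roi_id": 2, "taxon": "t", "centroid_x_um": 3.0, "centroid_y_um": 0.5},
                ]
            ),
        )
        summary = sn.summarize_rois(scene, depth_threshold_um=0.0)
        assert summary["mean_atom_percent"].iloc[0] == pytest.approx(50.0)
        assert summary["sd_atom_percent"].iloc[0] == 0.0


class TestColocalization:
    def test_identical_channels_give_pc_one(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 100, (50, 50))
        assert sn.pearson_coloc(TwoChannelImage(a=a, b=a.copy())) == pytest.approx(1.0)

    def test_inverted_channel_gives_pc_minus_one(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 100, (50, 50))
        img = TwoChannelImage(a=a, b=a.max() - a)
        assert sn.pearson_coloc(img) == pytest.approx(-1.0)

    def test_independent_noise_has_negligible_pc(self):
        rng = np.random.default_rng(2)
        img = TwoChannelImage(a=rng.uniform(0, 1, (100, 100)), b=rng.uniform(0, 1, (100, 100)))
        assert abs(sn.pearson_coloc(img)) < 0.05

    def test_pc_invariant_under_affine_rescaling(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 50, (40, 40))
        b = rng.uniform(0, 50, (40, 40))
        base = sn.pearson_coloc(TwoChannelImage(a=a, b=b))
        scaled = sn.pearson_coloc(TwoChannelImage(a=3.0 * a + 7.0, b=0.5 * b + 1.0))
        assert scaled == pytest.approx(base, rel=1e-12)

    def test_zero_variance_is_nan(self):
        img = TwoChannelImage(a=np.ones((5, 5)), b=np.ones((5, 5)))
        assert np.isnan(sn.pearson_coloc(img))

    def test_manders_full_overlap_and_disjoint(self):
        a = np.zeros((10, 10))
        a[2:5, 2:5] = 7.0
        assert sn.manders_coloc(TwoChannelImage(a=a, b=a.copy())) == (1.0, 1.0)
        b = np.zeros((10, 10))
        b[6:9, 6:9] = 3.0
        assert sn.manders_coloc(TwoChannelImage(a=a, b=b)) == (0.0, 0.0)

    def test_manders_zero_intensity_rejected(self):
        with pytest.raises(DegenerateDataError):
            sn.manders_coloc(TwoChannelImage(a=np.zeros((3, 3)), b=np.ones((3, 3))))

    def test_scatter_record_count_and_diagonal(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(0, 10, (20, 20))
        mask = rng.random((20, 20)) < 0.5
        df = sn.intensity_scatter(TwoChannelImage(a=a, b=a.copy()), mask)
        assert len(df) == int(mask.sum())
        assert np.allclose(df["a"], df["b"])

    def test_scatter_round_trips_through_csv(self, tmp_path):
        rng = np.random.default_rng(6)
        img = TwoChannelImage(a=rng.uniform(0, 9, (8, 8)), b=rng.uniform(0, 9, (8, 8)))
        df = sn.intensity_scatter(img)
        path = tmp_path / "scatter.csv"
        df.to_csv(path, index=False)
        back = pd.read_csv(path)
        assert np.allclose(back.values, df.values)


class TestSceneIO:
    def test_scene_round_trips_through_tiff_and_csv(self, tmp_path):
        scene = uniform_scene(counts=30.0)
        sn_imaging = pytest.importorskip("syntronet.imaging")
        sn_imaging.write_scene(scene, tmp_path / "s.tiff", tmp_path / "r.csv")
        back = sn_imaging.read_scene(tmp_path / "s.tiff", tmp_path / "r.csv")
        assert np.array_equal(back.c14, scene.c14)
        assert np.array_equal(back.c15, scene.c15)
        assert np.array_equal(back.roi_labels, scene.roi_labels)
        assert back.pixel_size_um == pytest.approx(scene.pixel_size_um)
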