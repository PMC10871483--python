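import numpy as np
import pytest

from lungmorph import airseg, phantomgen as pg
from lungmorph.gridio import LabelMap, Mask


class TestPhantomSpec:
    def test_stage_defaults_are_group_means(self):
        spec = pg.PhantomSpec.for_stage("neonate")
        assert (spec.sac_diameter_target, spec.septum_thickness_target) == (349.0, 41.0)
        spec = pg.PhantomSpec.for_stage("7dpn")
        assert (spec.sac_diameter_target, spec.septum_thickness_target) == (192.0, 24.0)
        spec = pg.PhantomSpec.for_stage("57dpn")
        assert (spec.sac_diameter_target, spec.septum_thickness_target) == (51.0, 10.0)

    def test_contrast_polarity_enforced(self):
        with pytest.raises(ValueError):
            pg.PhantomSpec.for_stage("neonate", gray_air=30000, gray_tissue=5000)

    def test_unresolvable_septa_rejected(self):
        with pytest.raises(ValueError, match="unresolvable"):
            pg.PhantomSpec.for_stage("57dpn", spacing=8.0)  # 10 um septa at 8 um


class TestStagePhantom:
    def test_neonate_has_six_lobar_sacs(self, neonate_phantom):
        assert len(neonate_phantom.sac_labels.labels()) == 6

    def test_determinism_same_seed_bitwise(self):
        spec = dict(stage_label="neonate", rng_seed=21, n_lobes=3, spacing=10.0,
                    sac_diameter_target=200.0, septum_thickness_target=30.0,
                    subdivision_rounds=1)
        a = pg.generate_stage_phantom(pg.PhantomSpec(**spec))
        b = pg.generate_stage_phantom(pg.PhantomSpec(**spec))
        np.testing.assert_array_equal(a.gray.values, b.gray.values)
        assert a.true_VA == b.true_VA
        assert a.true_mean_diameter == b.true_mean_diameter

    def test_distinct_seeds_differ(self):
        kw = dict(stage_label="neonate", n_lobes=3, spacing=10.0,
                  sac_diameter_target=200.0, septum_thickness_target=30.0,
                  subdivision_rounds=1)
        a = pg.generate_stage_phantom(pg.PhantomSpec(rng_seed=1, **kw))
        b = pg.generate_stage_phantom(pg.PhantomSpec(rng_seed=2, **kw))
        assert not np.array_equal(a.terminal_mask.values, b.terminal_mask.values)

    def test_neonate_truth_diameter_matches_group_mean(self, neonate_phantom):
        assert neonate_phantom.true_mean_diameter == pytest.approx(349.0, rel=0.10)

    def test_mask_containment_invariants(self, neonate_phantom):
        t = neonate_phantom
        assert not (t.tree_mask.values & t.terminal_mask.values).any()
        air = t.tree_mask.values | t.terminal_mask.values
        assert not (air & ~t.lung_mask.values).any()
        assert t.true_VL >= t.true_VA > 0

    def test_air_continuity_from_trachea(self, neonate_phantom):
        """Flood fill of the air band from the trachea reaches the sacs."""
        t = neonate_phantom
        filtered = airseg.denoise(t.gray)
        mask = airseg.region_grow(
            filtered, airseg.SegmentationConfig(seed=t.trachea_seed)
        )
        reached = (mask.values & t.terminal_mask.values).sum()
        assert reached / t.terminal_mask.count() >= 0.99


class TestSubdivideSacs:
    SP = (8.0, 8.0, 8.0)

    def _one_sphere(self, r_um=160.0):
        n = int(2 * r_um / self.SP[0]) + 8
        zz, yy, xx = np.ogrid[:n, :n, :n]
        c = n / 2
        ball = ((zz - c + 0.5) ** 2 + (yy - c + 0.5) ** 2 + (xx - c + 0.5) ** 2) <= (
            r_um / self.SP[0]
        ) ** 2
        return LabelMap(ball.astype(np.int32), self.SP)

    def test_zero_rounds_identity(self):
        sacs = self._one_sphere()
        got = pg.subdivide_sacs(sacs, 0, 30.0)
        np.testing.assert_array_equal(got.values, sacs.values)

    def test_single_split_voxel_count_oracle(self):
        sacs = self._one_sphere()
        before = int((sacs.values > 0).sum())
        rng = np.random.default_rng(3)
        got = pg.subdivide_sacs(sacs, 1, 32.0, rng=rng)
        labels = np.unique(got.values)
        assert set(labels) - {0} == {1, 2}
        # air volume drops by exactly the slab ∩ sphere voxels
        removed = before - int((got.values > 0).sum())
        # independent count of the slab voxels from the same plane
        rng2 = np.random.default_rng(3)
        idx = np.argwhere(sacs.values > 0)
        coords = (idx + 0.5) * self.SP[0]
        centroid = coords.mean(axis=0)
        normal = rng2.normal(size=3)
        normal /= np.linalg.norm(normal)
        signed = (coords - centroid) @ normal
        assert removed == int((np.abs(signed) <= 16.0).sum())

    def test_sac_count_nondecreasing_and_diameter_shrinks(self, rng):
        sacs = self._one_sphere(200.0)
        prev_count = 1
        prev_equiv = None
        voxvol = float(np.prod(self.SP))
        for rounds in (1, 2, 3):
            got = pg.subdivide_sacs(
                self._one_sphere(200.0), rounds, 24.0,
                rng=np.random.default_rng(9),
            )
            labels, counts = np.unique(got.values[got.values > 0], return_counts=True)
            assert len(labels) >= prev_count
            equiv = np.mean((6 * counts * voxvol / np.pi) ** (1 / 3))
            if prev_equiv is not None:
                assert equiv < prev_equiv
            prev_count = len(labels)
            prev_equiv = equiv

    def test_too_thin_septum_rejected(self):
        with pytest.raises(ValueError, match="thinner"):
            pg.subdivide_sacs(self._one_sphere(), 1, 4.0)


class TestRenderGray:
    SP = (10.0, 10.0, 10.0)

    def _masks(self):
        lung = np.zeros((20, 20, 20), dtype=bool)
        lung[4:16, 4:16, 4:16] = True
        air = np.zeros_like(lung)
        air[7:13, 7:13, 7:13] = True
        return Mask(lung, self.SP), Mask(air, self.SP)

    def test_noiseless_blurless_is_exactly_two_valued_inside_lung(self):
        lung, air = self._masks()
        grid = pg.render_gray(lung, air, gray_air=5000, gray_tissue=30000)
        inside = np.unique(grid.values[lung.values])
        assert set(inside) == {5000, 30000}

    def test_contrast_polarity(self):
        lung, air = self._masks()
        grid = pg.render_gray(
            lung, air, blur_sigma_um=5.0, noise_sd=300.0,
            rng=np.random.default_rng(0),
        )
        tissue = lung.values & ~air.values
        assert grid.values[air.values].mean() < grid.values[tissue].mean()

    def test_noise_is_zero_mean(self):
        # Monte-Carlo: the mask-restricted mean over repeated noise
        # realizations stays within 1 gray unit of the noiseless image.
        lung = Mask(np.ones((40, 40, 40), dtype=bool), self.SP)
        air = Mask(np.zeros((40, 40, 40), dtype=bool), self.SP)
        air.values[5:35, 5:35, 5:35] = True
        quiet = pg.render_gray(lung, air)
        rng = np.random.default_rng(11)
        for sel in (air.values, lung.values & ~air.values):
            means = [
                float(pg.render_gray(lung, air, noise_sd=400.0, rng=rng).values[sel].mean())
                for _ in range(25)
            ]
            assert abs(np.mean(means) - float(quiet.values[sel].mean())) < 1.0


class TestMonotoneDevelopment:
    def test_truth_diameter_decreases_and_sa_va_increases(self):
        """Compartmentalization: smaller air spaces, more relative surface."""
        stages = ["neonate", "7dpn", "14dpn", "35dpn", "57dpn"]
        diams, ratios = [], []
        for stage in stages:
            truth = pg.generate_stage_phantom(pg.PhantomSpec.for_stage(stage, rng_seed=2))
            diams.append(truth.true_mean_diameter)
            ratios.append(truth.true_SA / truth.true_VA)
        assert all(a > b for a, b in zip(diams, diams[1:])), diams
        assert all(a < b for a, b in zip(ratios, ratios[1:])), ratios
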