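"""Phantom generator: forward model, seeding, noise statistics, artifacts."""

import numpy as np
import pytest

from paleodect.phantom import (
    Box,
    Cylinder,
    DEFAULT_SIGNATURES,
    Difference,
    Ellipsoid,
    EXTANT_BONE_COMPOSITION,
    FOSSIL_BONE_COMPOSITION,
    PhantomSpec,
    Region,
    Sphere,
    SurfaceArtifact,
    add_surface_artifact,
    build_phantom,
    forward_hu,
    fossil_bone_phantom_spec,
    specimen_phantom_spec,
    DEFAULT_COHORT,
)


class TestForwardHU:
    def test_pure_material_identity(self):
        assert forward_hu({"calcite": 1.0}) == (4248.0, 3000.0)
        assert forward_hu({"background": 1.0}) == (0.0, 0.0)

    def test_half_half_mixture(self):
        assert forward_hu({"calcite": 0.5, "background": 0.5}) == (2124.0, 1500.0)

    def test_unknown_material(self):
        with pytest.raises(KeyError):
            forward_hu({"kryptonite": 1.0})

    @pytest.mark.parametrize("fractions", [{"calcite": 0.9}, {"calcite": -0.1, "background": 1.1}])
    def test_invalid_fractions(self, fractions):
        with pytest.raises(ValueError):
            forward_hu(fractions)


def _single_region_spec(composition, shape=(8, 8, 8), **kwargs):
    return PhantomSpec(
        grid_shape=shape,
        regions=(Region("r", Box((0, 0, 0), shape), dict(composition)),),
        **kwargs,
    )


class TestBuildPhantom:
    def test_noiseless_equals_forward_model(self):
        spec = _single_region_spec({"calcite": 1.0})
        vol = build_phantom(spec)
        assert np.all(vol.low == 4248.0) and np.all(vol.high == 3000.0)

    def test_uncovered_voxels_are_background(self):
        spec = PhantomSpec(
            grid_shape=(6, 6, 6),
            regions=(Region("core", Box((2, 2, 2), (4, 4, 4)), {"calcite": 1.0}),),
        )
        vol = build_phantom(spec)
        assert vol.low[0, 0, 0] == 0.0
        assert vol.region_labels[0, 0, 0] == 0

    def test_overlapping_regions_rejected(self):
        spec = PhantomSpec(
            grid_shape=(6, 6, 6),
            regions=(
                Region("a", Box((0, 0, 0), (4, 4, 4)), {"calcite": 1.0}),
                Region("b", Box((2, 2, 2), (6, 6, 6)), {"fluorite": 1.0}),
            ),
        )
        with pytest.raises(ValueError, match="overlaps"):
            build_phantom(spec)

    def test_seed_determinism(self):
        a = build_phantom(_single_region_spec({"calcite": 1.0}, noise_sd_low=50, noise_sd_high=30, seed=7))
        b = build_phantom(_single_region_spec({"calcite": 1.0}, noise_sd_low=50, noise_sd_high=30, seed=7))
        c = build_phantom(_single_region_spec({"calcite": 1.0}, noise_sd_low=50, noise_sd_high=30, seed=8))
        assert np.array_equal(a.low, b.low) and np.array_equal(a.high, b.high)
        assert not np.array_equal(a.low, c.low)

    def test_truth_fractions_sum_to_one(self):
        spec = fossil_bone_phantom_spec(grid_shape=(24, 24, 24), seed=1)
        vol = build_phantom(spec)
        total = sum(vol.truth.values())
        assert total == pytest.approx(np.ones(vol.shape))

    def test_noisy_moments_converge(self):
        """Sample mean/SD of the noisy 135-kVp volume match the fossil-bone
        targets (3040, 542) within 3 standard errors at n = 1e5."""
        n = 100_000
        spec = _single_region_spec(
            FOSSIL_BONE_COMPOSITION, shape=(50, 50, 40),
            noise_sd_low=542.0, noise_sd_high=542.0, seed=11,
        )
        vol = build_phantom(spec)
        se_mean = 542.0 / np.sqrt(n)
        se_sd = 542.0 / np.sqrt(2 * (n - 1))
        assert vol.high.mean() == pytest.approx(3040.0, abs=3 * se_mean + 0.01)
        assert vol.high.std(ddof=1) == pytest.approx(542.0, abs=3 * se_sd)
        # extant bone recipe pins the 135-kVp mean at 1658
        lo, hi = forward_hu(EXTANT_BONE_COMPOSITION)
        assert hi == pytest.approx(1658.0)

    def test_hu_clipped_to_scanner_range(self):
        spec = _single_region_spec({"iron": 1.0})  # 24422 HU at 80 kVp
        vol = build_phantom(spec)
        assert vol.low.max() <= 32_767.0
        assert np.all(vol.low == 24_422.0) or vol.low.max() == 32_767.0


class TestSurfaceArtifact:
    def _vol(self, shape=(12, 12, 12), box=((3, 3, 3), (9, 9, 9))):
        spec = PhantomSpec(
            grid_shape=shape,
            regions=(Region("obj", Box(*box), {"calcite": 1.0}),),
        )
        return build_phantom(spec)

    def test_zero_band_is_noop(self):
        vol = self._vol()
        out = add_surface_artifact(vol, 0, 500.0)
        assert np.array_equal(out.low, vol.low)
        assert not out.artifact_mask.any()

    def test_interior_voxel_unchanged_and_surface_shifted(self):
        vol = self._vol()
        out = add_surface_artifact(vol, 1, 500.0)
        assert out.low[6, 6, 6] == vol.low[6, 6, 6]  # deep interior
        assert out.low[3, 6, 6] == vol.low[3, 6, 6] + 500.0  # on the surface
        assert out.high[3, 6, 6] == vol.high[3, 6, 6] + 500.0

    @pytest.mark.parametrize("band", [1, 2, 3])
    def test_band_matches_brute_force_distance_scan(self, band):
        vol = self._vol(shape=(10, 10, 10), box=((2, 2, 2), (8, 8, 8)))
        out = add_surface_artifact(vol, band, 100.0)
        obj = vol.region_labels > 0
        bg = np.argwhere(~obj)
        expected = np.zeros(vol.shape, dtype=bool)
        for v in np.argwhere(obj):
            d2 = ((bg - v) ** 2).sum(axis=1).min()
            if d2 <= band * band:
                expected[tuple(v)] = True
        assert np.array_equal(out.artifact_mask, expected)


class TestGeometry:
    def test_sphere_equals_equal_radii_ellipsoid(self):
        shape = (9, 9, 9)
        s = Sphere((4, 4, 4), 3.0).mask(shape)
        e = Ellipsoid((4, 4, 4), (3.0, 3.0, 3.0)).mask(shape)
        assert np.array_equal(s, e)

    def test_cylinder_extent(self):
        m = Cylinder((4, 4, 4), radius=2.0, half_length=3.0, axis=2).mask((9, 9, 9))
        assert m[4, 4, 1] and m[4, 4, 7]
        assert not m[4, 4, 0] and not m[1, 1, 4]

    def test_difference_subtracts(self):
        shape = (8, 8, 8)
        outer = Box((0, 0, 0), (8, 8, 8))
        inner = Box((2, 2, 2), (6, 6, 6))
        m = Difference(outer, inner).mask(shape)
        assert m[0, 0, 0] and not m[3, 3, 3]


def test_spec_yaml_round_trip(tmp_path):
    spec = fossil_bone_phantom_spec(seed=5)
    path = tmp_path / "spec.yaml"
    spec.to_yaml(path)
    back = PhantomSpec.from_yaml(path)
    assert back == spec
    assert np.array_equal(build_phantom(back).low, build_phantom(spec).low)


def test_default_cohort_noiseless_targets(fluorine_basis):
    """The cohort recipes pin the printed noiseless values: fresh bone 1658
    HU at 135 kVp with zero fluorine; fossil theropod 3040 HU with 1809 HU
    fluorine; the oldest terrestrial specimen ~3500 HU fluorine."""
    from paleodect.decomposition import decompose_voxel

    by_name = {s.name: s for s in DEFAULT_COHORT}
    lo, hi = forward_hu(by_name["Bos taurus"].bone_composition)
    assert hi == pytest.approx(1658.0)
    assert decompose_voxel(lo, hi, fluorine_basis).map_values["fluorine"] == pytest.approx(
        0.0, abs=1e-9
    )

    lo, hi = forward_hu(by_name["Tyrannosaurus rex"].bone_composition)
    assert hi == pytest.approx(3040.0, abs=0.5)
    f = decompose_voxel(lo, hi, fluorine_basis).map_values["fluorine"]
    assert f == pytest.approx(1809.0, abs=1.0)

    lo, hi = forward_hu(by_name["Dysalotosaurus"].bone_composition)
    f = decompose_voxel(lo, hi, fluorine_basis).map_values["fluorine"]
    assert f == pytest.approx(3500.0, abs=2.0)


def test_specimen_phantom_spec_builds(rng):
    spec = specimen_phantom_spec(DEFAULT_COHORT[0], grid_shape=(20, 20, 20), seed=2)
    vol = build_phantom(spec)
    assert (vol.region_labels == 1).sum() > 200  # bone present
    assert (vol.region_labels == 2).sum() > 200  # sediment present
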