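"""Generator contracts: geometry, determinism, ground-truth consistency."""

import numpy as np
import pytest
import scipy.ndimage as ndi

import debriscope as dsc
from debriscope.synth import CLASS_CODES, PackingError

from conftest import study_scene_spec


class TestRenderMembrane:
    def test_slit_rasterization_and_classes(self):
        img, class_map = dsc.render_membrane(dsc.FilterSpec(), dsc.AcquisitionSpec.dic(), seed=0)
        assert img.shape == (512, 512)
        # 8 um at 2.5625 px/um rasterizes to 21 px (nearest integer, half up)
        slot_cols = np.nonzero((class_map == CLASS_CODES["slot"]).any(axis=0))[0]
        runs = np.split(slot_cols, np.nonzero(np.diff(slot_cols) > 1)[0] + 1)
        full = [r for r in runs if r[0] > 0 and r[-1] < 511]
        assert {len(r) for r in full} == {21}
        # background contains exactly slot, membrane and edge regions
        assert set(np.unique(class_map)) == {
            CLASS_CODES["slot"],
            CLASS_CODES["membrane"],
            CLASS_CODES["edge"],
        }

    def test_subpixel_slit_rejected(self):
        with pytest.raises(dsc.GeometryError):
            dsc.render_membrane(
                dsc.FilterSpec(),
                dsc.AcquisitionSpec(pixel_scale=0.05, image_shape=(64, 64)),
                seed=0,
            )

    def test_image_too_small_for_one_slit(self):
        with pytest.raises(dsc.GeometryError):
            dsc.render_membrane(
                dsc.FilterSpec(), dsc.AcquisitionSpec.dic(image_shape=(16, 16)), seed=0
            )

    def test_same_seed_bit_identical(self):
        a, _ = dsc.render_membrane(dsc.FilterSpec(), dsc.AcquisitionSpec.dic(), seed=5)
        b, _ = dsc.render_membrane(dsc.FilterSpec(), dsc.AcquisitionSpec.dic(), seed=5)
        assert np.array_equal(a.data, b.data)


class TestGenerateScene:
    def test_determinism(self):
        spec = study_scene_spec(seed=3)
        s1 = dsc.generate_scene(spec)
        s2 = dsc.generate_scene(spec)
        assert np.array_equal(s1.dic_image.data, s2.dic_image.data)
        assert np.array_equal(s1.fluo_image.data, s2.fluo_image.data)
        assert s1.particle_table.equals(s2.particle_table)
        assert s1.fiber_table.equals(s2.fiber_table)

    def test_empty_scene(self):
        scene = dsc.generate_scene(
            dsc.SceneSpec(n_particles=0, n_fibers=0, residue_patches=0, seed=0)
        )
        assert not scene.label_map.any()
        assert len(scene.particle_table) == 0
        assert len(scene.fiber_table) == 0

    def test_table_sizes_and_exact_stained_count(self):
        scene = dsc.generate_scene(
            study_scene_spec(seed=1, stained_fraction=0.05, n_fibers=3)
        )
        assert len(scene.particle_table) == 200
        assert len(scene.fiber_table) == 3
        assert int(scene.particle_table["stained"].sum()) == 10

    def test_stained_count_rounds_within_one(self):
        for frac in (0.013, 0.029, 0.086):
            scene = dsc.generate_scene(
                dsc.SceneSpec(n_particles=73, n_fibers=0, stained_fraction=frac, seed=2)
            )
            assert abs(scene.particle_table["stained"].sum() - frac * 73) <= 1

    def test_spanning_fibers_touch_opposite_borders(self):
        scene = dsc.generate_scene(study_scene_spec(seed=4))
        for fid in scene.fiber_table["id"]:
            mask = scene.label_map == fid
            sides = {
                "top": mask[0, :].any(),
                "bottom": mask[-1, :].any(),
                "left": mask[:, 0].any(),
                "right": mask[:, -1].any(),
            }
            assert (sides["top"] and sides["bottom"]) or (sides["left"] and sides["right"])

    def test_every_label_has_exactly_one_truth_row(self):
        scene = dsc.generate_scene(study_scene_spec(seed=5))
        labels = set(np.unique(scene.label_map)) - {0}
        ids = list(scene.particle_table["id"]) + list(scene.fiber_table["id"])
        assert len(ids) == len(set(ids))
        assert labels <= set(ids)

    def test_area_conservation_with_class_map(self):
        """Rendered per-object pixel areas sum exactly to the debris-class
        pixel count of the class map (before noise)."""
        scene = dsc.generate_scene(study_scene_spec(seed=6))
        total = (
            scene.particle_table["rendered_area_px"].sum()
            + scene.fiber_table["rendered_area_px"].sum()
        )
        assert total == np.count_nonzero(scene.class_map == CLASS_CODES["particle"])

    def test_fluorescence_marks_exactly_the_stained_objects(self):
        scene = dsc.generate_scene(study_scene_spec(seed=7, aggregate_fraction=0.0))
        mask = scene.fluo_noiseless > 0.05 + 0.85 / 2.0
        _, n = ndi.label(mask, structure=np.ones((3, 3), int))
        truth = scene.particle_table[scene.particle_table["stained"]]
        assert n == len(truth)
        # every stained centroid lies in the thresholded mask
        sf = scene.acq_fluo.pixel_scale
        for _, row in truth.iterrows():
            r = int(round(row.y_um * sf))
            c = int(round(row.x_um * sf))
            assert mask[r, c]

    def test_packing_error_when_overloaded(self):
        with pytest.raises(PackingError):
            dsc.generate_scene(
                dsc.SceneSpec(
                    n_particles=2000,
                    size_distribution=dsc.SizeDistribution(
                        median_um=15.0, sigma_log=0.2, min_um=10.0, max_um=25.0
                    ),
                    n_fibers=0,
                    seed=0,
                )
            )

    def test_synthetic_debris_probability_is_seeded(self):
        scene = dsc.generate_scene(study_scene_spec(seed=8))
        assert np.array_equal(
            scene.synthetic_debris_probability(), scene.synthetic_debris_probability()
        )
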