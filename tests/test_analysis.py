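"""Project pipeline, filtering, labeling, clustering."""

import numpy as np
import pytest

import fpmkit as fk
from fpmkit.analysis import (
    Group,
    ImageRecord,
    ObjectFilter,
    PipelineConfig,
    Project,
    filter_objects,
    kmeans_cluster,
    kmeans_labels,
    label_objects,
    run_pipeline,
    split_by_length,
)
from fpmkit.io import objects_to_frame


def small_project(n_images=3, seed=0):
    images = []
    for i in range(n_images):
        scene = fk.make_puncta_field(
            n=12, shape=(160, 160), noise=fk.NoiseModel("poisson"), seed=seed + i,
            name=f"img{i}",
        )
        images.append(ImageRecord(name=f"img{i}", stack=fk.render_stack(scene)))
    return Project(groups=[Group(name="g1", images=images)])


def best_1d_split_inertia(values, k=2):
    """Exhaustive best 2-cluster split of sorted 1-D data."""
    v = np.sort(np.asarray(values, dtype=float))
    best = np.inf
    for cut in range(1, len(v)):
        left, right = v[:cut], v[cut:]
        inertia = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
        best = min(best, inertia)
    return best


class TestProjectStructure:
    def test_duplicate_group_names_rejected(self):
        with pytest.raises(ValueError):
            Project(groups=[Group(name="a"), Group(name="a")])

    def test_duplicate_image_names_rejected(self):
        stack = fk.render_stack(fk.make_puncta_field(n=2, shape=(64, 64), seed=0))
        with pytest.raises(ValueError):
            Project(groups=[Group(name="a", images=[
                ImageRecord(name="x", stack=stack), ImageRecord(name="x", stack=stack)
            ])])

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = PipelineConfig(scheme="filaments", seed=9)
        cfg.puncta.min_area = 17
        cfg.to_yaml(tmp_path / "cfg.yaml")
        back = PipelineConfig.from_yaml(tmp_path / "cfg.yaml")
        assert back.scheme == "filaments"
        assert back.seed == 9
        assert back.puncta.min_area == 17


class TestRunPipeline:
    def test_rerun_is_byte_identical(self, tmp_path):
        cfg = PipelineConfig(compute_midlines=False)
        csvs = []
        for run in range(2):
            project = small_project()
            run_pipeline(project, cfg)
            path = tmp_path / f"objects_{run}.csv"
            fk.io.write_object_table(project.all_objects(), path)
            csvs.append(path.read_bytes())
        assert csvs[0] == csvs[1]

    def test_object_count_matches_planted(self):
        """Planted object count recovered within +/- 2% over 10 images."""
        images = []
        planted = 0
        for i in range(10):
            scene = fk.make_puncta_field(
                n=30, shape=(256, 256), noise=fk.NoiseModel("poisson"), seed=100 + i,
            )
            planted += len(scene.objects)
            images.append(ImageRecord(name=f"img{i}", stack=fk.render_stack(scene)))
        project = Project(groups=[Group(name="g", images=images)])
        run_pipeline(project, PipelineConfig(compute_midlines=False))
        found = len(project.all_objects())
        assert abs(found - planted) <= 0.02 * planted

    def test_empty_image_continues(self):
        blank = fk.FPMStack(np.full((4, 32, 32), 3.0))
        scene = fk.make_puncta_field(n=4, shape=(64, 64), seed=1)
        project = Project(groups=[Group(name="g", images=[
            ImageRecord(name="blank", stack=blank),
            ImageRecord(name="ok", stack=fk.render_stack(scene)),
        ])])
        with pytest.warns(UserWarning):
            run_pipeline(project, PipelineConfig(compute_midlines=False))
        names = {im.name: len(im.objects) for g in project.groups for im in g.images}
        assert names["blank"] == 0
        assert names["ok"] > 0

    def test_hierarchy_intact_after_processing(self):
        project = small_project(n_images=2)
        run_pipeline(project, PipelineConfig(compute_midlines=False))
        for group in project.groups:
            for image in group.images:
                for obj in image.objects:
                    assert obj.group == group.name
                    assert obj.image == image.name


class TestFiltering:
    @pytest.fixture
    def objects(self):
        return [
            fk.FPMObject(id=1, area=5, length_um=10.0, local_sb=1.5),
            fk.FPMObject(id=2, area=50, length_um=17.5, local_sb=8.0),
            fk.FPMObject(id=3, area=20, length_um=25.0, local_sb=3.0),
        ]

    def test_trivial_filter_keeps_all(self, objects):
        assert len(filter_objects(objects, ObjectFilter([("area", ">=", 0)]))) == 3

    def test_unknown_feature_rejected(self, objects):
        with pytest.raises(KeyError):
            filter_objects(objects, ObjectFilter([("no_such", ">", 0)]))

    def test_conjunction_equals_intersection(self, objects):
        f1 = ObjectFilter([("area", ">=", 10)])
        f2 = ObjectFilter([("local_sb", ">=", 3.0)])
        both = filter_objects(objects, f1 & f2)
        expected = set(id(o) for o in filter_objects(objects, f1)) & set(
            id(o) for o in filter_objects(objects, f2)
        )
        assert set(id(o) for o in both) == expected

    def test_length_threshold_boundary_inclusive(self, objects):
        """L >= 17.5 um keeps the boundary object (inclusive cutoff)."""
        long_objs = filter_objects(objects, ObjectFilter([("length_um", ">=", 17.5)]))
        assert {o.id for o in long_objs} == {2, 3}

    def test_split_by_length_boundary_is_long(self, objects):
        split_by_length(objects)
        assert [o.group_label for o in objects] == ["short", "long", "long"]

    def test_overlapping_rules_rejected(self, objects):
        with pytest.raises(ValueError):
            label_objects(objects, {
                "a": ObjectFilter([("area", ">=", 0)]),
                "b": ObjectFilter([("area", ">=", 10)]),
            })

    def test_empty_object_list(self):
        assert label_objects([], {"any": ObjectFilter([("area", ">=", 0)])}) == []

    def test_planted_long_set_recovered_exactly(self):
        """On a synthetic filament field, the L >= 17.5 um filter returns
        exactly the planted long filaments."""
        lengths = (8.0, 12.0, 16.0, 21.0, 30.0)
        scene = fk.make_filament_scene(
            shape=(512, 512), lengths_um=lengths, seed=11,
            noise=fk.NoiseModel("poisson"),
        )
        stack = fk.render_stack(scene)
        maps = fk.compute_pixel_maps(stack)
        seg = fk.segment_filaments(maps.S0)
        objs = fk.extract_features(seg, maps, stack)
        long_objs = filter_objects(objs, ObjectFilter([("length_um", ">=", 17.5)]))
        # match each planted filament to the detected object overlapping it
        matched_long = 0
        for truth in scene.objects:
            ids = np.unique(seg.labels[truth.mask])
            ids = ids[ids > 0]
            assert len(ids) >= 1, "planted filament missed"
            detected = [o for o in objs if o.id in ids]
            is_long = any(o in long_objs for o in detected)
            if truth.length_um >= 17.5:
                assert is_long
                matched_long += 1
            else:
                assert not is_long
        assert matched_long == 2


class TestKMeans:
    def test_separated_1d_clusters(self):
        objs = [fk.FPMObject(id=i + 1, local_sb=v)
                for i, v in enumerate([1.0, 1.1, 0.9, 10.0, 9.0, 11.0])]
        ids = kmeans_cluster(objs, ["local_sb"], k=2, seed=0)
        assert ids == [1, 1, 1, 2, 2, 2]

    def test_matches_exhaustive_1d_split(self, rng):
        """k-means inertia on 1-D data equals the best split over all
        sorted cut points."""
        for _ in range(10):
            values = rng.uniform(0, 10, size=rng.integers(8, 40))
            labels = kmeans_labels(values[:, None], k=2, seed=1, standardize=False)
            inertia = sum(
                ((values[labels == c] - values[labels == c].mean()) ** 2).sum()
                for c in (1, 2)
            )
            assert inertia == pytest.approx(best_1d_split_inertia(values), rel=1e-9)

    def test_cluster_one_is_low_first_feature(self, rng):
        values = np.concatenate([rng.normal(10, 1, 20), rng.normal(2, 1, 20)])
        labels = kmeans_labels(values[:, None], k=2, seed=3)
        assert values[labels == 1].mean() < values[labels == 2].mean()

    def test_same_seed_reruns_identically(self, rng):
        data = rng.normal(size=(40, 3))
        l1 = kmeans_labels(data, k=3, seed=7)
        l2 = kmeans_labels(data, k=3, seed=7)
        np.testing.assert_array_equal(l1, l2)

    def test_undefined_features_excluded(self):
        objs = [fk.FPMObject(id=1, local_sb=1.0), fk.FPMObject(id=2, local_sb=np.nan),
                fk.FPMObject(id=3, local_sb=5.0), fk.FPMObject(id=4, local_sb=5.5)]
        ids = kmeans_cluster(objs, ["local_sb"], k=2, seed=0)
        assert ids[1] is None
        assert objs[1].cluster_id is None

    def test_high_sb_cluster_has_higher_order(self):
        """Two-population S/B scene: the high-S/B cluster's mean object
        order is at least that of the low-S/B cluster (noise dilutes
        modulation where the background dominates)."""
        shape = (256, 256)
        bright = fk.make_puncta_field(
            n=15, shape=shape, amplitude=300.0, background=10.0, order=0.8,
            noise=fk.NoiseModel("poisson"), seed=21,
        )
        dim = fk.make_puncta_field(
            n=15, shape=shape, amplitude=25.0, background=10.0, order=0.8,
            noise=fk.NoiseModel("poisson"), seed=22,
        )
        objs = []
        for scene in (bright, dim):
            stack = fk.render_stack(scene)
            maps = fk.compute_pixel_maps(stack)
            seg = fk.segment_puncta(maps.S0)
            objs.extend(fk.extract_features(seg, maps, stack, compute_midlines=False))
        objs = [o for o in objs if np.isfinite(o.local_sb) and np.isfinite(o.mean_order)]
        kmeans_cluster(objs, ["local_sb"], k=2, seed=0)
        mean_order = {
            c: np.mean([o.mean_order for o in objs if o.cluster_id == c]) for c in (1, 2)
        }
        assert mean_order[2] >= mean_order[1]


def test_object_frame_has_fixed_schema():
    frame = objects_to_frame([fk.FPMObject(id=1)])
    assert list(frame.columns) == fk.io.OBJECT_TABLE_COLUMNS
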