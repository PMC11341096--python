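"""Project hierarchy, batch pipeline, filtering, labeling and clustering.

A *project* contains *groups* (experimental conditions or replicates);
each group contains *images* (one polarization stack plus its derived
data); processing an image yields *objects*. The batch pipeline applies,
per image: optional flat-field correction -> pixelwise maps ->
segmentation (puncta or filaments scheme) -> feature extraction with
midlines and relative azimuths. Everything is deterministic given the
configuration and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Dict, List, Literal, Optional, Sequence

import numpy as np
import yaml
from sklearn.cluster import KMeans

from .core import FPMStack, FlatFieldStack
from .features import FPMObject, extract_features
from .midline import MidlineParams
from .segmentation import (
    FilamentParams,
    PunctaParams,
    SegmentationResult,
    segment_filaments,
    segment_puncta,
)
from .stats import PixelMaps, compute_pixel_maps, flat_field_correct

logger = logging.getLogger("fpmkit")

__all__ = [
    "ImageRecord",
    "Group",
    "Project",
    "PipelineConfig",
    "ObjectFilter",
    "run_pipeline",
    "filter_objects",
    "label_objects",
    "split_by_length",
    "kmeans_labels",
    "kmeans_cluster",
    "PERSISTENCE_LENGTH_UM",
]

#: default short/long filament cutoff: the persistence length of
#: phalloidin-stabilized F-actin, 17.5 um
PERSISTENCE_LENGTH_UM = 17.5


@dataclass
class ImageRecord:
    """One technical replicate: the stack plus everything derived from it."""

    name: str
    stack: FPMStack
    flats: List[FlatFieldStack] = field(default_factory=list)
    maps: Optional[PixelMaps] = None
    segmentation: Optional[SegmentationResult] = None
    objects: List[FPMObject] = field(default_factory=list)


@dataclass
class Group:
    name: str
    images: List[ImageRecord] = field(default_factory=list)


@dataclass
class Project:
    groups: List[Group] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("group names must be unique")
        for g in self.groups:
            inames = [im.name for im in g.images]
            if len(set(inames)) != len(inames):
                raise ValueError(f"image names must be unique within group {g.name!r}")

    def all_objects(self) -> List[FPMObject]:
        return [obj for g in self.groups for im in g.images for obj in im.objects]


@dataclass
class PipelineConfig:
    """Single source of processing parameters; serializable to YAML."""

    scheme: Literal["puncta", "filaments"] = "puncta"
    puncta: PunctaParams = field(default_factory=PunctaParams)
    filaments: FilamentParams = field(default_factory=FilamentParams)
    midline: MidlineParams = field(default_factory=MidlineParams)
    sb_buffer_px: int = 2
    sb_annulus_px: int = 2
    compute_midlines: bool = True
    seed: int = 0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, value in raw.items():
            if key == "puncta":
                cfg.puncta = PunctaParams(**value)
            elif key == "filaments":
                cfg.filaments = FilamentParams(**value)
            elif key == "midline":
                cfg.midline = MidlineParams(**value)
            elif hasattr(cfg, key):
                setattr(cfg, key, value)
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cfg


def process_image(record: ImageRecord, config: PipelineConfig, group: str = "") -> None:
    """Run the per-image pipeline in place."""
    stack = record.stack
    if record.flats:
        stack = flat_field_correct(stack, record.flats)
    record.maps = compute_pixel_maps(stack)
    if config.scheme == "puncta":
        record.segmentation = segment_puncta(record.maps.S0, config.puncta)
    elif config.scheme == "filaments":
        record.segmentation = segment_filaments(record.maps.S0, config.filaments)
    else:
        raise ValueError(f"unknown scheme {config.scheme!r}")
    record.objects = extract_features(
        record.segmentation,
        record.maps,
        stack,
        group=group,
        image=record.name,
        sb_buffer_px=config.sb_buffer_px,
        sb_annulus_px=config.sb_annulus_px,
        midline_params=config.midline,
        compute_midlines=config.compute_midlines,
    )


def run_pipeline(project: Project, config: PipelineConfig) -> Project:
    """Process every image of the project in place; returns the project.

    Per-image failures are logged and skipped; an error is raised only
    when every image fails.
    """
    n_images = 0
    n_failed = 0
    for group in project.groups:
        for record in group.images:
            n_images += 1
            try:
                process_image(record, config, group=group.name)
                logger.info(
                    "%s/%s: %d objects", group.name, record.name, len(record.objects)
                )
            except Exception:
                n_failed += 1
                logger.exception("image %s/%s failed; skipping", group.name, record.name)
    if n_images > 0 and n_failed == n_images:
        raise RuntimeError("all images failed to process")
    return project


# --- filtering and labeling ----------------------------------------------

_COMPARATORS: Dict[str, Callable[[float, float], bool]] = {
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    ">": lambda a, b: a > b,
    ">=": lambda a, b: a >= b,
    "==": lambda a, b: a == b,
    "!=": lambda a, b: a != b,
}


@dataclass
class ObjectFilter:
    """A conjunction of scalar-feature predicates, e.g.
    ``ObjectFilter([("length_um", ">=", 17.5)])``."""

    predicates: List[tuple] = field(default_factory=list)

    def __post_init__(self) -> None:
        for feature, op, _ in self.predicates:
            if op not in _COMPARATORS:
                raise ValueError(f"unknown comparator {op!r}")
            _ = feature  # validated against each object at evaluation time

    def matches(self, obj: FPMObject) -> bool:
        for feature, op, value in self.predicates:
            actual = obj.get(feature)  # raises KeyError on unknown feature
            if actual is None or (isinstance(actual, float) and np.isnan(actual)):
                return False
            if not _COMPARATORS[op](actual, value):
                return False
        return True

    def __and__(self, other: "ObjectFilter") -> "ObjectFilter":
        return ObjectFilter(self.predicates + other.predicates)


def filter_objects(objects: Sequence[FPMObject] | Project, filt: ObjectFilter) -> List[FPMObject]:
    """Objects satisfying every predicate; the input is left untouched."""
    if isinstance(objects, Project):
        objects = objects.all_objects()
    return [obj for obj in objects if filt.matches(obj)]


def label_objects(
    objects: Sequence[FPMObject], rules: Dict[str, ObjectFilter]
) -> List[FPMObject]:
    """Assign exactly one label to every object from a partition of rules.

    Raises if any object matches more than one rule (overlap) or none
    (the rules do not partition the population).
    """
    for obj in objects:
        matched = [name for name, filt in rules.items() if filt.matches(obj)]
        if len(matched) > 1:
            raise ValueError(f"object {obj.id} matches overlapping rules {matched}")
        if not matched:
            raise ValueError(f"object {obj.id} matches no labeling rule")
        obj.group_label = matched[0]
    return list(objects)


def split_by_length(
    objects: Sequence[FPMObject], cutoff_um: float = PERSISTENCE_LENGTH_UM
) -> List[FPMObject]:
    """Label filaments 'short' (L < cutoff) or 'long' (L >= cutoff).

    The boundary is inclusive on the long side: L equal to the cutoff is
    'long'.
    """
    rules = {
        "short": ObjectFilter([("length_um", "<", cutoff_um)]),
        "long": ObjectFilter([("length_um", ">=", cutoff_um)]),
    }
    return label_objects(objects, rules)


# --- clustering ----------------------------------------------------------


def kmeans_labels(
    matrix: np.ndarray,
    k: int = 2,
    seed: int = 0,
    standardize: bool = True,
    n_init: int = 20,
    max_iter: int = 300,
) -> np.ndarray:
    """1-based k-means cluster ids for a (n_samples, n_features) matrix.

    Features are z-scored by default; clusters are renumbered so that
    cluster 1 has the lowest mean of the *first* feature column (on the
    raw scale). Deterministic for a fixed seed (k-means++ with
    ``n_init`` restarts).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("matrix must be 2-D (samples x features)")
    if k < 2:
        raise ValueError("k must be >= 2")
    if matrix.shape[0] < k:
        raise ValueError("fewer samples than clusters")
    if not np.all(np.isfinite(matrix)):
        raise ValueError("matrix must be finite")

    data = matrix
    if standardize:
        mean = data.mean(axis=0)
        std = data.std(axis=0)
        std = np.where(std > 0, std, 1.0)
        data = (data - mean) / std

    km = KMeans(
        n_clusters=k, n_init=n_init, max_iter=max_iter, tol=1e-6, random_state=seed
    )
    raw = km.fit_predict(data)

    first = matrix[:, 0]
    means = [first[raw == c].mean() for c in range(k)]
    order = np.argsort(means, kind="stable")
    remap = np.empty(k, dtype=int)
    for new, old in enumerate(order, start=1):
        remap[int(old)] = new
    return remap[raw]


def kmeans_cluster(
    objects: Sequence[FPMObject],
    features: Sequence[str],
    k: int = 2,
    seed: int = 0,
    standardize: bool = True,
    n_init: int = 20,
    max_iter: int = 300,
) -> List[Optional[int]]:
    """k-means over scalar features; writes 1-based cluster ids in place.

    Clusters are renumbered so that cluster 1 has the lowest mean of the
    *first* feature (so with S/B first, cluster 1 is the low-S/B
    population). Objects with undefined feature values are excluded with
    a warning (their id stays None).
    """
    if not features:
        raise ValueError("at least one feature is required")
    matrix = np.array([[obj.get(f) for f in features] for obj in objects], dtype=float)
    if matrix.ndim != 2:
        matrix = matrix.reshape(len(objects), -1)
    valid = np.all(np.isfinite(matrix), axis=1)
    if valid.sum() < k:
        raise ValueError("fewer valid objects than clusters")
    if not valid.all():
        logger.warning("excluding %d objects with undefined features", (~valid).sum())

    assigned = kmeans_labels(
        matrix[valid], k=k, seed=seed, standardize=standardize,
        n_init=n_init, max_iter=max_iter,
    )
    ids: List[Optional[int]] = []
    j = 0
    for i, obj in enumerate(objects):
        if valid[i]:
            cid = int(assigned[j])
            j += 1
        else:
            cid = None
        obj.cluster_id = cid
        ids.append(cid)
    return ids
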