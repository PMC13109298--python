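"""Pluggable promptable-segmentation backends.

Two backends share one interface:

* ``ClassicalBackend`` — deterministic, dependency-free: vegetation pixels
  (ExG-ExR > 0) are split into connected components; ``auto_masks`` returns
  one candidate per component plus one field-level candidate (the filled
  convex hull of the vegetation mask), and ``prompt_mask`` returns the
  component containing the first foreground point. Scores are a fill-fraction
  surrogate so downstream ranking works without a learned model.
* ``FoundationBackend`` — an adapter for an external promptable-segmentation
  foundation model (point-grid automatic mode and multi-point interactive
  mode). It requires the optional ``segment_anything`` package and a model
  checkpoint; without them, construction raises a configuration error
  pointing at the classical backend.

Backend defaults follow the automated-orthomosaic protocol: a 32x32 point
grid, quality/stability thresholds disabled (0.0) and the overlap-suppression
threshold raised to 1.0 so no candidate is discarded before ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage import measure, morphology

from .prompts import vegetation_index

logger = logging.getLogger(__name__)

__all__ = ["CandidateMask", "BackendParams", "ClassicalBackend", "FoundationBackend", "get_backend"]


@dataclass
class CandidateMask:
    """A candidate segmentation mask with backend-reported quality scores."""

    mask: np.ndarray  # bool (H, W)
    predicted_iou: float
    stability: float

    def __post_init__(self) -> None:
        if not np.any(self.mask):
            raise ValueError("candidate mask is empty")
        for s in (self.predicted_iou, self.stability):
            if not 0.0 <= s <= 1.0:
                raise ValueError("scores must lie in [0, 1]")

    @property
    def centroid(self) -> tuple[float, float]:
        """Center of the mask's bounding box, (x, y)."""
        ys, xs = np.nonzero(self.mask)
        return (float(xs.min() + xs.max()) / 2.0, float(ys.min() + ys.max()) / 2.0)


@dataclass(frozen=True)
class BackendParams:
    grid_side: int = 32
    iou_threshold: float = 0.0
    stability_threshold: float = 0.0
    nms_threshold: float = 1.0
    max_long_side: int = 1024

    def __post_init__(self) -> None:
        if self.grid_side < 1:
            raise ValueError("grid_side must be >= 1")
        for name in ("iou_threshold", "stability_threshold", "nms_threshold"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def _min_rect_fill_fraction(mask: np.ndarray) -> float:
    """Mask area over the area of its minimum oriented bounding rectangle.

    Rotation-invariant compactness surrogate in (0, 1]; a complete
    rectangular field scores near 1 at any orientation while individual
    canopy blobs score around the ellipse fill ratio (~0.79).
    """
    from .locate import mask_min_rect  # local import to avoid a cycle

    area = float(np.count_nonzero(mask))
    try:
        rect = mask_min_rect(mask)
    except ValueError:
        return 1.0
    e1 = np.hypot(*(rect[1] - rect[0]))
    e2 = np.hypot(*(rect[2] - rect[1]))
    rect_area = max(e1, 1.0) * max(e2, 1.0)
    return float(min(area / rect_area, 1.0))


class ClassicalBackend:
    """Vegetation-threshold + connected-components backend (no model weights).

    Deterministic: identical inputs give identical masks. Component labelling
    is cached per image so repeated prompt queries on one scene are cheap.
    """

    name = "classical"

    def __init__(self) -> None:
        self._cache_key: tuple | None = None
        self._cache: tuple[np.ndarray, int] | None = None

    def _components(self, image: np.ndarray) -> tuple[np.ndarray, int]:
        key = (id(image), image.shape, image.dtype.str)
        if self._cache_key == key and self._cache is not None:
            return self._cache
        veg = vegetation_index(image).mask
        labels, n = measure.label(veg, connectivity=2, return_num=True)
        self._cache_key = key
        self._cache = (labels, n)
        return labels, n

    def auto_masks(self, image: np.ndarray, params: BackendParams | None = None) -> list[CandidateMask]:
        """One candidate per vegetation component plus a field-level candidate.

        The field-level candidate is the filled convex hull of all vegetation
        pixels, scored like the rest; with ``nms_threshold = 1.0`` (default)
        no candidate is suppressed for overlap.
        """
        params = params or BackendParams()
        labels, n = self._components(image)
        candidates: list[CandidateMask] = []
        for lab in range(1, n + 1):
            mask = labels == lab
            score = _min_rect_fill_fraction(mask)
            candidates.append(CandidateMask(mask=mask, predicted_iou=score, stability=score))
        if n >= 1:
            hull = morphology.convex_hull_image(labels > 0)
            score = _min_rect_fill_fraction(hull)
            candidates.append(CandidateMask(mask=hull, predicted_iou=score, stability=score))
        candidates = [
            c
            for c in candidates
            if c.predicted_iou >= params.iou_threshold and c.stability >= params.stability_threshold
        ]
        if params.nms_threshold < 1.0:
            candidates = _suppress_overlaps(candidates, params.nms_threshold)
        return candidates

    def prompt_mask(
        self,
        image: np.ndarray,
        fg_points: list[tuple[float, float]],
        bg_points: list[tuple[float, float]] | None = None,
    ) -> np.ndarray:
        """The vegetation component containing the first foreground point,
        minus any component containing a background point.

        A foreground point on non-vegetation yields an empty mask (logged).
        """
        if not fg_points:
            raise ValueError("at least one foreground point is required")
        labels, _ = self._components(image)
        H, W = labels.shape

        def label_at(pt) -> int:
            x, y = int(round(pt[0])), int(round(pt[1]))
            if not (0 <= x < W and 0 <= y < H):
                return 0
            return int(labels[y, x])

        fg_label = label_at(fg_points[0])
        if fg_label == 0:
            logger.warning("foreground point %s is not on vegetation; empty mask", fg_points[0])
            return np.zeros((H, W), dtype=bool)
        bg_labels = {label_at(p) for p in (bg_points or [])} - {0}
        if fg_label in bg_labels:
            logger.warning(
                "foreground and a background point share component %d; returning it unchanged",
                fg_label,
            )
            bg_labels.discard(fg_label)
        mask = labels == fg_label
        return mask


def _suppress_overlaps(candidates: list[CandidateMask], threshold: float) -> list[CandidateMask]:
    """Greedy IoU-based suppression, highest mean score first."""
    order = sorted(
        range(len(candidates)),
        key=lambda i: (candidates[i].predicted_iou + candidates[i].stability) / 2,
        reverse=True,
    )
    kept: list[CandidateMask] = []
    for i in order:
        cand = candidates[i]
        area_c = np.count_nonzero(cand.mask)
        clash = False
        for k in kept:
            inter = np.count_nonzero(cand.mask & k.mask)
            union = area_c + np.count_nonzero(k.mask) - inter
            if union and inter / union >= threshold:
                clash = True
                break
        if not clash:
            kept.append(cand)
    return kept


class FoundationBackend:
    """Adapter for an external promptable-segmentation foundation model.

    ``variant`` selects the vision-transformer backbone ("vit_b", "vit_l",
    "vit_h"); a checkpoint file is required. The adapter forwards
    ``BackendParams`` to the model's automatic mask generator with filtering
    disabled as configured, and uses multi-point interactive queries for
    ``prompt_mask``, returning the best-scoring mask.
    """

    name = "foundation"

    def __init__(self, checkpoint_path: str | None = None, variant: str = "vit_h") -> None:
        if checkpoint_path is None:
            raise RuntimeError(
                "the foundation backend requires a model checkpoint; "
                "use the classical backend (backend='classical') to run without weights"
            )
        try:
            import segment_anything  # noqa: F401
        except ImportError as exc:
            raise RuntimeError(
                "the 'segment_anything' package is not installed; "
                "use the classical backend (backend='classical') to run without it"
            ) from exc
        from segment_anything import sam_model_registry

        self._model = sam_model_registry[variant](checkpoint=checkpoint_path)

    def auto_masks(self, image: np.ndarray, params: BackendParams | None = None) -> list[CandidateMask]:
        from segment_anything import SamAutomaticMaskGenerator

        params = params or BackendParams()
        gen = SamAutomaticMaskGenerator(
            self._model,
            points_per_side=params.grid_side,
            pred_iou_thresh=params.iou_threshold,
            stability_score_thresh=params.stability_threshold,
            box_nms_thresh=params.nms_threshold,
        )
        rgb = np.moveaxis(image, 0, -1) if image.ndim == 3 and image.shape[0] == 3 else image
        out = gen.generate(np.ascontiguousarray(rgb))
        return [
            CandidateMask(
                mask=m["segmentation"].astype(bool),
                predicted_iou=float(np.clip(m["predicted_iou"], 0, 1)),
                stability=float(np.clip(m["stability_score"], 0, 1)),
            )
            for m in out
        ]

    def prompt_mask(self, image, fg_points, bg_points=None) -> np.ndarray:
        from segment_anything import SamPredictor

        if not fg_points:
            raise ValueError("at least one foreground point is required")
        predictor = SamPredictor(self._model)
        rgb = np.moveaxis(image, 0, -1) if image.ndim == 3 and image.shape[0] == 3 else image
        predictor.set_image(np.ascontiguousarray(rgb))
        pts = np.array(list(fg_points) + list(bg_points or []), dtype=float)
        lbl = np.array([1] * len(fg_points) + [0] * len(bg_points or []))
        masks, scores, _ = predictor.predict(point_coords=pts, point_labels=lbl)
        return masks[int(np.argmax(scores))].astype(bool)


def get_backend(name: str = "classical", **kwargs):
    if name == "classical":
        return ClassicalBackend()
    if name == "foundation":
        return FoundationBackend(**kwargs)
    raise ValueError(f"unknown backend {name!r}")
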