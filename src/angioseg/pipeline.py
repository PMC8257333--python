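"""End-to-end segmentation: FCM clustering -> tri-class reference ->
GA seed search -> final region growing -> target-region mask.

The final mask is the union of grown regions whose mean intensity falls
in the configured target tier (dark by default: avascular/lesion regions
in fluorescein angiography are hypofluorescent).  No post-processing is
applied: the mask is exactly what region growing produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .fcm import FCMParams, FCMResult, run_fcm, update_memberships
from .genetic_optimizer import (
    BRIGHT,
    DARK,
    MID,
    GAConfig,
    SeedChromosome,
    TriClassReference,
    build_reference,
    run_ga,
)
from .image_io import BinaryMask, GrayImage
from .region_growing import GrowthConfig, RegionStats, grow_all

__all__ = ["PipelineConfig", "SegmentationResult", "segment", "segment_manual"]

_TIER_CODES = {"dark": DARK, "mid": MID, "bright": BRIGHT}

#: above this pixel count, FCM runs on a strided downsample (the GA loop
#: and final growth always use the full-resolution image)
_FCM_DOWNSAMPLE_PIXELS = 100_000
_FCM_STRIDE = 4


def _default_growth() -> GrowthConfig:
    # mode "sd": the 3-gray-level mean window is too tight for the noise
    # levels this pipeline targets and would fragment the grown regions
    return GrowthConfig(criterion_mode="sd")


@dataclass(frozen=True)
class PipelineConfig:
    fcm: FCMParams = field(default_factory=FCMParams)
    ga: GAConfig = field(default_factory=GAConfig)
    growth: GrowthConfig = field(default_factory=_default_growth)
    target_tier: str = "dark"

    def __post_init__(self) -> None:
        if self.target_tier not in _TIER_CODES:
            raise ValidationError(f"unknown target_tier: {self.target_tier}")


@dataclass(frozen=True)
class SegmentationResult:
    mask: BinaryMask
    label_map: np.ndarray = field(repr=False)
    best_chromosome: SeedChromosome | None
    fcm_result: FCMResult | None
    cost_history: np.ndarray = field(repr=False)
    reference: TriClassReference | None = field(default=None, repr=False)
    region_stats: list[RegionStats] = field(default_factory=list, repr=False)


def _target_mask(
    image: GrayImage,
    labels: np.ndarray,
    stats: list[RegionStats],
    reference: TriClassReference,
    target_tier: str,
) -> BinaryMask:
    want = _TIER_CODES[target_tier]
    keep = np.zeros(labels.max(initial=0) + 1, dtype=bool)
    for i, st in enumerate(stats):
        if not st.is_empty and reference.classify(st.mu) == want:
            keep[i + 1] = True
    return BinaryMask(keep[labels])


def _fit_fcm(image: GrayImage, params: FCMParams) -> FCMResult:
    """Run FCM, on a strided downsample for large images, and re-project
    memberships onto the full image so the reference matches its shape."""
    if image.data.size <= _FCM_DOWNSAMPLE_PIXELS:
        return run_fcm(image, params)
    small = GrayImage(image.data[::_FCM_STRIDE, ::_FCM_STRIDE])
    result = run_fcm(small, params)
    mem = update_memberships(image, result.centers, params)
    return FCMResult(
        centers=result.centers,
        memberships=mem,
        objective_trace=result.objective_trace,
        iterations=result.iterations,
        shape=image.shape,
    )


def segment(image: GrayImage, config: PipelineConfig | None = None) -> SegmentationResult:
    """Full GA-FCM segmentation; deterministic given the config RNG seeds."""
    config = config or PipelineConfig()
    fcm_result = _fit_fcm(image, config.fcm)
    reference = build_reference(image, fcm_result)
    best, history = run_ga(image, reference, config.ga, config.growth)
    labels, stats = grow_all(image, best.seeds, config.growth)
    mask = _target_mask(image, labels, stats, reference, config.target_tier)
    return SegmentationResult(
        mask=mask,
        label_map=labels,
        best_chromosome=best,
        fcm_result=fcm_result,
        cost_history=history,
        reference=reference,
        region_stats=stats,
    )


def segment_manual(
    image: GrayImage,
    seeds: list[tuple[int, int]],
    growth: GrowthConfig | None = None,
    target_tier: str = "dark",
    reference: TriClassReference | None = None,
    fcm_params: FCMParams | None = None,
) -> SegmentationResult:
    """Region growing from hand-picked seeds (the GA stage is bypassed).

    A tri-class reference is still needed to decide which grown regions
    belong to the target tier; pass one in (e.g. from a paired
    :func:`segment` run) or it is computed with ``fcm_params``.
    """
    if not seeds:
        raise ValidationError("segment_manual needs at least one seed")
    if target_tier not in _TIER_CODES:
        raise ValidationError(f"unknown target_tier: {target_tier}")
    growth = growth or _default_growth()
    fcm_result = None
    if reference is None:
        fcm_result = _fit_fcm(image, fcm_params or FCMParams())
        reference = build_reference(image, fcm_result)
    labels, stats = grow_all(image, seeds, growth)
    mask = _target_mask(image, labels, stats, reference, target_tier)
    return SegmentationResult(
        mask=mask,
        label_map=labels,
        best_chromosome=None,
        fcm_result=fcm_result,
        cost_history=np.asarray([]),
        reference=reference,
        region_stats=stats,
    )
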