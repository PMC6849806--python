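"""End-to-end segmentation pipelines.

Both pipelines share the fusion and refinement stages; they differ only in
how the atlases are registered:

* :func:`segment_pairwise` — N independent mutual-information registrations
  atlas -> target, labels propagated straight to the target grid, fused by
  majority voting.
* :func:`segment_joint` — one groupwise variance-minimizing registration of
  the target plus all atlases, labels fused on the mean-shape image and
  back-propagated through the inverted target transform.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .config import RegistrationConfig
from .fusion import backpropagate, majority_vote, propagate_labels
from .levelset import LevelSetParams, refine_segmentation
from .registration import GroupTransformEnsemble, register_joint, register_pairwise
from .transforms import resample
from .volumes import ImageVolume, LabelVolume

__all__ = ["SegmentationResult", "segment_pairwise", "segment_joint"]


@dataclass
class SegmentationResult:
    """Output of a segmentation pipeline.

    ``atlas_segmentation`` is the fused result before level-set refinement;
    ``labels`` is the final segmentation (equal to ``atlas_segmentation``
    when refinement is disabled).
    """

    labels: LabelVolume
    atlas_segmentation: LabelVolume
    mean_shape: ImageVolume | None = None
    ensemble: GroupTransformEnsemble | None = None
    transforms: list | None = None
    history: list | None = None


def _check_atlases(atlas_images: list[ImageVolume], atlas_labels: list[LabelVolume]) -> None:
    if len(atlas_images) != len(atlas_labels):
        raise ValueError("need one label volume per atlas image")
    if len(atlas_images) < 2:
        raise ValueError("need at least 2 atlases")
    for img, lab in zip(atlas_images, atlas_labels):
        if not img.same_grid(lab):
            raise ValueError("each atlas image and its labels must share one grid")


def segment_pairwise(
    target: ImageVolume,
    atlas_images: list[ImageVolume],
    atlas_labels: list[LabelVolume],
    cfg: RegistrationConfig | None = None,
    levelset_params: LevelSetParams | None = None,
    refine: bool = True,
) -> SegmentationResult:
    """Conventional multi-atlas segmentation: pairwise MI registrations,
    direct label propagation, majority voting, optional level-set refinement.

    Each pairwise registration uses ``cfg.seed + i`` so the stochastic
    sampling differs between atlases but the whole run is reproducible.
    """
    _check_atlases(atlas_images, atlas_labels)
    cfg = cfg or RegistrationConfig()
    history: list = []
    transforms = []
    propagated = []
    for i, (img, lab) in enumerate(zip(atlas_images, atlas_labels)):
        t = register_pairwise(target, img, replace(cfg, seed=cfg.seed + i), history=history)
        transforms.append(t)
        propagated.append(resample(lab, t, target.grid, mode="nearest"))
    fused = majority_vote(propagated)
    final = refine_segmentation(target, fused, levelset_params) if refine else fused
    return SegmentationResult(final, fused, transforms=transforms, history=history)


def segment_joint(
    target: ImageVolume,
    atlas_images: list[ImageVolume],
    atlas_labels: list[LabelVolume],
    cfg: RegistrationConfig | None = None,
    levelset_params: LevelSetParams | None = None,
    refine: bool = True,
) -> SegmentationResult:
    """Joint-atlas-optimization segmentation: one groupwise registration,
    fusion on the mean-shape image, back-propagation to the target, optional
    level-set refinement."""
    _check_atlases(atlas_images, atlas_labels)
    cfg = cfg or RegistrationConfig()
    history: list = []
    ensemble, mean_img = register_joint(target, atlas_images, cfg, history=history)
    propagated = propagate_labels(atlas_labels, ensemble)
    fused_mean = majority_vote(propagated)
    fused = backpropagate(fused_mean, ensemble, target.grid)
    final = refine_segmentation(target, fused, levelset_params) if refine else fused
    return SegmentationResult(final, fused, mean_shape=mean_img, ensemble=ensemble, history=history)
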