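"""Label propagation, majority-vote fusion, and back-propagation.

One fusion implementation serves both pipelines: in joint mode the atlas
labels are propagated onto the mean-shape grid and the fused segmentation is
carried back to the target through the inverted target transform; in pairwise
mode the labels are propagated directly to the target grid and the same
:func:`majority_vote` is applied there.
"""

from __future__ import annotations

import numpy as np

from .registration import GroupTransformEnsemble
from .transforms import invert_transform, resample
from .volumes import Grid, LabelVolume

__all__ = ["propagate_labels", "majority_vote", "backpropagate", "vote_tally"]


def propagate_labels(
    labels: list[LabelVolume],
    ensemble: GroupTransformEnsemble,
) -> list[LabelVolume]:
    """Warp each atlas label volume onto the mean-shape (reference) grid.

    ``labels[i]`` is resampled with nearest-neighbour interpolation through
    ``ensemble.transforms[i + 1]`` (index 0 belongs to the target image).
    """
    if len(labels) != ensemble.n_atlases:
        raise ValueError(
            f"got {len(labels)} label volumes for an ensemble of {ensemble.n_atlases} atlases"
        )
    ref = ensemble.reference_grid
    return [
        resample(lab, ensemble.transforms[i + 1], ref, mode="nearest")
        for i, lab in enumerate(labels)
    ]


def vote_tally(propagated: list[LabelVolume]) -> np.ndarray:
    """Per-voxel vote counts, shape ``(max_label + 1, *grid)``; counts at
    each voxel sum to the number of inputs."""
    if not propagated:
        raise ValueError("no label volumes to tally")
    g0 = propagated[0]
    for p in propagated[1:]:
        if not g0.same_grid(p):
            raise ValueError("all propagated label volumes must share one grid")
    max_label = max(int(p.data.max()) for p in propagated)
    tally = np.zeros((max_label + 1, *g0.data.shape), dtype=np.int32)
    for p in propagated:
        for lab in np.unique(p.data):
            tally[int(lab)] += p.data == lab
    return tally


def majority_vote(propagated: list[LabelVolume]) -> LabelVolume:
    """Per-voxel label with the highest vote count.

    Ties are broken toward the smaller label value, so background wins over
    any foreground label on an even split.
    """
    tally = vote_tally(propagated)
    # argmax returns the first (= smallest label) maximum: the tie rule
    fused = np.argmax(tally, axis=0).astype(np.int16)
    g0 = propagated[0]
    return LabelVolume(fused, g0.spacing, g0.origin, dict(g0.label_map))


def backpropagate(
    seg: LabelVolume,
    ensemble: GroupTransformEnsemble,
    target_grid: Grid,
    tol: float = 0.5,
    max_iter: int = 100,
) -> LabelVolume:
    """Carry a segmentation from the mean-shape grid back to the target.

    The target's transform (ensemble index 0) maps reference points into
    target space; its numerical inverse (fixed-point displacement-field
    inversion, residual ``<= tol`` mm) maps target voxels back to the
    mean-shape frame where ``seg`` is defined.  Nearest-neighbour resampling.
    The inverse field is built on the target grid refined to at most 2.5 mm
    per axis, keeping its interpolation error within the tolerance on coarse
    grids.  The default tolerance (0.5 mm) is looser than the generic
    inversion default: a transform fitted on noisy data has noise-driven
    sharp content in image-free background regions that dominates the global
    residual, while for nearest-neighbour label transport any sub-half-voxel
    residual is immaterial.
    """
    factors = [max(1, int(np.ceil(s / 2.5))) for s in target_grid.spacing]
    fine = Grid(
        tuple((n - 1) * f + 1 for n, f in zip(target_grid.shape, factors)),
        tuple(s / f for s, f in zip(target_grid.spacing, factors)),
        target_grid.origin,
    )
    inv = invert_transform(ensemble.transforms[0], fine, tol=tol, max_iter=max_iter)
    return resample(seg, inv, target_grid, mode="nearest")
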