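"""Registration configuration shared by the pairwise and joint modes."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RegistrationConfig:
    """Settings consumed identically (wherever applicable) by
    :func:`~jointatlas.registration.register_pairwise` and
    :func:`~jointatlas.registration.register_joint`.

    Attributes
    ----------
    n_resolutions:
        Levels in the coarse-to-fine image pyramid (downsampling by powers
    	of two; the finest level is the native resolution).
    iterations_per_resolution:
        Stochastic gradient descent iterations for the B-spline stage at each
        level.
    affine_iterations_per_resolution:
        Iterations for the preceding affine stage at each level.
    grid_spacing_mm:
        B-spline control point spacing ``sigma`` (mm), identical at all
        levels.
    samples_per_iteration:
        Random voxels drawn per SGD iteration to estimate the metric and its
        gradient.
    step_size_schedule:
        ``(a, A, alpha)`` of the decaying gain ``a / (A + k)^alpha`` (mm of
        maximum parameter step at iteration ``k``).
    seed:
        Seed for the sampling RNG; fixes the whole optimization.
    intensity_range:
        Range images are linearly normalized to before registration.
    mi_bins:
        Histogram bins per axis for the mutual-information metric.
    """

    n_resolutions: int = 3
    iterations_per_resolution: int = 1000
    affine_iterations_per_resolution: int = 300
    grid_spacing_mm: float = 10.0
    samples_per_iteration: int = 2048
    step_size_schedule: tuple[float, float, float] = (4.0, 50.0, 0.602)
    seed: int = 0
    intensity_range: tuple[float, float] = (0.0, 255.0)
    mi_bins: int = 32

    def __post_init__(self) -> None:
        if self.n_resolutions < 1:
            raise ValueError("n_resolutions must be >= 1")
        if self.grid_spacing_mm <= 0:
            raise ValueError("grid_spacing_mm must be > 0")
        lo, hi = self.intensity_range
        if not lo < hi:
            raise ValueError("intensity_range must satisfy low < high")
        self.step_size_schedule = tuple(float(v) for v in self.step_size_schedule)
        self.intensity_range = (float(lo), float(hi))

    # -- persistence ---------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RegistrationConfig":
        return cls(**d)

    def save(self, path: str | Path) -> None:
        p = Path(path)
        d = self.to_dict()
        d["step_size_schedule"] = list(d["step_size_schedule"])
        d["intensity_range"] = list(d["intensity_range"])
        if p.suffix in (".yaml", ".yml"):
            p.write_text(yaml.safe_dump(d))
        else:
            p.write_text(json.dumps(d, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "RegistrationConfig":
        p = Path(path)
        d = yaml.safe_load(p.read_text())
        if "step_size_schedule" in d:
            d["step_size_schedule"] = tuple(d["step_size_schedule"])
        if "intensity_range" in d:
            d["intensity_range"] = tuple(d["intensity_range"])
        return cls(**d)
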