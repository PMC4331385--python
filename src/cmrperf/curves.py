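"""Time-curve containers shared by every pipeline stage.

Two thin array-backed containers are used throughout: :class:`SignalCurve`
for raw scanner signal intensities and :class:`ConcentrationCurve` for
contrast-agent concentration in mM. Times are always seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = ["SignalCurve", "ConcentrationCurve", "AIF_LABEL"]

#: Conventional region label for the arterial input function (left-ventricular
#: blood pool) curve.
AIF_LABEL = "AIF"


def _as_float_array(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError("curve arrays must be one-dimensional")
    return arr


@dataclass
class _BaseCurve:
    times: np.ndarray
    values: np.ndarray
    region_label: str = AIF_LABEL

    def __post_init__(self) -> None:
        self.times = _as_float_array(self.times)
        self.values = _as_float_array(self.values)
        if self.times.shape != self.values.shape:
            raise ValueError(
                f"times and values length mismatch: {self.times.size} vs {self.values.size}"
            )
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("curve values must be finite")

    def __len__(self) -> int:
        return self.times.size

    @property
    def dt(self) -> float:
        """Sampling step; raises if the curve is not uniformly sampled."""
        steps = np.diff(self.times)
        if steps.size == 0:
            raise ValueError("curve has a single sample")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError(f"curve '{self.region_label}' is not uniformly sampled")
        return float(steps[0])

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        steps = np.diff(self.times)
        return steps.size > 0 and bool(np.allclose(steps, steps[0], rtol=rtol, atol=1e-9))

    def with_values(self, values: np.ndarray):
        """Copy of this curve with ``values`` replaced (same time base)."""
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass
class SignalCurve(_BaseCurve):
    """Signal-intensity time curve in arbitrary scanner units (non-negative)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.any(self.values < 0):
            raise ValueError("signal intensities must be non-negative")


@dataclass
class ConcentrationCurve(_BaseCurve):
    """Contrast-agent concentration time curve in mM.

    ``saturated`` marks samples whose originating signal intensity sat at or
    above the saturation plateau of the readout and was clipped during
    inversion; such samples carry a floor on the true concentration, not an
    estimate of it.
    """

    saturated: Optional[np.ndarray] = field(default=None)

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.saturated is not None:
            self.saturated = np.asarray(self.saturated, dtype=bool)
            if self.saturated.shape != self.values.shape:
                raise ValueError("saturated mask must match values length")

    @property
    def saturation_fraction(self) -> float:
        if self.saturated is None or len(self) == 0:
            return 0.0
        return float(np.mean(self.saturated))
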