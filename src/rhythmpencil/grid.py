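"""Uniform circadian-time sampling grids.

Every decomposition in this package assumes a uniform time axis: samples
taken at t_n = start + n*step for n = 0..N-1, in hours of circadian time
(CT). The canonical transcriptome design is 24 points, CT0 to CT46 at a
2-h step (a 48-h span, end-exclusive so phase folding keeps cycles
balanced); calorimetry traces use a finer step over a longer window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SamplingGrid:
    """A uniform time axis: ``t_n = start_ct_h + n * step_h``.

    Parameters
    ----------
    start_ct_h : float
        Circadian time of the first sample, hours.
    step_h : float
        Sampling interval in hours; must be positive.
    n_points : int
        Number of samples; at least 4 (shorter series cannot support
        even a single damped-cosine fit).
    """

    start_ct_h: float = 0.0
    step_h: float = 2.0
    n_points: int = 24

    def __post_init__(self) -> None:
        if self.step_h <= 0:
            raise ValueError(f"step_h must be positive, got {self.step_h}")
        if self.n_points < 4:
            raise ValueError(f"n_points must be >= 4, got {self.n_points}")

    @property
    def timepoints(self) -> np.ndarray:
        """Sample times in hours, shape ``(n_points,)``."""
        return self.start_ct_h + self.step_h * np.arange(self.n_points)

    @property
    def span_h(self) -> float:
        """Total span from first to last sample plus one step (the
        period of the implied circular design)."""
        return self.step_h * self.n_points

    def ct_labels(self) -> list[str]:
        """Zero-padded CT hour labels, e.g. ``CT00, CT02, ...``."""
        width = max(2, len(str(int(self.timepoints[-1]))))
        return [f"CT{int(round(t)):0{width}d}" for t in self.timepoints]
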