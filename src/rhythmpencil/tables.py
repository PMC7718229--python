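"""Flat-table serialisation of decompositions and rhythm calls.

Decompositions are written one row per (gene, component) with the gene's
DC level and residual repeated on each row; genes with no components get a
single row of NaN component fields so they survive the round trip.
"""

from __future__ import annotations

import cmath
import math

import numpy as np
import pandas as pd

from .grid import SamplingGrid
from .pencil import GeneDecomposition, OscillationComponent

__all__ = ["decompositions_to_frame", "frame_to_decompositions", "calls_to_frame"]

_COLUMNS = [
    "gene_id",
    "rank",
    "period_h",
    "amplitude",
    "phase_h",
    "decay_per_h",
    "dc",
    "residual_rms",
]


def decompositions_to_frame(decomps: list[GeneDecomposition]) -> pd.DataFrame:
    rows = []
    for d in decomps:
        if not d.components:
            rows.append(
                dict(
                    gene_id=d.gene_id, rank=0, period_h=np.nan, amplitude=np.nan,
                    phase_h=np.nan, decay_per_h=np.nan, dc=d.dc,
                    residual_rms=d.residual_rms,
                )
            )
        for rank, c in enumerate(d.components, start=1):
            rows.append(
                dict(
                    gene_id=d.gene_id, rank=rank, period_h=c.period_h,
                    amplitude=c.amplitude, phase_h=c.phase_h,
                    decay_per_h=c.decay_per_h, dc=d.dc,
                    residual_rms=d.residual_rms,
                )
            )
    return pd.DataFrame(rows, columns=_COLUMNS)


def _component_from_row(row, grid: SamplingGrid) -> OscillationComponent:
    period, amp = float(row.period_h), float(row.amplitude)
    phase, decay = float(row.phase_h), float(row.decay_per_h)
    omega = 2.0 * math.pi / period
    pole = cmath.exp(complex(decay, omega) * grid.step_h)
    residue = (amp / 2.0) * cmath.exp(complex(0.0, -omega * phase))
    return OscillationComponent(period, amp, phase, decay, pole, residue)


def frame_to_decompositions(
    df: pd.DataFrame, grid: SamplingGrid
) -> list[GeneDecomposition]:
    """Inverse of :func:`decompositions_to_frame` (trend terms and the
    stored residual refer to the original series, which is not re-read)."""
    out = []
    for gene_id, sub in df.groupby("gene_id", sort=False):
        comps = [
            _component_from_row(r, grid)
            for r in sub.itertuples()
            if r.rank > 0 and not math.isnan(r.period_h)
        ]
        comps.sort(key=lambda c: (-c.amplitude, c.period_h))
        out.append(
            GeneDecomposition(
                str(gene_id),
                float(sub["dc"].iloc[0]),
                comps,
                float(sub["residual_rms"].iloc[0]),
                grid,
            )
        )
    return out


def calls_to_frame(calls) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            dict(
                gene_id=c.gene_id,
                label=c.label,
                dominant_period_h=c.dominant.period_h if c.dominant else np.nan,
                dominant_amplitude=c.dominant.amplitude if c.dominant else np.nan,
                dominant_phase_h=c.dominant.phase_h if c.dominant else np.nan,
                p_value=c.p_value if c.p_value is not None else np.nan,
                q_value=c.q_value if c.q_value is not None else np.nan,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "label", "dominant_period_h", "dominant_amplitude",
            "dominant_phase_h", "p_value", "q_value",
        ],
    )
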