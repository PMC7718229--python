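"""Differential rhythmicity between two genotypes.

For genes rhythmic in the control genotype, the knockout decomposition
either retains a passing component in the 12-h band (``sustained`` — the
rhythm persists, possibly with altered phase or amplitude) or has none
(``abolished``).  Band *presence*, not dominance, is the default criterion:
a gene whose 12-h component merely drops below another component still has
a 12-h rhythm.  A strict-dominance mode is available for the narrower
reading.  Sustained genes get a circular phase difference (knockout minus
control, folded to ``(-T/2, T/2]`` on the control period) and a
knockout/control amplitude ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .classify import PeriodBands
from .pencil import GeneDecomposition, OscFilter, OscillationComponent, dominant_component

__all__ = [
    "DifferentialCall",
    "ComparisonSummary",
    "ConcordanceResult",
    "compare_genotypes",
    "matched_pairs_table",
    "gene_set_overlap",
]


@dataclass
class DifferentialCall:
    gene_id: str
    verdict: str  # "abolished" | "sustained"
    control_dominant: OscillationComponent
    knockout_band_component: OscillationComponent | None
    delta_phase_h: float | None
    amplitude_ratio: float | None


@dataclass(frozen=True)
class ComparisonSummary:
    """Cohort-level verdict counts, mirroring an abolished/sustained pie."""

    n_input: int
    n_abolished: int
    n_sustained: int

    @property
    def abolished_fraction(self) -> float:
        return self.n_abolished / self.n_input if self.n_input else 0.0

    @property
    def abolished_percent(self) -> float:
        return 100.0 * self.abolished_fraction

    @property
    def sustained_percent(self) -> float:
        return 100.0 - self.abolished_percent if self.n_input else 0.0


@dataclass(frozen=True)
class ConcordanceResult:
    size_a: int
    size_b: int
    size_intersection: int
    fraction_of_a: float


def circular_delta_h(phase_ko_h: float, phase_ctrl_h: float, period_h: float) -> float:
    """Signed circular difference knockout - control, in ``(-T/2, T/2]``."""
    d = (phase_ko_h - phase_ctrl_h) % period_h
    if d > period_h / 2.0:
        d -= period_h
    # fold the boundary so exactly half a period reports +T/2, not -T/2
    if d == -period_h / 2.0:
        d = period_h / 2.0
    return d


def _band_component(
    d: GeneDecomposition,
    band: tuple[float, float],
    f: OscFilter,
    require_dominant: bool,
) -> OscillationComponent | None:
    if require_dominant:
        dom = dominant_component(d, f)
        if dom is not None and band[0] <= dom.period_h <= band[1]:
            return dom
        return None
    in_band = [
        c
        for c in d.components
        if band[0] <= c.period_h <= band[1] and f.passes(c, d.grid, d.dc)
    ]
    if not in_band:
        return None
    return min(in_band, key=lambda c: (-f.effective_amplitude(c, d.grid), c.period_h))


def compare_genotypes(
    control_decomps: list[GeneDecomposition],
    knockout_decomps: list[GeneDecomposition],
    bands: PeriodBands | None = None,
    osc_filter: OscFilter | None = None,
    require_dominant: bool = False,
) -> tuple[list[DifferentialCall], ComparisonSummary]:
    """Call abolished vs sustained 12-h rhythms per gene.

    Inputs are matched-by-id decompositions of genes called ``twelve_h``
    in the control; unmatched ids raise.  Returns per-gene calls plus the
    cohort summary (counts and percentages).
    """
    bands = bands or PeriodBands()
    f = osc_filter or OscFilter()
    ko_by_id = {d.gene_id: d for d in knockout_decomps}
    ctrl_ids = [d.gene_id for d in control_decomps]
    missing = [g for g in ctrl_ids if g not in ko_by_id]
    extra = [g for g in ko_by_id if g not in set(ctrl_ids)]
    if missing or extra:
        raise ValueError(
            f"gene sets differ between genotypes; missing in knockout: "
            f"{missing[:5]}, extra in knockout: {extra[:5]}"
        )

    calls: list[DifferentialCall] = []
    for ctrl in control_decomps:
        ctrl_dom = _band_component(ctrl, bands.twelve_h, f, require_dominant=True)
        if ctrl_dom is None:
            # fall back to the strongest in-band component; the caller
            # promised a control-twelve_h gene set
            ctrl_dom = _band_component(ctrl, bands.twelve_h, f, require_dominant=False)
        if ctrl_dom is None:
            raise ValueError(
                f"gene {ctrl.gene_id!r} has no passing 12-h-band component in "
                "the control; restrict input to control twelve_h calls"
            )
        ko_comp = _band_component(
            ko_by_id[ctrl.gene_id], bands.twelve_h, f, require_dominant
        )
        if ko_comp is None:
            calls.append(
                DifferentialCall(ctrl.gene_id, "abolished", ctrl_dom, None, None, None)
            )
        else:
            dphi = circular_delta_h(ko_comp.phase_h, ctrl_dom.phase_h, ctrl_dom.period_h)
            ratio = (
                ko_comp.amplitude / ctrl_dom.amplitude if ctrl_dom.amplitude > 0 else 0.0
            )
            calls.append(
                DifferentialCall(ctrl.gene_id, "sustained", ctrl_dom, ko_comp, dphi, ratio)
            )
    n_ab = sum(c.verdict == "abolished" for c in calls)
    summary = ComparisonSummary(len(calls), n_ab, len(calls) - n_ab)
    return calls, summary


def matched_pairs_table(calls: list[DifferentialCall]) -> pd.DataFrame:
    """Phase/amplitude pairs for sustained genes, one row per gene.

    Phases are in hours on each genotype's own component period; rows are
    ordered by gene id.  Passing an abolished call raises.
    """
    rows = []
    for c in sorted(calls, key=lambda c: c.gene_id):
        if c.verdict != "sustained":
            raise ValueError(f"gene {c.gene_id!r} is abolished, not sustained")
        rows.append(
            {
                "gene_id": c.gene_id,
                "control_phase_h": c.control_dominant.phase_h,
                "knockout_phase_h": c.knockout_band_component.phase_h,
                "control_amplitude": c.control_dominant.amplitude,
                "knockout_amplitude": c.knockout_band_component.amplitude,
            }
        )
    cols = [
        "gene_id",
        "control_phase_h",
        "knockout_phase_h",
        "control_amplitude",
        "knockout_amplitude",
    ]
    return pd.DataFrame(rows, columns=cols)


def gene_set_overlap(a, b) -> ConcordanceResult:
    """Exact overlap of two gene-id sets (duplicates collapsed)."""
    sa, sb = set(a), set(b)
    inter = len(sa & sb)
    return ConcordanceResult(
        size_a=len(sa),
        size_b=len(sb),
        size_intersection=inter,
        fraction_of_a=inter / len(sa) if sa else 0.0,
    )
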