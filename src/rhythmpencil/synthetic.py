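"""Synthetic expression cohorts and calorimetry traces with known
superimposed oscillatory structure.

Each gene is a DC baseline plus damped cosines,

    x(t) = max(0, [c0 + sum_i A_i exp(b_i t) cos(2 pi (t - phi_i) / T_i)] * (1 + eps)),

with multiplicative Gaussian noise eps ~ N(0, noise_cv^2) drawn
independently per sample (replicates share the truth and differ only in
the noise draw).  A count mode (Poisson at the scaled noiseless mean) is
available for users who want integer, mean-variance-coupled data; the
default stays continuous because the analysis operates on normalised
abundances.  The paired-cohort generator produces a control cohort and a
knockout cohort sharing truths except that a seeded fraction of 12-h genes
loses every 10-14 h-band component — the ground truth for the
abolished/sustained comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .grid import SamplingGrid
from .preprocess import ExpressionMatrix

__all__ = [
    "ComponentSpec",
    "GeneTruth",
    "CohortSpec",
    "generate_cohort",
    "generate_paired_cohort",
    "generate_rer_trace",
    "truths_to_json",
]

CLASS_LABELS = ("twelve_h", "twentyfour_h", "other", "flat")
TWELVE_H_BAND = (10.0, 14.0)


@dataclass(frozen=True)
class ComponentSpec:
    """One damped cosine: peaks (undamped) at ``phase_h`` hours after CT0,
    repeating every ``period_h`` hours, decaying at ``decay_per_h``
    (negative = damping)."""

    period_h: float
    amplitude: float
    phase_h: float = 0.0
    decay_per_h: float = 0.0

    def __post_init__(self) -> None:
        if self.period_h <= 0:
            raise ValueError(f"period_h must be positive, got {self.period_h}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be non-negative, got {self.amplitude}")
        if not (0 <= self.phase_h < self.period_h):
            raise ValueError(
                f"phase_h must lie in [0, period_h), got {self.phase_h} for T={self.period_h}"
            )

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        return (
            self.amplitude
            * np.exp(self.decay_per_h * t)
            * np.cos(2.0 * np.pi * (t - self.phase_h) / self.period_h)
        )


@dataclass
class GeneTruth:
    """Ground truth for one simulated gene."""

    gene_id: str
    baseline: float
    components: list[ComponentSpec]
    noise_cv: float
    class_label: str

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class_label {self.class_label!r}")

    def noiseless(self, t: np.ndarray) -> np.ndarray:
        out = np.full_like(t, self.baseline, dtype=float)
        for c in self.components:
            out += c.evaluate(t)
        return out


@dataclass
class CohortSpec:
    """Design of one simulated cohort.

    ``fractions`` maps class labels to proportions summing to 1.
    ``rel_amplitude`` scales each rhythmic gene's dominant amplitude as a
    fraction of its baseline; the defaults (20% 12-h, 30% 24-h, 50% flat
    genes, relative amplitude 0.5, noise CV 0.1, 2 replicates on the
    24-point 2-h grid) emulate a liver time-course in which ultradian genes
    are a sizeable minority and rhythm amplitudes are comparable to the
    mean level.
    """

    n_genes: int = 2000
    fractions: dict[str, float] = field(
        default_factory=lambda: {"twelve_h": 0.2, "twentyfour_h": 0.3, "flat": 0.5}
    )
    grid: SamplingGrid = field(default_factory=SamplingGrid)
    n_replicates: int = 2
    seed: int = 0
    noise_cv: float = 0.1
    rel_amplitude: float = 0.5
    knockout_abolished_fraction: float = 0.8855
    secondary_rel_amplitude: float = 0.3
    decay_range: tuple[float, float] = (0.0, 0.0)
    count_mode: bool = False
    baseline_log_mean: float = np.log(100.0)
    baseline_log_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_replicates < 1:
            raise ValueError("n_genes and n_replicates must be positive")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, expected 1")
        unknown = set(self.fractions) - set(CLASS_LABELS)
        if unknown:
            raise ValueError(f"unknown class labels in fractions: {unknown}")
        if not (0.0 <= self.knockout_abolished_fraction <= 1.0):
            raise ValueError("knockout_abolished_fraction must be in [0, 1]")


_PERIOD_RANGES = {
    "twelve_h": (10.5, 13.5),
    "twentyfour_h": (21.0, 27.0),
    "other": (15.0, 19.0),
}


def _draw_truths(spec: CohortSpec, rng: np.random.Generator) -> list[GeneTruth]:
    labels: list[str] = []
    counts = {lab: int(round(frac * spec.n_genes)) for lab, frac in spec.fractions.items()}
    # rounding drift lands on the largest class so totals always match
    drift = spec.n_genes - sum(counts.values())
    counts[max(counts, key=counts.get)] += drift
    for lab in CLASS_LABELS:
        labels.extend([lab] * counts.get(lab, 0))

    width = len(str(spec.n_genes))
    truths: list[GeneTruth] = []
    for i, lab in enumerate(labels):
        baseline = float(np.exp(rng.normal(spec.baseline_log_mean, spec.baseline_log_sd)))
        comps: list[ComponentSpec] = []
        if lab != "flat":
            lo, hi = _PERIOD_RANGES[lab]
            period = float(rng.uniform(lo, hi))
            amp = spec.rel_amplitude * baseline
            decay = float(rng.uniform(*spec.decay_range))
            comps.append(
                ComponentSpec(period, amp, float(rng.uniform(0, period)), decay)
            )
            if spec.secondary_rel_amplitude > 0 and lab in ("twelve_h", "twentyfour_h"):
                # a weaker component in the sibling band, as real rhythmic
                # genes superimpose circadian and ultradian content
                p2_lo, p2_hi = (
                    _PERIOD_RANGES["twentyfour_h"]
                    if lab == "twelve_h"
                    else _PERIOD_RANGES["twelve_h"]
                )
                p2 = float(rng.uniform(p2_lo, p2_hi))
                comps.append(
                    ComponentSpec(
                        p2,
                        spec.secondary_rel_amplitude * amp,
                        float(rng.uniform(0, p2)),
                        0.0,
                    )
                )
        truths.append(
            GeneTruth(f"gene_{i:0{width}d}", baseline, comps, spec.noise_cv, lab)
        )
    return truths


def _render(
    truths: list[GeneTruth], spec: CohortSpec, rng: np.random.Generator
) -> ExpressionMatrix:
    grid = spec.grid
    t = grid.timepoints - grid.start_ct_h
    labels = [
        f"{ct}_r{k + 1}"
        for ct in grid.ct_labels()
        for k in range(spec.n_replicates)
    ]
    vals = np.empty((len(truths), grid.n_points * spec.n_replicates))
    for g, tr in enumerate(truths):
        clean = np.repeat(tr.noiseless(t), spec.n_replicates)
        if spec.count_mode:
            vals[g] = rng.poisson(np.maximum(clean, 0.0)).astype(float)
        elif tr.noise_cv > 0:
            eps = rng.normal(0.0, tr.noise_cv, clean.size)
            vals[g] = np.maximum(0.0, clean * (1.0 + eps))
        else:
            vals[g] = np.maximum(0.0, clean)
    df = pd.DataFrame(vals, index=[tr.gene_id for tr in truths], columns=labels)
    return ExpressionMatrix(df, grid)


def generate_cohort(spec: CohortSpec) -> tuple[ExpressionMatrix, list[GeneTruth]]:
    """Simulate one cohort; identical spec + seed gives identical output."""
    rng = np.random.default_rng(spec.seed)
    truths = _draw_truths(spec, rng)
    return _render(truths, spec, rng), truths


def generate_paired_cohort(
    spec: CohortSpec,
) -> tuple[ExpressionMatrix, ExpressionMatrix, list[GeneTruth], list[GeneTruth]]:
    """Simulate matched control and knockout cohorts.

    The knockout shares every truth with the control except that a seeded
    subset of ``twelve_h`` genes — a ``knockout_abolished_fraction`` of
    them, size ``round(fraction * n)`` — loses all components with period
    inside the 12-h band.  Returns (control matrix, knockout matrix,
    control truths, knockout truths); knockout truths carry the same gene
    ids, abolished genes relabelled by their remaining content.
    """
    rng = np.random.default_rng(spec.seed)
    truths = _draw_truths(spec, rng)
    control = _render(truths, spec, rng)

    twelve_idx = [i for i, tr in enumerate(truths) if tr.class_label == "twelve_h"]
    n_abolish = int(round(spec.knockout_abolished_fraction * len(twelve_idx)))
    abolish = set(
        rng.choice(twelve_idx, size=n_abolish, replace=False).tolist()
        if n_abolish
        else []
    )

    ko_truths: list[GeneTruth] = []
    lo, hi = TWELVE_H_BAND
    for i, tr in enumerate(truths):
        if i in abolish:
            kept = [c for c in tr.components if not (lo <= c.period_h <= hi)]
            label = "twentyfour_h" if kept else "flat"
            ko_truths.append(
                GeneTruth(tr.gene_id, tr.baseline, kept, tr.noise_cv, label)
            )
        else:
            ko_truths.append(tr)
    knockout = _render(ko_truths, spec, rng)
    return control, knockout, truths, ko_truths


def generate_rer_trace(
    components: list[ComponentSpec],
    baseline: float,
    n_animals: int,
    span_h: float,
    step_h: float,
    noise_sd: float,
    seed: int,
) -> pd.DataFrame:
    """Per-animal uniformly sampled respiratory-exchange-ratio traces.

    Returns a tidy frame (animal_id, time_h, value): baseline plus the
    summed components plus i.i.d. Gaussian noise, one trace per animal.
    """
    if step_h <= 0:
        raise ValueError(f"step_h must be positive, got {step_h}")
    if step_h >= span_h:
        raise ValueError("step_h must be smaller than span_h")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, span_h, step_h)
    clean = np.full_like(t, baseline)
    for c in components:
        clean += c.evaluate(t)
    frames = []
    for a in range(n_animals):
        noise = rng.normal(0.0, noise_sd, t.size) if noise_sd > 0 else 0.0
        frames.append(
            pd.DataFrame(
                {"animal_id": f"animal_{a + 1}", "time_h": t, "value": clean + noise}
            )
        )
    return pd.concat(frames, ignore_index=True)


def truths_to_json(truths: list[GeneTruth], path) -> None:
    payload = [
        {
            "gene_id": tr.gene_id,
            "baseline": tr.baseline,
            "noise_cv": tr.noise_cv,
            "class_label": tr.class_label,
            "components": [asdict(c) for c in tr.components],
        }
        for tr in truths
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
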