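"""Reading, filtering, normalising and replicate-averaging expression
matrices ahead of oscillation analysis.

The pipeline mirrors standard bulk RNA-seq practice for rhythm detection:
genes with a zero in *any* sample are removed (a single dropout breaks the
geometric means and the damped-cosine model alike), per-sample size factors
are estimated by the median-of-ratios method, columns are divided by their
factor, and replicates are averaged at each timepoint to yield one series
per gene on the sampling grid.  Filtering precedes normalisation so every
geometric mean is finite; the size-factor estimator restricted to
all-positive rows is unchanged by that order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import SamplingGrid

__all__ = [
    "ExpressionMatrix",
    "read_expression_matrix",
    "write_expression_matrix",
    "filter_zero_genes",
    "size_factors",
    "normalize",
    "average_replicates",
]

_LABEL_RE = re.compile(r"^CT(\d+)_r(\d+)$")


def parse_sample_label(label: str) -> tuple[int, int]:
    """Parse ``CT{tt}_r{k}`` into (CT hour, replicate index)."""
    m = _LABEL_RE.match(label)
    if m is None:
        raise ValueError(f"sample label {label!r} does not match CT{{tt}}_r{{k}}")
    return int(m.group(1)), int(m.group(2))


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance matrix with CT/replicate-coded columns.

    ``data`` is a DataFrame indexed by gene id with columns labelled
    ``CT{tt}_r{k}``; ``grid`` is the uniform time axis the labels must
    tile, every timepoint carrying the same replicate count.
    """

    data: pd.DataFrame
    grid: SamplingGrid

    def __post_init__(self) -> None:
        self.data.index.name = "gene_id"
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if (self.data.to_numpy() < 0).any():
            gene, col = np.argwhere(self.data.to_numpy() < 0)[0]
            raise ValueError(
                f"negative value at gene {self.data.index[gene]!r}, "
                f"sample {self.data.columns[col]!r}"
            )
        self._validate_labels()

    def _validate_labels(self) -> None:
        grid_hours = [int(round(t)) for t in self.grid.timepoints]
        seen: dict[int, set[int]] = {h: set() for h in grid_hours}
        for label in self.data.columns:
            ct, rep = parse_sample_label(label)
            if ct not in seen:
                raise ValueError(
                    f"sample {label!r}: CT{ct} is not a grid timepoint "
                    f"(start {self.grid.start_ct_h}, step {self.grid.step_h})"
                )
            if rep in seen[ct]:
                raise ValueError(f"duplicate sample label {label!r}")
            seen[ct].add(rep)
        counts = {h: len(r) for h, r in seen.items()}
        if len(set(counts.values())) != 1 or 0 in counts.values():
            missing = [h for h, c in counts.items() if c < max(counts.values())]
            raise ValueError(
                f"unbalanced replicate structure; deficient timepoints: CT{missing}"
            )

    @property
    def n_replicates(self) -> int:
        return self.data.shape[1] // self.grid.n_points

    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()


def read_expression_matrix(path, grid: SamplingGrid) -> ExpressionMatrix:
    """Read a TSV (first column gene id, header ``CT{tt}_r{k}``) and
    validate it against ``grid``. Ragged rows, negative values, duplicate
    gene ids and off-grid labels raise with the offending row/column named.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)][0]
        raise ValueError(f"missing/ragged value in row {bad!r}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric value in matrix body: {exc}") from exc
    return ExpressionMatrix(df, grid)


def write_expression_matrix(m: ExpressionMatrix, path) -> None:
    m.data.to_csv(path, sep="\t", index_label="gene_id")


def filter_zero_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Keep exactly the genes positive in every replicate and timepoint."""
    mask = (m.data.to_numpy() > 0).all(axis=1)
    return ExpressionMatrix(m.data.loc[mask], m.grid)


def size_factors(m: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample j, the factor is the median over genes of
    ``value[g, j] / geomean_g`` where ``geomean_g`` is gene g's geometric
    mean across samples; only all-positive gene rows enter, so logs stay
    finite.  Raises if no such row exists (filter zeros first).

    The factors are rescaled to geometric mean 1, which makes the
    estimator idempotent: the size factors of an already-normalised
    matrix are exactly 1.  (The raw median-of-ratios factors of a
    normalised matrix all equal the geometric mean of the original
    factors, a constant but not 1.)  Relative factors between samples
    are unaffected.
    """
    vals = m.data.to_numpy(dtype=float)
    pos = (vals > 0).all(axis=1)
    if not pos.any():
        raise ValueError(
            "no gene is positive in all samples; run filter_zero_genes first"
        )
    logs = np.log(vals[pos])
    log_geomean = logs.mean(axis=1, keepdims=True)
    log_factors = np.median(logs - log_geomean, axis=0)
    factors = np.exp(log_factors - log_factors.mean())
    return pd.Series(factors, index=m.data.columns, name="size_factor")


def normalize(m: ExpressionMatrix, factors: pd.Series) -> ExpressionMatrix:
    """Divide each sample column by its size factor."""
    f = factors.reindex(m.data.columns)
    if f.isna().any():
        missing = f.index[f.isna()].tolist()
        raise ValueError(f"no size factor for samples: {missing}")
    if (f <= 0).any():
        bad = f.index[f <= 0].tolist()
        raise ValueError(f"non-positive size factor for samples: {bad}")
    return ExpressionMatrix(m.data / f, m.grid)


def average_replicates(m: ExpressionMatrix) -> pd.DataFrame:
    """Arithmetic mean across replicates at each timepoint.

    Returns a DataFrame (genes x timepoints) with columns ``CT{tt}``
    ordered by time; each row is the series handed to the pencil.
    """
    hours = [parse_sample_label(c)[0] for c in m.data.columns]
    grouped = m.data.T.groupby(np.asarray(hours)).mean().T
    order = [int(round(t)) for t in m.grid.timepoints]
    grouped = grouped[order]
    grouped.columns = m.grid.ct_labels()
    return grouped
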