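"""Matrix-pencil (eigenvalue/pencil) decomposition of a uniformly sampled
series into a DC level plus superimposed exponentially damped sinusoids.

The model is

    y_n = c0 + sum_i A_i * exp(b_i * (t_n - t_0)) * cos(2*pi*(t_n - t_0)/T_i + theta_i) + eps_n

equivalently a sum of complex exponentials y_n = sum_k r_k * z_k**n with
poles z_k and residues r_k.  Poles are recovered as the eigenvalues of the
shifted-vs-unshifted pencil built from the rank-truncated SVD factors of
the data Hankel matrix (Hua & Sarkar's method); residues follow from a
Vandermonde least-squares solve.  Conjugate pole pairs become oscillatory
components with period ``T = 2*pi*step / |arg z|``, amplitude ``A = 2|r|``,
decay ``b = ln|z| / step`` and a phase reported as the peak time of the
undamped cosine after t_0, in ``[0, T)``.

Real poles are not oscillations: their content (a constant at z = 1, a
drifting exponential otherwise) is summarised into the DC level as its
time-mean over the grid, and whatever time variation that summary misses
lands in the residual.  They are never reported as components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .grid import SamplingGrid

__all__ = [
    "PencilConfig",
    "OscillationComponent",
    "GeneDecomposition",
    "OscFilter",
    "pencil_decompose",
    "reconstruct",
    "dominant_component",
]

# poles with |arg z| at or below this are trend content, not oscillations
_TREND_ARG_TOL = 1e-6


@dataclass(frozen=True)
class PencilConfig:
    """Settings for one pencil decomposition.

    ``n_oscillations`` is the number of conjugate-pair components sought
    (M; three by default, the conventional depth for superimposed
    circadian + ultradian + shorter harmonics).  ``pencil_param`` is the
    Hankel shift parameter P; ``None`` selects floor(N/3), the standard
    noise-robust choice.  ``rank_tolerance`` is the relative singular-value
    cutoff below which the signal subspace is considered degenerate and
    fewer components are returned rather than fabricated ones.
    """

    n_oscillations: int = 3
    pencil_param: int | None = None
    include_dc: bool = True
    rank_tolerance: float = 1e-10

    def model_order(self) -> int:
        return 2 * self.n_oscillations + (1 if self.include_dc else 0)


@dataclass(frozen=True)
class OscillationComponent:
    """One damped sinusoid recovered from a conjugate pole pair.

    ``phase_h`` is the peak time of the *undamped* cosine after the grid
    origin, in hours, folded to ``[0, period_h)``; the decay-induced peak
    shift is carried separately by ``decay_per_h``.
    """

    period_h: float
    amplitude: float
    phase_h: float
    decay_per_h: float
    pole: complex
    residue: complex

    def evaluate(self, t_rel: np.ndarray) -> np.ndarray:
        """Evaluate the component at times ``t_rel`` (hours after t0)."""
        omega = 2.0 * np.pi / self.period_h
        return (
            self.amplitude
            * np.exp(self.decay_per_h * t_rel)
            * np.cos(omega * (t_rel - self.phase_h))
        )


@dataclass
class GeneDecomposition:
    """A gene's DC level, amplitude-ranked components, and residual.

    ``dc`` carries the constant level plus the grid-averaged content of
    any real (non-oscillatory) poles; ``residual_rms`` is the exact RMS
    difference between the input and ``reconstruct`` on the grid.
    """

    gene_id: str
    dc: float
    components: list[OscillationComponent]
    residual_rms: float
    grid: SamplingGrid


@dataclass(frozen=True)
class OscFilter:
    """Which components count as genuine oscillations.

    A component passes when its period lies between the Nyquist limit
    (twice the sampling step) and ``max_period_factor`` times the grid
    span, its decay magnitude is at most ``max_decay_per_h``, and its
    amplitude relative to ``max(dc, amp_floor)`` is at least
    ``min_rel_amp``.  ``amplitude_measure`` selects how amplitude is
    judged: ``"mid"`` (default) uses the decay-adjusted mid-series value
    ``A * exp(b * span/2)``, which represents the oscillation's typical
    swing over the record and demotes transient spikes whose t0
    coefficient is large only because they die immediately; ``"raw"``
    uses the coefficient A itself.  No principled amplitude or damping
    cutoff exists for real data, so all of these are configuration.
    """

    min_rel_amp: float = 0.1
    max_decay_per_h: float = 0.2
    max_period_factor: float = 1.0
    amp_floor: float = 1e-12
    amplitude_measure: str = "mid"

    def effective_amplitude(self, c: OscillationComponent, grid: SamplingGrid) -> float:
        if self.amplitude_measure == "raw":
            return c.amplitude
        if self.amplitude_measure == "mid":
            return c.amplitude * float(np.exp(c.decay_per_h * grid.span_h / 2.0))
        raise ValueError(f"unknown amplitude_measure {self.amplitude_measure!r}")

    def passes(self, c: OscillationComponent, grid: SamplingGrid, dc: float) -> bool:
        if not (2.0 * grid.step_h <= c.period_h <= self.max_period_factor * grid.span_h):
            return False
        if abs(c.decay_per_h) > self.max_decay_per_h:
            return False
        ref = max(abs(dc), self.amp_floor)
        return self.effective_amplitude(c, grid) / ref >= self.min_rel_amp


def _signal_poles(y: np.ndarray, p: int, k: int, rank_tol: float) -> np.ndarray:
    """Poles of the rank-k signal subspace of the Hankel pencil of y."""
    n = y.size
    # Hankel matrix H[i, j] = y[i + j], shape (n - p) x (p + 1)
    hank = scipy.linalg.hankel(y[: n - p], y[n - p - 1 :])
    u, s, vh = np.linalg.svd(hank, full_matrices=False)
    if s[0] == 0.0:  # identically zero series
        return np.empty(0, dtype=complex)
    k_eff = min(k, int(np.sum(s > rank_tol * s[0])))
    if k_eff == 0:
        return np.empty(0, dtype=complex)
    v = vh[:k_eff].conj().T  # (p + 1) x k_eff right singular vectors
    v1, v2 = v[:-1], v[1:]
    # eigenvalues of pinv(V1) V2 = pencil poles restricted to the signal subspace
    return np.linalg.eigvals(np.linalg.pinv(v1) @ v2)


def pencil_decompose(
    series: np.ndarray,
    grid: SamplingGrid,
    cfg: PencilConfig | None = None,
    gene_id: str = "",
) -> GeneDecomposition:
    """Decompose one series on ``grid`` into DC + damped sinusoids.

    Raises ``ValueError`` when the series is shorter than twice the model
    order (the pencil then cannot separate ``n_oscillations`` pairs; lower
    M), or when the series is non-finite or does not match the grid.
    """
    cfg = cfg or PencilConfig()
    y = np.asarray(series, dtype=float)
    if y.ndim != 1 or y.size != grid.n_points:
        raise ValueError(
            f"series has shape {y.shape}, expected ({grid.n_points},) matching the grid"
        )
    if not np.all(np.isfinite(y)):
        raise ValueError("series contains non-finite values")
    n = y.size
    k = cfg.model_order()
    if n < 2 * k:
        raise ValueError(
            f"series of length {n} cannot support model order {k} "
            f"(need N >= {2 * k}); lower n_oscillations"
        )
    p = cfg.pencil_param if cfg.pencil_param is not None else n // 3
    if not (k <= p <= n - k):
        raise ValueError(f"pencil_param {p} outside valid range [{k}, {n - k}]")

    poles = _signal_poles(y, p, k, cfg.rank_tolerance)
    if poles.size == 0:
        rec = np.zeros(n)
        return GeneDecomposition(gene_id, 0.0, [], _rms(y - rec), grid)

    # residues: least-squares solve of the Vandermonde system Z r = y
    vand = poles[np.newaxis, :] ** np.arange(n)[:, np.newaxis]
    residues, *_ = np.linalg.lstsq(vand, y.astype(complex), rcond=None)

    dc = 0.0
    comps: list[OscillationComponent] = []
    nn = np.arange(n)
    used = np.zeros(poles.size, dtype=bool)
    order = np.argsort(-np.abs(residues))  # greedy conjugate pairing, big first
    for idx in order:
        if used[idx]:
            continue
        z, r = poles[idx], residues[idx]
        if abs(np.angle(z)) <= _TREND_ARG_TOL or abs(z.imag) < 1e-12 * max(1.0, abs(z.real)):
            used[idx] = True
            # real pole: constant or drifting trend, summarised by its
            # grid-mean level (exactly r for z = 1)
            dc += float(np.mean((r * z**nn).real))
            continue
        # find the conjugate partner among unused poles
        partner = -1
        best = np.inf
        for jdx in range(poles.size):
            if jdx == idx or used[jdx]:
                continue
            d = abs(poles[jdx] - np.conj(z))
            if d < best:
                best, partner = d, jdx
        used[idx] = True
        if partner >= 0 and best <= 1e-6 * max(1.0, abs(z)):
            used[partner] = True
            # average the pair for numerical symmetry
            z = (z + np.conj(poles[partner])) / 2.0
            r = (r + np.conj(residues[partner])) / 2.0
        if z.imag < 0:
            z, r = np.conj(z), np.conj(r)
        omega = abs(np.angle(z))  # rad per sample
        period = 2.0 * np.pi * grid.step_h / omega
        amplitude = 2.0 * abs(r)
        decay = np.log(abs(z)) / grid.step_h if abs(z) > 0 else 0.0
        phase = (float(np.mod(-np.angle(r), 2.0 * np.pi)) * period) / (2.0 * np.pi)
        comps.append(
            OscillationComponent(
                period_h=float(period),
                amplitude=float(amplitude),
                phase_h=float(phase),
                decay_per_h=float(decay),
                pole=complex(z),
                residue=complex(r),
            )
        )

    comps.sort(key=lambda c: (-c.amplitude, c.period_h))
    d = GeneDecomposition(gene_id, float(dc), comps, 0.0, grid)
    d.residual_rms = _rms(y - reconstruct(d))
    return d


def reconstruct(d: GeneDecomposition) -> np.ndarray:
    """Evaluate DC + components on the decomposition's grid."""
    t_rel = d.grid.timepoints - d.grid.start_ct_h
    out = np.full(d.grid.n_points, d.dc, dtype=float)
    for c in d.components:
        out += c.evaluate(t_rel)
    return out


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x)))) if x.size else 0.0


def dominant_component(
    d: GeneDecomposition, osc_filter: OscFilter | None = None
) -> OscillationComponent | None:
    """Largest component passing the oscillation filter, judged by the
    filter's amplitude measure (identical to the raw coefficient whenever
    decay is zero).  Ties break toward the shorter period, then toward
    the earlier list position, so the choice is deterministic.
    """
    f = osc_filter or OscFilter()
    passing = [c for c in d.components if f.passes(c, d.grid, d.dc)]
    if not passing:
        return None
    return min(passing, key=lambda c: (-f.effective_amplitude(c, d.grid), c.period_h))
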