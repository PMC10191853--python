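"""Kok S-state bookkeeping and flash-to-transition deconvolution.

The oxygen-evolving complex of photosystem II cycles through four semi-stable
states S0..S3; each saturating flash advances a centre by one step with
probability ``1 - miss - double_hit``, fails to advance with probability
``miss`` (alpha) and advances twice with probability ``double_hit`` (beta).
O2 is released on the S3->S0 step, so a dark-adapted (pure S1) sample shows
maximal O2 yield on flash 3 with a damped period-4 oscillation thereafter.

Because misses mix transitions across flashes, flash-indexed data are a known
linear mixture of the four pure transition signals; :func:`deconvolve_transitions`
inverts that mixture by ordinary least squares using the expected transition
weights of the Markov model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import FlashSeriesDataset, TransitionSeries
from .exceptions import DeconvolutionError, ValidationError

_S3_TO_S0 = 3  # index of the O2-evolving transition in TRANSITIONS ordering


@dataclass(frozen=True)
class KokParameters:
    """Miss/double-hit parameters of the standard Kok model.

    ``initial_populations`` is over (S0, S1, S2, S3); the default is the
    dark-stable pure-S1 start enforced by pre-flash protocols.
    ``per_transition_miss`` optionally overrides the scalar miss with one
    value per current S-state.
    """

    miss: float = 0.1
    double_hit: float = 0.0
    initial_populations: tuple = (0.0, 1.0, 0.0, 0.0)
    per_transition_miss: tuple | None = None

    def __post_init__(self):
        a = np.asarray(self.misses, dtype=float)
        b = self.double_hit
        if np.any(a < 0) or b < 0:
            raise ValidationError("miss and double_hit must be nonnegative")
        if np.any(a + b > 1):
            raise ValidationError(
                f"miss + double_hit must not exceed 1 (got miss={a}, double_hit={b})"
            )
        p = np.asarray(self.initial_populations, dtype=float)
        if p.shape != (4,):
            raise ValidationError("initial_populations must have 4 entries (S0..S3)")
        if np.any(p < -1e-15):
            raise ValidationError("initial populations must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValidationError(
                f"initial populations must sum to 1 (got {p.sum()!r})"
            )

    @property
    def misses(self) -> np.ndarray:
        """Per-state miss probabilities (broadcast of the scalar if unset)."""
        if self.per_transition_miss is not None:
            m = np.asarray(self.per_transition_miss, dtype=float)
            if m.shape != (4,):
                raise ValidationError("per_transition_miss must have 4 entries")
            return m
        return np.full(4, float(self.miss))


def transition_matrix(params: KokParameters) -> np.ndarray:
    """Single-flash advancement matrix M with M[i, j] = P(S_i after | S_j before).

    Column-stochastic: stay with probability alpha_j, advance one step with
    1 - alpha_j - beta, advance two (double hit) with beta, indices cyclic
    mod 4 (S3 advances to S0, releasing O2).
    """
    a = params.misses
    b = params.double_hit
    m = np.zeros((4, 4))
    for j in range(4):
        m[j, j] = a[j]
        m[(j + 1) % 4, j] = 1.0 - a[j] - b
        m[(j + 2) % 4, j] = b
    return m


def propagate_states(params: KokParameters, n_flashes: int) -> np.ndarray:
    """S-state populations after 0..n_flashes flashes, shape (n_flashes+1, 4)."""
    if n_flashes < 0:
        raise ValidationError("n_flashes must be >= 0")
    m = transition_matrix(params)
    pops = np.empty((n_flashes + 1, 4))
    pops[0] = np.asarray(params.initial_populations, dtype=float)
    for n in range(n_flashes):
        pops[n + 1] = m @ pops[n]
    return pops


def transition_weights(params: KokParameters, n_flashes: int) -> np.ndarray:
    """Expected fraction of centres executing each transition on each flash.

    Returns W of shape (n_flashes, 4) ordered as TRANSITIONS; transition j is
    S_j -> S_{j+1 mod 4}.  A double hit from S_j executes two transitions
    (j and j+1) and both legs are credited, so
    ``W[n, j] = p_j * (1 - alpha_j) + p_{j-1} * beta`` with p the populations
    before flash n.
    """
    if n_flashes < 1:
        raise ValidationError("n_flashes must be >= 1")
    a = params.misses
    b = params.double_hit
    pops = propagate_states(params, n_flashes)
    before = pops[:-1]  # populations before each flash
    w = np.empty((n_flashes, 4))
    for j in range(4):
        w[:, j] = before[:, j] * (1.0 - a[j]) + before[:, (j - 1) % 4] * b
    return w


def o2_yield_pattern(
    params: KokParameters, n_flashes: int, normalized: bool = False
) -> np.ndarray:
    """Per-flash O2 yield = weight of the S3->S0 transition on each flash.

    With ``normalized=True`` yields are divided by the steady-state mean
    yield (1 - alpha + beta)/4 of the scalar-miss chain, so the damped
    period-4 oscillation converges to 1.
    """
    w = transition_weights(params, n_flashes)
    y = w[:, _S3_TO_S0]
    if normalized:
        mean = (1.0 - float(np.mean(params.misses)) + params.double_hit) / 4.0
        y = y / mean
    return y


def deconvolve_transitions(
    dataset: FlashSeriesDataset,
    weights: np.ndarray,
    cond_max: float = 1e8,
) -> TransitionSeries:
    """Least-squares unmixing of flash-indexed data into pure transitions.

    Solves, independently for every (time, wavenumber) cell but through one
    shared pseudo-inverse, ``data[n] ~ sum_j W[n, j] * transition_j``.  Exact
    when the data were synthesized with the same weights.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[1] != 4:
        raise DeconvolutionError(f"weight matrix must be (n_flashes, 4), got {w.shape}")
    if w.shape[0] != dataset.n_flashes:
        raise DeconvolutionError(
            f"weight matrix rows ({w.shape[0]}) != dataset flashes "
            f"({dataset.n_flashes})"
        )
    if dataset.n_flashes < 4:
        raise DeconvolutionError("deconvolution needs at least 4 flashes")
    if np.linalg.matrix_rank(w) < 4:
        raise DeconvolutionError(
            "weight matrix is rank-deficient; choose Kok parameters that "
            "spread transitions across flashes"
        )
    cond = np.linalg.cond(w)
    if cond > cond_max:
        raise DeconvolutionError(
            f"weight matrix condition number {cond:.3g} exceeds {cond_max:.3g}; "
            "deconvolution would amplify noise — adjust Kok parameters"
        )
    n_flashes, n_t, n_wn = dataset.data.shape
    flat = dataset.data.reshape(n_flashes, -1)
    solution, *_ = np.linalg.lstsq(w, flat, rcond=None)
    residual = flat - w @ solution
    return TransitionSeries(
        data=solution.reshape(4, n_t, n_wn),
        time=dataset.time,
        wavenumbers=dataset.wavenumbers,
        residual_norm=float(np.linalg.norm(residual)),
        condition_number=float(cond),
    )
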