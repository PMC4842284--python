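"""Recovery of a moiety MID from a parent/sub-fragment pair by deconvolution.

The parent fragment's distribution is the convolution of the known
sub-fragment (e.g. aspartyl) distribution with the unknown complementary
moiety (e.g. acetamido) distribution.  Writing the convolution as a banded
linear system — column k of the design matrix is the known vector shifted
down by k — the moiety MID is the nonnegative weighted-least-squares
solution, optionally followed by natural-abundance correction when the
system was populated with raw spectral intensities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import nnls

from .core import MID, DataError, FragmentMeasurement, normalize_mid
from .isotopes import (
    DEFAULT_ISOTOPE_TABLE,
    ElementalFormula,
    IsotopeTable,
    correct_natural_abundance,
)

__all__ = [
    "ConvolutionSystem",
    "DeconvolutionResult",
    "build_convolution_system",
    "solve_complementary_mid",
    "deconvolve_moiety",
]


@dataclass(frozen=True)
class ConvolutionSystem:
    """Banded linear system ``design @ x = observation`` for an unknown moiety."""

    design: np.ndarray  # (p, q)
    observation: np.ndarray  # (p,)
    weights: np.ndarray  # (p,) positive

    def __post_init__(self) -> None:
        design = np.asarray(self.design, dtype=float)
        obs = np.asarray(self.observation, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if design.ndim != 2 or design.shape[1] < 1:
            raise ValueError("design must be a p x q matrix with q >= 1")
        if obs.shape != (design.shape[0],) or w.shape != obs.shape:
            raise ValueError("observation/weights must match design rows")
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
        object.__setattr__(self, "design", design)
        object.__setattr__(self, "observation", obs)
        object.__setattr__(self, "weights", w)

    @property
    def p(self) -> int:
        return self.design.shape[0]

    @property
    def q(self) -> int:
        return self.design.shape[1]


@dataclass(frozen=True)
class DeconvolutionResult:
    mid: MID
    residual_norm: float
    stderr: tuple[float, ...]
    used_raw_intensities: bool = False
    na_corrected: bool = False


def build_convolution_system(
    parent: Sequence[float],
    known_moiety: Sequence[float],
    weights: Sequence[float] | None = None,
) -> ConvolutionSystem:
    """Assemble the shifted-column design from the known moiety vector.

    ``q = len(parent) - len(known_moiety) + 1`` unknowns; default weights are
    ``1 / max(obs_i, eps)`` with ``eps = 1e-3 * max(parent)``, approximating
    intensity-proportional variance.
    """
    obs = np.asarray(list(parent), dtype=float)
    known = np.asarray(list(known_moiety), dtype=float)
    if obs.size < known.size:
        raise ValueError(
            f"parent vector (len {obs.size}) shorter than known moiety "
            f"(len {known.size})"
        )
    q = obs.size - known.size + 1
    design = np.zeros((obs.size, q))
    for k in range(q):
        design[k : k + known.size, k] = known
    if weights is None:
        eps = 1e-3 * float(np.max(obs)) if np.max(obs) > 0 else 1e-12
        w = 1.0 / np.maximum(obs, eps)
    else:
        w = np.asarray(list(weights), dtype=float)
    return ConvolutionSystem(design=design, observation=obs, weights=w)


def solve_complementary_mid(sys: ConvolutionSystem) -> DeconvolutionResult:
    """Weighted nonnegative least squares for the unknown moiety MID.

    Minimizes ``sum_i w_i (obs_i - (C x)_i)^2`` subject to ``x >= 0``, then
    renormalizes x to unit sum.  Standard errors come from the weighted
    normal-equations covariance scaled by the residual variance.
    """
    if np.linalg.matrix_rank(sys.design) < sys.q:
        raise DataError(
            "rank-deficient convolution system; a longer parent vector is needed"
        )
    sqrt_w = np.sqrt(sys.weights)
    aw = sys.design * sqrt_w[:, None]
    bw = sys.observation * sqrt_w
    x, rnorm = nnls(aw, bw)

    dof = max(sys.p - sys.q, 1)
    sigma2 = rnorm**2 / dof
    try:
        cov = sigma2 * np.linalg.inv(aw.T @ aw)
        raw_stderr = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:  # pragma: no cover
        raw_stderr = np.full(sys.q, np.nan)
    total = x.sum()
    if total <= 0:
        raise DataError("deconvolution produced an all-zero moiety vector")
    return DeconvolutionResult(
        mid=normalize_mid(x),
        residual_norm=float(rnorm),
        stderr=tuple(raw_stderr / total),
    )


def deconvolve_moiety(
    parent_frag: FragmentMeasurement,
    sub_frag: FragmentMeasurement,
    moiety_formula: ElementalFormula | None = None,
    isotope_table: IsotopeTable = DEFAULT_ISOTOPE_TABLE,
    weights: Sequence[float] | None = None,
) -> DeconvolutionResult:
    """Deconvolve the moiety by which a parent and sub-fragment differ.

    When both fragments carry raw spectral intensities the system is
    populated with them (known column vector = the sub-fragment's raw
    pattern at unit sum) and the solved MID is corrected for natural isotope
    abundance using ``moiety_formula``; otherwise the corrected MIDs are used
    directly and no further correction is applied.
    """
    use_raw = (
        parent_frag.raw_intensities is not None
        and sub_frag.raw_intensities is not None
    )
    if use_raw:
        parent_vec = np.asarray(parent_frag.raw_intensities, dtype=float)
        known_vec = np.asarray(sub_frag.raw_intensities, dtype=float)
        if known_vec.sum() <= 0:
            raise DataError("sub-fragment raw intensities are all zero")
        known_vec = known_vec / known_vec.sum()
    else:
        if parent_frag.mid is None or sub_frag.mid is None:  # pragma: no cover
            raise DataError("fragments carry neither raw intensities nor MIDs")
        parent_vec = parent_frag.mid.as_array()
        known_vec = sub_frag.mid.as_array()

    system = build_convolution_system(parent_vec, known_vec, weights)
    result = solve_complementary_mid(system)
    na_corrected = False
    if use_raw and moiety_formula is not None:
        corrected = correct_natural_abundance(
            result.mid.abundances, moiety_formula, isotope_table
        )
        result = DeconvolutionResult(
            mid=corrected,
            residual_norm=result.residual_norm,
            stderr=result.stderr,
        )
        na_corrected = True
    return DeconvolutionResult(
        mid=result.mid,
        residual_norm=result.residual_norm,
        stderr=result.stderr,
        used_raw_intensities=use_raw,
        na_corrected=na_corrected,
    )
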