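"""Isotopologue vector algebra.

Convolution of mass isotopomer distributions, theoretical natural-abundance
envelopes from elemental formulas, and correction of measured distributions
for natural isotope abundance by the standard correction-matrix method
(solved with nonnegative least squares for robustness to small negatives).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import nnls

from .core import MID, DataError, normalize_mid

__all__ = [
    "ElementalFormula",
    "IsotopeTable",
    "DEFAULT_ISOTOPE_TABLE",
    "convolve_mids",
    "natural_abundance_envelope",
    "correction_matrix",
    "correct_natural_abundance",
]

_TAIL_EPS = 1e-9


@dataclass(frozen=True)
class ElementalFormula:
    """Atom counts of a fragment ion plus the tracer backbone description.

    ``tracer_atoms`` counts the positions that can carry tracer label; these
    are excluded from the natural-abundance envelope used for correction.
    """

    counts: Mapping[str, int]
    tracer_element: str = "C"
    tracer_atoms: int = 0

    def __post_init__(self) -> None:
        counts = {k: int(v) for k, v in self.counts.items()}
        if any(v < 0 for v in counts.values()):
            raise ValueError("atom counts must be nonnegative")
        if self.tracer_atoms < 0:
            raise ValueError("tracer_atoms must be nonnegative")
        if self.tracer_atoms > counts.get(self.tracer_element, 0):
            raise ValueError(
                f"tracer_atoms={self.tracer_atoms} exceeds "
                f"{self.tracer_element} count {counts.get(self.tracer_element, 0)}"
            )
        object.__setattr__(self, "counts", counts)

    def non_tracer_counts(self) -> dict[str, int]:
        out = {k: v for k, v in self.counts.items() if v > 0}
        if self.tracer_atoms:
            out[self.tracer_element] = out.get(self.tracer_element, 0) - self.tracer_atoms
            if out[self.tracer_element] == 0:
                del out[self.tracer_element]
        return out


@dataclass(frozen=True)
class IsotopeTable:
    """Per-element isotope patterns as (mass shift, abundance) lists."""

    elements: Mapping[str, Sequence[tuple[int, float]]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        table: dict[str, tuple[tuple[int, float], ...]] = {}
        for sym, entries in self.elements.items():
            entries = tuple((int(s), float(a)) for s, a in entries)
            total = sum(a for _, a in entries)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"abundances of {sym} sum to {total}, expected 1"
                )
            if any(a < 0 or a > 1 for _, a in entries):
                raise ValueError(f"abundances of {sym} outside [0, 1]")
            table[sym] = entries
        object.__setattr__(self, "elements", table)

    def atom_distribution(self, element: str) -> np.ndarray:
        """Mass-shift distribution of a single atom as a dense vector."""
        if element not in self.elements:
            raise KeyError(f"element {element!r} not in isotope table")
        entries = self.elements[element]
        vec = np.zeros(max(s for s, _ in entries) + 1)
        for shift, abund in entries:
            vec[shift] += abund
        return vec

    @classmethod
    def from_config(cls, mapping: Mapping[str, Sequence[Sequence[float]]]) -> "IsotopeTable":
        return cls(
            {sym: [(int(s), float(a)) for s, a in rows] for sym, rows in mapping.items()}
        )


# Heavy-isotope fractions; silicon matters for trimethylsilyl derivatives.
DEFAULT_ISOTOPE_TABLE = IsotopeTable(
    {
        "C": [(0, 1 - 0.0107), (1, 0.0107)],
        "H": [(0, 1 - 0.000115), (1, 0.000115)],
        "N": [(0, 1 - 0.00364), (1, 0.00364)],
        "O": [(0, 1 - 0.00038 - 0.00205), (1, 0.00038), (2, 0.00205)],
        "Si": [(0, 1 - 0.04685 - 0.03092), (1, 0.04685), (2, 0.03092)],
        "S": [(0, 1 - 0.0075 - 0.0425), (1, 0.0075), (2, 0.0425)],
    }
)


def convolve_mids(a: MID | Sequence[float], b: MID | Sequence[float]) -> MID:
    """Cauchy product of two MIDs: the distribution of the combined molecule."""
    va = a.as_array() if isinstance(a, MID) else np.asarray(a, dtype=float)
    vb = b.as_array() if isinstance(b, MID) else np.asarray(b, dtype=float)
    return MID(tuple(np.convolve(va, vb)))


def natural_abundance_envelope(
    formula: ElementalFormula | Mapping[str, int],
    table: IsotopeTable = DEFAULT_ISOTOPE_TABLE,
    *,
    exclude_tracer: bool = False,
) -> MID:
    """Theoretical isotopologue pattern of a molecule at natural abundance.

    The envelope is the convolution of single-atom distributions; the
    vanishing heavy tail (cumulative < 1e-9) is truncated and the result
    renormalized.  With ``exclude_tracer`` the tracer backbone positions are
    left out, giving the envelope used to build the correction matrix.
    """
    if isinstance(formula, ElementalFormula):
        counts = formula.non_tracer_counts() if exclude_tracer else dict(formula.counts)
    else:
        counts = dict(formula)
    env = np.array([1.0])
    for element, n in sorted(counts.items()):
        if n == 0:
            continue
        atom = table.atom_distribution(element)  # raises on unknown element
        if atom.size == 1:
            continue
        # exponentiation by repeated squaring keeps this O(log n) convolutions
        power = atom
        k = n
        while k:
            if k & 1:
                env = np.convolve(env, power)
            k >>= 1
            if k:
                power = np.convolve(power, power)
    tail = np.cumsum(env[::-1])[::-1]
    keep = int(np.searchsorted(-tail, -_TAIL_EPS))
    env = env[: max(keep, 1)]
    return MID(tuple(env / env.sum()))


def correction_matrix(
    envelope: MID, n_measured: int, n_unknowns: int
) -> np.ndarray:
    """Lower-triangular design whose column k is the envelope shifted by k."""
    env = envelope.as_array()
    mat = np.zeros((n_measured, n_unknowns))
    for k in range(n_unknowns):
        stop = min(n_measured, k + env.size)
        mat[k:stop, k] = env[: stop - k]
    return mat


def correct_natural_abundance(
    measured: Sequence[float],
    formula: ElementalFormula,
    table: IsotopeTable = DEFAULT_ISOTOPE_TABLE,
) -> MID:
    """Remove the natural-isotope contribution from a measured distribution.

    Solves ``C x = measured`` where C is the correction matrix built from the
    natural envelope of the non-tracer atoms, restricted to
    ``tracer_atoms + 1`` unknowns, by nonnegative least squares; the solution
    is renormalized to an MID.
    """
    obs = np.asarray(list(measured), dtype=float)
    if obs.size < 1:
        raise DataError("measured vector must have at least one entry")
    envelope = natural_abundance_envelope(formula, table, exclude_tracer=True)
    n_unknowns = min(formula.tracer_atoms + 1, obs.size)
    mat = correction_matrix(envelope, obs.size, n_unknowns)
    cond = np.linalg.cond(mat)
    if cond > 1e8:
        warnings.warn(
            f"correction matrix ill-conditioned (cond={cond:.3g})", stacklevel=2
        )
    x, _ = nnls(mat, obs)
    return normalize_mid(x)
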