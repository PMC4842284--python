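"""Exact positional-isotopomer simulation of tracer propagation.

Small metabolic networks are described by compounds (tracer-atom counts),
reactions with explicit atom maps (transfer, condensation, cleavage) and
per-compound mixing fractions over producing reactions.  The simulator
iterates the induced linear map to its fixed point over full positional
labeling distributions (2^n states per compound, n capped at 12), which is
exact at isotopic steady state, and emits fragment MIDs — optionally with a
natural-abundance envelope folded into raw intensities and Gaussian
measurement noise — as a :class:`~midflux.core.LabelingDataset` together
with the ground truth.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from .core import (
    MID,
    CompoundRecord,
    FragmentMeasurement,
    LabelingDataset,
    normalize_mid,
)
from .isotopes import (
    DEFAULT_ISOTOPE_TABLE,
    ElementalFormula,
    IsotopeTable,
    convolve_mids,
    natural_abundance_envelope,
)

__all__ = [
    "NetworkModel",
    "Reaction",
    "FragmentSpec",
    "ModelError",
    "compile_model",
    "load_model",
    "simulate_labeling",
    "fragment_mid",
    "generate_dataset",
]

MAX_ATOMS = 12

REACTION_TYPES = ("transfer", "condensation", "cleavage")


class ModelError(ValueError):
    """The network description violates a structural invariant."""


@dataclass(frozen=True)
class Reaction:
    """One reaction: substrate atom maps onto the atoms of a single product."""

    reaction_id: str
    product: str
    # per substrate: (compound, {substrate atom -> product atom})
    substrates: tuple[tuple[str, Mapping[int, int]], ...]
    reaction_type: str = "transfer"

    def __post_init__(self) -> None:
        if self.reaction_type not in REACTION_TYPES:
            raise ModelError(
                f"reaction {self.reaction_id!r}: unknown type "
                f"{self.reaction_type!r}"
            )
        object.__setattr__(
            self,
            "substrates",
            tuple(
                (comp, dict(amap)) for comp, amap in self.substrates
            ),
        )


@dataclass(frozen=True)
class FragmentSpec:
    mz: int
    atoms: tuple[int, ...]
    formula: ElementalFormula | None = None


@dataclass
class NetworkModel:
    """Validated simulator description of compounds, reactions and mixing."""

    compounds: dict[str, int]  # name -> tracer atom count
    reactions: dict[str, Reaction]
    mixing: dict[str, list[tuple[str, float]]]  # product -> [(reaction, frac)]
    sources: dict[str, dict[str, float]]  # compound -> {bitstring: prob}
    tracers: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)
    fragments: dict[str, list[FragmentSpec]] = field(default_factory=dict)

    def source_distribution(
        self, compound: str, overrides: Mapping[str, dict[str, float]] | None = None
    ) -> np.ndarray:
        spec = dict(self.sources.get(compound, {}))
        if overrides and compound in overrides:
            spec = dict(overrides[compound])
        n = self.compounds[compound]
        vec = np.zeros(2**n)
        if not spec:
            vec[0] = 1.0
            return vec
        for pattern, prob in spec.items():
            if len(pattern) != n or set(pattern) - {"0", "1"}:
                raise ModelError(
                    f"source pattern {pattern!r} invalid for {compound!r} "
                    f"({n} atoms)"
                )
            idx = sum(1 << i for i, ch in enumerate(pattern) if ch == "1")
            vec[idx] += float(prob)
        if abs(vec.sum() - 1.0) > 1e-9:
            raise ModelError(
                f"source distribution of {compound!r} sums to {vec.sum()}"
            )
        return vec


def _validate(model: NetworkModel) -> None:
    for name, n in model.compounds.items():
        if not (1 <= n <= MAX_ATOMS):
            raise ModelError(
                f"compound {name!r}: atom count {n} outside [1, {MAX_ATOMS}]"
            )
    for rxn in model.reactions.values():
        if rxn.product not in model.compounds:
            raise ModelError(
                f"reaction {rxn.reaction_id!r}: dangling product {rxn.product!r}"
            )
        covered: set[int] = set()
        n_prod = model.compounds[rxn.product]
        for comp, amap in rxn.substrates:
            if comp not in model.compounds:
                raise ModelError(
                    f"reaction {rxn.reaction_id!r}: dangling substrate {comp!r}"
                )
            n_sub = model.compounds[comp]
            for sub_atom, prod_atom in amap.items():
                if not (0 <= sub_atom < n_sub):
                    raise ModelError(
                        f"reaction {rxn.reaction_id!r}: substrate atom "
                        f"{sub_atom} outside {comp!r}"
                    )
                if not (0 <= prod_atom < n_prod):
                    raise ModelError(
                        f"reaction {rxn.reaction_id!r}: product atom "
                        f"{prod_atom} outside {rxn.product!r}"
                    )
                if prod_atom in covered:
                    raise ModelError(
                        f"reaction {rxn.reaction_id!r}: product atom "
                        f"{prod_atom} mapped twice (atom map not a bijection)"
                    )
                covered.add(prod_atom)
        if covered != set(range(n_prod)):
            raise ModelError(
                f"reaction {rxn.reaction_id!r}: product atoms "
                f"{sorted(set(range(n_prod)) - covered)} unmapped"
            )
    for compound in model.compounds:
        if compound in model.sources:
            continue
        producers = model.mixing.get(compound, [])
        if not producers:
            raise ModelError(
                f"compound {compound!r} has no producing reaction and is not "
                "a source"
            )
        total = sum(frac for _, frac in producers)
        if abs(total - 1.0) > 1e-9:
            raise ModelError(
                f"mixing fractions of {compound!r} sum to {total}, expected 1"
            )
        for rid, frac in producers:
            if rid not in model.reactions:
                raise ModelError(
                    f"mixing of {compound!r} references unknown reaction {rid!r}"
                )
            if model.reactions[rid].product != compound:
                raise ModelError(
                    f"reaction {rid!r} does not produce {compound!r}"
                )
            if not (0.0 <= frac <= 1.0):
                raise ModelError(
                    f"mixing fraction {frac} of {compound!r} outside [0, 1]"
                )


def compile_model(spec: Mapping) -> NetworkModel:
    """Build and validate a :class:`NetworkModel` from a parsed description."""
    compounds = {str(k): int(v) for k, v in (spec.get("compounds") or {}).items()}
    reactions: dict[str, Reaction] = {}
    for entry in spec.get("reactions") or []:
        rid = str(entry["id"])
        if rid in reactions:
            raise ModelError(f"duplicate reaction id {rid!r}")
        subs = tuple(
            (
                str(s["compound"]),
                {int(a): int(b) for a, b in (s.get("map") or {}).items()},
            )
            for s in entry.get("substrates") or []
        )
        reactions[rid] = Reaction(
            reaction_id=rid,
            product=str(entry["product"]),
            substrates=subs,
            reaction_type=str(entry.get("type", "transfer")),
        )
    mixing: dict[str, list[tuple[str, float]]] = {}
    for compound, entries in (spec.get("mixing") or {}).items():
        mixing[str(compound)] = [
            (str(e["reaction"]), float(e["fraction"])) for e in entries
        ]
    # single-producer compounds get an implicit fraction of 1
    for rid, rxn in reactions.items():
        if rxn.product not in mixing:
            producers = [
                r for r in reactions.values() if r.product == rxn.product
            ]
            if len(producers) == 1:
                mixing[rxn.product] = [(rid, 1.0)]
    sources: dict[str, dict[str, float]] = {}
    for compound, dist in (spec.get("sources") or {}).items():
        sources[str(compound)] = _parse_source(dist)
    tracers: dict[str, dict[str, dict[str, float]]] = {}
    for label, per_compound in (spec.get("tracers") or {}).items():
        tracers[str(label)] = {
            str(c): _parse_source(d) for c, d in per_compound.items()
        }
    fragments: dict[str, list[FragmentSpec]] = {}
    for compound, frags in (spec.get("fragments") or {}).items():
        fragments[str(compound)] = [
            FragmentSpec(
                mz=int(f["mz"]),
                atoms=tuple(int(a) for a in f["atoms"]),
                formula=_parse_fragment_formula(f),
            )
            for f in frags
        ]
    model = NetworkModel(
        compounds=compounds,
        reactions=reactions,
        mixing=mixing,
        sources=sources,
        tracers=tracers,
        fragments=fragments,
    )
    _validate(model)
    return model


def _parse_source(dist) -> dict[str, float]:
    if isinstance(dist, str):
        if dist.lower() == "unlabeled":
            return {}
        raise ModelError(f"unrecognized source distribution {dist!r}")
    return {str(pattern): float(p) for pattern, p in (dist or {}).items()}


def _parse_fragment_formula(entry) -> ElementalFormula | None:
    from .core import parse_formula

    text = entry.get("formula")
    if not text:
        return None
    return ElementalFormula(
        counts=parse_formula(str(text)),
        tracer_element=str(entry.get("tracer_element", "C")),
        tracer_atoms=int(entry.get("tracer_atoms", len(entry["atoms"]))),
    )


def load_model(path) -> NetworkModel:
    with open(path) as fh:
        return compile_model(yaml.safe_load(fh))


def _induced_distribution(
    model: NetworkModel, rxn: Reaction, state: Mapping[str, np.ndarray]
) -> np.ndarray:
    """Push substrate distributions through a reaction's atom map.

    Substrate labelings are treated as independent, so the product
    distribution is the (atom-permuted) outer product of per-substrate
    marginals over their mapped atoms.
    """
    n_prod = model.compounds[rxn.product]
    factors: list[dict[int, float]] = []
    for comp, amap in rxn.substrates:
        dist = state[comp]
        marg: dict[int, float] = {}
        for s_idx, prob in enumerate(dist):
            if prob == 0.0:
                continue
            key = 0
            for sub_atom, prod_atom in amap.items():
                if (s_idx >> sub_atom) & 1:
                    key |= 1 << prod_atom
            marg[key] = marg.get(key, 0.0) + float(prob)
        factors.append(marg)
    out = np.zeros(2**n_prod)
    for combo in itertools.product(*(f.items() for f in factors)):
        mask = 0
        prob = 1.0
        for key, p in combo:
            mask |= key
            prob *= p
        out[mask] += prob
    return out


def simulate_labeling(
    model: NetworkModel,
    source_overrides: Mapping[str, dict[str, float]] | None = None,
    mixing_overrides: Mapping[str, Sequence[tuple[str, float]]] | None = None,
    max_iter: int = 10000,
    tol: float = 1e-10,
) -> dict[str, np.ndarray]:
    """Fixed point of the label-propagation map (Jacobi iteration).

    Each compound's positional distribution is the mixing-fraction combination
    of the distributions induced by its producing reactions; iteration starts
    from the unlabeled state and stops when the maximal absolute change drops
    below ``tol``.  Returns compound -> probability vector over 2^n labelings.
    """
    mixing = dict(model.mixing)
    if mixing_overrides:
        for compound, entries in mixing_overrides.items():
            entries = [(str(r), float(f)) for r, f in entries]
            total = sum(f for _, f in entries)
            if abs(total - 1.0) > 1e-9:
                raise ModelError(
                    f"override mixing of {compound!r} sums to {total}"
                )
            mixing[compound] = entries

    state: dict[str, np.ndarray] = {}
    for compound, n in model.compounds.items():
        if compound in model.sources or (
            source_overrides and compound in source_overrides
        ):
            state[compound] = model.source_distribution(
                compound, source_overrides
            )
        else:
            vec = np.zeros(2**n)
            vec[0] = 1.0
            state[compound] = vec

    source_names = set(model.sources) | set(source_overrides or {})
    for _ in range(max_iter):
        new_state = dict(state)
        residual = 0.0
        for compound in model.compounds:
            if compound in source_names:
                continue
            acc = np.zeros_like(state[compound])
            for rid, frac in mixing[compound]:
                if frac == 0.0:
                    continue
                acc += frac * _induced_distribution(
                    model, model.reactions[rid], state
                )
            residual = max(residual, float(np.abs(acc - state[compound]).max()))
            new_state[compound] = acc
        state = new_state
        if residual < tol:
            return state
    raise ModelError(
        f"label propagation did not converge in {max_iter} iterations "
        f"(residual {residual:.3g})"
    )


def fragment_mid(
    state: Mapping[str, np.ndarray], compound: str, atom_subset: Sequence[int]
) -> MID:
    """Marginalize a positional distribution onto a fragment's atom subset.

    Isotopomer probabilities are aggregated by the number of labeled atoms in
    the subset, giving a MID of length ``len(subset) + 1``.
    """
    dist = state[compound]
    atoms = sorted(set(int(a) for a in atom_subset))
    if not atoms:
        return MID((1.0,))
    n = int(np.log2(dist.size))
    if atoms[-1] >= n:
        raise ValueError(f"atom {atoms[-1]} outside compound {compound!r}")
    out = np.zeros(len(atoms) + 1)
    for idx, prob in enumerate(dist):
        if prob == 0.0:
            continue
        k = sum((idx >> a) & 1 for a in atoms)
        out[k] += prob
    return MID(tuple(out / out.sum()))


def _default_fragments(compound: str, n_atoms: int) -> list[FragmentSpec]:
    base_mz = 100 + 15 * n_atoms
    frags = [FragmentSpec(mz=base_mz, atoms=tuple(range(n_atoms)))]
    if n_atoms >= 2:
        frags.append(
            FragmentSpec(mz=base_mz - 15, atoms=tuple(range(1, n_atoms)))
        )
    return frags


@dataclass
class GroundTruth:
    """Exact MIDs and mixing fractions behind a generated dataset."""

    # (condition, tracer) -> compound -> fragment mz -> MID
    mids: dict[tuple[str, str], dict[str, dict[int, MID]]]
    mixing: dict[str, dict[str, list[tuple[str, float]]]]  # condition -> ...


def generate_dataset(
    model: NetworkModel,
    conditions: Sequence[tuple[str, Mapping[str, Sequence[tuple[str, float]]]]],
    tracers: Sequence[str],
    noise_sd: float = 0.0,
    natural_abundance: bool = False,
    replicates: int = 1,
    seed: int = 0,
    isotope_table: IsotopeTable = DEFAULT_ISOTOPE_TABLE,
) -> tuple[LabelingDataset, GroundTruth]:
    """Simulate every condition x tracer and emit a measurement dataset.

    ``conditions`` pairs a label with mixing-fraction overrides; ``tracers``
    names entries of ``model.tracers``.  Gaussian noise of ``noise_sd`` is
    added per replicate on the abundance scale (clamped, renormalized); with
    ``natural_abundance`` raw intensities are emitted as the MID convolved
    with the fragment formula's non-tracer envelope times a random total
    intensity.  Deterministic under a fixed seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    dataset = LabelingDataset()
    truth = GroundTruth(mids={}, mixing={})
    for cond_label, overrides in conditions:
        truth.mixing[cond_label] = {
            comp: [(r, float(f)) for r, f in entries]
            for comp, entries in (overrides or {}).items()
        }
        for tracer in tracers:
            if tracer not in model.tracers:
                raise ModelError(f"unknown tracer {tracer!r}")
            state = simulate_labeling(
                model,
                source_overrides=model.tracers[tracer],
                mixing_overrides=overrides,
            )
            slot: dict[str, dict[int, MID]] = {}
            truth.mids[(cond_label, tracer)] = slot
            for compound, n_atoms in model.compounds.items():
                specs = model.fragments.get(
                    compound, _default_fragments(compound, n_atoms)
                )
                slot[compound] = {
                    fs.mz: fragment_mid(state, compound, fs.atoms)
                    for fs in specs
                }
                for rep in range(1, replicates + 1):
                    frags = []
                    for fs in specs:
                        true_mid = slot[compound][fs.mz]
                        noisy = true_mid.as_array()
                        if noise_sd > 0:
                            noisy = noisy + rng.normal(
                                0.0, noise_sd, size=noisy.size
                            )
                        noisy = np.clip(noisy, 0.0, None)
                        if noisy.sum() <= 0:
                            noisy = true_mid.as_array()
                        noisy = noisy / noisy.sum()
                        raw = None
                        if natural_abundance:
                            if fs.formula is not None:
                                envelope = natural_abundance_envelope(
                                    fs.formula,
                                    isotope_table,
                                    exclude_tracer=True,
                                )
                                pattern = convolve_mids(
                                    MID(tuple(noisy)), envelope
                                ).as_array()
                            else:
                                pattern = noisy
                            total = rng.uniform(1e5, 1e6)
                            raw = tuple(pattern * total)
                        r2 = 1.0 if noise_sd == 0 else float(
                            np.clip(1.0 - abs(rng.normal(0.0, noise_sd)), 0.0, 1.0)
                        )
                        frags.append(
                            FragmentMeasurement(
                                fragment_mz=fs.mz,
                                mid=MID(tuple(noisy)),
                                r2=r2,
                                formula=(
                                    fs.formula.counts if fs.formula else None
                                ),
                                raw_intensities=raw,
                            )
                        )
                    dataset.add(
                        cond_label,
                        tracer,
                        rep,
                        CompoundRecord(
                            compound_id=compound,
                            name=compound,
                            fragments=tuple(frags),
                        ),
                    )
    return dataset, truth


def total_mid(state: Mapping[str, np.ndarray], compound: str) -> MID:
    """Whole-molecule MID: isotopomer probabilities aggregated by label count."""
    dist = state[compound]
    n = int(np.log2(dist.size))
    return fragment_mid(state, compound, range(n))
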