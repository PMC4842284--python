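"""Domain types and canonical tab-separated I/O for labeling datasets.

The central object is the :class:`LabelingDataset`, a container of per-compound
fragment measurements keyed by experimental condition, isotopic tracer and
replicate.  All pipeline stages (QC filtering, variation ranking, similarity
networks, moiety deconvolution) consume and/or produce this type, and the
canonical TSV schema defined in :func:`read_mid_table` / :func:`write_mid_table`
is its on-disk form.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MID",
    "FragmentMeasurement",
    "CompoundRecord",
    "LabelingDataset",
    "SimilarityNetwork",
    "DataError",
    "SchemaError",
    "normalize_mid",
    "mean_mid",
    "read_mid_table",
    "write_mid_table",
]

#: Most negative abundance tolerated as a natural-abundance-correction artifact.
NEGATIVE_TOLERANCE = -0.02


class SchemaError(ValueError):
    """The input table does not match the canonical column schema."""


class DataError(ValueError):
    """The input table is schema-valid but contains inconsistent data."""


@dataclass(frozen=True)
class MID:
    """A mass isotopomer distribution: relative abundances of M0..Mn.

    Abundances are stored exactly as given (small negatives from upstream
    correction are tolerated down to ``-0.02`` and flagged); use
    :meth:`normalized` to obtain a clamped unit-sum vector.
    """

    abundances: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.abundances) < 1:
            raise ValueError("MID must have at least one abundance")
        abund = tuple(float(a) for a in self.abundances)
        for j, a in enumerate(abund):
            if a < NEGATIVE_TOLERANCE:
                raise ValueError(
                    f"abundance M{j}={a} below tolerance {NEGATIVE_TOLERANCE}"
                )
        object.__setattr__(self, "abundances", abund)

    def __len__(self) -> int:
        return len(self.abundances)

    def __iter__(self) -> Iterator[float]:
        return iter(self.abundances)

    def __getitem__(self, j: int) -> float:
        return self.abundances[j]

    @property
    def has_negative(self) -> bool:
        """True when any abundance is a (tolerated) negative artifact."""
        return any(a < 0 for a in self.abundances)

    @property
    def abs_sum(self) -> float:
        """Sum of absolute abundances of the vector as read (pre-clamping)."""
        return float(np.abs(np.asarray(self.abundances)).sum())

    @property
    def m0(self) -> float:
        return self.abundances[0]

    @property
    def enrichment(self) -> float:
        """Fractional enrichment 1 - M0."""
        return 1.0 - self.abundances[0]

    def normalized(self) -> "MID":
        return normalize_mid(self.abundances)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.abundances, dtype=float)

    def padded(self, length: int) -> "MID":
        """Zero-pad on the heavy side to ``length`` (no-op if already longer)."""
        if len(self) >= length:
            return self
        return MID(self.abundances + (0.0,) * (length - len(self)))


def normalize_mid(raw: Sequence[float]) -> MID:
    """Clamp negatives to zero and rescale to unit sum.

    Raises :class:`DataError` on all-zero / all-negative input.
    """
    arr = np.asarray(list(raw), dtype=float)
    if arr.size < 1:
        raise DataError("cannot normalize an empty abundance vector")
    clamped = np.clip(arr, 0.0, None)
    total = clamped.sum()
    if total <= 0:
        raise DataError("degenerate MID: no positive abundance to normalize")
    return MID(tuple(clamped / total))


def mean_mid(mids: Iterable[MID]) -> MID:
    """Arithmetic mean of MIDs (zero-padded to common length), renormalized."""
    mids = list(mids)
    if not mids:
        raise ValueError("mean_mid of empty collection")
    n = max(len(m) for m in mids)
    stacked = np.stack([m.padded(n).as_array() for m in mids])
    return normalize_mid(stacked.mean(axis=0))


@dataclass(frozen=True)
class FragmentMeasurement:
    """One mass-spectrometric fragment: MID, quality and optional raw signal."""

    fragment_mz: int
    mid: MID
    r2: float | None = None
    formula: Mapping[str, int] | None = None
    raw_intensities: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.raw_intensities is not None:
            raw = tuple(float(v) for v in self.raw_intensities)
            if len(raw) < len(self.mid):
                raise ValueError(
                    "raw_intensities must be at least as long as the MID"
                )
            if any(v < 0 for v in raw):
                raise ValueError("raw intensities must be nonnegative")
            object.__setattr__(self, "raw_intensities", raw)
        if self.r2 is not None and not (0.0 <= self.r2 <= 1.0):
            raise ValueError(f"r2 must lie in [0, 1], got {self.r2}")
        if self.formula is not None:
            object.__setattr__(self, "formula", dict(self.formula))


@dataclass(frozen=True)
class CompoundRecord:
    """A compound in one (condition, tracer, replicate) slice."""

    compound_id: str
    fragments: tuple[FragmentMeasurement, ...]
    name: str | None = None
    retention_index: float | None = None
    derivative: str | None = None
    is_contaminant: bool = False

    def __post_init__(self) -> None:
        mzs = [f.fragment_mz for f in self.fragments]
        if len(mzs) != len(set(mzs)):
            raise ValueError(
                f"duplicate fragment m/z in compound {self.compound_id!r}"
            )

    def fragment(self, mz: int) -> FragmentMeasurement:
        for f in self.fragments:
            if f.fragment_mz == mz:
                return f
        raise KeyError(f"no fragment m/z {mz} in compound {self.compound_id!r}")

    def fragment_mzs(self) -> set[int]:
        return {f.fragment_mz for f in self.fragments}

    @property
    def display_name(self) -> str:
        """Known name, else 'RI<retention index>' for unidentified compounds."""
        if self.name:
            return self.name
        if self.retention_index is not None:
            return f"RI{self.retention_index:g}"
        return self.compound_id

    def with_fragments(
        self, fragments: Sequence[FragmentMeasurement]
    ) -> "CompoundRecord":
        return replace(self, fragments=tuple(fragments))


SampleKey = tuple[str, str, int]  # (condition, tracer, replicate)


@dataclass
class LabelingDataset:
    """compounds x fragments x conditions x tracers x replicates container."""

    entries: dict[SampleKey, dict[str, CompoundRecord]] = field(
        default_factory=dict
    )
    conditions: list[str] = field(default_factory=list)
    tracers: list[str] = field(default_factory=list)

    def add(
        self,
        condition: str,
        tracer: str,
        replicate: int,
        record: CompoundRecord,
    ) -> None:
        key = (condition, tracer, int(replicate))
        slot = self.entries.setdefault(key, {})
        if record.compound_id in slot:
            raise DataError(
                f"duplicate compound {record.compound_id!r} in sample {key}"
            )
        slot[record.compound_id] = record
        if condition not in self.conditions:
            self.conditions.append(condition)
        if tracer not in self.tracers:
            self.tracers.append(tracer)

    def sample_keys(self) -> list[SampleKey]:
        return sorted(self.entries)

    def replicates(self, condition: str, tracer: str) -> list[int]:
        return sorted(
            r for (c, t, r) in self.entries if c == condition and t == tracer
        )

    def compound_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for key in self.sample_keys():
            for cid in self.entries[key]:
                seen.setdefault(cid)
        return list(seen)

    def records_for(
        self, compound_id: str, condition: str, tracer: str
    ) -> list[CompoundRecord]:
        out = []
        for rep in self.replicates(condition, tracer):
            rec = self.entries.get((condition, tracer, rep), {}).get(compound_id)
            if rec is not None:
                out.append(rec)
        return out

    def conditions_with(self, compound_id: str, tracer: str) -> list[str]:
        """Conditions (dataset order) in which the compound was detected."""
        return [
            c
            for c in self.conditions
            if self.records_for(compound_id, c, tracer)
        ]

    def mean_fragment_mid(
        self, compound_id: str, condition: str, tracer: str, fragment_mz: int
    ) -> MID | None:
        """Replicate-mean MID of one fragment, renormalized; None if absent."""
        mids = []
        for rec in self.records_for(compound_id, condition, tracer):
            try:
                mids.append(rec.fragment(fragment_mz).mid)
            except KeyError:
                continue
        if not mids:
            return None
        return mean_mid(mids)

    def slice(self, condition: str, tracer: str) -> "LabelingDataset":
        out = LabelingDataset(conditions=[condition], tracers=[tracer])
        for (c, t, r), recs in self.entries.items():
            if c == condition and t == tracer:
                out.entries[(c, t, r)] = dict(recs)
        return out

    def n_compounds(self) -> int:
        return len(self.compound_ids())


@dataclass
class SimilarityNetwork:
    """Compounds as nodes; below-cutoff MID distances as condition-tagged edges."""

    nodes: set[str] = field(default_factory=set)
    # (a, b) with a < b -> {"conditions": set, "distances": {condition: d}}
    edges: dict[tuple[str, str], dict] = field(default_factory=dict)
    cutoff: float | None = None

    def add_edge(self, a: str, b: str, distance: float, condition: str) -> None:
        if a == b:
            raise ValueError("self-edges are not allowed")
        key = (a, b) if a < b else (b, a)
        self.nodes.update(key)
        entry = self.edges.setdefault(
            key, {"conditions": set(), "distances": {}}
        )
        entry["conditions"].add(condition)
        entry["distances"][condition] = distance

    def edge_distance(self, a: str, b: str) -> float:
        key = (a, b) if a < b else (b, a)
        return min(self.edges[key]["distances"].values())


# ---------------------------------------------------------------------------
# Canonical TSV schema
# ---------------------------------------------------------------------------

_META_COLUMNS = [
    "condition",
    "tracer",
    "replicate",
    "compound_id",
    "compound_name",
    "retention_index",
    "derivative",
    "fragment_mz",
    "formula",
    "r2",
    "n_isotopomers",
]

#: Tracer labels that do not trigger the unknown-tracer warning.
KNOWN_TRACERS = {"glc", "gln", "glucose", "glutamine", "none", "unlabeled"}

_SUM_WINDOW = (0.8, 1.2)


def _format_formula(formula: Mapping[str, int] | None) -> str:
    if not formula:
        return ""
    # Hill notation: C first, H second, rest alphabetical.
    symbols = sorted(formula, key=lambda s: (s != "C", s != "H", s))
    parts = []
    for sym in symbols:
        n = formula[sym]
        if n <= 0:
            continue
        parts.append(sym if n == 1 else f"{sym}{n}")
    return "".join(parts)


def parse_formula(text: str) -> dict[str, int] | None:
    """Parse 'C6H12O6' style elemental compositions; blank -> None."""
    text = (text or "").strip()
    if not text:
        return None
    import re

    counts: dict[str, int] = {}
    pos = 0
    for m in re.finditer(r"([A-Z][a-z]?)(\d*)", text):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise SchemaError(f"unparsable formula {text!r}")
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        pos = m.end()
    if pos != len(text):
        raise SchemaError(f"unparsable formula {text!r}")
    return counts


def write_mid_table(dataset: LabelingDataset, path) -> None:
    """Serialize a dataset to the canonical TSV (floats at 6 significant digits)."""
    max_iso = 1
    for recs in dataset.entries.values():
        for rec in recs.values():
            for frag in rec.fragments:
                n = len(frag.mid)
                if frag.raw_intensities is not None:
                    n = max(n, len(frag.raw_intensities))
                max_iso = max(max_iso, n)
    m_cols = [f"M{j}" for j in range(max_iso)]
    i_cols = [f"I{j}" for j in range(max_iso)]

    def fmt(x: float | None) -> str:
        if x is None or (isinstance(x, float) and math.isnan(x)):
            return ""
        return f"{x:.6g}"

    rows = []
    for (cond, tracer, rep) in dataset.sample_keys():
        for cid in sorted(dataset.entries[(cond, tracer, rep)]):
            rec = dataset.entries[(cond, tracer, rep)][cid]
            for frag in sorted(rec.fragments, key=lambda f: f.fragment_mz):
                row = {
                    "condition": cond,
                    "tracer": tracer,
                    "replicate": rep,
                    "compound_id": rec.compound_id,
                    "compound_name": rec.name or "",
                    "retention_index": fmt(rec.retention_index),
                    "derivative": rec.derivative or "",
                    "fragment_mz": frag.fragment_mz,
                    "formula": _format_formula(frag.formula),
                    "r2": fmt(frag.r2),
                    "n_isotopomers": len(frag.mid),
                }
                for j, col in enumerate(m_cols):
                    row[col] = (
                        fmt(frag.mid[j]) if j < len(frag.mid) else ""
                    )
                for j, col in enumerate(i_cols):
                    if frag.raw_intensities is not None and j < len(
                        frag.raw_intensities
                    ):
                        row[col] = fmt(frag.raw_intensities[j])
                    else:
                        row[col] = ""
                rows.append(row)
    frame = pd.DataFrame(rows, columns=_META_COLUMNS + m_cols + i_cols)
    frame.to_csv(path, sep="\t", index=False)


def read_mid_table(path) -> LabelingDataset:
    """Parse the canonical TSV into a :class:`LabelingDataset`.

    Schema violations raise :class:`SchemaError`; inconsistent rows raise
    :class:`DataError` carrying the 1-based data row number.  Unknown tracer
    labels produce a warning only.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _META_COLUMNS:
        if col not in frame.columns:
            raise SchemaError(f"missing mandatory column {col!r}")
    m_cols = [c for c in frame.columns if c.startswith("M") and c[1:].isdigit()]
    m_cols.sort(key=lambda c: int(c[1:]))
    i_cols = [c for c in frame.columns if c.startswith("I") and c[1:].isdigit()]
    i_cols.sort(key=lambda c: int(c[1:]))
    if not m_cols:
        raise SchemaError("missing mandatory column 'M0'")

    dataset = LabelingDataset()
    pending: dict[SampleKey, dict[str, dict]] = {}
    seen_rows: set[tuple] = set()
    for idx, row in frame.iterrows():
        rownum = int(idx) + 1
        cond = row["condition"].strip()
        tracer = row["tracer"].strip()
        try:
            rep = int(row["replicate"])
            mz = int(row["fragment_mz"])
            n_iso = int(row["n_isotopomers"])
        except ValueError as exc:
            raise DataError(f"row {rownum}: non-integer field ({exc})") from exc
        dup_key = (cond, tracer, rep, row["compound_id"], mz)
        if dup_key in seen_rows:
            raise DataError(
                f"row {rownum}: duplicate measurement for "
                f"(condition={cond!r}, tracer={tracer!r}, replicate={rep}, "
                f"compound_id={row['compound_id']!r}, fragment_mz={mz})"
            )
        seen_rows.add(dup_key)
        if tracer.lower() not in KNOWN_TRACERS:
            warnings.warn(
                f"row {rownum}: unknown tracer label {tracer!r}", stacklevel=2
            )
        if n_iso < 1 or n_iso > len(m_cols):
            raise DataError(
                f"row {rownum}: n_isotopomers={n_iso} outside table width"
            )
        try:
            abund = [float(row[c]) for c in m_cols[:n_iso]]
        except ValueError as exc:
            raise DataError(f"row {rownum}: bad abundance ({exc})") from exc
        total = sum(abund)
        if not (_SUM_WINDOW[0] <= total <= _SUM_WINDOW[1]):
            raise DataError(
                f"row {rownum}: abundances sum to {total:.4f}, outside "
                f"[{_SUM_WINDOW[0]}, {_SUM_WINDOW[1]}]"
            )
        raw: tuple[float, ...] | None = None
        raw_vals = [row[c] for c in i_cols]
        if any(v.strip() for v in raw_vals):
            filled = [v for v in raw_vals if v.strip()]
            raw = tuple(float(v) for v in filled)
        frag = FragmentMeasurement(
            fragment_mz=mz,
            mid=MID(tuple(abund)),
            r2=float(row["r2"]) if row["r2"].strip() else None,
            formula=parse_formula(row["formula"]),
            raw_intensities=raw,
        )
        skey: SampleKey = (cond, tracer, rep)
        comp = pending.setdefault(skey, {}).setdefault(
            row["compound_id"],
            {
                "name": row["compound_name"].strip() or None,
                "retention_index": (
                    float(row["retention_index"])
                    if row["retention_index"].strip()
                    else None
                ),
                "derivative": row["derivative"].strip() or None,
                "fragments": [],
            },
        )
        comp["fragments"].append(frag)
        if cond not in dataset.conditions:
            dataset.conditions.append(cond)
        if tracer not in dataset.tracers:
            dataset.tracers.append(tracer)

    for skey, comps in pending.items():
        for cid, info in comps.items():
            dataset.entries.setdefault(skey, {})[cid] = CompoundRecord(
                compound_id=cid,
                name=info["name"],
                retention_index=info["retention_index"],
                derivative=info["derivative"],
                fragments=tuple(info["fragments"]),
            )
    return dataset


def read_exclusion_list(path) -> list[str]:
    """One compound_id or name per line; '#' comments and blanks ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.append(line)
    return out
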