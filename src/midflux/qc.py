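"""Fragment/compound acceptance thresholds and trailing-noise removal.

A compound is retained when, under at least one experimental condition, a
minimum number of its fragments simultaneously satisfy the MID-determination
quality, absolute-sum, M0-window and minimal-enrichment criteria; compounds
on the contaminant exclusion list (e.g. siloxanes) are dropped regardless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import (
    MID,
    CompoundRecord,
    FragmentMeasurement,
    LabelingDataset,
    normalize_mid,
)

__all__ = [
    "QcThresholds",
    "QcFlags",
    "QcReport",
    "strip_trailing_noise",
    "fragment_passes_qc",
    "filter_dataset",
]


@dataclass(frozen=True)
class QcThresholds:
    min_r2: float = 0.98
    max_abs_sum: float = 1.05
    m0_lower: float = 0.45
    m0_upper: float = 1.0
    min_enrichment: float = 0.05
    trailing_noise: float = 0.01
    min_passing_fragments: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.min_r2 <= 1):
            raise ValueError("min_r2 must lie in (0, 1]")
        if not (0 <= self.m0_lower < self.m0_upper <= 1):
            raise ValueError("require 0 <= m0_lower < m0_upper <= 1")


@dataclass(frozen=True)
class QcFlags:
    """Per-criterion outcome of one fragment check."""

    r2_ok: bool
    abs_sum_ok: bool
    m0_ok: bool
    enrichment_ok: bool
    r2_missing: bool = False

    @property
    def passed(self) -> bool:
        return self.r2_ok and self.abs_sum_ok and self.m0_ok and self.enrichment_ok


@dataclass
class QcReport:
    """Counts of compounds kept/removed and the reason for each removal."""

    n_in: int = 0
    n_kept: int = 0
    removed: dict[str, str] = field(default_factory=dict)  # compound_id -> reason

    def counts_by_reason(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for reason in self.removed.values():
            out[reason] = out.get(reason, 0) + 1
        return out

    def to_dict(self) -> dict:
        return {
            "compounds_in": self.n_in,
            "compounds_kept": self.n_kept,
            "compounds_removed": len(self.removed),
            "removed_by_reason": self.counts_by_reason(),
            "removed": dict(sorted(self.removed.items())),
        }


def strip_trailing_noise(mid: MID, threshold: float = 0.01) -> MID:
    """Drop the maximal run of final abundances each below ``threshold``.

    The remainder is divided by its sum (negative correction artifacts are
    preserved, not clamped); at least one entry is always retained.
    """
    abund = mid.abundances
    end = len(abund)
    while end > 1 and abund[end - 1] < threshold:
        end -= 1
    if end == len(abund):
        return mid
    kept = abund[:end]
    total = sum(kept)
    if total <= 0:
        return normalize_mid(kept)
    return MID(tuple(a / total for a in kept))


def fragment_passes_qc(
    frag: FragmentMeasurement, t: QcThresholds = QcThresholds()
) -> QcFlags:
    """Evaluate the four acceptance criteria for a single fragment.

    The absolute sum is taken over the MID as read (pre-clamping) since the
    criterion exists to catch natural-abundance correction artifacts.
    """
    r2_missing = frag.r2 is None
    r2_ok = (not r2_missing) and frag.r2 > t.min_r2
    abs_sum_ok = frag.mid.abs_sum < t.max_abs_sum
    m0 = frag.mid.m0
    m0_ok = t.m0_lower < m0 < t.m0_upper
    enrichment_ok = (1.0 - m0) >= t.min_enrichment
    return QcFlags(
        r2_ok=r2_ok,
        abs_sum_ok=abs_sum_ok,
        m0_ok=m0_ok,
        enrichment_ok=enrichment_ok,
        r2_missing=r2_missing,
    )


def _matches_exclusion(record: CompoundRecord, exclusion: list[str]) -> bool:
    # exact on compound_id, case-insensitive substring on name
    for entry in exclusion:
        if record.compound_id == entry:
            return True
        if record.name and entry.lower() in record.name.lower():
            return True
    return False


def _passes_in_some_condition(
    ds: LabelingDataset, compound_id: str, t: QcThresholds
) -> bool:
    for cond in ds.conditions:
        for tracer in ds.tracers:
            n_passing = 0
            for mz in _all_fragment_mzs(ds, compound_id, cond, tracer):
                if any(
                    fragment_passes_qc(rec.fragment(mz), t).passed
                    for rec in ds.records_for(compound_id, cond, tracer)
                    if mz in rec.fragment_mzs()
                ):
                    n_passing += 1
            if n_passing >= t.min_passing_fragments:
                return True
    return False


def _all_fragment_mzs(
    ds: LabelingDataset, compound_id: str, condition: str, tracer: str
) -> set[int]:
    mzs: set[int] = set()
    for rec in ds.records_for(compound_id, condition, tracer):
        mzs |= rec.fragment_mzs()
    return mzs


def filter_dataset(
    ds: LabelingDataset,
    t: QcThresholds = QcThresholds(),
    exclusion_list: list[str] | None = None,
) -> tuple[LabelingDataset, QcReport]:
    """Apply compound-level QC and trailing-noise stripping to a dataset.

    A compound is kept iff it is not on the exclusion list and, in at least
    one (condition, tracer) slice, at least ``min_passing_fragments`` of its
    fragments pass all criteria in some replicate.  Criteria are evaluated on
    trailing-noise-stripped MIDs, which makes the filter idempotent.
    """
    exclusion = exclusion_list or []
    report = QcReport(n_in=ds.n_compounds())

    stripped = LabelingDataset(
        conditions=list(ds.conditions), tracers=list(ds.tracers)
    )
    for key in ds.sample_keys():
        for cid, rec in ds.entries[key].items():
            new_frags = [
                FragmentMeasurement(
                    fragment_mz=f.fragment_mz,
                    mid=strip_trailing_noise(f.mid, t.trailing_noise),
                    r2=f.r2,
                    formula=f.formula,
                    raw_intensities=f.raw_intensities,
                )
                for f in rec.fragments
            ]
            stripped.add(key[0], key[1], key[2], rec.with_fragments(new_frags))

    keep: set[str] = set()
    for cid in stripped.compound_ids():
        some_record = next(
            rec
            for key in stripped.sample_keys()
            for rec in [stripped.entries[key].get(cid)]
            if rec is not None
        )
        if some_record.is_contaminant or _matches_exclusion(some_record, exclusion):
            report.removed[cid] = "contaminant"
            continue
        if not _passes_in_some_condition(stripped, cid, t):
            report.removed[cid] = "insufficient_passing_fragments"
            continue
        keep.add(cid)

    out = LabelingDataset(
        conditions=list(stripped.conditions), tracers=list(stripped.tracers)
    )
    for key in stripped.sample_keys():
        for cid, rec in stripped.entries[key].items():
            if cid in keep:
                out.add(key[0], key[1], key[2], rec)
    report.n_kept = len(keep)
    return out, report
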