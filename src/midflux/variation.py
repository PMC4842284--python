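"""Ranking of putative metabolic flux changes by MID variation.

For each isotopically enriched compound the cross-condition population
standard deviation of each relative mass-isotopomer abundance is computed on
the heaviest fragment common to all conditions in which the compound was
detected; the maximum over isotopomer indices is the compound's variation
score, and compounds are ranked by it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import MID, LabelingDataset

__all__ = [
    "VariationRecord",
    "heaviest_common_fragment",
    "variation_score",
    "rank_by_variation",
]

#: Sentinel returned when no fragment is shared by all detection conditions.
NO_COMMON_FRAGMENT = -1


@dataclass(frozen=True)
class VariationRecord:
    compound_id: str
    fragment_mz: int
    sigma: tuple[float, ...]
    score: float
    argmax_j: int
    n_conditions: int
    name: str | None = None
    per_condition_abundance: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.sigma and abs(self.score - max(self.sigma)) > 1e-12:
            raise ValueError("score must equal max(sigma)")


def heaviest_common_fragment(
    ds: LabelingDataset,
    compound_id: str,
    tracer: str,
    min_r2: float = 0.0,
) -> int:
    """Largest fragment m/z observed in every condition where the compound is.

    Fragments require ``r2 >= min_r2`` (in at least one replicate) to qualify.
    Returns :data:`NO_COMMON_FRAGMENT` when no m/z is shared.
    """
    conditions = ds.conditions_with(compound_id, tracer)
    if not conditions:
        return NO_COMMON_FRAGMENT
    common: set[int] | None = None
    for cond in conditions:
        mzs: set[int] = set()
        for rec in ds.records_for(compound_id, cond, tracer):
            for frag in rec.fragments:
                if frag.r2 is None or frag.r2 >= min_r2:
                    mzs.add(frag.fragment_mz)
        common = mzs if common is None else common & mzs
    if not common:
        return NO_COMMON_FRAGMENT
    return max(common)


def variation_score(mids: Sequence[MID]) -> tuple[float, tuple[float, ...]]:
    """Per-isotopomer population SD across conditions and its maximum.

    ``sigma_j = sqrt((1/n) * sum_i (pbar_j - p_{j,i})^2)`` over the ``n``
    condition MIDs, which are zero-padded to a common length.
    """
    if len(mids) < 2:
        raise ValueError("variation score needs at least two condition MIDs")
    length = max(len(m) for m in mids)
    mat = np.stack([m.padded(length).as_array() for m in mids])
    sigma = mat.std(axis=0, ddof=0)
    return float(sigma.max()), tuple(float(s) for s in sigma)


def rank_by_variation(
    ds: LabelingDataset,
    tracer: str,
    min_conditions: int = 3,
    top_k: int | None = None,
    min_enrichment: float = 0.05,
    min_r2: float = 0.0,
) -> tuple[list[VariationRecord], dict[str, str]]:
    """Rank compounds by variation score under one tracer.

    Per compound the replicate-mean MID of the heaviest common fragment is
    taken per condition; conditions where the compound is unlabeled
    (enrichment below ``min_enrichment``) do not count.  Compounds enriched
    in fewer than ``min_conditions`` conditions are excluded, as is — per
    metabolite name — every derivative but the highest-scoring one.  Returns
    the descending ranking and a report of exclusions by reason.
    """
    excluded: dict[str, str] = {}
    records: list[VariationRecord] = []
    for cid in ds.compound_ids():
        mz = heaviest_common_fragment(ds, cid, tracer, min_r2=min_r2)
        if mz == NO_COMMON_FRAGMENT:
            excluded[cid] = "no_common_fragment"
            continue
        mids: list[MID] = []
        name: str | None = None
        for cond in ds.conditions_with(cid, tracer):
            mid = ds.mean_fragment_mid(cid, cond, tracer, mz)
            if mid is None:
                continue
            if mid.enrichment < min_enrichment:
                continue  # unlabeled under this condition
            mids.append(mid)
            if name is None:
                recs = ds.records_for(cid, cond, tracer)
                name = recs[0].name if recs else None
        if len(mids) < max(min_conditions, 2):
            excluded[cid] = "too_few_enriched_conditions"
            continue
        score, sigma = variation_score(mids)
        argmax = int(np.argmax(sigma))
        records.append(
            VariationRecord(
                compound_id=cid,
                fragment_mz=mz,
                sigma=sigma,
                score=score,
                argmax_j=argmax,
                n_conditions=len(mids),
                name=name,
                per_condition_abundance=tuple(
                    m.padded(len(sigma))[argmax] for m in mids
                ),
            )
        )

    # one derivative per named metabolite: highest score wins, unknowns kept
    best_by_name: dict[str, VariationRecord] = {}
    unnamed: list[VariationRecord] = []
    for rec in records:
        if rec.name is None:
            unnamed.append(rec)
            continue
        prev = best_by_name.get(rec.name)
        if prev is None or (rec.score, prev.compound_id) > (
            prev.score,
            rec.compound_id,
        ):
            if prev is not None:
                excluded[prev.compound_id] = "duplicate_derivative"
            best_by_name[rec.name] = rec
        else:
            excluded[rec.compound_id] = "duplicate_derivative"

    ranked = sorted(
        unnamed + list(best_by_name.values()),
        key=lambda r: (-r.score, r.compound_id),
    )
    if top_k is not None:
        ranked = ranked[:top_k]
    return ranked, excluded
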