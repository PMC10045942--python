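"""Tiered matching of amplicon sequence variants (ASVs) against the reference index.

An ASV "has a sequenced genome" at identity tier *t* (percent) when some
catalog 16S sequence contains, on either strand, a gapless window of the full
query length whose Hamming distance to the ASV is within the mismatch budget

    budget(L, t) = floor(L * (1 - t/100))

so for the standard 90-bp tags the tiers 100 / 98.7 / 97 % allow 0 / 1 / 2
mismatches. Full query coverage is implied by requiring a window of the whole
query length; gapped alignments are deliberately out of scope (an indel in a
short tag cannot reach 100% coverage at these identities without inflating the
alignment length), which makes the 100%-identity tier exactly equivalent to a
perfect BLASTn hit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .catalog import CATEGORY_PRECEDENCE, Category, ReferenceIndex

__all__ = [
    "DEFAULT_TIERS",
    "MatchResult",
    "mismatch_budget",
    "match_exact",
    "match_with_mismatches",
    "classify_asv",
    "classify_table",
    "best_category",
    "match_table_frame",
]

DEFAULT_TIERS: tuple[float, ...] = (100.0, 98.7, 97.0)


def mismatch_budget(query_length: int, identity_percent: float) -> int:
    """Number of mismatches a query of this length may carry at an identity tier."""
    if not 0 < identity_percent <= 100:
        raise ValueError("identity_percent must be in (0, 100]")
    if query_length < 1:
        raise ValueError("query_length must be >= 1")
    return math.floor(query_length * (1.0 - identity_percent / 100.0))


def match_exact(asv_sequence: str, index: ReferenceIndex) -> list[str]:
    """Accessions hit at 100% identity / 100% coverage (exact substring, both strands).

    A query containing ``N`` never matches exactly.
    """
    return index.search_exact(asv_sequence)


def match_with_mismatches(
    asv_sequence: str, index: ReferenceIndex, max_mismatches: int
) -> list[str]:
    """Accessions with a full-length gapless window within the Hamming budget."""
    if max_mismatches == 0 and "N" not in asv_sequence.upper():
        return match_exact(asv_sequence, index)
    return sorted(index.search_hamming(asv_sequence, max_mismatches))


def best_category(accessions: Sequence[str], index: ReferenceIndex) -> Category | None:
    """Highest-precedence genome subgroup among hit accessions, or None."""
    if not accessions:
        return None
    cats = {index.category(a) for a in accessions}
    for cat in CATEGORY_PRECEDENCE:
        if cat in cats:
            return cat
    return Category.UNASSIGNED


@dataclass
class MatchResult:
    """Per-ASV tiered match outcome.

    ``tier_hits`` are nested: relaxing the identity tier never removes a hit.
    ``best_category`` holds, per tier, the highest-precedence subgroup among
    that tier's hits (None when the tier has no hit).
    """

    asv_id: str
    tier_hits: dict[float, list[str]] = field(default_factory=dict)
    matched_at: dict[float, bool] = field(default_factory=dict)
    best_category: dict[float, Category | None] = field(default_factory=dict)
    n_mismatches_best: int | None = None

    def matched(self, tier: float) -> bool:
        return self.matched_at.get(tier, False)

    def category_at(self, tier: float) -> Category | None:
        return self.best_category.get(tier)


def classify_asv(
    asv_sequence: str,
    index: ReferenceIndex,
    tiers: Sequence[float] = DEFAULT_TIERS,
    asv_id: str = "",
) -> MatchResult:
    """Classify one ASV at every identity tier.

    One bounded-Hamming search at the loosest tier's budget yields per-accession
    minimum distances; each tier then filters by its own budget, which makes the
    tier nesting structural rather than re-computed.
    """
    tiers = sorted(tiers, reverse=True)
    seq = asv_sequence.upper()
    length = len(seq)
    max_budget = mismatch_budget(length, min(tiers))
    dists = index.search_hamming(seq, max_budget)
    has_n = "N" in seq

    result = MatchResult(asv_id=asv_id)
    for tier in tiers:
        budget = mismatch_budget(length, tier)
        if tier >= 100 and has_n:
            hits: list[str] = []
        else:
            hits = sorted(a for a, d in dists.items() if d <= budget)
        result.tier_hits[tier] = hits
        result.matched_at[tier] = bool(hits)
        result.best_category[tier] = best_category(hits, index)
    if dists:
        result.n_mismatches_best = min(dists.values())
    return result


def classify_table(
    sequences: Mapping[str, str],
    index: ReferenceIndex,
    tiers: Sequence[float] = DEFAULT_TIERS,
) -> dict[str, MatchResult]:
    """Classify every ASV in ``asv_id -> sequence``; keys are preserved."""
    return {
        asv_id: classify_asv(seq, index, tiers, asv_id=asv_id)
        for asv_id, seq in sequences.items()
    }


def match_table_frame(results: Mapping[str, MatchResult]) -> pd.DataFrame:
    """Long-format match table: one row per (ASV, tier)."""
    rows = []
    for asv_id, res in results.items():
        for tier, hits in sorted(res.tier_hits.items(), reverse=True):
            cat = res.best_category.get(tier)
            rows.append({
                "asv_id": asv_id,
                "tier": tier,
                "n_hits": len(hits),
                "best_category": cat.name if cat else "NONE",
                "example_accession": hits[0] if hits else "",
            })
    return pd.DataFrame(rows, columns=["asv_id", "tier", "n_hits",
                                       "best_category", "example_accession"])
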