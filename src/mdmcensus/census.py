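"""Genome-sequenced proportion census.

The two headline statistics per sample, at a given identity tier:

* ``P_number``    — fraction of the distinct taxa (ASVs present in the sample)
  that match a sequenced genome;
* ``P_abundance`` — summed relative abundance of the matched taxa, a proxy for
  the fraction of cells with a sequenced genome.

Both are monotone non-decreasing as the identity tier is relaxed, and removing
genomes from the reference (the ablation experiment) can only lower them.
Environment-level summaries report the median and quartiles across samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import CATEGORY_PRECEDENCE, ReferenceIndex
from .matching import MatchResult, classify_table
from .samples import AmpliconTable

__all__ = [
    "SampleCensus",
    "AblationReport",
    "sample_census",
    "census_table",
    "environment_summary",
    "pooled_summary",
    "correlate_with_diversity",
    "ablate_and_recompute",
]


@dataclass
class SampleCensus:
    """Per-sample genome-sequenced proportions at one identity tier."""

    sample_id: str
    environment: str
    tier: float
    p_number: float
    p_abundance: float
    n_present: int
    source_composition: dict[str, float] = field(default_factory=dict)
    alpha: dict[str, float] = field(default_factory=dict)
    empty: bool = False


def sample_census(
    relabund_row,
    match_results: Mapping[str, MatchResult],
    tier: float = 100.0,
    sample_id: str = "",
    environment: str = "",
) -> SampleCensus:
    """Census one sample from its relative-abundance row and ASV match results.

    ``P_number`` counts matched ASVs among those present (abundance > 0);
    ``P_abundance`` sums their relative abundance. The source composition
    splits the matched abundance by the best genome subgroup of each ASV and
    sums to 1 whenever any ASV matches.
    """
    row = pd.Series(relabund_row).astype(float)
    row = row[row > 0]
    if row.empty:
        return SampleCensus(sample_id, environment, tier, 0.0, 0.0, 0, empty=True)
    missing = [a for a in row.index if a not in match_results]
    if missing:
        raise ValueError(
            f"match results missing for {len(missing)} ASVs present in "
            f"{sample_id or 'sample'}, e.g. {missing[:3]}"
        )
    matched = [a for a in row.index if match_results[a].matched(tier)]
    p_number = len(matched) / len(row)
    matched_abund = float(row[matched].sum())
    p_abundance = matched_abund / float(row.sum())

    composition: dict[str, float] = {}
    if matched_abund > 0:
        by_cat: dict[str, float] = {}
        for a in matched:
            cat = match_results[a].category_at(tier)
            name = cat.name if cat else "UNASSIGNED"
            by_cat[name] = by_cat.get(name, 0.0) + float(row[a])
        composition = {c.name: by_cat.get(c.name, 0.0) / matched_abund
                       for c in CATEGORY_PRECEDENCE}
        if "UNASSIGNED" in by_cat:
            composition["UNASSIGNED"] = by_cat["UNASSIGNED"] / matched_abund
    return SampleCensus(
        sample_id, environment, tier, p_number, p_abundance, len(row), composition
    )


def census_table(
    table: AmpliconTable,
    match_results: Mapping[str, MatchResult],
    tier: float = 100.0,
) -> list[SampleCensus]:
    """Census every sample of an amplicon table at one tier."""
    rel = table.relative_abundance()
    return [
        sample_census(rel.loc[s], match_results, tier,
                      sample_id=s, environment=table.environment_of(s))
        for s in table.sample_ids
    ]


def _quartiles(values: Sequence[float]) -> tuple[float, float, float]:
    # linear-interpolation (type-7) quartiles
    arr = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return float(q1), float(med), float(q3)


def environment_summary(censuses: Iterable[SampleCensus]) -> pd.DataFrame:
    """Median and quartiles of P_number / P_abundance per environment and tier."""
    df = pd.DataFrame(
        [{"environment": c.environment, "tier": c.tier,
          "p_number": c.p_number, "p_abundance": c.p_abundance}
         for c in censuses]
    )
    if df.empty:
        return pd.DataFrame(columns=[
            "environment", "tier", "n_samples",
            "p_number_q1", "p_number_median", "p_number_q3",
            "p_abundance_q1", "p_abundance_median", "p_abundance_q3"])
    rows = []
    for (env, tier), grp in df.groupby(["environment", "tier"]):
        n_q1, n_med, n_q3 = _quartiles(grp["p_number"])
        a_q1, a_med, a_q3 = _quartiles(grp["p_abundance"])
        rows.append({
            "environment": env, "tier": tier, "n_samples": len(grp),
            "p_number_q1": n_q1, "p_number_median": n_med, "p_number_q3": n_q3,
            "p_abundance_q1": a_q1, "p_abundance_median": a_med,
            "p_abundance_q3": a_q3,
        })
    return pd.DataFrame(rows)


def pooled_summary(censuses: Iterable[SampleCensus]) -> dict[str, float]:
    """Median P statistics pooled over all samples regardless of environment."""
    cs = list(censuses)
    if not cs:
        return {"n_samples": 0, "p_number_median": float("nan"),
                "p_abundance_median": float("nan")}
    return {
        "n_samples": len(cs),
        "p_number_median": float(np.median([c.p_number for c in cs])),
        "p_abundance_median": float(np.median([c.p_abundance for c in cs])),
    }


def correlate_with_diversity(censuses: Iterable[SampleCensus]) -> pd.DataFrame:
    """Pearson r (and p) of P_number / P_abundance against each alpha index.

    Censuses without alpha indices are skipped; a zero-variance vector yields
    NaN r, reported rather than raised.
    """
    cs = [c for c in censuses if c.alpha]
    if len(cs) < 3:
        raise ValueError("need at least 3 samples with alpha diversity")
    indices = sorted(cs[0].alpha)
    rows = []
    for metric in ("p_number", "p_abundance"):
        y = np.array([getattr(c, metric) for c in cs])
        for idx in indices:
            x = np.array([c.alpha[idx] for c in cs])
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                r, p = float("nan"), float("nan")
            else:
                r, p = stats.pearsonr(x, y)
            rows.append({"metric": metric, "alpha_index": idx,
                         "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)


@dataclass
class AblationReport:
    """Paired before/after census when a genome subset is removed from the index."""

    before: list[SampleCensus]
    after: list[SampleCensus]
    summary_before: pd.DataFrame
    summary_after: pd.DataFrame
    deltas: pd.DataFrame          # per-sample paired differences
    flipped_asvs: pd.DataFrame    # high-abundance ASVs whose match status flipped

    def median_delta(self, metric: str = "p_abundance") -> float:
        return float(self.deltas[f"delta_{metric}"].median())


def ablate_and_recompute(
    index: ReferenceIndex,
    removal_accessions: Iterable[str],
    amplicon_table: AmpliconTable,
    tier: float = 100.0,
    tiers: Sequence[float] | None = None,
    high_abundance: float = 0.005,
) -> AblationReport:
    """Recompute the census after deleting a genome subset from the reference.

    Reports per-sample paired deltas (before - after, non-negative by
    construction) and the ASVs exceeding ``high_abundance`` relative abundance
    in some sample whose match status at ``tier`` flipped.
    """
    tiers = tuple(tiers) if tiers else (tier,)
    reduced = index.without(removal_accessions)
    seqs = {a: amplicon_table.sequences[a] for a in amplicon_table.asv_ids
            if a in amplicon_table.sequences}
    match_before = classify_table(seqs, index, tiers)
    match_after = classify_table(seqs, reduced, tiers)

    before = census_table(amplicon_table, match_before, tier)
    after = census_table(amplicon_table, match_after, tier)
    deltas = pd.DataFrame({
        "sample_id": [c.sample_id for c in before],
        "environment": [c.environment for c in before],
        "delta_p_number": [b.p_number - a.p_number for b, a in zip(before, after)],
        "delta_p_abundance": [b.p_abundance - a.p_abundance
                              for b, a in zip(before, after)],
    })

    rel = amplicon_table.relative_abundance()
    max_abund = rel.max(axis=0)
    flipped = []
    for asv in amplicon_table.asv_ids:
        if asv not in match_before:
            continue
        was, now = match_before[asv].matched(tier), match_after[asv].matched(tier)
        if was != now and max_abund[asv] > high_abundance:
            flipped.append({"asv_id": asv, "max_relative_abundance":
                            float(max_abund[asv]),
                            "matched_before": was, "matched_after": now})
    return AblationReport(
        before=before,
        after=after,
        summary_before=environment_summary(before),
        summary_after=environment_summary(after),
        deltas=deltas,
        flipped_asvs=pd.DataFrame(
            flipped, columns=["asv_id", "max_relative_abundance",
                              "matched_before", "matched_after"]),
    )
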