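"""Per-sample processing: amplicon tables, rarefaction, alpha diversity, abundance classes.

The census works on sample x ASV count tables. Rarefaction (subsampling
without replacement to a fixed depth, default 20,000 reads) feeds only the
alpha-diversity indices; the genome-sequenced proportion statistics are
computed on unrarefied relative abundances.

Abundance classes follow the hyper-dominance convention used for engineered
and natural communities alike: "abundant" taxa have within-sample relative
abundance strictly above 1%, "rare" strictly below 0.1%, and boundary values
fall in the intermediate class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio.diversity.alpha import chao1, shannon

__all__ = [
    "AmpliconTable",
    "AbundancePartition",
    "EXCLUDED_LOW_DEPTH",
    "rarefy",
    "rarefy_table",
    "alpha_diversity",
    "alpha_diversity_table",
    "abundance_partition",
]

#: Flag value for samples whose read depth is below the rarefaction depth.
EXCLUDED_LOW_DEPTH = "EXCLUDED_LOW_DEPTH"


@dataclass
class AmpliconTable:
    """Sample x ASV counts with ASV sequences and per-sample environment labels.

    ``counts`` rows are samples, columns are ASV ids. Every ASV with a nonzero
    count must have a sequence in ``sequences``; environments default to a
    single unlabeled group.
    """

    counts: pd.DataFrame
    sequences: dict[str, str]
    environments: pd.Series | None = None

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        present = self.counts.columns[(self.counts.sum(axis=0) > 0)]
        missing = [a for a in present if a not in self.sequences]
        if missing:
            raise ValueError(
                f"{len(missing)} ASVs with nonzero counts lack sequences, "
                f"e.g. {missing[:3]}"
            )
        if self.environments is None:
            self.environments = pd.Series("unlabeled", index=self.counts.index)
        else:
            self.environments = self.environments.reindex(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    def relative_abundance(self) -> pd.DataFrame:
        """Row-normalized counts; all-zero rows stay zero."""
        totals = self.counts.sum(axis=1)
        rel = self.counts.div(totals.where(totals > 0, 1), axis=0)
        return rel

    def environment_of(self, sample_id: str) -> str:
        return str(self.environments.loc[sample_id])

    def mean_relative_abundance(self) -> pd.Series:
        return self.relative_abundance().mean(axis=0)

    # -- I/O -------------------------------------------------------------

    def to_dir(self, out_dir) -> None:
        from . import io

        io.write_amplicon_table(self, out_dir)

    @classmethod
    def from_dir(cls, in_dir) -> "AmpliconTable":
        from . import io

        return io.read_amplicon_table(in_dir)


def rarefy(counts_row, depth: int = 20000, *, seed) -> np.ndarray | None:
    """Subsample a count vector without replacement to exactly ``depth`` reads.

    Multivariate-hypergeometric draw; returns None when the row total is
    below the depth (the caller flags such samples EXCLUDED_LOW_DEPTH rather
    than raising).
    """
    counts = np.asarray(counts_row, dtype=np.int64)
    if counts.sum() < depth:
        return None
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts, depth)


def rarefy_table(
    table: AmpliconTable, depth: int = 20000, *, seed
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Rarefy every sample; returns (rarefied counts, per-sample flags).

    Samples below the depth are dropped from the rarefied table and flagged
    ``EXCLUDED_LOW_DEPTH`` in the flags mapping.
    """
    rng = np.random.default_rng(seed)
    rows, flags, kept = [], {}, []
    for sample_id, row in table.counts.iterrows():
        sub = rarefy(row.values, depth, seed=rng)
        if sub is None:
            flags[sample_id] = EXCLUDED_LOW_DEPTH
        else:
            flags[sample_id] = "OK"
            rows.append(sub)
            kept.append(sample_id)
    rarefied = pd.DataFrame(rows, index=kept, columns=table.counts.columns,
                            dtype=np.int64)
    return rarefied, flags


def alpha_diversity(rarefied_row, base: float | None = None) -> dict[str, float]:
    """Observed richness, Shannon entropy (natural log by default), and
    bias-corrected Chao1 of a (rarefied) count vector."""
    counts = np.asarray(rarefied_row, dtype=np.int64)
    counts = counts[counts > 0]
    if counts.size == 0:
        return {"observed": 0.0, "shannon": 0.0, "chao1": 0.0}
    return {
        "observed": float(counts.size),
        "shannon": float(shannon(counts, base=base if base else np.e)),
        "chao1": float(chao1(counts, bias_corrected=True)),
    }


def alpha_diversity_table(rarefied: pd.DataFrame, base: float | None = None
                          ) -> pd.DataFrame:
    """Alpha indices per sample of an already-rarefied table."""
    return pd.DataFrame(
        {s: alpha_diversity(row.values, base=base) for s, row in rarefied.iterrows()}
    ).T


@dataclass
class AbundancePartition:
    """Within-sample split into abundant (>upper), intermediate, rare (<lower) taxa.

    Shares are fractions in [0, 1] over the taxa present in the sample;
    ``abundant_sequenced_abundance`` splits the abundant class's abundance by
    match status when match information is supplied.
    """

    abundant_taxa_share: float
    abundant_abundance_share: float
    rare_taxa_share: float
    rare_abundance_share: float
    intermediate_taxa_share: float
    intermediate_abundance_share: float
    abundant_sequenced_abundance: float = float("nan")
    abundant_unsequenced_abundance: float = float("nan")
    n_present: int = 0


def abundance_partition(
    relabund_row,
    match_results: Mapping[str, object] | None = None,
    upper: float = 0.01,
    lower: float = 0.001,
    tier: float = 100.0,
) -> AbundancePartition:
    """Partition a sample's taxa into abundant / intermediate / rare classes.

    ``relabund_row`` is a Series of relative abundances (asv_id -> fraction).
    Strict inequalities: a taxon at exactly ``upper`` or ``lower`` falls in
    the intermediate class. When ``match_results`` (asv_id -> MatchResult) is
    given, the abundant class's abundance is additionally split into matched
    (sequenced) and unmatched parts at ``tier``.
    """
    row = pd.Series(relabund_row).astype(float)
    row = row[row > 0]
    n = len(row)
    if n == 0:
        return AbundancePartition(0, 0, 0, 0, 0, 0, n_present=0)
    abundant = row[row > upper]
    rare = row[row < lower]
    middle_taxa = n - len(abundant) - len(rare)
    total = row.sum()
    part = AbundancePartition(
        abundant_taxa_share=len(abundant) / n,
        abundant_abundance_share=float(abundant.sum() / total),
        rare_taxa_share=len(rare) / n,
        rare_abundance_share=float(rare.sum() / total),
        intermediate_taxa_share=middle_taxa / n,
        intermediate_abundance_share=float(
            (total - abundant.sum() - rare.sum()) / total
        ),
        n_present=n,
    )
    if match_results is not None and len(abundant):
        matched = sum(
            v for a, v in abundant.items()
            if a in match_results and match_results[a].matched(tier)
        )
        part.abundant_sequenced_abundance = float(matched / abundant.sum())
        part.abundant_unsequenced_abundance = 1.0 - part.abundant_sequenced_abundance
    return part
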