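"""Genome catalog: metadata parsing, subgroup classification, and the 16S reference index.

A genome catalog (GTDB-dialect metadata plus an SSU FASTA) is the "known" side of
the census. Each genome is assigned to exactly one provenance/quality subgroup:

* ``ISOLATION`` — sequenced from a pure culture (``ncbi_genome_category`` is
  "none" or empty);
* ``COMPLETE`` — environmental genome assembled to completion;
* ``HQ`` / ``MQ`` / ``LQ`` — MIMAG high/medium/low-quality MAGs or SAGs;
* ``UNASSIGNED`` — environmental genome with no quality flag set.

The subgroups are forced disjoint with precedence
ISOLATION > COMPLETE > HQ > MQ > LQ: the first rule that fires wins.

The :class:`ReferenceIndex` holds every catalog 16S/SSU sequence and answers
substring and bounded-Hamming queries on both strands, mapping hits back to
genome accessions and their subgroup.
"""

from __future__ import annotations

import bisect
import gzip
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Category",
    "GenomeRecord",
    "CatalogSummary",
    "ReferenceIndex",
    "parse_metadata",
    "assign_category",
    "build_index",
    "summarize_catalog",
    "read_fasta",
    "reverse_complement",
]


class Category(Enum):
    """Genome subgroup; enumeration order is the classification precedence."""

    ISOLATION = "isolation"
    COMPLETE = "complete"
    HQ = "high-quality"
    MQ = "medium-quality"
    LQ = "low-quality"
    UNASSIGNED = "unassigned"


#: Classification precedence, best first. UNASSIGNED is the fallthrough.
CATEGORY_PRECEDENCE: tuple[Category, ...] = (
    Category.ISOLATION,
    Category.COMPLETE,
    Category.HQ,
    Category.MQ,
    Category.LQ,
)

_TAXONOMY_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")

MANDATORY_COLUMNS = ("accession", "gtdb_taxonomy", "ncbi_genome_category")

_TRUE_STRINGS = frozenset({"t", "true", "1"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeRecord:
    """One catalog genome with provenance flags and derived subgroup."""

    accession: str
    domain: str = ""
    taxonomy: str = ""
    ncbi_genome_category: str = ""
    assembly_level: str = ""
    mimag_hq: bool = False
    mimag_mq: bool = False
    mimag_lq: bool = False
    category: Category = Category.UNASSIGNED
    taxonomy_malformed: bool = False

    @property
    def is_isolate(self) -> bool:
        value = self.ncbi_genome_category.strip().lower()
        return value in ("", "none")

    def phylum(self) -> str:
        for rank in self.taxonomy.split(";"):
            rank = rank.strip()
            if rank.startswith("p__"):
                return rank[3:] or "Unclassified"
        return "Unclassified"


def _parse_bool(value: object) -> bool:
    return str(value).strip().lower() in _TRUE_STRINGS


def _taxonomy_ok(taxonomy: str) -> bool:
    ranks = [r.strip() for r in taxonomy.split(";")]
    if len(ranks) != 7:
        return False
    return all(r.startswith(p) for r, p in zip(ranks, _TAXONOMY_PREFIXES))


def _domain_of(taxonomy: str) -> str:
    head = taxonomy.split(";", 1)[0].strip()
    if head.startswith("d__"):
        return head[3:]
    return ""


def assign_category(record: GenomeRecord) -> Category:
    """Assign the subgroup by the first matching rule in precedence order."""
    if record.is_isolate:
        return Category.ISOLATION
    if "complete genome" in record.assembly_level.strip().lower():
        return Category.COMPLETE
    if record.mimag_hq:
        return Category.HQ
    if record.mimag_mq:
        return Category.MQ
    if record.mimag_lq:
        return Category.LQ
    return Category.UNASSIGNED


def parse_metadata(metadata_table) -> list[GenomeRecord]:
    """Parse a GTDB-dialect metadata TSV into classified :class:`GenomeRecord` s.

    Parameters
    ----------
    metadata_table
        Path or readable buffer of a tab-delimited table with a header row.
        Mandatory columns: accession, gtdb_taxonomy, ncbi_genome_category.
        Missing ``ncbi_assembly_level`` or ``mimag_*`` columns default to
        empty / false.

    Raises
    ------
    ValueError
        If a mandatory column is absent (the message names it).
    """
    df = pd.read_csv(metadata_table, sep="\t", dtype=str,
                     keep_default_na=False, comment="#")
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"metadata table is missing mandatory column {col!r}")
    for col in (
        "ncbi_assembly_level",
        "mimag_high_quality",
        "mimag_medium_quality",
        "mimag_low_quality",
    ):
        if col not in df.columns:
            df[col] = ""

    records: list[GenomeRecord] = []
    for row in df.itertuples(index=False):
        taxonomy = str(getattr(row, "gtdb_taxonomy"))
        rec = GenomeRecord(
            accession=str(getattr(row, "accession")),
            domain=_domain_of(taxonomy),
            taxonomy=taxonomy,
            ncbi_genome_category=str(getattr(row, "ncbi_genome_category")),
            assembly_level=str(getattr(row, "ncbi_assembly_level")),
            mimag_hq=_parse_bool(getattr(row, "mimag_high_quality")),
            mimag_mq=_parse_bool(getattr(row, "mimag_medium_quality")),
            mimag_lq=_parse_bool(getattr(row, "mimag_low_quality")),
        )
        rec.taxonomy_malformed = not _taxonomy_ok(taxonomy)
        if rec.taxonomy_malformed:
            logger.warning("malformed taxonomy for %s: %r", rec.accession, taxonomy)
        rec.category = assign_category(rec)
        records.append(rec)
    return records


def read_fasta(path) -> dict[str, list[str]]:
    """Read a (optionally gzipped) FASTA into accession -> list of sequences.

    The accession is the first whitespace-delimited token of the header.
    Sequences are uppercased.
    """
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    out: dict[str, list[str]] = {}
    with opener(path, "rt") as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            out.setdefault(rec.id, []).append(str(rec.seq).upper())
    return out


def _strip_prefix(accession: str) -> str:
    for prefix in ("RS_", "GB_"):
        if accession.startswith(prefix):
            return accession[len(prefix):]
    return accession


class ReferenceIndex:
    """Strand-insensitive substring / bounded-Hamming index over catalog SSUs.

    Every forward SSU sequence is stored; a query hits an entry if the query or
    its reverse complement occurs (exactly, or within a Hamming budget over a
    full-length gapless window) in the forward sequence — equivalent to
    searching both strands.

    Internally all sequences are concatenated with ``#`` separators so exact
    substring scans run in C via :meth:`str.find`; bounded-Hamming queries use
    a pigeonhole seed filter (split the query into ``budget + 1`` chunks, at
    least one of which must match exactly) with per-window verification.
    """

    def __init__(
        self,
        sequences: Mapping[str, Sequence[str]],
        categories: Mapping[str, Category] | None = None,
    ):
        if not sequences or all(not v for v in sequences.values()):
            raise ValueError("reference index needs at least one SSU sequence")
        self.entries: dict[str, list[str]] = {
            acc: [s.upper() for s in seqs] for acc, seqs in sequences.items() if seqs
        }
        self._categories = dict(categories or {})
        # flat segment table for the concatenated scan string
        self._accessions: list[str] = []
        self._segments: list[str] = []
        for acc, seqs in self.entries.items():
            for s in seqs:
                self._accessions.append(acc)
                self._segments.append(s)
        self._concat = "#".join(self._segments)
        self._starts: list[int] = []
        pos = 0
        for s in self._segments:
            self._starts.append(pos)
            pos += len(s) + 1

    # -- construction ---------------------------------------------------

    def without(self, accessions: Iterable[str]) -> "ReferenceIndex":
        """A new index with the listed accessions removed (non-members logged)."""
        remove = set(accessions)
        missing = remove - set(self.entries)
        if missing:
            logger.warning("%d removal accessions not in index: %s",
                           len(missing), sorted(missing)[:5])
        kept = {a: s for a, s in self.entries.items() if a not in remove}
        if not kept:
            raise ValueError("removing these accessions would empty the index")
        return ReferenceIndex(kept, {a: c for a, c in self._categories.items()
                                     if a not in remove})

    def category(self, accession: str) -> Category:
        return self._categories.get(accession, Category.UNASSIGNED)

    @property
    def accessions(self) -> set[str]:
        return set(self.entries)

    # -- queries ---------------------------------------------------------

    def _segment_of(self, pos: int) -> int:
        return bisect.bisect_right(self._starts, pos) - 1

    def _find_exact(self, query: str, hits: set[int]) -> None:
        start = self._concat.find(query)
        while start != -1:
            hits.add(self._segment_of(start))
            start = self._concat.find(query, start + 1)

    def search_exact(self, query: str) -> list[str]:
        """Accessions whose SSU contains the query on either strand, sorted."""
        query = query.upper()
        if not query or "N" in query:
            return []
        segs: set[int] = set()
        self._find_exact(query, segs)
        self._find_exact(reverse_complement(query), segs)
        return sorted({self._accessions[i] for i in segs})

    def search_hamming(self, query: str, max_mismatches: int) -> dict[str, int]:
        """Accession -> minimum Hamming distance over all full-length windows.

        A window is any gapless stretch of query length on either strand.
        ``N`` on either side counts as a mismatch. Only accessions with
        distance <= ``max_mismatches`` are returned.
        """
        query = query.upper()
        if max_mismatches < 0 or not query:
            return {}
        best: dict[str, int] = {}
        for q in (query, reverse_complement(query)):
            if "N" in q:
                self._scan_hamming(q, max_mismatches, best)
            else:
                self._pigeonhole(q, max_mismatches, best)
        return best

    def _record(self, best: dict[str, int], seg: int, dist: int) -> None:
        acc = self._accessions[seg]
        if dist < best.get(acc, 1 << 30):
            best[acc] = dist

    def _verify(self, q: str, seg: int, offset: int) -> int | None:
        """Hamming distance of q vs the window at `offset` within segment, or None."""
        ref = self._segments[seg]
        if offset < 0 or offset + len(q) > len(ref):
            return None
        window = ref[offset:offset + len(q)]
        dist = 0
        for a, b in zip(window, q):
            if a != b or a == "N" or b == "N":
                dist += 1
        return dist

    def _pigeonhole(self, q: str, budget: int, best: dict[str, int]) -> None:
        n_chunks = budget + 1
        L = len(q)
        bounds = [round(i * L / n_chunks) for i in range(n_chunks + 1)]
        seen: set[tuple[int, int]] = set()
        for i in range(n_chunks):
            chunk = q[bounds[i]:bounds[i + 1]]
            if not chunk:
                continue
            start = self._concat.find(chunk)
            while start != -1:
                seg = self._segment_of(start)
                offset = (start - self._starts[seg]) - bounds[i]
                key = (seg, offset)
                if key not in seen:
                    seen.add(key)
                    dist = self._verify(q, seg, offset)
                    if dist is not None and dist <= budget:
                        self._record(best, seg, dist)
                start = self._concat.find(chunk, start + 1)

    def _scan_hamming(self, q: str, budget: int, best: dict[str, int]) -> None:
        # numpy full scan; only used for queries containing N
        qa = np.frombuffer(q.encode(), dtype=np.uint8)
        n_code = ord("N")
        for seg, ref in enumerate(self._segments):
            if len(ref) < len(q):
                continue
            ra = np.frombuffer(ref.encode(), dtype=np.uint8)
            windows = np.lib.stride_tricks.sliding_window_view(ra, len(q))
            mism = (windows != qa) | (windows == n_code) | (qa == n_code)
            dists = mism.sum(axis=1)
            d = int(dists.min())
            if d <= budget:
                self._record(best, seg, d)


def build_index(records: Sequence[GenomeRecord], ssu_fasta) -> ReferenceIndex:
    """Join metadata records with an SSU FASTA into a :class:`ReferenceIndex`.

    FASTA accessions are matched to metadata verbatim first, then with the
    ``RS_`` / ``GB_`` prefix stripped from either side. Accessions present in
    the FASTA but absent from the metadata are indexed as UNASSIGNED and
    logged; genomes with no SSU are excluded (their count is logged).
    """
    sequences = ssu_fasta if isinstance(ssu_fasta, Mapping) else read_fasta(ssu_fasta)
    if not sequences:
        raise ValueError("SSU FASTA contains no sequences; nothing to match against")

    by_accession = {r.accession: r for r in records}
    by_stripped = {_strip_prefix(r.accession): r for r in records}

    categories: dict[str, Category] = {}
    orphans = []
    for acc in sequences:
        rec = by_accession.get(acc) or by_stripped.get(_strip_prefix(acc))
        if rec is None:
            orphans.append(acc)
            categories[acc] = Category.UNASSIGNED
        else:
            categories[acc] = rec.category
    if orphans:
        logger.warning("%d FASTA accessions absent from metadata (kept UNASSIGNED): %s",
                       len(orphans), orphans[:5])
    matched = {_strip_prefix(a) for a in sequences} | set(sequences)
    n_without_ssu = sum(
        1 for r in records
        if r.accession not in matched and _strip_prefix(r.accession) not in matched
    )
    if n_without_ssu:
        logger.info("%d catalog genomes have no SSU sequence and are not indexed",
                    n_without_ssu)
    return ReferenceIndex(sequences, categories)


@dataclass
class CatalogSummary:
    """Counts and percentages by domain x category and by phylum."""

    by_category: pd.DataFrame  # columns: domain, category, count, percent
    by_phylum: pd.DataFrame    # columns: domain, phylum, count, percent
    n_records: int = 0
    excluded_malformed: int = 0

    def percent(self, domain: str, category: Category) -> float:
        df = self.by_category
        sel = df[(df["domain"] == domain) & (df["category"] == category.name)]
        return float(sel["percent"].iloc[0]) if len(sel) else 0.0


def summarize_catalog(records: Sequence[GenomeRecord]) -> CatalogSummary:
    """Tally records by domain x category and by phylum.

    Percentages are of the domain total, rounded to one decimal.
    """
    rows = [
        {"domain": r.domain, "category": r.category.name, "phylum": r.phylum()}
        for r in records
    ]
    if not rows:
        empty = pd.DataFrame(columns=["domain", "category", "count", "percent"])
        empty_p = pd.DataFrame(columns=["domain", "phylum", "count", "percent"])
        return CatalogSummary(empty, empty_p, 0, 0)
    df = pd.DataFrame(rows)
    totals = df.groupby("domain").size()

    by_cat = (
        df.groupby(["domain", "category"]).size().rename("count").reset_index()
    )
    by_cat["percent"] = by_cat.apply(
        lambda r: round(100.0 * r["count"] / totals[r["domain"]], 1), axis=1
    )
    by_phy = df.groupby(["domain", "phylum"]).size().rename("count").reset_index()
    by_phy["percent"] = by_phy.apply(
        lambda r: round(100.0 * r["count"] / totals[r["domain"]], 1), axis=1
    )
    by_phy = by_phy.sort_values(["domain", "count"], ascending=[True, False],
                                kind="stable").reset_index(drop=True)
    n_bad = sum(1 for r in records if r.taxonomy_malformed)
    return CatalogSummary(by_cat, by_phy, len(records), n_bad)
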