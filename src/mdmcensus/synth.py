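"""Synthetic genome catalogs and amplicon worlds with known ground truth.

Real censuses of this kind run on thousands of public amplicon samples and a
full genome catalog; neither is practical to ship or re-download, so every
downstream stage is exercised against generated worlds whose planted
quantities (sequenced-abundance fraction, core set, dark phylum, dependent
OTU pairs, hybrid-genome abundance share) are recorded exactly.

The communities emulate the hyper-dominant rank-abundance structure of
activated-sludge-like ecosystems: per-sample abundances follow a lognormal
rank-abundance law (few taxa above 1% relative abundance, a long rare tail
below 0.1%), a controllable fraction of tags are exact 90-bp substrings of
catalog 16S genes, others carry planted mismatches, and the rest are novel.
Catalog SSUs are uniform i.i.d. DNA — adequate because matching is
exact/Hamming rather than model-based, and accidental 90-mer collisions are
vanishingly improbable.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import Category, GenomeRecord, parse_metadata
from .samples import AmpliconTable

__all__ = [
    "SyntheticCatalog",
    "SyntheticWorld",
    "generate_catalog",
    "generate_community",
    "plant_network_structure",
    "merge_tables",
    "preset",
]

_BASES = np.array(list("ACGT"))

#: GTDB R207-like bacterial subgroup frequencies (isolation, complete, HQ, MQ, LQ).
DEFAULT_CATEGORY_PROBS: dict[Category, float] = {
    Category.ISOLATION: 0.739,
    Category.COMPLETE: 0.001,
    Category.HQ: 0.017,
    Category.MQ: 0.2425,
    Category.LQ: 0.0005,
}

DEFAULT_PHYLA = (
    "Proteobacteria", "Bacteroidota", "Firmicutes", "Actinobacteriota",
    "Chloroflexota", "Myxococcota", "Acidobacteriota",
)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _mutate(rng: np.random.Generator, seq: str, n_mismatches: int) -> str:
    """Substitute ``n_mismatches`` distinct positions with a different base."""
    if n_mismatches == 0:
        return seq
    positions = rng.choice(len(seq), size=n_mismatches, replace=False)
    chars = list(seq)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alternatives[rng.integers(3)]
    return "".join(chars)


# ---------------------------------------------------------------------------
# Catalog generation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCatalog:
    """A generated genome catalog: metadata table, SSU FASTA, and ground truth."""

    metadata: pd.DataFrame
    ssu: dict[str, list[str]]
    truth: dict
    seed: int

    @property
    def records(self) -> list[GenomeRecord]:
        buf = _stdio.StringIO()
        self.metadata.to_csv(buf, sep="\t", index=False)
        buf.seek(0)
        return parse_metadata(buf)

    def write(self, out_dir) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        meta_path = out_dir / "catalog_metadata.tsv"
        with open(meta_path, "w") as fh:
            fh.write(f"# synthetic catalog, seed={self.seed}\n")
            self.metadata.to_csv(fh, sep="\t", index=False)
        fasta_path = out_dir / "catalog_ssu.fasta"
        with open(fasta_path, "w") as fh:
            for acc, seqs in self.ssu.items():
                for i, s in enumerate(seqs):
                    fh.write(f">{acc}{'.' + str(i) if i else ''}\n{s}\n")
        return {"metadata": meta_path, "ssu": fasta_path}


def _flags_for(rng: np.random.Generator, category: Category) -> dict[str, str]:
    """Metadata field values consistent with a target subgroup."""
    t, f = "t", "f"
    if category == Category.ISOLATION:
        return {
            "ncbi_genome_category": "none",
            "ncbi_assembly_level": str(rng.choice(
                ["Complete Genome", "Scaffold", "Contig"])),
            "mimag_high_quality": str(rng.choice([t, f])),
            "mimag_medium_quality": f,
            "mimag_low_quality": f,
        }
    env = str(rng.choice(["derived from metagenome",
                          "derived from environmental sample"]))
    if category == Category.COMPLETE:
        return {"ncbi_genome_category": env,
                "ncbi_assembly_level": "Complete Genome",
                "mimag_high_quality": t, "mimag_medium_quality": f,
                "mimag_low_quality": f}
    level = str(rng.choice(["Scaffold", "Contig"]))
    if category == Category.HQ:
        return {"ncbi_genome_category": env, "ncbi_assembly_level": level,
                "mimag_high_quality": t, "mimag_medium_quality": f,
                "mimag_low_quality": f}
    if category == Category.MQ:
        return {"ncbi_genome_category": env, "ncbi_assembly_level": level,
                "mimag_high_quality": f, "mimag_medium_quality": t,
                "mimag_low_quality": f}
    if category == Category.LQ:
        return {"ncbi_genome_category": env, "ncbi_assembly_level": level,
                "mimag_high_quality": f, "mimag_medium_quality": f,
                "mimag_low_quality": t}
    return {"ncbi_genome_category": env, "ncbi_assembly_level": level,
            "mimag_high_quality": f, "mimag_medium_quality": f,
            "mimag_low_quality": f}


def generate_catalog(
    n_genomes: int,
    category_probs: Mapping[Category, float] | None = None,
    phylum_labels: Sequence[str] = DEFAULT_PHYLA,
    ssu_length: int = 1500,
    seed: int = 0,
    domain: str = "Bacteria",
) -> SyntheticCatalog:
    """Generate a GTDB-dialect catalog with category-consistent metadata flags.

    ``category_probs`` maps subgroups to draw probabilities (must sum to 1;
    defaults mirror the bacterial subgroup frequencies of a recent GTDB
    release). Each genome gets one uniform-random SSU of ``ssu_length``.
    """
    probs = dict(category_probs or DEFAULT_CATEGORY_PROBS)
    total = sum(probs.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"category probabilities sum to {total}, not 1")
    rng = np.random.default_rng(seed)
    cats = list(probs)
    draw = rng.choice(len(cats), size=n_genomes, p=[probs[c] for c in cats])

    rows, ssu, truth_cat, truth_phy = [], {}, {}, {}
    for i in range(n_genomes):
        category = cats[draw[i]]
        accession = f"GB_GCA_{i + 1:09d}.1"
        phylum = str(phylum_labels[i % len(phylum_labels)])
        taxonomy = (f"d__{domain};p__{phylum};c__C{i % 3 + 1};o__O1;"
                    f"f__F{i % 5 + 1};g__G{i + 1};s__G{i + 1} sp{i + 1}")
        rows.append({"accession": accession, "gtdb_taxonomy": taxonomy,
                     **_flags_for(rng, category)})
        ssu[accession] = [_random_dna(rng, ssu_length)]
        truth_cat[accession] = category
        truth_phy[accession] = phylum
    metadata = pd.DataFrame(rows, columns=[
        "accession", "gtdb_taxonomy", "ncbi_genome_category",
        "ncbi_assembly_level", "mimag_high_quality", "mimag_medium_quality",
        "mimag_low_quality"])
    tallies = {c.name: int((draw == cats.index(c)).sum()) for c in cats}
    return SyntheticCatalog(
        metadata=metadata, ssu=ssu,
        truth={"categories": truth_cat, "phyla": truth_phy,
               "category_counts": tallies, "domain": domain},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Community generation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticWorld:
    """An amplicon world with its generating catalog and full ground truth."""

    table: AmpliconTable
    catalog: SyntheticCatalog
    taxonomy: dict[str, str]
    truth: dict = field(default_factory=dict)


def _greedy_subset(
    weights: np.ndarray, target: float, rng: np.random.Generator,
    big_cut: float = 0.005,
) -> np.ndarray:
    """Indices whose weights sum as close to ``target`` from below as the
    weight granularity allows.

    Big weights (> ``big_cut``) are admitted by a shuffled greedy pass capped
    below the target so the many small weights retain room to fine-fill; the
    final ascending pass closes the gap to within the smallest unchosen
    weight. Keeps the sequenced/unsequenced split random among dominant taxa
    rather than systematically sequencing the most abundant ones.
    """
    chosen = np.zeros(len(weights), dtype=bool)
    small = weights <= big_cut
    reserve = 0.5 * float(weights[small].sum())
    big_target = max(0.0, target - reserve)
    total = 0.0
    big_idx = np.where(~small)[0]
    for i in rng.permutation(big_idx):
        if total + weights[i] <= big_target + 1e-12:
            chosen[i] = True
            total += weights[i]
    small_idx = np.where(small)[0]
    for i in rng.permutation(small_idx):
        if total + weights[i] <= target + 1e-12:
            chosen[i] = True
            total += weights[i]
    rest = np.where(~chosen)[0]
    for i in rest[np.argsort(weights[rest])]:
        if total + weights[i] <= target + 1e-12:
            chosen[i] = True
            total += weights[i]
    return np.where(chosen)[0]


def generate_community(
    catalog: SyntheticCatalog,
    n_samples: int,
    n_taxa: int,
    f_sequenced_abundance: float,
    dominance_shape: float = 1.3,
    rare_tail_fraction: float = 0.8,
    mismatch_spectrum: Mapping[int, float] | None = None,
    n_reads_range: tuple[int, int] = (25000, 60000),
    seed: int = 0,
    environment: str = "AS",
    sample_noise_sigma: float = 0.25,
    asv_length: int = 90,
    n_core: int = 0,
    core_prevalence: float = 0.95,
    other_prevalence: tuple[float, float] | None = None,
    dark_phylum: str | None = None,
    n_dark_taxa: int = 3,
    hybrid_abundance_share: float = 0.0,
    sample_prefix: str = "S",
    f_tolerance: float = 0.02,
) -> SyntheticWorld:
    """Generate an amplicon world over a synthetic catalog.

    Parameters
    ----------
    f_sequenced_abundance
        Target fraction of total relative abundance carried by taxa whose tag
        is planted from a catalog SSU (within the mismatch spectrum). Fatal if
        unattainable within 0.02 given the drawn rank-abundance weights.
    dominance_shape
        Sigma of the lognormal rank-abundance law; larger = stronger
        hyper-dominance.
    rare_tail_fraction
        Fraction of taxa squeezed into the sub-0.1% rare tail.
    mismatch_spectrum
        Distribution of planted mismatch counts for sequenced taxa, e.g.
        ``{0: 0.8, 1: 0.1, 2: 0.1}``; default all exact (0 mismatches).
    n_core / core_prevalence / other_prevalence
        When ``other_prevalence`` is given, per-sample presence is Bernoulli:
        ``n_core`` planted core taxa are present with ``core_prevalence``,
        the rest with probabilities drawn uniformly from ``other_prevalence``.
        Otherwise every taxon can occur in every sample.
    dark_phylum
        When set, ``n_dark_taxa`` high-abundance *unsequenced* taxa get this
        phylum label and all other unsequenced taxa are left Unclassified, so
        the planted phylum is the unique under-represented one.
    hybrid_abundance_share
        Share of total abundance carried by sequenced taxa whose only source
        genome comes from a dedicated "hybrid-only" accession pool (recorded
        in the truth for ablation experiments).
    """
    rng = np.random.default_rng(seed)
    spectrum = dict(mismatch_spectrum or {0: 1.0})
    if abs(sum(spectrum.values()) - 1.0) > 1e-9:
        raise ValueError("mismatch_spectrum probabilities must sum to 1")
    if not 0.0 <= f_sequenced_abundance <= 1.0:
        raise ValueError("f_sequenced_abundance must be in [0, 1]")

    # -- rank-abundance weights -----------------------------------------
    weights = np.sort(rng.lognormal(0.0, dominance_shape, size=n_taxa))[::-1]
    weights /= weights.sum()
    n_tail = int(round(rare_tail_fraction * n_taxa))
    if n_tail > 0:
        tail = slice(n_taxa - n_tail, n_taxa)
        cap = 0.0008
        scale = np.minimum(1.0, cap / np.maximum(weights[tail], 1e-300))
        weights[tail] *= scale
        weights /= weights.sum()

    asv_ids = [f"ASV_{i + 1:05d}" for i in range(n_taxa)]

    core_idx = np.array([], dtype=int)
    if n_core > 0:
        top = max(n_core, n_taxa // 4)
        core_idx = rng.choice(top, size=n_core, replace=False)
        weights[core_idx] = np.maximum(weights[core_idx], 0.004)
        weights /= weights.sum()

    # -- which taxa are sequenced ---------------------------------------
    if f_sequenced_abundance >= 1.0:
        seq_idx = np.arange(n_taxa)
    elif f_sequenced_abundance <= 0.0:
        seq_idx = np.array([], dtype=int)
    else:
        seq_idx = _greedy_subset(weights, f_sequenced_abundance, rng)
    achieved_f = float(weights[seq_idx].sum())
    if abs(achieved_f - f_sequenced_abundance) > f_tolerance:
        raise ValueError(
            f"cannot plant sequenced-abundance fraction "
            f"{f_sequenced_abundance} with n_taxa={n_taxa}: closest "
            f"achievable is {achieved_f:.3f}; increase n_taxa or the rare tail"
        )
    is_seq = np.zeros(n_taxa, dtype=bool)
    is_seq[seq_idx] = True

    # -- hybrid-only subset among the sequenced taxa --------------------
    hybrid_taxa = np.array([], dtype=int)
    if hybrid_abundance_share > 0:
        if hybrid_abundance_share > achieved_f + 1e-9:
            raise ValueError("hybrid share cannot exceed the sequenced share")
        sub = _greedy_subset(weights[seq_idx], hybrid_abundance_share, rng)
        hybrid_taxa = seq_idx[sub]
    achieved_h = float(weights[hybrid_taxa].sum())
    is_hybrid = np.zeros(n_taxa, dtype=bool)
    is_hybrid[hybrid_taxa] = True

    # -- sequences, origins, taxonomy -----------------------------------
    accessions = list(catalog.ssu)
    non_hybrid_pool = [a for a in accessions]
    hybrid_pool: list[str] = []
    if len(hybrid_taxa) > 0:
        if len(accessions) < len(hybrid_taxa) + 1:
            raise ValueError("catalog too small for a dedicated hybrid pool")
        chosen = rng.choice(len(accessions), size=len(hybrid_taxa), replace=False)
        hybrid_pool = [accessions[i] for i in chosen]
        non_hybrid_pool = [a for a in accessions if a not in set(hybrid_pool)]

    mism_values = sorted(spectrum)
    mism_probs = [spectrum[m] for m in mism_values]

    sequences: dict[str, str] = {}
    taxonomy: dict[str, str] = {}
    origin: dict[str, str | None] = {}
    planted_mismatches: dict[str, int] = {}
    used: set[str] = set()
    ssu_len = len(next(iter(catalog.ssu.values()))[0])
    hybrid_iter = iter(hybrid_pool)
    novel_phyla = [f"CandidatusNova{i + 1}" for i in range(6)]

    for i, asv in enumerate(asv_ids):
        if is_seq[i]:
            acc = (next(hybrid_iter) if is_hybrid[i]
                   else non_hybrid_pool[rng.integers(len(non_hybrid_pool))])
            m = int(rng.choice(mism_values, p=mism_probs))
            for _ in range(100):
                offset = int(rng.integers(0, ssu_len - asv_length + 1))
                tag = _mutate(rng, catalog.ssu[acc][0][offset:offset + asv_length], m)
                if tag not in used:
                    break
            origin[asv] = acc
            planted_mismatches[asv] = m
            taxonomy[asv] = (f"d__{catalog.truth['domain']};"
                             f"p__{catalog.truth['phyla'][acc]};c__;o__;f__;g__;s__")
        else:
            for _ in range(100):
                tag = _random_dna(rng, asv_length)
                if tag not in used:
                    break
            origin[asv] = None
            planted_mismatches[asv] = -1
            if dark_phylum is not None:
                taxonomy[asv] = "d__Bacteria;p__;c__;o__;f__;g__;s__"
            else:
                phylum = novel_phyla[int(rng.integers(len(novel_phyla)))]
                taxonomy[asv] = f"d__Bacteria;p__{phylum};c__;o__;f__;g__;s__"
        used.add(tag)
        sequences[asv] = tag

    dark_taxa: list[str] = []
    if dark_phylum is not None:
        unseq = np.where(~is_seq)[0]
        if len(unseq) < n_dark_taxa:
            raise ValueError("not enough unsequenced taxa for the dark phylum")
        by_weight = unseq[np.argsort(-weights[unseq])][:n_dark_taxa]
        for i in by_weight:
            taxonomy[asv_ids[i]] = f"d__Bacteria;p__{dark_phylum};c__;o__;f__;g__;s__"
            dark_taxa.append(asv_ids[i])

    # -- per-sample presence and counts ----------------------------------
    presence_prob = np.ones(n_taxa)
    if other_prevalence is not None:
        presence_prob = rng.uniform(*other_prevalence, size=n_taxa)
        presence_prob[core_idx] = core_prevalence

    sample_ids = [f"{sample_prefix}{j + 1:04d}" for j in range(n_samples)]
    counts = np.zeros((n_samples, n_taxa), dtype=np.int64)
    latent_f = np.zeros(n_samples)
    for j in range(n_samples):
        present = rng.random(n_taxa) < presence_prob
        w = weights * present * np.exp(
            rng.normal(0.0, sample_noise_sigma, size=n_taxa))
        if w.sum() == 0:
            w = weights.copy()
        p = w / w.sum()
        latent_f[j] = float(p[is_seq].sum())
        depth = int(rng.integers(n_reads_range[0], n_reads_range[1] + 1))
        counts[j] = rng.multinomial(depth, p)

    table = AmpliconTable(
        counts=pd.DataFrame(counts, index=sample_ids, columns=asv_ids),
        sequences=sequences,
        environments=pd.Series(environment, index=sample_ids),
    )
    truth = {
        "seed": seed,
        "environment": environment,
        "f_target": f_sequenced_abundance,
        "f_achieved": achieved_f,
        "latent_f_per_sample": {s: float(v) for s, v in zip(sample_ids, latent_f)},
        "sequenced_asvs": [asv_ids[i] for i in seq_idx],
        "origin": origin,
        "planted_mismatches": planted_mismatches,
        "global_weights": {a: float(w) for a, w in zip(asv_ids, weights)},
        "core_asvs": [asv_ids[i] for i in sorted(core_idx)],
        "dark_phylum": dark_phylum,
        "dark_asvs": dark_taxa,
        "hybrid_accessions": sorted(hybrid_pool),
        "hybrid_asvs": [asv_ids[i] for i in sorted(hybrid_taxa)],
        "h_achieved": achieved_h,
        "dependent_pairs": [],
    }
    return SyntheticWorld(table=table, catalog=catalog,
                          taxonomy=taxonomy, truth=truth)


def plant_network_structure(
    table: AmpliconTable,
    dependent_pairs: Sequence[tuple[str, str]],
    effect_size: float,
    seed: int = 0,
) -> AmpliconTable:
    """Inject correlated latent abundance into listed taxon pairs.

    Each pair shares a per-sample standard-normal latent factor scaled by
    ``effect_size`` that multiplies both members' latent abundance before the
    per-sample multinomial is re-drawn at the original depth. Effect size 0
    reduces to a plain resampling of the table.
    """
    for a, b in dependent_pairs:
        for x in (a, b):
            if x not in table.counts.columns:
                raise ValueError(f"pair member {x!r} not in table")
    rng = np.random.default_rng(seed)
    counts = table.counts.values.astype(float)
    latent = counts + 0.5
    cols = list(table.counts.columns)
    col_idx = {c: i for i, c in enumerate(cols)}
    n_samples = counts.shape[0]
    for a, b in dependent_pairs:
        z = rng.normal(0.0, 1.0, size=n_samples)
        boost = np.exp(effect_size * z)
        latent[:, col_idx[a]] *= boost
        latent[:, col_idx[b]] *= boost
    depths = counts.sum(axis=1).astype(np.int64)
    new_counts = np.zeros_like(counts, dtype=np.int64)
    for j in range(n_samples):
        p = latent[j] / latent[j].sum()
        new_counts[j] = rng.multinomial(depths[j], p)
    return AmpliconTable(
        counts=pd.DataFrame(new_counts, index=table.counts.index, columns=cols),
        sequences=dict(table.sequences),
        environments=table.environments.copy(),
    )


def merge_tables(tables: Sequence[AmpliconTable]) -> AmpliconTable:
    """Stack amplicon tables over the union of their ASVs (zeros fill gaps)."""
    counts = pd.concat([t.counts for t in tables], axis=0).fillna(0).astype(np.int64)
    sequences: dict[str, str] = {}
    for t in tables:
        sequences.update(t.sequences)
    envs = pd.concat([t.environments for t in tables])
    return AmpliconTable(counts=counts, sequences=sequences, environments=envs)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def preset(name: str, seed: int = 0) -> SyntheticWorld:
    """Named study-like worlds.

    * ``as_like`` — one activated-sludge-like environment: 60 samples, 250
      taxa, half the abundance sequenced, strong dominance, planted core set
      and a dark phylum.
    * ``emp_like`` — three environments with different sequenced fractions
      for cross-environment summaries.
    * ``ablation`` — a world where hybrid-only genomes carry 30% of abundance.
    * ``network`` — 200 samples over few taxa with planted dependent pairs.
    """
    rng = np.random.default_rng(seed)
    sub = [int(x) for x in rng.integers(0, 2**31 - 1, size=8)]
    if name == "as_like":
        catalog = generate_catalog(150, seed=sub[0])
        world = generate_community(
            catalog, n_samples=60, n_taxa=250, f_sequenced_abundance=0.5,
            mismatch_spectrum={0: 0.8, 1: 0.1, 2: 0.1}, seed=sub[1],
            n_core=12, other_prevalence=(0.05, 0.15),
            dark_phylum="Patescibacteria")
        return world
    if name == "emp_like":
        catalog = generate_catalog(150, seed=sub[0])
        worlds = [
            generate_community(catalog, 25, 200, f, seed=s, environment=env,
                               sample_prefix=env + "_")
            for f, s, env in zip((0.65, 0.5, 0.4), sub[1:4],
                                 ("AS", "biofilm", "DS"))
        ]
        merged = merge_tables([w.table for w in worlds])
        taxonomy = {}
        for w in worlds:
            taxonomy.update(w.taxonomy)
        truth = {"environments": {w.truth["environment"]: w.truth for w in worlds}}
        return SyntheticWorld(table=merged, catalog=catalog,
                              taxonomy=taxonomy, truth=truth)
    if name == "ablation":
        catalog = generate_catalog(200, seed=sub[0])
        return generate_community(
            catalog, n_samples=40, n_taxa=250, f_sequenced_abundance=0.6,
            hybrid_abundance_share=0.3, seed=sub[1])
    if name == "network":
        catalog = generate_catalog(40, seed=sub[0])
        world = generate_community(
            catalog, n_samples=200, n_taxa=15, f_sequenced_abundance=0.5,
            dominance_shape=1.0, rare_tail_fraction=0.0,
            sample_noise_sigma=0.5, n_reads_range=(25000, 40000), seed=sub[1],
            # f is not a planted quantity of this preset; 15 coarse taxa
            # cannot hit an abundance-share target tightly
            f_tolerance=1.0)
        asvs = world.table.asv_ids
        pairs = [(asvs[0], asvs[1]), (asvs[2], asvs[3]), (asvs[4], asvs[5])]
        world.table = plant_network_structure(world.table, pairs,
                                              effect_size=2.0, seed=sub[2])
        world.truth["dependent_pairs"] = pairs
        return world
    raise ValueError(f"unknown preset {name!r}")
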