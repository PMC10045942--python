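"""Shared readers/writers, run configuration, and the pipeline driver.

Canonical table dialect: tab-delimited UTF-8 with ``#`` comment lines, gzip
transparently supported. BIOM tables are consumed via their TSV export only
(no HDF5 dependency in the core).
"""

from __future__ import annotations

import gzip
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .samples import AmpliconTable

logger = logging.getLogger(__name__)

__all__ = [
    "read_tsv",
    "write_tsv",
    "read_amplicon_table",
    "write_amplicon_table",
    "write_fasta",
    "read_asv_fasta",
    "RunConfig",
    "run_pipeline",
]


def _opener(path: Path, mode: str):
    return gzip.open(path, mode + "t") if path.suffix == ".gz" else open(path, mode)


def read_tsv(path, index_col=None) -> pd.DataFrame:
    path = Path(path)
    with _opener(path, "r") as fh:
        return pd.read_csv(fh, sep="\t", comment="#", index_col=index_col)


def write_tsv(df: pd.DataFrame, path, index: bool = False,
              comment: str | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with _opener(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=index)
    return path


def write_fasta(sequences: dict[str, str], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with _opener(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")
    return path


def read_asv_fasta(path) -> dict[str, str]:
    """ASV FASTA as id -> uppercase sequence (ids must be unique)."""
    from Bio import SeqIO

    path = Path(path)
    out: dict[str, str] = {}
    with _opener(path, "r") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in out:
                raise ValueError(f"duplicate ASV id {rec.id!r} in {path}")
            out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"no sequences in FASTA {path}")
    return out


def write_amplicon_table(table: AmpliconTable, out_dir) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts = table.counts.copy()
    counts.index.name = "sample_id"
    paths = {
        "counts": write_tsv(counts, out_dir / "counts.tsv", index=True),
        "sequences": write_fasta(table.sequences, out_dir / "asvs.fasta"),
        "metadata": write_tsv(
            pd.DataFrame({"sample_id": table.counts.index,
                          "environment": table.environments.values}),
            out_dir / "sample_metadata.tsv"),
    }
    return paths


def read_amplicon_table(in_dir) -> AmpliconTable:
    in_dir = Path(in_dir)
    counts = read_tsv(in_dir / "counts.tsv", index_col="sample_id")
    sequences = read_asv_fasta(in_dir / "asvs.fasta")
    meta = read_tsv(in_dir / "sample_metadata.tsv")
    envs = pd.Series(meta["environment"].values, index=meta["sample_id"].values)
    return AmpliconTable(counts=counts, sequences=sequences, environments=envs)


# ---------------------------------------------------------------------------
# Run configuration and pipeline driver
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything a full pipeline run needs; round-trips through YAML."""

    out_dir: str = "mdm_out"
    seed: int = 17
    tiers: tuple[float, ...] = (100.0, 98.7, 97.0)
    active_tier: float = 100.0
    rarefaction_depth: int = 20000
    prevalence: float = 0.40
    min_mean_abundance: float = 0.001
    network_prevalence: float = 0.30
    zi_threshold: float = 2.5
    pi_threshold: float = 0.62
    metadata_path: str | None = None
    ssu_path: str | None = None
    amplicon_dir: str | None = None
    synth_preset: str | None = None

    def __post_init__(self) -> None:
        self.tiers = tuple(float(t) for t in self.tiers)
        for name in ("prevalence", "network_prevalence"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.rarefaction_depth < 1:
            raise ValueError("rarefaction_depth must be positive")

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self)))
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> Path:
    """Run catalog -> match -> census -> wanted on real or preset inputs.

    Writes every stage's tables under ``config.out_dir`` plus a
    ``manifest.json`` listing each output with its sha256 checksum and the
    config used. On stage failure, partial outputs are kept next to a
    ``FAILED`` marker naming the stage.
    """
    from . import census as census_mod
    from . import catalog as catalog_mod
    from . import matching, samples, wanted
    from .matching import match_table_frame
    from .synth import preset
    from .wanted import topology_frame

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stage = "setup"
    try:
        # ---- inputs -----------------------------------------------------
        stage = "inputs"
        if config.synth_preset:
            world = preset(config.synth_preset, seed=config.seed)
            table = world.table
            records = world.catalog.records
            ssu = world.catalog.ssu
            taxonomy = world.taxonomy
            synth_paths = world.catalog.write(out / "synth")
            outputs.update({f"synth_{k}": v for k, v in synth_paths.items()})
            outputs.update({f"amplicon_{k}": v for k, v in
                            write_amplicon_table(table, out / "synth").items()})
        else:
            if not (config.metadata_path and config.ssu_path
                    and config.amplicon_dir):
                raise ValueError("need metadata_path, ssu_path and amplicon_dir "
                                 "(or a synth_preset)")
            records = catalog_mod.parse_metadata(config.metadata_path)
            ssu = catalog_mod.read_fasta(config.ssu_path)
            table = read_amplicon_table(config.amplicon_dir)
            taxonomy = {}

        # ---- catalog ----------------------------------------------------
        stage = "catalog"
        index = catalog_mod.build_index(records, ssu)
        summary = catalog_mod.summarize_catalog(records)
        outputs["catalog_summary"] = write_tsv(
            summary.by_category, out / "catalog_summary.tsv")
        outputs["catalog_phyla"] = write_tsv(
            summary.by_phylum, out / "catalog_phyla.tsv")

        # ---- match ------------------------------------------------------
        stage = "match"
        results = matching.classify_table(table.sequences, index, config.tiers)
        outputs["matches"] = write_tsv(
            match_table_frame(results), out / "matches.tsv")

        # ---- census -----------------------------------------------------
        stage = "census"
        rarefied, flags = samples.rarefy_table(
            table, config.rarefaction_depth, seed=config.seed)
        alpha = samples.alpha_diversity_table(rarefied)
        censuses = []
        for tier in config.tiers:
            cs = census_mod.census_table(table, results, tier)
            for c in cs:
                if c.sample_id in alpha.index:
                    c.alpha = alpha.loc[c.sample_id].to_dict()
            censuses.extend(cs)
        per_sample = pd.DataFrame([
            {"sample_id": c.sample_id, "environment": c.environment,
             "tier": c.tier, "p_number": c.p_number,
             "p_abundance": c.p_abundance, "n_present": c.n_present,
             "rarefaction": flags.get(c.sample_id, "")}
            for c in censuses])
        outputs["census"] = write_tsv(per_sample, out / "census_per_sample.tsv")
        outputs["environment_summary"] = write_tsv(
            census_mod.environment_summary(censuses),
            out / "environment_summary.tsv")
        rel = table.relative_abundance()
        active = [c for c in censuses if c.tier == config.active_tier]
        parts = []
        for c in active:
            p = samples.abundance_partition(rel.loc[c.sample_id], results,
                                            tier=config.active_tier)
            parts.append({"sample_id": c.sample_id, **vars(p)})
        outputs["abundance_partition"] = write_tsv(
            pd.DataFrame(parts), out / "abundance_partition.tsv")
        with_alpha = [c for c in active if c.alpha]
        if len(with_alpha) >= 3:
            outputs["diversity_correlation"] = write_tsv(
                census_mod.correlate_with_diversity(with_alpha),
                out / "diversity_correlation.tsv")

        # ---- wanted list ------------------------------------------------
        stage = "wanted"
        otu_table = wanted.build_otu_table(table, taxonomy=taxonomy)
        otu_results = {}
        for otu, centroid in otu_table.centroid.items():
            otu_results[centroid] = results[centroid]
        core = wanted.prevalence_filter(
            otu_table, config.prevalence, config.min_mean_abundance)
        network = wanted.infer_network(
            otu_table, config.network_prevalence, seed=config.seed)
        modules = wanted.detect_modules(network, seed=config.seed)
        topology = wanted.node_topology(network, modules)
        member_results = {a: r for a, r in results.items()}
        flagged = wanted.flag_underrepresented_phyla(
            otu_table, member_results, tier=config.active_tier)
        wlist = wanted.assemble_wanted_list(
            core, topology, member_results, flagged, otu_table,
            index=index, tier=config.active_tier)
        outputs["otu_counts"] = write_tsv(
            otu_table.counts.rename_axis("sample_id"),
            out / "otu_counts.tsv", index=True)
        outputs["edges"] = write_tsv(
            pd.DataFrame([{"source": u, "target": v,
                           "weight": d.get("weight", float("nan"))}
                          for u, v, d in network.edges(data=True)],
                         columns=["source", "target", "weight"]),
            out / "network_edges.tsv")
        outputs["topology"] = write_tsv(topology_frame(topology),
                                        out / "node_topology.tsv")
        outputs["wanted"] = write_tsv(wlist.entries, out / "wanted_list.tsv")
        outputs["flagged_phyla"] = write_tsv(
            pd.DataFrame({"phylum": wlist.flagged_phyla}),
            out / "flagged_phyla.tsv")
    except Exception as exc:  # keep partial outputs, mark the failed stage
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise StageError(stage, exc) from exc

    stage = "manifest"
    manifest = {
        "config": asdict(config),
        "outputs": {k: {"path": str(p.relative_to(out)), "sha256": _sha256(p)}
                    for k, p in outputs.items()},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path
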