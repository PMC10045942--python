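"""The "wanted list": prioritizing unsequenced taxa in a community.

Candidate taxa enter the list through two computed criteria plus one
inspection-driven flag:

* **prevalence** — operational taxonomic units (OTUs, ASVs clustered at 97%
  identity) present in more than 40% of samples with mean relative abundance
  above 0.1% (the usual "core microbiome" rule; tight = 50%, loose = 30%);
* **priority** — hub nodes of a co-occurrence network inferred by sparse
  neighborhood selection on centered log-ratio (CLR) transformed counts, with
  hubs defined on the Zi-Pi plane (within-module degree z-score vs
  among-module participation coefficient; thresholds 2.5 and 0.62);
* **under-represented phyla** — among the most abundant phyla, those whose
  abundance is mostly carried by OTUs without a sequenced genome.

Each listed OTU gets a knowledge status: ISOLATE (a pure-culture genome
matches), GENOME_ONLY (only MAG/SAG matches), or DARK (no genome at all).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso

from .catalog import Category, reverse_complement
from .matching import MatchResult, mismatch_budget
from .samples import AmpliconTable

logger = logging.getLogger(__name__)

__all__ = [
    "OTUTable",
    "NodeTopology",
    "Role",
    "KnowledgeStatus",
    "WantedList",
    "cluster_otus",
    "build_otu_table",
    "prevalence_filter",
    "clr_transform",
    "infer_network",
    "detect_modules",
    "node_topology",
    "flag_underrepresented_phyla",
    "assemble_wanted_list",
    "cross_environment_max",
]

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62


class Role(Enum):
    PERIPHERAL = "peripheral"
    CONNECTOR = "connector"
    MODULE_HUB = "module hub"
    NETWORK_HUB = "network hub"


class KnowledgeStatus(Enum):
    ISOLATE = "isolate"
    GENOME_ONLY = "genome only"
    DARK = "dark"


# ---------------------------------------------------------------------------
# OTU clustering
# ---------------------------------------------------------------------------

def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def cluster_otus(
    asv_sequences: Mapping[str, str],
    global_abundances: Mapping[str, float],
    identity: float = 0.97,
) -> tuple[dict[str, str], dict[str, list[str]]]:
    """Greedy centroid clustering of equal-length ASVs at an identity level.

    ASVs are processed by decreasing total abundance (ties broken by sequence,
    then id, lexicographically); each joins the first existing centroid within
    the Hamming mismatch budget (length 90 at 97% -> 2 mismatches), else
    founds a new OTU. Returns (otu_id -> centroid asv_id, otu_id -> members).

    Raises ``ValueError`` on mixed sequence lengths (one trimmed region is
    required upstream).
    """
    if not asv_sequences:
        return {}, {}
    lengths = {len(s) for s in asv_sequences.values()}
    if len(lengths) != 1:
        raise ValueError(
            f"mixed ASV lengths {sorted(lengths)}; trim to one region first"
        )
    length = lengths.pop()
    budget = mismatch_budget(length, identity * 100)

    order = sorted(
        asv_sequences,
        key=lambda a: (-float(global_abundances.get(a, 0.0)), asv_sequences[a], a),
    )
    centroids: list[tuple[str, str]] = []  # (otu_id, sequence)
    membership: dict[str, list[str]] = {}
    centroid_of: dict[str, str] = {}
    for asv in order:
        seq = asv_sequences[asv]
        for otu_id, cseq in centroids:
            if _hamming(seq, cseq) <= budget:
                membership[otu_id].append(asv)
                break
        else:
            otu_id = f"OTU_{len(centroids) + 1}"
            centroids.append((otu_id, seq))
            membership[otu_id] = [asv]
            centroid_of[otu_id] = asv
    return centroid_of, membership


@dataclass
class OTUTable:
    """OTUs with per-sample aggregated counts and centroid bookkeeping."""

    centroid: dict[str, str]          # otu_id -> centroid asv_id
    membership: dict[str, list[str]]  # otu_id -> member asv_ids
    counts: pd.DataFrame              # samples x otus, summed member counts
    sequences: dict[str, str]         # otu_id -> centroid sequence
    taxonomy: dict[str, str] = field(default_factory=dict)  # otu_id -> label

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        return self.counts.div(totals.where(totals > 0, 1), axis=0)

    def prevalence(self) -> pd.Series:
        """Fraction of samples where each OTU has a nonzero count."""
        return (self.counts > 0).mean(axis=0)

    def phylum_of(self, otu_id: str) -> str:
        label = self.taxonomy.get(otu_id, "")
        for rank in label.split(";"):
            rank = rank.strip()
            if rank.startswith("p__"):
                return rank[3:] or "Unclassified"
        return "Unclassified"


def build_otu_table(
    table: AmpliconTable,
    identity: float = 0.97,
    taxonomy: Mapping[str, str] | None = None,
) -> OTUTable:
    """Cluster an amplicon table's ASVs into OTUs and aggregate counts.

    The OTU taxonomy label is the centroid ASV's label (consumed as given).
    """
    mean_abund = table.mean_relative_abundance().to_dict()
    seqs = {a: table.sequences[a] for a in table.asv_ids}
    centroid_of, membership = cluster_otus(seqs, mean_abund, identity)
    counts = pd.DataFrame(
        {otu: table.counts[members].sum(axis=1)
         for otu, members in membership.items()},
        index=table.counts.index,
    )
    otu_tax = {}
    if taxonomy:
        otu_tax = {otu: taxonomy.get(centroid_of[otu], "") for otu in membership}
    return OTUTable(
        centroid=centroid_of,
        membership=membership,
        counts=counts,
        sequences={otu: seqs[c] for otu, c in centroid_of.items()},
        taxonomy=otu_tax,
    )


# ---------------------------------------------------------------------------
# Prevalence (core-microbiome) filter
# ---------------------------------------------------------------------------

def prevalence_filter(
    otu_table: OTUTable,
    min_prevalence: float = 0.40,
    min_mean_abundance: float = 0.001,
    per_sample_anywhere: bool = False,
) -> set[str]:
    """Core OTUs: present in more than ``min_prevalence`` of samples with
    relative abundance above ``min_mean_abundance`` (both strict).

    Presets: default 0.40, tight 0.50, loose 0.30. The abundance criterion is
    the mean relative abundance across all samples; set
    ``per_sample_anywhere`` to accept OTUs exceeding it in any single sample
    instead.
    """
    prev = otu_table.prevalence()
    rel = otu_table.relative_abundance()
    abund = rel.max(axis=0) if per_sample_anywhere else rel.mean(axis=0)
    keep = (prev > min_prevalence) & (abund > min_mean_abundance)
    return set(keep.index[keep])


# ---------------------------------------------------------------------------
# Co-occurrence network: CLR + neighborhood selection + stability selection
# ---------------------------------------------------------------------------

def clr_transform(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-sample centered log-ratio transform of a count table."""
    logged = np.log(counts.astype(float) + pseudocount)
    return logged.sub(logged.mean(axis=1), axis=0)


def _neighborhood_edges(X: np.ndarray, alpha: float) -> set[tuple[int, int]]:
    """Edge set from per-node lasso regressions at one penalty, OR-rule."""
    n, p = X.shape
    edges: set[tuple[int, int]] = set()
    model = Lasso(alpha=alpha, fit_intercept=True, max_iter=5000)
    for i in range(p):
        y = X[:, i]
        others = np.delete(np.arange(p), i)
        model.fit(X[:, others], y)
        for j_local in np.nonzero(model.coef_)[0]:
            j = others[j_local]
            edges.add((min(i, j), max(i, j)))
    return edges


def _lambda_path(X: np.ndarray, n_lambda: int, ratio: float = 0.01) -> np.ndarray:
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    lam_max = 0.0
    for i in range(p):
        others = np.delete(np.arange(p), i)
        lam_max = max(lam_max, np.abs(Xc[:, others].T @ Xc[:, i]).max() / n)
    lam_max = max(lam_max, 1e-6)
    return np.logspace(np.log10(lam_max), np.log10(lam_max * ratio), n_lambda)


def infer_network(
    otu_table: OTUTable,
    node_prevalence_filter: float = 0.30,
    method: str = "neighborhood_selection",
    seed: int = 0,
    n_lambda: int = 20,
    n_subsamples: int = 20,
    subsample_ratio: float = 0.8,
    instability_threshold: float = 0.05,
) -> nx.Graph:
    """Infer a co-occurrence network by sparse neighborhood selection.

    Pipeline: (1) restrict to OTUs present in more than
    ``node_prevalence_filter`` of samples; (2) add pseudocount 1 and CLR
    transform per sample; (3) for each node, lasso-regress its CLR abundance
    on all others over a log-spaced ``n_lambda`` penalty path; (4) pick the
    penalty by stability selection over ``n_subsamples`` random subsamples of
    ``subsample_ratio`` of the samples — the densest penalty whose
    monotonized edge-instability stays within ``instability_threshold``;
    (5) refit on all samples at that penalty, symmetrizing by the OR rule.

    Deterministic given ``seed``. Raises on fewer than 10 samples (stability
    selection is meaningless there). With a single subsample and a single
    penalty the procedure degenerates to one lasso fit per node.
    """
    if method != "neighborhood_selection":
        raise ValueError(f"unknown method {method!r}")
    prev = otu_table.prevalence()
    nodes = [o for o in otu_table.otu_ids if prev[o] > node_prevalence_filter]
    counts = otu_table.counts[nodes]
    n_samples = len(counts)
    if n_samples < 10:
        raise ValueError("network inference needs at least 10 samples")
    if len(nodes) > n_samples:
        logger.warning("more nodes (%d) than samples (%d); estimates unstable",
                       len(nodes), n_samples)
    G = nx.Graph()
    G.add_nodes_from(nodes)
    if len(nodes) < 2:
        return G

    X = clr_transform(counts).values
    lambdas = _lambda_path(X, n_lambda)
    rng = np.random.default_rng(seed)
    m = max(2, int(round(subsample_ratio * n_samples)))
    subsamples = [rng.choice(n_samples, size=m, replace=False)
                  for _ in range(n_subsamples)]

    p = len(nodes)
    n_pairs = p * (p - 1) // 2
    freq = np.zeros((len(lambdas), n_pairs))
    pair_index = {}
    k = 0
    for i in range(p):
        for j in range(i + 1, p):
            pair_index[(i, j)] = k
            k += 1
    for li, lam in enumerate(lambdas):
        for idx in subsamples:
            for e in _neighborhood_edges(X[idx], lam):
                freq[li, pair_index[e]] += 1
    if n_subsamples > 1:
        theta = freq / n_subsamples
        instability = (2 * theta * (1 - theta)).mean(axis=1)
        # monotonize from the sparse (large-lambda) end, StARS-style
        monotone = np.maximum.accumulate(instability)
        ok = np.nonzero(monotone <= instability_threshold)[0]
        lam_opt = lambdas[ok[-1]] if ok.size else lambdas[0]
    else:
        lam_opt = lambdas[-1]

    for i, j in _neighborhood_edges(X, lam_opt):
        # edge weight: empirical CLR correlation as sign/strength annotation
        w = float(np.corrcoef(X[:, i], X[:, j])[0, 1])
        G.add_edge(nodes[i], nodes[j], weight=w)
    G.graph["lambda_opt"] = float(lam_opt)
    return G


# ---------------------------------------------------------------------------
# Modules and Zi-Pi node roles
# ---------------------------------------------------------------------------

def detect_modules(network: nx.Graph, seed: int = 0) -> dict[str, int]:
    """Greedy modularity maximization; singleton components are own modules.

    Module ids are assigned deterministically by each module's lowest node id
    (sorted order); the seed is accepted for interface stability but the
    greedy algorithm itself is deterministic.
    """
    if network.number_of_nodes() == 0:
        return {}
    communities: list[set] = []
    for comp in nx.connected_components(network):
        sub = network.subgraph(comp)
        if sub.number_of_edges() == 0:
            communities.extend({n} for n in comp)
        else:
            communities.extend(
                set(c) for c in
                nx.algorithms.community.greedy_modularity_communities(sub)
            )
    communities.sort(key=lambda c: min(c))
    return {node: i for i, comm in enumerate(communities) for node in sorted(comm)}


@dataclass
class NodeTopology:
    """Degree, module, and Zi-Pi role of one network node."""

    node: str
    degree: int
    module: int
    within_module_degree: int
    zi: float
    pi: float
    role: Role


def _role(zi: float, pi: float) -> Role:
    # strict inequalities; boundary values fall to the peripheral/connector side
    if zi > ZI_THRESHOLD and pi > PI_THRESHOLD:
        return Role.NETWORK_HUB
    if zi > ZI_THRESHOLD:
        return Role.MODULE_HUB
    if pi > PI_THRESHOLD:
        return Role.CONNECTOR
    return Role.PERIPHERAL


def node_topology(
    network: nx.Graph, modules: Mapping[str, int]
) -> list[NodeTopology]:
    """Zi (within-module degree z-score) and Pi (participation coefficient).

    kappa_i is node i's number of edges into its own module; Zi standardizes
    kappa_i over the nodes of that module (0 when the module's kappa spread is
    zero). Pi = 1 - sum_m (k_im / k_i)^2 over modules m, 0 for isolated nodes.
    Roles follow the (2.5, 0.62) threshold plane with strict inequalities.
    """
    unassigned = [n for n in network.nodes if n not in modules]
    if unassigned:
        raise ValueError(f"nodes without module assignment, e.g. {unassigned[:3]}")
    kappa = {
        n: sum(1 for nb in network.neighbors(n) if modules[nb] == modules[n])
        for n in network.nodes
    }
    by_module: dict[int, list[str]] = {}
    for n in network.nodes:
        by_module.setdefault(modules[n], []).append(n)
    stats = {}
    for mod, members in by_module.items():
        ks = np.array([kappa[n] for n in members], dtype=float)
        stats[mod] = (ks.mean(), ks.std(ddof=0))

    out = []
    for n in sorted(network.nodes):
        k = network.degree(n)
        mean_k, sd_k = stats[modules[n]]
        zi = (kappa[n] - mean_k) / sd_k if sd_k > 0 else 0.0
        if k == 0:
            pi = 0.0
        else:
            per_module: dict[int, int] = {}
            for nb in network.neighbors(n):
                per_module[modules[nb]] = per_module.get(modules[nb], 0) + 1
            pi = 1.0 - sum((c / k) ** 2 for c in per_module.values())
        out.append(NodeTopology(
            node=n, degree=k, module=modules[n],
            within_module_degree=kappa[n], zi=float(zi), pi=float(pi),
            role=_role(zi, pi),
        ))
    return out


def topology_frame(topology: Iterable[NodeTopology]) -> pd.DataFrame:
    return pd.DataFrame([{
        "node": t.node, "degree": t.degree, "module": t.module,
        "within_module_degree": t.within_module_degree,
        "zi": t.zi, "pi": t.pi, "role": t.role.name,
    } for t in topology])


# ---------------------------------------------------------------------------
# Under-represented phyla and wanted-list assembly
# ---------------------------------------------------------------------------

def flag_underrepresented_phyla(
    otu_table: OTUTable,
    match_results: Mapping[str, MatchResult],
    top_n: int = 10,
    max_match_abundance: float = 0.5,
    tier: float = 100.0,
) -> list[str]:
    """Among the ``top_n`` phyla by summed mean abundance, those whose matched
    (genome-sequenced) abundance fraction is below ``max_match_abundance``.

    OTUs without a taxonomy label fall under "Unclassified", which is never
    flagged. Match status is taken from the centroid ASV at ``tier``.
    """
    mean_abund = otu_table.relative_abundance().mean(axis=0)
    per_phylum: dict[str, list[str]] = {}
    for otu in otu_table.otu_ids:
        per_phylum.setdefault(otu_table.phylum_of(otu), []).append(otu)
    totals = {ph: float(mean_abund[otus].sum()) for ph, otus in per_phylum.items()}
    top = sorted((ph for ph in totals if ph != "Unclassified"),
                 key=lambda ph: -totals[ph])[:top_n]
    flagged = []
    for ph in top:
        total = totals[ph]
        if total <= 0:
            continue
        matched = sum(
            float(mean_abund[otu]) for otu in per_phylum[ph]
            if _otu_matched(otu, otu_table, match_results, tier)
        )
        if matched / total < max_match_abundance:
            flagged.append(ph)
    return flagged


def _otu_matched(otu: str, otu_table: OTUTable,
                 match_results: Mapping[str, MatchResult], tier: float) -> bool:
    res = match_results.get(otu_table.centroid.get(otu, ""))
    return bool(res and res.matched(tier))


def _knowledge_status(
    otu: str,
    otu_table: OTUTable,
    match_results: Mapping[str, MatchResult],
    index,
    tier: float,
) -> KnowledgeStatus:
    """ISOLATE if any member/centroid hit is a pure-culture genome at the tier;
    GENOME_ONLY if any hit at all; else DARK."""
    any_hit = False
    for asv in otu_table.membership.get(otu, []):
        res = match_results.get(asv)
        if not res or not res.matched(tier):
            continue
        any_hit = True
        if res.category_at(tier) == Category.ISOLATION:
            return KnowledgeStatus.ISOLATE
    return KnowledgeStatus.GENOME_ONLY if any_hit else KnowledgeStatus.DARK


@dataclass
class WantedList:
    """Prioritized OTUs with criteria flags and knowledge status."""

    entries: pd.DataFrame   # otu_id, mean abundance, prevalence, flags, status
    flagged_phyla: list[str]
    total_mean_abundance: float   # average summed relative abundance covered

    def status_counts(self) -> dict[str, int]:
        return self.entries["status"].value_counts().to_dict()


def assemble_wanted_list(
    prevalence_set: set[str],
    topology: Iterable[NodeTopology],
    match_results: Mapping[str, MatchResult],
    flagged_phyla: Sequence[str],
    otu_table: OTUTable,
    index=None,
    tier: float = 100.0,
) -> WantedList:
    """Union of the prevalence core and the network hubs, with knowledge status.

    Hubs are nodes whose role is MODULE_HUB or NETWORK_HUB. The reported
    coverage is the mean across samples of the summed relative abundance of
    all listed OTUs.
    """
    hubs = {t.node for t in topology
            if t.role in (Role.MODULE_HUB, Role.NETWORK_HUB)}
    listed = sorted(prevalence_set | hubs,
                    key=lambda o: (int(o.split("_")[1]) if o.startswith("OTU_")
                                   and o.split("_")[1].isdigit() else 0, o))
    rel = otu_table.relative_abundance()
    mean_abund = rel.mean(axis=0)
    prev = otu_table.prevalence()
    rows = []
    for otu in listed:
        status = _knowledge_status(otu, otu_table, match_results, index, tier)
        rows.append({
            "otu_id": otu,
            "mean_relative_abundance": float(mean_abund.get(otu, 0.0)),
            "prevalence": float(prev.get(otu, 0.0)),
            "flag_prevalence": otu in prevalence_set,
            "flag_hub": otu in hubs,
            "status": status.name,
            "phylum": otu_table.phylum_of(otu),
        })
    entries = pd.DataFrame(rows, columns=[
        "otu_id", "mean_relative_abundance", "prevalence",
        "flag_prevalence", "flag_hub", "status", "phylum"])
    coverage = float(rel[listed].sum(axis=1).mean()) if listed else 0.0
    return WantedList(entries=entries, flagged_phyla=list(flagged_phyla),
                      total_mean_abundance=coverage)


# ---------------------------------------------------------------------------
# Cross-environment lookup
# ---------------------------------------------------------------------------

def cross_environment_max(
    wanted: WantedList | Sequence[str],
    otu_table: OTUTable,
    external_table: AmpliconTable,
) -> pd.DataFrame:
    """Highest relative abundance of each wanted OTU in an external survey.

    The OTU centroid is matched to external tags by exact sequence equality on
    either strand (the external tags are same-length trimmed sequences);
    absent OTUs get NA. Returns one row per OTU with the maximum relative
    abundance and the sample/environment attaining it.
    """
    otu_ids = (list(wanted.entries["otu_id"]) if isinstance(wanted, WantedList)
               else list(wanted))
    by_seq: dict[str, list[str]] = {}
    for asv, seq in external_table.sequences.items():
        by_seq.setdefault(seq, []).append(asv)
    rel = external_table.relative_abundance()
    rows = []
    for otu in otu_ids:
        seq = otu_table.sequences.get(otu, "")
        tags = by_seq.get(seq, []) + by_seq.get(reverse_complement(seq), [])
        tags = [t for t in dict.fromkeys(tags) if t in rel.columns]
        if not tags:
            rows.append({"otu_id": otu, "max_abundance": float("nan"),
                         "environment": "", "sample_id": ""})
            continue
        sub = rel[tags].sum(axis=1) if len(tags) > 1 else rel[tags[0]]
        sample = sub.idxmax()
        rows.append({
            "otu_id": otu,
            "max_abundance": float(sub.loc[sample]),
            "environment": external_table.environment_of(sample),
            "sample_id": sample,
        })
    return pd.DataFrame(rows, columns=["otu_id", "max_abundance",
                                       "environment", "sample_id"])
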