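"""Greedy gene-cluster search in a phenotypic-likelihood network.

Given a background network whose edge weights score the likelihood that two
genes share a phenotype, and a list of genomic events (an SNV hits one gene;
a CNV or GWAS locus spans a gene set), the search looks for a strongly
interconnected cluster among the hit genes.  Each event contributes at most
one gene to a cluster.  Starting from every input gene as a seed, the greedy
step repeatedly adds the gene (from a yet-unused event) that maximises the
increase in the cluster score — the weighted sum of within-cluster edges.

Significance is assessed by permutation: each event's genes are replaced by
a random, same-sized set of network genes, the search is re-run, and the
observed best score at each cluster size is compared with the null score
distribution.  P-values across tested cluster sizes are Bonferroni-adjusted
and the best size is the one minimising the adjusted p-value (ties broken by
maximal z-score).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np

__all__ = [
    "GenomicEvent",
    "LikelihoodNetwork",
    "ClusterCandidate",
    "ClusterResult",
    "cluster_score",
    "greedy_search",
    "null_distribution",
    "significance",
    "best_network",
    "report_interactor_expansion",
]


@dataclass(frozen=True)
class GenomicEvent:
    """An SNV (one gene) or a CNV/GWAS locus (gene set) entering the search."""

    event_id: str
    variant_type: str  # "SNV" | "CNV" | "GWAS"
    genes: FrozenSet[str]

    def __post_init__(self) -> None:
        if self.variant_type not in ("SNV", "CNV", "GWAS"):
            raise ValueError(f"unknown variant type {self.variant_type!r}")
        if not self.genes:
            raise ValueError(f"event {self.event_id} has no genes")
        if self.variant_type == "SNV" and len(self.genes) != 1:
            raise ValueError(f"SNV event {self.event_id} must have exactly one gene")
        object.__setattr__(self, "genes", frozenset(self.genes))


class LikelihoodNetwork:
    """Weighted undirected gene graph; absent edges have weight 0."""

    def __init__(self, graph: Optional[nx.Graph] = None):
        self.graph = graph if graph is not None else nx.Graph()
        self._adj: Optional[Dict[str, Dict[str, float]]] = None

    def adjacency(self) -> Dict[str, Dict[str, float]]:
        """Cached dict-of-dicts adjacency for fast repeated weight lookups."""
        if self._adj is None:
            self._adj = {
                n: {m: float(d["weight"]) for m, d in nbrs.items()}
                for n, nbrs in self.graph.adj.items()
            }
        return self._adj

    @classmethod
    def from_edges(cls, edges: Iterable[Tuple[str, str, float]]) -> "LikelihoodNetwork":
        g = nx.Graph()
        for a, b, w in edges:
            if a == b:
                raise ValueError(f"self-edge on {a!r}")
            g.add_edge(a, b, weight=float(w))
        return cls(g)

    @property
    def nodes(self) -> Set[str]:
        return set(self.graph.nodes)

    def sorted_nodes(self) -> List[str]:
        return sorted(self.graph.nodes)

    def weight(self, a: str, b: str) -> float:
        if self.graph.has_edge(a, b):
            return float(self.graph[a][b]["weight"])
        return 0.0

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph


@dataclass
class ClusterCandidate:
    """Best greedy cluster of one size: genes, event assignment, score."""

    genes: Tuple[str, ...]
    assignment: Dict[str, str]  # event_id -> selected gene
    score: float


@dataclass
class ClusterResult:
    """Outcome of the full search at the selected cluster size."""

    k: int
    genes: Tuple[str, ...]
    assignment: Dict[str, str]
    score: float
    z: float
    p_raw: float
    p_adj: float
    n_perm: int
    seed: Optional[int]
    per_size: Dict[int, Dict[str, float]] = field(default_factory=dict)
    expansion: Optional[FrozenSet[str]] = None


def cluster_score(genes: Iterable[str], network: LikelihoodNetwork) -> float:
    """Weighted sum of edges among ``genes``; empty/singleton sets score 0."""
    gene_list = list(genes)
    unknown = [g for g in gene_list if g not in network]
    if unknown:
        raise KeyError(f"gene(s) not in network: {sorted(unknown)}")
    sub = network.graph.subgraph(gene_list)
    return float(sum(d["weight"] for _, _, d in sub.edges(data=True)))


def _restricted_events(
    events: Sequence[GenomicEvent], network: LikelihoodNetwork
) -> List[Tuple[str, Tuple[str, ...]]]:
    """Event genes restricted to network nodes, sorted for determinism."""
    out = []
    for e in events:
        genes = tuple(sorted(g for g in e.genes if g in network))
        if genes:
            out.append((e.event_id, genes))
    return out


def greedy_search(
    events: Sequence[GenomicEvent],
    network: LikelihoodNetwork,
    k_max: int,
) -> Dict[int, ClusterCandidate]:
    """Best greedy cluster per size k <= k_max, over all seeds.

    Every gene of every event is used as a seed; growth adds, at each step,
    the gene from a yet-unused event with the largest score increment (ties:
    lexicographically smallest gene symbol).  At most one gene per event ever
    enters a set.  Genes absent from the network are ignored.
    """
    if k_max < 2:
        raise ValueError("k_max must be at least 2")
    evs = _restricted_events(events, network)
    best: Dict[int, ClusterCandidate] = {}

    def consider(k: int, selected: List[str], assignment: Dict[str, str], score: float):
        cur = best.get(k)
        key = (-score, tuple(sorted(selected)))
        if cur is None or key < (-cur.score, tuple(sorted(cur.genes))):
            best[k] = ClusterCandidate(
                genes=tuple(sorted(selected)), assignment=dict(assignment), score=score
            )

    adj = network.adjacency()
    candidate_genes = {g for _, genes in evs for g in genes}
    for seed_event, seed_genes in evs:
        for seed_gene in seed_genes:
            selected = [seed_gene]
            # incremental connection weight of every gene to the selected set
            seed_nbrs = adj.get(seed_gene, {})
            gain = {g: seed_nbrs.get(g, 0.0) for g in candidate_genes}
            assignment = {seed_event: seed_gene}
            used = {seed_event}
            consider(1, selected, assignment, 0.0)
            score = 0.0
            while len(selected) < k_max:
                best_gene, best_event, best_gain = None, None, -np.inf
                for event_id, genes in evs:
                    if event_id in used:
                        continue
                    for g in genes:
                        if g in selected:
                            continue
                        inc = gain[g]
                        if inc > best_gain or (
                            inc == best_gain
                            and best_gene is not None
                            and g < best_gene
                        ):
                            best_gene, best_event, best_gain = g, event_id, inc
                if best_gene is None:
                    break
                selected.append(best_gene)
                used.add(best_event)
                assignment[best_event] = best_gene
                score += best_gain
                for nbr, w in adj.get(best_gene, {}).items():
                    if nbr in gain:
                        gain[nbr] += w
                consider(len(selected), selected, assignment, score)
    return best


def _random_events(
    events: Sequence[GenomicEvent],
    nodes: Sequence[str],
    rng: np.random.Generator,
) -> List[GenomicEvent]:
    """Structure-matched random events: same count, same genes per event."""
    out = []
    for i, e in enumerate(events):
        picked = rng.choice(len(nodes), size=min(len(e.genes), len(nodes)),
                            replace=False)
        out.append(
            GenomicEvent(
                event_id=f"perm_{i}",
                variant_type=e.variant_type if len(e.genes) > 1 else "SNV",
                genes=frozenset(nodes[j] for j in picked),
            )
        )
    return out


def _null_best_scores(
    events: Sequence[GenomicEvent],
    network: LikelihoodNetwork,
    k_max: int,
    n_perm: int,
    seed: Optional[int],
    degree_matched: bool = False,
) -> np.ndarray:
    """(n_perm, k_max + 1) array of best greedy scores per size, per permutation."""
    rng = np.random.default_rng(seed)
    nodes = np.array(sorted(network.graph.nodes))
    scores = np.zeros((n_perm, k_max + 1))
    if degree_matched:
        degrees = dict(network.graph.degree)
        deciles = np.quantile(
            [degrees[n] for n in nodes], np.linspace(0, 1, 11)[1:-1]
        )
        node_bins = np.searchsorted(deciles, [degrees[n] for n in nodes],
                                    side="right")
        by_bin = {b: nodes[node_bins == b] for b in np.unique(node_bins)}
        gene_bin = {g: b for g, b in zip(nodes, node_bins)}
    for p in range(n_perm):
        if degree_matched:
            perm_events = []
            for i, e in enumerate(events):
                picked = []
                for g in sorted(e.genes):
                    pool = by_bin.get(gene_bin.get(g), nodes)
                    picked.append(str(rng.choice(pool)))
                perm_events.append(
                    GenomicEvent(f"perm_{i}",
                                 e.variant_type if len(e.genes) > 1 else "SNV",
                                 frozenset(picked)))
        else:
            perm_events = _random_events(events, nodes, rng)
        res = greedy_search(perm_events, network, k_max)
        for k, cand in res.items():
            if k <= k_max:
                scores[p, k] = cand.score
    return scores


def null_distribution(
    events: Sequence[GenomicEvent],
    network: LikelihoodNetwork,
    k: int,
    n_perm: int,
    seed: Optional[int] = None,
    degree_matched: bool = False,
) -> List[float]:
    """Permutation null of best greedy scores at cluster size ``k``."""
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    if k > len(events):
        raise ValueError(f"cluster size {k} exceeds event count {len(events)}")
    scores = _null_best_scores(events, network, k, n_perm, seed, degree_matched)
    return [float(s) for s in scores[:, k]]


def significance(observed: float, null: Sequence[float]) -> Tuple[float, float]:
    """Empirical (z, p_raw) of an observed score against a permutation null.

    p_raw uses the add-one counting rule (1 + #{null >= observed}) /
    (1 + n_perm); z is (observed - mean) / sd with z = 0 when sd = 0.
    """
    null_arr = np.asarray(null, dtype=float)
    if null_arr.size == 0:
        raise ValueError("null distribution is empty")
    p_raw = (1.0 + float(np.sum(null_arr >= observed))) / (1.0 + null_arr.size)
    sd = float(np.std(null_arr, ddof=1)) if null_arr.size > 1 else 0.0
    z = 0.0 if sd == 0.0 else (observed - float(np.mean(null_arr))) / sd
    return z, p_raw


def best_network(
    events: Sequence[GenomicEvent],
    network: LikelihoodNetwork,
    k_max: int,
    n_perm: int,
    seed: Optional[int] = None,
    degree_matched: bool = False,
) -> ClusterResult:
    """Full search: greedy clusters per size, permutation p-values, best size.

    Raw p-values across the k_max - 1 tested sizes (k = 2 .. k_max) are
    Bonferroni-adjusted; the reported cluster is the size minimising the
    adjusted p-value, ties broken by maximal z-score, then by smaller k.
    """
    if k_max > len(events):
        raise ValueError(f"k_max {k_max} exceeds event count {len(events)}")
    observed = greedy_search(events, network, k_max)
    nulls = _null_best_scores(events, network, k_max, n_perm, seed, degree_matched)
    n_tested = k_max - 1
    per_size: Dict[int, Dict[str, float]] = {}
    ranking = []
    for k in range(2, k_max + 1):
        obs_score = observed[k].score if k in observed else 0.0
        z, p_raw = significance(obs_score, nulls[:, k])
        p_adj = min(1.0, p_raw * n_tested)
        per_size[k] = {"score": obs_score, "z": z, "p_raw": p_raw, "p_adj": p_adj}
        ranking.append((p_adj, -z, k))
    p_adj, neg_z, k_best = min(ranking)
    stats = per_size[k_best]
    cand = observed.get(k_best, ClusterCandidate(genes=(), assignment={}, score=0.0))
    return ClusterResult(
        k=k_best,
        genes=cand.genes,
        assignment=cand.assignment,
        score=stats["score"],
        z=stats["z"],
        p_raw=stats["p_raw"],
        p_adj=stats["p_adj"],
        n_perm=n_perm,
        seed=seed,
        per_size=per_size,
    )


def report_interactor_expansion(
    selected_genes: Iterable[str],
    interactions: nx.Graph,
    annotation_sets: Mapping[str, Set[str]],
) -> FrozenSet[str]:
    """Reporting expansion: annotated cluster genes plus their direct interactors.

    Keeps the selected genes that carry one of the given annotations (e.g.
    microtubule-based process, actin cytoskeleton, synaptic transmission) and
    adds their direct neighbours in a physical-interaction network
    (BioGRID-style edge list).
    """
    annotated = set().union(*annotation_sets.values()) if annotation_sets else set()
    core = {g for g in selected_genes if g in annotated}
    expanded = set(core)
    for g in core:
        if g in interactions:
            expanded.update(interactions.neighbors(g))
    return frozenset(expanded)
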