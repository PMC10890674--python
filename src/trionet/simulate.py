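"""Synthetic inputs with known ground truth for every pipeline stage.

Nothing in the published study's raw sequence data is available, so every
stage is exercised on simulated data: trio read counts with planted de novo
events, labelled concordant/discordant calibration features, phenotypic-
likelihood networks with planted high-weight modules, genomic events, and
annotation collections with an injected enriched term.

All generators are pure functions of a :class:`SimulationConfig`: a single
root seed is split deterministically into one independent stream per
generator, so the same configuration always reproduces byte-identical
outputs regardless of call order.

Defaults are chosen to mimic the scale of the study the package targets
(about 181 trio families, exome-typical mean coverage, one or two validated
de novo mutations per carrier proband, 23 chromosomes) without claiming
biological realism; see ``docs/methods.md``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

from trionet.enrichment import AnnotationSet
from trionet.network_search import GenomicEvent, LikelihoodNetwork
from trionet.trio_denovo import CalibrationRecord, CalibrationSet, SiteReadData

__all__ = [
    "SimulationConfig",
    "simulate_trio_reads",
    "simulate_calibration_features",
    "simulate_labeled_scores",
    "simulate_likelihood_network",
    "simulate_events",
    "simulate_annotation_sets",
]

# fixed stream ids so each generator draws from an independent substream
_STREAMS = {
    "trio": 1,
    "calibration": 2,
    "scores": 3,
    "network": 4,
    "events": 5,
    "annotations": 6,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, _STREAMS[stream]]))


@dataclass
class SimulationConfig:
    """Parameters for every generator; see module docstring for rationale."""

    seed: int = 0

    # trio reads
    n_sites: int = 2000
    mean_depth: float = 60.0        # Poisson rate per trio member
    error_rate: float = 0.005       # per-read alternate error
    denovo_rate: float = 1e-3       # planted de novo events per site
    alt_allele_freq: float = 0.1    # population alternate frequency (HWE)

    # calibration features (per-class Normal location/scale)
    n_calibration: int = 2000
    feature_params: Dict[str, Tuple[Tuple[float, float], Tuple[float, float]]] = field(
        default_factory=lambda: {
            "qd": ((4.0, 1.0), (0.0, 1.0)),    # quality-by-depth-like
            "mq": ((2.0, 1.0), (0.0, 1.5)),    # mapping-quality-like
        }
    )
    p_discordant: float = 0.5
    het_fraction: float = 0.8

    # likelihood network
    n_genes: int = 200
    edge_prob: float = 0.05
    weight_scale: float = 1.0       # Exponential scale of edge weights
    module_size: int = 12
    module_multiplier: float = 3.0  # weight factor of planted-module edges

    # genomic events
    n_snv: int = 48
    n_multi: int = 12
    genes_per_multi: int = 4

    # annotation collections
    n_terms: int = 50
    term_size_range: Tuple[int, int] = (10, 100)
    universe_size: int = 1000
    list_size: int = 40
    enrichment_factor: float = 5.0

    def __post_init__(self) -> None:
        for name in ("error_rate", "denovo_rate", "alt_allele_freq",
                     "p_discordant", "het_fraction", "edge_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("n_sites", "mean_depth", "n_calibration", "n_genes",
                     "universe_size", "list_size", "n_terms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# Trio reads
# ---------------------------------------------------------------------------

_GENO_ALT_FRAC = {"RR": 0.0, "RA": 0.5, "AA": 1.0}


def _hwe_genotype(rng: np.random.Generator, q: float) -> str:
    u = rng.random()
    if u < (1 - q) ** 2:
        return "RR"
    if u < (1 - q) ** 2 + 2 * q * (1 - q):
        return "RA"
    return "AA"


def _transmit(rng: np.random.Generator, geno: str) -> str:
    if geno == "RR":
        return "R"
    if geno == "AA":
        return "A"
    return "R" if rng.random() < 0.5 else "A"


def simulate_trio_reads(
    config: SimulationConfig,
) -> Tuple[List[SiteReadData], np.ndarray]:
    """Per-member read counts for trio sites, with planted de novo events.

    Returns the sites and a boolean truth vector (True where a de novo
    heterozygote was planted: both parents RR, proband RA).  Non-planted
    sites draw parental genotypes from Hardy-Weinberg at the configured
    alternate frequency and transmit Mendelianly.  Depths are Poisson;
    alternate read counts are binomial with error-perturbed expected
    fractions.
    """
    rng = _rng(config.seed, "trio")
    eps = config.error_rate
    sites: List[SiteReadData] = []
    truth = np.zeros(config.n_sites, dtype=bool)
    for i in range(config.n_sites):
        if rng.random() < config.denovo_rate:
            genos = {"father": "RR", "mother": "RR", "proband": "RA"}
            truth[i] = True
        else:
            f = _hwe_genotype(rng, config.alt_allele_freq)
            m = _hwe_genotype(rng, config.alt_allele_freq)
            alleles = sorted((_transmit(rng, f), _transmit(rng, m)))
            child = {("A", "A"): "AA", ("A", "R"): "RA", ("R", "R"): "RR"}[
                tuple(alleles)
            ]
            genos = {"father": f, "mother": m, "proband": child}
        depth, alt = {}, {}
        for member, g in genos.items():
            d = int(rng.poisson(config.mean_depth))
            frac = _GENO_ALT_FRAC[g]
            p = frac * (1 - eps) + (1 - frac) * eps if g != "RA" else 0.5
            depth[member] = d
            alt[member] = int(rng.binomial(d, p)) if d > 0 else 0
        sites.append(
            SiteReadData(
                site_id=f"site{i:05d}", chrom="1", pos=i + 1,
                depth=depth, alt_count=alt,
            )
        )
    return sites, truth


# ---------------------------------------------------------------------------
# Calibration features and labelled scores
# ---------------------------------------------------------------------------

def simulate_calibration_features(config: SimulationConfig) -> CalibrationSet:
    """Labelled QC features emulating chip-vs-exome concordance classes.

    Each record draws its label (discordant with probability
    ``p_discordant``), a Poisson coverage, a het/hom flag and per-feature
    Gaussian values from the class-specific location/scale parameters.
    """
    rng = _rng(config.seed, "calibration")
    records: List[CalibrationRecord] = []
    names = sorted(config.feature_params)
    for _ in range(config.n_calibration):
        discordant = rng.random() < config.p_discordant
        coverage = float(rng.poisson(config.mean_depth))
        gclass = "het" if rng.random() < config.het_fraction else "hom"
        features = {}
        for f in names:
            (mu_c, sd_c), (mu_d, sd_d) = config.feature_params[f]
            mu, sd = (mu_d, sd_d) if discordant else (mu_c, sd_c)
            features[f] = float(rng.normal(mu, sd))
        records.append(
            CalibrationRecord(
                feature_vector=features,
                coverage=coverage,
                genotype_class=gclass,
                label="discordant" if discordant else "concordant",
            )
        )
    return CalibrationSet(records)


def simulate_labeled_scores(
    n: int,
    mu_true: float = 4.0,
    sd_true: float = 1.0,
    mu_false: float = 0.0,
    sd_false: float = 1.0,
    p_true: float = 0.5,
    seed: int = 0,
) -> List[Tuple[float, str]]:
    """Labelled log Bayes-factor scores from a two-Gaussian mixture.

    True (concordant) scores are Normal(mu_true, sd_true), false
    (discordant) scores Normal(mu_false, sd_false), mixed in proportion
    ``p_true``.  This is the stylised shape of the empirical score curves
    the threshold calibration targets.
    """
    rng = _rng(seed, "scores")
    out: List[Tuple[float, str]] = []
    for _ in range(n):
        if rng.random() < p_true:
            out.append((float(rng.normal(mu_true, sd_true)), "concordant"))
        else:
            out.append((float(rng.normal(mu_false, sd_false)), "discordant"))
    return out


# ---------------------------------------------------------------------------
# Networks, events, annotations
# ---------------------------------------------------------------------------

def simulate_likelihood_network(
    config: SimulationConfig,
) -> Tuple[LikelihoodNetwork, FrozenSet[str]]:
    """Background gene network with an optional planted high-weight module.

    Background edges are Bernoulli(``edge_prob``) with Exponential
    (``weight_scale``) weights.  The planted module is a fully connected
    gene subset whose edge weights are background draws multiplied by
    ``module_multiplier``.  A multiplier of 1 is the identity perturbation:
    nothing is planted and the returned truth set is empty, so the graph is
    pure background noise.
    """
    rng = _rng(config.seed, "network")
    genes = [f"g{i:04d}" for i in range(config.n_genes)]
    edges: List[Tuple[str, str, float]] = []
    n = config.n_genes
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < config.edge_prob:
                edges.append(
                    (genes[i], genes[j], float(rng.exponential(config.weight_scale)))
                )
    planted: FrozenSet[str] = frozenset()
    if config.module_size >= 2 and config.module_multiplier != 1.0:
        idx = rng.choice(n, size=min(config.module_size, n), replace=False)
        module = sorted(genes[i] for i in idx)
        planted = frozenset(module)
        existing = {(a, b) for a, b, _ in edges}
        module_edges = []
        for i in range(len(module)):
            for j in range(i + 1, len(module)):
                w = float(rng.exponential(config.weight_scale))
                module_edges.append(
                    (module[i], module[j], w * config.module_multiplier)
                )
        edges = [
            (a, b, w)
            for a, b, w in edges
            if not (a in planted and b in planted)
        ] + module_edges
    net = LikelihoodNetwork.from_edges(edges)
    net.graph.add_nodes_from(genes)  # isolated genes stay in the universe
    return net, planted


def simulate_events(
    genes: Sequence[str],
    config: SimulationConfig,
    required_genes: Optional[Sequence[str]] = None,
) -> List[GenomicEvent]:
    """Single-gene SNV events plus multi-gene CNV-like events.

    ``required_genes`` (e.g. a planted module) are each guaranteed to seed
    one SNV event; remaining SNV events and all multi-gene events sample
    genes uniformly, without replacement within an event.
    """
    rng = _rng(config.seed, "events")
    pool = sorted(genes)
    required = sorted(required_genes) if required_genes else []
    if len(required) > config.n_snv:
        raise ValueError("more required genes than SNV events")
    events: List[GenomicEvent] = []
    for i, g in enumerate(required):
        events.append(GenomicEvent(f"snv{i:03d}", "SNV", frozenset([g])))
    for i in range(len(required), config.n_snv):
        g = pool[int(rng.integers(len(pool)))]
        events.append(GenomicEvent(f"snv{i:03d}", "SNV", frozenset([g])))
    size = max(1, config.genes_per_multi)
    for i in range(config.n_multi):
        idx = rng.choice(len(pool), size=min(size, len(pool)), replace=False)
        events.append(
            GenomicEvent(
                f"cnv{i:03d}",
                "CNV" if size > 1 else "SNV",
                frozenset(pool[j] for j in idx),
            )
        )
    return events


def simulate_annotation_sets(
    config: SimulationConfig,
) -> Tuple[List[AnnotationSet], List[str], str]:
    """Annotation collection, a companion gene list, and the enriched term id.

    Term sizes are uniform over ``term_size_range``; genes are sampled from a
    synthetic universe.  With ``enrichment_factor`` > 1 the companion list
    over-samples the designated term by that factor relative to its null
    expectation; with factor <= 1 the list is uniform over the universe.
    """
    rng = _rng(config.seed, "annotations")
    universe = [f"u{i:04d}" for i in range(config.universe_size)]
    lo, hi = config.term_size_range
    ontologies = ("BP", "CC", "MF")
    terms: List[AnnotationSet] = []
    for t in range(config.n_terms):
        size = int(rng.integers(lo, hi + 1))
        idx = rng.choice(config.universe_size, size=size, replace=False)
        terms.append(
            AnnotationSet(
                term_id=f"TERM:{t:04d}",
                term_name=f"synthetic term {t}",
                ontology=ontologies[t % 3],
                genes=frozenset(universe[i] for i in idx),
            )
        )
    enriched = terms[0]
    if config.enrichment_factor > 1.0:
        null_overlap = config.list_size * len(enriched.genes) / config.universe_size
        target = int(round(config.enrichment_factor * null_overlap))
        target = min(target, len(enriched.genes), config.list_size)
        inside = rng.choice(sorted(enriched.genes), size=target, replace=False)
        outside_pool = sorted(set(universe) - enriched.genes)
        outside = rng.choice(
            outside_pool, size=config.list_size - target, replace=False
        )
        gene_list = sorted(str(g) for g in np.concatenate([inside, outside]))
    else:
        idx = rng.choice(config.universe_size, size=config.list_size, replace=False)
        gene_list = sorted(universe[i] for i in idx)
    return terms, gene_list, enriched.term_id
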