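"""Trio de novo candidate detection and Bayes-factor quality filtering.

Two separate probabilistic layers operate here:

1. **Genotype layer** — per-site genotype likelihoods under a binomial
   read-sampling model, combined over the trio to decide whether the data
   favour a de novo configuration (both parents homozygous reference, proband
   carrying a novel alternate allele) over every Mendelian-consistent
   configuration.

2. **Quality layer** — a naive-Bayes classifier over site-level QC features
   (mapping quality, strand bias, ... whatever the caller emits), trained on
   labelled calibration sites where an orthogonal genotyping technology is
   available.  Sites where chip and exome calls agree are *concordant*
   ("true"), sites where they disagree are *discordant* ("false positive").
   The classifier emits a log Bayes factor; the acceptance threshold is
   calibrated empirically so that the accepted set contains a chosen
   proportion of false positives (~5% by default).

Calibration densities are binned empirical distributions, stratified by mean
trio coverage (quartiles by default) and by the proband's genotype class
(het/hom), with Laplace smoothing so no density ratio is ever 0 or infinite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.special import gammaln, logsumexp

MEMBERS = ("father", "mother", "proband")
GENOTYPES = ("RR", "RA", "AA")

__all__ = [
    "SiteReadData",
    "CandidateSite",
    "CalibrationRecord",
    "CalibrationSet",
    "ClassDistributions",
    "BayesFactorModel",
    "genotype_log_likelihood",
    "detect_candidates",
    "build_class_distributions",
    "log_bayes_factor",
    "filter_candidates",
    "calibrate_threshold",
    "classify_trio_genotypes",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteReadData:
    """Read support at one genomic site for a father/mother/proband trio.

    ``depth`` and ``alt_count`` map each trio member to its total read count
    and the number of reads supporting the alternate allele.
    """

    site_id: str
    chrom: str
    pos: int
    depth: Mapping[str, int]
    alt_count: Mapping[str, int]

    def __post_init__(self) -> None:
        for m in MEMBERS:
            if m not in self.depth or m not in self.alt_count:
                raise ValueError(f"missing read data for trio member {m!r}")
            d, a = self.depth[m], self.alt_count[m]
            if d < 0 or a < 0:
                raise ValueError(f"negative read counts at {self.site_id} ({m})")
            if a > d:
                raise ValueError(
                    f"alt_count {a} exceeds depth {d} at {self.site_id} ({m})"
                )

    @property
    def min_depth(self) -> int:
        return min(self.depth[m] for m in MEMBERS)

    @property
    def mean_depth(self) -> float:
        return sum(self.depth[m] for m in MEMBERS) / 3.0


@dataclass
class CandidateSite:
    """A putative de novo site with its QC features and filter state."""

    site: SiteReadData
    genotype_class: str  # "het" | "hom"
    feature_vector: Dict[str, float] = field(default_factory=dict)
    log_posterior_odds: float = float("nan")
    log_bf: Optional[float] = None
    passed_filters: bool = False
    truth: Optional[bool] = None

    @property
    def min_depth(self) -> int:
        return self.site.min_depth


@dataclass(frozen=True)
class CalibrationRecord:
    feature_vector: Mapping[str, float]
    coverage: float
    genotype_class: str  # "het" | "hom"
    label: str  # "concordant" | "discordant"


@dataclass
class CalibrationSet:
    """Labelled QC-feature records from chip-vs-exome concordance."""

    records: List[CalibrationRecord]

    def __post_init__(self) -> None:
        labels = {r.label for r in self.records}
        bad = labels - {"concordant", "discordant"}
        if bad:
            raise ValueError(f"unknown calibration labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class ClassDistributions:
    """Binned per-class feature densities, stratified by coverage and het/hom.

    ``densities[(feature, stratum, gclass)]`` maps to a pair of arrays
    (concordant, discordant) of bin masses summing to 1.  ``stratum = -1``
    and ``gclass = "all"`` hold the pooled fallbacks used for cells without
    calibration data.
    """

    feature_names: Tuple[str, ...]
    bin_edges: Dict[str, np.ndarray]
    stratum_edges: np.ndarray  # internal coverage cut points
    densities: Dict[Tuple[str, int, str], Tuple[np.ndarray, np.ndarray]]
    pseudocount: float

    @property
    def n_strata(self) -> int:
        return len(self.stratum_edges) + 1

    def stratum_of(self, coverage: float) -> int:
        return int(np.searchsorted(self.stratum_edges, coverage, side="right"))

    def lookup(
        self, feature: str, stratum: int, gclass: str
    ) -> Tuple[np.ndarray, np.ndarray]:
        """Densities for a cell, falling back to pooled distributions."""
        for key in (
            (feature, stratum, gclass),
            (feature, -1, gclass),
            (feature, -1, "all"),
        ):
            if key in self.densities:
                return self.densities[key]
        raise KeyError(f"feature {feature!r} was not calibrated")


# ---------------------------------------------------------------------------
# Genotype layer
# ---------------------------------------------------------------------------

def _log_binom(k: int, n: int, p: float) -> float:
    if n == 0:
        return 0.0
    if p <= 0.0 or p >= 1.0:
        # degenerate only when error_rate is 0; guarded by the caller
        if (p <= 0.0 and k == 0) or (p >= 1.0 and k == n):
            return 0.0
        return -math.inf
    return (
        gammaln(n + 1)
        - gammaln(k + 1)
        - gammaln(n - k + 1)
        + k * math.log(p)
        + (n - k) * math.log1p(-p)
    )


def genotype_log_likelihood(
    depth: int, alt_count: int, genotype: str, error_rate: float = 0.005
) -> float:
    """log P(alt_count | depth, genotype) under binomial read sampling.

    The expected alternate-read fraction is ``error_rate`` for RR, 0.5 for RA
    and ``1 - error_rate`` for AA.
    """
    if not 0.0 < error_rate < 0.5:
        raise ValueError("error_rate must lie in (0, 0.5)")
    if depth < 0 or alt_count < 0:
        raise ValueError("read counts must be non-negative")
    if alt_count > depth:
        raise ValueError("alt_count exceeds depth")
    try:
        p = {"RR": error_rate, "RA": 0.5, "AA": 1.0 - error_rate}[genotype]
    except KeyError:
        raise ValueError(f"unknown genotype {genotype!r}") from None
    return _log_binom(alt_count, depth, p)


def _transmission_prob(child: str, father: str, mother: str) -> float:
    """P(child genotype | parental genotypes) under Mendelian transmission."""
    half = {"RR": (1.0, 0.0), "RA": (0.5, 0.5), "AA": (0.0, 1.0)}
    fr, fa = half[father]
    mr, ma = half[mother]
    return {
        "RR": fr * mr,
        "RA": fr * ma + fa * mr,
        "AA": fa * ma,
    }[child]


def _trio_config_log_priors(denovo_prior: float) -> Dict[Tuple[str, str, str], float]:
    """Log prior over the 27 trio genotype configurations.

    Parental genotype pairs are uniform (1/9).  Given the parents, the proband
    prior is Mendelian transmission scaled by (1 - mu), with the residual mass
    mu split evenly over the transmission-impossible genotypes (the de novo /
    violation channel).  Every configuration keeps positive prior mass.
    """
    priors: Dict[Tuple[str, str, str], float] = {}
    for f in GENOTYPES:
        for m in GENOTYPES:
            tprobs = {c: _transmission_prob(c, f, m) for c in GENOTYPES}
            zero = [c for c, t in tprobs.items() if t == 0.0]
            for c in GENOTYPES:
                if tprobs[c] > 0.0:
                    p = (1.0 - denovo_prior) * tprobs[c] if zero else tprobs[c]
                else:
                    p = denovo_prior / len(zero)
                priors[(f, m, c)] = math.log(p / 9.0)
    return priors


def detect_candidates(
    trio_sites: Iterable[SiteReadData],
    error_rate: float = 0.005,
    denovo_prior: float = 1e-4,
) -> List[CandidateSite]:
    """Detect de novo candidates by posterior odds over trio configurations.

    A site is a candidate iff the posterior mass of the de novo configurations
    (both parents RR, proband RA or AA) exceeds the summed mass of every
    Mendelian-consistent configuration.  The proband's genotype class (het or
    hom) is the maximum-likelihood proband genotype among RA/AA.
    """
    if not 0.0 < denovo_prior < 1.0:
        raise ValueError("denovo_prior must lie in (0, 1)")
    log_priors = _trio_config_log_priors(denovo_prior)
    out: List[CandidateSite] = []
    for site in trio_sites:
        ll = {
            m: {
                g: genotype_log_likelihood(
                    site.depth[m], site.alt_count[m], g, error_rate
                )
                for g in GENOTYPES
            }
            for m in MEMBERS
        }
        denovo_terms, mendel_terms = [], []
        for (f, m, c), lp in log_priors.items():
            w = lp + ll["father"][f] + ll["mother"][m] + ll["proband"][c]
            if f == "RR" and m == "RR" and c in ("RA", "AA"):
                denovo_terms.append(w)
            elif _transmission_prob(c, f, m) > 0.0:
                mendel_terms.append(w)
        log_odds = logsumexp(denovo_terms) - logsumexp(mendel_terms)
        if log_odds > 0.0:
            ll_p = ll["proband"]
            gclass = "het" if ll_p["RA"] >= ll_p["AA"] else "hom"
            out.append(
                CandidateSite(
                    site=site, genotype_class=gclass, log_posterior_odds=log_odds
                )
            )
    return out


# ---------------------------------------------------------------------------
# Quality layer: empirical class distributions and the log Bayes factor
# ---------------------------------------------------------------------------

def _smoothed_density(
    values: np.ndarray, edges: np.ndarray, pseudocount: float
) -> np.ndarray:
    counts, _ = np.histogram(values, bins=edges)
    smoothed = counts.astype(float) + pseudocount
    return smoothed / smoothed.sum()


def build_class_distributions(
    calib: CalibrationSet,
    bin_count: int = 20,
    pseudocount: float = 0.5,
    n_strata: int = 4,
) -> ClassDistributions:
    """Build binned concordant/discordant feature densities from labelled data.

    Bin edges per feature are equal-width over the pooled observed range and
    shared by both classes, every coverage stratum and both genotype classes,
    so density ratios are always over comparable bins.  Coverage strata are
    quantile cuts of the calibration coverages (quartiles for ``n_strata=4``).
    Cells with data for only one label fall back to the pooled densities.
    """
    if bin_count < 2:
        raise ValueError("bin_count must be at least 2")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    labels = {r.label for r in calib.records}
    if labels != {"concordant", "discordant"}:
        raise ValueError(
            "calibration requires both concordant and discordant records"
        )
    feature_names = tuple(sorted(calib.records[0].feature_vector))
    for r in calib.records:
        if tuple(sorted(r.feature_vector)) != feature_names:
            raise ValueError("inconsistent feature names across calibration records")

    coverages = np.array([r.coverage for r in calib.records])
    if n_strata > 1:
        qs = np.linspace(0, 1, n_strata + 1)[1:-1]
        stratum_edges = np.unique(np.quantile(coverages, qs))
    else:
        stratum_edges = np.array([])

    bin_edges: Dict[str, np.ndarray] = {}
    for f in feature_names:
        vals = np.array([r.feature_vector[f] for r in calib.records])
        lo, hi = float(vals.min()), float(vals.max())
        if lo == hi:  # degenerate feature: widen to a unit interval
            lo, hi = lo - 0.5, hi + 0.5
        bin_edges[f] = np.linspace(lo, hi, bin_count + 1)

    def cells(records: Sequence[CalibrationRecord]):
        by_label = {
            lab: [r for r in records if r.label == lab]
            for lab in ("concordant", "discordant")
        }
        if not by_label["concordant"] or not by_label["discordant"]:
            return None
        return by_label

    densities: Dict[Tuple[str, int, str], Tuple[np.ndarray, np.ndarray]] = {}

    def fill(key_stratum: int, key_gclass: str, records: Sequence[CalibrationRecord]):
        by_label = cells(records)
        if by_label is None:
            return
        for f in feature_names:
            conc = _smoothed_density(
                np.array([r.feature_vector[f] for r in by_label["concordant"]]),
                bin_edges[f],
                pseudocount,
            )
            disc = _smoothed_density(
                np.array([r.feature_vector[f] for r in by_label["discordant"]]),
                bin_edges[f],
                pseudocount,
            )
            densities[(f, key_stratum, key_gclass)] = (conc, disc)

    fill(-1, "all", calib.records)  # pooled fallback
    for gclass in ("het", "hom"):
        fill(-1, gclass, [r for r in calib.records if r.genotype_class == gclass])
    strata = np.searchsorted(stratum_edges, coverages, side="right")
    for s in range(len(stratum_edges) + 1):
        for gclass in ("het", "hom"):
            recs = [
                r
                for r, rs in zip(calib.records, strata)
                if rs == s and r.genotype_class == gclass
            ]
            fill(s, gclass, recs)

    return ClassDistributions(
        feature_names=feature_names,
        bin_edges=bin_edges,
        stratum_edges=stratum_edges,
        densities=densities,
        pseudocount=pseudocount,
    )


def log_bayes_factor(site: CandidateSite, dists: ClassDistributions) -> float:
    """Naive-Bayes log Bayes factor of a site's QC feature vector.

    Sums, over features, the log ratio of the concordant to the discordant
    bin mass in the site's (coverage stratum, genotype class) cell.  Natural
    logarithm.
    """
    unknown = set(site.feature_vector) - set(dists.feature_names)
    if unknown:
        raise KeyError(f"feature(s) not calibrated: {sorted(unknown)}")
    stratum = dists.stratum_of(site.site.mean_depth)
    total = 0.0
    for f, value in site.feature_vector.items():
        conc, disc = dists.lookup(f, stratum, site.genotype_class)
        edges = dists.bin_edges[f]
        idx = int(np.clip(np.searchsorted(edges, value, side="right") - 1,
                          0, len(edges) - 2))
        total += math.log(conc[idx]) - math.log(disc[idx])
    return total


def filter_candidates(
    sites: Sequence[CandidateSite],
    bf_threshold: float = 3.0,
    depth_threshold: int = 20,
) -> List[CandidateSite]:
    """Keep sites with log BF >= bf_threshold and min trio depth >= depth_threshold.

    Both boundaries are inclusive for retention; input order is preserved and
    ``passed_filters`` is set on every input site.
    """
    kept: List[CandidateSite] = []
    for s in sites:
        if s.log_bf is None:
            raise ValueError(f"log_bf not computed for site {s.site.site_id}")
        s.passed_filters = s.log_bf >= bf_threshold and s.min_depth >= depth_threshold
        if s.passed_filters:
            kept.append(s)
    return kept


def calibrate_threshold(
    labeled_sites: Iterable[Tuple[float, str]],
    target_fp: float = 0.05,
) -> float:
    """Smallest log-BF cutoff whose accepted set has <= target_fp false calls.

    ``labeled_sites`` are (log_bf, label) pairs with labels "concordant"
    (true) / "discordant" (false).  Returns the smallest threshold t such
    that the proportion of discordant sites among sites with log_bf >= t is
    at most ``target_fp``; +inf (with a warning) if no cutoff attains it.
    A target of 1 accepts everything (t = -inf).
    """
    if not 0.0 < target_fp <= 1.0:
        raise ValueError("target_fp must lie in (0, 1]")
    pairs = list(labeled_sites)
    labels = {lab for _, lab in pairs}
    if labels != {"concordant", "discordant"}:
        raise ValueError("calibration requires both concordant and discordant labels")
    scores = np.array([s for s, _ in pairs])
    is_false = np.array([lab == "discordant" for _, lab in pairs])
    order = np.argsort(scores, kind="stable")
    scores, is_false = scores[order], is_false[order]
    # suffix sums: accepted set when thresholding at scores[i]
    n = len(scores)
    false_above = np.cumsum(is_false[::-1])[::-1]
    total_above = n - np.arange(n)
    fp_prop = false_above / total_above
    if fp_prop[0] <= target_fp:
        return -math.inf
    # a cut at a tied score accepts every tie, so only first occurrences of
    # each distinct score are admissible cut points
    first = np.ones(n, dtype=bool)
    first[1:] = scores[1:] > scores[:-1]
    ok = np.nonzero((fp_prop <= target_fp) & first)[0]
    if len(ok) == 0:
        warnings.warn(
            "no threshold attains the requested false-positive proportion; "
            "returning +inf (reject all)",
            stacklevel=2,
        )
        return math.inf
    return float(scores[ok[0]])


# ---------------------------------------------------------------------------
# Fitted-model facade over the quality layer
# ---------------------------------------------------------------------------

class BayesFactorModel:
    """Calibrated naive-Bayes quality filter for de novo candidates.

    Construct with :meth:`fit` from a labelled :class:`CalibrationSet`; the
    fitted model scores candidate sites (:meth:`score`) and can calibrate its
    own acceptance threshold to a false-positive target
    (:meth:`calibrate`).
    """

    def __init__(self, distributions: ClassDistributions):
        self.distributions = distributions
        self.threshold: Optional[float] = None

    @classmethod
    def fit(
        cls,
        calib: CalibrationSet,
        bin_count: int = 20,
        pseudocount: float = 0.5,
        n_strata: int = 4,
    ) -> "BayesFactorModel":
        return cls(build_class_distributions(calib, bin_count, pseudocount, n_strata))

    def score(self, site: CandidateSite) -> float:
        site.log_bf = log_bayes_factor(site, self.distributions)
        return site.log_bf

    def score_all(self, sites: Sequence[CandidateSite]) -> List[float]:
        return [self.score(s) for s in sites]

    def calibrate(
        self, labeled_sites: Iterable[Tuple[float, str]], target_fp: float = 0.05
    ) -> float:
        self.threshold = calibrate_threshold(labeled_sites, target_fp)
        return self.threshold


# ---------------------------------------------------------------------------
# Genotype-string classification (validated-variant tables)
# ---------------------------------------------------------------------------

_ALLELES = frozenset("ACGT")


def _parse_genotype(gt: str) -> Tuple[str, str]:
    parts = gt.strip().upper().split("/")
    if len(parts) != 2 or not all(p in _ALLELES for p in parts):
        raise ValueError(f"malformed genotype {gt!r}")
    return parts[0], parts[1]


def classify_trio_genotypes(
    father: str, mother: str, proband: str, chromosome: str | None = None
) -> str:
    """Classify a trio of unphased genotype strings (e.g. ``"G/A"``).

    Returns one of ``consistent``, ``de_novo_het``, ``de_novo_hom`` or
    ``mendelian_violation_other``:

    * *consistent* — some pair of parental transmissions explains the proband;
    * *de_novo_het* — the proband carries exactly one allele absent from both
      parents;
    * *de_novo_hom* — the proband is homozygous for an allele absent from
      both parents;
    * *mendelian_violation_other* — inconsistent, but every proband allele is
      seen in a parent (allele-dropout-like patterns).
    """
    f = _parse_genotype(father)
    m = _parse_genotype(mother)
    p = _parse_genotype(proband)
    parental = set(f) | set(m)
    consistent = any(
        tuple(sorted((a, b))) == tuple(sorted(p)) for a in f for b in m
    )
    if consistent:
        return "consistent"
    novel = [a for a in set(p) if a not in parental]
    if p[0] == p[1] and p[0] not in parental:
        return "de_novo_hom"
    if len(novel) == 1 and p[0] != p[1]:
        return "de_novo_het"
    return "mendelian_violation_other"
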