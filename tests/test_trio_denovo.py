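"""Unit and property tests for de novo detection and Bayes-factor filtering."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import binom

from trionet.simulate import (
    SimulationConfig,
    simulate_calibration_features,
    simulate_labeled_scores,
    simulate_trio_reads,
)
from trionet.trio_denovo import (
    BayesFactorModel,
    CalibrationRecord,
    CalibrationSet,
    CandidateSite,
    SiteReadData,
    build_class_distributions,
    calibrate_threshold,
    classify_trio_genotypes,
    detect_candidates,
    filter_candidates,
    genotype_log_likelihood,
    log_bayes_factor,
)

# ---------------------------------------------------------------------------
# genotype_log_likelihood
# ---------------------------------------------------------------------------


def test_likelihood_zero_depth_is_log_one():
    for g in ("RR", "RA", "AA"):
        assert genotype_log_likelihood(0, 0, g, 0.01) == 0.0


def test_likelihood_heterozygote_symmetric():
    expected = math.log(math.comb(10, 5)) + 10 * math.log(0.5)
    assert genotype_log_likelihood(10, 5, "RA", 0.01) == pytest.approx(expected)


def test_likelihood_matches_per_read_product_oracle():
    # brute force: each of 20 reads independently shows ref with prob 1 - eps
    eps = 0.005
    oracle = 1.0
    for _ in range(20):
        oracle *= 1.0 - eps
    got = genotype_log_likelihood(20, 0, "RR", eps)
    assert got == pytest.approx(math.log(oracle), rel=1e-12)


@pytest.mark.parametrize("depth,alt,geno,eps", [
    (30, 3, "RR", 0.01), (25, 12, "RA", 0.005), (40, 39, "AA", 0.02),
])
def test_likelihood_matches_binomial_pmf(depth, alt, geno, eps):
    p = {"RR": eps, "RA": 0.5, "AA": 1 - eps}[geno]
    assert genotype_log_likelihood(depth, alt, geno, eps) == pytest.approx(
        binom.logpmf(alt, depth, p), rel=1e-12
    )


def test_likelihood_rejects_bad_inputs():
    with pytest.raises(ValueError):
        genotype_log_likelihood(10, -1, "RR", 0.01)
    with pytest.raises(ValueError):
        genotype_log_likelihood(10, 11, "RR", 0.01)
    with pytest.raises(ValueError):
        genotype_log_likelihood(10, 1, "RR", 0.7)


# ---------------------------------------------------------------------------
# detect_candidates and the 27-configuration enumeration oracle
# ---------------------------------------------------------------------------

GENOTYPES = ("RR", "RA", "AA")


def _oracle_is_candidate(site, error_rate=0.005, denovo_prior=1e-4):
    """Independent enumeration over all 27 trio configurations, in linear space."""

    def lik(member, g):
        p = {"RR": error_rate, "RA": 0.5, "AA": 1 - error_rate}[g]
        return float(
            binom.pmf(site.alt_count[member], site.depth[member], p)
        )

    def trans(child, father, mother):
        gam = {"RR": ["R"], "RA": ["R", "A"], "AA": ["A"]}
        total = 0.0
        for fa in gam[father]:
            for ma in gam[mother]:
                geno = "RA" if {fa, ma} == {"R", "A"} else fa * 2
                if geno == child:
                    total += 1.0 / (len(gam[father]) * len(gam[mother]))
        return total

    denovo = mendel = 0.0
    for f in GENOTYPES:
        for m in GENOTYPES:
            tp = {c: trans(c, f, m) for c in GENOTYPES}
            zero = [c for c in GENOTYPES if tp[c] == 0.0]
            for c in GENOTYPES:
                if tp[c] > 0:
                    prior = (1 - denovo_prior) * tp[c] if zero else tp[c]
                else:
                    prior = denovo_prior / len(zero)
                w = prior / 9.0 * lik("father", f) * lik("mother", m) * lik("proband", c)
                if f == "RR" and m == "RR" and c in ("RA", "AA"):
                    denovo += w
                elif tp[c] > 0:
                    mendel += w
    return denovo > mendel


def _site(fd, fa, md, ma, pd_, pa, sid="s"):
    return SiteReadData(
        site_id=sid, chrom="1", pos=1,
        depth={"father": fd, "mother": md, "proband": pd_},
        alt_count={"father": fa, "mother": ma, "proband": pa},
    )


def test_clear_denovo_site_is_candidate():
    cands = detect_candidates([_site(30, 0, 30, 0, 30, 14)], 0.005, 1e-4)
    assert len(cands) == 1
    assert cands[0].genotype_class == "het"


def test_all_reference_site_is_not_candidate():
    assert detect_candidates([_site(30, 0, 30, 0, 30, 0)]) == []


def test_empty_input_gives_empty_output():
    assert detect_candidates([]) == []


def test_detection_matches_enumeration_oracle_on_simulated_sites():
    cfg = SimulationConfig(seed=7, n_sites=400, denovo_rate=0.02, mean_depth=40)
    sites, truth = simulate_trio_reads(cfg)
    cands = detect_candidates(sites, cfg.error_rate, 1e-4)
    called = {c.site.site_id for c in cands}
    for site in sites:
        assert (site.site_id in called) == _oracle_is_candidate(
            site, cfg.error_rate, 1e-4
        ), site.site_id


def test_detection_recall_precision_on_planted_sites():
    cfg = SimulationConfig(seed=11, n_sites=1000, denovo_rate=0.01, mean_depth=60)
    sites, truth = simulate_trio_reads(cfg)
    cands = {c.site.site_id for c in detect_candidates(sites, cfg.error_rate)}
    planted = {s.site_id for s, t in zip(sites, truth) if t}
    assert planted, "generator planted no events at this seed"
    recall = len(cands & planted) / len(planted)
    precision = len(cands & planted) / len(cands) if cands else 0.0
    assert recall >= 0.9
    assert precision >= 0.9


@given(st.integers(0, 60), st.integers(0, 60), st.integers(0, 60),
       st.integers(0, 100), st.integers(0, 100), st.integers(0, 100))
def test_detection_agrees_with_oracle_on_random_read_counts(fa, ma, pa, fd, md, pd_):
    fd, md, pd_ = fd + 1, md + 1, pd_ + 1
    fa, ma, pa = min(fa, fd), min(ma, md), min(pa, pd_)
    site = _site(fd, fa, md, ma, pd_, pa)
    got = len(detect_candidates([site], 0.01, 1e-3)) == 1
    assert got == _oracle_is_candidate(site, 0.01, 1e-3)


# ---------------------------------------------------------------------------
# class distributions and the log Bayes factor
# ---------------------------------------------------------------------------


def _record(value, label, gclass="het", coverage=30.0, feature="f"):
    return CalibrationRecord(
        feature_vector={feature: value}, coverage=coverage,
        genotype_class=gclass, label=label,
    )


def test_identical_class_values_give_zero_log_bf():
    recs = [_record(1.0, "concordant") for _ in range(10)] + [
        _record(1.0, "discordant") for _ in range(10)
    ]
    dists = build_class_distributions(CalibrationSet(recs), bin_count=5,
                                      n_strata=1)
    site = CandidateSite(site=_site(30, 0, 30, 0, 30, 15), genotype_class="het",
                         feature_vector={"f": 1.0})
    assert log_bayes_factor(site, dists) == pytest.approx(0.0)


def test_density_ratio_four_gives_ln_four():
    # 2 bins over [0, 2): concordant mass heavily in bin 0, discordant in bin 1
    recs = []
    recs += [_record(0.5, "concordant")] * 8 + [_record(1.5, "concordant")] * 2
    recs += [_record(0.5, "discordant")] * 2 + [_record(1.5, "discordant")] * 8
    dists = build_class_distributions(CalibrationSet(recs), bin_count=2,
                                      pseudocount=1e-9, n_strata=1)
    site = CandidateSite(site=_site(30, 0, 30, 0, 30, 15), genotype_class="het",
                         feature_vector={"f": 0.5})
    assert log_bayes_factor(site, dists) == pytest.approx(math.log(4.0), abs=1e-6)


def test_log_bf_additive_over_independent_features():
    recs = []
    for val_f, val_g, lab, n in [
        (0.25, 0.25, "concordant", 8), (0.75, 0.25, "concordant", 2),
        (0.25, 0.75, "discordant", 4), (0.75, 0.75, "discordant", 6),
    ]:
        for _ in range(n):
            recs.append(CalibrationRecord(
                feature_vector={"f": val_f, "g": val_g}, coverage=30.0,
                genotype_class="het", label=lab))
    dists = build_class_distributions(CalibrationSet(recs), bin_count=2,
                                      pseudocount=1e-9, n_strata=1)

    def bf_of(features):
        site = CandidateSite(site=_site(30, 0, 30, 0, 30, 15),
                             genotype_class="het", feature_vector=features)
        return log_bayes_factor(site, dists)

    total = bf_of({"f": 0.25, "g": 0.25})
    assert total == pytest.approx(bf_of({"f": 0.25}) + bf_of({"g": 0.25}),
                                  abs=1e-9)


def test_distributions_match_independent_histogram_oracle(rng):
    n = 2000
    conc = rng.normal(2.0, 1.0, n)
    disc = rng.normal(0.0, 1.5, n)
    recs = [_record(v, "concordant") for v in conc] + [
        _record(v, "discordant") for v in disc
    ]
    pseudo = 0.5
    dists = build_class_distributions(CalibrationSet(recs), bin_count=20,
                                      pseudocount=pseudo, n_strata=1)
    edges = dists.bin_edges["f"]
    got_c, got_d = dists.lookup("f", 0, "het")
    for values, got in ((conc, got_c), (disc, got_d)):
        counts, _ = np.histogram(values, bins=edges)
        expected = (counts + pseudo) / (counts + pseudo).sum()
        np.testing.assert_allclose(got, expected, rtol=1e-12)
    assert np.all(got_c > 0) and np.all(got_d > 0)
    assert got_c.sum() == pytest.approx(1.0) and got_d.sum() == pytest.approx(1.0)


def test_single_label_calibration_raises():
    recs = [_record(1.0, "concordant")] * 5
    with pytest.raises(ValueError):
        build_class_distributions(CalibrationSet(recs))


def test_unknown_feature_raises_with_name():
    recs = [_record(1.0, "concordant"), _record(0.0, "discordant")]
    dists = build_class_distributions(CalibrationSet(recs), bin_count=2)
    site = CandidateSite(site=_site(30, 0, 30, 0, 30, 15), genotype_class="het",
                         feature_vector={"mystery": 1.0})
    with pytest.raises(KeyError, match="mystery"):
        log_bayes_factor(site, dists)


# ---------------------------------------------------------------------------
# filter_candidates
# ---------------------------------------------------------------------------


def _cand(log_bf, min_depth, sid="s"):
    d = {m: min_depth for m in ("father", "mother", "proband")}
    a = {m: 0 for m in ("father", "mother", "proband")}
    return CandidateSite(
        site=SiteReadData(sid, "1", 1, d, a), genotype_class="het",
        log_bf=log_bf,
    )


def test_filter_boundaries_inclusive():
    kept = filter_candidates([_cand(3.0, 20)])
    assert len(kept) == 1 and kept[0].passed_filters


def test_filter_removes_low_depth_despite_high_bf():
    assert filter_candidates([_cand(5.0, 19)]) == []


def test_filter_pass_through_with_permissive_thresholds():
    sites = [_cand(float(x), 10, sid=str(x)) for x in range(100)]
    kept = filter_candidates(sites, bf_threshold=-math.inf, depth_threshold=0)
    assert kept == sites  # order preserved, all retained


@given(st.lists(st.tuples(st.floats(-5, 10), st.integers(0, 60)), max_size=30),
       st.floats(-2, 6), st.floats(-2, 6), st.integers(0, 40), st.integers(0, 40))
def test_filter_subset_and_monotone(pairs, t1, t2, d1, d2):
    sites = [_cand(bf, dp, sid=str(i)) for i, (bf, dp) in enumerate(pairs)]
    lo_t, hi_t = sorted((t1, t2))
    lo_d, hi_d = sorted((d1, d2))
    loose = filter_candidates(sites, lo_t, lo_d)
    tight = filter_candidates(sites, hi_t, hi_d)
    assert set(id(s) for s in tight) <= set(id(s) for s in loose)
    assert all(s in sites for s in loose)


# ---------------------------------------------------------------------------
# calibrate_threshold
# ---------------------------------------------------------------------------


def test_calibration_separated_classes_yields_zero_fp():
    labeled = [(5.0 + i, "concordant") for i in range(10)] + [
        (-5.0 - i, "discordant") for i in range(10)
    ]
    t = calibrate_threshold(labeled, target_fp=0.05)
    accepted = [(s, l) for s, l in labeled if s >= t]
    assert accepted and all(l == "concordant" for _, l in accepted)


def test_calibration_target_one_accepts_everything():
    labeled = [(0.0, "concordant"), (1.0, "discordant")]
    assert calibrate_threshold(labeled, target_fp=1.0) == -math.inf


def test_calibration_unattainable_warns_and_returns_inf():
    labeled = [(1.0, "discordant")] * 10 + [(0.0, "concordant")]
    with pytest.warns(UserWarning):
        assert calibrate_threshold(labeled, target_fp=0.01) == math.inf


def test_calibration_single_label_raises():
    with pytest.raises(ValueError):
        calibrate_threshold([(1.0, "concordant")], 0.05)


def test_calibrated_threshold_matches_quantile_oracle_and_heldout_fp():
    """Two-Gaussian mixture: held-out FP proportion near target, and the
    threshold agrees with an independently computed empirical cut point."""
    scores = simulate_labeled_scores(10_000, seed=21)
    train, held = scores[:5000], scores[5000:]
    t = calibrate_threshold(train, target_fp=0.05)

    # independent oracle: brute-force scan over distinct empirical cut points
    svals = np.array([s for s, _ in train])
    disc = np.array([l == "discordant" for _, l in train])
    if disc.mean() <= 0.05:
        oracle = -math.inf
    else:
        oracle = math.inf
        for t0 in np.unique(svals):  # ascending: first hit is the smallest
            if disc[svals >= t0].mean() <= 0.05:
                oracle = float(t0)
                break
    assert t == pytest.approx(oracle)

    accepted = [(s, l) for s, l in held if s >= t]
    fp = sum(1 for _, l in accepted if l == "discordant") / len(accepted)
    # binomial 99% CI around the 5% target
    half_width = 2.576 * math.sqrt(0.05 * 0.95 / len(accepted))
    assert abs(fp - 0.05) <= half_width


def test_model_facade_fits_scores_and_calibrates():
    cfg = SimulationConfig(seed=3, n_calibration=1500)
    model = BayesFactorModel.fit(simulate_calibration_features(cfg))
    site = CandidateSite(site=_site(60, 0, 60, 0, 60, 30),
                         genotype_class="het",
                         feature_vector={"qd": 4.0, "mq": 2.0})
    bf = model.score(site)
    assert math.isfinite(bf) and site.log_bf == bf
    assert bf > 0  # class-typical concordant values
    t = model.calibrate(simulate_labeled_scores(2000, seed=4), 0.05)
    assert math.isfinite(t)


# ---------------------------------------------------------------------------
# classify_trio_genotypes
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("father,mother,proband,expected", [
    ("G/G", "G/G", "G/A", "de_novo_het"),       # published HISPPD1 row
    ("G/G", "T/T", "G/G", "mendelian_violation_other"),  # published CES4 row
    ("C/C", "C/C", "T/T", "de_novo_hom"),       # published PCDH19 row
    ("C/C", "C/C", "C/C", "consistent"),
    ("G/A", "G/A", "A/A", "consistent"),
    ("A/A", "A/G", "A/G", "consistent"),
    ("G/G", "G/A", "A/A", "mendelian_violation_other"),
])
def test_trio_genotype_classification_examples(father, mother, proband, expected):
    assert classify_trio_genotypes(father, mother, proband) == expected


def test_malformed_genotype_raises():
    with pytest.raises(ValueError):
        classify_trio_genotypes("G/", "G/G", "G/G")
    with pytest.raises(ValueError):
        classify_trio_genotypes("G/G", "GG", "G/N")


_allele = st.sampled_from("ACGT")
_geno = st.tuples(_allele, _allele).map(lambda p: f"{p[0]}/{p[1]}")


@given(_geno, _geno, _geno)
def test_classification_consistency_matches_transmission_oracle(f, m, p):
    """Brute-force oracle over the four parental transmission pairs."""
    fa, ma, pa = f.split("/"), m.split("/"), sorted(p.split("/"))
    oracle_consistent = any(
        sorted((x, y)) == pa for x in fa for y in ma
    )
    got = classify_trio_genotypes(f, m, p)
    assert (got == "consistent") == oracle_consistent
    if not oracle_consistent:
        parental = set(fa) | set(ma)
        novel = set(pa) - parental
        if pa[0] == pa[1] and pa[0] not in parental:
            assert got == "de_novo_hom"
        elif len(novel) == 1 and pa[0] != pa[1]:
            assert got == "de_novo_het"
        else:
            assert got == "mendelian_violation_other"
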