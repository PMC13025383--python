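"""Relationship likelihoods, LRs, posteriors and calls.

The independent oracle used throughout enumerates IBD states and allele
draws directly (shared allele + independent extras), rather than going
through the model's closed-form joint tables.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snpkin.kinship import (
    HYPOTHESES,
    HYPOTHESIS_NAMES,
    KinshipModel,
    classify,
    joint_genotype_prob,
    kinship_compare,
    relationship_log10_likelihood,
)
from snpkin.panel_io import SampleProfile
from snpkin.simulate import SimConfig, simulate_profile_pair


def oracle_joint_prob(g1: int, g2: int, p: float, k) -> float:
    """Brute-force joint genotype probability by allele enumeration."""
    q = 1 - p

    def allele_p(a):  # a=1 alt, a=0 ref
        return p if a else q

    def hw(g):
        return {0: q * q, 1: 2 * p * q, 2: p * p}[g]

    total = 0.0
    # IBD0: independent HWE draws
    total += k[0] * hw(g1) * hw(g2)
    # IBD1: shared allele s plus independent extras
    for s, e1, e2 in itertools.product([0, 1], repeat=3):
        if s + e1 == g1 and s + e2 == g2:
            total += k[1] * allele_p(s) * allele_p(e1) * allele_p(e2)
    # IBD2: identical genotypes
    if g1 == g2:
        total += k[2] * hw(g1)
    return total


def certain_profile(sample_id, genotypes, depth=30):
    sids = np.array([f"s{i:03d}" for i in range(len(genotypes))], dtype=object)
    gl = np.zeros((len(genotypes), 3))
    gl[np.arange(len(genotypes)), genotypes] = 1.0
    return SampleProfile(sample_id, sids, gl, np.full(len(genotypes), depth))


class TestJointGenotypeProb:
    def test_full_sibling_double_het(self):
        assert joint_genotype_prob(1, 1, 0.5, "full_sibling") == pytest.approx(0.3125)

    def test_parent_child_opposite_homozygotes_zero(self):
        assert joint_genotype_prob(0, 2, 0.3, "parent_child") == 0.0
        assert joint_genotype_prob(2, 0, 0.3, "parent_child") == 0.0

    @pytest.mark.parametrize("hyp", HYPOTHESIS_NAMES)
    def test_matches_allele_enumeration_oracle(self, hyp, rng):
        k = HYPOTHESES[hyp]
        for p in rng.uniform(0.01, 0.99, 5):
            for g1, g2 in itertools.product(range(3), repeat=2):
                assert joint_genotype_prob(g1, g2, p, k) == pytest.approx(
                    oracle_joint_prob(g1, g2, p, k), abs=1e-14
                )

    def test_normalisation_random_draws(self, rng):
        """Sum over the 9 cells is 1 for 1000 random (p, k) draws."""
        for _ in range(1000):
            p = rng.uniform(0.001, 0.999)
            k = rng.dirichlet([1, 1, 1])
            s = sum(
                joint_genotype_prob(g1, g2, p, k)
                for g1, g2 in itertools.product(range(3), repeat=2)
            )
            assert abs(s - 1.0) < 1e-12


class TestRelationshipLikelihood:
    def test_single_het_site_unrelated(self):
        gl = np.array([[0.0, 1.0, 0.0]])
        ll = relationship_log10_likelihood(gl, gl, [0.5], "unrelated")
        assert ll == pytest.approx(np.log10(0.25), abs=1e-12)

    def test_single_het_site_self_and_lr(self):
        gl = np.array([[0.0, 1.0, 0.0]])
        ll_self = relationship_log10_likelihood(gl, gl, [0.5], "self")
        assert ll_self == pytest.approx(np.log10(0.5), abs=1e-12)
        ll_unrel = relationship_log10_likelihood(gl, gl, [0.5], "unrelated")
        assert 10 ** (ll_self - ll_unrel) == pytest.approx(2.0)

    def test_gl_rescaling_shifts_all_hypotheses_equally(self, rng):
        n = 4
        gl_a = rng.random((n, 3))
        gl_b = rng.random((n, 3))
        p = rng.uniform(0.1, 0.9, n)
        scale = 7.3
        for hyp in HYPOTHESIS_NAMES:
            base = relationship_log10_likelihood(gl_a, gl_b, p, hyp)
            scaled = relationship_log10_likelihood(gl_a * scale, gl_b, p, hyp)
            assert scaled - base == pytest.approx(n * np.log10(scale), abs=1e-9)

    @pytest.mark.parametrize("hyp", ["unrelated", "full_sibling", "second_degree"])
    def test_exact_enumeration_on_certain_genotypes(self, hyp, rng):
        """<=5-site instances with certain genotypes match the brute
        force per-site sum of the enumeration oracle."""
        p = rng.uniform(0.05, 0.95, 5)
        g_a = rng.integers(0, 3, 5)
        g_b = rng.integers(0, 3, 5)
        gl_a = np.zeros((5, 3))
        gl_a[np.arange(5), g_a] = 1
        gl_b = np.zeros((5, 3))
        gl_b[np.arange(5), g_b] = 1
        expected = sum(
            np.log10(max(oracle_joint_prob(int(a), int(b), pi, HYPOTHESES[hyp]), 1e-300))
            for a, b, pi in zip(g_a, g_b, p)
        )
        got = relationship_log10_likelihood(gl_a, gl_b, p, hyp)
        assert got == pytest.approx(expected, abs=1e-12)


class TestKinshipCompare:
    def test_self_comparison_confident_profile(self, rng):
        g = rng.binomial(2, rng.uniform(0.05, 0.5, 1500))
        prof = certain_profile("X", g)
        freqs = {f"s{i:03d}": 0.3 for i in range(1500)}
        res = kinship_compare(prof, prof, freqs)
        assert res.most_likely == "self"
        assert res.pp["self"] > 0.9999

    def test_unrelated_lr_is_identically_one(self, rng):
        cfg = SimConfig(n_sites=300, seed=7)
        a, b, fr = simulate_profile_pair("third_degree", cfg)
        res = kinship_compare(a, b, fr, population="pop")
        assert res.log10_lr["unrelated"] == 0.0

    def test_pp_sums_to_one(self, rng):
        cfg = SimConfig(n_sites=300, seed=8)
        a, b, fr = simulate_profile_pair("full_sibling", cfg)
        res = kinship_compare(a, b, fr, population="pop")
        assert sum(res.pp.values()) == pytest.approx(1.0, abs=1e-9)
        assert res.most_likely == max(res.pp, key=res.pp.get)

    def test_unrelated_pairs_recovered(self):
        """Simulated unrelated pairs at 5000 matched-frequency sites are
        called unrelated in >=95% of seeds."""
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            cfg = SimConfig(n_sites=5000, depth=5.0, seed=1000 + seed)
            a, b, fr = simulate_profile_pair("unrelated", cfg)
            res = kinship_compare(a, b, fr, population="pop")
            hits += res.most_likely == "unrelated"
        assert hits >= 0.95 * n_seeds

    def test_empty_overlap_fails(self):
        a = certain_profile("A", [0, 1, 2])
        b = SampleProfile("B", np.array(["zzz"], dtype=object),
                          np.array([[1.0, 0.1, 0.0]]), np.array([1]))
        res = kinship_compare(a, b, {"s000": 0.5, "zzz": 0.5})
        assert res.failed
        assert classify(res).status == "failed"

    def test_relationship_recovery_across_categories(self):
        """argmax hypothesis equals the simulated category at 50k sites,
        depth 5, for self through third degree."""
        for cat in ["self", "parent_child", "full_sibling", "second_degree", "third_degree"]:
            hits = 0
            for seed in range(10):
                cfg = SimConfig(n_sites=50_000, depth=5.0, seed=hash((cat, seed)) % 2**31)
                a, b, fr = simulate_profile_pair(cat, cfg)
                res = kinship_compare(a, b, fr, population="pop")
                hits += res.most_likely == cat
            assert hits >= 9, f"{cat}: only {hits}/10 recovered"

    def test_lr_monotone_in_site_count(self):
        """Median log10 LR of the true category is non-decreasing in the
        number of sites."""
        sizes = [1000, 5000, 20_000, 50_000]
        medians = []
        for n in sizes:
            lrs = []
            for seed in range(10):
                cfg = SimConfig(n_sites=n, seed=50_000 + seed)
                a, b, fr = simulate_profile_pair("second_degree", cfg)
                res = kinship_compare(a, b, fr, population="pop")
                lrs.append(res.log10_lr["second_degree"])
            medians.append(np.median(lrs))
        assert all(m2 >= m1 for m1, m2 in zip(medians, medians[1:])), medians

    def test_lr_decreases_with_genetic_distance(self):
        """At equal site counts the median log10 LR of the true category
        falls from parent-child to 4th degree."""
        cats = ["parent_child", "full_sibling", "second_degree", "third_degree", "fourth_degree"]
        medians = {}
        for cat in cats:
            lrs = []
            for seed in range(10):
                cfg = SimConfig(n_sites=10_000, seed=90_000 + seed)
                a, b, fr = simulate_profile_pair(cat, cfg)
                res = kinship_compare(a, b, fr, population="pop")
                lrs.append(res.log10_lr[cat])
            medians[cat] = np.median(lrs)
        # both 1st-degree categories sit above the 2nd-degree median; the
        # two 1st-degree categories themselves are statistically tied
        assert medians["parent_child"] > medians["second_degree"]
        ladder = ["full_sibling", "second_degree", "third_degree", "fourth_degree"]
        assert all(
            medians[c1] > medians[c2] for c1, c2 in zip(ladder, ladder[1:])
        ), medians


class TestClassify:
    def make_result(self, lls):
        return kinship_compare(
            certain_profile("A", [1] * 3), certain_profile("B", [1] * 3),
            {f"s{i:03d}": 0.5 for i in range(3)},
        ) if lls is None else lls

    def test_low_lr_fourth_degree_inconclusive(self, rng):
        """A most-likely 4th-degree call with log10 LR 0.67 fails the
        >=4 threshold."""
        cfg = SimConfig(n_sites=60, seed=11)
        found = None
        for seed in range(60):
            a, b, fr = simulate_profile_pair("fourth_degree", cfg.with_(seed=seed))
            res = kinship_compare(a, b, fr, population="pop")
            if res.most_likely == "fourth_degree" and res.log10_lr["fourth_degree"] < 4:
                found = res
                break
        assert found is not None
        assert classify(found).status == "inconclusive"

    def test_pp_just_below_strict_threshold_inconclusive(self):
        """PP 99.982% passes the 95% threshold but not 99.99%."""
        lls = {h: -100.0 for h in HYPOTHESIS_NAMES}
        lls["second_degree"] = 0.0
        lls["third_degree"] = np.log10(1.8e-4 / (1 - 1.8e-4))  # PP(second) = 99.982%
        lls["unrelated"] = -50.0  # log10 LR(second) = 50, clears the LR bar
        from snpkin.kinship import KinshipResults

        res = KinshipResults("A", "B", lls, 12_820, 12_820)
        assert res.pp["second_degree"] == pytest.approx(0.99982, abs=1e-5)
        assert classify(res, pp_min=0.9999).status == "inconclusive"
        assert classify(res, pp_min=0.95).status == "conclusive"

    def test_unrelated_branch_ignores_lr(self):
        from snpkin.kinship import KinshipResults

        lls = {h: -10.0 for h in HYPOTHESIS_NAMES}
        lls["unrelated"] = 0.0
        res = KinshipResults("A", "B", lls, 100, 100)
        assert res.most_likely == "unrelated"
        assert res.log10_lr["unrelated"] == 0.0
        assert classify(res).status == "conclusive"

    def test_tie_breaks_toward_more_distant(self):
        from snpkin.kinship import KinshipResults

        lls = {h: 0.0 for h in HYPOTHESIS_NAMES}
        res = KinshipResults("A", "B", lls, 10, 10)
        assert res.most_likely == "unrelated"


@settings(derandomize=True, max_examples=30)
@given(p=st.floats(0.001, 0.999), w=st.floats(0.01, 1), x=st.floats(0.01, 1))
def test_joint_prob_normalisation_property(p, w, x):
    k = np.array([w, x, 1.0])
    k = k / k.sum()
    s = sum(
        joint_genotype_prob(g1, g2, p, k)
        for g1 in range(3)
        for g2 in range(3)
    )
    assert abs(s - 1.0) < 1e-12
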