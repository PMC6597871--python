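"""Diversity statistics, Tajima's D, the neutral coalescent and LD-Ne."""

import numpy as np
import pytest

from landgen.popgen import (
    NeutralSimSpec, _coalescent_branches, debias_tajimas_d, diversity_metrics,
    ld_ne, simulate_neutral_sample, tajimas_d, tajimas_d_from_counts,
)

from conftest import make_genotype_table


# ---------------------------------------------------------------------------
# Tajima's D

def test_tajimas_d_hand_case():
    # Independent spreadsheet evaluation of the 1989 constants at n=10,
    # S=1, derived count 5: pi = 2*5*5/90, D = (pi - 1/a1)/sqrt(e1).
    d = tajimas_d_from_counts(np.array([5]), 10)
    assert d == pytest.approx(1.4636386435610194, rel=1e-12)


def test_tajimas_d_singletons_negative():
    counts = np.ones(40)  # every site a singleton among 10 haplotypes
    assert tajimas_d_from_counts(counts, 10) < 0


def test_tajimas_d_no_segregating_sites_nan():
    assert np.isnan(tajimas_d_from_counts(np.array([0, 10]), 10))


def test_tajimas_d_diploid_table_matches_counts(rng):
    d = rng.integers(0, 3, size=(12, 60)).astype(float)
    gt = make_genotype_table(d)
    assert tajimas_d(gt) == pytest.approx(
        tajimas_d_from_counts(d.sum(axis=0), 24), rel=1e-12)


# ---------------------------------------------------------------------------
# Neutral coalescent

def test_pairwise_tmrca_expectation():
    # For two lineages, E[T2] = 1 in coalescent units; the two branch
    # segments of the genealogy each have length T2.
    rng = np.random.default_rng(5)
    t2 = []
    for _ in range(4000):
        lengths, _ = _coalescent_branches(2, rng)
        t2.append(lengths[0])
    assert np.mean(t2) == pytest.approx(1.0, abs=0.05)


def test_watterson_expected_segregating_sites():
    a1 = sum(1.0 / i for i in range(1, 10))
    spec = NeutralSimSpec(10, theta=10.0, replicates=3000, seed=3)
    reps = simulate_neutral_sample(spec)
    mean_s = np.mean([m.shape[1] for m in reps])
    assert mean_s == pytest.approx(10.0 * a1, rel=0.05)


def test_simulator_is_deterministic():
    spec = NeutralSimSpec(8, s_fixed=20, replicates=5, seed=11)
    a = simulate_neutral_sample(spec)
    b = simulate_neutral_sample(spec)
    assert all(np.array_equal(x, y) for x, y in zip(a, b))


def test_neutral_d_matches_msprime_oracle():
    """The simulator's Tajima's D distribution agrees with an independent
    coalescent implementation (msprime) at the same conditions."""
    msprime = pytest.importorskip("msprime")
    n, theta = 30, 20.0
    ours = simulate_neutral_sample(
        NeutralSimSpec(n, theta=theta, replicates=800, seed=1))
    d_ours = [tajimas_d_from_counts(m.sum(0), n) for m in ours if m.shape[1] > 0]
    d_ref = []
    reps = msprime.sim_ancestry(samples=n, ploidy=1, population_size=1,
                                sequence_length=1, num_replicates=800,
                                random_seed=7)
    for ts in reps:
        mts = msprime.sim_mutations(ts, rate=theta / 4, discrete_genome=False)
        if mts.num_sites:
            d_ref.append(mts.Tajimas_D())
    assert np.mean(d_ours) == pytest.approx(np.mean(d_ref), abs=0.08)
    assert np.std(d_ours) == pytest.approx(np.std(d_ref), rel=0.15)


# ---------------------------------------------------------------------------
# MAF-bias correction

def test_debias_null_filter_is_identity():
    spec = NeutralSimSpec(20, s_fixed=40, replicates=400, seed=2)
    reps = simulate_neutral_sample(spec)
    d_obs = float(np.mean([tajimas_d_from_counts(m.sum(0), 20) for m in reps]))
    res = debias_tajimas_d(d_obs, 0.0, NeutralSimSpec(20, s_fixed=40,
                                                      replicates=400, seed=9))
    # with no MAF filter the simulated null mean equals the observed mean
    # up to Monte-Carlo error, so the corrected value is ~0 + noise
    assert res["corrected"] == pytest.approx(0.0, abs=5 * res["mc_se"] + 0.05)


def test_debias_convergence_with_replicates():
    base = dict(n_haplotypes=20, s_fixed=40)
    r1 = debias_tajimas_d(0.0, 0.05, NeutralSimSpec(replicates=800, seed=4, **base))
    r2 = debias_tajimas_d(0.0, 0.05, NeutralSimSpec(replicates=1600, seed=5, **base))
    assert abs(r1["bias"] - r2["bias"]) < 3 * (r1["mc_se"] + r2["mc_se"])


# ---------------------------------------------------------------------------
# Diversity metrics

def test_single_locus_counts():
    gt = make_genotype_table(np.array([[0.0], [1.0], [2.0]]))
    s = diversity_metrics(gt, by_cluster=False, n_boot=50)[0]
    assert s.ho == pytest.approx(1 / 3)
    # p = 0.5, unbiased He = 2*0.25*6/5
    assert s.he == pytest.approx(0.6)


def test_all_homozygous_reference_zero_diversity():
    gt = make_genotype_table(np.zeros((4, 10)))
    s = diversity_metrics(gt, by_cluster=False, n_boot=50)[0]
    assert s.ho == 0 and np.isnan(s.he) or s.he == 0


def test_equilibrium_population_f_near_zero(rng):
    p = rng.uniform(0.2, 0.8, 800)
    d = rng.binomial(2, p, size=(40, 800)).astype(float)
    gt = make_genotype_table(d)
    s = diversity_metrics(gt, by_cluster=False, n_boot=300, seed=1)[0]
    assert s.f_ci[0] <= 0.0 <= s.f_ci[1] or abs(s.f) < 0.02


def test_pi_matches_brute_force_hamming_oracle(rng):
    # pi per locus equals the mean pairwise haplotype difference fraction;
    # oracle enumerates all ordered haplotype pairs from allele counts.
    d = rng.integers(0, 3, size=(10, 50)).astype(float)
    gt = make_genotype_table(d)
    s = diversity_metrics(gt, by_cluster=False, n_boot=10)[0]
    n_hap = 20
    pis = []
    for j in range(50):
        k = d[:, j].sum()
        diff = k * (n_hap - k)  # unordered pairs differing
        pis.append(diff / (n_hap * (n_hap - 1) / 2))
    assert s.pi == pytest.approx(np.mean(pis), rel=1e-9)


def test_cluster_of_one_errors(rng):
    d = rng.integers(0, 3, size=(3, 20)).astype(float)
    gt = make_genotype_table(d, cluster=[1, 1, 2])
    with pytest.raises(ValueError, match="2"):
        diversity_metrics(gt)


def test_he_ge_ho_implies_positive_f(rng):
    p = rng.uniform(0.2, 0.8, 400)
    d = rng.binomial(2, p, size=(30, 400)).astype(float)
    # induce inbreeding: set a fraction of hets to homozygotes
    het = d == 1
    flip = het & (rng.random(d.shape) < 0.4)
    d[flip] = np.where(rng.random(d.shape)[flip] < 0.5, 0.0, 2.0)
    s = diversity_metrics(make_genotype_table(d), by_cluster=False, n_boot=50)[0]
    assert s.he > s.ho
    assert s.f > 0


# ---------------------------------------------------------------------------
# LD-based Ne

def _wright_fisher_sample(ne, n_sample, n_loci, rng, generations=12):
    """Individual-based Wright-Fisher population of unlinked loci.

    Tracks both haplotypes of every diploid so the finite-pedigree linkage
    disequilibrium the LD-Ne method measures is actually generated."""
    h1 = (rng.random((ne, n_loci)) < rng.uniform(0.3, 0.7, n_loci)).astype(np.int8)
    h2 = (rng.random((ne, n_loci)) < rng.uniform(0.3, 0.7, n_loci)).astype(np.int8)
    for _ in range(generations):
        mothers = rng.integers(0, ne, ne)
        fathers = rng.integers(0, ne, ne)
        pick_m = rng.integers(0, 2, (ne, n_loci)).astype(bool)
        pick_f = rng.integers(0, 2, (ne, n_loci)).astype(bool)
        new1 = np.where(pick_m, h1[mothers], h2[mothers])
        new2 = np.where(pick_f, h1[fathers], h2[fathers])
        h1, h2 = new1, new2
    idx = rng.choice(ne, size=n_sample, replace=False)
    return (h1[idx] + h2[idx]).astype(float)


def test_ld_ne_recovers_order_of_magnitude(rng):
    hits = 0
    for s in range(6):
        r = np.random.default_rng(100 + s)
        d = _wright_fisher_sample(100, 60, 120, r)
        gt = make_genotype_table(d)
        ne, ci = ld_ne(gt, mating="random")
        if np.isfinite(ne) and ci[0] <= 100 <= ci[1]:
            hits += 1
    assert hits >= 4


def test_ld_ne_monogamy_doubles_random(rng):
    d = _wright_fisher_sample(80, 50, 80, rng)
    gt = make_genotype_table(d)
    ne_r, _ = ld_ne(gt, mating="random")
    ne_m, _ = ld_ne(gt, mating="monogamy")
    if np.isfinite(ne_r):
        assert ne_m == pytest.approx(2 * ne_r, rel=1e-9)


def test_ld_ne_nonpositive_r2_gives_infinite(rng):
    # huge sample of independent loci: corrected r^2 often <= 0
    p = rng.uniform(0.3, 0.7, 40)
    d = rng.binomial(2, p, size=(500, 40)).astype(float)
    ne, _ = ld_ne(make_genotype_table(d), mating="random")
    assert ne > 1e3 or np.isinf(ne)
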