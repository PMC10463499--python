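"""Feature engineering: filters, rarefaction, prevalence partition, CLR,
alpha diversity, F:B ratio and Bray-Curtis PCoA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rumenlink as rl
from rumenlink.containers import ConfigurationError
from tests.conftest import toy_abundance


# ------------------------------------------------------------------ filters

def test_filter_asvs_presence_and_total_rules():
    # t0: 2 samples -> removed; t1: 3 samples total 6 -> kept;
    # t2: 3 samples total 5 (not > 5) -> removed
    tab = toy_abundance(
        [[3, 2, 1, 0],
         [4, 2, 2, 0],
         [0, 2, 2, 0],
         [0, 0, 0, 0]]
    )
    out = rl.filter_asvs(tab, min_samples=3, min_total=5)
    assert out.taxon_ids == ["t1"]


def test_filter_asvs_rejects_relative_input():
    tab = toy_abundance([[0.5, 0.5]], kind="relative")
    with pytest.raises(TypeError):
        rl.filter_asvs(tab)


def test_filter_asvs_empty_result_is_valid():
    tab = toy_abundance([[1, 0], [0, 1], [0, 0]])
    out = rl.filter_asvs(tab)
    assert out.n_taxa == 0 and out.n_samples == 3


def test_filter_genera_strict_occurrence_and_unclassified():
    # g0: in exactly 3 samples -> removed (strictly more than 3 required)
    # g1: unclassified at high abundance -> removed
    # g2: passes both rules; g3: too rare on average -> removed
    vals = np.array(
        [[0.2, 0.3, 0.5 - 3e-7, 1e-7],
         [0.2, 0.3, 0.5 - 3e-7, 1e-7],
         [0.2, 0.3, 0.5 - 3e-7, 1e-7],
         [0.0, 0.3, 0.7 - 4e-7, 1e-7]]
    )
    tab = toy_abundance(vals, kind="relative",
                        is_classified=np.array([True, False, True, True]))
    out = rl.filter_genera(tab, min_mean_abund=1e-6, min_samples=3)
    assert out.taxon_ids == ["t2"]


def test_prevalence_direct_counts():
    tab = toy_abundance([[1, 0, 2], [1, 0, 0], [1, 0, 3], [1, 0, 5]])
    assert np.allclose(rl.prevalence(tab), [1.0, 0.0, 0.75])


def test_trait_partition_boundaries():
    # 100 samples; taxa present in 60, 59, 1 samples -> quantitative at the
    # 60% boundary, binary just below, excluded below 1.5%
    n = 100
    vals = np.zeros((n, 3))
    vals[:60, 0] = 1.0
    vals[:59, 1] = 1.0
    vals[:1, 2] = 1.0
    tab = toy_abundance(vals, kind="relative")
    quant, binary, excluded = rl.classify_traits(tab, low=0.015, split=0.60)
    assert list(quant) == [0] and list(binary) == [1] and list(excluded) == [2]


def test_trait_partition_is_exhaustive_and_disjoint(small_cohort):
    tab = small_cohort["abundance"]
    quant, binary, excluded = rl.classify_traits(tab)
    all_idx = np.sort(np.concatenate([quant, binary, excluded]))
    assert np.array_equal(all_idx, np.arange(tab.n_taxa))


# --------------------------------------------------------------- rarefaction

def test_rarefy_identity_at_full_depth():
    tab = toy_abundance([[5, 3, 2]])
    out = rl.rarefy(tab, depth=10, seed=0)
    assert np.array_equal(out.values, tab.values)


def test_rarefy_drops_shallow_samples_and_hits_depth_exactly():
    tab = toy_abundance([[50, 30, 20], [2, 1, 0]])
    out = rl.rarefy(tab, depth=10, seed=0)
    assert out.sample_ids == ["s0"]
    assert out.values.sum() == 10


def test_rarefy_matches_hypergeometric_expectation():
    counts = np.array([[60, 30, 10]])
    tab = toy_abundance(counts)
    depth, reps = 20, 200
    totals = np.zeros(3)
    for r in range(reps):
        totals += rl.rarefy(tab, depth=depth, seed=r).values[0]
    mean = totals / reps
    expected = depth * counts[0] / counts.sum()
    var = depth * (counts[0] / counts.sum()) * (1 - counts[0] / counts.sum()) \
        * (counts.sum() - depth) / (counts.sum() - 1)
    se = np.sqrt(var / reps)
    assert np.all(np.abs(mean - expected) < 3 * se)


# ---------------------------------------------------------------------- CLR

def test_clr_uniform_composition_is_zero():
    tab = toy_abundance([[0.25] * 4], kind="relative")
    assert np.allclose(rl.clr_transform(tab, 1e-6), 0.0, atol=1e-12)


def test_clr_two_taxon_closed_form():
    x = np.array([[0.8, 0.2]])
    out = rl.clr_transform(x, pseudocount=1e-6)
    expected = 0.5 * np.log(0.800001 / 0.200001)
    assert np.allclose(out, [[expected, -expected]], atol=1e-12)


def test_clr_requires_positive_pseudocount():
    with pytest.raises(ConfigurationError):
        rl.clr_transform(np.array([[0.5, 0.5]]), pseudocount=0.0)


@settings(deadline=None, derandomize=True)
@given(st.integers(min_value=2, max_value=12), st.integers(min_value=0, max_value=2**31 - 1))
def test_clr_rows_always_sum_to_zero(k, seed):
    rng = np.random.default_rng(seed)
    x = rng.dirichlet(np.ones(k), size=3)
    out = rl.clr_transform(x, pseudocount=1e-6)
    assert np.allclose(out.sum(axis=1), 0.0, atol=1e-10)


# ----------------------------------------------------------- alpha diversity

def test_chao1_no_singletons_equals_richness():
    r = rl.alpha_diversity([5, 5, 5])
    assert r.chao1 == r.S_obs == 3


def test_chao1_bias_corrected_hand_value():
    # counts [1,1,2,3]: S=4, F1=2, F2=1 -> 4 + 2*1/(2*2) = 4.5
    r = rl.alpha_diversity([1, 1, 2, 3])
    assert r.chao1 == pytest.approx(4.5)
    assert r.chao1 >= r.S_obs


def test_shannon_uniform_is_log_k():
    for k in (2, 5, 11):
        r = rl.alpha_diversity([7] * k)
        assert r.shannon == pytest.approx(np.log(k))


def test_alpha_diversity_rejects_empty_sample():
    with pytest.raises(ValueError):
        rl.alpha_diversity([0, 0, 0])


def test_chao1_never_below_richness_random():
    rng = np.random.default_rng(0)
    for _ in range(50):
        counts = rng.integers(0, 6, size=30)
        if counts.sum() == 0:
            continue
        r = rl.alpha_diversity(counts)
        assert r.chao1 >= r.S_obs
        assert r.ace >= 0


# ------------------------------------------------------------------ FB ratio

def test_fb_ratio_values_and_guard():
    tab = toy_abundance(
        [[0.6, 0.3, 0.1], [0.45, 0.45, 0.1], [0.5, 0.0, 0.5]],
        kind="relative",
        phylum=["Firmicutes", "Bacteroidota", "Proteobacteria"],
    )
    r = rl.fb_ratio(tab)
    assert r[0] == pytest.approx(2.0)
    assert r[1] == pytest.approx(1.0)
    assert np.isnan(r[2])  # zero Bacteroidetes -> missing


def test_fb_ratio_requires_relevant_phyla():
    tab = toy_abundance([[1.0]], kind="relative", phylum=["Proteobacteria"])
    with pytest.raises(ValueError):
        rl.fb_ratio(tab)


# --------------------------------------------------------------------- PCoA

def test_bray_curtis_distance_extremes():
    from scipy.spatial.distance import braycurtis

    assert braycurtis([1, 0], [0, 1]) == pytest.approx(1.0)
    assert braycurtis([3, 1], [3, 1]) == pytest.approx(0.0)


def test_pcoa_matches_dense_eigendecomposition():
    rng = np.random.default_rng(4)
    vals = rng.dirichlet(np.ones(6), size=4)
    tab = toy_abundance(vals, kind="relative")
    scores, frac = rl.bray_curtis_pcoa(tab, k=2)

    # independent brute-force: explicit double centring + numpy eig
    from scipy.spatial.distance import braycurtis
    n = 4
    d = np.array([[braycurtis(vals[i], vals[j]) for j in range(n)] for i in range(n)])
    a = -0.5 * d**2
    J = np.eye(n) - np.ones((n, n)) / n
    g = J @ a @ J
    w, v = np.linalg.eig(g)
    order = np.argsort(w.real)[::-1]
    ref = v.real[:, order[0]] * np.sqrt(w.real[order[0]])
    assert np.allclose(np.abs(scores[:, 0]), np.abs(ref), atol=1e-8)


def test_pcoa_invariant_to_sample_order():
    rng = np.random.default_rng(9)
    vals = rng.dirichlet(np.ones(8), size=10)
    tab = toy_abundance(vals, kind="relative")
    perm = rng.permutation(10)
    scores1, _ = rl.bray_curtis_pcoa(tab, k=3)
    scores2, _ = rl.bray_curtis_pcoa(tab.take_samples(perm), k=3)
    assert np.allclose(np.abs(scores1[perm]), np.abs(scores2), atol=1e-8)


def test_pcoa_k_bound():
    tab = toy_abundance(np.random.default_rng(0).dirichlet(np.ones(3), size=4),
                        kind="relative")
    with pytest.raises(ValueError):
        rl.bray_curtis_pcoa(tab, k=4)


# -------------------------------------------------------------- feature set

def test_build_feature_set_shapes(small_cohort):
    rel = rl.filter_genera(small_cohort["abundance"])
    counts = rl.to_counts(small_cohort["abundance"], seed=0)
    feats = rl.build_feature_set(rel, counts_table=counts)
    assert set(feats.community.columns) >= {"richness", "chao1", "ace",
                                            "shannon", "fb_ratio", "pcoa1"}
    quant_prev = feats.prevalence[feats.quantitative.columns]
    bin_prev = feats.prevalence[feats.binary.columns]
    assert (quant_prev >= 0.60).all()
    assert ((bin_prev >= 0.015) & (bin_prev < 0.60)).all()
    assert set(feats.quantitative.columns).isdisjoint(feats.binary.columns)
    # CLR quantitative rows need not sum to zero (subset of the CLR table),
    # but binary entries are strictly 0/1
    assert set(np.unique(feats.binary.to_numpy())) <= {0.0, 1.0}
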