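"""Model fits: reliabilities, factor models, n-gram composition models,
controls, and cross-validation hygiene."""

import itertools

import numpy as np
import pytest

import neurosep as ns
from neurosep import separability as sep
from neurosep.stimuli import DEFAULT_ALPHABET
from neurosep.synthetic_neurons import AttributeTuning


def _rm_from_means(means, sset, jitter=None):
    """Wrap per-stimulus means as a 4-repetition response matrix."""
    rates = np.repeat(means[:, :, None], 4, axis=2)
    if jitter is not None:
        rates = rates + jitter
    return ns.ResponseMatrix(np.clip(rates, 0, None), sset,
                             window_s=0.15)


# ---------------------------------------------------------------------------
# Split-half reliability
# ---------------------------------------------------------------------------


def test_split_half_is_one_for_noise_free_responses(noise_free_rm):
    rel = ns.split_half_reliability(noise_free_rm)
    assert np.allclose(rel.r, 1.0)
    assert rel.mask.all()


def test_split_half_detects_anticorrelated_halves(letters_set):
    n_stim = len(letters_set)
    x = np.linspace(1.0, 2.0, n_stim)
    rates = np.zeros((1, n_stim, 4))
    rates[0, :, 0] = rates[0, :, 2] = x          # odd reps
    rates[0, :, 1] = rates[0, :, 3] = 3.0 - x    # even reps: negated + const
    rel = ns.split_half_reliability(ns.ResponseMatrix(rates, letters_set))
    assert rel.r[0] == pytest.approx(-1.0)
    assert not rel.mask[0]


def test_split_half_of_pure_noise_is_near_zero(letters_set):
    rng = np.random.default_rng(0)
    n_stim = len(letters_set)
    rates = rng.poisson(6.0, size=(200, n_stim, 4)) / 0.15
    rel = ns.split_half_reliability(ns.ResponseMatrix(rates, letters_set))
    assert np.mean(np.abs(rel.r) < 0.2) >= 0.95


def test_split_half_requires_two_repetitions(letters_set):
    rm = ns.ResponseMatrix(np.ones((1, len(letters_set), 1)), letters_set)
    with pytest.raises(ValueError):
        ns.split_half_reliability(rm)


# ---------------------------------------------------------------------------
# Factor models
# ---------------------------------------------------------------------------


def _planted_factor_rm(rule, letters_set, seed=0):
    rng = np.random.default_rng(seed)
    pop = ns.make_separable_population(8, "all-broad", rule, "sum", True,
                                       seed=seed)
    return ns.noise_free_responses(pop, letters_set)


def test_factor_model_recovers_its_own_class_exactly(letters_set):
    for rule in ("additive", "multiplicative"):
        rm = _planted_factor_rm(rule, letters_set, seed=1)
        fits = sep.fit_factor_model(rm, rule)
        for f in fits:
            assert abs(f.cv_correlation - 1.0) < 1e-9
            assert f.valid


def test_factor_model_dissociates_on_noise_free_additive_data(letters_set):
    rm = _planted_factor_rm("additive", letters_set, seed=2)
    add = sep.fit_factor_model(rm, "additive")
    mult = sep.fit_factor_model(rm, "multiplicative")
    for fa, fm in zip(add, mult):
        assert abs(fa.cv_correlation - 1.0) < 1e-9
        assert fm.cv_correlation < 1.0 - 1e-6


def test_factor_model_has_18_marginal_parameters(letters_set):
    rm = _planted_factor_rm("multiplicative", letters_set)
    f = sep.fit_factor_model(rm, "multiplicative")[0]
    sizes = {k: len(v) for k, v in f.marginals.items()}
    assert sizes == {"shape": 8, "location": 6, "distortion": 4}
    assert sum(sizes.values()) == 18
    assert f.condition_shape == (8, 6, 4)  # 192 predicted responses


def test_empty_factor_subset_rejected(letters_set):
    rm = _planted_factor_rm("additive", letters_set)
    with pytest.raises(ValueError):
        sep.fit_factor_model(rm, "additive", factor_subset=())


def test_reduced_and_lateralized_fits_run(letters_set):
    rm = _planted_factor_rm("multiplicative", letters_set)
    f_shape = sep.fit_factor_model(rm, "multiplicative", factor_subset=("shape",))
    f_ipsi = sep.fit_factor_model(rm, "multiplicative", location_subset="ipsi")
    assert all(np.isfinite(f.cv_correlation) for f in f_shape)
    assert f_ipsi[0].condition_shape == (8, 3, 4)


def test_combination_model_nests_the_additive_model(letters_set):
    rm = _planted_factor_rm("additive", letters_set, seed=3)
    add = sep.fit_factor_model(rm, "additive")
    comb = sep.fit_combination_model(rm)
    for fa, fc in zip(add, comb):
        assert fc.cv_correlation >= fa.cv_correlation - 1e-6


def test_combination_model_recovers_pure_multiplicative_weights(letters_set):
    rm = _planted_factor_rm("multiplicative", letters_set, seed=4)
    for fc in sep.fit_combination_model(rm):
        w = fc.weights / fc.weights[1]  # scale by the multiplicative weight
        assert abs(w[0]) < 1e-6 and abs(w[2]) < 1e-6


def test_combination_model_masks_constant_responses(letters_set):
    means = np.full((2, len(letters_set)), 7.0)
    rm = _rm_from_means(means, letters_set)
    fits = sep.fit_combination_model(rm)
    assert all(not f.valid for f in fits)


def test_predicted_letter_matrix_matches_truth_and_clips(letters_set):
    pop = ns.make_separable_population(5, "all-broad", "multiplicative",
                                       "sum", True, seed=5)
    rm = ns.noise_free_responses(pop, letters_set)
    fits = sep.fit_factor_model(rm, "multiplicative")
    truth = sep.raw_letter_matrix(rm)
    for i, f in enumerate(fits):
        grid = sep.predicted_letter_matrix(f)
        assert np.max(np.abs(grid - truth[i])) < 1e-9
        assert (sep.predicted_letter_matrix(f, clip_at_zero=True) >= 0).all()


# ---------------------------------------------------------------------------
# Marginal averaging vs brute-force oracle (small design)
# ---------------------------------------------------------------------------


def _small_design():
    glyphs = DEFAULT_ALPHABET[:3]
    descs, subsets = [], []
    for g in glyphs:
        for j in (2, 3):
            for k in (0, 1):
                slots = "*" * j + g + "*" * (5 - j)
                descs.append(ns.StimulusDescriptor(slots, k))
                subsets.append("single_letter")
    return ns.StimulusSet(descs, subsets), glyphs


def test_marginal_averaging_matches_brute_force_grid_search():
    """On a 3x2x2 design the analytic marginal-averaging fit is within 0.02
    of the best correlation any marginal combination can achieve."""
    sset, glyphs = _small_design()
    rng = np.random.default_rng(6)
    truth = rng.uniform(0.2, 1.0, size=(1, 3, 2, 2))
    noise = rng.normal(0, 0.1, size=truth.shape)
    means = (truth[..., 0][..., None] * 0 + truth).reshape(1, -1)  # layout order
    # arrange means to the stimulus order used by the design above
    vals = []
    for g in range(3):
        for j in range(2):
            for k in range(2):
                vals.append(truth[0, g, j, k] + noise[0, g, j, k])
    means = np.array(vals)[None, :]
    rm = _rm_from_means(np.clip(means, 0, None), sset)

    fit = sep.fit_factor_model(rm, "multiplicative", alphabet=glyphs)[0]
    target = rm.means()[0].reshape(3, 2, 2)
    r_avg = np.corrcoef(fit.predicted.ravel(), target.ravel())[0, 1]

    # brute force: grid over all 7 marginal values, correlation with the data
    grid = np.linspace(0.05, 1.0, 6)
    best = -1.0
    for svals in itertools.product(grid, repeat=3):
        S = np.array(svals)[:, None, None]
        for pvals in itertools.product(grid, repeat=2):
            P = np.array(pvals)[None, :, None]
            for dvals in itertools.product(grid, repeat=2):
                D = np.array(dvals)[None, None, :]
                pred = (S * P * D).ravel()
                r = np.corrcoef(pred, target.ravel())[0, 1]
                best = max(best, r)
    assert r_avg >= best - 0.02


# ---------------------------------------------------------------------------
# N-gram composition models
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def sum_rule_fit_inputs(easy_set):
    pop = ns.make_separable_population(10, "all-broad", "multiplicative",
                                       "sum", True, seed=7)
    rm = ns.noise_free_responses(pop, easy_set)
    grid = sep.raw_letter_matrix(rm)
    return rm.select("ngram"), grid


def test_additive_design_is_200_by_25(sum_rule_fit_inputs):
    rm_ngrams, grid = sum_rule_fit_inputs
    fits = sep.fit_ngram_additive(rm_ngrams, grid)
    assert all(f.design_shape == (200, 25) for f in fits)


def test_additive_fit_recovers_sum_rule_and_inverse_length_weights(
        sum_rule_fit_inputs):
    rm_ngrams, grid = sum_rule_fit_inputs
    fits = sep.fit_ngram_additive(rm_ngrams, grid)
    col = 0
    for f in fits:
        assert abs(f.cv_correlation - 1.0) < 1e-9
    f = fits[0]
    col = 0
    for n in range(2, 7):
        w = f.weights_odd[col:col + n]
        assert np.allclose(w, 1.0 / n, atol=1e-7)  # divisive normalization
        assert abs(f.weights_odd[col + n]) < 1e-6  # constant term vanishes
        col += n + 1


def test_predicted_vs_raw_letter_grids_agree_on_separable_data(easy_set):
    pop = ns.make_separable_population(8, "all-broad", "multiplicative",
                                       "sum", True, seed=8)
    rm = ns.noise_free_responses(pop, easy_set)
    rn = rm.select("ngram")
    raw = sep.raw_letter_matrix(rm)
    pred = np.stack([sep.predicted_letter_matrix(f) for f in
                     sep.fit_factor_model(rm.select("single_letter"),
                                          "multiplicative")])
    r_raw = [f.cv_correlation for f in sep.fit_ngram_additive(rn, raw)]
    r_pred = [f.cv_correlation for f in sep.fit_ngram_additive(rn, pred)]
    assert np.max(np.abs(np.array(r_raw) - np.array(r_pred))) < 0.05


def test_log_linear_fit_recovers_planted_exponents(ngrams_set):
    rng = np.random.default_rng(9)
    grid = rng.uniform(0.5, 2.0, size=(1, 8, 6, 4))
    w_true = {n: rng.uniform(0.5, 1.5, size=n + 1) for n in range(2, 7)}
    glyph_index = {g: i for i, g in enumerate(DEFAULT_ALPHABET)}
    means = np.zeros((1, len(ngrams_set)))
    for s, d in enumerate(ngrams_set):
        w = w_true[d.ngram_length]
        vals = [grid[0, glyph_index[d.slots[j]], j, d.distortion_level]
                for j in d.occupied_slots]
        means[0, s] = np.exp(w[-1]) * np.prod(np.power(vals, w[:-1]))
    rm = _rm_from_means(means, ngrams_set)
    fit = sep.fit_ngram_multiplicative(rm, grid, epsilon=1e-12)[0]
    assert abs(fit.cv_correlation - 1.0) < 1e-9
    col = 0
    for n in range(2, 7):
        assert np.allclose(fit.weights_odd[col:col + n], w_true[n][:-1],
                           atol=1e-6)
        col += n + 1
    assert (fit.predicted_all > 0).all()


def test_noise_free_double_dissociation_of_string_rules(easy_set):
    for rule, expect_add_wins in (("sum", True), ("product", False)):
        pop = ns.make_separable_population(30, "all-broad", "multiplicative",
                                           rule, True, seed=10)
        rm = ns.noise_free_responses(pop, easy_set)
        rn = rm.select("ngram")
        grid = np.stack([sep.predicted_letter_matrix(f, clip_at_zero=True)
                         for f in sep.fit_factor_model(
                             rm.select("single_letter"), "multiplicative")])
        r_add = np.array([f.cv_correlation for f in
                          sep.fit_ngram_additive(rn, grid)])
        r_mul = np.array([f.cv_correlation for f in
                          sep.fit_ngram_multiplicative(rn, grid, epsilon=1e-12)])
        frac = np.mean(r_add > r_mul)
        assert (frac >= 0.9) if expect_add_wins else (frac <= 0.1)


# ---------------------------------------------------------------------------
# String x distortion model
# ---------------------------------------------------------------------------


def test_string_distortion_product_fit_is_exact_with_54_marginals(ngrams_set):
    rng = np.random.default_rng(11)
    s_tune = rng.uniform(0.2, 1.0, size=50)
    d_tune = rng.uniform(0.2, 1.0, size=4)
    strings = sorted({d.slots for d in ngrams_set})
    idx = {p: i for i, p in enumerate(strings)}
    means = np.array([[40 * s_tune[idx[d.slots]] * d_tune[d.distortion_level]
                       for d in ngrams_set]])
    rm = _rm_from_means(means, ngrams_set)
    fit = sep.fit_string_distortion_model(rm, "multiplicative")[0]
    assert abs(fit.cv_correlation - 1.0) < 1e-9
    assert len(fit.marginals["string"]) + len(fit.marginals["distortion"]) == 54


def test_string_distortion_dissociates_under_poisson_noise(easy_set, ngrams_set):
    pop = ns.make_separable_population(60, "all-broad", "multiplicative",
                                       "product", True, seed=12)
    matched, _ = ns.match_reliability(pop, 0.5, ngrams_set, seed=13)
    rm = ns.sample_poisson(matched, easy_set, seed=14).select("ngram")
    r_mul = np.array([f.cv_correlation for f in
                      sep.fit_string_distortion_model(rm, "multiplicative")])
    r_add = np.array([f.cv_correlation for f in
                      sep.fit_string_distortion_model(rm, "additive")])
    assert sep.signrank_p(r_mul, r_add) < 0.05
    assert np.nanmedian(r_mul - r_add) > 0


# ---------------------------------------------------------------------------
# Shuffle control, normalization, hygiene
# ---------------------------------------------------------------------------


def test_identity_permutation_reproduces_the_unshuffled_fit(sum_rule_fit_inputs):
    rm_ngrams, grid = sum_rule_fit_inputs
    plain = sep.fit_ngram_additive(rm_ngrams, grid)
    ident = sep.shuffle_control(rm_ngrams, grid,
                                permutation=np.arange(len(rm_ngrams.stimulus_set)))
    for a, b in zip(plain, ident):
        assert a.cv_correlation == pytest.approx(b.cv_correlation)


def test_invalid_permutation_rejected(sum_rule_fit_inputs):
    rm_ngrams, grid = sum_rule_fit_inputs
    perm = np.zeros(len(rm_ngrams.stimulus_set), dtype=int)  # not a permutation
    with pytest.raises(ValueError):
        sep.shuffle_control(rm_ngrams, grid, permutation=perm)


def test_shuffle_preserves_response_multiset_and_kills_fit(easy_set):
    pop = ns.make_separable_population(60, "all-broad", "multiplicative",
                                       "sum", True, seed=15)
    rm = ns.noise_free_responses(pop, easy_set)
    rn = rm.select("ngram")
    grid = sep.raw_letter_matrix(rm)
    shuffled = sep.shuffle_control(rn, grid, seed=16)
    cv = np.array([f.cv_correlation for f in shuffled])
    assert abs(np.nanmean(cv)) < 0.1


def test_normalized_correlation_arithmetic_and_masking():
    assert sep.normalized_model_correlation(0.3, 0.6) == pytest.approx(0.5)
    assert np.isnan(sep.normalized_model_correlation(0.3, 0.0))
    assert np.isnan(sep.normalized_model_correlation(0.3, -0.2))
    out = sep.normalized_model_correlation([0.4, 0.2], [0.8, -1.0])
    assert out[0] == pytest.approx(0.5) and np.isnan(out[1])


def test_noise_free_correct_model_has_unit_normalized_ratio(noise_free_rm):
    rm = noise_free_rm.select("single_letter")
    rel = ns.split_half_reliability(rm)
    fits = sep.fit_factor_model(rm, "multiplicative")
    ratios = sep.normalized_model_correlation(
        [f.cv_correlation for f in fits], rel.r)
    assert np.allclose(ratios, 1.0, atol=1e-9)


def test_held_out_half_never_influences_training(easy_set):
    """Corrupting the even repetitions must not change odd-trained weights."""
    pop = ns.make_separable_population(5, "all-broad", "multiplicative",
                                       "sum", True, seed=17)
    rm = ns.sample_poisson(pop, easy_set, seed=18)
    corrupted = rm.rates.copy()
    corrupted[:, :, 1::2] *= 100.0  # even repetitions only
    rm2 = ns.ResponseMatrix(corrupted, easy_set)

    rn1, rn2 = rm.select("ngram"), rm2.select("ngram")
    grid = sep.raw_letter_matrix(rm)  # computed from all trials; hold fixed
    f1 = sep.fit_ngram_additive(rn1, grid)
    f2 = sep.fit_ngram_additive(rn2, grid)
    for a, b in zip(f1, f2):
        assert np.allclose(a.weights_odd, b.weights_odd)

    g1 = sep.fit_factor_model(rm.select("single_letter"), "multiplicative")
    g2 = sep.fit_factor_model(rm2.select("single_letter"), "multiplicative")
    for a, b in zip(g1, g2):
        # odd-trained marginal predictions correlate identically with any
        # fixed vector; compare the odd-direction correlation inputs via
        # equality of odd tensors is implicit — the even-trained direction
        # must differ, the odd-trained direction's prediction must not
        pass
    # spot-check via the combination model's odd-trained weights
    c1 = sep.fit_combination_model(rm.select("single_letter"))
    c2 = sep.fit_combination_model(rm2.select("single_letter"))
    for a, b in zip(c1, c2):
        assert np.allclose(a.weights, b.weights)  # weights come from odd half
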