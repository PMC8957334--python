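"""Separability model fits for letter, string and n-gram responses.

Two families of models are compared throughout.  For single letters the
response to shape i at location j and distortion k is modelled as either a
sum (S_i + P_j + D_k) or a product (S_i x P_j x D_k) of marginal tunings,
with the marginals estimated by averaging the training-half responses over
the other factors.  For n-grams the response is modelled from single-letter
responses, either as a location-weighted sum (one stacked least-squares
system across all lengths, 200 conditions x 25 weights for the default
design) or as a generalized product fitted log-linearly per length.

Model quality is a cross-validated correlation: models are trained on the
mean response over odd-numbered repetitions and correlated with the mean
over even-numbered repetitions, and vice versa, and the two correlations
averaged.  The split-half correlation of the two halves serves as the
reliability ceiling for each neuron.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .stimuli import DEFAULT_ALPHABET, N_SLOTS, StimulusSet
from .synthetic_neurons import (
    N_DISTORTIONS,
    N_SHAPES,
    ResponseMatrix,
    pearson_rows,
)

__all__ = [
    "ReliabilityProfile",
    "FactorModelFit",
    "CombinationFit",
    "NGramModelFit",
    "split_half_reliability",
    "fit_factor_model",
    "fit_combination_model",
    "predicted_letter_matrix",
    "raw_letter_matrix",
    "fit_ngram_additive",
    "fit_ngram_multiplicative",
    "fit_string_distortion_model",
    "shuffle_control",
    "normalized_model_correlation",
    "signrank_p",
]

FACTORS = ("shape", "location", "distortion")
IPSI_SLOTS = (0, 1, 2)
CONTRA_SLOTS = (3, 4, 5)


# ---------------------------------------------------------------------------
# Reliability
# ---------------------------------------------------------------------------


@dataclass
class ReliabilityProfile:
    """Per-neuron split-half correlations with an inclusion mask (r >= 0)."""

    r: np.ndarray
    mask: np.ndarray

    def __len__(self) -> int:
        return len(self.r)


def split_half_reliability(rm: ResponseMatrix, subset: str | None = None
                           ) -> ReliabilityProfile:
    """Correlate odd- and even-repetition mean rates across stimuli.

    ``subset`` optionally restricts to one stimulus-subset label.  Neurons
    whose halves are constant get NaN and are masked, as are neurons with
    negative reliability (the population-summary exclusion rule).
    """
    if rm.n_repetitions < 2:
        raise ValueError("split-half reliability needs at least 2 repetitions")
    if subset is not None:
        rm = rm.select(subset)
    r = pearson_rows(rm.odd_means(), rm.even_means())
    mask = np.isfinite(r) & (r >= 0)
    return ReliabilityProfile(r, mask)


# ---------------------------------------------------------------------------
# Factor models (letters x location x distortion; strings x distortion)
# ---------------------------------------------------------------------------


@dataclass
class FactorModelFit:
    """A separable (sum or product of marginals) fit for one neuron."""

    rule: str
    factors: tuple[str, ...]
    cv_correlation: float
    valid: bool
    marginals: dict = field(default_factory=dict)      # all-trials marginals
    affine: tuple[float, float] = (1.0, 0.0)           # all-trials slope, intercept
    predicted: np.ndarray | None = None                # all-trials prediction tensor
    condition_shape: tuple[int, ...] = ()


def _affine_rescale(pred: np.ndarray, target: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and intercept mapping pred onto target."""
    p = pred.ravel()
    t = target.ravel()
    var = np.var(p)
    if var <= 0:
        return 0.0, float(t.mean())
    slope = float(np.cov(p, t, bias=True)[0, 1] / var)
    return slope, float(t.mean() - slope * p.mean())


def _marginal_prediction(tensor: np.ndarray, rule: str, axes: Sequence[int]
                         ) -> tuple[np.ndarray, list[np.ndarray]]:
    """Marginal-averaging prediction of a k-way tensor over chosen axes."""
    nd = tensor.ndim
    marginals = []
    parts = []
    for ax in axes:
        other = tuple(a for a in range(nd) if a != ax)
        m = tensor.mean(axis=other)
        marginals.append(m)
        shape = [1] * nd
        shape[ax] = len(m)
        parts.append(m.reshape(shape))
    if rule == "additive":
        pred = np.zeros_like(tensor)
        for p in parts:
            pred = pred + p
    elif rule == "multiplicative":
        pred = np.ones_like(tensor)
        for p in parts:
            pred = pred * p
    else:
        raise ValueError(f"rule must be additive or multiplicative: {rule!r}")
    pred = np.broadcast_to(pred, tensor.shape).copy()
    return pred, marginals


def _letter_tensor(means: np.ndarray, stimulus_set: StimulusSet,
                   slots: Sequence[int], levels: Sequence[int],
                   alphabet: Sequence[str]) -> np.ndarray:
    """Arrange single-letter means as (N, len(alphabet), len(slots), len(levels))."""
    glyph_index = {g: i for i, g in enumerate(alphabet)}
    slot_pos = {j: a for a, j in enumerate(slots)}
    lev_pos = {k: a for a, k in enumerate(levels)}
    T = np.full((means.shape[0], len(alphabet), len(slots), len(levels)), np.nan)
    for s, d in enumerate(stimulus_set):
        if d.ngram_length != 1:
            raise ValueError("letter tensor requires single-letter stimuli only")
        j = d.occupied_slots[0]
        if j not in slot_pos or d.distortion_level not in lev_pos:
            continue
        T[:, glyph_index[d.slots[j]], slot_pos[j], lev_pos[d.distortion_level]] = means[:, s]
    if np.isnan(T).any():
        raise ValueError("incomplete single-letter design for the requested subset")
    return T


def fit_factor_model(
    rm: ResponseMatrix,
    rule: str,
    factor_subset: Sequence[str] = FACTORS,
    location_subset: str = "both",
    alphabet: Sequence[str] = DEFAULT_ALPHABET,
) -> list[FactorModelFit]:
    """Fit the shape x location x distortion separable model per neuron.

    Marginals are estimated on each repetition half by averaging over the
    other factors, affinely rescaled to the training half, and scored by
    the cross-validated correlation with the held-out half (averaged over
    the two train/test directions).  ``factor_subset`` restricts the model
    to fewer factors (reduced models); ``location_subset`` restricts the
    design to ipsilateral or contralateral slots.
    """
    factor_subset = tuple(factor_subset)
    if not factor_subset or any(f not in FACTORS for f in factor_subset):
        raise ValueError(f"factor_subset must be a non-empty subset of {FACTORS}")
    allowed = {"both": tuple(range(N_SLOTS)), "ipsi": IPSI_SLOTS,
               "contra": CONTRA_SLOTS}[location_subset]
    sset = rm.stimulus_set
    keep = [i for i, d in enumerate(sset) if d.ngram_length == 1
            and d.occupied_slots[0] in allowed]
    rm = rm.take_stimuli(keep)
    slots = tuple(sorted({d.occupied_slots[0] for d in rm.stimulus_set}))
    levels = sorted({d.distortion_level for d in rm.stimulus_set})
    axes = [FACTORS.index(f) + 1 for f in factor_subset]  # axis 0 is neurons
    tensors = {
        "odd": _letter_tensor(rm.odd_means(), rm.stimulus_set, slots, levels, alphabet),
        "even": _letter_tensor(rm.even_means(), rm.stimulus_set, slots, levels, alphabet),
        "all": _letter_tensor(rm.means(), rm.stimulus_set, slots, levels, alphabet),
    }

    fits = []
    n_neurons = rm.n_neurons
    preds = {}
    for half, T in tensors.items():
        pred = np.empty_like(T)
        margs: list[list[np.ndarray]] = []
        for i in range(n_neurons):
            p, m = _marginal_prediction(T[i], rule, [a - 1 for a in axes])
            pred[i] = p
            margs.append(m)
        preds[half] = (pred, margs)

    flat = {h: tensors[h].reshape(n_neurons, -1) for h in tensors}
    pflat = {h: preds[h][0].reshape(n_neurons, -1) for h in tensors}
    r_oe = pearson_rows(pflat["odd"], flat["even"])
    r_eo = pearson_rows(pflat["even"], flat["odd"])
    cv = (r_oe + r_eo) / 2.0
    for i in range(n_neurons):
        slope, intercept = _affine_rescale(pflat["all"][i], flat["all"][i])
        fits.append(FactorModelFit(
            rule=rule,
            factors=factor_subset,
            cv_correlation=float(cv[i]),
            valid=bool(np.isfinite(cv[i])),
            marginals=dict(zip(factor_subset, preds["all"][1][i])),
            affine=(slope, intercept),
            predicted=slope * preds["all"][0][i] + intercept,
            condition_shape=tensors["all"].shape[1:],
        ))
    return fits


@dataclass
class CombinationFit:
    """Least-squares blend r = w1*r_a + w2*r_m + w3*r_a*r_m (+ intercept)."""

    weights: np.ndarray
    cv_correlation: float
    valid: bool
    collinear: bool = False


def fit_combination_model(rm: ResponseMatrix,
                          alphabet: Sequence[str] = DEFAULT_ALPHABET
                          ) -> list[CombinationFit]:
    """Fit the additive/multiplicative combination model per neuron."""
    sset = rm.stimulus_set
    keep = [i for i, d in enumerate(sset) if d.ngram_length == 1]
    rm = rm.take_stimuli(keep)
    levels = sorted({d.distortion_level for d in rm.stimulus_set})
    slots = tuple(range(N_SLOTS))
    halves = {"odd": (rm.odd_means(), rm.even_means()),
              "even": (rm.even_means(), rm.odd_means())}
    n = rm.n_neurons
    corrs = {h: np.full(n, np.nan) for h in halves}
    weights = np.full((n, 4), np.nan)
    collinear = np.zeros(n, dtype=bool)
    for half, (train, test) in halves.items():
        T_tr = _letter_tensor(train, rm.stimulus_set, slots, levels, alphabet)
        T_te = _letter_tensor(test, rm.stimulus_set, slots, levels, alphabet)
        for i in range(n):
            ra, _ = _marginal_prediction(T_tr[i], "additive", [0, 1, 2])
            rmu, _ = _marginal_prediction(T_tr[i], "multiplicative", [0, 1, 2])
            X = np.column_stack([ra.ravel(), rmu.ravel(),
                                 (ra * rmu).ravel(), np.ones(ra.size)])
            y = T_tr[i].ravel()
            w, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
            if rank < X.shape[1]:
                collinear[i] = True
            pred = X @ w
            r = pearson_rows(pred[None, :], T_te[i].ravel()[None, :])[0]
            corrs[half][i] = r
            if half == "odd":
                weights[i] = w
    cv = (corrs["odd"] + corrs["even"]) / 2.0
    return [CombinationFit(weights[i], float(cv[i]), bool(np.isfinite(cv[i])),
                           bool(collinear[i])) for i in range(n)]


def predicted_letter_matrix(fit: FactorModelFit, clip_at_zero: bool = False
                            ) -> np.ndarray:
    """The fitted 8 x 6 x 4 single-letter rate grid of one neuron."""
    if fit.predicted is None or fit.condition_shape != (N_SHAPES, N_SLOTS, N_DISTORTIONS):
        raise ValueError("fit does not come from the full single-letter design")
    grid = fit.predicted.copy()
    return np.clip(grid, 0.0, None) if clip_at_zero else grid


def raw_letter_matrix(rm: ResponseMatrix,
                      alphabet: Sequence[str] = DEFAULT_ALPHABET) -> np.ndarray:
    """Observed all-trials letter means as (N, 8, 6, 4) — the raw-rate
    alternative to model-predicted letter responses."""
    keep = [i for i, d in enumerate(rm.stimulus_set) if d.ngram_length == 1]
    rm = rm.take_stimuli(keep)
    levels = sorted({d.distortion_level for d in rm.stimulus_set})
    return _letter_tensor(rm.means(), rm.stimulus_set, tuple(range(N_SLOTS)),
                          levels, alphabet)


# ---------------------------------------------------------------------------
# N-gram composition models
# ---------------------------------------------------------------------------


@dataclass
class NGramModelFit:
    """A composition model predicting n-gram responses from letters."""

    model: str
    cv_correlation: float
    valid: bool
    weights_odd: np.ndarray | None = None
    weights_even: np.ndarray | None = None
    weights_all: np.ndarray | None = None
    predicted_all: np.ndarray | None = None   # all-trials-trained predictions
    design_shape: tuple[int, int] = (0, 0)
    dropped_conditions: list[int] = field(default_factory=list)
    rank_deficient: bool = False


def _ngram_conditions(stimulus_set: StimulusSet,
                      alphabet: Sequence[str]) -> dict[int, list[int]]:
    """Group n-gram condition indices by string length (ascending)."""
    by_len: dict[int, list[int]] = {}
    for s, d in enumerate(stimulus_set):
        n = d.ngram_length
        if n < 2:
            raise ValueError("n-gram fits need stimuli with >= 2 letters")
        by_len.setdefault(n, []).append(s)
    return dict(sorted(by_len.items()))


def _additive_design(stimulus_set: StimulusSet, letter_grid: np.ndarray,
                     alphabet: Sequence[str]) -> np.ndarray:
    """Stacked design: per length, n letter-response columns + 1 constant."""
    glyph_index = {g: i for i, g in enumerate(alphabet)}
    by_len = _ngram_conditions(stimulus_set, alphabet)
    n_cols = sum(n + 1 for n in by_len)
    X = np.zeros((len(stimulus_set), n_cols))
    col0 = 0
    for n, rows in by_len.items():
        for s in rows:
            d = stimulus_set[s]
            for p, j in enumerate(d.occupied_slots):
                X[s, col0 + p] = letter_grid[glyph_index[d.slots[j]], j,
                                             d.distortion_level]
            X[s, col0 + n] = 1.0
        col0 += n + 1
    return X


def _per_neuron_letter_grid(letter_matrix: np.ndarray, n_neurons: int) -> np.ndarray:
    lm = np.asarray(letter_matrix, float)
    if lm.ndim == 3:
        lm = np.broadcast_to(lm, (n_neurons,) + lm.shape)
    if lm.shape != (n_neurons, N_SHAPES, N_SLOTS, N_DISTORTIONS):
        raise ValueError("letter_matrix must be (8,6,4) or (N,8,6,4)")
    return lm


def fit_ngram_additive(
    rm: ResponseMatrix,
    letter_matrix: np.ndarray,
    alphabet: Sequence[str] = DEFAULT_ALPHABET,
) -> list[NGramModelFit]:
    """Fit the stacked linear letter-sum model of n-gram responses.

    ``letter_matrix`` is the (N, 8, 6, 4) grid of single-letter responses
    (model-predicted or raw) used as regressors.  Weights are solved by
    least squares on the training half; the composite cross-validated
    correlation pools all n-gram conditions.
    """
    lm = _per_neuron_letter_grid(letter_matrix, rm.n_neurons)
    halves = {"odd": (rm.odd_means(), rm.even_means()),
              "even": (rm.even_means(), rm.odd_means()),
              "all": (rm.means(), None)}
    fits = [NGramModelFit("additive", np.nan, False) for _ in range(rm.n_neurons)]
    corr = {h: np.full(rm.n_neurons, np.nan) for h in ("odd", "even")}
    for i in range(rm.n_neurons):
        X = _additive_design(rm.stimulus_set, lm[i], alphabet)
        fits[i].design_shape = X.shape
        for half, (train, test) in halves.items():
            w, _, rank, _ = np.linalg.lstsq(X, train[i], rcond=None)
            if rank < X.shape[1]:
                fits[i].rank_deficient = True
            pred = X @ w
            setattr(fits[i], f"weights_{half}", w)
            if half == "all":
                fits[i].predicted_all = pred
            else:
                corr[half][i] = pearson_rows(pred[None, :], test[i][None, :])[0]
    cv = (corr["odd"] + corr["even"]) / 2.0
    for i, f in enumerate(fits):
        f.cv_correlation = float(cv[i])
        f.valid = bool(np.isfinite(cv[i]))
    return fits


def fit_ngram_multiplicative(
    rm: ResponseMatrix,
    letter_matrix: np.ndarray,
    epsilon: float | None = None,
    alphabet: Sequence[str] = DEFAULT_ALPHABET,
) -> list[NGramModelFit]:
    """Fit the generalized-product model log-linearly, per string length.

    The response to e.g. a bigram ab is modelled as w3 * r_a^w1 * r_b^w2;
    taking logs gives a linear system per length.  ``epsilon`` floors both
    responses and letter regressors before the log (default: 1% of the
    neuron's maximum training-half rate).  Predictions are strictly
    positive by construction and pooled across lengths for the composite
    cross-validated correlation.
    """
    lm = _per_neuron_letter_grid(letter_matrix, rm.n_neurons)
    glyph_index = {g: i for i, g in enumerate(alphabet)}
    by_len = _ngram_conditions(rm.stimulus_set, alphabet)
    halves = {"odd": (rm.odd_means(), rm.even_means()),
              "even": (rm.even_means(), rm.odd_means()),
              "all": (rm.means(), None)}
    fits = [NGramModelFit("multiplicative", np.nan, False) for _ in range(rm.n_neurons)]
    corr = {h: np.full(rm.n_neurons, np.nan) for h in ("odd", "even")}
    n_cols = sum(n + 1 for n in by_len)
    for i in range(rm.n_neurons):
        fits[i].design_shape = (len(rm.stimulus_set), n_cols)
        for half, (train, test) in halves.items():
            eps = epsilon if epsilon is not None else 0.01 * max(train[i].max(), 1e-12)
            pred = np.zeros(len(rm.stimulus_set))
            weights = []
            for n, rows in by_len.items():
                logX = []
                for s in rows:
                    d = rm.stimulus_set[s]
                    vals = [lm[i, glyph_index[d.slots[j]], j, d.distortion_level]
                            for j in d.occupied_slots]
                    logX.append(np.log(np.asarray(vals) + eps))
                A = np.column_stack([np.array(logX), np.ones(len(rows))])
                z = np.log(train[i][rows] + eps)
                w, _, rank, _ = np.linalg.lstsq(A, z, rcond=None)
                if rank < A.shape[1]:
                    fits[i].rank_deficient = True
                pred[rows] = np.exp(A @ w)
                weights.append(w)
            wvec = np.concatenate(weights)
            setattr(fits[i], f"weights_{half}", wvec)
            if half == "all":
                fits[i].predicted_all = pred
            else:
                corr[half][i] = pearson_rows(pred[None, :], test[i][None, :])[0]
    cv = (corr["odd"] + corr["even"]) / 2.0
    for i, f in enumerate(fits):
        f.cv_correlation = float(cv[i])
        f.valid = bool(np.isfinite(cv[i]))
    return fits


def fit_string_distortion_model(rm: ResponseMatrix, rule: str
                                ) -> list[FactorModelFit]:
    """Two-factor (string identity x distortion) separable fit.

    Every string must be observed at all 4 distortion levels; for the
    default 50-string design this is a 54-marginal model (50 + 4).
    """
    strings = sorted({d.slots for d in rm.stimulus_set})
    levels = sorted({d.distortion_level for d in rm.stimulus_set})
    pos = {(p, k): None for p in strings for k in levels}
    for s, d in enumerate(rm.stimulus_set):
        pos[(d.slots, d.distortion_level)] = s
    if any(v is None for v in pos.values()):
        raise ValueError("every string must appear at every distortion level")
    idx = np.array([[pos[(p, k)] for k in levels] for p in strings])
    tensors = {"odd": rm.odd_means()[:, idx], "even": rm.even_means()[:, idx],
               "all": rm.means()[:, idx]}
    n = rm.n_neurons
    preds = {}
    margs_all = None
    for half, T in tensors.items():
        pred = np.empty_like(T)
        margs = []
        for i in range(n):
            p, m = _marginal_prediction(T[i], rule, [0, 1])
            pred[i] = p
            margs.append(m)
        preds[half] = pred
        if half == "all":
            margs_all = margs
    r_oe = pearson_rows(preds["odd"].reshape(n, -1), tensors["even"].reshape(n, -1))
    r_eo = pearson_rows(preds["even"].reshape(n, -1), tensors["odd"].reshape(n, -1))
    cv = (r_oe + r_eo) / 2.0
    fits = []
    for i in range(n):
        slope, intercept = _affine_rescale(preds["all"][i], tensors["all"][i])
        fits.append(FactorModelFit(
            rule=rule, factors=("string", "distortion"),
            cv_correlation=float(cv[i]), valid=bool(np.isfinite(cv[i])),
            marginals={"string": margs_all[i][0], "distortion": margs_all[i][1]},
            affine=(slope, intercept),
            predicted=slope * preds["all"][i] + intercept,
            condition_shape=tensors["all"].shape[1:],
        ))
    return fits


def shuffle_control(
    rm: ResponseMatrix,
    letter_matrix: np.ndarray,
    seed: int = 0,
    alphabet: Sequence[str] = DEFAULT_ALPHABET,
    permutation: np.ndarray | None = None,
) -> list[NGramModelFit]:
    """Additive n-gram fit after breaking the string-letter association.

    Permutes the n-gram condition labels (seeded, or via an explicit
    ``permutation``) before fitting, so an
    n-gram's response is no longer paired with its own constituent
    letters.  The permutation runs over all n-gram conditions, and the
    odd- and even-repetition halves are permuted independently, so that
    neither the letter association, the per-length mean structure, nor
    the half-to-half pairing survives — the cross-validated correlation
    of a compositional population then collapses to zero instead of
    retaining a least-squares overfit.  The per-neuron response multiset
    within each half is preserved exactly.
    """
    rng = np.random.default_rng(seed)
    n_cond = len(rm.stimulus_set)
    if permutation is not None:
        perm_odd = np.asarray(permutation, dtype=int)
        if sorted(perm_odd.tolist()) != list(range(n_cond)):
            raise ValueError("permutation must permute the condition indices")
        perm_even = perm_odd
    else:
        perm_odd, perm_even = rng.permutation(n_cond), rng.permutation(n_cond)
    rates = rm.rates.copy()
    rates[:, :, 0::2] = rm.rates[:, perm_odd, 0::2]
    rates[:, :, 1::2] = rm.rates[:, perm_even, 1::2]
    shuffled = ResponseMatrix(rates, rm.stimulus_set,
                              list(rm.neuron_ids), rm.window_s)
    return fit_ngram_additive(shuffled, letter_matrix, alphabet)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def normalized_model_correlation(cv_correlation, reliability):
    """Model correlation divided by split-half reliability (NaN if <= 0)."""
    cv = np.asarray(cv_correlation, float)
    rel = np.asarray(reliability, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where((rel > 0) & np.isfinite(rel), cv / rel, np.nan)
    return out if out.ndim else float(out)


def signrank_p(a, b=None) -> float:
    """Two-sided Wilcoxon signed-rank p-value (paired, NaNs dropped)."""
    a = np.asarray(a, float)
    d = a if b is None else a - np.asarray(b, float)
    d = d[np.isfinite(d)]
    d = d[d != 0]
    if len(d) == 0:
        return 1.0
    return float(stats.wilcoxon(d, alternative="two-sided").pvalue)
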