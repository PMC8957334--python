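"""Synthetic neural populations with controllable separability.

Simulated neurons carry marginal tuning curves over shape (8 glyphs),
retinal location (6 slots) and distortion level (4 levels).  Tuning can be
sharp (one-hot), broad (uniform on [0, 1]) or mixed (sparse Bernoulli mask
times uniform values).  Per-slot letter responses combine the three factors
either additively or multiplicatively; string responses combine the
occupied slots as a sum or product, optionally divided by string length
(divisive normalization).  Repetition noise is Poisson on spike counts in
a 150 ms window.

Three families of conjunction-coding neurons provide inseparable controls:
type 1 responds only when a preferred bigram occupies adjacent slots,
type 2 adds a constant baseline otherwise, and type 3 is compositional
except for a deviant bigram term.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .stimuli import (
    DEFAULT_ALPHABET,
    N_SLOTS,
    StimulusDescriptor,
    StimulusSet,
    default_ngram_strings,
)

__all__ = [
    "AttributeTuning",
    "SeparableNeuronSpec",
    "ConjunctionNeuronSpec",
    "ResponseMatrix",
    "make_separable_population",
    "make_conjunction_population",
    "expected_rate",
    "expected_rate_matrix",
    "sample_poisson",
    "noise_free_responses",
    "match_reliability",
    "odd_even_means",
    "pearson_rows",
]

N_SHAPES = 8
N_DISTORTIONS = 4
DEFAULT_WINDOW_S = 0.15  # the 50-200 ms counting window
DEFAULT_GAIN_RANGE = (20.0, 80.0)  # spikes/s


# ---------------------------------------------------------------------------
# Neuron specifications
# ---------------------------------------------------------------------------


@dataclass
class AttributeTuning:
    """Marginal tuning weights in [0, 1] for shape, location and distortion."""

    shape: np.ndarray
    location: np.ndarray
    distortion: np.ndarray
    kind: str  # sharp | broad | mixed

    def __post_init__(self) -> None:
        self.shape = np.asarray(self.shape, dtype=float)
        self.location = np.asarray(self.location, dtype=float)
        self.distortion = np.asarray(self.distortion, dtype=float)
        if self.shape.shape != (N_SHAPES,) or self.location.shape != (N_SLOTS,) \
                or self.distortion.shape != (N_DISTORTIONS,):
            raise ValueError("tuning vectors must have shapes (8,), (6,), (4,)")
        if self.kind not in ("sharp", "broad", "mixed"):
            raise ValueError(f"unknown tuning kind: {self.kind!r}")


@dataclass
class SeparableNeuronSpec:
    """A neuron whose responses factor over attributes and letters."""

    tuning: AttributeTuning
    attribute_rule: str  # additive | multiplicative
    string_rule: str     # sum | product
    normalize: bool
    gain: float

    def __post_init__(self) -> None:
        if self.attribute_rule not in ("additive", "multiplicative"):
            raise ValueError(f"unknown attribute rule: {self.attribute_rule!r}")
        if self.string_rule not in ("sum", "product"):
            raise ValueError(f"unknown string rule: {self.string_rule!r}")
        if self.gain <= 0:
            raise ValueError("gain must be positive")

    def unit_letter_grid(self) -> np.ndarray:
        """Per-slot letter tuning combined across attributes, (8, 6, 4) in
        [0, 1] units (gain not applied)."""
        t = self.tuning
        if self.attribute_rule == "multiplicative":
            return np.einsum("i,j,k->ijk", t.shape, t.location, t.distortion)
        # divide by 3 to keep additive and multiplicative on similar scales
        return (t.shape[:, None, None] + t.location[None, :, None]
                + t.distortion[None, None, :]) / 3.0

    def letter_rate_grid(self) -> np.ndarray:
        """Per-slot letter rates, an (8, 6, 4) grid in spikes/s.

        The gain multiplies the combined string response exactly once, so
        for single letters it appears here; responses therefore scale
        linearly with gain for both string rules.
        """
        return self.gain * self.unit_letter_grid()


@dataclass
class ConjunctionNeuronSpec:
    """A neuron with inseparable selectivity for one letter bigram.

    conj_type 1: responds only when the preferred bigram occupies adjacent
    slots.  conj_type 2: as type 1 plus a constant baseline (a fraction of
    the neuron's reference mean rate) on every other stimulus.  conj_type 3:
    compositional (sum of letter terms with divisive normalization) except
    that the bigram contributes a single deviant term when present.
    """

    conj_type: int
    preferred_bigram: str
    gain: float
    baseline_fraction: float = 0.30
    letter_tuning: np.ndarray | None = None  # (8, 6), type 3 only
    bigram_weight: float = 0.0               # type 3 only, in tuning units

    def __post_init__(self) -> None:
        if self.conj_type not in (1, 2, 3):
            raise ValueError(f"conj_type must be 1, 2 or 3: {self.conj_type}")
        if len(self.preferred_bigram) != 2:
            raise ValueError("preferred_bigram must have exactly 2 glyphs")
        if self.conj_type == 3 and self.letter_tuning is None:
            raise ValueError("type-3 neurons need an 8x6 letter tuning grid")
        if self.letter_tuning is not None:
            self.letter_tuning = np.asarray(self.letter_tuning, dtype=float)
            if self.letter_tuning.shape != (N_SHAPES, N_SLOTS):
                raise ValueError("letter_tuning must be (8, 6)")


# ---------------------------------------------------------------------------
# Population construction
# ---------------------------------------------------------------------------


def _draw_tuning(kind: str, rng: np.random.Generator) -> AttributeTuning:
    sizes = (N_SHAPES, N_SLOTS, N_DISTORTIONS)
    if kind == "sharp":
        vecs = []
        for m in sizes:
            v = np.zeros(m)
            v[rng.integers(m)] = 1.0
            vecs.append(v)
    elif kind == "broad":
        vecs = [rng.uniform(0.0, 1.0, size=m) for m in sizes]
    else:  # mixed: sparse mask with density 1/k, k drawn per neuron
        k = int(rng.integers(1, N_SLOTS + 1))
        vecs = []
        for m in sizes:
            mask = rng.random(m) < (1.0 / k)
            while not mask.any():  # a dead factor would silence the neuron
                mask = rng.random(m) < (1.0 / k)
            vecs.append(mask * rng.uniform(0.0, 1.0, size=m))
    return AttributeTuning(vecs[0], vecs[1], vecs[2], kind)


def make_separable_population(
    n: int,
    kind_policy: str = "mixed",
    attribute_rule: str = "multiplicative",
    string_rule: str = "sum",
    normalize: bool = True,
    gain_range: tuple[float, float] = DEFAULT_GAIN_RANGE,
    seed: int = 0,
) -> list[SeparableNeuronSpec]:
    """Draw a population of separable neuron specs.

    ``kind_policy``: ``all-sharp`` / ``all-broad`` / ``all-mixed`` give every
    neuron the same tuning kind; ``mixed`` assigns sharp or broad with
    probability 1/2 each.  Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("population size must be at least 1")
    policies = ("all-sharp", "all-broad", "all-mixed", "mixed")
    if kind_policy not in policies:
        raise ValueError(f"kind_policy must be one of {policies}")
    rng = np.random.default_rng(seed)
    specs = []
    for _ in range(n):
        if kind_policy == "mixed":
            kind = "sharp" if rng.random() < 0.5 else "broad"
        else:
            kind = kind_policy.removeprefix("all-")
        specs.append(SeparableNeuronSpec(
            tuning=_draw_tuning(kind, rng),
            attribute_rule=attribute_rule,
            string_rule=string_rule,
            normalize=normalize,
            gain=float(rng.uniform(*gain_range)),
        ))
    return specs


def make_conjunction_population(
    conj_type: int,
    n: int,
    seed: int = 0,
    bigrams: Sequence[str] | None = None,
    reference_rates: Sequence[float] | None = None,
    gain_range: tuple[float, float] = DEFAULT_GAIN_RANGE,
    baseline_fraction: float = 0.30,
    bigram_scale: float = 8.0,
) -> list[ConjunctionNeuronSpec]:
    """Draw a conjunction-coding population of one of the three types.

    Preferred bigrams cycle through the 10 bigram types of the recorded
    stimulus set (or ``bigrams`` if given).  For type 2 the baseline is
    ``baseline_fraction`` of the neuron's reference mean rate; for type 3
    the deviant bigram term is drawn like a letter term but scaled by
    ``bigram_scale`` (default 8: the conjunction is the neuron's dominant
    drive, exceeding the average whole-string letter sum, mirroring the
    full-gain bigram response of types 1 and 2).
    """
    if conj_type not in (1, 2, 3):
        raise ValueError(f"conj_type must be 1, 2 or 3: {conj_type}")
    if bigrams is None:
        bigrams = default_ngram_strings(0)[2]
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n):
        gain = float(rng.uniform(*gain_range))
        if reference_rates is not None:
            gain = float(reference_rates[i % len(reference_rates)])
        letter_tuning = None
        bigram_weight = 0.0
        if conj_type == 3:
            letter_tuning = rng.uniform(0.0, 1.0, size=(N_SHAPES, N_SLOTS))
            bigram_weight = bigram_scale * float(rng.uniform(0.0, 1.0))
        specs.append(ConjunctionNeuronSpec(
            conj_type=conj_type,
            preferred_bigram=bigrams[i % len(bigrams)],
            gain=gain,
            baseline_fraction=baseline_fraction,
            letter_tuning=letter_tuning,
            bigram_weight=bigram_weight,
        ))
    return specs


# ---------------------------------------------------------------------------
# Expected rates
# ---------------------------------------------------------------------------


def _contains_bigram(descriptor: StimulusDescriptor, bigram: str) -> bool:
    """True when the bigram's glyphs occupy two adjacent slots, in order."""
    s = descriptor.slots
    return any(s[j] == bigram[0] and s[j + 1] == bigram[1] for j in range(N_SLOTS - 1))


def expected_rate(spec, descriptor: StimulusDescriptor,
                  alphabet: Sequence[str] = DEFAULT_ALPHABET) -> float:
    """Noise-free expected firing rate of one neuron to one stimulus."""
    glyph_index = {g: i for i, g in enumerate(alphabet)}
    n = descriptor.ngram_length
    if isinstance(spec, SeparableNeuronSpec):
        grid = spec.unit_letter_grid()
        per_slot = [grid[glyph_index[descriptor.slots[j]], j, descriptor.distortion_level]
                    for j in descriptor.occupied_slots]
        rate = spec.gain * float(
            np.sum(per_slot) if spec.string_rule == "sum" else np.prod(per_slot))
        return rate / n if spec.normalize else rate
    if isinstance(spec, ConjunctionNeuronSpec):
        has = _contains_bigram(descriptor, spec.preferred_bigram)
        if spec.conj_type == 1:
            return spec.gain if has else 0.0
        if spec.conj_type == 2:
            return spec.gain if has else spec.baseline_fraction * spec.gain
        # type 3: compositional letter sum, with the bigram folded into one
        # deviant term when present; divisive normalization throughout
        terms = {j: spec.letter_tuning[glyph_index[descriptor.slots[j]], j]
                 for j in descriptor.occupied_slots}
        if has:
            s = descriptor.slots
            j = next(j for j in range(N_SLOTS - 1)
                     if s[j] == spec.preferred_bigram[0] and s[j + 1] == spec.preferred_bigram[1])
            del terms[j], terms[j + 1]
            total = spec.bigram_weight + sum(terms.values())
        else:
            total = sum(terms.values())
        return spec.gain * total / n
    raise TypeError(f"unknown neuron spec type: {type(spec)!r}")


def _stimulus_codes(stimulus_set: StimulusSet, alphabet: Sequence[str]
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Encode stimuli as (chars, dist): chars is (S, 6) glyph index or -1."""
    glyph_index = {g: i for i, g in enumerate(alphabet)}
    chars = np.full((len(stimulus_set), N_SLOTS), -1, dtype=int)
    dist = np.zeros(len(stimulus_set), dtype=int)
    for s, d in enumerate(stimulus_set):
        dist[s] = d.distortion_level
        for j, c in enumerate(d.slots):
            if c != "*":
                chars[s, j] = glyph_index[c]
    return chars, dist


def expected_rate_matrix(
    population: Sequence,
    stimulus_set: StimulusSet,
    alphabet: Sequence[str] = DEFAULT_ALPHABET,
) -> np.ndarray:
    """Expected rates for a whole population: (n_neurons, n_stimuli)."""
    chars, dist = _stimulus_codes(stimulus_set, alphabet)
    lengths = (chars >= 0).sum(axis=1)
    n_stim = len(stimulus_set)

    sep = [(i, sp) for i, sp in enumerate(population) if isinstance(sp, SeparableNeuronSpec)]
    conj = [(i, sp) for i, sp in enumerate(population) if isinstance(sp, ConjunctionNeuronSpec)]
    if len(sep) + len(conj) != len(population):
        raise TypeError("population contains unknown spec types")

    out = np.zeros((len(population), n_stim))
    if sep:
        grids = np.stack([sp.unit_letter_grid() for _, sp in sep])  # (N, 8, 6, 4)
        for rule in ("sum", "product"):
            rows = [r for r, (_, sp) in enumerate(sep) if sp.string_rule == rule]
            if not rows:
                continue
            g = grids[rows]
            acc = np.zeros((len(rows), n_stim)) if rule == "sum" else np.ones((len(rows), n_stim))
            for j in range(N_SLOTS):
                occ = chars[:, j] >= 0
                if not occ.any():
                    continue
                vals = g[:, chars[occ, j], j, dist[occ]]  # (rows, occ)
                if rule == "sum":
                    acc[:, occ] += vals
                else:
                    acc[:, occ] *= vals
            if rule == "product":
                # empty product over zero occupied slots is not meaningful
                acc[:, lengths == 0] = 0.0
            for rr, r in enumerate(rows):
                i, sp = sep[r]
                resp = sp.gain * acc[rr]
                out[i] = resp / lengths if sp.normalize else resp
    for i, sp in conj:
        out[i] = [expected_rate(sp, d, alphabet) for d in stimulus_set]
    return out


# ---------------------------------------------------------------------------
# Response matrices and Poisson sampling
# ---------------------------------------------------------------------------


@dataclass
class ResponseMatrix:
    """Firing rates as a (n_neurons, n_stimuli, n_repetitions) array.

    Repetitions are numbered 1..R; the odd-numbered half is reps 1, 3, ...
    (array indices 0, 2, ...).  Rates are spikes/s in the counting window.
    """

    rates: np.ndarray
    stimulus_set: StimulusSet
    neuron_ids: list[str] = field(default_factory=list)
    window_s: float = DEFAULT_WINDOW_S

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.ndim != 3:
            raise ValueError("rates must be (neurons, stimuli, repetitions)")
        if self.rates.shape[1] != len(self.stimulus_set):
            raise ValueError("stimulus axis does not match the stimulus set")
        if (self.rates < 0).any():
            raise ValueError("firing rates must be non-negative")
        if not self.neuron_ids:
            self.neuron_ids = [f"n{i:04d}" for i in range(self.rates.shape[0])]

    @property
    def n_neurons(self) -> int:
        return self.rates.shape[0]

    @property
    def n_repetitions(self) -> int:
        return self.rates.shape[2]

    def means(self) -> np.ndarray:
        return self.rates.mean(axis=2)

    def odd_means(self) -> np.ndarray:
        return self.rates[:, :, 0::2].mean(axis=2)

    def even_means(self) -> np.ndarray:
        if self.n_repetitions < 2:
            raise ValueError("need at least 2 repetitions for an even half")
        return self.rates[:, :, 1::2].mean(axis=2)

    def select(self, subset: str) -> "ResponseMatrix":
        keep = [i for i, s in enumerate(self.stimulus_set.subsets) if s == subset]
        return self.take_stimuli(keep)

    def take_stimuli(self, indices: Sequence[int]) -> "ResponseMatrix":
        sub = StimulusSet(
            [self.stimulus_set.descriptors[i] for i in indices],
            [self.stimulus_set.subsets[i] for i in indices],
            dict(self.stimulus_set.provenance),
        )
        return ResponseMatrix(self.rates[:, list(indices), :], sub,
                              list(self.neuron_ids), self.window_s)


def odd_even_means(rates: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Means over odd- and even-numbered repetitions (1-based numbering)."""
    return rates[..., 0::2].mean(axis=-1), rates[..., 1::2].mean(axis=-1)


def pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation; NaN where either row is constant."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ac = a - a.mean(axis=-1, keepdims=True)
    bc = b - b.mean(axis=-1, keepdims=True)
    num = (ac * bc).sum(axis=-1)
    den = np.sqrt((ac ** 2).sum(axis=-1) * (bc ** 2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return np.where(den > 0, r, np.nan)


def sample_poisson(
    population: Sequence,
    stimulus_set: StimulusSet,
    n_reps: int = 4,
    window_s: float = DEFAULT_WINDOW_S,
    seed: int = 0,
    expected: np.ndarray | None = None,
) -> ResponseMatrix:
    """Draw Poisson spike counts and return them as firing rates.

    Counts are Poisson with mean ``rate x window`` independently across
    neurons, stimuli and repetitions; stored rates are counts / window.
    """
    if n_reps < 2:
        raise ValueError("need at least 2 repetitions")
    if expected is None:
        expected = expected_rate_matrix(population, stimulus_set)
    expected = np.asarray(expected, float)
    if (expected < 0).any() or not np.isfinite(expected).all():
        raise ValueError("expected rates must be finite and non-negative")
    rng = np.random.default_rng(seed)
    lam = expected[:, :, None] * window_s
    counts = rng.poisson(np.broadcast_to(lam, lam.shape[:2] + (n_reps,)))
    return ResponseMatrix(counts / window_s, stimulus_set,
                          window_s=window_s)


def noise_free_responses(
    population: Sequence,
    stimulus_set: StimulusSet,
    n_reps: int = 4,
) -> ResponseMatrix:
    """Expected rates replicated over repetitions (zero noise)."""
    expected = expected_rate_matrix(population, stimulus_set)
    rates = np.repeat(expected[:, :, None], n_reps, axis=2)
    return ResponseMatrix(rates, stimulus_set)


# ---------------------------------------------------------------------------
# Reliability matching
# ---------------------------------------------------------------------------


def _mc_split_half(unit_rates: np.ndarray, gains: np.ndarray, n_reps: int,
                   window_s: float, n_mc: int, rng: np.random.Generator) -> np.ndarray:
    """Monte-Carlo mean split-half correlation at the given per-neuron gains."""
    lam = gains[:, None] * unit_rates * window_s  # (N, S)
    acc = np.zeros(len(gains))
    for _ in range(n_mc):
        counts = rng.poisson(np.broadcast_to(lam[:, :, None],
                                             lam.shape + (n_reps,)))
        odd, even = odd_even_means(counts.astype(float))
        r = pearson_rows(odd, even)
        acc += np.nan_to_num(r, nan=0.0)
    return acc / n_mc


def match_reliability(
    population: Sequence,
    target_reliabilities,
    stimulus_set: StimulusSet,
    n_reps: int = 4,
    seed: int = 0,
    tol: float = 0.05,
    n_mc: int = 20,
    window_s: float = DEFAULT_WINDOW_S,
    max_iter: int = 18,
) -> tuple[list, dict]:
    """Rescale each neuron's gain so its split-half reliability hits a target.

    Runs a per-neuron bisection on log-gain, scoring each probe gain by the
    mean split-half correlation over ``n_mc`` Monte-Carlo Poisson samplings
    of the stimulus set.  Returns (new population, info); neurons whose
    expected rates are constant across stimuli can never reach a positive
    target and are flagged in ``info["unreachable"]``.
    """
    targets = np.broadcast_to(np.asarray(target_reliabilities, float),
                              (len(population),)).copy()
    if ((targets <= 0) | (targets >= 1)).any():
        raise ValueError("target reliabilities must be in (0, 1)")
    expected = expected_rate_matrix(population, stimulus_set)
    gains = np.array([sp.gain for sp in population], float)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = expected / gains[:, None]
    unreachable = np.ptp(unit, axis=1) <= 0
    rng = np.random.default_rng(seed)

    lo = np.full(len(population), np.log(1e-2))
    hi = np.full(len(population), np.log(1e5))
    mid = (lo + hi) / 2.0
    for _ in range(max_iter):
        mid = (lo + hi) / 2.0
        r = _mc_split_half(unit, np.exp(mid), n_reps, window_s, n_mc, rng)
        too_low = r < targets
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)

    final_gains = np.exp((lo + hi) / 2.0)
    achieved = _mc_split_half(unit, final_gains, n_reps, window_s, n_mc, rng)
    matched = []
    for i, sp in enumerate(population):
        sp2 = copy.deepcopy(sp)
        sp2.gain = float(gains[i]) if unreachable[i] else float(final_gains[i])
        matched.append(sp2)
    info = {
        "achieved": achieved,
        "targets": targets,
        "unreachable": unreachable,
        "within_tol": np.abs(achieved - targets) <= tol,
    }
    return matched, info
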