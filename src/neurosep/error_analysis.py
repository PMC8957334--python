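"""Conjunction-detection error analysis.

If a neuron carries inseparable selectivity for a specific letter bigram,
its compositional-model error on that bigram should propagate to every
longer string containing it.  The analysis fits the additive letter-sum
model to the all-trials mean response (after normalizing each neuron to its
maximum rate), splits the base n-grams into high- and low-error groups at
the median, and compares the model error of longer strings containing
high- versus low-error base n-grams.  Because the grouping criterion
(base-n-gram error) uses different stimuli than the compared quantity
(longer-string error), the comparison needs no cross-validation.

A separable population shows no systematic high/low difference; bigram
conjunction populations do.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .stimuli import DEFAULT_ALPHABET, N_SLOTS, StimulusSet
from .separability import fit_ngram_additive, signrank_p
from .synthetic_neurons import ResponseMatrix

__all__ = ["ErrorTable", "compute_ngram_errors", "conjunction_error_test",
           "contains_contiguous"]


def contains_contiguous(slots: str, letters: str) -> bool:
    """True when ``letters`` occupies consecutive slots of ``slots``."""
    m = len(letters)
    return any(slots[j:j + m] == letters for j in range(N_SLOTS - m + 1))


@dataclass
class ErrorTable:
    """Absolute normalized model errors per neuron x n-gram condition."""

    errors: np.ndarray                   # (n_neurons, n_conditions)
    mask: np.ndarray                     # neurons with a positive max rate
    stimulus_set: StimulusSet
    lengths: np.ndarray                  # per-condition string length
    strings: list[str]                   # per-condition letter sequence
    membership: dict[int, dict[str, list[str]]] = field(default_factory=dict)


def compute_ngram_errors(
    rm: ResponseMatrix,
    letter_matrix: np.ndarray,
    alphabet: Sequence[str] = DEFAULT_ALPHABET,
) -> ErrorTable:
    """Fit the letter-sum model on all trials and tabulate |obs - pred|.

    Responses (and therefore errors) are normalized to each neuron's
    maximum mean firing rate, making the table invariant to global rate
    rescaling; neurons with a zero maximum are masked.  The membership
    index records, for every string length, which shorter set strings each
    longer string contains contiguously.
    """
    means = rm.means()
    maxrate = means.max(axis=1)
    mask = maxrate > 0
    safe = np.where(mask, maxrate, 1.0)
    norm = ResponseMatrix(rm.rates / safe[:, None, None], rm.stimulus_set,
                          list(rm.neuron_ids), rm.window_s)
    fits = fit_ngram_additive(norm, letter_matrix, alphabet)
    pred = np.stack([f.predicted_all for f in fits])
    errors = np.abs(norm.means() - pred)

    lengths = np.array([d.ngram_length for d in rm.stimulus_set])
    strings = [d.letters for d in rm.stimulus_set]
    by_len = {int(n): sorted({s for s, ln in zip(strings, lengths) if ln == n})
              for n in np.unique(lengths)}
    membership: dict[int, dict[str, list[str]]] = {}
    for m, bases in by_len.items():
        for n, longs in by_len.items():
            if n <= m:
                continue
            membership.setdefault(m, {})
            for s in longs:
                slots = next(d.slots for d in rm.stimulus_set if d.letters == s)
                membership[m].setdefault(s, [])
                membership[m][s].extend(b for b in bases
                                        if contains_contiguous(slots, b))
    return ErrorTable(errors, mask, rm.stimulus_set, lengths, strings, membership)


def _string_errors(table: ErrorTable, i: int, length: int) -> dict[str, float]:
    """Per-string mean error (over distortions) for one neuron."""
    rows = np.flatnonzero(table.lengths == length)
    out: dict[str, list[float]] = {}
    for s in rows:
        out.setdefault(table.strings[s], []).append(table.errors[i, s])
    return {k: float(np.mean(v)) for k, v in out.items()}


def conjunction_error_test(
    table: ErrorTable,
    base_length: int = 2,
    target_lengths: Sequence[int] | None = None,
    membership_seed: int | None = None,
) -> dict[int, dict]:
    """Compare longer-string model errors grouped by base-n-gram error.

    Per neuron, the base strings of ``base_length`` are median-split into
    high- and low-error groups (ties go to the low group); for each target
    length the mean error of strings containing at least one high-error
    base is compared against strings containing a low-error base, and a
    two-sided sign-rank test is run across neurons.  ``membership_seed``
    optionally permutes which longer strings contain which bases (within
    length) — a null control that destroys genuine conjunction signals.
    """
    lengths = sorted(set(table.lengths.tolist()))
    if base_length not in lengths:
        raise ValueError(f"no strings of base length {base_length}")
    if target_lengths is None:
        target_lengths = [n for n in lengths if n > base_length]
    member = {s: list(b) for s, b in table.membership.get(base_length, {}).items()}
    if membership_seed is not None:
        rng = np.random.default_rng(membership_seed)
        for n in target_lengths:
            strs = sorted({s for s, ln in zip(table.strings, table.lengths) if ln == n})
            perm = rng.permutation(len(strs))
            vals = [member.get(s, []) for s in strs]
            for s, p in zip(strs, perm):
                member[s] = vals[p]

    neurons = np.flatnonzero(table.mask)
    results: dict[int, dict] = {}
    for n in target_lengths:
        diffs, highs, lows = [], [], []
        for i in neurons:
            base_err = _string_errors(table, i, base_length)
            if len(base_err) < 4:
                continue
            med = float(np.median(list(base_err.values())))
            high = {s for s, e in base_err.items() if e > med}
            low = {s for s, e in base_err.items() if e <= med}
            if not high or not low:
                continue
            long_err = _string_errors(table, i, n)
            h = [e for s, e in long_err.items() if set(member.get(s, [])) & high]
            l = [e for s, e in long_err.items() if set(member.get(s, [])) & low]
            if not h or not l:
                continue
            highs.append(float(np.mean(h)))
            lows.append(float(np.mean(l)))
            diffs.append(highs[-1] - lows[-1])
        results[n] = {
            "high_mean": float(np.mean(highs)) if highs else float("nan"),
            "low_mean": float(np.mean(lows)) if lows else float("nan"),
            "diff": np.asarray(diffs),
            "p": signrank_p(np.asarray(diffs)) if diffs else 1.0,
            "n_neurons": len(diffs),
        }
    return results
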