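"""Balanced letter-string banks for stress-testing simulated populations.

The bank enumerates every ordered glyph sequence of a given length (repeats
allowed: 8^n base strings per length), expands the placements by circular
rotation of the 6-slot pattern and by redistributing the letters over
non-contiguous slots (order preserved), and finally samples a balanced set
with the same number of stimuli per length 2-6.

A bank stimulus is a (pattern, distortion-level) pair.  Including the
distortion level in the stimulus identity is what makes the default
balanced size of 3,584 per length reachable for bigrams, whose pattern
pool has a hard combinatorial ceiling of C(6,2) x 8^2 = 960.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .stimuli import (
    BLANK,
    DEFAULT_ALPHABET,
    DISTORTION_LEVELS,
    N_SLOTS,
    StimulusDescriptor,
    StimulusSet,
    layout_ngram,
)

__all__ = [
    "StringBank",
    "generate_base_strings",
    "expand_placements",
    "build_balanced_bank",
]


def generate_base_strings(
    length: int, alphabet: Sequence[str] = DEFAULT_ALPHABET
) -> list[str]:
    """All ordered glyph sequences of a length at the canonical slots.

    Repeats are allowed, so the pool has ``len(alphabet) ** length``
    members (64 bigrams ... 262,144 6-grams for the default alphabet).
    """
    if not 2 <= length <= N_SLOTS:
        raise ValueError(f"length must be 2-6, got {length}")
    template = layout_ngram("x" * length)
    start = template.index("x")
    pre, post = BLANK * start, BLANK * (N_SLOTS - start - length)
    return [pre + "".join(p) + post
            for p in itertools.product(alphabet, repeat=length)]


def _rotations(pattern: str) -> list[str]:
    return [pattern[-k:] + pattern[:-k] for k in range(N_SLOTS)]


def _spacings(pattern: str) -> list[str]:
    letters = [c for c in pattern if c != BLANK]
    out = []
    for combo in itertools.combinations(range(N_SLOTS), len(letters)):
        slots = [BLANK] * N_SLOTS
        for j, c in zip(combo, letters):
            slots[j] = c
        out.append("".join(slots))
    return out


def expand_placements(patterns: Iterable[str]) -> set[str]:
    """Expand patterns by circular rotation and letter re-spacing.

    Returns the closure of the input under 6-slot circular rotation and
    order-preserving redistribution of the letters over the slots
    (rotation of a gapped pattern can wrap letters around, so the closure
    is iterated to a fixed point).  Idempotent by construction: expanding
    an expanded set adds nothing new.
    """
    out: set[str] = set(patterns)
    frontier = set(out)
    while frontier:
        new: set[str] = set()
        for p in frontier:
            for q in _rotations(p):
                if q not in out:
                    new.add(q)
            for q in _spacings(p):
                if q not in out:
                    new.add(q)
        out |= new
        frontier = new
    return out


@dataclass
class StringBank:
    """A balanced set of (pattern, distortion) string stimuli."""

    descriptors: list[StimulusDescriptor]
    per_length_counts: dict[int, int]
    log: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.descriptors)

    @property
    def patterns(self) -> list[str]:
        return [d.slots for d in self.descriptors]

    def to_stimulus_set(self) -> StimulusSet:
        return StimulusSet(
            list(self.descriptors), ["bank"] * len(self.descriptors),
            dict(self.log, source="string_bank"),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# string bank; log={self.log}\n")
            for d in self.descriptors:
                fh.write(f"{d.slots}\t{d.distortion_level}\n")

    @classmethod
    def load(cls, path) -> "StringBank":
        descs = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                slots, lev = line.split()
                descs.append(StimulusDescriptor(slots, int(lev)))
        counts: dict[int, int] = {}
        for d in descs:
            counts[d.ngram_length] = counts.get(d.ngram_length, 0) + 1
        return cls(descs, counts, {"loaded_from": str(path)})


def build_balanced_bank(
    per_length_count: int = 3584,
    seed: int = 0,
    alphabet: Sequence[str] = DEFAULT_ALPHABET,
    distortion_levels: Iterable[int] = DISTORTION_LEVELS,
    expand: bool = True,
) -> StringBank:
    """Sample a bank with equally many stimuli per length 2-6.

    For each length the candidate pool is the (expanded) pattern set crossed
    with the distortion levels; ``per_length_count`` stimuli are drawn
    uniformly without replacement.  The default size is 5 x 3,584 = 17,920.
    Deterministic given ``seed``.
    """
    levels = sorted(set(distortion_levels))
    rng = np.random.default_rng(seed)
    descriptors: list[StimulusDescriptor] = []
    counts: dict[int, int] = {}
    stage_counts: dict[int, dict[str, int]] = {}
    for n in range(2, N_SLOTS + 1):
        base = generate_base_strings(n, alphabet)
        pool = sorted(expand_placements(base)) if expand else sorted(set(base))
        pool_size = len(pool) * len(levels)
        stage_counts[n] = {"base": len(base), "expanded": len(pool), "pool": pool_size}
        if per_length_count > pool_size:
            raise ValueError(
                f"per_length_count={per_length_count} exceeds the pool of "
                f"{pool_size} stimuli for length {n}"
            )
        idx = rng.choice(pool_size, size=per_length_count, replace=False)
        idx.sort()
        for i in idx:
            descriptors.append(StimulusDescriptor(pool[i // len(levels)], levels[i % len(levels)]))
        counts[n] = per_length_count
    log = {"seed": seed, "per_length_count": per_length_count,
           "distortion_levels": levels, "stage_counts": stage_counts}
    return StringBank(descriptors, counts, log)
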