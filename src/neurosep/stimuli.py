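"""Stimulus design for distorted letter-string experiments.

The experimental design places 8 character glyphs at 6 fixed retinal slots
(0.8 degrees apart; slots 1-3 labelled ipsilateral, 4-6 contralateral) and
combines them into n-grams of length 2-6.  Every easy stimulus appears at
4 distortion levels (0 = undistorted, 1 = fish-eye, 2 = + per-letter
rotation, 3 = + global bend); a small set of 6-letter strings additionally
appears in 4 "hard" CAPTCHA variants (touching letters, outlines, background
grid, strike-through stroke).

All downstream analyses (model fits, decoding, error analysis) operate on
the symbolic :class:`StimulusDescriptor` objects built here.  Rendering of
the actual grayscale images is optional and only needed when pixel-level
stimuli are wanted.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DEFAULT_ALPHABET",
    "GLYPH_RING",
    "HARD_STRINGS",
    "HARD_VARIANTS",
    "BLANK",
    "N_SLOTS",
    "StimulusDescriptor",
    "StimulusSet",
    "RenderedStimulus",
    "layout_ngram",
    "default_ngram_strings",
    "build_stimulus_set",
    "render_stimulus",
    "apply_distortion",
    "render_hard_variant",
]

#: The 8 glyphs of the recorded design (lower/upper case letters and digits).
DEFAULT_ALPHABET: tuple[str, ...] = ("a", "d", "g", "s", "T", "y", "7", "K")

#: Canonical circular ordering of the alphabet used to build nested n-grams.
GLYPH_RING: str = "adgsTy7K"

#: The eight 6-grams that also appear as hard CAPTCHA variants.
HARD_STRINGS: tuple[str, ...] = (
    "7Kadgs", "KadgsT", "Ty7Kad", "Tyadgs",
    "gsTy7K", "sTy7Ka", "y7Kadg", "yadgsT",
)

HARD_VARIANTS: tuple[str, ...] = ("touching", "outline", "grid", "strikethrough")

BLANK = "*"
N_SLOTS = 6
DISTORTION_LEVELS = (0, 1, 2, 3)

# ---------------------------------------------------------------------------
# Descriptors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StimulusDescriptor:
    """A 6-slot character/blank pattern at one distortion level.

    ``slots`` is a 6-character string over the alphabet plus ``'*'`` for
    blank.  Slots are indexed 1-6 left to right; 1-3 are ipsilateral and
    4-6 contralateral (the recordings were left-hemisphere, so only the
    label matters).  ``hard_variant`` is only legal on 6-letter strings.
    """

    slots: str
    distortion_level: int = 0
    hard_variant: str | None = None

    def __post_init__(self) -> None:
        if len(self.slots) != N_SLOTS:
            raise ValueError(f"slots must have length {N_SLOTS}: {self.slots!r}")
        if self.distortion_level not in DISTORTION_LEVELS:
            raise ValueError(f"distortion_level must be 0-3: {self.distortion_level}")
        if self.hard_variant is not None:
            if self.hard_variant not in HARD_VARIANTS:
                raise ValueError(f"unknown hard variant: {self.hard_variant!r}")
            if self.ngram_length != N_SLOTS:
                raise ValueError("hard variants only exist for 6-letter strings")

    @property
    def ngram_length(self) -> int:
        """Number of non-blank slots."""
        return sum(c != BLANK for c in self.slots)

    @property
    def letters(self) -> str:
        """The letters in left-to-right order, blanks removed."""
        return "".join(c for c in self.slots if c != BLANK)

    @property
    def occupied_slots(self) -> tuple[int, ...]:
        """0-based indices of the non-blank slots."""
        return tuple(i for i, c in enumerate(self.slots) if c != BLANK)

    @property
    def stimulus_id(self) -> str:
        base = self.slots.replace(BLANK, "-")
        if self.hard_variant is not None:
            return f"{base}_h{self.hard_variant}"
        return f"{base}_d{self.distortion_level}"

    def to_dict(self) -> dict:
        return {
            "id": self.stimulus_id,
            "slots": self.slots,
            "distortion_level": self.distortion_level,
            "hard_variant": self.hard_variant,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusDescriptor":
        return cls(
            slots=d["slots"],
            distortion_level=int(d["distortion_level"]),
            hard_variant=d.get("hard_variant"),
        )


def layout_ngram(chars: Sequence[str]) -> str:
    """Place a 2-6 letter sequence at its canonical contiguous slots.

    Even lengths are centred on fixation (length 2 -> slots 3-4, 4 -> 2-5,
    6 -> 1-6); odd lengths put the extra letter on the contralateral side
    (length 3 -> slots 3-5, 5 -> 2-6).
    """
    n = len(chars)
    if not 2 <= n <= N_SLOTS:
        raise ValueError(f"n-gram length must be 2-6, got {n}")
    if n % 2 == 0:
        start = (N_SLOTS - n) // 2        # 0-based
    else:
        start = (N_SLOTS - n + 1) // 2    # extra letter contralateral
    pattern = [BLANK] * N_SLOTS
    for i, c in enumerate(chars):
        pattern[start + i] = c
    return "".join(pattern)


def default_ngram_strings(seed: int = 0,
                          alphabet: Sequence[str] = DEFAULT_ALPHABET
                          ) -> dict[int, list[str]]:
    """The default 10 n-gram strings per length 2-6, built as nested chains.

    Ten distinct seed bigrams are drawn, and each is grown one random
    letter at a time (prepended or appended) up to length 6, giving ten
    chains in which the length-m string occurs contiguously inside every
    longer string of its chain ("sT" inside "sTy7Ka").  Growth avoids
    accidentally creating one of the other seed bigrams, so containment
    of the ten bigram types stays selective — each bigram is carried by
    its own chain rather than by every long string.
    """
    rng = np.random.default_rng(seed)
    glyphs = list(alphabet)
    # ten distinct ordered seed bigrams
    bigrams: list[str] = []
    while len(bigrams) < 10:
        b = "".join(rng.choice(glyphs, size=2))
        if b not in bigrams:
            bigrams.append(b)

    def grow(chain_start: str) -> list[str]:
        chain = [chain_start]
        s = chain_start
        while len(s) < N_SLOTS:
            for _ in range(100):
                g = str(rng.choice(glyphs))
                cand = g + s if rng.random() < 0.5 else s + g
                contained = [b for b in bigrams if b in cand]
                if contained == [b for b in bigrams if b in s]:
                    break
            s = cand
            chain.append(s)
        return chain

    out: dict[int, list[str]] = {n: [] for n in range(2, N_SLOTS + 1)}
    for b in bigrams:
        while True:
            chain = grow(b)
            if all(chain[n - 2] not in out[n] for n in out):
                break
        for n in out:
            out[n].append(chain[n - 2])
    return out


@dataclass
class StimulusSet:
    """An ordered collection of unique stimulus descriptors.

    ``subsets`` carries one label per descriptor: ``"single_letter"``,
    ``"ngram"`` or ``"hard"``.  ``provenance`` records the builder config.
    """

    descriptors: list[StimulusDescriptor]
    subsets: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.descriptors) != len(self.subsets):
            raise ValueError("descriptors and subsets must align")
        ids = [d.stimulus_id for d in self.descriptors]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate descriptors in stimulus set")
        self._index = {sid: i for i, sid in enumerate(ids)}

    def __len__(self) -> int:
        return len(self.descriptors)

    def __iter__(self):
        return iter(self.descriptors)

    def __getitem__(self, i: int) -> StimulusDescriptor:
        return self.descriptors[i]

    def index_of(self, stimulus_id: str) -> int:
        return self._index[stimulus_id]

    def select(self, subset: str) -> "StimulusSet":
        keep = [i for i, s in enumerate(self.subsets) if s == subset]
        return StimulusSet(
            [self.descriptors[i] for i in keep],
            [self.subsets[i] for i in keep],
            dict(self.provenance, selected=subset),
        )

    @property
    def single_letters(self) -> "StimulusSet":
        return self.select("single_letter")

    @property
    def ngrams(self) -> "StimulusSet":
        return self.select("ngram")

    def restrict_distortions(self, levels: Iterable[int]) -> "StimulusSet":
        levels = set(levels)
        keep = [i for i, d in enumerate(self.descriptors) if d.distortion_level in levels]
        return StimulusSet(
            [self.descriptors[i] for i in keep],
            [self.subsets[i] for i in keep],
            dict(self.provenance, distortion_levels=sorted(levels)),
        )

    def to_manifest(self) -> list[dict]:
        return [dict(d.to_dict(), subset=s) for d, s in zip(self.descriptors, self.subsets)]

    def save_manifest(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_manifest(), fh, indent=1)

    @classmethod
    def from_manifest(cls, records: list[dict], provenance: dict | None = None) -> "StimulusSet":
        descs = [StimulusDescriptor.from_dict(r) for r in records]
        subsets = [r.get("subset", "ngram") for r in records]
        return cls(descs, subsets, provenance or {})

    @classmethod
    def load_manifest(cls, path) -> "StimulusSet":
        with open(path) as fh:
            return cls.from_manifest(json.load(fh), {"manifest": str(path)})


def build_stimulus_set(
    alphabet: Sequence[str] = DEFAULT_ALPHABET,
    ngram_strings: dict[int, list[str]] | None = None,
    seed: int = 0,
    distortion_levels: Iterable[int] = DISTORTION_LEVELS,
    include_hard: bool = False,
) -> StimulusSet:
    """Construct the full stimulus design.

    The default easy set is every glyph at every slot plus 10 n-grams per
    length 2-6, each at 4 distortion levels: (48 + 50) x 4 = 392 stimuli.
    With ``include_hard`` the 8 listed 6-grams are added in each of the 4
    hard variants.  Deterministic given the config.
    """
    alphabet = tuple(alphabet)
    if len(alphabet) != 8 or len(set(alphabet)) != 8:
        raise ValueError("alphabet must contain exactly 8 distinct glyphs")
    levels = sorted(set(distortion_levels))
    if ngram_strings is None:
        ngram_strings = default_ngram_strings(seed)
    for n, strings in ngram_strings.items():
        if len(set(strings)) != len(strings):
            raise ValueError(f"duplicate n-grams in input list for length {n}")

    descriptors: list[StimulusDescriptor] = []
    subsets: list[str] = []
    for glyph in alphabet:
        for slot in range(N_SLOTS):
            pattern = BLANK * slot + glyph + BLANK * (N_SLOTS - slot - 1)
            for lev in levels:
                descriptors.append(StimulusDescriptor(pattern, lev))
                subsets.append("single_letter")
    for n in sorted(ngram_strings):
        for s in ngram_strings[n]:
            pattern = layout_ngram(s)
            for lev in levels:
                descriptors.append(StimulusDescriptor(pattern, lev))
                subsets.append("ngram")
    if include_hard:
        for s in HARD_STRINGS:
            pattern = layout_ngram(s)
            for variant in HARD_VARIANTS:
                descriptors.append(StimulusDescriptor(pattern, 0, hard_variant=variant))
                subsets.append("hard")
    provenance = {
        "seed": seed,
        "alphabet": list(alphabet),
        "distortion_levels": levels,
        "include_hard": include_hard,
        "ngram_strings": {str(k): list(v) for k, v in ngram_strings.items()},
    }
    return StimulusSet(descriptors, subsets, provenance)


# ---------------------------------------------------------------------------
# Rendering (optional; analyses operate on descriptors, not pixels)
# ---------------------------------------------------------------------------


@dataclass
class RenderedStimulus:
    """A grayscale luminance grid (background 0, foreground up to 1)."""

    image: np.ndarray
    descriptor: StimulusDescriptor
    pixels_per_degree: float
    glyph_boxes: list[tuple[int, int, int, int]] = field(default_factory=list)


GLYPH_DEGREES = 0.8          # visual size of one glyph and the slot pitch
DEFAULT_PPD = 40.0           # pixels per degree
FISHEYE_K = 0.10             # lens exponent of the radial remap
ROTATION_RANGE = (-15.0, 15.0)
BEND_SAGITTA = 0.4           # in glyph heights


def _serif_font_path() -> str:
    from matplotlib import font_manager

    try:
        return font_manager.findfont("DejaVu Serif", fallback_to_default=True)
    except Exception:  # pragma: no cover - font lookup is environment dependent
        return font_manager.findfont(font_manager.FontProperties())


@lru_cache(maxsize=256)
def _glyph_array(glyph: str, ppd: float) -> np.ndarray:
    """Render one glyph, cropped to its ink bounding box, height ~0.8 deg."""
    from PIL import Image, ImageDraw, ImageFont

    target_h = GLYPH_DEGREES * ppd
    path = _serif_font_path()

    def draw_at(size: int) -> np.ndarray:
        font = ImageFont.truetype(path, size=size)
        pad = size
        img = Image.new("L", (3 * pad, 3 * pad), 0)
        ImageDraw.Draw(img).text((pad, pad), glyph, fill=255, font=font)
        arr = np.asarray(img, dtype=float) / 255.0
        rows = np.flatnonzero(arr.any(axis=1))
        cols = np.flatnonzero(arr.any(axis=0))
        return arr[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]

    ref = draw_at(100)
    size = max(4, int(round(100 * target_h / ref.shape[0])))
    return draw_at(size)


def _paste_max(canvas: np.ndarray, tile: np.ndarray, cy: float, cx: float
               ) -> tuple[int, int, int, int]:
    """Composite ``tile`` centred at (cy, cx) via pixelwise maximum."""
    h, w = tile.shape
    y0 = int(round(cy - h / 2))
    x0 = int(round(cx - w / 2))
    ys, xs = max(y0, 0), max(x0, 0)
    ye = min(y0 + h, canvas.shape[0])
    xe = min(x0 + w, canvas.shape[1])
    if ye > ys and xe > xs:
        sub = tile[ys - y0:ye - y0, xs - x0:xe - x0]
        canvas[ys:ye, xs:xe] = np.maximum(canvas[ys:ye, xs:xe], sub)
    return (xs, ys, xe, ye)


def _canvas_shape(ppd: float) -> tuple[int, int]:
    return (int(round(3.0 * ppd)), int(round((N_SLOTS + 2) * GLYPH_DEGREES * ppd)))


def _slot_centers(ppd: float) -> np.ndarray:
    h, w = _canvas_shape(ppd)
    pitch = GLYPH_DEGREES * ppd
    return np.array([(w / 2 + (j - (N_SLOTS - 1) / 2) * pitch) for j in range(N_SLOTS)])


def _fisheye(image: np.ndarray, k: float, center: tuple[float, float]) -> np.ndarray:
    """Local fish-eye lens: a bounded radial remap, bilinear resampling.

    Within the lens radius L the output at radius r samples the source at
    L*(r/L)^(1+k), which magnifies the lens centre, compresses toward the
    rim, and is the identity at and beyond L — pixels are expanded and
    translated but total ink is approximately conserved.
    """
    from scipy.ndimage import map_coordinates

    h, w = image.shape
    cy, cx = center
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    dy, dx = yy - cy, xx - cx
    r = np.hypot(dy, dx)
    L = max(h, w) / 2.0
    with np.errstate(invalid="ignore"):
        scale = np.where(r < L, (np.minimum(r, L) / L) ** k, 1.0)
    src_y = cy + dy * scale
    src_x = cx + dx * scale
    return map_coordinates(image, [src_y, src_x], order=1, mode="constant", cval=0.0)


def _rotate(tile: np.ndarray, angle_deg: float) -> np.ndarray:
    from scipy.ndimage import rotate

    if angle_deg == 0.0:
        return tile
    return np.clip(rotate(tile, angle_deg, reshape=True, order=1, cval=0.0), 0.0, 1.0)


def apply_distortion(
    glyphs: list[tuple[np.ndarray, tuple[float, float]]],
    level: int,
    *,
    canvas_shape: tuple[int, int],
    seed: int = 0,
    fisheye_k: float = FISHEYE_K,
    rotation_range: tuple[float, float] = ROTATION_RANGE,
    bend_sagitta: float = BEND_SAGITTA,
) -> tuple[np.ndarray, list[tuple[int, int, int, int]]]:
    """Composite glyph tiles onto a canvas and distort at the given level.

    ``glyphs`` holds (tile, (cy, cx)) pairs.  Level 0 is the identity
    composite; level 1 adds the fish-eye remap; level 2 additionally rotates
    every glyph in place by an independent uniform angle; level 3
    additionally displaces glyph baselines along one of two fixed quadratic
    bending curves.  Deterministic given ``seed``.
    """
    if level not in DISTORTION_LEVELS:
        raise ValueError(f"level must be 0-3, got {level}")
    canvas = np.zeros(canvas_shape, dtype=float)
    if not glyphs:
        warnings.warn("apply_distortion called on an empty canvas")
        return canvas, []
    rng = np.random.default_rng(seed)

    tiles = [g[0] for g in glyphs]
    centers = [list(g[1]) for g in glyphs]

    if level >= 2:
        lo, hi = rotation_range
        angles = rng.uniform(lo, hi, size=len(tiles)) if hi > lo else np.full(len(tiles), lo)
        tiles = [_rotate(t, float(a)) for t, a in zip(tiles, angles)]
    if level >= 3:
        glyph_h = max(t.shape[0] for t in tiles)
        sign = 1.0 if rng.integers(2) == 0 else -1.0  # one of two spline arcs
        xs = np.array([c[1] for c in centers])
        span = max(xs.max() - xs.min(), 1.0)
        t_par = (xs - xs.min()) / span
        dy = sign * bend_sagitta * glyph_h * 4.0 * t_par * (1.0 - t_par)
        for c, d in zip(centers, dy):
            c[0] -= d

    boxes = [_paste_max(canvas, t, cy, cx) for t, (cy, cx) in zip(tiles, centers)]
    if level >= 1:
        cys = np.mean([c[0] for c in centers])
        cxs = np.mean([c[1] for c in centers])
        canvas = _fisheye(canvas, fisheye_k, (cys, cxs))
    return canvas, boxes


def _glyph_tiles(descriptor: StimulusDescriptor, ppd: float
                 ) -> list[tuple[np.ndarray, tuple[float, float]]]:
    h, _ = _canvas_shape(ppd)
    xcenters = _slot_centers(ppd)
    return [
        (_glyph_array(c, ppd), (h / 2.0, xcenters[j]))
        for j, c in enumerate(descriptor.slots)
        if c != BLANK
    ]


def render_stimulus(
    descriptor: StimulusDescriptor,
    ppd: float = DEFAULT_PPD,
    seed: int = 0,
    **distortion_params,
) -> RenderedStimulus:
    """Render a descriptor to a grayscale image at its distortion level."""
    if descriptor.hard_variant is not None:
        return render_hard_variant(descriptor, descriptor.hard_variant, ppd=ppd, seed=seed)
    glyphs = _glyph_tiles(descriptor, ppd)
    image, boxes = apply_distortion(
        glyphs, descriptor.distortion_level,
        canvas_shape=_canvas_shape(ppd), seed=seed, **distortion_params,
    )
    return RenderedStimulus(image, descriptor, ppd, boxes)


def render_hard_variant(
    descriptor: StimulusDescriptor,
    variant: str,
    ppd: float = DEFAULT_PPD,
    seed: int = 0,
) -> RenderedStimulus:
    """Render one of the hard CAPTCHA variants of a 6-letter string."""
    from scipy.ndimage import binary_erosion

    if descriptor.ngram_length != N_SLOTS:
        raise ValueError("hard variants require a 6-letter string")
    if variant not in HARD_VARIANTS:
        raise ValueError(f"unknown hard variant: {variant!r}")
    shape = _canvas_shape(ppd)
    rng = np.random.default_rng(seed)

    if variant == "touching":
        # rotate letters in place and close the spacing until the rotated
        # bounding boxes abut
        tiles = [_rotate(_glyph_array(c, ppd), float(a)) for c, a in zip(
            descriptor.slots, rng.uniform(*ROTATION_RANGE, size=N_SLOTS))]
        widths = np.array([t.shape[1] for t in tiles], dtype=float)
        total = widths.sum()
        x0 = (shape[1] - total) / 2.0
        canvas = np.zeros(shape, dtype=float)
        boxes = []
        x = x0
        for t in tiles:
            boxes.append(_paste_max(canvas, t, shape[0] / 2.0, x + t.shape[1] / 2.0))
            x += t.shape[1]
        return RenderedStimulus(canvas, descriptor, ppd, boxes)

    if variant == "outline":
        plain = render_stimulus(replace(descriptor, hard_variant=None, distortion_level=0),
                                ppd=ppd, seed=seed)
        fg = plain.image > 0.5
        outline = fg & ~binary_erosion(fg)
        return RenderedStimulus(outline.astype(float), descriptor, ppd, plain.glyph_boxes)

    # grid and strikethrough start from fish-eye + in-place rotation
    glyphs = _glyph_tiles(replace(descriptor, hard_variant=None), ppd)
    letters, boxes = apply_distortion(glyphs, 2, canvas_shape=shape, seed=seed)

    overlay = np.zeros(shape, dtype=float)
    if variant == "grid":
        spacing = max(4, int(round(0.4 * GLYPH_DEGREES * ppd)))
        overlay[::spacing, :] = 1.0
        overlay[:, ::spacing] = 1.0
    else:  # strikethrough: one wavy stroke crossing all glyphs
        h, w = shape
        thickness = max(1, int(round(ppd / 12)))
        amp = 0.4 * GLYPH_DEGREES * ppd
        phase = rng.uniform(0, 2 * np.pi)
        xs = np.arange(w)
        ys = h / 2.0 + amp * np.sin(2 * np.pi * xs / (w / 2.5) + phase)
        for dx in range(-thickness, thickness + 1):
            yy = np.clip(np.round(ys + dx).astype(int), 0, h - 1)
            overlay[yy, xs] = 1.0
    return RenderedStimulus(np.maximum(letters, overlay), descriptor, ppd, boxes)
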