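"""Procedural MNIST-like glyph fixtures.

Generates labelled 28x28 grayscale glyphs from stroke templates so the
full pipeline (generative blending, backbone pretraining, contextual
training, relevance analysis) is trainable and testable without any
external dataset download. Glyphs are anti-aliased polylines: control
points are arc-length resampled, jittered per seed, splatted onto the
pixel grid and Gaussian-smoothed. Classes are deliberately simple
shapes (lines, crosses, rings, letters) that a linear probe separates
almost perfectly, which is the property the downstream task needs —
not any resemblance to real handwriting statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

IMG_SIZE = 28
_RESAMPLE_POINTS = 32

__all__ = [
    "GlyphClassSpec",
    "LabeledImage",
    "render_glyph",
    "make_glyph_alphabet",
    "morph_glyphs",
    "make_dataset",
    "stack",
]


@dataclass(frozen=True)
class LabeledImage:
    """One grayscale image, its class label and optional blend annotation.

    ``ambiguity`` is ``(class_a, class_b, mix)`` iff the image is a
    generated blend of two classes, else ``None``.
    """

    pixels: np.ndarray  # (28, 28) float in [0, 1]
    label: int
    ambiguity: Optional[tuple[int, int, float]] = None

    def __post_init__(self) -> None:
        px = self.pixels
        if px.shape != (IMG_SIZE, IMG_SIZE):
            raise ValueError(f"pixels must be {IMG_SIZE}x{IMG_SIZE}, got {px.shape}")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("pixel values must lie in [0, 1]")


@dataclass(frozen=True)
class GlyphClassSpec:
    """Stroke template for one glyph class.

    ``stroke_template`` is a list of polyline paths with control points
    in unit-square coordinates; ``thickness`` (pixels) sets the blur of
    the rendered stroke and ``jitter_scale`` (pixels) the per-seed
    Gaussian perturbation of control points.
    """

    class_id: int
    stroke_template: tuple[tuple[tuple[float, float], ...], ...]
    thickness: float = 1.1
    jitter_scale: float = 0.6

    def __post_init__(self) -> None:
        if self.class_id < 0:
            raise ValueError("class_id must be >= 0")
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")
        if self.jitter_scale < 0:
            raise ValueError("jitter_scale must be non-negative")
        if not self.stroke_template:
            raise ValueError("stroke_template must contain at least one path")
        for path in self.stroke_template:
            if len(path) < 2:
                raise ValueError("each path needs at least two control points")
            for (x, y) in path:
                if not (0.0 <= x <= 1.0 and 0.0 <= y <= 1.0):
                    raise ValueError("control points must lie in the unit square")


def _circle(cx: float, cy: float, r: float, n: int = 24,
            start: float = 0.0, end: float = 2 * np.pi) -> tuple[tuple[float, float], ...]:
    t = np.linspace(start, end, n)
    return tuple(zip(cx + r * np.cos(t), cy + r * np.sin(t)))


def _template_pool() -> list[tuple[tuple[tuple[float, float], ...], ...]]:
    L = lambda *pts: tuple(pts)  # noqa: E731 - terse path builder
    pool: list[tuple] = [
        (L((.5, .08), (.5, .92)),),                                     # |
        (L((.08, .5), (.92, .5)),),                                     # -
        (L((.15, .1), (.85, .9)),),                                     # \
        (L((.85, .1), (.15, .9)),),                                     # /
        (L((.15, .1), (.85, .9)), L((.85, .1), (.15, .9))),             # X
        (L((.15, .1), (.5, .9), (.85, .1)),),                           # V
        (L((.15, .9), (.5, .1), (.85, .9)),),                           # ^
        (L((.1, .12), (.9, .12)), L((.5, .12), (.5, .9))),              # T
        (L((.25, .1), (.25, .9), (.85, .9)),),                          # L
        (L((.15, .15), (.85, .15), (.15, .85), (.85, .85)),),           # Z
        (L((.2, .9), (.2, .1), (.8, .9), (.8, .1)),),                   # N
        (L((.15, .9), (.15, .1), (.5, .6), (.85, .1), (.85, .9)),),     # M
        (L((.15, .1), (.32, .9), (.5, .4), (.68, .9), (.85, .1)),),     # W
        (L((.2, .1), (.2, .9)), L((.8, .1), (.8, .9)), L((.2, .5), (.8, .5))),  # H
        (L((.8, .12), (.22, .12), (.22, .9), (.8, .9)), L((.22, .5), (.7, .5))),  # E
        (L((.8, .12), (.25, .12), (.25, .9)), L((.25, .5), (.7, .5))),  # F
        (L((.5, .1), (.5, .9)), L((.1, .5), (.9, .5))),                 # +
        (_circle(.5, .5, .33),),                                        # O
        (_circle(.5, .3, .2), _circle(.5, .72, .22)),                   # 8
        (_circle(.5, .38, .26), L((.74, .45), (.68, .92))),             # 9-ish
        (L((.5, .1), (.88, .85), (.12, .85), (.5, .1)),),               # triangle
        (L((.5, .9), (.88, .15), (.12, .15), (.5, .9)),),               # nabla
        (L((.15, .15), (.85, .15), (.85, .85), (.15, .85), (.15, .15)),),  # square
        (L((.5, .08), (.9, .5), (.5, .92), (.1, .5), (.5, .08)),),      # diamond
        (L((.2, .1), (.2, .75), (.35, .92), (.65, .92), (.8, .75), (.8, .1)),),  # U
        (L((.8, .2), (.5, .08), (.2, .25), (.5, .5), (.8, .75), (.5, .92), (.2, .8)),),  # S
        (_circle(.5, .5, .33, start=np.pi / 2, end=3 * np.pi / 2),),    # C
        (_circle(.5, .5, .33, start=-np.pi / 2, end=np.pi / 2),),       # reverse C
        (L((.15, .12), (.85, .12), (.4, .9)),),                         # 7
        (L((.6, .9), (.6, .1), (.15, .62), (.85, .62)),),               # 4
        (L((.32, .28), (.5, .1), (.5, .9)),),                           # 1
        (L((.15, .1), (.5, .5)), L((.85, .1), (.5, .5)), L((.5, .5), (.5, .9))),  # Y
        (L((.25, .1), (.25, .9)), L((.8, .1), (.25, .5), (.8, .9))),    # K
        (L((.15, .9), (.5, .1), (.85, .9)), L((.3, .62), (.7, .62))),   # A
        (L((.2, .1), (.8, .1), (.2, .9), (.8, .9), (.2, .1)),),         # hourglass
        (L((.62, .08), (.35, .5), (.58, .5), (.38, .92)),),             # lightning
    ]
    return pool


def make_glyph_alphabet(n_classes: int, seed: int) -> list[GlyphClassSpec]:
    """Pick ``n_classes`` distinct stroke templates as a glyph alphabet.

    The order of templates is shuffled deterministically by ``seed``, so
    different seeds yield different alphabets of the same pool.
    """
    pool = _template_pool()
    if not (2 <= n_classes <= len(pool)):
        raise ValueError(f"n_classes must be in [2, {len(pool)}], got {n_classes}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pool))[:n_classes]
    return [GlyphClassSpec(class_id=i, stroke_template=pool[j]) for i, j in enumerate(order)]


def _resample_path(path: Sequence[tuple[float, float]], n: int = _RESAMPLE_POINTS) -> np.ndarray:
    pts = np.asarray(path, dtype=np.float64)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        return np.repeat(pts[:1], n, axis=0)
    t = np.linspace(0.0, total, n)
    x = np.interp(t, cum, pts[:, 0])
    y = np.interp(t, cum, pts[:, 1])
    return np.stack([x, y], axis=1)


def _rasterize(paths: list[np.ndarray], thickness: float) -> np.ndarray:
    img = np.zeros((IMG_SIZE, IMG_SIZE))
    # dense samples along each polyline, bilinear-splatted with max-accumulation
    for pts in paths:
        px = pts * (IMG_SIZE - 1)
        seg = np.linalg.norm(np.diff(px, axis=0), axis=1)
        samples = [px[:1]]
        for i in range(len(px) - 1):
            n_samp = max(2, int(np.ceil(seg[i] / 0.3)) + 1)
            t = np.linspace(0.0, 1.0, n_samp)[1:, None]
            samples.append(px[i] * (1 - t) + px[i + 1] * t)
        s = np.concatenate(samples, axis=0)
        x0 = np.floor(s[:, 0]).astype(int)
        y0 = np.floor(s[:, 1]).astype(int)
        fx, fy = s[:, 0] - x0, s[:, 1] - y0
        for dx, dy, w in ((0, 0, (1 - fx) * (1 - fy)), (1, 0, fx * (1 - fy)),
                          (0, 1, (1 - fx) * fy), (1, 1, fx * fy)):
            xi, yi = x0 + dx, y0 + dy
            ok = (xi >= 0) & (xi < IMG_SIZE) & (yi >= 0) & (yi < IMG_SIZE)
            np.maximum.at(img, (yi[ok], xi[ok]), w[ok])
    img = gaussian_filter(img, sigma=0.55 * thickness)
    m = img.max()
    if m > 0:
        img = img / m
    return np.clip(img, 0.0, 1.0)


def _jittered_paths(spec: GlyphClassSpec, rng: np.random.Generator) -> list[np.ndarray]:
    paths = []
    for path in spec.stroke_template:
        pts = _resample_path(path)
        pts = pts + rng.normal(0.0, spec.jitter_scale / (IMG_SIZE - 1), size=pts.shape)
        paths.append(np.clip(pts, 0.0, 1.0))
    return paths


def render_glyph(spec: GlyphClassSpec, seed: int) -> LabeledImage:
    """Render one jittered glyph; deterministic in ``(spec, seed)``."""
    rng = np.random.default_rng(seed)
    img = _rasterize(_jittered_paths(spec, rng), spec.thickness)
    return LabeledImage(pixels=img, label=spec.class_id)


def _common_topology(spec_a: GlyphClassSpec, spec_b: GlyphClassSpec
                     ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    pa = [_resample_path(p) for p in spec_a.stroke_template]
    pb = [_resample_path(p) for p in spec_b.stroke_template]
    while len(pa) < len(pb):
        pa.append(pa[-1].copy())
    while len(pb) < len(pa):
        pb.append(pb[-1].copy())
    return pa, pb


def morph_glyphs(spec_a: GlyphClassSpec, spec_b: GlyphClassSpec,
                 mix: float, seed: int) -> LabeledImage:
    """Linear shape morph between two glyph classes.

    ``mix=0`` reproduces ``render_glyph(spec_a, seed)`` exactly and
    ``mix=1`` reproduces spec_b's render; intermediate values move the
    (topology-aligned) control points linearly, so pixels are continuous
    in ``mix``.
    """
    if not (0.0 <= mix <= 1.0):
        raise ValueError("mix must lie in [0, 1]")
    if mix == 0.0:
        return render_glyph(spec_a, seed)
    if mix == 1.0:
        return render_glyph(spec_b, seed)
    pa, pb = _common_topology(spec_a, spec_b)
    blend_paths = tuple(
        tuple(map(tuple, (1.0 - mix) * a + mix * b)) for a, b in zip(pa, pb)
    )
    blend = GlyphClassSpec(
        class_id=spec_a.class_id if mix <= 0.5 else spec_b.class_id,
        stroke_template=blend_paths,
        thickness=(1.0 - mix) * spec_a.thickness + mix * spec_b.thickness,
        jitter_scale=(1.0 - mix) * spec_a.jitter_scale + mix * spec_b.jitter_scale,
    )
    img = render_glyph(blend, seed)
    ambiguity = None
    if 0.0 < mix < 1.0:
        ambiguity = (spec_a.class_id, spec_b.class_id, float(mix))
    return LabeledImage(pixels=img.pixels, label=img.label, ambiguity=ambiguity)


def make_dataset(specs: Sequence[GlyphClassSpec], n_per_class: int,
                 seed: int) -> list[LabeledImage]:
    """Render ``n_per_class`` jittered samples for every class."""
    out = []
    for spec in specs:
        base = seed * 1_000_003 + spec.class_id * 100_003
        for k in range(n_per_class):
            out.append(render_glyph(spec, base + k))
    return out


def stack(images: Sequence[LabeledImage]) -> tuple[np.ndarray, np.ndarray]:
    """Stack images into (N, 784) floats and (N,) int labels."""
    X = np.stack([im.pixels.reshape(-1) for im in images])
    y = np.array([im.label for im in images], dtype=np.int64)
    return X, y
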