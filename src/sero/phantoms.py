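"""Digital phantoms for accuracy/precision studies.

Two phantom classes are provided:

* randomized **line phantoms** -- piecewise-smooth 1D profiles of
  (S0, D, V, T1) along the through-slice direction, with plateaus and a mix
  of sharp and softened edges, spanning (the interior of) the fit bounds;
* a procedural **brain-like volume** -- nested, smoothly deformed ellipsoids
  (background / CSF / cortical ribbon / white-matter core) carrying
  per-tissue parameter values from an editable table, with optional letter
  inscriptions for qualitative resolution scoring.

Both are deterministic given a seed.  The per-tissue parameter defaults are
plausible configuration values, not ground truth for any particular tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal import ParameterColumn

__all__ = [
    "LinePhantomConfig",
    "ParameterVolume",
    "DEFAULT_TISSUE_PARAMS",
    "generate_line_phantom",
    "generate_brain_phantom",
    "inscribe_letters",
    "default_letter_layout",
]

#: Default per-parameter sampling ranges for line phantoms.  Each range lies
#: strictly inside the fit bounds (S0 [0,4] a.u., D [0.3,4] um^2/ms,
#: V [0,4] um^4/ms^2, T1 [0.3,5] s) so that noiseless recovery is never
#: bound-limited.
DEFAULT_LINE_RANGES: dict[str, tuple[float, float]] = {
    "s0": (0.2, 3.8),
    "d": (0.4, 3.8),
    "v": (0.05, 3.8),
    "t1": (0.4, 4.8),
}


@dataclass(frozen=True)
class LinePhantomConfig:
    """Configuration of the randomized piecewise-smooth line phantoms.

    ``segments`` is the inclusive range of plateau counts; plateau lengths
    are geometric; ``smooth_width`` is the moving-average window (in
    sub-voxels) applied around a random subset of edges (probability
    ``smooth_prob`` per edge); ``smooth_width = 0`` keeps every edge sharp.

    ``b_max`` (ms/um^2) enforces physical validity of the cumulant signal
    representation: per plateau, V is capped at D / b_max so that the
    noiseless signal decays monotonically over the sampled b-range (tissue
    signal is never amplified by stronger diffusion weighting).  Set to
    ``None`` to sample V independently of D.
    """

    n: int = 50
    segments: tuple[int, int] = (2, 8)
    ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LINE_RANGES)
    )
    smooth_width: int = 2
    smooth_prob: float = 0.5
    b_max: float | None = 1.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.segments[0] < 1 or self.segments[1] < self.segments[0]:
            raise ValueError("segment count range must satisfy 1 <= lo <= hi")
        for name, (lo, hi) in self.ranges.items():
            if not lo < hi:
                raise ValueError(f"empty range for {name}")


def _plateau_lengths(rng: np.random.Generator, n: int, n_seg: int) -> np.ndarray:
    """Random plateau lengths (geometric, min 1) summing to n."""
    if n_seg == 1:
        return np.array([n])
    p = min(1.0, n_seg / n)
    raw = rng.geometric(p, size=n_seg).astype(float)
    lengths = np.maximum(1, np.round(raw * n / raw.sum()).astype(int))
    # fix rounding so the lengths tile the grid exactly
    while lengths.sum() > n:
        lengths[np.argmax(lengths)] -= 1
    while lengths.sum() < n:
        lengths[np.argmin(lengths)] += 1
    return lengths


def generate_line_phantom(config: LinePhantomConfig) -> ParameterColumn:
    """Draw one randomized piecewise-smooth line phantom.

    The grid is split into plateaus; each plateau receives independent
    uniform values per parameter from the configured ranges; a random subset
    of edges is then softened by a short moving average shared across the
    four parameter profiles.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_seg = int(rng.integers(cfg.segments[0], cfg.segments[1] + 1))
    lengths = _plateau_lengths(rng, cfg.n, n_seg)
    edges = np.cumsum(lengths)[:-1]

    plateau_vals = {}
    for name in ("s0", "d", "v", "t1"):
        lo, hi = cfg.ranges[name]
        plateau_vals[name] = rng.uniform(lo, hi, size=n_seg)
    if cfg.b_max is not None:
        # keep the signal monotone-decaying in b: V <= D / b_max per plateau
        cap = plateau_vals["d"] / cfg.b_max
        lo, hi = cfg.ranges["v"]
        plateau_vals["v"] = np.minimum(lo, cap) + (
            plateau_vals["v"] - lo
        ) / (hi - lo) * (np.minimum(hi, cap) - np.minimum(lo, cap))
    profiles = {
        name: np.repeat(vals, lengths) for name, vals in plateau_vals.items()
    }

    if cfg.smooth_width > 0 and edges.size > 0:
        soften = rng.random(edges.size) < cfg.smooth_prob
        w = cfg.smooth_width
        kernel = np.ones(w) / w
        for name, prof in profiles.items():
            sm = np.convolve(np.pad(prof, w, mode="edge"), kernel, mode="same")[
                w:-w
            ]
            out = prof.copy()
            for e in edges[soften]:
                lo_i, hi_i = max(0, e - w), min(cfg.n, e + w)
                out[lo_i:hi_i] = sm[lo_i:hi_i]
            profiles[name] = out

    return ParameterColumn(**profiles)


# ---------------------------------------------------------------------------
# Brain-like labelled volume

BACKGROUND, CSF, GM, WM = 0, 1, 2, 3

#: Editable per-tissue parameter table (plausible values, declared as
#: configuration): S0 a.u., D um^2/ms, V um^4/ms^2, T1 s.
DEFAULT_TISSUE_PARAMS: dict[int, dict[str, float]] = {
    CSF: {"s0": 3.0, "d": 3.0, "v": 0.15, "t1": 4.0},
    GM: {"s0": 2.0, "d": 0.9, "v": 1.0, "t1": 1.4},
    WM: {"s0": 1.7, "d": 0.7, "v": 0.6, "t1": 0.8},
}


@dataclass
class ParameterVolume:
    """3D (S0, D, V, T1) maps with a tissue label map and voxel size (mm)."""

    s0: np.ndarray
    d: np.ndarray
    v: np.ndarray
    t1: np.ndarray
    labels: np.ndarray
    voxel_size: float = 1.5
    letter_masks: list = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.s0.shape

    @property
    def support(self) -> np.ndarray:
        """Boolean mask of non-background voxels."""
        return self.labels != BACKGROUND

    def items(self):
        return (("s0", self.s0), ("d", self.d), ("v", self.v), ("t1", self.t1))

    def column(self, ix: int, iy: int) -> ParameterColumn:
        """Extract the through-slice parameter column at in-plane (ix, iy)."""
        return ParameterColumn(
            self.s0[ix, iy], self.d[ix, iy], self.v[ix, iy], self.t1[ix, iy]
        )

    def copy(self) -> "ParameterVolume":
        return ParameterVolume(
            self.s0.copy(),
            self.d.copy(),
            self.v.copy(),
            self.t1.copy(),
            self.labels.copy(),
            self.voxel_size,
            [m.copy() for m in self.letter_masks],
        )


def _deformed_radius2(
    coords: tuple[np.ndarray, np.ndarray, np.ndarray],
    semi_axes: tuple[float, float, float],
    rng: np.random.Generator,
    wobble: float = 0.08,
) -> np.ndarray:
    """Squared normalized radius of a smoothly deformed ellipsoid."""
    x, y, z = coords
    r2 = (x / semi_axes[0]) ** 2 + (y / semi_axes[1]) ** 2 + (z / semi_axes[2]) ** 2
    phase = rng.uniform(0, 2 * np.pi, size=3)
    amp = rng.uniform(0.5, 1.0, size=3) * wobble
    bump = (
        amp[0] * np.sin(2 * np.pi * x / (2 * semi_axes[0]) + phase[0])
        + amp[1] * np.sin(2 * np.pi * y / (2 * semi_axes[1]) + phase[1])
        + amp[2] * np.sin(4 * np.pi * z / (2 * semi_axes[2]) + phase[2])
    )
    return r2 * (1.0 + bump)


def generate_brain_phantom(
    shape: tuple[int, int, int] = (32, 32, 50),
    voxel_size: float = 1.5,
    tissue_params: dict[int, dict[str, float]] | None = None,
    seed: int = 0,
) -> ParameterVolume:
    """Generate a brain-like labelled volume on a regular grid.

    Nested, smoothly deformed ellipsoids define background, an outer CSF
    shell, a cortical gray-matter ribbon, and a white-matter core; each
    tissue carries the parameter values of ``tissue_params`` (defaults are
    plausible values, declared as configuration).  The third axis is the
    through-slice direction.  Deterministic per seed.
    """
    if tissue_params is None:
        tissue_params = DEFAULT_TISSUE_PARAMS
    rng = np.random.default_rng(seed)
    nx, ny, nz = shape
    x, y, z = np.meshgrid(
        np.linspace(-1, 1, nx),
        np.linspace(-1, 1, ny),
        np.linspace(-1, 1, nz),
        indexing="ij",
    )
    coords = (x, y, z)
    outer = _deformed_radius2(coords, (0.90, 0.90, 0.90), rng) <= 1.0
    gm_outer = _deformed_radius2(coords, (0.78, 0.78, 0.80), rng) <= 1.0
    wm_core = _deformed_radius2(coords, (0.55, 0.55, 0.60), rng) <= 1.0

    labels = np.full(shape, BACKGROUND, dtype=np.int8)
    labels[outer] = CSF
    labels[gm_outer] = GM
    labels[wm_core] = WM

    maps = {name: np.zeros(shape) for name in ("s0", "d", "v", "t1")}
    maps["t1"][:] = 1.0  # positive placeholder outside the support
    maps["d"][:] = 1.0
    for lab, vals in tissue_params.items():
        sel = labels == lab
        for name in maps:
            maps[name][sel] = vals[name]
    return ParameterVolume(labels=labels, voxel_size=voxel_size, **maps)


# 5x7 block font (rows top to bottom) for inscription targets
_FONT: dict[str, tuple[str, ...]] = {
    "L": ("10000", "10000", "10000", "10000", "10000", "10000", "11111"),
    "U": ("10001", "10001", "10001", "10001", "10001", "10001", "01110"),
    "I": ("11111", "00100", "00100", "00100", "00100", "00100", "11111"),
    "T": ("11111", "00100", "00100", "00100", "00100", "00100", "00100"),
    "O": ("01110", "10001", "10001", "10001", "10001", "10001", "01110"),
    "E": ("11111", "10000", "10000", "11110", "10000", "10000", "11111"),
    "H": ("10001", "10001", "10001", "11111", "10001", "10001", "10001"),
}


def _rasterize(text: str, scale: int) -> np.ndarray:
    """Render text into a 2D binary array at integer scale (1 px gap)."""
    glyphs = []
    for ch in text.upper():
        if ch not in _FONT:
            raise ValueError(f"no glyph for character {ch!r}")
        g = np.array([[int(c) for c in row] for row in _FONT[ch]], dtype=bool)
        glyphs.append(g)
        glyphs.append(np.zeros((7, 1), dtype=bool))
    block = np.hstack(glyphs[:-1]) if glyphs else np.zeros((7, 0), dtype=bool)
    return np.kron(block, np.ones((scale, scale), dtype=bool))


def default_letter_layout(
    shape: tuple[int, int, int], text: str = "LU", gap: int = 2
) -> tuple[list[tuple[int, int, int]], list[int]]:
    """Choose letter locations/sizes that fit a volume: one large, one small.

    Both inscriptions sit in the mid-plane along axis 1; the large one is as
    big as the in-plane extent allows, the small one half that.  Placements
    that do not fit are dropped (at least one must fit).
    """
    nx, ny, nz = shape
    width1 = 6 * len(text) - 1  # 5 px glyphs + 1 px gaps at scale 1
    big = max(1, min((nx - 2) // 7, (nz - 2 * gap) // (2 * width1)))
    small = max(1, big // 2)
    locations, sizes = [], []
    z = gap
    for scale in (big, small) if big != small else (big,):
        w = width1 * scale
        if z + w <= nz and 1 + 7 * scale <= nx:
            locations.append((1, ny // 2, z))
            sizes.append(scale)
            z += w + gap
    if not locations:
        raise ValueError(f"volume of shape {shape} cannot hold the text {text!r}")
    return locations, sizes


def inscribe_letters(
    volume: ParameterVolume,
    text: str = "LU",
    locations: list[tuple[int, int, int]] | None = None,
    sizes: list[int] | None = None,
    contrast_rule: dict[str, float] | None = None,
) -> ParameterVolume:
    """Inscribe text into a parameter volume at given locations and sizes.

    The text is rasterized with a built-in 5x7 block font into binary masks
    lying in the (in-plane axis 0, through-slice) plane, one voxel thick
    along axis 1, anchored at each ``(ix, iy, iz)`` top-left corner with the
    given per-location integer scale.  Inside each mask the parameter maps
    are perturbed multiplicatively by ``contrast_rule`` (default: D x 1.5,
    T1 x 1.4).  Masks are recorded on the returned volume for downstream
    legibility scoring.  An empty ``text`` returns an unmodified copy.
    """
    out = volume.copy()
    if text == "":
        return out
    if locations is None:
        locations, auto_sizes = default_letter_layout(volume.shape, text)
        if sizes is None:
            sizes = auto_sizes
    elif sizes is None:
        sizes = [2, 1][: len(locations)] or [1]
    if contrast_rule is None:
        contrast_rule = {"d": 1.5, "t1": 1.4}
    maps = dict(out.items())
    for (ix, iy, iz), scale in zip(locations, sizes):
        raster = _rasterize(text, scale)
        h, w = raster.shape
        if (
            ix < 0
            or iy < 0
            or iz < 0
            or ix + h > out.shape[0]
            or iz + w > out.shape[2]
            or iy >= out.shape[1]
        ):
            raise ValueError(
                f"letter mask at ({ix},{iy},{iz}) scale {scale} exceeds volume bounds"
            )
        mask = np.zeros(out.shape, dtype=bool)
        mask[ix : ix + h, iy, iz : iz + w] = raster
        for name, factor in contrast_rule.items():
            maps[name][mask] *= factor
        out.letter_masks.append(mask)
    return out
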