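"""Through-slice sampling schemes for super-resolution diffusion-relaxation MRI.

Three acquisition strategies are modelled, all on a 1D high-resolution grid of
``n`` sub-voxels along the through-slice direction:

* **SERO** (slice excitation with random overlap): each shot excites ``k``
  contiguous sub-voxels at a uniformly random in-FOV position.  Random overlap
  between consecutive slices makes the local repetition time (TR) of every
  sub-voxel an emergent, heterogeneous quantity.  Proposals whose
  slice-averaged TR falls below a threshold are redrawn, thinning the
  low-SNR short-TR tail.
* **Slice shifting**: full thick-slice volumes are acquired at ``n_shifts``
  sub-voxel FOV offsets with a fixed revisit interval; the first few shots of
  each FOV are discarded to allow the magnetization to reach steady state.
* **Direct high-resolution sampling**: thin slices (``k = 1``) acquired
  cyclically, giving a single long fixed TR at every position.

Only the through-slice dimension is modelled; in-plane encoding is outside
the scope of the scheme abstraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SchemeConfig",
    "AcquisitionScheme",
    "SchemeStats",
    "SchemeError",
    "InfeasibleSchemeError",
    "generate_sero_scheme",
    "generate_slice_shift_scheme",
    "generate_direct_scheme",
    "compute_tr_matrix",
    "compute_weight_matrix",
    "scheme_statistics",
]

#: Surrogate offset (s) added to the elapsed-time term of never-excited
#: sub-voxels when evaluating the slice-averaged-TR rejection rule.  A fully
#: relaxed sub-voxel behaves like one with a very long TR, so early shots
#: must not be penalized by the rejection rule.
FRESH_SUBVOXEL_TR_OFFSET = 100.0

#: Maximum redraws per shot before the rejection loop declares the
#: configuration infeasible.
MAX_REJECTION_ATTEMPTS = 10_000


class SchemeError(ValueError):
    """Invalid scheme configuration or degenerate scheme."""


class InfeasibleSchemeError(SchemeError):
    """The rejection rule cannot be satisfied for this configuration."""


@dataclass(frozen=True)
class SchemeConfig:
    """Configuration of a through-slice sampling scheme.

    Parameters
    ----------
    n : int
        Number of high-resolution through-slice positions (sub-voxels).
    k : int
        Slice thickness in sub-voxels (the "aspect ratio" of the excited
        slice relative to the in-plane resolution).
    m : int
        Number of shots.
    shot_spacing : float
        Time between consecutive shots, in seconds.
    voxel_size : float
        Size of one high-resolution sub-voxel, in mm.
    b_levels : tuple of float
        Available diffusion weightings, in ms/um^2, strictly increasing.
    min_mean_tr : float
        Rejection threshold for the SERO scheme: a proposed slice position is
        redrawn while its slice-averaged TR is below this value (seconds).
    fixed_tr : float or None
        Nominal fixed TR for the reference schemes (informational; the
        realized TR is derived from the slice tiling and shot spacing).
    n_shifts : int
        Number of shifted FOV positions for the slice-shifting scheme.
    discard_per_fov : int
        Shots discarded from analysis at the start of each shifted FOV.
    seed : int
        Seed of the single pseudo-random stream driving slice positions and
        b-value draws.
    """

    n: int = 50
    k: int = 4
    m: int = 1000
    shot_spacing: float = 0.15
    voxel_size: float = 1.5
    b_levels: tuple[float, ...] = (0.1, 0.5, 0.9, 1.4)
    min_mean_tr: float = 1.5
    fixed_tr: float | None = None
    n_shifts: int = 4
    discard_per_fov: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.n >= self.k >= 1):
            raise SchemeError(f"need n >= k >= 1, got n={self.n}, k={self.k}")
        if self.m < 1:
            raise SchemeError("m must be >= 1")
        if self.shot_spacing <= 0:
            raise SchemeError("shot_spacing must be positive")
        b = np.asarray(self.b_levels, dtype=float)
        if b.size == 0 or np.any(b < 0) or np.any(np.diff(b) <= 0):
            raise SchemeError(
                "b_levels must be non-empty, non-negative and strictly increasing"
            )
        if self.min_mean_tr < 0:
            raise SchemeError("min_mean_tr must be >= 0")

    def with_(self, **kwargs) -> "SchemeConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    @property
    def fov(self) -> float:
        """Through-slice field of view in mm."""
        return self.n * self.voxel_size


def compute_weight_matrix(
    start_index: np.ndarray,
    k: int,
    n: int,
    profile: np.ndarray | None = None,
) -> np.ndarray:
    """Build the m x n slice-profile weight matrix W.

    Each row holds the contribution of every high-resolution sub-voxel to one
    thick-slice measurement.  The default profile is perfectly rectangular
    (ones over the covered sub-voxels); ``profile`` accepts an arbitrary
    length-``k`` non-negative vector for smoothed slice profiles.  Slice
    portions outside the grid are clipped.
    """
    start_index = np.asarray(start_index, dtype=int)
    if profile is None:
        profile = np.ones(k)
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (k,) or np.any(profile < 0):
        raise SchemeError("profile must be a non-negative length-k vector")
    m = start_index.shape[0]
    W = np.zeros((m, n))
    for j, s in enumerate(start_index):
        if s < 0 or s >= n:
            raise SchemeError(f"shot {j}: start index {s} outside [0, {n - 1}]")
        stop = min(s + k, n)
        W[j, s:stop] = profile[: stop - s]
    return W


def compute_tr_matrix(
    start_index: np.ndarray,
    shot_time: np.ndarray,
    k: int,
    n: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Derive per-sub-voxel repetition times from the slice order.

    The local TR of sub-voxel ``i`` at shot ``j`` is the time elapsed since
    the most recent earlier shot that covered ``i``.  Sub-voxels excited for
    the first time carry ``TR = inf`` (fully relaxed magnetization) and are
    flagged in the returned ``first_coverage`` mask.  Entries not covered by
    a shot are NaN.

    Returns
    -------
    TR : (m, n) ndarray
        Local repetition times in seconds; ``inf`` at first coverage, NaN
        where the shot does not cover the position.
    first_coverage : (m, n) ndarray of bool
        True where a shot is the first ever excitation of a sub-voxel.
    """
    start_index = np.asarray(start_index, dtype=int)
    shot_time = np.asarray(shot_time, dtype=float)
    if np.any(np.diff(shot_time) <= 0):
        raise SchemeError("shot times must be strictly increasing")
    m = start_index.shape[0]
    TR = np.full((m, n), np.nan)
    first = np.zeros((m, n), dtype=bool)
    last_time = np.full(n, np.nan)
    for j in range(m):
        s = start_index[j]
        stop = min(s + k, n)
        cov = slice(s, stop)
        prev = last_time[cov]
        never = np.isnan(prev)
        tr = shot_time[j] - prev
        tr[never] = np.inf
        TR[j, cov] = tr
        first[j, cov] = never
        last_time[cov] = shot_time[j]
    return TR, first


@dataclass
class AcquisitionScheme:
    """A realized through-slice sampling scheme.

    Holds per-shot slice positions, b-values and times together with the
    derived slice-profile weight matrix ``W`` (m x n), the per-sub-voxel TR
    matrix (m x n, seconds) and the first-coverage mask.  ``analysis_mask``
    marks the shots that enter parameter estimation.
    """

    config: SchemeConfig
    method: str
    start_index: np.ndarray
    b: np.ndarray
    shot_time: np.ndarray
    analysis_mask: np.ndarray
    W: np.ndarray = field(repr=False, default=None)
    TR: np.ndarray = field(repr=False, default=None)
    first_coverage: np.ndarray = field(repr=False, default=None)

    @classmethod
    def from_shots(
        cls,
        config: SchemeConfig,
        method: str,
        start_index: np.ndarray,
        b: np.ndarray,
        shot_time: np.ndarray,
        analysis_mask: np.ndarray | None = None,
        profile: np.ndarray | None = None,
    ) -> "AcquisitionScheme":
        """Assemble a scheme, deriving W, TR and the first-coverage mask."""
        start_index = np.asarray(start_index, dtype=int)
        b = np.asarray(b, dtype=float)
        shot_time = np.asarray(shot_time, dtype=float)
        m = start_index.shape[0]
        if analysis_mask is None:
            analysis_mask = np.ones(m, dtype=bool)
        analysis_mask = np.asarray(analysis_mask, dtype=bool)
        if not (b.shape == shot_time.shape == analysis_mask.shape == (m,)):
            raise SchemeError("per-shot arrays must share one length")
        k_eff = config.k if method != "direct" else 1
        W = compute_weight_matrix(start_index, k_eff, config.n, profile)
        TR, first = compute_tr_matrix(start_index, shot_time, k_eff, config.n)
        return cls(
            config=config,
            method=method,
            start_index=start_index,
            b=b,
            shot_time=shot_time,
            analysis_mask=analysis_mask,
            W=W,
            TR=TR,
            first_coverage=first,
        )

    @property
    def m(self) -> int:
        return self.start_index.shape[0]

    @property
    def n(self) -> int:
        return self.config.n

    def slice_averaged_tr(self) -> np.ndarray:
        """Per-shot mean TR over the covered sub-voxels.

        First-coverage entries (infinite TR) are excluded from the average;
        a shot whose coverage is entirely first-coverage returns ``inf``.
        """
        covered = self.W > 0
        finite = covered & np.isfinite(self.TR)
        out = np.full(self.m, np.inf)
        cnt = finite.sum(axis=1)
        has = cnt > 0
        tr = np.where(finite, self.TR, 0.0)
        out[has] = tr[has].sum(axis=1) / cnt[has]
        return out

    def coverage_counts(self) -> np.ndarray:
        """Number of shots covering each high-resolution position."""
        return (self.W > 0).sum(axis=0)

    def tr_spread(self) -> float:
        """Spread (max - min) of the defined, non-first-coverage TR entries
        among analysis-masked shots.  Zero for single-TR schemes."""
        pool = self.pooled_tr()
        if pool.size == 0:
            return 0.0
        return float(pool.max() - pool.min())

    def pooled_tr(self) -> np.ndarray:
        """All defined, non-first-coverage TR entries of analysis-masked shots."""
        mask = (self.W > 0) & ~self.first_coverage & self.analysis_mask[:, None]
        pool = self.TR[mask]
        return pool[np.isfinite(pool)]


@dataclass(frozen=True)
class SchemeStats:
    """Summary statistics of a sampling scheme (TR quantiles in seconds)."""

    coverage: np.ndarray
    mean_coverage: float
    tr_min: float
    tr_q1: float
    tr_median: float
    tr_q3: float
    tr_max: float
    frac_below: float
    below_threshold: float
    n_tr_entries: int


def generate_sero_scheme(config: SchemeConfig) -> AcquisitionScheme:
    """Generate a SERO sampling scheme.

    Slice start positions are drawn uniformly on ``{0, ..., n - k}`` so that
    every slice lies fully inside the FOV.  A proposal is accepted only if
    the mean, over its ``k`` covered sub-voxels, of the elapsed time since
    each sub-voxel's last excitation is at least ``min_mean_tr``; never-yet
    excited sub-voxels contribute their elapsed time plus a large surrogate
    offset so that early shots are acceptable.  After the position is
    accepted, the shot's b-value is drawn uniformly from ``b_levels``.

    Raises
    ------
    InfeasibleSchemeError
        If a single shot exhausts the redraw cap, indicating that the
        rejection threshold is unreachable for this FOV / slice thickness /
        shot spacing combination.
    """
    cfg = config
    if cfg.n - cfg.k < 1:
        raise SchemeError("SERO needs n - k >= 1 so that positions can vary")
    rng = np.random.default_rng(cfg.seed)
    b_levels = np.asarray(cfg.b_levels, dtype=float)
    last_time = np.full(cfg.n, np.nan)
    start = np.empty(cfg.m, dtype=int)
    b = np.empty(cfg.m)
    shot_time = np.arange(cfg.m) * cfg.shot_spacing
    for j in range(cfg.m):
        t = shot_time[j]
        for _ in range(MAX_REJECTION_ATTEMPTS):
            s = int(rng.integers(0, cfg.n - cfg.k + 1))
            prev = last_time[s : s + cfg.k]
            elapsed = t - prev
            elapsed = np.where(
                np.isnan(prev), t + FRESH_SUBVOXEL_TR_OFFSET, elapsed
            )
            if elapsed.mean() >= cfg.min_mean_tr:
                break
        else:
            raise InfeasibleSchemeError(
                f"shot {j}: no slice position reached a slice-averaged TR of "
                f"{cfg.min_mean_tr} s within {MAX_REJECTION_ATTEMPTS} redraws"
            )
        start[j] = s
        b[j] = b_levels[int(rng.integers(0, b_levels.size))]
        last_time[s : s + cfg.k] = t
    return AcquisitionScheme.from_shots(cfg, "sero", start, b, shot_time)


def generate_slice_shift_scheme(config: SchemeConfig) -> AcquisitionScheme:
    """Generate a slice-shifting reference scheme.

    Shots are partitioned into ``n_shifts`` contiguous FOV blocks; block
    ``q`` tiles the grid with slices starting at ``q + j*k`` for
    ``j = 0 .. n//k - 1``, visited cyclically, so the FOV shift between
    blocks is one sub-voxel (e.g. 0, 1.5, 3.0, 4.5 mm on a 1.5 mm grid with
    four shifts).  Slice portions extending past the grid are clipped from
    ``W``.  The within-block revisit interval -- and hence the realized TR --
    is ``(n // k) * shot_spacing``.  The first ``discard_per_fov`` shots of
    every block are excluded from analysis to emulate the approach to steady
    state.  b-values cycle over ``b_levels`` volume-by-volume.
    """
    cfg = config
    if cfg.n_shifts < 2:
        raise SchemeError("slice shifting needs n_shifts >= 2")
    if cfg.m % cfg.n_shifts != 0:
        raise SchemeError(
            f"m={cfg.m} is not divisible by n_shifts={cfg.n_shifts}"
        )
    slices_per_vol = cfg.n // cfg.k
    if slices_per_vol < 1:
        raise SchemeError("k exceeds the FOV: no slice fits")
    block = cfg.m // cfg.n_shifts
    start = np.empty(cfg.m, dtype=int)
    b = np.empty(cfg.m)
    analysis = np.ones(cfg.m, dtype=bool)
    b_levels = np.asarray(cfg.b_levels, dtype=float)
    for j in range(cfg.m):
        q, within = divmod(j, block)
        vol, sl = divmod(within, slices_per_vol)
        start[j] = q + sl * cfg.k
        b[j] = b_levels[vol % b_levels.size]
        if within < cfg.discard_per_fov:
            analysis[j] = False
    shot_time = np.arange(cfg.m) * cfg.shot_spacing
    return AcquisitionScheme.from_shots(
        cfg, "shift", start, b, shot_time, analysis
    )


def generate_direct_scheme(config: SchemeConfig) -> AcquisitionScheme:
    """Generate a direct high-resolution sampling scheme (``k = 1``).

    Positions ``0 .. n-1`` are visited cyclically, so the steady-state TR at
    every position is ``n * shot_spacing`` (7.5 s for n=50 at 150 ms).
    b-values cycle over ``b_levels`` volume-by-volume.
    """
    cfg = config
    if cfg.k != 1:
        raise SchemeError("direct sampling requires k = 1")
    b_levels = np.asarray(cfg.b_levels, dtype=float)
    idx = np.arange(cfg.m)
    start = idx % cfg.n
    vol = idx // cfg.n
    b = b_levels[vol % b_levels.size]
    shot_time = idx * cfg.shot_spacing
    return AcquisitionScheme.from_shots(cfg, "direct", start, b, shot_time)


def scheme_statistics(
    scheme: AcquisitionScheme, threshold: float = 0.3
) -> SchemeStats:
    """Summarize a scheme: per-position coverage and pooled TR quantiles.

    Coverage counts every shot; the TR pool contains the defined,
    non-first-coverage TR entries of analysis-masked shots, matching the
    convention that first excitations have no finite repetition time.
    ``frac_below`` is the fraction of pooled entries under ``threshold``
    seconds.
    """
    pool = scheme.pooled_tr()
    if pool.size == 0:
        raise SchemeError("degenerate scheme: no defined TR entries")
    coverage = scheme.coverage_counts()
    q = np.quantile(pool, [0.0, 0.25, 0.5, 0.75, 1.0])
    return SchemeStats(
        coverage=coverage,
        mean_coverage=float(coverage.sum() / scheme.n),
        tr_min=float(q[0]),
        tr_q1=float(q[1]),
        tr_median=float(q[2]),
        tr_q3=float(q[3]),
        tr_max=float(q[4]),
        frac_below=float(np.mean(pool < threshold)),
        below_threshold=threshold,
        n_tr_entries=int(pool.size),
    )
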