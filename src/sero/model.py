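"""Regularized super-resolution estimation of (S0, D, V, T1) maps.

The estimator inverts the thick-slice forward model per through-slice
column: given ``m`` magnitude measurements ``S`` and the experimental
parameters ``Theta = (W, TR, b)`` of an acquisition scheme, it solves

    x_hat = argmin_x || f(x, Theta) - S ||_2^2 + lambda * || delta_p ||_2^2

over the ``4 n`` high-resolution parameters within box bounds, where
``delta_p`` stacks the first spatial differences of each parameter vector
(a smoothness prior) and ``lambda`` trades data fidelity against spatial
regularity.  The problem is solved with a trust-region reflective
bound-constrained least-squares method with an analytic Jacobian, started
from a fast local (slice-wise) fit.  Before fitting, signals are normalized
by their global maximum so that S0 is estimated on a well-conditioned scale
and mapped back afterwards.

Schemes whose TR takes a single value (direct high-resolution sampling)
leave T1 and S0 jointly unidentifiable; such schemes are detected and T1 is
frozen at a nominal value, with S0 reported as apparent baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .schemes import AcquisitionScheme
from .signal import ParameterColumn, ShotSignals, predict_signal

__all__ = [
    "FitConfig",
    "SuperResolutionModel",
    "SuperResolutionResults",
    "normalize_signals",
    "local_fit_init",
    "regularization_residuals",
    "fit_column",
    "fit_volume",
]

PARAM_NAMES = ("s0", "d", "v", "t1")

#: Default box bounds: S0 in a.u. (on the normalized-signal scale), D in
#: um^2/ms, V in um^4/ms^2, T1 in s.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "s0": (0.0, 4.0),
    "d": (0.3, 4.0),
    "v": (0.0, 4.0),
    "t1": (0.3, 5.0),
}


@dataclass(frozen=True)
class FitConfig:
    """Solver settings for the super-resolution fit.

    ``lam`` is the smoothness-prior weight (dimensionless, applied to the
    raw first differences of all four parameter vectors, with S0 on its
    normalized scale).  ``t1_freeze_spread`` is the TR spread (s) below
    which a scheme is treated as single-TR and T1 is frozen at
    ``t1_frozen_value``.  ``init_margin`` pulls the starting point inside
    the bounds by that fraction of each range so trust-region steps never
    start on the boundary.
    """

    lam: float = 0.01
    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    gtol: float = 1e-8
    xtol: float = 1e-8
    ftol: float = 1e-8
    max_iter: int = 200
    jacobian: str = "analytic"  # "analytic" | "fd"
    normalize: bool = True
    per_param_weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    t1_freeze_spread: float = 1e-3
    t1_frozen_value: float | np.ndarray = 1.0
    init_margin: float = 0.01
    exclude_first_coverage_shots: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"bounds for {name} must satisfy lo < hi")
        if self.jacobian not in ("analytic", "fd"):
            raise ValueError("jacobian must be 'analytic' or 'fd'")

    def with_(self, **kwargs) -> "FitConfig":
        return replace(self, **kwargs)


def normalize_signals(signals: ShotSignals) -> tuple[ShotSignals, float]:
    """Scale signals by their global maximum; return (scaled, constant)."""
    c = float(np.max(signals.values))
    if c <= 0:
        raise ValueError("cannot normalize all-zero signals")
    if c == 1.0:
        return signals.copy(), 1.0
    out = signals.copy()
    out.values = out.values / c
    out.sigma = out.sigma / c
    return out, c


def regularization_residuals(
    params: ParameterColumn,
    lam: float,
    weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0),
) -> np.ndarray:
    """Smoothness-prior residuals: sqrt(lam) x stacked first differences.

    Returns a length ``4 (n - 1)`` vector (order S0, D, V, T1) that, when
    appended to the data residuals, contributes ``lam * ||delta_p||^2`` to
    the least-squares objective.
    """
    if params.n < 2:
        raise ValueError("need n >= 2 for spatial differences")
    root = np.sqrt(lam)
    return np.concatenate(
        [root * w * np.diff(arr) for w, (_, arr) in zip(weights, params.items())]
    )


# ---------------------------------------------------------------------------
# local (slice-wise) initialization


def _scalar_residual_jac(x, sat_or_none, tr, b, y, t1_free):
    """Residuals and Jacobian of the scalar model at one position."""
    if t1_free:
        s0, d, v, t1 = x
        finite = np.isfinite(tr)
        sat = np.where(finite, -np.expm1(-np.where(finite, tr, 1.0) / t1), 1.0)
        dsat = np.where(
            finite,
            -np.exp(-np.where(finite, tr, 1.0) / t1)
            * np.where(finite, tr, 0.0)
            / t1**2,
            0.0,
        )
    else:
        s0, d, v = x
        sat = sat_or_none
        dsat = None
    att = np.exp(-b * d + b * b * v / 2.0)
    model = s0 * sat * att
    r = model - y
    cols = [sat * att, -b * model, (b * b / 2.0) * model]
    if t1_free:
        cols.append(s0 * dsat * att)
    return r, np.column_stack(cols)


def local_fit_init(
    signals: ShotSignals,
    scheme: AcquisitionScheme,
    bounds: dict[str, tuple[float, float]] | None = None,
    t1_frozen: np.ndarray | None = None,
    init_margin: float = 0.01,
    max_nfev: int = 60,
) -> tuple[ParameterColumn, np.ndarray]:
    """Fast slice-wise initialization of the super-resolution fit.

    For every high-resolution position, the scalar model is fitted to the
    signals of all analysis-masked shots covering that position, each shot
    assigned its b-value and slice-averaged TR, with signals divided by the
    shot's W row sum to reach the sub-voxel scale.  Positions covered by
    fewer than 4 shots or fewer than 3 distinct b-values fall back to the
    bound midpoints and are flagged.

    Returns
    -------
    init : ParameterColumn
        Starting values, clamped ``init_margin`` inside the bounds.
    fallback : (n,) bool ndarray
        True where the fallback initialization was used.
    """
    if bounds is None:
        bounds = DEFAULT_BOUNDS
    if t1_frozen is not None:
        t1_frozen = np.asarray(t1_frozen, dtype=float)
        if t1_frozen.ndim == 0:
            t1_frozen = np.full(scheme.n, float(t1_frozen))
    names = PARAM_NAMES if t1_frozen is None else PARAM_NAMES[:3]
    lo = np.array([bounds[p][0] for p in names])
    hi = np.array([bounds[p][1] for p in names])
    mid = (lo + hi) / 2.0
    span = hi - lo
    lo_i = lo + init_margin * span
    hi_i = hi - init_margin * span

    n = scheme.n
    covered = scheme.W > 0
    row_sum = scheme.W.sum(axis=1)
    slice_tr = scheme.slice_averaged_tr()
    out = np.tile(mid, (n, 1))
    fallback = np.zeros(n, dtype=bool)
    for i in range(n):
        rows = np.flatnonzero(covered[:, i] & scheme.analysis_mask)
        b_i = scheme.b[rows]
        if rows.size < 4 or np.unique(b_i).size < 3:
            fallback[i] = True
            continue
        y_i = signals.values[rows] / row_sum[rows]
        tr_i = slice_tr[rows]
        t1_free = t1_frozen is None
        sat_frozen = None
        if not t1_free:
            finite = np.isfinite(tr_i)
            sat_frozen = np.where(
                finite, -np.expm1(-np.where(finite, tr_i, 1.0) / t1_frozen[i]), 1.0
            )
        try:
            res = least_squares(
                lambda x: _scalar_residual_jac(x, sat_frozen, tr_i, b_i, y_i, t1_free)[0],
                np.clip(mid, lo_i, hi_i),
                jac=lambda x: _scalar_residual_jac(x, sat_frozen, tr_i, b_i, y_i, t1_free)[1],
                bounds=(lo, hi),
                method="trf",
                max_nfev=max_nfev,
                xtol=1e-8,
                ftol=1e-8,
                gtol=1e-8,
            )
            out[i] = res.x
        except Exception:  # pragma: no cover - defensive fallback
            fallback[i] = True
    out = np.clip(out, lo_i, hi_i)
    t1 = t1_frozen if t1_frozen is not None else out[:, 3]
    init = ParameterColumn(out[:, 0], out[:, 1], out[:, 2], t1)
    return init, fallback


# ---------------------------------------------------------------------------
# the model object


class SuperResolutionModel:
    """Bound-constrained regularized least-squares model for one column.

    Parameters
    ----------
    signals : ShotSignals
        Measured (or simulated) thick-slice magnitudes, one per shot.
    scheme : AcquisitionScheme
        The sampling scheme that produced the signals; supplies W, TR, b
        and the analysis mask.
    config : FitConfig, optional
        Solver settings; defaults reproduce the reference configuration
        (lambda = 0.01, trust-region reflective, analytic Jacobian).

    Examples
    --------
    >>> model = SuperResolutionModel(signals, scheme)
    >>> res = model.fit()
    >>> res.params.d          # estimated diffusivity profile
    >>> print(res.summary())
    """

    def __init__(
        self,
        signals: ShotSignals,
        scheme: AcquisitionScheme,
        config: FitConfig | None = None,
    ):
        if signals.m != scheme.m:
            raise ValueError(
                f"signal length {signals.m} does not match scheme m={scheme.m}"
            )
        self.signals = signals
        self.scheme = scheme
        self.config = config or FitConfig()
        self.t1_frozen = scheme.tr_spread() < self.config.t1_freeze_spread
        self.n = scheme.n

        mask = scheme.analysis_mask.copy()
        if self.config.exclude_first_coverage_shots:
            mask &= ~scheme.first_coverage.any(axis=1)
        self._rows = np.flatnonzero(mask)
        W = scheme.W[self._rows]
        self._W = W
        self._b = scheme.b[self._rows]
        covered = W > 0
        first = scheme.first_coverage[self._rows] & covered
        finite = covered & ~first
        self._finite = finite
        self._first = first
        self._tr_safe = np.where(finite, scheme.TR[self._rows], 1.0)

        names = PARAM_NAMES[:3] if self.t1_frozen else PARAM_NAMES
        self.free_names = names
        self._lo = np.concatenate(
            [np.full(self.n, self.config.bounds[p][0]) for p in names]
        )
        self._hi = np.concatenate(
            [np.full(self.n, self.config.bounds[p][1]) for p in names]
        )
        t1f = np.asarray(self.config.t1_frozen_value, dtype=float)
        self._t1_frozen_vec = (
            np.full(self.n, float(t1f)) if t1f.ndim == 0 else t1f.copy()
        )

    # -- parameter packing ---------------------------------------------------

    def _unpack(self, x: np.ndarray) -> ParameterColumn:
        n = self.n
        s0, d, v = x[:n], x[n : 2 * n], x[2 * n : 3 * n]
        t1 = self._t1_frozen_vec if self.t1_frozen else x[3 * n : 4 * n]
        return ParameterColumn(s0, d, v, t1)

    def _pack(self, params: ParameterColumn) -> np.ndarray:
        blocks = [params.s0, params.d, params.v]
        if not self.t1_frozen:
            blocks.append(params.t1)
        return np.concatenate(blocks)

    # -- residuals and Jacobian ---------------------------------------------

    def _forward_parts(self, x: np.ndarray):
        n = self.n
        s0, d, v = x[:n], x[n : 2 * n], x[2 * n : 3 * n]
        t1 = self._t1_frozen_vec if self.t1_frozen else x[3 * n : 4 * n]
        sat = np.where(self._finite, -np.expm1(-self._tr_safe / t1[None, :]), 0.0)
        sat[self._first] = 1.0
        b = self._b[:, None]
        att = np.exp(-b * d[None, :] + b * b * v[None, :] / 2.0)
        G = self._W * sat * att
        return s0, d, v, t1, b, att, G

    def _data_residuals(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        s0, *_rest, G = self._forward_parts(x)
        return G @ s0 - y

    def _penalty_residuals(self, x: np.ndarray) -> np.ndarray:
        if self.config.lam == 0:
            return np.empty(0)
        root = np.sqrt(self.config.lam)
        n = self.n
        w = self.config.per_param_weights
        parts = []
        for ib, name in enumerate(self.free_names):
            wi = w[PARAM_NAMES.index(name)]
            parts.append(root * wi * np.diff(x[ib * n : (ib + 1) * n]))
        return np.concatenate(parts)

    def _residuals(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return np.concatenate(
            [self._data_residuals(x, y), self._penalty_residuals(x)]
        )

    def _penalty_jacobian(self) -> np.ndarray:
        n = self.n
        nb = len(self.free_names)
        if self.config.lam == 0:
            return np.empty((0, nb * n))
        root = np.sqrt(self.config.lam)
        D1 = np.zeros((n - 1, n))
        idx = np.arange(n - 1)
        D1[idx, idx] = -1.0
        D1[idx, idx + 1] = 1.0
        J = np.zeros((nb * (n - 1), nb * n))
        for ib, name in enumerate(self.free_names):
            wi = self.config.per_param_weights[PARAM_NAMES.index(name)]
            J[
                ib * (n - 1) : (ib + 1) * (n - 1), ib * n : (ib + 1) * n
            ] = root * wi * D1
        return J

    def _jacobian(self, x: np.ndarray, *_args) -> np.ndarray:
        n = self.n
        s0, d, v, t1, b, att, G = self._forward_parts(x)
        J_s0 = G
        Gs0 = G * s0[None, :]
        J_d = -b * Gs0
        J_v = (b * b / 2.0) * Gs0
        blocks = [J_s0, J_d, J_v]
        if not self.t1_frozen:
            dsat = np.where(
                self._finite,
                -np.exp(-self._tr_safe / t1[None, :])
                * self._tr_safe
                / t1[None, :] ** 2,
                0.0,
            )
            blocks.append(self._W * att * s0[None, :] * dsat)
        J_data = np.hstack(blocks)
        J_pen = self._penalty_jacobian()
        if J_pen.shape[0] == 0:
            return J_data
        return np.vstack([J_data, J_pen])

    def objective(self, params: ParameterColumn, y: np.ndarray | None = None) -> float:
        """Value of the regularized least-squares objective at ``params``.

        ``y`` defaults to the (normalized, if configured) measured signals.
        """
        if y is None:
            y = self._normalized()[0].values[self._rows]
        r = self._residuals(self._pack(params), y)
        return float(r @ r)

    def _normalized(self) -> tuple[ShotSignals, float]:
        if self.config.normalize:
            return normalize_signals(self.signals)
        return self.signals, 1.0

    # -- fitting -------------------------------------------------------------

    def fit(self, start_params: ParameterColumn | None = None) -> "SuperResolutionResults":
        """Solve the regularized bound-constrained least-squares problem.

        ``start_params`` (on the normalized-signal S0 scale when
        normalization is active) overrides the fast local-fit
        initialization.
        """
        cfg = self.config
        sig, scale = self._normalized()
        y = sig.values[self._rows]

        if start_params is None:
            init, fallback = local_fit_init(
                sig,
                self.scheme,
                cfg.bounds,
                t1_frozen=self._t1_frozen_vec if self.t1_frozen else None,
                init_margin=cfg.init_margin,
            )
        else:
            init, fallback = start_params, np.zeros(self.n, dtype=bool)
        x0 = np.clip(self._pack(init), self._lo, self._hi)
        span = self._hi - self._lo
        x0 = np.clip(
            x0, self._lo + cfg.init_margin * span, self._hi - cfg.init_margin * span
        )

        kwargs = dict(
            bounds=(self._lo, self._hi),
            method="trf",
            xtol=cfg.xtol,
            ftol=cfg.ftol,
            gtol=cfg.gtol,
            max_nfev=cfg.max_iter,
        )
        if cfg.jacobian == "analytic":
            kwargs["jac"] = self._jacobian
        res = least_squares(self._residuals, x0, args=(y,), **kwargs)
        if res.status == 0:
            warnings.warn(
                "super-resolution fit did not converge within max_iter; "
                "returning the best iterate",
                RuntimeWarning,
                stacklevel=2,
            )

        params_norm = self._unpack(res.x)
        params = params_norm.copy()
        params.s0 = params.s0 * scale
        data_resid = self._data_residuals(res.x, y)
        penalty = self._penalty_residuals(res.x)
        return SuperResolutionResults(
            model=self,
            params=params,
            params_normalized=params_norm,
            scale=scale,
            resid=data_resid,
            residual_norm=float(np.linalg.norm(data_resid)),
            penalty_norm=float(np.linalg.norm(penalty)),
            objective_value=float(2 * res.cost),
            n_iter=int(res.nfev),
            converged=bool(res.status > 0),
            status=int(res.status),
            message=str(res.message),
            init=init,
            init_fallback=fallback,
            t1_frozen=self.t1_frozen,
        )

    @classmethod
    def from_files(
        cls, signals_path, scheme_path, config: FitConfig | None = None
    ) -> "SuperResolutionModel":
        """Build a model from a signals CSV and a scheme CSV (+ sidecar)."""
        from . import io as sero_io

        scheme = sero_io.read_scheme(scheme_path)
        signals = sero_io.read_signals(signals_path)
        return cls(signals, scheme, config)


@dataclass
class SuperResolutionResults:
    """Estimates and diagnostics from a super-resolution column fit.

    ``params`` carries S0 on the original signal scale; the normalization
    constant applied during fitting is ``scale``.  ``resid`` holds the data
    residuals (normalized scale) at the solution.
    """

    model: SuperResolutionModel
    params: ParameterColumn
    params_normalized: ParameterColumn
    scale: float
    resid: np.ndarray
    residual_norm: float
    penalty_norm: float
    objective_value: float
    n_iter: int
    converged: bool
    status: int
    message: str
    init: ParameterColumn
    init_fallback: np.ndarray
    t1_frozen: bool

    def predict(self) -> ShotSignals:
        """Noiseless model prediction at the estimates, on the data scale."""
        return predict_signal(self.params, self.model.scheme)

    def summary(self) -> str:
        """Human-readable fit report."""
        cfg = self.model.config
        lines = [
            "Super-resolution column fit",
            "=" * 47,
            f"scheme: {self.model.scheme.method}   shots used: {self.model._rows.size}"
            f"/{self.model.scheme.m}   positions: {self.model.n}",
            f"lambda: {cfg.lam:g}   normalization constant: {self.scale:.6g}",
            f"converged: {self.converged} (status {self.status}, "
            f"{self.n_iter} evaluations)",
            f"residual norm: {self.residual_norm:.4e}   "
            f"penalty norm: {self.penalty_norm:.4e}",
            f"T1: {'frozen (single-TR scheme)' if self.t1_frozen else 'estimated'}"
            f"   fallback inits: {int(self.init_fallback.sum())}",
            "-" * 47,
            f"{'param':>6} {'mean':>10} {'min':>10} {'max':>10}",
        ]
        units = {"s0": "a.u.", "d": "um2/ms", "v": "um4/ms2", "t1": "s"}
        for name, arr in self.params.items():
            lines.append(
                f"{name:>6} {arr.mean():10.4f} {arr.min():10.4f} {arr.max():10.4f}"
                f"  [{units[name]}]"
            )
        return "\n".join(lines)


def fit_column(
    signals: ShotSignals,
    scheme: AcquisitionScheme,
    config: FitConfig | None = None,
    init: ParameterColumn | None = None,
) -> SuperResolutionResults:
    """Convenience wrapper: build a :class:`SuperResolutionModel` and fit."""
    return SuperResolutionModel(signals, scheme, config).fit(start_params=init)


def fit_volume(
    stack: np.ndarray,
    scheme: AcquisitionScheme,
    config: FitConfig | None = None,
):
    """Fit every through-plane column of a signal stack independently.

    Parameters
    ----------
    stack : (nx, ny, m) ndarray
        Thick-slice magnitude signals for every in-plane location.
    scheme : AcquisitionScheme
    config : FitConfig, optional

    Returns
    -------
    maps : dict of (nx, ny, n) ndarray
        Estimated parameter maps keyed by ``s0``, ``d``, ``v``, ``t1``.
    qc : pandas.DataFrame
        Per-column diagnostics (convergence flag, iterations, residual
        norm, fallback-initialization count).

    Columns are independent, so the result does not depend on the order in
    which they are processed.
    """
    import pandas as pd

    stack = np.asarray(stack, dtype=float)
    nx, ny, m = stack.shape
    if m != scheme.m:
        raise ValueError("stack's last axis must match the scheme's shot count")
    n = scheme.n
    maps = {name: np.zeros((nx, ny, n)) for name in PARAM_NAMES}
    records = []
    for ix in range(nx):
        for iy in range(ny):
            values = stack[ix, iy]
            if np.max(values) <= 0:  # empty background column
                for name in maps:
                    maps[name][ix, iy] = 0.0 if name == "s0" else np.nan
                records.append(
                    dict(ix=ix, iy=iy, converged=True, n_iter=0,
                         residual_norm=0.0, n_fallback=0, empty=True)
                )
                continue
            res = fit_column(ShotSignals(values, noiseless=False), scheme, config)
            for name, arr in res.params.items():
                maps[name][ix, iy] = arr
            records.append(
                dict(
                    ix=ix,
                    iy=iy,
                    converged=res.converged,
                    n_iter=res.n_iter,
                    residual_norm=res.residual_norm,
                    n_fallback=int(res.init_fallback.sum()),
                    empty=False,
                )
            )
    return maps, pd.DataFrame.from_records(records)
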