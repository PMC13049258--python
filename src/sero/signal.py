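"""Forward signal model for joint diffusion-relaxation encoding.

The scalar model for one sub-voxel measured with repetition time TR and
diffusion weighting b is the saturation-recovery cumulant representation

    S = S0 * (1 - exp(-TR / T1)) * exp(-b * D + b^2 * V / 2),

with baseline signal S0 (a.u.), longitudinal relaxation time T1 (s),
apparent diffusivity D (um^2/ms) and diffusional variance V (um^4/ms^2).
A thick-slice measurement is the slice-profile-weighted sum of this model
over the covered sub-voxels, each with its own local TR.  Only the most
recent excitation is tracked (long-TR approximation): a sub-voxel excited
for the first time is fully relaxed and contributes saturation factor 1.

Noise is modelled as Rician: independent zero-mean Gaussian noise on the
real and imaginary channels of a zero-phase signal, followed by taking the
magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schemes import AcquisitionScheme

__all__ = [
    "ParameterColumn",
    "ShotSignals",
    "predict_signal_scalar",
    "predict_signal",
    "sigma_from_snr",
    "add_rician_noise",
]


@dataclass
class ParameterColumn:
    """High-resolution (S0, D, V, T1) values along one through-slice column.

    Units: S0 in arbitrary units, D in um^2/ms, V in um^4/ms^2, T1 in
    seconds.  R1 = 1/T1 is available as a property.
    """

    s0: np.ndarray
    d: np.ndarray
    v: np.ndarray
    t1: np.ndarray

    def __post_init__(self) -> None:
        self.s0 = np.atleast_1d(np.asarray(self.s0, dtype=float))
        self.d = np.atleast_1d(np.asarray(self.d, dtype=float))
        self.v = np.atleast_1d(np.asarray(self.v, dtype=float))
        self.t1 = np.atleast_1d(np.asarray(self.t1, dtype=float))
        n = self.s0.shape[0]
        if not (self.d.shape == self.v.shape == self.t1.shape == (n,)):
            raise ValueError("parameter vectors must share one length")
        for name, arr in self.items():
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
        if np.any(self.t1 <= 0):
            raise ValueError("T1 must be positive")
        if np.any(self.d <= 0):
            raise ValueError("D must be positive")
        if np.any(self.s0 < 0) or np.any(self.v < 0):
            raise ValueError("S0 and V must be non-negative")

    def items(self):
        return (("s0", self.s0), ("d", self.d), ("v", self.v), ("t1", self.t1))

    @property
    def n(self) -> int:
        return self.s0.shape[0]

    @property
    def r1(self) -> np.ndarray:
        """Longitudinal relaxation rate 1/T1 in 1/s."""
        return 1.0 / self.t1

    def copy(self) -> "ParameterColumn":
        return ParameterColumn(
            self.s0.copy(), self.d.copy(), self.v.copy(), self.t1.copy()
        )

    def as_array(self) -> np.ndarray:
        """Stack as an (n, 4) array with columns (S0, D, V, T1)."""
        return np.column_stack([self.s0, self.d, self.v, self.t1])

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "ParameterColumn":
        arr = np.asarray(arr, dtype=float)
        return cls(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3])


@dataclass
class ShotSignals:
    """Magnitude signals for the shots of one scheme (one column).

    ``sigma`` is the standard deviation of the complex-channel noise in the
    same arbitrary units as ``values`` (0 for noiseless data); ``seed``
    records the noise stream when applicable.
    """

    values: np.ndarray
    noiseless: bool = True
    sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("magnitude signals must be non-negative")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    def copy(self) -> "ShotSignals":
        return ShotSignals(self.values.copy(), self.noiseless, self.sigma, self.seed)


def predict_signal_scalar(s0, d, v, t1, tr, b):
    """Evaluate the scalar saturation-recovery diffusion model.

    ``tr`` may be ``inf`` (fully relaxed magnetization, saturation factor
    exactly 1).  All arguments broadcast.
    """
    s0, d, v, t1, tr, b = map(np.asarray, (s0, d, v, t1, tr, b))
    sat = -np.expm1(-tr / t1)  # 1 - exp(-TR/T1); exact at tr = inf
    return s0 * sat * np.exp(-b * d + b * b * v / 2.0)


def _saturation_matrix(scheme: AcquisitionScheme, t1: np.ndarray) -> np.ndarray:
    """(m, n) saturation factors; 1 at first coverage, 0 where uncovered."""
    covered = scheme.W > 0
    finite = covered & ~scheme.first_coverage
    tr_safe = np.where(finite, scheme.TR, 1.0)
    sat = -np.expm1(-tr_safe / t1[None, :])
    sat = np.where(finite, sat, 0.0)
    sat[scheme.first_coverage & covered] = 1.0
    return sat


def predict_signal(
    params: ParameterColumn, scheme: AcquisitionScheme
) -> ShotSignals:
    """Evaluate the thick-slice forward model for every shot of a scheme.

    Each shot's noiseless signal is the W-weighted sum over its covered
    sub-voxels of the scalar model evaluated with the sub-voxel's local TR
    and the shot's b-value; first-coverage sub-voxels use saturation
    factor 1.
    """
    if params.n != scheme.n:
        raise ValueError(
            f"parameter column length {params.n} does not match scheme n={scheme.n}"
        )
    sat = _saturation_matrix(scheme, params.t1)
    b = scheme.b[:, None]
    att = np.exp(-b * params.d[None, :] + b * b * params.v[None, :] / 2.0)
    values = (scheme.W * sat * att) @ params.s0
    return ShotSignals(values=values, noiseless=True, sigma=0.0)


def sigma_from_snr(
    params, snr: float, support: np.ndarray | None = None
) -> float:
    """Noise standard deviation for a target SNR: sigma = mean(S0) / SNR.

    The mean baseline amplitude is taken over the object support (all
    positions for a line phantom; a mask for labelled volumes).  The SNR
    refers to the isotropic high-resolution voxel, so thick-slice
    measurements, whose noiseless amplitude is about k-fold larger, enjoy a
    voxel-volume advantage at equal sigma.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    s0 = params.s0 if isinstance(params, ParameterColumn) else np.asarray(params)
    s0 = np.asarray(s0, dtype=float)
    if support is not None:
        s0 = s0[np.asarray(support, dtype=bool)]
    if s0.size == 0 or s0.mean() <= 0:
        raise ValueError("degenerate object: mean baseline amplitude is zero")
    return float(s0.mean() / snr)


def add_rician_noise(
    signals: ShotSignals, sigma: float, seed: int | None = None
) -> ShotSignals:
    """Corrupt magnitude signals with Rician noise of scale ``sigma``.

    Independent zero-mean Gaussian noise of standard deviation ``sigma`` is
    added to the real and imaginary channels of a zero-phase signal and the
    magnitude is taken.  ``sigma = 0`` returns an unchanged copy.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return signals.copy()
    rng = np.random.default_rng(seed)
    g1 = rng.normal(0.0, sigma, signals.m)
    g2 = rng.normal(0.0, sigma, signals.m)
    values = np.hypot(signals.values + g1, g2)
    return ShotSignals(values=values, noiseless=False, sigma=float(sigma), seed=seed)
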