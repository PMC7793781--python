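"""MVAR fitting, Schwarz-criterion order selection, and generalized
partial directed coherence (gPDC).

Each clean 6-s epoch is modeled as a multivariate autoregressive process

    x(t) = Σ_{k=1..p} A_k x(t−k) + ε(t),   Cov(ε) = Σ̂,

fitted by least squares after per-channel mean centering.  The frequency-
transformed coefficient matrix

    Ā(f) = I − Σ_k A_k exp(−i 2π f k / f_s)

yields the directed coherence from channel j to channel i,

    gPDC_{i←j}(f) = (|Ā_{ij}(f)| / σ̂_i) / sqrt(Σ_k |Ā_{kj}(f)|² / σ̂_k²),

which is normalized by the residual standard deviations σ̂ so it is
invariant to per-channel amplitude scaling, lies in [0, 1], and satisfies
Σ_i gPDC²_{i←j}(f) = 1 for every source j.  Per-epoch gPDC magnitudes are
averaged across a session's epochs (a short-time stationary approach),
then summarized per canonical frequency band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .preprocess import CleanEpochSet
from .sessions import CHANNELS, EEG_RATE

#: Canonical EEG bands in Hz.  Edges are half-open [lo, hi) so shared edge
#: frequencies are not double-counted; gamma is closed at 50 Hz.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 50.0),
}

DEFAULT_ORDER = 12
DEFAULT_FREQS = np.arange(1.0, 51.0)  # 1..50 Hz in 1 Hz steps


@dataclass
class MvarFit:
    """A least-squares MVAR fit: coefficients, residual covariance, SBC."""

    order: int
    coeffs: np.ndarray  # (p, C, C)
    resid_cov: np.ndarray  # (C, C)
    n_obs: int
    sbc: float

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]


@dataclass
class GpdcResult:
    """Directed coherence on a frequency grid with per-band aggregates.

    ``values[i, j, f]`` is gPDC from source j to target i at ``freqs[f]``;
    ``band_means[i, j, b]`` averages over the grid points inside band b
    (order follows :data:`BANDS`).
    """

    freqs: np.ndarray
    values: np.ndarray  # (C, C, F) in [0, 1]
    band_means: np.ndarray  # (C, C, 5)
    n_epochs: int
    channel_names: tuple[str, ...] = CHANNELS

    @property
    def band_names(self) -> tuple[str, ...]:
        return tuple(BANDS)


def fit_mvar(epoch: np.ndarray, p: int) -> MvarFit:
    """Fit a VAR(p) to one epoch by least squares.

    The epoch is mean-centered per channel; no intercept is estimated.
    The residual covariance uses the bias-corrected divisor
    ``n_obs − C·p`` with ``n_obs = N − p``.
    """
    x = np.asarray(epoch, dtype=float)
    c, n = x.shape
    if p < 1:
        raise ValueError("order p must be >= 1")
    if n <= 10 * p:
        raise ValueError(f"epoch length {n} must exceed 10*p = {10 * p}")
    x = x - x.mean(axis=1, keepdims=True)
    n_obs = n - p
    # regressors: rows are x(t-1)..x(t-p) stacked, t = p..n-1
    z = np.concatenate([x[:, p - k: n - k] for k in range(1, p + 1)], axis=0)
    y = x[:, p:]
    sol, _res, rank, _sv = np.linalg.lstsq(z.T, y.T, rcond=None)
    if rank < c * p:
        raise ValueError(
            f"rank-deficient regressor matrix (rank {rank} < {c * p}); "
            "try a smaller model order"
        )
    b = sol.T  # (C, C*p)
    coeffs = b.reshape(c, p, c).transpose(1, 0, 2)
    resid = y - b @ z
    dof = n_obs - c * p
    if dof <= 0:
        raise ValueError("too few observations for the requested order")
    resid_cov = resid @ resid.T / dof
    fit = MvarFit(order=p, coeffs=coeffs, resid_cov=resid_cov,
                  n_obs=n_obs, sbc=np.nan)
    fit.sbc = sbc(fit)
    return fit


def sbc(fit: MvarFit) -> float:
    """Schwarz Bayesian Criterion of an MVAR fit.

    SBC(p) = ln det Σ̂_p + (ln n / n) · p · C², with n the number of fitted
    observations.  Terms independent of p are dropped (argmin unchanged).
    """
    c = fit.n_channels
    cov = (fit.resid_cov + fit.resid_cov.T) / 2
    evals = np.linalg.eigvalsh(cov)
    tiny = 1e-12 * max(float(evals.max()), 1.0)
    if evals.min() <= -tiny:
        raise ValueError("residual covariance is not positive semidefinite")
    evals = np.maximum(evals, tiny)
    if float(evals.min()) <= tiny and float(evals.max()) <= tiny:
        raise ValueError("singular residual covariance")
    logdet = float(np.log(evals).sum())
    n = fit.n_obs
    return logdet + (np.log(n) / n) * fit.order * c**2


def select_order(epochs: list[np.ndarray], p_max: int = 30) -> int:
    """Order minimizing the mean SBC across epochs, scanned over 1..p_max.

    The pipeline's default analysis order stays fixed (12) for
    comparability; this reports what the data themselves prefer.
    """
    if not epochs:
        raise ValueError("need at least one epoch")
    means = []
    for p in range(1, p_max + 1):
        means.append(np.mean([fit_mvar(e, p).sbc for e in epochs]))
    best = int(np.argmin(means)) + 1
    if best == p_max:
        warnings.warn(
            f"selected order hit the scan boundary p_max={p_max}; "
            "the true order may be larger", stacklevel=2,
        )
    return best


def transfer_matrix(fit: MvarFit, f: float, fs: float = EEG_RATE) -> np.ndarray:
    """Ā(f) = I − Σ_k A_k e^{−i 2π f k / fs} for one frequency."""
    if not 0 <= f < fs / 2:
        raise ValueError(f"frequency {f} outside [0, {fs / 2})")
    return _transfer(fit.coeffs, np.array([f]), fs)[..., 0]


def _transfer(coeffs: np.ndarray, freqs: np.ndarray, fs: float) -> np.ndarray:
    p, c, _ = coeffs.shape
    k = np.arange(1, p + 1)
    phase = np.exp(-2j * np.pi * np.outer(k, freqs) / fs)  # (p, F)
    a_f = np.tensordot(coeffs, phase, axes=(0, 0))  # (C, C, F)
    return np.eye(c)[:, :, None] - a_f


def _gpdc_values(coeffs: np.ndarray, resid_var: np.ndarray,
                 freqs: np.ndarray, fs: float) -> np.ndarray:
    if (resid_var <= 0).any():
        raise ValueError("zero residual variance: degenerate channel")
    a_bar = _transfer(coeffs, np.asarray(freqs, dtype=float), fs)
    w = np.abs(a_bar) / np.sqrt(resid_var)[:, None, None]  # |Ā_ij|/σ_i
    denom = np.sqrt((w**2).sum(axis=0, keepdims=True))
    return w / denom


def gpdc(fit: MvarFit, freqs: np.ndarray | None = None,
         fs: float = EEG_RATE,
         channel_names: tuple[str, ...] = CHANNELS) -> GpdcResult:
    """Single-epoch gPDC on a frequency grid (default 1..50 Hz, 1 Hz steps)."""
    freqs = DEFAULT_FREQS if freqs is None else np.asarray(freqs, dtype=float)
    values = _gpdc_values(fit.coeffs, np.diag(fit.resid_cov), freqs, fs)
    return GpdcResult(
        freqs=freqs,
        values=values,
        band_means=band_means(values, freqs),
        n_epochs=1,
        channel_names=channel_names,
    )


def gpdc_from_model(coeffs: np.ndarray, noise_cov: np.ndarray,
                    freqs: np.ndarray | None = None,
                    fs: float = EEG_RATE) -> np.ndarray:
    """Closed-form gPDC of a known VAR model (ground-truth oracle)."""
    freqs = DEFAULT_FREQS if freqs is None else np.asarray(freqs, dtype=float)
    return _gpdc_values(np.asarray(coeffs, dtype=float),
                        np.diag(np.asarray(noise_cov, dtype=float)), freqs, fs)


def band_means(values: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Average gPDC over the grid points inside each canonical band."""
    out = np.full(values.shape[:2] + (len(BANDS),), np.nan)
    for b, (lo, hi) in enumerate(BANDS.values()):
        if hi >= 50.0:  # gamma: closed upper edge
            sel = (freqs >= lo) & (freqs <= hi)
        else:
            sel = (freqs >= lo) & (freqs < hi)
        if sel.any():
            out[:, :, b] = values[:, :, sel].mean(axis=2)
    return out


def session_gpdc(
    epochset: CleanEpochSet,
    p: int = DEFAULT_ORDER,
    freqs: np.ndarray | None = None,
    fs: float = EEG_RATE,
) -> GpdcResult:
    """Session-level gPDC: per-epoch MVAR fit and gPDC, averaged pointwise.

    One MVAR per 6-s epoch keeps the stationarity assumption local; the
    epoch gPDC magnitudes are then averaged and summarized per band.
    """
    if not len(epochset.epochs):
        raise ValueError("empty epoch set: no clean epochs to analyze")
    freqs = DEFAULT_FREQS if freqs is None else np.asarray(freqs, dtype=float)
    acc = None
    for epoch in epochset.epochs:
        fit = fit_mvar(epoch, p)
        vals = _gpdc_values(fit.coeffs, np.diag(fit.resid_cov), freqs, fs)
        acc = vals if acc is None else acc + vals
    mean_vals = acc / len(epochset.epochs)
    names = epochset.channel_names or CHANNELS
    return GpdcResult(
        freqs=freqs,
        values=mean_vals,
        band_means=band_means(mean_vals, freqs),
        n_epochs=len(epochset.epochs),
        channel_names=tuple(names),
    )
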