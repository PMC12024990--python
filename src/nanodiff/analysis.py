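"""Mean-squared-displacement analysis and diffusion-coefficient estimation.

The MSD uses every available time origin (all overlapping lags) of the
unwrapped trajectories, averaged over particles and replicates.  Diffusion
coefficients come from a least-squares line through the MSD over a lag
window inside the linear regime, via ``<MSD>_ij = 2 D_ij N t`` with N the
motion dimension (1 per axis, 3 for the total).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants as c
from .transport import TrajectoryRecord


@dataclass
class MSDResult:
    """Ensemble MSD curves (m^2) on the lag-time grid ``lags`` (s)."""

    lags: np.ndarray
    msd_axes: np.ndarray  # (3, n_lags): x, y, z
    n_replicates: int = 1

    @property
    def msd_total(self) -> np.ndarray:
        return self.msd_axes.sum(axis=0)


@dataclass
class DiffusionFit:
    """Fitted diffusion coefficients (m^2/s) with fit standard errors."""

    d_axes: np.ndarray  # (3,)
    d_total: float
    d_axes_se: np.ndarray
    d_total_se: float
    window: tuple[float, float] = (0.1, 0.5)
    negative_slope: bool = False


@dataclass
class EnsembleSummary:
    """Mean over replicate diffusion coefficients and the replicate whose
    coefficient sits closest to that mean (ties -> lowest index)."""

    mean_d: float
    sd_d: float
    per_replicate: np.ndarray
    representative: int


@dataclass
class EquivalentViscosity:
    """Homogeneous-fluid viscosity reproducing a hindered diffusivity via the
    inverse Stokes-Einstein relation ``mu_e = k_B T / (6 pi R0 D_sub)``."""

    d_sub: float
    radius: float
    temperature: float
    mu_e: float = field(init=False)

    def __post_init__(self) -> None:
        if self.d_sub <= 0 or self.radius <= 0 or self.temperature <= 0:
            raise ValueError("d_sub, radius and temperature must be positive")
        self.mu_e = c.K_B * self.temperature / (6.0 * np.pi * self.radius * self.d_sub)


def _msd_single(pos: np.ndarray, max_lag: int) -> np.ndarray:
    """Time-origin-averaged per-axis MSD of one trajectory block via the FFT
    autocorrelation identity (O(S log S) instead of O(S^2)).

    ``pos``: (n_samples, n_particles, 3); returns (3, max_lag + 1).
    """
    s = pos.shape[0]
    nfft = 1 << (2 * s - 1).bit_length()
    fft = np.fft.rfft(pos, n=nfft, axis=0)
    acf = np.fft.irfft(fft * fft.conj(), n=nfft, axis=0)[:s].real  # (S, P, 3)
    sq = pos**2
    sumsq = sq.sum(axis=0)  # (P, 3)
    # S1(tau) = sum_t (x_t^2 + x_{t+tau}^2) over the S - tau valid origins
    s1 = np.empty_like(acf)
    s1[0] = 2.0 * sumsq
    head = np.cumsum(sq[: s - 1], axis=0)  # x_0^2 .. x_{S-2}^2 partial sums
    tail = np.cumsum(sq[:0:-1], axis=0)  # x_{S-1}^2 .. x_1^2 partial sums
    s1[1:] = 2.0 * sumsq - head - tail
    counts = (s - np.arange(s))[:, None, None]
    msd = (s1 - 2.0 * acf) / counts  # (S, P, 3), per-particle per-axis
    msd = np.maximum(msd, 0.0)  # FFT round-off can leave tiny negatives
    msd[0] = 0.0
    return msd[: max_lag + 1].mean(axis=1).T


def compute_msd(
    records: list[TrajectoryRecord] | TrajectoryRecord,
    max_lag: int | None = None,
) -> MSDResult:
    """Ensemble MSD over particles and replicates from unwrapped positions.

    All records must share the same uniform sampling interval; ``max_lag``
    defaults to half the shortest record (origin-averaged estimates beyond
    that are dominated by noise).
    """
    if isinstance(records, TrajectoryRecord):
        records = [records]
    if not records:
        raise ValueError("at least one trajectory is required")
    dts = []
    for r in records:
        steps = np.diff(r.times)
        if len(steps) == 0 or not np.allclose(steps, steps[0], rtol=1e-9):
            raise ValueError("records must be uniformly sampled")
        dts.append(steps[0])
    if not np.allclose(dts, dts[0], rtol=1e-9):
        raise ValueError("records must share one uniform sampling interval")
    dt_s = dts[0]
    n_min = min(len(r.times) for r in records)
    if max_lag is None:
        max_lag = max(1, n_min // 2)
    max_lag = min(max_lag, n_min - 1)
    acc = np.zeros((3, max_lag + 1))
    weight = 0
    for r in records:
        npart = r.positions.shape[1]
        acc += npart * _msd_single(r.positions[:n_min], max_lag)
        weight += npart
    return MSDResult(
        lags=np.arange(max_lag + 1) * dt_s,
        msd_axes=acc / weight,
        n_replicates=len(records),
    )


def fit_diffusion(
    msd: MSDResult,
    window: tuple[float, float] = (0.1, 0.5),
    n_dim: int = 3,
) -> DiffusionFit:
    """Least-squares slope of the MSD over the fractional lag window
    ``window`` (of the maximum lag), converted to D via slope / (2 N).

    Per-axis coefficients use N = 1; the total uses ``n_dim``.  A negative
    fitted slope is reported as-is with ``negative_slope=True``.
    """
    lo = window[0] * msd.lags[-1]
    hi = window[1] * msd.lags[-1]
    sel = (msd.lags >= lo) & (msd.lags <= hi) & (msd.lags > 0)
    if sel.sum() < 2:
        raise ValueError("fit window contains fewer than two lag points")
    t = msd.lags[sel]
    d_axes = np.empty(3)
    d_axes_se = np.empty(3)
    for ax in range(3):
        slope, se = _slope_with_se(t, msd.msd_axes[ax, sel])
        d_axes[ax] = slope / 2.0
        d_axes_se[ax] = se / 2.0
    slope, se = _slope_with_se(t, msd.msd_total[sel])
    d_total = slope / (2.0 * n_dim)
    return DiffusionFit(
        d_axes=d_axes,
        d_total=d_total,
        d_axes_se=d_axes_se,
        d_total_se=se / (2.0 * n_dim),
        window=window,
        negative_slope=bool(d_total < 0 or (d_axes < 0).any()),
    )


def _slope_with_se(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    A = np.vstack([t, np.ones_like(t)]).T
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    n = len(t)
    if n > 2 and res.size:
        sigma2 = res[0] / (n - 2)
        se = float(np.sqrt(sigma2 / ((t - t.mean()) ** 2).sum()))
    else:
        se = 0.0
    return float(coef[0]), se


def ensemble_summary(per_replicate_d) -> EnsembleSummary:
    """Arithmetic mean and SD over replicate coefficients plus the index of
    the replicate closest to the mean (lowest index on ties)."""
    d = np.asarray(per_replicate_d, dtype=float)
    if d.size < 2:
        raise ValueError("at least two replicates are required")
    mean = float(d.mean())
    rep = int(np.argmin(np.abs(d - mean)))
    return EnsembleSummary(
        mean_d=mean, sd_d=float(d.std(ddof=1)), per_replicate=d, representative=rep
    )


def equivalent_viscosity(
    d_sub: float, radius: float, temperature: float = c.BODY_TEMPERATURE
) -> EquivalentViscosity:
    """Equivalent viscosity of the ECM-plus-interstitial-fluid continuum:
    ``mu_e = k_B T / (6 pi R0 D_sub)``."""
    return EquivalentViscosity(d_sub=d_sub, radius=radius, temperature=temperature)


def sphere_array_reference_d(porosity: float) -> float:
    """Maxwell effective-diffusivity ratio ``D_eff / D0 = 2 eps / (3 - eps)``
    for a dilute array of impermeable spheres — the analytic reference used
    for the regular sphere-array validation."""
    if not 0 < porosity <= 1:
        raise ValueError("porosity must lie in (0, 1]")
    return 2.0 * porosity / (3.0 - porosity)


def fit_ensemble(records: list[TrajectoryRecord], window=(0.1, 0.5)) -> tuple[EnsembleSummary, DiffusionFit]:
    """Per-replicate total-D fits plus their ensemble summary; the second
    return value is the fit of the representative replicate."""
    per = []
    fits = []
    for r in records:
        f = fit_diffusion(compute_msd(r), window=window)
        per.append(f.d_total)
        fits.append(f)
    summ = ensemble_summary(per)
    return summ, fits[summ.representative]
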