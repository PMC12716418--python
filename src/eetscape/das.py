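"""Global lifetime analysis of time-resolved spectra (decay-associated spectra).

A delay x wavelength matrix (transient absorption or time-resolved
fluorescence) is modelled as a parallel sum of exponentials convolved with a
Gaussian instrument response function (IRF),

    S(t, lambda) = sum_k DAS_k(lambda) * c_k(t),
    c_k(t) = exp(-(t - t0)/tau_k)  (x)  G(t; fwhm),

fitted globally: the lifetimes tau_k are shared across wavelengths and
optimized by nonlinear least squares in log-space, while the per-wavelength
amplitudes DAS_k(lambda) are solved linearly at every iteration (variable
projection / separable least squares).  The sign convention follows the usual
transient-absorption reading: within a decay-associated spectrum, positive
amplitude decays and negative amplitude grows on that component's timescale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import erfc, erfcx

__all__ = [
    "TACube",
    "DASResult",
    "exp_conv_irf",
    "fit_global",
    "report_components",
]


@dataclass
class TACube:
    """Time-resolved spectral data: delays (ps) x wavelengths (nm) signal.

    ``irf_fwhm`` and ``t0`` record the instrument response recorded with the
    data; the fitter uses them unless asked to float them.
    """

    delays: np.ndarray
    wavelengths: np.ndarray
    signal: np.ndarray
    irf_fwhm: float = 0.07
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if np.any(np.diff(self.delays) <= 0) or np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("delay and wavelength grids must be strictly increasing")
        if self.signal.shape != (len(self.delays), len(self.wavelengths)):
            raise ValueError("signal must be (n_delays, n_wavelengths)")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")

    def to_csv(self, path: str | Path) -> None:
        """First row wavelengths, first column delays."""
        df = pd.DataFrame(self.signal, index=self.delays, columns=self.wavelengths)
        df.index.name = "delay_ps"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, irf_fwhm: float = 0.07, t0: float = 0.0) -> "TACube":
        df = pd.read_csv(path, index_col=0)
        return cls(
            delays=df.index.to_numpy(float),
            wavelengths=np.array([float(c) for c in df.columns]),
            signal=df.to_numpy(float),
            irf_fwhm=irf_fwhm,
            t0=t0,
        )

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("delays", data=self.delays)
            f.create_dataset("wavelengths", data=self.wavelengths)
            ds = f.create_dataset("signal", data=self.signal)
            ds.attrs["irf_fwhm_ps"] = self.irf_fwhm
            ds.attrs["t0_ps"] = self.t0

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "TACube":
        with h5py.File(path, "r") as f:
            sig = f["signal"]
            return cls(
                delays=f["delays"][:],
                wavelengths=f["wavelengths"][:],
                signal=sig[:],
                irf_fwhm=float(sig.attrs.get("irf_fwhm_ps", 0.0)),
                t0=float(sig.attrs.get("t0_ps", 0.0)),
            )


@dataclass
class DASResult:
    """Outcome of a global fit: shared lifetimes plus component spectra."""

    lifetimes: np.ndarray            # ps, ascending
    das: np.ndarray                  # (n_components, n_wavelengths)
    wavelengths: np.ndarray
    residual_norm: float
    per_wavelength_residual: np.ndarray
    irf_fwhm: float
    t0: float
    success: bool
    message: str = ""
    degenerate: bool = False
    cost_history: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.das.T,
            index=self.wavelengths,
            columns=[f"tau_{tau:.4g}ps" for tau in self.lifetimes],
        )
        df.index.name = "wavelength_nm"
        return df


def exp_conv_irf(
    tau: float, t0: float, fwhm: float, t: np.ndarray
) -> np.ndarray:
    """Single exponential convolved with a unit-area Gaussian IRF.

    Analytic exp*erfc form, evaluated with the scaled complementary error
    function for numerical stability; ``fwhm = 0`` reduces to a step
    exponential switched on at ``t0``.
    """
    if tau <= 0:
        raise ValueError("lifetime must be positive")
    if fwhm < 0:
        raise ValueError("irf fwhm must be non-negative")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    x = t - t0
    if fwhm == 0:
        out = np.zeros_like(x)
        mask = x >= 0
        out[mask] = np.exp(-x[mask] / tau)
        return out
    s = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    a = (s / tau - x / s) / np.sqrt(2.0)
    out = np.empty_like(x)
    early = a >= 0
    # erfcx form is stable where the argument is non-negative; at late times
    # (a < 0) erfcx overflows, so use the plain exp * erfc branch there.
    out[early] = 0.5 * erfcx(a[early]) * np.exp(-0.5 * (x[early] / s) ** 2)
    late = ~early
    with np.errstate(under="ignore"):
        out[late] = (
            0.5
            * erfc(a[late])
            * np.exp(0.5 * (s / tau) ** 2 - x[late] / tau)
        )
    return out


def _design_matrix(taus: np.ndarray, t0: float, fwhm: float, t: np.ndarray) -> np.ndarray:
    return np.column_stack([exp_conv_irf(tau, t0, fwhm, t) for tau in taus])


def _solve_amplitudes(c: np.ndarray, signal: np.ndarray) -> np.ndarray:
    """Least-squares amplitudes for all wavelengths at once: (k, n_lambda)."""
    amps, *_ = np.linalg.lstsq(c, signal, rcond=None)
    return amps


def fit_global(
    cube: TACube,
    n_components: int,
    init: np.ndarray | list | None = None,
    fit_irf: bool = False,
    max_components: int = 6,
    degenerate_ratio: float = 1.2,
) -> DASResult:
    """Global multi-exponential fit with shared lifetimes (variable projection).

    Lifetimes are optimized in log-space (they span femtoseconds to
    nanoseconds); per-wavelength amplitudes are profiled out linearly at each
    iteration.  ``init`` seeds the lifetimes (default: log-spaced across the
    positive delay range).  With ``fit_irf`` the IRF width and time zero float
    too.  Lifetimes whose ratio falls below ``degenerate_ratio`` set the
    ``degenerate`` flag on the result.
    """
    if not 1 <= n_components <= max_components:
        raise ValueError(f"n_components must be in [1, {max_components}]")
    if len(cube.delays) <= n_components:
        raise ValueError("need more delay points than components")

    t = cube.delays
    signal = cube.signal
    t_pos = t[t > max(cube.t0, 0.0) + 1e-12]
    if init is None:
        lo = max(cube.irf_fwhm, (t_pos[0] - cube.t0) if len(t_pos) else 0.01, 1e-3)
        hi = max(t[-1], 10 * lo)
        init = np.geomspace(lo, hi, n_components)
    init = np.asarray(init, dtype=float)
    if len(init) != n_components or np.any(init <= 0):
        raise ValueError("init must give one positive lifetime per component")

    def unpack(theta):
        taus = np.exp(theta[:n_components])
        if fit_irf:
            fwhm, t0 = np.exp(theta[n_components]), theta[n_components + 1]
        else:
            fwhm, t0 = cube.irf_fwhm, cube.t0
        return taus, fwhm, t0

    def residuals(theta):
        taus, fwhm, t0 = unpack(theta)
        c = _design_matrix(taus, t0, fwhm, t)
        amps = _solve_amplitudes(c, signal)
        return (signal - c @ amps).ravel()

    theta0 = np.log(init)
    if fit_irf:
        theta0 = np.concatenate([theta0, [np.log(max(cube.irf_fwhm, 1e-3)), cube.t0]])

    res = least_squares(residuals, theta0, method="trf", x_scale="jac", max_nfev=400)
    if not res.success and res.status <= 0:
        raise RuntimeError(f"global fit did not converge: {res.message}")

    taus, fwhm, t0 = unpack(res.x)
    order = np.argsort(taus)
    taus = taus[order]
    c = _design_matrix(taus, t0, fwhm, t)
    das = _solve_amplitudes(c, signal)
    resid = signal - c @ das

    ratios = taus[1:] / taus[:-1]
    degenerate = bool(np.any(ratios < degenerate_ratio))
    if degenerate:
        warnings.warn(
            f"nearly degenerate lifetimes (min ratio {ratios.min():.2f}); "
            "component spectra may be ill-determined"
        )
    return DASResult(
        lifetimes=taus,
        das=das,
        wavelengths=cube.wavelengths,
        residual_norm=float(np.linalg.norm(resid)),
        per_wavelength_residual=np.linalg.norm(resid, axis=0),
        irf_fwhm=fwhm,
        t0=t0,
        success=bool(res.success),
        message=str(res.message),
        degenerate=degenerate,
    )


def report_components(result: DASResult, red_edge_nm: float = 680.0) -> pd.DataFrame:
    """Summarize each component: lifetime, peak wavelength, sign structure.

    Heuristic labels: a component whose red-side and blue-side lobes carry
    opposite signs marks population transfer ("growth at red edge"); a
    nanosecond-scale component peaking on the blue side of ``red_edge_nm`` is
    attributed to long-lived/uncoupled chromophores.
    """
    rows = []
    for tau, spec in zip(result.lifetimes, result.das):
        if len(spec) == 0:
            continue
        peak_idx = int(np.argmax(np.abs(spec)))
        peak_nm = float(result.wavelengths[peak_idx])
        red = spec[result.wavelengths >= red_edge_nm]
        blue = spec[result.wavelengths < red_edge_nm]
        red_sign = np.sign(red[np.argmax(np.abs(red))]) if len(red) else 0.0
        blue_sign = np.sign(blue[np.argmax(np.abs(blue))]) if len(blue) else 0.0
        if tau >= 1000.0 and peak_nm < red_edge_nm:
            label = "long-lived/uncoupled"
        elif red_sign != 0 and blue_sign != 0 and red_sign != blue_sign:
            label = "transfer (growth at red edge)"
        else:
            label = "decay"
        rows.append(
            {
                "lifetime_ps": float(tau),
                "peak_nm": peak_nm,
                "peak_amplitude": float(spec[peak_idx]),
                "red_sign": red_sign,
                "blue_sign": blue_sign,
                "label": label,
            }
        )
    return pd.DataFrame(rows)
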