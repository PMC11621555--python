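"""One-dimensional diffusion from a constant-concentration source.

The lane assay forms its chemical gradient by passive diffusion out of an
agarose reservoir that is large relative to the lane volume, so the source
is modelled as an infinite reservoir holding the boundary at a fixed
concentration C0.  Under Fick's second law in a semi-infinite medium the
concentration a distance x from the barrier after time t is

    C(x, t) = C0 * erfc( x / (2 * sqrt(D * t)) )

with D the diffusion coefficient.  Fitting this form to dye profiles
measured at several times yields D by nonlinear least squares; the same
closed form then predicts the attractant gradient cells experience.

Units follow the field convention: positions in mm and times in hours at
the interface, converted internally to cm and s so D is in cm² s⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import erfc

__all__ = [
    "DiffusionProfile",
    "DiffusionFit",
    "DiffusionFitError",
    "fick_concentration",
    "fit_diffusion_coefficient",
    "read_profile_csv",
    "write_profile_csv",
]

MM_PER_CM = 10.0
S_PER_H = 3600.0


@dataclass
class DiffusionProfile:
    """Concentration (or dye intensity) as a positions x times matrix.

    positions_mm: distances from the source barrier, strictly increasing.
    times_h: sampling times in hours.
    values: array of shape (n_positions, n_times), arbitrary units.
    c0: source value in the same units, if known.
    """

    positions_mm: np.ndarray
    times_h: np.ndarray
    values: np.ndarray
    c0: float | None = None

    def __post_init__(self) -> None:
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.positions_mm < 0):
            raise ValueError("positions must be non-negative")
        if np.any(np.diff(self.positions_mm) <= 0):
            raise ValueError("positions must strictly increase")
        if np.any(self.times_h < 0):
            raise ValueError("times must be non-negative")
        if self.values.shape != (len(self.positions_mm), len(self.times_h)):
            raise ValueError("values must have shape (n_positions, n_times)")


@dataclass
class DiffusionFit:
    """Least-squares estimate of D with fit diagnostics."""

    D: float  # cm^2 s^-1
    c0: float
    residual_sum_squares: float
    r_squared: float
    n_points: int
    c0_was_fit: bool

    def report(self) -> dict:
        return {
            "D_cm2_per_s": self.D,
            "C0": self.c0,
            "residual_sum_squares": self.residual_sum_squares,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "c0_was_fit": self.c0_was_fit,
        }


class DiffusionFitError(RuntimeError):
    """Raised when the diffusion-coefficient fit cannot produce a valid result."""


def fick_concentration(x_mm, t_s, D, c0=1.0):
    """Concentration at distance ``x_mm`` (mm) after ``t_s`` seconds.

    Evaluates C0·erfc(x / (2√(Dt))) with D in cm²·s⁻¹.  At t = 0 the limit
    convention applies: C0 at x = 0, zero elsewhere.  Arrays broadcast.
    """
    x_mm = np.asarray(x_mm, dtype=float)
    t_s = np.asarray(t_s, dtype=float)
    if np.any(x_mm < 0):
        raise ValueError("x must be non-negative")
    if np.any(t_s < 0):
        raise ValueError("t must be non-negative")
    if not np.isfinite(D) or D <= 0:
        raise ValueError("D must be positive and finite")
    x_cm = x_mm / MM_PER_CM
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = np.where(t_s > 0, x_cm / (2.0 * np.sqrt(D * np.where(t_s > 0, t_s, 1.0))), np.inf)
    arg = np.where((t_s == 0) & (x_cm == 0), 0.0, arg)
    out = c0 * erfc(arg)
    if out.ndim == 0:
        return float(out)
    return out


def fit_diffusion_coefficient(
    profile: DiffusionProfile,
    fit_c0: bool = True,
    d0: float = 1e-5,
) -> DiffusionFit:
    """Estimate D (cm²·s⁻¹) from a measured profile time series.

    Nonlinear least squares of the erfc solution against all (x, t) samples
    with t > 0; t = 0 columns are excluded (they only encode the initial
    condition).  D — and C0 when ``fit_c0`` — are optimized in log space,
    which enforces positivity and makes convergence insensitive to scale.
    """
    keep = profile.times_h > 0
    if keep.sum() < 2:
        raise DiffusionFitError("need at least 2 timepoints with t > 0")
    if len(profile.positions_mm) < 5:
        raise DiffusionFitError("need at least 5 positions")
    x = profile.positions_mm
    t_s = profile.times_h[keep] * S_PER_H
    obs = profile.values[:, keep]
    if not np.any(obs != 0):
        raise DiffusionFitError("all-zero profile")

    xg, tg = np.meshgrid(x, t_s, indexing="ij")
    xf, tf, yf = xg.ravel(), tg.ravel(), obs.ravel()

    if fit_c0:
        c0_init = max(float(np.max(yf)), 1e-12)
        p0 = np.log([d0, c0_init])

        def resid(p):
            return fick_concentration(xf, tf, np.exp(p[0]), np.exp(p[1])) - yf

    else:
        if profile.c0 is None:
            raise DiffusionFitError("fit_c0=False requires profile.c0")
        c0_fixed = float(profile.c0)
        p0 = np.log([d0])

        def resid(p):
            return fick_concentration(xf, tf, np.exp(p[0]), c0_fixed) - yf

    sol = least_squares(resid, p0, method="lm", max_nfev=2000)
    if not sol.success or not np.all(np.isfinite(sol.x)):
        raise DiffusionFitError(f"optimizer did not converge: {sol.message}")
    D = float(np.exp(sol.x[0]))
    c0 = float(np.exp(sol.x[1])) if fit_c0 else float(profile.c0)
    rss = float(np.sum(sol.fun**2))
    tss = float(np.sum((yf - yf.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return DiffusionFit(
        D=D,
        c0=c0,
        residual_sum_squares=rss,
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        n_points=len(yf),
        c0_was_fit=fit_c0,
    )


def write_profile_csv(profile: DiffusionProfile, path) -> None:
    """Write a profile as long-format CSV (position_mm, time_h, value)."""
    xg, tg = np.meshgrid(profile.positions_mm, profile.times_h, indexing="ij")
    pd.DataFrame(
        {"position_mm": xg.ravel(), "time_h": tg.ravel(), "value": profile.values.ravel()}
    ).to_csv(path, index=False)


def read_profile_csv(path, c0: float | None = None) -> DiffusionProfile:
    """Read a long-format profile CSV written by :func:`write_profile_csv`."""
    df = pd.read_csv(path)
    for col in ("position_mm", "time_h", "value"):
        if col not in df.columns:
            raise ValueError(f"missing column {col}")
    pos = np.unique(df["position_mm"].to_numpy())
    times = np.unique(df["time_h"].to_numpy())
    mat = (
        df.pivot_table(index="position_mm", columns="time_h", values="value")
        .reindex(index=pos, columns=times)
        .to_numpy()
    )
    return DiffusionProfile(pos, times, mat, c0=c0)
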