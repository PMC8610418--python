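"""Quadratic one-site (ligand-depletion) binding model and Kd fitting.

For a protein P titrated at concentration x into a labeled DNA substrate at
fixed concentration D, the exact single-site equilibrium solution for the
bound fraction — valid when D is comparable to Kd, where the hyperbolic
Langmuir approximation fails — gives the anisotropy signal

    Y(x) = M * ((x + D + Kd) - sqrt((x + D + Kd)^2 - 4*D*x)) / (2*D)

with M the anisotropy amplitude at saturation and Kd the dissociation
constant.  Y(0) = 0 (the signal is baseline-subtracted), Y is monotone
non-decreasing and saturates at M; as D -> 0 the curve converges to
M*x/(x + Kd).  Concentrations are in nM throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize


class FitError(RuntimeError):
    """Nonlinear fit failed to converge; message carries diagnostics."""


def binding_model(x, m: float, d: float, kd: float):
    """Anisotropy at titrant concentration(s) ``x`` (nM).

    ``m``: saturation amplitude; ``d``: labeled substrate concentration (nM);
    ``kd``: dissociation constant (nM).
    """
    if d <= 0:
        raise ValueError("substrate concentration D must be > 0")
    if kd <= 0:
        raise ValueError("Kd must be > 0")
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("titrant concentrations must be >= 0")
    s = x + d + kd
    disc = s * s - 4.0 * d * x
    # algebraically disc = (x - d)^2 + kd^2 + 2 kd (x + d) > 0; guard rounding
    assert (disc >= -1e-9 * s * s).all()
    y = m * (s - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * d)
    return y if y.ndim else float(y)


@dataclass(frozen=True)
class BindingTitration:
    """One replicate titration: anisotropy Y vs titrant concentration x."""

    x: np.ndarray
    y: np.ndarray
    d_conc: float = 5.0
    replicate_id: str = ""
    substrate: str = "unmodified"

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-D and the same length")
        if (x < 0).any() or (np.diff(x) <= 0).any():
            raise ValueError("x must be non-negative and strictly increasing")
        if self.d_conc <= 0:
            raise ValueError("substrate concentration must be > 0")


@dataclass
class ReplicateFit:
    replicate_id: str
    kd: float
    m: float
    offset: float
    residual_rms: float


@dataclass
class BindingFit:
    """Per-replicate (Kd, M) fits and their mean +- SD across replicates."""

    substrate: str
    replicates: list[ReplicateFit]
    kd_mean: float = field(init=False)
    kd_sd: float = field(init=False)
    m_mean: float = field(init=False)
    m_sd: float = field(init=False)

    def __post_init__(self) -> None:
        kds = np.array([r.kd for r in self.replicates])
        ms = np.array([r.m for r in self.replicates])
        self.kd_mean = float(kds.mean())
        self.kd_sd = float(kds.std(ddof=1)) if len(kds) > 1 else 0.0
        self.m_mean = float(ms.mean())
        self.m_sd = float(ms.std(ddof=1)) if len(ms) > 1 else 0.0


def _initial_guesses(t: BindingTitration) -> tuple[float, float]:
    m0 = float(t.y.max())
    if m0 <= 0:
        m0 = 1e-3
    half = m0 / 2.0
    above = np.nonzero(t.y >= half)[0]
    kd0 = float(t.x[above[0]]) if above.size else float(t.x[-1])
    return m0, max(kd0, 1e-3)


def _fit_one(t: BindingTitration, fit_offset: bool) -> ReplicateFit:
    m0, kd0 = _initial_guesses(t)

    if fit_offset:
        def f(x, m, kd, c):
            return binding_model(x, m, t.d_conc, kd) + c
        p0, lo, hi = [m0, kd0, 0.0], [0.0, 1e-9, -np.inf], [np.inf] * 3
    else:
        def f(x, m, kd):
            return binding_model(x, m, t.d_conc, kd)
        p0, lo, hi = [m0, kd0], [0.0, 1e-9], [np.inf] * 2

    try:
        popt, _ = optimize.curve_fit(
            f, t.x, t.y, p0=p0, bounds=(lo, hi), maxfev=20000
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitError(
            f"binding fit failed for replicate {t.replicate_id!r} "
            f"(n={t.x.size}, y range {t.y.min():.3g}..{t.y.max():.3g}): {exc}"
        ) from exc
    resid = t.y - f(t.x, *popt)
    return ReplicateFit(
        replicate_id=t.replicate_id,
        m=float(popt[0]),
        kd=float(popt[1]),
        offset=float(popt[2]) if fit_offset else 0.0,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def fit_binding(
    titrations: list[BindingTitration],
    fit_offset: bool = False,
    pooled: bool = False,
) -> BindingFit:
    """Fit (Kd, M) to one or more replicate titrations.

    Default mode fits each replicate independently and reports the mean +- SD
    of Kd and M across replicates (matching replicate protein preparations);
    ``pooled`` concatenates all points into a single fit.  ``fit_offset``
    adds a free baseline for raw (non-subtracted) anisotropy.
    """
    if not titrations:
        raise ValueError("need >= 1 titration")
    substrates = {t.substrate for t in titrations}
    if len(substrates) > 1:
        raise ValueError(f"mixed substrates in one fit: {sorted(substrates)}")
    for t in titrations:
        if t.x.size < 4:
            raise ValueError(
                f"replicate {t.replicate_id!r}: need >= 4 titration points"
            )
    if pooled:
        order = np.argsort(np.concatenate([t.x for t in titrations]),
                           kind="stable")
        x = np.concatenate([t.x for t in titrations])[order]
        y = np.concatenate([t.y for t in titrations])[order]
        # strictly-increasing x not required for a pooled least-squares fit
        merged = object.__new__(BindingTitration)
        object.__setattr__(merged, "x", x)
        object.__setattr__(merged, "y", y)
        object.__setattr__(merged, "d_conc", titrations[0].d_conc)
        object.__setattr__(merged, "replicate_id", "pooled")
        object.__setattr__(merged, "substrate", titrations[0].substrate)
        fits = [_fit_one(merged, fit_offset)]
    else:
        fits = [_fit_one(t, fit_offset) for t in titrations]
    return BindingFit(substrate=titrations[0].substrate, replicates=fits)


def titrations_from_table(table: pd.DataFrame, d_conc: float = 5.0
                          ) -> dict[str, list[BindingTitration]]:
    """Group a tidy titration table into per-substrate replicate lists.

    Expected columns: replicate, substrate, x_nM, anisotropy.
    """
    required = {"replicate", "substrate", "x_nM", "anisotropy"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out: dict[str, list[BindingTitration]] = {}
    for (sub, rep), grp in table.groupby(["substrate", "replicate"]):
        grp = grp.sort_values("x_nM")
        out.setdefault(sub, []).append(
            BindingTitration(
                x=grp["x_nM"].to_numpy(),
                y=grp["anisotropy"].to_numpy(),
                d_conc=d_conc,
                replicate_id=str(rep),
                substrate=str(sub),
            )
        )
    return out
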