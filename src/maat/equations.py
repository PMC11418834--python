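"""Karplus-type coupling equations: truncated Fourier series J(phi) fitted to
DFT-style (phi, psi, J, energy) grids.

A grid is a :class:`pandas.DataFrame` with columns
``phi, psi, j_hz, energy_rel, distorted`` (degrees, Hz, kcal/mol, bool/0-1) —
the on-disk contract is a CSV with exactly that header. Parameterization
follows the standard protocol for torsional J-surfaces: drop grid structures
above an energy cutoff and structurally distorted ones ("trimmed" equations),
optionally restrict the secondary torsion psi to its experimentally supported
window ("constrained" equations), then least-squares fit

    J(phi) = a0 + sum_n [ a_n cos(n phi) + b_n sin(n phi) ],  n = 1..N.

Residual scatter at fixed phi reflects the secondary psi dependence and is
reported as the fit RMSD in Hz.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "GRID_COLUMNS",
    "CouplingEquation",
    "FourierCouplingRegression",
    "trim_grid",
    "constrain_psi",
    "fit_fourier",
    "evaluate",
    "read_grid",
    "write_grid",
    "load_equations",
    "save_equations",
]

GRID_COLUMNS = ["phi", "psi", "j_hz", "energy_rel", "distorted"]


@dataclass(frozen=True)
class CouplingEquation:
    """Fourier coefficient set mapping phi (degrees) to one J-coupling (Hz).

    ``a`` holds [a0, a1, ..., aN]; ``b`` holds [b1, ..., bN]. Evaluation is
    360-periodic by construction.
    """

    coupling_id: str
    a: tuple
    b: tuple
    variant: str = "trimmed"
    fit_rmsd: float = 0.0
    n_points: int = 0

    def __post_init__(self):
        a = tuple(float(x) for x in self.a)
        b = tuple(float(x) for x in self.b)
        if len(a) < 2 or len(b) != len(a) - 1:
            raise ValueError(
                "need a = [a0..aN] with N >= 1 and b = [b1..bN]"
            )
        if self.variant not in ("trimmed", "constrained", "synthetic"):
            raise ValueError(f"unknown variant {self.variant!r}")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def order(self) -> int:
        return len(self.a) - 1

    def __call__(self, phi):
        return evaluate(self, phi)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["a"] = list(d["a"])
        d["b"] = list(d["b"])
        d["order"] = self.order
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CouplingEquation":
        return cls(
            coupling_id=d["coupling_id"],
            a=d["a"],
            b=d["b"],
            variant=d.get("variant", "trimmed"),
            fit_rmsd=float(d.get("fit_rmsd", 0.0)),
            n_points=int(d.get("n_points", 0)),
        )


def evaluate(equation: CouplingEquation, phi):
    """Evaluate the Fourier series at phi (degrees); vectorized, periodic."""
    phi = np.radians(np.asarray(phi, dtype=float))
    n = np.arange(1, equation.order + 1)
    arg = np.multiply.outer(phi, n)
    out = equation.a[0] + np.cos(arg) @ np.asarray(equation.a[1:])
    out = out + np.sin(arg) @ np.asarray(equation.b)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# grid filtering

def trim_grid(points: pd.DataFrame, cutoff: float = 10.0) -> pd.DataFrame:
    """Drop grid structures above the relative-energy cutoff (kcal/mol) and
    any flagged as structurally distorted."""
    if not cutoff > 0:
        raise ValueError("cutoff must be > 0")
    keep = (points["energy_rel"] <= cutoff) & (
        ~points["distorted"].astype(bool)
    )
    out = points.loc[keep].reset_index(drop=True)
    if out.empty:
        raise ValueError(
            f"no grid points survive the {cutoff} kcal/mol cutoff"
        )
    return out


def constrain_psi(points: pd.DataFrame, window) -> pd.DataFrame:
    """Keep points whose psi lies in the closed window [lo, hi] (degrees),
    under circular containment — windows may cross 0/360."""
    lo, hi = (float(w) for w in window)
    span = (hi - lo) % 360.0
    if span == 0.0 and hi != lo:
        # e.g. [-180, 180): a full turn — keep everything
        return points.reset_index(drop=True)
    rel = (points["psi"] - lo) % 360.0
    keep = (rel <= span) | np.isclose(rel, 360.0)
    out = points.loc[keep].reset_index(drop=True)
    if out.empty:
        raise ValueError(f"no grid points with psi in [{lo}, {hi}]")
    return out


# ---------------------------------------------------------------------------
# Fourier fitting

def _design_matrix(phi_deg: np.ndarray, order: int) -> np.ndarray:
    phi = np.radians(phi_deg)
    n = np.arange(1, order + 1)
    arg = np.multiply.outer(phi, n)
    return np.hstack([np.ones((phi.size, 1)), np.cos(arg), np.sin(arg)])


class FourierCouplingRegression(RegressorMixin, BaseEstimator):
    """Least-squares truncated-Fourier regression of J on a torsion angle.

    scikit-learn estimator: ``fit(X, y)`` with X the torsion angle in degrees
    (shape (n,) or (n, 1)) and y the coupling in Hz.

    Parameters
    ----------
    order : int, default 3
        Number of harmonics N; the model has 2N + 1 coefficients.

    Attributes
    ----------
    a_ : ndarray, (order + 1,)
        Cosine coefficients [a0..aN] (a0 is the circular mean level).
    b_ : ndarray, (order,)
        Sine coefficients [b1..bN].
    rmsd_ : float
        Root-mean-square residual in Hz (denominator n).
    n_points_ : int
    aic_ : float
        Gaussian AIC of the fit, for order selection reports.
    """

    def __init__(self, order: int = 3):
        self.order = order

    def fit(self, X, y):
        phi = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if phi.size != y.size:
            raise ValueError("X and y lengths differ")
        n_coef = 2 * self.order + 1
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if phi.size < n_coef:
            raise ValueError(
                f"need at least {n_coef} points for order {self.order}"
            )
        D = _design_matrix(phi, self.order)
        coef, _, rank, _ = np.linalg.lstsq(D, y, rcond=None)
        if rank < n_coef:
            raise ValueError(
                "rank-deficient design: too few distinct phi values "
                f"for order {self.order}"
            )
        resid = y - D @ coef
        self.a_ = coef[: self.order + 1]
        self.b_ = coef[self.order + 1 :]
        self.rmsd_ = float(np.sqrt(np.mean(resid**2)))
        self.n_points_ = int(phi.size)
        # Gaussian log-likelihood AIC with sigma^2 = mean squared residual
        mse = max(np.mean(resid**2), 1e-300)
        self.aic_ = float(phi.size * np.log(mse) + 2 * (n_coef + 1))
        return self

    def predict(self, X):
        check_is_fitted(self)
        return evaluate(self.to_equation("fit"), np.asarray(X).reshape(-1))

    def to_equation(
        self, coupling_id: str, variant: str = "trimmed"
    ) -> CouplingEquation:
        check_is_fitted(self)
        return CouplingEquation(
            coupling_id=coupling_id,
            a=tuple(self.a_),
            b=tuple(self.b_),
            variant=variant,
            fit_rmsd=self.rmsd_,
            n_points=self.n_points_,
        )


def fit_fourier(
    points: pd.DataFrame,
    order: int = 3,
    coupling_id: str = "J",
    variant: str = "trimmed",
) -> CouplingEquation:
    """Fit a CouplingEquation to a (filtered) grid."""
    reg = FourierCouplingRegression(order=order).fit(
        points["phi"].to_numpy(), points["j_hz"].to_numpy()
    )
    return reg.to_equation(coupling_id, variant)


# ---------------------------------------------------------------------------
# I/O

def read_grid(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in GRID_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"grid file {path} missing columns {missing}")
    df["distorted"] = df["distorted"].astype(bool)
    return df[GRID_COLUMNS]


def write_grid(points: pd.DataFrame, path) -> None:
    out = points[GRID_COLUMNS].copy()
    out["distorted"] = out["distorted"].astype(int)
    out.to_csv(path, index=False)


def load_equations(path) -> list[CouplingEquation]:
    """Read a JSON array of equation records (the transcription format for
    externally parameterized coefficient sets)."""
    with open(path) as fh:
        records = json.load(fh)
    return [CouplingEquation.from_dict(r) for r in records]


def save_equations(equations, path) -> None:
    Path(path).write_text(
        json.dumps([eq.to_dict() for eq in equations], indent=1) + "\n"
    )
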