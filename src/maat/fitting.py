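"""Single-state von Mises fitting of a torsion angle to redundant J-couplings.

Given a set of experimental couplings J_i and torsional equations J_i(phi),
the estimator finds the von Mises distribution p(phi | mu, kappa) whose
ensemble-averaged couplings

    <J_i> = integral J_i(phi) p(phi | mu, kappa) dphi

best match experiment in the root-mean-square sense. For a truncated Fourier
equation the average has the closed form

    <J> = a0 + sum_n A_n(kappa) [a_n cos(n mu) + b_n sin(n mu)],
    A_n(kappa) = I_n(kappa) / I_0(kappa),

which is the default fast path; fixed-grid quadrature of the integral and
Monte-Carlo sampling are provided as independent slow paths.

The search is Monte Carlo multi-start: random (mu, CSD) candidates are scored
with the closed form, the best few are refined by bounded least squares in
(mu, log kappa), and the best refined candidate wins, with ties (< 1e-6 Hz)
broken toward the smaller CSD. The objective is the unweighted RMSD across
couplings in Hz (denominator = number of couplings).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.special import i0e, ive
from sklearn.base import BaseEstimator

from .circular import (
    VonMisesModel,
    canonical_angle,
    csd_from_kappa,
    kappa_from_csd,
)
from .equations import CouplingEquation, evaluate

__all__ = [
    "CouplingMeasurement",
    "FitResult",
    "RmsdProfile",
    "MaatFitter",
    "coupling_kind",
    "expected_j",
    "fit_single_state",
    "fit_group",
    "rmsd_profile",
]

KINDS = ("2JCOC", "2JCCH", "3JCOCC", "3JCOCH")


@dataclass(frozen=True)
class CouplingMeasurement:
    """One experimental J-coupling: signed value in Hz, 1-sigma uncertainty
    (0.1 Hz unless stated), and whether the sign was assumed rather than
    measured."""

    coupling_id: str
    value: float
    sigma: float = 0.1
    sign_assumed: bool = False

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")


@dataclass
class FitResult:
    """Fitted single-state model plus goodness-of-fit diagnostics."""

    model: VonMisesModel
    rmsd: float
    residuals: dict
    n_starts: int
    converged: bool
    group_label: str = "custom"
    sign_flipped: tuple = ()

    @property
    def mu(self) -> float:
        return self.model.mu

    @property
    def mu_signed(self) -> float:
        return self.model.mu_signed

    @property
    def csd(self) -> float:
        return self.model.csd

    def to_dict(self) -> dict:
        return {
            "group": self.group_label,
            "mu_deg": self.model.mu_signed,
            "csd_deg": self.model.csd,
            "kappa": self.model.kappa,
            "rmsd_hz": self.rmsd,
            "residuals_hz": dict(self.residuals),
            "n_starts": self.n_starts,
            "converged": self.converged,
            "sign_flipped": list(self.sign_flipped),
        }


def coupling_kind(coupling_id: str) -> str:
    """Classify a coupling label into one of the four phi-sensitive kinds.

    Accepts either the kind itself ("2JCCH") or a structural label such as
    "2JC1C4" / "3JH1C4" (n-bond pathway plus the two coupled nuclei).
    """
    cid = coupling_id.upper().replace("'", "").replace("_", "")
    if cid in KINDS:
        return cid
    if len(cid) < 2 or not cid[0].isdigit():
        raise ValueError(f"cannot classify coupling id {coupling_id!r}")
    bonds = int(cid[0])
    has_h = "H" in cid[1:].replace("J", "", 1)
    if bonds == 2:
        return "2JCCH" if has_h else "2JCOC"
    if bonds == 3:
        return "3JCOCH" if has_h else "3JCOCC"
    raise ValueError(f"cannot classify coupling id {coupling_id!r}")


# ---------------------------------------------------------------------------
# ensemble-averaged couplings

def _bessel_weights(order: int, kappa) -> np.ndarray:
    """A_n = I_n(kappa)/I_0(kappa) for n = 1..order (columns), broadcast over
    kappa (rows)."""
    kappa = np.atleast_1d(np.asarray(kappa, dtype=float))
    n = np.arange(1, order + 1)
    return ive(n[None, :], kappa[:, None]) / i0e(kappa)[:, None]


def expected_j(
    equation: CouplingEquation,
    model: VonMisesModel,
    method: str = "bessel",
    quad_step: float = 0.5,
    n_draws: int = 1_000_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Distribution-weighted mean coupling <J> in Hz.

    method "bessel" uses the closed form (default); "quadrature" integrates
    J(phi) p(phi) on a fixed grid (default 0.5 deg steps); "sampling" averages
    J over von Mises draws (Monte Carlo oracle; pass an rng for
    reproducibility).
    """
    if method == "bessel":
        w = _bessel_weights(equation.order, model.kappa)[0]
        n = np.arange(1, equation.order + 1)
        mu = np.radians(model.mu)
        val = equation.a[0]
        val += float(w @ (np.asarray(equation.a[1:]) * np.cos(n * mu)))
        val += float(w @ (np.asarray(equation.b) * np.sin(n * mu)))
        return val
    if method == "quadrature":
        phi = np.arange(0.0, 360.0, quad_step)
        p = model.pdf(phi)
        return float(np.sum(evaluate(equation, phi) * p) * quad_step)
    if method == "sampling":
        if rng is None:
            rng = np.random.default_rng()
        draws = model.rvs(n_draws, rng)
        return float(np.mean(evaluate(equation, draws)))
    raise ValueError(f"unknown method {method!r}")


def _pack_equations(equations):
    """Pad coefficient arrays to a common order for vectorized evaluation."""
    order = max(eq.order for eq in equations)
    a0 = np.array([eq.a[0] for eq in equations])
    a = np.zeros((len(equations), order))
    b = np.zeros((len(equations), order))
    for i, eq in enumerate(equations):
        a[i, : eq.order] = eq.a[1:]
        b[i, : eq.order] = eq.b
    return order, a0, a, b


def _rmsd_paired(mu_deg, kappa, equations, y):
    """RMSD (Hz) for paired (mu_i, kappa_i) candidates; shape (n_cand,)."""
    order, a0, a, b = _pack_equations(equations)
    mu = np.radians(np.atleast_1d(np.asarray(mu_deg, dtype=float)))
    n = np.arange(1, order + 1)
    cos_nmu = np.cos(np.multiply.outer(n, mu))  # (order, n_cand)
    sin_nmu = np.sin(np.multiply.outer(n, mu))
    w = _bessel_weights(order, kappa)  # (n_cand, order)
    pred = a0[None, :] + np.einsum("kn,en,nk->ke", w, a, cos_nmu)
    pred += np.einsum("kn,en,nk->ke", w, b, sin_nmu)
    resid = pred - np.asarray(y, dtype=float)[None, :]
    return np.sqrt(np.mean(resid**2, axis=1))


def _rmsd_surface(mu_deg, kappa, equations, y):
    """RMSD (Hz) for every (kappa, mu) pair; shape (len(kappa), len(mu))."""
    order, a0, a, b = _pack_equations(equations)
    mu = np.radians(np.atleast_1d(np.asarray(mu_deg, dtype=float)))
    n = np.arange(1, order + 1)
    cos_nmu = np.cos(np.multiply.outer(n, mu))  # (order, n_mu)
    sin_nmu = np.sin(np.multiply.outer(n, mu))
    w = _bessel_weights(order, kappa)  # (n_kappa, order)
    # predicted couplings: (n_kappa, n_eq, n_mu)
    pred = a0[None, :, None] + np.einsum("kn,en,nm->kem", w, a, cos_nmu)
    pred += np.einsum("kn,en,nm->kem", w, b, sin_nmu)
    resid = pred - np.asarray(y, dtype=float)[None, :, None]
    return np.sqrt(np.mean(resid**2, axis=1))


# ---------------------------------------------------------------------------
# the estimator

class MaatFitter(BaseEstimator):
    """Fit a single-state von Mises model of a torsion angle to redundant
    experimental J-couplings by RMSD minimization.

    scikit-learn style: ``fit(X, y)`` where X is a list of
    :class:`CouplingEquation` (the "design") and y the experimental couplings
    in Hz, one per equation. ``predict(X)`` returns the ensemble-averaged
    couplings of the fitted model.

    Parameters
    ----------
    n_starts : int, default 200
        Number of random (mu, CSD) Monte Carlo candidates.
    n_refine : int, default 10
        How many of the best-scoring candidates are refined by bounded
        least squares.
    seed : int, default 1234
        RNG seed for the multi-start draws.
    csd_bounds : (float, float), default (1, 120)
        Search bounds on the CSD in degrees. Below ~1 deg the kappa mapping
        saturates; above ~120 deg the model is near-uniform.
    method : {"hybrid", "mc"}, default "hybrid"
        "hybrid" refines the top candidates by least squares; "mc" is a pure
        Monte-Carlo random search (no local refinement).
    mu_bounds : (float, float) or None, default None
        Restrict the mean search to [lo, hi] degrees (span <= 360). None
        searches the full circle. Restricting the mean to a chemically
        motivated window (e.g. the syn region favoured by the exo-anomeric
        effect for glycosidic phi) excludes spurious RMSD minima in regions
        the molecule cannot populate.
    convention : {"circular", "approx"}
        CSD <-> kappa mapping convention.
    try_sign_flip : bool, default True
        For measurements whose sign was assumed, also fit with the sign
        flipped and keep the lower-RMSD branch (flagged in the result).

    Attributes
    ----------
    mu_, csd_, kappa_ : float
        Fitted circular mean (deg, [0, 360)), CSD (deg), concentration.
    rmsd_ : float
        Unweighted RMSD over couplings, Hz.
    residuals_ : ndarray
        J_exp - <J>_model per coupling, Hz.
    model_ : VonMisesModel
    converged_ : bool
    """

    _TIE_TOL = 1e-6  # Hz

    def __init__(
        self,
        n_starts: int = 200,
        n_refine: int = 10,
        seed: int = 1234,
        csd_bounds=(1.0, 120.0),
        method: str = "hybrid",
        convention: str = "circular",
        try_sign_flip: bool = True,
        mu_bounds=None,
    ):
        self.n_starts = n_starts
        self.n_refine = n_refine
        self.seed = seed
        self.csd_bounds = csd_bounds
        self.method = method
        self.convention = convention
        self.try_sign_flip = try_sign_flip
        self.mu_bounds = mu_bounds

    # -- internals ----------------------------------------------------------

    def _kappa_bounds(self):
        lo, hi = self.csd_bounds
        return (
            kappa_from_csd(hi, self.convention),
            kappa_from_csd(lo, self.convention),
        )

    def _fit_one(self, equations, y):
        rng = np.random.default_rng(self.seed)
        k_lo, k_hi = self._kappa_bounds()
        if self.mu_bounds is None:
            mu_lo, mu_hi = -360.0, 720.0
            mu0 = rng.uniform(0.0, 360.0, self.n_starts)
        else:
            mu_lo, mu_hi = (float(m) for m in self.mu_bounds)
            if not 0.0 < mu_hi - mu_lo <= 360.0:
                raise ValueError("mu_bounds span must be in (0, 360]")
            mu0 = rng.uniform(mu_lo, mu_hi, self.n_starts)
        csd0 = rng.uniform(*self.csd_bounds, self.n_starts)
        # monotone interpolation csd -> kappa for scoring the starts
        k_grid = np.geomspace(k_lo, k_hi, 512)
        s_grid = csd_from_kappa(k_grid, self.convention)
        kap0 = np.interp(csd0, s_grid[::-1], k_grid[::-1])
        scores = _rmsd_paired(mu0, kap0, equations, y)
        if self.method == "mc":
            best = self._pick_best(
                np.column_stack([mu0, kap0]), scores
            )
            return best + (True,)
        if self.method != "hybrid":
            raise ValueError(f"unknown method {self.method!r}")

        def resid(x):
            mu, logk = x
            order, a0, a, b = _pack_equations(equations)
            w = _bessel_weights(order, np.exp(logk))[0]
            n = np.arange(1, order + 1)
            murad = np.radians(mu)
            pred = a0 + (a * w) @ np.cos(n * murad) + (b * w) @ np.sin(
                n * murad
            )
            return pred - np.asarray(y, dtype=float)

        top = np.argsort(scores)[: max(1, self.n_refine)]
        cands, vals, ok = [], [], False
        for i in top:
            sol = least_squares(
                resid,
                x0=[mu0[i], np.log(kap0[i])],
                bounds=([mu_lo, np.log(k_lo)], [mu_hi, np.log(k_hi)]),
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
            cands.append([canonical_angle(sol.x[0]), np.exp(sol.x[1])])
            vals.append(float(np.sqrt(np.mean(sol.fun**2))))
            ok = ok or sol.success
        mu_b, kap_b, rmsd_b = self._pick_best(np.array(cands), np.array(vals))
        return mu_b, kap_b, rmsd_b, ok

    def _pick_best(self, cands, vals):
        """Best RMSD; among near-ties prefer the smaller CSD (larger kappa)."""
        best = float(np.min(vals))
        tied = np.flatnonzero(vals <= best + self._TIE_TOL)
        i = tied[np.argmax(cands[tied, 1])]
        return float(cands[i, 0]), float(cands[i, 1]), float(vals[i])

    # -- API ----------------------------------------------------------------

    def fit(self, X, y, sign_assumed=None):
        """X: sequence of CouplingEquation; y: experimental J values (Hz).

        sign_assumed: optional boolean mask; where true and try_sign_flip is
        on, the fit is repeated with that measurement's sign flipped and the
        lower-RMSD branch kept.
        """
        equations = list(X)
        y = np.asarray(y, dtype=float)
        if len(equations) != y.size:
            raise ValueError("one measurement per equation required")
        if y.size < 2:
            raise ValueError(
                "need >= 2 couplings to constrain the 2-parameter model"
            )
        variants = [(y, ())]
        if self.try_sign_flip and sign_assumed is not None:
            for i in np.flatnonzero(np.asarray(sign_assumed, dtype=bool)):
                flipped = y.copy()
                flipped[i] = -flipped[i]
                variants.append((flipped, (equations[i].coupling_id,)))
        best = None
        for y_v, flipped_ids in variants:
            mu, kap, rmsd, ok = self._fit_one(equations, y_v)
            if best is None or rmsd < best[2] - self._TIE_TOL:
                best = (mu, kap, rmsd, ok, y_v, flipped_ids)
        mu, kap, rmsd, ok, y_used, flipped_ids = best
        self.kappa_ = kap
        self.mu_ = float(canonical_angle(mu))
        self.csd_ = float(csd_from_kappa(kap, self.convention))
        self.model_ = VonMisesModel(mu, self.csd_, self.convention)
        self.residuals_ = y_used - np.array(
            [expected_j(eq, self.model_) for eq in equations]
        )
        self.rmsd_ = rmsd
        self.converged_ = bool(ok)
        self.sign_flipped_ = flipped_ids
        self.equations_ = equations
        return self

    def predict(self, X):
        return np.array([expected_j(eq, self.model_) for eq in X])

    def result(self, group_label: str = "custom") -> FitResult:
        return FitResult(
            model=self.model_,
            rmsd=self.rmsd_,
            residuals={
                eq.coupling_id: float(r)
                for eq, r in zip(self.equations_, self.residuals_)
            },
            n_starts=self.n_starts,
            converged=self.converged_,
            group_label=group_label,
            sign_flipped=tuple(self.sign_flipped_),
        )


# ---------------------------------------------------------------------------
# functional wrappers

def _match_equations(measurements, equations):
    """Resolve each measurement to an equation by id, falling back to the
    coupling kind when that is unambiguous."""
    by_id = {eq.coupling_id: eq for eq in equations}
    by_kind: dict = {}
    for eq in equations:
        by_kind.setdefault(coupling_kind(eq.coupling_id), []).append(eq)
    out = []
    for m in measurements:
        if m.coupling_id in by_id:
            out.append(by_id[m.coupling_id])
            continue
        kind = coupling_kind(m.coupling_id)
        cands = by_kind.get(kind, [])
        if len(cands) != 1:
            raise ValueError(
                f"no unique equation for measurement {m.coupling_id!r}"
            )
        out.append(cands[0])
    return out


def fit_single_state(
    measurements, equations, group_label: str = "custom", **settings
) -> FitResult:
    """Fit a VonMisesModel to a list of CouplingMeasurement given available
    equations (matched by coupling id, or uniquely by kind)."""
    measurements = list(measurements)
    eqs = _match_equations(measurements, equations)
    fitter = MaatFitter(**settings)
    fitter.fit(
        eqs,
        [m.value for m in measurements],
        sign_assumed=[m.sign_assumed for m in measurements],
    )
    return fitter.result(group_label)


GROUPS = {
    "I": ("2JCOC", "3JCOCC", "3JCOCH"),
    "II": ("2JCCH", "3JCOCC", "3JCOCH"),
    "III": ("2JCOC", "2JCCH", "3JCOCC", "3JCOCH"),
}


def fit_group(measurements, group: str, equations, **settings) -> FitResult:
    """Fit one coupling group (I: conventional; II: 2JCCH replaces 2JCOC;
    III: all four)."""
    if group not in GROUPS:
        raise ValueError(f"group must be one of {sorted(GROUPS)}")
    wanted = GROUPS[group]
    by_kind = {coupling_kind(m.coupling_id): m for m in measurements}
    missing = [k for k in wanted if k not in by_kind]
    if missing:
        raise ValueError(
            f"group {group} needs couplings {missing} not present in the "
            "measurement set"
        )
    subset = [by_kind[k] for k in wanted]
    return fit_single_state(subset, equations, group_label=group, **settings)


@dataclass
class RmsdProfile:
    """Dense RMSD evaluation over a rectangular (mu, CSD) grid."""

    mu_grid: np.ndarray
    csd_grid: np.ndarray
    rmsd: np.ndarray  # shape (len(csd_grid), len(mu_grid))

    @property
    def min_rmsd(self) -> float:
        return float(self.rmsd.min())

    @property
    def argmin(self):
        i, j = np.unravel_index(np.argmin(self.rmsd), self.rmsd.shape)
        return float(self.mu_grid[j]), float(self.csd_grid[i])

    def flat_csd_interval(self, tol: float = 0.1):
        """CSD interval over which the mu-minimized RMSD stays within ``tol``
        Hz of the global minimum — the profile's flatness width. A wide
        interval means the coupling set cannot discriminate dispersions."""
        prof = self.rmsd.min(axis=1)
        ok = np.flatnonzero(prof <= self.min_rmsd + tol)
        lo, hi = self.csd_grid[ok[0]], self.csd_grid[ok[-1]]
        return float(lo), float(hi), float(hi - lo)

    def to_frame(self):
        import pandas as pd

        mu, csd = np.meshgrid(self.mu_grid, self.csd_grid)
        return pd.DataFrame(
            {
                "mu_deg": mu.ravel(),
                "csd_deg": csd.ravel(),
                "rmsd_hz": self.rmsd.ravel(),
            }
        )


def rmsd_profile(
    measurements,
    equations,
    mu_step: float = 0.5,
    csd_step: float = 0.5,
    csd_bounds=(1.0, 120.0),
    convention: str = "circular",
) -> RmsdProfile:
    """Brute-force RMSD surface over (mu, CSD); the grid-search oracle for the
    optimizer and the discriminability diagnostic (a flat 2J_COC curve in the
    populated phi region widens the low-RMSD CSD interval)."""
    measurements = list(measurements)
    eqs = _match_equations(measurements, equations)
    y = [m.value for m in measurements]
    mu_grid = np.arange(0.0, 360.0, mu_step)
    csd_grid = np.arange(csd_bounds[0], csd_bounds[1] + 1e-9, csd_step)
    kappas = np.array([kappa_from_csd(s, convention) for s in csd_grid])
    surf = _rmsd_surface(mu_grid, kappas, eqs, y)
    return RmsdProfile(mu_grid=mu_grid, csd_grid=csd_grid, rmsd=surf)
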