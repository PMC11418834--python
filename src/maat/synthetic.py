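"""Synthetic generators for every upstream input of the pipeline.

The analysis consumes three kinds of data it does not produce: DFT-style
(phi, psi, J, energy) grids, experimental coupling sets, and MD dihedral
traces. This module fabricates all three with the statistical structure the
method assumes, so the whole pipeline can be exercised and validated with no
external files.

Truth curves follow the documented torsional behaviour of each coupling kind
across an O-glycosidic linkage:

* ``2JCCH`` (geminal C2'-C1'-H1' pathway) — positive, bimodal, maxima near
  phi = 120 and 300 deg, minima near 0 and 180 deg, peak about +7 Hz.
* ``2JCOC`` (geminal C1'-O1'-Cx) — negative, with a flat plateau around
  -2 to -3 Hz across phi = 0-180 deg; its variation concentrates near 270 deg.
* ``3JCOCH`` / ``3JCOCC`` (vicinal Karplus couplings) — classic
  A cos^2 + B cos + C shape in their own pathway torsion; the C2'-C1'-O1'-Cx
  pathway of 3JCOCC is offset +120 deg from phi (which is defined on H1').

The psi-scatter added by :func:`make_grid` emulates the secondary dependence
of each coupling on the neighbouring torsion; it is larger for the geminal
2JCOC than for the vicinal couplings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.stats import norm, vonmises

from .circular import VonMisesModel, canonical_angle
from .equations import CouplingEquation, FourierCouplingRegression, evaluate
from .fitting import CouplingMeasurement, expected_j

__all__ = [
    "TruthCurveSpec",
    "make_truth_curve",
    "make_grid",
    "make_pseudo_experiment",
    "make_torsion_trace",
    "reference_equation_set",
    "DEFAULT_PSI_SCATTER",
]

# secondary (psi) dependence amplitude per kind, Hz; the geminal COC coupling
# carries the largest secondary dependence
DEFAULT_PSI_SCATTER = {
    "2JCOC": 0.40,
    "2JCCH": 0.20,
    "3JCOCC": 0.15,
    "3JCOCH": 0.15,
}

_FOURIER_ORDER = {"2JCCH": 6, "2JCOC": 5, "3JCOCC": 3, "3JCOCH": 3}


@dataclass(frozen=True)
class TruthCurveSpec:
    """Recipe for one synthetic truth curve.

    ``jitter`` scales the seeded random perturbation of amplitudes (relative)
    and phases (degrees) so that different compounds get slightly different
    but shape-conforming curves.
    """

    coupling_kind: str
    psi_scatter_sd: float | None = None
    jitter: float = 1.0

    def __post_init__(self):
        if self.coupling_kind not in _FOURIER_ORDER:
            raise ValueError(
                f"unknown coupling kind {self.coupling_kind!r}; "
                f"choose from {sorted(_FOURIER_ORDER)}"
            )

    @property
    def scatter_sd(self) -> float:
        if self.psi_scatter_sd is not None:
            return self.psi_scatter_sd
        return DEFAULT_PSI_SCATTER[self.coupling_kind]


def _bump(phi_deg, center_deg, width_kappa):
    """Periodic bump exp(k (cos(phi - c) - 1)), peak 1 at the center."""
    d = np.radians(phi_deg - center_deg)
    return np.exp(width_kappa * (np.cos(d) - 1.0))


def _truth_values(kind: str, rng: np.random.Generator, jitter: float):
    """Closed-form truth curve evaluated on a 1-degree grid."""
    phi = np.arange(0.0, 360.0, 1.0)
    amp = lambda: 1.0 + 0.05 * jitter * rng.uniform(-1, 1)  # noqa: E731
    ph = lambda: 3.0 * jitter * rng.uniform(-1, 1)  # noqa: E731
    if kind == "2JCCH":
        # bimodal, asymmetric about each maximum: rises through ~1-5 Hz
        # across 0-180 with a sharper drop back to the 0/180 minima
        anchors = np.array(
            [0.85, 0.9, 2.6, 5.3, 6.4, 3.0, 0.6, 0.7, 1.1, 3.8, 6.9, 3.2]
        )
        anchor_phi = np.arange(0.0, 360.0, 30.0)
        jit = 1.0 + 0.05 * jitter * rng.uniform(-1, 1, anchors.size)
        spline = CubicSpline(
            np.append(anchor_phi, 360.0),
            np.append(anchors * jit, anchors[0] * jit[0]),
            bc_type="periodic",
        )
        j = spline((phi - ph()) % 360.0)
    elif kind == "2JCOC":
        # plateau near -2.2..-2.9 across 0-180; rises toward ~0 around 270
        j = (
            -2.55
            + 0.35 * amp() * np.cos(np.radians(phi - 15.0 - ph()))
            + 2.4 * amp() * _bump(phi, 270.0 + ph(), 3.0)
        )
    elif kind == "3JCOCH":
        x = np.radians(phi - ph())
        j = 7.0 * amp() * np.cos(x) ** 2 - 1.0 * amp() * np.cos(x) + 0.4
    elif kind == "3JCOCC":
        # pathway torsion (C2'-C1'-O1'-Cx) offset from the H1'-referenced phi
        x = np.radians(phi + 105.0 - ph())
        j = 4.4 * amp() * np.cos(x) ** 2 + 0.2 * amp() * np.cos(x) + 0.2
    else:  # pragma: no cover - guarded by TruthCurveSpec
        raise ValueError(kind)
    return phi, j


def _check_shape(kind: str, eq: CouplingEquation) -> None:
    phi = np.arange(0.0, 360.0, 1.0)
    j = evaluate(eq, phi)
    if kind == "2JCCH":
        if j.min() < -0.05:
            raise AssertionError("2JCCH curve must be non-negative")
        for low in (0.0, 180.0):
            if evaluate(eq, low) >= 1.0:
                raise AssertionError("2JCCH minima at 0/180 must be < 1 Hz")
        for high in (120.0, 300.0):
            if evaluate(eq, high) <= 5.0:
                raise AssertionError("2JCCH maxima at 120/300 must be > 5 Hz")
        if j.max() - j.min() < 4.0:
            raise AssertionError("2JCCH dynamic range must be >= 4 Hz")
    elif kind == "2JCOC":
        if j.max() >= 0.0:
            raise AssertionError("2JCOC curve must be negative-valued")
        slope = np.gradient(j, phi)
        inner = np.abs(slope[(phi >= 20) & (phi <= 160)]).max()
        if inner >= 0.25 * np.abs(slope).max():
            raise AssertionError("2JCOC must be flat across the 0-180 region")


def make_truth_curve(
    spec: TruthCurveSpec | str, seed: int = 0
) -> CouplingEquation:
    """Build a shape-conforming synthetic truth equation for one coupling
    kind. Deterministic in (spec, seed)."""
    if isinstance(spec, str):
        spec = TruthCurveSpec(spec)
    rng = np.random.default_rng(seed)
    kind = spec.coupling_kind
    phi, j = _truth_values(kind, rng, spec.jitter)
    reg = FourierCouplingRegression(order=_FOURIER_ORDER[kind]).fit(phi, j)
    eq = reg.to_equation(kind, variant="synthetic")
    _check_shape(kind, eq)
    return eq


def make_grid(
    equation: CouplingEquation,
    psi_scatter_sd: float = 0.3,
    high_energy_frac: float = 0.2,
    distorted_frac: float = 0.02,
    step: float = 15.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Emulate a DFT torsion grid: a full (phi, psi) matrix at ``step``-degree
    spacing (15 deg -> 24 x 24 = 576 rows) with

    * ``j_hz`` = truth curve + a smooth psi-dependent perturbation whose
      standard deviation over psi is ``psi_scatter_sd`` (Hz),
    * ``energy_rel`` from a generic 2-term periodic surface scaled so that
      ``high_energy_frac`` of the points exceed the 10 kcal/mol cutoff,
    * a random ``distorted_frac`` subset flagged as distorted.
    """
    if psi_scatter_sd < 0:
        raise ValueError("psi_scatter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    axis = np.arange(0.0, 360.0, step)
    phi, psi = (x.ravel() for x in np.meshgrid(axis, axis, indexing="ij"))

    # smooth secondary dependence: two psi harmonics with random phases,
    # normalized so the scatter SD over uniform psi equals psi_scatter_sd
    p1, p2 = rng.uniform(0.0, 360.0, 2)
    mix = rng.uniform(0.3, 0.7)
    raw = mix * np.cos(np.radians(psi - p1)) + (1 - mix) * np.cos(
        2.0 * np.radians(psi - p2)
    )
    scatter_unit_sd = np.sqrt(mix**2 / 2 + (1 - mix) ** 2 / 2)
    j = evaluate(equation, phi) + psi_scatter_sd * raw / scatter_unit_sd

    # torsional strain minimum in the exo-anomeric syn region (phi ~ 60,
    # psi ~ 0); high-energy cells concentrate on the anti side
    shape = (1 - np.cos(np.radians(phi - 60.0))) + 0.8 * (
        1 - np.cos(np.radians(psi))
    )
    if 0 < high_energy_frac < 1:
        scale = 10.0 / np.quantile(shape, 1.0 - high_energy_frac)
    else:
        scale = 1.0
    energy = scale * shape

    distorted = rng.random(phi.size) < distorted_frac
    return pd.DataFrame(
        {
            "phi": phi,
            "psi": psi,
            "j_hz": j,
            "energy_rel": energy,
            "distorted": distorted,
        }
    )


def make_pseudo_experiment(
    truth_model: VonMisesModel,
    equations,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> list[CouplingMeasurement]:
    """Pseudo-experimental couplings: the ensemble average of each equation
    under the planted torsion model plus Gaussian measurement noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for eq in equations:
        value = expected_j(eq, truth_model) + rng.normal(0.0, noise_sd)
        out.append(
            CouplingMeasurement(
                eq.coupling_id, float(value), sigma=max(noise_sd, 0.1)
            )
        )
    return out


def make_torsion_trace(
    model: VonMisesModel,
    n_frames: int,
    autocorr: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """MD-like dihedral series (degrees, [0, 360)).

    Frames are drawn from the model's von Mises marginal; ``autocorr`` adds
    AR(1) frame-to-frame correlation through a Gaussian copula, leaving the
    marginal distribution exact.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if not 0.0 <= autocorr < 1.0:
        raise ValueError("autocorr must be in [0, 1)")
    rng = np.random.default_rng(seed)
    if autocorr == 0.0:
        return model.rvs(n_frames, rng)
    z = np.empty(n_frames)
    z[0] = rng.standard_normal()
    innov = rng.standard_normal(n_frames - 1) * np.sqrt(1 - autocorr**2)
    for t in range(1, n_frames):
        z[t] = autocorr * z[t - 1] + innov[t - 1]
    u = norm.cdf(z)
    theta = vonmises.ppf(u, kappa=model.kappa, loc=np.radians(model.mu))
    return canonical_angle(np.degrees(theta))


def reference_equation_set(
    seed: int = 0, psi_scatter_sd: float | None = None
) -> list[CouplingEquation]:
    """One shape-conforming truth equation per coupling kind, seeded
    per kind; the default equation set for synthetic analyses."""
    out = []
    for i, kind in enumerate(sorted(_FOURIER_ORDER)):
        spec = TruthCurveSpec(kind, psi_scatter_sd=psi_scatter_sd)
        out.append(make_truth_curve(spec, seed=seed * 13 + i))
    return out
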