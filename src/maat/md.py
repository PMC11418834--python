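"""Summaries of MD dihedral trajectories and fitted-model vs MD overlays.

The package never runs MD; the contract is a plain-text dihedral series
(CSV with header ``frame,angle_deg``) extracted upstream from a trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circular import canonical_angle, circular_summary, vonmises_pdf
from .fitting import FitResult

__all__ = [
    "TorsionTrace",
    "read_torsion_trace",
    "write_torsion_trace",
    "md_summary",
    "overlay_table",
]


@dataclass
class TorsionTrace:
    """A single-torsion time series; angles canonicalized to [0, 360)."""

    angles: np.ndarray
    frame_interval: float = 1.0  # metadata only (e.g. ps per frame)
    torsion_label: str = "phi"

    def __post_init__(self):
        a = canonical_angle(np.asarray(self.angles, dtype=float)).reshape(-1)
        if a.size == 0:
            raise ValueError("empty torsion trace")
        self.angles = a

    def __len__(self) -> int:
        return self.angles.size


def read_torsion_trace(path, torsion_label: str = "phi") -> TorsionTrace:
    """Parse a ``frame,angle_deg`` CSV; malformed rows are reported with
    their line numbers."""
    df = pd.read_csv(path)
    if "angle_deg" not in df.columns:
        raise ValueError(f"{path}: expected columns 'frame,angle_deg'")
    angles = pd.to_numeric(df["angle_deg"], errors="coerce")
    bad = np.flatnonzero(angles.isna().to_numpy())
    if bad.size:
        # +2: 1-based line numbers plus the header line
        lines = ", ".join(str(i + 2) for i in bad[:10])
        raise ValueError(f"{path}: non-numeric angle on line(s) {lines}")
    if angles.empty:
        raise ValueError(f"{path}: no frames")
    return TorsionTrace(angles.to_numpy(), torsion_label=torsion_label)


def write_torsion_trace(trace: TorsionTrace, path) -> None:
    pd.DataFrame(
        {"frame": np.arange(len(trace)), "angle_deg": trace.angles}
    ).to_csv(path, index=False)


def md_summary(trace: TorsionTrace, convention: str = "circular"):
    """Circular mean and CSD (degrees) of the trajectory; ``convention``
    "linear" instead reports the linear SD of angles unwrapped about the
    circular mean."""
    if len(trace) < 2:
        raise ValueError("need at least 2 frames")
    return circular_summary(trace.angles, convention=convention)


def overlay_table(
    fit: FitResult, trace: TorsionTrace, bin_width: float = 5.0
) -> pd.DataFrame:
    """Density overlay of the fitted model on the MD histogram.

    Returns a table of (phi bin center, fitted von Mises density, MD histogram
    density), both columns in probability per degree; each integrates to 1
    over the circle (the model column is renormalized on the bin grid so that
    the discretized overlay is exactly comparable to the histogram).
    """
    if not np.isclose(360.0 / bin_width, round(360.0 / bin_width)):
        raise ValueError("bin_width must divide 360")
    edges = np.arange(0.0, 360.0 + bin_width, bin_width)
    md_density, _ = np.histogram(trace.angles, bins=edges, density=True)
    centers = edges[:-1] + bin_width / 2.0
    model_density = vonmises_pdf(centers, fit.model)
    model_density = model_density / (model_density.sum() * bin_width)
    return pd.DataFrame(
        {
            "phi": centers,
            "maat_density": model_density,
            "md_density": md_density,
        }
    )
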