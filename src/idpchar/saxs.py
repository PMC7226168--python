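"""Small-angle scattering analysis of conformational ensembles and curves.

Theoretical curves from coordinates by the Debye double sum over
point scatterers at the CA positions, Guinier fitting restricted to
qRg <= 0.8 (the regime appropriate for flexible chains), the Kratky
transform, real-space pair-distance distributions P(r) with Dmax and
moments, and 3-column text curve I/O.

Momentum transfer q is in inverse Angstrom, distances in Angstrom;
intensities are in arbitrary units (I(0) = (sum of form factors)^2).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .ensembles import Conformation, Ensemble


class CurveFormatError(ValueError):
    """Malformed scattering-curve text file."""


@dataclass(frozen=True)
class ScatteringCurve:
    """A 1-D scattering curve: q grid, intensities, optional uncertainties."""

    q: np.ndarray  # 1/Angstrom, strictly increasing, non-negative
    I: np.ndarray
    sigma: Optional[np.ndarray] = None
    comments: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        I = np.asarray(self.I, dtype=float)
        if q.shape != I.shape or q.ndim != 1:
            raise ValueError("q and I must be 1-D arrays of equal length")
        if np.any(q < 0):
            raise ValueError("q must be non-negative")
        if np.any(np.diff(q) <= 0):
            raise ValueError("q must be strictly increasing")
        if not np.all(np.isfinite(I)):
            raise ValueError("intensities must be finite")
        sigma = self.sigma
        if sigma is not None:
            sigma = np.asarray(sigma, dtype=float)
            if sigma.shape != q.shape or np.any(sigma <= 0):
                raise ValueError("sigma must be positive and match q in length")
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "I", I)
        object.__setattr__(self, "sigma", sigma)

    def __len__(self) -> int:
        return self.q.size


def _ensemble_sites(x: Union[Conformation, Ensemble]) -> tuple[np.ndarray, np.ndarray]:
    """(frames, weights) of CA site coordinates, frames shape (F, N, 3)."""
    if isinstance(x, Conformation):
        return x.ca[None], np.array([1.0])
    return x.ca, x.weights


def debye_curve(
    ensemble: Union[Conformation, Ensemble],
    q_grid: np.ndarray,
    form_factors: Optional[np.ndarray] = None,
) -> ScatteringCurve:
    """Ensemble-averaged Debye scattering curve over CA point scatterers.

    I(q) = sum_ij f_i f_j sin(q r_ij)/(q r_ij), averaged over frames with
    the ensemble weights.  ``form_factors`` are per-residue weights (unit by
    default), q-independent: the point-scatterer reduction of an all-atom
    continuum calculation.  I(0) = (sum_i f_i)^2 exactly.
    """
    q = np.asarray(q_grid, dtype=float)
    if np.any(q < 0):
        raise ValueError("q values must be non-negative")
    frames, weights = _ensemble_sites(ensemble)
    n_sites = frames.shape[1]
    f = (
        np.ones(n_sites)
        if form_factors is None
        else np.asarray(form_factors, dtype=float)
    )
    if f.shape != (n_sites,):
        raise ValueError("form_factors must have one entry per residue site")
    ii, jj = np.triu_indices(n_sites, k=1)
    ff = f[ii] * f[jj]
    self_term = np.dot(f, f)
    intensity = np.zeros_like(q)
    for frame, w in zip(frames, weights):
        r = np.linalg.norm(frame[ii] - frame[jj], axis=1)
        qr = np.outer(q, r)
        intensity += w * (self_term + 2.0 * np.sinc(qr / np.pi) @ ff)
    return ScatteringCurve(q, intensity)


# ---------------------------------------------------------------------------
# Pair-distance distribution
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairDistanceDistribution:
    """Binned P(r): bin centers, normalized densities, Dmax."""

    r: np.ndarray  # bin centers, Angstrom
    P: np.ndarray  # densities, integral 1
    Dmax: float
    bin_width: float

    def rg(self) -> float:
        """Rg from the second moment: Rg^2 = Integral r^2 P(r) dr / 2."""
        return float(np.sqrt(np.sum(self.r**2 * self.P) * self.bin_width / 2.0))


def pr_from_coordinates(
    ensemble: Union[Conformation, Ensemble], bin_width: float = 0.5
) -> PairDistanceDistribution:
    """Pair-distance distribution of all inter-site distances.

    Distances between all CA-site pairs are pooled over frames (frame
    weights respected), histogrammed at ``bin_width`` and normalized to unit
    integral.  Dmax is the upper edge of the largest occupied bin.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    frames, weights = _ensemble_sites(ensemble)
    n = frames.shape[1]
    ii, jj = np.triu_indices(n, k=1)
    all_d = np.linalg.norm(frames[:, ii] - frames[:, jj], axis=2)
    w = np.repeat(weights, ii.size)
    d = all_d.ravel()
    n_bins = int(np.ceil(d.max() / bin_width)) + 1
    edges = np.arange(0.0, (n_bins + 0.5) * bin_width, bin_width)
    counts, _ = np.histogram(d, bins=edges, weights=w)
    density = counts / (counts.sum() * bin_width)
    occupied = np.flatnonzero(counts)
    dmax = float(edges[occupied[-1] + 1])
    centers = 0.5 * (edges[:-1] + edges[1:])
    return PairDistanceDistribution(centers, density, dmax, bin_width)


# ---------------------------------------------------------------------------
# Guinier analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GuinierFit:
    """Result of an iterative low-q Guinier fit, ln I = ln I0 - q^2 Rg^2/3."""

    rg: float  # Angstrom
    I0: float
    q_range_used: tuple[float, float]
    n_points: int
    qrg_limit: float
    residual_rms: float  # rms of ln-I residuals over the final window

    @property
    def rg_nm(self) -> float:
        return self.rg / 10.0

    @property
    def q_max_rg(self) -> float:
        return self.q_range_used[1] * self.rg


def guinier_fit(
    curve: ScatteringCurve,
    qrg_limit: float = 0.8,
    min_points: int = 5,
    initial_points: int = 15,
    max_iter: int = 100,
) -> GuinierFit:
    """Iterative Guinier fit restricted to q_max * Rg <= ``qrg_limit``.

    Starting from the lowest ``initial_points`` points, ln I is fit
    against q^2 (weighted least squares when uncertainties are present),
    the window is shrunk from the high-q side until the limit holds and Rg
    is stable within 1%.  A positive ln-I slope (Rg^2 < 0) or window
    exhaustion is an error.
    """
    mask = curve.I > 0
    q = curve.q[mask]
    I = curve.I[mask]
    sigma = None if curve.sigma is None else curve.sigma[mask]
    if q.size < min_points:
        raise ValueError("not enough positive-intensity points for a Guinier fit")
    n_window = min(initial_points, q.size)
    rg_prev = None
    for _ in range(max_iter):
        if n_window < min_points:
            raise ValueError(
                f"Guinier window shrank below {min_points} points before "
                f"q_max*Rg <= {qrg_limit} was reached"
            )
        x = q[:n_window] ** 2
        y = np.log(I[:n_window])
        w = None if sigma is None else (I[:n_window] / sigma[:n_window]) ** 2
        coeffs = np.polyfit(x, y, 1, w=None if w is None else np.sqrt(w))
        slope, intercept = coeffs[0], coeffs[1]
        if slope >= 0:
            raise ValueError("non-negative Guinier slope: Rg^2 < 0 (no decay at low q)")
        rg = float(np.sqrt(-3.0 * slope))
        if q[n_window - 1] * rg > qrg_limit:
            n_window -= 1
            rg_prev = None
            continue
        if rg_prev is not None and abs(rg - rg_prev) <= 0.01 * rg_prev:
            break
        rg_prev = rg
    resid = np.log(I[:n_window]) - (intercept + slope * q[:n_window] ** 2)
    return GuinierFit(
        rg=rg,
        I0=float(np.exp(intercept)),
        q_range_used=(float(q[0]), float(q[n_window - 1])),
        n_points=n_window,
        qrg_limit=qrg_limit,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def kratky_transform(curve: ScatteringCurve) -> ScatteringCurve:
    """Pointwise Kratky transform (q, q^2 I(q)); no smoothing.

    Globular particles peak and decay; flexible extended chains rise to a
    non-decaying plateau at high q — the classic disorder signature.
    """
    return ScatteringCurve(
        curve.q,
        curve.q**2 * curve.I,
        sigma=None if curve.sigma is None else curve.q**2 * curve.sigma,
        comments=curve.comments + ("kratky transform",),
    )


# ---------------------------------------------------------------------------
# Curve I/O
# ---------------------------------------------------------------------------


def read_curve(path) -> ScatteringCurve:
    """Read a whitespace-separated 2- or 3-column text curve (q, I[, sigma]).

    '#'-prefixed lines are preserved as comments; non-numeric rows are
    reported with their line numbers.
    """
    comments: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            if text.startswith("#"):
                comments.append(text.lstrip("#").strip())
                continue
            parts = text.split()
            if len(parts) not in (2, 3):
                raise CurveFormatError(
                    f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                raise CurveFormatError(
                    f"{path}:{lineno}: non-numeric value in {text!r}"
                ) from None
    if not rows:
        raise CurveFormatError(f"{path}: no data rows")
    n_cols = {len(r) for r in rows}
    if len(n_cols) != 1:
        raise CurveFormatError(f"{path}: inconsistent column counts {sorted(n_cols)}")
    data = np.array(rows)
    sigma = data[:, 2] if data.shape[1] == 3 else None
    try:
        return ScatteringCurve(data[:, 0], data[:, 1], sigma, tuple(comments))
    except ValueError as err:
        raise CurveFormatError(f"{path}: {err}") from err


def write_curve(path, curve: ScatteringCurve) -> None:
    """Write a curve as 3-column (or 2-column) text with '#' comments."""
    path = Path(path)
    with open(path, "w") as fh:
        for c in curve.comments:
            fh.write(f"# {c}\n")
        fh.write("# q(1/A)  I  sigma\n" if curve.sigma is not None else "# q(1/A)  I\n")
        for i in range(len(curve)):
            if curve.sigma is not None:
                fh.write(
                    f"{curve.q[i]:.8e} {curve.I[i]:.8e} {curve.sigma[i]:.8e}\n"
                )
            else:
                fh.write(f"{curve.q[i]:.8e} {curve.I[i]:.8e}\n")
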