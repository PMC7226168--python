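"""Circular-dichroism spectra: unit conversion and basis decomposition.

Observed ellipticities (deg) are converted to mean residue molar ellipticity

    theta_MRE = theta_obs * mrw / (10 * l * c)

with mrw the mean residue weight (Da), l the path length (cm) and c the
concentration (g/mL); theta_MRE is in deg cm^2 dmol^-1.  A generic
constrained least-squares decomposition against labelled reference spectra
(weights on the probability simplex) provides secondary-structure-style
fitting against any basis set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
from scipy.optimize import minimize

from .properties import WATER_MASS, get_scale
from .sequence import PeptideSequence

UNITS_OBSERVED = "observed_deg"
UNITS_MRE = "mean_residue_deg_cm2_dmol"


@dataclass(frozen=True)
class CDSpectrum:
    """A CD spectrum with explicit units and conversion metadata.

    ``metadata`` may carry ``path_length_cm``, ``concentration_g_per_ml``
    and ``mean_residue_weight`` — all three are required for unit
    conversion.
    """

    wavelength: np.ndarray  # nm, monotone
    ellipticity: np.ndarray
    units: str = UNITS_OBSERVED
    metadata: Mapping[str, float] = field(default_factory=dict)
    label: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength, dtype=float)
        el = np.asarray(self.ellipticity, dtype=float)
        if wl.shape != el.shape or wl.ndim != 1:
            raise ValueError("wavelength and ellipticity must match in length")
        d = np.diff(wl)
        if wl.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavelength grid must be monotone")
        if self.units not in (UNITS_OBSERVED, UNITS_MRE):
            raise ValueError(f"unknown units tag {self.units!r}")
        object.__setattr__(self, "wavelength", wl)
        object.__setattr__(self, "ellipticity", el)
        object.__setattr__(self, "metadata", dict(self.metadata))

    def __len__(self) -> int:
        return self.wavelength.size

    def _conversion_factor(self) -> float:
        try:
            mrw = self.metadata["mean_residue_weight"]
            l = self.metadata["path_length_cm"]
            c = self.metadata["concentration_g_per_ml"]
        except KeyError as missing:
            raise ValueError(
                f"conversion metadata missing: {missing}"
            ) from None
        if mrw <= 0 or l <= 0 or c <= 0:
            raise ValueError("mrw, path length and concentration must be positive")
        return mrw / (10.0 * l * c)


def to_mean_residue_ellipticity(spectrum: CDSpectrum) -> CDSpectrum:
    """Convert observed ellipticity (deg) to mean residue molar ellipticity."""
    if spectrum.units != UNITS_OBSERVED:
        raise ValueError(f"expected observed units, got {spectrum.units!r}")
    factor = spectrum._conversion_factor()
    return replace(
        spectrum, ellipticity=spectrum.ellipticity * factor, units=UNITS_MRE
    )


def to_observed_ellipticity(spectrum: CDSpectrum) -> CDSpectrum:
    """Exact inverse of :func:`to_mean_residue_ellipticity`."""
    if spectrum.units != UNITS_MRE:
        raise ValueError(f"expected mean-residue units, got {spectrum.units!r}")
    factor = spectrum._conversion_factor()
    return replace(
        spectrum, ellipticity=spectrum.ellipticity / factor, units=UNITS_OBSERVED
    )


def mean_residue_weight(seq: PeptideSequence, convention: str = "per_bond") -> float:
    """Mean residue weight in Da: Mw/(N-1) (per-bond) or Mw/N (per-residue).

    The per-bond convention (number of peptide bonds as denominator) is the
    common one in CD practice and the default.
    """
    masses = get_scale("average_residue_mass")
    mw = sum(masses[aa] for aa in seq) + WATER_MASS
    n = len(seq)
    if convention == "per_bond":
        if n < 2:
            return mw
        return mw / (n - 1)
    if convention == "per_residue":
        return mw / n
    raise ValueError(f"unknown mrw convention {convention!r}")


# ---------------------------------------------------------------------------
# Constrained basis decomposition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DecompositionResult:
    """Simplex-constrained least-squares fit of a spectrum to a basis."""

    weights: Mapping[str, float]  # non-negative, sum to 1
    fitted: np.ndarray
    residual_rms: float
    wavelength: np.ndarray


def decompose_spectrum(
    spectrum: CDSpectrum,
    basis: Mapping[str, CDSpectrum],
    fit_range: Optional[tuple[float, float]] = None,
) -> DecompositionResult:
    """Fit a spectrum as a convex combination of labelled basis spectra.

    Solves min ||sum_k w_k B_k - y||^2 subject to w_k >= 0 and
    sum_k w_k = 1.  Basis spectra are linearly interpolated onto the
    target wavelength grid; ``fit_range`` (nm) restricts the fitted window.
    Wavelengths outside every basis spectrum's support are an error.
    """
    if not basis:
        raise ValueError("empty basis")
    wl = spectrum.wavelength
    mask = np.ones(wl.size, dtype=bool)
    if fit_range is not None:
        lo, hi = sorted(fit_range)
        mask &= (wl >= lo) & (wl <= hi)
    for b in basis.values():
        mask &= (wl >= b.wavelength.min()) & (wl <= b.wavelength.max())
    if mask.sum() < len(basis):
        raise ValueError("wavelength ranges of target and basis do not overlap enough")
    grid = wl[mask]
    y = spectrum.ellipticity[mask]
    labels = list(basis)
    B = np.column_stack(
        [
            np.interp(grid, *_ascending(basis[k].wavelength, basis[k].ellipticity))
            for k in labels
        ]
    )
    k = len(labels)
    w0 = np.full(k, 1.0 / k)
    res = minimize(
        lambda w: float(np.sum((B @ w - y) ** 2)),
        w0,
        jac=lambda w: 2.0 * B.T @ (B @ w - y),
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-14},
    )
    w = np.clip(res.x, 0.0, None)
    w = w / w.sum()
    fitted = B @ w
    return DecompositionResult(
        weights={k: float(v) for k, v in zip(labels, w)},
        fitted=fitted,
        residual_rms=float(np.sqrt(np.mean((fitted - y) ** 2))),
        wavelength=grid,
    )


def _ascending(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if x.size > 1 and x[0] > x[-1]:
        return x[::-1], y[::-1]
    return x, y


# ---------------------------------------------------------------------------
# 2-column text I/O with metadata headers
# ---------------------------------------------------------------------------

_META_KEYS = {
    "path_length_cm",
    "concentration_g_per_ml",
    "mean_residue_weight",
}


def read_spectrum(path, units: str = UNITS_OBSERVED) -> CDSpectrum:
    """Read a 2-column (wavelength nm, ellipticity) text spectrum.

    '#' header lines of the form ``# key = value`` populate the conversion
    metadata (keys: path_length_cm, concentration_g_per_ml,
    mean_residue_weight).
    """
    meta: dict[str, float] = {}
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            if text.startswith("#"):
                body = text.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    key = key.strip()
                    if key in _META_KEYS:
                        meta[key] = float(val.strip())
                continue
            parts = text.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            rows.append([float(p) for p in parts])
    data = np.array(rows)
    return CDSpectrum(data[:, 0], data[:, 1], units=units, metadata=meta,
                      label=Path(path).stem)


def write_spectrum(path, spectrum: CDSpectrum) -> None:
    with open(path, "w") as fh:
        fh.write(f"# units = {spectrum.units}\n")
        for key in sorted(_META_KEYS & set(spectrum.metadata)):
            fh.write(f"# {key} = {spectrum.metadata[key]!r}\n")
        for wl, el in zip(spectrum.wavelength, spectrum.ellipticity):
            fh.write(f"{wl:.4f} {el:.8e}\n")
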