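"""Structural observables on conformational ensembles.

Radius of gyration and end-to-end distance, residue-residue distance and
contact maps, a PPII-aware dihedral-window secondary-structure classifier,
Ramachandran statistics, Kabsch superposition RMSD, greedy neighbor-count
(GROMOS-style) clustering, time-series convergence diagnostics
(autocorrelation, block-averaged errors) and backbone PCA.

Coordinates are Angstrom throughout; report layers convert Rg/Ree to nm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

from .ensembles import CapabilityError, Conformation, Ensemble
from .properties import get_scale

# Average atomic masses of the backbone atoms, Da.
_ATOM_MASS = {"N": 14.007, "CA": 12.011, "C": 12.011, "O": 15.999}

SS_LABELS = ("H", "E", "P", "T", "C")

# Dihedral windows of the classifier, degrees.  E is checked before P so the
# overlap region goes to E.
_H_PHI, _H_PSI = (-100.0, -30.0), (-80.0, -5.0)
_E_PHI = (-180.0, -90.0)
_P_PHI, _P_PSI = (-110.0, -40.0), (120.0, 180.0)
_TURN_CA_DIST = 7.0  # CA(i)-CA(i+3) below this marks a chain reversal


def _as_ensemble(x: Union[Conformation, Ensemble]) -> Ensemble:
    if isinstance(x, Ensemble):
        return x
    return Ensemble(
        x.coords[None], x.sequence, x.atom_names,
        dihedrals=None if x.dihedrals is None else x.dihedrals[None],
    )


def _site_weights(ens: Ensemble, weighting: str) -> np.ndarray:
    """Per-site weights, flattened over (residue, atom)."""
    n_sites = ens.n_residues * len(ens.atom_names)
    if weighting == "uniform":
        return np.ones(n_sites)
    if weighting != "mass":
        raise ValueError(f"unknown weighting {weighting!r}")
    if ens.atom_names == ("CA",):
        # coarse-grained: each site carries its residue's average mass
        masses = get_scale("average_residue_mass")
        return np.array([masses[aa] for aa in ens.sequence])
    per_atom = np.array([_ATOM_MASS[a] for a in ens.atom_names])
    return np.tile(per_atom, ens.n_residues)


def radius_of_gyration(
    x: Union[Conformation, Ensemble], weighting: str = "mass"
) -> Union[float, np.ndarray]:
    """Radius of gyration in Angstrom, per frame.

    Rg^2 = sum_i w_i |r_i - rbar|^2 / sum_i w_i over all sites (backbone
    atoms, or CA beads for coarse chains).  ``weighting`` is "mass"
    (default; atomic masses, or residue masses for CA-only chains) or
    "uniform".  Returns a scalar for a single conformation, an array of
    per-frame values for an ensemble.
    """
    ens = _as_ensemble(x)
    w = _site_weights(ens, weighting)
    flat = ens.coords.reshape(len(ens), -1, 3)
    if flat.shape[1] == 0:
        raise ValueError("empty frame")
    com = np.average(flat, axis=1, weights=w)
    sq = ((flat - com[:, None, :]) ** 2).sum(axis=2)
    rg = np.sqrt(np.average(sq, axis=1, weights=w))
    return float(rg[0]) if isinstance(x, Conformation) else rg


def end_to_end(x: Union[Conformation, Ensemble]) -> Union[float, np.ndarray]:
    """Distance between the first and last residue CA, Angstrom, per frame."""
    ens = _as_ensemble(x)
    if ens.n_residues < 2:
        raise ValueError("end-to-end distance needs at least 2 residues")
    ca = ens.ca
    ree = np.linalg.norm(ca[:, -1] - ca[:, 0], axis=1)
    return float(ree[0]) if isinstance(x, Conformation) else ree


def ensemble_stats(values: np.ndarray, weights: Optional[np.ndarray] = None):
    """Weighted mean and standard deviation of a per-frame observable."""
    mean = np.average(values, weights=weights)
    var = np.average((values - mean) ** 2, weights=weights)
    return float(mean), float(np.sqrt(var))


# ---------------------------------------------------------------------------
# Distance and contact maps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistanceMap:
    """Residue-residue distances in Angstrom (symmetric, zero diagonal)."""

    matrix: np.ndarray
    reduction: str  # "single_frame" | "ensemble_mean"
    definition: str  # "min_backbone_atom" | "ca_only"


@dataclass(frozen=True)
class ContactMap:
    """Residue-residue contact probabilities in [0, 1]."""

    matrix: np.ndarray
    cutoff: float
    neighbor_exclusion: int


def _frame_min_distances(coords: np.ndarray) -> np.ndarray:
    """Per-residue-pair minimum atom distance for one frame (R, A, 3)."""
    n_res, n_atoms, _ = coords.shape
    flat = coords.reshape(n_res * n_atoms, 3)
    d = cdist(flat, flat)
    d = d.reshape(n_res, n_atoms, n_res, n_atoms)
    return d.min(axis=(1, 3))


def distance_map(
    x: Union[Conformation, Ensemble], definition: str = "min_backbone_atom"
) -> DistanceMap:
    """Residue-pair distance matrix.

    ``min_backbone_atom``: minimum pairwise distance over the backbone atoms
    of the two residues (requires backbone atoms); ``ca_only``: CA-CA
    distance.  For an ensemble, per-frame maps are averaged with the frame
    weights.
    """
    ens = _as_ensemble(x)
    if definition == "ca_only":
        ca = ens.ca
        maps = np.linalg.norm(ca[:, :, None, :] - ca[:, None, :, :], axis=-1)
    elif definition == "min_backbone_atom":
        if not ens.has_backbone:
            raise CapabilityError(
                "min_backbone_atom distances need backbone atoms; "
                "this ensemble is CA-only (use definition='ca_only')"
            )
        maps = np.stack([_frame_min_distances(f) for f in ens.coords])
    else:
        raise ValueError(f"unknown distance definition {definition!r}")
    if isinstance(x, Conformation):
        return DistanceMap(maps[0], "single_frame", definition)
    mean = np.average(maps, axis=0, weights=ens.weights)
    return DistanceMap(mean, "ensemble_mean", definition)


def contact_map(
    ensemble: Union[Conformation, Ensemble],
    cutoff: float = 4.0,
    neighbor_exclusion: int = 2,
) -> ContactMap:
    """Probability that residue pairs are closer than ``cutoff`` Angstrom.

    Distances are residue-pair minima over backbone atoms (CA-CA for
    CA-only chains).  The band |i - j| <= ``neighbor_exclusion`` (each
    residue with itself and its sequence neighbours) is excluded and forced
    to zero.
    """
    ens = _as_ensemble(ensemble)
    definition = "min_backbone_atom" if ens.has_backbone else "ca_only"
    if definition == "ca_only":
        ca = ens.ca
        dists = np.linalg.norm(ca[:, :, None, :] - ca[:, None, :, :], axis=-1)
    else:
        dists = np.stack([_frame_min_distances(f) for f in ens.coords])
    prob = np.average(dists < cutoff, axis=0, weights=ens.weights)
    n = ens.n_residues
    ii, jj = np.indices((n, n))
    prob[np.abs(ii - jj) <= neighbor_exclusion] = 0.0
    return ContactMap(prob, cutoff, neighbor_exclusion)


# ---------------------------------------------------------------------------
# Secondary structure and Ramachandran statistics
# ---------------------------------------------------------------------------


def _ensemble_phi_psi(ens: Ensemble) -> np.ndarray:
    if not ens.has_backbone:
        raise CapabilityError("dihedral analysis needs N, CA, C atoms")
    return np.stack([conf.phi_psi() for conf in ens])


@dataclass(frozen=True)
class SecondaryStructureAssignment:
    """Per-frame, per-residue labels in {H, E, P, T, C} + ensemble fractions."""

    labels: np.ndarray  # (n_frames, n_residues) of single characters
    weights: np.ndarray

    def fractions(self, exclude_terminal: bool = False) -> dict[str, float]:
        """Weighted fraction of residues per label (sums to 1)."""
        lab = self.labels[:, 1:-1] if exclude_terminal else self.labels
        out = {}
        for label in SS_LABELS:
            out[label] = float(
                np.average((lab == label).mean(axis=1), weights=self.weights)
            )
        return out

    def per_residue_fractions(self) -> dict[str, np.ndarray]:
        return {
            label: np.average(self.labels == label, axis=0, weights=self.weights)
            for label in SS_LABELS
        }


def _in_window(x: float, lo: float, hi: float) -> bool:
    return lo < x < hi


def _classify_residue(phi: float, psi: float) -> Optional[str]:
    if np.isnan(phi) or np.isnan(psi):
        return None
    if _in_window(phi, *_E_PHI) and (90.0 < psi <= 180.0 or -180.0 <= psi < -170.0):
        return "E"
    if _in_window(phi, *_H_PHI) and _in_window(psi, *_H_PSI):
        return "H"
    if _in_window(phi, *_P_PHI) and _in_window(psi, *_P_PSI):
        return "P"
    return None


def assign_secondary_structure(
    x: Union[Conformation, Ensemble]
) -> SecondaryStructureAssignment:
    """PPII-aware dihedral-window secondary-structure assignment.

    Residues fall into helix (H), extended/beta (E) or polyproline II (P)
    windows on (phi, psi); the extended window is checked first where it
    overlaps the PPII one.  H/E/P require runs of at least two consecutive
    in-window residues (singletons fall back to coil).  Residues at a chain
    reversal (CA(i)-CA(i+3) < 7 A) not already assigned become turn (T);
    terminal residues and everything else are coil (C).
    """
    ens = _as_ensemble(x)
    phi_psi = _ensemble_phi_psi(ens)
    n_frames, n_res = phi_psi.shape[:2]
    labels = np.full((n_frames, n_res), "C", dtype="U1")
    ca = ens.ca
    for f in range(n_frames):
        raw = [
            _classify_residue(phi_psi[f, i, 0], phi_psi[f, i, 1])
            for i in range(n_res)
        ]
        raw[0] = raw[-1] = None  # terminal residues are coil
        # enforce runs >= 2 for H/E/P
        i = 0
        while i < n_res:
            if raw[i] is None:
                i += 1
                continue
            j = i
            while j < n_res and raw[j] == raw[i]:
                j += 1
            if j - i >= 2:
                labels[f, i:j] = raw[i]
            i = j
        # turns at chain reversals
        for i in range(n_res - 3):
            if np.linalg.norm(ca[f, i + 3] - ca[f, i]) < _TURN_CA_DIST:
                for k in range(i, i + 4):
                    if labels[f, k] == "C" and 0 < k < n_res - 1:
                        labels[f, k] = "T"
    return SecondaryStructureAssignment(labels, ens.weights)


@dataclass(frozen=True)
class RamachandranHistogram:
    counts: np.ndarray  # (n_phi_bins, n_psi_bins)
    phi_edges: np.ndarray
    psi_edges: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def modal_bin(self) -> tuple[tuple[float, float], tuple[float, float]]:
        """(phi interval, psi interval) of the most populated bin."""
        i, j = np.unravel_index(np.argmax(self.counts), self.counts.shape)
        return (
            (self.phi_edges[i], self.phi_edges[i + 1]),
            (self.psi_edges[j], self.psi_edges[j + 1]),
        )


def ramachandran_histogram(
    x: Union[Conformation, Ensemble], bin: float = 10.0
) -> RamachandranHistogram:
    """2-D (phi, psi) counts over interior residues and all frames.

    The total count equals n_frames * (n_residues - 2); the bin width must
    divide 360.
    """
    if bin <= 0 or abs(360.0 / bin - round(360.0 / bin)) > 1e-9:
        raise ValueError(f"bin width {bin} does not divide 360")
    ens = _as_ensemble(x)
    phi_psi = _ensemble_phi_psi(ens)[:, 1:-1, :]
    edges = np.arange(-180.0, 180.0 + bin / 2, bin)
    counts, _, _ = np.histogram2d(
        phi_psi[..., 0].ravel(), phi_psi[..., 1].ravel(), bins=(edges, edges)
    )
    return RamachandranHistogram(counts, edges, edges)


# ---------------------------------------------------------------------------
# Superposition, RMSD and clustering
# ---------------------------------------------------------------------------


def _selection_coords(conf: Conformation, atoms: Sequence[str]) -> np.ndarray:
    missing = [a for a in atoms if a not in conf.atom_names]
    if missing:
        raise CapabilityError(f"conformation lacks atoms {missing}")
    idx = [conf.atom_names.index(a) for a in atoms]
    return conf.coords[:, idx, :].reshape(-1, 3)


def _default_rmsd_atoms(ens_or_conf) -> tuple[str, ...]:
    names = ens_or_conf.atom_names
    return ("N", "CA", "C") if all(a in names for a in ("N", "CA", "C")) else ("CA",)


def kabsch_rmsd(
    conf_a: Conformation,
    conf_b: Conformation,
    atoms: Optional[Sequence[str]] = None,
) -> float:
    """Least-squares optimal-rotation RMSD in Angstrom.

    Centroids are removed, the proper rotation (det = +1) minimizing the
    residual is found, and the root-mean-square deviation of the superposed
    selections (backbone N, CA, C by default) is returned.  Collinear
    selections are rejected as degenerate.
    """
    atoms = tuple(atoms) if atoms is not None else _default_rmsd_atoms(conf_a)
    a = _selection_coords(conf_a, atoms)
    b = _selection_coords(conf_b, atoms)
    if a.shape != b.shape:
        raise ValueError("selections have different atom counts")
    if a.shape[0] < 3:
        raise ValueError("RMSD superposition needs at least 3 atoms")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    if np.linalg.matrix_rank(a, tol=1e-8) < 2 or np.linalg.matrix_rank(b, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) atom selection")
    _, rssd = Rotation.align_vectors(a, b)
    return float(rssd / np.sqrt(a.shape[0]))


def pairwise_rmsd_matrix(
    ensemble: Ensemble, atoms: Optional[Sequence[str]] = None
) -> np.ndarray:
    """Symmetric matrix of pairwise Kabsch RMSD values (Angstrom)."""
    n = len(ensemble)
    out = np.zeros((n, n))
    confs = [ensemble[i] for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = kabsch_rmsd(confs[i], confs[j], atoms)
    return out


@dataclass(frozen=True)
class ClusteringResult:
    """Greedy RMSD clustering: assignments, populations, representatives."""

    cutoff: float
    assignment: np.ndarray  # frame -> cluster id (0-based, by rank)
    populations: tuple[float, ...]  # percentages, descending
    representatives: tuple[int, ...]  # central frame index per cluster

    @property
    def n_clusters(self) -> int:
        return len(self.populations)


def gromos_cluster(
    ensemble: Ensemble,
    cutoff: float,
    atoms: Optional[Sequence[str]] = None,
    rmsd_matrix: Optional[np.ndarray] = None,
) -> ClusteringResult:
    """Greedy neighbor-count clustering under a pairwise RMSD cutoff.

    Iteratively the frame with the most neighbours (pairwise RMSD <=
    cutoff) among the unassigned frames becomes the next cluster's
    representative; it and its neighbours are assigned and removed.  Ties
    are broken by the lowest frame index.  Populations are percentages of
    total frame weight, clusters ordered by descending population.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = len(ensemble)
    d = rmsd_matrix if rmsd_matrix is not None else pairwise_rmsd_matrix(ensemble, atoms)
    neighbor = d <= cutoff
    np.fill_diagonal(neighbor, True)
    remaining = np.ones(n, dtype=bool)
    assignment = np.full(n, -1)
    clusters: list[tuple[float, int, np.ndarray]] = []
    while remaining.any():
        counts = (neighbor & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(neighbor[center] & remaining)
        pop = float(ensemble.weights[members].sum() * 100.0)
        clusters.append((pop, center, members))
        remaining[members] = False
    clusters.sort(key=lambda c: -c[0])
    for rank, (_, _, members) in enumerate(clusters):
        assignment[members] = rank
    return ClusteringResult(
        cutoff=cutoff,
        assignment=assignment,
        populations=tuple(c[0] for c in clusters),
        representatives=tuple(c[1] for c in clusters),
    )


# ---------------------------------------------------------------------------
# Convergence diagnostics and PCA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SeriesDiagnostics:
    """Autocorrelation and block-averaged standard errors of a series."""

    lags: np.ndarray
    acf: np.ndarray
    block_sizes: np.ndarray
    block_se: np.ndarray
    name: str = ""


def series_diagnostics(series: np.ndarray, name: str = "") -> SeriesDiagnostics:
    """Normalized autocorrelation and block-averaging error estimates.

    The ACF is normalized to ACF(0) = 1 (defined as 1, with 0 elsewhere,
    for a constant series).  Block standard errors are computed over
    doubling block sizes; for uncorrelated data they are flat, for
    correlated data they grow towards the true standard error.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("series too short for diagnostics (need >= 4)")
    xc = x - x.mean()
    denom = np.dot(xc, xc)
    max_lag = n // 2
    lags = np.arange(max_lag + 1)
    if denom == 0.0:
        acf = np.zeros(max_lag + 1)
        acf[0] = 1.0
    else:
        full = np.correlate(xc, xc, mode="full")[n - 1 :]
        acf = full[: max_lag + 1] / denom
    sizes, errors = [], []
    bs = 1
    while bs <= n // 2:
        nb = n // bs
        blocks = x[: nb * bs].reshape(nb, bs).mean(axis=1)
        se = blocks.std(ddof=1) / np.sqrt(nb) if nb > 1 else 0.0
        sizes.append(bs)
        errors.append(se)
        bs *= 2
    return SeriesDiagnostics(
        lags=lags,
        acf=acf,
        block_sizes=np.array(sizes),
        block_se=np.array(errors),
        name=name,
    )


@dataclass(frozen=True)
class PCAResult:
    projections: np.ndarray  # (n_frames, n_components)
    explained_variance_ratio: np.ndarray


def _superpose_to_mean(ens: Ensemble, atoms: Sequence[str], n_iter: int = 3):
    idx = [ens.atom_names.index(a) for a in atoms]
    frames = ens.coords[:, :, idx, :].reshape(len(ens), -1, 3)
    frames = frames - frames.mean(axis=1, keepdims=True)
    mean = frames[0].copy()
    for _ in range(n_iter):
        aligned = np.empty_like(frames)
        for f in range(frames.shape[0]):
            rot, _ = Rotation.align_vectors(mean, frames[f])
            aligned[f] = rot.apply(frames[f])
        mean = np.average(aligned, axis=0, weights=ens.weights)
        frames = aligned
    return frames


def pca_backbone(
    ensemble: Ensemble,
    n_components: int = 2,
    atoms: Optional[Sequence[str]] = None,
) -> PCAResult:
    """PCA of superposed backbone coordinates.

    Frames are iteratively superposed (Kabsch) onto the ensemble-mean
    structure before the coordinate covariance is diagonalized; components
    are ordered by explained variance.
    """
    if len(ensemble) < 2:
        raise ValueError("PCA needs at least 2 frames")
    atoms = tuple(atoms) if atoms is not None else _default_rmsd_atoms(ensemble)
    frames = _superpose_to_mean(ensemble, atoms)
    flat = frames.reshape(len(ensemble), -1)
    pca = PCA(n_components=min(n_components, min(flat.shape) - 1))
    proj = pca.fit_transform(flat)
    return PCAResult(
        projections=proj,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )
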