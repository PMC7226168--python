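"""Synthetic conformational ensembles of disordered peptides.

This module generates backbone ensembles that stand in for an MD trajectory:
chains are built residue by residue in internal coordinates (fixed ideal
bond lengths and angles, trans peptide bonds) from per-residue (phi, psi)
dihedrals drawn from named Ramachandran basins — alpha-helix, polyproline II,
extended beta and a broad coil basin — with tunable mixture weights, short
segment-wise basin persistence, and excluded-volume rejection.  Ideal
freely-jointed chains with closed-form chain statistics are provided as an
analytic test harness.  Ensembles round-trip through multi-model PDB.

All coordinates are in Angstrom; dihedrals in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Iterator, Mapping, Optional, Sequence as TypingSequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from biotite.sequence import ProteinSequence

from .sequence import PeptideSequence

# Ideal trans-peptide backbone geometry (Angstrom, degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA_TRANS = 180.0

BACKBONE_ATOMS = ("N", "CA", "C", "O")
_ATOM_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O"}


class EnsembleFormatError(ValueError):
    """Malformed ensemble file or inconsistent models."""


class CapabilityError(ValueError):
    """The requested analysis needs atoms the ensemble does not carry."""


# ---------------------------------------------------------------------------
# Geometry primitives
# ---------------------------------------------------------------------------


def _place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Position atom d with |cd| = bond, angle(b,c,d) and torsion(a,b,c,d).

    The standard internal-coordinate (NeRF) construction; angles in degrees.
    """
    ang = math.radians(angle)
    tor = math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle of four points in degrees, in (-180, 180]."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return math.degrees(math.atan2(y, x))


def backbone_dihedrals(coords: np.ndarray) -> np.ndarray:
    """(phi, psi) per residue from backbone coordinates, NaN where undefined.

    ``coords`` has shape (n_res, >=3, 3) with atoms ordered N, CA, C.
    """
    n_res = coords.shape[0]
    out = np.full((n_res, 2), np.nan)
    N, CA, C = coords[:, 0], coords[:, 1], coords[:, 2]
    for i in range(n_res):
        if i > 0:
            out[i, 0] = dihedral(C[i - 1], N[i], CA[i], C[i])
        if i < n_res - 1:
            out[i, 1] = dihedral(N[i], CA[i], C[i], N[i + 1])
    return out


# ---------------------------------------------------------------------------
# Conformation / Ensemble containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Conformation:
    """Backbone (or CA-only) coordinates of one structure.

    ``coords`` has shape (n_residues, n_atoms, 3) in Angstrom with atoms
    ordered as in ``atom_names``.
    """

    coords: np.ndarray
    sequence: PeptideSequence
    atom_names: tuple[str, ...] = BACKBONE_ATOMS
    dihedrals: Optional[np.ndarray] = None  # (n_res, 2) degrees, NaN at ends

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (len(self.sequence), len(self.atom_names), 3):
            raise ValueError(
                f"coords shape {c.shape} does not match "
                f"{len(self.sequence)} residues x {len(self.atom_names)} atoms"
            )
        object.__setattr__(self, "coords", c)

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]

    @property
    def has_backbone(self) -> bool:
        return all(a in self.atom_names for a in ("N", "CA", "C"))

    @property
    def ca(self) -> np.ndarray:
        """CA coordinates, shape (n_residues, 3)."""
        return self.coords[:, self.atom_names.index("CA"), :]

    def phi_psi(self) -> np.ndarray:
        """Recompute (phi, psi) in degrees from the coordinates."""
        if not self.has_backbone:
            raise CapabilityError("dihedrals require N, CA, C atoms")
        idx = [self.atom_names.index(a) for a in ("N", "CA", "C")]
        return backbone_dihedrals(self.coords[:, idx, :])


@dataclass(frozen=True)
class Ensemble:
    """Ordered, optionally weighted collection of conformations.

    ``coords`` has shape (n_frames, n_residues, n_atoms, 3); weights are
    normalized to sum to one.  ``provenance`` records generator parameters
    and the seed.
    """

    coords: np.ndarray
    sequence: PeptideSequence
    atom_names: tuple[str, ...] = BACKBONE_ATOMS
    weights: Optional[np.ndarray] = None
    dihedrals: Optional[np.ndarray] = None  # (n_frames, n_res, 2)
    provenance: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 4 or c.shape[1:] != (len(self.sequence), len(self.atom_names), 3):
            raise ValueError(f"bad ensemble coords shape {c.shape}")
        object.__setattr__(self, "coords", c)
        w = self.weights
        if w is None:
            w = np.full(c.shape[0], 1.0 / c.shape[0])
        else:
            w = np.asarray(w, dtype=float)
            if w.shape != (c.shape[0],) or np.any(w < 0):
                raise ValueError("weights must be non-negative, one per frame")
            w = w / w.sum()
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "provenance", MappingProxyType(dict(self.provenance)))

    def __len__(self) -> int:
        return self.coords.shape[0]

    def __getitem__(self, i: int) -> Conformation:
        return Conformation(
            self.coords[i],
            self.sequence,
            self.atom_names,
            None if self.dihedrals is None else self.dihedrals[i],
        )

    def __iter__(self) -> Iterator[Conformation]:
        return (self[i] for i in range(len(self)))

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]

    @property
    def has_backbone(self) -> bool:
        return all(a in self.atom_names for a in ("N", "CA", "C"))

    @property
    def ca(self) -> np.ndarray:
        """CA coordinates, shape (n_frames, n_residues, 3)."""
        return self.coords[:, :, self.atom_names.index("CA"), :]

    @classmethod
    def from_conformations(
        cls, confs: TypingSequence[Conformation], **kwargs
    ) -> "Ensemble":
        if not confs:
            raise ValueError("empty conformation list")
        seq = confs[0].sequence
        names = confs[0].atom_names
        if any(c.sequence.residues != seq.residues or c.atom_names != names for c in confs):
            raise ValueError("all conformations must share one sequence and atom set")
        dih = None
        if all(c.dihedrals is not None for c in confs):
            dih = np.stack([c.dihedrals for c in confs])
        return cls(
            np.stack([c.coords for c in confs]), seq, names, dihedrals=dih, **kwargs
        )


# ---------------------------------------------------------------------------
# Backbone construction
# ---------------------------------------------------------------------------


def build_backbone(
    seq: PeptideSequence, dihedrals: TypingSequence
) -> Conformation:
    """Build backbone N/CA/C/O coordinates from per-residue (phi, psi).

    Deterministic internal-coordinate chain construction with ideal bond
    geometry and trans peptide bonds (omega = 180).  ``dihedrals`` is one
    (phi, psi) pair per residue in degrees; phi of the first and psi of the
    last residue are undefined and may be ``None``.  The first residue is
    placed in a canonical frame (N at the origin, CA on +x, C in the
    xy-plane).
    """
    n = len(seq)
    if len(dihedrals) != n:
        raise ValueError(
            f"need {n} (phi, psi) pairs, got {len(dihedrals)}"
        )
    phi = np.empty(n)
    psi = np.empty(n)
    for i, pair in enumerate(dihedrals):
        if pair is None or len(pair) != 2:
            raise ValueError(f"malformed dihedral entry at residue {i + 1}")
        p, s = pair
        phi[i] = 180.0 if p is None else float(p)
        psi[i] = 180.0 if s is None else float(s)

    coords = np.empty((n, 4, 3))
    # canonical frame for residue 1
    coords[0, 0] = (0.0, 0.0, 0.0)
    coords[0, 1] = (BOND_N_CA, 0.0, 0.0)
    ang = math.radians(ANGLE_N_CA_C)
    coords[0, 2] = coords[0, 1] + BOND_CA_C * np.array(
        [-math.cos(ang), math.sin(ang), 0.0]
    )
    for i in range(n - 1):
        N_i, CA_i, C_i = coords[i, 0], coords[i, 1], coords[i, 2]
        N_next = _place_atom(N_i, CA_i, C_i, BOND_C_N, ANGLE_CA_C_N, psi[i])
        CA_next = _place_atom(CA_i, C_i, N_next, BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS)
        C_next = _place_atom(C_i, N_next, CA_next, BOND_CA_C, ANGLE_N_CA_C, phi[i + 1])
        coords[i + 1, 0], coords[i + 1, 1], coords[i + 1, 2] = N_next, CA_next, C_next
        # carbonyl O anti to the next amide N
        coords[i, 3] = _place_atom(N_i, CA_i, C_i, BOND_C_O, ANGLE_CA_C_O, psi[i] + 180.0)
    coords[n - 1, 3] = _place_atom(
        coords[n - 1, 0], coords[n - 1, 1], coords[n - 1, 2],
        BOND_C_O, ANGLE_CA_C_O, psi[n - 1] + 180.0,
    )
    stored = np.column_stack([phi, psi]).astype(float)
    stored[0, 0] = np.nan
    stored[n - 1, 1] = np.nan
    return Conformation(coords, seq, BACKBONE_ATOMS, dihedrals=stored)


# ---------------------------------------------------------------------------
# Basin mixtures and stochastic sampling
# ---------------------------------------------------------------------------

#: Canonical Ramachandran basins: name -> ((phi, psi) mean, (phi, psi) std).
STANDARD_BASINS: Mapping[str, tuple[tuple[float, float], tuple[float, float]]] = (
    MappingProxyType(
        {
            "helix": ((-57.0, -47.0), (8.0, 8.0)),
            "ppii": ((-75.0, 145.0), (8.0, 8.0)),
            "beta": ((-120.0, 130.0), (10.0, 10.0)),
            "coil": ((-85.0, 75.0), (35.0, 70.0)),
        }
    )
)


@dataclass(frozen=True)
class BasinMixture:
    """Weighted mixture of named (phi, psi) basins.

    Weights are normalized; every mixture carries at least the four standard
    basins (weights may be zero).  ``mean_run_length`` is the expected length
    (residues) of same-basin segments: basins are drawn per contiguous
    segment rather than per residue, giving the short conformational
    persistence real chains show and keeping secondary-structure stretches
    long enough to be assigned.
    """

    weights: Mapping[str, float]
    basins: Mapping[str, tuple[tuple[float, float], tuple[float, float]]] = field(
        default_factory=lambda: STANDARD_BASINS
    )
    mean_run_length: float = 6.0

    def __post_init__(self) -> None:
        basins = dict(STANDARD_BASINS)
        basins.update(self.basins)
        unknown = set(self.weights) - set(basins)
        if unknown:
            raise ValueError(f"weights for unknown basins: {sorted(unknown)}")
        w = {name: float(self.weights.get(name, 0.0)) for name in basins}
        total = sum(w.values())
        if total <= 0 or any(v < 0 for v in w.values()):
            raise ValueError("basin weights must be non-negative with positive sum")
        w = {k: v / total for k, v in w.items()}
        if self.mean_run_length < 1:
            raise ValueError("mean_run_length must be >= 1")
        object.__setattr__(self, "weights", MappingProxyType(w))
        object.__setattr__(self, "basins", MappingProxyType(basins))


#: Default generator conditions: a disordered, extended ensemble dominated by
#: PPII and extended-beta basins with negligible helix, qualitatively the
#: composition reported for disordered peptides of this kind.
DEFAULT_DISORDERED_MIXTURE = BasinMixture(
    weights={"ppii": 0.40, "beta": 0.25, "helix": 0.05, "coil": 0.30}
)


def _sample_frame_dihedrals(
    rng: np.random.Generator, n_res: int, mixture: BasinMixture
) -> np.ndarray:
    names = list(mixture.weights)
    probs = np.array([mixture.weights[b] for b in names])
    p_end = 1.0 / mixture.mean_run_length
    out = np.empty((n_res, 2))
    i = 0
    while i < n_res:
        length = min(int(rng.geometric(p_end)), n_res - i)  # support {1, 2, ...}
        basin = names[rng.choice(len(names), p=probs)]
        (mp, ms), (sp, ss) = mixture.basins[basin]
        out[i : i + length, 0] = rng.normal(mp, sp, size=length)
        out[i : i + length, 1] = rng.normal(ms, ss, size=length)
        i += length
    # wrap into (-180, 180]
    out = (out + 180.0) % 360.0 - 180.0
    return out


def _has_clash(ca: np.ndarray, clash_distance: float) -> bool:
    """Any nonbonded CA pair (|i - j| >= 3) closer than ``clash_distance``?"""
    n = ca.shape[0]
    if n < 4:
        return False
    d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
    ii, jj = np.triu_indices(n, k=3)
    return bool(np.any(d[ii, jj] < clash_distance))


def sample_ensemble(
    seq: PeptideSequence,
    mixture: Optional[BasinMixture] = None,
    n_frames: int = 500,
    seed: int = 0,
    clash_distance: float = 3.0,
) -> Ensemble:
    """Sample a backbone ensemble from a Ramachandran basin mixture.

    Each frame draws same-basin segments (geometric lengths, expected
    ``mixture.mean_run_length``) along the chain, samples (phi, psi) from the
    segment's basin, builds the backbone, and rejects frames containing any
    nonbonded CA pair (|i - j| >= 3) closer than ``clash_distance``.
    Identical (parameters, seed) give identical ensembles.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    mixture = mixture or DEFAULT_DISORDERED_MIXTURE
    rng = np.random.default_rng(seed)
    confs: list[Conformation] = []
    attempts = 0
    while len(confs) < n_frames:
        attempts += 1
        if attempts > max(1000, 100 * n_frames):
            raise RuntimeError(
                "rejection rate above 99%: infeasible generator parameters "
                f"(accepted {len(confs)} of {attempts} attempts)"
            )
        dih = _sample_frame_dihedrals(rng, len(seq), mixture)
        conf = build_backbone(seq, [tuple(pair) for pair in dih])
        if _has_clash(conf.ca, clash_distance):
            continue
        confs.append(conf)
    return Ensemble.from_conformations(
        confs,
        provenance={
            "generator": "basin_mixture",
            "seed": seed,
            "n_frames": n_frames,
            "clash_distance": clash_distance,
            "mean_run_length": mixture.mean_run_length,
            "weights": dict(mixture.weights),
            "attempts": attempts,
        },
    )


def fjc_ensemble(
    n_beads: int, bond: float = 3.8, n_frames: int = 1000, seed: int = 0
) -> Ensemble:
    """Freely-jointed chain ensemble (CA-only sites, i.i.d. bond directions).

    The analytic harness: <Ree^2> = (N-1) b^2 and
    <Rg^2> = b^2 (N^2 - 1) / (6 N) in closed form for N beads of equal
    weight.  The chain carries a poly-glycine sequence so that every
    coarse-grained site has the same mass.
    """
    if n_beads < 2:
        raise ValueError("n_beads must be >= 2")
    rng = np.random.default_rng(seed)
    steps = rng.normal(size=(n_frames, n_beads - 1, 3))
    steps *= bond / np.linalg.norm(steps, axis=-1, keepdims=True)
    pos = np.concatenate(
        [np.zeros((n_frames, 1, 3)), np.cumsum(steps, axis=1)], axis=1
    )
    seq = PeptideSequence("G" * n_beads, name=f"fjc{n_beads}")
    return Ensemble(
        pos[:, :, None, :],
        seq,
        atom_names=("CA",),
        provenance={
            "generator": "fjc",
            "seed": seed,
            "n_beads": n_beads,
            "bond": bond,
            "n_frames": n_frames,
        },
    )


# ---------------------------------------------------------------------------
# Multi-model PDB I/O
# ---------------------------------------------------------------------------


def write_ensemble(path, ensemble: Ensemble) -> None:
    """Write an ensemble as multi-model PDB (MODEL/ENDMDL, chain A)."""
    n_res = ensemble.n_residues
    n_atoms_per_res = len(ensemble.atom_names)
    n_atoms = n_res * n_atoms_per_res
    template = struc.AtomArray(n_atoms)
    template.chain_id[:] = "A"
    template.res_id[:] = np.repeat(np.arange(1, n_res + 1), n_atoms_per_res)
    template.res_name[:] = np.repeat(
        [ProteinSequence.convert_letter_1to3(aa) for aa in ensemble.sequence.residues],
        n_atoms_per_res,
    )
    template.atom_name[:] = np.tile(ensemble.atom_names, n_res)
    template.element[:] = np.tile(
        [_ATOM_ELEMENTS.get(a, a[0]) for a in ensemble.atom_names], n_res
    )
    template.hetero[:] = False
    pdb = PDBFile()
    if len(ensemble) == 1:  # single structure: plain PDB without MODEL records
        template.coord = ensemble.coords.reshape(n_atoms, 3)
        pdb.set_structure(template)
    else:
        pdb.set_structure(
            struc.from_template(
                template, ensemble.coords.reshape(len(ensemble), n_atoms, 3)
            )
        )
    pdb.write(str(path))


def read_ensemble(path) -> Ensemble:
    """Read a (multi-model) PDB file into an :class:`Ensemble`.

    A file without MODEL records yields a single-frame ensemble.  Atom
    layout is detected: full backbone (N, CA, C, O), backbone without
    carbonyl O, or CA-only traces; anything else — including models that
    disagree in their atoms or residues — is rejected.
    """
    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None)
    except Exception as err:
        raise EnsembleFormatError(f"cannot parse PDB file {path}: {err}") from err
    stack = stack[:, struc.filter_amino_acids(stack)]
    if stack.array_length() == 0:
        raise EnsembleFormatError(f"no amino-acid atoms in {path}")

    res_ids = stack.res_id
    order = np.argsort(res_ids, kind="stable")
    unique_ids = np.unique(res_ids)
    present = {
        name
        for name in BACKBONE_ATOMS
        if all(
            np.any((res_ids == rid) & (stack.atom_name == name)) for rid in unique_ids
        )
    }
    if {"N", "CA", "C", "O"} <= present:
        atom_names = BACKBONE_ATOMS
    elif {"N", "CA", "C"} <= present:
        atom_names = ("N", "CA", "C")
    elif "CA" in present:
        atom_names = ("CA",)
    else:
        raise EnsembleFormatError(
            f"{path}: residues lack a consistent CA/backbone atom set"
        )

    n_res = len(unique_ids)
    frames = np.empty((stack.stack_depth(), n_res, len(atom_names), 3))
    seq_letters = []
    for r, rid in enumerate(unique_ids):
        mask = res_ids == rid
        names = stack.atom_name[mask]
        res_names = set(stack.res_name[mask])
        if len(res_names) != 1:
            raise EnsembleFormatError(
                f"{path}: residue {rid} has conflicting residue names across models"
            )
        try:
            seq_letters.append(
                ProteinSequence.convert_letter_3to1(res_names.pop())
            )
        except Exception as err:
            raise EnsembleFormatError(f"{path}: residue {rid}: {err}") from err
        for a, atom in enumerate(atom_names):
            sel = np.flatnonzero(mask & (stack.atom_name == atom))
            frames[:, r, a, :] = stack.coord[:, sel[0], :]
    seq = PeptideSequence("".join(seq_letters))
    return Ensemble(
        frames, seq, atom_names, provenance={"source": str(path)}
    )
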