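"""Sequence-level physicochemical analysis of disordered peptides.

Charge profiles (integer convention or Henderson-Hasselbalch titration),
isoelectric point by bisection, amino-acid composition and molecular weight,
charge-based diagram-of-states (Das-Pappu) classification, per-residue
disorder propensity, sliding-window hydropathy, transmembrane-segment length
rules, and 214-nm extinction coefficients.

Conventions: positions are 0-based in code and 1-based in emitted reports.
At neutral pH the integer charge convention counts K/R as +1, D/E as -1 and
His as neutral; the terminal amine and carboxylate count +1/-1.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
from Bio import SeqIO

from .properties import (
    CANONICAL_RESIDUES,
    WATER_MASS,
    get_pka_set,
    get_scale,
)

#: Helical rise along the axis per residue, in Angstrom.
HELIX_RISE = 1.5
#: Rise per residue of an extended beta-strand, in Angstrom.
STRAND_RISE = 3.3

POSITIVE_RESIDUES = frozenset("KR")  # His excluded at neutral pH
NEGATIVE_RESIDUES = frozenset("DE")


class InvalidSequenceError(ValueError):
    """Input text is not a valid one-letter amino-acid sequence."""


@dataclass(frozen=True)
class PeptideSequence:
    """A validated one-letter amino-acid sequence."""

    residues: str
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise InvalidSequenceError("empty sequence")
        for i, aa in enumerate(self.residues):
            if aa not in CANONICAL_RESIDUES:
                raise InvalidSequenceError(
                    f"non-canonical residue {aa!r} at position {i + 1}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[str]:
        return iter(self.residues)

    def __getitem__(self, i) -> str:
        return self.residues[i]

    def __str__(self) -> str:
        return self.residues


def parse_sequence(text: str, name: Optional[str] = None) -> PeptideSequence:
    """Parse a raw one-letter string or single-record FASTA text.

    Whitespace-tolerant and case-insensitive; a FASTA header becomes the
    sequence name.  Non-canonical characters raise
    :class:`InvalidSequenceError` reporting the (1-based) offending position.
    """
    if not text or not text.strip():
        raise InvalidSequenceError("empty input")
    stripped = text.strip()
    if stripped.startswith(">"):
        records = list(SeqIO.parse(io.StringIO(stripped), "fasta"))
        if len(records) != 1:
            raise InvalidSequenceError(
                f"expected exactly one FASTA record, found {len(records)}"
            )
        name = name or records[0].id
        stripped = str(records[0].seq)
    cleaned = "".join(stripped.split()).upper()
    return PeptideSequence(cleaned, name=name)


def read_fasta(path) -> PeptideSequence:
    """Read the first record of a FASTA file."""
    with open(path) as fh:
        return parse_sequence(fh.read())


# ---------------------------------------------------------------------------
# Composition and molecular weight
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompositionSummary:
    counts: dict[str, int]
    n_positive: int
    n_negative: int
    molecular_weight: float  # Da, average masses

    @property
    def length(self) -> int:
        return sum(self.counts.values())


def composition_summary(seq: PeptideSequence) -> CompositionSummary:
    """Residue counts, charged-residue counts and average molecular weight.

    ``n_positive`` counts K+R (His neutral at physiological pH) and
    ``n_negative`` counts D+E.  Mw = sum of average residue masses plus one
    water.
    """
    masses = get_scale("average_residue_mass")
    counts = {aa: seq.residues.count(aa) for aa in CANONICAL_RESIDUES if aa in seq.residues}
    mw = sum(masses[aa] for aa in seq) + WATER_MASS
    return CompositionSummary(
        counts=counts,
        n_positive=sum(counts.get(aa, 0) for aa in POSITIVE_RESIDUES),
        n_negative=sum(counts.get(aa, 0) for aa in NEGATIVE_RESIDUES),
        molecular_weight=mw,
    )


# ---------------------------------------------------------------------------
# Charge and titration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChargeProfile:
    """Per-position side-chain charges plus terminal-group charges."""

    per_position_charge: tuple[float, ...]
    termini_charges: tuple[float, float]
    pH: float
    mode: str  # "integer" | "henderson_hasselbalch"

    @property
    def net_charge(self) -> float:
        return sum(self.per_position_charge) + sum(self.termini_charges)


def _hh_positive(pH: float, pka: float) -> float:
    return 1.0 / (1.0 + 10.0 ** (pH - pka))


def _hh_negative(pH: float, pka: float) -> float:
    return -1.0 / (1.0 + 10.0 ** (pka - pH))


def charge_profile(
    seq: PeptideSequence, pH: float = 7.4, mode: str = "integer"
) -> ChargeProfile:
    """Charge per residue and for both termini at the given pH.

    ``integer`` mode assigns +1 to K/R, -1 to D/E, 0 to everything else
    (His included) and +1/-1 to the N-/C-terminus — the physiological-pH
    convention.  ``henderson_hasselbalch`` mode assigns partial charges from
    the Bjellqvist pKa set for the side chains of D/E/C/Y/H/K/R and both
    termini.
    """
    if not 0.0 <= pH <= 14.0:
        raise ValueError(f"pH must be within [0, 14], got {pH}")
    if mode == "integer":
        charges = tuple(
            1.0 if aa in POSITIVE_RESIDUES else -1.0 if aa in NEGATIVE_RESIDUES else 0.0
            for aa in seq
        )
        termini = (1.0, -1.0)
    elif mode == "henderson_hasselbalch":
        pka = get_pka_set()
        last = len(seq) - 1
        charges_list = []
        for i, aa in enumerate(seq):
            if aa in pka.BASIC:
                charges_list.append(_hh_positive(pH, pka.sidechain_pka(aa)))
            elif aa in pka.ACIDIC:
                charges_list.append(
                    _hh_negative(pH, pka.sidechain_pka(aa, is_cterminal=(i == last)))
                )
            else:
                charges_list.append(0.0)
        charges = tuple(charges_list)
        termini = (
            _hh_positive(pH, pka.nterm_pka(seq[0])),
            _hh_negative(pH, pka.cterm_default),
        )
    else:
        raise ValueError(f"unknown charge mode {mode!r}")
    return ChargeProfile(charges, termini, pH, mode)


def net_charge(seq: PeptideSequence, pH: float = 7.4, mode: str = "integer") -> float:
    """Net charge of the peptide (side chains plus termini)."""
    return charge_profile(seq, pH, mode).net_charge


def isoelectric_point(seq: PeptideSequence, decimals: int = 2) -> float:
    """Isoelectric point by bisection on the Henderson-Hasselbalch net charge.

    The net charge is strictly decreasing in pH, so the zero is unique;
    bisection runs to |charge| < 1e-4 and the result is rounded to
    ``decimals`` places (two, matching the standard calculator's output).
    Sequences with ionizable groups of only one sign still titrate through
    zero thanks to the two termini, but a sequence would need at least one
    acidic and one basic group for the pI to be meaningful; the termini
    always provide both.
    """
    lo, hi = 0.0, 14.0
    f = lambda pH: net_charge(seq, pH, mode="henderson_hasselbalch")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        q = f(mid)
        if abs(q) < 1e-4:
            break
        if q > 0:
            lo = mid
        else:
            hi = mid
    return round(mid, decimals)


# ---------------------------------------------------------------------------
# Das-Pappu diagram of states
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DasPappuResult:
    """Charge fractions and diagram-of-states region (R1..R5)."""

    f_plus: float
    f_minus: float
    region: str

    @property
    def FCR(self) -> float:
        return self.f_plus + self.f_minus

    @property
    def NCPR(self) -> float:
        return self.f_plus - self.f_minus


def das_pappu_classify(seq: PeptideSequence) -> DasPappuResult:
    """Classify the sequence on the charge-fraction diagram of states.

    Regions: R1 weak polyampholytes/polyelectrolytes (globule-formers,
    f+ < 0.25 and f- < 0.25); R2 boundary region; R3 strong polyampholytes;
    R4/R5 negative/positive strong polyelectrolytes.  K/R count positive,
    D/E negative, His neutral.
    """
    n = len(seq)
    f_plus = sum(1 for aa in seq if aa in POSITIVE_RESIDUES) / n
    f_minus = sum(1 for aa in seq if aa in NEGATIVE_RESIDUES) / n
    fcr = f_plus + f_minus
    ncpr = f_plus - f_minus
    if f_plus < 0.25 and f_minus < 0.25:
        region = "R1"
    elif 0.25 <= fcr <= 0.35 and abs(ncpr) <= 0.35:
        region = "R2"
    elif fcr > 0.35 and abs(ncpr) <= 0.35:
        region = "R3"
    elif f_minus > 0.35 and f_plus <= 0.35:
        region = "R4"
    elif f_plus > 0.35 and f_minus <= 0.35:
        region = "R5"
    else:  # unreachable for valid fractions; kept for safety
        region = "R3"
    return DasPappuResult(f_plus=f_plus, f_minus=f_minus, region=region)


# ---------------------------------------------------------------------------
# Position profiles: disorder propensity, hydropathy, TM rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PositionProfile:
    """Per-position values; window overhang positions are undefined (NaN)."""

    values: tuple[float, ...]
    window: int
    scale_name: str
    valid_range: tuple[int, int]  # half-open 0-based interval where defined

    def __len__(self) -> int:
        return len(self.values)

    @property
    def defined(self) -> tuple[bool, ...]:
        lo, hi = self.valid_range
        return tuple(lo <= i < hi for i in range(len(self.values)))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def disorder_propensity_profile(seq: PeptideSequence) -> PositionProfile:
    """Per-residue disorder propensity (database fractional difference).

    Positive values mark disorder-promoting residues.  Window = 1 (a raw
    per-position lookup, no smoothing).
    """
    scale = get_scale("disorder_propensity")
    return PositionProfile(
        values=tuple(scale[aa] for aa in seq),
        window=1,
        scale_name="disorder_propensity",
        valid_range=(0, len(seq)),
    )


def hydropathy_profile(
    seq: PeptideSequence, window: int = 5, scale: str = "ww_octanol"
) -> PositionProfile:
    """Centered sliding-window mean of a whole-residue hydropathy scale.

    The classic smoothing of Kyte and Doolittle, applied by default to the
    Wimley-White whole-residue octanol indices (charged-side-chain variant).
    Positions where the window overhangs the chain are undefined (NaN), not
    padded.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be odd and positive, got {window}")
    if window > len(seq):
        raise ValueError(f"window {window} exceeds sequence length {len(seq)}")
    table = get_scale(scale) if scale != "ww_octanol" else get_scale(scale, "charged")
    raw = np.array([table[aa] for aa in seq], dtype=float)
    half = window // 2
    values = np.full(len(seq), np.nan)
    means = np.convolve(raw, np.ones(window) / window, mode="valid")
    values[half : len(seq) - half] = means
    return PositionProfile(
        values=tuple(values),
        window=window,
        scale_name=scale,
        valid_range=(half, len(seq) - half),
    )


def min_tm_segment_length(
    bilayer_thickness: float = 30.0, rise_per_residue: float = HELIX_RISE
) -> int:
    """Residues needed to span a bilayer at the given rise per residue.

    With the 30 A thickness of a typical bilayer this gives ~20 residues for
    an alpha-helix (1.5 A/residue) and 9 for a beta-strand (3.3 A/residue).
    """
    if rise_per_residue <= 0:
        raise ValueError("rise per residue must be positive")
    if bilayer_thickness < 0:
        raise ValueError("bilayer thickness must be non-negative")
    return round(bilayer_thickness / rise_per_residue)


def find_tm_segments(
    profile: PositionProfile,
    threshold: float = 0.0,
    min_length: int = 20,
    hydrophobic_direction: Optional[str] = None,
) -> list[tuple[int, int]]:
    """Maximal hydrophobic runs long enough to be transmembrane segments.

    Returns half-open 0-based index intervals of maximal runs of defined
    window positions on the hydrophobic side of ``threshold`` with length >=
    ``min_length``.  Direction of hydrophobicity is inferred from the scale
    (octanol transfer free energies: hydrophobic below threshold;
    Kyte-Doolittle: above) unless given explicitly as "negative"/"positive".
    """
    if hydrophobic_direction is None:
        hydrophobic_direction = "positive" if profile.scale_name == "kyte_doolittle" else "negative"
    vals = profile.as_array()
    with np.errstate(invalid="ignore"):
        if hydrophobic_direction == "negative":
            ok = vals <= threshold
        elif hydrophobic_direction == "positive":
            ok = vals >= threshold
        else:
            raise ValueError(f"unknown hydrophobic_direction {hydrophobic_direction!r}")
    ok &= ~np.isnan(vals)
    segments: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate([*ok, False]):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_length:
                segments.append((start, i))
            start = None
    return segments


# ---------------------------------------------------------------------------
# 214-nm extinction coefficient
# ---------------------------------------------------------------------------


def extinction_coefficient_214(seq: PeptideSequence) -> float:
    """Molar extinction coefficient at 214 nm (M^-1 cm^-1).

    Composition-based estimate for peptide-concentration determination by
    far-UV absorbance: one per-peptide-bond contribution for each of the N-1
    backbone amides plus per-side-chain contributions; an N-terminal proline
    contributes its reduced secondary-amine value instead of the full
    proline term.
    """
    scale = get_scale("epsilon214")
    bond = scale.extras["PEPTIDE_BOND"]
    total = (len(seq) - 1) * bond
    for i, aa in enumerate(seq):
        if aa == "P" and i == 0:
            total += scale.extras["P_NTERM"]
        else:
            total += scale[aa]
    return float(total)
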