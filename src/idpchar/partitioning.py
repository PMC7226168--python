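"""Water-to-bilayer partitioning free energies on the Wimley-White scale.

Whole-residue transfer free energies from water to n-octanol are summed over
the sequence, selecting per-residue ionization variants according to a
convention, optionally adding charged free-terminal contributions.  A
positive total means partitioning into the bilayer interior is unfavourable.
The partitioning-folding coupling correction subtracts a constant free-energy
gain per residue (default 0.4 kcal/mol) available when partitioning is
coupled to interfacial folding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .properties import OCTANOL_VARIANT_RESIDUES, get_scale
from .sequence import PeptideSequence

#: Free-energy gain per residue from partitioning-folding coupling, kcal/mol.
DEFAULT_COUPLING_PER_RESIDUE = 0.4

#: Ionization conventions: residue -> variant of the octanol scale to use.
#: "physiological": His neutral, K/R positive, D/E negative (the convention
#: appropriate at neutral pH); "all_neutral" uses neutral variants throughout;
#: "all_charged" protonates/deprotonates every ionizable side chain.
CONVENTIONS: Mapping[str, Mapping[str, str]] = {
    "physiological": {"H": "neutral", "K": "charged", "R": "charged",
                      "D": "charged", "E": "charged"},
    "all_neutral": {r: "neutral" for r in OCTANOL_VARIANT_RESIDUES},
    "all_charged": {r: "charged" for r in OCTANOL_VARIANT_RESIDUES},
}


@dataclass(frozen=True)
class PartitioningResult:
    """Per-residue breakdown and totals of the partitioning free energy."""

    per_residue_dG: tuple[float, ...]  # kcal/mol
    terminal_dG: tuple[float, float]  # (N-terminus, C-terminus), kcal/mol
    per_residue_coupling: float  # kcal/mol per residue
    ionization: str

    @property
    def n_residues(self) -> int:
        return len(self.per_residue_dG)

    @property
    def total_dG(self) -> float:
        return sum(self.per_residue_dG) + sum(self.terminal_dG)

    @property
    def folding_coupled_dG(self) -> float:
        return folding_coupled(
            self.total_dG, self.n_residues, self.per_residue_coupling
        )


def partition_free_energy(
    seq: PeptideSequence,
    ionization: str = "physiological",
    include_termini: bool = True,
    per_residue_coupling: float = DEFAULT_COUPLING_PER_RESIDUE,
) -> PartitioningResult:
    """Sum whole-residue octanol transfer free energies over the sequence.

    ``ionization`` picks the protonation-state variant per ionizable residue
    (see :data:`CONVENTIONS`).  With ``include_termini`` the charged free
    N-terminal amine and C-terminal carboxylate contributions are added;
    free (unmodified) termini are assumed.
    """
    try:
        variant_of = CONVENTIONS[ionization]
    except KeyError:
        raise ValueError(
            f"unknown ionization convention {ionization!r}; "
            f"expected one of {sorted(CONVENTIONS)}"
        ) from None
    charged = get_scale("ww_octanol", "charged")
    neutral = get_scale("ww_octanol", "neutral")
    per_residue = tuple(
        (charged if variant_of.get(aa, "charged") == "charged" else neutral)[aa]
        for aa in seq
    )
    if include_termini:
        terminal = charged.terminal_contributions
    else:
        terminal = (0.0, 0.0)
    return PartitioningResult(
        per_residue_dG=per_residue,
        terminal_dG=terminal,
        per_residue_coupling=per_residue_coupling,
        ionization=ionization,
    )


def folding_coupled(
    total_dG: float,
    n_residues: int,
    per_residue: float = DEFAULT_COUPLING_PER_RESIDUE,
) -> float:
    """Partitioning free energy after the folding-coupling correction.

    ``total_dG - per_residue * n_residues``: each residue that folds upon
    partitioning gains roughly ``per_residue`` kcal/mol, applied here to the
    whole chain.
    """
    if n_residues < 0:
        raise ValueError("n_residues must be non-negative")
    return total_dG - per_residue * n_residues
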