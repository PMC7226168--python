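"""Per-residue property tables: the single source of truth for numeric scales.

Every scale used anywhere in the package (average residue masses,
Kyte-Doolittle hydropathy, Wimley-White octanol transfer free energies,
disorder-propensity fractional differences, Bjellqvist pKas, 214-nm molar
extinction coefficients) is shipped as a versioned TSV data file and exposed
through :func:`get_scale`.  Tables are immutable and validated on load.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from types import MappingProxyType
from typing import Iterator, Mapping, Optional

import pandas as pd

#: The 20 canonical one-letter amino-acid codes.
CANONICAL_RESIDUES: str = "ACDEFGHIKLMNPQRSTVWY"

#: Average mass of one water molecule in Da (added once per peptide chain).
WATER_MASS: float = 18.01524

# Registered scale name -> (data file, set of residue-level variants or None).
_SCALE_FILES = {
    "average_residue_mass": ("average_residue_mass.tsv", None),
    "kyte_doolittle": ("kyte_doolittle.tsv", None),
    "disorder_propensity": ("disorder_propensity.tsv", None),
    "ww_octanol": ("ww_octanol.tsv", {"neutral", "charged"}),
    "epsilon214": ("epsilon214.tsv", None),
}

_SCALE_UNITS = {
    "average_residue_mass": "Da",
    "kyte_doolittle": "dimensionless",
    "disorder_propensity": "dimensionless",
    "ww_octanol": "kcal/mol",
    "epsilon214": "M^-1 cm^-1",
}

#: Residues whose octanol entry distinguishes protonation states.
OCTANOL_VARIANT_RESIDUES = frozenset("DEHKR")


class UnknownScaleError(KeyError):
    """Requested scale (or scale variant) is not registered."""


@dataclass(frozen=True)
class ResiduePropertyTable(Mapping):
    """Immutable mapping from one-letter residue code to a scalar property.

    Parameters
    ----------
    scale_name :
        Registered identifier of the scale.
    entries :
        Value per canonical residue; exactly the 20 canonical codes.
    units :
        Physical units of the values.
    ionization_variant :
        ``"neutral"`` or ``"charged"`` for scales that distinguish
        protonation states, else ``None``.
    terminal_contributions :
        ``(N-terminus value, C-terminus value)`` for scales that include end
        groups, else ``None``.
    extras :
        Named non-residue constants belonging to the scale (e.g. the
        per-peptide-bond extinction coefficient).
    """

    scale_name: str
    entries: Mapping[str, float]
    units: str = ""
    ionization_variant: Optional[str] = None
    terminal_contributions: Optional[tuple[float, float]] = None
    extras: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", MappingProxyType(dict(self.entries)))
        object.__setattr__(self, "extras", MappingProxyType(dict(self.extras)))

    def __getitem__(self, code: str) -> float:
        try:
            return self.entries[code]
        except KeyError:
            raise KeyError(
                f"residue code {code!r} is not covered by scale "
                f"{self.scale_name!r} (canonical codes: {CANONICAL_RESIDUES})"
            ) from None

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def problems(self) -> list[str]:
        """Invariant violations of this single table (empty list = valid)."""
        out: list[str] = []
        missing = sorted(set(CANONICAL_RESIDUES) - set(self.entries))
        if missing:
            out.append(f"missing residues: {', '.join(missing)}")
        extra = sorted(set(self.entries) - set(CANONICAL_RESIDUES))
        if extra:
            out.append(f"non-canonical entries: {', '.join(extra)}")
        bad = sorted(k for k, v in self.entries.items() if not math.isfinite(v))
        if bad:
            out.append(f"non-finite values for: {', '.join(bad)}")
        if self.scale_name == "average_residue_mass":
            nonpos = sorted(k for k, v in self.entries.items() if v <= 0)
            if nonpos:
                out.append(f"non-positive masses for: {', '.join(nonpos)}")
        return out


@lru_cache(maxsize=None)
def _load_rows(filename: str) -> tuple[tuple[str, float, Optional[str]], ...]:
    with resources.files("idpchar.data").joinpath(filename).open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    rows = []
    for code, value, variant in df.itertuples(index=False):
        variant = None if (pd.isna(variant) or variant == "-") else str(variant)
        rows.append((str(code), float(value), variant))
    return tuple(rows)


@lru_cache(maxsize=None)
def get_scale(name: str, variant: Optional[str] = None) -> ResiduePropertyTable:
    """Return the registered, validated property table ``name``.

    For scales with ionization variants (the octanol scale) ``variant`` must
    be ``"neutral"`` or ``"charged"``; variant-free residues contribute the
    same value to either variant.  Passing a variant for a variant-free scale
    is an error.
    """
    try:
        filename, variants = _SCALE_FILES[name]
    except KeyError:
        raise UnknownScaleError(
            f"unknown scale {name!r}; registered scales: "
            f"{', '.join(sorted(_SCALE_FILES))}"
        ) from None
    if variants is None:
        if variant is not None:
            raise UnknownScaleError(
                f"scale {name!r} has no ionization variants (got {variant!r})"
            )
    else:
        if variant is None:
            variant = "charged"  # the physiological-pH default
        if variant not in variants:
            raise UnknownScaleError(
                f"unknown variant {variant!r} for scale {name!r}; "
                f"expected one of {sorted(variants)}"
            )

    entries: dict[str, float] = {}
    extras: dict[str, float] = {}
    nterm = cterm = None
    for code, value, row_variant in _load_rows(filename):
        if code == "NTERM":
            if row_variant in (None, variant):
                nterm = value
            continue
        if code == "CTERM":
            if row_variant in (None, variant):
                cterm = value
            continue
        if code not in CANONICAL_RESIDUES:
            extras[code] = value
            continue
        if row_variant is None or row_variant == variant:
            entries[code] = value
    terminal = None
    if nterm is not None and cterm is not None:
        terminal = (nterm, cterm)
    table = ResiduePropertyTable(
        scale_name=name,
        entries=entries,
        units=_SCALE_UNITS.get(name, ""),
        ionization_variant=variant,
        terminal_contributions=terminal,
        extras=extras,
    )
    bad = table.problems()
    if bad:
        raise UnknownScaleError(f"scale {name!r} failed validation: {bad}")
    return table


@dataclass(frozen=True)
class PKaSet:
    """Bjellqvist pKa constants for Henderson-Hasselbalch titration.

    ``sidechain`` covers the seven ionizable side chains (D, E, C, Y acidic;
    H, K, R basic).  ``sidechain_cterm`` overrides D/E when they are the
    C-terminal residue.  ``nterm_overrides`` are residue-specific pKas of the
    terminal amine; ``nterm_default``/``cterm_default`` apply otherwise.
    """

    sidechain: Mapping[str, float]
    sidechain_cterm: Mapping[str, float]
    nterm_overrides: Mapping[str, float]
    nterm_default: float
    cterm_default: float

    ACIDIC = frozenset("DECY")
    BASIC = frozenset("HKR")

    def nterm_pka(self, first_residue: str) -> float:
        return self.nterm_overrides.get(first_residue, self.nterm_default)

    def sidechain_pka(self, residue: str, is_cterminal: bool = False) -> float:
        if is_cterminal and residue in self.sidechain_cterm:
            return self.sidechain_cterm[residue]
        return self.sidechain[residue]

    def problems(self) -> list[str]:
        out = []
        missing = sorted((self.ACIDIC | self.BASIC) - set(self.sidechain))
        if missing:
            out.append(f"missing side-chain pKas: {', '.join(missing)}")
        vals = [
            *self.sidechain.values(),
            *self.sidechain_cterm.values(),
            *self.nterm_overrides.values(),
            self.nterm_default,
            self.cterm_default,
        ]
        if not all(math.isfinite(v) and 0 < v < 14 for v in vals):
            out.append("pKa values outside (0, 14)")
        return out


@lru_cache(maxsize=None)
def get_pka_set() -> PKaSet:
    """The Bjellqvist pKa set used for titration curves and pI."""
    sidechain: dict[str, float] = {}
    sidechain_cterm: dict[str, float] = {}
    nterm_overrides: dict[str, float] = {}
    nterm_default = cterm_default = math.nan
    for code, value, variant in _load_rows("pka_bjellqvist.tsv"):
        if variant == "sidechain":
            sidechain[code] = value
        elif variant == "sidechain_cterm":
            sidechain_cterm[code] = value
        elif variant == "nterm":
            nterm_overrides[code] = value
        elif variant == "default" and code == "NTERM":
            nterm_default = value
        elif variant == "default" and code == "CTERM":
            cterm_default = value
    return PKaSet(
        sidechain=MappingProxyType(sidechain),
        sidechain_cterm=MappingProxyType(sidechain_cterm),
        nterm_overrides=MappingProxyType(nterm_overrides),
        nterm_default=nterm_default,
        cterm_default=cterm_default,
    )


@dataclass(frozen=True)
class TableStatus:
    name: str
    ok: bool
    problems: tuple[str, ...]


@dataclass(frozen=True)
class ValidationReport:
    statuses: tuple[TableStatus, ...]

    @property
    def all_ok(self) -> bool:
        return all(s.ok for s in self.statuses)

    def __str__(self) -> str:
        lines = []
        for s in self.statuses:
            mark = "ok" if s.ok else "FAIL: " + "; ".join(s.problems)
            lines.append(f"{s.name}\t{mark}")
        return "\n".join(lines)


def _cross_checks() -> list[TableStatus]:
    """Registry-level invariants spanning more than one table/variant."""
    out = []

    dis = get_scale("disorder_propensity")
    bad = [r for r in "PESQ" if dis[r] <= 0] + [r for r in "WCFIY" if dis[r] >= 0]
    out.append(
        TableStatus(
            "disorder_propensity:signs",
            not bad,
            tuple(f"sign-inconsistent residue {r}" for r in bad),
        )
    )

    charged = get_scale("ww_octanol", "charged")
    neutral = get_scale("ww_octanol", "neutral")
    bad = [r for r in "DEKR" if charged[r] <= neutral[r]]
    out.append(
        TableStatus(
            "ww_octanol:variant_ordering",
            not bad,
            tuple(f"charged {r} not more hydrophilic than neutral {r}" for r in bad),
        )
    )

    pka = get_pka_set()
    probs = pka.problems()
    out.append(TableStatus("pka_bjellqvist", not probs, tuple(probs)))
    return out


def validate_tables(
    extra_tables: Optional[list[ResiduePropertyTable]] = None,
) -> ValidationReport:
    """Validate every registered table (plus any injected ones).

    Never raises: failures are reported as entries with ``ok=False``.
    """
    statuses: list[TableStatus] = []
    for name, (_, variants) in _SCALE_FILES.items():
        for variant in sorted(variants) if variants else [None]:
            label = name if variant is None else f"{name}[{variant}]"
            try:
                table = get_scale(name, variant)
            except UnknownScaleError as err:
                statuses.append(TableStatus(label, False, (str(err),)))
                continue
            probs = table.problems()
            if name == "ww_octanol":
                probs = probs + [
                    f"missing {variant} variant for {r}"
                    for r in sorted(OCTANOL_VARIANT_RESIDUES)
                    if r not in table.entries
                ]
            statuses.append(TableStatus(label, not probs, tuple(probs)))
    statuses.extend(_cross_checks())
    for table in extra_tables or []:
        probs = table.problems()
        statuses.append(
            TableStatus(f"injected:{table.scale_name}", not probs, tuple(probs))
        )
    return ValidationReport(tuple(statuses))
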