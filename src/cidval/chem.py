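"""Molecular formulas, isotope tables, adducts and monoisotopic masses.

The isotope masses and natural abundances ship with the package as a pinned
delimited table (``data/isotopes.tsv``).  Every element's abundances are
normalized to sum to exactly 1 so that downstream pattern arithmetic never
accumulates a normalization drift; the table version tag is recorded in all
reports so results can be traced to one abundance compilation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterator, Mapping

__all__ = [
    "ElementIsotopes",
    "IsotopeTable",
    "Formula",
    "Adduct",
    "ADDUCTS",
    "ELECTRON_MASS",
    "C13_C12_DELTA",
    "parse_formula",
    "monoisotopic_mass",
    "isotopologue_mz_list",
    "default_table",
]

#: Electron rest mass in Da (CODATA).
ELECTRON_MASS = 0.000548579909

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed formula strings or unsupported elements."""


@dataclass(frozen=True)
class ElementIsotopes:
    """Isotopes of one element: masses in Da, abundances as fractions."""

    symbol: str
    masses: tuple[float, ...]
    abundances: tuple[float, ...]
    source: str

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.masses, self.masses[1:])):
            raise ValueError(f"{self.symbol}: isotope masses must increase")
        if abs(sum(self.abundances) - 1.0) > 1e-9:
            raise ValueError(f"{self.symbol}: abundances must sum to 1")

    @property
    def lightest_mass(self) -> float:
        return self.masses[0]

    @property
    def n_isotopes(self) -> int:
        return len(self.masses)


class IsotopeTable:
    """Lookup of :class:`ElementIsotopes` keyed by element symbol."""

    def __init__(self, elements: Mapping[str, ElementIsotopes], version: str):
        self._elements = dict(elements)
        self.version = version

    def __getitem__(self, symbol: str) -> ElementIsotopes:
        try:
            return self._elements[symbol]
        except KeyError:
            raise FormulaError(f"element {symbol!r} not in isotope table") from None

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._elements

    def __iter__(self) -> Iterator[str]:
        return iter(self._elements)

    def mass(self, symbol: str, mass_number: int | None = None) -> float:
        el = self[symbol]
        if mass_number is None:
            return el.lightest_mass
        for m in el.masses:
            if round(m) == mass_number:
                return m
        raise FormulaError(f"no isotope {mass_number} of {symbol} in table")


def _load_default_table() -> IsotopeTable:
    text = resources.files("cidval").joinpath("data/isotopes.tsv").read_text()
    version = "unversioned"
    rows: dict[str, list[tuple[float, float]]] = {}
    for line in text.splitlines():
        if line.startswith("#"):
            if "version" in line:
                version = line.split("version", 1)[1].split()[0]
            continue
        if not line.strip() or line.startswith("element"):
            continue
        sym, _num, mass, ab = line.split("\t")
        rows.setdefault(sym, []).append((float(mass), float(ab)))
    elements = {}
    for sym, pairs in rows.items():
        pairs.sort()
        total = sum(a for _, a in pairs)
        elements[sym] = ElementIsotopes(
            symbol=sym,
            masses=tuple(m for m, _ in pairs),
            abundances=tuple(a / total for _, a in pairs),
            source=version,
        )
    return IsotopeTable(elements, version)


_DEFAULT_TABLE: IsotopeTable | None = None


def default_table() -> IsotopeTable:
    """The packaged isotope table (loaded once, cached)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = _load_default_table()
    return _DEFAULT_TABLE


@dataclass(frozen=True)
class Formula:
    """Element-count composition of one neutral species.

    ``counts`` maps element symbols to non-negative integers; ``charge`` is
    the charge of the bare species (usually 0 for a neutral metabolite —
    ionization lives in :class:`Adduct`).
    """

    counts: Mapping[str, int]
    charge: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        counts = {k: int(v) for k, v in self.counts.items() if int(v) != 0}
        if any(v < 0 for v in counts.values()):
            raise FormulaError("negative element count")
        if not counts:
            raise FormulaError("formula must contain at least one atom")
        object.__setattr__(self, "counts", counts)

    @property
    def n_carbons(self) -> int:
        """Number of carbon atoms — the *n* of the binomial CID model."""
        return self.counts.get("C", 0)

    def __format__(self, spec: str) -> str:
        return str(self)

    def __str__(self) -> str:
        # Hill-ish ordering: C, H, then alphabetical — matches common usage.
        keys = sorted(self.counts, key=lambda s: (s != "C", s != "H", s))
        return "".join(
            f"{k}{self.counts[k]}" if self.counts[k] != 1 else k for k in keys
        )

    def without(self, symbol: str, n: int | None = None) -> "Formula":
        """Copy with ``n`` atoms of ``symbol`` removed (all by default)."""
        counts = dict(self.counts)
        have = counts.get(symbol, 0)
        drop = have if n is None else n
        if drop > have:
            raise FormulaError(f"cannot remove {drop} {symbol} from {self}")
        counts[symbol] = have - drop
        counts = {k: v for k, v in counts.items() if v}
        if not counts:
            raise FormulaError("removal would empty the formula")
        return replace(self, counts=counts)


def parse_formula(
    text: str, *, charge: int = 0, label: str = "", table: IsotopeTable | None = None
) -> Formula:
    """Parse a flat element-count string such as ``"C5H11NO2Se"``.

    The grammar is a sequence of (element symbol, optional count) pairs;
    counts default to 1 and repeated symbols accumulate.  Parentheses and
    hydrate dot-notation are deliberately unsupported.
    """
    table = table or default_table()
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(
                f"malformed formula {text!r}: unexpected {text[pos:m.start()]!r}"
            )
        sym, num = m.group(1), m.group(2)
        if sym not in table:
            raise FormulaError(f"unsupported element {sym!r} in {text!r}")
        counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
        pos = m.end()
    if pos != len(text) or not counts:
        raise FormulaError(f"malformed formula {text!r}: unexpected {text[pos:]!r}")
    return Formula(counts=counts, charge=charge, label=label or text)


@dataclass(frozen=True)
class Adduct:
    """Ionization adduct: a mass delta and a charge.

    The default deltas use atom masses (electron mass neglected); pass
    ``include_electron=True`` to :func:`monoisotopic_mass` to account for the
    electrons gained/lost, which matters only below ~3 ppm at m/z 200.
    """

    name: str
    delta: float
    charge: int

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("adduct charge must be nonzero")


def _mk_adducts() -> dict[str, Adduct]:
    t = default_table()
    h = t.mass("H")
    return {
        "[M+H]+": Adduct("[M+H]+", +h, +1),
        "[M-H]-": Adduct("[M-H]-", -h, -1),
        "[M+Na]+": Adduct("[M+Na]+", +t.mass("Na"), +1),
        "[M+NH4]+": Adduct("[M+NH4]+", +t.mass("N") + 4 * h, +1),
        "[M+Cl]-": Adduct("[M+Cl]-", +t.mass("Cl"), -1),
        "[M]": Adduct("[M]", 0.0, +1),  # neutral pseudo-adduct, m/z = M
    }


ADDUCTS: dict[str, Adduct] = _mk_adducts()

#: Mass difference 13C - 12C in Da, the spacing of carbon tracer channels.
C13_C12_DELTA = default_table().mass("C", 13) - default_table().mass("C", 12)


def monoisotopic_mass(
    formula: Formula,
    adduct: Adduct = ADDUCTS["[M]"],
    *,
    table: IsotopeTable | None = None,
    include_electron: bool = False,
) -> float:
    """m/z of the all-light-isotope species of ``formula`` with ``adduct``.

    Sum of count x lightest-isotope mass per element, plus the adduct delta,
    divided by |charge|.  With ``include_electron`` the electron mass times
    the (signed) total charge is subtracted before dividing.
    """
    table = table or default_table()
    if adduct.charge == 0:
        raise ValueError("adduct charge must be nonzero")
    mass = sum(n * table[el].lightest_mass for el, n in formula.counts.items())
    mass += adduct.delta
    if include_electron:
        mass -= (formula.charge + adduct.charge) * ELECTRON_MASS
    return mass / abs(adduct.charge)


def isotopologue_mz_list(
    formula: Formula,
    adduct: Adduct = ADDUCTS["[M]"],
    tracer_element: str = "C",
    *,
    table: IsotopeTable | None = None,
) -> list[float]:
    """m/z values of the tracer channels M0..Mn for a carbon tracer.

    Entry k is the monoisotopic m/z shifted by k heavy-tracer substitutions.
    If the tracer element is absent the list holds M0 only.
    """
    table = table or default_table()
    n = formula.counts.get(tracer_element, 0)
    el = table[tracer_element]
    if el.n_isotopes < 2:
        raise FormulaError(f"{tracer_element} has a single isotope; no channels")
    step = (el.masses[1] - el.masses[0]) / abs(adduct.charge)
    m0 = monoisotopic_mass(formula, adduct, table=table)
    return [m0 + k * step for k in range(n + 1)]
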