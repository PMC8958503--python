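"""Building blocks, molecular-formula arithmetic and exact-mass bookkeeping.

The dynamic combinatorial library studied here is built by double reductive
amination of one tetraamine core (spermine, ``1``) with a panel of aromatic
aldehydes (``A``..``O``).  Each attachment is imine condensation (loss of
H2O) followed by cyanoborohydride reduction (gain of H2), so the net formula
change per arm is ``aldehyde - O``.  Mono-adducts are labelled ``3X`` and
bis-adducts ``3XY`` with ``X <= Y``; the label is order independent.

Monoisotopic (principal-isotope) masses reproduce the neutral "Calculated"
ESI-MS values to four decimals, and the bromine-containing members carry an
explicit 79Br/81Br isotopologue ladder because the two MS peaks are both
used for peak assignment.
"""

from __future__ import annotations

import csv
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations_with_replacement
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

__all__ = [
    "MolecularFormula",
    "BuildingBlock",
    "LibraryMember",
    "parse_formula",
    "adduct_formula",
    "monoisotopic_mass",
    "isotopologue_masses",
    "enumerate_library",
    "degeneracy_groups",
    "load_blocks",
    "default_blocks",
    "PROTON_MASS",
]

# Principal-isotope atomic masses (Da).  Six or more decimals so that the
# four-decimal neutral masses printed by ESI-TOF software are reproduced
# within 0.0005 Da from building-block arithmetic alone.
PRINCIPAL_MASS: Dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740,
    "O": 15.9949146,
    "S": 31.97207069,
    "Br": 78.9183376,
    "Cl": 34.96885268,
    "P": 30.97376151,
    "F": 18.99840320,
    "Na": 22.98976928,
    "I": 126.904473,
}

# Heavy-isotope masses for elements whose second isotope is abundant enough
# to produce a resolved ESI-MS doublet (79Br/81Br is near 1:1).
HEAVY_ISOTOPE_MASS: Dict[str, float] = {
    "Br": 80.9162906,
}

#: Mass of a proton, used to match detected [M+H]+ ions to neutral masses.
PROTON_MASS: float = 1.007276

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Element -> count map with element-wise arithmetic.

    Counts are non-negative; subtraction that would drive any count negative
    raises ``ValueError`` (it would mean removing atoms that are not there).
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for el, n in dict(self.counts).items():
            if el not in PRINCIPAL_MASS:
                raise ValueError(f"unknown element symbol: {el!r}")
            n = int(n)
            if n < 0:
                raise ValueError(f"negative count for {el}: {n}")
            if n > 0:
                clean[el] = n
        object.__setattr__(self, "counts", clean)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        c = Counter(self.counts)
        c.update(other.counts)
        return MolecularFormula(dict(c))

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        c = Counter(self.counts)
        c.subtract(other.counts)
        if any(v < 0 for v in c.values()):
            short = {k: -v for k, v in c.items() if v < 0}
            raise ValueError(f"subtraction would give negative counts: {short}")
        return MolecularFormula({k: v for k, v in c.items() if v > 0})

    def __mul__(self, k: int) -> "MolecularFormula":
        if k < 0:
            raise ValueError("multiplier must be non-negative")
        return MolecularFormula({el: n * k for el, n in self.counts.items()})

    __rmul__ = __mul__

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __bool__(self) -> bool:
        return bool(self.counts)

    @property
    def mass(self) -> float:
        """Monoisotopic (principal-isotope) mass in Da."""
        return monoisotopic_mass(self)

    def hill(self) -> str:
        """Hill-notation string: C first, H second, then alphabetical."""
        parts = []
        order = [el for el in ("C", "H") if el in self.counts]
        order += sorted(el for el in self.counts if el not in ("C", "H"))
        for el in order:
            n = self.counts[el]
            parts.append(el + (str(n) if n != 1 else ""))
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-notation formula string like ``"C32H42N4O2"``.

    Counts default to 1; an empty string is the empty formula (mass 0).
    Raises ``ValueError`` on malformed input or unknown element symbols.
    """
    counts: Counter = Counter()
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise ValueError(f"malformed formula {text!r} at position {pos}")
        el = m.group(1)
        if el not in PRINCIPAL_MASS:
            raise ValueError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] += int(m.group(2) or 1)
        pos = m.end()
    if pos != len(text):
        raise ValueError(f"malformed formula {text!r} at position {pos}")
    return MolecularFormula(dict(counts))


_H2 = MolecularFormula({"H": 2})
_H2O = MolecularFormula({"H": 2, "O": 1})


@dataclass(frozen=True)
class BuildingBlock:
    """One registry entry: the core amine or one aldehyde."""

    id: str
    kind: str  # "core-amine" | "aldehyde"
    formula: MolecularFormula
    n_reactive_sites: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("core-amine", "aldehyde"):
            raise ValueError(f"unknown block kind {self.kind!r}")
        if self.n_reactive_sites < 1:
            raise ValueError("n_reactive_sites must be >= 1")


@dataclass(frozen=True)
class LibraryMember:
    """A mono- or bis-adduct product of the reductive-amination library."""

    id: str
    composition: Tuple[str, ...]  # sorted aldehyde ids, length 1 or 2
    formula: MolecularFormula
    mono_mass: float
    isotopologue_masses: Tuple[Tuple[float, int], ...]


def monoisotopic_mass(f: MolecularFormula) -> float:
    """Sum of principal-isotope masses; 0.0 for the empty formula."""
    return sum(PRINCIPAL_MASS[el] * n for el, n in f.counts.items())


def isotopologue_masses(
    f: MolecularFormula, elements: Iterable[str] = ("Br",)
) -> List[Tuple[float, int]]:
    """Heavy-isotope substitution ladder for the given elements.

    Returns one ``(mass, n_substitutions)`` entry per heavy-isotope
    substitution count from 0 up to the number of substitutable atoms,
    masses strictly increasing.  For a Br-free formula this is a single
    entry equal to the monoisotopic mass.
    """
    elements = list(elements)
    unsupported = [el for el in elements if el not in HEAVY_ISOTOPE_MASS]
    if unsupported:
        raise ValueError(f"no heavy-isotope data for: {unsupported}")
    if len(elements) > 1:  # pragma: no cover - registry only needs Br
        raise ValueError("one substitutable element at a time is supported")
    base = monoisotopic_mass(f)
    if not elements:
        return [(base, 0)]
    el = elements[0]
    n = f[el]
    delta = HEAVY_ISOTOPE_MASS[el] - PRINCIPAL_MASS[el]
    return [(base + k * delta, k) for k in range(n + 1)]


def adduct_formula(
    core: BuildingBlock, aldehydes: Sequence[BuildingBlock]
) -> MolecularFormula:
    """Formula of the reduced adduct: core + sum(aldehyde + H2 - H2O).

    ``aldehydes`` is a multiset of size 0..n_reactive_sites of the core
    (0 returns the bare core, used as the enumeration identity).
    """
    if core.kind != "core-amine":
        raise ValueError("core must be a core-amine block")
    if len(aldehydes) > core.n_reactive_sites:
        raise ValueError(
            f"{len(aldehydes)} adducts exceed the {core.n_reactive_sites} "
            "reactive sites of the core"
        )
    f = core.formula
    for ald in aldehydes:
        if ald.kind != "aldehyde":
            raise ValueError(f"block {ald.id!r} is not an aldehyde")
        f = f + ald.formula + _H2 - _H2O
    return f


def _member(core: BuildingBlock, alds: Sequence[BuildingBlock]) -> LibraryMember:
    comp = tuple(sorted(a.id for a in alds))
    f = adduct_formula(core, alds)
    return LibraryMember(
        id="3" + "".join(comp),
        composition=comp,
        formula=f,
        mono_mass=monoisotopic_mass(f),
        isotopologue_masses=tuple(isotopologue_masses(f)),
    )


def enumerate_library(
    core: BuildingBlock, aldehydes: Sequence[BuildingBlock]
) -> List[LibraryMember]:
    """All mono-adducts plus all unordered bis-adducts with repetition.

    For n aldehydes this yields ``n + n(n+1)/2`` members with canonical,
    order-independent ids.  Dialdehydes attach through a single carbonyl;
    oligomer growth through the second one is outside the enumeration.
    """
    if not aldehydes:
        raise ValueError("empty aldehyde list")
    ids = [a.id for a in aldehydes]
    if len(set(ids)) != len(ids):
        raise ValueError("aldehyde ids must be unique")
    alds = sorted(aldehydes, key=lambda a: a.id)
    members = [_member(core, [a]) for a in alds]
    members += [_member(core, list(pair))
                for pair in combinations_with_replacement(alds, 2)]
    return members


def degeneracy_groups(
    members: Sequence[LibraryMember], tol: float
) -> List[List[LibraryMember]]:
    """Partition members by mass indistinguishability.

    Two members belong to the same group iff they are connected under
    ``|delta mono_mass| <= tol`` (transitive closure), which on the sorted
    mass axis is simply chaining of consecutive gaps.  Groups of size > 1
    are mass-degenerate and cannot be told apart in one LC-MS run.
    The partition is invariant to the input order.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    ordered = sorted(members, key=lambda m: (m.mono_mass, m.id))
    groups: List[List[LibraryMember]] = []
    for m in ordered:
        if groups and m.mono_mass - groups[-1][-1].mono_mass <= tol:
            groups[-1].append(m)
        else:
            groups.append([m])
    return [sorted(g, key=lambda m: m.id) for g in groups]


# ---------------------------------------------------------------------------
# registry I/O


def load_blocks(path) -> Dict[str, BuildingBlock]:
    """Read a registry CSV with columns id,kind,formula,n_sites."""
    blocks: Dict[str, BuildingBlock] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            bid = row["id"].strip()
            if bid in blocks:
                raise ValueError(f"duplicate block id {bid!r}")
            blocks[bid] = BuildingBlock(
                id=bid,
                kind=row["kind"].strip(),
                formula=parse_formula(row["formula"].strip()),
                n_reactive_sites=int(row.get("n_sites", 1) or 1),
            )
    cores = [b for b in blocks.values() if b.kind == "core-amine"]
    if len(cores) != 1:
        raise ValueError("registry must contain exactly one core-amine")
    return blocks


def default_blocks() -> Dict[str, BuildingBlock]:
    """Bundled default registry: spermine core ``1`` plus aldehydes A-O."""
    ref = resources.files("hepdcl.data").joinpath("default_blocks.csv")
    with resources.as_file(ref) as path:
        return load_blocks(path)


def split_registry(
    blocks: Mapping[str, BuildingBlock]
) -> Tuple[BuildingBlock, List[BuildingBlock]]:
    """Return (core, sorted aldehydes) from a registry mapping."""
    core = next(b for b in blocks.values() if b.kind == "core-amine")
    alds = sorted(
        (b for b in blocks.values() if b.kind == "aldehyde"), key=lambda b: b.id
    )
    return core, alds
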