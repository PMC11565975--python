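"""Molecular-formula arithmetic and combinatorial N-acyl lipid enumeration.

An N-acyl lipid is the amide condensation product of an amine-bearing
headgroup (amino acid, polyamine, neurotransmitter, ...) and a fatty acid
``Cn:d`` (n carbons, d C=C double bonds).  This module provides element-count
arithmetic, monoisotopic masses, enumeration of the acyl-chain space, and the
headgroup x chain cartesian product that yields the candidate list with
theoretical [M+H]+ precursor m/z values.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

__all__ = [
    "PROTON_MASS",
    "WATER",
    "ElementCounts",
    "Headgroup",
    "AcylChain",
    "NAcylLipid",
    "FragmentSpec",
    "parse_formula",
    "monoisotopic_mass",
    "acyl_formula",
    "enumerate_chains",
    "condense",
    "enumerate_candidates",
    "parse_display_name",
    "load_registry",
    "default_registry",
    "write_registry",
]

#: Mass of a proton in Da, used for the [M+H]+ precursor (not the H-atom mass).
PROTON_MASS = 1.007276

#: Monoisotopic (most abundant isotope) masses, IUPAC/AME values.
ELEMENT_MONOISOTOPIC: dict[str, float] = {
    "H": 1.007825032,
    "C": 12.0,
    "N": 14.003074005,
    "O": 15.994914620,
    "F": 18.998403163,
    "Na": 22.989769282,
    "P": 30.973761998,
    "S": 31.972071174,
    "Cl": 34.968852682,
    "K": 38.963706486,
    "Se": 79.916521762,
    "Br": 78.918337601,
    "I": 126.904471853,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ElementCounts(dict):
    """Element symbol -> non-negative count; supports + and - with checks.

    Subtraction that would drive any count negative raises ``ValueError`` —
    a condensation that cannot lose water is chemically impossible and must
    not silently produce a nonsense formula.
    """

    def __init__(self, counts: Mapping[str, int] | None = None):
        super().__init__()
        if counts:
            for el, n in counts.items():
                n = int(n)
                if n < 0:
                    raise ValueError(f"negative count for element {el!r}: {n}")
                if n:
                    self[el] = n

    def __add__(self, other: Mapping[str, int]) -> "ElementCounts":
        out = dict(self)
        for el, n in other.items():
            out[el] = out.get(el, 0) + n
        return ElementCounts(out)

    def __sub__(self, other: Mapping[str, int]) -> "ElementCounts":
        out = dict(self)
        for el, n in other.items():
            new = out.get(el, 0) - n
            if new < 0:
                raise ValueError(
                    f"subtraction yields negative count for element {el!r}"
                )
            out[el] = new
        return ElementCounts(out)

    def hill(self) -> str:
        """Hill-notation string: C first, H second, then alphabetical."""
        order = [el for el in ("C", "H") if el in self]
        order += sorted(el for el in self if el not in ("C", "H"))
        return "".join(
            f"{el}{self[el]}" if self[el] != 1 else el for el in order
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def parse_formula(text: str) -> ElementCounts:
    """Parse a Hill-notation formula string such as ``"C5H9N3"``.

    Raises ``ValueError`` on malformed strings or unknown element symbols.
    """
    if not text or not re.fullmatch(r"(?:[A-Z][a-z]?\d*)+", text):
        raise ValueError(f"malformed formula string: {text!r}")
    counts: dict[str, int] = {}
    for sym, num in _FORMULA_TOKEN.findall(text):
        if not sym:
            continue
        if sym not in ELEMENT_MONOISOTOPIC:
            raise ValueError(f"unknown element symbol {sym!r} in {text!r}")
        counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
    return ElementCounts(counts)


def monoisotopic_mass(f: Mapping[str, int]) -> float:
    """Monoisotopic mass in Da of an element-count map (0.0 for empty).

    Additive by construction: mass(a + b) = mass(a) + mass(b).
    """
    try:
        return sum(ELEMENT_MONOISOTOPIC[el] * n for el, n in f.items())
    except KeyError as exc:
        raise ValueError(f"element without tabulated mass: {exc.args[0]!r}") from exc


#: Formula of water, the molecule lost on amide condensation.
WATER = ElementCounts({"H": 2, "O": 1})
_WATER_MASS = monoisotopic_mass(WATER)


@dataclass(frozen=True)
class FragmentSpec:
    """A diagnostic headgroup fragment carried by the registry.

    ``min_relative_intensity`` is a fraction of the base peak in [0, 1].
    """

    mz: float
    tolerance: float = 0.02
    min_relative_intensity: float = 0.01

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("fragment m/z must be positive")
        if self.tolerance <= 0:
            raise ValueError("fragment tolerance must be positive")
        if not 0.0 <= self.min_relative_intensity <= 1.0:
            raise ValueError("min_relative_intensity must be in [0, 1]")


@dataclass(frozen=True)
class Headgroup:
    """A conjugatable amine: free-amine formula plus diagnostic fragments."""

    name: str
    formula: ElementCounts
    diagnostic_fragments: tuple[FragmentSpec, ...]
    n_acylation_sites: int = 1
    equivalence_group: str | None = None

    def __post_init__(self) -> None:
        if self.formula.get("N", 0) < 1:
            raise ValueError(f"headgroup {self.name!r} contains no nitrogen")
        if not self.diagnostic_fragments:
            raise ValueError(f"headgroup {self.name!r} has no diagnostic fragments")
        if self.n_acylation_sites < 1:
            raise ValueError("n_acylation_sites must be >= 1")


def default_chain_rule(n: int, d: int) -> bool:
    """Validity of a Cn:d chain: a chain of n carbons holds at most
    floor((n-1)/2) C=C double bonds, i.e. n >= 2d + 1."""
    return n >= 2 * d + 1


@dataclass(frozen=True, order=True)
class AcylChain:
    """Fatty acyl descriptor Cn:d (n carbons, d double bonds)."""

    n_carbons: int
    n_double_bonds: int

    def __post_init__(self) -> None:
        n, d = self.n_carbons, self.n_double_bonds
        if not 2 <= n <= 30:
            raise ValueError(f"chain length {n} outside C2-C30")
        if not 0 <= d <= 4:
            raise ValueError(f"{d} double bonds outside 0-4")
        if not default_chain_rule(n, d):
            raise ValueError(f"C{n}:{d} violates n >= 2d+1")

    def __str__(self) -> str:
        return f"C{self.n_carbons}:{self.n_double_bonds}"


def acyl_formula(chain: AcylChain) -> ElementCounts:
    """Free fatty acid formula CnH(2n-2d)O2 for a Cn:d chain."""
    n, d = chain.n_carbons, chain.n_double_bonds
    return ElementCounts({"C": n, "H": 2 * n - 2 * d, "O": 2})


def enumerate_chains(
    min_c: int = 2,
    max_c: int = 30,
    max_db: int = 4,
    rule: Callable[[int, int], bool] = default_chain_rule,
) -> list[AcylChain]:
    """All valid Cn:d chains with min_c <= n <= max_c, 0 <= d <= max_db.

    Sorted by (n, d).  The default rule reproduces the 129 chains per
    headgroup behind the 8,256-candidate space (29+28+26+24+22).
    """
    if not 2 <= min_c <= max_c:
        raise ValueError("need 2 <= min_c <= max_c")
    if max_db < 0:
        raise ValueError("max_db must be >= 0")
    return [
        AcylChain(n, d)
        for n in range(min_c, max_c + 1)
        for d in range(0, max_db + 1)
        if rule(n, d)
    ]


@dataclass(frozen=True)
class NAcylLipid:
    """A condensed headgroup-Cn:d conjugate with theoretical masses."""

    headgroup: Headgroup
    chain: AcylChain
    formula: ElementCounts
    monoisotopic_mass: float
    precursor_mz: float

    @property
    def display_name(self) -> str:
        return f"{self.headgroup.name}-{self.chain}"


_DISPLAY_RE = re.compile(r"^(?P<head>.+)-C(?P<n>\d+):(?P<d>\d+)$")


def parse_display_name(name: str) -> tuple[str, AcylChain]:
    """Invert ``display_name``: ``"histamine-C2:0"`` -> ("histamine", C2:0)."""
    m = _DISPLAY_RE.match(name)
    if not m:
        raise ValueError(f"not a head-Cn:d display name: {name!r}")
    return m.group("head"), AcylChain(int(m.group("n")), int(m.group("d")))


def condense(head: Headgroup, chain: AcylChain) -> NAcylLipid:
    """Amide condensation: head + fatty acid - H2O, as the [M+H]+ species."""
    formula = head.formula + acyl_formula(chain) - WATER
    mono = monoisotopic_mass(formula)
    return NAcylLipid(
        headgroup=head,
        chain=chain,
        formula=formula,
        monoisotopic_mass=mono,
        precursor_mz=mono + PROTON_MASS,
    )


def enumerate_candidates(
    registry: Sequence[Headgroup],
    min_c: int = 2,
    max_c: int = 30,
    max_db: int = 4,
    rule: Callable[[int, int], bool] = default_chain_rule,
) -> list[NAcylLipid]:
    """Cartesian product registry x chains, condensed.

    With the 64-headgroup registry and default chain space this yields the
    full 8,256-candidate list.
    """
    if not registry:
        raise ValueError("empty headgroup registry")
    chains = enumerate_chains(min_c, max_c, max_db, rule)
    return [condense(h, c) for h in registry for c in chains]


# ---------------------------------------------------------------------------
# Registry I/O.  TSV columns: name, formula, diagnostic_fragments
# (semicolon-separated mz@tol@min_rel triples), n_sites and optionally
# equivalence_group (isomer sets accepted as mutual true positives).
# ---------------------------------------------------------------------------

_REGISTRY_COLUMNS = ["name", "formula", "diagnostic_fragments", "n_sites"]


def _parse_fragments(text: str) -> tuple[FragmentSpec, ...]:
    out = []
    for triple in text.split(";"):
        triple = triple.strip()
        if not triple:
            continue
        parts = triple.split("@")
        if len(parts) != 3:
            raise ValueError(f"bad fragment triple {triple!r}")
        out.append(
            FragmentSpec(
                mz=float(parts[0]),
                tolerance=float(parts[1]),
                min_relative_intensity=float(parts[2]),
            )
        )
    return tuple(out)


def load_registry(path: str | Path) -> list[Headgroup]:
    """Load a headgroup registry TSV (see module docstring for columns)."""
    heads: list[Headgroup] = []
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in _REGISTRY_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"registry missing columns {missing}")
        idx = {c: header.index(c) for c in header}
        for line in fh:
            if not line.strip():
                continue
            row = line.rstrip("\n").split("\t")
            equiv = None
            if "equivalence_group" in idx and len(row) > idx["equivalence_group"]:
                equiv = row[idx["equivalence_group"]].strip() or None
            heads.append(
                Headgroup(
                    name=row[idx["name"]],
                    formula=parse_formula(row[idx["formula"]]),
                    diagnostic_fragments=_parse_fragments(
                        row[idx["diagnostic_fragments"]]
                    ),
                    n_acylation_sites=int(row[idx["n_sites"]]),
                    equivalence_group=equiv,
                )
            )
    names = [h.name for h in heads]
    if len(set(names)) != len(names):
        raise ValueError("duplicate headgroup names in registry")
    return heads


def write_registry(heads: Iterable[Headgroup], path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(_REGISTRY_COLUMNS + ["equivalence_group"]) + "\n")
        for h in heads:
            frags = ";".join(
                f"{f.mz:.6f}@{f.tolerance:g}@{f.min_relative_intensity:g}"
                for f in h.diagnostic_fragments
            )
            fh.write(
                "\t".join(
                    [
                        h.name,
                        h.formula.hill(),
                        frags,
                        str(h.n_acylation_sites),
                        h.equivalence_group or "",
                    ]
                )
                + "\n"
            )


def default_registry() -> list[Headgroup]:
    """The packaged 64-headgroup registry.

    Shipped as ``data/headgroups_synthetic.tsv``: headgroup names and free
    amine formulas for the 64 conjugatable amines the queries cover; the
    diagnostic fragment m/z values are computed ([head+H]+ and one neutral
    loss), i.e. synthetic stand-ins rather than curated experimental ions.
    """
    ref = resources.files("nacyl.data").joinpath("headgroups_synthetic.tsv")
    with resources.as_file(ref) as path:
        return load_registry(path)
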