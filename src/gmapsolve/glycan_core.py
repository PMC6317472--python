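"""Glycan structures: parsing, canonical serialization, composition and mass.

Glycans are rooted trees of monosaccharides.  The root is the reducing-end
residue; children extend toward the non-reducing termini.  Each non-root
residue carries its linkage to its parent: an anomeric configuration
(``a``/``b``/``?``), the anomeric carbon of the child (usually 1, 2 for
sialic acids) and the hydroxyl position on the parent (1-9 or ``?``).

The text dialect is condensed IUPAC, e.g. ``Neu5Aca2-6Galb1-4GlcNAc``.
The reducing-end residue is rightmost; a branch is parenthesized and placed
immediately before its parent residue, as in
``Mana1-3(Mana1-6)Manb1-4GlcNAc``.  Sibling order carries no meaning:
equality and deduplication go through :func:`canonical_form`.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping

__all__ = [
    "RESIDUE_CLASSES",
    "COMPOSITION_CLASSES",
    "Monosaccharide",
    "GlycanTree",
    "Composition",
    "MassTable",
    "DEFAULT_MASS_TABLE",
    "GlycanParseError",
    "parse_glycan",
    "canonical_form",
    "composition_of",
    "mass_of",
]

#: residue vocabulary -> composition class
RESIDUE_CLASSES: Mapping[str, str] = {
    "Glc": "Hex",
    "Gal": "Hex",
    "Man": "Hex",
    "GlcNAc": "HexNAc",
    "GalNAc": "HexNAc",
    "Fuc": "dHex",
    "Neu5Ac": "Neu5Ac",
    "Neu5Gc": "Neu5Gc",
    "Xyl": "Pent",
}

COMPOSITION_CLASSES = ("Hex", "HexNAc", "dHex", "Neu5Ac", "Neu5Gc", "Pent")

_ANOMERS = ("a", "b", "?")
_POSITIONS = set("123456789?")

_uid_counter = itertools.count(1)


class GlycanParseError(ValueError):
    """Raised on malformed glycan text; carries the offending position."""

    def __init__(self, message: str, text: str, pos: int):
        super().__init__(f"{message} at position {pos} in {text!r}")
        self.text = text
        self.pos = pos


@dataclass(eq=False)
class Monosaccharide:
    """One residue node.  Identity (not structure) semantics for ``==``/hash,
    so nodes can serve as match-site references; structural equality is via
    :func:`canonical_form` on the enclosing tree."""

    residue: str
    anomer: str | None = None          # a | b | ? ; None for the root
    child_pos: int | str | None = None  # anomeric carbon of this residue
    parent_pos: int | str | None = None  # attachment position on the parent
    children: list["Monosaccharide"] = field(default_factory=list)
    uid: int = field(default_factory=lambda: next(_uid_counter))

    def __post_init__(self) -> None:
        if self.residue not in RESIDUE_CLASSES:
            raise ValueError(f"unknown residue class {self.residue!r}")
        if self.anomer is not None and self.anomer not in _ANOMERS:
            raise ValueError(f"bad anomericity {self.anomer!r}")
        for p in (self.child_pos, self.parent_pos):
            if p is not None and str(p) not in _POSITIONS:
                raise ValueError(f"bad linkage position {p!r}")

    @property
    def linkage(self) -> str:
        if self.anomer is None:
            return ""
        return f"{self.anomer}{self.child_pos}-{self.parent_pos}"

    def copy(self) -> "Monosaccharide":
        """Deep copy preserving node uids (digestion provenance tracking)."""
        dup = Monosaccharide(
            self.residue, self.anomer, self.child_pos, self.parent_pos,
            [c.copy() for c in self.children],
        )
        dup.uid = self.uid
        return dup

    def walk(self) -> Iterator["Monosaccharide"]:
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass(eq=False)
class GlycanTree:
    root: Monosaccharide
    id: str = ""

    def walk(self) -> Iterator[Monosaccharide]:
        return self.root.walk()

    def residue_count(self) -> int:
        return sum(1 for _ in self.walk())

    def copy(self, id: str | None = None) -> "GlycanTree":
        return GlycanTree(self.root.copy(), self.id if id is None else id)

    def parent_map(self) -> dict[Monosaccharide, Monosaccharide | None]:
        parents: dict[Monosaccharide, Monosaccharide | None] = {self.root: None}
        for node in self.walk():
            for c in node.children:
                parents[c] = node
        return parents

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GlycanTree):
            return NotImplemented
        return canonical_form(self) == canonical_form(other)

    def __hash__(self) -> int:
        return hash(canonical_form(self))

    def __str__(self) -> str:
        return canonical_form(self)

    def __repr__(self) -> str:
        return f"GlycanTree({canonical_form(self)!r}, id={self.id!r})"


# ---------------------------------------------------------------------------
# parsing

_RESIDUE_RE = re.compile("|".join(sorted(RESIDUE_CLASSES, key=len, reverse=True)))
_LINKAGE_RE = re.compile(r"([ab?])([1-9?])-([1-9?])")


def _coerce_pos(tok: str) -> int | str:
    return tok if tok == "?" else int(tok)


def parse_glycan(text: str, id: str = "") -> GlycanTree:
    """Parse condensed IUPAC text into a :class:`GlycanTree`.

    Raises :class:`GlycanParseError` for empty input, unknown residues,
    dangling or missing linkages, and unbalanced parentheses.
    """
    if not text or not text.strip():
        raise GlycanParseError("empty glycan text", text, 0)
    s = text.strip()
    root, pos = _parse_chain(s, 0, depth=0)
    if pos != len(s):
        raise GlycanParseError("unbalanced parentheses", s, pos)
    if root.anomer is not None:
        raise GlycanParseError("dangling linkage on reducing-end residue", s, len(s))
    return GlycanTree(root, id)


def _parse_chain(s: str, pos: int, depth: int) -> tuple[Monosaccharide, int]:
    prev: Monosaccharide | None = None
    pending: list[Monosaccharide] = []
    while pos < len(s):
        ch = s[pos]
        if ch == "(":
            branch, pos = _parse_chain(s, pos + 1, depth + 1)
            if pos >= len(s) or s[pos] != ")":
                raise GlycanParseError("unbalanced parentheses", s, pos)
            pos += 1
            if branch.anomer is None:
                raise GlycanParseError("branch lacks a linkage", s, pos)
            pending.append(branch)
            continue
        if ch == ")":
            if depth == 0:
                raise GlycanParseError("unbalanced parentheses", s, pos)
            break
        m = _RESIDUE_RE.match(s, pos)
        if m is None:
            raise GlycanParseError("unknown residue token", s, pos)
        pos = m.end()
        node = Monosaccharide(m.group())
        if prev is not None:
            if prev.anomer is None:
                raise GlycanParseError("missing linkage between residues", s, pos)
            node.children.append(prev)
        if pending:
            node.children.extend(pending)
            pending = []
        prev = node
        # optional linkage to the (yet unseen) parent on the right
        if pos < len(s) and s[pos] in "ab?":
            lm = _LINKAGE_RE.match(s, pos)
            if lm is None:
                raise GlycanParseError("dangling linkage", s, pos)
            node.anomer = lm.group(1)
            node.child_pos = _coerce_pos(lm.group(2))
            node.parent_pos = _coerce_pos(lm.group(3))
            pos = lm.end()
    if prev is None:
        raise GlycanParseError("empty residue group", s, pos)
    if pending:
        raise GlycanParseError("branch without a parent residue", s, pos)
    return prev, pos


# ---------------------------------------------------------------------------
# serialization

def _sort_key(node: Monosaccharide) -> tuple:
    # '?' positions sort after numbered ones; final tie-break on subtree text
    pp = node.parent_pos
    return (pp == "?" or pp is None, pp if isinstance(pp, int) else 0,
            _serialize(node))


def _serialize(node: Monosaccharide, with_linkage: bool = True) -> str:
    kids = sorted(node.children, key=_sort_key)
    out = ""
    if kids:
        out += _serialize(kids[0])
        for b in kids[1:]:
            out += f"({_serialize(b)})"
    out += node.residue
    if with_linkage and node.anomer is not None:
        out += node.linkage
    return out


def canonical_form(g: GlycanTree) -> str:
    """Deterministic condensed-IUPAC serialization, invariant under sibling
    permutation.  ``parse_glycan(canonical_form(g))`` reproduces ``g``."""
    return _serialize(g.root)


# ---------------------------------------------------------------------------
# composition and mass

_COMP_TOKEN_RE = re.compile(r"(Hex(?!NAc)|HexNAc|dHex|Neu5Ac|Neu5Gc|Pent)(\d*)")


@dataclass(frozen=True)
class Composition:
    """Monosaccharide-class counts (Hex/HexNAc/dHex/Neu5Ac/Neu5Gc/Pent)."""

    Hex: int = 0
    HexNAc: int = 0
    dHex: int = 0
    Neu5Ac: int = 0
    Neu5Gc: int = 0
    Pent: int = 0

    def __post_init__(self) -> None:
        for cls in COMPOSITION_CLASSES:
            if getattr(self, cls) < 0:
                raise ValueError("composition counts must be non-negative")

    def total(self) -> int:
        return sum(getattr(self, cls) for cls in COMPOSITION_CLASSES)

    def __add__(self, other: "Composition") -> "Composition":
        return Composition(**{cls: getattr(self, cls) + getattr(other, cls)
                              for cls in COMPOSITION_CLASSES})

    def __str__(self) -> str:
        return "".join(f"{cls}{getattr(self, cls)}"
                       for cls in COMPOSITION_CLASSES if getattr(self, cls))

    @classmethod
    def from_string(cls, text: str) -> "Composition":
        """Parse e.g. ``"Hex5HexNAc4Neu5Ac2"``."""
        counts: dict[str, int] = {}
        pos = 0
        text = text.strip()
        while pos < len(text):
            m = _COMP_TOKEN_RE.match(text, pos)
            if m is None:
                raise ValueError(f"bad composition token at {pos} in {text!r}")
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
            pos = m.end()
        return cls(**counts)


def composition_of(g: GlycanTree) -> Composition:
    counts = dict.fromkeys(COMPOSITION_CLASSES, 0)
    for node in g.walk():
        counts[RESIDUE_CLASSES[node.residue]] += 1
    return Composition(**counts)


@dataclass(frozen=True)
class MassTable:
    """Monoisotopic residue masses (Da) per composition class, plus the water
    mass added once for a free reducing glycan, and a matching tolerance."""

    residue_masses: Mapping[str, float]
    water_mass: float = 18.0105646863
    tolerance: float = 0.5

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.residue_masses.values()):
            raise ValueError("residue masses must be positive")
        if self.tolerance < 0:
            raise ValueError("tolerance must be non-negative")

    @classmethod
    def from_dict(cls, data: Mapping) -> "MassTable":
        masses = {k: float(v) for k, v in data.get("residue_masses", {}).items()}
        return cls(residue_masses=masses,
                   water_mass=float(data.get("water_mass", 18.0105646863)),
                   tolerance=float(data.get("tolerance", 0.5)))


#: underivatized monoisotopic residue masses
DEFAULT_MASS_TABLE = MassTable(residue_masses={
    "Hex": 162.0528234315,
    "HexNAc": 203.0793725337,
    "dHex": 146.0579088094,
    "Neu5Ac": 291.0954165286,
    "Neu5Gc": 307.0903311475,
    "Pent": 132.0422587452,
})


def mass_of(c: Composition, table: MassTable = DEFAULT_MASS_TABLE) -> float:
    """Monoisotopic mass (Da) of a free reducing glycan of composition ``c``."""
    total = table.water_mass
    for cls in COMPOSITION_CLASSES:
        n = getattr(c, cls)
        if n == 0:
            continue
        if cls not in table.residue_masses:
            raise KeyError(f"mass table lacks residue class {cls!r}")
        total += n * table.residue_masses[cls]
    return total
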