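"""Motif matching, lectin-binding prediction, exoglycosidase simulation.

A motif is a small glycan-shaped pattern whose linkage fields may carry
``?`` wildcards.  A motif matches a glycan at a site where the pattern maps
onto a connected subtree whose root lies toward the reducing end: residue
classes must be equal, non-wildcard anomericity/positions must be equal, and
a pattern wildcard matches anything.  A ``?`` stored in the *glycan* matches
only a pattern wildcard — unknown linkages never silently satisfy a specific
pattern.  With ``terminal_required`` every pattern leaf must land on a
residue with no further non-reducing extension, which is how exoglycosidase
recognition (and terminal-epitope lectins) are anchored to exposed termini.

Enzymes are modeled as recognition -> replace motif substitution: wherever
the recognition motif matches, the residues present in the recognition
pattern but absent from the replace pattern are deleted, repeatedly, until
no site remains.  Substitution only ever removes residues, so digestion is
monotone and idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .glycan_core import GlycanTree, Monosaccharide, parse_glycan

__all__ = [
    "Motif",
    "LectinSpec",
    "EnzymeSpec",
    "match_motif",
    "predict_binding",
    "apply_enzyme",
    "apply_treatment",
    "EnzymeApplicationError",
]


class EnzymeApplicationError(RuntimeError):
    """A substitution that would not strictly reduce the residue count."""


@dataclass(frozen=True)
class Motif:
    pattern: GlycanTree
    terminal_required: bool = False

    @classmethod
    def from_text(cls, text: str, terminal_required: bool = False) -> "Motif":
        return cls(parse_glycan(text), terminal_required)

    def __str__(self) -> str:
        return str(self.pattern)


@dataclass(frozen=True)
class LectinSpec:
    """A lectin with one binding score per recognized motif."""

    name: str
    entries: tuple[tuple[Motif, float], ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError(f"lectin {self.name!r} has no motif entries")
        for _, score in self.entries:
            if not (score >= 0):
                raise ValueError(f"lectin {self.name!r} has a negative or "
                                 f"non-finite binding score")


def _field_matches(pat, gly) -> bool:
    if pat is None or pat == "?":
        return True
    if gly is None or gly == "?":
        return False  # unknowns only match explicit wildcards
    return pat == gly


def _node_matches(p: Monosaccharide, g: Monosaccharide, at_root: bool,
                  terminal_required: bool) -> dict | None:
    """Try to map pattern subtree ``p`` onto glycan subtree rooted at ``g``.

    Returns a pattern-node -> glycan-node mapping, or None.  The pattern
    root's own parent linkage is ignored (no parent context to compare)."""
    if p.residue != g.residue:
        return None
    if not at_root:
        if not (_field_matches(p.anomer, g.anomer)
                and _field_matches(p.child_pos, g.child_pos)
                and _field_matches(p.parent_pos, g.parent_pos)):
            return None
    if not p.children:
        if terminal_required and g.children:
            return None
        return {p: g}
    return _assign_children(p, g, terminal_required)


def _assign_children(p: Monosaccharide, g: Monosaccharide,
                     terminal_required: bool) -> dict | None:
    # injective assignment of pattern children onto distinct glycan children
    candidates: list[list[tuple[int, dict]]] = []
    for pc in p.children:
        opts = []
        for i, gc in enumerate(g.children):
            sub = _node_matches(pc, gc, False, terminal_required)
            if sub is not None:
                opts.append((i, sub))
        if not opts:
            return None
        candidates.append(opts)

    def backtrack(k: int, used: set[int], acc: dict) -> dict | None:
        if k == len(candidates):
            return acc
        for i, sub in candidates[k]:
            if i in used:
                continue
            res = backtrack(k + 1, used | {i}, {**acc, **sub})
            if res is not None:
                return res
        return None

    return backtrack(0, set(), {p: g})


def _match_mappings(g: GlycanTree, m: Motif) -> list[dict]:
    """One mapping per matched site (site = matched root residue)."""
    out = []
    for node in g.walk():
        mapping = _node_matches(m.pattern.root, node, True, m.terminal_required)
        if mapping is not None:
            out.append(mapping)
    return out


def match_motif(g: GlycanTree, m: Motif) -> list[Monosaccharide]:
    """Return the glycan residues (pattern-root anchors) where ``m`` matches."""
    return [mp[m.pattern.root] for mp in _match_mappings(g, m)]


def predict_binding(g: GlycanTree, lectin: LectinSpec,
                    mode: str = "max") -> float:
    """Predicted binding level of ``lectin`` to ``g``.

    ``mode='max'`` (default): maximum binding score over motifs with at least
    one match site.  ``'sum'``: sum of matched motif scores.
    ``'site_weighted'``: sum of score x site count.  0 if nothing matches.
    """
    if mode not in ("max", "sum", "site_weighted"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    total = 0.0
    best = 0.0
    for motif, score in lectin.entries:
        nsites = len(match_motif(g, motif))
        if nsites == 0:
            continue
        best = max(best, score)
        total += score * (nsites if mode == "site_weighted" else 1)
    return best if mode == "max" else total


# ---------------------------------------------------------------------------
# enzymes

@dataclass(frozen=True)
class EnzymeSpec:
    """Exoglycosidase model: recognition motif -> replace motif.

    The replace pattern must be the recognition pattern with one or more
    non-reducing-side residues deleted; the deleted residues are what the
    enzyme cleaves.
    """

    name: str
    recognition: Motif
    replace: Motif
    _deleted: frozenset = field(init=False, repr=False, compare=False,
                                default=frozenset())

    def __post_init__(self) -> None:
        deleted = _align_replace(self.recognition.pattern.root,
                                 self.replace.pattern.root, self.name)
        object.__setattr__(self, "_deleted", frozenset(deleted))

    @classmethod
    def from_text(cls, name: str, recognition: str, replace: str,
                  terminal_required: bool = True) -> "EnzymeSpec":
        return cls(name, Motif.from_text(recognition, terminal_required),
                   Motif.from_text(replace))


def _align_replace(rec: Monosaccharide, rep: Monosaccharide,
                   name: str) -> set[Monosaccharide]:
    """Pattern nodes of the recognition motif absent from the replace motif."""
    if (rep.residue != rec.residue):
        raise ValueError(f"enzyme {name!r}: replace motif root must equal "
                         f"recognition motif root")
    deleted: set[Monosaccharide] = set()

    def walk(rc: Monosaccharide, pc: Monosaccharide) -> None:
        remaining = list(rc.children)
        for child in pc.children:
            hit = next((c for c in remaining
                        if c.residue == child.residue
                        and c.anomer == child.anomer
                        and c.child_pos == child.child_pos
                        and c.parent_pos == child.parent_pos), None)
            if hit is None:
                raise ValueError(
                    f"enzyme {name!r}: replace motif adds or alters residues; "
                    f"it must be a reducing-side prefix of the recognition motif")
            remaining.remove(hit)
            walk(hit, child)
        for lost in remaining:
            deleted.update(lost.walk())

    walk(rec, rep)
    return deleted


def apply_enzyme(g: GlycanTree, e: EnzymeSpec) -> GlycanTree:
    """Digest ``g`` with ``e`` to exhaustion; returns a new tree.

    Sites are processed one at a time in a deterministic (outermost-first)
    order; since substitution only deletes terminal-side residues the fixed
    point is unique.  Raises :class:`EnzymeApplicationError` if a matching
    substitution would not remove any residue.
    """
    if not e._deleted:
        if _match_mappings(g, e.recognition):
            raise EnzymeApplicationError(
                f"enzyme {e.name!r} substitution does not reduce residue count")
        return g.copy(g.id)

    work = g.copy(g.id)
    while True:
        mappings = _match_mappings(work, e.recognition)
        if not mappings:
            return work
        parents = work.parent_map()
        depth: dict[Monosaccharide, int] = {}
        for node in work.walk():
            p = parents[node]
            depth[node] = 0 if p is None else depth[p] + 1
        # outermost (deepest) site first; tie-break on matched uid tuple
        mappings.sort(key=lambda mp: (-depth[mp[e.recognition.pattern.root]],
                                      tuple(sorted(n.uid for n in mp.values()))))
        applied = False
        for mp in mappings:
            doomed = {mp[pn] for pn in e._deleted if pn in mp}
            if not doomed:
                continue
            # never orphan residues outside the match
            if any(c not in doomed for n in doomed for c in n.children):
                continue
            for n in doomed:
                parent = parents[n]
                if parent is not None and n in parent.children:
                    parent.children.remove(n)
            applied = True
            break
        if not applied:
            return work


def apply_treatment(g: GlycanTree,
                    enzymes: Sequence[EnzymeSpec] | Iterable[EnzymeSpec]) -> GlycanTree:
    """Apply enzymes sequentially, each to exhaustion; [] is the identity."""
    out = g
    for e in enzymes:
        out = apply_enzyme(out, e)
    return out if out is not g else g.copy(g.id)
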