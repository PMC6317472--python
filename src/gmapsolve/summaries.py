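"""Weighted structural summaries of a deconvolution report.

Given per-glycan weights, these helpers summarize the solved glycan
population the way a glycomics reader expects: the share of each core type
(bi/tri/tetra-antennary N-glycans, O-glycan cores), the proportions of
terminal features (sialic-acid and galactose linkages, exposed GlcNAc),
the fraction of total weight carried by each monosaccharide composition
(mass), and the isomer breakdown within one composition.

All outputs are fractions that sum to 1 and are invariant to a global
rescaling of the weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

from .glycan_core import GlycanTree, Monosaccharide, composition_of
from .motif_enzyme import Motif, match_motif

__all__ = [
    "CoreRule",
    "TerminalFeature",
    "default_core_rules",
    "default_terminal_features",
    "core_type_of",
    "core_fractions",
    "terminal_feature_fractions",
    "mass_fractions",
    "isomer_breakdown",
]


@dataclass(frozen=True)
class CoreRule:
    label: str
    classifier: Callable[[GlycanTree], bool]


@dataclass(frozen=True)
class TerminalFeature:
    """A terminal epitope detector; all motifs must be terminal-required."""

    label: str
    motifs: tuple[Motif, ...]

    def __post_init__(self) -> None:
        if any(not m.terminal_required for m in self.motifs):
            raise ValueError(f"feature {self.label!r} has a non-terminal motif")

    def count_sites(self, g: GlycanTree) -> int:
        return sum(len(match_motif(g, m)) for m in self.motifs)


# ---------------------------------------------------------------------------
# core typing

def _n_core_antennae(g: GlycanTree) -> int | None:
    """Antenna count of an N-glycan, or None if the trimannosyl-chitobiose
    core is absent.  Antennae are GlcNAc branches on the two core
    alpha-mannoses; a bisecting GlcNAc (b1-4 on the beta-mannose) and core
    fucose are flags, not antennae."""
    root = g.root
    if root.residue != "GlcNAc":
        return None
    gn2 = [c for c in root.children if c.residue == "GlcNAc"]
    if not gn2:
        return None
    man_b = [c for c in gn2[0].children if c.residue == "Man"]
    if not man_b:
        return None
    alpha = [c for c in man_b[0].children
             if c.residue == "Man" and c.parent_pos in (3, 6)]
    if len(alpha) < 2:
        return None
    return sum(1 for m in alpha for c in m.children if c.residue == "GlcNAc")


def core_flags(g: GlycanTree) -> dict[str, bool]:
    """Core fucosylation and bisecting GlcNAc of an N-glycan."""
    root = g.root
    fuc = any(c.residue == "Fuc" for c in root.children)
    bisect = False
    gn2 = [c for c in root.children if c.residue == "GlcNAc"]
    if gn2:
        man_b = [c for c in gn2[0].children if c.residue == "Man"]
        if man_b:
            bisect = any(c.residue == "GlcNAc" and c.parent_pos == 4
                         for c in man_b[0].children)
    return {"core_fucose": fuc, "bisecting_glcnac": bisect}


def _is_o_core(g: GlycanTree, want_core2: bool) -> bool:
    root = g.root
    if root.residue != "GalNAc":
        return False
    has_gal13 = any(c.residue == "Gal" and c.anomer == "b" and c.parent_pos == 3
                    for c in root.children)
    has_gn16 = any(c.residue == "GlcNAc" and c.anomer == "b" and c.parent_pos == 6
                   for c in root.children)
    if want_core2:
        return has_gal13 and has_gn16
    return has_gal13 and not has_gn16


def default_core_rules() -> tuple[CoreRule, ...]:
    """Priority-ordered, mutually exclusive core classifiers."""
    def n_rule(n: int) -> Callable[[GlycanTree], bool]:
        return lambda g: _n_core_antennae(g) == n

    return (
        CoreRule("N-biantennary", n_rule(2)),
        CoreRule("N-triantennary", n_rule(3)),
        CoreRule("N-tetraantennary", n_rule(4)),
        CoreRule("N-other",
                 lambda g: _n_core_antennae(g) not in (None, 2, 3, 4)),
        CoreRule("O-core2", lambda g: _is_o_core(g, True)),
        CoreRule("O-core1", lambda g: _is_o_core(g, False)),
    )


def core_type_of(g: GlycanTree,
                 rules: Sequence[CoreRule] | None = None) -> str:
    """First matching core label in priority order; 'other' if none."""
    for rule in (rules if rules is not None else default_core_rules()):
        if rule.classifier(g):
            return rule.label
    return "other"


# ---------------------------------------------------------------------------
# terminal features

def default_terminal_features() -> tuple[TerminalFeature, ...]:
    def t(text: str) -> Motif:
        return Motif.from_text(text, terminal_required=True)

    return (
        TerminalFeature("Neu5Ac a2-3", (t("Neu5Aca2-3Gal"),)),
        TerminalFeature("Neu5Ac a2-6", (t("Neu5Aca2-6Gal"),)),
        TerminalFeature("Gal b1-3", (t("Galb1-3GlcNAc"), t("Galb1-3GalNAc"))),
        TerminalFeature("Gal b1-4", (t("Galb1-4GlcNAc"),)),
        TerminalFeature("terminal GlcNAc", (t("GlcNAc"),)),
    )


# ---------------------------------------------------------------------------
# weighted fractions

def _clean_weights(weights: Mapping[str, float]) -> dict[str, float]:
    w = {k: float(v) for k, v in weights.items() if v > 0}
    if not w:
        raise ValueError("all weights are zero")
    return w


def core_fractions(weights: Mapping[str, float],
                   glycans: Mapping[str, GlycanTree],
                   rules: Sequence[CoreRule] | None = None) -> dict[str, float]:
    """Weight fraction of each core label; sums to 1."""
    w = _clean_weights(weights)
    total = sum(w.values())
    out: dict[str, float] = {}
    for gid, wt in w.items():
        label = core_type_of(glycans[gid], rules)
        out[label] = out.get(label, 0.0) + wt / total
    return out


def terminal_feature_fractions(
    weights: Mapping[str, float],
    glycans: Mapping[str, GlycanTree],
    features: Sequence[TerminalFeature] | None = None,
    core_filter: str | Iterable[str] | None = None,
    per_site: bool = True,
) -> dict[str, float]:
    """Weighted proportions of terminal features, optionally restricted to
    glycans of given core label(s).

    Per-site mode (default): each glycan contributes its weight split across
    its terminal-feature sites, so a hybrid a2-3/a2-6 structure contributes
    half to each linkage.  Presence mode: each matched feature gets the full
    weight.  Fractions are normalized over features to sum to 1.
    """
    feats = tuple(features) if features is not None else default_terminal_features()
    w = _clean_weights(weights)
    if core_filter is not None:
        allowed = {core_filter} if isinstance(core_filter, str) else set(core_filter)
        w = {gid: wt for gid, wt in w.items()
             if core_type_of(glycans[gid]) in allowed}
        if not w:
            raise ValueError("no weighted glycans pass the core filter")
    acc = dict.fromkeys((f.label for f in feats), 0.0)
    for gid, wt in w.items():
        counts = {f.label: f.count_sites(glycans[gid]) for f in feats}
        total_sites = sum(counts.values())
        if total_sites == 0:
            continue
        for label, n in counts.items():
            if n:
                acc[label] += wt * (n / total_sites if per_site else 1.0)
    total = sum(acc.values())
    if total == 0:
        return {label: 0.0 for label in acc}
    return {label: v / total for label, v in acc.items()}


def mass_fractions(weights: Mapping[str, float],
                   glycans: Mapping[str, GlycanTree],
                   group_labels: Mapping[str, str] | None = None) -> dict[str, float]:
    """Fraction of total weight per composition group (isomers pooled).

    Groups default to the composition string (e.g. ``Hex5HexNAc4Neu5Ac2``);
    ``group_labels`` may override with e.g. printed mass labels.  Empty
    weights give an empty table.
    """
    w = {k: float(v) for k, v in weights.items() if v > 0}
    if not w:
        return {}
    total = sum(w.values())
    out: dict[str, float] = {}
    for gid, wt in w.items():
        key = (group_labels[gid] if group_labels is not None
               else str(composition_of(glycans[gid])))
        out[key] = out.get(key, 0.0) + wt / total
    return out


def isomer_breakdown(weights: Mapping[str, float],
                     glycans: Mapping[str, GlycanTree],
                     group: str,
                     group_labels: Mapping[str, str] | None = None) -> dict[str, float]:
    """Within-group relative weights of the isomers of one composition."""
    members = {}
    for gid, wt in weights.items():
        key = (group_labels[gid] if group_labels is not None
               else str(composition_of(glycans[gid])))
        if key == group and wt > 0:
            members[gid] = float(wt)
    total = sum(members.values())
    if total <= 0:
        raise ValueError(f"group {group!r} has zero total weight")
    return {gid: wt / total for gid, wt in members.items()}
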