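"""Model response vectors over a lectin x enzyme-treatment panel.

A panel is an ordered set of conditions (each an ordered exoglycosidase
sequence; the empty sequence is the untreated condition) crossed with a set
of lectins.  For each candidate glycan, the predicted binding of every
lectin to the glycan after every treatment is assembled into a model
response vector; stacking candidates column-wise gives the model matrix C
used by the deconvolution solver.  Both model and observed data are
normalized per lectin by the block maximum, which puts all channels on a
common relative-binding scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .glycan_core import (Composition, GlycanTree, MassTable,
                          DEFAULT_MASS_TABLE, composition_of, mass_of)
from .motif_enzyme import (EnzymeSpec, LectinSpec, _match_mappings,
                           apply_treatment, predict_binding)

__all__ = [
    "Condition",
    "Panel",
    "build_model_matrix",
    "normalize_per_lectin",
    "cluster_model_glycans",
    "restrict_candidates",
    "vector_correlation",
    "motif_coverage",
]


@dataclass(frozen=True)
class Condition:
    name: str
    enzymes: tuple[EnzymeSpec, ...] = ()


@dataclass(frozen=True)
class Panel:
    conditions: tuple[Condition, ...]
    lectins: tuple[LectinSpec, ...]
    binding_mode: str = "max"

    def __post_init__(self) -> None:
        if not self.conditions or not self.lectins:
            raise ValueError("panel needs at least one condition and one lectin")
        labels = self.channels()
        if len(set(labels)) != len(labels):
            raise ValueError("panel channel labels are not unique")

    def channels(self) -> list[tuple[str, str]]:
        """Row order of the response vector: conditions outer, lectins inner."""
        return [(c.name, l.name) for c in self.conditions for l in self.lectins]

    def channel_index(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_tuples(self.channels(),
                                         names=["condition", "lectin"])

    @property
    def n_channels(self) -> int:
        return len(self.conditions) * len(self.lectins)


def _treated_forms(g: GlycanTree, panel: Panel) -> dict[str, GlycanTree]:
    return {c.name: apply_treatment(g, c.enzymes) for c in panel.conditions}


def build_model_matrix(glycans: Sequence[GlycanTree], panel: Panel) -> pd.DataFrame:
    """Raw (pre-normalization) model matrix: one column per candidate glycan,
    rows indexed by (condition, lectin)."""
    idx = panel.channel_index()
    cols = {}
    for g in glycans:
        treated = _treated_forms(g, panel)
        col = [predict_binding(treated[c.name], l, panel.binding_mode)
               for c in panel.conditions for l in panel.lectins]
        key = g.id or str(g)
        if key in cols:
            raise ValueError(f"duplicate glycan id {key!r}")
        cols[key] = col
    return pd.DataFrame(cols, index=idx, dtype=float)


def normalize_per_lectin(data: pd.DataFrame | pd.Series):
    """Divide each lectin's row block by the block maximum.

    For the model matrix the maximum is over all conditions and all glycans;
    for an observed vector it is over that lectin's conditions.  Blocks whose
    maximum is not positive are left unchanged (no division by zero), and the
    operation is idempotent.
    """
    out = data.astype(float).copy()
    lectins = out.index.get_level_values("lectin")
    for lec in lectins.unique():
        mask = lectins == lec
        block = out[mask]
        m = np.nanmax(block.to_numpy()) if block.size else 0.0
        if m > 0:
            out[mask] = block / m
    return out


def cluster_model_glycans(matrix: pd.DataFrame, cutoff: float) -> pd.Series:
    """Complete-linkage hierarchical clustering of glycan columns by
    Euclidean distance, flattened at ``cutoff``; labels are dense integers
    (0-based, in order of first appearance)."""
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    ids = list(matrix.columns)
    if len(ids) == 1:
        return pd.Series([0], index=ids, name="cluster")
    X = matrix.to_numpy().T
    Z = linkage(pdist(X, metric="euclidean"), method="complete")
    raw = fcluster(Z, t=cutoff, criterion="distance")
    remap: dict[int, int] = {}
    labels = []
    for r in raw:
        if r not in remap:
            remap[r] = len(remap)
        labels.append(remap[r])
    return pd.Series(labels, index=ids, name="cluster")


def restrict_candidates(
    glycans: Sequence[GlycanTree],
    allowed_compositions: Iterable[Composition | str] | None = None,
    allowed_masses: Iterable[float] | None = None,
    mass_table: MassTable = DEFAULT_MASS_TABLE,
    tolerance: float | None = None,
) -> list[GlycanTree]:
    """Keep candidates whose composition is in the allowed set, or whose
    computed mass lies within ``tolerance`` of any allowed mass.  Input order
    is preserved.  An empty *allowed* specification is an error; an empty
    *result* only warns."""
    comps = None
    if allowed_compositions is not None:
        comps = {c if isinstance(c, Composition) else Composition.from_string(c)
                 for c in allowed_compositions}
    masses = list(allowed_masses) if allowed_masses is not None else None
    if not comps and not masses:
        raise ValueError("allowed composition/mass set is empty")
    tol = mass_table.tolerance if tolerance is None else tolerance

    kept = []
    for g in glycans:
        comp = composition_of(g)
        ok = comps is not None and comp in comps
        if not ok and masses:
            m = mass_of(comp, mass_table)
            ok = any(abs(m - target) <= tol for target in masses)
        if ok:
            kept.append(g)
    if not kept:
        warnings.warn("no candidate glycans survived the mass/composition "
                      "restriction", stacklevel=2)
    return kept


def vector_correlation(v1, v2) -> float:
    """Pearson correlation between two response vectors; NaN (with a warning)
    when either vector is constant."""
    a = np.asarray(v1, dtype=float).ravel()
    b = np.asarray(v2, dtype=float).ravel()
    if a.shape != b.shape or a.size < 2:
        raise ValueError("vectors must share a length of at least 2")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("correlation undefined for a constant vector",
                      stacklevel=2)
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def motif_coverage(g: GlycanTree, panel: Panel) -> int:
    """Number of distinct residues of ``g`` evaluated by at least one lectin
    motif in at least one panel condition.

    Residue identity is tracked through digestion via node uids, so a residue
    probed only after enzymatic exposure still counts.  Used to pick the
    representative of a colinear candidate group.
    """
    covered: set[int] = set()
    for cond in panel.conditions:
        treated = apply_treatment(g, cond.enzymes)
        for lectin in panel.lectins:
            for motif, _score in lectin.entries:
                for mp in _match_mappings(treated, motif):
                    covered.update(n.uid for n in mp.values())
    return len(covered)
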