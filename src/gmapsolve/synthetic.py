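"""Seeded synthetic data: glycan libraries, lectin/enzyme panels, and
simulated spot-level observations.

The structure grammar mirrors the repertoire the method is designed to
discriminate: complex N-glycans with 2-4 antennae, per-arm choices of
sialic-acid linkage (a2-3 vs a2-6), galactose linkage (b1-3 vs b1-4) and
elongation state, optional core fucose and bisecting GlcNAc, plus core-1
O-glycans.  The bundled lectins and exoglycosidases are synthetic
specificity models patterned on the plant lectins and commercial
glycosidases commonly used on lectin arrays (a2-3 vs broad sialidase,
b1-3/b1-4 galactosidase, sialic-linkage/galactose/GlcNAc/mannose/fucose
binders); their binding scores are plausible placeholders, not values
derived from any glycan-array dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glycan_core import GlycanTree, canonical_form, parse_glycan
from .motif_enzyme import EnzymeSpec, LectinSpec, Motif
from .response_model import Condition, Panel
from .solver import SolverReport

__all__ = [
    "SimulationSpec",
    "build_n_glycan",
    "build_o_core1",
    "default_lectins",
    "default_enzymes",
    "default_panel",
    "triantennary_isomer_pair",
    "generate_library",
    "support_is_identifiable",
    "mixture_essential_margin",
    "draw_mixture",
    "clean_observation",
    "simulate_observation",
    "recovery_metrics",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Conditions of a simulated on-chip profiling experiment.

    Probabilities are per-arm (or per-glycan for core flags); noise_sd is
    the spot-level additive Gaussian sd as a fraction of the maximum clean
    channel value.  Replicate structure defaults to six spots per array and
    three replicate arrays, matching common contact-printed array layouts.
    """

    library_size: int = 50
    antenna_range: tuple[int, int] = (2, 4)
    p_gal_present: float = 0.9
    p_gal_b13: float = 0.25
    p_arm_sialylated: float = 0.7
    p_sialyl_a23: float = 0.5
    p_core_fucose: float = 0.3
    p_bisecting: float = 0.2
    p_o_glycan: float = 0.1
    support_size: int = 4
    dirichlet_alpha: float = 2.0
    noise_sd: float = 0.05
    n_spots: int = 6
    n_arrays: int = 3
    background: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_gal_present", "p_gal_b13", "p_arm_sialylated",
                     "p_sialyl_a23", "p_core_fucose", "p_bisecting",
                     "p_o_glycan"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# structure grammar

#: antenna index -> (linkage to its mannose, which alpha-mannose arm)
_ARM_SLOTS = {1: ("b1-2", "3"), 2: ("b1-2", "6"), 3: ("b1-4", "3"),
              4: ("b1-6", "6")}


def _arm_text(sial: str | None, gal: str | None, link: str) -> str:
    s = f"GlcNAc{link}"
    if gal is not None:
        s = f"Gal{gal}" + s
        if sial is not None:
            s = f"Neu5Ac{sial}" + s
    return s


def build_n_glycan(arms, core_fucose: bool = False,
                   bisecting: bool = False, id: str = "") -> GlycanTree:
    """Complex N-glycan from per-arm specs.

    ``arms`` is a sequence of up to four ``(sialic, galactose)`` pairs, e.g.
    ``("a2-6", "b1-4")``; either element may be None (no sialic acid / bare
    GlcNAc antenna).  Arms occupy the canonical antenna slots in order:
    b1-2 on Man a1-3, b1-2 on Man a1-6, b1-4 on Man a1-3, b1-6 on Man a1-6.
    """
    arms = list(arms)
    if not 0 <= len(arms) <= 4:
        raise ValueError("at most four antennae are supported")
    by_man: dict[str, list[str]] = {"3": [], "6": []}
    for slot, (sial, gal) in enumerate(arms, start=1):
        link, man = _ARM_SLOTS[slot]
        by_man[man].append(_arm_text(sial, gal, link))

    def man_text(man: str) -> str:
        parts = by_man[man]
        s = parts[0] if parts else ""
        for extra in parts[1:]:
            s += f"({extra})"
        return s + f"Mana1-{man}"

    text = (man_text("3") + f"({man_text('6')})"
            + ("(GlcNAcb1-4)" if bisecting else "")
            + "Manb1-4GlcNAcb1-4"
            + ("(Fuca1-6)" if core_fucose else "") + "GlcNAc")
    return parse_glycan(text, id=id)


def build_o_core1(sialylated: bool = False, id: str = "") -> GlycanTree:
    text = ("Neu5Aca2-3" if sialylated else "") + "Galb1-3GalNAc"
    return parse_glycan(text, id=id)


def triantennary_isomer_pair() -> tuple[GlycanTree, GlycanTree]:
    """Two triantennary N-glycan isomers differing only in the sialic-acid
    and galactose linkages of the third arm (a2-3/b1-4 vs a2-6/b1-3)."""
    a = build_n_glycan([("a2-6", "b1-4"), ("a2-3", "b1-4"), ("a2-3", "b1-4")],
                       id="tri_a23_b14")
    b = build_n_glycan([("a2-6", "b1-4"), ("a2-3", "b1-4"), ("a2-6", "b1-3")],
                       id="tri_a26_b13")
    return a, b


# ---------------------------------------------------------------------------
# panel fixtures

def default_enzymes() -> dict[str, EnzymeSpec]:
    e = EnzymeSpec.from_text
    return {
        "sialidase-a23": e("sialidase-a23", "Neu5Aca2-3Gal", "Gal"),
        "sialidase-broad": e("sialidase-broad", "Neu5Aca2-?Gal", "Gal"),
        "galactosidase-b13": e("galactosidase-b13", "Galb1-3GlcNAc", "GlcNAc"),
        "galactosidase-b14": e("galactosidase-b14", "Galb1-4GlcNAc", "GlcNAc"),
    }


def default_lectins(extended: bool = False) -> tuple[LectinSpec, ...]:
    def m(text: str, terminal: bool = False) -> Motif:
        return Motif.from_text(text, terminal_required=terminal)

    core = (
        LectinSpec("ConA-like", ((m("Mana1-3Man"), 0.6), (m("Mana1-6Man"), 0.6))),
        LectinSpec("MAL-like", ((m("Neu5Aca2-3Gal"), 0.85),)),
        LectinSpec("SNA-like", ((m("Neu5Aca2-6Gal"), 0.9),)),
        LectinSpec("ECL-like", ((m("Galb1-4GlcNAc", True), 0.8),)),
        LectinSpec("DSL-like", ((m("Galb1-4GlcNAc"), 0.55),)),
        LectinSpec("PHAL-like", ((m("GlcNAcb1-6Man"), 0.65),)),
        LectinSpec("GSL-like", ((m("GlcNAc", True), 0.75),)),
    )
    if not extended:
        return core
    return core + (
        LectinSpec("BPL-like", ((m("Galb1-3GlcNAc", True), 0.7),
                                (m("Galb1-3GalNAc", True), 0.5))),
        LectinSpec("SRL-like", ((m("Galb1-3GalNAc", True), 0.6),)),
        LectinSpec("AAL-like", ((m("Fuca1-6GlcNAc"), 0.7),)),
        LectinSpec("PHAE-like", ((m("GlcNAcb1-4Man"), 0.6),)),
    )


def default_panel(extended: bool = False) -> Panel:
    """The bundled profiling designs.

    The basic design is three conditions (untreated, a2-3 sialidase, broad
    sialidase) across seven lectins.  The extended design adds b1-3/b1-4
    galactosidase rounds after broad desialylation, and galactose-, GlcNAc-,
    fucose- and bisecting-sensitive lectins, to probe subterminal features.
    """
    enz = default_enzymes()
    conditions = [
        Condition("untreated"),
        Condition("sialidase-a23", (enz["sialidase-a23"],)),
        Condition("sialidase-broad", (enz["sialidase-broad"],)),
    ]
    if extended:
        conditions += [
            Condition("gal-b13", (enz["galactosidase-b13"],)),
            Condition("gal-b14", (enz["galactosidase-b14"],)),
            Condition("sialidase-a23+gal-b14",
                      (enz["sialidase-a23"], enz["galactosidase-b14"])),
            Condition("sialidase-broad+gal-b13",
                      (enz["sialidase-broad"], enz["galactosidase-b13"])),
            Condition("sialidase-broad+gal-b14",
                      (enz["sialidase-broad"], enz["galactosidase-b14"])),
        ]
    return Panel(tuple(conditions), default_lectins(extended))


# ---------------------------------------------------------------------------
# library generation

def _random_glycan(spec: SimulationSpec, rng: np.random.Generator) -> GlycanTree:
    if rng.random() < spec.p_o_glycan:
        return build_o_core1(sialylated=rng.random() < spec.p_arm_sialylated)
    lo, hi = spec.antenna_range
    n_arms = int(rng.integers(lo, hi + 1))
    arms = []
    for _ in range(n_arms):
        if rng.random() < spec.p_gal_present:
            gal = "b1-3" if rng.random() < spec.p_gal_b13 else "b1-4"
            sial = None
            if rng.random() < spec.p_arm_sialylated:
                sial = "a2-3" if rng.random() < spec.p_sialyl_a23 else "a2-6"
            arms.append((sial, gal))
        else:
            arms.append((None, None))
    return build_n_glycan(arms,
                          core_fucose=rng.random() < spec.p_core_fucose,
                          bisecting=rng.random() < spec.p_bisecting)


def generate_library(spec: SimulationSpec,
                     rng: np.random.Generator | None = None) -> list[GlycanTree]:
    """Unique (by canonical form) glycans drawn from the biosynthetic
    grammar; stops at ``library_size`` or the grammar's effective maximum."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    seen: dict[str, GlycanTree] = {}
    attempts = 0
    max_attempts = max(1000, 200 * spec.library_size)
    while len(seen) < spec.library_size and attempts < max_attempts:
        attempts += 1
        g = _random_glycan(spec, rng)
        key = canonical_form(g)
        if key not in seen:
            g.id = f"G{len(seen) + 1:03d}"
            seen[key] = g
    return list(seen.values())


def support_is_identifiable(matrix: pd.DataFrame, support: list[str],
                            tol: float = 1e-9) -> bool:
    """True when a mixture on ``support`` is the unique nonnegative exact
    representation of its own response vector.

    A support S is identifiable iff the columns of S are linearly
    independent and no direction z exists with Cz = 0 and z >= 0 outside S
    (i.e. cone(S) is a face of the candidate cone).  This is a property of
    the model matrix alone, independent of any solver: a non-identifiable
    mixture cannot be recovered exactly by any method.  Checked by linear
    programming.
    """
    import scipy.optimize

    ids = list(matrix.columns)
    C = matrix.to_numpy(dtype=float)
    in_s = np.array([g in set(support) for g in ids])
    CS = C[:, in_s]
    if np.linalg.matrix_rank(CS) < len(support):
        return False
    n = C.shape[1]
    # maximize sum of z outside S subject to Cz = 0, bounded box
    c = np.where(in_s, 0.0, -1.0)
    bounds = [(-1.0, 1.0) if s else (0.0, 1.0) for s in in_s]
    res = scipy.optimize.linprog(c, A_eq=C, b_eq=np.zeros(C.shape[0]),
                                 bounds=bounds, method="highs")
    return bool(res.success) and -res.fun <= tol


def mixture_essential_margin(matrix: pd.DataFrame, a: pd.Series) -> float:
    """Minimum R^2 cost of swapping one mixture component for any single
    substitute candidate.

    For each glycan g in the support of ``a``, the clean observed vector
    d = C a is refit (nonnegative least squares) over the remaining support
    columns, alone and augmented with each single non-support candidate in
    turn; the margin is the smallest residual sum of squares relative to
    the centered total sum of squares of d, over all such sparse
    alternatives.  A mixture whose margin is comparable to the array noise
    admits a near-equivalent sparse explanation without one of its
    components, which noise can then favor regardless of the solver — so
    noisy-recovery benchmarks require a floor on this quantity.
    """
    import scipy.optimize

    ids = list(matrix.columns)
    X = matrix.to_numpy(dtype=float)
    d = X @ a.reindex(ids).fillna(0.0).to_numpy()
    ss_tot = float(np.sum((d - d.mean()) ** 2))
    if ss_tot == 0:
        return 0.0
    support = list(a.index[a > 0])
    outside = [j for j, g in enumerate(ids) if g not in set(support)]
    worst = np.inf
    for g in support:
        keep = [ids.index(h) for h in support if h != g]
        _, rnorm = scipy.optimize.nnls(X[:, keep], d)
        best = float(rnorm) ** 2 / ss_tot
        for j in outside:
            _, rnorm = scipy.optimize.nnls(X[:, keep + [j]], d)
            best = min(best, float(rnorm) ** 2 / ss_tot)
        worst = min(worst, best)
    return worst


def draw_mixture(library: list[GlycanTree], spec: SimulationSpec,
                 rng: np.random.Generator | None = None,
                 matrix: pd.DataFrame | None = None,
                 min_weight: float = 0.1,
                 min_r2_margin: float = 0.02,
                 max_tries: int = 4000) -> pd.Series:
    """True relative abundances: a Dirichlet-weighted support of
    ``support_size`` glycans, summing to 1 over the library.

    When the normalized model matrix is supplied, draws are rejection
    sampled until three resolvability conditions hold: the support is
    exactly identifiable (:func:`support_is_identifiable`), every component
    weight exceeds ``min_weight`` (components below the solver's
    10%-inclusion reporting rule are not meaningful recovery targets), and
    every component is essential by at least ``min_r2_margin`` in R^2 terms
    against single-substitute sparse alternatives
    (:func:`mixture_essential_margin`; the default of 0.02 is several times
    the R^2-scale perturbation of replicate-averaged 5% spot noise).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    ids = [g.id for g in library]
    k = min(spec.support_size, len(ids))
    for _ in range(max_tries):
        chosen = rng.choice(len(ids), size=k, replace=False)
        support = [ids[int(i)] for i in chosen]
        weights = rng.dirichlet([spec.dirichlet_alpha] * k)
        if min_weight is not None and weights.min() < min_weight:
            continue
        a = pd.Series(0.0, index=ids, name="true_weight")
        for gid, w in zip(support, weights):
            a[gid] = float(w)
        if matrix is None:
            return a
        if not support_is_identifiable(matrix, support):
            continue
        if mixture_essential_margin(matrix, a) < min_r2_margin:
            continue
        return a
    raise RuntimeError("no resolvable mixture found; the panel does not "
                       "separate this candidate library")


# ---------------------------------------------------------------------------
# observations

def clean_observation(normalized_matrix: pd.DataFrame,
                      a_true: pd.Series) -> pd.Series:
    """Noise-free observed vector on the normalized-model scale."""
    a = a_true.reindex(normalized_matrix.columns).fillna(0.0)
    return pd.Series(normalized_matrix.to_numpy() @ a.to_numpy(),
                     index=normalized_matrix.index, name="observed")


def simulate_observation(normalized_matrix: pd.DataFrame, a_true: pd.Series,
                         spec: SimulationSpec,
                         rng: np.random.Generator | None = None,
                         protein: str = "sample") -> pd.DataFrame:
    """Spot-level quantification table for the mixture ``a_true``.

    Each (condition, lectin) channel yields ``n_arrays`` x ``n_spots``
    replicate spots whose net signal is the clean channel value plus
    additive Gaussian noise with sd ``noise_sd`` x max clean value; the
    constant mean local background is added back onto the median signal, so
    spot reduction recovers the clean vector exactly at zero noise.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    d_clean = clean_observation(normalized_matrix, a_true)
    scale = float(d_clean.max()) if len(d_clean) else 0.0
    sd = spec.noise_sd * scale
    rows = []
    for (condition, lectin), value in d_clean.items():
        for array in range(1, spec.n_arrays + 1):
            for spot in range(1, spec.n_spots + 1):
                noise = rng.normal(0.0, sd) if sd > 0 else 0.0
                rows.append({
                    "slide_id": "S1",
                    "array_id": f"A{array}",
                    "spot_id": f"{condition}|{lectin}|{array}|{spot}",
                    "protein": protein,
                    "lectin": lectin,
                    "condition": condition,
                    "median_signal": spec.background + value + noise,
                    "mean_background": spec.background,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# benchmarking

def recovery_metrics(a_true: pd.Series, report: SolverReport) -> dict[str, float]:
    """Precision/recall of the reported glycan set against the true support,
    and the Pearson correlation between true and reported weights over the
    union of both supports (zeros filled)."""
    true_support = set(a_true.index[a_true > 0])
    reported = set(report.table.index)
    tp = len(true_support & reported)
    precision = tp / len(reported) if reported else 0.0
    recall = tp / len(true_support) if true_support else 1.0
    union = sorted(true_support | reported)
    if len(union) < 2:
        corr = 1.0 if tp == len(union) == 1 else float("nan")
    else:
        t = a_true.reindex(union).fillna(0.0).to_numpy()
        r = report.mean_weights.reindex(union).fillna(0.0).to_numpy()
        if np.ptp(t) == 0 or np.ptp(r) == 0:
            corr = float("nan")
        else:
            corr = float(np.corrcoef(t, r)[0, 1])
    return {"precision": precision, "recall": recall,
            "weight_correlation": corr}
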