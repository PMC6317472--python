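"""Nonnegative least-squares deconvolution of observed lectin responses.

The observed response vector d (N channels) is modeled as a nonnegative
mixture of model response vectors: min ||C a - d||_2^2 with a >= 0, where C
is the N x M normalized model matrix.  The weights a are read as relative
glycan abundances.  Because structurally similar candidates produce similar
columns, the solver

1. collapses perfectly colinear (pairwise proportional) columns to a single
   representative — the glycan whose residues are most thoroughly evaluated
   by the panel's lectin motifs;
2. samples alternative fits by recursively excluding initially predicted
   glycans and refitting, accepting a refit when its R^2 is within a window
   of the initial fit and it uses at most a small number of additional
   glycans; and
3. reports, over all accepted fits, each glycan's inclusion frequency, mean
   weight, and contribution to the solution response vector, dropping
   glycans below an inclusion-frequency threshold.

:class:`GlycanDeconvolver` wraps the whole procedure as a scikit-learn-style
estimator (``fit(C, d)`` with fitted ``weights_``/``report_`` attributes);
the module-level functions are the primitives it composes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
from sklearn.base import BaseEstimator, RegressorMixin

from .glycan_core import GlycanTree
from .response_model import Panel, motif_coverage, vector_correlation

__all__ = [
    "SolverConfig",
    "FitResult",
    "SolverReport",
    "filter_colinear",
    "nnls_fit",
    "sample_alternatives",
    "make_report",
    "solution_fit_quality",
    "GlycanDeconvolver",
]


@dataclass(frozen=True)
class SolverConfig:
    """Tuning knobs of the alternative-fit sampler and report.

    r2_window
        A refit is acceptable if its R^2 is within this window below the
        initial fit's R^2.
    max_additional_glycans
        Acceptable refits may use at most this many glycans outside the
        initially predicted set.
    samples_per_glycan
        Total refit budget = this x |initial predicted set|.
    inclusion_threshold
        Glycans included in fewer than this fraction of accepted fits are
        dropped from the report.
    positive_weight_epsilon
        A glycan counts as "predicted" by a fit when its weight exceeds this.
    average_over
        'all' (default): reported weight is the mean over all accepted fits,
        zero-filled where the glycan is absent; 'containing': mean over only
        the fits that include it.
    """

    r2_window: float = 0.05
    max_additional_glycans: int = 2
    samples_per_glycan: int = 100
    inclusion_threshold: float = 0.10
    positive_weight_epsilon: float = 1e-8
    average_over: str = "all"

    def __post_init__(self) -> None:
        if self.r2_window < 0:
            raise ValueError("r2_window must be >= 0")
        if not (0 <= self.inclusion_threshold <= 1):
            raise ValueError("inclusion_threshold must be in [0, 1]")
        if self.samples_per_glycan < 1:
            raise ValueError("samples_per_glycan must be >= 1")
        if self.average_over not in ("all", "containing"):
            raise ValueError("average_over must be 'all' or 'containing'")


@dataclass(frozen=True)
class FitResult:
    weights: pd.Series            # nonnegative, indexed by glycan id
    residual_ss: float
    r2: float
    predicted: tuple[str, ...]    # glycan ids with weight > epsilon
    excluded: frozenset = field(default_factory=frozenset)


@dataclass
class SolverReport:
    table: pd.DataFrame           # index glycan id; frequency/weight/contribution
    mean_weights: pd.Series       # over all accepted fits, all glycans
    solution: pd.Series           # C @ mean_weights, on the channel index
    n_accepted: int
    initial_r2: float
    collapsed: Mapping[str, tuple[str, ...]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# colinearity filter

def filter_colinear(
    matrix: pd.DataFrame,
    glycans: Mapping[str, GlycanTree] | None = None,
    panel: Panel | None = None,
    tol: float = 1e-9,
) -> tuple[pd.DataFrame, dict[str, tuple[str, ...]]]:
    """Collapse groups of pairwise-proportional columns to one representative.

    Two columns are grouped when their cosine similarity is within ``tol``
    of 1 (or both are zero).  The representative is the glycan with the most
    residues covered by at least one lectin-motif match across the panel
    (requires ``glycans`` and ``panel``); ties break on total residue count,
    then on glycan id.  Returns the reduced matrix and a map
    representative -> collapsed group (including itself).
    """
    ids = list(matrix.columns)
    X = matrix.to_numpy(dtype=float)
    norms = np.linalg.norm(X, axis=0)
    unit = np.where(norms > 0, 1.0, np.nan)
    U = np.divide(X, norms, out=np.zeros_like(X), where=norms > 0)

    parent = list(range(len(ids)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if norms[i] == 0 and norms[j] == 0:
                same = True
            elif norms[i] == 0 or norms[j] == 0:
                same = False
            else:
                same = abs(float(U[:, i] @ U[:, j]) - 1.0) <= tol
            if same:
                parent[find(j)] = find(i)

    groups: dict[int, list[int]] = {}
    for i in range(len(ids)):
        groups.setdefault(find(i), []).append(i)

    def rank(i: int) -> tuple:
        gid = ids[i]
        cov = size = 0
        if glycans is not None and gid in glycans:
            g = glycans[gid]
            size = g.residue_count()
            if panel is not None:
                cov = motif_coverage(g, panel)
        return (-cov, -size, gid)

    keep: list[int] = []
    collapsed: dict[str, tuple[str, ...]] = {}
    for members in groups.values():
        rep = min(members, key=rank)
        keep.append(rep)
        collapsed[ids[rep]] = tuple(sorted(ids[m] for m in members))
    keep.sort()
    return matrix.iloc[:, keep], {ids[i]: collapsed[ids[i]] for i in keep}


# ---------------------------------------------------------------------------
# NNLS

def _r_squared(d: np.ndarray, residual_ss: float) -> float:
    ss_tot = float(np.sum((d - d.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if residual_ss <= 1e-12 else 0.0
    return 1.0 - residual_ss / ss_tot


def nnls_fit(C: pd.DataFrame | np.ndarray, d, epsilon: float = 1e-8,
             excluded: frozenset = frozenset()) -> FitResult:
    """Solve min ||C a - d||_2^2, a >= 0 (Lawson-Hanson via scipy)."""
    if isinstance(C, pd.DataFrame):
        ids = list(C.columns)
        X = C.to_numpy(dtype=float)
    else:
        X = np.asarray(C, dtype=float)
        ids = [str(j) for j in range(X.shape[1])]
    dv = np.asarray(d, dtype=float).ravel()
    if X.shape[0] != dv.shape[0]:
        raise ValueError(f"C has {X.shape[0]} rows but d has {dv.shape[0]}")
    if X.shape[1] == 0:
        a, rnorm = np.zeros(0), float(np.linalg.norm(dv))
    else:
        a, rnorm = scipy.optimize.nnls(X, dv)
    residual_ss = float(rnorm ** 2)
    weights = pd.Series(a, index=ids, name="weight")
    predicted = tuple(weights.index[weights > epsilon])
    return FitResult(weights, residual_ss, _r_squared(dv, residual_ss),
                     predicted, excluded)


# ---------------------------------------------------------------------------
# alternative-fit sampling

def sample_alternatives(C: pd.DataFrame, d, initial: FitResult,
                        cfg: SolverConfig = SolverConfig(),
                        stats: dict | None = None) -> list[FitResult]:
    """Deterministic depth-first sampling of alternative fits.

    Starting from the initial fit, each node excludes one not-yet-excluded
    initially predicted glycan (in descending initial-weight order, ties on
    id) and refits over the remaining candidates.  A refit is accepted when
    its R^2 is at least the initial R^2 minus ``r2_window`` and its predicted
    set uses at most ``max_additional_glycans`` glycans outside the initial
    predicted set; accepted fits are recursed into, to a depth of at most
    |initial predicted set|.  Exploration stops once the number of refits
    reaches ``samples_per_glycan`` x |initial predicted set|.  The returned
    collection always starts with the initial fit.
    """
    dv = np.asarray(d, dtype=float).ravel()
    p0 = sorted(initial.predicted,
                key=lambda gid: (-float(initial.weights[gid]), gid))
    accepted: list[FitResult] = [initial]
    if stats is not None:
        stats["n_refits"] = 0
        stats["budget"] = cfg.samples_per_glycan * len(p0)
    if not p0:
        return accepted
    budget = cfg.samples_per_glycan * len(p0)
    r2_floor = initial.r2 - cfg.r2_window
    initial_set = set(p0)
    refits = 0
    visited: set[frozenset] = set()

    def dfs(excluded: frozenset) -> bool:
        nonlocal refits
        for gid in p0:
            if gid in excluded:
                continue
            nxt = excluded | {gid}
            if nxt in visited:
                continue
            visited.add(nxt)
            if refits >= budget:
                return False
            sub = C.drop(columns=list(nxt))
            refits += 1
            fit = nnls_fit(sub, dv, cfg.positive_weight_epsilon, nxt)
            extra = sum(1 for g in fit.predicted if g not in initial_set)
            if fit.r2 >= r2_floor and extra <= cfg.max_additional_glycans:
                accepted.append(fit)
                if len(nxt) < len(p0):
                    if not dfs(nxt):
                        return False
        return True

    dfs(frozenset())
    if stats is not None:
        stats["n_refits"] = refits
    return accepted


# ---------------------------------------------------------------------------
# report

def make_report(accepted: Sequence[FitResult], matrix: pd.DataFrame,
                cfg: SolverConfig = SolverConfig(),
                clusters: pd.Series | None = None,
                collapsed: Mapping[str, tuple[str, ...]] | None = None) -> SolverReport:
    """Aggregate accepted fits into per-glycan statistics.

    Inclusion frequency is the fraction of accepted fits whose weight for
    the glycan exceeds epsilon; glycans below ``inclusion_threshold`` are
    dropped.  The reported weight is the mean over accepted fits (zero
    filled, or over containing fits only, per config).  The contribution of
    glycan i is mean_weight_i * ||column_i||_1 normalized over the reported
    glycans — the share of the solution response vector it explains.
    """
    if not accepted:
        raise ValueError("no accepted fits")
    ids = list(matrix.columns)
    eps = cfg.positive_weight_epsilon
    W = pd.DataFrame(0.0, index=range(len(accepted)), columns=ids)
    for k, fit in enumerate(accepted):
        W.loc[k, fit.weights.index] = fit.weights.to_numpy()

    included = W.gt(eps)
    freq = included.mean(axis=0)
    if cfg.average_over == "all":
        mean_w = W.mean(axis=0)
    else:
        mean_w = W.where(included).mean(axis=0).fillna(0.0)

    solution = pd.Series(matrix.to_numpy() @ mean_w.to_numpy(),
                         index=matrix.index, name="solution")

    keep = freq[freq >= cfg.inclusion_threshold].index
    l1 = matrix[keep].abs().sum(axis=0)
    raw_contrib = mean_w[keep] * l1
    total = float(raw_contrib.sum())
    contrib = raw_contrib / total if total > 0 else raw_contrib * 0.0

    table = pd.DataFrame({
        "inclusion_frequency": freq[keep],
        "mean_weight": mean_w[keep],
        "contribution": contrib,
    })
    if clusters is not None:
        table["cluster"] = clusters.reindex(keep)
    table = table.sort_values(["contribution", "inclusion_frequency"],
                              ascending=False, kind="mergesort")
    return SolverReport(table=table, mean_weights=mean_w, solution=solution,
                        n_accepted=len(accepted), initial_r2=accepted[0].r2,
                        collapsed=dict(collapsed or {}))


def solution_fit_quality(report: SolverReport, d) -> tuple[float, float]:
    """(Pearson r, R^2) between the solution response vector and d."""
    dv = np.asarray(d, dtype=float).ravel()
    sol = report.solution.to_numpy()
    if sol.shape != dv.shape:
        raise ValueError("solution vector and d differ in length")
    r = vector_correlation(sol, dv)
    r2 = _r_squared(dv, float(np.sum((sol - dv) ** 2)))
    return r, r2


# ---------------------------------------------------------------------------
# estimator facade

class GlycanDeconvolver(BaseEstimator, RegressorMixin):
    """Scikit-learn-style estimator for lectin-response deconvolution.

    ``fit(X, y)`` takes the normalized model matrix (DataFrame, one column
    per candidate glycan) as ``X`` and the observed response vector as
    ``y``; it runs colinearity filtering, the initial NNLS fit, the
    alternative-fit sampler, and report assembly.

    Parameters mirror :class:`SolverConfig`; ``collapse_colinear`` toggles
    the proportional-column filter.  ``glycans``/``panel``/``clusters`` are
    optional side information used for the colinear-representative choice
    and for cluster labels in the report.

    Fitted attributes: ``weights_`` (mean weights over accepted fits, one
    per input column, zeros for collapsed columns), ``report_``,
    ``accepted_``, ``initial_fit_``, ``r2_``, ``n_refits_``.
    """

    def __init__(self, r2_window: float = 0.05, max_additional_glycans: int = 2,
                 samples_per_glycan: int = 100, inclusion_threshold: float = 0.10,
                 positive_weight_epsilon: float = 1e-8, average_over: str = "all",
                 collapse_colinear: bool = True):
        self.r2_window = r2_window
        self.max_additional_glycans = max_additional_glycans
        self.samples_per_glycan = samples_per_glycan
        self.inclusion_threshold = inclusion_threshold
        self.positive_weight_epsilon = positive_weight_epsilon
        self.average_over = average_over
        self.collapse_colinear = collapse_colinear

    def _config(self) -> SolverConfig:
        return SolverConfig(
            r2_window=self.r2_window,
            max_additional_glycans=self.max_additional_glycans,
            samples_per_glycan=self.samples_per_glycan,
            inclusion_threshold=self.inclusion_threshold,
            positive_weight_epsilon=self.positive_weight_epsilon,
            average_over=self.average_over,
        )

    def fit(self, X, y, glycans: Mapping[str, GlycanTree] | None = None,
            panel: Panel | None = None, clusters: pd.Series | None = None):
        cfg = self._config()
        C = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
        dv = np.asarray(y, dtype=float).ravel()
        if C.shape[0] != dv.shape[0]:
            raise ValueError("X and y have incompatible shapes")

        if self.collapse_colinear:
            C_red, collapsed = filter_colinear(C, glycans, panel)
        else:
            C_red, collapsed = C, {c: (c,) for c in C.columns}

        initial = nnls_fit(C_red, dv, cfg.positive_weight_epsilon)
        stats: dict = {}
        accepted = sample_alternatives(C_red, dv, initial, cfg, stats)
        report = make_report(accepted, C_red, cfg, clusters, collapsed)

        self.columns_ = list(C.columns)
        self.initial_fit_ = initial
        self.accepted_ = accepted
        self.report_ = report
        self.r2_ = initial.r2
        self.n_refits_ = stats.get("n_refits", 0)
        self.refit_budget_ = stats.get("budget", 0)
        self.weights_ = report.mean_weights.reindex(self.columns_).fillna(0.0)
        return self

    def predict(self, X):
        """Solution response vector for a model matrix with the fitted
        columns (after colinearity collapse)."""
        C = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float),
                                                               columns=self.columns_)
        return C.to_numpy(dtype=float) @ self.weights_.reindex(C.columns).fillna(0.0).to_numpy()
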