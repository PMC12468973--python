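"""Ensemble feature selection with Shapley-value refinement.

The full two-stage selector: run the three binary metaheuristics on a
training table, keep every feature chosen by at least two of them (majority
vote), fit the wrapper classifier on the ensemble subset, rank those
features by mean absolute Shapley contribution, and keep the top-ranked
features whose cumulative share of total importance first reaches θ
(default 90%).

For the linear wrapper classifier the Shapley values have the exact closed
form φ_ij = w_j (x_ij − mean_j), so importances are deterministic; a
model-agnostic permutation sampler is provided behind the same interface
for nonlinear models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.svm import LinearSVC

from .metaheuristics import (
    ALGORITHMS,
    FitnessSpec,
    OptimizerConfig,
    make_fitness,
    run_multi,
)
from .table import SampleTable

__all__ = [
    "SelectionMask",
    "ImportanceVector",
    "majority_vote",
    "shap_importances",
    "permutation_shap_importances",
    "cumulative_select",
    "select_features",
    "SelectionReport",
]


@dataclass(frozen=True)
class SelectionMask:
    """Binary selection over a named feature namespace, with provenance."""

    mask: np.ndarray
    namespace: tuple[str, ...]
    provenance: str = "ensemble"
    votes: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))
        if self.mask.shape[0] != len(self.namespace):
            raise ValueError(
                f"mask length {self.mask.shape[0]} != namespace size {len(self.namespace)}"
            )

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())

    def selected_names(self) -> list[str]:
        return [n for n, m in zip(self.namespace, self.mask) if m]

    def is_subset_of(self, other: "SelectionMask") -> bool:
        return bool(np.all(~self.mask | other.mask))

    def to_dict(self) -> dict:
        d = {
            "provenance": self.provenance,
            "selected": self.selected_names(),
            "mask": self.mask.astype(int).tolist(),
        }
        if self.votes is not None:
            d["votes"] = np.asarray(self.votes).astype(int).tolist()
        return d


@dataclass(frozen=True)
class ImportanceVector:
    """Per-feature mean |Shapley contribution| and the descending ranking."""

    importances: np.ndarray
    namespace: tuple[str, ...]

    def __post_init__(self) -> None:
        imp = np.asarray(self.importances, dtype=float)
        if (imp < 0).any():
            raise ValueError("importances must be nonnegative")
        object.__setattr__(self, "importances", imp)

    @property
    def ranking(self) -> np.ndarray:
        """Indices sorted by descending importance; ties keep feature order."""
        # stable sort on negated values preserves original order among ties
        return np.argsort(-self.importances, kind="stable")


def majority_vote(masks: Sequence[SelectionMask], min_votes: int = 2) -> SelectionMask:
    """Keep each feature selected by at least ``min_votes`` input masks."""
    if not masks:
        raise ValueError("no masks to vote over")
    ns = masks[0].namespace
    for m in masks[1:]:
        if m.namespace != ns:
            raise ValueError("namespace mismatch between masks")
    votes = np.sum([m.mask.astype(int) for m in masks], axis=0)
    return SelectionMask(
        mask=votes >= min_votes, namespace=ns, provenance="ensemble", votes=votes
    )


def shap_importances(
    classifier, table: SampleTable, mask: SelectionMask
) -> ImportanceVector:
    """Exact linear Shapley importances of the masked features.

    For a fitted linear model with coefficients w, the Shapley value of
    feature j for sample i (background = the table itself) is
    φ_ij = w_j (x_ij − x̄_j); the importance is mean_i |φ_ij|.
    """
    coef = getattr(classifier, "coef_", None)
    if coef is None:
        raise ValueError("classifier must be fitted and expose coef_")
    x = table.df[mask.selected_names()].to_numpy(dtype=float)
    w = np.asarray(coef)
    if w.ndim == 2 and w.shape[0] > 1:
        # multiclass: aggregate |φ| over the one-vs-rest coefficient rows
        phi = np.abs(x - x.mean(axis=0))[:, :, None] * np.abs(w.T)[None, :, :]
        imp = phi.mean(axis=(0, 2))
    else:
        w = w.ravel()
        phi = w * (x - x.mean(axis=0))
        imp = np.abs(phi).mean(axis=0)
    return ImportanceVector(importances=imp, namespace=tuple(mask.selected_names()))


def permutation_shap_importances(
    predict: Callable[[np.ndarray], np.ndarray],
    table: SampleTable,
    mask: SelectionMask,
    n_permutations: int = 64,
    seed: int = 0,
) -> ImportanceVector:
    """Model-agnostic Shapley importances by permutation sampling.

    Monte-Carlo estimate over random feature orderings of the marginal
    contribution of each feature to ``predict`` (a scalar score function of
    the masked feature matrix), with the column mean as the background.
    Converges to the exact values for linear models.
    """
    rng = np.random.default_rng(seed)
    x = table.df[mask.selected_names()].to_numpy(dtype=float)
    n, d = x.shape
    bg = x.mean(axis=0)
    phi = np.zeros((n, d))
    for _ in range(n_permutations):
        order = rng.permutation(d)
        current = np.tile(bg, (n, 1))
        prev = predict(current)
        for j in order:
            current[:, j] = x[:, j]
            cur = predict(current)
            phi[:, j] += cur - prev
            prev = cur
    phi /= n_permutations
    return ImportanceVector(
        importances=np.abs(phi).mean(axis=0), namespace=tuple(mask.selected_names())
    )


def cumulative_select(importances: ImportanceVector, theta: float = 0.9) -> SelectionMask:
    """Keep top-ranked features until cumulative importance share reaches θ.

    Features are taken in descending importance; the feature whose addition
    first makes the cumulative share ≥ θ is included.  θ = 1 keeps every
    feature with nonzero importance.
    """
    if not 0 < theta <= 1:
        raise ValueError("theta must be in (0, 1]")
    total = importances.importances.sum()
    if total <= 0:
        raise ValueError("all importances are zero; no ranking possible")
    order = importances.ranking
    shares = importances.importances[order] / total
    cum = np.cumsum(shares)
    # first index where cumulative share reaches theta, inclusive
    k = int(np.searchsorted(cum, theta - 1e-12)) + 1
    if theta == 1.0:
        k = int((importances.importances[order] > 0).sum())
    mask = np.zeros(len(importances.namespace), dtype=bool)
    mask[order[:k]] = True
    return SelectionMask(mask=mask, namespace=importances.namespace, provenance="shap")


@dataclass
class SelectionReport:
    """Everything the two-stage selector produced, for audit and JSON."""

    algorithm_masks: dict[str, SelectionMask]
    traces: dict[str, list[float]]
    ensemble: SelectionMask
    importances: ImportanceVector
    final: SelectionMask
    theta: float

    def to_dict(self) -> dict:
        return {
            "theta": self.theta,
            "algorithms": {k: v.to_dict() for k, v in self.algorithm_masks.items()},
            "traces": self.traces,
            "ensemble": self.ensemble.to_dict(),
            "importances": {
                "namespace": list(self.importances.namespace),
                "values": self.importances.importances.tolist(),
            },
            "final": self.final.to_dict(),
        }


def select_features(
    table: SampleTable,
    opt_config: OptimizerConfig | None = None,
    fitness_spec: FitnessSpec | None = None,
    theta: float = 0.9,
    seed: int = 0,
) -> tuple[SelectionMask, SelectionReport]:
    """Run the full two-stage selector on one (training) table.

    Runs HHO, mGTO and ZOA on the wrapper fitness, majority-votes their best
    masks (≥ 2 of 3), fits the linear wrapper classifier on the ensemble
    subset, and refines it to the features carrying θ of the cumulative
    Shapley importance.  The final mask is restricted to the supplied table;
    callers enforce that this is a training split (per-fold selection is the
    leakage-safe mode).
    """
    opt_config = opt_config or OptimizerConfig()
    fitness_spec = fitness_spec or FitnessSpec()
    ns = tuple(table.feature_names)
    d = len(ns)
    fitness = make_fitness(table, fitness_spec)
    rng = np.random.default_rng(seed)
    algo_masks: dict[str, SelectionMask] = {}
    traces: dict[str, list[float]] = {}
    for name in ("hho", "mgto", "zoa"):
        cand, trace = ALGORITHMS[name](opt_config, fitness, d, seed=int(rng.integers(2**31 - 1)))
        algo_masks[name] = SelectionMask(mask=cand.mask, namespace=ns, provenance=name)
        traces[name] = trace
    ensemble = majority_vote(list(algo_masks.values()), min_votes=2)
    if ensemble.n_selected == 0:
        # degenerate total disagreement: fall back to the union so the
        # classifier has something to fit; provenance records the fallback
        union = np.any([m.mask for m in algo_masks.values()], axis=0)
        ensemble = SelectionMask(mask=union, namespace=ns, provenance="ensemble-union")
    clf = LinearSVC(C=fitness_spec.C, max_iter=fitness_spec.max_iter, random_state=fitness_spec.seed)
    clf.fit(table.df[ensemble.selected_names()].to_numpy(dtype=float), table.labels)
    importances = shap_importances(clf, table, ensemble)
    refined_local = cumulative_select(importances, theta)
    # lift the refined sub-namespace mask back onto the full namespace
    full = np.zeros(d, dtype=bool)
    sel_idx = np.flatnonzero(ensemble.mask)
    full[sel_idx[refined_local.mask]] = True
    final = SelectionMask(mask=full, namespace=ns, provenance="shap")
    report = SelectionReport(
        algorithm_masks=algo_masks,
        traces=traces,
        ensemble=ensemble,
        importances=importances,
        final=final,
        theta=theta,
    )
    return final, report
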