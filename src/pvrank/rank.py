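"""Leave-one-PV-out experiment design and AUC-drop importance ranking.

For n PVs, n + 1 PV sets are designed: the full set plus one set per PV
with that PV removed.  One seeded stay-level split is fixed and reused
across all sets, so AUC differences reflect the PV set and not the split.
A PV's importance for a disease is the AUC drop

    delta_p = AUC(all PVs) - AUC(all PVs minus p),

and PVs are ranked by delta descending (exact ties broken by canonical
catalog order; negative deltas are allowed and sort last).  Disease
relationships are compared by top-k overlap (shared count, Jaccard) and
Kendall tau over the full rankings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from .features import FeatureMatrix, impute_and_standardize
from .model import evaluate_split, make_split

__all__ = [
    "PVSetFamily",
    "AUCMatrix",
    "ImportanceRanking",
    "ComparisonReport",
    "design_pv_sets",
    "run_experiment_family",
    "rank_importance",
    "compare_diseases",
    "top1_frequencies",
]

ALL_SET_ID = "all"


def loo_set_id(pv: str) -> str:
    return f"minus_{pv}"


@dataclass
class PVSetFamily:
    """The full PV set plus one leave-one-out set per PV."""

    full_set: tuple[str, ...]
    loo_sets: list[tuple[str, ...]]
    ids: list[str]

    @property
    def n(self) -> int:
        return len(self.full_set)

    def sets(self) -> dict[str, tuple[str, ...]]:
        return {self.ids[0]: self.full_set} | dict(zip(self.ids[1:], self.loo_sets))


def design_pv_sets(pvs: tuple[str, ...] | list[str]) -> PVSetFamily:
    """n PVs -> n + 1 sets: the full set and each single-PV deletion."""
    pvs = tuple(pvs)
    if len(pvs) < 2:
        raise ValueError(f"need at least 2 PVs, got {len(pvs)}")
    if len(set(pvs)) != len(pvs):
        raise ValueError("duplicate PV names")
    loo = [tuple(p for p in pvs if p != omitted) for omitted in pvs]
    ids = [ALL_SET_ID] + [loo_set_id(p) for p in pvs]
    return PVSetFamily(full_set=pvs, loo_sets=loo, ids=ids)


@dataclass
class AUCMatrix:
    """(PV set) x (disease) grid of held-out AUCs from one experiment family."""

    values: pd.DataFrame  # index = set ids, columns = diseases
    split_seed: int
    missing: dict[tuple[str, str], str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="pv_set_id")

    @classmethod
    def from_csv(cls, path, split_seed: int = -1) -> "AUCMatrix":
        df = pd.read_csv(path, index_col="pv_set_id")
        return cls(values=df, split_seed=split_seed)


def run_experiment_family(
    matrix: FeatureMatrix,
    labels: pd.DataFrame,
    family: PVSetFamily,
    split_seed: int,
    train_fraction: float = 0.7,
    diseases: list[str] | None = None,
    l2_lambda: float = 1.0,
    tol: float = 1e-5,
    max_iter: int = 1000,
    solver: str = "auto",
) -> AUCMatrix:
    """Run the n + 1 experiments on one shared split.

    ``matrix`` is the raw (unstandardized) feature matrix over
    ``family.full_set``.  Imputation/standardization is fitted once on the
    training rows of the full matrix; leave-one-out sets are column
    restrictions of it (both transforms act column-wise, so this equals
    standardizing each restricted matrix separately).  Leave-one-out fits
    warm-start from the full-set fit with the omitted PV's coordinates
    removed, which changes nothing about the optimum (strictly concave
    objective) but speeds convergence.
    """
    if tuple(matrix.pv_set) != tuple(family.full_set):
        raise ValueError("feature matrix PV set does not match the family's full set")
    if diseases is None:
        diseases = [c for c in labels.columns if c != "stay_id"]
    train_idx, test_idx = make_split(len(matrix.stay_ids), train_fraction, split_seed)
    if matrix.scaler is None:
        matrix = impute_and_standardize(matrix, train_idx)

    grid = pd.DataFrame(
        np.nan, index=pd.Index(family.ids, name="pv_set_id"), columns=diseases
    )
    missing: dict[tuple[str, str], str] = {}

    results, full_fits = evaluate_split(
        matrix, labels, train_idx, test_idx, diseases=diseases, pv_set_id=ALL_SET_ID,
        l2_lambda=l2_lambda, tol=tol, max_iter=max_iter, solver=solver,
    )
    for r in results:
        if r.auc is None:
            missing[(ALL_SET_ID, r.disease)] = r.reason
        else:
            grid.loc[ALL_SET_ID, r.disease] = r.auc

    n_per_pv = len(matrix.columns) // len(family.full_set)
    for omitted, loo_pvs in zip(family.full_set, family.loo_sets):
        sub = matrix.select_pvs(loo_pvs)
        omit_pos = family.full_set.index(omitted)
        keep = np.ones(len(matrix.columns) + 1, dtype=bool)
        keep[1 + omit_pos * n_per_pv : 1 + (omit_pos + 1) * n_per_pv] = False
        warm = {d: f.weights[keep] for d, f in full_fits.items()}
        set_id = loo_set_id(omitted)
        results, _ = evaluate_split(
            sub, labels, train_idx, test_idx, diseases=diseases, pv_set_id=set_id,
            l2_lambda=l2_lambda, tol=tol, max_iter=max_iter, solver=solver,
            warm_starts=warm,
        )
        for r in results:
            if r.auc is None:
                missing[(set_id, r.disease)] = r.reason
            else:
                grid.loc[set_id, r.disease] = r.auc

    return AUCMatrix(
        values=grid,
        split_seed=split_seed,
        missing=missing,
        provenance={
            "train_fraction": train_fraction,
            "l2_lambda": l2_lambda,
            "n_pv_sets": len(family.ids),
            "n_diseases": len(diseases),
        },
    )


@dataclass
class ImportanceRanking:
    """Per-disease PV order with AUC-drop scores, best first."""

    disease: str
    ranking: list[tuple[str, float]]  # (pv, delta), delta non-increasing
    tie_rule: str = "canonical_order"

    @property
    def order(self) -> list[str]:
        return [pv for pv, _ in self.ranking]

    @classmethod
    def from_order(cls, disease: str, pvs: list[str]) -> "ImportanceRanking":
        """Build from a printed PV order with unknown delta values."""
        return cls(disease=disease, ranking=[(pv, math.nan) for pv in pvs], tie_rule="as_given")


def rank_importance(matrix: AUCMatrix, disease: str) -> ImportanceRanking:
    """Rank PVs for one disease by delta = AUC(all) - AUC(minus_pv)."""
    if disease not in matrix.values.columns:
        raise ValueError(f"disease {disease!r} not in AUC matrix")
    col = matrix.values[disease]
    pvs = [sid[len("minus_"):] for sid in matrix.values.index if sid.startswith("minus_")]
    needed = [ALL_SET_ID] + [loo_set_id(p) for p in pvs]
    absent = [sid for sid in needed if sid not in col.index or not np.isfinite(col[sid])]
    if absent:
        raise ValueError(f"missing AUC cells for disease {disease!r}: {absent}")
    auc_all = float(col[ALL_SET_ID])
    deltas = {pv: auc_all - float(col[loo_set_id(pv)]) for pv in pvs}
    canonical = {pv: i for i, pv in enumerate(pvs)}
    ordered = sorted(pvs, key=lambda pv: (-deltas[pv], canonical[pv]))
    return ImportanceRanking(disease=disease, ranking=[(pv, deltas[pv]) for pv in ordered])


@dataclass
class ComparisonReport:
    disease_a: str
    disease_b: str
    k: int
    shared_top_k: int
    jaccard_top_k: float
    kendall_tau: float

    def to_dict(self) -> dict:
        return {
            "disease_a": self.disease_a,
            "disease_b": self.disease_b,
            "k": self.k,
            "shared_top_k": self.shared_top_k,
            "jaccard_top_k": self.jaccard_top_k,
            "kendall_tau": self.kendall_tau,
        }


def compare_diseases(
    r_a: ImportanceRanking, r_b: ImportanceRanking, k: int = 3
) -> ComparisonReport:
    """Top-k overlap and full-ranking concordance between two diseases."""
    univ_a, univ_b = set(r_a.order), set(r_b.order)
    if univ_a != univ_b:
        raise ValueError("rankings cover different PV universes")
    n = len(univ_a)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    top_a, top_b = set(r_a.order[:k]), set(r_b.order[:k])
    shared = len(top_a & top_b)
    jaccard = shared / len(top_a | top_b)
    pos_b = {pv: i for i, pv in enumerate(r_b.order)}
    tau = float(kendalltau(np.arange(n), [pos_b[pv] for pv in r_a.order]).statistic)
    return ComparisonReport(
        disease_a=r_a.disease,
        disease_b=r_b.disease,
        k=k,
        shared_top_k=shared,
        jaccard_top_k=jaccard,
        kendall_tau=tau,
    )


def top1_frequencies(rankings: list[ImportanceRanking]) -> pd.Series:
    """How often each PV lands at rank 1 across a collection of rankings.

    Diagnostic for seed-resampling stability and for null calibration
    (with no planted signal, no PV should dominate rank 1).
    """
    if not rankings:
        raise ValueError("no rankings given")
    universe = rankings[0].order
    counts = pd.Series(0, index=sorted(universe), dtype=int)
    for r in rankings:
        counts[r.order[0]] += 1
    return counts / len(rankings)
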