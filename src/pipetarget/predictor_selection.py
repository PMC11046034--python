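"""Informative-predictor extraction via random-forest importance.

The proximity (nGene) predictor is the baseline. Promoter-interaction
and eQTL predictors are retained only when a random forest — trained to
separate clinical proof-of-concept targets from simulated negatives —
deems them at least as important as the baseline: importance is the
out-of-bag permutation decrease in accuracy, the retention rule compares
median importance across seeded replicates against the nGene median.
The forest is purely a filter; final scoring stays unsupervised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

logger = logging.getLogger(__name__)

try:  # regenerating per-tree bootstrap masks needs these internals
    from sklearn.ensemble._forest import (
        _generate_unsampled_indices,
        _get_n_samples_bootstrap,
    )
    _HAVE_OOB_INTERNALS = True
except ImportError:  # pragma: no cover
    _HAVE_OOB_INTERNALS = False

from pipetarget.network_propagation import AffinityPredictor


@dataclass
class ImportanceReport:
    """Per-predictor importance replicates and retention decisions.

    ``importances`` is a (n_reps x J) frame, one column per predictor
    keyed ``dataset_id|evidence_type``; ``retained`` flags predictors
    whose median importance reaches the nGene baseline median.
    """

    predictors: list[tuple[str, str]]  # (dataset_id, evidence_type)
    importances: pd.DataFrame
    retained: dict[tuple[str, str], bool]

    def to_frame(self) -> pd.DataFrame:
        med = self.importances.median(axis=0)
        return pd.DataFrame({
            "dataset_id": [p[0] for p in self.predictors],
            "evidence_type": [p[1] for p in self.predictors],
            "median_importance": [med[f"{d}|{e}"] for d, e in self.predictors],
            "retained": [self.retained[p] for p in self.predictors],
        })


@dataclass
class GenePredictorMatrix:
    """Genes x retained predictors matrix of affinity scores."""

    genes: list[str]
    predictors: list[tuple[str, str]]
    af: np.ndarray  # shape (K, J)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.af, index=self.genes,
            columns=[f"{d}|{e}" for d, e in self.predictors])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenePredictorMatrix":
        preds = [tuple(c.split("|", 1)) for c in df.columns]
        return cls(genes=list(df.index), predictors=preds, af=df.values.astype(float))


def _oob_permutation_importance(
    rf: RandomForestClassifier, X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Mean decrease in OOB accuracy per feature, averaged over trees."""
    n, p = X.shape
    n_boot = _get_n_samples_bootstrap(n, rf.max_samples, None)
    drops = np.zeros(p)
    counts = np.zeros(p)
    for tree in rf.estimators_:
        oob = _generate_unsampled_indices(tree.random_state, n, n_boot, None)
        if len(oob) == 0:
            continue
        Xo, yo = X[oob], y[oob]
        base = np.mean(tree.predict(Xo) == yo)
        for j in range(p):
            Xp = Xo.copy()
            Xp[:, j] = Xp[rng.permutation(len(oob)), j]
            drops[j] += base - np.mean(tree.predict(Xp) == yo)
            counts[j] += 1
    counts[counts == 0] = 1
    return drops / counts


def assess_importance(
    predictors: list[AffinityPredictor],
    labels: dict[str, str],
    n_trees: int = 1000,
    n_reps: int = 10,
    seed: int = 0,
) -> ImportanceReport:
    """Rank predictor importance for separating positives from negatives.

    Fits a random forest on the affinity matrix restricted to labeled
    genes and measures each predictor's out-of-bag permutation decrease
    in accuracy, repeated ``n_reps`` times with derived seeds. Retained:
    every nGene predictor, plus any predictor whose median importance is
    at least the nGene baseline median. Deterministic given ``seed``.
    """
    genes = sorted(g for g, l in labels.items())
    y = np.array([1 if labels[g] == "positive" else 0 for g in genes])
    if y.sum() < 1 or (len(y) - y.sum()) < 1:
        raise ValueError("both a positive and a negative class are required")
    X = np.column_stack([p.vector(genes) for p in predictors])
    keys = [(p.dataset_id, p.evidence_type) for p in predictors]
    cols = [f"{d}|{e}" for d, e in keys]
    rows = []
    for rep in range(n_reps):
        rep_seed = (seed + 7919 * rep) % (2**31 - 1)
        # max_features=1 decorrelates importance across redundant
        # predictors: every predictor gets split opportunities, so
        # permutation importance reflects each one's own signal
        rf = RandomForestClassifier(
            n_estimators=n_trees, oob_score=False, bootstrap=True,
            max_features=1, random_state=rep_seed, n_jobs=1)
        rf.fit(X, y)
        rng = np.random.default_rng(rep_seed)
        if _HAVE_OOB_INTERNALS:
            imp = _oob_permutation_importance(rf, X, y, rng)
        else:  # pragma: no cover - fallback for sklearn without internals
            from sklearn.inspection import permutation_importance
            imp = permutation_importance(
                rf, X, y, n_repeats=5, random_state=rep_seed).importances_mean
        rows.append(imp)
    importances = pd.DataFrame(np.array(rows), columns=cols)
    med = importances.median(axis=0)
    ngene_keys = [k for k in keys if k[1] == "nGene"]
    if not ngene_keys:
        raise ValueError("an nGene baseline predictor is required")
    baseline = max(med[f"{d}|{e}"] for d, e in ngene_keys)
    retained = {
        k: (k[1] == "nGene") or (med[f"{k[0]}|{k[1]}"] >= baseline)
        for k in keys
    }
    return ImportanceReport(predictors=keys, importances=importances, retained=retained)


def build_matrix(
    predictors: list[AffinityPredictor],
    report: ImportanceReport | None = None,
) -> GenePredictorMatrix:
    """Assemble the gene-predictor matrix over all network genes.

    Columns are the retained predictors (all, if no report is given);
    rows the union of genes appearing in any predictor, so peripheral
    genes with purely propagated affinity are included. Missing
    affinities are zero. Matrix assembly itself is label-independent.
    """
    if report is not None:
        kept = [p for p in predictors
                if report.retained.get((p.dataset_id, p.evidence_type), False)]
        if all(p.evidence_type == "nGene" for p in kept):
            logger.warning("no cGene/eGene predictor retained; proceeding with nGene alone")
    else:
        kept = list(predictors)
    if not kept:
        raise ValueError("no predictor retained")
    genes = sorted(set().union(*(p.affinity.keys() for p in kept)))
    af = np.column_stack([p.vector(genes) for p in kept])
    keep_cols = [j for j in range(af.shape[1]) if af[:, j].any()]
    if len(keep_cols) < af.shape[1]:
        logger.warning("dropping %d all-zero predictor columns", af.shape[1] - len(keep_cols))
    kept = [kept[j] for j in keep_cols]
    af = af[:, keep_cols]
    return GenePredictorMatrix(
        genes=genes,
        predictors=[(p.dataset_id, p.evidence_type) for p in kept],
        af=af,
    )
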