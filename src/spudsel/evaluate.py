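"""Cross-validated prediction accuracy, bias, and the sqrt(h2) ceiling."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import gs
from .gs import GSConfig


@dataclass
class CVResult:
    """k-fold cross-validation summary for one trait/model combination.

    ``fold_assignments`` maps each sample to its fold (1..k); every sample is
    predicted exactly once, from the model trained on the other folds.
    Accuracy is the Pearson correlation of held-out GEBVs with phenotypes,
    averaged over folds with SE = sd(fold accuracies)/sqrt(k).  The bias
    slope regresses observed phenotypes on the pooled out-of-fold GEBVs:
    1 = unbiased, > 1 = underprediction.
    """

    fold_assignments: np.ndarray
    fold_accuracies: np.ndarray
    mean_accuracy: float
    se_accuracy: float
    bias_slope: float
    pooled_gebvs: np.ndarray

    def to_dict(self) -> dict:
        return {
            "fold_accuracies": self.fold_accuracies.tolist(),
            "mean_accuracy": self.mean_accuracy,
            "se_accuracy": self.se_accuracy,
            "bias_slope": self.bias_slope,
        }


def kfold_cv(
    Z: np.ndarray,
    y: np.ndarray,
    config: GSConfig,
    k: int = 5,
    seed: int = 0,
    loci: pd.DataFrame | None = None,
) -> CVResult:
    """Random balanced k-fold cross-validation of a genomic prediction model.

    The population is split into k groups of near-equal size (differing by at
    most one); each group is predicted from a model fitted on the remaining
    groups.  ``seed`` controls the partition; the chain seed lives in
    ``config``.
    """
    Z = np.asarray(Z, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    n = len(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError("need at least k samples")
    if Z.shape[0] != n:
        raise ValueError("Z rows must match y length")
    rng = np.random.default_rng(seed)
    folds = np.array_split(rng.permutation(n), k)
    assignments = np.zeros(n, dtype=int)
    pooled = np.full(n, np.nan)
    accuracies = np.zeros(k)
    for f, test_idx in enumerate(folds, start=1):
        assignments[test_idx] = f
        y_test = y[test_idx]
        if np.ptp(y_test) == 0:
            raise ValueError(f"fold {f} has constant phenotype; accuracy undefined")
        train = np.setdiff1d(np.arange(n), test_idx)
        if np.ptp(y[train]) == 0:
            raise ValueError(f"training complement of fold {f} has constant phenotype")
        fit_res = gs.fit(Z[train], y[train], config, loci=loci, keep_trace=False)
        gebv = gs.predict(fit_res, Z[test_idx])
        pooled[test_idx] = gebv
        accuracies[f - 1] = float(np.corrcoef(gebv, y_test)[0, 1])
    mean_acc = float(accuracies.mean())
    se_acc = float(accuracies.std(ddof=1) / np.sqrt(k))
    slope = bias_slope(y, pooled)
    return CVResult(
        fold_assignments=assignments,
        fold_accuracies=accuracies,
        mean_accuracy=mean_acc,
        se_accuracy=se_acc,
        bias_slope=slope,
        pooled_gebvs=pooled,
    )


def bias_slope(observed: np.ndarray, predicted: np.ndarray) -> float:
    """OLS slope of observed phenotype on predicted GEBV.

    1 means no bias; slopes above 1 mean the spread of GEBVs is too small,
    i.e. underprediction (shrinkage); below 1, overprediction.
    """
    observed = np.asarray(observed, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if len(observed) != len(predicted) or len(observed) < 3:
        raise ValueError("need equal-length vectors with at least 3 entries")
    if np.ptp(predicted) == 0:
        raise ValueError("predicted values are constant; slope undefined")
    return float(stats.linregress(predicted, observed).slope)


def max_potential_accuracy(h2: float) -> float:
    """The accuracy ceiling sqrt(h2) of a genomic prediction model.

    The correlation between GEBV and phenotype cannot exceed the correlation
    between the true genetic value and the phenotype, which is sqrt(h2).
    Report rounded to 2 decimals when formatting.
    """
    if not 0 <= h2 <= 1:
        raise ValueError("h2 must lie in [0, 1]")
    return float(np.sqrt(h2))
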