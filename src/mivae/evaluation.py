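"""Evaluation protocol: kappa, 10x10 cross-validation, diagnostics, sweeps.

Cohen's kappa for a balanced two-class task is the chance-corrected
accuracy (acc - rand)/(1 - rand) with rand = 0.5.  The cross-validation
scheme draws, for each of 10 repeats, a fresh stratified random 10-fold
partition (90% train / 10% test), yielding a 10x10 matrix of per-fold
kappas.  Summaries report both the standard deviation across the 10
repeat-means and across all 100 folds.

Diagnostics: a Lilliefors-style Kolmogorov-Smirnov normality test (Gaussian
reference with sample-estimated moments) and one-way ANOVA across methods
with pairwise p-values.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.diagnostic import lilliefors

from .representation import ImageSet

__all__ = [
    "CvScheme",
    "CvResults",
    "kappa",
    "cross_validate",
    "ks_normality",
    "anova_methods",
    "sweep",
]

logger = logging.getLogger(__name__)


def kappa(acc: float, rand: float = 0.5) -> float:
    """Chance-corrected accuracy (acc - rand)/(1 - rand).

    ``rand`` defaults to 1/n_classes = 0.5 for the balanced two-class task.
    """
    if not 0.0 <= acc <= 1.0:
        raise ValueError(f"acc must be in [0, 1], got {acc}")
    if not 0.0 <= rand < 1.0:
        raise ValueError(f"rand must be in [0, 1), got {rand}")
    return (acc - rand) / (1.0 - rand)


@dataclass(frozen=True)
class CvScheme:
    n_repeats: int = 10
    n_folds: int = 10
    seed: int = 0
    rand_accuracy: float = 0.5

    def __post_init__(self) -> None:
        if self.n_repeats < 1 or self.n_folds < 2:
            raise ValueError("need n_repeats >= 1 and n_folds >= 2")


@dataclass
class CvResults:
    """Per-fold kappa bookkeeping for a repeated k-fold run."""

    kappa_matrix: np.ndarray  # n_repeats x n_folds
    scheme: CvScheme

    @property
    def repeat_means(self) -> np.ndarray:
        return self.kappa_matrix.mean(axis=1)

    @property
    def mean(self) -> float:
        return float(self.repeat_means.mean())

    @property
    def sd_repeats(self) -> float:
        """Std dev across the repeat means (the headline +/- figure)."""
        return float(self.repeat_means.std(ddof=1)) if len(self.repeat_means) > 1 else 0.0

    @property
    def sd_folds(self) -> float:
        """Std dev across all individual folds."""
        return float(self.kappa_matrix.std(ddof=1))

    @property
    def sem_folds(self) -> float:
        flat = self.kappa_matrix.ravel()
        return float(flat.std(ddof=1) / np.sqrt(flat.size))

    def summary(self) -> dict:
        return {
            "mean_kappa": self.mean,
            "sd_repeats": self.sd_repeats,
            "sd_folds": self.sd_folds,
            "n_folds_total": int(self.kappa_matrix.size),
        }


def cross_validate(
    model_factory: Callable[[int], object],
    data: ImageSet,
    scheme: CvScheme,
) -> CvResults:
    """Repeated stratified k-fold kappa of ``model_factory`` products.

    ``model_factory(seed)`` must return an estimator with
    ``fit(ImageSet)`` and ``predict(ImageSet) -> labels`` (or
    ``(labels, probs)``).  Each repeat uses a fresh random partition; folds
    are stratified by class so a balanced 400-trial session always yields
    180/180 training splits of 360 trials.
    """
    n = len(data)
    if n < scheme.n_folds:
        raise ValueError(f"need at least {scheme.n_folds} trials, got {n}")
    labels = np.asarray(data.labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("cross-validation requires both classes present")
    mat = np.zeros((scheme.n_repeats, scheme.n_folds))
    for r in range(scheme.n_repeats):
        skf = StratifiedKFold(
            n_splits=scheme.n_folds, shuffle=True, random_state=scheme.seed + r
        )
        for f, (train_idx, test_idx) in enumerate(skf.split(np.zeros(n), labels)):
            model = model_factory(scheme.seed + 1000 * r + f)
            model.fit(data.subset(train_idx))
            pred = model.predict(data.subset(test_idx))
            if isinstance(pred, tuple):
                pred = pred[0]
            acc = float(np.mean(np.asarray(pred) == labels[test_idx]))
            mat[r, f] = kappa(acc, scheme.rand_accuracy)
    return CvResults(kappa_matrix=mat, scheme=scheme)


def ks_normality(samples: Sequence[float]) -> tuple[float, float]:
    """KS test against a Gaussian with sample-estimated mean and sd.

    Uses the Lilliefors correction (the reference distribution's moments
    are estimated from the data), so the null rejection rate is calibrated
    at the nominal level.  Returns (statistic, p-value).
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or len(x) < 8:
        raise ValueError("ks_normality needs a 1-D sample with n >= 8")
    if x.std() == 0:
        raise ValueError("degenerate (zero-variance) sample")
    stat, p = lilliefors(x, dist="norm", pvalmethod="table")
    return float(stat), float(p)


def anova_methods(results: Mapping[str, Sequence[float]]) -> dict:
    """One-way ANOVA omnibus p plus all pairwise two-method p-values.

    Returns ``{"omnibus_p": float, "omnibus_F": float, "pairwise":
    DataFrame}`` where the pairwise table is symmetric with NaN diagonal.
    """
    names = list(results)
    if len(names) < 2:
        raise ValueError("need at least two methods")
    groups = [np.asarray(results[k], dtype=float) for k in names]
    for name, g in zip(names, groups):
        if len(g) < 2:
            raise ValueError(f"method {name!r} has fewer than 2 values")
    def _f_test(*gs) -> tuple[float, float]:
        f_stat, p = stats.f_oneway(*gs)
        # floating cancellation can make a zero between-group variance
        # marginally negative, for which the F survival function is NaN
        if not np.isfinite(f_stat) or f_stat < 0:
            return 0.0, 1.0
        return float(f_stat), float(p)

    f_stat, p = _f_test(*groups)
    pair = pd.DataFrame(np.nan, index=names, columns=names)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i < j:
                _, pij = _f_test(groups[i], groups[j])
                pair.loc[a, b] = pair.loc[b, a] = pij
    return {"omnibus_F": f_stat, "omnibus_p": p, "pairwise": pair}


def sweep(
    harness: str,
    grid: Sequence,
    data: ImageSet,
    scheme: CvScheme,
    config_factory: Callable[[object], object],
    model_factory: Callable[[object, int], object],
) -> pd.DataFrame:
    """Cross-validate over a parameter grid (training epochs or kernel width).

    ``config_factory(value)`` builds the configuration for one setting (it
    may raise ValueError for invalid combinations, which are skipped with a
    logged reason); ``model_factory(config, seed)`` builds the per-fold
    estimator.  Returns one row per completed setting with the mean kappa
    and the mean wall-clock training time per fold (reported, never
    asserted).
    """
    if harness not in ("epochs", "kernel_width"):
        raise ValueError(f"unknown sweep harness {harness!r}")
    rows = []
    for value in grid:
        try:
            cfg = config_factory(value)
        except ValueError as exc:
            logger.warning("sweep: skipping %s=%r: %s", harness, value, exc)
            continue
        t0 = time.perf_counter()
        res = cross_validate(lambda seed: model_factory(cfg, seed), data, scheme)
        elapsed = time.perf_counter() - t0
        rows.append(
            {
                harness: value,
                "mean_kappa": res.mean,
                "sd_repeats": res.sd_repeats,
                "mean_train_time_s": elapsed / res.kappa_matrix.size,
            }
        )
    return pd.DataFrame(rows)
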