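"""Noise thresholding of log2 expression signals.

The distribution of log2 signals on an array is modelled as a Gaussian
mixture; the lowest-mean component is taken as the model of noise and the
remaining components as models of low and high expressed signals. The
expression threshold is the smallest signal at which the posterior
probability of the noise component drops below one half (posterior
crossover against the union of the other components).

Genes whose mean replicate signal exceeds the threshold of at least one
experimental group are "expressed"; the complement carries the below-noise
("nl") flag downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .gmm import InputError, Mixture1D, select_gmm_1d

__all__ = [
    "NoiseModelResults",
    "SignalNoiseModel",
    "noise_threshold",
    "call_expressed",
]


def noise_threshold(mixture: Mixture1D, tol: float = 1e-6) -> float:
    """Posterior-0.5 crossover threshold of the lowest-mean component.

    Returns the smallest x >= means[0] where the posterior probability of
    the noise (lowest-mean) component falls below 0.5, located by bracketed
    root search to ``tol``. If the posterior is already below 0.5 at the
    noise mean, the noise mean itself is returned.

    Raises
    ------
    InputError
        For single-component models, where no crossover exists.
    """
    if mixture.k < 2:
        raise InputError("noise threshold requires a mixture with K >= 2 components")

    def f(x: float) -> float:
        post = mixture.posteriors(x)[0]
        return post[0] - 0.5

    lo = float(mixture.means[0])
    if f(lo) <= 0.0:
        return lo
    # march right until the noise posterior has dropped below 0.5; beyond the
    # top component's mean + a few sds it must have (weights are non-zero)
    hi = float(mixture.means[-1] + 10.0 * mixture.sds[-1])
    step = max(mixture.sds[0], 1e-3)
    x = lo
    while x < hi and f(x) > 0.0:
        x += step
    if f(x) > 0.0:
        raise InputError("no posterior crossover found above the noise mean")
    return float(brentq(f, x - step, x, xtol=tol))


@dataclass
class NoiseModelResults:
    """Fitted per-dataset noise model: mixture parameters plus threshold."""

    mixture: Mixture1D
    threshold: float
    label: str = ""

    @property
    def k(self) -> int:
        return self.mixture.k

    @property
    def weights(self) -> np.ndarray:
        return self.mixture.weights

    @property
    def means(self) -> np.ndarray:
        return self.mixture.means

    @property
    def sds(self) -> np.ndarray:
        return self.mixture.sds

    @property
    def bic(self) -> float:
        return self.mixture.bic

    @property
    def loglik(self) -> float:
        return self.mixture.loglik

    def summary(self) -> pd.DataFrame:
        """One row per component plus the derived threshold."""
        df = pd.DataFrame(
            {
                "component": np.arange(1, self.k + 1),
                "weight": self.weights,
                "mean_log2": self.means,
                "sd_log2": self.sds,
            }
        )
        df["role"] = ["noise"] + ["signal"] * (self.k - 1)
        df.attrs["threshold_log2"] = self.threshold
        df.attrs["bic"] = self.bic
        df.attrs["label"] = self.label
        return df


class SignalNoiseModel:
    """Gaussian-mixture model of a log2 signal distribution.

    Parameters
    ----------
    values : array-like
        Pooled log2 signals of one experimental group (all replicate
        arrays of one cell type x condition).
    label : str
        Optional dataset label carried into the results.
    """

    def __init__(self, values, label: str = ""):
        self.values = np.asarray(values, dtype=float).ravel()
        self.label = label

    def fit(self, k_range: tuple[int, int] = (2, 5), seed: int = 0,
            n_init: int = 5) -> NoiseModelResults:
        """EM fit for each K in ``k_range`` (min >= 2), minimum-BIC model kept,
        threshold derived by posterior crossover."""
        if k_range[0] < 2:
            raise InputError("k_range min must be >= 2 for noise modelling")
        mixture = select_gmm_1d(self.values, k_range, seed=seed, n_init=n_init)
        return NoiseModelResults(
            mixture=mixture, threshold=noise_threshold(mixture), label=self.label
        )


def call_expressed(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    thresholds: dict[str, float],
) -> pd.DataFrame:
    """Flag genes above the noise threshold per group and anywhere.

    Parameters
    ----------
    matrix : DataFrame
        Genes x samples log2 signals; columns are sample ids.
    design : DataFrame
        Columns ``sample_id``, ``cell_type``, ``condition``, ``replicate``.
        A group is one ``cell_type:condition`` pair.
    thresholds : dict
        Group name -> log2 threshold; every design group must be present.

    Returns
    -------
    DataFrame indexed by gene with one boolean ``above_noise:<group>``
    column per group and ``expressed_anywhere`` (their OR: a gene counts as
    expressed when it exceeds the threshold in at least one group).
    """
    groups = _group_samples(design)
    missing = [g for g in groups if g not in thresholds]
    if missing:
        raise KeyError(f"missing noise thresholds for groups: {missing}")
    out = pd.DataFrame(index=matrix.index)
    for group, samples in groups.items():
        group_mean = matrix[samples].mean(axis=1)
        out[f"above_noise:{group}"] = group_mean > thresholds[group]
    out["expressed_anywhere"] = out.any(axis=1)
    return out


def _group_samples(design: pd.DataFrame) -> dict[str, list[str]]:
    """Map group name 'cell:condition' -> ordered sample id list."""
    groups: dict[str, list[str]] = {}
    for _, row in design.iterrows():
        key = f"{row['cell_type']}:{row['condition']}"
        groups.setdefault(key, []).append(row["sample_id"])
    return groups
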