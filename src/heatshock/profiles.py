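"""Clustering of temperature-response profiles by multivariate Gaussian
mixtures.

Each gene contributes a short profile vector (for instance its SLR at 38C
and at 43C, or its group means); profiles are clustered with a
full-covariance Gaussian mixture, the number of clusters chosen by BIC over
a coarse-then-refined grid. Cluster ids are reported 1..K ordered by
descending size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .gmm import FitError, InputError

__all__ = ["ProfileClusterModel", "ClusterResults"]


@dataclass
class ClusterResults:
    """Cluster assignment plus per-cluster summaries."""

    labels: pd.Series  # gene -> cluster id (1..K, by descending size)
    means: np.ndarray  # (K, d) cluster centroids in label order
    covariances: np.ndarray  # (K, d, d)
    k: int
    bic: float
    loglik: float

    @property
    def sizes(self) -> np.ndarray:
        return np.asarray(
            [(self.labels == c).sum() for c in range(1, self.k + 1)], dtype=int
        )

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "cluster": np.arange(1, self.k + 1),
                "size": self.sizes,
            }
        )
        for j in range(self.means.shape[1]):
            df[f"centroid_{j}"] = self.means[:, j]
        df.attrs["bic"] = self.bic
        df.attrs["k"] = self.k
        return df


class ProfileClusterModel:
    """Multivariate Gaussian-mixture model of per-gene response profiles.

    Parameters
    ----------
    profiles : DataFrame
        Genes x dimensions; NaNs are rejected. One-dimensional input must
        be acknowledged with ``allow_1d=True``.
    """

    def __init__(self, profiles: pd.DataFrame, allow_1d: bool = False):
        if profiles.isna().to_numpy().any():
            raise InputError("profiles contain NaNs")
        if profiles.shape[1] < 2 and not allow_1d:
            raise InputError("profiles have < 2 dimensions; pass allow_1d=True")
        self.profiles = profiles

    def fit(self, k_range: tuple[int, int] = (2, 100), seed: int = 0,
            n_init: int = 5) -> ClusterResults:
        """EM over a geometric coarse grid of K in ``k_range`` followed by a
        refinement around the coarse winner; minimum BIC wins."""
        x = self.profiles.to_numpy(dtype=float)
        n = x.shape[0]
        k_min, k_max = int(k_range[0]), int(k_range[1])
        k_max = min(k_max, n // 10)  # >= 10 genes per candidate cluster
        if k_max < k_min:
            raise InputError(
                f"too few genes ({n}) for k_range {k_range}: need >= 10*K"
            )
        if np.all(np.ptp(x, axis=0) == 0.0):
            raise FitError("all profiles identical: degenerate fit")

        def _fit_k(k: int) -> GaussianMixture:
            gm = GaussianMixture(
                n_components=k,
                covariance_type="full",
                reg_covar=1e-6,
                n_init=n_init,
                random_state=seed,
                max_iter=500,
            )
            gm.fit(x)
            return gm

        # coarse geometric grid, then +-1 refinement around the winner
        coarse = sorted(
            {int(round(k)) for k in np.geomspace(k_min, k_max, num=min(8, k_max - k_min + 1))}
        ) or [k_min]
        best_gm, best_bic = None, np.inf
        for k in coarse:
            gm = _fit_k(k)
            bic = gm.bic(x)
            if bic < best_bic:
                best_gm, best_bic = gm, bic
        for k in (best_gm.n_components - 1, best_gm.n_components + 1):
            if k_min <= k <= k_max and k not in coarse:
                gm = _fit_k(k)
                bic = gm.bic(x)
                if bic < best_bic:
                    best_gm, best_bic = gm, bic

        raw = best_gm.predict(x)
        # relabel 1..K by descending size (stable: ties by original label)
        sizes = np.bincount(raw, minlength=best_gm.n_components)
        order = np.argsort(-sizes, kind="stable")
        relabel = np.empty_like(order)
        relabel[order] = np.arange(1, best_gm.n_components + 1)
        labels = pd.Series(relabel[raw], index=self.profiles.index, name="cluster")
        return ClusterResults(
            labels=labels,
            means=best_gm.means_[order],
            covariances=best_gm.covariances_[order],
            k=best_gm.n_components,
            bic=float(best_bic),
            loglik=float(best_gm.score(x) * n),
        )
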