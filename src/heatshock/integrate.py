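"""Joining binding calls with differential-expression classes.

Three views: crosstabs of bound vs induced/repressed genes with
percentages of each margin, pairwise/three-way overlaps of named gene
sets, and direction-stratified Spearman correlation between binding score
and SLR. Genes with several promoters take the maximum binding score (the
"any binding" reading).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from ._utils import round_half_away

__all__ = [
    "crosstab",
    "overlap_sets",
    "spearman_binding_expression",
    "SpearmanResult",
    "gene_binding_scores",
]

EXACT_SPEARMAN_MAX_N = 10


def crosstab(bound: set[str], contrast: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages of bound genes among induced and repressed.

    ``contrast`` is a classified contrast table (``de_class`` column).
    Percentages are 100*count/denominator rounded half away from zero to
    two decimals, reported against both margins (share of the DE class
    and share of all bound genes).
    """
    bound = set(bound)
    rows = []
    for cls, label in (("up", "induction"), ("down", "repression")):
        in_class = set(contrast.index[contrast["de_class"] == cls])
        inter = bound & in_class
        rows.append(
            {
                "direction": label,
                "n_class": len(in_class),
                "n_bound": len(bound),
                "n_bound_and_class": len(inter),
                "pct_of_class": round_half_away(
                    100.0 * len(inter) / len(in_class), 2
                )
                if in_class
                else 0.0,
                "pct_of_bound": round_half_away(100.0 * len(inter) / len(bound), 2)
                if bound
                else 0.0,
            }
        )
    return pd.DataFrame(rows)


def overlap_sets(sets: dict[str, set[str]]) -> pd.DataFrame:
    """All single, pairwise and higher-order intersection counts of named
    gene sets (inclusion-exclusion consistent by construction)."""
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    names = list(sets)
    rows = [{"sets": name, "count": len(sets[name])} for name in names]
    for r in range(2, len(names) + 1):
        for combo in combinations(names, r):
            inter = set.intersection(*(set(sets[c]) for c in combo))
            rows.append({"sets": "&".join(combo), "count": len(inter)})
    return pd.DataFrame(rows)


@dataclass
class SpearmanResult:
    direction: str
    n: int
    rho: float
    p: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.rho)


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation tail of |rho| by full enumeration of
    the n! orderings of one variable (n <= 10)."""
    rx = rankdata(x)
    ry = rankdata(y)
    n = len(rx)
    perms = np.array(list(permutations(range(n))))
    ry_perm = ry[perms]  # (n!, n)
    rx_c = rx - rx.mean()
    ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum(axis=1))
    rhos = (ry_c @ rx_c) / denom
    return float((np.abs(rhos) >= abs(rho_obs) - 1e-12).mean())


def spearman_binding_expression(
    contrast: pd.DataFrame,
    binding_scores: pd.Series,
    direction: str,
) -> SpearmanResult:
    """Spearman correlation of binding score with SLR, one direction.

    Genes enter when they are evaluated (above noise in at least one
    condition), have SLR != 0 with the sign of ``direction``, and a
    positive binding score (AB1 > AB0). rho uses average ranks; p comes
    from the t approximation for n > 10 and from the exact permutation
    null for n <= 10. Fewer than 3 usable genes yields an undefined
    (NaN) correlation.
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    evaluated = contrast[contrast["de_class"] != "not_evaluated"]
    slr = evaluated["slr"]
    keep = (slr > 0) if direction == "up" else (slr < 0)
    joined = pd.DataFrame(
        {"slr": slr[keep], "score": binding_scores.reindex(slr[keep].index)}
    ).dropna()
    joined = joined[joined["score"] > 0]
    n = len(joined)
    if n < 3:
        return SpearmanResult(direction=direction, n=n, rho=float("nan"), p=float("nan"))
    x = joined["score"].to_numpy()
    y = joined["slr"].to_numpy()
    rho, p_t = spearmanr(x, y)
    if n <= EXACT_SPEARMAN_MAX_N:
        p = _exact_spearman_p(x, y, rho)
    else:
        p = float(p_t)
    return SpearmanResult(direction=direction, n=n, rho=float(rho), p=p)


def gene_binding_scores(
    binding_table: pd.DataFrame, promoter_to_gene: pd.Series | None = None
) -> pd.Series:
    """Per-gene binding score from a per-promoter result table.

    Promoter ids are gene accessions unless an explicit promoter -> gene
    map is given; genes with several promoters take the maximum score.
    """
    scores = binding_table.set_index("promoter")["score"]
    if promoter_to_gene is not None:
        scores = scores.groupby(promoter_to_gene.reindex(scores.index)).max()
    else:
        scores = scores.groupby(level=0).max()
    scores.index.name = "gene"
    return scores
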