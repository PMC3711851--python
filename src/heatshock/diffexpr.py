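"""Signal-log-ratio differential calling.

For a contrast of a heat-shocked group (HS) against its control (C) the
per-gene statistic is the SLR: difference of mean log2 signals,
``SLR = mean(HS) - mean(C)``. The SLR distribution over evaluated genes is
modelled as a 1-D Gaussian mixture; components are mapped to repressed /
unchanged / induced classes by the sign of their mean against a small
dead-band, and genes are assigned to classes by maximum posterior. The
"significant SLR" ranges reported are the min/max observed SLR inside each
directional class, so asymmetric bounds (e.g. +0.49 up vs -0.36 down) fall
out naturally.

Genes below the noise threshold in both conditions are not evaluated
(their SLR is reported as "-"); genes below noise in exactly one condition
keep their SLR but carry the corresponding ``nl`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import round_half_away
from .gmm import InputError, FitError, Mixture1D, select_gmm_1d
from .noise import _group_samples

__all__ = ["compute_slr", "SlrMixtureModel", "SlrResults", "DEAD_BAND"]

#: component-mean dead-band (log2) inside which a component is "null"
DEAD_BAND = 0.1

CLASSES = ("down", "null", "up")


def compute_slr(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    calls: pd.DataFrame,
    contrast: tuple[str, str],
) -> pd.DataFrame:
    """Per-gene contrast table for (control group, heat-shock group).

    Group names are ``cell_type:condition`` as in the design sheet. Returns
    a DataFrame indexed by gene with columns ``mean_c``, ``mean_hs``,
    ``slr`` (full precision), ``nl_c``, ``nl_hs`` (below-noise flags) and
    ``de_class`` preset to ``not_evaluated`` where both conditions are
    below noise and ``null`` otherwise (refined by :class:`SlrMixtureModel`).
    """
    control_group, hs_group = contrast
    groups = _group_samples(design)
    for g in contrast:
        if g not in groups:
            raise KeyError(f"unknown group {g!r}; design has {sorted(groups)}")
    mean_c = matrix[groups[control_group]].mean(axis=1)
    mean_hs = matrix[groups[hs_group]].mean(axis=1)
    nl_c = ~calls[f"above_noise:{control_group}"]
    nl_hs = ~calls[f"above_noise:{hs_group}"]
    table = pd.DataFrame(
        {
            "mean_c": mean_c,
            "mean_hs": mean_hs,
            "slr": mean_hs - mean_c,
            "nl_c": nl_c,
            "nl_hs": nl_hs,
        }
    )
    table["de_class"] = np.where(nl_c & nl_hs, "not_evaluated", "null")
    table["posterior_up"] = 0.0
    table["posterior_down"] = 0.0
    table.attrs["contrast"] = contrast
    return table


@dataclass
class SlrResults:
    """Classified contrast table plus the mixture that produced it."""

    table: pd.DataFrame
    mixture: Mixture1D
    component_class: list[str]
    significant_ranges: dict[str, tuple[float, float] | None]

    @property
    def counts(self) -> dict[str, int]:
        evaluated = self.table[self.table["de_class"] != "not_evaluated"]
        return {c: int((evaluated["de_class"] == c).sum()) for c in CLASSES}

    def summary(self) -> pd.DataFrame:
        """Per-class gene counts, SLR ranges and share of evaluated genes."""
        n_eval = int((self.table["de_class"] != "not_evaluated").sum())
        rows = []
        for cls in ("up", "down"):
            rng = self.significant_ranges[cls]
            rows.append(
                {
                    "class": {"up": "induction", "down": "repression"}[cls],
                    "slr_min": None if rng is None else round_half_away(rng[0], 2),
                    "slr_max": None if rng is None else round_half_away(rng[1], 2),
                    "n_genes": self.counts[cls],
                    "pct_of_evaluated": round_half_away(
                        100.0 * self.counts[cls] / n_eval, 2
                    )
                    if n_eval
                    else 0.0,
                }
            )
        return pd.DataFrame(rows)

    def report_table(self) -> pd.DataFrame:
        """Contrast table with 2-decimal rounded means/SLR and '-' for
        not-evaluated genes, the layout of the published gene tables."""
        t = self.table.copy()
        for col in ("mean_c", "mean_hs", "slr"):
            t[col] = round_half_away(t[col].to_numpy(), 2)
        ne = t["de_class"] == "not_evaluated"
        t = t.astype({"mean_c": object, "mean_hs": object, "slr": object})
        t.loc[ne, "slr"] = "-"
        return t


class SlrMixtureModel:
    """Gaussian-mixture model of an SLR distribution.

    Parameters
    ----------
    table : DataFrame
        Output of :func:`compute_slr`; only evaluated genes (not below
        noise in both conditions) enter the fit.
    """

    def __init__(self, table: pd.DataFrame):
        self.table = table
        self._evaluated = table.index[table["de_class"] != "not_evaluated"]
        if len(self._evaluated) < 100:
            raise InputError(
                f"need >= 100 evaluated SLR values, got {len(self._evaluated)}"
            )

    def fit(self, k_range: tuple[int, int] = (1, 5), seed: int = 0,
            n_init: int = 5) -> SlrResults:
        slr = self.table.loc[self._evaluated, "slr"].to_numpy(dtype=float)
        if np.ptp(slr) == 0.0:
            raise FitError("all SLR values identical: degenerate fit")
        mixture = select_gmm_1d(slr, k_range, seed=seed, n_init=n_init)

        # map components to classes; the component nearest zero is always
        # null, others are directional only outside the dead-band
        comp_class = []
        nearest = int(np.argmin(np.abs(mixture.means)))
        for j, mu in enumerate(mixture.means):
            if j == nearest or abs(mu) <= DEAD_BAND:
                comp_class.append("null")
            else:
                comp_class.append("up" if mu > 0 else "down")

        post = mixture.posteriors(slr)
        class_post = {
            c: post[:, [j for j, cc in enumerate(comp_class) if cc == c]].sum(axis=1)
            for c in CLASSES
        }
        stacked = np.column_stack([class_post[c] for c in CLASSES])
        # ties in maximum posterior break toward null (conservative)
        best = np.asarray(CLASSES)[np.argmax(stacked, axis=1)]
        tie_with_null = np.isclose(stacked.max(axis=1), class_post["null"])
        best = np.where(tie_with_null, "null", best)

        table = self.table.copy()
        table.loc[self._evaluated, "de_class"] = best
        table.loc[self._evaluated, "posterior_up"] = class_post["up"]
        table.loc[self._evaluated, "posterior_down"] = class_post["down"]

        ranges: dict[str, tuple[float, float] | None] = {}
        for cls in ("up", "down"):
            vals = slr[best == cls]
            ranges[cls] = (float(vals.min()), float(vals.max())) if vals.size else None
        return SlrResults(
            table=table,
            mixture=mixture,
            component_class=comp_class,
            significant_ranges=ranges,
        )
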