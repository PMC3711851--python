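"""Synthetic expression matrices, tiling ChIP signals and term annotations
with known ground truth.

The generators emulate the statistical structure the analysis assumes:

* log2 expression signals drawn from a three-component mixture of noise,
  low and high baseline signal, with replicate noise and planted
  condition-specific log2 shifts in heat-shocked groups;
* probe-level AB1/AB0 tiling intensities with a Gaussian positional
  enrichment peak at a planted subset of promoters (AB0 is pure
  background);
* a shallow term DAG with one designated term whose gene set overlaps a
  designated query set at a planted fraction.

Every generator draws from one pseudo-random stream per call, split
deterministically per gene / promoter, so enlarging a simulation leaves
the entities already present bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import child_rng
from .chip import ChipSignalSet, PromoterMap
from .enrich import TermAnnotation

__all__ = [
    "SimExprParams",
    "SimChipParams",
    "SimTruth",
    "ParameterError",
    "gen_expression",
    "gen_chip",
    "gen_annotation",
]


class ParameterError(ValueError):
    """Invalid simulation parameter; the message names the field."""


# ---------------------------------------------------------------------------
# parameter sets

#: study layout: spermatocytes at control / 38C / 43C, hepatocytes at
#: control / 43C; conditions named "C" are controls, everything else is a
#: heat-shock condition and receives the planted shift.
STUDY_GROUPS = [
    ("SC", "C"),
    ("SC", "HS38"),
    ("SC", "HS43"),
    ("HEP", "C"),
    ("HEP", "HS43"),
]


@dataclass(frozen=True)
class SimExprParams:
    """Parameters of the expression-matrix generator (log2 units)."""

    n_genes: int = 15000
    groups: tuple = (("SC", "C"), ("SC", "HS"))
    n_reps: int = 3
    mixture_weights: tuple = (0.35, 0.40, 0.25)  # noise, low, high
    mixture_means: tuple = (4.5, 7.0, 10.0)
    mixture_sds: tuple = (0.6, 1.0, 1.2)
    rep_sd: float = 0.25
    frac_up: float = 0.03
    frac_down: float = 0.06
    effect_up: tuple = (1.5, 0.4)  # (mean, sd) of log2 shift
    effect_down: tuple = (1.5, 0.4)  # magnitude; applied with negative sign
    floor: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ParameterError("n_genes must be >= 1")
        if abs(sum(self.mixture_weights) - 1.0) > 1e-9:
            raise ParameterError("mixture_weights must sum to 1")
        if any(s <= 0 for s in self.mixture_sds):
            raise ParameterError("mixture_sds must all be > 0")
        if self.rep_sd <= 0:
            raise ParameterError("rep_sd must be > 0")
        if not (0 <= self.frac_up and 0 <= self.frac_down
                and self.frac_up + self.frac_down <= 1):
            raise ParameterError("frac_up + frac_down must lie in [0, 1]")
        if self.n_reps < 2:
            raise ParameterError("n_reps must be >= 2")
        if self.effect_up[1] < 0 or self.effect_down[1] < 0:
            raise ParameterError("effect_up/effect_down sd must be >= 0")
        if not (len(self.mixture_weights) == len(self.mixture_means)
                == len(self.mixture_sds)):
            raise ParameterError("mixture_weights/means/sds lengths differ")


@dataclass(frozen=True)
class SimChipParams:
    """Parameters of the tiling ChIP generator (linear intensity units).

    Background intensities are log-normal with the given log-mean/log-sd;
    bound promoters add ``amplitude x Gaussian kernel`` centred at a probe
    position drawn away from the region edges.
    """

    n_promoters: int = 500
    probes_per_promoter: tuple = (28, 32)
    n_reps: int = 3
    background: tuple = (3.0, 0.05)  # (log-mean, log-sd), linear scale
    frac_bound: float = 0.10
    amplitude: tuple = (20.0, 120.0)
    peak_sd: float = 9.5  # positional spread, in probes
    probe_spacing: int = 35  # bp between probe starts
    probe_length: int = 25
    seed: int = 0

    def validate(self) -> None:
        if self.n_promoters < 1:
            raise ParameterError("n_promoters must be >= 1")
        if self.probes_per_promoter[0] < 3:
            raise ParameterError("probes_per_promoter min must be >= 3")
        if self.probes_per_promoter[0] > self.probes_per_promoter[1]:
            raise ParameterError("probes_per_promoter min exceeds max")
        if not 0 <= self.frac_bound <= 1:
            raise ParameterError("frac_bound must lie in [0, 1]")
        if self.amplitude[0] <= 0:
            raise ParameterError("amplitude min must be > 0")
        if self.amplitude[0] > self.amplitude[1]:
            raise ParameterError("amplitude min exceeds max")
        if self.background[1] <= 0:
            raise ParameterError("background log-sd must be > 0")
        if self.peak_sd <= 0:
            raise ParameterError("peak_sd must be > 0")
        if self.n_reps < 1:
            raise ParameterError("n_reps must be >= 1")


@dataclass
class SimTruth:
    """Planted labels for recovery testing.

    ``genes``: index gene id with columns expressed, de_class, effect.
    ``promoters``: index promoter id with columns bound, amplitude,
    peak_index.
    """

    genes: pd.DataFrame | None = None
    promoters: pd.DataFrame | None = None

    def __post_init__(self):
        if self.genes is not None:
            null_rows = self.genes["de_class"] == "null"
            assert (self.genes.loc[null_rows, "effect"] == 0).all()
        if self.promoters is not None:
            unbound = ~self.promoters["bound"]
            assert (self.promoters.loc[unbound, "amplitude"] == 0).all()


# ---------------------------------------------------------------------------
# expression


def gen_expression(params: SimExprParams) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate a genes x samples log2 matrix, its design sheet, and truth.

    Columns are one per group x replicate, named ``{cell}_{cond}_r{i}``.
    Per gene: a baseline from the noise/low/high mixture; genes from the
    noise component are never differentially expressed; expressed genes
    are shifted up/down in every heat-shock group (condition != "C") with
    probability frac_up/frac_down; replicate noise on every value; the
    result is floored.
    """
    params.validate()
    weights = np.asarray(params.mixture_weights, dtype=float)
    means = np.asarray(params.mixture_means, dtype=float)
    sds = np.asarray(params.mixture_sds, dtype=float)
    groups = list(params.groups)
    sample_cols = [
        f"{cell}_{cond}_r{r + 1}"
        for cell, cond in groups
        for r in range(params.n_reps)
    ]
    is_hs_col = np.asarray(
        [cond != "C" for cell, cond in groups for _ in range(params.n_reps)]
    )

    matrix = np.empty((params.n_genes, len(sample_cols)))
    expressed = np.empty(params.n_genes, dtype=bool)
    de_class = np.full(params.n_genes, "null", dtype=object)
    effect = np.zeros(params.n_genes)

    for i in range(params.n_genes):
        rng = child_rng(params.seed, 0, i)
        comp = rng.choice(len(weights), p=weights)
        baseline = rng.normal(means[comp], sds[comp])
        expressed[i] = comp != 0  # noise-component genes are never DE
        u = rng.uniform()
        eff = 0.0
        if expressed[i]:
            if u < params.frac_up:
                de_class[i] = "up"
                eff = abs(rng.normal(*params.effect_up))
            elif u < params.frac_up + params.frac_down:
                de_class[i] = "down"
                eff = -abs(rng.normal(*params.effect_down))
        effect[i] = eff
        noise = rng.normal(0.0, params.rep_sd, size=len(sample_cols))
        matrix[i] = baseline + np.where(is_hs_col, eff, 0.0) + noise

    np.maximum(matrix, params.floor, out=matrix)
    genes = pd.Index([f"g{i:05d}" for i in range(params.n_genes)], name="gene")
    matrix_df = pd.DataFrame(matrix, index=genes, columns=sample_cols)
    design = pd.DataFrame(
        {
            "sample_id": sample_cols,
            "cell_type": [c for c, _ in groups for _ in range(params.n_reps)],
            "condition": [k for _, k in groups for _ in range(params.n_reps)],
            "replicate": [r + 1 for _ in groups for r in range(params.n_reps)],
        }
    )
    truth = SimTruth(
        genes=pd.DataFrame(
            {"expressed": expressed, "de_class": de_class, "effect": effect},
            index=genes,
        )
    )
    return matrix_df, design, truth


# ---------------------------------------------------------------------------
# ChIP


def gen_chip(
    params: SimChipParams,
    promoter_ids: list[str] | None = None,
    bound: np.ndarray | None = None,
    amplitudes: np.ndarray | None = None,
) -> tuple[ChipSignalSet, PromoterMap, SimTruth]:
    """Generate probe-level AB1/AB0 intensities, a promoter map and truth.

    AB0 replicates are background noise only; AB1 replicates add, for
    bound promoters, ``amplitude x exp(-(i - peak)^2 / (2 peak_sd^2))``
    at probe index ``i``. Probe coordinates are emitted 0-based half-open
    on the synthetic chromosome ``chrS``.

    ``promoter_ids``, ``bound`` and ``amplitudes`` optionally override the
    random assignment so that binding truth can be linked to an expression
    truth (for end-to-end runs); lengths must equal ``n_promoters``.
    """
    params.validate()
    for name, arr in (("promoter_ids", promoter_ids), ("bound", bound),
                      ("amplitudes", amplitudes)):
        if arr is not None and len(arr) != params.n_promoters:
            raise ParameterError(f"{name} must have length n_promoters")

    lo, hi = params.probes_per_promoter
    rows = []
    ab1_cols = {f"AB1_r{r + 1}": [] for r in range(params.n_reps)}
    ab0_cols = {f"AB0_r{r + 1}": [] for r in range(params.n_reps)}
    truth_rows = []
    pos = 0
    for j in range(params.n_promoters):
        rng = child_rng(params.seed, 1, j)
        n_probes = int(rng.integers(lo, hi + 1))
        pid = promoter_ids[j] if promoter_ids is not None else f"prom{j:04d}"
        if bound is not None:
            is_bound = bool(bound[j])
            # keep the stream aligned whether or not the draw is used
            rng.uniform()
        else:
            is_bound = rng.uniform() < params.frac_bound
        if amplitudes is not None:
            amp = float(amplitudes[j]) if is_bound else 0.0
            rng.uniform()
        else:
            amp = float(rng.uniform(*params.amplitude)) if is_bound else 0.0
        # peak in the central third of the region: promoter tiling is
        # centred on the TSS neighbourhood the factor actually occupies
        third = max(1, n_probes // 3)
        peak = int(rng.integers(third, n_probes - third)) if n_probes >= 5 else n_probes // 2
        idx = np.arange(n_probes)
        kernel = np.exp(-((idx - peak) ** 2) / (2.0 * params.peak_sd**2))
        lift = amp * kernel if is_bound else np.zeros(n_probes)

        bg = rng.lognormal(params.background[0], params.background[1],
                           size=(n_probes, 2 * params.n_reps))
        for r in range(params.n_reps):
            ab0_cols[f"AB0_r{r + 1}"].append(bg[:, r])
            ab1_cols[f"AB1_r{r + 1}"].append(bg[:, params.n_reps + r] + lift)
        for i in range(n_probes):
            start = pos + i * params.probe_spacing
            rows.append(
                {
                    "chrom": "chrS",
                    "start": start,
                    "end": start + params.probe_length,
                    "probe_id": f"pr{j:04d}_{i:02d}",
                    "promoter_id": pid,
                    "strand": "+",
                }
            )
        pos += n_probes * params.probe_spacing + 500  # gap between promoters
        truth_rows.append(
            {"promoter": pid, "bound": is_bound, "amplitude": amp, "peak_index": peak}
        )

    map_df = pd.DataFrame(rows)
    probe_index = pd.Index(map_df["probe_id"], name="probe_id")
    ab1 = pd.DataFrame(
        {c: np.concatenate(v) for c, v in ab1_cols.items()}, index=probe_index
    )
    ab0 = pd.DataFrame(
        {c: np.concatenate(v) for c, v in ab0_cols.items()}, index=probe_index
    )
    truth = SimTruth(promoters=pd.DataFrame(truth_rows).set_index("promoter"))
    return ChipSignalSet(ab1=ab1, ab0=ab0), PromoterMap(table=map_df), truth


# ---------------------------------------------------------------------------
# annotation


def gen_annotation(
    n_genes: int,
    n_terms: int,
    planted_term_overlap: float,
    seed: int,
    genes: list[str] | None = None,
) -> tuple[TermAnnotation, dict]:
    """Generate a shallow term DAG with one planted enriched term.

    Returns the annotation plus a dict with the planted ``term`` and the
    designated ``query`` gene set whose overlap with the term's gene set
    is the planted fraction. The DAG has a single root and depth <= 3.
    """
    if n_terms < 2:
        raise ParameterError("n_terms must be >= 2")
    if not 0.0 <= planted_term_overlap <= 1.0:
        raise ParameterError("planted_term_overlap must lie in [0, 1]")
    if genes is None:
        genes = [f"g{i:05d}" for i in range(n_genes)]
    elif len(genes) != n_genes:
        raise ParameterError("genes must have length n_genes")
    rng = child_rng(seed, 2)
    universe = list(genes)

    levels = {"T000": 0}
    parents: dict[str, set[str]] = {}
    direct: dict[str, set[str]] = {}
    term_ids = [f"T{k:03d}" for k in range(n_terms)]
    for k, term in enumerate(term_ids[1:], start=1):
        candidates = [t for t in term_ids[:k] if levels[t] < 2]
        parent = candidates[rng.integers(len(candidates))]
        parents[term] = {parent}
        levels[term] = levels[parent] + 1
    set_size = max(3, min(30, n_genes // max(n_terms, 1)))
    for term in term_ids:
        size = int(rng.integers(max(3, set_size // 2), set_size + 1))
        direct[term] = set(rng.choice(universe, size=min(size, n_genes), replace=False))

    planted = term_ids[-1]
    term_genes = sorted(direct[planted])
    n_from_term = int(round(planted_term_overlap * len(term_genes)))
    outside = sorted(set(universe) - set(term_genes))
    query = set(rng.choice(term_genes, size=n_from_term, replace=False))
    n_fill = len(term_genes) - n_from_term
    if n_fill > 0 and outside:
        query |= set(rng.choice(outside, size=min(n_fill, len(outside)), replace=False))
    annotation = TermAnnotation(direct=direct, parents=parents, universe=set(universe))
    return annotation, {"term": planted, "query": query}
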