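"""Synthetic-data generators: determinism, planted-truth bookkeeping,
closed-form moments."""

import numpy as np
import pytest

from heatshock import (
    SimChipParams,
    SimExprParams,
    gen_annotation,
    gen_chip,
    gen_expression,
)
from heatshock.simulate import ParameterError


def test_expression_seeded_determinism():
    params = SimExprParams(n_genes=200, seed=4)
    a = gen_expression(params)
    b = gen_expression(params)
    assert a[0].equals(b[0])
    assert a[1].equals(b[1])
    assert a[2].genes.equals(b[2].genes)


def test_expression_per_gene_streams_stable_under_growth():
    """Adding genes must not perturb the genes already present."""
    small = gen_expression(SimExprParams(n_genes=50, seed=8))[0]
    large = gen_expression(SimExprParams(n_genes=80, seed=8))[0]
    assert np.allclose(small.to_numpy(), large.to_numpy()[:50])


@pytest.mark.parametrize(
    "bad, field",
    [
        (dict(mixture_weights=(0.5, 0.4, 0.2)), "mixture_weights"),
        (dict(rep_sd=0.0), "rep_sd"),
        (dict(frac_up=0.7, frac_down=0.5), "frac_up"),
        (dict(n_reps=1), "n_reps"),
        (dict(mixture_sds=(0.5, -1.0, 0.5)), "mixture_sds"),
    ],
)
def test_expression_invalid_params_name_field(bad, field):
    params = SimExprParams(n_genes=10, **bad)
    with pytest.raises(ParameterError, match=field.split("_")[0]):
        gen_expression(params)


def test_expression_floor_respected():
    params = SimExprParams(n_genes=500, floor=3.0, seed=1)
    matrix, _, _ = gen_expression(params)
    assert (matrix.to_numpy() >= 3.0).all()


def test_expression_null_contrast_moments():
    """With no planted effects, per-gene (mean HS - mean C) is centred at
    zero with sd rep_sd*sqrt(2/n_reps), within 10% at n=10000."""
    params = SimExprParams(n_genes=10000, frac_up=0.0, frac_down=0.0, seed=6)
    matrix, design, _ = gen_expression(params)
    c_cols = [s for s in matrix.columns if "_C_" in s]
    hs_cols = [s for s in matrix.columns if "_HS_" in s]
    delta = matrix[hs_cols].mean(axis=1) - matrix[c_cols].mean(axis=1)
    # the floor clips a small fraction of noise-component genes; restrict
    # to genes comfortably above it
    keep = matrix.min(axis=1) > params.floor
    expected_sd = params.rep_sd * np.sqrt(2 / params.n_reps)
    assert abs(delta[keep].mean()) < 0.01
    assert abs(delta[keep].std() - expected_sd) <= 0.10 * expected_sd


def test_expression_planted_up_count_in_binomial_band():
    """Truth-up count lies in the 99% binomial band around
    frac_up x (#expressed)."""
    params = SimExprParams(seed=13)  # defaults: 15000 genes, frac_up 0.03
    _, _, truth = gen_expression(params)
    n_expr = int(truth.genes["expressed"].sum())
    n_up = int((truth.genes["de_class"] == "up").sum())
    mu = params.frac_up * n_expr
    sd = np.sqrt(n_expr * params.frac_up * (1 - params.frac_up))
    assert mu - 2.576 * sd <= n_up <= mu + 2.576 * sd


def test_expression_truth_bookkeeping():
    _, _, truth = gen_expression(SimExprParams(n_genes=2000, seed=2))
    genes = truth.genes
    assert ((genes["de_class"] == "null") == (genes["effect"] == 0)).all()
    # noise-component genes are never differentially expressed
    assert (genes.loc[~genes["expressed"], "de_class"] == "null").all()


def test_chip_intensities_nonnegative_and_coords_half_open(small_chip):
    params, signals, pmap, truth = small_chip
    assert (signals.ab1.to_numpy() >= 0).all()
    assert (signals.ab0.to_numpy() >= 0).all()
    assert (pmap.table["start"] < pmap.table["end"]).all()
    unbound = ~truth.promoters["bound"]
    assert (truth.promoters.loc[unbound, "amplitude"] == 0).all()


def test_chip_invalid_params_name_field():
    with pytest.raises(ParameterError, match="probes_per_promoter"):
        gen_chip(SimChipParams(probes_per_promoter=(2, 5)))
    with pytest.raises(ParameterError, match="frac_bound"):
        gen_chip(SimChipParams(frac_bound=1.5))
    with pytest.raises(ParameterError, match="amplitude"):
        gen_chip(SimChipParams(amplitude=(0.0, 10.0)))


def test_chip_override_lengths_checked():
    with pytest.raises(ParameterError, match="bound"):
        gen_chip(SimChipParams(n_promoters=10), bound=np.ones(5, dtype=bool))


def test_chip_linked_truth_overrides():
    """Explicit bound/amplitude assignment is honoured exactly."""
    n = 30
    bound = np.zeros(n, dtype=bool)
    bound[[3, 7, 11]] = True
    amps = np.where(bound, 77.0, 0.0)
    ids = [f"gene{i}" for i in range(n)]
    _, _, truth = gen_chip(
        SimChipParams(n_promoters=n, seed=5), promoter_ids=ids,
        bound=bound, amplitudes=amps,
    )
    assert truth.promoters.loc["gene3", "bound"]
    assert truth.promoters.loc["gene3", "amplitude"] == 77.0
    assert truth.promoters["bound"].sum() == 3


def test_annotation_determinism_and_structure():
    a1, p1 = gen_annotation(100, 8, 0.5, seed=3)
    a2, p2 = gen_annotation(100, 8, 0.5, seed=3)
    assert {t: sorted(g) for t, g in a1.direct.items()} == {
        t: sorted(g) for t, g in a2.direct.items()
    }
    assert p1["term"] == p2["term"] and p1["query"] == p2["query"]
    graph = a1.graph()  # raises on cycles
    depths = {n: len(max(list(_paths_to_root(a1, n)), key=len)) for n in a1.direct}
    assert max(depths.values()) <= 3


def _paths_to_root(ann, node):
    if not ann.parents.get(node):
        yield [node]
        return
    for p in ann.parents[node]:
        for path in _paths_to_root(ann, p):
            yield path + [node]


def test_annotation_two_terms():
    ann, planted = gen_annotation(40, 2, 1.0, seed=1)
    assert len(ann.direct) == 2
    assert planted["query"] == ann.direct[planted["term"]]


def test_annotation_overlap_bounds():
    with pytest.raises(ParameterError, match="overlap"):
        gen_annotation(50, 4, 1.2, seed=0)
    with pytest.raises(ParameterError, match="n_terms"):
        gen_annotation(50, 1, 0.5, seed=0)
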