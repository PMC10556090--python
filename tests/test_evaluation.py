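"""CV evaluation, grid enumeration, aggregation and ceiling estimation."""

import numpy as np
import pandas as pd
import pytest

from proglimit.datasets import ExpressionDataset, SyntheticConfig, generate_synthetic_dataset
from proglimit.evaluation import (
    GridPlan,
    SignatureResult,
    ceiling_curve,
    correlate_with_cohort,
    enumerate_grid,
    evaluate_signature,
    rank_sum_test,
    results_to_frame,
    rss_prevalence,
    run_grid,
    summarize,
)
from proglimit.models import ModelSpec
from proglimit.selection import GeneSet


def _with_oracle_gene(ds):
    """Append the true latent factor as a pseudo-gene column."""
    expr = np.column_stack([ds.expression, ds.latent_factor])
    out = ExpressionDataset(
        name=ds.name, expression=expr, gene_ids=ds.gene_ids + ["ORACLE"],
        time=ds.time, event=ds.event, endpoint=ds.endpoint,
    )
    return out


@pytest.fixture(scope="module")
def strong_ds():
    return generate_synthetic_dataset(
        SyntheticConfig(n_samples=300, n_genes=50, factor_fraction=0.2,
                        loading_scale=2.0, hazard_coef=2.5,
                        censor_rate_target=0.2, seed=19),
        name="strong",
    )


def test_oracle_signature_scores_high(strong_ds):
    ds = _with_oracle_gene(strong_ds)
    gs = GeneSet("oracle", ("ORACLE",), "ml", "oracle")
    res = evaluate_signature(ds, gs, ModelSpec("coxph"), seed=1)
    assert res.median_c > 0.8
    assert len(res.fold_c) == 5 and not np.isnan(res.fold_c).any()


def test_stub_model_is_null(strong_ds):
    gs = GeneSet("rand", tuple(strong_ds.gene_ids[:20]), "random", "random")
    res = evaluate_signature(strong_ds, gs, ModelSpec("stub", seed=3), seed=2)
    assert abs(res.median_c - 0.5) < 0.12


def test_evaluation_is_seed_deterministic(strong_ds):
    gs = GeneSet("g", tuple(strong_ds.gene_ids[:10]), "random", "random")
    a = evaluate_signature(strong_ds, gs, ModelSpec("coxph"), seed=7)
    b = evaluate_signature(strong_ds, gs, ModelSpec("coxph"), seed=7)
    assert a.fold_c == b.fold_c
    c = evaluate_signature(strong_ds, gs, ModelSpec("coxph"), seed=8)
    assert a.fold_c != c.fold_c


def test_small_grid_cardinality(strong_ds):
    plan = GridPlan(n_random=2, random_set_size=10, reported=[], ml_methods=())
    results = run_grid([strong_ds], plan, ["coxph", "stub", "stree"], seed=0)
    assert len(results) == 6
    df = results_to_frame(results)
    assert set(df["model_id"]) == {"coxph", "stub", "stree"}
    assert df["median_c"].between(0, 1).all()


def test_enumerate_grid_matches_plan(strong_ds):
    plan = GridPlan(n_random=4, reported=[GeneSet("sig", ("A",), "reported")],
                    ml_methods=("UM", "MRMR"))
    df = enumerate_grid([strong_ds, strong_ds], plan, ["coxph", "rsf"])
    assert len(df) == 2 * (4 + 1 + 2) * 2


def test_grid_is_reproducible(strong_ds):
    plan = GridPlan(n_random=2, random_set_size=5, reported=[], ml_methods=())
    a = results_to_frame(run_grid([strong_ds], plan, ["coxph"], seed=11))
    b = results_to_frame(run_grid([strong_ds], plan, ["coxph"], seed=11))
    pd.testing.assert_frame_equal(a, b)


def _fake_results(medians, dataset="d", model="coxph", origin="random"):
    return [
        SignatureResult(dataset=dataset, gene_set=f"s{i}", origin=origin,
                        method=origin, model_id=model,
                        fold_c=[m] * 5, median_c=m)
        for i, m in enumerate(medians)
    ]


def test_summarize_hand_examples():
    s = summarize(_fake_results([0.6, 0.6, 0.6]))[0]
    assert (s.mom, s.mad, s.max_c) == (0.6, 0.0, 0.6)
    s = summarize(_fake_results([0.5, 0.6, 0.8]))[0]
    assert (s.mom, s.mad, s.max_c) == (0.6, pytest.approx(0.1), 0.8)
    assert s.n_signatures == 3
    with pytest.raises(ValueError):
        summarize([])


def test_summarize_grouping():
    res = _fake_results([0.5, 0.7], model="coxph") + _fake_results([0.6], model="rsf")
    stats = {(s.dataset, s.model_id): s for s in summarize(res)}
    assert stats[("d", "coxph")].mom == pytest.approx(0.6)
    assert stats[("d", "rsf")].mom == pytest.approx(0.6)


class _DS:
    def __init__(self, name, n, er):
        self.name, self.n_samples, self.event_rate = name, n, er


def test_correlation_perfect_line():
    datasets = [_DS(f"d{i}", 100 + 50 * i, 0.5) for i in range(5)]
    res = []
    for i, d in enumerate(datasets):
        res += _fake_results([0.4 + 0.001 * d.n_samples + e for e in (0, 0.01, -0.01)],
                             dataset=d.name)
    table = correlate_with_cohort(summarize(res), datasets)
    row = table[(table.statistic == "MOM") & (table.covariate == "n_patients")].iloc[0]
    assert row.pearson_r == pytest.approx(1.0)
    assert row.spearman_r == pytest.approx(1.0)


def test_correlation_needs_three_datasets():
    datasets = [_DS("a", 100, 0.5), _DS("b", 200, 0.5)]
    res = _fake_results([0.5], dataset="a") + _fake_results([0.6], dataset="b")
    with pytest.raises(ValueError, match=">= 3 datasets"):
        correlate_with_cohort(summarize(res), datasets)


def test_correlation_null_is_mostly_insignificant():
    """Shuffled summary statistics rarely correlate with cohort covariates."""
    rng = np.random.default_rng(99)
    n_rep = 20
    datasets = [_DS(f"d{i}", int(rng.integers(80, 500)), float(rng.uniform(0.2, 0.8)))
                for i in range(24)]
    pvals = []
    for _ in range(n_rep):
        res = []
        moms = rng.uniform(0.5, 0.7, size=len(datasets))
        for d, m in zip(datasets, moms):
            res += _fake_results([m], dataset=d.name)
        table = correlate_with_cohort(summarize(res), datasets)
        sub = table[table.statistic == "MOM"]
        pvals.extend(sub.pearson_p.tolist())
    assert np.mean(np.asarray(pvals) > 0.05) >= 0.9


def test_rss_prevalence_examples():
    ref = _fake_results([0.7])[0]
    below = _fake_results(np.linspace(0.4, 0.69, 10))
    assert rss_prevalence(below, ref).average == 0.0
    mixed = _fake_results([0.71] * 44 + [0.69] * 56)
    out = rss_prevalence(mixed, ref)
    assert out.average == pytest.approx(0.44)
    assert out.per_group.iloc[0].n_random == 100
    ties = _fake_results([0.7] * 10)
    assert rss_prevalence(ties, ref).average == 0.0  # strict inequality
    with pytest.raises(ValueError):
        rss_prevalence(_fake_results([0.5], model="rsf"), ref)


def test_ceiling_curve_hand_example():
    curve = ceiling_curve([0.5, 0.6, 0.7], [0.55, 0.65, 0.75], cut=0.4)
    np.testing.assert_allclose(curve.fraction_above, [2 / 3, 1 / 3, 0.0])
    assert curve.ceiling_estimate == 0.65  # first threshold with fraction < 0.4
    assert curve.zero_threshold == 0.75


def test_ceiling_curve_step_function():
    curve = ceiling_curve([0.6] * 5, [0.55, 0.6, 0.65], cut=0.01)
    np.testing.assert_allclose(curve.fraction_above, [1.0, 0.0, 0.0])
    with pytest.raises(ValueError):
        ceiling_curve([], [0.5])


def test_ceiling_curve_monotone_and_shift():
    rng = np.random.default_rng(1)
    med = rng.uniform(0.4, 0.8, 200)
    grid = np.linspace(0.3, 0.9, 61)
    c1 = ceiling_curve(med, grid)
    assert (np.diff(c1.fraction_above) <= 0).all()
    c2 = ceiling_curve(med + 0.05, grid)
    assert c2.ceiling_estimate >= c1.ceiling_estimate


def test_rank_sum_utility():
    rng = np.random.default_rng(0)
    a = rng.normal(0.6, 0.02, 50)
    _, p_same = rank_sum_test(a, rng.normal(0.6, 0.02, 50))
    _, p_diff = rank_sum_test(a, rng.normal(0.7, 0.02, 50))
    assert p_same > 0.05
    assert p_diff < 1e-6


def test_failed_folds_become_missing(strong_ds):
    # all-censored dataset: every fold either fails to fit or has no pairs
    ds = ExpressionDataset(
        name="cens", expression=strong_ds.expression[:100],
        gene_ids=strong_ds.gene_ids, time=strong_ds.time[:100],
        event=np.zeros(100, int),
    )
    gs = GeneSet("g", tuple(ds.gene_ids[:5]), "random", "random")
    res = evaluate_signature(ds, gs, ModelSpec("coxph"), seed=0)
    assert np.isnan(res.fold_c).all() and np.isnan(res.median_c)
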