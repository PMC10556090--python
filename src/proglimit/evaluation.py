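"""Fivefold-CV evaluation grids, aggregation and ceiling estimation.

Every (dataset, gene set, model) triple is scored by one event-stratified
fivefold cross-validation: per fold the expression is standardized on the
training part only, the model fitted, the held-out fold scored, and Harrell's
C computed on the held-out fold.  A signature's prognostic power is the
median of its five fold C-indices.

Aggregation follows the random-signature benchmarking convention: per
(dataset, model) group the MOM (median of per-signature medians), MAD (median
absolute deviation around the MOM) and MAX; across groups, the
fraction-above-threshold curve whose drop below a small cut estimates the
ceiling of attainable prognostic power.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .concordance import ConcordanceUndefinedError, concordance
from .datasets import ExpressionDataset
from .models import ModelSpec, fit, predict_risk
from .selection import (
    GeneSet,
    ML_METHODS,
    load_reported_gene_sets,
    sample_random_gene_sets,
    select_ml,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SignatureResult",
    "SummaryStats",
    "CeilingCurve",
    "GridPlan",
    "evaluate_signature",
    "build_gene_sets",
    "enumerate_grid",
    "run_grid",
    "summarize",
    "correlate_with_cohort",
    "rss_prevalence",
    "ceiling_curve",
    "rank_sum_test",
    "results_to_frame",
]

N_FOLDS = 5


@dataclass
class SignatureResult:
    """C-indices of one (dataset, gene set, model) evaluation."""

    dataset: str
    gene_set: str
    origin: str
    method: str
    model_id: str
    fold_c: list
    median_c: float

    def __post_init__(self) -> None:
        if len(self.fold_c) != N_FOLDS:
            raise ValueError(f"fold_c must have {N_FOLDS} entries")


@dataclass(frozen=True)
class SummaryStats:
    """Per-(dataset, model) aggregates over signature medians."""

    dataset: str
    model_id: str
    mom: float
    mad: float
    max_c: float
    n_signatures: int


@dataclass(frozen=True)
class CeilingCurve:
    """Fraction of signatures above each threshold plus ceiling estimates."""

    thresholds: np.ndarray
    fraction_above: np.ndarray
    ceiling_estimate: float  # smallest threshold with fraction < cut
    zero_threshold: float    # smallest threshold with fraction == 0
    cut: float


def _standardize_fold(X_train, X_test):
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd[sd == 0] = 1.0
    return (X_train - mu) / sd, (X_test - mu) / sd


def evaluate_signature(
    ds: ExpressionDataset, gene_set: GeneSet, model_spec: ModelSpec, seed: int = 0
) -> SignatureResult:
    """One event-stratified fivefold CV of a gene set with one model.

    Per-gene standardization uses training-fold statistics only.  Folds where
    the fit fails or the held-out fold has no comparable pair yield a missing
    C; the signature median is taken over the available folds.
    """
    X = ds.gene_matrix(gene_set.genes)
    skf = StratifiedKFold(n_splits=N_FOLDS, shuffle=True, random_state=seed % (2**32))
    fold_c: list[float] = []
    for k, (tr, te) in enumerate(skf.split(X, ds.event)):
        Xtr, Xte = _standardize_fold(X[tr], X[te])
        try:
            m = fit(model_spec, Xtr, ds.time[tr], ds.event[tr], list(gene_set.genes))
        except Exception as exc:  # degenerate fold (e.g. too few events)
            logger.warning("fold %d of %s/%s/%s unfittable: %s", k, ds.name,
                           gene_set.name, model_spec.model_id, exc)
            fold_c.append(np.nan)
            continue
        if not m.ok:
            logger.warning("fold %d of %s/%s/%s failed: %s", k, ds.name,
                           gene_set.name, model_spec.model_id, m.error)
            fold_c.append(np.nan)
            continue
        scores = predict_risk(m, Xte, list(gene_set.genes))
        try:
            fold_c.append(concordance(scores, ds.time[te], ds.event[te]))
        except ConcordanceUndefinedError:
            fold_c.append(np.nan)
    med = float(np.nanmedian(fold_c)) if not np.all(np.isnan(fold_c)) else np.nan
    return SignatureResult(
        dataset=ds.name, gene_set=gene_set.name, origin=gene_set.origin,
        method=gene_set.method, model_id=model_spec.model_id,
        fold_c=fold_c, median_c=med,
    )


@dataclass
class GridPlan:
    """Which gene sets to build per dataset.

    ``reported`` may hold :class:`GeneSet` objects (used as-is after
    validation against each dataset) or gene-list file paths (loaded per
    dataset).  ``ml_methods`` names selection schemes run per dataset.
    """

    n_random: int = 100
    random_set_size: int = 20
    reported: list = field(default_factory=list)
    ml_methods: tuple = ML_METHODS
    ml_params: dict = field(default_factory=dict)
    min_match: float = 0.5

    def n_sets(self) -> int:
        return self.n_random + len(self.reported) + len(self.ml_methods)


def _signature_seed(seed: int, *indices: int) -> int:
    return int(np.random.SeedSequence([seed, *indices]).generate_state(1)[0] % (2**31))


def build_gene_sets(ds: ExpressionDataset, plan: GridPlan, seed: int, ds_index: int = 0) -> list:
    """Materialize the plan's gene sets for one dataset."""
    sets: list[GeneSet] = []
    if plan.n_random:
        sets.extend(
            sample_random_gene_sets(
                ds, plan.random_set_size, plan.n_random,
                seed=_signature_seed(seed, ds_index, 0),
            )
        )
    if plan.reported:
        if all(isinstance(r, GeneSet) for r in plan.reported):
            present = set(ds.gene_ids)
            for gs in plan.reported:
                genes = tuple(g for g in gs.genes if g in present)
                if len(genes) / len(gs.genes) < plan.min_match or not genes:
                    logger.warning("reported set %s dropped on %s (match below %.0f%%)",
                                   gs.name, ds.name, 100 * plan.min_match)
                    continue
                sets.append(GeneSet(gs.name, genes, "reported", gs.method or gs.name))
        else:
            sets.extend(load_reported_gene_sets(plan.reported, ds, plan.min_match))
    for mi, method in enumerate(plan.ml_methods):
        params = dict(plan.ml_params.get(method, {}))
        sets.append(select_ml(ds, method, seed=_signature_seed(seed, ds_index, 1, mi), **params))
    return sets


def enumerate_grid(datasets, plan: GridPlan, model_ids) -> pd.DataFrame:
    """The planned (dataset, gene set, model) triples without any fitting.

    ML and reported entries appear as placeholders named after their method
    or file; used for cardinality checks and dry runs.
    """
    rows = []
    for ds in datasets:
        names = (
            [(f"random_{k:03d}", "random", "random") for k in range(plan.n_random)]
            + [
                (getattr(r, "name", None) or str(r), "reported", "reported")
                for r in plan.reported
            ]
            + [(m.lower(), "ml", m) for m in plan.ml_methods]
        )
        for set_name, origin, method in names:
            for model_id in model_ids:
                rows.append((ds.name, set_name, origin, method, model_id))
    return pd.DataFrame(rows, columns=["dataset", "gene_set", "origin", "method", "model_id"])


def run_grid(datasets, plan: GridPlan, model_ids, seed: int = 0, progress: bool = False) -> list:
    """Evaluate the full Cartesian grid dataset x gene set x model.

    Per-signature CV permutations are seeded from the grid seed and the
    (dataset, set, model) indices, making the grid bit-reproducible.
    """
    results: list[SignatureResult] = []
    for di, ds in enumerate(datasets):
        sets = build_gene_sets(ds, plan, seed, di)
        for si, gs in enumerate(sets):
            for mi, model_id in enumerate(model_ids):
                spec = ModelSpec(model_id, seed=_signature_seed(seed, di, si, mi, 1))
                res = evaluate_signature(
                    ds, gs, spec, seed=_signature_seed(seed, di, si, mi, 2)
                )
                results.append(res)
            if progress and (si + 1) % 25 == 0:
                logger.info("%s: %d/%d gene sets done", ds.name, si + 1, len(sets))
        logger.info("dataset %s done (%d results so far)", ds.name, len(results))
    return results


def results_to_frame(results) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "dataset": r.dataset, "gene_set": r.gene_set, "origin": r.origin,
            "method": r.method, "model_id": r.model_id, "median_c": r.median_c,
        }
        row.update({f"fold{k + 1}": c for k, c in enumerate(r.fold_c)})
        rows.append(row)
    cols = ["dataset", "gene_set", "origin", "method", "model_id",
            "fold1", "fold2", "fold3", "fold4", "fold5", "median_c"]
    return pd.DataFrame(rows, columns=cols)


def summarize(results, group_by=("dataset", "model_id")) -> list:
    """MOM / MAD / MAX of signature medians per (dataset, model) group."""
    df = results if isinstance(results, pd.DataFrame) else results_to_frame(results)
    if df.empty:
        raise ValueError("no results to summarize")
    out = []
    for key, grp in df.groupby(list(group_by), sort=True):
        med = grp["median_c"].dropna().to_numpy()
        if med.size == 0:
            raise ValueError(f"group {key} has no defined signature medians")
        mom = float(np.median(med))
        out.append(
            SummaryStats(
                dataset=str(key[0]), model_id=str(key[-1]), mom=mom,
                mad=float(np.median(np.abs(med - mom))),
                max_c=float(med.max()), n_signatures=int(med.size),
            )
        )
    return out


def correlate_with_cohort(summary, datasets) -> pd.DataFrame:
    """Correlate MOM and MAD with cohort size and event rate, per model.

    Returns Pearson and Spearman coefficients with two-sided p-values for
    each (model, statistic, covariate) combination across datasets.  Needs at
    least three datasets.
    """
    meta = {ds.name: (ds.n_samples, ds.event_rate) for ds in datasets}
    rows = []
    df = pd.DataFrame(
        [(s.dataset, s.model_id, s.mom, s.mad) for s in summary],
        columns=["dataset", "model_id", "MOM", "MAD"],
    )
    for model_id, grp in df.groupby("model_id"):
        if grp["dataset"].nunique() < 3:
            raise ValueError(
                f"correlation needs >= 3 datasets, model {model_id!r} has {grp['dataset'].nunique()}"
            )
        n_patients = np.array([meta[d][0] for d in grp["dataset"]], dtype=float)
        event_rate = np.array([meta[d][1] for d in grp["dataset"]], dtype=float)
        for stat_name in ("MOM", "MAD"):
            vals = grp[stat_name].to_numpy()
            for cov_name, cov in (("n_patients", n_patients), ("event_rate", event_rate)):
                pear = stats.pearsonr(vals, cov)
                spear = stats.spearmanr(vals, cov)
                rows.append(
                    {
                        "model_id": model_id, "statistic": stat_name, "covariate": cov_name,
                        "pearson_r": float(pear.statistic), "pearson_p": float(pear.pvalue),
                        "spearman_r": float(spear.statistic), "spearman_p": float(spear.pvalue),
                    }
                )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RSSPrevalence:
    """Random-signature-superiority prevalence against a reference signature."""

    per_group: pd.DataFrame  # dataset, model_id, fraction_above, n_random
    average: float


def rss_prevalence(random_results, reference_results) -> RSSPrevalence:
    """Fraction of random signatures strictly above the reference's median C.

    Matching is per (dataset, model); the across-group mean is the headline
    prevalence figure.
    """
    refs = {}
    ref_list = reference_results if isinstance(reference_results, (list, tuple)) else [reference_results]
    for r in ref_list:
        refs[(r.dataset, r.model_id)] = r.median_c
    rows = []
    df = results_to_frame(random_results)
    for (dataset, model_id), grp in df.groupby(["dataset", "model_id"]):
        key = (dataset, model_id)
        if key not in refs:
            continue
        med = grp["median_c"].dropna().to_numpy()
        if med.size == 0:
            continue
        frac = float(np.mean(med > refs[key]))
        rows.append({"dataset": dataset, "model_id": model_id,
                     "fraction_above": frac, "n_random": int(med.size)})
    if not rows:
        raise ValueError("no (dataset, model) group matches a reference result")
    per_group = pd.DataFrame(rows)
    return RSSPrevalence(per_group=per_group, average=float(per_group["fraction_above"].mean()))


def ceiling_curve(results, thresholds, cut: float = 0.01) -> CeilingCurve:
    """Fraction of signature medians strictly above each threshold.

    ``ceiling_estimate`` is the smallest grid threshold where the fraction
    drops below ``cut``; ``zero_threshold`` where it reaches zero (NaN if the
    grid never gets there).
    """
    if isinstance(results, pd.DataFrame):
        med = results["median_c"].to_numpy()
    elif len(results) and isinstance(results[0], SignatureResult):
        med = np.array([r.median_c for r in results])
    else:
        med = np.asarray(results, dtype=float)
    med = med[~np.isnan(med)]
    if med.size == 0:
        raise ValueError("no signature medians supplied")
    thresholds = np.asarray(sorted(thresholds), dtype=float)
    frac = np.array([np.mean(med > t) for t in thresholds])
    below = np.flatnonzero(frac < cut)
    zero = np.flatnonzero(frac == 0.0)
    return CeilingCurve(
        thresholds=thresholds,
        fraction_above=frac,
        ceiling_estimate=float(thresholds[below[0]]) if below.size else float("nan"),
        zero_threshold=float(thresholds[zero[0]]) if zero.size else float("nan"),
        cut=cut,
    )


def rank_sum_test(a, b):
    """Two-sided Wilcoxon rank-sum comparison of two vectors of medians."""
    res = stats.mannwhitneyu(np.asarray(a), np.asarray(b), alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
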