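"""Cross-validation harness and experiment orchestration.

Implements the evaluation designs used to benchmark genomic prediction on
a single population:

* repeated k-fold cross-validation (default five folds, five repeats) with
  **within-fold** GWAS preselection: the association scan that ranks
  markers is refitted on the training individuals of every fold, so no
  validation phenotype can influence marker choice, centering, variance
  components, or model fitting;
* the **inflation audit**: an ``all_gwas`` mode that deliberately selects
  markers from a whole-population scan (validation individuals included)
  — the biased design whose apparent accuracy overstates the truth, kept
  as a measurable contrast against the honest ``cv_gwas`` mode;
* a marker-density sweep and a training-population-size sweep with one
  frozen validation set.

Accuracy is the Pearson correlation between predicted GEBVs and the masked
observed phenotypes of the validation individuals, aggregated as mean ±
sd over the fold-by-repeat grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, PhenotypeSet
from .gpmodels import (
    McmcConfig,
    accuracy,
    fit_bayes,
    fit_gblup,
    predict_bayes,
    predict_gblup,
)
from .gwas import GwasResult, scan, vanraden_g
from .snpselect import select_evenly, select_gwas, select_random

__all__ = [
    "FoldPlan",
    "AccuracyRecord",
    "make_folds",
    "run_cv",
    "density_sweep",
    "training_size_sweep",
    "summarize",
    "optimal_density",
    "records_to_frame",
]


@dataclass(frozen=True)
class FoldPlan:
    """Repeated k-fold partition of ``n`` samples.

    ``assignments[r][f]`` is the index array of fold ``f`` in repeat
    ``r``; within a repeat the folds are disjoint, cover all samples, and
    differ in size by at most one.
    """

    n: int
    k: int
    repeats: int
    seed: int
    assignments: tuple[tuple[np.ndarray, ...], ...]


@dataclass
class AccuracyRecord:
    """One cross-validation cell: strategy x model x density x fold."""

    strategy: str
    model: str
    density: int
    mode: str
    repeat: int
    fold: int
    r: float | None
    n_train: int = 0
    n_val: int = 0
    reason: str | None = None


def make_folds(n: int, k: int = 5, repeats: int = 5, seed: int = 0) -> FoldPlan:
    """Random near-equal k-fold partitions, one per repeat.

    Fold sizes are ``n // k`` with the first ``n % k`` folds one larger
    (e.g. n=692, k=5 gives sizes 139, 139, 138, 138, 138).
    """
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    rng = np.random.default_rng(seed)
    reps = []
    sizes = [n // k + (1 if f < n % k else 0) for f in range(k)]
    for _ in range(repeats):
        perm = rng.permutation(n)
        folds, start = [], 0
        for sz in sizes:
            folds.append(np.sort(perm[start : start + sz]))
            start += sz
        reps.append(tuple(folds))
    return FoldPlan(n=n, k=k, repeats=repeats, seed=seed, assignments=tuple(reps))


def _select_panel(
    strategy: str,
    density: int,
    genotypes: GenotypeMatrix,
    gwas_result: GwasResult | None,
    seed: int,
):
    if strategy == "gwas":
        if gwas_result is None:
            raise ValueError("gwas strategy needs a GwasResult")
        return select_gwas(gwas_result, density, genotypes.layout)
    if strategy == "evenly":
        return select_evenly(genotypes.layout, density)
    if strategy == "random":
        return select_random(genotypes.layout, density, seed)
    raise ValueError(f"unknown strategy {strategy!r}")


def _fit_and_predict(
    model: str,
    panel: GenotypeMatrix,
    y: np.ndarray,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    mcmc: McmcConfig,
) -> np.ndarray:
    """Fit one model on the training rows of ``panel`` and return
    validation GEBVs.  Only ``y[train_idx]`` is ever read."""
    x_train = panel.values[train_idx].astype(float)
    x_val = panel.values[val_idx].astype(float)
    y_train = y[train_idx]
    if model == "GBLUP":
        fit = fit_gblup(y_train, x_train)
        return predict_gblup(fit, genotypes_test=x_val, x_train=x_train)
    fit = fit_bayes(model, y_train, x_train, mcmc)
    return predict_bayes(fit, x_val)


def run_cv(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeSet,
    plan: FoldPlan,
    strategy: str = "evenly",
    model: str = "GBLUP",
    density: int = 1000,
    mode: str = "cv_gwas",
    mcmc: McmcConfig | None = None,
    return_predictions: bool = False,
):
    """Repeated k-fold cross-validation of one strategy x model x density cell.

    ``mode="cv_gwas"`` refits the GWAS ranking on the training individuals
    of every fold (the honest design); ``mode="all_gwas"`` ranks markers by
    one whole-population scan that includes the validation individuals —
    the preselection-leakage arm retained as an audit.  For the
    phenotype-free strategies (evenly, random) the panel is chosen once per
    repeat.  Every model sees identical fold data.

    Returns a list of :class:`AccuracyRecord`; with
    ``return_predictions=True`` also a dict mapping ``(repeat, fold)`` to
    the validation GEBV array (used e.g. to assert that poisoning
    validation phenotypes leaves predictions untouched).
    """
    if mode not in ("cv_gwas", "all_gwas"):
        raise ValueError(f"unknown mode {mode!r}")
    if plan.n != genotypes.n:
        raise ValueError("fold plan does not match panel size")
    mcmc = mcmc or McmcConfig()
    y = phenotypes.y
    records: list[AccuracyRecord] = []
    predictions: dict[tuple[int, int], np.ndarray] = {}

    whole_scan: GwasResult | None = None
    if strategy == "gwas" and mode == "all_gwas":
        whole_scan = scan(y, genotypes, vanraden_g(genotypes))

    for rep, folds in enumerate(plan.assignments):
        # phenotype-free selections: once per repeat (random gets a fresh seed)
        panel_rep: GenotypeMatrix | None = None
        if strategy in ("evenly", "random"):
            sel_seed = int(np.random.default_rng([plan.seed, rep, 9173]).integers(2**31))
            keys = _select_panel(strategy, density, genotypes, None, sel_seed)
            panel_rep = genotypes.subset_snps(keys)

        for f, val_idx in enumerate(folds):
            train_idx = np.sort(np.concatenate([folds[j] for j in range(plan.k) if j != f]))
            if strategy == "gwas":
                if mode == "all_gwas":
                    fold_scan = whole_scan
                else:
                    g_train = genotypes.subset_samples(train_idx)
                    fold_scan = scan(y[train_idx], g_train, vanraden_g(g_train))
                keys = select_gwas(fold_scan, density, genotypes.layout)
                panel = genotypes.subset_snps(keys)
            else:
                panel = panel_rep

            gebv = _fit_and_predict(model, panel, y, train_idx, val_idx, mcmc)
            if return_predictions:
                predictions[(rep, f)] = gebv
            r = accuracy(gebv, y[val_idx])
            records.append(
                AccuracyRecord(
                    strategy=strategy,
                    model=model,
                    density=density,
                    mode=mode,
                    repeat=rep,
                    fold=f,
                    r=r,
                    n_train=train_idx.size,
                    n_val=val_idx.size,
                    reason=None if r is not None else "degenerate validation variance",
                )
            )
    if return_predictions:
        return records, predictions
    return records


def density_sweep(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeSet,
    plan: FoldPlan,
    densities,
    strategy: str = "evenly",
    model: str = "GBLUP",
    mode: str = "cv_gwas",
    mcmc: McmcConfig | None = None,
) -> list[AccuracyRecord]:
    """Cross-validated accuracy over a grid of marker-panel densities."""
    records: list[AccuracyRecord] = []
    for density in densities:
        records.extend(
            run_cv(genotypes, phenotypes, plan, strategy, model, density, mode, mcmc)
        )
    return records


def training_size_sweep(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeSet,
    sizes,
    fixed_validation_n: int = 138,
    strategy: str = "evenly",
    density: int = 10_000,
    replicates: int = 5,
    seed: int = 0,
) -> list[AccuracyRecord]:
    """Accuracy as a function of training-population size.

    One validation set of ``fixed_validation_n`` individuals is drawn once
    and frozen across every cell; for each size and replicate a fresh
    training subset is sampled from the remainder, markers are selected
    (GWAS strategy: scan on that training subset only) and GBLUP is
    fitted.
    """
    n = genotypes.n
    if max(sizes) + fixed_validation_n > n:
        raise ValueError("sizes + fixed_validation_n exceed the population")
    rng = np.random.default_rng(seed)
    val_idx = np.sort(rng.choice(n, size=fixed_validation_n, replace=False))
    pool = np.setdiff1d(np.arange(n), val_idx)
    y = phenotypes.y
    density = min(density, genotypes.p)
    records: list[AccuracyRecord] = []
    for size in sizes:
        for rep in range(replicates):
            train_idx = np.sort(rng.choice(pool, size=size, replace=False))
            if strategy == "gwas":
                g_train = genotypes.subset_samples(train_idx)
                fold_scan = scan(y[train_idx], g_train, vanraden_g(g_train))
                keys = select_gwas(fold_scan, density, genotypes.layout)
            else:
                sel_seed = int(rng.integers(2**31))
                keys = _select_panel(strategy, density, genotypes, None, sel_seed)
            panel = genotypes.subset_snps(keys)
            gebv = _fit_and_predict("GBLUP", panel, y, train_idx, val_idx, McmcConfig())
            r = accuracy(gebv, y[val_idx])
            records.append(
                AccuracyRecord(
                    strategy=strategy,
                    model="GBLUP",
                    density=density,
                    mode="cv_gwas",
                    repeat=rep,
                    fold=size,  # fold slot carries the training size
                    r=r,
                    n_train=size,
                    n_val=fixed_validation_n,
                    reason=None if r is not None else "degenerate validation variance",
                )
            )
    return records


def records_to_frame(records) -> pd.DataFrame:
    """Tidy one-record-per-row table (serialize with ``to_csv``)."""
    return pd.DataFrame([vars(r) for r in records])


def summarize(records, by=("strategy", "model", "density", "mode")) -> pd.DataFrame:
    """Per-cell mean ± sd of accuracy (sample sd; missing r excluded,
    counted in ``n_missing``)."""
    df = records_to_frame(records)
    if df.empty:
        raise ValueError("no records to summarize")
    by = list(by)
    out = (
        df.groupby(by, sort=True)["r"]
        .agg(
            mean_r=lambda s: s.dropna().mean(),
            sd_r=lambda s: s.dropna().std(ddof=1),
            n=lambda s: s.notna().sum(),
            n_missing=lambda s: s.isna().sum(),
        )
        .reset_index()
    )
    return out


def optimal_density(summary: pd.DataFrame) -> int:
    """Smallest density whose mean accuracy is within one sd of the best.

    The cost/accuracy elbow rule: among the summarized densities (one
    strategy/model at a time), find the maximum mean accuracy and report
    the smallest panel whose mean is within one sd (at the maximum) of it.
    """
    s = summary.sort_values("density")
    best = s.loc[s["mean_r"].idxmax()]
    threshold = best["mean_r"] - (best["sd_r"] if np.isfinite(best["sd_r"]) else 0.0)
    ok = s[s["mean_r"] >= threshold]
    return int(ok["density"].iloc[0])
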