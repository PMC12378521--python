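"""Genomic prediction models.

Six whole-genome regressions of a quantitative trait on a marker panel:

* **GBLUP** — linear mixed model with the VanRaden relationship matrix;
  variance components by REML (shared code path with the GWAS null model),
  training GEBVs from the mixed-model equations, test GEBVs by kinship
  regression on the training block.  Equivalent to ridge regression on
  centered markers (RR-BLUP) with penalty ``sigma_e2 * denom / sigma_g2``.
* **BayesA / BayesB / BayesC / Bayesian LASSO / Bayesian ridge (BRR)** —
  single-site Gibbs samplers differing only in the prior on marker
  effects: scaled-t (per-marker variances), spike-and-slab with scaled-t
  slab, spike-and-slab with a common slab variance, double-exponential via
  the exponential scale mixture, and a common Gaussian prior.

Hyperpriors follow the usual whole-genome-regression convention:
scaled-inverse-chi-square with 5 degrees of freedom, scales set so the
prior mode allocates a fraction ``r2 = 0.5`` of the phenotypic variance to
the markers.  Markers are centered by *training* allele frequencies only;
prediction applies the same centering to test genotypes, so no information
from validation individuals enters the fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import GenotypeMatrix, KinshipMatrix, PhenotypeSet, VarianceComponents
from .gwas import fit_null_mlm

__all__ = [
    "BAYES_MODELS",
    "ALL_MODELS",
    "McmcConfig",
    "MarkerEffects",
    "GpFit",
    "fit_gblup",
    "predict_gblup",
    "fit_bayes",
    "predict_bayes",
    "fit_model",
    "predict",
    "save_fit",
    "load_fit",
    "accuracy",
]

BAYES_MODELS = ("BayesA", "BayesB", "BayesC", "BL", "BRR")
ALL_MODELS = ("GBLUP",) + BAYES_MODELS

_RIDGE = 1e-8


@dataclass(frozen=True)
class McmcConfig:
    """Gibbs-sampler settings.

    Defaults are 10,000 iterations with a 2,000-iteration burn-in, thin 1
    (running posterior means, no stored chains).  ``pi0`` is the prior
    proportion of zero-effect markers for the spike-and-slab models, held
    fixed.  ``prior_df`` and ``prior_r2`` control the scaled-inverse-
    chi-square variance hyperpriors.
    """

    n_iter: int = 10_000
    burn_in: int = 2_000
    thin: int = 1
    seed: int = 0
    pi0: float = 0.95
    prior_df: float = 5.0
    prior_r2: float = 0.5
    store_traces: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must be in [0, n_iter)")
        if not 0.0 <= self.pi0 < 1.0:
            raise ValueError("pi0 must lie in [0, 1)")


@dataclass
class MarkerEffects:
    """Posterior-mean intercept and marker effects (trait units per allele)."""

    mu: float
    beta: np.ndarray
    inclusion_prob: np.ndarray | None = None  # spike-and-slab models only
    allele_freq: np.ndarray | None = None  # training centering frequencies


@dataclass
class GpFit:
    """A fitted genomic-prediction model.

    Exactly one of ``effects`` (marker-effect models) or
    ``gblup_solution`` is populated.
    """

    model: str
    effects: MarkerEffects | None = None
    gblup_solution: dict | None = None
    vc: VarianceComponents | None = None
    diagnostics: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# GBLUP
# --------------------------------------------------------------------------

def _vanraden_blocks(
    x_train: np.ndarray, x_test: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray | None, float, np.ndarray]:
    """G_train,train and G_test,train with centering and the scaling
    denominator taken from the training sample only."""
    freq = x_train.mean(axis=0) / 2.0
    denom = 2.0 * float(np.sum(freq * (1.0 - freq)))
    if denom <= 0.0:
        raise ValueError("all training markers monomorphic")
    w_train = x_train - 2.0 * freq
    g_tt = (w_train @ w_train.T) / denom
    g_ct = None
    if x_test is not None:
        w_test = x_test - 2.0 * freq
        g_ct = (w_test @ w_train.T) / denom
    return g_tt, g_ct, denom, freq


def fit_gblup(
    y_train: np.ndarray | PhenotypeSet,
    genotypes_train: GenotypeMatrix | np.ndarray,
    kinship: KinshipMatrix | None = None,
    vc: VarianceComponents | None = None,
) -> GpFit:
    """Fit GBLUP on the training individuals.

    The relationship matrix is built from the training genotypes (or passed
    in); variance components come from REML unless supplied.  Training
    GEBVs solve ``u_hat = sigma_g2 G V^{-1} (y - mu_hat)`` with
    ``V = sigma_g2 G + sigma_e2 I``.
    """
    y = y_train.y if isinstance(y_train, PhenotypeSet) else np.asarray(y_train, float)
    x = (
        genotypes_train.values.astype(float)
        if isinstance(genotypes_train, GenotypeMatrix)
        else np.asarray(genotypes_train, float)
    )
    if kinship is None:
        g_tt, _, denom, freq = _vanraden_blocks(x, None)
    else:
        g_tt, denom = kinship.values, kinship.denominator
        freq = x.mean(axis=0) / 2.0
    if vc is None:
        vc = fit_null_mlm(y, KinshipMatrix(g_tt, denom))
    n = y.size
    v = vc.sigma_g2 * g_tt + vc.sigma_e2 * np.eye(n)
    ones = np.ones(n)
    vinv_y = np.linalg.solve(v, y)
    vinv_1 = np.linalg.solve(v, ones)
    mu = float(ones @ vinv_y / (ones @ vinv_1))
    resid = y - mu
    u_hat = vc.sigma_g2 * (g_tt @ np.linalg.solve(v, resid))
    return GpFit(
        model="GBLUP",
        gblup_solution={
            "mu": mu,
            "u_train": u_hat,
            "g_train": g_tt,
            "x_train_freq": freq,
            "denominator": denom,
        },
        vc=vc,
    )


def predict_gblup(
    fit: GpFit,
    genotypes_test: GenotypeMatrix | np.ndarray | None = None,
    g_cross: np.ndarray | None = None,
    x_train: np.ndarray | None = None,
) -> np.ndarray:
    """GEBVs for test individuals by kinship regression.

    ``u_test = G_test,train G_train,train^{-1} u_train`` (ridge-stabilized).
    Supply either the cross-block ``g_cross`` directly, or the test
    genotypes together with the training genotype matrix used in the fit.
    """
    sol = fit.gblup_solution
    if sol is None:
        raise ValueError("not a GBLUP fit")
    if g_cross is None:
        if genotypes_test is None or x_train is None:
            raise ValueError("need g_cross, or genotypes_test plus x_train")
        xt = (
            genotypes_test.values.astype(float)
            if isinstance(genotypes_test, GenotypeMatrix)
            else np.asarray(genotypes_test, float)
        )
        freq = sol["x_train_freq"]
        w_test = xt - 2.0 * freq
        w_train = np.asarray(x_train, float) - 2.0 * freq
        g_cross = (w_test @ w_train.T) / sol["denominator"]
    g_tt = sol["g_train"]
    n = g_tt.shape[0]
    a = g_tt + _RIDGE * np.trace(g_tt) / n * np.eye(n)
    return g_cross @ np.linalg.solve(a, sol["u_train"])


# --------------------------------------------------------------------------
# Bayesian alphabet Gibbs samplers
# --------------------------------------------------------------------------

def _chi2_scale(df: float, mode: float) -> float:
    """Return nu*tau^2 of a scaled-inv-chi2 whose mode equals ``mode``."""
    return (df + 2.0) * mode


def fit_bayes(
    model: str,
    y_train: np.ndarray | PhenotypeSet,
    genotypes_train: GenotypeMatrix | np.ndarray,
    config: McmcConfig = McmcConfig(),
    *,
    fixed_sigma_e2: float | None = None,
    fixed_sigma_b2: float | None = None,
) -> GpFit:
    """Single-site Gibbs sampler for the Bayesian-alphabet models.

    ``model`` is one of ``BayesA``, ``BayesB``, ``BayesC``, ``BL``,
    ``BRR``.  Residual-update bookkeeping keeps the per-iteration cost at
    O(n*p).  ``fixed_sigma_e2`` / ``fixed_sigma_b2`` clamp the variance
    draws (used for conjugate closed-form checks).

    Raises on non-finite variance draws, dumping the iteration number and
    current state sizes in the exception message.
    """
    if model not in BAYES_MODELS:
        raise ValueError(f"unknown Bayesian model {model!r}; one of {BAYES_MODELS}")
    y = y_train.y if isinstance(y_train, PhenotypeSet) else np.asarray(y_train, float)
    x_raw = (
        genotypes_train.values.astype(float)
        if isinstance(genotypes_train, GenotypeMatrix)
        else np.asarray(genotypes_train, float)
    )
    n, p = x_raw.shape
    freq = x_raw.mean(axis=0) / 2.0
    w = x_raw - 2.0 * freq  # training-frequency centering
    x2 = np.einsum("ij,ij->j", w, w)
    active = x2 > 0  # monomorphic markers never move off zero

    rng = np.random.default_rng(config.seed)
    vary = float(np.var(y))
    msx = float(np.sum(np.var(w, axis=0)))
    if msx <= 0:
        msx = 1.0
    r2 = config.prior_r2
    df_b = config.prior_df
    df_e = config.prior_df
    # prior scale parameters: nu*tau^2 of the scaled-inv-chi2 priors
    mode_b = max(r2 * vary / msx, 1e-12)
    sb = _chi2_scale(df_b, mode_b)
    se_scale = _chi2_scale(df_e, max((1.0 - r2) * vary, 1e-12))
    # effective slab mode for spike-and-slab models: only (1-pi0) markers carry signal
    if model in ("BayesB", "BayesC") and config.pi0 > 0:
        sb = _chi2_scale(df_b, max(r2 * vary / (msx * (1.0 - config.pi0)), 1e-12))

    mu = float(np.mean(y))
    beta = np.zeros(p)
    e = y - mu
    sigma_e2 = fixed_sigma_e2 if fixed_sigma_e2 is not None else max(vary * (1.0 - r2), 1e-12)
    sigma_b = np.full(p, mode_b)  # per-marker (BayesA/B) or common value broadcast
    common_b2 = fixed_sigma_b2 if fixed_sigma_b2 is not None else mode_b
    delta = np.ones(p, dtype=bool)  # inclusion indicators (spike-and-slab)
    if model in ("BayesB", "BayesC"):
        delta = rng.random(p) >= config.pi0
    tau2 = np.full(p, 1.0)  # BL local scales
    lam2 = 2.0 * (1.0 - r2) * msx / max(r2, 1e-12)  # BL fixed regularization

    keep = 0
    beta_sum = np.zeros(p)
    mu_sum = 0.0
    incl_sum = np.zeros(p)
    traces: dict[str, list] = {"sigma_e2": [], "sigma_b2": []} if config.store_traces else {}

    log_prior_odds = None
    if model in ("BayesB", "BayesC"):
        pi0 = min(max(config.pi0, 1e-12), 1.0 - 1e-12)
        log_prior_odds = np.log((1.0 - pi0) / pi0)

    for it in range(config.n_iter):
        # intercept
        e += mu
        mu = float(np.mean(e)) + rng.standard_normal() * np.sqrt(sigma_e2 / n)
        e -= mu

        # marker effects, single site with residual update
        for j in range(p):
            if not active[j]:
                continue
            wj = w[:, j]
            b_old = beta[j]
            rhs = wj @ e + x2[j] * b_old
            if model == "BRR":
                var_j = common_b2
            elif model == "BayesA":
                var_j = sigma_b[j]
            elif model == "BayesB":
                var_j = sigma_b[j]
            elif model == "BayesC":
                var_j = common_b2
            else:  # BL
                var_j = sigma_e2 * tau2[j]

            if model in ("BayesB", "BayesC"):
                v1 = x2[j] * var_j + sigma_e2
                log_odds = (
                    log_prior_odds
                    - 0.5 * np.log(v1 / sigma_e2)
                    + 0.5 * rhs * rhs * var_j / (sigma_e2 * v1)
                )
                p_incl = 1.0 / (1.0 + np.exp(-np.clip(log_odds, -700, 700)))
                delta[j] = rng.random() < p_incl
                if not delta[j]:
                    if b_old != 0.0:
                        e += wj * b_old
                    beta[j] = 0.0
                    continue

            c = x2[j] + sigma_e2 / var_j
            b_new = rhs / c + rng.standard_normal() * np.sqrt(sigma_e2 / c)
            beta[j] = b_new
            e += wj * (b_old - b_new)

        # marker-effect variances
        if fixed_sigma_b2 is None:
            if model == "BRR":
                ssb = float(beta @ beta)
                common_b2 = (sb + ssb) / rng.chisquare(df_b + p)
            elif model == "BayesA":
                sigma_b = (sb + beta**2) / rng.chisquare(df_b + 1.0, size=p)
            elif model == "BayesB":
                # slab variances: posterior update for included, prior draw otherwise
                draw = (sb + beta**2) / rng.chisquare(df_b + 1.0, size=p)
                prior = sb / rng.chisquare(df_b, size=p)
                sigma_b = np.where(delta, draw, prior)
            elif model == "BayesC":
                m = int(delta.sum())
                ssb = float(beta[delta] @ beta[delta]) if m else 0.0
                common_b2 = (sb + ssb) / rng.chisquare(df_b + m)
            else:  # BL: inverse-Gaussian update of 1/tau^2
                bj = np.where(np.abs(beta) > 1e-12, np.abs(beta), 1e-12)
                mean_ig = np.sqrt(lam2 * sigma_e2) / bj
                inv_tau2 = rng.wald(mean_ig, lam2)
                tau2 = 1.0 / np.clip(inv_tau2, 1e-12, None)

        # residual variance
        if fixed_sigma_e2 is None:
            sse = float(e @ e)
            if model == "BL":
                # beta | tau2 scales with sigma_e2: include the prior quadratic form
                sse_full = sse + float(np.sum(beta**2 / tau2))
                sigma_e2 = (se_scale + sse_full) / rng.chisquare(df_e + n + int(active.sum()))
            else:
                sigma_e2 = (se_scale + sse) / rng.chisquare(df_e + n)

        if not np.isfinite(sigma_e2) or not np.all(np.isfinite(beta)):
            raise FloatingPointError(
                f"divergent draw at iteration {it}: sigma_e2={sigma_e2!r}, "
                f"|beta|_max={np.max(np.abs(beta))!r}"
            )

        if config.store_traces:
            traces["sigma_e2"].append(sigma_e2)
            traces["sigma_b2"].append(common_b2 if model in ("BRR", "BayesC") else float(np.mean(sigma_b)))

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            keep += 1
            beta_sum += beta
            mu_sum += mu
            if model in ("BayesB", "BayesC"):
                incl_sum += delta

    effects = MarkerEffects(
        mu=mu_sum / keep,
        beta=beta_sum / keep,
        inclusion_prob=(incl_sum / keep) if model in ("BayesB", "BayesC") else None,
        allele_freq=freq,
    )
    return GpFit(model=model, effects=effects, diagnostics={"traces": traces, "kept": keep})


def predict_bayes(fit: GpFit, genotypes_test: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """GEBVs for test individuals: centered test genotypes times the
    posterior-mean marker effects (training-frequency centering)."""
    if fit.effects is None:
        raise ValueError("not a marker-effect fit")
    xt = (
        genotypes_test.values.astype(float)
        if isinstance(genotypes_test, GenotypeMatrix)
        else np.asarray(genotypes_test, float)
    )
    w = xt - 2.0 * fit.effects.allele_freq
    return w @ fit.effects.beta


# --------------------------------------------------------------------------
# unified front door and accuracy
# --------------------------------------------------------------------------

def fit_model(
    model: str,
    y_train,
    genotypes_train,
    config: McmcConfig = McmcConfig(),
) -> GpFit:
    """Fit any of the six models by name (``GBLUP`` or a Bayesian model)."""
    if model == "GBLUP":
        return fit_gblup(y_train, genotypes_train)
    return fit_bayes(model, y_train, genotypes_train, config)


def predict(fit: GpFit, genotypes_test, x_train: np.ndarray | None = None) -> np.ndarray:
    """GEBVs for test individuals from any fitted model."""
    if fit.model == "GBLUP":
        return predict_gblup(fit, genotypes_test=genotypes_test, x_train=x_train)
    return predict_bayes(fit, genotypes_test)


def save_fit(fit: GpFit, prefix: str) -> None:
    """Serialize a fit as ``<prefix>.effects.tsv`` + ``<prefix>.meta.json``.

    Marker-effect models store per-marker posterior means (and inclusion
    probabilities where defined); GBLUP stores the training GEBVs.  The
    metadata carries the model name, intercept and variance components.
    """
    import json

    import pandas as pd

    meta: dict = {"model": fit.model}
    if fit.effects is not None:
        meta["mu"] = fit.effects.mu
        table = pd.DataFrame({"beta": fit.effects.beta})
        if fit.effects.inclusion_prob is not None:
            table["inclusion_prob"] = fit.effects.inclusion_prob
        if fit.effects.allele_freq is not None:
            table["allele_freq"] = fit.effects.allele_freq
    else:
        sol = fit.gblup_solution
        meta["mu"] = sol["mu"]
        meta["denominator"] = sol["denominator"]
        meta["sigma_g2"] = fit.vc.sigma_g2
        meta["sigma_e2"] = fit.vc.sigma_e2
        table = pd.DataFrame({"u_train": sol["u_train"]})
    table.to_csv(f"{prefix}.effects.tsv", sep="\t", index=False)
    with open(f"{prefix}.meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_fit(prefix: str) -> GpFit:
    """Load a marker-effect fit written by :func:`save_fit`.

    GBLUP archives store the training solution but not the training
    kinship block, so only marker-effect models round-trip to a
    predict-ready fit.
    """
    import json

    import pandas as pd

    with open(f"{prefix}.meta.json") as fh:
        meta = json.load(fh)
    table = pd.read_csv(f"{prefix}.effects.tsv", sep="\t")
    if meta["model"] == "GBLUP":
        raise ValueError("GBLUP archives are summaries; refit to predict")
    effects = MarkerEffects(
        mu=meta["mu"],
        beta=table["beta"].to_numpy(),
        inclusion_prob=(
            table["inclusion_prob"].to_numpy() if "inclusion_prob" in table else None
        ),
        allele_freq=table["allele_freq"].to_numpy() if "allele_freq" in table else None,
    )
    return GpFit(model=meta["model"], effects=effects)


def accuracy(gebv: np.ndarray, y_observed: np.ndarray) -> float | None:
    """Prediction accuracy: Pearson correlation of GEBVs with the masked
    observed phenotypes.  ``None`` (missing, not 0) when either side has
    zero variance or fewer than 3 pairs."""
    gebv = np.asarray(gebv, float)
    y_observed = np.asarray(y_observed, float)
    if gebv.size != y_observed.size:
        raise ValueError("length mismatch")
    if gebv.size < 3:
        return None
    if np.std(gebv) == 0.0 or np.std(y_observed) == 0.0:
        return None
    return float(stats.pearsonr(gebv, y_observed).statistic)
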