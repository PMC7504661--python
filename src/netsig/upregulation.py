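"""Per-gene Bayesian null model and doubled-variable up-regulation calls.

For each gene the control (normal-tissue) values ``D`` are modeled as draws
from Normal(mu, sigma^2) with independent priors

    mu      ~ Normal(w0, v0)
    sigma^2 ~ InverseGamma(a0, b0)

with vague defaults w0=0, v0=1e4, a0=1e-3, b0=1e-3.  The posterior
p(mu, sigma^2 | D) is simulated by a Gibbs sampler (both full conditionals
are available in closed form for this semi-conjugate model), and the
posterior predictive p(x | D) by drawing one new observation per posterior
draw.  The decision variable is the doubled predictive draw y = 2x: a tumor
value x is scored by the upper-tail mass P(Y >= x) of a kernel-density
estimate of y, so a gene must exceed a doubling of its own predictive
distribution -- not merely of the control mean -- to reach a small p-value.

A gene is called up-regulated in a tumor sample when fold change >= 2 AND
the doubled-variable p-value <= 0.05 (both gates, by default).
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.stats import gaussian_kde

from netsig.data_io import ExpressionMatrix

__all__ = [
    "PriorSpec",
    "McmcSettings",
    "GeneNullModel",
    "fit_null_model",
    "fit_null_models",
    "pvalue_doubled",
    "invert_threshold",
    "gene_probability",
    "call_upregulated",
]

RHAT_THRESHOLD = 1.05


@dataclass(frozen=True)
class PriorSpec:
    """Priors for the per-gene null: mu ~ N(w0, v0), sigma^2 ~ IG(a0, b0)."""

    w0: float = 0.0
    v0: float = 1e4
    a0: float = 1e-3
    b0: float = 1e-3

    def __post_init__(self) -> None:
        if self.v0 <= 0 or self.a0 <= 0 or self.b0 <= 0:
            raise ValueError("v0, a0, b0 must all be positive")


@dataclass(frozen=True)
class McmcSettings:
    """Sampler configuration.  ``predictive_draws`` defaults to chains x draws."""

    n_draws: int = 2000
    n_tune: int = 1000
    n_chains: int = 2
    seed: int = 0
    # KDE sample size for the doubled-variable density; 16k keeps the
    # smoothed tail within ~3e-3 of the empirical tail fraction
    predictive_draws: int | None = 16000
    grid_size: int = 1024

    def __post_init__(self) -> None:
        if self.n_draws < 1 or self.n_tune < 0 or self.n_chains < 1:
            raise ValueError("draw/tune/chain counts must be positive")
        if self.grid_size < 16:
            raise ValueError("grid_size too small for stable quadrature")

    @property
    def total_draws(self) -> int:
        return self.n_draws * self.n_chains

    @property
    def n_predictive(self) -> int:
        return self.predictive_draws if self.predictive_draws is not None else self.total_draws


@dataclass
class GeneNullModel:
    """Posterior and posterior-predictive summaries for one gene.

    ``grid``/``density`` tabulate the KDE of the doubled predictive variable
    y = 2x; ``survival`` is its upper-tail mass S(t) = P(Y >= t), computed by
    trapezoidal quadrature and clamped to [0, 1].
    """

    gene: str
    mu_draws: np.ndarray          # shape (chains, draws)
    sigma2_draws: np.ndarray      # shape (chains, draws)
    predictive: np.ndarray        # shape (n_predictive,)
    grid: np.ndarray
    density: np.ndarray
    survival: np.ndarray
    n_control: int
    settings: McmcSettings
    rhat_mu: float = float("nan")
    rhat_sigma2: float = float("nan")
    warnings: list[str] = field(default_factory=list)

    @property
    def doubled(self) -> np.ndarray:
        return 2.0 * self.predictive

    @property
    def converged(self) -> bool:
        return max(self.rhat_mu, self.rhat_sigma2) <= RHAT_THRESHOLD


def _split_rhat(draws: np.ndarray) -> np.ndarray:
    """Split-R-hat per gene over (chains, draws, G) draw arrays."""
    import arviz

    if draws.ndim == 2:
        draws = draws[:, :, None]
    half = draws.shape[1] // 2
    split = np.concatenate([draws[:, :half], draws[:, half : 2 * half]], axis=0)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        return np.atleast_1d(np.asarray(arviz.rhat(arviz.convert_to_dataset(split))["x"].values))


def _gibbs_batch(
    data: np.ndarray,
    priors: PriorSpec,
    settings: McmcSettings,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Gibbs-sample (mu, sigma^2) for a batch of genes simultaneously.

    ``data`` is (G, n).  Returns (mu, sigma2) arrays of shape
    (chains, draws, G).  Full conditionals:

        mu | sigma^2, D      ~ Normal(m*, 1/prec),
            prec = 1/v0 + n/sigma^2,  m* = (w0/v0 + sum(D)/sigma^2) / prec
        sigma^2 | mu, D      ~ IG(a0 + n/2, b0 + sum((d - mu)^2)/2)
    """
    G, n = data.shape
    sum_d = data.sum(axis=1)
    sum_d2 = (data**2).sum(axis=1)
    xbar = sum_d / n
    s2 = data.var(axis=1, ddof=1) if n > 1 else np.ones(G)

    mu_out = np.empty((settings.n_chains, settings.n_draws, G))
    sig_out = np.empty((settings.n_chains, settings.n_draws, G))
    a_post = priors.a0 + n / 2.0

    for chain in range(settings.n_chains):
        # overdispersed starts: jitter around the sample moments
        mu = xbar + rng.standard_normal(G) * np.sqrt(np.maximum(s2, 1e-12) / n) * (1 + chain)
        sigma2 = np.maximum(s2, 1e-12) * rng.uniform(0.5, 2.0, size=G)
        for it in range(settings.n_tune + settings.n_draws):
            prec = 1.0 / priors.v0 + n / sigma2
            mean = (priors.w0 / priors.v0 + sum_d / sigma2) / prec
            mu = mean + rng.standard_normal(G) / np.sqrt(prec)
            sse = np.maximum(sum_d2 - 2.0 * mu * sum_d + n * mu**2, 0.0)
            sigma2 = (priors.b0 + sse / 2.0) / rng.gamma(a_post, 1.0, size=G)
            if it >= settings.n_tune:
                mu_out[chain, it - settings.n_tune] = mu
                sig_out[chain, it - settings.n_tune] = sigma2
    return mu_out, sig_out


def _build_density(doubled: np.ndarray, grid_size: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """KDE (Silverman bandwidth) of the doubled draws on an even grid.

    The grid spans [min, max] of the draws padded by 3 bandwidths; the
    density is renormalized to integrate to exactly 1 on the grid so the
    survival function is exact in [0, 1].
    """
    kde = gaussian_kde(doubled, bw_method="silverman")
    bw = float(kde.factor * doubled.std(ddof=1))
    if bw <= 0 or not np.isfinite(bw):
        bw = max(abs(doubled.mean()) * 1e-9, 1e-12)
    lo, hi = doubled.min() - 3 * bw, doubled.max() + 3 * bw
    grid = np.linspace(lo, hi, grid_size)
    density = np.maximum(kde(grid), 0.0)
    total = np.trapezoid(density, grid)
    density = density / total
    cdf = cumulative_trapezoid(density, grid, initial=0.0)
    survival = np.clip(1.0 - cdf, 0.0, 1.0)
    return grid, density, survival


def fit_null_models(
    control: ExpressionMatrix | np.ndarray,
    priors: PriorSpec | None = None,
    settings: McmcSettings | None = None,
    zero_variance: str = "error",
    genes: list[str] | None = None,
) -> dict[str, GeneNullModel]:
    """Fit the Bayesian null for every gene of a control matrix.

    The Gibbs updates are vectorized across genes (each gene's chain is
    still an independent Markov chain).  ``zero_variance`` is ``'error'``
    (default: a constant control vector raises, since the inverse-gamma
    posterior degenerates) or ``'jitter'`` (add Normal(0, 1e-6) jitter and
    record a warning on the model).
    """
    priors = priors or PriorSpec()
    settings = settings or McmcSettings()
    if isinstance(control, ExpressionMatrix):
        data = control.values
        gene_ids = control.genes
    else:
        data = np.atleast_2d(np.asarray(control, dtype=float))
        gene_ids = genes if genes is not None else [f"g{i}" for i in range(data.shape[0])]
    if data.shape[1] < 3:
        raise ValueError(f"need >= 3 control values per gene, got {data.shape[1]}")
    if not np.all(np.isfinite(data)):
        raise ValueError("control values must be finite")

    jittered: set[str] = set()
    flat = data.copy()
    const = np.ptp(flat, axis=1) == 0
    if const.any():
        offenders = [gene_ids[i] for i in np.where(const)[0]]
        if zero_variance == "error":
            raise ValueError(
                f"zero-variance control vector for gene(s) {offenders}; "
                "pass zero_variance='jitter' to proceed with 1e-6 jitter"
            )
        if zero_variance != "jitter":
            raise ValueError(f"zero_variance must be 'error' or 'jitter', got {zero_variance!r}")
        rng_j = np.random.default_rng(settings.seed + 993319)
        flat[const] = flat[const] + rng_j.normal(0.0, 1e-6, size=flat[const].shape)
        jittered = set(offenders)

    rng = np.random.default_rng(settings.seed)
    mu, sigma2 = _gibbs_batch(flat, priors, settings, rng)

    G = flat.shape[0]
    total = settings.total_draws
    n_pred = settings.n_predictive
    mu_flat = mu.reshape(total, G)
    sig_flat = sigma2.reshape(total, G)
    if n_pred == total:
        idx = np.arange(total)
    else:
        idx = rng.integers(0, total, size=n_pred)
    pred = mu_flat[idx] + np.sqrt(sig_flat[idx]) * rng.standard_normal((n_pred, G))

    if settings.n_chains >= 2:
        rhat_mu = _split_rhat(mu)
        rhat_sig = _split_rhat(sigma2)
    else:
        rhat_mu = rhat_sig = np.full(G, np.nan)

    models: dict[str, GeneNullModel] = {}
    for i, gene in enumerate(gene_ids):
        grid, density, survival = _build_density(2.0 * pred[:, i], settings.grid_size)
        model = GeneNullModel(
            gene=gene,
            mu_draws=mu[:, :, i],
            sigma2_draws=sigma2[:, :, i],
            predictive=pred[:, i],
            grid=grid,
            density=density,
            survival=survival,
            n_control=flat.shape[1],
            settings=settings,
        )
        if settings.n_chains >= 2:
            model.rhat_mu = float(rhat_mu[i])
            model.rhat_sigma2 = float(rhat_sig[i])
            if max(model.rhat_mu, model.rhat_sigma2) > RHAT_THRESHOLD:
                model.warnings.append(
                    f"split-R-hat above {RHAT_THRESHOLD}: "
                    f"mu={model.rhat_mu:.3f}, sigma2={model.rhat_sigma2:.3f}"
                )
        if gene in jittered:
            model.warnings.append("zero-variance controls: 1e-6 jitter applied")
        models[gene] = model
    return models


def fit_null_model(
    control_values: np.ndarray,
    priors: PriorSpec | None = None,
    settings: McmcSettings | None = None,
    gene: str = "gene",
    zero_variance: str = "error",
) -> GeneNullModel:
    """Fit the null for a single gene's control values (see fit_null_models)."""
    values = np.asarray(control_values, dtype=float).ravel()
    return fit_null_models(
        values[None, :], priors=priors, settings=settings, zero_variance=zero_variance, genes=[gene]
    )[gene]


def pvalue_doubled(model: GeneNullModel, x: float | np.ndarray) -> float | np.ndarray:
    """Upper-tail mass P(Y >= x) of the doubled predictive variable Y = 2X.

    Monotonically non-increasing in x; 1 below the density support, 0 above.
    """
    if model.survival is None or len(model.survival) == 0:
        raise ValueError(f"model for gene {model.gene!r} is not fitted")
    p = np.interp(x, model.grid, model.survival, left=1.0, right=0.0)
    return float(p) if np.isscalar(x) else p


def invert_threshold(model: GeneNullModel, alpha: float) -> float:
    """Smallest grid value x* with P(Y >= x*) <= alpha (the decision threshold)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    below = np.nonzero(model.survival <= alpha)[0]
    if len(below) == 0:  # alpha smaller than the residual mass at the grid edge
        return float(model.grid[-1])
    return float(model.grid[below[0]])


def gene_probability(model: GeneNullModel, x: float | np.ndarray) -> float | np.ndarray:
    """Up-regulation probability 1 - P(Y >= x); non-decreasing in x, in [0, 1]."""
    p = pvalue_doubled(model, x)
    return 1.0 - p


def call_upregulated(
    control: ExpressionMatrix,
    tumor: ExpressionMatrix,
    priors: PriorSpec | None = None,
    settings: McmcSettings | None = None,
    fold_threshold: float = 2.0,
    alpha: float = 0.05,
    zero_variance: str = "error",
    models: dict[str, GeneNullModel] | None = None,
):
    """Call per-sample up-regulated genes: fold >= fold_threshold AND p <= alpha.

    Fold change is tumor value / arithmetic control mean on the working
    (linear) scale; non-positive control means are rejected.  Returns a
    pandas DataFrame with one row per (sample, gene) and columns
    (sample, gene, value, control_mean, fold_change, p_value, up), plus the
    fitted models for reuse by downstream stages.
    """
    import pandas as pd

    if set(control.genes) != set(tumor.genes):
        only_c = sorted(set(control.genes) - set(tumor.genes))[:5]
        only_t = sorted(set(tumor.genes) - set(control.genes))[:5]
        raise ValueError(
            f"gene sets differ between control and tumor matrices; "
            f"control-only: {only_c}, tumor-only: {only_t}"
        )
    if models is None:
        models = fit_null_models(control, priors, settings, zero_variance=zero_variance)

    control_means = control.values.mean(axis=1)
    if np.any(control_means <= 0):
        bad = [control.genes[i] for i in np.where(control_means <= 0)[0]]
        raise ValueError(f"non-positive control mean for gene(s) {bad[:5]}; check the scale flag")

    rows = []
    mean_by_gene = dict(zip(control.genes, control_means))
    for gi, gene in enumerate(tumor.genes):
        model = models[gene]
        cmean = mean_by_gene[gene]
        values = tumor.values[gi]
        pvals = pvalue_doubled(model, values)
        folds = values / cmean
        up = (folds >= fold_threshold) & (pvals <= alpha)
        for sj, sample in enumerate(tumor.samples):
            rows.append((sample, gene, values[sj], cmean, folds[sj], pvals[sj], bool(up[sj])))
    calls = pd.DataFrame(
        rows, columns=["sample", "gene", "value", "control_mean", "fold_change", "p_value", "up"]
    )
    return calls, models
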