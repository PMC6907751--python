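"""Bayesian logistic regression of drug approval on genetic evidence.

The model, per target-indication pair i with approval outcome y_i:

    y_i ~ Bernoulli(logit^-1(alpha + eta_i + x_i' beta))

    eta_i = sum_{j=0..p} gamma_j * E_C(g_i, t_i)^j   if the target gene
                                                     has any association
          = 0                                        otherwise

with E_C the (standardized) continuous genetic-evidence score and x_i
non-genetic covariates: indication-class and target-class indicators,
development time, and RVIS, continuous columns standardized.  Priors:

    alpha ~ N(mu_a, sigma_a^2)      mu_a = -2.2, sigma_a = 0.75
    beta_j ~ iid N(0, sigma_b^2)    sigma_b = 2
    gamma_j ~ iid N(0, sigma_g^2)   sigma_g = 2

The intercept prior centers the baseline approval probability at
logit^-1(-2.2) ~ 10%, the long-run fraction of Phase I compounds that
reach approval.  Separate evidence sources (e.g. GWAS and curated
Mendelian links) each get their own existence indicator and gamma
vector within one model.

Sampling runs several independent Markov chains of an independence
Metropolis-Hastings kernel whose proposal is a multivariate-t centered
on the posterior mode with the Laplace (inverse-Hessian) covariance,
slightly inflated and heavy-tailed.  The posterior is a smooth,
unimodal logistic-regression posterior with Gaussian priors, for which
the Laplace approximation is close and the independence kernel yields
near-independent draws; the kernel is nevertheless an exact MCMC
method, so its output is correct even where the approximation is not.
Convergence is never assumed: split-Rhat and effective sample size are
computed with ArviZ across chains, and a fit is accepted only when
split-Rhat <= 1.01 and ESS >= 400 for every parameter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """Sampler diagnostics failed the acceptance contract."""


@dataclass(frozen=True)
class ModelSpec:
    """Priors, polynomial degree and sampler settings."""

    degree: int = 2
    mu_a: float = -2.2
    sigma_a: float = 0.75
    sigma_b: float = 2.0
    sigma_g: float = 2.0
    chains: int = 4
    warmup: int = 500
    draws: int = 1500
    seed: int = 0
    rhat_max: float = 1.01
    ess_min: float = 400.0

    def __post_init__(self) -> None:
        if self.degree < 0:
            raise ValueError("degree must be nonnegative")
        if min(self.sigma_a, self.sigma_b, self.sigma_g) <= 0:
            raise ValueError("prior SDs must be positive")


@dataclass
class EvidenceBlock:
    """Per-source evidence inputs: existence indicator and standardized
    continuous evidence (0 where no association exists)."""

    exists: np.ndarray
    z: np.ndarray
    mean: float
    sd: float


@dataclass
class DesignMatrix:
    """Covariate matrix plus evidence blocks and standardization metadata."""

    X: np.ndarray
    columns: list[str]
    standardization: dict[str, tuple[float, float]]
    evidence: dict[str, EvidenceBlock] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]


def select_model_universe(pairs: pd.DataFrame) -> pd.DataFrame:
    """Restrict to pairs informative about approval: those approved, or
    with no drug still in active development (an active unapproved
    program has an unresolved outcome).  Unknown-phase unapproved pairs
    stay in, with y = 0."""
    keep = pairs["approved"].astype(bool) | ~pairs["active"].astype(bool)
    out = pairs.loc[keep].reset_index(drop=True)
    out["y"] = out["approved"].astype(int)
    return out


def _standardize(values: np.ndarray) -> tuple[np.ndarray, float, float]:
    mean = float(np.mean(values))
    sd = float(np.std(values))
    if sd == 0.0:
        return np.zeros_like(values, dtype=float), mean, 1.0
    return (values - mean) / sd, mean, sd


def build_design(
    pairs: pd.DataFrame,
    categorical: list[str] = (),
    continuous: list[str] = (),
    evidence: pd.DataFrame | None = None,
    rare_level_min: int = 20,
    standardize_ec_over: str = "assoc",
) -> DesignMatrix:
    """Assemble the covariate matrix and evidence blocks.

    Categorical covariates are one-hot encoded with the alphabetically
    first level as the dropped reference; levels carried by fewer than
    ``rare_level_min`` pairs are pooled into "other".  Continuous
    covariates are standardized to mean 0, SD 1; missing values are
    imputed at the standardized mean (0) with a companion missingness
    indicator.  All-constant columns are dropped with a warning.

    ``evidence`` is a long table (gene_id, indication, source, e_c,
    has_assoc) aligned by (gene_id, indication) to ``pairs``; each
    source becomes an :class:`EvidenceBlock` with E_C standardized over
    the pairs whose gene has an association (``standardize_ec_over=
    "assoc"``, the only pairs where E_C enters the model) or over all
    pairs (``"all"``, treating absent evidence as 0 before scaling).
    """
    n = len(pairs)
    cols: list[np.ndarray] = []
    names: list[str] = []
    standardization: dict[str, tuple[float, float]] = {}

    for cov in categorical:
        levels = pairs[cov].astype(str)
        counts = levels.value_counts()
        rare = set(counts.index[counts < rare_level_min])
        if rare:
            levels = levels.where(~levels.isin(rare), "other")
        uniq = sorted(levels.unique())
        for level in uniq[1:]:  # alphabetical first level is the reference
            cols.append((levels == level).to_numpy(dtype=float))
            names.append(f"{cov}[{level}]")

    for cov in continuous:
        raw = pairs[cov].to_numpy(dtype=float)
        missing = np.isnan(raw)
        observed = raw[~missing]
        if observed.size == 0:
            warnings.warn(f"column {cov!r} entirely missing; dropped")
            continue
        z, mean, sd = _standardize(observed)
        filled = np.zeros(n)
        filled[~missing] = z
        cols.append(filled)
        names.append(cov)
        standardization[cov] = (mean, sd)
        if missing.any():
            cols.append(missing.astype(float))
            names.append(f"{cov}_missing")

    keep = []
    for j, col in enumerate(cols):
        if np.all(col == col[0]):
            warnings.warn(f"design column {names[j]!r} is constant; dropped")
        else:
            keep.append(j)
    X = (
        np.column_stack([cols[j] for j in keep])
        if keep else np.empty((n, 0))
    )
    names = [names[j] for j in keep]

    blocks: dict[str, EvidenceBlock] = {}
    if evidence is not None:
        key = pd.MultiIndex.from_frame(pairs[["gene_id", "indication"]])
        for source, sub in evidence.groupby("source"):
            sub = sub.set_index(["gene_id", "indication"])
            sub = sub.loc[~sub.index.duplicated()]
            aligned = sub.reindex(key)
            exists = aligned["has_assoc"].fillna(0).to_numpy(dtype=float)
            e_c = aligned["e_c"].to_numpy(dtype=float)
            if standardize_ec_over == "assoc":
                basis = e_c[exists == 1]
            elif standardize_ec_over == "all":
                basis = np.where(exists == 1, e_c, 0.0)
            else:
                raise ValueError("standardize_ec_over must be 'assoc' or 'all'")
            if basis.size == 0:
                logger.warning("evidence source %s has no associated pairs; skipped",
                               source)
                continue
            mean = float(np.nanmean(basis))
            sd = float(np.nanstd(basis))
            if sd == 0.0:
                sd = 1.0
            z = np.where(exists == 1, (e_c - mean) / sd, 0.0)
            z = np.nan_to_num(z, nan=0.0)
            blocks[str(source)] = EvidenceBlock(exists=exists, z=z, mean=mean, sd=sd)

    return DesignMatrix(X=X, columns=names, standardization=standardization,
                        evidence=blocks)


# ---------------------------------------------------------------------------
# posterior


def _flat_design(design: DesignMatrix, degree: int) -> tuple[np.ndarray, list[str]]:
    """Concatenate covariates and per-source evidence polynomial columns
    into one matrix so the log posterior is a plain logistic form.

    Returns (F, names), both excluding the intercept.
    """
    parts = [design.X]
    names = list(design.columns)
    for source in sorted(design.evidence):
        blk = design.evidence[source]
        for j in range(degree + 1):
            parts.append(blk.exists * blk.z**j)
            names.append(f"gamma_{source}[{j}]")
    F = np.column_stack(parts) if parts else np.empty((design.n, 0))
    return F, names


def _prior_vectors(spec: ModelSpec, names: list[str]) -> tuple[np.ndarray, np.ndarray]:
    mean = np.zeros(1 + len(names))
    sd = np.empty(1 + len(names))
    mean[0] = spec.mu_a
    sd[0] = spec.sigma_a
    for k, name in enumerate(names, start=1):
        sd[k] = spec.sigma_g if name.startswith("gamma_") else spec.sigma_b
    return mean, sd


def _log_posterior_factory(y, F, prior_mean, prior_sd):
    y = np.asarray(y, dtype=float)

    def log_post(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)  # (W, K+1)
        logits = theta[:, 0][None, :] + F @ theta[:, 1:].T  # (N, W)
        # Bernoulli log-likelihood: y*l - log(1 + e^l), numerically stable
        ll = y[:, None] * logits - np.logaddexp(0.0, logits)
        lp = ll.sum(axis=0)
        dev = (theta - prior_mean) / prior_sd
        lp = lp - 0.5 * np.sum(dev**2, axis=1)
        return lp

    return log_post


def _posterior_hessian(theta, y, F, prior_sd):
    """Negative-log-posterior Hessian of the logistic model at ``theta``:
    X' diag(p(1-p)) X plus the diagonal prior precision, with X the
    intercept-augmented design."""
    X = np.column_stack([np.ones(F.shape[0]), F])
    p = expit(theta[0] + F @ theta[1:])
    w = p * (1.0 - p)
    return (X.T * w) @ X + np.diag(1.0 / prior_sd**2)


@dataclass
class PosteriorFit:
    """Posterior draws with diagnostics for one model fit."""

    chain_draws: np.ndarray  # (chains, draws, ndim)
    param_names: list[str]
    rhat: np.ndarray
    ess: np.ndarray
    spec: ModelSpec
    design: DesignMatrix
    y: np.ndarray
    converged: bool = True

    @property
    def draws(self) -> np.ndarray:
        """All draws flattened to (samples, ndim)."""
        return self.chain_draws.reshape(-1, self.chain_draws.shape[-1])

    def params(self, name: str) -> np.ndarray:
        return self.draws[:, self.param_names.index(name)]

    def summary(self) -> pd.DataFrame:
        d = self.draws
        q = np.quantile(d, [0.025, 0.5, 0.975], axis=0)
        return pd.DataFrame({
            "parameter": self.param_names,
            "median": q[1], "ci_low": q[0], "ci_high": q[2],
            "mean": d.mean(axis=0), "sd": d.std(axis=0),
            "rhat": self.rhat, "ess": self.ess,
        })

    def log_lik_pointwise(self, max_draws: int = 1000, seed: int = 0) -> np.ndarray:
        """Pointwise log-likelihood matrix (draws, observations) on a
        random subsample of at most ``max_draws`` posterior draws."""
        F, _ = _flat_design(self.design, self.spec.degree)
        d = self.draws
        if len(d) > max_draws:
            idx = np.random.default_rng(seed).choice(len(d), max_draws, replace=False)
            d = d[np.sort(idx)]
        logits = d[:, 0][:, None] + d[:, 1:] @ F.T  # (S, N)
        return self.y[None, :] * logits - np.logaddexp(0.0, logits)

    def gamma_names(self, source: str) -> list[str]:
        return [n for n in self.param_names if n.startswith(f"gamma_{source}[")]


def fit_approval_model(
    y: np.ndarray,
    design: DesignMatrix,
    spec: ModelSpec | None = None,
    check: bool = True,
) -> PosteriorFit:
    """Sample the approval-model posterior.

    ``spec.chains`` independent chains of a Laplace-guided independence
    Metropolis-Hastings kernel are run, each seeded from ``spec.seed``.
    With ``check`` the diagnostic contract (split-Rhat <= rhat_max,
    ESS >= ess_min per parameter) is enforced, raising
    :class:`ConvergenceError` on failure.
    """
    spec = spec or ModelSpec()
    y = np.asarray(y, dtype=float)
    F, names = _flat_design(design, spec.degree)
    ndim = 1 + F.shape[1]
    if len(y) and len(y) < ndim + 4:
        raise ValueError(f"need at least {ndim + 4} observations for {ndim} parameters")
    prior_mean, prior_sd = _prior_vectors(spec, names)
    log_post = _log_posterior_factory(y, F, prior_mean, prior_sd)

    opt = minimize(lambda t: -log_post(t)[0], prior_mean, method="L-BFGS-B")
    mode = opt.x if opt.success else prior_mean
    hess = _posterior_hessian(mode, y, F, prior_sd)
    scale = np.linalg.cholesky(np.linalg.inv(hess))

    # Warmup doubles as proposal adaptation: pilot chains run with the
    # Laplace proposal, then the proposal is moment-matched to the pooled
    # pilot draws (capturing skew the quadratic approximation misses).
    # Adaptation ends before the kept phase, so the final kernel is a
    # fixed, valid independence MH kernel.
    rngs = [
        np.random.default_rng((spec.seed * 1000003 + 7919 * c + 1) % (2**31 - 1))
        for c in range(spec.chains)
    ]
    pilots = [
        _independence_mh_chain(log_post, mode, scale, spec.warmup, rng)
        for rng in rngs
    ]
    pooled = np.concatenate(pilots, axis=0)
    if len(pooled) >= 10 * ndim:
        center = pooled.mean(axis=0)
        cov = np.cov(pooled, rowvar=False).reshape(ndim, ndim)
        try:
            adapted_scale = np.linalg.cholesky(cov + 1e-10 * np.eye(ndim))
            mode, scale = center, adapted_scale
        except np.linalg.LinAlgError:
            pass  # degenerate pilot: keep the Laplace proposal

    chains = [
        _independence_mh_chain(log_post, mode, scale, spec.draws, rng)
        for rng in rngs
    ]
    chain_draws = np.stack(chains)  # (chains, draws, ndim)

    rhat, ess = _diagnostics(chain_draws)
    param_names = ["alpha"] + names
    converged = bool(np.all(rhat <= spec.rhat_max) and np.all(ess >= spec.ess_min))
    fit = PosteriorFit(chain_draws=chain_draws, param_names=param_names,
                       rhat=rhat, ess=ess, spec=spec, design=design, y=y,
                       converged=converged)
    if check and not converged:
        worst = int(np.argmax(rhat))
        raise ConvergenceError(
            f"diagnostics failed: max Rhat {rhat.max():.4f} "
            f"({param_names[worst]}), min ESS {ess.min():.0f}"
        )
    return fit


def _independence_mh_chain(
    log_post,
    mode: np.ndarray,
    scale: np.ndarray,
    n_steps: int,
    rng: np.random.Generator,
    proposal_inflation: float = 1.2,
    proposal_df: float = 8.0,
) -> np.ndarray:
    """One chain of independence Metropolis-Hastings.

    Proposals are iid multivariate-t(df) draws centered on ``mode`` with
    squared scale matrix ``inflation^2 * scale scale'`` — the Laplace
    approximation, inflated and heavy-tailed so it dominates the target
    in the tails.  Because proposals do not depend on the current state,
    all target and proposal densities are evaluated vectorized up front
    and only the accept/reject scan is sequential.  Returns the sampled
    states, shape (n_steps, ndim); the first state is the first accepted
    proposal (the chain starts at the mode).
    """
    k = len(mode)
    eps = rng.standard_normal((n_steps + 1, k)) * proposal_inflation
    g = rng.chisquare(proposal_df, size=n_steps + 1) / proposal_df
    u = eps / np.sqrt(g)[:, None]
    u[0] = 0.0  # chain starts at the mode
    log_q = -0.5 * (proposal_df + k) * np.log1p(
        (u**2).sum(axis=1) / (proposal_inflation**2 * proposal_df)
    )
    log_p = log_post(mode + u @ scale.T)
    log_w = log_p - log_q
    log_accept = np.log(rng.random(n_steps + 1))
    idx = np.empty(n_steps, dtype=np.intp)
    current = 0
    for t in range(1, n_steps + 1):
        if log_accept[t] < log_w[t] - log_w[current]:
            current = t
        idx[t - 1] = current
    return mode + u[idx] @ scale.T


def _diagnostics(chain_draws: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(posterior={"theta": chain_draws})
        rhat = az.rhat(idata)["theta"].to_numpy()
        ess = az.ess(idata)["theta"].to_numpy()
    return np.asarray(rhat, dtype=float), np.asarray(ess, dtype=float)


def waic(fit: PosteriorFit, max_draws: int = 1000, seed: int = 0) -> tuple[float, float]:
    """Widely applicable information criterion on the deviance scale.

    WAIC = -2 * (lppd - p_waic), with lppd the summed log pointwise
    predictive density and p_waic the summed posterior variance of the
    pointwise log-likelihood; the SE comes from the spread of pointwise
    contributions.  Requires at least 100 draws.
    """
    ll = fit.log_lik_pointwise(max_draws=max_draws, seed=seed)  # (S, N)
    s = ll.shape[0]
    if s < 100:
        raise ValueError("waic needs at least 100 posterior draws")
    lppd_i = logsumexp(ll, axis=0) - np.log(s)
    p_waic_i = ll.var(axis=0, ddof=1)
    waic_i = -2.0 * (lppd_i - p_waic_i)
    n = ll.shape[1]
    se = float(np.sqrt(n * np.var(waic_i, ddof=1))) if n > 1 else 0.0
    return float(waic_i.sum()), se


def odds_ratio_curve(
    fit: PosteriorFit,
    source: str,
    grid: np.ndarray | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Posterior odds-ratio-of-approval curve over trait similarity.

    For each draw and similarity s, eta(s) = sum_j gamma_j z(s)^j with
    z(s) the standardized similarity; the odds ratio exp(eta(s)) is
    relative to a pair whose gene has no association (eta = 0).  Returns
    columns similarity, or_median, or_lo, or_hi, source.
    """
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    grid = np.asarray(grid, dtype=float)
    if grid.min() < 0.0 or grid.max() > 1.0:
        raise ValueError("similarity grid must lie in [0, 1]")
    blk = fit.design.evidence[source]
    z = (grid - blk.mean) / blk.sd
    gammas = np.column_stack([fit.params(n) for n in fit.gamma_names(source)])  # (S, p+1)
    powers = z[:, None] ** np.arange(gammas.shape[1])[None, :]  # (G, p+1)
    eta = powers @ gammas.T  # (G, S)
    orr = np.exp(eta)
    alpha = (1.0 - level) / 2.0
    q = np.quantile(orr, [alpha, 0.5, 1.0 - alpha], axis=1)
    return pd.DataFrame({
        "similarity": grid,
        "or_median": q[1], "or_lo": q[0], "or_hi": q[2],
        "source": source,
    })


def baseline_approval_probability(mu_a: float = -2.2) -> float:
    """Approval probability implied by the intercept prior mean."""
    return float(expit(mu_a))
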