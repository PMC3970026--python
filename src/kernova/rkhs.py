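"""Bayesian multi-kernel RKHS regression via Gibbs sampling.

The model is the kernel-averaging form of semi-parametric genomic regression:

    y_i = mu + sum_k g_k,i + eps_i,
    g_k ~ N(0, K_k sigma2_k),     eps_i ~ N(0, sigma2_e / w_i),

with one genetic random effect per kernel and optional per-record reliability
weights ``w_i``.  Per-kernel and residual variances carry scaled inverse
chi-squared priors (default: 5 degrees of freedom, scale = 0.5 * Var(y)).
Fitting a single additive genomic relationship kernel G reduces the model to
GBLUP; the per-kernel variance ratios ``sigma2_k / sum_k sigma2_k`` partition
the marked genetic variance among kernels (multiple kernel learning).

Implementation notes
--------------------
Each kernel is eigendecomposed once, ``K_k = U_k L_k U_k'`` (eigenvalues below
``1e-8 * max`` dropped), and the genetic effect is sampled in its eigenbasis,
``g_k = U_k L_k^{1/2} delta_k`` with ``delta_k ~ N(0, I sigma2_k)``.  Because
``B_k'B_k = L_k`` is diagonal, the blocked full conditional of ``delta_k`` has
a diagonal covariance and each sweep costs two matrix-vector products per
kernel.  Reliability weights are absorbed exactly by the transform
``S = diag(sqrt(w))``: the sampler runs on ``S y`` with kernels ``S K S`` and
back-transforms the genetic values.  Masked responses are handled by data
augmentation — resampled from their full conditional each sweep — so the
marginal posterior of all parameters is the observed-data posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kernels import Kernel

__all__ = [
    "PriorSpec",
    "ChainConfig",
    "ResponseVector",
    "FitResult",
    "DegenerateResponseError",
    "ridge_solution",
    "fit_gibbs",
    "predict",
    "variance_partition",
    "posterior_density_report",
]

#: Relative eigenvalue cutoff when factoring kernels for sampling.
EIG_RTOL = 1e-8


class DegenerateResponseError(ValueError):
    """The response carries no usable variation."""


@dataclass
class PriorSpec:
    """Scaled inverse chi-squared prior for every variance component.

    ``scale`` (if given) is the prior scale S directly; otherwise
    ``S = scale_multiplier * Var(observed y)``.
    """

    df: float = 5.0
    scale_multiplier: float = 0.5
    scale: float | None = None

    def __post_init__(self) -> None:
        if self.df <= 0:
            raise ValueError("prior degrees of freedom must be positive")
        if self.scale_multiplier <= 0:
            raise ValueError("scale_multiplier must be positive")

    def resolve_scale(self, y_obs: np.ndarray) -> float:
        if self.scale is not None:
            return float(self.scale)
        if y_obs.size < 2:
            raise DegenerateResponseError(
                "cannot derive prior scale from <2 observed responses; "
                "set PriorSpec.scale explicitly"
            )
        v = float(np.var(y_obs))
        if v <= 0.0:
            raise DegenerateResponseError("observed responses are all equal")
        return self.scale_multiplier * v


@dataclass
class ChainConfig:
    """Gibbs chain settings; retained draws = floor((iterations-burn_in)/thin)."""

    seed: int
    iterations: int = 50_000
    burn_in: int = 20_000
    thin: int = 10

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclass
class ResponseVector:
    """Response values with optional reliability weights and missing mask.

    ``NaN`` entries of ``values`` are treated as masked (to predict); weights,
    when present, must lie in (0, 1] and are interpreted as reliabilities:
    ``Var(eps_i) = sigma2_e / w_i``.
    """

    values: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("response values must be 1-D")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != self.values.shape:
                raise ValueError("weights shape mismatch")
            if np.any((self.weights <= 0) | (self.weights > 1)):
                raise ValueError("weights must lie in (0, 1]")
        n_obs = int(self.observed.sum())
        if n_obs == 1:
            raise ValueError("need >= 2 observed responses (or none, for a "
                             "pure prior draw)")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def observed(self) -> np.ndarray:
        return ~np.isnan(self.values)


@dataclass
class FitResult:
    """Posterior samples and summaries from :func:`fit_gibbs`."""

    kernel_names: list[str]
    samples_var_k: np.ndarray          # (n_retained, n_kernels)
    samples_var_e: np.ndarray          # (n_retained,)
    g_mean: np.ndarray                 # posterior mean total genetic value
    g_sd: np.ndarray                   # posterior sd of total genetic value
    mu_mean: float
    weights_k: np.ndarray              # posterior mean of sigma2_k / sum
    H2: float                          # posterior mean of V_K / (V_K + V_e)
    prior: PriorSpec
    chain: ChainConfig
    samples_g: np.ndarray | None = None     # (n_retained, n) if stored
    posterior_means: dict = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return self.samples_var_e.size

    def draws_table(self) -> pd.DataFrame:
        """Retained variance draws as a tidy table."""
        df = pd.DataFrame(
            self.samples_var_k,
            columns=[f"var_{k}" for k in self.kernel_names],
        )
        df.insert(0, "draw", np.arange(1, self.n_retained + 1))
        df["var_e"] = self.samples_var_e
        return df

    def effective_sample_size(self) -> dict:
        """Autocorrelation-based effective sample size per variance chain.

        A convergence diagnostic only; nothing gates on it.
        """
        out = {}
        chains = {f"var_{k}": self.samples_var_k[:, j]
                  for j, k in enumerate(self.kernel_names)}
        chains["var_e"] = self.samples_var_e
        for name, x in chains.items():
            x = x - x.mean()
            n = x.size
            acf = np.correlate(x, x, mode="full")[n - 1:] / (x @ x)
            # sum positive-lag autocorrelations until the first negative
            tau = 1.0
            for rho in acf[1:]:
                if rho <= 0:
                    break
                tau += 2.0 * rho
            out[name] = float(n / tau)
        return out

    def save(self, outdir, ids=None) -> None:
        """Write draws (TSV), posterior summary (JSON) and posterior-mean
        genetic values (TSV) under ``outdir``."""
        import json
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.draws_table().to_csv(outdir / "draws.tsv", sep="\t", index=False)
        summary = {
            "kernel_names": self.kernel_names,
            "posterior_means": self.posterior_means,
            "weights_k": self.weights_k.tolist(),
            "H2": self.H2,
            "effective_sample_size": self.effective_sample_size(),
            "chain": {"seed": self.chain.seed,
                      "iterations": self.chain.iterations,
                      "burn_in": self.chain.burn_in,
                      "thin": self.chain.thin},
            "prior": {"df": self.prior.df,
                      "scale_multiplier": self.prior.scale_multiplier,
                      "scale": self.prior.scale},
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
        n = self.g_mean.size
        gv = pd.DataFrame({
            "id": list(ids) if ids is not None else [f"i{j}" for j in range(n)],
            "g_mean": self.g_mean,
            "g_sd": self.g_sd,
        })
        gv.to_csv(outdir / "genetic_values.tsv", sep="\t", index=False)


def ridge_solution(k: Kernel, y: np.ndarray, lam: float) -> np.ndarray:
    """Closed-form kernel ridge fit ``g = K (K + lambda I)^{-1} y``.

    This is the minimizer of ``(y - K a)'(y - K a) + lambda a' K a`` mapped
    through ``g = K a``; it serves as the deterministic oracle for the Gibbs
    sampler with variances fixed at ratio ``lambda = sigma2_e / sigma2_g``.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    y = np.asarray(y, dtype=float)
    A = k.matrix + lam * np.eye(k.n)
    try:
        alpha = np.linalg.solve(A, y)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(f"K + lambda*I is singular: {e}") from e
    return k.matrix @ alpha


def _factor_kernel(K: np.ndarray) -> np.ndarray:
    """Return B with B B' = K, columns = eigenvectors * sqrt(eigenvalue)."""
    vals, vecs = np.linalg.eigh(K)
    keep = vals > EIG_RTOL * max(vals.max(), 0.0)
    if not keep.any():
        raise ValueError("kernel has no positive eigenvalues")
    return vecs[:, keep] * np.sqrt(vals[keep])


def _draw_scaled_inv_chi2(rng, df: float, scale_sum: float) -> float:
    # (nu*S + SS) / chi2_{nu + m}; here scale_sum = nu*S + SS, df = nu + m
    return scale_sum / rng.chisquare(df)


def fit_gibbs(
    kernels: list[Kernel] | Kernel,
    y: ResponseVector | np.ndarray,
    prior: PriorSpec | None = None,
    chain: ChainConfig | None = None,
    fix_var_k: list[float] | None = None,
    fix_var_e: float | None = None,
    fit_intercept: bool = True,
    store_g: bool = False,
) -> FitResult:
    """Sample the posterior of the multi-kernel RKHS model.

    Parameters
    ----------
    kernels
        One or more PSD kernels sharing the response dimension.
    y
        Responses; ``NaN`` marks individuals whose genetic value is to be
        predicted (they contribute nothing to the likelihood).
    fix_var_k, fix_var_e
        Clamp the per-kernel / residual variances instead of sampling them
        (used for oracle checks against :func:`ridge_solution`).
    """
    if isinstance(kernels, Kernel):
        kernels = [kernels]
    if not kernels:
        raise ValueError("at least one kernel required")
    if not isinstance(y, ResponseVector):
        y = ResponseVector(np.asarray(y, dtype=float))
    n = y.n
    for k in kernels:
        if k.n != n:
            raise ValueError(f"kernel {k.name} dimension {k.n} != response {n}")
        if not k.is_psd():
            raise ValueError(f"kernel {k.name} fails the PSD check")
    prior = prior or PriorSpec()
    chain = chain or ChainConfig(seed=0)
    if fix_var_k is not None and len(fix_var_k) != len(kernels):
        raise ValueError("fix_var_k length must match number of kernels")

    obs = y.observed
    y_obs = y.values[obs]
    if y_obs.size >= 2 and np.ptp(y_obs) == 0.0 and prior.scale is None:
        raise DegenerateResponseError("all observed responses are equal")
    S_prior = prior.resolve_scale(y_obs)
    nu = prior.df

    # --- exact reliability-weight transform to a homoskedastic model -------
    if y.weights is not None:
        s = np.sqrt(y.weights)
    else:
        s = np.ones(n)
    yt = np.where(obs, y.values * s, 0.0)
    x0 = s  # intercept column in the transformed scale
    Bs = [_factor_kernel(s[:, None] * k.matrix * s[None, :]) for k in kernels]
    ranks = [B.shape[1] for B in Bs]
    lam_diags = [np.einsum("ij,ij->j", B, B) for B in Bs]  # eigenvalues of K_j
    nk = len(kernels)

    rng = np.random.default_rng(chain.seed)

    # --- state -------------------------------------------------------------
    deltas = [np.zeros(m) for m in ranks]
    g_parts = [np.zeros(n) for _ in range(nk)]
    g_sum = np.zeros(n)
    mu = 0.0
    var_k = np.array([S_prior if fix_var_k is None else fix_var_k[j]
                      for j in range(nk)], dtype=float)
    var_e = S_prior if fix_var_e is None else float(fix_var_e)
    x0tx0 = float(x0 @ x0)

    n_ret = chain.n_retained
    samples_var_k = np.empty((n_ret, nk))
    samples_var_e = np.empty(n_ret)
    samples_mu = np.empty(n_ret)
    g_total_sum = np.zeros(n)
    g_total_sumsq = np.zeros(n)
    samples_g = np.empty((n_ret, n)) if store_g else None

    miss = ~obs
    any_miss = bool(miss.any())
    r_idx = 0
    for it in range(1, chain.iterations + 1):
        # impute masked responses from their full conditional
        if any_miss:
            fitted = mu * x0[miss] + g_sum[miss]
            yt[miss] = fitted + rng.standard_normal(miss.sum()) * np.sqrt(var_e)
        # intercept (flat prior)
        if fit_intercept:
            r = yt - g_sum
            mu = (x0 @ r) / x0tx0 + rng.standard_normal() * np.sqrt(var_e / x0tx0)
        resid = yt - mu * x0 - g_sum
        # blocked update of each kernel's eigen-coordinates
        for j in range(nk):
            B = Bs[j]
            resid += g_parts[j]                    # residual excluding block j
            c = lam_diags[j] / var_e + 1.0 / var_k[j]
            mean = (B.T @ resid) / var_e / c
            deltas[j] = mean + rng.standard_normal(ranks[j]) / np.sqrt(c)
            g_parts[j] = B @ deltas[j]
            resid -= g_parts[j]
            if fix_var_k is None:
                ss = float(deltas[j] @ deltas[j])
                var_k[j] = _draw_scaled_inv_chi2(
                    rng, nu + ranks[j], nu * S_prior + ss
                )
        g_sum = yt - mu * x0 - resid
        if fix_var_e is None:
            sse = float(resid @ resid)
            var_e = _draw_scaled_inv_chi2(rng, nu + n, nu * S_prior + sse)
        # record retained draws
        if it > chain.burn_in and (it - chain.burn_in) % chain.thin == 0:
            samples_var_k[r_idx] = var_k
            samples_var_e[r_idx] = var_e
            samples_mu[r_idx] = mu
            g_orig = g_sum / s       # back to the original response scale
            g_total_sum += g_orig
            g_total_sumsq += g_orig ** 2
            if store_g:
                samples_g[r_idx] = g_orig
            r_idx += 1
    assert r_idx == n_ret

    g_mean = g_total_sum / n_ret
    g_var = np.maximum(g_total_sumsq / n_ret - g_mean ** 2, 0.0)
    vk_sum = samples_var_k.sum(axis=1)
    weights_draws = samples_var_k / vk_sum[:, None]
    h2_draws = vk_sum / (vk_sum + samples_var_e)
    post = {
        "mu": float(samples_mu.mean()),
        "var_e": float(samples_var_e.mean()),
        **{f"var_{k.name}": float(samples_var_k[:, j].mean())
           for j, k in enumerate(kernels)},
    }
    return FitResult(
        kernel_names=[k.name for k in kernels],
        samples_var_k=samples_var_k,
        samples_var_e=samples_var_e,
        g_mean=g_mean,
        g_sd=np.sqrt(g_var),
        mu_mean=float(samples_mu.mean()),
        weights_k=weights_draws.mean(axis=0),
        H2=float(h2_draws.mean()),
        prior=prior,
        chain=chain,
        samples_g=samples_g,
        posterior_means=post,
    )


def predict(
    fit: FitResult,
    test_idx: np.ndarray,
    kernels_full: list[Kernel] | None = None,
) -> np.ndarray:
    """Posterior-mean genetic values of held-out (masked) individuals.

    ``test_idx`` are row indices into the kernels the fit was produced with;
    the fit must have been run with those responses masked so their genetic
    values were sampled jointly with the training rows.
    """
    test_idx = np.asarray(test_idx)
    if test_idx.dtype == bool:
        if test_idx.size != fit.g_mean.size:
            raise ValueError("boolean test mask length mismatch")
        test_idx = np.flatnonzero(test_idx)
    if test_idx.size and (test_idx.min() < 0 or test_idx.max() >= fit.g_mean.size):
        raise ValueError("test index outside the fitted kernel dimension")
    if kernels_full is not None:
        for k in kernels_full:
            if k.n != fit.g_mean.size:
                raise ValueError("kernel dimension does not match the fit")
    return fit.g_mean[test_idx]


def variance_partition(fit: FitResult, ci: float = 0.95) -> pd.DataFrame:
    """Posterior summaries of variance-component ratios.

    Per retained draw, ``V_P = sum_k sigma2_k + sigma2_e``; the table reports
    the posterior mean and equal-tailed credible interval of ``V_k / V_P`` for
    each kernel, broad-sense heritability ``H2 = V_K / V_P`` and the kernel-
    relative weights ``V_k / V_K`` (which sum to one in every draw).
    """
    vk = fit.samples_var_k
    ve = fit.samples_var_e
    vK = vk.sum(axis=1)
    vP = vK + ve
    lo, hi = (1 - ci) / 2, 1 - (1 - ci) / 2
    rows = []

    def add(name, draws):
        q = np.quantile(draws, [lo, hi])
        rows.append((name, float(draws.mean()), float(q[0]), float(q[1])))

    for j, k in enumerate(fit.kernel_names):
        add(f"V_{k}/V_P", vk[:, j] / vP)
    add("H2", vK / vP)
    for j, k in enumerate(fit.kernel_names):
        add(f"V_{k}/V_K", vk[:, j] / vK)
    return pd.DataFrame(rows, columns=["ratio", "mean", "ci_low", "ci_high"])


def posterior_density_report(fit: FitResult, out=None) -> dict:
    """Kernel-density estimates of each variance-ratio posterior.

    Returns, per ratio, a density grid and the count of local maxima of the
    KDE (a unimodality diagnostic).  Degenerate (constant-draw) posteriors
    are flagged instead of smoothed.  Requires >= 100 retained draws.
    """
    from scipy.stats import gaussian_kde

    if fit.n_retained < 100:
        raise ValueError("need >= 100 retained draws for density estimates")
    vk = fit.samples_var_k
    vP = vk.sum(axis=1) + fit.samples_var_e
    ratios = {f"V_{k}/V_P": vk[:, j] / vP
              for j, k in enumerate(fit.kernel_names)}
    ratios["H2"] = vk.sum(axis=1) / vP
    report = {}
    frames = []
    for name, draws in ratios.items():
        if np.ptp(draws) < 1e-12:
            report[name] = {"degenerate": True, "n_modes": 0,
                            "grid": None, "density": None}
            continue
        kde = gaussian_kde(draws)
        grid = np.linspace(draws.min(), draws.max(), 512)
        dens = kde(grid)
        interior = dens[1:-1]
        n_modes = int(np.sum((interior > dens[:-2]) & (interior >= dens[2:])))
        report[name] = {"degenerate": False, "n_modes": max(n_modes, 1),
                        "grid": grid, "density": dens}
        frames.append(pd.DataFrame({"ratio": name, "x": grid, "density": dens}))
    if out is not None and frames:
        pd.concat(frames).to_csv(out, sep="\t", index=False)
    return report
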