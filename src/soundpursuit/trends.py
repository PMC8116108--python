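"""Hierarchical trend inference: does a fitted parameter drift across trials?

The model is a two-level Bayesian linear regression of a per-trial quantity
y (e.g. the fitted quality factor) on trial number n::

    y_{s,n} ~ Normal(a_s + b_s * n, sigma)
    a_s ~ Normal(mu_a, tau_a),   b_s ~ Normal(mu_b, tau_b)

with weakly informative priors on standardized data: mu_a, mu_b ~
Normal(0, 10^2) and tau_a, tau_b, sigma ~ Half-Normal(0, 5^2).  The group
slope mu_b carries the adaptation claim; its 95% highest-density interval
(HDI) excluding zero is the evidence for a systematic drift.

Posteriors are drawn with an affine-invariant ensemble sampler (emcee);
convergence is monitored with split-R-hat and results are flagged, never
silently accepted, when R-hat >= 1.05.  HDIs and R-hat come from arviz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["TrendFit", "hierarchical_trend", "effort_trend"]

RHAT_LIMIT = 1.05


@dataclass(frozen=True)
class TrendFit:
    """Posterior summary of a hierarchical trial-number regression.

    Slopes are in parameter units per trial; ``endpoint_start`` /
    ``endpoint_end`` hold posterior draws of the group regression line at the
    first and last trial (the densities shown flanking a trend panel).
    """

    parameter: str
    slope_mean: float
    slope_hdi: tuple[float, float]
    intercept_mean: float
    intercept_hdi: tuple[float, float]
    subject_slopes: np.ndarray
    subject_intercepts: np.ndarray
    endpoint_start: np.ndarray
    endpoint_end: np.ndarray
    rhat_max: float
    converged: bool
    n_draws: int

    def slope_excludes_zero(self) -> bool:
        lo, hi = self.slope_hdi
        return bool(lo > 0 or hi < 0)


class _MarginalModel:
    """Hierarchical linear model with the subject effects integrated out.

    For Gaussian subject effects and Gaussian noise the per-subject marginal
    likelihood ``y_s ~ N(X_s mu, sigma^2 I + X_s T X_s^T)`` is available in
    closed form (T = diag(tau_a^2, tau_b^2)), so the sampler only has to
    explore the five hyperparameters (mu_a, mu_b, log tau_a, log tau_b,
    log sigma) -- no funnel over per-subject coordinates.  Sufficient
    statistics (X'X, X'y, y'y, n) are precomputed per subject.
    """

    def __init__(self, x: np.ndarray, y: np.ndarray, subj: np.ndarray, n_subj: int) -> None:
        self.n_subj = n_subj
        self.xtx = np.empty((n_subj, 2, 2))
        self.xty = np.empty((n_subj, 2))
        self.yty = np.empty(n_subj)
        self.n_obs = np.empty(n_subj)
        for s in range(n_subj):
            sel = subj == s
            xs = np.column_stack([np.ones(sel.sum()), x[sel]])
            ys = y[sel]
            self.xtx[s] = xs.T @ xs
            self.xty[s] = xs.T @ ys
            self.yty[s] = ys @ ys
            self.n_obs[s] = ys.size

    def _decompose(self, theta: np.ndarray):
        # theta: (..., 5); all returns broadcast over the leading axes
        mu = theta[..., :2]
        tau2 = np.exp(2 * theta[..., 2:4])
        sigma2 = np.exp(2 * theta[..., 4])
        # C_s = T^-1 + X'X / sigma^2, per subject (2x2)
        c = self.xtx / sigma2[..., None, None, None]
        c = np.array(c, copy=True)
        c[..., 0, 0] += (1.0 / tau2[..., 0])[..., None]
        c[..., 1, 1] += (1.0 / tau2[..., 1])[..., None]
        # right-hand side of the conditional-posterior mean: T^-1 mu + X'y/sigma^2
        rhs = self.xty / sigma2[..., None, None] + (mu / tau2)[..., None, :]
        return mu, tau2, sigma2, c, rhs

    def log_posterior(self, theta: np.ndarray) -> np.ndarray | float:
        theta = np.asarray(theta, float)
        scalar = theta.ndim == 1
        mu, tau2, sigma2, c, rhs = self._decompose(theta)
        det_c = c[..., 0, 0] * c[..., 1, 1] - c[..., 0, 1] * c[..., 1, 0]
        # quadratic form rhs' C^-1 rhs via the explicit 2x2 inverse
        with np.errstate(all="ignore"):
            quad = (
                c[..., 1, 1] * rhs[..., 0] ** 2
                - 2.0 * c[..., 0, 1] * rhs[..., 0] * rhs[..., 1]
                + c[..., 0, 0] * rhs[..., 1] ** 2
            ) / det_c
            mu_prec_mu = np.sum(mu**2 / tau2, axis=-1)
            ll = -0.5 * np.sum(
                self.n_obs * np.log(sigma2)[..., None]
                + np.log(det_c)
                + np.sum(np.log(tau2), axis=-1)[..., None]
                + self.yty / sigma2[..., None]
                + mu_prec_mu[..., None]
                - quad,
                axis=-1,
            )
            tau_sig2 = np.concatenate([tau2, sigma2[..., None]], axis=-1)
            lp = -0.5 * np.sum(mu**2, axis=-1) / 100.0
            lp = lp - 0.5 * np.sum(tau_sig2, axis=-1) / 25.0
            lp = lp + 0.5 * np.sum(np.log(tau_sig2), axis=-1)  # log-Jacobian
        out = ll + lp
        bad = ~np.isfinite(out) | np.any(np.abs(theta[..., 2:]) > 12, axis=-1)
        out = np.where(bad, -np.inf, out)
        return float(out) if scalar else out

    def subject_effects(self, theta: np.ndarray) -> np.ndarray:
        """Conditional posterior mean of (a_s, b_s) given hyperparameters."""
        _, _, _, c, rhs = self._decompose(theta)
        return np.linalg.solve(c, rhs[..., None])[..., 0]


def _hdi_interval(draws: np.ndarray, prob: float) -> tuple[float, float]:
    # narrowest interval containing `prob` of the pooled draws
    x = np.sort(draws.ravel())
    n = x.size
    m = int(np.ceil(prob * n))
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def hierarchical_trend(
    values: np.ndarray,
    parameter: str = "value",
    n_samples: int = 2000,
    seed: int | None = None,
    n_walkers: int | None = None,
    burn_frac: float = 0.5,
    hdi_prob: float = 0.95,
) -> TrendFit:
    """Fit the hierarchical trial-number regression to a subjects x trials array.

    Parameters
    ----------
    values : ndarray, shape (n_subjects, n_trials)
        Per-subject, per-trial values; NaNs are dropped.  Requires >= 2
        subjects and >= 3 trials each.
    n_samples : int
        Post-burn-in ensemble steps (each step yields one draw per walker).
    seed : int, optional
        Seed for walker initialisation and proposals.
    """
    import arviz as az
    import emcee

    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2 or values.shape[1] < 3:
        raise ValueError("values must be (n_subjects >= 2) x (n_trials >= 3)")
    n_subj, n_trials = values.shape
    trial_no = np.arange(1, n_trials + 1, dtype=float)
    subj_idx, x_raw, y_raw = [], [], []
    for s in range(n_subj):
        ok = np.isfinite(values[s])
        if ok.sum() < 3:
            raise ValueError(f"subject {s} has fewer than 3 finite values")
        subj_idx.append(np.full(ok.sum(), s))
        x_raw.append(trial_no[ok])
        y_raw.append(values[s, ok])
    subj = np.concatenate(subj_idx)
    x_raw = np.concatenate(x_raw)
    y_raw = np.concatenate(y_raw)
    if not np.all(np.isfinite(y_raw)):
        raise ValueError("values must be finite")

    # standardize for scale-free priors
    x_mu, x_sd = x_raw.mean(), x_raw.std()
    y_mu, y_sd = y_raw.mean(), y_raw.std()
    if y_sd == 0:
        raise ValueError("values have zero variance; no trend is identifiable")
    x = (x_raw - x_mu) / x_sd
    y = (y_raw - y_mu) / y_sd

    model = _MarginalModel(x, y, subj, n_subj)
    ndim = 5
    if n_walkers is None:
        n_walkers = 40
    rng = np.random.default_rng(seed)

    # initialise near per-subject OLS solutions
    a0 = np.empty(n_subj)
    b0 = np.empty(n_subj)
    for s in range(n_subj):
        sel = subj == s
        b0[s], a0[s] = np.polyfit(x[sel], y[sel], 1)
    resid_sd = max(np.std(y - (a0[subj] + b0[subj] * x)), 1e-3)
    center = np.array(
        [
            a0.mean(),
            b0.mean(),
            np.log(max(a0.std(), 0.05)),
            np.log(max(b0.std(), 0.05)),
            np.log(resid_sd),
        ]
    )
    p0 = center[None, :] + 0.05 * rng.standard_normal((n_walkers, ndim))

    sampler = emcee.EnsembleSampler(n_walkers, ndim, model.log_posterior, vectorize=True)
    sampler.random_state = np.random.RandomState(int(rng.integers(2**31 - 1))).get_state()
    n_burn = int(np.ceil(burn_frac * n_samples / (1 - burn_frac)))
    sampler.run_mcmc(p0, n_burn + n_samples, progress=False)
    chain = sampler.get_chain(discard=n_burn)  # (steps, walkers, 5)

    # back-transform to original units
    sy_sx = y_sd / x_sd
    mu_a_std, mu_b_std = chain[:, :, 0], chain[:, :, 1]
    slope = mu_b_std * sy_sx
    intercept = y_mu + y_sd * mu_a_std - slope * x_mu

    # split-R-hat with walkers pooled into 8 groups (ensemble walkers are
    # exchangeable, not independent chains; grouping denoises the diagnostic)
    n_groups = 8
    per = n_walkers // n_groups
    hyper = (
        chain[:, : n_groups * per, :]
        .reshape(chain.shape[0], n_groups, per, 5)
        .transpose(1, 0, 2, 3)
        .reshape(n_groups, -1, 5)
    )
    idata = az.convert_to_dataset({"hyper": hyper})
    rhat_max = float(az.rhat(idata)["hyper"].max())
    converged = rhat_max < RHAT_LIMIT
    if not converged:
        warnings.warn(
            f"hierarchical trend fit for {parameter!r} did not converge "
            f"(max split-R-hat = {rhat_max:.3f})",
            stacklevel=2,
        )

    # subject effects: conditional posterior means averaged over thinned draws
    flat = chain.reshape(-1, 5)
    thin = max(1, flat.shape[0] // 400)
    eff = np.mean([model.subject_effects(th) for th in flat[::thin]], axis=0)
    subj_slope = eff[:, 1] * sy_sx
    subj_intercept = y_mu + y_sd * eff[:, 0] - subj_slope * x_mu

    start = intercept + slope * 1.0
    end = intercept + slope * n_trials
    return TrendFit(
        parameter=parameter,
        slope_mean=float(slope.mean()),
        slope_hdi=_hdi_interval(slope, hdi_prob),
        intercept_mean=float(intercept.mean()),
        intercept_hdi=_hdi_interval(intercept, hdi_prob),
        subject_slopes=subj_slope,
        subject_intercepts=subj_intercept,
        endpoint_start=start.reshape(-1),
        endpoint_end=end.reshape(-1),
        rhat_max=rhat_max,
        converged=converged,
        n_draws=int(slope.size),
    )


def effort_trend(efforts: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Across-trial decline of movement effort.

    Parameters
    ----------
    efforts : ndarray, shape (n_subjects, n_trials)
        Band-averaged gain (spectral effort) of each subject's fitted model
        per trial.

    Returns
    -------
    (per_subject, group_mean, r) : the input series, the across-subject mean
    per trial, and the Pearson correlation of that mean with trial number
    (NaN, with a warning, when the mean series is constant).
    """
    efforts = np.asarray(efforts, dtype=float)
    if efforts.ndim == 1:
        efforts = efforts[None, :]
    mean_series = np.nanmean(efforts, axis=0)
    trials = np.arange(1, mean_series.size + 1)
    if np.std(mean_series) == 0:
        warnings.warn("constant effort series: correlation undefined", stacklevel=2)
        return efforts, mean_series, np.nan
    r = float(np.corrcoef(trials, mean_series)[0, 1])
    return efforts, mean_series, r
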