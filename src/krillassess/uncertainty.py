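"""Parameter and derived-quantity uncertainty: asymptotic and MCMC.

The asymptotic ("delta-approximation") route inverts the Hessian at the
penalized-likelihood optimum to approximate the covariance of the
estimates and propagates it to derived quantities through first-order
Taylor expansion.  The MCMC route runs a random-walk Metropolis-Hastings
sampler whose multivariate-normal proposal is scaled from the same inverse
Hessian, and summarizes the saved samples.  Convergence of the chains is
judged with Heidelberger-Welch stationarity/halfwidth tests, Geweke scores,
autocorrelations and effective sample sizes - the same diagnostics the
coda toolchain applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.tools.numdiff import approx_fprime
from statsmodels.tsa.ar_model import AutoReg, ar_select_order

from .errors import ConfigurationError, InvalidStateError

__all__ = [
    "MCMCResult",
    "DiagnosticsReport",
    "asymptotic_intervals",
    "mcmc_sample",
    "heidelberger_welch",
    "geweke_and_acf",
    "spectrum0_ar",
    "diagnose",
]

#: Default cap on the number of monitored quantities.
MAX_MONITORED = 27

#: 5% critical value of the Cramer-von Mises distribution.
_CVM_CRIT_5PCT = 0.4613


# ---------------------------------------------------------------------------
# Asymptotic (delta-approximation) intervals
# ---------------------------------------------------------------------------


def asymptotic_intervals(fit, derived: dict | None = None) -> pd.DataFrame:
    """Estimates, SDs and 95% CIs from the inverse Hessian.

    Parameter SDs come from the inverse-Hessian diagonal on the estimation
    scale; intervals ``estimate +/- 1.96 SD`` are mapped back through the
    bound transform, so bounded/logged parameters are reported on their
    natural scales.  ``derived`` maps names to scalar functions of the
    active estimation-scale vector; their SDs use the delta method.
    """
    if fit.hessian is None or not fit.hessian_ok:
        raise InvalidStateError(
            "asymptotic intervals unavailable: Hessian missing or not positive definite"
        )
    H = 0.5 * (fit.hessian + fit.hessian.T)
    cov = np.linalg.inv(H)
    z = fit.z_opt
    sd_u = np.sqrt(np.maximum(np.diag(cov), 0.0))
    rows = []
    if fit.adapter is not None:
        tf = fit.adapter.transform
        idx = fit.active_idx
        x_nat = fit.params.to_vector()
        jac = tf.jacobian_diag(fit.u_opt)
        for j, i in enumerate(idx):
            lo_u, hi_u = z[j] - 1.96 * sd_u[j], z[j] + 1.96 * sd_u[j]
            u_lo, u_hi = fit.u_opt.copy(), fit.u_opt.copy()
            u_lo[i], u_hi[i] = lo_u, hi_u
            rows.append(
                {
                    "name": fit.adapter.names[i],
                    "estimate": x_nat[i],
                    "sd": sd_u[j] * jac[i],
                    "lo95": tf.to_natural(u_lo)[i],
                    "hi95": tf.to_natural(u_hi)[i],
                    "kind": "parameter",
                }
            )
    else:  # plain unbounded objective (no transform)
        for j in range(len(z)):
            rows.append(
                {
                    "name": f"param_{j}",
                    "estimate": float(z[j]),
                    "sd": float(sd_u[j]),
                    "lo95": float(z[j] - 1.96 * sd_u[j]),
                    "hi95": float(z[j] + 1.96 * sd_u[j]),
                    "kind": "parameter",
                }
            )
    if derived:
        for name, fn in derived.items():
            g = approx_fprime(z, fn, epsilon=1e-5, centered=True).ravel()
            sd = float(np.sqrt(max(g @ cov @ g, 0.0)))
            est = float(fn(z))
            rows.append(
                {
                    "name": name,
                    "estimate": est,
                    "sd": sd,
                    "lo95": est - 1.96 * sd,
                    "hi95": est + 1.96 * sd,
                    "kind": "derived",
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Metropolis-Hastings sampling
# ---------------------------------------------------------------------------


@dataclass
class MCMCResult:
    """Saved (thinned) samples of the monitored quantities."""

    chains: np.ndarray  # (n_saved, n_monitored)
    labels: list[str]
    n_total: int
    burn_in: int
    thin: int
    acceptance_rate: float
    proposal_scale: float

    @property
    def n_saved(self) -> int:
        return self.chains.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.chains, columns=self.labels)


def default_monitor(fit, cap: int = MAX_MONITORED):
    """Monitored quantities: every estimated scalar (non-year-indexed)
    parameter, plus 2015 spawning biomass, 2015 recruitment and the 2011
    fishing-mortality deviation when present, capped at ``cap``."""
    from .core import project

    adapter = fit.adapter
    if adapter is None:  # toy objective: monitor the raw parameters
        n = len(fit.z_opt)
        return [f"param_{j}" for j in range(n)], lambda z: np.asarray(z)
    labels: list[str] = []
    slots: list[int] = []
    for j, i in enumerate(adapter.active_idx):
        name = adapter.names[i]
        if "[" not in name:  # year- and survey-indexed parameters excluded
            labels.append(name)
            slots.append(j)
        elif name.startswith(("alpha_s[", "beta_s[")):
            labels.append(name)
            slots.append(j)
    structure = adapter.structure
    extras = []
    if structure.first_year <= 2015 <= structure.last_year:
        extras += [("SSB_2015", "ssb"), ("R_2015", "rec")]
    if "eps_f[2011]" in [adapter.names[i] for i in adapter.active_idx]:
        extras += [("eps_f_2011", "epsf")]

    y2015 = 2015 - structure.first_year
    y2011 = 2011 - structure.first_year
    epsf_slot = None
    for j, i in enumerate(adapter.active_idx):
        if adapter.names[i] == "eps_f[2011]":
            epsf_slot = j

    def fn(z):
        u = adapter.full_u(z, fit.u_opt)
        params = adapter.params_from_u(u)
        x_nat = params.to_vector()
        out = list(x_nat[adapter.active_idx][slots])
        if extras:
            traj = project(params, None, structure)
            for name, kind in extras:
                if kind == "ssb":
                    out.append(traj.SSB_y[y2015])
                elif kind == "rec":
                    out.append(traj.R_y[y2015])
                elif kind == "epsf":
                    out.append(z[epsf_slot])
        return np.array(out)

    all_labels = (labels + [e[0] for e in extras])[:cap]

    def capped(z):
        return fn(z)[: len(all_labels)]

    return all_labels, capped


def mcmc_sample(
    fit,
    n_total: int = 100_000,
    thin: int = 20,
    burn_in: int | None = None,
    rng: np.random.Generator | int | None = None,
    monitor=None,
    adapt_steps: int = 1000,
    target_acceptance: float = 0.3,
) -> MCMCResult:
    """Random-walk Metropolis-Hastings over the estimation-scale parameters.

    The proposal is multivariate normal with covariance ``(2.4^2/d) * H^-1``
    times an adaptive scalar tuned toward ``target_acceptance`` during a
    pre-phase and frozen before any recorded sample (preserving detailed
    balance).  Saved samples are the monitored quantities evaluated at
    every ``thin``-th draw after ``burn_in`` (default 10% of ``n_total``).
    """
    if fit.hessian is None or not fit.hessian_ok:
        raise InvalidStateError(
            "MCMC unavailable: Hessian missing or not positive definite"
        )
    rng = np.random.default_rng(rng)
    if burn_in is None:
        burn_in = n_total // 10
    if not (0 <= burn_in < n_total and thin >= 1):
        raise ConfigurationError("need 0 <= burn_in < n_total and thin >= 1")
    H = 0.5 * (fit.hessian + fit.hessian.T)
    cov = np.linalg.inv(H)
    d = cov.shape[0]
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as e:
        raise InvalidStateError(
            "proposal covariance is degenerate; Hessian supports the asymptotic "
            "approximation but not MCMC sampling"
        ) from e
    base_scale = 2.4 / np.sqrt(d)
    f = fit.active_objective()
    z = fit.z_opt.copy()
    logpost = -f(z)

    # adaptive pre-phase: tune a scalar multiplier, then freeze it
    log_mult = 0.0
    if adapt_steps > 0:
        block = max(adapt_steps // 20, 25)
        accepted = 0
        since = 0
        for step in range(adapt_steps):
            prop = z + np.exp(log_mult) * base_scale * (L @ rng.standard_normal(d))
            lp = -f(prop)
            if np.log(rng.uniform()) < lp - logpost:
                z, logpost = prop, lp
                accepted += 1
            since += 1
            if since == block:
                rate = accepted / block
                log_mult += 0.5 * (rate - target_acceptance)
                accepted = since = 0
    scale = float(np.exp(log_mult)) * base_scale

    if monitor is None:
        labels, monitor_fn = default_monitor(fit)
    else:
        labels, monitor_fn = monitor
    n_saved = (n_total - burn_in) // thin
    chains = np.empty((n_saved, len(labels)))
    n_accept = 0
    k = 0
    for step in range(1, n_total + 1):
        prop = z + scale * (L @ rng.standard_normal(d))
        lp = -f(prop)
        if np.log(rng.uniform()) < lp - logpost:
            z, logpost = prop, lp
            n_accept += 1
        if step > burn_in and (step - burn_in) % thin == 0 and k < n_saved:
            chains[k] = monitor_fn(z)
            k += 1
    return MCMCResult(
        chains=chains,
        labels=list(labels),
        n_total=n_total,
        burn_in=burn_in,
        thin=thin,
        acceptance_rate=n_accept / n_total,
        proposal_scale=scale,
    )


# ---------------------------------------------------------------------------
# Spectral variance and diagnostics
# ---------------------------------------------------------------------------


def spectrum0_ar(x: np.ndarray) -> float:
    """Spectral density of a chain at frequency zero.

    Fits an autoregressive model with the order chosen by AIC;
    ``s0 = sigma^2 / (1 - sum(phi))^2``.  Falls back to the sample variance
    for (near-)constant or very short chains.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    v = float(np.var(x, ddof=1)) if n > 1 else 0.0
    if n < 10 or v <= 0 or not np.isfinite(v):
        return max(v, 0.0)
    maxlag = min(int(10 * np.log10(n)), n // 2 - 1)
    try:
        sel = ar_select_order(x, maxlag=maxlag, ic="aic", old_names=False)
        order = len(sel.ar_lags) if sel.ar_lags is not None else 0
        res = AutoReg(x, lags=order, old_names=False).fit() if order else None
    except (ValueError, np.linalg.LinAlgError):
        res = None
        order = 0
    if res is None or order == 0:
        return v
    phi_sum = float(np.sum(res.params[1:]))
    sigma2 = float(res.sigma2)
    denom = (1.0 - phi_sum) ** 2
    if denom < 1e-12:
        return v * n  # near unit root: report something large but finite
    return sigma2 / denom


@dataclass
class HWResult:
    stationarity_pass: bool
    kept_fraction: float
    halfwidth_pass: bool
    mean: float
    halfwidth: float
    warning: str = ""


def heidelberger_welch(chain: np.ndarray, alpha: float = 0.05, eps: float = 0.1) -> HWResult:
    """Heidelberger-Welch stationarity and halfwidth tests.

    The stationarity half uses the Cramer-von Mises statistic of the
    standardized Brownian bridge of cumulative sums, discarding the first
    10% of the chain repeatedly (up to 50%) until the retained part passes.
    The halfwidth half requires the 95% interval halfwidth (spectral
    variance at frequency zero) to be below ``eps`` times the |mean|.
    """
    x = np.asarray(chain, dtype=float)
    if x.size < 100:
        raise ConfigurationError("chain too short for Heidelberger-Welch (need >= 100)")
    n0 = x.size
    stationary = False
    kept = 0.0
    retained = x
    for drop in np.arange(0.0, 0.51, 0.1):
        retained = x[int(drop * n0) :]
        s0 = spectrum0_ar(retained)
        if s0 <= 0:
            stationary, kept = True, 1.0 - drop
            break
        n = retained.size
        csum = np.cumsum(retained)
        t = np.arange(1, n + 1) / n
        bridge = (csum - t * csum[-1]) / np.sqrt(n * s0)
        cvm = float(np.sum(bridge**2)) / n
        if cvm < _CVM_CRIT_5PCT:
            stationary, kept = True, 1.0 - drop
            break
    warning = ""
    if not stationary:
        return HWResult(False, 0.0, False, float(np.mean(x)), np.nan)
    mean = float(np.mean(retained))
    s0 = spectrum0_ar(retained)
    halfwidth = 1.96 * np.sqrt(s0 / retained.size)
    if abs(mean) < 1e-12 or np.var(retained) < 1e-24:
        # mean at zero (or constant chain): the relative test is undefined
        return HWResult(True, kept, True, mean, halfwidth, warning="halfwidth undefined")
    return HWResult(True, kept, bool(halfwidth / abs(mean) < eps), mean, halfwidth, warning)


def geweke_and_acf(
    chain: np.ndarray, first: float = 0.1, last: float = 0.5, max_lag: int = 50
):
    """Geweke z-score, lag-1..max_lag autocorrelations, and effective size.

    The z-score compares the means of the first ``first`` and last ``last``
    fractions using spectral variances; the effective size truncates the
    autocorrelation sum at the first non-positive value.
    """
    x = np.asarray(chain, dtype=float)
    n = x.size
    if n < 100:
        raise ConfigurationError("chain too short (need >= 100)")
    a = x[: int(first * n)]
    b = x[-int(last * n) :]
    va, vb = spectrum0_ar(a), spectrum0_ar(b)
    denom = np.sqrt(va / a.size + vb / b.size)
    z = float((np.mean(a) - np.mean(b)) / denom) if denom > 0 else 0.0
    xc = x - x.mean()
    var = float(np.dot(xc, xc)) / n
    max_lag = min(max_lag, n - 1)
    acf = np.empty(max_lag)
    for k in range(1, max_lag + 1):
        acf[k - 1] = float(np.dot(xc[:-k], xc[k:])) / (n * var) if var > 0 else 0.0
    rho_sum = 0.0
    for r in acf:
        if r <= 0:
            break
        rho_sum += r
    ess = n / (1.0 + 2.0 * rho_sum)
    return z, acf, float(ess)


@dataclass
class DiagnosticsReport:
    """Per-quantity convergence diagnostics for an MCMC run."""

    rows: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def overall_pass(self) -> bool:
        if self.rows.empty:
            return False
        return bool(
            self.rows["stationarity_pass"].all() and self.rows["halfwidth_pass"].all()
        )


def diagnose(result: MCMCResult, alpha: float = 0.05, eps: float = 0.1) -> DiagnosticsReport:
    """Heidelberger-Welch + Geweke + ESS for every monitored quantity."""
    rows = []
    for j, label in enumerate(result.labels):
        chain = result.chains[:, j]
        hw = heidelberger_welch(chain, alpha=alpha, eps=eps)
        z, acf, ess = geweke_and_acf(chain)
        rows.append(
            {
                "quantity": label,
                "stationarity_pass": hw.stationarity_pass,
                "kept_fraction": hw.kept_fraction,
                "halfwidth_pass": hw.halfwidth_pass,
                "mean": hw.mean,
                "halfwidth": hw.halfwidth,
                "geweke_z": z,
                "lag1_acf": acf[0] if len(acf) else np.nan,
                "ess": ess,
                "warning": hw.warning,
            }
        )
    return DiagnosticsReport(rows=pd.DataFrame(rows))
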