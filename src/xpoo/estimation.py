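"""Maximum-likelihood estimation of RRm, RRf, RR_B and RRR per window.

The observed-data conditional likelihood (see :mod:`xpoo.model`) is maximized
directly by quasi-Newton ascent with an analytic gradient, over haplotype
frequency logits and the free log relative risks. Per-haplotype confidence
intervals and p-values are Wald intervals on the log scale, with standard
errors from the inverse observed information (central-difference Hessian of
the log-likelihood). The window-level parent-of-origin test is a likelihood
ratio test of RRR = 1 for every non-reference haplotype, with the common
(RRm = RRf) effect still free under the null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import softmax

from .model import (MODELS, NO_X_INACTIVATION, X_INACTIVATION, RiskParams,
                    WindowLikelihood, hap_label)
from .triad_data import MISSING, TriadDataset


class FitError(ValueError):
    """A window that cannot be fitted (monomorphic, too few triads, ...)."""


@dataclass
class FitResult:
    """Per-window maximum-likelihood estimates.

    ``haplotypes`` holds one row per free (non-reference, non-pooled)
    haplotype with point estimates, 95% Wald CIs and two-sided p-values for
    RRm, RRf, RR_B and RRR = RRm/RRf. ``window_p`` is the likelihood-ratio
    p-value of the no-parent-of-origin-effect null (all RRR = 1).
    """

    params_hat: RiskParams
    haplotypes: pd.DataFrame
    window_p: float
    loglik: float
    loglik_null: float
    df: int
    converged: bool
    n_iter: int
    n_triads_used: int
    model: str
    window: list[int] = field(default_factory=list)
    reference: int = 0
    wald_window_p: float = float("nan")

    @property
    def rrr(self) -> np.ndarray:
        return self.haplotypes["rrr"].to_numpy()


def wald_interval_and_p(log_estimate: float, standard_error: float,
                        level: float = 0.95) -> tuple[float, float, float]:
    """Wald CI (on the natural scale) and two-sided p for a log-scale estimate."""
    if not np.isfinite(standard_error) or standard_error <= 0:
        return float("nan"), float("nan"), float("nan")
    z = stats.norm.ppf(0.5 + level / 2)
    lo = float(np.exp(log_estimate - z * standard_error))
    hi = float(np.exp(log_estimate + z * standard_error))
    p = float(2 * stats.norm.sf(abs(log_estimate) / standard_error))
    return lo, hi, p


def overall_window_test(fit_free: FitResult, fit_null: "FitResult | float",
                        df: int | None = None) -> float:
    """Likelihood-ratio p-value of the RRR = 1 null against the free model."""
    ll_null = fit_null.loglik if isinstance(fit_null, FitResult) else float(fit_null)
    if df is None:
        df = fit_free.df
    if fit_free.loglik < ll_null - 1e-6:
        raise FitError("free-model log-likelihood below the null: optimizer failure")
    stat = max(0.0, 2.0 * (fit_free.loglik - ll_null))
    return float(stats.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# Internal optimizer
# ---------------------------------------------------------------------------

class _Problem:
    """Parameter packing for one window fit.

    theta = [frequency logits of all haplotypes except the reference
    (softmax baseline), log RRm of the free haplotypes, log RRf of the free
    haplotypes]. Under the RRR = 1 null the two risk blocks collapse to one
    common block (RRm = RRf still free, isolating the transmission
    asymmetry).
    """

    def __init__(self, engine: WindowLikelihood, reference: int,
                 free_haps: np.ndarray, tied: bool):
        self.engine = engine
        self.k = engine.k
        self.reference = reference
        self.free_haps = free_haps
        self.free_logits = np.array([h for h in range(self.k) if h != reference])
        self.tied = tied
        self.nf = len(free_haps)
        self.n_params = (self.k - 1) + (self.nf if tied else 2 * self.nf)

    def unpack(self, theta: np.ndarray):
        gamma = np.zeros(self.k)
        gamma[self.free_logits] = theta[: self.k - 1]
        pi = softmax(gamma)
        log_rrm = np.zeros(self.k)
        log_rrf = np.zeros(self.k)
        if self.tied:
            b = theta[self.k - 1:]
            log_rrm[self.free_haps] = b
            log_rrf[self.free_haps] = b
        else:
            log_rrm[self.free_haps] = theta[self.k - 1: self.k - 1 + self.nf]
            log_rrf[self.free_haps] = theta[self.k - 1 + self.nf:]
        return pi, log_rrm, log_rrf

    def negloglik_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        pi, log_rrm, log_rrf = self.unpack(theta)
        ll, g_gamma, g_rrm, g_rrf = self.engine.loglik_grad(
            pi, log_rrm, log_rrf, self.free_haps)
        if self.tied:
            grad = np.concatenate([g_gamma[self.free_logits], g_rrm + g_rrf])
        else:
            grad = np.concatenate([g_gamma[self.free_logits], g_rrm, g_rrf])
        return -ll, -grad

    def loglik(self, theta: np.ndarray) -> float:
        pi, log_rrm, log_rrf = self.unpack(theta)
        return self.engine.loglik(pi, log_rrm, log_rrf)

    def init_theta(self, pi0: np.ndarray) -> np.ndarray:
        gamma = np.log(pi0) - np.log(pi0[self.reference])
        return np.concatenate([gamma[self.free_logits],
                               np.zeros(self.n_params - (self.k - 1))])

    def maximize(self, theta0: np.ndarray, tol: float, max_iter: int,
                 rng: np.random.Generator | None = None, n_restarts: int = 0):
        best = None
        starts = [theta0]
        if rng is not None:
            starts += [theta0 + rng.normal(scale=0.5, size=len(theta0))
                       for _ in range(n_restarts)]
        for start in starts:
            res = optimize.minimize(
                self.negloglik_grad, start, jac=True, method="BFGS",
                options={"gtol": tol, "maxiter": max_iter})
            if best is None or res.fun < best.fun:
                best = res
        return best

    def hessian(self, theta: np.ndarray, step: float = 1e-5) -> np.ndarray:
        """Observed information: central finite differences of the analytic
        gradient of the *negative* log-likelihood."""
        n = len(theta)
        h = np.zeros((n, n))
        for i in range(n):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += step
            tm[i] -= step
            _, gp = self.negloglik_grad(tp)
            _, gm = self.negloglik_grad(tm)
            h[i] = (gp - gm) / (2 * step)
        return (h + h.T) / 2


def _window_monomorphic(dataset: TriadDataset, window) -> bool:
    """True when no SNP in the window shows both alleles among observed calls."""
    m, f, c, girl = dataset.dose_matrices()
    for s in window:
        has_var = has_ref = False
        for arr, max_dose in ((m[:, s], 2), (f[:, s], 1),
                              (np.where(girl, c[:, s], np.minimum(c[:, s], 1)), None)):
            v = arr[arr != MISSING]
            if len(v) == 0:
                continue
            if (v > 0).any():
                has_var = True
            caps = np.full(len(v), 2 if max_dose == 2 else 1)
            if max_dose is None:  # children: girls carry 2 alleles, boys 1
                caps = np.where(girl[arr != MISSING], 2, 1)
            if (v < caps).any():
                has_ref = True
        if has_var and has_ref:
            return False
    return True


def _estimate_null_freqs(problem_engine: WindowLikelihood, tol: float,
                         max_iter: int) -> np.ndarray:
    """ML haplotype frequencies with all relative risks fixed at 1."""
    prob = _Problem(problem_engine, reference=0,
                    free_haps=np.zeros(0, dtype=int), tied=False)
    theta0 = np.zeros(prob.n_params)
    res = prob.maximize(theta0, tol, max_iter)
    pi, _, _ = prob.unpack(res.x)
    return pi


def fit_window(dataset: TriadDataset, window, model: str, tol: float = 1e-8,
               max_iter: int = 1000, seed_for_restarts: int | None = None,
               min_informative: int = 10,
               rare_haplotype_min_freq: float = 0.01,
               compute_se: bool = True) -> FitResult:
    """Maximize the observed-data likelihood of one window.

    Returns point estimates, Wald CIs/p-values per free haplotype, the
    window-level likelihood-ratio p for the parent-of-origin null (RRR = 1
    everywhere), and convergence diagnostics. Haplotypes whose estimated
    frequency falls below ``rare_haplotype_min_freq`` keep their frequency
    parameters but have their relative risks fixed at the reference level.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    window = list(window)
    engine = WindowLikelihood(dataset, window, model)
    if engine.n_triads_used < min_informative:
        raise FitError(f"only {engine.n_triads_used} informative triads "
                       f"(minimum {min_informative})")
    if _window_monomorphic(dataset, window):
        raise FitError("monomorphic window")

    # frequency prefit (reference haplotype, rare pooling, initialization):
    # hemizygosity-aware allele counting for a single SNP, ML with all RR = 1
    # for multi-SNP windows
    if engine.window_size == 1:
        m, f, c, girl = dataset.dose_matrices()
        s = window[0]
        var = (m[:, s][m[:, s] != MISSING].sum()
               + f[:, s][f[:, s] != MISSING].sum()
               + c[:, s][c[:, s] != MISSING].sum())
        tot = (2 * (m[:, s] != MISSING).sum() + (f[:, s] != MISSING).sum()
               + (girl + 1)[c[:, s] != MISSING].sum())
        freq = min(max(var / tot, 1e-6), 1 - 1e-6)
        pi0 = np.array([1 - freq, freq])
    else:
        pi0 = _estimate_null_freqs(engine, tol, max_iter)
    best_freq = pi0.max()
    candidates = np.flatnonzero(np.abs(pi0 - best_freq) < 1e-9)
    reference = int(min(candidates,
                        key=lambda h: hap_label(h, engine.window_size)))
    free_haps = np.array([h for h in range(engine.k)
                          if h != reference and pi0[h] >= rare_haplotype_min_freq],
                         dtype=int)
    if len(free_haps) == 0:
        raise FitError("no non-reference haplotype above the rare-frequency floor")

    rng = (np.random.default_rng(seed_for_restarts)
           if seed_for_restarts is not None else None)

    # null fit (RRm = RRf, frequencies free)
    prob_null = _Problem(engine, reference, free_haps, tied=True)
    res_null = prob_null.maximize(prob_null.init_theta(pi0), tol, max_iter,
                                  rng=rng, n_restarts=2 if rng is not None else 0)
    ll_null = -res_null.fun

    # free fit, warm-started from the null optimum
    prob = _Problem(engine, reference, free_haps, tied=False)
    gamma_part = res_null.x[: engine.k - 1]
    b_part = res_null.x[engine.k - 1:]
    theta0 = np.concatenate([gamma_part, b_part, b_part])
    res = prob.maximize(theta0, tol, max_iter, rng=rng,
                        n_restarts=2 if rng is not None else 0)
    ll = -res.fun
    if ll < ll_null - 1e-6:
        raise FitError("free fit below null fit: optimization failure")
    ll = max(ll, ll_null)

    pi, log_rrm, log_rrf = prob.unpack(res.x)
    params_hat = RiskParams(pi, log_rrm, log_rrf, reference=reference)

    df = len(free_haps)
    stat = max(0.0, 2.0 * (ll - ll_null))
    window_p = float(stats.chi2.sf(stat, df))

    # per-haplotype table; Wald CIs/p-values only when the Hessian is requested
    rows = []
    wald_window_p = float("nan")
    k1 = engine.k - 1
    nf = len(free_haps)
    if compute_se:
        hess = prob.hessian(res.x)
        try:
            cov = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            cov = np.full((prob.n_params, prob.n_params), np.nan)
    else:
        cov = np.full((prob.n_params, prob.n_params), np.nan)
    for i, h in enumerate(free_haps):
        im, jf = k1 + i, k1 + nf + i
        bm, bf = log_rrm[h], log_rrf[h]
        var_m, var_f, cov_mf = cov[im, im], cov[jf, jf], cov[im, jf]
        se_m = np.sqrt(var_m) if var_m > 0 else float("nan")
        se_f = np.sqrt(var_f) if var_f > 0 else float("nan")
        var_r = var_m + var_f - 2 * cov_mf
        se_r = np.sqrt(var_r) if var_r > 0 else float("nan")
        if model == X_INACTIVATION:
            log_rrb, var_b = bm + bf, var_m + var_f + 2 * cov_mf
        elif model == NO_X_INACTIVATION:
            log_rrb, var_b = bm, var_m
        else:
            log_rrb, var_b = float("nan"), float("nan")
        se_b = np.sqrt(var_b) if var_b > 0 else float("nan")
        rrm_lo, rrm_hi, rrm_p = wald_interval_and_p(bm, se_m)
        rrf_lo, rrf_hi, rrf_p = wald_interval_and_p(bf, se_f)
        rrr_lo, rrr_hi, rrr_p = wald_interval_and_p(bm - bf, se_r)
        rrb_lo, rrb_hi, rrb_p = wald_interval_and_p(log_rrb, se_b)
        rows.append({
            "haplotype": h,
            "label": hap_label(h, engine.window_size),
            "freq": pi[h],
            "rrm": float(np.exp(bm)), "rrm_lo": rrm_lo, "rrm_hi": rrm_hi, "rrm_p": rrm_p,
            "rrf": float(np.exp(bf)), "rrf_lo": rrf_lo, "rrf_hi": rrf_hi, "rrf_p": rrf_p,
            "rrb": float(np.exp(log_rrb)), "rrb_lo": rrb_lo, "rrb_hi": rrb_hi, "rrb_p": rrb_p,
            "rrr": float(np.exp(bm - bf)), "rrr_lo": rrr_lo, "rrr_hi": rrr_hi, "rrr_p": rrr_p,
        })
    if compute_se and rows:
        # Wald window test: quadratic form of the free log-RRR vector
        d = np.zeros((nf, prob.n_params))
        for i in range(nf):
            d[i, k1 + i] = 1.0
            d[i, k1 + nf + i] = -1.0
        delta = log_rrm[free_haps] - log_rrf[free_haps]
        vr = d @ cov @ d.T
        try:
            w_stat = float(delta @ np.linalg.solve(vr, delta))
            wald_window_p = float(stats.chi2.sf(w_stat, nf))
        except np.linalg.LinAlgError:
            pass
    hap_df = pd.DataFrame(
        rows, columns=["haplotype", "label", "freq",
                       "rrm", "rrm_lo", "rrm_hi", "rrm_p",
                       "rrf", "rrf_lo", "rrf_hi", "rrf_p",
                       "rrb", "rrb_lo", "rrb_hi", "rrb_p",
                       "rrr", "rrr_lo", "rrr_hi", "rrr_p"])

    converged = bool(res.success or np.linalg.norm(res.jac) < 1e-4)
    return FitResult(
        params_hat=params_hat, haplotypes=hap_df, window_p=window_p,
        loglik=ll, loglik_null=ll_null, df=df, converged=converged,
        n_iter=int(res.nit), n_triads_used=engine.n_triads_used,
        model=model, window=window, reference=reference,
        wald_window_p=wald_window_p)
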