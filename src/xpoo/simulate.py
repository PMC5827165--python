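"""Simulation of case-parent triads under the X-linked PoO model, and power.

Triads are drawn *exactly* from the conditional-on-affected configuration
distribution: for each child (sex drawn by ``prop_female``) a complete
configuration — mother's ordered haplotype pair and father's haplotype — is
sampled from the normalized prior x relative-risk weights of the generative
model. This is the distribution the likelihood conditions on, so no
rejection loop and no absolute baseline bookkeeping is needed; baselines
cancel on conditioning.

Power for the window-level RRR test is the fraction of simulated datasets
whose likelihood-ratio p falls below the nominal level, with per-replicate
seeds spawned deterministically from the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
import pandas as pd

from .estimation import FitError, fit_window
from .model import (MODELS, NO_X_INACTIVATION, X_INACTIVATION, RiskParams,
                    _config_indices, hap_allele_matrix)
from .triad_data import FEMALE, MALE, MISSING, SnpInfo, TriadDataset, TriadRecord


@dataclass(frozen=True)
class SimSpec:
    """Generative parameters for one simulated dataset / power cell.

    A single biallelic SNP by default; ``hap_freqs`` generalizes to a
    multi-SNP window (haplotype h carries the variant at SNP s iff bit s of h
    is set), with ``rrm``/``rrf`` applying to ``effect_hap`` and all other
    haplotypes at the reference level.
    """

    maf: float = 0.2
    rrm: float = 1.0
    rrf: float = 1.0
    true_model: str = X_INACTIVATION
    n_triads: int = 600
    prop_female: float = 0.5
    baseline_girl: float = 0.004
    baseline_boy: float = 0.005
    missing_rate_parent: float = 0.0
    n_reps: int = 1000
    alpha: float = 0.05
    seed: int = 0
    hap_freqs: tuple[float, ...] | None = None
    effect_hap: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.maf <= 0.5:
            raise ValueError("maf must be in (0, 0.5]")
        if self.rrm <= 0 or self.rrf <= 0:
            raise ValueError("relative risks must be positive")
        if self.true_model not in (X_INACTIVATION, NO_X_INACTIVATION):
            raise ValueError("true_model must be a combined constraint model")
        if not 0 <= self.prop_female <= 1:
            raise ValueError("prop_female must be in [0, 1]")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not 0 <= self.missing_rate_parent < 1:
            raise ValueError("missing_rate_parent must be in [0, 1)")

    def risk_params(self) -> RiskParams:
        if self.hap_freqs is None:
            freqs = np.array([1.0 - self.maf, self.maf])
        else:
            freqs = np.asarray(self.hap_freqs, dtype=float)
            freqs = freqs / freqs.sum()
        k = len(freqs)
        log_rrm = np.zeros(k)
        log_rrf = np.zeros(k)
        log_rrm[self.effect_hap] = np.log(self.rrm)
        log_rrf[self.effect_hap] = np.log(self.rrf)
        return RiskParams(freqs, log_rrm, log_rrf, reference=0,
                          baseline_girl=self.baseline_girl,
                          baseline_boy=self.baseline_boy)

    @property
    def window_size(self) -> int:
        if self.hap_freqs is None:
            return 1
        return int(np.log2(len(self.hap_freqs)))


@dataclass
class PowerResult:
    """Monte-Carlo power estimate for one simulation cell."""

    power: float
    mc_standard_error: float
    n_reps_used: int
    n_failed: int
    spec: SimSpec
    fit_model: str

    def __post_init__(self) -> None:
        expected = float(np.sqrt(self.power * (1 - self.power) / max(self.n_reps_used, 1)))
        self.mc_standard_error = expected


def _conditional_config_probs(params: RiskParams, model: str
                              ) -> tuple[np.ndarray, np.ndarray]:
    """(girl, boy) conditional probabilities over the K^3 configurations."""
    pi = params.hap_freqs
    mt, mu, f = _config_indices(params.n_haplotypes)
    prior = pi[mt] * pi[mu] * pi[f]
    w_girl = prior * np.exp(params.log_rrm[mt] + params.log_rrf[f])
    if model == X_INACTIVATION:
        w_boy = prior * np.exp(params.log_rrm[mt] + params.log_rrf[mt])
    else:
        w_boy = prior * np.exp(params.log_rrm[mt])
    return w_girl / w_girl.sum(), w_boy / w_boy.sum()


def simulate_triads(spec: SimSpec, rng: np.random.Generator | None = None
                    ) -> TriadDataset:
    """Draw one triad dataset from the conditional-on-affected model."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    params = spec.risk_params()
    k = params.n_haplotypes
    w = spec.window_size
    alleles = hap_allele_matrix(w)
    mt_idx, mu_idx, f_idx = _config_indices(k)
    p_girl, p_boy = _conditional_config_probs(params, spec.true_model)

    n = spec.n_triads
    is_girl = rng.random(n) < spec.prop_female
    configs = np.empty(n, dtype=np.int64)
    n_g = int(is_girl.sum())
    if n_g:
        configs[is_girl] = rng.choice(len(p_girl), size=n_g, p=p_girl)
    if n - n_g:
        configs[~is_girl] = rng.choice(len(p_boy), size=n - n_g, p=p_boy)

    mt, mu, f = mt_idx[configs], mu_idx[configs], f_idx[configs]
    mother = alleles[mt] + alleles[mu]                 # (n, w) doses
    father = alleles[f].copy()
    child = np.where(is_girl[:, None], alleles[mt] + alleles[f], alleles[mt])

    if spec.missing_rate_parent > 0:
        mother[rng.random(n) < spec.missing_rate_parent] = MISSING
        father[rng.random(n) < spec.missing_rate_parent] = MISSING

    snps = [SnpInfo(f"snp{s + 1}", 1000 * (s + 1), "A", "B") for s in range(w)]
    mother = mother.astype(np.int8)
    father = father.astype(np.int8)
    child = child.astype(np.int8)
    triads = [
        TriadRecord(f"triad{i + 1}", FEMALE if is_girl[i] else MALE,
                    mother[i], father[i], child[i])
        for i in range(n)
    ]
    ds = TriadDataset(snps, triads, validate=False)
    ds._dose_cache = (mother, father, child, is_girl)
    return ds


def simulate_chromosome(specs: list[SimSpec], seed: int | None = None
                        ) -> TriadDataset:
    """Stack independent single-SNP draws into one multi-SNP dataset with a
    shared child-sex vector (linkage equilibrium between SNPs; each SNP's
    genotypes drawn from its own conditional-on-affected distribution).

    Suitable for chromosome-scan fixtures where at most the marked SNPs carry
    an effect; under the null the conditional distribution is the Mendelian
    prior, so independence across SNPs is exact.
    """
    if not specs:
        raise ValueError("need at least one SimSpec")
    if seed is None:
        seed = specs[0].seed
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = specs[0].n_triads
    is_girl = rng.random(n) < specs[0].prop_female

    mothers, fathers, children, snps = [], [], [], []
    for s_idx, spec in enumerate(specs):
        if spec.n_triads != n or spec.window_size != 1:
            raise ValueError("all specs must share n_triads and be single-SNP")
        params = spec.risk_params()
        alleles = hap_allele_matrix(1)
        mt_idx, mu_idx, f_idx = _config_indices(2)
        p_girl, p_boy = _conditional_config_probs(params, spec.true_model)
        configs = np.empty(n, dtype=np.int64)
        n_g = int(is_girl.sum())
        if n_g:
            configs[is_girl] = rng.choice(len(p_girl), size=n_g, p=p_girl)
        if n - n_g:
            configs[~is_girl] = rng.choice(len(p_boy), size=n - n_g, p=p_boy)
        mt, mu, f = mt_idx[configs], mu_idx[configs], f_idx[configs]
        mo = (alleles[mt] + alleles[mu]).astype(np.int8)
        fa = alleles[f].astype(np.int8).copy()
        ch = np.where(is_girl[:, None], alleles[mt] + alleles[f],
                      alleles[mt]).astype(np.int8)
        if spec.missing_rate_parent > 0:
            mo[rng.random(n) < spec.missing_rate_parent] = MISSING
            fa[rng.random(n) < spec.missing_rate_parent] = MISSING
        mothers.append(mo[:, 0])
        fathers.append(fa[:, 0])
        children.append(ch[:, 0])
        snps.append(SnpInfo(f"snp{s_idx + 1}", 1000 * (s_idx + 1), "A", "B"))

    m = np.column_stack(mothers)
    f = np.column_stack(fathers)
    c = np.column_stack(children)
    triads = [
        TriadRecord(f"triad{i + 1}", FEMALE if is_girl[i] else MALE,
                    m[i], f[i], c[i])
        for i in range(n)
    ]
    ds = TriadDataset(snps, triads, validate=False)
    ds._dose_cache = (m, f, c, is_girl)
    return ds


def _rep_rng(seed: int, rep: int) -> np.random.Generator:
    """Deterministic per-replicate stream (counter-based spawning)."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(rep,)))


def estimate_power(spec: SimSpec, fit_model: str, min_informative: int = 10
                   ) -> PowerResult:
    """Monte-Carlo power of the window-level RRR likelihood-ratio test."""
    if fit_model not in MODELS:
        raise ValueError(f"unknown model {fit_model!r}")
    hits = 0
    used = 0
    failed = 0
    for rep in range(spec.n_reps):
        ds = simulate_triads(spec, rng=_rep_rng(spec.seed, rep))
        try:
            fit = fit_window(ds, list(range(ds.n_snps)), fit_model,
                             min_informative=min_informative, compute_se=False)
        except FitError:
            failed += 1
            continue
        used += 1
        if fit.window_p < spec.alpha:
            hits += 1
    if used == 0:
        raise FitError("all replicates failed to fit")
    if failed > 0.01 * spec.n_reps:
        import logging
        logging.getLogger("xpoo").warning(
            "%d/%d power replicates failed to fit and were excluded",
            failed, spec.n_reps)
    power = hits / used
    return PowerResult(power=power, mc_standard_error=0.0, n_reps_used=used,
                       n_failed=failed, spec=spec, fit_model=fit_model)


def power_grid(rrr_values=(1.0,), maf_values=(0.2,), n_values=(600,),
               fit_models=(X_INACTIVATION,), base_spec: SimSpec | None = None
               ) -> pd.DataFrame:
    """Power over a grid of RRR (varying RRm at RRf = 1), MAF, sample size
    and fitted model. One row per cell with the Monte-Carlo SE."""
    if not (len(rrr_values) and len(maf_values) and len(n_values) and len(fit_models)):
        raise ValueError("empty grid")
    if base_spec is None:
        base_spec = SimSpec()
    rows = []
    for rrr, maf, n, fit_model in product(rrr_values, maf_values, n_values, fit_models):
        spec = replace(base_spec, rrm=float(rrr), rrf=1.0, maf=float(maf),
                       n_triads=int(n))
        res = estimate_power(spec, fit_model)
        rows.append({
            "rrr": rrr, "maf": maf, "n_triads": n, "fit_model": fit_model,
            "true_model": spec.true_model, "power": res.power,
            "mc_se": res.mc_standard_error, "n_reps_used": res.n_reps_used,
            "n_failed": res.n_failed,
        })
    return pd.DataFrame(rows)
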