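"""Conditional likelihood for parent-of-origin effects on the X chromosome.

The model assigns each haplotype (allele, for a single SNP) a maternal
relative risk RRm and a paternal relative risk RRf. An affected girl carrying
maternal haplotype h_m and paternal haplotype h_f multiplies her baseline risk
by RRm(h_m) * RRf(h_f); an affected boy carrying h_m multiplies his by
RR_B(h_m), where RR_B is tied to the girls' parameters by one of two
X-inactivation constraints:

* ``x_inactivation``:     RR_B = RRm * RRf  (a girl's double dose acts like a
  boy's single dose, because one of her X's is silenced at random);
* ``no_x_inactivation``:  RR_B = RRm        (both of a girl's X's are active,
  so a boy's single maternal dose acts like the girl's maternal dose).

The parent-of-origin effect is the relative risk ratio RRR = RRm/RRf; RRR = 1
means the allele's effect does not depend on which parent transmitted it.

The likelihood is the joint multinomial over complete triad configurations
(mother's ordered haplotype pair, father's haplotype) conditional on an
affected child of known sex, assuming Hardy-Weinberg equilibrium, random
mating, a single haplotype-frequency vector shared by mothers and fathers,
and no recombination within a window of up to four SNPs. Baseline risks are
sex-specific but cancel in the conditional probabilities, so they are never
estimated. Missing genotypes and phase ambiguity are handled by summing the
conditional probabilities over all compatible configurations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .triad_data import FEMALE, MALE, MISSING, TriadDataset

X_INACTIVATION = "x_inactivation"
NO_X_INACTIVATION = "no_x_inactivation"
GIRLS_ONLY = "girls_only"

MODELS = (X_INACTIVATION, NO_X_INACTIVATION, GIRLS_ONLY)


@dataclass(frozen=True)
class ModelSpec:
    """Analysis configuration: constraint model, window size, reference and
    rare-haplotype policy."""

    model: str = X_INACTIVATION
    window_size: int = 1
    reference_policy: str = "most_frequent"
    rare_haplotype_min_freq: float = 0.01

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if not 1 <= self.window_size <= 4:
            raise ValueError("window_size must be in 1..4")
        if self.reference_policy != "most_frequent":
            raise ValueError("only the most_frequent reference policy is supported")


@dataclass
class RiskParams:
    """Haplotype frequencies and per-haplotype log relative risks.

    ``hap_freqs`` lives on the K-simplex; ``log_rrm``/``log_rrf`` are full
    K-vectors with the reference haplotype's entries fixed at zero. Baseline
    absolute risks are carried for the simulator's documentation only — they
    cancel in the conditional likelihood.
    """

    hap_freqs: np.ndarray
    log_rrm: np.ndarray
    log_rrf: np.ndarray
    reference: int = 0
    baseline_girl: float = 0.004
    baseline_boy: float = 0.005

    def __post_init__(self) -> None:
        self.hap_freqs = np.asarray(self.hap_freqs, dtype=float)
        self.log_rrm = np.asarray(self.log_rrm, dtype=float)
        self.log_rrf = np.asarray(self.log_rrf, dtype=float)
        k = len(self.hap_freqs)
        if not (len(self.log_rrm) == len(self.log_rrf) == k):
            raise ValueError("hap_freqs, log_rrm, log_rrf must share length")
        if np.any(self.hap_freqs <= 0):
            raise ValueError("haplotype frequencies must be positive")
        if abs(self.hap_freqs.sum() - 1.0) > 1e-12:
            raise ValueError("haplotype frequencies must sum to 1")
        if not 0 <= self.reference < k:
            raise ValueError("reference index out of range")
        if self.log_rrm[self.reference] != 0 or self.log_rrf[self.reference] != 0:
            raise ValueError("reference haplotype must have log RR = 0")

    @property
    def n_haplotypes(self) -> int:
        return len(self.hap_freqs)

    @property
    def rrm(self) -> np.ndarray:
        return np.exp(self.log_rrm)

    @property
    def rrf(self) -> np.ndarray:
        return np.exp(self.log_rrf)


@dataclass(frozen=True)
class TriadConfig:
    """One complete-data configuration: the mother's ordered haplotype pair
    (transmitted, untransmitted), the father's haplotype, child sex, and its
    prior probability under HWE, random mating and Mendelian transmission."""

    mother_haps: tuple[int, int]
    father_hap: int
    child_sex: str
    prior_prob: float


def rrb_from_constraint(rrm: float, rrf: float, model: str) -> float:
    """Boys' relative risk RR_B implied by the X-inactivation constraint."""
    if rrm <= 0 or rrf <= 0:
        raise ValueError("relative risks must be positive")
    if model == X_INACTIVATION:
        return rrm * rrf
    if model == NO_X_INACTIVATION:
        return rrm
    raise ValueError(f"RR_B is undefined for model {model!r}")


def child_relative_risk(maternal_hap: int, paternal_hap: int | None,
                        child_sex: str, params: RiskParams, model: str) -> float:
    """Multiplicative penetrance factor for an affected child's haplotypes.

    Girls: RRm(maternal) * RRf(paternal). Boys: RR_B(maternal) under the
    model constraint. The reference haplotype contributes a factor of 1.
    """
    if child_sex == FEMALE:
        if paternal_hap is None:
            raise ValueError("a girl requires a paternal haplotype")
        return float(np.exp(params.log_rrm[maternal_hap] + params.log_rrf[paternal_hap]))
    return rrb_from_constraint(float(np.exp(params.log_rrm[maternal_hap])),
                               float(np.exp(params.log_rrf[maternal_hap])), model)


# ---------------------------------------------------------------------------
# Configuration space
# ---------------------------------------------------------------------------

def _config_indices(n_haplotypes: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Index arrays (mt, mu, f) over the K^3 configurations, in the order
    (mother transmitted) x (mother untransmitted) x (father)."""
    k = n_haplotypes
    grid = np.indices((k, k, k)).reshape(3, -1)
    return grid[0], grid[1], grid[2]


def enumerate_configs(n_haplotypes: int, child_sex: str,
                      hap_freqs: Sequence[float] | None = None) -> list[TriadConfig]:
    """All complete-data configurations for one child sex with their priors.

    The mother's pair is ordered (transmitted, untransmitted), which folds the
    1/2 transmission probability into the pair prior pi_t * pi_u; the father's
    haplotype is retained for both sexes (for boys it does not enter the child
    but still informs the haplotype frequencies). Priors sum to 1 per sex for
    any frequency vector on the simplex.
    """
    if n_haplotypes < 2:
        raise ValueError("need at least 2 haplotypes (monomorphic window)")
    if hap_freqs is None:
        hap_freqs = np.full(n_haplotypes, 1.0 / n_haplotypes)
    pi = np.asarray(hap_freqs, dtype=float)
    mt, mu, f = _config_indices(n_haplotypes)
    priors = pi[mt] * pi[mu] * pi[f]
    return [
        TriadConfig((int(a), int(b)), int(c), child_sex, float(p))
        for a, b, c, p in zip(mt, mu, f, priors)
    ]


def _config_weights(params: RiskParams, model: str, child_sex: str) -> np.ndarray:
    """Unnormalized posterior weights prior * RR over the K^3 configurations."""
    pi = params.hap_freqs
    mt, mu, f = _config_indices(params.n_haplotypes)
    log_w = np.log(pi)[mt] + np.log(pi)[mu] + np.log(pi)[f]
    if child_sex == FEMALE:
        log_w = log_w + params.log_rrm[mt] + params.log_rrf[f]
    else:
        if model == X_INACTIVATION:
            log_w = log_w + params.log_rrm[mt] + params.log_rrf[mt]
        elif model == NO_X_INACTIVATION:
            log_w = log_w + params.log_rrm[mt]
        else:
            raise ValueError(f"boys are not modelled under {model!r}")
    return np.exp(log_w)


def config_conditional_probability(config: TriadConfig, params: RiskParams,
                                   model: str) -> float:
    """Probability of a complete configuration given an affected child of that
    sex: prior * relative risk, normalized within the sex. Baselines cancel."""
    w = _config_weights(params, model, config.child_sex)
    k = params.n_haplotypes
    idx = (config.mother_haps[0] * k + config.mother_haps[1]) * k + config.father_hap
    return float(w[idx] / w.sum())


# ---------------------------------------------------------------------------
# Observed-data likelihood engine
# ---------------------------------------------------------------------------

def hap_allele_matrix(window_size: int) -> np.ndarray:
    """(2^w x w) variant-allele doses of each haplotype; haplotype index h
    carries the variant at SNP s iff bit s of h is set."""
    k = 2 ** window_size
    hs = np.arange(k)[:, None]
    return ((hs >> np.arange(window_size)[None, :]) & 1).astype(np.int8)


def hap_label(h: int, window_size: int, snps=None) -> str:
    """Allele string of haplotype h, e.g. 'A-B' for ref at SNP1, var at SNP2."""
    bits = [(h >> s) & 1 for s in range(window_size)]
    if snps is not None:
        return "-".join(snps[s].allele_var if b else snps[s].allele_ref
                        for s, b in enumerate(bits))
    return "-".join("B" if b else "A" for b in bits)


class WindowLikelihood:
    """Observed-data conditional log-likelihood of one SNP window.

    Observed triads are grouped into unique genotype patterns per sex; each
    pattern holds a boolean compatibility mask over the K^3 complete
    configurations. Missing doses are compatible with everything, so EM-style
    marginalization over missing parents and ambiguous phase is a masked sum.
    """

    def __init__(self, dataset: TriadDataset, window: Sequence[int], model: str):
        if model not in MODELS:
            raise ValueError(f"unknown model {model!r}")
        self.model = model
        self.window = list(window)
        self.window_size = len(self.window)
        if not 1 <= self.window_size <= 4:
            raise ValueError("window must contain 1..4 SNPs")
        self.k = 2 ** self.window_size
        self.alleles = hap_allele_matrix(self.window_size)  # (K, w)
        self.mt, self.mu, self.f = _config_indices(self.k)
        # occurrence counts of each haplotype among (mt, mu, f), used by the
        # gradient of the frequency logits
        self.hap_count = np.zeros((self.k ** 3, self.k))
        for arr in (self.mt, self.mu, self.f):
            np.add.at(self.hap_count, (np.arange(self.k ** 3), arr), 1.0)

        m, f, c, girl = dataset.dose_matrices()
        m, f, c = m[:, self.window], f[:, self.window], c[:, self.window]
        if model == GIRLS_ONLY:
            keep = girl
            m, f, c, girl = m[keep], f[keep], c[keep], girl[keep]
        self._build_patterns(m, f, c, girl)

    def _compat_mask(self, m_obs, f_obs, c_obs, is_girl: bool) -> np.ndarray:
        mask = np.ones(self.k ** 3, dtype=bool)
        for s in range(self.window_size):
            a = self.alleles[:, s]
            if m_obs[s] != MISSING:
                mask &= (a[self.mt] + a[self.mu]) == m_obs[s]
            if f_obs[s] != MISSING:
                mask &= a[self.f] == f_obs[s]
            if c_obs[s] != MISSING:
                if is_girl:
                    mask &= (a[self.mt] + a[self.f]) == c_obs[s]
                else:
                    mask &= a[self.mt] == c_obs[s]
        return mask

    def _build_patterns(self, m, f, c, girl) -> None:
        pats: dict[tuple, int] = {}
        order: list[tuple] = []
        for i in range(len(girl)):
            key = (bool(girl[i]), tuple(m[i]), tuple(f[i]), tuple(c[i]))
            if all(v == MISSING for v in key[1] + key[2] + key[3]):
                continue  # fully missing triad carries no information
            if key not in pats:
                pats[key] = 0
                order.append(key)
            pats[key] += 1

        masks, counts, sexes = [], [], []
        for key in order:
            is_girl, mo, fo, co = key
            mask = self._compat_mask(mo, fo, co, is_girl)
            if not mask.any():
                fully = all(v != MISSING for v in mo + fo + co)
                kind = "fully observed" if fully else "observed"
                raise ValueError(
                    f"{kind} triad genotype pattern (sex="
                    f"{'girl' if is_girl else 'boy'}, mother={mo}, father={fo}, "
                    f"child={co}) admits no configuration; Mendelian-inconsistent "
                    f"triads should be masked before likelihood evaluation")
            masks.append(mask)
            counts.append(pats[key])
            sexes.append(is_girl)

        sexes = np.array(sexes, dtype=bool) if sexes else np.zeros(0, dtype=bool)
        self.pattern_masks_girl = (np.array([mk for mk, s in zip(masks, sexes) if s])
                                   .reshape(-1, self.k ** 3))
        self.pattern_counts_girl = np.array(
            [ct for ct, s in zip(counts, sexes) if s], dtype=float)
        self.pattern_masks_boy = (np.array([mk for mk, s in zip(masks, sexes) if not s])
                                  .reshape(-1, self.k ** 3))
        self.pattern_counts_boy = np.array(
            [ct for ct, s in zip(counts, sexes) if not s], dtype=float)
        self.n_girls = float(self.pattern_counts_girl.sum())
        self.n_boys = float(self.pattern_counts_boy.sum())
        self.n_triads_used = int(self.n_girls + self.n_boys)

    # -- evaluation ---------------------------------------------------------

    def _sex_weights(self, pi, log_rrm, log_rrf, sex: str) -> np.ndarray:
        log_pi = np.log(pi)
        log_w = log_pi[self.mt] + log_pi[self.mu] + log_pi[self.f]
        if sex == FEMALE:
            log_w = log_w + log_rrm[self.mt] + log_rrf[self.f]
        elif self.model == X_INACTIVATION:
            log_w = log_w + log_rrm[self.mt] + log_rrf[self.mt]
        else:  # no_x_inactivation
            log_w = log_w + log_rrm[self.mt]
        return np.exp(log_w)

    def loglik(self, pi: np.ndarray, log_rrm: np.ndarray, log_rrf: np.ndarray) -> float:
        total = 0.0
        if self.n_girls:
            w = self._sex_weights(pi, log_rrm, log_rrf, FEMALE)
            r = self.pattern_masks_girl @ w
            total += float(self.pattern_counts_girl @ np.log(r)
                           - self.n_girls * np.log(w.sum()))
        if self.n_boys:
            w = self._sex_weights(pi, log_rrm, log_rrf, MALE)
            r = self.pattern_masks_boy @ w
            total += float(self.pattern_counts_boy @ np.log(r)
                           - self.n_boys * np.log(w.sum()))
        return total

    def loglik_grad(self, pi, log_rrm, log_rrf, free_haps: np.ndarray
                    ) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
        """Log-likelihood and its gradient w.r.t. (frequency logits of
        ``free_logit_haps`` = all haplotypes but the softmax baseline,
        log RRm and log RRf of ``free_haps``).

        The frequency-logit gradient is returned for all K haplotypes as
        d loglik / d gamma_a with softmax parameterization; the caller selects
        its free components. Chain rule: d log w_j / d gamma_a =
        count_j(a) - 3 pi_a.
        """
        g_gamma = np.zeros(self.k)
        g_rrm = np.zeros(self.k)
        g_rrf = np.zeros(self.k)
        total = 0.0

        for sex, masks, counts, n_sex in (
                (FEMALE, self.pattern_masks_girl, self.pattern_counts_girl, self.n_girls),
                (MALE, self.pattern_masks_boy, self.pattern_counts_boy, self.n_boys)):
            if not n_sex:
                continue
            w = self._sex_weights(pi, log_rrm, log_rrf, sex)
            r = masks @ w
            total += float(counts @ np.log(r) - n_sex * np.log(w.sum()))
            # expected weight allocation: sum_p n_p * (w restricted to S_p)/r_p
            # minus n_sex * w / sum(w); gradients are its products with the
            # per-config design columns
            post = (masks * (counts / r)[:, None]).sum(axis=0) * w \
                - n_sex * w / w.sum()
            g_gamma += post @ self.hap_count - 3.0 * post.sum() * pi
            if sex == FEMALE:
                np.add.at(g_rrm, self.mt, post)
                np.add.at(g_rrf, self.f, post)
            elif self.model == X_INACTIVATION:
                np.add.at(g_rrm, self.mt, post)
                np.add.at(g_rrf, self.mt, post)
            else:
                np.add.at(g_rrm, self.mt, post)
        return total, g_gamma, g_rrm[free_haps], g_rrf[free_haps]


def observed_loglik(dataset: TriadDataset, window: Sequence[int],
                    params: RiskParams, model: str) -> float:
    """Sum over triads of the log marginal conditional probability of their
    observed window genotypes, marginalizing missing members and phase."""
    engine = WindowLikelihood(dataset, window, model)
    return engine.loglik(params.hap_freqs, params.log_rrm, params.log_rrf)
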