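"""Chromosome scans: sliding windows, q-value FDR, Manhattan-ready output.

A scan fits every consecutive window of 1-4 SNPs along the map with one
constraint model and one sex restriction, attaches Storey q-values to the
window-level parent-of-origin p-values, and emits one tabular row per window
with the relative-risk estimates, Mendelian-error count and Hardy-Weinberg p
of the leading SNP — the columns a results table or Manhattan plot needs.
Windows that cannot be fitted (monomorphic, too few informative triads) are
reported with a status flag and excluded from the FDR family.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .estimation import FitError, FitResult, fit_window
from .model import GIRLS_ONLY, MODELS
from .triad_data import (TriadDataset, count_mendelian_errors, hwe_exact_test,
                         mother_genotype_counts)

MANHATTAN_CUTOFF = 1e-4  # reference line for the Manhattan output


@dataclass
class ScanRow:
    """One window of a scan, Manhattan- and results-table-ready."""

    window_snp_ids: str
    position: int
    model: str
    sex_restriction: str  # "all" or "females"
    status: str  # "ok" or the fit-failure reason
    window_p: float = float("nan")
    q_value: float = float("nan")
    best_haplotype: str = ""
    reference_haplotype: str = ""
    mendelian_errors: int = 0
    hwe_p: float = float("nan")
    neg_log10_p: float = float("nan")
    fit: FitResult | None = None

    def to_dict(self) -> dict:
        d = {
            "window_snp_ids": self.window_snp_ids,
            "position": self.position,
            "model": self.model,
            "sex_restriction": self.sex_restriction,
            "status": self.status,
            "window_p": self.window_p,
            "q_value": self.q_value,
            "neg_log10_p": self.neg_log10_p,
            "best_haplotype": self.best_haplotype,
            "reference_haplotype": self.reference_haplotype,
            "mendelian_errors": self.mendelian_errors,
            "hwe_p": self.hwe_p,
        }
        if self.fit is not None and len(self.fit.haplotypes):
            best = self.fit.haplotypes.sort_values(["rrr_p", "label"]).iloc[0]
            for col in ("rrm", "rrm_lo", "rrm_hi", "rrm_p",
                        "rrf", "rrf_lo", "rrf_hi", "rrf_p",
                        "rrr", "rrr_lo", "rrr_hi", "rrr_p"):
                d[col] = float(best[col])
        else:
            for col in ("rrm", "rrm_lo", "rrm_hi", "rrm_p",
                        "rrf", "rrf_lo", "rrf_hi", "rrf_p",
                        "rrr", "rrr_lo", "rrr_hi", "rrr_p"):
                d[col] = float("nan")
        return d


def sliding_windows(n_snps: int, size: int) -> list[list[int]]:
    """All consecutive index windows of the given size, in map order."""
    if not 1 <= size <= 4:
        raise ValueError("window size must be in 1..4")
    if size > n_snps:
        raise ValueError(f"window size {size} exceeds {n_snps} SNPs")
    return [list(range(i, i + size)) for i in range(n_snps - size + 1)]


def _smoothing_spline_df3(x: np.ndarray, y: np.ndarray) -> "object":
    """Natural cubic smoothing spline with effective degrees of freedom 3.

    The penalty weight is found by bisection so that the trace of the linear
    smoother matrix (its effective df) equals 3, matching the conventional
    df=3 spline smoother used for pi0 estimation.
    """
    from scipy.interpolate import make_smoothing_spline

    key = tuple(np.round(x, 12))
    lam = _DF3_PENALTY_CACHE.get(key)
    if lam is None:
        def trace(lam: float) -> float:
            return sum(
                make_smoothing_spline(x, np.eye(len(x))[j], lam=lam)(x[j])
                for j in range(len(x)))

        lo, hi = 1e-8, 1e4  # df decreases with the penalty; bisect on trace
        for _ in range(50):
            mid = np.sqrt(lo * hi)
            if trace(mid) > 3.0:
                lo = mid
            else:
                hi = mid
        lam = np.sqrt(lo * hi)
        _DF3_PENALTY_CACHE[key] = lam
    return make_smoothing_spline(x, y, lam=lam)


_DF3_PENALTY_CACHE: dict = {}


def qvalues(pvals: Sequence[float]) -> np.ndarray:
    """Storey q-values.

    pi0 is estimated on the lambda grid 0.05..0.95 (step 0.05) with a cubic
    spline smoother (df = 3) evaluated at lambda = 0.95 and clamped to
    (0, 1]; for fewer than 100 p-values the conservative pi0 = 1 is used.
    q_(i) is the step-down minimum of pi0 * m * p_(j) / j over j >= i.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("need a non-empty 1-D p-value vector")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    pi0 = 1.0
    if m >= 100:
        lams = np.arange(0.05, 0.96, 0.05)
        pi0_lam = np.array([(p > lam).mean() / (1 - lam) for lam in lams])
        spline = _smoothing_spline_df3(lams, pi0_lam)
        pi0 = float(spline(0.95))
        pi0 = min(max(pi0, 1.0 / m), 1.0)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * pi0 * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def best_haplotype(fit: FitResult) -> str:
    """Label of the non-reference haplotype with the smallest RRR p-value;
    ties break lexicographically."""
    if fit.haplotypes.empty:
        raise ValueError("fit has no non-reference haplotypes")
    ordered = fit.haplotypes.sort_values(["rrr_p", "label"], na_position="last")
    return str(ordered.iloc[0]["label"])


def run_scan(dataset: TriadDataset, model: str, window_size: int = 1,
             sex_restriction: str = "all", min_informative: int = 10,
             seed_for_restarts: int | None = None) -> list[ScanRow]:
    """Fit every sliding window and attach q-values over the retained rows."""
    if dataset.n_triads == 0 or dataset.n_snps == 0:
        raise ValueError("empty dataset")
    if sex_restriction not in ("all", "females"):
        raise ValueError("sex_restriction must be 'all' or 'females'")
    if sex_restriction == "females":
        model = GIRLS_ONLY
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    if model == GIRLS_ONLY:
        sex_restriction = "females"

    mendel = [count_mendelian_errors(dataset, j) for j in range(dataset.n_snps)]
    hwe = [hwe_exact_test(mother_genotype_counts(dataset, j))
           if sum(mother_genotype_counts(dataset, j)) else float("nan")
           for j in range(dataset.n_snps)]

    rows: list[ScanRow] = []
    for window in sliding_windows(dataset.n_snps, window_size):
        lead = window[0]
        snp_ids = "-".join(dataset.snps[j].snp_id for j in window)
        row = ScanRow(
            window_snp_ids=snp_ids,
            position=dataset.snps[lead].position,
            model=model, sex_restriction=sex_restriction, status="ok",
            mendelian_errors=int(sum(mendel[j] for j in window)),
            hwe_p=hwe[lead])
        try:
            fit = fit_window(dataset, window, model,
                             min_informative=min_informative,
                             seed_for_restarts=seed_for_restarts)
            row.fit = fit
            row.window_p = fit.window_p
            row.neg_log10_p = float(-np.log10(fit.window_p)) if fit.window_p > 0 \
                else float("inf")
            row.best_haplotype = best_haplotype(fit)
            from .model import hap_label
            row.reference_haplotype = hap_label(fit.reference, len(window))
        except FitError as e:
            row.status = str(e)
        rows.append(row)

    retained = [r for r in rows if r.status == "ok"]
    if retained:
        qs = qvalues([r.window_p for r in retained])
        for r, qv in zip(retained, qs):
            r.q_value = float(qv)
    return rows


def scan_frame(rows: Sequence[ScanRow]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in rows])


def manhattan_table(rows: Sequence[ScanRow]) -> pd.DataFrame:
    """Manhattan-ready columns in map order, with the reference-line constant
    attached as frame metadata (``attrs['cutoff']``)."""
    if not rows:
        raise ValueError("no scan rows")
    df = pd.DataFrame([{
        "position": r.position,
        "neg_log10_p": r.neg_log10_p,
        "model": r.model,
        "sex_restriction": r.sex_restriction,
    } for r in rows])
    df.attrs["cutoff"] = MANHATTAN_CUTOFF
    df.attrs["cutoff_neg_log10"] = float(-np.log10(MANHATTAN_CUTOFF))
    return df


def manhattan_plot(rows: Sequence[ScanRow], path: str | Path) -> None:
    """Optional cosmetic Manhattan plot (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = manhattan_table(rows)
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.scatter(df["position"], df["neg_log10_p"], s=8, color="#33557a")
    ax.axhline(df.attrs["cutoff_neg_log10"], color="red", lw=0.8, ls="--")
    ax.set_xlabel("position (bp)")
    ax.set_ylabel(r"$-\log_{10}(p)$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_scan(rows: Sequence[ScanRow], path: str | Path) -> None:
    scan_frame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_scan(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
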