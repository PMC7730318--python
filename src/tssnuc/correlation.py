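"""Position-wise Kendall rank correlation between nucleosome counts and an
expression covariate.

At every TSS-relative offset the per-gene site counts are correlated with
the covariate (S2-cell RPKM or breadth of expression) using Kendall's
tau-b.  Significance follows the classical normal approximation for tau
with mean zero and variance ``D = 2(2N + 5) / (9 N (N - 1))``, two-sided,
with a Bonferroni mask over the scanned offsets (default alpha 0.05 over
m = number of offsets, i.e. p < 0.05/500 for the default window).

The classical variance ignores ties.  Per-offset count vectors can be
heavily tied, which makes the approximation anti-conservative; a
tie-corrected alternative (``tie_corrected=True``) uses the exact
tie-adjusted variance of the concordance statistic instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import PositionCountMatrix, moving_mean

logger = logging.getLogger(__name__)


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> float:
    """Tie-corrected Kendall rank correlation (tau-b).

    ``tau = (C - D) / sqrt((P - Tx)(P - Ty))`` with C/D the concordant and
    discordant pair counts, ``P = n(n-1)/2`` and Tx/Ty the within-vector
    tied pair counts.  Returns NaN when either vector is entirely tied
    (tau is undefined there).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 2:
        raise ValueError("kendall_tau requires n >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    return float(stats.kendalltau(x, y).statistic)


def tau_variance(n: int) -> float:
    """Null variance of Kendall's tau under the normal approximation.

    ``D = 2 (2n + 5) / (9 n (n - 1))``; exact for tie-free data.
    """
    if n < 2:
        raise ValueError(f"sample size must be >= 2, got {n}")
    return 2.0 * (2.0 * n + 5.0) / (9.0 * n * (n - 1.0))


def _tie_corrected_z(x: np.ndarray, y: np.ndarray, tau: float) -> tuple[float, float]:
    """z and two-sided p for tau using the tie-adjusted variance of S."""
    res = stats.kendalltau(x, y, method="asymptotic")
    p = float(res.pvalue)
    z = float(np.sign(tau) * stats.norm.isf(p / 2.0)) if p > 0 else np.inf * np.sign(tau)
    return z, p


@dataclass
class CorrelationProfile:
    """Per-offset tau, z, p and Bonferroni mask for one (gene set, covariate,
    sensitivity) combination."""

    offsets: np.ndarray
    tau: np.ndarray
    z: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    smoothed_tau: np.ndarray
    n: int
    alpha: float = 0.05
    m: int = 500
    labels: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset": self.offsets,
                "tau": self.tau,
                "smoothed_tau": self.smoothed_tau,
                "z": self.z,
                "p": self.p,
                "significant": self.significant,
            }
        )

    def significant_runs(self, min_length: int = 1, sign: int = 0) -> list[tuple[int, int]]:
        """Maximal stretches of consecutive Bonferroni-significant offsets.

        ``sign`` restricts to runs of positive (+1) or negative (-1) tau;
        returns closed offset ranges ``(first, last)`` of length >= min_length.
        """
        ok = self.significant.copy()
        if sign:
            ok &= np.sign(np.nan_to_num(self.tau)) == sign
        runs, start = [], None
        for i, flag in enumerate(np.append(ok, False)):
            if flag and start is None:
                start = i
            elif not flag and start is not None:
                if i - start >= min_length:
                    runs.append((int(self.offsets[start]), int(self.offsets[i - 1])))
                start = None
        return runs


def scan(
    matrix: PositionCountMatrix,
    covariate: Sequence[float],
    alpha: float = 0.05,
    m: int | None = None,
    tie_corrected: bool = False,
    smooth_window: int = 3,
    labels: dict[str, str] | None = None,
) -> CorrelationProfile:
    """Correlate per-gene counts with a covariate at every offset.

    Offsets where tau is undefined (all genes tied in the count column, or
    a constant covariate) carry NaN and are never significant.
    """
    cov = np.asarray(covariate, dtype=float)
    n = matrix.n_genes
    if cov.shape != (n,):
        raise ValueError("covariate length must equal the gene count")
    if n < 2:
        raise ValueError("scan requires at least 2 genes")
    n_off = len(matrix.offsets)
    if m is None:
        m = n_off
    if m < 1:
        raise ValueError("m must be >= 1")
    tau = np.full(n_off, np.nan)
    z = np.full(n_off, np.nan)
    p = np.full(n_off, np.nan)
    sd = np.sqrt(tau_variance(n))
    cov_constant = bool(np.all(cov == cov[0]))
    for j in range(n_off):
        col = matrix.counts[:, j]
        if cov_constant or np.all(col == col[0]):
            continue
        t = float(stats.kendalltau(col, cov).statistic)
        tau[j] = t
        if tie_corrected:
            z[j], p[j] = _tie_corrected_z(col, cov, t)
        else:
            z[j] = t / sd
            p[j] = 2.0 * stats.norm.sf(abs(z[j]))
    significant = np.zeros(n_off, dtype=bool)
    defined = np.isfinite(p)
    significant[defined] = p[defined] < alpha / m
    return CorrelationProfile(
        offsets=matrix.offsets.copy(),
        tau=tau,
        z=z,
        p=p,
        significant=significant,
        smoothed_tau=moving_mean(tau, smooth_window) if np.isfinite(tau).any() else tau.copy(),
        n=n,
        alpha=alpha,
        m=m,
        labels=labels or {},
    )


#: covariate name -> (classification column holding its value, forbidden stratifier)
_COVARIATES = {"RPKM": ("rpkm_s2", "rpkm_class"), "BoE": ("boe", "boe_class")}


def scan_by_class(
    classification: pd.DataFrame,
    matrices: dict[str, PositionCountMatrix],
    covariate: str = "RPKM",
    stratifier: str = "boe_class",
    alpha: float = 0.05,
    m: int | None = None,
    tie_corrected: bool = False,
    min_genes: int = 2,
) -> list[CorrelationProfile]:
    """One correlation profile per chromatin class x stratum x sensitivity.

    ``classification`` is the per-gene table from
    :func:`tssnuc.classify.build_classification`; ``matrices`` maps
    sensitivity class to a full-gene-set count matrix.  The covariate must
    not be stratified along its own axis (e.g. RPKM within RPKM classes).
    Strata with fewer than ``min_genes`` genes are skipped with a warning.
    """
    if covariate not in _COVARIATES:
        raise ValueError(f"covariate must be one of {sorted(_COVARIATES)}")
    value_col, forbidden = _COVARIATES[covariate]
    if stratifier == forbidden:
        raise ValueError(f"covariate {covariate} cannot be stratified by {stratifier}")
    if stratifier not in ("rpkm_class", "boe_class"):
        raise ValueError("stratifier must be 'rpkm_class' or 'boe_class'")
    from .classify import BOE_CLASSES, CHROMATIN_CLASSES, RPKM_CLASSES

    strata = BOE_CLASSES if stratifier == "boe_class" else RPKM_CLASSES
    profiles: list[CorrelationProfile] = []
    for cc in CHROMATIN_CLASSES:
        for stratum in strata:
            sub = classification[
                (classification["chromatin_class"] == cc)
                & (classification[stratifier] == stratum)
            ]
            if len(sub) < min_genes:
                logger.warning(
                    "skipping stratum %s/%s: only %d gene(s)", cc, stratum, len(sub)
                )
                continue
            cov = sub[value_col].to_numpy(dtype=float)
            for sens, matrix in matrices.items():
                sub_matrix = matrix.subset(sub["gene_id"].tolist())
                profiles.append(
                    scan(
                        sub_matrix,
                        cov,
                        alpha=alpha,
                        m=m,
                        tie_corrected=tie_corrected,
                        labels={
                            "chromatin_class": cc,
                            "stratum": stratum,
                            "stratifier": stratifier,
                            "covariate": covariate,
                            "sensitivity": sens,
                        },
                    )
                )
    return profiles
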