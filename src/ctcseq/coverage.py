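"""The SNP-detectability-vs-expression heuristic.

Full-length chemistry spreads reads across whole transcripts, so the chance
that a given exonic site has any coverage in a cell is governed by the gene's
expression (FPKM) rather than by the site's position. The module quantifies
this: per-site detection fractions across cells, an ordinary least-squares
regression of detection fraction on log2 mean FPKM (with the FPKM at which
the fitted line crosses 50% detection), and a closed-form uniform-coverage
probability that serves as the analytic oracle for the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix
from .variants import VariantMatrix


class CoverageModelError(ValueError):
    pass


@dataclass
class DetectionRegressionResult:
    """OLS of per-site detection fraction on log2 mean FPKM.

    ``fpkm50`` is the expression level at which the fitted line predicts a
    50% chance of coverage: 2 ** ((0.5 - intercept) / slope); NaN (flagged
    undefined) when the slope is not positive.
    """

    slope: float
    intercept: float
    r_squared: float
    fpkm50: float
    n_sites: int
    n_excluded: int
    site_table: pd.DataFrame

    def summary(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r2": self.r_squared,
            "fpkm50": None if np.isnan(self.fpkm50) else self.fpkm50,
            "n_sites": self.n_sites,
            "n_excluded": self.n_excluded,
        }


def detection_fraction(variant_matrix: VariantMatrix, site) -> float:
    """Fraction of cells with coverage (depth >= min_depth) at one site."""
    if not variant_matrix.cells:
        raise CoverageModelError("variant matrix has no cells")
    i = variant_matrix.site_index(site)
    return float(variant_matrix.covered[i].mean())


def fit_detection_regression(
    variant_matrix: VariantMatrix,
    expression: ExpressionMatrix,
) -> DetectionRegressionResult:
    """Regress per-site detection fraction on log2 of the gene's mean FPKM.

    The x value per site is log2 of the gene's mean FPKM across all cells
    (zeros included in the mean); sites on the same gene share an x but stay
    separate points. Sites whose gene has zero mean FPKM are excluded and
    counted in ``n_excluded``.
    """
    mean_fpkm = expression.fpkm.mean(axis=1)
    rows = []
    n_excluded = 0
    for i, site in enumerate(variant_matrix.sites):
        mu = float(mean_fpkm.get(site.gene_id, 0.0))
        frac = float(variant_matrix.covered[i].mean())
        if mu <= 0:
            n_excluded += 1
            continue
        rows.append(
            {
                "gene": site.gene_id,
                "position": site.position,
                "mean_fpkm": mu,
                "log2_mean_fpkm": float(np.log2(mu)),
                "detection_fraction": frac,
            }
        )
    if len(rows) < 3:
        raise CoverageModelError(
            f"need >= 3 sites with positive mean FPKM, have {len(rows)}"
        )
    table = pd.DataFrame(rows)
    fit = stats.linregress(table["log2_mean_fpkm"], table["detection_fraction"])
    slope, intercept = float(fit.slope), float(fit.intercept)
    r2 = float(fit.rvalue**2)
    fpkm50 = float(2.0 ** ((0.5 - intercept) / slope)) if slope > 0 else float("nan")
    return DetectionRegressionResult(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        fpkm50=fpkm50,
        n_sites=len(table),
        n_excluded=n_excluded,
        site_table=table,
    )


def fit_detection_logistic(
    variant_matrix: VariantMatrix,
    expression: ExpressionMatrix,
):
    """Diagnostic logistic fit of detection on log2 mean FPKM.

    This bounded-response alternative is provided for model criticism only;
    the heuristic of record is the plain linear regression above.
    """
    from scipy.optimize import minimize

    mean_fpkm = expression.fpkm.mean(axis=1)
    xs, ks, ns = [], [], []
    n_cells = len(variant_matrix.cells)
    for i, site in enumerate(variant_matrix.sites):
        mu = float(mean_fpkm.get(site.gene_id, 0.0))
        if mu <= 0:
            continue
        xs.append(np.log2(mu))
        ks.append(int(variant_matrix.covered[i].sum()))
        ns.append(n_cells)
    x = np.asarray(xs)
    k = np.asarray(ks, dtype=float)
    n = np.asarray(ns, dtype=float)

    def nll(theta):
        a, b = theta
        p = 1.0 / (1.0 + np.exp(-(a + b * x)))
        p = np.clip(p, 1e-9, 1 - 1e-9)
        return -np.sum(k * np.log(p) + (n - k) * np.log(1 - p))

    res = minimize(nll, x0=np.array([0.0, 1.0]), method="Nelder-Mead")
    a, b = res.x
    fpkm50 = float(2.0 ** (-a / b)) if b > 0 else float("nan")
    return {"intercept": float(a), "slope": float(b), "fpkm50": fpkm50}


def analytic_coverage_probability(
    transcript_length: int,
    read_length: int,
    n_reads: int,
    position: int,
) -> float:
    """P(site covered by >= 1 of N uniformly placed single-end reads).

    With reads of length L starting uniformly on [0, T - L], the per-read
    probability of covering ``position`` is the number of start positions s
    with s <= position < s + L over T - L + 1; the site is covered unless all
    N reads miss: 1 - (1 - q) ** N.
    """
    T, L, N, p = transcript_length, read_length, n_reads, position
    if L > T:
        raise CoverageModelError("read_length exceeds transcript_length")
    if not (0 <= p < T):
        raise CoverageModelError("position outside transcript")
    if N < 0:
        raise CoverageModelError("n_reads must be >= 0")
    s_lo = max(0, p - L + 1)
    s_hi = min(p, T - L)
    q = max(0, s_hi - s_lo + 1) / (T - L + 1)
    return float(1.0 - (1.0 - q) ** N)
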