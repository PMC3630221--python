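"""Pooled-vs-individual concordance statistics.

Three complementary checks of whether the pooled approach reproduces
the individual-based estimates: (i) ordinary least squares of pooled
values (y) on individual values (x), asking whether the 95% CI of the
slope contains the beta = 1 expectation and how much variance is
shared (R^2); (ii) interpretation agreement — the fraction of cases
where both approaches agree on the qualitative zero / non-zero call
that drives conservation inference (diversity present? populations
differentiated?); and (iii) a two-sided Mann-Whitney rank test on
per-population SNP counts. Negative differentiation estimates are
classified as zero for interpretation, and an optional "non-zero only"
subset repeats the regression with exact-zero pairs removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    ci_low: float
    ci_high: float
    r_squared: float
    n: int

    @property
    def contains_unity(self) -> bool:
        """True when the slope CI contains the beta = 1 expectation."""
        return self.ci_low <= 1.0 <= self.ci_high

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "slope_se": self.slope_se,
            "ci": [self.ci_low, self.ci_high],
            "r_squared": self.r_squared,
            "n": self.n,
            "ci_contains_1": self.contains_unity,
        }


@dataclass(frozen=True)
class AgreementResult:
    n_cases: int
    n_agree: int
    n_disagree: int
    proportion: float
    zero_tol: float

    def to_dict(self) -> dict:
        return {
            "n_cases": self.n_cases,
            "n_agree": self.n_agree,
            "n_disagree": self.n_disagree,
            "proportion": self.proportion,
        }


@dataclass(frozen=True)
class RankTestResult:
    u: float
    p: float
    n1: int
    n2: int

    def to_dict(self) -> dict:
        return {"U": self.u, "p": self.p, "n1": self.n1, "n2": self.n2}


def ols_with_slope_ci(
    x: Sequence[float],
    y: Sequence[float],
    alpha: float = 0.05,
    exclude_zeros: bool = False,
    zero_tol: float = 1e-12,
) -> RegressionResult:
    """OLS of pooled (y) on individual (x) estimates with a slope CI.

    The CI uses the t distribution with n-2 degrees of freedom. With
    ``exclude_zeros`` the regression is refit on the subset of pairs
    where at least one approach reports a non-zero value (exact-zero
    pairs arise naturally from monomorphic pools).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if exclude_zeros:
        keep = ~((x <= zero_tol) & (y <= zero_tol))
        x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=alpha)
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        slope_se=float(model.bse[1]),
        intercept_se=float(model.bse[0]),
        ci_low=float(ci[1][0]),
        ci_high=float(ci[1][1]),
        r_squared=float(model.rsquared),
        n=int(x.size),
    )


def interpretation_agreement(
    pairs: Sequence[tuple[float, float]], zero_tol: float = 1e-12
) -> AgreementResult:
    """Count zero / non-zero interpretation conflicts between approaches.

    A case disagrees iff exactly one of the two values is zero (at
    tolerance ``zero_tol``; negative estimates count as zero). The
    result is symmetric in the two approaches.
    """
    if not pairs:
        raise ValueError("pairs must be non-empty")
    n_disagree = 0
    for a, b in pairs:
        za = max(a, 0.0) <= zero_tol
        zb = max(b, 0.0) <= zero_tol
        if za != zb:
            n_disagree += 1
    n = len(pairs)
    return AgreementResult(
        n_cases=n,
        n_agree=n - n_disagree,
        n_disagree=n_disagree,
        proportion=(n - n_disagree) / n,
        zero_tol=zero_tol,
    )


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> RankTestResult:
    """Two-sided Mann-Whitney U for the first group.

    U from rank sums with midranks for ties; p from the normal
    approximation with tie-corrected variance and continuity
    correction. Two identical constant groups have no rank information
    and report p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.ptp(np.concatenate([a, b])) == 0:
        return RankTestResult(u=a.size * b.size / 2.0, p=1.0, n1=a.size, n2=b.size)
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return RankTestResult(
        u=float(res.statistic), p=float(res.pvalue), n1=int(a.size), n2=int(b.size)
    )


def fst_pairs(fst: np.ndarray) -> list[float]:
    """The upper-triangle F_ST values (n*(n-1)/2 unordered pool pairs)."""
    iu = np.triu_indices(fst.shape[0], k=1)
    return [float(v) for v in fst[iu]]


@dataclass(frozen=True)
class ConcordanceReport:
    """Full comparison of the pooled approach against the individual one."""

    pi_regression: RegressionResult
    fst_regression: RegressionResult
    pi_agreement: AgreementResult
    fst_agreement: AgreementResult
    snp_rank_test: RankTestResult | None = None

    def to_dict(self) -> dict:
        out = {
            "pi_regression": self.pi_regression.to_dict(),
            "fst_regression": self.fst_regression.to_dict(),
            "pi_agreement": self.pi_agreement.to_dict(),
            "fst_agreement": self.fst_agreement.to_dict(),
        }
        if self.snp_rank_test is not None:
            out["snp_rank_test"] = self.snp_rank_test.to_dict()
        return out


def compare_estimates(
    pi_individual: Sequence[float],
    pi_pooled: Sequence[float],
    fst_individual: np.ndarray,
    fst_pooled: np.ndarray,
    snp_counts_individual: Sequence[int] | None = None,
    snp_counts_pooled: Sequence[int] | None = None,
    zero_tol: float = 1e-12,
) -> ConcordanceReport:
    """Regression, agreement, and rank-test comparison of two runs.

    Individual-approach values are the x axis throughout.
    """
    fst_i = fst_pairs(np.asarray(fst_individual))
    fst_p = fst_pairs(np.asarray(fst_pooled))
    rank = None
    if snp_counts_individual is not None and snp_counts_pooled is not None:
        rank = mann_whitney_u(snp_counts_individual, snp_counts_pooled)
    return ConcordanceReport(
        pi_regression=ols_with_slope_ci(pi_individual, pi_pooled),
        fst_regression=ols_with_slope_ci(fst_i, fst_p),
        pi_agreement=interpretation_agreement(
            list(zip(pi_individual, pi_pooled)), zero_tol
        ),
        fst_agreement=interpretation_agreement(list(zip(fst_i, fst_p)), zero_tol),
        snp_rank_test=rank,
    )


def plot_concordance(x, y, path, xlabel="individual", ylabel="pooled", title=""):
    """Scatter of pooled vs individual estimates with the y = x line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(x, y, s=18, alpha=0.7)
    lim = max(max(x, default=1), max(y, default=1)) * 1.05 or 1.0
    ax.plot([0, lim], [0, lim], ls=":", color="grey", label="beta = 1")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
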