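"""Disproportionality statistics for 2x2 drug-event contingency tables.

Four signal-detection statistics standard in pharmacovigilance are provided,
each with its conventional interval and signal criterion:

* ROR — reporting odds ratio ``ad/(bc)`` with a Wald CI on the log scale;
  signal when the lower 95% bound exceeds 1 and a >= 3.
* PRR — proportional reporting ratio ``(a/(a+b)) / (c/(c+d))`` with its Wald
  CI and the Pearson chi-square of the table; signal when PRR >= 2,
  chi2 >= 4 and a >= 3.
* IC — the Bayesian confidence propagation neural network information
  component ``log2((a + 0.5)/(E + 0.5))`` with E = (a+b)(a+c)/N, using the
  Noren closed-form approximation to the credible interval; signal when
  IC025 > 0.
* EBGM — DuMouchel's multi-item gamma-Poisson shrinker: a_i ~ Poisson(lambda_i
  E_i) with lambda_i drawn from a two-component gamma mixture prior fitted by
  maximum marginal likelihood across all pairs; EBGM is the posterior
  geometric mean of lambda and EB05 its 5th percentile; signal when
  EB05 > 2.

Zero cells make ROR/PRR undefined; estimates are then returned with a
machine-readable reason instead of a silent continuity correction (an
explicit Haldane-Anscombe +0.5 mode is available).  A drug-event pair is
called a consensus signal when at least one method's criterion is met.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, special, stats as sps

from .smq import PairCounts, SmqCounts
from .ingest import normalize_drug_name, normalize_pt

__all__ = [
    "ContingencyTable",
    "SignalEstimate",
    "SignalThresholds",
    "MgpsPrior",
    "SignalDecision",
    "build_contingency",
    "contingency_from_totals",
    "ror_estimate",
    "prr_estimate",
    "ic_estimate",
    "pearson_chi2",
    "pvalue_2x2",
    "bonferroni",
    "fit_mgps_prior",
    "ebgm_estimate",
    "evaluate_signal",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Counts (a, b, c, d) of one drug-event pair against the background.

    a: target drug & target event; b: target drug, other events; c: other
    drugs, target event; d: other drugs, other events.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.n_total <= 0:
            raise ValueError("contingency table must contain at least one report")

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def drug_total(self) -> int:
        return self.a + self.b

    @property
    def event_total(self) -> int:
        return self.a + self.c

    @property
    def expected(self) -> float:
        """Expected count E = (a+b)(a+c)/N under row-column independence."""
        return self.drug_total * self.event_total / self.n_total

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


def contingency_from_totals(
    a: int, drug_total: int, event_total: int, grand_total: int
) -> ContingencyTable:
    """Build the 2x2 table from a count and the three marginal totals."""
    b = drug_total - a
    c = event_total - a
    d = grand_total - drug_total - event_total + a
    if min(b, c, d) < 0:
        raise ValueError(
            f"inconsistent totals: a={a}, drug_total={drug_total}, "
            f"event_total={event_total}, grand_total={grand_total}"
        )
    return ContingencyTable(a=a, b=b, c=c, d=d)


def build_contingency(
    pair_counts: PairCounts | SmqCounts, drug: str, event: str | None = None
) -> ContingencyTable:
    """Build a 2x2 table for ``(drug, event)`` from pair-count statistics.

    ``pair_counts`` may be PT-level sufficient statistics (``event`` names the
    member PT) or already-aggregated group-level counts.
    """
    if normalize_drug_name(drug) != pair_counts.drug:
        raise ValueError(
            f"pair counts are for {pair_counts.drug!r}, not {drug!r}"
        )
    if isinstance(pair_counts, SmqCounts):
        return contingency_from_totals(
            pair_counts.a,
            pair_counts.drug_total,
            pair_counts.event_total,
            pair_counts.grand_total,
        )
    if event is None:
        raise ValueError("event PT required for PT-level pair counts")
    pt = normalize_pt(event)
    if pt not in pair_counts.pt_a:
        raise ValueError(f"PT {pt!r} not among counted member PTs")
    return contingency_from_totals(
        pair_counts.pt_a[pt],
        pair_counts.drug_total,
        pair_counts.event_totals[pt],
        pair_counts.grand_total,
    )


@dataclass(frozen=True)
class SignalThresholds:
    """Signal criteria, exposed for configuration.

    Defaults follow pharmacovigilance convention: ROR lower bound > 1 with
    a >= 3; PRR >= 2 with chi2 >= 4 and a >= 3; IC025 > 0; EB05 > 2.
    """

    min_a: int = 3
    ror_ci_low: float = 1.0
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ic025_min: float = 0.0
    ebgm05_min: float = 2.0


DEFAULT_THRESHOLDS = SignalThresholds()


@dataclass(frozen=True)
class SignalEstimate:
    """One method's point estimate, interval and signal flag for one pair."""

    method: str
    point: float
    interval_low: float
    interval_high: float
    a_count: int
    is_signal: bool
    chi2: float | None = None
    p_value: float | None = None
    p_adjusted: float | None = None
    undefined_reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.undefined_reason is None

    def with_pvalues(self, p: float, p_adj: float | None = None) -> "SignalEstimate":
        return replace(self, p_value=p, p_adjusted=p_adj)


def _undefined(method: str, a_count: int, reason: str) -> SignalEstimate:
    return SignalEstimate(
        method=method,
        point=math.nan,
        interval_low=math.nan,
        interval_high=math.nan,
        a_count=a_count,
        is_signal=False,
        undefined_reason=reason,
    )


def ror_estimate(
    table: ContingencyTable,
    z: float = 1.96,
    continuity: bool = False,
    thresholds: SignalThresholds = DEFAULT_THRESHOLDS,
) -> SignalEstimate:
    """Reporting odds ratio ad/(bc) with a Wald CI on the log scale.

    The CI is exp(ln ROR +/- z sqrt(1/a + 1/b + 1/c + 1/d)), so the point is
    the geometric mean of the bounds.  With any zero cell the estimate is
    undefined unless ``continuity=True`` adds Haldane-Anscombe +0.5 to every
    cell.
    """
    a, b, c, d = (float(x) for x in table.cells())
    if continuity:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if min(a, b, c, d) <= 0:
        return _undefined("ROR", table.a, "zero cell in 2x2 table")
    point = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    low = point * math.exp(-z * se)
    high = point * math.exp(z * se)
    return SignalEstimate(
        method="ROR",
        point=point,
        interval_low=low,
        interval_high=high,
        a_count=table.a,
        is_signal=(low > thresholds.ror_ci_low and table.a >= thresholds.min_a),
    )


def pearson_chi2(table: ContingencyTable, yates: bool = False) -> float:
    """Pearson chi-square of the 2x2 table, N(ad-bc)^2 / product of margins.

    No continuity correction by default (the PRR chi2 >= 4 criterion is
    stated for the uncorrected statistic); ``yates=True`` applies Yates'
    correction.  Returns 0 for degenerate tables with an empty margin.
    """
    a, b, c, d = (float(x) for x in table.cells())
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2.0, 0.0)
    return n * diff * diff / denom


def prr_estimate(
    table: ContingencyTable,
    z: float = 1.96,
    yates: bool = False,
    thresholds: SignalThresholds = DEFAULT_THRESHOLDS,
) -> SignalEstimate:
    """Proportional reporting ratio with Wald CI and Pearson chi-square.

    PRR = (a/(a+b)) / (c/(c+d)); SE of ln PRR is
    sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d)).  Undefined when a = 0 or the
    background column is empty.
    """
    a, b, c, d = (float(x) for x in table.cells())
    if a == 0:
        return _undefined("PRR", table.a, "a = 0")
    if a + b == 0 or c + d == 0 or c == 0:
        return _undefined("PRR", table.a, "empty margin or zero background count")
    point = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    low = point * math.exp(-z * se)
    high = point * math.exp(z * se)
    chi2 = pearson_chi2(table, yates=yates)
    return SignalEstimate(
        method="PRR",
        point=point,
        interval_low=low,
        interval_high=high,
        a_count=table.a,
        is_signal=(
            point >= thresholds.prr_min
            and chi2 >= thresholds.chi2_min
            and table.a >= thresholds.min_a
        ),
        chi2=chi2,
    )


def ic_estimate(
    table: ContingencyTable, thresholds: SignalThresholds = DEFAULT_THRESHOLDS
) -> SignalEstimate:
    """BCPNN information component with the Noren credible-interval form.

    IC = log2((a + 0.5)/(E + 0.5)) with E = (a+b)(a+c)/N.  The 2.5th and
    97.5th credibility bounds use the closed-form approximation
    IC025 = IC - 3.3 (a+0.5)^-1/2 - 2.0 (a+0.5)^-3/2 and
    IC975 = IC + 2.4 (a+0.5)^-1/2 + 0.5 (a+0.5)^-3/2.  Defined for a = 0.
    """
    a = float(table.a)
    e = table.expected
    point = math.log2((a + 0.5) / (e + 0.5))
    s = a + 0.5
    low = point - 3.3 * s ** -0.5 - 2.0 * s ** -1.5
    high = point + 2.4 * s ** -0.5 + 0.5 * s ** -1.5
    return SignalEstimate(
        method="IC",
        point=point,
        interval_low=low,
        interval_high=high,
        a_count=table.a,
        is_signal=low > thresholds.ic025_min,
    )


def pvalue_2x2(table: ContingencyTable, yates: bool = False) -> float:
    """Two-sided p-value for association in the 2x2 table.

    Pearson chi-square (df = 1, no continuity correction by default) when all
    expected cells are >= 5; otherwise the two-sided Fisher exact test.
    """
    a, b, c, d = (float(x) for x in table.cells())
    n = a + b + c + d
    rows = (a + b, c + d)
    cols = (a + c, b + d)
    expected = [r * k / n for r in rows for k in cols]
    if min(expected) >= 5:
        chi2 = pearson_chi2(table, yates=yates)
        return float(sps.chi2.sf(chi2, df=1))
    return float(sps.fisher_exact([[table.a, table.b], [table.c, table.d]])[1])


def bonferroni(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment p_adj = min(1, m p); order-preserving.

    ``m`` defaults to the number of p-values and must be at least that many.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"m = {m} is smaller than the number of tests ({p.size})")
    return np.minimum(1.0, m * p)


# ---------------------------------------------------------------------------
# MGPS: gamma-Poisson shrinker
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MgpsPrior:
    """Five-parameter gamma-mixture prior of the gamma-Poisson shrinker.

    lambda ~ w Gamma(alpha1, beta1) + (1-w) Gamma(alpha2, beta2) with
    shape/rate parameterisation; the marginal of each observed count is then
    a two-component negative-binomial mixture.
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    w: float
    log_marginal_likelihood: float = math.nan

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma parameters must be strictly positive")
        if not (0.0 < self.w < 1.0):
            raise ValueError("mixture weight must lie strictly in (0, 1)")


def _nb_logpmf(a: np.ndarray, alpha: float, beta: float, e: np.ndarray) -> np.ndarray:
    """log pmf of the Poisson-gamma marginal (negative binomial)."""
    return (
        special.gammaln(alpha + a)
        - special.gammaln(alpha)
        - special.gammaln(a + 1.0)
        + alpha * (np.log(beta) - np.log(beta + e))
        + a * (np.log(e) - np.log(beta + e))
    )


def mixture_log_marginal(
    a: np.ndarray, e: np.ndarray, prior: MgpsPrior
) -> np.ndarray:
    """Per-pair log marginal likelihood under the mixture prior."""
    a = np.asarray(a, dtype=float)
    e = np.asarray(e, dtype=float)
    l1 = np.log(prior.w) + _nb_logpmf(a, prior.alpha1, prior.beta1, e)
    l2 = np.log1p(-prior.w) + _nb_logpmf(a, prior.alpha2, prior.beta2, e)
    return np.logaddexp(l1, l2)


# Fixed multi-start list on the natural scale (alpha1, beta1, alpha2, beta2, w).
# The first entry is DuMouchel's canonical starting point.
_MGPS_STARTS = (
    (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0),
    (1.0, 1.0, 1.0, 2.0, 0.5),
    (0.5, 0.5, 5.0, 5.0, 0.2),
    (2.0, 2.0, 0.2, 0.2, 0.8),
    (1.0, 0.5, 3.0, 1.0, 0.3),
)

_W_EPS = 1e-6


def _theta_to_params(theta: np.ndarray) -> tuple[float, float, float, float, float]:
    a1, b1, a2, b2 = np.exp(np.clip(theta[:4], -30.0, 30.0))
    w = special.expit(np.clip(theta[4], -30.0, 30.0))
    return float(a1), float(b1), float(a2), float(b2), float(w)


def fit_mgps_prior(
    tables: Iterable[ContingencyTable],
    starts: Sequence[tuple[float, float, float, float, float]] = _MGPS_STARTS,
    tol: float = 1e-8,
    single_component: bool = False,
) -> MgpsPrior:
    """Fit the gamma-mixture prior by maximum marginal likelihood.

    Observed counts a_i with baseline expectations E_i = (a+b)(a+c)/N are
    modelled as a_i ~ Poisson(lambda_i E_i) with the mixture prior on
    lambda_i, giving a negative-binomial mixture marginal.  Optimisation is
    quasi-Newton (L-BFGS-B) on log-transformed parameters (logit for w) from
    a fixed list of starting points, hence deterministic given data.  Pairs
    with E_i = 0 carry no information and are dropped; fewer than two usable
    pairs, or failure from every start, is an error.

    ``single_component=True`` restricts the prior to one gamma (useful when
    the mixture is weakly identified); the result carries two identical
    components with w = 0.5, so the downstream posterior is unchanged.
    """
    tables = list(tables)
    a = np.array([t.a for t in tables], dtype=float)
    e = np.array([t.expected for t in tables], dtype=float)
    keep = e > 0
    a, e = a[keep], e[keep]
    if a.size < 2:
        raise ValueError("need at least two drug-event pairs with positive E")

    if single_component:
        def negloglik1(theta: np.ndarray) -> float:
            alpha, beta = np.exp(np.clip(theta, -30.0, 30.0))
            return -float(_nb_logpmf(a, float(alpha), float(beta), e).sum())

        best1 = None
        for s0 in ((0.2, 0.1), (1.0, 1.0), (2.0, 2.0), (0.5, 2.0), (5.0, 1.0)):
            res = optimize.minimize(
                negloglik1,
                np.log(np.array(s0)),
                method="L-BFGS-B",
                options={"ftol": tol, "gtol": 1e-10, "maxiter": 2000},
            )
            if best1 is None or res.fun < best1.fun:
                best1 = res
        if best1 is None or not np.isfinite(best1.fun):
            raise RuntimeError("single-component MGPS prior fit failed")
        alpha, beta = (float(x) for x in np.exp(best1.x))
        return MgpsPrior(
            alpha1=alpha, beta1=beta, alpha2=alpha, beta2=beta, w=0.5,
            log_marginal_likelihood=-float(best1.fun),
        )

    def negloglik(theta: np.ndarray) -> float:
        a1, b1, a2, b2, w = _theta_to_params(theta)
        w = min(max(w, _W_EPS), 1.0 - _W_EPS)
        l1 = np.log(w) + _nb_logpmf(a, a1, b1, e)
        l2 = np.log1p(-w) + _nb_logpmf(a, a2, b2, e)
        return -float(np.logaddexp(l1, l2).sum())

    best: optimize.OptimizeResult | None = None
    failures: list[str] = []
    for start in starts:
        theta0 = np.array(
            [math.log(start[0]), math.log(start[1]), math.log(start[2]),
             math.log(start[3]), special.logit(start[4])]
        )
        res = optimize.minimize(
            negloglik,
            theta0,
            method="L-BFGS-B",
            options={"ftol": tol, "gtol": 1e-10, "maxiter": 2000},
        )
        if not res.success and not np.isfinite(res.fun):
            failures.append(f"start {start}: {res.message}")
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(
            "MGPS prior fit failed from every start:\n" + "\n".join(failures)
        )

    a1, b1, a2, b2, w = _theta_to_params(best.x)
    if w <= _W_EPS or w >= 1.0 - _W_EPS:
        warnings.warn(
            "MGPS mixture weight at boundary; clipped into (1e-6, 1-1e-6)",
            stacklevel=2,
        )
        w = min(max(w, _W_EPS), 1.0 - _W_EPS)
    # canonical component order: ascending prior component mean
    if a1 / b1 > a2 / b2:
        a1, b1, a2, b2, w = a2, b2, a1, b1, 1.0 - w
        w = min(max(w, _W_EPS), 1.0 - _W_EPS)
    return MgpsPrior(
        alpha1=a1,
        beta1=b1,
        alpha2=a2,
        beta2=b2,
        w=w,
        log_marginal_likelihood=-float(best.fun),
    )


def _posterior_mixture(
    table: ContingencyTable, prior: MgpsPrior
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Posterior over lambda: weights, shapes, rates of the gamma mixture."""
    a = float(table.a)
    e = table.expected
    if e <= 0:
        raise ValueError("EBGM requires positive expected count E")
    logq = np.array(
        [
            math.log(prior.w) + float(_nb_logpmf(np.array(a), prior.alpha1, prior.beta1, np.array(e))),
            math.log1p(-prior.w) + float(_nb_logpmf(np.array(a), prior.alpha2, prior.beta2, np.array(e))),
        ]
    )
    logq -= special.logsumexp(logq)
    q = np.exp(logq)
    shapes = np.array([prior.alpha1 + a, prior.alpha2 + a])
    rates = np.array([prior.beta1 + e, prior.beta2 + e])
    return q, shapes, rates


def _mixture_gamma_cdf(x: float, q: np.ndarray, shapes: np.ndarray, rates: np.ndarray) -> float:
    return float(np.sum(q * special.gammainc(shapes, rates * x)))


def _mixture_gamma_ppf(
    p: float, q: np.ndarray, shapes: np.ndarray, rates: np.ndarray
) -> float:
    mean = float(np.sum(q * shapes / rates))
    var = float(np.sum(q * (shapes / rates**2 + (shapes / rates) ** 2)) - mean**2)
    hi = mean + 10.0 * math.sqrt(max(var, 0.0)) + 1e-9
    while _mixture_gamma_cdf(hi, q, shapes, rates) < p:
        hi *= 2.0
    return float(
        optimize.brentq(
            lambda x: _mixture_gamma_cdf(x, q, shapes, rates) - p,
            0.0,
            hi,
            xtol=1e-12,
            maxiter=500,
        )
    )


def ebgm_estimate(
    table: ContingencyTable,
    prior: MgpsPrior,
    thresholds: SignalThresholds = DEFAULT_THRESHOLDS,
) -> SignalEstimate:
    """Empirical Bayes geometric mean and its 5th/95th posterior percentiles.

    The posterior over lambda is a two-component gamma mixture with
    components Gamma(alpha_j + a, beta_j + E) and data-updated weights.
    EBGM = exp(E[ln lambda | data]) (equivalently 2^E[log2 lambda]); EB05 and
    EB95 are found by bisection on the mixture CDF.
    """
    q, shapes, rates = _posterior_mixture(table, prior)
    e_log_lambda = float(np.sum(q * (special.digamma(shapes) - np.log(rates))))
    point = math.exp(e_log_lambda)
    low = _mixture_gamma_ppf(0.05, q, shapes, rates)
    high = _mixture_gamma_ppf(0.95, q, shapes, rates)
    return SignalEstimate(
        method="EBGM",
        point=point,
        interval_low=low,
        interval_high=high,
        a_count=table.a,
        is_signal=low > thresholds.ebgm05_min,
    )


@dataclass(frozen=True)
class SignalDecision:
    """Per-method signal flags plus the at-least-one-method consensus."""

    consensus: bool
    flags: dict[str, bool]


def evaluate_signal(estimates: Iterable[SignalEstimate]) -> SignalDecision:
    """Consensus = OR over per-method flags; a pair with a = 0 never signals."""
    estimates = list(estimates)
    if not estimates:
        raise ValueError("at least one method estimate required")
    flags = {est.method: bool(est.defined and est.is_signal) for est in estimates}
    a_count = max(est.a_count for est in estimates)
    consensus = a_count > 0 and any(flags.values())
    return SignalDecision(consensus=consensus, flags=flags)
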