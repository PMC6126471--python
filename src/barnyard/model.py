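"""Closed-form Poisson model of droplet loading in two-type cell-mixing experiments.

A "barnyard" experiment mixes two distinguishable cell types (classically human
and mouse) before partitioning cells into barcoded droplets or wells.  After
sequencing, every non-empty partition is classified as containing at least one
cell of type 1, at least one cell of type 2, or cells of both types; the three
observed counts are ``N1``, ``N2`` and ``N12``.  **Counting convention:** ``N1``
and ``N2`` each INCLUDE the mixed partitions, so the number of non-empty
partitions is ``N1 + N2 - N12``.

Under the single assumption that the number of cells per partition is Poisson
distributed (rates ``mu1`` and ``mu2`` per type, total partitions ``N``
including empty ones), the three observables identify all three parameters:

    N = N1 * N2 / N12                      (cross-type independence)
    mu_i = -ln((N - N_i) / N)              (moment inversion)

and the multiplet frequency -- the probability that a non-empty partition holds
two or more cells -- is

    M = 1 - mu * exp(-mu) / (1 - exp(-mu)),   mu = mu1 + mu2.

The classical equal-mix shortcut ``2 * N12 / (N1 + N2 - N12)`` ("twice the
cross-cell-type fraction") is also provided; it is accurate only for equal
mixes at low loading and overestimates M once higher-order multiplets matter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "DropletCounts",
    "PoissonLoad",
    "MultipletEstimate",
    "BootstrapInterval",
    "ValidationError",
    "EstimationError",
    "UnidentifiableTotalError",
    "InconsistentCountsError",
    "prob_nonempty",
    "prob_multiplet",
    "multiplet_frequency",
    "infer_total_droplets",
    "infer_rates",
    "expected_counts",
    "doublet_approximation",
    "estimate_from_counts",
    "estimator_standard_error",
    "bootstrap_interval",
]

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """An input violates a type invariant (negative count, N12 > N1, ...)."""

    code = "validation"


class EstimationError(ValueError):
    """Base class for degenerate inputs on which the estimator is undefined."""

    code = "estimation"


class UnidentifiableTotalError(EstimationError):
    """N12 = 0: the total droplet count N = N1*N2/N12 is unbounded.

    Zero mixed droplets leaves the multiplet frequency formally unconstrained
    (any sufficiently dilute loading is consistent with the data); callers may
    fall back on the doublet approximation's lower bound of 0.
    """

    code = "unidentifiable-total"


class InconsistentCountsError(EstimationError):
    """N12 >= N1 or N12 >= N2: the implied Poisson rate is infinite.

    The inferred total N = N1*N2/N12 would not exceed one of the observed
    per-type counts, putting a zero (or negative) argument under the logarithm
    of the rate inversion.
    """

    code = "inconsistent-counts"


def _check_count(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value < 0:
        raise ValidationError(f"{name} must be a finite nonnegative count, got {value!r}")
    if value != int(value):
        # Upstream pipelines sometimes report estimated (fractional) partition
        # counts; accepted, but worth a trace in logs.
        logger.info("non-integer count %s=%r accepted", name, value)
    return value


@dataclass(frozen=True)
class DropletCounts:
    """The three experimental observables of a two-type mixing experiment.

    ``n_type1``/``n_type2`` count partitions with at least one cell of that
    type, INCLUSIVE of mixed partitions; ``n_mixed`` counts partitions with at
    least one cell of both types.
    """

    n_type1: float
    n_type2: float
    n_mixed: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_type1", _check_count("n_type1", self.n_type1))
        object.__setattr__(self, "n_type2", _check_count("n_type2", self.n_type2))
        object.__setattr__(self, "n_mixed", _check_count("n_mixed", self.n_mixed))
        if self.n_mixed > self.n_type1 or self.n_mixed > self.n_type2:
            raise ValidationError(
                f"n_mixed={self.n_mixed} exceeds a per-type count "
                f"(n_type1={self.n_type1}, n_type2={self.n_type2}); per-type counts "
                "include mixed droplets, so n_mixed can be at most min(n_type1, n_type2)"
            )

    @property
    def n_nonempty(self) -> float:
        """Number of non-empty partitions, N1 + N2 - N12."""
        return self.n_type1 + self.n_type2 - self.n_mixed

    def swapped(self) -> "DropletCounts":
        """Counts with the two cell types exchanged."""
        return DropletCounts(self.n_type2, self.n_type1, self.n_mixed)


@dataclass(frozen=True)
class PoissonLoad:
    """Poisson loading parameters: mean cells per droplet per type, total droplets.

    ``n_droplets`` counts ALL partitions, empty included, and may be fractional
    when inferred from observed counts.
    """

    mu1: float
    mu2: float
    n_droplets: float

    def __post_init__(self) -> None:
        for name in ("mu1", "mu2"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {v!r}")
        if not math.isfinite(self.n_droplets) or self.n_droplets <= 0:
            raise ValidationError(f"n_droplets must be finite and > 0, got {self.n_droplets!r}")

    @property
    def mu_total(self) -> float:
        return self.mu1 + self.mu2


@dataclass(frozen=True)
class MultipletEstimate:
    """Result of the closed-form estimator, at full precision.

    ``doublet_approximation`` is the classical equal-mix shortcut
    ``2*N12/(N1+N2-N12)`` evaluated on the same counts.  ``degenerate`` is
    False whenever an estimate was produced; degenerate inputs raise instead.
    """

    multiplet_frequency: float
    load: PoissonLoad
    counts: DropletCounts
    doublet_approximation: float
    degenerate: bool = False


class BootstrapInterval(NamedTuple):
    lower: float
    upper: float
    n_redraws: int


def prob_nonempty(load: PoissonLoad) -> float:
    """Probability that a droplet contains at least one cell of any type."""
    return -math.expm1(-load.mu_total)


def prob_multiplet(load: PoissonLoad) -> float:
    """Probability that a droplet contains two or more cells of any type."""
    mu = load.mu_total
    return -math.expm1(-mu) - mu * math.exp(-mu)


def _m_from_mu(mu: float) -> float:
    # M = 1 - mu e^{-mu} / (1 - e^{-mu}); expm1 keeps the denominator accurate
    # at small mu, where M -> mu/2.
    return 1.0 - mu * math.exp(-mu) / (-math.expm1(-mu))


def multiplet_frequency(load: PoissonLoad) -> float:
    """Probability that a NON-EMPTY droplet contains two or more cells.

    Depends on the rates only through their sum and is strictly increasing in
    it.  Undefined when mu1 + mu2 = 0 (no droplet is ever non-empty).
    """
    mu = load.mu_total
    if mu == 0:
        raise EstimationError(
            "multiplet frequency is undefined at mu1 + mu2 = 0: no non-empty droplets"
        )
    return _m_from_mu(mu)


def infer_total_droplets(counts: DropletCounts) -> float:
    """Total droplet count (empty + non-empty), N = N1*N2/N12.

    Follows from the independence of the two Poisson loading processes:
    N12/N = (N1/N)(N2/N).  Generally fractional; kept real-valued because
    rounding it perturbs the inferred rates.
    """
    if counts.n_mixed == 0:
        raise UnidentifiableTotalError(
            "n_mixed = 0: total droplet count N = n_type1*n_type2/n_mixed is "
            "unbounded and the multiplet frequency is unidentifiable; the doublet "
            "approximation gives the lower bound 0"
        )
    n = counts.n_type1 * counts.n_type2 / counts.n_mixed
    return n


def infer_rates(counts: DropletCounts) -> PoissonLoad:
    """Invert the observed counts to per-type Poisson rates.

    mu_i = -ln((N - N_i)/N) with N from :func:`infer_total_droplets`.  Requires
    N12 strictly below both N1 and N2, otherwise a rate would be infinite.
    """
    n = infer_total_droplets(counts)
    # n_mixed = n_type2 makes N = n_type1, putting log(0) in the mu1 inversion
    # (and symmetrically); name the saturated observable in the error.
    for name, ni in (("n_type1", counts.n_type1), ("n_type2", counts.n_type2)):
        if counts.n_mixed >= ni:
            raise InconsistentCountsError(
                f"n_mixed={counts.n_mixed} >= {name}={ni}: the implied Poisson rate "
                "for the other type is infinite (inferred total droplets N does not "
                "exceed its observed per-type count)"
            )
    # -log1p(-Ni/N) = -ln((N-Ni)/N), stable when Ni/N is small
    mu1 = -math.log1p(-counts.n_type1 / n)
    mu2 = -math.log1p(-counts.n_type2 / n)
    return PoissonLoad(mu1=mu1, mu2=mu2, n_droplets=n)


def expected_counts(load: PoissonLoad) -> DropletCounts:
    """Expected (real-valued) observables under a Poisson load; inverse of infer_rates."""
    p1 = -math.expm1(-load.mu1)
    p2 = -math.expm1(-load.mu2)
    n = load.n_droplets
    return DropletCounts(n_type1=n * p1, n_type2=n * p2, n_mixed=n * p1 * p2)


def doublet_approximation(counts: DropletCounts) -> float:
    """Twice the cross-cell-type fraction, 2*N12/(N1+N2-N12).

    The classical shortcut for equal mixes at low loading: every multiplet is
    assumed to be a doublet, and half the doublets are cross-type.  At high
    loading it overestimates M; for unequal mixes it is not valid at all.
    """
    nonempty = counts.n_nonempty
    if nonempty == 0:
        raise EstimationError("no non-empty droplets: doublet approximation undefined")
    return 2.0 * counts.n_mixed / nonempty


def estimate_from_counts(counts: DropletCounts) -> MultipletEstimate:
    """Full closed-form estimate of the multiplet frequency from (N1, N2, N12).

    Raises :class:`UnidentifiableTotalError` when N12 = 0 and
    :class:`InconsistentCountsError` when N12 >= N1 or N12 >= N2.
    """
    load = infer_rates(counts)
    m = multiplet_frequency(load)
    return MultipletEstimate(
        multiplet_frequency=m,
        load=load,
        counts=counts,
        doublet_approximation=doublet_approximation(counts),
        degenerate=False,
    )


def _m_hat(n1: float, n2: float, n12: float) -> float:
    # Raw estimator map used for delta-method differentiation; no validation.
    n = n1 * n2 / n12
    mu = -math.log1p(-n1 / n) - math.log1p(-n2 / n)
    return _m_from_mu(mu)


def estimator_standard_error(load: PoissonLoad) -> float:
    """First-order (delta method) standard error of the estimated M.

    Treats (N1, N2, N12) as sums of per-droplet indicators under independent
    Poisson loading at ``load`` and propagates their exact covariance through
    the estimator map with a central-difference gradient.  This is the
    Monte-Carlo standard error of a single simulated experiment with
    ``load.n_droplets`` droplets.
    """
    p1 = -math.expm1(-load.mu1)
    p2 = -math.expm1(-load.mu2)
    p12 = p1 * p2
    n = load.n_droplets
    cov = n * np.array(
        [
            [p1 * (1 - p1), p12 - p1 * p2, p12 * (1 - p1)],
            [p12 - p1 * p2, p2 * (1 - p2), p12 * (1 - p2)],
            [p12 * (1 - p1), p12 * (1 - p2), p12 * (1 - p12)],
        ]
    )
    x0 = np.array([n * p1, n * p2, n * p12])
    grad = np.empty(3)
    for i in range(3):
        h = 1e-6 * max(x0[i], 1.0)
        up, dn = x0.copy(), x0.copy()
        up[i] += h
        dn[i] -= h
        grad[i] = (_m_hat(*up) - _m_hat(*dn)) / (2 * h)
    var = float(grad @ cov @ grad)
    return math.sqrt(max(var, 0.0))


def _draw_counts(load: PoissonLoad, rng: np.random.Generator) -> DropletCounts:
    # Droplets fall into four classes (empty / type1-only / type2-only / mixed)
    # with multinomial counts; identical in law to per-droplet Poisson draws.
    p1 = -math.expm1(-load.mu1)
    p2 = -math.expm1(-load.mu2)
    probs = [(1 - p1) * (1 - p2), p1 * (1 - p2), (1 - p1) * p2, p1 * p2]
    n = int(round(load.n_droplets))
    _, only1, only2, mixed = rng.multinomial(n, probs)
    return DropletCounts(
        n_type1=float(only1 + mixed), n_type2=float(only2 + mixed), n_mixed=float(mixed)
    )


def bootstrap_interval(
    counts: DropletCounts,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    max_redraws: int = 1000,
) -> BootstrapInterval:
    """Parametric bootstrap interval for the multiplet frequency.

    Replicate (N1, N2, N12) triples are simulated from the fitted Poisson load
    and re-estimated; the equal-tailed percentile interval at ``level`` is
    returned.  Parametric rather than nonparametric because the per-droplet
    data behind the three summary counts are not available.  Replicates that
    land on a degenerate triple (N12 = 0 or N12 >= min(N1, N2)) are redrawn up
    to ``max_redraws`` times in total; the count of redraws is reported.
    """
    if n_boot < 100:
        raise ValidationError(f"n_boot must be >= 100, got {n_boot}")
    if not 0 < level < 1:
        raise ValidationError(f"level must be in (0, 1), got {level}")
    load = infer_rates(counts)
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    redraws = 0
    for i in range(n_boot):
        while True:
            c = _draw_counts(load, rng)
            try:
                reps[i] = estimate_from_counts(c).multiplet_frequency
                break
            except EstimationError:
                redraws += 1
                if redraws > max_redraws:
                    raise EstimationError(
                        f"bootstrap exceeded {max_redraws} redraws of degenerate "
                        "replicates; the experiment is too underpowered for a "
                        "parametric interval"
                    ) from None
    alpha = 1 - level
    lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
    return BootstrapInterval(lower=float(lo), upper=float(hi), n_redraws=redraws)
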