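"""Closed-form population-genetic expectations for Ka/Ks and Pa/Ps.

The model is the classical decomposition of the rate ratio into neutral,
advantageous and deleterious mutational classes.  A fraction ``p`` of new
nonsynonymous mutations is advantageous with selection coefficient ``s1 > 0``,
a fraction ``q`` is deleterious with ``s2 < 0``, and the remainder is neutral.
Relative to the (neutral) synonymous rate, the expected divergence ratio in a
haploid population of size ``N`` is

    R = Ka/Ks = (1 - p - q) + p * N * f(N, s1) + q * N * f(N, s2)

where ``f(N, s) = (1 - e^(-2s)) / (1 - e^(-2Ns))`` is the fixation
probability of a new mutation.  When selection on the advantageous class is
modest (``s1`` small but ``2*N*s1 >= 1``) and the deleterious class is
effectively lethal on the fixation time scale, this reduces to

    R = 1 + p*(2Ns - 1) - q

while the polymorphism ratio, from which the deleterious fraction is usually
estimated, satisfies

    Pa/Ps ~ 1 - q

because advantageous mutations are too fleeting to contribute measurable
polymorphism.  All functions use the haploid convention; pass ``ploidy=2`` to
``SelectionRegime`` for a diploid census size (``N`` is then doubled
internally).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "SelectionRegime",
    "RateRatio",
    "fixation_probability",
    "expected_R",
    "expected_R_approx",
    "expected_paps",
    "solve_p",
]


class InvalidParameterError(ValueError):
    """Raised when a population-genetic parameter is outside its domain."""


@dataclass(frozen=True)
class RateRatio:
    """A nonnegative per-site rate ratio (Ka/Ks or Pa/Ps).

    ``undefined`` is set when the denominator of the ratio vanished; in that
    case ``value`` is ``nan``.
    """

    value: float
    kind: str = "Ka/Ks"  # or "Pa/Ps"
    undefined: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("Ka/Ks", "Pa/Ps"):
            raise InvalidParameterError(f"unknown ratio kind: {self.kind!r}")
        if not self.undefined and not self.value >= 0:
            raise InvalidParameterError("rate ratio must be nonnegative")

    def __float__(self) -> float:
        return float(self.value)


@dataclass(frozen=True)
class SelectionRegime:
    """Fractions and strengths of selected mutations in one lineage.

    Parameters
    ----------
    N : int
        Haploid population size (>= 2).  With ``ploidy=2`` the effective
        size used in every formula is ``ploidy * N``.
    p : float
        Fraction of new nonsynonymous mutations that are advantageous.
    q : float
        Fraction that are deleterious.
    s1 : float
        Selection coefficient of advantageous mutations (> 0).
    s2 : float
        Selection coefficient of deleterious mutations (< 0).
    """

    N: int
    p: float
    q: float
    s1: float = 0.01
    s2: float = -0.05
    ploidy: int = 1

    def __post_init__(self) -> None:
        if self.N < 2:
            raise InvalidParameterError("population size N must be >= 2")
        if self.ploidy not in (1, 2):
            raise InvalidParameterError("ploidy must be 1 or 2")
        if self.p < 0 or self.q < 0 or self.p + self.q > 1 + 1e-12:
            raise InvalidParameterError("need p >= 0, q >= 0, p + q <= 1")
        if self.p > 0 and not self.s1 > 0:
            raise InvalidParameterError("s1 must be > 0")
        if self.q > 0 and not self.s2 < 0:
            raise InvalidParameterError("s2 must be < 0")

    @property
    def effective_N(self) -> int:
        return self.ploidy * self.N

    def _warn_weak_selection(self) -> None:
        # The reduced-form theory assumes both |s| exceed the drift scale.
        thresh = 1.0 / (2.0 * self.effective_N)
        if self.p > 0 and self.s1 < thresh:
            warnings.warn(
                "s1 < 1/(2N): advantageous selection is in the drift regime; "
                "the reduced-form approximation is unreliable",
                stacklevel=3,
            )
        if self.q > 0 and abs(self.s2) < thresh:
            warnings.warn(
                "|s2| < 1/(2N): deleterious selection is in the drift regime; "
                "the reduced-form approximation is unreliable",
                stacklevel=3,
            )


def fixation_probability(N: float, s: float) -> float:
    """Probability that a single new mutant with coefficient ``s`` fixes.

    Uses ``f(N, s) = (1 - e^(-2s)) / (1 - e^(-2Ns))`` with the continuous
    limit ``1/N`` at ``s = 0``; stable for ``|N*s|`` up to ~1e4.
    """
    if N < 2:
        raise InvalidParameterError("population size N must be >= 2")
    two_Ns = 2.0 * N * s
    if s == 0.0 or abs(two_Ns) < 1e-12:
        return 1.0 / N
    num = -math.expm1(-2.0 * s)  # 1 - e^(-2s), sign matches s
    if -two_Ns > 700.0:
        # Deleterious and far below the drift scale: 1 - e^(-2Ns) ~ -e^(-2Ns),
        # so f ~ -(1 - e^(-2s)) * e^(2Ns); evaluate in log space to avoid
        # overflow (underflows cleanly to 0.0).
        log_f = math.log(-num) + two_Ns
        return math.exp(log_f) if log_f > -745.0 else 0.0
    den = -math.expm1(-two_Ns)
    return num / den


def expected_R(regime: SelectionRegime) -> RateRatio:
    """Expected Ka/Ks under the full three-class fixation model."""
    regime._warn_weak_selection()
    N = regime.effective_N
    r = 1.0 - regime.p - regime.q
    if regime.p > 0:
        r += regime.p * N * fixation_probability(N, regime.s1)
    if regime.q > 0:
        r += regime.q * N * fixation_probability(N, regime.s2)
    return RateRatio(r, kind="Ka/Ks")


def expected_R_approx(p: float, q: float, two_Ns: float) -> RateRatio:
    """Reduced-form expected Ka/Ks, ``R = 1 + p*(2Ns - 1) - q``.

    Valid when ``s1`` is small but ``2*N*s1 >= 1`` and deleterious mutations
    essentially never fix.
    """
    if not (0.0 <= p <= 1.0 and 0.0 <= q <= 1.0 and p + q <= 1.0 + 1e-12):
        raise InvalidParameterError("need p, q in [0,1] with p + q <= 1")
    if p > 0 and two_Ns < 1.0:
        warnings.warn("2Ns < 1: advantageous class is effectively neutral")
    return RateRatio(1.0 + p * (two_Ns - 1.0) - q, kind="Ka/Ks")


def expected_paps(q: float) -> RateRatio:
    """Expected Pa/Ps given the deleterious fraction: ``Pa/Ps ~ 1 - q``.

    Holds after low-frequency (deleterious-enriched) variants are filtered
    out, because advantageous mutations contribute negligible polymorphism.
    """
    if not 0.0 <= q <= 1.0:
        raise InvalidParameterError("q must be in [0, 1]")
    return RateRatio(1.0 - q, kind="Pa/Ps")


def solve_p(R: float, q: float, two_Ns: float) -> float:
    """Invert the reduced-form ratio for the advantageous fraction.

    ``p = (R - 1 + q) / (2Ns - 1)``.  Results outside [0, 1] are clipped
    with a warning (a negative raw estimate means the data are compatible
    with ``p = 0``).
    """
    if two_Ns == 1.0:
        raise ZeroDivisionError("2Ns = 1 makes the advantageous class neutral; p is unidentifiable")
    if two_Ns < 1.0:
        raise InvalidParameterError("solve_p requires 2Ns > 1")
    p = (R - 1.0 + q) / (two_Ns - 1.0)
    if p < -1e-12 or p > 1.0 + 1e-12:
        warnings.warn(f"estimated p = {p:.4g} outside [0, 1]; clipped")
    return min(max(p, 0.0), 1.0)
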