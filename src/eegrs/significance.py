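"""Exact-binomial chance thresholds for decoding accuracies.

A decoding accuracy evaluated on ``n`` balanced trials is declared
significant when it exceeds ``100 * k* / n`` percent, where ``k*`` is the
smallest count whose exact binomial upper-tail probability under chance
(``p0 = 0.5``) does not exceed the corrected alpha.  Tails are computed by
explicit log-space summation of binomial terms (no normal approximation).

The correction convention (sidedness and Bonferroni family size) is under-
determined by a bare "binomial test + Bonferroni over m features" recipe, so
it is fixed by an explicit calibration: :func:`calibrate_convention` searches
the convention grid for the one reproducing a stated threshold pair, and the
package default :data:`DEFAULT_CONVENTION` is the result of that calibration
for the reference setting n = 216, m = 119, thresholds (62.96, 64.35):
a two-sided tail with Bonferroni correction across 2m comparisons
(equivalently a one-sided tail at alpha / (4 m)).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

__all__ = [
    "SignificanceSpec",
    "Convention",
    "DEFAULT_CONVENTION",
    "binomial_threshold",
    "calibrate_convention",
    "flag_significant",
]


@dataclass(frozen=True)
class Convention:
    """Sidedness and Bonferroni multiplicity convention.

    ``alpha_effective = alpha / (m * m_multiplier) / (2 if two_sided else 1)``.
    """

    sided: str = "one_sided"        # {"one_sided", "two_sided"}
    m_multiplier: int = 1

    def __post_init__(self):
        if self.sided not in ("one_sided", "two_sided"):
            raise ValueError(f"unknown sidedness {self.sided!r}")
        if self.m_multiplier < 1:
            raise ValueError("m_multiplier must be >= 1")

    def alpha_effective(self, alpha: float, m: int) -> float:
        eff = alpha / (m * self.m_multiplier)
        if self.sided == "two_sided":
            eff /= 2.0
        return eff


#: Fixed by calibration against the reference threshold pair (62.96, 64.35)
#: at n = 216, m = 119; see module docstring and `calibrate_convention`.
DEFAULT_CONVENTION = Convention(sided="two_sided", m_multiplier=2)


@dataclass(frozen=True)
class SignificanceSpec:
    n: int = 216
    p0: float = 0.5
    alpha: float = 0.05
    m: int = 119
    convention: Convention = DEFAULT_CONVENTION

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.m < 1 or self.n < 1:
            raise ValueError("n and m must be >= 1")
        if not 0 < self.p0 < 1:
            raise ValueError("p0 must be in (0, 1)")


def _log_upper_tails(n: int, p0: float) -> np.ndarray:
    """log P(X >= k) for k = 0..n, by log-space summation of binomial terms."""
    i = np.arange(n + 1)
    log_pmf = gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1) \
        + i * np.log(p0) + (n - i) * np.log1p(-p0)
    tails = np.empty(n + 1)
    acc = -np.inf
    for k in range(n, -1, -1):
        acc = np.logaddexp(acc, log_pmf[k])
        tails[k] = acc
    return np.minimum(tails, 0.0)


@dataclass(frozen=True)
class BinomialThreshold:
    k: int
    n: int
    percent: float
    tail: float               # exact P(X >= k) under chance
    alpha_effective: float


def binomial_threshold(spec: SignificanceSpec) -> BinomialThreshold:
    """Smallest significant accuracy (percent) under the spec's convention.

    Returns the smallest ``k`` with exact upper-tail probability
    ``P(X >= k; n, p0) <= alpha_effective`` as ``100 * k / n`` percent.
    Raises if even ``k = n`` is not significant at the corrected level.
    """
    eff = spec.convention.alpha_effective(spec.alpha, spec.m)
    log_tails = _log_upper_tails(spec.n, spec.p0)
    ok = log_tails <= np.log(eff)
    if not ok.any():
        raise ValueError(
            f"no attainable threshold: P(X >= n) = {np.exp(log_tails[-1]):.3g} "
            f"> alpha_effective = {eff:.3g}"
        )
    k = int(np.argmax(ok))
    return BinomialThreshold(
        k=k, n=spec.n, percent=100.0 * k / spec.n,
        tail=float(np.exp(log_tails[k])), alpha_effective=eff,
    )


def calibrate_convention(
    targets: tuple[float, float] = (62.96, 64.35),
    alphas: tuple[float, float] = (0.05, 0.01),
    n: int = 216,
    m: int = 119,
    decimals: int = 2,
) -> list[Convention]:
    """Conventions whose thresholds reproduce ``targets`` at both alphas.

    Brute-force search over sidedness x Bonferroni-family multipliers; the
    comparison is on the threshold percentages rounded to ``decimals``.
    """
    matches = []
    for sided in ("one_sided", "two_sided"):
        for mult in (1, 2, 4):
            conv = Convention(sided=sided, m_multiplier=mult)
            try:
                got = tuple(
                    round(binomial_threshold(SignificanceSpec(n=n, alpha=a, m=m, convention=conv)).percent,
                          decimals)
                    for a in alphas
                )
            except ValueError:
                continue
            if got == tuple(round(t, decimals) for t in targets):
                matches.append(conv)
    return matches


def flag_significant(
    results: pd.DataFrame,
    spec05: SignificanceSpec | None = None,
    spec01: SignificanceSpec | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Annotate a decoding-result frame with {ns, p05, p01} flags.

    A feature is flagged at a level iff its mean DA **strictly exceeds** the
    level's threshold.  Specs default to the feature count of ``results`` at
    n = 216 under the calibrated convention.
    """
    m = len(results)
    if spec05 is None:
        spec05 = SignificanceSpec(alpha=0.05, m=m)
    if spec01 is None:
        spec01 = replace(spec05, alpha=0.01)
    t05 = binomial_threshold(spec05)
    t01 = binomial_threshold(spec01)
    da = results["mean_da"].to_numpy()
    sig = np.where(da > t01.percent, "p01", np.where(da > t05.percent, "p05", "ns"))
    out = results.copy()
    out["significance"] = sig
    meta = {
        "threshold_p05": t05.percent,
        "threshold_p01": t01.percent,
        "k_p05": t05.k,
        "k_p01": t01.k,
        "n": spec05.n,
        "m": spec05.m,
        "convention": {"sided": spec05.convention.sided, "m_multiplier": spec05.convention.m_multiplier},
    }
    return out, meta
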