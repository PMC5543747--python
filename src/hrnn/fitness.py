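"""Model-selection fitness: AIC / AICc over teacher-forced residuals.

Lower is fitter.  The residual sum of squares is accumulated over all
experiments and evaluated time points; the complexity term counts k, the
number of gene leaf nodes (a gene entering several neurons contributes one
leaf per entry; context nodes carry no data and are excluded).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .model import CandidateNetwork, simulate_target

__all__ = ["FitnessReport", "aic", "aicc", "evaluate_fitness", "RSS_FLOOR"]

#: substituted for a zero residual sum of squares (perfect fit) so the log
#: of the mean square stays finite
RSS_FLOOR = 1e-12

#: small-sample rule: prefer AICc whenever n / k < this ratio
AICC_RATIO = 40.0


@dataclass
class FitnessReport:
    """Fitness breakdown for one candidate on one dataset."""

    residual_ss: float
    n: int
    k: int
    aic: float
    aicc: float
    used: str  # "aic" | "aicc"

    @property
    def score(self) -> float:
        """The criterion actually used for selection (lower is fitter)."""
        return self.aic if self.used == "aic" else self.aicc


def aic(residual_ss: float, n: int, k: int) -> float:
    """Akaike information criterion  n * ln(RSS / n) + 2k."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if k < 0:
        raise ValueError("k must be >= 0")
    if residual_ss <= 0.0:
        warnings.warn(
            "residual sum of squares is zero; substituting floor "
            f"{RSS_FLOOR:g} for the AIC log term",
            RuntimeWarning,
            stacklevel=2,
        )
        residual_ss = RSS_FLOOR
    return n * math.log(residual_ss / n) + 2 * k


def aicc(aic_value: float, n: int, k: int) -> float:
    """Small-sample corrected AIC:  AIC + 2k(k+1) / (n - k - 1).

    For n <= k + 1 the correction is undefined; such candidates get an
    infinite penalty (effectively rejected).
    """
    if n <= k + 1:
        return math.inf
    return aic_value + (2.0 * k * (k + 1)) / (n - k - 1)


def evaluate_fitness(
    net: CandidateNetwork,
    experiments: list[np.ndarray],
    burn_in: int | None = None,
) -> FitnessReport:
    """Score a candidate against observed data (lower score = fitter).

    Residuals are summed over every experiment and every evaluated time
    point (the half-open window after the burn-in).  AICc is used in the
    small-sample regime (n / k < 40), AIC otherwise.
    """
    rss = 0.0
    n = 0
    for X in experiments:
        X = np.asarray(X, dtype=float)
        preds = simulate_target(net, X, burn_in=burn_in)
        obs = X[net.target_gene - 1, X.shape[1] - preds.size:]
        rss += float(np.sum((obs - preds) ** 2))
        n += preds.size
    k = net.n_gene_leaves()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        a = aic(rss, n, k)
    ac = aicc(a, n, k)
    used = "aicc" if (k > 0 and n / k < AICC_RATIO) else "aic"
    return FitnessReport(residual_ss=rss, n=n, k=k, aic=a, aicc=ac, used=used)
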