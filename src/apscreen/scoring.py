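"""Aggregation-propensity scores.

The raw aggregation propensity of a simulated peptide system is the ratio
of solvent-accessible surface areas at the start and end of the run,

    AP = SASA_initial / SASA_final,

so AP > 1 means surface was buried, i.e. the peptides aggregated.  On top
of the (0-1 normalized) AP' two hydrophilicity-corrected scores are built:

    AP_H^2-0.5 = AP'^2 * sqrt(logP')

which biases selection toward soluble aggregators, and

    AP_HC = AP_H^2-0.5 * exp(-(logP' - mu)^2 / (2 sigma^2))

whose Gaussian factor penalizes both the insoluble (logP' -> 0) and the
overly soluble (logP' -> 1) extremes.  The default (mu, sigma^2) =
(0.4113, 0.0657) are the mean and variance of logP' over experimentally
validated aggregating pentapeptides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import numpy as np


class ScoreError(ValueError):
    """Raised for invalid SASA values, score ranges, or normalizations."""


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Decimal half-up rounding used for report tables (1.2915 -> 1.292).

    Binary float noise is stripped at 9 decimals before the half-up step so
    that e.g. (1.174 + 1.035)/2 = 1.1044999...8 still reports as 1.105.
    """
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(float(x))).quantize(Decimal(1).scaleb(-9))
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SasaPair:
    """Solvent-accessible surface area at the start and end of a run."""

    sasa_initial: float
    sasa_final: float

    def __post_init__(self) -> None:
        if self.sasa_initial <= 0 or self.sasa_final <= 0:
            raise ScoreError(
                f"SASA values must be strictly positive, got "
                f"({self.sasa_initial}, {self.sasa_final})"
            )


def ap_from_sasa(pair: SasaPair) -> float:
    """AP = SASA_initial / SASA_final; > 1 indicates aggregation."""
    return pair.sasa_initial / pair.sasa_final


@dataclass(frozen=True)
class HCParams:
    """Gaussian penalty parameters of the AP_HC score (logP' units)."""

    mu: float = 0.4113
    sigma2: float = 0.0657

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise ScoreError("sigma2 must be > 0")
        if not 0.0 <= self.mu <= 1.0:
            raise ScoreError("mu must lie in [0, 1]")


DEFAULT_HC_PARAMS = HCParams()


@dataclass
class ScoreSet:
    """AP values keyed by system string, with their normalization constants.

    ``norm_constants`` is the (min, max) pair that defines the primed
    quantities AP' = (AP - min)/(max - min); it is persisted with the set so
    downstream analyses (and files) can reproduce the normalization.
    """

    values: dict[str, float]
    norm_constants: tuple[float, float] | None = None
    meta: dict = field(default_factory=dict)

    @classmethod
    def from_items(cls, items: Mapping[str, float] | Iterable[tuple[str, float]]):
        return cls(values=dict(items))

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def keys(self):
        return self.values.keys()

    def array(self) -> np.ndarray:
        return np.asarray(list(self.values.values()), dtype=float)

    def aligned(self, other: "ScoreSet") -> tuple[np.ndarray, np.ndarray]:
        """Values of self and other over their common keys, in self's order."""
        common = [k for k in self.values if k in other.values]
        if not common:
            raise ScoreError("score sets share no keys")
        a = np.asarray([self.values[k] for k in common], dtype=float)
        b = np.asarray([other.values[k] for k in common], dtype=float)
        return a, b


def normalize_scores(
    scores: ScoreSet, constants: tuple[float, float] | None = None
) -> ScoreSet:
    """Min-max normalize a score population to primed values in [0, 1].

    Without explicit ``constants`` the population's own (min, max) is used
    and must be non-degenerate.  With external constants, values are clipped
    into [0, 1] (a value outside the reference population's range saturates).
    The constants are recorded on the returned set.
    """
    vals = scores.array()
    if constants is None:
        if len(vals) < 2 or np.min(vals) == np.max(vals):
            raise ScoreError(
                "self-normalization needs at least two distinct values"
            )
        lo, hi = float(np.min(vals)), float(np.max(vals))
        clip = False
    else:
        lo, hi = float(constants[0]), float(constants[1])
        if not hi > lo:
            raise ScoreError(f"degenerate normalization constants ({lo}, {hi})")
        clip = True
    primed = (vals - lo) / (hi - lo)
    if clip:
        primed = np.clip(primed, 0.0, 1.0)
    out = ScoreSet(
        values=dict(zip(scores.values.keys(), primed.tolist())),
        norm_constants=(lo, hi),
        meta=dict(scores.meta),
    )
    return out


def _check_unit(name: str, x: float) -> None:
    if not 0.0 <= x <= 1.0:
        raise ScoreError(f"{name} must lie in [0, 1], got {x}")


def ap_h(ap_prime: float, logp_prime: float) -> float:
    """Hydrophilicity-corrected score AP'^2 * sqrt(logP')."""
    _check_unit("ap_prime", ap_prime)
    _check_unit("logp_prime", logp_prime)
    return ap_prime**2 * math.sqrt(logp_prime)


def hc_penalty(logp_prime: float, params: HCParams = DEFAULT_HC_PARAMS) -> float:
    """Gaussian factor exp(-(logP' - mu)^2 / (2 sigma^2)), in (0, 1]."""
    d = logp_prime - params.mu
    return math.exp(-(d * d) / (2.0 * params.sigma2))


def ap_hc(
    ap_prime: float, logp_prime: float, params: HCParams = DEFAULT_HC_PARAMS
) -> float:
    """AP_HC = AP_H^2-0.5 * Gaussian penalty centred on mu."""
    return ap_h(ap_prime, logp_prime) * hc_penalty(logp_prime, params)


def ap_h_array(ap_prime: np.ndarray, logp_prime: np.ndarray) -> np.ndarray:
    """Vectorized :func:`ap_h` (inputs already in [0, 1])."""
    ap_prime = np.asarray(ap_prime, dtype=float)
    logp_prime = np.asarray(logp_prime, dtype=float)
    if (ap_prime < 0).any() or (ap_prime > 1).any():
        raise ScoreError("ap_prime out of [0, 1]")
    if (logp_prime < 0).any() or (logp_prime > 1).any():
        raise ScoreError("logp_prime out of [0, 1]")
    return ap_prime**2 * np.sqrt(logp_prime)


def ap_hc_array(
    ap_prime: np.ndarray,
    logp_prime: np.ndarray,
    params: HCParams = DEFAULT_HC_PARAMS,
) -> np.ndarray:
    d = np.asarray(logp_prime, dtype=float) - params.mu
    return ap_h_array(ap_prime, logp_prime) * np.exp(-(d * d) / (2.0 * params.sigma2))
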