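"""Core information measures in nats.

The single measure underlying the whole calculus is the Jeffreys divergence

    J(p', p) = sum_i (p'_i - p_i) * ln(p'_i / p_i)  >= 0,

the symmetrized Kullback-Leibler divergence.  For any replicator-type update
p' = p * omega (omega the relative fitness w/wbar), J(p', p) equals the
selection-induced change in the mean of the informational character
Z = ln(omega), which by the Price identity is cov_p(omega, Z).  These three
routes — direct summation, mean-change of the log-ratio character, and the
Price covariance — agree to numerical precision and are each exposed here.

Zero frequencies are an error by default: the log-ratio is undefined off the
shared support.  Passing ``smoothing=True`` to the divergence functions adds
a pseudo-probability floor of 1e-9 and renormalizes; it is never applied
silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distributions import FrequencyDistribution

#: pseudo-probability added to every entry when smoothing is requested
SMOOTHING_EPS = 1e-9


@dataclass(frozen=True)
class InformationalCharacter:
    """Per-type log-ratio character Z_i = ln(p'_i / p_i), in nats.

    The mean-change of this character under the move p -> p' is exactly the
    Jeffreys divergence J(p', p).
    """

    labels: tuple
    values: np.ndarray

    def as_dict(self) -> dict:
        return dict(zip(self.labels, self.values.tolist()))


def _smoothed(values: np.ndarray) -> np.ndarray:
    v = values + SMOOTHING_EPS
    return v / v.sum()


def _aligned_positive(
    p_new: FrequencyDistribution,
    p_old: FrequencyDistribution,
    op: str,
    smoothing: bool,
    require_new_positive: bool = True,
):
    p_new.same_support(p_old, op)
    a, b = p_new.values, p_old.values
    if smoothing:
        return _smoothed(a), _smoothed(b)
    bad_old = b <= 0
    if require_new_positive:
        bad_old |= a <= 0
    else:  # KL: only cells where p_new > 0 need positive p_old
        bad_old &= a > 0
    if np.any(bad_old):
        label = p_new.labels[int(np.argmax(bad_old))]
        raise ValueError(
            f"{op}: zero frequency at label {label!r} without smoothing enabled"
        )
    return a, b


def kl_divergence(
    p_new: FrequencyDistribution,
    p_old: FrequencyDistribution,
    smoothing: bool = False,
) -> float:
    """Kullback-Leibler divergence KL(p_new || p_old) in nats.

    Terms with p_new_i = 0 contribute 0 (0 * log(0/x) = 0).
    """
    a, b = _aligned_positive(p_new, p_old, "kl_divergence", smoothing, require_new_positive=False)
    mask = a > 0
    return float(np.sum(a[mask] * np.log(a[mask] / b[mask])))


def jeffreys_divergence(
    p_new: FrequencyDistribution,
    p_old: FrequencyDistribution,
    smoothing: bool = False,
) -> float:
    """Jeffreys divergence J(p_new, p_old) = sum (p'-p) ln(p'/p), in nats.

    Symmetric, non-negative, and equal to
    ``kl(p_new, p_old) + kl(p_old, p_new)``.  Identical distributions give 0
    even on the boundary of the simplex (a degenerate fixed point produces no
    informational change).
    """
    p_new.same_support(p_old, "jeffreys_divergence")
    if np.array_equal(p_new.values, p_old.values):
        return 0.0
    a, b = _aligned_positive(p_new, p_old, "jeffreys_divergence", smoothing)
    # term-wise (a-b)*ln(a/b) >= 0; evaluated as (max-min)*ln(max/min) so the
    # result is non-negative and exactly symmetric in its arguments
    hi, lo = np.maximum(a, b), np.minimum(a, b)
    return float(np.sum((hi - lo) * np.log(hi / lo)))


def log_ratio_character(
    p_new: FrequencyDistribution,
    p_old: FrequencyDistribution,
    smoothing: bool = False,
) -> InformationalCharacter:
    """Component-wise log-ratio Z_i = ln(p_new_i / p_old_i)."""
    a, b = _aligned_positive(p_new, p_old, "log_ratio_character", smoothing)
    return InformationalCharacter(p_new.labels, np.log(a / b))


def price_mean_change(p: FrequencyDistribution, w, Z) -> tuple[float, float]:
    """Change in the population mean of a character under one selection step,
    and its Price-identity value cov_p(omega, Z).

    With relative fitness omega = w / wbar and p' = p * omega, returns

        (delta_Zbar, cov) = (sum (p'-p) Z,  E_p[omega Z] - E_p[omega] E_p[Z])

    The two are equal algebraically; with Z = ln(omega) both equal the
    Jeffreys divergence J(p', p).
    """
    w = np.asarray(w, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if w.shape != p.values.shape or Z.shape != p.values.shape:
        raise ValueError("price_mean_change: w and Z must match the distribution length")
    if not np.all(np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("price_mean_change: fitness must be finite and strictly positive")
    wbar = float(np.sum(p.values * w))
    omega = w / wbar
    p_next = p.values * omega
    delta = float(np.sum((p_next - p.values) * Z))
    cov = float(np.sum(p.values * omega * Z) - np.sum(p.values * omega) * np.sum(p.values * Z))
    return delta, cov
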