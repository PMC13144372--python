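"""ATP-driven Ca2+ response and the insulin secretion pathway.

The KATP-channel/membrane electrophysiology between ATP and cytosolic
Ca2+ is collapsed into a single Hill-type response curve: Ca2+ relaxes
toward an ATP-dependent target with time constant ``tau_Ca``.  Insulin is
released from a rapid-release pool (RRP) at a Ca2+-dependent rate and the
RRP refills in a glucose-dependent, capacity-limited manner.
"""

from __future__ import annotations

import math

from .config import SimConfig


def hill(x: float, k: float, n: float = 1.0) -> float:
    """Saturating Hill function x^n / (k^n + x^n), zero at x <= 0."""
    if x <= 0.0:
        return 0.0
    r = (x / k) ** n
    return r / (1.0 + r)


def calcium_target(atp: float, config: SimConfig) -> float:
    """Steady Ca2+ level toward which the cytosolic Ca2+ relaxes."""
    if atp < 0:
        raise ValueError("calcium_target: atp must be >= 0")
    return config.Ca_basal + (config.Ca_max - config.Ca_basal) * hill(
        atp, config.K_Ca, config.n_Ca)


def relax_calcium(ca: float, atp: float, dt: float, config: SimConfig) -> float:
    """Exact exponential relaxation of Ca2+ over an interval of length dt
    during which the ATP level (hence the target) is constant."""
    target = calcium_target(atp, config)
    if config.tau_Ca <= 0:
        return target
    return target + (ca - target) * math.exp(-dt / config.tau_Ca)


def insulin_release_propensity(rrp: int, ca: float, config: SimConfig) -> float:
    return config.k_sec * rrp * hill(ca, config.K_sec_ca, config.n_sec)


def rrp_refill_propensity(rrp: int, config: SimConfig) -> float:
    g = config.glucose_mM
    free = max(0, config.RRP_cap - rrp)
    if g <= 0 or free == 0:
        return 0.0
    return config.k_refill * g / (config.Km_refill_gluc + g) * free


def secretion_rate(times, secreted, window) -> float:
    """Mean insulin secretion rate (granules/s) over a time window.

    Parameters
    ----------
    times, secreted
        Parallel sequences: snapshot times and cumulative secreted counts.
    window
        ``(t1, t2)`` with ``t1 < t2``; both must lie within the recorded
        range (apply after burn-in).
    """
    t1, t2 = window
    if not t2 > t1:
        raise ValueError("secretion_rate: empty or inverted window")
    if t1 < times[0] - 1e-9 or t2 > times[-1] + 1e-9:
        raise ValueError("secretion_rate: window outside trajectory")

    def value_at(t):
        # cumulative count at the last snapshot <= t
        lo, hi = 0, len(times) - 1
        while lo < hi:
            mid = (lo + hi + 1) // 2
            if times[mid] <= t + 1e-9:
                lo = mid
            else:
                hi = mid - 1
        return secreted[lo]

    return (value_at(t2) - value_at(t1)) / (t2 - t1)
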