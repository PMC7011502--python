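"""Lin's concordance correlation coefficient (CCC) with a Fisher-z interval.

The CCC measures agreement of paired measurements with the identity line:

    rho_c = 2 s_xy / (s_x^2 + s_y^2 + (x̄ − ȳ)^2)

with biased (divide-by-n) moments, as in Lin's original definition. It
equals the Pearson correlation attenuated by a bias-correction factor that
penalizes location and scale shifts, so |rho_c| <= |r| always, with
equality only when the fit line is the identity.

The confidence interval applies the Fisher z transform, z = atanh(rho_c),
with Lin's asymptotic variance of the transformed estimate,

    var(z) = 1/(n−2) [ (1−r²)ρ²/((1−ρ²)r²) + 2ρ³(1−ρ)u²/(r(1−ρ²)²)
                       − ρ⁴u⁴/(2r²(1−ρ²)²) ],   u = (x̄−ȳ)/√(s_x s_y),

normal quantiles, and a tanh back-transform. At |rho_c| = 1 the z-variance
is not finite and the result is flagged as exact agreement instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class AgreementResult:
    """CCC with confidence interval over ``n`` paired districts.

    ``degenerate`` marks exact agreement (|ccc| = 1), where no finite
    Fisher-z variance exists; then ci_low = ci_high = ccc.
    """

    ccc: float
    ci_low: float
    ci_high: float
    n: int
    degenerate: bool = False


def _moments(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, float]:
    mx, my = float(x.mean()), float(y.mean())
    sx2 = float(((x - mx) ** 2).mean())  # biased, divide-by-n
    sy2 = float(((y - my) ** 2).mean())
    sxy = float(((x - mx) * (y - my)).mean())
    return mx, my, sx2, sy2, sxy


def concordance_correlation(
    x: np.ndarray, y: np.ndarray, *, bias_corrected_moments: bool = False
) -> float:
    """Lin's CCC between two equal-length vectors (n >= 3, no missing values).

    ``bias_corrected_moments=True`` uses (n−1)-denominator moments
    instead of Lin's divide-by-n convention; the two agree as n grows.
    Undefined (raises) when both vectors are constant with equal means.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("need 1-d vectors of length >= 3")
    if np.any(np.isnan(x)) or np.any(np.isnan(y)):
        raise ValueError("missing values are not allowed")
    mx, my, sx2, sy2, sxy = _moments(x, y)
    if bias_corrected_moments:
        n = len(x)
        sx2, sy2, sxy = (v * n / (n - 1) for v in (sx2, sy2, sxy))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0.0:
        raise ValueError("CCC undefined: both vectors constant with equal means")
    return 2.0 * sxy / denom


def ccc_confidence_interval(
    x: np.ndarray, y: np.ndarray, level: float = 0.95
) -> AgreementResult:
    """CCC with a Fisher-z confidence interval (n >= 4).

    Exact agreement (|rho_c| = 1) is returned flagged degenerate rather
    than with an interval.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("confidence interval requires n >= 4")
    rho_c = concordance_correlation(x, y)
    if abs(rho_c) >= 1.0 - 1e-15:
        rho_c = max(-1.0, min(1.0, rho_c))
        return AgreementResult(ccc=rho_c, ci_low=rho_c, ci_high=rho_c, n=n, degenerate=True)

    mx, my, sx2, sy2, sxy = _moments(x, y)
    sx, sy = math.sqrt(sx2), math.sqrt(sy2)
    if sx == 0.0 or sy == 0.0:
        raise ValueError("CCC interval undefined when one vector is constant")
    r = sxy / (sx * sy)
    u = (mx - my) / math.sqrt(sx * sy)

    r2 = r * r
    rc2 = rho_c * rho_c
    one_m_rc2 = 1.0 - rc2
    var_z = (
        (1.0 - r2) * rc2 / (one_m_rc2 * r2)
        + 2.0 * rho_c**3 * (1.0 - rho_c) * u * u / (r * one_m_rc2**2)
        - rho_c**4 * u**4 / (2.0 * r2 * one_m_rc2**2)
    ) / (n - 2)
    var_z = max(var_z, 0.0)

    z = math.atanh(rho_c)
    zq = stats.norm.ppf(0.5 + level / 2.0)
    half = zq * math.sqrt(var_z)
    return AgreementResult(
        ccc=rho_c,
        ci_low=math.tanh(z - half),
        ci_high=math.tanh(z + half),
        n=n,
        degenerate=False,
    )
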