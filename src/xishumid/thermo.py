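"""Humidity thermodynamics: dew point, relative humidity, heat index.

All formulas work over liquid water using the Bolton (1980) saturation
vapor-pressure curve, the convention shared by the common meteorological
toolkits. Temperatures are kelvins at the API surface; the heat index
internally follows the US National Weather Service convention of degrees
Fahrenheit and percent relative humidity.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

log = logging.getLogger(__name__)

#: Ratio of the molar mass of water vapor to that of dry air.
EPSILON = 0.622

#: Bolton (1980) saturation vapor pressure constants: es(T) = ES0 * exp(A*t/(t+B))
#: with t in degrees Celsius and es in pascals.
ES0_PA = 611.2
BOLTON_A = 17.67
BOLTON_B = 243.5

#: NWS heat-index regime threshold, degrees Fahrenheit. Below it the simple
#: Steadman average applies; at or above it, the Rothfusz regression with the
#: published low-RH and high-RH adjustments.
HI_THRESHOLD_F = 80.0

#: Rothfusz regression coefficients (T and RH in Fahrenheit / percent).
ROTHFUSZ = (
    -42.379,
    2.04901523,
    10.14333127,
    -0.22475541,
    -6.83783e-3,
    -5.481717e-2,
    1.22874e-3,
    8.5282e-4,
    -1.99e-6,
)


# ---------------------------------------------------------------------------
# unit conversions (exact affine maps)

def kelvin_to_celsius(t_k):
    return np.asarray(t_k, dtype=float) - 273.15


def celsius_to_kelvin(t_c):
    return np.asarray(t_c, dtype=float) + 273.15


def celsius_to_fahrenheit(t_c):
    return np.asarray(t_c, dtype=float) * 9.0 / 5.0 + 32.0


def fahrenheit_to_celsius(t_f):
    return (np.asarray(t_f, dtype=float) - 32.0) * 5.0 / 9.0


def kelvin_to_fahrenheit(t_k):
    return celsius_to_fahrenheit(kelvin_to_celsius(t_k))


def fahrenheit_to_kelvin(t_f):
    return celsius_to_kelvin(fahrenheit_to_celsius(t_f))


# ---------------------------------------------------------------------------
# vapor pressure and dew point

def saturation_vapor_pressure(t_k):
    """Saturation vapor pressure over liquid water, in pascals (Bolton 1980)."""
    t_k = np.asarray(t_k, dtype=float)
    if np.any(t_k <= 0):
        raise ValueError("temperature must be positive (kelvins)")
    t_c = t_k - 273.15
    return ES0_PA * np.exp(BOLTON_A * t_c / (t_c + BOLTON_B))


def dewpoint_from_vapor_pressure(e_pa):
    """Invert the Bolton curve: dew point (K) from vapor pressure (Pa)."""
    e_pa = np.asarray(e_pa, dtype=float)
    if np.any(e_pa <= 0):
        raise ValueError("vapor pressure must be positive")
    ln = np.log(e_pa / ES0_PA)
    return 273.15 + BOLTON_B * ln / (BOLTON_A - ln)


def vapor_pressure_from_specific_humidity(q, p_pa):
    """Vapor pressure e = q p / (eps + (1 - eps) q), all in pascals."""
    q = np.asarray(q, dtype=float)
    p_pa = np.asarray(p_pa, dtype=float)
    if np.any((q <= 0) | (q >= 1)):
        raise ValueError("specific humidity must lie in (0, 1) kg/kg")
    if np.any(p_pa <= 0):
        raise ValueError("pressure must be positive")
    return q * p_pa / (EPSILON + (1.0 - EPSILON) * q)


def specific_humidity_from_dewpoint(td_k, p_pa):
    """Forward map: specific humidity (kg/kg) whose dew point at p is ``td_k``."""
    e = saturation_vapor_pressure(td_k)
    p_pa = np.asarray(p_pa, dtype=float)
    return EPSILON * e / (p_pa - (1.0 - EPSILON) * e)


def dewpoint_from_specific_humidity(q, p_pa):
    """Dew point (K) from specific humidity (kg/kg) and air pressure (Pa).

    Strictly increasing in ``q`` at fixed pressure.
    """
    return dewpoint_from_vapor_pressure(vapor_pressure_from_specific_humidity(q, p_pa))


def relative_humidity(t_k, td_k):
    """Relative humidity in percent from temperature and dew point (K).

    Supersaturated inputs (Td > T) are clipped to 100 % with a warning rather
    than rejected, mirroring the observation-cleaning policy of keeping but
    flagging supersaturated records.
    """
    t_k = np.asarray(t_k, dtype=float)
    td_k = np.asarray(td_k, dtype=float)
    if np.any(t_k <= 0) or np.any(td_k <= 0):
        raise ValueError("temperatures must be positive (kelvins)")
    rh = 100.0 * saturation_vapor_pressure(td_k) / saturation_vapor_pressure(t_k)
    if np.any(rh > 100.0):
        warnings.warn("dew point exceeds temperature; clipping RH to 100%",
                      stacklevel=2)
        rh = np.minimum(rh, 100.0)
    return rh


# ---------------------------------------------------------------------------
# heat index

def _rothfusz_f(t_f, rh):
    c = ROTHFUSZ
    hi = (c[0] + c[1] * t_f + c[2] * rh + c[3] * t_f * rh
          + c[4] * t_f ** 2 + c[5] * rh ** 2
          + c[6] * t_f ** 2 * rh + c[7] * t_f * rh ** 2
          + c[8] * t_f ** 2 * rh ** 2)
    # low-humidity adjustment
    low = (rh < 13.0) & (t_f >= 80.0) & (t_f <= 112.0)
    adj_lo = ((13.0 - rh) / 4.0) * np.sqrt(
        np.clip(17.0 - np.abs(t_f - 95.0), 0.0, None) / 17.0)
    hi = np.where(low, hi - adj_lo, hi)
    # high-humidity adjustment
    high = (rh > 85.0) & (t_f >= 80.0) & (t_f <= 87.0)
    adj_hi = ((rh - 85.0) / 10.0) * ((87.0 - t_f) / 5.0)
    hi = np.where(high, hi + adj_hi, hi)
    return hi


def heat_index(t_mean_k, td_mean_k):
    """Heat index (K) from daily mean temperature and dew point (K).

    Follows the NWS algorithm: the simple Steadman average
    ``0.5 * (T + 61 + (T - 68) * 1.2 + 0.094 * RH)`` when it falls below
    80 degF, otherwise the Rothfusz regression with the low- and high-RH
    adjustment terms. Inputs and output are kelvins.
    """
    t_k = np.asarray(t_mean_k, dtype=float)
    td_k = np.asarray(td_mean_k, dtype=float)
    scalar = t_k.ndim == 0 and td_k.ndim == 0
    t_k, td_k = np.atleast_1d(t_k), np.atleast_1d(td_k)
    rh = np.asarray(np.atleast_1d(relative_humidity(t_k, td_k)), dtype=float)
    t_f = kelvin_to_fahrenheit(t_k)
    simple = 0.5 * (t_f + 61.0 + (t_f - 68.0) * 1.2 + 0.094 * rh)
    hi_f = np.where(simple < HI_THRESHOLD_F, simple, _rothfusz_f(t_f, rh))
    hi_k = fahrenheit_to_kelvin(hi_f)
    return float(hi_k[0]) if scalar else hi_k
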