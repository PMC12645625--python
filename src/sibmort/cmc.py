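"""Century-month code (CMC) date arithmetic.

The CMC is the DHS convention for survey dates: months elapsed since
January 1900, with January 1900 = 1. All internal dates in this package
are CMCs; ages are completed years.
"""

from __future__ import annotations

import numpy as np

__all__ = ["to_cmc", "from_cmc", "age_in_years"]


def to_cmc(year, month):
    """Convert a (year, month) pair to a century-month code.

    Parameters
    ----------
    year : int or array-like
        Calendar year, >= 1900.
    month : int or array-like
        Calendar month, 1-12.

    Returns
    -------
    int or ndarray
        ``(year - 1900) * 12 + month``.
    """
    year = np.asarray(year)
    month = np.asarray(month)
    if np.any(year < 1900):
        raise ValueError("year must be >= 1900")
    if np.any((month < 1) | (month > 12)):
        raise ValueError("month must be in 1..12")
    cmc = (year - 1900) * 12 + month
    return int(cmc) if cmc.ndim == 0 else cmc


def from_cmc(cmc):
    """Inverse of :func:`to_cmc`: recover (year, month) from a CMC."""
    cmc = np.asarray(cmc)
    if np.any(cmc < 1):
        raise ValueError("CMC must be >= 1")
    year = 1900 + (cmc - 1) // 12
    month = (cmc - 1) % 12 + 1
    if cmc.ndim == 0:
        return int(year), int(month)
    return year, month


def age_in_years(birth_cmc, at_cmc):
    """Completed years of age at ``at_cmc`` for someone born at ``birth_cmc``."""
    birth_cmc = np.asarray(birth_cmc)
    at_cmc = np.asarray(at_cmc)
    age = (at_cmc - birth_cmc) // 12
    return int(age) if age.ndim == 0 else age
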