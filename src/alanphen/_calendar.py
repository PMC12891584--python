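"""Fixed 365-day calendar helpers (Feb 29 dropped everywhere).

All day-of-year (DOY) values are 1-based: Jan 1 = 1, Dec 31 = 365.
"""

from __future__ import annotations

import numpy as np

MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
# cumulative end-DOY of each month: Jan=31, Feb=59, ..., Dec=365
MONTH_END_DOY = np.cumsum(MONTH_LENGTHS)
MONTH_START_DOY = MONTH_END_DOY - MONTH_LENGTHS + 1

DAYS_PER_YEAR = 365

#: northern-hemisphere summer solstice on the 365-day calendar
SOLSTICE_DOY = 172


def month_of_doy(doy: int) -> int:
    """Calendar month (1-12) containing a 1-based day of year."""
    if not 1 <= doy <= DAYS_PER_YEAR:
        raise ValueError(f"doy must be in [1, 365], got {doy}")
    return int(np.searchsorted(MONTH_END_DOY, doy) + 1)


def month_index(doys: np.ndarray) -> np.ndarray:
    """Vectorized month (1-12) for an array of 1-based DOYs."""
    return np.searchsorted(MONTH_END_DOY, doys) + 1


def doys_of_month(month: int) -> np.ndarray:
    """1-based DOYs belonging to a calendar month."""
    if not 1 <= month <= 12:
        raise ValueError(f"month must be in [1, 12], got {month}")
    return np.arange(MONTH_START_DOY[month - 1], MONTH_END_DOY[month - 1] + 1)
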