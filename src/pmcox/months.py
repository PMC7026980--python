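"""Calendar-month arithmetic.

Every date in the package is a calendar month, represented internally as an
integer index ``year * 12 + (month - 1)`` so that differences are months.
Files use ISO ``YYYY-MM`` strings.
"""

from __future__ import annotations

import re

import numpy as np

_MONTH_RE = re.compile(r"^(\d{4})-(\d{2})$")


def month_index(ym: str) -> int:
    """Convert an ISO ``YYYY-MM`` string to an integer month index."""
    m = _MONTH_RE.match(str(ym))
    if not m:
        raise ValueError(f"not a YYYY-MM month string: {ym!r}")
    year, month = int(m.group(1)), int(m.group(2))
    if not 1 <= month <= 12:
        raise ValueError(f"month out of range in {ym!r}")
    return year * 12 + (month - 1)


def month_str(idx: int) -> str:
    """Inverse of :func:`month_index`."""
    idx = int(idx)
    return f"{idx // 12:04d}-{idx % 12 + 1:02d}"


def month_index_array(ym: "np.ndarray | list[str]") -> np.ndarray:
    """Vectorised :func:`month_index` for a string array/Series."""
    import pandas as pd

    s = pd.Series(ym, dtype="string")
    parts = s.str.extract(r"^(\d{4})-(\d{2})$")
    if parts.isna().any().any():
        bad = s[parts.isna().any(axis=1)].iloc[0]
        raise ValueError(f"not a YYYY-MM month string: {bad!r}")
    return (parts[0].astype(int) * 12 + parts[1].astype(int) - 1).to_numpy()


def year_of(idx: "int | np.ndarray"):
    """Calendar year containing a month index."""
    return np.asarray(idx) // 12 if not np.isscalar(idx) else int(idx) // 12
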