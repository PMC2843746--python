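"""Positional distribution of word occurrences in fixed chromosome windows.

A uniformly spread word gives Poisson-like window counts (variance/mean near
1); strong clustering inflates the dispersion. The dispersion is computed
over full windows only, so the trailing partial window cannot bias it, and a
profile with dispersion above ``CLUSTER_DISPERSION`` is flagged as clustered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

DEFAULT_WINDOW_BP = 50_000
CLUSTER_DISPERSION = 2.0


@dataclass
class WindowProfile:
    chromosome_id: str
    oligomer: str
    window_bp: int
    counts: list[int]
    dispersion: float

    @property
    def clustered(self) -> bool:
        return math.isfinite(self.dispersion) and self.dispersion > CLUSTER_DISPERSION


def window_profile(
    positions: list[int],
    length_bp: int,
    window_bp: int = DEFAULT_WINDOW_BP,
    chromosome_id: str = "",
    oligomer: str = "",
) -> WindowProfile:
    """Occurrence counts per fixed window plus a variance/mean dispersion.

    Occurrences fall in window floor(start / window_bp); the final partial
    window is kept in ``counts`` but excluded from the dispersion. Dispersion
    is NaN (flagged) when there are fewer than two full windows or no
    occurrences in them.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    n_windows = math.ceil(length_bp / window_bp)
    pos = np.asarray(positions, dtype=np.int64)
    if pos.size and (pos.min() < 0 or pos.max() >= length_bp):
        raise ValueError("position outside chromosome")
    idx = pos // window_bp
    counts = np.bincount(idx, minlength=n_windows)
    n_full = n_windows if length_bp % window_bp == 0 else n_windows - 1
    full = counts[:n_full].astype(float)
    if n_full < 2 or full.sum() == 0:
        dispersion = math.nan
    else:
        mean = full.mean()
        dispersion = float(full.var(ddof=1) / mean)
    return WindowProfile(
        chromosome_id=chromosome_id,
        oligomer=oligomer,
        window_bp=window_bp,
        counts=[int(c) for c in counts],
        dispersion=dispersion,
    )
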