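"""Small shared statistical helpers."""

from __future__ import annotations

import numpy as np
from scipy import stats


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann–Whitney U with sane tie handling.

    * identical constant samples -> (n1·n2/2, p = 1) exactly;
    * ties present -> asymptotic p with tie correction, no continuity
      correction (so equal distributions give p = 1, not p < 1);
    * otherwise scipy's default (exact for small samples).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return float(x.size * y.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
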