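"""Dip-style unimodality oracle used by the generator tests.

``unimodal_misfit`` measures how badly a sample's ECDF deviates from the
best unimodal (convex-then-concave) CDF restricted to modes at sample
points: for every candidate mode position it takes the larger of the
convex-side and concave-side maximal ECDF deviation (against the lower
convex hull on the left and the upper concave hull on the right of the
mode), minimizes over the mode, and halves the result (a hull shifted
halfway into the band is the optimal fit).  Unimodal samples give values of
order n^-1/2; well-separated two-mode samples give values of order the
smaller mode mass.

``bimodality_pvalue`` calibrates the statistic by Monte Carlo against the
uniform null (the classical least-favorable unimodal case for dip-type
statistics).
"""

from __future__ import annotations

import numpy as np


def _prefix_hull_misfit(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """pre[m] = max deviation of points 0..m above their lower convex hull."""
    n = len(x)
    hull = [0]                 # indices of hull vertices
    seg_dev = [0.0]            # max deviation of the segment ending at hull[i]
    pref = [0.0]               # running max deviation up to hull[i]
    out = np.zeros(n)
    for m in range(1, n):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            cross = (x[b] - x[a]) * (y[m] - y[a]) - (x[m] - x[a]) * (y[b] - y[a])
            if cross <= 0:     # b is on or above the chord a->m: not a hull vertex
                hull.pop(); seg_dev.pop(); pref.pop()
            else:
                break
        a = hull[-1]
        if m > a + 1:
            xs = x[a + 1 : m]
            ys = y[a + 1 : m]
            if x[m] > x[a]:
                line = y[a] + (ys * 0 + xs - x[a]) * (y[m] - y[a]) / (x[m] - x[a])
            else:              # vertical segment: deviation against the lower end
                line = np.full(len(xs), y[a])
            dev = float(np.max(ys - line))
        else:
            dev = 0.0
        hull.append(m)
        seg_dev.append(dev)
        pref.append(max(pref[-1], dev))
        out[m] = pref[-1]
    return out


def unimodal_misfit(sample: np.ndarray) -> float:
    """Minimal worst-side ECDF misfit over all mode positions, halved."""
    x = np.sort(np.asarray(sample, dtype=float))
    n = len(x)
    if n < 4 or x[0] == x[-1]:
        return 0.0
    y = (np.arange(n) + 0.5) / n
    pre = _prefix_hull_misfit(x, y)
    # concave side via the point reflection (x, y) -> (-x, 1 - y)
    suf = _prefix_hull_misfit(-x[::-1], (1.0 - y)[::-1])[::-1]
    return 0.5 * float(np.min(np.maximum(pre, suf)))


def bimodality_pvalue(
    sample: np.ndarray, n_null: int = 199, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo p-value of ``unimodal_misfit`` against the uniform null."""
    rng = np.random.default_rng(seed)
    obs = unimodal_misfit(sample)
    n = len(sample)
    hits = sum(
        unimodal_misfit(rng.random(n)) >= obs for _ in range(n_null)
    )
    return obs, (1 + hits) / (n_null + 1)
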