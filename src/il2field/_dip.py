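"""Hartigan's dip statistic for unimodality.

The dip of an empirical CDF F is the smallest sup-norm distance between F and
any unimodal (convex-then-concave) distribution function.  It is computed by
the classical modal-interval iteration: greatest convex minorant (GCM) and
least concave majorant (LCM) envelopes are fitted inside a shrinking window;
deviations of the empirical CDF from the envelopes outside the final modal
interval determine the statistic.

The implementation operates on unique sample values with tie counts and uses
the left/right ECDF limits.  Limitation: the unimodal class is modeled as
continuous (no atom at the mode), so for samples dominated by a large atom
the statistic is an upper bound on the classical dip (e.g. [0,0,0,1] yields
0.375 instead of 0.125).  This is irrelevant for the continuous fluorescence
distributions the package applies it to, and the bootstrap null (continuous
uniforms) is unaffected; for heavily tied data the test errs toward
rejecting unimodality.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dip_statistic"]


def _gcm(y: np.ndarray, xs: np.ndarray):
    """Greatest convex minorant of points (xs, y): envelope values + touch indices."""
    touch = [0]
    for j in range(1, len(y)):
        while len(touch) >= 2:
            a, b = touch[-2], touch[-1]
            if (y[b] - y[a]) * (xs[j] - xs[b]) <= (y[j] - y[b]) * (xs[b] - xs[a]):
                break
            touch.pop()
        touch.append(j)
    return np.interp(xs, xs[touch], y[touch]), np.asarray(touch)


def _lcm(y: np.ndarray, xs: np.ndarray):
    """Least concave majorant of points (xs, y)."""
    touch = [0]
    for j in range(1, len(y)):
        while len(touch) >= 2:
            a, b = touch[-2], touch[-1]
            if (y[b] - y[a]) * (xs[j] - xs[b]) >= (y[j] - y[b]) * (xs[b] - xs[a]):
                break
            touch.pop()
        touch.append(j)
    return np.interp(xs, xs[touch], y[touch]), np.asarray(touch)


def dip_statistic(values) -> float:
    """Dip statistic of the empirical CDF of ``values``.

    Returns 0 for degenerate samples (fewer than two distinct values).  The
    statistic is bounded below by 1/(2n) for non-degenerate samples and above
    by 0.25.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    ux, counts = np.unique(x, return_counts=True)
    m = len(ux)
    if m < 2:
        return 0.0
    n = counts.sum()
    fv = np.cumsum(counts) / n          # ECDF right limits
    fl = fv - counts / n                # ECDF left limits

    lo, hi = 0, m - 1
    best = 0.0
    while True:
        xs = ux[lo:hi + 1]
        wl = fl[lo:hi + 1]
        wv = fv[lo:hi + 1]
        genv, gt = _gcm(wl, xs)
        lenv, lt = _lcm(wv, xs)

        gap = lenv - genv
        d_g = gap[gt].max()
        d_l = gap[lt].max()
        if d_l > d_g:
            d = d_l
            xr = int(lt[gap[lt] == d_l][-1])
            cand = gt[gt <= xr]
            xl = int(cand[-1]) if len(cand) else int(gt[0])
        else:
            d = d_g
            xl = int(gt[gap[gt] == d_g][0])
            cand = lt[lt >= xl]
            xr = int(cand[0]) if len(cand) else int(lt[-1])

        left_dev = float(np.max(wv[:xl + 1] - genv[:xl + 1]))
        right_dev = float(np.max(lenv[xr:] - wl[xr:]))

        if d <= best or xr == 0 or xl == hi - lo:
            return max(best, left_dev, right_dev) / 2.0
        best = max(best, left_dev, right_dev)
        lo, hi = lo + xl, lo + xr
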