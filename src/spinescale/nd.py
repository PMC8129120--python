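"""Normalized-difference (ND) change statistic and threshold classification.

The ND of a spine between two imaging sessions is

    ND = (x_post - x_pre) / (x_post + x_pre)

for strictly positive intensities ``x_pre`` and ``x_post``.  ND is bounded in
(-1, 1), antisymmetric under swapping the two sessions, and invariant to a
common rescaling of both intensities, which makes it robust to session-wide
gain changes.  An ND of +0.15 corresponds to a post/pre intensity ratio of
(1 + 0.15)/(1 - 0.15) ~ 135%; -0.15 corresponds to ~74%.
"""

from __future__ import annotations

import numpy as np

UP = "up"
DOWN = "down"
NO_CHANGE = "no_change"


def normalized_difference(x_pre, x_post):
    """ND = (x_post - x_pre)/(x_post + x_pre) for positive intensities.

    Parameters
    ----------
    x_pre, x_post : float or array-like
        Strictly positive intensities (arbitrary units).

    Returns
    -------
    float or ndarray in (-1, 1).

    Raises
    ------
    ValueError
        If any input is not strictly positive.
    """
    pre = np.asarray(x_pre, dtype=float)
    post = np.asarray(x_post, dtype=float)
    if np.any(pre <= 0) or np.any(post <= 0):
        raise ValueError("normalized difference requires strictly positive intensities")
    nd = (post - pre) / (post + pre)
    if nd.ndim == 0:
        return float(nd)
    return nd


def nd_to_ratio(nd):
    """Post/pre intensity ratio equivalent to an ND value: (1 + nd)/(1 - nd).

    Defined for |nd| < 1; the inverse of :func:`ratio_to_nd`.
    """
    nd = np.asarray(nd, dtype=float)
    if np.any(np.abs(nd) >= 1):
        raise ValueError("nd_to_ratio is defined only for |nd| < 1")
    r = (1.0 + nd) / (1.0 - nd)
    if r.ndim == 0:
        return float(r)
    return r


def ratio_to_nd(ratio):
    """ND equivalent to a post/pre ratio: (ratio - 1)/(ratio + 1)."""
    ratio = np.asarray(ratio, dtype=float)
    if np.any(ratio <= 0):
        raise ValueError("ratio_to_nd requires a strictly positive ratio")
    nd = (ratio - 1.0) / (ratio + 1.0)
    if nd.ndim == 0:
        return float(nd)
    return nd


def classify_spines(nds, threshold: float = 0.15):
    """Label each ND as ``up`` (nd > threshold), ``down`` (nd < -threshold) or
    ``no_change`` otherwise.

    The inequalities are strict: an ND exactly at +-threshold is ``no_change``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    nds = np.asarray(nds, dtype=float)
    labels = np.full(nds.shape, NO_CHANGE, dtype=object)
    labels[nds > threshold] = UP
    labels[nds < -threshold] = DOWN
    return labels
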