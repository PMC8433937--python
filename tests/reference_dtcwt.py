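"""Independent reference implementation of the dual-tree transform.

Used only as a cross-check oracle in tests.  Every filtering step is
expressed as an explicit dense periodic-convolution matrix acting on the
reflect-doubled input, with the polyphase split, tree pairing and
complex combination re-derived here by straightforward index arithmetic.
No code is shared with the package's transform beyond the filter bank
itself (whose defining relations have their own tests).
"""

from __future__ import annotations

import numpy as np

SQRT2 = np.sqrt(2.0)


def conv_matrix(n: int, h: np.ndarray, center: int) -> np.ndarray:
    """Dense matrix of periodic filtering y[i] = sum_m h[m] x[(i+center-m) % n]."""
    W = np.zeros((n, n))
    for i in range(n):
        for m, hm in enumerate(h):
            W[i, (i + center - m) % n] += hm
    return W


def decimating_matrix(n: int, h: np.ndarray, phase: int) -> np.ndarray:
    """Dense matrix of y[k] = sum_m h[m] x[(2k+phase-m) % n]."""
    W = np.zeros((n // 2, n))
    for k in range(n // 2):
        for m, hm in enumerate(h):
            W[k, (2 * k + phase - m) % n] += hm
    return W


def reference_dtcwt2d(X: np.ndarray, levels: int, fb) -> tuple[list[dict], dict]:
    """Oriented complex subbands and lowpass images, via dense operators.

    Returns (highpass_levels, lowpass) in the same layout as the
    package's result: a dict per level keyed by orientation, and the four
    cropped tree lowpass images keyed by tree letters.
    """
    X = np.asarray(X, dtype=float)
    d = np.block([[X, X[:, ::-1]], [X[::-1, :], X[::-1, ::-1]]])
    R2, C2 = d.shape
    h0, h1 = fb.stage1_tree_a
    c0, c1 = fb.stage1_lowpass_center, fb.stage1_highpass_center

    lo_rows = conv_matrix(R2, h0, c0) @ d
    hi_rows = conv_matrix(R2, h1, c1) @ d
    ll = lo_rows @ conv_matrix(C2, h0, c0).T
    lh = lo_rows @ conv_matrix(C2, h1, c1).T
    hl = hi_rows @ conv_matrix(C2, h0, c0).T
    hh = hi_rows @ conv_matrix(C2, h1, c1).T

    def polyphase(arr):
        return {(rt, ct): arr[i::2, j::2]
                for i, rt in ((0, "a"), (1, "b"))
                for j, ct in ((0, "a"), (1, "b"))}

    streams = polyphase(ll)
    raw_levels = [{bt: polyphase(arr) for bt, arr in
                   (("lh", lh), ("hl", hl), ("hh", hh))}]

    qfilt = {"a": fb.qshift_tree_b, "b": fb.qshift_tree_a}
    for _ in range(2, levels + 1):
        new_streams = {}
        lev = {"lh": {}, "hl": {}, "hh": {}}
        for (rt, ct), s in streams.items():
            h0r, h1r = qfilt[rt]
            h0c, h1c = qfilt[ct]
            m = h0r.size
            nr, nc = s.shape
            lo_r = decimating_matrix(nr, h0r, m // 2) @ s
            hi_r = decimating_matrix(nr, h1r, m // 2) @ s
            Dc0 = decimating_matrix(nc, h0c, m // 2)
            Dc1 = decimating_matrix(nc, h1c, m // 2)
            new_streams[(rt, ct)] = lo_r @ Dc0.T
            lev["lh"][(rt, ct)] = lo_r @ Dc1.T
            lev["hl"][(rt, ct)] = hi_r @ Dc0.T
            lev["hh"][(rt, ct)] = hi_r @ Dc1.T
        streams = new_streams
        raw_levels.append(lev)

    def crop(a):
        return a[: a.shape[0] // 2, : a.shape[1] // 2]

    trees = (("a", "a"), ("a", "b"), ("b", "a"), ("b", "b"))
    highpass = []
    for lev in raw_levels:
        bands = {}
        for bt, (op, om) in (("lh", (15, -15)), ("hh", (45, -45)), ("hl", (75, -75))):
            aa, ab, ba, bb = (crop(lev[bt][t]) for t in trees)
            bands[op] = ((aa - bb) + 1j * (ab + ba)) / SQRT2
            bands[om] = ((aa + bb) + 1j * (ba - ab)) / SQRT2
        highpass.append(bands)
    lowpass = {t: crop(streams[t]) for t in trees}
    return highpass, lowpass
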