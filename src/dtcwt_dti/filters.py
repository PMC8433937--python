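"""Filter banks for the dual-tree complex wavelet transform.

The dual tree runs two real two-channel filter banks in parallel.  At the
first analysis stage the second tree's filters are the first tree's delayed
by exactly one sample, which places the two trees' level-1 outputs half a
sample apart at the subband rate.  From level 2 onward the trees use an
even-length orthonormal *Q-shift* pair: one tree filters with ``h``, the
other with its time reverse, so the group delays sit a quarter sample
either side of centre and the cumulative inter-tree delay stays at half a
subband sample on every level.  That half-sample offset is what makes the
re-combined coefficients approximately analytic, hence the transform's
near shift invariance and six-orientation selectivity.

Two concrete filter sets are built here:

* a near-symmetric biorthogonal 13/19-tap pair for stage 1.  The 13-tap
  lowpass is the classic table of small dyadic-style rationals
  (denominator 5120); its 19-tap complement is *derived* at run time by
  solving the half-band (perfect-reconstruction) linear system with two
  extra vanishing moments, so the product filter is half-band to machine
  precision rather than to published rounding.
* the standard 14-tap Q-shift lowpass.  The published table is rounded to
  8 decimals, which leaves orthonormality errors near 1e-9; a Newton-type
  projection pulls the coefficients onto the exact constraint manifold
  (orthonormality, DC gain sqrt(2), zero at Nyquist) while moving each tap
  by less than 2e-8.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import optimize

__all__ = ["FilterBank", "default_filters"]

SQRT2 = np.sqrt(2.0)

# 13-tap near-symmetric analysis lowpass, exact rationals over 5120.
_H0_NUMERATORS = (-9, 0, 114, -240, -247, 1520, 2844, 1520, -247, -240, 114, 0, -9)

# 14-tap Q-shift lowpass (tree with +1/4-sample delay), published rounding.
_QSHIFT14 = (
    0.00325314, -0.00388321, 0.03466035, -0.03887280,
    -0.11720389, 0.27529538, 0.75614564, 0.56881042,
    0.01186609, -0.10671180, 0.02382538, 0.01702522,
    -0.00543948, -0.00455690,
)


def _derive_stage1_complement(h0_sum1: np.ndarray) -> np.ndarray:
    """Solve for the symmetric 19-tap lowpass complementary to ``h0``.

    The product P = h0 * g0 must be half-band: P[centre] = 1 and every
    coefficient an even offset away from the centre must vanish.  With a
    symmetric 19-tap g0 that gives 8 equations for 10 free coefficients;
    two vanishing-moment conditions at z = -1 (0th and 2nd order) close
    the system.  Everything is linear, so the solution is exact.
    """

    def build(free: np.ndarray) -> np.ndarray:
        g = np.zeros(19)
        g[:10] = free
        g[10:] = free[:9][::-1]
        return g

    eye = np.eye(10)
    basis = np.array([np.convolve(h0_sum1, build(eye[i])) for i in range(10)])
    rows, rhs = [], []
    for m in range(1, 8):                      # half-band zeros
        rows.append(basis[:, 15 + 2 * m])
        rhs.append(0.0)
    rows.append(basis[:, 15])                  # half-band centre
    rhs.append(1.0)
    signs = (-1.0) ** np.arange(19)
    n = np.arange(19.0)
    rows.append(np.array([build(eye[i]) @ signs for i in range(10)]))
    rhs.append(0.0)                            # zero at z = -1
    rows.append(np.array([build(eye[i]) @ (signs * (n - 9.0) ** 2) for i in range(10)]))
    rhs.append(0.0)                            # flatness of that zero
    return build(np.linalg.solve(np.array(rows), np.array(rhs)))


def _refine_qshift(h: np.ndarray) -> np.ndarray:
    """Project the rounded Q-shift table onto the exact constraint set."""

    def residual(v: np.ndarray) -> np.ndarray:
        cons = [np.dot(v[2 * k:], v[:-2 * k]) for k in range(1, 7)]
        cons.append(np.dot(v, v) - 1.0)
        cons.append(v.sum() - SQRT2)
        cons.append(((-1.0) ** np.arange(v.size)) @ v)   # zero at Nyquist
        return np.concatenate([1e8 * np.asarray(cons), v - h])

    sol = optimize.least_squares(residual, h, xtol=1e-15, ftol=1e-15, gtol=1e-15)
    return sol.x


@dataclass(frozen=True)
class FilterBank:
    """Analysis/synthesis filters for both trees of the dual tree.

    Stage-1 filters are zero-phase-indexed symmetric arrays; ``*_center``
    gives the index of the zero-delay tap.  Tree b's stage-1 filters are
    tree a's delayed by one sample (one leading zero), the defining
    relation of the dual tree's first stage.  The Q-shift arrays are the
    level >= 2 orthonormal pair; tree b's are tree a's time reverse.
    """

    stage1_tree_a: tuple[np.ndarray, np.ndarray]
    stage1_tree_b: tuple[np.ndarray, np.ndarray]
    stage1_synthesis: tuple[np.ndarray, np.ndarray]
    stage1_lowpass_center: int
    stage1_highpass_center: int
    qshift_tree_a: tuple[np.ndarray, np.ndarray]
    qshift_tree_b: tuple[np.ndarray, np.ndarray]

    def validate(self, tol: float = 1e-10) -> list[str]:
        """Numerically check the defining filter-bank relations."""
        problems: list[str] = []
        h0, h1 = self.stage1_tree_a
        g0, g1 = self.stage1_synthesis
        prod = np.convolve(h0, g0) + np.convolve(h1, g1)
        target = np.zeros_like(prod)
        target[prod.size // 2] = 2.0
        if np.abs(prod - target).max() > tol:
            problems.append("stage-1 pair is not perfect-reconstruction")
        b0 = self.stage1_tree_b[0]
        if b0[0] != 0.0 or not np.allclose(b0[1:], h0, atol=0):
            problems.append("stage-1 tree-b lowpass is not a one-sample delay of tree-a")
        ha, h1a = self.qshift_tree_a
        for k in range(1, ha.size // 2):
            if abs(np.dot(ha[2 * k:], ha[:-2 * k])) > tol:
                problems.append(f"qshift lowpass not orthonormal at lag {2 * k}")
                break
        if abs(np.dot(ha, ha) - 1.0) > tol:
            problems.append("qshift lowpass not unit norm")
        if not np.allclose(self.qshift_tree_b[0], ha[::-1], atol=0):
            problems.append("qshift tree-b lowpass is not the reverse of tree-a")
        if abs(np.dot(ha, h1a)) > tol:
            problems.append("qshift lowpass/highpass not orthogonal")
        return problems


@lru_cache(maxsize=1)
def default_filters() -> FilterBank:
    """Build the default 13/19-tap stage-1 and 14-tap Q-shift filter bank.

    All filters are scaled so each lowpass sums to sqrt(2), the
    orthonormal convention; a constant image therefore gains a factor of
    2 per 2-D level through the lowpass path.
    """
    h0_sum1 = np.array(_H0_NUMERATORS, dtype=float) / 5120.0
    h0 = h0_sum1 * SQRT2                                    # 13-tap, centre 6
    g0 = _derive_stage1_complement(h0_sum1) / SQRT2         # 19-tap, centre 9
    n19 = np.arange(19.0)
    n13 = np.arange(13.0)
    h1 = ((-1.0) ** (n19 - 9.0)) * g0                       # analysis highpass
    g1 = ((-1.0) ** (n13 - 6.0)) * h0                       # synthesis highpass

    h0a = _refine_qshift(np.array(_QSHIFT14))
    h0b = h0a[::-1].copy()
    h1a = ((-1.0) ** np.arange(14.0)) * h0b                 # CQF highpass, tree a
    h1b = h1a[::-1].copy()

    delay = np.concatenate([[0.0], h0])
    delay_h1 = np.concatenate([[0.0], h1])
    fb = FilterBank(
        stage1_tree_a=(h0, h1),
        stage1_tree_b=(delay, delay_h1),
        stage1_synthesis=(g0, g1),
        stage1_lowpass_center=6,
        stage1_highpass_center=9,
        qshift_tree_a=(h0a, h1a),
        qshift_tree_b=(h0b, h1b),
    )
    issues = fb.validate()
    if issues:  # pragma: no cover - construction is deterministic
        raise RuntimeError("default filter bank failed self-check: " + "; ".join(issues))
    return fb
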