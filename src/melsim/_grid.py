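"""Precomputed finite-difference operators for a non-uniform radial grid.

Three-point centred weights in the interior and second-order one-sided
weights at both ends.  Built once per time step (the mesh moves between
steps, not within one) and shared by the kinetics, chemotaxis and solver
assembly code.
"""

from __future__ import annotations

import numpy as np

__all__ = ["GridOps"]


class GridOps:
    """First/second-derivative weights on the grid ``r`` (strictly increasing)."""

    def __init__(self, r: np.ndarray):
        r = np.asarray(r, dtype=float)
        if r.size < 3:
            raise ValueError("grid operators need at least 3 nodes")
        self.r = r
        h1 = r[1:-1] - r[:-2]
        h2 = r[2:] - r[1:-1]
        # centred first derivative
        self.w1m = -h2 / (h1 * (h1 + h2))
        self.w1c = (h2 - h1) / (h1 * h2)
        self.w1p = h1 / (h2 * (h1 + h2))
        # centred second derivative
        self.w2m = 2.0 / (h1 * (h1 + h2))
        self.w2c = -2.0 / (h1 * h2)
        self.w2p = 2.0 / (h2 * (h1 + h2))
        # one-sided first derivative at both ends (3-point, second order)
        a1, a2 = r[1] - r[0], r[2] - r[1]
        self.e0 = np.array([-(2 * a1 + a2) / (a1 * (a1 + a2)),
                            (a1 + a2) / (a1 * a2),
                            -a1 / (a2 * (a1 + a2))])
        b1, b2 = r[-2] - r[-3], r[-1] - r[-2]
        self.e1 = np.array([b2 / (b1 * (b1 + b2)),
                            -(b1 + b2) / (b1 * b2),
                            (2 * b2 + b1) / (b2 * (b1 + b2))])

    def deriv(self, y: np.ndarray) -> np.ndarray:
        """d y / d r along the last axis (y may be batched)."""
        y = np.asarray(y, dtype=float)
        out = np.empty_like(y)
        out[..., 1:-1] = (self.w1m * y[..., :-2] + self.w1c * y[..., 1:-1]
                          + self.w1p * y[..., 2:])
        out[..., 0] = y[..., 0] * self.e0[0] + y[..., 1] * self.e0[1] + y[..., 2] * self.e0[2]
        out[..., -1] = (y[..., -3] * self.e1[0] + y[..., -2] * self.e1[1]
                        + y[..., -1] * self.e1[2])
        return out
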