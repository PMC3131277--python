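"""Shared geometric fixtures for the test suite."""

import numpy as np


def digitized_ellipsoid(semi_axes, pad=3):
    """Axis-aligned solid ellipsoid mask, semi-axes in voxels (z, y, x)."""
    a, b, c = semi_axes
    nz, ny, nx = (int(np.ceil(s)) + pad for s in semi_axes)
    zz, yy, xx = np.mgrid[-nz : nz + 1, -ny : ny + 1, -nx : nx + 1]
    return (zz / a) ** 2 + (yy / b) ** 2 + (xx / c) ** 2 <= 1.0


def digitized_ball(radius, pad=2):
    n = int(np.ceil(radius)) + pad
    zz, yy, xx = np.mgrid[-n : n + 1, -n : n + 1, -n : n + 1]
    return zz * zz + yy * yy + xx * xx <= radius * radius
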