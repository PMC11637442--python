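"""Circular geometry and von Mises population coding.

Stimulus features (shape, colour) live on a circle parameterised in degrees,
``[0, 360)``.  Agents never see the raw angle: a feature value is encoded as a
normalised von Mises activation profile over a bank of nodes that uniformly
tile the circle, so that learning about one angle generalises to its
neighbours.  The same geometry is used by the task generator to compute
rewards from angular distances.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_angle",
    "circular_distance",
    "node_angles",
    "von_mises_kernel",
    "encode_feature",
    "basis_cosines",
    "basis_matrix",
]

#: default number of basis nodes per feature dimension (24 degree spacing,
#: matching the 15-position stimulus grid; the stimulus is then a
#: 30-dimensional vector across its two feature dimensions)
DEFAULT_NODE_COUNT = 15


def wrap_angle(angle):
    """Normalise an angle (or array of angles) into ``[0, 360)`` degrees."""
    return np.asarray(angle, dtype=float) % 360.0


def circular_distance(a, b):
    """Shortest angular distance between two angles, in degrees ``[0, 180]``.

    Symmetric and invariant to full rotations of either argument; accepts
    scalars or broadcastable arrays.
    """
    d = np.abs(wrap_angle(a) - wrap_angle(b))
    d = np.minimum(d, 360.0 - d)
    if np.ndim(d) == 0:
        return float(d)
    return d


def node_angles(node_count: int) -> np.ndarray:
    """Angles (degrees) of ``node_count`` nodes uniformly tiling the circle.

    Node 0 sits at 0 degrees; spacing is ``360 / node_count``.
    """
    if node_count < 2:
        raise ValueError("node_count must be >= 2")
    return np.arange(node_count) * (360.0 / node_count)


def von_mises_kernel(kappa: float, node_count: int = DEFAULT_NODE_COUNT) -> np.ndarray:
    """Normalised von Mises activation profile centred on node 0.

    ``kernel[i] = exp(kappa * cos(d_i)) / Z`` where ``d_i`` is the angular
    distance of node ``i`` from 0 degrees, in radians, and ``Z`` normalises
    the profile to sum to 1.  Encoding any other angle is a circular shift of
    this kernel (for angles landing exactly on a node), which the fast
    simulation kernels exploit.
    """
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    d = np.deg2rad(node_angles(node_count))
    # subtract max exponent for numerical stability at large kappa
    a = kappa * np.cos(d)
    x = np.exp(a - a.max())
    return x / x.sum()


def encode_feature(
    angle: float, kappa: float, node_count: int = DEFAULT_NODE_COUNT
) -> np.ndarray:
    """Encode a feature angle as a normalised von Mises basis vector.

    Activation of node ``i`` is ``exp(kappa * cos(d_i))`` with ``d_i`` the
    angular distance (radians) between the encoded angle and node ``i``,
    normalised so the vector sums to 1.  With ``kappa`` approaching 0 the
    profile is uniform; with large ``kappa`` it concentrates on the node
    nearest the encoded angle.
    """
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    theta = wrap_angle(angle)
    d = np.deg2rad(theta - node_angles(node_count))
    a = kappa * np.cos(d)
    x = np.exp(a - a.max())
    return x / x.sum()


def basis_cosines(angles, node_count: int = DEFAULT_NODE_COUNT) -> np.ndarray:
    """Kappa-independent cosine table: ``cos`` of the angular distance between
    each angle (rows) and each node (columns), in radians.

    ``basis_matrix`` exponentiates this table; precomputing it once per block
    makes repeated encodings at different concentrations cheap inside
    optimiser loops.
    """
    theta = wrap_angle(np.atleast_1d(angles))
    d = np.deg2rad(theta[:, None] - node_angles(node_count)[None, :])
    return np.cos(d)


def basis_matrix(
    angles=None,
    kappa: float = 1.0,
    node_count: int = DEFAULT_NODE_COUNT,
    cosines: np.ndarray | None = None,
) -> np.ndarray:
    """Row-wise von Mises basis vectors for a sequence of angles.

    Each row is ``encode_feature`` of the corresponding angle: non-negative,
    summing to 1, peaked at the node nearest the angle.  Pass a precomputed
    ``cosines`` table (from :func:`basis_cosines`) to skip the trigonometry.
    """
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    cosd = basis_cosines(angles, node_count) if cosines is None else cosines
    a = kappa * cosd
    x = np.exp(a - a.max(axis=1, keepdims=True))
    return x / x.sum(axis=1, keepdims=True)
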