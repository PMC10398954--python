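"""Generic spherical-head lead field for the REST re-reference.

REST (reference electrode standardization) maps scalp potentials to an
approximation of a reference at infinity using a forward model.  Without
subject anatomy, the standard fallback is a generic spherical head: here a
homogeneous conducting sphere with an equivalent-source layer of radial
dipoles at 0.79 of the scalp radius, sampled on a Fibonacci lattice with the
bottom cap (below the ears) excluded.

The surface potential of a point current source inside an insulated
homogeneous sphere has the Legendre expansion

    V(theta) = (1 / 4 pi sigma R) * sum_{n>=1} (2n+1)/n * (b/R)^n P_n(cos theta)

with source depth ``b`` and electrode-source angle ``theta``.  A radial
dipole is evaluated as the difference quotient of two such monopoles along
the radius.  Only the column space of the lead field matters for REST (the
transform is G pinv(G_avg)), so conductivity and overall scale are
irrelevant and set to 1.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = ["electrode_positions", "lead_field", "rest_transform"]

_N_TERMS = 60
_SOURCE_RADIUS = 0.79
_N_SOURCES = 400
_MIN_Z = -0.5  # drop sources in the bottom spherical cap


@lru_cache(maxsize=8)
def electrode_positions(labels: tuple[str, ...]) -> np.ndarray:
    """Unit-sphere electrode positions for standard 10/20-family labels."""
    import mne

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        montage = mne.channels.make_standard_montage("standard_1005")
    pos = montage.get_positions()["ch_pos"]
    missing = [lab for lab in labels if lab not in pos]
    if missing:
        raise ValueError(f"no standard montage position for channels: {missing}")
    xyz = np.array([pos[lab] for lab in labels])
    xyz -= xyz.mean(axis=0) * 0  # montage is already head-centered
    return xyz / np.linalg.norm(xyz, axis=1, keepdims=True)


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n)
    z = 1 - (2 * i + 1) / n
    phi = np.pi * (1 + 5**0.5) * i
    r = np.sqrt(1 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _monopole_potential(electrodes: np.ndarray, sources: np.ndarray) -> np.ndarray:
    """Surface potential of unit point sources at ``sources`` (|r| < 1)."""
    b = np.linalg.norm(sources, axis=1)
    cos_theta = np.clip(electrodes @ (sources / b[:, None]).T, -1.0, 1.0)
    n = np.arange(1, _N_TERMS + 1)
    # sum_n (2n+1)/n * b^n * P_n(cos theta), accumulated per source column
    out = np.zeros_like(cos_theta)
    for j in range(sources.shape[0]):
        coef = np.zeros(_N_TERMS + 1)
        coef[1:] = (2 * n + 1) / n * b[j] ** n
        out[:, j] = np.polynomial.legendre.legval(cos_theta[:, j], coef)
    return out


@lru_cache(maxsize=8)
def lead_field(labels: tuple[str, ...]) -> np.ndarray:
    """Electrodes x sources lead field for a radial-dipole layer."""
    electrodes = electrode_positions(tuple(labels))
    src_dirs = _fibonacci_sphere(_N_SOURCES)
    src_dirs = src_dirs[src_dirs[:, 2] > _MIN_Z]
    eps = 0.02
    outer = src_dirs * (_SOURCE_RADIUS + eps / 2)
    inner = src_dirs * (_SOURCE_RADIUS - eps / 2)
    return (_monopole_potential(electrodes, outer) - _monopole_potential(electrodes, inner)) / eps


@lru_cache(maxsize=8)
def rest_transform(labels: tuple[str, ...]) -> np.ndarray:
    """The REST matrix T with V_rest = T @ V_average_referenced."""
    g = lead_field(tuple(labels))
    g_avg = g - g.mean(axis=0, keepdims=True)
    return g @ np.linalg.pinv(g_avg, rcond=1e-8)
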