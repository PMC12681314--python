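"""Brute-force discrete Fourier sums used as independent oracles."""

import numpy as np


def dft_forward(image: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Direct O(N^2 K) evaluation of sum_r x(r) exp(-2j pi k.r).

    Pixel offsets are centred on the grid midpoint (index N//2), matching
    the package's convention.
    """
    n = image.shape[-1]
    x = np.arange(n) - n // 2
    rx, ry = np.meshgrid(x, x, indexing="ij")
    out = np.empty(len(coords), dtype=complex)
    for m, k in enumerate(coords):
        out[m] = np.sum(image * np.exp(-2j * np.pi * (k[0] * rx + k[1] * ry)))
    return out


def dft_adjoint(samples: np.ndarray, coords: np.ndarray, grid_size: int) -> np.ndarray:
    """Direct adjoint: sum_k y(k) exp(+2j pi k.r) on the centred grid."""
    x = np.arange(grid_size) - grid_size // 2
    rx, ry = np.meshgrid(x, x, indexing="ij")
    out = np.zeros((grid_size, grid_size), dtype=complex)
    for m, k in enumerate(coords):
        out += samples[m] * np.exp(2j * np.pi * (k[0] * rx + k[1] * ry))
    return out
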