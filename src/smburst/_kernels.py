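"""Numba inner loops for the Brownian/photon hot paths.

These kernels only rearrange numbers handed to them; all random numbers are
drawn in bulk by numpy Generators in the calling modules, so results are
bit-reproducible for a given seed regardless of how work is chunked.
"""

from __future__ import annotations

import numba
import numpy as np


@numba.njit(cache=True)
def brownian_chunk(steps, start, box_half, out):
    """Accumulate displacements into periodically wrapped positions.

    steps    : (n_mol, n_steps, 3) float32, per-step displacements (μm)
    start    : (n_mol, 3) float64, position at the step before this chunk;
               overwritten in place with the final position (for the carry)
    box_half : (3,) float64, half box lengths (μm); box spans [-h, h)
    out      : (n_mol, n_steps, 3) float32, wrapped positions
    """
    n_mol, n_steps = steps.shape[0], steps.shape[1]
    for i in range(n_mol):
        for a in range(3):
            h = box_half[a]
            length = 2.0 * h
            x = start[i, a]
            for s in range(n_steps):
                x += steps[i, s, a]
                if x >= h:
                    x -= length
                elif x < -h:
                    x += length
                out[i, s, a] = x
            start[i, a] = x


@numba.njit(cache=True)
def unwrap_chunk(pos, prev, box_len, out):
    """Undo periodic wrapping by minimum-image continuity.

    pos     : (n_mol, n_steps, 3) float32 wrapped positions
    prev    : (n_mol, 3) float64 last *unwrapped* position before this chunk;
              overwritten with the final unwrapped position
    box_len : (3,) float64 box lengths (μm)
    out     : (n_mol, n_steps, 3) float64 unwrapped positions
    """
    n_mol, n_steps = pos.shape[0], pos.shape[1]
    for i in range(n_mol):
        for a in range(3):
            length = box_len[a]
            half = 0.5 * length
            x_prev_wrapped = prev[i, a] - length * np.round(prev[i, a] / length)
            x_unw = prev[i, a]
            for s in range(n_steps):
                d = pos[i, s, a] - x_prev_wrapped
                if d > half:
                    d -= length
                elif d < -half:
                    d += length
                x_unw += d
                x_prev_wrapped = pos[i, s, a]
                out[i, s, a] = x_unw
            prev[i, a] = x_unw


@numba.njit(cache=True)
def gaussian_emission(pos, inv_2s2, p_peak, u, out_mol, out_step):
    """Bernoulli thinning against a separable Gaussian detection profile.

    pos     : (n_mol, n_steps, 3) float32 positions (μm)
    inv_2s2 : (3,) float64, 1/(2σ²) per axis (1/μm²)
    p_peak  : per-step emission probability at the profile peak
    u       : (n_mol, n_steps) float32 uniform variates
    out_mol, out_step : preallocated int arrays collecting emissions

    Returns the number of photons written.  Positions with Gaussian exponent
    above 20 are skipped (emission probability < 2e-9 · p_peak).
    """
    n_mol, n_steps = pos.shape[0], pos.shape[1]
    k = 0
    for i in range(n_mol):
        for s in range(n_steps):
            x = pos[i, s, 0]
            y = pos[i, s, 1]
            z = pos[i, s, 2]
            q = x * x * inv_2s2[0] + y * y * inv_2s2[1] + z * z * inv_2s2[2]
            if q < 20.0:
                if u[i, s] < p_peak * np.exp(-q):
                    out_mol[k] = i
                    out_step[k] = s
                    k += 1
    return k
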