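"""Independent reference implementations used only as test oracles.

These deliberately use different algorithms from the package: crossing
counting by segment splitting and label compression, and superposition
RMSD by Horn's quaternion eigenvalue method.
"""
from __future__ import annotations

import numpy as np


def brute_force_crossings(z, lz, z_lo, z_hi):
    """Scan a single-ion z path for complete traversals.

    Returns a list of (frame_index, direction).  The path is split at
    periodic wraps (single-step |dz| > Lz/2); within each wrap-free
    segment, frames are labelled -1/0/+1 (below/inside/above), zeros are
    dropped, and every change of label in the compressed sequence is one
    crossing, completed at the first frame carrying the new label.
    """
    z = np.asarray(z, dtype=float)
    segments = []
    current = [0]
    for i in range(1, len(z)):
        if abs(z[i] - z[i - 1]) > lz / 2:
            segments.append(current)
            current = [i]
        else:
            current.append(i)
    segments.append(current)

    events = []
    for seg in segments:
        labelled = []
        for i in seg:
            if z[i] < z_lo:
                labelled.append((i, -1))
            elif z[i] > z_hi:
                labelled.append((i, +1))
        for (_, l0), (i1, l1) in zip(labelled, labelled[1:]):
            if l0 != l1:
                events.append((i1, l1))
    return events


def quaternion_rmsd(mobile, reference):
    """Minimum RMSD after optimal proper rotation, via Horn's quaternion
    eigenvalue method (no explicit rotation matrix is ever built)."""
    p = np.asarray(mobile, float)
    q = np.asarray(reference, float)
    p = p - p.mean(axis=0)
    q = q - q.mean(axis=0)
    s = p.T @ q  # S_ab = sum_i p_ia q_ib
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    key = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(key)[-1]
    residual = max((p * p).sum() + (q * q).sum() - 2.0 * lam, 0.0)
    return float(np.sqrt(residual / len(p)))


def random_z_walk(rng, n_steps, lz, step_sd=6.0):
    """A wrapped random z walk spanning the box, for detector fuzzing."""
    z = np.empty(n_steps)
    z[0] = rng.uniform(-lz / 2, lz / 2)
    steps = rng.normal(0.0, step_sd, n_steps - 1)
    # occasional large excursions so reservoirs and slab are all visited
    big = rng.random(n_steps - 1) < 0.05
    steps[big] *= 4.0
    raw = z[0] + np.cumsum(steps)
    z[1:] = raw
    # wrap into the primary cell (-lz/2, lz/2]
    z = z - lz * np.round(z / lz)
    return z
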