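"""Numba ray-tracing kernels for fan-beam (2D) and cone-beam (3D) projection.

Conventions shared by every kernel:

* world coordinates in mm, rotation isocenter at the origin;
* the source rotates counter-clockwise on a circle of radius ``sad``:
  at view angle ``a`` it sits at ``(sad*cos a, sad*sin a)``;
* the flat detector is centred on the source-isocenter line at distance
  ``sdd`` from the source, with tangential direction ``(-sin a, cos a)``
  and (in 3D) row direction along the rotation axis (volume axis 2);
* voxel centres are at ``origin + (index + 0.5) * pitch``, 0-based;
* the forward projector is pixel-driven: samples along each source->pixel
  ray at uniform step ``h`` with (bi/tri)linear interpolation, zero outside
  the grid, summed and scaled by ``h``;
* the back projector is voxel-driven: each voxel is projected onto the
  detector and the detector row is interpolated linearly (zero outside);
  with ``fbp_weight`` the contribution is scaled by ``sad^2 / w^2`` where
  ``w`` is the voxel's distance to the source along the central-ray axis.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def fan_forward(vol, o0, o1, pitch, angles, sad, sdd, dpitch, ndet, h, t_start, n_samples):
    nv = angles.shape[0]
    n0, n1 = vol.shape
    sino = np.zeros((nv, ndet))
    half = (ndet - 1) / 2.0
    for iv in range(nv):
        ca = math.cos(angles[iv])
        sa = math.sin(angles[iv])
        s0 = sad * ca
        s1 = sad * sa
        c0 = s0 - sdd * ca
        c1 = s1 - sdd * sa
        for u in range(ndet):
            su = (u - half) * dpitch
            p0 = c0 - su * sa
            p1 = c1 + su * ca
            d0 = p0 - s0
            d1 = p1 - s1
            inv = 1.0 / math.sqrt(d0 * d0 + d1 * d1)
            d0 *= inv
            d1 *= inv
            acc = 0.0
            for k in range(n_samples):
                t = t_start + k * h
                f0 = (s0 + t * d0 - o0) / pitch - 0.5
                f1 = (s1 + t * d1 - o1) / pitch - 0.5
                i0 = int(math.floor(f0))
                i1 = int(math.floor(f1))
                if i0 < -1 or i0 >= n0 or i1 < -1 or i1 >= n1:
                    continue
                w0 = f0 - i0
                w1 = f1 - i1
                v = 0.0
                if i0 >= 0 and i1 >= 0:
                    v += (1.0 - w0) * (1.0 - w1) * vol[i0, i1]
                if i0 >= 0 and i1 + 1 < n1:
                    v += (1.0 - w0) * w1 * vol[i0, i1 + 1]
                if i0 + 1 < n0 and i1 >= 0:
                    v += w0 * (1.0 - w1) * vol[i0 + 1, i1]
                if i0 + 1 < n0 and i1 + 1 < n1:
                    v += w0 * w1 * vol[i0 + 1, i1 + 1]
                acc += v
            sino[iv, u] = acc * h
    return sino


@njit(cache=True, fastmath=True)
def fan_back(sino, o0, o1, pitch, n0, n1, angles, sad, sdd, dpitch, fbp_weight):
    nv, ndet = sino.shape
    vol = np.zeros((n0, n1))
    half = (ndet - 1) / 2.0
    for iv in range(nv):
        ca = math.cos(angles[iv])
        sa = math.sin(angles[iv])
        row = sino[iv]
        for i0 in range(n0):
            x0 = o0 + (i0 + 0.5) * pitch
            for i1 in range(n1):
                x1 = o1 + (i1 + 0.5) * pitch
                w = sad - (ca * x0 + sa * x1)
                if w <= 1e-9:
                    continue
                su = sdd * (-sa * x0 + ca * x1) / w
                f = su / dpitch + half
                j = int(math.floor(f))
                if j < -1 or j >= ndet:
                    continue
                wf = f - j
                v = 0.0
                if j >= 0:
                    v += (1.0 - wf) * row[j]
                if j + 1 < ndet:
                    v += wf * row[j + 1]
                if fbp_weight:
                    v *= sad * sad / (w * w)
                vol[i0, i1] += v
    return vol


@njit(cache=True, fastmath=True)
def cone_forward(vol, o0, o1, o2, pitch, angles, sad, sdd, dpitch, nrow, ndet,
                 h, t_start, n_samples):
    nv = angles.shape[0]
    n0, n1, n2 = vol.shape
    sino = np.zeros((nv, nrow, ndet))
    half_u = (ndet - 1) / 2.0
    half_r = (nrow - 1) / 2.0
    for iv in range(nv):
        ca = math.cos(angles[iv])
        sa = math.sin(angles[iv])
        s0 = sad * ca
        s1 = sad * sa
        c0 = s0 - sdd * ca
        c1 = s1 - sdd * sa
        for r in range(nrow):
            pz = (r - half_r) * dpitch
            for u in range(ndet):
                su = (u - half_u) * dpitch
                p0 = c0 - su * sa
                p1 = c1 + su * ca
                d0 = p0 - s0
                d1 = p1 - s1
                d2 = pz
                inv = 1.0 / math.sqrt(d0 * d0 + d1 * d1 + d2 * d2)
                d0 *= inv
                d1 *= inv
                d2 *= inv
                acc = 0.0
                for k in range(n_samples):
                    t = t_start + k * h
                    f0 = (s0 + t * d0 - o0) / pitch - 0.5
                    f1 = (s1 + t * d1 - o1) / pitch - 0.5
                    f2 = (t * d2 - o2) / pitch - 0.5
                    i0 = int(math.floor(f0))
                    i1 = int(math.floor(f1))
                    i2 = int(math.floor(f2))
                    if (i0 < -1 or i0 >= n0 or i1 < -1 or i1 >= n1
                            or i2 < -1 or i2 >= n2):
                        continue
                    w0 = f0 - i0
                    w1 = f1 - i1
                    w2 = f2 - i2
                    v = 0.0
                    for b0 in range(2):
                        j0 = i0 + b0
                        if j0 < 0 or j0 >= n0:
                            continue
                        g0 = w0 if b0 == 1 else 1.0 - w0
                        for b1 in range(2):
                            j1 = i1 + b1
                            if j1 < 0 or j1 >= n1:
                                continue
                            g1 = w1 if b1 == 1 else 1.0 - w1
                            for b2 in range(2):
                                j2 = i2 + b2
                                if j2 < 0 or j2 >= n2:
                                    continue
                                g2 = w2 if b2 == 1 else 1.0 - w2
                                v += g0 * g1 * g2 * vol[j0, j1, j2]
                    acc += v
                sino[iv, r, u] = acc * h
    return sino


@njit(cache=True, fastmath=True)
def cone_back(sino, o0, o1, o2, pitch, n0, n1, n2, angles, sad, sdd, dpitch,
              fbp_weight):
    nv, nrow, ndet = sino.shape
    vol = np.zeros((n0, n1, n2))
    half_u = (ndet - 1) / 2.0
    half_r = (nrow - 1) / 2.0
    for iv in range(nv):
        ca = math.cos(angles[iv])
        sa = math.sin(angles[iv])
        view = sino[iv]
        for i0 in range(n0):
            x0 = o0 + (i0 + 0.5) * pitch
            for i1 in range(n1):
                x1 = o1 + (i1 + 0.5) * pitch
                w = sad - (ca * x0 + sa * x1)
                if w <= 1e-9:
                    continue
                mag = sdd / w
                su = mag * (-sa * x0 + ca * x1)
                fu = su / dpitch + half_u
                ju = int(math.floor(fu))
                if ju < -1 or ju >= ndet:
                    continue
                wu = fu - ju
                for i2 in range(n2):
                    x2 = o2 + (i2 + 0.5) * pitch
                    fr = mag * x2 / dpitch + half_r
                    jr = int(math.floor(fr))
                    if jr < -1 or jr >= nrow:
                        continue
                    wr = fr - jr
                    v = 0.0
                    if jr >= 0 and ju >= 0:
                        v += (1.0 - wr) * (1.0 - wu) * view[jr, ju]
                    if jr >= 0 and ju + 1 < ndet:
                        v += (1.0 - wr) * wu * view[jr, ju + 1]
                    if jr + 1 < nrow and ju >= 0:
                        v += wr * (1.0 - wu) * view[jr + 1, ju]
                    if jr + 1 < nrow and ju + 1 < ndet:
                        v += wr * wu * view[jr + 1, ju + 1]
                    if fbp_weight:
                        v *= sad * sad / (w * w)
                    vol[i0, i1, i2] += v
    return vol
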