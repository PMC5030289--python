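"""Numba kernel for voxelized photon transport (hop / drop / spin).

Implements the classic multilayer Monte Carlo photon loop on a 3-D
labeled voxel grid: exponential free paths in optical depth, sub-steps
clipped at voxel faces so each segment uses that voxel's interaction
coefficient, absorption weighting (dW = W mu_a / mu_t per collision),
Henyey-Greenstein deflection, and Russian roulette.  Fluence is scored
with a track-length estimator (sum of weight x segment length per
voxel), which is unbiased for the fluence rate and, unlike collision
scoring, has usable variance in nearly transparent media such as the
water column.

All lengths inside the kernel are in cm; coefficients in cm^-1.

The RNG is a counter-based splitmix64: every photon index gets its own
stream derived from (seed, index), so results are bit-reproducible for
a given seed regardless of batching.
"""

import numpy as np
from numba import njit

U64 = np.uint64
_PHI = U64(0x9E3779B97F4A7C15)
_M1 = U64(0xBF58476D1CE4E5B9)
_M2 = U64(0x94D049BB133111EB)

# Russian roulette: kill photons below WTHRESH with survival chance 1/M.
WTHRESH = 1e-4
ROULETTE_M = 10.0

# Source kinds understood by the kernel.
KIND_PENCIL = 0
KIND_DISK = 1
KIND_PLANE = 2

_BIG = 1e30
_MAX_EVENTS = 50_000_000


@njit(inline="always")
def _mix(z):
    z = (z ^ (z >> U64(30))) * _M1
    z = (z ^ (z >> U64(27))) * _M2
    return z ^ (z >> U64(31))


@njit(inline="always")
def _next(state):
    state = state + _PHI
    x = _mix(state)
    # uniform in (0, 1]
    return state, (np.float64(x >> U64(11)) + 1.0) * (1.0 / 9007199254740992.0)


@njit(inline="always")
def _hg_cos(u, g):
    if g != 0.0:
        tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    else:
        ct = 2.0 * u - 1.0
    if ct > 1.0:
        ct = 1.0
    elif ct < -1.0:
        ct = -1.0
    return ct


@njit(inline="always")
def _spin(ux, uy, uz, ct, psi):
    st = np.sqrt(max(0.0, 1.0 - ct * ct))
    cp = np.cos(psi)
    sp = np.sin(psi)
    if abs(uz) > 0.99999:
        nx = st * cp
        ny = st * sp
        nz = ct if uz >= 0.0 else -ct
    else:
        tmp = np.sqrt(1.0 - uz * uz)
        nx = st * (ux * uz * cp - uy * sp) / tmp + ux * ct
        ny = st * (uy * uz * cp + ux * sp) / tmp + uy * ct
        nz = -st * cp * tmp + uz * ct
    norm = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=False)
def run_transport(labels, mua_tab, mus_tab, g_tab,
                  dx, dy, dz,
                  src_kind, sx, sy, ux0, uy0, uz0, src_radius, src_gaussian,
                  n_photons, seed,
                  fluence, escape):
    """Trace n_photons through the grid; accumulate into fluence/escape.

    Returns (absorbed, escaped_top, escaped_other, residual) as raw
    weight sums (divide by n_photons for fractions of delivered power).
    """
    nx_, ny_, nz_ = labels.shape
    lx = nx_ * dx
    ly = ny_ * dy

    absorbed = 0.0
    esc_top = 0.0
    esc_other = 0.0
    residual = 0.0

    base = _mix(U64(seed) * _M1 + _PHI)

    for i in range(n_photons):
        state = _mix(base ^ (U64(i) * _PHI))

        # --- launch ---
        if src_kind == KIND_PENCIL:
            x = sx
            y = sy
        elif src_kind == KIND_DISK:
            state, u1 = _next(state)
            state, u2 = _next(state)
            if src_gaussian == 1:
                r = src_radius * np.sqrt(-np.log(u1) * 0.5)
            else:
                r = src_radius * np.sqrt(u1)
            psi = 2.0 * np.pi * u2
            x = sx + r * np.cos(psi)
            y = sy + r * np.sin(psi)
        else:  # plane wave over the full top face
            state, u1 = _next(state)
            state, u2 = _next(state)
            x = u1 * lx
            y = u2 * ly
        z = 0.0
        ux = ux0
        uy = uy0
        uz = uz0

        ix = int(x / dx)
        iy = int(y / dy)
        iz = 0
        if ix < 0 or ix >= nx_ or iy < 0 or iy >= ny_:
            esc_other += 1.0
            continue

        w = 1.0
        state, u = _next(state)
        s = -np.log(u)  # optical depth to next interaction
        events = 0

        while True:
            events += 1
            if events > _MAX_EVENTS:
                residual += w
                break
            lab = labels[ix, iy, iz]
            mua = mua_tab[lab]
            mut = mua + mus_tab[lab]

            interact = False
            d = 0.0
            if mut > 0.0:
                d = s / mut
                # undirected distance to the nearest face never exceeds
                # the ray distance to the boundary, so a free path inside
                # it is an interaction without computing the boundary
                safe = x - ix * dx
                tmp2 = (ix + 1) * dx - x
                if tmp2 < safe:
                    safe = tmp2
                tmp2 = y - iy * dy
                if tmp2 < safe:
                    safe = tmp2
                tmp2 = (iy + 1) * dy - y
                if tmp2 < safe:
                    safe = tmp2
                tmp2 = z - iz * dz
                if tmp2 < safe:
                    safe = tmp2
                tmp2 = (iz + 1) * dz - z
                if tmp2 < safe:
                    safe = tmp2
                if d <= safe:
                    interact = True

            if interact:
                fluence[ix, iy, iz] += w * d
                x += ux * d
                y += uy * d
                z += uz * d
                dwa = w * mua / mut
                absorbed += dwa
                w -= dwa
                if w <= 0.0:
                    break
                state, u = _next(state)
                ct = _hg_cos(u, g_tab[lab])
                state, u = _next(state)
                ux, uy, uz = _spin(ux, uy, uz, ct, 2.0 * np.pi * u)
                state, u = _next(state)
                s = -np.log(u)
                if w < WTHRESH:
                    state, u = _next(state)
                    if u <= 1.0 / ROULETTE_M:
                        residual -= w * (ROULETTE_M - 1.0)
                        w *= ROULETTE_M
                    else:
                        residual += w
                        break
                continue

            # distance to the nearest voxel face along the flight direction
            if ux > 0.0:
                tx = ((ix + 1) * dx - x) / ux
            elif ux < 0.0:
                tx = (ix * dx - x) / ux
            else:
                tx = _BIG
            if uy > 0.0:
                ty = ((iy + 1) * dy - y) / uy
            elif uy < 0.0:
                ty = (iy * dy - y) / uy
            else:
                ty = _BIG
            if uz > 0.0:
                tz = ((iz + 1) * dz - z) / uz
            elif uz < 0.0:
                tz = (iz * dz - z) / uz
            else:
                tz = _BIG
            if tx < 0.0:
                tx = 0.0
            if ty < 0.0:
                ty = 0.0
            if tz < 0.0:
                tz = 0.0
            db = tx
            axis = 0
            if ty < db:
                db = ty
                axis = 1
            if tz < db:
                db = tz
                axis = 2

            if mut > 0.0 and s <= db * mut:
                # interaction inside this voxel
                d = s / mut
                fluence[ix, iy, iz] += w * d
                x += ux * d
                y += uy * d
                z += uz * d
                dwa = w * mua / mut
                absorbed += dwa
                w -= dwa
                if w <= 0.0:
                    break
                state, u = _next(state)
                ct = _hg_cos(u, g_tab[lab])
                state, u = _next(state)
                ux, uy, uz = _spin(ux, uy, uz, ct, 2.0 * np.pi * u)
                state, u = _next(state)
                s = -np.log(u)
                if w < WTHRESH:
                    state, u = _next(state)
                    if u <= 1.0 / ROULETTE_M:
                        residual -= w * (ROULETTE_M - 1.0)
                        w *= ROULETTE_M
                    else:
                        residual += w
                        break
            else:
                # traverse to the voxel face and step into the neighbor
                fluence[ix, iy, iz] += w * db
                if mut > 0.0:
                    s -= db * mut
                x += ux * db
                y += uy * db
                z += uz * db
                if axis == 0:
                    if ux > 0.0:
                        ix += 1
                        x = ix * dx
                    else:
                        x = ix * dx
                        ix -= 1
                elif axis == 1:
                    if uy > 0.0:
                        iy += 1
                        y = iy * dy
                    else:
                        y = iy * dy
                        iy -= 1
                else:
                    if uz > 0.0:
                        iz += 1
                        z = iz * dz
                    else:
                        z = iz * dz
                        iz -= 1
                if iz < 0:
                    # escaped through the top face
                    exi = ix
                    eyi = iy
                    if exi < 0:
                        exi = 0
                    elif exi >= nx_:
                        exi = nx_ - 1
                    if eyi < 0:
                        eyi = 0
                    elif eyi >= ny_:
                        eyi = ny_ - 1
                    escape[exi, eyi] += w
                    esc_top += w
                    break
                if ix < 0 or ix >= nx_ or iy < 0 or iy >= ny_ or iz >= nz_:
                    esc_other += w
                    break

    return absorbed, esc_top, esc_other, residual
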