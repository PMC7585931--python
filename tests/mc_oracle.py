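"""Naive per-photon random-walk reference for the Monte-Carlo engine.

Pure-python re-implementation of the remittance path-length simulation,
following the same draw protocol and splitmix64 stream seeding as the
production kernel, so the two must agree bit-for-bit on any (optics,
n_photons, seed).  Kept deliberately simple and independent: plain
floats, no numpy in the inner loop.
"""

import math

MASK = (1 << 64) - 1
GOLDEN = 0x9E3779B97F4A7C15
MIX1 = 0xBF58476D1CE4E5B9
MIX2 = 0x94D049BB133111EB
STREAM_PRIME = 0xD2B74407B1CE6E93


def _stream_seed(seed, i):
    x = (seed ^ ((i + 1) * STREAM_PRIME)) & MASK
    x = ((x ^ (x >> 30)) * MIX1) & MASK
    x = ((x ^ (x >> 27)) * MIX2) & MASK
    return x ^ (x >> 31)


def _next(state):
    state = (state + GOLDEN) & MASK
    z = state
    z = ((z ^ (z >> 30)) * MIX1) & MASK
    z = ((z ^ (z >> 27)) * MIX2) & MASK
    z ^= z >> 31
    return state, (z >> 11) * (1.0 / 9007199254740992.0)


def naive_pathlength(mu_a, mu_s, g, n_photons, seed, max_steps=1_000_000,
                     wmin=1e-4, psurv=0.1):
    """Returns (mean_path, sum_w, n_detected) over remitted photons."""
    mu_t = mu_a + mu_s
    albedo = mu_s / mu_t
    sum_w = sum_wl = 0.0
    n_det = 0
    for i in range(n_photons):
        state = _stream_seed(seed, i)
        z = 0.0
        ux = uy = 0.0
        uz = 1.0
        w = 1.0
        path = 0.0
        detected = False
        for _ in range(max_steps):
            state, u = _next(state)
            s = -math.log(1.0 - u) / mu_t
            if uz < 0.0 and z + uz * s < 0.0:
                path += z / (-uz)
                detected = True
                break
            z += uz * s
            path += s
            w *= albedo
            if w < wmin:
                state, u = _next(state)
                if u < psurv:
                    w /= psurv
                else:
                    break
            state, u1 = _next(state)
            state, u2 = _next(state)
            if g == 0.0:
                cost = 2.0 * u1 - 1.0
            else:
                tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u1)
                cost = (1.0 + g * g - tmp * tmp) / (2.0 * g)
            cost = min(max(cost, -1.0), 1.0)
            sint = math.sqrt(1.0 - cost * cost)
            phi = 2.0 * math.pi * u2
            cosp = math.cos(phi)
            sinp = math.sin(phi)
            if abs(uz) > 0.99999:
                ux = sint * cosp
                uy = sint * sinp
                uz = cost if uz > 0.0 else -cost
            else:
                den = math.sqrt(1.0 - uz * uz)
                nux = sint * (ux * uz * cosp - uy * sinp) / den + ux * cost
                nuy = sint * (uy * uz * cosp + ux * sinp) / den + uy * cost
                nuz = -den * sint * cosp + uz * cost
                ux, uy, uz = nux, nuy, nuz
        if detected:
            sum_w += w
            sum_wl += w * path
            n_det += 1
    return (sum_wl / sum_w if sum_w > 0 else float("nan")), sum_w, n_det
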