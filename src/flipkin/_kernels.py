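"""Numba kernels for overdamped Langevin dynamics on tabulated landscapes.

The model free energy F (kcal/mol) and diffusivity D (rad^2/ps) are supplied
as dense periodic lookup tables over [0, 2*pi) (values of dF/dxi, D and
dD/dxi); kernels interpolate linearly with periodic wrap.  All kernels seed
numba's Mersenne generator internally, so results are bit-reproducible for a
given seed.

Euler-Maruyama update in the Ito convention, with the spurious-drift term
required for a position-dependent diffusivity:

    xi <- xi + [-beta D (F' + U') + D'] dt + sqrt(2 D dt) eta
"""

import numpy as np
from numba import njit

TWO_PI = 2.0 * np.pi


@njit(inline="always")
def _interp_periodic(tab, x):
    n = tab.shape[0]
    u = (x % TWO_PI) * (n / TWO_PI)
    i0 = int(u)
    if i0 >= n:
        i0 = n - 1
    frac = u - i0
    i1 = i0 + 1
    if i1 == n:
        i1 = 0
    return tab[i0] * (1.0 - frac) + tab[i1] * frac


@njit(inline="always")
def _wrap_pi(x):
    y = (x + np.pi) % TWO_PI
    return y - np.pi


@njit(cache=False)
def langevin_window(
    x0, n_equil, n_store, stride, dt, beta,
    fprime, d_tab, dprime,
    k_bias, center, biased, seed,
):
    """Single-walker trajectory; returns stored positions (rad).

    ``biased`` toggles the harmonic umbrella U = 1/2 k (xi - center)^2 with
    the periodic angular distance.
    """
    np.random.seed(seed)
    x = x0
    out = np.empty(n_store)
    n_total = n_equil + n_store * stride
    stored = 0
    for step in range(n_total):
        d = _interp_periodic(d_tab, x)
        fp = _interp_periodic(fprime, x)
        dp = _interp_periodic(dprime, x)
        up = k_bias * _wrap_pi(x - center) if biased else 0.0
        x += (-beta * d * (fp + up) + dp) * dt \
            + np.sqrt(2.0 * d * dt) * np.random.normal()
        if step >= n_equil and (step - n_equil) % stride == stride - 1:
            out[stored] = x
            stored += 1
            if stored == n_store:
                break
    return out


@njit(cache=False)
def campaign(
    centers, n_equil, n_store, stride, exchange_every, dt, beta,
    fprime, d_tab, dprime, k_bias, seed,
):
    """All umbrella walkers advanced together with neighbor exchanges.

    Walkers start at their window centers.  Every ``exchange_every`` steps,
    neighbor pairs of alternating parity attempt a configuration swap with
    Metropolis acceptance on the bias-energy change (the unbiased landscape
    energy cancels for a configuration swap).  Returns stored positions
    (n_windows, n_store), number of attempted and accepted swaps.
    """
    np.random.seed(seed)
    nw = centers.shape[0]
    x = centers.copy()
    out = np.empty((nw, n_store))
    n_total = n_equil + n_store * stride
    stored = 0
    attempts = 0
    accepts = 0
    parity = 0
    for step in range(n_total):
        for i in range(nw):
            xi = x[i]
            d = _interp_periodic(d_tab, xi)
            fp = _interp_periodic(fprime, xi)
            dp = _interp_periodic(dprime, xi)
            up = k_bias * _wrap_pi(xi - centers[i])
            x[i] = xi + (-beta * d * (fp + up) + dp) * dt \
                + np.sqrt(2.0 * d * dt) * np.random.normal()
        if exchange_every > 0 and step > 0 and step % exchange_every == 0:
            for i in range(parity, nw - 1, 2):
                j = i + 1
                di = _wrap_pi(x[i] - centers[i])
                dj = _wrap_pi(x[j] - centers[j])
                dij = _wrap_pi(x[j] - centers[i])
                dji = _wrap_pi(x[i] - centers[j])
                delta = 0.5 * k_bias * (
                    dij * dij + dji * dji - di * di - dj * dj
                )
                attempts += 1
                if delta <= 0.0 or np.random.random() < np.exp(-beta * delta):
                    tmp = x[i]
                    x[i] = x[j]
                    x[j] = tmp
                    accepts += 1
            parity = 1 - parity
        if step >= n_equil and (step - n_equil) % stride == stride - 1:
            for i in range(nw):
                out[i, stored] = x[i]
            stored += 1
            if stored == n_store:
                break
    return out, attempts, accepts


@njit(cache=False)
def first_passage(
    start, reflect, absorb, n_walkers, dt, beta,
    fprime, d_tab, dprime, max_steps, seed,
):
    """First-passage times (ps) of independent walkers from ``start`` to the
    absorbing boundary, mirrored at the reflecting boundary.

    Returns (times, n_censored); censored walkers carry time = max_steps*dt.
    """
    np.random.seed(seed)
    times = np.empty(n_walkers)
    censored = 0
    sign = 1.0 if absorb > reflect else -1.0
    for w in range(n_walkers):
        x = start
        t = 0.0
        done = False
        for _ in range(max_steps):
            d = _interp_periodic(d_tab, x)
            fp = _interp_periodic(fprime, x)
            dp = _interp_periodic(dprime, x)
            x += (-beta * d * fp + dp) * dt \
                + np.sqrt(2.0 * d * dt) * np.random.normal()
            t += dt
            if sign * (x - reflect) < 0.0:
                x = 2.0 * reflect - x     # mirror at the reflecting wall
            if sign * (x - absorb) >= 0.0:
                done = True
                break
        times[w] = t
        if not done:
            censored += 1
    return times, censored


@njit(cache=False)
def harmonic_restraint_traj(
    x0, n_equil, n_store, stride, dt, beta,
    k_ref, x_ref, lower, upper, k_restraint, d_aux, seed,
):
    """Auxiliary 1D coordinate (Angstrom) under a harmonic reference potential
    plus a flat-bottom restraint, constant diffusivity ``d_aux`` (A^2/ps)."""
    np.random.seed(seed)
    x = x0
    out = np.empty(n_store)
    n_total = n_equil + n_store * stride
    stored = 0
    for step in range(n_total):
        grad = k_ref * (x - x_ref)
        if x < lower:
            grad += k_restraint * (x - lower)
        elif x > upper:
            grad += k_restraint * (x - upper)
        x += -beta * d_aux * grad * dt + np.sqrt(2.0 * d_aux * dt) * np.random.normal()
        if step >= n_equil and (step - n_equil) % stride == stride - 1:
            out[stored] = x
            stored += 1
            if stored == n_store:
                break
    return out
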