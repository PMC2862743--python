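"""Numba kernels for the Brownian-dynamics line-scan simulator.

Coordinate conventions: the scanned line runs along x; the beam visits
pixel centers ``beam_x[p]`` for ``p = 0..n_pixels-1`` within each line and
then idles for the retrace dead time.  Particle positions are advanced by
one Gaussian step per pixel dwell while the beam is active and by one
lumped step over the retrace, so intensity samples see positions refreshed
at the dwell timescale.

The semi-permeable barrier is an infinitesimally thin plane at ``bx``
normal to x.  A proposed step whose x-path crosses the plane is accepted
with probability ``p_cross * sig_ref / s`` where ``s`` is the standard
deviation of the proposing step and ``sig_ref`` the smallest dwell-step
sigma in the system; otherwise, if the directional (active) channel is
enabled and the particle sits on its source side, the particle is captured
with probability ``p_active`` and released on the far side after an
exponentially distributed translocation dwell; otherwise the step is
reflected about the plane.  The ``1/s`` scaling is required for detailed
balance: the rate of crossing *attempts* from one side is proportional to
the step size there, so a side-independent acceptance would pump molecules
from the fast-diffusion side into the slow one.  With the scaling, equal
concentrations give equal fluxes for any D_left/D_right and any step
schedule.  Outer box walls always reflect (periodic wrap would teleport
molecules across the barrier).

All stochastic draws come from numba's global NumPy legacy RNG, seeded
once per kernel call, so a given seed reproduces trajectories bit-exactly.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# particle states
FREE = 0
TRANSLOCATING = 1

# event kinds
PASSIVE = 0
ACTIVE = 1


@njit(cache=True)
def _reflect(v, lo, hi):
    if v < lo:
        v = 2.0 * lo - v
    elif v > hi:
        v = 2.0 * hi - v
    return v


@njit(cache=True)
def _advance(
    x, y, z, slow, state, release_t,
    t_now, dt,
    sig_l, sig_r, sig_slow, sig_ref,
    xmin, xmax, ymin, ymax, zmin, zmax,
    has_barrier, bx, hw, p_cross,
    act_on, act_dir, p_act, trans_mean,
    ev_t, ev_dir, ev_kind, nev,
):
    """Advance every particle by one time step dt; returns event count.

    ``hw > 0`` turns the barrier into an impenetrable slab (void) of
    half-width ``hw``: each side reflects off its own face and nothing
    crosses -- the geometry of the gap between two adjacent cells.
    """
    n = x.size
    cap = ev_t.size
    t_end = t_now + dt
    for i in range(n):
        if state[i] == TRANSLOCATING:
            if t_end >= release_t[i]:
                # emerge on the destination side of the plane
                if act_dir == 1:
                    x[i] = bx + 1e-4
                else:
                    x[i] = bx - 1e-4
                state[i] = FREE
                if nev < cap:
                    ev_t[nev] = release_t[i]
                    ev_dir[nev] = act_dir
                    ev_kind[nev] = ACTIVE
                nev += 1
            continue
        if slow[i]:
            s = sig_slow
        elif has_barrier and x[i] >= bx:
            s = sig_r
        else:
            s = sig_l
        nx = x[i] + s * np.random.normal()
        ny = y[i] + s * np.random.normal()
        nz = z[i] + s * np.random.normal()
        if has_barrier and hw > 0.0:
            face = bx - hw if x[i] < bx else bx + hw
            if (x[i] < face) != (nx < face) or nx == face:
                nx = 2.0 * face - nx
        elif has_barrier and ((x[i] < bx) != (nx < bx)):
            going_right = x[i] < bx
            p_eff = p_cross * sig_ref / s if sig_ref > 0.0 else p_cross
            if np.random.random() < p_eff:
                # passive transmission
                if nev < cap:
                    ev_t[nev] = t_end
                    ev_dir[nev] = 1 if going_right else -1
                    ev_kind[nev] = PASSIVE
                nev += 1
            elif (
                act_on
                and ((act_dir == 1 and going_right) or (act_dir == -1 and not going_right))
                and np.random.random() < p_act
            ):
                # captured by the directional channel
                state[i] = TRANSLOCATING
                release_t[i] = t_end + np.random.exponential(trans_mean)
                x[i] = bx
                y[i] = _reflect(ny, ymin, ymax)
                z[i] = _reflect(nz, zmin, zmax)
                continue
            else:
                nx = 2.0 * bx - nx  # reflected off the barrier plane
        x[i] = _reflect(nx, xmin, xmax)
        y[i] = _reflect(ny, ymin, ymax)
        z[i] = _reflect(nz, zmin, zmax)
    return nev


@njit(cache=True)
def run_scan(
    seed,
    x, y, z, slow, state, release_t,
    n_burn_lines, n_lines, n_pixels,
    dwell, retrace,
    beam_x,
    sig_dw_l, sig_dw_r, sig_dw_slow, sig_ref,
    sig_rt_l, sig_rt_r, sig_rt_slow,
    xmin, xmax, ymin, ymax, zmin, zmax,
    has_barrier, bx, hw, p_cross,
    act_on, act_dir, p_act, trans_mean,
    inv2w0sq, inv2wzsq, trunc_r, trunc_z,
    brightness, background, do_intensity,
    intensity, occ_left, occ_right, occ_trans,
    ev_t, ev_dir, ev_kind,
):
    """Full line-scan simulation; fills intensity/occupancy, returns n_events.

    Lines ``0..n_burn_lines-1`` are burn-in: particles move and cross but
    nothing is recorded.  Event times are absolute simulation times
    (burn-in included); the caller rebases them to the recording start.
    """
    np.random.seed(seed)
    n = x.size
    nev = 0
    t = 0.0
    total = n_burn_lines + n_lines
    for l in range(total):
        rec = l >= n_burn_lines
        row = l - n_burn_lines
        for p in range(n_pixels):
            nev = _advance(
                x, y, z, slow, state, release_t,
                t, dwell,
                sig_dw_l, sig_dw_r, sig_dw_slow, sig_ref,
                xmin, xmax, ymin, ymax, zmin, zmax,
                has_barrier, bx, hw, p_cross,
                act_on, act_dir, p_act, trans_mean,
                ev_t, ev_dir, ev_kind, nev,
            )
            t += dwell
            if rec and do_intensity:
                bxp = beam_x[p]
                s = 0.0
                for i in range(n):
                    dx = x[i] - bxp
                    if -trunc_r < dx < trunc_r:
                        yy = y[i]
                        if -trunc_r < yy < trunc_r:
                            zz = z[i]
                            if -trunc_z < zz < trunc_z:
                                s += np.exp(
                                    -(dx * dx + yy * yy) * inv2w0sq
                                    - zz * zz * inv2wzsq
                                )
                intensity[row, p] = background + brightness * s
        if retrace > 0.0:
            nev = _advance(
                x, y, z, slow, state, release_t,
                t, retrace,
                sig_rt_l, sig_rt_r, sig_rt_slow, sig_ref,
                xmin, xmax, ymin, ymax, zmin, zmax,
                has_barrier, bx, hw, p_cross,
                act_on, act_dir, p_act, trans_mean,
                ev_t, ev_dir, ev_kind, nev,
            )
            t += retrace
        if rec:
            nl = 0
            nr = 0
            nt = 0
            for i in range(n):
                if state[i] == TRANSLOCATING:
                    nt += 1
                elif has_barrier and x[i] >= bx:
                    nr += 1
                else:
                    nl += 1
            occ_left[row] = nl
            occ_right[row] = nr
            occ_trans[row] = nt
    return nev


@njit(cache=True)
def first_passage_1d(
    seed,
    n_rep,
    x0,
    bx,
    xmin, xmax,
    n_pixels,
    dwell, retrace,
    sig_dw_l, sig_dw_r, sig_rt_l, sig_rt_r, sig_ref,
    p_cross,
    act_on, act_dir, p_act, trans_mean,
    horizon_s,
):
    """First-passage times across the barrier for independent walkers.

    Only the x coordinate matters for barrier crossing, so each replicate
    is a 1-D walk using the *same* step schedule as the scan kernel
    (n_pixels dwell steps then one retrace step per line).  An active
    capture counts as a passage at its release time.  Censored replicates
    (no passage within the horizon) return NaN.
    """
    np.random.seed(seed)
    out = np.empty(n_rep)
    for r in range(n_rep):
        xx = x0
        t = 0.0
        t_cross = np.nan
        while t < horizon_s:
            for k in range(n_pixels + 1):
                if k < n_pixels:
                    dt = dwell
                    s = sig_dw_l if xx < bx else sig_dw_r
                else:
                    dt = retrace
                    if dt <= 0.0:
                        continue
                    s = sig_rt_l if xx < bx else sig_rt_r
                nx = xx + s * np.random.normal()
                if (xx < bx) != (nx < bx):
                    going_right = xx < bx
                    p_eff = p_cross * sig_ref / s if sig_ref > 0.0 else p_cross
                    if np.random.random() < p_eff:
                        t_cross = t + dt
                        break
                    elif (
                        act_on
                        and (
                            (act_dir == 1 and going_right)
                            or (act_dir == -1 and not going_right)
                        )
                        and np.random.random() < p_act
                    ):
                        t_cross = t + dt + np.random.exponential(trans_mean)
                        break
                    else:
                        nx = 2.0 * bx - nx
                xx = _reflect(nx, xmin, xmax)
                t += dt
            if not np.isnan(t_cross):
                break
        out[r] = t_cross
    return out
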