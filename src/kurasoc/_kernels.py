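"""Numba-compiled inner loops for long closed-loop simulations.

These kernels mirror the reference implementations in :mod:`kurasoc.network`
and :mod:`kurasoc.embodiment` step for step (a regression test asserts the
two paths produce identical trajectories).  All randomness inside a kernel
(light blinking, decoupled sensor noise) is driven by an explicit integer
seed passed by the caller.

Integration order per control step (simultaneous forward Euler): the lit
flags and sensor drives, the relational phases/plasticity levels and the
motor speeds are all evaluated on the state at time t, then phases, weights
and pose advance together to t + dt.
"""

from __future__ import annotations

import numpy as np
from numba import njit

TWO_PI = 2.0 * np.pi
BLINK_PROB = 0.15


@njit(cache=True)
def _fmap(x):
    """Weight mapping F: sinusoidal lobe gated by a half-frequency positive
    square wave, exactly zero on alternating half-periods, continuous."""
    if np.sin(0.5 * x) > 0.0:
        return 0.5 * (1.0 - np.cos(x))
    return 0.0


@njit(cache=True)
def _wrap_pi(x):
    return (x + np.pi) % TWO_PI - np.pi


@njit(cache=True)
def _plast(x, h1, h2):
    ax = abs(x)
    if h1 == h2:
        return 1.0 if ax >= h1 else 0.0
    v = (ax - h1) / (h2 - h1)
    if v < 0.0:
        v = 0.0
    elif v > 1.0:
        v = 1.0
    return v


@njit(cache=True)
def _compute_phi_p(theta, dk, phi, p, phi0, alpha, h1, h2, k):
    """Refresh couplings, relational phases and plasticity levels in place.

    phi entries whose complex sum is degenerate (all incoming couplings
    zero) keep their previous value.
    """
    for i in range(3):
        for j in range(3):
            k[i, j] = 0.0 if i == j else alpha[i] * _fmap(dk[i, j])
    for i in range(3):
        zr = 0.0
        zi = 0.0
        for j in range(3):
            d = theta[j] - theta[i]
            zr += k[i, j] * np.cos(d)
            zi += k[i, j] * np.sin(d)
        if zr * zr + zi * zi > 1e-24:
            phi[i] = np.arctan2(zi, zr)
        p[i] = _plast(_wrap_pi(phi[i] - phi0[i]), h1, h2)


@njit(cache=True)
def _advance_network(theta, dk, p, omega, phi0, eta, k, i1, i2, dt):
    """Forward-Euler update of theta and dK using time-t couplings/plasticity."""
    d0 = omega[0] + i1
    d1 = omega[1] + i2
    d2 = omega[2]
    for j in range(3):
        d0 += k[0, j] * np.sin(theta[j] - theta[0])
        d1 += k[1, j] * np.sin(theta[j] - theta[1])
        d2 += k[2, j] * np.sin(theta[j] - theta[2])
    for i in range(3):
        if p[i] > 0.0:
            for j in range(3):
                if i != j:
                    dk[i, j] += dt * eta[i, j] * p[i] * np.sin((theta[j] - theta[i]) - phi0[i])
    theta[0] = (theta[0] + dt * d0) % TWO_PI
    theta[1] = (theta[1] + dt * d1) % TWO_PI
    theta[2] = (theta[2] + dt * d2) % TWO_PI


@njit(cache=True)
def _sensor_drive(x, y, h, lpos, ltype, lit, sgain, radius, sensor_ang, sa, sb):
    """Summed sensor inputs (I1 for type-A lights, I2 for type-B lights).

    Sensors sit on the body perimeter at +-sensor_ang from heading and point
    outward along that direction; activation is cosine-tuned in angle (gated
    at |angle| > pi/2) with a logistic distance falloff.
    """
    i1 = 0.0
    i2 = 0.0
    for li in range(lpos.shape[0]):
        if not lit[li]:
            continue
        t = ltype[li]
        for side in range(2):  # 0 = right, 1 = left
            ang = h - sensor_ang if side == 0 else h + sensor_ang
            sx = x + radius * np.cos(ang)
            sy = y + radius * np.sin(ang)
            dx = lpos[li, 0] - sx
            dy = lpos[li, 1] - sy
            d = np.sqrt(dx * dx + dy * dy)
            al = _wrap_pi(np.arctan2(dy, dx) - ang)
            if abs(al) <= 0.5 * np.pi:
                v = 0.5 * (1.0 + np.cos(al)) / (1.0 + np.exp(sa * (d - sb)))
                g = sgain[2 * t + side]
                if t == 0:
                    i1 += g * v
                else:
                    i2 += g * v
    return i1, i2


@njit(cache=True)
def run_trial_kernel(
    omega, phi0, eta, alpha, h1, h2,
    sgain, phir, phil, radius, sensor_ang, sa, sb, motor_gain,
    theta, dk, phi, p, pose,
    lpos, ltype, lblink, blink_seed,
    n_steps, dt, capture_radius, near_radius, target,
    meansin, theta_out, rec_theta, rec_stride,
    p_out, pose_out, dist_out, rec_full,
):
    """Closed-loop trial: sensors -> network -> motors -> kinematics.

    State arrays (theta, dk, phi, p, pose) are advanced in place so trials
    chain seamlessly.  meansin receives (1/3) sum_i sin(theta_i) every step;
    optional buffers record theta / p / pose / light distances at
    ``rec_stride``.  With capture_radius > 0 the trial ends as soon as the
    body center is within that radius of a light (checked before stepping,
    so a trial can terminate at t = 0).

    Returns (steps_done, d_init_target, d_final_target, near_count,
    homeo_sum, d_final_A, d_final_B, captured_light_index,
    blink_lit_count, blink_draw_count).
    """
    np.random.seed(blink_seed)
    nl = lpos.shape[0]
    lit = np.ones(nl, np.bool_)
    k = np.zeros((3, 3))
    dist = np.zeros(2)
    near = 0
    homeo = 0.0
    captured = -1
    d0t = 1.0
    blink_lit = 0
    blink_draws = 0
    steps = n_steps
    for step in range(n_steps):
        x = pose[0]
        y = pose[1]
        hd = pose[2]
        for li in range(nl):
            dx = lpos[li, 0] - x
            dy = lpos[li, 1] - y
            dist[ltype[li]] = np.sqrt(dx * dx + dy * dy)
            if lblink[li]:
                lit[li] = np.random.random() < BLINK_PROB
                blink_draws += 1
                if lit[li]:
                    blink_lit += 1
        if step == 0:
            d0t = dist[target]
        if capture_radius > 0.0:
            for li in range(nl):
                if dist[ltype[li]] < capture_radius:
                    captured = ltype[li]
            if captured >= 0:
                steps = step
                break
        i1, i2 = _sensor_drive(x, y, hd, lpos, ltype, lit, sgain, radius, sensor_ang, sa, sb)
        _compute_phi_p(theta, dk, phi, p, phi0, alpha, h1, h2, k)
        meansin[step] = (np.sin(theta[0]) + np.sin(theta[1]) + np.sin(theta[2])) / 3.0
        if step % rec_stride == 0:
            r = step // rec_stride
            if rec_theta:
                theta_out[r, 0] = theta[0]
                theta_out[r, 1] = theta[1]
                theta_out[r, 2] = theta[2]
            if rec_full:
                p_out[r, 0] = p[0]
                p_out[r, 1] = p[1]
                p_out[r, 2] = p[2]
                pose_out[r, 0] = x
                pose_out[r, 1] = y
                pose_out[r, 2] = hd
                dist_out[r, 0] = dist[0]
                dist_out[r, 1] = dist[1]
        homeo += 1.0 - (p[0] + p[1] + p[2]) / 3.0
        if dist[target] < near_radius:
            near += 1
        mr = motor_gain * np.sin(phi[2] - phir)
        ml = motor_gain * np.sin(phi[2] - phil)
        _advance_network(theta, dk, p, omega, phi0, eta, k, i1, i2, dt)
        v = 0.5 * (mr + ml)
        w = (mr - ml) / (2.0 * radius)
        pose[0] = x + dt * v * np.cos(hd)
        pose[1] = y + dt * v * np.sin(hd)
        pose[2] = (hd + dt * w) % TWO_PI
    # final distances from the final pose
    dfa = -1.0
    dfb = -1.0
    for li in range(nl):
        dx = lpos[li, 0] - pose[0]
        dy = lpos[li, 1] - pose[1]
        dd = np.sqrt(dx * dx + dy * dy)
        if ltype[li] == 0:
            dfa = dd
        else:
            dfb = dd
    dft = dfa if target == 0 else dfb
    return steps, d0t, dft, near, homeo, dfa, dfb, captured, blink_lit, blink_draws


@njit(cache=True)
def run_decoupled_kernel(
    omega, phi0, eta, alpha, h1, h2,
    sgain, sigma, noise_seed,
    theta, dk, phi, p,
    n_steps, dt,
    meansin, theta_out, rec_theta, rec_stride,
):
    """Environment-free run: each of the four sensor channels receives i.i.d.
    Gaussian(0, sigma) noise every step, applied before the evolved gains."""
    np.random.seed(noise_seed)
    k = np.zeros((3, 3))
    for step in range(n_steps):
        i1 = sgain[0] * sigma * np.random.standard_normal() + sgain[1] * sigma * np.random.standard_normal()
        i2 = sgain[2] * sigma * np.random.standard_normal() + sgain[3] * sigma * np.random.standard_normal()
        _compute_phi_p(theta, dk, phi, p, phi0, alpha, h1, h2, k)
        meansin[step] = (np.sin(theta[0]) + np.sin(theta[1]) + np.sin(theta[2])) / 3.0
        if rec_theta and step % rec_stride == 0:
            r = step // rec_stride
            theta_out[r, 0] = theta[0]
            theta_out[r, 1] = theta[1]
            theta_out[r, 2] = theta[2]
        _advance_network(theta, dk, p, omega, phi0, eta, k, i1, i2, dt)
    return n_steps
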