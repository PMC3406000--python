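"""Compiled inner loop of the Brownian dynamics propagator.

Everything here mirrors the reference implementations in ``bd_engine``
(step) and ``electrostatics`` (trilinear interpolation, finite-difference
forces) but runs under numba for the ensemble workloads. State is carried
in small preallocated arrays that the python driver owns.
"""

import numpy as np
from numba import njit

# status codes returned by _propagate
NOISE_EXHAUSTED = 0
ESCAPE = 1
TIMEOUT = 2


@njit(cache=True, fastmath=False)
def _tri(values, ox, oy, oz, inv_h, x, y, z):
    fx = (x - ox) * inv_h
    fy = (y - oy) * inv_h
    fz = (z - oz) * inv_h
    nx, ny, nz = values.shape
    if fx < 0.0 or fy < 0.0 or fz < 0.0 or fx > nx - 1 or fy > ny - 1 or fz > nz - 1:
        raise ValueError("bead outside grid during BD propagation")
    ix = min(int(fx), nx - 2)
    iy = min(int(fy), ny - 2)
    iz = min(int(fz), nz - 2)
    tx = fx - ix
    ty = fy - iy
    tz = fz - iz
    c00 = values[ix, iy, iz] * (1 - tx) + values[ix + 1, iy, iz] * tx
    c10 = values[ix, iy + 1, iz] * (1 - tx) + values[ix + 1, iy + 1, iz] * tx
    c01 = values[ix, iy, iz + 1] * (1 - tx) + values[ix + 1, iy, iz + 1] * tx
    c11 = values[ix, iy + 1, iz + 1] * (1 - tx) + values[ix + 1, iy + 1, iz + 1] * tx
    return (c00 * (1 - ty) + c10 * ty) * (1 - tz) + (c01 * (1 - ty) + c11 * ty) * tz


@njit(cache=True, fastmath=False)
def _energy(px, py, pz, R, beads, charges, pot, pox, poy, poz, pih,
            des, has_des):
    u = 0.0
    n = beads.shape[0]
    for i in range(n):
        bx = R[0, 0] * beads[i, 0] + R[0, 1] * beads[i, 1] + R[0, 2] * beads[i, 2] + px
        by = R[1, 0] * beads[i, 0] + R[1, 1] * beads[i, 1] + R[1, 2] * beads[i, 2] + py
        bz = R[2, 0] * beads[i, 0] + R[2, 1] * beads[i, 1] + R[2, 2] * beads[i, 2] + pz
        q = charges[i]
        u += q * _tri(pot, pox, poy, poz, pih, bx, by, bz)
        if has_des:
            u += q * q * _tri(des, pox, poy, poz, pih, bx, by, bz)
    return u


@njit(cache=True, fastmath=False)
def _quat_to_matrix(q, R):
    x, y, z, w = q[0], q[1], q[2], q[3]
    R[0, 0] = 1 - 2 * (y * y + z * z)
    R[0, 1] = 2 * (x * y - z * w)
    R[0, 2] = 2 * (x * z + y * w)
    R[1, 0] = 2 * (x * y + z * w)
    R[1, 1] = 1 - 2 * (x * x + z * z)
    R[1, 2] = 2 * (y * z - x * w)
    R[2, 0] = 2 * (x * z - y * w)
    R[2, 1] = 2 * (y * z + x * w)
    R[2, 2] = 1 - 2 * (x * x + y * y)


@njit(cache=True, fastmath=False)
def _quat_mul_rotvec(q, vx, vy, vz, out):
    """out = q * quat(rotvec v): compose a body-frame rotation."""
    angle = np.sqrt(vx * vx + vy * vy + vz * vz)
    if angle < 1e-300:
        for k in range(4):
            out[k] = q[k]
        return
    s = np.sin(angle / 2.0) / angle
    x2, y2, z2, w2 = vx * s, vy * s, vz * s, np.cos(angle / 2.0)
    x1, y1, z1, w1 = q[0], q[1], q[2], q[3]
    out[0] = w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2
    out[1] = w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2
    out[2] = w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2
    out[3] = w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2
    norm = np.sqrt(out[0] ** 2 + out[1] ** 2 + out[2] ** 2 + out[3] ** 2)
    for k in range(4):
        out[k] /= norm


@njit(cache=True, fastmath=False)
def _force_torque(px, py, pz, R, beads, charges, pot, pox, poy, poz, pih,
                  des, has_des, dtr, drot, F, T):
    """Central-difference force (lab frame) and torque (body axes)."""
    # translations
    F[0] = -(_energy(px + dtr, py, pz, R, beads, charges, pot, pox, poy, poz, pih, des, has_des)
             - _energy(px - dtr, py, pz, R, beads, charges, pot, pox, poy, poz, pih, des, has_des)) / (2 * dtr)
    F[1] = -(_energy(px, py + dtr, pz, R, beads, charges, pot, pox, poy, poz, pih, des, has_des)
             - _energy(px, py - dtr, pz, R, beads, charges, pot, pox, poy, poz, pih, des, has_des)) / (2 * dtr)
    F[2] = -(_energy(px, py, pz + dtr, R, beads, charges, pot, pox, poy, poz, pih, des, has_des)
             - _energy(px, py, pz - dtr, R, beads, charges, pot, pox, poy, poz, pih, des, has_des)) / (2 * dtr)
    # rotations about body axes: R' = R @ Rk(+-drot)
    c = np.cos(drot)
    s = np.sin(drot)
    Rp = np.empty((3, 3))
    for axis in range(3):
        up = 0.0
        for sign in range(2):
            ss = s if sign == 0 else -s
            for a in range(3):
                for b in range(3):
                    Rp[a, b] = 0.0
            if axis == 0:
                rot = ((1.0, 0.0, 0.0), (0.0, c, -ss), (0.0, ss, c))
            elif axis == 1:
                rot = ((c, 0.0, ss), (0.0, 1.0, 0.0), (-ss, 0.0, c))
            else:
                rot = ((c, -ss, 0.0), (ss, c, 0.0), (0.0, 0.0, 1.0))
            for a in range(3):
                for b in range(3):
                    acc = 0.0
                    for k in range(3):
                        acc += R[a, k] * rot[k][b]
                    Rp[a, b] = acc
            u = _energy(px, py, pz, Rp, beads, charges, pot, pox, poy, poz, pih, des, has_des)
            if sign == 0:
                up = u
            else:
                T[axis] = -(up - u) / (2 * drot)


@njit(cache=True, fastmath=False)
def _min_bead_z(R, beads):
    m = 1e300
    for i in range(beads.shape[0]):
        bz = R[2, 0] * beads[i, 0] + R[2, 1] * beads[i, 1] + R[2, 2] * beads[i, 2]
        if bz < m:
            m = bz
    return m


@njit(cache=True, fastmath=False)
def _propagate(pos, quat, time_arr, beads, charges,
               pot, pox, poy, poz, pih, des, has_des,
               dt_near, dt_far, switch_z, q_radius, z_surf, contact_height,
               max_time, sample_interval, D_t, D_r, dtr, drot, noise_scale,
               pip3_x, pip3_y, pip3_z, ref_vec,
               noise, samples, counters, next_sample, fe):
    """Advance one trajectory until noise runs out or it terminates.

    counters[0] = number of samples written; fe = [flag, r, d, theta];
    returns a status code.
    """
    R = np.empty((3, 3))
    F = np.empty(3)
    T = np.empty(3)
    qtmp = np.empty(4)
    n_noise = noise.shape[0]
    t = time_arr[0]
    for istep in range(n_noise):
        dt = dt_near if pos[2] < switch_z else dt_far
        _quat_to_matrix(quat, R)
        _force_torque(pos[0], pos[1], pos[2], R, beads, charges,
                      pot, pox, poy, poz, pih, des, has_des, dtr, drot, F, T)
        sig_t = noise_scale * np.sqrt(2.0 * D_t * dt)
        sig_r = noise_scale * np.sqrt(2.0 * D_r * dt)
        pos[0] += D_t * dt * F[0] + sig_t * noise[istep, 0]
        pos[1] += D_t * dt * F[1] + sig_t * noise[istep, 1]
        pos[2] += D_t * dt * F[2] + sig_t * noise[istep, 2]
        wx = D_r * dt * T[0] + sig_r * noise[istep, 3]
        wy = D_r * dt * T[1] + sig_r * noise[istep, 4]
        wz = D_r * dt * T[2] + sig_r * noise[istep, 5]
        _quat_mul_rotvec(quat, wx, wy, wz, qtmp)
        for k in range(4):
            quat[k] = qtmp[k]
        _quat_to_matrix(quat, R)
        m = _min_bead_z(R, beads)
        # reflecting wall at the upper-leaflet plane
        if pos[2] + m < z_surf:
            pos[2] = 2.0 * (z_surf - m) - pos[2]
        t += dt
        time_arr[0] = t

        # steering coordinates of the current pose
        dx = pos[0] - pip3_x
        dy = pos[1] - pip3_y
        r = np.sqrt(dx * dx + dy * dy)
        d = pos[2] - pip3_z
        rz = -(R[2, 0] * ref_vec[0] + R[2, 1] * ref_vec[1] + R[2, 2] * ref_vec[2])
        if rz > 1.0:
            rz = 1.0
        elif rz < -1.0:
            rz = -1.0
        theta = np.degrees(np.arccos(rz))

        # first encounter: lowest bead within contact_height of the surface
        if fe[0] == 0.0 and (pos[2] + m - z_surf) <= contact_height:
            fe[0] = 1.0
            fe[1] = r
            fe[2] = d
            fe[3] = theta

        if t >= next_sample[0] - 1e-9:
            k = int(counters[0])
            if k < samples.shape[0]:
                samples[k, 0] = t
                samples[k, 1] = r
                samples[k, 2] = d
                samples[k, 3] = theta
                counters[0] = k + 1
            while next_sample[0] <= t + 1e-9:
                next_sample[0] += sample_interval

        if pos[0] ** 2 + pos[1] ** 2 + pos[2] ** 2 >= q_radius * q_radius:
            return ESCAPE
        if t >= max_time - 1e-9:
            return TIMEOUT
    return NOISE_EXHAUSTED
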