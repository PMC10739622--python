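"""Independent brute-force reference implementations.

Every function here recomputes an operation with naive explicit loops and no
shared code with the package internals (beyond basic numpy indexing), so the
vectorized implementations can be checked against them on small instances.
"""

import numpy as np


def ann_forward_loops(w1, b1, w2, b2, x):
    """Two-layer forward pass, one multiply at a time."""
    n_hid, n_inp = w1.shape
    n_out = w2.shape[0]
    h = np.zeros(n_hid)
    for i in range(n_hid):
        s = b1[i]
        for j in range(n_inp):
            s += w1[i, j] * x[j]
        h[i] = s if s > 0 else 0.0
    out = np.zeros(n_out)
    for i in range(n_out):
        s = b2[i]
        for j in range(n_hid):
            s += w2[i, j] * h[j]
        out[i] = s
    return out


def denoise_frame_loops(model, z):
    """One cascade pass of the patch denoiser, voxel by voxel."""
    sc = model.scaling
    gmax = z.max()
    if gmax <= 0:
        return z.copy()
    zn = z / gmax
    pad = np.pad(zn, 1, mode="edge")
    acc = np.zeros(pad.shape)
    cov = np.zeros(pad.shape)
    nx, ny, nz = pad.shape
    for ox in range(nx - 3):
        for oy in range(ny - 3):
            for oz in range(nz - 3):
                patch = pad[ox : ox + 4, oy : oy + 4, oz : oz + 4]
                vec = patch.reshape(64).astype(float)
                mean = vec.mean()
                centered = vec - mean
                span = sc.input_max - sc.input_min
                xs = np.where(
                    span > 0, 2.0 * (centered - sc.input_min) / np.where(span > 0, span, 1.0) - 1.0, 0.0
                )
                ys = ann_forward_loops(model.w1, model.b1, model.w2, model.b2, xs)
                lspan = sc.label_max - sc.label_min
                out = np.where(
                    lspan > 0, (ys + 1.0) * 0.5 * lspan + sc.label_min, sc.label_min
                )
                out = out + mean
                block = out.reshape(2, 2, 2)
                acc[ox + 1 : ox + 3, oy + 1 : oy + 3, oz + 1 : oz + 3] += block
                cov[ox + 1 : ox + 3, oy + 1 : oy + 3, oz + 1 : oz + 3] += 1.0
    result = acc[1:-1, 1:-1, 1:-1] / cov[1:-1, 1:-1, 1:-1]
    return result * gmax


def box_filter_loops(vol, size):
    """Mean over the clamped size³ neighborhood, voxel by voxel."""
    r = size // 2
    nx, ny, nz = vol.shape
    out = np.zeros_like(vol, dtype=float)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                s = 0.0
                for dx in range(-r, r + 1):
                    for dy in range(-r, r + 1):
                        for dz in range(-r, r + 1):
                            cx = min(max(x + dx, 0), nx - 1)
                            cy = min(max(y + dy, 0), ny - 1)
                            cz = min(max(z + dz, 0), nz - 1)
                            s += vol[cx, cy, cz]
                out[x, y, z] = s / size**3
    return out


def hypr_loops(frames, durations, size):
    """Literal three-step HYPR: composite, ratio weighting, multiplication."""
    comp = np.zeros(frames.shape[:3])
    for i in range(frames.shape[-1]):
        comp += durations[i] * frames[..., i]
    comp /= durations.sum()
    fc = box_filter_loops(comp, size)
    out = np.empty_like(frames, dtype=float)
    for i in range(frames.shape[-1]):
        w = box_filter_loops(frames[..., i], size) / fc
        out[..., i] = comp * w
    return out


def nlm_st_loops(frames, search_spatial, search_frames, nbhd_spatial, nbhd_frames, h_t, window_frames):
    """Quadruple-loop spatiotemporal NLM.

    h_t — per-target-frame smoothing bandwidth; window_frames — list of
    candidate-frame index arrays per target frame.
    """
    nx, ny, nz, nt = frames.shape
    rs = search_spatial // 2
    rn = nbhd_spatial // 2
    rtn = nbhd_frames // 2

    def clamp(v, n):
        return min(max(v, 0), n - 1)

    out = np.zeros_like(frames, dtype=float)
    for t in range(nt):
        cand_frames = window_frames[t]
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    acc = 0.0
                    wsum = 0.0
                    for f in cand_frames:
                        for dx in range(-rs, rs + 1):
                            for dy in range(-rs, rs + 1):
                                for dz in range(-rs, rs + 1):
                                    d2 = 0.0
                                    cnt = 0
                                    for nt_off in range(-rtn, rtn + 1):
                                        a = clamp(t + nt_off, nt)
                                        b = clamp(f + nt_off, nt)
                                        for ex in range(-rn, rn + 1):
                                            for ey in range(-rn, rn + 1):
                                                for ez in range(-rn, rn + 1):
                                                    px = clamp(x + ex, nx)
                                                    py = clamp(y + ey, ny)
                                                    pz = clamp(z + ez, nz)
                                                    qx = clamp(px + dx, nx)
                                                    qy = clamp(py + dy, ny)
                                                    qz = clamp(pz + dz, nz)
                                                    diff = frames[px, py, pz, a] - frames[qx, qy, qz, b]
                                                    d2 += diff * diff
                                                    cnt += 1
                                    d2 /= cnt
                                    w = np.exp(-d2 / (h_t[t] * h_t[t]))
                                    cx = clamp(x + dx, nx)
                                    cy = clamp(y + dy, ny)
                                    cz = clamp(z + dz, nz)
                                    acc += w * frames[cx, cy, cz, f]
                                    wsum += w
                    out[x, y, z, t] = acc / wsum
    return out


def ennsd_loops(stack, roi_mask):
    """Direct EnNSD formula: per-voxel CV across realizations, ROI-averaged."""
    j = len(stack)
    vals = []
    idx = np.argwhere(roi_mask)
    for pos in idx:
        samples = np.array([im[tuple(pos)] for im in stack])
        mean = samples.mean()
        sd = np.sqrt(((samples - mean) ** 2).sum() / (j - 1))
        vals.append(sd / mean)
    return float(np.mean(vals)) * 100.0
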