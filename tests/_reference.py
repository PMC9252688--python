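"""Naive, loop-based reference implementations used as independent oracles.

Everything here is deliberately written the slow, obvious way (explicit
loops over pixels, channels and boundary-point pairs) and stays independent
of the package's vectorised code paths.
"""

import math

import numpy as np


def ref_conv2d(x, w, b=None, padding=None):
    """Quadruple-loop stride-1 2-D cross-correlation on (N, C, H, W)."""
    n, c, h, wd = x.shape
    oc, ic, kh, kw = w.shape
    assert ic == c
    if padding is None:
        padding = (kh // 2, (kh - 1) // 2, kw // 2, (kw - 1) // 2)
    pt, pb, pl, pr = padding
    ho = h + pt + pb - kh + 1
    wo = wd + pl + pr - kw + 1
    out = np.zeros((n, oc, ho, wo))
    for ni in range(n):
        for oi in range(oc):
            for y in range(ho):
                for xo in range(wo):
                    acc = 0.0
                    for ci in range(c):
                        for i in range(kh):
                            for j in range(kw):
                                yy = y + i - pt
                                xx = xo + j - pl
                                if 0 <= yy < h and 0 <= xx < wd:
                                    acc += x[ni, ci, yy, xx] * w[oi, ci, i, j]
                    out[ni, oi, y, xo] = acc
            if b is not None:
                out[ni, oi] += b[oi]
    return out


def ref_bn_eval(x, gamma, beta, running_mean, running_var, eps=1e-5):
    """Eval-mode batch normalisation with running statistics."""
    out = np.empty_like(x)
    for ci in range(x.shape[1]):
        xhat = (x[:, ci] - running_mean.ravel()[ci]) / math.sqrt(
            running_var.ravel()[ci] + eps
        )
        out[:, ci] = gamma.ravel()[ci] * xhat + beta.ravel()[ci]
    return out


def ref_sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def ref_spatial_gate(b, conv_w, conv_b, padding=None):
    """Channel-wise max/mean maps -> conv -> sigmoid."""
    mx = b.max(axis=1, keepdims=True)
    mn = b.mean(axis=1, keepdims=True)
    stacked = np.concatenate([mx, mn], axis=1)
    return ref_sigmoid(ref_conv2d(stacked, conv_w, conv_b, padding))


def ref_channel_gate(b, w1, b1, w2, b2):
    """Global max+avg pooling through a shared bottleneck MLP -> sigmoid."""
    def mlp(vec):  # vec: (C,)
        hidden = np.maximum(w1[:, :, 0, 0] @ vec + b1, 0.0)
        return w2[:, :, 0, 0] @ hidden + b2

    n, c = b.shape[:2]
    gate = np.empty((n, c, 1, 1))
    for ni in range(n):
        pmax = b[ni].max(axis=(1, 2))
        pavg = b[ni].mean(axis=(1, 2))
        gate[ni, :, 0, 0] = ref_sigmoid(mlp(pmax) + mlp(pavg))
    return gate


def ref_bilateral(image, sigma_spatial, sigma_range, radius):
    """Double-loop bilateral filter over in-bounds neighbourhoods."""
    h, w = image.shape
    out = np.empty_like(image)
    for y in range(h):
        for x in range(w):
            acc = 0.0
            norm = 0.0
            for dy in range(-radius, radius + 1):
                for dx in range(-radius, radius + 1):
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < h and 0 <= xx < w:
                        wgt = math.exp(
                            -(dy * dy + dx * dx) / (2.0 * sigma_spatial**2)
                            - (image[yy, xx] - image[y, x]) ** 2
                            / (2.0 * sigma_range**2)
                        )
                        acc += wgt * image[yy, xx]
                        norm += wgt
            out[y, x] = acc / norm
    return out


def ref_boundary(mask):
    """Foreground pixels with at least one background 4-neighbour."""
    m = np.asarray(mask).astype(bool)
    pts = []
    h, w = m.shape
    for y in range(h):
        for x in range(w):
            if not m[y, x]:
                continue
            for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                yy, xx = y + dy, x + dx
                if not (0 <= yy < h and 0 <= xx < w) or not m[yy, xx]:
                    pts.append((y, x))
                    break
    return np.array(pts, dtype=float).reshape(-1, 2)


def ref_hausdorff_mad(pred, truth):
    """Exhaustive pairwise boundary distances -> (HD, MAD)."""
    br = ref_boundary(pred)
    bg = ref_boundary(truth)
    assert br.size and bg.size
    d = np.sqrt(((br[:, None, :] - bg[None, :, :]) ** 2).sum(axis=2))
    d_rg = d.min(axis=1)  # for each predicted boundary point
    d_gr = d.min(axis=0)
    hd = max(d_rg.max(), d_gr.max())
    mad_val = 0.5 * (d_rg.mean() + d_gr.mean())
    return hd, mad_val


def random_blob_mask(rng, shape, p_empty=0.0):
    """A random connected-ish blob mask for metric stress tests."""
    if rng.random() < p_empty:
        return np.zeros(shape, dtype=bool)
    h, w = shape
    cy = rng.uniform(2, h - 2)
    cx = rng.uniform(2, w - 2)
    ry = rng.uniform(1.5, h / 2.5)
    rx = rng.uniform(1.5, w / 2.5)
    yy, xx = np.mgrid[0:h, 0:w]
    mask = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    # roughen the contour with random pixel flips near the edge
    noise = rng.random(shape) < 0.1
    return mask ^ (noise & mask)


def numeric_grad(f, x, eps=1e-6):
    """Central finite-difference gradient of scalar f at array x."""
    x = np.asarray(x, dtype=np.float64)
    g = np.zeros_like(x)
    flat = x.ravel()
    gf = g.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        fp = f(x)
        flat[i] = orig - eps
        fm = f(x)
        flat[i] = orig
        gf[i] = (fp - fm) / (2.0 * eps)
    return g
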