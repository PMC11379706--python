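"""Private NumPy compute engine: layers, forward/backward passes, Adam.

Everything here operates on plain parameter dictionaries (str -> ndarray) so
that the federation layer can average, serialize and diff parameters without
touching framework-specific objects.  Gradients are hand-derived and covered
by numeric grad-checks in the test suite.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError, NumericError

BACKBONE_CHANNELS = (8, 16, 32)  # stride-2 conv blocks; 64x64 -> 8x8 latent


# ---------------------------------------------------------------------------
# primitive layers
# ---------------------------------------------------------------------------

def conv2d_forward(x, w, b, stride=2, pad=1):
    """3x3 convolution, NHWC layout. Returns (out, cache)."""
    B, H, W, _ = x.shape
    kh, kw, _, O = w.shape
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    Ho = (H + 2 * pad - kh) // stride + 1
    Wo = (W + 2 * pad - kw) // stride + 1
    out = np.broadcast_to(b, (B, Ho, Wo, O)).copy()
    for di in range(kh):
        for dj in range(kw):
            patch = xp[:, di:di + stride * Ho:stride, dj:dj + stride * Wo:stride, :]
            out += patch @ w[di, dj]
    return out, (xp, x.shape, stride, pad, Ho, Wo)


def conv2d_backward(dout, w, cache):
    xp, x_shape, stride, pad, Ho, Wo = cache
    kh, kw, _, _ = w.shape
    dw = np.zeros_like(w)
    db = dout.sum(axis=(0, 1, 2))
    dxp = np.zeros_like(xp)
    for di in range(kh):
        for dj in range(kw):
            patch = xp[:, di:di + stride * Ho:stride, dj:dj + stride * Wo:stride, :]
            dw[di, dj] = np.einsum('bhwc,bhwo->co', patch, dout)
            dxp[:, di:di + stride * Ho:stride, dj:dj + stride * Wo:stride, :] += dout @ w[di, dj].T
    _, H, W, _ = x_shape
    dx = dxp[:, pad:pad + H, pad:pad + W, :]
    return dx, dw, db


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# backbone registry
# ---------------------------------------------------------------------------

def init_small_cnn(rng, in_channels):
    """He-initialized 3-block stride-2 CNN for ~64x64 inputs."""
    params = {}
    cin = in_channels
    for i, cout in enumerate(BACKBONE_CHANNELS, start=1):
        fan_in = 9 * cin
        params[f'conv{i}_w'] = rng.normal(0.0, np.sqrt(2.0 / fan_in), (3, 3, cin, cout))
        params[f'conv{i}_b'] = np.zeros(cout)
        cin = cout
    return params


def _densenet_unavailable(*_a, **_k):
    raise ConfigurationError(
        "backbone 'densenet' requires torch/torchvision, which are not "
        "installed in this environment; use 'small_cnn'")


BACKBONES = {
    'small_cnn': init_small_cnn,
    'densenet': _densenet_unavailable,
}


def backbone_out_channels(backbone: str) -> int:
    if backbone not in BACKBONES:
        raise ConfigurationError(f"unknown backbone {backbone!r}; "
                                 f"registered: {sorted(BACKBONES)}")
    return BACKBONE_CHANNELS[-1]


def init_addon(rng, in_channels, depth):
    # two 1x1 convs == per-pixel linear maps
    return {
        'addon1_w': rng.normal(0.0, np.sqrt(2.0 / in_channels), (in_channels, depth)),
        'addon1_b': np.zeros(depth),
        'addon2_w': rng.normal(0.0, np.sqrt(2.0 / depth), (depth, depth)),
        'addon2_b': np.zeros(depth),
    }


def backbone_forward(x, p):
    caches = []
    h = x
    for i in range(1, len(BACKBONE_CHANNELS) + 1):
        h, c = conv2d_forward(h, p[f'conv{i}_w'], p[f'conv{i}_b'])
        mask = h > 0
        h = h * mask  # ReLU
        caches.append((c, mask))
    return h, caches


def backbone_backward(dout, p, caches):
    grads = {}
    d = dout
    for i in range(len(BACKBONE_CHANNELS), 0, -1):
        c, mask = caches[i - 1]
        d = d * mask
        d, dw, db = conv2d_backward(d, p[f'conv{i}_w'], c)
        grads[f'conv{i}_w'] = dw
        grads[f'conv{i}_b'] = db
    return grads


def addon_forward(feat, p):
    a1 = feat @ p['addon1_w'] + p['addon1_b']
    mask = a1 > 0
    r = a1 * mask
    a2 = r @ p['addon2_w'] + p['addon2_b']
    z = _sigmoid(a2)
    return z, (feat, mask, r, z)


def addon_backward(dz, p, cache):
    feat, mask, r, z = cache
    da2 = dz * z * (1.0 - z)
    grads = {
        'addon2_w': np.einsum('bhwd,bhwe->de', r, da2),
        'addon2_b': da2.sum(axis=(0, 1, 2)),
    }
    dr = da2 @ p['addon2_w'].T
    da1 = dr * mask
    grads['addon1_w'] = np.einsum('bhwc,bhwd->cd', feat, da1)
    grads['addon1_b'] = da1.sum(axis=(0, 1, 2))
    dfeat = da1 @ p['addon1_w'].T
    return dfeat, grads


def encode(x, conv_params):
    """Full encoder: backbone + add-on layers. Returns (z, caches)."""
    feat, bc = backbone_forward(x, conv_params)
    z, ac = addon_forward(feat, conv_params)
    return z, (bc, ac)


# ---------------------------------------------------------------------------
# prototype head: distances, similarities, loss
# ---------------------------------------------------------------------------

def patch_distances(zf, protos):
    """Squared L2 distance of every latent patch to every prototype.

    zf: (B, HW, D) flattened latent patches; protos: (m, D).
    Returns (B, m, HW), clipped at 0 against rounding.
    """
    sq_z = np.einsum('bkd,bkd->bk', zf, zf)
    cross = np.einsum('bkd,md->bmk', zf, protos)
    sq_p = np.einsum('md,md->m', protos, protos)
    dist = sq_z[:, None, :] - 2.0 * cross + sq_p[None, :, None]
    return np.maximum(dist, 0.0)


def head_forward(z, protos, final_w, class_of, y, cfg_eps,
                 lam_cluster, lam_separation):
    """Head pass on encoded batch z (B,H,W,D); returns (loss, parts, cache)."""
    B = z.shape[0]
    m = protos.shape[0]
    zf = z.reshape(B, -1, z.shape[-1])
    dist = patch_distances(zf, protos)                       # (B,m,HW)
    sim = np.log((dist + 1.0) / (dist + cfg_eps))
    kstar = dist.argmin(axis=2)                              # (B,m) max-sim patch
    bi = np.arange(B)[:, None]
    mi = np.arange(m)[None, :]
    top = sim[bi, mi, kstar]                                 # (B,m)
    logits = top @ final_w
    logits = logits - logits.max(axis=1, keepdims=True)
    ex = np.exp(logits)
    probs = ex / ex.sum(axis=1, keepdims=True)
    if not np.all(np.isfinite(probs)):
        raise NumericError("non-finite class probabilities")
    ce = -np.log(np.maximum(probs[np.arange(B), y], 1e-300)).mean()

    same = class_of[None, :] == y[:, None]                   # (B,m)
    min_per_proto = dist[bi, mi, kstar]                      # (B,m) min over patches
    INF = np.inf
    same_min = np.where(same, min_per_proto, INF)
    wrong_min = np.where(~same, min_per_proto, INF)
    j_same = same_min.argmin(axis=1)                         # (B,)
    j_wrong = wrong_min.argmin(axis=1)
    cluster = same_min[np.arange(B), j_same]
    sep = wrong_min[np.arange(B), j_wrong]
    has_wrong = np.isfinite(sep)
    cluster_cost = cluster.mean()
    sep_cost = sep[has_wrong].mean() if has_wrong.any() else 0.0

    loss = ce + lam_cluster * cluster_cost - lam_separation * sep_cost
    parts = {'ce': ce, 'cluster': cluster_cost, 'separation': sep_cost,
             'probs': probs, 'top': top}
    cache = (zf, dist, kstar, j_same, j_wrong, has_wrong, probs, top, same)
    return loss, parts, cache


def head_backward(z_shape, protos, final_w, y, cfg_eps,
                  lam_cluster, lam_separation, cache):
    """Returns (dz, dprotos, dfinal_w)."""
    zf, dist, kstar, j_same, j_wrong, has_wrong, probs, top, _same = cache
    B, m = top.shape
    K = final_w.shape[1]
    onehot = np.zeros((B, K))
    onehot[np.arange(B), y] = 1.0
    dlogits = (probs - onehot) / B
    dfinal = top.T @ dlogits
    dtop = dlogits @ final_w.T                               # (B,m)

    ddist = np.zeros_like(dist)                              # (B,m,HW)
    bi = np.arange(B)[:, None]
    mi = np.arange(m)[None, :]
    dstar = dist[bi, mi, kstar]
    simgrad = 1.0 / (dstar + 1.0) - 1.0 / (dstar + cfg_eps)  # d(sim)/d(dist), < 0
    np.add.at(ddist, (bi, mi, kstar), dtop * simgrad)

    br = np.arange(B)
    np.add.at(ddist, (br, j_same, kstar[br, j_same]), lam_cluster / B)
    if has_wrong.any():
        nw = has_wrong.sum()
        idx = br[has_wrong]
        np.add.at(ddist, (idx, j_wrong[has_wrong], kstar[idx, j_wrong[has_wrong]]),
                  -lam_separation / nw)

    # dist[b,j,k] = ||zf[b,k] - p_j||^2
    s_bk = ddist.sum(axis=1)                                 # (B,HW)
    dzf = 2.0 * (zf * s_bk[..., None] - np.einsum('bjk,jd->bkd', ddist, protos))
    t_j = ddist.sum(axis=(0, 2))                             # (m,)
    dprotos = 2.0 * (protos * t_j[:, None] - np.einsum('bjk,bkd->jd', ddist, zf))
    return dzf.reshape(z_shape), dprotos, dfinal


def forward_backward(x, y, conv_params, protos, final_w, class_of,
                     eps, lam_cluster, lam_separation,
                     need_conv_grads=True):
    """Full loss + gradients for one batch.

    Returns (loss, parts, grads) where grads maps parameter names
    ('conv*', 'addon*', 'prototypes', 'final_weights') to arrays.
    """
    z, (bc, ac) = encode(x, conv_params)
    loss, parts, cache = head_forward(z, protos, final_w, class_of, y,
                                      eps, lam_cluster, lam_separation)
    dz, dprotos, dfinal = head_backward(z.shape, protos, final_w, y, eps,
                                        lam_cluster, lam_separation, cache)
    dfeat, addon_grads = addon_backward(dz, conv_params, ac)
    grads = dict(addon_grads)
    if need_conv_grads:
        grads.update(backbone_backward(dfeat, conv_params, bc))
    grads['prototypes'] = dprotos
    grads['final_weights'] = dfinal
    return loss, parts, grads


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam over a named parameter dict, restricted to `keys`."""

    def __init__(self, keys, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.keys = list(keys)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {}
        self.v = {}

    def step(self, params, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k in self.keys:
            g = grads[k]
            if k not in self.m:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] = params[k] - self.lr * mhat / (np.sqrt(vhat) + self.eps)
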