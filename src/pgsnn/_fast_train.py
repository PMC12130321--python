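"""Numba-compiled epoch kernel for the three-hidden-layer perceptrons.

Mirrors the reference numpy training step in ``nn_engine`` exactly: same
layer order (affine -> batch norm -> optional softplus -> inverted
dropout), same batch-norm backward, same plain-SGD update.  All
randomness (batch order, oversampling draws, dropout masks) is drawn by
the caller from its numpy Generator and passed in, so the kernel is
purely deterministic arithmetic and the numpy fallback path consumes an
identical random stream.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    NUMBA_AVAILABLE = True
except ImportError:  # pragma: no cover - numba is a standard install
    NUMBA_AVAILABLE = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _softplus(x):
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


@njit(cache=True)
def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


@njit(cache=True)
def run_epoch(
    Xtr,
    ytr,
    idx,
    bounds,
    W1, b1, W2, b2, W3, b3, W4, b4,
    g1, be1, rm1, rv1,
    g2, be2, rm2, rv2,
    g3, be3, rm3, rv3,
    mask1, mask2, mask3,
    lr,
    nonlinear,
    binary,
    bn_momentum,
    bn_eps,
):
    """One SGD epoch over the prepared batches; mutates parameters in place.

    Returns (summed loss, examples seen, case count) for the epoch log.
    Raises no exceptions: a non-finite loss is returned as-is for the
    caller to detect.
    """
    loss_sum = 0.0
    case_sum = 0.0
    n_seen = 0
    for bi in range(len(bounds) - 1):
        lo, hi = bounds[bi], bounds[bi + 1]
        rows = idx[lo:hi]
        m = hi - lo
        Xb = Xtr[rows]
        yb = ytr[rows]
        m1 = mask1[lo:hi]
        m2 = mask2[lo:hi]
        m3 = mask3[lo:hi]

        # ---- forward -----------------------------------------------------
        A1 = Xb @ W1 + b1
        mu1 = A1.sum(axis=0) / m
        xc1 = A1 - mu1
        var1 = (xc1 * xc1).sum(axis=0) / m
        inv1 = 1.0 / np.sqrt(var1 + bn_eps)
        xh1 = xc1 * inv1
        H1 = g1 * xh1 + be1
        for j in range(rm1.shape[0]):
            rm1[j] = (1.0 - bn_momentum) * rm1[j] + bn_momentum * mu1[j]
            rv1[j] = (1.0 - bn_momentum) * rv1[j] + bn_momentum * var1[j]
        if nonlinear:
            S1 = _softplus(H1)
            sg1 = _sigmoid(H1)
        else:
            S1 = H1
            sg1 = H1  # unused
        D1 = S1 * m1

        A2 = D1 @ W2 + b2
        mu2 = A2.sum(axis=0) / m
        xc2 = A2 - mu2
        var2 = (xc2 * xc2).sum(axis=0) / m
        inv2 = 1.0 / np.sqrt(var2 + bn_eps)
        xh2 = xc2 * inv2
        H2 = g2 * xh2 + be2
        for j in range(rm2.shape[0]):
            rm2[j] = (1.0 - bn_momentum) * rm2[j] + bn_momentum * mu2[j]
            rv2[j] = (1.0 - bn_momentum) * rv2[j] + bn_momentum * var2[j]
        if nonlinear:
            S2 = _softplus(H2)
            sg2 = _sigmoid(H2)
        else:
            S2 = H2
            sg2 = H2
        D2 = S2 * m2

        A3 = D2 @ W3 + b3
        mu3 = A3.sum(axis=0) / m
        xc3 = A3 - mu3
        var3 = (xc3 * xc3).sum(axis=0) / m
        inv3 = 1.0 / np.sqrt(var3 + bn_eps)
        xh3 = xc3 * inv3
        H3 = g3 * xh3 + be3
        for j in range(rm3.shape[0]):
            rm3[j] = (1.0 - bn_momentum) * rm3[j] + bn_momentum * mu3[j]
            rv3[j] = (1.0 - bn_momentum) * rv3[j] + bn_momentum * var3[j]
        if nonlinear:
            S3 = _softplus(H3)
            sg3 = _sigmoid(H3)
        else:
            S3 = H3
            sg3 = H3
        D3 = S3 * m3

        out = (D3 @ W4)[:, 0] + b4[0]

        # ---- loss --------------------------------------------------------
        if binary:
            p = _sigmoid(out)
            for j in range(m):
                if p[j] < 1e-12:
                    p[j] = 1e-12
                elif p[j] > 1.0 - 1e-12:
                    p[j] = 1.0 - 1e-12
            loss = -(yb * np.log(p) + (1.0 - yb) * np.log(1.0 - p)).sum() / m
            dout = p - yb
            case_sum += yb.sum()
        else:
            resid = out - yb
            loss = (resid * resid).sum() / m
            dout = 2.0 * resid
        loss_sum += loss * m
        n_seen += m

        # ---- backward ----------------------------------------------------
        G = dout.reshape(m, 1)
        dW4 = D3.T @ G
        db4 = G.sum(axis=0)
        G = G @ W4.T

        # layer 3
        G = G * m3
        if nonlinear:
            G = G * sg3
        dg3 = (G * xh3).sum(axis=0)
        dbe3 = G.sum(axis=0)
        GX = G * g3
        G = (inv3 / m) * (m * GX - GX.sum(axis=0) - xh3 * (GX * xh3).sum(axis=0))
        dW3 = D2.T @ G
        db3 = G.sum(axis=0)
        G = G @ W3.T

        # layer 2
        G = G * m2
        if nonlinear:
            G = G * sg2
        dg2 = (G * xh2).sum(axis=0)
        dbe2 = G.sum(axis=0)
        GX = G * g2
        G = (inv2 / m) * (m * GX - GX.sum(axis=0) - xh2 * (GX * xh2).sum(axis=0))
        dW2 = D1.T @ G
        db2 = G.sum(axis=0)
        G = G @ W2.T

        # layer 1
        G = G * m1
        if nonlinear:
            G = G * sg1
        dg1 = (G * xh1).sum(axis=0)
        dbe1 = G.sum(axis=0)
        GX = G * g1
        G = (inv1 / m) * (m * GX - GX.sum(axis=0) - xh1 * (GX * xh1).sum(axis=0))
        dW1 = Xb.T @ G
        db1 = G.sum(axis=0)

        # ---- SGD update --------------------------------------------------
        s = lr / m
        W1 -= s * dW1
        b1 -= s * db1
        W2 -= s * dW2
        b2 -= s * db2
        W3 -= s * dW3
        b3 -= s * db3
        W4 -= s * dW4
        b4 -= s * db4
        g1 -= s * dg1
        be1 -= s * dbe1
        g2 -= s * dg2
        be2 -= s * dbe2
        g3 -= s * dg3
        be3 -= s * dbe3

    return loss_sum, n_seen, case_sum
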