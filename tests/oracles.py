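"""Independent reference implementations used as test oracles.

Everything here is built from explicit shift-and-multiply arithmetic (no
im2col, no shared code with the package's engine) so that block outputs and
parameter counts can be verified against a second, independent path.
"""

import numpy as np

from hacrnet import nn


def conv_ref(x, w, b, pad):
    bsz, cin, h, wd = x.shape
    cout, _, k, _ = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho, wo = h + 2 * pad - k + 1, wd + 2 * pad - k + 1
    out = np.zeros((bsz, cout, ho, wo))
    for bi in range(bsz):
        for co in range(cout):
            acc = np.zeros((ho, wo))
            for ci in range(cin):
                for u in range(k):
                    for v in range(k):
                        acc += w[co, ci, u, v] * xp[bi, ci, u : u + ho, v : v + wo]
            out[bi, co] = acc + (0.0 if b is None else b[co])
    return out


def layer_ref(conv, x):
    return conv_ref(
        x, conv.weight.data, None if conv.bias is None else conv.bias.data, conv.padding
    )


def prelu_ref(act, x):
    s = act.slope.data.reshape(1, -1, *([1] * (x.ndim - 2)))
    return np.where(x < 0, s * x, x)


def sigmoid_ref(x):
    return 1.0 / (1.0 + np.exp(-x))


def gap_ref(x):
    return x.mean(axis=(2, 3), keepdims=True)


def zero_(module):
    for p in module.parameters():
        p.data[...] = 0.0


def forward(block, x):
    return block(nn.Tensor(x.astype(np.float64))).data


def ham_ref(ham, x):
    """Shallow extraction, channel attention, spatial attention, by hand."""
    f = prelu_ref(ham.act, layer_ref(ham.conv, x))
    fc = sigmoid_ref(
        layer_ref(ham.ca.expand, prelu_ref(ham.ca.act, layer_ref(ham.ca.reduce, gap_ref(f))))
    )
    fp = fc * f
    ms = sigmoid_ref(
        layer_ref(
            ham.sa.project,
            prelu_ref(ham.sa.act, layer_ref(ham.sa.wide, layer_ref(ham.sa.reduce, fp))),
        )
    )
    return ms * fp


def mfab_ref(block, cin):
    """Line-by-line reference of the multiscale aggregation block."""
    a1 = layer_ref(
        block.a1_conv2,
        prelu_ref(block.a1_act2, layer_ref(block.a1_conv1, prelu_ref(block.a1_act1, cin))),
    )
    a2 = layer_ref(
        block.a2_conv2,
        prelu_ref(block.a2_act2, layer_ref(block.a2_conv1, prelu_ref(block.a2_act1, cin))),
    )
    s = a1 + a2
    att = sigmoid_ref(
        layer_ref(
            block.att_expand, prelu_ref(block.att_act, layer_ref(block.att_reduce, gap_ref(s)))
        )
    )
    return s * att + layer_ref(block.hf, cin)


def crab_ref(block, cin):
    """Line-by-line reference of the channel-retention block."""
    h = layer_ref(block.conv, cin)
    z = gap_ref(h)
    u = layer_ref(block.fc_b, layer_ref(block.fc_a, z))
    v = layer_ref(block.fc_d, layer_ref(block.fc_c, prelu_ref(block.act, u)))
    return h * sigmoid_ref(v) + h


def count_oracle(cfg):
    """Closed-form layer enumeration, independent of the builder."""
    c = cfg.base_channels

    def conv(cin, cout, k):
        return k * k * cin * cout + cout

    total = conv(cfg.in_channels, c, 3) + c
    if cfg.use_ham:
        m = c // cfg.ca_reduction
        total += conv(c, m, 1) + m + conv(m, c, 1)
        s = c // cfg.sa_reduction
        total += conv(c, s, 1) + conv(s, s, 7) + s + conv(s, 1, 1)
    per = 2 * conv(c, c, 3) + 2 * c + conv(c, c, 3)
    if cfg.use_mfab:
        m = c // cfg.ca_reduction
        per += 2 * conv(c, c, 3) + 2 * c
        per += conv(c, c, 3) + conv(c, c, 1) + 2 * c
        per += conv(c, m, 1) + m + conv(m, c, 1)
        per += conv(c, c, 1)
    if cfg.use_crab:
        w = cfg.crab_width
        per += (
            conv(c, c, 3) + conv(c, w, 1) + conv(w, w, 1) + w + conv(w, w, 1) + conv(w, c, 1)
        )
    per += conv((int(cfg.use_mfab) + int(cfg.use_crab)) * c, c, 1)
    total += cfg.caam_count * per
    total += conv(c, c, 3)
    total += (1 if cfg.scale == 2 else 2) * conv(c, 4 * c, 3)
    total += conv(c, cfg.out_channels, 3)
    return total
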