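"""Hand-written numerical oracles shared by test modules.

Kept deliberately naive (scalar loops) and independent of the package's
vectorized implementations.
"""

import numpy as np


def bilinear_up2x_scalar(arr):
    """2x bilinear upsampling with half-pixel centres and edge clamp,
    as explicit scalar loops."""
    h, w = arr.shape
    out = np.zeros((2 * h, 2 * w))
    for r in range(2 * h):
        for c in range(2 * w):
            sr = (r + 0.5) / 2 - 0.5
            sc = (c + 0.5) / 2 - 0.5
            r0, c0 = int(np.floor(sr)), int(np.floor(sc))
            fr, fc = sr - r0, sc - c0
            val = 0.0
            for dr, wr in ((0, 1 - fr), (1, fr)):
                for dc, wc in ((0, 1 - fc), (1, fc)):
                    rr = min(max(r0 + dr, 0), h - 1)
                    cc = min(max(c0 + dc, 0), w - 1)
                    val += wr * wc * arr[rr, cc]
            out[r, c] = val
    return out
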