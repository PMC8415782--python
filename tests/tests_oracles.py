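"""Independent brute-force oracles shared by the test modules."""

import numpy as np


def mcc_loop_oracle(block):
    """Per-feature mean correlation coefficient by explicit Pearson loops.

    block: (trials, windows, features). Each trial's Pearson r against the
    all-trials composite is computed from the covariance/variance definition
    and averaged.
    """
    n_trials, _, n_feat = block.shape
    comp = block.mean(axis=0)
    out = np.empty(n_feat)
    for j in range(n_feat):
        rs = []
        for i in range(n_trials):
            x, y = block[i, :, j], comp[:, j]
            sx = np.sqrt(np.mean((x - x.mean()) ** 2))
            sy = np.sqrt(np.mean((y - y.mean()) ** 2))
            if sx == 0 or sy == 0:
                continue
            rs.append(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
        out[j] = np.mean(rs) if rs else np.nan
    return out
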