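"""Independent direct-convolution DWT/IDWT oracle.

A from-scratch implementation of the level-2 coif3 discrete wavelet
transform with symmetric half-point boundary extension, written directly
from the filter-bank definition (explicit extension, convolution,
down/upsampling).  Used to cross-check the package's transform; shares no
code path with it.  The 18-tap coif3 scaling filter is frozen as literals;
the high-pass and synthesis filters follow from the standard quadrature
mirror relations.
"""

import numpy as np

COIF3_DEC_LO = np.array([
    -3.459977319727278e-05,
    -7.0983302506379e-05,
    0.0004662169598204029,
    0.0011175187708306303,
    -0.0025745176881367972,
    -0.009007976136730624,
    0.015880544863669452,
    0.03455502757329774,
    -0.08230192710629983,
    -0.07179982161915484,
    0.42848347637737,
    0.7937772226260872,
    0.40517690240911824,
    -0.06112339000297255,
    -0.06577191128146936,
    0.023452696142077168,
    0.007782596425672746,
    -0.003793512864380802,
])
_L = COIF3_DEC_LO.size
COIF3_DEC_HI = np.array(
    [(-1.0) ** (n + 1) * COIF3_DEC_LO[_L - 1 - n] for n in range(_L)]
)
COIF3_REC_LO = COIF3_DEC_LO[::-1]
COIF3_REC_HI = COIF3_DEC_HI[::-1]


def _sym_ext(x: np.ndarray, n: int) -> np.ndarray:
    """Half-point symmetric extension by n samples on each side."""
    return np.concatenate([x[:n][::-1], x, x[-n:][::-1]])


def _analysis(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    out_len = (x.size + _L - 1) // 2
    ext = _sym_ext(x, _L - 1)
    lo = np.convolve(ext, COIF3_DEC_LO, mode="valid")[1::2][:out_len]
    hi = np.convolve(ext, COIF3_DEC_HI, mode="valid")[1::2][:out_len]
    return lo, hi


def _synthesis(ca: np.ndarray, cd: np.ndarray, out_len: int) -> np.ndarray:
    ua = np.zeros(2 * ca.size)
    ua[::2] = ca
    ud = np.zeros(2 * cd.size)
    ud[::2] = cd
    full = np.convolve(ua, COIF3_REC_LO) + np.convolve(ud, COIF3_REC_HI)
    start = _L - 2
    return full[start:start + out_len]


def dwt_oracle(x: np.ndarray) -> np.ndarray:
    """128 samples -> 160-coefficient vector [approx L2, detail L2, detail L1]."""
    x = np.asarray(x, dtype=float)
    ca1, cd1 = _analysis(x)
    ca2, cd2 = _analysis(ca1)
    return np.concatenate([ca2, cd2, cd1])


def idwt_oracle(coeffs: np.ndarray, n: int = 128) -> np.ndarray:
    coeffs = np.asarray(coeffs, dtype=float)
    ca2, cd2, cd1 = coeffs[:44], coeffs[44:88], coeffs[88:]
    ca1 = _synthesis(ca2, cd2, (n + _L - 1) // 2)
    return _synthesis(ca1, cd1, n)
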