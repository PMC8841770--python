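"""Independent reference implementations used as test oracles.

The DWT oracle implements one analysis level from first principles:
half-sample symmetric boundary extension by (filter length - 1) samples on
each side, full linear convolution with the analysis filters, and dyadic
downsampling. Multilevel decomposition cascades it on the approximation.
It shares no code path with eitclean.wavelet beyond the filter taps.
"""

import numpy as np
import pywt


def symmetric_extend(x: np.ndarray, pad: int) -> np.ndarray:
    """Half-sample symmetric extension: ... x1 x0 | x0 x1 ... xn | xn ..."""
    return np.concatenate([x[:pad][::-1], x, x[-pad:][::-1]])


def dwt_single_level(x: np.ndarray, wavelet: str = "db8"):
    w = pywt.Wavelet(wavelet)
    flen = w.dec_len
    lo = np.asarray(w.dec_lo)
    hi = np.asarray(w.dec_hi)
    ext = symmetric_extend(np.asarray(x, dtype=float), flen - 1)
    out_len = (len(x) + flen - 1) // 2
    approx = np.convolve(ext, lo)[flen::2][:out_len]
    detail = np.convolve(ext, hi)[flen::2][:out_len]
    return approx, detail


def dwt_multilevel(x: np.ndarray, level: int, wavelet: str = "db8"):
    """Returns (approx, [d_1 .. d_level]) with d_1 the finest detail."""
    details = []
    a = np.asarray(x, dtype=float)
    for _ in range(level):
        a, d = dwt_single_level(a, wavelet)
        details.append(d)
    return a, details
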