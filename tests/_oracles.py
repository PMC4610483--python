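"""Independent reference implementations used only as test oracles.

These are deliberately written in the most literal way possible
(explicit double loops, direct convolution, grid search) and share no
code with the package paths they verify.
"""

import numpy as np
import pywt


def apen_bruteforce(u, m=2, r_frac=0.2):
    """Approximate entropy by explicit O(n^2) window enumeration."""
    u = np.asarray(u, float)
    n = len(u)
    sd = np.std(u, ddof=1)
    if sd == 0:
        return 0.0
    r = r_frac * sd

    def phi(mm):
        nwin = n - mm + 1
        logs = []
        for i in range(nwin):
            count = 0
            for j in range(nwin):
                d = 0.0
                for k in range(mm):
                    d = max(d, abs(u[i + k] - u[j + k]))
                if d <= r:
                    count += 1
            logs.append(np.log(count / nwin))
        return float(np.mean(logs))

    return phi(m) - phi(m + 1)


def db10_detail_direct(x):
    """Interior detail coefficients of a 1-level db10 DWT.

    Direct convolution with the decomposition high-pass filter followed
    by dyadic downsampling; only coefficients unaffected by boundary
    extension are returned, together with their index offset into the
    pywt output.
    """
    x = np.asarray(x, float)
    g = np.array(pywt.Wavelet("db10").dec_hi)
    full = np.convolve(x, g)
    ds = full[1::2]
    margin = len(g) // 2  # coefficients touched by boundary extension
    return ds[margin:-margin], margin


def skewness_direct(x):
    """Third standardised moment, biased numerator over sample sd cubed."""
    x = np.asarray(x, float)
    mean = sum(x) / len(x)
    m3 = sum((v - mean) ** 3 for v in x) / len(x)
    s = np.std(x, ddof=1)
    return m3 / s**3


def spiral_rmse_grid(r, phi, constrained, a_range, b_range, steps=61, refinements=6):
    """Minimum polar-fit RMSE by iterative grid refinement."""
    r = np.asarray(r, float)
    phi = np.asarray(phi, float)

    def rmse(a, b):
        return np.sqrt(np.mean((r - a - b * phi) ** 2))

    a_lo, a_hi = a_range
    b_lo, b_hi = b_range
    best = None
    for _ in range(refinements):
        a_vals = np.array([0.0]) if constrained else np.linspace(a_lo, a_hi, steps)
        b_vals = np.linspace(b_lo, b_hi, steps)
        grid = [(rmse(a, b), a, b) for a in a_vals for b in b_vals]
        best = min(grid, key=lambda t: t[0])
        _, a0, b0 = best
        da = (a_hi - a_lo) / steps
        db = (b_hi - b_lo) / steps
        a_lo, a_hi = a0 - 2 * da, a0 + 2 * da
        b_lo, b_hi = b0 - 2 * db, b0 + 2 * db
    return best[0]
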