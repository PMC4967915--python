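"""Independent brute-force oracles kept separate from the implementation."""

import math

from calyxsim.units import KB

KT310 = KB * 310.0


def brute_force_wham(counts, bin_centers, window_centers, spring_ks,
                     kT=KT310, tol=1e-12, max_iter=2_000_000):
    """Independent scalar-loop fixed-point iteration of the WHAM equations."""
    n_w = len(counts)
    n_b = len(bin_centers)
    N = [sum(counts[i]) for i in range(n_w)]
    w = [[0.5 * spring_ks[i] * (bin_centers[b] - window_centers[i]) ** 2
          for b in range(n_b)] for i in range(n_w)]
    f = [0.0] * n_w
    for _ in range(max_iter):
        P = []
        for b in range(n_b):
            num = sum(counts[i][b] for i in range(n_w))
            den = sum(N[i] * math.exp((f[i] - w[i][b]) / kT)
                      for i in range(n_w))
            P.append(num / den if den > 0 else 0.0)
        s = sum(P)
        P = [p / s for p in P]
        f_new = []
        for i in range(n_w):
            z = sum(P[b] * math.exp(-w[i][b] / kT) for b in range(n_b))
            f_new.append(-kT * math.log(z))
        delta = max(abs(a - b) for a, b in zip(f_new, f))
        f = f_new
        if delta < tol:
            break
    W = [-kT * math.log(p) if p > 0 else math.inf for p in P]
    shift = min(v for v in W if math.isfinite(v))
    return [v - shift for v in W]
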