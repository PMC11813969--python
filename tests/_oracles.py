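"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: plain-Python,
symbol-by-symbol evaluations of the trait formulas, and a sums-of-squares
ANCOVA for the repeated-measures correlation.
"""

import math
from collections import Counter

import numpy as np
from scipy import stats as sps

ETA = 1.002e-9  # MPa s
RHO = 998.2  # kg m^-3


def brute_force_ring_traits(areas, groups, aoi_mm2, min_area=5000.0):
    """Evaluate every trait formula symbol by symbol on one ring.

    areas: lumen areas in µm²; groups: group label per vessel; aoi in mm².
    Returns a dict keyed by trait symbol, or None if nothing survives.
    """
    kept = [(a, g) for a, g in zip(areas, groups) if a >= min_area]
    if not kept:
        return None
    n = len(kept)
    kept_areas = [a for a, _ in kept]
    la = sum(kept_areas) / n
    vfrac = sum(kept_areas) / (aoi_mm2 * 1e6)
    vfreq = n / aoi_mm2
    ds = [2.0 * math.sqrt(a / math.pi) for a in kept_areas]
    hwd = sum(d**5 for d in ds) / sum(d**4 for d in ds)
    thc = (
        math.pi * RHO * sum((d * 1e-6) ** 4 for d in ds)
        / (128.0 * ETA * (aoi_mm2 * 1e-6))
    )
    mean_d = sum(ds) / n
    vi = mean_d / vfreq
    sizes = Counter(g for _, g in kept)
    gi = n / len(sizes)
    svi = sum(1 for c in sizes.values() if c == 1) / n
    return {
        "LA": la, "VFrac": vfrac, "VFreq": vfreq, "HWD": hwd,
        "THC": thc, "VI": vi, "GI": gi, "SVI": svi, "n_vessels": n,
    }


def ancova_rmcorr(x, y, subject):
    """Repeated-measures correlation via explicit ANCOVA sums of squares.

    Full model: y ~ subject dummies + x; reduced: y ~ subject dummies.
    r² is the proportional SSE drop, signed by the common slope;
    df = N − k − 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    subjects = sorted(set(subject))
    k = len(subjects)
    dummies = np.array(
        [[1.0 if s == su else 0.0 for su in subjects] for s in subject]
    )
    full = np.column_stack([dummies, x])
    beta, *_ = np.linalg.lstsq(full, y, rcond=None)
    sse_full = float(((y - full @ beta) ** 2).sum())
    beta_r, *_ = np.linalg.lstsq(dummies, y, rcond=None)
    sse_red = float(((y - dummies @ beta_r) ** 2).sum())
    r2 = (sse_red - sse_full) / sse_red
    r = math.copysign(math.sqrt(max(r2, 0.0)), beta[-1])
    df = len(y) - k - 1
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r2))
        p = 2.0 * sps.t.sf(abs(t), df)
    return r, df, p


def random_ring(rng, max_vessels=10, min_vessels=1):
    """A random small ring: (areas, groups, aoi) with mixed group sizes."""
    n = int(rng.integers(min_vessels, max_vessels + 1))
    areas = rng.uniform(2000.0, 60000.0, n)
    groups = []
    g = 0
    i = 0
    while i < n:
        size = min(int(rng.integers(1, 4)), n - i)
        groups.extend([f"g{g}"] * size)
        g += 1
        i += size
    aoi = float(rng.uniform(0.5, 20.0))
    return areas, groups, aoi
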