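"""Shared numerical helpers: robust statistics and seeding."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

#: scale factor turning a MAD into a consistent estimate of a Gaussian SD
MAD_TO_SD = 1.4826


def mad_sd(x: np.ndarray) -> float:
    """Robust SD estimate via the median absolute deviation."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return 0.0
    return MAD_TO_SD * float(np.median(np.abs(x - np.median(x))))


def robust_z(x: np.ndarray, reference: np.ndarray | None = None) -> np.ndarray:
    """Median/MAD z-score of ``x`` relative to ``reference`` (default: itself).

    A zero MAD (e.g. a flat reference) yields +/-inf outside the median and 0 at
    it, which downstream thresholds treat as "no detectable deviation" or
    "arbitrarily extreme" as appropriate.
    """
    x = np.asarray(x, dtype=float)
    ref = x if reference is None else np.asarray(reference, dtype=float)
    med = float(np.median(ref))
    sd = mad_sd(ref)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (x - med) / sd if sd > 0 else np.where(x == med, 0.0, np.inf * np.sign(x - med))
    return z


def running_median(x: np.ndarray, window: int) -> np.ndarray:
    """Centered running median with reflected edges; window forced odd, >= 1."""
    window = max(1, int(window) | 1)
    return ndimage.median_filter(np.asarray(x, dtype=float), size=window, mode="reflect")


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent generators from one master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def child_seed(seed: int, *key: int) -> int:
    """Deterministic child seed (< 2**31) from a master seed and an index path."""
    ss = np.random.SeedSequence([int(seed), *[int(k) for k in key]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
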