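"""Shared numerical utilities: seeding, truncated-normal draws, PSD checks."""
from __future__ import annotations

import hashlib

import numpy as np
from scipy import special

__all__ = [
    "rng_from",
    "child_seed",
    "sample_one_sided_truncnorm",
    "check_psd",
    "nearest_psd_jitter",
]


def _stable_word_key(word: str) -> int:
    # process-independent (Python's str hash is salted per interpreter)
    digest = hashlib.blake2s(word.encode("utf-8"), digest_size=4).digest()
    return int.from_bytes(digest, "little") % (2**31)


def child_seed(seed: int, *words: str) -> int:
    """Stable derived seed (< 2**31) from a base seed and a tag path."""
    ss = np.random.SeedSequence(int(seed), spawn_key=tuple(_stable_word_key(w) for w in words))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def rng_from(seed: int, *words: str) -> np.random.Generator:
    """Generator seeded stably from a base seed and a tag path."""
    return np.random.default_rng(child_seed(seed, *words) if words else int(seed))


def _std_lower_truncated(a: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw standard normals conditioned on z > a, accurate in far tails.

    Inverse-CDF through the upper-tail probability keeps precision for large
    a; beyond a=12 an exponential-tail approximation is used (the relative
    density error there is < 1e-2 and such bounds arise only transiently).
    """
    a = np.asarray(a, dtype=np.float64)
    z = np.empty_like(a)
    far = a > 12.0
    near = ~far
    if near.any():
        tail = special.ndtr(-a[near])
        u = rng.uniform(size=int(near.sum()))
        z[near] = -special.ndtri(u * tail)
    if far.any():
        af = a[far]
        u = rng.uniform(size=int(far.sum()))
        z[far] = af - np.log1p(-u) / af
    # guarantee the strict side even under float rounding
    return np.maximum(z, np.nextafter(a, np.inf))


def sample_one_sided_truncnorm(
    mean: np.ndarray,
    sd: float | np.ndarray,
    bound: float,
    above: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample N(mean, sd^2) truncated to (bound, inf) where ``above`` is True
    and to (-inf, bound) elsewhere. Vectorised and tail-robust."""
    mean = np.asarray(mean, dtype=np.float64)
    above = np.asarray(above, dtype=bool)
    sd = np.broadcast_to(np.asarray(sd, dtype=np.float64), mean.shape)
    if np.any(sd <= 0):
        raise ValueError("truncated-normal sampling requires positive residual variance")
    out = np.empty_like(mean)
    a_hi = (bound - mean[above]) / sd[above]
    out[above] = mean[above] + sd[above] * _std_lower_truncated(a_hi, rng)
    lo = ~above
    a_lo = -(bound - mean[lo]) / sd[lo]
    out[lo] = mean[lo] - sd[lo] * _std_lower_truncated(a_lo, rng)
    # enforce the strict side of the threshold
    out[above] = np.maximum(out[above], np.nextafter(bound, np.inf))
    out[lo] = np.minimum(out[lo], np.nextafter(bound, -np.inf))
    return out


def check_psd(mat: np.ndarray, name: str = "covariance", tol: float = 1e-8) -> None:
    mat = np.asarray(mat, dtype=np.float64)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be a square matrix")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    w = np.linalg.eigvalsh(mat)
    if w.min() < -tol * max(1.0, abs(w.max())):
        raise ValueError(f"{name} is not positive semi-definite (min eigenvalue {w.min():.3g})")


def nearest_psd_jitter(mat: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Symmetrise and lift tiny negative eigenvalues so Cholesky succeeds."""
    mat = 0.5 * (mat + mat.T)
    w, v = np.linalg.eigh(mat)
    w = np.maximum(w, eps)
    return (v * w) @ v.T
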