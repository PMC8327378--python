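"""Longitudinal representations: z-normalization, piecewise aggregate
approximation (PAA) and Symbolic Aggregate approXimation (SAX).

SAX turns a numeric series into a short word over a small alphabet:
z-normalize, average over ``n_segments`` equal-length frames, then map
each frame mean to a letter using the standard-normal quantile
breakpoints at ``1/α … (α−1)/α``.  Under the normality assumption the α
symbols are equiprobable; the word is invariant to affine transforms of
the input because of the normalization step.

Conventions (fixed and documented because they change outputs):

* the standard deviation uses denominator ``n`` (population form);
* a constant series z-normalizes to all zeros (guarded division);
* a frame mean exactly equal to a breakpoint maps to the *higher* symbol,
  so a constant series with α=2 reads ``"bb…b"``;
* irregularly sampled values are taken in time order, gaps are ignored —
  no interpolation is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError

ALPHABET = "abcdefghijklmnopqrst"
MAX_ALPHABET = len(ALPHABET)


@dataclass(frozen=True)
class SAXWord:
    """A symbolized series: the word, its geometry and its breakpoints."""

    symbols: str
    n_segments: int
    alphabet_size: int
    breakpoints: tuple[float, ...]

    def __str__(self) -> str:
        return self.symbols


def breakpoints(alphabet_size: int) -> np.ndarray:
    """Standard-normal quantiles at ``i/α`` for ``i = 1 … α−1``; strictly
    increasing and symmetric about 0."""
    if not 2 <= alphabet_size <= MAX_ALPHABET:
        raise DomainError(f"alphabet size must be in [2, {MAX_ALPHABET}]")
    return stats.norm.ppf(np.arange(1, alphabet_size) / alphabet_size)


def z_normalize(series) -> np.ndarray:
    """Shift/scale to mean 0, sd 1 (denominator ``n``); constant series
    map to all zeros.  Series shorter than 2 points have no scale."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise DomainError("z-normalization needs a 1-d series of length >= 2")
    sd = x.std()  # ddof=0
    if sd == 0.0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def paa(series, n_segments: int) -> np.ndarray:
    """Piecewise aggregate approximation: means over ``n_segments``
    equal-length frames.

    When the length is not divisible by ``n_segments``, each point
    contributes to the frame(s) covering its index interval in proportion
    to the overlap, so every frame averages exactly ``len/n_segments``
    points' worth of mass.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if not 1 <= n_segments <= n:
        raise DomainError(f"n_segments must be in [1, {n}], got {n_segments}")
    if n % n_segments == 0:
        return x.reshape(n_segments, n // n_segments).mean(axis=1)
    seg_len = n / n_segments
    out = np.empty(n_segments)
    for i in range(n_segments):
        lo, hi = i * seg_len, (i + 1) * seg_len
        j0, j1 = int(np.floor(lo)), int(np.ceil(hi))
        weights = np.minimum(np.arange(j0, j1) + 1, hi) - np.maximum(np.arange(j0, j1), lo)
        out[i] = np.dot(weights, x[j0:j1]) / seg_len
    return out


def sax(series, n_segments: int, alphabet_size: int) -> SAXWord:
    """Symbolize a series: z-normalize → PAA → breakpoint binning.

    A segment mean below the first breakpoint reads ``'a'``; means equal
    to a breakpoint map upward.
    """
    bp = breakpoints(alphabet_size)
    segments = paa(z_normalize(series), n_segments)
    indices = np.searchsorted(bp, segments, side="right")
    word = "".join(ALPHABET[i] for i in indices)
    return SAXWord(
        symbols=word,
        n_segments=n_segments,
        alphabet_size=alphabet_size,
        breakpoints=tuple(float(b) for b in bp),
    )
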