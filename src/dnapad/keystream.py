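"""One-time-pad keystream from the logistic map.

The shared secret (g, mu) seeds the logistic recurrence

    x_{n+1} = mu * x_n * (1 - x_n),   x_0 = g,

iterated in the chaotic regime (mu in (3.569945, 4]).  Each iterate is
thresholded to one key bit: bit_i = 1 if x_i >= threshold else 0, starting
at the first iterate x_1 (x_0 itself emits no bit).  Arithmetic is plain
IEEE double precision with no intermediate rounding, so the stream is
bit-reproducible across platforms; sensitivity to the initial value means
streams longer than a few hundred bits depend on every last digit of g.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["KeystreamParams", "logistic_orbit", "keystream_bits", "CHAOS_MU_MIN"]

# Onset of chaos for the logistic map (Feigenbaum accumulation point).
CHAOS_MU_MIN = 3.569945


@dataclass(frozen=True)
class KeystreamParams:
    """Logistic-map key parameters.

    g : initial value x_0, in (0, 1)
    mu : map parameter, in (3.569945, 4] (chaotic regime)
    threshold : bit threshold on iterates, in (0, 1); ties (x == threshold) emit 1
    nbits : number of key bits to produce
    """

    g: float
    mu: float
    threshold: float = 0.5
    nbits: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.g < 1.0:
            raise ValueError(f"g must lie in (0, 1), got {self.g}")
        if not CHAOS_MU_MIN < self.mu <= 4.0:
            raise ValueError(
                f"mu must lie in ({CHAOS_MU_MIN}, 4] for chaotic behaviour, got {self.mu}"
            )
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"threshold must lie in (0, 1), got {self.threshold}")
        if self.nbits < 0:
            raise ValueError("nbits must be non-negative")


def logistic_orbit(params: KeystreamParams, n: int) -> list[float]:
    """First *n* iterates x_1 .. x_n of the map, x_0 = params.g excluded."""
    x = params.g
    orbit = []
    for _ in range(n):
        x = params.mu * x * (1.0 - x)
        orbit.append(x)
    return orbit


def keystream_bits(params: KeystreamParams, nbits: int | None = None) -> str:
    """Threshold the orbit into a key bit string of length *nbits*.

    nbits defaults to params.nbits.  The m-bit stream is always a prefix of
    the n-bit stream for m < n under identical (g, mu, threshold).
    """
    n = params.nbits if nbits is None else nbits
    if n < 0:
        raise ValueError("nbits must be non-negative")
    t = params.threshold
    return "".join("1" if x >= t else "0" for x in logistic_orbit(params, n))
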