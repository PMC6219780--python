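"""Closed-form crack-probability model, evaluated in log10 space.

An attacker who holds only the public ciphertext must simultaneously
guess six independent choices; the crack probability is the product of
six factors:

    P1 = 1 / N1^n1          pick the reference strand for every plaintext bit
    P2 = 1 / C(n-15, 4)     pick the four 16-mer interception sites
    P3 = 1 / 4!             pick the bit-pair <-> base code table ordering
    P4, P6                  pick the strand <-> bit and fluorescence <-> bit maps
    P5 = 1 / C(4^n2, 2)     pick the primer pair among length-n2 sequences

with N1 the database size, n the reference-strand length, n1 the
plaintext bit length and n2 the primer length.  The schemes differ only
in the readout-convention factors: P4*P6 = 1/24 for the single-bit
scheme (1/12 x 1/2) and 1/576 for the double-bit scheme (1/24 x 1/24),
so the double-bit probability is always 1/24 of the single-bit one.

Totals:

    single:  P = 1 / (N1^n1 * C(n-15,4) * C(4^n2,2) * 24^2)
    double:  P = 1 / (N1^n1 * C(n-15,4) * C(4^n2,2) * 24^3)

These underflow double precision for realistic n1, so everything is
computed and stored as log10 and exponentiated only for display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy.special import gammaln

__all__ = [
    "SecurityParams",
    "CrackProbability",
    "components",
    "crack_probability",
    "crack_probability_table",
    "keyspace_estimate",
    "format_sci",
    "DEFAULTS",
]

_LN10 = math.log(10.0)

# The worked comparison point: a public database of 1.6e8 strands,
# kilobase reference strands, 5-nt primers.
DEFAULTS = dict(N1=1.6e8, n=1000, n2=5)

# Chaotic-regime width of the logistic parameter mu.
MU_RANGE = 4.0 - 3.569945
G_RANGE = 1.0


def _log10_choose(n: float, k: int) -> float:
    if n < k:
        raise ValueError(f"C({n},{k}) undefined for n < k")
    return (gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)) / _LN10


@dataclass(frozen=True)
class SecurityParams:
    """Attack-model parameters.

    N1 : number of strands in the public database
    n : reference strand length (nt), >= 19 so that C(n-15, 4) exists
    n1 : plaintext length in bits
    n2 : primer length (nt)
    scheme : 'single' or 'double'
    """

    N1: float
    n: int
    n1: int
    n2: int
    scheme: str = "single"

    def __post_init__(self) -> None:
        if min(self.N1, self.n, self.n1, self.n2) <= 0:
            raise ValueError("all parameters must be positive")
        if self.n - 15 < 4:
            raise ValueError(f"n={self.n} too short: C(n-15, 4) needs n >= 19")
        if self.scheme not in ("single", "double"):
            raise ValueError(f"scheme must be 'single' or 'double', got {self.scheme!r}")


@dataclass(frozen=True)
class CrackProbability:
    """Total log10 probability and its named factors (also log10)."""

    log10_p: float
    components: dict[str, float]

    @property
    def p(self) -> float:
        """Linear-scale probability; 0.0 if below double-precision underflow."""
        return 10.0**self.log10_p if self.log10_p > -307 else 0.0


def components(params: SecurityParams) -> dict[str, float]:
    """The six factors P1..P6 in log10.

    The single-bit readout factors are 1/12 and 1/2 (strand<->bit and
    signal<->bit conventions); the double-bit scheme replaces both with
    1/24 (full orderings of four strands and of four colours).
    """
    if params.scheme == "single":
        p4, p6 = -math.log10(12.0), -math.log10(2.0)
    else:
        p4 = p6 = -math.log10(24.0)
    return {
        "P1": -params.n1 * math.log10(params.N1),
        "P2": -_log10_choose(params.n - 15, 4),
        "P3": -math.log10(math.factorial(4)),
        "P4": p4,
        "P5": -_log10_choose(4.0**params.n2, 2),
        "P6": p6,
    }


def crack_probability(params: SecurityParams) -> CrackProbability:
    comp = components(params)
    return CrackProbability(log10_p=sum(comp.values()), components=comp)


def format_sci(log10_p: float, sig: int = 2) -> str:
    """Render a log10 probability as d.dE-ddd with *sig* significant figures."""
    exp = math.floor(log10_p)
    mant = 10.0 ** (log10_p - exp)
    mant = round(mant, sig - 1)
    if mant >= 10.0:  # rounding carried over
        mant /= 10.0
        exp += 1
    return f"{mant:.{sig - 1}f}E{exp:+04d}"


def crack_probability_table(
    n1_values=(24, 32, 40, 48, 56),
    N1: float = DEFAULTS["N1"],
    n: int = DEFAULTS["n"],
    n2: int = DEFAULTS["n2"],
) -> pd.DataFrame:
    """Crack probabilities of both schemes over a sweep of plaintext lengths.

    Values far below double-precision underflow remain exact in the
    ``log10`` columns; the formatted columns show 2 significant figures.
    """
    rows = []
    for n1 in n1_values:
        row = {"n1": n1}
        for scheme in ("single", "double"):
            cp = crack_probability(SecurityParams(N1, n, n1, n2, scheme))
            row[f"log10_{scheme}"] = cp.log10_p
            row[scheme] = format_sci(cp.log10_p)
        rows.append(row)
    return pd.DataFrame(rows, columns=["n1", "single", "double", "log10_single", "log10_double"])


def keyspace_estimate(digits_g: int, digits_mu: int) -> dict:
    """Size of the logistic-parameter keyspace at given decimal precisions.

    g ranges over (0, 1) and mu over the chaotic window (3.569945, 4], so
    at digits_g / digits_mu retained decimals the keyspace is
    1*10^digits_g x 0.430055*10^digits_mu distinguishable pairs.  The
    derivation is returned alongside the number.
    """
    if digits_g <= 0 or digits_mu <= 0:
        raise ValueError("digit counts must be positive")
    size = G_RANGE * 10.0**digits_g * MU_RANGE * 10.0**digits_mu
    return {
        "size": size,
        "log10_size": math.log10(size),
        "derivation": (
            f"(range g = {G_RANGE}) x 10^{digits_g} x "
            f"(range mu = {MU_RANGE:.6f}) x 10^{digits_mu} "
            f"= {MU_RANGE:.6f} x 10^{digits_g + digits_mu}"
        ),
    }
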