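"""Gel-based editing estimators: T7E1 mismatch cleavage and RFLP digestion.

Both estimators take band intensities as numeric inputs (quantified
externally): ``a`` is the uncleaved substrate band, ``b`` and ``c`` the two
cleavage products, so the cleaved fraction is f = (b+c)/(a+b+c).

T7 endonuclease I cleaves heteroduplexes formed when denatured PCR product
re-anneals with strands from different alleles.  Random strand pairing means
an edited-allele fraction m yields heteroduplexes at rate 1-(1-m)^2 (a
duplex escapes cleavage only when both strands are wild type, treating
distinct mutant alleles as mutually mismatched), nearly doubling the
apparent editing at small m.  The estimator inverts this:

    TE% = (1 - sqrt(1 - f)) * 100

Restriction digestion (e.g. HindIII on the HDR-introduced site) cleaves the
edited allele directly, so the fraction is read off without correction:

    HDR% = f * 100

``simulate_reannealing`` is a Monte-Carlo oracle for the pairing argument:
pairing strands uniformly at random from a pool with mutant fraction m and
applying the square-root correction to the simulated cleaved fraction
recovers m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


class NoSignalError(ValueError):
    """All band intensities are zero."""


@dataclass(frozen=True)
class GelBands:
    """Intensities (arbitrary units) of substrate ``a`` and products ``b``, ``c``."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        for name in "abc":
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"band {name} must be finite and >= 0, got {v}")

    @property
    def cleaved_fraction(self) -> float:
        total = self.a + self.b + self.c
        if total == 0:
            raise NoSignalError("all band intensities are zero")
        return (self.b + self.c) / total


def t7e1_total_editing(bands: GelBands) -> float:
    """Total editing percent from a T7E1 gel: (1 - sqrt(1 - f)) * 100.

    The square root undoes the random-pairing doubling of heteroduplexes.
    Monotone increasing in the cleaved fraction f; scale-invariant in the
    band intensities.
    """
    f = bands.cleaved_fraction
    return (1.0 - math.sqrt(1.0 - f)) * 100.0


def hindiii_hdr(bands: GelBands) -> float:
    """HDR percent from a restriction (RFLP) gel: f * 100.

    The enzyme cuts edited alleles directly, so no pairing correction is
    needed.
    """
    return bands.cleaved_fraction * 100.0


def simulate_reannealing(
    mutant_fraction: float,
    n_duplexes: int,
    seed: int | np.random.Generator = 0,
    distinct_mutants: bool = True,
) -> float:
    """Empirical cleaved fraction after denature/re-anneal of a mixed pool.

    Each duplex draws two strands independently from a pool with mutant
    fraction m; it is cleaved unless both strands are wild type.  With
    ``distinct_mutants=False`` identical mutant alleles re-form perfect
    duplexes and escape cleavage (cleaved only for mixed pairs), modelling a
    clonal mutant population.  Expectation: 1-(1-m)^2, or 2m(1-m) for the
    clonal case.
    """
    if not 0 <= mutant_fraction <= 1:
        raise ValueError("mutant_fraction must be in [0, 1]")
    if n_duplexes < 1:
        raise ValueError("n_duplexes must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s1 = rng.random(n_duplexes) < mutant_fraction
    s2 = rng.random(n_duplexes) < mutant_fraction
    cleaved = (s1 != s2) if not distinct_mutants else (s1 | s2)
    return float(cleaved.mean())
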