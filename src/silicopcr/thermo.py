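"""Nearest-neighbor duplex thermodynamics.

Melting temperature of a primer bound to a template site, from summed
nearest-neighbor enthalpy/entropy increments (the unified DNA parameter
set, with published single-mismatch and terminal-mismatch increments where
they exist), an entropy-term monovalent-salt correction, and the standard
two-state Tm expression.  Degenerate positions contribute the arithmetic
mean of dH and dS over the concrete expansions at each stack — the Tm of
the averaged parameters, not an extremum over expansions.

The annealing-temperature rule used for predicted amplicons is the lowest
primer Tm plus the natural logarithm of the product length.

Parameter tables are taken from Biopython's MeltingTemp module (unified
nearest-neighbor set ``DNA_NN3``; internal mismatches ``DNA_IMM1``;
terminal mismatches ``DNA_TMM1``) so perfect-match and single-mismatch
values agree with that implementation; the degeneracy-averaged summation
here is our own.
"""

from __future__ import annotations

import math
from itertools import product

from Bio.SeqUtils import MeltingTemp as mt

from .seqcore import COMPLEMENT, IUPAC_SETS

__all__ = ["nn_tm", "annealing_temperature", "DEFAULT_PRIMER_NM", "DEFAULT_NA_MM"]

#: Default primer concentration (nM) — the PCR recipe the predictions model.
DEFAULT_PRIMER_NM = 400.0
#: Default monovalent cation concentration (mM).
DEFAULT_NA_MM = 50.0

_R = 1.987  # gas constant, cal/(K*mol)
_MIN_DUPLEX = 8

_NN = mt.DNA_NN3
_IMM = mt.DNA_IMM1
_TMM = mt.DNA_TMM1

_WC = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _stack_params(p0: str, p1: str, c0: str, c1: str, terminal: str | None) -> tuple[float, float]:
    """dH (kcal/mol), dS (cal/mol/K) for one concrete stack.

    ``p0 p1`` is the primer dinucleotide 5'->3'; ``c0 c1`` the bound
    template strand beneath it (3'->5', same left-to-right order).
    ``terminal`` marks the leftmost/rightmost stack so that terminal
    mismatch parameters apply there.  Unparameterised mismatch stacks
    contribute (0, 0): the duplex simply loses that stack's stabilisation.
    """
    if terminal == "left":
        key = c1 + c0 + "/" + p1 + p0
        if key in _TMM:
            return _TMM[key]
    elif terminal == "right":
        key = p0 + p1 + "/" + c0 + c1
        if key in _TMM:
            return _TMM[key]
    key = p0 + p1 + "/" + c0 + c1
    rkey = c1 + c0 + "/" + p1 + p0  # same stack read from the other strand
    for table in (_IMM, _NN):
        if key in table:
            return table[key]
        if rkey in table:
            return table[rkey]
    return (0.0, 0.0)


def _mean_over_expansions(chars: tuple[str, ...], fn) -> tuple[float, float]:
    """Arithmetic mean of (dH, dS) over the concrete expansions of a tuple
    of IUPAC codes."""
    sets = [sorted(IUPAC_SETS[c]) for c in chars]
    total_h = total_s = 0.0
    n = 0
    for combo in product(*sets):
        h, s = fn(*combo)
        total_h += h
        total_s += s
        n += 1
    return total_h / n, total_s / n


def nn_tm(
    primer: str,
    site: str | None = None,
    primer_nm: float = DEFAULT_PRIMER_NM,
    na_mm: float = DEFAULT_NA_MM,
) -> float:
    """Melting temperature (Celsius) of the primer/site duplex.

    ``site`` is the template site in the primer's own sense (equal length,
    gap-free); it defaults to the primer itself, i.e. a perfect duplex.
    Either strand may contain degenerate codes; each stack contributes the
    mean dH/dS over its concrete expansions.  Duplexes shorter than 8 nt
    are refused (two-state nearest-neighbor model not valid).
    """
    p = primer.upper()
    s = (site if site is not None else primer).upper()
    if len(p) != len(s):
        raise ValueError("primer and site must be aligned to equal length")
    n = len(p)
    if n < _MIN_DUPLEX:
        raise ValueError(f"duplex of {n} nt is too short for the NN model (min {_MIN_DUPLEX})")
    # Bound template strand, same left-to-right order (3'->5').
    c = [COMPLEMENT[ch] for ch in s]

    dh = ds = 0.0
    # Helix initiation: per-terminal increments keyed on the primer's
    # terminal base (averaged when degenerate).
    for j in (0, n - 1):
        th = ts = 0.0
        bases = sorted(IUPAC_SETS[p[j]])
        for b in bases:
            key = "init_A/T" if b in "AT" else "init_G/C"
            th += _NN[key][0]
            ts += _NN[key][1]
        dh += th / len(bases)
        ds += ts / len(bases)
    # Stacks.
    for i in range(n - 1):
        terminal = "left" if i == 0 else ("right" if i == n - 2 else None)
        h, s_ = _mean_over_expansions(
            (p[i], p[i + 1], c[i], c[i + 1]),
            lambda a0, a1, b0, b1: _stack_params(a0, a1, b0, b1, terminal),
        )
        dh += h
        ds += s_
    # Entropy salt correction at the configured monovalent concentration.
    ds += 0.368 * (n - 1) * math.log(na_mm * 1e-3)
    k = primer_nm * 1e-9  # excess primer over template
    return (1000.0 * dh) / (ds + _R * math.log(k)) - 273.15


def annealing_temperature(tm_min: float, product_length: float) -> float:
    """Recommended PCR annealing temperature: the lowest primer Tm plus the
    natural logarithm of the product length (bp)."""
    if product_length <= 0:
        raise ValueError("product length must be positive")
    return tm_min + math.log(product_length)
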