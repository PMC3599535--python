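"""Nei-Gojobori (1986) pairwise dN/dS counting.

Site counting: for each codon position the synonymous site fraction is the
share of single-nucleotide changes that preserve the amino acid, with changes
creating stop codons removed from the denominator; per codon the synonymous
and nonsynonymous site counts always sum to 3.

Difference counting: codon pairs differing at several positions are resolved
by averaging synonymous/nonsynonymous step counts over all minimal mutational
pathways (orderings of the differing positions), with equal weights; pathways
passing through a stop codon are excluded, and a codon pair whose every
pathway passes a stop is skipped entirely.

Proportions of differences per site are converted to rates with the
Jukes-Cantor multiple-hit correction d = -3/4 ln(1 - 4p/3).
"""

from __future__ import annotations

import functools
import itertools
import math

from Bio.Data.CodonTable import unambiguous_dna_by_id

__all__ = [
    "BASES",
    "SENSE_CODONS",
    "STOP_CODONS",
    "translate_codon",
    "ng86_sites",
    "codon_differences",
    "jukes_cantor",
    "SaturationError",
    "InvalidCodonError",
]

BASES = "ACGT"
_TABLE = unambiguous_dna_by_id[1]  # the standard genetic code
STOP_CODONS = frozenset(_TABLE.stop_codons)
_AA = dict(_TABLE.forward_table)
SENSE_CODONS = tuple(sorted(_AA))


class InvalidCodonError(ValueError):
    """Codon is a stop, contains a gap, or has an ambiguous base."""


class SaturationError(ValueError):
    """Observed difference proportion at or beyond the Jukes-Cantor limit."""


def translate_codon(codon: str) -> str:
    try:
        return _AA[codon]
    except KeyError:
        raise InvalidCodonError(codon) from None


def _check_sense(codon: str) -> None:
    if codon in STOP_CODONS:
        raise InvalidCodonError(f"stop codon {codon}")
    if codon not in _AA:
        raise InvalidCodonError(f"not an unambiguous sense codon: {codon!r}")


@functools.lru_cache(maxsize=None)
def ng86_sites(codon: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) site counts of one sense codon.

    Stop-creating neighbours are excluded from each position's denominator;
    the two counts sum to 3 for every sense codon.
    """
    _check_sense(codon)
    aa = _AA[codon]
    s_sites = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            neighbour = codon[:pos] + b + codon[pos + 1 :]
            if neighbour in STOP_CODONS:
                continue
            valid += 1
            if _AA[neighbour] == aa:
                syn += 1
        if valid:
            s_sites += syn / valid
    return 3.0 - s_sites, s_sites


@functools.lru_cache(maxsize=None)
def codon_differences(codon1: str, codon2: str) -> tuple[float, float] | None:
    """Pathway-averaged (nonsynonymous, synonymous) difference counts.

    Returns ``None`` when every minimal pathway between the codons passes
    through a stop codon (the pair must then be skipped).
    """
    _check_sense(codon1)
    _check_sense(codon2)
    diff_positions = [i for i in range(3) if codon1[i] != codon2[i]]
    if not diff_positions:
        return 0.0, 0.0
    n_tot = s_tot = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_positions):
        current = codon1
        n = s = 0
        ok = True
        for pos in order:
            nxt = current[:pos] + codon2[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if _AA[current] == _AA[nxt]:
                s += 1
            else:
                n += 1
            current = nxt
        if ok:
            n_paths += 1
            n_tot += n
            s_tot += s
    if n_paths == 0:
        return None
    return n_tot / n_paths, s_tot / n_paths


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor distance for a proportion of differing sites."""
    if p < 0:
        raise ValueError(p)
    if p >= 0.75:
        raise SaturationError(f"proportion {p} is saturated (>= 3/4)")
    return -0.75 * math.log(1 - 4.0 * p / 3.0)
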