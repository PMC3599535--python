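"""Independent brute-force oracles used by the test suite.

Each oracle re-derives the expected behaviour from first principles
(exhaustive scans, direct enumeration, tail sums), without touching the
implementation paths it checks.
"""

from __future__ import annotations

import itertools
import math

from Bio.Seq import Seq

BASES = "ACGT"


def translate(codon: str) -> str:
    return str(Seq(codon).translate())


def is_stop(codon: str) -> bool:
    return translate(codon) == "*"


# -- age assignment ---------------------------------------------------------


def oldest_first_age_rank(presence: dict[str, bool], clades: list[list[str]]) -> int:
    """Scan clades oldest-first (highest index first) and return the rank of
    the first clade with a present species; 0 (youngest) if none."""
    for rank in range(len(clades) - 1, -1, -1):
        if any(presence.get(sp, False) for sp in clades[rank]):
            return rank
    return 0


# -- overlap resolution -----------------------------------------------------


def greedy_overlap_oracle(hits):
    """Keep hits in (E-value, -length, id) order, rejecting any residue overlap."""
    order = sorted(hits, key=lambda h: (h.e_value, -(h.end - h.start + 1), h.domain_type_id))
    kept = []
    for h in order:
        if all(h.end < k.start or h.start > k.end for k in kept):
            kept.append(h)
    return sorted(kept, key=lambda h: (h.start, h.end, h.domain_type_id))


# -- scenario classification ------------------------------------------------


def collapse_runs(types):
    out = []
    for t in types:
        if not out or out[-1] != t:
            out.append(t)
    return tuple(out)


def configurations_oracle(type_id, dataset):
    return {collapse_runs(a.domain_types) for a in dataset if type_id in a.domain_types}


def classify_pair_oracle(young, old, dataset):
    """Direct transcription of the four-way definition."""
    y_ind = len(configurations_oracle(young, dataset)) >= 2
    o_ind = len(configurations_oracle(old, dataset)) >= 2
    if o_ind and not y_ind:
        return "GAIN_DEPENDENT"
    if not o_ind and not y_ind:
        return "MUTUAL_DEPENDENCE"
    if o_ind and y_ind:
        return "FUSION"
    return "REVERSE_DEPENDENT"


def classify_protein_oracle(arch, dataset, young_of):
    """Classify every young-old type pair independently, then reduce."""
    young = sorted({t for t in arch.domain_types if young_of(t)})
    old = sorted({t for t in arch.domain_types if not young_of(t)})
    labels = {classify_pair_oracle(y, o, dataset) for y in young for o in old}
    return labels.pop() if len(labels) == 1 else "COMPLEX"


# -- NG86 -------------------------------------------------------------------


def ng86_sites_oracle(codon: str) -> tuple[float, float]:
    """Per-position single-neighbour enumeration against the standard code."""
    aa = translate(codon)
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            nb = codon[:pos] + b + codon[pos + 1 :]
            if is_stop(nb):
                continue
            valid += 1
            syn += translate(nb) == aa
        if valid:
            s += syn / valid
    return 3.0 - s, s


def pathway_counts_oracle(c1: str, c2: str):
    """Exhaustive enumeration of minimal mutational pathways."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    totals = []
    for order in itertools.permutations(diffs):
        cur, n, s, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if is_stop(nxt):
                ok = False
                break
            if translate(cur) == translate(nxt):
                s += 1
            else:
                n += 1
            cur = nxt
        if ok:
            totals.append((n, s))
    if not totals:
        return None
    return (
        sum(t[0] for t in totals) / len(totals),
        sum(t[1] for t in totals) / len(totals),
    )


def dnds_oracle(seq1: str, seq2: str):
    """Whole-alignment NG86 estimate from the two oracles above."""
    n_sites = s_sites = nd = sd = 0.0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        if "-" in c1 or "-" in c2 or is_stop(c1) or is_stop(c2):
            continue
        diffs = pathway_counts_oracle(c1, c2)
        if diffs is None:
            continue
        n1, s1 = ng86_sites_oracle(c1)
        n2, s2 = ng86_sites_oracle(c2)
        n_sites += (n1 + n2) / 2
        s_sites += (s1 + s2) / 2
        nd += diffs[0]
        sd += diffs[1]
    pn, ps = nd / n_sites, sd / s_sites
    dn = -0.75 * math.log(1 - 4 * pn / 3)
    ds = -0.75 * math.log(1 - 4 * ps / 3)
    return {"n_sites": n_sites, "s_sites": s_sites, "nd": nd, "sd": sd,
            "dn": dn, "ds": ds}


# -- binomial tail ----------------------------------------------------------


def binom_pmf(k: int, n: int, p: float) -> float:
    return math.comb(n, k) * p**k * (1 - p) ** (n - k)


def two_sided_binom_p_oracle(k: int, n: int, p0: float) -> float:
    """Two-sided exact binomial p-value: sum of all outcomes with pmf no
    larger than the observed one (the standard minlike definition)."""
    obs = binom_pmf(k, n, p0)
    return min(
        1.0,
        sum(binom_pmf(j, n, p0) for j in range(n + 1) if binom_pmf(j, n, p0) <= obs * (1 + 1e-12)),
    )


# -- region extraction ------------------------------------------------------


def extract_region_oracle(ref: str, oth: str, start_aa: int, end_aa: int):
    """Walk alignment columns counting ungapped reference codons; keep
    columns of reference codons start..end plus interior gap columns."""
    cols = []
    count = 0
    for c in range(len(ref) // 3):
        codon = ref[3 * c : 3 * c + 3]
        if codon != "---":
            count += 1
            if start_aa <= count <= end_aa:
                cols.append(c)
        else:
            if cols and count < end_aa:
                cols.append(c)
    r = "".join(ref[3 * c : 3 * c + 3] for c in cols)
    o = "".join(oth[3 * c : 3 * c + 3] for c in cols)
    return r, o
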