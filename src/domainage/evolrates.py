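"""Per-domain-region dN/dS estimation and young-vs-old comparisons.

Domain regions are cut out of pairwise codon alignments of 1:1 orthologous
coding sequences (reference species first) by reference amino-acid
coordinates, and their divergence is estimated with NG86 counting
(:mod:`domainage.ng86`).  Estimates are then filtered for reliability
(regions shorter than 60 aa, or with dN > 0.5 or dS > 2, are flagged out but
never deleted) and compared between age groups: two-sample
Kolmogorov-Smirnov tests across independent groups, a paired Wilcoxon
signed-rank test for young/old domains of the same protein, and a per-pair
binomial test on substitution counts with a site-adjusted null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import ng86
from ._util import round_half_up

__all__ = [
    "CodonAlignmentPair",
    "RateEstimate",
    "PairedComparison",
    "FilterThresholds",
    "extract_domain_region",
    "estimate_dnds",
    "apply_filters",
    "relative_difference",
    "paired_binomial_test",
    "compare_age_groups",
]

GAP = "-"


@dataclass(frozen=True)
class CodonAlignmentPair:
    """Gap-aligned coding sequences of a reference/ortholog pair.

    Gaps come in codon multiples so every aligned triplet is either a full
    codon or a full gap in each sequence.
    """

    ref_id: str
    oth_id: str
    ref_seq: str
    oth_seq: str

    def __post_init__(self) -> None:
        if len(self.ref_seq) != len(self.oth_seq):
            raise ValueError("aligned sequences differ in length")
        if len(self.ref_seq) % 3:
            raise ValueError("aligned length is not a codon multiple")
        for seq in (self.ref_seq, self.oth_seq):
            for i in range(0, len(seq), 3):
                codon = seq[i : i + 3]
                if GAP in codon and codon != GAP * 3:
                    raise ValueError(f"gap not in codon multiples at column {i}")

    @property
    def n_columns(self) -> int:
        """Number of aligned codon columns."""
        return len(self.ref_seq) // 3

    def codon_columns(self):
        for i in range(0, len(self.ref_seq), 3):
            yield self.ref_seq[i : i + 3], self.oth_seq[i : i + 3]

    @property
    def ref_length_aa(self) -> int:
        """Ungapped reference length in codons."""
        return sum(1 for r, _ in self.codon_columns() if r != GAP * 3)


def extract_domain_region(
    pair: CodonAlignmentPair, start_aa: int, end_aa: int
) -> CodonAlignmentPair:
    """Sub-alignment spanning reference codons ``start_aa``..``end_aa``.

    Coordinates are 1-based inclusive on the ungapped reference sequence;
    gap columns internal to the span are retained.
    """
    if not 1 <= start_aa <= end_aa:
        raise ValueError(f"bad span {start_aa}-{end_aa}")
    if end_aa > pair.ref_length_aa:
        raise ValueError(
            f"span {start_aa}-{end_aa} beyond reference length {pair.ref_length_aa}"
        )
    cols: list[int] = []
    ref_codon = 0
    for col, (r, _) in enumerate(pair.codon_columns()):
        if r != GAP * 3:
            ref_codon += 1
            if start_aa <= ref_codon <= end_aa:
                cols.append(col)
        elif cols and ref_codon < end_aa:
            cols.append(col)  # interior gap column
    ref = "".join(pair.ref_seq[3 * c : 3 * c + 3] for c in cols)
    oth = "".join(pair.oth_seq[3 * c : 3 * c + 3] for c in cols)
    return CodonAlignmentPair(pair.ref_id, pair.oth_id, ref, oth)


@dataclass(frozen=True)
class RateEstimate:
    """NG86 counts and rates for one domain region (or whole alignment)."""

    occurrence_id: str
    aligned_aa_length: int
    n_sites: float
    s_sites: float
    nd: float
    sd: float
    pn: float
    ps: float
    dn: float
    ds: float
    omega: float  # NaN when dS == 0
    pass_filter: bool = True

    @property
    def omega_defined(self) -> bool:
        return not math.isnan(self.omega)


def estimate_dnds(
    region: CodonAlignmentPair, occurrence_id: str | None = None
) -> RateEstimate:
    """NG86 estimate over the comparable codons of an aligned region.

    Columns gapped in either sequence, codons with ambiguous bases or stops,
    and codon pairs whose every mutational pathway passes a stop are all
    skipped (sites and differences alike).  Raises
    :class:`~domainage.ng86.SaturationError` when pN or pS reaches the
    Jukes-Cantor limit and ``ValueError`` when no codon is comparable.
    """
    n_sites = s_sites = nd = sd = 0.0
    for r_codon, o_codon in region.codon_columns():
        if GAP in r_codon or GAP in o_codon:
            continue
        try:
            diffs = ng86.codon_differences(r_codon, o_codon)
        except ng86.InvalidCodonError:
            continue
        if diffs is None:
            continue
        n1, s1 = ng86.ng86_sites(r_codon)
        n2, s2 = ng86.ng86_sites(o_codon)
        n_sites += (n1 + n2) / 2.0
        s_sites += (s1 + s2) / 2.0
        nd += diffs[0]
        sd += diffs[1]
    if n_sites + s_sites == 0:
        raise ValueError("no comparable codons in region")
    pn = nd / n_sites if n_sites else 0.0
    ps = sd / s_sites if s_sites else 0.0
    dn = ng86.jukes_cantor(pn)
    ds = ng86.jukes_cantor(ps)
    omega = dn / ds if ds > 0 else float("nan")
    return RateEstimate(
        occurrence_id=occurrence_id or f"{region.ref_id}",
        aligned_aa_length=region.ref_length_aa,
        n_sites=n_sites,
        s_sites=s_sites,
        nd=nd,
        sd=sd,
        pn=pn,
        ps=ps,
        dn=dn,
        ds=ds,
        omega=omega,
    )


@dataclass(frozen=True)
class FilterThresholds:
    """Reliability filter: keep regions with length >= min_aa, dN <= max_dn,
    dS <= max_ds (boundaries inclusive on the keep side)."""

    min_aa: int = 60
    max_dn: float = 0.5
    max_ds: float = 2.0


def apply_filters(
    est: RateEstimate, thresholds: FilterThresholds = FilterThresholds()
) -> RateEstimate:
    """Flag (never drop) estimates failing the reliability filter."""
    ok = (
        est.aligned_aa_length >= thresholds.min_aa
        and est.dn <= thresholds.max_dn
        and est.ds <= thresholds.max_ds
    )
    return replace(est, pass_filter=ok)


def relative_difference(omega_young: float, omega_old: float) -> float:
    """(w_young - w_old) / max(w_young, w_old), bounded in [-1, 1]."""
    for w in (omega_young, omega_old):
        if math.isnan(w):
            raise ValueError("relative difference undefined for NaN omega")
        if w < 0:
            raise ValueError("omega must be non-negative")
    if omega_young == omega_old:
        return 0.0
    return (omega_young - omega_old) / max(omega_young, omega_old)


@dataclass(frozen=True)
class PairedComparison:
    """Young-vs-old rate comparison for one domain pair of one protein."""

    protein_id: str
    young: RateEstimate
    old: RateEstimate
    rel_difference: float
    pvalue: float
    verdict: str  # young_faster | old_faster | no_difference
    degenerate: bool = False


def paired_binomial_test(
    young: RateEstimate,
    old: RateEstimate,
    alpha: float = 0.01,
    protein_id: str = "",
    site_adjusted: bool = True,
) -> PairedComparison:
    """Binomial test of the young domain's substitution spectrum against the
    old domain's rates.

    Successes are the young domain's nonsynonymous substitutions (rounded,
    half up), trials the rounded total substitutions.  The null success
    probability is the old domain's per-site rates projected onto the young
    domain's site composition:

        p0 = N_y * (Nd_o / N_o) / (N_y * (Nd_o / N_o) + S_y * (Sd_o / S_o))

    (``site_adjusted=False`` uses the unadjusted p0 = Nd_o / (Nd_o + Sd_o)).
    Degenerate inputs (no trials, or p0 at 0 or 1 with observations) yield a
    flagged ``no_difference``.
    """
    successes = int(round_half_up(young.nd))
    trials = int(round_half_up(young.nd + young.sd))
    successes = min(successes, trials)
    if young.omega_defined and old.omega_defined:
        rel = relative_difference(young.omega, old.omega)
    else:
        rel = float("nan")

    if site_adjusted:
        rate_n = old.nd / old.n_sites if old.n_sites else 0.0
        rate_s = old.sd / old.s_sites if old.s_sites else 0.0
        num = young.n_sites * rate_n
        den = num + young.s_sites * rate_s
        p0 = num / den if den > 0 else float("nan")
    else:
        tot = old.nd + old.sd
        p0 = old.nd / tot if tot > 0 else float("nan")

    if trials == 0 or math.isnan(p0) or p0 <= 0.0 or p0 >= 1.0:
        return PairedComparison(
            protein_id, young, old, rel, float("nan"), "no_difference", True
        )
    p = stats.binomtest(successes, trials, p0).pvalue
    if p > alpha:
        verdict = "no_difference"
    elif successes / trials > p0:
        verdict = "young_faster"
    else:
        verdict = "old_faster"
    return PairedComparison(protein_id, young, old, rel, float(p), verdict)


# ---------------------------------------------------------------------------
# group-level comparisons


@dataclass
class GroupComparison:
    group_stats: pd.DataFrame
    ks_tests: pd.DataFrame
    wilcoxon_stat: float
    wilcoxon_p: float
    per_type_medians: pd.DataFrame | None = None


def compare_age_groups(
    omegas_by_group: Mapping[str, Sequence[float]],
    paired: Sequence[tuple[float, float]] = (),
    domain_types_by_group: Mapping[str, Sequence[str]] | None = None,
) -> GroupComparison:
    """Distributional comparison of omega across age groups.

    ``omegas_by_group`` maps (merged) age labels to omega values of passing
    estimates with defined omega; ``paired`` holds (young, old) omega tuples
    from the same protein for the Wilcoxon signed-rank test.  When
    ``domain_types_by_group`` supplies a parallel domain-type id per value,
    per-type median omegas are also reported (an aggregation that removes the
    weight of very abundant domain families).
    """
    rows = []
    for label, values in omegas_by_group.items():
        arr = np.asarray([v for v in values if not math.isnan(v)], dtype=float)
        rows.append(
            {
                "group": label,
                "n": len(arr),
                "median": float(np.median(arr)) if len(arr) else float("nan"),
                "q1": float(np.percentile(arr, 25)) if len(arr) else float("nan"),
                "q3": float(np.percentile(arr, 75)) if len(arr) else float("nan"),
            }
        )
    group_stats = pd.DataFrame(rows)

    ks_rows = []
    labels = list(omegas_by_group)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            xa = np.asarray(omegas_by_group[a], dtype=float)
            xb = np.asarray(omegas_by_group[b], dtype=float)
            xa = xa[~np.isnan(xa)]
            xb = xb[~np.isnan(xb)]
            if len(xa) < 2 or len(xb) < 2:
                ks_rows.append(
                    {"group_a": a, "group_b": b, "statistic": float("nan"),
                     "pvalue": float("nan"), "skipped": True}
                )
                continue
            res = stats.ks_2samp(xa, xb)
            ks_rows.append(
                {"group_a": a, "group_b": b, "statistic": float(res.statistic),
                 "pvalue": float(res.pvalue), "skipped": False}
            )
    ks_tests = pd.DataFrame(
        ks_rows, columns=["group_a", "group_b", "statistic", "pvalue", "skipped"]
    )

    if len(paired) >= 2 and any(y != o for y, o in paired):
        y, o = zip(*paired)
        w = stats.wilcoxon(list(y), list(o))
        w_stat, w_p = float(w.statistic), float(w.pvalue)
    else:
        w_stat, w_p = float("nan"), float("nan")

    per_type = None
    if domain_types_by_group is not None:
        recs = []
        for label, values in omegas_by_group.items():
            types = domain_types_by_group[label]
            for t, v in zip(types, values):
                if not math.isnan(v):
                    recs.append({"group": label, "domain_type": t, "omega": v})
        if recs:
            per_type = (
                pd.DataFrame(recs)
                .groupby(["group", "domain_type"])["omega"]
                .median()
                .reset_index()
            )
    return GroupComparison(group_stats, ks_tests, w_stat, w_p, per_type)
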