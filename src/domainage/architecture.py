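"""Domain architectures, young-old arrangement scenarios and positional bias.

An architecture is the ordered tuple of domain types along a protein, read
off the filtered, overlap-resolved hits.  For proteins combining a young
(lineage-specific) and an old domain, the arrangement of the two types across
the whole dataset distinguishes how the combination arose:

* class 1 (gain_dependent)   — the old type also occurs in other
  configurations but the young type does not: compatible with the gain of a
  young domain inside an existing older protein;
* class 2 (mutual_dependence) — neither type occurs elsewhere;
* class 3 (fusion)            — both types also occur elsewhere: compatible
  with fusion of two pre-existing units;
* class 4 (complex)           — proteins with more than two domains whose
  young-old pairs disagree.

Classes 1 and 2 are jointly "gain-compatible".  The module also locates the
young domain within multi-domain proteins (N-terminal / internal /
C-terminal) and tests the position counts against a uniform-insertion null
with a chi-square goodness-of-fit test.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .phylostrata import AgeClass

__all__ = [
    "DomainHit",
    "Architecture",
    "ScenarioClass",
    "PositionLabel",
    "PositionalTestResult",
    "resolve_overlaps",
    "configuration",
    "configurations_of",
    "is_independent",
    "classify_pair",
    "classify_protein",
    "young_position",
    "young_positions",
    "positional_bias_test",
]


@dataclass(frozen=True)
class DomainHit:
    """One located domain occurrence (1-based inclusive aa coordinates)."""

    protein_id: str
    domain_type_id: str
    start: int
    end: int
    e_value: float = 0.0

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"bad coordinates {self.start}-{self.end} on {self.protein_id}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Architecture:
    """Ordered domain content of one protein."""

    protein_id: str
    domain_types: tuple[str, ...]
    ages: tuple[AgeClass, ...]

    def __post_init__(self) -> None:
        if len(self.domain_types) < 1:
            raise ValueError("an architecture has at least one domain")
        if len(self.ages) != len(self.domain_types):
            raise ValueError("one age per domain required")


class ScenarioClass(enum.Enum):
    GAIN_DEPENDENT = 1      # young depends on the old domain
    MUTUAL_DEPENDENCE = 2   # neither found elsewhere
    FUSION = 3              # both found elsewhere
    COMPLEX = 4             # >2 domains, pairs disagree
    # the symmetric case (old depends on young); tracked separately, the
    # study design predicts it to be empty
    REVERSE_DEPENDENT = 5

    @property
    def gain_compatible(self) -> bool:
        return self in (ScenarioClass.GAIN_DEPENDENT, ScenarioClass.MUTUAL_DEPENDENCE)


class PositionLabel(enum.Enum):
    N_TERMINAL = "N_terminal"
    INTERNAL = "internal"
    C_TERMINAL = "C_terminal"


# ---------------------------------------------------------------------------
# hit processing


def resolve_overlaps(
    hits: Sequence[DomainHit], max_overlap_fraction: float = 0.0
) -> list[DomainHit]:
    """Greedy overlap resolution among hits on one protein.

    Hits are ranked by (E-value, longer first, domain id); each hit is kept
    only if it overlaps every already-kept hit by at most
    ``max_overlap_fraction`` of the shorter hit (default: no residue overlap
    allowed).  Output is sorted by start coordinate.
    """
    if not hits:
        return []
    pids = {h.protein_id for h in hits}
    if len(pids) > 1:
        raise ValueError(f"hits span multiple proteins: {sorted(pids)}")
    ranked = sorted(hits, key=lambda h: (h.e_value, -h.length, h.domain_type_id))
    kept: list[DomainHit] = []
    for h in ranked:
        ok = True
        for k in kept:
            ov = min(h.end, k.end) - max(h.start, k.start) + 1
            if ov > max_overlap_fraction * min(h.length, k.length):
                ok = False
                break
        if ok:
            kept.append(h)
    return sorted(kept, key=lambda h: (h.start, h.end, h.domain_type_id))


def configuration(
    domain_types: Sequence[str], collapse_tandem: bool = True, ordered: bool = True
) -> tuple[str, ...]:
    """Configuration identity of an architecture.

    By default the ordered tuple of domain types with tandem runs of the same
    type collapsed to one element, so copy-number variation of repeat arrays
    (e.g. Zn-finger cassettes) does not create spurious extra configurations.
    ``ordered=False`` falls back to a sorted multiset-free identity.
    """
    types: Iterable[str] = domain_types
    if collapse_tandem:
        types = (t for t, _ in itertools.groupby(domain_types))
    tup = tuple(types)
    if not ordered:
        tup = tuple(sorted(set(tup)))
    return tup


def configurations_of(
    domain_type_id: str,
    dataset: Sequence[Architecture],
    collapse_tandem: bool = True,
    ordered: bool = True,
) -> set[tuple[str, ...]]:
    """All distinct configurations of proteins containing the given type."""
    return {
        configuration(a.domain_types, collapse_tandem, ordered)
        for a in dataset
        if domain_type_id in a.domain_types
    }


def is_independent(domain_type_id: str, dataset: Sequence[Architecture]) -> bool:
    """A type is independent if it occurs in at least two distinct configurations."""
    return len(configurations_of(domain_type_id, dataset)) >= 2


def classify_pair(
    young_type: str, old_type: str, dataset: Sequence[Architecture]
) -> ScenarioClass:
    """Scenario class of one young-old type pair across the dataset."""
    co = [
        a
        for a in dataset
        if young_type in a.domain_types and old_type in a.domain_types
    ]
    if not co:
        raise ValueError(
            f"types {young_type!r} and {old_type!r} never co-occur in a protein"
        )
    young_ind = is_independent(young_type, dataset)
    old_ind = is_independent(old_type, dataset)
    if old_ind and not young_ind:
        return ScenarioClass.GAIN_DEPENDENT
    if not old_ind and not young_ind:
        return ScenarioClass.MUTUAL_DEPENDENCE
    if old_ind and young_ind:
        return ScenarioClass.FUSION
    return ScenarioClass.REVERSE_DEPENDENT


def classify_protein(
    arch: Architecture,
    dataset: Sequence[Architecture],
    ranking=None,
) -> ScenarioClass:
    """Scenario class of a protein combining young and old domains.

    All young-old type pairs present in the protein are classified; if they
    agree the protein takes that class, otherwise (possible only with more
    than two domains) it is complex.
    """
    from .phylostrata import DEFAULT_RANKING

    ranking = ranking or DEFAULT_RANKING
    young_types = sorted(
        {t for t, a in zip(arch.domain_types, arch.ages) if ranking.is_young(a)}
    )
    old_types = sorted(
        {t for t, a in zip(arch.domain_types, arch.ages) if not ranking.is_young(a)}
    )
    if not young_types or not old_types:
        raise ValueError(
            f"protein {arch.protein_id} does not combine young and old domains"
        )
    classes = {
        classify_pair(y, o, dataset) for y in young_types for o in old_types
    }
    if len(classes) == 1:
        return classes.pop()
    return ScenarioClass.COMPLEX


# ---------------------------------------------------------------------------
# position of the young domain


def young_position(arch: Architecture, young_index: int) -> PositionLabel:
    """Locate the young domain occurrence at tuple index ``young_index``."""
    n = len(arch.domain_types)
    if n < 2:
        raise ValueError("position is undefined for single-domain proteins")
    if not 0 <= young_index < n:
        raise IndexError(young_index)
    if young_index == 0:
        return PositionLabel.N_TERMINAL
    if young_index == n - 1:
        return PositionLabel.C_TERMINAL
    return PositionLabel.INTERNAL


def young_positions(arch: Architecture, ranking=None) -> list[PositionLabel]:
    """Position labels for every young-age occurrence in a multi-domain protein."""
    from .phylostrata import DEFAULT_RANKING

    ranking = ranking or DEFAULT_RANKING
    return [
        young_position(arch, i)
        for i, a in enumerate(arch.ages)
        if ranking.is_young(a)
    ]


@dataclass
class PositionalTestResult:
    statistic: float
    pvalue: float
    dof: int
    observed: dict[str, int]
    expected: dict[str, float]
    small_sample_warning: bool


def positional_bias_test(
    counts: Mapping[PositionLabel, int],
    k_distribution: Sequence[int] | None = None,
) -> PositionalTestResult:
    """Chi-square goodness of fit of young-domain positions against a
    uniform-insertion null.

    For the two-domain stratum (``k_distribution`` omitted) the null is an
    even N/C split.  For the >2-domain stratum, pass the per-protein domain
    counts k; the null inserts the young domain uniformly among the k slots,
    giving expected probabilities 1/k (N), 1/k (C) and (k-2)/k (internal),
    aggregated over the observed k distribution.
    """
    if k_distribution is None:
        labels = [PositionLabel.N_TERMINAL, PositionLabel.C_TERMINAL]
        obs = [counts.get(lab, 0) for lab in labels]
        total = sum(obs)
        exp = [total / 2.0, total / 2.0]
    else:
        labels = [PositionLabel.N_TERMINAL, PositionLabel.INTERNAL, PositionLabel.C_TERMINAL]
        obs = [counts.get(lab, 0) for lab in labels]
        total = sum(obs)
        if len(k_distribution) != total:
            raise ValueError("one k per counted protein required")
        if any(k < 3 for k in k_distribution):
            raise ValueError("the >2-domain stratum requires k >= 3")
        e_n = sum(1.0 / k for k in k_distribution)
        e_i = sum((k - 2.0) / k for k in k_distribution)
        exp = [e_n, e_i, e_n]
    if total == 0:
        return PositionalTestResult(
            0.0, 1.0, len(labels) - 1,
            {lab.value: 0 for lab in labels},
            {lab.value: 0.0 for lab in labels},
            True,
        )
    stat, p = stats.chisquare(obs, exp)
    return PositionalTestResult(
        statistic=float(stat),
        pvalue=float(p),
        dof=len(labels) - 1,
        observed={lab.value: int(o) for lab, o in zip(labels, obs)},
        expected={lab.value: float(e) for lab, e in zip(labels, exp)},
        small_sample_warning=any(e < 5 for e in exp),
    )
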