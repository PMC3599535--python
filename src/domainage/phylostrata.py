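"""Phylostratigraphic age assignment for protein domains and proteins.

A domain type is dated by the most distant clade in which homologues of the
domain are detectable ("oldest hit" rule), tolerating secondary losses in
younger clades.  A protein inherits the age of the oldest domain it carries;
domainless proteins fall back to a sequence-similarity (homology) presence
profile dated by the same rule.

The default clade ranking reflects a human-centred study design: 15 non-human
eukaryotic species grouped into four ranked clades (mammals < other
vertebrates < other metazoans < other eukaryotes).  The reference species
(human) belongs to no clade; a domain observed only in the reference lineage
is by convention assigned the youngest age.  For reporting, the two oldest
classes (Metazoan, Eukarya; both older than roughly 550 My) are merged into a
single "Old" class; the merge is a projection applied at report time only, so
the full ordinal is preserved internally.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from ._util import round_half_up

__all__ = [
    "AgeClass",
    "Clade",
    "CladeRanking",
    "PhyleticProfile",
    "HomologyProfile",
    "AgeSummary",
    "DEFAULT_RANKING",
    "assign_domain_age",
    "assign_protein_age",
    "summarize_ages",
    "UnageableProteinError",
    "SpeciesMismatchError",
]


class SpeciesMismatchError(ValueError):
    """Profile and ranking disagree on the species universe."""


class UnageableProteinError(ValueError):
    """A protein with no domains and no homology fallback cannot be dated."""


@functools.total_ordering
@dataclass(frozen=True)
class AgeClass:
    """An ordinal phylogenetic age.

    ``rank`` counts clades from the reference species outward: 0 is the
    youngest clade of the ranking (Mammalian under the default), larger ranks
    are older.  Ordering compares ranks only, so ages from the same ranking
    are totally ordered.
    """

    rank: int
    label: str

    def __lt__(self, other: "AgeClass") -> bool:
        if not isinstance(other, AgeClass):
            return NotImplemented
        return self.rank < other.rank

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AgeClass):
            return NotImplemented
        return self.rank == other.rank

    def __hash__(self) -> int:
        return hash(self.rank)


@dataclass(frozen=True)
class Clade:
    name: str
    species: tuple[str, ...]


@dataclass(frozen=True)
class CladeRanking:
    """Ordered clades, youngest first (index = age rank; oldest last).

    ``merged_ranks`` lists the ranks that the reporting projection collapses
    into a single class (named ``merged_label``); by default the two oldest
    clades of the four-clade ranking.
    """

    clades: tuple[Clade, ...]
    merged_ranks: frozenset[int] = frozenset()
    merged_label: str = "Old"

    def __post_init__(self) -> None:
        if len(self.clades) < 2:
            raise ValueError("a clade ranking needs at least 2 clades")
        seen: set[str] = set()
        for clade in self.clades:
            if not clade.species:
                raise ValueError(f"clade {clade.name!r} is empty")
            for sp in clade.species:
                if sp in seen:
                    raise ValueError(f"species {sp!r} occurs in more than one clade")
                seen.add(sp)

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(sp for clade in self.clades for sp in clade.species)

    @property
    def ages(self) -> tuple[AgeClass, ...]:
        return tuple(AgeClass(i, c.name) for i, c in enumerate(self.clades))

    def age(self, rank: int) -> AgeClass:
        return AgeClass(rank, self.clades[rank].name)

    @property
    def youngest(self) -> AgeClass:
        return self.age(0)

    @property
    def oldest(self) -> AgeClass:
        return self.age(len(self.clades) - 1)

    def age_by_label(self, label: str) -> AgeClass:
        for i, clade in enumerate(self.clades):
            if clade.name == label:
                return AgeClass(i, label)
        raise KeyError(label)

    def merged(self, age: AgeClass) -> str:
        """Reporting projection: collapse the configured old ranks."""
        return self.merged_label if age.rank in self.merged_ranks else age.label

    def is_young(self, age: AgeClass) -> bool:
        """Young = any rank outside the merged ('Old') projection."""
        return age.rank not in self.merged_ranks

    def clade_of(self, species: str) -> int:
        for i, clade in enumerate(self.clades):
            if species in clade.species:
                return i
        raise KeyError(species)

    def to_yaml(self) -> str:
        # listed oldest-to-youngest in the config file
        doc = {
            "clades": [
                {"name": c.name, "species": list(c.species)}
                for c in reversed(self.clades)
            ],
            "merged": {
                "label": self.merged_label,
                "clades": [self.clades[r].name for r in sorted(self.merged_ranks)],
            },
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "CladeRanking":
        doc = yaml.safe_load(text)
        clades = tuple(
            Clade(c["name"], tuple(c["species"])) for c in reversed(doc["clades"])
        )
        merged = doc.get("merged", {})
        names = set(merged.get("clades", []))
        ranks = frozenset(i for i, c in enumerate(clades) if c.name in names)
        return cls(clades, ranks, merged.get("label", "Old"))


#: The study's ranking: mammals < vertebrates < metazoans < eukaryotes,
#: with human as the implicit reference species.
DEFAULT_RANKING = CladeRanking(
    clades=(
        Clade("Mammalian", ("mouse", "rat", "cow")),
        Clade("Vertebrate", ("zebrafish", "chicken", "fugu", "xenopus")),
        Clade("Metazoan", ("anopheles", "celegans", "ciona", "drosophila")),
        Clade("Eukarya", ("arabidopsis", "rice", "scerevisiae", "spombe")),
    ),
    merged_ranks=frozenset({2, 3}),
    merged_label="Old",
)


@dataclass(frozen=True)
class PhyleticProfile:
    """Presence/absence of one domain type across the ranking's species.

    Presence in the reference species is implicit (the profile exists because
    the domain was found there).
    """

    domain_type_id: str
    presence: Mapping[str, bool] = field(default_factory=dict)

    def present_species(self) -> frozenset[str]:
        return frozenset(sp for sp, flag in self.presence.items() if flag)


@dataclass(frozen=True)
class HomologyProfile:
    """Sequence-similarity presence of a whole protein across species."""

    protein_id: str
    presence: Mapping[str, bool] = field(default_factory=dict)


def _check_species(presence: Mapping[str, bool], ranking: CladeRanking) -> None:
    if set(presence) != set(ranking.species):
        missing = set(ranking.species) - set(presence)
        extra = set(presence) - set(ranking.species)
        raise SpeciesMismatchError(
            f"profile species do not match ranking (missing={sorted(missing)}, "
            f"unexpected={sorted(extra)})"
        )


def assign_domain_age(
    profile: PhyleticProfile, ranking: CladeRanking = DEFAULT_RANKING
) -> AgeClass:
    """Date a domain type by the oldest clade containing at least one hit.

    Scans clades oldest-first and returns the age of the first occupied one;
    gaps in younger clades are treated as secondary losses and never lower
    the age.  A profile with no presences at all (the domain is known only
    from the reference lineage) maps to the youngest age.
    """
    _check_species(profile.presence, ranking)
    present = profile.present_species()
    for rank in range(len(ranking.clades) - 1, -1, -1):
        if any(sp in present for sp in ranking.clades[rank].species):
            return ranking.age(rank)
    return ranking.youngest


def assign_protein_age(
    domain_ages: Sequence[AgeClass],
    fallback: HomologyProfile | None = None,
    ranking: CladeRanking = DEFAULT_RANKING,
) -> AgeClass:
    """Protein age = oldest domain age; domainless proteins use homology hits.

    The homology fallback applies the same oldest-occupied-clade rule to the
    protein's sequence-similarity presence profile.
    """
    if domain_ages:
        return max(domain_ages)
    if fallback is None:
        raise UnageableProteinError(
            "protein has no domains and no homology profile was provided"
        )
    return assign_domain_age(
        PhyleticProfile(fallback.protein_id, fallback.presence), ranking
    )


# ---------------------------------------------------------------------------
# summaries


@dataclass
class AgeSummary:
    """Per-age-class summary of domains and proteins (reporting projection applied)."""

    domain_summary: pd.DataFrame
    protein_summary: pd.DataFrame
    percentages: pd.DataFrame


def _merged_order(ranking: CladeRanking) -> list[str]:
    order: list[str] = []
    for age in reversed(ranking.ages):  # oldest first, as in the report tables
        label = ranking.merged(age)
        if label not in order:
            order.append(label)
    return order


def summarize_ages(
    domain_table: pd.DataFrame,
    protein_table: pd.DataFrame,
    ranking: CladeRanking = DEFAULT_RANKING,
) -> AgeSummary:
    """Summarise domain occurrences and proteins per (merged) age class.

    ``domain_table`` has one row per domain occurrence with columns
    ``domain_type``, ``age_label``, ``length``; ``protein_table`` one row per
    protein with ``protein_id``, ``age_label``, ``length``, ``n_domains``.
    Age labels are the unmerged clade names; the Old merge is applied here.
    """
    order = _merged_order(ranking)
    label_map = {age.label: ranking.merged(age) for age in ranking.ages}

    if len(domain_table):
        dt = domain_table.assign(
            age_merged=domain_table["age_label"].map(label_map)
        )
        dom = (
            dt.groupby("age_merged")
            .agg(
                n_occurrences=("domain_type", "size"),
                n_types=("domain_type", "nunique"),
                mean_length=("length", "mean"),
                median_length=("length", "median"),
            )
            .reindex(order)
            .fillna({"n_occurrences": 0, "n_types": 0})
            .astype({"n_occurrences": int, "n_types": int})
            .reset_index()
        )
    else:
        dom = pd.DataFrame(
            {
                "age_merged": order,
                "n_occurrences": 0,
                "n_types": 0,
                "mean_length": float("nan"),
                "median_length": float("nan"),
            }
        )

    if len(protein_table):
        pt = protein_table.assign(
            age_merged=protein_table["age_label"].map(label_map),
            has_domains=protein_table["n_domains"] > 0,
        )
        prot = (
            pt.groupby(["has_domains", "age_merged"])
            .agg(
                n_proteins=("protein_id", "size"),
                domains_per_protein=("n_domains", "mean"),
                mean_length=("length", "mean"),
                median_length=("length", "median"),
            )
            .reset_index()
        )
        prot["age_merged"] = pd.Categorical(prot["age_merged"], order, ordered=True)
        prot = prot.sort_values(
            ["has_domains", "age_merged"], ascending=[False, True]
        ).reset_index(drop=True)
    else:
        prot = pd.DataFrame(
            columns=[
                "has_domains",
                "age_merged",
                "n_proteins",
                "domains_per_protein",
                "mean_length",
                "median_length",
            ]
        )

    total_types = int(dom["n_types"].sum())
    young_labels = [
        age.label for age in ranking.ages if ranking.is_young(age)
    ]
    young_types = int(dom.loc[dom["age_merged"].isin(young_labels), "n_types"].sum())
    rows = [
        {
            "quantity": "young_domain_types",
            "numerator": young_types,
            "denominator": total_types,
            "percent": round_half_up(100 * young_types / total_types, 1)
            if total_types
            else float("nan"),
        }
    ]

    # fraction of each young class's types occurring only in proteins of the
    # same (young) age: "arose in newly formed genes"
    if len(domain_table) and len(protein_table):
        page = protein_table.set_index("protein_id")["age_label"].map(label_map)
        dt2 = domain_table.assign(
            age_merged=domain_table["age_label"].map(label_map),
            protein_age=domain_table["protein_id"].map(page),
        )
        for label in young_labels:
            types = dt2.loc[dt2["age_merged"] == label, "domain_type"].unique()
            n_total = len(types)
            only_young = 0
            for t in types:
                pages = dt2.loc[dt2["domain_type"] == t, "protein_age"]
                if (pages == label).all():
                    only_young += 1
            rows.append(
                {
                    "quantity": f"{label}_types_in_new_genes",
                    "numerator": only_young,
                    "denominator": n_total,
                    "percent": round_half_up(100 * only_young / n_total, 1)
                    if n_total
                    else float("nan"),
                }
            )

    return AgeSummary(dom, prot, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# TSV I/O


def read_profiles(path, ranking: CladeRanking) -> list[PhyleticProfile]:
    """Read phyletic profiles: one row per domain type, 0/1 column per species."""
    df = pd.read_csv(path, sep="\t")
    species = [c for c in df.columns if c != "domain_type"]
    _check_species({sp: True for sp in species}, ranking)
    return [
        PhyleticProfile(
            str(row["domain_type"]), {sp: bool(row[sp]) for sp in species}
        )
        for _, row in df.iterrows()
    ]


def read_homology_profiles(path, ranking: CladeRanking) -> list[HomologyProfile]:
    df = pd.read_csv(path, sep="\t")
    species = [c for c in df.columns if c != "protein_id"]
    _check_species({sp: True for sp in species}, ranking)
    return [
        HomologyProfile(str(row["protein_id"]), {sp: bool(row[sp]) for sp in species})
        for _, row in df.iterrows()
    ]


def write_ages(path, ids: Iterable[str], ages: Iterable[AgeClass], ranking: CladeRanking) -> None:
    ages = list(ages)
    df = pd.DataFrame(
        {
            "id": list(ids),
            "age_class": [a.label for a in ages],
            "age_class_merged": [ranking.merged(a) for a in ages],
        }
    )
    df.to_csv(path, sep="\t", index=False)
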