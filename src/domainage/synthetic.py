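"""Seeded synthetic datasets with a ground-truth ledger.

The generator emulates the statistical structure of a domain-centric
comparative study between a reference species and a panel of ranked clades:

* phyletic profiles per domain type: presence in every clade at or younger
  than the origin clade, thinned by independent secondary losses (optionally
  guaranteeing one surviving species in the origin clade, which makes the
  oldest-hit dating rule exact);
* a proteome mixing young-only, old-only and combined (young + old)
  proteins, where combined proteins are constructed per scenario regime
  (gain-dependent, mutual dependence, fusion, complex) and the young domain
  is inserted N-terminally with a tunable bias;
* pairwise codon alignments per protein, evolved segment-by-segment under a
  per-region omega and a common target synonymous divergence, using a
  per-site independent substitution process with stop-codon rejection (the
  counting assumptions of NG86, so recovery tests stay interpretable).

Every emitted entity is recorded once in a :class:`TruthLedger`; with the
same parameters and seed the emitted file bundle is byte-identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .architecture import DomainHit
from .evolrates import CodonAlignmentPair
from .ng86 import BASES, SENSE_CODONS, STOP_CODONS, translate_codon, ng86_sites
from .phylostrata import (
    DEFAULT_RANKING,
    CladeRanking,
    HomologyProfile,
    PhyleticProfile,
)

__all__ = [
    "SimulationParams",
    "TruthLedger",
    "SyntheticBundle",
    "simulate_profiles",
    "simulate_proteome",
    "simulate_codon_pair",
    "simulate_alignments",
    "generate_bundle",
    "emit_dataset",
    "load_bundle",
]

SCENARIOS = ("gain_dependent", "mutual_dependence", "fusion", "complex")


@dataclass(frozen=True)
class SimulationParams:
    """Full parameterization of the synthetic dataset.

    Defaults describe a scaled-down human-vs-15-species style study: a few
    hundred proteins, human-mouse-like synonymous divergence (target dS 0.5)
    and per-age omega medians taken from the age-dependent purifying
    selection gradient (old domains strongly constrained, mammalian-specific
    ones weakly).
    """

    ranking: CladeRanking = DEFAULT_RANKING
    # phyletic profiles
    loss_probability: float = 0.2
    origin_clade_guarantee: bool = True
    domain_type_counts: Mapping[str, int] | None = None  # derived when None
    # proteome composition
    n_young_only: int = 120
    n_old_only: int = 120
    n_combined: int = 60
    scenario_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "gain_dependent": 243 / 330,
            "mutual_dependence": 16 / 330,
            "fusion": 40 / 330,
            "complex": 31 / 330,
        }
    )
    young_age_mix: Mapping[str, float] = field(
        default_factory=lambda: {"Vertebrate": 0.85, "Mammalian": 0.15}
    )
    old_age_mix: Mapping[str, float] = field(
        default_factory=lambda: {"Metazoan": 0.4, "Eukarya": 0.6}
    )
    n_old_pool: int = 25
    duplication_rate: float = 0.05
    n_terminal_bias: float | None = 0.75  # None = uniform over insertion slots
    combined_base_old_counts: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.7, 2: 0.3}
    )
    domainless_counts: Mapping[str, int] = field(
        default_factory=lambda: {"Eukarya": 20, "Vertebrate": 12, "Mammalian": 6}
    )
    # sequence evolution
    omega_medians: Mapping[str, float] = field(
        default_factory=lambda: {
            "Mammalian": 0.33,
            "Vertebrate": 0.18,
            "Metazoan": 0.09,
            "Eukarya": 0.08,
        }
    )
    omega_sigma: float = 0.5
    linker_omega: float = 0.25
    target_ds: float = 0.5
    # geometry
    region_length_median: int = 110
    region_length_sigma: float = 0.35
    region_length_min: int = 60
    region_length_max: int = 400
    linker_range: tuple[int, int] = (5, 50)
    fraction_filter_fail: float = 0.1

    def __post_init__(self) -> None:
        for name in ("loss_probability", "duplication_rate", "fraction_filter_fail"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_terminal_bias is not None and not 0.0 <= self.n_terminal_bias <= 1.0:
            raise ValueError("n_terminal_bias must be in [0, 1] or None")
        for name in ("n_young_only", "n_old_only", "n_combined", "n_old_pool"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if abs(sum(self.scenario_mix.values()) - 1.0) > 1e-9:
            raise ValueError("scenario_mix must sum to 1")
        if self.target_ds < 0:
            raise ValueError("target_ds must be >= 0")

    # -- derived allocations -------------------------------------------------

    def scenario_counts(self) -> dict[str, int]:
        """Integer combined-protein counts per regime (largest remainder)."""
        raw = {s: self.scenario_mix.get(s, 0.0) * self.n_combined for s in SCENARIOS}
        counts = {s: int(math.floor(v)) for s, v in raw.items()}
        short = self.n_combined - sum(counts.values())
        for s in sorted(SCENARIOS, key=lambda s: raw[s] - counts[s], reverse=True):
            if short <= 0:
                break
            counts[s] += 1
            short -= 1
        n_fusion = counts["fusion"]
        if n_fusion > self.n_young_only:
            raise ValueError(
                "fusion regime needs a young-only partner protein per fusion "
                f"pair: {n_fusion} > n_young_only={self.n_young_only}"
            )
        if self.n_combined and not (
            counts["gain_dependent"] + counts["fusion"] + counts["complex"] == 0
            or self.n_old_only > 0
        ):
            raise ValueError(
                "gain/fusion/complex regimes need old-only proteins for the "
                "old domain to occur in another configuration"
            )
        if self.n_combined > 0 and sum(self.young_age_mix.values()) == 0:
            raise ValueError("combined proteins requested but no young types")
        return counts

    def _split(self, total: int, mix: Mapping[str, float]) -> dict[str, int]:
        labels = list(mix)
        raw = {lab: mix[lab] * total for lab in labels}
        counts = {lab: int(math.floor(raw[lab])) for lab in labels}
        short = total - sum(counts.values())
        for lab in sorted(labels, key=lambda l: raw[l] - counts[l], reverse=True):
            if short <= 0:
                break
            counts[lab] += 1
            short -= 1
        return counts

    def resolved_type_counts(self) -> dict[str, int]:
        """Domain types per clade label (explicit or derived from composition)."""
        if self.domain_type_counts is not None:
            return dict(self.domain_type_counts)
        sc = self.scenario_counts()
        n_young = self.n_combined + self.n_young_only - sc["fusion"]
        n_old = self.n_old_pool + sc["mutual_dependence"] + sc["complex"]
        counts: dict[str, int] = {c.name: 0 for c in self.ranking.clades}
        counts.update(self._split(n_young, self.young_age_mix))
        for lab, n in self._split(n_old, self.old_age_mix).items():
            counts[lab] = counts.get(lab, 0) + n
        return counts


# ---------------------------------------------------------------------------
# ledger


@dataclass
class TruthLedger:
    """Ground truth for every emitted entity (exactly once each)."""

    domain_types: dict[str, dict] = field(default_factory=dict)
    proteins: dict[str, dict] = field(default_factory=dict)
    regions: list[dict] = field(default_factory=list)

    def age_label_counts(self, merged_by: CladeRanking | None = None) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.domain_types.values():
            label = rec["age_label"]
            if merged_by is not None:
                label = merged_by.merged(merged_by.age_by_label(label))
            counts[label] = counts.get(label, 0) + 1
        return counts

    def protein_age_counts(self, merged_by: CladeRanking | None = None) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.proteins.values():
            label = rec["age_label"]
            if merged_by is not None:
                label = merged_by.merged(merged_by.age_by_label(label))
            counts[label] = counts.get(label, 0) + 1
        return counts

    def scenario_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.proteins.values():
            s = rec.get("scenario")
            if s:
                counts[s] = counts.get(s, 0) + 1
        return counts

    def position_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.proteins.values():
            p = rec.get("young_position")
            if p:
                counts[p] = counts.get(p, 0) + 1
        return counts

    def to_json(self) -> str:
        return json.dumps(
            {
                "domain_types": self.domain_types,
                "proteins": self.proteins,
                "regions": self.regions,
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthLedger":
        doc = json.loads(text)
        return cls(doc["domain_types"], doc["proteins"], doc["regions"])


# ---------------------------------------------------------------------------
# phyletic profiles


def simulate_profiles(
    params: SimulationParams, rng: np.random.Generator
) -> tuple[list[PhyleticProfile], TruthLedger]:
    """Create domain types with true ages and their phyletic profiles.

    Presence is seeded in every species of every clade at or younger than the
    origin clade, then thinned by independent losses; with the origin-clade
    guarantee one randomly chosen species of the origin clade never loses the
    domain, so the oldest-occupied-clade rule recovers the true age exactly.
    """
    ranking = params.ranking
    ledger = TruthLedger()
    profiles: list[PhyleticProfile] = []
    counts = params.resolved_type_counts()
    prefix = {c.name: c.name[:3].upper() for c in ranking.clades}
    for rank, clade in enumerate(ranking.clades):
        n = counts.get(clade.name, 0)
        for i in range(n):
            tid = f"{prefix[clade.name]}{i:04d}"
            presence = {sp: False for sp in ranking.species}
            seeded = [
                sp
                for r in range(rank + 1)
                for sp in ranking.clades[r].species
            ]
            guard = None
            if params.origin_clade_guarantee:
                members = ranking.clades[rank].species
                guard = members[int(rng.integers(len(members)))]
            for sp in seeded:
                lost = rng.random() < params.loss_probability
                presence[sp] = not lost or sp == guard
            profiles.append(PhyleticProfile(tid, presence))
            ledger.domain_types[tid] = {
                "age_label": clade.name,
                "origin_rank": rank,
            }
    return profiles, ledger


# ---------------------------------------------------------------------------
# proteome


def _region_length(params: SimulationParams, rng: np.random.Generator, fail: bool) -> int:
    if fail:
        return int(rng.integers(20, params.region_length_min))
    mu = math.log(params.region_length_median)
    length = int(round(rng.lognormal(mu, params.region_length_sigma)))
    return int(np.clip(length, params.region_length_min, params.region_length_max))


def _linker(params: SimulationParams, rng: np.random.Generator) -> int:
    lo, hi = params.linker_range
    return int(rng.integers(lo, hi + 1))


def _insert_young(
    base: list[str], young: str, params: SimulationParams, rng: np.random.Generator
) -> tuple[list[str], str]:
    """Insert the young type into a base old architecture; returns the new
    architecture and the position label of the young domain."""
    m = len(base)
    beta = params.n_terminal_bias
    if beta is None:
        slot = int(rng.integers(m + 1))
    elif rng.random() < beta:
        slot = 0
    else:
        slot = int(rng.integers(1, m + 1))
    arch = base[:slot] + [young] + base[slot:]
    if slot == 0:
        label = "N_terminal"
    elif slot == m:
        label = "C_terminal"
    else:
        label = "internal"
    return arch, label


def simulate_proteome(
    params: SimulationParams,
    profiles: Sequence[PhyleticProfile],
    ledger: TruthLedger,
    rng: np.random.Generator,
) -> tuple[list[DomainHit], dict[str, int]]:
    """Build protein architectures, hit coordinates and the region ledger.

    Combined proteins are constructed per scenario regime so the intended
    arrangement class is guaranteed by construction: gain-dependent young
    types occur in a single configuration while their old partner also occurs
    in an old-only protein; mutual pairs use private types on both sides;
    fusion young types additionally get a young-only partner protein; complex
    proteins carry one shared and one private old domain, so their two pairs
    disagree.  Whole proteins are duplicated at the duplication rate, which
    leaves every type's configuration set unchanged.
    """
    ranking = params.ranking
    young_labels = {a.label for a in ranking.ages if ranking.is_young(a)}
    young_types = [t for t, r in ledger.domain_types.items() if r["age_label"] in young_labels]
    old_types = [t for t, r in ledger.domain_types.items() if r["age_label"] not in young_labels]
    young_types = list(rng.permutation(young_types))
    old_types = list(rng.permutation(old_types))

    sc = params.scenario_counts()
    need_young = params.n_combined + params.n_young_only - sc["fusion"]
    need_old = sc["mutual_dependence"] + sc["complex"]
    if len(young_types) < need_young:
        raise ValueError(
            f"{need_young} young domain types required, only {len(young_types)} available"
        )
    if len(old_types) < need_old + (1 if params.n_old_only else 0):
        raise ValueError("not enough old domain types for the requested composition")

    fresh_old = old_types[:need_old]
    pool_old = old_types[need_old:]
    if params.n_old_only and not pool_old:
        raise ValueError("old-only proteins requested but the old pool is empty")
    young_iter = iter(young_types)
    fresh_old_iter = iter(fresh_old)

    # -- old-only proteins (the source of 'other configurations' for old types)
    plans: list[dict] = []  # {types, scenario, young_position, age_label}
    old_used: list[str] = []
    for _ in range(params.n_old_only):
        k = 1 + int(rng.choice([0, 1, 2], p=[0.6, 0.3, 0.1]))
        k = min(k, len(pool_old))
        types = list(rng.choice(pool_old, size=k, replace=False))
        old_used.extend(t for t in types if t not in old_used)
        plans.append({"types": types, "scenario": None, "young_position": None})
    if params.n_combined and not old_used:
        raise ValueError("combined proteins need old types seen in old-only proteins")

    def pick_base(size: int) -> list[str]:
        size = min(size, len(old_used))
        return list(rng.choice(old_used, size=size, replace=False))

    base_sizes = sorted(params.combined_base_old_counts)
    base_probs = np.array(
        [params.combined_base_old_counts[s] for s in base_sizes], dtype=float
    )
    base_probs /= base_probs.sum()

    # -- combined proteins, regime by regime
    fusion_young: list[str] = []
    for scenario in SCENARIOS:
        for _ in range(sc[scenario]):
            if scenario == "gain_dependent":
                v = next(young_iter)
                base = pick_base(int(rng.choice(base_sizes, p=base_probs)))
            elif scenario == "mutual_dependence":
                v = next(young_iter)
                base = [next(fresh_old_iter)]
            elif scenario == "fusion":
                v = next(young_iter)
                fusion_young.append(v)
                base = pick_base(int(rng.choice(base_sizes, p=base_probs)))
            else:  # complex: one shared old + one private old
                v = next(young_iter)
                base = pick_base(1) + [next(fresh_old_iter)]
                base = list(rng.permutation(base))
            arch, pos = _insert_young(base, v, params, rng)
            plans.append({"types": arch, "scenario": scenario, "young_position": pos})

    # -- young-only proteins (fusion partners first, then fresh types)
    for i in range(params.n_young_only):
        v = fusion_young[i] if i < len(fusion_young) else next(young_iter)
        plans.append({"types": [v], "scenario": None, "young_position": None})

    # -- whole-protein duplications (configuration sets are unchanged)
    duplicated = [p for p in plans if rng.random() < params.duplication_rate]
    for p in duplicated:
        plans.append({**p, "duplicate": True})

    # -- coordinates, lengths, per-region truth
    hits: list[DomainHit] = []
    protein_lengths: dict[str, int] = {}
    label_of = {t: r["age_label"] for t, r in ledger.domain_types.items()}
    rank_of = {t: r["origin_rank"] for t, r in ledger.domain_types.items()}
    for idx, plan in enumerate(plans):
        pid = f"P{idx:05d}"
        pos = _linker(params, rng) if rng.random() < 0.8 else 0
        n_regions = len(plan["types"])
        for j, t in enumerate(plan["types"]):
            fail = rng.random() < params.fraction_filter_fail
            length = _region_length(params, rng, fail)
            start = pos + 1
            end = pos + length
            evalue = 10.0 ** float(rng.uniform(-30, -6))
            hits.append(DomainHit(pid, t, start, end, evalue))
            med = params.omega_medians[label_of[t]]
            omega = float(rng.lognormal(math.log(med), params.omega_sigma))
            ledger.regions.append(
                {
                    "protein_id": pid,
                    "domain_type": t,
                    "start": start,
                    "end": end,
                    "length_aa": length,
                    "true_omega": omega,
                    "true_ds": params.target_ds,
                    "intended_filter_fail": bool(fail),
                }
            )
            pos = end
            if j < n_regions - 1:
                pos += _linker(params, rng)
        if rng.random() < 0.8:
            pos += _linker(params, rng)
        protein_lengths[pid] = pos
        oldest = max(rank_of[t] for t in plan["types"])
        ledger.proteins[pid] = {
            "age_label": ranking.clades[oldest].name,
            "architecture": list(plan["types"]),
            "scenario": plan["scenario"],
            "young_position": plan["young_position"],
            "length_aa": pos,
            "n_domains": n_regions,
            "is_duplicate": bool(plan.get("duplicate", False)),
        }
    return hits, protein_lengths


def simulate_domainless(
    params: SimulationParams, ledger: TruthLedger, rng: np.random.Generator
) -> tuple[list[HomologyProfile], dict[str, int]]:
    """Domainless proteins dated through homology (sequence-similarity) profiles."""
    ranking = params.ranking
    profiles: list[HomologyProfile] = []
    lengths: dict[str, int] = {}
    idx = 0
    for label, n in params.domainless_counts.items():
        rank = ranking.age_by_label(label).rank
        for _ in range(n):
            pid = f"Q{idx:05d}"
            idx += 1
            presence = {sp: False for sp in ranking.species}
            members = ranking.clades[rank].species
            guard = members[int(rng.integers(len(members)))]
            for r in range(rank + 1):
                for sp in ranking.clades[r].species:
                    lost = rng.random() < params.loss_probability
                    presence[sp] = not lost or sp == guard
            profiles.append(HomologyProfile(pid, presence))
            length = int(round(rng.lognormal(math.log(300), 0.4)))
            lengths[pid] = max(length, 30)
            ledger.proteins[pid] = {
                "age_label": label,
                "architecture": [],
                "scenario": None,
                "young_position": None,
                "length_aa": lengths[pid],
                "n_domains": 0,
                "is_duplicate": False,
            }
    return profiles, lengths


# ---------------------------------------------------------------------------
# codon evolution


def simulate_codon_pair(
    length_codons: int,
    omega: float,
    target_ds: float,
    rng: np.random.Generator,
) -> tuple[str, str]:
    """Evolve an ungapped aligned codon pair at a given omega and target dS.

    A random sense-codon ancestor receives Poisson numbers of synonymous and
    nonsynonymous single-nucleotide substitutions whose expectations are
    ``target_ds * S_sites`` and ``omega * target_ds * N_sites`` (NG86 site
    counting on the ancestor); stop-creating changes are rejected.  The
    Jukes-Cantor correction in the estimator undoes multiple hits on average.
    """
    if length_codons < 1:
        raise ValueError("length_codons must be >= 1")
    if omega < 0 or target_ds < 0:
        raise ValueError("omega and target_ds must be >= 0")
    for d in (target_ds, omega * target_ds):
        if 0.75 * (1.0 - math.exp(-4.0 * d / 3.0)) >= 0.75:
            raise ValueError(f"divergence target {d} saturates NG86 counting")

    codon_idx = rng.integers(0, len(SENSE_CODONS), size=length_codons)
    ancestor = [SENSE_CODONS[i] for i in codon_idx]
    n_sites = sum(ng86_sites(c)[0] for c in ancestor)
    s_sites = 3.0 * length_codons - n_sites
    n_syn = int(rng.poisson(target_ds * s_sites))
    n_non = int(rng.poisson(omega * target_ds * n_sites))
    events = np.array(["s"] * n_syn + ["n"] * n_non)
    rng.shuffle(events)

    derived = list(ancestor)
    for ev in events:
        want_syn = ev == "s"
        while True:
            i = int(rng.integers(length_codons))
            pos = int(rng.integers(3))
            b = BASES[int(rng.integers(4))]
            codon = derived[i]
            if b == codon[pos]:
                continue
            candidate = codon[:pos] + b + codon[pos + 1 :]
            if candidate in STOP_CODONS:
                continue
            if (translate_codon(candidate) == translate_codon(codon)) == want_syn:
                derived[i] = candidate
                break
    return "".join(ancestor), "".join(derived)


def simulate_alignments(
    params: SimulationParams,
    protein_lengths: Mapping[str, int],
    ledger: TruthLedger,
    rng: np.random.Generator,
    ref_suffix: str = "ref",
    oth_suffix: str = "orth",
) -> dict[str, CodonAlignmentPair]:
    """One codon alignment pair per domain-bearing protein.

    Each protein's CDS is the concatenation of its linker and domain
    segments; domain segments evolve at their ledgered true omega, linkers at
    the background linker omega, all at the common target dS.
    """
    regions_by_protein: dict[str, list[dict]] = {}
    for reg in ledger.regions:
        regions_by_protein.setdefault(reg["protein_id"], []).append(reg)
    alignments: dict[str, CodonAlignmentPair] = {}
    for pid in sorted(regions_by_protein):
        regions = sorted(regions_by_protein[pid], key=lambda r: r["start"])
        length = protein_lengths[pid]
        ref_parts: list[str] = []
        oth_parts: list[str] = []
        cursor = 1
        for reg in regions:
            if reg["start"] > cursor:  # leading/inter-domain linker
                r, o = simulate_codon_pair(
                    reg["start"] - cursor, params.linker_omega, params.target_ds, rng
                )
                ref_parts.append(r)
                oth_parts.append(o)
            r, o = simulate_codon_pair(
                reg["length_aa"], reg["true_omega"], reg["true_ds"], rng
            )
            ref_parts.append(r)
            oth_parts.append(o)
            cursor = reg["end"] + 1
        if cursor <= length:  # trailing linker
            r, o = simulate_codon_pair(
                length - cursor + 1, params.linker_omega, params.target_ds, rng
            )
            ref_parts.append(r)
            oth_parts.append(o)
        alignments[pid] = CodonAlignmentPair(
            f"{pid}|{ref_suffix}",
            f"{pid}|{oth_suffix}",
            "".join(ref_parts),
            "".join(oth_parts),
        )
    return alignments


# ---------------------------------------------------------------------------
# bundle assembly and I/O


@dataclass
class SyntheticBundle:
    """In-memory dataset in exactly the shapes the analysis stages consume."""

    ranking: CladeRanking
    profiles: list[PhyleticProfile]
    homology_profiles: list[HomologyProfile]
    hits: list[DomainHit]
    protein_lengths: dict[str, int]
    alignments: dict[str, CodonAlignmentPair]
    ledger: TruthLedger | None = None


def generate_bundle(params: SimulationParams, seed: int) -> SyntheticBundle:
    """Generate the full dataset in memory (deterministic in params + seed)."""
    rng = np.random.default_rng(seed)
    profiles, ledger = simulate_profiles(params, rng)
    hits, lengths = simulate_proteome(params, profiles, ledger, rng)
    hom_profiles, hom_lengths = simulate_domainless(params, ledger, rng)
    lengths = {**lengths, **hom_lengths}
    alignments = simulate_alignments(params, lengths, ledger, rng)
    return SyntheticBundle(
        params.ranking, profiles, hom_profiles, hits, lengths, alignments, ledger
    )


def emit_dataset(params: SimulationParams, outdir: str | Path, seed: int) -> SyntheticBundle:
    """Generate and write the dataset bundle; byte-identical per (params, seed).

    Layout: ``ranking.yaml``, ``profiles.tsv``, ``homology_profiles.tsv``,
    ``hits.tsv``, ``proteins.tsv``, ``alignments/<protein>.fasta`` (two
    records each, reference first), ``ledger.json``.
    """
    bundle = generate_bundle(params, seed)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ranking = bundle.ranking

    (out / "ranking.yaml").write_text(ranking.to_yaml())

    species = list(ranking.species)
    with open(out / "profiles.tsv", "w") as fh:
        fh.write("domain_type\t" + "\t".join(species) + "\n")
        for p in bundle.profiles:
            flags = "\t".join(str(int(p.presence[sp])) for sp in species)
            fh.write(f"{p.domain_type_id}\t{flags}\n")
    with open(out / "homology_profiles.tsv", "w") as fh:
        fh.write("protein_id\t" + "\t".join(species) + "\n")
        for p in bundle.homology_profiles:
            flags = "\t".join(str(int(p.presence[sp])) for sp in species)
            fh.write(f"{p.protein_id}\t{flags}\n")
    with open(out / "hits.tsv", "w") as fh:
        fh.write("protein_id\tdomain_id\tstart\tend\tevalue\n")
        for h in bundle.hits:
            fh.write(
                f"{h.protein_id}\t{h.domain_type_id}\t{h.start}\t{h.end}\t"
                f"{h.e_value:.6e}\n"
            )
    with open(out / "proteins.tsv", "w") as fh:
        fh.write("protein_id\tlength_aa\n")
        for pid in sorted(bundle.protein_lengths):
            fh.write(f"{pid}\t{bundle.protein_lengths[pid]}\n")

    aln_dir = out / "alignments"
    aln_dir.mkdir(exist_ok=True)
    for pid in sorted(bundle.alignments):
        pair = bundle.alignments[pid]
        with open(aln_dir / f"{pid}.fasta", "w") as fh:
            fh.write(f">{pair.ref_id}\n{pair.ref_seq}\n>{pair.oth_id}\n{pair.oth_seq}\n")

    assert bundle.ledger is not None
    (out / "ledger.json").write_text(bundle.ledger.to_json())
    return bundle


def load_bundle(path: str | Path) -> SyntheticBundle:
    """Read a bundle written by :func:`emit_dataset` back into memory."""
    import pandas as pd

    root = Path(path)
    ranking = CladeRanking.from_yaml((root / "ranking.yaml").read_text())
    species = list(ranking.species)

    def read_profiles(fname, id_col, cls):
        df = pd.read_csv(root / fname, sep="\t")
        return [
            cls(str(row[id_col]), {sp: bool(row[sp]) for sp in species})
            for _, row in df.iterrows()
        ]

    profiles = read_profiles("profiles.tsv", "domain_type", PhyleticProfile)
    hom = read_profiles("homology_profiles.tsv", "protein_id", HomologyProfile)
    hits_df = pd.read_csv(root / "hits.tsv", sep="\t")
    hits = [
        DomainHit(
            str(r.protein_id), str(r.domain_id), int(r.start), int(r.end), float(r.evalue)
        )
        for r in hits_df.itertuples()
    ]
    lengths_df = pd.read_csv(root / "proteins.tsv", sep="\t")
    lengths = dict(zip(lengths_df["protein_id"].astype(str), lengths_df["length_aa"]))

    from Bio import SeqIO

    alignments: dict[str, CodonAlignmentPair] = {}
    for fasta in sorted((root / "alignments").glob("*.fasta")):
        records = list(SeqIO.parse(str(fasta), "fasta"))
        if len(records) != 2:
            raise ValueError(f"{fasta} must hold exactly two records")
        ref, oth = records
        alignments[fasta.stem] = CodonAlignmentPair(
            ref.id, oth.id, str(ref.seq), str(oth.seq)
        )
    ledger = None
    ledger_path = root / "ledger.json"
    if ledger_path.exists():
        ledger = TruthLedger.from_json(ledger_path.read_text())
    return SyntheticBundle(ranking, profiles, hom, hits, lengths, alignments, ledger)
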