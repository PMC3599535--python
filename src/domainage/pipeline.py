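"""End-to-end orchestration: ages -> architectures -> rates -> report.

`run_analysis` consumes a dataset bundle (either generated in memory by
:mod:`domainage.synthetic` or loaded from the on-disk TSV/FASTA layout) and
produces a :class:`ReportBundle` holding every table of the study report:
age summaries of domains and proteins, scenario class counts with derived
percentages, young-domain position counts with the chi-square bias test, the
per-region rate table and the young-vs-old comparisons.  All p-values are
reported raw (no multiple-testing correction is applied across the handful
of global tests; they are labelled as such in the JSON report).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import architecture as arch_mod
from . import evolrates as rates_mod
from ._util import round_half_up
from .architecture import (
    Architecture,
    PositionLabel,
    PositionalTestResult,
    ScenarioClass,
    resolve_overlaps,
)
from .evolrates import FilterThresholds, RateEstimate, extract_domain_region
from .phylostrata import (
    AgeClass,
    AgeSummary,
    CladeRanking,
    assign_domain_age,
    assign_protein_age,
    summarize_ages,
)
from .synthetic import SyntheticBundle

logger = logging.getLogger("domainage")

__all__ = ["AnalysisConfig", "ReportBundle", "run_analysis", "derived_percentages"]


@dataclass(frozen=True)
class AnalysisConfig:
    """All thresholds of the analysis.

    ``hit_evalue`` filters domain hits (the homology E-value that produced
    the fallback profiles is dataset metadata, recorded here for the report
    only).  ``filters_enabled=False`` marks every rate estimate as passing.
    """

    hit_evalue: float = 1e-5
    homology_evalue: float = 1e-4
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    filters_enabled: bool = True
    alpha: float = 0.01
    site_adjusted_null: bool = True


@dataclass
class ReportBundle:
    """Every table of the study report, plus a flat JSON-able summary."""

    age_summary: AgeSummary
    domain_ages: pd.DataFrame
    protein_ages: pd.DataFrame
    scenario_counts: dict[str, int]
    scenario_table: pd.DataFrame
    derived: pd.DataFrame
    position_counts_2dom: dict[str, int]
    position_counts_multi: dict[str, int]
    position_test_2dom: PositionalTestResult | None
    position_test_multi: PositionalTestResult | None
    rates: pd.DataFrame
    group_comparison: rates_mod.GroupComparison | None
    paired: pd.DataFrame
    paired_tallies: dict[str, int]
    new_gene_fraction_types: float
    new_gene_fraction_occurrences: float

    def summary_dict(self) -> dict:
        return {
            "scenario_counts": self.scenario_counts,
            "paired_tallies": self.paired_tallies,
            "position_counts_2dom": self.position_counts_2dom,
            "position_counts_multi": self.position_counts_multi,
            "position_test_2dom": _test_dict(self.position_test_2dom),
            "position_test_multi": _test_dict(self.position_test_multi),
            "new_gene_fraction": {
                "types_basis": self.new_gene_fraction_types,
                "occurrences_basis": self.new_gene_fraction_occurrences,
            },
            "derived": self.derived.to_dict(orient="records"),
            "group_medians": (
                self.group_comparison.group_stats.to_dict(orient="records")
                if self.group_comparison is not None
                else []
            ),
            "ks_tests": (
                self.group_comparison.ks_tests.to_dict(orient="records")
                if self.group_comparison is not None
                else []
            ),
            "wilcoxon": (
                {
                    "statistic": self.group_comparison.wilcoxon_stat,
                    "pvalue": self.group_comparison.wilcoxon_p,
                }
                if self.group_comparison is not None
                else None
            ),
            "pvalue_note": "raw p-values, no multiple-testing correction",
        }

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.domain_ages.to_csv(out / "domain_ages.tsv", sep="\t", index=False)
        self.protein_ages.to_csv(out / "protein_ages.tsv", sep="\t", index=False)
        self.age_summary.domain_summary.to_csv(
            out / "domain_age_summary.tsv", sep="\t", index=False
        )
        self.age_summary.protein_summary.to_csv(
            out / "protein_age_summary.tsv", sep="\t", index=False
        )
        self.scenario_table.to_csv(out / "scenarios.tsv", sep="\t", index=False)
        self.derived.to_csv(out / "derived_percentages.tsv", sep="\t", index=False)
        self.rates.to_csv(out / "rates.tsv", sep="\t", index=False)
        self.paired.to_csv(out / "paired_comparisons.tsv", sep="\t", index=False)
        (out / "report.json").write_text(
            json.dumps(self.summary_dict(), indent=1, sort_keys=True, default=float)
        )


def _test_dict(t: PositionalTestResult | None) -> dict | None:
    if t is None:
        return None
    return {
        "statistic": t.statistic,
        "pvalue": t.pvalue,
        "dof": t.dof,
        "observed": t.observed,
        "expected": t.expected,
        "small_sample_warning": t.small_sample_warning,
    }


# ---------------------------------------------------------------------------


def derived_percentages(
    type_counts: Mapping[str, int] | None = None,
    new_gene_types: Mapping[str, tuple[int, int]] | None = None,
    scenario_counts: Sequence[int] | None = None,
    n_young_only: int | None = None,
    n_combined: int | None = None,
    old_label: str = "Old",
) -> pd.DataFrame:
    """Headline ratios from labelled integer counts.

    * ``type_counts``: domain types per merged age class (the old class named
      by ``old_label``); yields the young-type count and percentage.
    * ``new_gene_types``: per young class, (types occurring only in proteins
      of that age, total types of that age).
    * ``scenario_counts``: (class1, class2, class3, class4) protein counts;
      yields gain-compatible and fusion percentages of all combined proteins.
    * ``n_young_only`` / ``n_combined``: young-only-to-combined protein ratio.

    Percentages are rounded half-up to 1 decimal, ratios to 2 decimals; zero
    denominators yield NaN entries flagged ``undefined``.
    """
    rows: list[dict] = []

    def add(quantity, num, den, kind):
        if den:
            value = (
                round_half_up(100.0 * num / den, 1)
                if kind == "percent"
                else round_half_up(num / den, 2)
            )
            undef = False
        else:
            value, undef = float("nan"), True
        rows.append(
            {
                "quantity": quantity,
                "numerator": num,
                "denominator": den,
                "value": value,
                "kind": kind,
                "undefined": undef,
            }
        )

    if type_counts is not None:
        total = sum(type_counts.values())
        young = sum(v for k, v in type_counts.items() if k != old_label)
        rows.append(
            {
                "quantity": "young_domain_types",
                "numerator": young,
                "denominator": total,
                "value": float(young),
                "kind": "count",
                "undefined": False,
            }
        )
        add("young_type_fraction", young, total, "percent")
    if new_gene_types is not None:
        for label, (num, den) in new_gene_types.items():
            add(f"{label}_types_in_new_genes", num, den, "percent")
    if scenario_counts is not None:
        c1, c2, c3, c4 = scenario_counts
        total = c1 + c2 + c3 + c4
        add("gain_compatible", c1 + c2, total, "percent")
        add("fusion", c3, total, "percent")
    if n_young_only is not None and n_combined is not None:
        add("young_only_to_combined", n_young_only, n_combined, "ratio")
    return pd.DataFrame(
        rows,
        columns=["quantity", "numerator", "denominator", "value", "kind", "undefined"],
    )


# ---------------------------------------------------------------------------


def run_analysis(
    bundle: SyntheticBundle, config: AnalysisConfig = AnalysisConfig()
) -> ReportBundle:
    """Execute the full analysis on a dataset bundle."""
    ranking = bundle.ranking

    # -- stage 1: ages
    type_age: dict[str, AgeClass] = {
        p.domain_type_id: assign_domain_age(p, ranking) for p in bundle.profiles
    }
    logger.info("ages: dated %d domain types", len(type_age))

    hits_in = list(bundle.hits)
    hits_kept = [h for h in hits_in if h.e_value <= config.hit_evalue]
    logger.info("hits: %d in, %d pass E <= %g", len(hits_in), len(hits_kept), config.hit_evalue)

    by_protein: dict[str, list] = {}
    for h in hits_kept:
        by_protein.setdefault(h.protein_id, []).append(h)

    architectures: dict[str, Architecture] = {}
    resolved_hits: dict[str, list] = {}
    for pid in sorted(by_protein):
        kept = resolve_overlaps(by_protein[pid])
        resolved_hits[pid] = kept
        types = tuple(h.domain_type_id for h in kept)
        missing = [t for t in types if t not in type_age]
        if missing:
            raise ValueError(
                f"protein {pid}: no phyletic profile for domain type(s) {missing}"
            )
        architectures[pid] = Architecture(
            pid, types, tuple(type_age[t] for t in types)
        )

    hom_by_id = {p.protein_id: p for p in bundle.homology_profiles}
    protein_age: dict[str, AgeClass] = {}
    for pid in sorted(bundle.protein_lengths):
        if pid in architectures:
            protein_age[pid] = assign_protein_age(
                list(architectures[pid].ages), None, ranking
            )
        elif pid in hom_by_id:
            protein_age[pid] = assign_protein_age([], hom_by_id[pid], ranking)
        else:
            raise ValueError(
                f"protein {pid} has neither domain hits nor a homology profile"
            )

    domain_table = pd.DataFrame(
        [
            {
                "protein_id": pid,
                "domain_type": h.domain_type_id,
                "age_label": type_age[h.domain_type_id].label,
                "length": h.length,
                "start": h.start,
                "end": h.end,
            }
            for pid in sorted(resolved_hits)
            for h in resolved_hits[pid]
        ],
        columns=["protein_id", "domain_type", "age_label", "length", "start", "end"],
    )
    protein_table = pd.DataFrame(
        [
            {
                "protein_id": pid,
                "age_label": protein_age[pid].label,
                "length": bundle.protein_lengths[pid],
                "n_domains": len(architectures[pid].domain_types)
                if pid in architectures
                else 0,
            }
            for pid in sorted(protein_age)
        ],
        columns=["protein_id", "age_label", "length", "n_domains"],
    )
    age_summary = summarize_ages(domain_table, protein_table, ranking)

    domain_ages_df = pd.DataFrame(
        [
            {
                "id": t,
                "age_class": a.label,
                "age_class_merged": ranking.merged(a),
            }
            for t, a in sorted(type_age.items())
        ],
        columns=["id", "age_class", "age_class_merged"],
    )
    protein_ages_df = pd.DataFrame(
        [
            {
                "id": pid,
                "age_class": a.label,
                "age_class_merged": ranking.merged(a),
            }
            for pid, a in sorted(protein_age.items())
        ],
        columns=["id", "age_class", "age_class_merged"],
    )

    # -- stage 2: scenarios and positions
    dataset = [architectures[pid] for pid in sorted(architectures)]
    combined = [
        a
        for a in dataset
        if any(ranking.is_young(x) for x in a.ages)
        and any(not ranking.is_young(x) for x in a.ages)
    ]
    scen_rows = []
    scen_counts = {c.name: 0 for c in ScenarioClass}
    for a in combined:
        cls = arch_mod.classify_protein(a, dataset, ranking)
        scen_counts[cls.name] += 1
        scen_rows.append(
            {
                "protein_id": a.protein_id,
                "architecture": ";".join(a.domain_types),
                "scenario_class": cls.name,
                "class_number": cls.value,
                "gain_compatible": cls.gain_compatible,
            }
        )
    scenario_table = pd.DataFrame(
        scen_rows,
        columns=[
            "protein_id",
            "architecture",
            "scenario_class",
            "class_number",
            "gain_compatible",
        ],
    )
    logger.info("scenarios: %d combined proteins classified", len(combined))

    counts2: dict[PositionLabel, int] = {}
    counts_multi: dict[PositionLabel, int] = {}
    k_multi: list[int] = []
    for a in combined:
        k = len(a.domain_types)
        if k < 2:
            continue
        for label in arch_mod.young_positions(a, ranking):
            if k == 2:
                counts2[label] = counts2.get(label, 0) + 1
            else:
                counts_multi[label] = counts_multi.get(label, 0) + 1
                k_multi.append(k)
    test2 = arch_mod.positional_bias_test(counts2) if counts2 else None
    test_multi = (
        arch_mod.positional_bias_test(counts_multi, k_multi) if counts_multi else None
    )

    # -- stage 3: rates
    rate_rows = []
    estimates: dict[str, list[tuple[str, RateEstimate]]] = {}
    n_est = n_pass = 0
    for pid in sorted(architectures):
        pair = bundle.alignments.get(pid)
        if pair is None:
            continue
        for h in resolved_hits[pid]:
            occ_id = f"{pid}:{h.domain_type_id}:{h.start}"
            try:
                region = extract_domain_region(pair, h.start, h.end)
                est = rates_mod.estimate_dnds(region, occ_id)
            except (ValueError, rates_mod.ng86.SaturationError):
                rate_rows.append(
                    {
                        "occurrence_id": occ_id,
                        "protein_id": pid,
                        "domain_type": h.domain_type_id,
                        "age_merged": ranking.merged(type_age[h.domain_type_id]),
                        "length_aa": h.length,
                        "n_sites": float("nan"),
                        "s_sites": float("nan"),
                        "nd": float("nan"),
                        "sd": float("nan"),
                        "dn": float("nan"),
                        "ds": float("nan"),
                        "omega": float("nan"),
                        "pass_filter": False,
                    }
                )
                continue
            est = (
                rates_mod.apply_filters(est, config.thresholds)
                if config.filters_enabled
                else est
            )
            n_est += 1
            n_pass += est.pass_filter
            estimates.setdefault(pid, []).append((h.domain_type_id, est))
            rate_rows.append(
                {
                    "occurrence_id": est.occurrence_id,
                    "protein_id": pid,
                    "domain_type": h.domain_type_id,
                    "age_merged": ranking.merged(type_age[h.domain_type_id]),
                    "length_aa": est.aligned_aa_length,
                    "n_sites": est.n_sites,
                    "s_sites": est.s_sites,
                    "nd": est.nd,
                    "sd": est.sd,
                    "dn": est.dn,
                    "ds": est.ds,
                    "omega": est.omega,
                    "pass_filter": est.pass_filter,
                }
            )
    rates_df = pd.DataFrame(
        rate_rows,
        columns=[
            "occurrence_id",
            "protein_id",
            "domain_type",
            "age_merged",
            "length_aa",
            "n_sites",
            "s_sites",
            "nd",
            "sd",
            "dn",
            "ds",
            "omega",
            "pass_filter",
        ],
    )
    logger.info("rates: %d estimated, %d pass filters", n_est, n_pass)

    # group comparison on passing estimates with defined omega
    group_comp = None
    paired_rows = []
    tallies = {"young_faster": 0, "old_faster": 0, "no_difference": 0}
    if len(rates_df):
        usable = rates_df[rates_df["pass_filter"] & rates_df["omega"].notna()]
        groups = {
            label: list(sub["omega"])
            for label, sub in usable.groupby("age_merged")
        }
        types_by_group = {
            label: list(sub["domain_type"])
            for label, sub in usable.groupby("age_merged")
        }
        paired_omegas = []
        for pid in sorted(estimates):
            ests = estimates[pid]
            young = [
                (t, e)
                for t, e in ests
                if ranking.is_young(type_age[t]) and e.pass_filter and e.omega_defined
            ]
            old = [
                (t, e)
                for t, e in ests
                if not ranking.is_young(type_age[t]) and e.pass_filter and e.omega_defined
            ]
            for ty, ey in young:
                for to, eo in old:
                    comp = rates_mod.paired_binomial_test(
                        ey,
                        eo,
                        alpha=config.alpha,
                        protein_id=pid,
                        site_adjusted=config.site_adjusted_null,
                    )
                    tallies[comp.verdict] += 1
                    paired_omegas.append((ey.omega, eo.omega))
                    paired_rows.append(
                        {
                            "protein_id": pid,
                            "young_type": ty,
                            "old_type": to,
                            "omega_young": ey.omega,
                            "omega_old": eo.omega,
                            "rel_difference": comp.rel_difference,
                            "pvalue": comp.pvalue,
                            "verdict": comp.verdict,
                            "degenerate": comp.degenerate,
                        }
                    )
        if groups:
            group_comp = rates_mod.compare_age_groups(
                groups, paired_omegas, types_by_group
            )
    paired_df = pd.DataFrame(
        paired_rows,
        columns=[
            "protein_id",
            "young_type",
            "old_type",
            "omega_young",
            "omega_old",
            "rel_difference",
            "pvalue",
            "verdict",
            "degenerate",
        ],
    )
    logger.info(
        "paired comparisons: %d (young faster %d, old faster %d)",
        len(paired_df),
        tallies["young_faster"],
        tallies["old_faster"],
    )

    # -- stage 4: derived report numbers
    merged_types = (
        domain_ages_df.groupby("age_class_merged")["id"].nunique().to_dict()
        if len(domain_ages_df)
        else {}
    )
    new_gene = {}
    for _, row in age_summary.percentages.iterrows():
        q = row["quantity"]
        if q.endswith("_types_in_new_genes"):
            new_gene[q.replace("_types_in_new_genes", "")] = (
                int(row["numerator"]),
                int(row["denominator"]),
            )
    n_young_only = sum(
        1
        for a in dataset
        if all(ranking.is_young(x) for x in a.ages)
    )
    derived = derived_percentages(
        type_counts=merged_types or None,
        new_gene_types=new_gene or None,
        scenario_counts=(
            scen_counts["GAIN_DEPENDENT"],
            scen_counts["MUTUAL_DEPENDENCE"],
            scen_counts["FUSION"],
            scen_counts["COMPLEX"],
        )
        if combined
        else None,
        n_young_only=n_young_only if combined else None,
        n_combined=len(combined) if combined else None,
        old_label=ranking.merged_label,
    )

    # the 'arose in newly formed genes' fraction on both bases
    frac_types = float("nan")
    if new_gene:
        num = sum(v[0] for v in new_gene.values())
        den = sum(v[1] for v in new_gene.values())
        frac_types = 100.0 * num / den if den else float("nan")
    frac_occ = float("nan")
    if len(domain_table):
        page = protein_table.set_index("protein_id")["age_label"]
        young_labels = {a.label for a in ranking.ages if ranking.is_young(a)}
        young_occ = domain_table[domain_table["age_label"].isin(young_labels)]
        if len(young_occ):
            in_young_prot = young_occ["protein_id"].map(page).isin(young_labels)
            frac_occ = 100.0 * in_young_prot.sum() / len(young_occ)

    if not bundle.profiles and not bundle.hits:
        logger.warning("empty input: report contains zero counts only")

    return ReportBundle(
        age_summary=age_summary,
        domain_ages=domain_ages_df,
        protein_ages=protein_ages_df,
        scenario_counts={k: v for k, v in scen_counts.items() if v or k != "REVERSE_DEPENDENT"},
        scenario_table=scenario_table,
        derived=derived,
        position_counts_2dom={k.value: v for k, v in counts2.items()},
        position_counts_multi={k.value: v for k, v in counts_multi.items()},
        position_test_2dom=test2,
        position_test_multi=test_multi,
        rates=rates_df,
        group_comparison=group_comp,
        paired=paired_df,
        paired_tallies=tallies,
        new_gene_fraction_types=frac_types,
        new_gene_fraction_occurrences=frac_occ,
    )
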