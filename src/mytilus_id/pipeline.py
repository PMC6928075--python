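"""End-to-end orchestration of the identification workflow.

Stage order is fixed: reference labelling with the Me15-16 assay, exclusion of
DUI individuals, diploid encoding of mitochondrial haplotypes, mono-locus
calls (rule-based for ITS/COI, leave-one-out Bayesian re-allocation for mac-1
and 16S), confusion matrices and diagnostic statistics per marker, 4-marker
(Me15-16 excluded) and 5-marker panel re-allocation, ordinations, and an
optional panel comparison.  Per-stage counts (scored, excluded, unassigned)
are logged so every reported denominator is auditable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .assignment import (
    SPECIES_ORDER,
    classify_diagnostic,
    classify_me15_16,
    flag_introgression,
    loo_reallocate,
)
from .dataset import Dataset, DatasetError, filter_dui
from .diagnostics import concordance, confusion_matrix, diagnostic_stats, heatmap_matrix
from .ordination import build_indicator_matrix, correspondence_analysis, pca
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)

MONO_RULE_MARKERS = ("ITS", "COI")
MONO_LOO_MARKERS = ("mac-1", "16S")
PANEL4 = ("mac-1", "ITS", "COI", "16S")
PANEL5 = ("Me15-16", "mac-1", "ITS", "COI", "16S")


@dataclass
class MarkerReport:
    confusion: pd.DataFrame
    concordance: float
    stats: dict[str, object]
    unassigned: int = 0


@dataclass
class RunReport:
    n_input: int
    n_retained: int
    excluded_dui: list[str]
    reference: dict[str, str]
    hybrids: dict[str, str]
    mono: dict[str, MarkerReport]
    multi: dict[str, MarkerReport]
    introgression: dict[str, str]
    ordination: dict[str, object]
    assignments: pd.DataFrame
    panel_comparison: pd.DataFrame | None = None
    provenance: dict[str, object] = field(default_factory=dict)


def _marker_report(reference_map, calls, group_aware: bool) -> MarkerReport:
    ids = list(calls)
    matrix = confusion_matrix(
        [reference_map[i] for i in ids],
        [calls[i] for i in ids],
        ids=ids,
        group_aware=group_aware,
    )
    stats = {}
    for sp in SPECIES_ORDER:
        if sp in matrix.index and int(matrix.loc[sp].sum()) > 0:
            stats[sp] = diagnostic_stats(matrix, sp)
    labels = [c.species if hasattr(c, "species") else str(c) for c in calls.values()]
    return MarkerReport(
        confusion=matrix,
        concordance=concordance(matrix),
        stats=stats,
        unassigned=sum(1 for lab in labels if lab == "unassigned"),
    )


def run_full_analysis(
    source: Dataset | SimulationConfig,
    threshold: float = 0.05,
    compare_panels: bool = False,
    outdir: str | Path | None = None,
) -> RunReport:
    """Run the whole mono- plus multi-locus workflow and return a RunReport.

    ``source`` is either a ready Dataset or a SimulationConfig (simulated on
    the fly).  With ``outdir`` all tables are also written as delimited text.
    """
    provenance: dict[str, object] = {"version": __version__}
    if isinstance(source, SimulationConfig):
        provenance["seed"] = source.seed
        provenance["config"] = {
            "populations": source.populations,
            "missing_rate": source.missing_rate,
        }
        dataset = simulate_dataset(source)
    else:
        dataset = source
    if len(dataset) == 0:
        raise DatasetError("empty dataset")
    n_input = len(dataset)

    # stage 1: reference labelling (Me15-16 rule calls)
    me = dataset.markers["Me15-16"]
    ref_calls = {
        ind.id: classify_me15_16(ind.genotype("Me15-16"), me)
        for ind in dataset.individuals
    }
    reference = {i: c.species for i, c in ref_calls.items() if c.is_species}
    hybrids = {i: c.species for i, c in ref_calls.items() if c.is_hybrid}
    logger.info(
        "reference labelling: %d species-level, %d hybrid, %d unassigned",
        len(reference), len(hybrids), n_input - len(reference) - len(hybrids),
    )

    # stage 2: DUI exclusion (whole individuals)
    dataset, excluded = filter_dui(dataset)
    excluded_ids = [ind.id for ind in excluded]
    reference = {i: s for i, s in reference.items() if i not in set(excluded_ids)}
    logger.info("DUI filter: excluded %d of %d individuals", len(excluded), n_input)

    # stage 3: mono-locus rule calls (ITS, COI); mito handled haplotype-wise
    mono: dict[str, MarkerReport] = {}
    for m in MONO_RULE_MARKERS:
        calls = {
            ind.id: classify_diagnostic(ind.genotype(m), dataset.markers[m])
            for ind in dataset.individuals
            if ind.id in reference and ind.genotype(m) is not None
        }
        mono[m] = _marker_report(reference, calls, group_aware=True)

    # stage 4: mono-locus LOO re-allocation (mac-1, 16S; raw alleles)
    for m in MONO_LOO_MARKERS:
        sub = dataset.subset(
            [
                ind.id
                for ind in dataset.individuals
                if ind.id in reference and ind.genotype(m) is not None
            ]
        )
        results = loo_reallocate(sub, [m], reference=reference, threshold=threshold)
        calls = {r.id: r.assigned for r in results}
        mono[m] = _marker_report(reference, calls, group_aware=False)

    # stage 5: multi-locus panels
    multi: dict[str, MarkerReport] = {}
    assignment_rows = []
    for name, panel in (("panel4", PANEL4), ("panel5", PANEL5)):
        sub = dataset.subset([i for i in reference])
        results = loo_reallocate(sub, list(panel), reference=reference, threshold=threshold)
        calls = {r.id: r.assigned for r in results if r.loci_used}
        multi[name] = _marker_report(reference, calls, group_aware=False)
        for r in results:
            assignment_rows.append(
                {
                    "panel": name,
                    "id": r.id,
                    "reference_species": r.reference_species,
                    "assigned": r.assigned,
                    "unassigned": r.unassigned,
                    "loci_used": ";".join(r.loci_used),
                    **{f"score_{sp}": r.scores.get(sp) for sp in SPECIES_ORDER},
                }
            )
    assignments = pd.DataFrame(assignment_rows)

    # stage 6: mito-nuclear introgression flags (Me15-16 vs COI)
    introgression = {}
    coi = dataset.markers["COI"]
    for ind in dataset.individuals:
        if ind.id not in reference:
            continue
        flag = flag_introgression(
            ref_calls[ind.id], classify_diagnostic(ind.genotype("COI"), coi)
        )
        if flag:
            introgression[ind.id] = flag
    logger.info("introgression flags: %d", len(introgression))

    # stage 7: ordinations on the five-marker indicator matrix
    indicator = build_indicator_matrix(dataset, list(PANEL5), mode="counts")
    ordination = {
        "fca": correspondence_analysis(indicator, n_axes=2),
        "pca": pca(indicator, n_axes=2),
        "indicator_columns": list(indicator.values.columns),
    }

    report = RunReport(
        n_input=n_input,
        n_retained=len(dataset),
        excluded_dui=excluded_ids,
        reference=reference,
        hybrids=hybrids,
        mono=mono,
        multi=multi,
        introgression=introgression,
        ordination=ordination,
        assignments=assignments,
        provenance=provenance,
    )
    if compare_panels:
        from .diagnostics import wilcoxon_signed_rank

        per_species = []
        for sp in SPECIES_ORDER:
            m5 = multi["panel5"].confusion
            if sp in m5.index and int(m5.loc[sp].sum()) > 0:
                per_species.append(
                    {
                        "species": sp,
                        "panel5": 100.0 * m5.loc[sp, sp] / m5.loc[sp].sum(),
                        "panel4": 100.0
                        * multi["panel4"].confusion.loc[sp, sp]
                        / multi["panel4"].confusion.loc[sp].sum(),
                    }
                )
        cmp_df = pd.DataFrame(per_species)
        stat, p = wilcoxon_signed_rank(cmp_df["panel5"], cmp_df["panel4"])
        cmp_df.attrs["wilcoxon"] = {"statistic": stat, "p_value": p}
        report.panel_comparison = cmp_df
    if outdir is not None:
        write_report(report, outdir)
    return report


def write_report(report: RunReport, outdir: str | Path) -> None:
    """Write all report tables as delimited text under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, object] = {
        "n_input": report.n_input,
        "n_retained": report.n_retained,
        "n_dui_excluded": len(report.excluded_dui),
        "n_hybrid_reference": len(report.hybrids),
        "introgression_flags": sorted(report.introgression),
        "provenance": report.provenance,
        "concordance": {},
    }
    for scope, reports in (("mono", report.mono), ("multi", report.multi)):
        for name, mr in reports.items():
            safe = name.replace("/", "_")
            mr.confusion.to_csv(out / f"confusion_{safe}.csv")
            heatmap_matrix(mr.confusion).round(1).to_csv(out / f"heatmap_{safe}.csv")
            summary["concordance"][name] = mr.concordance
            rows = []
            for sp, st in mr.stats.items():
                rows.append(
                    {
                        "species": sp,
                        "sensitivity": round(st.sensitivity, 3),
                        "specificity": round(st.specificity, 3),
                        "lr_plus": round(st.lr_plus, 2),
                        "sens_ci_low": round(st.sensitivity_ci[0], 3),
                        "sens_ci_high": round(st.sensitivity_ci[1], 3),
                        "spec_ci_low": round(st.specificity_ci[0], 3),
                        "spec_ci_high": round(st.specificity_ci[1], 3),
                    }
                )
            pd.DataFrame(rows).to_csv(out / f"stats_{safe}.csv", index=False)
    report.assignments.to_csv(out / "assignments.csv", index=False)
    for method in ("fca", "pca"):
        res = report.ordination[method]
        res.coordinates.to_csv(out / f"{method}_coordinates.csv")
        pd.DataFrame(
            {"eigenvalue": res.eigenvalues, "proportion": res.proportion}
        ).to_csv(out / f"{method}_eigenvalues.csv", index=False)
    if report.panel_comparison is not None:
        report.panel_comparison.to_csv(out / "panel_comparison.csv", index=False)
        summary["panel_comparison_wilcoxon"] = report.panel_comparison.attrs.get("wilcoxon")
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, default=str)
        fh.write("\n")
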