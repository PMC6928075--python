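"""Species assignment.

Two complementary routes:

* **Rule-based calls** for the diagnostic markers — Me15-16 (the reference
  assay, resolving all four species and F1 hybrids), ITS (trossulus vs the
  edulis/galloprovincialis/chilensis group) and COI (chilensis vs the rest).

* **Bayesian leave-one-out re-allocation** for any marker subset, using the
  Rannala–Mountain genotype probability: each locus contributes the Dirichlet
  posterior-predictive probability of the individual's genotype given the
  baseline allele counts of a candidate species, with per-allele prior mass
  1/k (k = distinct alleles observed across all baselines at the locus).  The
  focal individual's own gene copies are removed from its source baseline
  before scoring (leave-one-out), and an individual is left unassigned when
  its top normalized score falls below a threshold (default 0.05).

Mitochondrial haplotypes enter the diploid likelihood homozygous-encoded.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy.special import logsumexp

from .dataset import Dataset, DatasetError, Individual, MarkerGenotype, encode_mito_as_diploid
from .markers import MarkerDef

__all__ = [
    "SPECIES_ORDER",
    "SpeciesCall",
    "BaselineCounts",
    "AssignmentResult",
    "classify_me15_16",
    "classify_diagnostic",
    "rm_genotype_probability",
    "rm_log_genotype_probability",
    "build_baselines",
    "loo_reallocate",
    "flag_introgression",
    "expand_group",
]

#: Fixed species order; also the deterministic tie-break order in argmax.
SPECIES_ORDER = ("trossulus", "edulis", "galloprovincialis", "chilensis")

_ABBREV = {"T": "trossulus", "E": "edulis", "G": "galloprovincialis", "Ch": "chilensis"}


def expand_group(call: str) -> tuple[str, ...]:
    """Expand a group call like 'E/G/Ch' to full species names."""
    return tuple(_ABBREV.get(part, part) for part in call.split("/"))


@dataclass(frozen=True)
class SpeciesCall:
    """A species-level, group-level, hybrid or unassigned call."""

    species: str
    basis: tuple[str, ...] = ()
    score: float | None = None

    @property
    def is_species(self) -> bool:
        return self.species in SPECIES_ORDER

    @property
    def is_group(self) -> bool:
        return "/" in self.species and not self.is_hybrid

    @property
    def is_hybrid(self) -> bool:
        return self.species.startswith("hybrid(")

    @property
    def is_unassigned(self) -> bool:
        return self.species == "unassigned"


def _call_rank(call: str) -> tuple:
    if call in SPECIES_ORDER:
        return (0, SPECIES_ORDER.index(call))
    return (1, call)


def _hybrid(a: str, b: str) -> str:
    a, b = sorted((a, b), key=_call_rank)
    return f"hybrid({a}×{b})"


def classify_me15_16(genotype: MarkerGenotype | None, marker: MarkerDef) -> SpeciesCall:
    """Rule-based call from the Me15-16 AciI assay (the reference marker).

    Homospecific genotypes map through the diagnostic table (180/180 edulis,
    168/168 trossulus, cut 126 galloprovincialis, uncut 126 chilensis);
    heterospecific allele pairs are F1 hybrid calls.
    """
    if genotype is None or genotype.missing:
        return SpeciesCall("unassigned", basis=("Me15-16",))
    calls = {marker.diagnostic_map.get(a) for a in genotype.alleles}
    if None in calls:
        return SpeciesCall("unassigned", basis=("Me15-16",))
    if len(calls) == 1:
        return SpeciesCall(calls.pop(), basis=("Me15-16",))
    return SpeciesCall(_hybrid(*sorted(calls)), basis=("Me15-16",))


def classify_diagnostic(genotype: MarkerGenotype | None, marker: MarkerDef) -> SpeciesCall:
    """Rule-based call for ITS (nuclear) or COI (mitochondrial).

    ITS separates trossulus from the E/G/Ch group and detects F1 hybrids as
    one-of-each-pattern heterozygotes; COI separates chilensis (cut amplicon)
    from the T/E/G group.
    """
    if marker.name not in ("ITS", "COI"):
        raise DatasetError(f"classify_diagnostic expects ITS or COI, got {marker.name}")
    if genotype is None or genotype.missing:
        return SpeciesCall("unassigned", basis=(marker.name,))
    calls = [marker.diagnostic_map.get(a) for a in genotype.alleles]
    if any(c is None for c in calls):
        return SpeciesCall("unassigned", basis=(marker.name,))
    uniq = sorted(set(calls), key=_call_rank)
    if len(uniq) == 1:
        return SpeciesCall(uniq[0], basis=(marker.name,))
    return SpeciesCall(_hybrid(*uniq), basis=(marker.name,))


# ---------------------------------------------------------------------------
# Rannala-Mountain genotype probability and leave-one-out re-allocation
# ---------------------------------------------------------------------------


@dataclass
class BaselineCounts:
    """Per-baseline, per-marker allele gene-copy counts plus per-marker k."""

    counts: dict[str, dict[str, Counter]] = field(default_factory=dict)
    k: dict[str, int] = field(default_factory=dict)

    @property
    def baselines(self) -> tuple[str, ...]:
        return tuple(self.counts)

    def copy_counts(self, baseline: str, marker: str) -> Counter:
        return Counter(self.counts.get(baseline, {}).get(marker, Counter()))


def _genotype_copies(gt: MarkerGenotype, marker: MarkerDef) -> tuple[str, str]:
    if marker.inheritance == "mito":
        gt = encode_mito_as_diploid(gt)
    if len(gt.alleles) == 2:
        return gt.alleles  # type: ignore[return-value]
    return (gt.alleles[0], gt.alleles[0])


def build_baselines(
    dataset: Dataset,
    markers: Sequence[str],
    reference: Mapping[str, str],
) -> BaselineCounts:
    """Pool gene-copy counts per reference species at each marker.

    ``reference`` maps individual id -> species; individuals without a
    species-level reference are omitted.  ``k`` per marker is the number of
    distinct alleles observed across all baselines.
    """
    bl = BaselineCounts()
    seen: dict[str, set[str]] = {m: set() for m in markers}
    for ind in dataset.individuals:
        sp = reference.get(ind.id)
        if sp not in SPECIES_ORDER:
            continue
        per_marker = bl.counts.setdefault(sp, {})
        for m in markers:
            gt = ind.genotype(m)
            if gt is None:
                continue
            a, b = _genotype_copies(gt, dataset.markers[m])
            counter = per_marker.setdefault(m, Counter())
            counter[a] += 1
            counter[b] += 1
            seen[m].update((a, b))
    bl.k = {m: len(alleles) for m, alleles in seen.items()}
    return bl


def rm_log_genotype_probability(
    genotype: Mapping[str, tuple[str, str]],
    baseline: Mapping[str, Mapping[str, int]],
    k: Mapping[str, int],
) -> float:
    """Log multi-locus Rannala-Mountain genotype probability.

    Per locus, with baseline gene-copy counts ``n_a`` (total ``n``) and prior
    mass ``1/k`` per allele:

    * heterozygote ab:  2 (n_a + 1/k)(n_b + 1/k) / ((n + 1)(n + 2))
    * homozygote aa:    (n_a + 1/k)(n_a + 1 + 1/k) / ((n + 1)(n + 2))

    Alleles absent from the baseline contribute through the prior alone.
    Loci multiply (log-sum); assumes Hardy-Weinberg and linkage equilibrium
    within each baseline.
    """
    logp = 0.0
    for locus, (a, b) in genotype.items():
        kl = k.get(locus, 0)
        if kl <= 0:
            raise DatasetError(f"k=0 at locus {locus}: no alleles observed")
        counts = baseline.get(locus, {})
        n = sum(counts.values())
        prior = 1.0 / kl
        na = counts.get(a, 0) + prior
        denom = math.log(n + 1.0) + math.log(n + 2.0)
        if a == b:
            logp += math.log(na) + math.log(na + 1.0) - denom
        else:
            nb = counts.get(b, 0) + prior
            logp += math.log(2.0) + math.log(na) + math.log(nb) - denom
    return logp


def rm_genotype_probability(
    genotype: Mapping[str, tuple[str, str]],
    baseline: Mapping[str, Mapping[str, int]],
    k: Mapping[str, int],
) -> float:
    """Linear-scale wrapper around :func:`rm_log_genotype_probability`."""
    return math.exp(rm_log_genotype_probability(genotype, baseline, k))


@dataclass
class AssignmentResult:
    id: str
    reference_species: str | None
    log_probs: dict[str, float]
    scores: dict[str, float]
    assigned: str
    unassigned: bool
    loci_used: tuple[str, ...]


def _argmax_species(scores: Mapping[str, float]) -> str:
    best = max(scores.values())
    winners = [sp for sp in scores if scores[sp] >= best - 1e-12]
    ordered = sorted(winners, key=_call_rank)
    if len(ordered) > 1:
        warnings.warn(
            f"assignment tie between {ordered}; taking {ordered[0]} "
            "(fixed species order)",
            stacklevel=2,
        )
    return ordered[0]


def loo_reallocate(
    dataset: Dataset,
    marker_subset: Sequence[str],
    reference: Mapping[str, str] | None = None,
    threshold: float = 0.05,
) -> list[AssignmentResult]:
    """Leave-one-out Bayesian re-allocation of every individual.

    Baselines are species-level pools of the reference-labelled individuals.
    For each individual its own gene copies are removed from its source
    baseline before the genotype probability is computed against every
    species baseline; it is assigned to the top-scoring species unless the
    top normalized score is below ``threshold`` (then flagged unassigned).
    Individuals absent from all baselines (no species-level reference) are
    scored without LOO subtraction, with a warning.

    Works for single markers (mono-locus mode) and multi-marker panels.
    """
    if reference is None:
        reference = {
            ind.id: ind.reference_species
            for ind in dataset.individuals
            if ind.reference_species in SPECIES_ORDER
        }
    baselines = build_baselines(dataset, marker_subset, reference)
    results: list[AssignmentResult] = []
    for ind in dataset.individuals:
        loci: dict[str, tuple[str, str]] = {}
        for m in marker_subset:
            gt = ind.genotype(m)
            if gt is not None:
                loci[m] = _genotype_copies(gt, dataset.markers[m])
        if not loci:
            results.append(
                AssignmentResult(ind.id, reference.get(ind.id), {}, {}, "unassigned", True, ())
            )
            continue
        src = reference.get(ind.id)
        if src not in baselines.counts:
            if src is not None or ind.reference_species is not None:
                warnings.warn(
                    f"{ind.id}: no source baseline; scoring without LOO subtraction",
                    stacklevel=2,
                )
            src = None
        log_probs: dict[str, float] = {}
        for sp in SPECIES_ORDER:
            if sp not in baselines.counts:
                continue
            counts: dict[str, Mapping[str, int]] = {}
            for m in loci:
                c = baselines.copy_counts(sp, m)
                if sp == src:
                    a, b = loci[m]
                    c[a] -= 1
                    c[b] -= 1
                counts[m] = c
            log_probs[sp] = rm_log_genotype_probability(loci, counts, baselines.k)
        if not log_probs:
            raise DatasetError("no baselines available for re-allocation")
        total = logsumexp(list(log_probs.values()))
        scores = {sp: math.exp(lp - total) for sp, lp in log_probs.items()}
        assigned = _argmax_species(scores)
        unassigned = scores[assigned] < threshold
        results.append(
            AssignmentResult(
                id=ind.id,
                reference_species=reference.get(ind.id),
                log_probs=log_probs,
                scores=scores,
                assigned="unassigned" if unassigned else assigned,
                unassigned=unassigned,
                loci_used=tuple(loci),
            )
        )
    return results


def flag_introgression(nuclear_call: SpeciesCall | str, mito_call: SpeciesCall | str) -> str | None:
    """Flag mito-nuclear discordance (e.g. a galloprovincialis nuclear genotype
    carrying the chilensis mitochondrial haplotype).

    Returns ``"introgression"`` when both calls are species-level and
    disagree; ``None`` when they agree or either is a group/hybrid/unassigned
    call (uninformative).
    """
    nuc = nuclear_call.species if isinstance(nuclear_call, SpeciesCall) else nuclear_call
    mito = mito_call.species if isinstance(mito_call, SpeciesCall) else mito_call
    if nuc not in SPECIES_ORDER or mito not in SPECIES_ORDER:
        return None
    return "introgression" if nuc != mito else None
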