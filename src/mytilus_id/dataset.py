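"""Genotype data model and I/O.

Long-format delimited genotype tables (individual, population, marker,
allele_1, allele_2) are read into a :class:`Dataset`; raw fragment sizes such
as ``134+99`` are resolved to registered allele labels through the marker
models.  The module also implements the two preprocessing rules that precede
all frequency-based analyses: exclusion of individuals showing two
mitochondrial haplotypes (doubly uniparental inheritance, DUI) and encoding of
single mitochondrial haplotypes as homozygous diploid genotypes so that they
can enter a diploid assignment likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .markers import FragmentPattern, MarkerDef, MarkerError, marker_registry

__all__ = [
    "MarkerGenotype",
    "Individual",
    "Dataset",
    "DatasetError",
    "read_genotype_table",
    "write_genotype_table",
    "allele_frequencies",
    "filter_dui",
    "encode_mito_as_diploid",
    "export_genepop",
    "DEFAULT_POPULATIONS",
]

#: Site-code -> species map for the six study-style sampling sites.
DEFAULT_POPULATIONS = {
    "MT-1": "trossulus",
    "ME-1": "edulis",
    "MG-1": "galloprovincialis",
    "MG-2": "galloprovincialis",
    "MCh-1": "chilensis",
    "MCh-2": "chilensis",
}


class DatasetError(ValueError):
    """Invalid genotype table or dataset operation."""


@dataclass(frozen=True)
class MarkerGenotype:
    """Observed genotype at one marker.

    Nuclear markers carry exactly two allele entries (homozygotes duplicated);
    mitochondrial markers carry one haplotype, or two for a DUI individual.
    ``missing`` marks amplification failure (no alleles).
    """

    marker: str
    alleles: tuple[str, ...] = ()
    missing: bool = False

    def __post_init__(self) -> None:
        if self.missing and self.alleles:
            raise DatasetError(f"{self.marker}: missing genotype with alleles")
        if not self.missing and not self.alleles:
            raise DatasetError(f"{self.marker}: empty genotype not flagged missing")
        if len(self.alleles) > 2:
            raise DatasetError(
                f"{self.marker}: more than two alleles {self.alleles}"
            )

    @property
    def is_dui(self) -> bool:
        """Two *distinct* haplotypes at a mitochondrial marker."""
        return len(self.alleles) == 2 and self.alleles[0] != self.alleles[1]


@dataclass
class Individual:
    id: str
    population: str
    genotypes: dict[str, MarkerGenotype] = field(default_factory=dict)
    reference_species: str | None = None

    def genotype(self, marker: str) -> MarkerGenotype | None:
        gt = self.genotypes.get(marker)
        if gt is None or gt.missing:
            return None
        return gt


@dataclass
class Dataset:
    individuals: list[Individual]
    markers: dict[str, MarkerDef]
    populations: dict[str, str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for ind in self.individuals:
            if ind.id in seen:
                raise DatasetError(f"duplicate individual id {ind.id!r}")
            seen.add(ind.id)
            for marker, gt in ind.genotypes.items():
                if marker not in self.markers:
                    raise DatasetError(
                        f"individual {ind.id}: unknown marker {marker!r}"
                    )
                mdef = self.markers[marker]
                for allele in gt.alleles:
                    if allele not in mdef.alleles:
                        raise DatasetError(
                            f"individual {ind.id}: allele {allele!r} not in "
                            f"{marker} registry"
                        )

    def __len__(self) -> int:
        return len(self.individuals)

    def species_of(self, ind: Individual) -> str | None:
        return self.populations.get(ind.population)

    def subset(self, ids: Iterable[str]) -> "Dataset":
        keep = set(ids)
        return Dataset(
            [ind for ind in self.individuals if ind.id in keep],
            self.markers,
            self.populations,
        )


def _resolve_allele(value: str, marker: MarkerDef, row_ctx: str) -> str:
    value = value.strip()
    if value in marker.alleles:
        return value
    try:
        pattern = FragmentPattern.parse(value)
    except MarkerError as exc:
        raise DatasetError(f"{row_ctx}: cannot interpret allele {value!r}") from exc
    label = marker.match(pattern, auto_register=marker.open_registry)
    if label == "unrecognized":
        raise DatasetError(
            f"{row_ctx}: pattern {pattern.render()} unresolvable at "
            f"tolerance {marker.tolerance_bp} for marker {marker.name}"
        )
    return label


def read_genotype_table(
    path,
    markers: Mapping[str, MarkerDef] | None = None,
    populations: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> Dataset:
    """Read a long-format genotype table into a Dataset.

    Columns: ``individual_id, population, marker, allele_1, allele_2``.
    A blank ``allele_2`` means homozygote (nuclear) or single haplotype
    (mitochondrial); both blank means amplification failure.  Values may be
    allele labels or raw fragment sizes (``+``-joined), which are resolved via
    pattern matching at the marker's tolerance.
    """
    if markers is None:
        markers = marker_registry()
    else:
        markers = dict(markers)
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    expected = ["individual_id", "population", "marker", "allele_1", "allele_2"]
    if list(df.columns[:5]) != expected:
        raise DatasetError(
            f"genotype table must have columns {expected}, got {list(df.columns)}"
        )
    inds: dict[str, Individual] = {}
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        ctx = f"{path} line {i}"
        name = row.marker.strip()
        if name not in markers:
            errors.append(f"{ctx}: unknown marker {name!r}")
            continue
        marker = markers[name]
        ind = inds.setdefault(
            row.individual_id.strip(),
            Individual(id=row.individual_id.strip(), population=row.population.strip()),
        )
        if name in ind.genotypes:
            errors.append(f"{ctx}: duplicate row for {ind.id}/{name}")
            continue
        raw = [v for v in (row.allele_1, row.allele_2) if v.strip()]
        if not raw:
            ind.genotypes[name] = MarkerGenotype(name, (), missing=True)
            continue
        try:
            labels = [_resolve_allele(v, marker, ctx) for v in raw]
        except DatasetError as exc:
            errors.append(str(exc))
            continue
        if marker.inheritance == "nuclear":
            if len(labels) == 1:
                labels = labels * 2  # homozygote shorthand
            labels = sorted(labels)
        ind.genotypes[name] = MarkerGenotype(name, tuple(labels))
    if errors:
        raise DatasetError("genotype table errors:\n" + "\n".join(errors))
    pops: dict[str, str | None] = dict(DEFAULT_POPULATIONS)
    if populations:
        pops.update(populations)
    present = {ind.population for ind in inds.values()}
    return Dataset(list(inds.values()), markers, {p: pops.get(p) for p in present})


def write_genotype_table(dataset: Dataset, path, delimiter: str = ",") -> None:
    """Inverse of :func:`read_genotype_table` (labels, not raw sizes)."""
    rows = []
    for ind in dataset.individuals:
        for name, gt in ind.genotypes.items():
            a1 = gt.alleles[0] if gt.alleles else ""
            a2 = gt.alleles[1] if len(gt.alleles) > 1 else ""
            rows.append((ind.id, ind.population, name, a1, a2))
    df = pd.DataFrame(
        rows, columns=["individual_id", "population", "marker", "allele_1", "allele_2"]
    )
    df.to_csv(path, sep=delimiter, index=False, lineterminator="\n")


def allele_frequencies(
    dataset: Dataset,
    marker: str,
    grouping: str = "population",
    diploid_encoded: bool = False,
) -> pd.DataFrame:
    """Per-group allele counts (gene copies) and frequencies at one marker.

    Nuclear genotypes contribute 2 copies (homozygotes both); a single
    mitochondrial haplotype contributes 1 copy, or 2 when
    ``diploid_encoded=True``.  Missing genotypes are excluded from the
    denominators.  Grouping is by ``"population"`` or ``"species"`` (via the
    dataset's population->species map).
    """
    if grouping not in ("population", "species"):
        raise DatasetError(f"grouping must be 'population' or 'species', got {grouping}")
    mdef = dataset.markers[marker]
    records: list[tuple[str, str, int]] = []
    for ind in dataset.individuals:
        gt = ind.genotype(marker)
        if gt is None:
            continue
        group = ind.population if grouping == "population" else dataset.species_of(ind)
        if group is None:
            continue
        if mdef.inheritance == "mito" and len(gt.alleles) == 1 and diploid_encoded:
            records.append((group, gt.alleles[0], 2))
        else:
            records.extend((group, a, 1) for a in gt.alleles)
    if not records:
        return pd.DataFrame(columns=["group", "allele", "count", "frequency"])
    df = pd.DataFrame(records, columns=["group", "allele", "count"])
    out = df.groupby(["group", "allele"], as_index=False)["count"].sum()
    out["frequency"] = out["count"] / out.groupby("group")["count"].transform("sum")
    return out.sort_values(["group", "allele"], ignore_index=True)


def filter_dui(
    dataset: Dataset, mito_markers: Sequence[str] = ("COI", "16S")
) -> tuple[Dataset, list[Individual]]:
    """Remove individuals carrying two distinct mitochondrial haplotypes.

    Somatic tissue of mussels can carry both the maternal and (in males) the
    paternal mitochondrial genome; such double-haplotype individuals are
    excluded whole from all downstream analyses.  Returns the filtered dataset
    and the excluded individuals, in input order.
    """
    if not mito_markers:
        raise DatasetError("mito_markers must be non-empty")
    excluded, kept = [], []
    for ind in dataset.individuals:
        dui = any(
            (gt := ind.genotype(m)) is not None and gt.is_dui for m in mito_markers
        )
        (excluded if dui else kept).append(ind)
    return Dataset(kept, dataset.markers, dataset.populations), excluded


def encode_mito_as_diploid(genotype: MarkerGenotype) -> MarkerGenotype:
    """Encode a single mitochondrial haplotype as a homozygous diploid genotype.

    Under this encoding each individual contributes 2 gene copies at the
    marker, making the haplotype usable by a diploid genotype likelihood.
    Missing genotypes pass through unchanged; two-haplotype (DUI) genotypes are
    an error — they must be filtered out first.
    """
    if genotype.missing:
        return genotype
    if len(genotype.alleles) == 2:
        if genotype.alleles[0] != genotype.alleles[1]:
            raise DatasetError(
                f"{genotype.marker}: two haplotypes present "
                f"{genotype.alleles}; DUI individuals must be filtered first"
            )
        return genotype
    return replace(genotype, alleles=(genotype.alleles[0], genotype.alleles[0]))


def _allele_size_key(marker: MarkerDef, label: str) -> tuple:
    allele = marker.alleles[label]
    size = allele.pattern.total if allele.pattern is not None else float("inf")
    return (size, label)


def genepop_codes(marker: MarkerDef) -> dict[str, int]:
    """Stable 1-based integer codes, ascending fragment-size order."""
    ordered = sorted(marker.alleles, key=lambda lab: _allele_size_key(marker, lab))
    return {lab: i + 1 for i, lab in enumerate(ordered)}


def export_genepop(dataset: Dataset, path, title: str = "mytilus-id export") -> None:
    """Write the dataset as a GenePop file (3-digit allele codes).

    Mitochondrial single haplotypes are written diploid-encoded; missing
    genotypes as ``000000``.
    """
    marker_names = list(dataset.markers)
    codes = {}
    for name in marker_names:
        c = genepop_codes(dataset.markers[name])
        if len(c) > 999:
            raise DatasetError(f"marker {name}: >999 alleles, GenePop limit")
        codes[name] = c
    by_pop: dict[str, list[Individual]] = {}
    for ind in dataset.individuals:
        by_pop.setdefault(ind.population, []).append(ind)
    lines = [title]
    lines.extend(marker_names)
    for pop, inds in by_pop.items():
        lines.append("Pop")
        for ind in inds:
            fields = []
            for name in marker_names:
                gt = ind.genotype(name)
                if gt is None:
                    fields.append("000000")
                    continue
                if dataset.markers[name].inheritance == "mito":
                    gt = encode_mito_as_diploid(gt)
                a, b = gt.alleles if len(gt.alleles) == 2 else gt.alleles * 2
                fields.append(f"{codes[name][a]:03d}{codes[name][b]:03d}")
            lines.append(f"{ind.id} , " + " ".join(fields))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
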