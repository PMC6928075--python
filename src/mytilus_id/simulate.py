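"""Synthetic genotype datasets with the statistical structure of a four-species
*Mytilus* survey.

The study's raw genotype matrix is not deposited, so every downstream stage is
exercised on simulated data: per-species allele-frequency profiles at the five
marker loci, Hardy-Weinberg diploid draws at nuclear loci, single maternal
haplotypes at mitochondrial loci (COI and 16S drawn from the same maternal
lineage, mirroring their linkage on the mitochondrial genome), plus the
structures that complicate real surveys — F1 hybrids, mito-nuclear
introgressed individuals, double-haplotype (DUI) males, and ~2% amplification
failure at mac-1 and 16S.

Profile frequencies that are reported (e.g. the 16S edulis haplotype at 0.980
in edulis and 0.957 in northern galloprovincialis, the mac-1 328 bp allele at
0.220 in southern galloprovincialis) are encoded as printed; the remaining
frequencies are plausible fill-in chosen once and documented in the methods
note, not fitted to anything.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .dataset import DEFAULT_POPULATIONS, Dataset, DatasetError, Individual, MarkerGenotype
from .markers import marker_registry

__all__ = [
    "SpeciesProfile",
    "SimulationConfig",
    "default_profiles",
    "default_config",
    "pure_config",
    "simulate_dataset",
    "simulate_panel_comparison",
]

NUCLEAR_MARKERS = ("Me15-16", "ITS", "mac-1")
MITO_MARKERS = ("COI", "16S")


@dataclass(frozen=True)
class SpeciesProfile:
    """Per-marker allele/haplotype frequencies for one species."""

    species: str
    frequencies: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        for marker, freqs in self.frequencies.items():
            vals = np.array(list(freqs.values()), dtype=float)
            if (vals < 0).any() or (vals > 1).any():
                raise DatasetError(f"{self.species}/{marker}: frequencies outside [0,1]")
            if abs(vals.sum() - 1.0) > 1e-9:
                raise DatasetError(
                    f"{self.species}/{marker}: frequencies sum to {vals.sum()}, not 1"
                )


def default_profiles(galloprovincialis_hemisphere: str = "southern") -> dict[str, SpeciesProfile]:
    """Shipped four-species profiles at the five markers.

    ``galloprovincialis_hemisphere`` switches the hemisphere-dependent parts of
    the galloprovincialis profile: the private mac-1 alleles 328/303 swap
    frequencies (0.220/0.021 southern vs 0.021/0.220 northern) and the southern
    mitochondrial pool carries the chilensis and novel haplotypes seen in the
    Chilean hybrid-zone population.
    """
    if galloprovincialis_hemisphere not in ("southern", "northern"):
        raise DatasetError("galloprovincialis_hemisphere must be 'southern' or 'northern'")
    southern = galloprovincialis_hemisphere == "southern"
    mac1_g = (
        {"255": 0.38, "266": 0.379, "303": 0.021, "328": 0.220}
        if southern
        else {"255": 0.38, "266": 0.379, "303": 0.220, "328": 0.021}
    )
    s16_g = (
        {"edulis": 0.75, "chilensis": 0.10, "gallo-new": 0.15}
        if southern
        else {"edulis": 0.957, "galloprovincialis": 0.043}
    )
    profiles = {
        "trossulus": SpeciesProfile(
            "trossulus",
            {
                "Me15-16": {"168-T": 1.0},
                "ITS": {"tros": 1.0},
                "COI": {"uncut": 1.0},
                "16S": {"trossulus": 0.978, "tros-new": 0.022},
                "mac-1": {
                    "487": 0.30,
                    "494": 0.25,
                    "255": 0.05,
                    "266": 0.05,
                    "164": 0.05,
                    "180": 0.05,
                    "211": 0.05,
                    "230": 0.05,
                    "347": 0.05,
                    "376": 0.05,
                    "402": 0.05,
                },
            },
        ),
        "edulis": SpeciesProfile(
            "edulis",
            {
                "Me15-16": {"180-E": 1.0},
                "ITS": {"EGCh": 1.0},
                "COI": {"uncut": 1.0},
                "16S": {"edulis": 0.98, "chilensis": 0.02},
                "mac-1": {"255": 0.50, "266": 0.30, "298": 0.20},
            },
        ),
        "galloprovincialis": SpeciesProfile(
            "galloprovincialis",
            {
                "Me15-16": {"126-G": 1.0},
                "ITS": {"EGCh": 1.0},
                "COI": {"uncut": 1.0},
                "16S": s16_g,
                "mac-1": mac1_g,
            },
        ),
        "chilensis": SpeciesProfile(
            "chilensis",
            {
                "Me15-16": {"126-Ch": 1.0},
                "ITS": {"EGCh": 1.0},
                "COI": {"chilensis-cut": 1.0},
                "16S": {"chilensis": 1.0},
                "mac-1": {"255": 0.40, "266": 0.40, "298": 0.20},
            },
        ),
    }
    return profiles


@dataclass
class SimulationConfig:
    """Survey structure: population sizes and the complicating fractions.

    Fractions may be single floats (applied to every population) or per
    population dicts; counts per population are ``round(fraction * n)``, so a
    fixture like 7/30/3 DUI individuals is reproduced exactly.  ``seed`` is
    mandatory — the same seed yields a byte-identical dataset.
    """

    populations: dict[str, tuple[str, int]]
    hybrid_fraction: float | dict[str, float] = 0.0
    hybrid_partner: str = "chilensis"
    introgressed_fraction: float | dict[str, float] = 0.0
    introgression_mito_species: str = "chilensis"
    dui_fraction: float | dict[str, float] = 0.0
    dui_markers: tuple[str, ...] = ("16S",)
    missing_rate: dict[str, float] = field(
        default_factory=lambda: {"mac-1": 0.02, "16S": 0.02}
    )
    seed: int = 0

    def fraction(self, which: str, pop: str) -> float:
        val = getattr(self, which)
        f = val.get(pop, 0.0) if isinstance(val, dict) else float(val)
        if not 0.0 <= f <= 1.0:
            raise DatasetError(f"{which}[{pop}]={f} outside [0,1]")
        return f


def default_config(seed: int = 0) -> SimulationConfig:
    """Six study-style populations (298 individuals) with the observed
    DUI (7/30/3) and introgression (2 in MG-2) structure."""
    return SimulationConfig(
        populations={
            "MT-1": ("trossulus", 50),
            "ME-1": ("edulis", 50),
            "MG-1": ("galloprovincialis", 49),
            "MG-2": ("galloprovincialis", 50),
            "MCh-1": ("chilensis", 50),
            "MCh-2": ("chilensis", 49),
        },
        dui_fraction={"MCh-1": 7 / 50, "MG-2": 30 / 50, "MG-1": 3 / 49},
        introgressed_fraction={"MG-2": 2 / 50},
        introgression_mito_species="chilensis",
        seed=seed,
    )


def pure_config(n: int = 50, seed: int = 0, missing: bool = True) -> SimulationConfig:
    """One pure population per species, no hybrids/introgression/DUI."""
    return SimulationConfig(
        populations={
            "MT-1": ("trossulus", n),
            "ME-1": ("edulis", n),
            "MG-1": ("galloprovincialis", n),
            "MCh-1": ("chilensis", n),
        },
        missing_rate={"mac-1": 0.02, "16S": 0.02} if missing else {},
        seed=seed,
    )


def _draw(rng: np.random.Generator, freqs: Mapping[str, float], size: int = 1) -> list[str]:
    labels = list(freqs)
    p = np.array([freqs[l] for l in labels], dtype=float)
    p = p / p.sum()
    return list(rng.choice(labels, size=size, p=p, replace=True))


def _second_haplotype(
    rng: np.random.Generator,
    maternal: str,
    own: Mapping[str, float],
    pooled: Mapping[str, float],
) -> str:
    """Paternal-lineage haplotype for a DUI individual: drawn from the same
    species' pool excluding the maternal haplotype, falling back to the pooled
    across-species haplotype frequencies when the species pool is monomorphic."""
    options = {h: f for h, f in own.items() if h != maternal and f > 0}
    if not options:
        options = {h: f for h, f in pooled.items() if h != maternal and f > 0}
    return _draw(rng, options)[0]


def simulate_dataset(
    config: SimulationConfig, profiles: Mapping[str, SpeciesProfile] | None = None
) -> Dataset:
    """Draw a full dataset under the configured survey structure.

    Pure individuals: Hardy-Weinberg diploid genotypes per nuclear marker and
    one maternal mitochondrial lineage providing both COI and 16S haplotypes.
    F1 hybrids: one gamete from each parental profile at nuclear loci, the
    maternal (population) species' mitochondrial lineage.  Introgressed
    individuals: nuclear genotypes from the population species, mitochondrial
    haplotypes from ``introgression_mito_species``.  DUI individuals carry a
    second haplotype at ``dui_markers``.  Genotypes are then dropped at the
    per-marker missing rate.
    """
    if profiles is None:
        profiles = default_profiles()
    markers = marker_registry()
    rng = np.random.default_rng(config.seed)
    pooled_16s: dict[str, float] = {}
    for prof in profiles.values():
        for h, f in prof.frequencies.get("16S", {}).items():
            pooled_16s[h] = pooled_16s.get(h, 0.0) + f / len(profiles)

    individuals: list[Individual] = []
    populations: dict[str, str | None] = {}
    for pop, (species, n) in config.populations.items():
        populations[pop] = species
        fractions = {
            which: config.fraction(which, pop)
            for which in ("hybrid_fraction", "introgressed_fraction", "dui_fraction")
        }
        if sum(fractions.values()) > 1.0 + 1e-9:
            raise DatasetError(f"{pop}: hybrid+introgressed+DUI fractions exceed 1")
        n_hyb = round(fractions["hybrid_fraction"] * n)
        n_intro = round(fractions["introgressed_fraction"] * n)
        n_dui = round(fractions["dui_fraction"] * n)
        roles = (
            ["hybrid"] * n_hyb
            + ["introgressed"] * n_intro
            + ["dui"] * n_dui
            + ["pure"] * (n - n_hyb - n_intro - n_dui)
        )
        rng.shuffle(roles)
        for i, role in enumerate(roles, start=1):
            ind = Individual(id=f"{pop}-{i:03d}", population=pop)
            own = profiles[species].frequencies
            # nuclear loci
            for m in NUCLEAR_MARKERS:
                if role == "hybrid":
                    partner = profiles[config.hybrid_partner].frequencies
                    alleles = [_draw(rng, own[m])[0], _draw(rng, partner[m])[0]]
                else:
                    alleles = _draw(rng, own[m], size=2)
                ind.genotypes[m] = MarkerGenotype(m, tuple(sorted(alleles)))
            # mitochondrial lineage: COI and 16S inherited linked
            mito_species = (
                config.introgression_mito_species if role == "introgressed" else species
            )
            mito_prof = profiles[mito_species].frequencies
            for m in MITO_MARKERS:
                hap = _draw(rng, mito_prof[m])[0]
                if role == "dui" and m in config.dui_markers:
                    second = _second_haplotype(rng, hap, mito_prof[m], pooled_16s)
                    ind.genotypes[m] = MarkerGenotype(m, (hap, second))
                else:
                    ind.genotypes[m] = MarkerGenotype(m, (hap,))
            # amplification failure; a DUI double haplotype was by definition
            # amplified, so those genotypes are exempt (failures and DUI
            # exclusions are disjoint)
            for m, rate in config.missing_rate.items():
                if role == "dui" and m in config.dui_markers:
                    continue
                if rate > 0 and rng.random() < rate:
                    ind.genotypes[m] = MarkerGenotype(m, (), missing=True)
            if role != "hybrid":
                ind.reference_species = species
            individuals.append(ind)
    pops = dict(DEFAULT_POPULATIONS)
    pops.update(populations)
    return Dataset(individuals, markers, {p: pops.get(p) for p in populations})


def simulate_panel_comparison(
    config: SimulationConfig,
    profiles: Mapping[str, SpeciesProfile] | None = None,
    snp_error: float | Mapping[str, float] = 0.0,
):
    """Paired per-species accuracy of the five-marker RFLP panel vs a
    high-accuracy SNP-style classifier with configurable per-species error.

    Returns a DataFrame with columns species, rflp_accuracy, snp_accuracy
    (percent correct against the Me15-16 reference), suitable for
    :func:`mytilus_id.diagnostics.wilcoxon_signed_rank`.
    """
    import pandas as pd

    from .assignment import SPECIES_ORDER, classify_me15_16, loo_reallocate
    from .dataset import filter_dui

    dataset = simulate_dataset(config, profiles)
    dataset, _ = filter_dui(dataset)
    me = dataset.markers["Me15-16"]
    reference = {
        ind.id: call.species
        for ind in dataset.individuals
        if (call := classify_me15_16(ind.genotype("Me15-16"), me)).is_species
    }
    results = loo_reallocate(
        dataset, ["Me15-16", "mac-1", "ITS", "COI", "16S"], reference=reference
    )
    rng = np.random.default_rng(config.seed + 1)
    rows = []
    for sp in SPECIES_ORDER:
        ids = [i for i, s in reference.items() if s == sp]
        if not ids:
            continue
        by_id = {r.id: r for r in results}
        correct = sum(1 for i in ids if by_id[i].assigned == sp)
        err = snp_error.get(sp, 0.0) if isinstance(snp_error, Mapping) else float(snp_error)
        snp_correct = sum(1 for _ in ids if err <= 0 or rng.random() >= err)
        rows.append(
            {
                "species": sp,
                "rflp_accuracy": 100.0 * correct / len(ids),
                "snp_accuracy": 100.0 * snp_correct / len(ids),
                "n": len(ids),
            }
        )
    return pd.DataFrame(rows)
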