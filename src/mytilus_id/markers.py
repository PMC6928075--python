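"""PCR-RFLP marker models for *Mytilus* specimen identification.

Each of the five loci (Me15-16, ITS, COI, 16S rRNA, mac-1) is modelled as an
amplicon plus a restriction map: an allele (nuclear) or haplotype
(mitochondrial) is either a cut-position list on a known amplicon length, or a
fragment-size multiset read directly off a gel/fragment analyzer when the cut
positions are unpublished.  In-silico digestion and tolerance-based pattern
matching convert observed fragment sizes into registered allele labels, which
is the entry point for everything downstream (genotype tables, assignment,
diagnostics).

Fragment coordinates are 1-based lengths in bp; cut positions are measured
from the amplicon 5' end.  Only fragment multisets are compared: gel
electrophoresis cannot observe fragment order.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "MarkerError",
    "AmbiguousPatternError",
    "FragmentPattern",
    "AlleleDef",
    "MarkerDef",
    "digest",
    "match_pattern",
    "load_marker_definitions",
    "MARKER_NAMES",
]

MARKER_NAMES = ("Me15-16", "mac-1", "ITS", "COI", "16S")

#: Fragments shorter than this (bp) may fall off the bottom of a silver-stained
#: polyacrylamide gel; they are flagged but still matched by default.
DEFAULT_DETECTION_FLOOR = 20


class MarkerError(ValueError):
    """Invalid marker definition or fragment data."""


class AmbiguousPatternError(MarkerError):
    """An observed pattern matches more than one registered allele."""


@dataclass(frozen=True, init=False)
class FragmentPattern:
    """A multiset of restriction-fragment lengths (bp), order-free.

    Stored internally as a descending tuple so that equality and hashing are
    multiset equality.
    """

    fragments: tuple[int, ...]

    def __init__(self, fragments: Iterable[int]):
        frags = tuple(sorted((int(f) for f in fragments), reverse=True))
        if not frags:
            raise MarkerError("empty fragment pattern")
        if any(f <= 0 for f in frags):
            raise MarkerError(f"non-positive fragment length in {frags}")
        object.__setattr__(self, "fragments", frags)

    @classmethod
    def parse(cls, text: str) -> "FragmentPattern":
        """Parse '134+99', '134,99' or '134 99' into a pattern."""
        for sep in ("+", ",", ";"):
            text = text.replace(sep, " ")
        parts = text.split()
        if not parts:
            raise MarkerError(f"cannot parse fragment pattern from {text!r}")
        try:
            return cls(int(p) for p in parts)
        except ValueError as exc:
            raise MarkerError(f"cannot parse fragment pattern from {text!r}") from exc

    @property
    def total(self) -> int:
        return sum(self.fragments)

    def __len__(self) -> int:
        return len(self.fragments)

    def render(self, sep: str = ",") -> str:
        """Comma-joined descending integers, e.g. '342,85,82,28'."""
        return sep.join(str(f) for f in self.fragments)

    def matches(self, other: "FragmentPattern", tolerance_bp: int = 0) -> bool:
        """Fragment-for-fragment match within +/- tolerance_bp.

        Both patterns must have the same fragment count; fragments are paired
        greedily after sorting descending (nearest pairing for equal-length
        sorted vectors).
        """
        if tolerance_bp < 0:
            raise MarkerError("tolerance_bp must be >= 0")
        if len(self) != len(other):
            return False
        return all(
            abs(a - b) <= tolerance_bp
            for a, b in zip(self.fragments, other.fragments)
        )

    def faint_fragments(self, floor: int = DEFAULT_DETECTION_FLOOR) -> tuple[int, ...]:
        """Fragments below the gel detection floor (possibly unobserved)."""
        return tuple(f for f in self.fragments if f < floor)


def digest(amplicon_length: int, cut_positions: Sequence[int]) -> FragmentPattern:
    """In-silico restriction digestion of an amplicon.

    Parameters
    ----------
    amplicon_length : length of the PCR product in bp (> 0).
    cut_positions : strictly increasing positions (bp from the 5' end),
        each strictly inside the amplicon.

    Returns
    -------
    FragmentPattern with the two terminal fragments and all inter-cut
    distances; fragment lengths sum to ``amplicon_length`` and the count is
    ``len(cut_positions) + 1``.
    """
    if amplicon_length <= 0:
        raise MarkerError(f"non-positive amplicon length {amplicon_length}")
    cuts = list(cut_positions)
    if any(not (0 < c < amplicon_length) for c in cuts):
        raise MarkerError(
            f"cut positions {cuts} out of range for amplicon of {amplicon_length} bp"
        )
    if sorted(set(cuts)) != cuts:
        raise MarkerError(f"cut positions must be strictly increasing, got {cuts}")
    bounds = [0, *cuts, amplicon_length]
    return FragmentPattern(b - a for a, b in zip(bounds, bounds[1:]))


@dataclass
class AlleleDef:
    """One allele/haplotype: an amplicon with an optional restriction map.

    Exactly one of (``cut_positions`` with ``amplicon_length``) or
    ``fragments`` defines the observable pattern; haplotypes known only from
    gained/lost restriction sites carry a ``sites`` descriptor and no pattern.
    """

    label: str
    amplicon_length: int | None = None
    cut_positions: list[int] | None = None
    fragments: FragmentPattern | None = None
    sites: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.cut_positions is not None:
            if self.amplicon_length is None:
                raise MarkerError(
                    f"allele {self.label}: cut_positions without amplicon_length"
                )
            derived = digest(self.amplicon_length, self.cut_positions)
            if self.fragments is not None and self.fragments != derived:
                raise MarkerError(
                    f"allele {self.label}: given fragments {self.fragments} "
                    f"inconsistent with cut positions (derived {derived})"
                )
            self.fragments = derived
        if self.fragments is not None and self.amplicon_length is None:
            self.amplicon_length = self.fragments.total

    @property
    def pattern(self) -> FragmentPattern | None:
        """Observable fragment pattern, or None for site-descriptor haplotypes."""
        return self.fragments


@dataclass
class MarkerDef:
    """A marker: inheritance mode, allele registry, and diagnostic table."""

    name: str
    inheritance: str  # "nuclear" or "mito"
    enzymes: list[str] = field(default_factory=list)
    alleles: dict[str, AlleleDef] = field(default_factory=dict)
    diagnostic_map: dict[str, str] = field(default_factory=dict)
    diagnostic_level: str = "not"
    tolerance_bp: int = 4
    open_registry: bool = False
    detection_floor: int = DEFAULT_DETECTION_FLOOR
    size_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.inheritance not in ("nuclear", "mito"):
            raise MarkerError(
                f"marker {self.name}: inheritance must be 'nuclear' or 'mito'"
            )
        for key in self.diagnostic_map:
            if key not in self.alleles:
                raise MarkerError(
                    f"marker {self.name}: diagnostic_map key {key!r} "
                    "not in allele registry"
                )

    def add_allele(self, allele: AlleleDef) -> None:
        if allele.label in self.alleles:
            raise MarkerError(
                f"marker {self.name}: duplicate allele label {allele.label!r}"
            )
        self.alleles[allele.label] = allele

    def match(
        self,
        observed: FragmentPattern,
        tolerance_bp: int | None = None,
        auto_register: bool = False,
    ) -> str:
        return match_pattern(observed, self, tolerance_bp, auto_register)


def match_pattern(
    observed: FragmentPattern,
    marker: MarkerDef,
    tolerance_bp: int | None = None,
    auto_register: bool = False,
) -> str:
    """Resolve an observed fragment pattern to a registered allele label.

    Returns the unique registered allele whose pattern matches ``observed``
    within ``tolerance_bp`` (marker default when None), or ``"unrecognized"``.
    With ``auto_register=True`` an unrecognized pattern is added to the
    registry as a new haplotype named after its fragments (single-fragment
    patterns, e.g. mac-1 size alleles, are named by their size alone) and that
    new label is returned.

    Raises
    ------
    MarkerError : empty observed pattern.
    AmbiguousPatternError : two registered alleles both match, naming both.
    """
    if observed is None or len(observed) == 0:
        raise MarkerError("empty observed pattern")
    tol = marker.tolerance_bp if tolerance_bp is None else tolerance_bp
    if tol < 0:
        raise MarkerError("tolerance_bp must be >= 0")
    hits = [
        a.label
        for a in marker.alleles.values()
        if a.pattern is not None and observed.matches(a.pattern, tol)
    ]
    if len(hits) > 1:
        raise AmbiguousPatternError(
            f"marker {marker.name}: pattern {observed.render()} matches "
            f"multiple alleles: {', '.join(hits)}"
        )
    if len(hits) == 1:
        return hits[0]
    if auto_register:
        if len(observed) == 1:
            label = str(observed.fragments[0])
        else:
            label = observed.render("+")
        marker.add_allele(AlleleDef(label=label, fragments=observed))
        return label
    return "unrecognized"


def _parse_allele(marker_name: str, raw: Mapping) -> AlleleDef:
    try:
        label = str(raw["label"])
    except KeyError as exc:
        raise MarkerError(f"marker {marker_name}: allele without label: {raw}") from exc
    fragments = raw.get("fragments")
    return AlleleDef(
        label=label,
        amplicon_length=raw.get("amplicon_length"),
        cut_positions=raw.get("cut_positions"),
        fragments=FragmentPattern(fragments) if fragments is not None else None,
        sites=raw.get("sites"),
    )


def load_marker_definitions(source=None) -> list[MarkerDef]:
    """Load marker definitions from a YAML file (packaged default if None).

    The packaged default ships the five-locus registry: Me15-16 (180/168/126 bp
    alleles, AciI cut at 77 bp in galloprovincialis only), ITS HhaI patterns,
    COI XbaI (233 bp, cut at 134 in chilensis), the four described 16S
    haplotypes plus the two novel site-descriptor haplotypes, and the open
    mac-1 size registry (164-494 bp).
    """
    if source is None:
        ref = importlib.resources.files("mytilus_id") / "data" / "markers.yaml"
        text = ref.read_text(encoding="utf-8")
    elif isinstance(source, Mapping):
        return _markers_from_mapping(source)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        # YAML errors carry line/column marks; surface them verbatim.
        raise MarkerError(f"malformed marker definition file: {exc}") from exc
    if not isinstance(doc, Mapping) or "markers" not in doc:
        raise MarkerError("marker definition file must contain a 'markers' list")
    return _markers_from_mapping(doc)


def _markers_from_mapping(doc: Mapping) -> list[MarkerDef]:
    markers: list[MarkerDef] = []
    for raw in doc["markers"]:
        size_range = raw.get("size_range")
        marker = MarkerDef(
            name=str(raw["name"]),
            inheritance=raw.get("inheritance", "nuclear"),
            enzymes=list(raw.get("enzymes", [])),
            diagnostic_level=raw.get("diagnostic_level", "not"),
            tolerance_bp=int(raw.get("tolerance_bp", 4)),
            open_registry=bool(raw.get("open_registry", False)),
            size_range=tuple(size_range) if size_range else None,
        )
        for raw_allele in raw.get("alleles", []):
            marker.add_allele(_parse_allele(marker.name, raw_allele))
        marker.diagnostic_map = dict(raw.get("diagnostic_map") or {})
        MarkerDef.__post_init__(marker)  # re-validate diagnostic_map keys
        markers.append(marker)
    names = [m.name for m in markers]
    if len(set(names)) != len(names):
        raise MarkerError(f"duplicate marker names in definition file: {names}")
    return markers


def marker_registry(source=None) -> dict[str, MarkerDef]:
    """Name-keyed convenience wrapper around :func:`load_marker_definitions`."""
    return {m.name: m for m in load_marker_definitions(source)}
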