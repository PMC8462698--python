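"""Domain types for the allele-replacement panel.

The experimental unit is a strain: either a wild-type purebred of the
recipient or donor species, or a transgenic carrying donor-species alleles
at a subset of the panel's loci. A strain's swap state is a bit-vector
aligned to the panel's locus list (0 = recipient allele, 1 = donor allele).
Wild-type purebreds are *not* encoded as bit-vectors: the donor wild type
differs from the recipient genome-wide, so it is not the all-ones genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

__all__ = [
    "PanelError",
    "SchemaError",
    "InvariantError",
    "ConfigError",
    "InsufficientDataError",
    "FUNCTIONAL_CLASSES",
    "RECIPIENT_WT",
    "DONOR_WT",
    "WT_LABELS",
    "LAWN",
    "Locus",
    "Genotype",
    "StrainRecord",
    "GrowthMeasurement",
    "Timecourse",
    "ViabilityMeasurement",
    "AnalysisConfig",
]


class PanelError(Exception):
    """Base class for all package errors."""


class SchemaError(PanelError):
    """A table does not match the expected column layout."""


class InvariantError(PanelError):
    """A record violates a stated domain invariant.

    ``row`` carries the 0-based data-row index when the violation was
    detected while parsing a table, so the offending line can be located.
    """

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class ConfigError(PanelError):
    """An analysis or generator configuration is invalid."""


class InsufficientDataError(PanelError):
    """Too few observations for the requested computation."""


#: Declared vocabulary for locus functional classes.
FUNCTIONAL_CLASSES = frozenset(
    {"mitotic", "transcription-translation", "other"}
)

#: Reserved genotype tokens for wild-type purebreds.
RECIPIENT_WT = "recipient_wt"
DONOR_WT = "donor_wt"
WT_LABELS = (RECIPIENT_WT, DONOR_WT)

#: Token used in count fields for uncountably dense spots.
LAWN = "LAWN"


@dataclass(frozen=True)
class Locus:
    """A swapped gene, with its functional annotation."""

    name: str
    functional_class: str = "other"

    def __post_init__(self):
        if self.functional_class not in FUNCTIONAL_CLASSES:
            raise InvariantError(
                f"functional_class {self.functional_class!r} not in "
                f"{sorted(FUNCTIONAL_CLASSES)}"
            )


@dataclass(frozen=True)
class Genotype:
    """Ordered swap state over the panel's loci; 1 = donor allele."""

    bits: tuple[int, ...]

    def __post_init__(self):
        if not all(b in (0, 1) for b in self.bits):
            raise InvariantError(f"genotype bits must be 0/1, got {self.bits}")
        object.__setattr__(self, "bits", tuple(int(b) for b in self.bits))

    @classmethod
    def from_string(cls, s: str) -> "Genotype":
        if not s or any(c not in "01" for c in s):
            raise InvariantError(f"malformed genotype string {s!r}")
        return cls(tuple(int(c) for c in s))

    def __str__(self) -> str:
        return "".join(str(b) for b in self.bits)

    def __len__(self) -> int:
        return len(self.bits)

    @property
    def n_swaps(self) -> int:
        return sum(self.bits)

    def differing_loci(self, other: "Genotype") -> tuple[int, ...]:
        """Indices at which two genotypes disagree."""
        if len(other) != len(self):
            raise InvariantError("genotype lengths differ")
        return tuple(i for i, (a, b) in enumerate(zip(self.bits, other.bits)) if a != b)


GenotypeLike = Union[Genotype, str]


def parse_genotype_token(token: str, n_loci: int | None = None) -> GenotypeLike:
    """Parse a genotype table cell: a bit-string or a wild-type token."""
    token = token.strip()
    if token in WT_LABELS:
        return token
    g = Genotype.from_string(token)
    if n_loci is not None and len(g) != n_loci:
        raise InvariantError(
            f"genotype {token!r} has length {len(g)}, panel has {n_loci} loci"
        )
    return g


@dataclass(frozen=True)
class StrainRecord:
    """A strain of the panel: transgenic (bit-vector) or wild-type purebred."""

    strain_id: str
    genotype: Genotype | None = None
    species_label: str | None = None
    description: str = ""

    def __post_init__(self):
        if (self.genotype is None) == (self.species_label is None):
            raise InvariantError(
                f"strain {self.strain_id!r}: exactly one of genotype / "
                "species_label must be set"
            )
        if self.species_label is not None and self.species_label not in WT_LABELS:
            raise InvariantError(
                f"strain {self.strain_id!r}: species_label must be one of "
                f"{WT_LABELS}, got {self.species_label!r}"
            )

    @property
    def genotype_token(self) -> str:
        return self.species_label if self.species_label else str(self.genotype)


@dataclass(frozen=True)
class GrowthMeasurement:
    """One replicate culture's endpoint optical densities."""

    strain_id: str
    temperature: float  # degrees C
    replicate_id: str
    day_id: str
    od_initial: float  # OD600, dimensionless
    od_final: float
    duration: float  # hours

    def __post_init__(self):
        if self.od_initial < 0:
            raise InvariantError(
                f"od_initial must be >= 0, got {self.od_initial}"
            )
        if self.duration <= 0:
            raise InvariantError(f"duration must be > 0, got {self.duration}")


@dataclass(frozen=True)
class Timecourse:
    """One replicate culture's OD series over a multi-day incubation."""

    strain_id: str
    temperature: float
    replicate_id: str
    times: tuple[float, ...]  # days
    ods: tuple[float, ...]

    def __post_init__(self):
        if len(self.times) != len(self.ods):
            raise InvariantError("times and ods must have equal length")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise InvariantError("times must be strictly increasing")
        if self.times and self.times[0] != 0:
            raise InvariantError("first timepoint must be day 0")


Count = Union[int, str]  # non-negative int or the LAWN token


@dataclass(frozen=True)
class ViabilityMeasurement:
    """One replicate culture's spotting dilution series."""

    strain_id: str
    temperature: float
    replicate_id: str
    spot_volume: float  # mL per spot
    dilution_factors: tuple[float, ...]  # e.g. 1e-1 ... 1e-5, decreasing
    spot_counts: tuple[tuple[Count, ...], ...]  # per dilution, technical reps
    od_end: float  # turbidity at sampling

    def __post_init__(self):
        if any(
            b >= a
            for a, b in zip(self.dilution_factors, self.dilution_factors[1:])
        ):
            raise InvariantError("dilution_factors must be strictly decreasing")
        if self.od_end <= 0:
            raise InvariantError(f"od_end must be > 0, got {self.od_end}")
        if len(self.spot_counts) != len(self.dilution_factors):
            raise InvariantError("one count tuple required per dilution")
        for counts in self.spot_counts:
            for c in counts:
                if c == LAWN:
                    continue
                if not isinstance(c, (int,)) or c < 0:
                    raise InvariantError(
                        f"counts must be non-negative integers or {LAWN!r}, "
                        f"got {c!r}"
                    )


def _default_sidedness() -> dict[str, str]:
    # One-tailed at the stress temperatures (the direction of the divergence
    # is the hypothesis), two-tailed at the 28 C control.
    return {
        "growth_39": "greater",
        "growth_28": "two-sided",
        "growth_4": "less",
        "viability": "greater",
    }


#: Documented default seed used when a config omits rng_seed.
DEFAULT_SEED = 2021


@dataclass
class AnalysisConfig:
    """Panel-wide analysis settings: locus order, references, inference knobs."""

    loci: tuple[Locus, ...]
    path_order: tuple[str, ...]  # stacking sequence, prefix of the locus list
    recipient_wt_id: str = RECIPIENT_WT
    donor_wt_id: str = DONOR_WT
    transgenic_id: str | None = None  # all-swaps strain; derived if None
    temperatures: tuple[float, ...] = (39.0,)
    n_boot: int = 10_000
    alpha: float = 0.05
    ci_level: float = 0.95
    rng_seed: int = DEFAULT_SEED
    sidedness: Mapping[str, str] = field(default_factory=_default_sidedness)

    def __post_init__(self):
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise ConfigError("locus names must be unique within a panel")
        unknown = [n for n in self.path_order if n not in names]
        if unknown:
            raise ConfigError(f"path order references unknown loci: {unknown}")
        if len(set(self.path_order)) != len(self.path_order):
            raise ConfigError("path order must not repeat loci")
        if self.n_boot < 1:
            raise ConfigError(f"n_boot must be >= 1, got {self.n_boot}")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.ci_level < 1:
            raise ConfigError(f"ci_level must be in (0, 1), got {self.ci_level}")

    @property
    def locus_names(self) -> tuple[str, ...]:
        return tuple(l.name for l in self.loci)
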