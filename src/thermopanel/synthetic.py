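"""Ground-truth-known synthetic panels emulating the study design.

The generator produces the three tidy measurement tables the pipeline
consumes — endpoint growth efficiencies, multi-day OD timecourses, and
spotting-assay dilution series — for a combinatorial allele-swap strain
panel, under a configurable genotype-phenotype map. Interaction regimes
cover the phenomena the analysis must detect: pure additivity, uniform
magnitude damping (diminishing joint effects), masking of one locus by
others, and sign reversal.

The defaults are a stated world, chosen once: baseline efficiency
0.4 dOD and per-locus effects of 0.15 dOD keep every single swap below a
1.4-fold benefit while clearing its own detection threshold at the default
replicate noise (0.05 dOD, 8 replicates); the donor wild type saturates at
2.0 dOD. See docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import GROWTH_COLUMNS, TIMECOURSE_COLUMNS, VIABILITY_COLUMNS
from .model import (
    DONOR_WT,
    LAWN,
    RECIPIENT_WT,
    ConfigError,
    Genotype,
    Locus,
    StrainRecord,
)

__all__ = [
    "Additive",
    "MagnitudeDamping",
    "Masking",
    "SignReversal",
    "SyntheticConfig",
    "default_loci",
    "default_path_order",
    "panel_strains",
    "true_phenotype",
    "strain_truth",
    "generate_growth_panel",
    "generate_timecourses",
    "generate_viability",
    "damping_factor_for_joint_fraction",
    "DAY_GRID",
]

#: Sampling days for cold timecourses (supplementary grid, incl. day 6).
DAY_GRID = (0.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0, 11.0)


@dataclass(frozen=True)
class Additive:
    """Locus effects sum independently."""


@dataclass(frozen=True)
class MagnitudeDamping:
    """Each added locus contributes its effect scaled by factor**(rank-1).

    Rank is the locus's position among the genotype's 1-bits in panel locus
    order, so a fully stacked genotype realizes a joint effect strictly
    below the additive sum for factor < 1.
    """

    factor: float = 0.85


@dataclass(frozen=True)
class Masking:
    """The target locus contributes nothing when any masker allele is present."""

    target: str = "SCC2"
    maskers: tuple[str, ...] = ("DYN1", "MYO1")


@dataclass(frozen=True)
class SignReversal:
    """The target locus's effect is negated when any context allele is present."""

    target: str = "SCC2"
    context: tuple[str, ...] = ("DYN1", "MYO1")


Regime = Additive | MagnitudeDamping | Masking | SignReversal


def default_loci() -> tuple[Locus, ...]:
    """The eight-locus panel: six mitotic genes, two in gene expression."""
    mitotic = ("DYN1", "MYO1", "SCC2", "APC1", "CEP3", "ESP1")
    expression = ("TAF2", "AFG2")
    return tuple(
        [Locus(n, "mitotic") for n in mitotic]
        + [Locus(n, "transcription-translation") for n in expression]
    )


def default_path_order() -> tuple[str, ...]:
    """Stacking order for the combinatorial series (DYN1 first)."""
    return tuple(l.name for l in default_loci())


@dataclass
class SyntheticConfig:
    """Generative ground truth for a synthetic panel."""

    loci: tuple[Locus, ...] = field(default_factory=default_loci)
    baseline_efficiency: float = 0.4  # dOD of the all-zeros genotype
    donor_wt_efficiency: float = 2.0  # dOD of the donor purebred
    per_locus_effects: Mapping[str, float] | float = 0.15  # dOD each
    interaction: Regime = field(default_factory=Additive)
    noise_sd: float = 0.05  # replicate dOD standard deviation
    replicates_per_day: int = 8
    n_days: int = 1
    day_batch_sd: float = 0.0  # optional additive day-batch shift
    od_initial: float = 0.1
    duration_h: float = 24.0
    # timecourse truth: per-strain (K, R, x0); required by generate_timecourses
    logistic_truth: Mapping[str, tuple[float, float, float]] | None = None
    timecourse_noise_sd: float = 0.03
    day_grid: tuple[float, ...] = DAY_GRID
    # viability truth: per-strain CFU/mL; required by generate_viability
    cfu_truth: Mapping[str, float] | None = None
    spot_volume: float = 0.003  # mL (3 uL spots)
    dilution_factors: tuple[float, ...] = (1e-1, 1e-2, 1e-3, 1e-4, 1e-5)
    lawn_threshold: int = 100  # colonies per spot beyond which a spot is a lawn
    n_tech_reps: int = 2
    seed: int = 2021

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not 2 <= self.replicates_per_day <= 8:
            raise ConfigError(
                "replicates_per_day must lie in the emulated design range "
                f"2-8, got {self.replicates_per_day}"
            )
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise ConfigError("locus names must be unique")

    @property
    def locus_names(self) -> tuple[str, ...]:
        return tuple(l.name for l in self.loci)

    def effect_of(self, locus_name: str) -> float:
        if isinstance(self.per_locus_effects, Mapping):
            try:
                return float(self.per_locus_effects[locus_name])
            except KeyError:
                raise ConfigError(f"no effect configured for locus {locus_name!r}")
        return float(self.per_locus_effects)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def true_phenotype(config: SyntheticConfig, genotype: Genotype) -> float:
    """Noise-free growth efficiency of a transgenic genotype."""
    names = config.locus_names
    if len(genotype) != len(names):
        raise ConfigError(
            f"genotype length {len(genotype)} does not match panel size {len(names)}"
        )
    present = [n for n, b in zip(names, genotype.bits) if b]
    regime = config.interaction
    total = config.baseline_efficiency
    if isinstance(regime, Additive):
        for n in present:
            total += config.effect_of(n)
    elif isinstance(regime, MagnitudeDamping):
        for rank, n in enumerate(present):
            total += config.effect_of(n) * regime.factor**rank
    elif isinstance(regime, Masking):
        masked = regime.target in present and any(
            m in present for m in regime.maskers
        )
        for n in present:
            if n == regime.target and masked:
                continue
            total += config.effect_of(n)
    elif isinstance(regime, SignReversal):
        flipped = regime.target in present and any(
            c in present for c in regime.context
        )
        for n in present:
            e = config.effect_of(n)
            total += -e if (n == regime.target and flipped) else e
    else:
        raise ConfigError(f"unknown interaction regime {regime!r}")
    return total


def strain_truth(config: SyntheticConfig, strain: StrainRecord) -> float:
    """True efficiency of any panel strain, wild-type purebreds included."""
    if strain.species_label == RECIPIENT_WT:
        return config.baseline_efficiency
    if strain.species_label == DONOR_WT:
        return config.donor_wt_efficiency
    return true_phenotype(config, strain.genotype)


def panel_strains(
    config: SyntheticConfig,
    path_order: Sequence[str] | None = None,
    include_singles: bool = True,
    include_path: bool = True,
) -> list[StrainRecord]:
    """The emulated strain panel: purebreds, single swaps, stacking series.

    Strain ids are genotype-derived (``swap_<bits>``), so the first strain
    of the stacking series *is* the corresponding single-swap strain, as in
    the real panel.
    """
    names = config.locus_names
    path_order = tuple(path_order or names)
    unknown = [n for n in path_order if n not in names]
    if unknown:
        raise ConfigError(f"path order references unknown loci: {unknown}")
    strains: dict[str, StrainRecord] = {}
    for label, desc in (
        (RECIPIENT_WT, "recipient-species purebred"),
        (DONOR_WT, "donor-species purebred"),
    ):
        strains[label] = StrainRecord(label, species_label=label, description=desc)

    def add(bits: tuple[int, ...], desc: str):
        g = Genotype(bits)
        sid = f"swap_{g}"
        if sid not in strains:
            strains[sid] = StrainRecord(sid, genotype=g, description=desc)

    if include_singles:
        for i, n in enumerate(names):
            bits = tuple(1 if j == i else 0 for j in range(len(names)))
            add(bits, f"single swap {n}")
    if include_path:
        current = [0] * len(names)
        for k, n in enumerate(path_order, start=1):
            current[names.index(n)] = 1
            add(tuple(current), f"stack of {k}: {'+'.join(path_order[:k])}")
    return list(strains.values())


def strain_id_for(genotype_bits: Sequence[int]) -> str:
    return "swap_" + "".join(str(int(b)) for b in genotype_bits)


def generate_growth_panel(
    config: SyntheticConfig,
    strains: Sequence[StrainRecord],
    temperature: float = 39.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Replicate endpoint growth table for the given strains.

    Each strain contributes ``n_days`` batches of ``replicates_per_day``
    cultures; efficiency = true phenotype + N(0, noise_sd) (+ an optional
    per-day batch shift); cultures start at a fixed od_initial.
    """
    rng = rng if rng is not None else config.rng()
    rows = []
    for strain in strains:
        truth = strain_truth(config, strain)
        for day in range(1, config.n_days + 1):
            batch = (
                rng.normal(0.0, config.day_batch_sd)
                if config.day_batch_sd > 0
                else 0.0
            )
            for rep in range(1, config.replicates_per_day + 1):
                eff = truth + batch + (
                    rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0
                )
                rows.append(
                    {
                        "strain_id": strain.strain_id,
                        "genotype": strain.genotype_token,
                        "temperature_C": temperature,
                        "replicate": f"d{day}r{rep}",
                        "day": f"d{day}",
                        "od_initial": config.od_initial,
                        "od_final": config.od_initial + eff,
                        "duration_h": config.duration_h,
                    }
                )
    return pd.DataFrame(rows, columns=list(GROWTH_COLUMNS))


def _logistic(t: np.ndarray, K: float, R: float, x0: float) -> np.ndarray:
    return K / (1.0 + np.exp(-R * (t - x0)))


def generate_timecourses(
    config: SyntheticConfig,
    strains: Sequence[StrainRecord],
    temperature: float = 4.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Logistic OD timecourses on the configured day grid, with noise.

    ODs are clamped at zero from below. Requires ``logistic_truth`` to map
    every strain id to its (K, R, x0).
    """
    if config.logistic_truth is None:
        raise ConfigError("generate_timecourses requires logistic_truth")
    rng = rng if rng is not None else config.rng()
    t = np.asarray(config.day_grid, dtype=float)
    rows = []
    for strain in strains:
        try:
            K, R, x0 = config.logistic_truth[strain.strain_id]
        except KeyError:
            raise ConfigError(
                f"missing logistic_truth for strain {strain.strain_id!r}"
            )
        for day in range(1, config.n_days + 1):
            for rep in range(1, config.replicates_per_day + 1):
                ods = _logistic(t, K, R, x0)
                if config.timecourse_noise_sd > 0:
                    ods = ods + rng.normal(0.0, config.timecourse_noise_sd, t.size)
                ods = np.maximum(ods, 0.0)
                rid = f"d{day}r{rep}"
                for ti, od in zip(t, ods):
                    rows.append(
                        {
                            "strain_id": strain.strain_id,
                            "temperature_C": temperature,
                            "replicate": rid,
                            "day": ti,
                            "od": od,
                        }
                    )
    return pd.DataFrame(rows, columns=list(TIMECOURSE_COLUMNS))


def generate_viability(
    config: SyntheticConfig,
    strains: Sequence[StrainRecord],
    temperature: float = 39.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Poisson colony counts across a 1:10 dilution spotting series.

    Expected colonies per spot at dilution d are cfu_truth * spot_volume * d;
    counts at or above lawn_threshold are emitted as the LAWN token. The
    end-point turbidity is tied loosely to log10 CFU so normalized viability
    stays on a plausible scale.
    """
    if config.cfu_truth is None:
        raise ConfigError("generate_viability requires cfu_truth")
    rng = rng if rng is not None else config.rng()
    rows = []
    for strain in strains:
        try:
            cfu = float(config.cfu_truth[strain.strain_id])
        except KeyError:
            raise ConfigError(f"missing cfu_truth for strain {strain.strain_id!r}")
        for rep in range(1, config.replicates_per_day + 1):
            od_end = max(0.2, 0.25 * np.log10(max(cfu, 10.0)))
            for d in config.dilution_factors:
                lam = cfu * config.spot_volume * d
                for tech in range(1, config.n_tech_reps + 1):
                    count = int(rng.poisson(lam)) if lam > 0 else 0
                    rows.append(
                        {
                            "strain_id": strain.strain_id,
                            "temperature_C": temperature,
                            "replicate": f"r{rep}",
                            "dilution_exponent": round(np.log10(d)),
                            "tech_rep": tech,
                            "colonies_or_LAWN": LAWN
                            if count >= config.lawn_threshold
                            else count,
                            "od_end": od_end,
                            "spot_volume_ml": config.spot_volume,
                        }
                    )
    return pd.DataFrame(rows, columns=list(VIABILITY_COLUMNS))


def damping_factor_for_joint_fraction(n_loci: int, fraction: float) -> float:
    """Damping factor f with sum_{k=0}^{n-1} f^k = fraction * n.

    Under uniform per-locus effects this places the fully stacked joint
    effect at the given fraction of the additive sum.
    """
    if not 1.0 / n_loci < fraction <= 1.0:
        raise ConfigError(
            f"attainable joint fractions lie in ({1.0 / n_loci:.3f}, 1]"
        )
    if fraction == 1.0:
        return 1.0
    return brentq(
        lambda f: sum(f**k for k in range(n_loci)) - fraction * n_loci,
        1e-9,
        1.0 - 1e-12,
    )


def with_interaction(config: SyntheticConfig, regime: Regime) -> SyntheticConfig:
    """Copy of a config under a different interaction regime."""
    return replace(config, interaction=regime)
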