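"""Operating-characteristic studies of the epistasis machinery.

Each study repeatedly generates a ground-truth-known panel with the real
generator, runs the real estimator path (shared-reference bootstrap,
additive expectation, epistasis test or interaction classifier), and
reports the empirical rejection/detection rate. These are the package's
own power analyses: type-I error under pure additivity, power against
uniform magnitude damping, and detection of a masked locus.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .epistasis import (
    additive_expectation,
    classify_locus_interaction,
    epistasis_test,
    panel_bootstrap_effects,
)
from .model import RECIPIENT_WT, Genotype, StrainRecord
from .synthetic import (
    Additive,
    MagnitudeDamping,
    Masking,
    SyntheticConfig,
    damping_factor_for_joint_fraction,
    generate_growth_panel,
    strain_id_for,
)

__all__ = [
    "epistasis_strains",
    "null_calibration",
    "damping_power",
    "masking_detection",
]


def epistasis_strains(config: SyntheticConfig) -> list[StrainRecord]:
    """Minimal strain set for a joint-vs-additive test: wt, singles, joint."""
    L = len(config.loci)
    strains = [StrainRecord(RECIPIENT_WT, species_label=RECIPIENT_WT)]
    for i in range(L):
        bits = tuple(1 if j == i else 0 for j in range(L))
        strains.append(StrainRecord(strain_id_for(bits), genotype=Genotype(bits)))
    joint = (1,) * L
    strains.append(StrainRecord(strain_id_for(joint), genotype=Genotype(joint)))
    return strains


def _one_epistasis_panel(
    config: SyntheticConfig,
    n_boot: int,
    alpha: float,
    rng: np.random.Generator,
    temperature: float = 39.0,
):
    strains = epistasis_strains(config)
    table = generate_growth_panel(config, strains, temperature, rng=rng)
    L = len(config.loci)
    singles = [s.strain_id for s in strains[1 : 1 + L]]
    joint = strains[-1].strain_id
    est = panel_bootstrap_effects(
        table, singles + [joint], RECIPIENT_WT, temperature, n_boot, rng
    )
    expected = additive_expectation([est[s] for s in singles])
    return epistasis_test(est[joint], expected, alternative="less", alpha=alpha)


@dataclass
class RateResult:
    """Empirical event rate over seeded replicate panels."""

    n_panels: int
    n_events: int

    @property
    def rate(self) -> float:
        return self.n_events / self.n_panels


def null_calibration(
    n_panels: int = 1000,
    noise_sd: float = 0.05,
    replicates: int = 8,
    n_boot: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
    base_config: SyntheticConfig | None = None,
) -> RateResult:
    """Type-I error of the epistasis test on purely additive panels."""
    base = base_config or SyntheticConfig()
    config = replace(
        base,
        interaction=Additive(),
        noise_sd=noise_sd,
        replicates_per_day=replicates,
        n_days=1,
    )
    rng = np.random.default_rng(seed)
    hits = sum(
        _one_epistasis_panel(config, n_boot, alpha, rng).p_value <= alpha
        for _ in range(n_panels)
    )
    return RateResult(n_panels, hits)


def damping_power(
    n_panels: int = 200,
    joint_fraction: float = 0.6,
    noise_sd: float = 0.05,
    replicates: int = 8,
    n_boot: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
    base_config: SyntheticConfig | None = None,
) -> RateResult:
    """Power to label negative magnitude epistasis under uniform damping.

    The damping factor is solved so the fully stacked joint effect sits at
    ``joint_fraction`` of the additive sum.
    """
    base = base_config or SyntheticConfig()
    factor = damping_factor_for_joint_fraction(len(base.loci), joint_fraction)
    config = replace(
        base,
        interaction=MagnitudeDamping(factor),
        noise_sd=noise_sd,
        replicates_per_day=replicates,
        n_days=1,
    )
    rng = np.random.default_rng(seed)
    hits = sum(
        _one_epistasis_panel(config, n_boot, alpha, rng).label
        == "negative_magnitude"
        for _ in range(n_panels)
    )
    return RateResult(n_panels, hits)


def masking_detection(
    n_panels: int = 200,
    noise_over_effect: float = 0.25,
    replicates: int = 8,
    n_boot: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
    base_config: SyntheticConfig | None = None,
) -> RateResult:
    """Detection rate of a masked locus by the interaction classifier.

    The target locus is swapped alone (detectable) and on top of a
    background carrying its maskers (truth: zero contribution). Detection
    means the classifier returns ``masking``.
    """
    base = base_config or SyntheticConfig()
    regime = Masking()
    effect = base.effect_of(regime.target)
    config = replace(
        base,
        interaction=regime,
        noise_sd=noise_over_effect * effect,
        replicates_per_day=replicates,
        n_days=1,
    )
    names = config.locus_names
    L = len(names)
    target_i = names.index(regime.target)
    masker_is = [names.index(m) for m in regime.maskers]

    def strain(bits):
        return StrainRecord(strain_id_for(bits), genotype=Genotype(bits))

    alone_bits = tuple(1 if j == target_i else 0 for j in range(L))
    bg_bits = tuple(1 if j in masker_is else 0 for j in range(L))
    combo_bits = tuple(
        1 if (j in masker_is or j == target_i) else 0 for j in range(L)
    )
    strains = [
        StrainRecord(RECIPIENT_WT, species_label=RECIPIENT_WT),
        strain(alone_bits),
        strain(bg_bits),
        strain(combo_bits),
    ]
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_panels):
        table = generate_growth_panel(config, strains, 39.0, rng=rng)
        alone = panel_bootstrap_effects(
            table, [strain_id_for(alone_bits)], RECIPIENT_WT, 39.0, n_boot, rng
        )[strain_id_for(alone_bits)]
        combo = panel_bootstrap_effects(
            table,
            [strain_id_for(combo_bits)],
            strain_id_for(bg_bits),
            39.0,
            n_boot,
            rng,
        )[strain_id_for(combo_bits)]
        label = classify_locus_interaction(alone, combo, alpha=alpha)
        hits += label == "masking"
    return RateResult(n_panels, hits)
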