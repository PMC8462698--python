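"""End-to-end orchestration: simulate -> phenotypes -> effects -> epistasis -> report.

A run consumes one seed; each stage draws from its own deterministically
spawned substream, so skipping or reordering stages never perturbs another
stage's numbers. Every run writes a manifest (config snapshot, input
checksums, seed, stages, outputs, version) sufficient to reproduce it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .effects import (
    fold_change,
    pairwise_comparisons,
    path_effects,
    recapitulation_fraction,
)
from .epistasis import (
    additive_expectation,
    classify_locus_interaction,
    epistasis_test,
    panel_bootstrap_effects,
    trend_binomial_test,
)
from .io import write_results
from .model import AnalysisConfig, ConfigError, PanelError
from .phenotypes import with_efficiency
from .synthetic import (
    SyntheticConfig,
    generate_growth_panel,
    panel_strains,
    strain_id_for,
)

__all__ = ["RunManifest", "run_pipeline", "report_summary", "ALL_STAGES"]

ALL_STAGES = ("simulate", "growth", "effects", "epistasis", "report")

#: Fixed substream indices per stage (stage-order independent).
_STAGE_STREAM = {name: i for i, name in enumerate(ALL_STAGES)}


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    seed: int
    stages: list[str]
    config: dict
    input_checksums: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    version: str = __version__

    def write(self, path: Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    children = np.random.SeedSequence(seed).spawn(len(ALL_STAGES))
    return np.random.default_rng(children[_STAGE_STREAM[stage]])


def _config_snapshot(config: AnalysisConfig, synth: SyntheticConfig | None) -> dict:
    snap = {
        "loci": [l.name for l in config.loci],
        "path_order": list(config.path_order),
        "n_boot": config.n_boot,
        "alpha": config.alpha,
        "ci_level": config.ci_level,
        "rng_seed": config.rng_seed,
        "temperatures": list(config.temperatures),
        "sidedness": dict(config.sidedness),
    }
    if synth is not None:
        snap["synthetic"] = {
            "baseline_efficiency": synth.baseline_efficiency,
            "donor_wt_efficiency": synth.donor_wt_efficiency,
            "interaction": type(synth.interaction).__name__,
            "noise_sd": synth.noise_sd,
            "replicates_per_day": synth.replicates_per_day,
            "n_days": synth.n_days,
            "seed": synth.seed,
        }
    return snap


def _path_strain_ids(config: AnalysisConfig) -> list[str]:
    names = list(config.locus_names)
    ids = [config.recipient_wt_id]
    bits = [0] * len(names)
    for locus in config.path_order:
        bits[names.index(locus)] = 1
        ids.append(strain_id_for(bits))
    return ids


def run_pipeline(
    config: AnalysisConfig,
    out_dir,
    synth: SyntheticConfig | None = None,
    growth_table: pd.DataFrame | None = None,
    growth_path=None,
    stages: Sequence[str] = ALL_STAGES,
    seed: int | None = None,
    temperature: float | None = None,
) -> tuple[RunManifest, dict]:
    """Execute the requested stages in dependency order.

    Inputs are either a synthetic config (for the ``simulate`` stage) or an
    existing growth table / CSV path. Returns the manifest and a dict of
    in-memory stage results; tables are also written under ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = config.rng_seed if seed is None else int(seed)
    temperature = (
        config.temperatures[0] if temperature is None else float(temperature)
    )
    requested = set(stages)
    bad = requested - set(ALL_STAGES)
    if bad:
        raise ConfigError(f"unknown stage(s): {sorted(bad)}")
    stages = [s for s in ALL_STAGES if s in requested]
    manifest = RunManifest(
        seed=seed, stages=list(stages), config=_config_snapshot(config, synth)
    )
    results: dict = {}

    def record(name: str, path: Path):
        manifest.outputs[name] = str(path)

    try:
        if growth_path is not None:
            from .io import read_measurements

            manifest.input_checksums[str(growth_path)] = _sha256(growth_path)
            growth_table = read_measurements(growth_path, "growth").table
        if "simulate" in stages:
            if synth is None:
                raise ConfigError("simulate stage requires a synthetic config")
            strains = panel_strains(synth, path_order=config.path_order)
            growth_table = generate_growth_panel(
                synth, strains, temperature, rng=_stage_rng(seed, "simulate")
            )
            p = out_dir / "growth_table.csv"
            growth_table.to_csv(p, index=False)
            record("growth_table", p)
            results["growth_table"] = growth_table
        if growth_table is None and any(
            s in stages for s in ("growth", "effects", "epistasis")
        ):
            raise ConfigError("no growth table available for analysis stages")

        if "growth" in stages:
            eff = with_efficiency(growth_table)
            per_strain = (
                eff.groupby("strain_id")["efficiency"]
                .agg(["count", "mean", "std"])
                .reset_index()
                .rename(columns={"count": "n", "mean": "mean_efficiency",
                                 "std": "sd_efficiency"})
            )
            p = out_dir / "efficiency_by_strain.csv"
            write_results(per_strain, p)
            record("efficiency_by_strain", p)
            results["efficiency_by_strain"] = per_strain

        if "effects" in stages or "epistasis" in stages:
            rng = _stage_rng(seed, "effects")
            names = list(config.locus_names)
            singles = [
                strain_id_for([1 if j == i else 0 for j in range(len(names))])
                for i in range(len(names))
            ]
            transgenic = config.transgenic_id or strain_id_for([1] * len(names))
            focal = singles + [transgenic]
            estimates = panel_bootstrap_effects(
                growth_table,
                focal,
                config.recipient_wt_id,
                temperature,
                config.n_boot,
                rng,
                loci=names + [None],
                ci_level=config.ci_level,
            )
            results["single_effects"] = {
                n: estimates[s] for n, s in zip(names, singles)
            }
            results["joint_effect"] = estimates[transgenic]

        if "effects" in stages:
            path_ids = _path_strain_ids(config)
            steps = path_effects(
                growth_table, path_ids, temperature, loci=names
            )
            results["path_effects"] = steps
            p = out_dir / "path_effects.csv"
            write_results(steps, p)
            record("path_effects", p)

            single_rows = list(results["single_effects"].values())
            p = out_dir / "single_effects.csv"
            write_results(single_rows, p)
            record("single_effects", p)

            headline = {
                "temperature_C": temperature,
                "fold_change_transgenic_vs_recipient": fold_change(
                    growth_table, transgenic, config.recipient_wt_id, temperature
                ),
                "recapitulation_percent": recapitulation_fraction(
                    growth_table,
                    transgenic,
                    config.recipient_wt_id,
                    config.donor_wt_id,
                    temperature,
                ),
            }
            results["headline"] = headline
            # decreasing expected phenotype: one-sided tests point the right way
            comparisons = pairwise_comparisons(
                growth_table,
                [transgenic] + singles + [config.recipient_wt_id],
                temperature,
                sidedness=dict(config.sidedness).get("growth_39", "greater"),
            )
            results["comparisons"] = comparisons
            p = out_dir / "comparisons.csv"
            write_results(comparisons, p)
            record("comparisons", p)

        if "epistasis" in stages:
            expected = additive_expectation(
                list(results["single_effects"].values())
            )
            epi = epistasis_test(
                results["joint_effect"],
                expected,
                alternative="less",
                alpha=config.alpha,
            )
            results["epistasis"] = epi

            # per-locus background dependence: alone vs in-combination
            rng2 = _stage_rng(seed, "epistasis")
            path_ids = _path_strain_ids(config)
            combo = panel_bootstrap_effects(
                growth_table,
                path_ids[1:],
                config.recipient_wt_id,
                temperature,
                config.n_boot,
                rng2,
                ci_level=config.ci_level,
            )
            # step effects with bootstraps: X vs X-1
            labels = {}
            for i, locus in enumerate(config.path_order):
                prev_id, cur_id = path_ids[i], path_ids[i + 1]
                step = panel_bootstrap_effects(
                    growth_table,
                    [cur_id],
                    prev_id,
                    temperature,
                    config.n_boot,
                    rng2,
                    loci=[locus],
                    ci_level=config.ci_level,
                )[cur_id]
                alone = results["single_effects"][locus]
                labels[locus] = classify_locus_interaction(
                    alone, step, alpha=config.alpha, ci_level=config.ci_level
                )
            results["interaction_labels"] = labels

            path_with_boot = []
            for i, locus in enumerate(config.path_order):
                est = panel_bootstrap_effects(
                    growth_table,
                    [path_ids[i + 1]],
                    path_ids[i],
                    temperature,
                    config.n_boot,
                    rng2,
                    loci=[locus],
                    ci_level=config.ci_level,
                )[path_ids[i + 1]]
                path_with_boot.append(est)
            results["trend_test"] = trend_binomial_test(path_with_boot)

            epi_df = pd.DataFrame(
                [
                    {
                        "observed_joint": epi.observed_joint,
                        "expected_additive": epi.expected_additive,
                        "epsilon": epi.epsilon,
                        "p_value": epi.p_value,
                        "alternative": epi.alternative,
                        "label": epi.label,
                        "n_boot": epi.n_boot,
                    }
                ]
            )
            p = out_dir / "epistasis.csv"
            write_results(epi_df, p)
            record("epistasis", p)
            lab_df = pd.DataFrame(
                [{"locus": k, "label": v} for k, v in labels.items()]
            )
            p = out_dir / "interaction_labels.csv"
            write_results(lab_df, p)
            record("interaction_labels", p)

        if "report" in stages:
            text = report_summary(results)
            p = out_dir / "summary.md"
            p.write_text(text, encoding="utf-8")
            record("summary", p)
            results["summary"] = text
    except PanelError as err:
        raise type(err)(f"pipeline aborted: {err}") from err

    log = out_dir / "run.log"
    log.write_text(
        f"thermopanel {__version__}\nseed={seed}\nstages={','.join(stages)}\n"
        f"n_boot={config.n_boot} alpha={config.alpha} ci_level={config.ci_level}\n"
        f"loci={','.join(config.locus_names)}\npath={','.join(config.path_order)}\n",
        encoding="utf-8",
    )
    record("log", log)
    manifest.write(out_dir / "manifest.json")
    record("manifest", out_dir / "manifest.json")
    return manifest, results


def report_summary(results: Mapping) -> str:
    """Human-readable run summary mirroring the analysis's headline metrics."""
    lines = ["# Panel analysis summary", ""]
    if "headline" in results:
        h = results["headline"]
        lines += [
            f"Temperature: {h['temperature_C']} C",
            f"Fold change, transgenic vs recipient wild type: "
            f"{h['fold_change_transgenic_vs_recipient']:.3f}",
            f"Recapitulation of wild-type divergence: "
            f"{h['recapitulation_percent']:.1f}%",
            "",
        ]
    if "single_effects" in results:
        lines.append("Per-locus effects alone (dOD vs recipient wild type):")
        for locus, est in results["single_effects"].items():
            ci = est.ci or est.ci_from_boot()
            lines.append(
                f"  {locus}: {est.effect:+.4f} [{ci[0]:+.4f}, {ci[1]:+.4f}]"
            )
        lines.append("")
    if "path_effects" in results:
        lines.append("Per-step effects along the stacking path:")
        for est in results["path_effects"]:
            lines.append(f"  {est.locus}: {est.effect:+.4f}")
        lines.append("")
    if "epistasis" in results:
        e = results["epistasis"]
        lines += [
            "Joint-vs-additive epistasis:",
            f"  observed joint effect: {e.observed_joint:+.4f}",
            f"  additive expectation:  {e.expected_additive:+.4f}",
            f"  epsilon: {e.epsilon:+.4f} (p = {e.p_value:.4g}, "
            f"alternative = {e.alternative}, label = {e.label})",
            "",
        ]
    if "interaction_labels" in results:
        lines.append("Per-locus background dependence:")
        for locus, label in results["interaction_labels"].items():
            lines.append(f"  {locus}: {label}")
        lines.append("")
    if "trend_test" in results:
        t = results["trend_test"]
        lines.append(
            f"Path trend: {t.n_positive}/{t.n_steps} beneficial steps, "
            f"one-sided binomial p = {t.p_value:.4g}"
        )
        lines.append("")
    return "\n".join(lines)
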