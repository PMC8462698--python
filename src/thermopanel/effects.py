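"""Allele-effect estimation across backgrounds, and the panel's rank tests.

An allele's *marginal effect* is the difference in mean growth efficiency
between a focal strain and a reference strain, replicates pooled across
days. A *path* decomposes the fully stacked transgenic into per-step
effects along a stacking series (each step toggles exactly one locus).
Strain pairs are compared with Wilcoxon rank-sum tests; families of
comparisons are corrected with Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .model import (
    RECIPIENT_WT,
    WT_LABELS,
    Genotype,
    InsufficientDataError,
    PanelError,
    parse_genotype_token,
)
from .phenotypes import with_efficiency

__all__ = [
    "EffectEstimate",
    "ComparisonResult",
    "strain_efficiencies",
    "marginal_effect",
    "path_effects",
    "fold_change",
    "recapitulation_fraction",
    "rank_sum_test",
    "compare_strains",
    "pairwise_comparisons",
    "bh_adjust",
]


@dataclass
class EffectEstimate:
    """A locus's mean efficiency effect in a stated background."""

    locus: str | None
    background: str  # genotype bit-string or wild-type token of the pre-swap strain
    effect: float  # dOD: mean(focal) - mean(reference)
    n_focal: int
    n_ref: int
    focal_id: str = ""
    reference_id: str = ""
    boot: np.ndarray | None = field(default=None, repr=False)
    ci: tuple[float, float] | None = None

    def ci_from_boot(self, level: float = 0.95) -> tuple[float, float]:
        if self.boot is None:
            raise PanelError("no bootstrap distribution attached")
        a = 100 * (1 - level) / 2
        lo, hi = np.percentile(self.boot, [a, 100 - a])
        return float(lo), float(hi)


@dataclass
class ComparisonResult:
    """One Wilcoxon rank-sum comparison between two strains."""

    strain_a: str
    strain_b: str
    statistic: float
    p_value: float
    sidedness: str
    method: str = ""
    q_value: float | None = None
    low_n: bool = False  # fewer than 3 replicates in a group


def strain_efficiencies(
    table: pd.DataFrame, strain_id: str, temperature: float
) -> np.ndarray:
    """Replicate efficiencies for one strain at one temperature, all days pooled."""
    if "efficiency" not in table.columns:
        table = with_efficiency(table)
    sel = table[
        (table["strain_id"] == strain_id)
        & (table["temperature_C"] == temperature)
    ]
    if sel.empty:
        raise PanelError(
            f"no measurements for strain {strain_id!r} at {temperature} C"
        )
    # canonical value order: estimates become exactly row-order invariant
    return np.sort(sel["efficiency"].to_numpy(dtype=float))


def marginal_effect(
    table: pd.DataFrame,
    focal: str,
    reference: str,
    temperature: float,
    locus: str | None = None,
    background: str | None = None,
) -> EffectEstimate:
    """Mean efficiency of the focal strain minus that of the reference."""
    x = strain_efficiencies(table, focal, temperature)
    y = strain_efficiencies(table, reference, temperature)
    return EffectEstimate(
        locus=locus,
        background=background if background is not None else reference,
        effect=float(np.mean(x) - np.mean(y)),
        n_focal=x.size,
        n_ref=y.size,
        focal_id=focal,
        reference_id=reference,
    )


def _strain_genotypes(table: pd.DataFrame) -> dict[str, str]:
    if "genotype" not in table.columns:
        raise PanelError("table has no genotype column; cannot validate a path")
    out = {}
    for sid, grp in table.groupby("strain_id"):
        tokens = set(str(t) for t in grp["genotype"])
        if len(tokens) != 1:
            raise PanelError(f"strain {sid!r} has inconsistent genotype entries")
        out[str(sid)] = tokens.pop()
    return out


def path_effects(
    table: pd.DataFrame,
    path: Sequence[str],
    temperature: float,
    loci: Sequence[str] | None = None,
) -> list[EffectEstimate]:
    """Per-step effects along a stacking series of strain ids.

    Consecutive strains must differ at exactly one locus (validated from
    the table's genotype column); a leading recipient wild type stands for
    the all-zeros genotype. Step i's effect, mean(S_i) - mean(S_{i-1}), is
    attributed to the toggled locus.
    """
    if len(path) < 2:
        raise PanelError("a path needs at least two strains")
    genotypes = _strain_genotypes(table)

    def bits_of(sid: str, pos: int) -> Genotype:
        try:
            token = genotypes[sid]
        except KeyError:
            raise PanelError(f"path strain {sid!r} absent from table")
        g = parse_genotype_token(token)
        if isinstance(g, Genotype):
            return g
        if g == RECIPIENT_WT and pos == 0:
            # infer panel width from any transgenic in the table
            widths = {
                len(t) for t in genotypes.values() if t not in WT_LABELS
            }
            if len(widths) != 1:
                raise PanelError("cannot infer panel width for wild-type start")
            return Genotype((0,) * widths.pop())
        raise PanelError(
            f"wild-type strain {sid!r} may only start a path (position {pos})"
        )

    out: list[EffectEstimate] = []
    prev = bits_of(path[0], 0)
    for i, sid in enumerate(path[1:], start=1):
        g = bits_of(sid, i)
        diff = prev.differing_loci(g)
        if len(diff) != 1:
            raise PanelError(
                f"path step {path[i - 1]!r} -> {sid!r} toggles {len(diff)} "
                "loci; consecutive strains must differ at exactly one"
            )
        idx = diff[0]
        locus = loci[idx] if loci is not None else f"locus_{idx}"
        est = marginal_effect(
            table,
            focal=sid,
            reference=path[i - 1],
            temperature=temperature,
            locus=locus,
            background=str(prev) if i > 1 else genotypes[path[0]],
        )
        out.append(est)
        prev = g
    return out


def fold_change(
    table: pd.DataFrame, focal: str, reference: str, temperature: float
) -> float:
    """Ratio of mean efficiencies, focal over reference."""
    x = strain_efficiencies(table, focal, temperature)
    y = strain_efficiencies(table, reference, temperature)
    ref_mean = float(np.mean(y))
    if ref_mean <= 0:
        raise PanelError(
            f"fold change undefined: reference {reference!r} mean efficiency "
            f"{ref_mean:.4g} is not positive"
        )
    return float(np.mean(x)) / ref_mean


def recapitulation_fraction(
    table: pd.DataFrame,
    transgenic: str,
    recipient_wt: str,
    donor_wt: str,
    temperature: float,
) -> float:
    """Percent of the interspecies divergence reconstituted by the transgenic.

    100 * (mean(transgenic) - mean(recipient)) / (mean(donor) - mean(recipient)),
    on the linear efficiency scale.
    """
    t = float(np.mean(strain_efficiencies(table, transgenic, temperature)))
    r = float(np.mean(strain_efficiencies(table, recipient_wt, temperature)))
    d = float(np.mean(strain_efficiencies(table, donor_wt, temperature)))
    if d == r:
        raise PanelError("wild-type endpoints do not diverge; fraction undefined")
    return 100.0 * (t - r) / (d - r)


_ALTERNATIVES = {"two-sided", "greater", "less"}


def rank_sum_test(
    x, y, sidedness: str = "two-sided", names: tuple[str, str] = ("a", "b")
) -> ComparisonResult:
    """Wilcoxon rank-sum (Mann-Whitney) test on two replicate vectors.

    ``sidedness='greater'`` tests whether the first group tends larger.
    The exact null distribution is used when the combined sample size is
    at most 25 and there are no ties; otherwise the normal approximation
    with mid-rank tie correction and continuity correction.
    """
    if sidedness not in _ALTERNATIVES:
        raise PanelError(f"sidedness must be one of {sorted(_ALTERNATIVES)}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InsufficientDataError("empty replicate group in comparison")
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size + y.size <= 25 and not ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative=sidedness, method=method)
    return ComparisonResult(
        strain_a=str(names[0]),
        strain_b=str(names[1]),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        sidedness=sidedness,
        method=method,
        low_n=bool(min(x.size, y.size) < 3),
    )


def compare_strains(
    table: pd.DataFrame,
    a: str,
    b: str,
    temperature: float,
    sidedness: str = "two-sided",
) -> ComparisonResult:
    """Rank-sum comparison of two strains' pooled replicate efficiencies."""
    return rank_sum_test(
        strain_efficiencies(table, a, temperature),
        strain_efficiencies(table, b, temperature),
        sidedness=sidedness,
        names=(a, b),
    )


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone, capped at 1)."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise PanelError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pairwise_comparisons(
    table: pd.DataFrame,
    strains: Sequence[str],
    temperature: float,
    sidedness: str = "two-sided",
) -> pd.DataFrame:
    """All pairwise strain comparisons of one run, BH-corrected as one family.

    Pairs are tested in list order with the earlier member as the first
    sample, so for a one-sided family pass ``strains`` in decreasing order
    of the hypothesized phenotype (e.g. full transgenic first, reference
    wild type last with ``sidedness='greater'``).
    """
    results = []
    for i, a in enumerate(strains):
        for b in strains[i + 1 :]:
            results.append(
                compare_strains(table, a, b, temperature, sidedness=sidedness)
            )
    q = bh_adjust([r.p_value for r in results]) if results else []
    rows = []
    for r, qv in zip(results, q):
        r.q_value = float(qv)
        rows.append(
            {
                "strain_a": r.strain_a,
                "strain_b": r.strain_b,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "sidedness": r.sidedness,
                "method": r.method,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "strain_a",
            "strain_b",
            "statistic",
            "p_value",
            "q_value",
            "sidedness",
            "method",
        ],
    )
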