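"""qPCR analysis: dilution-series amplification efficiency, 2^-ddCt
relative expression against a reference gene, and genotype comparisons.

Efficiency comes from the standard-curve regression of Ct on
log10(relative template amount): E = 10^(-1/slope) - 1, so a slope of
-3.3219 (perfect doubling) gives E = 1. Relative expression uses the
Livak 2^-ddCt estimator: dCt = Ct(target) - Ct(reference) per group,
ddCt = dCt(treated) - dCt(control). Group means define the headline fold
change; per-replicate folds (replicates paired by index against the
control-group mean dCt) provide the spread and feed the two-sample
Student's t-test used to compare genotypes at each timepoint
(marks: ** for P<0.01, * for P<0.05).

Efficiencies are reported per primer pair but do not correct the fold
change by default; an efficiency-corrected mode ((1+E)^-ddCt) is optional.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class EfficiencyResult:
    gene: str
    efficiency: float
    slope: float
    r_squared: float
    n_points: int


def amplification_efficiency(
    series: Sequence[tuple[float, float]],
    *,
    gene: str = "",
) -> EfficiencyResult:
    """Estimate E from (dilution_factor, Ct) pairs.

    x = log10(1/dilution_factor) is the relative template amount on a log
    scale; an OLS fit of Ct on x must have negative slope for an
    amplifying series, and E = 10^(-1/slope) - 1.
    """
    factors = np.array([f for f, _ in series], dtype=float)
    cts = np.array([c for _, c in series], dtype=float)
    if (factors <= 0).any():
        raise ValueError("dilution factors must be > 0")
    if len(np.unique(factors)) < 3:
        raise ValueError("need Ct values at >= 3 distinct dilution levels")
    x = np.log10(1.0 / factors)
    fit = stats.linregress(x, cts)
    if fit.slope >= 0:
        raise ValueError(f"series not amplifying: slope {fit.slope:.3f} >= 0")
    efficiency = 10.0 ** (-1.0 / fit.slope) - 1.0
    return EfficiencyResult(
        gene=gene,
        efficiency=efficiency,
        slope=float(fit.slope),
        r_squared=float(fit.rvalue**2),
        n_points=len(series),
    )


def efficiency_table(dilutions: pd.DataFrame) -> pd.DataFrame:
    """Per-gene efficiency estimates from a long dilution table
    (columns gene, dilution_factor, replicate, ct)."""
    rows = []
    for gene, sub in dilutions.groupby("gene", sort=True):
        res = amplification_efficiency(
            list(zip(sub["dilution_factor"], sub["ct"])), gene=gene
        )
        rows.append(
            {
                "gene": gene,
                "efficiency": res.efficiency,
                "slope": res.slope,
                "r_squared": res.r_squared,
                "n_points": res.n_points,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# relative expression
# ---------------------------------------------------------------------------


def _select(ct: pd.DataFrame, gene: str, group: Mapping[str, object]) -> pd.DataFrame:
    sub = ct[ct["gene"] == gene]
    for col, value in group.items():
        sub = sub[sub[col] == value]
    return sub


@dataclass
class RelativeExpressionResult:
    gene: str
    fold_change: float
    replicate_folds: list[float]
    sd: float
    ddct: float


def relative_expression(
    ct: pd.DataFrame,
    target: str,
    reference: str,
    treated: Mapping[str, object],
    control: Mapping[str, object],
    *,
    efficiency: float | None = None,
) -> RelativeExpressionResult:
    """2^-ddCt fold change of ``target`` in ``treated`` vs ``control``.

    ``treated``/``control`` are column filters on the Ct table (e.g.
    ``{"genotype": "KF", "treatment": "Al", "timepoint": "6h"}``). The
    reference gene must be present in both groups. When ``efficiency`` is
    given, the base 2 is replaced by (1 + E).
    """
    cells = {}
    for role, gene, group in (
        ("treated target", target, treated),
        ("treated reference", reference, treated),
        ("control target", target, control),
        ("control reference", reference, control),
    ):
        sub = _select(ct, gene, group)
        if sub.empty:
            raise ValueError(f"no Ct rows for {role} ({gene!r}, {dict(group)})")
        cells[role] = sub

    dct_treated = cells["treated target"]["ct"].mean() - cells["treated reference"]["ct"].mean()
    dct_control = cells["control target"]["ct"].mean() - cells["control reference"]["ct"].mean()
    ddct = dct_treated - dct_control
    base = 2.0 if efficiency is None else 1.0 + efficiency
    fold = float(base**-ddct)

    # replicate-level folds: pair target/reference within each treated
    # replicate, compare against the control-group mean dCt
    treated_target = cells["treated target"].set_index("replicate")["ct"]
    treated_ref = cells["treated reference"].set_index("replicate")["ct"]
    shared = treated_target.index.intersection(treated_ref.index)
    rep_folds = [
        float(base ** -((treated_target[r] - treated_ref[r]) - dct_control))
        for r in sorted(shared)
    ]
    sd = float(np.std(rep_folds, ddof=1)) if len(rep_folds) >= 2 else 0.0
    return RelativeExpressionResult(
        gene=target,
        fold_change=fold,
        replicate_folds=rep_folds,
        sd=sd,
        ddct=float(ddct),
    )


# ---------------------------------------------------------------------------
# genotype comparison
# ---------------------------------------------------------------------------


def significance_mark(p_value: float) -> str:
    if np.isnan(p_value):
        return "none"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return "none"


def compare_genotypes(
    values_a: Sequence[float],
    values_b: Sequence[float],
    *,
    equal_var: bool = True,
) -> tuple[float, str]:
    """Two-sample two-tailed t-test on per-replicate values; returns
    (p_value, mark). Fewer than 2 replicates on either side -> (nan, 'nd');
    two identical zero-variance samples -> (1.0, 'none')."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        return float("nan"), "nd"
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
        return p, significance_mark(p)
    _, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(p), significance_mark(float(p))


def analyze_al_response(
    ct: pd.DataFrame,
    targets: Sequence[str],
    reference: str,
    *,
    genotypes: Sequence[str] = ("T", "S"),
    control_treatment: object = "control",
    treated_treatment: object = "treated",
    equal_var: bool = True,
    test_on: Literal["fold", "ddct"] = "fold",
) -> pd.DataFrame:
    """Per gene/genotype/timepoint fold changes + per-timepoint genotype test.

    For every target gene, genotype and timepoint, the treated group is
    compared with its own-genotype control at the same timepoint (2^-ddCt);
    the two genotypes' per-replicate values (folds, or ddCt when
    ``test_on='ddct'``) are then compared by t-test at each timepoint.
    """
    if len(genotypes) != 2:
        raise ValueError("exactly two genotypes are compared")
    timepoints = sorted(ct["timepoint"].unique())
    rows = []
    for gene in targets:
        for tp in timepoints:
            per_genotype = {}
            for genotype in genotypes:
                res = relative_expression(
                    ct,
                    gene,
                    reference,
                    treated={"genotype": genotype, "treatment": treated_treatment, "timepoint": tp},
                    control={"genotype": genotype, "treatment": control_treatment, "timepoint": tp},
                )
                per_genotype[genotype] = res
            if test_on == "fold":
                va = per_genotype[genotypes[0]].replicate_folds
                vb = per_genotype[genotypes[1]].replicate_folds
            else:
                va = [-np.log2(f) for f in per_genotype[genotypes[0]].replicate_folds]
                vb = [-np.log2(f) for f in per_genotype[genotypes[1]].replicate_folds]
            p, mark = compare_genotypes(va, vb, equal_var=equal_var)
            for genotype in genotypes:
                res = per_genotype[genotype]
                rows.append(
                    {
                        "gene": gene,
                        "genotype": genotype,
                        "timepoint": tp,
                        "fold_change": res.fold_change,
                        "sd": res.sd,
                        "p_value": p,
                        "mark": mark,
                    }
                )
    return pd.DataFrame(rows)


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    results.to_csv(path, sep="\t", index=False)
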