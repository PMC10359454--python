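"""Pairwise substrate-class specificity and its energetic interpretation.

The central quantity is the per-context ratio of rate constants between two
substrate classes (e.g. HM/UM, the maintenance-methylation "copy accuracy").
Two aggregate conventions are always reported side by side — the mean of
per-context ratios and the ratio of class means — because they answer
slightly different questions and differ on skewed rate distributions.

A rate ratio r maps to a transition-state free-energy difference
ddG = R * T * ln(r).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

GAS_CONSTANT = 8.314  # J/(mol*K)


@dataclass
class SpecificityTable:
    pair: tuple[str, str]
    table: pd.DataFrame  # nncgnn, k_x, k_y, ratio, finite
    mean_of_ratios: float
    ratio_of_means: float
    n_undefined: int


@dataclass
class EnergyResult:
    delta_delta_g: float  # kJ/mol
    temperature: float  # K
    gas_constant: float = GAS_CONSTANT


def pairwise_ratios(rates: pd.DataFrame, pair: tuple[str, str]) -> SpecificityTable:
    """Per-context k_x / k_y for an ordered class pair.

    Contexts where k_y = 0 yield an infinite ratio: they are flagged and
    excluded from the aggregate means, with their count reported.
    """
    x, y = pair
    sub_x = rates[rates["substrate_class"] == x].set_index("nncgnn")["k"]
    sub_y = rates[rates["substrate_class"] == y].set_index("nncgnn")["k"]
    common = sorted(set(sub_x.index) & set(sub_y.index))
    if not common:
        raise ValueError(f"no shared contexts between classes {x} and {y}")
    kx = sub_x.loc[common].to_numpy(float)
    ky = sub_y.loc[common].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ky > 0, kx / np.where(ky > 0, ky, 1.0), np.inf)
    finite = np.isfinite(ratio) & np.isfinite(kx)
    table = pd.DataFrame(
        {
            "nncgnn": common,
            "k_x": kx,
            "k_y": ky,
            "ratio": ratio,
            "finite": finite,
        }
    )
    if not finite.any():
        raise ValueError("no finite ratios for this pair")
    mean_of_ratios = float(ratio[finite].mean())
    ratio_of_means = float(kx.mean() / ky.mean()) if ky.mean() > 0 else float("inf")
    return SpecificityTable(
        pair=(x, y),
        table=table,
        mean_of_ratios=mean_of_ratios,
        ratio_of_means=ratio_of_means,
        n_undefined=int((~finite).sum()),
    )


def summarize_ratios(table: SpecificityTable) -> dict:
    """Box-plot style summary of the finite per-context ratios.

    Quartiles use the linear-interpolation convention; whiskers extend to
    the most extreme data point within 1.5 IQR of the quartiles.
    """
    sub = table.table[table.table["finite"]]
    if sub.empty:
        raise ValueError("no finite ratios to summarize")
    r = sub["ratio"].to_numpy()
    ctx = sub["nncgnn"].to_numpy()
    q1, med, q3 = np.percentile(r, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = r[(r >= lo_fence) & (r <= hi_fence)]
    return {
        "mean": float(r.mean()),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "outliers": sorted(float(v) for v in r[(r < lo_fence) | (r > hi_fence)]),
        "min": float(r.min()),
        "max": float(r.max()),
        "argmin": str(ctx[np.argmin(r)]),
        "argmax": str(ctx[np.argmax(r)]),
        "n": int(r.size),
    }


def compare_enzymes(
    a: pd.DataFrame, b: pd.DataFrame, pair: tuple[str, str]
) -> dict:
    """Compare the class-pair specificity of two enzymes context by context.

    Returns per-context specificity ratios for each enzyme, the fold change
    a/b, the geometric-mean fold change, and a two-sided paired t-test on
    the natural-log specificity ratios (ratio data, multiplicative noise).
    A zero-variance difference (a == b) reports p = 1.0 by convention.
    """
    spec_a = pairwise_ratios(a, pair).table.set_index("nncgnn")["ratio"]
    spec_b = pairwise_ratios(b, pair).table.set_index("nncgnn")["ratio"]
    only_a = set(spec_a.index) ^ set(spec_b.index)
    if only_a:
        raise ValueError(
            f"context sets differ between enzymes: {sorted(only_a)[:5]} ..."
        )
    joint = pd.DataFrame({"spec_a": spec_a, "spec_b": spec_b})
    joint = joint[np.isfinite(joint["spec_a"]) & np.isfinite(joint["spec_b"])]
    if joint.empty:
        raise ValueError("no jointly finite specificity ratios")
    log_a = np.log(joint["spec_a"].to_numpy())
    log_b = np.log(joint["spec_b"].to_numpy())
    diff = log_a - log_b
    sd = diff.std(ddof=1) if diff.size > 1 else 0.0
    if np.allclose(sd, 0.0):
        # degenerate: identical specificities -> p = 1 by convention; a
        # constant non-zero shift is infinitely significant
        if np.allclose(diff.mean(), 0.0):
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = float(np.sign(diff.mean()) * np.inf), 0.0
    else:
        t_stat, p = stats.ttest_rel(log_a, log_b)
    joint = joint.assign(fold_change=joint["spec_a"] / joint["spec_b"])
    return {
        "per_context": joint.reset_index(),
        "geometric_mean_fold": float(np.exp(diff.mean())),
        "t": float(t_stat),
        "p": float(p),
        "n": int(diff.size),
    }


def delta_g(ratio: float, temperature: float = 298.0) -> EnergyResult:
    """Transition-state energy difference R*T*ln(ratio) in kJ/mol."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    ddg = GAS_CONSTANT * temperature * np.log(ratio) / 1000.0
    return EnergyResult(delta_delta_g=float(ddg), temperature=temperature)


def burial_energy(area: float, coefficient: float = 60.8) -> float:
    """Hydrophobic burial energy (kJ/mol) of a surface patch.

    ``area`` in square Angstrom, ``coefficient`` in J/(mol*A^2); the default
    is the standard hydrophobic-burial coefficient, and 30.3 A^2 is the
    solvent-accessible surface of a pyrimidine C5-methyl group in DNA.
    """
    if area < 0 or coefficient < 0:
        raise ValueError("area and coefficient must be non-negative")
    return area * coefficient / 1000.0


def write_specificity(path, table: SpecificityTable) -> None:
    df = table.table.copy()
    df.insert(0, "pair", f"{table.pair[0]}/{table.pair[1]}")
    df.to_csv(path, sep="\t", index=False)
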