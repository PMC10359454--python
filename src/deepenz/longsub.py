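"""Multi-CpG (long-substrate) methylation analysis.

Long substrates carry tens of CpG sites whose lower strands are either
unmodified or 5mC (a hemimethylation pattern mimicking post-replication
DNA).  Per-site methylation fractions over the dose series are pooled into
group-level reaction-progress fits (HM sites vs UM sites, per substrate),
and the observed group-rate ratios are compared with the specificity
expected from the single-site rate table given the sites' flanking
contexts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import kinetics


def group_rates(
    series: pd.DataFrame,
    by: tuple[str, ...] = ("substrate", "lower_state"),
    plateau: float = 1.0,
    exclude_sites: tuple[int, ...] = (),
) -> pd.DataFrame:
    """Average methylation rate per site group.

    ``series`` holds per-(site, dose) rows with columns dose, n_methylated,
    n_reads plus the grouping columns (typically substrate label and
    lower-strand state).  Within each group and dose the fractions are
    pooled read-weighted, then fitted to a monoexponential progress curve.
    Sites listed in ``exclude_sites`` (e.g. CpGs created by sequence tags)
    are dropped first.  Empty groups are reported with status
    ``insufficient-data``.
    """
    df = series.copy()
    if exclude_sites and "site" in df.columns:
        df = df[~df["site"].isin(exclude_sites)]
    rows = []
    for key, sub in df.groupby(list(by)):
        pooled = (
            sub.groupby("dose")[["n_methylated", "n_reads"]].sum().reset_index()
        )
        res = kinetics.fit_monoexponential(
            pooled["dose"].to_numpy(float),
            (pooled["n_methylated"] / pooled["n_reads"]).to_numpy(float),
            weights=pooled["n_reads"].to_numpy(float),
            plateau=plateau,
        )
        key = key if isinstance(key, tuple) else (key,)
        rows.append(
            dict(zip(by, key))
            | {
                "k": res.k,
                "n_points": res.n_points,
                "status": res.status,
                "n_sites": sub["site"].nunique() if "site" in sub.columns else np.nan,
            }
        )
    return pd.DataFrame(rows)


def observed_vs_expected(
    observed_hm: float,
    observed_um: float,
    rates: pd.DataFrame,
    hm_contexts: list[str],
    um_contexts: list[str],
) -> dict:
    """Compare an observed HM/UM group-rate ratio with the specificity
    expected from single-site rates given the sites' flanking contexts.

    Expected specificity = mean(k_HM over HM-site contexts) /
    mean(k_UM over UM-site contexts) (unweighted arithmetic means, so the
    result is invariant to rescaling the whole rate table).  Missing
    contexts raise KeyError.
    """
    if observed_um <= 0:
        raise ValueError("observed UM rate must be positive")
    hm_lookup = _class_lookup(rates, "HM")
    um_lookup = _class_lookup(rates, "UM")
    k_hm = np.array([_get(hm_lookup, ctx, "HM") for ctx in hm_contexts])
    k_um = np.array([_get(um_lookup, ctx, "UM") for ctx in um_contexts])
    expected = float(k_hm.mean() / k_um.mean())
    observed = float(observed_hm / observed_um)
    return {
        "observed_ratio": observed,
        "expected_ratio": expected,
        "observed_over_expected": observed / expected,
        "n_hm_sites": len(hm_contexts),
        "n_um_sites": len(um_contexts),
    }


def specificity_quotient(full: dict, patterned: dict) -> dict:
    """Relative specificity of two substrate settings (e.g. fully modified
    vs patterned): the quotients of their observed and expected ratios."""
    return {
        "observed_quotient": full["observed_ratio"] / patterned["observed_ratio"],
        "expected_quotient": full["expected_ratio"] / patterned["expected_ratio"],
    }


def _class_lookup(rates: pd.DataFrame, substrate_class: str) -> dict[str, float]:
    sub = rates[rates["substrate_class"] == substrate_class]
    return dict(zip(sub["nncgnn"], sub["k"]))


def _get(lookup: dict[str, float], ctx: str, cls: str) -> float:
    if ctx not in lookup:
        raise KeyError(f"context {ctx} missing from {cls} rates")
    return lookup[ctx]


def write_site_series(path, series: pd.DataFrame) -> None:
    series.to_csv(path, sep="\t", index=False)


def read_site_annotation(path) -> pd.DataFrame:
    """Site-annotation TSV: position, lower_state, include flag."""
    return pd.read_csv(path, sep="\t")
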