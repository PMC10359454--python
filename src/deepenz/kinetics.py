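"""Monoexponential reaction-progress fitting of per-context methylation.

Each NNCGNN context's methylated fraction y over dose d (enzyme
concentration x time, pseudo-first-order) follows

    y(d) = plateau * (1 - exp(-k * d))

and k is estimated by weighted least squares (weights = read counts) with a
non-negativity bound and multi-start initialisation.  Per-experiment fits
are scaled to a common axis via class-average rates and merged into a
RateTable with context-wise SEM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from ._seq import ALL_NNCGNN

STATUS_OK = "ok"
STATUS_BOUNDARY = "boundary"
STATUS_INSUFFICIENT = "insufficient-data"

_K_STARTS = (0.01, 0.1, 1.0)


@dataclass
class FitResult:
    k: float
    plateau: float
    rss: float
    n_points: int
    status: str


def progress_curve(dose, k, plateau=1.0):
    """Expected methylated fraction at the given dose(s)."""
    return plateau * -np.expm1(-k * np.asarray(dose, dtype=float))


def fit_monoexponential(
    doses,
    fractions,
    weights=None,
    plateau: float = 1.0,
) -> FitResult:
    """Fit k >= 0 for one context from (dose, fraction) observations.

    Requires >= 2 distinct doses, at least one positive.  All-zero
    fractions short-circuit to k = 0 with status ``boundary``.  Multi-start
    bounded least squares; ties broken by lowest residual, then smallest k.
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(fractions, dtype=float)
    w = np.ones_like(d) if weights is None else np.asarray(weights, dtype=float)
    n = d.size
    if n < 2 or np.unique(d).size < 2 or not (d > 0).any():
        return FitResult(np.nan, plateau, np.nan, n, STATUS_INSUFFICIENT)
    if not (y > 0).any():
        return FitResult(0.0, plateau, 0.0, n, STATUS_BOUNDARY)

    sw = np.sqrt(w)

    def resid(params):
        return sw * (y - progress_curve(d, params[0], plateau))

    best = None
    for k0 in _K_STARTS:
        sol = least_squares(resid, x0=[k0], bounds=([0.0], [np.inf]))
        rss = float(np.sum(sol.fun**2))
        k = float(sol.x[0])
        if best is None or rss < best[1] - 1e-12 or (
            abs(rss - best[1]) <= 1e-12 and k < best[0]
        ):
            best = (k, rss)
    k, rss = best
    status = STATUS_BOUNDARY if k == 0.0 else STATUS_OK
    return FitResult(k, plateau, rss, n, status)


def fit_global_plateau(counts: pd.DataFrame) -> float:
    """Stage-one estimate of a single plateau shared by an experiment.

    Pools reads per (class, dose) and jointly fits one k per class plus a
    common plateau; accounts for a non-convertible or inactive fraction.
    """
    pooled = (
        counts.groupby(["substrate_class", "dose"])[["n_methylated", "n_total"]]
        .sum()
        .reset_index()
    )
    classes = sorted(pooled["substrate_class"].unique())
    d = pooled["dose"].to_numpy(float)
    y = pooled["n_methylated"].to_numpy(float) / pooled["n_total"].to_numpy(float)
    w = np.sqrt(pooled["n_total"].to_numpy(float))
    cls_idx = pooled["substrate_class"].map({c: i for i, c in enumerate(classes)})

    def resid(params):
        ks = np.asarray(params[:-1])[cls_idx]
        plateau = params[-1]
        return w * (y - plateau * -np.expm1(-ks * d))

    x0 = [0.1] * len(classes) + [0.95]
    lo = [0.0] * len(classes) + [1e-3]
    hi = [np.inf] * len(classes) + [1.0]
    sol = least_squares(resid, x0=x0, bounds=(lo, hi))
    return float(sol.x[-1])


def fit_experiment(
    counts: pd.DataFrame,
    plateau: float | str = 1.0,
    min_reads: int = 50,
) -> pd.DataFrame:
    """Fit every (class, context) present in one experiment's count table.

    ``counts`` has columns substrate_class, dose, nncgnn, n_methylated,
    n_total.  Points with fewer than ``min_reads`` total reads are dropped
    from that context's fit; contexts left with < 2 distinct doses are
    flagged ``insufficient-data``.  ``plateau="fit"`` estimates one global
    plateau for the experiment first (two-stage).
    """
    if not (counts["dose"] > 0).any():
        raise ValueError("experiment must span at least one positive dose")
    plateau_val = fit_global_plateau(counts) if plateau == "fit" else float(plateau)

    rows = []
    for (cls, ctx), sub in counts.groupby(["substrate_class", "nncgnn"]):
        sub = sub[sub["n_total"] >= min_reads]
        if len(sub) < 2 or sub["dose"].nunique() < 2:
            res = FitResult(np.nan, plateau_val, np.nan, len(sub), STATUS_INSUFFICIENT)
        else:
            res = fit_monoexponential(
                sub["dose"].to_numpy(float),
                (sub["n_methylated"] / sub["n_total"]).to_numpy(float),
                weights=sub["n_total"].to_numpy(float),
                plateau=plateau_val,
            )
        rows.append(
            {
                "substrate_class": cls,
                "nncgnn": ctx,
                "k": res.k,
                "plateau": res.plateau,
                "rss": res.rss,
                "n_points": res.n_points,
                "status": res.status,
            }
        )
    return pd.DataFrame(rows)


def scale_and_merge(
    experiments: list[pd.DataFrame], reference: int = 0
) -> pd.DataFrame:
    """Scale experiments to the reference's rate axis and merge.

    The scale factor of an experiment is the (geometric mean over shared
    substrate classes of the) ratio of class-average rates reference /
    experiment, computed over contexts fitted ``ok`` in both.  Scaled
    per-context rates are averaged; SEM = sample SD / sqrt(n) (0 for a
    single experiment).  The result is invariant to rescaling any single
    experiment by a positive constant.
    """
    if not experiments:
        raise ValueError("no experiments to merge")
    ref = experiments[reference]

    scaled = []
    for i, exp in enumerate(experiments):
        if exp is ref or i == reference:
            ok = exp[exp["status"].isin([STATUS_OK, STATUS_BOUNDARY])]
            scaled.append(ok[["substrate_class", "nncgnn", "k"]])
            continue
        shared = sorted(
            set(ref["substrate_class"]).intersection(exp["substrate_class"])
        )
        if not shared:
            raise ValueError("experiment shares no substrate class with reference")
        log_factors = []
        for cls in shared:
            r = ref[(ref["substrate_class"] == cls) & (ref["status"] == STATUS_OK)]
            e = exp[(exp["substrate_class"] == cls) & (exp["status"] == STATUS_OK)]
            common = set(r["nncgnn"]).intersection(e["nncgnn"])
            if not common:
                continue
            rm = r[r["nncgnn"].isin(common)]["k"].mean()
            em = e[e["nncgnn"].isin(common)]["k"].mean()
            if em == 0 or rm == 0:
                raise ValueError(f"zero class-average rate for {cls}")
            log_factors.append(np.log(rm / em))
        if not log_factors:
            raise ValueError("no jointly fitted contexts to scale on")
        factor = float(np.exp(np.mean(log_factors)))
        ok = exp[exp["status"].isin([STATUS_OK, STATUS_BOUNDARY])].copy()
        ok["k"] = ok["k"] * factor
        scaled.append(ok[["substrate_class", "nncgnn", "k"]])

    stacked = pd.concat(scaled, ignore_index=True)
    g = stacked.groupby(["substrate_class", "nncgnn"])["k"]
    merged = g.agg(k="mean", sd="std", n="count").reset_index()
    merged["sem"] = np.where(merged["n"] > 1, merged["sd"] / np.sqrt(merged["n"]), 0.0)
    return merged[["substrate_class", "nncgnn", "k", "sem", "n"]]


def rate_vector(rates: pd.DataFrame, substrate_class: str) -> np.ndarray:
    """Length-256 rate vector in ALL_NNCGNN order for one class.

    Missing contexts raise with their names (the table should be complete).
    """
    sub = rates[rates["substrate_class"] == substrate_class]
    lookup = dict(zip(sub["nncgnn"], sub["k"]))
    missing = [ctx for ctx in ALL_NNCGNN if ctx not in lookup]
    if missing:
        raise KeyError(
            f"{len(missing)} contexts missing for {substrate_class}: "
            + ", ".join(missing[:5])
            + ("..." if len(missing) > 5 else "")
        )
    return np.array([lookup[ctx] for ctx in ALL_NNCGNN])


DEFAULT_RATE_COLUMNS = {
    "nncgnn": "nncgnn",
    "substrate_class": "substrate_class",
    "k": "k",
    "sem": "sem",
    "n": "n",
}


def write_rate_table(path, rates: pd.DataFrame) -> None:
    rates.to_csv(path, sep="\t", index=False)


def read_rate_table(path, columns: dict | None = None) -> pd.DataFrame:
    """Read a RateTable TSV; ``columns`` maps canonical names to file
    column names so externally deposited rate tables (e.g. per-NNCGNN rate
    constants with SEM for HM/OH/UM) can be loaded directly."""
    df = pd.read_csv(path, sep="\t")
    mapping = dict(DEFAULT_RATE_COLUMNS)
    if columns:
        mapping.update(columns)
    rename = {v: k for k, v in mapping.items() if v in df.columns}
    out = df.rename(columns=rename)
    required = {"nncgnn", "substrate_class", "k"}
    missing = required - set(out.columns)
    if missing:
        raise ValueError(f"rate table missing columns: {sorted(missing)}")
    return out
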