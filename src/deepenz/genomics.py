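"""Genomic NNCGNN methylation profiles and randomization correlation tests.

Per-CpG WGBS-style coverage tables are condensed into a 256-vector of mean
methylation per NNCGNN context and correlated with enzyme preference
profiles.  Significance uses a randomization scheme: the measured genomic
context means are randomly reassigned to contexts, the correlation is
recomputed for each shuffle, and the observed r is converted to a Z score
against the shuffled-null mean and SD (one-sided upper-tail normal p by
default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._seq import ALL_NNCGNN, NNCGNN_INDEX, revcomp


@dataclass
class GenomicContextProfile:
    """Mean genomic methylation per NNCGNN context.

    ``table`` has one row per context: mean_methylation (coverage-weighted),
    oe (context mean / global mean), n_sites, total_coverage; contexts with
    no qualifying site have NaN means.
    """

    table: pd.DataFrame
    n_excluded_coverage: int
    n_excluded_not_cpg: int
    n_excluded_n_flank: int

    def vector(self, kind: str = "mean") -> np.ndarray:
        col = {"mean": "mean_methylation", "oe": "oe"}[kind]
        return self.table.set_index("nncgnn").loc[list(ALL_NNCGNN), col].to_numpy()


@dataclass
class CorrelationTest:
    r_observed: float
    null_mean: float
    null_sd: float
    z: float
    p: float
    n_shuffles: int
    seed: int
    low_confidence: bool = False


def _chrom_seq(genome, chrom: str) -> str:
    seq = genome[chrom]  # KeyError propagates for a missing chromosome
    return seq.upper() if isinstance(seq, str) else str(seq[:]).upper()


def genomic_profile(
    coverage: pd.DataFrame,
    genome,
    min_coverage: int = 4,
    strand: str = "upper",
) -> GenomicContextProfile:
    """Per-context mean methylation from a Bismark-like coverage table.

    ``coverage`` columns: chrom, start (1-based position of the cytosine),
    end, meth_pct, count_methylated, count_unmethylated.  Sites with total
    coverage <= ``min_coverage`` are excluded (default keeps coverage > 4).
    ``strand="upper"`` keeps only cytosines that start a CpG on the upper
    strand; ``strand="both"`` additionally books lower-strand cytosines
    under the reverse-complement context.  Sites that are no CpG in the
    genome, or whose flanks contain N or run off the chromosome, are
    excluded and counted.
    """
    if strand not in ("upper", "both"):
        raise ValueError(f"unknown strand policy {strand!r}")
    cov_total = (
        coverage["count_methylated"].to_numpy()
        + coverage["count_unmethylated"].to_numpy()
    )
    keep = cov_total > min_coverage
    n_excl_cov = int((~keep).sum())
    kept = coverage[keep].reset_index(drop=True)

    ctx_idx = np.full(len(kept), -1, dtype=np.int64)
    n_not_cpg = 0
    n_nflank = 0
    for chrom, sub in kept.groupby("chrom", sort=False):
        seq = _chrom_seq(genome, chrom)
        pos0 = sub["start"].to_numpy() - 1
        rows = sub.index.to_numpy()
        for row, p in zip(rows, pos0):
            p = int(p)
            ctx = None
            if 0 <= p < len(seq) - 1 and seq[p] == "C" and seq[p + 1] == "G":
                if p - 2 >= 0 and p + 4 <= len(seq):
                    ctx = seq[p - 2 : p + 4]
            elif (
                strand == "both"
                and 1 <= p < len(seq)
                and seq[p] == "G"
                and seq[p - 1] == "C"
            ):
                if p - 4 >= 0 and p + 2 <= len(seq):
                    ctx = revcomp(seq[p - 4 : p + 2])
            else:
                n_not_cpg += 1
                continue
            if ctx is None or ctx not in NNCGNN_INDEX:
                n_nflank += 1
                continue
            ctx_idx[row] = NNCGNN_INDEX[ctx]

    valid = ctx_idx >= 0
    meth = kept["count_methylated"].to_numpy()[valid]
    unmeth = kept["count_unmethylated"].to_numpy()[valid]
    idx = ctx_idx[valid]

    sum_m = np.bincount(idx, weights=meth, minlength=256)
    sum_t = np.bincount(idx, weights=meth + unmeth, minlength=256)
    n_sites = np.bincount(idx, minlength=256)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(sum_t > 0, sum_m / np.maximum(sum_t, 1), np.nan)
    total = sum_t.sum()
    global_mean = sum_m.sum() / total if total > 0 else np.nan
    table = pd.DataFrame(
        {
            "nncgnn": list(ALL_NNCGNN),
            "mean_methylation": mean,
            "oe": mean / global_mean if total > 0 else np.full(256, np.nan),
            "n_sites": n_sites,
            "total_coverage": sum_t,
        }
    )
    return GenomicContextProfile(
        table=table,
        n_excluded_coverage=n_excl_cov,
        n_excluded_not_cpg=n_not_cpg,
        n_excluded_n_flank=n_nflank,
    )


def correlate(a, b) -> float:
    """Pearson r between two context vectors, NaN pairs dropped pairwise.

    Returns NaN (reported, not raised) if either vector has zero variance;
    requires at least 3 finite pairs.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must share context ordering and length")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("need at least 3 finite pairs")
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)


def _null_rs(genomic, func, n_shuffles, rng):
    rs = np.empty(n_shuffles)
    for i in range(n_shuffles):
        rs[i] = func(rng.permutation(genomic))
    return rs


def randomization_pvalue(
    genomic,
    pref,
    n_shuffles: int = 20,
    seed: int = 0,
    two_sided: bool = False,
) -> CorrelationTest:
    """Randomization Z-test of the genomic-vs-preference correlation.

    The genomic means are permuted across contexts ``n_shuffles`` times;
    Z = (r_obs - mean(r_null)) / SD(r_null) and p is the upper-tail normal
    probability (two-sided optional).  With few shuffles (< 10) the result
    is flagged low-confidence: 20 shuffles only support a Z-extrapolated,
    not an empirical, p-value.
    """
    if n_shuffles < 2:
        raise ValueError("need at least 2 shuffles")
    genomic = np.asarray(genomic, dtype=float)
    pref = np.asarray(pref, dtype=float)
    rng = np.random.default_rng(seed)
    r_obs = correlate(genomic, pref)
    rs = _null_rs(genomic, lambda g: correlate(g, pref), n_shuffles, rng)
    return _ztest(r_obs, rs, n_shuffles, seed, two_sided)


def correlation_difference_test(
    genomic,
    pref_a,
    pref_b,
    n_shuffles: int = 20,
    seed: int = 0,
    two_sided: bool = False,
) -> CorrelationTest:
    """Randomization test of dr = r(genomic, a) - r(genomic, b) > 0.

    Shuffling the genomic vector preserves the a/b dependence structure, so
    the null distribution of dr is symmetric around 0; swapping a and b
    negates the statistic and maps p to 1 - p (up to resampling noise).
    """
    if n_shuffles < 2:
        raise ValueError("need at least 2 shuffles")
    genomic = np.asarray(genomic, dtype=float)
    pref_a = np.asarray(pref_a, dtype=float)
    pref_b = np.asarray(pref_b, dtype=float)
    rng = np.random.default_rng(seed)
    stat = lambda g: correlate(g, pref_a) - correlate(g, pref_b)
    d_obs = stat(genomic)
    ds = _null_rs(genomic, stat, n_shuffles, rng)
    return _ztest(d_obs, ds, n_shuffles, seed, two_sided)


def _ztest(obs, null, n_shuffles, seed, two_sided) -> CorrelationTest:
    mu = float(null.mean())
    sd = float(null.std(ddof=1))
    if sd == 0:
        # degenerate null: if the observation equals every null draw the
        # midpoint of the (symmetric) null is reported, else p is undefined
        if obs == mu:
            z, p = 0.0, 0.5
        else:
            z, p = float("nan"), float("nan")
    else:
        z = (obs - mu) / sd
        p = 2 * stats.norm.sf(abs(z)) if two_sided else float(stats.norm.sf(z))
        p = min(max(p, np.nextafter(0, 1)), 1.0)
    return CorrelationTest(
        r_observed=float(obs),
        null_mean=mu,
        null_sd=sd,
        z=float(z),
        p=float(p),
        n_shuffles=n_shuffles,
        seed=seed,
        low_confidence=n_shuffles < 10,
    )


def read_coverage_table(
    path,
    columns: tuple[str, ...] = (
        "chrom", "start", "end", "meth_pct",
        "count_methylated", "count_unmethylated",
    ),
) -> pd.DataFrame:
    """Read a headerless Bismark-coverage dialect TSV."""
    return pd.read_csv(path, sep="\t", header=None, names=list(columns))
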