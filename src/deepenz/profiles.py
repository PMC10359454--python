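"""Flanking-base preference profiles around the CpG.

The observed/expected (o/e) profile compares per-position base frequencies
among methylated reads with those expected from the full read pool of the
same substrate class; values above 1 mark favored bases.  Contexts can also
be ranked by fitted rate to inspect base occurrence in the most preferred
and most disfavored NNCGNN flanks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import BASES, encode_many
from .kinetics import rate_vector

CALL_METHYLATED, CALL_UNMETHYLATED = 1, 0


def window_positions(flank_len: int) -> list[int]:
    """Flank position labels -f..-1, +1..+f (the CpG core is unnumbered)."""
    return list(range(-flank_len, 0)) + list(range(1, flank_len + 1))


@dataclass
class OEProfile:
    positions: list[int]
    oe_meth: np.ndarray  # (n_positions, 4) in ACGT order
    oe_unmeth: np.ndarray
    sem_meth: np.ndarray | None = None
    sem_unmeth: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: position, base, oe_meth, oe_unmeth (+ SEM)."""
        rows = []
        for i, pos in enumerate(self.positions):
            for j, b in enumerate(BASES):
                row = {
                    "position": pos,
                    "base": b,
                    "oe_meth": self.oe_meth[i, j],
                    "oe_unmeth": self.oe_unmeth[i, j],
                }
                if self.sem_meth is not None:
                    row["sem_meth"] = self.sem_meth[i, j]
                    row["sem_unmeth"] = self.sem_unmeth[i, j]
                rows.append(row)
        return pd.DataFrame(rows)

    def cell(self, position: int, base: str, subset: str = "meth") -> float:
        i = self.positions.index(position)
        j = BASES.index(base)
        return float((self.oe_meth if subset == "meth" else self.oe_unmeth)[i, j])


def position_base_counts(windows: list[str], flank_len: int) -> np.ndarray:
    """(n_positions, 4) base counts over the flank positions of the given
    windows (core CpG columns excluded); non-ACGT bases are ignored."""
    mat = encode_many(windows)
    flank_cols = np.r_[np.arange(0, flank_len), np.arange(flank_len + 2, 2 * flank_len + 2)]
    mat = mat[:, flank_cols]
    counts = np.zeros((mat.shape[1], 4))
    for b in range(4):
        counts[:, b] = (mat == b).sum(axis=0)
    return counts


def _freq(counts: np.ndarray, pseudocount: float) -> np.ndarray:
    padded = counts + pseudocount
    return padded / padded.sum(axis=1, keepdims=True)


def oe_profile(
    records: pd.DataFrame,
    expected: str = "pool",
    pseudocount: float = 1.0,
) -> OEProfile:
    """Observed/expected base profile of one class's call records.

    Numerators are the per-position base frequencies in the methylated
    (resp. unmethylated) subset; the denominator is the same frequency over
    the full pool (``expected="pool"``, absorbs synthesis bias) or the
    uniform 0.25 (``expected="uniform"``).  A pseudo-count (default 1) is
    added to every (base, position, subset) cell.
    """
    if records.empty:
        raise ValueError("no records")
    flank_len = (len(records["window"].iat[0]) - 2) // 2
    subsets = {}
    for name, mask in (
        ("methylated", records["call_upper"] == CALL_METHYLATED),
        ("unmethylated", records["call_upper"] == CALL_UNMETHYLATED),
    ):
        if not mask.any():
            raise ValueError(f"empty {name} subset")
        subsets[name] = records.loc[mask, "window"].tolist()

    counts_m = position_base_counts(subsets["methylated"], flank_len)
    counts_u = position_base_counts(subsets["unmethylated"], flank_len)
    if expected == "pool":
        exp_freq = _freq(
            position_base_counts(records["window"].tolist(), flank_len), pseudocount
        )
    elif expected == "uniform":
        exp_freq = np.full_like(counts_m, 0.25)
    else:
        raise ValueError(f"unknown expected mode {expected!r}")

    return OEProfile(
        positions=window_positions(flank_len),
        oe_meth=_freq(counts_m, pseudocount) / exp_freq,
        oe_unmeth=_freq(counts_u, pseudocount) / exp_freq,
    )


def aggregate_profiles(profiles: list[OEProfile]) -> OEProfile:
    """Cell-wise mean and SEM (SD/sqrt(N)) across replicate profiles."""
    if not profiles:
        raise ValueError("no profiles")
    ref = profiles[0]
    for p in profiles[1:]:
        if p.positions != ref.positions or p.oe_meth.shape != ref.oe_meth.shape:
            raise ValueError("profile shape mismatch")
    stack_m = np.stack([p.oe_meth for p in profiles])
    stack_u = np.stack([p.oe_unmeth for p in profiles])
    n = len(profiles)
    sem = lambda s: s.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(s[0])
    return OEProfile(
        positions=list(ref.positions),
        oe_meth=stack_m.mean(axis=0),
        oe_unmeth=stack_u.mean(axis=0),
        sem_meth=sem(stack_m),
        sem_unmeth=sem(stack_u),
    )


@dataclass
class RankedContexts:
    top: list[str]
    bottom: list[str]
    top_counts: pd.DataFrame  # position x base occurrence among top contexts
    bottom_counts: pd.DataFrame


def extreme_flanks(rates: pd.DataFrame, substrate_class: str, m: int = 20) -> RankedContexts:
    """Top-m and bottom-m NNCGNN contexts of one class by fitted rate.

    The sort is deterministic: descending k with lexicographic tie-break on
    the context string.  Per-position (-2, -1, +1, +2) base occurrence is
    tallied within each subset.
    """
    if 2 * m > 256:
        raise ValueError("2m must not exceed 256")
    k = rate_vector(rates, substrate_class)  # validates 256 contexts present
    sub = rates[rates["substrate_class"] == substrate_class].copy()
    sub = sub.sort_values(["k", "nncgnn"], ascending=[False, True], kind="mergesort")
    ordered = sub["nncgnn"].tolist()
    top, bottom = ordered[:m], ordered[-m:]
    return RankedContexts(top, bottom, _occurrence(top), _occurrence(bottom))


def _occurrence(contexts: list[str]) -> pd.DataFrame:
    positions = [-2, -1, 1, 2]
    cols = [0, 1, 4, 5]  # indices of N bases within the NNCGNN 6-mer
    data = {
        b: [sum(ctx[c] == b for ctx in contexts) for c in cols] for b in BASES
    }
    return pd.DataFrame(data, index=pd.Index(positions, name="position"))


def write_profile(path, profile: OEProfile) -> None:
    profile.to_frame().to_csv(path, sep="\t", index=False)
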