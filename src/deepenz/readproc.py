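"""Hairpin bisulfite read processing.

Read pairs from hairpin-ligated, bisulfite-converted molecules carry both
strands of one original duplex: read1 is the converted upper strand and
read2 the converted lower strand (5'->3', so position j of read2 pairs
with upper position L-1-j).  Comparing the two strands recovers the
pre-conversion sequence and the methylation state of both CpG cytosines:

========  =============  ==================================================
upper     lower (paired)  original upper base
========  =============  ==================================================
A         T              A
C         G              C, upper strand protected (methylated)
T         A              T
T         G              C, upper strand converted (unmethylated)
G         C              G, lower strand protected (methylated)
G         T              G, lower strand converted (unmethylated)
other     other          ambiguous
========  =============  ==================================================
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._seq import C, G, decode, decode_rows, encode_many, revcomp

CALL_METHYLATED, CALL_UNMETHYLATED, CALL_AMBIGUOUS = 1, 0, -1

# rule table: (upper code, aligned lower code) -> original upper code
_RULE = np.full((5, 5), 255, dtype=np.uint8)
_RULE[0, 3] = 0  # A / T
_RULE[1, 2] = 1  # C / G   upper protected
_RULE[3, 0] = 3  # T / A
_RULE[3, 2] = 1  # T / G   upper converted
_RULE[2, 1] = 2  # G / C   lower protected
_RULE[2, 3] = 2  # G / T   lower converted


@dataclass
class Reconstruction:
    """Original sequence plus per-position strand-retention flags."""

    original: str
    upper_retained: np.ndarray  # original C whose upper read kept C
    lower_retained: np.ndarray  # original G whose paired lower read kept C
    ambiguous: np.ndarray


@dataclass
class CallRecord:
    """Methylation call at one CpG with its flanking context."""

    substrate_class: str
    dose: float
    original_sequence: str
    flank_context: str  # positions -f..-1, CpG, +1..+f
    nncgnn: str
    call_upper: int
    call_lower: int


@dataclass
class QCReport:
    reads_in: int = 0
    assigned: int = 0
    unassigned: int = 0
    discarded_size: int = 0
    ambiguous: int = 0
    by_class: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def read_fastq(path) -> tuple[list[str], list[str]]:
    """Read a FASTQ file into (ids-with-description, sequences)."""
    ids, seqs = [], []
    with open(path) as fh:
        for title, seq, _qual in FastqGeneralIterator(fh):
            ids.append(title)
            seqs.append(seq)
    return ids, seqs


def _reconstruct_matrix(r1: np.ndarray, r2: np.ndarray):
    """Vectorized rule-table reconstruction on (n, L) code matrices."""
    lower_aligned = r2[:, ::-1]
    u = np.minimum(r1, 4)
    l = np.minimum(lower_aligned, 4)
    orig = _RULE[u, l]
    up_ret = (u == C) & (l == G)
    low_ret = (u == G) & (l == C)
    return orig, up_ret, low_ret


def reconstruct_hairpin(read1: str, read2: str) -> Reconstruction:
    """Reconstruct one molecule from its hairpin read pair.

    Raises ValueError on length mismatch (the pair would be discarded and
    counted by the bulk pipeline).
    """
    if len(read1) != len(read2):
        raise ValueError("read pair length mismatch")
    r1 = encode_many([read1])
    r2 = encode_many([read2])
    orig, up, low = _reconstruct_matrix(r1, r2)
    return Reconstruction(
        original=decode(orig[0]),
        upper_retained=up[0],
        lower_retained=low[0],
        ambiguous=orig[0] == 255,
    )


def call_site(
    recon: Reconstruction,
    site: int,
    flank_len: int = 10,
    substrate_class: str = "UM",
    dose: float = 0.0,
) -> CallRecord:
    """Assign methylation calls at the CpG whose C is at ``site``.

    The call is ambiguous when the reconstructed NNCGNN window contains any
    contradictory position or the site is not a CpG.
    """
    orig = recon.original
    window = orig[site - flank_len : site + 2 + flank_len]
    nncgnn = orig[site - 2 : site + 4]
    ambiguous_win = "N" in orig[site - 2 : site + 4]
    if nncgnn[2:4] != "CG" or ambiguous_win or len(window) != 2 * flank_len + 2:
        up = low = CALL_AMBIGUOUS
    else:
        up = CALL_METHYLATED if recon.upper_retained[site] else CALL_UNMETHYLATED
        low = CALL_METHYLATED if recon.lower_retained[site + 1] else CALL_UNMETHYLATED
    return CallRecord(
        substrate_class=substrate_class,
        dose=dose,
        original_sequence=orig,
        flank_context=window,
        nncgnn=nncgnn,
        call_upper=up,
        call_lower=low,
    )


def demultiplex(
    reads1: Sequence[str],
    barcodes: Mapping[str, str],
    max_mismatch: int = 0,
) -> dict[str, np.ndarray]:
    """Route read indices to substrate classes by the read1 5' barcode.

    Exact match by default; ``max_mismatch=1`` tolerates one substitution.
    Unmatched reads go to the ``"unassigned"`` bucket, never dropped.
    """
    buckets: dict[str, list[int]] = {cls: [] for cls in barcodes}
    buckets["unassigned"] = []
    items = list(barcodes.items())
    for i, read in enumerate(reads1):
        hit = None
        for cls, bc in items:
            prefix = read[: len(bc)]
            if len(prefix) < len(bc):
                continue
            mism = sum(a != b for a, b in zip(prefix, bc))
            if mism <= max_mismatch:
                hit = cls
                break
        buckets[hit if hit is not None else "unassigned"].append(i)
    return {k: np.asarray(v, dtype=np.int64) for k, v in buckets.items()}


def process_read_pairs(
    reads1: Sequence[str],
    reads2: Sequence[str],
    barcodes: Mapping[str, str],
    cpg_pos: int,
    flank_len: int,
    dose: float,
    expected_len: int | None = None,
    size_tolerance: int = 2,
    max_mismatch: int = 0,
) -> tuple[pd.DataFrame, QCReport]:
    """Full per-time-point processing: size filter, demultiplexing,
    reconstruction and CpG calling.

    Returns a call-record table (columns substrate_class, dose, window,
    nncgnn, call_upper, call_lower; ambiguous calls are -1) plus QC counts.
    """
    qc = QCReport(reads_in=len(reads1))
    if expected_len is None:
        expected_len = max((len(r) for r in reads1), default=0)

    keep = [
        i
        for i in range(len(reads1))
        if len(reads1[i]) == len(reads2[i])
        and abs(len(reads1[i]) - expected_len) <= size_tolerance
    ]
    qc.discarded_size = len(reads1) - len(keep)

    frames = []
    # group by exact length so positions align within each batch
    by_len: dict[int, list[int]] = {}
    for i in keep:
        by_len.setdefault(len(reads1[i]), []).append(i)
    for L, idxs in sorted(by_len.items()):
        if cpg_pos + 2 + flank_len > L:
            qc.discarded_size += len(idxs)
            continue
        sub1 = [reads1[i] for i in idxs]
        buckets = demultiplex(sub1, barcodes, max_mismatch=max_mismatch)
        qc.unassigned += len(buckets.pop("unassigned"))
        for cls, rows in buckets.items():
            if rows.size == 0:
                continue
            r1 = encode_many([sub1[j] for j in rows])
            r2 = encode_many([reads2[idxs[j]] for j in rows])
            orig, up_ret, low_ret = _reconstruct_matrix(r1, r2)
            frames.append(
                _calls_frame(orig, up_ret, low_ret, cpg_pos, flank_len, cls, dose)
            )
            qc.assigned += rows.size
            qc.by_class[cls] = qc.by_class.get(cls, 0) + int(rows.size)

    if frames:
        records = pd.concat(frames, ignore_index=True)
    else:
        records = pd.DataFrame(
            columns=["substrate_class", "dose", "window", "nncgnn",
                     "call_upper", "call_lower"]
        )
    qc.ambiguous = int((records["call_upper"] == CALL_AMBIGUOUS).sum())
    return records, qc


def _calls_frame(orig, up_ret, low_ret, cpg_pos, flank_len, cls, dose):
    n = orig.shape[0]
    p, fl = cpg_pos, flank_len
    win = orig[:, p - fl : p + 2 + fl]
    windows = decode_rows(win)
    core_ok = (orig[:, p] == C) & (orig[:, p + 1] == G)
    ctx_ok = core_ok & (orig[:, p - 2 : p + 4] != 255).all(axis=1)
    up = np.where(ctx_ok, up_ret[:, p].astype(np.int8), CALL_AMBIGUOUS)
    low = np.where(ctx_ok, low_ret[:, p + 1].astype(np.int8), CALL_AMBIGUOUS)
    nncgnn = [w[fl - 2 : fl + 4] for w in windows]
    return pd.DataFrame(
        {
            "substrate_class": cls,
            "dose": dose,
            "window": windows,
            "nncgnn": nncgnn,
            "call_upper": up,
            "call_lower": low,
        }
    )


def tabulate_contexts(
    records: pd.DataFrame, class_rule: str = "per-strand"
) -> pd.DataFrame:
    """Count methylation events per (substrate_class, dose, NNCGNN).

    For HM and OH substrates only the upper strand is a methylation target
    (the lower strand is pre-modified), so only ``call_upper`` counts.  For
    UM substrates both CpG cytosines are targets:

    - ``"per-strand"`` (default): each unambiguous strand contributes an
      independent event; lower-strand events are booked under the
      reverse-complement context.
    - ``"per-molecule"``: one event per molecule under the upper-strand
      context, methylated if either strand is methylated.

    Ambiguous calls are excluded from both numerator and denominator.
    """
    if class_rule not in ("per-strand", "per-molecule"):
        raise ValueError(f"unknown class_rule {class_rule!r}")
    parts = []
    ok = records[records["call_upper"] != CALL_AMBIGUOUS]
    upper = ok[["substrate_class", "dose", "nncgnn", "call_upper"]].rename(
        columns={"call_upper": "methylated"}
    )
    if class_rule == "per-molecule":
        merged = upper.copy()
        um_mask = (ok["substrate_class"] == "UM").to_numpy()
        either = ((ok["call_upper"] == 1) | (ok["call_lower"] == 1)).to_numpy()
        vals = merged["methylated"].to_numpy().copy()
        vals[um_mask] = either[um_mask].astype(vals.dtype)
        merged["methylated"] = vals
        parts.append(merged)
    else:
        parts.append(upper)
        um = ok[(ok["substrate_class"] == "UM") & (ok["call_lower"] != CALL_AMBIGUOUS)]
        if len(um):
            lower = um[["substrate_class", "dose", "nncgnn", "call_lower"]].rename(
                columns={"call_lower": "methylated"}
            )
            lower = lower.assign(nncgnn=[revcomp(c) for c in lower["nncgnn"]])
            parts.append(lower)
    events = pd.concat(parts, ignore_index=True)
    counts = (
        events.groupby(["substrate_class", "dose", "nncgnn"])["methylated"]
        .agg(n_methylated="sum", n_total="count")
        .reset_index()
    )
    return counts


def estimate_background(no_enzyme_counts: pd.DataFrame) -> dict[str, float]:
    """Pooled false-methylation fraction per class from a zero-dose control.

    Classes with zero total reads are reported as NaN (missing).
    """
    out: dict[str, float] = {}
    for cls, sub in no_enzyme_counts.groupby("substrate_class"):
        total = sub["n_total"].sum()
        out[cls] = float(sub["n_methylated"].sum() / total) if total else float("nan")
    return out


def write_call_records(path, records: pd.DataFrame) -> None:
    records.to_csv(path, sep="\t", index=False)


def write_context_counts(path, counts: pd.DataFrame) -> None:
    counts.to_csv(path, sep="\t", index=False)


def read_context_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
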