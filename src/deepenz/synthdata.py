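"""Synthetic deep-enzymology data with known ground truth.

This module emulates the experimental inputs of a DNMT1 "deep enzymology"
run: pools of double-stranded substrates carrying a single CpG in randomized
flanks, first-order methylation kinetics with flanking-context-dependent
rate constants, hairpin ligation followed by bisulfite conversion and
paired-end read-out, a long multi-CpG substrate with a defined
hemimethylation pattern, and a synthetic genome plus WGBS-style coverage
table whose per-CpG methylation depends on the NNCGNN context.

Substrate classes
-----------------
``HM``  hemimethylated   — lower-strand CpG carries 5mC
``OH``  hemihydroxymethylated — lower-strand CpG carries 5hmC
``UM``  unmethylated     — both strands unmodified

Doses are the product of relative enzyme concentration and time
(pseudo-first-order contract); absolute units are arbitrary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import (
    ALL_NNCGNN,
    NNCGNN_INDEX,
    C,
    G,
    complement_codes,
    context_index_from_codes,
    decode,
    decode_rows,
    encode,
    revcomp,
)

logger = logging.getLogger(__name__)

SUBSTRATE_CLASSES = ("HM", "OH", "UM")

#: Default demultiplexing barcodes; C-free so bisulfite conversion cannot
#: corrupt them, and trivially CpG-free.
DEFAULT_BARCODES = {"HM": "TGGATA", "OH": "TAGGAT", "UM": "ATTGGA"}

#: Default hairpin linker: 8 nt, C-free (conversion-proof).
DEFAULT_LINKER = "GATTAGGA"

# Fixed arm filler patterns flanking the randomized window.  Drawn from
# {A,G,T} only so the arms can never contribute the C of a spurious CpG,
# either internally or across the arm/flank junctions.
_LEFT_FILL_PAT = "TAGATTGGATAGTTAGGTTAGAATGAGTTAGATAGGATTAGTGATAGAT"
_RIGHT_FILL_PAT = "ATTGAGTAGGATTAGATAGTTGGATAGATTAGGTAGATTGAGATTAGGA"

# integer codes for modification states
MOD_C, MOD_5MC, MOD_5HMC = 0, 1, 2
_MOD_NAMES = {MOD_C: "C", MOD_5MC: "5mC", MOD_5HMC: "5hmC"}
_LOWER_INIT = {"HM": MOD_5MC, "OH": MOD_5HMC, "UM": MOD_C}

# index of the reverse-complement context for each of the 256 NNCGNN
RC_INDEX = np.array([NNCGNN_INDEX[revcomp(ctx)] for ctx in ALL_NNCGNN])


@dataclass(frozen=True)
class SubstrateSpec:
    """Layout of a single-CpG randomized substrate.

    The duplex is ``barcode + left filler + N*flank_len + CG + N*flank_len
    + right filler`` with fixed, CpG-free arms; only the flanks are random.
    """

    substrate_class: str
    barcode: str = ""
    flank_len: int = 10
    total_len: int = 67

    def __post_init__(self):
        if self.substrate_class not in SUBSTRATE_CLASSES:
            raise ValueError(f"unknown substrate class {self.substrate_class!r}")
        if not self.barcode:
            object.__setattr__(
                self, "barcode", DEFAULT_BARCODES[self.substrate_class]
            )
        if self.flank_len < 2:
            raise ValueError("flank_len must be >= 2 (NNCGNN context undefined)")
        if "CG" in self.barcode:
            raise ValueError("barcode must not contain a CpG")
        if self.total_len < 2 * self.flank_len + 2 + len(self.barcode):
            raise ValueError("total_len too short for barcode + flanks + CpG")

    @property
    def arms(self) -> tuple[str, str]:
        """Fixed (left, right) arm sequences, barcode included in the left."""
        spare = self.total_len - 2 * self.flank_len - 2 - len(self.barcode)
        left_fill = spare // 2
        right_fill = spare - left_fill
        left = self.barcode + _tile(_LEFT_FILL_PAT, left_fill)
        right = _tile(_RIGHT_FILL_PAT, right_fill)
        return left, right

    @property
    def cpg_pos(self) -> int:
        """0-based position of the CpG's C in the full upper strand."""
        return len(self.arms[0]) + self.flank_len


def _tile(pattern: str, n: int) -> str:
    if n <= 0:
        return ""
    return (pattern * (n // len(pattern) + 1))[:n]


@dataclass
class TrueRateModel:
    """Ground-truth first-order rate constants per (class, NNCGNN context).

    ``plateau`` is the maximal attainable methylated fraction (accounts for
    inactive or non-convertible substrate); the expected methylated fraction
    at dose d is ``plateau * (1 - exp(-k * d))``.
    """

    k_true: Mapping[tuple[str, str], float]
    plateau: float = 1.0

    def __post_init__(self):
        if not 0 < self.plateau <= 1:
            raise ValueError("plateau must be in (0, 1]")
        for key, k in self.k_true.items():
            if k < 0:
                raise ValueError(f"negative rate for {key}")

    @classmethod
    def from_arrays(cls, rates: Mapping[str, np.ndarray], plateau: float = 1.0):
        """Build from per-class length-256 arrays ordered like ALL_NNCGNN."""
        k = {}
        for sclass, arr in rates.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (256,):
                raise ValueError("per-class rate array must have length 256")
            k.update({(sclass, ctx): arr[i] for i, ctx in enumerate(ALL_NNCGNN)})
        return cls(k, plateau=plateau)

    def rate_array(self, substrate_class: str) -> np.ndarray:
        """Length-256 rate vector for one class; KeyError names any gap."""
        out = np.empty(256)
        for i, ctx in enumerate(ALL_NNCGNN):
            key = (substrate_class, ctx)
            if key not in self.k_true:
                raise KeyError(f"no rate for context {ctx} in class {substrate_class}")
            out[i] = self.k_true[key]
        return out


@dataclass
class MoleculeSet:
    """A pool of simulated substrate molecules of one class.

    Sequences are stored as an (n, L) uint8 code matrix (upper strand);
    per-molecule CpG modification states are tracked separately for the two
    strands.  ``dose`` is attached by :func:`simulate_kinetics`.
    """

    substrate_class: str
    seqs: np.ndarray
    cpg_pos: int
    flank_len: int
    upper_state: np.ndarray  # MOD_C or MOD_5MC
    lower_state: np.ndarray  # MOD_C, MOD_5MC or MOD_5HMC
    dose: float | None = None
    barcode: str = ""

    def __len__(self) -> int:
        return self.seqs.shape[0]

    @property
    def context_idx(self) -> np.ndarray:
        """0..255 NNCGNN index per molecule."""
        p = self.cpg_pos
        flanks = self.seqs[:, [p - 2, p - 1, p + 2, p + 3]]
        return context_index_from_codes(flanks)

    @property
    def contexts(self) -> list[str]:
        idx = self.context_idx
        return [ALL_NNCGNN[i] for i in idx]

    def sequences(self) -> list[str]:
        return decode_rows(self.seqs)

    @property
    def molecules(self) -> list[tuple[str, str, str, str, float | None]]:
        """(upper sequence, lower CpG mod, upper CpG state, class, dose)."""
        seqs = self.sequences()
        return [
            (
                seqs[i],
                _MOD_NAMES[int(self.lower_state[i])],
                _MOD_NAMES[int(self.upper_state[i])],
                self.substrate_class,
                self.dose,
            )
            for i in range(len(self))
        ]


def generate_pool(
    spec: SubstrateSpec, n: int, seed: int, single_cpg: str = "context"
) -> MoleculeSet:
    """Draw ``n`` substrate molecules with i.i.d. uniform random flanks.

    ``single_cpg`` controls how extra CpGs created by the random flanks are
    handled, by rejection sampling (regeneration; the rate is logged):

    - ``"context"`` (default): CpGs outside the central NNCGNN 6-mer are
      rejected; CpGs *inside* the 6-mer are part of the context definition.
      The 31 contexts such as CGCGNN or NNCGCG would otherwise be
      unrealizable and the context space would shrink below 256.
    - ``"strict"``: any extra CpG in the randomized window is rejected
      (exact single-site semantics, 225 realizable contexts).
    - ``"off"``: no rejection — flank bases are exactly i.i.d. uniform, as
      in a synthesized N-base library.  Note that under either rejection
      mode the conditioning itself shifts flank C/G marginals by a few
      percent; only ``"off"`` keeps per-position base frequencies at 0.25.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if single_cpg not in ("context", "strict", "off"):
        raise ValueError(f"unknown single_cpg policy {single_cpg!r}")
    rng = np.random.default_rng(seed)
    left, right = spec.arms
    template = encode(left + "N" * spec.flank_len + "CG" + "N" * spec.flank_len + right)
    seqs = np.tile(template, (n, 1))
    fl = spec.flank_len
    p = spec.cpg_pos
    flank_cols = np.r_[np.arange(p - fl, p), np.arange(p + 2, p + 2 + fl)]

    pending = np.arange(n)
    attempts = 0
    while pending.size:
        draw = rng.integers(0, 4, size=(pending.size, 2 * fl), dtype=np.uint8)
        seqs[np.ix_(pending, flank_cols)] = draw
        attempts += pending.size
        if single_cpg == "off":
            break
        win = seqs[pending][:, p - fl : p + 2 + fl]
        # CG pair start positions, window-relative; the NNCGNN 6-mer spans
        # [fl-2, fl+4) so starts in [fl-2, fl+2] are part of the context
        cg = (win[:, :-1] == C) & (win[:, 1:] == G)
        outside = np.ones(cg.shape[1], dtype=bool)
        if single_cpg == "context":
            outside[fl - 2 : fl + 3] = False
        else:  # strict: only the core CG itself is allowed
            outside[fl] = False
        bad = (cg & outside).any(axis=1)
        pending = pending[bad]
    logger.info(
        "generate_pool(%s): %d molecules, rejection rate %.3f",
        spec.substrate_class, n, 1 - n / attempts,
    )

    lower = np.full(n, _LOWER_INIT[spec.substrate_class], dtype=np.uint8)
    return MoleculeSet(
        substrate_class=spec.substrate_class,
        seqs=seqs,
        cpg_pos=p,
        flank_len=fl,
        upper_state=np.zeros(n, dtype=np.uint8),
        lower_state=lower,
        barcode=spec.barcode,
    )


def simulate_kinetics(
    pool: MoleculeSet,
    model: TrueRateModel,
    dose: float,
    seed: int = 0,
) -> MoleculeSet:
    """Methylate each molecule's CpG per first-order progress kinetics.

    The upper-strand C becomes 5mC with probability
    ``plateau * (1 - exp(-k[class, context] * dose))``.  For UM substrates
    the lower strand is an equally valid target: it is methylated
    independently using the rate of the reverse-complement context.
    """
    if dose < 0:
        raise ValueError("dose must be non-negative")
    rng = np.random.default_rng(seed)
    k = pool_rates(pool, model)
    p_meth = model.plateau * -np.expm1(-k * dose)
    upper = (rng.random(len(pool)) < p_meth).astype(np.uint8)

    lower = pool.lower_state.copy()
    if pool.substrate_class == "UM":
        k_rc = model.rate_array("UM")[RC_INDEX[pool.context_idx]]
        p_rc = model.plateau * -np.expm1(-k_rc * dose)
        hit = rng.random(len(pool)) < p_rc
        lower = np.where(hit, MOD_5MC, lower).astype(np.uint8)

    return replace(pool, upper_state=upper, lower_state=lower, dose=dose)


def pool_rates(pool: MoleculeSet, model: TrueRateModel) -> np.ndarray:
    """Per-molecule true rate constants (errors name missing contexts)."""
    rates = model.rate_array(pool.substrate_class)
    return rates[pool.context_idx]


@dataclass
class ReadPairSet:
    """Hairpin bisulfite read pairs: read1 = upper strand, read2 = lower
    strand 5'->3' (i.e. position j of read2 pairs with upper position
    L-1-j).  ``amplicons`` joins them through the hairpin linker."""

    ids: list[str]
    read1: list[str]
    read2: list[str]
    linker: str = DEFAULT_LINKER

    def __len__(self) -> int:
        return len(self.ids)

    def amplicons(self) -> list[str]:
        return [r1 + self.linker + r2 for r1, r2 in zip(self.read1, self.read2)]


def emit_reads(
    pool: MoleculeSet,
    conversion: float = 1.0,
    error_rate: float = 0.0,
    seed: int = 0,
    linker: str = DEFAULT_LINKER,
) -> ReadPairSet:
    """Bisulfite-convert both strands of each molecule and emit a read pair.

    Unmethylated cytosines deaminate (read as T) with probability
    ``conversion``; 5mC and 5hmC are fully protected and read as C.
    Uniform substitution errors are applied at ``error_rate`` afterwards.
    One read pair is emitted per molecule (conservation).
    """
    if not 0 <= conversion <= 1:
        raise ValueError("conversion must be in [0, 1]")
    if not 0 <= error_rate <= 1:
        raise ValueError("error_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n, L = pool.seqs.shape
    p = pool.cpg_pos

    upper = pool.seqs.copy()
    is_c = upper == C
    protected_u = np.zeros((n, L), dtype=bool)
    protected_u[:, p] = pool.upper_state == MOD_5MC
    convert_u = is_c & ~protected_u & (rng.random((n, L)) < conversion)
    upper[convert_u] = 3  # T

    # lower strand 5'->3': reverse complement of the original upper strand
    lower = complement_codes(pool.seqs)[:, ::-1].copy()
    is_c_l = lower == C
    protected_l = np.zeros((n, L), dtype=bool)
    protected_l[:, L - 1 - (p + 1)] = pool.lower_state != MOD_C
    convert_l = is_c_l & ~protected_l & (rng.random((n, L)) < conversion)
    lower[convert_l] = 3

    if error_rate > 0:
        for mat in (upper, lower):
            hit = rng.random((n, L)) < error_rate
            shift = rng.integers(1, 4, size=(n, L), dtype=np.uint8)
            mat[hit] = (mat[hit] + shift[hit]) % 4

    dose = pool.dose if pool.dose is not None else 0.0
    ids = [
        f"mol{i} class={pool.substrate_class} dose={dose:g}"
        for i in range(n)
    ]
    return ReadPairSet(ids, decode_rows(upper), decode_rows(lower), linker=linker)


def write_fastq(path, ids: Sequence[str], seqs: Sequence[str]) -> None:
    """Write reads as 4-line FASTQ records with constant Phred+33 quality."""
    with open(path, "w") as fh:
        for rid, seq in zip(ids, seqs):
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_ground_truth(path, pool: MoleculeSet) -> None:
    """Sidecar TSV: molecule id, context, class, dose, methylated flag."""
    idx = pool.context_idx
    dose = pool.dose if pool.dose is not None else 0.0
    with open(path, "w") as fh:
        fh.write("molecule\tcontext\tclass\tdose\tmethylated\n")
        for i in range(len(pool)):
            fh.write(
                f"mol{i}\t{ALL_NNCGNN[idx[i]]}\t{pool.substrate_class}\t"
                f"{dose:g}\t{int(pool.upper_state[i])}\n"
            )


def to_call_records(pool: MoleculeSet) -> pd.DataFrame:
    """Ground-truth call records (bypassing read emission/reconstruction).

    Same schema as :func:`deepenz.readproc.call_sites`; useful for profile
    analyses where the read round trip is exercised elsewhere.
    """
    p, fl = pool.cpg_pos, pool.flank_len
    windows = decode_rows(pool.seqs[:, p - fl : p + 2 + fl])
    contexts = pool.contexts
    dose = pool.dose if pool.dose is not None else 0.0
    return pd.DataFrame(
        {
            "substrate_class": pool.substrate_class,
            "dose": dose,
            "window": windows,
            "nncgnn": contexts,
            "call_upper": pool.upper_state.astype(np.int8),
            "call_lower": (pool.lower_state != MOD_C).astype(np.int8),
        }
    )


# ---------------------------------------------------------------------------
# long multi-CpG substrate


@dataclass(frozen=True)
class LongSubstrateSpec:
    """A long substrate with multiple CpGs and a per-site lower-strand
    modification pattern ('C' or '5mC')."""

    sequence: str
    cpg_sites: tuple[int, ...]
    pattern: tuple[str, ...]

    def __post_init__(self):
        if list(self.cpg_sites) != sorted(set(self.cpg_sites)):
            raise ValueError("cpg_sites must be strictly increasing")
        if len(self.pattern) != len(self.cpg_sites):
            raise ValueError("pattern and cpg_sites length mismatch")
        for pos in self.cpg_sites:
            if self.sequence[pos : pos + 2] != "CG":
                raise ValueError(f"position {pos} is not a CpG")
        if any(s not in ("C", "5mC") for s in self.pattern):
            raise ValueError("pattern states must be 'C' or '5mC'")

    def fourmer(self, site: int) -> str:
        pos = self.cpg_sites[site]
        return self.sequence[pos - 1 : pos + 3]

    def nncgnn(self, site: int) -> str:
        pos = self.cpg_sites[site]
        return self.sequence[pos - 2 : pos + 4]

    @property
    def hm_sites(self) -> tuple[int, ...]:
        return tuple(i for i, s in enumerate(self.pattern) if s == "5mC")

    @property
    def um_sites(self) -> tuple[int, ...]:
        return tuple(i for i, s in enumerate(self.pattern) if s == "C")


def default_pattern_rule(fourmer: str) -> bool:
    """Hemimethylation rule of the patterned substrate: CCGG or GCGC."""
    return fourmer in ("CCGG", "GCGC")


def generate_long_substrate(
    seed: int = 0,
    n_cpg: int = 44,
    length: int = 349,
    pattern_rule: Callable[[str], bool] | None = None,
    n_match: int = 18,
    max_tries: int = 50,
) -> LongSubstrateSpec:
    """Generate a long substrate with exactly ``n_cpg`` CpGs, ``n_match``
    of which sit in a 4-mer satisfying ``pattern_rule`` (default CCGG/GCGC)
    and carry lower-strand 5mC."""
    if n_cpg < 1:
        raise ValueError("n_cpg must be >= 1")
    if not 0 <= n_match <= n_cpg:
        raise ValueError("n_match out of range")
    rule = pattern_rule if pattern_rule is not None else default_pattern_rule
    rng = np.random.default_rng(seed)

    min_gap = 6
    lo_margin, hi_margin = 3, 4
    span = length - lo_margin - hi_margin - (n_cpg - 1) * min_gap - 2
    if span < 0:
        raise ValueError("cannot place that many CpGs in the sequence")

    for _ in range(max_tries):
        offsets = np.sort(rng.choice(span + 1, size=n_cpg, replace=True))
        sites = lo_margin + offsets + np.arange(n_cpg) * min_gap
        seq = rng.integers(0, 4, size=length, dtype=np.uint8)

        fixed = np.zeros(length, dtype=bool)
        match_sites = set(rng.choice(n_cpg, size=n_match, replace=False).tolist())
        for i, pos in enumerate(sites):
            seq[pos], seq[pos + 1] = C, G
            fixed[pos] = fixed[pos + 1] = True
            if i in match_sites:
                if rng.random() < 0.5:  # CCGG
                    seq[pos - 1], seq[pos + 2] = C, G
                else:  # GCGC; keep -2 non-C and +3 non-G to avoid extra CpGs
                    seq[pos - 1], seq[pos + 2] = G, C
                    if seq[pos - 2] == C:
                        seq[pos - 2] = 3
                    if seq[pos + 3] == G:
                        seq[pos + 3] = 0
                    fixed[pos - 2] = fixed[pos + 3] = True
                fixed[pos - 1] = fixed[pos + 2] = True
            else:
                for _try in range(64):
                    l, r = rng.integers(0, 4, size=2)
                    fm = "ACGT"[l] + "CG" + "ACGT"[r]
                    if not rule(fm):
                        break
                else:
                    raise RuntimeError(
                        "pattern_rule matches every 4-mer but n_match < n_cpg"
                    )
                seq[pos - 1], seq[pos + 2] = l, r
                fixed[pos - 1] = fixed[pos + 2] = True

        # remove spurious CpGs outside the designated sites
        ok = True
        for _pass in range(4):
            cg = np.flatnonzero((seq[:-1] == C) & (seq[1:] == G))
            extra = [i for i in cg if i not in set(sites)]
            if not extra:
                break
            for i in extra:
                if not fixed[i + 1]:
                    seq[i + 1] = 0  # G -> A
                elif not fixed[i]:
                    seq[i] = 3  # C -> T
                else:
                    ok = False
        else:
            ok = False
        if not ok:
            continue
        cg = np.flatnonzero((seq[:-1] == C) & (seq[1:] == G))
        if list(cg) != list(sites):
            continue

        sequence = decode(seq)
        pattern = tuple(
            "5mC" if rule(sequence[pos - 1 : pos + 3]) else "C" for pos in sites
        )
        if sum(s == "5mC" for s in pattern) != n_match:
            continue
        return LongSubstrateSpec(sequence, tuple(int(s) for s in sites), pattern)

    raise RuntimeError("could not satisfy long-substrate constraints; relax them")


def simulate_long_site_series(
    spec: LongSubstrateSpec,
    site_rates: np.ndarray,
    doses: Iterable[float],
    n_reads: int,
    seed: int = 0,
    plateau: float = 1.0,
) -> pd.DataFrame:
    """Per-site methylation fractions over a dose series.

    Counts are binomial draws from the first-order progress curve; one row
    per (site, dose) with columns site, position, nncgnn, lower_state,
    dose, n_methylated, n_reads, fraction.
    """
    site_rates = np.asarray(site_rates, dtype=float)
    if site_rates.shape != (len(spec.cpg_sites),):
        raise ValueError("site_rates must have one entry per CpG site")
    rng = np.random.default_rng(seed)
    rows = []
    for dose in doses:
        p = plateau * -np.expm1(-site_rates * dose)
        m = rng.binomial(n_reads, p)
        for i, pos in enumerate(spec.cpg_sites):
            rows.append(
                {
                    "site": i,
                    "position": pos,
                    "nncgnn": spec.nncgnn(i),
                    "lower_state": spec.pattern[i],
                    "dose": float(dose),
                    "n_methylated": int(m[i]),
                    "n_reads": n_reads,
                    "fraction": m[i] / n_reads,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# synthetic genome + WGBS-style coverage table


@dataclass
class SyntheticGenomeSpec:
    """Stands in for real WGBS input: a random genome whose per-CpG
    methylation mean depends only on the NNCGNN context.

    ``context_effect`` is a scalar, a length-256 array (ALL_NNCGNN order),
    or a mapping context -> mean methylation in [0, 1].  Coverage is
    Poisson with mean ``coverage_mean``.
    """

    n_chroms: int = 2
    chrom_len: int = 20000
    gc_fraction: float = 0.42
    context_effect: object = 0.5
    coverage_mean: float = 30.0

    def effect_array(self) -> np.ndarray:
        eff = self.context_effect
        if np.isscalar(eff):
            arr = np.full(256, float(eff))
        elif isinstance(eff, Mapping):
            arr = np.array([float(eff[ctx]) for ctx in ALL_NNCGNN])
        else:
            arr = np.asarray(eff, dtype=float)
            if arr.shape != (256,):
                raise ValueError("context_effect array must have length 256")
        if ((arr < 0) | (arr > 1)).any():
            raise ValueError("context_effect means must be in [0, 1]")
        return arr


def simulate_genomic_table(
    spec: SyntheticGenomeSpec, seed: int = 0
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random genome and Bismark-coverage-like table (1-based inclusive).

    Returns (genome as chrom -> sequence, coverage DataFrame with columns
    chrom, start, end, meth_pct, count_methylated, count_unmethylated); one
    row per upper-strand CpG cytosine with coverage >= 1.
    """
    if spec.coverage_mean < 0:
        raise ValueError("coverage must be non-negative")
    rng = np.random.default_rng(seed)
    gc = spec.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    effect = spec.effect_array()

    genome: dict[str, str] = {}
    frames = []
    for ci in range(spec.n_chroms):
        chrom = f"chr{ci + 1}"
        seq = rng.choice(4, size=spec.chrom_len, p=probs).astype(np.uint8)
        genome[chrom] = decode(seq)
        pos = np.flatnonzero((seq[:-1] == C) & (seq[1:] == G))
        pos = pos[(pos >= 2) & (pos <= spec.chrom_len - 4)]
        if pos.size == 0:
            continue
        flanks = np.stack([seq[pos - 2], seq[pos - 1], seq[pos + 2], seq[pos + 3]], axis=1)
        idx = context_index_from_codes(flanks)
        cov = rng.poisson(spec.coverage_mean, size=pos.size)
        keep = cov >= 1
        pos, idx, cov = pos[keep], idx[keep], cov[keep]
        meth = rng.binomial(cov, effect[idx])
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": pos + 1,  # 1-based C position
                    "end": pos + 1,
                    "meth_pct": 100.0 * meth / cov,
                    "count_methylated": meth,
                    "count_unmethylated": cov - meth,
                }
            )
        )
    cov_df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=[
                "chrom", "start", "end", "meth_pct",
                "count_methylated", "count_unmethylated",
            ]
        )
    )
    return genome, cov_df


def write_genome_fasta(path, genome: Mapping[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_coverage_table(path, cov: pd.DataFrame) -> None:
    cov.to_csv(path, sep="\t", header=False, index=False)
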