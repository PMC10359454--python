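"""Shared fixtures: simulated experiments reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from deepenz import kinetics, readproc, synthdata
from deepenz._seq import ALL_NNCGNN

RECOVERY_DOSES = (0.3, 0.8, 2.0, 5.0)


def make_recovery_model(seed: int) -> synthdata.TrueRateModel:
    """Ground-truth rates: HM spanning 10-fold, OH and UM spanning 25-fold,
    centered so the shared dose series informs every class."""
    rng = np.random.default_rng(seed)
    spans = {"HM": (0.5, 5.0), "OH": (0.2, 5.0), "UM": (0.1, 2.5)}
    arrays = {
        cls: np.exp(rng.uniform(np.log(lo), np.log(hi), size=256))
        for cls, (lo, hi) in spans.items()
    }
    return synthdata.TrueRateModel.from_arrays(arrays)


def run_read_pipeline(
    model: synthdata.TrueRateModel,
    n_per_class_dose: int,
    doses=RECOVERY_DOSES,
    seed: int = 0,
    classes=("HM", "OH", "UM"),
    conversion: float = 1.0,
    error_rate: float = 0.0,
):
    """Full in-memory chain: pool -> kinetics -> reads -> reconstruct ->
    tabulate.  Returns (records, counts)."""
    root = np.random.default_rng(seed)
    specs = {cls: synthdata.SubstrateSpec(cls) for cls in classes}
    cpg_pos = specs[classes[0]].cpg_pos
    barcodes = {cls: specs[cls].barcode for cls in classes}
    all_records = []
    for dose in doses:
        reads1, reads2 = [], []
        for cls in classes:
            pool = synthdata.generate_pool(
                specs[cls], n_per_class_dose, int(root.integers(2**31))
            )
            pool = synthdata.simulate_kinetics(
                pool, model, dose, int(root.integers(2**31))
            )
            rp = synthdata.emit_reads(
                pool, conversion=conversion, error_rate=error_rate,
                seed=int(root.integers(2**31)),
            )
            reads1 += rp.read1
            reads2 += rp.read2
        records, _qc = readproc.process_read_pairs(
            reads1, reads2, barcodes, cpg_pos=cpg_pos, flank_len=10, dose=dose,
            expected_len=67,
        )
        all_records.append(records)
    records = pd.concat(all_records, ignore_index=True)
    counts = readproc.tabulate_contexts(records)
    return records, counts


@pytest.fixture(scope="session")
def recovery_world():
    """One full-depth recovery experiment: 3 classes x 256 contexts,
    4 doses, 5e4 reads per class and dose, fitted and merged."""
    model = make_recovery_model(seed=2024)
    _records, counts = run_read_pipeline(model, 50_000, seed=11)
    fits = kinetics.fit_experiment(counts, plateau=1.0, min_reads=50)
    rates = kinetics.scale_and_merge([fits])
    true = {cls: model.rate_array(cls) for cls in ("HM", "OH", "UM")}
    return {"model": model, "counts": counts, "rates": rates, "true": true}


@pytest.fixture(scope="session")
def replicate_rates():
    """Four read-level replicates at reduced depth, scaled and merged."""
    model = make_recovery_model(seed=2024)
    fits = []
    for rep in range(4):
        _records, counts = run_read_pipeline(model, 20_000, seed=101 + rep)
        # threshold scaled to the reduced replicate depth (~78 reads per
        # context and dose; the rarest contexts sit near 45)
        fits.append(kinetics.fit_experiment(counts, plateau=1.0, min_reads=30))
    return kinetics.scale_and_merge(fits)


def complete_rate_table(values: dict[str, np.ndarray]) -> pd.DataFrame:
    """RateTable DataFrame from per-class length-256 arrays."""
    rows = []
    for cls, arr in values.items():
        rows += [
            {"substrate_class": cls, "nncgnn": ctx, "k": float(arr[i]),
             "sem": 0.0, "n": 1}
            for i, ctx in enumerate(ALL_NNCGNN)
        ]
    return pd.DataFrame(rows)
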