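"""Relative quantification of transcripts from qPCR threshold cycles.

Expression of a gene of interest relative to a housekeeping gene
(GAPDH in the heme-biosynthesis panel) is

    rel = 2^(-Ct_gene) / 2^(-Ct_hk).

When the gene and the housekeeping gene were amplified on different
plates, each plate's 2^(-Ct) is first divided by the mean 2^(-Ct) of that
plate's calibrator wells (a shared cDNA amplified with the housekeeping
primer on every plate), which cancels constant per-plate cycle offsets
before the ratio is formed.  Technical replicates are averaged on the Ct
scale before the exponential transform (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import CtTable, SchemaError

__all__ = ["RelExpr", "relative_expression"]


@dataclass
class RelExpr:
    gene: str
    sample_id: str
    rel: float
    calibrated: bool

    def __post_init__(self) -> None:
        if not self.rel > 0:
            raise SchemaError(f"RelExpr: rel must be > 0 ({self.gene!r}/{self.sample_id!r})")


def _collapse_ct(group: pd.DataFrame, replicate_scale: str) -> float:
    """Average technical replicates, on the Ct scale by default."""
    cts = group["ct"].to_numpy(dtype=float)
    if replicate_scale == "ct":
        return float(np.mean(cts))
    if replicate_scale == "linear":
        return float(-np.log2(np.mean(2.0 ** (-cts))))
    raise ValueError(f"replicate_scale must be 'ct' or 'linear', got {replicate_scale!r}")


def _calibrator_mean(ct: CtTable, plate_id: str) -> float:
    """Mean calibrator signal of a plate, on the 2^(-Ct) scale."""
    cal = ct.table[(ct.table["plate_id"] == plate_id) & ct.table["is_calibrator"]]
    if cal.empty:
        raise SchemaError(f"qpcr: plate {plate_id!r} has no calibrator wells")
    return float(np.mean(2.0 ** (-cal["ct"].to_numpy(dtype=float))))


def relative_expression(
    ct: CtTable,
    gene: str,
    housekeeping: str = "GAPDH",
    replicate_scale: str = "ct",
) -> list[RelExpr]:
    """Relative expression of ``gene`` vs ``housekeeping`` for every sample
    carrying both measurements.

    Same-plate pairs use the plain ratio of 2^(-Ct).  Cross-plate pairs
    divide each side by its own plate's calibrator mean first; a needed
    plate without calibrator wells is a hard error.
    """
    t = ct.table[~ct.table["is_calibrator"]]
    gene_rows = t[t["gene"] == gene]
    hk_rows = t[t["gene"] == housekeeping]
    if gene_rows.empty:
        raise SchemaError(f"qpcr: no measurements for gene {gene!r}")
    results: list[RelExpr] = []
    for sid in sorted(gene_rows["sample_id"].unique()):
        g_rows = gene_rows[gene_rows["sample_id"] == sid]
        h_rows = hk_rows[hk_rows["sample_id"] == sid]
        if h_rows.empty:
            raise SchemaError(f"qpcr: sample {sid!r} lacks housekeeping gene {housekeeping!r}")
        g_plates = set(g_rows["plate_id"])
        h_plates = set(h_rows["plate_id"])
        if len(g_plates) > 1 or len(h_plates) > 1:
            raise SchemaError(f"qpcr: sample {sid!r}/{gene!r}: replicates span multiple plates")
        g_plate, h_plate = g_plates.pop(), h_plates.pop()
        g_val = 2.0 ** (-_collapse_ct(g_rows, replicate_scale))
        h_val = 2.0 ** (-_collapse_ct(h_rows, replicate_scale))
        calibrated = g_plate != h_plate
        if calibrated:
            g_val /= _calibrator_mean(ct, g_plate)
            h_val /= _calibrator_mean(ct, h_plate)
        results.append(RelExpr(gene=gene, sample_id=sid, rel=g_val / h_val, calibrated=calibrated))
    return results
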