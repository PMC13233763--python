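"""Normalization, scaling, and filtering of LC-MS feature tables.

The carbon-source challenge is normalized in two steps: each analyte
intensity is divided by the co-measured ¹³C yeast internal standard (IS)
for the same metabolite and sample, and the resulting ratio is divided by
the mean ratio of the carbon-source-free HBSS control wells of the same
cell system,

    R[m, s] = (I[m, s] / IS[m, s]) / mean_c∈controls(model(s)) (I[m, c] / IS[m, c]).

The differentiation comparison (AA3 vs AAGly) instead divides raw
intensities by the total DNA (µg) of each well.  Metabolites with missing
values in any condition × cell-model group are removed before multivariate
analysis; the medium carbon sources themselves are excluded to avoid
multicollinearity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import FeatureTable, OcrTrace, SampleMeta, SchemaError

__all__ = [
    "NormalizedTable",
    "normalize_is",
    "normalize_to_control",
    "normalize_per_dna",
    "drop_incomplete",
    "exclude_features",
    "minmax_scale_rows",
    "spare_capacity",
]


@dataclass
class NormalizedTable:
    """Metabolite × sample matrix of unitless ratios or per-DNA intensities,
    with a provenance trail of the steps applied, in order."""

    values: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.validate()

    #: steps that must not be applied twice; exclusion/scaling may repeat
    _ONCE_ONLY = ("is", "per_dna", "control", "drop_incomplete")

    def validate(self) -> None:
        if not self.provenance:
            raise SchemaError("normalized table: provenance must be non-empty")
        steps = [p.split("(")[0] for p in self.provenance if p.split("(")[0] in self._ONCE_ONLY]
        if len(steps) != len(set(steps)):
            raise SchemaError(f"normalized table: step applied twice: {self.provenance}")

    def _derive(self, values: pd.DataFrame, step: str) -> "NormalizedTable":
        return NormalizedTable(values, self.provenance + [step])

    @property
    def metabolites(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def normalize_is(ft: FeatureTable) -> NormalizedTable:
    """Divide each analyte intensity by its internal-standard intensity.

    Missing analyte cells propagate as missing.  An IS that is zero or
    missing where the analyte was measured is a hard error (the ratio
    would be undefined), listing the offending cells.
    """
    if ft.is_intensity is None:
        raise SchemaError("normalize_is: feature table has no IS channel")
    a = ft.analyte.to_numpy()
    s = ft.is_intensity.to_numpy()
    bad = np.argwhere(np.isfinite(a) & ~(s > 0))
    if len(bad):
        cells = [(ft.metabolites[i], ft.samples[j]) for i, j in bad[:10]]
        raise SchemaError(f"normalize_is: IS zero/missing where analyte present at {cells}")
    ratio = pd.DataFrame(a / s, index=ft.analyte.index, columns=ft.analyte.columns)
    return NormalizedTable(ratio, ["is"])


def _group_key(meta: SampleMeta, group_by: list[str]) -> pd.Series:
    idx = meta.indexed()
    return idx[group_by].astype(str).agg("|".join, axis=1)


def normalize_to_control(
    nt: NormalizedTable,
    meta: SampleMeta,
    control_condition: str = "HBSS",
    group_by: list[str] | None = None,
    aggregate: str = "mean",
) -> NormalizedTable:
    """Divide each value by the aggregate (mean, or median) value of the
    control-condition replicates within the same cell-model group.

    Control samples themselves are divided by their own group mean, so a
    group's mean control profile maps to the all-ones vector.  A metabolite
    whose control aggregate is zero or all-missing in a group becomes
    missing for every sample of that group (it is then removed by
    :func:`drop_incomplete`).
    """
    if group_by is None:
        group_by = ["cell_model"]
    if aggregate not in ("mean", "median"):
        raise ValueError(f"aggregate must be 'mean' or 'median', got {aggregate!r}")
    idx = meta.indexed()
    missing_meta = [s for s in nt.samples if s not in idx.index]
    if missing_meta:
        raise SchemaError(f"normalize_to_control: samples without metadata: {missing_meta}")
    keys = _group_key(meta, group_by)
    out = nt.values.copy()
    for key in sorted(keys.unique()):
        group_samples = [s for s in nt.samples if keys.get(s) == key]
        if not group_samples:
            continue
        controls = [s for s in group_samples if idx.loc[s, "condition"] == control_condition]
        if not controls:
            raise SchemaError(
                f"normalize_to_control: group {key!r} has no {control_condition!r} control sample"
            )
        ctrl = nt.values[controls]
        agg = ctrl.mean(axis=1) if aggregate == "mean" else ctrl.median(axis=1)
        denom = agg.where(agg > 0)  # zero or all-missing control -> NaN -> missing
        out[group_samples] = nt.values[group_samples].div(denom, axis=0)
    return nt._derive(out, f"control({control_condition},{aggregate})")


def normalize_per_dna(ft: FeatureTable, meta: SampleMeta) -> NormalizedTable:
    """Divide raw intensities by each sample's total DNA amount (µg)."""
    idx = meta.indexed()
    bad = [s for s in ft.samples if s not in idx.index or pd.isna(idx.loc[s, "dna_ug"])]
    if bad:
        raise SchemaError(f"normalize_per_dna: missing dna_ug for sample(s) {bad}")
    dna = idx.loc[ft.samples, "dna_ug"].astype(float)
    return NormalizedTable(ft.analyte.div(dna, axis=1), ["per_dna"])


def drop_incomplete(
    nt: NormalizedTable,
    meta: SampleMeta,
    by: tuple[str, ...] = ("condition", "cell_model"),
) -> tuple[NormalizedTable, list[str]]:
    """Remove metabolites with any missing value in any experimental group.

    A metabolite survives only if it is observed (non-missing) in every
    ``by`` group (default condition × cell model, the stricter reading).
    Returns the filtered table and the list of removed metabolites.
    """
    keys = _group_key(meta, list(by))
    observed_everywhere = pd.Series(True, index=nt.values.index)
    for key in keys.unique():
        group_samples = [s for s in nt.samples if keys.get(s) == key]
        if group_samples:
            observed_everywhere &= nt.values[group_samples].notna().all(axis=1)
    removed = list(nt.values.index[~observed_everywhere])
    kept = nt.values.loc[observed_everywhere]
    if kept.empty:
        warnings.warn("drop_incomplete: no metabolite observed in every group", stacklevel=2)
    prov = "drop_incomplete"
    if any(p.startswith(prov) for p in nt.provenance):
        # idempotent: re-application removes nothing and is not re-recorded
        return NormalizedTable(kept, nt.provenance), removed
    return nt._derive(kept, prov), removed


def exclude_features(nt: NormalizedTable, names: list[str]) -> NormalizedTable:
    """Remove named metabolites (e.g. the added carbon sources, to avoid
    multicollinearity in PCA/LDA).  Names absent from the table are ignored
    with a warning."""
    present = [n for n in names if n in nt.values.index]
    absent = [n for n in names if n not in nt.values.index]
    if absent:
        warnings.warn(f"exclude_features: not in table, ignored: {absent}", stacklevel=2)
    kept = nt.values.drop(index=present)
    if kept.empty:
        warnings.warn("exclude_features: all metabolites excluded", stacklevel=2)
    return nt._derive(kept, f"exclude({len(present)})")


def minmax_scale_rows(nt: NormalizedTable, constant_row: str = "error") -> NormalizedTable:
    """Map each metabolite row to [0, 1] via (x - min)/(max - min).

    ``constant_row='error'`` (default) rejects rows with min == max;
    ``constant_row='mid'`` maps such rows to 0.5.
    """
    v = nt.values
    lo = v.min(axis=1)
    hi = v.max(axis=1)
    span = hi - lo
    const = span[(span == 0) | span.isna()]
    if len(const):
        if constant_row == "error":
            raise SchemaError(f"minmax_scale_rows: constant row(s) {list(const.index)[:5]}")
        scaled = v.sub(lo, axis=0).div(span.where(span > 0), axis=0)
        scaled.loc[const.index] = v.loc[const.index].notna() * 0.5
        scaled = scaled.where(v.notna())
    else:
        scaled = v.sub(lo, axis=0).div(span, axis=0)
    return nt._derive(scaled, "minmax")


def spare_capacity(tr: OcrTrace) -> float:
    """Mitochondrial spare capacity: mean maximal OCR minus mean basal OCR
    (pmol O₂/min).  A negative value is reported with a warning, not
    clipped."""
    sc = float(np.mean(tr.maximal_ocr) - np.mean(tr.basal_ocr))
    if sc < 0:
        warnings.warn(
            f"spare_capacity: negative spare capacity ({sc:.3g}) for sample {tr.sample_id!r}",
            stacklevel=2,
        )
    return sc
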