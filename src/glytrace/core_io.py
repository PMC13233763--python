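"""Domain types, schema validation, and CSV/TSV readers/writers.

All tabular inputs and outputs of the pipeline pass through the types in
this module.  Missingness is a first-class concept: an empty cell in a CSV
becomes NaN in memory and an empty cell again on write.  Zero is a
legitimate measured intensity and is never conflated with missing — the
downstream rule that removes metabolites unobserved in some experimental
group depends on that distinction.

Files are plain CSV or TSV with a mandatory header row; the delimiter is
inferred from the file extension (``.tsv``/``.tab`` -> tab, else comma).
Floats round-trip at 12 significant digits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CELL_MODELS",
    "CARBON_SOURCES",
    "SchemaError",
    "SampleMeta",
    "FeatureTable",
    "IsotopologueTable",
    "CtTable",
    "OcrTrace",
    "read_feature_table",
    "read_sample_meta",
    "read_isotopologues",
    "read_ct_table",
    "read_ocr_traces",
    "write_table",
]

#: Cell systems from the hepatocyte-maturation study; the list is a default,
#: not a closed enum — validation accepts any non-empty string but the
#: synthetic generator and presets use these four.
CELL_MODELS = ("HepG2", "mHepG2", "HLC_d22", "HLC_d44")

#: Single carbon sources used in the 2 h carbon-source challenge.
CARBON_SOURCES = ("GLN", "LAC", "PYR", "GLU", "GLY", "none")

_FLOAT_FMT = "%.12g"


class SchemaError(ValueError):
    """A table violates its documented schema or an invariant."""


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).lower().endswith((".tsv", ".tab")) else ","


def _require_columns(df: pd.DataFrame, cols: Iterable[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}; got {list(df.columns)}")


# ---------------------------------------------------------------------------
# SampleMeta
# ---------------------------------------------------------------------------

_META_COLUMNS = [
    "sample_id",
    "cell_model",
    "condition",
    "carbon_source",
    "dose_mM",
    "replicate",
    "batch",
    "dna_ug",
    "cell_count",
]


@dataclass
class SampleMeta:
    """Per-sample design factors and normalizers.

    One row per sample: cell model, medium condition (e.g. ``HBSS``,
    ``GLY20``, ``AA3``, ``AAGly``), optional carbon source and dose (mM),
    replicate index (independently processed wells of the same
    differentiation batch), batch label, and optional per-sample
    normalizers (total DNA in µg, cell count).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.table = self.table.copy()
        _require_columns(self.table, _META_COLUMNS, "samples")
        for col in ("dose_mM", "dna_ug", "cell_count"):
            self.table[col] = pd.to_numeric(self.table[col], errors="coerce").astype(float)
        self.table["replicate"] = pd.to_numeric(self.table["replicate"]).astype("int64")
        self.validate()

    def validate(self) -> None:
        t = self.table
        dup = t["sample_id"][t["sample_id"].duplicated()]
        if len(dup):
            raise SchemaError(f"samples: duplicate sample_id {sorted(set(dup))}")
        for _, row in t.iterrows():
            sid = row["sample_id"]
            cs = row["carbon_source"]
            has_cs = isinstance(cs, str) and cs not in ("", "none")
            has_dose = pd.notna(row["dose_mM"])
            if has_cs != has_dose:
                raise SchemaError(
                    f"samples: sample {sid!r}: dose_mM must be present iff "
                    f"carbon_source is set (carbon_source={cs!r}, dose_mM={row['dose_mM']!r})"
                )
            if has_dose and row["dose_mM"] < 0:
                raise SchemaError(f"samples: sample {sid!r}: negative dose_mM")
            if pd.notna(row["dna_ug"]) and not row["dna_ug"] > 0:
                raise SchemaError(f"samples: sample {sid!r}: dna_ug must be > 0")
            rep = row["replicate"]
            if pd.isna(rep) or int(rep) < 1:
                raise SchemaError(f"samples: sample {sid!r}: replicate must be a positive integer")
            cc = row["cell_count"]
            if pd.notna(cc) and not cc > 0:
                raise SchemaError(f"samples: sample {sid!r}: cell_count must be positive")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def indexed(self) -> pd.DataFrame:
        """The metadata table indexed by sample_id."""
        return self.table.set_index("sample_id")

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# FeatureTable
# ---------------------------------------------------------------------------


@dataclass
class FeatureTable:
    """Metabolite × sample intensity matrix, optionally paired with the
    fully ¹³C-labeled yeast internal-standard (IS) channel of the same shape.

    ``analyte`` and ``is_intensity`` are DataFrames indexed by metabolite id
    with one column per sample_id; NaN encodes a missing measurement.
    """

    analyte: pd.DataFrame
    is_intensity: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.analyte = self.analyte.astype(float).rename_axis("metabolite")
        if self.is_intensity is not None:
            self.is_intensity = self.is_intensity.astype(float).rename_axis("metabolite")
        self.validate()

    def validate(self) -> None:
        a = self.analyte
        if a.index.duplicated().any():
            raise SchemaError("features: duplicate metabolite ids")
        if a.columns.duplicated().any():
            raise SchemaError("features: duplicate sample ids")
        neg = np.argwhere((a.to_numpy() < 0) & np.isfinite(a.to_numpy()))
        if len(neg):
            i, j = neg[0]
            raise SchemaError(
                f"features: negative intensity at metabolite {a.index[i]!r}, sample {a.columns[j]!r}"
            )
        if self.is_intensity is not None:
            s = self.is_intensity
            if not (list(s.index) == list(a.index) and list(s.columns) == list(a.columns)):
                raise SchemaError("features: IS channel shape/ids do not match analyte channel")
            bad = np.argwhere(np.isfinite(a.to_numpy()) & ~(s.to_numpy() > 0))
            if len(bad):
                i, j = bad[0]
                raise SchemaError(
                    "features: IS intensity must be strictly positive wherever the analyte "
                    f"is measured; violated at metabolite {a.index[i]!r}, sample {a.columns[j]!r}"
                )

    @property
    def metabolites(self) -> list[str]:
        return list(self.analyte.index)

    @property
    def samples(self) -> list[str]:
        return list(self.analyte.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.analyte.shape


# ---------------------------------------------------------------------------
# IsotopologueTable
# ---------------------------------------------------------------------------


@dataclass
class IsotopologueTable:
    """Raw isotopologue intensities from a tracing experiment.

    Long table with one row per metabolite × sample: columns ``metabolite``,
    ``n_carbons``, ``sample_id``, then ``m0, m1, ... m<K>``; intensities
    beyond the measured isotopologue range of a given metabolite are NaN.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.table = self.table.copy()
        _require_columns(self.table, ["metabolite", "n_carbons", "sample_id", "m0"], "isotopologues")
        self.validate()

    @property
    def m_columns(self) -> list[str]:
        cols = [c for c in self.table.columns if c.startswith("m") and c[1:].isdigit()]
        return sorted(cols, key=lambda c: int(c[1:]))

    def validate(self) -> None:
        t = self.table
        if t.duplicated(subset=["metabolite", "sample_id"]).any():
            dup = t[t.duplicated(subset=["metabolite", "sample_id"])]
            raise SchemaError(
                f"isotopologues: duplicate metabolite×sample rows: "
                f"{list(zip(dup['metabolite'], dup['sample_id']))[:3]}"
            )
        mcols = self.m_columns
        if [int(c[1:]) for c in mcols] != list(range(len(mcols))):
            raise SchemaError(f"isotopologues: m-columns must be contiguous m0..mK, got {mcols}")
        vals = t[mcols].to_numpy(dtype=float)
        if np.any(vals[np.isfinite(vals)] < 0):
            raise SchemaError("isotopologues: negative intensity")
        for _, row in t.iterrows():
            n = int(row["n_carbons"])
            if n < 1:
                raise SchemaError(f"isotopologues: n_carbons must be >= 1 ({row['metabolite']!r})")
            k = self._k_for_row(row, mcols)
            if k > n:
                raise SchemaError(
                    f"isotopologues: {row['metabolite']!r}/{row['sample_id']!r}: highest "
                    f"isotopologue M+{k} exceeds carbon count {n}"
                )

    @staticmethod
    def _k_for_row(row: pd.Series, mcols: Sequence[str]) -> int:
        k = 0
        for c in mcols:
            if pd.notna(row[c]):
                k = int(c[1:])
        return k

    def intensities(self, metabolite: str, sample_id: str) -> tuple[np.ndarray, int]:
        """Return (M+0..M+k intensity vector, n_carbons) for one row."""
        sel = self.table[
            (self.table["metabolite"] == metabolite) & (self.table["sample_id"] == sample_id)
        ]
        if len(sel) != 1:
            raise KeyError(f"no unique row for {metabolite!r}/{sample_id!r}")
        row = sel.iloc[0]
        mcols = self.m_columns
        k = self._k_for_row(row, mcols)
        vec = row[mcols[: k + 1]].to_numpy(dtype=float)
        if np.any(~np.isfinite(vec)):
            raise SchemaError(
                f"isotopologues: {metabolite!r}/{sample_id!r}: gap inside M+0..M+{k}"
            )
        return vec, int(row["n_carbons"])


# ---------------------------------------------------------------------------
# CtTable
# ---------------------------------------------------------------------------


@dataclass
class CtTable:
    """qPCR threshold-cycle table: gene, sample_id, plate_id, ct, is_calibrator."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.table = self.table.copy()
        _require_columns(self.table, ["gene", "sample_id", "plate_id", "ct", "is_calibrator"], "qpcr")
        # CSV round-trip may read booleans back as strings
        if self.table["is_calibrator"].dtype == object:
            self.table["is_calibrator"] = self.table["is_calibrator"].map(
                lambda v: str(v).strip().lower() in ("true", "1", "yes")
            )
        self.validate()

    def validate(self) -> None:
        t = self.table
        if np.any(~(t["ct"].to_numpy(dtype=float) > 0)):
            bad = t[~(t["ct"] > 0)].iloc[0]
            raise SchemaError(f"qpcr: ct must be > 0 (gene {bad['gene']!r}, sample {bad['sample_id']!r})")

    def plates(self) -> list[str]:
        return sorted(set(self.table["plate_id"]))


# ---------------------------------------------------------------------------
# OcrTrace
# ---------------------------------------------------------------------------


@dataclass
class OcrTrace:
    """Oxygen consumption rate measurements (pmol O₂/min) for one sample:
    repeated basal readings and repeated maximal (uncoupled) readings."""

    sample_id: str
    basal_ocr: np.ndarray
    maximal_ocr: np.ndarray

    def __post_init__(self) -> None:
        self.basal_ocr = np.asarray(self.basal_ocr, dtype=float)
        self.maximal_ocr = np.asarray(self.maximal_ocr, dtype=float)
        self.validate()

    def validate(self) -> None:
        for name, vec in (("basal_ocr", self.basal_ocr), ("maximal_ocr", self.maximal_ocr)):
            if vec.size < 1:
                raise SchemaError(f"ocr: {self.sample_id!r}: {name} must have >= 1 measurement")
            if np.any(vec < 0) or np.any(~np.isfinite(vec)):
                raise SchemaError(f"ocr: {self.sample_id!r}: {name} values must be finite and >= 0")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _read_csv(path: str | Path, **kw) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep=_sep_for(path), **kw)


def read_sample_meta(meta_path: str | Path) -> SampleMeta:
    df = _read_csv(meta_path, dtype={"sample_id": str, "batch": str})
    return SampleMeta(df)


def read_feature_table(
    path: str | Path,
    meta_path: str | Path,
    is_path: str | Path | None = None,
) -> tuple[FeatureTable, SampleMeta]:
    """Read a wide feature CSV (col 1 ``metabolite``, then one column per
    sample) plus sample metadata, and optionally the matching IS channel."""
    meta = read_sample_meta(meta_path)

    def _read_wide(p: str | Path) -> pd.DataFrame:
        df = _read_csv(p)
        if df.columns[0] != "metabolite":
            raise SchemaError(f"{p}: first column must be 'metabolite', got {df.columns[0]!r}")
        return df.set_index("metabolite")

    analyte = _read_wide(path)
    unknown = [s for s in analyte.columns if s not in set(meta.sample_ids)]
    if unknown:
        raise SchemaError(f"features: sample columns {unknown} absent from sample metadata")
    is_df = _read_wide(is_path) if is_path is not None else None
    ft = FeatureTable(analyte, is_df)
    return ft, meta


def read_isotopologues(path: str | Path) -> IsotopologueTable:
    return IsotopologueTable(_read_csv(path, dtype={"metabolite": str, "sample_id": str}))


def read_ct_table(path: str | Path) -> CtTable:
    return CtTable(_read_csv(path, dtype={"gene": str, "sample_id": str, "plate_id": str}))


def read_ocr_traces(path: str | Path) -> list[OcrTrace]:
    """Read long OCR CSV: sample_id, phase (basal|maximal), ocr."""
    df = _read_csv(path, dtype={"sample_id": str, "phase": str})
    _require_columns(df, ["sample_id", "phase", "ocr"], "ocr")
    traces = []
    for sid, grp in df.groupby("sample_id", sort=True):
        traces.append(
            OcrTrace(
                sample_id=str(sid),
                basal_ocr=grp.loc[grp["phase"] == "basal", "ocr"].to_numpy(dtype=float),
                maximal_ocr=grp.loc[grp["phase"] == "maximal", "ocr"].to_numpy(dtype=float),
            )
        )
    return traces


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_table(obj, path: str | Path) -> Path:
    """Write any domain table to CSV/TSV so that the matching reader
    reproduces it (floats at 12 significant digits)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sep = _sep_for(path)
    if isinstance(obj, FeatureTable):
        obj.analyte.rename_axis("metabolite").to_csv(path, sep=sep, float_format=_FLOAT_FMT)
    elif isinstance(obj, SampleMeta):
        obj.table.to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)
    elif isinstance(obj, (IsotopologueTable, CtTable)):
        obj.table.to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)
    elif isinstance(obj, list) and all(isinstance(t, OcrTrace) for t in obj):
        rows = []
        for tr in obj:
            rows += [{"sample_id": tr.sample_id, "phase": "basal", "ocr": v} for v in tr.basal_ocr]
            rows += [{"sample_id": tr.sample_id, "phase": "maximal", "ocr": v} for v in tr.maximal_ocr]
        pd.DataFrame(rows).to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)
    else:
        raise TypeError(f"write_table: unsupported object type {type(obj).__name__}")
    return path


def write_is_channel(ft: FeatureTable, path: str | Path) -> Path:
    if ft.is_intensity is None:
        raise ValueError("feature table has no IS channel")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ft.is_intensity.rename_axis("metabolite").to_csv(
        path, sep=_sep_for(path), float_format=_FLOAT_FMT
    )
    return path
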