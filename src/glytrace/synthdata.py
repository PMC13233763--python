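"""Synthetic-data generation with known ground truth.

The generator stands in for the study's raw data and emulates its three
experimental designs:

* **carbon-source challenge** — 4 hepatic cell systems (HepG2, mHepG2,
  day-22 and day-44 HLCs) exposed for 2 h to one of 5 carbon sources
  (GLN, LAC, PYR, GLU, GLY) at 5 or 20 mM, plus a carbon-source-free HBSS
  control; N = 3 independently processed wells; 64-metabolite LC-MS panel
  with a ¹³C-yeast internal-standard channel.  Intensities are log-normal:
  ``analyte = 10^(μ_m + effect + ε)`` with ε ~ N(0, noise_sd²).
* **differentiation comparison** — AA3 (1.5 mM glycine) vs AAGly (268 mM
  glycine) media, N = 5, with per-sample total-DNA normalizers.
* **[2-¹³C]glycine tracing** — true MIDs from the atom-fate forward model,
  convolved with ¹³C natural abundance and sampled multinomially at a
  configurable ion count (or analytically at infinite ions).
* **qPCR** — plate-structured Ct values with a per-plate cycle offset and
  calibrator wells, from known expression ratios.

Everything is deterministic given (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import CELL_MODELS, CtTable, FeatureTable, IsotopologueTable, SampleMeta
from .sirm import MODEL_METABOLITES, P13_DEFAULT, TracerModel, forward_convolve_na, predict_mids

__all__ = [
    "GLYCINE_MW",
    "KEY_PANEL",
    "TRACER_PRESETS",
    "GroundTruth",
    "carbon_source_ground_truth",
    "aa_design_ground_truth",
    "sirm_ground_truth",
    "gen_feature_experiment",
    "gen_sirm_experiment",
    "gen_qpcr",
    "glycine_molarity",
]

#: Molecular weight of glycine (g/mol).
GLYCINE_MW = 75.07

#: Named metabolites of the semi-targeted central-carbon panel; the panel
#: is padded with generic fillers to 64 features.
KEY_PANEL = [
    "ATP", "UTP", "GTP", "CTP", "citrate", "NAD+", "NADP+",
    "glycine", "serine", "methionine", "SAM", "SAH", "ALA", "PBG",
    "succinyl-CoA", "G6P", "UDP-glucose", "glutamate", "fumarate", "malate",
]

CARBON_CONDITIONS = [
    f"{src}{dose}" for src in ("GLN", "LAC", "PYR", "GLU", "GLY") for dose in (5, 20)
]

#: Tracer scenarios matching the two feeding regimes.  Values live here in
#: config, not in test assertions.
TRACER_PRESETS: dict[str, TracerModel] = {
    # low glycine: SHMT2 route dominates, one-carbon pool stays unlabeled
    "AA3-like": TracerModel(g=0.55, f=0.0, s=0.73, m=0.0, q=0.0, a=0.3),
    # high glycine: full tracer uptake, GCS feeds a hot one-carbon pool
    "AAGly-like-HLC": TracerModel(g=1.0, f=0.70, s=0.70, m=0.30, q=0.90, a=0.5),
    "AAGly-like-mHepG2": TracerModel(g=1.0, f=0.85, s=0.82, m=0.02, q=0.5, a=0.5),
}


def _panel(n_metabolites: int) -> list[str]:
    fillers = [f"met{i:03d}" for i in range(1, n_metabolites - len(KEY_PANEL) + 1)]
    return (KEY_PANEL + fillers)[:n_metabolites]


@dataclass
class GroundTruth:
    """Serializable generator configuration + truth.

    ``effects`` maps ``"metabolite|cell_model|condition"`` (metabolite may
    be ``*`` for all) to a log10 intensity effect.  ``tracer_params`` maps
    condition name to the true atom-fate parameters.  ``qpcr_ratios`` maps
    ``"gene|sample_id"`` to a true expression ratio vs housekeeping;
    ``plate_offsets`` maps plate id to a constant cycle offset.
    """

    seed: int = 0
    cell_models: tuple[str, ...] = CELL_MODELS
    conditions: tuple[str, ...] = ("HBSS", *CARBON_CONDITIONS)
    control_condition: str = "HBSS"
    n_replicates: int = 3
    n_metabolites: int = 64
    noise_sd: float = 0.1
    effects: dict[str, float] = field(default_factory=dict)
    tracer_params: dict[str, TracerModel] = field(default_factory=dict)
    ion_counts: int | None = 10_000
    p13: float = P13_DEFAULT
    qpcr_ratios: dict[str, float] = field(default_factory=dict)
    plate_offsets: dict[str, float] = field(default_factory=dict)
    ct_noise_sd: float = 0.0
    ct_housekeeping: float = 20.0

    @property
    def metabolites(self) -> list[str]:
        return _panel(self.n_metabolites)

    def effect(self, metabolite: str, model: str, condition: str) -> float:
        return self.effects.get(
            f"{metabolite}|{model}|{condition}", self.effects.get(f"*|{model}|{condition}", 0.0)
        )

    def to_json(self, path: str | Path | None = None) -> str:
        d = {
            k: v
            for k, v in self.__dict__.items()
            if k not in ("tracer_params", "cell_models", "conditions")
        }
        d["cell_models"] = list(self.cell_models)
        d["conditions"] = list(self.conditions)
        d["tracer_params"] = {c: tm.to_dict() for c, tm in self.tracer_params.items()}
        text = json.dumps(d, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        d["cell_models"] = tuple(d["cell_models"])
        d["conditions"] = tuple(d["conditions"])
        d["tracer_params"] = {c: TracerModel(**p) for c, p in d["tracer_params"].items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# Preset ground truths
# ---------------------------------------------------------------------------


def carbon_source_ground_truth(
    seed: int = 0,
    signal_condition: str = "GLY20",
    signal_model: str = "HLC_d44",
    signal_strength: float = 1.0,
    noise_sd: float = 0.1,
) -> GroundTruth:
    """Carbon-source challenge with a class signal in one condition column.

    One cell model responds to one condition with a +``signal_strength``
    log10 effect on every metabolite (default: day-44 HLCs under 20 mM
    glycine, emulating the study's finding that this condition separated
    the cell systems); every other condition is pure noise around the
    control level.
    """
    gt = GroundTruth(seed=seed, noise_sd=noise_sd)
    gt.effects[f"*|{signal_model}|{signal_condition}"] = float(signal_strength)
    return gt


def aa_design_ground_truth(seed: int = 0, noise_sd: float = 0.1) -> GroundTruth:
    """AA3 vs AAGly differentiation design (N = 5, DNA normalizers)."""
    gt = GroundTruth(
        seed=seed,
        cell_models=("mHepG2", "HLC_d44"),
        conditions=("AA3", "AAGly"),
        control_condition="AA3",
        n_replicates=5,
        noise_sd=noise_sd,
    )
    # glycine and one-carbon intermediates up under high glycine
    for met, eff in (("glycine", 1.2), ("serine", 0.5), ("SAM", 0.3), ("PBG", 0.6)):
        gt.effects[f"{met}|HLC_d44|AAGly"] = eff
        gt.effects[f"{met}|mHepG2|AAGly"] = eff / 2
    return gt


def sirm_ground_truth(seed: int = 0, ion_counts: int | None = 10_000) -> GroundTruth:
    """Tracing design: AA3 vs AAGly scenarios from the named presets."""
    return GroundTruth(
        seed=seed,
        cell_models=("mHepG2", "HLC_d44"),
        conditions=("AA3", "AAGly"),
        n_replicates=5,
        ion_counts=ion_counts,
        tracer_params={
            "AA3": TRACER_PRESETS["AA3-like"],
            "AAGly": TRACER_PRESETS["AAGly-like-HLC"],
        },
    )


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def _parse_condition(cond: str) -> tuple[str, float | None]:
    for src in ("GLN", "LAC", "PYR", "GLU", "GLY"):
        if cond.startswith(src) and cond[len(src):].isdigit():
            return src, float(cond[len(src):])
    return "none", None


def gen_feature_experiment(gt: GroundTruth) -> tuple[FeatureTable, SampleMeta]:
    """Generate the LC-MS feature table (analyte + IS channels) and sample
    metadata for the configured design."""
    rng = np.random.default_rng(gt.seed)
    mets = gt.metabolites
    mu = rng.uniform(4.5, 6.5, size=len(mets))
    is_base = 10 ** rng.uniform(4.0, 6.0, size=len(mets))

    meta_rows = []
    analyte = {}
    is_chan = {}
    for model in gt.cell_models:
        for cond in gt.conditions:
            src, dose = _parse_condition(cond)
            for rep in range(1, gt.n_replicates + 1):
                sid = f"{model}_{cond}_r{rep}"
                eps = rng.normal(0.0, gt.noise_sd, size=len(mets))
                eps_is = rng.normal(0.0, gt.noise_sd / 2, size=len(mets))
                eff = np.array([gt.effect(m, model, cond) for m in mets])
                analyte[sid] = 10 ** (mu + eff + eps)
                is_chan[sid] = is_base * 10 ** eps_is
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "cell_model": model,
                        "condition": cond,
                        "carbon_source": src,
                        "dose_mM": dose,
                        "replicate": rep,
                        "batch": "B1",
                        "dna_ug": float(np.round(rng.uniform(1.0, 3.0), 4)),
                        "cell_count": int(rng.integers(50_000, 200_000)),
                    }
                )
    meta = SampleMeta(pd.DataFrame(meta_rows))
    ft = FeatureTable(
        pd.DataFrame(analyte, index=mets),
        pd.DataFrame(is_chan, index=mets),
    )
    return ft, meta


def gen_sirm_experiment(gt: GroundTruth) -> IsotopologueTable:
    """Generate raw isotopologue intensities for the tracing design.

    For each condition × replicate and model metabolite: the true MID from
    the atom-fate forward model is convolved with ¹³C natural abundance,
    then sampled as a multinomial with ``ion_counts`` ions (or used
    analytically when ``ion_counts`` is None), and scaled to an arbitrary
    intensity unit.
    """
    if not gt.tracer_params:
        raise ValueError("gen_sirm_experiment: ground truth has no tracer_params")
    rng = np.random.default_rng(gt.seed)
    rows = []
    for cond, tm in sorted(gt.tracer_params.items()):
        mids = predict_mids(tm)
        for rep in range(1, gt.n_replicates + 1):
            sid = f"{cond}_r{rep}"
            for met, mid in mids.items():
                conv = forward_convolve_na(mid, gt.p13)
                if gt.ion_counts is None:
                    intensities = conv * 1e6
                else:
                    counts = rng.multinomial(gt.ion_counts, conv / conv.sum())
                    intensities = counts * float(rng.uniform(50.0, 150.0))
                # instrument reports M+0..M+2 at most for this panel
                k_obs = min(len(conv) - 1, 2)
                row = {"metabolite": met, "n_carbons": mid.n_carbons, "sample_id": sid}
                for i in range(k_obs + 1):
                    row[f"m{i}"] = float(intensities[i])
                rows.append(row)
    df = pd.DataFrame(rows)
    mcols = sorted([c for c in df.columns if c.startswith("m") and c[1:].isdigit()],
                   key=lambda c: int(c[1:]))
    return IsotopologueTable(df[["metabolite", "n_carbons", "sample_id"] + mcols])


def gen_qpcr(gt: GroundTruth, genes: tuple[str, ...] = ("ALAS1", "ALAD", "UROS", "CPOX", "FECH"),
             housekeeping: str = "GAPDH", n_calibrator_wells: int = 3) -> CtTable:
    """Generate a plate-structured Ct table from known expression ratios.

    The housekeeping gene runs on plate ``P0``; each target gene runs on
    its own plate with a constant cycle offset; every plate carries
    replicated calibrator wells (the shared cDNA amplified with the
    housekeeping primer).  ``Ct = ct_hk - log2(ratio) + offset + noise``.
    """
    rng = np.random.default_rng(gt.seed + 1)
    sample_ids = sorted({k.split("|", 1)[1] for k in gt.qpcr_ratios}) or [
        f"{m}_{c}_r{r}"
        for m in gt.cell_models
        for c in gt.conditions
        for r in range(1, gt.n_replicates + 1)
    ]
    rows = []

    def _cal_wells(plate: str, offset: float) -> None:
        for w in range(n_calibrator_wells):
            rows.append(
                {
                    "gene": housekeeping,
                    "sample_id": f"calibrator_{plate}_{w + 1}",
                    "plate_id": plate,
                    "ct": gt.ct_housekeeping + offset + rng.normal(0.0, gt.ct_noise_sd),
                    "is_calibrator": True,
                }
            )

    hk_plate = "P0"
    hk_offset = gt.plate_offsets.get(hk_plate, 0.0)
    _cal_wells(hk_plate, hk_offset)
    for sid in sample_ids:
        rows.append(
            {
                "gene": housekeeping,
                "sample_id": sid,
                "plate_id": hk_plate,
                "ct": gt.ct_housekeeping + hk_offset + rng.normal(0.0, gt.ct_noise_sd),
                "is_calibrator": False,
            }
        )
    for gi, gene in enumerate(genes):
        plate = f"P{gi + 1}"
        offset = gt.plate_offsets.get(plate, 0.0)
        _cal_wells(plate, offset)
        for sid in sample_ids:
            ratio = gt.qpcr_ratios.get(f"{gene}|{sid}", 1.0)
            ct_val = gt.ct_housekeeping - np.log2(ratio) + offset + rng.normal(0.0, gt.ct_noise_sd)
            rows.append(
                {"gene": gene, "sample_id": sid, "plate_id": plate, "ct": ct_val,
                 "is_calibrator": False}
            )
    return CtTable(pd.DataFrame(rows))


def glycine_molarity(
    supplement_g_per_L: float,
    base_mM: float,
    mw_g_per_mol: float = GLYCINE_MW,
    rounded: bool = False,
) -> float:
    """Final glycine molarity (mM) of a medium with a mass/volume
    supplement on top of a base concentration: 1000·g/L / MW + base.

    2% (m/v) glycine (20 g/L) on a 1.5 mM base gives 267.9, reported as
    268 mM when ``rounded``.
    """
    if supplement_g_per_L < 0 or base_mM < 0 or mw_g_per_mol <= 0:
        raise ValueError("glycine_molarity: inputs must be positive")
    mM = 1000.0 * supplement_g_per_L / mw_g_per_mol + base_mM
    return float(round(mM)) if rounded else mM
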