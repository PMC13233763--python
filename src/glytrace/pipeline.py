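"""End-to-end pipeline orchestration with config, logging and run manifests.

A run is a list of named steps (simulate, preprocess, mvstats, sirm_correct,
sirm_fit, qpcr) executed in order inside one output directory.  The manifest
written at the end records the config, the seed, package version, per-step
timing, and a SHA-256 hash of every file read or written, so a run can be
re-executed and verified exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .core_io import (
    SchemaError,
    read_ct_table,
    read_feature_table,
    read_isotopologues,
    write_is_channel,
    write_table,
)
from .preprocess import (
    drop_incomplete,
    exclude_features,
    normalize_is,
    normalize_per_dna,
    normalize_to_control,
    NormalizedTable,
)
from .multivariate import build_lda_design, lda_importance, pca, top_k
from .qpcr import relative_expression
from .sirm import MAX_LABEL, P13_DEFAULT, correct_natural_abundance, fit_tracer_model, Mid
from .synthdata import (
    GroundTruth,
    aa_design_ground_truth,
    carbon_source_ground_truth,
    gen_feature_experiment,
    gen_qpcr,
    gen_sirm_experiment,
    sirm_ground_truth,
)

__all__ = ["RunConfig", "run", "correct_isotopologue_table", "mids_by_sample", "pooled_mids"]

log = logging.getLogger(__name__)

_KNOWN_STEPS = ("simulate", "preprocess", "mvstats", "sirm_correct", "sirm_fit", "qpcr")

PRESETS = {
    "carbon-source": carbon_source_ground_truth,
    "aa3-vs-aagly": aa_design_ground_truth,
    "sirm": sirm_ground_truth,
}


@dataclass
class RunConfig:
    """Ordered step list with parameters, plus output directory and seed."""

    steps: list[dict]
    outdir: str = "glytrace_run"
    seed: int = 0

    def __post_init__(self) -> None:
        for step in self.steps:
            if len(step) != 1:
                raise SchemaError(f"run config: each step must be a single-key mapping, got {step}")
            (name,) = step
            if name not in _KNOWN_STEPS:
                raise SchemaError(f"run config: unknown step {name!r}; known: {_KNOWN_STEPS}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(steps=d["steps"], outdir=d.get("outdir", "glytrace_run"), seed=d.get("seed", 0))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump({"steps": self.steps, "outdir": self.outdir, "seed": self.seed})
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# SIRM helpers shared by CLI and pipeline
# ---------------------------------------------------------------------------


def correct_isotopologue_table(
    iso, p13: float = P13_DEFAULT, max_label: dict[str, int] | None = None
) -> pd.DataFrame:
    """Natural-abundance-correct every row of an isotopologue table.

    Returns a long DataFrame (metabolite, sample_id, isotopologue,
    fraction).  ``max_label`` caps the tracer-reachable support per
    metabolite (defaults to the atom-fate model's reach where known).
    """
    caps = dict(MAX_LABEL)
    if max_label:
        caps.update(max_label)
    out = []
    for _, row in iso.table.iterrows():
        met, sid = row["metabolite"], row["sample_id"]
        raw, n = iso.intensities(met, sid)
        mid = correct_natural_abundance(raw, n, p13=p13, max_label=caps.get(met), metabolite=met)
        for i, frac in enumerate(mid.fractions):
            out.append(
                {"metabolite": met, "sample_id": sid, "n_carbons": n,
                 "isotopologue": f"M+{i}", "fraction": frac}
            )
    return pd.DataFrame(out)


def mids_by_sample(corrected: pd.DataFrame) -> dict[str, dict[str, Mid]]:
    """Regroup the corrected long table into per-sample MID dictionaries."""
    res: dict[str, dict[str, Mid]] = {}
    for (sid, met), grp in corrected.groupby(["sample_id", "metabolite"], sort=True):
        grp = grp.sort_values("isotopologue", key=lambda s: s.str.slice(2).astype(int))
        frac = grp["fraction"].to_numpy(dtype=float)
        res.setdefault(sid, {})[met] = Mid(met, int(grp["n_carbons"].iloc[0]), frac / frac.sum())
    return res


def pooled_mids(corrected: pd.DataFrame, samples: list[str]) -> dict[str, Mid]:
    """Mean MID over a group of samples (e.g. replicates of one condition)."""
    sub = corrected[corrected["sample_id"].isin(samples)]
    res = {}
    for met, grp in sub.groupby("metabolite", sort=True):
        wide = grp.pivot_table(index="sample_id", columns="isotopologue", values="fraction")
        wide = wide[sorted(wide.columns, key=lambda c: int(c[2:]))]
        mean = wide.mean(axis=0).to_numpy(dtype=float)
        res[met] = Mid(met, int(grp["n_carbons"].iloc[0]), mean / mean.sum())
    return res


# ---------------------------------------------------------------------------
# Step execution
# ---------------------------------------------------------------------------


def _step_simulate(params: dict, outdir: Path, seed: int, artifacts: dict) -> None:
    preset = params.get("preset", "carbon-source")
    if preset not in PRESETS:
        raise SchemaError(f"simulate: unknown preset {preset!r}; known: {sorted(PRESETS)}")
    gt = PRESETS[preset](seed=seed)
    gt.to_json(outdir / "ground_truth.json")
    if preset == "sirm":
        iso = gen_sirm_experiment(gt)
        write_table(iso, outdir / "isotopologues.csv")
        artifacts["isotopologues"] = iso
    else:
        ft, meta = gen_feature_experiment(gt)
        write_table(ft, outdir / "features.csv")
        write_is_channel(ft, outdir / "features_is.csv")
        write_table(meta, outdir / "samples.csv")
        artifacts["features"], artifacts["meta"] = ft, meta
    ct = gen_qpcr(gt)
    write_table(ct, outdir / "qpcr.csv")
    artifacts["ct"] = ct
    artifacts["ground_truth"] = gt


def _step_preprocess(params: dict, outdir: Path, seed: int, artifacts: dict) -> None:
    if "features" in params:
        ft, meta = read_feature_table(
            params["features"], params["samples"], params.get("is")
        )
    else:
        ft, meta = artifacts["features"], artifacts["meta"]
    steps = params.get("steps", ["is", "control", "drop_incomplete"])
    nt: NormalizedTable | None = None
    removed: list[str] = []
    for s in steps:
        if s == "is":
            nt = normalize_is(ft)
        elif s == "per_dna":
            nt = normalize_per_dna(ft, meta)
        elif s == "control":
            nt = normalize_to_control(
                nt, meta,
                control_condition=params.get("control_condition", "HBSS"),
                aggregate=params.get("aggregate", "mean"),
            )
        elif s == "drop_incomplete":
            nt, removed = drop_incomplete(nt, meta)
        else:
            raise SchemaError(f"preprocess: unknown step {s!r}")
    if params.get("exclude"):
        nt = exclude_features(nt, list(params["exclude"]))
    out = outdir / "normalized.csv"
    nt.values.rename_axis("metabolite").to_csv(out, float_format="%.12g")
    (outdir / "normalized_provenance.json").write_text(
        json.dumps({"provenance": nt.provenance, "removed_metabolites": removed}, indent=2)
    )
    artifacts["normalized"], artifacts["meta"] = nt, meta


def _step_mvstats(params: dict, outdir: Path, seed: int, artifacts: dict) -> None:
    nt, meta = artifacts["normalized"], artifacts["meta"]
    method = params.get("method", "lda")
    if method == "pca":
        res = pca(nt, center=params.get("center", True), scale=params.get("scale", False),
                  transform=params.get("transform", "none"))
        res.scores.rename_axis("sample_id").to_csv(outdir / "pca_scores.csv", float_format="%.12g")
        res.loadings.rename_axis("metabolite").to_csv(
            outdir / "pca_loadings.csv", float_format="%.12g"
        )
        artifacts["pca"] = res
    elif method == "lda":
        design, labels, row_info = build_lda_design(nt, meta)
        imp = lda_importance(design, labels, weight_by_trace=params.get("weight_by_trace", True),
                             row_info=row_info)
        pd.DataFrame(
            {"condition": imp.ranking,
             "score": [imp.condition_scores[c] for c in imp.ranking]}
        ).to_csv(outdir / "importance.csv", index=False, float_format="%.12g")
        pd.DataFrame(
            sorted(imp.metabolite_scores.items(), key=lambda kv: (-kv[1], kv[0])),
            columns=["metabolite", "score"],
        ).to_csv(outdir / "metabolite_importance.csv", index=False, float_format="%.12g")
        (outdir / "lda_report.json").write_text(json.dumps({
            "ranking": imp.ranking,
            "proportion_of_trace": list(map(float, imp.proportion_of_trace)),
            "top10_metabolites": top_k(imp, 10) if imp.metabolite_scores else [],
        }, indent=2))
        artifacts["lda"] = imp
    else:
        raise SchemaError(f"mvstats: unknown method {method!r}")


def _step_sirm_correct(params: dict, outdir: Path, seed: int, artifacts: dict) -> None:
    iso = (read_isotopologues(params["isotopologues"]) if "isotopologues" in params
           else artifacts["isotopologues"])
    corrected = correct_isotopologue_table(iso, p13=params.get("p13", P13_DEFAULT))
    corrected.to_csv(outdir / "mids.csv", index=False, float_format="%.12g")
    artifacts["mids"] = corrected


def _step_sirm_fit(params: dict, outdir: Path, seed: int, artifacts: dict) -> None:
    corrected = (pd.read_csv(params["mids"]) if "mids" in params else artifacts["mids"])
    groups: dict[str, list[str]] = {}
    for sid in sorted(corrected["sample_id"].unique()):
        cond = sid.rsplit("_r", 1)[0]
        groups.setdefault(cond, []).append(sid)
    fits = {}
    for cond, samples in groups.items():
        report = fit_tracer_model(pooled_mids(corrected, samples), seed=seed)
        fits[cond] = report.to_dict()
    (outdir / "theta.json").write_text(json.dumps(fits, indent=2))
    artifacts["fits"] = fits


def _step_qpcr(params: dict, outdir: Path, seed: int, artifacts: dict) -> None:
    ct = read_ct_table(params["ct"]) if "ct" in params else artifacts["ct"]
    housekeeping = params.get("housekeeping", "GAPDH")
    genes = params.get("genes") or sorted(
        set(ct.table.loc[~ct.table["is_calibrator"], "gene"]) - {housekeeping}
    )
    rows = []
    for gene in genes:
        for r in relative_expression(ct, gene, housekeeping):
            rows.append({"gene": r.gene, "sample_id": r.sample_id, "rel": r.rel,
                         "calibrated": r.calibrated})
    pd.DataFrame(rows).to_csv(outdir / "relexpr.csv", index=False, float_format="%.12g")
    artifacts["relexpr"] = rows


_STEP_FNS = {
    "simulate": _step_simulate,
    "preprocess": _step_preprocess,
    "mvstats": _step_mvstats,
    "sirm_correct": _step_sirm_correct,
    "sirm_fit": _step_sirm_fit,
    "qpcr": _step_qpcr,
}


def run(config: RunConfig) -> dict:
    """Execute the configured steps in order; return (and write) the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # preflight: file inputs must exist unless produced by an earlier step
    produced = any(next(iter(s)) == "simulate" for s in config.steps)
    for step in config.steps:
        (name,), params = step.keys(), next(iter(step.values())) or {}
        for key in ("features", "samples", "is", "isotopologues", "ct", "mids"):
            if key in params and not Path(params[key]).exists():
                if not produced:
                    raise SchemaError(f"run: step {name!r} input {params[key]!r} does not exist "
                                      "and no simulate step precedes it")
    artifacts: dict = {}
    manifest: dict = {"version": __version__, "seed": config.seed, "steps": []}
    for step in config.steps:
        (name,) = step
        params = step[name] or {}
        t0 = time.perf_counter()
        log.info("run: step %s", name)
        try:
            _STEP_FNS[name](params, outdir, config.seed, artifacts)
        except Exception as exc:
            raise RuntimeError(f"run: step {name!r} failed: {exc}") from exc
        manifest["steps"].append(
            {"name": name, "params": params, "seconds": round(time.perf_counter() - t0, 4)}
        )
    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
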