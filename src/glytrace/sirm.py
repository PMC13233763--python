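"""Stable-isotope-resolved metabolomics: natural-abundance correction,
mass-isotopomer algebra, and a forward atom-fate model of [2-¹³C]glycine
routing through one-carbon and heme metabolism.

Natural-abundance correction
----------------------------
Measured isotopologue intensities are inflated by the ~1.07% natural
abundance of ¹³C: a molecule with j tracer-derived labels among n carbons
appears at mass M+i (i >= j) with probability Binom(n-j, p13) of i-j
natural-abundance hits.  Stacking these binomials columnwise gives a
lower-triangular correction matrix C; the tracer-only mass-isotopomer
distribution (MID) is recovered by non-negative least squares,
min ||C a - x||₂ s.t. a >= 0, then renormalizing a to fractions.  When only
M+0..M+k of an n-carbon metabolite is measured (k < n), the observed rows
of C are used with the tracer-reachable label support capped at K.

Atom-fate model
---------------
The tracer is glycine labeled at its alpha carbon (C2).  Six pool-level
parameters, all in [0, 1], describe its routing over the labeling window:

====  =========================================================
g     intracellular glycine M+1 enrichment (tracer uptake)
f     ¹³C enrichment of the 5,10-CH₂-THF one-carbon pool (GCS)
s     fraction of the serine pool newly made from glycine (SHMT)
m     fraction of methionine remethylated via 5-CH₃-THF
q     SAM turnover fraction (methionine adenosylation)
a     fraction of the ALA pool newly made (glycine + succinyl-CoA)
====  =========================================================

Serine made by SHMT combines a glycine backbone (label with prob. g) with
a one-carbon unit (label with prob. f), so newly made serine is M+1 if
exactly one precursor carbon is labeled and M+2 if both are.  Methionine
gains at most one label via remethylation (m·f); SAM inherits it with
turnover q; SAH is unlabeled because the labeled methyl departs during
transmethylation.  ALA keeps only the glycine alpha carbon (the carboxyl
carbon is lost in the ALAS decarboxylation; succinyl-CoA is assumed
unlabeled), so ALA is at most M+1, and PBG — the condensation of two ALA —
is their MID convolution, at most M+2.

The estimator inverts this forward model: bounded weighted least squares
of predicted against observed MIDs over θ ∈ [0,1]⁶ with seeded multistart,
flagging parameters that are at a bound or whose residual profile is flat
as not identified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, nnls
from scipy.stats import binom

from .core_io import SchemaError

__all__ = [
    "P13_DEFAULT",
    "Mid",
    "CorrectionMatrix",
    "TracerModel",
    "FitReport",
    "build_correction_matrix",
    "forward_convolve_na",
    "correct_natural_abundance",
    "convolve_mids",
    "predict_mids",
    "fit_tracer_model",
    "MODEL_METABOLITES",
    "MAX_LABEL",
]

log = logging.getLogger(__name__)

#: Natural abundance of ¹³C.
P13_DEFAULT = 0.0107

#: Metabolites of the glycine/one-carbon/heme atom-fate model with their
#: carbon counts and the maximum tracer-derived label count.
MODEL_METABOLITES = {
    "glycine": 2,
    "serine": 3,
    "methionine": 5,
    "SAM": 15,
    "SAH": 14,
    "ALA": 5,
    "PBG": 10,
}
MAX_LABEL = {
    "glycine": 1,
    "serine": 2,
    "methionine": 1,
    "SAM": 1,
    "SAH": 1,
    "ALA": 1,
    "PBG": 2,
}


@dataclass
class Mid:
    """Mass-isotopomer distribution: fractions over M+0..M+k, summing to 1."""

    metabolite: str
    n_carbons: int
    fractions: np.ndarray

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.validate()

    def validate(self) -> None:
        f = self.fractions
        if f.ndim != 1 or len(f) < 1 or len(f) - 1 > self.n_carbons:
            raise SchemaError(
                f"mid {self.metabolite!r}: support M+0..M+{len(f) - 1} exceeds "
                f"{self.n_carbons} carbons"
            )
        if np.any(f < -1e-12):
            raise SchemaError(f"mid {self.metabolite!r}: negative fraction")
        if abs(f.sum() - 1.0) > 1e-9:
            raise SchemaError(f"mid {self.metabolite!r}: fractions sum to {f.sum()!r}, not 1")


@dataclass
class CorrectionMatrix:
    """Lower-triangular natural-abundance convolution matrix.

    ``C[i, j] = Binom(n - j, p13).pmf(i - j)`` for i >= j: the probability
    that a molecule with j tracer labels appears at M+i through natural
    ¹³C in its remaining n - j carbons.
    """

    n_carbons: int
    p13: float
    matrix: np.ndarray

    def __post_init__(self) -> None:
        C = self.matrix
        if not np.allclose(C, np.tril(C)):
            raise SchemaError("correction matrix must be lower-triangular")
        if np.any(C.sum(axis=0) > 1 + 1e-9):
            raise SchemaError("correction matrix columns must sum to <= 1")


def build_correction_matrix(n_carbons: int, p13: float = P13_DEFAULT) -> CorrectionMatrix:
    """Build the (n+1) × (n+1) natural-abundance correction matrix."""
    if n_carbons < 1:
        raise ValueError("n_carbons must be >= 1")
    if not 0 <= p13 < 1:
        raise ValueError("p13 must be in [0, 1)")
    n = n_carbons
    C = np.zeros((n + 1, n + 1))
    if p13 < 1e-15:  # no measurable natural abundance: identity
        np.fill_diagonal(C, 1.0)
    else:
        for j in range(n + 1):
            C[j:, j] = binom.pmf(np.arange(n - j + 1), n - j, p13)
    return CorrectionMatrix(n_carbons=n, p13=p13, matrix=C)


def forward_convolve_na(mid: Mid, p13: float = P13_DEFAULT) -> np.ndarray:
    """Convolve a tracer-only MID with ¹³C natural abundance (the
    brute-force oracle for the correction): out[i] = Σ_j mid[j]·
    Binom(n-j, p13).pmf(i-j).  Returns a length n+1 vector summing to 1."""
    C = build_correction_matrix(mid.n_carbons, p13).matrix
    padded = np.zeros(mid.n_carbons + 1)
    padded[: len(mid.fractions)] = mid.fractions
    return C @ padded


def correct_natural_abundance(
    raw: np.ndarray,
    n_carbons: int,
    p13: float = P13_DEFAULT,
    max_label: int | None = None,
    metabolite: str = "",
) -> Mid:
    """Recover the tracer-only MID from raw isotopologue intensities.

    Solves min ||C a - x||₂ subject to a >= 0 over a₀..a_K, where K is the
    maximum tracer-reachable label count (default: the highest observed
    isotopologue).  When fewer isotopologues than carbons are measured,
    only the observed rows of C are used.  The solution is renormalized to
    fractions.
    """
    x = np.asarray(raw, dtype=float)
    if x.ndim != 1 or len(x) < 1:
        raise ValueError("raw must be a 1-D intensity vector M+0..M+k")
    if np.any(x < 0):
        raise SchemaError(f"correct_natural_abundance: negative intensity in {metabolite!r}")
    if not np.any(x > 0):
        raise SchemaError(f"correct_natural_abundance: all-zero intensity vector for {metabolite!r}")
    k = len(x) - 1
    if k > n_carbons:
        raise SchemaError(f"correct_natural_abundance: M+{k} exceeds {n_carbons} carbons")
    K = k if max_label is None else min(max_label, k)
    C = build_correction_matrix(n_carbons, p13).matrix
    C_obs = C[: k + 1, : K + 1]
    a, _ = nnls(C_obs, x)
    total = a.sum()
    if total <= 0:
        raise SchemaError(f"correct_natural_abundance: degenerate solution for {metabolite!r}")
    return Mid(metabolite=metabolite, n_carbons=n_carbons, fractions=a / total)


def convolve_mids(x: Mid, y: Mid, metabolite: str = "") -> Mid:
    """MID of a condensation product: out[k] = Σ_{i+j=k} x[i]·y[j]
    (carbon counts add)."""
    frac = np.convolve(x.fractions, y.fractions)
    return Mid(
        metabolite=metabolite or f"{x.metabolite}+{y.metabolite}",
        n_carbons=x.n_carbons + y.n_carbons,
        fractions=frac,
    )


@dataclass
class TracerModel:
    """Route-enrichment and pool-turnover parameters of the glycine
    atom-fate network (all in [0, 1]; see module docstring)."""

    g: float = 0.0  # glycine M+1 enrichment
    f: float = 0.0  # one-carbon (5,10-CH2-THF) pool enrichment
    s: float = 0.0  # serine fraction newly synthesized from glycine
    m: float = 0.0  # methionine fraction remethylated
    q: float = 0.0  # SAM turnover fraction
    a: float = 0.0  # ALA fraction newly synthesized

    PARAM_NAMES = ("g", "f", "s", "m", "q", "a")

    def __post_init__(self) -> None:
        for name in self.PARAM_NAMES:
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SchemaError(f"TracerModel: {name} = {v!r} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, theta: np.ndarray) -> "TracerModel":
        return cls(**dict(zip(cls.PARAM_NAMES, np.clip(theta, 0.0, 1.0))))

    def to_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in self.PARAM_NAMES}


def predict_mids(tm: TracerModel) -> dict[str, Mid]:
    """Forward atom-fate model: tracer-only MIDs of the model metabolites.

    glycine    (1-g, g)
    serine     s·((1-g)(1-f), g(1-f)+(1-g)f, g·f) + (1-s)·(1, 0, 0)
    methionine (1 - m·f, m·f)
    SAM        (1 - q·m·f, q·m·f)
    SAH        (1, 0)                       # labeled methyl departs
    ALA        (1 - a·g, a·g)               # glycine C1 lost at ALAS
    PBG        ALA ⊗ ALA                    # two ALA condense to one PBG
    """
    g, f, s, m, q, a = tm.as_array()
    mids = {
        "glycine": Mid("glycine", MODEL_METABOLITES["glycine"], [1 - g, g]),
        "serine": Mid(
            "serine",
            MODEL_METABOLITES["serine"],
            [
                s * (1 - g) * (1 - f) + (1 - s),
                s * (g * (1 - f) + (1 - g) * f),
                s * g * f,
            ],
        ),
        "methionine": Mid("methionine", MODEL_METABOLITES["methionine"], [1 - m * f, m * f]),
        "SAM": Mid("SAM", MODEL_METABOLITES["SAM"], [1 - q * m * f, q * m * f]),
        "SAH": Mid("SAH", MODEL_METABOLITES["SAH"], [1.0, 0.0]),
        "ALA": Mid("ALA", MODEL_METABOLITES["ALA"], [1 - a * g, a * g]),
    }
    mids["PBG"] = convolve_mids(mids["ALA"], mids["ALA"], metabolite="PBG")
    return mids


@dataclass
class FitReport:
    theta: "TracerModel"
    residual_norm: float
    residuals: dict[str, np.ndarray]
    identified: dict[str, bool]
    flags: dict[str, str] = field(default_factory=dict)
    n_starts: int = 0

    def to_dict(self) -> dict:
        return {
            "theta": self.theta.to_dict(),
            "residual_norm": self.residual_norm,
            "identified": self.identified,
            "flags": self.flags,
            "n_starts": self.n_starts,
        }


def _stack_residuals(theta: np.ndarray, observed: dict[str, Mid], weights: dict[str, float]):
    pred = predict_mids(TracerModel.from_array(theta))
    res = []
    for name in sorted(observed):
        obs = observed[name]
        p = pred[name].fractions
        o = np.zeros(max(len(p), len(obs.fractions)))
        o[: len(obs.fractions)] = obs.fractions
        pp = np.zeros_like(o)
        pp[: len(p)] = p
        res.append(weights.get(name, 1.0) * (pp - o))
    return np.concatenate(res)


def fit_tracer_model(
    observed: dict[str, Mid],
    weights: dict[str, float] | None = None,
    n_starts: int = 16,
    seed: int = 0,
) -> FitReport:
    """Estimate the atom-fate parameters from observed (corrected) MIDs.

    Bounded least squares of predicted against observed fractions over
    θ ∈ [0, 1]⁶, with ``n_starts`` seeded multistarts; ties are broken by
    lowest residual, then lexicographically smallest θ.  Parameters at a
    bound or with a flat residual profile are flagged as not identified
    and pinned to 0 for determinism.

    ``observed`` must contain at least glycine and serine; metabolites
    outside the model vocabulary are rejected.
    """
    unknown = sorted(set(observed) - set(MODEL_METABOLITES))
    if unknown:
        raise SchemaError(f"fit_tracer_model: unknown metabolite(s) {unknown}")
    if not {"glycine", "serine"} <= set(observed):
        estimable = sorted(set(observed) & set(MODEL_METABOLITES))
        raise SchemaError(
            "fit_tracer_model: need at least glycine and serine MIDs; "
            f"got {estimable or 'nothing usable'}"
        )
    weights = weights or {}
    rng = np.random.default_rng(seed)
    starts = [np.full(6, 0.5)] + [rng.uniform(0, 1, 6) for _ in range(max(0, n_starts - 1))]
    tols = dict(xtol=1e-12, ftol=1e-12, gtol=1e-12)

    best = None
    for x0 in starts:
        sol = least_squares(
            _stack_residuals, x0, bounds=(0.0, 1.0), args=(observed, weights),
            method="trf", **tols,
        )
        key = (round(float(sol.cost), 12), tuple(np.round(sol.x, 9)))
        if best is None or key < best[0]:
            best = (key, sol)
    theta_hat = np.clip(best[1].x, 0.0, 1.0)
    cost = float(best[1].cost)

    # A parameter the optimizer drives against a bound tends to stall a
    # hair inside it; snap near-bound parameters onto the bound and refit
    # the remaining free ones, keeping the snap only if the fit does not
    # degrade.  Repeat until stable.
    fixed: set[int] = set()
    for _ in range(len(theta_hat)):
        near = [
            i for i in range(len(theta_hat))
            if i not in fixed and min(theta_hat[i], 1 - theta_hat[i]) < 1e-3
        ]
        if not near:
            break
        trial = theta_hat.copy()
        for i in near:
            trial[i] = float(np.round(trial[i]))
        free = [i for i in range(len(trial)) if i not in fixed and i not in near]

        def _masked(x_free, template=trial, free_idx=tuple(free)):
            full = template.copy()
            full[list(free_idx)] = x_free
            return _stack_residuals(full, observed, weights)

        if free:
            sub = least_squares(
                _masked, trial[free], bounds=(0.0, 1.0), method="trf", **tols
            )
            trial[free] = sub.x
            trial_cost = float(sub.cost)
        else:
            trial_cost = 0.5 * float(np.sum(_stack_residuals(trial, observed, weights) ** 2))
        if trial_cost <= cost * 1.10 + 1e-10:
            theta_hat, cost = trial, trial_cost
            fixed |= set(near)
        else:
            break

    # identifiability: flat residual profile (tiny Jacobian column) or at-bound
    J = _finite_diff_jacobian(theta_hat, observed, weights)
    colnorm = np.linalg.norm(J, axis=0)
    scale = max(1.0, float(colnorm.max()))
    identified, flags = {}, {}
    for i, name in enumerate(TracerModel.PARAM_NAMES):
        if colnorm[i] < 1e-7 * scale:
            identified[name] = False
            flags[name] = "flat_profile"
            theta_hat[i] = 0.0
        elif theta_hat[i] < 1e-9 or theta_hat[i] > 1 - 1e-9:
            identified[name] = False
            flags[name] = "at_bound"
            theta_hat[i] = float(np.round(theta_hat[i]))
        else:
            identified[name] = True

    tm = TracerModel.from_array(theta_hat)
    pred = predict_mids(tm)
    residuals = {}
    for name in sorted(observed):
        p = pred[name].fractions
        o = observed[name].fractions
        L = max(len(p), len(o))
        residuals[name] = np.pad(p, (0, L - len(p))) - np.pad(o, (0, L - len(o)))
    rnorm = float(np.sqrt(sum(np.sum(r**2) for r in residuals.values())))
    if not any(identified.values()):
        log.warning("fit_tracer_model: no parameter identified by the supplied metabolites")
    return FitReport(
        theta=tm,
        residual_norm=rnorm,
        residuals=residuals,
        identified=identified,
        flags=flags,
        n_starts=len(starts),
    )


def _finite_diff_jacobian(theta, observed, weights, h=1e-6):
    r0 = _stack_residuals(theta, observed, weights)
    J = np.zeros((len(r0), len(theta)))
    for i in range(len(theta)):
        tp = theta.copy()
        step = h if theta[i] + h <= 1 else -h
        tp[i] += step
        J[:, i] = (_stack_residuals(tp, observed, weights) - r0) / step
    return J
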