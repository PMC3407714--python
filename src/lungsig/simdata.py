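"""Synthetic NSCLC cohort generator with planted gene programs.

Cohorts carry two latent per-patient traits: a prognostic score (drives
disease-specific hazard in everyone) and a responder score (drives a
hazard *reduction*, but only under adjuvant chemotherapy). A configurable
block of genes loads on each trait, with one gene shared between the two
programs by default, mirroring the single-gene overlap seen between
real prognostic and chemo-response signatures. Survival times come from
inverse-transform sampling of a Weibull (default exponential) hazard

    h(t | i) = h0 * k * t^(k-1) * exp(b_risk*risk_i + sum_c b_c*z_ic
                                      - b_resp * treated_i * resp_i)

with independent exponential censoring plus administrative censoring at
the follow-up horizon. The responder trait Z is a two-component Gaussian
mixture — a latent molecular subtype with a responder mode (Z around
+1) and a non-responder mode (Z around -1) — and the hazard uses its
rectification ``resp = max(Z,0)``: treatment benefit is confined to the
latent responder subgroup, while the planted response *genes* load on
the continuous Z, so the subtype is detectable from expression in both
subgroups.

The baseline hazard can be calibrated by bisection so that the expected
observed event fraction at a stated horizon matches a target (cohorts in
this disease area are usually described by their 5-year disease-specific
death fraction, not by a hazard).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, LungsigError

# Marginal clinical covariate distributions typical of resected
# stage I-III adenocarcinoma series (proportions used as defaults).
STAGE_PROBS = {"IA": 0.33, "IB": 0.36, "IIA": 0.15, "IIB": 0.03, "IIIA": 0.09, "IIIB": 0.04}
SMOKING_PROBS = {"never": 0.10, "former": 0.55, "current": 0.08, "unknown": 0.27}
GRADE_PROBS = {1: 0.14, 2: 0.50, 3: 0.36}


@dataclass
class SimConfig:
    """Configuration for one simulated cohort.

    The survival-relevant effects are log-hazard scales: ``prognostic_effect``
    per unit latent risk, ``response_effect`` the log-hazard *reduction*
    under treatment per unit latent responder score. ``baseline_hazard``
    is events/month; leave ``None`` to calibrate it to
    ``event_target_fraction`` observed events by ``event_horizon_months``.
    """

    n_samples: int = 332
    n_genes: int = 1000
    n_prognostic_genes: int = 30
    n_response_genes: int = 37
    overlap_genes: int = 1
    prognostic_effect: float = 0.6
    response_effect: float = 2.4
    response_floor_slope: float = 0.0
    responder_fraction: float = 0.55
    responder_separation: float = 2.0
    responder_within_sd: float = 0.5
    gene_loading: float = 1.0
    gene_noise_sd: float = 0.4
    baseline_hazard: float | None = None
    baseline_shape: float = 0.75  # Weibull shape; <1 = early-peaked recurrence hazard
    censoring_rate: float = 0.006
    followup_horizon_months: float = 120.0
    covariate_effects: dict = field(default_factory=dict)
    event_target_fraction: float = 0.37
    event_horizon_months: float = 60.0
    treatment_arms: str = "none"  # "none" | "randomized"
    p_treated: float = 0.5
    seed: int = 0

    def validate(self):
        for name in ("n_samples", "n_genes", "n_prognostic_genes", "n_response_genes"):
            if int(getattr(self, name)) <= 0:
                raise LungsigError(f"invalid SimConfig.{name}: must be positive")
        if self.overlap_genes < 0 or self.overlap_genes > min(
            self.n_prognostic_genes, self.n_response_genes
        ):
            raise LungsigError("invalid SimConfig.overlap_genes")
        if (
            self.n_prognostic_genes + self.n_response_genes - self.overlap_genes
            > self.n_genes
        ):
            raise LungsigError(
                "invalid SimConfig.n_genes: planted gene sets exceed n_genes"
            )
        if not (0.0 < self.event_target_fraction < 1.0):
            raise LungsigError("invalid SimConfig.event_target_fraction: must be in (0,1)")
        if self.baseline_hazard is not None and self.baseline_hazard <= 0:
            raise LungsigError("invalid SimConfig.baseline_hazard: must be positive")
        if self.baseline_shape <= 0:
            raise LungsigError("invalid SimConfig.baseline_shape: must be positive")
        if self.censoring_rate < 0:
            raise LungsigError("invalid SimConfig.censoring_rate: must be >= 0")
        if self.treatment_arms not in ("none", "randomized"):
            raise LungsigError("invalid SimConfig.treatment_arms: none|randomized")
        if not (0.0 <= self.p_treated <= 1.0):
            raise LungsigError("invalid SimConfig.p_treated: must be in [0,1]")
        if not (0.0 <= self.response_floor_slope < 1.0):
            raise LungsigError("invalid SimConfig.response_floor_slope: must be in [0,1)")
        return self


@dataclass
class SimTruth:
    """Ground truth for a simulated cohort."""

    prognostic_gene_ids: list
    response_gene_ids: list
    latent_risk: np.ndarray
    latent_response: np.ndarray  # rectified responder score used in the hazard
    latent_response_raw: np.ndarray  # underlying Gaussian the genes load on
    baseline_hazard: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "prognostic_gene_ids": list(self.prognostic_gene_ids),
                "response_gene_ids": list(self.response_gene_ids),
                "latent_risk": np.asarray(self.latent_risk).tolist(),
                "latent_response": np.asarray(self.latent_response).tolist(),
                "latent_response_raw": np.asarray(self.latent_response_raw).tolist(),
                "baseline_hazard": self.baseline_hazard,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        obj = json.loads(text)
        return cls(
            obj["prognostic_gene_ids"],
            obj["response_gene_ids"],
            np.asarray(obj["latent_risk"]),
            np.asarray(obj["latent_response"]),
            np.asarray(obj["latent_response_raw"]),
            obj["baseline_hazard"],
        )


def planted_gene_ids(config: SimConfig):
    """Deterministic planted gene id sets (independent of the seed).

    The response block starts ``overlap_genes`` before the end of the
    prognostic block, so the two programs share exactly that many genes.
    """
    ids = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    prog = ids[: config.n_prognostic_genes]
    start = config.n_prognostic_genes - config.overlap_genes
    resp = ids[start : start + config.n_response_genes]
    return ids, prog, resp


def _covariate_lp(clinical: pd.DataFrame, effects: dict) -> np.ndarray:
    """Mean-centered covariate contribution to the log hazard."""
    lp = np.zeros(len(clinical))
    for name, beta in effects.items():
        if name == "age":
            x = clinical["age"].to_numpy(dtype=float)
        elif name == "gender":
            x = clinical["gender"].eq("male").to_numpy(dtype=float)
        elif name == "stage":
            x = (
                clinical["stage"]
                .map({"IA": 1, "IB": 1, "IIA": 2, "IIB": 2, "IIIA": 3, "IIIB": 3, "IV": 4})
                .to_numpy(dtype=float)
            )
        elif name == "tumor_size_gt3":
            x = (clinical["tumor_size_cm"].to_numpy(dtype=float) > 3.0).astype(float)
        else:
            raise LungsigError(f"invalid SimConfig.covariate_effects key: {name!r}")
        lp += float(beta) * (x - x.mean())
    return lp


def _expected_event_fraction(h0, shape, lp, cens_rate, horizon):
    """Expected fraction observed to fail by ``horizon`` under the model."""
    lam = h0 * np.exp(lp)
    if shape == 1.0:
        tot = lam + cens_rate
        return float(np.mean(lam / tot * (1.0 - np.exp(-tot * horizon))))
    # Weibull event hazard, exponential censoring: quadrature after the
    # substitution u = t^shape, which removes the t^(shape-1) singularity
    u = np.linspace(0.0, horizon**shape, 513)
    dens = (
        lam[:, None]
        * np.exp(-lam[:, None] * u[None, :])
        * np.exp(-cens_rate * u[None, :] ** (1.0 / shape))
    )
    return float(np.mean(np.trapezoid(dens, u, axis=1)))


def calibrate_baseline_hazard(
    lp: np.ndarray,
    target_fraction: float,
    horizon: float,
    shape: float = 1.0,
    censoring_rate: float = 0.0,
    tol: float = 0.005,
) -> float:
    """Bisection on h0 so the expected observed event fraction hits target."""
    lo, hi = 1e-8, 5.0
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        f = _expected_event_fraction(mid, shape, lp, censoring_rate, horizon)
        if abs(f - target_fraction) <= tol * 0.2:
            return mid
        if f < target_fraction:
            lo = mid
        else:
            hi = mid
    return np.sqrt(lo * hi)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def simulate_cohort(config: SimConfig):
    """Generate (ExpressionMatrix, clinical DataFrame, SimTruth).

    Deterministic: identical config (including seed) gives bitwise
    identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    # --- clinical covariates (marginals typical of resected adenocarcinoma)
    age = np.round(_truncated_normal(rng, 65.0, 10.0, 35.0, 90.0, n), 1)
    gender = np.where(rng.random(n) < 0.5, "female", "male")
    stage = rng.choice(list(STAGE_PROBS), p=list(STAGE_PROBS.values()), size=n)
    grade = rng.choice(list(GRADE_PROBS), p=list(GRADE_PROBS.values()), size=n)
    smoking = rng.choice(list(SMOKING_PROBS), p=list(SMOKING_PROBS.values()), size=n)
    tumor_size = np.round(np.exp(rng.normal(np.log(3.0), 0.45, size=n)), 1)
    if config.treatment_arms == "randomized":
        treated = rng.random(n) < config.p_treated
    else:
        treated = np.zeros(n, dtype=bool)

    # --- latent traits and expression
    latent_risk = rng.standard_normal(n)
    # responder trait: two-component mixture (a latent molecular subtype),
    # responder mode centered at +sep/2, non-responder mode at -sep/2
    is_responder = rng.random(n) < config.responder_fraction
    centers = np.where(is_responder, 0.5, -0.5) * config.responder_separation
    latent_resp_raw = centers + config.responder_within_sd * rng.standard_normal(n)
    latent_resp = np.maximum(latent_resp_raw, 0.0) + config.response_floor_slope * np.minimum(
        latent_resp_raw, 0.0
    )

    gene_ids, prog_genes, resp_genes = planted_gene_ids(config)
    prog_set, resp_set = set(prog_genes), set(resp_genes)
    base_mean = rng.normal(8.0, 1.0, size=config.n_genes)
    expr = np.empty((config.n_genes, n))
    lam, sd = config.gene_loading, config.gene_noise_sd
    for i, g in enumerate(gene_ids):
        row = base_mean[i] + rng.normal(0.0, sd if (g in prog_set or g in resp_set) else 1.0, n)
        if g in prog_set:
            row = row + lam * latent_risk
        if g in resp_set:
            row = row + lam * latent_resp_raw
        expr[i] = row

    clinical = pd.DataFrame(
        {
            "age": age,
            "gender": gender,
            "stage": stage,
            "grade": grade,
            "smoking": smoking,
            "histology": "adenocarcinoma",
            "treatment": np.where(treated, "ACT", "OBS" if config.treatment_arms == "randomized" else "none"),
            "radiotherapy": 0,
            "tumor_size_cm": tumor_size,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    # --- survival
    lp = (
        config.prognostic_effect * latent_risk
        + _covariate_lp(clinical, config.covariate_effects)
        - config.response_effect * treated.astype(float) * latent_resp
    )
    if config.baseline_hazard is None:
        h0 = calibrate_baseline_hazard(
            lp,
            config.event_target_fraction,
            config.event_horizon_months,
            config.baseline_shape,
            config.censoring_rate,
        )
    else:
        h0 = float(config.baseline_hazard)
    u = rng.random(n)
    t_event = (-np.log(u) / (h0 * np.exp(lp))) ** (1.0 / config.baseline_shape)
    if config.censoring_rate > 0:
        t_cens = -np.log(rng.random(n)) / config.censoring_rate
    else:
        rng.random(n)  # keep the stream layout fixed across configs
        t_cens = np.full(n, np.inf)
    t_admin = config.followup_horizon_months
    followup = np.minimum(np.minimum(t_event, t_cens), t_admin)
    event = (t_event <= t_cens) & (t_event <= t_admin)
    clinical["followup_months"] = np.round(followup, 3)
    clinical["dss_event"] = event.astype(int)

    em = ExpressionMatrix(
        pd.DataFrame(np.round(expr, 4), index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids),
        pd.Series("SIM", index=sample_ids),
    )
    truth = SimTruth(prog_genes, resp_genes, latent_risk, latent_resp, latent_resp_raw, h0)
    return em, clinical, truth


def mask_platform(expr: ExpressionMatrix, keep, seed: int = 0) -> ExpressionMatrix:
    """Restrict a matrix to a platform-like subset of its genes.

    ``keep`` is either a fraction in (0, 1] — ``floor(keep * n_genes)``
    genes retained, chosen reproducibly under ``seed`` — or an explicit
    gene list. Sample set and gene order are unchanged.
    """
    genes = list(expr.values.index)
    if isinstance(keep, (int, float)) and not isinstance(keep, bool):
        frac = float(keep)
        if not (0.0 < frac <= 1.0):
            raise LungsigError("keep_fraction must be in (0, 1]")
        if frac == 1.0:
            return ExpressionMatrix(expr.values.copy(), expr.platform.copy())
        k = int(np.floor(frac * len(genes)))
        if k == 0:
            raise LungsigError("keep_fraction leaves no scorable genes")
        rng = np.random.default_rng(seed)
        chosen = set(rng.choice(len(genes), size=k, replace=False).tolist())
        retained = [g for i, g in enumerate(genes) if i in chosen]
    else:
        retained = [g for g in genes if g in set(keep)]
        if not retained:
            raise LungsigError("gene list leaves no scorable genes")
    return ExpressionMatrix(expr.values.loc[retained].copy(), expr.platform.copy())


def config_to_dict(config: SimConfig) -> dict:
    return asdict(config)
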