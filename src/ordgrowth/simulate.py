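"""Synthetic longitudinal HIV-cohort generator.

Generates cohorts with the statistical structure the downstream analysis
assumes: a closed cohort of seroconverting women followed over irregular
visits, a four-category ordinal immunological outcome driven by a
cumulative-logit model with correlated subject-level random intercept and
time slope, combination-ART initiation triggered by the first visit at
which the stage falls below the CD4-500 band, and clinical laboratory
panels with a planted factor structure.

Defaults emulate the cohort this analysis was designed for: 219 subjects,
follow-up between 0 and 13.13 years with median ~2.12 years (per-subject
lognormal follow-up duration, Poisson visit process within it), baseline
covariate frequencies matching the published baseline table, thresholds
exp(delta) = (0.02, 19.87, 24.51) and random-effect covariance
[[12.21, -0.36], [-0.36, 0.02]] on the latent logit scale.

All randomness flows from a single seed through a splittable
``numpy.random.SeedSequence``; visits and outcomes use one sub-stream per
subject, so per-subject output is invariant to subject reordering.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .model import ModelSpec, ParamVector, NonMonotoneError

__all__ = [
    "SimConfig",
    "default_true_params",
    "default_npo_true_params",
    "default_model_spec",
    "default_covariate_specs",
    "default_panel",
    "simulate_subjects",
    "simulate_visits",
    "simulate_ordinal_outcomes",
    "simulate_clinical_panel",
    "simulate_cohort",
    "write_cohort",
    "CD4_SIM_BANDS",
]

#: stage -> CD4 sampling interval; WHO bands with invented caps (1200 above,
#: 50 below) so that simulated counts stay clinically plausible.
CD4_SIM_BANDS: dict[int, tuple[float, float]] = {
    1: (500.0, 1200.0),
    2: (350.0, 500.0),
    3: (200.0, 350.0),
    4: (50.0, 200.0),
}

_BASE_COLUMNS = [
    "subject_id",
    "time",
    "phase",
    "stage",
    "cd4",
    "on_cart",
    "log_vl",
    "qol_phys",
    "qol_psych",
    "qol_indep",
    "qol_social",
]


def default_covariate_specs() -> list[dict]:
    """Covariate distribution descriptors matching the baseline table.

    Category probabilities are the published baseline frequencies over 219
    subjects; continuous defaults (weight, viral load, QoL domains) use
    published medians/IQRs where available, otherwise field-plausible
    values documented in the methods note.
    """
    return [
        {"name": "age_group", "level": "subject", "dist": {"kind": "categorical", "levels": ["18-20", "21-39", ">=40"], "probs": [29 / 219, 178 / 219, 12 / 219]}},
        {"name": "education", "level": "subject", "dist": {"kind": "categorical", "levels": ["<=Gr8", "Gr9-10", ">=Gr11"], "probs": [16 / 219, 50 / 219, 153 / 219]}},
        {"name": "marital", "level": "subject", "dist": {"kind": "categorical", "levels": ["single", "stable", "many"], "probs": [34 / 219, 174 / 219, 11 / 219]}},
        {"name": "sex_under_alcohol", "level": "subject", "dist": {"kind": "categorical", "levels": [0, 1], "probs": [197 / 219, 22 / 219]}},
        {"name": "weight", "level": "subject", "dist": {"kind": "normal", "mean": 65.0, "sd": 12.0, "clip": [35.0, 150.0]}},
        {"name": "log_vl", "level": "visit", "dist": {"kind": "normal", "mean": 4.46, "sd": 0.90, "clip": [1.47, 6.81]}},
        {"name": "qol_phys", "level": "visit", "dist": {"kind": "normal", "mean": 14.0, "sd": 2.5, "clip": [4.0, 20.0]}},
        {"name": "qol_psych", "level": "visit", "dist": {"kind": "normal", "mean": 14.0, "sd": 2.5, "clip": [4.0, 20.0]}},
        {"name": "qol_indep", "level": "visit", "dist": {"kind": "normal", "mean": 14.0, "sd": 2.5, "clip": [4.0, 20.0]}},
        {"name": "qol_social", "level": "visit", "dist": {"kind": "normal", "mean": 14.0, "sd": 2.5, "clip": [4.0, 20.0]}},
    ]


def default_true_params() -> ParamVector:
    """Proportional-odds generating parameters on the published scale.

    Thresholds are ln of the published exponentiated thresholds
    (0.02, 19.87, 24.51); the random-effect covariance is the published
    random-components block.  Coefficients are ln of published odds ratios
    for cART (1.28) and viral load (0.52) and physical QoL (1.11), with a
    +0.15/year latent time trend.  Continuous covariates enter centered
    (log_vl_c, qol_phys_c) so the thresholds keep their marginal meaning.
    """
    return ParamVector(
        thresholds=np.log([0.02, 19.87, 24.51]),
        shared_coefs=np.array([0.15, 0.25, -0.65, 0.10]),
        category_coefs=np.zeros((0, 3)),
        re_cov=np.array([[12.21, -0.36], [-0.36, 0.02]]),
    )


def default_npo_true_params() -> ParamVector:
    """Non-proportional variant: cART gets one coefficient per logit
    (ln of the published 1.42, 1.27, 1.28)."""
    return ParamVector(
        thresholds=np.log([0.02, 19.87, 24.51]),
        shared_coefs=np.array([0.15, -0.65, 0.10]),
        category_coefs=np.log([[1.42, 1.27, 1.28]]),
        re_cov=np.array([[12.21, -0.36], [-0.36, 0.02]]),
    )


def default_model_spec(npo_cart: bool = False) -> ModelSpec:
    """Model specification matching :func:`default_true_params`."""
    if npo_cart:
        return ModelSpec(shared=("time", "log_vl_c", "qol_phys_c"), npo=("on_cart",))
    return ModelSpec(shared=("time", "on_cart", "log_vl_c", "qol_phys_c"), npo=())


def default_panel() -> dict:
    """A white-cell-style laboratory panel with the published loading block.

    Six variables on three factors (granulocyte, mononuclear, eosinophil
    components); noise SDs are sqrt(1 - communality) so simulated variables
    have roughly unit variance.
    """
    variables = ["leucocyte", "neutrophils", "monocytes", "lymphocytes", "basophils", "eosinophils"]
    loadings = np.array(
        [
            [0.925, 0.0, 0.0],
            [0.936, 0.0, 0.0],
            [0.635, 0.0, 0.0],
            [0.0, 0.838, 0.0],
            [0.0, 0.616, 0.0],
            [0.0, 0.0, 0.947],
        ]
    )
    noise_sd = np.sqrt(1.0 - (loadings**2).sum(axis=1))
    return {"variables": variables, "loadings": loadings, "noise_sd": noise_sd}


@dataclass
class SimConfig:
    """Configuration of one synthetic cohort.

    ``followup`` describes the per-subject follow-up duration:
    ``{"kind": "lognormal", "median": 2.12, "log_sd": 1.61}`` (truncated at
    ``max_followup``) or ``{"kind": "fixed"}`` (everyone followed for
    ``max_followup``).  ``cart_rule`` is the stage threshold triggering
    cART at the *next* visit (2 = CD4 below 500).  ``center`` maps
    covariate names to centering constants; a centered copy ``<name>_c`` is
    added to the table.
    """

    n_subjects: int = 219
    max_followup: float = 13.13
    visit_rate: float = 4.0
    followup: dict = field(default_factory=lambda: {"kind": "lognormal", "median": 2.12, "log_sd": 1.61})
    true_params: ParamVector = field(default_factory=default_true_params)
    model_spec: ModelSpec = field(default_factory=default_model_spec)
    covariate_specs: list = field(default_factory=default_covariate_specs)
    center: dict = field(default_factory=lambda: {"log_vl": 4.46, "qol_phys": 14.0})
    cart_rule: int = 2
    panel: dict | None = field(default_factory=default_panel)
    with_cd4: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.max_followup < 0:
            raise ValueError("max_followup must be >= 0")
        if self.visit_rate <= 0:
            raise ValueError("visit_rate must be > 0")
        self.true_params.validate()


def _draw(rng: np.random.Generator, desc: dict, size: int):
    kind = desc["kind"]
    if kind == "categorical":
        return rng.choice(np.asarray(desc["levels"], dtype=object), size=size, p=desc["probs"])
    if kind == "normal":
        x = rng.normal(desc["mean"], desc["sd"], size=size)
        if "clip" in desc:
            x = np.clip(x, *desc["clip"])
        return x
    if kind == "uniform":
        return rng.uniform(desc["low"], desc["high"], size=size)
    if kind == "constant":
        return np.full(size, desc["value"])
    raise ValueError(f"unknown distribution kind {kind!r}")


def _re_transform(D: np.ndarray) -> np.ndarray:
    """Matrix A with A A' = D, valid for singular PSD D."""
    w, V = np.linalg.eigh(np.asarray(D, dtype=float))
    if np.min(w) < -1e-8:
        raise ValueError("random-effects covariance D is not positive semidefinite")
    return V * np.sqrt(np.clip(w, 0.0, None))


def simulate_subjects(config: SimConfig, seed=None) -> pd.DataFrame:
    """Draw the subject-level table: covariates plus random effects (u0, u1).

    Random effects are mean-zero bivariate normal with covariance
    ``config.true_params.re_cov``; a zero matrix yields (0, 0) for
    everyone.  Covariate frequencies follow ``config.covariate_specs``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_subjects
    out = {"subject_id": [f"S{i+1:05d}" for i in range(n)]}
    for cs in config.covariate_specs:
        if cs["level"] == "subject":
            out[cs["name"]] = _draw(rng, cs["dist"], n)
    A = _re_transform(config.true_params.re_cov)
    z = rng.standard_normal((n, 2))
    u = z @ A.T
    out["u0"], out["u1"] = u[:, 0], u[:, 1]
    return pd.DataFrame(out)


def _phase_from_time(t: np.ndarray) -> np.ndarray:
    # II = [0, 0.25), III = [0.25, 1), IV = [1, cART); V assigned once cART known
    return np.select([t < 0.25, t < 1.0], ["II", "III"], default="IV")


def simulate_visits(subjects: pd.DataFrame, config: SimConfig, seed=None) -> pd.DataFrame:
    """Generate the visit grid and time-varying covariates (no outcomes yet).

    Every subject has a baseline visit at t = 0; additional visits arrive
    as a homogeneous Poisson process at ``config.visit_rate`` within the
    subject's follow-up duration.  ``max_followup = 0`` degenerates to the
    baseline visit only.
    """
    if len(subjects) == 0:
        raise ValueError("subjects table is empty")
    s = config.seed + 1 if seed is None else seed
    ss = s if isinstance(s, np.random.SeedSequence) else np.random.SeedSequence(s)
    streams = ss.spawn(len(subjects))
    fu = config.followup
    visit_specs = [cs for cs in config.covariate_specs if cs["level"] == "visit"]
    frames = []
    for (_, subj), child in zip(subjects.iterrows(), streams):
        rng = np.random.default_rng(child)
        if fu["kind"] == "fixed" or config.max_followup == 0:
            duration = config.max_followup
        elif fu["kind"] == "lognormal":
            duration = min(
                float(rng.lognormal(np.log(fu["median"]), fu["log_sd"])), config.max_followup
            )
        else:
            raise ValueError(f"unknown follow-up kind {fu['kind']!r}")
        n_extra = rng.poisson(config.visit_rate * duration)
        times = np.concatenate([[0.0], np.sort(rng.uniform(0.0, duration, size=n_extra))])
        rec = {
            "subject_id": subj["subject_id"],
            "time": times,
            "phase": _phase_from_time(times),
            "stage": np.zeros(len(times), dtype=int),
            "cd4": np.full(len(times), np.nan),
            "on_cart": np.zeros(len(times), dtype=int),
        }
        for cs in visit_specs:
            rec[cs["name"]] = _draw(rng, cs["dist"], len(times))
        df = pd.DataFrame(rec)
        for col in subjects.columns:
            if col != "subject_id":
                df[col] = subj[col]
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    for name, c in config.center.items():
        if name in table.columns:
            table[f"{name}_c"] = table[name] - c
    return table


def simulate_ordinal_outcomes(
    long_table: pd.DataFrame,
    params: ParamVector,
    spec: ModelSpec | None = None,
    seed=None,
    cart_rule: int = 2,
    cart_col: str = "on_cart",
    with_cd4: bool = True,
) -> pd.DataFrame:
    """Draw ordinal stages from the cumulative-logit model, visit by visit.

    Stages are drawn from the category probabilities implied by each row's
    linear predictors and the subject's (u0, u1).  cART switches on from
    the first visit *after* the observed stage reaches ``cart_rule``
    (initiation cannot precede observation) and never reverts.  When
    ``with_cd4``, a CD4 count is drawn uniformly within the stage's CD4
    interval so that WHO staging round-trips.

    Raises :class:`~ordgrowth.model.NonMonotoneError` naming the offending
    covariate pattern if any row's cumulative probabilities are not
    monotone (possible under non-proportional odds).
    """
    params.validate()
    spec = spec or default_model_spec()
    K = params.K
    table = long_table.reset_index(drop=True).copy()
    for col in ("u0", "u1"):
        if col not in table.columns:
            raise ValueError(f"long table must carry random-effect column {col!r}")

    def colvals(name: str) -> np.ndarray:
        if name not in table.columns:
            raise ValueError(f"missing covariate column {name!r}")
        v = table[name]
        if not np.issubdtype(np.asarray(v).dtype, np.number):
            raise ValueError(f"simulation requires numeric covariates; {name!r} is not")
        return v.to_numpy(dtype=float)

    t_all = colvals(spec.time)
    inter_shared = tuple(n for n in spec.time_interactions if n not in spec.npo)
    inter_npo = tuple(n for n in spec.time_interactions if n in spec.npo)
    shared_cols = list(spec.shared) + [f"{n}:t" for n in inter_shared]
    npo_cols = list(spec.npo) + [f"{n}:t" for n in inter_npo]
    if params.shared_coefs.size != len(shared_cols):
        raise ValueError(
            f"params.shared_coefs has {params.shared_coefs.size} entries for "
            f"{len(shared_cols)} shared design columns"
        )
    if params.category_coefs.shape[0] != len(npo_cols):
        raise ValueError(
            f"params.category_coefs has {params.category_coefs.shape[0]} rows for "
            f"{len(npo_cols)} npo design columns"
        )
    base = {}
    for name in set(spec.shared) | set(spec.npo) | set(spec.time_interactions):
        base[name] = colvals(name)
    u0 = colvals("u0")
    u1 = colvals("u1")
    stage_out = np.zeros(len(table), dtype=int)
    cd4_out = np.full(len(table), np.nan)
    cart_out = np.zeros(len(table), dtype=int)

    sids, _ = pd.factorize(table["subject_id"], sort=False)
    s = seed if seed is not None else 0
    ss = s if isinstance(s, np.random.SeedSequence) else np.random.SeedSequence(s)
    streams = ss.spawn(int(sids.max()) + 1)
    delta = params.thresholds
    beta = params.shared_coefs
    Bc = params.category_coefs
    order = np.lexsort((t_all, sids))
    for sid in range(int(sids.max()) + 1):
        rows = order[sids[order] == sid]
        rng = np.random.default_rng(streams[sid])
        on = 0
        triggered = False
        for r in rows:
            vals = {n: base[n][r] for n in base}
            if cart_col in vals:
                vals[cart_col] = float(on)
            eta = delta.copy()
            for j, cn in enumerate(shared_cols):
                v = vals[cn[:-2]] * t_all[r] if cn.endswith(":t") else vals[cn]
                eta = eta + beta[j] * v
            for j, cn in enumerate(npo_cols):
                v = vals[cn[:-2]] * t_all[r] if cn.endswith(":t") else vals[cn]
                eta = eta + Bc[j] * v
            eta = eta + u0[r] + u1[r] * t_all[r]
            if K > 2 and np.any(np.diff(eta) < 0):
                raise NonMonotoneError(
                    f"non-monotone cumulative probabilities at subject index {sid}, "
                    f"time {t_all[r]:.3f}, covariates {vals}"
                )
            cum = expit(eta)
            stage = 1 + int(np.searchsorted(cum, rng.uniform()))
            stage_out[r] = stage
            cart_out[r] = on
            if with_cd4:
                lo, hi = CD4_SIM_BANDS[stage]
                cd4_out[r] = rng.uniform(lo, hi)
            if not triggered and stage >= cart_rule:
                triggered = True
                on = 1  # takes effect from the next visit
    table["stage"] = stage_out
    table["on_cart"] = cart_out
    if with_cd4:
        table["cd4"] = cd4_out
    if "phase" in table.columns:
        table.loc[table["on_cart"] == 1, "phase"] = "V"
    return table


def simulate_clinical_panel(
    loadings: np.ndarray,
    n: int,
    noise_sd=1.0,
    seed=None,
    variable_names: list | None = None,
    return_factors: bool = False,
):
    """Simulate a clinical panel X = F loadings' + E with standard-normal
    factors F and independent Gaussian noise E (scalar or per-variable SD).
    """
    loadings = np.asarray(loadings, dtype=float)
    if loadings.ndim != 2 or loadings.shape[0] <= loadings.shape[1]:
        raise ValueError("loadings must be variables x factors with more variables than factors")
    rng = np.random.default_rng(seed)
    F = rng.standard_normal((n, loadings.shape[1]))
    E = rng.standard_normal((n, loadings.shape[0])) * np.asarray(noise_sd, dtype=float)
    X = F @ loadings.T + E
    if variable_names is not None:
        X = pd.DataFrame(X, columns=variable_names)
    return (X, F) if return_factors else X


def simulate_cohort(config: SimConfig) -> pd.DataFrame:
    """End-to-end cohort: subjects -> visits -> outcomes (-> clinical panel).

    All sub-stages draw from children of ``SeedSequence(config.seed)``;
    identical config and seed give byte-identical output.
    """
    ss = np.random.SeedSequence(config.seed)
    s_subj, s_vis, s_out, s_panel = ss.spawn(4)
    subjects = simulate_subjects(config, seed=s_subj)
    visits = simulate_visits(subjects, config, seed=s_vis)
    table = simulate_ordinal_outcomes(
        visits,
        config.true_params,
        config.model_spec,
        seed=s_out,
        cart_rule=config.cart_rule,
        with_cd4=config.with_cd4,
    )
    if config.panel is not None:
        panel = simulate_clinical_panel(
            config.panel["loadings"],
            len(table),
            noise_sd=config.panel.get("noise_sd", 1.0),
            seed=s_panel,
            variable_names=config.panel["variables"],
        )
        table = pd.concat([table, panel.reset_index(drop=True)], axis=1)
    return table


def write_cohort(table: pd.DataFrame, path) -> None:
    """Write a cohort as headered CSV with a fixed leading column order."""
    lead = [c for c in _BASE_COLUMNS if c in table.columns]
    rest = [c for c in table.columns if c not in lead]
    table[lead + rest].to_csv(path, index=False, float_format="%.10g")
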