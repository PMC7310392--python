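"""End-to-end orchestration: simulate -> stage -> reduce -> fit -> compare.

One :func:`run_pipeline` call writes, in order: the cohort CSV (when
simulated), the baseline descriptive table, factor loadings and scores,
the proportional-odds and non-proportional-odds fits, the proportionality
LR test, the DIC report, a published-style odds-ratio report, and a
manifest with the config hash, seeds, library versions and wall-clock.
A stage failure halts with the stage name; artifacts written before the
failure remain on disk.

Identical configuration and seeds give byte-identical numeric outputs;
the manifest (which embeds wall-clock time) is the only file that differs
between repeated runs.
"""
from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import compare_dic, lr_proportionality_test, odds_ratio_table
from .factors import extract_components, score_factors, varimax_rotate, classify_loadings
from .model import (
    ModelSpec,
    ParamVector,
    build_design,
    fit_mcmc,
    fit_mle,
    nested_init,
)
from .simulate import SimConfig, simulate_cohort, write_cohort
from .staging import baseline_table

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "validate_input"]

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_path`` (a long-format CSV) or ``sim`` (a
    :class:`~ordgrowth.simulate.SimConfig`) must be provided.  ``model``
    is the NPO specification; the nested PO specification is derived by
    moving its npo covariates into the shared set.
    """

    outdir: str = "run"
    input_path: str | None = None
    sim: SimConfig | None = None
    model: ModelSpec = field(default_factory=ModelSpec)
    panels: dict = field(default_factory=dict)  # panel name -> list of columns
    quad_order: int = 5
    mcmc_iters: int = 1500
    mcmc_burn: int = 500
    seed: int = 0
    baseline_categorical: dict = field(default_factory=dict)
    baseline_continuous: list = field(default_factory=list)

    def validate(self) -> None:
        if (self.input_path is None) == (self.sim is None):
            raise ValueError("exactly one of input_path / sim must be set")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d and d["sim"] is not None:
            sim = dict(d["sim"])
            if "true_params" in sim:
                tp = sim["true_params"]
                sim["true_params"] = ParamVector(
                    thresholds=np.asarray(tp["thresholds"], dtype=float),
                    shared_coefs=np.asarray(tp.get("shared_coefs", []), dtype=float),
                    category_coefs=np.asarray(tp.get("category_coefs", np.zeros((0, len(tp["thresholds"])))), dtype=float),
                    re_cov=np.asarray(tp.get("re_cov", np.zeros((2, 2))), dtype=float),
                )
            if "model_spec" in sim:
                sim["model_spec"] = ModelSpec(**sim["model_spec"])
            d["sim"] = SimConfig(**sim)
        if "model" in d and not isinstance(d["model"], ModelSpec):
            d["model"] = ModelSpec(**d["model"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            if hasattr(o, "__dict__"):
                return vars(o)
            return str(o)

        blob = json.dumps(vars(self), default=default, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def validate_input(table: pd.DataFrame, K: int = 4) -> list[dict]:
    """Machine-readable validation of a long-format visit table.

    Checks column presence, stage codes in 1..K, non-negative finite
    times, within-subject cART monotonicity, and (when CD4 present) WHO
    stage/CD4 consistency.  Always returns the issue list (empty = clean).
    """
    from .staging import who_stage_codes

    issues: list[dict] = []
    for col in ("subject_id", "time", "stage"):
        if col not in table.columns:
            issues.append({"field": col, "row": None, "issue": "missing column"})
    if issues:
        return issues
    stage = table["stage"].to_numpy()
    bad = np.nonzero((stage < 1) | (stage > K))[0]
    for r in bad:
        issues.append({"field": "stage", "row": int(r), "issue": f"stage {stage[r]} outside 1..{K}"})
    t = table["time"].to_numpy(dtype=float)
    bad = np.nonzero(~np.isfinite(t) | (t < 0))[0]
    for r in bad:
        issues.append({"field": "time", "row": int(r), "issue": f"invalid time {t[r]}"})
    if "on_cart" in table.columns:
        for sid, grp in table.groupby("subject_id", sort=False):
            oc = grp.sort_values("time")["on_cart"].to_numpy()
            if np.any(np.diff(oc) < 0):
                issues.append(
                    {"field": "on_cart", "row": str(sid), "issue": "cART status reverts within subject"}
                )
    if "cd4" in table.columns:
        cd4 = table["cd4"].to_numpy(dtype=float)
        ok = np.isfinite(cd4)
        if ok.any():
            codes = who_stage_codes(cd4[ok])
            mism = np.nonzero(codes != stage[ok])[0]
            rows = np.nonzero(ok)[0][mism]
            for r in rows:
                issues.append(
                    {"field": "cd4", "row": int(r), "issue": f"cd4 {cd4[r]:.0f} inconsistent with stage {stage[r]}"}
                )
    return issues


def _derive_po_spec(npo_spec: ModelSpec) -> ModelSpec:
    return ModelSpec(
        outcome=npo_spec.outcome,
        time=npo_spec.time,
        K=npo_spec.K,
        shared=tuple(npo_spec.shared) + tuple(npo_spec.npo),
        npo=(),
        time_interactions=npo_spec.time_interactions,
        random_effects=npo_spec.random_effects,
        categorical_refs=dict(npo_spec.categorical_refs),
    )


def _write_fit(fit, outdir: Path, name: str, seed: int) -> None:
    fit.table.to_csv(outdir / f"{name}.csv", index=False, float_format=_FLOAT_FMT)
    meta = {
        "minus2loglik": fit.minus2loglik,
        "icc": fit.icc,
        "converged": bool(fit.converged),
        "n_iter": int(fit.n_iter),
        "grad_norm": fit.grad_norm,
        "quad_order": int(fit.quad_order),
        "n_params": int(fit.n_params),
        "seed": seed,
    }
    with open(outdir / f"{name}_meta.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full analysis; returns the output directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = _time.time()
    artifacts: list[str] = []
    stage = "setup"
    try:
        # ---- cohort ------------------------------------------------------
        stage = "cohort"
        if config.sim is not None:
            table = simulate_cohort(config.sim)
            write_cohort(table, outdir / "cohort.csv")
            artifacts.append("cohort.csv")
        else:
            table = pd.read_csv(config.input_path)
        issues = validate_input(table, K=config.model.K)
        if issues:
            raise ValueError(f"input validation failed with {len(issues)} issues; first: {issues[0]}")

        # ---- baseline descriptives --------------------------------------
        stage = "baseline"
        base = table.sort_values(["subject_id", "time"]).groupby("subject_id", sort=False).first().reset_index()
        fu = table.groupby("subject_id", sort=False)["time"].max().rename("followup_years")
        base = base.merge(fu, on="subject_id")
        cat = dict(config.baseline_categorical)
        if not cat:
            for c in ("age_group", "education", "marital", "sex_under_alcohol"):
                if c in base.columns:
                    cat[c] = sorted(base[c].dropna().unique().tolist())
            cat["stage"] = [1, 2, 3, 4][: config.model.K]
        cont = list(config.baseline_continuous)
        if not cont:
            cont = [c for c in ("weight", "log_vl", "followup_years") if c in base.columns]
        summary = baseline_table(base, categorical=cat, continuous=cont)
        summary.categorical.to_csv(outdir / "baseline_table.csv", index=False, float_format=_FLOAT_FMT)
        (outdir / "baseline_table.txt").write_text(summary.to_text() + "\n")
        artifacts.append("baseline_table.csv")

        # ---- factor reduction -------------------------------------------
        stage = "factors"
        panels = dict(config.panels)
        if not panels and config.sim is not None and config.sim.panel is not None:
            panels = {"panel1": list(config.sim.panel["variables"])}
        load_rows = []
        scores_out = table[["subject_id", "time"]].copy()
        for pname, cols in panels.items():
            sol = varimax_rotate(extract_components(table[cols]))
            strength = classify_loadings(sol.loadings)
            for i, v in enumerate(sol.variable_names):
                for j, f in enumerate(sol.factor_names):
                    load_rows.append(
                        {
                            "panel": pname,
                            "variable": v,
                            "factor": f,
                            "loading": sol.loadings[i, j],
                            "strength": strength[i, j],
                            "cumulative_variance": sol.variance_explained,
                        }
                    )
            sc = score_factors(table[cols], sol)
            for j, f in enumerate(sol.factor_names):
                scores_out[f"{pname}_{f}"] = sc[:, j]
        pd.DataFrame(load_rows).to_csv(outdir / "factor_loadings.csv", index=False, float_format=_FLOAT_FMT)
        scores_out.to_csv(outdir / "factor_scores.csv", index=False, float_format=_FLOAT_FMT)
        artifacts += ["factor_loadings.csv", "factor_scores.csv"]

        # ---- model fits --------------------------------------------------
        stage = "fit_po"
        npo_spec = config.model
        po_spec = _derive_po_spec(npo_spec)
        bundle_po = build_design(table, po_spec)
        fit_po = fit_mle(bundle_po, quad_order=config.quad_order)
        _write_fit(fit_po, outdir, "fit_po", config.seed)
        artifacts.append("fit_po.csv")

        have_npo = bool(npo_spec.npo) and npo_spec.K > 2
        if have_npo:
            stage = "fit_npo"
            bundle_npo = build_design(table, npo_spec)
            fit_npo = fit_mle(bundle_npo, quad_order=config.quad_order, init=nested_init(fit_po, bundle_npo))
            _write_fit(fit_npo, outdir, "fit_npo", config.seed)
            artifacts.append("fit_npo.csv")

        # ---- LR test ------------------------------------------------------
        stage = "lr_test"
        if have_npo:
            tr = lr_proportionality_test(fit_po, fit_npo)
            lr_doc = {
                "skipped": False,
                "statistic": tr.statistic,
                "df": tr.df,
                "p_value": tr.p_value,
                "alpha": tr.alpha,
                "reject_proportional_odds": tr.reject,
            }
        else:
            lr_doc = {
                "skipped": True,
                "reason": "npo covariate set is empty; the PO and NPO models coincide",
            }
        with open(outdir / "lr_test.json", "w") as fh:
            json.dump(lr_doc, fh, indent=1, sort_keys=True)
        artifacts.append("lr_test.json")

        # ---- DIC ----------------------------------------------------------
        stage = "dic"
        mcmc_po = fit_mcmc(
            bundle_po,
            quad_order=config.quad_order,
            n_iter=config.mcmc_iters + config.mcmc_burn,
            burn=config.mcmc_burn,
            seed=(config.seed + 101) % (2**31),
            init=fit_po,
        )
        if have_npo:
            mcmc_npo = fit_mcmc(
                bundle_npo,
                quad_order=config.quad_order,
                n_iter=config.mcmc_iters + config.mcmc_burn,
                burn=config.mcmc_burn,
                seed=(config.seed + 202) % (2**31),
                init=fit_npo,
            )
            rep = compare_dic(mcmc_po, mcmc_npo)
            dic_doc = {
                "models": rep.models.to_dict(orient="records"),
                "delta_dic": rep.delta_dic,
                "preferred": rep.preferred,
                "warnings": rep.warnings,
            }
        else:
            dic_doc = {
                "models": [
                    {"model": "proportional_odds", "dbar": mcmc_po.dbar, "pD": mcmc_po.p_d, "dic": mcmc_po.dic}
                ],
                "delta_dic": None,
                "preferred": None,
                "warnings": mcmc_po.warnings,
            }
        with open(outdir / "dic_report.json", "w") as fh:
            json.dump(dic_doc, fh, indent=1, sort_keys=True)
        artifacts.append("dic_report.json")

        # ---- published-style report --------------------------------------
        stage = "report"
        report_fit = fit_npo if have_npo else fit_po
        odds_ratio_table(report_fit).to_csv(outdir / "model_report.csv", index=False)
        artifacts.append("model_report.csv")

        # ---- manifest -----------------------------------------------------
        stage = "manifest"
        manifest = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "artifacts": artifacts,
            "versions": {
                "ordgrowth": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "wall_clock_seconds": round(_time.time() - t0, 3),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    except PipelineError:
        raise
    except BaseException as exc:
        raise PipelineError(stage, exc) from exc
    return outdir
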