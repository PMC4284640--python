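"""End-to-end analysis pipeline: measurement models, age effects, MIMIC
comparisons, mediation, and the young/old multigroup stage, with structured
reporting.

Every stage that yields a p-value family records Benjamini-Hochberg FDR
flags for that family.  Raw-data mode runs everything; covariance-only input
runs the covariance-structure stages and downgrades the rest with explicit
notes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fit import FitResult, fit
from .indices import compare_nested
from .mediation import decompose
from .models import (CATALOG, MODEL_BEHAV, frontal_lobe_single_factor,
                     mediation_fluid, mediation_multitask, mimic_full,
                     mimic_with_controls, multigroup, neural_two_factor,
                     one_factor_cfa, prepare_model_frame, two_factor_cfa,
                     hierarchical_cfa, young_old_split)
from .modindices import modification_indices
from .population import (ALL_NEURAL, BEHAV_VARS, CohortConfig,
                         build_population_model, generate_cohort,
                         screen_outliers)
from .scores import factor_scores
from .stats import (breusch_pagan, fdr_bh, fisher_ci, levene_test,
                    robust_regression, williams_test)

REQUIRED_COLUMNS = ["age"] + BEHAV_VARS + ALL_NEURAL


@dataclass
class PipelineConfig:
    seed: int = 7
    n: int = 567
    calibration: CohortConfig = field(default_factory=CohortConfig)
    z_threshold: float = 4.0
    hc_type: str = "HC1"
    bp_studentized: bool = True
    split_n_each: int = 210
    fdr_q: float = 0.05

    def digest(self) -> str:
        blob = repr(sorted(self.__dict__.items(), key=lambda kv: kv[0]))
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


# ------------------------------------------------------------------------ io
def load_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file missing required columns: {missing}")
    sub = df[REQUIRED_COLUMNS]
    bad = sub.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(f"missing/non-numeric cell at row {r}, column "
                         f"{REQUIRED_COLUMNS[c]!r}")
    for c in REQUIRED_COLUMNS:
        if not np.issubdtype(sub[c].dtype, np.number):
            raise ValueError(f"non-numeric column {c!r}")
    return df


def write_cohort(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def load_covariance(path: str | Path, n: int | None = None) -> tuple[pd.DataFrame, int]:
    """Covariance CSV with a header row and an index column of variable names.

    The sample size comes from ``n`` or a ``# n = <int>`` comment on the
    first line.  Asymmetry beyond 1e-8 is an error; beyond 1e-12 the matrix
    is symmetrized with a warning field left to the caller's logger.
    """
    path = Path(path)
    text = path.read_text().splitlines()
    if text and text[0].startswith("#"):
        if n is None and "n" in text[0]:
            n = int(text[0].split("=")[1])
        body = "\n".join(text[1:])
    else:
        body = "\n".join(text)
    import io
    S = pd.read_csv(io.StringIO(body), index_col=0)
    if n is None:
        raise ValueError("sample size n not given (argument or '# n = ...' header)")
    a = S.to_numpy(float)
    if not np.allclose(a, a.T, atol=1e-8):
        raise ValueError("covariance matrix asymmetric beyond 1e-8")
    S.loc[:, :] = (a + a.T) / 2
    return S, int(n)


def write_covariance(S: pd.DataFrame, n: int, path: str | Path) -> None:
    Path(path).write_text(f"# n = {n}\n" + S.to_csv())


# ------------------------------------------------------------------ helpers
def _fit_block(f: FitResult) -> dict:
    return f.to_json_dict()


def _cmp_block(c) -> dict:
    return {"chi2_diff_scaled": c.chi2_diff_scaled, "df_diff": c.df_diff,
            "p": c.p_value, "delta_aic": c.delta_aic,
            "scaling_correction": c.scaling_correction}


def _fdr_family(p_dict: dict[str, float], q: float) -> dict:
    names = list(p_dict)
    flags = fdr_bh([p_dict[k] for k in names], q)
    return {k: bool(v) for k, v in zip(names, flags)}


# ----------------------------------------------------------------- pipeline
def run_full_analysis(data, config: PipelineConfig | None = None) -> dict:
    """Execute the full analysis sequence and return the report dict.

    ``data`` is a cohort DataFrame or ``(S, n)`` covariance input (pandas
    DataFrame with variable names matching the model frame, i.e. including
    ``hotel_ttm_rev``).
    """
    config = config or PipelineConfig()
    report: dict = {"provenance": {
        "seed": config.seed, "config_digest": config.digest(),
        "version": __version__,
    }}
    cov_mode = not isinstance(data, pd.DataFrame)

    if cov_mode:
        S, n = data
        frame = None
        report["screen"] = {"skipped": "covariance-only input"}
        def fit_model(spec):
            names = [v for v in spec.observed]
            sub = S.loc[names, names].to_numpy()
            return fit(spec, (sub, n))
    else:
        screened = screen_outliers(data, config.z_threshold)
        report["screen"] = {"n_in": int(len(data)), "n_out": int(len(screened)),
                            "n_removed": int(len(data) - len(screened)),
                            "z_threshold": config.z_threshold}
        frame = prepare_model_frame(screened)
        def fit_model(spec, fr=None):
            return fit(spec, fr if fr is not None else frame)

    notes: list[str] = []

    # 1. measurement models -------------------------------------------------
    two = fit_model(two_factor_cfa())
    one = fit_model(one_factor_cfa())
    hier = fit_model(hierarchical_cfa())
    meas = {
        "two_factor": _fit_block(two),
        "one_factor": _fit_block(one),
        "hierarchical": _fit_block(hier),
        "one_vs_two": _cmp_block(compare_nested(one, two)),
        "aic_hierarchical_minus_one_factor": float(hier.aic - one.aic),
    }
    report["measurement_models"] = meas

    # 2. age effects ---------------------------------------------------------
    if cov_mode:
        report["age_effects"] = {"skipped": "needs raw data (factor scores, "
                                            "heteroscedasticity, regression)"}
    else:
        sc = factor_scores(two, frame)
        age = screened["age"].to_numpy(float)
        n_ = len(age)
        r_af = float(np.corrcoef(age, sc["fluid"])[0, 1])
        r_am = float(np.corrcoef(age, sc["multitask"])[0, 1])
        r_fm = float(np.corrcoef(sc["fluid"], sc["multitask"])[0, 1])
        ci_f = fisher_ci(r_af, n_)
        ci_m = fisher_ci(r_am, n_)
        will = williams_test(r_af, r_am, r_fm, n_)
        bp_f = breusch_pagan(sc["fluid"], age, config.bp_studentized)
        bp_m = breusch_pagan(sc["multitask"], age, config.bp_studentized)
        regs = {}
        for name, score in (("fluid", sc["fluid"]), ("multitask", sc["multitask"])):
            coefs = robust_regression(score, age, config.hc_type, names=["age"])
            regs[name] = {"age": coefs[1].auxiliaries | {"z": coefs[1].statistic,
                                                         "p": coefs[1].p_value}}
        pfam = {"age_fluid": ci_f.p_value, "age_multitask": ci_m.p_value,
                "williams": will.p_value, "bp_fluid": bp_f.p_value,
                "bp_multitask": bp_m.p_value}
        report["age_effects"] = {
            "r_age_fluid": {"r": r_af, "ci": ci_f.auxiliaries["ci"], "p": ci_f.p_value},
            "r_age_multitask": {"r": r_am, "ci": ci_m.auxiliaries["ci"], "p": ci_m.p_value},
            "r_fluid_multitask_scores": r_fm,
            "williams": {"t": will.statistic, "df": will.df, "p": will.p_value},
            "breusch_pagan": {"fluid": {"chi2": bp_f.statistic, "df": bp_f.df, "p": bp_f.p_value},
                              "multitask": {"chi2": bp_m.statistic, "df": bp_m.df, "p": bp_m.p_value}},
            "robust_regression": regs,
            "fdr_flags": _fdr_family(pfam, config.fdr_q),
        }

    # 3. MIMIC and neural control models --------------------------------------
    mim = fit_model(mimic_full())
    mim_eq = fit_model(mimic_full(equal_brain_paths=True))
    ctrl = fit_model(mimic_with_controls())
    ctrl0 = fit_model(mimic_with_controls(controls_zero=True))
    frontal = fit_model(frontal_lobe_single_factor())
    ntf = fit_model(neural_two_factor())
    gamma_p = {}
    if mim.se_robust is not None or mim.se is not None:
        from scipy.stats import norm
        for lab in mim.theta_hat.labels:
            if lab.startswith("b:"):
                z = mim.z(lab)
                gamma_p[lab] = float(2 * norm.sf(abs(z)))
    report["mimic"] = {
        "full": _fit_block(mim),
        "equal_brain_paths": _fit_block(mim_eq),
        "equality_test": _cmp_block(compare_nested(mim_eq, mim)),
        "with_controls": _fit_block(ctrl),
        "controls_zero": _fit_block(ctrl0),
        "controls_test": _cmp_block(compare_nested(ctrl0, ctrl)),
        "frontal_lobe": _fit_block(frontal),
        "neural_two_factor": _fit_block(ntf),
        "aic_neural_two_factor_minus_full": float(ntf.aic - mim.aic),
        "brain_path_p": gamma_p,
        "fdr_flags": _fdr_family(gamma_p, config.fdr_q) if gamma_p else {},
    }

    # 4. mediation -------------------------------------------------------------
    med = {}
    try:
        mf = fit_model(mediation_fluid())
        med["fluid"] = decompose(mf, "age", ["gmv_ba10", "fa_fm"], "fluid").to_json_dict()
        med["fluid"]["fit"] = _fit_block(mf)
    except Exception as exc:
        med["fluid"] = {"failed": str(exc)}
    try:
        mm = fit_model(mediation_multitask())
        med["multitask"] = decompose(mm, "age", ["fa_atr"], "multitask").to_json_dict()
        med["multitask"]["fit"] = _fit_block(mm)
    except Exception as exc:
        med["multitask"] = {"failed": str(exc)}
    report["mediation"] = med

    # 5. multigroup young/old ---------------------------------------------------
    if cov_mode:
        report["multigroup"] = {"skipped": "needs raw data (grouping column)"}
    else:
        try:
            split = young_old_split(screened, config.split_n_each)
            gframe = prepare_model_frame(split, keep=("age_group",))
            configural = fit(multigroup(mimic_full()), gframe)
            constrained = fit(multigroup(mimic_full(),
                                         ("loadings", "regressions")), gframe)
            mis = [m for m in modification_indices(constrained)
                   if m.parameter_id.startswith("split:b:")][:10]
            lev = {}
            grp = split["age_group"].to_numpy()
            for c in ["age"] + ALL_NEURAL:
                t = levene_test(split[c].to_numpy(float), grp)
                lev[c] = {"F": t.statistic, "p": t.p_value}
            report["multigroup"] = {
                "configural": _fit_block(configural),
                "constrained": _fit_block(constrained),
                "constraint_test": _cmp_block(compare_nested(constrained, configural)),
                "modification_indices": [
                    {"parameter": m.parameter_id, "mi": m.mi,
                     "epc": m.expected_parameter_change} for m in mis],
                "levene": lev,
                "group_sizes": [int(config.split_n_each)] * 2,
            }
        except Exception as exc:
            report["multigroup"] = {"failed": str(exc)}

    report["notes"] = notes
    return report


def simulate_cohort(config: PipelineConfig | None = None,
                    n: int | None = None, seed: int | None = None,
                    n_outliers: int = 0) -> pd.DataFrame:
    config = config or PipelineConfig()
    model = build_population_model(config.calibration)
    return generate_cohort(model, n or config.n,
                           seed if seed is not None else config.seed,
                           n_outliers=n_outliers)


# ------------------------------------------------------------------ reports
def write_report(report: dict, path: str | Path) -> None:
    """JSON report plus a Markdown summary next to it."""
    path = Path(path)
    path.write_text(json.dumps(report, indent=2, sort_keys=True,
                               default=_json_default))
    md = path.with_suffix(".md")
    md.write_text(_markdown_summary(report))


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def _fmt_fit(name: str, f: dict) -> str:
    if "skipped" in f or "failed" in f:
        return f"| {name} | - | - | - | - | - | - |"
    return (f"| {name} | {f['chi2']:.3f} | {f['chi2_scaled']:.3f} | {f['df']} "
            f"| {f['rmsea']:.3f} | {f['cfi']:.3f} | {f['srmr']:.3f} |")


def _markdown_summary(report: dict) -> str:
    lines = ["# Analysis report", ""]
    prov = report.get("provenance", {})
    lines.append(f"seed={prov.get('seed')} config={prov.get('config_digest')} "
                 f"version={prov.get('version')}")
    lines += ["", "## Model fits", "",
              "| model | chi2 | scaled chi2 | df | RMSEA | CFI | SRMR |",
              "|---|---|---|---|---|---|---|"]
    mm = report.get("measurement_models", {})
    for k in ("two_factor", "one_factor", "hierarchical"):
        if k in mm:
            lines.append(_fmt_fit(k, mm[k]))
    mi = report.get("mimic", {})
    for k in ("full", "equal_brain_paths", "with_controls", "frontal_lobe",
              "neural_two_factor"):
        if k in mi:
            lines.append(_fmt_fit(f"mimic/{k}", mi[k]))
    med = report.get("mediation", {})
    lines += ["", "## Mediation", ""]
    for k, v in med.items():
        if "effect_size_pct" in v:
            lines.append(f"- {k}: total={v['total_effect']:.3f}, "
                         f"indirect={v['total_indirect']:.3f}, "
                         f"effect size={v['effect_size_pct']:.1f}%")
    mg = report.get("multigroup", {})
    if "constraint_test" in mg:
        ct = mg["constraint_test"]
        lines += ["", "## Multigroup",
                  f"- constraint test: scaled dchi2={ct['chi2_diff_scaled']:.3f}, "
                  f"df={ct['df_diff']}, p={ct['p']:.4f}"]
        for m in mg.get("modification_indices", [])[:5]:
            lines.append(f"- MI {m['parameter']}: {m['mi']:.2f} (EPC {m['epc']:.3f})")
    return "\n".join(lines) + "\n"
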