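"""Ready-made model specifications for the analysis.

All builders work on the *model frame* produced by
:func:`prepare_model_frame`: standardized columns, with the Hotel
total-time-misallocated score reverse-coded (``hotel_ttm_rev``) so both
multitasking loadings are positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .population import ALL_NEURAL, CATTELL_VARS, CONTROL_VARS, NEURAL_VARS
from .spec import SemModelSpec

MODEL_BEHAV = CATTELL_VARS + ["hotel_ttm_rev", "hotel_ntasks"]
FLUID_IND = CATTELL_VARS
MULTI_IND = ["hotel_ttm_rev", "hotel_ntasks"]


def prepare_model_frame(table: pd.DataFrame, standardize: bool = True,
                        keep: tuple[str, ...] = ()) -> pd.DataFrame:
    """Reverse-code the TTM indicator and z-score the model columns."""
    out = pd.DataFrame(index=table.index)
    cols = CATTELL_VARS + ["hotel_ntasks"] + [c for c in ALL_NEURAL if c in table.columns]
    out["hotel_ttm_rev"] = -table["hotel_ttm"]
    for c in cols:
        out[c] = table[c]
    if "age" in table.columns:
        out["age"] = table["age"]
    if standardize:
        for c in out.columns:
            sd = out[c].std(ddof=1)
            out[c] = (out[c] - out[c].mean()) / sd
    for c in keep:
        out[c] = table[c].to_numpy()
    return out


# ------------------------------------------------------------- measurement
def two_factor_cfa() -> SemModelSpec:
    """Fluid intelligence and multitasking as correlated factors; all
    loadings free, factor variances fixed to 1."""
    spec = SemModelSpec(MODEL_BEHAV, ["fluid", "multitask"])
    for v in FLUID_IND:
        spec.add_loading("fluid", v)
    for v in MULTI_IND:
        spec.add_loading("multitask", v)
    spec.add_variance("fluid", free=False, value=1.0)
    spec.add_variance("multitask", free=False, value=1.0)
    spec.add_covariance("fluid", "multitask", label="c:fluid~~multitask")
    return spec


def one_factor_cfa() -> SemModelSpec:
    """A single executive-function factor behind all six indicators."""
    spec = SemModelSpec(MODEL_BEHAV, ["ef"])
    for v in MODEL_BEHAV:
        spec.add_loading("ef", v)
    spec.add_variance("ef", free=False, value=1.0)
    return spec


def hierarchical_cfa() -> SemModelSpec:
    """Two first-order factors under one higher-order factor.

    With only two first-order factors the higher-order structure is not
    separately identified; the conventional constraint used here (both
    second-order loadings fixed equal, first-order disturbances zero,
    higher-order variance free) makes it fit exactly like the one-factor
    model while carrying one extra (redundant) parameter.
    """
    spec = SemModelSpec(MODEL_BEHAV, ["fluid", "multitask", "g"])
    for v in FLUID_IND:
        spec.add_loading("fluid", v)
    for v in MULTI_IND:
        spec.add_loading("multitask", v)
    spec.add_regression("fluid", "g", free=False, value=1.0)
    spec.add_regression("multitask", "g", free=False, value=1.0)
    spec.add_variance("fluid", free=False, value=0.0)
    spec.add_variance("multitask", free=False, value=0.0)
    spec.add_variance("g", free=True)
    return spec


# ------------------------------------------------------------------- MIMIC
def _measurement_first_fixed(spec: SemModelSpec) -> None:
    spec.add_loading("fluid", FLUID_IND[0], free=False, value=1.0)
    for v in FLUID_IND[1:]:
        spec.add_loading("fluid", v)
    spec.add_loading("multitask", MULTI_IND[0], free=False, value=1.0)
    spec.add_loading("multitask", MULTI_IND[1])
    spec.add_variance("fluid")
    spec.add_variance("multitask")
    spec.add_covariance("fluid", "multitask", label="c:fluid~~multitask")


def mimic_full(equal_brain_paths: bool = False) -> SemModelSpec:
    """Four neural regressors (fixed-x) each predicting both factors.

    ``equal_brain_paths=True`` ties each neural variable's two paths (to
    fluid and to multitasking) to a single parameter -- the 4-df equality
    test of brain-behaviour specificity.
    """
    spec = SemModelSpec(MODEL_BEHAV + NEURAL_VARS, ["fluid", "multitask"])
    _measurement_first_fixed(spec)
    for v in NEURAL_VARS:
        lab_f = f"b:eq:{v}" if equal_brain_paths else None
        lab_m = f"b:eq:{v}" if equal_brain_paths else None
        spec.add_regression("fluid", v, label=lab_f)
        spec.add_regression("multitask", v, label=lab_m)
    spec.set_fixed_x(NEURAL_VARS)
    return spec


def mimic_with_controls(controls_zero: bool = False) -> SemModelSpec:
    """MIMIC model plus two control regions (temporal pole GMV, forceps
    major FA); ``controls_zero`` fixes their paths to zero for the nested
    specificity test."""
    spec = SemModelSpec(MODEL_BEHAV + NEURAL_VARS + CONTROL_VARS,
                        ["fluid", "multitask"])
    _measurement_first_fixed(spec)
    for v in NEURAL_VARS:
        spec.add_regression("fluid", v)
        spec.add_regression("multitask", v)
    for v in CONTROL_VARS:
        spec.add_regression("fluid", v, free=not controls_zero, value=0.0)
        spec.add_regression("multitask", v, free=not controls_zero, value=0.0)
    spec.set_fixed_x(NEURAL_VARS + CONTROL_VARS)
    return spec


def frontal_lobe_single_factor() -> SemModelSpec:
    """One 'overall PFC integrity' factor behind the four neural measures,
    predicting both cognitive factors."""
    spec = SemModelSpec(MODEL_BEHAV + NEURAL_VARS,
                        ["fluid", "multitask", "pfc"])
    _measurement_first_fixed(spec)
    spec.add_loading("pfc", NEURAL_VARS[0], free=False, value=1.0)
    for v in NEURAL_VARS[1:]:
        spec.add_loading("pfc", v)
    spec.add_variance("pfc")
    spec.add_regression("fluid", "pfc")
    spec.add_regression("multitask", "pfc")
    return spec


def neural_two_factor() -> SemModelSpec:
    """Separate grey-matter and white-matter latent variables, each
    predicting both cognitive factors."""
    spec = SemModelSpec(MODEL_BEHAV + NEURAL_VARS,
                        ["fluid", "multitask", "gm", "wm"])
    _measurement_first_fixed(spec)
    spec.add_loading("gm", "gmv_ba10", free=False, value=1.0)
    spec.add_loading("gm", "gmv_md")
    spec.add_loading("wm", "fa_fm", free=False, value=1.0)
    spec.add_loading("wm", "fa_atr")
    spec.add_variance("gm")
    spec.add_variance("wm")
    spec.add_covariance("gm", "wm")
    for f in ("fluid", "multitask"):
        spec.add_regression(f, "gm")
        spec.add_regression(f, "wm")
    return spec


# --------------------------------------------------------------- mediation
def mediation_fluid() -> SemModelSpec:
    """age -> {BA10 GMV, FM FA} -> fluid factor, with a direct age path and
    independent mediator disturbances."""
    spec = SemModelSpec(["age"] + FLUID_IND + ["gmv_ba10", "fa_fm"], ["fluid"])
    spec.add_loading("fluid", FLUID_IND[0], free=False, value=1.0)
    for v in FLUID_IND[1:]:
        spec.add_loading("fluid", v)
    spec.add_regression("gmv_ba10", "age", label="a1")
    spec.add_regression("fa_fm", "age", label="a2")
    spec.add_regression("fluid", "gmv_ba10", label="b1")
    spec.add_regression("fluid", "fa_fm", label="b2")
    spec.add_regression("fluid", "age", label="c")
    spec.add_variance("fluid")
    spec.set_fixed_x(["age"])
    return spec


def mediation_multitask() -> SemModelSpec:
    """age -> ATR FA -> multitasking factor with a direct age path."""
    spec = SemModelSpec(["age", "fa_atr"] + MULTI_IND, ["multitask"])
    spec.add_loading("multitask", MULTI_IND[0], free=False, value=1.0)
    spec.add_loading("multitask", MULTI_IND[1])
    spec.add_regression("fa_atr", "age", label="a")
    spec.add_regression("multitask", "fa_atr", label="b")
    spec.add_regression("multitask", "age", label="c")
    spec.add_variance("multitask")
    spec.set_fixed_x(["age"])
    return spec


# -------------------------------------------------------------- multigroup
def _labels_by_kind(spec: SemModelSpec, kinds: tuple[str, ...]) -> set[str]:
    return {e.label for e in spec._entries if e.free and e.kind in kinds}


def multigroup(spec: SemModelSpec, constraints: tuple[str, ...] = (),
               group_var: str = "age_group") -> SemModelSpec:
    """Two-group version of a single-group spec.

    ``constraints`` may contain ``"loadings"`` and/or ``"regressions"``;
    those parameter classes are tied across groups, everything else is
    estimated per group.
    """
    kinds = []
    if "loadings" in constraints:
        kinds.append("loading")
    if "regressions" in constraints:
        kinds.append("regression")
    unknown = set(constraints) - {"loadings", "regressions"}
    if unknown:
        raise ValueError(f"unknown constraint classes: {sorted(unknown)}")
    labels = _labels_by_kind(spec, tuple(kinds)) if kinds else set()
    return spec.to_multigroup(group_var, equal_labels=labels)


def young_old_split(table: pd.DataFrame, n_each: int = 210) -> pd.DataFrame:
    """The youngest and oldest ``n_each`` participants, labelled in an
    ``age_group`` column."""
    if 2 * n_each > len(table):
        raise ValueError("table too small for the requested split")
    srt = table.sort_values("age", kind="mergesort")
    young = srt.iloc[:n_each].copy()
    old = srt.iloc[-n_each:].copy()
    young["age_group"] = "1_young"
    old["age_group"] = "2_old"
    return pd.concat([young, old], ignore_index=True)


# ------------------------------------------------------------------ catalog
@dataclass
class ModelCatalogEntry:
    name: str
    builder: Callable[[], SemModelSpec]
    expected_df: int
    description: str


CATALOG: dict[str, ModelCatalogEntry] = {
    e.name: e for e in [
        ModelCatalogEntry("two_factor_cfa", two_factor_cfa, 8,
                          "two correlated cognitive factors, all loadings free"),
        ModelCatalogEntry("one_factor_cfa", one_factor_cfa, 9,
                          "single executive-function factor"),
        ModelCatalogEntry("hierarchical_cfa", hierarchical_cfa, 8,
                          "two first-order factors under a higher-order factor"),
        ModelCatalogEntry("mimic_full", mimic_full, 24,
                          "four neural regressors to both factors (fixed-x)"),
        ModelCatalogEntry("mimic_with_controls", mimic_with_controls, 32,
                          "MIMIC plus two control regions"),
        ModelCatalogEntry("frontal_lobe_single_factor",
                          frontal_lobe_single_factor, 32,
                          "single PFC-integrity factor predicting both factors"),
        ModelCatalogEntry("neural_two_factor", neural_two_factor, 29,
                          "separate GM and WM latent variables"),
        ModelCatalogEntry("mediation_fluid", mediation_fluid, 12,
                          "BA10 and FM mediate age differences in fluid intelligence"),
        ModelCatalogEntry("mediation_multitask", mediation_multitask, 1,
                          "ATR mediates age differences in multitasking"),
    ]
}


def build(name: str) -> SemModelSpec:
    if name not in CATALOG:
        raise KeyError(f"unknown model {name!r}; see CATALOG")
    return CATALOG[name].builder()
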