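"""Covariance-structure model specification.

A model is written in the LISREL-style all-y form

    y = Lambda * eta + epsilon
    eta = B * eta + zeta

where ``eta`` collects both latent variables and any observed variable that
takes part in structural regressions (such variables receive a unit loading
and a zero measurement residual).  The implied covariance matrix of the
observed variables is

    Sigma(theta) = Lambda (I - B)^-1 Psi (I - B)^-T Lambda^T + Theta

with ``Psi`` the covariance matrix of exogenous variables and disturbances
and ``Theta`` the measurement-residual covariance matrix.

Parameters live in four pattern matrices.  Each cell is either fixed to a
value or free; free cells carry a label, and cells sharing a label are a
single parameter (equality constraint).  Observed exogenous predictors can
be declared ``fixed_x``: their variances and covariances are then frozen at
the sample values and do not count as free parameters or as fitted moments.

Multigroup models repeat the pattern per group; labels listed in
``equal_across_groups`` are shared between groups, everything else is
instantiated once per group.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import yaml


class ModelSpecError(ValueError):
    """Raised for structurally invalid model specifications."""


@dataclass
class _Entry:
    """One declared cell of Lambda / B / Psi / Theta."""

    kind: str  # "loading" | "regression" | "variance" | "covariance"
    a: str  # target (indicator for loadings, dependent for regressions)
    b: str  # source (factor for loadings, predictor for regressions)
    free: bool = True
    value: float = 0.0  # fixed value if not free
    label: str | None = None


class SemModelSpec:
    """Builder and container for a structural equation model specification.

    Parameters
    ----------
    observed
        Ordered names of the observed variables entering the model.
    latents
        Names of the latent variables.
    group_var, n_groups
        Optional grouping: name of the (categorical, two-level) column and
        the number of groups.  ``n_groups > 2`` is not supported.
    """

    def __init__(
        self,
        observed: Sequence[str],
        latents: Sequence[str] = (),
        group_var: str | None = None,
        n_groups: int = 1,
    ):
        if len(set(observed)) != len(observed):
            raise ModelSpecError("duplicate observed variable names")
        if set(observed) & set(latents):
            raise ModelSpecError("observed and latent names overlap")
        if group_var is not None and n_groups != 2:
            raise ModelSpecError(">2 groups (or 1 group with group_var) unsupported")
        self.observed = list(observed)
        self.latents = list(latents)
        self.group_var = group_var
        self.n_groups = n_groups if group_var is not None else 1
        self.fixed_x: list[str] = []
        self.equal_across_groups: set[str] = set()
        self._entries: list[_Entry] = []

    # ------------------------------------------------------------------ build
    def add_loading(self, factor: str, indicator: str, *, free: bool = True,
                    value: float = 1.0, label: str | None = None) -> "SemModelSpec":
        self._check(factor, self.latents, "latent")
        self._check(indicator, self.observed, "observed")
        self._entries.append(_Entry("loading", indicator, factor, free, value,
                                    label or f"l:{indicator}~{factor}"))
        return self

    def add_regression(self, target: str, source: str, *, free: bool = True,
                       value: float = 0.0, label: str | None = None) -> "SemModelSpec":
        allnames = self.observed + self.latents
        self._check(target, allnames, "model")
        self._check(source, allnames, "model")
        if target in self.fixed_x:
            raise ModelSpecError(f"fixed-x variable {target!r} cannot be endogenous")
        self._entries.append(_Entry("regression", target, source, free, value,
                                    label or f"b:{target}~{source}"))
        return self

    def add_variance(self, name: str, *, free: bool = True, value: float = 1.0,
                     label: str | None = None) -> "SemModelSpec":
        self._check(name, self.observed + self.latents, "model")
        self._entries.append(_Entry("variance", name, name, free, value,
                                    label or f"v:{name}"))
        return self

    def add_covariance(self, a: str, b: str, *, free: bool = True, value: float = 0.0,
                       label: str | None = None) -> "SemModelSpec":
        if a == b:
            raise ModelSpecError("use add_variance for diagonal cells")
        self._check(a, self.observed + self.latents, "model")
        self._check(b, self.observed + self.latents, "model")
        key = "~~".join(sorted([a, b]))
        self._entries.append(_Entry("covariance", a, b, free, value,
                                    label or f"c:{key}"))
        return self

    def set_fixed_x(self, names: Iterable[str]) -> "SemModelSpec":
        names = list(names)
        for n in names:
            self._check(n, self.observed, "observed")
        self.fixed_x = names
        return self

    @staticmethod
    def _check(name: str, pool: Sequence[str], what: str) -> None:
        if name not in pool:
            raise ModelSpecError(f"unknown {what} variable {name!r}")

    # ------------------------------------------------------------- structure
    @property
    def structural_observed(self) -> list[str]:
        """Observed variables that are nodes of the structural part."""
        used = set(self.fixed_x)
        for e in self._entries:
            if e.kind == "regression":
                used.update([e.a, e.b])
            elif e.kind in ("variance", "covariance"):
                # an explicit (co)variance on an observed var makes it structural
                # only when it is also used in a regression or fixed-x; pure
                # indicator variances belong to Theta.
                pass
        return [o for o in self.observed if o in used]

    @property
    def nodes(self) -> list[str]:
        return self.latents + self.structural_observed

    @property
    def indicator_observed(self) -> list[str]:
        s = set(self.structural_observed)
        return [o for o in self.observed if o not in s]

    def validate(self) -> None:
        """Check identification conventions and structural sanity."""
        nodes = self.nodes
        # acyclicity of B
        edges = [(e.b, e.a) for e in self._entries if e.kind == "regression"]
        order: dict[str, int] = {}
        remaining = {n: set() for n in nodes}
        for s, t in edges:
            if s in remaining and t in remaining:
                remaining[t].add(s)
        placed = 0
        while True:
            ready = [n for n, deps in remaining.items() if not deps]
            if not ready:
                break
            for n in ready:
                order[n] = placed
                placed += 1
                del remaining[n]
            for deps in remaining.values():
                deps.difference_update(ready)
        if remaining:
            raise ModelSpecError(f"structural paths contain a cycle through {sorted(remaining)}")
        # latent scaling
        for lat in self.latents:
            loads = [e for e in self._entries if e.kind == "loading" and e.b == lat]
            down = [e for e in self._entries if e.kind == "regression"
                    and e.b == lat and e.a in self.latents]
            fixed_load = any(not e.free for e in loads) or any(not e.free for e in down)
            var_entries = [e for e in self._entries
                           if e.kind == "variance" and e.a == lat]
            fixed_var = any(not e.free for e in var_entries)
            any_free = any(e.free for e in loads + down)
            if fixed_load and fixed_var and any_free:
                raise ModelSpecError(f"latent {lat!r} is over-scaled (fixed loading and fixed variance)")
            if not fixed_load and not fixed_var:
                raise ModelSpecError(f"latent {lat!r} has no scale (fix one loading or its variance)")

    # ------------------------------------------------------------ completion
    def _completed_entries(self) -> list[_Entry]:
        """Entries plus the default residual/disturbance variances."""
        entries = list(self._entries)
        have_var = {e.a for e in entries if e.kind == "variance"}
        for o in self.indicator_observed:
            if o not in have_var:
                entries.append(_Entry("variance", o, o, True, 1.0, f"v:{o}"))
        for n in self.nodes:
            if n not in have_var:
                if n in self.fixed_x:
                    entries.append(_Entry("variance", n, n, False, np.nan, f"v:{n}"))
                else:
                    entries.append(_Entry("variance", n, n, True, 1.0, f"v:{n}"))
        # fixed-x covariances among all fixed-x pairs
        have_cov = {frozenset((e.a, e.b)) for e in entries if e.kind == "covariance"}
        for i, a in enumerate(self.fixed_x):
            for b in self.fixed_x[i + 1:]:
                if frozenset((a, b)) not in have_cov:
                    entries.append(_Entry("covariance", a, b, False, np.nan,
                                          f"c:{'~~'.join(sorted([a, b]))}"))
        return entries

    # --------------------------------------------------------------- counting
    def n_free_parameters(self) -> int:
        labels: set[str] = set()
        for g in range(self.n_groups):
            for e in self._completed_entries():
                if e.free:
                    labels.add(self._group_label(e.label, g))
        return len(labels)

    def _group_label(self, label: str, g: int) -> str:
        if self.n_groups == 1 or label in self.equal_across_groups:
            return label
        return f"{label}@g{g}"

    def count_df(self) -> int:
        """Model degrees of freedom.

        Moments are ``p(p+1)/2`` per group minus the moments frozen at sample
        values under the fixed-x convention; free parameters are counted once
        per distinct label.
        """
        p = len(self.observed)
        q = len(self.fixed_x)
        per_group = p * (p + 1) // 2 - q * (q + 1) // 2
        return per_group * self.n_groups - self.n_free_parameters()

    # ------------------------------------------------------------- compiling
    def compile(self) -> "CompiledModel":
        self.validate()
        return CompiledModel(self)

    # ----------------------------------------------------------------- clone
    def to_multigroup(self, group_var: str,
                      equal_labels: Iterable[str] = ()) -> "SemModelSpec":
        """Two-group version of a single-group spec.

        ``equal_labels`` are parameter labels tied across the groups; all
        other free parameters are estimated separately per group.
        """
        if self.n_groups != 1:
            raise ModelSpecError("spec is already multigroup")
        new = copy.deepcopy(self)
        new.group_var = group_var
        new.n_groups = 2
        new.equal_across_groups = set(equal_labels)
        return new

    def free_labels(self) -> set[str]:
        out: set[str] = set()
        for g in range(self.n_groups):
            for e in self._completed_entries():
                if e.free:
                    out.add(self._group_label(e.label, g))
        return out

    # ------------------------------------------------------------------ yaml
    def to_yaml(self) -> str:
        doc = {
            "observed": self.observed,
            "latents": self.latents,
            "group_var": self.group_var,
            "n_groups": self.n_groups,
            "fixed_x": self.fixed_x,
            "equal_across_groups": sorted(self.equal_across_groups),
            "entries": [
                {"kind": e.kind, "a": e.a, "b": e.b, "free": e.free,
                 "value": None if (isinstance(e.value, float) and np.isnan(e.value)) else float(e.value),
                 "label": e.label}
                for e in self._entries
            ],
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SemModelSpec":
        doc = yaml.safe_load(text)
        spec = cls(doc["observed"], doc.get("latents", []),
                   group_var=doc.get("group_var"),
                   n_groups=doc.get("n_groups", 1) if doc.get("group_var") else 1)
        spec.fixed_x = list(doc.get("fixed_x", []))
        spec.equal_across_groups = set(doc.get("equal_across_groups", []))
        for e in doc.get("entries", []):
            value = e["value"] if e["value"] is not None else np.nan
            spec._entries.append(_Entry(e["kind"], e["a"], e["b"], e["free"],
                                        value, e["label"]))
        return spec


@dataclass
class FreeParameter:
    label: str
    lower: float  # -inf except variance parameters
    is_variance: bool
    cells: list = field(default_factory=list)  # (group, matrix, i, j)


class CompiledModel:
    """Index structure mapping a free-parameter vector onto the matrices.

    Attributes
    ----------
    params : list[FreeParameter]
        Distinct free parameters (after equality collapsing), in a stable
        order.  ``cells`` lists every (group, matrix, i, j) the parameter
        occupies; symmetric cells are stored once with (i >= j) and mirrored
        when materializing.
    """

    MATS = ("lam", "b", "psi", "theta")
    VARIANCE_FLOOR = 1e-6

    def __init__(self, spec: SemModelSpec):
        self.spec = spec
        self.obs = list(spec.observed)
        self.nodes = spec.nodes
        self.n_groups = spec.n_groups
        p, m = len(self.obs), len(self.nodes)
        self.p, self.m = p, m
        oi = {o: i for i, o in enumerate(self.obs)}
        ni = {n: i for i, n in enumerate(self.nodes)}
        self.fixedx_idx = [ni[x] for x in spec.fixed_x]
        self.fixedx_obs_idx = [oi[x] for x in spec.fixed_x]

        self._base = []  # per group dict of fixed matrices
        param_map: dict[str, FreeParameter] = {}
        self.params: list[FreeParameter] = []
        for g in range(self.n_groups):
            base = {
                "lam": np.zeros((p, m)),
                "b": np.zeros((m, m)),
                "psi": np.zeros((m, m)),
                "theta": np.zeros((p, p)),
            }
            # identity loadings for observed structural nodes
            for o in spec.structural_observed:
                base["lam"][oi[o], ni[o]] = 1.0
            for e in spec._completed_entries():
                mat, i, j = self._locate(e, oi, ni)
                if e.free:
                    lab = spec._group_label(e.label, g)
                    fp = param_map.get(lab)
                    if fp is None:
                        is_var = e.kind == "variance"
                        fp = FreeParameter(lab, self.VARIANCE_FLOOR if is_var else -np.inf,
                                           is_var)
                        param_map[lab] = fp
                        self.params.append(fp)
                    fp.cells.append((g, mat, i, j))
                else:
                    base[mat][i, j] = e.value
                    if mat in ("psi", "theta") and i != j:
                        base[mat][j, i] = e.value
            self._base.append(base)
        self.npar = len(self.params)
        self.labels = [fp.label for fp in self.params]
        self.lower = np.array([fp.lower for fp in self.params])
        # sample-dependent fixed-x values, filled by the fitter
        self._fixedx_values: list[np.ndarray | None] = [None] * self.n_groups

    def _locate(self, e: _Entry, oi: dict, ni: dict) -> tuple[str, int, int]:
        struct = set(self.nodes)
        if e.kind == "loading":
            return "lam", oi[e.a], ni[e.b]
        if e.kind == "regression":
            return "b", ni[e.a], ni[e.b]
        if e.kind == "variance":
            if e.a in struct:
                return "psi", ni[e.a], ni[e.a]
            return "theta", oi[e.a], oi[e.a]
        # covariance
        if e.a in struct and e.b in struct:
            return "psi", ni[e.a], ni[e.b]
        if e.a not in struct and e.b not in struct:
            return "theta", oi[e.a], oi[e.b]
        raise ModelSpecError(
            f"covariance between a structural and a pure indicator variable "
            f"({e.a!r}, {e.b!r}) is not representable")

    # ----------------------------------------------------------- fixed-x fill
    def set_fixed_x_values(self, group: int, cov_xx: np.ndarray) -> None:
        """Freeze the fixed-x block of Psi at the sample covariance."""
        self._fixedx_values[group] = np.asarray(cov_xx, float)

    def n_fixed_moments(self) -> int:
        q = len(self.fixedx_idx)
        return q * (q + 1) // 2 * self.n_groups

    # ------------------------------------------------------------ materialize
    def matrices(self, theta: np.ndarray, group: int):
        """Return (Lambda, B, Psi, Theta) for one group at parameter vector theta."""
        base = self._base[group]
        lam = base["lam"].copy()
        b = base["b"].copy()
        psi = base["psi"].copy()
        theta_m = base["theta"].copy()
        out = {"lam": lam, "b": b, "psi": psi, "theta": theta_m}
        for val, fp in zip(theta, self.params):
            for (g, mat, i, j) in fp.cells:
                if g != group:
                    continue
                out[mat][i, j] = val
                if mat in ("psi", "theta") and i != j:
                    out[mat][j, i] = val
        fx = self._fixedx_values[group]
        if fx is not None and self.fixedx_idx:
            idx = np.array(self.fixedx_idx)
            psi[np.ix_(idx, idx)] = fx
        return lam, b, psi, theta_m

    def start_values(self, sample_sd: np.ndarray | None = None) -> np.ndarray:
        """Heuristic starts: loadings 0.7*SD(indicator), variances 0.5*var, paths 0."""
        p = len(self.obs)
        sd = np.ones(p) if sample_sd is None else np.asarray(sample_sd, float)
        theta0 = np.zeros(self.npar)
        for k, fp in enumerate(self.params):
            g, mat, i, j = fp.cells[0]
            if mat == "lam":
                theta0[k] = 0.7 * sd[i]
            elif mat == "theta" and i == j:
                theta0[k] = 0.5 * sd[i] ** 2
            elif mat == "psi" and i == j:
                node = self.nodes[j]
                if node in self.spec.observed:
                    theta0[k] = 0.5 * sd[self.obs.index(node)] ** 2
                else:
                    theta0[k] = 0.5
            else:
                theta0[k] = 0.0
        return theta0
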