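"""Mediation decomposition and the proportion-mediated effect size.

All paths are taken from the fully standardized solution; indirect products
a_i * b_i get delta-method standard errors from the joint (robust when
available) parameter covariance.  The percentage effect size is the
proportion of the total effect carried by the indirect paths,

    100 * sum_i(a_i b_i) / (sum_i(a_i b_i) + c'),

reported with an "inconsistent mediation" flag when the indirect and total
effects disagree in sign (the value then falls outside [0, 100]).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .fit import FitResult
from .standardize import standardized_cov


class MediationError(ValueError):
    pass


@dataclass
class PathEstimate:
    name: str
    estimate: float
    se: float
    z: float
    p: float


@dataclass
class MediationResult:
    a_paths: list[PathEstimate]
    b_paths: list[PathEstimate]
    c_prime: PathEstimate
    indirect_products: list[PathEstimate]
    total_indirect: float
    total_effect: float
    effect_size_pct: float
    inconsistent: bool
    mediators: list[str]
    flags: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        as_d = lambda p: {"estimate": p.estimate, "se": p.se, "z": p.z, "p": p.p}
        return {
            "mediators": self.mediators,
            "a_paths": {p.name: as_d(p) for p in self.a_paths},
            "b_paths": {p.name: as_d(p) for p in self.b_paths},
            "c_prime": as_d(self.c_prime),
            "indirect": {p.name: as_d(p) for p in self.indirect_products},
            "total_indirect": self.total_indirect,
            "total_effect": self.total_effect,
            "effect_size_pct": self.effect_size_pct,
            "inconsistent_mediation": self.inconsistent,
            "flags": self.flags,
        }


def effect_size(indirect_products, c_prime: float) -> tuple[float, bool]:
    """Percent of the total effect carried by the indirect paths.

    Returns (percentage, inconsistent_flag); raises on a zero total effect.
    """
    ab = float(np.sum(indirect_products))
    total = ab + float(c_prime)
    if total == 0:
        raise MediationError("total effect is zero: proportion mediated undefined")
    inconsistent = ab != 0 and np.sign(ab) != np.sign(total)
    return 100.0 * ab / total, inconsistent


def decompose(fit: FitResult, exposure: str, mediators: list[str],
              outcome: str) -> MediationResult:
    """Split a fitted model's exposure effect into direct and indirect parts.

    ``exposure``/``mediators``/``outcome`` name model variables; the fit must
    contain paths exposure->mediator, mediator->outcome and the direct path
    exposure->outcome.
    """
    spec = fit.spec
    by_pair = {}
    for e in spec._entries:
        if e.kind == "regression":
            by_pair[(e.a, e.b)] = e.label

    labels = []
    for m in mediators:
        if (m, exposure) not in by_pair:
            raise MediationError(f"missing a-path {exposure} -> {m}")
        if (outcome, m) not in by_pair:
            raise MediationError(f"missing b-path {m} -> {outcome}")
    if (outcome, exposure) not in by_pair:
        raise MediationError(f"missing direct path {exposure} -> {outcome}")
    a_labels = [by_pair[(m, exposure)] for m in mediators]
    b_labels = [by_pair[(outcome, m)] for m in mediators]
    c_label = by_pair[(outcome, exposure)]
    labels = a_labels + b_labels + [c_label]

    est, cov = standardized_cov(fit, labels)
    k = len(mediators)
    a, b_, c = est[:k], est[k:2 * k], est[2 * k]

    def path(name, value, var) -> PathEstimate:
        se = float(np.sqrt(max(var, 0.0)))
        z = value / se if se > 0 else np.nan
        p = 2 * stats.norm.sf(abs(z)) if se > 0 else np.nan
        return PathEstimate(name, float(value), se, float(z), float(p))

    a_paths = [path(f"a:{m}", a[i], cov[i, i]) for i, m in enumerate(mediators)]
    b_paths = [path(f"b:{m}", b_[i], cov[k + i, k + i]) for i, m in enumerate(mediators)]
    c_prime = path("c_prime", c, cov[2 * k, 2 * k])

    indirect = []
    for i, m in enumerate(mediators):
        ai, bi = a[i], b_[i]
        # delta method on the product: grad = (b, a) over (a_i, b_i)
        var = (bi ** 2 * cov[i, i] + ai ** 2 * cov[k + i, k + i]
               + 2 * ai * bi * cov[i, k + i])
        indirect.append(path(f"ab:{m}", ai * bi, var))

    total_indirect = float(np.sum([p.estimate for p in indirect]))
    total = total_indirect + c_prime.estimate
    flags = []
    try:
        pct, inconsistent = effect_size([p.estimate for p in indirect],
                                        c_prime.estimate)
    except MediationError:
        pct, inconsistent = np.nan, False
        flags.append("zero total effect")
    if inconsistent:
        flags.append("inconsistent mediation (indirect and total effect "
                     "differ in sign)")
    return MediationResult(
        a_paths=a_paths, b_paths=b_paths, c_prime=c_prime,
        indirect_products=indirect, total_indirect=total_indirect,
        total_effect=float(total), effect_size_pct=float(pct),
        inconsistent=bool(inconsistent), mediators=list(mediators),
        flags=flags,
    )
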