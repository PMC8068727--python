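"""Declarative factor-model specifications shared by the phenotypic CFA and
genomic SEM engines.

A :class:`FactorModelSpec` says which indicators load on which factors, which
parameters are fixed, whether a mean structure is estimated, and (for
multi-group fits) which parameter classes are constrained equal across groups.
Identification defaults to unit factor variances, so loadings are reported on
the standardized-factor scale.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Sequence

import yaml

GROUP_CONSTRAINT_LEVELS = (
    "none",
    "loadings",
    "loadings+intercepts",
    "loadings+intercepts+residuals",
)

#: invariance-ladder level names, in nesting order
INVARIANCE_LEVELS = ("configural", "metric", "scalar", "residual")

#: map from ladder level to the cross-group constraint set it imposes
LEVEL_CONSTRAINTS = {
    "configural": "none",
    "metric": "loadings",
    "scalar": "loadings+intercepts",
    "residual": "loadings+intercepts+residuals",
}

_PARAM_RE = re.compile(r"^(lambda|psi|theta|nu|alpha)\[([^\]]+)\]$")


@dataclass(frozen=True)
class FactorModelSpec:
    """Specification of a confirmatory factor model.

    Parameters
    ----------
    indicators : ordered observed-variable names.
    factors : ordered latent-factor names. An empty list denotes the
        independence (baseline) model: uncorrelated indicators.
    loading_pattern : map indicator -> factors it loads on. Defaults to every
        indicator loading on every factor only when a single factor is given.
    fixed_params : list of ``(name, value)`` pairs, e.g. ``("theta[MDD]", 0.0)``
        or ``("lambda[MDD,INT]", 1.0)``. Applied in every group.
    factor_covariances : "free" (correlated factors) or "fixed" (orthogonal).
    mean_structure : estimate intercepts/factor means (required for scalar
        invariance testing and FIML).
    group_constraints : which parameter classes are equal across groups.
    identification : "variance" fixes factor variances to 1 (default);
        "loading" fixes the first loading of each factor to 1 instead.
    """

    indicators: tuple
    factors: tuple
    loading_pattern: dict = field(default=None)
    fixed_params: tuple = ()
    factor_covariances: str = "free"
    mean_structure: bool = False
    group_constraints: str = "none"
    identification: str = "variance"

    def __post_init__(self):
        object.__setattr__(self, "indicators", tuple(self.indicators))
        object.__setattr__(self, "factors", tuple(self.factors))
        if len(set(self.indicators)) != len(self.indicators):
            raise ValueError("duplicate indicator names")
        if len(set(self.factors)) != len(self.factors):
            raise ValueError("duplicate factor names")
        if self.loading_pattern is None:
            if len(self.factors) == 1:
                pattern = {ind: [self.factors[0]] for ind in self.indicators}
            elif len(self.factors) == 0:
                pattern = {ind: [] for ind in self.indicators}
            else:
                raise ValueError(
                    "loading_pattern is required for multi-factor models"
                )
            object.__setattr__(self, "loading_pattern", pattern)
        pattern = {k: list(v) for k, v in self.loading_pattern.items()}
        object.__setattr__(self, "loading_pattern", pattern)
        for ind in self.indicators:
            if ind not in pattern:
                raise ValueError(f"indicator {ind!r} missing from loading_pattern")
            if self.factors and not pattern[ind]:
                raise ValueError(f"indicator {ind!r} loads on no factor")
            for fac in pattern[ind]:
                if fac not in self.factors:
                    raise ValueError(f"unknown factor {fac!r} for {ind!r}")
        if self.factor_covariances not in ("free", "fixed"):
            raise ValueError("factor_covariances must be 'free' or 'fixed'")
        if self.group_constraints not in GROUP_CONSTRAINT_LEVELS:
            raise ValueError(
                f"group_constraints must be one of {GROUP_CONSTRAINT_LEVELS}"
            )
        if self.identification not in ("variance", "loading"):
            raise ValueError("identification must be 'variance' or 'loading'")
        object.__setattr__(
            self, "fixed_params", tuple((str(k), float(v)) for k, v in self.fixed_params)
        )
        for name, _ in self.fixed_params:
            self._parse_param(name)  # validates

    # -- helpers -----------------------------------------------------------

    @property
    def n_indicators(self) -> int:
        return len(self.indicators)

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    def _parse_param(self, name: str):
        """Return (matrix, i, j) index tuple for a parameter name."""
        m = _PARAM_RE.match(name.replace(" ", ""))
        if not m:
            raise ValueError(f"cannot parse parameter name {name!r}")
        mat, args = m.group(1), m.group(2).split(",")
        ind_ix = {v: i for i, v in enumerate(self.indicators)}
        fac_ix = {v: i for i, v in enumerate(self.factors)}
        if mat == "lambda":
            if len(args) != 2:
                raise ValueError(f"lambda parameter needs [indicator,factor]: {name}")
            return ("lambda", ind_ix[args[0]], fac_ix[args[1]])
        if mat == "psi":
            if len(args) != 2:
                raise ValueError(f"psi parameter needs [factor,factor]: {name}")
            return ("psi", fac_ix[args[0]], fac_ix[args[1]])
        if mat == "theta":
            return ("theta", ind_ix[args[0]], ind_ix[args[0]])
        if mat == "nu":
            return ("nu", ind_ix[args[0]], 0)
        return ("alpha", fac_ix[args[0]], 0)

    def fixed_map(self) -> dict:
        return {self._parse_param(k): v for k, v in self.fixed_params}

    def with_(self, **kw) -> "FactorModelSpec":
        return replace(self, **kw)

    def baseline_spec(self) -> "FactorModelSpec":
        """Independence model on the same indicators (the CFI/TLI baseline)."""
        return FactorModelSpec(
            indicators=self.indicators,
            factors=(),
            loading_pattern={i: [] for i in self.indicators},
            mean_structure=self.mean_structure,
        )

    # -- constructors ------------------------------------------------------

    @classmethod
    def one_factor(cls, indicators: Sequence[str], factor: str = "G", **kw):
        return cls(indicators=tuple(indicators), factors=(factor,), **kw)

    @classmethod
    def two_factor(cls, pattern: dict, factor_names=None, **kw):
        """``pattern`` maps each indicator to its factor name (or list)."""
        norm = {k: (v if isinstance(v, (list, tuple)) else [v]) for k, v in pattern.items()}
        facs = factor_names or sorted({f for v in norm.values() for f in v})
        return cls(indicators=tuple(norm), factors=tuple(facs), loading_pattern=norm, **kw)

    @classmethod
    def from_yaml(cls, path) -> "FactorModelSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            indicators=tuple(d["indicators"]),
            factors=tuple(d.get("factors", [])),
            loading_pattern=d.get("loading_pattern"),
            fixed_params=tuple((k, v) for k, v in d.get("fixed_params", {}).items()),
            factor_covariances=d.get("factor_covariances", "free"),
            mean_structure=bool(d.get("mean_structure", False)),
            group_constraints=d.get("group_constraints", "none"),
            identification=d.get("identification", "variance"),
        )

    def to_yaml(self, path):
        d = {
            "indicators": list(self.indicators),
            "factors": list(self.factors),
            "loading_pattern": {k: list(v) for k, v in self.loading_pattern.items()},
            "fixed_params": {k: v for k, v in self.fixed_params},
            "factor_covariances": self.factor_covariances,
            "mean_structure": self.mean_structure,
            "group_constraints": self.group_constraints,
            "identification": self.identification,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)
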