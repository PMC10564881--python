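"""Hyperparameter search-space declarations and genetic operators on them.

Each hyperparameter declares its type (real / integer / categorical), bounds
or choices, optional log scaling, and a mutation shift in its own units
(log10 units for log-scaled parameters).  The default shift is 10% of the
bound width.  These defaults are the package's own choices: the tuning ranges
used in the original study are not public.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["HyperParam", "SearchSpace", "default_space"]


@dataclass
class HyperParam:
    name: str
    kind: str  # 'real' | 'int' | 'categorical'
    bounds: tuple[float, float] | None = None
    choices: list | None = None
    log: bool = False
    mutation_shift: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"real", "int", "categorical"}:
            raise ValueError(f"unknown hyperparameter kind {self.kind!r}")
        if self.kind == "categorical":
            if not self.choices:
                raise ValueError(f"{self.name}: categorical needs choices")
            return
        lo, hi = self.bounds
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError(f"{self.name}: bounds must be finite with lo < hi")
        if self.log and lo <= 0:
            raise ValueError(f"{self.name}: log scale needs positive bounds")
        if self.mutation_shift is None:
            width = np.log10(hi) - np.log10(lo) if self.log else hi - lo
            self.mutation_shift = 0.1 * width
        if not 0 <= self.mutation_shift <= (np.log10(hi / lo) if self.log else hi - lo):
            raise ValueError(f"{self.name}: mutation shift outside bound width")

    # -- sampling / genetic operators --------------------------------------
    def sample(self, rng: np.random.Generator):
        if self.kind == "categorical":
            return self.choices[rng.integers(len(self.choices))]
        lo, hi = self.bounds
        if self.log:
            val = 10 ** rng.uniform(np.log10(lo), np.log10(hi))
        else:
            val = rng.uniform(lo, hi)
        return int(round(val)) if self.kind == "int" else float(val)

    def _reflect(self, x: float) -> float:
        lo, hi = (np.log10(self.bounds[0]), np.log10(self.bounds[1])) if self.log else self.bounds
        width = hi - lo
        if width == 0:
            return lo
        # reflect into [lo, hi]
        y = (x - lo) % (2 * width)
        y = 2 * width - y if y > width else y
        return lo + y

    def mutate(self, value, rng: np.random.Generator):
        """Shift by +/- the declared mutation shift, reflected at bounds."""
        if self.kind == "categorical":
            others = [c for c in self.choices if c != value]
            return value if not others else others[rng.integers(len(others))]
        if self.mutation_shift == 0:
            return value
        sign = 1 if rng.uniform() < 0.5 else -1
        x = np.log10(value) if self.log else float(value)
        x = self._reflect(x + sign * self.mutation_shift)
        out = 10**x if self.log else x
        return int(round(out)) if self.kind == "int" else float(out)

    def average(self, a, b, rng: np.random.Generator):
        """Element-wise parent average (categorical: seeded parent choice)."""
        if self.kind == "categorical":
            return a if rng.uniform() < 0.5 else b
        if self.log:
            out = 10 ** ((np.log10(a) + np.log10(b)) / 2)
        else:
            out = (a + b) / 2
        return int(round(out)) if self.kind == "int" else float(out)

    def contains(self, value) -> bool:
        if self.kind == "categorical":
            return value in self.choices
        lo, hi = self.bounds
        tol = 1e-9 * max(1.0, abs(hi))
        return lo - tol <= value <= hi + tol


@dataclass
class SearchSpace:
    params: list[HyperParam] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [p.name for p in self.params]
        if len(set(names)) != len(names):
            raise ValueError("duplicate hyperparameter names")

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.params]

    def __getitem__(self, name: str) -> HyperParam:
        for p in self.params:
            if p.name == name:
                return p
        raise KeyError(name)

    def sample(self, rng: np.random.Generator) -> dict:
        return {p.name: p.sample(rng) for p in self.params}

    def validate(self, assignment: dict) -> None:
        for p in self.params:
            if p.name not in assignment:
                raise ValueError(f"missing hyperparameter {p.name!r}")
            if not p.contains(assignment[p.name]):
                raise ValueError(
                    f"hyperparameter {p.name!r}={assignment[p.name]!r} outside the search space"
                )


def default_space(family: str) -> SearchSpace:
    """Default (non-canonical) search space per classifier family."""
    if family == "neural_net":
        return SearchSpace(
            [
                HyperParam("learning_rate", "real", (1e-5, 1e-1), log=True),
                HyperParam("batch_size", "int", (16, 256)),
                HyperParam("epochs", "int", (10, 200)),
            ]
        )
    if family == "boosted_trees":
        return SearchSpace(
            [
                HyperParam("eta", "real", (0.01, 0.5)),
                HyperParam("max_depth", "int", (2, 10)),
                HyperParam("n_estimators", "int", (50, 500)),
                HyperParam("subsample", "real", (0.5, 1.0)),
                HyperParam("colsample_bytree", "real", (0.5, 1.0)),
                HyperParam("reg_lambda", "real", (0.0, 10.0)),
                HyperParam("gamma", "real", (0.0, 5.0)),
            ]
        )
    if family == "logistic_elasticnet":
        return SearchSpace(
            [
                HyperParam("l1_mix", "real", (0.0, 1.0)),
                HyperParam("strength", "real", (1e-3, 1e3), log=True),
            ]
        )
    raise ValueError(f"unknown family {family!r}")
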