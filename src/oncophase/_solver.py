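"""Thin MILP backend.

A minimal model-building surface (binary/continuous variables, linear
constraints, linear objective) solved through :func:`scipy.optimize.milp`,
which drives HiGHS. Keeping the surface this small means any branch-and-cut
backend could be swapped in behind it.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .exceptions import SolverError

__all__ = ["MilpBuilder", "SolveResult"]


@dataclass
class SolveResult:
    status: str  # optimal | timeout | infeasible | unbounded | failed
    objective: float | None
    x: np.ndarray | None
    gap: float | None
    seconds: float


@dataclass
class MilpBuilder:
    """Accumulates a minimization MILP and hands it to HiGHS."""

    n_vars: int = 0
    _integrality: list[int] = field(default_factory=list)
    _lb: list[float] = field(default_factory=list)
    _ub: list[float] = field(default_factory=list)
    # constraint triplets + row bounds
    _rows: list[int] = field(default_factory=list)
    _cols: list[int] = field(default_factory=list)
    _vals: list[float] = field(default_factory=list)
    _con_lb: list[float] = field(default_factory=list)
    _con_ub: list[float] = field(default_factory=list)
    _obj: dict[int, float] = field(default_factory=dict)
    constraint_families: dict[str, int] = field(default_factory=dict)

    def add_binary(self) -> int:
        idx = self.n_vars
        self.n_vars += 1
        self._integrality.append(1)
        self._lb.append(0.0)
        self._ub.append(1.0)
        return idx

    def add_continuous(self, lb: float = 0.0, ub: float = 1.0) -> int:
        idx = self.n_vars
        self.n_vars += 1
        self._integrality.append(0)
        self._lb.append(lb)
        self._ub.append(ub)
        return idx

    def add_constraint(
        self,
        coeffs: dict[int, float],
        lb: float = -np.inf,
        ub: float = np.inf,
        family: str = "",
    ) -> None:
        row = len(self._con_lb)
        for col, val in coeffs.items():
            self._rows.append(row)
            self._cols.append(col)
            self._vals.append(val)
        self._con_lb.append(lb)
        self._con_ub.append(ub)
        if family:
            self.constraint_families[family] = self.constraint_families.get(family, 0) + 1

    def set_objective(self, coeffs: dict[int, float]) -> None:
        self._obj = dict(coeffs)

    @property
    def n_binary(self) -> int:
        return sum(self._integrality)

    @property
    def n_continuous(self) -> int:
        return self.n_vars - self.n_binary

    @property
    def n_constraints(self) -> int:
        return len(self._con_lb)

    def solve(
        self, mip_gap: float = 1e-9, time_limit: float | None = None
    ) -> SolveResult:
        c = np.zeros(self.n_vars)
        for idx, val in self._obj.items():
            c[idx] = val
        A = sparse.csr_matrix(
            (self._vals, (self._rows, self._cols)),
            shape=(self.n_constraints, self.n_vars),
        )
        options: dict = {"mip_rel_gap": mip_gap}
        if time_limit is not None:
            options["time_limit"] = float(time_limit)
        t0 = time.perf_counter()
        res = milp(
            c,
            constraints=LinearConstraint(A, np.array(self._con_lb), np.array(self._con_ub)),
            integrality=np.array(self._integrality),
            bounds=Bounds(np.array(self._lb), np.array(self._ub)),
            options=options,
        )
        seconds = time.perf_counter() - t0
        # scipy.optimize.milp status: 0 optimal, 1 iteration/time limit,
        # 2 infeasible, 3 unbounded, 4 other
        if res.status == 0:
            status = "optimal"
        elif res.status == 1 and res.x is not None:
            status = "timeout"
        elif res.status == 2:
            raise SolverError("model is infeasible")
        elif res.status == 3:
            raise SolverError("model is unbounded")
        else:
            raise SolverError(f"solver failed: {res.message}")
        gap = float(res.mip_gap) if getattr(res, "mip_gap", None) is not None else None
        return SolveResult(
            status=status,
            objective=float(res.fun),
            x=np.asarray(res.x),
            gap=gap,
            seconds=seconds,
        )
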