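"""Minimal MILP facade over :func:`scipy.optimize.milp` (HiGHS).

The rest of the package talks to this interface only — named binary and
continuous variables, linear constraints, a linear objective, and the
three-way status {optimal, infeasible, limit} — so any MILP engine can
be slotted in behind it.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.sparse import csr_array


class Status(Enum):
    OPTIMAL = "optimal"
    INFEASIBLE = "infeasible"
    LIMIT = "limit"
    ERROR = "error"


class SolverError(RuntimeError):
    pass


@dataclass
class Solution:
    status: Status
    objective: float | None
    values: dict[str, float]


class MilpProblem:
    """A mixed-integer linear program assembled constraint by constraint.

    Constraints are linear expressions ``lb <= sum(coeff * var) <= ub``
    given as ``{var_name: coeff}`` maps.  Minimization only.
    """

    def __init__(self) -> None:
        self._names: list[str] = []
        self._index: dict[str, int] = {}
        self._integrality: list[int] = []
        self._lb: list[float] = []
        self._ub: list[float] = []
        self._constraints: list[tuple[dict[str, int], float, float, str]] = []
        self._objective: dict[str, float] = {}

    # -- variables -------------------------------------------------------
    def add_binary(self, name: str) -> str:
        return self._add_var(name, 1, 0.0, 1.0)

    def add_continuous(self, name: str, lb: float = 0.0, ub: float = np.inf) -> str:
        return self._add_var(name, 0, lb, ub)

    def _add_var(self, name: str, integrality: int, lb: float, ub: float) -> str:
        if name in self._index:
            raise SolverError(f"duplicate variable {name!r}")
        self._index[name] = len(self._names)
        self._names.append(name)
        self._integrality.append(integrality)
        self._lb.append(lb)
        self._ub.append(ub)
        return name

    def has_variable(self, name: str) -> bool:
        return name in self._index

    @property
    def num_variables(self) -> int:
        return len(self._names)

    @property
    def num_constraints(self) -> int:
        return len(self._constraints)

    # -- constraints / objective ----------------------------------------
    def add_constraint(
        self,
        coeffs: dict[str, float],
        lb: float = -np.inf,
        ub: float = np.inf,
        name: str = "",
    ) -> None:
        for var in coeffs:
            if var not in self._index:
                raise SolverError(f"constraint {name!r} uses unknown variable {var!r}")
        self._constraints.append((dict(coeffs), float(lb), float(ub), name))

    def set_objective(self, coeffs: dict[str, float]) -> None:
        self._objective = dict(coeffs)

    # -- solving ---------------------------------------------------------
    def solve(self, time_limit: float | None = None, mip_gap: float = 0.0) -> Solution:
        n = len(self._names)
        c = np.zeros(n)
        for var, coeff in self._objective.items():
            c[self._index[var]] = coeff

        rows, cols, data, lbs, ubs = [], [], [], [], []
        for row, (coeffs, lb, ub, _name) in enumerate(self._constraints):
            for var, coeff in coeffs.items():
                rows.append(row)
                cols.append(self._index[var])
                data.append(coeff)
            lbs.append(lb)
            ubs.append(ub)
        constraints = None
        if self._constraints:
            a = csr_array(
                (data, (rows, cols)), shape=(len(self._constraints), n)
            )
            constraints = LinearConstraint(a, np.array(lbs), np.array(ubs))

        options: dict = {"mip_rel_gap": mip_gap}
        if time_limit is not None:
            options["time_limit"] = time_limit
        res = milp(
            c,
            integrality=np.array(self._integrality),
            bounds=Bounds(np.array(self._lb), np.array(self._ub)),
            constraints=constraints,
            options=options,
        )
        if res.status == 0:
            values = {name: float(res.x[k]) for k, name in enumerate(self._names)}
            return Solution(Status.OPTIMAL, float(res.fun), values)
        if res.status == 2:
            return Solution(Status.INFEASIBLE, None, {})
        if res.status == 1:
            return Solution(Status.LIMIT, None, {})
        return Solution(Status.ERROR, None, {})
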