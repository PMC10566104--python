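"""Box-Behnken designs, coded quadratic response surfaces, ANOVA, and
Derringer desirability optimization.

The workflow mirrors standard response-surface practice for chromatographic
method development: three factors are varied over three levels each in a
Box-Behnken design (BBD), a full second-order polynomial is fitted in coded
units by ordinary least squares, term significance is judged by partial
(drop-one-term, Type III) sums of squares, and the operating point is chosen
by maximizing the geometric-mean desirability of the fitted responses.

Coded units map each factor's (low, center, high) levels onto (-1, 0, +1)
piecewise-linearly, so coefficients are directly comparable across factors
with different physical units.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

TERM_NAMES = ("Intercept", "A", "B", "C", "AB", "AC", "BC", "A^2", "B^2", "C^2")


class UnsupportedDesignError(ValueError):
    """Raised when a design request falls outside the 3-factor BBD family."""


class SingularDesignError(ValueError):
    """Raised when the 10-term quadratic basis is rank-deficient on a design."""


class OutOfBoundsWarning(UserWarning):
    """A factor level outside [low, high] was coded by extrapolation."""


@dataclass(frozen=True)
class FactorSpec:
    """One experimental factor with its three BBD levels.

    ``low``, ``center`` and ``high`` are actual (physical) levels mapped to
    coded -1, 0, +1.  The mapping is piecewise linear, so an asymmetric
    center (center != (low+high)/2) is allowed and stays monotone.
    """

    name: str
    low: float
    center: float
    high: float
    units: str = ""

    def __post_init__(self) -> None:
        if not (self.low < self.center < self.high):
            raise ValueError(
                f"factor {self.name!r}: require low < center < high, "
                f"got {self.low}, {self.center}, {self.high}"
            )

    def code(self, actual):
        """Map actual level(s) to coded units (low→-1, center→0, high→+1)."""
        x = np.asarray(actual, dtype=float)
        lo_span = self.center - self.low
        hi_span = self.high - self.center
        coded = np.where(x <= self.center, (x - self.center) / lo_span,
                         (x - self.center) / hi_span)
        if np.any((x < self.low) | (x > self.high)):
            warnings.warn(
                f"factor {self.name!r}: level outside [{self.low}, {self.high}]; "
                "coded value extrapolated", OutOfBoundsWarning, stacklevel=2)
        return coded if coded.ndim else float(coded)

    def uncode(self, coded):
        """Inverse of :meth:`code`; exact round-trip to 1e-12."""
        z = np.asarray(coded, dtype=float)
        actual = np.where(z <= 0, self.center + z * (self.center - self.low),
                          self.center + z * (self.high - self.center))
        return actual if actual.ndim else float(actual)


def code_levels(factors, actual_point):
    """Code a point (one value per factor) into the (-1, 0, +1) scale."""
    return np.array([f.code(x) for f, x in zip(factors, actual_point, strict=True)])


def uncode_levels(factors, coded_point):
    """Map a coded point back to actual factor levels."""
    return np.array([f.uncode(z) for f, z in zip(factors, coded_point, strict=True)])


# The 12 edge midpoints of the 3-factor BBD in conventional standard order:
# (±1,±1,0) block, then (±1,0,±1), then (0,±1,±1).
_BBD3_EDGES = [
    (-1, -1, 0), (1, -1, 0), (-1, 1, 0), (1, 1, 0),
    (-1, 0, -1), (1, 0, -1), (-1, 0, 1), (1, 0, 1),
    (0, -1, -1), (0, 1, -1), (0, -1, 1), (0, 1, 1),
]


@dataclass
class DesignTable:
    """A designed experiment: coded run matrix plus measured responses.

    ``coded`` has one row per run and one column per factor; ``responses``
    maps a response name to a vector aligned with the rows (absent until the
    experiment is run or simulated).
    """

    factors: tuple
    coded: np.ndarray
    std_order: np.ndarray
    run_order: np.ndarray
    responses: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coded = np.asarray(self.coded, dtype=float)
        self.std_order = np.asarray(self.std_order, dtype=int)
        self.run_order = np.asarray(self.run_order, dtype=int)
        n = self.coded.shape[0]
        if not (len(self.std_order) == len(self.run_order) == n):
            raise ValueError("std/run order length must match the run count")
        for name, y in list(self.responses.items()):
            y = np.asarray(y, dtype=float)
            if y.shape != (n,):
                raise ValueError(f"response {name!r} must have one value per run")
            self.responses[name] = y

    @property
    def n_runs(self) -> int:
        return self.coded.shape[0]

    @property
    def actual(self) -> np.ndarray:
        """Run matrix in actual (physical) units."""
        cols = [f.uncode(self.coded[:, j]) for j, f in enumerate(self.factors)]
        return np.column_stack(cols)

    def with_responses(self, **responses) -> "DesignTable":
        merged = dict(self.responses)
        for name, y in responses.items():
            merged[name] = np.asarray(y, dtype=float)
        return replace(self, responses=merged)

    def to_frame(self):
        import pandas as pd

        data = {"std": self.std_order, "run": self.run_order}
        for j, f in enumerate(self.factors):
            data[f.name] = f.uncode(self.coded[:, j])
        for name, y in self.responses.items():
            data[name] = y
        return pd.DataFrame(data)


def generate_bbd(factors, n_center: int = 5, seed=None) -> DesignTable:
    """Generate a 3-factor Box-Behnken design with ``n_center`` center runs.

    Standard order lists the 12 edge midpoints first, then the center
    replicates.  ``seed`` (optional) shuffles the run order; the standard
    order is always deterministic.
    """
    factors = tuple(factors)
    if len(factors) != 3:
        raise UnsupportedDesignError(
            f"only the 3-factor Box-Behnken design is supported, got {len(factors)} factors")
    if n_center < 1:
        raise ValueError("n_center must be >= 1 (pure error needs center replicates)")
    coded = np.array(_BBD3_EDGES + [(0, 0, 0)] * n_center, dtype=float)
    n = len(coded)
    std = np.arange(1, n + 1)
    if seed is None:
        run = std.copy()
    else:
        rng = np.random.default_rng(seed)
        run = rng.permutation(n) + 1
    return DesignTable(factors=factors, coded=coded, std_order=std, run_order=run)


def quadratic_basis(coded: np.ndarray) -> np.ndarray:
    """10-term second-order basis {1, A, B, C, AB, AC, BC, A², B², C²}."""
    X = np.atleast_2d(np.asarray(coded, dtype=float))
    A, B, C = X[:, 0], X[:, 1], X[:, 2]
    return np.column_stack([
        np.ones(len(X)), A, B, C, A * B, A * C, B * C, A * A, B * B, C * C,
    ])


@dataclass(frozen=True)
class QuadraticSurfaceModel:
    """Fitted full quadratic in coded units for one response.

    Exactly ten coefficients: intercept ``b0``, linear ``b_linear`` (A, B, C),
    two-factor interactions ``b_interaction`` (AB, AC, BC) and pure quadratic
    ``b_quadratic`` (A², B², C²).  Prediction at the coded origin equals b0.
    """

    response_name: str
    b0: float
    b_linear: tuple
    b_interaction: tuple
    b_quadratic: tuple
    basis: str = "coded"

    @property
    def coefficients(self) -> np.ndarray:
        return np.concatenate([[self.b0], self.b_linear,
                               self.b_interaction, self.b_quadratic])

    def predict(self, coded_point):
        """Evaluate the polynomial; vectorized over an (n, 3) array of points."""
        pts = np.atleast_2d(np.asarray(coded_point, dtype=float))
        y = quadratic_basis(pts) @ self.coefficients
        return float(y[0]) if np.ndim(coded_point) == 1 else y

    def to_dict(self) -> dict:
        return {
            "response_name": self.response_name,
            "basis": self.basis,
            "coefficients": dict(zip(TERM_NAMES, map(float, self.coefficients))),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QuadraticSurfaceModel":
        c = [d["coefficients"][t] for t in TERM_NAMES]
        return cls(response_name=d["response_name"], b0=c[0],
                   b_linear=tuple(c[1:4]), b_interaction=tuple(c[4:7]),
                   b_quadratic=tuple(c[7:10]), basis=d.get("basis", "coded"))


def predict(model: QuadraticSurfaceModel, coded_point):
    """Functional alias for :meth:`QuadraticSurfaceModel.predict`."""
    return model.predict(coded_point)


def _lstsq_sse(X: np.ndarray, y: np.ndarray):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def fit_quadratic(design: DesignTable, response_name: str) -> QuadraticSurfaceModel:
    """OLS fit of the 10-term coded quadratic to one response of a design."""
    if response_name not in design.responses:
        raise KeyError(f"design has no response {response_name!r}")
    y = design.responses[response_name]
    if design.n_runs < 10:
        raise ValueError("need at least 10 runs to fit the 10-term quadratic")
    if np.any(~np.isfinite(y)):
        raise ValueError(f"response {response_name!r} contains non-finite values")
    X = quadratic_basis(design.coded)
    if np.linalg.matrix_rank(X) < 10:
        # name the offending terms: columns whose removal does not drop the rank
        base_rank = np.linalg.matrix_rank(X)
        collinear = [TERM_NAMES[j] for j in range(10)
                     if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == base_rank]
        raise SingularDesignError(
            f"quadratic basis is rank-deficient on this design; "
            f"collinear terms: {', '.join(collinear)}")
    beta, _ = _lstsq_sse(X, y)
    return QuadraticSurfaceModel(
        response_name=response_name, b0=float(beta[0]),
        b_linear=tuple(map(float, beta[1:4])),
        b_interaction=tuple(map(float, beta[4:7])),
        b_quadratic=tuple(map(float, beta[7:10])))


@dataclass(frozen=True)
class AnovaRow:
    source: str
    ss: float
    df: int
    ms: float | None
    f: float | None
    p: float | None


@dataclass(frozen=True)
class AnovaTable:
    rows: tuple
    r2: float
    r2_adj: float
    degenerate: bool = False

    def __getitem__(self, source: str) -> AnovaRow:
        for row in self.rows:
            if row.source == source:
                return row
        raise KeyError(source)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [{"source": r.source, "SS": r.ss, "df": r.df, "MS": r.ms,
              "F": r.f, "p": r.p} for r in self.rows])


def anova(design: DesignTable, model: QuadraticSurfaceModel) -> AnovaTable:
    """ANOVA with partial (drop-one-term, Type III) sums of squares.

    Pure error is pooled from replicate runs (identical coded rows); lack of
    fit is the residual remainder.  When pure error is exactly zero (identical
    replicates, as happens with rounded printed data) the lack-of-fit F is
    reported absent rather than infinite.
    """
    y = design.responses[model.response_name]
    n = design.n_runs
    X = quadratic_basis(design.coded)
    _, sse = _lstsq_sse(X, y)
    sst = float(np.sum((y - y.mean()) ** 2))
    ssm = sst - sse
    df_model, df_resid = 9, n - 10
    degenerate = df_resid <= 0
    ms_resid = sse / df_resid if df_resid > 0 else None

    def frow(source, ss, df):
        if degenerate or ms_resid is None or df == 0:
            return AnovaRow(source, ss, df, ss / df if df else None, None, None)
        ms = ss / df
        fval = ms / ms_resid
        return AnovaRow(source, ss, df, ms, fval,
                        float(stats.f.sf(fval, df, df_resid)))

    rows = [frow("Model", ssm, df_model)]
    for j, term in enumerate(TERM_NAMES[1:], start=1):
        _, sse_j = _lstsq_sse(np.delete(X, j, axis=1), y)
        rows.append(frow(term, sse_j - sse, 1))

    rows.append(AnovaRow("Residual", sse, df_resid,
                         ms_resid, None, None))

    # pure error from replicate groups of identical coded points
    _, inverse = np.unique(design.coded, axis=0, return_inverse=True)
    ss_pe, df_pe = 0.0, 0
    for g in np.unique(inverse):
        yg = y[inverse == g]
        if len(yg) > 1:
            ss_pe += float(np.sum((yg - yg.mean()) ** 2))
            df_pe += len(yg) - 1
    ss_lof = max(sse - ss_pe, 0.0)
    df_lof = df_resid - df_pe
    ms_lof = ss_lof / df_lof if df_lof > 0 else None
    ms_pe = ss_pe / df_pe if df_pe > 0 else None
    if ms_lof is not None and ms_pe is not None and ms_pe > 0:
        f_lof = ms_lof / ms_pe
        p_lof = float(stats.f.sf(f_lof, df_lof, df_pe))
    else:
        f_lof = p_lof = None
    rows.append(AnovaRow("LackOfFit", ss_lof, max(df_lof, 0), ms_lof, f_lof, p_lof))
    rows.append(AnovaRow("PureError", ss_pe, df_pe, ms_pe, None, None))
    rows.append(AnovaRow("CorTotal", sst, n - 1, None, None, None))

    r2 = ssm / sst if sst > 0 else float("nan")
    r2_adj = (1 - (1 - r2) * (n - 1) / df_resid) if df_resid > 0 else float("nan")
    return AnovaTable(rows=tuple(rows), r2=r2, r2_adj=r2_adj, degenerate=degenerate)


@dataclass(frozen=True)
class DesirabilityGoal:
    """Derringer-Suich ramp for one response.

    ``maximize``: d = 0 at/below ``lower``, 1 at/above ``upper``, a power ramp
    in between; ``minimize`` is the mirror image; ``target`` ramps up to 1 at
    ``target_value`` then back down; ``in_range`` is the 0/1 indicator.
    """

    response_name: str
    goal: str
    lower: float
    upper: float
    weight: float = 1.0
    target_value: float | None = None

    def __post_init__(self) -> None:
        if self.goal not in ("maximize", "minimize", "target", "in_range"):
            raise ValueError(f"unknown goal {self.goal!r}")
        if not self.lower < self.upper:
            raise ValueError("goal requires lower < upper")
        if self.weight < 0.1:
            raise ValueError("weight must be >= 0.1")
        if self.goal == "target":
            if self.target_value is None or not (self.lower < self.target_value < self.upper):
                raise ValueError("target goal needs lower < target_value < upper")

    def d(self, value):
        """Individual desirability in [0, 1]; vectorized."""
        v = np.asarray(value, dtype=float)
        lo, hi, w = self.lower, self.upper, self.weight
        if self.goal == "maximize":
            out = np.clip((v - lo) / (hi - lo), 0.0, 1.0) ** w
        elif self.goal == "minimize":
            out = np.clip((hi - v) / (hi - lo), 0.0, 1.0) ** w
        elif self.goal == "target":
            t = self.target_value
            up = np.clip((v - lo) / (t - lo), 0.0, 1.0)
            down = np.clip((hi - v) / (hi - t), 0.0, 1.0)
            out = np.where(v <= t, up, down) ** w
        else:  # in_range
            out = ((v >= lo) & (v <= hi)).astype(float)
        return out if out.ndim else float(out)


def desirability(models, goals, coded_point):
    """Overall desirability D: unweighted geometric mean of the per-response
    ramps evaluated on the model predictions at ``coded_point``."""
    if not goals:
        raise ValueError("desirability requires at least one goal")
    by_name = {m.response_name: m for m in models}
    pts = np.atleast_2d(np.asarray(coded_point, dtype=float))
    ds = []
    for goal in goals:
        if goal.response_name not in by_name:
            raise KeyError(f"no model for response {goal.response_name!r}")
        pred = by_name[goal.response_name].predict(pts)
        ds.append(np.atleast_1d(goal.d(pred)))
    D = np.exp(np.mean(np.log(np.maximum(np.vstack(ds), 1e-300)), axis=0))
    D = np.where(np.min(np.vstack(ds), axis=0) <= 0.0, 0.0, D)
    return float(D[0]) if np.ndim(coded_point) == 1 else D


@dataclass(frozen=True)
class OptimizationResult:
    point: np.ndarray
    desirability: float
    predictions: dict
    feasible: bool


def optimize_desirability(models, goals, grid_resolution: int = 21,
                          refine: bool = True) -> OptimizationResult:
    """Maximize D over the coded cube [-1, 1]^3.

    Exhaustive grid search (deterministic; ties broken by first point in
    lexicographic grid order) followed, when ``refine`` is true, by a
    coordinate-descent polish with a fixed halving step schedule.  If D is
    zero everywhere the goals are infeasible on these models and the result
    carries ``feasible=False`` instead of raising.
    """
    if grid_resolution < 3:
        raise ValueError("grid_resolution must be >= 3")
    axis = np.linspace(-1.0, 1.0, grid_resolution)
    A, B, C = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([A.ravel(), B.ravel(), C.ravel()])
    D = desirability(models, goals, pts)
    best = int(np.argmax(D))  # first maximum in lexicographic (C-order) grid order
    x, Dbest = pts[best].copy(), float(D[best])

    if refine and Dbest > 0.0:
        step = axis[1] - axis[0]
        for _ in range(40):
            improved = False
            for j in range(3):
                for delta in (+step, -step):
                    cand = x.copy()
                    cand[j] = np.clip(cand[j] + delta, -1.0, 1.0)
                    Dc = desirability(models, goals, cand[None, :])[0]
                    if Dc > Dbest + 1e-15:
                        x, Dbest, improved = cand, float(Dc), True
            if not improved:
                step /= 2.0
                if step < 1e-6:
                    break

    preds = {m.response_name: m.predict(x) for m in models}
    return OptimizationResult(point=x, desirability=Dbest, predictions=preds,
                              feasible=Dbest > 0.0)


@dataclass(frozen=True)
class ResponseConstraint:
    """A one-sided bound on a predicted response for overlay plots."""

    response_name: str
    bound: str  # "min" (response must be >= value) or "max" (<= value)
    value: float

    def __post_init__(self) -> None:
        if self.bound not in ("min", "max"):
            raise ValueError("bound must be 'min' or 'max'")

    def satisfied(self, pred):
        return pred >= self.value if self.bound == "min" else pred <= self.value


def overlay_region(models, constraints, grid_resolution: int = 41,
                   axes=(0, 1), fixed_value: float = 0.0):
    """Feasible-region mask over a coded 2-factor grid at a fixed third factor.

    Returns ``(axis_values, mask)`` where ``mask[i, j]`` is True when every
    constraint holds at (axis[i] on axes[0], axis[j] on axes[1], fixed third).
    """
    by_name = {m.response_name: m for m in models}
    axis = np.linspace(-1.0, 1.0, grid_resolution)
    U, V = np.meshgrid(axis, axis, indexing="ij")
    pts = np.zeros((U.size, 3))
    other = ({0, 1, 2} - set(axes)).pop()
    pts[:, axes[0]] = U.ravel()
    pts[:, axes[1]] = V.ravel()
    pts[:, other] = fixed_value
    mask = np.ones(U.size, dtype=bool)
    for c in constraints:
        pred = by_name[c.response_name].predict(pts)
        mask &= c.satisfied(pred)
    return axis, mask.reshape(U.shape)
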