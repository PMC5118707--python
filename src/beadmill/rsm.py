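"""Response-surface fitting and design-of-experiments diagnostics.

Polynomial models over coded factors are fitted by ordinary least squares and
summarized with the full diagnostic suite customary in response-surface work:
Type III (partial) sums of squares per term, lack-of-fit vs pure-error
decomposition of the residual, PRESS and predicted R², coefficient of
variation, and the adequate-precision signal-to-noise ratio.  A reduced model
can be selected by per-term p-value thresholds with hierarchy preservation,
and any fitted (or externally supplied) polynomial can be evaluated, exported
as a prediction grid for contour plots, or maximized over a box.

Two term sets for the packaged four-factor dataset are provided:
``FIFTEEN_TERMS`` (the full reduced-cubic ANOVA table: 4 linear, 6 two-factor
interactions, 4 quadratics, ABC) and ``ELEVEN_TERMS`` (the term set of the
reduced coded equation reported for this process).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .design import DesignTable, Factor, replicate_groups

__all__ = [
    "TermSpec",
    "PolynomialModel",
    "RsmFit",
    "AnovaRow",
    "AnovaReport",
    "FIFTEEN_TERMS",
    "ELEVEN_TERMS",
    "REFERENCE_EQUATION",
    "SingularDesignError",
    "PureErrorUnavailableError",
    "LeverageOneError",
    "fit_ols",
    "anova_type3",
    "lack_of_fit",
    "press_pred_r2",
    "adequate_precision",
    "reduce_model",
    "predict",
    "rsm_optimum",
    "surface_grid",
    "write_grid_csv",
    "model_to_json",
    "model_from_json",
]


class SingularDesignError(ValueError):
    """Model matrix is rank deficient."""


class PureErrorUnavailableError(ValueError):
    """No replicate group of size >= 2: pure error cannot be estimated."""


class LeverageOneError(ValueError):
    """A run has leverage 1, so its leave-one-out residual is undefined."""


Term = tuple[int, ...]

_LETTERS = "ABCDEFGH"


def _term_name(term: Term) -> str:
    parts = []
    for j, e in enumerate(term):
        if e == 0:
            continue
        letter = _LETTERS[j] if j < len(_LETTERS) else f"X{j}"
        parts.append(letter if e == 1 else f"{letter}^{e}")
    return "".join(parts) if parts else "1"


@dataclass(frozen=True)
class TermSpec:
    """An ordered set of monomials over coded factors (intercept implicit).

    Each term is an exponent vector, e.g. for four factors A..D the linear
    term A is ``(1,0,0,0)``, the interaction AC is ``(1,0,1,0)`` and the
    quadratic A² is ``(2,0,0,0)``.
    """

    terms: tuple[Term, ...]

    def __post_init__(self) -> None:
        seen = set()
        for t in self.terms:
            if any((e < 0 or int(e) != e) for e in t):
                raise ValueError(f"term {t}: exponents must be non-negative integers")
            if sum(t) == 0:
                raise ValueError("the intercept is implicit; do not list it")
            if sum(t) > 3:
                raise ValueError(f"term {t}: total degree > 3 not supported")
            if t in seen:
                raise ValueError(f"duplicate term {t}")
            seen.add(t)

    @property
    def n_factors(self) -> int:
        return len(self.terms[0]) if self.terms else 0

    @property
    def names(self) -> list[str]:
        return [_term_name(t) for t in self.terms]

    def degree(self, i: int) -> int:
        return int(sum(self.terms[i]))

    def matrix(self, coded: np.ndarray) -> np.ndarray:
        """Model matrix including the leading intercept column."""
        coded = np.atleast_2d(np.asarray(coded, dtype=float))
        cols = [np.ones(coded.shape[0])]
        for t in self.terms:
            cols.append(np.prod(coded ** np.asarray(t, dtype=float), axis=1))
        return np.column_stack(cols)

    def drop(self, i: int) -> "TermSpec":
        return TermSpec(self.terms[:i] + self.terms[i + 1 :])


def _t(*exps: int) -> Term:
    return tuple(exps)


#: Full reduced-cubic term set of the ANOVA table for the packaged design:
#: A, B, C, D, AB, AC, AD, BC, BD, CD, A², B², C², D², ABC.
FIFTEEN_TERMS = TermSpec(
    (
        _t(1, 0, 0, 0), _t(0, 1, 0, 0), _t(0, 0, 1, 0), _t(0, 0, 0, 1),
        _t(1, 1, 0, 0), _t(1, 0, 1, 0), _t(1, 0, 0, 1),
        _t(0, 1, 1, 0), _t(0, 1, 0, 1), _t(0, 0, 1, 1),
        _t(2, 0, 0, 0), _t(0, 2, 0, 0), _t(0, 0, 2, 0), _t(0, 0, 0, 2),
        _t(1, 1, 1, 0),
    )
)

#: Term set of the reduced coded equation reported for the packaged process:
#: A, B, C, D, AB, AC, BD, CD, A², B², D².
ELEVEN_TERMS = TermSpec(
    (
        _t(1, 0, 0, 0), _t(0, 1, 0, 0), _t(0, 0, 1, 0), _t(0, 0, 0, 1),
        _t(1, 1, 0, 0), _t(1, 0, 1, 0), _t(0, 1, 0, 1), _t(0, 0, 1, 1),
        _t(2, 0, 0, 0), _t(0, 2, 0, 0), _t(0, 0, 0, 2),
    )
)


@dataclass(frozen=True)
class PolynomialModel:
    """A polynomial over coded factors: intercept + coefficients per term."""

    spec: TermSpec
    intercept: float
    coefficients: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.spec.terms):
            raise ValueError("coefficient count does not match term count")

    def predict(self, coded) -> np.ndarray | float:
        coded = np.asarray(coded, dtype=float)
        scalar = coded.ndim == 1
        X = self.spec.matrix(np.atleast_2d(coded))
        beta = np.concatenate(([self.intercept], self.coefficients))
        out = X @ beta
        return float(out[0]) if scalar else out


#: Reduced 11-term coded-variable equation previously fitted (on unrounded
#: responses) to the packaged bead-milling dataset; used as the default
#: ground truth in the synthetic-data generator.
REFERENCE_EQUATION = PolynomialModel(
    ELEVEN_TERMS,
    2.22,
    (-0.57, 0.077, 0.26, 0.32, 0.072, -0.20, 0.15, 0.055, -0.26, -0.094, -0.17),
)


@dataclass
class RsmFit:
    """An ordinary least-squares fit of a :class:`TermSpec` on coded factors."""

    spec: TermSpec
    intercept: float
    coefficients: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    hat_diagonal: np.ndarray
    ss_total_corrected: float
    ss_model: float
    ss_residual: float
    sigma2: float  # residual mean square; NaN when residual df == 0
    n: int
    p: int  # parameter count including the intercept
    xtx_inv: np.ndarray = field(repr=False)
    _y: np.ndarray = field(repr=False)
    _coded: np.ndarray = field(repr=False)

    @property
    def df_residual(self) -> int:
        return self.n - self.p

    @property
    def model(self) -> PolynomialModel:
        return PolynomialModel(self.spec, self.intercept, tuple(self.coefficients))

    def predict(self, coded):
        return self.model.predict(coded)


def fit_ols(table: DesignTable, spec: TermSpec) -> RsmFit:
    """Fit ``spec`` to the table's response by least squares on coded factors.

    Raises :class:`SingularDesignError` (naming the dependent columns) when
    the model matrix is rank deficient, and ``ValueError`` when there are
    fewer runs than parameters or no response.
    """
    if table.response is None:
        raise ValueError("design table has no response column")
    coded = table.coded_matrix
    y = np.asarray(table.response, dtype=float)
    X = spec.matrix(coded)
    n, p = X.shape
    if n < p:
        raise ValueError(f"need at least p={p} runs, got n={n}")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        names = ["intercept"] + spec.names
        dependent = _dependent_columns(X, names)
        raise SingularDesignError(
            f"model matrix is rank deficient (rank {rank} < {p}); "
            f"dependent columns: {', '.join(dependent)}"
        )
    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (X.T @ y)
    fitted = X @ beta
    residuals = y - fitted
    hat = np.einsum("ij,jk,ik->i", X, xtx_inv, X)
    ss_res = float(residuals @ residuals)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    ss_mod = ss_tot - ss_res
    sigma2 = ss_res / (n - p) if n > p else math.nan
    return RsmFit(
        spec=spec,
        intercept=float(beta[0]),
        coefficients=beta[1:].copy(),
        fitted=fitted,
        residuals=residuals,
        hat_diagonal=hat,
        ss_total_corrected=ss_tot,
        ss_model=ss_mod,
        ss_residual=ss_res,
        sigma2=sigma2,
        n=n,
        p=p,
        xtx_inv=xtx_inv,
        _y=y,
        _coded=coded,
    )


def _dependent_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns not selected by a greedy rank-revealing sweep."""
    kept: list[int] = []
    for j in range(X.shape[1]):
        trial = X[:, kept + [j]]
        if np.linalg.matrix_rank(trial) > len(kept):
            kept.append(j)
    return [names[j] for j in range(X.shape[1]) if j not in kept]


# ---------------------------------------------------------------------------
# ANOVA


@dataclass(frozen=True)
class AnovaRow:
    source: str
    ss: float
    df: int
    ms: float
    f: float  # NaN where undefined
    p: float  # NaN where undefined


@dataclass
class AnovaReport:
    """Type III ANOVA with lack-of-fit split and summary diagnostics."""

    spec: TermSpec
    term_rows: list[AnovaRow]
    model_row: AnovaRow
    residual_row: AnovaRow
    lack_of_fit_row: AnovaRow | None
    pure_error_row: AnovaRow | None
    total_row: AnovaRow
    std_dev: float
    mean_response: float
    cv_percent: float
    r2: float
    adj_r2: float
    pred_r2: float
    press: float
    adequate_precision: float

    def p_value(self, name: str) -> float:
        for row in self.term_rows:
            if row.source == name:
                return row.p
        raise KeyError(name)

    def to_dict(self) -> dict:
        def row(r: AnovaRow | None):
            if r is None:
                return None
            return {
                "term": r.source,
                "ss": r.ss,
                "df": r.df,
                "ms": r.ms,
                "f": None if math.isnan(r.f) else r.f,
                "p": None if math.isnan(r.p) else r.p,
            }

        return {
            "rows": [row(self.model_row)]
            + [row(r) for r in self.term_rows]
            + [row(self.residual_row), row(self.lack_of_fit_row),
               row(self.pure_error_row), row(self.total_row)],
            "summary": {
                "std_dev": self.std_dev,
                "mean": self.mean_response,
                "cv_percent": self.cv_percent,
                "r2": self.r2,
                "adj_r2": self.adj_r2,
                "pred_r2": self.pred_r2,
                "press": self.press,
                "adequate_precision": self.adequate_precision,
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def render_text(self) -> str:
        """Aligned plain-text table in the conventional report row order."""
        lines = []
        hdr = f"{'Source':<14}{'Sum of squares':>15}{'df':>5}{'Mean square':>13}{'F-value':>10}{'p-value':>10}"
        lines.append("ANOVA (partial sum of squares - Type III)")
        lines.append(hdr)
        lines.append("-" * len(hdr))

        def fmt(r: AnovaRow | None):
            if r is None:
                return
            f_txt = "" if math.isnan(r.f) else f"{r.f:10.4g}"
            p_txt = "" if math.isnan(r.p) else f"{r.p:10.4g}"
            ms_txt = "" if math.isnan(r.ms) else f"{r.ms:13.4g}"
            lines.append(
                f"{r.source:<14}{r.ss:>15.4g}{r.df:>5d}{ms_txt:>13}{f_txt:>10}{p_txt:>10}"
            )

        fmt(self.model_row)
        for r in self.term_rows:
            fmt(r)
        fmt(self.residual_row)
        fmt(self.lack_of_fit_row)
        fmt(self.pure_error_row)
        fmt(self.total_row)
        lines.append("")
        lines.append(f"{'Std. dev.':<20}{self.std_dev:10.4f}    {'R^2':<16}{self.r2:8.4f}")
        lines.append(f"{'Mean':<20}{self.mean_response:10.4f}    {'Adjusted R^2':<16}{self.adj_r2:8.4f}")
        lines.append(f"{'CV %':<20}{self.cv_percent:10.4f}    {'Predicted R^2':<16}{self.pred_r2:8.4f}")
        lines.append(f"{'PRESS':<20}{self.press:10.4f}    {'Adeq. precision':<16}{self.adequate_precision:8.4f}")
        return "\n".join(lines)


def anova_type3(fit: RsmFit, table: DesignTable) -> AnovaReport:
    """Type III ANOVA of a fit: per-term partial SS, F and p, plus summaries.

    The partial SS of a single-df term equals beta_j^2 / (X'X)^{-1}_jj, the
    increase in residual SS when that term alone is dropped.  With zero
    residual df the F and p columns are reported as NaN rather than raising.
    """
    n, p = fit.n, fit.p
    df_res = fit.df_residual
    ms_res = fit.sigma2

    term_rows = []
    for i, name in enumerate(fit.spec.names):
        j = i + 1  # skip intercept
        pss = float(fit.coefficients[i] ** 2 / fit.xtx_inv[j, j])
        if df_res > 0:
            f_val = pss / ms_res
            p_val = float(stats.f.sf(f_val, 1, df_res))
        else:
            f_val = p_val = math.nan
        term_rows.append(AnovaRow(name, pss, 1, pss, f_val, p_val))

    df_model = p - 1
    ms_model = fit.ss_model / df_model if df_model > 0 else math.nan
    if df_res > 0 and df_model > 0:
        f_model = ms_model / ms_res
        p_model = float(stats.f.sf(f_model, df_model, df_res))
    else:
        f_model = p_model = math.nan
    model_row = AnovaRow("Model", fit.ss_model, df_model, ms_model, f_model, p_model)
    residual_row = AnovaRow(
        "Residual", fit.ss_residual, df_res,
        ms_res if df_res > 0 else math.nan, math.nan, math.nan,
    )
    total_row = AnovaRow("Cor total", fit.ss_total_corrected, n - 1,
                         math.nan, math.nan, math.nan)

    try:
        lof_row, pe_row = lack_of_fit(fit, table)
    except PureErrorUnavailableError:
        lof_row = pe_row = None

    mean = float(fit._y.mean())
    std_dev = math.sqrt(ms_res) if df_res > 0 else math.nan
    cv = 100.0 * std_dev / mean if mean != 0 else math.inf
    if fit.ss_total_corrected > 0:
        r2 = fit.ss_model / fit.ss_total_corrected
        adj = 1.0 - (1.0 - r2) * (n - 1) / df_res if df_res > 0 else math.nan
    else:
        r2, adj = 0.0, 0.0  # constant response: define R^2 as 0
    try:
        press, pred_r2 = press_pred_r2(fit)
    except LeverageOneError:
        press = pred_r2 = math.nan

    return AnovaReport(
        spec=fit.spec,
        term_rows=term_rows,
        model_row=model_row,
        residual_row=residual_row,
        lack_of_fit_row=lof_row,
        pure_error_row=pe_row,
        total_row=total_row,
        std_dev=std_dev,
        mean_response=mean,
        cv_percent=cv,
        r2=r2,
        adj_r2=adj,
        pred_r2=pred_r2,
        press=press,
        adequate_precision=adequate_precision(fit),
    )


def lack_of_fit(fit: RsmFit, table: DesignTable) -> tuple[AnovaRow, AnovaRow]:
    """Split the residual SS into lack-of-fit and pure-error rows.

    Pure error is the within-replicate-group scatter about group means; it
    depends only on the data, not on the fitted model.  Lack of fit is the
    remainder of the residual SS, on (residual df − pure-error df) degrees of
    freedom.
    """
    groups = replicate_groups(table)
    reps = [g for g in groups if len(g) >= 2]
    if not reps:
        raise PureErrorUnavailableError(
            "no replicate group of size >= 2 in the design"
        )
    y = fit._y
    id_to_idx = {rid: i for i, rid in enumerate(table.run_ids)}
    ss_pe = 0.0
    df_pe = 0
    for g in reps:
        vals = y[[id_to_idx[r] for r in g]]
        ss_pe += float(((vals - vals.mean()) ** 2).sum())
        df_pe += len(g) - 1
    ss_lof = max(fit.ss_residual - ss_pe, 0.0)
    df_lof = fit.df_residual - df_pe
    ms_pe = ss_pe / df_pe
    if df_lof > 0 and ms_pe > 0:
        ms_lof = ss_lof / df_lof
        f_lof = ms_lof / ms_pe
        p_lof = float(stats.f.sf(f_lof, df_lof, df_pe))
    else:
        ms_lof = ss_lof / df_lof if df_lof > 0 else math.nan
        f_lof = p_lof = math.nan
    lof = AnovaRow("Lack of fit", ss_lof, df_lof, ms_lof, f_lof, p_lof)
    pe = AnovaRow("Pure error", ss_pe, df_pe, ms_pe, math.nan, math.nan)
    return lof, pe


def press_pred_r2(fit: RsmFit) -> tuple[float, float]:
    """PRESS via the hat-matrix shortcut, and predicted R² = 1 − PRESS/SS_tot.

    PRESS = Σ (e_i / (1 − h_ii))², algebraically identical to refitting with
    each run left out and summing its squared prediction error.
    """
    h = fit.hat_diagonal
    bad = np.nonzero(h >= 1.0 - 1e-12)[0]
    if bad.size:
        raise LeverageOneError(
            f"run index {int(bad[0])} has leverage 1; PRESS undefined"
        )
    press = float(((fit.residuals / (1.0 - h)) ** 2).sum())
    pred = 1.0 - press / fit.ss_total_corrected if fit.ss_total_corrected > 0 else 0.0
    return press, pred


def adequate_precision(fit: RsmFit) -> float:
    """Signal-to-noise ratio (max ŷ − min ŷ) / sqrt(p·σ²/n), p incl. intercept.

    Values above 4 indicate an adequate signal for navigating the design
    space.  A zero residual mean square yields +inf.
    """
    spread = float(fit.fitted.max() - fit.fitted.min())
    if not (fit.sigma2 > 0):  # 0 or NaN
        return math.inf if spread > 0 or fit.sigma2 == 0 else 0.0
    return spread / math.sqrt(fit.p * fit.sigma2 / fit.n)


def reduce_model(
    report: AnovaReport,
    p_individual: float = 0.05,
    p_interaction: float = 0.10,
    hierarchy: bool = True,
) -> TermSpec:
    """Select the terms passing per-class p-value thresholds.

    Linear (degree-1) terms are kept at ``p < p_individual``; interactions and
    quadratics at the relaxed ``p < p_interaction``.  With ``hierarchy`` on,
    any factor appearing in a kept higher-order term has its linear term
    retained even if individually non-significant.
    """
    spec = report.spec
    kept: list[Term] = []
    for i, row in enumerate(report.term_rows):
        thr = p_individual if spec.degree(i) == 1 else p_interaction
        if not math.isnan(row.p) and row.p < thr:
            kept.append(spec.terms[i])
    if hierarchy:
        needed = set()
        for t in kept:
            if sum(t) > 1:
                needed.update(j for j, e in enumerate(t) if e > 0)
        present_linear = {
            next(j for j, e in enumerate(t) if e) for t in kept if sum(t) == 1
        }
        k = spec.n_factors
        for j in sorted(needed - present_linear):
            lin = tuple(1 if jj == j else 0 for jj in range(k))
            kept.append(lin)
    # conventional order: linear terms, then interactions, then pure powers
    kept_sorted = sorted(set(kept), key=lambda t: (sum(t), max(t), [-e for e in t]))
    return TermSpec(tuple(kept_sorted))


def predict(model, coded):
    """Evaluate an :class:`RsmFit` or :class:`PolynomialModel` at coded points."""
    if isinstance(model, RsmFit):
        model = model.model
    return model.predict(coded)


@dataclass(frozen=True)
class OptimumResult:
    coded: tuple[float, ...]
    value: float
    actual: tuple[float, ...] | None = None


def rsm_optimum(
    model,
    bounds: Sequence[tuple[float, float]],
    factors: Sequence[Factor] | None = None,
    grid_points: int = 21,
) -> OptimumResult:
    """Maximize a polynomial over a coded box.

    A dense grid scan locates the basin; an L-BFGS-B polish refines the
    maximizer.  When ``factors`` are supplied the optimum is also reported in
    actual units.
    """
    if isinstance(model, RsmFit):
        model = model.model
    bounds = [(float(lo), float(hi)) for lo, hi in bounds]
    for lo, hi in bounds:
        if not (math.isfinite(lo) and math.isfinite(hi) and lo <= hi):
            raise ValueError("bounds must be finite with low <= high")
    axes = [np.linspace(lo, hi, grid_points) for lo, hi in bounds]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([m.ravel() for m in mesh])
    vals = model.predict(pts)
    best = int(np.argmax(vals))
    x0 = pts[best]

    res = optimize.minimize(
        lambda x: -model.predict(x),
        x0,
        method="L-BFGS-B",
        bounds=bounds,
    )
    x_opt, v_opt = (res.x, -res.fun) if -res.fun >= vals[best] else (x0, vals[best])
    actual = (
        tuple(f.decode(c) for f, c in zip(factors, x_opt)) if factors else None
    )
    return OptimumResult(tuple(float(c) for c in x_opt), float(v_opt), actual)


def surface_grid(
    model,
    pair: tuple[int, int],
    held: Sequence[float],
    grid_points: int = 41,
    bounds: Sequence[tuple[float, float]] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Predictions on a 2-D coded grid for contour plotting.

    ``pair`` gives the two varied factor indices; ``held`` the coded values of
    all factors (entries at the varied indices are ignored).  Returns the two
    grid axes and the matrix ``Z[i, j]`` = prediction at ``(axis1[i], axis2[j])``.
    """
    if isinstance(model, RsmFit):
        model = model.model
    k = model.spec.n_factors
    held = np.asarray(held, dtype=float)
    if held.shape != (k,):
        raise ValueError(f"held values must have length {k}")
    i, j = pair
    if bounds is None:
        bounds = [(-DEFAULT_GRID_HALFWIDTH, DEFAULT_GRID_HALFWIDTH)] * k
    ax1 = np.linspace(bounds[i][0], bounds[i][1], grid_points)
    ax2 = np.linspace(bounds[j][0], bounds[j][1], grid_points)
    G1, G2 = np.meshgrid(ax1, ax2, indexing="ij")
    pts = np.tile(held, (G1.size, 1))
    pts[:, i] = G1.ravel()
    pts[:, j] = G2.ravel()
    Z = np.asarray(model.predict(pts)).reshape(G1.shape)
    return ax1, ax2, Z


#: Default half-width of plotting grids in coded units (the axial distance).
DEFAULT_GRID_HALFWIDTH = 1.4142


def write_grid_csv(path, ax1: np.ndarray, ax2: np.ndarray, Z: np.ndarray,
                   names: tuple[str, str] = ("x1", "x2")) -> None:
    """Export a surface grid in long CSV form (x1, x2, prediction)."""
    import pandas as pd

    G1, G2 = np.meshgrid(ax1, ax2, indexing="ij")
    pd.DataFrame(
        {names[0]: G1.ravel(), names[1]: G2.ravel(), "prediction": Z.ravel()}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Serialization


def model_to_json(model, factors: Sequence[Factor] | None = None, **kwargs) -> str:
    if isinstance(model, RsmFit):
        model = model.model
    payload = {
        "terms": [list(t) for t in model.spec.terms],
        "intercept": model.intercept,
        "coefficients": list(model.coefficients),
    }
    if factors is not None:
        payload["coding"] = [
            {"name": f.name, "unit": f.unit, "center": f.center, "step": f.step,
             "role": f.role}
            for f in factors
        ]
    return json.dumps(payload, **kwargs)


def model_from_json(text: str) -> tuple[PolynomialModel, tuple[Factor, ...] | None]:
    payload = json.loads(text)
    spec = TermSpec(tuple(tuple(t) for t in payload["terms"]))
    model = PolynomialModel(
        spec, float(payload["intercept"]), tuple(payload["coefficients"])
    )
    factors = None
    if "coding" in payload:
        factors = tuple(
            Factor(d["name"], d["unit"], d["center"], d["step"], d.get("role", "generic"))
            for d in payload["coding"]
        )
    return model, factors
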