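"""Criterion validity: relating sensed contact durations to self-reports.

Inputs are a symmetric weighted contact matrix ``x`` (minutes of sensed
interaction per dyad) and a directed binary nomination matrix ``y``
(``y[i, j] = 1`` when i named j as an interaction partner in a survey).
The analyses:

* a two-sample t test of dyad-level duration by nomination status, with a
  pooled-SD Cohen's d;
* a logistic regression of the nomination indicator on duration in
  minutes, summarized by coefficients, standard errors, log-likelihood and
  McFadden's pseudo-R² = 1 − ℓ/ℓ₀;
* a descriptive deviance comparison 2·|ℓ_a − ℓ_b| between fits of the same
  outcome on differently processed duration matrices (the compared models
  are not nested, so this is reported as a deviance difference, not a
  formal likelihood-ratio test, with a caller-supplied reference df).

The unit of analysis is the directed dyad by default (each undirected
duration appears in both directions, mirroring the survey's directed
nominations); an undirected unit on a pre-symmetrized ``y`` is available.
Dyads involving survey non-responders can be dropped listwise from the
outcome while durations stay intact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .events import ConfigError, Ident, ValidationError

__all__ = [
    "AssociationResult",
    "ConvergenceError",
    "symmetrize",
    "reciprocity",
    "dyad_table",
    "duration_by_nomination_test",
    "fit_duration_logit",
    "compare_fits",
    "read_matrix_csv",
    "write_matrix_csv",
    "read_nominations",
]


class ConvergenceError(Exception):
    """The logistic fit did not converge (e.g. perfect separation)."""


def _check_square(m: pd.DataFrame, name: str) -> None:
    if m.shape[0] != m.shape[1] or list(m.index) != list(m.columns):
        raise ValidationError(f"{name} must be square with matching index/columns")


def symmetrize(y: pd.DataFrame, mode: str = "none") -> pd.DataFrame:
    """Symmetrize a directed nomination matrix.

    ``weak``: a tie exists when at least one direction was nominated
    (logical OR with the transpose); ``strong``: both directions required
    (logical AND); ``none``: identity.
    """
    _check_square(y, "nomination matrix")
    vals = y.to_numpy().astype(bool)
    if mode == "none":
        out = vals
    elif mode == "weak":
        out = vals | vals.T
    elif mode == "strong":
        out = vals & vals.T
    else:
        raise ConfigError(f"unknown symmetrization mode {mode!r}; expected none/weak/strong")
    out = out.astype(int)
    np.fill_diagonal(out, 0)
    return pd.DataFrame(out, index=y.index, columns=y.columns)


def reciprocity(y: pd.DataFrame) -> float:
    """Fraction of directed ties whose reverse tie is also present."""
    _check_square(y, "nomination matrix")
    vals = y.to_numpy().astype(bool)
    np.fill_diagonal(vals, False)
    ties = int(vals.sum())
    if ties == 0:
        raise ValidationError("reciprocity undefined: matrix has no ties")
    mutual = int((vals & vals.T).sum())
    return mutual / ties


@dataclass
class AssociationResult:
    """Results of one duration-vs-nomination analysis.

    Group-difference fields (``t``, ``df``, ``d``) and logistic-fit fields
    are populated by the respective analyses; unused fields are None.
    ``d`` carries the sign of mean(duration | nominated) − mean(duration |
    not nominated), while ``t`` is reported for the (not-nominated −
    nominated) contrast, so a positive duration effect prints as negative
    t and positive d.
    """

    n: int
    t: float | None = None
    df: int | None = None
    d: float | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    slope: float | None = None
    slope_se: float | None = None
    log_likelihood: float | None = None
    mcfadden_r2: float | None = None
    degenerate_predictor: bool = False

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def dyad_table(
    x: pd.DataFrame,
    y: pd.DataFrame,
    unit: str = "directed",
    responders: Iterable[Ident] | None = None,
) -> pd.DataFrame:
    """Long-form dyad table with columns ``ego, alter, minutes, nominated``.

    ``directed``: all ordered pairs (the undirected duration appears in
    both directions); ``undirected``: unordered pairs, requiring ``y`` to
    be symmetric (symmetrize it first).  With ``responders`` given, rows
    whose ego did not respond to the survey are dropped.
    """
    _check_square(x, "duration matrix")
    _check_square(y, "nomination matrix")
    if list(x.index) != list(y.index):
        raise ValidationError("duration and nomination matrices must share a roster")
    ids = list(x.index)
    xv = x.to_numpy(dtype=float)
    yv = y.to_numpy()
    if not np.allclose(xv, xv.T):
        raise ValidationError("duration matrix must be symmetric")
    rows = []
    if unit == "directed":
        resp = None if responders is None else set(responders)
        for i, ego in enumerate(ids):
            if resp is not None and ego not in resp:
                continue
            for j, alter in enumerate(ids):
                if i == j:
                    continue
                rows.append((ego, alter, xv[i, j], int(yv[i, j])))
    elif unit == "undirected":
        if not np.array_equal(yv, yv.T):
            raise ValidationError("undirected unit requires a symmetric nomination matrix")
        resp = None if responders is None else set(responders)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if resp is not None and ids[i] not in resp and ids[j] not in resp:
                    continue
                rows.append((ids[i], ids[j], xv[i, j], int(yv[i, j])))
    else:
        raise ConfigError(f"unknown unit {unit!r}; expected directed/undirected")
    return pd.DataFrame(rows, columns=["ego", "alter", "minutes", "nominated"])


def duration_by_nomination_test(
    x: pd.DataFrame,
    y: pd.DataFrame,
    unit: str = "directed",
    responders: Iterable[Ident] | None = None,
) -> AssociationResult:
    """Pooled-variance two-sample t test of duration by nomination status.

    Returns t (not-nominated minus nominated contrast), integer df, and
    Cohen's d with pooled SD (positive when nominated dyads interact
    longer).
    """
    from scipy import stats

    table = dyad_table(x, y, unit=unit, responders=responders)
    g1 = table.loc[table["nominated"] == 1, "minutes"].to_numpy()
    g0 = table.loc[table["nominated"] == 0, "minutes"].to_numpy()
    if len(g0) < 2 or len(g1) < 2:
        raise ValidationError(
            f"both nomination groups need >= 2 observations (got {len(g0)} and {len(g1)})"
        )
    v0, v1 = g0.var(ddof=1), g1.var(ddof=1)
    if v0 == 0 and v1 == 0:
        raise ValidationError("degenerate zero within-group variance; t statistic undefined")
    t_stat, _ = stats.ttest_ind(g0, g1, equal_var=True)
    df = len(g0) + len(g1) - 2
    pooled_sd = math.sqrt(((len(g0) - 1) * v0 + (len(g1) - 1) * v1) / df)
    d = (g1.mean() - g0.mean()) / pooled_sd
    return AssociationResult(n=len(table), t=float(t_stat), df=df, d=float(d))


def fit_duration_logit(
    x: pd.DataFrame,
    y: pd.DataFrame,
    unit: str = "directed",
    responders: Iterable[Ident] | None = None,
) -> AssociationResult:
    """Maximum-likelihood logistic regression of nomination on minutes.

    A zero-variance duration predictor is flagged (``degenerate_predictor``)
    and fit intercept-only; non-convergence (including perfect separation)
    raises :class:`ConvergenceError`.
    """
    import statsmodels.api as sm

    table = dyad_table(x, y, unit=unit, responders=responders)
    outcome = table["nominated"].to_numpy(dtype=float)
    minutes = table["minutes"].to_numpy(dtype=float)
    if not np.all(np.isfinite(minutes)):
        raise ValidationError("durations must be finite")
    if outcome.min() == outcome.max():
        raise ValidationError("outcome vector has a single class; logistic fit undefined")

    if np.ptp(minutes) == 0:
        p = outcome.mean()
        intercept = math.log(p / (1 - p))
        ll0 = len(outcome) * (p * math.log(p) + (1 - p) * math.log(1 - p))
        return AssociationResult(
            n=len(outcome),
            intercept=intercept,
            slope=math.nan,
            log_likelihood=ll0,
            mcfadden_r2=0.0,
            degenerate_predictor=True,
        )

    design = sm.add_constant(minutes)
    try:
        fit = sm.Logit(outcome, design).fit(disp=0)
    except Exception as exc:
        raise ConvergenceError(f"logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", False) or not np.all(np.isfinite(fit.params)):
        raise ConvergenceError("logistic fit did not converge (possible perfect separation)")
    return AssociationResult(
        n=len(outcome),
        intercept=float(fit.params[0]),
        intercept_se=float(fit.bse[0]),
        slope=float(fit.params[1]),
        slope_se=float(fit.bse[1]),
        log_likelihood=float(fit.llf),
        mcfadden_r2=float(1 - fit.llf / fit.llnull),
    )


def compare_fits(
    result_a: AssociationResult, result_b: AssociationResult, df: int = 2
) -> tuple[float, int]:
    """Descriptive deviance difference χ² = 2·|ℓ_a − ℓ_b| between two fits
    of the same outcome on different duration matrices, with a reference df.
    """
    if result_a.n != result_b.n:
        raise ValidationError(f"fits use different numbers of dyads: {result_a.n} vs {result_b.n}")
    if result_a.log_likelihood is None or result_b.log_likelihood is None:
        raise ValidationError("both results need a log-likelihood")
    chi2 = 2.0 * abs(result_a.log_likelihood - result_b.log_likelihood)
    return chi2, df


# ---------------------------------------------------------------------------
# matrix I/O
# ---------------------------------------------------------------------------

def read_matrix_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Square matrix CSV with identifier header row and index column."""
    m = pd.read_csv(path, index_col=0)
    m.index = [_maybe_int(i) for i in m.index]
    m.columns = [_maybe_int(c) for c in m.columns]
    _check_square(m, str(path))
    return m


def write_matrix_csv(m: pd.DataFrame, path: Union[str, Path]) -> None:
    m.to_csv(path)


def read_nominations(path: Union[str, Path], roster: Iterable[Ident] | None = None) -> pd.DataFrame:
    """Read a nomination matrix: either a square 0/1 CSV or a long-form
    edge list with columns ``from,to`` (roster required or inferred)."""
    head = pd.read_csv(path, nrows=0)
    cols = [str(c).strip().lower() for c in head.columns]
    if cols[:2] == ["from", "to"] and len(cols) == 2:
        edges = pd.read_csv(path)
        edges.columns = ["from", "to"]
        senders = [_maybe_int(v) for v in edges["from"]]
        receivers = [_maybe_int(v) for v in edges["to"]]
        if roster is None:
            roster = sorted(set(senders) | set(receivers), key=lambda v: (isinstance(v, str), v))
        else:
            roster = list(roster)
        y = pd.DataFrame(0, index=roster, columns=roster)
        for s, r in zip(senders, receivers):
            if s == r:
                raise ValidationError(f"self-nomination {s} -> {r}")
            y.loc[s, r] = 1
        return y
    y = read_matrix_csv(path)
    vals = y.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValidationError("nomination matrix entries must be 0/1")
    if np.diag(vals).any():
        raise ValidationError("nomination matrix must have a zero diagonal")
    return y


def _maybe_int(v):
    try:
        return int(v)
    except (TypeError, ValueError):
        return str(v)
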