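"""Factorial linear-model inference: sequential ANOVA, a multiple-response
variant, and Tukey HSD post-hoc comparisons.

The study design is factorial — localities crossed with years, optionally
with a covariate (sampling date, cumulative °C, or annual mean temperature).
Models are ordinary least-squares fits with **sequential (Type I) sums of
squares** in the order the terms are listed, so each term is tested after
everything listed before it.  Because sampling date and cumulative °C are
nearly collinear by construction, a model spec refuses to carry both.

For the per-stage bud counts, six responses (egg..adult per bud) share one
design; the multiple-response model tests each term with Pillai's trace on
the sequential hypothesis SSCP, converted to an approximate F by the
standard distributional rule.  Degenerate response sets (collinear or
duplicated responses) are handled by using the rank of the total response
covariance as the effective number of responses, so a single response — or
six identical copies of one — reduces exactly to the univariate F.

Tukey HSD adjusted p-values come from the studentized range distribution
with the Tukey–Kramer standard error, using the fit's residual mean square.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats

from .errors import DomainError, SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "AnovaResult",
    "MultiResponseResult",
    "fit_anova",
    "fit_multiresponse",
    "tukey_hsd",
]

#: Covariate pairs that must never appear in the same model (high collinearity
#: by construction: cumulative °C is a monotone function of sampling date).
DEFAULT_COLLINEAR_PAIRS: tuple[tuple[str, str], ...] = (("date", "cum_degc"),)


@dataclass(frozen=True)
class ModelSpec:
    """A factorial model: response(s), ordered terms, and factor columns.

    ``terms`` are main effects (column names) and interactions written with
    ``:`` (e.g. ``"locality:year"``).  Columns named in ``factors`` are
    treated as categorical regardless of dtype.  Term order matters: sums of
    squares are sequential.
    """

    responses: tuple[str, ...]
    terms: tuple[str, ...]
    factors: tuple[str, ...] = ()
    collinear_pairs: tuple[tuple[str, str], ...] = DEFAULT_COLLINEAR_PAIRS

    def __post_init__(self) -> None:
        if not self.responses:
            raise SchemaError("model spec needs at least one response")
        if not self.terms:
            raise SchemaError("model spec needs at least one term")
        vars_used = {v for t in self.terms for v in t.split(":")}
        for a, b in self.collinear_pairs:
            if a in vars_used and b in vars_used:
                raise SchemaError(
                    f"covariates {a!r} and {b!r} are collinear and must not "
                    "appear in the same model"
                )

    def _render(self, term: str) -> str:
        parts = [
            f"C({v})" if v in self.factors else v for v in term.split(":")
        ]
        return ":".join(parts)

    def rhs(self, upto: int | None = None) -> str:
        """Right-hand side of the formula using the first ``upto`` terms."""
        terms = self.terms if upto is None else self.terms[:upto]
        return " + ".join(["1"] + [self._render(t) for t in terms])

    def formula(self, response: str | None = None) -> str:
        resp = self.responses[0] if response is None else response
        return f"{resp} ~ {self.rhs()}"


@dataclass(frozen=True)
class AnovaResult:
    """Sequential ANOVA of a single-response factorial model.

    ``table`` has one row per term: ``term``, ``df_num``, ``df_den``,
    ``sum_sq``, ``F``, ``p``; the model-level R² and residual quantities are
    carried alongside for post-hoc use.
    """

    spec: ModelSpec
    data: pd.DataFrame = field(repr=False)
    table: pd.DataFrame = field(repr=False)
    r_squared: float = 0.0
    mse_resid: float = 0.0
    df_resid: int = 0
    ss_total: float = 0.0
    ss_resid: float = 0.0

    @property
    def response(self) -> str:
        return self.spec.responses[0]


@dataclass(frozen=True)
class MultiResponseResult:
    """Sequential multiple-response ANOVA (Pillai's trace per term)."""

    spec: ModelSpec
    data: pd.DataFrame = field(repr=False)
    table: pd.DataFrame = field(repr=False)
    r_squared: float = 0.0
    df_resid: int = 0
    n_responses_effective: int = 0


def _interaction_name(spec: ModelSpec) -> str:
    """Highest-order (then last-listed) term, for residual-df error messages."""
    return max(spec.terms, key=lambda t: (t.count(":"), spec.terms.index(t)))


def _check_residual_df(df_resid: int, spec: ModelSpec) -> None:
    if df_resid < 1:
        raise DomainError(
            "lack of required residual degrees of freedom: dropping the "
            f"{_interaction_name(spec)!r} term is required to test this model"
        )


def _prefix_designs(spec: ModelSpec, data: pd.DataFrame) -> list[np.ndarray]:
    """Design matrices for the intercept-only model and each term prefix."""
    designs = []
    for k in range(len(spec.terms) + 1):
        X = patsy.dmatrix(spec.rhs(upto=k), data, return_type="matrix")
        designs.append(np.asarray(X))
    return designs


def _sequential_sscp(
    spec: ModelSpec, data: pd.DataFrame, responses: list[str]
) -> tuple[list[tuple[str, np.ndarray, int]], np.ndarray, np.ndarray, int]:
    """Sequential hypothesis SSCP matrices in listed term order.

    Returns ``(terms, E, T0, df_resid)`` where ``terms`` is a list of
    ``(name, H, df)``, ``E`` the residual SSCP of the full model, ``T0`` the
    intercept-corrected total SSCP, and ``df_resid`` the residual degrees of
    freedom.
    """
    Y = data[responses].to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise SchemaError("responses contain missing values")
    designs = _prefix_designs(spec, data)
    n = Y.shape[0]

    resid_sscp: list[np.ndarray] = []
    ranks: list[int] = []
    for X in designs:
        beta, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
        R = Y - X @ beta
        resid_sscp.append(R.T @ R)
        ranks.append(int(rank))

    df_resid = n - ranks[-1]
    _check_residual_df(df_resid, spec)

    terms = []
    for k, name in enumerate(spec.terms, start=1):
        df_k = ranks[k] - ranks[k - 1]
        if df_k < 1:
            raise SchemaError(
                f"term {name!r} adds no estimable degrees of freedom "
                "(aliased with earlier terms)"
            )
        H = resid_sscp[k - 1] - resid_sscp[k]
        terms.append((name, (H + H.T) / 2.0, df_k))
    return terms, resid_sscp[-1], resid_sscp[0], df_resid


def fit_anova(spec: ModelSpec, data: pd.DataFrame) -> AnovaResult:
    """Least-squares factorial ANOVA with sequential sums of squares.

    F for each term is the term mean square over the residual mean square of
    the full model; R² = 1 − SSE/SST.  A constant response yields all-zero F
    (p = 1) and R² = 0.  A saturated model (residual df = 0) raises an error
    naming the term to drop.
    """
    if len(spec.responses) != 1:
        raise SchemaError("fit_anova takes a single-response spec; see fit_multiresponse")
    resp = spec.responses[0]
    terms, E, T0, df_resid = _sequential_sscp(spec, data, [resp])
    sse = float(E[0, 0])
    sst = float(T0[0, 0])
    mse = sse / df_resid

    rows = []
    for name, H, df_k in terms:
        ss = max(float(H[0, 0]), 0.0)
        if mse > 0 and sst > np.finfo(float).eps * len(data):
            F = (ss / df_k) / mse
            p = float(stats.f.sf(F, df_k, df_resid))
        else:
            # constant (or perfectly fitted) response carries no signal
            F, p = 0.0, 1.0
        rows.append({"term": name, "df_num": df_k, "df_den": df_resid,
                     "sum_sq": ss, "F": F, "p": p})
    r2 = 1.0 - sse / sst if sst > np.finfo(float).eps * len(data) else 0.0

    return AnovaResult(
        spec=spec,
        data=data,
        table=pd.DataFrame(rows),
        r_squared=float(r2),
        mse_resid=float(mse),
        df_resid=int(df_resid),
        ss_total=sst,
        ss_resid=sse,
    )


def _pillai_f(V: float, p: int, df_h: int, df_e: int) -> tuple[float, float, float]:
    """Approximate F for Pillai's trace; returns (F, df1, df2)."""
    s = min(p, df_h)
    m = (abs(p - df_h) - 1) / 2.0
    n_ = (df_e - p - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * n_ + s + 1)
    if df2 <= 0:
        raise DomainError(
            f"residual df {df_e} too small for {p} responses (Pillai F undefined)"
        )
    V = min(max(V, 0.0), s)
    denom = s - V
    F = (df2 / df1) * (V / denom) if denom > 0 else np.inf
    return F, df1, df2


def fit_multiresponse(spec: ModelSpec, data: pd.DataFrame) -> MultiResponseResult:
    """Multivariate linear model with per-term Pillai's trace F tests.

    Hypothesis SSCP matrices are sequential in listed term order; Pillai's
    trace V = tr(H(H+E)⁻) is converted to an approximate F with the standard
    (s, m, n) rule.  The effective number of responses is the rank of the
    total response SSCP, so collinear/duplicated responses collapse and a
    single response reproduces the univariate F exactly.  The model-level R²
    is 1 − tr(E)/tr(T), the share of total response variance explained.
    """
    responses = list(spec.responses)
    terms, E, T0, df_resid = _sequential_sscp(spec, data, responses)
    p_eff = int(np.linalg.matrix_rank(T0)) if float(np.trace(T0)) > 0 else 1
    if p_eff > df_resid:
        raise DomainError(
            f"{p_eff} (effective) responses exceed the residual degrees of "
            f"freedom ({df_resid})"
        )

    tr_T = float(np.trace(T0))
    rows = []
    for name, H, df_k in terms:
        if tr_T <= np.finfo(float).eps * len(data) * len(responses):
            rows.append({"term": name, "pillai": 0.0, "F": 0.0,
                         "df_num": df_k * p_eff, "df_den": df_resid, "p": 1.0})
            continue
        V = float(np.trace(H @ np.linalg.pinv(H + E)))
        F, df1, df2 = _pillai_f(V, p_eff, df_k, df_resid)
        rows.append({"term": name, "pillai": V, "F": F, "df_num": df1,
                     "df_den": df2, "p": float(stats.f.sf(F, df1, df2))})
    r2 = 1.0 - float(np.trace(E)) / tr_T if tr_T > 0 else 0.0
    return MultiResponseResult(
        spec=spec,
        data=data,
        table=pd.DataFrame(rows),
        r_squared=r2,
        df_resid=int(df_resid),
        n_responses_effective=p_eff,
    )


def tukey_hsd(result: AnovaResult, factor: str) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons of a factor's level means.

    Uses the fit's residual mean square and residual df; the adjusted
    p-value is the upper tail of the studentized range distribution at
    q = |difference| / SE_q with the Tukey–Kramer standard error
    SE_q = sqrt(MSE/2 · (1/nᵢ + 1/nⱼ)).  Each unordered level pair appears
    once; ``p_unadj`` is the ordinary two-sample p for reference.
    """
    if factor not in result.data.columns:
        raise SchemaError(f"factor {factor!r} not in the model data")
    groups = result.data.groupby(factor, observed=False)[result.response]
    sizes = groups.size()
    if (sizes == 0).any():
        empty = sizes[sizes == 0].index.tolist()
        raise DomainError(f"factor {factor!r} has empty level(s): {empty}")
    means = groups.mean()
    levels = list(means.index)
    k = len(levels)
    if k < 2:
        raise DomainError(f"factor {factor!r} needs at least 2 levels, has {k}")
    if result.mse_resid <= 0:
        raise DomainError("residual mean square is zero; post hoc undefined")

    rows = []
    for a, b in itertools.combinations(levels, 2):
        diff = float(means[b] - means[a])
        se_pair = np.sqrt(result.mse_resid * (1 / sizes[a] + 1 / sizes[b]))
        q = abs(diff) / (se_pair / np.sqrt(2.0))
        p_adj = float(stats.studentized_range.sf(q, k, result.df_resid))
        t = abs(diff) / se_pair
        p_unadj = 2.0 * float(stats.t.sf(t, result.df_resid))
        rows.append(
            {
                "level_a": a,
                "level_b": b,
                "diff": diff,
                "se": float(se_pair),
                "q": float(q),
                "p_adj": min(p_adj, 1.0),
                "p_unadj": min(p_unadj, 1.0),
            }
        )
    return pd.DataFrame(rows)
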