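"""Log-linear model for parent-of-origin effects in case-parent trios.

The 15 Mendelian-compatible (M, P, C) cells are modelled with a Poisson
log-linear mean structure

    m_i = exp( mu_s(i) + c1*I(C=1) + c2*I(C=2)
               + alpha*I(maternal origin) + beta*I(M=2) + gamma*I(M=1) )

with one free intercept mu_s per unordered parental mating type
{2x2, 2x1, 2x0, 1x1, 1x0, 0x0}.  Because the stratum intercepts are free,
maximising this Poisson likelihood is equivalent, for likelihood-ratio
purposes, to the multinomial likelihood conditional on the stratum totals.

* ``alpha`` (imprinting): excess risk when the single copy carried by a
  heterozygous child was inherited from the mother.  Only heterozygous
  children have an origin; homozygous children received one copy from each
  parent (or none), so C=0 and C=2 cells carry no alpha.
* ``beta`` / ``gamma`` (maternal effects): risk multipliers when the mother
  carries two / one copies, regardless of transmission.

The double-heterozygote cell 9, (M,P,C) = (1,1,1), merges two latent
transmission paths (maternal-origin and paternal-origin), so its mean is
the sum of the two path means:

    m_9 = exp(mu_{1x1} + c1 + gamma) * (exp(alpha) + 1)

With all coefficients zero this reduces to the 2x Mendelian path
multiplicity of the double-heterozygote cell.

Each term is tested by a likelihood-ratio chi-square with 1 df, dropping
that term alone from the jointly fitted model (or, optionally, testing it
as the sole term over the baseline model).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
from scipy import optimize, stats

from .trio_data import CELL_ORDER, CellTable

__all__ = [
    "STRATUM_LABELS",
    "ModelSpec",
    "CellDesign",
    "FitResult",
    "TermTest",
    "TERMS",
    "build_design",
    "expected_cell_means",
    "log_likelihood",
    "fit",
    "lrt_term",
    "test_all_terms",
]

TERMS = ("alpha", "beta", "gamma")

STRATUM_LABELS = ("2x2", "2x1", "2x0", "1x1", "1x0", "0x0")

# Per-cell design constants (cells in CELL_ORDER, 0-based arrays).
_STRATUM = np.array([0, 1, 1, 1, 1, 2, 2, 3, 3, 3, 4, 4, 4, 4, 5])
_IC1 = np.array([(c == 1) for (_m, _p, c) in CELL_ORDER], dtype=float)
_IC2 = np.array([(c == 2) for (_m, _p, c) in CELL_ORDER], dtype=float)
_IM1 = np.array([(m == 1) for (m, _p, _c) in CELL_ORDER], dtype=float)
_IM2 = np.array([(m == 2) for (m, _p, _c) in CELL_ORDER], dtype=float)
_ORIGIN = (
    "none", "none", "maternal", "none", "paternal", "maternal", "paternal",
    "none", "ambiguous", "none", "maternal", "none", "paternal", "none", "none",
)
# alpha enters linearly only in the three determinate maternal-origin cells;
# the ambiguous cell 9 is handled through its merged-path mean.
_IA = np.array([(o == "maternal") for o in _ORIGIN], dtype=float)
_CELL9 = 8  # 0-based index of (1, 1, 1)

_MATERNAL_CELLS = np.flatnonzero(_IA).tolist()          # cells 3, 6, 11
_PATERNAL_CELLS = [i for i, o in enumerate(_ORIGIN) if o == "paternal"]


@dataclass(frozen=True)
class ModelSpec:
    """Which parent-of-origin terms the model includes.

    Stratum intercepts and the child-dose terms (c1, c2) are always
    present; the flags toggle the imprinting term (alpha) and the two
    maternal-genotype terms (beta for M=2, gamma for M=1).
    """

    include_imprinting: bool = True
    include_maternal_hom: bool = True
    include_maternal_het: bool = True

    @property
    def terms(self) -> tuple[str, ...]:
        out = []
        if self.include_imprinting:
            out.append("alpha")
        if self.include_maternal_hom:
            out.append("beta")
        if self.include_maternal_het:
            out.append("gamma")
        return tuple(out)

    def drop(self, term: str) -> "ModelSpec":
        if term not in TERMS:
            raise ValueError(f"unknown term {term!r}")
        return ModelSpec(
            include_imprinting=self.include_imprinting and term != "alpha",
            include_maternal_hom=self.include_maternal_hom and term != "beta",
            include_maternal_het=self.include_maternal_het and term != "gamma",
        )

    def only(self, term: str) -> "ModelSpec":
        return ModelSpec(
            include_imprinting=term == "alpha",
            include_maternal_hom=term == "beta",
            include_maternal_het=term == "gamma",
        )


@dataclass(frozen=True)
class CellDesign:
    """Deterministic design of the 15 cells under a ModelSpec."""

    stratum: tuple[int, ...]
    stratum_label: tuple[str, ...]
    child_het: tuple[int, ...]
    child_hom: tuple[int, ...]
    mother_hom: tuple[int, ...]
    mother_het: tuple[int, ...]
    origin: tuple[str, ...]
    terms: tuple[str, ...]


def build_design(spec: ModelSpec | None = None) -> CellDesign:
    spec = spec or ModelSpec()
    return CellDesign(
        stratum=tuple(int(s) + 1 for s in _STRATUM),
        stratum_label=tuple(STRATUM_LABELS[s] for s in _STRATUM),
        child_het=tuple(int(v) for v in _IC1),
        child_hom=tuple(int(v) for v in _IC2),
        mother_hom=tuple(int(v) for v in _IM2),
        mother_het=tuple(int(v) for v in _IM1),
        origin=_ORIGIN,
        terms=spec.terms,
    )


@dataclass
class FitResult:
    coefficients: dict[str, float]
    log_likelihood: float
    converged: bool
    n_iterations: int
    spec: ModelSpec
    inestimable_terms: list[tuple[str, str]] = field(default_factory=list)
    capped_terms: list[str] = field(default_factory=list)
    excluded_strata: list[str] = field(default_factory=list)

    def coef(self, name: str) -> float:
        return self.coefficients[name]


@dataclass
class TermTest:
    term: str
    status: Literal["ok", "inestimable"]
    lrt_statistic: float | None = None
    df: int = 1
    p_value: float | None = None
    odds_ratio: float | None = None
    reason: str | None = None
    capped: bool = False


# ---------------------------------------------------------------------------
# Mean structure and likelihood
# ---------------------------------------------------------------------------


def expected_cell_means(params: Mapping[str, float], spec: ModelSpec | None = None) -> np.ndarray:
    """Expected counts for all 15 cells given coefficients on the log scale.

    ``params`` may contain ``mu1``..``mu6``, ``c1``, ``c2``, ``alpha``,
    ``beta``, ``gamma``; absent keys default to 0 (an excluded term is
    simply absent).  Cell 9 uses the merged two-path mean.
    """
    spec = spec or ModelSpec()
    get = lambda k: float(params.get(k, 0.0))
    mus = np.array([get(f"mu{s + 1}") for s in range(6)])
    alpha = get("alpha") if spec.include_imprinting else 0.0
    beta = get("beta") if spec.include_maternal_hom else 0.0
    gamma = get("gamma") if spec.include_maternal_het else 0.0
    for name, v in (("c1", get("c1")), ("c2", get("c2")),
                    ("alpha", alpha), ("beta", beta), ("gamma", gamma)):
        if not math.isfinite(v):
            raise ValueError(f"non-finite coefficient {name}={v}")
    eta = (
        mus[_STRATUM]
        + get("c1") * _IC1
        + get("c2") * _IC2
        + alpha * _IA
        + beta * _IM2
        + gamma * _IM1
    )
    means = np.exp(eta)
    means[_CELL9] = math.exp(mus[3] + get("c1") + gamma) * (math.exp(alpha) + 1.0)
    return means


def log_likelihood(
    cell_table: CellTable, params: Mapping[str, float], spec: ModelSpec | None = None
) -> float:
    """Poisson log-likelihood sum(n*log m - m), up to the data-only constant.

    With free stratum intercepts this is equivalent, for likelihood-ratio
    purposes, to the 15-cell multinomial conditional on the stratum totals.
    A zero mean with a positive count yields -inf (returned, not raised).
    """
    n = np.asarray(cell_table.counts, dtype=float)
    m = expected_cell_means(params, spec)
    ll = -m.sum()
    pos = n > 0
    if (m[pos] == 0).any():
        return -math.inf
    ll += float(n[pos] @ np.log(m[pos]))
    return ll


# ---------------------------------------------------------------------------
# Estimability screening
# ---------------------------------------------------------------------------


def _inestimable(counts: np.ndarray, spec: ModelSpec) -> list[tuple[str, str]]:
    """Count-based screen for terms the table carries no information on.

    Indices below are 0-based into CELL_ORDER.  A term whose informative
    contrast cells are all empty has a flat (or boundary-divergent)
    profile likelihood and is reported instead of fitted.
    """
    n = counts
    out: list[tuple[str, str]] = []
    if spec.include_imprinting:
        det = n[_MATERNAL_CELLS].sum() + n[_PATERNAL_CELLS].sum()
        if det == 0:
            out.append(("alpha", "no origin-determinate heterozygous children"))
    if spec.include_maternal_hom:
        # beta contrasts live in the 2x1 and 2x0 strata (cells 2, 3, 6);
        # the 2x2 stratum is absorbed by its own intercept.
        if n[[1, 2, 5]].sum() == 0:
            out.append(("beta", "no homozygous-risk mothers in informative mating types"))
    if spec.include_maternal_het:
        # gamma contrasts live in the 2x1 and 1x0 strata (cells 4, 5, 11, 12);
        # the 1x1 stratum is absorbed by its own intercept.
        if n[[3, 4, 10, 11]].sum() == 0:
            out.append(("gamma", "no heterozygous mothers in informative mating types"))
    return out


# ---------------------------------------------------------------------------
# Maximum likelihood fit
# ---------------------------------------------------------------------------

_COEF_BOUND = 12.0  # |coef| cap keeps the likelihood finite on empty classes


def _design_matrix(terms: tuple[str, ...]) -> tuple[np.ndarray, int | None]:
    cols = [_IC1.copy(), _IC2.copy()]
    alpha_idx = None
    for t in terms:
        if t == "alpha":
            alpha_idx = len(cols)
            cols.append(_IA.copy())
        elif t == "beta":
            cols.append(_IM2.copy())
        elif t == "gamma":
            cols.append(_IM1.copy())
    X = np.column_stack(cols)
    return X, alpha_idx


def _profile_negloglik(theta, X, alpha_idx, counts, stratum_totals, total):
    """Negative profile log-likelihood (stratum intercepts maximised out).

    For fixed non-intercept coefficients the score equation for each
    stratum intercept gives exp(mu_s) = N_s / sum_{i in s} w_i where
    w_i = exp(linear predictor without the intercept).  Gradient by the
    envelope theorem: d l / d theta_j = sum_i (n_i - m_i) d eta_i/d theta_j.
    """
    eta = X @ theta
    if alpha_idx is not None:
        a = theta[alpha_idx]
        eta[_CELL9] += np.logaddexp(0.0, a)  # log(1 + e^alpha)
    else:
        eta[_CELL9] += math.log(2.0)
    # Guard against overflow on extreme intermediate steps.
    w = np.exp(np.clip(eta, -60.0, 60.0))
    T = np.bincount(_STRATUM, weights=w, minlength=6)
    active = stratum_totals > 0
    logratio = np.zeros(6)
    logratio[active] = np.log(stratum_totals[active] / T[active])
    ll = float(counts @ eta) + float(stratum_totals[active] @ logratio[active]) - total
    m = np.where(active[_STRATUM], w * np.exp(logratio)[_STRATUM], 0.0)
    resid = counts - m
    grad = X.T @ resid
    if alpha_idx is not None:
        # d eta_9 / d alpha = sigmoid(alpha); the linear alpha column is 0
        # at cell 9 by construction.
        grad[alpha_idx] += resid[_CELL9] / (1.0 + math.exp(-theta[alpha_idx]))
    return -ll, -grad


def _recover_mus(theta, X, alpha_idx, stratum_totals):
    eta = X @ theta
    if alpha_idx is not None:
        eta[_CELL9] += np.logaddexp(0.0, theta[alpha_idx])
    else:
        eta[_CELL9] += math.log(2.0)
    w = np.exp(eta)
    T = np.bincount(_STRATUM, weights=w, minlength=6)
    mus = np.full(6, -np.inf)
    active = stratum_totals > 0
    mus[active] = np.log(stratum_totals[active]) - np.log(T[active])
    return mus


def _moment_start(counts: np.ndarray, terms: tuple[str, ...]) -> np.ndarray:
    """Crude frequency-matched starting values (log count ratios)."""
    n = counts.astype(float)
    lr = lambda a, b: math.log((a + 0.5) / (b + 0.5))
    c1 = lr(n[8] / 2.0, n[9])
    c2 = lr(n[7], n[9])
    start = [np.clip(c1, -3, 3), np.clip(c2, -3, 3)]
    vals = {
        "alpha": lr(n[[2, 5, 10]].sum(), n[[4, 6, 12]].sum()),
        "beta": lr(n[[1, 2, 5]].sum(), n[[3, 4, 6]].sum()),
        "gamma": lr(n[[10, 11]].sum(), n[[12, 13]].sum()),
    }
    start.extend(np.clip(vals[t], -3, 3) for t in terms)
    return np.asarray(start, dtype=float)


def fit(cell_table: CellTable, spec: ModelSpec | None = None) -> FitResult:
    """Maximum-likelihood fit of the log-linear triad model.

    Stratum intercepts are profiled out analytically; the remaining
    coefficients are maximised by L-BFGS-B with the analytic gradient from
    two deterministic starts (all-zeros and frequency-matched).  Strata
    with zero total count are excluded and reported; terms with no
    informative counts are recorded as inestimable and not fitted.
    """
    spec = spec or ModelSpec()
    counts = np.asarray(cell_table.counts, dtype=float)
    if counts.sum() == 0:
        raise ValueError("cannot fit a model to an all-zero cell table")

    inest = _inestimable(counts, spec)
    inest_names = {t for t, _ in inest}
    terms = tuple(t for t in spec.terms if t not in inest_names)
    X, alpha_idx = _design_matrix(terms)
    stratum_totals = np.bincount(_STRATUM, weights=counts, minlength=6)
    total = float(counts.sum())

    args = (X, alpha_idx, counts, stratum_totals, total)
    bounds = [(-_COEF_BOUND, _COEF_BOUND)] * X.shape[1]
    best = None
    n_iter = 0
    for start in (np.zeros(X.shape[1]), _moment_start(counts, terms)):
        res = optimize.minimize(
            _profile_negloglik,
            start,
            args=args,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-13, "gtol": 1e-9, "maxiter": 500},
        )
        n_iter += res.nit
        if best is None or res.fun < best.fun:
            best = res

    theta = best.x
    mus = _recover_mus(theta, X, alpha_idx, stratum_totals)
    coefficients: dict[str, float] = {
        f"mu{s + 1}": float(mus[s]) for s in range(6)
    }
    coefficients["c1"] = float(theta[0])
    coefficients["c2"] = float(theta[1])
    capped = []
    for k, t in enumerate(terms, start=2):
        coefficients[t] = float(theta[k])
        if abs(theta[k]) >= _COEF_BOUND - 1e-6:
            capped.append(t)
    for k, name in ((0, "c1"), (1, "c2")):
        if abs(theta[k]) >= _COEF_BOUND - 1e-6:
            capped.append(name)

    grad_norm = float(np.max(np.abs(best.jac)))
    return FitResult(
        coefficients=coefficients,
        log_likelihood=float(-best.fun),
        converged=bool(best.success) and grad_norm < 1e-4,
        n_iterations=n_iter,
        spec=spec,
        inestimable_terms=inest,
        capped_terms=capped,
        excluded_strata=[
            STRATUM_LABELS[s] for s in range(6) if stratum_totals[s] == 0
        ],
    )


# ---------------------------------------------------------------------------
# Likelihood-ratio tests
# ---------------------------------------------------------------------------


def lrt_term(
    cell_table: CellTable,
    term: str,
    spec: ModelSpec | None = None,
    baseline: Literal["joint", "single"] = "joint",
    full_fit: FitResult | None = None,
) -> TermTest:
    """Likelihood-ratio chi-square (1 df) for one parent-of-origin term.

    ``baseline='joint'`` (default) tests the term by dropping it from the
    jointly fitted model; ``baseline='single'`` tests it as the only term
    over the strata + child-dose baseline.
    """
    spec = spec or ModelSpec()
    if term not in spec.terms:
        raise ValueError(f"term {term!r} is not included in the model spec")
    full_spec = spec if baseline == "joint" else spec.only(term)
    if full_fit is None or full_fit.spec != full_spec:
        full_fit = fit(cell_table, full_spec)
    for t, reason in full_fit.inestimable_terms:
        if t == term:
            return TermTest(term=term, status="inestimable", reason=reason)
    reduced_fit = fit(cell_table, full_spec.drop(term))
    statistic = 2.0 * (full_fit.log_likelihood - reduced_fit.log_likelihood)
    if statistic < 1e-8:  # clamp optimizer noise; an exact 0 reports p = 1
        statistic = 0.0
    p_value = float(stats.chi2.sf(statistic, df=1)) if statistic > 0 else 1.0
    return TermTest(
        term=term,
        status="ok",
        lrt_statistic=float(statistic),
        df=1,
        p_value=p_value,
        odds_ratio=float(math.exp(full_fit.coef(term))),
        capped=term in full_fit.capped_terms,
    )


def test_all_terms(
    cell_table: CellTable,
    spec: ModelSpec | None = None,
    baseline: Literal["joint", "single"] = "joint",
) -> dict[str, TermTest]:
    """LRT for alpha, beta and gamma, sharing one full-model fit when joint."""
    spec = spec or ModelSpec()
    shared = fit(cell_table, spec) if baseline == "joint" else None
    return {
        term: lrt_term(cell_table, term, spec, baseline=baseline, full_fit=shared)
        for term in spec.terms
    }
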