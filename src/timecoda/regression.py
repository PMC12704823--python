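"""Outcome model: %TWL on ILR coordinates plus screened covariates.

The composition enters a multiple linear regression through its three ILR
coordinates; the overall composition-outcome association is tested with a
nested F-test comparing the model with and without the ILR block. Because
the four pivot bases span the same 3-dimensional column space, fitted
values, residual sums of squares, the F statistic and its p-value are
identical whichever pivot is chosen.

Candidate covariates (age, sex, race, pre-surgery BMI, surgery type) are
screened one at a time alongside the ILR block and retained when their
partial F-test falls below the screening alpha. Least squares is solved by
QR in-package; p-values use exact t/F distributions, appropriate at the
small sample sizes this design targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .coda import BEHAVIORS, IlrBasis, ilr, pivot_basis

PART_COLUMNS = [f"{b}_min" for b in BEHAVIORS]
DEFAULT_CANDIDATES = ["age", "sex", "race", "bmi_pre", "surgery"]


def percent_total_weight_loss(pre_kg, post_kg):
    """%TWL = 100 (pre - post) / pre. Accepts scalars or arrays."""
    pre = np.asarray(pre_kg, dtype=float)
    post = np.asarray(post_kg, dtype=float)
    if np.any(pre <= 0) or np.any(post <= 0):
        raise ValueError("weights must be strictly positive")
    out = 100.0 * (pre - post) / pre
    return float(out) if out.ndim == 0 else out


@dataclass
class CodaFit:
    """Least-squares fit with coefficient covariance and residual df."""
    params: pd.Series
    cov: pd.DataFrame
    rss: float
    sigma2: float
    df_resid: int
    n: int
    fitted: np.ndarray
    ilr_terms: list[str] = field(default_factory=list)
    basis: IlrBasis | None = None

    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.values)),
                         index=self.params.index)

    def summary_frame(self) -> pd.DataFrame:
        se = self.se()
        t = self.params / se
        p = 2 * stats.t.sf(np.abs(t), self.df_resid)
        return pd.DataFrame({"estimate": self.params, "se": se,
                             "t": t, "p": p})


@dataclass(frozen=True)
class CompositionTest:
    """Nested F-test of the 3-coordinate ILR block."""
    f_stat: float
    df_num: int
    df_den: int
    p_value: float


def fit_linear_model(X: pd.DataFrame, y, *, ilr_terms=None,
                     basis: IlrBasis | None = None) -> CodaFit:
    """Ordinary least squares of ``y`` on the columns of ``X``.

    Requires full column rank (rank-deficient designs are rejected with the
    offending columns named) and n > p. Coefficient covariance is
    ``sigma^2 (X'X)^{-1}`` with ``sigma^2 = RSS / (n - p)``.
    """
    Xm = X.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than columns ({p})")

    Q, R = np.linalg.qr(Xm, mode="reduced")
    diag = np.abs(np.diag(R))
    tol = max(n, p) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    if np.any(diag < tol):
        # pivoted QR names which columns fail to add rank
        from scipy.linalg import qr as sqr
        _, Rp, piv = sqr(Xm, pivoting=True, mode="economic")
        rank = int(np.sum(np.abs(np.diag(Rp)) >= tol))
        bad = [X.columns[j] for j in piv[rank:]]
        raise ValueError(f"design matrix is rank deficient; offending "
                         f"column(s): {bad}")

    beta = np.linalg.solve(R, Q.T @ yv)
    fitted = Xm @ beta
    resid = yv - fitted
    rss = float(resid @ resid)
    df = n - p
    sigma2 = rss / df
    Rinv = np.linalg.solve(R, np.eye(p))
    cov = sigma2 * (Rinv @ Rinv.T)
    return CodaFit(
        params=pd.Series(beta, index=X.columns),
        cov=pd.DataFrame(cov, index=X.columns, columns=X.columns),
        rss=rss, sigma2=sigma2, df_resid=df, n=n, fitted=fitted,
        ilr_terms=list(ilr_terms or []), basis=basis,
    )


def _encode_covariate(cohort: pd.DataFrame, name: str) -> pd.DataFrame:
    """Numeric columns pass through; categoricals are reference-coded with
    the most frequent level as reference."""
    col = cohort[name]
    if pd.api.types.is_numeric_dtype(col):
        return col.to_frame(name)
    levels = col.value_counts()
    ref = levels.index[0]
    others = [lv for lv in levels.index if lv != ref]
    return pd.DataFrame(
        {f"{name}[{lv}]": (col == lv).astype(float) for lv in others},
        index=cohort.index)


def build_design(cohort: pd.DataFrame, basis: IlrBasis,
                 covariates=()) -> tuple[pd.DataFrame, list[str]]:
    """Design matrix: intercept, 3 ILR coordinates, encoded covariates.

    Returns ``(X, ilr_column_names)``. Compositions are read from the
    ``sleep_min .. mvpa_min`` columns.
    """
    comps = cohort[PART_COLUMNS].to_numpy(dtype=float)
    z = ilr(comps, basis)
    names = basis.coordinate_names
    X = pd.DataFrame({"const": 1.0}, index=cohort.index)
    for j, nm in enumerate(names):
        X[nm] = z[:, j]
    for cov in covariates:
        X = pd.concat([X, _encode_covariate(cohort, cov)], axis=1)
    return X, names


def partial_f_test(full: CodaFit, reduced: CodaFit, q: int) -> tuple[float, float]:
    """F-test for dropping a q-column block from ``full`` to ``reduced``."""
    f = ((reduced.rss - full.rss) / q) / (full.rss / full.df_resid)
    f = max(f, 0.0)
    return f, float(stats.f.sf(f, q, full.df_resid))


def screen_covariates(cohort: pd.DataFrame, basis: IlrBasis | None = None,
                      candidates=DEFAULT_CANDIDATES, outcome: str = "twl_pct",
                      alpha: float = 0.05,
                      with_composition: bool = True) -> list[str]:
    """One-at-a-time covariate screening; retain when partial p < alpha.

    Each candidate is tested in a model that (by default) already contains
    the ILR block, via the partial F-test of its encoded column(s); with
    ``with_composition=False`` candidates are screened against the
    intercept-only model instead. The screening outcome is basis-invariant.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("screening alpha must be in (0, 1]")
    basis = basis or pivot_basis(BEHAVIORS[0])
    y = cohort[outcome].to_numpy(dtype=float)
    if with_composition:
        X0, _ = build_design(cohort, basis)
    else:
        X0 = pd.DataFrame({"const": 1.0}, index=cohort.index)
    base_fit = fit_linear_model(X0, y)
    retained = []
    for cand in candidates:
        enc = _encode_covariate(cohort, cand)
        enc = enc.loc[:, enc.std(ddof=0) > 0]
        if enc.shape[1] == 0:  # constant candidates carry no signal
            continue
        full = fit_linear_model(pd.concat([X0, enc], axis=1), y)
        _, p = partial_f_test(full, base_fit, enc.shape[1])
        if p < alpha:
            retained.append(cand)
    return retained


def test_composition(full: CodaFit, reduced: CodaFit) -> CompositionTest:
    """Overall composition test: nested F for the 3 ILR columns.

    ``reduced`` must be ``full`` minus the ILR block, fitted on the same
    rows. For a 4-part composition the numerator df is 3.
    """
    if full.n != reduced.n:
        raise ValueError("full and reduced fits use different rows")
    q = len(full.ilr_terms)
    if q == 0:
        raise ValueError("full fit has no ILR terms recorded")
    if len(full.params) - len(reduced.params) != q:
        raise ValueError("reduced model must drop exactly the ILR block")
    f, p = partial_f_test(full, reduced, q)
    return CompositionTest(f_stat=f, df_num=q, df_den=full.df_resid,
                           p_value=p)


@dataclass
class CodaModelResult:
    """End-to-end model: screening, full and reduced fits, F-test."""
    fit: CodaFit
    reduced_fit: CodaFit
    test: CompositionTest
    retained_covariates: list[str]


def fit_coda_model(cohort: pd.DataFrame, basis: IlrBasis | None = None,
                   outcome: str = "twl_pct", alpha: float = 0.05,
                   candidates=DEFAULT_CANDIDATES, screen: bool = True,
                   screen_with_composition: bool = True) -> CodaModelResult:
    """Screen covariates, fit the ILR model, and test the composition."""
    basis = basis or pivot_basis(BEHAVIORS[0])
    y = cohort[outcome].to_numpy(dtype=float)
    retained = (screen_covariates(cohort, basis, candidates, outcome, alpha,
                                  screen_with_composition)
                if screen else list(candidates))
    X, ilr_names = build_design(cohort, basis, retained)
    fit = fit_linear_model(X, y, ilr_terms=ilr_names, basis=basis)
    X_red = X.drop(columns=ilr_names)
    reduced = fit_linear_model(X_red, y)
    return CodaModelResult(fit=fit, reduced_fit=reduced,
                           test=test_composition(fit, reduced),
                           retained_covariates=retained)
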