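"""Attribute measured phenotypes to individual mutations by ridge regression.

Each assayed variant becomes a row of a binary design matrix: one indicator
column per distinct mutation observed anywhere in the combined libraries,
plus a "library" column separating the two assay groups (0 for the
model-sampled library, 1 for the consensus library). Replicate measurements
of each response (specific activity in umol/min/mg, melting temperature in
degC) are averaged per variant and standardized to z-scores; coefficients are
estimated by ridge (L2-penalized) least squares with an unpenalized
intercept, solved in closed form on the centered design. The ridge penalty
lambda defaults to 1.0 on standardized responses and can be chosen by exact
leave-one-out cross-validation over a log grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DesignMatrix",
    "RegressionResult",
    "build_design",
    "standardize",
    "ridge_fit",
    "loo_cv_lambda",
    "coefficient_quadrants",
]

DEFAULT_LAMBDA = 1.0
DEFAULT_LAMBDA_GRID = tuple(np.logspace(-3, 3, 25))


@dataclass
class DesignMatrix:
    X: np.ndarray  # (n, p) binary
    predictor_names: list[str]  # mutations ... , "library"
    variant_ids: list[str]

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.variant_ids), len(self.predictor_names)):
            raise ValueError("design matrix shape mismatch")
        if self.predictor_names.count("library") != 1:
            raise ValueError("exactly one 'library' column is required")
        vals = np.unique(self.X)
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("design matrix entries must be 0/1")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=self.variant_ids,
                            columns=self.predictor_names)


@dataclass
class RegressionResult:
    coefficients: pd.Series  # indexed by predictor name
    intercept: float
    lam: float
    fitted: np.ndarray
    residuals: np.ndarray

    def coefficient(self, name: str) -> float:
        return float(self.coefficients[name])


def _mutation_key(name: str) -> tuple[int, str]:
    core = name[1:] if name.startswith("Δ") else name
    digits = "".join(c for c in core if c.isdigit())
    return (int(digits) if digits else 0, name)


def build_design(
    mutations_per_variant: Mapping[str, Sequence[str]],
    library_labels: Mapping[str, int],
) -> DesignMatrix:
    """Binary indicators for every mutation observed in >= 1 variant.

    ``mutations_per_variant`` maps variant id -> mutation names ("S60A",
    "ΔK70"); ``library_labels`` maps variant id -> 0 (model-sampled) or 1
    (consensus). Predictors are ordered by position then name, with
    "library" last.
    """
    ids = list(mutations_per_variant)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate variant ids")
    missing = [v for v in ids if v not in library_labels]
    if missing:
        raise ValueError(f"variants without a library label: {missing[:5]}")
    universe = sorted(
        {m for muts in mutations_per_variant.values() for m in muts},
        key=_mutation_key,
    )
    names = universe + ["library"]
    X = np.zeros((len(ids), len(names)), dtype=float)
    col = {m: j for j, m in enumerate(universe)}
    for i, vid in enumerate(ids):
        for m in mutations_per_variant[vid]:
            X[i, col[m]] = 1.0
        X[i, -1] = float(library_labels[vid])
    return DesignMatrix(X=X, predictor_names=names, variant_ids=ids)


def standardize(responses: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Average replicate columns per variant, then z-score across variants.

    Accepts an (n, r) table of replicate measurements (or an (n,) vector of
    already-averaged responses). Uses the sample standard deviation (n-1).
    """
    y = np.asarray(responses, dtype=float)
    if y.ndim == 2:
        y = np.nanmean(y, axis=1)
    if y.size < 2:
        raise ValueError("need at least two observations")
    sd = np.std(y, ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zero or undefined variance; cannot standardize")
    return (y - y.mean()) / sd


def ridge_fit(design: DesignMatrix, z: np.ndarray,
              lam: float = DEFAULT_LAMBDA) -> RegressionResult:
    """Closed-form ridge solution with an unpenalized intercept.

    Minimizes ||z - X beta - beta0||^2 + lam ||beta||^2. The intercept is
    fitted on centered data (beta0 = mean(z) - mean(X) . beta), so for
    standardized z it is ~0 plus the centering offset.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    z = np.asarray(z, dtype=float)
    X = design.X
    if z.shape[0] != X.shape[0]:
        raise ValueError("response length does not match design matrix")
    if X.shape[0] < 2:
        raise ValueError("need at least two observations")
    x_mean = X.mean(axis=0)
    z_mean = z.mean()
    Xc = X - x_mean
    zc = z - z_mean
    gram = Xc.T @ Xc + lam * np.eye(X.shape[1])
    try:
        beta = np.linalg.solve(gram, Xc.T @ zc)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "normal equations are singular (collinear predictors); "
            "use lambda > 0"
        ) from exc
    if lam == 0 and np.linalg.cond(gram) > 1e12:
        raise np.linalg.LinAlgError(
            "design is (near-)collinear at lambda=0; use lambda > 0"
        )
    intercept = z_mean - float(x_mean @ beta)
    fitted = X @ beta + intercept
    return RegressionResult(
        coefficients=pd.Series(beta, index=design.predictor_names),
        intercept=intercept,
        lam=float(lam),
        fitted=fitted,
        residuals=z - fitted,
    )


def loo_cv_lambda(
    design: DesignMatrix,
    z: np.ndarray,
    grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
) -> float:
    """Exact leave-one-out CV for the ridge penalty via the hat matrix.

    Uses the SVD of the centered design once; for each lambda the LOO
    residual is (z_i - yhat_i) / (1 - h_ii) with h_ii including the
    intercept's 1/n contribution.
    """
    z = np.asarray(z, dtype=float)
    X = design.X
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    zc = z - z.mean()
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    Uz = U.T @ zc
    best_lam, best_err = None, np.inf
    for lam in grid:
        shrink = s ** 2 / (s ** 2 + lam)
        fitted_c = U @ (shrink * Uz)
        h = 1.0 / n + (U ** 2 @ shrink)
        loo = (zc - fitted_c) / (1.0 - h)
        err = float(np.mean(loo ** 2))
        if err < best_err:
            best_err, best_lam = err, float(lam)
    assert best_lam is not None
    return best_lam


def coefficient_quadrants(
    result_activity: RegressionResult,
    result_tm: RegressionResult,
) -> pd.DataFrame:
    """Classify each predictor by the signs of its two coefficients.

    "++" improves both responses, "--" harms both, "+-"/"-+" trade off;
    exact zeros are "neutral". Sorted by Euclidean coefficient magnitude,
    largest first.
    """
    a = result_activity.coefficients
    t = result_tm.coefficients
    if list(a.index) != list(t.index):
        raise ValueError("results must share predictor names")

    def _quad(ba: float, bt: float) -> str:
        if ba == 0 and bt == 0:
            return "neutral"
        sa = "+" if ba > 0 else ("-" if ba < 0 else "0")
        st = "+" if bt > 0 else ("-" if bt < 0 else "0")
        return sa + st

    df = pd.DataFrame(
        {
            "mutation": a.index,
            "beta_activity": a.values,
            "beta_tm": t.values,
        }
    )
    df["quadrant"] = [
        _quad(ba, bt) for ba, bt in zip(df.beta_activity, df.beta_tm)
    ]
    df["magnitude"] = np.hypot(df.beta_activity, df.beta_tm)
    return df.sort_values("magnitude", ascending=False).reset_index(drop=True)
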