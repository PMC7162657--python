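"""Mass-univariate developmental statistics, FDR, partial correlation, mediation.

Age and cognition effects on per-region control energy are modeled with
generalized additive models (penalized cubic regression splines for age,
smoothing selected by restricted maximum likelihood) with linear covariates:

    energy ~ s(age) + sex + handedness + motion + tbv + network_strength
    energy ~ ef_score + s(age) + sex + handedness + motion + tbv + network_strength

Fitting delegates to mgcv (the reference GAM implementation) through an
Rscript subprocess; a whole feature matrix is fit in one call.  The smooth
term's p-value is converted to a signed Z via the inverse standard normal,
``Z = sign(partial r) * Phi^-1(1 - p/2)``, with the sign taken from the
linear partial correlation of the feature with age given the covariates —
GAM software reports unsigned smooth statistics, so the sign is a
reconstruction.  Effect sizes are linear partial correlations with Fisher-z
confidence intervals; multiple comparisons use Benjamini-Hochberg FDR.

The mediation model is the single-mediator a/b/c/c' scheme: all variables are
residualized on the nuisance covariates, standardized to unit variance, the
paths estimated by OLS, and the indirect effect ``a*b`` given a
case-resampling percentile bootstrap confidence interval.
"""

from __future__ import annotations

import logging
import subprocess
import tempfile
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .errors import (
    DegenerateTestError,
    ParameterError,
    UndefinedCorrelationError,
    ValidationError,
)

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("sex", "handedness", "motion", "tbv", "network_strength")
SPLINE_BASIS_DIM = 10


@dataclass
class GamResult:
    feature_id: str
    z_value: float
    p_value: float
    q_value: float
    partial_r: float
    ci_low: float
    ci_high: float
    edf: float


@dataclass
class MediationResult:
    path_a: float
    path_b: float
    path_c: float
    path_c_prime: float
    indirect: float
    ci_low: float
    ci_high: float
    p_value: float
    n_boot: int


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def _residualize(y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Residuals of ``y`` after OLS on covariates plus an intercept."""
    n = len(y)
    if covariates is None or covariates.size == 0:
        design = np.ones((n, 1))
    else:
        design = np.column_stack([np.ones(n), covariates])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def _check_design_rank(design: pd.DataFrame) -> None:
    x = np.column_stack([np.ones(len(design)), design.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify offending columns via incremental rank
        bad = []
        cols = [np.ones(len(design))]
        for name in design.columns:
            cols.append(design[name].to_numpy(dtype=float))
            if np.linalg.matrix_rank(np.column_stack(cols)) < len(cols):
                bad.append(name)
                cols.pop()
        raise ValidationError(f"rank-deficient design; collinear columns: {bad}")


def partial_correlation(
    x, y, covariates=None
) -> tuple[float, float, float]:
    """Linear partial correlation with a 95% Fisher-z confidence interval.

    ``r`` is the Pearson correlation of the OLS residuals of ``x`` and ``y``
    after regressing each on the covariates (plus intercept).  The CI uses
    ``se = 1 / sqrt(n_eff - 3)`` with the effective sample size reduced by
    the number of covariates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = None if covariates is None else np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov is not None and cov.shape[0] != len(x):
        cov = cov.T
    k = 0 if cov is None else cov.shape[1]
    n = len(x)
    if n <= k + 3:
        raise ParameterError("n must exceed the number of covariates + 3")
    rx = _residualize(x, cov)
    ry = _residualize(y, cov)
    if rx.std() == 0 or ry.std() == 0:
        raise UndefinedCorrelationError("constant residuals: correlation undefined")
    r = float(np.corrcoef(rx, ry)[0, 1])
    n_eff = n - k
    se = 1.0 / np.sqrt(n_eff - 3)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    lo, hi = np.tanh(z - 1.959963984540054 * se), np.tanh(z + 1.959963984540054 * se)
    return r, float(lo), float(hi)


def fdr_correct(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (q_values, rejected flags)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    _, q_values, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return q_values, q_values <= q


def signed_z_from_p(p: float, sign: float) -> float:
    """``Z = sign * Phi^-1(1 - p/2)`` with the sign of a linear effect.

    p is floored at 1e-300 so the reconstruction stays finite (|Z| <= 37.1).
    """
    p = min(max(p, 1e-300), 1.0)
    z = norm.isf(p / 2.0)
    return float(np.copysign(z, sign) if sign != 0 else z)


# ---------------------------------------------------------------------------
# GAM fitting via mgcv
# ---------------------------------------------------------------------------

def _run_gam_batch(
    features: pd.DataFrame,
    cohort: pd.DataFrame,
    mode: str,
    covariates: tuple[str, ...],
) -> pd.DataFrame:
    data = pd.concat(
        [
            features.reset_index(drop=True).rename(
                columns={c: f"feat_{i}" for i, c in enumerate(features.columns)}
            ),
            cohort.reset_index(drop=True)[
                list(covariates) + ["age"] + (["ef_score"] if mode == "cognition" else [])
            ],
        ],
        axis=1,
    )
    script = resources.files("ctrlenergy").joinpath("gam_fit.R")
    with tempfile.TemporaryDirectory() as tmp:
        data_path = Path(tmp) / "data.tsv"
        out_path = Path(tmp) / "out.tsv"
        data.to_csv(data_path, sep="\t", index=False)
        cmd = [
            "Rscript",
            "--vanilla",
            str(script),
            str(data_path),
            str(out_path),
            mode,
            ",".join(covariates),
            str(SPLINE_BASIS_DIM),
        ]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise RuntimeError(f"mgcv fit failed:\n{proc.stderr[-2000:]}")
        out = pd.read_csv(out_path, sep="\t")
    out["feature"] = list(features.columns)
    return out


def fit_age_gam_replicates(
    features: list[np.ndarray],
    cohorts: list[pd.DataFrame],
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Age-GAM smooth p-values for one feature per replicate cohort.

    All replicates are fitted in a single R session (each cohort brings its
    own subjects and covariates), which makes large null-calibration sweeps
    cheap.  Returns one row per replicate with edf, F and p of the age smooth.
    """
    if len(features) != len(cohorts):
        raise ValidationError("one feature vector per replicate cohort is required")
    blocks = []
    for i, (feat, cohort) in enumerate(zip(features, cohorts)):
        block = cohort.reset_index(drop=True)[list(covariates) + ["age"]].copy()
        block.insert(0, "feat_0", np.asarray(feat, dtype=float))
        block["replicate"] = i
        blocks.append(block)
    data = pd.concat(blocks, ignore_index=True)
    script = resources.files("ctrlenergy").joinpath("gam_fit.R")
    with tempfile.TemporaryDirectory() as tmp:
        data_path = Path(tmp) / "data.tsv"
        out_path = Path(tmp) / "out.tsv"
        data.to_csv(data_path, sep="\t", index=False)
        cmd = [
            "Rscript",
            "--vanilla",
            str(script),
            str(data_path),
            str(out_path),
            "age",
            ",".join(covariates),
            str(SPLINE_BASIS_DIM),
            "replicate",
        ]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise RuntimeError(f"mgcv replicate fit failed:\n{proc.stderr[-2000:]}")
        return pd.read_csv(out_path, sep="\t")


def _prepare(feature_df, cohort, covariates, extra_covariates, need_ef):
    cohort = cohort.reset_index(drop=True)
    feature_df = feature_df.reset_index(drop=True)
    if len(feature_df) != len(cohort):
        raise ValidationError("feature rows must match cohort rows")
    if extra_covariates is not None:
        extra = extra_covariates.reset_index(drop=True)
        cohort = pd.concat([cohort, extra], axis=1)
        covariates = tuple(covariates) + tuple(extra.columns)
    cols = list(covariates) + ["age"] + (["ef_score"] if need_ef else [])
    keep = cohort[cols].notna().all(axis=1) & feature_df.notna().all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropping %d subject(s) with missing values", dropped)
        cohort = cohort[keep].reset_index(drop=True)
        feature_df = feature_df[keep].reset_index(drop=True)
    _check_design_rank(cohort[list(covariates)])
    return feature_df, cohort, covariates


def fit_age_gam_table(
    features: pd.DataFrame,
    cohort: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    extra_covariates: pd.DataFrame | None = None,
    fdr_q: float = 0.05,
) -> pd.DataFrame:
    """Age GAMs for every feature column; returns a tidy result table.

    Columns: feature_id, z_value, p_value, q_value (BH across the supplied
    features), partial_r with 95% CI, edf.
    """
    features, cohort, covariates = _prepare(
        features, cohort, covariates, extra_covariates, need_ef=False
    )
    raw = _run_gam_batch(features, cohort, "age", covariates)
    cov_arr = cohort[list(covariates)].to_numpy(dtype=float)
    age = cohort["age"].to_numpy(dtype=float)
    rows = []
    for (_, rr), col in zip(raw.iterrows(), features.columns):
        r, lo, hi = partial_correlation(features[col].to_numpy(), age, cov_arr)
        rows.append(
            {
                "feature_id": col,
                "z_value": signed_z_from_p(rr["p_value"], np.sign(r)),
                "p_value": float(rr["p_value"]),
                "partial_r": r,
                "ci_low": lo,
                "ci_high": hi,
                "edf": float(rr["edf"]),
            }
        )
    out = pd.DataFrame(rows)
    out["q_value"], out["significant"] = fdr_correct(out["p_value"], fdr_q)
    return out


def fit_cognition_gam_table(
    features: pd.DataFrame,
    cohort: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    extra_covariates: pd.DataFrame | None = None,
    fdr_q: float = 0.05,
) -> pd.DataFrame:
    """Executive-function GAMs (linear EF term + age smooth) per feature."""
    features, cohort, covariates = _prepare(
        features, cohort, covariates, extra_covariates, need_ef=True
    )
    raw = _run_gam_batch(features, cohort, "cognition", covariates)
    n = len(cohort)
    k = len(covariates) + 1  # + spline-adjusted age
    rows = []
    for (_, rr), col in zip(raw.iterrows(), features.columns):
        r = float(rr["partial_r"])
        n_eff = n - k
        se = 1.0 / np.sqrt(n_eff - 3)
        zr = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
        rows.append(
            {
                "feature_id": col,
                "z_value": signed_z_from_p(rr["p_value"], np.sign(rr["statistic"])),
                "p_value": float(rr["p_value"]),
                "partial_r": r,
                "ci_low": float(np.tanh(zr - 1.96 * se)),
                "ci_high": float(np.tanh(zr + 1.96 * se)),
                "edf": float(rr["edf"]),
            }
        )
    out = pd.DataFrame(rows)
    out["q_value"], out["significant"] = fdr_correct(out["p_value"], fdr_q)
    return out


def _single(table: pd.DataFrame) -> GamResult:
    rr = table.iloc[0]
    return GamResult(
        feature_id=str(rr["feature_id"]),
        z_value=float(rr["z_value"]),
        p_value=float(rr["p_value"]),
        q_value=float(rr["q_value"]),
        partial_r=float(rr["partial_r"]),
        ci_low=float(rr["ci_low"]),
        ci_high=float(rr["ci_high"]),
        edf=float(rr["edf"]),
    )


def fit_age_gam(feature, cohort, covariates=DEFAULT_COVARIATES, extra_covariates=None) -> GamResult:
    """Age GAM for a single feature vector."""
    table = fit_age_gam_table(
        pd.DataFrame({"feature": np.asarray(feature, dtype=float)}),
        cohort,
        covariates,
        extra_covariates,
    )
    return _single(table)


def fit_cognition_gam(feature, cohort, covariates=DEFAULT_COVARIATES, extra_covariates=None) -> GamResult:
    """Executive-function GAM for a single feature vector."""
    table = fit_cognition_gam_table(
        pd.DataFrame({"feature": np.asarray(feature, dtype=float)}),
        cohort,
        covariates,
        extra_covariates,
    )
    return _single(table)


# ---------------------------------------------------------------------------
# mediation
# ---------------------------------------------------------------------------

def _paths(x: np.ndarray, m: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    sxx = x @ x
    a = (x @ m) / sxx
    c = (x @ y) / sxx
    d2 = np.column_stack([m, x])
    beta = np.linalg.solve(d2.T @ d2, d2.T @ y)
    b, c_prime = float(beta[0]), float(beta[1])
    return float(a), b, float(c), c_prime


def mediation_bootstrap(
    x,
    m,
    y,
    covariates=None,
    n_boot: int = 10000,
    seed: int | None = None,
    ci: float = 95.0,
) -> MediationResult:
    """Single-mediator bootstrap mediation on residualized, standardized data.

    Paths: ``a`` from ``m ~ x``; ``b`` and ``c'`` from ``y ~ m + x``; ``c``
    from ``y ~ x``; indirect effect ``a*b`` with a case-resampling percentile
    bootstrap CI and a two-sided sign-proportion p-value.
    """
    if n_boot < 100:
        raise ParameterError("n_boot must be >= 100")
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (len(x) == len(m) == len(y)):
        raise ValidationError("x, m, y must have equal length")
    cov = None if covariates is None else np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov is not None and cov.shape[0] != len(x):
        cov = cov.T
    vals = []
    for v in (x, m, y):
        rv = _residualize(v, cov)
        sd = rv.std(ddof=0)
        if sd == 0:
            raise DegenerateTestError("degenerate residuals in mediation input")
        vals.append(rv / sd)
    xs, ms, ys = vals
    a, b, c, c_prime = _paths(xs, ms, ys)
    indirect = a * b

    rng = np.random.default_rng(seed)
    n = len(xs)
    boots = np.empty(n_boot)
    chunk = max(1, int(2e6 // n))
    done = 0
    while done < n_boot:
        nb = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(nb, n))
        bx, bm, by = xs[idx], ms[idx], ys[idx]
        sxx = np.einsum("ij,ij->i", bx, bx)
        sxm = np.einsum("ij,ij->i", bx, bm)
        sxy = np.einsum("ij,ij->i", bx, by)
        smm = np.einsum("ij,ij->i", bm, bm)
        smy = np.einsum("ij,ij->i", bm, by)
        a_b = sxm / sxx
        det = smm * sxx - sxm**2
        b_b = (smy * sxx - sxm * sxy) / det
        boots[done : done + nb] = a_b * b_b
        done += nb
    alpha = (100.0 - ci) / 2.0
    lo, hi = np.percentile(boots, [alpha, 100.0 - alpha])
    p = 2.0 * min(np.mean(boots <= 0.0), np.mean(boots >= 0.0))
    return MediationResult(
        path_a=a,
        path_b=b,
        path_c=c,
        path_c_prime=c_prime,
        indirect=indirect,
        ci_low=float(lo),
        ci_high=float(hi),
        p_value=float(min(p, 1.0)),
        n_boot=n_boot,
    )
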