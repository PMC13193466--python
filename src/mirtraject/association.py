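"""Per-miRNA matched case-control association within lead-time windows.

Expression is recoded to decile scores (1-10) from the pooled case+control
values of each analysis window; a 1:1 conditional logistic regression on
within-pair differences estimates the odds ratio per one-decile increase,
adjusted for age, BMI, smoking, diabetes and family history; p-values are
Benjamini-Hochberg adjusted across the panel.

For 1:1 matching the conditional likelihood of pair ``i`` with case-minus-
control covariate difference ``d_i`` is the logistic ``sigma(beta' d_i)``, so
the fit maximizes ``sum_i log sigma(beta' d_i)`` — solved here by
Newton-Raphson with the analytic gradient/Hessian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .errors import EstimationError, ValidationError
from .io import CountMatrix

ADJUSTMENT_FEATURES = (
    "age_at_draw",
    "bmi",
    "smoking_former",
    "smoking_current",
    "diabetes",
    "family_history",
)


# ---------------------------------------------------------------------------
# Decile exposure
# ---------------------------------------------------------------------------

def decile_transform(
    values: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str]]:
    """Recode each probe's values to decile scores 1..10.

    Cutpoints are the 10th..90th empirical percentiles of the pooled values
    (cases and controls together); the score is ``1 + #{cutpoints < value}``
    so tied values share the lower decile.  Scores are invariant to strictly
    monotone transforms of a probe's values.  Probes with a single distinct
    value are flagged degenerate (all scores 1).
    """
    data = values.to_numpy(dtype=float)
    qs = np.quantile(data, np.linspace(0.1, 0.9, 9), axis=1)  # 9 x probes
    scores = 1 + (qs[:, :, None] < data[None, :, :]).sum(axis=0)
    degenerate = [
        pid
        for pid, row in zip(values.index, data)
        if len(np.unique(row)) == 1
    ]
    out = pd.DataFrame(scores, index=values.index, columns=values.columns, dtype=int)
    out.loc[degenerate] = 1
    return out, degenerate


# ---------------------------------------------------------------------------
# 1:1 conditional logistic regression
# ---------------------------------------------------------------------------

@dataclass
class ClogitResult:
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    n_pairs: int
    names: list[str] = field(default_factory=list)

    def wald(self, index: int = 0) -> tuple[float, float, float, float]:
        """(OR, ci_low, ci_high, p) for coefficient ``index``."""
        b, s = float(self.beta[index]), float(self.se[index])
        if s > 0 and np.isfinite(s):
            p = 2.0 * stats.norm.sf(abs(b) / s)
        else:
            p = float("nan")
        return (
            float(np.exp(b)),
            float(np.exp(b - 1.96 * s)),
            float(np.exp(b + 1.96 * s)),
            float(p),
        )


def clogit_loglik(beta: np.ndarray, diffs: np.ndarray) -> float:
    """Conditional log-likelihood sum_i log sigma(beta' d_i)."""
    eta = diffs @ beta
    return float(-np.logaddexp(0.0, -eta).sum())


def clogit_fit(
    diffs: np.ndarray | pd.DataFrame,
    names: Sequence[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 50,
    separation_bound: float = 15.0,
) -> ClogitResult:
    """Newton-Raphson fit of the 1:1 matched conditional likelihood.

    ``diffs`` holds one row per pair of case-minus-control covariate
    differences.  Convergence: score norm below ``tol``.  Separation
    (any |beta| above ``separation_bound``, or a singular Hessian) yields
    ``converged=False`` with the last iterate.
    """
    if isinstance(diffs, pd.DataFrame):
        names = list(diffs.columns)
        diffs = diffs.to_numpy(dtype=float)
    diffs = np.atleast_2d(np.asarray(diffs, dtype=float))
    n, p = diffs.shape
    if n == 0:
        raise EstimationError("no pairs to fit")
    if np.all(diffs[:, 0] == 0.0):
        raise EstimationError(
            "non-identifiable: exposure difference is zero in every pair"
        )
    beta = np.zeros(p)
    converged = False
    singular = False
    ll = clogit_loglik(beta, diffs)
    for _ in range(max_iter):
        eta = diffs @ beta
        resid = expit(-eta)  # 1 - sigma(eta)
        grad = diffs.T @ resid
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        w = expit(eta) * resid
        info = (diffs * w[:, None]).T @ diffs  # observed information
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            singular = True
            break
        # step halving keeps the likelihood non-decreasing
        factor = 1.0
        for _ in range(30):
            candidate = beta + factor * step
            ll_new = clogit_loglik(candidate, diffs)
            if ll_new >= ll - 1e-12:
                break
            factor *= 0.5
        beta = beta + factor * step
        ll = clogit_loglik(beta, diffs)
        if np.abs(beta).max() > separation_bound:
            break
    if np.abs(beta).max() > separation_bound:
        converged = False
    eta = diffs @ beta
    w = expit(eta) * expit(-eta)
    info = (diffs * w[:, None]).T @ diffs
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        singular = True
        se = np.full(p, np.nan)
    if singular:
        converged = False
    return ClogitResult(
        beta=beta,
        se=se,
        loglik=clogit_loglik(beta, diffs),
        converged=converged,
        n_pairs=n,
        names=list(names) if names is not None else [f"x{i}" for i in range(p)],
    )


# ---------------------------------------------------------------------------
# Lead-time windows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowSpec:
    """Disjoint, exhaustive lead-time windows; upper bounds inclusive.

    Default boundaries (5, 10) give (0,5], (5,10], (10,inf): a lead time of
    exactly 5.0 falls in the first window, 10.0 in the second.
    """

    boundaries: tuple[float, ...] = (5.0, 10.0)

    def __post_init__(self) -> None:
        if list(self.boundaries) != sorted(set(self.boundaries)):
            raise ValidationError("window boundaries must be strictly increasing")

    @property
    def labels(self) -> list[str]:
        labels, lo = [], 0.0
        for b in self.boundaries:
            labels.append(f"{lo:g}-{b:g}y")
            lo = b
        labels.append(f">{lo:g}y")
        return labels

    def assign(self, lead_time: float) -> str:
        lo = 0.0
        for label, b in zip(self.labels, self.boundaries):
            if lead_time <= b:
                return label
            lo = b
        return self.labels[-1]


def window_stratify(
    manifest: pd.DataFrame, spec: WindowSpec | None = None
) -> dict[str, list[str]]:
    """Assign each pair to exactly one window by its case's lead time."""
    spec = spec or WindowSpec()
    pairs = manifest.drop_duplicates("pair_id")[["pair_id", "lead_time_years"]]
    out: dict[str, list[str]] = {label: [] for label in spec.labels}
    for pair_id, t in pairs.itertuples(index=False):
        out[spec.assign(float(t))].append(pair_id)
    return out


# ---------------------------------------------------------------------------
# Benjamini-Hochberg with a panel-wide test count
# ---------------------------------------------------------------------------

def bh_adjust(p_values: Sequence[float], m_total: int | None = None) -> np.ndarray:
    """Step-up FDR adjustment: adj_(i) = min(1, min_{j>=i} p_(j) * m/j).

    ``m_total`` is the total number of tests in the family (>= the length of
    the vector); probes filtered before testing still count toward it.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0.0 or np.nanmax(p) > 1.0):
        raise ValidationError("p-values outside [0, 1]")
    m = len(p) if m_total is None else int(m_total)
    if m < len(p):
        raise ValidationError("m_total smaller than the number of p-values")
    order = np.argsort(p, kind="stable")
    adjusted = np.empty_like(p)
    running = 1.0
    for rank in range(len(p), 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adjusted[i] = running
    return adjusted


# ---------------------------------------------------------------------------
# Covariate differences and the full Table-2-style analysis
# ---------------------------------------------------------------------------

def encode_covariates(manifest: pd.DataFrame) -> pd.DataFrame:
    """Per-sample numeric design columns (smoking reference = never)."""
    out = pd.DataFrame(index=manifest["sample_id"])
    m = manifest.set_index("sample_id")
    out["age_at_draw"] = m["age_at_draw"].astype(float)
    out["bmi"] = m["bmi"].astype(float)
    out["smoking_former"] = (m["smoking"] == "former").astype(float)
    out["smoking_current"] = (m["smoking"] == "current").astype(float)
    out["diabetes"] = m["diabetes"].astype(float)
    out["family_history"] = m["family_history"].astype(float)
    if "ca199" in m.columns:
        out["log_ca199"] = np.log(m["ca199"].astype(float))
    return out


def pair_differences(
    manifest: pd.DataFrame, features: pd.DataFrame
) -> pd.DataFrame:
    """Case-minus-control feature differences, one row per pair."""
    m = manifest.set_index("sample_id")
    cases = manifest[manifest["role"] == "case"].set_index("pair_id")["sample_id"]
    controls = manifest[manifest["role"] == "control"].set_index("pair_id")[
        "sample_id"
    ]
    pair_ids = [p for p in cases.index if p in controls.index]
    diff = (
        features.loc[cases.loc[pair_ids]].to_numpy()
        - features.loc[controls.loc[pair_ids]].to_numpy()
    )
    return pd.DataFrame(diff, index=pair_ids, columns=features.columns)


def association_table(
    normed: CountMatrix,
    manifest: pd.DataFrame,
    windows: WindowSpec | None = None,
    covariates: Sequence[str] = ADJUSTMENT_FEATURES,
    m_total: int | None = None,
    low_information_frac: float = 0.2,
) -> pd.DataFrame:
    """Window-stratified per-miRNA conditional-logistic association table.

    Within each lead-time window: decile-transform the window's pooled
    samples, fit OR per decile adjusted for ``covariates``, then BH-adjust
    across probes with family size ``m_total`` (default: the endogenous panel
    size).  Output columns mirror a published association table: miRNA,
    accession, window, OR, CI bounds, p, p_fdr, n_pairs, converged flags.
    """
    windows = windows or WindowSpec()
    endo = normed.endogenous
    if m_total is None:
        m_total = len(endo)
    cov = encode_covariates(manifest)
    strata = window_stratify(manifest, windows)
    results: list[dict] = []
    for label, pair_ids in strata.items():
        if not pair_ids:
            warnings.warn(f"window {label}: no pairs, association skipped")
            continue
        sub_manifest = manifest[manifest["pair_id"].isin(pair_ids)]
        sample_ids = list(sub_manifest["sample_id"])
        deciles, degenerate = decile_transform(endo[sample_ids])
        cov_diff = pair_differences(sub_manifest, cov[list(covariates)])
        exp_diff = pair_differences(
            sub_manifest, deciles.T.astype(float)
        )  # pairs x probes
        discordant = (exp_diff != 0).mean(axis=0)
        for pid in endo.index:
            row = {
                "miRNA": pid,
                "accession": normed.accession[pid],
                "window": label,
                "n_pairs": len(cov_diff),
                "degenerate": pid in degenerate,
                "low_information": bool(discordant[pid] < low_information_frac),
            }
            try:
                design = pd.concat(
                    [exp_diff[pid].rename("exposure"), cov_diff], axis=1
                )
                fit = clogit_fit(design)
                or_, lo, hi, p = fit.wald(0)
                row.update(
                    OR=or_, ci_low=lo, ci_high=hi, p=p, converged=fit.converged
                )
            except EstimationError:
                row.update(
                    OR=np.nan, ci_low=np.nan, ci_high=np.nan, p=np.nan,
                    converged=False,
                )
            results.append(row)
    table = pd.DataFrame(results)
    table["p_fdr"] = np.nan
    for label in table["window"].unique():
        mask = (table["window"] == label) & table["converged"] & table["p"].notna()
        if mask.any():
            table.loc[mask, "p_fdr"] = bh_adjust(
                table.loc[mask, "p"].to_numpy(), m_total
            )
    return table.sort_values(["window", "p"], kind="stable").reset_index(drop=True)
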