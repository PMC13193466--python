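"""Case/control log-ratio trajectories over the decade before diagnosis.

For each matched pair the statistic is the natural log of the case's
normalized miRNA level over its control's.  A per-probe ordinary least
squares fit of log(ratio) on lead time, restricted to pairs with lead time
<= 10 years, gives the trajectory slope (per year); participants with
repeated draws are handled by a random-intercept linear mixed model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError
from .io import CountMatrix

DEFAULT_MAX_LEAD = 10.0


def pair_log_ratio(
    case: np.ndarray | float,
    control: np.ndarray | float,
    pseudocount: float = 0.5,
) -> np.ndarray | float:
    """ln((case + c)/(control + c)) with c applied only to zero-containing pairs.

    Both values zero yields 0 (degenerate pair).  Inputs must be
    non-negative (post-normalization values).
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    if (case < 0).any() or (control < 0).any():
        raise ValueError("log-ratio inputs must be non-negative")
    has_zero = (case == 0.0) | (control == 0.0)
    both_zero = (case == 0.0) & (control == 0.0)
    c = np.where(has_zero, pseudocount, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log((case + c) / (control + c))
    out = np.where(both_zero, 0.0, out)
    return out if out.shape else float(out)


def pair_ratio_matrix(
    normed: CountMatrix, manifest: pd.DataFrame, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Probes x pairs matrix of log(case/control) on normalized values."""
    cases = manifest[manifest["role"] == "case"].set_index("pair_id")["sample_id"]
    controls = manifest[manifest["role"] == "control"].set_index("pair_id")[
        "sample_id"
    ]
    pair_ids = [p for p in cases.index if p in controls.index]
    endo = normed.endogenous
    case_vals = endo[list(cases.loc[pair_ids])].to_numpy()
    ctrl_vals = endo[list(controls.loc[pair_ids])].to_numpy()
    ratios = pair_log_ratio(case_vals, ctrl_vals, pseudocount)
    return pd.DataFrame(ratios, index=endo.index, columns=pair_ids)


@dataclass
class TrendResult:
    probe_id: str
    mean_log_ratio: float
    sd_log_ratio: float
    beta: float
    se: float
    p: float
    n_pairs: int


def trend_fit(
    log_ratios: np.ndarray,
    lead_times: np.ndarray,
    max_lead: float = DEFAULT_MAX_LEAD,
    probe_id: str = "",
) -> TrendResult:
    """OLS of log(ratio) on lead time, restricted to lead time <= max_lead.

    Returns the included ratios' mean/SD, the slope per year with its SE and
    the two-sided t-test p-value.
    """
    log_ratios = np.asarray(log_ratios, dtype=float)
    lead_times = np.asarray(lead_times, dtype=float)
    keep = lead_times <= max_lead
    y, x = log_ratios[keep], lead_times[keep]
    if len(y) < 3:
        raise InsufficientDataError(
            f"trend fit needs >= 3 pairs with lead time <= {max_lead}, "
            f"got {len(y)}"
        )
    if np.ptp(y) == 0.0:
        # constant response: flat line, no evidence of trend
        return TrendResult(
            probe_id=probe_id,
            mean_log_ratio=float(y.mean()),
            sd_log_ratio=0.0,
            beta=0.0,
            se=0.0,
            p=1.0,
            n_pairs=int(len(y)),
        )
    fit = stats.linregress(x, y)
    return TrendResult(
        probe_id=probe_id,
        mean_log_ratio=float(y.mean()),
        sd_log_ratio=float(y.std(ddof=1)),
        beta=float(fit.slope),
        se=float(fit.stderr),
        p=float(fit.pvalue),
        n_pairs=int(len(y)),
    )


@dataclass
class RepeatedTrendResult:
    beta: float
    se: float
    p: float
    sigma_u2: float  # participant random-intercept variance
    sigma_e2: float  # residual variance
    n_participants: int
    n_obs: int
    method: str  # "mixed" or "ols_cluster" fallback
    converged: bool


def repeated_trend_fit(series: pd.DataFrame) -> RepeatedTrendResult:
    """Random-intercept mixed model for participants with repeated draws.

    ``series`` needs columns participant, lead_time_years, log_ratio, with
    >= 2 observations per participant.  Fits
    ``log_ratio = b0 + b1*lead + u_i + eps`` by REML (statsmodels MixedLM);
    on non-convergence falls back to OLS with cluster-robust standard errors.
    """
    counts = series.groupby("participant").size()
    if (counts < 2).any():
        raise InsufficientDataError("every participant needs >= 2 draws")
    if len(counts) < 3:
        raise InsufficientDataError("need >= 3 participants with repeated draws")
    import statsmodels.api as sm

    exog = sm.add_constant(series["lead_time_years"].to_numpy())
    endog = series["log_ratio"].to_numpy()
    groups = series["participant"].to_numpy()
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(endog, exog, groups=groups)
            fit = model.fit(reml=True)
        if fit.converged:
            return RepeatedTrendResult(
                beta=float(fit.params[1]),
                se=float(fit.bse[1]),
                p=float(fit.pvalues[1]),
                sigma_u2=float(np.asarray(fit.cov_re)[0, 0]),
                sigma_e2=float(fit.scale),
                n_participants=int(len(counts)),
                n_obs=int(len(series)),
                method="mixed",
                converged=True,
            )
    except Exception:
        pass
    ols = sm.OLS(endog, exog).fit(cov_type="cluster", cov_kwds={"groups": groups})
    return RepeatedTrendResult(
        beta=float(ols.params[1]),
        se=float(ols.bse[1]),
        p=float(ols.pvalues[1]),
        sigma_u2=float("nan"),
        sigma_e2=float(ols.mse_resid),
        n_participants=int(len(counts)),
        n_obs=int(len(series)),
        method="ols_cluster",
        converged=False,
    )


def trend_table(
    normed: CountMatrix,
    manifest: pd.DataFrame,
    probe_subset: list[str],
    max_lead: float = DEFAULT_MAX_LEAD,
    pseudocount: float = 0.5,
) -> tuple[pd.DataFrame, dict]:
    """Per-probe trend fits plus fitted-line series for plotting.

    Probes are partitioned by slope sign (column ``pattern``: "rising" for
    negative slopes, i.e. the case-control contrast grows toward diagnosis;
    "falling" for positive slopes).  An empty subset yields an empty table.
    """
    if not probe_subset:
        return (
            pd.DataFrame(
                columns=[
                    "miRNA", "mean_log_ratio", "sd_log_ratio", "beta", "se",
                    "p", "n_pairs", "pattern",
                ]
            ),
            {},
        )
    ratios = pair_ratio_matrix(normed, manifest, pseudocount)
    lead = (
        manifest.drop_duplicates("pair_id")
        .set_index("pair_id")["lead_time_years"]
        .reindex(ratios.columns)
        .to_numpy(dtype=float)
    )
    rows, plot_data = [], {}
    grid = np.linspace(0.0, max_lead, 21)
    for pid in probe_subset:
        res = trend_fit(ratios.loc[pid].to_numpy(), lead, max_lead, probe_id=pid)
        intercept = res.mean_log_ratio - res.beta * float(
            np.mean(lead[lead <= max_lead])
        )
        rows.append(
            {
                "miRNA": pid,
                "mean_log_ratio": res.mean_log_ratio,
                "sd_log_ratio": res.sd_log_ratio,
                "beta": res.beta,
                "se": res.se,
                "p": res.p,
                "n_pairs": res.n_pairs,
                "pattern": "rising" if res.beta < 0 else "falling",
            }
        )
        plot_data[pid] = {
            "lead_time": grid.tolist(),
            "fitted_log_ratio": (intercept + res.beta * grid).tolist(),
        }
    return pd.DataFrame(rows), plot_data
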