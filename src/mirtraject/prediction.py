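"""Nested risk models and time-dependent AUC with bootstrap validation.

Four nested models are scored: Model 1 — age, BMI, smoking, diabetes,
family history; Model 2 — Model 1 + CA19-9; Model 3 — Model 1 + the
trend-significant miRNAs; Model 4 — everything.  Coefficients come from the
1:1 matched conditional likelihood (see :mod:`.association`); the risk score
of a sample is the linear predictor ``beta' x`` (rank-based AUC needs no
intercept).

AUC(t) uses the cumulative definition: restrict to pairs whose case has lead
time <= t, then compute the Mann-Whitney probability that a case score
exceeds a control score over all case x control combinations (ties 0.5).
Internal validation resamples pairs with replacement, refits on the in-bag
pairs and evaluates on the out-of-bag pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .association import (
    ADJUSTMENT_FEATURES,
    ClogitResult,
    clogit_fit,
    encode_covariates,
    pair_differences,
)
from .errors import ConfigurationError, EstimationError, InsufficientDataError
from .io import CountMatrix

MODEL_IDS = (1, 2, 3, 4)

CA199_CONTRIBUTION_DEFINITION = (
    "share of above-chance AUC attributable to CA19-9: "
    "(AUC_full(t) - AUC_without_ca199(t)) / (AUC_full(t) - 0.5), "
    "where the reduced model refits the full model without CA19-9"
)


def model_features(
    model_id: int, mirna_features: Sequence[str]
) -> list[str]:
    """Feature list of one of the four nested risk models."""
    if model_id not in MODEL_IDS:
        raise ConfigurationError(f"unknown model id {model_id!r}")
    base = list(ADJUSTMENT_FEATURES)
    if model_id == 1:
        return base
    if model_id == 2:
        return base + ["log_ca199"]
    if model_id == 3:
        return base + list(mirna_features)
    return base + ["log_ca199"] + list(mirna_features)


def build_feature_table(
    normed: CountMatrix,
    manifest: pd.DataFrame,
    mirnas: Sequence[str],
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-sample model features: covariates, log CA19-9, log miRNA levels."""
    features = encode_covariates(manifest)
    endo = normed.endogenous
    for pid in mirnas:
        features[pid] = np.log(
            endo.loc[pid, features.index].to_numpy(dtype=float) + pseudocount
        )
    return features


def fit_risk_score(
    features: pd.DataFrame,
    manifest: pd.DataFrame,
    feature_names: Sequence[str],
    pair_ids: Sequence[str] | None = None,
) -> tuple[pd.Series, ClogitResult]:
    """Conditional-logistic fit on pair differences -> per-sample score.

    ``pair_ids`` restricts the pairs used for fitting (the score is still
    computed for every sample in ``features``).  Missing feature values are
    not allowed.
    """
    sub = manifest if pair_ids is None else manifest[
        manifest["pair_id"].isin(set(pair_ids))
    ]
    cols = list(feature_names)
    block = features[cols]
    if block.isna().any().any():
        raise EstimationError("risk-model features contain missing values")
    diffs = pair_differences(sub, block)
    # features constant within every pair carry no conditional information;
    # drop them from the fit and give them a zero coefficient
    active = [c for c in cols if (diffs[c] != 0).any()]
    if not active:
        raise EstimationError("all features constant within pairs")
    fit = clogit_fit(diffs[active])
    beta = pd.Series(0.0, index=cols)
    beta[active] = fit.beta
    scores = pd.Series(
        block.to_numpy(dtype=float) @ beta.to_numpy(), index=features.index
    )
    return scores, fit


def mann_whitney_auc(case_scores: np.ndarray, control_scores: np.ndarray) -> float:
    """P(case score > control score) + 0.5 P(tie), over all combinations."""
    case_scores = np.asarray(case_scores, dtype=float)
    control_scores = np.asarray(control_scores, dtype=float)
    n1, n0 = case_scores.size, control_scores.size
    if n1 == 0 or n0 == 0:
        raise InsufficientDataError("AUC needs at least one case and one control")
    if n1 * n0 <= 10_000:
        greater = (case_scores[:, None] > control_scores[None, :]).sum()
        ties = (case_scores[:, None] == control_scores[None, :]).sum()
        return float((greater + 0.5 * ties) / (n1 * n0))
    # identical value via the rank-sum identity (average ranks handle ties)
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([case_scores, control_scores]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


@dataclass
class AUCPoint:
    model: int
    horizon: float
    auc: float
    ci_low: float
    ci_high: float
    n_case_pairs: int


def _eligible_pairs(manifest: pd.DataFrame, horizon: float) -> list[str]:
    pairs = manifest.drop_duplicates("pair_id")
    return list(
        pairs.loc[pairs["lead_time_years"].astype(float) <= horizon, "pair_id"]
    )


def time_dependent_auc(
    scores: pd.Series,
    manifest: pd.DataFrame,
    horizon: float,
    model: int = 0,
    pair_ids: Sequence[str] | None = None,
) -> AUCPoint:
    """Cumulative AUC at ``horizon`` years (cases with lead time <= horizon)."""
    if horizon <= 0:
        raise ConfigurationError("horizon must be > 0")
    sub = manifest if pair_ids is None else manifest[
        manifest["pair_id"].isin(set(pair_ids))
    ]
    eligible = set(_eligible_pairs(sub, horizon))
    if not eligible:
        raise InsufficientDataError(
            f"no case pairs with lead time <= {horizon}"
        )
    window = sub[sub["pair_id"].isin(eligible)]
    case_ids = window.loc[window["role"] == "case", "sample_id"]
    ctrl_ids = window.loc[window["role"] == "control", "sample_id"]
    auc = mann_whitney_auc(
        scores.loc[case_ids].to_numpy(), scores.loc[ctrl_ids].to_numpy()
    )
    return AUCPoint(
        model=model,
        horizon=float(horizon),
        auc=auc,
        ci_low=float("nan"),
        ci_high=float("nan"),
        n_case_pairs=len(eligible),
    )


def fit_all_models(
    features: pd.DataFrame,
    manifest: pd.DataFrame,
    mirnas: Sequence[str],
    models: Sequence[int] = MODEL_IDS,
    pair_ids: Sequence[str] | None = None,
) -> dict[int, tuple[pd.Series, ClogitResult]]:
    return {
        m: fit_risk_score(features, manifest, model_features(m, mirnas), pair_ids)
        for m in models
    }


def auc_curve(
    features: pd.DataFrame,
    manifest: pd.DataFrame,
    mirnas: Sequence[str],
    horizons: Sequence[float] = tuple(range(1, 11)),
    models: Sequence[int] = MODEL_IDS,
) -> pd.DataFrame:
    """Apparent AUC(t) grid: all models fitted on all pairs, one row per
    model per horizon."""
    fits = fit_all_models(features, manifest, mirnas, models)
    rows = []
    for m, (scores, fit) in fits.items():
        for t in horizons:
            try:
                point = time_dependent_auc(scores, manifest, t, model=m)
            except InsufficientDataError:
                continue
            rows.append(
                {
                    "model": m,
                    "horizon": point.horizon,
                    "auc": point.auc,
                    "ci_low": point.ci_low,
                    "ci_high": point.ci_high,
                    "n_case_pairs": point.n_case_pairs,
                    "converged": fit.converged,
                }
            )
    return pd.DataFrame(rows)


def bootstrap_validate(
    features: pd.DataFrame,
    manifest: pd.DataFrame,
    mirnas: Sequence[str],
    horizons: Sequence[float] = tuple(range(1, 11)),
    models: Sequence[int] = MODEL_IDS,
    n_boot: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Out-of-bag bootstrap AUC(t): mean and 2.5/97.5 percentile bands.

    The matched pair is the resampling unit.  Replicates whose out-of-bag
    set has no case pair within a horizon are skipped for that horizon (the
    replicate count per cell is reported).
    """
    if n_boot < 50:
        raise ConfigurationError("bootstrap needs B >= 50")
    rng = np.random.default_rng(seed)
    all_pairs = np.array(manifest["pair_id"].drop_duplicates())
    acc: dict[tuple[int, float], list[float]] = {
        (m, float(t)): [] for m in models for t in horizons
    }
    for _ in range(n_boot):
        in_bag = rng.choice(all_pairs, size=len(all_pairs), replace=True)
        oob = np.setdiff1d(all_pairs, in_bag)
        if len(oob) == 0:
            continue
        try:
            fits = fit_all_models(
                features, _resample_pairs(manifest, in_bag), mirnas, models,
                pair_ids=None,
            )
        except EstimationError:
            continue
        oob_manifest = manifest[manifest["pair_id"].isin(set(oob))]
        for m, (scores, _) in fits.items():
            for t in horizons:
                try:
                    point = time_dependent_auc(scores, oob_manifest, t, model=m)
                except InsufficientDataError:
                    continue
                acc[(m, float(t))].append(point.auc)
    rows = []
    for (m, t), values in acc.items():
        if not values:
            continue
        arr = np.asarray(values)
        rows.append(
            {
                "model": m,
                "horizon": t,
                "auc": float(arr.mean()),
                "ci_low": float(np.percentile(arr, 2.5)),
                "ci_high": float(np.percentile(arr, 97.5)),
                "n_replicates": len(arr),
            }
        )
    return pd.DataFrame(rows)


def _resample_pairs(manifest: pd.DataFrame, pair_draw: np.ndarray) -> pd.DataFrame:
    """In-bag manifest where a pair drawn k times appears k times."""
    blocks = []
    grouped = dict(tuple(manifest.groupby("pair_id", sort=False)))
    for i, pid in enumerate(pair_draw):
        block = grouped[pid].copy()
        # unique pair id per draw; sample ids stay, so feature lookup works
        block["pair_id"] = f"{pid}#b{i}"
        blocks.append(block)
    return pd.concat(blocks, ignore_index=True)


def ca199_contribution(
    features: pd.DataFrame,
    manifest: pd.DataFrame,
    mirnas: Sequence[str],
    horizon: float,
) -> dict:
    """Fraction of Model 4's above-chance AUC(t) attributable to CA19-9.

    Computed as ``(AUC4(t) - AUC4_without_ca199(t)) / (AUC4(t) - 0.5)``; the
    reduced model is Model 4 refitted without the CA19-9 feature.  Undefined
    (error) when the full model is at or below chance.
    """
    full_feats = model_features(4, mirnas)
    reduced_feats = [f for f in full_feats if f != "log_ca199"]
    scores_full, _ = fit_risk_score(features, manifest, full_feats)
    scores_red, _ = fit_risk_score(features, manifest, reduced_feats)
    auc_full = time_dependent_auc(scores_full, manifest, horizon).auc
    auc_red = time_dependent_auc(scores_red, manifest, horizon).auc
    if auc_full <= 0.5:
        raise EstimationError(
            f"full-model AUC({horizon}) = {auc_full:.3f} <= 0.5; "
            "contribution undefined"
        )
    fraction = (auc_full - auc_red) / (auc_full - 0.5)
    return {
        "fraction": float(fraction),
        "auc_full": float(auc_full),
        "auc_without_ca199": float(auc_red),
        "horizon": float(horizon),
        "definition": CA199_CONTRIBUTION_DEFINITION,
    }


def sensitivity_filters(manifest: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Pair-level restriction for sensitivity analyses.

    ``early_stage`` keeps pairs whose case stage is TNM I or IIA;
    ``min_lead_1y`` keeps pairs with lead time strictly greater than 1 year;
    ``none`` is the identity.  Pairs are removed atomically.
    """
    if mode == "none":
        return manifest.copy()
    if mode == "min_lead_1y":
        keep = set(
            manifest.loc[
                manifest["lead_time_years"].astype(float) > 1.0, "pair_id"
            ]
        )
        return manifest[manifest["pair_id"].isin(keep)].reset_index(drop=True)
    if mode == "early_stage":
        if "stage" not in manifest.columns:
            raise ConfigurationError(
                "early_stage filter requires a 'stage' manifest column"
            )
        cases = manifest[manifest["role"] == "case"]
        keep = set(cases.loc[cases["stage"].isin(["I", "IIA"]), "pair_id"])
        return manifest[manifest["pair_id"].isin(keep)].reset_index(drop=True)
    raise ConfigurationError(f"unknown sensitivity filter {mode!r}")
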