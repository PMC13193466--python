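"""Four-step normalization of nCounter-style miRNA counts.

Order is fixed: (1) background correction — subtract each sample's mean
negative-control count, floored at zero; (2) spike-in normalization — scale
each sample so its mean count over the three extraction spike-ins matches
the cross-sample geometric mean of those means; (3) content normalization —
the same construction on the geometric mean of the 50 most abundant
endogenous probes, excluding the three hemolysis markers; (4) quantile
normalization of the endogenous rows.  Steps record themselves in the
matrix's ``stages`` tag and may each be applied once.

Scale factors use a cross-sample geometric-mean reference, so rescaling one
sample's raw counts by ``c`` leaves every between-sample contrast (and every
case/control ratio) unchanged — all normalized values pick up only the common
constant ``c**(1/n)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import NormalizationError, StageError
from .io import CountMatrix, HEMOLYSIS_PROBES
from .simulate import SPIKE_NORMALIZATION_IDS


@dataclass
class NormalizationConfig:
    negative_count: int | None = None  # None = use all Negative probes
    spike_ids: tuple[str, ...] = SPIKE_NORMALIZATION_IDS
    content_set_size: int = 50
    hemolysis_exclusions: tuple[str, ...] = HEMOLYSIS_PROBES
    enable_quantile: bool = True


@dataclass
class NormalizationFactors:
    """Per-sample factor provenance for a pipeline run."""

    background: dict[str, float] = field(default_factory=dict)
    spike_factor: dict[str, float] = field(default_factory=dict)
    content_factor: dict[str, float] = field(default_factory=dict)
    content_probes: list[str] = field(default_factory=list)
    excluded_probes: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)


def _check_stage(matrix: CountMatrix, stage: str) -> None:
    if stage in matrix.stages:
        raise StageError(f"stage {stage!r} already applied: {matrix.stages}")


def background_correct(
    matrix: CountMatrix, negative_count: int | None = None
) -> tuple[CountMatrix, pd.Series]:
    """Subtract each sample's mean negative-control count, floored at 0.

    Applied to endogenous and spike-in rows; assay-control rows are retained
    unchanged (marked consumed by the stage tag).  ``negative_count`` limits
    how many Negative probes enter the mean (first N in panel order).
    """
    _check_stage(matrix, "background")
    neg_ids = matrix.ids_of("Negative")
    if not neg_ids:
        raise NormalizationError("no Negative probes present")
    if negative_count is not None:
        neg_ids = neg_ids[:negative_count]
    bg = matrix.values.loc[neg_ids].mean(axis=0)
    target = matrix.probe_class.isin(["Endogenous", "SpikeIn"]).to_numpy()
    values = matrix.values.copy()
    corrected = values.loc[target].sub(bg, axis=1).clip(lower=0.0)
    values.loc[target] = corrected
    return matrix.replace_values(values, "background"), bg


def spikein_normalize(
    matrix: CountMatrix, spike_ids=SPIKE_NORMALIZATION_IDS
) -> tuple[CountMatrix, pd.Series]:
    """Scale each sample by its mean spike-in count vs. the cohort reference.

    ``m_s`` is the arithmetic mean of the three spike-in counts in sample s;
    the factor is ``geomean_t(m_t) / m_s`` and multiplies the sample's
    endogenous and spike-in counts.
    """
    _check_stage(matrix, "spikein")
    missing = [s for s in spike_ids if s not in matrix.probe_ids]
    if missing:
        raise NormalizationError(f"spike-in probes missing: {missing}")
    m = matrix.values.loc[list(spike_ids)].mean(axis=0)
    if (m <= 0).any():
        bad = m.index[m <= 0][0]
        raise NormalizationError(
            f"sample {bad!r} has zero mean spike-in signal"
        )
    log_m = np.log(m)
    factors = np.exp(log_m.mean() - log_m)  # geomean(m) / m_s, exact at 1
    target = matrix.probe_class.isin(["Endogenous", "SpikeIn"]).to_numpy()
    values = matrix.values.copy()
    values.loc[target] = values.loc[target].mul(factors, axis=1)
    return matrix.replace_values(values, "spikein"), factors


def content_normalize(
    matrix: CountMatrix,
    content_set_size: int = 50,
    exclusions=HEMOLYSIS_PROBES,
) -> tuple[CountMatrix, pd.Series, list[str]]:
    """Scale samples by the geometric mean of the top expressed miRNAs.

    The content set is the ``content_set_size`` endogenous probes with the
    highest mean count across samples, excluding the hemolysis markers (the
    red-blood-cell trio would otherwise let a hemolysed sample drag its own
    factor).  Zeros are replaced by 0.5 inside the geometric mean only.
    """
    _check_stage(matrix, "content")
    endo = matrix.endogenous
    eligible = endo.drop(index=[p for p in exclusions if p in endo.index])
    if eligible.empty:
        raise NormalizationError("no endogenous probes available")
    size = min(content_set_size, len(eligible))
    content_ids = list(
        eligible.mean(axis=1).sort_values(ascending=False).index[:size]
    )
    content = eligible.loc[content_ids].to_numpy(dtype=float)
    if (content.max(axis=0) <= 0).any():
        s = endo.columns[content.max(axis=0) <= 0][0]
        raise NormalizationError(f"sample {s!r}: all content-set counts zero")
    log_g = np.log(np.where(content == 0.0, 0.5, content)).mean(axis=0)
    log_g = pd.Series(log_g, index=endo.columns)
    factors = np.exp(log_g.mean() - log_g)  # geomean(g) / g_s, exact at 1
    target = matrix.probe_class.isin(["Endogenous", "SpikeIn"]).to_numpy()
    values = matrix.values.copy()
    values.loc[target] = values.loc[target].mul(factors, axis=1)
    return matrix.replace_values(values, "content"), factors, content_ids


def quantile_normalize(matrix: CountMatrix) -> CountMatrix:
    """Rank-mean quantile normalization across samples (endogenous rows).

    Each sample's k-th order statistic is replaced by the across-sample mean
    of k-th order statistics; ties within a sample receive the mean of the
    reference values their ranks span.  With a single sample this is a no-op.
    """
    _check_stage(matrix, "quantile")
    endo = matrix.endogenous
    if endo.shape[1] < 2:
        import warnings

        warnings.warn("quantile normalization skipped: single sample")
        return matrix.replace_values(matrix.values, "quantile")
    data = endo.to_numpy(dtype=float)
    order = np.sort(data, axis=0)
    reference = order.mean(axis=1)  # mean k-th order statistic
    n = data.shape[0]
    out = np.empty_like(data)
    positions = np.arange(1, n + 1)
    for j in range(data.shape[1]):
        # average ranks so ties get the mean of the values they span
        ranks = pd.Series(data[:, j]).rank(method="average").to_numpy()
        out[:, j] = np.interp(ranks, positions, reference)
    values = matrix.values.copy()
    values.loc[endo.index] = out
    return matrix.replace_values(values, "quantile")


def normalize_pipeline(
    matrix: CountMatrix, config: NormalizationConfig | None = None
) -> tuple[CountMatrix, NormalizationFactors]:
    """background -> spike-in -> content (-> quantile), factors recorded."""
    config = config or NormalizationConfig()
    matrix, bg = background_correct(matrix, config.negative_count)
    matrix, spike = spikein_normalize(matrix, config.spike_ids)
    matrix, content, content_ids = content_normalize(
        matrix, config.content_set_size, config.hemolysis_exclusions
    )
    if config.enable_quantile:
        matrix = quantile_normalize(matrix)
    factors = NormalizationFactors(
        background=bg.to_dict(),
        spike_factor=spike.to_dict(),
        content_factor=content.to_dict(),
        content_probes=content_ids,
        excluded_probes=[
            p for p in config.hemolysis_exclusions if p in matrix.probe_ids
        ],
    )
    return matrix, factors
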