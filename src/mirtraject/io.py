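"""Count-matrix and manifest I/O for nCounter-style miRNA panels.

The central container is :class:`CountMatrix`: a probes x samples table of
non-negative values annotated with a probe class (Endogenous, Negative,
Positive, SpikeIn) and a ``stages`` tag recording which normalization steps
have been applied, in order.  Raw counts are integers; normalized values are
reals.  Alongside it live the sample manifest (one row per sample, pairs
linked by ``pair_id``), a reader for a minimal RCC dialect, matched-pair
validation, and per-sample QC flagging.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    FormatError,
    ParseError,
    ValidationError,
)

PROBE_CLASSES = ("Endogenous", "Negative", "Positive", "SpikeIn")

#: miRNAs abundant in red blood cells; excluded from content normalization.
HEMOLYSIS_PROBES = ("hsa-miR-451a", "hsa-miR-16-5p", "hsa-miR-320e")

MANIFEST_COLUMNS = (
    "sample_id",
    "pair_id",
    "cohort",
    "role",
    "sex",
    "race",
    "age_at_draw",
    "draw_date",
    "lead_time_years",
    "bmi",
    "smoking",
    "diabetes",
    "family_history",
    "ca199",
)


@dataclass(frozen=True)
class Probe:
    probe_id: str
    probe_class: str
    accession: str | None = None

    def __post_init__(self) -> None:
        if self.probe_class not in PROBE_CLASSES:
            raise ParseError(
                f"unknown probe_class {self.probe_class!r} for probe "
                f"{self.probe_id!r}; allowed: {PROBE_CLASSES}"
            )


class CountMatrix:
    """Probes x samples matrix with probe-class annotation and stage tags.

    Parameters
    ----------
    values
        DataFrame indexed by probe_id with one column per sample.
    probe_class
        Series mapping probe_id -> class (one of :data:`PROBE_CLASSES`).
    accession
        Optional Series mapping probe_id -> accession string.
    stages
        Normalization steps already applied, in order (append-only).
    """

    def __init__(
        self,
        values: pd.DataFrame,
        probe_class: pd.Series | Mapping[str, str],
        accession: pd.Series | Mapping[str, str] | None = None,
        stages: Sequence[str] = (),
    ) -> None:
        values = pd.DataFrame(values).astype(float)
        values.index.name = "probe_id"
        if values.index.duplicated().any():
            dup = values.index[values.index.duplicated()][0]
            raise ParseError(f"duplicate probe_id {dup!r}")
        probe_class = pd.Series(probe_class).reindex(values.index)
        if probe_class.isna().any():
            missing = probe_class.index[probe_class.isna()][0]
            raise ParseError(f"probe {missing!r} has no probe_class")
        bad = ~probe_class.isin(PROBE_CLASSES)
        if bad.any():
            pid = probe_class.index[bad][0]
            raise ParseError(
                f"unknown probe_class {probe_class[pid]!r} for probe {pid!r}"
            )
        if (values.to_numpy() < 0).any():
            raise ValidationError("count matrix contains negative entries")
        self.values = values
        self.probe_class = probe_class
        if accession is None:
            accession = pd.Series("", index=values.index)
        self.accession = pd.Series(accession).reindex(values.index).fillna("")
        self.stages: tuple[str, ...] = tuple(stages)

    # -- basic views ----------------------------------------------------
    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def ids_of(self, probe_class: str) -> list[str]:
        return list(self.values.index[self.probe_class == probe_class])

    @property
    def endogenous(self) -> pd.DataFrame:
        return self.values.loc[self.probe_class == "Endogenous"]

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(
            self.values[list(sample_ids)],
            self.probe_class,
            self.accession,
            self.stages,
        )

    def replace_values(
        self, values: pd.DataFrame, new_stage: str | None = None
    ) -> "CountMatrix":
        stages = self.stages + (new_stage,) if new_stage else self.stages
        return CountMatrix(values, self.probe_class, self.accession, stages)

    def copy(self) -> "CountMatrix":
        return CountMatrix(
            self.values.copy(), self.probe_class, self.accession, self.stages
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        n_p, n_s = self.shape
        return (
            f"CountMatrix({n_p} probes x {n_s} samples, "
            f"stages={list(self.stages)})"
        )


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------

def write_count_matrix(matrix: CountMatrix, path) -> None:
    """Write probes x samples CSV: probe_id, probe_class, accession, samples."""
    out = pd.DataFrame(
        {
            "probe_id": matrix.probe_ids,
            "probe_class": matrix.probe_class.to_numpy(),
            "accession": matrix.accession.to_numpy(),
        }
    )
    out = pd.concat([out, matrix.values.reset_index(drop=True)], axis=1)
    out.to_csv(path, index=False)


def read_count_matrix(path, panel: Iterable[Probe] | None = None) -> CountMatrix:
    """Read a counts CSV written by :func:`write_count_matrix`.

    If ``panel`` is given, the file's probes must match it exactly (same ids,
    same classes).
    """
    raw = pd.read_csv(path, dtype=str)
    for col in ("probe_id", "probe_class"):
        if col not in raw.columns:
            raise FormatError(f"counts file missing required column {col!r}")
    sample_cols = [
        c for c in raw.columns if c not in ("probe_id", "probe_class", "accession")
    ]
    if not sample_cols:
        raise FormatError("counts file has no sample columns")
    values = {}
    for col in sample_cols:
        parsed = pd.to_numeric(raw[col], errors="coerce")
        if parsed.isna().any():
            row = int(parsed.index[parsed.isna()][0])
            raise ParseError(
                f"non-numeric count at row {row} (probe "
                f"{raw['probe_id'].iloc[row]!r}), column {col!r}"
            )
        values[col] = parsed.to_numpy(dtype=float)
    frame = pd.DataFrame(values, index=raw["probe_id"])
    accession = (
        raw.set_index("probe_id")["accession"]
        if "accession" in raw.columns
        else None
    )
    matrix = CountMatrix(frame, raw.set_index("probe_id")["probe_class"], accession)
    if panel is not None:
        expected = {p.probe_id: p.probe_class for p in panel}
        got = dict(matrix.probe_class)
        if got != expected:
            raise ValidationError("counts file does not match the given panel")
    return matrix


# ---------------------------------------------------------------------------
# RCC-lite reader
# ---------------------------------------------------------------------------

_RCC_REQUIRED = ("Header", "Sample_Attributes", "Lane_Attributes", "Code_Summary")


def read_rcc(path) -> tuple[dict, pd.DataFrame]:
    """Parse a minimal RCC file into (attributes, per-probe count records).

    The dialect is bracketed sections of comma-separated lines::

        <Header> ... </Header>
        <Sample_Attributes> ... </Sample_Attributes>
        <Lane_Attributes> ... </Lane_Attributes>
        <Code_Summary>
        CodeClass,Name,Accession,Count
        ...
        </Code_Summary>

    Counts must be integers; ``Code_Summary`` must be present and non-empty.
    """
    sections: dict[str, list[str]] = {}
    current: str | None = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("</") and line.endswith(">"):
                current = None
            elif line.startswith("<") and line.endswith(">"):
                current = line[1:-1]
                sections[current] = []
            elif current is not None:
                sections[current].append(line)
    if "Code_Summary" not in sections:
        raise FormatError("RCC file has no Code_Summary section")
    attrs: dict[str, dict[str, str]] = {}
    for sec in ("Header", "Sample_Attributes", "Lane_Attributes"):
        attrs[sec] = {}
        for line in sections.get(sec, []):
            key, _, value = line.partition(",")
            attrs[sec][key] = value
    body = sections["Code_Summary"]
    if not body or body[0].split(",")[:2] != ["CodeClass", "Name"]:
        raise FormatError("RCC Code_Summary missing its header line")
    records = []
    for line in body[1:]:
        parts = line.split(",")
        if len(parts) != 4:
            raise ParseError(f"malformed Code_Summary line: {line!r}")
        code_class, name, accession, count = parts
        if code_class not in PROBE_CLASSES:
            raise ParseError(
                f"unknown probe_class {code_class!r} for probe {name!r}"
            )
        try:
            count_value = int(count)
        except ValueError:
            raise ParseError(
                f"non-integer count {count!r} for probe {name!r}"
            ) from None
        records.append(
            {
                "probe_class": code_class,
                "probe_id": name,
                "accession": accession,
                "count": count_value,
            }
        )
    if not records:
        raise FormatError("RCC Code_Summary section is empty")
    return attrs, pd.DataFrame(records)


# ---------------------------------------------------------------------------
# Manifest handling
# ---------------------------------------------------------------------------

def read_manifest(path) -> pd.DataFrame:
    manifest = pd.read_csv(path, dtype={"sample_id": str, "pair_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise FormatError(f"manifest missing columns: {missing}")
    return manifest


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, index=False)


def validate_pairs(
    manifest: pd.DataFrame,
    age_tolerance: float = 2.0,
    date_tolerance_days: float = 90.0,
    strict: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Check the 1:1 matched structure of a manifest.

    Every ``pair_id`` must map to exactly one case and one control sharing
    cohort, sex and race, with ages within ``age_tolerance`` years and draw
    dates within ``date_tolerance_days`` days.  Returns ``(manifest,
    violations)`` where violations has columns pair_id/criterion/detail.
    In strict mode structural violations (orphans, duplicated roles) raise
    :class:`ValidationError`; matching-tolerance violations raise too.  In
    lenient mode all violations are only reported.
    """
    violations: list[dict] = []
    for pair_id, group in manifest.groupby("pair_id", sort=False):
        roles = sorted(group["role"])
        if roles != ["case", "control"]:
            violations.append(
                {
                    "pair_id": pair_id,
                    "criterion": "structure",
                    "detail": f"roles {roles} (need exactly one case, one control)",
                }
            )
            continue
        case = group[group["role"] == "case"].iloc[0]
        control = group[group["role"] == "control"].iloc[0]
        for col in ("cohort", "sex", "race"):
            if case[col] != control[col]:
                violations.append(
                    {
                        "pair_id": pair_id,
                        "criterion": col,
                        "detail": f"{case[col]!r} vs {control[col]!r}",
                    }
                )
        age_gap = abs(float(case["age_at_draw"]) - float(control["age_at_draw"]))
        if age_gap > age_tolerance:
            violations.append(
                {"pair_id": pair_id, "criterion": "age", "detail": f"gap {age_gap:.2f}y"}
            )
        gap_days = abs(
            (pd.Timestamp(case["draw_date"]) - pd.Timestamp(control["draw_date"])).days
        )
        if gap_days > date_tolerance_days:
            violations.append(
                {
                    "pair_id": pair_id,
                    "criterion": "draw_date",
                    "detail": f"gap {gap_days}d",
                }
            )
    frame = pd.DataFrame(violations, columns=["pair_id", "criterion", "detail"])
    if strict and len(frame):
        raise ValidationError(
            f"{len(frame)} pair-matching violation(s); first: "
            f"{frame.iloc[0].to_dict()}"
        )
    return manifest, frame


def drop_pairs(manifest: pd.DataFrame, pair_ids: Iterable[str]) -> pd.DataFrame:
    """Remove whole pairs (matched design cannot use singleton samples)."""
    drop = set(pair_ids)
    return manifest[~manifest["pair_id"].isin(drop)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Sample QC
# ---------------------------------------------------------------------------

@dataclass
class QCThresholds:
    """nCounter-convention QC cutoffs; ``None`` disables a flag."""

    min_fov_ratio: float | None = 0.75
    min_binding_density: float | None = 0.1
    max_binding_density: float | None = 2.25
    min_positive_r2: float | None = 0.95
    require_lod: bool = True
    #: nominal positive-control amounts (fM) used for the linearity fit
    positive_nominal: Mapping[str, float] = field(
        default_factory=lambda: {
            "POS_A": 128.0,
            "POS_B": 32.0,
            "POS_C": 8.0,
            "POS_D": 2.0,
            "POS_E": 0.5,
            "POS_F": 0.125,
        }
    )
    #: positive probe compared against the negative-control LOD
    lod_probe: str = "POS_E"


@dataclass
class QCReport:
    flags: pd.DataFrame  # samples x flag columns (True = pass)
    passed: pd.Series  # overall per-sample pass

    @property
    def failed_samples(self) -> list[str]:
        return list(self.passed.index[~self.passed])

    def to_json(self, path) -> None:
        payload = {
            "flags": {
                s: {k: bool(v) for k, v in row.items()}
                for s, row in self.flags.to_dict("index").items()
            },
            "passed": {s: bool(v) for s, v in self.passed.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def qc_sample(
    matrix: CountMatrix,
    thresholds: QCThresholds | None = None,
    attributes: pd.DataFrame | None = None,
) -> QCReport:
    """Flag samples against imaging and control-probe QC thresholds.

    Imaging metrics (field-of-view ratio, binding density) cannot be derived
    from counts; they are evaluated only when ``attributes`` provides
    ``fov_ratio`` / ``binding_density`` columns indexed by sample.  Count
    metrics — positive-control log-linearity R^2 and limit-of-detection
    (the ``lod_probe`` count exceeding mean + 2 SD of negatives) — always run
    when enabled.  A sample fails iff at least one enabled flag fails.
    """
    thresholds = thresholds or QCThresholds()
    neg_ids = matrix.ids_of("Negative")
    pos_ids = matrix.ids_of("Positive")
    if not neg_ids or not pos_ids:
        raise ConfigurationError("QC requires both Negative and Positive probes")
    flags: dict[str, dict[str, bool]] = {s: {} for s in matrix.sample_ids}

    if attributes is not None:
        attributes = attributes.reindex(matrix.sample_ids)
        if thresholds.min_fov_ratio is not None and "fov_ratio" in attributes:
            for s in matrix.sample_ids:
                flags[s]["fov_ratio"] = bool(
                    attributes.loc[s, "fov_ratio"] >= thresholds.min_fov_ratio
                )
        if "binding_density" in attributes and (
            thresholds.min_binding_density is not None
            or thresholds.max_binding_density is not None
        ):
            lo = thresholds.min_binding_density or -math.inf
            hi = thresholds.max_binding_density or math.inf
            for s in matrix.sample_ids:
                bd = attributes.loc[s, "binding_density"]
                flags[s]["binding_density"] = bool(lo <= bd <= hi)

    pos_counts = matrix.values.loc[pos_ids]
    neg_counts = matrix.values.loc[neg_ids]
    nominal = pd.Series(thresholds.positive_nominal).reindex(pos_ids)
    if thresholds.min_positive_r2 is not None and nominal.notna().all():
        log_nom = np.log2(nominal.to_numpy(dtype=float))
        for s in matrix.sample_ids:
            log_obs = np.log2(pos_counts[s].to_numpy(dtype=float) + 1.0)
            r = np.corrcoef(log_nom, log_obs)[0, 1]
            flags[s]["positive_linearity"] = bool(r * r >= thresholds.min_positive_r2)
    if thresholds.require_lod and thresholds.lod_probe in matrix.probe_ids:
        lod = neg_counts.mean(axis=0) + 2.0 * neg_counts.std(axis=0, ddof=1)
        for s in matrix.sample_ids:
            flags[s]["lod"] = bool(
                matrix.values.loc[thresholds.lod_probe, s] > lod[s]
            )

    frame = pd.DataFrame.from_dict(flags, orient="index")
    if frame.empty or frame.shape[1] == 0:
        frame = pd.DataFrame(index=matrix.sample_ids)
        passed = pd.Series(True, index=matrix.sample_ids)
    else:
        passed = frame.fillna(True).all(axis=1)
    return QCReport(flags=frame, passed=passed)


def apply_qc(
    matrix: CountMatrix, manifest: pd.DataFrame, report: QCReport
) -> tuple[CountMatrix, pd.DataFrame]:
    """Drop every pair containing a QC-failed sample, atomically."""
    failed = set(report.failed_samples)
    bad_pairs = set(
        manifest.loc[manifest["sample_id"].isin(failed), "pair_id"]
    )
    kept = drop_pairs(manifest, bad_pairs)
    return matrix.subset_samples(list(kept["sample_id"])), kept
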