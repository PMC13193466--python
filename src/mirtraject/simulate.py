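"""Synthetic matched-cohort generator for pre-diagnostic miRNA counts.

Emulates a nested case-control resource: 1:1 matched pairs drawn from several
prospective cohorts, each sample carrying an nCounter-style probe panel (798
endogenous miRNAs plus negative/positive assay controls and non-mammalian
spike-ins), covariates with cohort-specific prevalences, CA19-9, and a
lead-time distribution per cohort.

The count model for endogenous probe ``k`` in sample ``s`` is

    count_ks ~ Poisson( b_s + e_s * exp(mu_k + Delta_ks + eps_ks) )

with per-sample background ``b_s``, extraction efficiency
``e_s = exp(N(0, efficiency_sd))``, probe baseline ``mu_k``, measurement
noise ``eps_ks ~ N(0, noise_sd)``, and a case-only signal

    Delta_ks = a_k + b_k * min(T_i, 10)

for the trajectory-panel probes, where ``T_i`` is the pair's lead time in
years (the case-control contrast is linear in lead time up to 10 years and
held constant beyond).  With ``a_k > 0, b_k < 0`` (oncogenic) the
case/control ratio rises as diagnosis approaches; with ``a_k < 0, b_k > 0``
(suppressor) it falls — the "scissors" pattern.  Spike-in counts scale with
``e_s`` only; negative controls are pure background; a Bernoulli hemolysis
event multiplies the counts of the three red-blood-cell miRNAs by a
log-normal factor > 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .io import CountMatrix, HEMOLYSIS_PROBES

# ---------------------------------------------------------------------------
# Panel constants
# ---------------------------------------------------------------------------

SPIKE_NOMINAL = {
    "ath-miR159a": 2000.0,
    "cel-miR248": 500.0,
    "cel-miR254": 800.0,
    "osa-miR414": 1000.0,
    "osa-miR442": 300.0,
}
#: the three spike-ins added at extraction and used for normalization
SPIKE_NORMALIZATION_IDS = ("ath-miR159a", "cel-miR248", "osa-miR414")

POSITIVE_NOMINAL = {
    "POS_A": 128.0,
    "POS_B": 32.0,
    "POS_C": 8.0,
    "POS_D": 2.0,
    "POS_E": 0.5,
    "POS_F": 0.125,
}
NEGATIVE_IDS = tuple(f"NEG_{c}" for c in "ABCDEFGH")
POSITIVE_COUNT_SCALE = 40.0  # counts per fM of positive-control target

#: MIMAT accessions for the named endogenous probes
ACCESSIONS = {
    "hsa-let-7g-5p": "MIMAT0000414",
    "hsa-let-7i-5p": "MIMAT0000415",
    "hsa-miR-15b-5p": "MIMAT0000417",
    "hsa-miR-93-5p": "MIMAT0000093",
    "hsa-miR-106a-5p+hsa-miR-17-5p": "MIMAT0000103",
    "hsa-miR-106b-5p": "MIMAT0000680",
    "hsa-miR-155-5p": "MIMAT0000646",
    "hsa-miR-181a-5p": "MIMAT0000256",
    "hsa-miR-191-5p": "MIMAT0000440",
    "hsa-miR-199a-3p+hsa-miR-199b-3p": "MIMAT0000232",
    "hsa-miR-223-3p": "MIMAT0000280",
    "hsa-miR-340-5p": "MIMAT0004692",
    "hsa-miR-493-3p": "MIMAT0003161",
    "hsa-miR-451a": "MIMAT0001631",
    "hsa-miR-16-5p": "MIMAT0000069",
    "hsa-miR-320e": "MIMAT0015072",
}


# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LeadTimeLaw:
    """Distribution of years from blood draw to the case's diagnosis.

    Families: ``gamma`` (params shape, scale), ``uniform`` (low, high),
    ``fixed`` (value).  Draws are truncated to ``support`` by rejection.
    """

    family: str = "gamma"
    params: Mapping[str, float] = field(default_factory=dict)
    support: tuple[float, float] = (0.03, 19.61)

    def __post_init__(self) -> None:
        if self.family not in ("gamma", "uniform", "fixed"):
            raise ConfigurationError(
                f"unsupported lead-time family {self.family!r}"
            )
        lo, hi = self.support
        if lo <= 0 or hi <= lo:
            raise ConfigurationError("lead-time support must be positive")


@dataclass(frozen=True)
class TrajectoryParam:
    """Case-control log-contrast for one probe: Delta(T) = a + b*min(T, 10).

    ``noise_sd`` is the probe's per-sample log-scale biological+measurement
    SD (``None`` falls back to the generator default); the pair log-ratio SD
    is sqrt(2) times it.
    """

    probe_id: str
    role: str  # oncogenic | suppressor | null
    intercept: float = 0.0  # a_k: log-scale difference at lead time 0
    slope: float = 0.0  # b_k: change in log(ratio) per year of lead time
    noise_sd: float | None = None

    def __post_init__(self) -> None:
        if self.role not in ("oncogenic", "suppressor", "null"):
            raise ConfigurationError(f"unknown trajectory role {self.role!r}")
        is_zero = self.intercept == 0.0 and self.slope == 0.0
        if (self.role == "null") != is_zero:
            raise ConfigurationError(
                f"{self.probe_id}: role 'null' iff intercept == slope == 0"
            )


@dataclass(frozen=True)
class CohortSpec:
    n_pairs: int
    lead_time_law: LeadTimeLaw
    age_mean: float
    age_sd: float
    female_frac: float
    race_probs: Mapping[str, float]
    bmi_mean: float
    bmi_sd: float
    smoking_probs: tuple[float, float, float]  # never, former, current
    diabetes_prev: float
    family_history_prev: float
    enroll_years: tuple[int, int]


@dataclass(frozen=True)
class CA199Params:
    """Log-normal CA19-9 stand-in; cases get a shift that fades with lead time.

    The case shift on the log scale is ``gamma * max(0, 1 - lead_time/tau)``:
    full amplitude at diagnosis, zero once lead time reaches ``tau`` years.
    Arbitrary calibration (U/mL-like); no assay is being reproduced.
    """

    log_mean: float = 2.3
    log_sd: float = 0.8
    gamma: float = 2.0
    tau: float = 5.0


def _table3_defaults() -> list[TrajectoryParam]:
    # (mean log-ratio over the 0-10y window, its SD, slope per year).  The
    # intercept is set so the simulated window mean matches (mean truncated
    # lead ~5y); the per-sample noise SD is the ratio SD over sqrt(2).
    rows = {
        "hsa-miR-155-5p": (0.10918, 2.00819, -0.06326, "oncogenic"),
        "hsa-miR-493-3p": (0.19100, 2.70659, -0.06726, "oncogenic"),
        "hsa-let-7g-5p": (-0.18967, 2.58012, 0.06671, "suppressor"),
        "hsa-let-7i-5p": (-0.19328, 1.43214, 0.05073, "suppressor"),
        "hsa-miR-15b-5p": (-0.12071, 2.84524, 0.07010, "suppressor"),
        "hsa-miR-93-5p": (-0.22180, 2.83169, 0.06859, "suppressor"),
        "hsa-miR-106a-5p+hsa-miR-17-5p": (-0.20257, 2.79543, 0.07356, "suppressor"),
        "hsa-miR-106b-5p": (-0.10502, 3.07616, 0.08960, "suppressor"),
        "hsa-miR-181a-5p": (-0.16192, 3.16183, 0.09358, "suppressor"),
        "hsa-miR-191-5p": (-0.37669, 2.81328, 0.08622, "suppressor"),
        "hsa-miR-199a-3p+hsa-miR-199b-3p": (-0.10454, 1.26999, 0.02939, "suppressor"),
        "hsa-miR-223-3p": (-0.18569, 2.23051, 0.06275, "suppressor"),
        "hsa-miR-340-5p": (-0.12536, 2.65253, 0.10080, "suppressor"),
    }
    return [
        TrajectoryParam(
            pid,
            role,
            round(mean - 5.0 * slope, 5),
            slope,
            round(sd / float(np.sqrt(2.0)), 5),
        )
        for pid, (mean, sd, slope, role) in rows.items()
    ]


def default_trajectory_panel() -> list[TrajectoryParam]:
    """Default scissors panel: 2 oncogenic + 11 suppressor probes."""
    return _table3_defaults()


def null_panel() -> list[TrajectoryParam]:
    """The default panel's probes with all effects zeroed (null generator)."""
    return [
        TrajectoryParam(p.probe_id, "null", 0.0, 0.0, p.noise_sd)
        for p in _table3_defaults()
    ]


def default_cohorts(scale: float = 1.0) -> dict[str, CohortSpec]:
    """Four cohort strata sized 290/395/154/468 pairs (scaled by ``scale``).

    Lead-time gamma laws are tuned so their medians are ~3.7, ~9.4, ~6.5 and
    ~8.2 years; covariate prevalences follow the control arms of a typical
    multi-cohort pancreatic-cancer resource.
    """

    def n(x: int) -> int:
        return max(1, int(round(x * scale)))

    return {
        "PLCO": CohortSpec(
            n_pairs=n(290),
            lead_time_law=LeadTimeLaw("gamma", {"shape": 1.370, "scale": 3.507}),
            age_mean=67.8, age_sd=5.3, female_frac=0.42,
            race_probs={"White": 0.89, "Black": 0.03, "Other": 0.08},
            bmi_mean=26.7, bmi_sd=3.9,
            smoking_probs=(0.53, 0.40, 0.07),
            diabetes_prev=0.05, family_history_prev=0.024,
            enroll_years=(1994, 2001),
        ),
        "SWHS/SMHS": CohortSpec(
            n_pairs=n(395),
            lead_time_law=LeadTimeLaw("gamma", {"shape": 5.089, "scale": 1.975}),
            age_mean=60.8, age_sd=8.9, female_frac=0.52,
            race_probs={"Asian": 1.0},
            bmi_mean=24.2, bmi_sd=3.4,
            smoking_probs=(0.71, 0.06, 0.23),
            diabetes_prev=0.06, family_history_prev=0.015,
            enroll_years=(1997, 2006),
        ),
        "SCCS": CohortSpec(
            n_pairs=n(154),
            lead_time_law=LeadTimeLaw("gamma", {"shape": 2.413, "scale": 3.112}),
            age_mean=56.0, age_sd=9.8, female_frac=0.48,
            race_probs={"White": 0.23, "Black": 0.74, "Other": 0.03},
            bmi_mean=29.7, bmi_sd=6.9,
            smoking_probs=(0.34, 0.27, 0.39),
            diabetes_prev=0.22, family_history_prev=0.005,
            enroll_years=(2002, 2009),
        ),
        "MEC": CohortSpec(
            n_pairs=n(468),
            lead_time_law=LeadTimeLaw("gamma", {"shape": 3.455, "scale": 2.621}),
            age_mean=69.2, age_sd=8.0, female_frac=0.54,
            race_probs={"White": 0.15, "Black": 0.19, "Asian": 0.37, "Other": 0.29},
            bmi_mean=26.5, bmi_sd=4.9,
            smoking_probs=(0.52, 0.39, 0.09),
            diabetes_prev=0.07, family_history_prev=0.013,
            enroll_years=(2001, 2006),
        ),
    }


@dataclass
class GeneratorConfig:
    cohorts: dict[str, CohortSpec] = field(default_factory=default_cohorts)
    n_probes: int = 798
    panel: Sequence[TrajectoryParam] = field(
        default_factory=default_trajectory_panel
    )
    #: case-enrichment odds multipliers echoing cohort imbalances
    smoking_case_or: float = 2.5
    diabetes_case_or: float = 2.2
    hemolysis_prob: float = 0.03
    hemolysis_log_factor_mean: float = float(np.log(8.0))
    hemolysis_log_factor_sd: float = 0.3
    background_rate: float = 8.0
    #: SD of log extraction efficiency; 0.5 gives the several-fold
    #: sample-to-sample RNA yield variation typical of plasma extractions
    efficiency_sd: float = 0.5
    #: biological+measurement log-SD of endogenous probes (pair log-ratio SD
    #: is sqrt(2) times this); signal probes may override per probe
    noise_sd: float = 1.2
    #: technical log-SD of spike-in probes (added at extraction, so they see
    #: no biological variance)
    spike_noise_sd: float = 0.15
    baseline_log_mean: float = 4.0
    baseline_log_sd: float = 1.5
    #: baseline for trajectory-panel probes; kept at the filler level so that
    #: their lognormal means stay below the top-50 content-set cutoff and the
    #: case-control contrast cannot leak into the content factors
    signal_log_mean: float = 4.0
    signal_log_sd: float = 0.3
    hemolysis_probe_log_mean: float = 7.5
    ca199: CA199Params = field(default_factory=CA199Params)
    stage_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "I": 0.12, "IIA": 0.10, "IIB": 0.28, "III": 0.25, "IV": 0.25
        }
    )
    seed: int = 0

    @classmethod
    def from_dict(cls, spec: Mapping | None, seed: int = 0) -> "GeneratorConfig":
        """Build a config from a (YAML-derived) mapping.

        Recognized keys: ``scale`` (shrink default cohort sizes),
        ``n_pairs_per_cohort`` (mapping cohort -> pairs), ``n_probes``,
        ``panel`` ("default", "null", or a list of trajectory dicts),
        ``hemolysis_prob``, ``background_rate``, ``efficiency_sd``,
        ``noise_sd``, ``ca199`` (mapping of CA199Params fields), ``seed``.
        """
        spec = dict(spec or {})
        cohorts = default_cohorts(float(spec.pop("scale", 1.0)))
        n_override = spec.pop("n_pairs_per_cohort", None)
        if n_override:
            from dataclasses import replace

            cohorts = {
                name: replace(c, n_pairs=int(n_override.get(name, c.n_pairs)))
                for name, c in cohorts.items()
            }
        panel_spec = spec.pop("panel", "default")
        if panel_spec == "default":
            panel = default_trajectory_panel()
        elif panel_spec == "null":
            panel = null_panel()
        else:
            panel = [TrajectoryParam(**p) for p in panel_spec]
        ca199 = CA199Params(**spec.pop("ca199", {}))
        seed = int(spec.pop("seed", seed))
        return cls(
            cohorts=cohorts, panel=panel, ca199=ca199, seed=seed, **spec
        )

    def validate(self) -> None:
        if not self.cohorts:
            raise ConfigurationError("at least one cohort required")
        for name, spec in self.cohorts.items():
            if spec.n_pairs <= 0:
                raise ConfigurationError(f"cohort {name!r}: n_pairs must be > 0")
            for p in (
                spec.female_frac, spec.diabetes_prev, spec.family_history_prev,
                *spec.smoking_probs, *spec.race_probs.values(),
            ):
                if not 0.0 <= p <= 1.0:
                    raise ConfigurationError(
                        f"cohort {name!r}: probability {p} outside [0, 1]"
                    )
        if self.panel is None or len(self.panel) == 0:
            raise ConfigurationError(
                "trajectory panel must be non-empty (use null probes for a "
                "no-effect panel)"
            )
        named = [p.probe_id for p in self.panel]
        if len(set(named)) != len(named):
            raise ConfigurationError("duplicate probe in trajectory panel")
        needed = len(set(named) | set(HEMOLYSIS_PROBES))
        if self.n_probes < needed:
            raise ConfigurationError(
                f"n_probes={self.n_probes} cannot hold {needed} named probes"
            )
        for sd in (
            self.efficiency_sd, self.noise_sd, self.baseline_log_sd,
            self.hemolysis_log_factor_sd, self.ca199.log_sd,
        ):
            if sd < 0:
                raise ConfigurationError("standard deviations must be >= 0")
        if not 0.0 <= self.hemolysis_prob <= 1.0:
            raise ConfigurationError("hemolysis_prob outside [0, 1]")


@dataclass
class TruthRecord:
    """Everything needed to recompute expected counts up to the noise model."""

    efficiency: dict[str, float]  # sample -> e_s
    background: dict[str, float]  # sample -> b_s
    hemolysis_factor: dict[str, float]  # sample -> factor (1.0 = none)
    mu: dict[str, float]  # endogenous probe -> baseline log-expression
    panel: list[TrajectoryParam]
    ca199_shift: dict[str, float]  # pair -> true log-scale case shift

    def to_json(self, path) -> None:
        payload = asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path) as fh:
            payload = json.load(fh)
        payload["panel"] = [TrajectoryParam(**p) for p in payload["panel"]]
        return cls(**payload)


# ---------------------------------------------------------------------------
# Elementary draws
# ---------------------------------------------------------------------------

def sample_lead_time(
    law: LeadTimeLaw, rng: np.random.Generator, size: int | None = None
) -> float | np.ndarray:
    """Draw lead times from ``law``, truncated to its support by rejection."""
    n = 1 if size is None else size
    lo, hi = law.support
    if law.family == "fixed":
        out = np.full(n, float(law.params["value"]))
    else:
        if law.family == "gamma":
            draw = lambda m: rng.gamma(law.params["shape"], law.params["scale"], m)
        else:  # uniform
            draw = lambda m: rng.uniform(law.params["low"], law.params["high"], m)
        out = np.empty(n)
        filled = 0
        while filled < n:
            cand = draw(max(n - filled, 16))
            cand = cand[(cand >= lo) & (cand <= hi)]
            take = min(len(cand), n - filled)
            out[filled : filled + take] = cand[:take]
            filled += take
    if np.any((out < lo) | (out > hi)):  # fixed law outside support
        raise ConfigurationError("lead-time law puts mass outside its support")
    return float(out[0]) if size is None else out


def simulate_ca199(
    is_case: bool,
    lead_time: float,
    params: CA199Params,
    rng: np.random.Generator,
) -> float:
    """Log-normal CA19-9 draw; the case shift decays linearly to 0 at tau."""
    shift = ca199_case_shift(lead_time, params) if is_case else 0.0
    return float(np.exp(rng.normal(params.log_mean + shift, params.log_sd)))


def ca199_case_shift(lead_time: float, params: CA199Params) -> float:
    return params.gamma * max(0.0, 1.0 - lead_time / params.tau)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _case_probs(base: Sequence[float], odds_multipliers: Sequence[float]):
    odds = np.asarray(base, dtype=float) * np.asarray(odds_multipliers)
    return odds / odds.sum()


def _enrich(prev: float, odds_ratio: float) -> float:
    return prev * odds_ratio / (1.0 - prev + prev * odds_ratio)


def build_panel(config: GeneratorConfig) -> tuple[list[str], dict[str, str]]:
    """Endogenous probe id list (length n_probes) and accession map.

    Named signal probes come first, then the hemolysis trio, then simulated
    filler probes.
    """
    names = [p.probe_id for p in config.panel]
    for probe in HEMOLYSIS_PROBES:
        if probe not in names:
            names.append(probe)
    filler = config.n_probes - len(names)
    names += [f"hsa-miR-sim-{i:04d}" for i in range(1, filler + 1)]
    accession = {n: ACCESSIONS.get(n, "") for n in names}
    return names, accession


def generate_cohort(
    config: GeneratorConfig | None = None,
) -> tuple[pd.DataFrame, CountMatrix, TruthRecord]:
    """Generate (manifest, raw CountMatrix, TruthRecord) for a full cohort set.

    Deterministic given ``config.seed``.  See the module docstring for the
    count model.
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    endo_ids, accession_map = build_panel(config)
    signal = {p.probe_id: p for p in config.panel if p.role != "null"}

    # --- per-probe baselines -----------------------------------------------
    mu = {}
    for pid in endo_ids:
        if pid in HEMOLYSIS_PROBES:
            mu[pid] = rng.normal(config.hemolysis_probe_log_mean, 0.2)
        elif pid in signal:
            mu[pid] = rng.normal(config.signal_log_mean, config.signal_log_sd)
        else:
            mu[pid] = rng.normal(config.baseline_log_mean, config.baseline_log_sd)

    # --- manifest -----------------------------------------------------------
    rows: list[dict] = []
    pair_lead: dict[str, float] = {}
    pair_cohort: dict[str, str] = {}
    stages = list(config.stage_probs)
    stage_p = np.array([config.stage_probs[s] for s in stages], dtype=float)
    stage_p = stage_p / stage_p.sum()
    for cohort, spec in config.cohorts.items():
        tag = cohort.replace("/", "-")
        lead = sample_lead_time(spec.lead_time_law, rng, spec.n_pairs)
        races = list(spec.race_probs)
        race_p = np.array([spec.race_probs[r] for r in races], dtype=float)
        race_p = race_p / race_p.sum()
        smoke_case_p = _case_probs(
            spec.smoking_probs, (1.0, 1.0, config.smoking_case_or)
        )
        diab_case = _enrich(spec.diabetes_prev, config.diabetes_case_or)
        y0, y1 = spec.enroll_years
        start = pd.Timestamp(f"{y0}-01-01")
        span_days = (pd.Timestamp(f"{y1}-12-31") - start).days
        for i in range(spec.n_pairs):
            pair_id = f"{tag}-{i + 1:04d}"
            t = float(lead[i])
            pair_lead[pair_id] = t
            pair_cohort[pair_id] = cohort
            sex = "F" if rng.random() < spec.female_frac else "M"
            race = races[int(rng.choice(len(races), p=race_p))]
            case_age = float(np.clip(rng.normal(spec.age_mean, spec.age_sd), 40, 85))
            ctrl_age = case_age + rng.uniform(-2.0, 2.0)
            case_date = start + pd.Timedelta(days=int(rng.integers(0, span_days + 1)))
            ctrl_date = case_date + pd.Timedelta(days=int(rng.integers(-90, 91)))
            stage = stages[int(rng.choice(len(stages), p=stage_p))]
            for role in ("case", "control"):
                is_case = role == "case"
                smoke_p = smoke_case_p if is_case else np.asarray(spec.smoking_probs)
                smoking = ("never", "former", "current")[
                    int(rng.choice(3, p=smoke_p / smoke_p.sum()))
                ]
                diabetes = int(
                    rng.random() < (diab_case if is_case else spec.diabetes_prev)
                )
                famhist = int(rng.random() < spec.family_history_prev)
                bmi = float(np.clip(rng.normal(spec.bmi_mean, spec.bmi_sd), 15, 55))
                rows.append(
                    {
                        "sample_id": f"{pair_id}-{role}",
                        "pair_id": pair_id,
                        "cohort": cohort,
                        "role": role,
                        "sex": sex,
                        "race": race,
                        "age_at_draw": round(case_age if is_case else ctrl_age, 2),
                        "draw_date": (case_date if is_case else ctrl_date).date().isoformat(),
                        "lead_time_years": round(t, 4),
                        "bmi": round(bmi, 2),
                        "smoking": smoking,
                        "diabetes": diabetes,
                        "family_history": famhist,
                        "ca199": round(
                            simulate_ca199(is_case, t, config.ca199, rng), 3
                        ),
                        "stage": stage if is_case else "",
                    }
                )
    manifest = pd.DataFrame(rows)
    sample_ids = list(manifest["sample_id"])
    n_samples = len(sample_ids)
    is_case_arr = (manifest["role"] == "case").to_numpy()
    lead_arr = manifest["lead_time_years"].to_numpy(dtype=float)

    # --- per-sample technical factors --------------------------------------
    efficiency = np.exp(rng.normal(0.0, config.efficiency_sd, n_samples))
    background = config.background_rate * np.exp(rng.normal(0.0, 0.1, n_samples))
    hemolysed = rng.random(n_samples) < config.hemolysis_prob
    hemo_factor = np.ones(n_samples)
    hemo_factor[hemolysed] = np.exp(
        rng.normal(
            config.hemolysis_log_factor_mean,
            config.hemolysis_log_factor_sd,
            int(hemolysed.sum()),
        )
    )

    # --- endogenous counts ---------------------------------------------------
    mu_vec = np.array([mu[p] for p in endo_ids])
    delta = np.zeros((len(endo_ids), n_samples))
    for r, pid in enumerate(endo_ids):
        par = signal.get(pid)
        if par is not None:
            delta[r, is_case_arr] = par.intercept + par.slope * np.minimum(
                lead_arr[is_case_arr], 10.0
            )
    panel_by_id = {p.probe_id: p for p in config.panel}
    probe_sd = np.array(
        [
            (panel_by_id[p].noise_sd or config.noise_sd)
            if p in panel_by_id
            else config.noise_sd
            for p in endo_ids
        ]
    )
    eps = rng.normal(0.0, 1.0, (len(endo_ids), n_samples)) * probe_sd[:, None]
    lam = background[None, :] + efficiency[None, :] * np.exp(
        mu_vec[:, None] + delta + eps
    )
    endo_counts = rng.poisson(lam).astype(float)
    # hemolysis artifact: the trio's observed counts are inflated
    for pid in HEMOLYSIS_PROBES:
        r = endo_ids.index(pid)
        endo_counts[r, :] = np.round(endo_counts[r, :] * hemo_factor)

    # --- control probes ------------------------------------------------------
    spike_ids = list(SPIKE_NOMINAL)
    spike_eps = rng.normal(0.0, config.spike_noise_sd, (len(spike_ids), n_samples))
    spike_lam = background[None, :] + np.array(
        [SPIKE_NOMINAL[s] for s in spike_ids]
    )[:, None] * efficiency[None, :] * np.exp(spike_eps)
    spike_counts = rng.poisson(spike_lam).astype(float)

    neg_counts = rng.poisson(
        np.broadcast_to(background, (len(NEGATIVE_IDS), n_samples))
    ).astype(float)

    pos_ids = list(POSITIVE_NOMINAL)
    pos_lam = background[None, :] + POSITIVE_COUNT_SCALE * np.array(
        [POSITIVE_NOMINAL[p] for p in pos_ids]
    )[:, None]
    pos_counts = rng.poisson(np.broadcast_to(pos_lam, (len(pos_ids), n_samples))).astype(float)

    all_ids = endo_ids + neg_counts_ids() + pos_ids + spike_ids
    values = pd.DataFrame(
        np.vstack([endo_counts, neg_counts, pos_counts, spike_counts]),
        index=all_ids,
        columns=sample_ids,
    )
    classes = pd.Series(
        ["Endogenous"] * len(endo_ids)
        + ["Negative"] * len(NEGATIVE_IDS)
        + ["Positive"] * len(pos_ids)
        + ["SpikeIn"] * len(spike_ids),
        index=all_ids,
    )
    accession = pd.Series(
        {pid: accession_map.get(pid, "") for pid in all_ids}
    ).reindex(all_ids)
    matrix = CountMatrix(values, classes, accession, stages=("raw",))

    truth = TruthRecord(
        efficiency=dict(zip(sample_ids, efficiency.tolist())),
        background=dict(zip(sample_ids, background.tolist())),
        hemolysis_factor=dict(zip(sample_ids, hemo_factor.tolist())),
        mu={p: float(m) for p, m in mu.items()},
        panel=list(config.panel),
        ca199_shift={
            pid: ca199_case_shift(t, config.ca199) for pid, t in pair_lead.items()
        },
    )
    return manifest, matrix, truth


def neg_counts_ids() -> list[str]:
    return list(NEGATIVE_IDS)


def simulate_qc_attributes(
    sample_ids: Sequence[str], seed: int, fail_rate: float = 0.003
) -> pd.DataFrame:
    """Imaging-level QC attributes (FOV ratio, binding density) per sample.

    These are instrument metrics with no counterpart in the count model; a
    small fraction of samples fall outside the conventional pass ranges.
    """
    rng = np.random.default_rng(seed)
    n = len(sample_ids)
    fov = np.clip(rng.beta(80, 2, n), 0.0, 1.0)
    bad_fov = rng.random(n) < fail_rate
    fov[bad_fov] = rng.uniform(0.3, 0.7, int(bad_fov.sum()))
    bd = np.clip(rng.normal(0.9, 0.25, n), 0.05, 3.0)
    bad_bd = rng.random(n) < fail_rate
    bd[bad_bd] = rng.uniform(2.3, 3.0, int(bad_bd.sum()))
    return pd.DataFrame(
        {"fov_ratio": fov, "binding_density": bd}, index=list(sample_ids)
    )


def simulate_repeated_series(
    n_participants: int = 330,
    slope: float = 0.05,
    intercept: float = 0.0,
    sigma_u: float = 0.5,
    sigma_e: float = 1.0,
    three_draw_frac: float = 196 / 330,
    seed: int = 0,
) -> pd.DataFrame:
    """Repeated per-participant log-ratio series for the mixed-model analysis.

    Emulates the cohort subset with miRNA measured in 2-3 blood draws per
    participant: ``log_ratio = intercept + slope*lead + u_i + eps`` with a
    participant random intercept ``u_i ~ N(0, sigma_u^2)``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_participants):
        k = 3 if rng.random() < three_draw_frac else 2
        leads = np.sort(rng.uniform(0.3, 10.0, k))
        u = rng.normal(0.0, sigma_u)
        for t in leads:
            rows.append(
                {
                    "participant": f"P{i + 1:04d}",
                    "lead_time_years": float(t),
                    "log_ratio": float(
                        intercept + slope * t + u + rng.normal(0.0, sigma_e)
                    ),
                }
            )
    return pd.DataFrame(rows)
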