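"""Synthetic CE-MS peptidome cohorts with planted prognostic structure.

The generator emulates a case-control study nested in prospective
cohorts: urine is sampled at baseline, cases suffer an acute coronary
syndrome (ACS) event within the follow-up window, controls stay
event-free.  Each sample carries a deconvoluted CE-MS peak list whose
peptides are drawn from a shared catalogue; a configurable subset of
peptides is differentially excreted between future cases and controls
(the "planted" biomarkers), detection is Bernoulli per peptide and
sample, and every profile is multiplied by a per-sample dilution factor
that the housekeeping-peptide normalization downstream must remove.

All randomness flows from one :class:`numpy.random.Generator` seeded by
``SimConfig.seed``; identical configurations therefore yield identical
cohorts, catalogues and profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from acspredict.errors import ConfigError, SimulationInfeasibleError
from acspredict.peptidome import RawProfile, cluster_half_window

__all__ = [
    "SimConfig",
    "SplitResult",
    "generate_catalog",
    "generate_cohort",
    "generate_amplitude_matrix",
    "generate_profiles",
    "split_discovery_validation",
    "truncated_exponential_times",
]

#: Study centres with cohort-size proportions mirroring a multi-centre
#: design dominated by one large population study.
CENTRES = ("AUS", "FLE", "CAC", "HAC")
CENTRE_WEIGHTS = (0.865, 0.056, 0.032, 0.047)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic cohort.

    Defaults reproduce the study conditions the pipeline is built for:
    126 future-ACS cases and 126 matched controls followed for up to
    five years, roughly two thousand catalogued urinary peptides of
    which 75 are truly differential, and 29 housekeeping peptides with
    stable excretion used for dilution normalization.
    """

    n_cases: int = 126
    n_controls: int = 126
    n_peptides: int = 2042
    n_true_biomarkers: int = 75
    #: mean/sd of the absolute planted case-control shift on log2 amplitude
    log2_effect_mean: float = 1.0
    log2_effect_sd: float = 0.3
    #: within-peptide biological + analytical spread of log2 amplitudes
    base_log_amplitude_sd: float = 1.0
    #: background per-peptide detection frequencies (uniform over range)
    detect_freq_range: tuple[float, float] = (0.05, 0.95)
    #: detection frequency of planted biomarkers; None draws from the range
    biomarker_freq: float | None = 0.85
    #: additive detection-frequency shift of planted biomarkers in cases
    case_freq_shift: float = 0.0
    mass_range_da: tuple[float, float] = (800.0, 15000.0)
    cemt_range_min: tuple[float, float] = (19.0, 45.0)
    #: analytical jitter of observed masses; must stay below the 50 ppm
    #: clustering tolerance or profiles become unmatchable by construction
    mass_jitter_ppm: float = 15.0
    #: migration-time jitter as a fraction of the cluster half-window;
    #: the default keeps post-calibration deviation below the 0.35 min
    #: bound a controlled CE run guarantees
    cemt_jitter_fraction: float = 0.15
    n_housekeeping: int = 29
    follow_up_years: float = 5.0
    #: baseline event hazard (events/year) at average risk
    baseline_hazard: float = 0.1
    #: independent censoring hazard for controls (1/year)
    censor_rate: float = 0.02
    #: per-sample urine dilution factor, log-uniform over this range
    dilution_range: tuple[float, float] = (0.5, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_controls", "n_peptides",
                     "n_true_biomarkers", "n_housekeeping"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ConfigError(name, "must be a non-negative integer")
        if self.n_true_biomarkers + self.n_housekeeping > self.n_peptides:
            raise ConfigError(
                "n_true_biomarkers",
                "biomarkers plus housekeeping peptides exceed n_peptides "
                "(the two sets must be disjoint)")
        lo, hi = self.detect_freq_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigError("detect_freq_range",
                              "must be an ordered pair within [0, 1]")
        if self.biomarker_freq is not None and not (
                0.0 <= self.biomarker_freq <= 1.0):
            raise ConfigError("biomarker_freq", "must lie in [0, 1]")
        if not (-1.0 <= self.case_freq_shift <= 1.0):
            raise ConfigError("case_freq_shift", "must lie in [-1, 1]")
        if not (0.0 <= self.cemt_jitter_fraction):
            raise ConfigError("cemt_jitter_fraction", "must be >= 0")
        if self.mass_jitter_ppm < 0:
            raise ConfigError("mass_jitter_ppm", "must be >= 0")
        m_lo, m_hi = self.mass_range_da
        if not (0 < m_lo < m_hi):
            raise ConfigError("mass_range_da",
                              "must be an ordered pair of positive masses")
        t_lo, t_hi = self.cemt_range_min
        if not (19.0 <= t_lo < t_hi <= 45.0):
            raise ConfigError("cemt_range_min",
                              "must be an ordered pair within [19, 45] min")
        if self.follow_up_years <= 0:
            raise ConfigError("follow_up_years", "must be positive")
        if self.baseline_hazard < 0 or self.censor_rate < 0:
            raise ConfigError("baseline_hazard", "hazards must be >= 0")
        d_lo, d_hi = self.dilution_range
        if not (0 < d_lo <= d_hi):
            raise ConfigError("dilution_range",
                              "must be an ordered pair of positive factors")

    def rng(self, stage: int = 0) -> np.random.Generator:
        """Deterministic substream for one generation stage.

        Stages: 0 catalogue, 1 cohort, 2 amplitude matrix, 3 profiles.
        Keying the generator on ``(seed, stage)`` keeps the stages
        statistically independent while remaining reproducible from the
        single configured seed.
        """
        return np.random.default_rng([int(self.seed), int(stage)])


def generate_catalog(config: SimConfig) -> pd.DataFrame:
    """Draw the peptide catalogue (mass, migration time, planted truth).

    Returns a DataFrame indexed by ``peptide_id`` with columns
    ``mass_da``, ``cemt_min``, ``is_housekeeping``, ``is_true_biomarker``,
    ``true_log2_effect``, ``detect_freq``, ``base_log2_amp`` and
    ``ref_amplitude``.  Housekeeping peptides are detected in every
    sample and carry the reference amplitudes used for normalization;
    they are never planted biomarkers.
    """
    rng = config.rng(stage=0)
    m = config.n_peptides
    ids = [f"p{i:05d}" for i in range(1, m + 1)]
    mass = rng.uniform(*config.mass_range_da, size=m)
    cemt = rng.uniform(*config.cemt_range_min, size=m)

    order = rng.permutation(m)
    hk_idx = order[:config.n_housekeeping]
    bm_idx = order[config.n_housekeeping:
                   config.n_housekeeping + config.n_true_biomarkers]
    is_hk = np.zeros(m, dtype=bool)
    is_hk[hk_idx] = True
    is_bm = np.zeros(m, dtype=bool)
    is_bm[bm_idx] = True

    effect = np.zeros(m)
    magnitude = rng.normal(config.log2_effect_mean, config.log2_effect_sd,
                           size=config.n_true_biomarkers)
    sign = rng.choice([-1.0, 1.0], size=config.n_true_biomarkers)
    effect[bm_idx] = sign * magnitude

    freq = rng.uniform(*config.detect_freq_range, size=m)
    if config.biomarker_freq is not None:
        freq[bm_idx] = config.biomarker_freq
    freq[hk_idx] = 1.0

    base_log2_amp = rng.uniform(8.0, 14.0, size=m)

    return pd.DataFrame(
        {
            "mass_da": mass,
            "cemt_min": cemt,
            "is_housekeeping": is_hk,
            "is_true_biomarker": is_bm,
            "true_log2_effect": effect,
            "detect_freq": freq,
            "base_log2_amp": base_log2_amp,
            "ref_amplitude": 2.0 ** base_log2_amp,
        },
        index=pd.Index(ids, name="peptide_id"),
    )


def truncated_exponential_times(hazard: np.ndarray, horizon: float,
                                rng: np.random.Generator) -> np.ndarray:
    """Event times from an exponential hazard conditioned on t < horizon.

    Inverse-CDF sampling of ``Exp(hazard)`` truncated to ``[0, horizon)``;
    the conditional mean is ``1/h - horizon/(exp(h*horizon) - 1)``.
    """
    hazard = np.asarray(hazard, dtype=float)
    if np.any(hazard <= 0):
        raise SimulationInfeasibleError(
            "baseline_hazard is 0: no events can occur before the end of "
            "follow-up, so case labels cannot be generated")
    u = rng.uniform(size=hazard.shape)
    return -np.log1p(-u * (-np.expm1(-hazard * horizon))) / hazard


def _draw_covariates(rng: np.random.Generator, n: int,
                     case: bool) -> pd.DataFrame:
    """Clinical covariates with cases stochastically older / higher risk.

    Location/scale choices follow the demographics of a discovery cohort
    of asymptomatic individuals in their mid-sixties (blood pressures in
    mm Hg, cholesterol in mmol/L, eGFR in mL/min/1.73m2).
    """
    p = {
        # (control, case) parameterizations
        "age": ((64, 11), (66, 12)),
        "sbp": ((136, 19), (147, 23)),
        "dbp": ((72, 12), (79, 13)),
        "bmi": ((26, 4), (29, 5)),
        "tchol": ((6.0, 1.1), (5.9, 1.3)),
        "hdl": ((1.5, 0.4), (1.2, 0.3)),
        "egfr": ((72, 11), (70, 15)),
    }
    b = {
        "female": (0.36, 0.35),
        "smoker": (0.10, 0.24),
        "diabetes": (0.13, 0.29),
        "hypertension": (0.45, 0.69),
        "history_cvd": (0.07, 0.23),
    }
    k = 1 if case else 0
    out = {}
    for name, spec in p.items():
        mu, sd = spec[k]
        out[name] = rng.normal(mu, sd, size=n)
    out["age"] = np.clip(out["age"], 35, 95)
    out["hdl"] = np.clip(out["hdl"], 0.4, None)
    out["egfr"] = np.clip(out["egfr"], 10, None)
    out["bmi"] = np.clip(out["bmi"], 15, None)
    for name, probs in b.items():
        out[name] = (rng.uniform(size=n) < probs[k]).astype(int)
    return pd.DataFrame(out)


def generate_cohort(config: SimConfig,
                    catalog: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the cohort table and the per-sample ground truth.

    Returns ``(cohort, truth)``.  ``cohort`` is indexed by ``sample_id``
    and holds centre, case status, observed time/event flag, clinical
    covariates, a synthetic Framingham-type 10-year risk score ``fcvrs``
    in [0, 1] (monotone in the true risk up to noise) and a synthetic
    ``cad238`` coronary-artery-disease pattern score.  ``truth`` records
    the latent risk and the uncensored event/censoring times.
    """
    rng = config.rng(stage=1)
    n = config.n_cases + config.n_controls
    ids = [f"S{i:04d}" for i in range(1, n + 1)]
    is_case = np.zeros(n, dtype=bool)
    case_pos = rng.choice(n, size=config.n_cases, replace=False)
    is_case[case_pos] = True

    centre = rng.choice(CENTRES, size=n, p=CENTRE_WEIGHTS)

    cov_case = _draw_covariates(rng, int(is_case.sum()), case=True)
    cov_ctrl = _draw_covariates(rng, int((~is_case).sum()), case=False)
    # controls are selected to match cases on sex and (roughly) age, as
    # in a nested case-control design: resample their age and sex from
    # the cases with a small downward age offset (cases remain
    # stochastically older, but every case has matchable controls)
    if len(cov_case) and len(cov_ctrl):
        # permutation first: with equal group sizes every case has a
        # dedicated age/sex-compatible control, so a perfect pairing exists
        reps = int(np.ceil(len(cov_ctrl) / len(cov_case)))
        src = np.concatenate([rng.permutation(len(cov_case))
                              for _ in range(reps)])[:len(cov_ctrl)]
        cov_ctrl["female"] = cov_case["female"].to_numpy()[src]
        cov_ctrl["age"] = np.clip(
            cov_case["age"].to_numpy()[src] - 2.0
            + rng.uniform(-3.0, 3.0, size=len(cov_ctrl)), 35, 95)
    cov = pd.DataFrame(index=range(n), columns=cov_case.columns, dtype=float)
    cov.iloc[np.flatnonzero(is_case)] = cov_case.to_numpy()
    cov.iloc[np.flatnonzero(~is_case)] = cov_ctrl.to_numpy()

    # latent risk: a fixed linear predictor over the covariates plus noise
    eta = (
        0.04 * (cov["age"] - 65)
        + 0.010 * (cov["sbp"] - 140)
        + 0.50 * cov["diabetes"]
        + 0.35 * cov["hypertension"]
        + 0.60 * cov["history_cvd"]
        + 0.30 * cov["smoker"]
        - 0.50 * (cov["hdl"] - 1.35)
        - 0.010 * (cov["egfr"] - 70)
        + rng.normal(0, 0.5, size=n)
    ).to_numpy()
    eta_z = (eta - eta.mean()) / (eta.std() or 1.0)

    fcvrs = expit(-1.7 + 0.8 * eta_z + rng.normal(0, 0.4, size=n))
    cad238 = 0.8 * eta_z + rng.normal(0, 0.6, size=n)

    horizon = config.follow_up_years
    time = np.empty(n)
    event = np.zeros(n, dtype=int)
    censor_time = np.full(n, np.inf)
    event_time = np.full(n, np.inf)

    case_rows = np.flatnonzero(is_case)
    if case_rows.size:
        hazard = config.baseline_hazard * np.exp(0.7 * eta_z[case_rows])
        t_ev = truncated_exponential_times(hazard, horizon, rng)
        event_time[case_rows] = t_ev
        time[case_rows] = t_ev
        event[case_rows] = 1
    ctrl_rows = np.flatnonzero(~is_case)
    if ctrl_rows.size:
        if config.censor_rate > 0:
            c = rng.exponential(1.0 / config.censor_rate, size=ctrl_rows.size)
        else:
            c = np.full(ctrl_rows.size, np.inf)
        censor_time[ctrl_rows] = c
        time[ctrl_rows] = np.minimum(c, horizon)

    cohort = pd.DataFrame(
        {
            "centre": centre,
            "is_case": is_case.astype(int),
            "time_years": time,
            "event": event,
            "fcvrs": fcvrs,
            "cad238": cad238,
        },
        index=pd.Index(ids, name="sample_id"),
    )
    cohort = pd.concat([cohort, cov.set_index(cohort.index)], axis=1)

    truth = pd.DataFrame(
        {
            "true_risk": eta_z,
            "event_time": event_time,
            "censor_time": censor_time,
        },
        index=cohort.index,
    )
    return cohort, truth


def generate_amplitude_matrix(config: SimConfig, catalog: pd.DataFrame,
                              cohort: pd.DataFrame) -> pd.DataFrame:
    """The planted, dilution-free sample x peptide amplitude matrix.

    Detected amplitudes are log-normal: log2 amplitude = peptide base
    level + N(0, sd) + planted effect in cases.  Undetected cells are 0.
    Housekeeping peptides are detected in every sample with a quarter of
    the base spread (stable excretion).
    """
    rng = config.rng(stage=2)
    n, m = len(cohort), len(catalog)
    is_case = cohort["is_case"].to_numpy(dtype=bool)

    freq_ctrl = catalog["detect_freq"].to_numpy()
    shift = np.where(catalog["is_true_biomarker"], config.case_freq_shift, 0.0)
    freq_case = np.clip(freq_ctrl + shift, 0.0, 1.0)
    freq = np.where(is_case[:, None], freq_case[None, :], freq_ctrl[None, :])
    detected = rng.uniform(size=(n, m)) < freq
    detected[:, catalog["is_housekeeping"].to_numpy()] = True

    sd = np.where(catalog["is_housekeeping"],
                  0.25 * config.base_log_amplitude_sd,
                  config.base_log_amplitude_sd)
    log2amp = (catalog["base_log2_amp"].to_numpy()[None, :]
               + rng.normal(size=(n, m)) * sd[None, :]
               + np.outer(is_case, catalog["true_log2_effect"].to_numpy()))
    values = np.where(detected, 2.0 ** log2amp, 0.0)
    return pd.DataFrame(values, index=cohort.index, columns=catalog.index)


def generate_profiles(config: SimConfig, catalog: pd.DataFrame,
                      cohort: pd.DataFrame,
                      matrix: pd.DataFrame | None = None,
                      mass_tol_ppm: float = 50.0,
                      ) -> tuple[list[RawProfile], pd.DataFrame, np.ndarray]:
    """Per-sample peak lists with dilution, mass and time jitter.

    Returns ``(profiles, planted_matrix, dilution)``.  Every detected
    cell of the planted matrix becomes one detection whose observed mass
    deviates from the catalogue mass by less than ``mass_jitter_ppm``
    and whose migration time deviates by at most ``cemt_jitter_fraction``
    of the cluster half-window, so profiles are matchable back to the
    catalogue by construction; amplitudes are scaled by a per-sample
    dilution factor shared across all peptides of the sample.
    """
    if config.mass_jitter_ppm >= mass_tol_ppm:
        raise ConfigError(
            "mass_jitter_ppm",
            f"jitter must stay below the matching tolerance ({mass_tol_ppm} ppm)")
    if config.cemt_jitter_fraction >= 1.0:
        raise ConfigError(
            "cemt_jitter_fraction",
            "jitter must stay inside the cluster window (fraction < 1)")
    if matrix is None:
        matrix = generate_amplitude_matrix(config, catalog, cohort)
    rng = config.rng(stage=3)

    d_lo, d_hi = config.dilution_range
    dilution = np.exp(rng.uniform(np.log(d_lo), np.log(d_hi),
                                  size=len(cohort)))

    mass_ref = catalog["mass_da"].to_numpy()
    cemt_ref = catalog["cemt_min"].to_numpy()
    half_window = cluster_half_window(cemt_ref)

    profiles: list[RawProfile] = []
    values = matrix.to_numpy()
    for i, sample_id in enumerate(matrix.index):
        det = np.flatnonzero(values[i] > 0)
        ppm = rng.uniform(-config.mass_jitter_ppm, config.mass_jitter_ppm,
                          size=det.size)
        dt = rng.uniform(-1.0, 1.0, size=det.size) * (
            config.cemt_jitter_fraction * half_window[det])
        mass = mass_ref[det] * (1.0 + ppm * 1e-6)
        cemt = cemt_ref[det] + dt
        amp = values[i, det] * dilution[i]
        order = np.argsort(cemt, kind="stable")
        profiles.append(RawProfile(sample_id=str(sample_id),
                                   mass_da=mass[order],
                                   cemt_min=cemt[order],
                                   amplitude=amp[order]))
    return profiles, matrix, dilution


@dataclass
class SplitResult:
    """Discovery/validation assignment with case-control pairing."""

    discovery_cases: list[str]
    discovery_controls: list[str]
    validation_cases: list[str]
    validation_controls: list[str]
    #: cases for which no eligible (same-sex, age-window) control remained
    unmatched_cases: list[str] = field(default_factory=list)
    pairs: dict[str, str] = field(default_factory=dict)

    @property
    def discovery_ids(self) -> list[str]:
        return self.discovery_cases + self.discovery_controls

    @property
    def validation_ids(self) -> list[str]:
        return self.validation_cases + self.validation_controls


def _allocate_stratified(sizes: dict[str, int], total: int,
                         ratio: float) -> dict[str, int]:
    """Largest-remainder allocation of ``round(ratio*total)`` across strata."""
    target = int(round(ratio * total))
    quotas = {k: ratio * v for k, v in sizes.items()}
    base = {k: int(np.floor(q)) for k, q in quotas.items()}
    short = target - sum(base.values())
    remainders = sorted(quotas, key=lambda k: (quotas[k] - base[k], k),
                        reverse=True)
    for k in remainders[:max(short, 0)]:
        if base[k] < sizes[k]:
            base[k] += 1
    return base


def split_discovery_validation(cohort: pd.DataFrame, ratio: float = 2 / 3,
                               match_age_window: float = 5.0,
                               seed: int = 0) -> SplitResult:
    """Random 2/3 : 1/3 case split with age- and sex-matched controls.

    Cases are assigned to discovery/validation at random within each
    study centre (largest-remainder rounding keeps the global ratio
    exact).  Each case is then paired with a previously unused control
    of the same sex whose age differs by at most ``match_age_window``
    years, preferring the nearest age; cases with no eligible control
    are reported in ``unmatched_cases`` rather than silently dropped.
    """
    cases = cohort[cohort["is_case"] == 1]
    controls = cohort[cohort["is_case"] == 0]
    if cases.empty or controls.empty:
        raise ValueError("cohort must contain both cases and controls")
    rng = np.random.default_rng(seed)

    by_centre = {c: list(g.index) for c, g in cases.groupby("centre")}
    alloc = _allocate_stratified({c: len(v) for c, v in by_centre.items()},
                                 len(cases), ratio)
    disc_cases: list[str] = []
    val_cases: list[str] = []
    for centre in sorted(by_centre):
        ids = np.array(by_centre[centre])
        rng.shuffle(ids)
        k = alloc.get(centre, 0)
        disc_cases.extend(ids[:k])
        val_cases.extend(ids[k:])

    used: set[str] = set()
    unmatched: list[str] = []
    pairs: dict[str, str] = {}

    def match(case_ids: list[str]) -> list[str]:
        """Maximum bipartite matching over the eligibility graph.

        Eligibility = same sex and age within the window; a maximum
        matching leaves as few cases unmatched as the pool permits and
        recovers a unique valid pairing exactly.
        """
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import maximum_bipartite_matching

        cids = sorted(case_ids)
        pool = controls[~controls.index.isin(used)].sort_index()
        if not cids or pool.empty:
            unmatched.extend(cids)
            return []
        c_age = cohort.loc[cids, "age"].to_numpy()
        c_sex = cohort.loc[cids, "female"].to_numpy()
        eligible = ((pool["female"].to_numpy()[None, :] == c_sex[:, None])
                    & (np.abs(pool["age"].to_numpy()[None, :]
                              - c_age[:, None]) <= match_age_window))
        assign = maximum_bipartite_matching(csr_matrix(eligible),
                                            perm_type="column")
        chosen: list[str] = []
        for i, cid in enumerate(cids):
            j = assign[i]
            if j < 0:
                unmatched.append(str(cid))
                continue
            ctrl_id = str(pool.index[j])
            used.add(ctrl_id)
            pairs[str(cid)] = ctrl_id
            chosen.append(ctrl_id)
        return chosen

    # one global maximum matching, so the validation pairing is not
    # starved by controls already consumed for discovery; each matched
    # control follows its case into the case's split
    match(list(cases.index))
    disc_controls = [pairs[str(c)] for c in disc_cases if str(c) in pairs]
    val_controls = [pairs[str(c)] for c in val_cases if str(c) in pairs]
    return SplitResult(
        discovery_cases=[str(c) for c in disc_cases],
        discovery_controls=disc_controls,
        validation_cases=[str(c) for c in val_cases],
        validation_controls=val_controls,
        unmatched_cases=unmatched,
        pairs=pairs,
    )
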