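"""Synthetic study-design generator for the PRM verification pipeline.

Emulates the verification-phase study design end to end so every downstream
stage is testable without the measured cohort: a two-group serum cohort
(79 PCa / 84 BPH with clinical markers drawn to match published group
medians and IQRs), duplicate LC-MS runs per sample with lognormal
TiO2-enrichment recovery variation, 30 reference glycopeptides whose summed
XIC tracks that recovery, heavy internal standards spiked after enrichment
(hence untouched by the recovery factor), per-peptide group fold-changes
planted on the 32-peptide panel, and injected discordant replicate pairs /
low-recovery runs for the QC rules to catch.

Every dataset is reproducible from ``(config, seed)``; a truth sidecar
records planted baselines, fold-changes, per-run enrichment factors, the
injected failures, and which features carry a recoverable effect.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .candidates import VALID_RESIDUES, load_verification_panel

__all__ = [
    "ClinicalParam",
    "CohortConfig",
    "SignalConfig",
    "CLINICAL_DEFAULTS",
    "generate_cohort",
    "generate_prm_runs",
    "generate_discovery_table",
    "generate_dataset",
    "write_dataset",
]

_Z75 = float(stats.norm.ppf(0.75))  # quartile z-score of the standard normal


@dataclass(frozen=True)
class ClinicalParam:
    """Lognormal marker parameterized by its group median and quartiles."""

    median: float
    q1: float
    q3: float

    def __post_init__(self) -> None:
        if self.median <= 0:
            raise ValueError("median must be > 0")
        if not self.q1 < self.q3:
            raise ValueError(f"inverted IQR bounds ({self.q1}, {self.q3})")

    @property
    def mu(self) -> float:
        return float(np.log(self.median))

    @property
    def sigma(self) -> float:
        # Match the IQR *ratio*: for LN(mu, sigma) the quartiles are
        # exp(mu +/- z75*sigma), so sigma = ln(q3/q1) / (2 z75).  The median
        # is matched exactly; the individual quartiles are approximate when
        # the configured median is not the geometric mean of q1 and q3.
        return float(np.log(self.q3 / self.q1) / (2.0 * _Z75))

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.exp(rng.normal(self.mu, self.sigma, size=n))


#: Published baseline characteristics of the verification cohort
#: (median and IQR per group).  ftPSA is in percent, fPSA/tPSA in ng/mL,
#: proPSA in pg/mL, prostate dimension in cc, age in years.
CLINICAL_DEFAULTS: dict[str, dict[str, ClinicalParam]] = {
    "PCa": {
        "age": ClinicalParam(69, 64.5, 73.5),
        "prostate_dimension": ClinicalParam(40, 30, 50),
        "propsa": ClinicalParam(553.9, 385.7, 996),
        "tpsa": ClinicalParam(8.05, 5.66, 15.85),
        "ftpsa": ClinicalParam(16, 12, 22),
        "fpsa": ClinicalParam(1.43, 0.99, 2.7),
    },
    "BPH": {
        "age": ClinicalParam(69, 62, 72.5),
        "prostate_dimension": ClinicalParam(55, 40, 78),
        "propsa": ClinicalParam(257.7, 87, 440),
        "tpsa": ClinicalParam(2.4, 0.93, 4.84),
        "ftpsa": ClinicalParam(35, 24, 45),
        "fpsa": ClinicalParam(0.81, 0.28, 1.72),
    },
}

#: Gleason strata within PCa: 3+3 (NAG) vs the aggressive strata, with the
#: published stratum counts 26 / 22 / 16 / 15.
_GLEASON_AG_STRATA = (("3+4", 22), ("4+3", 16), (">=8", 15))


@dataclass(frozen=True)
class CohortConfig:
    """Cohort design: group sizes, Gleason split and clinical distributions."""

    n_pca: int = 79
    n_bph: int = 84
    n_nag: int = 26
    n_ag: int = 53
    clinical_params: dict[str, dict[str, ClinicalParam]] = field(
        default_factory=lambda: CLINICAL_DEFAULTS
    )
    ftpsa_noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pca < 0 or self.n_bph < 0:
            raise ValueError("group sizes must be non-negative")
        if self.n_pca > 0 and self.n_ag + self.n_nag != self.n_pca:
            raise ValueError("n_ag + n_nag must equal n_pca")
        for group, params in self.clinical_params.items():
            if group not in ("PCa", "BPH"):
                raise ValueError(f"unknown group {group!r}")
            for name, p in params.items():
                if not isinstance(p, ClinicalParam):
                    raise TypeError(f"{group}/{name}: expected ClinicalParam")


def generate_cohort(config: CohortConfig | None = None) -> pd.DataFrame:
    """Simulate the clinical table: one row per subject.

    Markers are lognormal, matched to the configured group median and IQR
    ratio.  fPSA is derived as ``ftPSA/100 * tPSA`` times a small lognormal
    error so the free/total ratio stays internally consistent; its own
    configured median is then implied rather than imposed.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    frames = []
    for group, n in (("PCa", config.n_pca), ("BPH", config.n_bph)):
        params = config.clinical_params[group]
        df = pd.DataFrame(
            {
                "diagnosis": [group] * n,
                "age": np.round(params["age"].draw(rng, n), 1),
                "prostate_dimension": params["prostate_dimension"].draw(rng, n),
                "propsa": params["propsa"].draw(rng, n),
                "tpsa": params["tpsa"].draw(rng, n),
                "ftpsa": np.minimum(params["ftpsa"].draw(rng, n), 95.0),
            }
        )
        noise = np.exp(rng.normal(0.0, config.ftpsa_noise_cv, size=n))
        df["fpsa"] = df["ftpsa"] / 100.0 * df["tpsa"] * noise
        frames.append(df)
    cohort = pd.concat(frames, ignore_index=True)
    cohort.insert(0, "sample_id", [f"S{i + 1:03d}" for i in range(len(cohort))])

    # Gleason grade: 3+3 for NAG, aggressive strata proportional to the
    # published counts for AG; BPH has no grade.
    gleason = np.array(["NA"] * len(cohort), dtype=object)
    aggr = np.array(["NA"] * len(cohort), dtype=object)
    pca_idx = np.flatnonzero(cohort["diagnosis"].to_numpy() == "PCa")
    if len(pca_idx):
        grades = ["3+3"] * config.n_nag
        total = sum(c for _, c in _GLEASON_AG_STRATA)
        counts = [int(round(config.n_ag * c / total)) for _, c in _GLEASON_AG_STRATA]
        counts[-1] = config.n_ag - sum(counts[:-1])
        for (name, _), c in zip(_GLEASON_AG_STRATA, counts):
            grades.extend([name] * c)
        order = rng.permutation(len(pca_idx))
        gleason[pca_idx] = np.asarray(grades, dtype=object)[order]
        aggr[pca_idx] = np.where(gleason[pca_idx] == "3+3", "NAG", "AG")
    cohort["gleason"] = gleason
    cohort["aggressiveness"] = aggr
    return cohort


def _panel_defaults() -> pd.DataFrame:
    return load_verification_panel()


@dataclass(frozen=True)
class SignalConfig:
    """Signal model for the PRM runs.

    ``enrichment_cv``/``heavy_spike_cv``/``measurement_cv`` are lognormal
    sigmas of, respectively, the per-run TiO2 recovery factor, the per-run
    heavy-spike pipetting error, and the per-observation XIC integration
    error.  ``biological_cv`` is the between-subject sigma of each peptide's
    endogenous level.  Discordant pairs are injected by dividing one
    replicate's recovery factor by ``discordant_factor`` (2.6 puts the
    replicate-concordance statistic just above 0.6, deterministically beyond
    the 0.50 exclusion rule); low-recovery runs by multiplying it by
    ``low_recovery_factor``.
    """

    target_fold_changes: dict[str, float] | None = None
    ag_fold_changes: dict[str, float] | None = None
    n_reference_glycopeptides: int = 30
    enrichment_cv: float = 0.10
    heavy_spike_cv: float = 0.05
    measurement_cv: float = 0.08
    biological_cv: float = 0.40
    reference_biological_cv: float = 0.10
    frac_discordant_runs: float = 32.0 / 163.0
    frac_low_recovery_runs: float = 0.0
    discordant_factor: float = 2.6
    low_recovery_factor: float = 0.05
    duplicate: bool = True
    baseline_log10_range: tuple[float, float] = (4.0, 9.0)
    reference_log10_range: tuple[float, float] = (6.0, 8.0)

    def __post_init__(self) -> None:
        for name in (
            "enrichment_cv",
            "heavy_spike_cv",
            "measurement_cv",
            "biological_cv",
            "reference_biological_cv",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("frac_discordant_runs", "frac_low_recovery_runs"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.target_fold_changes is not None:
            if any(fc <= 0 for fc in self.target_fold_changes.values()):
                raise ValueError("fold-changes must be > 0")
        if self.n_reference_glycopeptides < 1:
            raise ValueError("need at least one reference glycopeptide")


def _resolve_panel(signal: SignalConfig):
    panel = _panel_defaults()
    peptides = panel["peptide_id"].tolist()
    fc = dict(zip(panel["peptide_id"], panel["planted_fc_pca_vs_bph"].astype(float)))
    fc_ag = dict(zip(panel["peptide_id"], panel["planted_fc_ag_vs_nag"].astype(float)))
    if signal.target_fold_changes:
        unknown = set(signal.target_fold_changes) - set(peptides)
        if unknown:
            raise ValueError(f"unknown peptide id(s) in config: {sorted(unknown)}")
        fc.update(signal.target_fold_changes)
    if signal.ag_fold_changes:
        unknown = set(signal.ag_fold_changes) - set(peptides)
        if unknown:
            raise ValueError(f"unknown peptide id(s) in config: {sorted(unknown)}")
        fc_ag.update(signal.ag_fold_changes)
    is_peptides = set(panel.loc[panel["quant_mode"] == "IS", "peptide_id"])
    return peptides, fc, fc_ag, is_peptides


def _lognormal_moments(median: float, sigma: float) -> tuple[float, float]:
    mean = median * float(np.exp(sigma**2 / 2.0))
    var = mean**2 * float(np.expm1(sigma**2))
    return mean, var


def _point_biserial(e1, v1, e0, v0, p1) -> float:
    """Population correlation between a 0/1 label and a mixture feature."""
    q = 1.0 - p1
    denom = np.sqrt(p1 * q * (e1 - e0) ** 2 + p1 * v1 + q * v0)
    return 0.0 if denom == 0 else abs(e1 - e0) * np.sqrt(p1 * q) / denom


def _informative_features(
    signal: SignalConfig,
    fold_changes: dict[str, float],
    cohort_config: CohortConfig,
    r_min: float = 0.25,
) -> list[str]:
    """Planted features recoverable by raw-scale selectors.

    "Recoverable" means the population point-biserial correlation between the
    feature and the group label is at least ``r_min``; for the lognormal
    variables planted here it follows in closed form from the group
    medians/sigmas.  The raw-scale correlation, not the log-scale effect
    size, is what bounds the linear univariate selectors: a marker with a
    large log-scale shift but a heavy-tailed null group (e.g. the BPH proPSA
    IQR spanning 87-440) can still be nearly uncorrelated with the label on
    the raw scale.
    """
    n1, n0 = cohort_config.n_pca, cohort_config.n_bph
    p1 = n1 / (n1 + n0) if (n1 + n0) else 0.5
    feats = []
    s = signal.biological_cv
    for pep, fc in fold_changes.items():
        e0, v0 = _lognormal_moments(1.0, s)
        e1, v1 = _lognormal_moments(fc, s)
        if _point_biserial(e1, v1, e0, v0, p1) >= r_min:
            feats.append(pep)
    pca = cohort_config.clinical_params["PCa"]
    bph = cohort_config.clinical_params["BPH"]
    for var in pca:
        if var == "fpsa":  # derived column; no direct effect planted
            continue
        e1, v1 = _lognormal_moments(pca[var].median, pca[var].sigma)
        e0, v0 = _lognormal_moments(bph[var].median, bph[var].sigma)
        if _point_biserial(e1, v1, e0, v0, p1) >= r_min:
            feats.append(var)
    return feats


def generate_prm_runs(
    samples: pd.DataFrame,
    signal: SignalConfig | None = None,
    seed: int = 0,
    enrichment_scale: dict[tuple[str, int], float] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate the long-format PRM run table for a cohort.

    Returns ``(runs, truth)``.  ``runs`` has one row per (run, peptide,
    channel) with columns ``sample_id, replicate_idx, peptide_id, channel,
    area``; channels are ``light`` (endogenous target), ``heavy`` (internal
    standard, IS-quantified peptides only) and ``reference`` (the
    normalization glycopeptides REFnn).

    Light and reference areas scale with the run's enrichment factor; heavy
    areas do not (the standards are spiked after enrichment).
    ``enrichment_scale`` multiplies selected runs' enrichment factors after
    all random draws, so regenerating with the same seed isolates a pure
    scaling of those runs.
    """
    if samples.empty:
        raise ValueError("samples table is empty")
    signal = signal or SignalConfig()
    peptides, fc_pca, fc_ag, is_peptides = _resolve_panel(signal)
    n_ref = signal.n_reference_glycopeptides
    ref_ids = [f"REF{i + 1:02d}" for i in range(n_ref)]

    root = np.random.SeedSequence(seed)
    rng_global, rng_subject, rng_run = (
        np.random.default_rng(s) for s in root.spawn(3)
    )

    lo, hi = signal.baseline_log10_range
    baselines = pd.Series(
        10.0 ** rng_global.uniform(lo, hi, size=len(peptides)), index=peptides
    )
    rlo, rhi = signal.reference_log10_range
    ref_baselines = pd.Series(
        10.0 ** rng_global.uniform(rlo, rhi, size=n_ref), index=ref_ids
    )
    heavy_spikes = baselines.copy()  # standards matched to expected levels

    sample_ids = samples["sample_id"].tolist()
    n_samples = len(sample_ids)
    n_disc = int(round(signal.frac_discordant_runs * n_samples))
    n_low = int(round(signal.frac_low_recovery_runs * n_samples))
    if n_disc + n_low > n_samples:
        raise ValueError("injected-failure fractions exceed the cohort size")
    flagged = rng_global.choice(n_samples, size=n_disc + n_low, replace=False)
    discordant = {sample_ids[i] for i in flagged[:n_disc]}
    low_recovery = {sample_ids[i] for i in flagged[n_disc:]}
    if not signal.duplicate:
        discordant = set()  # replicate discordance needs duplicates

    diag = dict(zip(samples["sample_id"], samples["diagnosis"]))
    aggr = dict(zip(samples["sample_id"], samples.get("aggressiveness", "NA")))

    fc_vec_by_group = {}
    for sid in sample_ids:
        key = (diag[sid], aggr.get(sid, "NA"))
        if key not in fc_vec_by_group:
            vec = np.ones(len(peptides))
            if key[0] == "PCa":
                vec *= np.array([fc_pca[p] for p in peptides])
                if key[1] == "AG":
                    vec *= np.array([fc_ag[p] for p in peptides])
            fc_vec_by_group[key] = vec

    records = []
    enrich_truth = []
    is_mask = np.array([p in is_peptides for p in peptides])
    for sid in sample_ids:
        subj_pep = np.exp(
            rng_subject.normal(0.0, signal.biological_cv, size=len(peptides))
        )
        subj_ref = np.exp(
            rng_subject.normal(0.0, signal.reference_biological_cv, size=n_ref)
        )
        level = baselines.to_numpy() * fc_vec_by_group[(diag[sid], aggr.get(sid, "NA"))] * subj_pep
        ref_level = ref_baselines.to_numpy() * subj_ref

        n_reps = 2 if signal.duplicate else 1
        e_reps = [
            float(np.exp(rng_run.normal(0.0, signal.enrichment_cv)))
            for _ in range(n_reps)
        ]
        if sid in discordant:
            # derive replicate 2 from replicate 1 so the planted concordance
            # violation is deterministic, not at the mercy of two draws
            e_reps[1] = e_reps[0] / signal.discordant_factor
        if sid in low_recovery:
            e_reps[-1] *= signal.low_recovery_factor
        for rep in range(1, n_reps + 1):
            e = e_reps[rep - 1]
            if enrichment_scale:
                e *= enrichment_scale.get((sid, rep), 1.0)
            meas = np.exp(
                rng_run.normal(0.0, signal.measurement_cv, size=len(peptides))
            )
            ref_meas = np.exp(
                rng_run.normal(0.0, signal.measurement_cv, size=n_ref)
            )
            heavy_noise = float(np.exp(rng_run.normal(0.0, signal.heavy_spike_cv)))

            light = level * e * meas
            refs = ref_level * e * ref_meas
            heavy = heavy_spikes.to_numpy() * heavy_noise

            enrich_truth.append((sid, rep, e))
            for j, pep in enumerate(peptides):
                records.append((sid, rep, pep, "light", light[j]))
                if is_mask[j]:
                    records.append((sid, rep, pep, "heavy", heavy[j]))
            for k, rid in enumerate(ref_ids):
                records.append((sid, rep, rid, "reference", refs[k]))

    runs = pd.DataFrame(
        records,
        columns=["sample_id", "replicate_idx", "peptide_id", "channel", "area"],
    )
    truth = {
        "baselines": baselines,
        "reference_baselines": ref_baselines,
        "heavy_spikes": heavy_spikes,
        "fold_changes": fc_pca,
        "ag_fold_changes": fc_ag,
        "is_peptides": sorted(is_peptides),
        "enrichment_factors": pd.DataFrame(
            enrich_truth, columns=["sample_id", "replicate_idx", "enrichment"]
        ),
        "planted_discordant": sorted(discordant),
        "planted_low_recovery": sorted(low_recovery),
    }
    return runs, truth


def generate_dataset(
    cohort_config: CohortConfig | None = None,
    signal: SignalConfig | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Full synthetic study: clinical table, PRM run table and truth sidecar.

    ``seed`` overrides ``cohort_config.seed`` when given; the run table uses
    a deterministically derived sub-seed so the cohort and the runs never
    share random draws.
    """
    cohort_config = cohort_config or CohortConfig()
    if seed is not None:
        cohort_config = dataclasses.replace(cohort_config, seed=seed)
    signal = signal or SignalConfig()
    cohort = generate_cohort(cohort_config)
    runs, truth = generate_prm_runs(
        cohort, signal, seed=cohort_config.seed + 10_000
    )
    truth["informative_features"] = _informative_features(
        signal, truth["fold_changes"], cohort_config
    )
    return cohort, runs, truth


# ---------------------------------------------------------------------------
# Discovery-table fixture generator
# ---------------------------------------------------------------------------

_BODY = sorted(VALID_RESIDUES - set("KRNP"))  # no tryptic sites / sequon N / P


def _random_peptide(
    rng: np.random.Generator,
    length: int,
    with_sequon: bool,
    internal_k: int = 0,
) -> str:
    body = [str(rng.choice(_BODY)) for _ in range(length - 1)]
    if with_sequon:
        pos = int(rng.integers(0, length - 3))
        body[pos] = "N"
        body[pos + 2] = "S" if rng.random() < 0.5 else "T"
    if internal_k:
        free = [i for i in range(length - 2) if body[i] not in "NST"]
        for i in rng.choice(free, size=internal_k, replace=False):
            body[int(i)] = "K"
    return "".join(body) + ("K" if rng.random() < 0.5 else "R")


def generate_discovery_table(
    n_peptides: int,
    n_significant: int,
    fc_range: tuple[float, float] = (1.2, 2.5),
    seed: int = 0,
) -> pd.DataFrame:
    """Planted-truth discovery table for exercising the candidate filter.

    Exactly ``n_significant`` rows satisfy the default selection rules
    (fold-change >= 1.2, p < 0.1, sequon present, length <= 25, no extra
    missed cleavages); every other row violates at least one rule.  The
    ``planted_significant`` column records the truth.
    """
    if n_significant > n_peptides:
        raise ValueError("n_significant must not exceed n_peptides")
    if not fc_range or len(fc_range) != 2 or not fc_range[0] < fc_range[1]:
        raise ValueError("fc_range must be a (low, high) pair with low < high")
    if fc_range[0] < 1.2:
        raise ValueError("significant fold-changes must start at >= 1.2")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows, seen = [], set()
    violations = ("fold_change", "p_value", "sequon", "length", "missed_cleavages")
    for i in range(n_peptides):
        significant = i < n_significant
        mode = "ok" if significant else str(rng.choice(violations))
        length = int(rng.integers(8, 21))
        with_sequon, internal_k = True, 0
        if mode == "sequon":
            with_sequon = False
        elif mode == "length":
            length = int(rng.integers(26, 31))
        elif mode == "missed_cleavages":
            internal_k = 2  # beyond the default tolerance of one
        while True:
            seq = _random_peptide(rng, length, with_sequon, internal_k)
            if seq not in seen:
                seen.add(seq)
                break
        fc = float(rng.uniform(*fc_range))
        p = float(rng.uniform(0.001, 0.095))
        if mode == "fold_change":
            fc = float(rng.uniform(0.5, 1.05))
        elif mode == "p_value":
            p = float(rng.uniform(0.15, 0.9))
        rows.append(
            {
                "sequence": seq,
                "gene": f"GENE{i + 1:03d}",
                "fold_change": round(fc, 3),
                "p_value": round(p, 4),
                "source_experiment": "synthetic",
                "literature_flag": False,
                "planted_significant": significant,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_dataset(
    out_dir,
    cohort: pd.DataFrame,
    runs: pd.DataFrame,
    truth: dict,
) -> dict[str, str]:
    """Write clinical CSV, run TSV and the truth sidecar TSVs under out_dir."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "clinical": out / "clinical.csv",
        "runs": out / "prm_runs.tsv",
        "truth_fold_changes": out / "truth_fold_changes.tsv",
        "truth_runs": out / "truth_runs.tsv",
    }
    cohort.to_csv(paths["clinical"], index=False)
    runs.to_csv(paths["runs"], sep="\t", index=False)
    fc = pd.DataFrame(
        {
            "peptide_id": list(truth["fold_changes"]),
            "planted_fc_pca_vs_bph": list(truth["fold_changes"].values()),
            "planted_fc_ag_vs_nag": [
                truth["ag_fold_changes"][p] for p in truth["fold_changes"]
            ],
            "baseline": [truth["baselines"][p] for p in truth["fold_changes"]],
        }
    )
    fc.to_csv(paths["truth_fold_changes"], sep="\t", index=False)
    tr = truth["enrichment_factors"].copy()
    tr["planted_discordant"] = tr["sample_id"].isin(truth["planted_discordant"])
    tr["planted_low_recovery"] = tr["sample_id"].isin(truth["planted_low_recovery"])
    tr.to_csv(paths["truth_runs"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}
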