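"""Verification-phase QC and normalization of PRM peak areas.

The verification design runs every serum digest in technical duplicate.
Because the TiO2 glycopeptide enrichment precedes the spiking of heavy
internal standards, the summed XIC of 30 high-abundance reference
glycopeptides (C) proxies the run's enrichment recovery and drives both QC
and normalization:

* replicate concordance by the scaled relative difference
  SRD = (C1 - C2) / (mean(C1, C2) * sqrt(2)); |SRD| > 0.50 drops the
  replicate with the lower recovery;
* any run with C more than 2 SD below the dataset mean C is dropped;
* light areas of IS-quantified peptides are corrected by f = Hm / Hn
  (cohort-mean heavy over this run's heavy);
* all areas are divided by C_run / C_a (run recovery over cohort mean);
* duplicates are averaged and clinical variables joined, yielding the
  samples-by-features quantification matrix.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "compute_srd",
    "reference_sums",
    "qc_filter",
    "is_correct",
    "enrichment_normalize",
    "assemble_matrix",
    "QCReport",
    "CLINICAL_COLUMNS",
]

#: clinical covariates carried into the quantification matrix
CLINICAL_COLUMNS = ["age", "prostate_dimension", "propsa", "tpsa", "fpsa", "ftpsa"]

SQRT2 = math.sqrt(2.0)


def compute_srd(c1: float, c2: float) -> float:
    """Scaled relative difference between duplicate reference-glycopeptide sums.

    ``(c1 - c2) / (mean(c1, c2) * sqrt(2))``; antisymmetric under swapping the
    replicates, zero for identical ones, and ~|SRD| = 0.47 at a twofold
    recovery difference.
    """
    if c1 <= 0 or c2 <= 0:
        raise ValueError("reference sums must be positive")
    return (c1 - c2) / (((c1 + c2) / 2.0) * SQRT2)


def reference_sums(runs: pd.DataFrame) -> pd.DataFrame:
    """Per-run sum of reference-glycopeptide XIC areas.

    Returns one row per (sample_id, replicate_idx) with column ``C``.
    """
    refs = runs[runs["channel"] == "reference"]
    if refs.empty:
        raise ValueError("run table contains no reference channel rows")
    c = (
        refs.groupby(["sample_id", "replicate_idx"], sort=True)["area"]
        .sum()
        .rename("C")
        .reset_index()
    )
    if (c["C"] <= 0).any():
        bad = c.loc[c["C"] <= 0, "sample_id"].tolist()
        raise ValueError(f"non-positive reference sum for runs of {bad}")
    return c


@dataclass
class QCReport:
    """Outcome of the replicate-concordance and low-recovery filters."""

    srd: pd.DataFrame  # sample_id, c1, c2, srd (duplicate samples only)
    dropped: pd.DataFrame  # sample_id, replicate_idx, C, reason
    c_mean: float  # dataset mean of C before exclusions
    c_sd: float  # dataset SD of C before exclusions
    sd_mult: float = 2.0
    n_runs_in: int = 0
    n_runs_retained: int = 0

    @property
    def threshold(self) -> float:
        return self.c_mean - self.sd_mult * self.c_sd

    def summary(self) -> dict:
        reasons = self.dropped["reason"].value_counts().to_dict()
        return {
            "n_runs_in": self.n_runs_in,
            "n_runs_retained": self.n_runs_retained,
            "n_dropped": int(len(self.dropped)),
            "dropped_by_reason": reasons,
            "c_mean": self.c_mean,
            "c_sd": self.c_sd,
        }


def qc_filter(
    runs: pd.DataFrame,
    srd_max: float = 0.50,
    sd_mult: float = 2.0,
) -> tuple[pd.DataFrame, QCReport]:
    """Apply the replicate-concordance and low-recovery exclusion rules.

    For each duplicate pair with |SRD| > ``srd_max`` the replicate with the
    lower reference-glycopeptide recovery is dropped.  Additionally, any run
    whose C falls more than ``sd_mult`` standard deviations below the dataset
    mean C is dropped (one-sided rule; mean and SD are computed over all runs
    before any exclusion, in a single pass).  A run is dropped for exactly one
    reason; the concordance rule is applied first.

    Returns the retained subset of ``runs`` and a :class:`QCReport`.
    """
    c = reference_sums(runs)
    counts = c.groupby("sample_id")["replicate_idx"].count()
    if (counts > 2).any():
        bad = counts[counts > 2].index.tolist()
        raise ValueError(f"samples with more than two runs: {bad}")

    c_mean = float(c["C"].mean())
    c_sd = float(c["C"].std(ddof=1)) if len(c) > 1 else 0.0
    low_threshold = c_mean - sd_mult * c_sd

    dropped: list[tuple] = []
    dropped_keys: set[tuple] = set()
    srd_rows = []
    for sid, grp in c.groupby("sample_id", sort=True):
        if len(grp) != 2:
            continue
        grp = grp.sort_values("replicate_idx")
        c1, c2 = grp["C"].tolist()
        srd = compute_srd(c1, c2)
        srd_rows.append((sid, c1, c2, srd))
        if abs(srd) > srd_max:
            loser = grp.iloc[int(np.argmin(grp["C"].to_numpy()))]
            key = (sid, int(loser["replicate_idx"]))
            dropped.append((*key, float(loser["C"]), "discordant_pair_lower_recovery"))
            dropped_keys.add(key)

    for _, row in c.iterrows():
        key = (row["sample_id"], int(row["replicate_idx"]))
        if key in dropped_keys:
            continue
        if row["C"] < low_threshold:
            dropped.append((*key, float(row["C"]), "low_recovery_2sd"))
            dropped_keys.add(key)

    dropped_df = pd.DataFrame(
        dropped, columns=["sample_id", "replicate_idx", "C", "reason"]
    )
    keys = pd.MultiIndex.from_frame(runs[["sample_id", "replicate_idx"]])
    keep = ~keys.isin(dropped_keys)
    retained = runs.loc[keep].reset_index(drop=True)
    report = QCReport(
        srd=pd.DataFrame(srd_rows, columns=["sample_id", "c1", "c2", "srd"]),
        dropped=dropped_df,
        c_mean=c_mean,
        c_sd=c_sd,
        sd_mult=sd_mult,
        n_runs_in=int(len(c)),
        n_runs_retained=int(len(c) - len(dropped_df)),
    )
    return retained, report


def is_correct(light, heavy, heavy_mean):
    """Internal-standard correction: ``(heavy_mean / heavy) * light``.

    The per-run instrument response cancels because light and heavy areas of
    the same precursor share it.  Accepts scalars or aligned arrays.
    """
    heavy = np.asarray(heavy, dtype=float)
    heavy_mean = np.asarray(heavy_mean, dtype=float)
    if np.any(heavy <= 0) or np.any(heavy_mean <= 0):
        raise ValueError("heavy areas and their cohort mean must be positive")
    return (heavy_mean / heavy) * np.asarray(light, dtype=float)


def enrichment_normalize(area, c_run, c_a):
    """Divide an area by the run's relative recovery ``c_run / c_a``."""
    c_run = np.asarray(c_run, dtype=float)
    if np.any(c_run <= 0) or c_a <= 0:
        raise ValueError("reference sums must be positive")
    return np.asarray(area, dtype=float) / (c_run / float(c_a))


def assemble_matrix(
    retained_runs: pd.DataFrame,
    clinical: pd.DataFrame,
    panel: pd.DataFrame,
    c_a: float | None = None,
    heavy_means: pd.Series | None = None,
    clinical_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Build the samples-by-features quantification matrix.

    Per peptide and run: IS-correct (IS-quantified peptides), then divide by
    the run's relative enrichment recovery, then average the replicates that
    survived QC.  Label-free peptides skip the IS step.  Clinical covariates
    are joined on ``sample_id``; the result carries ``diagnosis`` (and, when
    present, ``gleason``/``aggressiveness``) plus an ``n_runs_used``
    provenance column.

    ``c_a`` (cohort mean reference sum) and ``heavy_means`` (cohort mean
    heavy area per peptide) default to values computed over the retained
    runs; pass them explicitly to hold the cohort constants fixed.

    A peptide missing from one replicate is averaged over the available
    replicate; a peptide missing from every run of a sample is imputed at
    half the cohort minimum of that peptide and flagged in the
    ``imputed_features`` column.
    """
    if retained_runs.empty:
        raise ValueError("no retained runs")
    clinical_columns = clinical_columns or CLINICAL_COLUMNS

    c = reference_sums(retained_runs).set_index(["sample_id", "replicate_idx"])["C"]
    if c_a is None:
        c_a = float(c.mean())

    light = retained_runs[retained_runs["channel"] == "light"].copy()
    heavy = retained_runs[retained_runs["channel"] == "heavy"]
    heavy_by_run = heavy.set_index(["sample_id", "replicate_idx", "peptide_id"])["area"]
    if heavy_means is None:
        heavy_means = heavy.groupby("peptide_id")["area"].mean()

    is_peptides = set(panel.loc[panel["quant_mode"] == "IS", "peptide_id"])
    panel_peptides = panel["peptide_id"].tolist()
    light = light[light["peptide_id"].isin(panel_peptides)]

    run_keys = pd.MultiIndex.from_frame(light[["sample_id", "replicate_idx"]])
    values = light["area"].to_numpy(dtype=float)

    needs_is = light["peptide_id"].isin(is_peptides).to_numpy()
    if needs_is.any():
        hkeys = pd.MultiIndex.from_frame(
            light[["sample_id", "replicate_idx", "peptide_id"]]
        )
        h = heavy_by_run.reindex(hkeys).to_numpy(dtype=float)
        hm = heavy_means.reindex(light["peptide_id"]).to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            corrected = np.where(needs_is & (h > 0), (hm / h) * values, values)
        missing_heavy = needs_is & ~(h > 0)
        if missing_heavy.any():
            warnings.warn(
                f"{int(missing_heavy.sum())} light observations lack a heavy "
                "area; left uncorrected",
                stacklevel=2,
            )
        values = corrected

    values = values / (c.reindex(run_keys).to_numpy(dtype=float) / c_a)
    light = light.assign(norm_area=values)

    mat = (
        light.pivot_table(
            index="sample_id", columns="peptide_id", values="norm_area", aggfunc="mean"
        )
        .reindex(columns=panel_peptides)
    )
    n_runs = (
        retained_runs.groupby("sample_id")["replicate_idx"].nunique().rename("n_runs_used")
    )

    # fully missing sample/peptide cells: impute at half the cohort minimum
    imputed = []
    for pep in mat.columns:
        col = mat[pep]
        if col.isna().any():
            fill = 0.5 * float(col.min()) if col.notna().any() else 0.0
            for sid in mat.index[col.isna()]:
                imputed.append((sid, pep))
            mat[pep] = col.fillna(fill)

    missing_clinical = set(mat.index) - set(clinical["sample_id"])
    if missing_clinical:
        raise ValueError(
            f"samples missing from the clinical table: {sorted(missing_clinical)}"
        )
    meta_cols = ["sample_id", "diagnosis"] + [
        col for col in ("gleason", "aggressiveness") if col in clinical.columns
    ]
    out = (
        clinical[meta_cols + [c_ for c_ in clinical_columns if c_ in clinical.columns]]
        .set_index("sample_id")
        .join(mat, how="inner")
        .join(n_runs, how="left")
    )
    flags = pd.Series("", index=out.index, name="imputed_features")
    for sid, pep in imputed:
        flags.loc[sid] = (flags.loc[sid] + ";" + pep).lstrip(";")
    out["imputed_features"] = flags
    if (out.select_dtypes("number") < 0).any().any():
        raise ValueError("negative values in assembled matrix")
    return out.reset_index()
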