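"""Discovery-phase candidate selection for the PRM glycopeptide panel.

The discovery experiments (two TMT comparisons of pooled PCa vs BPH sera plus
a label-free spectral-library experiment) yield tables of formerly
N-glycosylated tryptic peptides with fold-changes and p-values.  This module
implements the rules that turn those tables into the targeted-MS candidate
panel: sequon detection, missed-cleavage counting, threshold filtering with a
literature-rescue branch, and deduplicated merging of candidate lists with
provenance tracking.

Packaged fixtures (``glycoprm.data``) carry the published candidate tables and
the final verification panel so that every rule can be exercised against the
real lists.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "VALID_RESIDUES",
    "FilterPolicy",
    "find_sequons",
    "count_missed_cleavages",
    "filter_candidates",
    "merge_candidate_lists",
    "load_candidate_table",
    "load_verification_panel",
    "load_consensus_grid",
    "n_proteins",
]

#: the twenty proteinogenic amino acids, one-letter upper case
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

# Packaged table name -> file
_DATA_FILES = {
    "tmt_a": "tmt_a_candidates.tsv",
    "tmt_b": "tmt_b_candidates.tsv",
    "3d": "discovery_3d_candidates.tsv",
    "prm_panel": "prm_panel_34.tsv",
    "verification_panel": "verification_panel.tsv",
    "consensus_grid": "consensus_grid.tsv",
}


def _check_sequence(sequence: str) -> str:
    if not isinstance(sequence, str) or not sequence:
        raise ValueError("peptide sequence must be a non-empty string")
    bad = set(sequence) - VALID_RESIDUES
    if bad:
        raise ValueError(
            f"invalid residues {sorted(bad)} in sequence {sequence!r}; "
            "expected upper-case one-letter amino-acid codes"
        )
    return sequence


def find_sequons(sequence: str, exclude_proline: bool = True) -> list[int]:
    """Locate N-glycosylation sequons (N-X-S/T) in a peptide.

    Returns 1-based positions ``i`` such that ``sequence[i] == 'N'`` and
    ``sequence[i+2]`` is S or T.  By biochemical convention X = P abolishes
    glycosylation, so positions with a proline at X are skipped unless
    ``exclude_proline=False``.

    >>> find_sequons("SNSSMHITDCR")
    [2]
    >>> find_sequons("NPSA"), find_sequons("NASA")
    ([], [1])
    """
    _check_sequence(sequence)
    hits = []
    for i in range(len(sequence) - 2):
        if sequence[i] != "N":
            continue
        if exclude_proline and sequence[i + 1] == "P":
            continue
        if sequence[i + 2] in "ST":
            hits.append(i + 1)
    return hits


def count_missed_cleavages(sequence: str) -> int:
    """Number of internal tryptic sites (K/R not followed by P) in a peptide.

    The C-terminal residue is never counted: a peptide ending in K or R is a
    fully cleaved tryptic product.
    """
    _check_sequence(sequence)
    n = 0
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR" and sequence[i + 1] != "P":
            n += 1
    return n


@dataclass(frozen=True)
class FilterPolicy:
    """Thresholds of the discovery-phase candidate filter.

    The rescue branch admits peptides with a fold-change between
    ``fc_rescue_min`` and ``fc_min`` when their protein has documented disease
    involvement (``literature_flag``).  Fold-change comparisons are inclusive
    (``>=``): the published lists retain a candidate printed exactly at 1.09
    under a "> 1.08" rule, so boundary values pass.

    ``max_missed_cleavages`` defaults to 1: the published candidate lists
    retain one peptide with a single internal missed cleavage, and the
    discovery database search itself tolerated up to two.
    """

    p_max: float = 0.1
    fc_min: float = 1.2
    fc_rescue_min: float = 1.08
    max_length: int = 25
    max_missed_cleavages: int = 1
    require_sequon: bool = True
    sequon_exclude_proline: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.p_max < 1:
            raise ValueError("p_max must lie in (0, 1)")
        if not 0 < self.fc_rescue_min < self.fc_min:
            raise ValueError("need 0 < fc_rescue_min < fc_min")
        if self.max_length < 1 or self.max_missed_cleavages < 0:
            raise ValueError("max_length/max_missed_cleavages out of range")


def _parse_glycosites(value) -> list[int]:
    """Annotated glycosite column: int, 'i' or 'i;j' string, or empty."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return []
    if isinstance(value, (int, float)):
        return [int(value)]
    text = str(value).strip()
    if not text:
        return []
    return [int(tok) for tok in text.replace(",", ";").split(";") if tok.strip()]


def _has_sequon(row: pd.Series, policy: FilterPolicy) -> bool:
    # Detected motif wins; otherwise fall back on the experimentally annotated
    # glycosite (some published glycosites sit at the tryptic C-terminus where
    # the S/T of the sequon belongs to the next peptide, or are non-canonical).
    if find_sequons(row["sequence"], exclude_proline=policy.sequon_exclude_proline):
        return True
    if "glycosite" in row.index:
        sites = _parse_glycosites(row["glycosite"])
        seq = row["sequence"]
        return any(1 <= s <= len(seq) and seq[s - 1] == "N" for s in sites)
    return False


def filter_candidates(
    table: pd.DataFrame, policy: FilterPolicy | None = None
) -> pd.DataFrame:
    """Apply the discovery-phase selection rules to a candidate table.

    Required columns: ``sequence``, ``fold_change``, ``p_value``; optional
    ``literature_flag`` (rescue branch, default False) and ``glycosite``
    (annotated site fallback for the sequon rule).

    Returns a copy of the table with two added columns: boolean ``retained``
    and ``rejection_reason`` (the first failing rule, in the order ``p_value``,
    ``sequon``, ``length``, ``missed_cleavages``, ``fold_change``; empty string
    for retained rows).
    """
    policy = policy or FilterPolicy()
    out = table.copy()
    if out.empty:
        out["retained"] = pd.Series(dtype=bool)
        out["rejection_reason"] = pd.Series(dtype=str)
        return out

    lit = (
        out["literature_flag"].fillna(False).astype(bool)
        if "literature_flag" in out.columns
        else pd.Series(False, index=out.index)
    )
    reasons = []
    for idx, row in out.iterrows():
        seq = _check_sequence(row["sequence"])
        reason = ""
        if not row["p_value"] < policy.p_max:
            reason = "p_value"
        elif policy.require_sequon and not _has_sequon(row, policy):
            reason = "sequon"
        elif len(seq) > policy.max_length:
            reason = "length"
        elif count_missed_cleavages(seq) > policy.max_missed_cleavages:
            reason = "missed_cleavages"
        elif not (
            row["fold_change"] >= policy.fc_min
            or (row["fold_change"] >= policy.fc_rescue_min and lit.loc[idx])
        ):
            reason = "fold_change"
        reasons.append(reason)

    out["rejection_reason"] = reasons
    out["retained"] = out["rejection_reason"] == ""
    return out


def merge_candidate_lists(*tables: pd.DataFrame) -> pd.DataFrame:
    """Deduplicated union of candidate tables, keyed by peptide sequence.

    Provenance (``source_experiment``) is accumulated across lists as a
    sorted ``+``-joined string.  A sequence annotated with conflicting gene
    symbols in different lists raises ``ValueError``.
    """
    merged: dict[str, dict] = {}
    for table in tables:
        if table["sequence"].duplicated().any():
            dup = table.loc[table["sequence"].duplicated(), "sequence"].iloc[0]
            raise ValueError(f"input list not unique by sequence: {dup!r}")
        for _, row in table.iterrows():
            seq = _check_sequence(row["sequence"])
            sources = set()
            for tok in str(row.get("source_experiment", "") or "").split("+"):
                if tok.strip():
                    sources.add(tok.strip())
            if seq not in merged:
                rec = row.to_dict()
                rec["source_experiment"] = sources
                merged[seq] = rec
            else:
                rec = merged[seq]
                if str(rec.get("gene")) != str(row.get("gene")):
                    raise ValueError(
                        f"conflicting gene annotation for {seq!r}: "
                        f"{rec.get('gene')} vs {row.get('gene')}"
                    )
                rec["source_experiment"] |= sources
                # keep first occurrence's stats; provenance is the union
                for col, val in row.items():
                    if col not in rec or pd.isna(rec[col]):
                        rec[col] = val
    rows = []
    for rec in merged.values():
        rec = dict(rec)
        rec["source_experiment"] = "+".join(sorted(rec["source_experiment"]))
        rows.append(rec)
    return pd.DataFrame(rows).reset_index(drop=True)


def n_proteins(table: pd.DataFrame, key: str = "gene") -> int:
    """Number of distinct proteins (by gene symbol) in a candidate table."""
    return int(table[key].nunique())


def _read_packaged(name: str) -> pd.DataFrame:
    fname = _DATA_FILES[name]
    with resources.files("glycoprm.data").joinpath(fname).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_candidate_table(experiment: str) -> pd.DataFrame:
    """Load a packaged discovery candidate table.

    ``experiment`` is one of ``"tmt_a"``, ``"tmt_b"``, ``"3d"`` (the three
    discovery lists) or ``"prm_panel"`` (the merged 34-candidate panel).
    """
    if experiment not in ("tmt_a", "tmt_b", "3d", "prm_panel"):
        raise KeyError(f"unknown candidate table {experiment!r}")
    return _read_packaged(experiment)


def load_verification_panel() -> pd.DataFrame:
    """The final 32-peptide verification panel (29 IS + 3 label-free).

    This panel is an explicit editable file rather than a derived object:
    the assay-development exclusions (two PZP peptides and the ENG peptide
    dropped; the NCAM1 peptide complemented by DGQLLPSSNYSNIK) rest on
    empirical solubility/peak-shape grounds that cannot be recomputed.
    """
    return _read_packaged("verification_panel")


def load_consensus_grid() -> pd.DataFrame:
    """The published variables-by-selectors boolean grid (11 printed rows)."""
    df = _read_packaged("consensus_grid")
    return df.set_index("feature").astype(bool)
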