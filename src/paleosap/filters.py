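"""PSM retention rules, protein acceptance and SAP acceptance filtering.

Three layers of quality control are applied to cross-species search results:

* **PSM retention** — a PSM is kept only if its peptide is at least 10
  residues long (by default), its spectrum was matched in the ground-truth
  search, it does not hit a contaminant or an excluded (absent or
  mispredicted) protein/region, and it clears the score/FDR threshold.
* **Protein acceptance** — a protein is reported only with at least two
  PSMs of distinct peptide sequences (distinct after I/L collapsing).
* **SAP acceptance** — a suggested substitution at a protein position is
  accepted only when at least two PSMs carry it *and* those PSMs form a
  strict majority of all PSMs covering that position. This is the filter
  that, in practice, removes every incorrectly suggested substitution at
  the cost of discarding correct singletons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import (
    Dict,
    FrozenSet,
    Iterable,
    List,
    Mapping,
    Optional,
    Sequence,
    Set,
    Tuple,
    Union,
)

import pandas as pd

from .digest import collapse_il

PSM_COLUMNS = [
    "dataset_id",
    "scan_id",
    "search_label",
    "accession",
    "start",
    "end",
    "peptide",
    "modifications",
    "score",
    "substitutions",
]

#: removal reasons in precedence order (a PSM violating several rules is
#: logged once, under the first applicable reason)
REMOVAL_REASONS = (
    "length",
    "no_search1_match",
    "contaminant",
    "excluded_protein",
    "excluded_region",
    "score",
)


@dataclass(frozen=True)
class FilterCriteria:
    min_peptide_length: int = 10
    #: per-PSM FDR ceiling (requires an ``fdr`` column) — mutually exclusive
    #: with ``score_min``
    fdr_max: Optional[float] = None
    #: minimum acceptable score — mutually exclusive with ``fdr_max``
    score_min: Optional[float] = None
    contaminant_accessions: FrozenSet[str] = frozenset()
    excluded_accessions: FrozenSet[str] = frozenset()
    excluded_regions: Tuple[Tuple[str, int, int], ...] = ()
    require_search1_match: bool = True

    def __post_init__(self) -> None:
        if self.min_peptide_length < 1:
            raise ValueError("min_peptide_length must be >= 1")
        if (self.fdr_max is None) == (self.score_min is None):
            raise ValueError("exactly one of fdr_max / score_min must be set")


@dataclass(frozen=True)
class SAPCall:
    """A candidate substitution at a protein position, with its support."""

    accession: str
    position: int
    db_aa: str
    observed_aa: str
    n_mutated_psms: int
    n_total_psms_at_position: int
    accepted: bool
    correctness: str = "unknown"  # known-correct | known-incorrect | unknown

    def __post_init__(self) -> None:
        if self.n_mutated_psms > self.n_total_psms_at_position:
            raise ValueError("more mutated than covering PSMs")
        should = (
            self.n_mutated_psms >= 2
            and 2 * self.n_mutated_psms > self.n_total_psms_at_position
        )
        if self.accepted != should:
            raise ValueError("acceptance flag inconsistent with support counts")


def _validate_table(psms: pd.DataFrame, need_fdr: bool) -> None:
    missing = [c for c in PSM_COLUMNS if c not in psms.columns]
    if missing:
        raise ValueError(f"PSM table missing columns: {missing}")
    if need_fdr and "fdr" not in psms.columns:
        raise ValueError("fdr_max filtering requires an 'fdr' column")
    bad = psms.index[
        (psms["end"] < psms["start"])
        | (psms["peptide"].str.len() != psms["end"] - psms["start"] + 1)
    ].tolist()
    if bad:
        raise ValueError(f"malformed PSM rows (coordinates/peptide): lines {bad}")


def filter_psms(
    psms: pd.DataFrame,
    criteria: FilterCriteria,
    search1_keys: Optional[Set[Tuple[str, str]]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the PSM retention rules; return (retained, removal log).

    ``search1_keys`` is the set of (dataset_id, scan_id) pairs matched in the
    ground-truth search; it is required when
    ``criteria.require_search1_match`` is true. The removal log has one row
    per removed PSM with a single reason, assigned by the fixed precedence
    length > search1-match > contaminant > excluded-protein/region > score,
    so logs are deterministic. Retained and removed partition the input.
    """
    _validate_table(psms, need_fdr=criteria.fdr_max is not None)
    if criteria.require_search1_match and search1_keys is None:
        raise ValueError("require_search1_match needs search1_keys")

    reason = pd.Series("", index=psms.index, dtype=object)

    def mark(mask: pd.Series, why: str) -> None:
        reason[mask & (reason == "")] = why

    length = psms["end"] - psms["start"] + 1
    mark(length < criteria.min_peptide_length, "length")
    if criteria.require_search1_match:
        keys = list(zip(psms["dataset_id"], psms["scan_id"]))
        in_s1 = pd.Series([k in search1_keys for k in keys], index=psms.index)
        mark(~in_s1, "no_search1_match")
    mark(psms["accession"].isin(criteria.contaminant_accessions), "contaminant")
    mark(psms["accession"].isin(criteria.excluded_accessions), "excluded_protein")
    if criteria.excluded_regions:
        region_mask = pd.Series(False, index=psms.index)
        for acc, r_start, r_end in criteria.excluded_regions:
            region_mask |= (
                (psms["accession"] == acc)
                & (psms["start"] <= r_end)
                & (psms["end"] >= r_start)
            )
        mark(region_mask, "excluded_region")
    if criteria.fdr_max is not None:
        mark(psms["fdr"] > criteria.fdr_max, "score")
    else:
        mark(psms["score"] < criteria.score_min, "score")

    removed = reason != ""
    log = psms.loc[removed, ["dataset_id", "scan_id", "accession"]].copy()
    log["reason"] = reason[removed]
    return psms.loc[~removed].copy(), log.reset_index(drop=True)


def accept_proteins(psms: pd.DataFrame) -> List[str]:
    """Accessions supported by >= 2 PSMs with distinct peptide sequences.

    Distinctness is judged after I/L collapsing, so two PSMs differing only
    by an I/L swap do not count as independent evidence.
    """
    if psms.empty:
        return []
    collapsed = psms["peptide"].map(collapse_il)
    n_unique = collapsed.groupby(psms["accession"]).nunique()
    return sorted(n_unique.index[n_unique >= 2])


def position_coverage(
    psms: pd.DataFrame, positions: Iterable[Tuple[str, int]]
) -> Dict[Tuple[str, int], int]:
    """Number of PSMs covering each (accession, position) of interest."""
    wanted: Dict[str, List[int]] = {}
    for acc, pos in positions:
        wanted.setdefault(acc, []).append(pos)
    out: Dict[Tuple[str, int], int] = {}
    for acc, pos_list in wanted.items():
        sub = psms[psms["accession"] == acc]
        for pos in pos_list:
            out[(acc, pos)] = int(
                ((sub["start"] <= pos) & (sub["end"] >= pos)).sum()
            )
    return out


def accept_saps(
    observations: pd.DataFrame,
    coverage: Union[Mapping[Tuple[str, int], int], pd.DataFrame],
) -> List[SAPCall]:
    """Apply the two-PSM-plus-strict-majority acceptance rule.

    ``observations`` has one row per suggested substitution per mutated PSM:
    columns accession, position, db_aa, observed_aa, and optionally
    correctness (known-correct / known-incorrect / unknown). Each distinct
    (accession, position, observed_aa) is evaluated separately. ``coverage``
    maps (accession, position) to the total number of PSMs covering the
    position (computed over the retained PSM table, e.g. via
    :func:`position_coverage`). A call is accepted iff it is carried by at
    least two PSMs and those PSMs form a strict majority of the covering
    PSMs; ties reject.
    """
    if observations.empty:
        return []
    if isinstance(coverage, pd.DataFrame):
        coverage = {
            (r.accession, int(r.position)): int(r.n_total_psms)
            for r in coverage.itertuples()
        }
    has_corr = "correctness" in observations.columns
    calls: List[SAPCall] = []
    grouped = observations.groupby(
        ["accession", "position", "db_aa", "observed_aa"], sort=True
    )
    for (acc, pos, db_aa, obs_aa), grp in grouped:
        pos = int(pos)
        n_mut = len(grp)
        try:
            n_tot = int(coverage[(acc, pos)])
        except KeyError:
            raise KeyError(f"no coverage for position {acc}:{pos}") from None
        if has_corr:
            labels = set(grp["correctness"])
            correctness = labels.pop() if len(labels) == 1 else "unknown"
        else:
            correctness = "unknown"
        accepted = n_mut >= 2 and 2 * n_mut > n_tot
        calls.append(
            SAPCall(
                accession=acc,
                position=pos,
                db_aa=db_aa,
                observed_aa=obs_aa,
                n_mutated_psms=n_mut,
                n_total_psms_at_position=n_tot,
                accepted=accepted,
                correctness=correctness,
            )
        )
    return calls


def accepted_psm_ids(
    observations: pd.DataFrame, calls: Sequence[SAPCall]
) -> Set:
    """PSM ids whose every suggested substitution was accepted.

    ``observations`` must carry a ``psm_id`` column; a mutated PSM survives
    SAP filtering only if each of its substitutions is an accepted call
    (both-or-nothing for multi-substitution PSMs).
    """
    if "psm_id" not in observations.columns:
        raise ValueError("observations need a psm_id column")
    accepted = {
        (c.accession, c.position, c.observed_aa) for c in calls if c.accepted
    }
    ok = [
        (r.accession, int(r.position), r.observed_aa) in accepted
        for r in observations.itertuples()
    ]
    flags = pd.Series(ok, index=observations.index).groupby(
        observations["psm_id"]
    ).all()
    return set(flags.index[flags])
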