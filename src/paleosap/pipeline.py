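"""End-to-end synthetic experiment: simulate, filter, classify, summarize.

This is the glue that reproduces the structure of the cross-species search
experiment on simulated data: a ground-truth search of the target data
against its own proteome, one error-tolerant search per divergent database,
PSM retention filtering, outcome classification of every mutable PSM,
SAP acceptance filtering, and the recovery statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

import pandas as pd

from .classify import (
    Outcome,
    OutcomeRecord,
    classify_outcome,
    outcome_accounting,
    AccountingTable,
)
from .digest import UNALIGNABLE
from .filters import (
    FilterCriteria,
    SAPCall,
    accept_saps,
    accepted_psm_ids,
    filter_psms,
    position_coverage,
)
from .io import psm_record_from_row
from .sim import (
    OrthologTruth,
    ReferenceProteome,
    SimulationConfig,
    evolve_proteome,
    generate_reference_proteome,
    simulate_search,
)
from .stats import recovery_stats

#: default score threshold for synthetic data, sitting between the bulk of
#: the incorrect and correct score laws
DEFAULT_SCORE_MIN = 15.0


@dataclass
class SearchResult:
    """Everything derived from one cross-species search."""

    db_label: str
    database: ReferenceProteome
    truth: OrthologTruth
    psms: pd.DataFrame  # retained cross-species PSMs
    removal_log: pd.DataFrame
    outcome_records: List[OutcomeRecord]
    #: cross-species mutated PSMs on non-mutable scans (spurious suggestions)
    off_target: pd.DataFrame
    sap_observations: pd.DataFrame
    sap_calls: List[SAPCall]
    accepted_psms: Set[Tuple[str, str]]
    accounting_unfiltered: AccountingTable
    accounting_filtered: AccountingTable
    recovery: pd.DataFrame
    scan_distance: Dict[Tuple[str, str], int]


@dataclass
class ExperimentResult:
    config: SimulationConfig
    target: ReferenceProteome
    search1: pd.DataFrame  # retained ground-truth PSMs
    search1_removal_log: pd.DataFrame
    searches: Dict[str, SearchResult]


def _default_criteria(
    target: ReferenceProteome, **overrides
) -> FilterCriteria:
    base = dict(
        min_peptide_length=10,
        score_min=DEFAULT_SCORE_MIN,
        contaminant_accessions=frozenset(target.contaminants),
    )
    base.update(overrides)
    return FilterCriteria(**base)


def mutated_observations(
    psms: pd.DataFrame, correctness: Optional[Dict[Tuple[str, str], str]] = None
) -> pd.DataFrame:
    """One row per suggested substitution of each mutated PSM."""
    from .io import parse_substitutions

    rows = []
    for r in psms.itertuples():
        subs = parse_substitutions(r.substitutions)
        if not subs:
            continue
        psm_key = (r.dataset_id, r.scan_id)
        label = correctness.get(psm_key, "unknown") if correctness else "unknown"
        for pos, db_aa, obs_aa in subs:
            rows.append(
                (r.dataset_id, r.scan_id, psm_key, r.accession, pos, db_aa, obs_aa, label)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "dataset_id",
            "scan_id",
            "psm_id",
            "accession",
            "position",
            "db_aa",
            "observed_aa",
            "correctness",
        ],
    )


def analyze_search(
    target: ReferenceProteome,
    database: ReferenceProteome,
    truth: OrthologTruth,
    config: SimulationConfig,
    s1: pd.DataFrame,
    criteria_overrides: Optional[dict] = None,
    cross_raw: Optional[pd.DataFrame] = None,
) -> SearchResult:
    """Filter, classify and summarize one cross-species search.

    ``s1`` is the retained ground-truth PSM table. The cross-species search
    is simulated from (target, database, truth) unless a raw table is
    supplied. Applies the retention rules (length, ground-truth-search
    match, contaminants, absent/mispredicted proteins, score), classifies
    every mutable PSM into outcomes 1-4, applies the SAP acceptance filter
    and computes accounting and recovery tables.
    """
    overrides = criteria_overrides or {}
    db_label = database.taxon
    s1_keys = set(zip(s1["dataset_id"], s1["scan_id"]))
    s1_by_key = {(r.dataset_id, r.scan_id): r for r in s1.itertuples()}

    if cross_raw is None:
        cross_raw = simulate_search(target, database, truth, config)
    criteria = _default_criteria(
        target,
        require_search1_match=True,
        excluded_accessions=frozenset(truth.dropped),
        excluded_regions=tuple(
            (acc, s, e) for acc, (s, e) in sorted(truth.mispredicted.items())
        ),
        **overrides,
    )
    cross, log = filter_psms(cross_raw, criteria, search1_keys=s1_keys)
    cross_by_key = {(r.dataset_id, r.scan_id): r for r in cross.itertuples()}

    # ground-truth distance of every retained search-1 scan in this db
    site_maps = {
        acc: truth.site_map(acc, len(seq))
        for acc, seq in target.proteins.items()
        if acc not in target.contaminants and acc not in truth.dropped
    }
    scan_distance: Dict[Tuple[str, str], int] = {}
    outcome_records: List[OutcomeRecord] = []
    for key, row in s1_by_key.items():
        sm = site_maps.get(row.accession)
        if sm is None:
            continue  # dropped protein or contaminant: no ortholog
        if not sm.fully_aligned(row.start, row.end):
            continue  # overlaps a mispredicted region: excluded territory
        expected = sm.substitutions_in(row.start, row.end)
        scan_distance[key] = len(expected)
        if not expected:
            continue
        cross_row = cross_by_key.get(key)
        cross_psm = (
            psm_record_from_row(cross_row) if cross_row is not None else None
        )
        outcome_records.append(
            classify_outcome(psm_record_from_row(row), cross_psm, expected)
        )

    # correctness of each mutated cross-species PSM, from the outcomes;
    # mutated PSMs on non-mutable scans are spurious by construction
    correctness = {
        (r.dataset_id, r.scan_id): (
            "known-correct" if r.outcome is Outcome.CORRECT else "known-incorrect"
        )
        for r in outcome_records
        if r.n_suggested_substitutions >= 1
    }
    mutated = cross[cross["substitutions"] != ""]
    off_target_mask = [
        scan_distance.get((r.dataset_id, r.scan_id), 0) == 0
        for r in mutated.itertuples()
    ]
    off_target = mutated[pd.Series(off_target_mask, index=mutated.index)]
    for r in off_target.itertuples():
        correctness[(r.dataset_id, r.scan_id)] = "known-incorrect"

    observations = mutated_observations(mutated, correctness)
    if observations.empty:
        calls: List[SAPCall] = []
        kept: Set[Tuple[str, str]] = set()
    else:
        coverage = position_coverage(
            cross, set(zip(observations["accession"], observations["position"]))
        )
        calls = accept_saps(observations, coverage)
        kept = accepted_psm_ids(observations, calls)

    n_subs_by_psm = (
        observations.groupby("psm_id").size() if not observations.empty else {}
    )
    acct_rows = pd.DataFrame(
        {
            "search_label": db_label,
            "psm_id": list(correctness.keys()),
            "n_suggested_substitutions": [
                int(n_subs_by_psm.get(k, 0)) for k in correctness.keys()
            ],
            "correct": [v == "known-correct" for v in correctness.values()],
        }
    )
    acct_unf = outcome_accounting(acct_rows, filtered=False)
    acct_fil = outcome_accounting(
        acct_rows[acct_rows["psm_id"].isin(kept)], filtered=True
    )

    recovery = recovery_stats(s1, cross, scan_distance)

    return SearchResult(
        db_label=db_label,
        database=database,
        truth=truth,
        psms=cross,
        removal_log=log,
        outcome_records=outcome_records,
        off_target=off_target,
        sap_observations=observations,
        sap_calls=calls,
        accepted_psms=kept,
        accounting_unfiltered=acct_unf,
        accounting_filtered=acct_fil,
        recovery=recovery,
        scan_distance=scan_distance,
    )


def run_synthetic_experiment(
    config: SimulationConfig,
    criteria_overrides: Optional[dict] = None,
) -> ExperimentResult:
    """Run the full simulated cross-species experiment.

    Generates the target proteome, simulates and filters the ground-truth
    search, then runs :func:`analyze_search` for every configured database
    at its own divergence.
    """
    config.validate()
    overrides = criteria_overrides or {}
    target = generate_reference_proteome(config)

    s1_raw = simulate_search(target, target, None, config)
    s1_criteria = _default_criteria(
        target, require_search1_match=False, **overrides
    )
    s1, s1_log = filter_psms(s1_raw, s1_criteria)

    searches: Dict[str, SearchResult] = {}
    for db_index, db_label in enumerate(config.db_labels):
        database, truth = evolve_proteome(target, db_index, config)
        searches[db_label] = analyze_search(
            target, database, truth, config, s1, criteria_overrides=overrides
        )

    return ExperimentResult(
        config=config,
        target=target,
        search1=s1,
        search1_removal_log=s1_log,
        searches=searches,
    )
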