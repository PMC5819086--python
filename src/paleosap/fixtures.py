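"""Deterministic benchmark fixture for the accounting and SAP filters.

The fixture is a synthetic set of mutated-PSM observations for two
cross-species searches (a chimpanzee-like and an orangutan-like database)
whose marginal counts equal the published validity accounting of suggested
amino acid mutations: per search, the number of mutated PSMs carrying one or
two suggested substitutions, split into correct and incorrect calls, before
and after the two-PSM-plus-majority acceptance filter. The per-position
support groupings are synthesized minimally — incorrect calls and discarded
correct calls as singletons or minorities, accepted calls as small majority
groups — so that the filtered marginals emerge from the real filter code
rather than from bookkeeping.

Construction is fully deterministic (no randomness); the same tables are
also shipped as TSV files under ``paleosap/data`` and hash-pinned in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Sequence, Set, Tuple

import pandas as pd

from .filters import SAPCall, accept_saps, accepted_psm_ids

OBS_COLUMNS = [
    "search_label",
    "psm_id",
    "accession",
    "position",
    "db_aa",
    "observed_aa",
    "correctness",
]
COV_COLUMNS = ["search_label", "accession", "position", "n_total_psms"]

PAN = "Pan"
PONGO = "Pongo"


@dataclass
class ValidationFixture:
    """Mutated-PSM observations plus per-position PSM coverage."""

    observations: pd.DataFrame  # OBS_COLUMNS
    coverage: pd.DataFrame  # COV_COLUMNS

    def for_search(self, label: str) -> Tuple[pd.DataFrame, Dict[Tuple[str, int], int]]:
        obs = self.observations[self.observations["search_label"] == label]
        cov = self.coverage[self.coverage["search_label"] == label]
        cov_map = {
            (r.accession, int(r.position)): int(r.n_total_psms)
            for r in cov.itertuples()
        }
        return obs.reset_index(drop=True), cov_map


class _Builder:
    def __init__(self) -> None:
        self.obs: List[tuple] = []
        self.cov: List[tuple] = []
        self._psm_counter = 0

    def group(
        self,
        search: str,
        accession: str,
        n_psms: int,
        coverage_per_position: Sequence[Tuple[int, int]],
        db_aa: str,
        obs_aa: str,
        correctness: str,
    ) -> None:
        """``n_psms`` mutated PSMs all carrying the same substitution set.

        ``coverage_per_position`` lists (position, total covering PSMs); a
        PSM with several entries carries one substitution at each position.
        """
        for pos, total in coverage_per_position:
            self.cov.append((search, accession, pos, total))
        for _ in range(n_psms):
            self._psm_counter += 1
            psm_id = f"{search}-psm{self._psm_counter:04d}"
            for pos, _total in coverage_per_position:
                self.obs.append(
                    (search, psm_id, accession, pos, db_aa, obs_aa, correctness)
                )

    def build(self) -> ValidationFixture:
        return ValidationFixture(
            observations=pd.DataFrame(self.obs, columns=OBS_COLUMNS),
            coverage=pd.DataFrame(self.cov, columns=COV_COLUMNS),
        )


def build_validation_fixture() -> ValidationFixture:
    """Construct the benchmark observation/coverage tables.

    Chimpanzee-like search: 170 mutated PSMs, all single-substitution —
    32 incorrect (each a 1-of-3 minority at its position), 138 correct of
    which 13 are singletons (1-of-2) lost to filtering and 125 survive
    (55 positions supported 2-of-2 and 5 positions supported 3-of-4).

    Orangutan-like search: 435 mutated PSMs — 66 incorrect singletons
    (1-of-3), 352 correct single-substitution calls of which 24 are
    1-of-2 singletons and 328 survive (160 positions 2-of-2, 2 positions
    4-of-5), plus 17 correct two-substitution PSMs of which 15 survive
    (six positions-pairs supported 2-of-2 and one 3-of-3) and 2 are lost
    because one of their two positions is only a 2-of-5 minority.
    """
    b = _Builder()

    # --- chimpanzee-like search -------------------------------------------
    for i in range(32):
        b.group(PAN, f"PANI{i + 1:03d}", 1, [(50, 3)], "G", "W", "known-incorrect")
    for i in range(13):
        b.group(PAN, f"PANS{i + 1:03d}", 1, [(60, 2)], "A", "S", "known-correct")
    for i in range(55):
        b.group(PAN, f"PAND{i + 1:03d}", 2, [(70, 2)], "A", "S", "known-correct")
    for i in range(5):
        b.group(PAN, f"PANT{i + 1:03d}", 3, [(80, 4)], "A", "S", "known-correct")

    # --- orangutan-like search --------------------------------------------
    for i in range(66):
        b.group(PONGO, f"PGI{i + 1:03d}", 1, [(50, 3)], "G", "W", "known-incorrect")
    for i in range(24):
        b.group(PONGO, f"PGS{i + 1:03d}", 1, [(60, 2)], "A", "S", "known-correct")
    for i in range(160):
        b.group(PONGO, f"PGD{i + 1:03d}", 2, [(70, 2)], "A", "S", "known-correct")
    for i in range(2):
        b.group(PONGO, f"PGQ{i + 1:03d}", 4, [(80, 5)], "A", "S", "known-correct")
    for i in range(6):
        b.group(PONGO, f"PGM{i + 1:03d}", 2, [(40, 2), (48, 2)], "A", "S", "known-correct")
    b.group(PONGO, "PGM007", 3, [(40, 3), (48, 3)], "A", "S", "known-correct")
    b.group(PONGO, "PGX001", 2, [(40, 2), (48, 5)], "A", "S", "known-correct")

    return b.build()


def accounting_records(observations: pd.DataFrame) -> pd.DataFrame:
    """Per-PSM accounting rows (search, substitution count, correctness)."""
    grouped = observations.groupby(["search_label", "psm_id"], sort=True)
    rows = []
    for (search, psm_id), grp in grouped:
        correctness = set(grp["correctness"])
        rows.append(
            (
                search,
                psm_id,
                len(grp),
                correctness == {"known-correct"},
            )
        )
    return pd.DataFrame(
        rows,
        columns=["search_label", "psm_id", "n_suggested_substitutions", "correct"],
    )


def apply_sap_filter(
    fixture: ValidationFixture, search_label: str
) -> Tuple[List[SAPCall], Set[str]]:
    """Run the SAP acceptance filter on one search of the fixture.

    Returns the SAP calls and the ids of mutated PSMs whose every
    substitution was accepted (the PSMs surviving into the filtered
    accounting).
    """
    obs, cov = fixture.for_search(search_label)
    calls = accept_saps(obs, cov)
    kept = accepted_psm_ids(obs, calls)
    return calls, kept


def load_validation_fixture() -> ValidationFixture:
    """Load the TSV copies shipped with the package."""
    pkg = resources.files("paleosap").joinpath("data")
    obs = pd.read_csv(pkg.joinpath("benchmark_observations.tsv"), sep="\t")
    cov = pd.read_csv(pkg.joinpath("benchmark_coverage.tsv"), sep="\t")
    return ValidationFixture(observations=obs, coverage=cov)
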