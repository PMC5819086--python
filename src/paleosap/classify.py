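"""Outcome classification of mutable PSMs across database searches.

A mutable PSM is a spectrum whose ground-truth peptide (from the search
against the target's own proteome, "search 1") differs from the orthologous
sequence in a cross-species database by one or more single amino acid
polymorphisms (SAPs). For each such spectrum the cross-species search has
four possible outcomes:

1. the correct sequence was identified, i.e. every required substitution was
   suggested at the right position and of the right type (up to isobaric
   equivalence);
2. the spectrum was matched to the unmutated database sequence, with no
   substitution suggested;
3. a substitution was suggested, but at the wrong position or of the wrong
   type (including the case where only a subset of the required
   substitutions was suggested);
4. the spectrum was not matched at all.

Isobaric equivalence handles sequence differences a mass spectrometer cannot
resolve at the configured fragment tolerance: I vs L (identical mass),
formylated K vs R, and deamidated N/Q vs D/E. A PSM that explains a required
substitution by the corresponding isobaric modification is counted as
correct, not as outcome 2.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd
from pyteomics import mass as _pmass

from .digest import STANDARD_AA, collapse_il

_AA_SET = frozenset(STANDARD_AA)

#: monoisotopic residue masses (Da)
RESIDUE_MASS = {aa: _pmass.std_aa_mass[aa] for aa in STANDARD_AA}

#: monoisotopic modification masses (Da)
MODIFICATION_MASS = {
    "deamidation": _pmass.calculate_mass(formula="O") - _pmass.calculate_mass(formula="NH"),
    "formylation": _pmass.calculate_mass(formula="CO"),
}

# directional isobaric rules: (reported residue, modification) behaves like
# the substituted residue on the right
_ISOBARIC_MOD_RULES = {
    ("K", "formylation"): "R",
    ("N", "deamidation"): "D",
    ("Q", "deamidation"): "E",
}

DEFAULT_FRAGMENT_TOL_DA = 1.0


class Outcome(enum.IntEnum):
    CORRECT = 1
    NO_SUBSTITUTION = 2
    INCORRECT = 3
    UNMATCHED = 4


@dataclass(frozen=True)
class PSMRecord:
    """One scan's match in one search."""

    dataset_id: str
    scan_id: str
    search_label: str
    peptide: str
    accession: str
    start: int
    end: int
    score: float
    #: [(position, name, mass shift in Da)], protein coordinates
    modifications: Tuple[Tuple[int, str, float], ...] = ()
    #: [(position, db_aa, observed_aa)], protein coordinates
    suggested_substitutions: Tuple[Tuple[int, str, str], ...] = ()

    def __post_init__(self) -> None:
        if len(self.peptide) != self.end - self.start + 1:
            raise ValueError(
                f"{self.dataset_id}/{self.scan_id}: peptide length does not "
                "match coordinates"
            )
        for pos, *_ in list(self.modifications) + list(self.suggested_substitutions):
            if not (self.start <= pos <= self.end):
                raise ValueError(
                    f"{self.dataset_id}/{self.scan_id}: annotation position "
                    f"{pos} outside [{self.start}, {self.end}]"
                )

    @property
    def key(self) -> Tuple[str, str]:
        return (self.dataset_id, self.scan_id)


@dataclass(frozen=True)
class OutcomeRecord:
    """A mutable PSM joined across searches, with its outcome label."""

    scan_id: str
    dataset_id: str
    search_label: str
    evolutionary_distance: int
    outcome: Outcome
    peptide_length: int
    score_in_search1: float
    n_suggested_substitutions: int = 0

    def __post_init__(self) -> None:
        if self.evolutionary_distance < 1:
            raise ValueError("outcome records are defined for mutable PSMs only")
        if self.outcome is Outcome.UNMATCHED and self.n_suggested_substitutions:
            raise ValueError("an unmatched PSM cannot carry suggested substitutions")


def isobaric_substitution_equivalent(
    db_aa: str,
    obs_aa: str,
    modification: Optional[Union[str, Tuple[str, float]]] = None,
    fragment_tol_da: float = DEFAULT_FRAGMENT_TOL_DA,
) -> bool:
    """Is reporting ``db_aa`` (optionally modified) equivalent to ``obs_aa``?

    True iff (a) the pair is I/L (identical residue masses, no modification
    needed); or (b/c) ``db_aa`` carries a modification whose mass shift is
    within ``fragment_tol_da`` of the residue mass difference
    ``obs_aa - db_aa`` for one of the directional rules formyl-K == R,
    deamidated-N == D, deamidated-Q == E.

    ``modification`` may be a known name or a ``(name, observed mass shift)``
    pair; in the latter case the observed shift is used in the mass test.
    """
    if fragment_tol_da <= 0:
        raise ValueError("fragment_tol_da must be > 0")
    for aa in (db_aa, obs_aa):
        if aa not in _AA_SET:
            raise ValueError(f"unknown residue {aa!r}")
    if modification is None:
        return {db_aa, obs_aa} == {"I", "L"}
    if isinstance(modification, tuple):
        name, shift = modification
    else:
        name, shift = modification, None
    name = name.lower()
    if name not in MODIFICATION_MASS:
        raise ValueError(f"unknown modification {name!r}")
    if shift is None:
        shift = MODIFICATION_MASS[name]
    if _ISOBARIC_MOD_RULES.get((db_aa, name)) != obs_aa:
        return False
    delta = RESIDUE_MASS[obs_aa] - RESIDUE_MASS[db_aa]
    return abs(delta - shift) <= fragment_tol_da


def _normalize_reported(psm: PSMRecord, fragment_tol_da: float) -> str:
    """Reported sequence with isobaric modifications resolved to residues.

    A formylated K becomes R, a deamidated N becomes D and a deamidated Q
    becomes E (if the mass shift is consistent at the fragment tolerance);
    every other modification leaves the sequence untouched. I/L collapsing is
    applied last.
    """
    chars = list(psm.peptide)
    for pos, name, shift in psm.modifications:
        residue = chars[pos - psm.start]
        target = _ISOBARIC_MOD_RULES.get((residue, name.lower()))
        if target is None:
            continue
        if isobaric_substitution_equivalent(
            residue, target, (name.lower(), shift), fragment_tol_da
        ):
            chars[pos - psm.start] = target
    return collapse_il("".join(chars))


def classify_outcome(
    search1_psm: PSMRecord,
    crossspecies_psm: Optional[PSMRecord],
    expected_substitutions: Sequence[Tuple[int, str, str]],
    fragment_tol_da: float = DEFAULT_FRAGMENT_TOL_DA,
) -> OutcomeRecord:
    """Label one mutable PSM with its cross-species search outcome.

    ``expected_substitutions`` is the ground-truth SAP set for the peptide
    region, ``(position, target_aa, db_aa)`` from a site map; it must be
    non-empty (the PSM must be mutable). ``crossspecies_psm`` is the match of
    the same spectrum in the cross-species search, or ``None`` when the
    spectrum went unmatched (outcome 4).
    """
    if not expected_substitutions:
        raise ValueError("classify_outcome requires a mutable PSM (>=1 expected SAP)")
    distance = len(expected_substitutions)
    common = dict(
        scan_id=search1_psm.scan_id,
        dataset_id=search1_psm.dataset_id,
        evolutionary_distance=distance,
        peptide_length=len(search1_psm.peptide),
        score_in_search1=search1_psm.score,
    )
    if crossspecies_psm is None:
        return OutcomeRecord(
            search_label=search1_psm.search_label,
            outcome=Outcome.UNMATCHED,
            n_suggested_substitutions=0,
            **common,
        )
    if crossspecies_psm.key != search1_psm.key:
        raise ValueError(
            f"scan mismatch: {crossspecies_psm.key} vs {search1_psm.key}"
        )
    reconstructed = _normalize_reported(crossspecies_psm, fragment_tol_da)
    target_seq = collapse_il(search1_psm.peptide)
    n_sug = len(crossspecies_psm.suggested_substitutions)
    if reconstructed == target_seq:
        outcome = Outcome.CORRECT
    elif n_sug == 0:
        outcome = Outcome.NO_SUBSTITUTION
    else:
        outcome = Outcome.INCORRECT
    return OutcomeRecord(
        search_label=crossspecies_psm.search_label,
        outcome=outcome,
        n_suggested_substitutions=n_sug,
        **common,
    )


@dataclass
class AccountingTable:
    """Counts and percentages of mutated PSMs by substitution multiplicity.

    Rows are keyed by (number of suggested substitutions, correctness);
    there is one count/percentage column pair per search label. Percentages
    are relative to each search's total mutated PSMs, so each column sums to
    100 up to rounding. ``filtered`` records whether the underlying records
    passed the SAP acceptance filter.
    """

    table: pd.DataFrame
    totals: "pd.Series[int]"
    filtered: bool = False

    def count(self, search_label: str, n_mutations: int, correct: bool) -> int:
        key = (n_mutations, "correct" if correct else "incorrect")
        if key not in self.table.index:
            return 0
        return int(self.table.loc[key, (search_label, "count")])

    def percentage(self, search_label: str, n_mutations: int, correct: bool) -> float:
        key = (n_mutations, "correct" if correct else "incorrect")
        if key not in self.table.index:
            return 0.0
        return float(self.table.loc[key, (search_label, "percent")])

    def total(self, search_label: str) -> int:
        return int(self.totals[search_label])

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index = [f"{n} mutation{'s' if n != 1 else ''} ({c})" for n, c in out.index]
        out.loc["Total PSMs"] = [
            self.totals[s] if kind == "count" else 100.0
            for s, kind in out.columns
        ]
        out.to_csv(path, sep="\t")


def _records_frame(
    records: Union[pd.DataFrame, Iterable[OutcomeRecord]],
) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        if "correct" not in df.columns:
            df["correct"] = df["outcome"] == int(Outcome.CORRECT)
        return df
    rows = []
    for r in records:
        rows.append(
            (
                r.search_label,
                r.n_suggested_substitutions,
                r.outcome is Outcome.CORRECT,
                int(r.outcome),
            )
        )
    return pd.DataFrame(
        rows, columns=["search_label", "n_suggested_substitutions", "correct", "outcome"]
    )


def outcome_accounting(
    records: Union[pd.DataFrame, Iterable[OutcomeRecord]],
    filtered: bool = False,
) -> AccountingTable:
    """Tabulate mutated PSMs by search, multiplicity and correctness.

    Only mutated PSMs enter the accounting: records whose match carries at
    least one suggested substitution (outcomes 1 and 3, plus any off-target
    mutated PSMs supplied by the caller, which count as incorrect).
    Percentages are per search column, relative to that search's total
    mutated PSMs. An empty input yields an empty table.
    """
    df = _records_frame(records)
    df = df[df["n_suggested_substitutions"] >= 1]
    if df.empty:
        empty = pd.DataFrame()
        return AccountingTable(table=empty, totals=pd.Series(dtype=int), filtered=filtered)
    df = df.assign(
        correctness=df["correct"].map({True: "correct", False: "incorrect"})
    )
    counts = (
        df.groupby(["n_suggested_substitutions", "correctness", "search_label"])
        .size()
        .unstack("search_label", fill_value=0)
    )
    totals = counts.sum(axis=0).astype(int)
    percent = 100.0 * counts / totals
    table = pd.concat({"count": counts, "percent": percent}, axis=1)
    # -> columns (search_label, {count, percent})
    table = table.swaplevel(axis=1).sort_index(axis=1)
    table = table.sort_index()
    return AccountingTable(table=table, totals=totals, filtered=filtered)
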