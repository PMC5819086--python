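"""Synthetic proteome trios, peptides and search-result tables.

This module emulates the structure of the cross-species proteomics
experiment: a target proteome (the organism actually measured), one or more
database proteomes at configurable evolutionary divergence from it, an
in-silico digest of the target, and a stochastic identification model that
turns peptides into peptide-spectrum match (PSM) tables — one table per
database search, with scan identifiers shared across searches so that the
same underlying spectrum can be followed from the ground-truth search to the
cross-species searches.

The identification model is logistic in peptide length and SAP count:

    P(identified) = sigmoid(base_logit
                            + length_coefficient * length
                            + sap_coefficient * n_saps)

with a hard cap: peptides whose distance to the database sequence exceeds
``max_suggested_saps`` are never identified (error-tolerant engines bound the
number of substitutions they will propose), and peptides from dropped or
mispredicted database regions are never identified in that search.

Identified peptides that require substitutions receive the correct ones with
probability ``1 - outcome3_rate - outcome2_rate``, a wrong one (wrong
position or wrong residue) with probability ``outcome3_rate``, and none with
probability ``outcome2_rate`` (default 0: in practice error-tolerant engines
lose such spectra entirely rather than matching them unmutated).

All randomness flows from ``SimulationConfig.seed`` through independent
numpy seed-sequence streams, so every artefact is byte-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .digest import (
    STANDARD_AA,
    PeptideSpan,
    SiteMap,
    collapse_il,
    identity_site_map,
    tryptic_digest,
)

_AA = np.array(list(STANDARD_AA))
_IL_PARTNER = {"I": "L", "L": "I"}


class SimulationConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass(frozen=True)
class ReferenceProteome:
    """A labelled set of protein records for one taxon."""

    taxon: str
    proteins: Dict[str, str]
    contaminants: FrozenSet[str] = frozenset()

    def __post_init__(self) -> None:
        unknown = self.contaminants - set(self.proteins)
        if unknown:
            raise ValueError(f"contaminant accessions not in proteome: {sorted(unknown)}")

    @property
    def accessions(self) -> List[str]:
        return list(self.proteins)

    def __len__(self) -> int:
        return len(self.proteins)


@dataclass(frozen=True)
class IdentificationModel:
    """Logistic identification odds of a peptide in one search.

    Defaults emulate the qualitative behaviour reported for error-tolerant
    engines on bone proteomes: short 0-SAP peptides are nearly always
    identified, identification decays with length, each SAP costs about one
    log-odds unit, and no peptide needing more than ``max_suggested_saps``
    substitutions is ever matched. Scores are drawn from two overlapping
    log-normal laws (correct matches score higher) so a score threshold
    behaves like an FDR cut-off.
    """

    base_logit: float = 6.0
    length_coefficient: float = -0.3
    sap_coefficient: float = -1.4
    max_suggested_saps: int = 2
    # (mu, sigma) of log-score
    score_law_correct: Tuple[float, float] = (3.6, 0.35)
    score_law_incorrect: Tuple[float, float] = (3.2, 0.40)

    def validate(self) -> None:
        if self.max_suggested_saps < 0:
            raise SimulationConfigError("max_suggested_saps must be >= 0")
        for name in ("score_law_correct", "score_law_incorrect"):
            mu, sigma = getattr(self, name)
            if sigma <= 0:
                raise SimulationConfigError(f"{name}: sigma must be > 0")

    def p_identified(self, length, n_saps):
        """Vectorized identification probability; 0 above the SAP cap."""
        length = np.asarray(length, dtype=float)
        n_saps = np.asarray(n_saps, dtype=float)
        logit = (
            self.base_logit
            + self.length_coefficient * length
            + self.sap_coefficient * n_saps
        )
        with np.errstate(over="ignore"):
            p = 1.0 / (1.0 + np.exp(-logit))
        return np.where(n_saps > self.max_suggested_saps, 0.0, p)


@dataclass(frozen=True)
class SimulationConfig:
    n_proteins: int = 100
    protein_length_range: Tuple[int, int] = (100, 500)
    #: expected SAPs per 100 residues, one entry per database; defaults mimic
    #: a chimpanzee-like and an orangutan-like divergence from the target
    divergence_per_db: Tuple[float, ...] = (0.5, 1.5)
    db_labels: Tuple[str, ...] = ("Pan", "Pongo")
    target_label: str = "Homo"
    clustering_weight: float = 0.0
    hotspot_fraction: float = 0.1
    hotspot_window: int = 10
    drop_fraction: float = 0.02
    mispredict_fraction: float = 0.02
    mispredict_span_fraction: float = 0.2
    n_contaminants: int = 0
    n_individuals: int = 7
    files_per_individual: int = 3
    missed_cleavages: int = 1
    digestion_mode: str = "tryptic"
    id_model: IdentificationModel = field(default_factory=IdentificationModel)
    outcome3_rate: float = 0.2
    outcome2_rate: float = 0.0
    seed: int = 0

    @property
    def n_datasets(self) -> int:
        return self.n_individuals * self.files_per_individual

    @property
    def dataset_ids(self) -> List[str]:
        return [
            f"I{i + 1:02d}F{j + 1}"
            for i in range(self.n_individuals)
            for j in range(self.files_per_individual)
        ]

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise SimulationConfigError("n_proteins must be >= 1")
        lo, hi = self.protein_length_range
        if not (1 <= lo <= hi):
            raise SimulationConfigError("protein_length_range must satisfy 1 <= min <= max")
        if len(self.divergence_per_db) != len(self.db_labels):
            raise SimulationConfigError("divergence_per_db and db_labels must have equal length")
        for d in self.divergence_per_db:
            if d < 0:
                raise SimulationConfigError("divergence_per_db entries must be >= 0")
        for name in (
            "drop_fraction",
            "mispredict_fraction",
            "mispredict_span_fraction",
            "hotspot_fraction",
            "outcome3_rate",
            "outcome2_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SimulationConfigError(f"{name} must be in [0, 1]")
        if self.outcome3_rate + self.outcome2_rate > 1.0:
            raise SimulationConfigError("outcome3_rate + outcome2_rate must be <= 1")
        if self.clustering_weight < 0:
            raise SimulationConfigError("clustering_weight must be >= 0")
        if self.hotspot_window < 1:
            raise SimulationConfigError("hotspot_window must be >= 1")
        if self.n_contaminants < 0:
            raise SimulationConfigError("n_contaminants must be >= 0")
        if self.n_individuals < 1 or self.files_per_individual < 1:
            raise SimulationConfigError("n_individuals and files_per_individual must be >= 1")
        if self.missed_cleavages < 0:
            raise SimulationConfigError("missed_cleavages must be >= 0")
        if self.digestion_mode not in ("tryptic", "semitryptic", "nontryptic-allowed"):
            raise SimulationConfigError(f"unknown digestion_mode {self.digestion_mode!r}")
        self.id_model.validate()


@dataclass
class OrthologTruth:
    """Ground-truth substitutions between a target and a database proteome."""

    target_label: str
    db_label: str
    #: accession -> [(position in target, target_aa, db_aa), ...]
    substitutions: Dict[str, List[Tuple[int, str, str]]] = field(default_factory=dict)
    dropped: FrozenSet[str] = frozenset()
    #: accession -> (start, end) of the corrupted (mispredicted) region
    mispredicted: Dict[str, Tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for acc, subs in self.substitutions.items():
            for pos, t_aa, d_aa in subs:
                if t_aa == d_aa:
                    raise ValueError(f"{acc}:{pos}: target_aa == db_aa")

    def n_substitutions(self) -> int:
        return sum(len(v) for v in self.substitutions.values())

    def site_map(self, accession: str, target_length: int) -> SiteMap:
        """Identity SiteMap (no indels are simulated) with the planted SAPs."""
        return identity_site_map(
            accession,
            target_length,
            substitutions=self.substitutions.get(accession, ()),
            unaligned_region=self.mispredicted.get(accession),
        )


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *key]))


def generate_reference_proteome(config: SimulationConfig) -> ReferenceProteome:
    """Draw the target proteome: uniform lengths, i.i.d. residues.

    Contaminant records (if any) are appended with ``CONT`` accessions and
    flagged; they model the adventitious-protein list appended to every
    search database and are shared, unevolved, by all databases.
    """
    config.validate()
    rng = _stream(config.seed, 0)
    lo, hi = config.protein_length_range
    proteins: Dict[str, str] = {}
    for i in range(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        proteins[f"SIM{i + 1:04d}"] = "".join(rng.choice(_AA, size=length))
    contaminants = []
    for i in range(config.n_contaminants):
        length = int(rng.integers(lo, hi + 1))
        acc = f"CONT{i + 1:03d}"
        proteins[acc] = "".join(rng.choice(_AA, size=length))
        contaminants.append(acc)
    return ReferenceProteome(
        taxon=config.target_label,
        proteins=proteins,
        contaminants=frozenset(contaminants),
    )


def _substitute(rng: np.random.Generator, original: str) -> str:
    """A replacement residue that is a real SAP even after I/L collapsing."""
    forbidden = {original, _IL_PARTNER.get(original)}
    choices = [aa for aa in STANDARD_AA if aa not in forbidden]
    return choices[int(rng.integers(len(choices)))]


def evolve_proteome(
    target: ReferenceProteome, db_index: int, config: SimulationConfig
) -> Tuple[ReferenceProteome, OrthologTruth]:
    """Derive a database proteome from the target by point substitution.

    Substitutions are placed per residue with expectation
    ``divergence_per_db[db_index] / 100``; when ``clustering_weight > 0`` a
    fraction of fixed-width sequence windows ("hotspots") receives
    proportionally more substitutions, emulating the clustered SAP patterns
    seen in collagens. A fraction of proteins is dropped entirely and another
    fraction has a contiguous region replaced by unrelated sequence
    (mispredicted gene models); both are recorded in the returned truth.
    Contaminant records are never evolved, dropped or mispredicted.
    """
    config.validate()
    if not (0 <= db_index < len(config.divergence_per_db)):
        raise SimulationConfigError(
            f"db_index {db_index} out of range for {len(config.divergence_per_db)} databases"
        )
    divergence = config.divergence_per_db[db_index]
    base_p = divergence / 100.0
    if base_p > 1.0:
        raise SimulationConfigError(
            f"divergence {divergence} per 100 residues exceeds total substitution"
        )
    rng = _stream(config.seed, 1, db_index)

    core = [a for a in target.proteins if a not in target.contaminants]
    dropped = {a for a in core if rng.random() < config.drop_fraction}
    mispredict_pool = [a for a in core if a not in dropped]
    mispredicted_accs = {
        a for a in mispredict_pool if rng.random() < config.mispredict_fraction
    }

    proteins: Dict[str, str] = {}
    truth_subs: Dict[str, List[Tuple[int, str, str]]] = {}
    mispredicted: Dict[str, Tuple[int, int]] = {}

    for acc, seq in target.proteins.items():
        if acc in target.contaminants:
            proteins[acc] = seq
            continue
        if acc in dropped:
            continue
        n = len(seq)
        weights = np.ones(n)
        if config.clustering_weight > 0:
            n_windows = max(1, math.ceil(n / config.hotspot_window))
            n_hot = max(1, round(config.hotspot_fraction * n_windows))
            hot = rng.choice(n_windows, size=n_hot, replace=False)
            for w in hot:
                weights[w * config.hotspot_window : (w + 1) * config.hotspot_window] = (
                    1.0 + config.clustering_weight
                )
        p = base_p * weights / weights.mean()
        if np.any(p > 1.0):
            raise SimulationConfigError(
                "per-residue substitution probability exceeds 1; lower "
                "divergence_per_db or clustering_weight"
            )
        hits = np.nonzero(rng.random(n) < p)[0]
        chars = list(seq)
        subs: List[Tuple[int, str, str]] = []
        for i in hits:
            new = _substitute(rng, seq[i])
            chars[i] = new
            subs.append((int(i) + 1, seq[i], new))

        region: Optional[Tuple[int, int]] = None
        if acc in mispredicted_accs:
            span = max(1, round(config.mispredict_span_fraction * n))
            s0 = int(rng.integers(0, n - span + 1))
            region = (s0 + 1, s0 + span)
            chars[s0 : s0 + span] = list(rng.choice(_AA, size=span))
            subs = [t for t in subs if not (region[0] <= t[0] <= region[1])]
            mispredicted[acc] = region

        proteins[acc] = "".join(chars)
        if subs:
            truth_subs[acc] = subs

    db = ReferenceProteome(
        taxon=config.db_labels[db_index],
        proteins=proteins,
        contaminants=target.contaminants & set(proteins),
    )
    truth = OrthologTruth(
        target_label=target.taxon,
        db_label=db.taxon,
        substitutions=truth_subs,
        dropped=frozenset(dropped),
        mispredicted=mispredicted,
    )
    return db, truth


def apply_substitutions(
    target: ReferenceProteome,
    substitutions: Dict[str, List[Tuple[int, str]]],
    db_label: str,
) -> Tuple[ReferenceProteome, OrthologTruth]:
    """Build a database proteome carrying exactly the given substitutions.

    ``substitutions`` maps accession to ``[(position, db_aa), ...]``. Useful
    for planting taxon-specific SAP patterns (e.g. shared derived states)
    that the random evolution model would almost never produce.
    """
    proteins: Dict[str, str] = {}
    truth_subs: Dict[str, List[Tuple[int, str, str]]] = {}
    for acc, seq in target.proteins.items():
        subs = substitutions.get(acc, [])
        chars = list(seq)
        rec: List[Tuple[int, str, str]] = []
        for pos, db_aa in subs:
            if not (1 <= pos <= len(seq)):
                raise ValueError(f"{acc}:{pos}: position outside sequence")
            if collapse_il(db_aa) == collapse_il(seq[pos - 1]):
                raise ValueError(f"{acc}:{pos}: not a substitution after I/L collapsing")
            rec.append((pos, seq[pos - 1], db_aa))
            chars[pos - 1] = db_aa
        proteins[acc] = "".join(chars)
        if rec:
            truth_subs[acc] = sorted(rec)
    db = ReferenceProteome(
        taxon=db_label, proteins=proteins, contaminants=target.contaminants
    )
    truth = OrthologTruth(
        target_label=target.taxon, db_label=db_label, substitutions=truth_subs
    )
    return db, truth


def digest_proteome(
    proteome: ReferenceProteome, config: SimulationConfig
) -> List[PeptideSpan]:
    """Digest every protein of the proteome under the configured mode."""
    spans: List[PeptideSpan] = []
    for acc, seq in proteome.proteins.items():
        spans.extend(
            tryptic_digest(
                seq,
                missed_cleavages=config.missed_cleavages,
                mode=config.digestion_mode,
                accession=acc,
            )
        )
    return spans


def _wrong_substitution(
    rng: np.random.Generator,
    span_start: int,
    span_end: int,
    db_region: str,
    true_subs: List[Tuple[int, str, str]],
) -> List[Tuple[int, str, str]]:
    """Corrupt the true substitution set: wrong residue or wrong position.

    The corrupted call is guaranteed not to reconstruct the target sequence,
    even after I/L collapsing.
    """
    # convert truth entries (pos, target_aa, db_aa) into suggestion format
    # (pos, db_aa, observed_aa), then corrupt one of them
    subs = [[p, d, t] for (p, t, d) in true_subs]
    k = int(rng.integers(len(subs)))
    pos, d_aa, t_aa = subs[k]
    sub_positions = {s[0] for s in subs}
    others = [
        p for p in range(span_start, span_end + 1) if p not in sub_positions
    ]
    if rng.random() < 0.5 and others:
        # wrong position: move the suggestion to a non-substituted residue
        new_pos = others[int(rng.integers(len(others)))]
        here = db_region[new_pos - span_start]
        forbidden = {here, _IL_PARTNER.get(here)}
        obs = [aa for aa in STANDARD_AA if aa not in forbidden]
        subs[k] = [new_pos, here, obs[int(rng.integers(len(obs)))]]
    else:
        # wrong residue at the right position
        forbidden = {d_aa, t_aa, _IL_PARTNER.get(t_aa), _IL_PARTNER.get(d_aa)}
        obs = [aa for aa in STANDARD_AA if aa not in forbidden]
        subs[k] = [pos, d_aa, obs[int(rng.integers(len(obs)))]]
    return sorted(tuple(s) for s in subs)


def simulate_search(
    target: ReferenceProteome,
    database: ReferenceProteome,
    truth: Optional[OrthologTruth],
    config: SimulationConfig,
) -> pd.DataFrame:
    """Simulate one database search over all pseudo-datasets.

    ``truth is None`` (or ``database is target``) denotes the ground-truth
    search of the target data against its own proteome: every peptide has
    zero SAPs and all identifications are correct. Otherwise ``database``
    must be the proteome produced together with ``truth``.

    Returns a PSM table in the package's TSV schema (one row per PSM):
    dataset_id, scan_id, search_label, accession, start, end, peptide,
    modifications, score, substitutions. Scan identifiers are shared across
    searches: the same (dataset_id, scan_id) pair denotes the same underlying
    spectrum in every search.
    """
    config.validate()
    self_search = truth is None
    if self_search:
        if database is not target and database.proteins != target.proteins:
            raise ValueError("truth is required unless database equals target")
    else:
        if truth.db_label != database.taxon:
            raise ValueError(
                f"truth is for database {truth.db_label!r}, got {database.taxon!r}"
            )
        for acc in truth.substitutions:
            if acc in truth.dropped or acc not in database.proteins:
                raise ValueError(f"truth/database mismatch for {acc}")

    spans = digest_proteome(target, config)
    n_pep = len(spans)
    acc_arr = np.array([s.accession for s in spans])
    start = np.array([s.start for s in spans])
    end = np.array([s.end for s in spans])
    length = end - start + 1

    n_saps = np.zeros(n_pep, dtype=int)
    identifiable = np.ones(n_pep, dtype=bool)
    site_maps: Dict[str, SiteMap] = {}
    if not self_search:
        for i, s in enumerate(spans):
            acc = s.accession
            if acc in truth.dropped or acc not in database.proteins:
                identifiable[i] = False
                continue
            sm = site_maps.get(acc)
            if sm is None:
                sm = truth.site_map(acc, len(target.proteins[acc]))
                site_maps[acc] = sm
            if not sm.fully_aligned(s.start, s.end):
                identifiable[i] = False  # overlaps a mispredicted region
            else:
                n_saps[i] = len(sm.substitutions_in(s.start, s.end))

    model = config.id_model
    p_id = model.p_identified(length, n_saps) * identifiable

    stream_key = (2, 0) if self_search else (3, config.db_labels.index(database.taxon))
    rng = _stream(config.seed, *stream_key)

    label = target.taxon if self_search else database.taxon
    mu_c, sg_c = model.score_law_correct
    mu_i, sg_i = model.score_law_incorrect

    rows: List[tuple] = []
    for ds in config.dataset_ids:
        hit = np.nonzero(rng.random(n_pep) < p_id)[0]
        for i in hit:
            s = spans[i]
            if self_search or n_saps[i] == 0:
                peptide = s.sequence
                subs_str = ""
                score = float(np.exp(rng.normal(mu_c, sg_c)))
            else:
                sm = site_maps[s.accession]
                true_subs = sm.substitutions_in(s.start, s.end)
                db_region = database.proteins[s.accession][s.start - 1 : s.end]
                u = rng.random()
                if u < config.outcome2_rate:
                    applied: List[Tuple[int, str, str]] = []
                    score = float(np.exp(rng.normal(mu_i, sg_i)))
                elif u < config.outcome2_rate + config.outcome3_rate:
                    applied = _wrong_substitution(
                        rng, s.start, s.end, db_region, true_subs
                    )
                    score = float(np.exp(rng.normal(mu_i, sg_i)))
                else:
                    # correct: report every required substitution (db -> target)
                    applied = [(p, d, t) for (p, t, d) in true_subs]
                    score = float(np.exp(rng.normal(mu_c, sg_c)))
                chars = list(db_region)
                for p, _d, obs in applied:
                    chars[p - s.start] = obs
                peptide = "".join(chars)
                subs_str = ";".join(f"{p}:{d}>{o}" for p, d, o in applied)
            rows.append(
                (
                    ds,
                    f"sc{i:06d}",
                    label,
                    s.accession,
                    int(s.start),
                    int(s.end),
                    peptide,
                    "",
                    round(score, 4),
                    subs_str,
                )
            )

    return pd.DataFrame(
        rows,
        columns=[
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
        ],
    )
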