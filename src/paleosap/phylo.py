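"""Informative-position alignments and neighbor-joining trees.

Accepted single amino acid polymorphisms, together with the reference
proteomes they were called against, define a character matrix: one column
per phylogenetically informative protein position, one row per taxon (the
analyzed sample plus each reference proteome). This module builds that
matrix, infers a p-distance neighbor-joining tree with column-resampling
bootstrap support, roots it on a designated outgroup, and exports the
alignment for external maximum-likelihood tools.

Missing data (positions not observed in the sample, or unmappable in a
reference) use the ``?`` symbol and are handled by pairwise deletion in the
distance computation.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .digest import SiteMap, collapse_il
from .filters import SAPCall
from .sim import ReferenceProteome

logger = logging.getLogger(__name__)

MISSING = "?"


@dataclass
class InformativeAlignment:
    """Residue matrix over phylogenetically informative positions."""

    taxa: List[str]
    #: one (accession, position) descriptor per column, in column order
    columns: List[Tuple[str, int]]
    #: one residue string per taxon, aligned with ``taxa``
    rows: List[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("one row per taxon required")
        ncol = len(self.columns)
        for taxon, row in zip(self.taxa, self.rows):
            if len(row) != ncol:
                raise ValueError(f"row for {taxon!r} has wrong length")
        if len(set(self.columns)) != ncol:
            raise ValueError("column descriptors must be unique")

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]


def sample_observations_from_psms(
    psms: pd.DataFrame, accepted_calls: Sequence[SAPCall] = ()
) -> Dict[Tuple[str, int], str]:
    """Observed sample residue at every position covered by a PSM.

    Non-mutated coverage contributes the residue read from the matched
    peptide; accepted SAP calls override with the substituted residue. When
    overlapping PSMs disagree at a position the majority residue wins (ties
    break lexicographically, for determinism).
    """
    votes: Dict[Tuple[str, int], Dict[str, int]] = {}
    for r in psms.itertuples():
        for off, aa in enumerate(r.peptide):
            key = (r.accession, r.start + off)
            votes.setdefault(key, {}).setdefault(aa, 0)
            votes[key][aa] += 1
    out = {
        key: min(v, key=lambda aa: (-votes[key][aa], aa))
        for key, v in votes.items()
    }
    for call in accepted_calls:
        if call.accepted:
            out[(call.accession, call.position)] = call.observed_aa
    return out


def build_informative_alignment(
    sap_calls: Sequence[SAPCall],
    proteomes: Mapping[str, ReferenceProteome],
    site_maps: Mapping[str, Mapping[str, SiteMap]],
    sample_observations: Mapping[Tuple[str, int], str],
    target_taxon: str,
    sample_name: str = "sample",
) -> InformativeAlignment:
    """Assemble the informative-position matrix for sample + references.

    Candidate columns are the union of accepted SAP positions and every
    position (in target coordinates) where some reference taxon differs from
    the target; a column is emitted when the sample observed the position
    and, across all rows, at least two distinct non-missing residues remain.
    ``site_maps[taxon][accession]`` maps target coordinates into ``taxon``;
    the target taxon itself needs no map. Reference positions that cannot be
    mapped are set to the missing symbol with a logged warning.
    """
    rejected = [c for c in sap_calls if not c.accepted]
    if rejected:
        raise ValueError("build_informative_alignment expects accepted SAP calls only")
    taxa = [sample_name, target_taxon] + [
        t for t in proteomes if t != target_taxon
    ]

    candidates: Set[Tuple[str, int]] = {
        (c.accession, c.position) for c in sap_calls
    }
    for taxon, maps in site_maps.items():
        if taxon == target_taxon:
            continue
        for acc, sm in maps.items():
            for pos, _a, _b in sm.substitutions:
                candidates.add((acc, pos))

    def reference_residue(taxon: str, acc: str, pos: int) -> str:
        prot = proteomes[taxon]
        if taxon == target_taxon:
            seq = prot.proteins.get(acc)
            return seq[pos - 1] if seq and pos <= len(seq) else MISSING
        sm = site_maps.get(taxon, {}).get(acc)
        if sm is None:
            if acc in prot.proteins:
                seq = prot.proteins[acc]
                return seq[pos - 1] if pos <= len(seq) else MISSING
            return MISSING
        mapped = sm.map_position(pos)
        if mapped is None:
            return MISSING
        seq = prot.proteins.get(acc)
        return seq[mapped - 1] if seq and mapped <= len(seq) else MISSING

    columns: List[Tuple[str, int]] = []
    col_residues: List[List[str]] = []
    for acc, pos in sorted(candidates):
        sample_aa = sample_observations.get((acc, pos))
        if sample_aa is None:
            continue
        residues = [sample_aa]
        for taxon in taxa[1:]:
            aa = reference_residue(taxon, acc, pos)
            if aa == MISSING:
                logger.warning(
                    "position %s:%d unmappable in %s; set to missing", acc, pos, taxon
                )
            residues.append(aa)
        distinct = {collapse_il(a) for a in residues if a != MISSING}
        if len(distinct) < 2:
            continue
        if sum(a != MISSING for a in residues) < 2:
            continue
        columns.append((acc, pos))
        col_residues.append(residues)

    rows = [
        "".join(col[i] for col in col_residues) for i in range(len(taxa))
    ]
    return InformativeAlignment(taxa=taxa, columns=columns, rows=rows)


def _p_distance_matrix(rows: np.ndarray, taxa: Sequence[str]) -> DistanceMatrix:
    """p-distance with pairwise deletion of missing data (I/L collapsed)."""
    n = len(taxa)
    d = np.zeros((n, n))
    present = rows != MISSING
    for i in range(n):
        for j in range(i + 1, n):
            shared = present[i] & present[j]
            m = shared.sum()
            if m == 0:
                raise ValueError(
                    f"no shared non-missing columns between {taxa[i]!r} and {taxa[j]!r}"
                )
            diff = (rows[i, shared] != rows[j, shared]).sum()
            d[i, j] = d[j, i] = diff / m
    return DistanceMatrix(d, list(taxa))


def _nontrivial_splits(tree: TreeNode, taxa: frozenset) -> Set[frozenset]:
    """Canonical non-trivial bipartitions (smaller side; ties by sorting)."""
    splits: Set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        other = taxa - clade
        if len(clade) < 2 or len(other) < 2:
            continue
        if (len(clade), sorted(clade)) <= (len(other), sorted(other)):
            splits.add(clade)
        else:
            splits.add(other)
    return splits


def nj_tree(
    alignment: InformativeAlignment,
    n_bootstrap: int = 1000,
    outgroup: str = "",
    seed: int = 0,
) -> TreeNode:
    """Neighbor-joining tree with column-resampling bootstrap support.

    Distances are p-distances with pairwise deletion; the topology is
    inferred on the full matrix, rooted on ``outgroup``, and each internal
    node whose bipartition is non-trivial is labelled with the percentage of
    bootstrap replicates (columns resampled with replacement, seeded) whose
    NJ tree contains the same unrooted bipartition. Support values are in
    [0, 100].
    """
    if len(alignment.taxa) < 3:
        raise ValueError("need at least three taxa")
    if alignment.n_columns < 1:
        raise ValueError("need at least one column")
    if not outgroup:
        raise ValueError("an outgroup taxon is required for rooting")
    if outgroup not in alignment.taxa:
        raise ValueError(f"outgroup {outgroup!r} not among taxa")
    rows = np.array([list(collapse_il(r)) for r in alignment.rows])
    for taxon, row in zip(alignment.taxa, alignment.rows):
        if all(ch == MISSING for ch in row):
            raise ValueError(f"taxon {taxon!r} has only missing data")

    dm = _p_distance_matrix(rows, alignment.taxa)
    tree = nj(dm)
    rooted = tree.root_by_outgroup([outgroup])

    taxa_set = frozenset(alignment.taxa)
    counts: Dict[frozenset, int] = {
        s: 0 for s in _nontrivial_splits(rooted, taxa_set)
    }
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 17]))
    ncol = alignment.n_columns
    completed = 0
    for _ in range(n_bootstrap):
        idx = rng.integers(0, ncol, size=ncol)
        try:
            bdm = _p_distance_matrix(rows[:, idx], alignment.taxa)
        except ValueError:
            continue  # a pair lost all shared columns in this replicate
        bsplits = _nontrivial_splits(nj(bdm), taxa_set)
        completed += 1
        for s in counts:
            if s in bsplits:
                counts[s] += 1

    for node in rooted.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        other = taxa_set - clade
        if len(clade) < 2 or len(other) < 2:
            node.name = None
            continue
        key = clade if clade in counts else other
        if key in counts and completed:
            node.name = f"{100.0 * counts[key] / completed:.0f}"
    return rooted


def tree_topology(tree: TreeNode) -> Set[frozenset]:
    """Unrooted non-trivial bipartitions of a tree (topology fingerprint)."""
    taxa = frozenset(t.name for t in tree.tips())
    return _nontrivial_splits(tree, taxa)


def export_for_external(
    alignment: InformativeAlignment, directory: str, basename: str = "informative"
) -> Dict[str, str]:
    """Write FASTA + relaxed PHYLIP + column-map TSV; return the paths.

    The relaxed PHYLIP format places no 10-character limit on taxon names
    (name and sequence separated by whitespace), which downstream ML tools
    such as RAxML accept directly.
    """
    if alignment.n_columns == 0:
        raise ValueError("refusing to export an empty alignment")
    os.makedirs(directory, exist_ok=True)
    paths = {
        "fasta": os.path.join(directory, f"{basename}.fasta"),
        "phylip": os.path.join(directory, f"{basename}.phy"),
        "columns": os.path.join(directory, f"{basename}.columns.tsv"),
    }
    with open(paths["fasta"], "w") as fh:
        for taxon, row in zip(alignment.taxa, alignment.rows):
            fh.write(f">{taxon}\n{row}\n")
    with open(paths["phylip"], "w") as fh:
        fh.write(f"{len(alignment.taxa)} {alignment.n_columns}\n")
        width = max(len(t) for t in alignment.taxa) + 2
        for taxon, row in zip(alignment.taxa, alignment.rows):
            fh.write(f"{taxon:<{width}}{row}\n")
    pd.DataFrame(
        alignment.columns, columns=["accession", "position"]
    ).to_csv(paths["columns"], sep="\t", index=False)
    return paths


def load_exported_alignment(
    fasta_path: str, columns_path: str
) -> InformativeAlignment:
    """Inverse of :func:`export_for_external` (FASTA + column map)."""
    taxa: List[str] = []
    rows: List[str] = []
    with open(fasta_path) as fh:
        name, chunks = None, []
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    taxa.append(name)
                    rows.append("".join(chunks))
                name, chunks = line[1:], []
            else:
                chunks.append(line)
        if name is not None:
            taxa.append(name)
            rows.append("".join(chunks))
    cols_df = pd.read_csv(columns_path, sep="\t")
    columns = [(r.accession, int(r.position)) for r in cols_df.itertuples()]
    return InformativeAlignment(taxa=taxa, columns=columns, rows=rows)
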