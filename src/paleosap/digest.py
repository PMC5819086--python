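"""In-silico digestion, ortholog alignment and per-peptide evolutionary distance.

The unit of analysis downstream is the peptide-spectrum match (PSM). Here we
provide the peptide side of that unit: tryptic (or semi-/non-tryptic) spans of
a protein, a residue-level correspondence between orthologous protein
sequences, and the evolutionary distance of a peptide — the number of single
amino acid polymorphisms (SAPs) between the peptide's region in the target
protein and the orthologous database sequence. Peptides with distance >= 1 are
"mutable": they can only be matched by an error-tolerant search.

Conventions used throughout the package:

* residue coordinates are 1-based and inclusive on both ends;
* isoleucine and leucine are isobaric and indistinguishable by standard
  tandem MS, so they are collapsed to a single symbol *before* any distance
  or substitution-site computation.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

from Bio import Align
from Bio.Align import substitution_matrices

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(STANDARD_AA)

#: sentinel returned by :func:`peptide_evolutionary_distance` when the peptide
#: overlaps a region with no residue-level ortholog (a gap, a mispredicted or
#: absent stretch); such peptides have no defined SAP count.
UNALIGNABLE = "unalignable"

_IL_TABLE = str.maketrans("IL", "JJ")

# peptides outside this length range are emitted but flagged; the hard
# length >= 10 retention rule is applied downstream by the filters module
FLAG_MIN_LENGTH = 6
FLAG_MAX_LENGTH = 45


def collapse_il(sequence: str) -> str:
    """Replace both I and L by the joint symbol 'J' (isobaric equivalence)."""
    return sequence.translate(_IL_TABLE)


def validate_sequence(sequence: str) -> None:
    """Raise ``ValueError`` naming the first invalid residue position."""
    if not sequence:
        raise ValueError("empty protein sequence")
    for i, aa in enumerate(sequence):
        if aa not in _AA_SET:
            raise ValueError(
                f"unknown residue symbol {aa!r} at position {i + 1}"
            )


@dataclass(frozen=True)
class PeptideSpan:
    """A peptide as a span of its parent protein (1-based inclusive)."""

    accession: str
    start: int
    end: int
    sequence: str
    n_missed_cleavages: int
    tryptic_status: str  # "full" | "semi" | "non"
    flagged: bool = False  # length outside the usual detectable range

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("end < start")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("sequence length inconsistent with coordinates")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def covers(self, position: int) -> bool:
        return self.start <= position <= self.end


def cleavage_sites(sequence: str) -> List[int]:
    """0-based indices i such that trypsin cuts between i and i+1.

    Trypsin cleaves C-terminal of K or R except when the next residue is
    proline.
    """
    sites = []
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR" and sequence[i + 1] != "P":
            sites.append(i)
    return sites


def tryptic_digest(
    sequence: str,
    missed_cleavages: int = 0,
    mode: str = "tryptic",
    accession: str = "",
) -> List[PeptideSpan]:
    """Digest ``sequence`` with trypsin.

    Parameters
    ----------
    sequence:
        Protein sequence over the 20 standard amino acids.
    missed_cleavages:
        Maximum number of internal uncut K/R sites per peptide.
    mode:
        ``"tryptic"`` emits fully tryptic peptides only. ``"semitryptic"``
        additionally emits every peptide with exactly one ragged (non-tryptic)
        terminus. ``"nontryptic-allowed"`` further emits all remaining
        substrings within the flag length range, mimicking an unconstrained
        search space.

    Returns
    -------
    list of PeptideSpan, sorted by (start, end), without duplicates.
    """
    validate_sequence(sequence)
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    if mode not in ("tryptic", "semitryptic", "nontryptic-allowed"):
        raise ValueError(f"unknown digestion mode {mode!r}")

    n = len(sequence)
    # boundaries: 0-based start offsets of fully tryptic fragments, plus n
    cuts = cleavage_sites(sequence)
    starts = [0] + [c + 1 for c in cuts]
    bounds = starts + [n]

    spans: dict[Tuple[int, int], PeptideSpan] = {}

    def _add(s0: int, e0: int, mc: int, status: str) -> None:
        # s0/e0 are 0-based inclusive
        key = (s0, e0)
        if key in spans:
            return
        seq = sequence[s0 : e0 + 1]
        length = e0 - s0 + 1
        spans[key] = PeptideSpan(
            accession=accession,
            start=s0 + 1,
            end=e0 + 1,
            sequence=seq,
            n_missed_cleavages=mc,
            tryptic_status=status,
            flagged=not (FLAG_MIN_LENGTH <= length <= FLAG_MAX_LENGTH),
        )

    full_spans: List[Tuple[int, int, int]] = []
    for i in range(len(bounds) - 1):
        for mc in range(missed_cleavages + 1):
            j = i + mc + 1
            if j >= len(bounds):
                break
            s0, e0 = bounds[i], bounds[j] - 1
            full_spans.append((s0, e0, mc))
            _add(s0, e0, mc, "full")

    if mode in ("semitryptic", "nontryptic-allowed"):
        for s0, e0, mc in full_spans:
            # one ragged terminus: shrink from the right, or from the left
            for e in range(s0, e0):
                _add(s0, e, mc, "semi") if (s0, e) not in spans else None
            for s in range(s0 + 1, e0 + 1):
                _add(s, e0, mc, "semi") if (s, e0) not in spans else None

    if mode == "nontryptic-allowed":
        for s0 in range(n):
            for e0 in range(
                s0 + FLAG_MIN_LENGTH - 1, min(n, s0 + FLAG_MAX_LENGTH)
            ):
                _add(s0, e0, 0, "non")

    return sorted(spans.values(), key=lambda p: (p.start, p.end))


@dataclass
class SiteMap:
    """Residue-level correspondence between a target and a database ortholog.

    ``blocks`` are maximal gapless aligned runs ``(start_a, start_b, length)``
    in 1-based coordinates; ``substitutions`` are the matched positions whose
    residues differ after I/L collapsing, reported as
    ``(pos_a, aa_a, aa_b)``. Positions of sequence A not covered by any block
    have no ortholog (gaps, absent or mispredicted regions).
    """

    accession: str
    length_a: int
    length_b: int
    blocks: List[Tuple[int, int, int]] = field(default_factory=list)
    substitutions: List[Tuple[int, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.blocks = sorted(self.blocks)
        self.substitutions = sorted(self.substitutions)
        self._starts = [b[0] for b in self.blocks]
        self._sub_pos = [s[0] for s in self.substitutions]
        prev_a = prev_b = 0
        for a, b, ln in self.blocks:
            if a <= prev_a or b <= prev_b:
                raise ValueError("site map blocks not strictly increasing")
            prev_a, prev_b = a + ln - 1, b + ln - 1
        for pos, aa_a, aa_b in self.substitutions:
            if collapse_il(aa_a) == collapse_il(aa_b):
                raise ValueError(
                    f"substitution at {pos} is not a substitution after "
                    "I/L collapsing"
                )

    def _block_for(self, pos_a: int) -> Optional[Tuple[int, int, int]]:
        i = bisect.bisect_right(self._starts, pos_a) - 1
        if i < 0:
            return None
        a, b, ln = self.blocks[i]
        if pos_a <= a + ln - 1:
            return self.blocks[i]
        return None

    def is_aligned(self, pos_a: int) -> bool:
        return self._block_for(pos_a) is not None

    def map_position(self, pos_a: int) -> Optional[int]:
        """Database coordinate of target position ``pos_a`` (None if gapped)."""
        blk = self._block_for(pos_a)
        if blk is None:
            return None
        a, b, _ = blk
        return b + (pos_a - a)

    def substitutions_in(self, start: int, end: int) -> List[Tuple[int, str, str]]:
        lo = bisect.bisect_left(self._sub_pos, start)
        hi = bisect.bisect_right(self._sub_pos, end)
        return self.substitutions[lo:hi]

    def fully_aligned(self, start: int, end: int) -> bool:
        return all(self.is_aligned(p) for p in range(start, end + 1))


def identity_site_map(
    accession: str,
    length: int,
    substitutions: Iterable[Tuple[int, str, str]] = (),
    unaligned_region: Optional[Tuple[int, int]] = None,
) -> SiteMap:
    """SiteMap for equal-length orthologs related by substitutions only.

    ``unaligned_region`` (1-based inclusive) marks a stretch with no usable
    ortholog, e.g. a wrongly predicted database region.
    """
    if unaligned_region is None:
        blocks = [(1, 1, length)] if length else []
    else:
        s, e = unaligned_region
        if not (1 <= s <= e <= length):
            raise ValueError("unaligned region outside sequence")
        blocks = []
        if s > 1:
            blocks.append((1, 1, s - 1))
        if e < length:
            blocks.append((e + 1, e + 1, length - e))
    subs = [
        t
        for t in substitutions
        if unaligned_region is None
        or not (unaligned_region[0] <= t[0] <= unaligned_region[1])
    ]
    return SiteMap(
        accession=accession,
        length_a=length,
        length_b=length,
        blocks=blocks,
        substitutions=list(subs),
    )


# Alignment defaults are fixed so that site maps are bit-stable across runs:
# BLOSUM62 with affine gap costs (open 11, extend 1), global mode.
_ALIGNER = Align.PairwiseAligner()
_ALIGNER.mode = "global"
_ALIGNER.substitution_matrix = substitution_matrices.load("BLOSUM62")
_ALIGNER.open_gap_score = -11.0
_ALIGNER.extend_gap_score = -1.0


def align_orthologs(seq_a: str, seq_b: str, accession: str = "") -> SiteMap:
    """Globally align two orthologous protein sequences into a SiteMap.

    Uses BLOSUM62 with affine gap penalties; of the co-optimal alignments the
    first in Biopython's deterministic enumeration order is taken, so the
    result is reproducible.
    """
    validate_sequence(seq_a)
    validate_sequence(seq_b)
    aln = _ALIGNER.align(seq_a, seq_b)[0]
    blocks: List[Tuple[int, int, int]] = []
    substitutions: List[Tuple[int, str, str]] = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        blocks.append((a0 + 1, b0 + 1, a1 - a0))
        for off in range(a1 - a0):
            aa_a, aa_b = seq_a[a0 + off], seq_b[b0 + off]
            if collapse_il(aa_a) != collapse_il(aa_b):
                substitutions.append((a0 + off + 1, aa_a, aa_b))
    return SiteMap(
        accession=accession,
        length_a=len(seq_a),
        length_b=len(seq_b),
        blocks=blocks,
        substitutions=substitutions,
    )


def peptide_evolutionary_distance(span: PeptideSpan, site_map: SiteMap):
    """Number of SAPs between the peptide and its orthologous database region.

    Returns an ``int`` (0 means the peptide is not mutable; >= 1 means it is a
    mutable peptide), or the :data:`UNALIGNABLE` sentinel when any residue of
    the span has no orthologous database position.
    """
    if site_map.accession and span.accession and site_map.accession != span.accession:
        raise KeyError(
            f"site map is for {site_map.accession!r}, span is for "
            f"{span.accession!r}"
        )
    if span.end > site_map.length_a:
        raise KeyError("span exceeds the mapped sequence length")
    if not site_map.fully_aligned(span.start, span.end):
        return UNALIGNABLE
    return len(site_map.substitutions_in(span.start, span.end))
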