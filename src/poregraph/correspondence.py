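"""Residue correspondence between two homologous structures.

Correspondence is established once, from a pairwise global sequence
alignment (Needleman–Wunsch with BLOSUM62 and affine gap penalties, via
Biopython's PairwiseAligner), and then restricted to residues actually
modeled in both coordinate sets. Identity is the fraction of aligned
(both-residue) columns with identical amino acids; similarity is the
fraction with a positive BLOSUM62 score (which includes identities).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable

from Bio import Align
from Bio.Align import substitution_matrices

from .structure import Structure

AMINO_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class AlignParams:
    matrix: str = "BLOSUM62"
    gap_open: float = -11.0
    gap_extend: float = -1.0
    end_gap_free: bool = False


@dataclass
class ResidueMap:
    """Ordered one-to-one pairing of positions or residue keys."""

    pairs: list[tuple[Hashable, Hashable]]
    identity_pct: float
    similarity_pct: float
    unmatched_a: list[Hashable] = field(default_factory=list)
    unmatched_b: list[Hashable] = field(default_factory=list)
    score: float = 0.0
    aligned_a: str = ""
    aligned_b: str = ""

    def __post_init__(self) -> None:
        a_seen: set[Hashable] = set()
        b_seen: set[Hashable] = set()
        for a, b in self.pairs:
            if a in a_seen or b in b_seen:
                raise ValueError("residue appears in more than one pair")
            a_seen.add(a)
            b_seen.add(b)

    def a_to_b(self) -> dict[Hashable, Hashable]:
        return dict(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


def _check_sequence(seq: str, which: str) -> None:
    if not seq:
        raise ValueError(f"sequence {which} is empty")
    bad = set(seq) - AMINO_ALPHABET
    if bad:
        raise ValueError(f"sequence {which} contains non-amino-acid characters: {sorted(bad)}")


def make_aligner(params: AlignParams | None = None) -> Align.PairwiseAligner:
    params = params or AlignParams()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    if params.end_gap_free:
        try:
            aligner.end_insertion_score = 0.0
            aligner.end_deletion_score = 0.0
        except AttributeError:
            aligner.target_end_gap_score = 0.0
            aligner.query_end_gap_score = 0.0
    return aligner


def align_sequences(
    seq_a: str, seq_b: str, params: AlignParams | None = None
) -> ResidueMap:
    """Global alignment of two sequences; pairs are 0-based positions."""
    _check_sequence(seq_a, "A")
    _check_sequence(seq_b, "B")
    params = params or AlignParams()
    aligner = make_aligner(params)
    aln = aligner.align(seq_a, seq_b)[0]

    matrix = substitution_matrices.load(params.matrix)
    pairs: list[tuple[int, int]] = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        pairs.extend((a0 + k, b0 + k) for k in range(a1 - a0))
    n_cols = len(pairs)
    if n_cols == 0:
        raise ValueError("alignment produced no aligned columns")
    ident = sum(1 for i, j in pairs if seq_a[i] == seq_b[j])
    simil = sum(1 for i, j in pairs if matrix[seq_a[i], seq_b[j]] > 0)

    matched_a = {i for i, _ in pairs}
    matched_b = {j for _, j in pairs}
    return ResidueMap(
        pairs=pairs,
        identity_pct=100.0 * ident / n_cols,
        similarity_pct=100.0 * simil / n_cols,
        unmatched_a=[i for i in range(len(seq_a)) if i not in matched_a],
        unmatched_b=[j for j in range(len(seq_b)) if j not in matched_b],
        score=float(aln.score),
        aligned_a=str(aln[0]),
        aligned_b=str(aln[1]),
    )


def map_residues(
    seq_map: ResidueMap,
    s_a: Structure,
    s_b: Structure,
    chain_a: str | None = None,
    chain_b: str | None = None,
) -> ResidueMap:
    """Turn a sequence-position map into a residue-key map.

    The positional pairs of ``seq_map`` must refer to the protein
    residues of the chosen chains, in order. Pairs are restricted to
    residues modeled in both structures; unmatched residues of either
    structure are listed.
    """
    res_a = s_a.protein_residues(chain_a or s_a.protein_chains()[0])
    res_b = s_b.protein_residues(chain_b or s_b.protein_chains()[0])
    pairs = [
        (res_a[i].key, res_b[j].key)
        for i, j in seq_map.pairs
        if i < len(res_a) and j < len(res_b)
    ]
    if not pairs:
        raise ValueError("no residue correspondence between the two structures")
    matched_a = {a for a, _ in pairs}
    matched_b = {b for _, b in pairs}
    return ResidueMap(
        pairs=pairs,
        identity_pct=seq_map.identity_pct,
        similarity_pct=seq_map.similarity_pct,
        unmatched_a=[r.key for r in res_a if r.key not in matched_a],
        unmatched_b=[r.key for r in res_b if r.key not in matched_b],
        score=seq_map.score,
    )


def structure_residue_map(
    s_a: Structure,
    s_b: Structure,
    chain_a: str | None = None,
    chain_b: str | None = None,
    params: AlignParams | None = None,
) -> ResidueMap:
    """Align the sequences of two structures and map modeled residues."""
    seq_map = align_sequences(
        s_a.sequence(chain_a), s_b.sequence(chain_b), params
    )
    return map_residues(seq_map, s_a, s_b, chain_a, chain_b)


def alignment_text(rmap: ResidueMap, width: int = 60) -> str:
    """CLUSTAL-like rendering of the stored alignment strings."""
    a, b = rmap.aligned_a, rmap.aligned_b
    if not a:
        raise ValueError("map carries no alignment strings")
    lines = []
    for i in range(0, len(a), width):
        block_a, block_b = a[i : i + width], b[i : i + width]
        marks = "".join(
            "*" if x == y and x != "-" else " " for x, y in zip(block_a, block_b)
        )
        lines += [f"A  {block_a}", f"B  {block_b}", f"   {marks}", ""]
    return "\n".join(lines)


def residue_map_tsv(rmap: ResidueMap) -> str:
    lines = ["a\tb"]
    for a, b in rmap.pairs:
        lines.append(f"{_fmt(a)}\t{_fmt(b)}")
    return "\n".join(lines) + "\n"


def _fmt(key: Hashable) -> str:
    if isinstance(key, tuple) and len(key) == 3:
        return f"{key[0]}:{key[1]}{key[2]}"
    return str(key)
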