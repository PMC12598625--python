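"""Shared pairwise-alignment helpers.

Thin wrappers around :class:`Bio.Align.PairwiseAligner` fixing the scoring
conventions used throughout the package:

* nucleotide **global** identity — identical aligned positions divided by the
  length of the *shorter* sequence (cd-hit convention; used for clustering,
  dereplication sanity checks and read binning);
* nucleotide / protein **local** alignment — identity defined as identical
  positions divided by the number of alignment columns (gaps included).
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Align import PairwiseAligner, substitution_matrices

_COMPLEMENT = str.maketrans("ACGTRYKMacgtrykm", "TGCAYRMKtgcayrmk")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC subset)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """G+C fraction of ``seq`` in [0, 1]; 0.0 for the empty string."""
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


@lru_cache(maxsize=None)
def nucleotide_global_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.5
    aligner.extend_gap_score = -0.5
    # free end gaps so that a contained fragment aligns without penalty
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


@lru_cache(maxsize=None)
def nucleotide_local_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    return aligner


@lru_cache(maxsize=None)
def protein_local_aligner() -> PairwiseAligner:
    # BLAST-like protein defaults: BLOSUM62, gap open 11, extend 1.
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -12.0
    aligner.extend_gap_score = -1.0
    return aligner


def global_identity(a: str, b: str) -> float:
    """Global-alignment identity over the shorter sequence, in [0, 1]."""
    if not a or not b:
        return 0.0
    a, b = a.upper(), b.upper()
    if a == b:
        return 1.0
    aln = nucleotide_global_aligner().align(a, b)[0]
    identities = aln.counts().identities
    return identities / min(len(a), len(b))


def local_alignment(a: str, b: str, aligner: PairwiseAligner):
    """Best local alignment of ``a`` vs ``b``.

    Returns ``(score, identity, columns, a_interval, b_interval)`` where
    identity = identities / alignment columns and the intervals are 0-based
    half-open coordinates of the locally aligned region on each sequence.
    Returns ``None`` when no positive-scoring alignment exists.
    """
    alns = aligner.align(a, b)
    if len(alns) == 0:
        return None
    aln = alns[0]
    if aln.score <= 0:
        return None
    counts = aln.counts()
    columns = aln.length
    if columns == 0:
        return None
    blocks_a, blocks_b = aln.aligned
    a_iv = (int(blocks_a[0][0]), int(blocks_a[-1][1]))
    b_iv = (int(blocks_b[0][0]), int(blocks_b[-1][1]))
    return float(aln.score), counts.identities / columns, columns, a_iv, b_iv
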