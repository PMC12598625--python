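"""Translated read classification.

Reads are translated in all six frames and locally aligned against a
family-labelled protein database (BLOSUM62, BLAST-like gap costs).  Hits are
kept when they clear the identity floor (default 60%) and the E-value cutoff;
within each direction (the three forward frames pooled, likewise reverse) up
to four matches are retained, any two overlapping by at most 15 amino acids
on read coordinates.  Same-family hits collapse to the best E-value and
homologous families compete so a read ends up with at most one family per
homolog group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Seq import Seq
from scipy.stats import gumbel_r

from ._pairwise import local_alignment, protein_local_aligner, revcomp
from .errors import CalibrationError, UncalibratedProfileError, ValidationError
from .target_registry import AA_ALPHABET, Registry, SequenceRecord

DEFAULT_MIN_IDENTITY = 60.0  # percent
DEFAULT_MAX_PER_DIRECTION = 4
DEFAULT_MAX_OVERLAP_AA = 15
DEFAULT_E_MAX = 0.001
_MIN_PEPTIDE = 8  # frames shorter than this cannot produce a scored hit

FRAMES = (1, 2, 3, -1, -2, -3)


class ProteinDB:
    """Family-labelled protein sequences with a shared Gumbel null.

    A 4-mer word index shortlists database entries per query peptide before
    any alignment is scored; pass ``word_size=None`` to disable the filter
    and score every pair.
    """

    def __init__(self, records: list[SequenceRecord], word_size: int | None = 4):
        if not records:
            raise ValidationError("protein database is empty")
        for rec in records:
            if rec.family_label is None:
                raise ValidationError(f"protein {rec.id!r} lacks a family label")
        self.records = list(records)
        self.calibration: tuple[float, float] | None = None
        self.word_size = word_size
        self._index: dict[str, set[int]] = {}
        if word_size:
            for i, rec in enumerate(self.records):
                seq = rec.residues.upper()
                for j in range(len(seq) - word_size + 1):
                    self._index.setdefault(seq[j : j + word_size], set()).add(i)

    def candidates(self, peptide: str) -> list[int]:
        """Indices of records sharing at least one word with ``peptide``."""
        if not self.word_size:
            return list(range(len(self.records)))
        w = self.word_size
        pep = peptide.upper()
        found: set[int] = set()
        for j in range(len(pep) - w + 1):
            found |= self._index.get(pep[j : j + w], set())
        return sorted(found)

    def __len__(self) -> int:
        return len(self.records)

    def calibrate(
        self, seed: int = 0, n_decoys: int = 200, peptide_length: int = 90
    ) -> "ProteinDB":
        """Fit the null from best-vs-database scores of random peptides."""
        rng = np.random.default_rng(seed)
        aligner = protein_local_aligner()
        aa = np.array(list(AA_ALPHABET))
        scores = []
        for _ in range(n_decoys):
            pep = "".join(rng.choice(aa, size=peptide_length))
            scores.append(max(aligner.score(pep, r.residues) for r in self.records))
        scores = np.array(scores, dtype=float)
        if float(np.std(scores)) < 1e-9:
            raise CalibrationError("degenerate protein null-score distribution")
        loc, scale = gumbel_r.fit(scores)
        self.calibration = (float(loc), float(scale))
        return self

    def evalue(self, score: float) -> float:
        if self.calibration is None:
            raise UncalibratedProfileError("protein database is not calibrated")
        loc, scale = self.calibration
        return len(self.records) * float(gumbel_r.sf(score, loc=loc, scale=scale))


@dataclass(frozen=True)
class MatchHit:
    read_id: str
    frame: int  # one of +1,+2,+3,-1,-2,-3
    target_id: str
    family: str
    percent_identity: float
    read_interval_aa: tuple[int, int]  # 0-based half-open on the frame peptide
    nt_interval: tuple[int, int]  # forward-strand nt coordinates on the read
    score: float
    evalue: float

    @property
    def direction(self) -> str:
        return "forward" if self.frame > 0 else "reverse"


@dataclass(frozen=True)
class ReadAnnotation:
    read_id: str
    families: frozenset[str]
    best_hits: dict  # family/decoy label -> MatchHit
    reassigned: tuple[tuple[str, str], ...] = ()  # (dropped label, winning label)


@dataclass
class AbundanceTable:
    counts: dict[str, int]
    total_reads: int

    def __post_init__(self):
        if self.total_reads < 1:
            raise ValidationError("total_reads must be >= 1")

    @property
    def rel_target(self) -> dict[str, float]:
        """100 · count_g / Σ_h count_h over families with count > 0."""
        present = {f: c for f, c in self.counts.items() if c > 0}
        total = sum(present.values())
        if total == 0:
            return {}
        return {f: 100.0 * c / total for f, c in sorted(present.items())}

    @property
    def rel_total(self) -> dict[str, float]:
        """100 · count_g / total sequenced reads."""
        return {f: 100.0 * c / self.total_reads for f, c in sorted(self.counts.items())}

    def write_tsv(self, path: str | Path) -> None:
        rel_t, rel_n = self.rel_target, self.rel_total
        with open(path, "w") as fh:
            fh.write("family\tcount\trel_target\trel_total\n")
            for fam in sorted(self.counts):
                fh.write(
                    f"{fam}\t{self.counts[fam]}\t{rel_t.get(fam, 0.0):.6f}\t"
                    f"{rel_n.get(fam, 0.0):.6f}\n"
                )


def translate_six_frames(read: str) -> dict[int, str]:
    """Standard-code translation of all six frames; '*' marks stops, the
    trailing partial codon is dropped.  Reads shorter than 3 nt give six
    empty frames."""
    read = read.upper()
    frames: dict[int, str] = {}
    rc = revcomp(read)
    for f in (1, 2, 3):
        for source, key in ((read, f), (rc, -f)):
            sub = source[f - 1 :]
            sub = sub[: len(sub) - len(sub) % 3]
            frames[key] = str(Seq(sub).translate()) if sub else ""
    return frames


def _nt_interval(frame: int, aa_interval: tuple[int, int], read_len: int) -> tuple[int, int]:
    offset = abs(frame) - 1
    a, b = aa_interval
    lo, hi = offset + 3 * a, offset + 3 * b
    if frame > 0:
        return lo, hi
    return read_len - hi, read_len - lo


def _overlap_aa(a: tuple[int, int], b: tuple[int, int]) -> float:
    return max(0, min(a[1], b[1]) - max(a[0], b[0])) / 3.0


def map_and_retain(
    read_id: str,
    read_seq: str,
    db: ProteinDB,
    *,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_per_direction: int = DEFAULT_MAX_PER_DIRECTION,
    max_overlap_aa: int = DEFAULT_MAX_OVERLAP_AA,
    e_max: float = DEFAULT_E_MAX,
) -> list[MatchHit]:
    """Align all six frames against the database and apply the retention rules.

    No minimum coverage is enforced.  Per direction, hits are admitted in
    descending score order; a hit is kept only if it overlaps every
    already-admitted hit of that direction by <= ``max_overlap_aa`` amino
    acids, stopping after ``max_per_direction`` hits.
    """
    aligner = protein_local_aligner()
    frames = translate_six_frames(read_seq)
    read_len = len(read_seq)
    raw: list[MatchHit] = []
    for frame, peptide in frames.items():
        if len(peptide) < _MIN_PEPTIDE:
            continue
        for rec_i in db.candidates(peptide):
            rec = db.records[rec_i]
            score = aligner.score(peptide, rec.residues)
            evalue = db.evalue(score)
            if evalue > e_max:
                continue
            res = local_alignment(peptide, rec.residues, aligner)
            if res is None:
                continue
            _, identity, _, pep_iv, _ = res
            if 100.0 * identity < min_identity:
                continue
            raw.append(
                MatchHit(
                    read_id=read_id,
                    frame=frame,
                    target_id=rec.id,
                    family=rec.family_label,
                    percent_identity=100.0 * identity,
                    read_interval_aa=pep_iv,
                    nt_interval=_nt_interval(frame, pep_iv, read_len),
                    score=score,
                    evalue=evalue,
                )
            )
    retained: list[MatchHit] = []
    for direction in ("forward", "reverse"):
        hits = sorted(
            (h for h in raw if h.direction == direction),
            key=lambda h: (-h.score, h.evalue, h.target_id, h.frame),
        )
        admitted: list[MatchHit] = []
        for hit in hits:
            if len(admitted) >= max_per_direction:
                break
            if all(
                _overlap_aa(hit.nt_interval, a.nt_interval) <= max_overlap_aa
                for a in admitted
            ):
                admitted.append(hit)
        retained.extend(admitted)
    return retained


def resolve_homologs(hits: list[MatchHit], registry: Registry) -> ReadAnnotation:
    """Collapse same-family hits to the best E-value and let homologous
    labels compete: within a connected homolog-group component only the
    best-E label survives; decoy winners eliminate their competitors without
    being counted themselves."""
    if not hits:
        return ReadAnnotation(read_id="", families=frozenset(), best_hits={})
    read_id = hits[0].read_id
    best: dict[str, MatchHit] = {}
    for hit in hits:
        cur = best.get(hit.family)
        if cur is None or (hit.evalue, -hit.score) < (cur.evalue, -cur.score):
            best[hit.family] = hit

    # connected components over shared homolog groups
    labels = sorted(best)
    group_members: dict[str, list[str]] = {}
    for label in labels:
        for g in registry.groups_of(label):
            group_members.setdefault(g, []).append(label)
    parent = {lb: lb for lb in labels}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for members in group_members.values():
        for other in members[1:]:
            parent[find(other)] = find(members[0])

    components: dict[str, list[str]] = {}
    for lb in labels:
        components.setdefault(find(lb), []).append(lb)

    final: set[str] = set()
    reassigned: list[tuple[str, str]] = []
    for members in components.values():
        winner = min(members, key=lambda lb: (best[lb].evalue, -best[lb].score, lb))
        for lb in members:
            if lb != winner:
                reassigned.append((lb, winner))
        if not registry.is_decoy(winner):
            final.add(winner)
    return ReadAnnotation(
        read_id=read_id,
        families=frozenset(final),
        best_hits=best,
        reassigned=tuple(sorted(reassigned)),
    )


def classify_reads(
    reads: list[tuple[str, str]],
    db: ProteinDB,
    registry: Registry,
    *,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_per_direction: int = DEFAULT_MAX_PER_DIRECTION,
    max_overlap_aa: int = DEFAULT_MAX_OVERLAP_AA,
    e_max: float = DEFAULT_E_MAX,
) -> tuple[list[MatchHit], list[ReadAnnotation]]:
    """Run map_and_retain + resolve_homologs over ``(read_id, sequence)`` pairs."""
    all_hits: list[MatchHit] = []
    annotations: list[ReadAnnotation] = []
    for read_id, seq in reads:
        hits = map_and_retain(
            read_id,
            seq,
            db,
            min_identity=min_identity,
            max_per_direction=max_per_direction,
            max_overlap_aa=max_overlap_aa,
            e_max=e_max,
        )
        all_hits.extend(hits)
        if hits:
            annotations.append(resolve_homologs(hits, registry))
    return all_hits, annotations


def tabulate(annotations: list[ReadAnnotation], total_reads: int) -> AbundanceTable:
    """Per-family read counts (a read counts once per assigned family)."""
    if total_reads < 1:
        raise ValidationError("total_reads must be >= 1")
    counts: dict[str, int] = {}
    for ann in annotations:
        for fam in ann.families:
            counts[fam] = counts.get(fam, 0) + 1
    return AbundanceTable(counts=dict(sorted(counts.items())), total_reads=total_reads)


def write_hits_tsv(hits: list[MatchHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "read_id\tframe\ttarget_id\tfamily\tpercent_identity\t"
            "aa_start\taa_end\tnt_start\tnt_end\tscore\tevalue\n"
        )
        for h in hits:
            fh.write(
                f"{h.read_id}\t{h.frame:+d}\t{h.target_id}\t{h.family}\t"
                f"{h.percent_identity:.2f}\t{h.read_interval_aa[0]}\t{h.read_interval_aa[1]}\t"
                f"{h.nt_interval[0]}\t{h.nt_interval[1]}\t{h.score:.1f}\t{h.evalue:.3e}\n"
            )


def write_annotations_tsv(annotations: list[ReadAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tfamilies\treassigned\n")
        for ann in annotations:
            fams = ",".join(sorted(ann.families))
            moved = ";".join(f"{a}->{b}" for a, b in ann.reassigned)
            fh.write(f"{ann.read_id}\t{fams}\t{moved}\n")
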