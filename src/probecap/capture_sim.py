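"""Fragmentation, probe-hybridization capture and paired-read simulation.

The capture model is a parameterized stand-in for wet-lab hybridization:
capture probability is a ceiling times a logistic in the best probe-match
identity, optionally times a linear GC-efficiency term (low-GC fragments
capture less efficiently when the bias is enabled).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._pairwise import gc_fraction, local_alignment, nucleotide_local_aligner, revcomp
from .mock_community import MockDesign, TruthInterval
from .probe_design import ProbePanel

DEFAULT_MEAN_INSERT = 630.0
DEFAULT_READ_LENGTH = 300
_MIN_FRAGMENT = 50


@dataclass(frozen=True)
class Fragment:
    id: str
    strain: str
    start: int  # 0-based, half-open on the source genome
    end: int
    strand: str
    sequence: str
    truth_families: frozenset[str] = frozenset()

    @property
    def gc_fraction(self) -> float:
        return gc_fraction(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CaptureModel:
    p_max: float = 0.95
    kappa: float = 30.0
    x0: float = 0.8
    gamma0: float = 0.2
    gamma1: float = 1.0
    gc_bias_enabled: bool = True
    probe_match_min_len: int = 25

    def __post_init__(self):
        if not 0 <= self.p_max <= 1:
            raise ValueError("p_max must be in [0, 1]")

    def identity_term(self, x: float) -> float:
        z = -self.kappa * (x - self.x0)
        if z > 700.0:  # exp() overflow guard; logistic is 0 to double precision
            return 0.0
        return 1.0 / (1.0 + math.exp(z))

    def gc_term(self, gc: float) -> float:
        if not self.gc_bias_enabled:
            return 1.0
        return min(1.0, max(0.0, self.gamma0 + self.gamma1 * gc))

    def capture_probability(self, x: float, gc: float) -> float:
        """p = p_max · logistic(identity) · clamp(gamma0 + gamma1·gc, 0, 1)."""
        return self.p_max * self.identity_term(x) * self.gc_term(gc)


def fragment_pool(
    design: MockDesign,
    genomes: dict[str, str],
    n_fragments: int,
    *,
    mean_len: float = DEFAULT_MEAN_INSERT,
    sd_len: float = 60.0,
    seed: int = 0,
    truth: dict[str, list[TruthInterval]] | None = None,
    min_truth_overlap: int = 50,
) -> list[Fragment]:
    """Sample fragments from the pooled community.

    Strains are drawn proportionally to mass fractions, fragment length is
    Normal(mean_len, sd_len) truncated to [50, source length], start is
    uniform, strand is uniform.  Truth families are attached from planted-gene
    intervals overlapping by >= ``min_truth_overlap`` bp.
    """
    rng = np.random.default_rng(seed)
    strains = [s.name for s in design.strains]
    fractions = np.asarray(design.mass_fractions, dtype=float)
    picks = rng.choice(len(strains), size=n_fragments, p=fractions)
    fragments: list[Fragment] = []
    for i, si in enumerate(picks):
        name = strains[si]
        source = genomes[name]
        length = int(round(rng.normal(mean_len, sd_len)))
        length = max(_MIN_FRAGMENT, min(length, len(source)))
        start = int(rng.integers(0, len(source) - length + 1))
        end = start + length
        strand = "+" if rng.random() < 0.5 else "-"
        seq = source[start:end]
        if strand == "-":
            seq = revcomp(seq)
        families = frozenset(
            iv.family
            for iv in (truth or {}).get(name, ())
            if min(end, iv.end) - max(start, iv.start) >= min_truth_overlap
        )
        fragments.append(
            Fragment(
                id=f"frag_{i:07d}",
                strain=name,
                start=start,
                end=end,
                strand=strand,
                sequence=seq,
                truth_families=families,
            )
        )
    return fragments


class _SeedIndex:
    """Exact k-mer index over probe sequences (both strands) used to shortlist
    probes before alignment; fragments sharing no seed with any probe are
    treated as identity-0 (never captured in practice)."""

    def __init__(self, panel: ProbePanel, word: int = 14):
        self.word = word
        self.probes = [p.sequence.upper() for p in panel]
        self.index: dict[str, set[int]] = {}
        for pi, seq in enumerate(self.probes):
            for variant in (seq, revcomp(seq)):
                for j in range(len(variant) - word + 1):
                    self.index.setdefault(variant[j : j + word], set()).add(pi)

    def candidates(self, fragment_seq: str, limit: int = 8) -> list[int]:
        votes: dict[int, int] = {}
        seq = fragment_seq.upper()
        for j in range(len(seq) - self.word + 1):
            for pi in self.index.get(seq[j : j + self.word], ()):
                votes[pi] = votes.get(pi, 0) + 1
        ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
        return [pi for pi, _ in ranked[:limit]]


def best_probe_identity(
    fragment_seq: str, seed_index: _SeedIndex, min_len: int
) -> float:
    """Best local-alignment identity of any shortlisted probe vs the fragment
    (either strand), requiring >= ``min_len`` alignment columns."""
    best = 0.0
    aligner = nucleotide_local_aligner()
    targets = (fragment_seq.upper(), revcomp(fragment_seq.upper()))
    for pi in seed_index.candidates(fragment_seq):
        probe = seed_index.probes[pi]
        for target in targets:
            res = local_alignment(probe, target, aligner)
            if res is None:
                continue
            _, identity, columns, _, _ = res
            if columns >= min_len and identity > best:
                best = identity
    return best


def hybridize(
    fragments: list[Fragment],
    panel: ProbePanel,
    model: CaptureModel,
    seed: int = 0,
) -> list[Fragment]:
    """Bernoulli capture of each fragment at the model's probability."""
    if len(panel) == 0:
        return []
    rng = np.random.default_rng(seed)
    index = _SeedIndex(panel)
    captured = []
    for frag in fragments:
        x = best_probe_identity(frag.sequence, index, model.probe_match_min_len)
        p = model.capture_probability(x, frag.gc_fraction)
        if rng.random() < p:
            captured.append(frag)
    return captured


# ------------------------------------------------------------------- reads

@dataclass(frozen=True)
class ReadPair:
    read_id: str
    seq1: str
    seq2: str
    fragment_id: str
    truth_families: frozenset[str]

    @property
    def on_target(self) -> bool:
        return bool(self.truth_families)


@dataclass
class ReadSet:
    pairs: list[ReadPair] = field(default_factory=list)
    read_length: int = DEFAULT_READ_LENGTH
    quality_char: str = "?"  # constant Q30

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @property
    def on_target_fraction(self) -> float:
        if not self.pairs:
            return 0.0
        return sum(p.on_target for p in self.pairs) / len(self.pairs)

    def write_fastq(self, prefix: str | Path) -> tuple[Path, Path]:
        prefix = Path(prefix)
        r1, r2 = Path(f"{prefix}_R1.fastq"), Path(f"{prefix}_R2.fastq")
        with open(r1, "w") as f1, open(r2, "w") as f2:
            for p in self.pairs:
                f1.write(f"@{p.read_id}/1\n{p.seq1}\n+\n{self.quality_char * len(p.seq1)}\n")
                f2.write(f"@{p.read_id}/2\n{p.seq2}\n+\n{self.quality_char * len(p.seq2)}\n")
        return r1, r2

    def write_provenance(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\tfragment_id\ton_target\ttruth_families\n")
            for p in self.pairs:
                fams = ",".join(sorted(p.truth_families))
                fh.write(f"{p.read_id}\t{p.fragment_id}\t{int(p.on_target)}\t{fams}\n")


def _with_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    hits = np.nonzero(rng.random(arr.size) < error_rate)[0]
    bases = "ACGT"
    for i in hits:
        alts = [b for b in bases if b != arr[i]]
        arr[i] = alts[int(rng.integers(3))]
    return "".join(arr)


def sequence_reads(
    fragments: list[Fragment],
    read_len: int = DEFAULT_READ_LENGTH,
    error_rate: float = 0.0,
    seed: int = 0,
) -> ReadSet:
    """Paired-end reads off both fragment ends (mate 2 reverse-complemented),
    uniform substitution errors, constant Q30 qualities."""
    rng = np.random.default_rng(seed)
    pairs = []
    for frag in fragments:
        seq1 = frag.sequence[:read_len]
        seq2 = revcomp(frag.sequence)[:read_len]
        pairs.append(
            ReadPair(
                read_id=f"read_{frag.id}",
                seq1=_with_errors(seq1, error_rate, rng),
                seq2=_with_errors(seq2, error_rate, rng),
                fragment_id=frag.id,
                truth_families=frag.truth_families,
            )
        )
    return ReadSet(pairs=pairs, read_length=read_len)
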