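"""Greedy identity clustering and 50-mer capture-probe design.

Target sequences are clustered greedily at an identity threshold (default
0.80, shorter-sequence convention, longest sequence founds each cluster) and
up to six unique probes per cluster are picked from the representative,
scored by how many cluster members they cover and how close their melting
temperature sits to the design target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._pairwise import gc_fraction, global_identity
from .errors import ValidationError
from .target_registry import SequenceRecord

DEFAULT_THRESHOLD = 0.80
DEFAULT_PROBE_LENGTH = 50
DEFAULT_MAX_PROBES = 6
DEFAULT_TM_TARGET = 47.0
DEFAULT_MAX_MISMATCHES = 5

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class Cluster:
    representative_id: str
    member_ids: tuple[str, ...]  # includes the representative
    threshold: float


@dataclass(frozen=True)
class Probe:
    sequence: str
    family: str | None
    cluster_id: str
    offset: int  # 0-based start on the cluster representative
    gc_fraction: float
    tm_celsius: float
    member_coverage: int


def melting_temperature(sequence: str) -> float:
    """Length-adjusted GC melting temperature: 64.9 + 41*(nGC - 16.4)/len."""
    n_gc = sum(1 for c in sequence.upper() if c in "GC")
    return 64.9 + 41.0 * (n_gc - 16.4) / len(sequence)


def cluster_sequences(
    seqs: list[SequenceRecord],
    threshold: float = DEFAULT_THRESHOLD,
    *,
    identity_fn=global_identity,
) -> list[Cluster]:
    """Greedy incremental clustering.

    Sequences are visited longest first (ties by id); each joins the first
    existing cluster whose representative it matches at >= ``threshold``
    identity, otherwise it founds a new cluster.
    """
    if not 0 < threshold <= 1:
        raise ValidationError("threshold must be in (0, 1]")
    order = sorted(seqs, key=lambda r: (-len(r.residues), r.id))
    reps: list[SequenceRecord] = []
    members: list[list[str]] = []
    for rec in order:
        for i, rep in enumerate(reps):
            if identity_fn(rec.residues, rep.residues) >= threshold:
                members[i].append(rec.id)
                break
        else:
            reps.append(rec)
            members.append([rec.id])
    return [
        Cluster(representative_id=rep.id, member_ids=tuple(mem), threshold=threshold)
        for rep, mem in zip(reps, members)
    ]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def _covered_offsets(rep: str, member: str, k: int, max_mismatches: int) -> np.ndarray:
    """Boolean per representative k-mer offset: does ``member`` contain a
    length-k window matching it with <= ``max_mismatches`` (ungapped, any
    diagonal shift)?

    Only diagonals sharing an exact seed word are evaluated; by pigeonhole a
    window with <= m mismatches over k bases contains an exact run of
    ``k // (m + 1)`` matches, so any seed no longer than that keeps the scan
    lossless.
    """
    a, b = _encode(rep), _encode(member)
    n_off = len(a) - k + 1
    covered = np.zeros(n_off, dtype=bool)
    need = k - max_mismatches
    word = max(4, k // (max_mismatches + 1))
    index: dict[bytes, list[int]] = {}
    bb = b.tobytes()
    for j in range(len(b) - word + 1):
        index.setdefault(bb[j : j + word], []).append(j)
    ab = a.tobytes()
    diagonals = {
        m - j
        for j in range(len(a) - word + 1)
        for m in index.get(ab[j : j + word], ())
    }
    kernel = np.ones(k, dtype=np.int32)
    for d in sorted(diagonals):
        lo = max(0, -d)
        hi = min(len(a), len(b) - d)
        if hi - lo < k:
            continue
        eq = (a[lo:hi] == b[lo + d : hi + d]).astype(np.int32)
        window = np.convolve(eq, kernel, mode="valid")
        offs = np.nonzero(window >= need)[0] + lo
        covered[offs[offs < n_off]] = True
    return covered


def design_probes(
    cluster: Cluster,
    members: dict[str, str],
    *,
    family: str | None = None,
    k: int = DEFAULT_PROBE_LENGTH,
    max_probes: int = DEFAULT_MAX_PROBES,
    tm_target: float = DEFAULT_TM_TARGET,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    max_homopolymer: int = 7,
) -> list[Probe]:
    """Pick up to ``max_probes`` k-mers of the cluster representative.

    Candidates containing ambiguity codes or homopolymer runs longer than
    ``max_homopolymer`` are discarded; the rest are ranked by member coverage
    (windows with <= ``max_mismatches``), then |Tm - tm_target|, then offset,
    and chosen greedily with pairwise offset spacing >= k // 2.
    """
    rep = members[cluster.representative_id].upper()
    if len(rep) < k:
        raise ValidationError(
            f"representative {cluster.representative_id!r} shorter than probe length {k}"
        )
    n_off = len(rep) - k + 1
    valid = np.ones(n_off, dtype=bool)
    for j in range(n_off):
        window = rep[j : j + k]
        if set(window) - _ACGT or _max_run(window) > max_homopolymer:
            valid[j] = False
    coverage = np.zeros(n_off, dtype=np.int64)
    for mid in cluster.member_ids:
        coverage += _covered_offsets(rep, members[mid].upper(), k, max_mismatches)
    candidates = [
        (int(-coverage[j]), abs(melting_temperature(rep[j : j + k]) - tm_target), j)
        for j in range(n_off)
        if valid[j] and coverage[j] >= 1
    ]
    candidates.sort()
    spacing = k // 2
    chosen: list[int] = []
    for _, _, j in candidates:
        if len(chosen) >= max_probes:
            break
        if all(abs(j - c) >= spacing for c in chosen):
            chosen.append(j)
    probes = []
    for j in chosen:
        seq = rep[j : j + k]
        probes.append(
            Probe(
                sequence=seq,
                family=family,
                cluster_id=cluster.representative_id,
                offset=j,
                gc_fraction=gc_fraction(seq),
                tm_celsius=melting_temperature(seq),
                member_coverage=int(coverage[j]),
            )
        )
    return probes


def _max_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


@dataclass
class ProbePanel:
    probes: list[Probe] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.probes)

    def __iter__(self):
        return iter(self.probes)

    @property
    def by_family(self) -> dict[str, list[Probe]]:
        out: dict[str, list[Probe]] = {}
        for p in self.probes:
            out.setdefault(p.family or "unassigned", []).append(p)
        return out

    @property
    def by_cluster(self) -> dict[str, list[Probe]]:
        out: dict[str, list[Probe]] = {}
        for p in self.probes:
            out.setdefault(p.cluster_id, []).append(p)
        return out

    def summary(self) -> dict:
        gcs = [p.gc_fraction for p in self.probes]
        return {
            "n_probes": len(self.probes),
            "per_family": {f: len(ps) for f, ps in sorted(self.by_family.items())},
            "per_cluster": {c: len(ps) for c, ps in sorted(self.by_cluster.items())},
            "gc_mean": float(np.mean(gcs)) if gcs else None,
            "gc_min": float(np.min(gcs)) if gcs else None,
            "gc_max": float(np.max(gcs)) if gcs else None,
        }

    # ------------------------------------------------------------------ io
    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "panel.fasta", "w") as fh:
            for i, p in enumerate(self.probes):
                fh.write(
                    f">probe_{i:06d} family={p.family} cluster={p.cluster_id} "
                    f"offset={p.offset} gc={p.gc_fraction:.4f} tm={p.tm_celsius:.2f} "
                    f"coverage={p.member_coverage}\n{p.sequence}\n"
                )
        with open(outdir / "panel.tsv", "w") as fh:
            fh.write("probe_id\tfamily\tcluster\toffset\tgc\ttm\tcoverage\tsequence\n")
            for i, p in enumerate(self.probes):
                fh.write(
                    f"probe_{i:06d}\t{p.family}\t{p.cluster_id}\t{p.offset}\t"
                    f"{p.gc_fraction:.4f}\t{p.tm_celsius:.2f}\t{p.member_coverage}\t{p.sequence}\n"
                )
        (outdir / "panel.json").write_text(json.dumps(self.summary(), indent=2))

    @classmethod
    def read(cls, outdir: str | Path) -> "ProbePanel":
        """Load a panel written by :meth:`write` (from ``panel.tsv``)."""
        probes = []
        with open(Path(outdir) / "panel.tsv") as fh:
            fh.readline()
            for line in fh:
                _, family, cluster, offset, gc, tm, coverage, seq = line.rstrip("\n").split("\t")
                probes.append(
                    Probe(
                        sequence=seq,
                        family=None if family == "None" else family,
                        cluster_id=cluster,
                        offset=int(offset),
                        gc_fraction=float(gc),
                        tm_celsius=float(tm),
                        member_coverage=int(coverage),
                    )
                )
        return cls(probes=probes)


def assemble_panel(per_cluster_probes: list[list[Probe]]) -> ProbePanel:
    """Concatenate per-cluster probe lists, dropping duplicate sequences.

    The copy from the earlier cluster (input order) wins.
    """
    seen: set[str] = set()
    probes: list[Probe] = []
    for probe_list in per_cluster_probes:
        for p in probe_list:
            if p.sequence in seen:
                continue
            seen.add(p.sequence)
            probes.append(p)
    return ProbePanel(probes=probes)
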