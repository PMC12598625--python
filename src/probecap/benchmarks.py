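"""Self-contained benchmark computations on seeded synthetic fixtures.

Each ``target_*`` function generates its own inputs, runs the relevant
pipeline stage with default parameters, and measures the advertised quantity
from the outputs; they back both the acceptance report script and the test
suite.  Returns are ``(value, n)`` with ``n`` the problem size measured.
"""

from __future__ import annotations

import numpy as np

from . import probe_design, read_classify
from ._pairwise import global_identity
from .mock_community import mutate_cds, synth_reference_set
from .read_classify import ProteinDB, map_and_retain
from .target_registry import (
    Registry,
    SequenceRecord,
    build_profile,
    calibrate_profile,
    sample_background_sequences,
    search_profile,
)

_BASES = np.array(list("ACGT"))


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _mutate(seq: str, divergence: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    hits = np.nonzero(rng.random(arr.size) < divergence)[0]
    for i in hits:
        arr[i] = _BASES[_BASES != arr[i]][rng.integers(3)]
    return "".join(arr)


def target_probe_length(seed: int = 1) -> tuple[float, int]:
    """Distinct probe length over a 20-cluster synthetic suite (must be one)."""
    rng = np.random.default_rng(seed)
    per_cluster = []
    for c in range(20):
        consensus = _random_seq(int(rng.integers(600, 1801)), rng)
        n_members = int(rng.integers(5, 31))
        seqs = [
            SequenceRecord(
                id=f"c{c:02d}_m{m:02d}",
                residues=_mutate(consensus, rng.uniform(0.0, 0.15), rng),
            )
            for m in range(n_members)
        ]
        lookup = {r.id: r.residues for r in seqs}
        for cluster in probe_design.cluster_sequences(seqs):
            per_cluster.append(probe_design.design_probes(cluster, lookup, family=f"fam{c:02d}"))
    panel = probe_design.assemble_panel(per_cluster)
    lengths = {len(p.sequence) for p in panel}
    if len(lengths) != 1:
        raise AssertionError(f"probe lengths not unique: {sorted(lengths)}")
    return float(lengths.pop()), len(panel)


def target_min_cluster_identity(seed: int = 2) -> tuple[float, int]:
    """Minimum member-to-representative identity (%) after default clustering
    of 200 sequences in 10 families spanning ~60-100% pairwise identity."""
    rng = np.random.default_rng(seed)
    seqs = []
    for f in range(10):
        consensus = _random_seq(int(rng.integers(400, 801)), rng)
        for m in range(20):
            divergence = rng.uniform(0.0, 0.40)
            seqs.append(
                SequenceRecord(
                    id=f"f{f:02d}_m{m:02d}", residues=_mutate(consensus, divergence, rng)
                )
            )
    clusters = probe_design.cluster_sequences(seqs)
    lookup = {r.id: r.residues for r in seqs}
    min_identity = 100.0
    for cluster in clusters:
        rep = lookup[cluster.representative_id]
        for mid in cluster.member_ids:
            min_identity = min(min_identity, 100.0 * global_identity(lookup[mid], rep))
    return min_identity, len(seqs)


def target_min_retained_identity(seed: int = 3) -> tuple[float, int]:
    """Minimum percent identity among matches the classifier retains on a
    mutation-ladder read set (ladder spans ~30-95% protein identity)."""
    registry = Registry.default()
    refset = synth_reference_set(registry, seed=seed)
    db = ProteinDB(refset.protein_db(include_decoys=False)).calibrate(seed=seed)
    rng = np.random.default_rng(seed)
    identities = []
    families = ("nifH", "nosZ", "mcrA", "nirS")
    for divergence in (0.50, 0.40, 0.30, 0.20, 0.12, 0.06, 0.02):
        for fam in families:
            variant = mutate_cds(refset[fam].cds, divergence, rng)
            for _ in range(3):
                start = 3 * int(rng.integers(0, (len(variant) - 300) // 3))
                read = variant[start : start + 300]
                hits = map_and_retain(f"{fam}_{divergence}", read, db)
                identities.extend(h.percent_identity for h in hits)
    if not identities:
        raise AssertionError("ladder produced no retained hits")
    return min(identities), len(identities)


_CODON = {  # one deterministic codon per amino acid (reverse translation)
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT", "Q": "CAA",
    "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT", "L": "CTT", "K": "AAA",
    "M": "ATG", "F": "TTT", "P": "CCT", "S": "TCT", "T": "ACT", "W": "TGG",
    "Y": "TAT", "V": "GTT",
}


def _reverse_translate(peptide: str) -> str:
    return "".join(_CODON[a] for a in peptide)


def fusion_read_fixture(seed: int = 5, overlaps: tuple[int, ...] = (5, 10, 14, 16, 25)):
    """Fusion-style reads whose two protein segments align with controlled
    overlaps.  For each requested overlap ``d`` two 60-aa proteins A and B are
    built with A's last ``d`` residues equal to B's first ``d``; the read
    peptide A + B[d:] then aligns to A on [0,60) and to B on [60-d,120-d).
    Returns (reads, db) with distinct non-homologous family labels."""
    rng = np.random.default_rng(seed)
    aa = np.array(list("ARNDCQEGHILKMFPSTWYV"))
    records, reads = [], []
    for i, d in enumerate(overlaps):
        prot_a = "".join(rng.choice(aa, size=60))
        prot_b = prot_a[60 - d :] + "".join(rng.choice(aa, size=60 - d))
        records.append(SequenceRecord(id=f"A{i}", residues=prot_a, family_label=f"famA{i}"))
        records.append(SequenceRecord(id=f"B{i}", residues=prot_b, family_label=f"famB{i}"))
        read_peptide = prot_a + prot_b[d:]
        reads.append((f"fusion_overlap{d}", _reverse_translate(read_peptide)))
    db = ProteinDB(records).calibrate(seed=seed)
    return reads, db


def target_max_codirectional_overlap(seed: int = 5) -> tuple[float, int]:
    """Maximum pairwise overlap (aa, read coordinates) among retained
    co-directional matches over the fusion-read fixture."""
    reads, db = fusion_read_fixture(seed)
    max_overlap = 0.0
    n_hits = 0
    for read_id, seq in reads:
        hits = map_and_retain(read_id, seq, db)
        n_hits += len(hits)
        for i, a in enumerate(hits):
            for b in hits[i + 1 :]:
                if a.direction != b.direction:
                    continue
                lo = max(a.nt_interval[0], b.nt_interval[0])
                hi = min(a.nt_interval[1], b.nt_interval[1])
                max_overlap = max(max_overlap, max(0, hi - lo) / 3.0)
    return max_overlap, n_hits


def target_max_accepted_evalue(seed: int = 6) -> tuple[float, int]:
    """Maximum E-value among sequences accepted by the default profile-search
    filter on 50 family members + 500 random decoys."""
    rng = np.random.default_rng(seed)
    consensus = _random_seq(600, rng)
    alignment = [
        SequenceRecord(id=f"train{i:02d}", residues=_mutate(consensus, 0.08, rng))
        for i in range(12)
    ]
    profile = build_profile(alignment, "synthfam")
    profile = calibrate_profile(profile, n_decoys=500, seed=seed)
    members = [
        SequenceRecord(id=f"member{i:03d}", residues=_mutate(consensus, 0.10, rng))
        for i in range(50)
    ]
    decoys = [
        SequenceRecord(id=f"decoy{i:03d}", residues=s)
        for i, s in enumerate(sample_background_sequences(500, 600, rng))
    ]
    hits = search_profile(profile, members + decoys, e_threshold=0.001)
    member_ids = {m.id for m in members}
    recovered = sum(1 for h in hits if h[0] in member_ids)
    if recovered < len(members):
        raise AssertionError(f"only {recovered}/50 members recovered")
    return max(h[2] for h in hits), len(members) + len(decoys)


def target_registry_size() -> tuple[float, int]:
    """Number of top-level gene-family entries in the shipped registry."""
    registry = Registry.default()
    return float(len(registry)), len(registry)
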