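"""Mock-community design and synthetic fixture generation.

Everything the rest of the pipeline consumes can be generated here: a
synthetic reference set (one coding consensus per registry family, with
homolog-group members sharing an ancestor so cross-hits actually occur),
strain genomes with planted marker genes and truth coordinates, and mock
designs — mass fractions hitting a target weighted GC mol% plus the
ground-truth expected per-family abundances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Seq import Seq
from scipy.optimize import brentq

from ._pairwise import gc_fraction, revcomp
from .errors import InfeasibleTargetError, PlacementError, ValidationError
from .target_registry import Registry, SequenceRecord

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


# --------------------------------------------------------------- design math

@dataclass(frozen=True)
class StrainSpec:
    name: str
    length_bp: int
    gc_molpercent: float
    gene_copies: dict[str, int] = field(default_factory=dict)
    kind: str = "genome"  # "genome" | "fragment"
    dna_concentration: float | None = None  # ng/uL, only used for volume->mass

    def __post_init__(self):
        if not 0 < self.gc_molpercent < 100:
            raise ValidationError(f"{self.name}: gc_molpercent must be in (0,100)")
        if any(v < 0 for v in self.gene_copies.values()):
            raise ValidationError(f"{self.name}: gene copies must be >= 0")
        if self.kind not in ("genome", "fragment"):
            raise ValidationError(f"{self.name}: unknown kind {self.kind!r}")


def weighted_gc(strains: list[StrainSpec], mass_fractions) -> float:
    """Mass-fraction-weighted GC mol% of the pooled DNA."""
    f = np.asarray(mass_fractions, dtype=float)
    if abs(f.sum() - 1.0) > 1e-6:
        raise ValidationError(f"mass fractions sum to {f.sum():.8f}, expected 1")
    gc = np.array([s.gc_molpercent for s in strains])
    return float(f @ gc)


def solve_fractions(
    strains: list[StrainSpec],
    target_gc: float,
    prior_fractions=None,
) -> np.ndarray:
    """Mass fractions achieving ``target_gc`` mol%, closest (in KL divergence)
    to the prior (default uniform).

    The minimizer of KL(f || prior) under the two linear constraints is the
    exponentially tilted prior f_i ∝ prior_i · exp(λ·gc_i); λ is found by
    root-finding on the weighted GC, which is monotone in λ.
    """
    gc = np.array([s.gc_molpercent for s in strains], dtype=float)
    if prior_fractions is None:
        prior = np.full(len(strains), 1.0 / len(strains))
    else:
        prior = np.asarray(prior_fractions, dtype=float)
        prior = prior / prior.sum()
    lo, hi = float(gc.min()), float(gc.max())
    if not lo <= target_gc <= hi:
        raise InfeasibleTargetError(target_gc, lo, hi)

    def tilted(lam: float) -> np.ndarray:
        w = prior * np.exp(lam * (gc - gc.mean()))
        return w / w.sum()

    def gap(lam: float) -> float:
        return float(tilted(lam) @ gc) - target_gc

    if abs(gap(0.0)) < 1e-12:
        return tilted(0.0)
    lam_lo, lam_hi = -1.0, 1.0
    for _ in range(200):
        if gap(lam_lo) <= 0 <= gap(lam_hi):
            break
        lam_lo *= 2.0
        lam_hi *= 2.0
    else:  # pragma: no cover - boundary targets
        raise InfeasibleTargetError(target_gc, lo, hi)
    lam = brentq(gap, lam_lo, lam_hi, xtol=1e-14)
    return tilted(lam)


def expected_abundance(strains: list[StrainSpec], mass_fractions) -> dict[str, float]:
    """Ground-truth per-family percent abundance.

    Gene dosage d_g = Σ_i f_i · copies_{g,i} / length_i (copies per unit
    mass); abundances are dosages normalized to 100 over families present.
    """
    f = np.asarray(mass_fractions, dtype=float)
    if abs(f.sum() - 1.0) > 1e-6:
        raise ValidationError("mass fractions must sum to 1")
    dosage: dict[str, float] = {}
    for frac, strain in zip(f, strains):
        for fam, copies in strain.gene_copies.items():
            if copies > 0:
                dosage[fam] = dosage.get(fam, 0.0) + frac * copies / strain.length_bp
    total = sum(dosage.values())
    if total <= 0:
        raise ValidationError("no target genes anywhere in the design")
    return {fam: 100.0 * d / total for fam, d in sorted(dosage.items())}


def volume_to_mass_fractions(volumes, concentrations) -> np.ndarray:
    """Convert pipetted volumes (uL) and concentrations (ng/uL) to mass fractions."""
    mass = np.asarray(volumes, dtype=float) * np.asarray(concentrations, dtype=float)
    if mass.sum() <= 0:
        raise ValidationError("total DNA mass must be positive")
    return mass / mass.sum()


@dataclass
class MockDesign:
    strains: list[StrainSpec]
    mass_fractions: np.ndarray
    weighted_gc: float
    expected_abundance: dict[str, float]

    @classmethod
    def from_target_gc(
        cls, strains: list[StrainSpec], target_gc: float, prior_fractions=None
    ) -> "MockDesign":
        f = solve_fractions(strains, target_gc, prior_fractions)
        return cls(
            strains=strains,
            mass_fractions=f,
            weighted_gc=weighted_gc(strains, f),
            expected_abundance=expected_abundance(strains, f),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "MockDesign":
        doc = json.loads(Path(path).read_text())
        strains = [
            StrainSpec(
                name=s["name"],
                kind=s["kind"],
                length_bp=s["length_bp"],
                gc_molpercent=s["gc_molpercent"],
                gene_copies=s["gene_copies"],
            )
            for s in doc["strains"]
        ]
        fractions = np.array([doc["mass_fractions"][s.name] for s in strains])
        return cls(
            strains=strains,
            mass_fractions=fractions,
            weighted_gc=doc["weighted_gc"],
            expected_abundance=doc["expected_abundance"],
        )

    def to_json(self, path: str | Path) -> None:
        doc = {
            "weighted_gc": self.weighted_gc,
            "mass_fractions": {
                s.name: float(f) for s, f in zip(self.strains, self.mass_fractions)
            },
            "expected_abundance": self.expected_abundance,
            "strains": [
                {
                    "name": s.name,
                    "kind": s.kind,
                    "length_bp": s.length_bp,
                    "gc_molpercent": s.gc_molpercent,
                    "gene_copies": s.gene_copies,
                }
                for s in self.strains
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=2))


def write_strains_tsv(strains: list[StrainSpec], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tkind\tlength_bp\tgc_molpercent\tdna_concentration\tgene_copies\n")
        for s in strains:
            copies = ",".join(f"{k}:{v}" for k, v in sorted(s.gene_copies.items()))
            conc = "" if s.dna_concentration is None else f"{s.dna_concentration}"
            fh.write(f"{s.name}\t{s.kind}\t{s.length_bp}\t{s.gc_molpercent}\t{conc}\t{copies}\n")


def read_strains_tsv(path: str | Path) -> list[StrainSpec]:
    strains = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            copies = {}
            if parts[idx["gene_copies"]]:
                for tok in parts[idx["gene_copies"]].split(","):
                    k, v = tok.split(":")
                    copies[k] = int(v)
            conc = parts[idx["dna_concentration"]]
            strains.append(
                StrainSpec(
                    name=parts[idx["name"]],
                    kind=parts[idx["kind"]],
                    length_bp=int(parts[idx["length_bp"]]),
                    gc_molpercent=float(parts[idx["gc_molpercent"]]),
                    gene_copies=copies,
                    dna_concentration=float(conc) if conc else None,
                )
            )
    return strains


# ------------------------------------------------------ reference synthesis

@dataclass(frozen=True)
class FamilyReference:
    family: str
    cds: str  # consensus coding sequence (no internal stops, frame 0)
    is_decoy: bool = False

    @property
    def protein(self) -> str:
        return str(Seq(self.cds).translate())


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    codons = rng.choice(len(_CODONS), size=n_codons)
    return "ATG" + "".join(_CODONS[i] for i in codons[1:])


def mutate_cds(
    cds: str,
    divergence: float,
    rng: np.random.Generator,
    *,
    gc_weight: float | None = None,
) -> str:
    """Substitution-only, codon-aware mutation of a coding sequence.

    Each position mutates independently with probability ``divergence``; the
    replacement base is drawn uniformly from the three alternatives, or
    GC/AT-weighted when ``gc_weight`` (a target GC fraction) is given.
    Substitutions creating an in-frame stop codon are skipped, so the
    translated product never gains internal stops.
    """
    seq = list(cds.upper())
    n = len(seq)
    positions = np.nonzero(rng.random(n) < divergence)[0]
    for pos in positions:
        old = seq[pos]
        alts = [b for b in "ACGT" if b != old]
        if gc_weight is None:
            p = None
        else:
            w = np.array([gc_weight / 2 if b in "GC" else (1 - gc_weight) / 2 for b in alts])
            p = w / w.sum()
        new = alts[int(rng.choice(len(alts), p=p))]
        codon_start = (pos // 3) * 3
        codon = seq[codon_start : codon_start + 3]
        codon[pos - codon_start] = new
        if "".join(codon) in _STOPS:
            continue
        seq[pos] = new
    return "".join(seq)


class ReferenceSet:
    """Synthetic per-family consensus CDS pool (families + decoys)."""

    def __init__(self, registry: Registry, references: dict[str, FamilyReference]):
        self.registry = registry
        self.references = references

    def __getitem__(self, family: str) -> FamilyReference:
        return self.references[family]

    @property
    def family_names(self) -> list[str]:
        return [n for n, r in self.references.items() if not r.is_decoy]

    def variants(
        self, family: str, n: int, divergence: float, seed: int, *,
        gc_weight: float | None = None,
    ) -> list[SequenceRecord]:
        """Mutated copies of the family consensus (equal length: alignment-free rows)."""
        rng = np.random.default_rng(seed)
        cds = self.references[family].cds
        return [
            SequenceRecord(
                id=f"{family}_v{i:03d}",
                residues=mutate_cds(cds, divergence, rng, gc_weight=gc_weight),
                family_label=family,
            )
            for i in range(n)
        ]

    def alignment(self, family: str, n_rows: int, divergence: float, seed: int):
        """A gapless reference 'alignment' of mutated consensus copies."""
        return self.variants(family, n_rows, divergence, seed)

    def protein_db(self, *, include_decoys: bool = True) -> list[SequenceRecord]:
        out = []
        for name, ref in self.references.items():
            if ref.is_decoy and not include_decoys:
                continue
            out.append(
                SequenceRecord(id=f"{name}_ref", residues=ref.protein, family_label=name)
            )
        return out


def synth_reference_set(
    registry: Registry,
    seed: int = 0,
    *,
    codon_range: tuple[int, int] = (150, 320),
    group_divergence: float = 0.22,
    decoy_divergence: float = 0.30,
) -> ReferenceSet:
    """Generate one consensus CDS per family and decoy.

    Families sharing a homolog group are derived from a common ancestor CDS
    at ``group_divergence`` so that translated cross-hits above the 60%
    identity floor are plausible; unrelated families are independent draws.
    """
    rng = np.random.default_rng(seed)
    ancestors: dict[str, str] = {}

    def ancestor(group: str, n_codons: int) -> str:
        if group not in ancestors:
            ancestors[group] = _random_cds(n_codons, rng)
        return ancestors[group]

    references: dict[str, FamilyReference] = {}
    for fam in registry.families:
        n_codons = int(rng.integers(*codon_range))
        if fam.homolog_group:
            cds = mutate_cds(ancestor(fam.homolog_group, n_codons), group_divergence, rng)
        else:
            cds = _random_cds(n_codons, rng)
        references[fam.name] = FamilyReference(family=fam.name, cds=cds)
    for decoy, groups in registry.decoys.items():
        n_codons = int(rng.integers(*codon_range))
        cds = mutate_cds(ancestor(groups[0], n_codons), decoy_divergence, rng)
        references[decoy] = FamilyReference(family=decoy, cds=cds, is_decoy=True)
    return ReferenceSet(registry, references)


# ----------------------------------------------------------- strain genomes

@dataclass(frozen=True)
class TruthInterval:
    family: str
    start: int  # 0-based
    end: int  # half-open
    strand: str  # "+" | "-"


def synth_strain(
    name: str,
    length_bp: int,
    gc_molpercent: float,
    genes: dict[str, tuple[int, float]],  # family -> (copies, divergence)
    refset: ReferenceSet,
    seed: int,
    *,
    kind: str = "genome",
    gc_ameliorate: bool = False,
) -> tuple[StrainSpec, str, list[TruthInterval]]:
    """Background genome at the requested GC with planted marker genes.

    Gene copies are codon-aware mutations of the family consensus, planted at
    non-overlapping positions on random strands.  With ``gc_ameliorate`` the
    substituted bases are drawn GC-weighted toward the host GC, coupling gene
    GC to genome GC.  Returns the spec (with re-measured GC), the genome
    string, and 0-based half-open truth intervals.
    """
    rng = np.random.default_rng(seed)
    gene_lengths = {
        fam: len(refset[fam].cds) for fam, (copies, _) in genes.items() if copies > 0
    }
    total_gene_bp = sum(gene_lengths[f] * genes[f][0] for f in gene_lengths)
    if total_gene_bp > length_bp:
        raise PlacementError(
            f"{name}: {total_gene_bp} bp of genes exceed genome length {length_bp}"
        )
    g = gc_molpercent / 100.0
    genome = rng.choice(_BASES, size=length_bp, p=[(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])

    placed: list[tuple[int, int]] = []
    truth: list[TruthInterval] = []
    for fam in sorted(gene_lengths):
        copies, divergence = genes[fam]
        glen = gene_lengths[fam]
        for _ in range(copies):
            for _attempt in range(1000):
                start = int(rng.integers(0, length_bp - glen + 1))
                end = start + glen
                if all(end <= s or start >= e for s, e in placed):
                    break
            else:
                raise PlacementError(f"{name}: could not place {fam} (genome overcrowded)")
            placed.append((start, end))
            variant = mutate_cds(
                refset[fam].cds,
                divergence,
                rng,
                gc_weight=g if gc_ameliorate else None,
            )
            strand = "+" if rng.random() < 0.5 else "-"
            insert = variant if strand == "+" else revcomp(variant)
            genome[start:end] = np.frombuffer(insert.encode(), dtype="S1").astype("U1")
            truth.append(TruthInterval(family=fam, start=start, end=end, strand=strand))
    genome_str = "".join(genome)
    spec = StrainSpec(
        name=name,
        kind=kind,
        length_bp=length_bp,
        gc_molpercent=100.0 * gc_fraction(genome_str),
        gene_copies={fam: genes[fam][0] for fam in gene_lengths},
    )
    truth.sort(key=lambda t: t.start)
    return spec, genome_str, truth


def write_truth_bed(truth: dict[str, list[TruthInterval]], path: str | Path) -> None:
    """BED6 (0-based, half-open) of planted genes, one line per copy."""
    with open(path, "w") as fh:
        for strain in sorted(truth):
            for iv in truth[strain]:
                fh.write(f"{strain}\t{iv.start}\t{iv.end}\t{iv.family}\t0\t{iv.strand}\n")


def read_truth_bed(path: str | Path) -> dict[str, list[TruthInterval]]:
    out: dict[str, list[TruthInterval]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, fam, _, strand = line.rstrip("\n").split("\t")[:6]
            out.setdefault(chrom, []).append(
                TruthInterval(family=fam, start=int(start), end=int(end), strand=strand)
            )
    return out


def write_genomes_fasta(genomes: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(genomes):
            fh.write(f">{name}\n")
            seq = genomes[name]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
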