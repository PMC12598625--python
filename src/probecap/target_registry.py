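"""Gene-family registry, profile models, profile search and dereplication.

A :class:`Registry` names the marker-gene families a panel targets and the
homolog groups that require competitive disambiguation downstream.  For each
family a :class:`ProfileModel` — a position-specific scoring matrix with
affine gaps, scored locally and calibrated against a Gumbel null — supports
E-value-filtered searches of nucleotide sequence collections.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.stats import gumbel_r

from . import _pssm
from ._pairwise import gc_fraction
from .errors import (
    AlignmentShapeError,
    CalibrationError,
    EmptyModelError,
    UncalibratedProfileError,
    ValidationError,
)

PATHWAYS = frozenset(
    {
        "N_fixation",
        "nitrification",
        "denitrification",
        "anammox",
        "DNRA",
        "methanogenesis",
        "methanotrophy",
    }
)

NT_ALPHABET = "ACGT"
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
GAP_CHARS = frozenset("-.")


@dataclass(frozen=True)
class GeneFamily:
    name: str
    pathway: str
    homolog_group: str | None = None
    sub_clades: tuple[str, ...] = ()

    def __post_init__(self):
        if self.pathway not in PATHWAYS:
            raise ValidationError(f"unknown pathway {self.pathway!r}")


@dataclass(frozen=True)
class SequenceRecord:
    """A sequence with optional truth label; residues are never empty."""

    id: str
    residues: str
    family_label: str | None = None

    def __post_init__(self):
        if not self.residues:
            raise ValidationError(f"record {self.id!r} has empty residues")

    @property
    def gc_fraction(self) -> float:
        return gc_fraction(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


class Registry:
    """Named gene families plus decoy homolog labels.

    ``decoys`` maps a decoy label (a non-target homolog such as narH) to the
    homolog groups whose members it can cross-hit.
    """

    def __init__(self, families: list[GeneFamily], decoys: dict[str, tuple[str, ...]] | None = None):
        names = [f.name for f in families]
        if len(set(names)) != len(names):
            raise ValidationError("family names must be unique")
        self.families = list(families)
        self.decoys = {k: tuple(v) for k, v in (decoys or {}).items()}
        self._by_name = {f.name: f for f in self.families}
        counts: dict[str, int] = {}
        for f in self.families:
            if f.homolog_group:
                counts[f.homolog_group] = counts.get(f.homolog_group, 0) + 1
        for groups in self.decoys.values():
            for g in groups:
                counts[g] = counts.get(g, 0) + 1
        for group, n in counts.items():
            if n < 2:
                raise ValidationError(f"homolog group {group!r} has fewer than 2 members")

    def __len__(self) -> int:
        return len(self.families)

    def __iter__(self):
        return iter(self.families)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def family(self, name: str) -> GeneFamily:
        return self._by_name[name]

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.families]

    def groups_of(self, label: str) -> frozenset[str]:
        """Homolog groups a family or decoy label belongs to (possibly empty)."""
        if label in self._by_name:
            g = self._by_name[label].homolog_group
            return frozenset((g,)) if g else frozenset()
        return frozenset(self.decoys.get(label, ()))

    def is_decoy(self, label: str) -> bool:
        return label in self.decoys

    # ---------------------------------------------------------------- io
    @classmethod
    def from_yaml(cls, path: str | Path) -> "Registry":
        with open(path) as fh:
            return cls._from_mapping(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "Registry":
        ref = importlib.resources.files("probecap").joinpath("data/registry.yaml")
        return cls._from_mapping(yaml.safe_load(ref.read_text()))

    @classmethod
    def _from_mapping(cls, doc: dict) -> "Registry":
        families = [
            GeneFamily(
                name=e["name"],
                pathway=e["pathway"],
                homolog_group=e.get("homolog_group"),
                sub_clades=tuple(e.get("sub_clades", ())),
            )
            for e in doc["families"]
        ]
        decoys = {e["name"]: tuple(e["homolog_groups"]) for e in doc.get("decoys", [])}
        return cls(families, decoys)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "families": [
                {
                    "name": f.name,
                    "pathway": f.pathway,
                    **({"homolog_group": f.homolog_group} if f.homolog_group else {}),
                    **({"sub_clades": list(f.sub_clades)} if f.sub_clades else {}),
                }
                for f in self.families
            ],
            "decoys": [
                {"name": k, "homolog_groups": list(v)} for k, v in self.decoys.items()
            ],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


@dataclass(frozen=True)
class ProfileModel:
    """Position-specific scoring matrix with local affine-gap scoring."""

    family: str
    alphabet: str  # "nucleotide" | "amino_acid"
    match_scores: np.ndarray  # (length, |alphabet|) log-odds
    gap_open: float = 3.0
    gap_extend: float = 0.3
    calibration: tuple[float, float] | None = None  # Gumbel (location, scale)
    n_train: int = 0

    def __post_init__(self):
        if self.match_scores.ndim != 2 or self.match_scores.shape[0] < 1:
            raise ValidationError("profile needs >=1 match column")
        if not np.all(np.isfinite(self.match_scores)):
            raise ValidationError("profile scores must be finite")
        if self.calibration is not None and self.calibration[1] <= 0:
            raise ValidationError("calibration scale must be > 0")

    @property
    def length(self) -> int:
        return self.match_scores.shape[0]

    @property
    def is_calibrated(self) -> bool:
        return self.calibration is not None

    def score(self, residues: str) -> float:
        return _pssm.score_sequence(
            self.match_scores, residues, self.gap_open, self.gap_extend, self.alphabet
        )

    def evalue(self, score: float, db_size: int) -> float:
        """Expected count of >= ``score`` hits in a null database of ``db_size``."""
        if self.calibration is None:
            raise UncalibratedProfileError(f"profile {self.family!r} is not calibrated")
        loc, scale = self.calibration
        return float(db_size) * float(gumbel_r.sf(score, loc=loc, scale=scale))


def _symbols(alphabet: str) -> str:
    if alphabet == "nucleotide":
        return NT_ALPHABET
    if alphabet == "amino_acid":
        return AA_ALPHABET
    raise ValidationError(f"unknown alphabet {alphabet!r}")


def build_profile(
    alignment: list[SequenceRecord],
    family: GeneFamily | str,
    *,
    alphabet: str = "nucleotide",
    pseudocount: float = 1.0,
    background: dict[str, float] | None = None,
    gap_open: float = 3.0,
    gap_extend: float = 0.3,
) -> ProfileModel:
    """Build a PSSM from an aligned family.

    A column is a match column iff its gap fraction is strictly below 0.5
    (columns at exactly 0.5 are dropped).  Per-column score of symbol ``a``:
    ``log((count(a)+pc) / (rows+pc*|A|)) - log(background(a))``.
    """
    if len(alignment) < 2:
        raise ValidationError("alignment needs >=2 rows")
    rows = [r.residues.upper() for r in alignment]
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise AlignmentShapeError("alignment rows have unequal lengths")
    symbols = _symbols(alphabet)
    n_sym = len(symbols)
    if background is None:
        bg = np.full(n_sym, 1.0 / n_sym)
    else:
        bg = np.array([background[s] for s in symbols], dtype=float)
        bg = bg / bg.sum()
    n_rows = len(rows)
    columns = []
    for j in range(width):
        col = [r[j] for r in rows]
        gap_frac = sum(c in GAP_CHARS for c in col) / n_rows
        if gap_frac >= 0.5:
            continue
        counts = np.array([sum(c == s for c in col) for s in symbols], dtype=float)
        scores = np.log((counts + pseudocount) / (n_rows + pseudocount * n_sym)) - np.log(bg)
        columns.append(scores)
    if not columns:
        raise EmptyModelError("no alignment column has <50% gaps")
    name = family.name if isinstance(family, GeneFamily) else family
    return ProfileModel(
        family=name,
        alphabet=alphabet,
        match_scores=np.vstack(columns),
        gap_open=gap_open,
        gap_extend=gap_extend,
        n_train=n_rows,
    )


def sample_background_sequences(
    n: int, length: int, rng: np.random.Generator, *,
    alphabet: str = "nucleotide", background: dict[str, float] | None = None,
) -> list[str]:
    symbols = np.array(list(_symbols(alphabet)))
    if background is None:
        p = None
    else:
        p = np.array([background[s] for s in symbols], dtype=float)
        p = p / p.sum()
    return ["".join(rng.choice(symbols, size=length, p=p)) for _ in range(n)]


def calibrate_profile(
    profile: ProfileModel,
    n_decoys: int = 500,
    decoy_length: int | None = None,
    seed: int = 0,
    *,
    background: dict[str, float] | None = None,
) -> ProfileModel:
    """Fit a Gumbel null from best local scores of i.i.d. background decoys."""
    if n_decoys < 100:
        raise ValidationError("n_decoys must be >= 100")
    if decoy_length is None:
        decoy_length = profile.length
    rng = np.random.default_rng(seed)
    decoys = sample_background_sequences(
        n_decoys, decoy_length, rng, alphabet=profile.alphabet, background=background
    )
    scores = _pssm.score_many(
        profile.match_scores, decoys, profile.gap_open, profile.gap_extend, profile.alphabet
    )
    if float(np.std(scores)) < 1e-9:
        raise CalibrationError("degenerate decoy score distribution")
    loc, scale = gumbel_r.fit(scores)
    return dataclasses.replace(profile, calibration=(float(loc), float(scale)))


def search_profile(
    profile: ProfileModel,
    seqs: list[SequenceRecord],
    e_threshold: float = 0.001,
    *,
    db_size: int | None = None,
) -> list[tuple[str, float, float]]:
    """Return ``(id, score, E)`` for records with E <= threshold, best first.

    E-values are scaled to ``db_size`` (defaults to ``len(seqs)``); ties in E
    are broken by id.
    """
    if not profile.is_calibrated:
        raise UncalibratedProfileError(f"profile {profile.family!r} is not calibrated")
    if e_threshold <= 0:
        raise ValidationError("e_threshold must be > 0")
    n_db = db_size if db_size is not None else len(seqs)
    hits = []
    for rec in seqs:
        score = profile.score(rec.residues)
        e = profile.evalue(score, n_db)
        if e <= e_threshold:
            hits.append((rec.id, score, e))
    hits.sort(key=lambda h: (h[2], h[0]))
    return hits


def dereplicate(seqs: list[SequenceRecord]) -> list[SequenceRecord]:
    """Collapse duplicates at 100% identity, cd-hit style.

    Case-folded identical residues collapse to the first-seen record; records
    that are exact substrings of a longer retained sequence are removed too.
    Output preserves first-occurrence order.
    """
    first_seen: dict[str, int] = {}
    uniq: list[SequenceRecord] = []
    for rec in seqs:
        key = rec.residues.upper()
        if key not in first_seen:
            first_seen[key] = len(uniq)
            uniq.append(rec)
    # longest-first pass removing exact substrings of retained sequences
    order = sorted(uniq, key=lambda r: (-len(r.residues), first_seen[r.residues.upper()]))
    kept: list[SequenceRecord] = []
    for rec in order:
        s = rec.residues.upper()
        if any(s in k.residues.upper() for k in kept):
            continue
        kept.append(rec)
    kept_ids = {r.id for r in kept}
    return [r for r in uniq if r.id in kept_ids]


# ------------------------------------------------------------------ FASTA io

def read_fasta(path: str | Path, *, family_from_header: bool = True) -> list[SequenceRecord]:
    """Read FASTA; a ``family=<name>`` token in the description sets the label."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        label = None
        if family_from_header:
            for token in rec.description.split():
                if token.startswith("family="):
                    label = token.split("=", 1)[1]
        out.append(SequenceRecord(id=rec.id, residues=str(rec.seq), family_label=label))
    return out


def write_fasta(records: list[SequenceRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(
            Seq(r.residues),
            id=r.id,
            description=f"family={r.family_label}" if r.family_label else "",
        )
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")
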