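"""Benchmark scoring: expected-vs-observed correlation, homolog-aware
precision/recall, identity-cutoff binning and rarefaction."""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import gammaln
from scipy.stats import pearsonr

from ._pairwise import global_identity
from .errors import InsufficientDataError, ValidationError
from .probe_design import cluster_sequences
from .read_classify import AbundanceTable, ReadAnnotation
from .target_registry import Registry, SequenceRecord

BACKGROUND_LABEL = "background"


# ------------------------------------------------------------- correlation

@dataclass
class EvalReport:
    pearson_r: float
    p_value: float
    n_shared: int
    expected: dict[str, float]
    observed: dict[str, float]
    deviations: dict[str, float]  # observed - expected, percent points
    per_gc_category: dict[str, float] = field(default_factory=dict)
    precision: dict[str, float] = field(default_factory=dict)
    recall: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        def clean(x):
            return None if isinstance(x, float) and math.isnan(x) else x

        doc = {
            "pearson_r": clean(self.pearson_r),
            "p_value": clean(self.p_value),
            "n_shared": self.n_shared,
            "expected": self.expected,
            "observed": self.observed,
            "deviations": self.deviations,
            "per_gc_category": {k: clean(v) for k, v in self.per_gc_category.items()},
            "precision": {k: clean(v) for k, v in self.precision.items()},
            "recall": {k: clean(v) for k, v in self.recall.items()},
        }
        Path(path).write_text(json.dumps(doc, indent=2))


def compare_abundance(
    expected: dict[str, float],
    observed: AbundanceTable | dict[str, float],
) -> EvalReport:
    """Pearson r between expected and observed rel_target percentages over
    shared families (requires >= 3)."""
    obs = observed.rel_target if isinstance(observed, AbundanceTable) else dict(observed)
    shared = sorted(set(expected) & set(obs))
    if len(shared) < 3:
        raise InsufficientDataError(
            f"only {len(shared)} shared families; need >= 3 for a correlation"
        )
    x = np.array([expected[f] for f in shared])
    y = np.array([obs[f] for f in shared])
    if float(np.std(y)) < 1e-12 or float(np.std(x)) < 1e-12:
        warnings.warn("degenerate variance: Pearson r undefined", RuntimeWarning)
        r, p = float("nan"), float("nan")
    else:
        r, p = pearsonr(x, y)
    return EvalReport(
        pearson_r=float(r),
        p_value=float(p),
        n_shared=len(shared),
        expected={f: float(expected[f]) for f in shared},
        observed={f: float(obs[f]) for f in shared},
        deviations={f: float(obs[f] - expected[f]) for f in shared},
    )


# -------------------------------------------------------- precision/recall

def _project(label: str, registry: Registry, merge: bool) -> str:
    if not merge or label == BACKGROUND_LABEL:
        return label
    groups = registry.groups_of(label)
    return sorted(groups)[0] if groups else label


def precision_recall(
    predictions: dict[str, frozenset[str] | set[str]],
    truth: dict[str, str],
    registry: Registry,
    *,
    merge_homologs: bool = False,
) -> dict[str, tuple[float, float]]:
    """Read-level per-family (precision, recall) against planted truth.

    ``predictions`` maps read id -> set of assigned families (empty set for
    unassigned reads); ``truth`` maps read id -> family or ``background``.
    With ``merge_homologs`` both sides are first projected onto homolog-group
    labels.  Families with zero predictions get NaN precision; families with
    zero truth reads get NaN recall.
    """
    missing = set(predictions) - set(truth)
    if missing:
        raise ValidationError(f"{len(missing)} predicted reads lack truth labels")
    tp: dict[str, int] = {}
    fp: dict[str, int] = {}
    fn: dict[str, int] = {}
    labels: set[str] = set()
    for read_id, true_label in truth.items():
        t = _project(true_label, registry, merge_homologs)
        preds = {
            _project(p, registry, merge_homologs)
            for p in predictions.get(read_id, frozenset())
        }
        labels |= preds
        if t != BACKGROUND_LABEL:
            labels.add(t)
        for p in preds:
            if p == t:
                tp[p] = tp.get(p, 0) + 1
            else:
                fp[p] = fp.get(p, 0) + 1
        if t != BACKGROUND_LABEL and t not in preds:
            fn[t] = fn.get(t, 0) + 1
    out: dict[str, tuple[float, float]] = {}
    for label in sorted(labels):
        n_tp, n_fp, n_fn = tp.get(label, 0), fp.get(label, 0), fn.get(label, 0)
        precision = n_tp / (n_tp + n_fp) if n_tp + n_fp else float("nan")
        recall = n_tp / (n_tp + n_fn) if n_tp + n_fn else float("nan")
        out[label] = (precision, recall)
    return out


def annotations_to_predictions(annotations: list[ReadAnnotation]) -> dict[str, frozenset[str]]:
    return {ann.read_id: ann.families for ann in annotations}


# ----------------------------------------------------------------- binning

@dataclass(frozen=True)
class BinSet:
    cutoff: float
    centroids: tuple[str, ...]
    members: dict  # centroid id -> tuple of member ids (includes centroid)

    @property
    def n_bins(self) -> int:
        return len(self.centroids)

    def sizes(self) -> dict[str, int]:
        return {c: len(m) for c, m in self.members.items()}

    def assignment(self) -> dict[str, str]:
        """member id -> centroid id"""
        return {m: c for c, ms in self.members.items() for m in ms}

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("centroid\tsize\tmembers\n")
            for c in self.centroids:
                fh.write(f"{c}\t{len(self.members[c])}\t{','.join(self.members[c])}\n")


def bin_at_identity(seqs: list[SequenceRecord], cutoff: float = 0.90) -> BinSet:
    """Greedy centroid binning at an identity cutoff (diversity units)."""
    clusters = cluster_sequences(seqs, threshold=cutoff)
    return BinSet(
        cutoff=cutoff,
        centroids=tuple(c.representative_id for c in clusters),
        members={c.representative_id: c.member_ids for c in clusters},
    )


# -------------------------------------------------------------- rarefaction

@dataclass
class RarefactionCurve:
    depths: list[int]
    mean_richness: list[float]
    sd_richness: list[float]
    expected_richness: list[float]  # closed-form hypergeometric expectation
    n_replicates: int
    seed: int

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("depth\tmean_richness\tsd_richness\texpected_richness\treplicates\n")
            for d, m, s, e in zip(
                self.depths, self.mean_richness, self.sd_richness, self.expected_richness
            ):
                fh.write(f"{d}\t{m:.6f}\t{s:.6f}\t{e:.6f}\t{self.n_replicates}\n")


def expected_richness(bin_sizes: list[int], depth: int) -> float:
    """Exact expectation Σ_b (1 − C(N−n_b, d) / C(N, d)) of distinct bins in a
    without-replacement subsample of size ``depth``."""
    n_total = sum(bin_sizes)
    if depth > n_total:
        raise ValidationError("depth exceeds total reads")

    def log_comb(n: int, k: int) -> float:
        if k < 0 or k > n:
            return -math.inf
        return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))

    denom = log_comb(n_total, depth)
    total = 0.0
    for size in bin_sizes:
        num = log_comb(n_total - size, depth)
        total += 1.0 - (math.exp(num - denom) if num > -math.inf else 0.0)
    return total


def rarefy(
    bin_assignments: list[str],
    depths: list[int],
    n_replicates: int = 10,
    seed: int = 0,
) -> RarefactionCurve:
    """Mean distinct-bin richness over without-replacement subsamples."""
    n_total = len(bin_assignments)
    if any(d > n_total for d in depths):
        raise ValidationError("depth exceeds total reads")
    if any(d < 0 for d in depths):
        raise ValidationError("depths must be >= 0")
    rng = np.random.default_rng(seed)
    labels = np.asarray(bin_assignments, dtype=object)
    sizes = [int(n) for n in np.unique(labels, return_counts=True)[1]]
    means, sds, exps = [], [], []
    for depth in depths:
        richness = [
            len(set(labels[rng.choice(n_total, size=depth, replace=False)]))
            for _ in range(n_replicates)
        ]
        means.append(float(np.mean(richness)))
        sds.append(float(np.std(richness, ddof=1)) if n_replicates > 1 else 0.0)
        exps.append(expected_richness(sizes, depth))
    return RarefactionCurve(
        depths=list(depths),
        mean_richness=means,
        sd_richness=sds,
        expected_richness=exps,
        n_replicates=n_replicates,
        seed=seed,
    )
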