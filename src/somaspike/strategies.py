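"""Training-set composition strategies and the classifier harness.

Three ways of assembling a training set for a somatic-call classifier:

* ``spike_only`` — all candidates from an in-silico spike-in pair;
* ``gt_real`` — candidates from a "real" pair restricted to the training
  half of the genome, labeled by a curated truth set;
* ``combined`` — all ``gt_real`` candidates plus a uniform 10% subsample of
  the spike candidates (fraction configurable).

The genome split tiles the high-confidence regions into ~92-kb blocks,
assigns half the blocks to training at random, and removes a 5-bp segment
around every gray-zone mutation (low-confidence calls, and unclassified calls
above 30% VAF) from the training side only.

The classifier is pluggable behind :class:`TrainedModel`; the reference
implementation is a multinomial logistic model over standardized, flattened
pileup feature matrices, balanced by class reweighting. It trains in seconds
on a CPU, which is the point: strategy comparisons, not architecture, are
what this harness isolates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from somaspike.candidates import (
    LABEL_INDEL,
    LABEL_NONSOMATIC,
    LABEL_SNV,
    CandidateStore,
)
from somaspike.errors import (
    EncodingMismatchError,
    LeakageError,
    ParameterError,
)
from somaspike.regions import RegionSet
from somaspike.variants import (
    TIER_LOWCONF,
    TIER_UNCLASSIFIED,
    VariantRecord,
)

#: Genome-split block size (bp): the half-genome hold-out uses ~92-kb blocks.
DEFAULT_BLOCK_SIZE = 92_000
#: Width (bp) of the segment removed around each gray-zone mutation.
GRAY_ZONE_BUFFER = 5
#: Unclassified calls above this VAF count as gray zone.
GRAY_ZONE_VAF = 0.30
#: Fraction of spike candidates folded into the combined strategy.
DEFAULT_SPIKE_FRACTION = 0.10

CLASSES = [LABEL_NONSOMATIC, LABEL_SNV, LABEL_INDEL]


def gray_zone_records(records: Sequence[VariantRecord]) -> List[VariantRecord]:
    """Gray zone: LowConf calls, plus Unclassified calls with VAF > 0.30."""
    out = []
    for r in records:
        if r.tier == TIER_LOWCONF:
            out.append(r)
        elif (
            r.tier == TIER_UNCLASSIFIED
            and r.target_vaf is not None
            and r.target_vaf > GRAY_ZONE_VAF
        ):
            out.append(r)
    return out


def split_genome(
    regions: RegionSet,
    block_size: int = DEFAULT_BLOCK_SIZE,
    train_fraction: float = 0.5,
    gray_zone: Sequence[VariantRecord] = (),
    buffer: int = GRAY_ZONE_BUFFER,
    seed: int = 0,
) -> Tuple[RegionSet, RegionSet]:
    """Tile ``regions`` into blocks, assign blocks to train/eval, punch out
    gray-zone buffers from the train side.

    Returns ``(train, eval)`` region sets. Train and eval are disjoint, and
    their union plus the removed buffers (within train-assigned blocks)
    reconstructs the input.
    """
    if not regions:
        raise ParameterError("cannot split an empty region set")
    if block_size <= 0:
        raise ParameterError("block_size must be positive")
    if buffer % 2 == 0 or buffer < 1:
        raise ParameterError("gray-zone buffer must be odd and positive")
    if not 0 <= train_fraction <= 1:
        raise ParameterError("train_fraction must be in [0, 1]")
    blocks = []
    for contig, start, end in regions.intervals:
        for s in range(start, end, block_size):
            blocks.append((contig, s, min(s + block_size, end)))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(blocks))
    n_train = int(round(train_fraction * len(blocks)))
    train_blocks = [blocks[i] for i in order[:n_train]]
    eval_blocks = [blocks[i] for i in order[n_train:]]
    train = RegionSet(train_blocks, name="train")
    eval_ = RegionSet(eval_blocks, name="eval")
    if gray_zone:
        half = buffer // 2
        buffers = RegionSet(
            [(g.contig, g.pos - 1 - half, g.pos + half) for g in gray_zone],
            name="gray_zone_buffers",
        )
        train = train.subtract(buffers, name="train")
    return train, eval_


@dataclass
class StrategySpec:
    """Which candidate sources make up a training set, and how."""

    kind: str  # spike_only | gt_real | combined
    sources: Dict[str, CandidateStore] = field(default_factory=dict)
    spike_fraction: float = DEFAULT_SPIKE_FRACTION

    def __post_init__(self) -> None:
        if self.kind not in ("spike_only", "gt_real", "combined"):
            raise ParameterError(f"unknown strategy kind {self.kind!r}")
        if not 0 <= self.spike_fraction <= 1:
            raise ParameterError("spike_fraction must be in [0, 1]")
        need = {"spike_only": ["spike"], "gt_real": ["real"], "combined": ["spike", "real"]}
        for src in need[self.kind]:
            if src not in self.sources:
                raise ParameterError(f"strategy {self.kind} requires a {src!r} source")


def _restrict(store: CandidateStore, regions: Optional[RegionSet]) -> CandidateStore:
    if regions is None or store.meta.empty:
        return store
    keep = [
        i
        for i, row in enumerate(store.meta.itertuples(index=False))
        if regions.contains(row.contig, row.pos)
    ]
    return store.subset(keep)


def compose_training_set(
    spec: StrategySpec,
    seed: int = 0,
    train_regions: Optional[RegionSet] = None,
) -> Tuple[CandidateStore, Dict]:
    """Assemble the training store per the strategy; returns (store, manifest).

    The combined subsample size is ``floor(fraction * n + 0.5)`` (half-up),
    drawn per candidate uniformly without replacement.
    """
    encodings = {name: s.encoding for name, s in spec.sources.items()}
    if len(set(encodings.values())) > 1:
        raise EncodingMismatchError(f"sources disagree on encoding: {encodings}")
    rng = np.random.default_rng(seed)
    if spec.kind == "spike_only":
        store = spec.sources["spike"]
    elif spec.kind == "gt_real":
        store = _restrict(spec.sources["real"], train_regions)
    else:
        spike = spec.sources["spike"]
        n_keep = int(math.floor(spec.spike_fraction * len(spike) + 0.5))
        idx = rng.choice(len(spike), size=n_keep, replace=False) if n_keep else []
        sub = spike.subset(sorted(idx)) if n_keep else spike.subset([])
        real = _restrict(spec.sources["real"], train_regions)
        store = real.concat(sub) if len(sub) else real
    counts = store.meta["label"].value_counts().to_dict() if len(store) else {}
    manifest = {
        "strategy": spec.kind,
        "spike_fraction": spec.spike_fraction if spec.kind == "combined" else None,
        "seed": seed,
        "n_candidates": len(store),
        "class_counts": {str(k): int(v) for k, v in counts.items()},
        "encoding": store.encoding,
    }
    return store, manifest


@dataclass
class TrainedModel:
    """Classifier state plus the provenance needed to apply it safely."""

    pipeline: Pipeline
    encoding: str
    classes: List[str]
    manifest: Dict

    def predict_proba(self, store: CandidateStore) -> np.ndarray:
        """Probability simplex over CLASSES (columns in that order)."""
        if store.encoding != self.encoding:
            raise EncodingMismatchError(
                f"model encodes {self.encoding!r}, store {store.encoding!r}"
            )
        X = store.features.reshape(len(store), -1)
        raw = self.pipeline.predict_proba(X)
        out = np.zeros((len(store), len(CLASSES)))
        for j, cls in enumerate(self.pipeline.classes_):
            out[:, CLASSES.index(cls)] = raw[:, j]
        return out


def train_classifier(
    candidates: CandidateStore,
    hyperparams: Optional[Dict] = None,
    seed: int = 0,
    eval_regions: Optional[RegionSet] = None,
    manifest_extra: Optional[Dict] = None,
) -> TrainedModel:
    """Fit the reference logistic model on a labeled candidate store.

    ``eval_regions``, when given, arms the leakage guard: any training
    candidate inside the held-out regions aborts training.
    """
    if eval_regions is not None and len(candidates):
        leaks = [
            (row.contig, row.pos)
            for row in candidates.meta.itertuples(index=False)
            if eval_regions.contains(row.contig, row.pos)
        ]
        if leaks:
            raise LeakageError(
                f"{len(leaks)} training candidates fall inside the evaluation "
                f"regions (first: {leaks[0][0]}:{leaks[0][1]})"
            )
    labels = candidates.meta["label"].to_numpy()
    present = sorted(set(labels))
    if len(present) < 2:
        raise ParameterError(
            f"training needs >= 2 classes, got {present or 'no candidates'}"
        )
    hp = {"C": 1.0, "max_iter": 300}
    hp.update(hyperparams or {})
    X = candidates.features.reshape(len(candidates), -1)
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "clf",
                LogisticRegression(
                    C=hp["C"],
                    max_iter=hp["max_iter"],
                    class_weight="balanced",
                    random_state=seed,
                ),
            ),
        ]
    )
    pipe.fit(X, labels)
    manifest = {
        "seed": seed,
        "hyperparams": hp,
        "n_train": len(candidates),
        "class_counts": {c: int((labels == c).sum()) for c in present},
        "encoding": candidates.encoding,
        "classifier": "logistic-multinomial",
    }
    manifest.update(manifest_extra or {})
    return TrainedModel(pipe, candidates.encoding, list(present), manifest)


def call_somatic(
    model: TrainedModel,
    candidates: CandidateStore,
    threshold: float = 0.5,
):
    """Emit somatic calls: candidates with P(somatic) >= threshold.

    Returns a list of :class:`somaspike.evaluation.Call`. The call's type
    follows the argmax among the somatic classes; QUAL is the Phred-scaled
    somatic probability.
    """
    from somaspike.evaluation import Call

    if len(candidates) == 0:
        return []
    proba = model.predict_proba(candidates)
    p_snv = proba[:, CLASSES.index(LABEL_SNV)]
    p_indel = proba[:, CLASSES.index(LABEL_INDEL)]
    p_som = p_snv + p_indel
    calls = []
    for i, row in enumerate(candidates.meta.itertuples(index=False)):
        if p_som[i] < threshold:
            continue
        qual = -10.0 * math.log10(max(1.0 - p_som[i], 1e-10))
        rec = VariantRecord(row.contig, int(row.pos), row.ref, row.alt)
        calls.append(
            Call(
                record=rec,
                qual=qual,
                alt_depth=int(row.tumor_alt),
                depth=int(row.tumor_depth),
                somatic_prob=float(p_som[i]),
            )
        )
    return calls
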