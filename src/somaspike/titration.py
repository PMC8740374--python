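"""Purity and coverage titration by fragment-level read mixing.

A tumor of purity P at coverage C is built by sampling, without replacement,
fragments from a tumor-origin pool and a normal-origin pool so that the
expected tumor-origin fraction is P and the expected mean depth is C. The
same machinery builds contaminated normals (e.g. 95% normal + 5% tumor).
Purity is applied first, then any further downsampling, so seeds reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from somaspike.errors import CapacityError, ParameterError
from somaspike.reads import AlignedRead, cigar_reference_length, group_fragments


@dataclass(frozen=True)
class ReplicateSpec:
    """One titration cell: tumor purity P, normal purity, mean coverage C."""

    tumor_purity: float
    normal_purity: float
    mean_coverage: float
    label: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.tumor_purity <= 1:
            raise ParameterError(f"tumor purity must be in (0, 1], got {self.tumor_purity}")
        if not 0 < self.normal_purity <= 1:
            raise ParameterError(f"normal purity must be in (0, 1], got {self.normal_purity}")
        if self.mean_coverage <= 0:
            raise ParameterError("mean coverage must be positive")


def _fragment_table(reads: Sequence[AlignedRead]):
    frags = group_fragments(reads)
    ids = list(frags)
    bases = np.array(
        [sum(cigar_reference_length(r.cigar) for r in frags[fid]) for fid in ids],
        dtype=np.int64,
    )
    return frags, ids, bases


def _emit(frags: Dict[str, List[AlignedRead]], chosen_ids) -> List[AlignedRead]:
    out = [r for fid in chosen_ids for r in frags[fid]]
    out.sort(key=lambda r: (r.contig, r.pos, r.read_id))
    return out


def mix_purity(
    tumor_reads: Sequence[AlignedRead],
    normal_reads: Sequence[AlignedRead],
    purity: float,
    target_coverage: float,
    genome_length: int,
    seed: int = 0,
) -> List[AlignedRead]:
    """Sample a purity-``purity`` mixture at ``target_coverage`` mean depth.

    Fragments are drawn without replacement from each pool; ``origin`` tags
    are preserved so the realized purity is auditable.
    """
    if not 0 < purity <= 1:
        raise ParameterError(f"purity must be in (0, 1], got {purity}")
    if target_coverage <= 0:
        raise ParameterError("target_coverage must be positive")
    rng = np.random.default_rng(seed)
    t_frags, t_ids, t_bases = _fragment_table(tumor_reads)
    pools = [(t_frags, t_ids, t_bases, purity, "tumor")]
    if purity < 1:
        n_frags, n_ids, n_bases = _fragment_table(normal_reads)
        shared = set(t_ids) & set(n_ids)
        if shared:
            raise ParameterError(
                f"tumor and normal pools share {len(shared)} fragment ids "
                f"(e.g. {sorted(shared)[0]!r}); pools must hold distinct fragments"
            )
        pools.append((n_frags, n_ids, n_bases, 1 - purity, "normal"))
        mean_frag = np.concatenate([t_bases, n_bases]).mean()
    else:
        mean_frag = t_bases.mean()
    total = int(round(target_coverage * genome_length / mean_frag))
    out: List[AlignedRead] = []
    for frags, ids, bases, frac, name in pools:
        want = int(round(frac * total))
        if want > len(ids):
            raise CapacityError(
                f"{name} pool has {len(ids)} fragments but the mix needs {want} "
                f"(purity {purity}, target {target_coverage}x)"
            )
        chosen = rng.choice(len(ids), size=want, replace=False)
        out.extend(_emit(frags, [ids[i] for i in chosen]))
    out.sort(key=lambda r: (r.contig, r.pos, r.read_id))
    return out


def downsample(
    reads: Sequence[AlignedRead],
    target_coverage: float,
    genome_length: int,
    seed: int = 0,
) -> List[AlignedRead]:
    """Uniform fragment-level thinning to ``target_coverage`` mean depth."""
    if target_coverage <= 0:
        raise ParameterError("target_coverage must be positive")
    frags, ids, bases = _fragment_table(reads)
    current = bases.sum() / genome_length
    p = target_coverage / current
    if p > 1 + 1e-9:
        raise CapacityError(
            f"target {target_coverage}x exceeds available {current:.1f}x"
        )
    if p >= 1:
        return _emit(frags, ids)
    rng = np.random.default_rng(seed)
    keep = np.nonzero(rng.random(len(ids)) < p)[0]
    return _emit(frags, [ids[i] for i in keep])


def build_titration_grid(
    tumor_reads: Sequence[AlignedRead],
    normal_reads: Sequence[AlignedRead],
    purities: Sequence[float],
    coverages: Sequence[float],
    normal_purities: Sequence[float],
    genome_length: int,
    seed: int = 0,
) -> List[Tuple[ReplicateSpec, List[AlignedRead], List[AlignedRead]]]:
    """One tumor/normal pair per grid cell (purity x coverage x normal purity).

    The tumor and normal pools are each split in half up front so that no
    fragment can appear in both members of one pair: the tumor side of a pair
    draws from one half of each pool, the normal side from the other.
    """
    if not purities or not coverages or not normal_purities:
        raise ParameterError("titration grids must be non-empty")
    rng = np.random.default_rng(seed)

    def halves(reads):
        frags = group_fragments(reads)
        ids = list(frags)
        perm = rng.permutation(len(ids))
        half = len(ids) // 2
        a = [r for i in perm[:half] for r in frags[ids[i]]]
        b = [r for i in perm[half:] for r in frags[ids[i]]]
        a.sort(key=lambda r: (r.contig, r.pos, r.read_id))
        b.sort(key=lambda r: (r.contig, r.pos, r.read_id))
        return a, b

    tumor_a, tumor_b = halves(tumor_reads)
    normal_a, normal_b = halves(normal_reads)

    out = []
    for P in purities:
        for C in coverages:
            for NP in normal_purities:
                label = f"P{P:g}_C{C:g}_N{NP:g}"
                spec = ReplicateSpec(P, NP, C, label=label)
                cell_seed = int(rng.integers(2**31))
                try:
                    tumor = mix_purity(
                        tumor_a, normal_a, P, C, genome_length, seed=cell_seed
                    )
                    # the "normal" is normal_b contaminated with tumor_b at 1-NP
                    if NP < 1:
                        normal = mix_purity(
                            tumor_b, normal_b, 1 - NP, C, genome_length, seed=cell_seed + 1
                        )
                    else:
                        normal = downsample(normal_b, C, genome_length, seed=cell_seed + 1)
                except CapacityError as e:
                    raise CapacityError(f"titration cell {label}: {e}") from e
                out.append((spec, tumor, normal))
    return out
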