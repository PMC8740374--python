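"""Stratified evaluation of one trained caller: VAF bins and INDEL sizes.

Runs the end-to-end pipeline on one pair, calls somatic variants with the
combined-strategy model, and reports per-stratum precision/recall/F1.
Writes results/stratified_evaluation.json.
"""

import json
from pathlib import Path

from somaspike.candidates import CandidateStore, label_candidates, scan_candidates
from somaspike.evaluation import compute_metrics, evaluate_calls, normalize_variants, stratify
from somaspike.experiment import build_spiked_pair
from somaspike.io import derive_seed
from somaspike.regions import RegionSet
from somaspike.spike import VafModel
from somaspike.strategies import call_somatic, split_genome, train_classifier
from somaspike.titration import ReplicateSpec

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 1

if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    pair = build_spiked_pair(
        seed=SEED, genome_length=200_000, coverage=80,
        vaf_model=VafModel(2, 5), n_snv=400, n_indel=95, label="strat",
    )
    truth = normalize_variants(pair.truth, pair.ref)
    whole = RegionSet([(pair.ref.names[0], 0, pair.ref.total_length)])
    train_r, eval_r = split_genome(whole, block_size=10_000, seed=derive_seed(SEED, "strat-split"))
    sites = scan_candidates(pair.tumor_reads, pair.normal_reads, pair.ref)
    train_store = CandidateStore.from_sites(
        label_candidates(list(sites), truth, regions=train_r)
    )
    eval_store = CandidateStore.from_sites(
        label_candidates(list(sites), truth, regions=eval_r)
    )
    model = train_classifier(train_store, seed=SEED, eval_regions=eval_r)
    calls = call_somatic(model, eval_store, threshold=0.5)
    spec = ReplicateSpec(1.0, 1.0, 80, label="strat")
    adjudicated = evaluate_calls(calls, truth, eval_r, spec)

    overall = compute_metrics(adjudicated)
    by_vaf = stratify(adjudicated, "vaf_bins")
    by_size = stratify(adjudicated, "indel_size")
    payload = {
        "overall": overall.as_dict(),
        "by_vaf": by_vaf.as_dict(),
        "by_indel_size": by_size.as_dict(),
    }
    (OUT / "stratified_evaluation.json").write_text(json.dumps(payload, indent=2))

    b = overall.overall
    print(f"overall: P={b.precision:.3f} R={b.recall:.3f} F1={b.f1:.3f} "
          f"(TP {b.tp} / FP {b.fp} / FN {b.fn}, {b.excluded} excluded)")
    print("by VAF bin:")
    for name, m in by_vaf.strata.items():
        f1 = "n/a" if m.f1 is None else f"{m.f1:.3f}"
        print(f"  {name:>12}: F1={f1} (TP {m.tp} / FN {m.fn})")
    print("by INDEL size (negative = deletions):")
    for name, m in sorted(by_size.strata.items(), key=lambda kv: (kv[0] == "SNV", int(kv[0]) if kv[0] != "SNV" else 0)):
        f1 = "n/a" if m.f1 is None else f"{m.f1:.3f}"
        print(f"  {name:>4}: F1={f1} (TP {m.tp} / FN {m.fn})")
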