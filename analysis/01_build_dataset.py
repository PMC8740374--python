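"""Build the core in-silico dataset: reference, normal, spiked tumor, truth.

Writes FASTA/SAM/VCF artifacts plus a site table under results/dataset/.
"""

from pathlib import Path

import pandas as pd

from somaspike.experiment import build_spiked_pair
from somaspike.io import write_fasta, write_sam, write_vcf

OUT = Path(__file__).resolve().parent.parent / "results" / "dataset"
SEED = 1

if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    pair = build_spiked_pair(
        seed=SEED, genome_length=200_000, coverage=80, n_snv=400, n_indel=95
    )
    write_fasta(pair.ref, OUT / "reference.fa")
    write_vcf(pair.germline.records, pair.ref, OUT / "germline.vcf")
    write_sam(pair.normal_reads, pair.ref, OUT / "normal.sam")
    write_sam(pair.tumor_reads, pair.ref, OUT / "tumor.sam")
    write_vcf(pair.truth, pair.ref, OUT / "truth.vcf")
    table = pd.DataFrame(
        [
            (s.contig, s.pos, s.ref, s.alt, s.vtype, round(s.target_vaf, 4))
            for s in pair.plan.sites
        ],
        columns=["contig", "pos", "ref", "alt", "type", "target_vaf"],
    )
    table.to_csv(OUT / "spike_sites.tsv", sep="\t", index=False)
    print(
        f"dataset: {pair.ref.total_length} bp genome, "
        f"{len(pair.normal_reads)} normal / {len(pair.tumor_reads)} tumor reads, "
        f"{len(pair.truth)} spiked sites "
        f"({sum(s.vtype == 'SNV' for s in pair.plan.sites)} SNV / "
        f"{sum(s.vtype != 'SNV' for s in pair.plan.sites)} INDEL) -> {OUT}"
    )
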