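#!/usr/bin/env python
"""Generate every synthetic input the downstream analyses consume.

Emits, under scratch/data/ (bulk inputs stay out of the results tree): a 100 kb genome with the five guides' on-target
sites implanted, edited/control VCFs (five biallelic cut-site indels plus
200 background SNVs, half germline-shared), the truth registry, a
56-patient cohort realisation of the survey summary, and a 1,000-protein
TMT-style quant table planted with the published knockout-line ratios.
"""

from pathlib import Path

from rbcedit import datasets
from rbcedit.proteome import write_quant_tsv
from rbcedit.sequence import write_guides
from rbcedit.simulate import (
    simulate_screen_dataset,
    synth_cohort,
    synth_proteome,
    write_fasta,
    write_registry,
)
from rbcedit.variants import write_vcf

SEED = 2018
OUT = Path(__file__).resolve().parents[1] / "scratch" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    ds = simulate_screen_dataset(contig_len=100_000, n_background=200, seed=SEED)
    write_fasta(ds.contigs, OUT / "reference.fa")
    write_guides(ds.guides, OUT / "guides.tsv")
    lengths = {n: len(s) for n, s in ds.contigs.items()}
    write_vcf(ds.edited, OUT / "edited.vcf", lengths)
    write_vcf(ds.control, OUT / "control.vcf", lengths)
    write_registry(ds, OUT / "registry.json")
    print(
        f"screen inputs: {sum(lengths.values())} bp genome, "
        f"{len(ds.guides)} guides, {len(ds.edits)} planted edits, "
        f"{len(ds.shared_background)} shared + "
        f"{len(ds.edited_background)} clone-private background SNVs"
    )

    cohort = synth_cohort(seed=SEED)
    cohort.to_tsv(OUT / "cohort.tsv")
    print(f"cohort: {len(cohort)} patients ({cohort.n_mcleod} McLeod, "
          f"{cohort.n_multi} multi-system)")

    planted = {acc: r for (acc, _, _, _, r) in datasets.RBC_PROTEIN_QUANT}
    genes = {acc: g for (acc, g, _, _, _) in datasets.RBC_PROTEIN_QUANT}
    quant = synth_proteome(
        n_proteins=1000, planted=planted, genes=genes, noise_cv=0.05, seed=SEED
    )
    write_quant_tsv(quant, OUT / "quant.tsv")
    print(f"proteome: {len(quant)} proteins "
          f"({len(planted)} planted at published ratios)")


if __name__ == "__main__":
    main()
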