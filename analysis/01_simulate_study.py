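"""Generate the synthetic study: cohort genotypes, expression traits with
planted genetic correlations, an eQTL summary table with planted shared
eSNPs, chromatin contacts anchored at transcript loci, and a TF list.

Writes every input the downstream stages consume under results/study/.
"""

import argparse
from pathlib import Path

from txgc import io
from txgc.simulate import SimConfig, StudyConfig, simulate_study


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/study"))
    args = parser.parse_args()

    config = StudyConfig(
        sim=SimConfig(
            n_individuals=700, n_snps=5000, n_causal=100,
            h2_i=0.5, h2_j=0.5, r_G=0.0, r_E=0.2, seed=args.seed,
        ),
        n_pairs=12,
        n_shared_esnp_pairs=6,
        n_planted_contact_pairs=6,
        n_background_contacts=40,
        tf_fraction=0.15,
    )
    bundle = simulate_study(config)

    out = args.out
    out.mkdir(parents=True, exist_ok=True)
    io.write_genotypes_tsv(bundle.genotypes, out / "genotypes.tsv")
    io.write_expression(bundle.expression, out / "expression.tsv")
    io.write_annotation(bundle.annotation, out / "annotation.tsv")
    io.write_eqtl(bundle.eqtl, out / "eqtl.tsv")
    io.write_bedpe(bundle.contacts, out / "contacts.bedpe")
    io.write_gene_list(bundle.tf_genes, out / "tf_genes.txt")
    bundle.truth.pairs.to_csv(out / "truth_pairs.tsv", sep="\t", index=False)

    t = bundle.truth.pairs
    print(f"simulated {config.sim.n_individuals} individuals x {config.sim.n_snps} SNPs")
    print(f"{config.n_pairs} transcript pairs ({(t['r_G'].abs() >= 0.9).sum()} with |r_G| = 0.9)")
    print(f"{(t['shared_esnp'] != '').sum()} pairs with a planted shared eSNP")
    print(f"{t['contact_planted'].sum()} pairs with a planted chromatin contact")
    print(f"{len(bundle.tf_genes)} transcription-factor genes of {len(bundle.annotation)}")
    print(f"inputs written to {out}/")


if __name__ == "__main__":
    main()
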