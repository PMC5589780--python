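"""Build the GRM, drop related individuals, and screen transcripts for
heritability (univariate GREML, keep h2 > 0.25).

Reads results/study/, writes the GRM, the retained-individual list and
the per-probe h2 table under results/.
"""

import argparse
from pathlib import Path

import numpy as np

from txgc import io
from txgc.greml import GRMEigen
from txgc.grm import GRM, compute_grm, filter_unrelated, offdiag_variance
from txgc.pipeline import PipelineConfig, h2_screen


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--study", type=Path, default=Path("results/study"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    config = PipelineConfig()

    genotypes = io.read_genotypes_tsv(args.study / "genotypes.tsv")
    expression = io.read_expression(args.study / "expression.tsv")

    grm_full = compute_grm(genotypes, maf_min=config.maf_min)
    retained = filter_unrelated(grm_full, threshold=config.relatedness_threshold)
    grm = GRM(
        A=grm_full.A[np.ix_(retained, retained)],
        individual_ids=grm_full.individual_ids[retained],
        n_snps_used=grm_full.n_snps_used,
    )
    print(f"GRM from {grm.n_snps_used} SNPs; var(A_ij) = {offdiag_variance(grm):.2e}")
    print(f"unrelatedness filter (> {config.relatedness_threshold}): "
          f"kept {len(retained)} of {grm_full.n} individuals")

    eig = GRMEigen.from_grm(grm)
    h2 = h2_screen(expression.iloc[:, retained], eig, config.h2_min)
    n_pass = int(h2["passed"].sum())
    print(f"h2 screen (> {config.h2_min}): {n_pass} of {len(h2)} probes retained "
          f"(mean h2 of retained = {h2.loc[h2['passed'], 'h2'].mean():.3f})")

    args.out.mkdir(parents=True, exist_ok=True)
    io.write_grm_tsv(grm, args.out / "grm.tsv")
    h2.to_csv(args.out / "h2_table.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
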