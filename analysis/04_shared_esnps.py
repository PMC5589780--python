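"""Cross-lookup of top eSNPs between correlated transcript pairs: for
each pair, each transcript's strongest eSNP (p < 1e-6) is looked up
against the partner transcript; significant shared eSNPs are classified
by the sign concordance of their cross betas against the sign of r_G.

Writes results/esnp_results.tsv and results/esnp_bins.tsv.
"""

import argparse
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from txgc import io
from txgc.esnp import bin_shared_fraction, concordance_chi2, cross_lookup
from txgc.pipeline import PipelineConfig


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--study", type=Path, default=Path("results/study"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    config = PipelineConfig()

    rg = pd.read_csv(args.out / "rg_table.tsv", sep="\t")
    eqtl = io.read_eqtl(args.study / "eqtl.tsv")
    annotation = io.read_annotation(args.study / "annotation.tsv")

    focus = rg[rg["fdr_significant"]] if rg["fdr_significant"].any() else rg
    n_evaluable = 2 * len(focus)  # two lookups attempted per pair
    results, rg_by_pair = [], {}
    for _, row in focus.iterrows():
        res = cross_lookup(
            row["probe_i"], row["probe_j"], eqtl,
            n_evaluable=n_evaluable, alpha=config.alpha,
            p_max=config.esnp_p_max, annotation=annotation, r_G=row["r_G"],
        )
        results.append(res)
        rg_by_pair[(row["probe_i"], row["probe_j"])] = row["r_G"]

    n_eval = sum(r.evaluable for r in results)
    n_sig = sum(r.significant for r in results)
    print(f"{len(focus)} pairs examined; {n_eval} evaluable; "
          f"{n_sig} with a significant shared eSNP "
          f"(Bonferroni p < {config.alpha / n_evaluable:.2e})")

    cats = [r.concordance_category for r in results if r.concordance_category]
    counts = {c: cats.count(c) for c in ("i", "ii", "iii", "iv")}
    print(f"concordance categories i-iv: {counts}")
    if sum(counts.values()):
        chi2, p = concordance_chi2(counts)
        print(f"equal-occupancy goodness of fit: chi2 = {chi2:.1f}, p = {p:.2e}")

    table = pd.DataFrame([asdict(r) for r in results])
    table.to_csv(args.out / "esnp_results.tsv", sep="\t", index=False)
    bins = bin_shared_fraction(results, rg_by_pair)
    bins.to_csv(args.out / "esnp_bins.tsv", sep="\t", index=False)
    occupied = bins[bins["n_evaluable"] > 0]
    print("shared-eSNP percentage by r_G bin:")
    for _, b in occupied.iterrows():
        print(f"  [{b['bin_lo']:+.1f}, {b['bin_hi']:+.1f}): "
              f"{b['percent_shared']:.0f}% of {int(b['n_evaluable'])}")


if __name__ == "__main__":
    main()
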