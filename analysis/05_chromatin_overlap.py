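"""Ask whether correlated transcript pairs co-locate with chromatin
contacts more often than expected: filter self-ligation artifacts,
count window overlaps, and compare against a null of shuffled pairs
(1000 permutations, two-tailed empirical p).

Writes results/hic_overlap.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from txgc import io
from txgc.hic import filter_self_ligation, permutation_test
from txgc.pipeline import PipelineConfig, pair_loci


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--study", type=Path, default=Path("results/study"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    config = PipelineConfig()

    rg = pd.read_csv(args.out / "rg_table.tsv", sep="\t")
    annotation = io.read_annotation(args.study / "annotation.tsv")
    contacts = io.read_bedpe(args.study / "contacts.bedpe")

    kept = filter_self_ligation(contacts)
    print(f"self-ligation filter (< 20 kb): kept {len(kept)} of {len(contacts)} contacts")

    focus = rg[rg["fdr_significant"]] if rg["fdr_significant"].any() else rg
    pairs = pair_loci(focus, annotation)
    rows = []
    for window in config.windows:
        res = permutation_test(pairs, kept, window=window,
                               B=config.n_permutations, seed=args.seed)
        rows.append(
            {
                "window": window,
                "observed": res.observed,
                "null_mean": float(res.null_counts.mean()),
                "null_max": int(res.null_counts.max()),
                "p_two_tailed": res.p_two_tailed,
            }
        )
        print(f"window {window // 1000:>5} kb: observed {res.observed} overlaps, "
              f"null mean {res.null_counts.mean():.2f}, p = {res.p_two_tailed:.4g}")

    pd.DataFrame(rows).to_csv(args.out / "hic_overlap.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
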