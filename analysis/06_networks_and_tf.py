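"""Build co-regulation networks from r_G exceedances of the 3-sigma
null threshold, rank hub transcripts by connection count, export the
edge list, and test hub genes for transcription-factor enrichment
(hypergeometric upper tail).

Writes results/hub_table.tsv and results/network_edges.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from txgc import io
from txgc.grm import offdiag_variance
from txgc.network import build_network, hub_table, network_edge_list, tf_enrichment
from txgc.nullmodel import null_rg_variance, sigma_threshold


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--study", type=Path, default=Path("results/study"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    rg = pd.read_csv(args.out / "rg_table.tsv", sep="\t")
    annotation = io.read_annotation(args.study / "annotation.tsv")
    tf_genes = io.read_gene_list(args.study / "tf_genes.txt")
    h2 = pd.read_csv(args.out / "h2_table.tsv", sep="\t")
    grm = io.read_grm_tsv(args.out / "grm.tsv")

    h2bar = float(h2.loc[h2["passed"], "h2"].mean())
    var_null = null_rg_variance(h2bar, h2bar, grm.n, offdiag_variance(grm))
    threshold = min(sigma_threshold(var_null, 3), 1.0)
    print(f"3-sigma edge threshold from the cohort's own null model: |r_G| >= {threshold:.2f}")

    hubs = hub_table(rg, annotation, threshold=threshold)
    connected = hubs[hubs["n_connections"] > 0]
    print(f"{len(connected)} transcripts with at least one connection; top hubs:")
    for _, h in hubs.head(5).iterrows():
        print(f"  {h['probe_id']} ({h['gene_id']}, {h['chromosome']}): "
              f"{h['n_connections']} connections, "
              f"{h['fraction_interchromosomal']:.0%} interchromosomal, "
              f"{h['fraction_positive_rg']:.0%} positive")

    G = build_network(rg, threshold=threshold)
    edges = network_edge_list(G)
    print(f"network: {G.number_of_nodes()} nodes, {G.number_of_edges()} signed edges")

    ann = annotation.set_index("probe_id")
    hub_genes = set(ann.reindex(connected["probe_id"])["gene_id"].dropna())
    background = set(annotation["gene_id"])
    if hub_genes:
        res = tf_enrichment(hub_genes, set(tf_genes), background)
        print(f"TF enrichment in hub genes: {res.successes_in_sample}/{res.sample_size} TFs "
              f"vs {res.successes_in_population}/{res.population} in background, "
              f"hypergeometric p = {res.p_value:.3g}")

    hubs.to_csv(args.out / "hub_table.tsv", sep="\t", index=False)
    edges.to_csv(args.out / "network_edges.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
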