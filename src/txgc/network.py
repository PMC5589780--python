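"""Co-regulation networks from r_G exceedances, hub ranking and TF enrichment.

Transcripts whose |r_G| with a partner exceeds a sigma threshold from
the null model form network edges; per-transcript connection counts
identify co-regulation hubs, and a hypergeometric test asks whether hub
genes are enriched for transcription factors relative to the expressed
gene universe.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EnrichmentResult",
    "connection_counts",
    "hub_table",
    "tf_enrichment",
    "build_network",
]


@dataclass
class EnrichmentResult:
    population: int
    successes_in_population: int
    sample_size: int
    successes_in_sample: int
    p_value: float  # upper tail, P(X >= observed)


def _edges_above(rg_table: pd.DataFrame, threshold: float) -> pd.DataFrame:
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if (rg_table["probe_i"] == rg_table["probe_j"]).any():
        raise ValueError("r_G table contains self-edges")
    return rg_table[rg_table["r_G"].abs() >= threshold]


def connection_counts(rg_table: pd.DataFrame, threshold: float = 0.72) -> pd.Series:
    """Number of partners with |r_G| >= threshold per transcript.

    Every transcript appearing in the table gets a count (zero when it
    never exceeds the threshold); each qualifying edge contributes to
    both endpoints.
    """
    strong = _edges_above(rg_table, threshold)
    endpoints = pd.concat([strong["probe_i"], strong["probe_j"]], ignore_index=True)
    all_probes = pd.concat([rg_table["probe_i"], rg_table["probe_j"]], ignore_index=True).unique()
    counts = endpoints.value_counts().reindex(all_probes, fill_value=0).astype(int)
    counts.index.name = "probe_id"
    counts.name = "n_connections"
    return counts.sort_index()


def hub_table(
    rg_table: pd.DataFrame,
    annotation: pd.DataFrame,
    threshold: float = 0.72,
    top_k: int = 50,
) -> pd.DataFrame:
    """Ranked hub summary for the top_k most connected transcripts.

    Descending connection count, ties broken by probe id; reports the
    fraction of qualifying partners on a different chromosome and the
    fraction with positive r_G.
    """
    counts = connection_counts(rg_table, threshold)
    strong = _edges_above(rg_table, threshold)
    ann = annotation.set_index("probe_id")
    rows = []
    for probe, n_conn in counts.items():
        sub = strong[(strong["probe_i"] == probe) | (strong["probe_j"] == probe)]
        if n_conn > 0:
            if "interchromosomal" in sub.columns:
                frac_inter = float(sub["interchromosomal"].mean())
            else:
                partner_chrom = np.where(
                    sub["probe_i"] == probe,
                    ann.reindex(sub["probe_j"])["chromosome"].to_numpy(),
                    ann.reindex(sub["probe_i"])["chromosome"].to_numpy(),
                )
                own = ann.loc[probe, "chromosome"]
                frac_inter = float(np.mean(partner_chrom != own))
            frac_pos = float((sub["r_G"] > 0).mean())
        else:
            frac_inter = frac_pos = 0.0
        rows.append(
            {
                "probe_id": probe,
                "gene_id": ann.loc[probe, "gene_id"] if probe in ann.index else "",
                "chromosome": ann.loc[probe, "chromosome"] if probe in ann.index else "",
                "n_connections": int(n_conn),
                "fraction_interchromosomal": frac_inter,
                "fraction_positive_rg": frac_pos,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["n_connections", "probe_id"], ascending=[False, True], kind="mergesort"
    )
    return table.head(top_k).reset_index(drop=True)


def tf_enrichment(
    sample_genes: set[str] | list[str],
    tf_genes: set[str] | list[str],
    background_genes: set[str] | list[str],
) -> EnrichmentResult:
    """Hypergeometric upper-tail test for TF enrichment in a gene set.

    Population = background gene universe, successes = TFs present in
    the background, sample = the query gene set (must be a subset of
    the background).  p = P(X >= observed overlap).
    """
    bg = set(background_genes)
    sample = set(sample_genes)
    tfs = set(tf_genes) & bg
    if not sample <= bg:
        raise ValueError("sample genes must be a subset of the background")
    M, K, N = len(bg), len(tfs), len(sample)
    k = len(sample & tfs)
    p = float(stats.hypergeom.sf(k - 1, M, K, N))
    return EnrichmentResult(
        population=M,
        successes_in_population=K,
        sample_size=N,
        successes_in_sample=k,
        p_value=p,
    )


def build_network(
    rg_table: pd.DataFrame,
    threshold: float,
    focal_probe: str | None = None,
) -> nx.Graph:
    """Graph of edges with |r_G| >= threshold, signed edge weights.

    With ``focal_probe`` the graph is restricted to edges incident to
    the focal transcript plus edges among its partners.  Nodes carry no
    layout; rendering is left to the caller.
    """
    strong = _edges_above(rg_table, threshold)
    G = nx.Graph()
    for _, row in strong.iterrows():
        G.add_edge(row["probe_i"], row["probe_j"], r_G=float(row["r_G"]))
    if focal_probe is not None:
        if focal_probe not in G:
            raise ValueError(f"focal probe {focal_probe!r} has no edge above threshold")
        keep = set(G.neighbors(focal_probe)) | {focal_probe}
        G = G.subgraph(keep).copy()
    return G


def network_edge_list(G: nx.Graph) -> pd.DataFrame:
    """Export a graph to a (probe_i, probe_j, r_G) edge-list table."""
    rows = [
        {"probe_i": u, "probe_j": v, "r_G": data["r_G"]}
        for u, v, data in G.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["probe_i", "probe_j", "r_G"])
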