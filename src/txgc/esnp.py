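"""Shared-eSNP cross-lookup between genetically correlated transcript pairs.

For each transcript in a correlated pair, the strongest associated SNP
(top eSNP, smallest p below 1e-6) is taken from an independent eQTL
summary table; the cross-association of each transcript's top eSNP with
the partner transcript is then looked up.  A pair is evaluable when both
cross rows exist, and carries a significant shared eSNP when a cross
p-value falls below the Bonferroni threshold over all attempted lookups.
The sign structure of the two cross betas against the sign of r_G
classifies each shared eSNP into four concordance categories, summarized
with a goodness-of-fit chi-square against equal occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TopEsnp",
    "SharedEsnpResult",
    "select_top_esnp",
    "cross_lookup",
    "classify_concordance",
    "concordance_chi2",
    "bin_shared_fraction",
]

TOP_ESNP_P_MAX = 1e-6
CIS_WINDOW = 1_000_000


@dataclass
class TopEsnp:
    snp_id: str
    chromosome: str
    position: int
    beta: float
    se: float
    p_value: float


@dataclass
class SharedEsnpResult:
    probe_i: str
    probe_j: str
    top_esnp_i: str | None
    top_esnp_j: str | None
    cross_beta_ij: float  # eSNP_i on transcript j
    cross_p_ij: float
    cross_beta_ji: float  # eSNP_j on transcript i
    cross_p_ji: float
    evaluable: bool
    significant: bool
    concordance_category: str | None = None
    cis_trans_class: str | None = None


def _validate_assocs(assocs: pd.DataFrame) -> None:
    if ((assocs["p_value"] <= 0) | (assocs["p_value"] > 1)).any():
        raise ValueError("association p-values must lie in (0, 1]")


def select_top_esnp(assocs: pd.DataFrame, p_max: float = TOP_ESNP_P_MAX) -> TopEsnp | None:
    """Pick the strongest association for one probe, or None.

    Smallest p below ``p_max``; ties broken by larger |beta|, then by
    smaller (chromosome, position).
    """
    if assocs.empty:
        return None
    if assocs["probe_id"].nunique() > 1:
        raise ValueError("select_top_esnp expects rows for a single probe")
    _validate_assocs(assocs)
    hits = assocs[assocs["p_value"] < p_max]
    if hits.empty:
        return None
    ranked = hits.assign(_absbeta=hits["beta"].abs()).sort_values(
        ["p_value", "_absbeta", "chromosome", "position"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    row = ranked.iloc[0]
    return TopEsnp(
        snp_id=row["snp_id"],
        chromosome=row["chromosome"],
        position=int(row["position"]),
        beta=float(row["beta"]),
        se=float(row["se"]),
        p_value=float(row["p_value"]),
    )


def _is_cis(snp_chrom: str, snp_pos: int, tx_chrom: str, tx_pos: int, window: int = CIS_WINDOW) -> bool:
    return snp_chrom == tx_chrom and abs(int(snp_pos) - int(tx_pos)) <= window


def cross_lookup(
    probe_i: str,
    probe_j: str,
    eqtl: pd.DataFrame,
    n_evaluable: int,
    alpha: float = 0.05,
    p_max: float = TOP_ESNP_P_MAX,
    annotation: pd.DataFrame | None = None,
    r_G: float | None = None,
) -> SharedEsnpResult:
    """Cross-lookup of top eSNPs between the two transcripts of a pair.

    ``n_evaluable`` is the study-wide number of attempted cross-lookups,
    setting the Bonferroni threshold alpha / n_evaluable.  A missing
    partner row renders the pair non-evaluable (not an error).  With an
    annotation table the eSNP/transcript geometry is classified cis/trans
    (cis = same chromosome and within 1 Mb); with an r_G value the sign
    concordance category is attached.
    """
    by_probe = {p: g for p, g in eqtl.groupby("probe_id")}
    top_i = select_top_esnp(by_probe.get(probe_i, eqtl.iloc[0:0]), p_max)
    top_j = select_top_esnp(by_probe.get(probe_j, eqtl.iloc[0:0]), p_max)
    nan = float("nan")
    result = SharedEsnpResult(
        probe_i=probe_i,
        probe_j=probe_j,
        top_esnp_i=top_i.snp_id if top_i else None,
        top_esnp_j=top_j.snp_id if top_j else None,
        cross_beta_ij=nan,
        cross_p_ij=nan,
        cross_beta_ji=nan,
        cross_p_ji=nan,
        evaluable=False,
        significant=False,
    )
    if top_i is None or top_j is None:
        return result

    def lookup(snp_id: str, probe: str):
        rows = by_probe.get(probe)
        if rows is None:
            return None
        rows = rows[rows["snp_id"] == snp_id]
        if rows.empty:
            return None
        row = rows.sort_values("p_value").iloc[0]
        return float(row["beta"]), float(row["p_value"])

    ij = lookup(top_i.snp_id, probe_j)
    ji = lookup(top_j.snp_id, probe_i)
    if ij is None or ji is None:
        return result
    result.cross_beta_ij, result.cross_p_ij = ij
    result.cross_beta_ji, result.cross_p_ji = ji
    result.evaluable = True
    threshold = alpha / n_evaluable
    result.significant = result.cross_p_ij < threshold or result.cross_p_ji < threshold

    if annotation is not None:
        ann = annotation.set_index("probe_id")
        classes = []
        for top, probe in [(top_i, probe_j), (top_j, probe_i)]:
            tx = ann.loc[probe]
            classes.append(
                "cis" if _is_cis(top.chromosome, top.position, tx["chromosome"], tx["position"]) else "trans"
            )
        result.cis_trans_class = "cis/trans" if "cis" in classes else "trans/trans"
    if r_G is not None and result.significant:
        result.concordance_category = classify_concordance(
            r_G, result.cross_beta_ij, result.cross_beta_ji
        )
    return result


def classify_concordance(r_G: float, beta_i: float, beta_j: float) -> str | None:
    """Concordance category of a shared eSNP's cross betas against r_G.

    (i) positive r_G, same beta sign; (ii) positive r_G, opposite sign;
    (iii) negative r_G, same sign; (iv) negative r_G, opposite sign.
    Zero r_G or a zero beta is excluded (returns None).
    """
    if r_G == 0 or beta_i == 0 or beta_j == 0:
        return None
    same_sign = (beta_i > 0) == (beta_j > 0)
    if r_G > 0:
        return "i" if same_sign else "ii"
    return "iii" if same_sign else "iv"


def concordance_chi2(counts: dict[str, int]) -> tuple[float, float]:
    """Goodness-of-fit of category counts against equal occupancy, df = 3."""
    obs = np.array([counts.get(c, 0) for c in ("i", "ii", "iii", "iv")], dtype=float)
    total = obs.sum()
    if total == 0:
        raise ValueError("no classified shared eSNPs to test")
    expected = np.full(4, total / 4.0)
    chi2 = float(np.sum((obs - expected) ** 2 / expected))
    p = float(stats.chi2.sf(chi2, df=3))
    return chi2, p


def bin_shared_fraction(
    results: list[SharedEsnpResult],
    rg_by_pair: dict[tuple[str, str], float],
    bin_width: float = 0.1,
) -> pd.DataFrame:
    """Percentage of evaluable pairs with a significant shared eSNP per r_G bin.

    Bins are half-open [lo, hi) over [-1, 1] with the top bin closed.
    Returns a table with bin edges, evaluable count, shared count and
    percentage (0 for empty bins).
    """
    n_bins = int(round(2.0 / bin_width))
    edges = -1.0 + bin_width * np.arange(n_bins + 1)
    evaluable = np.zeros(n_bins, dtype=int)
    shared = np.zeros(n_bins, dtype=int)
    for res in results:
        if not res.evaluable:
            continue
        rg = rg_by_pair.get((res.probe_i, res.probe_j), rg_by_pair.get((res.probe_j, res.probe_i)))
        if rg is None:
            continue
        idx = int(np.floor((rg - (-1.0)) / bin_width))
        idx = min(max(idx, 0), n_bins - 1)  # top bin closed
        evaluable[idx] += 1
        if res.significant:
            shared[idx] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(evaluable > 0, 100.0 * shared / np.maximum(evaluable, 1), 0.0)
    return pd.DataFrame(
        {
            "bin_lo": edges[:-1],
            "bin_hi": edges[1:],
            "n_evaluable": evaluable,
            "n_shared": shared,
            "percent_shared": pct,
        }
    )
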