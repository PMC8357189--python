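"""Occupancy peak-to-gene assignment and feature annotation.

Each peak is assigned to the gene with the nearest TSS (peak midpoint to TSS,
unsigned distance, ties broken by lexicographic gene id) and annotated by
feature: *promoter* when the midpoint lies in the strand-aware promoter window
around the TSS, *gene_body* when inside the gene span, else *intergenic*.
Peaks farther than ``max_distance_bp`` from every TSS stay unassigned. The
per-gene table (bound iff >= 1 assigned peak) feeds the wave classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("slamwaves")

FEATURE_CLASSES = ("promoter", "gene_body", "intergenic")


@dataclass(frozen=True)
class PromoterWindow:
    """Strand-aware promoter interval around the TSS.

    A midpoint at signed distance d from the TSS (negative = upstream of the
    gene, positive = into the gene) is in the promoter iff
    -upstream_bp <= d <= downstream_bp.
    """

    upstream_bp: int = 2000
    downstream_bp: int = 500

    def __post_init__(self) -> None:
        if self.upstream_bp < 0 or self.downstream_bp < 0:
            raise ValueError("promoter extents must be non-negative")
        if self.upstream_bp == 0 and self.downstream_bp == 0:
            raise ValueError("promoter window cannot be empty")


def genes_frame(genes) -> pd.DataFrame:
    """Normalise gene input (GeneModel list or DataFrame) to a frame."""
    if isinstance(genes, pd.DataFrame):
        df = genes.copy()
    else:
        import dataclasses

        df = pd.DataFrame([dataclasses.asdict(g) for g in genes])
    required = {"gene_id", "contig", "start", "end", "strand", "tss"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene table lacks columns: {sorted(missing)}")
    return df


def read_genes_bed(path) -> pd.DataFrame:
    """BED6 gene spans; the TSS is the strand-dependent 5' end."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            start, end = int(f[1]), int(f[2])
            strand = f[5] if len(f) > 5 else "+"
            rows.append({"gene_id": f[3], "contig": f[0], "start": start,
                         "end": end, "strand": strand,
                         "tss": start if strand == "+" else end - 1})
    return pd.DataFrame(rows)


def signed_tss_distance(midpoint: int, tss: int, strand: str) -> int:
    """Signed bp from TSS to midpoint; negative upstream of the gene."""
    return midpoint - tss if strand == "+" else tss - midpoint


def _classify_feature(signed: int, midpoint: int, start: int, end: int,
                      window: PromoterWindow) -> str:
    if -window.upstream_bp <= signed <= window.downstream_bp:
        return "promoter"
    if start <= midpoint < end:
        return "gene_body"
    return "intergenic"


def assign_peaks(
    peaks: pd.DataFrame,
    genes,
    window: PromoterWindow = PromoterWindow(),
    max_distance_bp: int = 10_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Nearest-TSS peak assignment plus the per-gene occupancy table.

    Returns (per-peak annotation, per-gene table). The per-peak annotation has
    one row per peak with assigned gene (or None), signed TSS distance, and
    feature class; the per-gene table flags each gene bound iff at least one
    peak was assigned to it within ``max_distance_bp``.
    """
    gdf = genes_frame(genes)
    unknown = sorted(set(peaks["contig"]) - set(gdf["contig"]))
    if unknown:
        raise ValueError(f"peaks on contigs absent from gene annotation: {unknown}")

    by_contig = {}
    for contig, sub in gdf.groupby("contig"):
        # sort by (tss, gene_id) so equidistant ties resolve lexicographically
        sub = sub.sort_values(["tss", "gene_id"], kind="stable")
        by_contig[contig] = (
            sub["tss"].to_numpy(), sub.reset_index(drop=True))

    rows = []
    for r in peaks.itertuples(index=False):
        if r.start >= r.end:
            raise ValueError(f"peak {r.peak_id}: start must precede end")
        mid = (int(r.start) + int(r.end)) // 2
        tss_arr, sub = by_contig[r.contig]
        j = int(np.searchsorted(tss_arr, mid))
        cands = [k for k in (j - 1, j, j + 1) if 0 <= k < len(tss_arr)]
        dists = [abs(mid - int(tss_arr[k])) for k in cands]
        dmin = min(dists)
        # among equidistant TSSs pick the lexicographically smallest gene id
        best = min(
            (sub.iloc[k] for k, dk in zip(cands, dists) if dk == dmin),
            key=lambda g: g.gene_id)
        if dmin > max_distance_bp:
            rows.append({"peak_id": r.peak_id, "contig": r.contig,
                         "start": r.start, "end": r.end, "midpoint": mid,
                         "gene_id": None, "tss_distance": None,
                         "feature": None, "assigned": False})
            continue
        signed = signed_tss_distance(mid, int(best.tss), best.strand)
        feature = _classify_feature(signed, mid, int(best.start),
                                    int(best.end), window)
        rows.append({"peak_id": r.peak_id, "contig": r.contig,
                     "start": r.start, "end": r.end, "midpoint": mid,
                     "gene_id": best.gene_id, "tss_distance": signed,
                     "feature": feature, "assigned": True})
    annotations = pd.DataFrame(
        rows, columns=["peak_id", "contig", "start", "end", "midpoint",
                       "gene_id", "tss_distance", "feature", "assigned"])

    assigned = annotations[annotations["assigned"]]
    per_gene = []
    groups = {gid: sub for gid, sub in assigned.groupby("gene_id")}
    for g in gdf.sort_values("gene_id").itertuples(index=False):
        sub = groups.get(g.gene_id)
        if sub is None:
            per_gene.append({"gene_id": g.gene_id, "bound": False,
                             "n_peaks": 0, "peak_ids": "",
                             "nearest_tss_distance": None})
        else:
            nearest = sub.loc[sub["tss_distance"].abs().idxmin()]
            per_gene.append({
                "gene_id": g.gene_id, "bound": True, "n_peaks": len(sub),
                "peak_ids": ";".join(sub["peak_id"]),
                "nearest_tss_distance": int(nearest["tss_distance"]),
            })
    occupancy_table = pd.DataFrame(per_gene)
    logger.info("assign_peaks: %d/%d peaks assigned; %d genes bound",
                len(assigned), len(annotations),
                int(occupancy_table["bound"].sum()))
    return annotations, occupancy_table


def feature_distribution(annotations: pd.DataFrame) -> dict:
    """Fractions of assigned peaks per feature class (summing to 1)."""
    assigned = annotations[annotations["assigned"]]
    if assigned.empty:
        raise ValueError("no assigned peaks to summarise")
    n = len(assigned)
    counts = assigned["feature"].value_counts()
    out = {feat: float(counts.get(feat, 0)) / n for feat in FEATURE_CLASSES}
    out["n_assigned"] = n
    out["n_unassigned"] = int((~annotations["assigned"]).sum())
    return out
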