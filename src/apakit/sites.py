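"""Cleavage-site calling: event extraction, merging, annotation, regions.

Coordinates are 0-based half-open throughout (BED-native). A cleavage event
is the inferred mRNA 3'-end position of one read; events are pooled across
samples, single-linkage merged within a gap (15 nt by default), and mapped to
an annotated poly(A)-site catalogue (1-bp BED6 records named
``geneID|anything``). Events of a feature overlapping several annotated sites
are split to the nearest site so counts are conserved.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from apakit._util import read_bed6

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ["contig", "position", "strand", "sample_id"]


def extract_cleavage_events(
    path,
    sample_id: str,
    orientation: str = "forward",
    known_contigs: set[str] | None = None,
) -> pd.DataFrame:
    """Read per-read cleavage events from a BAM/SAM or a read-end BED6 file.

    With ``orientation='forward'`` the transcriptional 3' end of a
    '+'-aligned read is its rightmost aligned base (leftmost for '-');
    ``'reverse'`` flips both the event strand and which end is taken.
    Unmapped/secondary/supplementary records are skipped with a counted
    warning.
    """
    if orientation not in ("forward", "reverse"):
        raise ValueError("orientation must be 'forward' or 'reverse'")
    path = Path(path)
    if path.suffix.lower() == ".bed":
        bed = read_bed6(path)
        if not ((bed["end"] - bed["start"]) == 1).all():
            raise ValueError("read-end BED must contain 1-bp intervals")
        if not bed["strand"].isin(["+", "-"]).all():
            raise ValueError("read-end BED strand must be '+' or '-'")
        if (bed["start"] < 0).any():
            raise ValueError("negative coordinates in read-end BED")
        events = pd.DataFrame(
            {
                "contig": bed["contig"],
                "position": bed["start"],
                "strand": bed["strand"],
                "sample_id": sample_id,
            }
        )
    else:
        import pysam

        recs = []
        skipped = 0
        mode = "rb" if path.suffix.lower() == ".bam" else "r"
        with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
            for aln in fh:
                if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                    skipped += 1
                    continue
                strand = "-" if aln.is_reverse else "+"
                if strand == "+":
                    pos = aln.reference_end - 1
                else:
                    pos = aln.reference_start
                recs.append((aln.reference_name, pos, strand))
        if skipped:
            warnings.warn(f"skipped {skipped} unmapped/secondary records")
        events = pd.DataFrame(recs, columns=["contig", "position", "strand"])
        events["sample_id"] = sample_id
    if orientation == "reverse":
        flip = events["strand"] == "+"
        events["strand"] = np.where(flip, "-", "+")
    if known_contigs is not None:
        unknown = set(events["contig"]) - set(known_contigs)
        if unknown:
            raise ValueError(f"unknown contigs in {path.name}: {sorted(unknown)}")
    return events[EVENT_COLUMNS]


@dataclass
class MergeResult:
    """Merged features plus the per-event cluster assignment."""

    features: pd.DataFrame  # feature_id, contig, strand, start, end, <samples>
    assignments: pd.DataFrame  # events + feature_id column
    samples: list[str]


def merge_cleavage_sites(events: pd.DataFrame, gap: int = 15) -> MergeResult:
    """Single-linkage merge of pooled event positions per contig and strand.

    Two positions are linked when ``|p1 - p2| <= gap`` (inclusive); each
    cluster becomes one interval ``[min, max + 1)`` with per-sample counts.
    """
    if gap < 0:
        raise ValueError("gap must be non-negative")
    ev = events.sort_values(["contig", "strand", "position"], kind="mergesort").copy()
    samples = sorted(events["sample_id"].unique())

    feature_rows = []
    assignment_parts = []
    fid = 0
    for (contig, strand), sub in ev.groupby(["contig", "strand"], sort=True):
        pos = sub["position"].to_numpy()
        breaks = np.diff(pos) > gap
        cluster = np.concatenate([[0], np.cumsum(breaks)])
        sub = sub.assign(_cluster=cluster)
        for _, members in sub.groupby("_cluster", sort=True):
            counts = members["sample_id"].value_counts()
            feature_rows.append(
                {
                    "feature_id": fid,
                    "contig": contig,
                    "strand": strand,
                    "start": int(members["position"].min()),
                    "end": int(members["position"].max()) + 1,
                    **{s: int(counts.get(s, 0)) for s in samples},
                }
            )
            assignment_parts.append(members.assign(feature_id=fid))
            fid += 1
    if feature_rows:
        features = pd.DataFrame(feature_rows)
        assignments = pd.concat(assignment_parts, ignore_index=True).drop(
            columns="_cluster"
        )
    else:
        features = pd.DataFrame(
            columns=["feature_id", "contig", "strand", "start", "end"]
        )
        assignments = ev.assign(feature_id=pd.Series(dtype=int))
    return MergeResult(features=features, assignments=assignments, samples=samples)


def _site_order_distal_first(positions: np.ndarray, strand: str) -> np.ndarray:
    """Rank of each position with 1 = most distal in transcription direction."""
    if strand == "+":
        order = np.argsort(-positions, kind="mergesort")
    else:
        order = np.argsort(positions, kind="mergesort")
    ranks = np.empty(len(positions), dtype=int)
    ranks[order] = np.arange(1, len(positions) + 1)
    return ranks


def map_to_annotation(
    merged: MergeResult, pas_annotation: pd.DataFrame
) -> pd.DataFrame:
    """Assign merged features to annotated poly(A) sites.

    Annotation records must be 1-bp BED6 intervals whose name starts with the
    gene ID (``gene`` or ``gene|suffix``). Features overlapping no annotated
    base on the same strand are dropped (logged). A feature overlapping
    several sites is split: each event goes to the nearest site, ties to the
    5'-most site. Returns the PasFeature table with distal-first site indices
    and per-sample counts.
    """
    ann = pas_annotation.copy()
    if not ((ann["end"] - ann["start"]) == 1).all():
        raise ValueError(
            "annotation intervals must be single-base; collapse records to "
            "site positions first"
        )
    if not ann["strand"].isin(["+", "-"]).all():
        raise ValueError("annotation strand must be '+' or '-'")
    ann["gene_id"] = ann["name"].str.split("|").str[0]
    ann["site_pos"] = ann["start"]

    samples = merged.samples
    out_rows = []
    dropped = 0
    ann_groups = {k: v for k, v in ann.groupby(["contig", "strand"], sort=False)}
    for _, feat in merged.features.iterrows():
        key = (feat["contig"], feat["strand"])
        sub_ann = ann_groups.get(key)
        hits = (
            sub_ann[(sub_ann["site_pos"] >= feat["start"]) & (sub_ann["site_pos"] < feat["end"])]
            if sub_ann is not None
            else None
        )
        if hits is None or hits.empty:
            dropped += 1
            continue
        members = merged.assignments[
            merged.assignments["feature_id"] == feat["feature_id"]
        ]
        site_pos = hits["site_pos"].to_numpy()
        if len(hits) == 1:
            groups = {0: members}
        else:
            dist = np.abs(
                members["position"].to_numpy()[:, None] - site_pos[None, :]
            ).astype(float)
            # tie -> 5'-most site: smaller coordinate on '+', larger on '-'
            tiebreak = np.argsort(site_pos)
            if feat["strand"] == "-":
                tiebreak = tiebreak[::-1]
            rank_5p = np.empty(len(site_pos))
            rank_5p[tiebreak] = np.arange(len(site_pos))
            nearest = np.argmin(dist + 1e-9 * rank_5p[None, :], axis=1)
            groups = {
                k: members.iloc[np.flatnonzero(nearest == k)]
                for k in range(len(site_pos))
            }
        for k, (_, hit) in enumerate(hits.iterrows()):
            assigned = groups.get(k)
            if assigned is None or assigned.empty:
                continue
            counts = assigned["sample_id"].value_counts()
            out_rows.append(
                {
                    "gene_id": hit["gene_id"],
                    "contig": feat["contig"],
                    "strand": feat["strand"],
                    "start": int(assigned["position"].min()),
                    "end": int(assigned["position"].max()) + 1,
                    "site_pos": int(hit["site_pos"]),
                    **{s: int(counts.get(s, 0)) for s in samples},
                }
            )
    if dropped:
        logger.info("dropped %d features without annotation overlap", dropped)
    if not out_rows:
        return pd.DataFrame(
            columns=["gene_id", "site_index", "contig", "strand", "start", "end", "site_pos"]
            + samples
        )
    out = pd.DataFrame(out_rows)
    out["site_index"] = 0
    for gene, sub in out.groupby("gene_id", sort=False):
        ranks = _site_order_distal_first(
            sub["site_pos"].to_numpy(), sub["strand"].iloc[0]
        )
        out.loc[sub.index, "site_index"] = ranks
    cols = ["gene_id", "site_index", "contig", "strand", "start", "end", "site_pos"] + samples
    return (
        out[cols]
        .sort_values(["gene_id", "site_index"], kind="mergesort")
        .reset_index(drop=True)
    )


def _parse_blocks(model: pd.Series) -> list[tuple[int, int]]:
    sizes = [int(x) for x in str(model["block_sizes"]).rstrip(",").split(",")]
    starts = [int(x) for x in str(model["block_starts"]).rstrip(",").split(",")]
    return [
        (model["start"] + s, model["start"] + s + sz) for s, sz in zip(starts, sizes)
    ]


def classify_site_region(position: int, model: pd.Series) -> str:
    """Label one genomic position against a BED12 gene model."""
    if not (model["start"] <= position < model["end"]):
        return "intergenic"
    in_block = any(a <= position < b for a, b in _parse_blocks(model))
    if not in_block:
        return "intron"
    ts, te = model["thick_start"], model["thick_end"]
    if ts <= position < te:
        return "CDS"
    if model["strand"] == "+":
        return "5UTR" if position < ts else "3UTR"
    return "3UTR" if position < ts else "5UTR"


def classify_site_regions(
    pas_features: pd.DataFrame, gene_models: pd.DataFrame, samples: list[str]
) -> tuple[pd.DataFrame, pd.Series]:
    """Region label per site plus read-weighted fractions over the four
    genic regions (intergenic sites are excluded from the fractions)."""
    models = gene_models.set_index("name")
    labels = []
    for _, row in pas_features.iterrows():
        gene = row["gene_id"]
        if gene not in models.index:
            warnings.warn(f"gene {gene} absent from gene models; site excluded")
            labels.append("unknown")
            continue
        labels.append(classify_site_region(int(row["site_pos"]), models.loc[gene]))
    out = pas_features.copy()
    out["region"] = labels
    out["_reads"] = out[samples].sum(axis=1)
    genic = out[out["region"].isin(["5UTR", "CDS", "intron", "3UTR"])]
    totals = genic.groupby("region")["_reads"].sum()
    fractions = (totals / totals.sum()).reindex(
        ["5UTR", "CDS", "intron", "3UTR"], fill_value=0.0
    )
    return out.drop(columns="_reads"), fractions
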