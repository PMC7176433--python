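"""UGUA (TGTA in DNA space) frequency profiling around cleavage sites.

For each gene with >= 2 sites, the two sites with the maximum loss and gain
of reads (mean treated CPM minus mean control CPM) are selected; +/-200-nt
strand-specific flanks are extracted in transcript orientation (negative
offsets are 5'/upstream); per-offset UGUA match-start frequencies are
averaged over sequences, mean-filtered with a 5-nt sliding window, and
Gaussian-smoothed (sigma = 20, reflect boundaries).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from apakit._util import CONTROL, TREATED, check_design, condition_samples, revcomp

MOTIF = "TGTA"
_VALID = re.compile(r"^[ACGTUN]*$")


@dataclass
class ShiftSitePair:
    gene_id: str
    loss_index: int  # distal-first site index with maximum read loss
    gain_index: int
    loss_change: float
    gain_change: float
    degenerate: bool


def select_shift_sites(
    cpm_table: pd.DataFrame, design: pd.DataFrame
) -> pd.DataFrame:
    """Per gene, the sites with the maximum CPM loss and gain (treated minus
    control means). Ties break toward the more distal site (lower index)."""
    check_design(design)
    ctrl = condition_samples(design, CONTROL)
    trt = condition_samples(design, TREATED)
    rows = []
    for gene, sub in cpm_table.groupby("gene_id", sort=True):
        if len(sub) < 2:
            continue
        sub = sub.sort_values("site_index")  # distal first => stable argmin/argmax
        change = (
            sub[trt].to_numpy(dtype=float).mean(axis=1)
            - sub[ctrl].to_numpy(dtype=float).mean(axis=1)
        )
        loss = int(np.argmin(change))
        gain = int(np.argmax(change))
        rows.append(
            {
                "gene_id": gene,
                "loss_index": int(sub["site_index"].iloc[loss]),
                "gain_index": int(sub["site_index"].iloc[gain]),
                "loss_change": float(change[loss]),
                "gain_change": float(change[gain]),
                "degenerate": bool(loss == gain),
            }
        )
    return pd.DataFrame(rows)


def _get_seq(genome, contig: str, start: int, end: int) -> str:
    """Fetch genome[contig][start:end] from a dict or pyfaidx.Fasta-like."""
    if isinstance(genome, dict):
        if contig not in genome:
            raise KeyError(f"contig {contig!r} missing from genome")
        return genome[contig][start:end]
    seq = genome[contig][start:end]
    return str(getattr(seq, "seq", seq))


def _contig_length(genome, contig: str) -> int:
    if isinstance(genome, dict):
        return len(genome[contig])
    return len(genome[contig])


def extract_flanks(
    genome, sites: pd.DataFrame, flank: int = 200
) -> tuple[pd.DataFrame, int]:
    """401-nt transcript-orientation flanks around each site.

    ``sites`` needs columns contig, site_pos, strand. '-'-strand sequences
    are reverse complemented so negative profile offsets are always
    transcript-5'. Sites within ``flank`` of a contig edge are dropped and
    counted; returns (frame with a ``flank_seq`` column, n_dropped).
    """
    seqs = []
    keep = []
    dropped = 0
    for i, row in sites.iterrows():
        pos = int(row["site_pos"])
        start, end = pos - flank, pos + flank + 1
        if start < 0 or end > _contig_length(genome, row["contig"]):
            dropped += 1
            continue
        seq = _get_seq(genome, row["contig"], start, end).upper()
        if row["strand"] == "-":
            seq = revcomp(seq)
        seqs.append(seq)
        keep.append(i)
    out = sites.loc[keep].copy()
    out["flank_seq"] = seqs
    return out, dropped


def match_indicator(seq: str, motif: str = MOTIF) -> np.ndarray:
    """Per-position indicator of a motif match starting there (U == T,
    N never matches). Positions within len(motif)-1 of the end are 0."""
    s = seq.upper().replace("U", "T")
    if not _VALID.match(s):
        raise ValueError("sequence contains characters outside ACGTUN")
    ind = np.zeros(len(s), dtype=float)
    for m in re.finditer(f"(?={motif})", s):
        ind[m.start()] = 1.0
    return ind


def ugua_frequency(sequences: list[str], window: int = 5) -> np.ndarray:
    """Mean match-start frequency per offset, mean-filtered with a centred
    window (truncated at the profile ends)."""
    if not sequences:
        raise ValueError("no sequences")
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise ValueError("sequences must have equal length")
    raw = np.mean([match_indicator(s) for s in sequences], axis=0)
    kernel = np.ones(window)
    sums = np.convolve(raw, kernel, mode="same")
    norm = np.convolve(np.ones(length), kernel, mode="same")
    return sums / norm


def gaussian_smooth(profile: np.ndarray, sigma: float = 20.0) -> np.ndarray:
    """Gaussian filter, kernel truncated at 4 sigma, reflect boundaries."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return gaussian_filter1d(
        np.asarray(profile, dtype=float), sigma, mode="reflect", truncate=4.0
    )


@dataclass
class MotifProfile:
    group: str  # shortened / lengthened / nontarget
    site_class: str  # loss / gain
    offsets: np.ndarray  # -flank..+flank
    raw: np.ndarray
    smoothed: np.ndarray
    n_sequences: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group,
                "site_class": self.site_class,
                "offset": self.offsets,
                "raw": self.raw,
                "smoothed": self.smoothed,
            }
        )


def group_motif_profiles(
    results: pd.DataFrame,
    pairs: pd.DataFrame,
    pas_table: pd.DataFrame,
    genome,
    flank: int = 200,
    window: int = 5,
    sigma: float = 20.0,
    alpha: float = 0.05,
    nontarget_max_change: float = 0.05,
) -> dict[tuple[str, str], MotifProfile]:
    """UGUA profiles for {shortened, lengthened, nontarget} x {loss, gain}.

    ``results`` must carry gene_id, adj_pvalue and length_change (the
    non-target rule |change| <= ``nontarget_max_change`` assumes
    proportion-based length changes; pass a different threshold for raw CPM
    scores). ``pas_table`` provides site coordinates (gene_id, site_index,
    contig, site_pos, strand).
    """
    sig = results["adj_pvalue"] < alpha
    groups = {
        "shortened": results.loc[sig & (results["length_change"] < 0), "gene_id"],
        "lengthened": results.loc[sig & (results["length_change"] > 0), "gene_id"],
        "nontarget": results.loc[
            ~sig & (results["length_change"].abs() <= nontarget_max_change), "gene_id"
        ],
    }
    site_lookup = pas_table.set_index(["gene_id", "site_index"])
    offsets = np.arange(-flank, flank + 1)
    profiles: dict[tuple[str, str], MotifProfile] = {}
    pairs_by_gene = pairs.set_index("gene_id")
    for group, genes in groups.items():
        genes = [g for g in genes if g in pairs_by_gene.index]
        for site_class, col in (("loss", "loss_index"), ("gain", "gain_index")):
            rows = []
            for g in genes:
                idx = int(pairs_by_gene.loc[g, col])
                try:
                    site = site_lookup.loc[(g, idx)]
                except KeyError:
                    continue
                rows.append(
                    {
                        "contig": site["contig"],
                        "site_pos": site["site_pos"],
                        "strand": site["strand"],
                    }
                )
            if not rows:
                warnings.warn(f"empty motif group {group}/{site_class}; omitted")
                continue
            flanks, _ = extract_flanks(genome, pd.DataFrame(rows), flank)
            if flanks.empty:
                warnings.warn(f"all flanks dropped for {group}/{site_class}")
                continue
            raw = ugua_frequency(flanks["flank_seq"].tolist(), window)
            profiles[(group, site_class)] = MotifProfile(
                group=group,
                site_class=site_class,
                offsets=offsets,
                raw=raw,
                smoothed=gaussian_smooth(raw, sigma),
                n_sequences=len(flanks),
            )
    return profiles


def profiles_to_frame(profiles: dict[tuple[str, str], MotifProfile]) -> pd.DataFrame:
    if not profiles:
        return pd.DataFrame(columns=["group", "site_class", "offset", "raw", "smoothed"])
    return pd.concat([p.to_frame() for p in profiles.values()], ignore_index=True)
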