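"""Synthetic two-condition 3'-end sequencing study generator.

Emits a mutually consistent genome, gene models, poly(A)-site annotation,
per-read cleavage positions, site-level count tables, a log-normal proteome
with abundance-dependent missingness, and a truth table, all derived from a
single seed so every downstream stage can be checked against known ground
truth.

Geometry guarantees baked into the reference:

- true poly(A) sites within a gene are >= 40 nt apart (60 nt used), so with
  read-end jitter truncated at +/- 7 nt a 15-nt single-linkage merge recovers
  exactly one feature per site;
- every site keeps >= 260 nt of contig on both flanks, so +/-200 nt motif
  windows never fall off the contig;
- background sequence is depleted of UGUA in transcript space on both strands
  (TGTA and TACA removed genome-wide) before motif blocks are planted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from apakit._util import CONTROL, TREATED, revcomp, write_bed6, write_bed12, write_fasta

# Gene layout constants (all nt). Two exons with an intron; the CDS runs from
# EXON1 interior into the terminal exon; sites sit in the 3'UTR of the
# terminal exon.
_EXON1_LEN = 200
_INTRON_LEN = 100
_THICK_START = 50
_CDS_INTO_EXON2 = 100  # thickEnd = 400 in plus-layout coordinates
_UTR_LEAD = 60  # first (most proximal) site this far after the CDS end
_SITE_SPACING = 60
_FLANK_PAD = 260  # clearance after the distal site inside the gene
_GENE_GAP = 500
_CONTIG_MARGIN = 300
_MOTIF_BLOCK = "TGTA" * 4  # >= 4 tandem UGUA in transcript space
_JITTER_MAX = 7


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study (3-vs-3 by default)."""

    n_genes: int = 60
    sites_per_gene_range: tuple[int, int] = (1, 4)
    n_target_genes: int = 20
    shift_magnitude: float = 0.2
    precision: float = 100.0
    depth_per_sample: int = 300
    n_per_condition: int = 3
    jitter_scale: float = 1.5
    motif_offset: int = 50
    protein_slope: float = 0.8
    protein_noise_sd: float = 0.25
    missingness_steepness: float = 1.0
    missingness_midpoint: float = 14.0
    seed: int = 0
    n_contigs: int = 2
    gene_dispersion: float = 0.05
    min_site_fraction: float = 0.05
    max_gene_length: int | None = None

    def validate(self) -> None:
        lo, hi = self.sites_per_gene_range
        if self.n_genes <= 0 or lo < 1 or hi < lo:
            raise ValueError("invalid gene/site configuration")
        if not 0 <= self.n_target_genes <= self.n_genes:
            raise ValueError("n_target_genes must be <= n_genes")
        if not 0.0 <= self.shift_magnitude <= 1.0:
            raise ValueError("shift_magnitude must lie in [0, 1]")
        if self.precision <= 0:
            raise ValueError("precision must be positive")
        if self.depth_per_sample <= 0 or self.n_per_condition <= 0:
            raise ValueError("depth and sample counts must be positive")
        if self.jitter_scale < 0:
            raise ValueError("jitter_scale must be non-negative")
        if self.protein_noise_sd <= 0:
            raise ValueError("protein_noise_sd must be positive")
        if self.n_contigs < 2:
            raise ValueError("need >= 2 contigs")

    def samples(self) -> list[str]:
        n = self.n_per_condition
        return [f"{CONTROL}_{i + 1}" for i in range(n)] + [
            f"{TREATED}_{i + 1}" for i in range(n)
        ]

    def design(self) -> pd.DataFrame:
        n = self.n_per_condition
        return pd.DataFrame(
            {"sample": self.samples(), "condition": [CONTROL] * n + [TREATED] * n}
        )


def _streams(config: SimConfig) -> dict[str, np.random.Generator]:
    """One independent RNG stream per artifact, all derived from the seed."""
    names = ["reference", "counts", "reads", "proteome"]
    children = np.random.SeedSequence(config.seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


@dataclass
class SimReference:
    genome: dict[str, str]
    gene_models: pd.DataFrame  # BED12
    pas_annotation: pd.DataFrame  # BED6, name = "gene|site_index" (distal-first)
    truth: pd.DataFrame  # one row per (gene, site)


@dataclass
class SimResult:
    config: SimConfig
    reference: SimReference
    counts: pd.DataFrame
    events: pd.DataFrame
    proteome: pd.DataFrame
    design: pd.DataFrame

    @property
    def truth(self) -> pd.DataFrame:
        return self.reference.truth


def _deplete_ugua(seq: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Rejection-style removal of TGTA/TACA tetramers from a base array."""
    text = "".join(seq)
    pattern = re.compile(r"(?=(TGTA|TACA))")
    for _ in range(20):
        hits = [m.start() for m in pattern.finditer(text)]
        if not hits:
            break
        arr = np.frombuffer(text.encode(), dtype="S1").copy()
        for pos in hits:
            # mutate the final A of the tetramer to a non-A base
            arr[pos + 3] = rng.choice([b"C", b"G"])
        text = arr.tobytes().decode()
    return np.frombuffer(text.encode(), dtype="S1").astype("U1")


def _floor_props(p: np.ndarray, floor: float) -> np.ndarray:
    p = np.maximum(p, floor)
    return p / p.sum()


def simulate_reference(config: SimConfig) -> SimReference:
    """Build genome, BED12 gene models, BED6 site annotation and truth table.

    Genes alternate contigs and strands. Site index 1 is the most distal site
    in transcription direction (largest coordinate on '+', smallest on '-').
    """
    config.validate()
    rng = _streams(config)["reference"]
    lo, hi = config.sites_per_gene_range

    ns_per_gene = rng.integers(lo, hi + 1, size=config.n_genes)
    multi = np.flatnonzero(ns_per_gene >= 2)
    if config.shift_magnitude > 0 and config.n_target_genes > multi.size:
        raise ValueError(
            f"cannot place {config.n_target_genes} target genes: only "
            f"{multi.size} genes have >= 2 sites"
        )
    targets = set(
        rng.choice(multi, size=min(config.n_target_genes, multi.size), replace=False)
    )

    cursor = {f"chr{c + 1}": _CONTIG_MARGIN for c in range(config.n_contigs)}
    model_rows, annot_rows, truth_rows = [], [], []
    motif_plants: list[tuple[str, int, str]] = []  # (contig, genomic start, strand)

    for g in range(config.n_genes):
        ns = int(ns_per_gene[g])
        gene = f"gene{g + 1:04d}"
        contig = f"chr{(g % config.n_contigs) + 1}"
        strand = "+" if (g // config.n_contigs) % 2 == 0 else "-"
        thick_end_rel = _EXON1_LEN + _INTRON_LEN + _CDS_INTO_EXON2
        distal_rel = thick_end_rel + _UTR_LEAD + _SITE_SPACING * (ns - 1)
        length = distal_rel + _FLANK_PAD
        if config.max_gene_length is not None and length > config.max_gene_length:
            raise ValueError(
                f"gene {gene}: length {length} nt needed for {ns} sites exceeds "
                f"max_gene_length={config.max_gene_length}"
            )
        start = cursor[contig]
        cursor[contig] = start + length + _GENE_GAP

        # plus-layout (transcription left->right) relative intervals
        blocks = [(0, _EXON1_LEN), (_EXON1_LEN + _INTRON_LEN, length)]
        thick = (_THICK_START, thick_end_rel)
        sites_rel = [thick_end_rel + _UTR_LEAD + _SITE_SPACING * k for k in range(ns)]
        if strand == "-":  # mirror the layout within the locus
            blocks = [(length - b, length - a) for a, b in blocks][::-1]
            thick = (length - thick[1], length - thick[0])
            sites_rel = [length - 1 - p for p in sites_rel]

        positions = [start + p for p in sites_rel]
        # distal-first ordering along transcription
        order = np.argsort(positions)[::-1] if strand == "+" else np.argsort(positions)
        distal_first = [positions[i] for i in order]

        model_rows.append(
            {
                "contig": contig,
                "start": start,
                "end": start + length,
                "name": gene,
                "score": 0,
                "strand": strand,
                "thick_start": start + thick[0],
                "thick_end": start + thick[1],
                "item_rgb": 0,
                "block_count": len(blocks),
                "block_sizes": ",".join(str(b - a) for a, b in blocks),
                "block_starts": ",".join(str(a) for a, _ in blocks),
            }
        )

        is_target = g in targets and config.shift_magnitude > 0
        p_control = _floor_props(
            rng.dirichlet(np.full(ns, 2.0)), config.min_site_fraction
        )
        shift = config.shift_magnitude
        if is_target:
            # guarantee enough distal mass to move
            if p_control[0] < shift + 0.15:
                rest = 1.0 - (shift + 0.15)
                p_control = np.concatenate(
                    [[shift + 0.15], p_control[1:] * rest / p_control[1:].sum()]
                )
                p_control = _floor_props(p_control, config.min_site_fraction)
            p_treated = p_control.copy()
            moved = min(shift, p_control[0] - config.min_site_fraction / 2)
            p_treated[0] -= moved
            p_treated[-1] += moved
            lc_sign = -1
        else:
            p_treated = p_control.copy()
            lc_sign = 0

        weight = rng.lognormal(mean=0.0, sigma=0.4)
        for idx, pos in enumerate(distal_first, start=1):
            annot_rows.append(
                {
                    "contig": contig,
                    "start": pos,
                    "end": pos + 1,
                    "name": f"{gene}|{idx}",
                    "score": 0,
                    "strand": strand,
                }
            )
            truth_rows.append(
                {
                    "gene_id": gene,
                    "site_index": idx,
                    "contig": contig,
                    "position": pos,
                    "strand": strand,
                    "prop_control": p_control[idx - 1],
                    "prop_treated": p_treated[idx - 1],
                    "is_target": is_target,
                    "length_change_sign": lc_sign,
                    "protein_log2_effect": (
                        -lc_sign * config.protein_slope if is_target else 0.0
                    ),
                    "gene_weight": weight,
                }
            )
        if is_target:
            distal_pos = distal_first[0]
            o = config.motif_offset
            if strand == "+":
                motif_plants.append((contig, distal_pos - o - len(_MOTIF_BLOCK), "+"))
            else:
                motif_plants.append((contig, distal_pos + o + 1, "-"))

    genome: dict[str, str] = {}
    for contig in sorted(cursor):
        clen = cursor[contig] - _GENE_GAP + _CONTIG_MARGIN
        seq = rng.choice(np.array(list("ACGT")), size=clen)
        seq = _deplete_ugua(seq, rng)
        genome[contig] = "".join(seq)
    # '-'-strand plants are the reverse complement in genome space
    for contig, bstart, strand in motif_plants:
        block = _MOTIF_BLOCK if strand == "+" else revcomp(_MOTIF_BLOCK)
        s = genome[contig]
        genome[contig] = s[:bstart] + block + s[bstart + len(block) :]

    truth = pd.DataFrame(truth_rows)

    return SimReference(
        genome=genome,
        gene_models=pd.DataFrame(model_rows),
        pas_annotation=pd.DataFrame(annot_rows),
        truth=truth,
    )


def simulate_site_counts(truth: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Draw the gene x site x sample count table.

    Gene totals are negative binomial (mild dispersion) around
    ``depth_per_sample * gene_weight``; within-gene site splits are
    Dirichlet-multinomial with the condition's true proportions at the
    configured precision.
    """
    if config.precision <= 0:
        raise ValueError("precision must be positive")
    rng = _streams(config)["counts"]
    design = config.design()
    samples = design["sample"].tolist()
    conditions = design["condition"].tolist()

    rows = []
    disp = config.gene_dispersion
    r = 1.0 / disp
    for gene, sub in truth.groupby("gene_id", sort=True):
        sub = sub.sort_values("site_index")
        props = {
            CONTROL: sub["prop_control"].to_numpy(),
            TREATED: sub["prop_treated"].to_numpy(),
        }
        mu = config.depth_per_sample * sub["gene_weight"].iloc[0]
        counts = np.zeros((len(sub), len(samples)), dtype=int)
        for j, (sample, cond) in enumerate(zip(samples, conditions)):
            total = rng.negative_binomial(r, r / (r + mu))
            p = props[cond]
            if config.precision > 1e7:  # multinomial limit
                split = rng.multinomial(total, p)
            else:
                split = rng.multinomial(total, rng.dirichlet(config.precision * p))
            counts[:, j] = split
        for i, (_, site) in enumerate(sub.iterrows()):
            rows.append(
                {
                    "gene_id": gene,
                    "site_index": site["site_index"],
                    "contig": site["contig"],
                    "position": site["position"],
                    "strand": site["strand"],
                    **{s: int(counts[i, j]) for j, s in enumerate(samples)},
                }
            )
    return pd.DataFrame(rows)


def _jitter(rng: np.random.Generator, n: int, scale: float) -> np.ndarray:
    """Discretized symmetric Laplace truncated at +/- 7 nt."""
    if scale == 0 or n == 0:
        return np.zeros(n, dtype=int)
    ks = np.arange(-_JITTER_MAX, _JITTER_MAX + 1)
    w = np.exp(-np.abs(ks) / scale)
    return rng.choice(ks, size=n, p=w / w.sum())


def simulate_read_ends(
    counts: pd.DataFrame, truth: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """Expand the count table into one cleavage-event record per read."""
    rng = _streams(config)["reads"]
    samples = config.samples()
    recs = []
    for _, row in counts.iterrows():
        for sample in samples:
            c = int(row[sample])
            if c == 0:
                continue
            jit = _jitter(rng, c, config.jitter_scale)
            for dj in jit:
                recs.append(
                    (
                        row["contig"],
                        int(row["position"]) + int(dj),
                        row["strand"],
                        sample,
                        row["gene_id"],
                        int(row["site_index"]),
                    )
                )
    return pd.DataFrame(
        recs,
        columns=["contig", "position", "strand", "sample_id", "gene_id", "site_index"],
    )


def simulate_proteome(truth: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Linear-scale intensity table (NaN = missing) with MNAR missingness.

    log2 intensity = baseline + condition * protein effect + noise; each value
    goes missing with probability logistic(-steepness * (value - midpoint)).
    """
    rng = _streams(config)["proteome"]
    design = config.design()
    genes = truth.drop_duplicates("gene_id").set_index("gene_id")
    samples = design["sample"].tolist()
    treated = (design["condition"] == TREATED).to_numpy()

    rows = {}
    for gene, row in genes.iterrows():
        baseline = rng.normal(18.0, 2.0)
        effect = row["protein_log2_effect"]
        log2 = (
            baseline
            + treated * effect
            + rng.normal(0.0, config.protein_noise_sd, size=len(samples))
        )
        z = config.missingness_steepness * (log2 - config.missingness_midpoint)
        p_miss = 1.0 / (1.0 + np.exp(z))
        missing = rng.random(len(samples)) < p_miss
        vals = np.power(2.0, log2)
        vals[missing] = np.nan
        rows[gene] = vals
    table = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    table.index.name = "gene_id"
    return table


def simulate_all(config: SimConfig) -> SimResult:
    """Run every generator stage from one config."""
    ref = simulate_reference(config)
    counts = simulate_site_counts(ref.truth, config)
    events = simulate_read_ends(counts, ref.truth, config)
    proteome = simulate_proteome(ref.truth, config)
    return SimResult(
        config=config,
        reference=ref,
        counts=counts,
        events=events,
        proteome=proteome,
        design=config.design(),
    )


def events_to_bed6(events: pd.DataFrame, sample: str) -> pd.DataFrame:
    sub = events[events["sample_id"] == sample]
    return pd.DataFrame(
        {
            "contig": sub["contig"],
            "start": sub["position"],
            "end": sub["position"] + 1,
            "name": sub["gene_id"] + "|" + sub["site_index"].astype(str),
            "score": 0,
            "strand": sub["strand"],
        }
    )


def events_to_sam(
    events: pd.DataFrame, genome: dict[str, "str | int"], read_length: int = 50
) -> str:
    """Render events as a text SAM whose alignments end at each event position.

    ``genome`` maps contig name to its sequence or its length.

    '+' reads span [pos - L + 1, pos + 1); '-' reads span [pos, pos + L).
    Sequences are omitted ('*'): only coordinates matter downstream.
    """
    lines = ["@HD\tVN:1.6\tSO:unknown"]
    for contig in sorted(genome):
        ref = genome[contig]
        length = ref if isinstance(ref, int) else len(ref)
        lines.append(f"@SQ\tSN:{contig}\tLN:{length}")
    for i, row in enumerate(events.itertuples(index=False)):
        if row.strand == "+":
            pos1 = row.position - read_length + 2  # SAM is 1-based
            flag = 0
        else:
            pos1 = row.position + 1
            flag = 16
        lines.append(
            "\t".join(
                [
                    f"read{i}:{row.sample_id}",
                    str(flag),
                    row.contig,
                    str(pos1),
                    "60",
                    f"{read_length}M",
                    "*",
                    "0",
                    "0",
                    "*",
                    "*",
                ]
            )
        )
    return "\n".join(lines) + "\n"


def write_outputs(result: SimResult, outdir) -> None:
    """Write every artifact as plain text (FASTA/BED/TSV)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ref = result.reference
    write_fasta(out / "genome.fa", ref.genome)
    write_bed12(out / "gene_models.bed", ref.gene_models)
    write_bed6(out / "pas_annotation.bed", ref.pas_annotation)
    ref.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    result.counts.to_csv(out / "site_counts.tsv", sep="\t", index=False)
    result.design.to_csv(out / "design.tsv", sep="\t", index=False)
    result.proteome.to_csv(out / "proteome.tsv", sep="\t")
    for sample in result.config.samples():
        write_bed6(out / f"reads_{sample}.bed", events_to_bed6(result.events, sample))
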