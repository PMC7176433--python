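"""Shared helpers: design handling, BH adjustment, sequence utilities, I/O."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

CONTROL = "control"
TREATED = "treated"

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be finite and in [0, 1]")
    return stats.false_discovery_control(p, method="bh")


def check_design(design: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample->condition design table.

    Requires columns ``sample`` and ``condition``, each sample assigned to
    exactly one of the two conditions ``control``/``treated``.
    """
    if not {"sample", "condition"}.issubset(design.columns):
        raise ValueError("design needs 'sample' and 'condition' columns")
    if design["sample"].duplicated().any():
        raise ValueError("duplicate sample in design")
    bad = set(design["condition"]) - {CONTROL, TREATED}
    if bad:
        raise ValueError(f"unknown conditions {sorted(bad)!r}")
    return design


def condition_samples(design: pd.DataFrame, condition: str) -> list[str]:
    return design.loc[design["condition"] == condition, "sample"].tolist()


def sample_columns(design: pd.DataFrame) -> list[str]:
    return design["sample"].tolist()


def write_fasta(path, records: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed6(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=range(6),
        names=["contig", "start", "end", "name", "score", "strand"],
        dtype={"contig": str, "start": int, "end": int, "name": str, "strand": str},
    )
    return df


def write_bed6(path, df: pd.DataFrame) -> None:
    df[["contig", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


BED12_COLUMNS = [
    "contig",
    "start",
    "end",
    "name",
    "score",
    "strand",
    "thick_start",
    "thick_end",
    "item_rgb",
    "block_count",
    "block_sizes",
    "block_starts",
]


def read_bed12(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, names=BED12_COLUMNS, dtype={"contig": str, "strand": str}
    )


def write_bed12(path, df: pd.DataFrame) -> None:
    df[BED12_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def gof_chi2(observed, expected=None) -> tuple[float, int, float]:
    """Goodness-of-fit chi-square of ``observed`` counts against ``expected``
    (equal split by default). Returns (chi2, df, two-tailed p)."""
    obs = np.asarray(observed, dtype=float)
    if expected is None:
        expected = np.full(obs.shape, obs.sum() / obs.size)
    exp = np.asarray(expected, dtype=float)
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    df = obs.size - 1
    return chi2, df, float(stats.chi2.sf(chi2, df))
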