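"""Small reporting utilities: volcano-style tables and PCA coordinates for
sample-separation checks."""

from __future__ import annotations

import numpy as np
import pandas as pd


def pca_coordinates(
    matrix: pd.DataFrame, samples: list[str], n_components: int = 2, log: bool = True
) -> pd.DataFrame:
    """Principal-component coordinates of the samples (columns).

    ``matrix`` is features x samples; counts are log2(x+1)-transformed by
    default, features centred, components from the SVD of the feature x
    sample matrix.
    """
    x = matrix[samples].to_numpy(dtype=float)
    if log:
        x = np.log2(x + 1.0)
    x = x - x.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, vt.shape[0])
    coords = (vt[:k].T * s[:k]).astype(float)
    var = s**2 / np.sum(s**2) if np.sum(s**2) > 0 else np.zeros_like(s)
    out = pd.DataFrame(
        coords, columns=[f"PC{i + 1}" for i in range(k)], index=samples
    )
    out.attrs["explained_variance_ratio"] = var[:k]
    out.index.name = "sample"
    return out


def volcano_table(apa_with_length: pd.DataFrame) -> pd.DataFrame:
    """Length change vs -log10 adjusted p, with shortened/lengthened calls."""
    out = apa_with_length.copy()
    with np.errstate(divide="ignore"):
        out["neg_log10_padj"] = -np.log10(out["adj_pvalue"])
    sig = out["adj_pvalue"] < 0.05
    out["call"] = "ns"
    out.loc[sig & (out["length_change"] < 0), "call"] = "shortened"
    out.loc[sig & (out["length_change"] > 0), "call"] = "lengthened"
    return out
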