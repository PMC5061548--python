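"""Expression-table transforms and expressed-gene calls.

FPKM values are converted to transcripts per million (TPM) by
``TPM_i = FPKM_i / sum(FPKM) * 1e6``; genes with TPM >= 2 (inclusive) are
called expressed. Unique-read counts per paralog come from the read
assignments produced by :mod:`retroexpand.copy_number`.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

Vector = Union[Sequence[float], np.ndarray, pd.Series, Mapping[str, float]]

EXPRESSED_TPM_THRESHOLD = 2.0


def fpkm_to_tpm(fpkm: Vector):
    """Rescale FPKM so the values sum to one million (TPM).

    Accepts a sequence, numpy array, pandas Series, or mapping; returns the
    same flavor of container.
    """
    if isinstance(fpkm, Mapping):
        keys = list(fpkm)
        values = np.asarray([fpkm[k] for k in keys], dtype=float)
    else:
        keys = None
        values = np.asarray(pd.Series(fpkm), dtype=float)
    if values.size == 0:
        raise ValueError("empty FPKM vector")
    if (values < 0).any():
        raise ValueError("FPKM values must be >= 0")
    total = values.sum()
    if total <= 0:
        raise ValueError("all-zero FPKM vector: TPM undefined")
    tpm = values / total * 1e6
    if keys is not None:
        return dict(zip(keys, tpm))
    if isinstance(fpkm, pd.Series):
        return pd.Series(tpm, index=fpkm.index)
    return tpm


def call_expressed(tpm: Vector, threshold: float = EXPRESSED_TPM_THRESHOLD,
                   gene_ids: Optional[Iterable[str]] = None) -> set[str]:
    """Genes with TPM at or above the threshold (boundary inclusive)."""
    if isinstance(tpm, Mapping):
        items = list(tpm.items())
    elif isinstance(tpm, pd.Series):
        items = list(tpm.items())
    else:
        ids = list(gene_ids) if gene_ids is not None else [str(i) for i in range(len(tpm))]
        items = list(zip(ids, tpm))
    for _, v in items:
        if v < 0:
            raise ValueError("TPM values must be >= 0")
    return {g for g, v in items if v >= threshold}


def unique_read_counts(assignments, genes: Optional[Iterable[str]] = None) -> pd.Series:
    """Uniquely mapped reads per gene; ambiguous and unassigned reads are
    excluded."""
    counts: dict[str, int] = {g: 0 for g in (genes or [])}
    for a in assignments:
        if a.status == "unique":
            counts[a.genes[0]] = counts.get(a.genes[0], 0) + 1
    return pd.Series(counts, dtype=int).sort_index()
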