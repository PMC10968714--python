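"""Exact-match read counting and log2 reads-per-million normalization.

A trimmed small-RNA read supports a catalog signature iff the read
sequence equals the signature sequence exactly (full length,
case-insensitive, U unified to T).  Full-length equality keeps
assignment unambiguous even when one signature is a suffix of another.
Unmatched reads contribute only to the library size.

Expression values are ``log2(count / denominator * 1e6 + 1)`` with the
denominator either the total library reads (default, the TCGA
miRNA-seq convention) or the catalog-assigned total.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .classify import FragmentSignature

logger = logging.getLogger(__name__)


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _signature_lookup(catalog: list[FragmentSignature]) -> dict[str, str]:
    lookup: dict[str, str] = {}
    for sig in catalog:
        if sig.sequence in lookup:
            raise ValueError(f"catalog sequences not unique: {sig.sequence}")
        lookup[sig.sequence] = sig.signature_id
    return lookup


def count_sample(
    fastq_path: str | Path, catalog: list[FragmentSignature]
) -> tuple[dict[str, int], int]:
    """Count exact full-length read support per signature in one FASTQ.

    Returns ``(counts, library_size)`` where ``library_size`` is the total
    number of reads in the file.
    """
    lookup = _signature_lookup(catalog)
    counts = {sig.signature_id: 0 for sig in catalog}
    library_size = 0
    with _open_text(fastq_path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            library_size += 1
            seq = str(rec.seq).upper().replace("U", "T")
            sig_id = lookup.get(seq)
            if sig_id is not None:
                counts[sig_id] += 1
    if library_size == 0:
        logger.warning("%s: empty FASTQ, all counts zero", fastq_path)
    return counts, library_size


def count_samples(
    fastq_paths: dict[str, str | Path], catalog: list[FragmentSignature]
) -> tuple[pd.DataFrame, pd.Series]:
    """Count every sample; returns (signatures x samples counts, library sizes)."""
    cols = {}
    sizes = {}
    for sample, path in fastq_paths.items():
        counts, lib = count_sample(path, catalog)
        cols[sample] = counts
        sizes[sample] = lib
    counts_df = pd.DataFrame(cols).astype(int)
    counts_df.index.name = "signature_id"
    return counts_df, pd.Series(sizes, name="library_size")


def normalize(
    counts: pd.DataFrame,
    library_sizes: pd.Series | None = None,
    denominator_mode: str = "library",
) -> pd.DataFrame:
    """log2(per-million + 1) expression from raw counts.

    ``denominator_mode='library'`` divides by the FASTQ read total;
    ``'assigned'`` divides by the catalog-assigned total so per-million
    values sum to 1e6 within each sample.  Samples with a zero
    denominator are excluded with a warning.
    """
    if denominator_mode == "assigned":
        denom = counts.sum(axis=0).astype(float)
    elif denominator_mode == "library":
        if library_sizes is None:
            raise ValueError("library mode requires library_sizes")
        denom = library_sizes.reindex(counts.columns).astype(float)
    else:
        raise ValueError(f"unknown denominator_mode {denominator_mode!r}")

    keep = denom > 0
    if not keep.all():
        excluded = list(denom.index[~keep])
        logger.warning("samples excluded for zero denominator: %s", excluded)
    counts = counts.loc[:, keep[keep].index]
    denom = denom[keep]
    return np.log2(counts.div(denom, axis=1) * 1e6 + 1.0)


def detection_filter(
    expr: pd.DataFrame,
    counts: pd.DataFrame,
    min_detect_fraction: float = 0.5,
) -> tuple[pd.DataFrame, dict]:
    """Keep signatures detected (count > 0) in >= a fraction of samples.

    Returns the filtered expression matrix and a report of kept/dropped
    totals (class/chromosome composition is layered on by the caller
    from the catalog table).
    """
    counts = counts.reindex(index=expr.index, columns=expr.columns)
    frac = (counts > 0).mean(axis=1)
    kept = frac[frac >= min_detect_fraction].index
    report = {
        "min_detect_fraction": min_detect_fraction,
        "n_input": int(expr.shape[0]),
        "n_kept": int(len(kept)),
        "n_dropped": int(expr.shape[0] - len(kept)),
        "kept_ids": list(map(str, kept)),
    }
    return expr.loc[kept], report
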