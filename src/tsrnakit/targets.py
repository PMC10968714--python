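"""miRNA-like tRF target-site prediction in 3'UTR sequences.

tRNA fragments loaded into Argonaute can repress mRNAs through seed
pairing just like microRNAs.  This module scans 3'UTRs for canonical
seed sites of a tRF (seed = fragment positions 2-8, 5'->3') and scores
the surrounding duplex with a simple local anti-parallel
complementarity alignment.  It is a deliberately transparent scorer —
no thermodynamics — so the prediction stage is fully testable.

Site taxonomy (standard miRNA convention, UTR coordinates 1-based
inclusive on the given strand):

* ``6mer``     — UTR reverse-complements tRF positions 2-7;
* ``7mer-m8``  — 6mer extended by a match to position 8;
* ``7mer-A1``  — 6mer plus an ``A`` in the UTR opposite position 1;
* ``8mer``     — both the m8 match and the A1 anchor.

Each site is reported once at its best type (8mer > 7mer-m8 > 7mer-A1 >
6mer).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .reference import revcomp

logger = logging.getLogger(__name__)

MATCH_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
_WC = {"A": "T", "T": "A", "C": "G", "G": "C"}
_WOBBLE = {("G", "T"), ("T", "G")}

WC_SCORE = 1.0
WOBBLE_SCORE = 0.5
MISMATCH_SCORE = -1.0
GAP_OPEN = -2.0
GAP_EXTEND = -1.0


class TargetScanError(ValueError):
    pass


@dataclass(frozen=True)
class SeedMatch:
    utr_gene: str
    site_start: int  # 1-based inclusive on the UTR
    site_end: int
    match_type: str


@dataclass
class TargetPrediction:
    trf_id: str
    utr_gene: str
    seed_matches: list[SeedMatch]
    best_score: float
    best_alignment: str
    pass_threshold: bool


def _clean(seq: str, what: str) -> str:
    seq = seq.strip().upper().replace("U", "T")
    if not seq:
        raise TargetScanError(f"empty {what} sequence")
    bad = set(seq) - set("ACGT")
    if bad:
        raise TargetScanError(f"non-DNA characters in {what}: {sorted(bad)}")
    return seq


def find_seed_sites(
    trf_sequence: str, utr_sequence: str, utr_gene: str = "utr"
) -> list[SeedMatch]:
    """All canonical seed sites of a tRF in one UTR.

    The core match is the UTR occurrence of the reverse complement of
    seed positions 2-7; the m8 extension and the A1 anchor upgrade the
    site type.  Overlapping occurrences are all reported.
    """
    trf = _clean(trf_sequence, "tRF")
    utr = _clean(utr_sequence, "UTR")
    if len(trf) < 8:
        raise TargetScanError("tRF must be >= 8 nt for seed matching")

    core = revcomp(trf[1:7])       # pairs tRF positions 2-7
    m8_base = _WC[trf[7]]          # UTR base pairing tRF position 8
    sites: list[SeedMatch] = []
    pos = utr.find(core)
    while pos != -1:
        s = pos + 1                # 1-based start of the 6mer core
        e6 = s + 5
        has_m8 = s >= 2 and utr[s - 2] == m8_base
        has_a1 = e6 < len(utr) and utr[e6] == "A"
        if has_m8 and has_a1:
            sites.append(SeedMatch(utr_gene, s - 1, e6 + 1, "8mer"))
        elif has_m8:
            sites.append(SeedMatch(utr_gene, s - 1, e6, "7mer-m8"))
        elif has_a1:
            sites.append(SeedMatch(utr_gene, s, e6 + 1, "7mer-A1"))
        else:
            sites.append(SeedMatch(utr_gene, s, e6, "6mer"))
        pos = utr.find(core, pos + 1)
    return sites


def _pair_score(a: str, b: str) -> float:
    if _WC[a] == b:
        return WC_SCORE
    if (a, b) in _WOBBLE:
        return WOBBLE_SCORE
    return MISMATCH_SCORE


def duplex_score(trf_sequence: str, utr_window: str) -> tuple[float, str]:
    """Best local anti-parallel complementarity between tRF and a UTR window.

    Smith-Waterman with affine gaps over pairing scores (Watson-Crick
    +1, G:U wobble +0.5, mismatch -1, gap open/extend -2/-1).  Returns
    the maximum score (floored at 0) and a three-line alignment text.
    """
    a = _clean(trf_sequence, "tRF")
    b_fwd = _clean(utr_window, "UTR window")
    if len(b_fwd) > 60:
        raise TargetScanError("UTR window longer than 60 nt")
    b = b_fwd[::-1]  # anti-parallel: walk the UTR 3'->5'
    n, m = len(a), len(b)
    NEG = -1e18
    # H: pair state, Ea: gap in UTR (consume tRF), Eb: gap in tRF
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ea = [[NEG] * (m + 1) for _ in range(n + 1)]
    Eb = [[NEG] * (m + 1) for _ in range(n + 1)]
    best, best_ij = 0.0, None
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            Ea[i][j] = max(H[i - 1][j] + GAP_OPEN, Ea[i - 1][j] + GAP_EXTEND)
            Eb[i][j] = max(H[i][j - 1] + GAP_OPEN, Eb[i][j - 1] + GAP_EXTEND)
            diag = max(H[i - 1][j - 1], Ea[i - 1][j - 1], Eb[i - 1][j - 1])
            h = max(0.0, diag + _pair_score(a[i - 1], b[j - 1]), Ea[i][j], Eb[i][j])
            H[i][j] = h
            if h > best:
                best, best_ij = h, (i, j)

    if best_ij is None:
        return 0.0, "(no favorable duplex)"

    # greedy traceback through the pair state
    i, j = best_ij
    top, mid, bot = [], [], []
    while i > 0 and j > 0 and H[i][j] > 0:
        sc = _pair_score(a[i - 1], b[j - 1])
        diag = max(H[i - 1][j - 1], Ea[i - 1][j - 1], Eb[i - 1][j - 1])
        if abs(H[i][j] - (diag + sc)) < 1e-9 and H[i][j] > 0:
            top.append(a[i - 1])
            bot.append(b[j - 1])
            mid.append("|" if _pair_score(a[i - 1], b[j - 1]) == WC_SCORE
                       else (":" if sc == WOBBLE_SCORE else " "))
            i, j = i - 1, j - 1
        elif abs(H[i][j] - Ea[i][j]) < 1e-9:
            top.append(a[i - 1]); mid.append(" "); bot.append("-")
            i -= 1
        else:
            top.append("-"); mid.append(" "); bot.append(b[j - 1])
            j -= 1
    aln = (
        "tRF 5'-" + "".join(reversed(top)) + "-3'\n"
        "       " + "".join(reversed(mid)) + "\n"
        "UTR 3'-" + "".join(reversed(bot)) + "-5'"
    )
    return best, aln


def _site_window(utr: str, site: SeedMatch, flank: int = 30, max_len: int = 60) -> str:
    lo = max(1, site.site_start - flank)
    hi = min(len(utr), site.site_end + flank)
    window = utr[lo - 1 : hi]
    if len(window) > max_len:
        # trim symmetrically around the site center
        center = (site.site_start + site.site_end) // 2 - lo
        half = max_len // 2
        start = min(max(0, center - half), len(window) - max_len)
        window = window[start : start + max_len]
    return window


def predict_targets(
    trf_sequence: str,
    utrs: "dict[str, str] | str | Path",
    trf_id: str = "trf",
    score_threshold: float | None = None,
    flank: int = 30,
) -> list[TargetPrediction]:
    """Scan a set of 3'UTRs for seed sites plus duplex support.

    ``utrs`` is a FASTA path or a mapping gene -> UTR sequence.  A UTR
    passes when it has at least one seed site and its best duplex score
    over windows around the sites reaches the threshold (default: half
    the tRF length).
    """
    trf = _clean(trf_sequence, "tRF")
    if score_threshold is None:
        score_threshold = 0.5 * len(trf)
    if isinstance(utrs, (str, Path)):
        utrs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(utrs), "fasta")}

    predictions: list[TargetPrediction] = []
    for gene, utr_seq in utrs.items():
        utr = _clean(utr_seq, "UTR")
        sites = find_seed_sites(trf, utr, gene)
        best, best_aln = 0.0, ""
        for site in sites:
            score, aln = duplex_score(trf, _site_window(utr, site, flank))
            if score > best:
                best, best_aln = score, aln
        predictions.append(
            TargetPrediction(
                trf_id=trf_id,
                utr_gene=gene,
                seed_matches=sites,
                best_score=best,
                best_alignment=best_aln,
                pass_threshold=bool(sites) and best >= score_threshold,
            )
        )
    return predictions


def predictions_to_frame(predictions: list[TargetPrediction]) -> pd.DataFrame:
    rows = []
    for pred in predictions:
        rows.append(
            {
                "trf_id": pred.trf_id,
                "utr_gene": pred.utr_gene,
                "n_sites": len(pred.seed_matches),
                "sites": ";".join(
                    f"{s.site_start}-{s.site_end}:{s.match_type}"
                    for s in pred.seed_matches
                ),
                "best_score": pred.best_score,
                "pass": pred.pass_threshold,
            }
        )
    return pd.DataFrame(rows)


def edge_list(predictions: list[TargetPrediction]) -> pd.DataFrame:
    """tRF -> gene edges for passing predictions (network export)."""
    return pd.DataFrame(
        [
            {"trf": p.trf_id, "gene": p.utr_gene, "score": p.best_score}
            for p in predictions
            if p.pass_threshold
        ]
    )
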