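"""Exact-match fragment placement, tRF classification and tDR naming.

A candidate fragment (16-35 nt) is placed by exhaustive exact substring
search into every mature, trailer and leader sequence of the reference.
Placements determine the class:

* mature space: start at the 5' end (tolerance 1, or 2 for His genes
  whose G-1 is post-transcriptional) with the 3' end short of the mature
  terminus -> ``5p_trf``; end exactly at the mature terminus (CCA
  inclusive) -> ``3p_trf``; anything else -> ``i_trf``;
* trailer space: start at trailer position 1 (immediately after the
  mature 3' end) -> ``trf1``;
* leader space: end at the leader's last base (abutting the mature
  start) -> ``5pU_trf``.

When placements disagree, the class of highest precedence wins
(mature 3p > 5p > i, then trailer, then leader) and conflicting
placements are dropped with a log message.  5' fragments of >= 30 nt
are flagged as 5' halves (tiRNAs); when the anticodon position is
annotated, ending within [anticodon_start - 2, anticodon_start + 4]
overrides the length heuristic.

Names follow the tDRnamer convention ``tDR-<start>:<end>-<Isotype>-
<Anticodon>-<family>[-M<k>]`` where the span is mature 1-based inclusive
and ``k >= 2`` counts distinct mature sequences containing the fragment.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .reference import DNA_ALPHABET, ReferenceBundle

logger = logging.getLogger(__name__)

MIN_FRAGMENT_LEN = 16
MAX_FRAGMENT_LEN = 35
HALF_LENGTH_THRESHOLD = 30

CLASS_5P = "5p_trf"
CLASS_3P = "3p_trf"
CLASS_I = "i_trf"
CLASS_5PU = "5pU_trf"
CLASS_TRF1 = "trf1"
UNCLASSIFIED = "unclassified"

# mature identity is biologically primary; smaller = higher precedence
_PRECEDENCE = {CLASS_3P: 0, CLASS_5P: 1, CLASS_I: 2, CLASS_TRF1: 3, CLASS_5PU: 4}


class ClassificationError(ValueError):
    pass


class TDRParseError(ValueError):
    pass


@dataclass(frozen=True)
class Placement:
    """An exact occurrence of a fragment within one region's sequence."""

    gene_id: str
    region: str  # mature | leader | trailer
    start: int  # 1-based inclusive
    end: int


@dataclass
class FragmentSignature:
    signature_id: str
    sequence: str
    trf_class: str
    placements: tuple[Placement, ...]
    multimap_count: int
    is_5p_half: bool


@dataclass(frozen=True)
class TDRName:
    start: int
    end: int
    isotype: str
    anticodon: str
    family_index: int
    multimap_count: int = 1

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise TDRParseError(f"span start {self.start} > end {self.end}")

    def __str__(self) -> str:
        base = (
            f"tDR-{self.start}:{self.end}-{self.isotype}-"
            f"{self.anticodon}-{self.family_index}"
        )
        if self.multimap_count >= 2:
            base += f"-M{self.multimap_count}"
        return base


_TDR_RE = re.compile(
    r"^tDR-(?P<start>\d+):(?P<end>\d+)-(?P<isotype>[A-Za-z]{3})-"
    r"(?P<anticodon>[ACGTUacgtu]{3})-(?P<family>\d+)(?:-M(?P<mm>\d+))?$"
)


def parse_tdr_id(text: str) -> TDRName:
    """Parse a tDRnamer-style identifier, e.g. ``tDR-60:76-His-GTG-1-M2``."""
    m = _TDR_RE.match(text)
    if m is None:
        # report the first position where the grammar breaks
        prefix = "tDR-"
        pos = 0
        while pos < min(len(text), len(prefix)) and text[pos] == prefix[pos]:
            pos += 1
        raise TDRParseError(f"malformed tDR id {text!r} (near position {pos})")
    return TDRName(
        start=int(m["start"]),
        end=int(m["end"]),
        isotype=m["isotype"],
        anticodon=m["anticodon"].upper().replace("U", "T"),
        family_index=int(m["family"]),
        multimap_count=int(m["mm"]) if m["mm"] else 1,
    )


def _find_all(haystack: str, needle: str) -> list[int]:
    """All 1-based start positions of (possibly overlapping) occurrences."""
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i + 1)
        i = haystack.find(needle, i + 1)
    return out


def _placement_class(
    p: Placement, bundle: ReferenceBundle, start_tolerance: int, his_tolerance: int
) -> str:
    region_len = len(bundle.region_sequence(p.gene_id, p.region))
    if p.region == "mature":
        if p.end == region_len:
            return CLASS_3P
        tol = his_tolerance if bundle.genes[p.gene_id].isotype == "His" else start_tolerance
        if p.start <= tol:
            return CLASS_5P
        return CLASS_I
    if p.region == "trailer":
        return CLASS_TRF1 if p.start == 1 else UNCLASSIFIED
    if p.region == "leader":
        return CLASS_5PU if p.end == region_len else UNCLASSIFIED
    raise KeyError(p.region)


def classify_fragment(
    sequence: str,
    bundle: ReferenceBundle,
    signature_id: str | None = None,
    min_len: int = MIN_FRAGMENT_LEN,
    max_len: int = MAX_FRAGMENT_LEN,
    start_tolerance: int = 1,
    his_start_tolerance: int = 2,
) -> FragmentSignature:
    """Place a fragment in all reference spaces and assign its tRF class."""
    seq = sequence.strip().upper().replace("U", "T")
    if not seq:
        raise ClassificationError("empty fragment sequence")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ClassificationError(f"non-DNA characters in fragment: {sorted(bad)}")
    sig_id = signature_id if signature_id is not None else seq

    if not (min_len <= len(seq) <= max_len):
        return FragmentSignature(sig_id, seq, UNCLASSIFIED, (), 0, False)

    placements: list[Placement] = []
    for gid in bundle.gene_ids():
        for region in ("mature", "trailer", "leader"):
            hay = bundle.region_sequence(gid, region)
            for start in _find_all(hay, seq):
                placements.append(Placement(gid, region, start, start + len(seq) - 1))

    classed = [
        (p, _placement_class(p, bundle, start_tolerance, his_start_tolerance))
        for p in placements
    ]
    usable = [(p, c) for p, c in classed if c != UNCLASSIFIED]
    if not usable:
        return FragmentSignature(sig_id, seq, UNCLASSIFIED, tuple(placements), 0, False)

    best = min(_PRECEDENCE[c] for _, c in usable)
    trf_class = next(c for c in _PRECEDENCE if _PRECEDENCE[c] == best)
    kept = tuple(p for p, c in usable if c == trf_class)
    dropped = len(placements) - len(kept)
    if dropped:
        logger.info(
            "%s: retained %d %s placement(s), dropped %d conflicting",
            sig_id, len(kept), trf_class, dropped,
        )

    if trf_class in (CLASS_3P, CLASS_5P, CLASS_I):
        multimap = len({bundle.matures[p.gene_id].sequence for p in kept})
    else:
        multimap = len({p.gene_id for p in kept})

    is_half = False
    if trf_class == CLASS_5P:
        is_half = len(seq) >= HALF_LENGTH_THRESHOLD
        annotated = [
            (p, bundle.anticodon_mature_start(p.gene_id)) for p in kept
        ]
        annotated = [(p, a) for p, a in annotated if a is not None]
        if annotated:
            is_half = any(a - 2 <= p.end <= a + 4 for p, a in annotated)

    return FragmentSignature(sig_id, seq, trf_class, kept, multimap, is_half)


def name_fragment(sig: FragmentSignature, bundle: ReferenceBundle) -> TDRName:
    """tDRnamer-style name from the fragment's mature placements.

    Uses the lexicographically smallest ``(gene_id, start)`` mature
    placement for the span; leader/trailer fragments have no mature span
    and raise.
    """
    mature = [p for p in sig.placements if p.region == "mature"]
    if sig.trf_class in (CLASS_TRF1, CLASS_5PU, UNCLASSIFIED) or not mature:
        raise ClassificationError(
            f"{sig.signature_id}: tDR mature-span names do not apply to "
            f"{sig.trf_class} fragments; use the signature id"
        )
    anchor = min(mature, key=lambda p: (p.gene_id, p.start))
    gene = bundle.genes[anchor.gene_id]
    multimap = len(
        {m.sequence for m in bundle.matures.values() if sig.sequence in m.sequence}
    )
    return TDRName(
        start=anchor.start,
        end=anchor.end,
        isotype=gene.isotype,
        anticodon=gene.anticodon,
        family_index=gene.family_index,
        multimap_count=multimap,
    )


def build_catalog(
    sequences: "pd.DataFrame | list[tuple[str, str]] | str | Path",
    bundle: ReferenceBundle,
    **classify_kwargs,
) -> list[FragmentSignature]:
    """Classify a set of candidate signatures (TSV path, DataFrame or pairs).

    Input sequences are deduplicated by exact sequence; the first id wins
    and the duplicate is logged.  Every input sequence is retained in the
    catalog, unclassifiable ones flagged as such.
    """
    if isinstance(sequences, (str, Path)):
        df = pd.read_csv(sequences, sep="\t")
        pairs = list(zip(df["signature_id"].astype(str), df["sequence"].astype(str)))
    elif isinstance(sequences, pd.DataFrame):
        pairs = list(
            zip(sequences["signature_id"].astype(str), sequences["sequence"].astype(str))
        )
    else:
        pairs = [(str(i), str(s)) for i, s in sequences]
    if not pairs:
        raise ClassificationError("empty signature input")

    seen: dict[str, str] = {}
    catalog: list[FragmentSignature] = []
    for sig_id, seq in pairs:
        key = seq.strip().upper().replace("U", "T")
        if key in seen:
            logger.warning(
                "duplicate sequence for %s (already cataloged as %s); skipped",
                sig_id, seen[key],
            )
            continue
        seen[key] = sig_id
        catalog.append(classify_fragment(key, bundle, sig_id, **classify_kwargs))
    return catalog


def catalog_summary(catalog: list[FragmentSignature], bundle: ReferenceBundle) -> dict:
    """Class and source-chromosome composition of a catalog."""
    by_class = Counter(sig.trf_class for sig in catalog)
    by_chrom: Counter[str] = Counter()
    for sig in catalog:
        chroms = {bundle.genes[p.gene_id].chromosome for p in sig.placements}
        for c in sorted(chroms):
            by_chrom[c] += 1
    n = len(catalog)
    return {
        "n_signatures": n,
        "by_class": dict(by_class),
        "class_proportions": {k: v / n for k, v in by_class.items()},
        "by_chromosome": dict(by_chrom),
    }


def catalog_to_frame(
    catalog: list[FragmentSignature], bundle: ReferenceBundle
) -> pd.DataFrame:
    """Flatten a catalog to the tabular interchange form."""
    rows = []
    for sig in catalog:
        try:
            tdr = str(name_fragment(sig, bundle))
        except ClassificationError:
            tdr = ""
        chroms = sorted({bundle.genes[p.gene_id].chromosome for p in sig.placements})
        rows.append(
            {
                "signature_id": sig.signature_id,
                "sequence": sig.sequence,
                "length": len(sig.sequence),
                "trf_class": sig.trf_class,
                "tdr_name": tdr,
                "multimap_count": sig.multimap_count,
                "is_5p_half": sig.is_5p_half,
                "placements": ";".join(
                    f"{p.gene_id}:{p.region}:{p.start}-{p.end}" for p in sig.placements
                ),
                "chromosome": ";".join(chroms),
            }
        )
    return pd.DataFrame(rows)
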