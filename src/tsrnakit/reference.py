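"""Mature-tRNA, 5'-leader and 3'-trailer sequence spaces.

tRNA-derived fragments are classified against three sequence spaces per
tRNA gene:

* the **mature** tRNA: the spliced gene body with the post-transcriptional
  3' ``CCA`` appended and, for histidine tRNAs, the post-transcriptional
  ``G-1`` prepended (mature position 1);
* the **5' leader**: the stretch of primary transcript immediately
  upstream of the gene (default window 50 nt), the source of 5'U-tRFs;
* the **3' trailer**: the stretch immediately downstream (default window
  35 nt), the source of tRF-1 fragments.

All coordinates are 1-based inclusive.  Mature positions that do not
exist in the genome (CCA, His G-1) map to ``None`` in the
mature-to-gene coordinate map.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

DEFAULT_LEADER_WINDOW = 50
DEFAULT_TRAILER_WINDOW = 35


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


class ReferenceError(ValueError):
    """Raised for invalid gene records or malformed reference inputs."""


@dataclass(frozen=True)
class TRNAGeneRecord:
    """A tRNA gene with its coding-strand sequence and annotation.

    ``gene_sequence`` is always stored 5'->3' on the coding strand;
    minus-strand genes are reverse-complemented on load.  ``intron_spans``
    are gene-local 1-based inclusive intervals.
    """

    gene_id: str
    isotype: str
    anticodon: str
    family_index: int
    chromosome: str
    strand: str
    genomic_start: int
    genomic_end: int
    gene_sequence: str
    intron_spans: tuple[tuple[int, int], ...] = ()
    anticodon_position: int | None = None
    leader_seq: str | None = None
    trailer_seq: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ReferenceError(f"{self.gene_id}: strand must be '+' or '-'")
        span = self.genomic_end - self.genomic_start + 1
        if span != len(self.gene_sequence):
            raise ReferenceError(
                f"{self.gene_id}: genomic span length {span} != "
                f"sequence length {len(self.gene_sequence)}"
            )
        bad = set(self.gene_sequence) - DNA_ALPHABET
        if bad:
            raise ReferenceError(
                f"{self.gene_id}: non-DNA characters in sequence: {sorted(bad)}"
            )
        prev_end = 0
        for s, e in self.intron_spans:
            if not (1 < s <= e < len(self.gene_sequence)):
                raise ReferenceError(
                    f"{self.gene_id}: intron span {s}-{e} not strictly inside gene"
                )
            if s <= prev_end:
                raise ReferenceError(
                    f"{self.gene_id}: intron spans overlap or are unsorted"
                )
            prev_end = e

    @property
    def spliced_sequence(self) -> str:
        seq = self.gene_sequence
        for s, e in reversed(self.intron_spans):
            seq = seq[: s - 1] + seq[e:]
        return seq


@dataclass(frozen=True)
class MatureTRNA:
    """Processed tRNA: spliced body, His G-1 (if any), terminal CCA.

    ``mature_to_gene[i]`` gives the gene-local 1-based position of mature
    position ``i + 1``, or ``None`` for post-transcriptional bases.
    """

    gene_id: str
    sequence: str
    has_g_minus1: bool
    mature_to_gene: tuple[int | None, ...]

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrecursorContext:
    """Leader/trailer windows of the primary transcript around a gene."""

    gene_id: str
    leader_sequence: str
    trailer_sequence: str


def build_mature(gene: TRNAGeneRecord) -> MatureTRNA:
    """Build the mature tRNA sequence and its coordinate map.

    Introns are excised, ``CCA`` is appended unconditionally (eukaryotic
    tRNA genes do not encode it) and histidine tRNAs gain a 5' ``G-1``
    that becomes mature position 1.
    """
    intronic: set[int] = set()
    for s, e in gene.intron_spans:
        intronic.update(range(s, e + 1))
    coords = [p for p in range(1, len(gene.gene_sequence) + 1) if p not in intronic]
    seq = "".join(gene.gene_sequence[p - 1] for p in coords)

    mapping: list[int | None] = list(coords)
    has_g = gene.isotype == "His"
    if has_g:
        seq = "G" + seq
        mapping = [None] + mapping
    seq = seq + "CCA"
    mapping += [None, None, None]
    return MatureTRNA(
        gene_id=gene.gene_id,
        sequence=seq,
        has_g_minus1=has_g,
        mature_to_gene=tuple(mapping),
    )


def get_precursor_context(
    gene: TRNAGeneRecord,
    genome: dict[str, str] | None = None,
    leader_window: int = DEFAULT_LEADER_WINDOW,
    trailer_window: int = DEFAULT_TRAILER_WINDOW,
) -> PrecursorContext:
    """Extract leader/trailer flanks, strand-aware.

    Explicit ``leader_seq``/``trailer_seq`` on the record take priority;
    otherwise flanks are cut from ``genome`` (a mapping chromosome ->
    plus-strand sequence).  The trailer is downstream in the direction of
    transcription, so for minus-strand genes it is the reverse complement
    of the genomic *upstream* flank.  Flanks shorter than the window are
    truncated with a warning, never padded.
    """
    if gene.leader_seq is not None or gene.trailer_seq is not None:
        leader = (gene.leader_seq or "")[-leader_window:]
        trailer = (gene.trailer_seq or "")[:trailer_window]
    elif genome is not None:
        try:
            chrom = genome[gene.chromosome]
        except KeyError:
            raise ReferenceError(
                f"{gene.gene_id}: chromosome {gene.chromosome!r} not in genome"
            ) from None
        if gene.strand == "+":
            lo = max(0, gene.genomic_start - 1 - leader_window)
            leader = chrom[lo : gene.genomic_start - 1]
            trailer = chrom[gene.genomic_end : gene.genomic_end + trailer_window]
        else:
            leader = revcomp(chrom[gene.genomic_end : gene.genomic_end + leader_window])
            lo = max(0, gene.genomic_start - 1 - trailer_window)
            trailer = revcomp(chrom[lo : gene.genomic_start - 1])
    else:
        raise ReferenceError(
            f"{gene.gene_id}: no flank sequences in metadata and no genome given"
        )
    leader = leader.upper()
    trailer = trailer.upper()
    if len(leader) < leader_window:
        logger.warning(
            "%s: leader truncated to %d nt (< window %d)",
            gene.gene_id, len(leader), leader_window,
        )
    if len(trailer) < trailer_window:
        logger.warning(
            "%s: trailer truncated to %d nt (< window %d)",
            gene.gene_id, len(trailer), trailer_window,
        )
    return PrecursorContext(gene.gene_id, leader, trailer)


def _parse_intron_spans(text: str | float | None) -> tuple[tuple[int, int], ...]:
    if text is None or (isinstance(text, float)) or not str(text).strip():
        return ()
    spans = []
    for part in str(text).split(";"):
        s, e = part.split("-")
        spans.append((int(s), int(e)))
    return tuple(spans)


def load_gene_set(fasta_path: str | Path, metadata_path: str | Path) -> list[TRNAGeneRecord]:
    """Load tRNA genes from a FASTA plus a TSV metadata table.

    The FASTA carries the plus-strand genomic sequence of each gene span;
    minus-strand genes are reverse-complemented so every stored sequence
    reads 5'->3' on the coding strand.  Every FASTA id must have exactly
    one metadata row and vice versa; duplicates are rejected.
    """
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"chromosome": str})
    if meta["gene_id"].duplicated().any():
        dups = meta.loc[meta["gene_id"].duplicated(), "gene_id"].tolist()
        raise ReferenceError(f"duplicate gene_id in metadata: {dups}")
    meta = meta.set_index("gene_id")

    records: list[TRNAGeneRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        gid = rec.id
        if gid in seen:
            raise ReferenceError(f"duplicate FASTA record: {gid}")
        seen.add(gid)
        if gid not in meta.index:
            raise ReferenceError(f"FASTA record {gid} has no metadata row")
        row = meta.loc[gid]
        seq = str(rec.seq).upper().replace("U", "T")
        strand = str(row["strand"])
        if strand == "-":
            seq = revcomp(seq)

        def _opt(col, cast=str):
            if col in row.index and pd.notna(row[col]) and str(row[col]).strip():
                return cast(row[col])
            return None

        records.append(
            TRNAGeneRecord(
                gene_id=gid,
                isotype=str(row["isotype"]),
                anticodon=str(row["anticodon"]).upper().replace("U", "T"),
                family_index=int(row["family_index"]),
                chromosome=str(row["chromosome"]),
                strand=strand,
                genomic_start=int(row["genomic_start"]),
                genomic_end=int(row["genomic_end"]),
                gene_sequence=seq,
                intron_spans=_parse_intron_spans(_opt("intron_spans")),
                anticodon_position=_opt("anticodon_position", int),
                leader_seq=_opt("leader_seq"),
                trailer_seq=_opt("trailer_seq"),
            )
        )
    missing = set(meta.index) - seen
    if missing:
        raise ReferenceError(f"metadata rows with no FASTA record: {sorted(missing)}")
    if not records:
        raise ReferenceError("empty gene set")
    return records


@dataclass
class ReferenceBundle:
    """Per-gene mature/leader/trailer spaces fragments are placed into."""

    genes: dict[str, TRNAGeneRecord]
    matures: dict[str, MatureTRNA]
    contexts: dict[str, PrecursorContext]
    leader_window: int = DEFAULT_LEADER_WINDOW
    trailer_window: int = DEFAULT_TRAILER_WINDOW

    def gene_ids(self) -> list[str]:
        return sorted(self.genes)

    def region_sequence(self, gene_id: str, region: str) -> str:
        if region == "mature":
            return self.matures[gene_id].sequence
        if region == "leader":
            return self.contexts[gene_id].leader_sequence
        if region == "trailer":
            return self.contexts[gene_id].trailer_sequence
        raise KeyError(region)

    def anticodon_mature_start(self, gene_id: str) -> int | None:
        """Mature 1-based position of the anticodon's first base, if annotated."""
        gene = self.genes[gene_id]
        if gene.anticodon_position is None:
            return None
        mature = self.matures[gene_id]
        for i, gpos in enumerate(mature.mature_to_gene):
            if gpos == gene.anticodon_position:
                return i + 1
        return None

    def save(self, outdir: str | Path) -> None:
        """Serialize as FASTA (mature/leader/trailer, suffixed ids) + JSON manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "reference.fasta", "w") as fh:
            for gid in self.gene_ids():
                for region in ("mature", "leader", "trailer"):
                    seq = self.region_sequence(gid, region)
                    if seq:
                        fh.write(f">{gid}|{region}\n{seq}\n")
        manifest = {
            "leader_window": self.leader_window,
            "trailer_window": self.trailer_window,
            "genes": {
                gid: {
                    "isotype": g.isotype,
                    "anticodon": g.anticodon,
                    "family_index": g.family_index,
                    "chromosome": g.chromosome,
                    "strand": g.strand,
                    "genomic_start": g.genomic_start,
                    "genomic_end": g.genomic_end,
                    "mature_length": self.matures[gid].length,
                    "has_g_minus1": self.matures[gid].has_g_minus1,
                    "anticodon_position": g.anticodon_position,
                }
                for gid, g in self.genes.items()
            },
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)


def build_reference(
    genes: list[TRNAGeneRecord],
    genome: dict[str, str] | None = None,
    leader_window: int = DEFAULT_LEADER_WINDOW,
    trailer_window: int = DEFAULT_TRAILER_WINDOW,
) -> ReferenceBundle:
    """Assemble the classification reference from loaded gene records."""
    matures = {g.gene_id: build_mature(g) for g in genes}
    contexts = {
        g.gene_id: get_precursor_context(g, genome, leader_window, trailer_window)
        for g in genes
    }
    return ReferenceBundle(
        genes={g.gene_id: g for g in genes},
        matures=matures,
        contexts=contexts,
        leader_window=leader_window,
        trailer_window=trailer_window,
    )
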