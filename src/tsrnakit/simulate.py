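"""Seeded generators for every input the pipeline consumes.

These emulate the statistical structure of a tumor/normal small-RNA
cohort so that every stage — reference building, classification,
counting, differential expression, survival, correlation, enrichment
and target scanning — can be exercised and validated by parameter
recovery without any external download:

* tRNA-like genes (70-90 nt) with isotype/anticodon metadata and
  explicit leader/trailer flanks; at least one His-GTG family with two
  isodecoders sharing their 3' end, so 3' fragments multimap (``-M2``);
* fragment signatures engineered per class (5p/3p/i/trf1/5pU);
* negative-binomial counts with planted tumor-vs-normal fold changes;
* exponential survival with an expression-dependent hazard and
  independent uniform censoring;
* categorical pathology covariates associated with the biomarker;
* an mRNA matrix with planted Spearman correlation to the biomarker via
  a Gaussian copula;
* FASTQ reads drawn from signature sequences (optional per-base
  substitution error) plus background reads matching no signature.

Group sizes default to 16 tumor vs 9 normal, the scale of a paired
TCGA-style tumor/control comparison.  Every generator is deterministic
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import FragmentSignature, build_catalog
from .reference import ReferenceBundle, TRNAGeneRecord, build_reference

_BASES = np.array(list("ACGT"))

ISOTYPE_ANTICODONS = {
    "His": "GTG", "Gly": "GCC", "Glu": "CTC", "Lys": "CTT",
    "Val": "CAC", "Cys": "GCA", "Asp": "GTC", "Leu": "CAG",
}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with cohort-realistic defaults."""

    seed: int = 0
    # reference
    n_genes: int = 8
    isotypes: tuple[str, ...] = ("His", "Gly", "Glu", "Lys", "Val", "Cys", "Asp", "Leu")
    gene_length_range: tuple[int, int] = (70, 90)
    leader_window: int = 50
    trailer_window: int = 35
    # signatures per class
    n_per_class: dict = field(
        default_factory=lambda: {"5p_trf": 3, "3p_trf": 3, "i_trf": 3, "trf1": 3, "5pU_trf": 2}
    )
    # cohort
    n_tumor: int = 16
    n_normal: int = 9
    baseline_mean: float = 200.0
    nb_dispersion: float = 0.3
    planted_log2fc: dict = field(default_factory=dict)  # signature_id -> log2FC
    # reads
    background_fraction: float = 0.2
    error_rate: float = 0.0
    # survival
    baseline_hazard: float = 0.02
    planted_beta: dict = field(default_factory=dict)  # signature_id -> log-HR per SD
    censor_max: float = 150.0
    # pathology
    pathology_assoc: float = 1.0  # log-odds of 'present' per SD of biomarker
    # mRNA
    n_mrna: int = 200
    n_correlated: int = 50
    planted_rho: float = 0.8  # Spearman, within tumor samples
    # UTRs
    n_utrs: int = 20
    utr_length: int = 100

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for frac in (self.background_fraction, self.error_rate):
            if not 0 <= frac <= 1:
                raise ValueError("fractions/rates must lie in [0, 1]")
        if abs(self.planted_rho) > 0.99:
            raise ValueError("infeasible correlation: |rho| > 0.99")


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def make_reference(
    config: SimulationConfig, outdir: str | Path | None = None
) -> tuple[list[TRNAGeneRecord], ReferenceBundle]:
    """Random tRNA-like gene set with metadata and explicit flanks.

    Gene 1 and 2 form a His-GTG isodecoder pair: identical last 25 nt
    (so fragments ending at the mature 3' end hit both sequences and
    names carry ``-M2``), divergent elsewhere.
    """
    rng = np.random.default_rng(config.seed)
    chroms = ["chr1", "chr6", "chr15", "chr16"]
    genes: list[TRNAGeneRecord] = []
    family_counter: dict[str, int] = {}
    pos_cursor = 10_000

    his_len = int(rng.integers(*config.gene_length_range))
    his_a = _random_dna(rng, his_len)
    # isodecoder: same 3' 25-mer and 5' 12-mer, different middle
    mid = _random_dna(rng, his_len - 37)
    his_b = his_a[:12] + mid + his_a[-25:]
    if his_b == his_a:  # force at least one difference in the middle
        pos = 15
        alt = "A" if his_a[pos] != "A" else "C"
        his_b = his_b[:pos] + alt + his_b[pos + 1 :]

    seqs_meta: list[tuple[str, str, str]] = [("His", his_a, "GTG"), ("His", his_b, "GTG")]
    for i in range(max(0, config.n_genes - 2)):
        iso = config.isotypes[(i + 1) % len(config.isotypes)]
        length = int(rng.integers(*config.gene_length_range))
        seqs_meta.append((iso, _random_dna(rng, length), ISOTYPE_ANTICODONS[iso]))

    for idx, (iso, seq, anticodon) in enumerate(seqs_meta, start=1):
        family_counter.setdefault(iso, 0)
        if not (iso == "His" and idx == 2):  # isodecoders share family index
            family_counter[iso] += 1
        strand = "+" if rng.random() < 0.7 else "-"
        start = pos_cursor
        pos_cursor += len(seq) + 500
        genes.append(
            TRNAGeneRecord(
                gene_id=f"tRNA-{iso}-{anticodon}-{family_counter[iso]}-{idx}",
                isotype=iso,
                anticodon=anticodon,
                family_index=family_counter[iso],
                chromosome=chroms[idx % len(chroms)],
                strand=strand,
                genomic_start=start,
                genomic_end=start + len(seq) - 1,
                gene_sequence=seq,
                leader_seq=_random_dna(rng, config.leader_window),
                trailer_seq=_random_dna(rng, config.trailer_window),
            )
        )

    bundle = build_reference(
        genes, leader_window=config.leader_window, trailer_window=config.trailer_window
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "genes.fasta", "w") as fh:
            for g in genes:
                # FASTA carries plus-strand genomic sequence over the span
                seq = g.gene_sequence
                if g.strand == "-":
                    from .reference import revcomp
                    seq = revcomp(seq)
                fh.write(f">{g.gene_id}\n{seq}\n")
        meta = pd.DataFrame(
            [
                {
                    "gene_id": g.gene_id,
                    "isotype": g.isotype,
                    "anticodon": g.anticodon,
                    "family_index": g.family_index,
                    "chromosome": g.chromosome,
                    "strand": g.strand,
                    "genomic_start": g.genomic_start,
                    "genomic_end": g.genomic_end,
                    "intron_spans": "",
                    "leader_seq": g.leader_seq,
                    "trailer_seq": g.trailer_seq,
                }
                for g in genes
            ]
        )
        meta.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    return genes, bundle


def make_signatures(
    config: SimulationConfig, bundle: ReferenceBundle
) -> list[FragmentSignature]:
    """Engineer fragment signatures of each class from the reference."""
    rng = np.random.default_rng(config.seed + 1)
    gene_ids = bundle.gene_ids()
    pairs: list[tuple[str, str]] = []
    seen: set[str] = set()

    def take(seq: str, prefix: str) -> None:
        if seq not in seen and 16 <= len(seq) <= 35:
            seen.add(seq)
            pairs.append((f"{prefix}-{len(pairs) + 1:03d}", seq))

    spec = config.n_per_class
    for cls, want in spec.items():
        got = 0
        for gid in rng.permutation(gene_ids):
            if got >= want:
                break
            mature = bundle.matures[gid].sequence
            ctx = bundle.contexts[gid]
            length = int(rng.integers(17, 26))
            before = len(pairs)
            if cls == "5p_trf":
                start = 2 if bundle.matures[gid].has_g_minus1 else 1
                take(mature[start - 1 : start - 1 + length], "sig-5p")
            elif cls == "3p_trf":
                take(mature[-length:], "sig-3p")
            elif cls == "i_trf":
                take(mature[9 : 9 + length], "sig-i")
            elif cls == "trf1":
                take(ctx.trailer_sequence[:length], "sig-trf1")
            elif cls == "5pU_trf":
                take(ctx.leader_sequence[-length:], "sig-5pU")
            got += len(pairs) - before
    return build_catalog(pairs, bundle)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_cohort(
    config: SimulationConfig, catalog: list[FragmentSignature]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Counts, clinical table and mRNA matrix for a tumor/normal cohort.

    Returns ``(counts, clinical, mrna)``.  Counts are NB with mean
    ``baseline * 2^(log2FC * is_tumor)``; survival times (tumor samples)
    are exponential with hazard ``lambda0 * exp(beta * z)`` where z is
    the standardized log2 expression of each designated biomarker;
    censoring is uniform on (0, censor_max]; a binary pathology column
    (``invasion``) is Bernoulli with log-odds proportional to -z; the
    mRNA matrix gets ``n_correlated`` genes tied to the first biomarker
    at Spearman rho ``planted_rho`` through a Gaussian copula.
    """
    rng = np.random.default_rng(config.seed + 2)
    sig_ids = [s.signature_id for s in catalog]
    tumor_ids = [f"T{i + 1:02d}" for i in range(config.n_tumor)]
    normal_ids = [f"N{i + 1:02d}" for i in range(config.n_normal)]
    samples = tumor_ids + normal_ids
    is_tumor = np.array([1] * config.n_tumor + [0] * config.n_normal)

    base = config.baseline_mean * np.exp(rng.normal(0, 0.4, size=len(sig_ids)))
    lfc = np.array([config.planted_log2fc.get(s, 0.0) for s in sig_ids])
    mean = base[:, None] * np.power(2.0, lfc[:, None] * is_tumor[None, :])
    counts = pd.DataFrame(
        _nb_draw(rng, mean, config.nb_dispersion), index=sig_ids, columns=samples
    )
    counts.index.name = "signature_id"

    # paired design bookkeeping: first n_normal tumors pair with the normals
    pair = {}
    for i, nid in enumerate(normal_ids):
        pair[tumor_ids[i]] = f"P{i + 1:02d}"
        pair[nid] = f"P{i + 1:02d}"

    logexpr = np.log2(counts / counts.sum(axis=0) * 1e6 + 1.0)
    biomarkers = list(config.planted_beta) or (sig_ids[:1])
    z_by_marker = {}
    for sig in biomarkers:
        v = logexpr.loc[sig, tumor_ids].to_numpy()
        sd = v.std()
        z_by_marker[sig] = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    hazard = config.baseline_hazard * np.ones(config.n_tumor)
    for sig, beta in config.planted_beta.items():
        hazard = hazard * np.exp(beta * z_by_marker[sig])
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.uniform(0, config.censor_max, size=config.n_tumor)
    os_time = np.minimum(t_event, t_cens)
    os_event = (t_event <= t_cens).astype(int)

    z0 = z_by_marker[biomarkers[0]]
    p_invasion = 1.0 / (1.0 + np.exp(config.pathology_assoc * z0))
    invasion = np.where(rng.random(config.n_tumor) < p_invasion, "present", "absent")
    stages = rng.choice(["I", "II", "III", "IV"], size=config.n_tumor, p=[0.2, 0.3, 0.3, 0.2])

    clinical = pd.DataFrame(
        {
            "sample_id": samples,
            "group": ["tumor"] * config.n_tumor + ["normal"] * config.n_normal,
            "pair_id": [pair.get(s, "") for s in samples],
            "os_time": list(np.round(os_time, 3)) + [np.nan] * config.n_normal,
            "os_event": list(os_event) + [-1] * config.n_normal,
            "age": rng.integers(40, 85, size=len(samples)),
            "stage": list(stages) + [""] * config.n_normal,
            "invasion": list(invasion) + [""] * config.n_normal,
        }
    ).set_index("sample_id")

    # mRNA matrix over tumor samples, Gaussian copula on the biomarker ranks
    n_t = config.n_tumor
    ranks = pd.Series(z0).rank().to_numpy()
    u = (ranks - 0.5) / n_t
    from scipy import stats as _st

    latent0 = _st.norm.ppf(u)
    r = 2.0 * np.sin(np.pi * config.planted_rho / 6.0)  # Spearman -> Pearson latent
    mrna = np.empty((config.n_mrna, n_t))
    for g in range(config.n_mrna):
        eps = rng.normal(size=n_t)
        if g < config.n_correlated:
            lat = r * latent0 + np.sqrt(1 - r * r) * eps
        else:
            lat = eps
        mrna[g] = np.exp(0.5 * lat + 3.0)  # monotone map keeps Spearman intact
    mrna_df = pd.DataFrame(
        mrna,
        index=[f"GENE{g + 1:04d}" for g in range(config.n_mrna)],
        columns=tumor_ids,
    )
    return counts, clinical, mrna_df


def simulate_reads(
    config: SimulationConfig,
    catalog: list[FragmentSignature],
    counts: pd.DataFrame,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write one FASTQ per sample reproducing the given counts.

    Each signature contributes exactly its count in reads (per-base
    substitution noise at ``error_rate`` applied afterwards), topped up
    with background reads (random 16-35-mers never matching a catalog
    sequence) so background is ~``background_fraction`` of the library.
    """
    rng = np.random.default_rng(config.seed + 3)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seqs = {s.signature_id: s.sequence for s in catalog}
    sig_set = set(seqs.values())
    paths: dict[str, Path] = {}

    for sample in counts.columns:
        path = outdir / f"{sample}.fastq"
        with open(path, "w") as fh:
            read_no = 0
            for sig_id, count in counts[sample].items():
                seq = seqs[sig_id]
                for _ in range(int(count)):
                    read = seq
                    if config.error_rate > 0:
                        arr = np.array(list(read))
                        hit = rng.random(len(arr)) < config.error_rate
                        for k in np.nonzero(hit)[0]:
                            choices = [b for b in "ACGT" if b != arr[k]]
                            arr[k] = choices[int(rng.integers(3))]
                        read = "".join(arr)
                    read_no += 1
                    fh.write(f"@{sample}:r{read_no}\n{read}\n+\n{'I' * len(read)}\n")
            assigned = int(counts[sample].sum())
            n_bg = int(
                round(
                    assigned * config.background_fraction / max(1e-9, 1 - config.background_fraction)
                )
            )
            made = 0
            while made < n_bg:
                bg = _random_dna(rng, int(rng.integers(16, 36)))
                if bg in sig_set:
                    continue
                read_no += 1
                fh.write(f"@{sample}:bg{read_no}\n{bg}\n+\n{'I' * len(bg)}\n")
                made += 1
        paths[sample] = path
    return paths


def make_utrs(
    config: SimulationConfig,
    trf_sequence: str,
    site_type: str = "7mer-m8",
    planted_fraction: float = 1.0,
) -> tuple[dict[str, str], dict[str, int]]:
    """Synthetic 3'UTRs with one planted seed site each.

    Returns (utrs, planted site start positions, 1-based).  UTR
    backgrounds are rejected-sampled to contain no spurious seed core.
    """
    from .reference import revcomp

    rng = np.random.default_rng(config.seed + 4)
    trf = trf_sequence.upper().replace("U", "T")
    core = revcomp(trf[1:7])
    m8 = revcomp(trf[7])
    if site_type == "6mer":
        insert = core
    elif site_type == "7mer-m8":
        insert = m8 + core
    elif site_type == "7mer-A1":
        insert = core + "A"
    elif site_type == "8mer":
        insert = m8 + core + "A"
    else:
        raise ValueError(f"unknown site type {site_type!r}")

    utrs: dict[str, str] = {}
    planted: dict[str, int] = {}
    n_planted = int(round(config.n_utrs * planted_fraction))
    for i in range(config.n_utrs):
        gene = f"UTR{i + 1:03d}"
        if i < n_planted:
            while True:
                bg = _random_dna(rng, config.utr_length)
                if core in bg:
                    continue
                offset = int(rng.integers(10, config.utr_length - len(insert) - 10))
                seq = bg[:offset] + insert + bg[offset + len(insert) :]
                # the splice must not create a second core occurrence
                if seq.count(core) == 1:
                    break
            utrs[gene] = seq
            planted[gene] = offset + 1
        else:
            while True:
                bg = _random_dna(rng, config.utr_length)
                if core not in bg:
                    break
            utrs[gene] = bg
    return utrs, planted
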